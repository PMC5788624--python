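"""Semi-quantitative in situ hybridization (ISH) scoring and association tests.

Nuclear miRNA staining on tissue-microarray cores is scored as the sum of a
staining-intensity tier (0 negative, 1 weak, 2 moderate, 3 strong) and a
frequency tier for the percentage of immunoreactive cells (0: 0%, 1: up to
33%, 2: up to 66%, 3: above 66%). The combined 0-6 score is dichotomized
into negative (0-2) vs positive (3-6), and associations between the
dichotomous call and tumor diagnosis are tested with Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import DegenerateDataError, DomainError
from .stats import fisher_exact_2x2

NEGATIVE = "negative"
POSITIVE = "positive"

#: Combined scores at or below this are called negative.
DICHOTOMY_CUTOFF = 2


def frequency_tier(percent: float) -> int:
    """Map % immunoreactive cells to the 4-tier frequency score.

    0% -> 0; (0, 33] -> 1; (33, 66] -> 2; (66, 100] -> 3. The published tier
    labels leave (33, 34) unassigned; the tiers here cover the percentage
    axis continuously, assigning that sliver to tier 2.
    """
    if not 0 <= percent <= 100:
        raise DomainError(f"percent immunoreactive cells {percent} outside [0, 100]")
    if percent == 0:
        return 0
    if percent <= 33:
        return 1
    if percent <= 66:
        return 2
    return 3


def combined_score(intensity: int, freq_tier: int) -> int:
    """Sum of intensity tier and frequency tier (0-6)."""
    for name, v in (("intensity", intensity), ("frequency tier", freq_tier)):
        if v not in (0, 1, 2, 3):
            raise DomainError(f"{name} must be an integer in 0..3, got {v}")
    return intensity + freq_tier


def dichotomize(score: int) -> str:
    """Negative (score 0-2) vs positive (score 3-6)."""
    if score not in range(0, 7):
        raise DomainError(f"combined score must be in 0..6, got {score}")
    return NEGATIVE if score <= DICHOTOMY_CUTOFF else POSITIVE


@dataclass(frozen=True)
class ISHRecord:
    """One scored core: raw tiers plus the derived score and call."""

    sample_id: str
    diagnosis: str
    mirna: str
    intensity: int
    pct_positive_cells: float

    @property
    def freq_tier(self) -> int:
        return frequency_tier(self.pct_positive_cells)

    @property
    def score(self) -> int:
        return combined_score(self.intensity, self.freq_tier)

    @property
    def call(self) -> str:
        return dichotomize(self.score)


def score_table(records: pd.DataFrame) -> pd.DataFrame:
    """Add derived columns (freq_tier, score, call) to an ISH table.

    Expects columns sample_id, diagnosis, mirna, intensity,
    pct_positive_cells; returns a copy with the three derived columns.
    """
    required = {"sample_id", "diagnosis", "mirna", "intensity", "pct_positive_cells"}
    missing = required - set(records.columns)
    if missing:
        raise DomainError(f"ISH table missing columns: {sorted(missing)}")
    out = records.copy()
    out["freq_tier"] = [frequency_tier(p) for p in out["pct_positive_cells"]]
    out["score"] = [
        combined_score(int(i), int(f)) for i, f in zip(out["intensity"], out["freq_tier"])
    ]
    out["call"] = [dichotomize(int(s)) for s in out["score"]]
    return out


def consensus_of_cores(scores: Sequence[int]) -> int:
    """Combine scores of replicate cores from one specimen (default: max)."""
    if len(scores) == 0:
        raise DomainError("no core scores to combine")
    return max(int(s) for s in scores)


@dataclass(frozen=True)
class AssociationResult:
    """2x2 association of dichotomized calls with a diagnosis pair."""

    mirna: str
    diagnoses: tuple[str, str]
    table: pd.DataFrame          # rows = diagnoses, cols = negative/positive
    odds_ratio: float | None
    p_value: float | None
    row_percent: pd.DataFrame    # share of each call within a diagnosis
    col_percent: pd.DataFrame    # share of each diagnosis within a call


def tabulate_association(
    records: pd.DataFrame, mirna: str, diagnoses: tuple[str, str]
) -> AssociationResult:
    """Cross-tabulate dichotomized calls against a diagnosis pair and test.

    Returns the 2x2 count table (rows in the order of ``diagnoses``, columns
    negative/positive), Fisher's exact odds ratio and two-sided p, and both
    row-wise and column-wise percentage views. Published ISH tables print
    column-wise percentages (share of all negatives / of all positives
    falling in each diagnosis) while prose tends to quote row-wise ones
    ("x% of ccRCC were positive"); both are reported so either reading can
    be checked. A degenerate margin (e.g. no positive calls at all) yields a
    warning and no test.
    """
    scored = records if "call" in records.columns else score_table(records)
    sub = scored[(scored["mirna"] == mirna) & (scored["diagnosis"].isin(diagnoses))]
    counts = pd.DataFrame(
        0, index=list(diagnoses), columns=[NEGATIVE, POSITIVE], dtype=int
    )
    for dx in diagnoses:
        for call in (NEGATIVE, POSITIVE):
            counts.loc[dx, call] = int(
                ((sub["diagnosis"] == dx) & (sub["call"] == call)).sum()
            )
    total = counts.values.sum()
    row_pct = counts.div(counts.sum(axis=1).replace(0, pd.NA), axis=0) * 100
    col_pct = counts.div(counts.sum(axis=0).replace(0, pd.NA), axis=1) * 100
    odds = p = None
    if total > 0:
        try:
            odds, p = fisher_exact_2x2(counts.values)
        except DegenerateDataError:
            warnings.warn(
                f"{mirna} {diagnoses}: a margin of the 2x2 table is zero; Fisher test skipped",
                stacklevel=2,
            )
    return AssociationResult(
        mirna=mirna,
        diagnoses=tuple(diagnoses),
        table=counts,
        odds_ratio=odds,
        p_value=p,
        row_percent=row_pct,
        col_percent=col_pct,
    )


def association_report(
    records: pd.DataFrame, comparisons: Sequence[tuple[str, tuple[str, str]]]
) -> pd.DataFrame:
    """Run tabulate_association for several (miRNA, diagnosis-pair) combos."""
    rows = []
    for mirna, pair in comparisons:
        res = tabulate_association(records, mirna, pair)
        a, b = pair
        rows.append(
            {
                "mirna": mirna,
                "comparison": f"{a} vs {b}",
                f"{a}_negative": res.table.loc[a, NEGATIVE],
                f"{a}_positive": res.table.loc[a, POSITIVE],
                f"{b}_negative": res.table.loc[b, NEGATIVE],
                f"{b}_positive": res.table.loc[b, POSITIVE],
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)
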