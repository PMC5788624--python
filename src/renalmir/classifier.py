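"""Two-step hierarchical subtype classifier for renal tumors.

Step 1 separates the proximal-nephron tumors (ccRCC, pRCC) from the distal
ones (chRCC, oncocytoma) using miR-222 with a 3-point cutoff: values above
the upper bound call distal (Category 1), values below the lower bound call
proximal (Category 3), and values inside the grey zone (Category 2) defer to
an optional single miR-221 cutoff. Step 2a separates ccRCC from pRCC by a
miR-126 cutoff, falling back to a miR-222 3-point call (682/358 copies) when
miR-126 is unavailable. Step 2b separates chRCC from oncocytoma by majority
vote over single cutoffs on miR-200b (197), miR-200c (180) and miR-222
(1399), each voting chRCC when expression is above its cutoff.

All comparisons are strict: a value exactly on a bound falls into the grey
zone (3-point calls) or the below-label (single cutoffs). Cutoffs are in
absolute copies on the same per-reaction scale as the standard curves and
are fully configurable; the defaults are the published ones where printed,
and ``None`` (to be derived from training data) where not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import panel
from .errors import (
    ConfigurationError,
    DegenerateDataError,
    MarkerMissingError,
    ThresholdDerivationError,
    UsageError,
)
from .stats import youden_cutoff

CATEGORY_ABOVE = 1   # above the upper bound
CATEGORY_GREY = 2    # strictly inside the grey zone (bounds inclusive)
CATEGORY_BELOW = 3   # below the lower bound


@dataclass(frozen=True)
class ThreePointZone:
    """A 3-point cutoff: upper/lower bounds with the grey zone between them.

    ``lower == upper`` encodes an empty grey zone (fully separated training
    data); only a value exactly equal to the bound then lands grey.
    """

    upper: float
    lower: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ConfigurationError(
                f"grey-zone lower bound {self.lower} exceeds upper bound {self.upper}"
            )
        if self.lower <= 0:
            raise ConfigurationError("cutoffs must be > 0 copies")


@dataclass(frozen=True)
class ClassifierThresholds:
    """All cutoffs of the two-step scheme, in absolute copies."""

    step1_mir222: ThreePointZone = ThreePointZone(upper=1205.0, lower=589.0)
    step1_mir221_cutoff: float | None = None  # not published; derive from training
    step2a_mir126_cutoff: float | None = None  # not published; derive from training
    step2a_mir222: ThreePointZone = ThreePointZone(upper=682.0, lower=358.0)
    step2b_mir200b_cutoff: float = 197.0
    step2b_mir200c_cutoff: float = 180.0
    step2b_mir222_cutoff: float = 1399.0

    def __post_init__(self) -> None:
        for name in ("step2b_mir200b_cutoff", "step2b_mir200c_cutoff", "step2b_mir222_cutoff"):
            v = getattr(self, name)
            if v <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {v}")
        for name in ("step1_mir221_cutoff", "step2a_mir126_cutoff"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {v}")

    def to_dict(self) -> dict:
        return {
            "step1": {
                "mir222_upper": self.step1_mir222.upper,
                "mir222_lower": self.step1_mir222.lower,
                "mir221_cutoff": self.step1_mir221_cutoff,
            },
            "step2a": {
                "mir126_cutoff": self.step2a_mir126_cutoff,
                "mir222_upper": self.step2a_mir222.upper,
                "mir222_lower": self.step2a_mir222.lower,
            },
            "step2b": {
                "mir200b_cutoff": self.step2b_mir200b_cutoff,
                "mir200c_cutoff": self.step2b_mir200c_cutoff,
                "mir222_cutoff": self.step2b_mir222_cutoff,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClassifierThresholds":
        try:
            s1, s2a, s2b = d["step1"], d["step2a"], d["step2b"]
            return cls(
                step1_mir222=ThreePointZone(upper=s1["mir222_upper"], lower=s1["mir222_lower"]),
                step1_mir221_cutoff=s1.get("mir221_cutoff"),
                step2a_mir126_cutoff=s2a.get("mir126_cutoff"),
                step2a_mir222=ThreePointZone(upper=s2a["mir222_upper"], lower=s2a["mir222_lower"]),
                step2b_mir200b_cutoff=s2b["mir200b_cutoff"],
                step2b_mir200c_cutoff=s2b["mir200c_cutoff"],
                step2b_mir222_cutoff=s2b["mir222_cutoff"],
            )
        except KeyError as e:
            raise ConfigurationError(f"thresholds config missing key: {e}") from e

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ClassifierThresholds":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class Vote:
    """One threshold comparison made during classification."""

    marker: str
    value: float
    threshold: float
    direction: str  # "above" or "below" or "grey"
    label: str      # label this vote supports ("" for grey)


@dataclass
class SubtypeCall:
    """Full classifier output for one sample, with provenance."""

    sample_id: str
    step1_group: str                 # proximal | distal | grey
    final: str                       # ccRCC | pRCC | chRCC | oncocytoma | indeterminate
    category: int | None = None      # miR-222 step-1 3-point category (1/2/3)
    votes: list[Vote] = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "step1_group": self.step1_group,
            "category": self.category,
            "final_call": self.final,
            "votes": json.dumps([asdict(v) for v in self.votes]),
        }


def three_point_call(
    value: float,
    upper: float,
    lower: float,
    above_label: str,
    below_label: str,
) -> tuple[str, int]:
    """Classify against a 3-point cutoff; returns (label-or-grey, category).

    Strictly above the upper bound -> ``above_label`` (Category 1); strictly
    below the lower bound -> ``below_label`` (Category 3); anything else,
    bounds included, is grey (Category 2).
    """
    if lower > upper:
        raise ConfigurationError(f"lower bound {lower} exceeds upper bound {upper}")
    if value > upper:
        return above_label, CATEGORY_ABOVE
    if value < lower:
        return below_label, CATEGORY_BELOW
    return panel.GREY, CATEGORY_GREY


def _get(sample: Mapping[str, float], marker: str) -> float | None:
    v = sample.get(marker)
    if v is None:
        return None
    v = float(v)
    return v if np.isfinite(v) else None


def step1_classify(
    sample: Mapping[str, float], t: ClassifierThresholds
) -> tuple[str, int | None, list[Vote]]:
    """Step 1: proximal (ccRCC/pRCC) vs distal (chRCC/oncocytoma).

    Primary decision: miR-222 3-point call. A grey miR-222 falls back to the
    single miR-221 cutoff when one is configured (above -> distal, otherwise
    proximal); with no miR-221 cutoff the sample stays grey.
    """
    votes: list[Vote] = []
    v222 = _get(sample, panel.MIR_222)
    if v222 is None:
        raise MarkerMissingError(panel.MIR_222, "step 1 requires miR-222")
    zone = t.step1_mir222
    label, cat = three_point_call(v222, zone.upper, zone.lower, panel.DISTAL, panel.PROXIMAL)
    votes.append(
        Vote(panel.MIR_222, v222, zone.upper if cat == CATEGORY_ABOVE else zone.lower,
             {1: "above", 2: "grey", 3: "below"}[cat], label if label != panel.GREY else "")
    )
    if label != panel.GREY:
        return label, cat, votes
    if t.step1_mir221_cutoff is not None:
        v221 = _get(sample, panel.MIR_221)
        if v221 is not None:
            if v221 > t.step1_mir221_cutoff:
                votes.append(Vote(panel.MIR_221, v221, t.step1_mir221_cutoff, "above", panel.DISTAL))
                return panel.DISTAL, cat, votes
            votes.append(Vote(panel.MIR_221, v221, t.step1_mir221_cutoff, "below", panel.PROXIMAL))
            return panel.PROXIMAL, cat, votes
    return panel.GREY, cat, votes


def step2a_classify(
    sample: Mapping[str, float], t: ClassifierThresholds, step1_group: str = panel.PROXIMAL
) -> tuple[str, list[Vote]]:
    """Step 2a: ccRCC vs pRCC among proximal tumors.

    miR-126 (above its cutoff -> ccRCC) is primary; when miR-126 or its
    cutoff is unavailable, the miR-222 3-point call at 682/358 copies is
    used; a grey miR-222, or neither marker available, is indeterminate.
    """
    if step1_group != panel.PROXIMAL:
        raise UsageError(f"step2a applies to proximal samples, got step-1 group {step1_group!r}")
    votes: list[Vote] = []
    v126 = _get(sample, panel.MIR_126)
    if v126 is not None and t.step2a_mir126_cutoff is not None:
        if v126 > t.step2a_mir126_cutoff:
            votes.append(Vote(panel.MIR_126, v126, t.step2a_mir126_cutoff, "above", panel.CCRCC))
            return panel.CCRCC, votes
        votes.append(Vote(panel.MIR_126, v126, t.step2a_mir126_cutoff, "below", panel.PRCC))
        return panel.PRCC, votes
    v222 = _get(sample, panel.MIR_222)
    if v222 is not None:
        zone = t.step2a_mir222
        label, cat = three_point_call(v222, zone.upper, zone.lower, panel.CCRCC, panel.PRCC)
        votes.append(
            Vote(panel.MIR_222, v222, zone.upper if cat == CATEGORY_ABOVE else zone.lower,
                 {1: "above", 2: "grey", 3: "below"}[cat], label if label != panel.GREY else "")
        )
        if label != panel.GREY:
            return label, votes
    return panel.INDETERMINATE, votes


def step2b_classify(
    sample: Mapping[str, float], t: ClassifierThresholds, step1_group: str = panel.DISTAL
) -> tuple[str, list[Vote]]:
    """Step 2b: chRCC vs oncocytoma among distal tumors, by majority vote.

    Each available marker votes chRCC when above its cutoff (miR-200b 197,
    miR-200c 180, miR-222 1399 copies), otherwise oncocytoma. A tie or no
    available marker is indeterminate.
    """
    if step1_group != panel.DISTAL:
        raise UsageError(f"step2b applies to distal samples, got step-1 group {step1_group!r}")
    cutoffs = (
        (panel.MIR_200B, t.step2b_mir200b_cutoff),
        (panel.MIR_200C, t.step2b_mir200c_cutoff),
        (panel.MIR_222, t.step2b_mir222_cutoff),
    )
    votes: list[Vote] = []
    n_ch = n_onco = 0
    for marker, cut in cutoffs:
        v = _get(sample, marker)
        if v is None:
            continue
        if v > cut:
            votes.append(Vote(marker, v, cut, "above", panel.CHRCC))
            n_ch += 1
        else:
            votes.append(Vote(marker, v, cut, "below", panel.ONCOCYTOMA))
            n_onco += 1
    if n_ch > n_onco:
        return panel.CHRCC, votes
    if n_onco > n_ch:
        return panel.ONCOCYTOMA, votes
    return panel.INDETERMINATE, votes


def classify(
    sample: Mapping[str, float], t: ClassifierThresholds, sample_id: str = ""
) -> SubtypeCall:
    """Run the full two-step scheme on one sample's copy numbers."""
    group, cat, votes = step1_classify(sample, t)
    if group == panel.GREY:
        return SubtypeCall(sample_id, panel.GREY, panel.INDETERMINATE, cat, votes)
    if group == panel.PROXIMAL:
        final, v2 = step2a_classify(sample, t, group)
    else:
        final, v2 = step2b_classify(sample, t, group)
    return SubtypeCall(sample_id, group, final, cat, votes + v2)


def classify_table(
    expression: pd.DataFrame, t: ClassifierThresholds
) -> pd.DataFrame:
    """Classify every row of a samples x miRNAs copy matrix."""
    calls = []
    for sid, row in expression.iterrows():
        sample = {k: v for k, v in row.items() if isinstance(v, (int, float, np.floating))}
        calls.append(classify(sample, t, sample_id=str(sid)).to_row())
    return pd.DataFrame(calls)


# ---------------------------------------------------------------------------
# Threshold derivation from labelled training data
# ---------------------------------------------------------------------------

def derive_grey_zone(
    values: Sequence[float],
    is_above_class: Sequence[bool],
    purity_target: float = 0.97,
) -> ThreePointZone:
    """Tightest grey zone reaching ``purity_target`` purity on each side.

    The upper bound is the smallest candidate cutoff (midpoints between
    adjacent distinct values) such that the fraction of above-class samples
    among all samples strictly above it is at least ``purity_target``; the
    lower bound is symmetric for the below class. When the two cross (the
    classes separate at the target already), the grey zone is empty and both
    bounds collapse onto a single cutoff between them.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(is_above_class, dtype=bool)
    if lab.all() or (~lab).all():
        raise ThresholdDerivationError("both classes must be present to derive a grey zone")
    if np.ptp(v[lab]) == 0 and np.ptp(v[~lab]) == 0 and v[lab][0] == v[~lab][0]:
        raise DegenerateDataError("classes are constant and identical; cannot derive bounds")
    uniq = np.unique(v)
    if len(uniq) < 2:
        raise DegenerateDataError("need at least two distinct values")
    cands = (uniq[:-1] + uniq[1:]) / 2.0

    upper = None
    for c in cands:  # ascending: first hit is the smallest adequate upper bound
        above = v > c
        if above.any() and lab[above].mean() >= purity_target:
            upper = float(c)
            break
    lower = None
    for c in cands[::-1]:
        below = v < c
        if below.any() and (~lab[below]).mean() >= purity_target:
            lower = float(c)
            break
    if upper is None or lower is None:
        raise ThresholdDerivationError(
            f"no cutoff achieves per-side purity {purity_target}; classes too interleaved"
        )
    if lower > upper:  # fully separated at the target: empty grey zone
        mid = (lower + upper) / 2.0
        return ThreePointZone(upper=mid, lower=mid)
    return ThreePointZone(upper=upper, lower=lower)


def fill_unset_cutoffs(
    t: ClassifierThresholds, expression: pd.DataFrame, labels: Sequence[str]
) -> ClassifierThresholds:
    """Derive the unpublished single cutoffs from labelled training data.

    The miR-221 step-1 fallback cutoff and the miR-126 step-2a cutoff were
    never printed; when they are ``None`` this derives each by the Youden
    index on the training ROC and returns a completed threshold set. Grey
    zones and the published single cutoffs are left untouched.
    """
    lab = np.asarray(labels)
    mir221 = t.step1_mir221_cutoff
    mir126 = t.step2a_mir126_cutoff
    is_distal = np.isin(lab, [panel.CHRCC, panel.ONCOCYTOMA])
    if mir221 is None and panel.MIR_221 in expression.columns:
        v = np.asarray(expression[panel.MIR_221], dtype=float)
        mir221 = youden_cutoff(v[is_distal], v[~is_distal])[0]
    if mir126 is None and panel.MIR_126 in expression.columns:
        v = np.asarray(expression[panel.MIR_126], dtype=float)
        is_cc = lab == panel.CCRCC
        mir126 = youden_cutoff(v[is_cc], v[~is_distal & ~is_cc])[0]
    return ClassifierThresholds(
        step1_mir222=t.step1_mir222,
        step1_mir221_cutoff=mir221,
        step2a_mir126_cutoff=mir126,
        step2a_mir222=t.step2a_mir222,
        step2b_mir200b_cutoff=t.step2b_mir200b_cutoff,
        step2b_mir200c_cutoff=t.step2b_mir200c_cutoff,
        step2b_mir222_cutoff=t.step2b_mir222_cutoff,
    )


def derive_thresholds(
    expression: pd.DataFrame,
    labels: Sequence[str],
    purity_target: float = 0.97,
) -> ClassifierThresholds:
    """Derive the full threshold set from a labelled training cohort.

    Grey-zone bounds (miR-222 at steps 1 and 2a) come from
    :func:`derive_grey_zone` at ``purity_target``; all single cutoffs come
    from the Youden index on the training ROC. ``expression`` is a samples x
    miRNAs copy matrix; ``labels`` the matching histology calls.
    """
    lab = np.asarray(labels)
    for subtype, count in zip(*np.unique(lab, return_counts=True)):
        if count < 2:
            raise ThresholdDerivationError(f"need >= 2 training samples per class, {subtype} has {count}")
    is_distal = np.isin(lab, [panel.CHRCC, panel.ONCOCYTOMA])
    prox = expression[~is_distal]
    dist = expression[is_distal]
    is_cc = lab[~is_distal] == panel.CCRCC
    is_ch = lab[is_distal] == panel.CHRCC

    def _col(df: pd.DataFrame, marker: str) -> np.ndarray:
        if marker not in df.columns:
            raise MarkerMissingError(marker, "threshold derivation")
        return np.asarray(df[marker], dtype=float)

    def _youden(pos: np.ndarray, neg: np.ndarray, what: str) -> float:
        if np.ptp(pos) == 0 and np.ptp(neg) == 0 and pos[0] == neg[0]:
            raise DegenerateDataError(f"constant values; cannot derive {what} cutoff")
        return youden_cutoff(pos, neg)[0]

    v222 = _col(expression, panel.MIR_222)
    step1_zone = derive_grey_zone(v222, is_distal, purity_target)
    mir221 = _youden(_col(dist, panel.MIR_221), _col(prox, panel.MIR_221), "miR-221 step-1")
    v222p = _col(prox, panel.MIR_222)
    step2a_zone = derive_grey_zone(v222p, is_cc, purity_target)
    mir126 = _youden(_col(prox, panel.MIR_126)[is_cc], _col(prox, panel.MIR_126)[~is_cc], "miR-126")
    v200b = _col(dist, panel.MIR_200B)
    v200c = _col(dist, panel.MIR_200C)
    v222d = _col(dist, panel.MIR_222)
    return ClassifierThresholds(
        step1_mir222=step1_zone,
        step1_mir221_cutoff=mir221,
        step2a_mir126_cutoff=mir126,
        step2a_mir222=step2a_zone,
        step2b_mir200b_cutoff=_youden(v200b[is_ch], v200b[~is_ch], "miR-200b"),
        step2b_mir200c_cutoff=_youden(v200c[is_ch], v200c[~is_ch], "miR-200c"),
        step2b_mir222_cutoff=_youden(v222d[is_ch], v222d[~is_ch], "miR-222 step-2b"),
    )
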