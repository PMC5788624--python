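"""Absolute qRT-PCR quantification via log-linear standard curves.

A standard curve relates the PCR cycle threshold (Ct) to the natural log of
input copy number for one miRNA:

    Ct = m * ln(copies) + b        (m < 0 for an amplifying assay)

fitted by ordinary least squares to a serial-dilution series of a synthetic
oligonucleotide of known copy number. Sample Ct values are then interpolated
back to absolute copies. Ct values above ``CT_TRUNCATION`` (35 cycles) are
considered non-expressed and truncated to 35 before any conversion; the
truncation is applied per replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, DomainError, InsufficientDataError

#: Ct above this is treated as non-expressed and truncated.
CT_TRUNCATION = 35.0

AVOGADRO = 6.02214076e23

# Average residue mass of single-stranded RNA plus the 5'-triphosphate /
# end-group correction, in g/mol.
RNA_MASS_PER_NT = 320.5
RNA_MASS_END = 159.0


def rna_molecular_weight(length_nt: int) -> float:
    """Molecular weight (g/mol) of a single-stranded RNA oligo of ``length_nt``."""
    if length_nt < 1:
        raise DomainError(f"oligo length must be >= 1 nt, got {length_nt}")
    return length_nt * RNA_MASS_PER_NT + RNA_MASS_END


def oligo_copy_number(mass_ng: float, length_nt: int) -> float:
    """Number of molecules in ``mass_ng`` nanograms of an RNA oligo.

    copies = mass[g] / MW[g/mol] * N_A, with MW = 320.5*N + 159.0.
    """
    if mass_ng < 0:
        raise DomainError(f"mass must be >= 0 ng, got {mass_ng}")
    mw = rna_molecular_weight(length_nt)
    return mass_ng * 1e-9 / mw * AVOGADRO


@dataclass(frozen=True)
class CtRecord:
    """Raw triplicate Ct measurements for one (sample, miRNA) pair."""

    sample_id: str
    mirna: str
    cts: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cts) < 1:
            raise DomainError("CtRecord needs at least one replicate Ct")
        for ct in self.cts:
            if not (0 < ct <= 50):
                raise DomainError(f"Ct {ct} outside (0, 50]")


@dataclass(frozen=True)
class StandardCurve:
    """Fitted log-linear standard curve for one miRNA.

    ``slope`` is in Ct per natural-log copy (negative), ``intercept`` is the
    Ct at 1 copy, and ``copy_range`` records the span of the dilution points
    used in the fit.
    """

    mirna: str
    slope: float
    intercept: float
    r_squared: float
    copy_range: tuple[float, float] = field(default=(1.0, 1e12))

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise DomainError(f"standard-curve slope must be negative, got {self.slope}")
        if not (0 <= self.r_squared <= 1 + 1e-12):
            raise DomainError(f"r^2 {self.r_squared} outside [0, 1]")
        lo, hi = self.copy_range
        if not lo < hi:
            raise DomainError(f"copy range min {lo} must be < max {hi}")

    def predict_ct(self, copies: float) -> float:
        """Forward model: expected Ct for a given copy number."""
        if copies <= 0:
            raise DomainError(f"copies must be > 0, got {copies}")
        return self.slope * math.log(copies) + self.intercept


def fit_standard_curve(
    series: pd.DataFrame,
    mirna: str = "",
    linear_range: tuple[float, float] | None = None,
) -> StandardCurve:
    """OLS fit of Ct on ln(copies) over a dilution series.

    ``series`` must have columns ``copies`` and ``ct``. Points with copies
    outside ``linear_range`` (min, max copies, inclusive) are excluded before
    fitting, mirroring the practice of fitting only the linear range of the
    dilution series.
    """
    if not {"copies", "ct"}.issubset(series.columns):
        raise DomainError("dilution series needs 'copies' and 'ct' columns")
    copies = np.asarray(series["copies"], dtype=float)
    ct = np.asarray(series["ct"], dtype=float)
    if np.any(copies <= 0):
        raise DomainError("all dilution-series copy numbers must be > 0")
    if linear_range is not None:
        lo, hi = linear_range
        keep = (copies >= lo) & (copies <= hi)
        copies, ct = copies[keep], ct[keep]
    if len(np.unique(copies)) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct copy values to fit a curve, have {len(np.unique(copies))}"
        )
    x = np.log(copies)
    if np.ptp(x) == 0:
        raise DegenerateDataError("zero variance in ln(copies); cannot fit")
    fit = stats.linregress(x, ct)
    return StandardCurve(
        mirna=mirna,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        copy_range=(float(copies.min()), float(copies.max())),
    )


def truncate_ct(ct: float) -> tuple[float, bool]:
    """Apply the non-expression rule: Ct > 35 is truncated to 35 and flagged."""
    if ct > CT_TRUNCATION:
        return CT_TRUNCATION, True
    return ct, False


def ct_to_copies(ct: float, curve: StandardCurve) -> tuple[float, bool]:
    """Interpolate absolute copies from a Ct value.

    Returns ``(copies, expressed)``. A Ct above 35 is truncated to 35 before
    conversion and flagged as non-expressed (``expressed=False``); the sample
    still receives the copy number implied by Ct = 35 so downstream stages
    always see a number.
    """
    ct_eff, truncated = truncate_ct(ct)
    copies = math.exp((ct_eff - curve.intercept) / curve.slope)
    return copies, not truncated


@dataclass(frozen=True)
class QuantResult:
    """Per-sample quantification with replicate spread."""

    sample_id: str
    mirna: str
    copies: float
    mean_ct: float
    ct_sd: float
    expressed: bool
    n_replicates: int
    n_truncated: int


def aggregate_replicates(record: CtRecord, curve: StandardCurve) -> QuantResult:
    """Average replicate Cts, then convert once to copies.

    Each replicate is truncated at 35 first (the non-expression rule is
    stated per Ct value), replicates are averaged on the Ct scale — the
    measured quantity — and the mean Ct is converted via the standard curve.
    Averaging on the Ct scale corresponds to a geometric mean of per-replicate
    copies, which is the conventional choice for qPCR; averaging copies
    arithmetically would weight low-Ct replicates more heavily.
    """
    truncated = [truncate_ct(ct) for ct in record.cts]
    cts = np.array([t[0] for t in truncated])
    n_trunc = sum(t[1] for t in truncated)
    mean_ct = float(cts.mean())
    ct_sd = float(cts.std(ddof=1)) if len(cts) > 1 else 0.0
    copies, expressed = ct_to_copies(mean_ct, curve)
    return QuantResult(
        sample_id=record.sample_id,
        mirna=record.mirna,
        copies=copies,
        mean_ct=mean_ct,
        ct_sd=ct_sd,
        expressed=expressed,
        n_replicates=len(cts),
        n_truncated=n_trunc,
    )


def quantify_ct_table(
    ct_table: pd.DataFrame, curves: dict[str, StandardCurve]
) -> pd.DataFrame:
    """Quantify a long-format Ct table into a samples x miRNAs copy matrix.

    ``ct_table`` columns: ``sample_id``, ``mirna``, ``ct`` (one row per
    replicate). Returns a wide DataFrame indexed by sample_id with one column
    per miRNA, in absolute copies.
    """
    required = {"sample_id", "mirna", "ct"}
    if not required.issubset(ct_table.columns):
        missing = required - set(ct_table.columns)
        raise DomainError(f"Ct table missing columns: {sorted(missing)}")
    rows = []
    for (sid, mir), grp in ct_table.groupby(["sample_id", "mirna"], sort=True):
        if mir not in curves:
            raise DomainError(f"no standard curve for marker {mir!r}")
        rec = CtRecord(str(sid), str(mir), tuple(float(c) for c in grp["ct"]))
        q = aggregate_replicates(rec, curves[mir])
        rows.append({"sample_id": q.sample_id, "mirna": q.mirna, "copies": q.copies})
    long = pd.DataFrame(rows)
    wide = long.pivot(index="sample_id", columns="mirna", values="copies")
    wide.columns.name = None
    return wide


def expression_to_ct(
    expression: pd.DataFrame,
    curves: dict[str, StandardCurve],
    replicates: int = 3,
    ct_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Forward-simulate a replicate Ct table from a copy matrix.

    Inverse of :func:`quantify_ct_table` up to replicate noise; used to
    exercise the quantification stage end-to-end on synthetic cohorts.
    """
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for sid, row in expression.iterrows():
        for mir, copies in row.items():
            if mir not in curves:
                continue
            base = curves[mir].predict_ct(float(copies))
            for rep in range(1, replicates + 1):
                ct = base + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                rows.append(
                    {"sample_id": sid, "mirna": mir, "replicate": rep, "ct": float(np.clip(ct, 1e-6, 50.0))}
                )
    return pd.DataFrame(rows)
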