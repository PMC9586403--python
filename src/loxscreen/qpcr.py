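"""qPCR standard-curve quantification and concordance with sequencing.

Three primer sets interrogate each sample: an amplicon spanning an
intact (non-cleaved) cassette, one spanning the loxP excision junction,
and one spanning the lox2272 excision junction.  Each assay is
calibrated against its own 10-fold dilution series (7 points,
1e7 copies/uL down to 1 copy/uL) by least squares of Cq on log10
copies; quantified copy numbers then enter the same rate algebra as the
sequencing counts, which makes the two routes directly comparable.

Amplification efficiency is reported as 10^(-1/slope) - 1 (1.0 = perfect
doubling per cycle, slope -3.32).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

ASSAYS = ("NC", "loxP", "lox2272")

#: Default dilution series: 7 points, 10-fold, 1e7 down to 1 copy/uL.
DEFAULT_DILUTION_COPIES = tuple(10.0 ** k for k in range(7, 0, -1))


class CalibrationError(ValueError):
    """Standard-curve fit impossible or non-physical."""


@dataclasses.dataclass(frozen=True)
class StandardCurve:
    """Linear calibration Cq = intercept + slope * log10(copies)."""

    slope: float
    intercept: float
    r_squared: float
    copy_range: tuple[float, float] = (1.0, 1e7)

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise CalibrationError(f"slope must be negative, got {self.slope}")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise CalibrationError("r_squared must be in [0, 1]")

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency, 1.0 = perfect doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def cq(self, copies: float) -> float:
        """Expected Cq for a given copy number (the curve's forward map)."""
        return self.intercept + self.slope * np.log10(copies)


@dataclasses.dataclass(frozen=True)
class QpcrMeasurement:
    """Quantified copies of the three assays for one sample/replicate."""

    sample: str
    nc_copies: float
    loxp_copies: float
    lox2272_copies: float
    replicate: int = 1

    def __post_init__(self) -> None:
        for v in (self.nc_copies, self.loxp_copies, self.lox2272_copies):
            if v < 0:
                raise ValueError("copy numbers must be non-negative")


def fit_standard_curve(
    copies: Sequence[float], cq: Sequence[float]
) -> StandardCurve:
    """Least-squares calibration of Cq against log10 copies.

    Requires at least 3 distinct positive copy levels and a negative
    fitted slope.
    """
    copies = np.asarray(copies, dtype=float)
    cq = np.asarray(cq, dtype=float)
    if copies.shape != cq.shape:
        raise CalibrationError("copies and cq must have equal length")
    if np.any(copies <= 0):
        raise CalibrationError("copy numbers must be positive")
    if len(np.unique(copies)) < 3:
        raise CalibrationError("need >= 3 distinct copy levels")
    fit = stats.linregress(np.log10(copies), cq)
    if fit.slope >= 0:
        raise CalibrationError(f"non-negative slope {fit.slope:.3f}: bad series")
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        copy_range=(float(copies.min()), float(copies.max())),
    )


def quantify(curve: StandardCurve, cq: float) -> float:
    """Invert the calibration: copies = 10^((cq - intercept)/slope)."""
    return float(10.0 ** ((cq - curve.intercept) / curve.slope))


def is_extrapolated(curve: StandardCurve, copies: float) -> bool:
    lo, hi = curve.copy_range
    return not lo <= copies <= hi


def rates_from_copies(m: QpcrMeasurement) -> tuple[float, float]:
    """(non-cleavage %, loxP cleavage %) from the three copy numbers.

    Same algebra as the sequencing route; invariant to scaling all three
    assays by a common positive factor (absolute copy calibration
    cancels).
    """
    cleaved = m.loxp_copies + m.lox2272_copies
    total = m.nc_copies + cleaved
    if total == 0:
        raise ZeroDivisionError("all three assays are zero")
    non_cleavage = 100.0 * m.nc_copies / total
    if cleaved == 0:
        raise ZeroDivisionError("no cleaved copies: loxP rate undefined")
    loxp_rate = 100.0 * m.loxp_copies / cleaved
    return non_cleavage, loxp_rate


def concordance(ngs_rates: Sequence[float], qpcr_rates: Sequence[float]) -> float:
    """Squared Pearson correlation between the two quantification routes."""
    x = np.asarray(ngs_rates, dtype=float)
    y = np.asarray(qpcr_rates, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, _ = stats.pearsonr(x, y)
    return float(r**2)


def simulate_cq(
    curve: StandardCurve,
    copies: Sequence[float],
    *,
    noise_sd: float = 0.15,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Cq values for given copy numbers with Gaussian cycle noise."""
    rng = np.random.default_rng(seed)
    copies = np.asarray(copies, dtype=float)
    return curve.cq(copies) + rng.normal(0.0, noise_sd, size=copies.shape)


def quantify_samples(
    cq_table: pd.DataFrame, curves: dict[str, StandardCurve]
) -> pd.DataFrame:
    """Per-sample rates from a long-format Cq table.

    ``cq_table`` columns: sample, assay (NC/loxP/lox2272), replicate, cq.
    Replicates are averaged on the copy scale (rates are ratios of
    copies, so averaging Cq would bias them); output has one row per
    sample with non_cleavage_rate_pct, cleavage_rate_pct and n_replicates.
    """
    required = {"sample", "assay", "replicate", "cq"}
    if not required.issubset(cq_table.columns):
        raise ValueError(f"cq table must have columns {sorted(required)}")
    unknown = set(cq_table["assay"]) - set(ASSAYS)
    if unknown:
        raise ValueError(f"unknown assays {sorted(unknown)}; expected {ASSAYS}")
    rows = []
    for sample, grp in cq_table.groupby("sample", sort=True):
        mean_copies = {}
        for assay in ASSAYS:
            sub = grp[grp["assay"] == assay]
            if sub.empty:
                raise ValueError(f"sample {sample!r} lacks assay {assay!r}")
            mean_copies[assay] = float(
                np.mean([quantify(curves[assay], c) for c in sub["cq"]])
            )
        m = QpcrMeasurement(
            sample=str(sample),
            nc_copies=mean_copies["NC"],
            loxp_copies=mean_copies["loxP"],
            lox2272_copies=mean_copies["lox2272"],
        )
        nc, lp = rates_from_copies(m)
        rows.append(
            {
                "sample": sample,
                "non_cleavage_rate_pct": nc,
                "cleavage_rate_pct": lp,
                "n_replicates": int(grp["replicate"].nunique()),
            }
        )
    return pd.DataFrame(rows)


def cre_dependence_test(
    nc_rates_uninduced: Sequence[float], nc_rates_induced: Sequence[float]
) -> tuple[float, float]:
    """Welch two-tailed t-test that induction lowers the non-cleavage rate.

    Returns (t statistic, p value).  With Cre off essentially every
    molecule stays intact (non-cleavage ~100%); induction should drop it
    to a few percent.
    """
    t, p = stats.ttest_ind(
        nc_rates_uninduced, nc_rates_induced, equal_var=False
    )
    return float(t), float(p)
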