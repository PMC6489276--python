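"""Dose-response statistics: voxel-wise ΔHU, 5-Gy binning, correlation and
zero-intercept regression.

The quantitative model is the one used throughout the voxel-based lung
density literature: each analyzed parenchyma voxel contributes a pair
(D, ΔHU) of planned dose and Hounsfield-unit change between the deformed
follow-up scan and the planning scan (positive = densification).  Pairs are
aggregated in half-open 5-Gy dose strata, rank-correlated (Spearman), and fit
with a linear regression forced through the origin,

    ΔHU = b · D,      b̂ = Σ dᵢ yᵢ / Σ dᵢ²   [HU/Gy],

with the usual no-intercept t inference on n−1 residual degrees of freedom.
The zero intercept encodes the physical constraint that unirradiated lung is
expected to show no dose-driven density change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .volumes import BinaryMask, ScalarVolume

__all__ = [
    "VoxelPairTable",
    "DoseBinSummary",
    "RegressionResult",
    "CorrelationResult",
    "compute_delta",
    "bin_by_dose",
    "spearman_correlation",
    "fit_zero_intercept",
    "per_patient_results",
    "pooled_results",
    "compare_groups",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class VoxelPairTable:
    """Flat (dose, ΔHU) pairs for one patient/timepoint, plus an exclusion ledger."""

    data: pd.DataFrame  # columns: dose, delta_hu, patient_id, timepoint
    excluded: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.data) and (self.data["dose"] < 0).any():
            raise ValueError("dose must be >= 0 for every voxel pair")

    @property
    def n(self) -> int:
        return len(self.data)

    @staticmethod
    def concat(tables: list["VoxelPairTable"]) -> "VoxelPairTable":
        if not tables:
            return VoxelPairTable(
                data=pd.DataFrame(columns=["dose", "delta_hu", "patient_id", "timepoint"]),
                excluded={},
            )
        excluded: dict[str, int] = {}
        for t in tables:
            for k, v in t.excluded.items():
                excluded[k] = excluded.get(k, 0) + v
        return VoxelPairTable(
            data=pd.concat([t.data for t in tables], ignore_index=True), excluded=excluded
        )


@dataclass(frozen=True)
class DoseBinSummary:
    bin_lower: float
    bin_upper: float
    n_voxels: int
    mean_delta: float
    sd: float
    ci95_low: float
    ci95_high: float
    truncated: bool = False


@dataclass(frozen=True)
class RegressionResult:
    slope: float  # HU/Gy
    stderr: float
    p_value: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    rho: float | None  # None when undefined (constant dose)
    p_value: float | None
    n: int


def compute_delta(
    planning: ScalarVolume,
    aligned_followup: ScalarVolume,
    analysis: BinaryMask,
    dose: ScalarVolume,
    validity: BinaryMask | None = None,
    patient_id: str = "",
    timepoint: str = "",
) -> VoxelPairTable:
    """Voxel-wise ΔHU = follow-up − planning inside analysis ∩ validity.

    Every analysis-mask voxel is accounted for: it either contributes a row or
    is counted in the exclusion ledger under ``invalid_after_registration``.
    """
    for other in (aligned_followup, analysis, dose):
        if not planning.same_geometry(other):
            raise ValueError("geometry mismatch: all inputs must be on the planning grid")
    if validity is not None and not planning.same_geometry(validity):
        raise ValueError("geometry mismatch: validity mask not on the planning grid")

    sel = analysis.values.copy()
    n_analysis = int(sel.sum())
    n_invalid = 0
    if validity is not None:
        n_invalid = int((sel & ~validity.values).sum())
        sel &= validity.values

    delta = aligned_followup.values[sel] - planning.values[sel]
    d = dose.values[sel]
    data = pd.DataFrame(
        {
            "dose": d,
            "delta_hu": delta,
            "patient_id": patient_id,
            "timepoint": timepoint,
        }
    )
    excluded = {
        "outside_analysis_mask": int(np.prod(planning.shape)) - n_analysis,
        "invalid_after_registration": n_invalid,
    }
    return VoxelPairTable(data=data, excluded=excluded)


def bin_by_dose(pairs: VoxelPairTable, width: float = 5.0) -> list[DoseBinSummary]:
    """Aggregate ΔHU in half-open dose strata [k·width, (k+1)·width).

    The CI of the bin mean uses the normal approximation mean ± 1.96·sd/√n
    (bins hold thousands of voxels).  The top bin is flagged truncated: it
    ends at the cohort maximum dose rather than a full stratum boundary.
    """
    if width <= 0:
        raise ValueError("bin width must be > 0")
    if pairs.n == 0:
        return []
    d = pairs.data["dose"].to_numpy()
    y = pairs.data["delta_hu"].to_numpy()
    idx = np.floor(d / width).astype(int)
    dmax = float(d.max())
    out: list[DoseBinSummary] = []
    for k in np.unique(idx):
        in_bin = idx == k
        vals = y[in_bin]
        n = int(in_bin.sum())
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        half = Z95 * sd / np.sqrt(n)
        upper = (k + 1) * width
        truncated = upper > dmax
        out.append(
            DoseBinSummary(
                bin_lower=float(k * width),
                bin_upper=float(min(upper, dmax) if truncated else upper),
                n_voxels=n,
                mean_delta=mean,
                sd=sd,
                ci95_low=mean - half,
                ci95_high=mean + half,
                truncated=truncated,
            )
        )
    return out


def spearman_correlation(pairs: VoxelPairTable) -> CorrelationResult:
    """Spearman rank correlation of ΔHU with dose (average ranks, tie-corrected).

    With all doses identical the correlation is undefined and reported as
    ``rho=None`` rather than propagating NaN.
    """
    if pairs.n < 3:
        raise ValueError(f"need n >= 3 pairs for a correlation, got {pairs.n}")
    d = pairs.data["dose"].to_numpy()
    y = pairs.data["delta_hu"].to_numpy()
    if np.all(d == d[0]) or np.all(y == y[0]):
        return CorrelationResult(rho=None, p_value=None, n=pairs.n)
    res = sps.spearmanr(d, y)
    return CorrelationResult(rho=float(res.statistic), p_value=float(res.pvalue), n=pairs.n)


def fit_zero_intercept(pairs: VoxelPairTable) -> RegressionResult:
    """Linear regression without a constant: ΔHU = b·D.

    slope b̂ = Σdy/Σd²; residual variance on n−1 degrees of freedom;
    se(b̂) = √(s²/Σd²); two-sided p from Student's t with n−1 df.
    """
    if pairs.n < 2:
        raise ValueError(f"need n >= 2 pairs for regression, got {pairs.n}")
    d = pairs.data["dose"].to_numpy(dtype=np.float64)
    y = pairs.data["delta_hu"].to_numpy(dtype=np.float64)
    sdd = float(d @ d)
    if sdd == 0.0:
        raise ValueError("all doses are zero; zero-intercept slope undefined")
    slope = float(d @ y) / sdd
    resid = y - slope * d
    df = pairs.n - 1
    s2 = float(resid @ resid) / df
    stderr = float(np.sqrt(s2 / sdd))
    if stderr == 0.0:
        p = 0.0 if slope != 0 else 1.0
    else:
        t = slope / stderr
        p = float(2 * sps.t.sf(abs(t), df))
    return RegressionResult(slope=slope, stderr=stderr, p_value=p, n=pairs.n)


def per_patient_results(
    tables: dict[str, VoxelPairTable], timepoint: str = ""
) -> pd.DataFrame:
    """Per-patient slope and rank correlation, plus cohort summary columns.

    Patients whose table fails the statistical preconditions (too few voxels,
    all-zero dose) are listed with NaN results and a reason instead of
    aborting the cohort.
    """
    rows = []
    for pid, tab in tables.items():
        row: dict[str, object] = {"patient_id": pid, "timepoint": timepoint, "n_voxels": tab.n}
        try:
            reg = fit_zero_intercept(tab)
            row.update(slope=reg.slope, slope_stderr=reg.stderr, slope_p=reg.p_value)
        except ValueError as exc:
            row.update(slope=np.nan, slope_stderr=np.nan, slope_p=np.nan, excluded_reason=str(exc))
        try:
            cor = spearman_correlation(tab)
            row.update(rho=cor.rho if cor.rho is not None else np.nan, rho_p=cor.p_value)
        except ValueError as exc:
            row.update(rho=np.nan, rho_p=np.nan, excluded_reason=str(exc))
        row["mean_delta_hu"] = float(tab.data["delta_hu"].mean()) if tab.n else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    slopes = df["slope"].dropna()
    if len(slopes):
        df.attrs["cohort_summary"] = {
            "slope_min": float(slopes.min()),
            "slope_max": float(slopes.max()),
            "slope_mean": float(slopes.mean()),
            "slope_sd": float(slopes.std(ddof=1)) if len(slopes) > 1 else 0.0,
        }
    return df


def pooled_results(
    tables: list[VoxelPairTable],
    weighting: str = "voxel",
) -> tuple[RegressionResult, CorrelationResult, float]:
    """Pooled slope, rank correlation and mean ΔHU across patients.

    weighting="voxel" (default) concatenates all voxel pairs so each voxel
    counts once; weighting="patient" gives each patient equal weight by
    averaging per-patient statistics (slope and rho then carry no pooled
    standard error; their stderr/p are reported as NaN).
    """
    pooled = VoxelPairTable.concat(tables)
    if pooled.n == 0:
        raise ValueError("no voxel pairs to pool")
    if weighting == "voxel":
        reg = fit_zero_intercept(pooled)
        cor = spearman_correlation(pooled)
        mean_delta = float(pooled.data["delta_hu"].mean())
        return reg, cor, mean_delta
    if weighting == "patient":
        slopes, rhos, means = [], [], []
        for tab in tables:
            if tab.n == 0:
                continue
            slopes.append(fit_zero_intercept(tab).slope)
            c = spearman_correlation(tab)
            if c.rho is not None:
                rhos.append(c.rho)
            means.append(float(tab.data["delta_hu"].mean()))
        reg = RegressionResult(
            slope=float(np.mean(slopes)), stderr=float("nan"), p_value=float("nan"), n=len(slopes)
        )
        cor = CorrelationResult(
            rho=float(np.mean(rhos)) if rhos else None, p_value=None, n=len(rhos)
        )
        return reg, cor, float(np.mean(means))
    raise ValueError(f"unknown weighting {weighting!r}")


def compare_groups(
    values_a: np.ndarray, values_b: np.ndarray, kind: str = "timepoint"
) -> tuple[float, float]:
    """Welch's unequal-variance two-sided t-test between two groups of summaries.

    Used for 12-week vs 6-month mean ΔHU and for between-entity comparisons.
    Degenerate case (both groups constant and equal) returns (0.0, 1.0).
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
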