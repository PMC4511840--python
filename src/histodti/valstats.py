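"""Joint histology/DTI voxel statistics.

Once histological voxel FODs and diffusion tensors live on the same
grid, each voxel contributes one record with the two in-plane axes
Phi_ST (primary von Mises center) and Phi_DT (projected principal
eigenvector), their axis-angle difference

    d(a, b) = min(|a - b|, 180 - |a - b|)  in [0, 90],

the DTI scalars (FA, MD, RD) and the histological covariates (staining
intensity, component amplitudes and widths).  This module builds that
table, applies the inclusion filters in the canonical order (tissue
damage, stained material, out-of-plane angle) with an exclusion ledger,
and computes the summary statistics: per-tissue and FA-binned central
tendencies with 1.96*SE confidence intervals, generalized Pareto fits of
the difference distribution, voxel-count-weighted sectionwise Pearson
correlations, and sectionwise multiple-regression explained variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "axis_angle_diff",
    "mean_axis",
    "max_mean_axis_deviation",
    "summarize_differences",
    "fit_gpd",
    "sectionwise_correlations",
    "regression_r2",
    "build_voxel_table",
    "ExclusionLedger",
]

HISTOLOGY_VARIABLES = ["stain", "ampl1", "width1", "ampl2", "width2", "ampl3", "width3"]


def axis_angle_diff(a, b):
    """Axis-angle difference min(|a-b|, 180-|a-b|) in degrees, in [0, 90].

    Inputs are axes in [0, 180); out-of-range values are normalized
    modulo 180 with a warning.  Symmetric, zero iff the axes coincide.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if ((a < 0) | (a >= 180) | (b < 0) | (b >= 180)).any():
        warnings.warn("axis angles outside [0, 180) normalized modulo 180")
        a = np.mod(a, 180.0)
        b = np.mod(b, 180.0)
    d = np.abs(a - b)
    out = np.minimum(d, 180.0 - d)
    return float(out) if out.ndim == 0 else out


def mean_axis(a: float, b: float, w_a: float = 1.0, w_b: float = 1.0) -> float:
    """Weighted mean of two axes via the doubled-angle vector mean.

    Each axis is doubled to a full-circle direction, the weighted unit
    vectors are summed, and the resultant angle halved back to [0, 180).
    Orthogonal axes with equal weights have antipodal doubled vectors
    whose sum cancels: the mean is undefined and NaN is returned.
    """
    if w_a < 0 or w_b < 0:
        raise ValueError("weights must be >= 0")
    if w_a == 0 and w_b == 0:
        raise ValueError("at least one weight must be positive")
    za = w_a * np.exp(2j * np.radians(a))
    zb = w_b * np.exp(2j * np.radians(b))
    z = za + zb
    if np.abs(z) <= 1e-12 * (w_a + w_b):
        return float("nan")
    out = float(np.mod(np.degrees(np.angle(z)) / 2.0, 180.0))
    return 0.0 if out >= 180.0 else out  # mod can round -eps up to 180.0


def max_mean_axis_deviation(
    step_deg: float = 1.0,
    refine_levels: int = 20,
) -> float:
    """Supremum of d(mean_axis(a, b), a) over planar axis pairs.

    Enumerates ordered axis pairs on a ``step_deg`` grid over [0, 180),
    skipping pairs whose equal-weight mean is undefined (exactly
    orthogonal axes), then refines toward the orthogonal configuration by
    repeated halving of the remaining gap and extrapolates the linear
    sequence of maxima to its limit.  The supremum — the crossing-fiber
    averaging bound — is attained in the limit of orthogonal pairs.
    """
    grid = np.arange(0.0, 180.0, step_deg)
    best = 0.0
    for a in grid:
        for b in grid:
            m = mean_axis(a, b, 1.0, 1.0)
            if np.isnan(m):
                continue
            best = max(best, axis_angle_diff(m, a))
    # refine toward the orthogonal tie: separation 90 - eps, eps halving
    eps = step_deg / 2.0
    seq = []
    for _ in range(refine_levels):
        m = mean_axis(0.0, 90.0 - eps, 1.0, 1.0)
        seq.append(axis_angle_diff(m, 0.0))
        eps /= 2.0
    # d(eps) is linear in eps, so Richardson extrapolation is exact:
    # d(eps/2) + (d(eps/2) - d(eps)) removes the O(eps) term.
    limit = 2.0 * seq[-1] - seq[-2]
    return float(max(best, limit))


def summarize_differences(
    records: pd.DataFrame,
    by: Optional[Sequence[str]] = ("tissue",),
    *,
    fa_bins: bool = False,
    fa_bin_width: float = 0.05,
    min_bin_n: int = 100,
    truncation_deg: Optional[float] = None,
    diff_column: str = "diff",
) -> pd.DataFrame:
    """Grouped central tendencies of the angular difference.

    Groups by the given columns and/or FA bins of width ``fa_bin_width``.
    If ``truncation_deg`` is set, records with larger differences are
    dropped first (truncated mean).  Per group: n, mean, median, SE and
    the 1.96*SE confidence half-width; groups with fewer than
    ``min_bin_n`` voxels are flagged ``suppressed`` (they are reported
    but should not be displayed).
    """
    if records.empty:
        raise ValueError("no records to summarize")
    df = records.copy()
    if truncation_deg is not None:
        df = df[df[diff_column] <= truncation_deg]
    keys: list[str] = list(by) if by else []
    if fa_bins:
        edges = np.arange(0.0, 1.0 + fa_bin_width, fa_bin_width)
        df = df.assign(
            fa_bin=pd.cut(df["fa"], bins=edges, right=False, include_lowest=True)
        )
        keys.append("fa_bin")
    if not keys:
        keys = [pd.Series(0, index=df.index, name="_all")]
    grouped = df.groupby(keys, observed=True)[diff_column]
    out = grouped.agg(n="count", mean="mean", median="median", sd="std").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] <= 1, "se"] = 0.0
    out["ci95"] = 1.96 * out["se"]
    out["suppressed"] = out["n"] < min_bin_n
    return out.drop(columns="sd")


def fit_gpd(
    diffs: np.ndarray,
    *,
    min_n: int = 100,
    bin_width_deg: float = 1.0,
) -> dict[str, float]:
    """Generalized Pareto fit of the angular-difference distribution.

    Maximum-likelihood fit with the location pinned to 0 (differences are
    nonnegative by construction).  Goodness of fit is reported as
    R^2 = 1 - SS_res/SS_tot between the fitted probability mass per
    1-degree bin over [0, 90] and the empirical normalized histogram.
    Returns ``{"shape", "scale", "r2"}``.
    """
    x = np.asarray(diffs, float)
    x = x[np.isfinite(x)]
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} differences for a stable fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all differences equal")
    shape, loc, scale = stats.genpareto.fit(x, floc=0.0)
    edges = np.arange(0.0, 90.0 + bin_width_deg, bin_width_deg)
    counts, _ = np.histogram(x, bins=edges)
    empirical = counts / counts.sum()
    cdf = stats.genpareto.cdf(edges, shape, loc=0.0, scale=scale)
    model = np.diff(cdf)
    ss_res = float(((empirical - model) ** 2).sum())
    ss_tot = float(((empirical - empirical.mean()) ** 2).sum())
    return {
        "shape": float(shape),
        "scale": float(scale),
        "r2": 1.0 - ss_res / ss_tot,
    }


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def sectionwise_correlations(
    records: pd.DataFrame,
    variables: Sequence[str],
    section_column: str = "section_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Voxel-count-weighted mean of per-section Pearson correlations.

    Staining intensity varies between sections for technical reasons, so
    pooled correlations are unreliable; instead the correlation of each
    variable pair is computed per section and averaged with weights
    proportional to the section's voxel count.  Sections in which either
    variable of a pair is constant (or has fewer than 2 finite pairs) are
    skipped for that pair and tallied.  Returns ``(matrix, n_skipped)``
    DataFrames indexed by variable.
    """
    k = len(variables)
    num = np.zeros((k, k))
    den = np.zeros((k, k))
    skipped = np.zeros((k, k), dtype=int)
    for _, sec in records.groupby(section_column):
        n_s = len(sec)
        if n_s < 2:
            skipped += 1
            continue
        for p in range(k):
            for q in range(p, k):
                sub = sec[[variables[p], variables[q]]].dropna()
                if len(sub) < 2:
                    skipped[p, q] += 1
                    continue
                if p == q:
                    r = 1.0 if sub.iloc[:, 0].std() >= 0 else np.nan
                else:
                    r = _pearson(sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy())
                if np.isnan(r):
                    skipped[p, q] += 1
                    continue
                num[p, q] += len(sub) * r
                den[p, q] += len(sub)
    with np.errstate(invalid="ignore"):
        mat = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    mat = np.where(np.eye(k, dtype=bool), 1.0, mat)
    iu = np.triu_indices(k, 1)
    mat[(iu[1], iu[0])] = mat[iu]
    skipped[(iu[1], iu[0])] = skipped[iu]
    matrix = pd.DataFrame(mat, index=list(variables), columns=list(variables))
    n_skipped = pd.DataFrame(skipped, index=list(variables), columns=list(variables))
    return matrix, n_skipped


def regression_r2(
    records: pd.DataFrame,
    target: str,
    predictors: Sequence[str] = tuple(HISTOLOGY_VARIABLES),
    section_column: str = "section_id",
) -> tuple[float, int]:
    """Sectionwise multiple-regression explained variance for one target.

    Per section an OLS regression of the target on the histology
    predictors (plus intercept) gives an R^2; the reported value is the
    voxel-count-weighted mean over sections, mirroring the sectionwise
    correlation rule.  Sections with too few voxels or a rank-deficient
    predictor matrix are skipped and tallied.  Returns
    ``(weighted_r2, n_sections_skipped)``.
    """
    predictors = list(predictors)
    num = 0.0
    den = 0.0
    skipped = 0
    for _, sec in records.groupby(section_column):
        sub = sec[[target] + predictors].dropna()
        n_s = len(sub)
        if n_s <= len(predictors) + 1:
            skipped += 1
            continue
        y = sub[target].to_numpy()
        X = np.column_stack([np.ones(n_s), sub[predictors].to_numpy()])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            skipped += 1
            continue
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            skipped += 1
            continue
        r2 = 1.0 - float((resid**2).sum()) / ss_tot
        num += n_s * r2
        den += n_s
    if den == 0:
        raise ValueError(f"no usable section for regression on {target!r}")
    return num / den, skipped


@dataclass
class ExclusionLedger:
    """Counts of voxels removed at each inclusion stage, in pipeline order."""

    n_pairs: int = 0
    n_damage: int = 0
    n_unstained: int = 0
    n_out_of_plane: int = 0
    n_final: int = 0

    def as_dict(self) -> dict[str, float]:
        frac = lambda k, d: (k / d) if d else float("nan")
        after_damage = self.n_pairs - self.n_damage
        after_stain = after_damage - self.n_unstained
        return {
            "n_pairs": self.n_pairs,
            "n_damage": self.n_damage,
            "frac_damage": frac(self.n_damage, self.n_pairs),
            "n_unstained": self.n_unstained,
            "frac_unstained": frac(self.n_unstained, self.n_pairs),
            "n_out_of_plane": self.n_out_of_plane,
            "frac_within_out_of_plane": frac(
                after_stain - self.n_out_of_plane, after_stain
            ),
            "n_final": self.n_final,
        }


def build_voxel_table(
    fod_table: pd.DataFrame,
    dti_table: pd.DataFrame,
    *,
    min_valid_fraction: float = 0.05,
    min_stain: float = 0.02,
    max_out_of_plane_deg: float = 45.0,
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Join histology and DTI voxels and apply the inclusion filters.

    ``fod_table`` (from :func:`histodti.fodfit.fods_to_table`, augmented
    with a ``k`` slice column via the section-to-slice assignment) and
    ``dti_table`` (from :func:`histodti.dtifit.fit_volume`) are
    inner-joined on the voxel index (i, j, k).  Filters are applied in
    the canonical order — valid-fraction (tissue damage), staining
    intensity (stained material), out-of-plane angle — and tallied.
    Records get ``diff``, the Phi_DT vs Phi_ST axis-angle difference.
    """
    if "k" not in fod_table.columns:
        raise ValueError("fod_table needs a 'k' slice column (apply assign_sections)")
    merged = fod_table.merge(dti_table, on=["i", "j", "k"], how="inner", suffixes=("_st", "_dt"))
    if merged.empty:
        raise ValueError(
            "empty histology/DTI join: check alignment and voxel grids "
            f"(fod n={len(fod_table)}, dti n={len(dti_table)})"
        )
    ledger = ExclusionLedger(n_pairs=len(merged))
    ok_damage = merged["valid_fraction"] >= min_valid_fraction
    ledger.n_damage = int((~ok_damage).sum())
    merged = merged[ok_damage]
    ok_stain = merged["stain"] >= min_stain
    ledger.n_unstained = int((~ok_stain).sum())
    merged = merged[ok_stain]
    keep = merged["out_of_plane"] <= max_out_of_plane_deg
    ledger.n_out_of_plane = int((~keep).sum())
    merged = merged[keep].copy()
    merged["phi_st"] = merged["theta1"]
    merged["diff"] = axis_angle_diff(
        merged["phi_dt"].to_numpy(), merged["phi_st"].to_numpy()
    )
    ledger.n_final = len(merged)
    return merged.reset_index(drop=True), ledger
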