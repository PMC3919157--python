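"""Statistical validation of the VBM pipeline.

Parametric voxelwise inference rests on two assumptions worth checking
for any new species or field strength: that GLM residuals are close to
Gaussian, and that the corrected thresholds deliver their nominal false
positive rates when the null hypothesis is true.  This module provides

* a QQ-normality coefficient: the Pearson correlation between sorted
  residuals and standard-normal quantiles at Blom plotting positions
  q_j = √2·erfinv(2(j−3/8)/(J+¼) − 1), with a Gaussian reference
  distribution of the coefficient for comparison;
* a permutation harness that re-runs the group analysis under random
  balanced relabelings, counting suprathreshold voxels per permutation
  and per voxel, so both the rate and the spatial distribution of false
  positives can be compared with theory;
* an empirical-vs-theoretical F-distribution comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import erfinv
from skimage.measure import label as cc_label

from .glmstats import (DesignMatrix, GLMFit, StatMap, build_design, contrast_map,
                       estimate_smoothness, fit_glm, fwe_threshold)
from .imagegeom import Volume3D

__all__ = [
    "QQResult",
    "NullPermutationSummary",
    "qq_coefficient",
    "reference_qq_distribution",
    "expected_false_positives",
    "permutation_null",
    "fp_spatial_uniformity",
    "compare_f_distribution",
]


@dataclass
class QQResult:
    r: float
    J: int
    quantiles: np.ndarray
    sorted_residuals: np.ndarray


def normal_quantiles(J: int) -> np.ndarray:
    """Standard-normal quantiles at Blom plotting positions (j−3/8)/(J+¼)."""
    j = np.arange(1, J + 1)
    return np.sqrt(2.0) * erfinv(2.0 * (j - 0.375) / (J + 0.25) - 1.0)


def qq_coefficient(residuals) -> QQResult:
    """Normality coefficient r: correlation of sorted residuals with q_j."""
    x = np.asarray(residuals, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("need at least 3 residuals")
    if not np.all(np.isfinite(x)):
        raise ValueError("residuals must be finite")
    if np.ptp(x) == 0:
        raise ValueError("constant residual vector: correlation undefined")
    xs = np.sort(x)
    q = normal_quantiles(x.size)
    r = float(np.corrcoef(xs, q)[0, 1])
    return QQResult(r=r, J=x.size, quantiles=q, sorted_residuals=xs)


def reference_qq_distribution(J: int, reps: int = 1000, seed: int = 0,
                              bin_tolerance: float | None = None,
                              n_bins: int = 100,
                              max_reps: int = 200_000) -> np.ndarray:
    """Distribution of the QQ coefficient under exact Gaussianity.

    Draws ``reps`` Gaussian samples of size J and returns their r values.
    With ``bin_tolerance`` set (e.g. 0.001), sampling instead continues in
    batches until the relative change of every occupied histogram bin
    between successive batches falls below the tolerance.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)

    def batch(n: int) -> np.ndarray:
        draws = rng.standard_normal((n, J))
        draws.sort(axis=1)
        q = normal_quantiles(J)
        qc = q - q.mean()
        xc = draws - draws.mean(axis=1, keepdims=True)
        num = xc @ qc
        den = np.sqrt((xc**2).sum(axis=1) * (qc**2).sum())
        return num / den

    if bin_tolerance is None:
        return batch(reps)
    edges = np.linspace(0.8, 1.0, n_bins + 1)
    rs = batch(reps)
    hist = np.histogram(np.clip(rs, edges[0], edges[-1]), bins=edges)[0].astype(float)
    while rs.size < max_reps:
        new = batch(reps)
        rs = np.concatenate([rs, new])
        new_hist = np.histogram(np.clip(rs, edges[0], edges[-1]), bins=edges)[0].astype(float)
        occupied = new_hist > 0
        old_frac = hist[occupied] / max(hist.sum(), 1.0)
        new_frac = new_hist[occupied] / new_hist.sum()
        delta = np.abs(new_frac - old_frac) / np.where(new_frac > 0, new_frac, 1.0)
        hist = new_hist
        if np.all(delta < bin_tolerance):
            break
    return rs


def expected_false_positives(n_tests: int, alpha: float) -> tuple[int, float]:
    """Expected suprathreshold-test count under the null: (rounded, exact).

    E.g. 2,048 tests at 5% → 102 (exact 102.4).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    exact = n_tests * alpha
    return int(round(exact)), float(exact)


@dataclass
class NullPermutationSummary:
    """Per-permutation and per-voxel false-positive bookkeeping."""

    voxel_counts: np.ndarray       # suprathreshold voxels per permutation
    cluster_counts: np.ndarray     # suprathreshold clusters per permutation
    count_map: Volume3D            # voxelwise exceedance counts
    mask: np.ndarray
    n_permutations: int
    threshold_rule: tuple          # ("fwe-rft" | "uncorrected", alpha)
    seed: int
    f_values: np.ndarray           # pooled in-mask F statistics (subsampled)
    df_num: int
    df_err: int

    def __post_init__(self) -> None:
        assert self.count_map.data.sum() == self.voxel_counts.sum(), \
            "count map total must equal summed per-permutation counts"


def _balanced_labels(rng: np.random.Generator, n_a: int, n_b: int) -> np.ndarray:
    labels = np.array([0] * n_a + [1] * n_b)
    rng.shuffle(labels)
    return labels


def permutation_null(images: list[Volume3D], tiv, n_perms: int = 2048,
                     threshold_rule: tuple = ("fwe-rft", 0.05),
                     seed: int = 17,
                     group_sizes: tuple[int, int] | None = None,
                     contrast=(-1.0, 1.0, 0.0),
                     mask_threshold: float = 0.05,
                     keep_f_values: int = 200_000) -> NullPermutationSummary:
    """Repeat the group analysis under random balanced relabelings.

    Each permutation assigns the subjects to two groups at random
    (uniformly over balanced labelings, with replacement across
    permutations), fits the GLM with the fixed TIV covariate, computes
    the F-contrast [−1 1 0], applies the threshold rule, and records the
    suprathreshold voxel and cluster counts plus a voxelwise exceedance
    count map.
    """
    n = len(images)
    if group_sizes is None:
        if n % 2:
            raise ValueError("odd subject count: pass group_sizes explicitly")
        group_sizes = (n // 2, n // 2)
    n_a, n_b = group_sizes
    if n_a + n_b != n:
        raise ValueError("group sizes must sum to the number of images")
    if n_perms > math.comb(n, n_a):
        warnings.warn(f"{n_perms} permutations exceed the {math.comb(n, n_a)} distinct "
                      "balanced labelings; sampling is with replacement", RuntimeWarning)
    rule, alpha = threshold_rule
    if rule not in ("fwe-rft", "uncorrected"):
        raise ValueError(f"unknown threshold rule {rule!r}")

    rng = np.random.default_rng(seed)
    ref = images[0]
    y4 = np.stack([im.data for im in images], axis=0)
    mask = y4.mean(axis=0) > mask_threshold
    if not mask.any():
        raise ValueError("analysis mask is empty")
    tiv = np.asarray(tiv, dtype=float)

    voxel_counts = np.zeros(n_perms, dtype=int)
    cluster_counts = np.zeros(n_perms, dtype=int)
    count_map = np.zeros(mask.shape, dtype=np.int64)
    pooled_f: list[np.ndarray] = []
    pooled_total = 0
    df_num, df_err = 1, 0

    for p_i in range(n_perms):
        labels = _balanced_labels(rng, n_a, n_b)
        stat, fit = analyze_labels(images, labels, tiv, contrast=contrast,
                                   mask=mask, y4=y4)
        df_num, df_err = stat.df_num, stat.df_err
        if rule == "uncorrected":
            thr = float(stats.f.ppf(1.0 - alpha, df_num, df_err))
        else:
            sm = estimate_smoothness(fit)
            thr = fwe_threshold(stat, sm, alpha=alpha, method="rft")
        supra = stat.values > thr
        voxel_counts[p_i] = int(supra.sum())
        if supra.any():
            grid = np.zeros(mask.shape, dtype=bool)
            grid[mask] = supra
            cluster_counts[p_i] = int(cc_label(grid, connectivity=3).max())
            count_map[mask] += supra
        if pooled_total < keep_f_values:
            pooled_f.append(stat.values.copy())
            pooled_total += stat.values.size

    return NullPermutationSummary(
        voxel_counts=voxel_counts, cluster_counts=cluster_counts,
        count_map=ref.with_data(count_map.astype(float)), mask=mask,
        n_permutations=n_perms, threshold_rule=threshold_rule, seed=seed,
        f_values=np.concatenate(pooled_f) if pooled_f else np.empty(0),
        df_num=df_num, df_err=df_err)


def analyze_labels(images: list[Volume3D], labels, tiv,
                   contrast=(-1.0, 1.0, 0.0), mask: np.ndarray | None = None,
                   y4: np.ndarray | None = None) -> tuple[StatMap, GLMFit]:
    """One F-contrast analysis for a given labelling (the permutation unit)."""
    labels = np.asarray(labels)
    design = build_design(labels, tiv=tiv, interaction=False)
    ref = images[0]
    if y4 is None:
        y4 = np.stack([im.data for im in images], axis=0)
    if mask is None:
        mask = y4.mean(axis=0) > 0.05
    y = y4[:, mask]
    x = design.matrix
    pinv = np.linalg.pinv(x)
    betas = pinv @ y
    resid = y - x @ betas
    sigma2 = np.einsum("nv,nv->v", resid, resid) / design.error_df
    fit = GLMFit(design=design, betas=betas, sigma2=sigma2, residuals=resid,
                 mask=mask, reference=ref)
    stat = contrast_map(fit, list(contrast)[: design.p], kind="F")
    return stat, fit


def fp_spatial_uniformity(summary: NullPermutationSummary,
                          expected_rate: float | None = None,
                          min_spacing_mm: float | None = None) -> dict:
    """Test spatial homogeneity of false positives across in-mask voxels.

    Compares the distribution of per-voxel exceedance counts with the
    Binomial(n_perms, α) model: if no brain region is especially prone
    to false positives, every voxel's count is a draw from the same
    binomial.  The chi-square comparison treats voxels as independent
    draws, which smooth statistic fields violate; ``min_spacing_mm``
    decimates the mask to a lattice at roughly that spacing (use a few
    times the field FWHM) so the assumption approximately holds.
    Returns the count map, the chi-square statistic, its degrees of
    freedom and p-value.
    """
    if summary.n_permutations < 30:
        raise ValueError("need at least 30 permutations for the homogeneity test")
    mask = summary.mask
    if min_spacing_mm is not None:
        vs = summary.count_map.voxel_size
        lattice = np.zeros_like(mask)
        steps = tuple(max(1, int(round(min_spacing_mm / d))) for d in vs)
        lattice[:: steps[0], :: steps[1], :: steps[2]] = True
        mask = mask & lattice
    counts = summary.count_map.data[mask].astype(int)
    if counts.size == 0:
        raise ValueError("empty mask")
    n = summary.n_permutations
    if expected_rate is None:
        rule, alpha = summary.threshold_rule
        expected_rate = alpha if rule == "uncorrected" else counts.mean() / n
    pmf = stats.binom.pmf(np.arange(n + 1), n, expected_rate)
    observed = np.bincount(counts, minlength=n + 1).astype(float)
    expected = pmf * counts.size
    # merge tail bins so every cell has expected count >= 5
    obs_cells, exp_cells = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= 5.0:
            obs_cells.append(o_acc)
            exp_cells.append(e_acc)
            o_acc = e_acc = 0.0
    if o_acc or e_acc:
        if exp_cells:
            obs_cells[-1] += o_acc
            exp_cells[-1] += e_acc
        else:
            obs_cells, exp_cells = [o_acc], [e_acc]
    obs_arr = np.asarray(obs_cells)
    exp_arr = np.asarray(exp_cells) * obs_arr.sum() / max(np.sum(exp_cells), 1e-12)
    if len(obs_arr) < 2:
        chi2, dof, p = 0.0, 0, 1.0
    else:
        chi2 = float(np.sum((obs_arr - exp_arr) ** 2 / exp_arr))
        dof = len(obs_arr) - 1
        p = float(stats.chi2.sf(chi2, dof))
    # the histogram test has little power against a single extreme voxel,
    # so the maximum count gets its own Šidák-corrected p-value
    max_count = int(counts.max())
    log_cdf = stats.binom.logcdf(max_count - 1, n, expected_rate)
    max_count_p = float(-np.expm1(counts.size * log_cdf))
    return {"count_map": summary.count_map, "chi2": chi2, "dof": dof, "p_value": p,
            "max_count": max_count, "max_count_p": max_count_p,
            "expected_rate": expected_rate}


def compare_f_distribution(f_values, df_num: int, df_err: int,
                           grid: np.ndarray | None = None) -> dict:
    """Empirical vs theoretical F CDF with the Kolmogorov–Smirnov distance."""
    if df_num <= 0 or df_err <= 0:
        raise ValueError("degrees of freedom must be positive")
    f_values = np.asarray(f_values, dtype=float).ravel()
    if not np.all(np.isfinite(f_values)):
        raise ValueError("F values must be finite")
    dist = stats.f(df_num, df_err)
    if grid is None:
        hi = max(float(dist.ppf(0.999)), float(f_values.max()) if f_values.size else 1.0)
        grid = np.linspace(0.0, hi, 512)
    ecdf = np.searchsorted(np.sort(f_values), grid, side="right") / max(f_values.size, 1)
    table = pd.DataFrame({"f": grid, "empirical_cdf": ecdf, "theoretical_cdf": dist.cdf(grid)})
    ks = float(stats.kstest(f_values, dist.cdf).statistic) if f_values.size else 0.0
    return {"table": table, "ks_distance": ks}
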