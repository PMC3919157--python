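"""Voxelwise general linear model and corrected inference.

Each voxel of the smoothed, modulated GM maps is fit by ordinary least
squares against a shared design (group indicators plus total intracranial
volume, optionally interacting with group).  Contrasts yield t or F maps;
multiple comparisons are handled by Benjamini–Hochberg FDR over in-mask
voxels, or family-wise error control via the expected Euler characteristic
of t/F random fields (Worsley's closed forms) with image smoothness
estimated from the standardised residuals, or by a permutation null of the
maximum statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from skimage.measure import label as cc_label

from .imagegeom import Volume3D, voxel_to_world

__all__ = [
    "DesignMatrix",
    "GLMFit",
    "StatMap",
    "SmoothnessEstimate",
    "build_design",
    "fit_glm",
    "contrast_map",
    "fdr_threshold",
    "estimate_smoothness",
    "fwe_threshold",
    "cluster_table",
]


class DesignError(ValueError):
    pass


@dataclass
class DesignMatrix:
    """Scans × labelled-columns design with full column rank."""

    matrix: np.ndarray
    columns: list

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DesignError("design must be 2-D")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise DesignError("design matrix is rank deficient")
        if self.error_df <= 0:
            raise DesignError("no error degrees of freedom")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    @property
    def error_df(self) -> int:
        return self.matrix.shape[0] - self.matrix.shape[1]


def build_design(groups, tiv=None, interaction: bool = False) -> DesignMatrix:
    """Two-group design with optional TIV covariate / TIV-by-group interaction.

    Columns are the two group indicators followed by the TIV column(s);
    TIV is mean-centred within its support so the group-indicator betas
    stay interpretable as group means.
    """
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups.tolist()))  # order of first appearance
    if len(levels) != 2:
        raise DesignError(f"expected exactly 2 group levels, got {levels}")
    a = (groups == levels[0]).astype(float)
    b = (groups == levels[1]).astype(float)
    if a.sum() < 2 or b.sum() < 2:
        raise DesignError("need at least 2 scans per group")
    cols = [a, b]
    names = [f"group:{levels[0]}", f"group:{levels[1]}"]
    if tiv is not None:
        tiv = np.asarray(tiv, dtype=float)
        if tiv.shape != groups.shape:
            raise DesignError("TIV length must match number of scans")
        if interaction:
            for ind, lev in ((a, levels[0]), (b, levels[1])):
                col = np.where(ind > 0, tiv - tiv[ind > 0].mean(), 0.0)
                cols.append(col)
                names.append(f"tiv:{lev}")
        else:
            cols.append(tiv - tiv.mean())
            names.append("tiv")
    return DesignMatrix(np.column_stack(cols), names)


@dataclass
class GLMFit:
    design: DesignMatrix
    betas: np.ndarray          # (p, V) in-mask
    sigma2: np.ndarray         # (V,)
    residuals: np.ndarray      # (n, V), kept for smoothness / QQ work
    mask: np.ndarray           # boolean grid
    reference: Volume3D        # geometry carrier

    @property
    def error_df(self) -> int:
        return self.design.error_df


def fit_glm(images, design: DesignMatrix, mask: np.ndarray | None = None,
            mask_threshold: float = 0.05) -> GLMFit:
    """Ordinary least squares at every in-mask voxel.

    ``images`` is a list of :class:`Volume3D` sharing geometry (or an
    (n, n1, n2, n3) array plus a reference volume is not supported — pass
    volumes).  The default analysis mask keeps voxels where the cohort
    mean exceeds ``mask_threshold``, suiting smoothed GM probability maps.
    """
    ref = images[0]
    for im in images[1:]:
        if not ref.same_geometry(im):
            raise ValueError("image geometries differ")
    y4 = np.stack([im.data for im in images], axis=0)
    n = y4.shape[0]
    if n != design.n:
        raise DesignError(f"{n} images but design has {design.n} rows")
    if n <= design.p:
        raise DesignError("fewer images than design columns")
    if mask is None:
        mask = y4.mean(axis=0) > mask_threshold
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("analysis mask is empty")
    y = y4[:, mask]
    x = design.matrix
    pinv = np.linalg.pinv(x)
    betas = pinv @ y
    resid = y - x @ betas
    df = design.error_df
    sigma2 = np.einsum("nv,nv->v", resid, resid) / df
    return GLMFit(design=design, betas=betas, sigma2=sigma2, residuals=resid,
                  mask=mask, reference=ref)


@dataclass
class StatMap:
    """Voxelwise t or F statistic with its degrees of freedom."""

    kind: str                  # "t" or "F"
    values: np.ndarray         # (V,) in-mask statistics
    df_num: int
    df_err: int
    mask: np.ndarray
    reference: Volume3D
    tail: str = "two"          # for t maps: "one" or "two"

    def __post_init__(self) -> None:
        if self.kind == "F" and np.any(self.values < -1e-9):
            raise ValueError("F values must be non-negative")
        if self.df_err <= 0 or self.df_num <= 0:
            raise ValueError("degrees of freedom must be positive")

    def p_values(self) -> np.ndarray:
        if self.kind == "t":
            if self.tail == "one":
                return stats.t.sf(self.values, self.df_err)
            return 2.0 * stats.t.sf(np.abs(self.values), self.df_err)
        return stats.f.sf(self.values, self.df_num, self.df_err)

    def as_volume(self) -> Volume3D:
        out = np.zeros(self.mask.shape)
        out[self.mask] = self.values
        return self.reference.with_data(out)


def contrast_map(fit: GLMFit, contrast, kind: str = "t", tail: str = "two") -> StatMap:
    """t or F statistic map for a contrast vector (t) or matrix (F).

    For a single-row contrast the F statistic equals the squared t
    statistic identically.
    """
    c = np.atleast_2d(np.asarray(contrast, dtype=float))
    if c.shape[1] != fit.design.p:
        raise DesignError(f"contrast length {c.shape[1]} != design columns {fit.design.p}")
    x = fit.design.matrix
    xtx_inv = np.linalg.inv(x.T @ x)
    mid = c @ xtx_inv @ c.T
    if np.linalg.matrix_rank(mid) < c.shape[0]:
        raise DesignError("contrast is inestimable under this design")
    cb = c @ fit.betas  # (rank, V)
    if kind == "t":
        if c.shape[0] != 1:
            raise DesignError("t contrasts must be a single row")
        se = np.sqrt(fit.sigma2 * mid[0, 0])
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(se > 0, cb[0] / se, 0.0)
        return StatMap("t", vals, 1, fit.error_df, fit.mask, fit.reference, tail=tail)
    if kind == "F":
        rank = c.shape[0]
        mid_inv = np.linalg.inv(mid)
        quad = np.einsum("rv,rs,sv->v", cb, mid_inv, cb)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(fit.sigma2 > 0, quad / (rank * fit.sigma2), 0.0)
        return StatMap("F", np.clip(vals, 0.0, None), rank, fit.error_df,
                       fit.mask, fit.reference)
    raise ValueError(f"unknown statistic kind {kind!r}")


def fdr_threshold(stat_or_p, q: float = 0.05):
    """Benjamini–Hochberg step-up over in-mask voxelwise p-values.

    Returns ``(p_threshold, surviving)`` where ``p_threshold`` is the
    largest p(k) ≤ k·q/m (0.0 if nothing survives) and ``surviving`` is a
    boolean array aligned with the input p-values.
    """
    if isinstance(stat_or_p, StatMap):
        p = stat_or_p.p_values()
    else:
        p = np.asarray(stat_or_p, dtype=float).ravel()
    m = p.size
    if m == 0:
        raise ValueError("no p-values to threshold")
    order = np.argsort(p)
    ranked = p[order]
    crit = (np.arange(1, m + 1) / m) * q
    passed = ranked <= crit
    if not passed.any():
        return 0.0, np.zeros(m, dtype=bool)
    k = np.max(np.nonzero(passed)[0])
    p_thr = ranked[k]
    return float(p_thr), p <= p_thr


@dataclass
class SmoothnessEstimate:
    """Residual smoothness as per-axis FWHM (mm) and RFT resel counts."""

    fwhm_mm: np.ndarray        # (3,)
    resels: np.ndarray         # (R0, R1, R2, R3)
    mask_volume_mm3: float


def estimate_smoothness(fit: GLMFit) -> SmoothnessEstimate:
    """Estimate field FWHM from normalised residual spatial derivatives.

    For a unit-variance smooth Gaussian field the variance of the spatial
    derivative along axis a is Λ_a and FWHM_a = sqrt(4 ln 2 / Λ_a).  Λ is
    estimated from the scan-wise standardised residuals with finite
    differences inside the mask.  Resel counts use the actual mask volume
    for the 3-D term and the mask bounding box for the lower orders.
    """
    if fit.residuals.shape[0] < 3:
        raise ValueError("need at least 3 residual maps to estimate smoothness")
    mask = fit.mask
    norm = np.sqrt(np.einsum("nv,nv->v", fit.residuals, fit.residuals))
    u = fit.residuals / np.where(norm > 0, norm, 1.0)
    grid = np.zeros((u.shape[0],) + mask.shape)
    grid[:, mask] = u
    vs = fit.reference.voxel_size
    lam = np.empty(3)
    for axis in range(3):
        d = np.diff(grid, axis=axis + 1) / vs[axis]
        both = mask & np.roll(mask, -1, axis=axis)
        sl = [slice(None)] * 3
        sl[axis] = slice(0, mask.shape[axis] - 1)
        valid = both[tuple(sl)]
        lam[axis] = np.mean(np.sum(d[:, valid] ** 2, axis=0))
    fwhm = np.sqrt(4.0 * np.log(2.0) / np.clip(lam, 1e-12, None))
    vox_vol = fit.reference.voxel_volume_mm3
    v_mm3 = float(mask.sum()) * vox_vol
    # bounding-box extents in mm for the 0-2 dimensional resel terms
    idx = np.nonzero(mask)
    ext = np.array([(idx[a].max() - idx[a].min() + 1) * vs[a] for a in range(3)])
    s = ext / fwhm
    resels = np.array([1.0,
                       s[0] + s[1] + s[2],
                       s[0] * s[1] + s[0] * s[2] + s[1] * s[2],
                       v_mm3 / np.prod(fwhm)])
    return SmoothnessEstimate(fwhm_mm=fwhm, resels=resels, mask_volume_mm3=v_mm3)


def _ec_density_t(u: np.ndarray, v: float) -> np.ndarray:
    """EC densities ρ_0..ρ_3 of a t field with v error df (per unit resel)."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    l2 = 4.0 * np.log(2.0)
    base = (1.0 + u**2 / v) ** ((1.0 - v) / 2.0)
    ec0 = stats.t.sf(u, v)
    ec1 = np.sqrt(l2) / (2.0 * np.pi) * base
    ec2 = (l2 / (2.0 * np.pi) ** 1.5 * base * u
           * np.exp(gammaln((v + 1) / 2.0) - gammaln(v / 2.0)) / np.sqrt(v / 2.0))
    ec3 = l2**1.5 / (2.0 * np.pi) ** 2 * base * ((v - 1.0) * u**2 / v - 1.0)
    return np.stack([ec0, ec1, ec2, ec3])


def _ec_density_f(u: np.ndarray, k: float, v: float) -> np.ndarray:
    """EC densities ρ_0..ρ_3 of an F field with (k, v) df (per unit resel)."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    l2a = 4.0 * np.log(2.0) / (2.0 * np.pi)
    b = gammaln(v / 2.0) + gammaln(k / 2.0)
    t = k * u / v
    base = (1.0 + t) ** (-(v + k - 2.0) / 2.0)
    ec0 = stats.f.sf(u, k, v)
    ec1 = (l2a**0.5 * np.exp(gammaln((v + k - 1.0) / 2.0) - b) * np.sqrt(2.0)
           * t ** ((k - 1.0) / 2.0) * base)
    ec2 = (l2a * np.exp(gammaln((v + k - 2.0) / 2.0) - b)
           * t ** ((k - 2.0) / 2.0) * base * ((v - 1.0) * t - (k - 1.0)))
    ec3 = (l2a**1.5 * np.exp(gammaln((v + k - 3.0) / 2.0) - b) / np.sqrt(2.0)
           * t ** ((k - 3.0) / 2.0) * base
           * ((v - 1.0) * (v - 2.0) * t**2 - (2.0 * v * k - v - k - 1.0) * t
              + (k - 1.0) * (k - 2.0)))
    return np.stack([ec0, ec1, ec2, ec3])


def expected_euler_characteristic(u, stat_kind: str, df_num: int, df_err: int,
                                  resels: np.ndarray) -> np.ndarray:
    """E[EC] of the suprathreshold excursion set at height u."""
    if stat_kind == "t":
        ec = _ec_density_t(u, df_err)
    elif stat_kind == "F":
        ec = _ec_density_f(u, df_num, df_err)
    else:
        raise ValueError(f"unknown statistic kind {stat_kind!r}")
    return np.einsum("d,d...->...", np.asarray(resels, dtype=float), ec)


def fwe_threshold(stat: StatMap, smoothness: SmoothnessEstimate | None = None,
                  alpha: float = 0.05, method: str = "rft",
                  null_maxima=None) -> float:
    """Height threshold controlling family-wise error at ``alpha``.

    ``rft``: smallest u with expected Euler characteristic ≤ alpha.
    ``permutation``: the (1−alpha) quantile of a supplied null
    distribution of maximum statistics, placed so that exactly
    ⌊alpha·N⌋ of the N null maxima exceed it.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if method == "permutation":
        if null_maxima is None:
            raise ValueError("permutation method needs null_maxima")
        m = np.sort(np.asarray(null_maxima, dtype=float))
        n = m.size
        k = int(np.floor(alpha * n))
        return float(m[n - 1] if k == 0 else m[n - k - 1])
    if method != "rft":
        raise ValueError(f"unknown method {method!r}")
    if smoothness is None:
        raise ValueError("rft method needs a SmoothnessEstimate")
    resels = smoothness.resels
    if stat.kind == "t":
        lo = float(stats.t.ppf(1.0 - alpha, stat.df_err))
    else:
        lo = float(stats.f.ppf(1.0 - alpha, stat.df_num, stat.df_err))

    def ec(u):
        return float(np.ravel(expected_euler_characteristic(
            u, stat.kind, stat.df_num, stat.df_err, resels))[0])

    if ec(lo) <= alpha:
        return lo
    hi = lo + 1.0
    while ec(hi) > alpha:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("could not bracket the RFT threshold")
    from scipy.optimize import brentq
    return float(brentq(lambda u: ec(u) - alpha, lo, hi, xtol=1e-8))


_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


def cluster_table(stat: StatMap, threshold: float, connectivity: int = 26) -> pd.DataFrame:
    """Connected suprathreshold clusters with peaks in bregma-relative mm.

    Columns: extent_vox, peak_stat, x_mm, y_mm, z_mm.  Empty tables are
    allowed.  ``connectivity`` is 6, 18 or 26 neighbours.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be 6, 18 or 26")
    vol = stat.as_volume()
    supra = (vol.data > threshold) & stat.mask
    lab = cc_label(supra, connectivity=_CONNECTIVITY[connectivity])
    rows = []
    for lid in range(1, lab.max() + 1):
        where = lab == lid
        extent = int(where.sum())
        masked = np.where(where, vol.data, -np.inf)
        peak_idx = np.unravel_index(np.argmax(masked), masked.shape)
        peak = voxel_to_world(vol, peak_idx)
        rows.append({"extent_vox": extent, "peak_stat": float(vol.data[peak_idx]),
                     "x_mm": peak.x, "y_mm": peak.y, "z_mm": peak.z})
    rows.sort(key=lambda r: -r["extent_vox"])
    return pd.DataFrame(rows, columns=["extent_vox", "peak_stat", "x_mm", "y_mm", "z_mm"])
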