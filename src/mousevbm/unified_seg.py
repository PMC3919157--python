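"""Joint bias-field correction and tissue segmentation.

Each voxel's corrected intensity is modelled as a mixture of Gaussians,
``K`` components per tissue class (GM, WM, CSF, plus the implicit
"everything else" class), with per-voxel mixing proportions taken from
template-space tissue probability maps.  A smooth multiplicative bias
field — ``exp`` of a low-frequency separable cosine expansion, spatial
cutoff 10–15 mm for typical mouse coils — is estimated jointly by
interleaving a damped Gauss–Newton update of the bias coefficients with
the EM updates of the mixture.  Every accepted step decreases the
penalised negative log-likelihood, so the objective trace is monotone.

The deformation update is deliberately not part of this loop: non-linear
normalisation is a separate stage (see :mod:`mousevbm.spatial`), keeping
each stage independently testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._dct import dct_basis, evaluate_field, n_orders_for_cutoff
from .imagegeom import Volume3D

__all__ = [
    "TissueProbabilityMaps",
    "SegmentationResult",
    "BiasFieldFit",
    "fit_bias_basis",
    "segment_unified",
    "total_intracranial_volume",
]

CLASSES = ("gm", "wm", "csf", "other")
_TPM_FLOOR = 1e-4


@dataclass
class TissueProbabilityMaps:
    """Template-space prior probability images for GM, WM and CSF.

    The residual ``1 − (gm+wm+csf)`` is the implicit fourth class.
    """

    gm: Volume3D
    wm: Volume3D
    csf: Volume3D

    def __post_init__(self) -> None:
        for name in ("wm", "csf"):
            if not self.gm.same_geometry(getattr(self, name)):
                raise ValueError(f"TPM '{name}' geometry differs from GM")
        total = self.gm.data + self.wm.data + self.csf.data
        if total.max() > 1.0 + 1e-6:
            raise ValueError(f"TPM probabilities sum to {total.max():.4f} > 1 somewhere")

    def stacked_priors(self) -> np.ndarray:
        """(V, 4) per-voxel class priors incl. 'other', floored and renormalised."""
        gm = self.gm.data.ravel()
        wm = self.wm.data.ravel()
        csf = self.csf.data.ravel()
        other = np.clip(1.0 - gm - wm - csf, 0.0, 1.0)
        p = np.stack([gm, wm, csf, other], axis=1)
        p = np.clip(p, _TPM_FLOOR, None)
        return p / p.sum(axis=1, keepdims=True)


@dataclass
class SegmentationResult:
    posteriors: dict  # class name -> Volume3D
    bias_field: Volume3D
    mixture: dict     # class name -> list of (weight, mean, variance)
    objective_trace: list

    def posterior_stack(self) -> np.ndarray:
        return np.stack([self.posteriors[c].data for c in CLASSES], axis=-1)


@dataclass
class BiasFieldFit:
    """Coefficients of the log-bias cosine expansion plus the grid context."""

    coefficients: np.ndarray        # (k1, k2, k3) log-field coefficients
    cutoff_mm: float
    shape: tuple
    voxel_size: tuple

    def log_field(self) -> np.ndarray:
        bases = tuple(dct_basis(n, k) for n, k in zip(self.shape, self.coefficients.shape))
        return evaluate_field(self.coefficients, bases)

    def field(self) -> np.ndarray:
        """The multiplicative bias field (strictly positive)."""
        return np.exp(self.log_field())


def _bias_orders(shape, voxel_size, cutoff_mm) -> tuple[int, int, int]:
    if cutoff_mm <= 2.0 * max(voxel_size):
        raise ValueError(
            f"bias cutoff {cutoff_mm} mm too small for this grid; "
            f"minimum is {2.0 * max(voxel_size):.3g} mm (twice the largest voxel)")
    return tuple(n_orders_for_cutoff(n, d, cutoff_mm)
                 for n, d in zip(shape, voxel_size))


def _masked_design(shape, voxel_size, orders, mask_flat: np.ndarray) -> np.ndarray:
    """Dense (n_mask, K) design of the separable basis restricted to a mask."""
    bases = [dct_basis(n, k) for n, k in zip(shape, orders)]
    ii, jj, kk = np.unravel_index(np.flatnonzero(mask_flat), shape)
    b = (bases[0][ii][:, :, None, None]
         * bases[1][jj][:, None, :, None]
         * bases[2][kk][:, None, None, :])
    return b.reshape(len(ii), -1)


def fit_bias_basis(volume: Volume3D, cutoff_mm: float,
                   mask: np.ndarray | None = None) -> BiasFieldFit:
    """Fit the smooth multiplicative field of an image by least squares.

    Projects log-intensities (inside ``mask``, default: positive voxels)
    onto the low-frequency cosine basis whose shortest retained period is
    ``cutoff_mm``.  For an image that is a flat tissue times a smooth
    field this recovers the field directly; inside the segmentation loop
    the same basis is driven by the mixture model instead.
    """
    orders = _bias_orders(volume.shape, volume.voxel_size, cutoff_mm)
    data = volume.data
    if mask is None:
        mask = data > 0
    mask_flat = mask.ravel() & (data.ravel() > 0)
    if mask_flat.sum() < np.prod(orders):
        raise ValueError("mask too small for the requested cutoff")
    y = np.log(data.ravel()[mask_flat])
    b = _masked_design(volume.shape, volume.voxel_size, orders, mask_flat)
    coefs, *_ = np.linalg.lstsq(b, y, rcond=None)
    return BiasFieldFit(coefficients=coefs.reshape(orders), cutoff_mm=cutoff_mm,
                        shape=volume.shape, voxel_size=volume.voxel_size)


def _gauss_pdf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return np.exp(-0.5 * (x - mean) ** 2 / var) / np.sqrt(2.0 * np.pi * var)


def _mixture_likelihoods(x, mixture) -> np.ndarray:
    """(V, 4) class-conditional likelihoods Σ_g w_g N(x; μ_g, σ²_g)."""
    out = np.zeros((x.size, len(CLASSES)))
    for ci, cname in enumerate(CLASSES):
        for w, mu, var in mixture[cname]:
            out[:, ci] += w * _gauss_pdf(x, mu, var)
    return out


def _objective(y, f, mixture, priors, ridge, coefs) -> float:
    x = y * np.exp(-f)
    lik = (_mixture_likelihoods(x, mixture) * priors).sum(axis=1)
    return float(np.sum(-np.log(lik + 1e-300) + f) + ridge * np.sum(coefs**2))


def segment_unified(volume: Volume3D, tpms: TissueProbabilityMaps,
                    gaussians_per_class: int = 2, cutoff_mm: float = 12.0,
                    max_iter: int = 30, tol: float = 1e-5,
                    ridge: float = 1e-3) -> SegmentationResult:
    """Unified bias correction + mixture segmentation.

    ``volume`` must already be affine-aligned to the TPM space.  Returns
    per-class posteriors summing to one per voxel, the multiplicative
    bias field, the fitted mixture, and the (non-increasing) penalised
    negative log-likelihood trace.
    """
    if not np.all(np.isfinite(volume.data)):
        raise ValueError("input volume contains non-finite intensities")
    if not volume.same_geometry(tpms.gm):
        raise ValueError("volume geometry differs from the TPM space")

    y = volume.data.ravel().astype(float)
    y = np.clip(y, 1e-9, None)  # multiplicative model needs positive data
    priors = tpms.stacked_priors()
    orders = _bias_orders(volume.shape, volume.voxel_size, cutoff_mm)
    n_coef = int(np.prod(orders))
    design = _masked_design(volume.shape, volume.voxel_size, orders,
                            np.ones(y.size, dtype=bool))
    design = np.ascontiguousarray(design)
    # the DC term is indistinguishable from a global rescaling of the class
    # means, so it is pinned to zero and the means absorb overall scale
    dc_index = 0
    coefs = np.zeros(n_coef)
    f = np.zeros_like(y)

    k = gaussians_per_class
    mixture: dict[str, list] = {}
    global_var = float(np.var(y))
    for ci, cname in enumerate(CLASSES):
        w_prior = priors[:, ci]
        mu = float(np.sum(w_prior * y) / np.sum(w_prior))
        var = max(float(np.sum(w_prior * (y - mu) ** 2) / np.sum(w_prior)), 1e-6 * global_var)
        offsets = np.linspace(0.9, 1.1, k) if k > 1 else np.array([1.0])
        mixture[cname] = [(1.0 / k, mu * o, var) for o in offsets]

    frozen: set[str] = set()
    trace: list[float] = []
    obj = _objective(y, f, mixture, priors, ridge, coefs)

    for iteration in range(max_iter):
        x = y * np.exp(-f)
        # E-step: responsibilities per (class, gaussian)
        comp = np.zeros((y.size, len(CLASSES), k))
        for ci, cname in enumerate(CLASSES):
            for gi, (w, mu, var) in enumerate(mixture[cname]):
                comp[:, ci, gi] = priors[:, ci] * w * _gauss_pdf(x, mu, var)
        total = comp.sum(axis=(1, 2)) + 1e-300
        resp = comp / total[:, None, None]

        # M-step: weights, means, variances per class
        for ci, cname in enumerate(CLASSES):
            if cname in frozen:
                continue
            r_c = resp[:, ci, :]
            mass = r_c.sum()
            if mass < 1e-8:
                warnings.warn(f"class '{cname}' has no posterior mass; freezing its Gaussians",
                              RuntimeWarning)
                frozen.add(cname)
                continue
            new = []
            for gi in range(k):
                r = r_c[:, gi]
                s = r.sum()
                if s < 1e-12:
                    new.append(mixture[cname][gi])
                    continue
                mu = float(r @ x / s)
                var = max(float(r @ (x - mu) ** 2 / s), 1e-8 * global_var)
                new.append((float(s / mass), mu, var))
            mixture[cname] = new

        # bias step: damped Gauss-Newton with backtracking on the objective
        x = y * np.exp(-f)
        g_vox = np.zeros(y.size)   # dE/df per voxel
        h_vox = np.zeros(y.size)   # Fisher-style curvature
        for ci, cname in enumerate(CLASSES):
            for gi, (w, mu, var) in enumerate(mixture[cname]):
                r = resp[:, ci, gi]
                g_vox += r * (x - mu) / var
                h_vox += r / var
        g_vox = -x * g_vox + 1.0
        h_vox = x**2 * h_vox + 1e-6
        grad = design.T @ g_vox + 2.0 * ridge * coefs
        hess = (design * h_vox[:, None]).T @ design + 2.0 * ridge * np.eye(n_coef)
        grad[dc_index] = 0.0
        hess[dc_index, :] = 0.0
        hess[:, dc_index] = 0.0
        hess[dc_index, dc_index] = 1.0
        step = np.linalg.solve(hess, grad)
        obj_now = _objective(y, f, mixture, priors, ridge, coefs)
        scale = 1.0
        for _ in range(8):
            cand = coefs - scale * step
            f_cand = design @ cand
            obj_cand = _objective(y, f_cand, mixture, priors, ridge, cand)
            if obj_cand < obj_now:
                coefs, f, obj_now = cand, f_cand, obj_cand
                break
            scale *= 0.5

        trace.append(obj_now)
        if iteration > 0 and abs(trace[-2] - trace[-1]) < tol * abs(trace[-2]):
            break
        obj = obj_now

    # final posteriors at converged parameters
    x = y * np.exp(-f)
    lik = _mixture_likelihoods(x, mixture) * priors
    post = lik / (lik.sum(axis=1, keepdims=True) + 1e-300)
    posteriors = {c: volume.with_data(post[:, ci].reshape(volume.shape))
                  for ci, c in enumerate(CLASSES)}
    bias = volume.with_data(np.exp(f).reshape(volume.shape))
    return SegmentationResult(posteriors=posteriors, bias_field=bias,
                              mixture=mixture, objective_trace=trace)


def total_intracranial_volume(seg: SegmentationResult,
                              voxel_volume_mm3: float | None = None) -> float:
    """TIV in mm³: posterior GM+WM+CSF mass times voxel volume."""
    if voxel_volume_mm3 is None:
        voxel_volume_mm3 = seg.posteriors["gm"].voxel_volume_mm3
    brain = sum(seg.posteriors[c].data.sum() for c in ("gm", "wm", "csf"))
    return float(brain * voxel_volume_mm3)
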