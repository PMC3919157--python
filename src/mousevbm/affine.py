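"""12-parameter affine registration with a Gaussian prior on scales and shears.

The affine matrix is composed as ``T · R · S`` where ``S`` is the symmetric
positive-definite stretch.  Scales and shears parameterise the stretch
through its Cholesky factor ``K = diag(sx, sy, sz) · H`` (``H`` unit upper
triangular with entries hxy, hxz, hyz), so ``S = sqrtm(KᵀK)`` and
``det S = sx·sy·sz``.  Because scales and shears are functions of ``MᵀM``
alone they are invariant to any rigid motion composed on the left — which
is what makes a population prior over them meaningful: it captures how much
individual brains deviate in size and shape from the atlas, independent of
head position.

The shipped default prior holds the scale/shear statistics of mouse brains
registered to the Paxinos-aligned atlas: scales 1.00±0.01, 1.00±0.02,
1.00±0.02 (x, y, z) and shears 0.00±0.02, 0.01±0.04, 0.02±0.01 (xy, xz,
yz).  Only marginal SDs are published, so the covariance is diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.linalg import cholesky, eigh
from scipy.spatial.transform import Rotation

from .imagegeom import Volume3D

__all__ = [
    "AffineParams",
    "AffinePrior",
    "DEFAULT_PRIOR",
    "compose_affine",
    "polar_decompose",
    "prior_penalty",
    "register_affine",
    "resample_affine",
]


class AffineDomainError(ValueError):
    pass


class RegistrationError(RuntimeError):
    pass


@dataclass
class AffineParams:
    """Affine transform in polar-decomposition form.

    translation in mm, rotation as intrinsic x-y-z Euler angles in radians,
    scales dimensionless (strictly positive), shears dimensionless.
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shear: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.scale) <= 0):
            raise AffineDomainError(f"scales must be strictly positive, got {self.scale}")

    def scale_shear_vector(self) -> np.ndarray:
        """(sx, sy, sz, hxy, hxz, hyz) — the rigid-invariant parameters."""
        return np.array([*self.scale, *self.shear], dtype=float)

    def to_vector(self) -> np.ndarray:
        return np.array([*self.translation, *self.rotation, *self.scale, *self.shear])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "AffineParams":
        v = np.asarray(v, dtype=float)
        return cls(tuple(v[0:3]), tuple(v[3:6]), tuple(v[6:9]), tuple(v[9:12]))


@dataclass
class AffinePrior:
    """Gaussian prior over the six rigid-invariant parameters (scales, shears)."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(6)
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(6, 6)
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise AffineDomainError("prior covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.covariance) < -1e-10):
            raise AffineDomainError("prior covariance must be positive semi-definite")


#: Scale/shear prior of mouse brains against the Paxinos-aligned atlas
#: (diagonal covariance from the published marginal SDs).
DEFAULT_PRIOR = AffinePrior(
    mean=np.array([1.00, 1.00, 1.00, 0.00, 0.01, 0.02]),
    covariance=np.diag(np.array([0.01, 0.02, 0.02, 0.02, 0.04, 0.01]) ** 2),
)


def _stretch_matrix(scale, shear) -> np.ndarray:
    """Symmetric positive-definite stretch from scales and shears."""
    sx, sy, sz = scale
    hxy, hxz, hyz = shear
    k = np.array([[sx, sx * hxy, sx * hxz],
                  [0.0, sy, sy * hyz],
                  [0.0, 0.0, sz]])
    m = k.T @ k
    w, v = eigh(m)
    return (v * np.sqrt(w)) @ v.T


def compose_affine(params: AffineParams) -> np.ndarray:
    """4×4 matrix Translation · Rotation · Stretch; det = sx·sy·sz."""
    r = Rotation.from_euler("XYZ", params.rotation).as_matrix()
    s = _stretch_matrix(params.scale, params.shear)
    m = np.eye(4)
    m[:3, :3] = r @ s
    m[:3, 3] = params.translation
    return m


def polar_decompose(matrix: np.ndarray) -> AffineParams:
    """Recover polar-form parameters from a 4×4 affine.

    The rotation is the orthogonal polar factor of the 3×3 block; scales
    and shears come from the Cholesky factor of MᵀM.  Reflections
    (negative determinant) are not representable and raise.
    """
    matrix = np.asarray(matrix, dtype=float)
    a = matrix[:3, :3]
    if np.linalg.det(a) <= 0:
        raise AffineDomainError("3x3 block must have positive determinant "
                                "(reflections are not representable)")
    mtm = a.T @ a
    w, v = eigh(mtm)
    p = (v * np.sqrt(w)) @ v.T          # symmetric stretch
    r = a @ np.linalg.inv(p)            # orthogonal polar factor
    # re-orthogonalise against round-off before angle extraction
    rot = Rotation.from_matrix(r)
    angles = rot.as_euler("XYZ")
    k = cholesky(mtm, lower=False)
    sx, sy, sz = np.diag(k)
    shear = (k[0, 1] / sx, k[0, 2] / sx, k[1, 2] / sy)
    return AffineParams(
        translation=tuple(matrix[:3, 3]),
        rotation=tuple(angles),
        scale=(float(sx), float(sy), float(sz)),
        shear=tuple(float(h) for h in shear),
    )


def prior_penalty(params: AffineParams, prior: AffinePrior) -> float:
    """½ (v − μ)ᵀ Σ⁻¹ (v − μ) over the rigid-invariant parameters."""
    cov = prior.covariance
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        cov = cov + 1e-8 * np.eye(6)
        try:
            cov_inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError as exc:
            raise AffineDomainError("prior covariance singular after regularisation") from exc
    d = params.scale_shear_vector() - prior.mean
    return float(0.5 * d @ cov_inv @ d)


# ---------------------------------------------------------------------------
# registration


def resample_affine(source: Volume3D, reference: Volume3D,
                    matrix: np.ndarray, order: int = 1,
                    cval: float = 0.0) -> Volume3D:
    """Pull-back resample ``source`` onto ``reference``'s grid.

    ``matrix`` maps reference-world (mm) to source-world (mm); sampling
    is spline interpolation of the given order with ``cval`` fill outside.
    """
    vox_map = np.linalg.inv(source.vox2world) @ matrix @ reference.vox2world
    out = ndimage.affine_transform(
        source.data, vox_map[:3, :3], offset=vox_map[:3, 3],
        output_shape=reference.shape, order=order, mode="constant", cval=cval,
    )
    return reference.with_data(out)


def _overlap_weight(source: Volume3D, reference: Volume3D, matrix: np.ndarray) -> np.ndarray:
    """Fractional in-bounds weight of each reference voxel under the map."""
    ones = source.with_data(np.ones(source.shape))
    return resample_affine(ones, reference, matrix).data


def _nmi(fixed: np.ndarray, moving: np.ndarray, weight: np.ndarray, bins: int = 64) -> float:
    """Normalised mutual information (H(A)+H(B))/H(A,B) on a soft joint histogram.

    Voxels enter the histogram with their fractional overlap weight, and
    intensities are spread over the two neighbouring bins (partial-volume
    binning), so the measure varies smoothly with the transform.
    """
    w = weight.ravel()
    m = w > 0.05
    if m.sum() < 100:
        raise RegistrationError("volumes do not overlap")
    a = fixed.ravel()[m]
    b = moving.ravel()[m]
    w = w[m]

    def frac_bins(x):
        lo, hi = np.percentile(x, [0.5, 99.5])
        if hi <= lo:
            hi = lo + 1.0
        f = np.clip((x - lo) / (hi - lo), 0.0, 1.0) * (bins - 1)
        i0 = np.floor(f).astype(np.intp)
        i0 = np.minimum(i0, bins - 2)
        return i0, f - i0

    ia, fa = frac_bins(a)
    ib, fb = frac_bins(b)
    hist = np.zeros((bins, bins))
    for da, wa in ((0, 1 - fa), (1, fa)):
        for db, wb in ((0, 1 - fb), (1, fb)):
            np.add.at(hist, (ia + da, ib + db), w * wa * wb)
    p = hist / hist.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    eps = 1e-12
    ha = -np.sum(pa * np.log(pa + eps))
    hb = -np.sum(pb * np.log(pb + eps))
    hab = -np.sum(p * np.log(p + eps))
    return (ha + hb) / max(hab, eps)


def _downsample(vol: Volume3D, factor: int = 2) -> Volume3D:
    data = ndimage.gaussian_filter(vol.data, sigma=factor / 2.0)[
        ::factor, ::factor, ::factor]
    m = vol.vox2world @ np.diag([factor, factor, factor, 1.0])
    vs = tuple(s * factor for s in vol.voxel_size)
    return Volume3D(data=data, voxel_size=vs, vox2world=m, units=vol.units)


def _centre_of_mass_world(vol: Volume3D) -> np.ndarray:
    d = np.clip(vol.data, 0, None)
    com = np.asarray(ndimage.center_of_mass(d))
    return (vol.vox2world @ np.append(com, 1.0))[:3]


@dataclass
class AffineRegistrationResult:
    params: AffineParams
    matrix: np.ndarray
    objective: float
    n_evals: int
    objective_trace: list = field(default_factory=list)


# natural step sizes per parameter block: mm, rad, scale, shear — Powell's
# initial unit steps act on the scaled vector, so a unit move is modest
# in every block instead of doubling a scale factor
_PARAM_SCALES = np.array([0.2, 0.2, 0.2, 0.05, 0.05, 0.05,
                          0.02, 0.02, 0.02, 0.02, 0.02, 0.02])


def register_affine(source: Volume3D, template: Volume3D,
                    prior: AffinePrior | None = DEFAULT_PRIOR,
                    init: AffineParams | None = None,
                    prior_weight: float = 0.01,
                    bins: int = 64,
                    coarse_iter: int = 15,
                    fine_iter: int = 6) -> AffineRegistrationResult:
    """Estimate the template→source affine minimising −NMI + prior penalty.

    Runs a derivative-free Powell search over the 12 parameters at two
    resolutions (2× downsampled, then full), with each parameter block
    scaled to its natural step size.  ``prior=None`` disables the
    penalty.  Initialisation is centre-of-mass alignment unless ``init``
    is given.
    """
    if init is None:
        t0 = _centre_of_mass_world(source) - _centre_of_mass_world(template)
        init = AffineParams(translation=tuple(t0))

    n_evals = [0]
    trace: list[float] = []
    centre = init.to_vector()

    def make_objective(src: Volume3D, tpl: Volume3D):
        def objective(u: np.ndarray) -> float:
            n_evals[0] += 1
            v = centre + u * _PARAM_SCALES
            if np.any(v[6:9] <= 0.5) or np.any(v[6:9] >= 2.0) or np.any(np.abs(v[9:12]) > 0.5):
                return 10.0
            params = AffineParams.from_vector(v)
            m = compose_affine(params)
            moving = resample_affine(src, tpl, m).data
            w = _overlap_weight(src, tpl, m)
            try:
                cost = -_nmi(tpl.data, moving, w, bins=bins)
            except RegistrationError:
                return 10.0
            if prior is not None:
                cost += prior_weight * prior_penalty(params, prior)
            return cost
        return objective

    u = np.zeros(12)
    levels = []
    if min(source.shape) >= 16 and min(template.shape) >= 16:
        levels.append((_downsample(source), _downsample(template), 1e-4, 1e-7, coarse_iter))
    # NMI varies on a ~1e-3 scale near the optimum, so the fine level needs
    # a much tighter function tolerance than parameter tolerance
    levels.append((source, template, 1e-5, 1e-9, fine_iter))

    full_objective = make_objective(source, template)
    f_init = full_objective(u)
    for src, tpl, xtol, ftol, maxiter in levels:
        obj = make_objective(src, tpl)
        res = optimize.minimize(obj, u, method="Powell",
                                options={"xtol": xtol, "ftol": ftol, "maxiter": maxiter})
        # objective values are only comparable within one resolution level;
        # Powell is monotone per level, so its result always moves forward
        u = res.x
        trace.append(float(res.fun))

    best = full_objective(u)
    if best > f_init - 1e-8:
        warnings.warn("affine registration failed to improve on initialisation; "
                      "returning best-found parameters", RuntimeWarning)
    params = AffineParams.from_vector(centre + u * _PARAM_SCALES)
    return AffineRegistrationResult(params=params, matrix=compose_affine(params),
                                    objective=best, n_evals=n_evals[0],
                                    objective_trace=trace)
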