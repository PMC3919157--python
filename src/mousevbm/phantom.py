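"""Synthetic mouse-brain cohorts with known ground truth.

The phantom is stylised, not anatomically faithful: an outer GM
(cortex-like) ellipsoid, a WM core, two CSF ventricle lobes and two
lateral striatum-like GM blobs, all defined analytically in bregma
millimetre coordinates.  Each subject is produced by evaluating that
geometry through its own random small affine plus a smooth random warp
(inter-subject anatomical jitter), optionally atrophying labelled GM
regions for "disease" subjects, and rendering class intensities with a
multiplicative bias field and additive Gaussian noise.  Because the
geometry is analytic, every stage of the pipeline has exact truth to be
scored against: tissue labels, regional volumes, the bias field, the
applied transform and the intracranial volume.

Atrophy is an analytic erosion: the region's ellipsoids are shrunk
radially so its GM volume drops by exactly the requested fraction and
the vacated shell becomes CSF — a true volumetric effect that Jacobian
modulation must conserve.  Noise is additive Gaussian (a high-SNR
approximation to Rician magnitude noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._dct import dct_basis, evaluate_field
from .affine import AffineParams, compose_affine
from .imagegeom import Volume3D, default_vox2world
from .spatial import smooth
from .unified_seg import TissueProbabilityMaps

__all__ = [
    "PhantomSpec",
    "PhantomSubject",
    "PhantomCohort",
    "make_phantom_cohort",
    "null_cohort",
    "make_tpms",
    "smoothed_gm_maps",
]

# tissue label codes
BG, CORTEX_GM, WM, CSF, STRIATUM_GM = 0, 1, 2, 3, 4
GM_LABELS = (CORTEX_GM, STRIATUM_GM)


@dataclass
class Ellipsoid:
    centre: tuple  # mm, bregma-relative
    semi_axes: tuple

    def inside(self, pts: np.ndarray, shrink: float = 1.0) -> np.ndarray:
        d = (pts - np.asarray(self.centre)) / (np.asarray(self.semi_axes) * shrink)
        return np.einsum("...a,...a->...", d, d) <= 1.0


@dataclass
class PhantomSpec:
    """Everything that determines a cohort, including the seed.

    Default geometry fits a 9.6 mm cube field of view at 0.2 mm voxels;
    intensity means mimic T2-weighted contrast (CSF bright, WM dark) in
    arbitrary units.  ``atrophy`` maps region name → GM volume reduction
    fraction in [0, 1), applied to disease subjects only.
    """

    shape: tuple = (48, 48, 48)
    voxel_size: tuple = (0.2, 0.2, 0.2)
    brain: Ellipsoid = field(default_factory=lambda: Ellipsoid((0, 0, 0), (3.6, 4.2, 3.0)))
    wm_core: Ellipsoid = field(default_factory=lambda: Ellipsoid((0, -0.3, -0.2), (2.2, 2.8, 1.8)))
    ventricles: tuple = (Ellipsoid((-0.95, 0.2, -0.2), (0.3, 0.7, 0.4)),
                         Ellipsoid((0.95, 0.2, -0.2), (0.3, 0.7, 0.4)))
    striatum: tuple = (Ellipsoid((-1.25, 0.2, -0.2), (0.8, 1.1, 0.8)),
                       Ellipsoid((1.25, 0.2, -0.2), (0.8, 1.1, 0.8)))
    class_means: dict = field(default_factory=lambda: {
        BG: 0.05, CORTEX_GM: 0.60, WM: 0.40, CSF: 0.95, STRIATUM_GM: 0.60})
    class_sds: dict = field(default_factory=lambda: {
        BG: 0.01, CORTEX_GM: 0.02, WM: 0.02, CSF: 0.02, STRIATUM_GM: 0.02})
    bias_amplitude: float = 0.1        # SD of log-bias coefficients
    bias_orders: tuple = (3, 3, 3)
    noise_sd: float = 0.03             # additive, intensity units
    atrophy: dict = field(default_factory=dict)   # region -> fraction in [0, 1)
    affine_jitter: dict = field(default_factory=lambda: {
        "translation": 0.1, "rotation": 0.02, "scale": 0.02, "shear": 0.01})
    warp_jitter_mm: float = 0.02       # SD of displacement-basis coefficients
    warp_orders: tuple = (4, 4, 4)
    supersample: int = 3               # sub-grid per axis for partial-volume rendering
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.voxel_size = tuple(float(d) for d in self.voxel_size)
        self.warp_orders = tuple(int(k) for k in self.warp_orders)
        self.bias_orders = tuple(int(k) for k in self.bias_orders)
        self.class_means = {int(k): v for k, v in self.class_means.items()}
        self.class_sds = {int(k): v for k, v in self.class_sds.items()}
        for region, frac in self.atrophy.items():
            if not 0.0 <= frac < 1.0:
                raise ValueError(f"atrophy fraction for {region!r} must be in [0, 1)")
        g = self.ventricle_growth(self.atrophy.get("striatum", 0.0))
        if g > 1.0:
            u = np.random.default_rng(0).normal(size=(2000, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            for vent in self.ventricles:
                surface = np.asarray(vent.centre) + u * np.asarray(vent.semi_axes) * g
                if not any(e.inside(surface).all() for e in self.striatum):
                    raise ValueError(
                        f"striatum atrophy {self.atrophy['striatum']} needs ventricle "
                        f"growth {g:.3f}, which leaves the striatum; reduce the fraction")

    def vox2world(self) -> np.ndarray:
        return default_vox2world(self.shape, self.voxel_size)

    def ventricle_growth(self, striatum_loss: float) -> float:
        """Ventricle scale factor implementing ex-vacuo striatal atrophy.

        Each lateral ventricle sits inside its striatum; enlarging it by a
        factor g consumes striatal GM.  Solving (g³−1)·ΣV_vent =
        loss·Σ(V_str − V_vent) gives the growth that removes exactly the
        requested GM fraction (continuum calculation; the enlarged
        ventricle must stay inside the striatum, checked at cohort
        construction).
        """
        if striatum_loss <= 0.0:
            return 1.0
        v_vent = sum(4.0 / 3.0 * np.pi * np.prod(e.semi_axes) for e in self.ventricles)
        v_str = sum(4.0 / 3.0 * np.pi * np.prod(e.semi_axes) for e in self.striatum)
        return float((1.0 + striatum_loss * (v_str - v_vent) / v_vent) ** (1.0 / 3.0))

    def labels_at(self, pts: np.ndarray, atrophy: dict | None = None) -> np.ndarray:
        """Tissue label code at world points.

        Striatal atrophy is ex vacuo: the embedded lateral ventricles
        enlarge into the striatum so its GM volume drops by the requested
        fraction — the pattern of GM loss around enlarging ventricles
        seen in striatal neurodegeneration.  Cortical atrophy is a
        boundary erosion of the outer GM shell.
        """
        atrophy = atrophy or {}
        lab = np.full(pts.shape[:-1], BG, dtype=np.int8)
        lab[self.brain.inside(pts)] = CORTEX_GM
        lab[self.wm_core.inside(pts)] = WM
        for e in self.striatum:
            lab[e.inside(pts)] = STRIATUM_GM
        if "cortex" in atrophy:
            s = (1.0 - atrophy["cortex"]) ** (1.0 / 3.0)
            outer = self.brain.inside(pts) & ~self.brain.inside(pts, shrink=s) \
                & (lab == CORTEX_GM)
            lab[outer] = CSF
        g = self.ventricle_growth(atrophy.get("striatum", 0.0))
        for e in self.ventricles:
            lab[e.inside(pts, shrink=g)] = CSF
        return lab


@dataclass
class PhantomSubject:
    name: str
    group: str
    volume: Volume3D           # rendered intensity image
    labels: Volume3D           # majority tissue label codes
    gm_fraction: Volume3D      # partial-volume GM fraction in [0, 1]
    striatum_fraction: Volume3D  # partial-volume fraction of striatal GM
    tiv_truth: float           # mm³
    affine_params: AffineParams
    warp_coefs: np.ndarray
    bias_truth: Volume3D

    def gm_truth(self) -> np.ndarray:
        """Per-voxel true GM content (partial-volume fraction)."""
        return self.gm_fraction.data

    def region_gm_volume(self, spec: PhantomSpec, region: str = "striatum") -> float:
        """True anatomical GM volume (mm³) of a labelled structure.

        Integrates the structure's partial-volume GM fraction weighted by
        the Jacobian of the subject's private transform, so the reported
        volume is measured in the subject's anatomy, independent of how
        the jitter stretched the rendering grid.
        """
        frac = (self.striatum_fraction.data if region == "striatum"
                else self.gm_fraction.data)
        pts = _world_points(spec)
        pts_subj = _subject_points(pts, self.affine_params, self.warp_coefs, spec)
        grad = np.empty(spec.shape + (3, 3))
        for a in range(3):
            for b in range(3):
                grad[..., a, b] = np.gradient(pts_subj[..., a], spec.voxel_size[b], axis=b)
        jac = np.abs(np.linalg.det(grad))
        return float(np.sum(jac * frac)) * self.volume.voxel_volume_mm3


@dataclass
class PhantomCohort:
    spec: PhantomSpec
    subjects: list

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame([{"subject": s.name, "group": s.group,
                              "tiv_truth": s.tiv_truth} for s in self.subjects])

    def volumes(self) -> list:
        return [s.volume for s in self.subjects]

    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])


def _world_points(spec: PhantomSpec) -> np.ndarray:
    idx = np.indices(spec.shape, dtype=float)
    m = spec.vox2world()
    return np.einsum("ab,b...->...a", m[:3, :3], idx) + m[:3, 3]


def _subject_points(pts: np.ndarray, params: AffineParams, warp_coefs: np.ndarray,
                    spec: PhantomSpec) -> np.ndarray:
    """Map template points into the subject's private anatomy coordinates."""
    m = compose_affine(params)
    out = np.einsum("ab,...b->...a", m[:3, :3], pts) + m[:3, 3]
    if warp_coefs is not None and np.any(warp_coefs):
        bases = tuple(dct_basis(n, k) for n, k in zip(spec.shape, warp_coefs.shape[:3]))
        u = np.stack([evaluate_field(warp_coefs[..., a], bases) for a in range(3)], axis=-1)
        out = out + u
    return out


def _class_fractions(spec: PhantomSpec, params: AffineParams, warp_coefs: np.ndarray,
                     atrophy: dict) -> np.ndarray:
    """(n1, n2, n3, 5) per-voxel tissue volume fractions, partial-volume
    rendered by evaluating the analytic geometry on a supersampled grid."""
    ss = max(1, int(spec.supersample))
    fractions = np.zeros(spec.shape + (5,))
    m = spec.vox2world()
    offsets = (np.arange(ss) + 0.5) / ss - 0.5
    idx = np.indices(spec.shape, dtype=float)
    for ox in offsets:
        for oy in offsets:
            for oz in offsets:
                shifted = idx + np.array([ox, oy, oz])[:, None, None, None]
                pts = np.einsum("ab,b...->...a", m[:3, :3], shifted) + m[:3, 3]
                pts_subj = _subject_points(pts, params, warp_coefs, spec)
                lab = spec.labels_at(pts_subj, atrophy=atrophy)
                for c in range(5):
                    fractions[..., c] += lab == c
    return fractions / ss**3


def _render_subject(spec: PhantomSpec, name: str, group: str, atrophy: dict,
                    rng: np.random.Generator) -> PhantomSubject:
    j = spec.affine_jitter
    params = AffineParams(
        translation=tuple(rng.normal(0.0, j["translation"], 3)),
        rotation=tuple(rng.normal(0.0, j["rotation"], 3)),
        scale=tuple(np.exp(rng.normal(0.0, j["scale"], 3))),
        shear=tuple(rng.normal(0.0, j["shear"], 3)),
    )
    warp_coefs = rng.normal(0.0, spec.warp_jitter_mm, spec.warp_orders + (3,))
    warp_coefs[0, 0, 0, :] = 0.0  # no net shift beyond the affine part

    fractions = _class_fractions(spec, params, warp_coefs, atrophy)
    labels = fractions.argmax(axis=-1).astype(np.int8)

    means_lut = np.array([spec.class_means[c] for c in range(5)])
    sds_lut = np.array([spec.class_sds[c] for c in range(5)])
    signal = fractions @ means_lut + (fractions @ sds_lut) * rng.standard_normal(spec.shape)

    bias_coefs = rng.normal(0.0, spec.bias_amplitude, spec.bias_orders)
    bias_coefs[0, 0, 0] = 0.0
    bases = tuple(dct_basis(n, k) for n, k in zip(spec.shape, spec.bias_orders))
    bias = np.exp(evaluate_field(bias_coefs, bases))

    intensity = signal * bias + spec.noise_sd * rng.standard_normal(spec.shape)

    v2w = spec.vox2world()
    vol = Volume3D(intensity, spec.voxel_size, v2w)
    lab_vol = Volume3D(labels.astype(float), spec.voxel_size, v2w.copy())
    gm_frac = fractions[..., CORTEX_GM] + fractions[..., STRIATUM_GM]
    tiv = float((1.0 - fractions[..., BG]).sum()) * vol.voxel_volume_mm3
    return PhantomSubject(name=name, group=group, volume=vol, labels=lab_vol,
                          gm_fraction=Volume3D(gm_frac, spec.voxel_size, v2w.copy()),
                          striatum_fraction=Volume3D(fractions[..., STRIATUM_GM],
                                                     spec.voxel_size, v2w.copy()),
                          tiv_truth=tiv, affine_params=params, warp_coefs=warp_coefs,
                          bias_truth=Volume3D(bias, spec.voxel_size, v2w.copy()))


def make_phantom_cohort(spec: PhantomSpec, n_control: int, n_disease: int) -> PhantomCohort:
    """Render a two-group cohort; disease subjects carry the spec's atrophy.

    The spec's seed fully determines the output; the same spec generates
    bit-identical cohorts on every call.
    """
    if n_control < 1 or n_disease < 1:
        raise ValueError("need at least one subject per group")
    rng = np.random.default_rng(spec.seed)
    subjects = []
    for i in range(n_control):
        subjects.append(_render_subject(spec, f"ctl{i:02d}", "control", {}, rng))
    for i in range(n_disease):
        subjects.append(_render_subject(spec, f"dis{i:02d}", "disease", dict(spec.atrophy), rng))
    return PhantomCohort(spec=spec, subjects=subjects)


def null_cohort(spec: PhantomSpec, n: int) -> PhantomCohort:
    """n exchangeable subjects from one population: no atrophy, one group."""
    if n < 2:
        raise ValueError("need at least 2 subjects")
    spec = replace(spec, atrophy={})
    rng = np.random.default_rng(spec.seed)
    subjects = [_render_subject(spec, f"sub{i:02d}", "null", {}, rng) for i in range(n)]
    return PhantomCohort(spec=spec, subjects=subjects)


def make_tpms(spec: PhantomSpec, fwhm_um: float = 600.0) -> TissueProbabilityMaps:
    """Template-space tissue priors: smoothed progenitor tissue fractions."""
    fractions = _class_fractions(spec, AffineParams(), np.zeros(spec.warp_orders + (3,)), {})
    v2w = spec.vox2world()

    def prior(frac: np.ndarray) -> Volume3D:
        vol = Volume3D(frac, spec.voxel_size, v2w.copy())
        return smooth(vol, fwhm_um)

    gm = prior(fractions[..., CORTEX_GM] + fractions[..., STRIATUM_GM])
    wm = prior(fractions[..., WM])
    csf = prior(fractions[..., CSF])
    total = gm.data + wm.data + csf.data
    scale = np.clip(total, 1.0, None)
    return TissueProbabilityMaps(gm=gm.with_data(gm.data / scale),
                                 wm=wm.with_data(wm.data / scale),
                                 csf=csf.with_data(csf.data / scale))


def template_region_mask(spec: PhantomSpec, region: str = "striatum") -> np.ndarray:
    """Boolean template-space mask of a named labelled region."""
    pts = _world_points(spec)
    ells = spec.striatum if region == "striatum" else (spec.brain,)
    inside = np.zeros(spec.shape, dtype=bool)
    for e in ells:
        inside |= e.inside(pts)
    return inside


def smoothed_gm_maps(cohort: PhantomCohort, fwhm_um: float = 400.0,
                     noise_sd: float = 0.02, seed: int = 0) -> list:
    """True-geometry GM maps plus iid noise, smoothed: the light route to
    group-level inputs when segmentation itself is not under test."""
    rng = np.random.default_rng(seed)
    out = []
    for s in cohort.subjects:
        gm = s.gm_truth().astype(float)
        gm = gm + noise_sd * rng.standard_normal(gm.shape)
        out.append(smooth(s.volume.with_data(gm), fwhm_um))
    return out
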