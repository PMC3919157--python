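import numpy as np
import pytest

from mousevbm.imagegeom import Volume3D, default_vox2world
from mousevbm.spatial import (WarpField, apply_warp, build_template,
                              jacobian_determinant, register_nonlinear, smooth)


@pytest.fixture(scope="module")
def template(quiet_subject):
    return quiet_subject.volume


@pytest.fixture(scope="module")
def brain_mask(quiet_subject):
    return quiet_subject.labels.data > 0


def synthetic_warp(reference, scale=0.02, orders=(4, 4, 4), seed=5):
    rng = np.random.default_rng(seed)
    coefs = np.zeros(orders + (3,))
    coefs[:3, :3, :3, :] = rng.normal(0, scale, (3, 3, 3, 3))
    coefs[0, 0, 0, :] = 0.0
    return WarpField(coefs=coefs, reference=reference)


class TestRegisterNonlinear:
    def test_self_registration_is_identity(self, template):
        w = register_nonlinear(template, template, n_basis=(4, 4, 4),
                               reg_weight=0.01, iterations=40)
        assert np.linalg.norm(w.dense(), axis=-1).max() < 0.05

    def test_recovers_known_smooth_warp(self, template, brain_mask):
        w_true = synthetic_warp(template)
        assert np.linalg.norm(w_true.dense(), axis=-1).max() < 0.6
        deformed = apply_warp(template, w_true)
        w_rec = register_nonlinear(template, deformed, n_basis=(4, 4, 4),
                                   reg_weight=0.01, iterations=150)
        err = np.linalg.norm(w_rec.dense() - w_true.dense(), axis=-1)
        assert np.sqrt(np.mean(err[brain_mask] ** 2)) < 0.1


class TestJacobian:
    def test_identity_warp(self, template):
        w = WarpField(coefs=np.zeros((3, 3, 3, 3)), reference=template)
        assert np.allclose(jacobian_determinant(w).data, 1.0)

    def test_matches_finite_difference_oracle(self, template):
        w = synthetic_warp(template, seed=9)
        jd = jacobian_determinant(w).data
        u = w.dense()
        vs = template.voxel_size
        g = np.empty(template.shape + (3, 3))
        for a in range(3):
            for b in range(3):
                g[..., a, b] = np.gradient(u[..., a], vs[b], axis=b)
        oracle = np.linalg.det(np.eye(3) + g)
        inner = (slice(2, -2),) * 3
        rel = np.abs(jd[inner] - oracle[inner]) / np.abs(oracle[inner])
        assert rel.max() < 1e-2


class TestApplyWarp:
    def test_identity_returns_input(self, template):
        w = WarpField(coefs=np.zeros((3, 3, 3, 3)), reference=template)
        out = apply_warp(template, w)
        assert np.abs(out.data - template.data).max() < 1e-6

    def test_modulation_conserves_mass(self, template):
        total = template.data.sum()
        for seed in (5, 9, 13):
            w = synthetic_warp(template, seed=seed)
            mod = apply_warp(template, w, modulate=True)
            assert abs(mod.data.sum() - total) / total < 0.01

    def test_regional_loss_survives_modulation(self):
        """A 15% implanted regional GM loss shows up as a ≈0.85 modulated
        regional integral ratio between disease and control truth maps."""
        from mousevbm.phantom import (PhantomSpec, make_phantom_cohort,
                                      template_region_mask)
        spec = PhantomSpec(seed=23, atrophy={"striatum": 0.15})
        coh = make_phantom_cohort(spec, 3, 3)
        region = template_region_mask(spec)
        tpl = smooth(coh.subjects[0].gm_fraction.with_data(
            np.mean([s.gm_fraction.data for s in coh.subjects[:3]], axis=0)), 200.0)
        sums = []
        for s in coh.subjects:
            g = smooth(s.gm_fraction, 200.0)
            w = register_nonlinear(g, tpl, n_basis=(8, 8, 6), reg_weight=0.05,
                                   iterations=60)
            sums.append(apply_warp(g, w, modulate=True).data[region].sum())
        ratio = np.mean(sums[3:]) / np.mean(sums[:3])
        assert ratio == pytest.approx(0.85, abs=0.05)


class TestSmooth:
    def test_zero_fwhm_is_identity(self, template):
        assert np.array_equal(smooth(template, 0.0).data, template.data)

    def test_negative_fwhm_rejected(self, template):
        with pytest.raises(ValueError):
            smooth(template, -1.0)

    def test_measured_fwhm_of_point_response(self):
        shape = (41, 41, 41)
        data = np.zeros(shape)
        data[20, 20, 20] = 1.0
        v = Volume3D(data, (0.1,) * 3, default_vox2world(shape, (0.1,) * 3))
        prof = smooth(v, 400.0).data[:, 20, 20]
        half = prof.max() / 2
        i = np.argmax(prof)
        left = np.interp(half, prof[:i + 1], np.arange(i + 1))
        right = np.interp(half, prof[i:][::-1], np.arange(i, len(prof))[::-1])
        measured_um = (right - left) * 100
        assert measured_um == pytest.approx(400.0, rel=0.05)

    def test_total_intensity_conserved(self, template):
        out = smooth(template, 400.0)
        assert abs(out.data.sum() - template.data.sum()) / template.data.sum() < 1e-6

    def test_linearity(self, template):
        rng = np.random.default_rng(3)
        b = template.with_data(rng.random(template.shape))
        lhs = smooth(template.with_data(template.data + b.data), 400.0).data
        rhs = smooth(template, 400.0).data + smooth(b, 400.0).data
        assert np.abs(lhs - rhs).max() < 1e-9

    def test_gaussian_semigroup(self, template):
        twice = smooth(smooth(template, 400.0), 400.0).data
        once = smooth(template, 400.0 * np.sqrt(2)).data
        inner = (slice(6, -6),) * 3
        denom = np.abs(once[inner]).max()
        assert np.abs(twice[inner] - once[inner]).max() / denom < 0.01


class TestBuildTemplate:
    def test_identical_inputs_reproduce_input(self, template):
        out = build_template([template, template], rounds=1, n_basis=(4, 4, 4),
                             iterations=20)
        assert np.abs(out.data - template.data).max() < 1e-6

    def test_opposite_deformations_average_to_progenitor(self, template):
        w = synthetic_warp(template, scale=0.03, seed=21)
        v1 = apply_warp(template, w)
        v2 = apply_warp(template, WarpField(coefs=-w.coefs, reference=template))
        tpl = build_template([v1, v2], rounds=2, n_basis=(4, 4, 4),
                             reg_weight=0.01, iterations=40)

        def rms(a, b):
            return np.sqrt(np.mean((a - b) ** 2))

        assert rms(tpl.data, template.data) < rms(v1.data, template.data)
        assert rms(tpl.data, template.data) < rms(v2.data, template.data)

    def test_too_few_volumes_rejected(self, template):
        with pytest.raises(ValueError):
            build_template([template])
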