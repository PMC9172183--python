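"""Phantom generators: signal model, ground-truth bookkeeping, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungwater.synthetic import (
    ShadingParams,
    ThoraxTruth,
    Vial,
    VialLayout,
    coil_shading_field,
    default_vial_layout,
    generate_thorax_phantom,
    generate_vial_phantom,
    partition_slices,
)
from lungwater.volumes import LABELS


class TestCoilShadingField:
    def test_no_gaussians_gives_constant_offset(self):
        fld = coil_shading_field((4, 5, 6), (3.5,) * 3, ShadingParams(offset=1.3))
        np.testing.assert_allclose(fld, 1.3)

    def test_positive_and_capped(self):
        params = ShadingParams(offset=0.5, cap=2.0, gaussians=(
            (5.0, (0.0, 0.0, 0.0), (30.0, 30.0, 30.0)),))
        fld = coil_shading_field((16, 16, 16), (3.5,) * 3, params)
        assert fld.min() > 0
        assert fld.max() / fld.min() <= 2.0 + 1e-9

    def test_symmetric_params_give_mirror_symmetric_field(self):
        ext = 15 * 3.5
        params = ShadingParams(gaussians=(
            (0.5, (ext / 2, ext / 2, ext / 2), (40.0, 40.0, 40.0)),))
        fld = coil_shading_field((16, 16, 16), (3.5,) * 3, params)
        np.testing.assert_allclose(fld, fld[::-1, ::-1, ::-1], rtol=1e-12)

    def test_posterior_gaussian_decreases_anteriorward(self):
        shape = (16, 16, 16)
        ext = [15 * 3.5] * 3
        params = ShadingParams(gaussians=(
            (0.5, (ext[0], ext[1] / 2, ext[2] / 2), (80.0, 200.0, 200.0)),))
        fld = coil_shading_field(shape, (3.5,) * 3, params)
        central = fld[:, 8, 8]
        assert np.all(np.diff(central) > 0)  # increases toward posterior

    def test_nonpositive_offset_rejected(self):
        with pytest.raises(ValueError):
            coil_shading_field((4, 4, 4), (3.5,) * 3, ShadingParams(offset=0.0))


class TestVialPhantom:
    def test_noise_free_vial_means_exact(self):
        vol, layout = generate_vial_phantom(noise_sd=0.0, seed=0, s0=100.0)
        rr = (np.arange(vol.shape[1]) * vol.spacing[1])[:, None]
        cc = (np.arange(vol.shape[2]) * vol.spacing[2])[None, :]
        for v in layout.vials:
            disc = ((rr - v.center_mm[0]) ** 2 + (cc - v.center_mm[1]) ** 2
                    <= (0.8 * v.radius_mm) ** 2)
            mean = vol.data[layout.central_slice][disc].mean()
            assert mean == pytest.approx(v.concentration, abs=1e-9)

    def test_seed_contract(self):
        a, _ = generate_vial_phantom(noise_sd=0.02, seed=1)
        b, _ = generate_vial_phantom(noise_sd=0.02, seed=2)
        a2, _ = generate_vial_phantom(noise_sd=0.02, seed=1)
        assert not np.array_equal(a.data, b.data)
        np.testing.assert_array_equal(a.data, a2.data)

    def test_overlapping_vials_rejected(self):
        layout = VialLayout(vials=(
            Vial((50.0, 50.0), 12.0, 50.0),
            Vial((55.0, 55.0), 12.0, 100.0, is_reference=True),
        ))
        with pytest.raises(ValueError, match="overlap"):
            generate_vial_phantom(layout)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            generate_vial_phantom(noise_sd=-0.1)

    def test_reference_flag_required(self):
        layout = VialLayout(vials=(Vial((50.0, 50.0), 10.0, 40.0),))
        with pytest.raises(ValueError, match="reference"):
            layout.validate()


class TestThoraxPhantom:
    def test_regional_means_match_targets(self, thorax_noise_free):
        vol, lab, truth = thorax_noise_free
        lung = lab.mask("right_lung") | lab.mask("left_lung")
        prof = truth.lung_profile
        names = ("anterior", "mid", "posterior")
        for target, part in zip(truth.regional_means, prof["partition"]):
            sl = prof["slices"][part]
            mean_wd = truth.wd_field[sl][lung[sl]].mean()
            assert mean_wd == pytest.approx(target, abs=0.5)

    def test_prone_reverses_gradient(self):
        truth = ThoraxTruth(shape=(48, 96, 96), posture="prone", noise_sd=0.0)
        _, lab, tr = generate_thorax_phantom(truth)
        lung = lab.mask("right_lung") | lab.mask("left_lung")
        prof = tr.lung_profile
        seg_means = [tr.wd_field[prof["slices"][p]][lung[prof["slices"][p]]].mean()
                     for p in prof["partition"]]
        assert seg_means[0] > seg_means[2]  # anterior > posterior when prone

    def test_shading_is_multiplicative(self):
        base = ThoraxTruth(shape=(32, 64, 64), noise_sd=0.0,
                           shading=ShadingParams(offset=1.0))
        ext = [n * 3.5 for n in base.shape]
        shaded = ThoraxTruth(shape=(32, 64, 64), noise_sd=0.0,
                             shading=ShadingParams(offset=1.0, gaussians=(
                                 (0.5, (ext[0], ext[1] / 2, ext[2] / 2),
                                  (150.0, 200.0, 200.0)),)))
        v0, _, _ = generate_thorax_phantom(base)
        v1, _, t1 = generate_thorax_phantom(shaded)
        nz = v0.data > 0
        np.testing.assert_allclose(v1.data[nz] / v0.data[nz],
                                   t1.coil_field[nz], rtol=1e-9)

    def test_liver_sits_directly_under_right_lung(self, thorax_noise_free):
        _, lab, _ = thorax_noise_free
        right = lab.mask("right_lung")
        liver = lab.mask("liver")
        sl, rw, cl = np.nonzero(right)
        touching = 0
        columns = set(zip(sl.tolist(), cl.tolist()))
        for s, c in columns:
            bottom = rw[(sl == s) & (cl == c)].max()
            if bottom + 1 < lab.shape[1] and liver[s, bottom + 1, c]:
                touching += 1
        assert touching / len(columns) > 0.95

    def test_deterministic_given_seed(self):
        t = ThoraxTruth(shape=(32, 64, 64), noise_sd=0.02, seed=7)
        a, _, _ = generate_thorax_phantom(t)
        b, _, _ = generate_thorax_phantom(ThoraxTruth(shape=(32, 64, 64),
                                                      noise_sd=0.02, seed=7))
        np.testing.assert_array_equal(a.data, b.data)

    def test_invalid_regional_means_rejected(self):
        with pytest.raises(ValueError):
            ThoraxTruth(regional_means=(21.0, 23.0, 130.0)).validate()

    def test_unknown_posture_rejected(self):
        with pytest.raises(ValueError):
            ThoraxTruth(posture="sideways").validate()


class TestPartitionSlices:
    @given(st.integers(min_value=3, max_value=200))
    @settings(max_examples=50, deadline=None)
    def test_partition_covers_contiguously_and_balances(self, n):
        a, m, p = partition_slices(n)
        sizes = [a.stop - a.start, m.stop - m.start, p.stop - p.start]
        assert sum(sizes) == n
        assert a.start == 0 and a.stop == m.start and m.stop == p.start
        assert p.stop == n
        assert max(sizes) - min(sizes) <= 1

    def test_exact_division(self):
        a, m, p = partition_slices(9)
        assert (a, m, p) == (slice(0, 3), slice(3, 6), slice(6, 9))

    def test_remainder_goes_to_mid_then_posterior(self):
        a, m, p = partition_slices(10)
        assert (m.stop - m.start, p.stop - p.start, a.stop - a.start) == (4, 3, 3)
        a, m, p = partition_slices(11)
        assert (a.stop - a.start, m.stop - m.start, p.stop - p.start) == (3, 4, 4)

    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError):
            partition_slices(2)
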