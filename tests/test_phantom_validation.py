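"""Vial phantom analysis: ROI extraction, regression, Bland-Altman, ICC."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from lungwater.phantom import (
    bland_altman,
    extract_vial_means,
    icc_absolute_agreement,
    linear_agreement,
    run_phantom_experiment,
)
from lungwater.synthetic import (
    Vial,
    VialLayout,
    default_vial_layout,
    generate_vial_phantom,
)


class TestExtractVialMeans:
    def test_noise_free_relative_densities_exact(self):
        vol, layout = generate_vial_phantom(noise_sd=0.0, seed=0)
        ms = extract_vial_means(vol, layout)
        for m in ms:
            assert m.relative_density == pytest.approx(m.known_concentration,
                                                       abs=1e-9)
        ref = [m for m in ms if m.is_reference]
        assert len(ref) == 1 and ref[0].relative_density == pytest.approx(100.0)

    def test_noisy_estimates_within_three_percent(self):
        layout = default_vial_layout()
        for seed in (1, 2, 3):
            vol, _ = generate_vial_phantom(layout, noise_sd=0.02, seed=seed)
            for m in extract_vial_means(vol, layout):
                assert abs(m.relative_density - m.known_concentration) < 3.0

    def test_roi_outside_volume_rejected(self):
        layout = VialLayout(
            shape=(8, 32, 32),
            vials=(Vial((5.0, 5.0), 10.0, 50.0),
                   Vial((60.0, 60.0), 10.0, 100.0, is_reference=True)),
            slice_range=(2, 6),
        )
        vol, _ = generate_vial_phantom(layout, noise_sd=0.0)
        with pytest.raises(ValueError, match="leaves the volume"):
            extract_vial_means(vol, layout, roi_shrink=1.2)


class TestLinearAgreement:
    def test_identity(self):
        slope, intercept, r2 = linear_agreement([1, 2, 3, 4], [1, 2, 3, 4])
        assert (slope, intercept, r2) == pytest.approx((1.0, 0.0, 1.0))

    def test_affine(self):
        known = np.array([10.0, 20.0, 30.0, 40.0])
        slope, intercept, r2 = linear_agreement(known, 2 * known + 5)
        assert (slope, intercept, r2) == pytest.approx((2.0, 5.0, 1.0))

    def test_hand_solved_three_points(self):
        # OLS through (0,1), (1,1), (2,3): slope 1, intercept 2/3
        slope, intercept, _ = linear_agreement([0, 1, 2], [1, 1, 3])
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(2.0 / 3.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            linear_agreement([5, 5, 5], [1, 2, 3])

    def test_r2_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(0)
        x = rng.normal(50, 20, 12)
        y = x + rng.normal(0, 4, 12)
        _, _, r2 = linear_agreement(x, y)
        _, _, r2b = linear_agreement(3.0 * x - 7.0, 0.5 * y + 11.0)
        assert r2b == pytest.approx(r2, abs=1e-12)


class TestBlandAltman:
    def test_identical_lists(self):
        bias, sd = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (bias, sd) == (0.0, 0.0)

    def test_constant_offset(self):
        a = np.array([10.0, 20.0, 30.0])
        bias, sd = bland_altman(a + 4.3, a)
        assert bias == pytest.approx(4.3)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_sd(self):
        # differences {1, -1}: bias 0, sample SD sqrt(2)
        bias, sd = bland_altman([1.0, 0.0], [0.0, 1.0])
        assert bias == pytest.approx(0.0)
        assert sd == pytest.approx(np.sqrt(2.0))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0, 2.0])


class TestICC:
    def test_perfect_agreement(self):
        assert icc_absolute_agreement([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0

    def test_discordant_pairs_negative(self):
        assert icc_absolute_agreement([1, 2, 3, 4], [4, 3, 2, 1]) < 0

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(30, 10, 10)
        y = x + rng.normal(0, 3, 10)
        assert icc_absolute_agreement(x + 100, y + 100) == pytest.approx(
            icc_absolute_agreement(x, y), abs=1e-12)

    def test_matches_variance_components_reference(self):
        # independent oracle: pingouin's two-way absolute-agreement single-
        # measure ICC on random 10x2 tables
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.normal(50, 20, 10)
            y = x * rng.uniform(0.8, 1.2) + rng.normal(0, 5, 10)
            df = pd.DataFrame({
                "target": list(range(10)) * 2,
                "rater": ["known"] * 10 + ["measured"] * 10,
                "rating": np.concatenate([x, y]),
            })
            ref = (pg.intraclass_corr(df, targets="target", raters="rater",
                                      ratings="rating")
                   .set_index("Type").loc["ICC(A,1)", "ICC"])
            assert icc_absolute_agreement(x, y) == pytest.approx(ref,
                                                                 abs=1e-8)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement([1, 2], [1, 2])


class TestPhantomExperiment:
    def test_noise_free_is_perfect(self):
        stats, per_repeat = run_phantom_experiment(2, noise_sd=0.0,
                                                   seeds=(5, 9))
        assert stats.bias == pytest.approx(0.0, abs=1e-9)
        assert stats.icc == pytest.approx(1.0, abs=1e-12)
        assert stats.r_squared == pytest.approx(1.0, abs=1e-12)
        assert per_repeat == pytest.approx([1.0, 1.0])

    def test_more_noise_does_not_improve_agreement(self):
        # Monte-Carlo trend: mean ICC at doubled noise is not higher
        low, high = [], []
        for seed in range(20):
            s_low, _ = run_phantom_experiment(1, noise_sd=0.03,
                                              seeds=(seed,))
            s_high, _ = run_phantom_experiment(1, noise_sd=0.06,
                                               seeds=(seed,))
            low.append(s_low.icc)
            high.append(s_high.icc)
        assert np.mean(high) <= np.mean(low)

    def test_seed_per_repeat_required(self):
        with pytest.raises(ValueError):
            run_phantom_experiment(3, seeds=(1,))
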