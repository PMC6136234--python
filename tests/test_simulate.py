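"""Synthetic CGM generator: determinism, target fidelity, fractal oracle."""

import numpy as np
import pytest

from glucodyn.errors import ParameterError
from glucodyn.gv import compute_gv
from glucodyn.simulate import (
    CohortSpec,
    SimProfile,
    fgn_autocovariance,
    generate_cgm,
    generate_cohort,
    generate_fgn,
    preset,
)
from glucodyn.dfa import scaling_exponent


class TestFgn:
    def test_h_half_is_white_noise(self):
        x = generate_fgn(0.5, 1024, seed=1)
        lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(lag1) < 3 / np.sqrt(1024)

    def test_deterministic_given_seed(self):
        a = generate_fgn(0.7, 512, seed=9)
        b = generate_fgn(0.7, 512, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_autocovariance_sign_structure(self):
        # persistent noise (H>1/2) has positive lag-1 autocovariance,
        # anti-persistent (H<1/2) negative
        assert fgn_autocovariance(0.8, np.array([1]))[0] > 0
        assert fgn_autocovariance(0.3, np.array([1]))[0] < 0

    def test_empirical_variance_near_unity(self):
        x = generate_fgn(0.8, 8192, seed=3)
        assert 0.8 < x.std() < 1.2

    @pytest.mark.parametrize("hurst,n", [(0.0, 64), (1.0, 64), (-0.2, 64), (0.5, 4)])
    def test_parameter_errors(self, hurst, n):
        with pytest.raises(ParameterError):
            generate_fgn(hurst, n, seed=0)

    def test_high_hurst_dfa_slope(self):
        ests = [scaling_exponent(generate_fgn(0.9, 4096, seed=s)) for s in range(30)]
        assert abs(np.mean(ests) - 0.9) <= 0.1


class TestGenerateCgm:
    def test_nd_preset_mean_within_one_percent(self):
        for seed in range(20):
            series = generate_cgm(preset("ND"), n_points=576, seed=seed)
            assert 5.35 <= series.values.mean() <= 5.45

    def test_target_fidelity_all_presets(self):
        # realized mean within 1% and %CV within 10% relative, 100 seeds
        for label in ("ND", "T2D", "T1D"):
            prof = preset(label)
            for seed in range(100):
                g = compute_gv(generate_cgm(prof, seed=seed))
                assert abs(g.mean_glucose - prof.mean_glucose) <= 0.01 * prof.mean_glucose
                assert abs(g.cv_percent - prof.cv_percent) <= 0.10 * prof.cv_percent

    def test_degenerate_profile_constant_series(self):
        prof = SimProfile(
            label="flat", mean_glucose=6.0, cv_percent=0.0, hurst=0.5,
            circadian_amp=0.0, meal_amp=0.0, noise_sd=0.0, fgn_sd=0.0,
        )
        series = generate_cgm(prof, n_points=64, seed=0)
        np.testing.assert_allclose(series.values, 6.0)

    def test_t1d_cv_exceeds_nd_cv_every_seed(self):
        nd = [compute_gv(generate_cgm(preset("ND"), seed=s)).cv_percent for s in range(100)]
        t1d = [compute_gv(generate_cgm(preset("T1D"), seed=s)).cv_percent for s in range(100)]
        assert min(t1d) > max(nd)

    def test_clipping_recorded(self):
        prof = SimProfile(label="x", mean_glucose=4.0, cv_percent=60.0, hurst=0.5)
        series = generate_cgm(prof, n_points=576, seed=1)
        assert series.values.min() >= 2.2
        assert series.meta["clip_fraction"] > 0
        assert "warning" in series.meta  # >5% of points clipped

    def test_invalid_profile_rejected(self):
        with pytest.raises(ParameterError):
            SimProfile(label="bad", mean_glucose=-1.0, cv_percent=10, hurst=0.5)
        with pytest.raises(ParameterError):
            SimProfile(label="bad", mean_glucose=5.0, cv_percent=10, hurst=1.5)


class TestCohort:
    def test_study_sized_cohort(self):
        spec = CohortSpec(
            groups=((preset("ND"), 12), (preset("T2D"), 143), (preset("T1D"), 22)),
            n_points=64,
            seed=7,
        )
        series, records = generate_cohort(spec)
        assert len(series) == 177
        assert len(records) == 177
        ids = [r.subject_id for r in records]
        assert len(set(ids)) == 177

    def test_reproducible_bitwise(self):
        spec = CohortSpec(groups=((preset("ND"), 3),), n_points=64, seed=11)
        s1, r1 = generate_cohort(spec)
        s2, r2 = generate_cohort(spec)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.values, b.values)
        assert r1 == r2

    def test_all_series_have_requested_length(self):
        spec = CohortSpec(groups=((preset("ND"), 12),), n_points=96, seed=3)
        series, _ = generate_cohort(spec)
        assert all(len(s) == 96 for s in series)

    def test_covariates_plausible(self):
        spec = CohortSpec(groups=((preset("T1D"), 22),), n_points=64, seed=5)
        _, records = generate_cohort(spec)
        assert all(r.therapy_code == 4 for r in records)  # insulin alone
        assert all(r.diabetes_duration > 0 for r in records)
        assert all(18 <= r.age for r in records)

    def test_target_jitter_spreads_cv_within_group(self):
        base = CohortSpec(groups=((preset("T1D"), 20),), n_points=96, seed=2)
        jit = CohortSpec(
            groups=((preset("T1D"), 20),), n_points=96, seed=2, target_jitter=True
        )
        cvs_base = [
            s.meta["realized_cv_percent"] for s in generate_cohort(base)[0]
        ]
        cvs_jit = [s.meta["realized_cv_percent"] for s in generate_cohort(jit)[0]]
        assert np.std(cvs_base) < 1.0  # every subject near the group target
        assert np.std(cvs_jit) > 2.0  # published between-subject spread

    def test_empty_groups_rejected(self):
        with pytest.raises(ParameterError):
            CohortSpec(groups=(), seed=0)
        with pytest.raises(ParameterError):
            CohortSpec(groups=((preset("ND"), 0),), seed=0)
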