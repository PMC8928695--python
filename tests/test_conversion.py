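"""Three-segment conversion model: prediction, distances, fitting."""
import numpy as np
import pytest

from sinusmrac import conversion
from sinusmrac.conversion import (
    ConversionModel,
    IllPosedFitWarning,
    derive_subject_seed,
    fit_bootstrap,
    fit_cohort,
    fit_once,
    leave_one_out,
    point_curve_distance,
)


def law_sample(rng, n, m_low=120.0, m_high=880.0, lo=40.0, hi=960.0,
               mri_sd=0.0, hu_sd=0.0):
    m = rng.uniform(lo, hi, n)
    hu = np.interp(m, [m_low, m_high], [-1000.0, 0.0])
    return np.column_stack([m + rng.normal(0, mri_sd, n) if mri_sd else m,
                            hu + rng.normal(0, hu_sd, n) if hu_sd else hu])


class TestPredict:
    def test_plateaus_are_exact(self):
        model = ConversionModel(100.0, 900.0)
        assert model.predict_hu(90.0) == -1000.0
        assert model.predict_hu(910.0) == 0.0

    def test_midpoint_of_ramp(self):
        model = ConversionModel(100.0, 900.0)
        assert model.predict_hu(500.0) == pytest.approx(-500.0)

    def test_range_and_monotonicity_on_dense_grid(self):
        model = ConversionModel(120.0, 880.0)
        hu = model.predict_hu(np.linspace(-500, 2000, 4001))
        assert hu.min() >= -1000.0 and hu.max() <= 0.0
        assert np.all(np.diff(hu) >= 0)

    def test_inverted_breakpoints_rejected(self):
        with pytest.raises(ValueError):
            ConversionModel(900.0, 100.0)


def polyline_distance_oracle(point, m_low, m_high, scales, n=100_000):
    """Dense sampling of the polyline; distances in normalized units."""
    s_mri, s_hu = scales
    span = m_high - m_low
    xs = np.concatenate([
        np.linspace(m_low - 5 * span, m_low, n // 3),
        np.linspace(m_low, m_high, n // 3),
        np.linspace(m_high, m_high + 5 * span, n // 3),
    ])
    ys = np.interp(xs, [m_low, m_high], [-1000.0, 0.0])
    dx = (point[0] - xs) / s_mri
    dy = (point[1] - ys) / s_hu
    return float(np.sqrt(dx**2 + dy**2).min())


class TestPointCurveDistance:
    def test_on_diagonal_is_zero(self):
        assert point_curve_distance((500.0, -500.0), (100.0, 900.0), (1000.0, 1000.0)) \
            == pytest.approx(0.0, abs=1e-12)

    def test_left_plateau_extends_forever(self):
        assert point_curve_distance((-1e6, -1000.0), (100.0, 900.0), (1000.0, 1000.0)) \
            == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "point", [(900.0, -500.0), (0.0, 200.0), (1200.0, -100.0), (450.0, -900.0)]
    )
    def test_matches_dense_sampling_oracle(self, point):
        scales = (1.0, 1.0)
        got = point_curve_distance(point, (100.0, 900.0), scales)
        want = polyline_distance_oracle(point, 100.0, 900.0, scales)
        assert got == pytest.approx(want, abs=1e-3)

    def test_nonpositive_scales_rejected(self):
        with pytest.raises(ValueError):
            point_curve_distance((0, 0), (1, 2), (0.0, 1000.0))


class TestFitOnce:
    def test_exact_recovery_when_truth_on_lattice(self):
        # sample spans [0, 63] so the 64-point lattice is the integers;
        # the generating breakpoints (10, 50) lie on it -> zero-loss minimum
        rng = np.random.default_rng(0)
        m = np.concatenate([[0.0, 63.0], rng.uniform(0, 63, 200)])
        hu = np.interp(m, [10.0, 50.0], [-1000.0, 0.0])
        m_low, m_high = fit_once(np.column_stack([m, hu]))
        assert m_low == pytest.approx(10.0, abs=1e-9)
        assert m_high == pytest.approx(50.0, abs=1e-9)

    def test_noisy_recovery_within_five_percent(self):
        rng = np.random.default_rng(1)
        sample = law_sample(rng, 400, mri_sd=10.0, hu_sd=25.0)
        m_low, m_high = fit_once(sample)
        assert abs(m_low - 120.0) / 120.0 < 0.05
        assert abs(m_high - 880.0) / 880.0 < 0.05

    def test_plateau_only_sample_warns_ill_posed(self):
        sample = np.column_stack([np.linspace(40, 100, 50),
                                  np.full(50, -1000.0)])
        with pytest.warns(IllPosedFitWarning):
            fit_once(sample)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            fit_once([(0.0, -1000.0)] * 5)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_once([])

    def test_returned_candidate_minimizes_lattice_loss(self):
        """The fit never loses to any candidate on its own coarse lattice."""
        rng = np.random.default_rng(2)
        sample = law_sample(rng, 80, mri_sd=15.0, hu_sd=40.0)
        m_low, m_high = fit_once(sample, n_grid=16)
        scales = conversion.default_scales(sample[:, 0])
        xm = sample[:, 0] / scales[0]
        ym = sample[:, 1] / scales[1]

        def loss(l, h):
            d2 = conversion._squared_distances(
                xm, ym, np.array([l / scales[0]]), np.array([h / scales[0]]),
                y_air=-1000.0 / scales[1],
            )
            return d2.sum()

        best = loss(m_low, m_high)
        lattice = np.linspace(sample[:, 0].min(), sample[:, 0].max(), 16)
        for l in lattice:
            for h in lattice:
                if l < h:
                    assert best <= loss(l, h) + 1e-9


class TestBootstrap:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        voxels = law_sample(rng, 300, mri_sd=10.0, hu_sd=25.0)
        a = fit_bootstrap(voxels, n_vox=100, n_reps=5, seed=7)
        b = fit_bootstrap(voxels, n_vox=100, n_reps=5, seed=7)
        assert (a.m_low, a.m_high) == (b.m_low, b.m_high)
        assert a.fit_meta["per_repeat"] == b.fit_meta["per_repeat"]

    def test_noise_free_repeats_are_identical(self):
        rng = np.random.default_rng(4)
        voxels = law_sample(rng, 300)
        model = fit_bootstrap(voxels, n_vox=150, n_reps=4, seed=0)
        reps = np.asarray(model.fit_meta["per_repeat"])
        assert np.ptp(reps[:, 0]) < 1.0 and np.ptp(reps[:, 1]) < 1.0
        assert abs(model.m_low - 120.0) < 5.0
        assert abs(model.m_high - 880.0) < 10.0

    def test_noisy_bootstrap_spreads_and_recovers(self):
        rng = np.random.default_rng(5)
        voxels = law_sample(rng, 500, mri_sd=10.0, hu_sd=25.0)
        model = fit_bootstrap(voxels, n_vox=100, n_reps=20, seed=1)
        reps = np.asarray(model.fit_meta["per_repeat"])
        assert reps[:, 0].std() > 0
        assert abs(model.m_low - 120.0) / 120.0 < 0.05
        assert abs(model.m_high - 880.0) / 880.0 < 0.05

    def test_insufficient_voxels_rejected(self):
        with pytest.raises(ValueError, match="voxels"):
            fit_bootstrap(law_sample(np.random.default_rng(0), 50), n_vox=100)


class TestCohortAndLeaveOneOut:
    def make_samples(self, n_subjects, seed=6, clean=True):
        rng = np.random.default_rng(seed)
        kwargs = {} if clean else {"mri_sd": 10.0, "hu_sd": 25.0}
        return [law_sample(rng, 300, **kwargs) for _ in range(n_subjects)]

    def test_single_subject_equals_bootstrap(self):
        [sample] = self.make_samples(1)
        cohort = fit_cohort([sample], seed=2, n_reps=5)
        solo = fit_bootstrap(sample, seed=derive_subject_seed(2, 0), n_reps=5)
        assert cohort.m_low == solo.m_low
        assert cohort.m_high == solo.m_high

    def test_identical_clean_subjects_average_to_same_model(self):
        sample = self.make_samples(1)[0]
        cohort = fit_cohort([sample, sample], seed=0, n_reps=4)
        solo = fit_bootstrap(sample, seed=derive_subject_seed(0, 0), n_reps=4)
        assert cohort.m_low == pytest.approx(solo.m_low, abs=1e-6)
        assert cohort.m_high == pytest.approx(solo.m_high, abs=1e-6)

    def test_loo_of_two_reduces_to_other_subject(self):
        samples = self.make_samples(2, clean=False)
        model = leave_one_out(samples, held_out=1, seed=3, n_reps=5)
        solo = fit_bootstrap(samples[0], seed=derive_subject_seed(3, 0), n_reps=5)
        assert model.m_low == solo.m_low
        assert model.m_high == solo.m_high
        assert model.fit_meta["held_out"] == 1

    def test_loo_invariant_to_held_out_data(self):
        samples = self.make_samples(3, clean=False)
        a = leave_one_out(samples, held_out=2, seed=4, n_reps=5)
        samples[2] = samples[2] * 1.7 + 3.0  # corrupt the excluded subject
        b = leave_one_out(samples, held_out=2, seed=4, n_reps=5)
        assert (a.m_low, a.m_high) == (b.m_low, b.m_high)

    def test_index_out_of_range_rejected(self):
        samples = self.make_samples(2)
        with pytest.raises(IndexError):
            leave_one_out(samples, held_out=5)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_cohort([])

    def test_cohort_of_one_rejected_for_loo(self):
        with pytest.raises(ValueError):
            leave_one_out(self.make_samples(1), held_out=0)


def test_bias_shrinks_as_noise_shrinks():
    """Parameter-recovery bias goes to zero with the noise level."""
    errors = []
    for sd_scale in (2.0, 1.0, 0.0):
        rng = np.random.default_rng(8)
        sample = law_sample(rng, 400, mri_sd=10 * sd_scale, hu_sd=25 * sd_scale)
        m_low, m_high = fit_once(sample)
        errors.append(abs(m_low - 120.0) + abs(m_high - 880.0))
    assert errors[2] <= errors[0] + 1e-6
    assert errors[2] < 2.0
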