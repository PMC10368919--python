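"""Fisher averaging, masked correlations, deviation-scores and curve fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disconnmap import (
    UndefinedCorrelationError,
    VolumeGrid,
    deviation_score,
    external_reliability,
    fisher_mean,
    fit_reliability_curve,
    internal_reliability,
    make_patient_like_map,
    masked_correlation,
)


class TestFisherMean:
    def test_fixed_points(self):
        assert fisher_mean([0.0, 0.0]) == 0.0
        np.testing.assert_allclose(fisher_mean([0.5, 0.5]), 0.5, atol=1e-12)

    def test_closed_form(self):
        expected = np.tanh((np.arctanh(0.3) + np.arctanh(0.7)) / 2)
        np.testing.assert_allclose(fisher_mean([0.3, 0.7]), expected, rtol=1e-12)

    def test_degenerate_perfect_correlations_stay_finite(self):
        r = fisher_mean([1.0, 1.0, 1.0])
        assert 0.999 < r <= 1.0

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            fisher_mean([])
        with pytest.raises(ValueError):
            fisher_mean([0.2, np.nan])
        with pytest.raises(ValueError):
            fisher_mean([1.2])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-0.95, 0.95), min_size=2, max_size=8))
    def test_permutation_symmetric(self, rs):
        np.testing.assert_allclose(
            fisher_mean(rs), fisher_mean(list(reversed(rs))), rtol=1e-12
        )


@pytest.fixture
def corr_setup(identity_grid, rng):
    brain = identity_grid.like(np.ones(identity_grid.shape, dtype=bool))
    lesion = identity_grid.like(np.zeros(identity_grid.shape, dtype=bool))
    lesion.data[3:5, 3:5, 3:5] = True
    a = identity_grid.like(rng.random(identity_grid.shape))
    return brain, lesion, a


class TestMaskedCorrelation:
    def test_affine_relation_gives_unit_correlation(self, corr_setup):
        brain, lesion, a = corr_setup
        b = a.like(2 * a.data + 1)
        r, n = masked_correlation(a, b, brain)
        np.testing.assert_allclose(r, 1.0, atol=1e-12)
        assert n == a.data.size

    def test_negated_map_gives_minus_one(self, corr_setup):
        brain, _, a = corr_setup
        r, _ = masked_correlation(a, a.like(-a.data), brain)
        np.testing.assert_allclose(r, -1.0, atol=1e-12)

    def test_matches_sum_based_pearson_oracle(self, corr_setup, rng):
        brain, lesion, a = corr_setup
        b = a.like(rng.random(a.shape))
        for include in (True, False):
            r, n = masked_correlation(a, b, brain, lesion, include_lesion=include)
            used = brain.data.astype(bool)
            if not include:
                used &= ~lesion.data.astype(bool)
            x, y = a.data[used], b.data[used]
            sx, sy, sxy = x.sum(), y.sum(), (x * y).sum()
            sxx, syy, m = (x * x).sum(), (y * y).sum(), x.size
            expected = (m * sxy - sx * sy) / np.sqrt(
                (m * sxx - sx**2) * (m * syy - sy**2)
            )
            np.testing.assert_allclose(r, expected, rtol=1e-10)
            assert n == m

    def test_lesion_exclusion_removes_exactly_lesion_voxels(self, corr_setup, rng):
        brain, lesion, a = corr_setup
        b = a.like(rng.random(a.shape))
        _, n_in = masked_correlation(a, b, brain, lesion, include_lesion=True)
        _, n_ex = masked_correlation(a, b, brain, lesion, include_lesion=False)
        assert n_in - n_ex == int(lesion.data.sum())

    def test_zero_variance_raises(self, corr_setup):
        brain, _, a = corr_setup
        flat = a.like(np.ones(a.shape))
        with pytest.raises(UndefinedCorrelationError):
            masked_correlation(a, flat, brain)

    def test_invariant_to_positive_rescaling(self, corr_setup, rng):
        brain, _, a = corr_setup
        b = a.like(rng.random(a.shape))
        r1, _ = masked_correlation(a, b, brain)
        r2, _ = masked_correlation(a.like(3.7 * a.data), b.like(0.2 * b.data), brain)
        np.testing.assert_allclose(r1, r2, rtol=1e-10)


class TestInternalReliability:
    def test_identical_maps_reach_clamp_ceiling(self, identity_grid, rng):
        base = rng.random(identity_grid.shape)
        maps = [identity_grid.like(base.copy()) for _ in range(4)]
        brain = identity_grid.like(np.ones(identity_grid.shape, dtype=bool))
        rep = internal_reliability(maps, brain)
        assert all(r > 0.999 for r in rep.per_subject_r)
        assert rep.mean_r > 0.999

    def test_three_subjects_match_pairwise_mean_oracle(self, identity_grid, rng):
        maps = [identity_grid.like(rng.random(identity_grid.shape)) for _ in range(3)]
        brain = identity_grid.like(np.ones(identity_grid.shape, dtype=bool))
        rep = internal_reliability(maps, brain)
        for i in range(3):
            others = [m.data for j, m in enumerate(maps) if j != i]
            loo = (others[0] + others[1]) / 2
            expected = np.corrcoef(maps[i].data.ravel(), loo.ravel())[0, 1]
            np.testing.assert_allclose(rep.per_subject_r[i], expected, rtol=1e-10)
        np.testing.assert_allclose(rep.mean_r, fisher_mean(rep.per_subject_r))

    def test_white_noise_maps_have_near_zero_reliability(self, identity_grid, rng):
        maps = [identity_grid.like(rng.standard_normal(identity_grid.shape))
                for _ in range(6)]
        brain = identity_grid.like(np.ones(identity_grid.shape, dtype=bool))
        rep = internal_reliability(maps, brain)
        assert abs(rep.mean_r) < 3 / np.sqrt(rep.n_voxels_used)

    def test_zero_variance_subject_dropped_with_warning(self, identity_grid, rng):
        maps = [identity_grid.like(rng.random(identity_grid.shape)) for _ in range(3)]
        maps.append(identity_grid.like(np.zeros(identity_grid.shape)))
        brain = identity_grid.like(np.ones(identity_grid.shape, dtype=bool))
        with pytest.warns(UserWarning, match="dropped"):
            rep = internal_reliability(maps, brain)
        assert rep.dropped_subjects == [3]
        assert len(rep.per_subject_r) == 3

    def test_requires_three_subjects(self, identity_grid):
        m = identity_grid.like(np.ones(identity_grid.shape))
        brain = identity_grid.like(np.ones(identity_grid.shape, dtype=bool))
        with pytest.raises(ValueError, match=">= 3"):
            internal_reliability([m, m], brain)


class TestExternalReliability:
    def test_patient_equal_to_prediction_gives_unit_r(self, small_scene, small_prediction):
        rep = external_reliability(
            small_prediction, small_prediction.mean, small_scene["brain_mask"]
        )
        assert rep.mean_r > 0.999
        assert rep.kind == "external"

    def test_fov_mask_halves_used_voxels(self, small_scene, small_prediction, rng):
        brain = small_scene["brain_mask"]
        patient = small_prediction.mean.like(
            small_prediction.mean.data + rng.random(brain.shape)
        )
        fov = brain.like(np.ones(brain.shape, dtype=bool))
        fov.data[brain.shape[0] // 2:, :, :] = False
        full = external_reliability(small_prediction, patient, brain)
        half = external_reliability(small_prediction, patient, brain, fov_mask=fov)
        expected = int((brain.data.astype(bool) & fov.data).sum())
        assert half.n_voxels_used == expected
        assert half.n_voxels_used < full.n_voxels_used

    def test_same_model_patient_r_within_database_range(self, small_scene, small_prediction):
        """A patient drawn from the database's own generative model should
        agree with the prediction about as well as the database members
        agree among themselves."""
        from disconnmap import (
            SelectionMode, internal_reliability, make_patient_tractogram,
            select_damaged, visitation_map,
        )

        maps = [
            visitation_map(select_damaged(t, small_scene["lesion"]), small_scene["grid"])
            for t in small_scene["tractograms"]
        ]
        rep_int = internal_reliability(maps, small_scene["brain_mask"])
        pt = make_patient_tractogram(
            small_scene["spec"], seed=5,
            translation_sd_mm=small_scene["spec"].subject_translation_sd_mm,
        )
        pmap = visitation_map(
            select_damaged(pt, small_scene["lesion"], SelectionMode("patient", 2.0)),
            small_scene["grid"],
        )
        rep_ext = external_reliability(small_prediction, pmap, small_scene["brain_mask"])
        lo = min(rep_int.per_subject_r) - 0.1
        hi = 1.0
        assert lo <= rep_ext.mean_r <= hi


class TestDeviationScore:
    def test_zero_for_patient_equal_to_mean(self, small_scene, small_prediction):
        d = deviation_score(
            small_prediction, small_prediction.mean, small_scene["brain_mask"],
            small_scene["lesion"],
        )
        assert d.score == 0.0
        assert d.lesion_volume_ml > 0

    def test_one_when_offset_by_total_deviation(self, small_scene, small_prediction):
        s = small_prediction.total_deviation()
        patient = small_prediction.mean.like(small_prediction.mean.data + s)
        d = deviation_score(small_prediction, patient, small_scene["brain_mask"])
        np.testing.assert_allclose(d.score, 1.0, rtol=1e-10)

    def test_gaussian_draws_calibrate_to_one(self, small_scene, small_prediction, rng):
        """d ~ N(mean, s^2) per voxel gives RMS normalized deviation ~ 1."""
        s = small_prediction.total_deviation()
        used = small_scene["brain_mask"].data.astype(bool) & (s > 0)
        draw = small_prediction.mean.data + rng.standard_normal(s.shape) * s
        d = deviation_score(
            small_prediction, small_prediction.mean.like(draw),
            small_scene["brain_mask"],
        )
        assert abs(d.score - 1.0) < 4 / np.sqrt(2 * used.sum())

    def test_scales_linearly_in_patient_deviation(self, small_scene, small_prediction, rng):
        s = small_prediction.total_deviation()
        noise = rng.standard_normal(s.shape) * s
        base = deviation_score(
            small_prediction, small_prediction.mean.like(small_prediction.mean.data + noise),
            small_scene["brain_mask"],
        )
        doubled = deviation_score(
            small_prediction,
            small_prediction.mean.like(small_prediction.mean.data + 2 * noise),
            small_scene["brain_mask"],
        )
        np.testing.assert_allclose(doubled.score, 2 * base.score, rtol=1e-10)

    def test_sd_scale_switch(self, small_scene, small_prediction):
        s_sd = small_prediction.total_deviation("sd")
        patient = small_prediction.mean.like(small_prediction.mean.data + s_sd)
        d = deviation_score(
            small_prediction, patient, small_scene["brain_mask"],
            deviation_scale="sd",
        )
        np.testing.assert_allclose(d.score, 1.0, rtol=1e-10)

    def test_patient_like_map_noise_zero_gives_zero_score(self, small_scene, small_prediction):
        patient = make_patient_like_map(small_prediction, 0.0, seed=3)
        d = deviation_score(small_prediction, patient, small_scene["brain_mask"])
        assert d.score == 0.0


class TestCurveFit:
    @staticmethod
    def _curve(v, a, b, c):
        return a - b * np.exp(-c * v)

    def test_recovers_planted_parameters_exactly(self):
        v = np.linspace(0.5, 20, 60)
        y = self._curve(v, 0.8, 0.5, 0.3)
        fit = fit_reliability_curve(v, y)
        np.testing.assert_allclose(fit.params, (0.8, 0.5, 0.3), atol=1e-4)
        assert fit.adjusted_r2 > 0.9999
        assert fit.converged

    def test_constant_scores_give_flat_curve(self):
        v = np.linspace(1, 10, 20)
        fit = fit_reliability_curve(v, np.full(20, 0.6))
        np.testing.assert_allclose(fit.a, 0.6, atol=1e-3)
        assert abs(fit.b) < 1e-3

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(42)
        v = np.linspace(0.5, 20, 100)
        y = self._curve(v, 0.8, 0.5, 0.3) + rng.normal(0, 0.02, 100)
        fit = fit_reliability_curve(v, y)
        assert abs(fit.a - 0.8) < 0.05
        assert fit.adjusted_r2 < 1.0

    def test_contract_errors(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_reliability_curve([1, 2, 3], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="positive"):
            fit_reliability_curve([0, 1, 2, 3], [0.1, 0.2, 0.3, 0.4])
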