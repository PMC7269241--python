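"""Scoring tests: intensity normalization, reference-model fit against a
per-voxel OLS oracle, t-map hand arithmetic and oracle equivalence, AD
t-sum, PET-score transform and pipeline invariances."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palzsim.palz import (
    ReferenceModel,
    ScoringOptions,
    ad_t_sum,
    fit_reference_model,
    intensity_normalize,
    pet_score,
    score_subject,
    t_map,
)
from palzsim.synthetic import SubjectRecord, sample_subject_volume
from palzsim.volume import VolumeGrid
from conftest import tiny_config


def _toy_grid(shape=(5, 5, 5)):
    affine = np.diag([4.0, 4.0, 4.0, 1.0])
    return VolumeGrid(np.zeros(shape), affine)


def _full_mask(shape=(5, 5, 5)):
    return _toy_grid(shape).with_data(np.ones(shape, dtype=bool))


class TestIntensityNormalize:
    def test_scale_cancellation(self, rng):
        vol = _toy_grid().with_data(rng.uniform(0.5, 2.0, (5, 5, 5)))
        mask = _full_mask()
        n1, _ = intensity_normalize(vol, mask)
        n2, _ = intensity_normalize(vol.with_data(vol.data * 7.3), mask)
        np.testing.assert_allclose(n1.data, n2.data, atol=1e-12)

    def test_constant_volume(self):
        vol = _toy_grid().with_data(np.full((5, 5, 5), 5.0))
        out, mean = intensity_normalize(vol, _full_mask())
        assert mean == 5.0
        np.testing.assert_array_equal(out.data, 1.0)

    def test_two_voxel_hand_arithmetic(self):
        data = np.zeros((5, 5, 5))
        data[0, 0, 0], data[0, 0, 1] = 2.0, 4.0
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = mask[0, 0, 1] = True
        out, mean = intensity_normalize(_toy_grid().with_data(data), _toy_grid().with_data(mask))
        assert mean == 3.0
        assert out.data[0, 0, 0] == pytest.approx(2.0 / 3.0)
        assert out.data[0, 0, 1] == pytest.approx(4.0 / 3.0)

    def test_degenerate_image_rejected(self):
        vol = _toy_grid().with_data(np.zeros((5, 5, 5)))
        with pytest.raises(ValueError):
            intensity_normalize(vol, _full_mask())


class TestFitReferenceModel:
    def test_matches_scalar_ols_oracle(self, rng):
        """Voxel-wise fit equals an independently coded per-voxel
        least-squares (statsmodels OLS) at randomly chosen voxels."""
        import statsmodels.api as sm

        n = 14
        ages = rng.uniform(55, 90, n)
        vols = [_toy_grid().with_data(rng.uniform(0.5, 1.5, (5, 5, 5))) for _ in range(n)]
        model = fit_reference_model(vols, ages, _full_mask())
        y_all = np.stack([v.data for v in vols])
        for _ in range(10):
            i, j, k = rng.integers(0, 5, 3)
            fit = sm.OLS(y_all[:, i, j, k], sm.add_constant(ages)).fit()
            assert model.intercept.data[i, j, k] == pytest.approx(fit.params[0], abs=1e-10)
            assert model.slope.data[i, j, k] == pytest.approx(fit.params[1], abs=1e-10)
            s_oracle = np.sqrt(fit.ssr / (n - 2))
            assert model.residual_sd.data[i, j, k] == pytest.approx(s_oracle, abs=1e-10)

    def test_too_few_subjects_rejected(self, rng):
        vols = [_toy_grid().with_data(rng.uniform(0.5, 1.5, (5, 5, 5))) for _ in range(2)]
        with pytest.raises(ValueError):
            fit_reference_model(vols, [60.0, 70.0], _full_mask())

    def test_equal_ages_rejected(self, rng):
        vols = [_toy_grid().with_data(rng.uniform(0.5, 1.5, (5, 5, 5))) for _ in range(12)]
        with pytest.raises(ValueError):
            fit_reference_model(vols, [70.0] * 12, _full_mask())


def _single_voxel_model(a=1.0, b=0.0, s=0.1, n=12, mean_age=70.0, sxx=1000.0):
    shape = (5, 5, 5)
    grid = _toy_grid(shape)
    mask = np.zeros(shape, dtype=bool)
    mask[2, 2, 2] = True
    return ReferenceModel(
        intercept=grid.with_data(np.full(shape, a)),
        slope=grid.with_data(np.full(shape, b)),
        residual_sd=grid.with_data(np.full(shape, s)),
        n=n,
        mean_age=mean_age,
        age_ssq=sxx,
        mask=grid.with_data(mask),
    )


class TestTMap:
    def test_zero_residual_everywhere(self):
        model = _single_voxel_model()
        vol = _toy_grid().with_data(np.full((5, 5, 5), 1.0))  # u == a + b*age
        t = t_map(vol, 70.0, model)
        np.testing.assert_array_equal(t.data, 0.0)

    def test_hypometabolism_positive_t(self):
        model = _single_voxel_model()
        vol = _toy_grid().with_data(np.full((5, 5, 5), 0.9))
        t = t_map(vol, 70.0, model)
        assert t.data[2, 2, 2] > 0

    def test_hand_arithmetic_single_voxel(self):
        # t = 0.2 / (0.1 * sqrt(1 + 1/12 + 0)) = 1.921538...
        model = _single_voxel_model(a=1.0, b=0.0, s=0.1, n=12, mean_age=70.0, sxx=1000.0)
        vol = _toy_grid().with_data(np.full((5, 5, 5), 0.8))
        t = t_map(vol, 70.0, model)
        assert t.data[2, 2, 2] == pytest.approx(0.2 / (0.1 * np.sqrt(1 + 1 / 12)), abs=1e-10)
        assert t.data[2, 2, 2] == pytest.approx(1.9215387, abs=1e-6)

    def test_zero_sd_voxel_yields_zero_t(self):
        model = _single_voxel_model(s=0.0)
        vol = _toy_grid().with_data(np.full((5, 5, 5), 0.8))
        t = t_map(vol, 70.0, model)
        assert t.data[2, 2, 2] == 0.0

    def test_full_grid_matches_prediction_interval_oracle(self, rng):
        """On a 5^3 grid the t-map equals an independently coded
        regression + prediction-standard-error computation (statsmodels
        ``get_prediction``) at every voxel, to 1e-10."""
        import statsmodels.api as sm

        n = 14
        ages = rng.uniform(55, 90, n)
        vols = [_toy_grid().with_data(rng.uniform(0.5, 1.5, (5, 5, 5))) for _ in range(n)]
        model = fit_reference_model(vols, ages, _full_mask())
        subject = _toy_grid().with_data(rng.uniform(0.5, 1.5, (5, 5, 5)))
        age0 = 72.0
        t = t_map(subject, age0, model)

        y_all = np.stack([v.data for v in vols])
        x = sm.add_constant(ages)
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    fit = sm.OLS(y_all[:, i, j, k], x).fit()
                    pred = fit.get_prediction([1.0, age0])
                    se_obs = float(pred.se_obs[0])  # sqrt(s^2 (1 + 1/n + d^2/Sxx))
                    expected = float(pred.predicted_mean[0])
                    t_oracle = (expected - subject.data[i, j, k]) / se_obs
                    assert t.data[i, j, k] == pytest.approx(t_oracle, abs=1e-10)

    def test_residual_denominator_option(self):
        model = _single_voxel_model()
        vol = _toy_grid().with_data(np.full((5, 5, 5), 0.8))
        t = t_map(vol, 70.0, model, ScoringOptions(t_denominator="residual"))
        assert t.data[2, 2, 2] == pytest.approx(2.0, abs=1e-10)


class TestAdTSum:
    def test_zero_map(self):
        t = _toy_grid().with_data(np.zeros((5, 5, 5)))
        assert ad_t_sum(t, _full_mask()) == 0.0

    def test_unit_map_counts_mask(self):
        t = _toy_grid().with_data(np.ones((5, 5, 5)))
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask.flat[:50] = True
        assert ad_t_sum(t, _toy_grid().with_data(mask)) == 50.0

    def test_matches_masked_sum_oracle(self, rng):
        t = _toy_grid().with_data(rng.normal(size=(5, 5, 5)))
        mask = rng.uniform(size=(5, 5, 5)) > 0.5
        oracle = sum(
            t.data[i, j, k]
            for i in range(5)
            for j in range(5)
            for k in range(5)
            if mask[i, j, k]
        )
        assert ad_t_sum(t, _toy_grid().with_data(mask)) == pytest.approx(oracle, abs=1e-12)

    def test_clip_negative_option(self, rng):
        t = _toy_grid().with_data(rng.normal(size=(5, 5, 5)))
        mask = _full_mask()
        clipped = ad_t_sum(t, mask, clip_negative=True)
        signed = ad_t_sum(t, mask, clip_negative=False)
        assert clipped >= signed
        assert clipped == pytest.approx(float(np.clip(t.data, 0, None).sum()))

    def test_empty_mask_rejected(self):
        t = _toy_grid().with_data(np.zeros((5, 5, 5)))
        with pytest.raises(ValueError):
            ad_t_sum(t, _toy_grid().with_data(np.zeros((5, 5, 5), dtype=bool)))


class TestPetScore:
    def test_prediction_limit_maps_to_one(self):
        assert pet_score(11089.0) == 1.0

    def test_zero_maps_to_zero(self):
        assert pet_score(0.0) == 0.0

    def test_three_times_limit_maps_to_two(self):
        assert pet_score(3 * 11089.0) == pytest.approx(2.0, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            pet_score(-11089.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(min_value=-11000, max_value=1e6),
        b=st.floats(min_value=-11000, max_value=1e6),
    )
    def test_monotone_in_t_sum(self, a, b):
        lo, hi = sorted((a, b))
        assert pet_score(lo) <= pet_score(hi)


@pytest.fixture(scope="module")
def scored_setup(small_template):
    """Noise-bearing reference model plus matched NC/AD subjects."""
    from palzsim.palz import fit_reference_model, intensity_normalize
    from palzsim.preprocessing import gaussian_smooth
    from palzsim.synthetic import build_reference_cohort

    cfg = tiny_config(n_reference=20)
    rng = np.random.default_rng(77)
    vols, ages = build_reference_cohort(small_template, cfg, rng)
    refs = []
    for v in vols:
        sm_v = gaussian_smooth(v, 12.0)
        norm, _ = intensity_normalize(sm_v, small_template.preserved_mask)
        refs.append(norm)
    model = fit_reference_model(refs, ages, small_template.brain_mask)
    nc = sample_subject_volume(
        small_template, SubjectRecord("nc", 72.0, "NC"), cfg, np.random.default_rng(8)
    )
    ad = sample_subject_volume(
        small_template, SubjectRecord("ad", 72.0, "AD"), cfg, np.random.default_rng(8)
    )
    return cfg, model, nc, ad


class TestScoreSubject:
    def test_ad_scores_above_matched_nc(self, small_template, scored_setup):
        _, model, nc, ad = scored_setup
        r_nc = score_subject(nc, 72.0, model, small_template, subject_id="nc")
        r_ad = score_subject(ad, 72.0, model, small_template, subject_id="ad")
        assert r_ad.pet_score > r_nc.pet_score

    def test_global_scale_invariance(self, small_template, scored_setup):
        _, model, nc, _ = scored_setup
        r1 = score_subject(nc, 72.0, model, small_template)
        r2 = score_subject(nc.with_data(nc.data * 3.7), 72.0, model, small_template)
        assert r2.pet_score == pytest.approx(r1.pet_score, abs=1e-9)
        # a power-of-two factor divides out exactly in binary floats
        r4 = score_subject(nc.with_data(nc.data * 4.0), 72.0, model, small_template)
        assert r4.pet_score == r1.pet_score

    def test_monotone_under_ad_mask_reduction(self, small_template, scored_setup):
        """Reducing uptake only inside the AD mask (preserved mask
        untouched) never decreases the AD t-sum."""
        _, model, nc, _ = scored_setup
        reduced = nc.data.copy()
        reduced[small_template.ad_mask.mask_array()] *= 0.9
        r_base = score_subject(nc, 72.0, model, small_template, already_normalized=True)
        r_red = score_subject(
            nc.with_data(reduced), 72.0, model, small_template, already_normalized=True
        )
        assert r_red.ad_t_sum >= r_base.ad_t_sum

    def test_score_result_transform_consistency(self, small_template, scored_setup):
        _, model, nc, _ = scored_setup
        r = score_subject(nc, 72.0, model, small_template)
        assert r.pet_score == pytest.approx(
            np.log2(r.ad_t_sum / 11089.0 + 1.0), abs=1e-12
        )
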