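import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import median_abs_deviation

from devoxel.asl_cbf import (
    AslAcquisition,
    AslSeries,
    CbfMap,
    GmProbabilityMap,
    effective_pld,
    gm_partial_volume_correct,
    quantify_cbf,
    reject_outlier_pairs,
    split_and_difference,
)

SHAPE = (6, 6, 4)


def make_series(diffs, baseline=100.0, shape=SHAPE):
    """Interleaved series whose pair p has uniform control-label diff diffs[p]."""
    n = len(diffs)
    vols = np.empty(shape + (2 * n,))
    for p, d in enumerate(diffs):
        vols[..., 2 * p] = baseline + d / 2.0
        vols[..., 2 * p + 1] = baseline - d / 2.0
    return AslSeries(volumes=vols, voxel_dims=(3.0, 3.0, 7.0))


class TestAslAcquisition:
    def test_defaults_valid(self, acq):
        assert acq.n_slices == 17
        assert acq.tau == 1650.0

    @pytest.mark.parametrize("kw", [
        {"t1_blood": 0.0}, {"tau": -1.0}, {"alpha": 0.0}, {"alpha": 1.5},
        {"alpha_inv": 0.0}, {"lambda_bp": -0.9}, {"n_slices": 0},
        {"t_delay": 0.0}, {"t_slice": -35.0},
    ])
    def test_invalid_parameters(self, kw):
        with pytest.raises(ValueError):
            AslAcquisition(**kw)

    def test_slice_order_must_be_permutation(self):
        with pytest.raises(ValueError):
            AslAcquisition(n_slices=3, slice_order=(1, 1, 2))


class TestSplitAndDifference:
    def test_control_equals_label_gives_zero(self):
        series = make_series([0.0, 0.0])
        si_pd = np.full(SHAPE, 100.0)
        diff = split_and_difference(series, si_pd)
        assert np.allclose(diff.delta_si, 0.0)

    def test_mean_of_two_uniform_pairs(self):
        series = make_series([1.0, 3.0])
        diff = split_and_difference(series, np.full(SHAPE, 100.0))
        assert np.allclose(diff.delta_si, 2.0)
        assert diff.kept_pairs == (0, 1)
        assert diff.rejected_pairs == ()

    def test_odd_repetition_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            AslSeries(volumes=np.zeros(SHAPE + (5,)))

    def test_all_zero_series_warns_not_errors(self):
        series = AslSeries(volumes=np.zeros(SHAPE + (4,)))
        with pytest.warns(RuntimeWarning, match="zero"):
            diff = split_and_difference(series, np.full(SHAPE, 100.0))
        assert np.allclose(diff.delta_si, 0.0)

    def test_label_first_ordering(self):
        series = make_series([2.0])
        flipped = AslSeries(volumes=series.volumes[..., ::-1].copy(),
                            control_first=False)
        diff = split_and_difference(flipped, np.full(SHAPE, 100.0))
        assert np.allclose(diff.delta_si, 2.0)

    def test_sampling_distribution_of_mean_difference(self):
        # oracle: mean of 50 pair diffs ~ N(1, 0.1^2/50); 5*SE bound per voxel
        rng = np.random.default_rng(11)
        n_pairs, base = 50, 100.0
        vols = np.empty(SHAPE + (2 * n_pairs,))
        for p in range(n_pairs):
            d = rng.normal(1.0, 0.1, SHAPE)
            vols[..., 2 * p] = base + d / 2
            vols[..., 2 * p + 1] = base - d / 2
        diff = split_and_difference(AslSeries(volumes=vols), np.full(SHAPE, base))
        se = 0.1 / math.sqrt(n_pairs)
        assert np.all(np.abs(diff.delta_si - 1.0) < 5 * se)


class TestRejectOutlierPairs:
    def test_single_corrupted_pair_detected(self):
        # clean spread is bounded (uniform) so no clean pair can reach 3*MAD
        rng = np.random.default_rng(3)
        diffs = list(rng.uniform(0.9, 1.1, 49)) + [50.0]
        series = make_series(diffs)
        si_pd = np.full(SHAPE, 100.0)
        diff = reject_outlier_pairs(series, si_pd, k=3.0)
        assert diff.rejected_pairs == (49,)
        # direct MAD oracle on the per-pair scores
        scores = np.abs(np.array(diffs))
        dev = np.abs(scores - np.median(scores))
        thresh = 3.0 * median_abs_deviation(scores, scale="normal")
        assert set(np.flatnonzero(dev > thresh)) == {49}

    def test_identical_pairs_zero_mad_no_rejections(self):
        diff = reject_outlier_pairs(make_series([2.0] * 6),
                                    np.full(SHAPE, 100.0), k=3.0)
        assert diff.rejected_pairs == ()

    def test_infinite_k_rejects_nothing(self):
        diff = reject_outlier_pairs(make_series([1.0, 5.0, 2.0, 9.0]),
                                    np.full(SHAPE, 100.0), k=np.inf)
        assert diff.rejected_pairs == ()

    def test_requires_four_pairs(self):
        with pytest.raises(ValueError, match=">= 4"):
            reject_outlier_pairs(make_series([1.0, 2.0, 3.0]),
                                 np.full(SHAPE, 100.0))

    def test_all_rejected_is_hard_error(self):
        # scores {0,0,10,10}: every deviation equals 5 > 0.5*MAD -> all out
        with pytest.raises(ValueError, match="manual review"):
            reject_outlier_pairs(make_series([0.0, 0.0, 10.0, 10.0]),
                                 np.full(SHAPE, 100.0), k=0.5)

    def test_no_rejection_leaves_mean_unchanged(self):
        series = make_series([1.0, 1.1, 0.9, 1.05])
        si_pd = np.full(SHAPE, 100.0)
        plain = split_and_difference(series, si_pd)
        qc = reject_outlier_pairs(series, si_pd, k=10.0)
        assert qc.rejected_pairs == ()
        np.testing.assert_array_equal(plain.delta_si, qc.delta_si)

    def test_symmetric_outliers_keep_mean_near_clean(self):
        clean = [0.9, 0.95, 1.0, 1.05, 1.1, 0.92, 0.98, 1.02, 1.08, 1.0]
        series = make_series(clean + [30.0, -28.0])
        diff = reject_outlier_pairs(series, np.full(SHAPE, 100.0), k=3.0)
        assert set(diff.rejected_pairs) == {10, 11}
        assert np.allclose(diff.delta_si, np.mean(clean))


class TestEffectivePld:
    def test_first_slice_is_t_delay(self, acq):
        assert effective_pld(1, acq) == 1525.0

    def test_last_slice_of_17(self, acq):
        assert effective_pld(17, acq) == 2085.0

    def test_second_slice(self, acq):
        assert effective_pld(2, acq) == 1560.0

    @pytest.mark.parametrize("z", [0, 18, -1])
    def test_out_of_range(self, acq, z):
        with pytest.raises(IndexError):
            effective_pld(z, acq)

    def test_slice_order_remaps_timing(self):
        acq = AslAcquisition(n_slices=3, slice_order=(3, 2, 1))
        assert effective_pld(1, acq) == 1525.0 + 2 * 35.0
        assert effective_pld(3, acq) == 1525.0

    @given(st.integers(min_value=1, max_value=16))
    def test_strictly_increasing_with_step_t_slice(self, z):
        acq = AslAcquisition()
        assert effective_pld(z + 1, acq) - effective_pld(z, acq) == acq.t_slice


class TestQuantifyCbf:
    def test_zero_difference_gives_zero_cbf(self, acq):
        shape = (4, 4, 17)
        diff = split_and_difference(_series_from_delta(0.0, 100.0, shape),
                                    np.full(shape, 100.0))
        cbf = quantify_cbf(diff, acq)
        assert np.allclose(cbf.values[cbf.valid_mask], 0.0)

    def test_scalar_worked_value_first_slice(self, acq):
        # frozen from an independent evaluation of the model:
        # 6000*0.9*1*exp(1.525/1.65) / (2*0.85*0.83*1.65*100*(1-exp(-1)))
        shape = (2, 2, 17)
        diff = split_and_difference(_series_from_delta(1.0, 100.0, shape),
                                    np.full(shape, 100.0))
        cbf = quantify_cbf(diff, acq)
        assert cbf.values[0, 0, 0] == pytest.approx(92.46476521999163, rel=1e-12)
        assert cbf.values[0, 0, 0] == pytest.approx(92.5, abs=0.05)

    def test_linear_in_delta_inverse_in_pd(self, acq):
        shape = (3, 3, 17)
        rng = np.random.default_rng(0)
        delta = rng.uniform(0.5, 2.0, shape)
        pd_img = np.full(shape, 200.0)
        base = quantify_cbf(
            _diff_from_arrays(delta, pd_img), acq).values
        doubled = quantify_cbf(
            _diff_from_arrays(2 * delta, pd_img), acq).values
        halfpd = quantify_cbf(
            _diff_from_arrays(delta, pd_img / 2), acq).values
        np.testing.assert_allclose(doubled, 2 * base, rtol=1e-12)
        np.testing.assert_allclose(halfpd, 2 * base, rtol=1e-12)

    def test_nonpositive_pd_excluded(self, acq):
        shape = (2, 2, 17)
        pd_img = np.full(shape, 100.0)
        pd_img[0, 0, :] = 0.0
        cbf = quantify_cbf(_diff_from_arrays(np.ones(shape), pd_img), acq)
        assert not cbf.valid_mask[0, 0, 0]
        assert cbf.valid_mask[1, 1, 0]

    def test_negative_cbf_retained(self, acq):
        shape = (2, 2, 17)
        cbf = quantify_cbf(
            _diff_from_arrays(np.full(shape, -1.0), np.full(shape, 100.0)), acq)
        assert np.all(cbf.values[cbf.valid_mask] < 0)
        assert cbf.n_negative == cbf.valid_mask.sum()

    def test_slice_count_mismatch(self, acq):
        shape = (2, 2, 5)
        with pytest.raises(ValueError, match="slices"):
            quantify_cbf(
                _diff_from_arrays(np.ones(shape), np.full(shape, 100.0)), acq)

    def test_deeper_slices_get_larger_decay_compensation(self, acq):
        shape = (2, 2, 17)
        cbf = quantify_cbf(
            _diff_from_arrays(np.ones(shape), np.full(shape, 100.0)), acq)
        per_slice = cbf.values[0, 0, :]
        assert np.all(np.diff(per_slice) > 0)


class TestGmPartialVolumeCorrect:
    def make_cbf(self, value, shape=(3, 3, 2)):
        vals = np.full(shape, float(value))
        return CbfMap(values=vals, valid_mask=np.ones(shape, bool))

    def test_full_gm_is_identity(self):
        cbf = self.make_cbf(30.0)
        gm = GmProbabilityMap(prob=np.ones((3, 3, 2)))
        out = gm_partial_volume_correct(cbf, gm)
        np.testing.assert_array_equal(out.values, cbf.values)
        assert out.gm_corrected and out.gm_threshold_used == 0.3

    def test_division_by_gm_fraction(self):
        out = gm_partial_volume_correct(
            self.make_cbf(15.0), GmProbabilityMap(prob=np.full((3, 3, 2), 0.5)),
            min_gm=0.3)
        assert np.allclose(out.values[out.valid_mask], 30.0)

    def test_below_threshold_empties_mask_with_warning(self):
        with pytest.warns(RuntimeWarning, match="every voxel"):
            out = gm_partial_volume_correct(
                self.make_cbf(15.0),
                GmProbabilityMap(prob=np.full((3, 3, 2), 0.1)), min_gm=0.3)
        assert not out.valid_mask.any()

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            gm_partial_volume_correct(
                self.make_cbf(15.0), GmProbabilityMap(prob=np.ones((4, 4, 2))))

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            GmProbabilityMap(prob=np.full((2, 2, 2), 1.5))


@settings(max_examples=25, deadline=None)
@given(scale=st.floats(min_value=0.1, max_value=10.0,
                       allow_nan=False, allow_infinity=False))
def test_quantification_linearity_property(scale):
    acq = AslAcquisition(n_slices=4)
    shape = (3, 3, 4)
    rng = np.random.default_rng(42)
    delta = rng.uniform(0.5, 2.0, shape)
    base = quantify_cbf(_diff_from_arrays(delta, np.full(shape, 100.0),
                                          n_slices=4), acq).values
    scaled = quantify_cbf(_diff_from_arrays(scale * delta, np.full(shape, 100.0),
                                            n_slices=4), acq).values
    np.testing.assert_allclose(scaled, scale * base, rtol=1e-9)


def _series_from_delta(delta, baseline, shape):
    vols = np.empty(shape + (2,))
    vols[..., 0] = baseline + np.asarray(delta) / 2.0
    vols[..., 1] = baseline - np.asarray(delta) / 2.0
    return AslSeries(volumes=vols)


def _diff_from_arrays(delta, si_pd, n_slices=17):
    from devoxel.asl_cbf import PerfusionDifference
    delta = np.asarray(delta, dtype=float)
    si_pd = np.asarray(si_pd, dtype=float)
    return PerfusionDifference(
        delta_si=delta, si_pd=si_pd,
        brain_mask=np.ones(delta.shape, bool), kept_pairs=(0,),
    )
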