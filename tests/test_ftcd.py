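"""Doppler preprocessing chain and the GAM interaction LI."""

import numpy as np
import pandas as pd
import pytest

from latmirror import (
    CbfvRecording,
    CbfvSpec,
    PoiWindow,
    average_epochs,
    baseline_correct,
    downsample,
    epochize,
    gam_li,
    generate_cbfv,
    generate_epoch_set,
    heart_cycle_integrate,
    normalise,
    participant_exclusion,
    preprocess,
    reject_extreme_samples,
    reject_trials,
    scale_ftcd_li,
)
from latmirror.errors import (
    NoMarkersError,
    NonIntegerFactorError,
    NonPositiveMeanError,
    PipelineOrderError,
    RankDeficientDesignError,
)
from latmirror.ftcd import EpochSet, subtraction_li


def _rec(left, right, fs=100.0, markers=()):
    return CbfvRecording(left=np.asarray(left, float),
                         right=np.asarray(right, float),
                         fs=fs, markers=np.asarray(markers, int))


class TestDownsample:
    def test_counts_and_rate(self):
        rec = downsample(_rec(np.arange(4000.0), np.arange(4000.0)))
        assert rec.n_samples == 1000 and rec.fs == 25.0

    def test_marker_rescaled_and_floored(self):
        rec = downsample(_rec(np.zeros(1000), np.zeros(1000), markers=[400, 411]))
        np.testing.assert_array_equal(rec.markers, [100, 102])

    def test_constant_signal_unchanged(self):
        rec = downsample(_rec(np.full(400, 7.0), np.full(400, 3.0)))
        assert (rec.left == 7.0).all() and (rec.right == 3.0).all()

    def test_non_integer_factor(self):
        with pytest.raises(NonIntegerFactorError):
            downsample(_rec(np.zeros(100), np.zeros(100), fs=60.0), 25.0)


class TestRejectExtremeSamples:
    def test_single_spike_flagged(self):
        rng = np.random.default_rng(0)
        left = rng.normal(100, 1, 100_000)
        left[12345] = 1e6
        rec = reject_extreme_samples(_rec(left, rng.normal(100, 1, 100_000)))
        assert rec.artefact[12345]

    def test_gaussian_flag_rate_matches_quantiles(self):
        """~0.02% of samples flagged per channel on clean Gaussian noise
        (binomial expectation at the 0.0001/0.9999 quantiles)."""
        rng = np.random.default_rng(1)
        n = 200_000
        rec = reject_extreme_samples(_rec(rng.normal(size=n), rng.normal(size=n)))
        rate = rec.artefact.mean()
        assert 0.0001 <= rate <= 0.0008  # two channels, ~2e-4 each, union

    def test_constant_channel_no_flags(self):
        rec = reject_extreme_samples(_rec(np.full(1000, 5.0), np.full(1000, 5.0)))
        assert not rec.artefact.any()


class TestNormalise:
    def test_means_become_100(self):
        rng = np.random.default_rng(2)
        rec = normalise(_rec(rng.uniform(50, 70, 5000), rng.uniform(40, 60, 5000)))
        assert rec.left.mean() == pytest.approx(100.0)
        assert rec.right.mean() == pytest.approx(100.0)
        assert rec.channel_means[0] == pytest.approx(60.0, rel=0.02)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        left = rng.uniform(50, 70, 1000)
        right = rng.uniform(40, 60, 1000)
        a = normalise(_rec(left, right))
        b = normalise(_rec(3.7 * left, right))
        np.testing.assert_allclose(a.left, b.left)

    def test_toy_channel_arithmetic(self):
        left = np.arange(1.0, 11.0)  # mean 5.5
        rec = normalise(_rec(left, np.ones(10)))
        np.testing.assert_allclose(rec.left, 100.0 * left / 5.5)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(NonPositiveMeanError):
            normalise(_rec(np.zeros(10) - 1.0, np.ones(10)))


class TestHeartCycleIntegrate:
    @staticmethod
    def _pulse(fs=100.0, bpm=70.0, seconds=30.0, base_l=100.0, base_r=98.0,
               depth=10.0):
        t = np.arange(int(seconds * fs)) / fs
        pulse = depth * np.cos(2 * np.pi * bpm / 60.0 * t)
        return _rec(base_l + pulse, base_r + pulse, fs=fs)

    def test_per_cycle_means_recovered(self):
        rec = heart_cycle_integrate(self._pulse())
        # interior cycles span whole pulse periods -> mean = channel base
        # tolerance covers the +-1-sample discretisation of cycle bounds
        interior = slice(500, 2500)
        np.testing.assert_allclose(rec.left[interior], 100.0, atol=0.2)
        np.testing.assert_allclose(rec.right[interior], 98.0, atol=0.2)

    def test_output_piecewise_constant(self):
        rec = heart_cycle_integrate(self._pulse())
        # far fewer distinct values than samples: one value per cycle + edges
        assert len(np.unique(rec.left)) < 50

    def test_constant_input_identity(self):
        rec = heart_cycle_integrate(_rec(np.full(1000, 7.0), np.full(1000, 3.0)))
        assert (rec.left == 7.0).all() and (rec.right == 3.0).all()

    def test_amplitude_scaling_keeps_boundaries(self):
        """Doubling pulse amplitude must not move the detected peaks."""
        from scipy.signal import find_peaks

        for depth in (5.0, 10.0):
            rec = self._pulse(depth=depth)
            combined = rec.left + rec.right
            iqr = np.subtract(*np.percentile(combined, [75, 25]))
            peaks, _ = find_peaks(combined, distance=int(100 * 60 / 150),
                                  prominence=0.5 * iqr)
            if depth == 5.0:
                ref = peaks
        np.testing.assert_array_equal(ref, peaks)


class TestEpochize:
    def test_23_trials_full_shape(self):
        fs = 25.0
        markers = (np.arange(23) * 50 + 15) * fs
        n = int((15 + 23 * 50 + 35) * fs)
        rec = _rec(np.zeros(n), np.zeros(n), fs=fs, markers=markers.astype(int))
        epochs = epochize(rec)
        assert epochs.epochs.shape == (23, int(42 * fs), 2)
        assert epochs.kept.all()

    def test_early_marker_flagged_truncated(self):
        rec = _rec(np.zeros(3000), np.zeros(3000), fs=25.0, markers=[125])  # 5 s in
        epochs = epochize(rec)
        assert not epochs.kept[0]
        assert epochs.reasons[0] == "truncated"

    def test_content_matches_direct_slice(self):
        rng = np.random.default_rng(4)
        left = rng.normal(size=3000)
        right = rng.normal(size=3000)
        rec = _rec(left, right, fs=25.0, markers=[1000])
        epochs = epochize(rec)
        a, b = 1000 - 12 * 25, 1000 + 30 * 25
        np.testing.assert_array_equal(epochs.epochs[0, :, 0], left[a:b])
        np.testing.assert_array_equal(epochs.epochs[0, :, 1], right[a:b])

    def test_no_markers(self):
        with pytest.raises(NoMarkersError):
            epochize(_rec(np.zeros(100), np.zeros(100)))


def _flat_epochs(n_trials=3, value=100.0, fs=25.0):
    n_t = int(42 * fs)
    time = np.arange(n_t) / fs - 12.0
    return EpochSet(
        epochs=np.full((n_trials, n_t, 2), value),
        time=time, fs=fs,
        kept=np.ones(n_trials, bool),
        reasons=[None] * n_trials,
    )


class TestBaselineCorrect:
    def test_flat_epoch_becomes_zero(self):
        out = baseline_correct(_flat_epochs())
        np.testing.assert_array_equal(out.epochs, 0.0)

    def test_poi_reads_shift_after_correction(self):
        ep = _flat_epochs(1, 102.0)
        ep.epochs[0, ep.time >= 5.0, 0] = 105.0
        out = baseline_correct(ep)
        assert out.epochs[0, out.time >= 5.0, 0] == pytest.approx(3.0)

    def test_baseline_window_mean_zero_postcondition(self):
        rng = np.random.default_rng(5)
        ep = _flat_epochs(6)
        ep.epochs += rng.normal(0, 5, ep.epochs.shape)
        out = baseline_correct(ep)
        sel = (out.time >= -10.0) & (out.time < 0.0)
        base_means = out.epochs[:, sel, :].mean(axis=1)
        np.testing.assert_allclose(base_means, 0.0, atol=1e-10)

    def test_double_correction_refused(self):
        with pytest.raises(PipelineOrderError):
            baseline_correct(baseline_correct(_flat_epochs()))


class TestRejectTrials:
    def test_low_dip_rejected(self):
        ep = _flat_epochs(2)
        ep.raw[0, 50, 1] = 55.0
        out = reject_trials(ep)
        assert not out.kept[0] and out.reasons[0] == "low-signal"
        assert out.kept[1]

    def test_all_within_bounds_kept(self):
        rng = np.random.default_rng(6)
        ep = _flat_epochs(5)
        ep.raw[:] = rng.uniform(80, 120, ep.raw.shape)
        assert reject_trials(ep).kept.all()

    def test_crafted_four_of_fifteen_rejected(self):
        ep = _flat_epochs(15)
        for i, bad in enumerate([55.0, 150.0, 30.0, 145.0]):
            ep.raw[i, 10 + i, 0] = bad
        out = reject_trials(ep)
        assert out.kept.sum() == 11


class TestParticipantExclusion:
    @pytest.mark.parametrize("n_rej, expected", [(0, False), (3, False), (4, True)])
    def test_fifteen_trials(self, n_rej, expected):
        ep = _flat_epochs(15)
        ep.kept[:n_rej] = False
        excluded, n, allowed = participant_exclusion(ep)
        assert allowed == 3
        assert excluded is expected

    def test_twenty_three_trials_allows_five(self):
        ep = _flat_epochs(23)
        ep.kept[:5] = False
        assert participant_exclusion(ep)[0] is False
        ep.kept[5] = False
        assert participant_exclusion(ep)[0] is True


class TestAverageEpochs:
    def test_identical_trials(self):
        ep = baseline_correct(_flat_epochs(2, 104.0))
        avg = average_epochs(ep)
        np.testing.assert_array_equal(avg["left"], ep.epochs[0, :, 0])

    def test_symmetric_sides_zero_difference(self):
        rng = np.random.default_rng(7)
        ep = _flat_epochs(3)
        ep.epochs[:, :, 0] = rng.normal(size=ep.epochs.shape[:2])
        ep.epochs[:, :, 1] = ep.epochs[:, :, 0]
        np.testing.assert_array_equal(average_epochs(ep)["diff"], 0.0)

    def test_hand_averaged_three_trials(self):
        ep = _flat_epochs(3)
        ep.epochs[0] = 1.0
        ep.epochs[1] = 2.0
        ep.epochs[2] = 6.0
        np.testing.assert_allclose(average_epochs(ep)["left"], 3.0)

    def test_rejected_trials_excluded(self):
        ep = _flat_epochs(3)
        ep.epochs[2] = 1000.0
        ep.kept[2] = False
        np.testing.assert_allclose(average_epochs(ep)["left"], 100.0)


POI = PoiWindow(7.0, 17.0)


class TestGamLi:
    def test_recovers_injected_interaction(self):
        ep = generate_epoch_set(n_trials=10, delta_pct=6.0, noise_sd_pct=1.0, seed=1)
        fit = gam_li(ep, POI)
        assert fit.li > 0
        assert fit.ci_low <= 6.0 + 3 * fit.se and fit.ci_high >= 6.0 - 3 * fit.se
        assert fit.category == "left"

    def test_channel_swap_negates_exactly(self):
        ep = generate_epoch_set(n_trials=6, delta_pct=4.0, seed=2)
        swapped = EpochSet(
            epochs=ep.epochs[:, :, ::-1].copy(), time=ep.time, fs=ep.fs,
            kept=ep.kept.copy(), reasons=list(ep.reasons),
            baseline_corrected=True,
        )
        a = gam_li(ep, POI)
        b = gam_li(swapped, POI)
        assert b.li == pytest.approx(-a.li, abs=1e-9)
        assert b.se == pytest.approx(a.se, rel=1e-9)

    def test_flat_limit_reduces_to_subtraction(self):
        """Noise-free epochs constant inside/outside the POI: the interaction
        equals mean(L-R in POI) - mean(L-R outside POI)."""
        ep = _flat_epochs(4, 0.0)
        in_poi = (ep.time >= POI.start) & (ep.time < POI.end)
        ep.epochs[:, in_poi, 0] = 5.0   # left in POI
        ep.epochs[:, in_poi, 1] = 2.0   # right in POI
        ep.epochs[:, ~in_poi, 0] = 1.0
        ep.epochs[:, ~in_poi, 1] = 1.0
        fit = gam_li(ep, POI)
        assert fit.li == pytest.approx(subtraction_li(ep, POI), abs=1e-6)
        assert fit.li == pytest.approx(3.0, abs=1e-6)

    def test_poi_spanning_epoch_rank_deficient(self):
        ep = generate_epoch_set(n_trials=4, seed=3)
        whole = PoiWindow(ep.time[0], ep.time[-1] + 1.0 / ep.fs)
        with pytest.raises(RankDeficientDesignError):
            gam_li(ep, whole)

    def test_baseline_correction_leaves_estimate_close(self):
        """Per-trial offsets are absorbed by the epoch terms, so correcting
        the baseline barely moves the interaction estimate."""
        ep = generate_epoch_set(n_trials=8, delta_pct=5.0, seed=4,
                                trial_scatter_pct=2.0)
        uncorrected = gam_li(ep, POI)
        corrected = gam_li(baseline_correct(
            EpochSet(epochs=ep.epochs.copy(), time=ep.time, fs=ep.fs,
                     kept=ep.kept.copy(), reasons=list(ep.reasons))
        ), POI)
        assert corrected.li == pytest.approx(uncorrected.li, abs=3 * uncorrected.se)


class TestScaleFtcdLi:
    def test_divide_by_six(self):
        ep = generate_epoch_set(n_trials=6, delta_pct=6.0, noise_sd_pct=0.5, seed=5)
        fit = gam_li(ep, POI)
        scaled = scale_ftcd_li(fit, 6.0)
        assert scaled.li == pytest.approx(fit.li / 6.0)
        assert scaled.category == fit.category

    def test_category_invariance_random_fits(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            li = rng.normal(0, 3)
            se = rng.uniform(0.1, 2)
            from latmirror.ftcd import GamLiFit
            from latmirror import categorise

            fit = GamLiFit(li=li, se=se, ci_low=li - 1.96 * se,
                           ci_high=li + 1.96 * se, n_trials_used=10, terms={},
                           category=categorise(li - 1.96 * se, li + 1.96 * se))
            assert scale_ftcd_li(fit, 6.0).category == fit.category

    def test_nonpositive_divisor(self):
        from latmirror.ftcd import GamLiFit

        fit = GamLiFit(1, 1, -0.96, 2.96, 2, {}, "bilateral")
        with pytest.raises(ValueError):
            scale_ftcd_li(fit, -2.0)


class TestPipelineOrder:
    def test_downsample_after_normalise_refused(self):
        rec = normalise(_rec(np.random.default_rng(9).uniform(50, 70, 1000),
                             np.random.default_rng(10).uniform(50, 70, 1000)))
        with pytest.raises(PipelineOrderError):
            downsample(rec, 50.0)

    def test_stage_cannot_repeat(self):
        rec = _rec(np.arange(100.0) + 50, np.arange(100.0) + 50)
        rec = reject_extreme_samples(rec)
        with pytest.raises(PipelineOrderError):
            reject_extreme_samples(rec)

    def test_full_chain_runs_in_order(self):
        rec, _ = generate_cbfv(CbfvSpec(n_trials=4, seed=11))
        epochs = preprocess(rec)
        assert epochs.n_trials == 4
        assert epochs.baseline_corrected


class TestFullPipelineRecovery:
    def test_delta_sign_recovered_through_pipeline(self):
        rec, truth = generate_cbfv(CbfvSpec(n_trials=10, delta_pct=6.0, seed=12))
        epochs = preprocess(rec)
        fit = gam_li(epochs, POI)
        assert fit.li > 0
        assert fit.category == "left"

    def test_zero_delta_noise_free_symmetric_difference(self):
        """Both channels share the same shape when delta = 0, so after
        normalisation the averaged L-R trace vanishes identically.  The
        quantile-flag stage is skipped: on a noise-free periodic signal it
        would tag the crest of every (identical) trial."""
        rec, _ = generate_cbfv(CbfvSpec(n_trials=4, delta_pct=0.0,
                                        noise_sd_pct=0.0, seed=13))
        rec = heart_cycle_integrate(normalise(downsample(rec)))
        epochs = baseline_correct(epochize(rec))
        avg = average_epochs(epochs)
        np.testing.assert_allclose(avg["diff"], 0.0, atol=1e-8)
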