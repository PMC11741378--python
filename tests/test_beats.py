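"""Beat detection, feature extraction and transition-delta arithmetic."""

import numpy as np
import pytest

from avdopt import (
    SubjectParams,
    aggregate_response,
    beat_features,
    detect_beats,
    generate_subject,
    transition_deltas,
)
from avdopt.beats import BeatDetectionWarning, BeatFeature

FS = 100.0


def _synthetic_features(values, period=1.0, avd=None):
    """Constant-spacing BeatFeature list with given per-beat values."""
    return [
        BeatFeature(beat_time_s=i * period, end_time_s=(i + 1) * period,
                    channel="abp", peak_mmHg=v, mean_mmHg=v, avd_ms=avd)
        for i, v in enumerate(values)
    ]


class TestDetect:
    def test_clean_synthetic_count_matches_pacing_rate(self):
        rec = generate_subject(SubjectParams(
            seed=1, replicates_per_avd=1, sample_rate_hz=FS,
            beat_noise_sd_mmHg=0.0, resp_amp_abp_mmHg=0.0,
            resp_amp_cvp_mmHg=0.0, resp_irregularity=0.0))
        onsets = detect_beats(rec.abp[:int(60 * FS)], FS, 90.0)
        assert abs(len(onsets) - 90) <= 1

    def test_flat_line_yields_no_beats_and_warns(self):
        with pytest.warns(BeatDetectionWarning, match="flat-line"):
            onsets = detect_beats(np.full(1000, 8.0), FS, 90.0)
        assert onsets.size == 0

    def test_rate_deviation_warns(self):
        t = np.arange(0, 60, 1 / FS)
        x = np.maximum(np.sin(2 * np.pi * 0.9 * t), 0.0)  # 54 bpm vs 90 paced
        with pytest.warns(BeatDetectionWarning, match="deviates"):
            detect_beats(x, FS, 90.0)

    @pytest.mark.parametrize("channel", ["abp", "cvp"])
    def test_beats_match_ground_truth_at_default_noise(self, noisy_record,
                                                       channel):
        sig = getattr(noisy_record, channel)
        onsets = detect_beats(sig, FS, 90.0)
        feats = beat_features(sig, onsets, channel, FS)
        truth_t = getattr(noisy_record.truth, f"beat_peak_times_{channel}_s")
        # each extracted beat peak time should sit within 100 ms of a true one
        peak_times = []
        for f in feats:
            i0 = int(np.ceil(f.beat_time_s * FS))
            i1 = int(np.floor(f.end_time_s * FS))
            peak_times.append((i0 + np.argmax(sig[i0:i1])) / FS)
        matched = sum(np.abs(truth_t - pt).min() <= 0.1 for pt in peak_times)
        assert matched / len(peak_times) >= 0.99


class TestFeatures:
    def test_cvp_two_peak_beat_reports_taller_peak(self):
        t = np.arange(0, 1.0, 1 / FS)
        beat = (8.0 * np.exp(-0.5 * ((t - 0.2) / 0.05) ** 2)
                + 6.0 * np.exp(-0.5 * ((t - 0.6) / 0.05) ** 2))
        feats = beat_features(beat, np.array([0.0]), "cvp", FS)
        assert len(feats) == 1
        assert abs(feats[0].peak_mmHg - 8.0) < 0.05

    def test_constant_signal_peak_equals_mean(self):
        feats = beat_features(np.full(100, 5.0), np.array([0.0]), "cvp", FS)
        assert feats[0].peak_mmHg == feats[0].mean_mmHg == 5.0

    def test_peak_never_below_mean(self, noisy_record):
        onsets = detect_beats(noisy_record.cvp, FS, 90.0)
        for f in beat_features(noisy_record.cvp, onsets, "cvp", FS):
            assert f.peak_mmHg >= f.mean_mmHg

    def test_noiseless_systolic_abp_equals_generator_truth(self,
                                                           noiseless_record):
        rec = noiseless_record
        fs = rec.sample_rate_hz
        onsets = detect_beats(rec.abp, fs, 90.0)
        feats = beat_features(rec.abp, onsets, "abp", fs)
        truth = dict(zip(np.round(rec.truth.beat_peak_times_abp_s, 3),
                         rec.truth.beat_peaks_abp_mmhg))
        checked = 0
        for f in feats:
            i0 = int(np.ceil(f.beat_time_s * fs))
            i1 = int(np.floor(f.end_time_s * fs))
            t_pk = np.round((i0 + np.argmax(rec.abp[i0:i1])) / fs, 3)
            if t_pk in truth:
                assert abs(f.peak_mmHg - truth[t_pk]) < 1e-6
                checked += 1
        assert checked >= 0.95 * len(feats)


class TestTransitions:
    def test_step_change_recovered_in_both_directions(self):
        # 13 beats at 0, step +3 at a ref->test event, 13 beats at 3, back
        values = [0.0] * 13 + [3.0] * 13 + [0.0] * 13
        feats = _synthetic_features(values)
        events = [(12.5, 160.0), (25.5, 120.0)]
        deltas = transition_deltas(feats, events, 6)
        assert len(deltas) == 2
        d_ref_test = next(d for d in deltas if d.direction == "ref_to_test")
        d_test_ref = next(d for d in deltas if d.direction == "test_to_ref")
        assert d_ref_test.delta_mmHg == pytest.approx(3.0)
        assert d_test_ref.delta_mmHg == pytest.approx(3.0)  # sign convention
        assert d_test_ref.avd_tested_ms == 160.0

    def test_straddling_beat_excluded(self):
        # event mid-beat: the straddling beat's value must not contaminate
        values = [0.0] * 13 + [100.0] + [3.0] * 13
        feats = _synthetic_features(values)
        events = [(13.5, 160.0)]  # beat 13 (value 100) straddles the event
        deltas = transition_deltas(feats, events, 6)
        assert deltas[0].pre_mean_mmHg == pytest.approx(0.0)
        assert deltas[0].post_mean_mmHg == pytest.approx(3.0)

    def test_too_close_events_drop_transition(self):
        values = [0.0] * 30
        feats = _synthetic_features(values)
        events = [(10.5, 160.0), (13.5, 120.0)]  # only 2 complete beats between
        with pytest.warns(BeatDetectionWarning, match="dropped"):
            deltas = transition_deltas(feats, events, 6)
        assert len(deltas) < 2

    def test_sign_convention_symmetry(self):
        """Reversing event roles while negating the effect leaves the
        aggregated means unchanged."""
        rng = np.random.default_rng(4)
        effect = 2.5
        base = list(rng.normal(0, 0.3, 13))
        up = list(rng.normal(effect, 0.3, 13))
        values = base + up + [v - 0 for v in base]
        feats = _synthetic_features(values)
        events = [(12.5, 200.0), (25.5, 120.0)]
        resp_fwd = aggregate_response(
            transition_deltas(feats, events, 6), "abp")
        # mirrored experiment: negate the effect and swap who is "tested"
        values_neg = [-v for v in values]
        feats_neg = _synthetic_features(values_neg)
        deltas_neg = transition_deltas(feats_neg, events, 6)
        resp_neg = aggregate_response(deltas_neg, "abp")
        np.testing.assert_allclose(resp_fwd.means, -resp_neg.means, atol=1e-12)

    def test_noiseless_aggregate_matches_quadratic_exactly(self,
                                                           noiseless_record,
                                                           noiseless_params):
        rec = noiseless_record
        fs = rec.sample_rate_hz
        onsets = detect_beats(rec.abp, fs, 90.0)
        feats = beat_features(rec.abp, onsets, "abp", fs)
        deltas = transition_deltas(feats, rec.events, 6)
        resp = aggregate_response(deltas, "abp")
        a_abp, _ = noiseless_params.resolved_curvatures()
        opt = noiseless_params.true_optimum_ms
        ref = noiseless_params.ref_avd_ms
        for avd, mean, sem, n in resp.per_avd:
            expected = a_abp * ((avd - opt) ** 2 - (ref - opt) ** 2)
            assert abs(mean - expected) < 1e-9
            assert sem < 1e-9

    def test_reference_vs_reference_delta_consistent_with_zero(self,
                                                               noisy_record):
        fs = noisy_record.sample_rate_hz
        onsets = detect_beats(noisy_record.abp, fs, 90.0)
        feats = beat_features(noisy_record.abp, onsets, "abp", fs)
        deltas = transition_deltas(feats, noisy_record.events, 6)
        resp = aggregate_response(deltas, "abp")
        row = {r[0]: r for r in resp.per_avd}[120.0]
        assert abs(row[1]) < 3 * row[2]


class TestAggregate:
    def test_identical_replicates_have_zero_sem(self):
        feats = _synthetic_features([0.0] * 13 + [2.0] * 13 + [0.0] * 13
                                    + [2.0] * 13 + [0.0] * 13)
        events = [(12.5, 160.0), (25.5, 120.0), (38.5, 160.0), (51.5, 120.0)]
        resp = aggregate_response(transition_deltas(feats, events, 6), "abp")
        assert resp.per_avd == [(160.0, 2.0, 0.0, 4)]

    def test_two_replicates_mean_and_sem(self):
        from avdopt.beats import TransitionDelta

        deltas = [
            TransitionDelta(160.0, i, "ref_to_test", 0.0, v, v, 6, 6)
            for i, v in enumerate([1.0, 3.0])
        ]
        resp = aggregate_response(deltas, "abp")
        assert resp.per_avd == [(160.0, 2.0, 1.0, 2)]

    def test_single_replicate_avd_excluded(self):
        from avdopt.beats import TransitionDelta

        deltas = [TransitionDelta(160.0, 0, "ref_to_test", 0, 1, 1.0, 6, 6),
                  TransitionDelta(200.0, 0, "ref_to_test", 0, 1, 1.0, 6, 6),
                  TransitionDelta(200.0, 1, "ref_to_test", 0, 2, 2.0, 6, 6)]
        with pytest.warns(BeatDetectionWarning, match="excluded"):
            resp = aggregate_response(deltas, "abp")
        assert [r[0] for r in resp.per_avd] == [200.0]

    def test_sem_matches_sampling_theory_over_seeds(self):
        """Average per-AVD SEM ~ sigma*sqrt(2/W)/sqrt(n) over 200 subjects."""
        sigma, W, n_rep = 3.0, 6, 8
        sems = []
        for seed in range(200):
            rec = generate_subject(SubjectParams(
                seed=seed, tested_avds_ms=(160.0,), replicates_per_avd=n_rep,
                abp_curvature=-1e-4, cvp_curvature=1e-4,
                beat_noise_sd_mmHg=sigma, resp_amp_abp_mmHg=0.0,
                resp_amp_cvp_mmHg=0.0, resp_irregularity=0.0,
                sample_rate_hz=FS))
            onsets = detect_beats(rec.abp, FS, 90.0)
            feats = beat_features(rec.abp, onsets, "abp", FS)
            deltas = transition_deltas(feats, rec.events, W,
                                       use_both_directions=False)
            resp = aggregate_response(deltas, "abp")
            sems.append(resp.per_avd[0][2])
        theory = sigma * np.sqrt(2.0 / W) / np.sqrt(n_rep)
        assert abs(np.mean(sems) - theory) < 0.35 * theory


class TestWindowChoice:
    def test_respiratory_cycle_window_beats_fixed_window(self):
        """With a 5-beat respiratory cycle, a 5-beat window cancels the
        oscillation better than the fixed 6-beat window."""
        p = SubjectParams(seed=8, resp_freq_hz=0.3, beat_noise_sd_mmHg=0.0,
                          resp_irregularity=0.0, sample_rate_hz=FS,
                          replicates_per_avd=4)
        rec = generate_subject(p)
        a_abp, _ = p.resolved_curvatures()
        onsets = detect_beats(rec.abp, FS, 90.0)
        feats = beat_features(rec.abp, onsets, "abp", FS)

        def mean_abs_err(w):
            deltas = transition_deltas(feats, rec.events, w)
            errs = []
            for d in deltas:
                truth = a_abp * ((d.avd_tested_ms - p.true_optimum_ms) ** 2
                                 - (p.ref_avd_ms - p.true_optimum_ms) ** 2)
                errs.append(abs(d.delta_mmHg - truth))
            return np.mean(errs)

        assert mean_abs_err(5) < mean_abs_err(6)
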