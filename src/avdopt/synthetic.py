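"""Synthetic paced-haemodynamics generator.

Emulates the AV-delay optimisation protocol: a subject atrially paced at
a fixed rate alternates between a reference AVD (120 ms) and each tested
AVD (40–280 ms), with replicate transitions for every tested setting.
Per-beat peak pressures follow a quadratic response over AVD — arterial
pressure is maximised at the subject's true optimum (concave response),
central venous pressure is the inverted, smaller mirror image (convex) —
on top of a respiratory oscillation shared by both channels, irregular
inspiratory amplitude spikes, and Gaussian beat-to-beat noise.

Every record carries a :class:`~avdopt.records.GroundTruth` so downstream
stages (beat extraction, respiratory correction, optimum fitting) can be
verified against the exact simulated truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .records import GroundTruth, HaemoRecord

__all__ = [
    "SubjectParams",
    "CohortSpread",
    "generate_subject",
    "generate_cohort",
    "curvature_for_effect",
]

#: Default tested AVD grid (ms): 40 to 280 in 40 ms steps, reference 120.
DEFAULT_TESTED_AVDS = (40.0, 80.0, 120.0, 160.0, 200.0, 240.0, 280.0)

# Fixed waveform morphology constants (fractions of the beat period).
# Only the per-beat peak amplitude carries the AVD effect; the shapes are
# cosmetic but give realistic peak/onset structure for the detectors.
_ABP_PEAK_PHASE = 0.30       # systolic peak location within the beat
_ABP_UP_FRAC = 0.25          # raised-cosine upstroke half-width
_ABP_DOWN_FRAC = 0.45        # raised-cosine decay half-width
_ABP_PULSE_PRESSURE = 40.0   # systolic minus diastolic, mmHg
_CVP_A_PHASE = 0.15          # a-wave peak (the taller of the two)
_CVP_A_HALFWIDTH = 0.12
_CVP_V_PHASE = 0.57          # v-wave peak
_CVP_V_HALFWIDTH = 0.15
_CVP_V_REL_HEIGHT = 0.75     # v-wave height relative to the a-wave
_CVP_PULSE_AMP = 5.0         # a-wave height above the venous floor, mmHg
_SPIKE_GAIN = 2.5            # inspiratory spike amplitude multiplier
_SPIKE_RATE_PER_MIN = 2.0    # baseline spike rate at irregularity = 1
# Event placed inside the last beat of the outgoing state, so that beat
# straddles the transition and belongs to neither analysis window.
_EVENT_PHASE_BEFORE_ONSET = 0.35


def curvature_for_effect(
    effect_mmhg: float,
    optimum_ms: float,
    tested_avds_ms=DEFAULT_TESTED_AVDS,
) -> float:
    """Quadratic coefficient giving a best-to-worst effect of ``effect_mmhg``.

    The response over AVD is ``effect = k * (avd - optimum)**2``; the
    best-to-worst span over the tested grid is ``|k|`` times the spread of
    squared distances from the optimum.  Returns the magnitude ``|k|``
    (mmHg/ms^2); negate for a concave (ABP-like) response.
    """
    d2 = (np.asarray(tested_avds_ms, dtype=float) - optimum_ms) ** 2
    span = d2.max() - d2.min()
    if span <= 0:
        raise ValueError("tested grid has no spread around the optimum")
    return effect_mmhg / span


@dataclass
class SubjectParams:
    """Generator configuration for one synthetic subject.

    Defaults reproduce the study conditions: pacing at 90 bpm, the
    40–280 ms tested grid against a 120 ms reference with 8 replicates,
    an 11.4 mmHg best-to-worst arterial effect mirrored by a 4.15 mmHg
    venous effect, and respiratory swings of 2.5 / 2.3 mmHg (ABP / CVP).
    """

    heart_rate_bpm: float = 90.0
    sample_rate_hz: float = 250.0
    ref_avd_ms: float = 120.0
    tested_avds_ms: tuple[float, ...] = DEFAULT_TESTED_AVDS
    replicates_per_avd: int = 8
    true_optimum_ms: float = 180.0
    abp_curvature: float | None = None   # mmHg/ms^2, < 0; None -> from 11.4 mmHg span
    cvp_curvature: float | None = None   # mmHg/ms^2, > 0; None -> from 4.15 mmHg span
    abp_systolic_base_mmHg: float = 120.0
    cvp_peak_base_mmHg: float = 12.0
    resp_freq_hz: float = 0.25
    resp_amp_cvp_mmHg: float = 2.3       # peak-to-trough
    resp_amp_abp_mmHg: float = 2.5       # peak-to-trough
    resp_irregularity: float = 1.0       # scales inspiratory-spike rate; 0 = regular
    beat_noise_sd_mmHg: float = 4.0
    cvp_noise_scale: float = 4.15 / 11.4  # CVP beat noise relative to ABP's;
    # default keeps the two channels' signal-to-noise comparable, as observed
    seed: int = 0
    beats_per_state: int = 13            # beats per pacing state; 13 keeps the
    # 6-beat pre/post windows of neighbouring transitions disjoint
    # (6 + straddling beat + 6), so replicate deltas are independent
    lead_in_beats: int = 8               # reference beats before the first transition
    settle_beats: float = 0.0            # optional exponential transient, 0-2 beats

    def resolved_curvatures(self) -> tuple[float, float]:
        a_abp = (
            self.abp_curvature
            if self.abp_curvature is not None
            else -curvature_for_effect(11.4, self.true_optimum_ms, self.tested_avds_ms)
        )
        a_cvp = (
            self.cvp_curvature
            if self.cvp_curvature is not None
            else curvature_for_effect(4.15, self.true_optimum_ms, self.tested_avds_ms)
        )
        return a_abp, a_cvp

    def validate(self) -> None:
        avds = np.asarray(self.tested_avds_ms, dtype=float)
        if avds.size == 0:
            raise ValueError("tested_avds_ms is empty")
        bad = avds[(avds < 40.0) | (avds > 280.0)]
        if bad.size:
            raise ValueError(
                f"tested AVD {bad[0]:g} ms outside the protocol range [40, 280] ms"
            )
        if not np.all(np.diff(avds) > 0):
            i = int(np.argmin(np.diff(avds) > 0))
            raise ValueError(
                f"tested_avds_ms must be sorted and unique; offending value "
                f"{avds[i + 1]:g} ms at position {i + 1}"
            )
        if self.replicates_per_avd < 1:
            raise ValueError("replicates_per_avd must be >= 1")
        a_abp, a_cvp = self.resolved_curvatures()
        if a_abp >= 0:
            raise ValueError("abp_curvature must be negative (concave ABP response)")
        if a_cvp <= 0:
            raise ValueError("cvp_curvature must be positive (convex CVP response)")
        if self.resp_freq_hz >= self.heart_rate_bpm / 60.0:
            raise ValueError("respiration must be slower than the cardiac cycle")
        if self.resp_irregularity < 0:
            raise ValueError("resp_irregularity must be >= 0")
        if self.beats_per_state < 2:
            raise ValueError("beats_per_state must be >= 2")
        if not 0.0 <= self.settle_beats <= 2.0:
            raise ValueError("settle_beats must be in [0, 2]")


def _raised_cosine(t: np.ndarray, centre: float, halfwidth: float) -> np.ndarray:
    """cos^2 bump peaking at 1 at ``centre``, zero outside +/- halfwidth."""
    out = np.zeros_like(t)
    m = np.abs(t - centre) < halfwidth
    out[m] = np.cos(np.pi * (t[m] - centre) / (2.0 * halfwidth)) ** 2
    return out


def _respiratory_trace(
    t: np.ndarray,
    amp_p2p: float,
    freq_hz: float,
    phase0: float,
    envelope: np.ndarray,
) -> np.ndarray:
    return 0.5 * amp_p2p * envelope * np.sin(2.0 * np.pi * freq_hz * t + phase0)


def _spike_envelope(t: np.ndarray, params: SubjectParams, rng) -> np.ndarray:
    """Multiplicative respiratory envelope with Poisson-timed spikes.

    Emulates sudden irregular inspirations: each spike raises the local
    respiratory amplitude by a Gaussian-shaped factor up to x2.5, lasting
    about one respiratory cycle.
    """
    env = np.ones_like(t)
    if params.resp_irregularity <= 0:
        return env
    duration = t[-1] - t[0] if t.size else 0.0
    rate_hz = _SPIKE_RATE_PER_MIN * params.resp_irregularity / 60.0
    n_spikes = rng.poisson(rate_hz * duration)
    centres = np.sort(rng.uniform(t[0], t[-1], size=n_spikes))
    tau = 0.5 / params.resp_freq_hz  # spike half-width ~ half a resp cycle
    for c in centres:
        env += (_SPIKE_GAIN - 1.0) * np.exp(-0.5 * ((t - c) / tau) ** 2)
    return env


def _state_schedule(params: SubjectParams) -> list[tuple[float, int]]:
    """(avd_ms, n_beats) per protocol state: lead-in, then test/ref pairs."""
    schedule = [(params.ref_avd_ms, params.lead_in_beats)]
    for avd in params.tested_avds_ms:
        for _ in range(params.replicates_per_avd):
            schedule.append((float(avd), params.beats_per_state))
            schedule.append((params.ref_avd_ms, params.beats_per_state))
    return schedule


def generate_subject(params: SubjectParams) -> HaemoRecord:
    """Simulate one subject's protocolised recording, with ground truth.

    Deterministic: identical ``params`` (including ``seed``) produce
    bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate_hz
    beat_period = 60.0 / params.heart_rate_bpm

    schedule = _state_schedule(params)
    beat_avd = np.concatenate(
        [np.full(n, avd, dtype=float) for avd, n in schedule]
    )
    n_beats = beat_avd.size
    onset_times = np.arange(n_beats) * beat_period

    events: list[tuple[float, float]] = []
    k = 0
    for i, (avd, n) in enumerate(schedule):
        if i > 0:
            events.append(((k - _EVENT_PHASE_BEFORE_ONSET) * beat_period, avd))
        k += n

    n_samples = int(round(n_beats * beat_period * fs))
    t = np.arange(n_samples) / fs

    # Shared intrathoracic respiratory source, channel-specific amplitude.
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    envelope = _spike_envelope(t, params, rng)
    resp_abp = _respiratory_trace(t, params.resp_amp_abp_mmHg, params.resp_freq_hz,
                                  phase0, envelope)
    resp_cvp = _respiratory_trace(t, params.resp_amp_cvp_mmHg, params.resp_freq_hz,
                                  phase0, envelope)

    a_abp, a_cvp = params.resolved_curvatures()
    d2 = (beat_avd - params.true_optimum_ms) ** 2
    amp_abp = params.abp_systolic_base_mmHg + a_abp * d2
    amp_cvp = params.cvp_peak_base_mmHg + a_cvp * d2

    if params.settle_beats > 0:
        # Exponential approach to the new level over the first beats of
        # each state (off by default; the protocol itself has no transient).
        tau = params.settle_beats
        for arr in (amp_abp, amp_cvp):
            k = 0
            prev_level = arr[0]
            for avd, n in schedule:
                target = arr[k]
                idx = np.arange(n)
                arr[k:k + n] = target + (prev_level - target) * np.exp(-(idx + 1) / tau)
                prev_level = arr[k + n - 1]
                k += n

    amp_abp = amp_abp + rng.normal(0.0, params.beat_noise_sd_mmHg, n_beats)
    amp_cvp = amp_cvp + rng.normal(
        0.0, params.cvp_noise_scale * params.beat_noise_sd_mmHg, n_beats
    )

    abp = resp_abp + (params.abp_systolic_base_mmHg - _ABP_PULSE_PRESSURE)
    cvp = resp_cvp + (params.cvp_peak_base_mmHg - _CVP_PULSE_AMP)

    dia = params.abp_systolic_base_mmHg - _ABP_PULSE_PRESSURE
    floor_cvp = params.cvp_peak_base_mmHg - _CVP_PULSE_AMP

    peak_idx_abp = np.empty(n_beats, dtype=int)
    peak_idx_cvp = np.empty(n_beats, dtype=int)
    for kb in range(n_beats):
        onset = onset_times[kb]
        # Snap each peak to the sample grid so the sampled maximum equals
        # the configured per-beat peak exactly.
        i_pk = int(round((onset + _ABP_PEAK_PHASE * beat_period) * fs))
        i_pk = min(i_pk, n_samples - 1)
        peak_idx_abp[kb] = i_pk
        t_pk = i_pk / fs
        up_w = _ABP_UP_FRAC * beat_period
        dn_w = _ABP_DOWN_FRAC * beat_period
        i0 = max(int(np.ceil((t_pk - up_w) * fs)), 0)
        i1 = min(int(np.floor((t_pk + dn_w) * fs)), n_samples - 1)
        seg = t[i0:i1 + 1]
        pulse = np.where(
            seg <= t_pk,
            np.cos(np.pi * (seg - t_pk) / (2.0 * up_w)) ** 2,
            np.cos(np.pi * (seg - t_pk) / (2.0 * dn_w)) ** 2,
        )
        abp[i0:i1 + 1] += (amp_abp[kb] - dia) * pulse

        i_a = int(round((onset + _CVP_A_PHASE * beat_period) * fs))
        i_a = min(i_a, n_samples - 1)
        peak_idx_cvp[kb] = i_a
        t_a = i_a / fs
        a_w = _CVP_A_HALFWIDTH * beat_period
        i0 = max(int(np.ceil((t_a - a_w) * fs)), 0)
        i1 = min(int(np.floor((t_a + a_w) * fs)), n_samples - 1)
        seg = t[i0:i1 + 1]
        cvp[i0:i1 + 1] += (amp_cvp[kb] - floor_cvp) * (
            np.cos(np.pi * (seg - t_a) / (2.0 * a_w)) ** 2
        )
        # v-wave: second, smaller peak of the venous cycle
        i_v = int(round((onset + _CVP_V_PHASE * beat_period) * fs))
        t_v = i_v / fs
        v_w = _CVP_V_HALFWIDTH * beat_period
        i0 = max(int(np.ceil((t_v - v_w) * fs)), 0)
        i1 = min(int(np.floor((t_v + v_w) * fs)), n_samples - 1)
        seg = t[i0:i1 + 1]
        cvp[i0:i1 + 1] += _CVP_V_REL_HEIGHT * (amp_cvp[kb] - floor_cvp) * (
            np.cos(np.pi * (seg - t_v) / (2.0 * v_w)) ** 2
        )

    truth = GroundTruth(
        true_optimum_abp_ms=params.true_optimum_ms,
        true_optimum_cvp_ms=params.true_optimum_ms,
        resp_trace_abp=resp_abp,
        resp_trace_cvp=resp_cvp,
        beat_onset_times_s=onset_times,
        beat_avd_ms=beat_avd,
        beat_peak_times_abp_s=peak_idx_abp / fs,
        beat_peaks_abp_mmhg=abp[peak_idx_abp],
        beat_peak_times_cvp_s=peak_idx_cvp / fs,
        beat_peaks_cvp_mmhg=cvp[peak_idx_cvp],
    )
    record = HaemoRecord(
        time=t,
        abp=abp,
        cvp=cvp,
        sample_rate_hz=fs,
        events=events,
        beat_times=onset_times,
        truth=truth,
    )
    record.validate()
    return record


@dataclass
class CohortSpread:
    """Between-subject heterogeneity for cohort simulation.

    Each range is sampled uniformly per subject; ``None`` leaves the base
    parameter untouched.  Respiratory frequency spread defaults to the
    realistic adult range 0.18–0.35 Hz (11–21 breaths/min) so that the
    fixed 6-beat analysis window does not coincide with one respiratory
    cycle in every subject.
    """

    true_optimum_range_ms: tuple[float, float] | None = (100.0, 320.0)
    resp_freq_range_hz: tuple[float, float] | None = (0.18, 0.35)
    beat_noise_range_mmHg: tuple[float, float] | None = None
    resp_amp_scale_range: tuple[float, float] | None = None

    @classmethod
    def none(cls) -> "CohortSpread":
        """No heterogeneity: every subject shares the base parameters."""
        return cls(None, None, None, None)


def generate_cohort(
    n_subjects: int,
    base_params: SubjectParams,
    spread: CohortSpread | None = None,
    seed: int = 0,
) -> list[HaemoRecord]:
    """Simulate a cohort of subjects drawn around ``base_params``."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    spread = spread if spread is not None else CohortSpread()
    master = np.random.default_rng(seed)
    records = []
    for i in range(n_subjects):
        p = replace(base_params, seed=int(master.integers(2**31 - 1)))
        if spread.true_optimum_range_ms is not None:
            p = replace(p, true_optimum_ms=float(
                master.uniform(*spread.true_optimum_range_ms)))
        if spread.resp_freq_range_hz is not None:
            p = replace(p, resp_freq_hz=float(
                master.uniform(*spread.resp_freq_range_hz)))
        if spread.beat_noise_range_mmHg is not None:
            p = replace(p, beat_noise_sd_mmHg=float(
                master.uniform(*spread.beat_noise_range_mmHg)))
        if spread.resp_amp_scale_range is not None:
            s = float(master.uniform(*spread.resp_amp_scale_range))
            p = replace(p, resp_amp_cvp_mmHg=base_params.resp_amp_cvp_mmHg * s,
                        resp_amp_abp_mmHg=base_params.resp_amp_abp_mmHg * s)
        records.append(generate_subject(p))
    return records
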