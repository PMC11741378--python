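"""Beat detection, per-beat features, and replicate transition deltas.

The protocol paces the atrium at a fixed known rate, so beat detection
amounts to finding one dominant peak per pacing cycle and anchoring the
beat onset at the pulse foot (the minimum preceding the upstroke).  For
arterial pressure the per-beat feature of interest is the systolic peak;
for venous pressure the cycle shows two peaks (a- and v-waves) and the
feature is either the taller peak or the beat-window mean.

Each pacing transition contributes one replicate delta: the difference
between the mean feature over a window of beats immediately after the
transition and the window immediately before, signed as
tested-minus-reference.  Deltas are aggregated per tested AVD into a
mean +/- SEM response curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "BeatFeature",
    "TransitionDelta",
    "AVDResponse",
    "BeatDetectionWarning",
    "detect_beats",
    "beat_features",
    "transition_deltas",
    "aggregate_response",
]


class BeatDetectionWarning(UserWarning):
    """Detected beat rate deviates from the pacing rate, or no beats found."""


@dataclass
class BeatFeature:
    """Per-beat summary of one channel."""

    beat_time_s: float          # onset (pulse foot)
    end_time_s: float           # start of the next beat (window close)
    channel: str                # "abp" | "cvp"
    peak_mmHg: float
    mean_mmHg: float
    avd_ms: float | None = None  # setting in force at onset; filled on attribution


@dataclass
class TransitionDelta:
    """One replicate transition's signed pressure change."""

    avd_tested_ms: float
    replicate_index: int
    direction: str              # "ref_to_test" | "test_to_ref"
    pre_mean_mmHg: float
    post_mean_mmHg: float
    delta_mmHg: float           # signed tested-minus-reference
    n_pre: int
    n_post: int


@dataclass
class AVDResponse:
    """Mean +/- SEM pressure change per tested AVD for one channel."""

    channel: str
    feature: str                # "peak" | "mean"
    per_avd: list[tuple[float, float, float, int]]  # (avd, mean, sem, n)

    @property
    def avds(self) -> np.ndarray:
        return np.array([row[0] for row in self.per_avd])

    @property
    def means(self) -> np.ndarray:
        return np.array([row[1] for row in self.per_avd])

    @property
    def sems(self) -> np.ndarray:
        return np.array([row[2] for row in self.per_avd])

    @property
    def counts(self) -> np.ndarray:
        return np.array([row[3] for row in self.per_avd])


def detect_beats(
    signal: np.ndarray, fs: float, pacing_rate_bpm: float
) -> np.ndarray:
    """Beat onset times (pulse-foot anchored), one per pacing cycle.

    Peaks are found with a minimum separation of 0.6 pacing cycles, so
    the taller of the two venous peaks wins within each cycle; the onset
    is the signal minimum in the half-cycle preceding each peak.  Emits
    :class:`BeatDetectionWarning` when nothing is found or the detected
    rate deviates more than 25% from the pacing rate.
    """
    x = np.asarray(signal, dtype=float)
    period_s = 60.0 / pacing_rate_bpm
    span = np.ptp(x)
    if span <= 1e-12:
        warnings.warn("flat-line signal: no beats detected", BeatDetectionWarning)
        return np.array([])
    peaks, _ = find_peaks(
        x, distance=max(1, int(0.6 * period_s * fs)), prominence=0.1 * span
    )
    if peaks.size == 0:
        warnings.warn("no beats detected", BeatDetectionWarning)
        return np.array([])
    if peaks.size >= 2:
        ibi = np.median(np.diff(peaks)) / fs
        rate = 60.0 / ibi
        if abs(rate - pacing_rate_bpm) > 0.25 * pacing_rate_bpm:
            warnings.warn(
                f"detected beat rate {rate:.1f} bpm deviates from pacing rate "
                f"{pacing_rate_bpm:.1f} bpm by more than 25%",
                BeatDetectionWarning,
            )
    onsets = np.empty(peaks.size)
    half = max(1, int(0.45 * period_s * fs))
    for i, pk in enumerate(peaks):
        lo = max(0, pk - half)
        onsets[i] = (lo + int(np.argmin(x[lo:pk + 1]))) / fs
    return onsets


def beat_features(
    signal: np.ndarray,
    beats: np.ndarray,
    channel: str,
    fs: float,
) -> list[BeatFeature]:
    """Per-beat peak and mean over consecutive onset-to-onset windows.

    The venous peak is the maximum of the (up to) two most prominent
    local maxima in the beat window; the arterial peak is the single
    systolic maximum.  The final beat's window closes at the end of the
    signal.  Empty windows are skipped.
    """
    x = np.asarray(signal, dtype=float)
    beats = np.asarray(beats, dtype=float)
    ends = np.append(beats[1:], x.size / fs)
    out: list[BeatFeature] = []
    for t0, t1 in zip(beats, ends):
        i0, i1 = int(np.ceil(t0 * fs)), int(np.floor(t1 * fs))
        seg = x[i0:i1]
        if seg.size == 0:
            continue
        if channel == "cvp" and seg.size >= 3:
            local, props = find_peaks(seg, prominence=0.0)
            if local.size:
                top2 = local[np.argsort(props["prominences"])[-2:]]
                peak = float(seg[top2].max())
            else:
                peak = float(seg.max())
        else:
            peak = float(seg.max())
        out.append(
            BeatFeature(
                beat_time_s=float(t0),
                end_time_s=float(t1),
                channel=channel,
                peak_mmHg=peak,
                mean_mmHg=float(seg.mean()),
            )
        )
    return out


def _event_directions(
    events: list[tuple[float, float]], ref_avd_ms: float | None
) -> list[tuple[float, float, str]]:
    """(time, tested_avd, direction) per transition, from protocol parity.

    Even-indexed events enter a tested state, odd-indexed return to the
    reference; the tested AVD of a return transition is the setting that
    was just left.
    """
    out = []
    for i, (t, avd) in enumerate(events):
        if i % 2 == 0:
            out.append((t, avd, "ref_to_test"))
        else:
            if ref_avd_ms is not None and avd != ref_avd_ms:
                raise ValueError(
                    f"event {i} at t={t:.3f}s returns to {avd:g} ms, "
                    f"not the reference {ref_avd_ms:g} ms"
                )
            out.append((t, events[i - 1][1], "test_to_ref"))
    return out


def transition_deltas(
    features: list[BeatFeature],
    events: list[tuple[float, float]],
    window_beats: int,
    feature: str = "peak",
    ref_avd_ms: float | None = None,
    use_both_directions: bool = True,
) -> list[TransitionDelta]:
    """Replicate deltas around every usable pacing transition.

    The pre-window is the last ``window_beats`` beats whose windows close
    before the event instant and the post-window the first
    ``window_beats`` beats starting after it; the beat straddling the
    transition belongs to neither.  Windows clipped by a neighbouring
    transition drop the transition (logged as a warning).  Deltas are
    signed tested-minus-reference so both transition directions pool.
    """
    if window_beats < 1:
        raise ValueError("window_beats must be >= 1")
    if feature not in ("peak", "mean"):
        raise ValueError(f"unknown feature {feature!r}")
    onsets = np.array([f.beat_time_s for f in features])
    ends = np.array([f.end_time_s for f in features])
    values = np.array(
        [f.peak_mmHg if feature == "peak" else f.mean_mmHg for f in features]
    )
    dirs = _event_directions(events, ref_avd_ms)
    times = np.array([t for t, _, _ in dirs])
    rep_counter: dict[float, int] = {}
    out: list[TransitionDelta] = []
    for i, (t_e, avd, direction) in enumerate(dirs):
        if direction == "test_to_ref" and not use_both_directions:
            continue
        t_prev = times[i - 1] if i > 0 else -np.inf
        t_next = times[i + 1] if i + 1 < len(dirs) else np.inf
        pre_idx = np.nonzero((ends <= t_e) & (onsets > t_prev))[0]
        post_idx = np.nonzero((onsets >= t_e) & (ends <= t_next))[0]
        if pre_idx.size < window_beats or post_idx.size < window_beats:
            warnings.warn(
                f"transition at t={t_e:.2f}s dropped: only {pre_idx.size} pre / "
                f"{post_idx.size} post beats for a {window_beats}-beat window",
                BeatDetectionWarning,
            )
            continue
        pre = values[pre_idx[-window_beats:]]
        post = values[post_idx[:window_beats]]
        raw = float(post.mean() - pre.mean())
        delta = raw if direction == "ref_to_test" else -raw
        rep = rep_counter.get(avd, 0)
        rep_counter[avd] = rep + 1
        out.append(
            TransitionDelta(
                avd_tested_ms=float(avd),
                replicate_index=rep,
                direction=direction,
                pre_mean_mmHg=float(pre.mean()),
                post_mean_mmHg=float(post.mean()),
                delta_mmHg=delta,
                n_pre=window_beats,
                n_post=window_beats,
            )
        )
    return out


def aggregate_response(
    deltas: list[TransitionDelta], channel: str, feature: str = "peak"
) -> AVDResponse:
    """Mean and SEM of replicate deltas per tested AVD.

    AVDs retaining fewer than 2 replicates are excluded (SEM undefined)
    with a warning.
    """
    by_avd: dict[float, list[float]] = {}
    for d in deltas:
        by_avd.setdefault(d.avd_tested_ms, []).append(d.delta_mmHg)
    per_avd = []
    for avd in sorted(by_avd):
        vals = np.array(by_avd[avd])
        if vals.size < 2:
            warnings.warn(
                f"AVD {avd:g} ms excluded: only {vals.size} replicate(s)",
                BeatDetectionWarning,
            )
            continue
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size))
        per_avd.append((float(avd), float(vals.mean()), sem, int(vals.size)))
    return AVDResponse(channel=channel, feature=feature, per_avd=per_avd)
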