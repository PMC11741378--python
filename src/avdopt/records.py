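"""Core data containers for paced haemodynamic recordings.

A recording couples two uniformly sampled invasive pressure channels —
arterial blood pressure (ABP, radial) and central venous pressure (CVP,
superior vena cava) — with a stream of pacing-setting annotations: the
instants at which the programmed atrioventricular delay (AVD) changed.
The optimisation protocol alternates between a reference AVD and each
tested AVD, so consecutive annotations alternate between entering a
tested state and returning to the reference state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GroundTruth", "HaemoRecord", "ProtocolError"]


class ProtocolError(ValueError):
    """Raised when a record violates the alternating pacing protocol."""


@dataclass
class GroundTruth:
    """Generator-side truth attached to synthetic records.

    Used as the oracle for beat extraction and respiratory-correction
    tests; absent on real recordings.
    """

    true_optimum_abp_ms: float
    true_optimum_cvp_ms: float
    resp_trace_abp: np.ndarray
    resp_trace_cvp: np.ndarray
    beat_onset_times_s: np.ndarray
    beat_avd_ms: np.ndarray
    beat_peak_times_abp_s: np.ndarray
    beat_peaks_abp_mmhg: np.ndarray
    beat_peak_times_cvp_s: np.ndarray
    beat_peaks_cvp_mmhg: np.ndarray

    @property
    def per_beat_peaks(self):
        """All true per-beat peaks as (time_s, channel, value) tuples."""
        out = [
            (t, "abp", v)
            for t, v in zip(self.beat_peak_times_abp_s, self.beat_peaks_abp_mmhg)
        ]
        out += [
            (t, "cvp", v)
            for t, v in zip(self.beat_peak_times_cvp_s, self.beat_peaks_cvp_mmhg)
        ]
        return sorted(out)


@dataclass
class HaemoRecord:
    """A dual-channel pressure recording with pacing annotations.

    ``events`` holds ``(time_s, avd_ms)`` pairs marking the instant a new
    AVD takes effect.  The recording starts in the reference state, so
    even-indexed events enter a tested state and odd-indexed events
    return to the reference.
    """

    time: np.ndarray
    abp: np.ndarray
    cvp: np.ndarray
    sample_rate_hz: float
    events: list[tuple[float, float]] = field(default_factory=list)
    beat_times: np.ndarray | None = None
    truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        self.cvp = np.asarray(self.cvp, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def infer_reference_avd(self) -> float:
        """Reference AVD implied by protocol alternation.

        Odd-indexed events all return to the reference state, so their
        settings must agree; that shared value is the reference.
        """
        if len(self.events) < 2:
            raise ProtocolError("need at least 2 events to infer the reference AVD")
        refs = {avd for _, avd in self.events[1::2]}
        if len(refs) != 1:
            raise ProtocolError(
                f"return-to-reference events carry inconsistent settings: {sorted(refs)}"
            )
        return refs.pop()

    def validate(self) -> None:
        """Check structural invariants; raise on violation."""
        if not (self.abp.size == self.cvp.size == self.time.size):
            raise ValueError(
                f"channel lengths differ: time={self.time.size} "
                f"abp={self.abp.size} cvp={self.cvp.size}"
            )
        if np.isnan(self.abp).any() or np.isnan(self.cvp).any():
            raise ValueError("missing samples (NaN) in pressure channels")
        times = np.array([t for t, _ in self.events])
        if times.size and not np.all(np.diff(times) > 0):
            i = int(np.argmin(np.diff(times) > 0))
            raise ValueError(f"events not strictly increasing at index {i + 1}")
        t0, t1 = self.time[0], self.time[-1]
        for t, avd in self.events:
            if not (t0 <= t <= t1):
                raise ValueError(
                    f"event at t={t:.3f}s (avd={avd:g}ms) outside recording span "
                    f"[{t0:.3f}, {t1:.3f}]s"
                )
        if len(self.events) >= 2:
            self.infer_reference_avd()
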