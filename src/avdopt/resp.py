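"""Respiratory baseline estimation and removal for pressure signals.

Central venous pressure swings by a few mmHg with every breath — the
same order as the pacing effect being measured — so the respiratory
component must be estimated and subtracted (or averaged out) before
beat-level analysis.  Three approaches are provided:

* **ALS** — asymmetric least squares: a Whittaker-style penalised
  smoother whose asymmetry weight ``p`` biases the baseline toward the
  lower envelope (``p`` small) or the midline (``p = 0.5``) of the
  signal; the second-difference penalty ``lam`` sets the effective
  cutoff between the respiratory (<= 0.5 Hz) and cardiac (>= 1 Hz) bands.
* **DWT** — a shift-invariant stationary wavelet transform; the
  respiratory trace is reconstructed from the dyadic detail levels whose
  nominal band overlaps the estimated respiratory frequency and then
  subtracted from the signal.
* **Respiratory-cycle windowing** — no subtraction at all: the
  transition analysis window is set to the number of beats spanning one
  respiratory cycle, so the oscillation integrates out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps
from scipy.linalg import solveh_banded

__all__ = [
    "ALSConfig",
    "DWTConfig",
    "RespEstimate",
    "RespirationNotDetected",
    "estimate_resp_als",
    "estimate_resp_dwt",
    "estimate_resp_freq",
    "estimate_resp_cycle_beats",
    "subtract_resp",
    "respiratory_band_power",
]

RESP_BAND_HZ = (0.05, 1.0)


class RespirationNotDetected(ValueError):
    """No spectral peak in the respiratory band and no frequency hint."""


@dataclass
class ALSConfig:
    """Asymmetric-least-squares smoother parameters.

    ``lam`` is auto-scaled as ``lam0 * (fs / 250)**4`` when ``None`` so
    the smoother's cutoff stays between the respiratory and cardiac
    bands regardless of sampling rate (the second-difference penalty
    strength grows with sampling density).  ``p = 0.5`` tracks the
    midline of the respiratory swing; the classic small-``p``
    lower-envelope choice is available but not the default.
    """

    lam: float | None = None
    p: float = 0.5
    n_iter: int = 10
    lam0: float = 1.0e7  # penalty at 250 Hz; cutoff ~0.7 Hz

    def resolved_lam(self, fs: float) -> float:
        lam = self.lam if self.lam is not None else self.lam0 * (fs / 250.0) ** 4
        if lam <= 0:
            raise ValueError("lam must be > 0")
        return lam

    def validate(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must be in (0, 1)")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class DWTConfig:
    """Stationary-wavelet respiratory extraction parameters."""

    wavelet: str = "sym8"
    band_factor: float = 1.5  # keep levels overlapping [f/1.5, 1.5f]
    resp_freq_hint_hz: float | None = None


@dataclass
class RespEstimate:
    """An estimated respiratory trace, same length as its input."""

    resp_trace: np.ndarray
    resp_freq_hz: float
    method: str  # "als" or "dwt"
    band_power_removed_frac: float
    freq_reliable: bool = True


def respiratory_band_power(
    x: np.ndarray, fs: float, band: tuple[float, float] = (0.1, 0.5)
) -> float:
    """Mean power spectral density integrated over ``band`` (Welch)."""
    x = np.asarray(x, dtype=float)
    nperseg = min(x.size, int(60 * fs))
    f, p = sps.welch(x - x.mean(), fs=fs, nperseg=nperseg)
    m = (f >= band[0]) & (f <= band[1])
    return float(np.trapezoid(p[m], f[m]))


def estimate_resp_freq(signal: np.ndarray, fs: float) -> float:
    """Respiratory frequency from the Welch periodogram peak in 0.05–1 Hz.

    Raises :class:`RespirationNotDetected` when the band holds no clear
    peak (peak power < 5x the band's median power).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 10 * fs / RESP_BAND_HZ[0]:
        # too short to resolve the band floor; still try with what we have
        pass
    nperseg = min(x.size, int(60 * fs))
    f, p = sps.welch(x - x.mean(), fs=fs, nperseg=nperseg)
    m = (f >= RESP_BAND_HZ[0]) & (f <= RESP_BAND_HZ[1])
    if not m.any() or not np.any(p[m] > 0):
        raise RespirationNotDetected("respiration not detected")
    band_p = p[m]
    peak = band_p.max()
    med = np.median(band_p)
    if med > 0 and peak < 5.0 * med:
        raise RespirationNotDetected("respiration not detected")
    if med == 0 and peak == 0:
        raise RespirationNotDetected("respiration not detected")
    # the peak must carry a non-trivial share of the signal's variance,
    # otherwise it is spectral leakage from outside the band
    total = np.trapezoid(p, f)
    df = f[1] - f[0] if f.size > 1 else 1.0
    if total > 0 and peak * df < 1e-3 * total:
        raise RespirationNotDetected("respiration not detected")
    return float(f[m][np.argmax(band_p)])


def _band_frac(signal, resp_trace, fs, resp_freq):
    band = (max(0.05, 0.5 * resp_freq), min(1.0, 2.0 * resp_freq))
    before = respiratory_band_power(signal, fs, band)
    if before <= 0:
        return 0.0
    after = respiratory_band_power(np.asarray(signal) - resp_trace, fs, band)
    return float(np.clip(1.0 - after / before, 0.0, 1.0))


def estimate_resp_als(
    signal: np.ndarray, fs: float, cfg: ALSConfig | None = None
) -> RespEstimate:
    """Asymmetric-least-squares respiratory baseline.

    Minimises ``sum_i w_i (y_i - z_i)^2 + lam * sum_i (d2 z_i)^2`` with
    ``w_i = p`` where ``y_i > z_i`` else ``1 - p``, iterated ``n_iter``
    times.  Solved with a banded Cholesky factorisation (the normal
    matrix is pentadiagonal), O(n) per iteration.
    """
    cfg = cfg or ALSConfig()
    cfg.validate()
    y = np.asarray(signal, dtype=float)
    n = y.size
    min_len = int(10 * fs / RESP_BAND_HZ[1])  # >= 10 cardiac-free cycles worth
    if n < max(min_len, 16):
        raise ValueError("too short for baseline estimation")
    lam = cfg.resolved_lam(fs)

    # Banded (upper) representation of lam * D2'D2, fixed across iterations.
    ab0 = np.zeros((3, n))
    ab0[2, :] = 6.0
    ab0[2, [0, -1]] = 1.0
    ab0[2, [1, -2]] = 5.0
    ab0[1, 1:] = -4.0
    ab0[1, [1, -1]] = -2.0
    ab0[0, 2:] = 1.0
    ab0 *= lam

    w = np.full(n, 0.5)
    z = y
    for _ in range(cfg.n_iter):
        ab = ab0.copy()
        ab[2, :] += w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, cfg.p, 1.0 - cfg.p)
        if np.array_equal(w_new, w):
            break
        w = w_new

    try:
        f_resp = estimate_resp_freq(y, fs)
        reliable = True
    except RespirationNotDetected:
        f_resp = np.nan
        reliable = False
    frac = _band_frac(y, z, fs, f_resp) if reliable else 0.0
    return RespEstimate(resp_trace=z, resp_freq_hz=f_resp, method="als",
                        band_power_removed_frac=frac, freq_reliable=reliable)


def _swt_levels_for_band(fs: float, f_resp: float, band_factor: float,
                         n: int) -> tuple[int, list[int]]:
    """Total decomposition depth and the detail levels to keep.

    Detail level ``j`` spans the nominal band (fs/2^(j+1), fs/2^j]; keep
    every level overlapping [f_resp/band_factor, f_resp*band_factor].
    """
    lo = f_resp / band_factor
    hi = f_resp * band_factor
    max_level = int(np.ceil(np.log2(fs / lo))) - 1
    keep = []
    for j in range(1, max_level + 1):
        f_hi = fs / 2**j
        f_lo = fs / 2**(j + 1)
        if f_hi > lo and f_lo < hi:
            keep.append(j)
    if not keep:
        keep = [max_level]
    depth = max(keep)
    # swt needs len divisible by 2**depth; the caller pads accordingly
    return depth, keep


def estimate_resp_dwt(
    signal: np.ndarray,
    fs: float,
    resp_freq_hint_hz: float | None = None,
    cfg: DWTConfig | None = None,
) -> RespEstimate:
    """Shift-invariant wavelet estimate of the respiratory trace.

    The signal is decomposed with a stationary (undecimated) wavelet
    transform and the respiratory trace reconstructed from the detail
    levels whose dyadic band overlaps the estimated (or hinted)
    respiratory frequency.  Shift invariance avoids edge artefacts at
    pacing transitions that a decimated transform would introduce.
    """
    cfg = cfg or DWTConfig()
    y = np.asarray(signal, dtype=float)
    if y.size < 16:
        raise ValueError("too short for wavelet decomposition")
    hint = resp_freq_hint_hz if resp_freq_hint_hz is not None else cfg.resp_freq_hint_hz
    if np.ptp(y) == 0:
        # degenerate but well-defined: nothing to remove
        return RespEstimate(resp_trace=np.zeros_like(y), resp_freq_hz=np.nan,
                            method="dwt", band_power_removed_frac=0.0,
                            freq_reliable=False)
    try:
        f_resp = estimate_resp_freq(y, fs)
        reliable = True
    except RespirationNotDetected:
        if hint is None:
            raise
        f_resp = float(hint)
        reliable = False

    depth, keep = _swt_levels_for_band(fs, f_resp, cfg.band_factor, y.size)
    block = 2**depth
    pad = (-y.size) % block
    # symmetric padding split across both ends limits edge leakage
    pad_l = pad // 2
    pad_r = pad - pad_l
    yp = np.pad(y - y.mean(), (pad_l, pad_r), mode="reflect")
    coeffs = pywt.swt(yp, cfg.wavelet, level=depth, trim_approx=True, norm=True)
    # coeffs = [cA_depth, cD_depth, ..., cD_1]; zero everything but the
    # respiratory detail levels, then invert.
    kept = [np.zeros_like(coeffs[0])]
    for i, c in enumerate(coeffs[1:]):
        j = depth - i  # this detail's level
        kept.append(c if j in keep else np.zeros_like(c))
    resp = pywt.iswt(kept, cfg.wavelet, norm=True)
    resp = np.asarray(resp)[pad_l:pad_l + y.size]
    frac = _band_frac(y, resp, fs, f_resp)
    return RespEstimate(resp_trace=resp, resp_freq_hz=f_resp, method="dwt",
                        band_power_removed_frac=frac, freq_reliable=reliable)


def subtract_resp(signal: np.ndarray, est: RespEstimate) -> np.ndarray:
    """Level-preserving subtraction: remove the oscillation, keep the mean."""
    y = np.asarray(signal, dtype=float)
    r = np.asarray(est.resp_trace, dtype=float)
    if y.size != r.size:
        raise ValueError(
            f"length mismatch: signal {y.size} vs resp_trace {r.size}"
        )
    return y - r + r.mean()


def estimate_resp_cycle_beats(
    signal: np.ndarray, fs: float, heart_rate_bpm: float
) -> int:
    """Beats spanning one respiratory cycle (respiratory-cycle windowing).

    Raises :class:`RespirationNotDetected` when respiration cannot be
    resolved; the caller then falls back to the fixed 6-beat window.
    """
    f_resp = estimate_resp_freq(signal, fs)
    return max(1, int(round(heart_rate_bpm / (60.0 * f_resp))))
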