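"""Agreement and signal-quality statistics for ABP-vs-CVP optimisation.

Covers the comparison layer of the analysis: the per-channel
signal-to-noise ratio of the AVD response, the pooled per-transition
rank correlation between venous and arterial pressure changes (the
"mirror image" relationship), the relationship between SE_opt and the
gap between the two channels' optima, and Bland–Altman agreement of the
optima themselves.  Rank (Spearman) correlation is used throughout
because the replicate deltas are markedly heteroskedastic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from .beats import AVDResponse, TransitionDelta

__all__ = [
    "SNRResult",
    "AgreementResult",
    "signal_to_noise",
    "spearman",
    "per_transition_correlation",
    "pair_transition_deltas",
    "seopt_vs_discrepancy",
    "bland_altman",
]

EXACT_PERMUTATION_N = 10  # below this, the Spearman p-value is exact


@dataclass
class SNRResult:
    """Signal-to-noise ratio of one channel's AVD response.

    Signal: spread between the best and worst tested AVD means.
    Noise: the average of the per-AVD SEMs.
    """

    channel: str
    feature: str
    signal_mmHg: float
    noise_mmHg: float
    snr: float


@dataclass
class AgreementResult:
    """Rank correlation and/or Bland–Altman agreement summary."""

    r: float
    p_value: float
    n_pairs: int
    bland_bias: float = math.nan
    loa_low: float = math.nan
    loa_high: float = math.nan


def signal_to_noise(resp: AVDResponse) -> SNRResult:
    """Best-to-worst spread of observed per-AVD means over the mean SEM.

    Uses the observed means of the tested AVDs, not fitted parabola
    values.  Zero signal gives SNR 0; zero noise with nonzero signal is
    reported as infinity.
    """
    if len(resp.per_avd) < 2:
        raise ValueError("need >= 2 tested AVDs with SEMs for an SNR")
    means = resp.means
    sems = resp.sems
    sig = float(means.max() - means.min())
    noise = float(sems.mean())
    if sig == 0:
        snr = 0.0
    elif noise == 0:
        snr = math.inf
    else:
        snr = sig / noise
    return SNRResult(channel=resp.channel, feature=resp.feature,
                     signal_mmHg=sig, noise_mmHg=noise, snr=snr)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p-value for small n (midrank ties)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = np.sqrt((sx**2).sum() * (sy**2).sum())
    if denom == 0:
        return math.nan
    perms = np.array(list(permutations(range(n))))
    stats_all = (sx[perms] * sy).sum(axis=1) / denom
    return float(np.mean(np.abs(stats_all) >= abs(r_obs) - 1e-12))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    p-value by the t-approximation for n >= 10 and exact permutation
    enumeration below that.  Degenerate margins (a constant vector)
    yield (nan, nan) rather than a spurious value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    r, p = stats.spearmanr(x, y)
    if x.size < EXACT_PERMUTATION_N:
        p = _exact_spearman_p(x, y, r)
    return float(r), float(p)


def pair_transition_deltas(
    deltas_a: list[TransitionDelta], deltas_b: list[TransitionDelta]
) -> tuple[np.ndarray, np.ndarray]:
    """Match two channels' replicate deltas by (AVD, replicate, direction)."""
    key = lambda d: (d.avd_tested_ms, d.replicate_index, d.direction)
    lut = {key(d): d.delta_mmHg for d in deltas_b}
    xs, ys = [], []
    for d in deltas_a:
        k = key(d)
        if k in lut:
            xs.append(d.delta_mmHg)
            ys.append(lut[k])
    return np.array(xs), np.array(ys)


def per_transition_correlation(
    deltas_abp: list[TransitionDelta], deltas_cvp: list[TransitionDelta]
) -> AgreementResult:
    """Pooled rank correlation of per-transition CVP vs ABP changes.

    A reliable venous mirror image shows as a negative correlation:
    transitions that raise arterial pressure lower venous pressure.
    """
    x, y = pair_transition_deltas(deltas_abp, deltas_cvp)
    if x.size < 5:
        raise ValueError(f"only {x.size} matched transition pairs; need >= 5")
    r, p = spearman(x, y)
    return AgreementResult(r=r, p_value=p, n_pairs=int(x.size))


def seopt_vs_discrepancy(
    pairs: list[tuple[float, float]]
) -> AgreementResult:
    """Rank correlation of per-subject SE_opt against |ABP − CVP optimum|.

    A positive correlation means the internally estimated uncertainty
    predicts how far the two channels' optima diverge — i.e. a small
    SE_opt certifies a trustworthy optimum.  Degenerate cohorts (all
    SE_opt or all gaps tied, e.g. noiseless data) report NaN.
    """
    if len(pairs) < 5:
        raise ValueError(f"only {len(pairs)} subjects; need >= 5")
    se = np.array([p[0] for p in pairs], dtype=float)
    gap = np.array([abs(p[1]) for p in pairs], dtype=float)
    r, p = spearman(se, gap)
    return AgreementResult(r=r, p_value=p, n_pairs=len(pairs))


def bland_altman(optima_abp, optima_cvp) -> AgreementResult:
    """Bland–Altman agreement of paired optima (CVP minus ABP).

    Bias is the mean difference; the limits of agreement are
    bias +/- 1.96 SD of the differences.  The pair rank correlation is
    reported alongside.
    """
    a = np.asarray(optima_abp, dtype=float)
    c = np.asarray(optima_cvp, dtype=float)
    if a.size != c.size:
        raise ValueError("optima lists must be paired")
    if a.size < 3:
        raise ValueError(f"only {a.size} pairs; need >= 3")
    diff = c - a
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if a.size > 1 else 0.0
    r, p = spearman(a, c)
    return AgreementResult(
        r=r, p_value=p, n_pairs=int(a.size),
        bland_bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
    )
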