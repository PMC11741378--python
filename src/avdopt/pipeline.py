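"""End-to-end subject analysis and cohort aggregation.

``run_pipeline`` takes a validated recording through respiratory
correction, beat extraction, replicate transition deltas, per-AVD
aggregation, parabolic optimum fitting with SE_opt, quality control and
between-channel agreement, returning a :class:`SubjectReport`.  Cohort
helpers aggregate subject reports into the comparison statistics
(SE_opt-vs-discrepancy, Bland–Altman of the optima, median SNR).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import agreement as agg
from . import beats as bt
from . import optimum as opt
from . import resp as rc
from .records import HaemoRecord

__all__ = [
    "AnalysisConfig",
    "ChannelReport",
    "SubjectReport",
    "run_pipeline",
    "cohort_table",
    "analyze_cohort",
    "CohortSummary",
]

log = logging.getLogger("avdopt")

CARDIAC_BAND_HZ = (0.8, 3.0)


@dataclass
class AnalysisConfig:
    """Run configuration mirroring the analysis protocol.

    ``window_mode`` selects the fixed 6-beat transition window or the
    per-subject respiratory-cycle window; ``correction`` selects the
    respiratory subtraction method applied to the CVP trace.
    """

    window_mode: str = "fixed_beats"        # "fixed_beats" | "resp_cycle"
    window_beats: int = 6
    correction: str = "none"                # "none" | "als" | "dwt"
    cvp_feature: str = "peak"               # "peak" | "mean"
    qc_seopt_threshold_ms: float = opt.DEFAULT_SEOPT_THRESHOLD_MS
    bootstrap_reps: int = 1000
    seed: int = 0
    als: rc.ALSConfig = field(default_factory=rc.ALSConfig)
    dwt: rc.DWTConfig = field(default_factory=rc.DWTConfig)
    weighting: str = "inverse_variance"
    use_both_directions: bool = True
    correct_abp: bool = False
    ref_avd_ms: float | None = None         # None: inferred from event parity
    pacing_rate_bpm: float | None = None    # None: estimated from the ABP spectrum

    def validate(self) -> None:
        if self.window_beats < 1:
            raise ValueError("window_beats must be >= 1")
        if self.qc_seopt_threshold_ms <= 0:
            raise ValueError("qc_seopt_threshold_ms must be > 0")
        if self.window_mode not in ("fixed_beats", "resp_cycle"):
            raise ValueError(f"unknown window_mode {self.window_mode!r}")
        if self.correction not in ("none", "als", "dwt"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.cvp_feature not in ("peak", "mean"):
            raise ValueError(f"unknown cvp_feature {self.cvp_feature!r}")


@dataclass
class ChannelReport:
    """Per-channel analysis products."""

    channel: str
    response: bt.AVDResponse
    fit: opt.ParabolaFit | None
    qc: opt.QCResult
    snr: agg.SNRResult | None
    se_opt_delta_ms: float
    se_opt_bootstrap_ms: float
    se_opt_qc_ms: float  # value the QC gate used
    n_deltas: int
    deltas: list[bt.TransitionDelta] = field(default_factory=list)


@dataclass
class SubjectReport:
    """Everything the pipeline computed for one subject."""

    channels: dict[str, ChannelReport]
    window_beats_used: int
    correction: str
    transition_agreement: agg.AgreementResult | None
    optimum_gap_ms: float

    def qc_passed(self) -> bool:
        return all(ch.qc.passed for ch in self.channels.values())


def estimate_pacing_rate(abp: np.ndarray, fs: float) -> float:
    """Pacing rate (bpm) from the dominant cardiac-band spectral peak."""
    x = np.asarray(abp, dtype=float)
    nperseg = min(x.size, int(60 * fs))
    f, p = sps.welch(x - x.mean(), fs=fs, nperseg=nperseg)
    m = (f >= CARDIAC_BAND_HZ[0]) & (f <= CARDIAC_BAND_HZ[1])
    if not m.any() or p[m].max() <= 0:
        raise ValueError("cannot estimate pacing rate: no cardiac-band peak")
    return float(f[m][np.argmax(p[m])] * 60.0)


def _effective_window(cfg: AnalysisConfig, record: HaemoRecord,
                      pacing_rate: float) -> int:
    if cfg.window_mode == "fixed_beats":
        return cfg.window_beats
    try:
        w = rc.estimate_resp_cycle_beats(record.cvp, record.sample_rate_hz,
                                         pacing_rate)
    except rc.RespirationNotDetected:
        log.info("respiration undetectable; falling back to fixed %d-beat window",
                 cfg.window_beats)
        return cfg.window_beats
    # cap so pre/post windows fit between consecutive transitions
    times = [t for t, _ in record.events]
    if len(times) >= 2:
        min_gap = min(np.diff(times))
        w_max = int(math.floor(min_gap / (60.0 / pacing_rate))) - 1
        if w < 1 or w_max < 1:
            return cfg.window_beats
        if w > w_max:
            log.info("respiratory-cycle window %d capped at %d beats", w, w_max)
            w = w_max
    return w


def _analyse_channel(
    signal: np.ndarray,
    channel: str,
    feature: str,
    record: HaemoRecord,
    cfg: AnalysisConfig,
    window: int,
    pacing_rate: float,
) -> tuple[ChannelReport, list[bt.TransitionDelta]]:
    fs = record.sample_rate_hz
    beat_times = bt.detect_beats(signal, fs, pacing_rate)
    feats = bt.beat_features(signal, beat_times, channel, fs)
    deltas = bt.transition_deltas(
        feats, record.events, window, feature=feature,
        ref_avd_ms=cfg.ref_avd_ms, use_both_directions=cfg.use_both_directions,
    )
    response = bt.aggregate_response(deltas, channel, feature)
    log.info("%s: %d beats, %d deltas, %d tested AVDs",
             channel, len(feats), len(deltas), len(response.per_avd))

    fit = None
    se_delta = math.inf
    se_boot = math.inf
    try:
        fit = opt.fit_parabola(response, weighting=cfg.weighting)
        se_delta = fit.se_opt_ms
        se_boot, discarded = opt.se_opt_bootstrap(
            response, n_boot=cfg.bootstrap_reps,
            seed=np.random.default_rng(
                [cfg.seed, {"abp": 0, "cvp": 1}[channel]]
            ).integers(2**31 - 1).item(),
            weighting=cfg.weighting,
        )
        if discarded > 0.5:
            log.info("%s: bootstrap SE unreliable (%.0f%% replicates discarded)",
                     channel, 100 * discarded)
    except opt.InsufficientSettingsError:
        pass
    # delta method is the fast default; when the two estimators disagree
    # badly the bootstrap (robust near degeneracy) feeds the QC gate
    se_qc = se_delta
    if fit is not None and np.isfinite(se_boot) and se_boot > 0:
        if abs(se_delta - se_boot) / se_boot > 0.5:
            se_qc = se_boot
    qc = opt.qc_single(fit, cfg.qc_seopt_threshold_ms, se_opt_ms=se_qc)
    snr = agg.signal_to_noise(response) if len(response.per_avd) >= 2 else None
    return ChannelReport(
        channel=channel, response=response, fit=fit, qc=qc, snr=snr,
        se_opt_delta_ms=se_delta, se_opt_bootstrap_ms=se_boot,
        se_opt_qc_ms=se_qc, n_deltas=len(deltas), deltas=deltas,
    ), deltas


def run_pipeline(cfg: AnalysisConfig, record: HaemoRecord) -> SubjectReport:
    """Run the full per-subject analysis; deterministic under ``cfg.seed``."""
    cfg.validate()
    record.validate()
    fs = record.sample_rate_hz
    pacing_rate = (cfg.pacing_rate_bpm if cfg.pacing_rate_bpm is not None
                   else estimate_pacing_rate(record.abp, fs))

    cvp_sig = record.cvp
    abp_sig = record.abp
    if cfg.correction != "none":
        est = _estimate_resp(cvp_sig, fs, cfg)
        cvp_sig = rc.subtract_resp(cvp_sig, est)
        log.info("cvp: %s removed %.0f%% of respiratory-band power",
                 cfg.correction, 100 * est.band_power_removed_frac)
        if cfg.correct_abp:
            est_a = _estimate_resp(abp_sig, fs, cfg)
            abp_sig = rc.subtract_resp(abp_sig, est_a)

    window = _effective_window(cfg, record, pacing_rate)
    abp_report, abp_deltas = _analyse_channel(
        abp_sig, "abp", "peak", record, cfg, window, pacing_rate)
    cvp_report, cvp_deltas = _analyse_channel(
        cvp_sig, "cvp", cfg.cvp_feature, record, cfg, window, pacing_rate)

    transition_agreement = None
    x, y = agg.pair_transition_deltas(abp_deltas, cvp_deltas)
    if x.size >= 5:
        transition_agreement = agg.per_transition_correlation(abp_deltas, cvp_deltas)

    gap = math.nan
    if (abp_report.fit is not None and cvp_report.fit is not None
            and not abp_report.fit.degenerate and not cvp_report.fit.degenerate):
        gap = abs(abp_report.fit.x_opt_ms - cvp_report.fit.x_opt_ms)

    return SubjectReport(
        channels={"abp": abp_report, "cvp": cvp_report},
        window_beats_used=window,
        correction=cfg.correction,
        transition_agreement=transition_agreement,
        optimum_gap_ms=gap,
    )


def _estimate_resp(signal: np.ndarray, fs: float, cfg: AnalysisConfig):
    if cfg.correction == "als":
        return rc.estimate_resp_als(signal, fs, cfg.als)
    return rc.estimate_resp_dwt(signal, fs, cfg=cfg.dwt)


def replicate_table(report: SubjectReport) -> pd.DataFrame:
    """Per-replicate delta table (one row per channel x transition)."""
    rows = []
    for ch, cr in report.channels.items():
        for d in cr.deltas:
            rows.append({
                "channel": ch,
                "feature": cr.response.feature,
                "avd_ms": d.avd_tested_ms,
                "replicate": d.replicate_index,
                "direction": d.direction,
                "delta_mmhg": d.delta_mmHg,
            })
    return pd.DataFrame(rows)


def cohort_table(reports: dict[str, SubjectReport]) -> pd.DataFrame:
    """One row per subject x channel: fit, SE_opt and QC summary."""
    rows = []
    for sid, rep in reports.items():
        for ch, cr in rep.channels.items():
            fit = cr.fit
            rows.append({
                "subject": sid,
                "channel": ch,
                "correction": rep.correction,
                "feature": cr.response.feature,
                "a": fit.a if fit else math.nan,
                "b": fit.b if fit else math.nan,
                "c": fit.c if fit else math.nan,
                "x_opt_ms": fit.x_opt_ms if fit else math.nan,
                "se_opt_ms": cr.se_opt_qc_ms,
                "se_opt_delta_ms": cr.se_opt_delta_ms,
                "se_opt_bootstrap_ms": cr.se_opt_bootstrap_ms,
                "snr": cr.snr.snr if cr.snr else math.nan,
                "qc_pass": cr.qc.passed,
                "qc_reasons": ";".join(cr.qc.reasons),
            })
    return pd.DataFrame(rows)


@dataclass
class CohortSummary:
    """Cohort-level comparison statistics."""

    seopt_vs_gap: agg.AgreementResult | None
    optima_agreement: agg.AgreementResult | None
    median_snr_abp: float
    median_snr_cvp: float
    n_subjects: int
    n_qc_passed: int


def analyze_cohort(reports: dict[str, SubjectReport],
                   qc_only_agreement: bool = True) -> CohortSummary:
    """Aggregate subject reports into the between-channel statistics.

    The SE_opt-vs-discrepancy correlation uses every subject with two
    valid fits (each subject's SE_opt is the mean of its two channels');
    the Bland–Altman optima agreement uses QC-passing subjects when
    ``qc_only_agreement`` is set.
    """
    se_gap_pairs = []
    opt_abp, opt_cvp = [], []
    snr_abp, snr_cvp = [], []
    n_pass = 0
    for rep in reports.values():
        a, c = rep.channels["abp"], rep.channels["cvp"]
        if a.snr:
            snr_abp.append(a.snr.snr)
        if c.snr:
            snr_cvp.append(c.snr.snr)
        if not math.isnan(rep.optimum_gap_ms):
            se = 0.5 * (a.se_opt_qc_ms + c.se_opt_qc_ms)
            if math.isfinite(se):
                se_gap_pairs.append((se, rep.optimum_gap_ms))
        if rep.qc_passed():
            n_pass += 1
        if (not qc_only_agreement or rep.qc_passed()) and not math.isnan(rep.optimum_gap_ms):
            opt_abp.append(a.fit.x_opt_ms)
            opt_cvp.append(c.fit.x_opt_ms)
    seopt_vs_gap = (agg.seopt_vs_discrepancy(se_gap_pairs)
                    if len(se_gap_pairs) >= 5 else None)
    optima = (agg.bland_altman(opt_abp, opt_cvp)
              if len(opt_abp) >= 3 else None)
    return CohortSummary(
        seopt_vs_gap=seopt_vs_gap,
        optima_agreement=optima,
        median_snr_abp=float(np.median(snr_abp)) if snr_abp else math.nan,
        median_snr_cvp=float(np.median(snr_cvp)) if snr_cvp else math.nan,
        n_subjects=len(reports),
        n_qc_passed=n_pass,
    )
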