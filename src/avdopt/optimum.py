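"""Parabolic optimum estimation with uncertainty, and quality control.

The pressure response to AVD is modelled as ``y = a x^2 + b x + c``; the
haemodynamic optimum is the vertex ``x_opt = -b / (2a)``.  Horizontal
uncertainty (SE_opt) is obtained from the vertical replicate noise in
two ways: first-order (delta-method) propagation of the (a, b)
coefficient covariance through the vertex formula, and a parametric
bootstrap that resamples each per-AVD mean from Normal(mean, SEM) and
refits.  Quality control rejects fits that open the physiologically
wrong way (arterial response must be concave, venous convex) or whose
SE_opt exceeds a threshold (default 50 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beats import AVDResponse

__all__ = [
    "ParabolaFit",
    "QCResult",
    "InsufficientSettingsError",
    "fit_parabola",
    "se_opt_delta",
    "se_opt_bootstrap",
    "qc_check",
    "qc_single",
    "DEGENERACY_TOL",
    "DEFAULT_SEOPT_THRESHOLD_MS",
]

DEGENERACY_TOL = 1e-12          # |a| below this (mmHg/ms^2) => no usable vertex
DEFAULT_SEOPT_THRESHOLD_MS = 50.0
EXTRAPOLATION_MARGIN_MS = 40.0  # vertex beyond tested range +/- this => flagged


class InsufficientSettingsError(ValueError):
    """Fewer than 3 distinct tested AVDs: the parabola is underdetermined."""


@dataclass
class ParabolaFit:
    """Quadratic fit of mean pressure change versus tested AVD."""

    a: float                    # mmHg/ms^2
    b: float                    # mmHg/ms
    c: float                    # mmHg
    cov_abc: np.ndarray         # 3x3 coefficient covariance (a, b, c order)
    x_opt_ms: float
    se_opt_ms: float
    channel: str
    orientation_ok: bool
    degenerate: bool
    extrapolated: bool


@dataclass
class QCResult:
    """Quality-gate verdict; ``passed`` iff ``reasons`` is empty."""

    passed: bool
    reasons: list[str] = field(default_factory=list)


def _orientation_ok(a: float, channel: str) -> bool:
    # Arterial response is maximised (concave, a < 0); venous response is
    # its mirror image, minimised at the optimum (convex, a > 0).
    if channel == "abp":
        return a < 0
    if channel == "cvp":
        return a > 0
    raise ValueError(f"unknown channel {channel!r}")


def _weights(sems: np.ndarray, weighting: str) -> np.ndarray | None:
    if weighting == "unweighted":
        return None
    if weighting != "inverse_variance":
        raise ValueError(f"unknown weighting {weighting!r}")
    sems = np.asarray(sems, dtype=float)
    if np.all(sems == 0):
        return None  # no variance information: fall back to unweighted
    s = sems.copy()
    s[s == 0] = s[s > 0].min()  # zero-SEM points get the smallest nonzero SEM
    return 1.0 / s**2


def fit_parabola(
    resp: AVDResponse, weighting: str = "inverse_variance"
) -> ParabolaFit:
    """(Weighted) least-squares quadratic fit of the per-AVD response.

    With inverse-variance weighting the SEMs are treated as known
    standard deviations of the per-AVD means, so the coefficient
    covariance is the inverse of the weighted normal matrix.  Unweighted
    fits estimate the residual variance from the fit (df = n - 3).
    """
    x = resp.avds.astype(float)
    y = resp.means.astype(float)
    if np.unique(x).size < 3:
        raise InsufficientSettingsError(
            f"only {np.unique(x).size} distinct tested AVDs; need >= 3"
        )
    w = _weights(resp.sems, weighting)
    X = np.column_stack([x**2, x, np.ones_like(x)])
    if w is None:
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        XtX_inv = np.linalg.inv(X.T @ X)
        dof = x.size - 3
        resid = y - X @ coef
        sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
        cov = sigma2 * XtX_inv
    else:
        XtW = X.T * w
        A = XtW @ X
        coef = np.linalg.solve(A, XtW @ y)
        cov = np.linalg.inv(A)
    a, b, c = (float(v) for v in coef)
    degenerate = abs(a) < DEGENERACY_TOL
    if degenerate:
        x_opt, se = np.nan, np.inf
    else:
        x_opt = -b / (2.0 * a)
        se = _delta_se(a, b, cov)
    lo, hi = x.min() - EXTRAPOLATION_MARGIN_MS, x.max() + EXTRAPOLATION_MARGIN_MS
    return ParabolaFit(
        a=a, b=b, c=c, cov_abc=cov, x_opt_ms=float(x_opt), se_opt_ms=float(se),
        channel=resp.channel,
        orientation_ok=(not degenerate) and _orientation_ok(a, resp.channel),
        degenerate=degenerate,
        extrapolated=(not degenerate) and not (lo <= x_opt <= hi),
    )


def _delta_se(a: float, b: float, cov: np.ndarray) -> float:
    # gradient of x_opt = -b/(2a) w.r.t. (a, b)
    g = np.array([b / (2.0 * a**2), -1.0 / (2.0 * a)])
    var = float(g @ cov[:2, :2] @ g)
    return np.sqrt(max(var, 0.0))


def se_opt_delta(fit: ParabolaFit) -> float:
    """First-order (delta-method) SE of the vertex; inf when degenerate."""
    if fit.degenerate:
        return np.inf
    return _delta_se(fit.a, fit.b, fit.cov_abc)


def se_opt_bootstrap(
    resp: AVDResponse,
    n_boot: int = 1000,
    seed: int = 0,
    weighting: str = "inverse_variance",
) -> tuple[float, float]:
    """Parametric bootstrap SE of the vertex.

    Resamples each per-AVD mean from Normal(mean, SEM), refits, and takes
    the SD of the vertices over replicates that yield a correctly
    oriented, non-degenerate fit.  Returns ``(se_ms, discarded_frac)``;
    the SE is NaN-flagged unreliable when more than half the replicates
    are discarded.
    """
    x = resp.avds.astype(float)
    y = resp.means.astype(float)
    sems = resp.sems.astype(float)
    if np.unique(x).size < 3:
        raise InsufficientSettingsError(
            f"only {np.unique(x).size} distinct tested AVDs; need >= 3"
        )
    if np.all(sems == 0):
        return 0.0, 0.0
    w = _weights(sems, weighting)
    X = np.column_stack([x**2, x, np.ones_like(x)])
    if w is None:
        P = np.linalg.pinv(X)
    else:
        XtW = X.T * w
        P = np.linalg.solve(XtW @ X, XtW)
    rng = np.random.default_rng(seed)
    Y = rng.normal(y, sems, size=(n_boot, x.size))
    coefs = P @ Y.T                                   # (3, n_boot)
    a, b = coefs[0], coefs[1]
    ok = np.abs(a) >= DEGENERACY_TOL
    if resp.channel == "abp":
        ok &= a < 0
    elif resp.channel == "cvp":
        ok &= a > 0
    discarded = 1.0 - ok.mean()
    if ok.sum() < 2 or discarded > 0.5:
        return np.nan, float(discarded)
    vertices = -b[ok] / (2.0 * a[ok])
    return float(vertices.std(ddof=1)), float(discarded)


def qc_single(
    fit: ParabolaFit | None,
    threshold_ms: float = DEFAULT_SEOPT_THRESHOLD_MS,
    se_opt_ms: float | None = None,
) -> QCResult:
    """Apply the two quality-control tests to one fit.

    Pass requires the physiologically correct orientation and
    SE_opt strictly below the threshold.  ``se_opt_ms`` overrides the
    fit's own (delta-method) SE, e.g. with the bootstrap value.
    """
    if fit is None:
        return QCResult(passed=False, reasons=["insufficient_settings"])
    reasons = []
    if fit.degenerate:
        reasons.append("degenerate_fit")
    elif not fit.orientation_ok:
        reasons.append("wrong_orientation")
    se = fit.se_opt_ms if se_opt_ms is None else se_opt_ms
    if not fit.degenerate and not (se < threshold_ms):
        reasons.append("seopt_exceeds_threshold")
    return QCResult(passed=not reasons, reasons=reasons)


def qc_check(
    fit_abp: ParabolaFit | None,
    fit_cvp: ParabolaFit | None,
    threshold_ms: float = DEFAULT_SEOPT_THRESHOLD_MS,
) -> dict[str, QCResult]:
    """Quality-control verdict per channel (never raises)."""
    return {
        "abp": qc_single(fit_abp, threshold_ms),
        "cvp": qc_single(fit_cvp, threshold_ms),
    }
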