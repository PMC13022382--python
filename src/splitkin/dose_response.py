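"""Half-maximal complementing concentration (EC50) inference.

Per-concentration labeling rates (apparent second-order rate constants or
initial slopes) are aggregated into a dose-response curve with Hill slope
fixed at 1. Two equivalent parameterizations are supported:

* ``log_sigmoid``:  rate([P]) = k_max / (1 + 10**(log10 EC50 - log10 [P]))
  with the lower asymptote fixed at 0;
* ``hyperbolic``:   rate = Bottom + [P] * (Top - Bottom) / (EC50 + [P]).

With Bottom = 0 the two are algebraically identical. EC50 is fitted on the
log10 scale to keep it positive and to stabilize the optimizer.

Confidence intervals come from parametric Monte Carlo resampling: synthetic
datasets are drawn as Gaussian noise around the fitted curve (scale = the
fit's residual standard deviation, or the per-point rate uncertainty when
given), each is refit, the configurable worst fraction by refit SSE is
discarded, and the 2.5th/97.5th percentiles of the surviving EC50 estimates
form the 95% interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "DoseResponsePoint",
    "DoseResponseFit",
    "fit_ec50",
    "monte_carlo_ci",
    "fold_change",
    "round_fold",
]

log = logging.getLogger(__name__)


@dataclass
class DoseResponsePoint:
    """One peptide concentration with its measured labeling rate."""

    hpep_conc: float  # M
    rate: float  # k_app (M^-1 s^-1) or initial slope (mP/s)
    rate_sd: float = 0.0
    ordinate_kind: str = "k_app"  # "k_app" | "slope"

    def __post_init__(self) -> None:
        if self.hpep_conc <= 0:
            raise ValueError("hpep_conc must be positive")


@dataclass
class DoseResponseFit:
    """Fitted dose-response curve with optional Monte Carlo interval."""

    ec50: float  # M
    k_max: float  # upper asymptote (Top)
    bottom: float  # lower asymptote (0 for the log_sigmoid form)
    form: str
    sse: float
    converged: bool
    ordinate_kind: str = "k_app"
    extrapolated: bool = False  # EC50 > 10x outside the tested range
    ec50_ci_low: float | None = None
    ec50_ci_high: float | None = None
    mc_samples: np.ndarray | None = None
    n_mc: int = 0
    discard_frac: float = 0.0

    def predict(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.bottom + conc * (self.k_max - self.bottom) / (self.ec50 + conc)


def _profiled_sse(logec: float, x: np.ndarray, y: np.ndarray, form: str) -> tuple[float, float, float]:
    """SSE at a fixed log10(EC50) with the asymptotes solved linearly.

    With Hill slope 1 the model is linear in (Top, Bottom) given EC50:
    y = Bottom * (1 - w) + Top * w, w = x / (EC50 + x); profiling them out
    leaves a one-dimensional problem in log10(EC50).
    """
    w = x / (10.0**logec + x)
    if form == "log_sigmoid":
        denom = float(w @ w)
        top = float(w @ y) / denom if denom > 0 else 0.0
        r = top * w - y
        return float(r @ r), top, 0.0
    a = np.column_stack([w, 1.0 - w])
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    r = a @ coef - y
    return float(r @ r), float(coef[0]), float(coef[1])


def _fit_core(
    x: np.ndarray, y: np.ndarray, form: str, x0: np.ndarray | None = None
) -> tuple[float, float, float, float, bool]:
    """Least-squares core shared by fit_ec50 and the Monte Carlo refits.

    One-dimensional bounded minimization over log10(EC50) (the asymptote
    parameters are profiled out analytically). Returns
    (ec50, top, bottom, sse, converged). ``x0`` is accepted for interface
    symmetry with multi-parameter optimizers but is not needed.
    """
    if form not in ("log_sigmoid", "hyperbolic"):
        raise ValueError(f"unknown form {form!r}")
    logx = np.log10(x)
    lo, hi = float(logx.min()) - 3.0, float(logx.max()) + 3.0
    sol = minimize_scalar(
        lambda le: _profiled_sse(le, x, y, form)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    logec = float(sol.x)
    sse, top, bottom = _profiled_sse(logec, x, y, form)
    return float(10.0**logec), top, bottom, sse, bool(sol.success)


def fit_ec50(points: list[DoseResponsePoint], form: str = "log_sigmoid") -> DoseResponseFit:
    """Fit the EC50 dose-response curve (Hill slope fixed at 1).

    Raises on non-identifiable (all-equal) rates and on mixed ordinate kinds;
    flags ``extrapolated`` when the fitted EC50 falls more than tenfold
    outside the tested concentration range.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 dose-response points")
    kinds = {p.ordinate_kind for p in points}
    if len(kinds) > 1:
        raise ValueError(f"mixed ordinate kinds in one dataset: {sorted(kinds)}")
    x = np.array([p.hpep_conc for p in points], dtype=float)
    y = np.array([p.rate for p in points], dtype=float)
    if np.ptp(y) < 1e-12 * max(abs(float(np.mean(y))), 1e-300) or np.ptp(y) == 0.0:
        raise ValueError("all rates equal: EC50 is not identifiable")
    ec50, top, bottom, sse, ok = _fit_core(x, y, form)
    extrapolated = bool(ec50 < np.min(x) / 10.0 or ec50 > np.max(x) * 10.0)
    fit = DoseResponseFit(
        ec50=ec50, k_max=top, bottom=bottom, form=form, sse=sse,
        converged=ok, ordinate_kind=kinds.pop(), extrapolated=extrapolated,
    )
    log.info("EC50 fit (%s): ec50=%.6g k_max=%.6g bottom=%.4g sse=%.4g converged=%s",
             form, ec50, top, bottom, sse, ok)
    return fit


def monte_carlo_ci(
    fit: DoseResponseFit,
    points: list[DoseResponsePoint],
    n: int = 1000,
    discard_frac: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Parametric Monte Carlo 95% confidence interval for EC50.

    Draws ``n`` synthetic datasets around the fitted curve, refits each,
    drops the ``discard_frac`` worst refits by SSE and takes the 2.5th and
    97.5th percentiles of the surviving EC50 estimates. The per-point noise
    scale is the point's ``rate_sd`` when every point provides one, else the
    residual standard deviation of the original fit. Deterministic under
    ``seed``. The interval and retained samples are stored on ``fit``.
    """
    if not fit.converged:
        raise ValueError("cannot bootstrap a non-converged fit")
    x = np.array([p.hpep_conc for p in points], dtype=float)
    y = np.array([p.rate for p in points], dtype=float)
    yhat = fit.predict(x)
    sds = np.array([p.rate_sd for p in points], dtype=float)
    if np.all(sds > 0):
        scale = sds
    else:
        dof = max(len(x) - (2 if fit.form == "log_sigmoid" else 3), 1)
        scale = np.full_like(x, np.sqrt(np.sum((y - yhat) ** 2) / dof))
    rng = np.random.default_rng(seed)
    x0 = (
        np.array([fit.k_max, np.log10(fit.ec50)])
        if fit.form == "log_sigmoid"
        else np.array([fit.k_max, fit.bottom, np.log10(fit.ec50)])
    )
    ec50s = np.empty(n)
    sses = np.empty(n)
    failures = 0
    for i in range(n):
        ysim = yhat + rng.normal(0.0, scale)
        try:
            ec, _, _, sse, ok = _fit_core(x, ysim, fit.form, x0=x0)
        except Exception:
            ok = False
        if not ok:
            failures += 1
            ec, sse = np.nan, np.inf
        ec50s[i], sses[i] = ec, sse
    if failures > 0.2 * n:
        raise RuntimeError(f"Monte Carlo unstable: {failures}/{n} refits failed")
    keep = np.argsort(sses)[: int(np.ceil(n * (1.0 - discard_frac)))]
    kept = ec50s[keep]
    kept = kept[np.isfinite(kept)]
    low, high = (float(v) for v in np.percentile(kept, [2.5, 97.5]))
    fit.ec50_ci_low, fit.ec50_ci_high = low, high
    fit.mc_samples = kept
    fit.n_mc = n
    fit.discard_frac = discard_frac
    log.info("Monte Carlo CI: [%.6g, %.6g] from %d/%d retained refits", low, high, len(kept), n)
    return low, high


def fold_change(ec50_ref: float, ec50_new: float) -> float:
    """Ratio of a reference EC50 (or K_d) over a new one; >1 means tighter."""
    if ec50_ref <= 0 or ec50_new <= 0:
        raise ValueError("EC50 values must be positive")
    return ec50_ref / ec50_new


def round_fold(fold: float) -> int:
    """Reporting helper: round a fold change to the nearest integer fold."""
    return int(round(fold))
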