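"""Fitting of covalent labeling time courses followed by fluorescence polarization.

The labeling reaction between a chloroalkane-dye substrate A (initial
concentration ``a0``) and a reconstituted self-labeling protein B (``b0``)
is an irreversible bimolecular reaction A + B -> AB with apparent
second-order rate constant ``k_app``. With unequal starting concentrations
the remaining free substrate is

    [A](t) = a0 * (a0 - b0) / (a0 - b0 * exp(-(a0 - b0) * k_app * t))

and the polarization signal interpolates between the anisotropy of free and
bound dye in proportion to the labeled fraction:

    FP(t) = FP_bound + (FP_free - FP_bound) * [A](t) / a0

When a0 == b0 the expression degenerates to the analytic limit
FP(t) = FP_bound + (FP_free - FP_bound) / (1 + a0 * k_app * t).

Instruments introduce a dead time between mixing and the first recorded
point; it is handled as a fixed, configurable offset added to all recorded
times (a freely fitted offset is weakly identified against k_app).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TimeCourse",
    "KineticFit",
    "BackgroundFit",
    "second_order_fp",
    "fit_second_order",
    "choose_model",
    "initial_slope",
    "fit_timecourse",
    "fit_background",
    "DEFAULT_DEAD_TIME",
    "PLATEAU_THRESHOLD",
    "EQUAL_CONC_RTOL",
]

log = logging.getLogger(__name__)

#: Default mixing-to-first-read delay, seconds.
DEFAULT_DEAD_TIME = 30.0
#: Predicted reaction completion at the last point below which the trace is
#: treated as pre-plateau and fitted linearly (inclusive at the boundary:
#: completion == threshold keeps the second-order model).
PLATEAU_THRESHOLD = 0.20
#: Relative |a0 - b0| below which the equal-concentration limit form is used.
EQUAL_CONC_RTOL = 1e-6


@dataclass
class TimeCourse:
    """One labeling reaction: replicate-averaged FP versus time.

    ``a0`` is the dye substrate concentration at mixing, ``b0`` the protein
    concentration, ``condition`` the peptide concentration of this well (all
    molar). ``fp_sd`` optionally carries the per-time replicate spread.
    """

    t: np.ndarray
    fp: np.ndarray
    a0: float
    b0: float
    condition: float = 0.0
    fp_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.fp = np.asarray(self.fp, dtype=float)
        if self.t.shape != self.fp.shape:
            raise ValueError("t and fp must have the same length")
        if np.any(self.t < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.a0 <= 0 or self.b0 <= 0:
            raise ValueError("a0 and b0 must be positive")


@dataclass
class KineticFit:
    """Fitted labeling model for one time course."""

    model: str  # "second_order" | "linear"
    k_app: float | None  # M^-1 s^-1; None for the linear fallback
    fp_free: float
    fp_bound: float
    slope0: float  # mP/s, d(FP)/dt at reaction start
    dead_time: float
    sse: float
    converged: bool
    completion: float = float("nan")  # predicted labeled fraction at t_end


@dataclass
class BackgroundFit:
    """One-phase (pseudo-first-order) association fit of background labeling."""

    k_obs: float  # s^-1
    t_half: float  # seconds, ln(2)/k_obs
    plateau: float
    y0: float
    sse: float = 0.0
    converged: bool = True


def second_order_fp(
    t: np.ndarray,
    k_app: float,
    fp_free: float,
    fp_bound: float,
    a0: float,
    b0: float,
) -> np.ndarray:
    """Evaluate the second-order labeling FP model.

    Numerically stable for either sign of a0 - b0 (the growing exponential is
    rewritten as a decaying one) and switches to the analytic equal-
    concentration limit when |a0 - b0| / a0 < EQUAL_CONC_RTOL.
    """
    t = np.asarray(t, dtype=float)
    d = a0 - b0
    if abs(d) < EQUAL_CONC_RTOL * a0:
        frac_free = 1.0 / (1.0 + a0 * k_app * t)
    elif d < 0:
        # exponent d*k*t <= 0: direct form is stable
        e = np.exp(d * k_app * t)
        frac_free = d * e / (a0 * e - b0)
    else:
        # divide through by exp(d*k*t) so the exponential decays
        e = np.exp(-d * k_app * t)
        frac_free = d / (a0 - b0 * e)
    return fp_bound + (fp_free - fp_bound) * frac_free


def _completion(k_app: float, t_end: float, a0: float, b0: float) -> float:
    """Labeled fraction of the limiting reagent predicted at t_end."""
    fp = second_order_fp(np.array([t_end]), k_app, 0.0, 1.0, a0, b0)[0]
    # with fp_free=0, fp_bound=1 the model value *is* the consumed-A fraction
    cap = min(a0, b0) / a0  # fraction of A that can ever react
    return float(fp / cap) if cap > 0 else float("nan")


def fit_second_order(tc: TimeCourse, dead_time: float = DEFAULT_DEAD_TIME) -> KineticFit:
    """Nonlinear least squares of (k_app, FP_free, FP_bound).

    The model is evaluated at ``t + dead_time`` to account for the delay
    between substrate addition and the first recorded point. k_app is fitted
    as log10(k_app) after a coarse log-grid scan (1e2-1e7) for the start
    value; FP_free/FP_bound start from the first/last observations.
    """
    if len(tc.t) < 5:
        raise ValueError("need at least 5 time points for a second-order fit")
    t = tc.t + dead_time
    y = tc.fp
    f0, f1 = float(y[0]), float(y[-1])
    if abs(f1 - f0) < 1e-12:
        f1 = f0 + 1.0  # degenerate constant trace; keep the fit well posed

    def resid(p: np.ndarray) -> np.ndarray:
        logk, ffree, fbound = p
        return second_order_fp(t, 10.0**logk, ffree, fbound, tc.a0, tc.b0) - y

    grid = np.linspace(2.0, 7.0, 11)
    sses = [float(np.sum(resid(np.array([g, f0, f1])) ** 2)) for g in grid]
    logk0 = float(grid[int(np.argmin(sses))])

    sol = least_squares(
        resid,
        x0=np.array([logk0, f0, f1]),
        bounds=([-3.0, -np.inf, -np.inf], [10.0, np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    logk, fp_free, fp_bound = sol.x
    k_app = float(10.0**logk)
    sse = float(np.sum(sol.fun**2))
    slope0 = k_app * tc.b0 * (fp_bound - fp_free)
    fit = KineticFit(
        model="second_order",
        k_app=k_app,
        fp_free=float(fp_free),
        fp_bound=float(fp_bound),
        slope0=float(slope0),
        dead_time=dead_time,
        sse=sse,
        converged=bool(sol.success),
        completion=_completion(k_app, float(t[-1]), tc.a0, tc.b0),
    )
    log.info(
        "second-order fit: k_app=%.6g fp_free=%.4g fp_bound=%.4g sse=%.4g converged=%s",
        k_app, fp_free, fp_bound, sse, sol.success,
    )
    return fit


def choose_model(tc: TimeCourse, fit: KineticFit) -> str:
    """Pick the reporting model for a fitted trace.

    Traces whose predicted reaction completion at the final time point is
    below PLATEAU_THRESHOLD (exclusive), or whose second-order fit failed to
    converge, are reported with the linear model; otherwise second-order.
    """
    if not fit.converged:
        return "linear"
    if np.isnan(fit.completion) or fit.completion >= PLATEAU_THRESHOLD:
        return "second_order"
    return "linear"


def _fit_linear(tc: TimeCourse, dead_time: float) -> KineticFit:
    slope, intercept = np.polyfit(tc.t + dead_time, tc.fp, 1)
    pred = slope * (tc.t + dead_time) + intercept
    return KineticFit(
        model="linear",
        k_app=None,
        fp_free=float(intercept),
        fp_bound=float("nan"),
        slope0=float(slope),
        dead_time=dead_time,
        sse=float(np.sum((pred - tc.fp) ** 2)),
        converged=True,
    )


def fit_timecourse(tc: TimeCourse, dead_time: float = DEFAULT_DEAD_TIME) -> KineticFit:
    """Fit the second-order model and fall back to a line pre-plateau."""
    fit = fit_second_order(tc, dead_time=dead_time)
    if choose_model(tc, fit) == "linear":
        return _fit_linear(tc, dead_time)
    return fit


def initial_slope(fit: KineticFit, tc: TimeCourse) -> float:
    """Labeling speed at reaction start, mP/s.

    For the second-order model this is the analytic derivative at t = 0,
    k_app * b0 * (FP_bound - FP_free); for the linear fallback it is the
    fitted line slope.
    """
    if fit.model == "linear":
        return fit.slope0
    assert fit.k_app is not None
    return fit.k_app * tc.b0 * (fit.fp_bound - fit.fp_free)


def fit_background(tc: TimeCourse) -> BackgroundFit:
    """Fit the one-phase association model of residual (peptide-free) labeling.

    y(t) = y0 + (plateau - y0) * (1 - exp(-k_obs t)); the labeling half-time
    is t_1/2 = ln(2)/k_obs. A k_obs estimate at the numerical floor flags the
    fit as non-converged (no measurable reaction).
    """
    if len(tc.t) < 5:
        raise ValueError("need at least 5 time points")
    t, y = tc.t, tc.fp
    y0_0, plateau_0 = float(y[0]), float(y[-1])
    span = max(abs(plateau_0 - y0_0), 1e-9)
    k0 = 1.0 / max(t[-1], 1.0)

    def resid(p: np.ndarray) -> np.ndarray:
        y0, plateau, logk = p
        return y0 + (plateau - y0) * (1.0 - np.exp(-(10.0**logk) * t)) - y

    sol = least_squares(
        resid,
        x0=np.array([y0_0, plateau_0 + 0.05 * span, np.log10(k0)]),
        bounds=([-np.inf, -np.inf, -12.0], [np.inf, np.inf, 2.0]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    y0, plateau, logk = sol.x
    k_obs = float(10.0**logk)
    degenerate = logk <= -11.5 or abs(plateau - y0) < 1e-9 * max(float(np.max(np.abs(y))), 1.0)
    fit = BackgroundFit(
        k_obs=k_obs,
        t_half=float(np.log(2.0) / k_obs) if k_obs > 0 else float("inf"),
        plateau=float(plateau),
        y0=float(y0),
        sse=float(np.sum(sol.fun**2)),
        converged=bool(sol.success) and not degenerate,
    )
    log.info("background fit: k_obs=%.6g t_half=%.6g converged=%s", fit.k_obs, fit.t_half, fit.converged)
    return fit
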