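"""Equilibrium and kinetic binding-affinity inference.

Equilibrium: a fluorescent tracer is titrated against the binding partner
and polarization follows the single-site isotherm
FP(c) = bottom + (top - bottom) * c / (Kd + c) (Hill slope 1); with the
tracer far below the titrated species, free ~= total concentration and the
half-saturation point is Kd.

Kinetic: bio-layer interferometry sensorgrams at several analyte
concentrations are baseline-aligned, smoothed with a Savitzky-Golay filter
and fitted globally to the 1:1 Langmuir model with shared (kon, koff, Rmax)
and a per-trace offset nuisance; Kd = koff / kon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from .io import AssayTable

__all__ = [
    "SaturationFit",
    "Sensorgram",
    "BLIFit",
    "fit_saturation_kd",
    "sensorgrams_from_table",
    "bli_preprocess",
    "bli_global_fit",
]

log = logging.getLogger(__name__)


@dataclass
class SaturationFit:
    """Single-site equilibrium binding fit."""

    kd: float  # M
    top: float  # mP
    bottom: float  # mP
    sse: float
    converged: bool
    inverted: bool = False  # bottom >= top (signal decreases with binding)
    extrapolated: bool = False  # Kd > 10x outside the titrated range
    ci: tuple[float, float] | None = None


@dataclass
class Sensorgram:
    """One BLI trace: response versus time with per-point phase labels."""

    conc: float  # M analyte
    t: np.ndarray
    r: np.ndarray
    phases: np.ndarray  # "baseline" | "association" | "dissociation"
    t_assoc_end: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.phases = np.asarray(self.phases)
        order = {"baseline": 0, "association": 1, "dissociation": 2}
        codes = np.array([order[p] for p in self.phases])
        if np.any(np.diff(codes) < 0):
            raise ValueError("phases must be ordered baseline < association < dissociation")

    def phase(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.phases == name
        return self.t[m], self.r[m]


@dataclass
class BLIFit:
    """Globally fitted 1:1 kinetic binding parameters."""

    kon: float  # M^-1 s^-1
    koff: float  # s^-1
    kd: float  # M, koff/kon
    rmax: float
    offsets: list[float]
    sse: float
    converged: bool
    koff_at_bound: bool = False  # slow-dissociator warning


def fit_saturation_kd(table: AssayTable) -> SaturationFit:
    """Fit the saturation isotherm (three parameters, Hill slope 1)."""
    if table.kind != "saturation":
        raise ValueError("expected a saturation-kind assay table")
    c = table.data["condition"].to_numpy(float)
    y = table.data["value"].to_numpy(float)
    if len(np.unique(c)) < 6:
        raise ValueError("need at least 6 distinct concentrations")
    top0, bot0 = float(y[np.argmax(c)]), float(y[np.argmin(c)])
    logkd0 = float(np.log10(np.median(c)))

    def resid(p: np.ndarray) -> np.ndarray:
        top, bot, logkd = p
        kd = 10.0**logkd
        return bot + (top - bot) * c / (kd + c) - y

    sol = least_squares(resid, np.array([top0, bot0, logkd0]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, method="lm")
    top, bottom, logkd = sol.x
    kd = float(10.0**logkd)
    fit = SaturationFit(
        kd=kd, top=float(top), bottom=float(bottom),
        sse=float(np.sum(sol.fun**2)), converged=bool(sol.success),
        inverted=bool(bottom >= top),
        extrapolated=bool(kd < c.min() / 10.0 or kd > c.max() * 10.0),
    )
    log.info("saturation fit: kd=%.6g top=%.4g bottom=%.4g converged=%s",
             fit.kd, fit.top, fit.bottom, fit.converged)
    return fit


def sensorgrams_from_table(table: AssayTable) -> list[Sensorgram]:
    """Split a sensorgram assay table into per-trace objects."""
    if table.kind != "sensorgram":
        raise ValueError("expected a sensorgram-kind assay table")
    if "phase" not in table.data.columns:
        raise ValueError("sensorgram table needs a phase column")
    out = []
    for sid in table.series_ids():
        sub = table.series(sid)
        t = sub["time"].to_numpy(float)
        phases = sub["phase"].to_numpy()
        assoc = phases == "association"
        if not assoc.any():
            raise ValueError(f"trace {sid!r} has no association phase")
        dissoc = phases == "dissociation"
        # the phase boundary is the first dissociation sample (the
        # association ends where dissociation recording starts)
        t_assoc_end = float(t[dissoc].min()) if dissoc.any() else float(t[assoc].max())
        out.append(
            Sensorgram(
                conc=float(sub["condition"].iloc[0]),
                t=t,
                r=sub["value"].to_numpy(float),
                phases=phases,
                t_assoc_end=t_assoc_end,
            )
        )
    return out


def bli_preprocess(sg: Sensorgram, sg_window: int = 11, sg_order: int = 2,
                   smooth: bool = True) -> Sensorgram:
    """Baseline-align and Savitzky-Golay smooth one trace.

    The mean of the baseline phase is subtracted from the whole trace (an
    idempotent operation), then the filter removes high-frequency noise.
    Phase labels are preserved.
    """
    tb, rb = sg.phase("baseline")
    if len(rb) < 5:
        raise ValueError("baseline phase needs at least 5 points")
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise ValueError("Savitzky-Golay window must be odd and exceed the order")
    if sg_window >= len(sg.r):
        raise ValueError("Savitzky-Golay window must be shorter than the trace")
    r = sg.r - rb.mean()
    if smooth:
        r = savgol_filter(r, sg_window, sg_order)
    return replace(sg, r=r)


def _bli_model(
    sgs: list[Sensorgram], kon: float, koff: float, rmax: float, offsets: np.ndarray
) -> list[np.ndarray]:
    kd = koff / kon
    out = []
    for sg, off in zip(sgs, offsets):
        t0 = sg.t[sg.phases == "association"].min()
        tt = sg.t - t0
        req = rmax * sg.conc / (kd + sg.conc)
        kobs = kon * sg.conc + koff
        assoc = req * (1.0 - np.exp(-kobs * np.clip(tt, 0.0, None)))
        t_end = sg.t_assoc_end - t0
        r_end = req * (1.0 - np.exp(-kobs * t_end))
        pred = np.where(tt <= t_end, assoc, r_end * np.exp(-koff * (tt - t_end)))
        pred = np.where(tt < 0, 0.0, pred)  # baseline sits at the offset
        out.append(pred + off)
    return out


def bli_global_fit(sgs: list[Sensorgram], fit_offsets: bool = True) -> BLIFit:
    """Simultaneous 1:1 fit across all traces.

    Shares (kon, koff, Rmax) across traces; each trace contributes an
    additive offset nuisance that absorbs immobilization differences. Rates
    are fitted on the log10 scale from a small multi-start grid. A koff
    estimate at its lower bound is flagged (slow-dissociator regime: the
    dissociation window carries little decay information).
    """
    if len(sgs) < 3:
        raise ValueError("global fit needs at least 3 analyte concentrations")
    y = np.concatenate([sg.r for sg in sgs])
    rmax0 = float(max(np.max(sg.r) for sg in sgs)) * 1.2
    n_off = len(sgs) if fit_offsets else 0

    def resid(p: np.ndarray) -> np.ndarray:
        logkon, logkoff, rmax = p[:3]
        offsets = p[3:] if fit_offsets else np.zeros(len(sgs))
        preds = _bli_model(sgs, 10.0**logkon, 10.0**logkoff, rmax, offsets)
        return np.concatenate(preds) - y

    lo = np.concatenate(([1.0, -7.0, 1e-6], np.full(n_off, -np.inf)))
    hi = np.concatenate(([9.0, 1.0, np.inf], np.full(n_off, np.inf)))
    best = None
    for logkon0 in (4.0, 5.0, 6.0):
        for logkoff0 in (-4.0, -3.0, -2.0):
            x0 = np.concatenate(([logkon0, logkoff0, rmax0], np.zeros(n_off)))
            sol = least_squares(resid, x0, bounds=(lo, hi),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if best is None or sol.cost < best.cost:
                best = sol
    assert best is not None
    logkon, logkoff, rmax = best.x[:3]
    kon, koff = float(10.0**logkon), float(10.0**logkoff)
    fit = BLIFit(
        kon=kon,
        koff=koff,
        kd=koff / kon,
        rmax=float(rmax),
        offsets=[float(v) for v in (best.x[3:] if fit_offsets else np.zeros(len(sgs)))],
        sse=float(np.sum(best.fun**2)),
        converged=bool(best.success),
        koff_at_bound=bool(logkoff < -6.9),
    )
    log.info("BLI global fit: kon=%.6g koff=%.6g kd=%.6g rmax=%.4g converged=%s",
             fit.kon, fit.koff, fit.kd, fit.rmax, fit.converged)
    return fit
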