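"""End-to-end convenience: per-concentration kinetic fits to an EC50 estimate."""

from __future__ import annotations

import logging

from .dose_response import DoseResponseFit, DoseResponsePoint, fit_ec50, monte_carlo_ci
from .io import AssayTable
from .kinetics import DEFAULT_DEAD_TIME, TimeCourse, fit_timecourse, initial_slope

__all__ = ["timecourses_from_table", "rates_from_table", "ec50_pipeline"]

log = logging.getLogger(__name__)


def timecourses_from_table(table: AssayTable) -> list[TimeCourse]:
    """Split a multi-concentration labeling table into per-series traces.

    Reagent concentrations (a0, b0) are taken from the table metadata.
    """
    if table.kind != "fp_timecourse":
        raise ValueError("expected an fp_timecourse assay table")
    try:
        a0, b0 = float(table.meta["a0"]), float(table.meta["b0"])
    except KeyError as exc:
        raise KeyError(f"table metadata must provide reagent concentration {exc}") from None
    out = []
    for sid in table.series_ids():
        sub = table.series(sid)
        out.append(
            TimeCourse(
                t=sub["time"].to_numpy(float),
                fp=sub["value"].to_numpy(float),
                a0=a0,
                b0=b0,
                condition=float(sub["condition"].iloc[0]),
            )
        )
    return out


def rates_from_table(
    table: AssayTable, dead_time: float = DEFAULT_DEAD_TIME
) -> list[DoseResponsePoint]:
    """Fit every concentration's time course and collect labeling rates.

    The ordinate is k_app when the second-order model converged for every
    concentration; otherwise the initial slope is used for all points so the
    dataset stays on one ordinate.
    """
    fits = []
    for tc in timecourses_from_table(table):
        fits.append((tc, fit_timecourse(tc, dead_time=dead_time)))
    all_second_order = all(f.model == "second_order" for _, f in fits)
    points = []
    for tc, f in fits:
        if all_second_order:
            assert f.k_app is not None
            points.append(DoseResponsePoint(hpep_conc=tc.condition, rate=f.k_app, ordinate_kind="k_app"))
        else:
            points.append(
                DoseResponsePoint(hpep_conc=tc.condition, rate=initial_slope(f, tc), ordinate_kind="slope")
            )
    log.info("collected %d dose-response points (ordinate=%s)",
             len(points), points[0].ordinate_kind if points else "n/a")
    return points


def ec50_pipeline(
    table: AssayTable,
    dead_time: float = DEFAULT_DEAD_TIME,
    form: str = "log_sigmoid",
    n_mc: int = 1000,
    seed: int = 0,
) -> DoseResponseFit:
    """Full EC50 analysis of a multi-concentration labeling dataset.

    Fits each concentration's time course, aggregates the rates into the
    dose-response fit and attaches the Monte Carlo confidence interval.
    """
    points = rates_from_table(table, dead_time=dead_time)
    fit = fit_ec50(points, form=form)
    monte_carlo_ci(fit, points, n=n_mc, seed=seed)
    return fit
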