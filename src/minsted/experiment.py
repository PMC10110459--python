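"""End-to-end experiment glue: kinetics -> localization loop -> tables.

Turns a ground-truth site set plus binding kinetics into a set of
localization traces, and traces into a localization table ready for
rendering and structure analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epsf_model import OpticsModel
from .localizer import (
    LocalizerConfig,
    Schedule,
    Trace,
    UnbindingEmitter,
    position_estimate,
    run_localization,
)
from .precision_stats import (
    PrecisionConfig,
    convergence_filter,
    fit_power_law,
    max_block_size,
    sigma_block_curve,
)
from .sample_models import BindingEvent, KineticsModel, SiteSet, generate_events

__all__ = ["simulate_experiment", "traces_to_locs"]

#: std of the confocal pre-localization error used to seed the loop, nm
START_SIGMA_NM = 50.0


def simulate_experiment(
    sites: SiteSet,
    kin: KineticsModel,
    cfg: LocalizerConfig,
    optics: OpticsModel,
    duration_s: float,
    rng: np.random.Generator,
    schedule: Schedule | None = None,
) -> tuple[list[Trace], list[BindingEvent]]:
    """Simulate binding events on ``sites`` and localize each one.

    Each event is localized with the online loop, starting from the event
    position blurred by the confocal search uncertainty.  Events flagged as
    overlapping (second fluorophore in the focal region) are skipped, as
    the instrument cannot localize them meaningfully.
    """
    if schedule is None:
        schedule = Schedule(cfg, optics)
    events = generate_events(sites, kin, duration_s, rng)
    traces = []
    for k, ev in enumerate(events):
        if ev.overlaps:
            continue
        emitter = UnbindingEmitter(
            position=ev.position, t_unbind_ms=ev.duration_ms
        )
        start = np.asarray(ev.position) + rng.normal(0, START_SIGMA_NM, 2)
        cfg_ev = cfg
        if ev.photon_budget is not None:
            cfg_ev = LocalizerConfig(**{**cfg.__dict__})
            cfg_ev.max_photons = max(int(ev.photon_budget), 1)
        tr = run_localization(
            emitter, cfg_ev, optics, rng, start=start,
            schedule=schedule, trace_id=k,
        )
        tr.trace_id = k
        traces.append(tr)
    return traces, events


def _trace_sigma(trace: Trace, prec: PrecisionConfig) -> float:
    """Per-trace precision estimate for table export.

    Power-law extrapolation to the full trace length when the trace admits
    a fit; otherwise the spread of the post-``n_c`` centers.
    """
    if max_block_size(trace, prec) >= 5:
        Ms, sig = sigma_block_curve(trace, prec)
        try:
            fit = fit_power_law(Ms, sig, prec)
            return float(fit(trace.L - trace.n_c + 1))
        except (ValueError, RuntimeError):
            pass
    seg = trace.post_centers()
    if len(seg) < 2:
        return float("nan")
    return float(
        math.sqrt(np.std(seg[:, 0], ddof=1) * np.std(seg[:, 1], ddof=1))
    )


def traces_to_locs(
    traces: list[Trace],
    prec: PrecisionConfig | None = None,
    apply_filter: bool = True,
) -> pd.DataFrame:
    """Build a localization table (one row per converged trace)."""
    if prec is None:
        prec = PrecisionConfig()
    rows = []
    for tr in traces:
        if not tr.converged:
            continue
        if apply_filter and not convergence_filter(tr, prec):
            continue
        x, y = position_estimate(tr, tr.L)
        row = {
            "id": tr.trace_id,
            "x_nm": x,
            "y_nm": y,
            "sigma_nm": _trace_sigma(tr, prec),
            "L": tr.L,
            "n_c": tr.n_c,
            "t_s": tr.times_ms[-1] / 1e3 if tr.L else 0.0,
        }
        if tr.truth is not None and tr.L:
            row["truth_x_nm"] = float(tr.truth[-1, 0])
            row["truth_y_nm"] = float(tr.truth[-1, 1])
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "id", "x_nm", "y_nm", "sigma_nm", "L", "n_c", "t_s",
            "truth_x_nm", "truth_y_nm",
        ],
    )
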