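"""Simulation analyses: concentration response, knockdown screen, dose table.

All analyses follow the perturb-after-steady-state protocol: the context
model is first relaxed to steady state, and every perturbed run restarts
from that state (continuation) rather than from y_init, so responses are
measured against an established operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import DEFAULT_MAX_TIME, run_to_steady_state
from .model import NetworkModel
from .perturb import Perturbation, apply_knockdown, apply_perturbations, perturbed_initial_state

__all__ = [
    "DoseResponseCurve",
    "ScreenMatrix",
    "concentration_response",
    "estimate_half_max",
    "knockdown_screen",
    "dose_simulation",
    "RESPONSE_DELTA",
]

RESPONSE_DELTA = 1e-3  # minimum end-to-end change for a node to "respond"


@dataclass(frozen=True)
class DoseResponseCurve:
    """Steady-state activities of every node over a knockdown grid."""

    target: str
    grid: np.ndarray  # knockdown fractions, 0 .. 1
    activities: pd.DataFrame  # index: species ids, columns: grid fractions
    converged: np.ndarray  # per grid point
    half_max: dict[str, float | None] = field(default_factory=dict)

    @property
    def normalized(self) -> pd.DataFrame:
        """Min-max rescaling between each node's 0%- and 100%-KD activities.

        Non-responding nodes (end-to-end change below RESPONSE_DELTA) are
        returned as NaN rows.
        """
        a0 = self.activities.iloc[:, 0]
        a1 = self.activities.iloc[:, -1]
        span = a1 - a0
        out = self.activities.sub(a0, axis=0).div(span, axis=0)
        out[np.abs(span) <= RESPONSE_DELTA] = np.nan
        return out

    def to_csv(self) -> str:
        df = self.activities.T.copy()
        df.insert(0, "knockdown_fraction", self.grid)
        df.insert(1, "converged", self.converged.astype(int))
        return df.to_csv(index=False)


@dataclass(frozen=True)
class ScreenMatrix:
    """Activity change of every readout under single-node knockouts.

    Rows are the knocked-down node, columns the readout node, entries the
    steady-state activity change relative to the context reference.
    """

    context: tuple[Perturbation, ...]
    reference: pd.Series
    deltas: pd.DataFrame
    converged: pd.Series

    def to_csv(self) -> str:
        df = self.deltas.copy()
        df.index.name = "knocked_down"
        return df.to_csv()


def _steady_after(model, perturbations, y0, max_time):
    perturbed = apply_perturbations(model, perturbations)
    start = perturbed_initial_state(model, perturbations, y0)
    return run_to_steady_state(perturbed, max_time=max_time, y0=start)


def concentration_response(
    model: NetworkModel,
    target: str = "DYRK1A",
    step: float = 0.01,
    max_time: float = DEFAULT_MAX_TIME,
) -> DoseResponseCurve:
    """Graded knockdown of ``target`` over the grid 0, step, ..., 1.

    Each grid point re-runs the model to steady state from the baseline
    steady state.  Half-max knockdown fractions (EC50 for rising nodes,
    IC50 for falling ones) are attached for every responding node; they
    are suppressed for all nodes if any grid point failed to converge.
    """
    n_steps = round(1.0 / step)
    if abs(n_steps * step - 1.0) > 1e-9:
        raise ValueError(f"step must divide 1 evenly, got {step}")
    grid = np.arange(n_steps + 1) / n_steps
    base = run_to_steady_state(model, max_time=max_time)
    ids = list(model.species_ids)
    acts = np.empty((len(ids), grid.size))
    conv = np.empty(grid.size, dtype=bool)
    acts[:, 0] = base.state.to_numpy()
    conv[0] = base.converged
    for j, frac in enumerate(grid[1:], start=1):
        res = run_to_steady_state(
            apply_knockdown(model, target, float(frac)),
            max_time=max_time,
            y0=base.state.to_numpy(),
        )
        acts[:, j] = res.state.to_numpy()
        conv[j] = res.converged
    curve = DoseResponseCurve(
        target=target,
        grid=grid,
        activities=pd.DataFrame(acts, index=ids, columns=grid),
        converged=conv,
    )
    half_max: dict[str, float | None] = {}
    for sid in ids:
        half_max[sid] = estimate_half_max(curve, sid) if conv.all() else None
    object.__setattr__(curve, "half_max", half_max)
    return curve


def estimate_half_max(curve: DoseResponseCurve, node: str) -> float | None:
    """Knockdown fraction at which the node's normalized activity crosses 0.5.

    The first grid crossing is linearly interpolated between the two
    bracketing points.  Returns None for non-responding nodes.
    """
    a = curve.activities.loc[node].to_numpy()
    lo, hi = a[0], a[-1]
    if abs(hi - lo) <= RESPONSE_DELTA:
        return None
    nrm = (a - lo) / (hi - lo)
    for j in range(nrm.size - 1):
        y0, y1 = nrm[j], nrm[j + 1]
        if (y0 - 0.5) * (y1 - 0.5) <= 0 and y0 != y1:
            k = curve.grid[j] + (curve.grid[j + 1] - curve.grid[j]) * (0.5 - y0) / (y1 - y0)
            return float(k)
    return None


def knockdown_screen(
    model: NetworkModel,
    context=(),
    max_time: float = DEFAULT_MAX_TIME,
) -> ScreenMatrix:
    """100% single-node knockouts on top of a context perturbation.

    The reference is the steady state under the context alone; each row
    reports, for one additionally knocked-out node, the change of every
    readout relative to that reference.  Context targets yield (near-)zero
    rows since they are already perturbed.
    """
    context = tuple(context)
    base = run_to_steady_state(model, max_time=max_time)
    ref = _steady_after(model, context, base.state.to_numpy(), max_time) if context else base
    ids = list(model.species_ids)
    rows = {}
    conv = {}
    for sid in ids:
        perts = context + (Perturbation.knockdown(sid, 1.0),)
        res = _steady_after(model, perts, ref.state.to_numpy(), max_time)
        rows[sid] = res.state - ref.state
        conv[sid] = res.converged
    deltas = pd.DataFrame(rows).T
    deltas = deltas.loc[ids, ids]  # fixed row/column order
    return ScreenMatrix(
        context=context,
        reference=ref.state,
        deltas=deltas,
        converged=pd.Series(conv).loc[ids],
    )


def dose_simulation(
    model: NetworkModel,
    target: str = "DYRK1A",
    doses=(0.15, 0.30, 0.45),
    max_time: float = DEFAULT_MAX_TIME,
) -> pd.DataFrame:
    """Steady-state activities at a few knockdown doses (plus dose 0).

    Emulates low/medium/high inhibitor concentrations as graded target
    knockdowns; rows are doses, columns species.
    """
    if any(not (0 <= d <= 1) for d in doses):
        raise ValueError("doses must lie in [0, 1]")
    base = run_to_steady_state(model, max_time=max_time)
    table = {0.0: base.state}
    for d in doses:
        res = run_to_steady_state(
            apply_knockdown(model, target, float(d)),
            max_time=max_time,
            y0=base.state.to_numpy(),
        )
        table[float(d)] = res.state
    df = pd.DataFrame(table).T
    df.index.name = "knockdown_fraction"
    return df
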