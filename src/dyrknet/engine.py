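"""Logic-based ODE core: normalized-Hill activation, gate algebra, integration.

Each species follows

    dY_i/dt = (Ymax_i * g_i(Y) - Y_i) / tau_i

where the gate input g_i OR-combines the fluxes of all rules producing
species i.  A rule's flux is its weight times the product (AND) of one
normalized-Hill term per regulator,

    f(x) = B * x^n / (K^n + x^n),
    B = (ec50^n - 1) / (2 * ec50^n - 1),   K = (B - 1)^(1/n),

the unique member of the Hill family with f(0) = 0, f(ec50) = 0.5 and
f(1) = 1.  Inhibiting regulators contribute 1 - f(x).  Each regulator term
is clamped to [0, 1] before gate combination so that overexpression
(activities above 1) cannot drive the inclusive-or algebra out of range.

Steady state is declared when, over a check window of one time unit, every
species changes by less than 0.05% in relative terms (with an absolute
fallback of 5e-7 for species below activity 1e-3, where relative change is
ill-posed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import NetworkModel

__all__ = [
    "HillParameters",
    "SimulationResult",
    "SteadyStateResult",
    "IntegrationError",
    "hill_constants",
    "hill_activation",
    "rule_flux",
    "node_input",
    "rhs",
    "simulate",
    "run_to_steady_state",
    "REL_TOL",
    "ABS_TOL",
    "STEADY_REL_CHANGE",
    "STEADY_ABS_CHANGE",
    "STEADY_LOW_ACTIVITY",
    "STEADY_WINDOW",
    "DEFAULT_MAX_TIME",
    "DEFAULT_REPORT_STEP",
]

# integrator tolerances: the overexpression clamp (tau = 1e9) makes the
# system stiff, so the defaults are tight and the method stiff-capable
REL_TOL = 1e-8
ABS_TOL = 1e-10
ODE_METHOD = "LSODA"

STEADY_REL_CHANGE = 5e-4  # < 0.05% change per window for every node
STEADY_ABS_CHANGE = 5e-7  # absolute fallback below STEADY_LOW_ACTIVITY
STEADY_LOW_ACTIVITY = 1e-3
STEADY_WINDOW = 1.0  # time units
DEFAULT_MAX_TIME = 1000.0
DEFAULT_REPORT_STEP = 0.1


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last valid state."""

    def __init__(self, message: str, t: float, state: np.ndarray):
        super().__init__(message)
        self.t = t
        self.state = state


@dataclass(frozen=True)
class HillParameters:
    """Normalized-Hill constants for one (n, ec50) pair."""

    n: float
    ec50: float
    B: float
    K: float


def hill_constants(n: float, ec50: float) -> HillParameters:
    """Derive the normalization constants B and K for given n and ec50.

    Valid for n > 0 and 0 < ec50 < 0.5^(1/n); outside that region the gain
    B would be non-positive and the normalization identities unsatisfiable.
    """
    if n <= 0:
        raise ValueError(f"Hill coefficient n must be > 0, got {n}")
    e = ec50**n
    if not (0 < ec50 and e < 0.5):
        raise ValueError(
            f"ec50 must lie in (0, 0.5^(1/n)) = (0, {0.5 ** (1.0 / n):.4f}), got {ec50}"
        )
    # algebraically B = (e-1)/(2e-1) and K = (B-1)^(1/n); the equivalent
    # forms below avoid catastrophic cancellation in B - 1 for e near 0
    B = (1.0 - e) / (1.0 - 2.0 * e)
    K = (e / (1.0 - 2.0 * e)) ** (1.0 / n)
    return HillParameters(n=n, ec50=ec50, B=B, K=K)


def hill_activation(x, p: HillParameters):
    """Evaluate f(x) = B x^n / (K^n + x^n); accepts scalars or arrays."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("regulator activity must be >= 0")
    out = p.B * x**p.n / (p.K**p.n + x**p.n)
    return float(out) if out.ndim == 0 else out


class _CompiledModel:
    """Index-based view of a NetworkModel for fast right-hand-side evaluation."""

    def __init__(self, model: NetworkModel):
        self.model = model
        ids = model.species_ids
        index = {sid: i for i, sid in enumerate(ids)}
        self.n_species = len(ids)
        self.y_init = np.array([s.y_init for s in model.species])
        self.y_max = np.array([s.y_max for s in model.species])
        self.tau = np.array([s.tau for s in model.species])
        self.rules = []
        for rule in model.rules:
            p = hill_constants(rule.n, rule.ec50)
            regs = [(index[rid], sign) for rid, sign in rule.regulators]
            self.rules.append((index[rule.product], rule.w, p, regs))

    def gates(self, y: np.ndarray) -> np.ndarray:
        g = np.zeros(self.n_species)
        for prod, w, p, regs in self.rules:
            flux = w
            for ridx, sign in regs:
                x = y[ridx]
                t = p.B * x**p.n / (p.K**p.n + x**p.n) if x > 0 else 0.0
                t = min(max(t, 0.0), 1.0)
                flux *= t if sign > 0 else 1.0 - t
            # OR fold in declaration order: a + b - ab
            g[prod] = g[prod] + flux - g[prod] * flux
        return g

    def rhs(self, y: np.ndarray) -> np.ndarray:
        return (self.y_max * self.gates(y) - y) / self.tau


def rule_flux(rule, state: dict[str, float], model: NetworkModel | None = None) -> float:
    """Flux of one rule given a {species id: activity} state mapping."""
    p = hill_constants(rule.n, rule.ec50)
    flux = rule.w
    for rid, sign in rule.regulators:
        t = hill_activation(state[rid], p)
        t = min(max(t, 0.0), 1.0)
        flux *= t if sign > 0 else 1.0 - t
    return flux


def node_input(product: str, rules, state: dict[str, float]) -> float:
    """OR-combine (left fold of a + b - ab) the fluxes of rules for a product."""
    g = 0.0
    for rule in rules:
        if rule.product != product:
            continue
        flux = rule_flux(rule, state)
        g = g + flux - g * flux
    return g


def rhs(model: NetworkModel, state) -> np.ndarray:
    """Derivative vector dY/dt at the given state (array in species order)."""
    cm = _CompiledModel(model)
    y = np.asarray(state, dtype=float)
    return cm.rhs(y)


@dataclass(frozen=True)
class SimulationResult:
    """A trajectory on a fixed reporting grid."""

    time: np.ndarray
    activities: pd.DataFrame  # index: time, columns: species ids
    final_state: np.ndarray

    def to_csv(self) -> str:
        df = self.activities.copy()
        df.insert(0, "time", self.time)
        return df.to_csv(index=False)


@dataclass(frozen=True)
class SteadyStateResult:
    """Converged (or not) activity vector with convergence metadata."""

    state: pd.Series  # index: species ids
    converged: bool
    t_reached: float
    max_rel_change: float

    def to_dict(self) -> dict:
        out = {sid: float(v) for sid, v in self.state.items()}
        out["converged"] = bool(self.converged)
        out["t_reached"] = float(self.t_reached)
        out["max_rel_change"] = float(self.max_rel_change)
        return out


def _integrate(cm: _CompiledModel, y0: np.ndarray, t0: float, t1: float, t_eval=None):
    sol = solve_ivp(
        lambda t, y: cm.rhs(y),
        (t0, t1),
        y0,
        method=ODE_METHOD,
        rtol=REL_TOL,
        atol=ABS_TOL,
        t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed at t={sol.t[-1] if sol.t.size else t0}: {sol.message}",
            t=float(sol.t[-1]) if sol.t.size else t0,
            state=sol.y[:, -1] if sol.t.size else y0,
        )
    return sol


def simulate(
    model: NetworkModel,
    t_end: float,
    report_step: float = DEFAULT_REPORT_STEP,
    y0=None,
) -> SimulationResult:
    """Integrate the network ODE from ``y0`` (default: the species y_init)."""
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    cm = _CompiledModel(model)
    start = cm.y_init.copy() if y0 is None else np.asarray(y0, dtype=float).copy()
    n_steps = int(round(t_end / report_step))
    t_eval = np.linspace(0.0, t_end, n_steps + 1)
    sol = _integrate(cm, start, 0.0, t_end, t_eval=t_eval)
    df = pd.DataFrame(sol.y.T, columns=list(model.species_ids))
    return SimulationResult(time=sol.t, activities=df, final_state=sol.y[:, -1].copy())


def run_to_steady_state(
    model: NetworkModel,
    max_time: float = DEFAULT_MAX_TIME,
    y0=None,
    rel_change: float = STEADY_REL_CHANGE,
    abs_change: float = STEADY_ABS_CHANGE,
) -> SteadyStateResult:
    """Integrate until every node's change over one time unit is < 0.05%.

    Non-convergence within ``max_time`` is reported, not raised: the result
    carries ``converged=False`` and the state at ``max_time``.  The
    convergence thresholds can be overridden where a tighter endpoint is
    needed than the standard perturbation protocol's.
    """
    if max_time <= 0:
        raise ValueError("max_time must be > 0")
    cm = _CompiledModel(model)
    y = cm.y_init.copy() if y0 is None else np.asarray(y0, dtype=float).copy()
    t = 0.0
    max_rel = np.inf
    while t < max_time:
        t_next = min(t + STEADY_WINDOW, max_time)
        sol = _integrate(cm, y, t, t_next)
        y_new = sol.y[:, -1]
        denom = np.maximum(np.abs(y), np.finfo(float).tiny)
        rel = np.abs(y_new - y) / denom
        low = np.abs(y) < STEADY_LOW_ACTIVITY
        ok = np.where(
            low,
            np.abs(y_new - y) < abs_change,
            rel < rel_change,
        )
        max_rel = float(np.max(rel))
        y = y_new
        t = t_next
        if bool(np.all(ok)):
            return SteadyStateResult(
                state=pd.Series(y.copy(), index=list(model.species_ids)),
                converged=True,
                t_reached=t,
                max_rel_change=max_rel,
            )
    return SteadyStateResult(
        state=pd.Series(y.copy(), index=list(model.species_ids)),
        converged=False,
        t_reached=t,
        max_rel_change=max_rel,
    )
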