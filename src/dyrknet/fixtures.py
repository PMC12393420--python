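"""Synthetic networks and validation suites with known ground truth.

Every generator is fully determined by its arguments (and seed, where one
is taken).  The acyclic fixtures come with an independent steady-state
oracle — a topological-order fixed-point composition of the gate
functions, evaluated with plain arithmetic and no ODE integration — so the
engine can be checked against something it does not share code with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import run_to_steady_state
from .model import (
    DEFAULT_EC50,
    DEFAULT_N,
    NetworkModel,
    ReactionRule,
    Species,
    ValidationExperiment,
)
from .perturb import Perturbation, apply_perturbations, perturbed_initial_state
from .validate import DIRECTION_THRESHOLD, classify_direction

__all__ = [
    "FixtureSpec",
    "generate_cascade",
    "generate_fan_in",
    "generate_feedback",
    "generate_random_network",
    "generate_validation_suite",
    "fixed_point_oracle",
    "hill_oracle",
]

_KINDS = ("cascade", "fan_in", "feedback", "random_acyclic", "random")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible synthetic network."""

    kind: str = "random_acyclic"
    n_species: int = 6
    n_rules: int = 8
    seed: int = 0
    n_range: tuple[float, float] = (1.0, 4.0)
    w_range: tuple[float, float] = (0.2, 1.0)
    # ec50 sampled in (ec50_low, 0.9 * 0.5^(1/n)) for the drawn n, staying
    # clear of the singular edge of the admissible region
    ec50_low: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")


def hill_oracle(x: float, n: float = DEFAULT_N, ec50: float = DEFAULT_EC50) -> float:
    """Normalized-Hill value computed from first principles (math only)."""
    e = ec50**n
    b = (1.0 - e) / (1.0 - 2.0 * e)
    kn = e / (1.0 - 2.0 * e)  # K^n = B - 1, cancellation-free
    if x <= 0:
        return 0.0
    return b * x**n / (kn + x**n)


def fixed_point_oracle(model: NetworkModel) -> dict[str, float]:
    """Steady state of an acyclic network by topological gate composition.

    Independent of the ODE engine: species are ordered by Kahn's
    algorithm, and each steady activity is y_max times the OR-fold of its
    rule fluxes evaluated at the already-resolved upstream activities.
    Raises ValueError if the network has a cycle.
    """
    ids = list(model.species_ids)
    deps: dict[str, set[str]] = {sid: set() for sid in ids}
    for rule in model.rules:
        for rid, _sign in rule.regulators:
            if rid != rule.product:
                deps[rule.product].add(rid)
    order: list[str] = []
    ready = [sid for sid in ids if not deps[sid]]
    deps = {k: set(v) for k, v in deps.items()}
    while ready:
        sid = ready.pop(0)
        order.append(sid)
        for other in ids:
            if sid in deps[other]:
                deps[other].discard(sid)
                if not deps[other] and other not in order and other not in ready:
                    ready.append(other)
    if len(order) != len(ids):
        raise ValueError("fixed_point_oracle requires an acyclic network")
    state: dict[str, float] = {}
    for sid in order:
        g = 0.0
        for rule in model.rules_for(sid):
            flux = rule.w
            for rid, sign in rule.regulators:
                t = min(max(hill_oracle(state[rid], rule.n, rule.ec50), 0.0), 1.0)
                flux *= t if sign > 0 else 1.0 - t
            g = g + flux - g * flux
        state[sid] = model.species_by_id(sid).y_max * g
    return state


def generate_cascade(
    depth: int, input_level: float = 1.0
) -> tuple[NetworkModel, dict[str, float]]:
    """Linear chain ``=> A0``, ``A0 => A1``, ... with its exact steady state.

    The expected steady state is the closed-form composition of the
    normalized-Hill function, computed without touching the ODE solver.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if input_level < 0:
        raise ValueError("input_level must be >= 0")
    species = [Species("A0", role="input", y_max=input_level)]
    rules = [ReactionRule((), "A0")]
    for i in range(1, depth + 1):
        species.append(Species(f"A{i}", role="output" if i == depth else "intermediate"))
        rules.append(ReactionRule(((f"A{i-1}", 1),), f"A{i}"))
    expected = {"A0": input_level}
    y = input_level
    for i in range(1, depth + 1):
        y = min(max(hill_oracle(y), 0.0), 1.0)
        expected[f"A{i}"] = y
    return NetworkModel(tuple(species), tuple(rules)), expected


def generate_fan_in(
    n_inputs: int, levels=None, gate: str = "and"
) -> tuple[NetworkModel, dict[str, float]]:
    """Several inputs converging on one target through an AND or OR gate."""
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    if levels is None:
        levels = [1.0] * n_inputs
    species = [Species(f"I{i}", role="input", y_max=float(levels[i])) for i in range(n_inputs)]
    species.append(Species("T", role="output"))
    rules = [ReactionRule((), f"I{i}") for i in range(n_inputs)]
    if gate == "and":
        rules.append(ReactionRule(tuple((f"I{i}", 1) for i in range(n_inputs)), "T"))
    elif gate == "or":
        rules.extend(ReactionRule(((f"I{i}", 1),), "T") for i in range(n_inputs))
    else:
        raise ValueError("gate must be 'and' or 'or'")
    model = NetworkModel(tuple(species), tuple(rules))
    return model, fixed_point_oracle(model)


def generate_feedback(n_nodes: int = 3, n: float = 4.0, ec50: float = 0.35) -> NetworkModel:
    """An inhibitory ring (repressilator-style) of 2-4 nodes.

    With three or more nodes and a steep Hill coefficient the ring admits
    sustained oscillations, so steady-state detection must report
    non-convergence.  (A 2-node ring always converges: the system's
    divergence is negative everywhere, ruling out planar limit cycles.)
    """
    if not 2 <= n_nodes <= 4:
        raise ValueError("n_nodes must be in 2..4")
    species = tuple(
        Species(f"R{i}", role="intermediate", y_init=0.9 if i == 0 else 0.0)
        for i in range(n_nodes)
    )
    rules = tuple(
        ReactionRule(((f"R{i}", -1),), f"R{(i + 1) % n_nodes}", n=n, ec50=ec50)
        for i in range(n_nodes)
    )
    return NetworkModel(species, rules)


def generate_random_network(spec: FixtureSpec) -> NetworkModel:
    """Sample a structurally valid model from a FixtureSpec (seed-determined)."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "cascade":
        return generate_cascade(max(spec.n_species - 1, 1))[0]
    if spec.kind == "fan_in":
        return generate_fan_in(max(spec.n_species - 1, 1))[0]
    if spec.kind == "feedback":
        return generate_feedback(min(max(spec.n_species, 2), 4))

    k = spec.n_species
    n_inputs = max(1, k // 3)
    max_rules = n_inputs + 2 * (k - n_inputs)
    if spec.n_rules > max_rules:
        raise ValueError(
            f"n_rules={spec.n_rules} infeasible for n_species={k} "
            f"(at most {max_rules} with <=2 rules per non-input node)"
        )
    species = []
    for i in range(k):
        role = "input" if i < n_inputs else ("output" if i == k - 1 else "intermediate")
        y_max = float(rng.uniform(0.3, 1.0)) if role == "input" else 1.0
        tau = float(rng.uniform(0.5, 2.0))
        species.append(Species(f"N{i}", role=role, y_max=y_max, tau=tau))

    def draw_params():
        n = float(rng.uniform(*spec.n_range))
        hi = 0.9 * 0.5 ** (1.0 / n)
        ec50 = float(rng.uniform(spec.ec50_low, hi))
        w = float(rng.uniform(*spec.w_range))
        return w, n, ec50

    rules = [ReactionRule((), f"N{i}") for i in range(n_inputs)]
    # one guaranteed rule per non-input node, then extras up to n_rules
    for i in range(n_inputs, k):
        pool = list(range(i)) if spec.kind == "random_acyclic" else [j for j in range(k) if j != i]
        n_regs = int(rng.integers(1, min(3, len(pool)) + 1))
        regs = tuple(
            (f"N{j}", 1 if rng.random() < 0.7 else -1)
            for j in sorted(rng.choice(pool, size=n_regs, replace=False))
        )
        w, n, ec50 = draw_params()
        rules.append(ReactionRule(regs, f"N{i}", w=w, n=n, ec50=ec50))
    while len(rules) < spec.n_rules:
        i = int(rng.integers(n_inputs, k))
        pool = list(range(i)) if spec.kind == "random_acyclic" else [j for j in range(k) if j != i]
        if not pool:
            continue
        j = int(rng.choice(pool))
        w, n, ec50 = draw_params()
        rules.append(
            ReactionRule(((f"N{j}", 1 if rng.random() < 0.7 else -1),), f"N{i}", w=w, n=n, ec50=ec50)
        )
    return NetworkModel(tuple(species), tuple(rules))


_CONTRADICT = {"increase": "decrease", "decrease": "increase", "no_change": "increase"}


def generate_validation_suite(
    model: NetworkModel,
    n_match: int,
    n_mismatch: int,
    seed: int = 0,
    context: str = "synthetic",
) -> list[ValidationExperiment]:
    """Build a suite whose ground-truth accuracy is 100*n_match/(n_match+n_mismatch).

    Candidate single-perturbation experiments are simulated; n_match of
    them are labelled with the observed direction and n_mismatch with a
    contradicting one.
    """
    total = n_match + n_mismatch
    if total < 1:
        raise ValueError("need at least one experiment")
    rng = np.random.default_rng(seed)
    perturbable = [s.id for s in model.species if model.rules_for(s.id)]
    readouts = list(model.species_ids)
    if not perturbable or not readouts:
        raise ValueError("model has no perturbable species or readouts")
    base = run_to_steady_state(model)
    candidates = []
    for target in perturbable:
        for readout in readouts:
            if readout == target:
                continue
            candidates.append((target, readout))
    order = rng.permutation(len(candidates))
    experiments: list[ValidationExperiment] = []
    observed: list[str] = []
    for idx in order:
        if len(experiments) >= total:
            break
        target, readout = candidates[idx]
        kind = "knockdown" if rng.random() < 0.7 else "overexpression"
        pert = (
            Perturbation.knockdown(target)
            if kind == "knockdown"
            else Perturbation.overexpression(target)
        )
        perturbed = apply_perturbations(model, [pert])
        y0 = perturbed_initial_state(model, [pert], base.state.to_numpy())
        res = run_to_steady_state(perturbed, y0=y0)
        if not res.converged:
            continue
        direction = classify_direction(
            float(base.state[readout]), float(res.state[readout]), DIRECTION_THRESHOLD
        )
        experiments.append(
            ValidationExperiment(
                id=f"s{len(experiments) + 1}",
                perturbations=((target, kind, 1.0 if kind == "knockdown" else 0.0),),
                readout=readout,
                expected_direction=direction,  # provisional; flipped below
                context=context,
                source="synthetic",
            )
        )
        observed.append(direction)
    if len(experiments) < total:
        raise ValueError(
            f"could only realize {len(experiments)} of {total} requested experiments"
        )
    flip = rng.choice(total, size=n_mismatch, replace=False)
    out = []
    for i, (exp, direction) in enumerate(zip(experiments, observed)):
        expected = _CONTRADICT[direction] if i in flip else direction
        out.append(
            ValidationExperiment(
                id=exp.id,
                perturbations=exp.perturbations,
                readout=exp.readout,
                expected_direction=expected,
                context=exp.context,
                source=exp.source,
            )
        )
    return out
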