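"""Knockdown and overexpression protocols as pure model transformations.

A knockdown of fraction k scales the target's y_max by (1 - k); k = 1 is
the full knockout (y_max = 0).  Overexpression sets y_max = 10 for input
nodes, and for intermediate/output nodes sets y_init = 10 with tau = 1e9,
clamping the node near 10 for the simulated horizon.  Perturbations are
applied after the unperturbed model has reached steady state: downstream
runs restart from that state, with overexpressed non-input nodes lifted to
their clamped initial activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import NetworkModel

__all__ = [
    "Perturbation",
    "OE_Y_MAX",
    "OE_Y_INIT",
    "OE_TAU",
    "apply_knockdown",
    "apply_overexpression",
    "apply_perturbations",
    "perturbed_initial_state",
]

OE_Y_MAX = 10.0
OE_Y_INIT = 10.0
OE_TAU = 1e9

KINDS = ("knockdown", "overexpression")


@dataclass(frozen=True)
class Perturbation:
    target: str
    kind: str  # "knockdown" | "overexpression"
    fraction: float = 1.0  # knockdown fraction; ignored for overexpression

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.kind == "knockdown" and not (0.0 <= self.fraction <= 1.0):
            raise ValueError(f"knockdown fraction must be in [0, 1], got {self.fraction}")

    @classmethod
    def knockdown(cls, target: str, fraction: float = 1.0) -> "Perturbation":
        return cls(target=target, kind="knockdown", fraction=fraction)

    @classmethod
    def overexpression(cls, target: str) -> "Perturbation":
        return cls(target=target, kind="overexpression")


def apply_knockdown(model: NetworkModel, target: str, fraction: float = 1.0) -> NetworkModel:
    """Return a copy with the target's y_max scaled by (1 - fraction)."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"knockdown fraction must be in [0, 1], got {fraction}")
    sp = model.species_by_id(target)  # KeyError for unknown species
    return model.with_species(target, y_max=sp.y_max * (1.0 - fraction))


def apply_overexpression(model: NetworkModel, target: str) -> NetworkModel:
    """Return a copy with the target clamped high (idempotent)."""
    sp = model.species_by_id(target)
    if sp.role == "input":
        return model.with_species(target, y_max=OE_Y_MAX)
    return model.with_species(target, y_init=OE_Y_INIT, tau=OE_TAU)


def apply_perturbations(model: NetworkModel, perturbations) -> NetworkModel:
    """Apply a list of perturbations left to right.

    Order-independent when targets are distinct; a target appearing with
    both kinds is rejected as ambiguous.
    """
    kinds_seen: dict[str, str] = {}
    for p in perturbations:
        prev = kinds_seen.get(p.target)
        if prev is not None and prev != p.kind:
            raise ValueError(
                f"conflicting perturbations for {p.target!r}: {prev} and {p.kind}"
            )
        kinds_seen[p.target] = p.kind
    out = model
    for p in perturbations:
        if p.kind == "knockdown":
            out = apply_knockdown(out, p.target, p.fraction)
        else:
            out = apply_overexpression(out, p.target)
    return out


def perturbed_initial_state(
    model: NetworkModel, perturbations, state: np.ndarray
) -> np.ndarray:
    """Adjust a pre-perturbation steady state for use as initial condition.

    Knocked-down nodes keep their steady-state activity and decay under the
    reduced y_max; overexpressed non-input nodes are lifted to the clamped
    y_init (their tau of 1e9 then holds them there).
    """
    y0 = np.asarray(state, dtype=float).copy()
    for p in perturbations:
        if p.kind == "overexpression" and model.species_by_id(p.target).role != "input":
            y0[model.index(p.target)] = OE_Y_INIT
    return y0
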