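"""Literature-direction validation: simulate, classify, score per context.

Each curated experiment perturbs the model, re-runs it to steady state
from the unperturbed steady state, and classifies the readout's response
as increase / decrease / no_change against an absolute activity
threshold.  Accuracy is the percentage of experiments whose predicted
direction matches the literature direction, reported per context and
overall, rounded half-up to integer percent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

from .engine import DEFAULT_MAX_TIME, run_to_steady_state
from .model import NetworkModel, ValidationExperiment
from .perturb import Perturbation, apply_perturbations, perturbed_initial_state

__all__ = [
    "DIRECTION_THRESHOLD",
    "ExperimentRecord",
    "ValidationReport",
    "classify_direction",
    "run_validation",
]

DIRECTION_THRESHOLD = 0.01  # absolute activity change below which = no_change


def classify_direction(
    baseline_value: float,
    perturbed_value: float,
    delta_threshold: float = DIRECTION_THRESHOLD,
) -> str:
    """Classify a steady-state change as increase / decrease / no_change."""
    delta = perturbed_value - baseline_value
    if delta > delta_threshold:
        return "increase"
    if delta < -delta_threshold:
        return "decrease"
    return "no_change"


def _round_half_up_percent(matches: int, total: int) -> int:
    if total == 0:
        return 0
    return int(100 * matches / total + 0.5)


@dataclass(frozen=True)
class ExperimentRecord:
    experiment: ValidationExperiment
    predicted_direction: str | None
    match: bool | None
    delta: float | None
    error: str | None = None


@dataclass(frozen=True)
class ValidationReport:
    records: tuple[ExperimentRecord, ...]
    context_accuracy: dict[str, int]  # context -> integer percent
    overall_accuracy: int
    context_counts: dict[str, tuple[int, int]]  # context -> (matches, total)

    def to_json(self) -> str:
        payload = {
            "experiments": [
                {
                    "id": r.experiment.id,
                    "context": r.experiment.context,
                    "readout": r.experiment.readout,
                    "expected_direction": r.experiment.expected_direction,
                    "predicted_direction": r.predicted_direction,
                    "delta": r.delta,
                    "match": r.match,
                    "error": r.error,
                }
                for r in self.records
            ],
            "context_accuracy": self.context_accuracy,
            "context_counts": {k: list(v) for k, v in self.context_counts.items()},
            "overall_accuracy": self.overall_accuracy,
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def run_validation(
    model: NetworkModel,
    suite,
    delta_threshold: float = DIRECTION_THRESHOLD,
    max_time: float = DEFAULT_MAX_TIME,
) -> ValidationReport:
    """Score a validation suite against the model.

    Experiments referencing unknown species are marked as errors, warned
    about, and excluded from accuracy denominators.
    """
    suite = list(suite)
    base = run_to_steady_state(model, max_time=max_time)
    known = set(model.species_ids)
    records: list[ExperimentRecord] = []
    tallies: dict[str, list[int]] = {}
    all_matches = all_total = 0
    for exp in suite:
        missing = [t for t, _k, _f in exp.perturbations if t not in known]
        if exp.readout not in known:
            missing.append(exp.readout)
        if missing:
            msg = f"experiment {exp.id!r}: unknown species {sorted(set(missing))}"
            warnings.warn(msg)
            records.append(ExperimentRecord(exp, None, None, None, error=msg))
            continue
        perts = tuple(
            Perturbation.knockdown(t, f) if kind == "knockdown" else Perturbation.overexpression(t)
            for t, kind, f in exp.perturbations
        )
        perturbed = apply_perturbations(model, perts)
        y0 = perturbed_initial_state(model, perts, base.state.to_numpy())
        res = run_to_steady_state(perturbed, max_time=max_time, y0=y0)
        b = float(base.state[exp.readout])
        p = float(res.state[exp.readout])
        predicted = classify_direction(b, p, delta_threshold)
        match = predicted == exp.expected_direction
        records.append(ExperimentRecord(exp, predicted, match, p - b))
        t = tallies.setdefault(exp.context, [0, 0])
        t[0] += int(match)
        t[1] += 1
        all_matches += int(match)
        all_total += 1
    return ValidationReport(
        records=tuple(records),
        context_accuracy={c: _round_half_up_percent(m, n) for c, (m, n) in tallies.items()},
        overall_accuracy=_round_half_up_percent(all_matches, all_total),
        context_counts={c: (m, n) for c, (m, n) in tallies.items()},
    )
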