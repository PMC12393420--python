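"""The curated DYRK1A cell-cycle network.

DYRK1A enforces cardiomyocyte quiescence along two arms: it phosphorylates
LIN52 at serine 28 (pLIN52), nucleating assembly of the repressive DREAM
complex, and it destabilizes cyclin D, keeping RB-1 hypophosphorylated and
active.  DREAM and active RB-1 together silence the activator E2Fs
(E2F1/2/3), which drive cyclin E and, jointly, the DNA-replication
program; cyclin E/CDK2 in turn inactivates both RB-1 and DREAM, closing a
positive feedback loop that makes cell-cycle entry switch-like.

Node and gating choices beyond the core mechanisms above:

* B-Myb is a low-activity input (y_max = 0.1) competing with DREAM
  assembly (MuvB bound by B-Myb is unavailable to the repressive complex).
* Cyclin D feeds back on DREAM (``!CycD`` in the DREAM rule): cyclin
  D-associated kinase activity phosphorylates the RB-like DREAM subunit
  and disassembles the complex.
* Cyclin E carries a weak basal source rule (w = 0.18) for its
  E2F-independent basal transcription; this sets the quiescent operating
  tone of the CDK2 arm.
* RB-1 is an AND of two inhibitions, so cyclin D and cyclin E/CDK2 act as
  redundant RB inactivators.
* The three activator E2Fs require release from both RB-1 and DREAM
  (AND), and the DNA-replication program requires all three E2Fs jointly,
  OR a cyclin E/CDK2 bypass.
* Input calibration: DYRK1A y_max = 0.9, B-Myb y_max = 0.1, CDK2
  y_max = 0.8, leaving each input headroom to respond to perturbation.

The same network ships as a diffable model file
(``dyrknet/data/dyrk1a_cellcycle.tsv``); replacing that file swaps the
model for every command-line analysis without code changes.
"""

from __future__ import annotations

from importlib import resources

from .engine import SteadyStateResult, run_to_steady_state
from .model import NetworkModel, ReactionRule, Species, load_model

__all__ = [
    "build_dyrk1a_model",
    "baseline_steady_state",
    "load_packaged_model",
    "packaged_model_path",
    "packaged_suite_path",
]

_A = 1  # activating
_I = -1  # inhibiting

CYCE_BASAL_W = 0.18


def build_dyrk1a_model() -> NetworkModel:
    """Construct the reference DYRK1A cell-cycle network."""
    species = (
        Species("DYRK1A", "DYRK1A kinase", "input", y_max=0.9),
        Species("BMyb", "B-Myb transcription factor", "input", y_max=0.1),
        Species("CDK2", "cyclin-dependent kinase 2", "input", y_max=0.8),
        Species("pLIN52", "LIN52 phosphorylated at S28", "intermediate"),
        Species("DREAM", "DREAM repressor complex", "intermediate"),
        Species("CycD", "cyclin D", "intermediate"),
        Species("CycE", "cyclin E", "intermediate"),
        Species("CycE_CDK2", "cyclin E/CDK2 complex", "intermediate"),
        Species("RB1", "active (hypophosphorylated) RB-1", "intermediate"),
        Species("E2F1", "E2F1 transcription factor", "intermediate"),
        Species("E2F2", "E2F2 transcription factor", "intermediate"),
        Species("E2F3", "E2F3 transcription factor", "intermediate"),
        Species("DNA_replication", "DNA replication program", "output"),
    )
    r = ReactionRule
    rules = (
        r((), "DYRK1A"),
        r((), "BMyb"),
        r((), "CDK2"),
        r((("DYRK1A", _A),), "pLIN52"),
        r((("pLIN52", _A), ("BMyb", _I), ("CycD", _I)), "DREAM"),
        r((("DYRK1A", _I),), "CycD"),
        r((), "CycE", w=CYCE_BASAL_W),
        r((("E2F1", _A),), "CycE"),
        r((("E2F2", _A),), "CycE"),
        r((("E2F3", _A),), "CycE"),
        r((("CycE", _A), ("CDK2", _A)), "CycE_CDK2"),
        r((("CycD", _I), ("CycE_CDK2", _I)), "RB1"),
        r((("RB1", _I), ("DREAM", _I)), "E2F1"),
        r((("RB1", _I), ("DREAM", _I)), "E2F2"),
        r((("RB1", _I), ("DREAM", _I)), "E2F3"),
        r((("E2F1", _A), ("E2F2", _A), ("E2F3", _A)), "DNA_replication"),
        r((("CycE_CDK2", _A),), "DNA_replication"),
    )
    return NetworkModel(species, rules)


def baseline_steady_state(max_time: float = 1000.0) -> SteadyStateResult:
    """Steady state of the reference network from y_init = 0.

    Raises ``RuntimeError`` on non-convergence, which must not occur for
    the shipped asset.
    """
    result = run_to_steady_state(build_dyrk1a_model(), max_time=max_time)
    if not result.converged:
        raise RuntimeError(
            f"reference network failed to converge within {max_time} time units"
        )
    return result


def packaged_model_path():
    """Filesystem path of the installed model asset."""
    return resources.files("dyrknet").joinpath("data/dyrk1a_cellcycle.tsv")


def packaged_suite_path(context: str = "cardiomyocyte"):
    """Path of a packaged validation suite ('cardiomyocyte' or 'cancer')."""
    names = {
        "cardiomyocyte": "validation_cardiomyocyte.tsv",
        "cancer": "validation_cancer_template.tsv",
    }
    return resources.files("dyrknet").joinpath(f"data/{names[context]}")


def load_packaged_model() -> NetworkModel:
    return load_model(packaged_model_path())
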