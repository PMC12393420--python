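"""Network model containers and the plain-text model dialect.

A model is a list of *species* (nodes) and a list of *reaction rules*
(edges).  Each species carries an initial activity ``y_init``, a maximal
activity ``y_max`` and a time constant ``tau``; each rule carries a weight
``w``, a Hill coefficient ``n`` and a half-maximal input ``ec50``.
Regulators within one rule are AND-combined, distinct rules sharing a
product are OR-combined, and a rule with no regulators is a constant
source (the input-node convention).

Models are serialized as a two-section TSV::

    #species
    id<TAB>name<TAB>role<TAB>y_init<TAB>y_max<TAB>tau
    DYRK1A<TAB>DYRK1A kinase<TAB>input<TAB>0<TAB>0.9<TAB>1
    #rules
    rule<TAB>w<TAB>n<TAB>ec50
    => DYRK1A<TAB>1<TAB>1.4<TAB>0.5
    !DYRK1A => CycD<TAB>1<TAB>1.4<TAB>0.5

Rule syntax follows the ``!X & Y => Z`` convention: ``!`` marks an
inhibiting regulator, ``&`` separates AND-ed regulators, and one product
follows ``=>``.  Comment lines start with ``#`` (except the ``#species`` /
``#rules`` section markers) and blank lines are ignored.  Ids are
case-sensitive and may not contain whitespace or ``!&=>,#``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "ACTIVATING",
    "INHIBITING",
    "DEFAULT_W",
    "DEFAULT_N",
    "DEFAULT_EC50",
    "Species",
    "ReactionRule",
    "NetworkModel",
    "ValidationExperiment",
    "ModelFormatError",
    "ModelValidationError",
    "parse_model",
    "write_model",
    "load_model",
    "save_model",
    "parse_validation_suite",
    "load_validation_suite",
]

ACTIVATING = 1
INHIBITING = -1

DEFAULT_W = 1.0
DEFAULT_N = 1.4
DEFAULT_EC50 = 0.5

DEFAULT_Y_INIT = 0.0
DEFAULT_Y_MAX = 1.0
DEFAULT_TAU = 1.0

_ROLES = ("input", "intermediate", "output")
_RESERVED = set("!&=>,#")


class ModelFormatError(ValueError):
    """Raised when a model or suite file cannot be parsed."""


class ModelValidationError(ValueError):
    """Raised when a parsed model violates a structural invariant."""


def _valid_id(token: str) -> bool:
    return bool(token) and not any(c.isspace() or c in _RESERVED for c in token)


@dataclass(frozen=True)
class Species:
    """A network node: molecule, complex, or cellular process."""

    id: str
    name: str = ""
    role: str = "intermediate"
    y_init: float = DEFAULT_Y_INIT
    y_max: float = DEFAULT_Y_MAX
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        if not _valid_id(self.id):
            raise ModelValidationError(
                f"invalid species id {self.id!r}: ids may not contain "
                "whitespace or any of '!&=>,#'"
            )
        if self.role not in _ROLES:
            raise ModelValidationError(
                f"species {self.id!r}: role must be one of {_ROLES}, got {self.role!r}"
            )
        if self.tau <= 0:
            raise ModelValidationError(f"species {self.id!r}: tau must be > 0")
        if self.y_max < 0:
            raise ModelValidationError(f"species {self.id!r}: y_max must be >= 0")
        if self.y_init < 0:
            raise ModelValidationError(f"species {self.id!r}: y_init must be >= 0")


@dataclass(frozen=True)
class ReactionRule:
    """One reaction: AND-gated regulators driving a single product.

    ``regulators`` is an ordered tuple of ``(species_id, sign)`` with sign
    ``ACTIVATING`` (+1) or ``INHIBITING`` (-1).  An empty tuple denotes a
    constant source with flux ``w``.
    """

    regulators: tuple[tuple[str, int], ...]
    product: str
    w: float = DEFAULT_W
    n: float = DEFAULT_N
    ec50: float = DEFAULT_EC50

    def __post_init__(self) -> None:
        object.__setattr__(self, "regulators", tuple(tuple(r) for r in self.regulators))
        for rid, sign in self.regulators:
            if sign not in (ACTIVATING, INHIBITING):
                raise ModelValidationError(
                    f"rule for {self.product!r}: regulator sign must be +1/-1"
                )
        if not (0 < self.w <= 1):
            raise ModelValidationError(
                f"rule for {self.product!r}: w must be in (0, 1], got {self.w}"
            )
        if self.n <= 0:
            raise ModelValidationError(f"rule for {self.product!r}: n must be > 0")
        # ec50^n < 0.5 keeps the normalized-Hill gain positive.
        if not (0 < self.ec50 and self.ec50**self.n < 0.5):
            raise ModelValidationError(
                f"rule for {self.product!r}: ec50 must lie in (0, 0.5^(1/n)) = "
                f"(0, {0.5 ** (1.0 / self.n):.4f}), got {self.ec50}"
            )

    @property
    def is_source(self) -> bool:
        return not self.regulators

    def text(self) -> str:
        """Render the rule in ``!X & Y => Z`` form."""
        lhs = " & ".join(
            ("!" if sign == INHIBITING else "") + rid for rid, sign in self.regulators
        )
        return f"{lhs} => {self.product}" if lhs else f"=> {self.product}"


@dataclass(frozen=True)
class NetworkModel:
    """A complete logic-ODE network: species plus reaction rules."""

    species: tuple[Species, ...]
    rules: tuple[ReactionRule, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "rules", tuple(self.rules))
        validate_model(self)

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species)

    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(f"unknown species {sid!r}")

    def index(self, sid: str) -> int:
        for i, s in enumerate(self.species):
            if s.id == sid:
                return i
        raise KeyError(f"unknown species {sid!r}")

    def rules_for(self, sid: str) -> tuple[ReactionRule, ...]:
        return tuple(r for r in self.rules if r.product == sid)

    def with_species(self, sid: str, **changes) -> "NetworkModel":
        """Return a copy with one species' parameters replaced."""
        self.species_by_id(sid)  # raise KeyError for unknown targets
        new = tuple(replace(s, **changes) if s.id == sid else s for s in self.species)
        return NetworkModel(new, self.rules)


def validate_model(model: NetworkModel) -> None:
    """Check the cross-cutting structural invariants; raise on violation."""
    ids = [s.id for s in model.species]
    seen: set[str] = set()
    for sid in ids:
        if sid in seen:
            raise ModelValidationError(f"duplicate species id {sid!r}")
        seen.add(sid)
    for rule in model.rules:
        if rule.product not in seen:
            raise ModelValidationError(
                f"rule {rule.text()!r}: undeclared product species {rule.product!r}"
            )
        for rid, _sign in rule.regulators:
            if rid not in seen:
                raise ModelValidationError(
                    f"rule {rule.text()!r}: undeclared regulator species {rid!r}"
                )
    for s in model.species:
        targeting = model.rules_for(s.id)
        sources = [r for r in targeting if r.is_source]
        regulated = [r for r in targeting if not r.is_source]
        if s.role == "input":
            if len(sources) != 1 or regulated:
                raise ModelValidationError(
                    f"input species {s.id!r} must have exactly one source rule "
                    f"and no regulated rules (found {len(sources)} source, "
                    f"{len(regulated)} regulated)"
                )
        else:
            if targeting and not regulated:
                raise ModelValidationError(
                    f"non-input species {s.id!r} has only source rules"
                )


# ---------------------------------------------------------------------------
# model file dialect
# ---------------------------------------------------------------------------


def _parse_float(token: str, what: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ModelFormatError(f"line {lineno}: {what} is not a number: {token!r}") from None


def _parse_rule_text(text: str, lineno: int) -> tuple[tuple[tuple[str, int], ...], str]:
    if "=>" not in text:
        raise ModelFormatError(f"line {lineno}: rule {text!r} is missing '=>'")
    lhs, _, rhs = text.partition("=>")
    product = rhs.strip()
    if not _valid_id(product):
        raise ModelFormatError(f"line {lineno}: invalid rule product {product!r}")
    regulators: list[tuple[str, int]] = []
    lhs = lhs.strip()
    if lhs:
        for part in lhs.split("&"):
            tok = part.strip()
            sign = ACTIVATING
            if tok.startswith("!"):
                sign = INHIBITING
                tok = tok[1:].strip()
            if not _valid_id(tok):
                raise ModelFormatError(f"line {lineno}: invalid regulator {part.strip()!r}")
            regulators.append((tok, sign))
    return tuple(regulators), product


def parse_model(text: str) -> NetworkModel:
    """Parse a model file; unspecified parameters take the documented defaults.

    Raises :class:`ModelFormatError` for syntax problems (with line number)
    and :class:`ModelValidationError` for structural violations; a malformed
    input never yields a partially constructed model.
    """
    species: list[Species] = []
    rules: list[ReactionRule] = []
    section = None
    header_done = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped:
            continue
        lower = stripped.lower()
        if lower == "#species":
            section, header_done = "species", False
            continue
        if lower == "#rules":
            section, header_done = "rules", False
            continue
        if stripped.startswith("#"):
            continue
        if section is None:
            raise ModelFormatError(
                f"line {lineno}: content before the '#species' section marker"
            )
        fields = [f.strip() for f in line.split("\t")]
        if not header_done:
            header_done = True
            head = fields[0].lower()
            if (section == "species" and head == "id") or (
                section == "rules" and head == "rule"
            ):
                continue  # header row is optional but conventional
        if section == "species":
            sid = fields[0]
            name = fields[1] if len(fields) > 1 and fields[1] else ""
            role = fields[2] if len(fields) > 2 and fields[2] else "intermediate"
            y_init = (
                _parse_float(fields[3], "y_init", lineno)
                if len(fields) > 3 and fields[3]
                else DEFAULT_Y_INIT
            )
            y_max = (
                _parse_float(fields[4], "y_max", lineno)
                if len(fields) > 4 and fields[4]
                else DEFAULT_Y_MAX
            )
            tau = (
                _parse_float(fields[5], "tau", lineno)
                if len(fields) > 5 and fields[5]
                else DEFAULT_TAU
            )
            try:
                species.append(
                    Species(id=sid, name=name, role=role, y_init=y_init, y_max=y_max, tau=tau)
                )
            except ModelValidationError as exc:
                raise ModelFormatError(f"line {lineno}: {exc}") from None
        else:
            regulators, product = _parse_rule_text(fields[0], lineno)
            w = (
                _parse_float(fields[1], "w", lineno)
                if len(fields) > 1 and fields[1]
                else DEFAULT_W
            )
            n = (
                _parse_float(fields[2], "n", lineno)
                if len(fields) > 2 and fields[2]
                else DEFAULT_N
            )
            ec50 = (
                _parse_float(fields[3], "ec50", lineno)
                if len(fields) > 3 and fields[3]
                else DEFAULT_EC50
            )
            rules.append(ReactionRule(regulators=regulators, product=product, w=w, n=n, ec50=ec50))
    return NetworkModel(tuple(species), tuple(rules))


def _fmt(x: float) -> str:
    """Shortest decimal that round-trips through float()."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


def write_model(model: NetworkModel) -> str:
    """Serialize a model deterministically (declaration order, byte-stable)."""
    lines = ["#species", "id\tname\trole\ty_init\ty_max\ttau"]
    for s in model.species:
        lines.append(
            "\t".join([s.id, s.name, s.role, _fmt(s.y_init), _fmt(s.y_max), _fmt(s.tau)])
        )
    lines.append("#rules")
    lines.append("rule\tw\tn\tec50")
    for r in model.rules:
        lines.append("\t".join([r.text(), _fmt(r.w), _fmt(r.n), _fmt(r.ec50)]))
    return "\n".join(lines) + "\n"


def load_model(path) -> NetworkModel:
    with open(path, encoding="utf-8") as fh:
        return parse_model(fh.read())


def save_model(model: NetworkModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_model(model))


# ---------------------------------------------------------------------------
# validation suites
# ---------------------------------------------------------------------------

_DIRECTIONS = ("increase", "decrease", "no_change")


@dataclass(frozen=True)
class ValidationExperiment:
    """A literature-direction test case: perturbations, readout, expectation."""

    id: str
    perturbations: tuple[tuple[str, str, float], ...]  # (species, kind, fraction)
    readout: str
    expected_direction: str
    context: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.expected_direction not in _DIRECTIONS:
            raise ModelFormatError(
                f"experiment {self.id!r}: unknown direction "
                f"{self.expected_direction!r} (expected one of {_DIRECTIONS})"
            )


def parse_perturbation_spec(spec: str) -> tuple[tuple[str, str, float], ...]:
    """Parse ``KO:<species>[:<fraction>]`` / ``OE:<species>``, ';'-separated."""
    out = []
    for part in spec.split(";"):
        part = part.strip()
        if not part:
            continue
        bits = part.split(":")
        kind = bits[0].strip().upper()
        if kind == "KO":
            if len(bits) == 2:
                target, fraction = bits[1].strip(), 1.0
            elif len(bits) == 3:
                target = bits[1].strip()
                try:
                    fraction = float(bits[2])
                except ValueError:
                    raise ModelFormatError(
                        f"malformed knockdown fraction in {part!r}"
                    ) from None
                if not 0 <= fraction <= 1:
                    raise ModelFormatError(
                        f"knockdown fraction must be in [0, 1]: {part!r}"
                    )
            else:
                raise ModelFormatError(f"malformed perturbation spec {part!r}")
            out.append((target, "knockdown", fraction))
        elif kind == "OE":
            if len(bits) != 2:
                raise ModelFormatError(f"malformed perturbation spec {part!r}")
            out.append((bits[1].strip(), "overexpression", 0.0))
        else:
            raise ModelFormatError(
                f"unknown perturbation kind {kind!r} in {part!r} (expected KO or OE)"
            )
    if not out:
        raise ModelFormatError(f"empty perturbation spec {spec!r}")
    return tuple(out)


def parse_validation_suite(text: str) -> list[ValidationExperiment]:
    """Parse a TSV suite with columns id, perturbation, readout,
    expected_direction, context, source.  A header row is recognised and
    skipped; an empty file yields an empty list."""
    experiments: list[ValidationExperiment] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if fields[0].lower() == "id" and len(fields) >= 4:
            continue
        if len(fields) < 4:
            raise ModelFormatError(
                f"line {lineno}: expected at least 4 tab-separated fields, got {len(fields)}"
            )
        try:
            perturbations = parse_perturbation_spec(fields[1])
        except ModelFormatError as exc:
            raise ModelFormatError(f"line {lineno}: {exc}") from None
        experiments.append(
            ValidationExperiment(
                id=fields[0],
                perturbations=perturbations,
                readout=fields[2],
                expected_direction=fields[3],
                context=fields[4] if len(fields) > 4 else "",
                source=fields[5] if len(fields) > 5 else "",
            )
        )
    return experiments


def load_validation_suite(path) -> list[ValidationExperiment]:
    with open(path, encoding="utf-8") as fh:
        return parse_validation_suite(fh.read())
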