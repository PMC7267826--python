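"""Declarative error rules: one process's error behaviour as data.

An :class:`ErrorRule` describes how one wet-lab process (synthesis, a PCR
polymerase, a storage condition, a sequencing technology) corrupts DNA: a
raw per-base error rate, the split between insertions, deletions and
substitutions, per-base insertion/deletion weights, a bias toward
homopolymeric regions, context-specific substitution patterns (e.g. the
CG->CA pattern of PacBio reads) and positional substitution weights (e.g.
elevated T substitution at one read position).

Rules are plain validated data so users can edit them without touching
code; the shipped presets live as JSON files under ``dnasim/presets`` and
carry a ``source`` citation field.  Their numeric rates are editable
starting points taken to be representative of the cited literature, not
measured constants of this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict

from .records import VALID_BASES

ERROR_TYPES = ("insertion", "deletion", "substitution")
BASES = ("A", "C", "G", "T")

#: distributions must sum to 1 within this tolerance
SUM_TOL = 1e-9


class Replacement(BaseModel):
    model_config = ConfigDict(extra="ignore")
    sequence: str
    weight: float = 1.0


class SubstitutionRule(BaseModel):
    """Replace ``target`` (>= 1 base) by one of the weighted ``replacements``.

    ``position_range`` optionally restricts the rule to target matches whose
    start lies in [start, end) on the current sequence.
    """

    model_config = ConfigDict(extra="ignore")

    target: str
    replacements: list[Replacement]
    position_range: Optional[tuple[int, int]] = None


class PositionalRule(BaseModel):
    """Weight multiplier for substitution *to* ``base`` at one read position."""

    model_config = ConfigDict(extra="ignore")

    position: int
    base: str
    weight: float = 1.0


class TypeDistribution(BaseModel):
    model_config = ConfigDict(extra="ignore")
    insertion: float = 1 / 3
    deletion: float = 1 / 3
    substitution: float = 1 / 3

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.insertion, self.deletion, self.substitution)


def uniform_base_weights() -> dict[str, float]:
    return {b: 0.25 for b in BASES}


class ErrorRule(BaseModel):
    """Full declarative description of one process's error behaviour.

    ``homopolymer_bias`` is the probability that an insertion or deletion
    targets a homopolymeric region rather than a uniform-random position.
    Field types are checked on construction; the semantic invariants
    (distributions summing to 1, rates in range, replacement != target) are
    checked by :func:`validate_rule`, which reports violations instead of
    raising so that partially edited rules can be diagnosed in full.
    """

    model_config = ConfigDict(extra="ignore")

    name: str
    raw_rate: float
    type_distribution: TypeDistribution = TypeDistribution()
    insertion_weights: dict[str, float] = uniform_base_weights()
    deletion_weights: dict[str, float] = uniform_base_weights()
    homopolymer_bias: float = 0.0
    substitution_rules: list[SubstitutionRule] = []
    positional_rules: list[PositionalRule] = []
    stage: Optional[Literal["synthesis", "pcr", "storage", "sequencing"]] = None
    source: Optional[str] = None


@dataclass(frozen=True)
class Violation:
    path: str
    message: str

    def __str__(self) -> str:
        return f"{self.path}: {self.message}"


def _check_distribution(values, path, violations, *, tol=SUM_TOL):
    if any(v < 0 for v in values):
        violations.append(Violation(path, "weights must be non-negative"))
    total = sum(values)
    if abs(total - 1.0) > tol:
        violations.append(Violation(path, f"weights sum to {total!r}, expected 1"))


def validate_rule(rule: ErrorRule) -> list[Violation]:
    """Check every semantic invariant of a rule; empty list means usable.

    Total (never raises) and idempotent; each violation carries a
    machine-readable path into the rule.
    """
    v: list[Violation] = []
    if not rule.name:
        v.append(Violation("name", "must be non-empty"))
    if not 0.0 <= rule.raw_rate <= 1.0:
        v.append(Violation("raw_rate", f"{rule.raw_rate!r} outside [0, 1]"))
    _check_distribution(rule.type_distribution.as_tuple(), "type_distribution", v)
    for field_name, weights in (
        ("insertion_weights", rule.insertion_weights),
        ("deletion_weights", rule.deletion_weights),
    ):
        if set(weights) != set(BASES):
            v.append(Violation(field_name, f"keys must be exactly {BASES}"))
        else:
            _check_distribution([weights[b] for b in BASES], field_name, v)
    if not 0.0 <= rule.homopolymer_bias <= 1.0:
        v.append(Violation("homopolymer_bias", "outside [0, 1]"))
    for i, sr in enumerate(rule.substitution_rules):
        path = f"substitution_rules[{i}]"
        if not sr.target or any(c not in VALID_BASES for c in sr.target):
            v.append(Violation(f"{path}.target", "must be a non-empty A/C/G/T string"))
        if not sr.replacements:
            v.append(Violation(f"{path}.replacements", "needs at least one replacement"))
        else:
            for j, rep in enumerate(sr.replacements):
                rpath = f"{path}.replacements[{j}]"
                if not rep.sequence or any(c not in VALID_BASES for c in rep.sequence):
                    v.append(Violation(rpath, "must be a non-empty A/C/G/T string"))
                if rep.sequence == sr.target:
                    v.append(Violation(rpath, "replacement equals target"))
            _check_distribution(
                [r.weight for r in sr.replacements], f"{path}.replacements", v
            )
        if sr.position_range is not None:
            start, end = sr.position_range
            if start < 0 or end <= start:
                v.append(
                    Violation(f"{path}.position_range", "need 0 <= start < end")
                )
    for i, pr in enumerate(rule.positional_rules):
        path = f"positional_rules[{i}]"
        if pr.position < 0:
            v.append(Violation(f"{path}.position", "must be >= 0"))
        if pr.base not in VALID_BASES:
            v.append(Violation(f"{path}.base", "must be one of A/C/G/T"))
        if pr.weight < 0:
            v.append(Violation(f"{path}.weight", "must be >= 0"))
    return v


class PresetError(ValueError):
    """A shipped preset file could not be loaded or parsed."""


def preset_registry() -> dict[str, ErrorRule]:
    """Load all shipped preset rules, keyed by name.

    Presets are plain JSON files in the package data directory
    ``dnasim/presets``; editing a file changes the preset.  A malformed
    file raises :class:`PresetError` naming it.
    """
    registry: dict[str, ErrorRule] = {}
    root = resources.files("dnasim").joinpath("presets")
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if not entry.name.endswith(".json"):
            continue
        try:
            rule = ErrorRule.model_validate(json.loads(entry.read_text()))
        except Exception as exc:
            raise PresetError(f"preset file {entry.name}: {exc}") from exc
        registry[rule.name] = rule
    return registry
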