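"""Sequential error simulation with full per-base provenance.

Stages run in the fixed wet-lab order synthesis -> PCR -> storage ->
sequencing (absent stages are skipped).  Within a stage, the number of
error events is the sequence length times the effective rate with
stochastic rounding, and events are drawn and applied one at a time:
each draw sees the sequence as left by all earlier edits, so an earlier
deletion can create the context (e.g. a TAG triplet) that a later
substitution pattern then hits — error cross-talk.

Every modification is recorded in a :class:`Ledger` together with a map
from output coordinates back to the original sequence, so the simulation
can be replayed, audited and its quality line remapped through indels.

Randomness: one root seed; stage ``i`` of the canonical order draws from
an independent stream keyed by (root seed, i), so adding or removing one
stage does not perturb the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .assessment import find_homopolymers
from .records import SequenceRecord
from .rules import BASES, ErrorRule, SubstitutionRule, validate_rule
from .storage import StorageModelConfig, storage_model_events

STAGE_ORDER = ("synthesis", "pcr", "storage", "sequencing")


class RuleValidationError(ValueError):
    """An error rule failed semantic validation; carries all violations."""

    def __init__(self, stage: str, violations):
        self.stage = stage
        self.violations = list(violations)
        details = "; ".join(str(v) for v in self.violations)
        super().__init__(f"invalid rule for stage '{stage}': {details}")


def stage_rng(seed: int, stage_index: int) -> np.random.Generator:
    """Independent per-stage stream derived from (root seed, stage index)."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(stage_index,))))


def child_seed(seed: int, index: int) -> int:
    """Deterministic child seed (e.g. one per FASTA record), < 2**31."""
    ss = np.random.SeedSequence(seed, spawn_key=(index,))
    return int(ss.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


@dataclass(frozen=True)
class Modification:
    """One edit: insertion (before == ''), deletion (after == '') or substitution.

    ``position_current`` is the 0-based index at application time;
    ``position_original`` maps the edited base back to the input sequence,
    or is None for a base that itself arose from an earlier insertion.
    """

    stage: str
    type: str  # "insertion" | "deletion" | "substitution"
    position_current: int
    position_original: Optional[int]
    before: str
    after: str

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "type": self.type,
            "position_current": self.position_current,
            "position_original": "inserted" if self.position_original is None else self.position_original,
            "before": self.before,
            "after": self.after,
        }


@dataclass
class Ledger:
    """Ordered modifications plus the output->input coordinate map.

    ``origin_map[i]`` is the original index of output base i, or None if it
    was inserted during simulation.  Replaying the modifications on the
    input reproduces the output exactly.
    """

    modifications: list[Modification] = field(default_factory=list)
    origin_map: list[Optional[int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "modifications": [m.to_dict() for m in self.modifications],
            "origin_map": ["inserted" if o is None else o for o in self.origin_map],
        }


def replay(modifications: Sequence[Modification], input_seq: str) -> str:
    """Re-apply a ledger's modifications to the input sequence.

    Verifies at every step that the recorded ``before`` context matches;
    the result must equal the simulation output.
    """
    seq = input_seq
    for m in modifications:
        i = m.position_current
        if m.type == "insertion":
            seq = seq[:i] + m.after + seq[i:]
        else:
            if seq[i : i + len(m.before)] != m.before:
                raise ValueError(
                    f"ledger replay mismatch at position {i}: expected "
                    f"{m.before!r}, found {seq[i:i+len(m.before)]!r}"
                )
            seq = seq[:i] + m.after + seq[i + len(m.before) :]
    return seq


def remap_quality(origin_map: Sequence[Optional[int]], input_quality: Sequence[float]) -> list[float]:
    """Carry per-base error probabilities through indels via the origin map.

    Bases inserted by the simulation have no input probability and get 1.0
    (quality '!'), marking them as untrusted.
    """
    return [1.0 if o is None else float(input_quality[o]) for o in origin_map]


# --------------------------------------------------------------------------
# Drawing errors
# --------------------------------------------------------------------------

def error_count(length: int, rate: float, rng: np.random.Generator) -> int:
    """Number of error events: length*rate with stochastic rounding.

    floor(length*rate) events plus one more with probability equal to the
    fractional part, so the expectation is exactly length*rate (plain
    truncation would bias low).  Products that are integral up to float
    round-off are treated as exact.
    """
    expected = length * rate
    base = int(expected)
    frac = expected - base
    if frac > 1.0 - 1e-9:
        return base + 1
    if frac < 1e-9:
        return base
    return base + (1 if rng.random() < frac else 0)


def _substitution_sites(
    rules: Sequence[SubstitutionRule], seq: str
) -> list[tuple[SubstitutionRule, int]]:
    sites = []
    for sr in rules:
        lo, hi = sr.position_range or (0, len(seq))
        start = seq.find(sr.target)
        while start != -1:
            if lo <= start < hi:
                sites.append((sr, start))
            start = seq.find(sr.target, start + 1)
    return sites


def _homopolymer_positions(seq: str, min_run: int, base: Optional[str] = None) -> list[int]:
    positions = []
    for s, e, b, _ in find_homopolymers(seq, min_run):
        if base is None or b == base:
            positions.extend(range(s, e))
    return positions


def _weighted_choice(rng: np.random.Generator, weights: Sequence[float]) -> int:
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        return int(rng.integers(len(w)))
    return int(rng.choice(len(w), p=w / total))


def draw_error(
    rule: ErrorRule,
    seq: str,
    rng: np.random.Generator,
    homopolymer_min_run: int = 3,
) -> Optional[tuple[str, int, str, str]]:
    """Draw one error event on the current sequence.

    Returns (type, position, before, after) or None when the sequence is
    empty and no error can be placed.

    * The type comes from the rule's type distribution.
    * Insertions/deletions: the base is drawn from the per-base weights;
      with probability ``homopolymer_bias`` the position is uniform over
      bases inside maximal homopolymer runs (length >= ``homopolymer_min_run``,
      restricted to runs of the drawn base for deletions), otherwise uniform
      over the whole sequence.  Deletions outside homopolymers target the
      drawn base's positions when any exist.  Whenever a biased/restricted
      position set is empty the draw falls back to a uniform position.
    * Substitutions: if any substitution rule's target matches at an
      admissible position (respecting ``position_range``), one (site, rule)
      pair is chosen uniformly and the replacement by its weights; otherwise
      a single-base substitution is drawn, with positional rules acting as
      position weight multipliers that also steer the replacement base.
    """
    n = len(seq)
    if n == 0:
        return None
    etype = ("insertion", "deletion", "substitution")[
        _weighted_choice(rng, rule.type_distribution.as_tuple())
    ]

    if etype == "substitution":
        sites = _substitution_sites(rule.substitution_rules, seq)
        if sites:
            sr, pos = sites[int(rng.integers(len(sites)))]
            rep = sr.replacements[_weighted_choice(rng, [r.weight for r in sr.replacements])]
            return ("substitution", pos, sr.target, rep.sequence)
        # fallback: single-base substitution with positional weighting
        weights = np.ones(n)
        for pr in rule.positional_rules:
            if pr.position < n:
                weights[pr.position] *= pr.weight
        pos = _weighted_choice(rng, weights)
        directed = [
            pr for pr in rule.positional_rules
            if pr.position == pos and pr.base != seq[pos] and pr.weight > 0
        ]
        if directed:
            new_base = directed[_weighted_choice(rng, [pr.weight for pr in directed])].base
        else:
            others = [b for b in BASES if b != seq[pos]]
            new_base = others[int(rng.integers(3))]
        return ("substitution", pos, seq[pos], new_base)

    weights_map = rule.insertion_weights if etype == "insertion" else rule.deletion_weights
    base = BASES[_weighted_choice(rng, [weights_map[b] for b in BASES])]
    in_homopolymer = rule.homopolymer_bias > 0 and rng.random() < rule.homopolymer_bias

    if etype == "insertion":
        if in_homopolymer:
            candidates = _homopolymer_positions(seq, homopolymer_min_run)
        else:
            candidates = []
        if not candidates:
            candidates = list(range(n + 1))  # insert before index, incl. end
        pos = candidates[int(rng.integers(len(candidates)))]
        return ("insertion", pos, "", base)

    # deletion: restrict to positions of the drawn base when possible
    if in_homopolymer:
        candidates = _homopolymer_positions(seq, homopolymer_min_run, base)
        if not candidates:
            candidates = list(range(n))
    else:
        candidates = [i for i, c in enumerate(seq) if c == base] or list(range(n))
    pos = candidates[int(rng.integers(len(candidates)))]
    return ("deletion", pos, seq[pos], "")


# --------------------------------------------------------------------------
# Applying stages
# --------------------------------------------------------------------------

def _apply_event(
    seq: str,
    origin_map: list[Optional[int]],
    stage: str,
    etype: str,
    pos: int,
    before: str,
    after: str,
) -> tuple[str, Modification]:
    if etype == "insertion":
        original = origin_map[pos] if pos < len(origin_map) else None
        origin_map[pos:pos] = [None] * len(after)
        seq = seq[:pos] + after + seq[pos:]
    else:
        original = origin_map[pos]
        replacement_origins = origin_map[pos : pos + len(before)][: len(after)]
        replacement_origins += [None] * (len(after) - len(replacement_origins))
        origin_map[pos : pos + len(before)] = replacement_origins
        seq = seq[:pos] + after + seq[pos + len(before) :]
    mod = Modification(
        stage=stage,
        type=etype,
        position_current=pos,
        position_original=original,
        before=before,
        after=after,
    )
    return seq, mod


def effective_rate(rule: ErrorRule, stage: str, pcr_cycles: int = 1, storage_generations: int = 1) -> float:
    """Per-base rate a stage applies in one pass.

    PCR rules carry a per-cycle rate and storage host presets a
    per-generation rate; both compound as 1 - (1 - r)^n.
    """
    if stage == "pcr":
        return 1.0 - (1.0 - rule.raw_rate) ** pcr_cycles
    if stage == "storage":
        return 1.0 - (1.0 - rule.raw_rate) ** storage_generations
    return rule.raw_rate


def apply_stage(
    seq: str,
    origin_map: list[Optional[int]],
    rule: ErrorRule,
    stage: str,
    rng: np.random.Generator,
    rate: Optional[float] = None,
    homopolymer_min_run: int = 3,
) -> tuple[str, list[Modification], bool]:
    """Apply one rule-based stage; returns (sequence, modifications, truncated).

    The error count is fixed up front from the stage-entry length; events
    are then drawn against the *current* sequence so each sees all earlier
    edits (cross-talk).  If the sequence shrinks to empty mid-stage the
    stage stops early and ``truncated`` is True.
    """
    if rate is None:
        rate = rule.raw_rate
    n_errors = error_count(len(seq), rate, rng)
    mods: list[Modification] = []
    for _ in range(n_errors):
        drawn = draw_error(rule, seq, rng, homopolymer_min_run)
        if drawn is None:
            return seq, mods, True
        etype, pos, before, after = drawn
        seq, mod = _apply_event(seq, origin_map, stage, etype, pos, before, after)
        mods.append(mod)
    return seq, mods, False


def apply_storage_model(
    seq: str,
    origin_map: list[Optional[int]],
    model: StorageModelConfig,
    rng: np.random.Generator,
) -> tuple[str, list[Modification]]:
    """Apply a storage channel model with the same provenance as rule stages."""
    events = storage_model_events(model, seq, rng)
    mods: list[Modification] = []
    deleted = 0
    for pos, etype, before, after in events:  # input-coordinate, ascending
        current_pos = pos - deleted
        seq, mod = _apply_event(seq, origin_map, "storage", etype, current_pos, before, after)
        mods.append(mod)
        if etype == "deletion":
            deleted += len(before)
    return seq, mods


# --------------------------------------------------------------------------
# Full simulation
# --------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Everything needed to audit and reproduce one simulated read."""

    input: SequenceRecord
    output: SequenceRecord
    ledger: Ledger
    seed: int
    counts: dict[str, dict[str, int]]  # stage -> error type -> count
    truncated: bool = False

    def to_dict(self) -> dict:
        return {
            "input_id": self.input.id,
            "input_sequence": self.input.sequence,
            "output_sequence": self.output.sequence,
            "seed": self.seed,
            "counts": self.counts,
            "truncated": self.truncated,
            "ledger": self.ledger.to_dict(),
        }


def simulate(record: SequenceRecord, config, seed: Optional[int] = None) -> SimulationResult:
    """Run the configured stages over one record.

    ``config`` is a :class:`dnasim.config.RunConfig`.  Stages execute in
    the canonical order regardless of their order in the config; every rule
    is validated before any mutation.  Deterministic under a fixed seed.
    """
    if seed is None:
        seed = config.seed
    by_stage = {s.stage: s for s in config.stages}
    for name, stage_cfg in by_stage.items():
        if stage_cfg.rule is not None:
            violations = validate_rule(stage_cfg.rule)
            if violations:
                raise RuleValidationError(name, violations)

    seq = record.sequence
    origin_map: list[Optional[int]] = list(range(len(seq)))
    all_mods: list[Modification] = []
    truncated = False
    hp_min = config.assessment.homopolymer_min_run

    for index, name in enumerate(STAGE_ORDER):
        stage_cfg = by_stage.get(name)
        if stage_cfg is None:
            continue
        rng = stage_rng(seed, index)
        if stage_cfg.rule is not None:
            rate = effective_rate(
                stage_cfg.rule, name, config.pcr_cycles, config.storage_generations
            )
            seq, mods, stage_truncated = apply_stage(
                seq, origin_map, stage_cfg.rule, name, rng, rate, hp_min
            )
            truncated = truncated or stage_truncated
        else:
            seq, mods = apply_storage_model(seq, origin_map, stage_cfg.model, rng)
        all_mods.extend(mods)

    counts: dict[str, dict[str, int]] = {}
    for m in all_mods:
        counts.setdefault(m.stage, {"insertion": 0, "deletion": 0, "substitution": 0})[m.type] += 1

    output = SequenceRecord(id=record.id, sequence=seq)
    ledger = Ledger(modifications=all_mods, origin_map=origin_map)
    return SimulationResult(
        input=record, output=output, ledger=ledger, seed=seed, counts=counts, truncated=truncated
    )
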