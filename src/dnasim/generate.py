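"""Seeded generators for test sequences, rules and configurations.

Real fixture data is unnecessary for this tool: its inputs are arbitrary
DNA strings and declarative configurations.  These generators produce the
sequence classes that stress each assessment criterion — uniform-random,
GC-skewed, homopolymer-rich and repeat-rich — plus random-but-valid error
rules and run configurations for property and round-trip testing.
"""

from __future__ import annotations

import numpy as np

from .assessment import AssessmentSettings, Motif, ProbabilityFunction
from .config import RunConfig, StageConfig
from .rules import (
    BASES,
    ErrorRule,
    PositionalRule,
    Replacement,
    SubstitutionRule,
    TypeDistribution,
)
from .storage import AwgnStorage, DepurinationStorage, ErasureStorage, KimuraStorage


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random DNA with expected GC fraction ``gc``."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=length, p=p))


def homopolymer_rich_sequence(
    rng: np.random.Generator, length: int, mean_run: float = 5.0
) -> str:
    """Concatenated single-base runs with geometric-ish lengths."""
    parts: list[str] = []
    total = 0
    while total < length:
        run = 1 + int(rng.geometric(1.0 / mean_run))
        base = BASES[int(rng.integers(4))]
        parts.append(base * run)
        total += run
    return "".join(parts)[:length]


def repeat_rich_sequence(
    rng: np.random.Generator, length: int, unit_length: int = 12, n_copies: int = 3
) -> str:
    """Random backbone with one repeat unit pasted in at random offsets."""
    seq = list(random_sequence(rng, length))
    unit = random_sequence(rng, unit_length)
    for _ in range(n_copies):
        start = int(rng.integers(0, max(1, length - unit_length)))
        seq[start : start + unit_length] = unit
    return "".join(seq)[:length]


def _random_distribution(rng: np.random.Generator, n: int) -> list[float]:
    w = rng.dirichlet(np.ones(n))
    w = w / w.sum()
    w[-1] = 1.0 - float(w[:-1].sum())  # exact unit sum for validation
    return [float(x) for x in w]


def random_probability_function(rng: np.random.Generator, lo=0.0, hi=100.0) -> ProbabilityFunction:
    n = int(rng.integers(2, 6))
    xs = np.sort(rng.choice(np.arange(int(lo), int(hi) + 1), size=n, replace=False))
    return ProbabilityFunction(points=[(float(x), float(rng.random())) for x in xs])


def random_rule(rng: np.random.Generator, max_rate: float = 0.05) -> ErrorRule:
    """A random rule that always passes :func:`dnasim.rules.validate_rule`."""
    td = _random_distribution(rng, 3)
    ins = _random_distribution(rng, 4)
    dele = _random_distribution(rng, 4)
    subs = []
    for _ in range(int(rng.integers(0, 3))):
        target = random_sequence(rng, int(rng.integers(1, 4)))
        reps = []
        rep_w = _random_distribution(rng, int(rng.integers(1, 3)))
        for w in rep_w:
            rep = random_sequence(rng, int(rng.integers(1, 4)))
            while rep == target:
                rep = random_sequence(rng, len(target))
            reps.append(Replacement(sequence=rep, weight=w))
        subs.append(SubstitutionRule(target=target, replacements=reps))
    pos_rules = [
        PositionalRule(
            position=int(rng.integers(0, 100)),
            base=BASES[int(rng.integers(4))],
            weight=float(rng.uniform(0, 5)),
        )
        for _ in range(int(rng.integers(0, 2)))
    ]
    return ErrorRule(
        name=f"random_rule_{int(rng.integers(1 << 30))}",
        raw_rate=float(rng.uniform(0, max_rate)),
        type_distribution=TypeDistribution(
            insertion=td[0], deletion=td[1], substitution=td[2]
        ),
        insertion_weights=dict(zip(BASES, ins)),
        deletion_weights=dict(zip(BASES, dele)),
        homopolymer_bias=float(rng.random()),
        substitution_rules=subs,
        positional_rules=pos_rules,
    )


def random_storage_model(rng: np.random.Generator):
    kind = int(rng.integers(4))
    if kind == 0:
        return KimuraStorage(
            alpha=float(rng.uniform(0, 0.05)), beta=float(rng.uniform(0, 0.02)), t=float(rng.uniform(0, 2))
        )
    if kind == 1:
        return DepurinationStorage(
            ph=float(rng.uniform(1, 9)),
            temperature_k=float(rng.uniform(275, 350)),
            duration_s=float(rng.uniform(0, 1e6)),
        )
    if kind == 2:
        return ErasureStorage(p=float(rng.uniform(0, 0.05)))
    return AwgnStorage(sigma=float(rng.uniform(0, 0.8)))


def random_config(rng: np.random.Generator, max_rate: float = 0.05) -> RunConfig:
    """A random valid run configuration with a random subset of stages."""
    stages: list[StageConfig] = []
    for name in ("synthesis", "pcr", "storage", "sequencing"):
        if rng.random() < 0.5:
            continue
        if name == "storage" and rng.random() < 0.5:
            stages.append(StageConfig(stage=name, model=random_storage_model(rng)))
        else:
            stages.append(StageConfig(stage=name, rule=random_rule(rng, max_rate)))
    motifs = [
        Motif(
            pattern=random_sequence(rng, int(rng.integers(4, 8))),
            description="random motif",
            error_probability=float(rng.random()),
            search_both_strands=bool(rng.integers(2)),
        )
        for _ in range(int(rng.integers(0, 3)))
    ]
    assessment = AssessmentSettings(
        gc_window=int(rng.integers(10, 120)),
        gc_function=random_probability_function(rng, 0, 100),
        homopolymer_function=random_probability_function(rng, 2, 30),
        repeat_function=random_probability_function(rng, 8, 60),
        motifs=motifs,
    )
    return RunConfig(
        seed=int(rng.integers(0, 2**31 - 1)),
        pcr_cycles=int(rng.integers(1, 40)),
        storage_generations=int(rng.integers(1, 100)),
        assessment=assessment,
        stages=stages,
    )
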