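"""Simulation engine: error counts, drawing, cross-talk, ledger provenance."""

import math

import numpy as np
import pytest

from dnasim.config import RunConfig, StageConfig
from dnasim.engine import (
    RuleValidationError,
    apply_stage,
    child_seed,
    draw_error,
    effective_rate,
    error_count,
    remap_quality,
    replay,
    simulate,
    stage_rng,
)
from dnasim.generate import random_config, random_sequence
from dnasim.records import SequenceRecord
from dnasim.rules import ErrorRule, Replacement, SubstitutionRule, TypeDistribution
from dnasim.storage import ErasureStorage


def make_rule(**overrides):
    fields = dict(name="r", raw_rate=0.01)
    fields.update(overrides)
    return ErrorRule(**fields)


ONLY = {
    "insertion": TypeDistribution(insertion=1.0, deletion=0.0, substitution=0.0),
    "deletion": TypeDistribution(insertion=0.0, deletion=1.0, substitution=0.0),
    "substitution": TypeDistribution(insertion=0.0, deletion=0.0, substitution=1.0),
}


class TestErrorCount:
    def test_zero_rate(self, rng):
        assert error_count(100, 0.0, rng) == 0

    def test_integral_product_is_deterministic(self, rng):
        assert all(error_count(100, 0.05, rng) == 5 for _ in range(200))

    def test_stochastic_rounding_is_unbiased(self, rng):
        n, rate, reps = 100, 0.013, 100_000
        draws = [error_count(n, rate, rng) for _ in range(reps)]
        mean = np.mean(draws)
        # only the fractional 0.3 is random: Bernoulli(0.3) on top of 1
        sigma = math.sqrt(0.3 * 0.7 / reps)
        assert abs(mean - 1.3) < 3 * sigma


class TestDrawError:
    def test_degenerate_distribution_forces_type(self, rng):
        rule = make_rule(type_distribution=ONLY["deletion"])
        for _ in range(50):
            assert draw_error(rule, "ACGTACGT", rng)[0] == "deletion"

    def test_pattern_substitution_payload(self, rng):
        rule = make_rule(
            type_distribution=ONLY["substitution"],
            substitution_rules=[
                SubstitutionRule(target="CG", replacements=[Replacement(sequence="CA", weight=1.0)])
            ],
        )
        etype, pos, before, after = draw_error(rule, "ACGT", rng)
        assert (etype, pos, before, after) == ("substitution", 1, "CG", "CA")
        seq = "ACGT"
        assert seq[:pos] + after + seq[pos + len(before):] == "ACAT"

    def test_homopolymer_bias_confines_deletions_to_runs(self, rng):
        rule = make_rule(type_distribution=ONLY["deletion"], homopolymer_bias=1.0,
                         deletion_weights={"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0})
        seen = set()
        for _ in range(10_000):
            _, pos, _, _ = draw_error(rule, "AAAATCGC", rng, homopolymer_min_run=3)
            seen.add(pos)
        assert seen == {0, 1, 2, 3}

    def test_position_range_restricts_pattern_sites(self, rng):
        rule = make_rule(
            type_distribution=ONLY["substitution"],
            substitution_rules=[
                SubstitutionRule(target="CG", position_range=(4, 8),
                                 replacements=[Replacement(sequence="TG", weight=1.0)])
            ],
        )
        positions = {draw_error(rule, "ACGTACGT", rng)[1] for _ in range(200)}
        assert positions == {5}  # the CG at 1 is outside [4, 8)

    def test_positional_rule_steers_fallback_substitution(self, rng):
        rule = make_rule(
            type_distribution=ONLY["substitution"],
            positional_rules=[{"position": 3, "base": "T", "weight": 1000.0}],
        )
        draws = [draw_error(rule, "ACGAACGA", rng) for _ in range(300)]
        at3 = [d for d in draws if d[1] == 3]
        assert len(at3) > 250  # weight 1000 vs 7 unit positions
        assert all(d[3] == "T" for d in at3)

    def test_empty_sequence_yields_no_event(self, rng):
        assert draw_error(make_rule(), "", rng) is None


class TestApplyStage:
    def test_zero_rate_is_identity(self, rng):
        origin = list(range(8))
        seq, mods, truncated = apply_stage("ACGTACGT", origin, make_rule(raw_rate=0.0),
                                           "synthesis", rng)
        assert seq == "ACGTACGT" and mods == [] and not truncated
        assert origin == list(range(8))

    def test_stage_stops_when_sequence_empties(self, rng):
        rule = make_rule(raw_rate=1.0, type_distribution=ONLY["deletion"])
        origin = [0, 1]
        seq, mods, truncated = apply_stage("AC", origin, rule, "synthesis", rng)
        # 2 errors budgeted from entry length; both apply, then no truncation needed
        assert seq == "" and len(mods) == 2 and not truncated

    def test_crosstalk_deletion_creates_pattern_for_substitution(self):
        """A deletion forming TAG must be visible to a later TAG->TGG pattern."""
        rule = make_rule(
            raw_rate=0.5,  # length 4 -> exactly 2 error events
            type_distribution=TypeDistribution(insertion=0.0, deletion=0.5, substitution=0.5),
            deletion_weights={"A": 0.0, "C": 1.0, "G": 0.0, "T": 0.0},
            substitution_rules=[
                SubstitutionRule(target="TAG", replacements=[Replacement(sequence="TGG", weight=1.0)])
            ],
        )
        for seed in range(1000):
            rng = stage_rng(seed, 0)
            origin = list(range(4))
            seq, mods, _ = apply_stage("TACG", origin, rule, "synthesis", rng)
            if [m.type for m in mods] == ["deletion", "substitution"]:
                break
        else:  # pragma: no cover
            pytest.fail("no seed produced the deletion-then-substitution order")
        # the deletion of C turns TACG into TAG; the pattern rule then fires on it
        assert mods[0].before == "C" and mods[0].position_current == 2
        assert (mods[1].before, mods[1].after) == ("TAG", "TGG")
        assert seq == "TGG"
        # both modifications trace back to the same original neighbourhood
        assert mods[0].position_original == 2 and mods[1].position_original == 0
        assert replay(mods, "TACG") == "TGG"


class TestSimulate:
    def test_empty_pipeline_is_identity(self):
        record = SequenceRecord(id="x", sequence="ACGTACGT")
        result = simulate(record, RunConfig(seed=5, stages=[]))
        assert result.output.sequence == record.sequence
        assert result.ledger.modifications == []
        assert result.ledger.origin_map == list(range(8))

    def test_seed_determinism_bit_for_bit(self, rng):
        record = SequenceRecord(id="x", sequence=random_sequence(rng, 400))
        config = random_config(rng)
        a = simulate(record, config, seed=99)
        b = simulate(record, config, seed=99)
        assert a.to_dict() == b.to_dict()

    def test_invalid_rule_rejected_before_mutation(self):
        bad = make_rule(raw_rate=2.0)
        config = RunConfig(seed=1, stages=[StageConfig(stage="synthesis", rule=bad)])
        with pytest.raises(RuleValidationError, match="raw_rate"):
            simulate(SequenceRecord(id="x", sequence="ACGT"), config)

    def test_counts_match_ledger_tallies(self, rng):
        record = SequenceRecord(id="x", sequence=random_sequence(rng, 500))
        rule = make_rule(raw_rate=0.05)
        config = RunConfig(seed=3, stages=[
            StageConfig(stage="synthesis", rule=rule),
            StageConfig(stage="storage", model=ErasureStorage(p=0.02)),
        ])
        result = simulate(record, config)
        for stage, by_type in result.counts.items():
            for etype, n in by_type.items():
                matching = [m for m in result.ledger.modifications
                            if m.stage == stage and m.type == etype]
                assert len(matching) == n

    def test_length_conservation_from_ledger(self, rng):
        record = SequenceRecord(id="x", sequence=random_sequence(rng, 300))
        config = random_config(rng, max_rate=0.1)
        result = simulate(record, config, seed=11)
        delta = sum(len(m.after) - len(m.before) for m in result.ledger.modifications)
        assert len(result.output.sequence) == len(record.sequence) + delta
        assert len(result.ledger.origin_map) == len(result.output.sequence)

    def test_ledger_replay_over_random_simulations(self, rng):
        for _ in range(200):
            seq = random_sequence(rng, int(rng.integers(10, 200)))
            config = random_config(rng, max_rate=0.1)
            result = simulate(SequenceRecord(id="x", sequence=seq), config,
                              seed=int(rng.integers(2**31)))
            assert replay(result.ledger.modifications, seq) == result.output.sequence

    def test_origin_map_points_back_to_input(self, rng):
        seq = random_sequence(rng, 200)
        config = random_config(rng, max_rate=0.05)
        result = simulate(SequenceRecord(id="x", sequence=seq), config, seed=17)
        for orig in result.ledger.origin_map:
            if orig is not None:
                assert 0 <= orig < len(seq)
        # every surviving original index appears at most once
        survivors = [o for o in result.ledger.origin_map if o is not None]
        assert len(survivors) == len(set(survivors))

    def test_stage_stream_independence(self, rng):
        """Adding a later stage must not change an earlier stage's draws."""
        record = SequenceRecord(id="x", sequence=random_sequence(rng, 300))
        synth = make_rule(raw_rate=0.03)
        base = RunConfig(seed=8, stages=[StageConfig(stage="synthesis", rule=synth)])
        extended = RunConfig(seed=8, stages=[
            StageConfig(stage="synthesis", rule=synth),
            StageConfig(stage="sequencing", rule=make_rule(raw_rate=0.03)),
        ])
        mods_base = simulate(record, base).ledger.modifications
        mods_ext = [m for m in simulate(record, extended).ledger.modifications
                    if m.stage == "synthesis"]
        assert mods_base == mods_ext


class TestRateCalibration:
    def test_pooled_error_count_and_type_proportions(self, rng):
        length, rate, reps = 1000, 0.01, 300
        rule = make_rule(raw_rate=rate)
        config = RunConfig(seed=0, stages=[StageConfig(stage="sequencing", rule=rule)])
        record = SequenceRecord(id="x", sequence=random_sequence(rng, length))
        totals = {"insertion": 0, "deletion": 0, "substitution": 0}
        n_errors = 0
        for i in range(reps):
            result = simulate(record, config, seed=i)
            for etype, n in result.counts.get("sequencing", {}).items():
                totals[etype] += n
                n_errors += n
        mean = n_errors / reps
        sigma = math.sqrt(length * rate * (1 - rate) / reps)
        assert abs(mean - length * rate) < 3 * sigma
        for etype, n in totals.items():
            prop_sigma = math.sqrt((1 / 3) * (2 / 3) / n_errors)
            assert abs(n / n_errors - 1 / 3) < 4 * prop_sigma, etype

    def test_pcr_rate_compounds_over_cycles(self):
        rule = make_rule(raw_rate=0.001)
        assert effective_rate(rule, "pcr", pcr_cycles=30) == pytest.approx(
            1 - (1 - 0.001) ** 30
        )
        assert effective_rate(rule, "synthesis") == 0.001


class TestSeeding:
    def test_child_seeds_are_stable_and_bounded(self):
        seeds = [child_seed(42, i) for i in range(10)]
        assert seeds == [child_seed(42, i) for i in range(10)]
        assert len(set(seeds)) == 10
        assert all(0 <= s < 2**31 for s in seeds)


def test_remap_quality_marks_insertions_untrusted():
    # output positions: orig 0, inserted, orig 2
    assert remap_quality([0, None, 2], [0.1, 0.2, 0.3]) == [0.1, 1.0, 0.3]
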