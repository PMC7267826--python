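# Methods

This note documents the models behind `dnasim`, the conventions chosen
where the design was genuinely open, and what the test suite does and does
not demonstrate.

## Assessment model

Each criterion produces regions `[start, end)` (0-based, half-open
everywhere internally; human-readable output renders 1-based) with an
error probability, and the per-base vector is the **capped sum**
`per_base[i] = min(1, Σ p(region ∋ i))`. Summation reflects the view that
each flagged feature contributes its own independent failure chance;
capping (rather than renormalising or combining as `1−Π(1−p)`) keeps the
displayed numbers equal to the user's configured function values wherever
regions do not overlap.

**Probability functions.** Piecewise-linear maps from a feature value to a
probability, linear between points, constant beyond the endpoints.
Evaluation at a stored x returns the stored p exactly. Domains: GC in
percent (0–100); homopolymer and repeat functions in bases. The same GC
function scores both the tiling windows and the whole sequence.

**Windows.** GC windows tile without overlap, `[0,w), [w,2w), …`, the last
window possibly shorter and evaluated as-is; one whole-sequence GC region
is added (deduplicated when the window equals the sequence length).
Tiling is the simplest reproducible choice and keeps region boundaries
predictable for downstream tools.

**Homopolymers.** Maximal runs of one base, default minimum run 3 —
short enough to flag the runs Illumina/Nanopore chemistry starts to
mis-call, long enough not to drown the report.

**Repeats.** Exact matches only, no mismatches or inverted repeats,
default minimum length 8. A pair `(start1, start2, length)` is reported
when it is left-maximal (`seq[start1−1] ≠ seq[start2−1]`), `length` is the
maximal right extension, and the occurrences do not overlap
(`start2 ≥ start1 + length`). The non-overlap condition excludes
self-similar shifts inside homopolymers and short tandem arrays, which the
homopolymer criterion already covers; both occurrence intervals receive
the repeat probability. The brute-force oracle used in tests enumerates
the same definition from all substrings, independently of the scanner.

**Motifs.** Literal patterns with per-motif probabilities; overlapping
occurrences all count. Both-strand search reports reverse-complement hits
in forward coordinates with strand `-`; palindromes deduplicate to one
`+` hit. The default panel is eight common 6–8-cutter cloning sites at
p = 0.1 each — an editable starting point, not a measurement.

## Simulation engine

Stages always execute in wet-lab order synthesis → PCR → storage →
sequencing; absent stages are skipped.

**Error count.** Per stage, `n = length × effective_rate` with
*stochastic rounding*: `⌊n⌋` errors plus one more with probability equal
to the fractional part, making the expectation exact (truncation would
bias low). Products within 1e−9 of an integer are treated as exact so
that, e.g., 100 × 0.05 is deterministically 5 despite float round-off.
The count is fixed from the stage-entry length; subsequent indels do not
re-size it.

**PCR and storage compounding.** PCR rules carry a per-cycle rate and
host-organism storage presets a per-generation rate; both compound as
`1 − (1 − r)^n` (`pcr_cycles`, `storage_generations` in the config) and
are applied in one pass. This is equivalent in expectation to
cycle-by-cycle resampling and far cheaper.

**Drawing one error.** Type from the rule's insertion/deletion/
substitution weights. Insertions and deletions draw their base from the
rule's per-base weights; with probability `homopolymer_bias` the position
is uniform over bases inside maximal homopolymer runs (runs of the drawn
base, for deletions), otherwise uniform over the sequence; deletions
outside homopolymers prefer positions holding the drawn base. Whenever a
biased or restricted candidate set is empty — e.g. the drawn base has no
homopolymer run — the position falls back to uniform over the whole
sequence rather than silently dropping the event, which would break rate
calibration. Substitutions first look for matches of the rule's context
patterns (respecting each pattern's positional range, interpreted on the
match start); one `(site, pattern)` pair is chosen uniformly among matches
and the replacement by its weights. With no admissible match, a
single-base substitution is drawn, positional rules acting as position
weight multipliers that also steer the replacement base (falling back to
a uniform different base when the positional rule names the base already
present). Variable-length replacements (target and replacement of
different lengths) are permitted; the coordinate map absorbs the shift.

**Cross-talk.** Events are applied one at a time against the *current*
sequence, so each draw sees all earlier edits — a deletion that forms a
high-error triplet exposes that triplet to later pattern substitutions.
The test suite constructs this directly: on `TACG`, deleting `C` yields
`TAG`, and a `TAG→TGG` rule then fires on it.

**Provenance ledger.** Every modification records stage, type, the
position at application time, the original-coordinate position (or an
inserted marker), and before/after strings. A parallel origin map carries
output-position → input-position (None for inserted bases). Replaying the
ledger against the input must reproduce the output exactly; this is
asserted over thousands of random simulations. Deletions remove the base
from sequence output (FASTQ has no way to render a gap); the ledger is
the lossless machine-readable record of where they occurred.

**Seeding.** One root integer seed. Stage *i* of the canonical order
draws from `SeedSequence(seed, spawn_key=(i,))` (PCG64), so adding or
removing one stage does not perturb the other stages' streams. The CLI
derives one child seed per FASTA record from (root seed, record index) the
same way, making multi-record runs order-stable and parallelizable. No OS
entropy is ever consulted; a reported seed is sufficient to reproduce a
run bit-for-bit.

**Quality of simulated reads.** The mutated FASTQ's quality line is the
input assessment's per-base probability remapped through the origin map;
bases the simulation inserted get p = 1 (quality `!`). This is a
convention — the probability of *future* errors at a position is taken to
travel with the original base.

## Storage models

**Depurination.** Rate law in pH and absolute temperature (Kelvin),
two branches with the boundary pH 2.5 on the second branch:

    pH <  2.5:  lg k = 14.6 − 0.707·pH − 5.63e3/T
    pH ≥  2.5:  lg k = 16.5 − 0.982·pH − 5.85e3/T

with k in events per base per second. Over duration d each purine (A/G)
is lost independently with probability `1 − exp(−k·d)`; pyrimidines are
never touched. A lost purine is realized as a **deletion**: an abasic
site has no representation in a strict ACGT alphabet, and deletion is its
conservative sequencing-visible consequence (a substitution-to-random
convention could be configured via a rule-based stage instead).

**Kimura two-parameter (K80).** α the transition rate (A↔G, C↔T), β the
rate of each of the two transversions, per site per unit time:

    P(transition)        = 1/4 + 1/4·e^{−4βt} − 1/2·e^{−2(α+β)t}
    P(each transversion) = 1/4 − 1/4·e^{−4βt}

applied i.i.d. per site from the matrix row (K80 is site-independent).
t = 0 gives the identity; α = β reduces to Jukes–Cantor; the closed form
is checked against a matrix-exponential oracle of the independently
constructed rate matrix to 1e−9 over a parameter grid.

**Binary erasure channel.** Each base erased independently with
probability p. Erasures delete (no `N` placeholder, by the strict-alphabet
decision); the ledger preserves every erased position.

**AWGN channel.** Fixed PAM-4-style mapping A,C,G,T → −3,−1,+1,+3, i.i.d.
Gaussian noise of standard deviation σ, re-quantization at thresholds
−2, 0, +2. Only substitutions can result and adjacent-level substitutions
dominate (Gaussian tails are monotone), e.g. at σ = 1,
P(A→C) = Φ̄(1) − Φ̄(3) ≈ 0.1574.

## Presets

22 presets ship as editable JSON package data: 8 synthesis-platform ×
error-correction combinations, 4 PCR polymerases (per-cycle rates), 6
sequencing technologies (with their context substitution patterns and an
Illumina paired-end positional rule), 4 host organisms (per-generation
rates). Each file carries a `source` citation; the numeric rates are
representative editable values for the cited literature, and nothing in
the package's correctness depends on them — tests assert structure
(patterns present, distributions valid), never the numbers.

## Formats and configuration

FASTA ingest is strict: the alphabet is exactly {A,C,G,T} (lowercase
normalized; N and other IUPAC codes rejected with record and position),
empty records rejected. FASTQ output uses Q = round(−10·log₁₀ p) clamped
to [0, 93]: p ≥ 1 → `!`, p ≤ 10^−9.3 (including 0) → `~`, the printable
Sanger/Illumina 1.8+ range. The configuration JSON carries a top-level
`format_version`; unknown versions are rejected, unknown keys warned and
ignored, and serialize→deserialize is the identity (property-tested over
random configurations). A generated JSON Schema ships under
`dnasim/schema/` for external validators.

## Synthetic test data

The generators in `dnasim.generate` produce uniform-random, GC-skewed,
homopolymer-rich and repeat-rich sequences plus random valid rules and
configurations. They emulate composition features, not real reads: no
quality-by-position profiles, no fragment-length or coverage structure, no
chimeras. Passing tests therefore demonstrate the *mechanics* —
calibration, determinism, provenance, closed-form model correctness — on
the stated composition classes, not that any preset reproduces a
particular instrument's empirical error spectrum.

## Problem sizes and numerical choices

The test suite and acceptance script use sequences up to a few hundred
bases for oracle comparisons (the brute-force oracles are quadratic to
cubic), 1000 replicates × length 1000 for rate calibration, 10⁵–10⁶
symbols for channel statistics and thousands of random simulations for
ledger soundness — sizes at which the statistical bands (3σ binomial) are
tight while the whole suite stays fast. Distribution sums are validated to
1e−9; Kimura rows sum to 1 within 1e−12; ties among equally weighted
substitution sites break uniformly using the stage's own stream.

## Known limitations

* No secondary-structure or melting-temperature assessment.
* Repeats are exact and direct only (no near-repeats, no inverted
  repeats).
* The storage stage applies exactly one model; combining depurination
  with host mutation requires two runs or a rule-based approximation.
* Evolutionary models beyond K80 (HKY, GTR, rate heterogeneity) are out
  of scope, as are paired-end read geometry and quality-by-position
  error profiles.
* A stage that deletes the entire sequence stops early and is flagged
  (`truncated`); budgeted but unplaced errors are not carried into later
  stages.
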