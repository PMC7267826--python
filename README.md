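# dnasim

Assessment of synthetic DNA fragments and seeded simulation of the errors
introduced by DNA synthesis, PCR, storage and sequencing.

Designing synthetic DNA — for cloning, gene synthesis or DNA data storage —
means staying inside the tolerances of every process the molecule will pass
through. Extreme GC content, homopolymer runs, repeated subsequences and
motifs with biological activity (restriction sites, for instance) all raise
error rates during synthesis, amplification and sequencing. `dnasim` does
two things about that:

* **Assessment** — scores every base of a fragment with an error
  probability derived from four criteria (GC content over tiling windows
  and the whole sequence, homopolymer run length, exact repeats, undesired
  motifs), each driven by a user-editable piecewise-linear probability
  function. Overlapping region probabilities add (capped at 1), and the
  per-base vector is written as a PHRED quality line
  (Q = −10·log₁₀ p, ASCII offset 33), so the report is an ordinary FASTQ
  file.
* **Simulation** — applies an ordered pipeline of error stages
  (synthesis → PCR → storage → sequencing). Each stage is a declarative
  `ErrorRule`: a raw per-base error rate, an insertion/deletion/substitution
  split, per-base weights, a homopolymer bias, context substitution
  patterns (e.g. PacBio `CG→CA`, Nanopore `TAG→TGG`, Illumina `GGG→GGT`)
  and positional weights. Errors are drawn and applied **sequentially**, so
  an early deletion can create the context a later pattern rule then hits
  (cross-talk). The storage stage can instead use a physical model: in
  vitro depurination (pH/temperature rate law), the Kimura two-parameter
  substitution model, a binary erasure channel, or an AWGN channel over the
  level mapping A,C,G,T → −3,−1,+1,+3.

Every simulated edit is recorded in a provenance ledger mapping mutated
positions back to original coordinates; replaying the ledger reproduces the
output exactly. A single integer seed makes whole runs bit-for-bit
reproducible (each stage and each FASTA record gets an independent derived
stream), and the complete configuration round-trips through versioned JSON.

## Worked example

Assess a fragment, then simulate Nanopore 1D sequencing over it:

```sh
$ printf '>fragment1\nACGGGGGGGGGCATGAATTCTTACGTAGCATCGGATCAGGCTAACGGTAC\n' > demo.fasta
$ dnasim assess --input demo.fasta --out-fastq demo_assessed.fastq --out-report demo_report.json
$ cat demo_assessed.fastq
@fragment1
ACGGGGGGGGGCATGAATTCTTACGTAGCATCGGATCAGGCTAACGGTAC
+
~~#########~~~++++++~~~~~~~~~~~~~~~~~~~~~~~~~~~~~~
```

The quality line *is* the assessment: `#` (Q=2, p≈0.63) marks the
9-base G homopolymer, `+` (Q=10, p=0.1) the EcoRI site `GAATTC`, and `~`
(Q=93) bases with no flagged risk. `demo_report.json` lists the same
regions with coordinates and criteria.

```sh
$ dnasim simulate --input demo.fasta --config demo_config.json --seed 17 \
      --out-fastq demo_sim.fastq --out-ledger demo_ledger.json
$ cat demo_sim.fastq
@fragment1
ACGGGCGGGCGGGCATGAATTCTTGCGTGGATCGGATCAGGCTAACGGTGC
+
~~###!###!###~~~++++++~~~~~~~~~~~~~~~~~~~~~~~~~~~~~
```

(`demo_config.json` is the serialized default configuration with one
sequencing stage using the `nanopore_1d` preset; write it with
`serialize_config` or edit `dnasim presets show nanopore_1d`.) With seed 17
this run drew 6 errors — 2 insertions, 1 deletion, 3 substitutions — and
the technology's context patterns are visible: both `TAC` sites became
`TGC` and a `TAG` became `TGG`. Inserted bases carry quality `!` (p = 1);
all other qualities are the input assessment's, remapped through the
indels. The ledger records each modification with its stage, type, both
coordinate systems and before/after strings, e.g.:

```json
{"stage": "sequencing", "type": "substitution", "position_current": 27,
 "position_original": 25, "before": "TAG", "after": "TGG"}
```

Re-running with the same `--seed 17` reproduces all outputs byte-for-byte.

Other verbs:

```sh
$ dnasim depurination-rate --ph 7 --temp-kelvin 310.15
lg k = -9.235841
k = 5.809770e-10 per base per second
$ dnasim presets list        # 22 editable presets: synthesis platforms,
                             # polymerases, sequencers, host organisms
```

## Library use

```python
from dnasim import (RunConfig, StageConfig, SequenceRecord,
                    assess, simulate, preset_registry, replay)

report = assess("ACGGGGGGGGGCAT")           # per-base probabilities
rule = preset_registry()["pacbio_subread"]
cfg = RunConfig(seed=1, stages=[StageConfig(stage="sequencing", rule=rule)])
result = simulate(SequenceRecord(id="s", sequence="ACGT" * 50), cfg)
assert replay(result.ledger.modifications, result.input.sequence) == result.output.sequence
```

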