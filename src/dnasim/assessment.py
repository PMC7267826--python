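"""Per-base error-probability assessment of DNA fragments.

Four criteria known to limit synthesis, PCR, cloning and sequencing are
scored: GC content (whole sequence and tiling windows), homopolymer runs,
exact repeated subsequences, and undesired motifs (restriction sites and
other biologically relevant patterns).  Each criterion yields regions with
an error probability; overlapping regions combine by capped addition into a
per-base probability vector that can be written out as a FASTQ quality line.

Coordinates are 0-based half-open throughout; they are rendered 1-based only
in human-readable output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from .records import VALID_BASES, reverse_complement


class ProbabilityFunction(BaseModel):
    """Piecewise-linear map from a scalar sequence feature to an error probability.

    ``points`` are (x, p) pairs with strictly increasing x and p in [0, 1];
    evaluation interpolates linearly between points and extrapolates
    constantly at the endpoints.  The x axis is GC percent (0-100) for the GC
    criterion and a length in bases for the homopolymer and repeat criteria.
    """

    model_config = ConfigDict(extra="ignore")

    points: list[tuple[float, float]]

    @field_validator("points")
    @classmethod
    def _check_points(cls, points):
        if len(points) < 2:
            raise ValueError("a probability function needs at least 2 points")
        xs = [x for x, _ in points]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("x values must be strictly increasing")
        if any(not (0.0 <= p <= 1.0) for _, p in points):
            raise ValueError("probabilities must lie in [0, 1]")
        return [(float(x), float(p)) for x, p in points]

    def __call__(self, x: float) -> float:
        xs = [pt[0] for pt in self.points]
        ps = [pt[1] for pt in self.points]
        return float(np.interp(x, xs, ps))


class Motif(BaseModel):
    """An undesired DNA pattern with an attached error probability.

    With ``search_both_strands`` the reverse complement is searched too and
    hits are reported in forward coordinates with strand '-'.
    """

    model_config = ConfigDict(extra="ignore")

    pattern: str
    description: str = ""
    error_probability: float = 0.1
    search_both_strands: bool = True

    @field_validator("pattern")
    @classmethod
    def _check_pattern(cls, pattern: str) -> str:
        pattern = pattern.upper()
        if not pattern or any(c not in VALID_BASES for c in pattern):
            raise ValueError("motif pattern must be a non-empty A/C/G/T string")
        return pattern

    @field_validator("error_probability")
    @classmethod
    def _check_prob(cls, p: float) -> float:
        if not (0.0 <= p <= 1.0):
            raise ValueError("error_probability must lie in [0, 1]")
        return p


@dataclass(frozen=True)
class Region:
    """One scored region: [start, end) on the input sequence."""

    start: int
    end: int
    criterion: str  # "gc" | "homopolymer" | "repeat" | "motif"
    probability: float
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "start": self.start,
            "end": self.end,
            "criterion": self.criterion,
            "probability": self.probability,
            "note": self.note,
        }


@dataclass
class AssessmentReport:
    """All scored regions plus the aggregated per-base probability vector.

    ``per_base[i]`` is min(1, sum of probabilities of regions covering i):
    individual criterion probabilities add per region and are capped at 1,
    since independent penalty sums may exceed the probability range.
    """

    sequence_length: int
    regions: list[Region]
    per_base: np.ndarray

    def regions_by_criterion(self, criterion: str) -> list[Region]:
        return [r for r in self.regions if r.criterion == criterion]

    def to_dict(self) -> dict:
        return {
            "sequence_length": self.sequence_length,
            "regions": [r.to_dict() for r in self.regions],
            "per_base": [float(p) for p in self.per_base],
        }


# --------------------------------------------------------------------------
# Criterion primitives
# --------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    """Fraction of G+C bases; contract violation on an empty sequence."""
    if not seq:
        raise ValueError("gc_content of an empty sequence is undefined")
    return (seq.count("G") + seq.count("C")) / len(seq)


def tile_windows(length: int, window: int) -> list[tuple[int, int]]:
    """Non-overlapping tiling [0,w), [w,2w), ... with a final partial window."""
    if window < 1:
        raise ValueError("window length must be >= 1")
    return [(s, min(s + window, length)) for s in range(0, length, window)]


def windowed_gc(
    seq: str, window: int, fn: ProbabilityFunction
) -> list[tuple[int, int, float]]:
    """Evaluate the GC probability function on tiling windows and whole sequence.

    Each window [s, e) is scored as fn(100 * gc_content(seq[s:e])); one
    whole-sequence region is appended unless the single window already covers
    the full sequence.  The function's domain is GC percent.
    """
    if not 1 <= window <= len(seq):
        raise ValueError(f"window must be in [1, {len(seq)}], got {window}")
    out = [
        (s, e, fn(100.0 * gc_content(seq[s:e]))) for s, e in tile_windows(len(seq), window)
    ]
    if out[0][1] != len(seq) or len(out) > 1:
        out.append((0, len(seq), fn(100.0 * gc_content(seq))))
    return out


def find_homopolymers(
    seq: str, min_length: int = 3
) -> list[tuple[int, int, str, int]]:
    """Maximal single-nucleotide runs of length >= ``min_length``.

    Returns (start, end, base, run_length), ordered by start.  Only maximal
    runs are reported: no run contained in a longer run of the same base.
    """
    out = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_length:
            out.append((i, j, seq[i], j - i))
        i = j
    return out


def find_repeats(
    seq: str, min_length: int = 8, window: Optional[int] = None
) -> list[tuple[int, int, int]]:
    """Exact repeated subsequences of length >= ``min_length``.

    A repeat pair is reported as (start1, start2, length) with start1 <
    start2, under three conditions: the pair is *left-maximal*
    (seq[start1-1] != seq[start2-1] or start1 == 0), ``length`` is the
    maximal common extension to the right, and the two occurrences do not
    overlap (start2 >= start1 + length).  Self-overlapping matches, i.e.
    shifted copies inside a homopolymer or short tandem array, are the
    homopolymer detector's job and are excluded here.

    With ``window``, the search runs independently inside each tiling window
    and coordinates are reported on the full sequence.
    """
    if window is not None:
        out = []
        for s, e in tile_windows(len(seq), window):
            for a, b, l in find_repeats(seq[s:e], min_length):
                out.append((a + s, b + s, l))
        return out

    n = len(seq)
    out = []
    for i in range(n - 2 * min_length + 1):
        for j in range(i + min_length, n - min_length + 1):
            if i > 0 and seq[i - 1] == seq[j - 1]:
                continue  # not left-maximal: part of a longer pair
            if seq[i] != seq[j]:
                continue
            length = 1
            while j + length < n and seq[i + length] == seq[j + length]:
                length += 1
            if length >= min_length and j >= i + length:
                out.append((i, j, length))
    return out


def scan_motifs(
    seq: str, motifs: Sequence[Motif]
) -> list[tuple[int, int, Motif, str]]:
    """All (overlapping) occurrences of each motif; optionally both strands.

    Reverse-complement hits are reported in forward coordinates with strand
    '-'.  For palindromic motifs the '+' and '-' hits coincide and are
    deduplicated, keeping '+'.
    """
    out = []
    for motif in motifs:
        hits: dict[tuple[int, int], str] = {}
        for strand, pattern in (("+", motif.pattern), ("-", reverse_complement(motif.pattern))):
            if strand == "-" and not motif.search_both_strands:
                continue
            start = seq.find(pattern)
            while start != -1:
                key = (start, start + len(pattern))
                hits.setdefault(key, strand)  # '+' searched first, so it wins ties
                start = seq.find(pattern, start + 1)
        for (s, e), strand in sorted(hits.items()):
            out.append((s, e, motif, strand))
    return out


# --------------------------------------------------------------------------
# Aggregation
# --------------------------------------------------------------------------

class AssessmentSettings(BaseModel):
    """Tunable parameters of the assessment.

    Defaults flag the regions practitioners adjust for: GC outside the
    40-60% band, runs of >= 3 identical bases, exact repeats of >= 8 bp and
    a panel of common cloning sites.
    """

    model_config = ConfigDict(extra="ignore")

    gc_window: int = 50
    gc_function: ProbabilityFunction = ProbabilityFunction(
        points=[(0, 0.9), (30, 0.2), (40, 0.0), (60, 0.0), (70, 0.2), (100, 0.9)]
    )
    homopolymer_min_run: int = 3
    homopolymer_function: ProbabilityFunction = ProbabilityFunction(
        points=[(2, 0.0), (3, 0.05), (6, 0.4), (10, 0.8), (20, 1.0)]
    )
    repeat_min_length: int = 8
    repeat_function: ProbabilityFunction = ProbabilityFunction(
        points=[(8, 0.2), (15, 0.5), (30, 0.9)]
    )
    motifs: list[Motif] = [
        Motif(pattern="GAATTC", description="EcoRI restriction site"),
        Motif(pattern="GGATCC", description="BamHI restriction site"),
        Motif(pattern="AAGCTT", description="HindIII restriction site"),
        Motif(pattern="CTCGAG", description="XhoI restriction site"),
        Motif(pattern="GCGGCCGC", description="NotI restriction site"),
        Motif(pattern="TCTAGA", description="XbaI restriction site"),
        Motif(pattern="CTGCAG", description="PstI restriction site"),
        Motif(pattern="GTCGAC", description="SalI restriction site"),
    ]


def assess(seq: str, settings: AssessmentSettings | None = None) -> AssessmentReport:
    """Run all four criteria and aggregate regions into a per-base vector.

    per_base[i] = min(1, sum of probabilities of all regions covering i).
    Deterministic: identical (seq, settings) give an identical report.
    """
    if settings is None:
        settings = AssessmentSettings()
    if not seq:
        raise ValueError("cannot assess an empty sequence")
    regions: list[Region] = []

    window = min(settings.gc_window, len(seq))
    for s, e, p in windowed_gc(seq, window, settings.gc_function):
        note = "whole sequence" if (s, e) == (0, len(seq)) and window != len(seq) else "window"
        regions.append(Region(s, e, "gc", p, note))

    for s, e, base, run in find_homopolymers(seq, settings.homopolymer_min_run):
        regions.append(
            Region(s, e, "homopolymer", settings.homopolymer_function(run), f"{base}x{run}")
        )

    for s1, s2, length in find_repeats(seq, settings.repeat_min_length):
        p = settings.repeat_function(length)
        regions.append(Region(s1, s1 + length, "repeat", p, f"mate at {s2}"))
        regions.append(Region(s2, s2 + length, "repeat", p, f"mate at {s1}"))

    for s, e, motif, strand in scan_motifs(seq, settings.motifs):
        label = motif.description or motif.pattern
        regions.append(Region(s, e, "motif", motif.error_probability, f"{label} ({strand})"))

    per_base = np.zeros(len(seq))
    for r in regions:
        per_base[r.start : r.end] += r.probability
    np.minimum(per_base, 1.0, out=per_base)
    return AssessmentReport(sequence_length=len(seq), regions=regions, per_base=per_base)
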