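"""Sequence records, FASTA/FASTQ input/output and PHRED quality encoding.

The unit of all I/O is :class:`SequenceRecord`: an identifier, a DNA string
over the strict alphabet {A, C, G, T}, and an optional per-base error
*probability* vector.  Probabilities are converted to PHRED quality scores
(Q = -10 log10 p) only at the FASTQ boundary, using the Sanger/Illumina 1.8+
ASCII-33 offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from Bio import SeqIO

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Largest printable PHRED score ('~' = ASCII 126); probabilities below
#: 10**-9.3 clamp here.
MAX_PHRED = 93


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input (bad header, empty record)."""


class AlphabetError(ValueError):
    """Raised when a sequence contains a symbol outside {A, C, G, T}.

    Ambiguity codes (N and the other IUPAC letters) are rejected on purpose:
    every downstream model — base weights, substitution patterns, the Kimura
    matrix, the AWGN level mapping — is defined on exactly four symbols.
    """

    def __init__(self, record_id: str, position: int, char: str):
        self.record_id = record_id
        self.position = position  # 0-based
        self.char = char
        super().__init__(
            f"record '{record_id}': invalid character {char!r} at position "
            f"{position + 1} (only A/C/G/T are accepted; ambiguity codes such "
            f"as N must be resolved before analysis)"
        )


def _first_invalid(seq: str) -> int:
    for i, c in enumerate(seq):
        if c not in VALID_BASES:
            return i
    return -1


@dataclass
class SequenceRecord:
    """One DNA sequence with optional per-base error probabilities.

    ``sequence`` is uppercased on construction and must contain only
    A/C/G/T.  ``quality`` holds error *probabilities* in [0, 1] (not PHRED
    integers) and, when present, must match the sequence length.  An empty
    sequence is representable (a simulation stage may delete every base);
    :func:`read_fasta` rejects empty input records at ingest.
    """

    id: str
    sequence: str
    quality: list[float] | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = _first_invalid(self.sequence)
        if bad >= 0:
            raise AlphabetError(self.id, bad, self.sequence[bad])
        if self.quality is not None:
            self.quality = [float(p) for p in self.quality]
            if len(self.quality) != len(self.sequence):
                raise ValueError(
                    f"record '{self.id}': quality vector length "
                    f"{len(self.quality)} != sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-record) FASTA file into :class:`SequenceRecord` objects.

    Order is preserved and lowercase bases are uppercased.  Raises
    :class:`FastaParseError` for malformed or empty input and
    :class:`AlphabetError` (naming record and position) for non-ACGT symbols.
    """
    path = Path(path)
    try:
        with open(path) as handle:
            parsed = list(SeqIO.parse(handle, "fasta"))
    except ValueError as exc:  # Biopython: header/structure problems
        raise FastaParseError(f"{path}: {exc}") from exc
    if not parsed:
        raise FastaParseError(f"{path}: no FASTA records found")
    records: list[SequenceRecord] = []
    for index, rec in enumerate(parsed):
        seq = str(rec.seq)
        if not seq:
            raise FastaParseError(
                f"{path}: record {index} ('{rec.id}') has an empty sequence"
            )
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.sequence}\n")


# --------------------------------------------------------------------------
# PHRED encoding
# --------------------------------------------------------------------------

def prob_to_phred(p: float) -> int:
    """Map an error probability to an integer PHRED score, clamped to [0, 93].

    Q = round(-10 log10 p).  p >= 1 clamps to Q=0 ('!'); p <= 10**-9.3
    (including p = 0) clamps to Q=93 ('~'), the top of the printable
    Sanger/Illumina 1.8+ range.
    """
    if p >= 1.0:
        return 0
    if p <= 0.0:
        return MAX_PHRED
    q = round(-10.0 * math.log10(p))
    return max(0, min(MAX_PHRED, int(q)))


def prob_to_qchar(p: float) -> str:
    return chr(33 + prob_to_phred(p))


def phred_to_prob(q: int) -> float:
    return 10.0 ** (-q / 10.0)


def write_fastq(
    records: Iterable[SequenceRecord],
    path: str | Path,
    encode: Callable[[float], str] = prob_to_qchar,
) -> None:
    """Write records as 4-line FASTQ, encoding error probabilities as quality.

    Every record must carry a quality vector; a missing one is a contract
    violation.  ``encode`` maps one probability to one quality character
    (default: ASCII-33 PHRED).
    """
    with open(path, "w") as handle:
        for rec in records:
            if rec.quality is None:
                raise ValueError(
                    f"record '{rec.id}' has no quality vector; FASTQ output "
                    "requires per-base error probabilities"
                )
            qline = "".join(encode(p) for p in rec.quality)
            handle.write(f"@{rec.id}\n{rec.sequence}\n+\n{qline}\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read FASTQ; PHRED scores become error probabilities 10**(-Q/10)."""
    records = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            probs = [phred_to_prob(q) for q in rec.letter_annotations["phred_quality"]]
            records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq), quality=probs))
    return records
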