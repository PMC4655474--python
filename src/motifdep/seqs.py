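"""Sequence containers and FASTA input/output.

Two containers drive the whole pipeline: :class:`BindingSiteSet`, the aligned
equal-length binding sequences of one transcription factor (the positive
training set), and :class:`Genome`, the chromosome used for background
estimation, candidate scanning and negative-set construction.

Motif positions are 1-based everywhere a user sees them ("C2" is cytosine at
the second motif position); genome coordinates are 0-based half-open
internally and only converted on report/export.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
#: integer encoding used throughout: A=0, C=1, G=2, T=3, N/other=-1
_ENCODE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    """A sequence contains characters outside the expected DNA alphabet."""


class LengthMismatchError(ValueError):
    """Aligned binding sites do not all share one width."""


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 indices (A=0,C=1,G=2,T=3, other=-1)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    out = np.full(arr.shape, ord("N"), dtype=np.uint8)
    for b, i in BASE_INDEX.items():
        out[arr == i] = ord(b)
    return out.tobytes().decode("ascii")


@dataclass(frozen=True)
class BindingSiteSet:
    """Aligned, equal-length binding sequences of one TF (the positive set)."""

    tf_name: str
    sequences: tuple[str, ...]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("a binding site set needs at least 2 sequences")
        object.__setattr__(self, "sequences", tuple(s.upper() for s in self.sequences))
        L = len(self.sequences[0])
        if L < 2:
            raise ValueError("motif width must be at least 2")
        for i, s in enumerate(self.sequences):
            if len(s) != L:
                raise LengthMismatchError(
                    f"record {i} ({s!r}) has length {len(s)}, expected {L}"
                )
            if any(c not in BASE_INDEX for c in s):
                bad = next(c for c in s if c not in BASE_INDEX)
                raise AlphabetError(
                    f"record {i} contains non-ACGT character {bad!r}"
                )
        object.__setattr__(self, "length", L)

    def __len__(self) -> int:
        return len(self.sequences)

    def as_array(self) -> np.ndarray:
        """(n, L) int8 matrix of base indices."""
        return np.vstack([encode(s) for s in self.sequences])

    @property
    def gc_fraction(self) -> float:
        arr = self.as_array()
        return float(np.mean((arr == 1) | (arr == 2)))


@dataclass(frozen=True)
class Genome:
    """One scanning target: a DNA string over {A,C,G,T,N}.

    Multi-record FASTA inputs are concatenated with single ``N`` separators so
    that no scanning window spans a record boundary; ``record_bounds`` maps
    concatenated coordinates back to the source records.
    """

    id: str
    sequence: str
    topology: str = "linear"
    record_bounds: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("empty genome")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise AlphabetError(f"genome contains non-nucleotide characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        if not self.record_bounds:
            object.__setattr__(self, "record_bounds", ((self.id, 0, len(seq)),))

    def __len__(self) -> int:
        return len(self.sequence)

    def as_array(self) -> np.ndarray:
        return encode(self.sequence)


def read_sites(path: str | Path, tf_name: str | None = None) -> BindingSiteSet:
    """Read an aligned binding-site set from FASTA or one-sequence-per-line text.

    Raises
    ------
    LengthMismatchError
        if the records do not all share one width.
    AlphabetError
        if any record contains a character outside {A,C,G,T}.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        seqs = [str(r.seq) for r in SeqIO.parse(io.StringIO(text), "fasta")]
    else:
        seqs = [line.strip() for line in text.splitlines() if line.strip()]
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return BindingSiteSet(tf_name or path.stem, tuple(seqs))


def write_sites(sites: BindingSiteSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=f"{sites.tf_name}_{i+1}", description="")
        for i, s in enumerate(sites.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome(path: str | Path) -> Genome:
    """Read a genome FASTA; multiple records are joined with ``N`` separators."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA: {path}")
    parts: list[str] = []
    bounds: list[tuple[str, int, int]] = []
    offset = 0
    for i, rec in enumerate(records):
        if i > 0:
            parts.append("N")
            offset += 1
        s = str(rec.seq).upper()
        parts.append(s)
        bounds.append((rec.id, offset, offset + len(s)))
        offset += len(s)
    return Genome(
        id=records[0].id if len(records) == 1 else Path(path).stem,
        sequence="".join(parts),
        record_bounds=tuple(bounds),
    )


def write_genome(genome: Genome, path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(genome.sequence), id=genome.id, description="")],
        str(path),
        "fasta",
    )


def validate_equal_length(seqs: Iterable[str]) -> int:
    """Return the common length of *seqs* or raise LengthMismatchError."""
    it = iter(seqs)
    first = next(it)
    L = len(first)
    for i, s in enumerate(it, start=1):
        if len(s) != L:
            raise LengthMismatchError(f"sequence {i} has length {len(s)}, expected {L}")
    return L
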