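"""Genome and interval I/O plus one-hot encoding.

Sequences live in memory as plain uppercase strings over {A, C, G, T, N};
coordinates are 0-based, half-open throughout (BED convention). Fragments
are encoded as n x 4 matrices with fixed column order A, C, G, T; ambiguous
N bases encode as a uniform 0.25 row so every row sums to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Union

import numpy as np
from Bio import SeqIO

from .errors import (
    BedFormatError,
    CoordinateError,
    FastaFormatError,
    SequenceEncodingError,
)

ALPHABET = "ACGTN"
BASE_ORDER = "ACGT"

POSITIVE = "positive"
NEGATIVE = "negative"

# lookup table: byte value of base -> one-hot row (N -> uniform)
_ENCODE_LUT = np.full((256, 4), -1.0, dtype=np.float32)
for _i, _b in enumerate(BASE_ORDER):
    _ENCODE_LUT[ord(_b)] = np.eye(4, dtype=np.float32)[_i]
_ENCODE_LUT[ord("N")] = 0.25

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome: uppercase bases over {A, C, G, T, N}."""

    chrom_name: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise FastaFormatError(
                f"chromosome {self.chrom_name!r} has an empty sequence"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class GenomicInterval:
    """A labeled half-open coordinate span [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    label: str = POSITIVE

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown label {self.label!r}")

    def __len__(self) -> int:
        return self.end - self.start


GenomeMap = Dict[str, GenomeSequence]


def _as_genome_map(
    genomes: Union[GenomeMap, Iterable[GenomeSequence]],
) -> GenomeMap:
    if isinstance(genomes, Mapping):
        return dict(genomes)
    return {g.chrom_name: g for g in genomes}


def read_fasta(path) -> List[GenomeSequence]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Record names are the first whitespace-delimited token of the header;
    lowercase bases are uppercased. Raises :class:`FastaFormatError` on an
    empty file or on characters outside {A, C, G, T, N}, naming the record
    and the 1-based offending position.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        bases = str(rec.seq).upper()
        bad = next((i for i, c in enumerate(bases) if c not in ALPHABET), None)
        if bad is not None:
            raise FastaFormatError(
                f"record {rec.id!r}: illegal character {bases[bad]!r} "
                f"at position {bad + 1}"
            )
        if not bases:
            raise FastaFormatError(f"record {rec.id!r} is empty")
        records.append(GenomeSequence(chrom_name=rec.id, bases=bases))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, genomes: Iterable[GenomeSequence], width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.chrom_name}\n")
            for i in range(0, len(g.bases), width):
                fh.write(g.bases[i : i + width] + "\n")


def read_intervals(path, label: str = POSITIVE) -> List[GenomicInterval]:
    """Read a BED3+ file (tab-separated, 0-based half-open) as intervals
    carrying ``label``. Extra columns are ignored; malformed lines raise
    :class:`BedFormatError` with their 1-based line number."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedFormatError(
                    f"line {lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}"
                ) from None
            if start < 0 or start >= end:
                raise BedFormatError(
                    f"line {lineno}: invalid span {start}-{end}"
                )
            out.append(GenomicInterval(chrom, start, end, label))
    return out


def write_intervals(path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def extract_fragment(
    genomes: Union[GenomeMap, Iterable[GenomeSequence]],
    iv: GenomicInterval,
) -> str:
    """Return the forward-strand bases covered by ``iv``."""
    gmap = _as_genome_map(genomes)
    if iv.chrom not in gmap:
        raise CoordinateError(f"unknown chromosome {iv.chrom!r}")
    bases = gmap[iv.chrom].bases
    if iv.end > len(bases):
        raise CoordinateError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
            f"length {len(bases)}"
        )
    return bases[iv.start : iv.end]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as an n x 4 float32 matrix.

    Columns are A, C, G, T; an N row is uniform (0.25 each) so that every
    row sums to exactly 1.
    """
    if not seq:
        raise SequenceEncodingError("cannot encode an empty sequence")
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mat = _ENCODE_LUT[codes]
    if (mat[:, 0] < 0).any():
        bad = int(np.argmax(mat[:, 0] < 0))
        raise SequenceEncodingError(
            f"illegal character {seq[bad]!r} at position {bad + 1}"
        )
    return mat.copy()


def one_hot_decode(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` for N-free sequences (argmax)."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[1] != 4:
        raise SequenceEncodingError(f"expected an n x 4 matrix, got {mat.shape}")
    return "".join(BASE_ORDER[i] for i in mat.argmax(axis=1))
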