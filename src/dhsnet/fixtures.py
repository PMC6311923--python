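"""Synthetic genomes with planted-motif "DHS" intervals.

The generator emulates the structure of the real corpora: fragment lengths
200-800 bp whose frequency decreases with length, an approximately 1:1
positive:negative ratio once length-matched negatives are drawn, and
positives distinguishable from background only by a short planted motif.
It does not emulate real-genome k-mer statistics, chromatin state, or
DNase-seq signal — passing tests on fixtures demonstrate the pipeline and
the learnability of a sequence signal, not biological performance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import DhsnetError, SamplingError
from .sequence_io import (
    POSITIVE,
    GenomeSequence,
    GenomicInterval,
    write_fasta,
    write_intervals,
)


def geometric_length_distribution(
    min_len: int = 200, max_len: int = 800, mean_excess: float = 100.0
) -> Tuple[np.ndarray, np.ndarray]:
    """A decreasing discrete length distribution on [min_len, max_len]:
    a truncated geometric on the excess over ``min_len``. Mirrors the
    empirical pattern that shorter accessible sites are more numerous."""
    support = np.arange(min_len, max_len + 1)
    p = 1.0 / (1.0 + mean_excess)
    probs = (1.0 - p) ** (support - min_len) * p
    return support, probs / probs.sum()


@dataclass
class FixtureSpec:
    """Parameters of a synthetic corpus.

    Defaults are sized so the genome comfortably hosts length-matched,
    mutually disjoint negatives (final occupancy about one half).
    """

    n_chromosomes: int = 2
    chrom_length: int = 600_000
    n_positives: int = 1000
    motif: str = "TGCACGTA"
    motif_copies_per_positive: int = 1
    min_len: int = 200
    max_len: int = 800
    length_mean_excess: float = 100.0
    background_composition: Tuple[float, float, float, float] = (
        0.25, 0.25, 0.25, 0.25)  # A, C, G, T
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.background_composition) - 1.0) > 1e-9:
            raise ValueError("background_composition must sum to 1")
        if len(self.motif) >= self.min_len:
            raise ValueError("motif must be shorter than the minimum fragment")
        if set(self.motif) - set("ACGT"):
            raise ValueError("motif must be over {A, C, G, T}")

    def length_distribution(self) -> Tuple[np.ndarray, np.ndarray]:
        return geometric_length_distribution(
            self.min_len, self.max_len, self.length_mean_excess
        )


def _random_genome(spec: FixtureSpec, rng: np.random.Generator) -> List[GenomeSequence]:
    bases = np.array(list("ACGT"))
    out = []
    for i in range(spec.n_chromosomes):
        seq = rng.choice(bases, size=spec.chrom_length,
                         p=np.asarray(spec.background_composition))
        out.append(GenomeSequence(f"chr{i + 1}", "".join(seq)))
    return out


def generate_fixture(
    spec: FixtureSpec,
    out_dir: Optional[Path] = None,
) -> Tuple[List[GenomeSequence], List[GenomicInterval], List[GenomicInterval]]:
    """Build a synthetic genome plus planted-motif positive intervals.

    Returns (genome, positives, excluded); ``excluded`` is the full set of
    "known DHS" regions that negatives must avoid (here identical to the
    positives). Each positive interval carries ``motif_copies_per_positive``
    exact motif copies at uniformly random internal offsets; intervals are
    mutually non-overlapping. Deterministic given ``spec.seed``. When
    ``out_dir`` is given, writes genome.fa, positives.bed, excluded.bed and
    a provenance JSON embedding the spec.
    """
    rng = np.random.default_rng(spec.seed)
    genomes = _random_genome(spec, rng)
    support, probs = spec.length_distribution()
    lengths = rng.choice(support, size=spec.n_positives, p=probs)
    chrom_of = rng.integers(0, spec.n_chromosomes, size=spec.n_positives)

    # place per chromosome without overlap by rejection against placed spans
    positives: List[GenomicInterval] = []
    occupied: Dict[str, List[Tuple[int, int]]] = {g.chrom_name: [] for g in genomes}
    mutable = {g.chrom_name: np.frombuffer(g.bases.encode(), dtype=np.uint8).copy()
               for g in genomes}
    motif_bytes = np.frombuffer(spec.motif.encode(), dtype=np.uint8)
    for idx in range(spec.n_positives):
        g = genomes[chrom_of[idx]]
        length = int(lengths[idx])
        placed = False
        for _ in range(10_000):
            start = int(rng.integers(0, len(g) - length + 1))
            end = start + length
            if any(s < end and start < e for s, e in occupied[g.chrom_name]):
                continue
            occupied[g.chrom_name].append((start, end))
            for _copy in range(spec.motif_copies_per_positive):
                off = int(rng.integers(0, length - len(spec.motif) + 1))
                mutable[g.chrom_name][start + off : start + off + len(motif_bytes)] = (
                    motif_bytes
                )
            positives.append(GenomicInterval(g.chrom_name, start, end, POSITIVE))
            placed = True
            break
        if not placed:
            raise SamplingError(
                f"could not place positive {idx} of length {length}: "
                f"genome too densely packed"
            )
    genomes = [
        GenomeSequence(g.chrom_name, mutable[g.chrom_name].tobytes().decode())
        for g in genomes
    ]
    positives.sort(key=lambda iv: (iv.chrom, iv.start))
    excluded = list(positives)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(out_dir / "genome.fa", genomes)
        write_intervals(out_dir / "positives.bed", positives)
        write_intervals(out_dir / "excluded.bed", excluded)
        with open(out_dir / "provenance.json", "w") as fh:
            json.dump(asdict(spec), fh, indent=2)
    return genomes, positives, excluded


def motif_hit_rate(
    motif_len: int, fragment_len: int, p_match: float
) -> float:
    """Chance that a background fragment contains the motif, under the
    independent-windows approximation 1 - (1 - p_match)^(L - m + 1)."""
    if motif_len > fragment_len:
        raise DhsnetError(
            f"motif length {motif_len} exceeds fragment length {fragment_len}"
        )
    windows = fragment_len - motif_len + 1
    return 1.0 - (1.0 - p_match) ** windows


def fixture_difficulty(spec: FixtureSpec) -> dict:
    """Expected separability of a fixture.

    Reports the motif information content (bits relative to the background
    composition) and the probability that a random background fragment
    contains the motif by chance, at the minimum, mean, and maximum
    fragment lengths and in expectation over the length distribution.
    """
    comp = dict(zip("ACGT", spec.background_composition))
    p_match = float(np.prod([comp[b] for b in spec.motif]))
    info_bits = float(-np.log2(p_match))
    support, probs = spec.length_distribution()
    rates = np.array(
        [motif_hit_rate(len(spec.motif), int(L), p_match) for L in support]
    )
    return {
        "motif": spec.motif,
        "p_match_per_window": p_match,
        "information_content_bits": info_bits,
        "chance_hit_rate_min_len": float(rates[0]),
        "chance_hit_rate_max_len": float(rates[-1]),
        "expected_chance_hit_rate": float((rates * probs).sum()),
        "mean_fragment_length": float((support * probs).sum()),
    }


def contains_motif(seq: str, motif: str) -> bool:
    """The trivial string-matching classifier used as a separability
    baseline for fixtures."""
    return motif in seq
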