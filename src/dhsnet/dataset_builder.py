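"""Corpus construction: length filtering, length-matched negative sampling,
redundancy removal, descriptive statistics and cross-validation folds.

The recipe: keep DHS fragments of 200-800 bp, draw for every positive one
same-length fragment from the non-DHS portion of the same chromosome (so the
class length distributions coincide exactly), drop near-identical sequences
with a greedy identity filter, and split stratified k-fold.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.model_selection import StratifiedKFold

from .errors import SamplingError
from .sequence_io import (
    NEGATIVE,
    POSITIVE,
    GenomeMap,
    GenomeSequence,
    GenomicInterval,
    _as_genome_map,
    extract_fragment,
)


def filter_by_length(
    intervals: Iterable[GenomicInterval],
    min_bp: int = 200,
    max_bp: int = 800,
) -> List[GenomicInterval]:
    """Keep intervals with min_bp <= length <= max_bp (bounds inclusive)."""
    return [iv for iv in intervals if min_bp <= len(iv) <= max_bp]


def sample_negatives(
    genomes: Union[GenomeMap, Iterable[GenomeSequence]],
    positives: Sequence[GenomicInterval],
    excluded: Sequence[GenomicInterval],
    seed: int = 0,
    max_attempts: int = 10_000,
) -> List[GenomicInterval]:
    """Draw one same-length, same-chromosome negative per positive.

    Negatives avoid every ``excluded`` interval (all known DHS regions, not
    just the filtered positives) and each other, by uniform rejection
    sampling with at most ``max_attempts`` draws per positive. Deterministic
    given ``seed``.

    Raises :class:`SamplingError` naming the positive when no placement is
    found.
    """
    gmap = _as_genome_map(genomes)
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in excluded:
        trees[iv.chrom].addi(iv.start, iv.end)
    rng = np.random.default_rng(seed)
    negatives: List[GenomicInterval] = []
    for pos in positives:
        if pos.chrom not in gmap:
            raise SamplingError(f"unknown chromosome for positive {pos}")
        chrom_len = len(gmap[pos.chrom])
        length = len(pos)
        hi = chrom_len - length
        if hi < 0:
            raise SamplingError(
                f"positive {pos.chrom}:{pos.start}-{pos.end}: chromosome "
                f"shorter than fragment"
            )
        tree = trees[pos.chrom]
        for _ in range(max_attempts):
            start = int(rng.integers(0, hi + 1))
            if not tree.overlaps(start, start + length):
                neg = GenomicInterval(pos.chrom, start, start + length, NEGATIVE)
                negatives.append(neg)
                tree.addi(start, start + length)  # keep negatives disjoint too
                break
        else:
            raise SamplingError(
                f"no feasible placement for positive "
                f"{pos.chrom}:{pos.start}-{pos.end} after {max_attempts} attempts"
            )
    return negatives


# ---------------------------------------------------------------------------
# redundancy removal


def _kmer_positions(seq: str, k: int) -> Dict[str, List[int]]:
    pos: Dict[str, List[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        pos[seq[i : i + k]].append(i)
    return pos


def pairwise_identity(a: str, b: str, offsets: Optional[Iterable[int]] = None) -> float:
    """Ungapped best-offset identity: max over offsets of
    matches / min(len(a), len(b)).

    ``offsets`` are shifts of ``b`` relative to ``a``; by default every
    overlapping offset is tried (exact but O(len^2), for small inputs and
    tests).
    """
    la, lb = len(a), len(b)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    if offsets is None:
        offsets = range(-(lb - 1), la)
    denom = min(la, lb)
    best = 0
    for off in set(offsets):
        a0, b0 = max(0, off), max(0, -off)
        n = min(la - a0, lb - b0)
        if n <= 0:
            continue
        best = max(best, int((aa[a0 : a0 + n] == bb[b0 : b0 + n]).sum()))
    return best / denom


def redundant_filter_indices(
    sequences: Sequence[str],
    identity_threshold: float = 0.9,
    word_size: int = 12,
) -> List[int]:
    """Indices of sequences kept by greedy length-sorted deduplication.

    Sequences are visited longest-first (ties broken by original order); a
    sequence is dropped when its best-offset ungapped identity to an
    already-kept sequence reaches ``identity_threshold``. Candidate offsets
    come from shared ``word_size``-mers (a cd-hit-style word filter): pairs
    sharing no word are treated as dissimilar.
    """
    if not 0.5 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0.5, 1.0]")
    order = sorted(range(len(sequences)), key=lambda i: (-len(sequences[i]), i))
    kept: List[int] = []
    kept_kmers: List[Dict[str, List[int]]] = []
    for idx in order:
        seq = sequences[idx]
        words = _kmer_positions(seq, word_size)
        redundant = False
        for kidx, kwords in zip(kept, kept_kmers):
            offsets = {
                kp - qp
                for w, qpos in words.items()
                if w in kwords
                for qp in qpos
                for kp in kwords[w]
            }
            if not offsets:
                continue
            if (
                pairwise_identity(sequences[kidx], seq, offsets)
                >= identity_threshold
            ):
                redundant = True
                break
        if not redundant:
            kept.append(idx)
            kept_kmers.append(words)
    return sorted(kept)


def remove_redundant(
    sequences: Sequence[str],
    identity_threshold: float = 0.9,
    word_size: int = 12,
) -> List[str]:
    """Greedy redundancy removal; see :func:`redundant_filter_indices`."""
    idx = redundant_filter_indices(sequences, identity_threshold, word_size)
    return [sequences[i] for i in idx]


# ---------------------------------------------------------------------------
# descriptive statistics


@dataclass
class CorpusStats:
    """Descriptive panel for a built corpus: counts, lengths and per-class
    nucleotide composition."""

    n_positive: int
    n_negative: int
    mean_length: float
    ratio: float  # n_positive / n_negative
    length_bin_edges: np.ndarray  # len B+1
    length_histogram: np.ndarray  # len B, counts over both classes
    mono_freqs: Dict[str, Dict[str, float]]  # class -> base -> frequency
    di_freqs: Dict[str, Dict[str, float]]  # class -> dinucleotide -> frequency

    def to_dict(self) -> dict:
        return {
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "mean_length": self.mean_length,
            "ratio": self.ratio,
            "length_bin_edges": self.length_bin_edges.tolist(),
            "length_histogram": self.length_histogram.tolist(),
            "mono_freqs": self.mono_freqs,
            "di_freqs": self.di_freqs,
        }


def _composition(seqs: Iterable[str]) -> Tuple[Dict[str, float], Dict[str, float]]:
    mono = {b: 0 for b in "ACGT"}
    di = {a + b: 0 for a in "ACGT" for b in "ACGT"}
    for s in seqs:
        for b in s:
            if b in mono:
                mono[b] += 1
        for i in range(len(s) - 1):
            d = s[i : i + 2]
            if d in di:
                di[d] += 1
    mt, dt = sum(mono.values()), sum(di.values())
    return (
        {b: c / mt if mt else 0.0 for b, c in mono.items()},
        {d: c / dt if dt else 0.0 for d, c in di.items()},
    )


def corpus_stats(
    positives: Sequence[GenomicInterval],
    negatives: Sequence[GenomicInterval],
    genomes: Union[GenomeMap, Iterable[GenomeSequence]],
    bin_width: int = 50,
) -> CorpusStats:
    """Counts, mean length, class ratio, a length histogram and per-class
    mono/dinucleotide frequencies."""
    if not positives or not negatives:
        raise ValueError("corpus_stats requires nonempty positive and negative sets")
    gmap = _as_genome_map(genomes)
    lengths = np.array([len(iv) for iv in itertools.chain(positives, negatives)])
    lo = (lengths.min() // bin_width) * bin_width
    hi = -(-int(lengths.max()) // bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    hist, _ = np.histogram(lengths, bins=edges)
    mono, di = {}, {}
    for name, ivs in ((POSITIVE, positives), (NEGATIVE, negatives)):
        seqs = [extract_fragment(gmap, iv) for iv in ivs]
        mono[name], di[name] = _composition(seqs)
    return CorpusStats(
        n_positive=len(positives),
        n_negative=len(negatives),
        mean_length=float(lengths.mean()),
        ratio=len(positives) / len(negatives),
        length_bin_edges=edges,
        length_histogram=hist,
        mono_freqs=mono,
        di_freqs=di,
    )


# ---------------------------------------------------------------------------
# cross-validation folds


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified k-fold assignment: sample index -> fold id."""

    k: int
    fold_of: np.ndarray  # shape (n_samples,), values in [0, k)
    seed: int

    def indices(self, fold: int) -> Tuple[np.ndarray, np.ndarray]:
        """(train_idx, test_idx) for one fold."""
        test = np.flatnonzero(self.fold_of == fold)
        train = np.flatnonzero(self.fold_of != fold)
        return train, test


def make_folds(labels: Sequence[int], k: int, seed: int = 0) -> FoldAssignment:
    """Stratified k-fold split, deterministic given ``seed``.

    Fold sizes differ by at most 1 overall and per class.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(n, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((n, 1)), labels)):
        fold_of[test_idx] = fold
    return FoldAssignment(k=k, fold_of=fold_of, seed=seed)


# ---------------------------------------------------------------------------
# manifest


MANIFEST_COLUMNS = ["id", "chrom", "start", "end", "label", "fold"]


def build_manifest(
    positives: Sequence[GenomicInterval],
    negatives: Sequence[GenomicInterval],
    folds: FoldAssignment,
) -> pd.DataFrame:
    """Tab-separable corpus manifest: one row per sample with its fold.

    Samples are ordered positives-then-negatives; ``folds`` must have been
    made over labels in that same order.
    """
    rows = []
    for i, iv in enumerate(itertools.chain(positives, negatives)):
        rows.append(
            {
                "id": f"s{i:06d}",
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "label": iv.label,
                "fold": int(folds.fold_of[i]),
            }
        )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def write_manifest(path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def manifest_intervals(manifest: pd.DataFrame) -> List[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.label)
        for r in manifest.itertuples()
    ]
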