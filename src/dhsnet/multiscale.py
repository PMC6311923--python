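"""Multi-scale (length-binned) training.

Fragments are grouped into fixed-width length bins; every fragment in a bin
is extended on-chromosome to the bin's upper bound (the target length), so
each bin becomes a fixed-length dataset. Training cycles bins in ascending
target-length order, one full epoch per bin, all bins sharing one parameter
set — the pyramid-pooling head guarantees the parameter dimensions never
change with input length. One pass over all bins is an iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import BinAssignmentError, ExtensionError
from .nn.losses import cross_entropy
from .nn.model import Model
from .nn.optim import SGDMomentum
from .sequence_io import (
    POSITIVE,
    GenomeMap,
    GenomeSequence,
    GenomicInterval,
    _as_genome_map,
    extract_fragment,
    one_hot_encode,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LengthBin:
    """Length range (low, high]; fragments in the bin are extended to
    ``target_length`` = high. The lowest bin also admits length == low."""

    low: int
    high: int

    @property
    def target_length(self) -> int:
        return self.high


def assign_bins(
    intervals: Sequence[GenomicInterval],
    interval_width: int = 100,
    min_len: int = 200,
    max_len: int = 800,
) -> Tuple[List[LengthBin], np.ndarray]:
    """Tile [min_len, max_len] with bins of ``interval_width`` and assign
    each fragment to the unique bin with low < length <= high (the first
    bin also takes length == min_len).

    Returns (bins, bin_index_per_interval).
    """
    span = max_len - min_len
    if interval_width <= 0 or span % interval_width != 0:
        raise BinAssignmentError(
            f"interval_width {interval_width} must divide {span}"
        )
    bins = [
        LengthBin(min_len + i * interval_width, min_len + (i + 1) * interval_width)
        for i in range(span // interval_width)
    ]
    ids = np.empty(len(intervals), dtype=np.int64)
    for i, iv in enumerate(intervals):
        length = len(iv)
        if not min_len <= length <= max_len:
            raise BinAssignmentError(
                f"fragment {iv.chrom}:{iv.start}-{iv.end} length {length} "
                f"outside [{min_len}, {max_len}]"
            )
        ids[i] = 0 if length == min_len else (length - min_len - 1) // interval_width
    return bins, ids


def _split_padding(
    pad: int, policy: str, rng: Optional[np.random.Generator]
) -> Tuple[int, int]:
    if pad == 0:
        return 0, 0
    if policy == "centered":
        left = pad // 2
    elif policy == "random":
        if rng is None:
            raise ValueError("random split policy needs an RNG")
        left = int(rng.integers(0, pad + 1))
    else:
        raise ValueError(f"unknown split_policy {policy!r}")
    return left, pad - left


def extend_to_target(
    iv: GenomicInterval,
    target_length: int,
    genomes: Union[GenomeMap, Iterable[GenomeSequence]],
    split_policy: str = "random",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> GenomicInterval:
    """Extend ``iv`` symmetrically-or-randomly to ``target_length`` bases.

    The returned interval contains the original span, has exactly the
    target length, and stays within chromosome bounds (padding is shifted
    inward at chromosome edges). Deterministic given ``seed``.
    """
    gmap = _as_genome_map(genomes)
    chrom_len = len(gmap[iv.chrom])
    pad = target_length - len(iv)
    if pad < 0:
        raise ExtensionError(
            f"fragment {iv.chrom}:{iv.start}-{iv.end} longer than target "
            f"{target_length}"
        )
    if target_length > chrom_len:
        raise ExtensionError(
            f"chromosome {iv.chrom} ({chrom_len} bp) shorter than target "
            f"{target_length}"
        )
    if rng is None and split_policy == "random":
        rng = np.random.default_rng(seed)
    left, right = _split_padding(pad, split_policy, rng)
    start, end = iv.start - left, iv.end + right
    if start < 0:  # shift padding rightward at the chromosome start
        end -= start
        start = 0
    if end > chrom_len:  # and leftward at the chromosome end
        start -= end - chrom_len
        end = chrom_len
    return GenomicInterval(iv.chrom, start, end, iv.label)


def amplify(
    iv: GenomicInterval,
    target_length: int,
    n_variants: int,
    genomes: Union[GenomeMap, Iterable[GenomeSequence]],
    seed: Optional[int] = None,
) -> List[GenomicInterval]:
    """Produce up to ``n_variants`` extended intervals with distinct
    left/right padding splits (evenly spaced across the feasible range).

    Fewer variants are returned, with a logged warning, when the padding or
    flanking sequence cannot support that many distinct splits.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    gmap = _as_genome_map(genomes)
    pad = target_length - len(iv)
    if pad < 0:
        raise ExtensionError(
            f"fragment {iv.chrom}:{iv.start}-{iv.end} longer than target"
        )
    if n_variants == 1:
        return [extend_to_target(iv, target_length, gmap, "centered")]
    lefts = sorted(
        {int(round(i * pad / (n_variants - 1))) for i in range(n_variants)}
    )
    out: List[GenomicInterval] = []
    seen = set()
    for left in lefts:
        chrom_len = len(gmap[iv.chrom])
        start, end = iv.start - left, iv.end + (pad - left)
        if start < 0:
            end -= start
            start = 0
        if end > chrom_len:
            start -= end - chrom_len
            end = chrom_len
        if (start, end) not in seen:
            seen.add((start, end))
            out.append(GenomicInterval(iv.chrom, start, end, iv.label))
    if len(out) < n_variants:
        logger.warning(
            "amplify: only %d of %d distinct variants for %s:%d-%d",
            len(out), n_variants, iv.chrom, iv.start, iv.end,
        )
    return out


@dataclass
class MultiScaleDataset:
    """Per-bin fixed-length encoded samples with labels.

    ``samples[i]`` is a float32 array (n_i, 4, bins[i].target_length);
    ``labels[i]`` the matching 0/1 vector (1 = positive);
    ``sources[i]`` the extended intervals the rows came from.
    """

    bins: List[LengthBin]
    samples: List[np.ndarray]
    labels: List[np.ndarray]
    sources: List[List[GenomicInterval]]
    amplification_factor: int = 1

    @property
    def n_samples(self) -> int:
        return int(sum(len(l) for l in self.labels))

    def class_ratio(self, bin_idx: int) -> float:
        lab = self.labels[bin_idx]
        n_neg = int((lab == 0).sum())
        return float((lab == 1).sum()) / n_neg if n_neg else np.inf


def build_multiscale_dataset(
    genomes: Union[GenomeMap, Iterable[GenomeSequence]],
    intervals: Sequence[GenomicInterval],
    interval_width: int = 100,
    min_len: int = 200,
    max_len: int = 800,
    split_policy: str = "random",
    amplification_factor: int = 1,
    seed: int = 0,
) -> MultiScaleDataset:
    """Bin, extend (positives and negatives alike), optionally amplify,
    and one-hot encode a set of labeled intervals."""
    gmap = _as_genome_map(genomes)
    bins, ids = assign_bins(intervals, interval_width, min_len, max_len)
    rng = np.random.default_rng(seed)
    per_bin_rows: List[List[np.ndarray]] = [[] for _ in bins]
    per_bin_labels: List[List[int]] = [[] for _ in bins]
    per_bin_sources: List[List[GenomicInterval]] = [[] for _ in bins]
    for iv, b in zip(intervals, ids):
        target = bins[b].target_length
        if amplification_factor > 1:
            extended = amplify(iv, target, amplification_factor, gmap)
        else:
            extended = [extend_to_target(iv, target, gmap, split_policy, rng=rng)]
        for ext in extended:
            mat = one_hot_encode(extract_fragment(gmap, ext))
            per_bin_rows[b].append(mat.T)  # (4, L)
            per_bin_labels[b].append(1 if ext.label == POSITIVE else 0)
            per_bin_sources[b].append(ext)
    samples = [
        np.stack(rows).astype(np.float32) if rows
        else np.empty((0, 4, bins[i].target_length), dtype=np.float32)
        for i, rows in enumerate(per_bin_rows)
    ]
    labels = [np.asarray(l, dtype=np.int64) for l in per_bin_labels]
    return MultiScaleDataset(
        bins=bins,
        samples=samples,
        labels=labels,
        sources=per_bin_sources,
        amplification_factor=amplification_factor,
    )


@dataclass
class TrainConfig:
    """Optimizer schedule: classical momentum 0.98, initial learning rate
    0.002 decayed by 0.97 after every (per-bin) epoch, mini-batches of 128,
    and a fixed iteration budget."""

    momentum: float = 0.98
    learning_rate: float = 0.002
    lr_decay_per_epoch: float = 0.97
    batch_size: int = 128
    iterations: int = 100
    seed: int = 0
    clip_grad_norm: Optional[float] = 5.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.lr_decay_per_epoch <= 1:
            raise ValueError("lr_decay_per_epoch must be in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class EpochRecord:
    iteration: int
    bin_target_length: int
    mean_loss: float
    learning_rate: float  # rate in force during the epoch


class Trainer:
    """Stateful multi-scale trainer: cycles bins in ascending target-length
    order, one epoch per bin; the learning rate decays after every epoch.
    Deterministic given ``config.seed`` (single-threaded contract)."""

    def __init__(self, model: Model, config: TrainConfig):
        self.model = model
        self.config = config
        self.optimizer = SGDMomentum(
            model,
            lr=config.learning_rate,
            momentum=config.momentum,
            clip_grad_norm=config.clip_grad_norm,
        )
        self.rng = np.random.default_rng(config.seed)
        model.set_rng(self.rng)  # dropout shares the run RNG
        self.history: List[EpochRecord] = []
        self._iteration = 0

    def _epoch(self, x: np.ndarray, y: np.ndarray) -> float:
        order = self.rng.permutation(len(y))
        losses = []
        bs = self.config.batch_size
        for lo in range(0, len(order), bs):
            idx = order[lo : lo + bs]
            self.optimizer.zero_grad()
            logits = self.model.forward(x[idx], train=True)
            loss, dlogits = cross_entropy(logits, y[idx])
            self.model.backward(dlogits)
            self.optimizer.step()
            losses.append(loss)
        return float(np.mean(losses))

    def run_iteration(self, dataset: MultiScaleDataset) -> None:
        order = np.argsort([b.target_length for b in dataset.bins])
        for b in order:
            if len(dataset.labels[b]) == 0:
                logger.warning(
                    "skipping empty length bin (%d, %d]",
                    dataset.bins[b].low, dataset.bins[b].high,
                )
                continue
            loss = self._epoch(dataset.samples[b], dataset.labels[b])
            self.history.append(
                EpochRecord(
                    iteration=self._iteration,
                    bin_target_length=dataset.bins[b].target_length,
                    mean_loss=loss,
                    learning_rate=self.optimizer.lr,
                )
            )
            self.optimizer.lr *= self.config.lr_decay_per_epoch
        self._iteration += 1

    def train(self, dataset: MultiScaleDataset, iterations: Optional[int] = None):
        for _ in range(iterations if iterations is not None else
                       self.config.iterations):
            self.run_iteration(dataset)
        return self.model, self.history


def train(model: Model, dataset: MultiScaleDataset, config: TrainConfig):
    """Train ``model`` on a multi-scale dataset; returns (model, history)."""
    return Trainer(model, config).train(dataset)


def score_dataset(model: Model, dataset: MultiScaleDataset):
    """Positive-class probabilities and labels pooled over all bins
    (evaluation mode; each bin scored at its own length)."""
    scores, labels = [], []
    for x, y in zip(dataset.samples, dataset.labels):
        if len(y) == 0:
            continue
        for lo in range(0, len(y), 256):
            scores.append(model.predict_proba(x[lo : lo + 256])[:, 1])
        labels.append(y)
    return np.concatenate(scores), np.concatenate(labels)
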