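"""Corpus construction: length filter, length-matched negatives, dedup,
folds, and the descriptive statistics panel.

Uses a synthetic planted-motif fixture in place of real DHS downloads; the
same calls apply to a genome FASTA + DHS BED pair.
"""

from dhsnet import (
    FixtureSpec,
    build_manifest,
    corpus_stats,
    extract_fragment,
    filter_by_length,
    generate_fixture,
    make_folds,
    redundant_filter_indices,
    sample_negatives,
)

spec = FixtureSpec(n_positives=200, chrom_length=150_000, seed=7)
genomes, positives, excluded = generate_fixture(spec)
gmap = {g.chrom_name: g for g in genomes}

positives = filter_by_length(positives, 200, 800)  # bounds inclusive
seqs = [extract_fragment(gmap, iv) for iv in positives]
kept = redundant_filter_indices(seqs, identity_threshold=0.9)
positives = [positives[i] for i in kept]
print(f"{len(positives)} positives after length filter + redundancy removal")

negatives = sample_negatives(gmap, positives, excluded, seed=1)
print(f"{len(negatives)} negatives, length-matched on the same chromosomes")

stats = corpus_stats(positives, negatives, gmap)
print(f"mean fragment length: {stats.mean_length:.1f} bp; "
      f"P:N ratio {stats.ratio:.2f}")
print("positive mononucleotide frequencies:",
      {b: round(f, 3) for b, f in stats.mono_freqs['positive'].items()})

labels = [1] * len(positives) + [0] * len(negatives)
folds = make_folds(labels, k=5, seed=0)
manifest = build_manifest(positives, negatives, folds)
print(manifest.head())
print(f"fold sizes: {manifest['fold'].value_counts().sort_index().tolist()}")
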