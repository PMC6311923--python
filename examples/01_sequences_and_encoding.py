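"""Reading sequences, extracting fragments, one-hot encoding.

Builds a two-chromosome toy genome, extracts a fragment by BED-style
half-open coordinates, and shows the n x 4 encoding the network consumes.
"""

from dhsnet import (
    GenomeSequence,
    GenomicInterval,
    extract_fragment,
    one_hot_decode,
    one_hot_encode,
)

genome = {
    "chr1": GenomeSequence("chr1", "AACGTACGTTACGNACGT"),
    "chr2": GenomeSequence("chr2", "TTTTACGTACGTAAAA"),
}

iv = GenomicInterval("chr1", 2, 10)  # 0-based, half-open: 8 bases
frag = extract_fragment(genome, iv)
print(f"fragment {iv.chrom}:{iv.start}-{iv.end} -> {frag} ({len(frag)} bp)")

mat = one_hot_encode(frag)
print(f"one-hot matrix shape: {mat.shape} (rows are bases, columns A,C,G,T)")
print(mat)
print("decoded back:", one_hot_decode(mat))

# N bases encode as a uniform row so every row still sums to 1
print("row for N:", one_hot_encode("N")[0])
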