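"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately simple pure Python (string slicing and
explicit loops), sharing no code path with the package's vectorized
implementations.
"""

from collections import Counter

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def kmer_census(seqs, k, trimm5=0, trimm3=0):
    """Canonical k-mer counts by explicit window enumeration."""
    counts = Counter()
    valid_windows = 0
    for seq in seqs:
        s = seq[trimm5 : len(seq) - trimm3] if len(seq) > trimm5 + trimm3 else ""
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if all(b in "ACGT" for b in w):
                counts[canonical(w)] += 1
                valid_windows += 1
    return counts, valid_windows


def genome_truth(genome: dict, k: int):
    """Per-chromosome canonical k-mer counts of a genome dict."""
    out = {}
    for label, seq in genome.items():
        counts, _ = kmer_census([seq], k)
        out[label] = counts
    return out


def pam_sites_cas9(kmer: str):
    """(strand, offset) pairs of 20-nt protospacer + NGG placements."""
    sites = []
    for strand in "+-":
        s = kmer if strand == "+" else revcomp(kmer)
        for i in range(len(s) - 22):
            if s[i + 21] == "G" and s[i + 22] == "G":
                sites.append((strand, i, s[i : i + 20], s[i + 20 : i + 23]))
    return sites


def pam_sites_cas12a(kmer: str, min_spacer=20):
    """(strand, offset) pairs of TTTV + >= min_spacer protospacer placements."""
    sites = []
    for strand in "+-":
        s = kmer if strand == "+" else revcomp(kmer)
        for i in range(len(s) - 4 - min_spacer + 1):
            if s[i : i + 3] == "TTT" and s[i + 3] in "ACG":
                sites.append((strand, i + 4, s[i + 4 :], s[i : i + 4]))
    return sites


def hamming_hits(pattern: str, text: str, max_mm: int):
    """(start, mismatches) for every forward placement within max_mm."""
    L = len(pattern)
    hits = []
    for i in range(len(text) - L + 1):
        w = text[i : i + L]
        if any(b not in "ACGT" for b in w):
            continue
        mm = sum(1 for a, b in zip(pattern, w) if a != b)
        if mm <= max_mm:
            hits.append((i, mm))
    return hits


def offtarget_counts(protospacer: str, seqs, max_mm: int):
    """Both-strand Hamming occurrence counts at mm 0..max_mm."""
    counts = [0] * (max_mm + 1)
    for pat in (protospacer, revcomp(protospacer)):
        for seq in seqs:
            for _i, mm in hamming_hits(pat, seq, max_mm):
                counts[mm] += 1
    return counts


def map_hits(kmer: str, assembly: dict, max_mm: int):
    """(scaffold, start, strand, mm) of full-length ungapped placements."""
    hits = []
    for scaffold, seq in assembly.items():
        for strand, pat in (("+", kmer), ("-", revcomp(kmer))):
            for start, mm in hamming_hits(pat, seq, max_mm):
                hits.append((scaffold, start, strand, mm))
    return hits
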