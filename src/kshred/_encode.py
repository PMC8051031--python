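"""2-bit k-mer encoding primitives shared across the pipeline.

Bases are encoded A=0, C=1, G=2, T=3; any other byte becomes the invalid
code 255 so that windows containing ambiguous bases (or record sentinels)
can be masked out with one cumulative-sum pass.  A k-mer with k <= 32 packs
into a uint64, two bits per base, first base in the highest occupied bits.
"""

from __future__ import annotations

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
INVALID = np.uint8(255)

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _LUT[_b] = _i

_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_RC)[::-1]


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a sequence to uint8 base codes (255 for non-ACGT)."""
    if isinstance(seq, str):
        seq = seq.encode()
    return _LUT[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for valid codes only."""
    return _BASES[codes].tobytes().decode()


def window_codes(codes: np.ndarray, k: int):
    """Pack every length-k window of a code array into uint64 integers.

    Returns ``(fwd, rc, valid)`` where ``fwd[i]`` encodes the window
    starting at i, ``rc[i]`` its reverse complement, and ``valid[i]`` is
    False when the window contains any invalid base.
    """
    if k < 1 or k > 32:
        raise ValueError(f"k must be in [1, 32], got {k}")
    n = codes.size
    m = n - k + 1
    if m <= 0:
        e = np.empty(0, np.uint64)
        return e, e.copy(), np.empty(0, bool)

    # validity from the (sparse) invalid positions: window i is bad iff an
    # invalid base lies in [i, i+k)
    badpos = np.flatnonzero(codes > 3)
    if badpos.size == 0:
        valid = np.ones(m, bool)
    else:
        delta = np.zeros(m + 1, np.int32)
        np.add.at(delta, np.clip(badpos - k + 1, 0, m), 1)
        np.add.at(delta, np.minimum(badpos + 1, m), -1)
        valid = np.cumsum(delta[:m], dtype=np.int32) == 0

    # log-doubling construction: window codes for power-of-two lengths in
    # the narrowest dtype that holds them, composed along the binary
    # decomposition of k.  Invalid bases leave garbage bits; the validity
    # mask excludes those windows.
    _dt = {1: np.uint8, 2: np.uint8, 4: np.uint8, 8: np.uint16, 16: np.uint32, 32: np.uint64}
    c = codes & np.uint8(3)
    fs = {1: c}
    rs = {1: np.uint8(3) - c}
    a = 1
    while a * 2 <= k:
        fa, ra = fs[a], rs[a]
        lb = fa.size - a
        dt = _dt[2 * a]
        sh = dt(2 * a)
        tf = fa[:lb].astype(dt)
        tf <<= sh
        tf |= fa[a : a + lb]
        fs[2 * a] = tf
        tr = ra[a : a + lb].astype(dt)
        tr <<= sh
        tr |= ra[:lb]
        rs[2 * a] = tr
        a *= 2
    parts = []
    rem, p = k, a
    while rem:
        if p <= rem:
            parts.append(p)
            rem -= p
        p //= 2
    off = 0
    f = r = None
    for p in parts:
        fp = fs[p][off : off + m]
        rp = rs[p][off : off + m]
        if f is None:
            f, r = fp.astype(np.uint64), rp.astype(np.uint64)
        else:
            f <<= np.uint64(2 * p)
            f |= fp
            tr = rp.astype(np.uint64)
            tr <<= np.uint64(2 * off)
            r |= tr
        off += p
    return f, r, valid


def canonical_windows(codes: np.ndarray, k: int):
    """Canonical (min of strand pair) packed codes for every valid window."""
    f, r, valid = window_codes(codes, k)
    return np.minimum(f, r), valid


def kmer_to_code(kmer: str) -> int:
    """Pack a single k-mer string (forward strand, no canonicalization)."""
    c = encode(kmer)
    if np.any(c > 3):
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
    f, _, _ = window_codes(c, len(kmer))
    return int(f[0])


def canonical_code(kmer: str) -> int:
    c = encode(kmer)
    if np.any(c > 3):
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
    f, r, _ = window_codes(c, len(kmer))
    return int(min(f[0], r[0]))


def code_to_kmer(code: int, k: int) -> str:
    out = np.empty(k, np.uint8)
    for j in range(k - 1, -1, -1):
        out[j] = code & 3
        code >>= 2
    return decode(out)


def codes_to_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized decode of packed codes to fixed-width byte strings."""
    n = codes.size
    chars = np.empty((n, k), np.uint8)
    c = codes.astype(np.uint64)
    for j in range(k - 1, -1, -1):
        chars[:, j] = _BASES[(c & np.uint64(3)).astype(np.intp)]
        c >>= np.uint64(2)
    return chars.reshape(n * k).view(f"S{k}")


def flatten_with_sentinels(seqs) -> np.ndarray:
    """Concatenate sequences into one code array separated by invalid bytes.

    Windows spanning two sequences are automatically invalidated by the
    sentinel, so one vectorized pass handles a whole batch of reads.
    """
    joined = "\x00".join(seqs) if seqs else ""
    return encode(joined)


def hamming_pack_mismatches(window_codes_fwd: np.ndarray, pattern_code: int, k: int) -> np.ndarray:
    """Per-window base mismatches vs a packed pattern via 2-bit XOR popcount."""
    x = window_codes_fwd ^ np.uint64(pattern_code)
    # collapse each 2-bit base field to its low bit, then count set bits
    y = (x | (x >> np.uint64(1))) & np.uint64(0x5555555555555555)
    return np.bitwise_count(y)
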