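"""Canonical k-mer census of sexed short-read libraries and the CQ statistic.

Reads are end-trimmed, every ACGT-only window of length k contributes one
count to its canonical (lexicographically smaller strand) k-mer, and the
male and female censuses are merged, floored at a combined-count noise
threshold, library-size normalized and scored with the chromosome quotient

    CQ = (count_f / total_f) / (count_m / total_m)

which is ~2 for X-linked, ~1 for autosomal and ~0 for Y-linked sequence in
an XX/XY system.  k-mers absent from the male library receive an infinite
sentinel so they sort into the X band and are vetted later by the long-read
X-specificity index.

Counting is numpy-vectorized over 2-bit packed windows; the noise floor is
applied to the combined count (a Y-specific k-mer legitimately has zero
female count, so per-library floors would erase the Y class).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np
import pandas as pd

from . import io as _io
from ._encode import canonical_windows, codes_to_kmers, flatten_with_sentinels

CQ_CAP = np.inf

CLASS_X = "X"
CLASS_A = "A"
CLASS_Y = "Y"
CLASS_AMBIGUOUS = "GA"


@dataclass
class CensusParams:
    k: int = 25
    trimm5: int = 5
    trimm3: int = 5
    kmernoise: int = 5
    lsum: int = 100

    def validate(self):
        errs = []
        if not (1 <= self.k <= 32):
            errs.append("census: k must be in [1, 32]")
        if self.trimm5 < 0 or self.trimm3 < 0:
            errs.append("census: trims must be >= 0")
        if self.kmernoise < 0:
            errs.append("census: kmernoise must be >= 0")
        if self.lsum < 0:
            errs.append("census: lsum must be >= 0")
        return errs


@dataclass
class ClassThresholds:
    """CQ bands: Y-like <= y_max; a_min <= autosomal <= a_max; X >= x_min.

    The X floor sits well below the theoretical X value of 2 because at
    moderate coverage the per-k-mer CQ of even a high-copy repeat has a
    log-sd of several percent, and the normalization itself centres CQ at
    2*(total_m/total_f) < 2; a floor of 1.5 keeps the false-negative rate
    for true X repeats negligible while autosomal leakage into the band
    stays rare and is removed downstream by the abundance and XSI filters.
    """

    y_max: float = 0.2
    a_min: float = 0.5
    a_max: float = 1.4
    x_min: float = 1.5

    def validate(self):
        errs = []
        if not (0 <= self.y_max < self.a_min <= self.a_max < self.x_min):
            errs.append(
                "thresholds: bands must satisfy 0 <= y_max < a_min <= a_max < x_min "
                f"(got {self.y_max}, {self.a_min}, {self.a_max}, {self.x_min})"
            )
        return errs


def trim_read(sequence: str, trimm5: int, trimm3: int) -> str:
    """Remove trimm5 leading and trimm3 trailing bases (empty when too short)."""
    if len(sequence) <= trimm5 + trimm3:
        return ""
    return sequence[trimm5 : len(sequence) - trimm3] if trimm3 else sequence[trimm5:]


def canonical(kmer: str) -> str:
    """The lexicographically smaller of a k-mer and its reverse complement."""
    from ._encode import revcomp

    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


class KmerCounter:
    """Accumulates canonical k-mer counts from batches of sequences.

    Maintains a sorted (codes, counts) pair merged incrementally, so memory
    stays proportional to the number of distinct k-mers, not to the number
    of windows counted.
    """

    def __init__(self, k: int = 25):
        self.k = k
        self.codes = np.empty(0, np.uint64)
        self.counts = np.empty(0, np.int64)
        self.total_windows = 0  # windows attempted (incl. invalid)
        self.total_valid = 0  # windows counted
        self.n_invalid = 0

    def update(self, seqs: Iterable[str]) -> None:
        seqs = [s for s in seqs if s]
        if not seqs:
            return
        flat = flatten_with_sentinels(seqs)
        canon, valid = canonical_windows(flat, self.k)
        # windows attempted per read: max(0, len - k + 1)
        self.total_windows += sum(max(0, len(s) - self.k + 1) for s in seqs)
        good = canon[valid]
        self.total_valid += good.size
        self.n_invalid = self.total_windows - self.total_valid
        if good.size == 0:
            return
        u, c = np.unique(good, return_counts=True)
        self._merge(u, c)

    def _merge(self, u: np.ndarray, c: np.ndarray) -> None:
        if self.codes.size == 0:
            self.codes, self.counts = u, c
            return
        codes = np.concatenate([self.codes, u])
        counts = np.concatenate([self.counts, c])
        order = np.argsort(codes, kind="stable")
        codes, counts = codes[order], counts[order]
        new = np.empty(codes.size, bool)
        new[0] = True
        np.not_equal(codes[1:], codes[:-1], out=new[1:])
        idx = np.flatnonzero(new)
        self.codes = codes[idx]
        self.counts = np.add.reduceat(counts, idx)

    def count_of(self, kmer: str) -> int:
        from ._encode import canonical_code

        code = np.uint64(canonical_code(kmer))
        i = np.searchsorted(self.codes, code)
        if i < self.codes.size and self.codes[i] == code:
            return int(self.counts[i])
        return 0

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=self.codes)


def count_kmers(reads: Union[str, Iterable], params: CensusParams, batch_size: int = 200_000) -> KmerCounter:
    """Census a read library (FASTQ/FASTA path, or iterable of sequences)."""
    errs = params.validate()
    if errs:
        raise ValueError("; ".join(errs))
    counter = KmerCounter(params.k)
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        seq_iter = (seq for _name, seq in _io.read_seqs(reads))
    else:
        seq_iter = iter(reads)
    batch = []
    for seq in seq_iter:
        t = trim_read(seq, params.trimm5, params.trimm3)
        if t:
            batch.append(t)
        if len(batch) >= batch_size:
            counter.update(batch)
            batch = []
    counter.update(batch)
    return counter


def compute_cq(count_m, count_f, total_m: int, total_f: int):
    """Chromosome quotient; vectorized. count_m == 0 maps to the +inf cap."""
    if total_m <= 0 or total_f <= 0:
        raise ValueError("library totals must be > 0")
    count_m = np.asarray(count_m, float)
    count_f = np.asarray(count_f, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cq = (count_f / total_f) / (count_m / total_m)
    cq = np.where(count_m == 0, np.where(count_f == 0, 0.0, CQ_CAP), cq)
    if cq.ndim == 0:
        return float(cq)
    return cq


def classify_cq(cq, thresholds: ClassThresholds = ClassThresholds()):
    """Map CQ values to {X, A, Y, GA(ambiguous)} class labels."""
    errs = thresholds.validate()
    if errs:
        raise ValueError("; ".join(errs))
    cq = np.asarray(cq, float)
    out = np.full(cq.shape, CLASS_AMBIGUOUS, dtype="U2")
    out[cq <= thresholds.y_max] = CLASS_Y
    out[(cq >= thresholds.a_min) & (cq <= thresholds.a_max)] = CLASS_A
    out[cq >= thresholds.x_min] = CLASS_X
    if out.ndim == 0:
        return str(out)
    return out


def merge_census(
    census_m: KmerCounter,
    census_f: KmerCounter,
    params: CensusParams,
    thresholds: ClassThresholds = ClassThresholds(),
) -> pd.DataFrame:
    """Join the two sexed censuses into the k-mer record table.

    Columns: count_m, count_f, sum, cpm_m, cpm_f, cq, kmer_class; the index
    is the packed canonical code.  Records with combined count below
    ``kmernoise`` are dropped.
    """
    if census_m.k != census_f.k:
        raise ValueError(f"censuses built with different k: {census_m.k} vs {census_f.k}")
    total_m = max(census_m.total_valid, 1)
    total_f = max(census_f.total_valid, 1)
    codes = np.union1d(census_m.codes, census_f.codes)
    cm = np.zeros(codes.size, np.int64)
    cf = np.zeros(codes.size, np.int64)
    im = np.searchsorted(codes, census_m.codes)
    cm[im] = census_m.counts
    if_ = np.searchsorted(codes, census_f.codes)
    cf[if_] = census_f.counts
    s = cm + cf
    keep = s >= params.kmernoise
    codes, cm, cf, s = codes[keep], cm[keep], cf[keep], s[keep]
    cq = compute_cq(cm, cf, total_m, total_f)
    df = pd.DataFrame(
        {
            "count_m": cm,
            "count_f": cf,
            "sum": s,
            "cpm_m": cm / total_m * 1e6,
            "cpm_f": cf / total_f * 1e6,
            "cq": cq,
            "kmer_class": classify_cq(cq, thresholds),
        },
        index=pd.Index(codes, name="code"),
    )
    df.attrs["k"] = params.k
    df.attrs["total_m"] = total_m
    df.attrs["total_f"] = total_f
    return df


def census_to_tsv(df: pd.DataFrame, path, chunk: int = 500_000) -> None:
    """Write the census with decoded k-mer sequences (chunked: the decoded
    string column would otherwise dominate memory at genome scale)."""
    k = df.attrs.get("k", 25)
    codes = df.index.to_numpy(np.uint64)
    with open(path, "wt") as fh:
        for start in range(0, max(len(df), 1), chunk):
            part = df.iloc[start : start + chunk].copy()
            part.insert(0, "kmer", codes_to_kmers(codes[start : start + chunk], k).astype("U"))
            part.to_csv(fh, sep="\t", index=False, float_format="%.6g", header=(start == 0))


def census_from_tsv(path, k: int = 25) -> pd.DataFrame:
    from ._encode import canonical_code

    out = pd.read_csv(path, sep="\t")
    codes = np.array([canonical_code(s) for s in out.pop("kmer")], np.uint64)
    out.index = pd.Index(codes, name="code")
    out.attrs["k"] = k
    return out
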