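"""Long-read filtering, chromosome binning and per-k-mer long-read statistics.

Reads are first filtered by length and mitochondrial k-mer content, then
assigned to an X / Y / autosomal bin from the census-classified diagnostic
k-mers they carry (majority class with a dominance margin; GA = ambiguous
otherwise).  For every candidate k-mer the pass accumulates its total
occurrences across kept reads (hits_sum), its maximum occurrence within any
single read (max_pt), the number of distinct reads containing it
(unique_bin_occurrence), per-bin hit counts and the X-specificity index

    XSI = hits on X-bin reads / hits on all kept reads

whose floor (0.995) is the decisive specificity filter.  Matching is exact
canonical k-mer lookup; sequencing error in the simulator is the stress
test for that choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as _io
from ._encode import canonical_windows, codes_to_kmers, encode
from .census import CLASS_A, CLASS_X, CLASS_Y

STATUS_KEPT = "kept"
STATUS_TOO_SHORT = "too_short"
STATUS_TOO_LONG = "too_long"
STATUS_MITO = "mito"

BIN_X, BIN_Y, BIN_A, BIN_GA = "X", "Y", "A", "GA"


@dataclass
class BinningParams:
    min_length: int = 2000
    max_length: int = 100000
    mito_share_threshold: float = 0.5
    # Majority rule with margin.  At moderate simulated coverage the
    # per-k-mer CQ classification of single-copy k-mers is noisy enough that
    # a clean X read carries only ~70-80% X-classified diagnostics, so a
    # dominance cut above that would send whole chromosomes to GA.
    dominance_threshold: float = 0.6
    k: int = 25

    def validate(self):
        errs = []
        if self.min_length > self.max_length:
            errs.append("binning: min_length must be <= max_length")
        if not (0.0 <= self.mito_share_threshold <= 1.0):
            errs.append("binning: mito_share_threshold must be in [0, 1]")
        if not (0.0 < self.dominance_threshold <= 1.0):
            errs.append("binning: dominance_threshold must be in (0, 1]")
        return errs


def filter_long_reads(lengths, min_length: int = 2000, max_length: int = 100000) -> np.ndarray:
    """Status per read; bounds are inclusive on both ends."""
    if min_length > max_length:
        raise ValueError("min_length must be <= max_length")
    lengths = np.asarray(lengths)
    out = np.full(lengths.shape, STATUS_KEPT, dtype="U9")
    out[lengths < min_length] = STATUS_TOO_SHORT
    out[lengths > max_length] = STATUS_TOO_LONG
    return out


def mito_kmer_set(mito_sequence: str, k: int = 25) -> np.ndarray:
    """Sorted canonical codes of the mitochondrial reference."""
    canon, valid = canonical_windows(encode(mito_sequence), k)
    return np.unique(canon[valid])


def mito_share(read_codes: np.ndarray, mito_codes: np.ndarray) -> float:
    """Fraction of a read's valid canonical k-mers present in the mito set."""
    if read_codes.size == 0:
        return 0.0
    return float(_in_sorted(read_codes, mito_codes).mean())


def mito_filter(
    reads: Iterable[Tuple[str, str]],
    mito_reference: str,
    share_threshold: float = 0.5,
    k: int = 25,
):
    """Partition (id, sequence) reads into (kept, mito) lists.

    A read is mitochondrial when the fraction of its canonical k-mers found
    in the reference's k-mer set reaches the threshold.
    """
    if not mito_reference:
        raise ValueError("mito reference must be non-empty")
    ref = mito_kmer_set(mito_reference, k)
    kept, mito = [], []
    for name, seq in reads:
        canon, valid = canonical_windows(encode(seq), k)
        codes = np.sort(canon[valid])
        (mito if mito_share(codes, ref) >= share_threshold else kept).append((name, seq))
    return kept, mito


def _in_sorted(values: np.ndarray, sorted_ref: np.ndarray) -> np.ndarray:
    if sorted_ref.size == 0:
        return np.zeros(values.shape, bool)
    idx = np.searchsorted(sorted_ref, values)
    idx[idx == sorted_ref.size] = sorted_ref.size - 1
    return sorted_ref[idx] == values


class DiagnosticKmers:
    """Census-classified k-mers of the three diagnostic classes.

    Stored as one sorted code array plus a class-label array, so a read is
    scored with a single merge-style lookup (queries are pre-sorted, which
    keeps the binary searches cache-friendly on multi-million-k-mer sets).
    """

    _LABELS = (CLASS_X, CLASS_A, CLASS_Y)

    def __init__(self, census: pd.DataFrame):
        codes = census.index.to_numpy(np.uint64)
        cls = census["kmer_class"].to_numpy()
        self.k = census.attrs.get("k", 25)
        diag = np.isin(cls, self._LABELS)
        order = np.argsort(codes[diag], kind="stable")
        self.codes = codes[diag][order]
        label_of = {l: i for i, l in enumerate(self._LABELS)}
        self.labels = np.array([label_of[c] for c in cls[diag]], np.uint8)[order]
        self.x = self.codes[self.labels == 0]
        self.a = self.codes[self.labels == 1]
        self.y = self.codes[self.labels == 2]

    def tallies(self, read_codes: np.ndarray) -> Tuple[int, int, int]:
        """(X, A, Y) diagnostic occurrence counts; sorted input is fastest."""
        if self.codes.size == 0 or read_codes.size == 0:
            return 0, 0, 0
        idx = np.searchsorted(self.codes, read_codes)
        idx_c = np.minimum(idx, self.codes.size - 1)
        hit = self.codes[idx_c] == read_codes
        counts = np.bincount(self.labels[idx_c[hit]], minlength=3)
        return int(counts[0]), int(counts[1]), int(counts[2])


def assign_bin(tally_x: int, tally_a: int, tally_y: int, dominance_threshold: float = 0.6) -> str:
    """Largest-tally class if its diagnostic share clears the margin, else GA."""
    total = tally_x + tally_a + tally_y
    if total == 0:
        return BIN_GA
    best = max((tally_x, BIN_X), (tally_a, BIN_A), (tally_y, BIN_Y))
    if best[0] / total >= dominance_threshold and (
        # a strict tie between two classes is never dominant
        [tally_x, tally_a, tally_y].count(best[0]) == 1
        or best[0] == total
    ):
        return best[1]
    return BIN_GA


def bin_long_read(sequence: str, census: pd.DataFrame, dominance_threshold: float = 0.6) -> str:
    """Bin one read against a classified census (convenience wrapper)."""
    diag = DiagnosticKmers(census)
    canon, valid = canonical_windows(encode(sequence), diag.k)
    return assign_bin(*diag.tallies(canon[valid]), dominance_threshold)


@dataclass
class LongReadStatsResult:
    read_table: pd.DataFrame
    kmer_stats: pd.DataFrame
    n_kept: int = 0


class _StatsAccumulator:
    """Per-candidate-k-mer accumulators over kept, binned reads."""

    def __init__(self, codes: np.ndarray):
        self.codes = np.unique(np.asarray(codes, np.uint64))
        n = self.codes.size
        self.hits_sum = np.zeros(n, np.int64)
        self.max_pt = np.zeros(n, np.int64)
        self.unique = np.zeros(n, np.int64)
        self.bin_hits = {b: np.zeros(n, np.int64) for b in (BIN_X, BIN_Y, BIN_A, BIN_GA)}

    def add_read(self, read_codes: np.ndarray, bin_label: str) -> None:
        if read_codes.size == 0 or self.codes.size == 0:
            return
        idx = np.searchsorted(self.codes, read_codes)
        idx_c = np.minimum(idx, self.codes.size - 1)
        matched = idx_c[self.codes[idx_c] == read_codes]
        if matched.size == 0:
            return
        # sparse per-read update: only the candidates present on this read
        u, occ = np.unique(matched, return_counts=True)
        self.hits_sum[u] += occ
        np.maximum.at(self.max_pt, u, occ)
        self.unique[u] += 1
        self.bin_hits[bin_label][u] += occ

    def frame(self, k: int) -> pd.DataFrame:
        total = self.hits_sum.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            xsi = np.where(total > 0, self.bin_hits[BIN_X] / np.maximum(total, 1), np.nan)
        df = pd.DataFrame(
            {
                "hits_sum": self.hits_sum,
                "max_pt": self.max_pt,
                "unique_bin_occurrence": self.unique,
                "hits_X": self.bin_hits[BIN_X],
                "hits_Y": self.bin_hits[BIN_Y],
                "hits_A": self.bin_hits[BIN_A],
                "hits_GA": self.bin_hits[BIN_GA],
                "xsi": xsi,
            },
            index=pd.Index(self.codes, name="code"),
        )
        df.attrs["k"] = k
        return df


def process_long_reads(
    reads: Iterable[Tuple[str, str]],
    census: pd.DataFrame,
    mito_sequence: Optional[str] = None,
    params: BinningParams = BinningParams(),
    stat_codes: Optional[np.ndarray] = None,
) -> LongReadStatsResult:
    """Single pass over a long-read library: filter, bin and accumulate stats.

    ``reads`` is an iterable of (id, sequence) or a FASTA/FASTQ path.
    ``stat_codes`` selects the k-mers whose long-read statistics are
    accumulated (default: the census X-candidate class).
    """
    errs = params.validate()
    if errs:
        raise ValueError("; ".join(errs))
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        reads = _io.read_seqs(reads)
    diag = DiagnosticKmers(census)
    k = params.k
    mito_codes = mito_kmer_set(mito_sequence, k) if mito_sequence else np.empty(0, np.uint64)
    if stat_codes is None:
        stat_codes = diag.x
    acc = _StatsAccumulator(stat_codes)

    rows = []
    n_kept = 0
    for name, seq in reads:
        L = len(seq)
        if L < params.min_length:
            rows.append((name, L, STATUS_TOO_SHORT, "", 0, 0, 0))
            continue
        if L > params.max_length:
            rows.append((name, L, STATUS_TOO_LONG, "", 0, 0, 0))
            continue
        canon, valid = canonical_windows(encode(seq), k)
        codes = np.sort(canon[valid])  # sorted queries keep lookups cache-friendly
        if mito_codes.size and codes.size and mito_share(codes, mito_codes) >= params.mito_share_threshold:
            rows.append((name, L, STATUS_MITO, "", 0, 0, 0))
            continue
        tx, ta, ty = diag.tallies(codes)
        b = assign_bin(tx, ta, ty, params.dominance_threshold)
        rows.append((name, L, STATUS_KEPT, b, tx, ta, ty))
        acc.add_read(codes, b)
        n_kept += 1

    read_table = pd.DataFrame(
        rows, columns=["read_id", "length", "status", "bin", "tally_X", "tally_A", "tally_Y"]
    )
    return LongReadStatsResult(read_table=read_table, kmer_stats=acc.frame(k), n_kept=n_kept)


def kmer_longread_stats(kmer: str, binned_reads: Iterable[Tuple[str, str]], k: int = 25) -> dict:
    """Statistics of one k-mer over (sequence, bin) pairs (reference path)."""
    from ._encode import canonical_code

    code = np.uint64(canonical_code(kmer))
    hits_sum = 0
    max_pt = 0
    unique = 0
    bin_hits = {b: 0 for b in (BIN_X, BIN_Y, BIN_A, BIN_GA)}
    for seq, b in binned_reads:
        canon, valid = canonical_windows(encode(seq), k)
        occ = int(np.count_nonzero(canon[valid] == code))
        if occ:
            hits_sum += occ
            max_pt = max(max_pt, occ)
            unique += 1
            bin_hits[b] += occ
    xsi = bin_hits[BIN_X] / hits_sum if hits_sum else float("nan")
    return {
        "kmer": kmer,
        "hits_sum": hits_sum,
        "max_pt": max_pt,
        "unique_bin_occurrence": unique,
        **{f"hits_{b}": v for b, v in bin_hits.items()},
        "xsi": xsi,
    }


def xsi_filter(
    kmer_stats: pd.DataFrame,
    census: pd.DataFrame,
    xsi_min: float = 0.995,
    lsum: int = 100,
) -> pd.DataFrame:
    """Validated candidate set: X-class k-mers with XSI >= floor, sum >= LSum.

    k-mers absent from all long reads (hits_sum 0, XSI undefined) are
    excluded from candidacy.
    """
    joined = kmer_stats.join(census[["count_m", "count_f", "sum", "cq", "kmer_class"]], how="inner")
    keep = (
        (joined["kmer_class"] == CLASS_X)
        & (joined["hits_sum"] > 0)
        & (joined["xsi"] >= xsi_min)
        & (joined["sum"] >= lsum)
    )
    out = joined[keep].copy()
    out.attrs["k"] = kmer_stats.attrs.get("k", census.attrs.get("k", 25))
    return out


def stats_to_tsv(df: pd.DataFrame, path) -> None:
    k = df.attrs.get("k", 25)
    out = df.copy()
    out.insert(0, "kmer", codes_to_kmers(df.index.to_numpy(np.uint64), k).astype("U"))
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
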