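"""Post-hoc genome-assembly audit: contig sex assignment, k-mer mapping,
repeat-array dissection and region-derived k-mer specificity.

Contigs are sexed by the median chromosome quotient of their annotated
genes (contigs with fewer than 10 genes stay unassigned).  Selected k-mers
are located in the assembly by full-length, ungapped, mismatch-tolerant
scanning on both strands; per-scaffold hits are clustered by single
linkage, and the median inter-hit spacing of a cluster approximates the
repeat-unit length of a head-to-tail tandem array.  All coordinates are
0-based, half-open (BED convention).
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._encode import (
    canonical_windows,
    codes_to_kmers,
    encode,
    hamming_pack_mismatches,
    kmer_to_code,
    revcomp,
    window_codes,
)
from .census import ClassThresholds, classify_cq, compute_cq

CONTIG_UNASSIGNED = "unassigned"


def gene_cq(
    gene_counts: pd.DataFrame,
    total_m: Optional[int] = None,
    total_f: Optional[int] = None,
) -> pd.DataFrame:
    """Per-gene chromosome quotient from sexed read counts.

    ``gene_counts`` needs columns gene, contig, reads_m, reads_f.  Library
    totals default to the column sums.  Genes with zero reads in both sexes
    get NaN and are excluded from downstream medians.
    """
    df = gene_counts.copy()
    tm = int(total_m) if total_m is not None else int(df["reads_m"].sum())
    tf = int(total_f) if total_f is not None else int(df["reads_f"].sum())
    cq = compute_cq(df["reads_m"].to_numpy(), df["reads_f"].to_numpy(), tm, tf)
    cq = np.where((df["reads_m"] == 0) & (df["reads_f"] == 0), np.nan, cq)
    df["cq"] = cq
    return df


def contig_cq(
    gene_table: pd.DataFrame,
    min_genes: int = 10,
    thresholds: ClassThresholds = ClassThresholds(),
) -> pd.DataFrame:
    """Median gene CQ per contig with the minimum-gene-count rule.

    Contigs with fewer than ``min_genes`` CQ-scored genes are classed
    ``unassigned``; the others reuse the census CQ bands.
    """
    rows = []
    for contig, grp in gene_table.groupby("contig", sort=True):
        cqs = grp["cq"].dropna().to_numpy()
        n = cqs.size
        if n < min_genes:
            rows.append((contig, n, np.nan, CONTIG_UNASSIGNED))
        else:
            med = float(np.median(cqs))
            rows.append((contig, n, med, str(classify_cq(med, thresholds))))
    return pd.DataFrame(rows, columns=["contig", "n_genes", "median_cq", "contig_class"])


def map_kmers_to_assembly(
    kmers: Sequence[str],
    assembly: Dict[str, str],
    max_mm: int = 0,
) -> pd.DataFrame:
    """Every full-length ungapped placement of each k-mer with <= max_mm
    substitutions, on both strands.

    Returns a BED-like frame (scaffold, start, end, kmer, mismatches,
    strand) sorted by scaffold and start.  Scaffolds shorter than k yield
    no hits.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    rows = []
    enc = {name: encode(seq) for name, seq in assembly.items()}
    for kmer in kmers:
        k = len(kmer)
        p_fwd = kmer_to_code(kmer)
        p_rev = kmer_to_code(revcomp(kmer))
        for scaffold, codes in enc.items():
            if codes.size < k:
                continue
            f, _r, valid = window_codes(codes, k)
            for strand, pat in (("+", p_fwd), ("-", p_rev)):
                mm = hamming_pack_mismatches(f, pat, k)
                hit = valid & (mm <= max_mm)
                for start in np.flatnonzero(hit):
                    rows.append((scaffold, int(start), int(start) + k, kmer, int(mm[start]), strand))
    df = pd.DataFrame(rows, columns=["scaffold", "start", "end", "kmer", "mismatches", "strand"])
    return df.sort_values(["scaffold", "start", "strand"], kind="stable").reset_index(drop=True)


def cluster_hits(hits: pd.DataFrame, max_gap: int = 20000) -> pd.DataFrame:
    """Single-linkage clustering of hits per scaffold into repeat arrays.

    Hits on the same scaffold whose start-to-start gap is <= max_gap join
    one array.  Median inter-hit spacing (over consecutive starts) estimates
    the repeat-unit length of a head-to-tail array.
    """
    rows = []
    for scaffold, grp in hits.groupby("scaffold", sort=True):
        starts = np.sort(grp["start"].to_numpy())
        ends = grp["end"].to_numpy()[np.argsort(grp["start"].to_numpy(), kind="stable")]
        if starts.size == 0:
            continue
        gaps = np.diff(starts)
        breaks = np.flatnonzero(gaps > max_gap) + 1
        for seg_start, seg_end in zip(np.r_[0, breaks], np.r_[breaks, starts.size]):
            seg = slice(seg_start, seg_end)
            s = starts[seg]
            e = ends[seg]
            spacing = float(np.median(np.diff(s))) if s.size >= 2 else np.nan
            rows.append((scaffold, int(s[0]), int(e.max()), int(s.size), spacing))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "n_hits", "median_spacing"])


def region_kmer_specificity(
    assembly: Dict[str, str],
    scaffold: str,
    start: int,
    end: int,
    k: int = 25,
) -> pd.DataFrame:
    """Census the k-mers of a region and count their exact hits at region,
    host-scaffold and whole-assembly scale.

    ``specificity`` is scaffold hits / genome hits: 1.0 means the k-mer
    occurs nowhere outside the host scaffold.  Counts are canonical (strand
    agnostic) exact matches.
    """
    if scaffold not in assembly:
        raise KeyError(f"scaffold {scaffold!r} not in assembly")
    region = assembly[scaffold][start:end]
    canon, valid = canonical_windows(encode(region), k)
    if canon.size == 0 or not valid.any():
        return pd.DataFrame(
            columns=["kmer", "region_count", "scaffold_count", "genome_count", "specificity"]
        )
    codes, region_count = np.unique(canon[valid], return_counts=True)

    def counts_against(seq_iter: Iterable[str]) -> np.ndarray:
        out = np.zeros(codes.size, np.int64)
        for seq in seq_iter:
            c, v = canonical_windows(encode(seq), k)
            u, cnt = np.unique(c[v], return_counts=True)
            idx = np.searchsorted(codes, u)
            idx_c = np.minimum(idx, codes.size - 1)
            hit = codes[idx_c] == u
            out[idx_c[hit]] += cnt[hit]
        return out

    scaffold_count = counts_against([assembly[scaffold]])
    genome_count = counts_against(assembly.values())
    with np.errstate(divide="ignore", invalid="ignore"):
        spec = np.where(genome_count > 0, scaffold_count / np.maximum(genome_count, 1), np.nan)
    return pd.DataFrame(
        {
            "kmer": codes_to_kmers(codes, k).astype("U"),
            "region_count": region_count,
            "scaffold_count": scaffold_count,
            "genome_count": genome_count,
            "specificity": spec,
        }
    )


def hits_to_bed(hits: pd.DataFrame, path) -> None:
    cols = ["scaffold", "start", "end", "kmer", "mismatches", "strand"]
    hits[cols].to_csv(path, sep="\t", index=False, header=False)


def read_gene_counts(path) -> pd.DataFrame:
    """Read a per-gene sexed count TSV (gene, contig, reads_m, reads_f)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "contig", "reads_m", "reads_f"} - set(df.columns)
    if missing:
        raise ValueError(f"gene count table missing columns: {sorted(missing)}")
    return df
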