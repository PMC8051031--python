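"""Ranking of validated X-candidate k-mers and CRISPR target-site selection.

Candidates are ranked on four statistics — combined short-read abundance
(sum), total long-read occurrences (hits_sum), maximum occurrences within
one long read (max_pt) and the number of distinct long reads containing the
k-mer (unique_bin_occurrence).  Per criterion, the top-q percentile cut is
rank-based with ties included; the default combination is the intersection
of the four top sets, falling back to rank-sum ordering when the
intersection is smaller than the requested list, so the final pick is
algorithmic and reproducible.  Each surviving 25-mer is scanned for Cas9
(20-nt protospacer + NGG 3') and Cas12a (TTTV 5' + >=20-nt protospacer)
placements, and protospacers are screened PAM-agnostically against the
non-X long-read bins at Hamming distance 0..max_mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._encode import codes_to_kmers, encode, flatten_with_sentinels, revcomp

CRITERIA = ("sum", "hits_sum", "max_pt", "unique_bin_occurrence")


@dataclass
class SelectionParams:
    q: float = 0.0005  # top fraction per criterion (0.05%)
    top_n: int = 25
    xsi_min: float = 0.995
    combination: str = "intersection"  # with rank-sum fallback
    fallback_factor: int = 6  # rank-sum fallback flags top_n * factor
    max_mm: int = 3
    offtarget_mm_max: int = 2  # exclude on any background hit at mm <= this
    offtarget_max_hits: int = 0
    cas12a_min_spacer: int = 20

    def validate(self):
        errs = []
        if not (0.0 < self.q <= 1.0):
            errs.append("selection: q must be in (0, 1]")
        if self.top_n < 1:
            errs.append("selection: top_n must be >= 1")
        if not (0.0 <= self.xsi_min <= 1.0):
            errs.append("selection: xsi_min must be in [0, 1]")
        if self.combination not in ("intersection", "rank-sum"):
            errs.append("selection: combination must be intersection or rank-sum")
        if self.max_mm < 0:
            errs.append("selection: max_mm must be >= 0")
        if self.offtarget_mm_max > self.max_mm:
            errs.append("selection: offtarget_mm_max must be <= max_mm")
        return errs


@dataclass
class NucleasePlacement:
    nuclease: str  # Cas9 | Cas12a
    strand: str  # +/- relative to the stored k-mer
    offset: int  # protospacer start within the k-mer (on the given strand)
    protospacer: str
    pam: str


def pam_scan_cas9(kmer: str) -> List[NucleasePlacement]:
    """All placements of a 20-nt protospacer + NGG PAM inside the k-mer."""
    out = []
    for strand in "+-":
        s = kmer if strand == "+" else revcomp(kmer)
        for i in range(0, len(s) - 23 + 1):
            pam = s[i + 20 : i + 23]
            if pam[1] == "G" and pam[2] == "G":
                out.append(NucleasePlacement("Cas9", strand, i, s[i : i + 20], pam))
    return out


def pam_scan_cas12a(kmer: str, min_spacer: int = 20) -> List[NucleasePlacement]:
    """All placements of a TTTV PAM followed by a >= min_spacer protospacer.

    Inside a 25-mer the protospacer is necessarily truncated to <= 21 nt;
    the full remainder after the PAM is reported.
    """
    out = []
    for strand in "+-":
        s = kmer if strand == "+" else revcomp(kmer)
        for i in range(0, len(s) - 4 - min_spacer + 1):
            pam = s[i : i + 4]
            if pam[:3] == "TTT" and pam[3] in "ACG":
                out.append(NucleasePlacement("Cas12a", strand, i + 4, s[i + 4 :], pam))
    return out


def scan_placements(kmer: str, min_spacer: int = 20) -> List[NucleasePlacement]:
    return pam_scan_cas9(kmer) + pam_scan_cas12a(kmer, min_spacer)


# ---------------------------------------------------------------------------
# percentile filtering


def percentile_filter(candidates: pd.DataFrame, params: SelectionParams = SelectionParams()) -> pd.DataFrame:
    """Flag the top-percentile candidates and order them deterministically.

    Per criterion the threshold is the value at rank ceil(q*N) from the top
    with ties included.  Returns the flagged subset with per-criterion ranks,
    their rank sum, and a final deterministic ordering (rank-sum, then
    lexicographic k-mer).
    """
    errs = params.validate()
    if errs:
        raise ValueError("; ".join(errs))
    k = candidates.attrs.get("k", 25)
    if len(candidates) == 0:
        import warnings

        warnings.warn("percentile_filter: empty candidate set")
        out = candidates.copy()
        out["rank_sum"] = np.empty(0, np.int64)
        return out
    n = len(candidates)
    r = int(np.ceil(params.q * n))
    df = candidates.copy()
    in_top = np.ones(n, bool)
    rank_sum = np.zeros(n, np.int64)
    for crit in CRITERIA:
        vals = df[crit].to_numpy(float)
        ranks = rankdata(-vals, method="min").astype(np.int64)
        df[f"rank_{crit}"] = ranks
        rank_sum += ranks
        cut = np.sort(vals)[::-1][r - 1]
        in_top &= vals >= cut
    df["rank_sum"] = rank_sum
    kmers = codes_to_kmers(df.index.to_numpy(np.uint64), k).astype("U")
    df["kmer_str"] = kmers
    order = np.lexsort((kmers, rank_sum))

    if params.combination == "intersection" and int(in_top.sum()) >= params.top_n:
        flagged = df.iloc[order][in_top[order]]
    else:
        # rank-sum fallback: flag enough headroom for downstream drops
        n_flag = max(params.top_n * params.fallback_factor, int(in_top.sum()))
        flagged = df.iloc[order].head(n_flag)
    flagged = flagged.copy()
    flagged["rank"] = np.arange(1, len(flagged) + 1)
    flagged.attrs["k"] = k
    return flagged


# ---------------------------------------------------------------------------
# off-target screening


def offtarget_screen(protospacer: str, background: Iterable[str], max_mm: int = 3) -> np.ndarray:
    """Counts of the protospacer in background sequences at Hamming 0..max_mm.

    PAM-agnostic, both strands, substitutions only.  Dense vectorized scan;
    see BackgroundIndex for the seeded fast path over large read bins.
    """
    counts = np.zeros(max_mm + 1, np.int64)
    seqs = list(background)
    if not seqs:
        import warnings

        warnings.warn("offtarget_screen: empty background")
        return counts
    flat = flatten_with_sentinels(seqs)
    L = len(protospacer)
    for pat in (protospacer, revcomp(protospacer)):
        p = encode(pat)
        if flat.size < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(flat, L)
        mm = (win != p).sum(axis=1) + (win > 3).any(axis=1) * (max_mm + 1 + L)
        good = mm[mm <= max_mm]
        counts += np.bincount(good, minlength=max_mm + 1)
    return counts


class BackgroundIndex:
    """Pigeonhole-seeded Hamming search over a fixed background read set.

    The background is flattened with sentinels and indexed by the packed
    code of every 5-mer position.  A length-L query split into max_mm+1
    disjoint parts must match at least one part exactly at any hit with
    <= max_mm mismatches, so candidate positions come from part lookups and
    are verified densely.  Supports max_mm <= 3 for queries of length >= 20.
    """

    PART = 5

    def __init__(self, background: Iterable[str]):
        seqs = background if isinstance(background, list) else list(background)
        self.n_seqs = len(seqs)
        self.flat = flatten_with_sentinels(seqs) if seqs else np.empty(0, np.uint8)
        del seqs
        nkeys = 4**self.PART
        m = self.flat.size - self.PART + 1
        if m > 0:
            # 5-mer key per position in uint16; windows touching an invalid
            # byte get the out-of-band key `nkeys` and sort to the end
            keys = (self.flat[:m] & np.uint8(3)).astype(np.uint16)
            for j in range(1, self.PART):
                keys <<= np.uint16(2)
                keys |= self.flat[j : j + m] & np.uint8(3)
            badpos = np.flatnonzero(self.flat > 3)
            if badpos.size:
                delta = np.zeros(m + 1, np.int32)
                np.add.at(delta, np.clip(badpos - self.PART + 1, 0, m), 1)
                np.add.at(delta, np.minimum(badpos + 1, m), -1)
                keys[np.cumsum(delta[:m], dtype=np.int32) > 0] = nkeys
        else:
            keys = np.empty(0, np.uint16)
        # stable argsort of the small-range keys doubles as the position list
        self._pos = np.argsort(keys, kind="stable").astype(np.int32)
        self._bounds = np.zeros(nkeys + 2, np.int64)
        np.cumsum(np.bincount(keys, minlength=nkeys + 1), out=self._bounds[1:])

    def count(self, protospacer: str, max_mm: int = 3) -> np.ndarray:
        L = len(protospacer)
        nparts = max_mm + 1
        if L < nparts * self.PART:
            raise ValueError(f"query of length {L} too short for max_mm={max_mm}")
        counts = np.zeros(max_mm + 1, np.int64)
        if self.flat.size < L:
            return counts
        for pat in (protospacer, revcomp(protospacer)):
            p = encode(pat)
            cand = []
            for part in range(nparts):
                off = part * self.PART
                q = 0
                for j in range(self.PART):
                    q = (q << 2) | int(p[off + j])
                cand.append(self._pos[self._bounds[q] : self._bounds[q + 1]] - off)
            cand = np.unique(np.concatenate(cand))
            cand = cand[(cand >= 0) & (cand <= self.flat.size - L)]
            if cand.size == 0:
                continue
            win = self.flat[cand[:, None] + np.arange(L)]
            bad = (win > 3).any(axis=1)
            mm = (win != p).sum(axis=1)
            mm = mm[~bad]
            good = mm[mm <= max_mm]
            counts += np.bincount(good, minlength=max_mm + 1)
        return counts


# ---------------------------------------------------------------------------
# final ranking


def rank_targets(
    flagged: pd.DataFrame,
    background_index: Optional[BackgroundIndex],
    params: SelectionParams = SelectionParams(),
) -> pd.DataFrame:
    """Final target table: placements of the top_n surviving candidates.

    Candidates are examined in the deterministic flagged order; one is
    dropped when it has no nuclease placement, or when every placement has
    more than ``offtarget_max_hits`` background hits at mm <=
    ``offtarget_mm_max``.  Screening stops once top_n survivors are found
    (later candidates cannot displace earlier ones).
    """
    errs = params.validate()
    if errs:
        raise ValueError("; ".join(errs))
    rows = []
    n_selected = 0
    mm_cols = [f"offtarget_mm{m}" for m in range(params.max_mm + 1)]
    for code, rec in flagged.iterrows():
        if n_selected >= params.top_n:
            break
        kmer = rec["kmer_str"]
        placements = scan_placements(kmer, params.cas12a_min_spacer)
        if not placements:
            continue
        kept_rows = []
        for pl in placements:
            if background_index is not None:
                counts = background_index.count(pl.protospacer, params.max_mm)
            else:
                counts = np.zeros(params.max_mm + 1, np.int64)
            near = int(counts[: params.offtarget_mm_max + 1].sum())
            if near > params.offtarget_max_hits:
                continue
            kept_rows.append((pl, counts))
        if not kept_rows:
            continue
        n_selected += 1
        for pl, counts in kept_rows:
            row = {
                "kmer": kmer,
                "code": int(code),
                **{c: rec[c] for c in CRITERIA},
                "xsi": rec.get("xsi", np.nan),
                "nuclease": pl.nuclease,
                "strand": pl.strand,
                "offset": pl.offset,
                "protospacer": pl.protospacer,
                "pam": pl.pam,
                **dict(zip(mm_cols, counts.tolist())),
                "rank": int(rec["rank"]),
                "selected": True,
            }
            rows.append(row)
    if n_selected < params.top_n:
        import warnings

        warnings.warn(
            f"rank_targets: only {n_selected} of the requested {params.top_n} targets survived"
        )
    cols = (
        ["kmer", "code", *CRITERIA, "xsi", "nuclease", "strand", "offset", "protospacer", "pam"]
        + mm_cols
        + ["rank", "selected"]
    )
    return pd.DataFrame(rows, columns=cols)
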