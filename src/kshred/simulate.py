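"""Synthetic genomes, sexed short-read libraries and male long reads.

The generator emulates the statistical structure the discovery pipeline
assumes: an XY male / XX female diploid sampling model, X-linked
head-to-tail tandem repeat arrays (optionally with an inverted central
block), autosomal and Y background repeats, and a high-copy mitochondrial
contaminant.  Ground truth — the exact per-chromosome count of every
canonical k-mer in the emitted genome — is computed post hoc from the
sequences themselves, so random background collisions with planted arrays
are reported rather than prevented.

All randomness flows from integer seeds through numpy SeedSequence spawns;
identical seeds reproduce outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._encode import _BASES, canonical_windows, codes_to_kmers, encode

MITO_LABEL = "MT"
DEFAULT_K = 25


# ---------------------------------------------------------------------------
# specs


@dataclass
class RepeatClusterSpec:
    """A planted head-to-tail tandem repeat array.

    ``inverted_block`` is a 1-based inclusive (start_copy, end_copy) range of
    copies emitted reverse-complemented, mimicking a large inversion in the
    middle of an array.  ``substitution_rate`` mutates each copy
    independently (per-copy divergence), not the reads.
    """

    chromosome: str
    unit_length: int
    copy_number: int
    unit_seed: int
    start: Optional[int] = None
    head_to_tail: bool = True
    inverted_block: Optional[Tuple[int, int]] = None
    substitution_rate: float = 0.0
    name: Optional[str] = None

    def validate(self) -> List[str]:
        errs = []
        if self.copy_number < 1:
            errs.append(f"cluster {self.name}: copy_number must be >= 1")
        if self.unit_length < 25:
            errs.append(f"cluster {self.name}: unit_length must be >= 25")
        if not (0.0 <= self.substitution_rate < 1.0):
            errs.append(f"cluster {self.name}: substitution_rate must be in [0, 1)")
        if self.inverted_block is not None:
            a, b = self.inverted_block
            if not (1 <= a <= b <= self.copy_number):
                errs.append(
                    f"cluster {self.name}: inverted_block {self.inverted_block} "
                    f"outside [1, {self.copy_number}]"
                )
        return errs

    @property
    def span(self) -> int:
        return self.unit_length * self.copy_number


@dataclass
class GenomeSpec:
    """Chromosome lengths plus the planted repeat clusters.

    ``chromosomes`` maps labels to lengths; labels other than ``X``/``Y``
    are autosomes.  The mitochondrion is a separate template labelled
    ``MT``.
    """

    chromosomes: Dict[str, int]
    mito_length: int = 16000
    gc: float = 0.40
    clusters: List[RepeatClusterSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> List[str]:
        errs = []
        if not self.chromosomes:
            errs.append("genome: at least one chromosome required")
        if MITO_LABEL in self.chromosomes:
            errs.append(f"genome: label {MITO_LABEL} is reserved for the mitochondrion")
        if not (0.0 < self.gc < 1.0):
            errs.append("genome: gc must be in (0, 1)")
        if self.mito_length < 100:
            errs.append("genome: mito_length must be >= 100")
        for c in self.clusters:
            errs.extend(c.validate())
            if c.chromosome not in self.chromosomes:
                errs.append(f"cluster {c.name}: unknown chromosome {c.chromosome!r}")
        # placement feasibility / overlap, per chromosome
        by_chrom: Dict[str, list] = {}
        for c in self.clusters:
            if c.chromosome in self.chromosomes and c.start is not None:
                by_chrom.setdefault(c.chromosome, []).append(c)
        for chrom, cs in by_chrom.items():
            length = self.chromosomes[chrom]
            cs = sorted(cs, key=lambda c: c.start)
            prev_end, prev_name = -1, None
            for c in cs:
                if c.start < 0 or c.start + c.span > length:
                    errs.append(
                        f"cluster {c.name}: span [{c.start}, {c.start + c.span}) "
                        f"overflows chromosome {chrom} (length {length})"
                    )
                if c.start < prev_end:
                    errs.append(f"cluster {c.name}: overlaps cluster {prev_name} on {chrom}")
                prev_end, prev_name = c.start + c.span, c.name
        return errs

    @property
    def autosomes(self) -> List[str]:
        return sorted(l for l in self.chromosomes if l not in ("X", "Y"))


@dataclass
class ReadSimParams:
    """Short-read (Illumina-like) simulation parameters.

    ``depth`` is fold coverage per haploid genome copy: every template copy
    in the sex-specific multiset (female: autosomes x2, X x2; male:
    autosomes x2, X x1, Y x1; mitochondrion x ``mito_copy_multiplier``) is
    sampled to that depth with uniform start positions and i.i.d.
    substitution errors.
    """

    sex: str
    depth: float
    read_length: int = 150
    error_rate: float = 0.001
    mito_copy_multiplier: int = 100
    seed: int = 0

    def validate(self) -> List[str]:
        errs = []
        if self.sex not in ("male", "female"):
            errs.append(f"reads: sex must be male or female, got {self.sex!r}")
        if self.depth < 0:
            errs.append("reads: depth must be >= 0")
        if not (0.0 <= self.error_rate < 1.0):
            errs.append("reads: error_rate must be in [0, 1)")
        if self.read_length <= 35:
            errs.append("reads: read_length must be > 35")
        if self.mito_copy_multiplier < 0:
            errs.append("reads: mito_copy_multiplier must be >= 0")
        return errs


@dataclass
class LongReadSimParams:
    """Long-read (corrected PacBio-like) simulation parameters.

    Lengths are log-normal with the given linear-scale mean and log-scale
    sd, clipped to [min_length, max_length].  Either an explicit ``count``
    or a target ``depth`` over the male template multiset may be given.
    """

    mean_length: float = 10000.0
    sigma: float = 0.9
    min_length: int = 300
    max_length: int = 120000
    count: Optional[int] = None
    depth: Optional[float] = 20.0
    error_rate: float = 0.01
    mito_copy_multiplier: int = 100
    seed: int = 0

    def validate(self) -> List[str]:
        errs = []
        if self.min_length > self.max_length:
            errs.append("long reads: min_length must be <= max_length")
        if self.min_length < 25:
            errs.append("long reads: min_length must be >= 25")
        if not (0.0 <= self.error_rate < 1.0):
            errs.append("long reads: error_rate must be in [0, 1)")
        if self.count is None and self.depth is None:
            errs.append("long reads: one of count or depth is required")
        if self.count is not None and self.count < 0:
            errs.append("long reads: count must be >= 0")
        if self.depth is not None and self.depth < 0:
            errs.append("long reads: depth must be >= 0")
        return errs


# ---------------------------------------------------------------------------
# truth


@dataclass
class SyntheticTruth:
    """Exact canonical k-mer counts per chromosome of an emitted genome."""

    k: int
    labels: List[str]
    codes: np.ndarray  # sorted uint64 canonical codes
    counts: np.ndarray  # (n_codes, n_labels) int64
    clusters: List[dict] = field(default_factory=list)

    def _li(self, label: str) -> int:
        return self.labels.index(label)

    def counts_for(self, kmer: str) -> Dict[str, int]:
        from ._encode import canonical_code

        i = np.searchsorted(self.codes, np.uint64(canonical_code(kmer)))
        if i >= self.codes.size or self.codes[i] != np.uint64(canonical_code(kmer)):
            return {l: 0 for l in self.labels}
        return {l: int(self.counts[i, j]) for j, l in enumerate(self.labels)}

    def x_exclusive_codes(self, min_count: int = 1) -> np.ndarray:
        """Canonical codes occurring >= min_count times on X and nowhere else."""
        xi = self._li("X")
        other = np.delete(np.arange(len(self.labels)), xi)
        mask = (self.counts[:, xi] >= min_count) & (self.counts[:, other].sum(axis=1) == 0)
        return self.codes[mask]

    def exclusive_codes(self, label: str, min_count: int = 1) -> np.ndarray:
        li = self._li(label)
        other = np.delete(np.arange(len(self.labels)), li)
        mask = (self.counts[:, li] >= min_count) & (self.counts[:, other].sum(axis=1) == 0)
        return self.codes[mask]

    def counts_for_codes(self, codes: np.ndarray) -> np.ndarray:
        """(len(codes), n_labels) counts; zero rows for absent codes."""
        codes = np.asarray(codes, np.uint64)
        idx = np.searchsorted(self.codes, codes)
        idx_c = np.clip(idx, 0, max(self.codes.size - 1, 0))
        out = np.zeros((codes.size, len(self.labels)), np.int64)
        if self.codes.size:
            hit = self.codes[idx_c] == codes
            out[hit] = self.counts[idx_c[hit]]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Aggregated truth table: kmer, count_A, count_X, count_Y, count_mito."""
        a_cols = [j for j, l in enumerate(self.labels) if l not in ("X", "Y", MITO_LABEL)]
        df = pd.DataFrame(
            {
                "kmer": codes_to_kmers(self.codes, self.k).astype("U"),
                "count_A": self.counts[:, a_cols].sum(axis=1),
                "count_X": self.counts[:, self._li("X")] if "X" in self.labels else 0,
                "count_Y": self.counts[:, self._li("Y")] if "Y" in self.labels else 0,
                "count_mito": self.counts[:, self._li(MITO_LABEL)],
            }
        )
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def span_codes(genome: Dict[str, str], chromosome: str, start: int, end: int, k: int = DEFAULT_K) -> np.ndarray:
    """Unique canonical k-mer codes of a genomic interval (0-based, half-open)."""
    canon, valid = canonical_windows(encode(genome[chromosome][start:end]), k)
    return np.unique(canon[valid])


# ---------------------------------------------------------------------------
# genome construction


def _random_seq_codes(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return codes
    out = codes.copy()
    mask = rng.random(codes.size) < rate
    if mask.any():
        out[mask] = (out[mask] + rng.integers(1, 4, mask.sum())) % 4
    return out


def _build_cluster(cluster: RepeatClusterSpec, gc: float) -> np.ndarray:
    unit_rng = np.random.default_rng(np.random.SeedSequence(cluster.unit_seed))
    unit = _random_seq_codes(unit_rng, cluster.unit_length, gc)
    mut_rng = np.random.default_rng(np.random.SeedSequence([cluster.unit_seed, 1]))
    copies = []
    inv = cluster.inverted_block
    for i in range(1, cluster.copy_number + 1):
        cp = _mutate(mut_rng, unit, cluster.substitution_rate)
        if inv is not None and inv[0] <= i <= inv[1]:
            cp = (3 - cp)[::-1]  # reverse complement in code space
        copies.append(cp)
    return np.concatenate(copies)


def build_genome(spec: GenomeSpec) -> Tuple[Dict[str, str], SyntheticTruth]:
    """Emit chromosome sequences (plus 'MT') and the exact k-mer truth table."""
    errs = spec.validate()
    if errs:
        raise ValueError("invalid genome spec: " + "; ".join(errs))

    root = np.random.SeedSequence(spec.seed)
    labels = spec.autosomes + [l for l in ("X", "Y") if l in spec.chromosomes] + [MITO_LABEL]
    children = {l: s for l, s in zip(labels, root.spawn(len(labels)))}

    chrom_codes: Dict[str, np.ndarray] = {}
    for label in labels:
        length = spec.mito_length if label == MITO_LABEL else spec.chromosomes[label]
        rng = np.random.default_rng(children[label])
        chrom_codes[label] = _random_seq_codes(rng, length, spec.gc)

    # auto-place clusters lacking an explicit start: sequential with 1 kb gaps
    cursors = {l: 1000 for l in spec.chromosomes}
    placed = []
    for c in spec.clusters:
        if c.start is None:
            start = cursors[c.chromosome]
        else:
            start = c.start
        end = start + c.span
        if end > spec.chromosomes[c.chromosome]:
            raise ValueError(
                f"cluster {c.name}: span [{start}, {end}) overflows chromosome "
                f"{c.chromosome} (length {spec.chromosomes[c.chromosome]})"
            )
        cursors[c.chromosome] = max(cursors[c.chromosome], end + 1000)
        arr = _build_cluster(c, spec.gc)
        chrom_codes[c.chromosome][start:end] = arr
        placed.append(
            {
                "name": c.name,
                "chromosome": c.chromosome,
                "start": start,
                "end": end,
                "unit_length": c.unit_length,
                "copy_number": c.copy_number,
                "inverted_block": c.inverted_block,
            }
        )

    genome = {l: _BASES[chrom_codes[l]].tobytes().decode() for l in labels}

    # exact truth from the emitted sequences
    per_label = []
    for l in labels:
        canon, valid = canonical_windows(chrom_codes[l], DEFAULT_K)
        u, cnt = np.unique(canon[valid], return_counts=True)
        per_label.append((u, cnt))
    all_codes = np.unique(np.concatenate([u for u, _ in per_label]))
    counts = np.zeros((all_codes.size, len(labels)), np.int64)
    for j, (u, cnt) in enumerate(per_label):
        counts[np.searchsorted(all_codes, u), j] = cnt

    truth = SyntheticTruth(k=DEFAULT_K, labels=labels, codes=all_codes, counts=counts, clusters=placed)
    return genome, truth


# ---------------------------------------------------------------------------
# read simulation


def template_multiset(genome: Dict[str, str], sex: str, mito_copy_multiplier: int) -> List[Tuple[str, int]]:
    """Sex-specific template copies: the diploid sampling model."""
    autosomes = sorted(l for l in genome if l not in ("X", "Y", MITO_LABEL))
    templates = [(l, 2) for l in autosomes]
    if "X" in genome:
        templates.append(("X", 2 if sex == "female" else 1))
    if "Y" in genome and sex == "male":
        templates.append(("Y", 1))
    if MITO_LABEL in genome and mito_copy_multiplier > 0:
        templates.append((MITO_LABEL, mito_copy_multiplier))
    return templates


def _apply_errors(rng: np.random.Generator, w: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return w
    mask = rng.random(w.shape) < rate
    if mask.any():
        w = w.copy()
        w[mask] = (w[mask] + rng.integers(1, 4, int(mask.sum()))) % 4
    return w


def simulate_short_reads(genome: Dict[str, str], params: ReadSimParams, path) -> int:
    """Write a sexed short-read library as Sanger FASTQ (constant Q30).

    Read ids encode the origin (``label|start|strand|serial``) so simulated
    libraries carry their own per-read ground truth.
    """
    errs = params.validate()
    if errs:
        raise ValueError("; ".join(errs))
    rl = params.read_length
    root = np.random.SeedSequence(params.seed)
    templates = template_multiset(genome, params.sex, params.mito_copy_multiplier)
    streams = root.spawn(len(templates))
    qual = "?" * rl  # Q30 placeholder
    n_total = 0
    with open(path, "wt") as fh:
        for (label, copies), ss in zip(templates, streams):
            seq_codes = encode(genome[label])
            L = seq_codes.size
            if L < rl:
                continue
            n = int(round(params.depth * copies * L / rl))
            rng = np.random.default_rng(ss)
            for off in range(0, n, 200_000):
                m = min(200_000, n - off)
                starts = rng.integers(0, L - rl + 1, m)
                w = seq_codes[starts[:, None] + np.arange(rl)]
                w = _apply_errors(rng, w, params.error_rate)
                flip = rng.random(m) < 0.5
                w[flip] = (3 - w[flip])[:, ::-1]
                seqs = _BASES[w].reshape(m * rl).view(f"S{rl}")
                for i in range(m):
                    strand = "-" if flip[i] else "+"
                    fh.write(
                        f"@{label}|{starts[i]}|{strand}|{n_total + off + i}\n"
                        f"{seqs[i].decode()}\n+\n{qual}\n"
                    )
            n_total += n
    return n_total


def _draw_lengths(rng: np.random.Generator, n: int, p: LongReadSimParams) -> np.ndarray:
    mu = np.log(p.mean_length) - p.sigma**2 / 2.0
    lens = rng.lognormal(mu, p.sigma, n) if p.sigma > 0 else np.full(n, float(p.mean_length))
    return np.clip(np.round(lens), p.min_length, p.max_length).astype(np.int64)


def simulate_long_reads(genome: Dict[str, str], params: LongReadSimParams, path) -> int:
    """Write a male long-read library as FASTA.

    Templates follow the male multiset (autosomes x2, X, Y, MT x
    multiplier); reads longer than their template are truncated to it.
    """
    errs = params.validate()
    if errs:
        raise ValueError("; ".join(errs))
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    templates = template_multiset(genome, "male", params.mito_copy_multiplier)
    seqs = {l: encode(genome[l]) for l, _ in templates}
    weights = np.array([copies * len(genome[l]) for l, copies in templates], float)
    target = None
    if params.count is not None:
        n_reads = params.count
    else:
        target = params.depth * weights.sum()
        n_reads = None
    weights = weights / weights.sum()

    emitted = 0
    total_bases = 0
    with open(path, "wt") as fh:
        while True:
            if n_reads is not None:
                batch = min(2048, n_reads - emitted)
                if batch <= 0:
                    break
            else:
                if total_bases >= target:
                    break
                batch = 2048
            lens = _draw_lengths(rng, batch, params)
            tpl = rng.choice(len(templates), size=batch, p=weights)
            for i in range(batch):
                if n_reads is None and total_bases >= target:
                    break
                label = templates[tpl[i]][0]
                codes = seqs[label]
                eff = int(min(lens[i], codes.size))
                start = int(rng.integers(0, codes.size - eff + 1))
                w = codes[start : start + eff]
                w = _apply_errors(rng, w, params.error_rate)
                if rng.random() < 0.5:
                    w = (3 - w)[::-1]
                    strand = "-"
                else:
                    strand = "+"
                fh.write(f">{label}|{start}|{strand}|{emitted}\n{_BASES[w].tobytes().decode()}\n")
                emitted += 1
                total_bases += eff
    return emitted
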