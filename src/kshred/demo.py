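"""Packaged synthetic study conditions.

``demo_genome_spec`` is the full-size demonstration: a ~5 Mb genome whose X
carries one 1.7-kb-unit and one 4-kb-unit head-to-tail array (the latter
with a reverse-complemented central block, copies 21-30), plus a decoy
repeat shared between X (48 copies) and an autosome (2 copies) that passes
the chromosome-quotient and abundance filters but fails the X-specificity
index, an autosomal and a Y background repeat, and a 100x mitochondrial
contaminant.  ``mini_genome_spec`` is the same design scaled down for
replicate (multi-seed) checks.

Cluster names are stable identifiers used by tests and the acceptance
script to look up planted coordinates in the truth table.
"""

from __future__ import annotations

import numpy as np

from .simulate import GenomeSpec, LongReadSimParams, ReadSimParams, RepeatClusterSpec

DEPTH = 20.0
READ_LENGTH = 150
ILLUMINA_ERROR = 0.001
LONGREAD_ERROR = 0.01
MITO_MULT = 100


def demo_genome_spec(seed: int = 0) -> GenomeSpec:
    """The ~5 Mb demonstration genome (A1 3.2 Mb, A2 1.1 Mb, X 0.45 Mb, Y 0.15 Mb).

    X is a small fraction of the genome, as in real karyotypes, which keeps
    the library-size bias of the chromosome quotient to a few percent.
    """
    return GenomeSpec(
        chromosomes={"A1": 3_200_000, "A2": 1_100_000, "X": 450_000, "Y": 150_000},
        mito_length=16_000,
        gc=0.40,
        clusters=[
            RepeatClusterSpec("X", 1700, 50, unit_seed=101, start=20_000, name="x_unit1700"),
            RepeatClusterSpec(
                "X", 4000, 50, unit_seed=102, start=120_000, inverted_block=(21, 30), name="x_unit4000"
            ),
            RepeatClusterSpec("X", 1000, 48, unit_seed=103, start=340_000, name="decoy_x"),
            RepeatClusterSpec("A1", 1000, 2, unit_seed=103, start=1_500_000, name="decoy_a"),
            RepeatClusterSpec("A1", 1200, 30, unit_seed=104, start=2_000_000, name="a_repeat"),
            RepeatClusterSpec("Y", 800, 20, unit_seed=105, start=50_000, name="y_repeat"),
        ],
        seed=seed,
    )


def mini_genome_spec(seed: int = 0) -> GenomeSpec:
    """A ~0.6 Mb genome with the same planted design, for replicate checks."""
    return GenomeSpec(
        chromosomes={"A1": 400_000, "X": 120_000, "Y": 40_000},
        mito_length=2_000,
        gc=0.40,
        clusters=[
            RepeatClusterSpec("X", 1000, 25, unit_seed=201, start=10_000, name="x_unit1700"),
            RepeatClusterSpec("X", 600, 25, unit_seed=202, start=45_000, inverted_block=(11, 16), name="x_unit4000"),
            RepeatClusterSpec("X", 800, 40, unit_seed=203, start=70_000, name="decoy_x"),
            RepeatClusterSpec("A1", 800, 2, unit_seed=203, start=50_000, name="decoy_a"),
            RepeatClusterSpec("A1", 900, 15, unit_seed=204, start=100_000, name="a_repeat"),
            RepeatClusterSpec("Y", 700, 10, unit_seed=205, start=10_000, name="y_repeat"),
        ],
        seed=seed,
    )


def demo_read_params(sex: str, seed: int, depth: float = DEPTH) -> ReadSimParams:
    return ReadSimParams(
        sex=sex,
        depth=depth,
        read_length=READ_LENGTH,
        error_rate=ILLUMINA_ERROR,
        mito_copy_multiplier=MITO_MULT,
        seed=seed,
    )


def demo_longread_params(seed: int, depth: float = DEPTH) -> LongReadSimParams:
    return LongReadSimParams(
        mean_length=10_000.0,
        sigma=0.9,
        min_length=300,
        max_length=120_000,
        depth=depth,
        error_rate=LONGREAD_ERROR,
        mito_copy_multiplier=MITO_MULT,
        seed=seed,
    )


def toy_gene_counts(seed: int = 0, depth: float = 200.0):
    """Per-gene sexed read counts over a toy 6-contig assembly.

    Two autosomal contigs, two X, one Y, and one autosomal contig with only
    9 genes (below the minimum-gene rule).  Counts follow the diploid
    sampling model: per-gene female/male Poisson means proportional to
    ploidy (A 2:2, X 2:1, Y 0:1).  Returns (gene table, expected classes).
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    design = [
        ("contig_a1", "A", 12),
        ("contig_a2", "A", 15),
        ("contig_x1", "X", 11),
        ("contig_x2", "X", 20),
        ("contig_y1", "Y", 10),
        ("contig_small", "A", 9),
    ]
    ploidy = {"A": (2, 2), "X": (1, 2), "Y": (1, 0)}
    rows = []
    for contig, cls, n in design:
        pm, pf = ploidy[cls]
        for g in range(n):
            rows.append(
                (
                    f"{contig}_g{g}",
                    contig,
                    int(rng.poisson(depth * pm)),
                    int(rng.poisson(depth * pf)),
                )
            )
    genes = pd.DataFrame(rows, columns=["gene", "contig", "reads_m", "reads_f"])
    expected = {c: (cls if n >= 10 else "unassigned") for c, cls, n in design}
    return genes, expected
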