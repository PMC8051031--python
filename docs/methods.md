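# Methods

`kshred` implements a k-mer based discovery pipeline for abundant,
X-chromosome-specific, CRISPR-targetable sequence repeats in species with an
XX/XY karyotype, together with the post-hoc audit of a genome assembly
(contig sexing, target-site mapping, repeat-array dissection) and a
synthetic-data generator that provides exact planted ground truth for every
stage. The intended application is the design of X-shredding sex distorters:
gRNAs against sites that are highly repeated on the X and absent everywhere
else, so that cleavage in the male germline biases offspring toward sons.

## The discovery model

The pipeline combines two orthogonal signals computed for every canonical
25-mer (the lexicographically smaller of a k-mer and its reverse
complement, making all counting strand-agnostic):

**Chromosome quotient (CQ).** Male and female short-read libraries are
end-trimmed (5 bp each side by default), censused, floored at a combined
raw count of `kmernoise = 5`, and scored with

    CQ = (count_f / total_f) / (count_m / total_m)

where the totals are each library's valid k-mer instances. In an XX/XY
system CQ is ~2 for X-linked, ~1 for autosomal and ~0 for Y-linked
sequence. k-mers absent from the male library receive an infinite sentinel
(they sort into the X band and are vetted downstream). The noise floor is
applied to the combined count, not per library: a legitimate Y-specific
k-mer has a female count of zero, and per-library floors would erase the
entire Y class.

**X-specificity index (XSI).** Male long reads are filtered to
[2,000, 100,000] bp (inclusive), cleared of mitochondrial contamination
(a read whose canonical k-mers are >= 50% contained in the mitochondrial
reference k-mer set is dropped), and each read is assigned to an X / A / Y
bin by majority over the census-classified diagnostic k-mers it carries
(ambiguous = GA). For each X-band k-mer the pass accumulates its total
occurrences over kept reads (`hits_sum`), the maximum occurrences within a
single read (`max_pt`), the number of distinct reads containing it
(`unique_bin_occurrence`), and

    XSI = hits on X-bin reads / hits on all kept reads,

with the GA bin counting against specificity (conservative). Candidates
require XSI >= 0.995 and a combined short-read abundance `sum >= LSum =
100`.

**Selection.** The four ranking statistics (`sum`, `hits_sum`, `max_pt`,
`unique_bin_occurrence`) are each cut at the top 0.05 percentile
(rank `ceil(q*N)` from the top, ties included). The default combination is
the intersection of the four top sets; when the intersection is smaller
than the requested list the filter falls back to rank-sum ordering and
flags six times the requested list size as headroom for downstream drops.
Ordering is always (rank-sum, then lexicographic k-mer), so results are
reproducible. Each flagged 25-mer is scanned for Cas9 placements (20-nt
protospacer immediately followed by an NGG PAM, both strands — at most
three offsets per strand inside a 25-mer) and Cas12a placements (TTTV PAM
followed by a >= 20-nt protospacer — at most two offsets per strand; inside
a 25-mer the spacer is necessarily truncated to <= 21 nt, and the full
remainder after the PAM is reported). Protospacers are screened
PAM-agnostically against the autosomal + Y long-read bins at Hamming
distance 0..3 (substitutions only); a candidate is dropped when no
placement is free of background hits at <= 2 mismatches. The final table is
the first `top_n = 25` survivors in the deterministic order.

## Assembly audit

Contigs are classed by the median CQ of their annotated genes, computed
from sexed per-gene read counts; contigs with fewer than 10 scored genes
stay unassigned. Library totals are a property of the libraries and should
be supplied explicitly when the gene table is a subset of the genome (the
column-sum default is only correct when the table is genome-wide).
Selected k-mers are located in an assembly by full-length ungapped scanning
on both strands with a configurable substitution tolerance (a 2-bit XOR
popcount per window; equivalent to brute-force Hamming and tested against
it). Per-scaffold hits are clustered by single linkage with a 20 kb default
gap cap; the median inter-hit spacing of a cluster estimates the repeat
unit length of a head-to-tail array, and the cluster span its extent.
`region_kmer_specificity` censuses a region's k-mers and counts their exact
hits at region, host-scaffold and assembly scale (specificity = scaffold
hits / assembly hits). All coordinates are 0-based half-open; GFF input
would convert from 1-based closed.

## Synthetic data generator

The generator emulates what the pipeline assumes about real data and
nothing more:

- **Diploid sampling.** Per-sex template multisets (female: autosomes x2,
  X x2; male: autosomes x2, X, Y) sampled uniformly at a per-haploid-copy
  depth with i.i.d. substitution errors; constant Q30 placeholder
  qualities. Read ids carry the origin (`chromosome|start|strand|serial`),
  so simulated libraries contain their own per-read truth.
- **Planted arrays.** Head-to-tail tandem repeat clusters with optional
  per-copy substitution divergence and an optional reverse-complemented
  central block. Canonical counting makes the inverted block invisible in
  the truth table for all unit-interior k-mers and interior junctions
  (an inverted-inverted junction is the reverse complement of a normal
  junction); only the two inversion-boundary junctions introduce new
  junction k-mers, which occur once or twice and sit below the pipeline's
  abundance floor.
- **Mitochondrial contaminant.** A separate template at a 100x copy
  multiplier in both sexes, giving the mito-exclusion stage something to
  remove without disturbing CQ (it cancels in the normalization).
- **Long reads.** Log-normal lengths (mean 10 kb, log-sd 0.9 by default)
  clipped to configurable bounds and truncated to the template; 1%
  substitution error by default, emulating corrected long reads. Exact
  k-mer matching in the binning stage is deliberately mismatch-intolerant;
  the simulated error rate is its stress test.
- **Truth.** Computed post hoc from the emitted sequences by the same
  canonical window census the tests verify against a pure-Python oracle,
  so background collisions with planted arrays are reported, not hidden.

All randomness flows from integer seeds through `numpy.random.SeedSequence`
spawns; identical configurations reproduce outputs byte for byte.

### Packaged study conditions

The full demonstration (`kshred.pipeline.demo_config`, also the basis of
`scripts/acceptance.py`) uses a ~5 Mb genome — A1 3.2 Mb, A2 1.1 Mb,
X 450 kb, Y 150 kb, mitochondrion 16 kb — with, on X, a 1.7 kb unit
repeated 50 times head-to-tail (~85 kb), a 4 kb unit repeated 50 times with
copies 21-30 inverted (~200 kb), and a decoy 1 kb unit with 48 copies on X
plus 2 on A1; an autosomal 1.2 kb x30 and a Y 0.8 kb x20 background repeat;
Illumina-like reads at depth 20 per haploid copy (150 bp, 0.1% error) and
long reads at depth 20 (1% error). X is kept a small fraction of the genome
as in real karyotypes, which bounds the library-size bias of CQ at a few
percent. The decoy's 48/2 split makes it a true hard negative: its expected
CQ (~1.9) clears the X band and its abundance clears LSum, so only the XSI
floor rejects it (XSI ~ 0.96, since ~4% of its long-read hits fall on
autosome-binned reads). Replicate checks (ten independent seeds) run the
same design on a ~0.6 Mb genome; depth, error rates and filter parameters
are identical, only sequence lengths and copy numbers shrink.

## Numerical and design choices

- **CQ class bands** default to Y <= 0.2, autosomal 0.5-1.4, X >= 1.5.
  The X floor sits below the theoretical value of 2 for two reasons: the
  normalization centres CQ at `2 * total_m/total_f < 2` because the female
  library is the larger one at matched depth, and at moderate coverage the
  per-k-mer CQ of even a 50-copy repeat has a log-sd of ~4-6%, so a floor
  near 2 would lose a few planted k-mers in every run. At 1.5 the expected
  false-negative rate for true X repeats is negligible, while autosomal
  leakage into the band (~2% of single-copy autosomal k-mers) is removed by
  the LSum and XSI filters. All bands are configurable.
- **Binning dominance** defaults to 0.6 (majority with margin). A clean
  single-chromosome read carries a diagnostic-hit share equal to the
  per-k-mer classification accuracy of its chromosome's k-mers (~0.8 at
  depth 20), so a dominance cut above that would send entire chromosomes to
  the ambiguous bin. A strict tie between classes is never dominant.
- **XSI denominator** includes GA-bin hits: ambiguous placements count
  against specificity.
- **Off-target matching** is Hamming-only and PAM-agnostic, with the
  exclusion rule made concrete (any background hit at <= 2 mismatches) and
  configurable. The fast path is a pigeonhole index (four disjoint 5-mer
  parts of the protospacer; any hit with <= 3 mismatches matches at least
  one part exactly), verified against dense scanning and a pure-Python
  oracle. Palindromic protospacers count once per strand.
- **Percentile cuts** never split ties; equal values at the cut rank are
  all included.
- **Degenerate inputs**: a read shorter than the trims plus k contributes
  nothing; non-ACGT windows are skipped and tallied; an empty candidate set
  or empty background produces an empty result with a warning, not an
  error; k-mers absent from all long reads are flagged and excluded from
  candidacy; both-sexes-zero genes are excluded from contig medians.

## What passing tests do and do not show

The simulator plants exactly the structure the pipeline searches for, with
uniform coverage, substitution-only errors, no chimeras or structural
variation beyond the single inverted block, and no diploid heterozygosity.
Recovering precision = recall = 1.0 under these conditions validates the
statistics and the plumbing — the filters reject shared repeats and
contamination for the right quantitative reasons — but does not measure
robustness to real-library artefacts (coverage waves, indels, adapter
chimeras, strain divergence between libraries and assembly). Recall is
scored against planted X-exclusive k-mers with at least 3 copies: the
inversion-boundary junction k-mers occur exactly twice, and their expected
combined short-read count (~99 at depth 20) straddles the LSum = 100 floor,
so their detection is a coin flip by design, in either direction; precision
is scored against all X-exclusive planted k-mers.

## Problem sizes

The packaged demonstration (~5 Mb genome, ~2.4 M short reads per sex,
~20 k long reads) runs the full pipeline in a few minutes on one CPU within
~4 GB; the replicate checks use the ~0.6 Mb design so ten independent
simulations remain cheap. Counting is numpy-vectorized over 2-bit packed
windows (log-doubling composition, dtype-laddered), with sorted-array
membership lookups for binning; nothing is disk-backed, so multi-gigabase
libraries are out of scope.

## Known limitations

- In-memory counting only; no quality-aware counting.
- No platform error models (substitutions only, uniform rates).
- Off-target screening ignores indels and PAM context; no cleavage-activity
  scoring.
- Long-read binning is exact-match k-mer lookup; no alignment, no chimera
  detection.
- BLASTN-style word-seeded alignment is replaced by ungapped full-length
  scanning; for 25-mers at small mismatch counts the hit sets coincide.
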