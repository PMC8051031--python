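# kshred

Discovery of abundant, X-chromosome-specific, CRISPR-targetable sequence
repeats from male/female whole-genome sequencing data — the computational
target-finding step for X-shredding sex distorters, where gRNAs cleave the
X chromosome at many sites in the male germline so that offspring are
biased toward males. The package is aimed at genome engineers and insect
genetic-control researchers who need X-specific repeat targets in species
(such as the Mediterranean fruit fly) without assuming a finished genome,
plus a post-hoc audit of whatever assembly does exist.

## Method

For every canonical 25-mer (the lexicographically smaller of the k-mer and
its reverse complement) in trimmed male and female short-read libraries the
pipeline computes the **chromosome quotient**

    CQ = (count_f / total_f) / (count_m / total_m)

(~2 for X-linked, ~1 for autosomal, ~0 for Y-linked sequence in an XX/XY
system), floors raw counts at `kmernoise = 5` (combined) and keeps abundant
X-band candidates. Male long reads in [2,000, 100,000] bp, cleared of
mitochondrial contamination by k-mer sharing against a mitochondrial
reference, are binned to X / autosome / Y by the census-classified
diagnostic k-mers they carry. Per candidate k-mer the long-read pass yields
`hits_sum` (total occurrences), `max_pt` (maximum occurrences in one read),
`unique_bin_occurrence` (distinct reads containing it) and the
**X-specificity index** `XSI = X-bin hits / all hits`, filtered at
`XSI >= 0.995` and combined short-read abundance `sum >= LSum = 100`.
Candidates are then cut at the top 0.05 percentile of each of the four
statistics (ties included; intersection with a deterministic rank-sum
fallback), scanned for Cas9 (protospacer-NGG) and Cas12a (TTTV-protospacer)
placements, screened PAM-agnostically against the autosomal+Y read bins at
Hamming distance 0-3, and the top 25 survivors are reported.

The assembly audit assigns contigs to sex chromosomes by the median CQ of
their genes (fewer than 10 genes → unassigned), maps k-mers into the
assembly by mismatch-tolerant ungapped scanning, clusters hits into repeat
arrays whose median inter-hit spacing estimates the tandem-repeat unit
length, and scores region-derived k-mers for scaffold specificity.

A synthetic-data module generates genomes with planted head-to-tail repeat
arrays (including an inverted central block and an X+autosome decoy), sexed
short-read libraries under the diploid sampling model, male long reads and
a high-copy mitochondrial contaminant — with the exact per-chromosome count
of every canonical k-mer as machine-checkable ground truth.

## Worked example

Running the pipeline end to end on a small synthetic genome (~0.6 Mb, one
X-linked 1 kb unit x25 array, one 600 bp unit x25 array with an inverted
block, a decoy repeat shared 40:2 between X and an autosome, autosomal and
Y background repeats, 100x mitochondrial contaminant, depth 20 per haploid
copy):

```
$ kshred run --config small.yaml
{
  "simulate": { "male_reads": 154667, "female_reads": 165334, "long_reads": 2673 },
  "census": {
    "male_valid_windows": 17941372,
    "female_valid_windows": 19178744,
    "kmers_counted": 1305242,
    "kmers_after_noise_floor": 472453,
    "class_counts": { "A": 366278, "X": 54028, "Y": 33684, "GA": 18463 }
  },
  "bin-reads": {
    "reads_in": 2673,
    "reads_kept": 2003,
    "status_counts": { "kept": 2003, "mito": 422, "too_short": 246, "too_long": 2 },
    "bin_counts": { "A": 1652, "X": 268, "Y": 81, "GA": 2 }
  },
  "select": {
    "candidates_after_xsi_lsum": 1612,
    "flagged": 60,
    "selected_kmers": 9,
    "target_rows": 13
  }
}
```

Reading the report: of 1.3 M distinct canonical 25-mers, 472 k survive the
combined-count noise floor and 54 k fall in the X band of the chromosome
quotient. Of 2,673 long reads, 422 are removed as mitochondrial and 248 by
the length window; the rest bin overwhelmingly to their true chromosomes.
After the XSI >= 0.995 and LSum >= 100 filters exactly the 1,612 planted
X-array k-mers remain (the decoy's k-mers reach XSI ~ 0.96 and are
rejected), 60 are flagged by the top-percentile ranking, and 9 targetable
k-mers (13 placement rows: a k-mer can carry both a Cas9 and a Cas12a
site) form the final table in `out/targets.tsv`:

```
kmer                       sum   hits_sum  max_pt  unique_bin_occurrence  nuclease  strand  pam   offtarget_mm0 ... rank
CAACCGCCCTAAACGCTATGTTAAA  1404  649       27      97                     Cas12a    -       TTTA  0                  2
AGCGTTTAGGGCGGTTGTACAGAGG  1410  645       27      97                     Cas9      +       AGG   0                  4
...
```

Every selected k-mer is one of the planted X-specific repeats; `sum` is its
combined male+female short-read count, `hits_sum`/`max_pt`/
`unique_bin_occurrence` its long-read abundance profile, and the
`offtarget_mm0..3` columns its Hamming-distance background hits in the
autosomal and Y read bins (selection requires none at <= 2 mismatches).

The same stages are available individually (`kshred simulate`, `census`,
`bin-reads`, `select`) and for the assembly audit (`kshred contig-cq`,
`map-kmers`, `arrays`, `region-specificity`); `--help` on any subcommand
lists the parameters, whose defaults are the pipeline's standard settings
(k 25, trims 5/5, kmernoise 5, LSum 100, XSI 0.995, length window
2,000-100,000 bp, top 0.05%, top 25).

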