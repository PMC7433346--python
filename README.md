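# tdscan

Detection of tandem duplications (TDs) from short-read sequencing data.

A tandem duplication is a genomic segment duplicated and inserted
immediately after its original copy.  TDs are a recurrent structural
variant class in cancer genomes (ovarian and breast tumors in
particular), so calling them accurately — including their exact
breakpoints — matters for genome analysis.  `tdscan` is aimed at anyone
with a coordinate-sorted BAM and a reference FASTA who wants TD calls at
nucleotide resolution without relying on insert-size models.

## Method

The caller is a two-stage pipeline over non-overlapping genomic bins
(default `len_bin` = 2000 bp):

1. **Rough detection by density clustering.**  For each bin *i* two
   features are computed from a per-base pileup: read depth
   RD_i = mean per-position read count, and mapping quality
   MQ_i = mean per-position MAPQ.  Bins containing reference N positions
   are filtered.  Both tracks are corrected for GC bias,
   r̃_i = (n / n_GC) · r_i, where n is the global median and n_GC the
   median over bins with GC fraction within 0.001 of bin *i*; denoised by
   exact 1D total-variation minimization,
   min_a ½‖b − a‖² + λ‖Da‖₁ (default λ = 0.25); and MQ is affinely
   rescaled onto the RD range so both features weigh comparably in
   Euclidean distance.  DBSCAN (ε = 0.7, MinPts = 4) then clusters the
   2D points (RD_i, M̃Q_i): the genomic background forms dense clusters,
   while TD bins — elevated depth, depressed mapping quality — end up as
   density **noise**.  Consecutive noise bins are merged into rough TD
   regions.  Neighborhood searches run on an exact 2D k-d tree
   (alternating median splits, MQ axis first); a brute-force backend is
   provided and produces identical results.
2. **Breakpoint refinement by split reads.**  Alignment records whose
   CIGAR is one clip plus one match pinpoint breakpoints: a clip-first
   record (xS(L−x)M) anchors the low boundary at its mapped position
   *a* = pos, a clip-last record (yM(L−y)S) anchors the high boundary at
   *b* = pos + y − 1 (1-based inclusive).  Within a window around each
   rough boundary, the breakpoint candidate with the most supporting
   records wins, refining calls to nucleotide resolution.

The package also ships a **simulator** (synthetic reference, donor
genome with embedded TDs, and an analytically rendered BAM with correct
junction clips, depth elevation and MAPQ degradation — no aligner
needed) and the **evaluation metrics**: sensitivity, precision, F1 under
the half-overlap rule, boundary bias, the cross-method overlapping
density score ODS = M²_overlap / N_called, and a permutation test on
|X̄ − Ȳ|.

## Worked example

Simulate a 600 kb chromosome with two embedded TDs, call, and score:

```sh
tdscan simulate --out-dir demo --ref-length 600000 --n-td 2 \
    --td-len-min 4000 --td-len-max 9000 --seed 11
tdscan call --bam demo/sim.bam --fasta demo/sim.ref.fa --out-prefix demo/out
tdscan evaluate --truth demo/sim.truth.bed --calls demo/out.calls.bed
```

which prints

```
{
  "tp": 2, "fp": 0, "fn": 0,
  "sensitivity": 1.0, "precision": 1.0, "f1": 1.0,
  "boundary_bias": 0.0
}
```

and `demo/out.calls.bed` contains

```
#chrom  start   end     name  score strand left_support right_support mean_rd  stage
chr1    125527  134519  TD1   6     .      12           8             46.906   refined
chr1    216029  223240  TD2   5     .      32           49            118.029  refined
```

Both calls match the truth BED exactly: `score` is the number of merged
noise bins, `left_support`/`right_support` count the split reads backing
each refined breakpoint (boundary bias 0 means the breakpoints are
nucleotide-exact), and `mean_rd` is the smoothed read depth of the
region — TD2 carries 5 extra copies, hence the ~4× background depth.

The same workflow is available as library calls
(`tdscan.simulate_dataset`, `tdscan.run_pipeline`,
`tdscan.compute_metrics`) for scripted studies.

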