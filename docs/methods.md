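# Methods

## Signal model

A tandem duplication (TD) with k extra copies multiplies the copy number
of its source segment from 1 to k+1.  In a tumor sample of purity p
(fraction of reads from the variant-carrying genome) sequenced to
coverage c, the expected read depth over the source segment is
c·(1 + p·k) against a background of c, while mapping quality inside the
segment drops because reads from the repeated sequence align ambiguously.
`tdscan` treats each genomic bin as a point in the (read depth, mapping
quality) plane and declares TDs where those points are density outliers,
then uses clip+match split reads to place the breakpoints exactly.

Low-MAPQ reads are deliberately **not** filtered from the pileup:
removing them would depress apparent coverage uniformly and erase the
mapping-quality signature that the clustering exploits.

## Pipeline stages and their assumptions

1. **Pileup** (`alignment_io`).  Read depth is per-base: every aligned
   M/=/X base of a primary, mapped, non-duplicate record increments the
   covered position, so a read spanning a bin boundary contributes to
   both bins (start-position counting would credit only the first).
   Mapping quality per position is the mean MAPQ of covering reads — the
   natural reduction when several reads overlap — and 0 where uncovered.
   Reference N positions carry no information; they are NaN and any bin
   containing one is dropped from all statistics.
2. **Binning** (`profile_prep.bin_signals`).  Non-overlapping bins of
   `len_bin` = 2000 bp (default).  A terminal partial bin is kept when it
   spans ≥ len_bin/2, otherwise dropped: shorter bins have too few
   positions for a comparable mean.  GC fraction uses non-N bases as the
   denominator to avoid bias next to masked regions.
3. **GC correction** (`profile_prep.gc_correct`).  Median matching
   within GC strata: corrected_i = (n/n_GC)·value_i with a ±0.001 GC
   window.  When strata are equivalence classes (GC values on a grid
   coarser than twice the window) the corrected stratum medians all equal
   the global median exactly; with overlapping windows the identity is
   approximate.  A stratum whose median is 0 would divide by zero; such
   bins are set to 0 with a warning rather than propagating infinities.
   The correction is scale-equivariant, so it commutes with coverage.
4. **TV denoising** (`tv_denoise.tv_smooth`).  The fused-lasso signal
   approximator min_a ½‖b−a‖² + λ‖Da‖₁ flattens sampling noise while
   preserving the copy-number jumps at TD boundaries.  The solver is an
   exact direct O(n) scan (segment fusion with dual-variable bounds),
   not an iterative scheme: no tolerance or iteration count to tune, and
   the output is the unique minimizer up to float rounding (validated
   against a box-constrained least-squares dual oracle to 1e−6 in the
   tests).  λ = 0.25 by default; one scalar serves both tracks.  λ→0
   returns the input, λ→∞ the mean; the minimizer always preserves the
   signal mean and its total variation is non-increasing in λ.
5. **MQ rescaling** (`profile_prep.normalize_mq`).  MAPQ (0–60) would
   dominate Euclidean distances over depth; the affine map
   (mq−mq_min)/(mq_max−mq_min)·(rd_max−rd_min)+rd_min puts both features
   on one scale without changing the MQ ordering.  Applied after
   smoothing, so the clustering features are (rd_smooth, mq_norm).  If
   all MQ values coincide (e.g. no duplication signal at purity 0) the
   track is mapped to the midpoint of the RD range — constant, hence
   ignorable by the clustering — with a warning.
6. **DBSCAN** (`density_cluster`).  ε = 0.7, MinPts = 4 (twice the
   number of features).  The ε-ball is closed and includes the point
   itself.  Clusters are density-connected components of core points;
   border points join the first cluster that reaches them with seed
   points scanned in ascending bin index, so output is deterministic.
   Noise points — bins reachable from no cluster — are the TD
   candidates.  Neighborhoods come from an exact 2D k-d tree
   (alternating lower-median splits, MQ axis first, leaf size 16); a
   brute-force backend exists and the test suite proves both produce
   identical core and noise sets, also against an independent all-pairs
   implementation and against scikit-learn's DBSCAN.  ε is expressed in
   smoothed-read-depth units, so its default presumes this package's
   preprocessing; with different scaling it must be retuned.
7. **Region assembly and refinement** (`td_caller`).  Consecutive noise
   bins merge into rough regions; runs separated only by N-filtered bins
   are still merged (a masked gap should not split one event;
   configurable).  Candidate breakpoints near each rough boundary come
   from split reads: clip-first records vote for the low boundary at
   their mapped position, clip-last records for the high boundary at
   position + matched length.  The candidate with the most votes wins;
   ties break toward the rough boundary, then the smaller coordinate.
   Clips shorter than 10 bp are ignored (dominated by sequencing error).
   The search window default is **2·len_bin** per side: reads overhanging
   a TD boundary degrade the adjacent bin's mapping quality, so the
   merged rough boundary regularly sits one full bin plus an in-bin
   offset outside the event — just beyond a one-bin window.  Two bins of
   slack covers this geometry; with well-separated events it introduces
   no cross-talk.  A side with no candidate keeps its rough coordinate
   and support count 0.
8. **Optional depth filter** (`filter_duplication_like`).  Density noise
   is sign-agnostic: an isolated low-depth bin is as anomalous as a
   duplicated one.  The optional filter keeps only regions whose mean
   smoothed depth exceeds the genome median; it is off by default, so
   every noise region is reported.

All coordinates are 0-based half-open internally; SAM's 1-based
positions are converted on input and the 1-based inclusive high boundary
b = pos + y − 1 becomes the half-open end pos + y on output.

## Simulator

`simulator` generates the study conditions end to end: an i.i.d. random
reference with configurable GC content, N-masked chromosome ends
(`telomere_n` = 10 kb, mirroring unassembled telomeres — this also hides
the unavoidable coverage droop where reads cannot extend past the
sequence end), disjoint TD events, and a coordinate-sorted indexed BAM
rendered analytically rather than by running an aligner.  Donor reads
inside extra copies map back to the source segment (raising depth by the
factor 1 + p·k); reads crossing a copy junction receive the clip+match
CIGAR of their longer matched side anchored at the true breakpoint;
donor-origin reads overlapping a TD span draw MAPQ uniformly from
[0, 30] while all other reads get 60.  Purity mixes donor reads
(fraction p, binomially sampled) with reads from the unmutated
reference.  Single-end reads suffice because the method uses depth,
MAPQ and clips — never insert size.  By default records carry no SEQ
(the caller never reads it); `with_seq`/FASTQ output exist for running a
real aligner instead.

Default conditions (one simulated sample): 2 Mb chromosome, 5 TDs of
2–10 kb with 1–6 extra copies, 30× coverage, purity 0.9, 100 bp reads.
These desk-scale sizes keep a full replicate under ~10 s; the
chromosome-scale configuration (tens of Mb, 10 TDs of 10–50 kb) is the
same code with larger numbers.

**What the simulator does not model** — and therefore what passing tests
do not establish about real data: sequencing errors and indels, paired
ends, mappability structure and repeat families beyond the embedded TDs,
coverage waviness beyond GC-free i.i.d. sampling, and real aligner
idiosyncrasies (multi-part split alignments, MAPQ calibration).  Clip
signals here are perfectly clean; on real data breakpoint support will
be noisier and refinement accuracy correspondingly lower.

## Evaluation

A truth region is a true positive when one call covers ≥ 50% of its
length; matching is greedy by overlap and one-to-one (a single call
cannot certify two truths — the conservative reading).  Precision is
defined as 0 when there are no calls, keeping curves plottable.
Boundary bias averages |Δstart| and |Δend| over matched pairs.  The
overlapping density score uses the same half-overlap rule between
methods and averages over the *other* methods:
ODS = M²_overlap/N_called.  The permutation test statistic is
s = |X̄ − Ȳ|; p is the fraction of label permutations with statistic
strictly greater than s, which is approximately uniform under the null
(verified by KS test in the suite).

## Numerical and degenerate-input choices

- k-d tree median: lower median on even splits (determinism); duplicate
  points are retained (multiset).
- DBSCAN neighborhood counts include the query point; MinPts compares
  against that inclusive count.
- Refinement that would cross boundaries (new start ≥ new end) reverts
  to the rough span.
- `len_bin` larger than the chromosome yields a single bin with a
  warning; empty signals, empty call sets and zero-call methods all
  return well-defined values (0 or NaN as documented) rather than
  raising.
- Isolated background bins can exceed ε from all neighbors by sampling
  noise alone (~4σ depth excursions), so a handful of unsupported
  single-bin calls per genome is expected even without any TD —
  including at purity 0.  They carry `left_support = right_support = 0`
  and stage `rough`, and the optional depth filter removes the low-depth
  half of them.

## Problem sizes used in the automated checks

The end-to-end checks run 50 desk-scale replicates (2 Mb, 5 TDs, 30×,
purity 0.9) plus smaller fixtures; oracle comparisons use up to 2000
points (DBSCAN) and length-30 signals × 200 draws (TV).
`scripts/acceptance.py` pools 10 desk-scale replicates.  These sizes
were chosen so the whole validation runs in minutes on a laptop while
every statistic is still estimated from ≥ 50 events.
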