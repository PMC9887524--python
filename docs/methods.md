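# Methods

`spcnv` detects copy-number variants (CNVs) in a single whole-genome
sequencing sample from its read-depth (RD) profile. Under the RD model the
number of reads covering a locus is proportional to the local copy number,
so gains sit above and losses below the diploid depth. Because aberrant
segments are a minority of the genome, the caller treats them as outliers:
each read-depth segment is mapped to a two-dimensional feature point and
scored by how sparse its shortest-path tree is relative to those of its
k nearest neighbours.

## Pipeline

1. **Binning.** The chromosome is tiled with fixed, non-overlapping windows
   (default 1,000 bp when extracting from BAM). The RD value of a bin is
   its mean per-base read count (read-start counting is available as a
   flag). Any bin whose reference slice contains an `N` is removed: reads
   never align there, and the resulting zero depths would mimic deletions.
2. **GC correction.** Coverage depends unimodally on GC content. Bins are
   stratified by GC rounded to the nearest percent and each stratum is
   rescaled by `m / m_g` (global median over stratum median), so every
   stratum's median depth matches the genome-wide median. Strata with
   fewer than 20 bins, or a zero median, borrow the global median (i.e.
   stay uncorrected): tiny strata have unstable medians and rescaling by
   them injects more bias than it removes.
3. **Working resolution.** Consecutive bins are aggregated to ~5 kb
   spans before segmentation (`working_bin_size=5000`; `None` disables).
   At ~5× coverage a 1 kb bin holds very few counts and its relative
   noise is large; averaging five bins roughly halves the coefficient of
   variation while a 10 kb event — the smallest in the intended detection
   range — still spans two working bins. GC correction runs at the working
   resolution, where strata are larger and their medians stabler.
4. **Total-variation segmentation.** The denoised profile is the exact
   minimiser of `(1/2)·Σ(x_i − rd_i)² + λ·Σ|x_{i+1} − x_i|`, computed with
   a direct non-iterative algorithm (no solver tolerance; the minimiser is
   exact to floating point). Maximal runs of equal denoised values become
   read-depth segments; a segment's value is the mean of the *original*
   corrected RD values it covers, so smoothing chooses breakpoints but
   never biases levels. Segmentation is per chromosome. The default
   penalty is `λ = c·σ̂` with `c = 2` and
   `σ̂ = median(|ΔRD|) / (0.6745·√2)`, the normal-consistent
   median-absolute-deviation estimate of the noise level taken on first
   differences, which is insensitive to the sparse true jumps. The merge
   tolerance for "equal" plateau values is 1e-8 absolute — the solver
   produces exactly equal plateaus, so the tolerance only guards float
   noise.
5. **Feature map.** Segment `i` becomes the point `(x_i, y_i)`:
   `x_i = value_i / mean(values)` (the RD ratio — global copy-number
   evidence; the median is available as the denominator flag) and
   `y_i` = mean of `x_i − x_j` over the existing adjacent segments
   `j ∈ {i−1, i+1}` (local contrast; boundary segments use their single
   neighbour; an absolute-value variant is behind a flag). Each dimension
   is min-max scaled to [0, 1] before any distance is computed, so neither
   dominates the Euclidean metric; a degenerate (constant) dimension maps
   to 0.5 everywhere.
6. **Relative shortest-path score.** For object `o`, the k-distance is the
   distance to its k-th closest other object, and the neighbourhood
   `N(o)` holds every object within it (exact ties can expand it past k).
   A Prim-style tree is grown over `{o} ∪ N(o)`: repeatedly absorb the
   outside node closest to the tree, recording the edge and its cost.
   The mean edge cost `SPCm(o)` measures local sparsity, and
   `RSPS(o) = |N(o)|·SPCm(o) / Σ_{a∈N(o)} SPCm(a)` compares it with the
   neighbours' own sparsity: interior points of a homogeneous cloud score
   ≈ 1, isolated points and members of small sparse clusters score above
   1. Unlike a plain k-NN distance, the tree cost still rises for a small
   *cluster* of aberrant segments whose members are mutually close,
   because the tree must pay the bridge to the main cloud.
7. **Calling.** Scores are thresholded at the boxplot upper inner fence
   `τ = Q3 + λ_f·(Q3 − Q1)` with `λ_f = 1.5` (type-7 linear-interpolation
   quartiles; infinite sentinel scores are excluded from the quartiles but
   always exceed τ). This adapts to each sample's score distribution with
   no parametric assumption. Flagged segments are typed by comparing
   their RD with the mean RD of the unflagged segments — at or above is a
   gain, below is a loss — and genomically adjacent flagged segments of
   one type merge into a single call (score = max member score).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `bin_size` | 1,000 bp | BAM extraction window; 10–50 kb events span ≥10 bins |
| `working_bin_size` | 5,000 bp | aggregation span before segmentation (see above) |
| `penalty_scale` (c) | 2.0 | TV penalty in units of the robust noise level |
| `k` | min(40, n/5, n−1) | see below |
| `lam` (λ_f) | 1.5 | classical Tukey inner fence |
| `ratio_center` | mean | denominator of the RD ratio |
| `diff_mode` | signed | neighbour-difference convention (preserves direction) |
| `min_stratum_size` | 20 | smallest GC stratum corrected independently |

**Choice of k.** k trades off two failure modes. If k is smaller than the
number of aberrant segments that cluster together in feature space
(a realistic profile carries ~14 events plus boundary fragments), the
CNV segments populate each other's neighbourhoods and normalise each
other's scores toward 1 — the classic masking failure of relative-density
scores. If k approaches the profile size, every neighbourhood covers much
of the plane, all scores inflate together and the fence flags nothing.
The default therefore grows with the profile but is capped both at 40
and at one fifth of the number of segments.

## Synthetic data

The generator emulates the benchmark design used for read-depth callers:
one synthetic 10 Mb chromosome (`chrS`, 10,000 bins of 1 kb), base depth
5 (mean RD at copy number 2), six gains and eight losses per sample with
lengths uniform in 10–50 kb, placed uniformly without overlap (one bin of
clearance). A bin inside an event with copy number `CN` in a sample of
tumour purity `p` has expected depth `5·(p·CN/2 + (1 − p))`; bins partially
covered by an event get the coverage-weighted mixture. Default purity is
0.6 — mid-range for tumour samples; benchmarks sweep 0.2–0.8. Counts are
negative-binomial with `var = μ + 0.1·μ²` (real read depth is
overdispersed relative to Poisson; dispersion 0 falls back to Poisson).
Default event copy numbers are 3 (gain) and 1 (loss); 4/0 give
strong-signal fixtures. An optional multiplicative GC bias curve peaking
at 45% GC (strength 0 by default) exercises the corrector in isolation.

What the generator does **not** emulate: read-level artefacts (mapping
errors, duplicates, mappability structure), inter-chromosomal variation,
subclonal heterogeneity, and the within-bin count correlation of real
fragment sampling. In particular, drawing a bin's depth as a single
negative-binomial count with mean ≈ 5 is substantially noisier per bin
(CV ≈ 0.55) than physical 5× data binned at 1 kb, where each bin
aggregates ~50 reads. Passing tests on this generator therefore show the
pipeline's self-consistency under harsh, well-specified noise — not a
performance guarantee on real libraries, where per-bin noise is milder
but structured biases are worse.

## Numerical choices and degenerate inputs

- All neighbour orderings and Prim tie-breaks are ascending
  (distance, index) — runs are bit-reproducible.
- The mean shortest-path cost divides by the number of tree edges, which
  equals k unless exact distance ties expanded the neighbourhood.
- Exact duplicates (flat profiles produce them after scaling): if an
  object and all its neighbours have zero tree cost, its score is 1; if
  only the neighbours' total is zero, the score is +∞ and is flagged by
  any finite fence.
- Edge costs are exact doubles; two-decimal values appear only in
  display.
- An all-flagged profile (no normal baseline) is a hard error advising a
  larger fence multiplier; an all-zero profile has no defined RD ratio
  and is rejected.

## Known limitations

- Event-level recall/precision on the strong-signal synthetic benchmark
  (purity 1.0, CN 4/0, 20 samples) is ≈ 0.83/0.86 under the default
  fence. The residual errors are boundary fragments flagged just outside
  true events and background segments whose means drift under the
  generator's per-bin noise; raising the fence trades the false calls
  against missed events along a frontier that the defaults balance.
- Breakpoint resolution is limited to the working bin size; no split-read
  refinement is attempted.
- No mappability correction, no integer copy-number genotyping, and no
  per-event significance values — calls carry the relative score only.
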