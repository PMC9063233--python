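# Methods

`sctrait` implements the bespoke statistical layer used to connect large
GWAS panels with single-cell transcriptomes of an immune stimulation time
course: a sum-based marker-set enrichment test with an LD-preserving
rotation null, a cell-cycle proliferation index, stimulus-response module
scoring, and pseudocell aggregation — together with seeded synthetic-data
generators that give every stage a known ground truth.

## The marker-set enrichment test

For a gene set *f*, the statistic is the sum of squared single-marker GWAS
effects over the markers inside the set's windows,

    T_sum = Σ_{i=1..m_f} b_i² ,

where *b_i* is the signed effect of marker *i* from a single-marker GWAS and
*m_f* is the number of markers falling inside the set. Gene windows extend
each gene body by 20 kb on both sides (clipped at the chromosome origin) to
capture nearby cis-regulatory variation; windows of one set are unioned, so
a marker covered twice counts once.

Coordinates follow one convention throughout: intervals are 0-based
half-open (BED semantics; GFF3 input is converted on read), marker
positions are 1-based on input and converted once at the membership test
(`start <= pos−1 < end`). Chromosomes are ordered by natural sort unless an
explicit order is declared; markers and annotation share that order.

### The rotation (cyclical permutation) null

A naive null that resamples markers destroys two structures that inflate
T_sum under the null: the set's size/spacing and the local correlation (LD)
between neighbouring effects. The rotation null preserves both. The
genome-wide vector of squared effects, ordered by chromosome and position,
is rotated by a random offset *k*: the marker at position *k* becomes the
first, the rest follow in their original order and wrap across the end of
the genome (and across chromosome boundaries). Set positions stay fixed,
and T_sum is recomputed on the rotated vector. Neighbourhoods of the effect
vector travel together, so LD is conserved; only the alignment between
effects and set windows is randomized.

The empirical p-value is one-tailed: the proportion of rotated statistics
strictly greater than the observed one. Two conventions are fixed and
recorded with every result:

* **Floor.** p is floored at 1/n_null so that a statistic exceeding every
  null value is reported as p = 1/n_null rather than 0 (downstream FDR
  cannot digest 0). The raw exceedance count is reported alongside, so the
  unfloored convention is recoverable from any results table.
* **Exact enumeration.** A genome of *m* markers has exactly m−1 distinct
  non-identity rotations. When m−1 does not exceed the requested number of
  permutations (default 10,000), all of them are enumerated and the null is
  exact (`exact_flag` true); otherwise k is sampled uniformly with
  replacement from {1, …, m−1}. Enumeration is strictly better than
  sampling whenever it is affordable.

### The trait × set grid and FDR

`run_grid` tests every trait against every set and applies
Benjamini–Hochberg step-up FDR across all tested cells of one invocation
(the family is the whole grid). Sets with no resolvable genes or no markers
in their windows are reported with a reason code rather than dropped
silently. Each (trait, set) cell draws its rotations from an RNG stream
seeded by `SeedSequence([root_seed, trait_rank, set_rank])` with ranks from
the sorted ids, so results are independent of iteration order.

## Cell-state scoring

Scoring operates on an `AnnData` of UMI counts. Normalization (required
before any scoring) scales each cell to the median total count and applies
log1p; zero-count cells are dropped and counted. Raw counts remain in
`layers["counts"]`.

* **Cell-cycle score** — per-cell mean of normalized expression over a
  G1/S + G2/M panel (the classical panels have 43 + 55 genes; any panel
  TSV can be supplied). The mean, not the total, is used so that panel
  genes missing from a matrix do not deflate the score; the per-cell total
  is available as an option and orders cells identically when no gene is
  missing.
* **Proliferation classification** — a cell is "actively proliferating" iff
  its score strictly exceeds the across-cluster average. "Average of all
  clusters" is ambiguous between the grand mean over cells and the
  unweighted mean of per-cluster means; the latter is the default (small
  clusters weigh equally) and the grand mean is a config switch.
* **Cell-cycle index** — fraction of proliferating cells per group
  (cluster, time point, or their cross).
* **Module score** — per gene, mean normalized expression per group,
  z-scaled across groups with the population SD (so each varying gene row
  has mean 0 and SD exactly 1 across groups); a module's score per group is
  the mean of scaled values over its genes. Zero-variance genes contribute
  0 rather than NaN.
* **Trajectory classification** — an ordered score vector is "sustained"
  when its maximum comes after the first time point and the final value
  stays more than a tolerance above the first (rise and hold), "peaked"
  when the maximum is interior and the final value returns to within the
  tolerance of the first (rise and fall back), otherwise "flat". The
  tolerance default is 0.25 scaled units — about a tenth of the typical
  peak-to-trough range of a responding module — and is a parameter, not a
  fitted constant.
* **Pseudocells** — per cluster, the average expression of `size` cells
  (default 100) sampled without replacement within a draw, draws
  independent; clusters smaller than `size` are skipped with a warning, the
  usual treatment of tiny clusters before co-expression analysis. Sampling
  a 100-cell cluster at size 100 reproduces the cluster mean exactly, which
  pins the arithmetic.

## Synthetic data

The generators define the conditions under which the statistics are
validated; their defaults are fixed once and the validation experiments run
at those conditions.

**GWAS generator.** Markers sit every 10 kb (marker *i* at position
*i*·10 kb, 1-based), 400 per chromosome on 3 chromosomes by default —
scale is a free choice, picked so that the exact rotation null (m−1 = 1199
rotations) is enumerable while windows still hold ~80 markers per 10-gene
set. Effects follow an equicorrelated factor model per block of
`ld_block_size` consecutive markers:

    b = sd · ( √ρ · z_block + √(1−ρ) · z_marker ),

giving exact pairwise correlation ρ (default 0.5, blocks of 10) — an LD
proxy for calibration testing, not a model of any real panel. Genes are
non-overlapping marker-aligned intervals grouped into sets; "enriched"
sets have the effect SD of markers inside their gene bodies multiplied by
`enrichment_lambda` (λ ≥ 1), so the enrichment truth is exactly the
in-window variance inflation the test is designed to detect.

**Single-cell generator.** Counts are negative binomial with mean μ and
inverse dispersion θ (variance μ + μ²/θ, θ = 2 by default); per-gene
baselines are lognormal around `baseline_mean` (default 2). Each cluster
gets multiplicative signatures on a random tenth of the non-panel genes.
A configured fraction of each cluster's cells is "cycling": their
cell-cycle-panel means are multiplied by `cycle_effect` (default 5). Module
genes have their means scaled per time point by the configured trajectory
(defaults: core antiviral and peaked inflammatory rise to an interior
maximum and return to baseline; sustained inflammatory rises and holds with
a slight late decrease). True cycling flags ship in the cell metadata.

The default transcriptome holds 1,000 genes. With many fewer genes the
three 30-gene modules dominate total counts, and median-depth normalization
then converts the modules' own rise into an apparent dip of everything
else (composition bias) — an artifact of an unrealistically module-heavy
transcriptome, second-order at the default scale. Features of real data the
generator does not emulate: gene-specific dispersion, dropout beyond NB
sampling, doublets, batch effects, ambient RNA, and realistic LD maps — so
passing recovery tests demonstrate the statistics' correctness under the
stated model, not robustness to those artifacts.

## Validation experiments

`sctrait.experiments` packages the simulation studies that
`scripts/acceptance.py` reports and the acceptance tests assert; all derive
their randomness from one seed. Problem sizes are the package's own
choices, fixed with the generator defaults:

* **Oracle agreement** — 100 random instances (200–2,000 markers, 10–100
  set markers): sampled p (10,000 rotations) versus exactly enumerated p,
  agreement within 2·√(p(1−p)/10⁴) + 10⁻⁴. A two-SE band has ~96%
  per-instance coverage, so the ≥95%-of-instances bar is intrinsically
  tight; the test seed is fixed.
* **Calibration** — 200 replicate grids of 5 traits × 8 sets at λ = 1
  (8,000 tests): type-I error at α = 0.05 and a Kolmogorov–Smirnov
  uniformity check of the pooled p-values.
* **Power** — 50 replicates per λ ∈ {1, 2, 3}, one enriched (trait, set)
  cell per grid: mean −log₁₀(p) of the enriched cell must increase
  strictly with λ, and at λ = 3 the enriched cell should attain the
  grid-wide smallest q in ≥90% of replicates.
* **Cycle recovery** — three 2,000-cell clusters with true cycling
  fractions 0.1/0.3/0.5 at `cycle_effect` 5 (300-gene transcriptome —
  composition bias is irrelevant here and the panel needs only 98 genes),
  20 replicates: recovered indices within ±0.05 and balanced accuracy of
  the flags ≥0.9.
* **Trajectories** — 100 replicates at generator defaults, one monocyte
  cluster, 150 cells per time point: all three module labels must match
  their injected shapes.
* **Pseudocells** — exactness on a 100-cell cluster and ≤1% per-gene error
  of the grand mean over 500 draws from a 2,000-cell cluster.

## Numerical and degenerate-input choices

Ties in the empirical p use strict ">" (a statistic equal to every null
value gets the floor value, not 1). Rotation offset 0 (identity) is
excluded from the null. A set whose windows cover every marker has a
degenerate null (every rotation reproduces T_obs). Empty index sets are a
validation error for the null but give T_sum = 0. Effects must be finite;
markers on chromosomes absent from the annotation stay in the rotation
vector but can never be in-set. Module scoring casts to float64 before
group means so z-scaling is exact; GWAS TSVs are written at %.17g and read
with round-trip float parsing so effects survive text I/O bit-exactly.

## Known limitations

The rotation null assumes approximate stationarity of squared effects along
the genome; strong systematic gradients (e.g. chromosome-scale polygenicity
differences) would be rotated into and out of windows and are not modelled
by the generator. FDR is computed across whichever grid a single invocation
tests — joining grids across invocations changes the family and hence q.
The generators are calibration instruments, not data emulators; see above
for what they deliberately omit.
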