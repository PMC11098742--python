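# Methods

## The measurement being modelled

DPC-seq libraries are sequencing read sets whose coverage is proportional to
the local density of DNA–protein crosslinks. The analysis compares paired
libraries from the same cells at 0 h (immediately after crosslinking) and
after a recovery time t, and asks how much crosslink signal *remains* per
gene:

    R_g = CPM_g(t) / CPM_g(0 h)

R_g = 1 means no removal; R_g → 0 means complete removal. All headline
statistics are functions of R_g: Spearman correlation with expression,
means per TPM bin and per gene-length bin (± s.e.m. across replicates),
TSS-versus-TES 1-kb-window contrasts, and between-genotype t-tests.

### Shares versus absolute survival

Sequencing depth is normalized away (CPM), so coverage measures each gene's
*share* of the library, not absolute crosslink density. The observed ratio
therefore estimates

    R_obs,g = E[R_g] / (T_t / T_0),

where T_t/T_0 is the genome-wide surviving-intensity fraction. This factor is
identical for every gene: orderings, correlations and condition contrasts are
unaffected, which is why the binned statistics are computed directly on
shares. Absolute calibration requires an external measurement of T_t/T_0 —
experimentally, a bulk precipitated-DNA fraction assay
(`coverage.dpc_fraction`); in simulation it is closed-form
(`simulate.global_survival`) and is carried in the truth bundle. The
parameter fit and the oracle comparisons rescale by it; with the default
simulation parameters T_4h/T_0 ≈ 0.91 for wild type.

## Gene universe

One transcript per gene (maximal genomic span; ties to the lexicographically
smallest transcript id), then strand-blind exclusion of any gene whose span
intersects another gene's span (both members of a pair are dropped —
coverage inside overlaps cannot be attributed to one gene), then removal of
mitochondrial genes (and, in mouse mode, X/Y genes). Gene length is the
unspliced span end − start, since coverage is computed over genomic gene
bodies. Coordinates are 0-based half-open internally; GTF input is converted
on read.

Bin edges are configurable; the defaults are seven length bins
[0,3), [3,10), [10,20), [20,50), [50,100), [100,200), [200,∞) kb, four TPM
bins [0.1,1), [1,10), [10,100), [100,∞), and a six-bin TPM scheme starting at
0.01 for mouse-style data. Bins are left-closed.

## Counting and normalization

A read counts toward a region when it overlaps it by ≥ 1 bp (half-open
intervals, strand-blind — the chemistry is not strand-resolved). Counting
uses a sorted-array formula (#starts < b − #ends ≤ a per chromosome), which
tests verify against a quadratic all-pairs oracle. Two normalizations:

* CPM, using the genome-wide mapped-read count (not only genic reads);
* reads per gene length per million: counts divided by gene length, rescaled
  so the per-sample total is exactly 10⁶ (relative tolerance 1e−9 in tests).

Residual ratios flag genes whose 0 h count is below `min_baseline_count`
(default 10) as `low_count`; they are reported but excluded from summaries.
The replicate is the unit of error throughout: per-replicate bin means first,
then mean ± s.e.m. across replicates, and t-tests act on replicate means.

## Metagene profiles

Scale-regions geometry: gene body in `body_bins` = 100 equal-width genomic
windows (the last absorbs the remainder), flanks of 2,000 bp in 50-bp bins,
minus-strand rows reversed so columns run 5′→3′. Values are CPM per bin by
default (matching the display convention of coverage heatmaps). For
*quantitative* comparisons between flank and body columns the
`per_bp`/`midpoint_mode` options give per-bp fragment-midpoint density, which
is width-independent; the promoter-dip statistic uses that form. The dip
statistic smooths the averaged profile with a centered 3-column rolling mean
before taking the minimum, because the nucleosome-free region is a ~200-bp
feature spanning several columns — an unsmoothed single-column minimum would
measure counting noise. Genes are weighted equally when averaging.

## The generative model

Deposition at 0 h is piecewise-constant intensity λ₀(x):

* gene bodies: d₀ × occupancy, with occupancy 1 in 147-bp nucleosome cores
  and `linker_occupancy` = 0.3 in 50-bp linkers, phase fixed at the TSS;
* a promoter nucleosome-free region from 150 bp upstream to 50 bp downstream
  of the TSS multiplies intensity by 1 − α·TPM/(TPM+K) (α = 0.8, K = 10):
  active promoters are nucleosome-depleted, saturating with expression;
* intergenic space: b₀ = d₀ × (147 + 50·0.3)/197 ≈ 0.822·d₀, i.e. the same
  average nucleosome density as gene bodies — chromatin is genome-wide, and
  this keeps metagene flanks continuous with bodies. A `histone_only` mode
  zeroes it.

Removal over recovery time t multiplies λ₀ by the survival

    S(x,t) = exp(−[k_b + γ·k_max·f_g·exp(−d_TSS(x)/λ_w)]·t),  f_g = TPM/(TPM+K)

inside gene g (d_TSS = transcription-oriented distance from the TSS) and by
exp(−k_b·t) elsewhere. The exponential distance attenuation is a stand-in
for a polymerase-traversal wave — equivalent at first order — chosen because
it integrates in closed form: per constant-rate segment,
∫ exp(−a·e^(−d/λ)) dd = λ·[E1(a·e^(−d₂/λ)) − E1(a·e^(−d₁/λ))] with the
scipy exponential integral, switching to the series −γ̄ − ln u + u below
u = 1e−8 to avoid cancellation. `expected_residual` evaluates E[R_g]
exactly this way; tests confirm agreement with 10⁶-sample Monte-Carlo
integration within 3 standard errors across random parameter draws.

Default parameters (no quantitative rates are published for this process;
these values are fixed once, produce the qualitative orderings the assay
shows, and are not biological estimates): k_max = 1.0/h, λ_w = 10 kb,
k_b = 0.01/h, K = 10 TPM, t = 4 h; genotype factors γ: wild type 1.0,
ΔCSB 0.05, p97/proteasome inhibition 0.2. Study geometry: 2,000 genes with
log-uniform lengths on [1 kb, 300 kb] and zero-inflated log-normal TPM
(P(0) = 0.3, meanlog 1, sdlog 2), placed without overlap and with ≥ 5-kb gaps
on a single 140-Mb chromosome — compact so that genic fragments dominate the
library as in a real nucleosome-rich genome. Depth is 10⁶ fragments per
library (fragment length ~ N(200, 50²) truncated at 100 bp).

Sampling draws fragment midpoints by inverse CDF over the exact per-segment
masses at time t, uniform within a segment; segments are ≤ 147 bp while the
survival varies on the λ_w (kb) scale, so per-gene totals are exactly
proportional to the analytic integral. Every artifact is a pure function of
(params, seed); per-sample streams are keyed by (seed, genotype, time,
replicate), so adding a condition leaves existing samples byte-identical.

## Parameter estimation

`estimate_removal_parameters` minimizes the weighted sum of squared
differences between observed and model log residuals over QC-passing genes.
Observed log ratios get the delta-method correction for logs of Poisson
ratios (+1/(2C_t) − 1/(2C_0)) and inverse-variance weights
1/(1/C_t + 1/C_0), combined across replicates; a 7×7×3 grid over
(k_max, λ_w, k_b) seeds bounded least squares in log-parameter space. The
gene integrand is coarsened to ~3-nucleosome spans carrying their
length-weighted mean rate (the E1 integral stays exact per span); the
noise-free self-inversion test recovers all three parameters to < 1 %.

Known limitation: fragments overlapping gene edges import flanking signal
(survival ≈ e^(−k_b·t)) into gene counts. This inflates residuals of short,
strongly-repaired genes and biases the fitted k_max low and λ_w high by
10–20 % at the default conditions even though per-gene agreement with the
oracle is tight (median |R_obs·gf − E[R]| ≈ 0.03). A midpoint-assignment
counting mode would remove the bias at the cost of departing from the
standard ≥ 1 bp overlap rule; the default keeps the standard rule.

## What the simulation does and does not establish

The simulator reproduces the statistical structure the analysis relies on:
nucleosome-periodic deposition with promoter depletion, removal increasing
with expression and attenuating with TSS distance, genotype severity as a
multiplicative factor, replicate noise from fragment sampling. It does not
model sequence-level effects (mappability, GC bias, adapter chemistry),
replication (deliberately: removal is measured in non-S-phase conditions),
bidirectional promoter read-through, or inter-gene variation in repair
capacity. Passing tests therefore demonstrate that the *pipeline* computes
the intended quantities and that the statistics behave as designed under
realistic counting noise — not that the kinetic defaults describe any real
cell line.

## Numerical and design choices

* Ratio QC threshold 10 baseline counts balances bias (E[1/C] inflation) and
  gene retention; flagged genes are always reported.
* Degenerate t-tests (zero pooled variance) return p = 1 for equal means and
  p = 0 flagged `degenerate` otherwise.
* Multi-group comparisons expose pairwise t-tests with Bonferroni adjustment,
  a deliberately conservative stand-in labelled as such in output.
* All tabular outputs are sorted (gene_id, bin, sample) so reruns are
  byte-identical; manifests carry SHA-256 checksums.
* Problem sizes in the test suite (2,000 genes × 10⁶ fragments for
  end-to-end checks; hundreds of genes × 10⁴–10⁵ fragments for unit tests)
  are the package's reference study conditions; they complete the full suite
  in about two minutes.
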