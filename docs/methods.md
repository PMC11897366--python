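# Methods

This note documents the models, the synthetic world, the numerical choices
and the known limitations of `biofilmstab`. It states no result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The experiment being emulated

A two-phase field manipulation of rocky-shore biofilm. Phase 1 (days ~7–77):
six biweekly 70-min warming pulses, ΔT = +12 °C above ambient, either constant
(*fixed*, SD 0) or varying between pulses (*fluct-s1/s2/s3*), each fluctuating
sequence moment-matched to mean 12 °C and sample SD 5 °C (n−1 denominator)
but with a distinct temporal profile. Phase 2 (days 84 and 88): two extreme
events of 60 °C for 120 min. Controls are unmanipulated; *extreme-only* plots
receive only phase 2; *artifact-control* plots are shaded but never warmed.
Default sampling: nine biomass dates (four before, five after the extremes)
and four community dates (start, end of phase 1, after the extremes, end).
Four plots per treatment, six subplots per plot for biomass.

## Synthetic world

The generator's purpose is parameter recovery: every downstream statistic can
be checked against a known truth.

**Regime.** Fluctuating pulse vectors are uniform draws affinely rescaled
(shift-and-scale) so sample mean and SD match the design *exactly*; the
distribution of the draws is otherwise unconstrained, which mirrors the fact
that only the moments of the real sequences are specified. The n−1 SD is the
conventional choice.

**Phylogeny.** A birth–death tree (birth 1.0, death 0.5) over the MAG pool,
default 137 tips (the study's scale); strictly positive branch lengths.

**Traits.** Minimal doubling time (MDT) is log-normal (median 3 h, log-SD
0.6); genome size log-normal around 4 Mb; completeness uniform on 70–100 %.
The expected stress-module count rises linearly with log MDT at
`tradeoff_slope` (default 2 modules per log-hour) with Gaussian rate noise
(`trait_noise_sd`, default 1), Poisson-sampled; in the noise-free limit the
count is the rounded expectation so the trade-off becomes exact. Which module
families a genome carries is a prevalence-weighted random subset (15
families, geometric popularity 0.75^k): real stress-module families are very
unevenly distributed, and uneven prevalence is what lets trait combinations
recur so the functional-entity partition is non-trivial.

**Abundances.** A shared log-normal baseline (log-SD 1.5) defines the rank
structure; per treatment, an evenness exponent (<1 compresses ranks; fixed
warming default 0.8), a selection term against slow growers (standardised log
MDT, ramping over the experiment; fluctuating default 0.8) and rare-taxon
loss (fluctuating default 0.30 of the bottom abundance quartile) modify it.
AR(1) noise (ρ = 0.6, innovation SD 0.5) gives within-plot temporal
autocorrelation. Each sample closes to the TPM constant (10⁶) over the MAG
rows **plus one explicit `unbinned` pseudo-taxon** holding the non-MAG
fraction (Beta(13, 7) binned fraction per sample, mean 0.65); MAGs whose TPM
falls below 200 are recorded as absent. The sub-composition matters: if the
MAG rows themselves summed to a constant, Gross' η would equal −1 identically
(every trajectory is perfectly anti-correlated with its complement) and
βMNTD between samples would be identically zero (every genome present
everywhere is its own nearest taxon). Real MAG tables are sub-compositions of
the metagenome, and all genome-level drivers here exclude the unbinned row.

**Biomass.** Generated on the log scale so treatment effects are additive in
log-response-ratio (LRR) units: log B = control trajectory (intercept 2.1,
slope 0.004 d⁻¹) + treatment deviation + plot random intercept/slope +
residual, exponentiated, with subplot noise. The deviation is zero before the
extremes and afterwards equals sensitivity + resilience·t + a recovery offset
ramping linearly to its full value at the last date (the offset is an *extra*
deviation on top of what sensitivity and resilience already imply at the last
date — the three are not independent axes under a linear model). Default
noise: residual SD 0.08, plot intercept SD 0.05, plot slope SD 0.002, subplot
SD 0.10 (all log-scale). Default planted effects mirror the qualitative
outcome of the experiment: extreme-only crashes (−0.60) and rebounds
(+0.018 d⁻¹); fixed warming is buffered (−0.12); fluctuating treatments are
barely sensitive (−0.05) and overshoot (+0.008 d⁻¹).

**What the generator does not emulate:** sequence-level data, spatial
structure beyond plot/subplot nesting, treatment effects on the phylogeny,
seasonal covariates, or correlated module profiles beyond prevalence
weighting. Passing tests therefore show that the estimators recover known
effects under the assumed noise model, not that the field data satisfy it.

## Estimators and models

**Hill numbers** drop zero abundances, normalise, and use the natural log;
q = 1 is the exponential-Shannon limit, general q ≥ 0 is supported.

**Synchrony/variability.** Gross' η uses Pearson correlations of each
genome's trajectory with the summed remainder; weights are mean relative
abundances over the plot's dates, renormalised after excluding
constant-trajectory genomes (whose correlation is undefined). Population
variability is the same-weighted mean of per-genome temporal SDs on the raw
TPM scale. Both choices (time-aggregated weights; SD rather than CV) are the
plain readings of the quantities and are documented here because alternative
conventions exist.

**βMNTD / βNTI / pNST.** βMNTD is abundance-weighted by default (TPM relative
abundances; an unweighted flag exists). The null model shuffles tip labels
across the whole phylogeny — equivalently, permutes rows/columns of the
patristic matrix — holding composition fixed; 1000 randomisations by default,
all plot pairs sharing each permutation. βNTI is the standardised effect
size; a zero null SD (e.g. a star phylogeny) yields a flagged NaN that is
excluded from summaries. The stochasticity fraction scales observed and
null-expected dissimilarity by the **maximum attainable βMNTD over the taxon
pool** (the tree diameter, reached by two single-taxon communities at the
deepest split) and uses the two-branch selection-strength form: for scaled
observed d and null expectation e, SS = (d−e)/(1−e) on divergence and
(e−d)/e on convergence; NST = 1 − SS, clamped to [0, 1]. The diameter rather
than the sample maximum of the null draws is used because the sample maximum
sits only ~3 null-SDs above the null mean, which would cap fully stochastic
assemblies near 80 % instead of near 100 %; with the diameter, phylogeny-
random assemblies calibrate to ~90 % and clade-filtered convergence to ~0 %
(both recomputed by the acceptance script). Pairs with zero observed *and*
zero null dissimilarity (full taxon overlap) are scored 100 %: the tip-shuffle
null cannot detect convergence to an identical composition, only convergence
into phylogenetically tight subsets. Group comparisons resample pairwise
values (one-sided bootstrap; the direction should be pre-specified — with a
post-hoc direction the type-I rate doubles, which the `side` argument
documents), p floored at 1/(n_boot+1), BH-FDR within each sampling date.

**Functional structure.** Trait combinations are binarised module profiles
(count > 0 = present); FE identifiers are lexicographic in the profile, so
the partition is deterministic. FOR is the presence-based "excess above mean
fill" form; abundance-weighted FOR is deliberately out of scope. Presence for
per-sample FE metrics is TPM > 0 (configurable). The trade-off model is an
explicit two-stage scheme: WLS of log MDT on module count, genome size (Mb)
and completeness, with residual variance modelled log-linearly in log genome
size (OLS on log squared residuals), iterated to convergence (tolerance 1e−8,
max 50 iterations); the Wald z of the module coefficient is the reported
statistic. The two-stage form makes every step inspectable; its type-I error
and sign-recovery are verified by simulation in the test suite.

**Stability.** The response is the LRR of subplot-averaged plot biomass
against the mean control trajectory per date; control plots are retained so
the model estimates the control slope and residual SD. The mixed model is
fitted by REML with an uncorrelated random intercept and slope per plot
(variance-component parameterisation); a singular random-slope fit downgrades
to intercept-only with a logged warning. Sensitivity and resilience are the
treatment main effects and time interactions; recovery is the fixed-effect
deviation at the last date; temporal stability is 1/SD of the fit's residuals
pooled within treatment. Uncertainty: a parametric bootstrap (default 1000)
re-simulates responses at the fitted parameters (fresh random-effect and
residual draws) and refits; percentile 95 % CIs for location dimensions, and
a log-scale pivot interval (recentred on the treatment's own estimate) for
temporal stability, because the homoscedastic refit centres the raw
percentile interval on the pooled residual SD. Bootstrap refits use the
package's profiled REML solver for this model family (coarse log-grid scan
over the two variance ratios, then Nelder–Mead; fixed effects and residual
variance profiled out), which matches the general mixed-model fitter to
numerical precision — the agreement is itself a test — at a small fraction of
the cost. BACI uses fixed Treatment × Period with a random plot intercept;
its interaction equals the difference-in-differences in the balanced limit
(checked against that closed form). Phase-1 trend models pool the fluctuating
sequences into one level and report the two planned contrasts (control vs
fluctuating, fixed vs fluctuating), each as a level contrast at the centring
date and a trend contrast, centred on the 2nd and on the last sampling date;
Wald z statistics throughout (no denominator-df approximation), BH-FDR over
the last-date family. The control vs extreme-only pre-phase model uses a
random intercept only; the artifact-control model has treatment as the sole
fixed effect.

**BCa intervals** (for control-band panels) delegate to
`scipy.stats.bootstrap(method="BCa")`; all-equal samples short-circuit to a
flagged zero-width interval.

## Numerical and engineering choices

- All randomness flows from explicit integer seeds; component streams are
  salted by name so regenerating one artefact never perturbs another.
  Identical (config, seed) gives byte-identical fixture bundles (SHA-256
  manifests).
- TSV floats are written in shortest round-trip form and parsed with
  round-trip precision, so read∘write is the identity.
- Calibration problem sizes: the pNST calibrations use 100 replicates at 200
  randomisations on the 137-tip pool; the stability coverage study uses a
  control + one-treatment world at 4 plots × 6 subplots × 5 post-extreme
  dates, 200 replicates × 200 bootstrap draws; the bootstrap type-I study
  uses 500 simulations at 1000 resamples. These sizes give Monte-Carlo error
  well inside the asserted bands.
- The planted "truth" for temporal stability in the coverage study is the
  effective residual SD of plot-level LRRs — the plot×date draw, the
  subplot-averaging remainder (SD/√6) and the shared control-baseline noise
  (previous two terms /4 control plots) combined — not the raw residual SD
  parameter.

## Known limitations

- The tip-shuffle null randomises phylogenetic relatedness only; richness- or
  occupancy-preserving compositional nulls (Raup–Crick style) are a
  documented extension point, not implemented.
- η is computed as temporal synchrony among genomes within a plot; the
  field literature sometimes uses the same statistic across plots.
- Temporal stability assumes the pooled-fit residuals are exchangeable within
  treatment; strong heteroscedasticity across treatments is reflected in the
  point estimates but not in the (homoscedastic) bootstrap generative model.
- The trade-off model is a stand-in for an unprinted mixed-package call in
  the field workflow; its response/link structure (log MDT, log-linear
  dispersion in genome size) is a declared choice, validated only by
  simulation.
- Wald z tests are used throughout; small-sample denominator-df corrections
  are out of scope, so p-values near the threshold should be read with care.
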