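# Methods

`tldkit` reimplements, as a tested library, the statistical pipeline used to
dissect thymineless death (TLD) in *E. coli*: genome-wide Tn-seq survival
profiling, stress-gene-set enrichment against a fitness compendium,
RNA-seq/genetics concordance, size-corrected flow-cytometry fluorescence
modeling, FACS sort-survival regression, and the small statistics used for
kill curves and growth rates.  This note records the models, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions made where the design was open.

## Tn-seq survival profiling

A saturated Tn5 library in a thymidine auxotroph is starved of thymidine.
Reads at insertion sites are sequenced at three points: **Start** (selection
onset, no recovery outgrowth), **t0** (0 h starvation, followed by a 2–3
doubling outgrowth in high thymidine) and **t3** (3 h starvation, same
outgrowth).  The outgrowth amplifies signal from surviving cells over
residual DNA from dead ones; the t0 outgrowth controls for genotypes that
simply regrow faster.

Counts are aggregated per gene by strand-agnostic containment of the
insertion coordinate in the 1-based inclusive gene interval (a site in
overlapping genes counts toward all of them; sites in no gene go to an
intergenic bucket).  Per-sample counts are normalized to footprints per
million (FPM).  The gene-level **survival score** is

    S = log2( (FPM_t3 + eps) / (FPM_t0 + eps) ),   eps = 0.5 FPM,

so a positive score means the disruption *helps* survival.  The pseudocount
keeps scores finite and symmetric at zero counts; it is a display/filter
device only — significance always comes from the raw counts via the exact
conditional rate-ratio test: given x_t0 + x_t3, x_t3 is Binomial with
success probability N_t3/(N_t0+N_t3) under equal rates, and the two-sided
p-value sums all outcomes no more likely than the observed one (the
minimum-likelihood rule; a doubled-tail variant is selectable, since exact
two-sided tests in circulation use either rule).  Genes with fewer
than 10 reads across t0+t3 are not tested; such exact tests are degenerate.

FDR correction defaults to Benjamini–Yekutieli with Benjamini–Hochberg
selectable; both corrections are in circulation for gene-level screen
statistics, so both are first-class and the more conservative one is the
default.  Candidate lists take |S| > 0.5 with q < 0.05 and then discard
genes whose 3h-vs-Start score has the opposite sign from S (regrowth
artifacts).  The high-confidence flag requires at least two insertion sites
each individually significant (per-site two-proportion test of site reads
vs rest of library between t0 and t3; 2×2 chi-squared with continuity
correction, Fisher's exact when any expected cell is below 5; BH across
sites, q < 0.1) and all significant sites agreeing in direction.

## Stress-gene-set enrichment

Per-gene fitness scores and t-statistics from a pooled-mutant compendium
are partitioned per stress condition into *beneficial* (fitness < −1 and
t < −2), *deleterious* (fitness > +1 and t > +2; per-condition overrides
supported, e.g. +0.5 for weak-effect conditions) and *neutral*.  Deleterious
genes are excluded; the universe is beneficial ∪ neutral.  Enrichment of a
hit list is log2[(hits∩beneficial/|hits|) / (|beneficial|/|universe|)] — a
ratio of proportions, with a log-odds variant exposed — tested by a 2×2
chi-squared without continuity correction (the plain statistic matches the
scale of enrichment p-values this analysis is meant to produce; the choice
is configurable).

## Expression concordance

RPKM and TPM are computed from gene-level counts and lengths; LFCs are
log2((TPM_a + 1)/(TPM_b + 1)) with the numerator being the evolved/starved
condition.  The 1-TPM pseudocount and the default exclusion of genes below
5 TPM in every sample implement a stringent low-expression filter; both are
configurable since the original cutoffs are unstated.  A gene is
*concordant-exacerbating* when its disruption significantly helps survival
(S > +0.5, q < 0.05) and its expression drops in the resistant strain
(LFC < −0.5), and *concordant-alleviating* in the mirrored case.
Differential-expression q-values from an external negative-binomial test
can be required on top; they are consumed, never computed here.  The
(KO-harmful × upregulated) enrichment uses the shared 2×2 machinery with a
Fisher fallback on degenerate margins.

## Flow cytometry

Events are gated to log2(fsc) > 8 and log2(ssc) > 8 (strict).  For each
acquisition batch, autofluorescence is fit on the pooled no-dye events as a
locally weighted (LOESS-style) degree-1 surface of fluorescence over the
raw (FSC, SSC) plane — tricube weights over the nearest `span` fraction of
training points (default 0.5), training capped at 4000 points by
deterministic subsampling.  No installed package provides 2-D LOESS, so the
smoother is implemented here; degree 1 with span 0.5 is robust at the
event counts a batch provides.  Predictions for events outside the training
bounding box are clamped to its boundary and flagged.  The prediction is
subtracted per event; events with non-positive adjusted signal cannot enter
a log-scale model and are dropped by default with their per-condition
fraction reported (an optional mode shifts all events by the first
percentile of the positive values instead).

The adjusted signal is modeled on the log2 scale:

    log2(fluor_adj) ~ a·log2(fsc) + b·log2(ssc) + c_strain
                      + (1 | batch) + (1 | rep)

with crossed random intercepts for acquisition day and biological replicate
(a nested reading of the two terms is possible; crossed is the default and
matches day-by-replicate designs).  log2 is used throughout for internal
consistency between the model and the per-cell corrected quantity.  The fit
uses REML with variance components; a component estimated at zero is
dropped with a refit and a warning.  `c_strain` is reported relative to a
designated reference condition (offset exactly zero), with 95% Wald
intervals — the mixed-model implementation used here does not expose
profile likelihood intervals, and at the event counts involved the two
agree closely.  Condition contrasts are Wald tests on c differences; stars
follow the 0.05/0.01/0.001/0.0001 convention.  The per-cell
`log2(fluor_adj) − a·log2(fsc) − b·log2(ssc)` is provided for plotting and
sorting thresholds only and is never re-fed to the model.

## Sort survival

Colony counts from sorted high/low-fluorescence fractions (1000 cells
plated per fraction) are modeled by Bayesian negative-binomial regression
with log link and offset log(n_sorted): coefficients for dye condition
(including the no-dye control), dye × level(low) interaction, and
experiment date.  Priors are Student-t(3, 0, 2.5) on coefficients and
half-t(3, 0, 2.5) on the NB dispersion — the weakly informative defaults
typical of Bayesian regression packages.
Sampling is an affine-invariant ensemble sampler with differential-
evolution moves (4000 burn + 2000 retained steps by default across ~30–45
walkers, seedable); split R-hat over walkers must be ≤ 1.05 or the fit
errors with diagnostics.  The headline probability is the Monte-Carlo
fraction of draws with (low−high contrast | dye) > (low−high contrast |
no dye); the within-dye contrast P(γ_dye > 0) is available as an option
because the published description of the contrast is loose.  The reported
MC standard error uses the effective sample size, not the raw draw count.

Note that for any *single* finite null dataset this posterior probability
is approximately uniform on (0,1) — it equals Φ(z) for a roughly standard
normal z — so "≈ 0.5 under the null" is a statement about the average over
null datasets (or about an exactly level-symmetric dataset), and that is
how the acceptance checks read it.

## Assays

Relative survival is cfu_t/cfu_0 with log10 summaries and SEM over
replicates; zero counts are censored at a detection limit.  Strain
comparisons use Welch's t-test on log10 relative survival — the scale on
which kill curves are plotted and variances are comparable.  Doubling rates
are the maximal slope of log2(OD600) over a sliding 5-point window (~50 min
at 10-min reads), with the window and R² reported and a warning when no
window reaches R² ≥ 0.98.  The first-timepoint OD is subtracted as blank by
default; because a maximal-slope window and a fixed-interval fit can give
different rates, the chosen window is always reported in the output.

## Synthetic data

The generators emulate the statistical structure the analyses assume, with
ground truth emitted for recovery harnesses.  They are pure functions of
(parameters, seed).

**Tn-seq** — per-site library abundances are Exponential (a skewed
library); the Start sample is a multinomial draw at the stated depth
(default 1e7).  t0 multiplies each gene's abundance by its outgrowth
fitness over 2.5 doublings; t3 additionally multiplies by 2^S_g.  Residual
dead-cell DNA persists at 5% of pre-selection abundance, while live signal
is amplified 2^2.5-fold during the outgrowth, so the dead component enters
the t3 composition with weight 0.05/(0.05 + 2^2.5) ≈ 0.9% — the dilution of
dead signal is precisely what the outgrowth exists to achieve, and any
working footprinting design requires live signal to dominate.  Estimated
scores recover S_g up to a compositional renormalization shared by all
genes (scores are relative abundances), so recovery is assessed by
regression of estimates on truth: slope and residual RMSE.

**Flow** — log2 scatter is Normal per strain (per-strain mean shifts create
size-confounded designs); dye signal is 2^(a·log2 fsc + b·log2 ssc + c +
batch + rep + noise) with a = 0.8, b = 0.3, batch SD 0.2, rep SD 0.1,
residual SD 0.5 on the log2 scale, over 3 batches × 4 replicates by default
— replicate counts in the range the experiments used; the measured
fluorescence adds a smooth linear autofluorescence surface plus noise, and
matched no-dye events carry autofluorescence only.  Not emulated: detector
saturation, spectral spillover, debris/doublets beyond the gate, and any
dye-to-pH calibration — passing tests show the correction machinery
works when its model holds, not that a given dye is a linear pH reporter.

**Expression** — NB counts with known per-gene LFC, log-normal gene
lengths and expression levels, dispersion 0.1.  **Sort** — NB survivor
counts at stated per-cell rates, n_sorted = 1000, with the study's replicate
design (BCECF 5, pHrodo 7, no-dye 4; replicate i of each dye shares date i
so date effects are identified).  Baseline sorted-cell survival defaults to
0.2–0.3, matching an early (1.5 h) starvation timepoint with modest death.

## Problem sizes used by the acceptance script

The script regenerates everything at desk scale chosen to make the checks
statistically meaningful: 1500 genes (150 with effects spanning [−3, +4])
at depth 1e7 for Tn-seq recovery; a 2000-gene Poisson null for test
calibration; 100 simulated acquisitions for the size-confound check and
~10,000 events per strain for shift recovery; 20 null sort datasets plus
one two-fold-effect dataset at the study's replicate counts.

## Known limitations

- The per-site high-confidence test treats sites independently; local
  PCR-jackpot correlation between nearby sites is not modeled.
- The LOESS boundary policy (clamp to the training box) is a first-order
  stand-in for true convex-hull nearest-boundary prediction; flagged events
  let callers apply stricter policies.
- Wald (not profile) intervals for the strain effects; at a few thousand
  events per condition the difference is negligible, at very small event
  counts it may not be.
- The NB sort-survival model identifies dye-level interactions cleanly, but
  dye main effects and date effects are only weakly separated when dates
  are nested in dyes; priors regularize this, and simulated dates are
  shared across dyes.
- Compositional renormalization means absolute survival scores are defined
  only up to a library-wide constant; all thresholds operate on the same
  scale as the published scores only insofar as the effect-gene fraction is
  comparable.
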