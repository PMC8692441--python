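# Methods

## Dosage model

A male somatic cell carries two copies of each autosome and one copy
each of X and Y. Under mosaic loss, a fraction `f_Y` of cells lacks the
Y (and optionally `f_X` lacks the X), so bulk copy number is 2 for
autosomes, `1 − f_X` for X and `1 − f_Y` for Y. All estimators express
dosage relative to a haploid unit defined as half the autosomal
coverage: autosomes sit at 1× the diploid depth, an intact single-copy
sex chromosome at 0.5×.

Only the first 3.3 Mb of the Y — the male-specific region (MSY), which
is non-recombining, uniquely mappable and contains all Y protein-coding
genes — enters any Y statistic. The remainder of the Y assembly is
repeat-dense; coverage there mostly reflects unresolved repeat copy
number, not chromosome dosage, and is excluded by `restrict_to_msy`.

### Amplicon score

For unique read counts `n_Y` (Y-linked single-copy locus) and `n_A`
(autosomal single-copy locus) from one two-locus pool,
`score = log10(n_Y) − log10(n_A / 2)`. Under the multinomial sampling
model the expectation is `log10(1 − f_Y)` plus the log-ratio of
amplification efficiencies; with locus efficiencies drawn symmetrically
in log-space the score is median-unbiased at 0 for intact samples,
which is what the signed-rank screen tests. A zero Y count is replaced
by a half count so the score stays finite; consumers can flag such
samples from `n_Y == 0`.

### WGS estimate

Per-base depth is averaged over non-overlapping 10 kb windows (window
value = mean depth, implicit zeros for uncovered bases; the last window
of a chromosome may be shorter). Window values are divided by library
size in millions of reads — any consistent positive scale works, since
every downstream statistic is a within-sample ratio; the scale
invariance is tested to 1e-9. Medians are taken per chromosome, with
the autosomal reference median pooled over all autosomal windows rather
than averaged per chromosome (robust to unequal window counts). The
loss-fraction estimate is `f_hat = clip(1 − observed/expected, 0, 1)`;
the unclipped ratio is always reported alongside, and
`diff = observed − expected` is the quantity tested against zero.

### Log2 ratio profile

Per MSY window, `log2(sample / reference)` with a young intact
reference. The orientation puts the aged sample in the numerator so
that **loss is negative**, consistent with the sign convention of the
score and the diff. Windows where either track is zero are dropped by
default (and counted); a positive pseudocount retains them. The profile
median estimates `log2(1 − f_Y)`; the profile variance (n − 1
denominator) captures window-level structural heterogeneity. Profiles
are computed at 10 kb analysis resolution; a coarser display resolution
(default 100 kb) is produced by length-weighted re-binning for plotting
and browser tracks.

## Statistical battery

* **Signed-rank location test vs 0** — two-sided, zeros dropped before
  ranking (this reduces n and is reported), absolute values midranked
  under ties. Exact null distribution for n ≤ 25 by dynamic programming
  over doubled midranks (valid under ties, unlike textbook tables);
  above that, a normal approximation with tie-corrected variance and
  continuity correction. The two-sided exact p is
  `min(1, 2·min(P(W ≤ w), P(W ≥ w)))`.
* **Mann–Whitney U** — exact when min(n) ≤ 8 and the pooled data is
  tie-free, otherwise tie-corrected normal approximation with
  continuity correction (disable continuity to recover the exact
  two-group Kruskal–Wallis equivalence).
* **Benjamini–Hochberg** — step-up, applied separately within each test
  family (per screen panel); raw and adjusted p are always emitted
  together, with `*` / `***` annotation at adjusted 0.05 / 0.001.
* **OLS** — slope p from the two-sided t test with n − 2 df; requires
  n ≥ 3 and non-constant x.
* **Kruskal–Wallis** — tie-corrected H, chi-squared(k − 1) p; groups
  with no pooled variation return H = 0, p = 1.
* **Spearman** — rho as the Pearson correlation of midranks; exact p by
  full permutation enumeration for n ≤ 7, t approximation otherwise.

Exactness thresholds (25 / 8 / 7) were chosen so the exact paths
enumerate in milliseconds; every result records which path ran in
`method_detail`, because small LOY cohorts sit exactly where the paths
diverge. Each exact path is tested against an independent brute-force
enumeration oracle implemented in the test suite.

## Synthetic cohorts

The generator produces the two data types the analysis consumes, with
recorded ground truth:

* **Window counts** — expected count
  `μ_w = (base_depth/2) · copy · m_w · window_length`, drawn
  negative-binomial with dispersion α (variance `μ + αμ²`; Poisson at
  α = 0). `m_w` is an optional per-Y-window multiplier emulating
  collapsed assembly repeats. Structural heterogeneity co-occurring
  with loss is modelled as mean-one multiplicative log-normal noise on
  Y windows with log-SD `aberration_sd_scale · f_Y` — one admissible
  choice for a phenomenon with no established generative model; its
  linear coupling to `f_Y` is what produces the negative
  median–variance association the profile analysis detects.
* **Amplicon pools** — `(n_Y, n_A)` multinomial with weights
  `(1 − f_Y)·e_Y : 2·e_A`, efficiencies `e ~ lognormal(0, efficiency_sd)`,
  total fixed at the pool size.

Defaults are the study regime: `base_depth = 10` (upper end of the
7–10X unique-read coverage the analysis assumes), `window_size = 10 kb`,
`nb_dispersion = 0.05` (mild overdispersion typical of PCR-free WGS),
`amplicon_total = 440 000` reads, `efficiency_sd = 0.05` (a few percent
between-locus efficiency jitter), `aberration_sd_scale = 0` unless
heterogeneity is under study. The desk-scale default layout keeps the
real MSY bound (3.3 Mb → 330 analysis windows) but shrinks autosomes to
10 Mb: medians are size-invariant, so only window counts, not real
chromosome lengths, matter to the statistics.

Cohorts derive per-sample seeds by stable hashing of (master seed,
sample index), so enlarging a cohort never changes existing samples.
Young reference samples are always intact (`f = 0`, 3 months); aged
samples draw ages uniformly on 22–25 months, matching the two-point age
design of a young-vs-senescent comparison.

What the generator does **not** emulate: GC bias, mappability
gradients, PCR chimeras, replication-timing waves, X inactivation
biology, or segmental CNVs off the Y. Passing recovery tests therefore
demonstrate estimator correctness under the dosage + overdispersion
model, not robustness to every artifact of real libraries; the mask
(`mask_windows`, 50% overlap rule, optional depth floor) and the
median-based summaries are the intended defenses against such artifacts
in real data.

## Numerical conventions and edge cases

* Coordinates: 0-based half-open internally; depth TSV input is 1-based
  (`samtools depth` dialect); BED input 0-based. Conversions are tested.
* Median of an even window count = mean of the two middle values.
* A window overlapped > 50% by gap-mask intervals is dropped
  (mask intervals are merged before measuring overlap); the threshold
  keeps windows that merely touch an N-run.
* Normalizing an already-normalized track is an error, not a silent
  rescale.
* `f_hat` is clipped to [0, 1]; the unclipped ratio is retained.
* Profiles with fewer than two retained windows get variance 0.
* Groups smaller than 3 are flagged `underpowered` and not tested; the
  reference profiled against itself is all-zero and is reported as
  `degenerate` rather than fed to the signed-rank test.
* Fits excluding anchor points drop the reference self-anchor plus
  user-designated sample ids only — extreme samples are never
  auto-excluded.

## Design choices

* The per-group location screen uses the one-sample Wilcoxon
  signed-rank test of location 0. (The same comparison is sometimes
  described as a Mann–Whitney test against a fixed median; for a single
  sample with `mu = 0` that procedure *is* the signed-rank test, and the
  function is named for what it computes.)
* Signs standardized so loss is negative in every statistic (score,
  diff, log2 ratio); two-sided tests make all conclusions invariant to
  this choice.
* Within-window aggregation is the mean per-base depth; robustness
  comes from the cross-window median downstream.
* BH families follow screen panels: one family per age group for the
  per-tissue location tests, one for young-vs-old contrasts, one for
  the 22-chromosome panel, one for the per-sample profile tests.
* Tables are the output contract; all artifacts are TSV/JSON and the
  ratio tracks are BED-like for genome-browser conversion.

## Problem sizes

The acceptance computations use 24-sample recovery cohorts (4 per
stratum, f ∈ {0…0.5}), 200 amplicon pools for the score expectation,
50 × 10-sample cohorts for screen specificity, 500 replicates for test
calibration, and 50 × 30-sample cohorts for the heterogeneity
direction check — sizes at which the whole battery completes in about
a minute on one core while keeping Monte-Carlo error well inside the
asserted bounds.

## Known limitations

* `f_hat` is a bulk dosage estimate; it cannot separate uniform partial
  loss from a mixture of full-loss and intact clones, and it says
  nothing about which cell types carry the loss.
* The amplicon score rests on two loci; locus-specific efficiency drift
  biases it in ways the WGS estimator is immune to. Cross-assay
  concordance (Spearman ρ ≈ 0.96 on joint simulations) is the intended
  sanity check, and per-sample conclusions should prefer the WGS
  estimate.
* The heterogeneity model is phenomenological; the variance–median
  association it reproduces should be read as a directionality check,
  not a calibrated effect size.
* No segmentation of profiles into discrete aberration calls is
  attempted.
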