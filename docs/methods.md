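# Methods

This note documents the statistical model, the numerical conventions, the
synthetic-data generator and the open design choices behind `splicecons`.

## The model

### FIRMA scoring

Probe intensities are quantile-normalized (every sample column is mapped onto
the across-sample mean quantile profile of the log2 values; ties take the
rank-average of profile values) and each transcript's probes-by-samples block
is fitted with the additive model

    y_pj = m + a_p + c_j + r_pj

by Tukey median polish. No background correction is applied: the generator's
data model — and the minimal assumption the method needs — is additive on the
log2 scale, and inventing an unspecified background convolution would add a
parameter the analysis cannot check.

The FIRMA score of exon e in sample j is

    F_ej = median_{p in e}(r_pj) / s,
    s    = max(1.4826 * MAD(r), 1e-8)

with the MAD taken over **all** residuals of the transcript, not the exon's
own: an exon's genuine deviation must not inflate its denominator. The
1.4826 factor makes s estimate the residual standard deviation under Gaussian
noise; the 1e-8 floor keeps exactly additive data at score 0 instead of 0/0.
Scores live on the symmetric log2-residual scale, so "log-transformed" scores
are obtained natively rather than by post-hoc transformation. Single-probe
exons are allowed (the median of one residual).

**Median polish sweep order.** Sweeps alternate column (chip) medians and row
(probe) medians, *columns first*, absorbing the median of each effect vector
into the overall term, and stop when the total absolute residual changes by
at most `tol` (default 1e-6, max 20 sweeps; even-length medians use the
midpoint). Columns-first is a deliberate numerical choice: a constant added
to one sample column is then absorbed exactly by that column's effect in the
first sweep, making residuals — and therefore all FIRMA scores — bit-stable
under per-chip intensity shifts. Rows-first polishing converges to
shift-dependent fixed points (median polish has non-unique fixed points), and
chip-shift invariance is the property the scores must have for the downstream
percentile thresholds to be meaningful across chips.

Median polish is robust but not surgical: a single corrupted cell leaks
residual mass of the order of one order-statistic gap into its row and
column. On realistic transcripts a +100 corruption moves other exons' scores
by well under one score unit while the corrupted exon-sample score moves by
tens of units; the tests assert exactly that bound rather than a fictional
zero.

### Event calling

Thresholds are the 1st and 99th percentiles (linear interpolation between
closest order statistics — conventions differ between libraries, so this one
is stated explicitly) of the pooled scores of all exons in *all* samples and
groups together. Calls use strict inequalities: score > q_high is an
inclusion event, score < q_low an exclusion event, ties stay uncalled, so
inclusion/exclusion/uncalled partition the exon-sample grid and the call rate
is pinned near 2% by construction. An event's identity everywhere downstream
is the triple (transcript, exon, direction); the two directions are never
pooled. Per-group event counts are summarized by the median with a
percentile-bootstrap 95% CI over samples and compared across groups by a
two-sided Mann-Whitney (2 groups) or Kruskal-Wallis (3+) test — the CI and
test choices are this package's conventions.

### The consistency statistic

For a group of n samples and one direction, each distinct called event has a
multiplicity k in 1..n. The *random* benchmark is a Poisson model of k; the
observed multiplicities are fitted by a negative binomial with mean mu and
size theta, variance mu + mu^2/theta. Both likelihoods are **zero-truncated**:
an event called in no sample of the group is unobservable, so the data are
conditioned on k >= 1. Small theta means overdispersion — many singleton
events plus a core of events shared by most of the group — which is the
signature of consistent splicing; theta near the Poisson limit means sharing
is no stronger than chance. The interpretation direction (higher theta =
reduced consistency) is hard-coded into the report text to prevent sign
errors.

* **ZT-Poisson MLE.** The likelihood equation is lam/(1 - e^(-lam)) =
  mean(k), solved by Newton iteration safeguarded by the bracket
  [mean-1, mean] (the truncated mean exceeds lam by at most 1). A sample
  mean <= 1 admits no interior optimum and raises a boundary error.
* **ZT-NB MLE.** Maximized over (log mu, log theta) with L-BFGS-B and the
  analytic gradient, theta bounded to [1e-3, 1e6], started from a crude
  moment inversion of var = mu + mu^2/theta and from theta = 1. A fit at the
  upper bound is flagged Poisson-consistent. The NB support is unbounded
  while multiplicities are capped at n; no right-truncation correction is
  applied — an approximation valid for mean << n and documented as such.
  The data can be (and in mixture-like histograms often are) more
  overdispersed than any interior NB, in which case theta sits at the 1e-3
  bound; this is reported, not hidden.
* **Uncertainty.** theta gets a nonparametric bootstrap: events are resampled
  with replacement (multinomially over the histogram), the ZT-NB refitted
  per replicate (single moment-based start for speed), and the 2.5/97.5
  percentiles taken over converged replicates; replicates at the theta
  boundary enter the percentiles at the bound and their fraction is reported.
  More than half the replicates failing to converge raises a CI-unstable
  error. Whether the original analysis used bootstrap, profile-likelihood or
  Wald intervals is unknown; the bootstrap is this package's declared
  convention, and its ~95% coverage is verified by simulation in the tests.
* **Group comparison.** Pairwise, a group is flagged "reduced consistency"
  only when the bootstrap CIs are disjoint; otherwise "indeterminate". In
  driver runs (`consistency_report`, `run_pipeline`) a group/direction whose
  histogram admits no fit (all counts equal, mean <= 1, too few events for a
  CI) is reported with NaN estimates and an explanatory note instead of
  aborting the other groups; the direct estimator functions always raise.

The Poisson rate of the random case is *fitted* to the observed multiplicities
by ZT-MLE; an alternative — deriving lambda from event totals and the exon
universe — would need the effective number of callable exons, which the
percentile thresholds make ill-defined.

### Overlap enrichment

`list_overlap_test(A, B, N)` computes the overlap m = |A ∩ B|, the fraction
m/|A| (reported relative to A; the roles are explicit), and the one-sided
hypergeometric upper tail P(X >= m) for |A| draws from a universe of N
containing |B| successes. N has no default: the correct universe (array-wide
gene count vs. detectable subset) is a scientific judgement the caller must
make. Identifiers are opaque strings throughout; no genomic coordinates.

## The synthetic-data generator

`simulate_exon_array` emulates the structure the analysis assumes:
transcripts of ~4-10 exons, ~4 probes per exon, samples in labelled groups,
and log2 intensity

    log2 y = b_t + a_p + c_j + delta * 1[event] + eps

with defaults b_t ~ N(8, 1.5^2) (log2 units, a bright-transcript regime),
probe affinities N(0, 1), chip effects N(0, 0.3^2), noise sd 0.25 and event
effect |delta| = 1.5 (sign = direction). The noise magnitude and effect size
of real arrays are not published for this design; these values are
conventions chosen to put injected events ~6 residual SDs out — detectable
but not trivial — and are deliberately not tuned further. Consistent events
pick group-specific (transcript, exon, direction) targets and are carried by
each group sample independently with probability `p_share`, making
within-group sharing Binomial(n, p_share); random events are placed uniformly
over free (exon, sample) cells. All injected events are returned as ground
truth with origin labels. The seed is mandatory and no global RNG state is
touched.

What the generator does *not* emulate: probe cross-hybridization, background
signal, sequence-dependent affinities, batch effects, correlated biological
splicing programs. Passing tests therefore demonstrate the statistical
machinery under the stated additive model, not performance on any real
cohort.

**A detectability constraint worth knowing.** Median polish absorbs any
pattern present in more than half of all samples into the probe effects, so a
consistent event carried by the majority of the *entire* dataset becomes
invisible (and partially reflects, inverted, into the remaining samples).
The bundled study conditions therefore keep each group's consistent events in
a minority of total samples (a ballast control group does this in the
contrast experiments). Real designs satisfy this automatically whenever a
condition group is a minority of the cohort.

## Study conditions for the reproduction experiments

`splicecons.experiments` fixes the synthetic conditions used by both the test
suite and `scripts/acceptance.py`:

* **Directional contrast** — 1500 transcripts x 4 exons x 4 probes, groups
  cons(6)/rand(6)/ctrl(12); 40 consistent events in `cons` at p_share = 0.9;
  600 random events; 20 seeds. Per group the two directions' theta-hats are
  combined by geometric mean (a singleton-only direction counts as
  Poisson-consistent at the upper bound). Expected outcome: the consistent
  group's theta is orders of magnitude below the random group's.
* **Estimator recovery** — ZT-NB(mu=2, theta=0.5), 5000 events, 10 seeds;
  mean absolute errors on mu and theta.
* **CI coverage** — ZT-NB(mu=2, theta=1), 1000 events, 400 bootstrap
  replicates, 200 simulations.

Problem sizes were chosen so the full suite and the reproduction script each
run in minutes on a single CPU while leaving all statistical checks
well-powered.

## Known limitations

* theta saturates at its bounds for strongly mixed histograms (background
  singletons plus a shared core); between-group comparison remains valid but
  the point value is then a censored summary.
* No right-truncation at k = n in the NB likelihood (see above).
* The rank tests and bootstrap CIs assume exchangeable samples within groups;
  paired or batched designs are out of scope.
* No FDR-controlled per-exon inference: event calls are descriptive tail
  exceedances, not hypothesis tests.
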