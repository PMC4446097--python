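# splicecons

Exon-array alternative-splicing consistency analysis.

`splicecons` asks a simple question of a probe-level exon-array experiment:
**do the samples of a group share the same splice events, or does each sample
splice differently?** Consistent splicing across a group is the signature of
regulated, functionally appropriate splicing; events scattered at random
across samples look like splicing noise, so the degree of sharing serves as a
proxy for the splicing error rate. The package is aimed at transcriptomics
analysts working with Affymetrix Human Exon 1.0 ST-style data (patient
cohorts split into disease/control or progression groups) and at
methodologists who want a tested, reusable implementation of the statistic.

## What it computes

1. **FIRMA scores.** Probe intensities are quantile-normalized and
   log2-transformed; each transcript t gets a robust additive model fitted by
   Tukey median polish,

   ```
   y_pj = m_t + a_p + c_j + r_pj
   ```

   (probe effect `a_p`, chip effect `c_j`, residual `r_pj`). The FIRMA score
   of exon e in sample j is the median residual of the exon's probes divided
   by a robust scale (MAD × 1.4826) of the transcript's residuals. Positive
   scores mean the exon runs above its transcript model (inclusion), negative
   below (skipping).

2. **Splice-event calls.** The 1st and 99th percentiles of the pooled scores
   of all exons in all samples define global thresholds; cells beyond them
   are exclusion/inclusion events. Per-group event counts are summarized as
   medians with bootstrap 95% CIs and compared by rank tests.

3. **Consistency statistic θ.** For each group (size n) and direction, every
   distinct event has a multiplicity k = number of samples sharing it. The
   random case is modelled by a Poisson distribution and the observed counts
   are fitted by a negative binomial with mean μ and size θ (variance
   μ + μ²/θ); both likelihoods are zero-truncated because events unseen in a
   group are unobservable. **Small θ = strong overdispersion = events recur
   across samples = consistent splicing; large θ = near-Poisson = random,
   inconsistent splicing.** θ gets a nonparametric bootstrap 95% CI.

4. **List-overlap enrichment.** A one-sided hypergeometric test for the
   overlap of two gene lists within a stated universe.

A synthetic-data module generates probe-level matrices with known injected
events (group-consistent events carried with probability `p_share`, plus
uniformly placed random events), so every stage can be validated against
ground truth.

## Worked example

```python
import numpy as np
from splicecons import (
    SimulationConfig, simulate_exon_array, quantile_normalize,
    fit_all_transcripts, compute_thresholds, call_events, EventSharingModel,
)

cfg = SimulationConfig(
    n_transcripts=300, exons_per_transcript=4, probes_per_exon=4,
    groups=[("case", 6), ("ctrl", 18)],
    n_consistent_events_per_group=15, p_share=0.9,
    consistent_event_groups=["case"], n_random_events=150, seed=42,
)
matrix, truth = simulate_exon_array(cfg)
_, scores = fit_all_transcripts(quantile_normalize(matrix))
callsets = call_events(scores, compute_thresholds(scores))
case = [cs for cs in callsets if cs.sample_id.startswith("case")]
res = EventSharingModel.from_callsets(case, "inclusion", label="case").fit(
    bootstrap=500, seed=1
)
print(res.summary())
```

prints

```
Event-sharing consistency fit
================================================================
group: case    direction: inclusion
samples (n): 6    events (E): 65    mean k: 1.5077
----------------------------------------------------------------
ZT-Poisson   lambda =     0.8862   loglik =     -76.2742
ZT-NegBin    mu     =     0.0012   loglik =     -56.6430
             theta  =      0.001   95% CI = (0.001, 0.001523)
             untruncated variance mu + mu^2/theta = 0.0025
----------------------------------------------------------------
note: a higher level of theta corresponds to a variance closer to the Poisson
distribution and reduced consistency of splicing
```

The 65 distinct inclusion events in the case group share heavily (mean
multiplicity 1.51, with a cluster of events present in 5–6 of 6 samples), so
the negative binomial fit gains ~20 log-likelihood units over the Poisson and
θ sits at the maximum-overdispersion end of its range: consistent splicing.
Repeating this on a group with only random events drives θ to the
Poisson-consistent region (θ ≫ 100).

The same pipeline runs from the shell:

```sh
splicecons simulate --config sim.json --out-prefix data/run1
splicecons run --matrix data/run1_matrix.tsv --groups data/run1_groups.tsv \
    --out-dir results/ --bootstrap 1000 --seed 7
```

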