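"""Synthetic study-condition experiments.

These functions define the reference conditions under which the pipeline's
statistical behaviour is evaluated: a consistently splicing group contrasted
with a purely random one, estimator recovery on clean zero-truncated NB
draws, and bootstrap CI coverage.  They are used both by the test suite and
by the reproduction script, so the conditions live in one place.

The contrast dataset has three groups: ``cons`` (6 samples, group-specific
consistent events carried with probability ``p_share``), ``rand`` (6 samples,
only uniformly placed random events) and a 12-sample ``ctrl`` ballast group.
The ballast keeps any consistent event in a minority of all samples so that
the per-transcript median polish does not absorb it into the probe effects
(an event present in more than half of all samples would otherwise be
reflected, inverted, into the remaining samples).
"""

from __future__ import annotations

import numpy as np

from .consistency import (
    THETA_MAX,
    bootstrap_theta_ci,
    fit_zt_negbin,
    sharing_histogram,
)
from .events import DIRECTIONS, call_events, compute_thresholds
from .exceptions import DegenerateDataError
from .firma import fit_all_transcripts, quantile_normalize
from .simulate import SimulationConfig, simulate_exon_array, simulate_sharing_counts

__all__ = [
    "contrast_thetas",
    "directional_contrast_study",
    "pshare_sweep",
    "ztnb_recovery_study",
    "theta_ci_coverage_study",
]


def _contrast_config(seed: int, p_share: float) -> SimulationConfig:
    return SimulationConfig(
        n_transcripts=1500,
        exons_per_transcript=4,
        probes_per_exon=4,
        groups=[("cons", 6), ("rand", 6), ("ctrl", 12)],
        n_consistent_events_per_group=40,
        p_share=p_share,
        n_random_events=600,
        consistent_event_groups=["cons"],
        seed=seed,
    )


def contrast_thetas(seed: int, p_share: float = 0.9) -> dict[str, float]:
    """Run the full pipeline on one contrast dataset and return, per group,
    the geometric mean of theta-hat over the two event directions.

    A direction whose histogram is all singletons carries no dispersion
    information and is scored as Poisson-consistent (theta at the upper
    bound).
    """
    config = _contrast_config(seed, p_share)
    matrix, _ = simulate_exon_array(config)
    norm = quantile_normalize(matrix)
    _, scores = fit_all_transcripts(norm)
    thr = compute_thresholds(scores)
    callsets = call_events(scores, thr)
    groups = matrix.sample_groups
    out = {}
    for label in ("cons", "rand"):
        sub = [cs for cs in callsets if groups[cs.sample_id] == label]
        thetas = []
        for direction in DIRECTIONS:
            hist = sharing_histogram(sub, direction, group=label)
            try:
                thetas.append(fit_zt_negbin(hist).theta_hat)
            except DegenerateDataError:
                thetas.append(THETA_MAX)
        out[label] = float(np.exp(np.mean(np.log(thetas))))
    return out


def directional_contrast_study(
    n_seeds: int = 20, base_seed: int = 0
) -> dict[str, object]:
    """Consistent vs random group over many seeds.

    Returns the number of seeds in which the consistent group's theta-hat is
    smaller than the random group's (the expected direction: lower theta =
    more consistent splicing), plus the per-seed estimates.
    """
    cons, rand = [], []
    for i in range(n_seeds):
        o = contrast_thetas(base_seed + i)
        cons.append(o["cons"])
        rand.append(o["rand"])
    wins = int(sum(c < r for c, r in zip(cons, rand)))
    return {
        "n_seeds": n_seeds,
        "wins": wins,
        "theta_consistent": cons,
        "theta_random": rand,
    }


def pshare_sweep(
    p_shares=(0.2, 0.5, 0.9), n_seeds: int = 10, base_seed: int = 1000
) -> dict[float, float]:
    """Median theta-hat of the consistent group at each sharing probability."""
    out = {}
    for p in p_shares:
        vals = [contrast_thetas(base_seed + i, p_share=p)["cons"] for i in range(n_seeds)]
        out[float(p)] = float(np.median(vals))
    return out


def ztnb_recovery_study(
    mu: float = 2.0,
    theta: float = 0.5,
    n_events: int = 5000,
    n_seeds: int = 10,
    base_seed: int = 0,
) -> dict[str, float]:
    """Mean absolute error of the ZT-NB MLE on clean simulated sharing counts."""
    err_mu, err_theta = [], []
    for i in range(n_seeds):
        k = simulate_sharing_counts(mu, theta, n_events, 10, seed=base_seed + i)
        fit = fit_zt_negbin(k)
        err_mu.append(abs(fit.mu_hat - mu))
        err_theta.append(abs(fit.theta_hat - theta))
    return {
        "mae_mu": float(np.mean(err_mu)),
        "mae_theta": float(np.mean(err_theta)),
    }


def theta_ci_coverage_study(
    mu: float = 2.0,
    theta: float = 1.0,
    n_events: int = 1000,
    n_sims: int = 200,
    B: int = 400,
    base_seed: int = 0,
) -> dict[str, float]:
    """Empirical coverage of the bootstrap 95% CI for theta."""
    covered = 0
    for i in range(n_sims):
        k = simulate_sharing_counts(mu, theta, n_events, 10, seed=base_seed + i)
        lo, hi, _ = bootstrap_theta_ci(k, B=B, seed=base_seed + 10_000 + i)
        covered += lo <= theta <= hi
    return {"coverage": covered / n_sims, "n_sims": n_sims}
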