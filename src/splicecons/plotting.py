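"""Minimal figure exports: sharing histograms with fits, count summaries."""

from __future__ import annotations

import numpy as np

from .consistency import EventSharingResults
from .events import EventCountSummary
from .ztrunc import ztnb_pmf, ztpois_pmf

__all__ = ["plot_sharing_fit", "plot_event_counts"]


def plot_sharing_fit(results: EventSharingResults, ax=None):
    """Observed sharing histogram with the fitted ZT-Poisson and ZT-NB pmfs.

    The Poisson curve is the random case; the NB curve should track the
    observed bars when splicing is consistent within the group.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    hist = results.model.histogram
    frame = hist.to_frame()
    ks = frame["k"].to_numpy()
    total = hist.total_events
    ax.bar(ks, frame["c_k"], color="0.8", label="observed")
    ax.plot(
        ks,
        total * ztpois_pmf(ks, results.poisson.lambda_hat),
        "o-",
        label=f"ZT-Poisson (lambda={results.poisson.lambda_hat:.2f})",
    )
    ax.plot(
        ks,
        total * ztnb_pmf(ks, results.negbin.mu_hat, results.negbin.theta_hat),
        "s--",
        label=f"ZT-NB (theta={results.negbin.theta_hat:.3g})",
    )
    ax.set_xlabel("samples sharing the event (k)")
    ax.set_ylabel("number of events")
    ax.set_title(f"{results.model.label} / {results.model.direction}")
    ax.legend()
    return ax


def plot_event_counts(summaries: list[EventCountSummary], ax=None):
    """Median event counts per group with bootstrap 95% CIs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.arange(len(summaries))
    med = [s.median for s in summaries]
    err = np.array(
        [[s.median - s.ci_low for s in summaries], [s.ci_high - s.median for s in summaries]]
    )
    ax.errorbar(x, med, yerr=err, fmt="o", capsize=4)
    ax.set_xticks(x, [s.group for s in summaries])
    ax.set_ylabel(f"{summaries[0].direction} events per sample")
    if summaries and not np.isnan(summaries[0].p_value):
        ax.set_title(f"across-group rank test p = {summaries[0].p_value:.3g}")
    return ax
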