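"""Splicing-consistency statistics from event-sharing counts.

For one sample group of size n, every distinct called event (transcript,
exon, direction) has a multiplicity k = number of the group's samples in
which it was called.  Functionally appropriate splicing should recur across
samples of a group, so the distribution of k separates consistent splicing
from random splicing noise:

* the *random* case is modelled by a Poisson distribution;
* the *observed* counts are fitted by a negative binomial with mean ``mu``
  and size ``theta`` (untruncated variance ``mu + mu**2/theta``).

Both likelihoods are zero-truncated, because events unseen in a group are
unobservable.  ``theta`` is the consistency statistic: a *small* theta means
strong overdispersion (the same events recur in many samples — consistent
splicing), a *large* theta means near-Poisson sharing (random, inconsistent
splicing).  Uncertainty on theta is a nonparametric bootstrap over events.

The statsmodels-style entry point is :class:`EventSharingModel`; module-level
functions expose the individual estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .events import DIRECTIONS, EventCallSet
from .exceptions import (
    BoundaryError,
    ConvergenceError,
    DegenerateDataError,
    ValidationError,
)
from .ztrunc import _log1mexp, nb_logp0

__all__ = [
    "SharingHistogram",
    "ZTPoissonFit",
    "ZTNegBinFit",
    "ConsistencyResult",
    "EventSharingModel",
    "EventSharingResults",
    "sharing_histogram",
    "fit_zt_poisson",
    "fit_zt_negbin",
    "bootstrap_theta_ci",
    "consistency_report",
]

THETA_MIN = 1e-3
THETA_MAX = 1e6
#: theta above this is reported as Poisson-consistent (boundary)
THETA_BOUNDARY = 0.999 * THETA_MAX


@dataclass
class SharingHistogram:
    """Counts c_k of events present in exactly k of a group's n samples."""

    group: str
    direction: str
    n: int
    counts: dict[int, int]  # k -> c_k, only k with c_k > 0 stored

    def __post_init__(self) -> None:
        if any(k < 1 or k > self.n for k in self.counts):
            raise ValidationError("multiplicities must lie in 1..n")
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError("histogram counts must be >= 0")

    @property
    def total_events(self) -> int:
        return sum(self.counts.values())

    @property
    def multiplicities(self) -> np.ndarray:
        """Expanded k values, one per event (sorted)."""
        return np.repeat(
            sorted(self.counts), [self.counts[k] for k in sorted(self.counts)]
        )

    def mean(self) -> float:
        e = self.total_events
        return sum(k * c for k, c in self.counts.items()) / e

    def to_frame(self) -> pd.DataFrame:
        ks = np.arange(1, self.n + 1)
        return pd.DataFrame(
            {"k": ks, "c_k": [self.counts.get(int(k), 0) for k in ks]}
        )


@dataclass
class ZTPoissonFit:
    """Zero-truncated Poisson MLE for the random-splicing null."""

    lambda_hat: float
    loglik: float
    converged: bool


@dataclass
class ZTNegBinFit:
    """Zero-truncated negative-binomial MLE (mean mu, size theta)."""

    mu_hat: float
    theta_hat: float
    loglik: float
    converged: bool
    at_boundary: bool

    @property
    def untruncated_variance(self) -> float:
        return self.mu_hat + self.mu_hat**2 / self.theta_hat


# ---------------------------------------------------------------------------
# histogram construction
# ---------------------------------------------------------------------------

def sharing_histogram(
    callsets: list[EventCallSet], direction: str, group: str = ""
) -> SharingHistogram:
    """Within-group sharing histogram for one direction.

    Each distinct (transcript, exon, direction) event seen in >= 1 sample of
    the group contributes its multiplicity; the histogram is zero-truncated
    by construction.
    """
    if direction not in DIRECTIONS:
        raise ValidationError(f"direction must be one of {DIRECTIONS}")
    if len(callsets) < 2:
        raise ValidationError("a group needs at least 2 samples")
    mult: dict[tuple[str, str, str], int] = {}
    for cs in callsets:
        for key in cs.keys(direction):
            mult[key] = mult.get(key, 0) + 1
    counts: dict[int, int] = {}
    for k in mult.values():
        counts[k] = counts.get(k, 0) + 1
    return SharingHistogram(group=group, direction=direction, n=len(callsets), counts=counts)


# ---------------------------------------------------------------------------
# zero-truncated Poisson MLE
# ---------------------------------------------------------------------------

def _as_weighted(values) -> tuple[np.ndarray, np.ndarray]:
    """Collapse raw multiplicities (or a SharingHistogram) to (k, weight)."""
    if isinstance(values, SharingHistogram):
        ks = np.array(sorted(values.counts), dtype=float)
        ws = np.array([values.counts[int(k)] for k in ks], dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValidationError("no sharing counts supplied")
        if np.any(arr < 1) or np.any(arr != np.round(arr)):
            raise ValidationError("sharing counts must be integers >= 1")
        ks, ws = np.unique(arr, return_counts=True)
        ws = ws.astype(float)
    return ks, ws


def _ztpois_loglik(ks: np.ndarray, ws: np.ndarray, lam: float) -> float:
    return float(
        np.sum(
            ws
            * (ks * np.log(lam) - lam - special.gammaln(ks + 1.0) - _log1mexp(-lam))
        )
    )


def fit_zt_poisson(data, tol: float = 1e-12, max_iter: int = 100) -> ZTPoissonFit:
    """MLE of the zero-truncated Poisson rate.

    The MLE solves ``lam / (1 - exp(-lam)) = mean(k)`` — the truncated mean
    matches the sample mean.  Solved by Newton iteration safeguarded by the
    bracket ``[mean-1, mean]`` (the truncated mean exceeds lam by at most 1).
    A sample mean <= 1 admits no interior optimum (lam -> 0) and raises
    :class:`BoundaryError`.
    """
    ks, ws = _as_weighted(data)
    e_total = ws.sum()
    if e_total < 2:
        raise ValidationError("need at least 2 events to fit")
    mean = float(np.sum(ks * ws) / e_total)
    if mean <= 1.0 + 1e-12:
        raise BoundaryError(
            f"sample mean {mean:.6g} <= 1: zero-truncated Poisson MLE is at lam=0"
        )
    lo, hi = max(mean - 1.0, 1e-12), mean
    lam = mean - 0.5  # decent start anywhere in the bracket
    if lam <= lo:
        lam = 0.5 * (lo + hi)
    converged = False
    for _ in range(max_iter):
        u = -np.expm1(-lam)  # 1 - exp(-lam)
        f = lam / u - mean
        if f > 0:
            hi = min(hi, lam)
        else:
            lo = max(lo, lam)
        fprime = (u - lam * np.exp(-lam)) / u**2
        step = f / fprime
        new = lam - step
        if not lo <= new <= hi:  # safeguard: bisect
            new = 0.5 * (lo + hi)
        if abs(new - lam) <= tol * max(1.0, lam):
            lam = new
            converged = True
            break
        lam = new
    return ZTPoissonFit(
        lambda_hat=float(lam),
        loglik=_ztpois_loglik(ks, ws, float(lam)),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# zero-truncated negative-binomial MLE
# ---------------------------------------------------------------------------

def _ztnb_nll(x: np.ndarray, ks: np.ndarray, ws: np.ndarray) -> float:
    mu, theta = np.exp(x)
    ll = np.sum(
        ws
        * (
            special.gammaln(ks + theta)
            - special.gammaln(theta)
            - special.gammaln(ks + 1.0)
            + theta * np.log(theta / (theta + mu))
            + ks * np.log(mu / (theta + mu))
            - _log1mexp(nb_logp0(mu, theta))
        )
    )
    return -float(ll)


def _ztnb_nll_grad(x: np.ndarray, ks: np.ndarray, ws: np.ndarray):
    """Negative log-likelihood and its gradient in (log mu, log theta)."""
    mu, theta = np.exp(x)
    s = theta + mu
    log_ratio = np.log(theta / s)
    logp0 = theta * log_ratio
    p0 = np.exp(logp0)
    one_m_p0 = -np.expm1(logp0)
    logpmf = (
        special.gammaln(ks + theta)
        - special.gammaln(theta)
        - special.gammaln(ks + 1.0)
        + theta * log_ratio
        + ks * np.log(mu / s)
        - np.log(one_m_p0)
    )
    # d logpmf / d mu and / d theta (natural scale)
    d_mu = ks / mu - (ks + theta) / s - p0 * theta / (s * one_m_p0)
    d_theta = (
        special.digamma(ks + theta)
        - special.digamma(theta)
        + log_ratio
        + 1.0
        - (ks + theta) / s
        + p0 * (log_ratio + mu / s) / one_m_p0
    )
    nll = -float(np.sum(ws * logpmf))
    grad = -np.array([np.sum(ws * d_mu) * mu, np.sum(ws * d_theta) * theta])
    return nll, grad


_LOG_THETA_BOUNDS = (np.log(THETA_MIN), np.log(THETA_MAX))
_LOG_MU_BOUNDS = (np.log(1e-8), np.log(1e6))


def fit_zt_negbin(data, starts: tuple | None = None) -> ZTNegBinFit:
    """MLE of the zero-truncated negative binomial (mu, theta).

    Maximizes the truncated likelihood over (log mu, log theta) with L-BFGS-B,
    theta bounded to [1e-3, 1e6].  Started from a moment estimate and from
    (sample mean, theta=1); an estimate at the theta upper bound is flagged
    ``at_boundary`` and means the data are Poisson-consistent (no detectable
    overdispersion).
    """
    ks, ws = _as_weighted(data)
    if ws.sum() < 3:
        raise ValidationError("need at least 3 events to fit a two-parameter model")
    if len(ks) < 2:
        raise DegenerateDataError(
            "all sharing counts identical: no dispersion information"
        )
    mean = float(np.sum(ks * ws) / ws.sum())
    var = float(np.sum(ws * (ks - mean) ** 2) / ws.sum())
    if starts is None:
        start_list = [(mean, 1.0)]
        if var > mean * 1.0001:
            # crude untruncated moment inversion of var = mu + mu^2/theta
            start_list.append((mean, mean**2 / (var - mean)))
        else:
            start_list.append((mean, 100.0))
    else:
        start_list = [starts]

    best = None
    for mu0, th0 in start_list:
        x0 = np.array(
            [
                np.clip(np.log(mu0), *_LOG_MU_BOUNDS),
                np.clip(np.log(th0), *_LOG_THETA_BOUNDS),
            ]
        )
        res = optimize.minimize(
            _ztnb_nll_grad,
            x0,
            args=(ks, ws),
            method="L-BFGS-B",
            jac=True,
            bounds=[_LOG_MU_BOUNDS, _LOG_THETA_BOUNDS],
        )
        if best is None or res.fun < best.fun:
            best = res
    mu_hat, theta_hat = np.exp(best.x)
    return ZTNegBinFit(
        mu_hat=float(mu_hat),
        theta_hat=float(theta_hat),
        loglik=-float(best.fun),
        converged=bool(best.success),
        at_boundary=bool(theta_hat >= THETA_BOUNDARY),
    )


def bootstrap_theta_ci(
    multiplicities,
    B: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI for theta, resampling events with replacement.

    Returns ``(low, high, boundary_fraction)`` where the boundary fraction is
    the share of converged replicates whose theta sat at the upper bound
    (those replicates enter the percentile as theta = 1e6, i.e. effectively
    Poisson).  Raises :class:`ConvergenceError` when more than half of the
    replicates fail to converge.
    """
    ks, ws = _as_weighted(multiplicities)
    e_total = int(ws.sum())
    if e_total < 10:
        raise ValidationError("need at least 10 events for a bootstrap CI")
    rng = np.random.default_rng(seed)
    probs = ws / ws.sum()
    thetas = []
    n_boundary = 0
    n_failed = 0
    for _ in range(B):
        w_star = rng.multinomial(e_total, probs).astype(float)
        kept = w_star > 0
        if kept.sum() < 2:
            n_failed += 1
            continue
        try:
            fit = fit_zt_negbin_weighted(ks[kept], w_star[kept])
        except (DegenerateDataError, ValidationError):
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        thetas.append(fit.theta_hat)
        n_boundary += int(fit.at_boundary)
    if n_failed > B / 2:
        raise ConvergenceError(
            f"{n_failed}/{B} bootstrap replicates failed: CI unstable"
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(thetas, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi), n_boundary / max(len(thetas), 1)


def fit_zt_negbin_weighted(ks: np.ndarray, ws: np.ndarray) -> ZTNegBinFit:
    """Single-start ZT-NB fit on pre-aggregated (k, weight) data.

    Used inside the bootstrap where speed matters; the moment start is a
    good initial point for resampled data close to the original.
    """
    if len(ks) < 2:
        raise DegenerateDataError("all sharing counts identical")
    mean = float(np.sum(ks * ws) / ws.sum())
    var = float(np.sum(ws * (ks - mean) ** 2) / ws.sum())
    th0 = mean**2 / (var - mean) if var > mean * 1.0001 else 100.0
    x0 = np.array(
        [
            np.clip(np.log(mean), *_LOG_MU_BOUNDS),
            np.clip(np.log(th0), *_LOG_THETA_BOUNDS),
        ]
    )
    res = optimize.minimize(
        _ztnb_nll_grad,
        x0,
        args=(ks, ws),
        method="L-BFGS-B",
        jac=True,
        bounds=[_LOG_MU_BOUNDS, _LOG_THETA_BOUNDS],
    )
    mu_hat, theta_hat = np.exp(res.x)
    return ZTNegBinFit(
        mu_hat=float(mu_hat),
        theta_hat=float(theta_hat),
        loglik=-float(res.fun),
        converged=bool(res.success),
        at_boundary=bool(theta_hat >= THETA_BOUNDARY),
    )


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

INTERPRETATION = (
    "a higher level of theta corresponds to a variance closer to the Poisson "
    "distribution and reduced consistency of splicing"
)


class EventSharingModel:
    """Model of within-group event-sharing counts.

    Wraps one group's sharing histogram and fits the zero-truncated Poisson
    (random splicing) and negative-binomial (observed splicing) models.

    Parameters
    ----------
    multiplicities
        Sharing counts k >= 1, one per distinct event, or a
        :class:`SharingHistogram`.
    group_size
        Number of samples in the group (n); inferred from a histogram.
    label, direction
        Carried through to results and the summary table.
    """

    def __init__(
        self,
        multiplicities,
        group_size: int | None = None,
        label: str = "",
        direction: str = "",
    ) -> None:
        if isinstance(multiplicities, SharingHistogram):
            self.histogram = multiplicities
        else:
            arr = np.asarray(multiplicities, dtype=int)
            if group_size is None:
                group_size = int(arr.max())
            counts: dict[int, int] = {}
            for k in arr:
                counts[int(k)] = counts.get(int(k), 0) + 1
            self.histogram = SharingHistogram(
                group=label, direction=direction, n=group_size, counts=counts
            )
        self.label = label or self.histogram.group
        self.direction = direction or self.histogram.direction

    @classmethod
    def from_callsets(
        cls, callsets: list[EventCallSet], direction: str, label: str = ""
    ) -> "EventSharingModel":
        return cls(sharing_histogram(callsets, direction, group=label))

    def fit(
        self,
        bootstrap: int = 1000,
        seed: int | None = None,
        ci_errors: str = "raise",
    ) -> "EventSharingResults":
        """Fit both truncated models and bootstrap a 95% CI for theta.

        ``ci_errors="nan"`` keeps the point estimates and reports a NaN CI
        when the histogram is too small for a stable bootstrap (the report
        then flags the comparison as indeterminate); ``"raise"`` propagates
        the error.
        """
        hist = self.histogram
        poisson = fit_zt_poisson(hist)
        negbin = fit_zt_negbin(hist)
        theta_ci = (float("nan"), float("nan"))
        boundary_fraction = float("nan")
        if bootstrap and bootstrap > 0:
            try:
                lo, hi, bf = bootstrap_theta_ci(hist, B=bootstrap, seed=seed)
                theta_ci = (lo, hi)
                boundary_fraction = bf
            except (ValidationError, ConvergenceError):
                if ci_errors != "nan":
                    raise
        return EventSharingResults(
            model=self,
            poisson=poisson,
            negbin=negbin,
            theta_ci=theta_ci,
            boundary_fraction=boundary_fraction,
        )


@dataclass
class EventSharingResults:
    """Fitted consistency statistics for one group and direction."""

    model: EventSharingModel
    poisson: ZTPoissonFit
    negbin: ZTNegBinFit
    theta_ci: tuple[float, float]
    boundary_fraction: float
    note: str = ""

    @property
    def theta(self) -> float:
        return self.negbin.theta_hat

    @property
    def mu(self) -> float:
        return self.negbin.mu_hat

    @property
    def mean_splicing_rate(self) -> float:
        """The x-axis of the theta plots: the fitted NB mean."""
        return self.negbin.mu_hat

    @property
    def interpretation(self) -> str:
        note = INTERPRETATION
        if self.negbin.at_boundary:
            note += "; theta at upper bound: Poisson-consistent (no overdispersion)"
        return note

    def summary(self) -> str:
        h = self.model.histogram
        lines = [
            "Event-sharing consistency fit",
            "=" * 64,
            f"group: {self.model.label or '-'}    direction: {self.model.direction or '-'}",
            f"samples (n): {h.n}    events (E): {h.total_events}    mean k: {h.mean():.4f}",
            "-" * 64,
            f"ZT-Poisson   lambda = {self.poisson.lambda_hat:10.4f}   "
            f"loglik = {self.poisson.loglik:12.4f}",
            f"ZT-NegBin    mu     = {self.negbin.mu_hat:10.4f}   "
            f"loglik = {self.negbin.loglik:12.4f}",
            f"             theta  = {self.negbin.theta_hat:10.4g}   "
            f"95% CI = ({self.theta_ci[0]:.4g}, {self.theta_ci[1]:.4g})",
            f"             untruncated variance mu + mu^2/theta = "
            f"{self.negbin.untruncated_variance:.4f}",
            "-" * 64,
            f"note: {self.interpretation}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        h = self.model.histogram
        return {
            "group": self.model.label,
            "direction": self.model.direction,
            "n": h.n,
            "E": h.total_events,
            "c_k": {str(k): int(v) for k, v in sorted(h.counts.items())},
            "lambda_hat": self.poisson.lambda_hat,
            "poisson_loglik": self.poisson.loglik,
            "mu_hat": self.negbin.mu_hat,
            "theta_hat": self.negbin.theta_hat,
            "negbin_loglik": self.negbin.loglik,
            "theta_ci": list(self.theta_ci),
            "boundary_fraction": self.boundary_fraction,
            "at_boundary": self.negbin.at_boundary,
            "note": self.note,
        }


@dataclass
class ConsistencyResult:
    """One group/direction result plus the shared interpretation note."""

    group: str
    direction: str
    results: EventSharingResults

    @property
    def theta(self) -> float:
        return self.results.theta


def consistency_report(
    groups: list[tuple[str, list[EventCallSet]]],
    directions: tuple[str, ...] = DIRECTIONS,
    bootstrap: int = 1000,
    seed: int | None = None,
) -> tuple[list[ConsistencyResult], pd.DataFrame]:
    """Fit every (group, direction) and compare thetas pairwise.

    Groups are fitted independently (no size matching).  A pair is flagged
    'reduced consistency' for the higher-theta group when the bootstrap CIs
    are disjoint, 'indeterminate' otherwise.  A group/direction whose
    histogram admits no interior fit (all counts 1, or too few events) is
    reported with NaN estimates and an explanatory note instead of aborting
    the remaining groups.
    """
    rng = np.random.default_rng(seed)
    results: list[ConsistencyResult] = []
    for direction in directions:
        for label, callsets in groups:
            model = EventSharingModel.from_callsets(callsets, direction, label=label)
            fit_seed = int(rng.integers(2**31 - 1))
            try:
                res = model.fit(bootstrap=bootstrap, seed=fit_seed, ci_errors="nan")
            except (BoundaryError, DegenerateDataError, ValidationError) as err:
                nan = float("nan")
                res = EventSharingResults(
                    model=model,
                    poisson=ZTPoissonFit(nan, nan, False),
                    negbin=ZTNegBinFit(nan, nan, nan, False, False),
                    theta_ci=(nan, nan),
                    boundary_fraction=nan,
                    note=f"no fit: {err}",
                )
            results.append(ConsistencyResult(label, direction, res))

    rows = []
    for direction in directions:
        sub = [r for r in results if r.direction == direction]
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                a, b = sub[i], sub[j]
                ci_a, ci_b = a.results.theta_ci, b.results.theta_ci
                disjoint = ci_a[1] < ci_b[0] or ci_b[1] < ci_a[0]
                if disjoint:
                    worse = a.group if a.theta > b.theta else b.group
                    verdict = f"reduced consistency in {worse}"
                else:
                    verdict = "indeterminate"
                rows.append(
                    {
                        "direction": direction,
                        "group_a": a.group,
                        "group_b": b.group,
                        "theta_a": a.theta,
                        "theta_b": b.theta,
                        "verdict": verdict,
                    }
                )
    return results, pd.DataFrame(rows)
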