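"""Synthetic exon-array data with known splice-event ground truth.

The generator emulates the structure of Affymetrix Human Exon 1.0 ST-style
data: transcripts composed of exons, each exon interrogated by a few probes,
samples partitioned into groups.  Log2 intensity is additive —

    log2 y_pj = b_t + a_p + c_j + delta * 1[event on (exon, sample)] + eps

with transcript baselines ``b_t``, probe affinities ``a_p``, chip effects
``c_j`` and Gaussian noise ``eps``.  Two kinds of splice events are injected:

* *consistent* events target a group-specific (transcript, exon, direction);
  each sample of the group carries the event independently with probability
  ``p_share``, so within-group sharing is Binomial(n, p_share) — the
  overdispersed signal the consistency statistic must detect;
* *random* events are placed uniformly over (exon, sample) pairs.

``simulate_sharing_counts`` separately draws event-sharing counts directly
from a zero-truncated negative binomial, for estimator tests that need clean
model data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .firma import ProbeIntensityMatrix
from .ztrunc import ztnb_rvs

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_exon_array",
    "simulate_sharing_counts",
]

INCLUSION = "inclusion"
EXCLUSION = "exclusion"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic exon-array generator.

    ``exons_per_transcript`` and ``probes_per_exon`` may be a single count or
    an inclusive (low, high) range sampled per transcript/exon.
    ``effect_size_delta`` is the magnitude of the log2 shift applied to every
    probe of an affected exon; the event's direction sets the sign.
    ``seed`` is mandatory: the generator never touches global RNG state.
    """

    n_transcripts: int
    exons_per_transcript: int | tuple[int, int]
    probes_per_exon: int | tuple[int, int]
    groups: list[tuple[str, int]]
    seed: int
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    probe_affinity_sd: float = 1.0
    chip_effect_sd: float = 0.3
    noise_sd: float = 0.25
    n_consistent_events_per_group: int = 0
    p_share: float = 0.8
    n_random_events: int = 0
    effect_size_delta: float = 1.5
    #: restrict consistent-event injection to these group labels
    #: (None = every group); lets one dataset contrast a consistently
    #: splicing group against a purely random one
    consistent_event_groups: list[str] | None = None

    def __post_init__(self) -> None:
        def _check_count(name: str, value, minimum=0) -> None:
            if isinstance(value, tuple):
                if len(value) != 2 or value[0] > value[1] or value[0] < max(1, minimum):
                    raise ValidationError(f"{name}: invalid range {value!r}")
            elif not isinstance(value, (int, np.integer)) or value < minimum:
                raise ValidationError(f"{name}: must be a count >= {minimum}, got {value!r}")

        _check_count("n_transcripts", self.n_transcripts, minimum=1)
        _check_count("exons_per_transcript", self.exons_per_transcript, minimum=1)
        _check_count("probes_per_exon", self.probes_per_exon, minimum=1)
        _check_count("n_consistent_events_per_group", self.n_consistent_events_per_group)
        _check_count("n_random_events", self.n_random_events)
        for name in ("baseline_log2_sd", "probe_affinity_sd", "chip_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name}: standard deviation must be >= 0")
        if not 0.0 <= self.p_share <= 1.0:
            raise ValidationError(f"p_share: must lie in [0, 1], got {self.p_share!r}")
        if not self.groups:
            raise ValidationError("groups: at least one group required")
        labels = [g[0] for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValidationError("groups: labels must be unique")
        if any(n < 1 for _, n in self.groups):
            raise ValidationError("groups: each group needs >= 1 sample")
        if sum(n for _, n in self.groups) < 2:
            raise ValidationError("groups: total samples must be >= 2")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed: an integer seed is required")
        if self.consistent_event_groups is not None:
            unknown = set(self.consistent_event_groups) - {g[0] for g in self.groups}
            if unknown:
                raise ValidationError(
                    f"consistent_event_groups: unknown labels {sorted(unknown)!r}"
                )


@dataclass
class GroundTruth:
    """Injected events: one row per (transcript, exon, sample) incidence.

    Columns: transcript_id, exon_id, sample_id, direction
    ({'inclusion', 'exclusion'}), origin ({'consistent', 'random'}).
    """

    events: pd.DataFrame

    def group_multiplicities(
        self, sample_groups: pd.Series, group: str, direction: str
    ) -> pd.Series:
        """Sharing count of each distinct event within one group."""
        samples = sample_groups.index[sample_groups == group]
        sub = self.events[
            self.events["sample_id"].isin(samples)
            & (self.events["direction"] == direction)
        ]
        return sub.groupby(["transcript_id", "exon_id"]).size()


def _draw_counts(rng: np.random.Generator, spec: int | tuple[int, int], size: int) -> np.ndarray:
    if isinstance(spec, tuple):
        return rng.integers(spec[0], spec[1] + 1, size=size)
    return np.full(size, spec, dtype=int)


def simulate_exon_array(
    config: SimulationConfig,
) -> tuple[ProbeIntensityMatrix, GroundTruth]:
    """Generate a probe-level intensity matrix and its event ground truth.

    Deterministic given (config, seed); linear-scale output is strictly
    positive by construction (2**x).
    """
    rng = np.random.default_rng(config.seed)

    n_exons = _draw_counts(rng, config.exons_per_transcript, config.n_transcripts)
    transcript_ids = [f"t{i + 1:04d}" for i in range(config.n_transcripts)]

    probe_rows: list[tuple[str, str, str]] = []  # (probe, transcript, exon)
    exon_index: list[tuple[str, str]] = []  # (transcript, exon)
    for t_id, ne in zip(transcript_ids, n_exons):
        n_probes = _draw_counts(rng, config.probes_per_exon, ne)
        for e in range(ne):
            e_id = f"{t_id}_e{e + 1:02d}"
            exon_index.append((t_id, e_id))
            for p in range(n_probes[e]):
                probe_rows.append((f"{e_id}_p{p + 1}", t_id, e_id))

    annotation = pd.DataFrame(
        probe_rows, columns=["probe_id", "transcript_id", "exon_id"]
    ).set_index("probe_id")

    sample_ids: list[str] = []
    sample_group: list[str] = []
    for label, n in config.groups:
        for i in range(n):
            sample_ids.append(f"{label}_{i + 1:02d}")
            sample_group.append(label)
    groups = pd.Series(sample_group, index=pd.Index(sample_ids, name="sample_id"), name="group")

    n_probes_total = len(probe_rows)
    n_samples = len(sample_ids)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_transcripts)
    b_t = dict(zip(transcript_ids, baseline))
    a_p = rng.normal(0.0, config.probe_affinity_sd, n_probes_total)
    c_j = rng.normal(0.0, config.chip_effect_sd, n_samples)

    log2y = (
        np.array([b_t[t] for _, t, _ in probe_rows])[:, None]
        + a_p[:, None]
        + c_j[None, :]
        + rng.normal(0.0, config.noise_sd, (n_probes_total, n_samples))
    )

    # --- event injection ------------------------------------------------
    exon_pos = {te: i for i, te in enumerate(exon_index)}
    sample_pos = {s: j for j, s in enumerate(sample_ids)}
    delta = np.zeros((len(exon_index), n_samples))
    occupied: set[tuple[int, int]] = set()
    records: list[tuple[str, str, str, str, str]] = []

    def _place(te: tuple[str, str], sample: str, direction: str, origin: str) -> None:
        i, j = exon_pos[te], sample_pos[sample]
        if (i, j) in occupied:
            return  # an (exon, sample) pair carries at most one direction
        occupied.add((i, j))
        sign = 1.0 if direction == INCLUSION else -1.0
        delta[i, j] = sign * abs(config.effect_size_delta)
        records.append((te[0], te[1], sample, direction, origin))

    for label, _ in config.groups:
        if config.n_consistent_events_per_group == 0:
            continue
        if (
            config.consistent_event_groups is not None
            and label not in config.consistent_event_groups
        ):
            continue
        if config.n_consistent_events_per_group > len(exon_index):
            raise ValidationError(
                "n_consistent_events_per_group exceeds the number of exons"
            )
        targets = rng.choice(
            len(exon_index), size=config.n_consistent_events_per_group, replace=False
        )
        members = [s for s, g in zip(sample_ids, sample_group) if g == label]
        for idx in targets:
            direction = INCLUSION if rng.random() < 0.5 else EXCLUSION
            carried = rng.random(len(members)) < config.p_share
            for s, hit in zip(members, carried):
                if hit:
                    _place(exon_index[idx], s, direction, "consistent")

    if config.n_random_events:
        total_cells = len(exon_index) * n_samples
        free = [k for k in range(total_cells) if divmod(k, n_samples) not in occupied]
        if config.n_random_events > len(free):
            raise ValidationError("n_random_events exceeds available (exon, sample) pairs")
        chosen = rng.choice(len(free), size=config.n_random_events, replace=False)
        for k in chosen:
            i, j = divmod(free[k], n_samples)
            direction = INCLUSION if rng.random() < 0.5 else EXCLUSION
            _place(exon_index[i], sample_ids[j], direction, "random")

    # map exon-level deltas down to probes
    exon_of_probe = np.array([exon_pos[(t, e)] for _, t, e in probe_rows])
    log2y += delta[exon_of_probe, :]

    values = pd.DataFrame(
        np.exp2(log2y),
        index=pd.Index([p for p, _, _ in probe_rows], name="probe_id"),
        columns=pd.Index(sample_ids, name="sample_id"),
    )
    truth = GroundTruth(
        pd.DataFrame(
            records,
            columns=["transcript_id", "exon_id", "sample_id", "direction", "origin"],
        )
    )
    matrix = ProbeIntensityMatrix(values, annotation)
    matrix.sample_groups = groups  # type: ignore[attr-defined]
    return matrix, truth


def simulate_sharing_counts(
    mu: float,
    theta: float,
    n_events: int,
    group_size: int,
    cap_at_group_size: bool = False,
    seed: int | None = None,
) -> np.ndarray:
    """Draw event-sharing counts from a zero-truncated NB(mu, theta).

    Zeros are resampled (events unseen in a group are unobservable); with
    ``cap_at_group_size`` draws above the group size n are clamped to n,
    emulating the hard cap a real sharing histogram has.
    """
    if mu <= 0 or theta <= 0:
        raise ValidationError("mu and theta must be > 0")
    if n_events < 1:
        raise ValidationError("n_events must be >= 1")
    if group_size < 2:
        raise ValidationError("group_size must be >= 2")
    rng = np.random.default_rng(seed)
    draws = ztnb_rvs(mu, theta, n_events, rng)
    if cap_at_group_size:
        draws = np.minimum(draws, group_size)
    return draws
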