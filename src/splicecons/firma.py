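"""FIRMA scoring of exon-array probe intensities.

The pipeline is the classic robust multichip workflow: quantile-normalize the
probe-by-sample intensity matrix, log2-transform, fit each transcript an
additive model ``y_pj = m + a_p + c_j + r_pj`` by median polish, and score
each exon in each sample by the median probe residual divided by a robust
scale of the transcript's residuals.  Large positive scores mean the exon is
expressed above its transcript model (inclusion side); large negative scores
mean below (skipping side).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "ProbeIntensityMatrix",
    "TranscriptModelFit",
    "FirmaScoreMatrix",
    "quantile_normalize",
    "median_polish",
    "firma_scores",
    "fit_all_transcripts",
]

logger = logging.getLogger(__name__)

#: floor on the robust residual scale; prevents 0/0 on exactly additive data
SCALE_FLOOR = 1e-8

#: MAD-to-sigma consistency factor for Gaussian residuals
MAD_FACTOR = 1.4826


@dataclass
class ProbeIntensityMatrix:
    """Probe-by-sample intensities plus probe -> (transcript, exon) annotation.

    Parameters
    ----------
    values
        DataFrame indexed by probe_id with one column per sample.  Linear
        scale (strictly positive) unless ``log2_scale`` is True.
    annotation
        DataFrame indexed by probe_id with columns ``transcript_id`` and
        ``exon_id``; every probe of ``values`` must be annotated and every
        exon must map to exactly one transcript.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame
    log2_scale: bool = False

    def __post_init__(self) -> None:
        self.values.index.name = "probe_id"
        self.values.columns.name = "sample_id"
        self.annotation.index.name = "probe_id"
        if self.values.isna().any().any():
            raise ValidationError("intensity matrix contains missing values")
        missing = self.values.index.difference(self.annotation.index)
        if len(missing):
            raise ValidationError(
                f"unannotated probes: {list(missing[:5])!r}"
            )
        for col in ("transcript_id", "exon_id"):
            if col not in self.annotation.columns:
                raise ValidationError(f"annotation lacks column {col!r}")
        ann = self.annotation.loc[self.values.index]
        n_parents = ann.groupby("exon_id")["transcript_id"].nunique()
        multi = n_parents[n_parents > 1]
        if len(multi):
            raise ValidationError(
                f"exons mapping to several transcripts: {list(multi.index[:5])!r}"
            )
        if not self.log2_scale:
            vals = self.values.to_numpy()
            if np.any(vals <= 0):
                i, j = np.argwhere(vals <= 0)[0]
                raise ValidationError(
                    "non-positive intensity at probe "
                    f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
                )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class TranscriptModelFit:
    """Additive model fit for one transcript (all quantities in log2 units)."""

    transcript_id: str
    overall: float
    probe_effects: pd.Series
    chip_effects: pd.Series
    residuals: pd.DataFrame
    scale: float

    def reconstruct(self) -> pd.DataFrame:
        """m + a_p + c_j + r_pj, which must reproduce the fitted input."""
        return (
            self.overall
            + self.probe_effects.to_numpy()[:, None]
            + self.chip_effects.to_numpy()[None, :]
            + self.residuals
        )


@dataclass
class FirmaScoreMatrix:
    """Exon-by-sample FIRMA scores (log2-residual units).

    ``scores`` is indexed by a (transcript_id, exon_id) MultiIndex with one
    column per sample.
    """

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        self.scores.columns.name = "sample_id"
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValidationError("FIRMA scores must be finite")

    @property
    def exon_ids(self) -> pd.Index:
        return self.scores.index.get_level_values("exon_id")

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.columns

    def pooled(self) -> np.ndarray:
        """All exon-by-sample scores as a flat array (threshold input)."""
        return self.scores.to_numpy().ravel()


def quantile_normalize(matrix: ProbeIntensityMatrix) -> ProbeIntensityMatrix:
    """Quantile-normalize across samples and return log2-scale intensities.

    Every output column has the identical sorted value multiset: the mean
    quantile profile of the log2 inputs.  Ties within a column are mapped to
    the average of the profile values at their tied ranks (rank-average
    convention), so the operation is permutation-equivariant.
    """
    if matrix.log2_scale:
        raise ValidationError("expected a linear-scale matrix")
    log_vals = np.log2(matrix.values.to_numpy())
    n, m = log_vals.shape
    order = np.argsort(log_vals, axis=0, kind="stable")
    profile = np.take_along_axis(log_vals, order, axis=0).mean(axis=1)
    out = np.empty_like(log_vals)
    for j in range(m):
        col = log_vals[:, j]
        # rank-average tie handling: interpolate the profile at average ranks
        ranks = pd.Series(col).rank(method="average").to_numpy()
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), profile)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ProbeIntensityMatrix(values, matrix.annotation, log2_scale=True)


def median_polish(
    Y: np.ndarray, tol: float = 1e-6, max_iter: int = 20
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a 2-D array.

    Alternately sweeps out column medians (chip effects) and row medians
    (probe effects), absorbing the median of each effect vector into the
    overall term, until the total absolute residual changes by at most
    ``tol`` or ``max_iter`` sweeps have run.  Columns are swept first so that
    a constant added to one column is absorbed exactly by its column effect
    on the first sweep, leaving residuals bit-identical (chip-shift
    invariance); see the methods note.

    Returns ``(overall, row_effects, col_effects, residuals)`` with the exact
    decomposition ``Y = overall + row + col + residuals``.
    """
    z = np.array(Y, dtype=float)
    if z.ndim != 2 or z.size == 0:
        raise ValidationError("median_polish requires a non-empty 2-D matrix")
    if not np.all(np.isfinite(z)):
        raise ValidationError("median_polish requires finite values")
    n_rows, n_cols = z.shape
    overall = 0.0
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    old_sum = 0.0
    for _ in range(max_iter):
        col_delta = np.median(z, axis=0)
        z -= col_delta[None, :]
        col_eff += col_delta
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta

        row_delta = np.median(z, axis=1)
        z -= row_delta[:, None]
        row_eff += row_delta
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta

        new_sum = float(np.abs(z).sum())
        if abs(new_sum - old_sum) <= tol:
            break
        old_sum = new_sum
    return overall, row_eff, col_eff, z


def firma_scores(
    fit: TranscriptModelFit, exon_map: dict[str, list[str]]
) -> pd.DataFrame:
    """FIRMA scores for one transcript's exons.

    For exon e and sample j the score is the median over the exon's probes of
    the model residual ``r_pj``, divided by the transcript's robust residual
    scale (MAD x 1.4826 over all residuals, floored at ``SCALE_FLOOR``).
    """
    rows = {}
    for exon_id, probes in exon_map.items():
        missing = [p for p in probes if p not in fit.residuals.index]
        if missing:
            raise ValidationError(
                f"exon {exon_id!r}: probes {missing!r} absent from fit "
                f"of transcript {fit.transcript_id!r}"
            )
        rows[exon_id] = fit.residuals.loc[probes].median(axis=0) / fit.scale
    out = pd.DataFrame(rows).T
    out.index = pd.MultiIndex.from_product(
        [[fit.transcript_id], out.index], names=["transcript_id", "exon_id"]
    )
    return out


def fit_all_transcripts(
    norm: ProbeIntensityMatrix, tol: float = 1e-6, max_iter: int = 20
) -> tuple[list[TranscriptModelFit], FirmaScoreMatrix]:
    """Fit every transcript independently and assemble the score matrix.

    Transcripts are processed in sorted id order, each over its own probes
    only, so the result is invariant to input row order.  Transcripts with
    no probes are skipped with a warning.
    """
    if not norm.log2_scale:
        raise ValidationError("fit_all_transcripts expects normalized log2 data")
    ann = norm.annotation.loc[norm.values.index]
    vals = norm.values.to_numpy()
    probe_index = norm.values.index
    samples = norm.values.columns
    transcripts = ann["transcript_id"].to_numpy()
    exons = ann["exon_id"].to_numpy()

    fits: list[TranscriptModelFit] = []
    score_rows: list[np.ndarray] = []
    score_index: list[tuple[str, str]] = []
    # positional grouping keeps everything in numpy; sorted ids for
    # order-invariance of the assembled result
    codes, uniques = pd.factorize(transcripts, sort=True)
    order = np.argsort(codes, kind="stable")
    boundaries = np.searchsorted(codes[order], np.arange(len(uniques) + 1))
    for u, transcript_id in enumerate(uniques):
        pos = order[boundaries[u] : boundaries[u + 1]]
        transcript_id = str(transcript_id)
        if pos.size == 0:  # pragma: no cover - defensive
            logger.warning("transcript %s has no probes; skipped", transcript_id)
            continue
        Y = vals[pos]
        overall, row_eff, col_eff, resid = median_polish(Y, tol=tol, max_iter=max_iter)
        flat = resid.ravel()
        scale = max(
            MAD_FACTOR * float(np.median(np.abs(flat - np.median(flat)))), SCALE_FLOOR
        )
        fits.append(
            TranscriptModelFit(
                transcript_id=transcript_id,
                overall=overall,
                probe_effects=pd.Series(row_eff, index=probe_index[pos]),
                chip_effects=pd.Series(col_eff, index=samples),
                residuals=pd.DataFrame(resid, index=probe_index[pos], columns=samples),
                scale=scale,
            )
        )
        t_exons = exons[pos]
        for exon_id in sorted(set(t_exons)):
            rows = resid[t_exons == exon_id]
            score_rows.append(np.median(rows, axis=0) / scale)
            score_index.append((transcript_id, str(exon_id)))
    if not score_rows:
        raise ValidationError("no transcripts to fit")
    scores = pd.DataFrame(
        np.vstack(score_rows),
        index=pd.MultiIndex.from_tuples(
            score_index, names=["transcript_id", "exon_id"]
        ),
        columns=samples,
    )
    return fits, FirmaScoreMatrix(scores)
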