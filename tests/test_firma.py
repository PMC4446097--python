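"""FIRMA core: quantile normalization, median polish, exon scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from splicecons import (
    ProbeIntensityMatrix,
    ValidationError,
    fit_all_transcripts,
    firma_scores,
    median_polish,
    quantile_normalize,
)
from splicecons.firma import MAD_FACTOR, SCALE_FLOOR


# ---------------------------------------------------------------------------
# reference implementations (independent oracles)
# ---------------------------------------------------------------------------

def reference_median_polish(Y, tol=1e-6, max_iter=20):
    """Naive loop-based median polish, columns first, same conventions."""
    z = [[float(v) for v in row] for row in Y]
    nr, nc = len(z), len(z[0])
    overall, row_eff, col_eff = 0.0, [0.0] * nr, [0.0] * nc
    med = lambda xs: float(np.median(xs))
    old = 0.0
    for _ in range(max_iter):
        for j in range(nc):
            d = med([z[i][j] for i in range(nr)])
            for i in range(nr):
                z[i][j] -= d
            col_eff[j] += d
        d = med(row_eff)
        row_eff = [r - d for r in row_eff]
        overall += d
        for i in range(nr):
            d = med(z[i])
            for j in range(nc):
                z[i][j] -= d
            row_eff[i] += d
        d = med(col_eff)
        col_eff = [c - d for c in col_eff]
        overall += d
        new = sum(abs(v) for row in z for v in row)
        if abs(new - old) <= tol:
            break
        old = new
    return overall, np.array(row_eff), np.array(col_eff), np.array(z)


def reference_quantile_normalize(log_vals):
    """Brute-force: sort, average, map back by rank (ties -> rank average)."""
    n, m = log_vals.shape
    profile = np.sort(log_vals, axis=0).mean(axis=1)
    out = np.empty_like(log_vals)
    for j in range(m):
        col = log_vals[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty(n)
        i = 0
        sorted_col = col[order]
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            avg_rank = (i + k) / 2.0
            lo, hi = int(np.floor(avg_rank)), int(np.ceil(avg_rank))
            val = 0.5 * (profile[lo] + profile[hi])
            for idx in order[i : k + 1]:
                out[idx, j] = val
            i = k + 1
    return out


def _matrix_from_values(vals, probes_per_exon=2):
    n = vals.shape[0]
    probe_ids = [f"p{i}" for i in range(n)]
    ann = pd.DataFrame(
        {
            "transcript_id": ["t1"] * n,
            "exon_id": [f"e{i // probes_per_exon}" for i in range(n)],
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    values = pd.DataFrame(
        vals, index=probe_ids, columns=[f"s{j}" for j in range(vals.shape[1])]
    )
    return ProbeIntensityMatrix(values, ann)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def test_quantile_normalize_symmetric_hand_case():
    m = _matrix_from_values(np.array([[4.0, 16.0], [16.0, 4.0]]))
    out = quantile_normalize(m)
    assert out.log2_scale
    np.testing.assert_allclose(out.values.to_numpy(), [[2.0, 4.0], [4.0, 2.0]])


def test_quantile_normalize_equalizes_column_multisets(rng):
    m = _matrix_from_values(rng.lognormal(3, 1, (30, 5)))
    out = quantile_normalize(m).values.to_numpy()
    ref = np.sort(out[:, 0])
    for j in range(1, 5):
        np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)


def test_quantile_normalize_matches_bruteforce_oracle(rng):
    vals = rng.lognormal(3, 1, (50, 6))
    vals[3, :] = vals[7, :]  # inject ties within columns
    m = _matrix_from_values(vals)
    out = quantile_normalize(m).values.to_numpy()
    expect = reference_quantile_normalize(np.log2(vals))
    np.testing.assert_allclose(out, expect, atol=1e-12)


def test_quantile_normalize_rejects_nonpositive():
    with pytest.raises(ValidationError):
        _matrix_from_values(np.array([[1.0, -2.0], [3.0, 4.0]]))


# ---------------------------------------------------------------------------
# median polish
# ---------------------------------------------------------------------------

def test_median_polish_additive_matrix_zero_residuals():
    Y = np.array([[1.0, 2.0], [3.0, 4.0]])
    overall, r, c, resid = median_polish(Y)
    np.testing.assert_allclose(resid, 0.0, atol=1e-12)
    np.testing.assert_allclose(
        overall + r[:, None] + c[None, :] + resid, Y, atol=1e-12
    )


def test_median_polish_single_row_absorbed_by_columns():
    _, _, _, resid = median_polish(np.array([[5.0, 7.0, 9.0]]))
    np.testing.assert_allclose(resid, 0.0, atol=1e-12)


def test_median_polish_outlier_cell_recovered():
    rng = np.random.default_rng(0)
    r = rng.normal(0, 1, 4)
    c = rng.normal(0, 1, 4)
    Y = 3.0 + r[:, None] + c[None, :]
    Y[1, 2] += 5.0
    _, _, _, resid = median_polish(Y)
    assert resid[1, 2] == pytest.approx(5.0, abs=0.5)
    mask = np.ones_like(Y, bool)
    mask[1, 2] = False
    assert np.abs(resid[mask]).max() < 0.5
    # and the full decomposition matches the independent reference run
    ref = reference_median_polish(Y)
    np.testing.assert_allclose(resid, ref[3], atol=1e-9)


def test_median_polish_rejects_empty_and_nonfinite():
    with pytest.raises(ValidationError):
        median_polish(np.empty((0, 3)))
    with pytest.raises(ValidationError):
        median_polish(np.array([[1.0, np.nan]]))


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    arrays(
        float,
        st.tuples(st.integers(1, 8), st.integers(1, 8)),
        elements=st.floats(-50, 50, allow_nan=False),
    )
)
def test_median_polish_reconstruction_identity(Y):
    overall, r, c, resid = median_polish(Y)
    np.testing.assert_allclose(
        overall + r[:, None] + c[None, :] + resid, Y, atol=1e-9
    )


# ---------------------------------------------------------------------------
# FIRMA scores
# ---------------------------------------------------------------------------

def _fit_single_transcript(vals):
    n = vals.shape[0]
    m = _matrix_from_values(np.exp2(vals))
    norm = ProbeIntensityMatrix(
        pd.DataFrame(vals, index=m.values.index, columns=m.values.columns),
        m.annotation,
        log2_scale=True,
    )
    fits, scores = fit_all_transcripts(norm)
    return fits[0], scores


def test_zero_scores_on_exactly_additive_data():
    r = np.arange(8.0)
    c = np.array([0.0, 1.0, -1.0, 2.0])
    fit, scores = _fit_single_transcript(5.0 + r[:, None] + c[None, :])
    assert fit.scale == SCALE_FLOOR
    np.testing.assert_allclose(scores.scores.to_numpy(), 0.0, atol=1e-12)


def test_chip_shift_moves_chip_effect_not_scores():
    rng = np.random.default_rng(3)
    vals = 8 + rng.normal(0, 0.3, (12, 6))
    fit1, scores1 = _fit_single_transcript(vals)
    shifted = vals.copy()
    shifted[:, 2] += 3.0
    fit2, scores2 = _fit_single_transcript(shifted)
    np.testing.assert_allclose(
        scores1.scores.to_numpy(), scores2.scores.to_numpy(), atol=1e-9
    )
    # residuals and probe effects unchanged; the shift lands entirely in the
    # sample terms (overall + chip effect, up to median recentering)
    np.testing.assert_allclose(
        fit1.residuals.to_numpy(), fit2.residuals.to_numpy(), atol=1e-9
    )
    np.testing.assert_allclose(
        fit1.probe_effects.to_numpy(), fit2.probe_effects.to_numpy(), atol=1e-9
    )
    sample_terms1 = fit1.overall + fit1.chip_effects.to_numpy()
    sample_terms2 = fit2.overall + fit2.chip_effects.to_numpy()
    expect = np.zeros(6)
    expect[2] = 3.0
    np.testing.assert_allclose(sample_terms2 - sample_terms1, expect, atol=1e-9)


def test_shifted_exon_score_matches_direct_computation():
    rng = np.random.default_rng(7)
    vals = 8 + rng.normal(0, 0.1, (16, 6))
    vals[0:2, 4] += 2.0  # exon e0 (probes 0-1) up in sample 4
    fit, scores = _fit_single_transcript(vals)
    resid = fit.residuals.to_numpy()
    flat = resid.ravel()
    s = max(MAD_FACTOR * np.median(np.abs(flat - np.median(flat))), SCALE_FLOOR)
    expect = np.median(resid[0:2, :], axis=0) / s
    np.testing.assert_allclose(
        scores.scores.to_numpy()[0], expect, atol=1e-12
    )
    assert scores.scores.to_numpy()[0, 4] > 3.0  # clearly called upward


def test_single_cell_corruption_stays_local():
    """+100 on one probe-sample cell must swamp its own exon's score but
    barely move other exons (median polish leaks only order-statistic gaps)."""
    rng = np.random.default_rng(11)
    vals = 8 + rng.normal(0, 0.25, (16, 8))
    _, scores1 = _fit_single_transcript(vals)
    corrupted = vals.copy()
    corrupted[0, 0] += 100.0
    _, scores2 = _fit_single_transcript(corrupted)
    diff = np.abs(scores1.scores.to_numpy() - scores2.scores.to_numpy())
    assert diff[0, 0] > 50.0
    assert diff[1:, :].max() < 1.0


def test_firma_scores_unknown_exon_probes_raise():
    rng = np.random.default_rng(1)
    fit, _ = _fit_single_transcript(8 + rng.normal(0, 0.2, (8, 4)))
    with pytest.raises(ValidationError):
        firma_scores(fit, {"eX": ["missing_probe"]})


# ---------------------------------------------------------------------------
# multi-transcript assembly
# ---------------------------------------------------------------------------

def _two_transcript_matrix(rng):
    vals = rng.lognormal(5, 1, (16, 5))
    probe_ids = [f"p{i}" for i in range(16)]
    ann = pd.DataFrame(
        {
            "transcript_id": ["t1"] * 8 + ["t2"] * 8,
            "exon_id": [f"t1e{i // 4}" for i in range(8)]
            + [f"t2e{i // 4}" for i in range(8)],
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    values = pd.DataFrame(vals, index=probe_ids, columns=[f"s{j}" for j in range(5)])
    return ProbeIntensityMatrix(values, ann)


def test_transcripts_fit_independently_and_order_invariant(rng):
    m = _two_transcript_matrix(rng)
    norm = quantile_normalize(m)
    fits, scores = fit_all_transcripts(norm)
    assert [f.transcript_id for f in fits] == ["t1", "t2"]
    # row-shuffled input gives identical scores
    perm = rng.permutation(norm.values.index)
    shuffled = ProbeIntensityMatrix(
        norm.values.loc[perm], norm.annotation.loc[perm], log2_scale=True
    )
    _, scores2 = fit_all_transcripts(shuffled)
    pd.testing.assert_frame_equal(scores.scores, scores2.scores)
    # concatenation equals independent single-transcript fits
    for t in ("t1", "t2"):
        probes = norm.annotation.index[norm.annotation["transcript_id"] == t]
        sub = ProbeIntensityMatrix(
            norm.values.loc[probes], norm.annotation.loc[probes], log2_scale=True
        )
        _, sub_scores = fit_all_transcripts(sub)
        pd.testing.assert_frame_equal(
            scores.scores.loc[[t]], sub_scores.scores
        )


def test_sample_permutation_equivariance(rng):
    m = _two_transcript_matrix(rng)
    norm = quantile_normalize(m)
    _, scores = fit_all_transcripts(norm)
    cols = ["s3", "s0", "s4", "s1", "s2"]
    permuted = ProbeIntensityMatrix(
        norm.values[cols], norm.annotation, log2_scale=True
    )
    _, scores2 = fit_all_transcripts(permuted)
    pd.testing.assert_frame_equal(scores.scores[cols], scores2.scores)


def test_reconstruction_identity_on_simulated_data(small_dataset):
    _, matrix, _ = small_dataset
    norm = quantile_normalize(matrix)
    fits, _ = fit_all_transcripts(norm)
    for fit in fits[:10]:
        rec = fit.reconstruct().to_numpy()
        expect = norm.values.loc[fit.residuals.index].to_numpy()
        np.testing.assert_allclose(rec, expect, atol=1e-9)
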