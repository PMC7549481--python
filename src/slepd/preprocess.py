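"""Probe-level preprocessing: background correction, quantile
normalization, and robust summarization to transcript-cluster level.

The summarization fits, per transcript cluster (TC), the additive
two-way model

    log2(y_ps) = mu + probe_p + sample_s + eps

by iteratively reweighted least squares with Huber weights, with probe
effects constrained to sum to zero so that ``mu + sample_s`` is the
sample-level summary.  This mirrors gene-level array pipelines that
estimate sample effects with robust regression rather than median
polish.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, ProbeMatrix, ValidationError

log = logging.getLogger("slepd")

HUBER_K = 1.345  # tuning constant on standardized residuals


def background_correct(
    probes: ProbeMatrix, method: str = "quantile-floor", quantile: float = 1.0,
    epsilon: float = 0.5,
) -> ProbeMatrix:
    """Subtract a per-sample lower-quantile floor from linear intensities.

    ``method='identity'`` returns the input unchanged (synthetic data
    carries no optical background).  The default subtracts each
    sample's ``quantile``-th percentile and clamps at ``epsilon`` so
    intensities stay strictly positive for the log transform.
    """
    if method == "identity":
        return probes
    if method != "quantile-floor":
        raise ValidationError(f"unknown background method {method!r}")
    values = probes.data.to_numpy(dtype=float)
    floors = np.percentile(values, quantile, axis=0)
    corrected = np.maximum(values - floors[None, :], epsilon)
    return ProbeMatrix(
        pd.DataFrame(corrected, index=probes.data.index, columns=probes.data.columns),
        probes.probe_to_tc,
        is_log2=probes.is_log2,
    )


def quantile_normalize(probes: ProbeMatrix) -> ProbeMatrix:
    """Force every sample onto the across-sample mean distribution.

    After normalization each sample's sorted value vector equals the
    mean of the per-sample sorted vectors; within-sample ranks are
    preserved and ties receive the mean of their tied target quantiles.
    """
    values = probes.data.to_numpy(dtype=float)
    n_probes, n_samples = values.shape
    if n_samples < 2:
        raise ValidationError("quantile normalization needs >=2 samples")
    order = np.argsort(values, axis=0, kind="stable")
    reference = np.mean(np.take_along_axis(values, order, axis=0), axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        target = np.empty(n_probes)
        target[order[:, j]] = reference
        # average target quantiles over tied input values
        s = pd.Series(target)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    return ProbeMatrix(
        pd.DataFrame(out, index=probes.data.index, columns=probes.data.columns),
        probes.probe_to_tc,
        is_log2=probes.is_log2,
    )


MAD_FACTOR = 0.6744897501960817  # Phi^{-1}(3/4): MAD → sigma for Gaussians


def _robust_two_way(y: np.ndarray, huber_k: float, max_iter: int, tol: float):
    """Huber IRLS fit of y[p, s] = mu + probe_p + sample_s.

    The weighted normal equations are solved exactly each iteration by
    eliminating the (diagonal) sample block, so the cost per iteration
    is O(n_probes · n_samples).  Probe effects are re-centered to sum
    to zero; the returned per-sample summary is mu + sample_s.  The
    robustness scale is the MAD of the residuals, re-estimated every
    iteration; weights are w = min(1, k·scale/|r|).
    """
    n_probes, n_samples = y.shape
    alpha = np.zeros(n_probes)   # probe effects, sum-to-zero
    s_eff = y.mean(axis=0)       # sample summaries (carry the level)
    w = np.ones_like(y)
    converged = False
    for _ in range(max_iter):
        # exact WLS solve with probe reference coding (last probe dropped)
        D = w.sum(axis=0)                      # per-sample weight totals
        r_s = (w * y).sum(axis=0)
        Bf = w[:-1, :]                         # free-probe × sample weights
        A = Bf.sum(axis=1)
        r_p = (Bf * y[:-1, :]).sum(axis=1)
        BD = Bf / D[None, :]
        schur = np.diag(A) - BD @ Bf.T
        rhs = r_p - BD @ r_s
        a_free = np.linalg.solve(schur, rhs)
        alpha_new = np.concatenate([a_free, [0.0]])
        shift = alpha_new.mean()
        alpha_new -= shift
        s_new = (r_s - w.T @ alpha_new) / D    # includes the level (mu)
        delta = max(np.max(np.abs(alpha_new - alpha)),
                    np.max(np.abs(s_new - s_eff)))
        alpha, s_eff = alpha_new, s_new
        resid = y - alpha[:, None] - s_eff[None, :]
        scale = np.median(np.abs(resid)) / MAD_FACTOR
        if scale <= 0:
            w = np.ones_like(y)
            converged = True
            break
        with np.errstate(divide="ignore"):
            w = np.minimum(1.0, huber_k * scale / np.abs(resid))
        w[resid == 0] = 1.0
        if delta < tol:
            converged = True
            break
    return s_eff, converged


def summarize_to_tc(
    probes: ProbeMatrix,
    huber_k: float = HUBER_K,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> ExpressionMatrix:
    """Summarize log2 probe intensities to one value per TC and sample.

    Expects normalized probe data; a linear-scale matrix is log2
    transformed first.  Single-probe TCs pass through unchanged (logged).
    """
    if probes.data.shape[1] < 2:
        raise ValidationError("summarization needs >=2 samples")
    values = probes.data.to_numpy(dtype=float)
    if not probes.is_log2:
        if (values <= 0).any():
            raise ValidationError("cannot log2-transform non-positive intensities")
        values = np.log2(values)
    probe_pos = {p: i for i, p in enumerate(probes.data.index)}
    groups = probes.tc_groups()
    n_single = 0
    n_nonconv = 0
    out = {}
    for tc in groups:
        idx = [probe_pos[p] for p in groups[tc]]
        block = values[idx, :]
        if block.shape[0] == 1:
            out[tc] = block[0]
            n_single += 1
            continue
        summary, converged = _robust_two_way(block, huber_k, max_iter, tol)
        if not converged:
            n_nonconv += 1
        out[tc] = summary
    if n_single:
        log.info("summarize_to_tc: %d single-probe TC(s) passed through", n_single)
    if n_nonconv:
        log.warning("summarize_to_tc: %d TC fit(s) hit the iteration cap", n_nonconv)
    frame = pd.DataFrame.from_dict(out, orient="index", columns=probes.data.columns)
    frame = frame.loc[list(groups)]  # keep input TC order
    return ExpressionMatrix(frame)


def preprocess_pipeline(
    probes: ProbeMatrix, background: str = "identity", **kwargs
) -> ExpressionMatrix:
    """background correction → quantile normalization → TC summarization."""
    corrected = background_correct(probes, method=background)
    normalized = quantile_normalize(corrected)
    return summarize_to_tc(normalized, **kwargs)
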