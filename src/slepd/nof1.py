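"""Single-subject (N-of-1) signature analysis and trajectory testing.

A patient's baseline expression of a gene signature (e.g. JAK1-activated
genes) is compared with the patient-population mean gene-by-gene; a
Wilcoxon signed-rank test on the per-gene differences classifies the
patient as signature-high, signature-low or neither.  Whether the
high and low strata then diverge in their SLEDAI-2K trajectories is
assessed with a Monte Carlo permutation test that shuffles the baseline
labels while preserving group sizes.

The module also carries the percentile-based STAT1/STAT2 co-elevation
analysis: patients are flagged 'high' per gene when baseline expression
strictly exceeds the healthy-control 95th percentile, and the joint
2×2 table is tested with Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .types import ExpressionMatrix, GeneSignature, SampleMeta, ValidationError

log = logging.getLogger("slepd")

POST_BASELINE_WEEKS = (2, 4, 12, 24)


@dataclass
class SignatureCall:
    """Per-patient baseline signature status."""

    patient_id: str
    signature: str
    status: str  # high | low | neither
    wilcoxon_p: float
    median_delta: float  # log2; patient − population mean over signature genes


@dataclass
class MonteCarloResult:
    """Observed trajectory statistic against its permutation null."""

    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    B: int
    seed: int
    arm: str
    group_means: pd.DataFrame  # week × {high, low} mean SLEDAI-2K change
    n_high: int
    n_low: int


@dataclass
class ContingencyTable2x2:
    """Joint classification counts for two per-gene high/normal flags."""

    n_both_normal: int
    n_a_only: int
    n_b_only: int
    n_both_high: int

    def __post_init__(self) -> None:
        for v in (self.n_both_normal, self.n_a_only, self.n_b_only,
                  self.n_both_high):
            if v < 0 or v != int(v):
                raise ValidationError("contingency counts must be nonnegative ints")

    @property
    def total(self) -> int:
        return (self.n_both_normal + self.n_a_only + self.n_b_only
                + self.n_both_high)


def baseline_matrix(expr: ExpressionMatrix, meta: SampleMeta,
                    group: str | None = None) -> ExpressionMatrix:
    """Week-0 expression with columns renamed to patient ids.

    ``group='healthy'`` selects controls; the default selects SLE
    patients (all arms).
    """
    frame = meta.baseline()
    if group == "healthy":
        frame = frame[frame["group"] == "healthy"]
    else:
        frame = frame[frame["group"] != "healthy"]
    frame = frame[frame["sample_id"].isin(expr.data.columns)]
    sub = expr.data[list(frame["sample_id"])]
    sub.columns = list(frame["patient_id"])
    return ExpressionMatrix(sub)


def call_signature_status(
    expr_baseline: ExpressionMatrix,
    signature: GeneSignature,
    alpha: float = 0.05,
    method: str = "signed_rank",
    leave_one_out: bool = False,
) -> list:
    """Classify each patient as signature-high, -low or neither.

    Per patient, the per-gene differences d_g = x_{patient,g} −
    mean-over-patients(x_{·,g}) over the signature genes feed a
    two-sided Wilcoxon signed-rank test (zero differences dropped).  A
    patient is 'high' when p < alpha with positive median difference,
    'low' when p < alpha with negative median difference, else
    'neither'.  ``method='rank_sum'`` instead compares the patient's
    signature-gene values with the population-mean values as two
    samples (Mann-Whitney U).

    Columns of ``expr_baseline`` are patient ids (see
    :func:`baseline_matrix`).
    """
    present, missing = signature.resolve(expr_baseline.feature_ids)
    if missing:
        log.warning("signature %s: %d gene(s) not in the matrix: %s",
                    signature.name, len(missing), missing[:10])
    if len(present) < 5:
        raise ValidationError(
            f"signature {signature.name!r} resolves to only {len(present)} "
            f"genes; >=5 required"
        )
    block = expr_baseline.data.loc[present]
    pop_mean = block.mean(axis=1)
    n_zero_dropped = 0
    calls = []
    for patient in block.columns:
        if leave_one_out:
            others = block.drop(columns=patient)
            ref = others.mean(axis=1)
        else:
            ref = pop_mean
        d = (block[patient] - ref).to_numpy()
        median_delta = float(np.median(d))
        nonzero = d[d != 0]
        n_zero_dropped += len(d) - len(nonzero)
        if method == "signed_rank":
            if len(nonzero) == 0:
                p = 1.0
            else:
                p = float(stats.wilcoxon(
                    nonzero, alternative="two-sided", method="auto"
                ).pvalue)
        elif method == "rank_sum":
            p = float(stats.mannwhitneyu(
                block[patient].to_numpy(), ref.to_numpy(),
                alternative="two-sided",
            ).pvalue)
        else:
            raise ValidationError(f"unknown method {method!r}")
        if p < alpha and median_delta > 0:
            status = "high"
        elif p < alpha and median_delta < 0:
            status = "low"
        else:
            status = "neither"
        calls.append(SignatureCall(
            patient_id=patient, signature=signature.name, status=status,
            wilcoxon_p=p, median_delta=median_delta,
        ))
    if n_zero_dropped:
        log.info("call_signature_status: dropped %d zero difference(s)",
                 n_zero_dropped)
    return calls


def calls_frame(calls) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])


def _changes_matrix(trajectories, patient_ids, weeks):
    by_pid = {t.patient_id: t.changes_from_baseline() for t in trajectories}
    unknown = [p for p in patient_ids if p not in by_pid]
    if unknown:
        raise ValidationError(f"no trajectory for patient(s) {unknown[:5]}")
    C = np.full((len(patient_ids), len(weeks)), np.nan)
    for i, pid in enumerate(patient_ids):
        ch = by_pid[pid]
        for j, w in enumerate(weeks):
            if w in ch:
                C[i, j] = ch[w]
    return C


def trajectory_permutation_test(
    calls,
    trajectories,
    meta: SampleMeta,
    arm: str,
    B: int = 10_000,
    seed: int = 0,
    direction: str = "high_better",
    weeks=POST_BASELINE_WEEKS,
) -> MonteCarloResult:
    """Monte Carlo test of high-vs-low trajectory separation in one arm.

    The observed statistic is the mean over post-baseline visits of
    (mean SLEDAI-2K change in the signature-low group − mean change in
    the signature-high group); positive values mean the high group
    improved more.  Each of the B iterations shuffles the high/low
    labels among the same patients, preserving group sizes.  The
    one-sided p uses the add-one convention

        p = (1 + #{null >= observed}) / (B + 1),

    so p is always in (0, 1]; ``direction='two_sided'`` compares
    absolute values instead.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    arm_patients = set(
        meta.frame.loc[meta.frame["group"] == arm, "patient_id"]
    )
    labelled = [(c.patient_id, c.status) for c in calls
                if c.status in ("high", "low") and c.patient_id in arm_patients]
    n_high = sum(1 for _, s in labelled if s == "high")
    n_low = len(labelled) - n_high
    if n_high < 2 or n_low < 2:
        raise ValidationError(
            f"arm {arm!r}: need >=2 patients per signature group "
            f"(high={n_high}, low={n_low})"
        )
    pids = sorted(p for p, _ in labelled)  # order-invariant
    status = {p: s for p, s in labelled}
    is_high = np.array([status[p] == "high" for p in pids])
    weeks = tuple(weeks)
    C = _changes_matrix(trajectories, pids, weeks)
    valid = np.isfinite(C)
    Cz = np.where(valid, C, 0.0)

    def group_stat(high_mask):
        A = high_mask.astype(float)
        n_h = A @ valid
        n_l = (1.0 - A) @ valid
        mean_h = (A @ Cz) / n_h
        mean_l = ((1.0 - A) @ Cz) / n_l
        return mean_h, mean_l

    mean_h, mean_l = group_stat(is_high[None, :])
    per_visit_diff = mean_l - mean_h
    observed = float(np.nanmean(per_visit_diff))

    rng = np.random.default_rng(seed)
    keys = rng.random((B, len(pids)))
    order = np.argsort(keys, axis=1)
    perm_high = np.zeros((B, len(pids)), dtype=bool)
    rows = np.repeat(np.arange(B), n_high)
    perm_high[rows, order[:, :n_high].ravel()] = True
    mh, ml = group_stat(perm_high)
    null_stats = np.nanmean(ml - mh, axis=1)

    if direction == "high_better":
        exceed = int(np.sum(null_stats >= observed))
    elif direction == "two_sided":
        exceed = int(np.sum(np.abs(null_stats) >= abs(observed)))
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    p_value = (1.0 + exceed) / (B + 1.0)

    group_means = pd.DataFrame(
        {"high": mean_h[0], "low": mean_l[0]}, index=pd.Index(weeks, name="week")
    )
    return MonteCarloResult(
        observed_stat=observed,
        null_stats=null_stats,
        p_value=float(p_value),
        B=B,
        seed=seed,
        arm=arm,
        group_means=group_means,
        n_high=n_high,
        n_low=n_low,
    )


def loess_group_trajectories(
    calls,
    trajectories,
    span: float = 0.75,
    grid=None,
) -> dict:
    """LOESS-smoothed mean SLEDAI-2K change per signature group.

    Locally weighted linear regression (tricube weights, degree 1) of
    every per-patient change on week, evaluated on a week grid.
    Display only — the permutation statistic never uses these curves.
    """
    if not 0 < span <= 1:
        raise ValidationError("span must be in (0, 1]")
    status = {c.patient_id: c.status for c in calls
              if c.status in ("high", "low")}
    points: dict = {"high": [], "low": []}
    for t in trajectories:
        s = status.get(t.patient_id)
        if s is None:
            continue
        for w, ch in t.changes_from_baseline().items():
            points[s].append((w, ch))
    out = {}
    for group, pts in points.items():
        if not pts:
            continue
        x = np.array([p[0] for p in pts], float)
        y = np.array([p[1] for p in pts], float)
        if len(np.unique(x)) < 3:
            raise ValidationError("LOESS needs >=3 distinct weeks")
        xg = np.asarray(grid, float) if grid is not None else np.unique(x)
        smoothed = lowess(y, x, frac=span, it=0, xvals=xg)
        out[group] = pd.DataFrame({"week": xg, "change": smoothed})
    return out


def percentile_classify(
    expr_baseline_sle: ExpressionMatrix,
    expr_healthy: ExpressionMatrix,
    genes=("STAT1", "STAT2"),
    percentile: float = 95.0,
):
    """Flag patients above the healthy percentile for two genes.

    The per-gene threshold is the empirical ``percentile`` of healthy
    values (linear interpolation between order statistics); a patient
    is 'high' only when strictly above it.  Returns per-patient flags
    and the joint 2×2 table (gene A = first, gene B = second).
    """
    gene_a, gene_b = genes
    for g in genes:
        if g not in expr_baseline_sle.data.index:
            raise ValidationError(f"gene {g!r} absent from the SLE matrix")
        if g not in expr_healthy.data.index:
            raise ValidationError(f"gene {g!r} absent from the healthy matrix")
    n_healthy = expr_healthy.data.shape[1]
    if n_healthy < 20:
        log.warning("percentile_classify: only %d healthy controls; "
                    "threshold unstable below 20", n_healthy)
    thresholds = {
        g: float(np.percentile(
            expr_healthy.data.loc[g].to_numpy(), percentile,
            method="linear",
        ))
        for g in genes
    }
    flags = pd.DataFrame(
        {
            f"{g}_high": expr_baseline_sle.data.loc[g] > thresholds[g]
            for g in genes
        }
    )
    flags.index.name = "patient_id"
    a = flags[f"{gene_a}_high"].to_numpy()
    b = flags[f"{gene_b}_high"].to_numpy()
    table = ContingencyTable2x2(
        n_both_normal=int((~a & ~b).sum()),
        n_a_only=int((a & ~b).sum()),
        n_b_only=int((~a & b).sum()),
        n_both_high=int((a & b).sum()),
    )
    return flags, table, thresholds


def fisher_exact_2x2(table: ContingencyTable2x2):
    """Fisher's exact test of joint high/normal status.

    The sample odds ratio is (both_normal · both_high) / (a_only ·
    b_only), infinite when a denominator count is 0; the two-sided p
    sums hypergeometric probabilities no larger than the observed
    table's.
    """
    a, b = table.n_both_normal, table.n_a_only
    c, d = table.n_b_only, table.n_both_high
    if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
        raise ValidationError("contingency table has an all-zero margin")
    # rows: gene A normal/high; columns: gene B normal/high
    res = stats.fisher_exact([[a, c], [b, d]], alternative="two-sided")
    if b * c == 0:
        odds = np.inf
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(res.pvalue)
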