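"""Simulation studies that validate the pipeline's operating
characteristics on ground-truth synthetic cohorts.

Each function generates its own data at the study's trial-shaped
defaults (90 patients/arm, visits {0, 2, 4, 12, 24}), runs the
corresponding analysis stage, and reports a calibration or recovery
summary.  These are the experiments behind the numbers quoted in the
project documentation; the analysis drivers and the acceptance script
call them directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import differential as diff
from . import nof1
from . import simulate as sim
from .nof1 import GeneSignature, SignatureCall


def _calls_from_status(status: pd.Series) -> list:
    return [
        SignatureCall(patient_id=p, signature="TRUTH", status=s,
                      wilcoxon_p=0.0,
                      median_delta=1.0 if s == "high" else -1.0)
        for p, s in status.items()
    ]


def permutation_null_calibration(
    n_reps: int = 500,
    B: int = 2000,
    alpha: float = 0.05,
    n_patients: int = 90,
    arm: str = "bari4mg",
    seed: int = 0,
) -> dict:
    """Type-I error of the trajectory permutation test under the null.

    One cohort's signature statuses are held fixed; each replicate draws
    fresh SLEDAI-2K trajectories with responder benefit 0 (labels carry
    no information) and runs the one-sided test.  Returns the rejection
    rate at ``alpha`` over ``n_reps`` replicates.
    """
    rng = np.random.default_rng(seed)
    _, meta, truth = sim.simulate_expression(
        n_patients=n_patients, n_genes=2, seed=int(rng.integers(2**31))
    )
    calls = _calls_from_status(truth.patient_status)
    rejections = 0
    for _ in range(n_reps):
        traj = sim.simulate_trajectories(
            meta, truth, responder_benefit=0.0,
            seed=int(rng.integers(2**31)),
        )
        res = nof1.trajectory_permutation_test(
            calls, traj, meta, arm, B=B, seed=int(rng.integers(2**31)),
        )
        rejections += res.p_value <= alpha
    return dict(rejection_rate=rejections / n_reps, rejections=rejections,
                n_reps=n_reps, B=B, alpha=alpha)


def permutation_power_pattern(
    n_reps: int = 100,
    B: int = 2000,
    n_patients: int = 90,
    seed: int = 0,
    arms=("placebo", "bari2mg", "bari4mg"),
) -> dict:
    """Arm-wise power of the trajectory test with the default planted
    benefit (signature-high patients improve under active treatment,
    scaled by dose; placebo carries no benefit).

    Returns the median permutation p per arm over replicates — the
    qualitative pattern is significance on the 4 mg arm and a null
    placebo arm.
    """
    rng = np.random.default_rng(seed)
    _, meta, truth = sim.simulate_expression(
        n_patients=n_patients, n_genes=2, seed=int(rng.integers(2**31))
    )
    calls = _calls_from_status(truth.patient_status)
    ps = {arm: [] for arm in arms}
    for _ in range(n_reps):
        traj = sim.simulate_trajectories(
            meta, truth, seed=int(rng.integers(2**31)),
        )
        for arm in arms:
            res = nof1.trajectory_permutation_test(
                calls, traj, meta, arm, B=B, seed=int(rng.integers(2**31)),
            )
            ps[arm].append(res.p_value)
    return {arm: dict(median_p=float(np.median(v)), n_reps=n_reps)
            for arm, v in ps.items()}


def mmrm_effect_recovery(
    n_planted: int = 200,
    n_null: int = 200,
    n_patients: int = 90,
    pd_effect_log2: float = -0.5,
    arm: str = "bari4mg",
    week: int = 12,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Bias and null calibration of the per-gene MMRM PD contrast.

    Simulates ``n_planted`` genes carrying the full planted effect at
    the target week plus ``n_null`` unaffected genes, fits the MMRM per
    gene, and summarizes the contrast at (arm, week): mean estimate
    over planted genes, and type-I error of the Wald test over null
    genes.
    """
    expr, meta, truth = sim.simulate_expression(
        n_patients=n_patients,
        n_genes=n_planted + n_null,
        n_ifn_genes=n_planted,
        pd_effect_log2=pd_effect_log2,
        seed=seed,
    )
    fits = diff.fit_mmrm(expr, meta)
    table = diff.pd_effects_table(fits, arms=(arm,), weeks=(week,))
    table = table.set_index("feature_id")
    planted = truth.pd_effects.query(
        "arm == @arm and week == @week and effect != 0"
    )["feature_id"]
    nulls = truth.pd_effects.query(
        "arm == @arm and week == @week and effect == 0"
    )["feature_id"]
    est = table.loc[planted, "estimate"]
    null_p = table.loc[nulls, "p"]
    truth_effect = float(truth.pd_effects.query(
        "arm == @arm and week == @week and effect != 0")["effect"].iloc[0])
    return dict(
        mean_estimate=float(est.mean()),
        sd_estimate=float(est.std()),
        truth_effect=truth_effect,
        n_planted=len(est),
        null_type_i=float((null_p < alpha).mean()),
        n_null=len(null_p),
        alpha=alpha,
    )


def signature_recall_study(
    n_patients: int = 30,
    n_genes: int = 20,
    elevation_log2: float = 1.0,
    noise_sd: float = 0.5,
    frac_high: float = 1 / 3,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Recall of planted signature-high patients by the N-of-1 call.

    A minority of patients carries the elevated signature so the
    population-mean reference stays anchored near the unelevated level;
    per-gene noise is the only noise source.  Returns the fraction of
    planted high patients called 'high'.
    """
    expr, meta, truth = sim.simulate_expression(
        n_patients=n_patients, n_genes=n_genes, n_ifn_genes=n_genes,
        elevation_log2=elevation_log2, frac_ifn_high=frac_high,
        noise_sd=noise_sd, patient_sd=0.0, seed=seed,
    )
    base = nof1.baseline_matrix(expr, meta)
    signature = GeneSignature("PLANTED", frozenset(expr.feature_ids))
    calls = nof1.call_signature_status(base, signature, alpha=alpha)
    status = {c.patient_id: c.status for c in calls}
    high = [p for p, s in truth.patient_status.items() if s == "high"]
    recall = float(np.mean([status[p] == "high" for p in high]))
    return dict(recall=recall, n_high=len(high),
                n_patients=len(truth.patient_status))


def stat1_stat2_association(
    counts=(56, 5, 34, 174),
) -> dict:
    """Fisher's exact test of joint STAT1/STAT2 elevation counts
    (both-normal, STAT1-only, STAT2-only, both-high)."""
    table = nof1.ContingencyTable2x2(*counts)
    odds, p = nof1.fisher_exact_2x2(table)
    return dict(odds_ratio=odds, p=p, n=table.total)
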