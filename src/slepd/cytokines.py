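"""Left-censored serum cytokine analysis.

Concentrations below an analyte's lower limit of quantification (LLOQ)
are imputed to 0.5×LLOQ.  Baseline compares SLE with healthy controls
on log concentrations; treatment effects are change-from-baseline log
deltas per arm against placebo, excluding patients undetectable at both
visits.  Rank tests (Mann-Whitney U) are the default because the
imputed log deltas are non-Gaussian; a Welch t option is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import SampleMeta, TREATMENT_ARMS, ValidationError

log = logging.getLogger("slepd")


def impute_lloq(measurements: pd.DataFrame) -> pd.DataFrame:
    """Set censored concentrations to 0.5×LLOQ; detectable rows unchanged.

    Idempotent.  Every row needs a positive LLOQ.
    """
    out = measurements.copy()
    if out["lloq"].isna().any() or (out["lloq"] <= 0).any():
        raise ValidationError("every measurement needs a positive LLOQ")
    censored = out["below_lloq"].astype(bool)
    out.loc[censored, "concentration"] = 0.5 * out.loc[censored, "lloq"]
    return out


def _patient_groups(meta: SampleMeta) -> pd.DataFrame:
    return meta.frame.drop_duplicates("patient_id")[["patient_id", "group"]]


@dataclass
class BaselineCytokineResult:
    analyte: str
    detectable_fraction: dict  # group label -> fraction not censored
    p: float
    degenerate: bool


def baseline_group_compare(
    measurements: pd.DataFrame, meta: SampleMeta, analyte: str,
    test: str = "mannwhitney",
) -> BaselineCytokineResult:
    """Detectable fractions and SLE-vs-healthy test at baseline.

    Censored values enter the test at their imputed 0.5×LLOQ value on
    the log scale.  When every sample in both groups is censored the
    test degenerates and p is reported as 1 with a flag.
    """
    sub = measurements[(measurements["analyte"] == analyte)
                       & (measurements["visit_week"] == 0)]
    if sub.empty:
        raise ValidationError(f"analyte {analyte!r} absent at baseline")
    sub = impute_lloq(sub).merge(_patient_groups(meta), on="patient_id")
    sub["is_sle"] = sub["group"] != "healthy"
    if not sub["is_sle"].any() or sub["is_sle"].all():
        raise ValidationError("need both SLE and healthy baseline samples")
    fractions = (
        (~sub["below_lloq"]).groupby(sub["is_sle"].map(
            {True: "sle", False: "healthy"})).mean().to_dict()
    )
    sle = np.log(sub.loc[sub["is_sle"], "concentration"].to_numpy())
    healthy = np.log(sub.loc[~sub["is_sle"], "concentration"].to_numpy())
    if sub["below_lloq"].all():
        return BaselineCytokineResult(analyte, fractions, 1.0, True)
    if test == "mannwhitney":
        p = float(stats.mannwhitneyu(sle, healthy,
                                     alternative="two-sided").pvalue)
    elif test == "welch":
        p = float(stats.ttest_ind(sle, healthy, equal_var=False).pvalue)
    else:
        raise ValidationError(f"unknown test {test!r}")
    return BaselineCytokineResult(analyte, fractions, p, False)


def delta_vs_placebo(
    measurements: pd.DataFrame,
    meta: SampleMeta,
    analyte: str,
    week: int = 12,
    test: str = "mannwhitney",
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-arm change-from-baseline log deltas against placebo.

    delta = log(concentration at ``week``) − log(concentration at week
    0) after 0.5×LLOQ imputation (natural log; the base cancels in the
    rank test).  Patients censored at BOTH visits are excluded; the
    exclusion count is reported per arm.  Returns one row per treatment
    arm with the median delta, n analyzed, n excluded and the two-sided
    p against placebo (NaN for placebo itself).
    """
    sub = measurements[measurements["analyte"] == analyte]
    if sub.empty:
        raise ValidationError(f"analyte {analyte!r} not measured")
    sub = sub[sub["visit_week"].isin([0, week])]
    sub = impute_lloq(sub).merge(_patient_groups(meta), on="patient_id")
    sub = sub[sub["group"] != "healthy"]

    wide = sub.pivot_table(index=["patient_id", "group"],
                           columns="visit_week",
                           values=["concentration", "below_lloq"],
                           aggfunc="first")
    has_both = wide["concentration"][[0, week]].notna().all(axis=1)
    wide = wide[has_both]
    both_censored = (wide["below_lloq"][0].astype(bool)
                     & wide["below_lloq"][week].astype(bool))
    deltas = (np.log(wide["concentration"][week])
              - np.log(wide["concentration"][0]))
    frame = pd.DataFrame({
        "delta": deltas,
        "excluded": both_censored,
    }).reset_index()

    rows = []
    placebo = frame[(frame["group"] == "placebo") & ~frame["excluded"]]
    if placebo.empty:
        raise ValidationError("no eligible placebo patients")
    for arm in TREATMENT_ARMS:
        arm_frame = frame[frame["group"] == arm]
        kept = arm_frame[~arm_frame["excluded"]]
        if kept.empty:
            raise ValidationError(f"arm {arm!r} has no eligible patients")
        if arm == "placebo":
            p = np.nan
        elif test == "mannwhitney":
            p = float(stats.mannwhitneyu(
                kept["delta"], placebo["delta"], alternative="two-sided"
            ).pvalue)
        elif test == "welch":
            p = float(stats.ttest_ind(
                kept["delta"], placebo["delta"], equal_var=False
            ).pvalue)
        else:
            raise ValidationError(f"unknown test {test!r}")
        rows.append(dict(
            analyte=analyte, arm=arm, week=week,
            median_delta=float(kept["delta"].median()),
            n=len(kept), n_excluded=int(arm_frame["excluded"].sum()), p=p,
        ))
    out = pd.DataFrame(rows)
    if adjust:
        from .differential import bh_qvalues

        mask = out["p"].notna()
        out.loc[mask, "q"] = bh_qvalues(out.loc[mask, "p"].to_numpy())
    return out
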