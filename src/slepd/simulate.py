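"""Trial-shaped synthetic data with known ground truth.

Emulates the statistical structure the downstream analyses assume:

* whole-blood log2 expression with an interferon-responsive gene block
  elevated in a subset of patients (the "IFN-high" stratum, seen in
  roughly half to three-quarters of patients with active SLE),
* three arms (placebo, baricitinib 2 mg, baricitinib 4 mg) with dose-
  and time-dependent reduction of the elevated genes,
* SLEDAI-2K disease-activity trajectories over weeks {0, 2, 4, 12, 24}
  whose treatment response depends on baseline signature status,
* log-normal serum cytokine concentrations left-censored at
  analyte-specific lower limits of quantification.

Every generative mean admits a closed form, and the drawn truth is
recorded in :class:`SimulationTruth` so tests can score recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ClinicalTrajectory,
    ExpressionMatrix,
    ProbeMatrix,
    SampleMeta,
    SLEDAI_MAX,
    TREATMENT_ARMS,
    ValidationError,
    VISIT_WEEKS,
)

POST_BASELINE_WEEKS = (2, 4, 12, 24)
#: Fractional onset of the pharmacodynamic effect by week (full by week 12).
DEFAULT_WEEK_RAMP = {2: 0.5, 4: 0.75, 12: 1.0, 24: 1.0}
#: 2 mg effect as a fraction of the 4 mg effect (graded dose response).
DEFAULT_DOSE_RATIO = {"placebo": 0.0, "bari2mg": 0.5, "bari4mg": 1.0}
#: Clinical benefit (SLEDAI-2K change) for signature-high patients on 4 mg.
DEFAULT_RESPONDER_BENEFIT = {2: -1.0, 4: -2.0, 12: -3.0, 24: -4.0}
#: Background drift shared by every patient (regression to the mean, placebo).
DEFAULT_PLACEBO_DRIFT = {2: -0.5, 4: -1.0, 12: -1.5, 24: -2.0}
#: Serum panel with analyte-specific LLOQs (pg/mL, ultrasensitive assays).
DEFAULT_ANALYTE_LLOQ = {
    "IFN-alpha": 0.02,
    "IFN-gamma": 0.05,
    "IL-6": 0.2,
    "IL-12p40": 1.0,
    "IL-10": 0.1,
    "IL-17A": 0.5,
}
#: Log-scale treatment deltas at weeks >= 12 (4 mg; 2 mg scaled by dose ratio).
DEFAULT_CYTOKINE_ARM_EFFECTS = {
    ("IL-12p40", "bari4mg"): -0.3,
    ("IL-12p40", "bari2mg"): -0.15,
    ("IL-6", "bari4mg"): -0.4,
    ("IL-6", "bari2mg"): -0.2,
}
CYTOKINE_WEEKS = (0, 12, 24)


@dataclass
class SimulationTruth:
    """Ground truth recorded exactly as drawn.

    Attributes
    ----------
    patient_status
        Series patient_id → 'high' or 'low' interferon-signature status.
    baseline_elevation
        Series feature_id → log2 elevation over the healthy mean carried
        by IFN-high patients (0 outside the IFN block).
    pd_effects
        Long frame (feature_id, arm, week, effect): planted log2
        treatment-vs-placebo change from baseline.
    cytokine_effects
        Long frame (analyte, arm, week, log_effect).
    latent_cytokines
        Uncensored concentrations per (analyte, patient, week).
    censoring_fractions
        Realized censored fraction per (analyte, group).
    """

    patient_status: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    baseline_elevation: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    pd_effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    cytokine_effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    latent_cytokines: pd.DataFrame = field(default_factory=pd.DataFrame)
    censoring_fractions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.patient_status.rename("status").to_csv(
            outdir / "truth_patient_status.tsv", sep="\t", index_label="patient_id"
        )
        self.baseline_elevation.rename("elevation_log2").to_csv(
            outdir / "truth_baseline_elevation.tsv", sep="\t", index_label="feature_id"
        )
        for name, frame in [
            ("pd_effects", self.pd_effects),
            ("cytokine_effects", self.cytokine_effects),
            ("latent_cytokines", self.latent_cytokines),
            ("censoring_fractions", self.censoring_fractions),
        ]:
            frame.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False,
                         float_format="%.10g")

    @classmethod
    def load(cls, outdir) -> "SimulationTruth":
        outdir = Path(outdir)
        status = pd.read_csv(
            outdir / "truth_patient_status.tsv", sep="\t", index_col="patient_id"
        )["status"].rename(None)
        elevation = pd.read_csv(
            outdir / "truth_baseline_elevation.tsv", sep="\t", index_col="feature_id"
        )["elevation_log2"].rename(None)
        frames = {
            name: pd.read_csv(outdir / f"truth_{name}.tsv", sep="\t")
            for name in [
                "pd_effects",
                "cytokine_effects",
                "latent_cytokines",
                "censoring_fractions",
            ]
        }
        return cls(
            patient_status=status,
            baseline_elevation=elevation,
            **frames,
        )


def _patient_ids(prefix: str, n: int) -> list:
    return [f"{prefix}{i:03d}" for i in range(1, n + 1)]


def _make_meta(rng, n_per_arm: int, n_healthy: int) -> SampleMeta:
    rows = []

    def covariates():
        age = float(np.clip(np.round(rng.normal(45, 12)), 18, 80))
        sex = "F" if rng.random() < 0.92 else "M"
        log_leuco = float(rng.normal(np.log(5.8), 0.35))
        return age, sex, log_leuco

    for i, pid in enumerate(_patient_ids("H", n_healthy)):
        age, sex, ll = covariates()
        rows.append(
            dict(sample_id=f"{pid}_w0", patient_id=pid, group="healthy",
                 visit_week=0, age=age, sex=sex, log_leucocytes=ll)
        )
    pid_counter = 0
    for arm in TREATMENT_ARMS:
        for _ in range(n_per_arm):
            pid_counter += 1
            pid = f"P{pid_counter:03d}"
            age, sex, ll = covariates()
            for week in VISIT_WEEKS:
                rows.append(
                    dict(sample_id=f"{pid}_w{week}", patient_id=pid, group=arm,
                         visit_week=week, age=age, sex=sex, log_leucocytes=ll)
                )
    return SampleMeta(pd.DataFrame(rows))


def simulate_expression(
    n_patients: int = 90,
    n_genes: int = 300,
    frac_ifn_high: float = 0.6,
    elevation_log2: float = 2.0,
    pd_effect_log2: float = -0.5,
    noise_sd: float = 0.5,
    seed: int = 0,
    *,
    n_ifn_genes: int = 60,
    n_healthy: int = 50,
    patient_sd: float | None = None,
    dose_ratio: dict | None = None,
    week_ramp: dict | None = None,
    probe_level: bool = False,
    n_probes_per_tc: int = 4,
    probe_affinity_sd: float = 0.5,
    outlier_probe_frac: float = 0.0,
    outlier_shift_log2: float = 6.0,
):
    """Simulate the trial's expression dataset.

    Per gene g, patient i, week w the log2 expression is

        y_giw = m_g + e_g·1[g in IFN block]·1[i IFN-high]
                + d(arm_i)·r(w)·delta_g·1[g in IFN block]
                + b_i + eps_giw

    with healthy-gene mean m_g, elevation e_g = ``elevation_log2``,
    dose scaling d (placebo 0, 2 mg 0.5, 4 mg 1), onset ramp r(w)
    (0 at week 0), maximal 4 mg effect delta_g = ``pd_effect_log2``,
    patient random intercept b_i ~ N(0, patient_sd²) and white noise
    eps ~ N(0, noise_sd²).  The treatment effect applies to the elevated
    (IFN-block) genes of every patient in the arm.

    Parameters
    ----------
    n_patients
        Patients per treatment arm (three arms).
    frac_ifn_high
        Fraction of SLE patients carrying the elevated IFN block.
    probe_level
        When True, return a linear-scale :class:`ProbeMatrix` with
        ``n_probes_per_tc`` probes per gene, per-probe affinity offsets
        and optionally a fraction of outlier probes; otherwise return a
        gene-level :class:`ExpressionMatrix`.

    Returns
    -------
    (ProbeMatrix | ExpressionMatrix, SampleMeta, SimulationTruth)
    """
    if n_patients <= 0 or n_genes <= 0 or n_healthy <= 0:
        raise ValidationError("n_patients, n_genes and n_healthy must be positive")
    if not 0 <= frac_ifn_high <= 1:
        raise ValidationError("frac_ifn_high must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if patient_sd is None:
        patient_sd = 0.5 * noise_sd
    dose_ratio = dict(DEFAULT_DOSE_RATIO if dose_ratio is None else dose_ratio)
    week_ramp = dict(DEFAULT_WEEK_RAMP if week_ramp is None else week_ramp)
    n_ifn = min(n_ifn_genes, n_genes)

    meta = _make_meta(rng, n_patients, n_healthy)
    frame = meta.frame
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    ifn_block = genes[:n_ifn]

    gene_mean = rng.normal(8.0, 1.0, size=n_genes)
    elevation = pd.Series(0.0, index=pd.Index(genes, name="feature_id"))
    elevation.loc[ifn_block] = elevation_log2

    sle_patients = sorted(set(frame.loc[frame["group"] != "healthy", "patient_id"]))
    n_high = int(round(frac_ifn_high * len(sle_patients)))
    high_ids = rng.choice(sle_patients, size=n_high, replace=False)
    status = pd.Series("low", index=pd.Index(sle_patients, name="patient_id"))
    status.loc[high_ids] = "high"

    all_patients = list(dict.fromkeys(frame["patient_id"]))
    intercepts = pd.Series(
        rng.normal(0.0, patient_sd, size=len(all_patients)), index=all_patients
    )

    arm = frame["group"].to_numpy()
    week = frame["visit_week"].to_numpy()
    pid = frame["patient_id"].to_numpy()
    is_high = np.array([status.get(p) == "high" for p in pid])
    dose = np.array([dose_ratio.get(a, 0.0) for a in arm])
    ramp = np.array([week_ramp.get(w, 0.0) if w != 0 else 0.0 for w in week])

    n_samples = len(frame)
    values = np.empty((n_genes, n_samples))
    ifn_mask = np.array([g in set(ifn_block) for g in genes])
    base = gene_mean[:, None] + intercepts.loc[pid].to_numpy()[None, :]
    elev_term = np.outer(elevation.to_numpy(), is_high.astype(float))
    pd_term = np.outer(
        ifn_mask.astype(float) * pd_effect_log2, dose * ramp
    )
    noise = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    values = base + elev_term + pd_term + noise

    pd_rows = []
    for g, is_ifn in zip(genes, ifn_mask):
        for a in ("bari2mg", "bari4mg"):
            for w in POST_BASELINE_WEEKS:
                pd_rows.append(
                    dict(
                        feature_id=g,
                        arm=a,
                        week=w,
                        effect=(pd_effect_log2 * dose_ratio[a] * week_ramp[w]
                                if is_ifn else 0.0),
                    )
                )
    truth = SimulationTruth(
        patient_status=status,
        baseline_elevation=elevation,
        pd_effects=pd.DataFrame(pd_rows),
    )

    expr_frame = pd.DataFrame(values, index=genes, columns=frame["sample_id"])
    if not probe_level:
        return ExpressionMatrix(expr_frame), meta, truth

    probe_rows = []
    probe_ids = []
    mapping = {}
    for gi, g in enumerate(genes):
        affinities = rng.normal(0.0, probe_affinity_sd, size=n_probes_per_tc)
        affinities -= affinities.mean()  # offsets, not a level shift
        for p in range(n_probes_per_tc):
            probe_id = f"{g}_p{p + 1}"
            probe_ids.append(probe_id)
            mapping[probe_id] = g
            row = values[gi] + affinities[p] + rng.normal(
                0.0, noise_sd * 0.5, size=n_samples
            )
            probe_rows.append(row)
    probe_log2 = np.array(probe_rows)
    if outlier_probe_frac > 0:
        n_out = int(round(outlier_probe_frac * len(probe_ids)))
        out_idx = rng.choice(len(probe_ids), size=n_out, replace=False)
        for idx in out_idx:
            hit = rng.random(n_samples) < 0.1
            probe_log2[idx, hit] += outlier_shift_log2
    probes = ProbeMatrix(
        pd.DataFrame(2.0 ** probe_log2, index=probe_ids, columns=frame["sample_id"]),
        pd.Series(mapping),
        is_log2=False,
    )
    return probes, meta, truth


def simulate_trajectories(
    meta: SampleMeta,
    truth: SimulationTruth,
    responder_benefit: dict | float | None = None,
    placebo_drift: dict | None = None,
    noise_sd: float = 3.0,
    seed: int = 0,
    *,
    baseline_mean: float = 9.0,
    baseline_sd: float = 3.0,
    dose_ratio: dict | None = None,
) -> list:
    """Simulate SLEDAI-2K trajectories whose response tracks signature status.

    Change from baseline at week w for patient i in arm a:

        drift(w) + d(a)·1[status_i = high]·benefit(w) + noise,

    rounded to integers and floored so scores stay in [0, 105].  Week 0
    change is identically 0.  ``responder_benefit`` may be a week → benefit
    mapping or a scalar applied at every post-baseline week; 0 disables
    the status–response link (the null configuration).
    """
    rng = np.random.default_rng(seed)
    if responder_benefit is None:
        benefit = dict(DEFAULT_RESPONDER_BENEFIT)
    elif np.isscalar(responder_benefit):
        benefit = {w: float(responder_benefit) for w in POST_BASELINE_WEEKS}
    else:
        benefit = dict(responder_benefit)
    drift = dict(DEFAULT_PLACEBO_DRIFT if placebo_drift is None else placebo_drift)
    dose_ratio = dict(DEFAULT_DOSE_RATIO if dose_ratio is None else dose_ratio)

    sle = meta.sle()
    patients = sle.drop_duplicates("patient_id")[["patient_id", "group"]]
    unknown = set(patients["patient_id"]) - set(truth.patient_status.index)
    if unknown:
        raise ValidationError(
            f"patients without a truth status: {sorted(unknown)[:5]}"
        )
    trajectories = []
    for pid, arm in patients.itertuples(index=False):
        weeks = sorted(sle.loc[sle["patient_id"] == pid, "visit_week"])
        base = int(np.clip(np.round(rng.normal(baseline_mean, baseline_sd)), 4, 40))
        is_high = truth.patient_status.loc[pid] == "high"
        visits = []
        for w in weeks:
            if w == 0:
                visits.append((0, base))
                continue
            mean_change = drift.get(w, 0.0) + (
                dose_ratio.get(arm, 0.0) * benefit.get(w, 0.0) if is_high else 0.0
            )
            change = int(np.round(mean_change + rng.normal(0.0, noise_sd)))
            score = int(np.clip(base + change, 0, SLEDAI_MAX))
            visits.append((int(w), score))
        trajectories.append(ClinicalTrajectory(patient_id=pid, visits=visits))
    return trajectories


def simulate_cytokines(
    meta: SampleMeta,
    analytes_with_lloq: dict | None = None,
    arm_log_effects: dict | None = None,
    sd_log: float = 0.8,
    seed: int = 0,
    *,
    healthy_log_mean: dict | float | None = None,
    sle_shift_log: float = 1.0,
    patient_sd_log: float = 0.3,
    weeks: tuple = CYTOKINE_WEEKS,
    truth: SimulationTruth | None = None,
) -> tuple:
    """Simulate the left-censored serum cytokine panel.

    Concentrations are log-normal per analyte: healthy log-mean at
    log(LLOQ) by default (so roughly half of healthy samples fall below
    the limit), SLE patients shifted up by ``sle_shift_log``, and
    treatment arms shifted by ``arm_log_effects[(analyte, arm)]`` at
    weeks >= 12.  Values below the LLOQ are flagged ``below_lloq`` with
    the concentration withheld (NaN); the uncensored value is kept in
    the returned truth.

    Returns
    -------
    (measurements DataFrame, SimulationTruth)
        The measurement frame has the cytokine table schema; the truth
        carries latent concentrations, planted arm effects and realized
        censoring fractions.
    """
    rng = np.random.default_rng(seed)
    lloqs = dict(DEFAULT_ANALYTE_LLOQ if analytes_with_lloq is None else analytes_with_lloq)
    for analyte, lloq in lloqs.items():
        if lloq <= 0:
            raise ValidationError(f"LLOQ for {analyte} must be positive")
    effects = dict(
        DEFAULT_CYTOKINE_ARM_EFFECTS if arm_log_effects is None else arm_log_effects
    )
    if healthy_log_mean is None:
        log_means = {a: float(np.log(l)) for a, l in lloqs.items()}
    elif np.isscalar(healthy_log_mean):
        log_means = {a: float(healthy_log_mean) for a in lloqs}
    else:
        log_means = dict(healthy_log_mean)

    frame = meta.frame.drop_duplicates("patient_id")[["patient_id", "group"]]
    rows = []
    latent_rows = []
    for analyte, lloq in lloqs.items():
        for pid, group in frame.itertuples(index=False):
            b_i = rng.normal(0.0, patient_sd_log)
            visit_weeks = (0,) if group == "healthy" else tuple(weeks)
            for w in visit_weeks:
                mu = log_means[analyte] + b_i
                if group != "healthy":
                    mu += sle_shift_log
                    if w >= 12:
                        mu += effects.get((analyte, group), 0.0)
                conc = float(np.exp(mu + rng.normal(0.0, sd_log)))
                censored = conc < lloq
                rows.append(
                    dict(
                        analyte=analyte,
                        patient_id=pid,
                        visit_week=int(w),
                        concentration=np.nan if censored else conc,
                        lloq=lloq,
                        below_lloq=censored,
                    )
                )
                latent_rows.append(
                    dict(analyte=analyte, patient_id=pid, visit_week=int(w),
                         group=group, latent_concentration=conc)
                )
    measurements = pd.DataFrame(rows)
    latent = pd.DataFrame(latent_rows)
    cens = (
        measurements.merge(
            meta.frame.drop_duplicates("patient_id")[["patient_id", "group"]],
            on="patient_id",
        )
        .groupby(["analyte", "group"])["below_lloq"]
        .mean()
        .rename("censored_fraction")
        .reset_index()
    )
    effect_rows = [
        dict(analyte=a, arm=arm, week=w, log_effect=delta)
        for (a, arm), delta in effects.items()
        for w in weeks
        if w >= 12
    ]
    if truth is None:
        truth = SimulationTruth()
    truth.cytokine_effects = pd.DataFrame(
        effect_rows, columns=["analyte", "arm", "week", "log_effect"]
    )
    truth.latent_cytokines = latent
    truth.censoring_fractions = cens
    return measurements, truth
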