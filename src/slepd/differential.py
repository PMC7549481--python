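"""Baseline disease-vs-control ranking and per-gene repeated-measures
pharmacodynamic effects.

The pharmacodynamic (PD) effect of a treatment arm at a visit is the
arm's change in log2 expression from baseline minus the placebo change
at the same visit.  It is estimated per gene from a mixed-effect model
for repeated measures (MMRM): fixed effects for treatment, discrete
time, their interaction and control covariates (age, sex, cell counts),
with a structured within-patient residual covariance.  With placebo and
week 0 as reference levels the treatment×week interaction coefficient
IS the PD contrast.

The default covariance is spatial power, R_ij = rho^|week_i − week_j|,
the standard MMRM choice for the unequally spaced visit grid
{0, 2, 4, 12, 24}.  Parameters are estimated by profiled (RE)ML over
rho with generalized least squares for the fixed effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .types import ExpressionMatrix, SampleMeta, ValidationError

log = logging.getLogger("slepd")

COVARIANCE_STRUCTURES = ("spatial_power", "compound_symmetry", "independence")


@dataclass
class MMRMConfig:
    """Settings for the per-gene repeated-measures fit."""

    covariance: str = "spatial_power"
    estimation: str = "REML"
    covariates: tuple = ("age", "sex", "log_leucocytes")
    max_iter: int = 200
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.covariance not in COVARIANCE_STRUCTURES:
            raise ValidationError(f"unknown covariance {self.covariance!r}")
        if self.estimation not in ("REML", "ML"):
            raise ValidationError(f"estimation must be REML or ML")


@dataclass
class MMRMFit:
    """A converged per-gene fit: coefficients, vcov and covariance parameters."""

    feature_id: str
    params: pd.Series
    vcov: pd.DataFrame
    rho: float
    sigma2: float
    converged: bool
    n_obs: int
    n_patients: int
    arms: tuple
    weeks: tuple


def bh_qvalues(pvec) -> np.ndarray:
    """Benjamini–Hochberg FDR q-values.

    q_(i) = min_{j >= i} p_(j)·m/j, clipped at 1, in the input order.
    """
    p = np.asarray(pvec, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p-value vector must be 1-D and non-empty")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def baseline_de(expr: ExpressionMatrix, meta: SampleMeta) -> pd.DataFrame:
    """Rank genes by baseline SLE-vs-healthy log2 difference.

    Uses week-0 SLE samples against healthy controls: per gene the log2
    fold difference of group means, a Welch two-sample t-test p and a BH
    q over all genes.  ``rank`` is 1 for the most elevated gene.
    """
    frame = meta.frame
    healthy = frame.loc[frame["group"] == "healthy", "sample_id"]
    sle0 = frame.loc[(frame["group"] != "healthy") & (frame["visit_week"] == 0),
                     "sample_id"]
    healthy = [s for s in healthy if s in expr.data.columns]
    sle0 = [s for s in sle0 if s in expr.data.columns]
    if len(healthy) < 2 or len(sle0) < 2:
        raise ValidationError(
            f"need >=2 samples per group (healthy={len(healthy)}, SLE={len(sle0)})"
        )
    h = expr.data[healthy].to_numpy()
    s = expr.data[list(sle0)].to_numpy()
    diff = s.mean(axis=1) - h.mean(axis=1)
    t = stats.ttest_ind(s, h, axis=1, equal_var=False)
    result = pd.DataFrame(
        {
            "feature_id": expr.feature_ids,
            "log2_fold_difference": diff,
            "p": t.pvalue,
        }
    )
    result["q"] = bh_qvalues(result["p"].to_numpy())
    result["rank"] = (
        result["log2_fold_difference"].rank(ascending=False, method="first").astype(int)
    )
    return result.sort_values("rank").reset_index(drop=True)


def top_genes(baseline: pd.DataFrame, n: int, direction: str = "elevated") -> list:
    """Top-n gene list from a baseline ranking (elevated or decreased)."""
    if direction == "elevated":
        ordered = baseline.sort_values("rank")
    elif direction == "decreased":
        ordered = baseline.sort_values("rank", ascending=False)
    else:
        raise ValidationError("direction must be 'elevated' or 'decreased'")
    return list(ordered["feature_id"].head(n))


# ---------------------------------------------------------------------------
# MMRM machinery


class _Design:
    """Shared fixed-effect design and patient grouping for one dataset."""

    def __init__(self, expr: ExpressionMatrix, meta: SampleMeta,
                 config: MMRMConfig):
        frame = meta.sle().copy()
        frame = frame[frame["sample_id"].isin(expr.data.columns)]
        # require a baseline and at least one post-baseline visit
        keep = []
        dropped = []
        for pid, grp in frame.groupby("patient_id"):
            weeks = set(grp["visit_week"])
            if 0 in weeks and len(weeks) > 1:
                keep.append(pid)
            else:
                dropped.append(pid)
        if dropped:
            log.warning("MMRM: %d patient(s) without baseline + post-baseline "
                        "visit excluded", len(dropped))
        frame = frame[frame["patient_id"].isin(keep)]
        frame = frame.sort_values(["patient_id", "visit_week"]).reset_index(drop=True)
        if frame.empty:
            raise ValidationError("no usable SLE samples for the MMRM")

        self.frame = frame
        self.arms = tuple(a for a in ("bari2mg", "bari4mg")
                          if a in set(frame["group"]))
        self.weeks = tuple(sorted(w for w in set(frame["visit_week"]) if w != 0))
        cols = {"Intercept": np.ones(len(frame))}
        for a in self.arms:
            cols[f"arm[{a}]"] = (frame["group"] == a).to_numpy(float)
        for w in self.weeks:
            cols[f"week[{w}]"] = (frame["visit_week"] == w).to_numpy(float)
        for a in self.arms:
            for w in self.weeks:
                cols[f"arm[{a}]:week[{w}]"] = (
                    cols[f"arm[{a}]"] * cols[f"week[{w}]"]
                )
        for cov in config.covariates:
            if cov == "sex":
                cols["sex[M]"] = (frame["sex"] == "M").to_numpy(float)
            else:
                if cov not in frame.columns:
                    raise ValidationError(f"covariate {cov!r} missing from metadata")
                v = frame[cov].to_numpy(float)
                cols[cov] = v - v.mean()
        self.columns = list(cols)
        self.X = np.column_stack([cols[c] for c in self.columns])
        self.sample_ids = list(frame["sample_id"])

        # group patients by visit pattern for block-wise whitening
        self.patterns = []  # (weeks array, row-index array (k, m))
        pattern_rows: dict = {}
        for pid, grp in frame.groupby("patient_id"):
            key = tuple(grp["visit_week"])
            pattern_rows.setdefault(key, []).append(grp.index.to_numpy())
        for key, rows in pattern_rows.items():
            self.patterns.append((np.asarray(key, float), np.vstack(rows)))
        self.n_obs = len(frame)
        self.n_patients = frame["patient_id"].nunique()
        self.n_params = self.X.shape[1]

    def correlation(self, weeks: np.ndarray, rho: float, structure: str):
        m = len(weeks)
        if structure == "independence" or m == 1:
            return np.eye(m)
        if structure == "spatial_power":
            d = np.abs(weeks[:, None] - weeks[None, :])
            return rho ** d
        if structure == "compound_symmetry":
            return np.full((m, m), rho) + (1.0 - rho) * np.eye(m)
        raise ValidationError(f"unknown covariance {structure!r}")

    def whiten(self, rho: float, structure: str, Y: np.ndarray):
        """Whitened (X, Y) under unit-variance correlation R(rho), plus
        the summed log|R| over patients.

        Y has one column per gene (n_obs × G).
        """
        Xw = np.empty_like(self.X)
        Yw = np.empty_like(Y)
        logdet = 0.0
        for weeks, rows in self.patterns:
            R = self.correlation(weeks, rho, structure)
            try:
                L = linalg.cholesky(R, lower=True)
            except linalg.LinAlgError:
                return None, None, np.inf
            Linv = linalg.solve_triangular(L, np.eye(len(weeks)), lower=True)
            logdet += 2.0 * np.log(np.diag(L)).sum() * rows.shape[0]
            xb = self.X[rows]                      # (k, m, p)
            yb = Y[rows]                           # (k, m, G)
            Xw[rows] = np.einsum("ij,kjp->kip", Linv, xb)
            Yw[rows] = np.einsum("ij,kjg->kig", Linv, yb)
        return Xw, Yw, logdet

    def rho_bounds(self, structure: str):
        if structure == "compound_symmetry":
            m_max = max(len(w) for w, _ in self.patterns)
            return (-1.0 / max(m_max - 1, 1) + 1e-3, 0.99)
        return (-0.5, 0.99)


def _criterion(design: _Design, rho: float, structure: str, Y2d: np.ndarray,
               estimation: str):
    """Profiled −2·log-likelihood (REML or ML) per gene at this rho."""
    Xw, Yw, logdetR = design.whiten(rho, structure, Y2d)
    if Xw is None:
        return np.full(Y2d.shape[-1], np.inf), None
    n, p = design.n_obs, design.n_params
    beta, rss, rank, _ = np.linalg.lstsq(Xw, Yw.reshape(n, -1), rcond=None)
    if rank < p:
        return np.full(Y2d.shape[-1], np.inf), None
    resid = Yw.reshape(n, -1) - Xw @ beta
    rss = (resid ** 2).sum(axis=0)
    if estimation == "REML":
        sig2 = rss / (n - p)
        _, ld_xtx = np.linalg.slogdet(Xw.T @ Xw)
        crit = (n - p) * np.log(sig2) + logdetR + ld_xtx
    else:
        sig2 = rss / n
        crit = n * np.log(sig2) + logdetR
    return crit, (beta, sig2, Xw)


def fit_mmrm(
    expr: ExpressionMatrix,
    meta: SampleMeta,
    config: MMRMConfig | None = None,
    features=None,
) -> dict:
    """Fit the MMRM for each gene; returns feature_id → :class:`MMRMFit`.

    The correlation parameter rho is estimated per gene by bounded
    scalar minimization of the profiled (RE)ML criterion; the fixed
    effects follow by generalized least squares.  Genes whose optimizer
    fails are flagged ``converged=False`` and reported, never silently
    dropped.
    """
    config = config or MMRMConfig()
    design = _Design(expr, meta, config)
    if features is None:
        features = expr.feature_ids
    Y_all = expr.data.loc[features, design.sample_ids].to_numpy().T  # n_obs × G

    fits = {}
    n_nonconv = 0
    for gi, feature in enumerate(features):
        y = Y_all[:, gi][:, None]
        structure = config.covariance
        if structure == "independence":
            rho, converged = 0.0, True
        else:
            lo, hi = design.rho_bounds(structure)
            res = optimize.minimize_scalar(
                lambda r: float(
                    _criterion(design, r, structure, y, config.estimation)[0][0]
                ),
                bounds=(lo, hi), method="bounded",
                options={"xatol": config.tol ** 0.5, "maxiter": config.max_iter},
            )
            rho, converged = float(res.x), bool(res.success)
        crit, aux = _criterion(design, rho, structure, y, config.estimation)
        if aux is None:
            n_nonconv += 1
            fits[feature] = MMRMFit(
                feature_id=feature,
                params=pd.Series(np.nan, index=design.columns),
                vcov=pd.DataFrame(np.nan, index=design.columns,
                                  columns=design.columns),
                rho=rho, sigma2=np.nan, converged=False,
                n_obs=design.n_obs, n_patients=design.n_patients,
                arms=design.arms, weeks=design.weeks,
            )
            continue
        beta, sig2, Xw = aux
        xtx_inv = np.linalg.inv(Xw.T @ Xw)
        vcov = xtx_inv * float(sig2[0])
        fits[feature] = MMRMFit(
            feature_id=feature,
            params=pd.Series(beta[:, 0], index=design.columns),
            vcov=pd.DataFrame(vcov, index=design.columns, columns=design.columns),
            rho=rho,
            sigma2=float(sig2[0]),
            converged=converged,
            n_obs=design.n_obs,
            n_patients=design.n_patients,
            arms=design.arms,
            weeks=design.weeks,
        )
        if not converged:
            n_nonconv += 1
    if n_nonconv:
        log.warning("fit_mmrm: %d gene(s) did not converge", n_nonconv)
    return fits


def pd_contrast(fit: MMRMFit, arm: str, week: int) -> dict:
    """PD effect for one arm and week from a fitted model.

    The contrast (arm change-from-baseline) − (placebo change-from-
    baseline) equals the arm:week interaction coefficient under the
    reference coding.  The placebo arm contrasted with itself is
    exactly 0.  Wald p-values use the normal reference.
    """
    if arm == "placebo":
        return dict(feature_id=fit.feature_id, arm=arm, week=week,
                    estimate=0.0, se=0.0, p=1.0)
    name = f"arm[{arm}]:week[{week}]"
    if name not in fit.params.index or arm not in fit.arms or week not in fit.weeks:
        raise ValidationError(f"arm {arm!r} / week {week} not in the design")
    est = float(fit.params[name])
    se = float(np.sqrt(fit.vcov.loc[name, name]))
    z = est / se if se > 0 else np.nan
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return dict(feature_id=fit.feature_id, arm=arm, week=week,
                estimate=est, se=se, p=p)


def pd_effects_table(fits: dict, arms=None, weeks=None) -> pd.DataFrame:
    """All PD contrasts with BH q-values within each (arm, week) slice.

    Non-converged genes are excluded from the q computation (reported
    with q = NaN and a logged count), mirroring how the evaluation set
    is restricted to usable fits.
    """
    some = next(iter(fits.values()))
    arms = tuple(arms) if arms is not None else some.arms
    weeks = tuple(weeks) if weeks is not None else some.weeks
    rows = []
    n_bad = 0
    for fit in fits.values():
        if not fit.converged or not np.isfinite(fit.sigma2):
            n_bad += 1
        for arm in arms:
            for week in weeks:
                rows.append(
                    dict(pd_contrast(fit, arm, week), converged=fit.converged)
                )
    if n_bad:
        log.warning("pd_effects_table: %d non-converged gene(s) excluded "
                    "from q-values", n_bad)
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for (arm, week), idx in table.groupby(["arm", "week"]).groups.items():
        sub = table.loc[idx]
        ok = sub["converged"] & sub["p"].notna()
        if ok.any():
            table.loc[sub.index[ok], "q"] = bh_qvalues(
                sub.loc[ok, "p"].to_numpy()
            )
    return table.drop(columns="converged")
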