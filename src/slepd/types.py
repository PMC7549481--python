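"""Domain types shared by every pipeline stage.

The central object is the :class:`ExpressionMatrix` — a log2-scale
feature × sample table of whole-blood transcript abundance.  Probe-level
inputs (:class:`ProbeMatrix`) are linear-scale intensities; the log2
transform happens inside the preprocessing stage so that module
boundaries carry an unambiguous unit contract.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Trial arms plus the healthy-control group.
GROUPS = ("healthy", "placebo", "bari2mg", "bari4mg")
TREATMENT_ARMS = ("placebo", "bari2mg", "bari4mg")
#: Scheduled visits (weeks); healthy controls are sampled at week 0 only.
VISIT_WEEKS = (0, 2, 4, 12, 24)
#: Maximum attainable SLEDAI-2K composite score.
SLEDAI_MAX = 105


class ValidationError(ValueError):
    """An input violated a domain-type invariant."""


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()]))
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Log2 expression, features (genes / transcript clusters) × samples.

    Parameters
    ----------
    data
        DataFrame indexed by feature id with one column per sample id.
        All values must be finite; ids must be unique; at least one
        feature and two samples are required.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] < 1 or self.data.shape[1] < 2:
            raise ValidationError(
                f"expression matrix needs >=1 feature and >=2 samples, "
                f"got {self.data.shape}"
            )
        _check_unique(self.data.index, "feature ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression value at feature "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def feature_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])


@dataclass
class ProbeMatrix:
    """Probe-level intensities plus the many-to-one probe → TC map.

    Intensities are linear scale by default (``is_log2=False``) and must
    be strictly positive before a log transform is applied.
    """

    data: pd.DataFrame
    probe_to_tc: pd.Series
    is_log2: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe ids")
        _check_unique(self.data.columns, "sample ids")
        self.probe_to_tc = pd.Series(self.probe_to_tc)
        missing = self.data.index.difference(self.probe_to_tc.index)
        if len(missing):
            raise ValidationError(
                f"probes without a transcript-cluster mapping: {sorted(missing)[:5]}"
            )
        _check_unique(self.probe_to_tc.index, "probe map entries")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise ValidationError("probe intensities must be finite")
        if not self.is_log2 and (values <= 0).any():
            raise ValidationError(
                "linear-scale probe intensities must be strictly positive"
            )

    @property
    def probe_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    def tc_groups(self) -> dict:
        """Map transcript-cluster id → list of member probe ids."""
        tc = self.probe_to_tc.loc[self.data.index]
        out: dict = {}
        for probe, cluster in tc.items():
            out.setdefault(cluster, []).append(probe)
        return out


@dataclass
class SampleMeta:
    """Sample-level metadata: patient, arm, visit and model covariates.

    ``frame`` must contain columns ``sample_id, patient_id, group,
    visit_week, age, sex`` plus one or more numeric cell-count covariate
    columns (``covariate_cols``).  Missing covariates are an error, not
    imputed, because the repeated-measures model includes them
    unconditionally.
    """

    frame: pd.DataFrame
    covariate_cols: tuple = ("log_leucocytes",)

    REQUIRED = ("sample_id", "patient_id", "group", "visit_week", "age", "sex")

    def __post_init__(self) -> None:
        self.frame = self.frame.reset_index(drop=True)
        for col in self.REQUIRED + tuple(self.covariate_cols):
            if col not in self.frame.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        _check_unique(self.frame["sample_id"], "sample ids")
        _check_unique(
            list(zip(self.frame["patient_id"], self.frame["visit_week"])),
            "(patient_id, visit_week) pairs",
        )
        bad_group = set(self.frame["group"]) - set(GROUPS)
        if bad_group:
            raise ValidationError(f"unknown groups: {sorted(bad_group)}")
        bad_week = set(self.frame["visit_week"]) - set(VISIT_WEEKS)
        if bad_week:
            raise ValidationError(f"unknown visit weeks: {sorted(bad_week)}")
        healthy = self.frame[self.frame["group"] == "healthy"]
        if (healthy["visit_week"] != 0).any():
            raise ValidationError("healthy controls must be week 0 only")
        bad_sex = set(self.frame["sex"]) - {"F", "M"}
        if bad_sex:
            raise ValidationError(f"sex must be F or M, got {sorted(bad_sex)}")
        cov = self.frame[list(self.covariate_cols) + ["age"]]
        if cov.isna().any().any():
            raise ValidationError("missing covariate values (age/cell counts)")

    def baseline(self) -> pd.DataFrame:
        return self.frame[self.frame["visit_week"] == 0]

    def sle(self) -> pd.DataFrame:
        return self.frame[self.frame["group"] != "healthy"]


@dataclass(frozen=True)
class GeneSignature:
    """A named, non-empty gene set (e.g. JAK1-activated genes)."""

    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} has no genes")

    def resolve(self, feature_ids) -> tuple:
        """Split into (present, missing) against a feature universe.

        Unresolvable genes are reported, never silently dropped.
        """
        universe = set(feature_ids)
        present = sorted(g for g in self.genes if g in universe)
        missing = sorted(g for g in self.genes if g not in universe)
        return present, missing


@dataclass
class ClinicalTrajectory:
    """Per-patient SLEDAI-2K disease-activity scores over visits."""

    patient_id: str
    visits: list  # [(week, score)], week 0 first

    def __post_init__(self) -> None:
        weeks = [w for w, _ in self.visits]
        scores = [s for _, s in self.visits]
        if not weeks or weeks[0] != 0:
            raise ValidationError(
                f"trajectory for {self.patient_id} must start at week 0"
            )
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ValidationError(
                f"trajectory weeks for {self.patient_id} must strictly increase"
            )
        for s in scores:
            if s != int(s) or not (0 <= s <= SLEDAI_MAX):
                raise ValidationError(
                    f"SLEDAI-2K scores must be integers in [0, {SLEDAI_MAX}], "
                    f"got {s} for {self.patient_id}"
                )

    @property
    def baseline_score(self) -> int:
        return int(self.visits[0][1])

    def changes_from_baseline(self) -> dict:
        """week → (score − baseline score); week 0 maps to 0."""
        base = self.baseline_score
        return {int(w): int(s) - base for w, s in self.visits}


@dataclass
class RunConfig:
    """Pipeline-wide analysis settings.

    ``n_permutations`` defaults to the 10 000 Monte Carlo iterations of
    the trajectory test; ``percentile_threshold`` to the healthy 95th
    percentile used for STAT1/STAT2 co-elevation calls.
    """

    rng_seed: int = 0
    n_permutations: int = 10_000
    alpha: float = 0.05
    visit_weeks: tuple = VISIT_WEEKS
    percentile_threshold: float = 95.0
    covariance: str = "spatial_power"
    estimation: str = "REML"
    covariates: tuple = ("age", "sex", "log_leucocytes")
    mmrm_max_iter: int = 200
    mmrm_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("visit_weeks", "covariates"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)
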