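"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is TSV (UTF-8, tab-separated, '.' decimal) except gene
signatures (GMT) and interaction tables (SIF or 3+-column TSV).
Expression I/O is log2 scale by contract; probe matrices are linear
scale until preprocessing log-transforms them.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    ClinicalTrajectory,
    ExpressionMatrix,
    GeneSignature,
    ProbeMatrix,
    RunConfig,
    SampleMeta,
    ValidationError,
)

log = logging.getLogger("slepd")

CYTOKINE_COLUMNS = [
    "analyte",
    "patient_id",
    "visit_week",
    "concentration",
    "lloq",
    "below_lloq",
]


def _read_matrix_tsv(path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = sorted({h for h in header if header.count(h) > 1})
    if dup:
        raise ValidationError(f"{path}: duplicate sample ids in header: {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at row "
            f"{df.index[r]!r}, column {df.columns[c]!r}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return numeric


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a log2 expression matrix: first column feature ids, header sample ids."""
    return ExpressionMatrix(_read_matrix_tsv(path))


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="feature_id", float_format="%.10g")


def read_probe_tsv(path, map_path, is_log2: bool = False) -> ProbeMatrix:
    """Read probe intensities plus a probe → transcript-cluster map TSV.

    The map file has two columns, ``probe_id`` and ``tc_id``.
    """
    data = _read_matrix_tsv(path)
    pmap = pd.read_csv(map_path, sep="\t")
    if not {"probe_id", "tc_id"} <= set(pmap.columns):
        raise ValidationError(f"{map_path}: need columns probe_id, tc_id")
    mapping = pmap.set_index("probe_id")["tc_id"]
    return ProbeMatrix(data, mapping, is_log2=is_log2)


def write_probe_tsv(probes: ProbeMatrix, path, map_path) -> None:
    probes.data.to_csv(path, sep="\t", index_label="probe_id", float_format="%.10g")
    probes.probe_to_tc.rename("tc_id").to_csv(
        map_path, sep="\t", index_label="probe_id"
    )


def read_meta_tsv(path, covariate_cols=("log_leucocytes",)) -> SampleMeta:
    frame = pd.read_csv(path, sep="\t")
    return SampleMeta(frame, covariate_cols=tuple(covariate_cols))


def write_meta_tsv(meta: SampleMeta, path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> list:
    """Parse a GMT file: one signature per line, name TAB description TAB genes...

    Duplicate genes within a line are deduplicated with a logged warning.
    """
    signatures = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            unique = frozenset(genes)
            if len(unique) < len(genes):
                log.warning(
                    "GMT %s line %d (%s): %d duplicate gene(s) removed",
                    path, lineno, name, len(genes) - len(unique),
                )
            signatures.append(GeneSignature(name=name, genes=unique))
    return signatures


def write_gmt(signatures, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, "na", *sorted(sig.genes)]) + "\n")


def read_trajectories_tsv(path) -> list:
    """Read long-format trajectories: columns patient_id, visit_week, sledai2k."""
    df = pd.read_csv(path, sep="\t")
    need = {"patient_id", "visit_week", "sledai2k"}
    if not need <= set(df.columns):
        raise ValidationError(f"{path}: need columns {sorted(need)}")
    out = []
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("visit_week")
        visits = list(zip(grp["visit_week"].astype(int), grp["sledai2k"].astype(int)))
        out.append(ClinicalTrajectory(patient_id=pid, visits=visits))
    return out


def write_trajectories_tsv(trajectories, path) -> None:
    rows = [
        {"patient_id": t.patient_id, "visit_week": w, "sledai2k": s}
        for t in trajectories
        for w, s in t.visits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cytokines_tsv(path) -> pd.DataFrame:
    """Read a cytokine measurement table.

    Columns: analyte, patient_id, visit_week, concentration (empty when
    censored), lloq, below_lloq.  LLOQ must be positive.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(CYTOKINE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    df["below_lloq"] = df["below_lloq"].astype(bool)
    if df["lloq"].isna().any() or (df["lloq"] <= 0).any():
        raise ValidationError(f"{path}: every measurement needs a positive LLOQ")
    return df[CYTOKINE_COLUMNS].copy()


def write_cytokines_tsv(measurements: pd.DataFrame, path) -> None:
    measurements.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_interactions(path) -> pd.DataFrame:
    """Read an interaction table as SIF or TSV.

    SIF lines are ``source TAB relation TAB target``; TSV needs columns
    source, mechanism, target (extra columns ignored).  Returns a frame
    with columns source, mechanism, target.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    cols = set(df.columns)
    if {"source", "mechanism", "target"} <= cols:
        out = df[["source", "mechanism", "target"]].copy()
    else:
        # headerless SIF
        df = pd.read_csv(path, sep="\t", header=None)
        if df.shape[1] < 3:
            raise ValidationError(f"{path}: SIF needs 3 tab-separated columns")
        out = df.iloc[:, :3].copy()
        out.columns = ["source", "mechanism", "target"]
    return out


def read_config(path) -> RunConfig:
    """Read a YAML key-value config file into a RunConfig."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a key-value mapping")
    return RunConfig.from_dict(raw)
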