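#!/usr/bin/env python
"""Generate the synthetic trial bundle every later stage consumes.

Writes a full cohort — probe-level intensities, gene-level log2
expression, sample metadata, SLEDAI-2K trajectories, censored cytokine
panel, the IFN-block gene signature, and the generative truth — under
scratch/trial_data/ (large TSVs) and a small design summary under
results/.
"""

from pathlib import Path

import pandas as pd

from slepd import io, nof1, preprocess
from slepd import simulate as sim

SEED = 20260929
OUT = Path("scratch/trial_data")
RESULTS = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    probes, meta, truth = sim.simulate_expression(
        n_patients=90, n_genes=120, n_ifn_genes=50, seed=SEED,
        probe_level=True, outlier_probe_frac=0.02,
    )
    trajectories = sim.simulate_trajectories(meta, truth, seed=SEED + 1)
    measurements, truth = sim.simulate_cytokines(meta, seed=SEED + 2,
                                                 truth=truth)
    io.write_probe_tsv(probes, OUT / "probes.tsv", OUT / "probe2tc.tsv")
    io.write_meta_tsv(meta, OUT / "meta.tsv")
    io.write_trajectories_tsv(trajectories, OUT / "trajectories.tsv")
    io.write_cytokines_tsv(measurements, OUT / "cytokines.tsv")
    ifn = sorted(truth.baseline_elevation[truth.baseline_elevation > 0].index)
    io.write_gmt([nof1.GeneSignature("IFN_BLOCK", frozenset(ifn))],
                 OUT / "signatures.gmt")
    truth.save(OUT)

    n_sle = meta.sle()["patient_id"].nunique()
    n_high = int((truth.patient_status == "high").sum())
    summary = pd.DataFrame([
        dict(quantity="patients_per_arm", value=90),
        dict(quantity="healthy_controls", value=50),
        dict(quantity="sle_patients", value=n_sle),
        dict(quantity="ifn_high_patients", value=n_high),
        dict(quantity="genes", value=120),
        dict(quantity="ifn_block_genes", value=len(ifn)),
        dict(quantity="probes_per_gene", value=4),
    ])
    summary.to_csv(RESULTS / "01_cohort_summary.tsv", sep="\t", index=False)
    print(f"cohort: {n_sle} SLE patients ({n_high} IFN-high) + 50 controls; "
          f"120 genes, 50-gene IFN block; bundle in {OUT}/")


if __name__ == "__main__":
    main()
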