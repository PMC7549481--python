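#!/usr/bin/env python
"""Stratify patients by baseline signature status and test whether the
strata separate clinically.

Per patient, a Wilcoxon signed-rank test of baseline signature-gene
expression against the population mean assigns high/low/neither status.
Per arm, a 10 000-iteration Monte Carlo test asks whether signature-high
patients' SLEDAI-2K improved more than signature-low patients'.  Also
runs the healthy-95th-percentile co-elevation analysis on the two most
elevated genes as the STAT1/STAT2-style worked example.
"""

from pathlib import Path

import pandas as pd

from slepd import differential as diff
from slepd import io, nof1

SEED = 20260929
DATA = Path("scratch/trial_data")
RESULTS = Path("results")


def main() -> None:
    expr = io.read_expression_tsv(DATA / "expression.tsv")
    meta = io.read_meta_tsv(DATA / "meta.tsv")
    trajectories = io.read_trajectories_tsv(DATA / "trajectories.tsv")
    signature = io.read_gmt(DATA / "signatures.gmt")[0]

    baseline = nof1.baseline_matrix(expr, meta)
    calls = nof1.call_signature_status(baseline, signature)
    nof1.calls_frame(calls).to_csv(RESULTS / "05_signature_calls.tsv",
                                   sep="\t", index=False, float_format="%.6g")

    rows = []
    for arm in ("placebo", "bari2mg", "bari4mg"):
        res = nof1.trajectory_permutation_test(
            calls, trajectories, meta, arm, B=10_000, seed=SEED)
        rows.append(dict(arm=arm, observed_stat=res.observed_stat,
                         p_value=res.p_value, n_high=res.n_high,
                         n_low=res.n_low, B=res.B))
    mc = pd.DataFrame(rows)
    mc.to_csv(RESULTS / "05_trajectory_tests.tsv", sep="\t", index=False,
              float_format="%.6g")

    curves = nof1.loess_group_trajectories(calls, trajectories,
                                           grid=[0, 2, 4, 12, 24])
    pd.concat([f.assign(group=g) for g, f in curves.items()]).to_csv(
        RESULTS / "05_loess_curves.tsv", sep="\t", index=False,
        float_format="%.4g")

    # percentile co-elevation on the two most elevated genes
    ranking = diff.baseline_de(expr, meta)
    g1, g2 = diff.top_genes(ranking, 2)
    healthy = nof1.baseline_matrix(expr, meta, group="healthy")
    flags, table, thresholds = nof1.percentile_classify(
        baseline, healthy, genes=(g1, g2))
    odds, p = nof1.fisher_exact_2x2(table)
    pd.DataFrame([dict(
        gene_a=g1, gene_b=g2, n_both_normal=table.n_both_normal,
        n_a_only=table.n_a_only, n_b_only=table.n_b_only,
        n_both_high=table.n_both_high, odds_ratio=odds, p=p,
    )]).to_csv(RESULTS / "05_coelevation.tsv", sep="\t", index=False,
               float_format="%.6g")

    n_high = sum(c.status == "high" for c in calls)
    n_low = sum(c.status == "low" for c in calls)
    print(f"signature calls: {n_high} high, {n_low} low, "
          f"{len(calls) - n_high - n_low} neither")
    print(mc.round(4).to_string(index=False))
    print(f"co-elevation of {g1}/{g2}: OR {odds:.1f}, p {p:.2e}")


if __name__ == "__main__":
    main()
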