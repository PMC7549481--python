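import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from slepd import nof1
from slepd import simulate as sim
from slepd.nof1 import ContingencyTable2x2, GeneSignature, SignatureCall
from slepd.types import ExpressionMatrix, ValidationError

from conftest import calls_from_truth


def exact_signed_rank_p(d):
    """Enumeration oracle: two-sided signed-rank p for tie-free d != 0."""
    d = np.asarray(d, float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append((ranks * np.array(signs)).sum())
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


def exact_fisher_p(a, b, c, d):
    """Hypergeometric enumeration oracle for the two-sided Fisher p."""
    n = a + b + c + d
    r1, c1 = a + c, a + b
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for a2 in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p2 = stats.hypergeom.pmf(a2, n, r1, c1)
        if p2 <= p_obs * (1 + 1e-10):
            total += p2
    return total


class TestCallSignatureStatus:
    def test_patient_at_population_mean_is_neither(self):
        vals = np.array([[1.0, 0.0, 2.0], [5.0, 4.0, 6.0],
                         [2.0, 1.0, 3.0], [8.0, 7.0, 9.0], [4.0, 3.0, 5.0]])
        # column 0 equals the row means of the full matrix
        expr = ExpressionMatrix(pd.DataFrame(
            vals, index=[f"g{i}" for i in range(5)],
            columns=["P1", "P2", "P3"]))
        sig = GeneSignature("S", frozenset(expr.feature_ids))
        calls = {c.patient_id: c for c in nof1.call_signature_status(expr, sig)}
        assert calls["P1"].status == "neither"
        assert calls["P1"].median_delta == 0.0

    def test_planted_high_patients_recovered(self):
        # 20 signature genes, +1 log2 elevation, per-gene sd 0.5; a minority
        # of high patients so the population-mean reference stays anchored
        expr, meta, truth = sim.simulate_expression(
            n_patients=30, n_genes=20, n_ifn_genes=20, elevation_log2=1.0,
            frac_ifn_high=1 / 3, noise_sd=0.5, patient_sd=0.0, seed=111,
        )
        base = nof1.baseline_matrix(expr, meta)
        sig = GeneSignature("IFN", frozenset(expr.feature_ids))
        calls = nof1.call_signature_status(base, sig)
        status = {c.patient_id: c.status for c in calls}
        high = [p for p, s in truth.patient_status.items() if s == "high"]
        recall = np.mean([status[p] == "high" for p in high])
        assert recall >= 0.95

    def test_signed_rank_p_matches_enumeration(self):
        rng = np.random.default_rng(7)
        for n in (6, 9, 12):
            d = rng.normal(0.3, 1.0, n)
            expr = ExpressionMatrix(pd.DataFrame(
                {"P1": d, "P2": -d / 3, "P3": d * 0.1, "P4": -d},
                index=[f"g{i}" for i in range(n)]))
            sig = GeneSignature("S", frozenset(expr.feature_ids))
            calls = {c.patient_id: c
                     for c in nof1.call_signature_status(expr, sig)}
            block = expr.data
            pop_mean = block.mean(axis=1)
            d1 = (block["P1"] - pop_mean).to_numpy()
            assert calls["P1"].wilcoxon_p == pytest.approx(
                exact_signed_rank_p(d1), rel=1e-10)

    def test_too_few_genes_errors(self):
        expr = ExpressionMatrix(pd.DataFrame(
            np.ones((3, 3)) + np.eye(3), index=["a", "b", "c"],
            columns=["P1", "P2", "P3"]))
        sig = GeneSignature("S", frozenset(["a", "b", "c"]))
        with pytest.raises(ValidationError, match=">=5"):
            nof1.call_signature_status(expr, sig)

    def test_unresolvable_genes_reported(self, small_sim, caplog):
        expr, meta, _ = small_sim
        base = nof1.baseline_matrix(expr, meta)
        sig = GeneSignature("S", frozenset(expr.feature_ids[:10]
                                           + ["NOT_A_GENE"]))
        with caplog.at_level("WARNING", logger="slepd"):
            nof1.call_signature_status(base, sig)
        assert any("NOT_A_GENE" in r.message for r in caplog.records)


class TestTrajectoryPermutation:
    def test_extreme_observed_gives_add_one_floor(self, small_sim):
        _, meta, truth = small_sim
        from slepd.types import ClinicalTrajectory

        calls = calls_from_truth(truth)
        # deterministic separation: high patients improve hugely
        trajs = [
            ClinicalTrajectory(pid, [(0, 25), (2, 25 - drop), (4, 25 - drop),
                                     (12, 25 - drop), (24, 25 - drop)])
            for pid, drop in (
                (p, 20 if s == "high" else 0)
                for p, s in truth.patient_status.items()
            )
        ]
        B = 199
        res = nof1.trajectory_permutation_test(calls, trajs, meta, "bari4mg",
                                               B=B, seed=5)
        assert res.p_value == pytest.approx(1.0 / (B + 1))

    def test_reproducible_and_order_invariant(self, small_sim, truth_calls):
        _, meta, truth = small_sim
        traj = sim.simulate_trajectories(meta, truth, seed=13)
        a = nof1.trajectory_permutation_test(truth_calls, traj, meta,
                                             "bari4mg", B=500, seed=3)
        b = nof1.trajectory_permutation_test(truth_calls[::-1], traj[::-1],
                                             meta, "bari4mg", B=500, seed=3)
        assert a.p_value == b.p_value
        assert a.observed_stat == b.observed_stat
        np.testing.assert_array_equal(a.null_stats, b.null_stats)

    def test_null_p_superuniform_quick(self, small_sim, truth_calls):
        _, meta, truth = small_sim
        rejections = 0
        n_rep = 60
        for rep in range(n_rep):
            traj = sim.simulate_trajectories(meta, truth,
                                             responder_benefit=0.0,
                                             seed=1000 + rep)
            res = nof1.trajectory_permutation_test(
                truth_calls, traj, meta, "bari4mg", B=199, seed=rep)
            rejections += res.p_value <= 0.05
        lo, hi = stats.binom.ppf([0.001, 0.999], n_rep, 0.05)
        assert lo <= rejections <= hi

    def test_invalid_inputs(self, small_sim, truth_calls):
        _, meta, truth = small_sim
        traj = sim.simulate_trajectories(meta, truth, seed=1)
        with pytest.raises(ValidationError, match="B"):
            nof1.trajectory_permutation_test(truth_calls, traj, meta,
                                             "bari4mg", B=0, seed=1)
        only_high = [c for c in truth_calls if c.status == "high"]
        with pytest.raises(ValidationError, match="bari4mg"):
            nof1.trajectory_permutation_test(only_high, traj, meta,
                                             "bari4mg", B=10, seed=1)


class TestLoess:
    def test_linear_trajectories_reproduced_exactly(self, small_sim):
        from slepd.types import ClinicalTrajectory

        _, meta, truth = small_sim
        calls = calls_from_truth(truth)
        trajs = [
            ClinicalTrajectory(p, [(0, 24), (2, 23), (4, 22), (12, 18),
                                   (24, 12)])
            for p in truth.patient_status.index
        ]
        curves = nof1.loess_group_trajectories(calls, trajs, span=0.75)
        for frame in curves.values():
            np.testing.assert_allclose(frame["change"],
                                       -0.5 * frame["week"], atol=1e-6)

    def test_constant_trajectories_give_constant_curve(self, small_sim):
        from slepd.types import ClinicalTrajectory

        _, meta, truth = small_sim
        calls = calls_from_truth(truth)
        trajs = [ClinicalTrajectory(p, [(0, 10), (2, 10), (4, 10), (12, 10),
                                        (24, 10)])
                 for p in truth.patient_status.index]
        curves = nof1.loess_group_trajectories(calls, trajs, span=1.0)
        for frame in curves.values():
            np.testing.assert_allclose(frame["change"], 0.0, atol=1e-9)

    def test_matches_tricube_wls_oracle(self, small_sim):
        _, meta, truth = small_sim
        calls = calls_from_truth(truth)
        traj = sim.simulate_trajectories(meta, truth, seed=17)
        curves = nof1.loess_group_trajectories(calls, traj, span=1.0)

        status = {c.patient_id: c.status for c in calls}
        for group, frame in curves.items():
            pts = [(w, ch) for t in traj if status.get(t.patient_id) == group
                   for w, ch in t.changes_from_baseline().items()]
            x = np.array([p[0] for p in pts], float)
            y = np.array([p[1] for p in pts], float)
            for week, got in zip(frame["week"], frame["change"]):
                d = np.abs(x - week)
                dmax = np.sort(d)[int(np.ceil(1.0 * len(x))) - 1] or 1.0
                w = np.clip(1 - (d / dmax) ** 3, 0, None) ** 3
                X = np.column_stack([np.ones_like(x), x - week])
                beta, *_ = np.linalg.lstsq(np.sqrt(w)[:, None] * X,
                                           np.sqrt(w) * y, rcond=None)
                assert got == pytest.approx(beta[0], abs=1e-8)

    def test_bad_span_errors(self, small_sim, truth_calls):
        _, meta, truth = small_sim
        traj = sim.simulate_trajectories(meta, truth, seed=1)
        with pytest.raises(ValidationError, match="span"):
            nof1.loess_group_trajectories(truth_calls, traj, span=0.0)


def make_cohort(n_both_normal, n_a_only, n_b_only, n_both_high, seed=0):
    """SLE baseline + healthy matrices planting exact joint STAT1/STAT2
    statuses with wide margins around the healthy 95th percentile."""
    rng = np.random.default_rng(seed)
    healthy = ExpressionMatrix(pd.DataFrame(
        {f"H{i}": [v, v] for i, v in enumerate(rng.uniform(5, 7, 50))},
        index=["STAT1", "STAT2"]))
    blocks = [("nn", n_both_normal, (6.0, 6.0)), ("ao", n_a_only, (9.0, 6.0)),
              ("bo", n_b_only, (6.0, 9.0)), ("bb", n_both_high, (9.0, 9.0))]
    cols = {}
    for tag, n, (s1, s2) in blocks:
        for i in range(n):
            cols[f"{tag}{i}"] = [s1 + rng.uniform(-0.5, 0.5),
                                 s2 + rng.uniform(-0.5, 0.5)]
    sle = ExpressionMatrix(pd.DataFrame(cols, index=["STAT1", "STAT2"]))
    return sle, healthy


class TestPercentileClassify:
    def test_interpolated_threshold_formula(self):
        healthy = ExpressionMatrix(pd.DataFrame(
            {f"H{i}": [v, 0.0] for i, v in enumerate(range(1, 101))},
            index=["STAT1", "STAT2"], dtype=float))
        sle = ExpressionMatrix(pd.DataFrame(
            {"P1": [96.0, 1.0], "P2": [95.0, 1.0]},
            index=["STAT1", "STAT2"]))
        _, _, thresholds = nof1.percentile_classify(sle, healthy)
        assert thresholds["STAT1"] == pytest.approx(95.05)

    def test_patient_at_threshold_is_not_high(self):
        healthy = ExpressionMatrix(pd.DataFrame(
            {f"H{i}": [float(i % 5), 0.0] for i in range(20)},
            index=["STAT1", "STAT2"]))
        thr = np.percentile(healthy.data.loc["STAT1"], 95)
        sle = ExpressionMatrix(pd.DataFrame(
            {"AT": [thr, 0.0], "ABOVE": [thr + 1e-9, 0.0]},
            index=["STAT1", "STAT2"]))
        flags, _, _ = nof1.percentile_classify(sle, healthy)
        assert not flags.loc["AT", "STAT1_high"]
        assert flags.loc["ABOVE", "STAT1_high"]

    def test_planted_joint_counts_reproduce(self):
        sle, healthy = make_cohort(56, 5, 34, 174)
        _, table, _ = nof1.percentile_classify(sle, healthy)
        assert (table.n_both_normal, table.n_a_only,
                table.n_b_only, table.n_both_high) == (56, 5, 34, 174)
        assert table.total == 269

    def test_absent_gene_errors(self, small_sim):
        expr, meta, _ = small_sim
        base = nof1.baseline_matrix(expr, meta)
        healthy = nof1.baseline_matrix(expr, meta, group="healthy")
        with pytest.raises(ValidationError, match="STAT1"):
            nof1.percentile_classify(base, healthy)


class TestFisherExact:
    def test_reported_association_example(self):
        odds, p = nof1.fisher_exact_2x2(ContingencyTable2x2(56, 5, 34, 174))
        assert odds == pytest.approx((56 * 174) / (5 * 34), rel=1e-12)
        assert odds == pytest.approx(57.32, abs=0.005)
        assert p < 2.0e-16

    def test_no_association_table(self):
        odds, p = nof1.fisher_exact_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_tables(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            a, b, c, d = rng.integers(0, 11, size=4)
            if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
                continue
            _, p = nof1.fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            assert p == pytest.approx(exact_fisher_p(a, c, b, d), rel=1e-8)

    def test_infinite_odds_and_margin_error(self):
        odds, _ = nof1.fisher_exact_2x2(ContingencyTable2x2(5, 0, 3, 7))
        assert odds == np.inf
        with pytest.raises(ValidationError, match="margin"):
            nof1.fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 7))
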