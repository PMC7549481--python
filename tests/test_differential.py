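import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from slepd import differential as diff
from slepd import simulate as sim
from slepd.types import ExpressionMatrix, SampleMeta, ValidationError


class TestBHQvalues:
    def test_step_down_hand_case(self):
        q = diff.bh_qvalues([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_second_hand_case(self):
        q = diff.bh_qvalues([0.005, 0.04, 0.03])
        np.testing.assert_allclose(q, [0.015, 0.04, 0.04])

    def test_single_p(self):
        np.testing.assert_allclose(diff.bh_qvalues([0.37]), [0.37])

    def test_out_of_range_errors(self):
        with pytest.raises(ValidationError):
            diff.bh_qvalues([0.5, 1.2])
        with pytest.raises(ValidationError):
            diff.bh_qvalues([-0.1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(ps=st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_monotone_and_matches_statsmodels(self, ps):
        from statsmodels.stats.multitest import multipletests

        q = diff.bh_qvalues(ps)
        order = np.argsort(ps, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        _, q_sm, _, _ = multipletests(ps, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, atol=1e-12)


def _two_group_meta(n_h, n_s):
    rows = []
    for i in range(n_h):
        rows.append(dict(sample_id=f"h{i}", patient_id=f"H{i}",
                         group="healthy", visit_week=0, age=40.0, sex="F",
                         log_leucocytes=1.7))
    for i in range(n_s):
        rows.append(dict(sample_id=f"s{i}", patient_id=f"P{i}",
                         group="placebo", visit_week=0, age=40.0, sex="F",
                         log_leucocytes=1.7))
    return SampleMeta(pd.DataFrame(rows))


class TestBaselineDE:
    def test_identical_groups_give_zero_difference_p_one(self):
        meta = _two_group_meta(3, 3)
        vals = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                         [5.0, 6.0, 7.0, 5.0, 6.0, 7.0]])
        expr = ExpressionMatrix(pd.DataFrame(
            vals, index=["G1", "G2"],
            columns=["h0", "h1", "h2", "s0", "s1", "s2"]))
        res = diff.baseline_de(expr, meta)
        np.testing.assert_allclose(res["log2_fold_difference"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_planted_block_tops_ranking(self, small_sim):
        expr, meta, truth = small_sim
        res = diff.baseline_de(expr, meta)
        ifn = set(truth.baseline_elevation[truth.baseline_elevation > 0].index)
        top = set(res.head(len(ifn))["feature_id"])
        assert top == ifn

    def test_type_one_error_on_null_genes(self):
        expr, meta, _ = sim.simulate_expression(
            n_patients=20, n_genes=1000, elevation_log2=0.0,
            pd_effect_log2=0.0, seed=71, n_healthy=30,
        )
        res = diff.baseline_de(expr, meta)
        n_reject = int((res["p"] < 0.05).sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.05)
        assert lo <= n_reject <= hi

    def test_small_group_errors(self):
        meta = _two_group_meta(1, 3)
        expr = ExpressionMatrix(pd.DataFrame(
            np.ones((1, 4)), index=["G1"], columns=["h0", "s0", "s1", "s2"]))
        with pytest.raises(ValidationError, match=">=2"):
            diff.baseline_de(expr, meta)

    def test_top_genes_directions(self):
        meta = _two_group_meta(2, 2)
        expr = ExpressionMatrix(pd.DataFrame(
            [[0.0, 0.0, 5.0, 5.1], [0.0, 0.0, -3.0, -3.1], [0.0, 0.0, 1.0, 1.1]],
            index=["UP", "DOWN", "MID"], columns=["h0", "h1", "s0", "s1"]))
        res = diff.baseline_de(expr, meta)
        assert diff.top_genes(res, 1) == ["UP"]
        assert diff.top_genes(res, 1, "decreased") == ["DOWN"]


class TestMMRM:
    def test_independence_matches_ols(self, small_sim):
        import statsmodels.api as sm

        expr, meta, _ = small_sim
        config = diff.MMRMConfig(covariance="independence")
        fits = diff.fit_mmrm(expr, meta, config,
                             features=expr.feature_ids[:3])
        design = diff._Design(expr, meta, config)
        for fid, fit in fits.items():
            y = expr.data.loc[fid, design.sample_ids].to_numpy()
            ols = sm.OLS(y, design.X).fit()
            np.testing.assert_allclose(fit.params.to_numpy(), ols.params,
                                       atol=1e-4)

    def test_compound_symmetry_matches_diff_in_diff(self):
        # balanced two-visit data, no covariates: the arm:week estimate is
        # the closed-form difference of mean changes vs placebo
        rng = np.random.default_rng(81)
        rows, y = [], []
        for ai, arm in enumerate(["placebo", "bari2mg", "bari4mg"]):
            for i in range(12):
                pid = f"{arm}{i}"
                b = rng.normal(8, 1)
                for w in (0, 12):
                    rows.append(dict(sample_id=f"{pid}_w{w}", patient_id=pid,
                                     group=arm, visit_week=w, age=40.0,
                                     sex="F", log_leucocytes=1.7))
                    y.append(b + (0.5 * ai if w == 12 else 0)
                             + rng.normal(0, 0.5))
        meta = SampleMeta(pd.DataFrame(rows))
        expr = ExpressionMatrix(pd.DataFrame(
            [y, list(np.asarray(y) * 0.5)], index=["G1", "G2"],
            columns=[r["sample_id"] for r in rows]))
        config = diff.MMRMConfig(covariance="compound_symmetry", covariates=())
        fits = diff.fit_mmrm(expr, meta, config)
        f = meta.frame.assign(y=y)
        changes = f.pivot_table(index=["patient_id", "group"],
                                columns="visit_week", values="y",
                                aggfunc="first")
        changes = (changes[12] - changes[0]).groupby(level="group").mean()
        for arm in ("bari2mg", "bari4mg"):
            expected = changes[arm] - changes["placebo"]
            got = diff.pd_contrast(fits["G1"], arm, 12)["estimate"]
            assert got == pytest.approx(expected, abs=1e-6)

    def test_parameter_recovery_quick(self):
        expr, meta, truth = sim.simulate_expression(
            n_patients=60, n_genes=30, n_ifn_genes=30, seed=91
        )
        fits = diff.fit_mmrm(expr, meta)
        ests = [diff.pd_contrast(f, "bari4mg", 12)["estimate"]
                for f in fits.values()]
        assert np.mean(ests) == pytest.approx(-0.5, abs=0.1)

    def test_placebo_self_contrast_exactly_zero(self, small_sim):
        expr, meta, _ = small_sim
        fits = diff.fit_mmrm(expr, meta, features=expr.feature_ids[:1])
        c = diff.pd_contrast(next(iter(fits.values())), "placebo", 12)
        assert c["estimate"] == 0.0 and c["p"] == 1.0

    def test_missing_arm_week_errors(self, small_sim):
        expr, meta, _ = small_sim
        fits = diff.fit_mmrm(expr, meta, features=expr.feature_ids[:1])
        fit = next(iter(fits.values()))
        with pytest.raises(ValidationError):
            diff.pd_contrast(fit, "bari4mg", 7)
        with pytest.raises(ValidationError):
            diff.pd_contrast(fit, "bari9mg", 12)

    def test_qvalues_equal_bruteforce_bh(self, small_sim):
        expr, meta, _ = small_sim
        fits = diff.fit_mmrm(expr, meta, features=expr.feature_ids[:8])
        table = diff.pd_effects_table(fits)
        sub = table[(table["arm"] == "bari4mg") & (table["week"] == 12)]
        np.testing.assert_allclose(sub["q"].to_numpy(),
                                   diff.bh_qvalues(sub["p"].to_numpy()),
                                   atol=1e-12)

    def test_row_order_invariance(self, small_sim):
        expr, meta, _ = small_sim
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.data.shape[1])
        expr_shuffled = ExpressionMatrix(expr.data.iloc[:, perm])
        meta_shuffled = SampleMeta(
            meta.frame.set_index("sample_id")
            .loc[expr_shuffled.sample_ids].reset_index()
        )
        a = diff.fit_mmrm(expr, meta, features=expr.feature_ids[:2])
        b = diff.fit_mmrm(expr_shuffled, meta_shuffled,
                          features=expr.feature_ids[:2])
        for fid in a:
            np.testing.assert_allclose(a[fid].params.to_numpy(),
                                       b[fid].params.to_numpy(), atol=1e-8)

    def test_patients_without_baseline_are_excluded(self, small_sim, caplog):
        expr, meta, _ = small_sim
        pid = meta.sle()["patient_id"].iloc[0]
        frame = meta.frame[~((meta.frame["patient_id"] == pid)
                             & (meta.frame["visit_week"] == 0))]
        meta2 = SampleMeta(frame)
        with caplog.at_level("WARNING", logger="slepd"):
            fits = diff.fit_mmrm(expr, meta2, features=expr.feature_ids[:1])
        fit = next(iter(fits.values()))
        assert fit.n_patients == meta.sle()["patient_id"].nunique() - 1
        assert any("excluded" in r.message for r in caplog.records)
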