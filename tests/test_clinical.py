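"""Signature scoring, stage binning and survival statistics.

The Cox model and the log-rank test are implemented in-package; lifelines
serves as the independent oracle on the same data.
"""

import numpy as np
import pandas as pd
import pytest

from caflineage import clinical, simulate
from caflineage.errors import DataError
from tests.conftest import make_config


def _cohort(expr: np.ndarray, genes, time=None, event=None, stage=None):
    n = expr.shape[0]
    idx = pd.Index([f"B{i}" for i in range(n)], name="sample")
    clin = pd.DataFrame(
        {
            "time": time if time is not None else np.arange(1, n + 1, dtype=float),
            "event": event if event is not None else np.ones(n, dtype=int),
            "stage": stage if stage is not None else ["Stage 1"] * n,
            "age": 60.0,
            "sex": "F",
            "cancer_type": "SYN",
        },
        index=idx,
    )
    return simulate.BulkCohort(
        expression=pd.DataFrame(expr, index=idx, columns=genes), clinical=clin
    )


class TestSignatureScore:
    def test_matches_hand_computed_z_mean(self):
        expr = np.array([[1.0, 10.0, 7.0], [3.0, 20.0, 7.0], [9.0, 5.0, 7.0]])
        cohort = _cohort(expr, ["a", "b", "c"])
        score = clinical.signature_score(cohort, ["a", "b", "c"])
        L = np.log1p(expr[:, :2])  # "c" is constant and dropped
        Z = (L - L.mean(0)) / L.std(0, ddof=1)
        np.testing.assert_allclose(score.to_numpy(), Z.mean(1), atol=1e-12)

    def test_invariant_to_extra_nonsignature_genes(self, rng):
        expr = rng.lognormal(1, 1, size=(20, 6))
        a = _cohort(expr[:, :4], list("abcd"))
        b = _cohort(expr, list("abcdef"))
        s1 = clinical.signature_score(a, ["a", "b"])
        s2 = clinical.signature_score(b, ["a", "b"])
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy())

    def test_uniformly_elevated_sample_has_top_score(self, rng):
        expr = rng.lognormal(1, 0.3, size=(15, 5))
        expr[3] *= 8.0
        score = clinical.signature_score(_cohort(expr, list("abcde")), list("abcde"))
        assert score.idxmax() == "B3"

    def test_missing_genes_and_all_constant_errors(self, rng):
        cohort = _cohort(np.ones((10, 2)), ["a", "b"])
        with pytest.raises(DataError):
            clinical.signature_score(cohort, ["a", "x", "y"])
        with pytest.raises(DataError):
            clinical.signature_score(cohort, ["a", "b"])


class TestCafAbundance:
    def test_correlates_with_planted_signature(self):
        cfg = make_config(5, bulk_n=300).synthetic
        cohort, s = simulate.generate_bulk_cohort(cfg)
        rng = np.random.default_rng(cfg.seed)
        bp = simulate._Blueprint(cfg, rng)
        panel = sorted(
            set(bp.programs["lineage"]) - {p[1] for p in cfg.lr_pairs_planted}
        ) + [cfg.marker_gene_id]
        ab = clinical.caf_abundance(cohort, panel)
        from scipy.stats import spearmanr

        assert spearmanr(ab, s.loc[ab.index]).statistic >= 0.8
        noise_panel = [g for g in cohort.expression.columns if g.startswith("G14")][:20]
        ab0 = clinical.caf_abundance(cohort, noise_panel)
        assert abs(spearmanr(ab0, s).statistic) < 0.15

    def test_empty_panel_error(self, rng):
        with pytest.raises(DataError):
            clinical.caf_abundance(_cohort(np.ones((5, 2)), ["a", "b"]), [])


class TestStage:
    @pytest.mark.parametrize(
        "label,expected",
        [("Stage 1", "low"), ("Stage 2", "low"), ("LOW", "low"),
         ("Stage 3", "high"), ("Stage 4", "high"), ("HIGH", "high")],
    )
    def test_binning(self, label, expected):
        assert clinical.bin_stage(label) == expected

    def test_unknown_label_error_lists_accepted(self):
        with pytest.raises(DataError, match="Stage 1"):
            clinical.bin_stage("Stage X")

    def test_subtype_proportions(self):
        table = pd.DataFrame(
            {
                "fib_class": ["CAF"] * 150 + ["NF"] * 10,
                "stage": ["Stage 3"] * 120 + ["Stage 1"] * 40,
                "subtype": ["GJB2+"] * 30 + ["ST1"] * 130,
            }
        )
        out = clinical.subtype_proportion_by_stage(table, "GJB2+")
        assert out.loc["high", "proportion"] == pytest.approx(30 / 120)
        assert out.loc["high", "n_caf"] == 120
        assert out["n_caf"].sum() == 150


TOY_TIMES = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
TOY_EVENTS = np.ones(6, dtype=int)
TOY_GROUPS = np.array(["A", "A", "A", "B", "B", "B"])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.r_[TOY_TIMES, TOY_TIMES]
        e = np.r_[TOY_EVENTS, TOY_EVENTS]
        g = np.r_[["A"] * 6, ["B"] * 6]
        stat, p = clinical.logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_toy_data_matches_hand_computation_and_lifelines(self):
        stat, p = clinical.logrank_test(TOY_TIMES, TOY_EVENTS, TOY_GROUPS)
        # O-E for group A over event times 1..6: 1-1/2, 1-2/5... A fails first
        o_minus_e = (1 - 3 / 6) + (1 - 2 / 5) + (1 - 1 / 4)
        v = (
            (3 / 6) * (3 / 6)
            + (2 / 5) * (3 / 5)
            + (1 / 4) * (3 / 4)
            + (0 / 3) * 1
            + 0
            + 0
        )
        assert stat == pytest.approx(o_minus_e**2 / v, abs=1e-12)
        from lifelines.statistics import logrank_test as ll_logrank

        ref = ll_logrank(TOY_TIMES[:3], TOY_TIMES[3:], TOY_EVENTS[:3], TOY_EVENTS[3:])
        assert stat == pytest.approx(ref.test_statistic, abs=1e-10)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_invariant_to_time_rescaling(self, rng):
        t = rng.exponential(10, size=40)
        e = rng.integers(0, 2, size=40)
        e[0] = 1
        g = np.repeat(["A", "B"], 20)
        s1, _ = clinical.logrank_test(t, e, g)
        s2, _ = clinical.logrank_test(37.5 * t, e, g)
        assert s1 == pytest.approx(s2, abs=1e-12)


class TestCox:
    def test_constant_covariate_rejected(self):
        with pytest.raises(DataError, match="constant"):
            clinical.cox_ph(
                TOY_TIMES, TOY_EVENTS, pd.DataFrame({"z": np.zeros(6)})
            )

    def test_score_test_equals_logrank_on_toy_data(self):
        x = (TOY_GROUPS == "A").astype(float)
        stat, _ = clinical.cox_score_test(TOY_TIMES, TOY_EVENTS, x)
        lr_stat, _ = clinical.logrank_test(TOY_TIMES, TOY_EVENTS, TOY_GROUPS)
        assert stat == pytest.approx(lr_stat, abs=1e-8)

    def test_binary_covariate_matches_grid_search_oracle(self, rng):
        t = rng.exponential(1.0, size=60) * np.where(np.arange(60) < 30, 1.0, 0.5)
        t += rng.uniform(0, 1e-6, size=60)  # no ties
        e = np.ones(60, dtype=int)
        x = (np.arange(60) >= 30).astype(float)

        def neg_pl(beta):  # Breslow partial likelihood, 1-D
            order = np.argsort(t)
            xs = x[order]
            eta = beta * xs
            ll = 0.0
            for i in range(60):
                ll += eta[i] - np.log(np.exp(eta[i:]).sum())
            return -ll

        from scipy.optimize import minimize_scalar

        opt = minimize_scalar(neg_pl, bounds=(-3, 3), method="bounded",
                              options={"xatol": 1e-10})
        res = clinical.cox_ph(t, e, pd.DataFrame({"x": x}))
        assert res.table.loc["x", "beta"] == pytest.approx(opt.x, abs=1e-6)

    def test_matches_lifelines_multivariate(self, rng):
        n = 150
        X = pd.DataFrame(
            {"a": rng.normal(size=n), "b": rng.integers(0, 2, n).astype(float)}
        )
        t = np.asarray(rng.exponential(1.0 / np.exp(0.5 * X["a"] - 0.3 * X["b"])))
        e = (rng.random(n) > 0.2).astype(int)
        res = clinical.cox_ph(t, e, X)
        from lifelines import CoxPHFitter

        df = X.assign(time=t, event=e)
        cph = CoxPHFitter().fit(df, "time", "event")
        np.testing.assert_allclose(
            res.table["beta"].to_numpy(), cph.params_[["a", "b"]].to_numpy(), atol=1e-5
        )
        np.testing.assert_allclose(
            res.table["se"].to_numpy(),
            cph.standard_errors_[["a", "b"]].to_numpy(),
            atol=1e-5,
        )


class TestSurvivalBySignature:
    def test_planted_hazard_detected_and_median_split_sizes(self):
        cfg = make_config(3, bulk_n=400, hazard_beta=1.0).synthetic
        cohort, s = simulate.generate_bulk_cohort(cfg)
        score = pd.Series(s, index=cohort.clinical.index, name="score")
        out = clinical.survival_by_signature(cohort, score)
        assert out["logrank_p"] < 0.05
        sizes = out["groups"].value_counts()
        assert abs(sizes["high"] - sizes["low"]) <= 1
        assert out["cox_continuous"].table.loc["score", "p"] < 0.05
        assert out["cox_continuous"].table.loc["score", "beta"] > 0

    def test_split_rules(self):
        cfg = make_config(4, bulk_n=200).synthetic
        cohort, s = simulate.generate_bulk_cohort(cfg)
        score = pd.Series(s, index=cohort.clinical.index)
        tert = clinical.survival_by_signature(cohort, score, split_rule="tertile-extremes")
        assert set(tert["groups"].unique()) == {"high", "low"}
        cont = clinical.survival_by_signature(cohort, score, split_rule="continuous")
        assert "logrank_p" not in cont
        with pytest.raises(DataError):
            clinical.survival_by_signature(cohort, score, split_rule="quartiles")


class TestGroupCompare:
    def test_exact_mann_whitney(self):
        stat, p = clinical.group_compare([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        _, p = clinical.group_compare([1.0, 2, 3], [1.0, 2, 3])
        assert p == pytest.approx(1.0)

    def test_t_test_and_zero_variance_error(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(2, 1, 30)
        _, p = clinical.group_compare(a, b, method="t")
        assert p < 0.01
        with pytest.raises(DataError):
            clinical.group_compare([1.0, 1.0], [2.0, 2.0], method="t")

    def test_high_stage_has_higher_scores_on_planted_cohort(self):
        cfg = make_config(9, bulk_n=500).synthetic
        cohort, s = simulate.generate_bulk_cohort(cfg)
        high = cohort.clinical["stage"].map(clinical.bin_stage) == "high"
        stat, p = clinical.group_compare(s[high], s[~high])
        assert p < 0.05 and s[high].mean() > s[~high].mean()
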