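"""Moderated differential tests, core features, promoter correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neomix.differential import (
    ModerationPrior,
    core_features,
    estimate_moderation_prior,
    expr_meth_correlation,
    fit_moderated_pairwise,
    map_cpgs_to_promoters,
    squeeze_variances,
)


def _two_group_matrix(rng, n_features=40, n_per=6, effect=None):
    cols = [f"s{i}" for i in range(2 * n_per)]
    values = pd.DataFrame(
        rng.normal(size=(n_features, 2 * n_per)),
        index=[f"f{i}" for i in range(n_features)], columns=cols,
    )
    if effect:
        for feat, delta in effect.items():
            values.loc[feat, cols[n_per:]] += delta
    groups = pd.Series(["a"] * n_per + ["b"] * n_per, index=cols)
    return values, groups


class TestModeratedFit:
    def test_unmoderated_reduces_to_classical_t(self, rng):
        values, groups = _two_group_matrix(rng)
        res = fit_moderated_pairwise(values, groups, theta=0.0, d0_override=0.0)[("a", "b")]
        for f in values.index:
            t, p = stats.ttest_ind(values.loc[f].iloc[6:], values.loc[f].iloc[:6], equal_var=True)
            assert res.loc[f, "t"] == pytest.approx(t, abs=1e-10)
            assert res.loc[f, "p"] == pytest.approx(p, abs=1e-10)

    def test_threshold_shrinks_the_statistic_by_theta_over_se(self, rng):
        values, groups = _two_group_matrix(rng, effect={"f0": 4.0})
        r0 = fit_moderated_pairwise(values, groups, theta=0.0, d0_override=0.0)[("a", "b")]
        r2 = fit_moderated_pairwise(values, groups, theta=2.0, d0_override=0.0)[("a", "b")]
        f = "f0"
        expected = abs(r0.loc[f, "t"]) - 2.0 / r0.loc[f, "se"]
        assert abs(r2.loc[f, "t"]) == pytest.approx(expected, abs=1e-10)

    def test_effect_below_threshold_has_zero_statistic_and_unit_p(self, rng):
        values, groups = _two_group_matrix(rng, effect={"f0": 0.5})
        res = fit_moderated_pairwise(values, groups, theta=2.0, d0_override=0.0)[("a", "b")]
        small = res[res["b"].abs() < 2.0]
        assert (small["t"] == 0).all()
        assert (small["p"] == 1.0).all()

    def test_significant_set_shrinks_as_theta_grows(self, rng):
        effects = {f"f{i}": 3.0 + i * 0.2 for i in range(10)}
        values, groups = _two_group_matrix(rng, n_features=60, n_per=10, effect=effects)
        previous = None
        for theta in (2.0, 1.0, 0.0):
            res = fit_moderated_pairwise(values, groups, theta=theta)[("a", "b")]
            sig = set(res[res["q"] < 0.05].index)
            if previous is not None:
                assert previous <= sig
            previous = sig

    def test_covariable_adjustment_removes_confounded_batch_effect(self, rng):
        """Batch is imbalanced across groups; a pure batch effect masquerades
        as a group effect unless the covariable enters the design."""
        values, groups = _two_group_matrix(rng, n_features=30, n_per=8)
        batch = pd.Series(["x"] * 8 + ["x"] * 4 + ["y"] * 4, index=values.columns)
        confounded = [f"f{i}" for i in range(10)]
        values.loc[confounded, (batch == "y").to_numpy()] += 5.0
        plain = fit_moderated_pairwise(values, groups, theta=0.0)[("a", "b")]
        adjusted = fit_moderated_pairwise(
            values, groups, covariables=batch.to_frame("batch"), theta=0.0
        )[("a", "b")]
        # unadjusted: the batch shift leaks into the group effect estimate
        assert plain.loc[confounded, "b"].mean() > 1.5
        # adjusted: the batch term absorbs the shift and its variance
        assert adjusted.loc[confounded, "b"].abs().mean() < 0.75
        assert (adjusted.loc[confounded, "se"] < plain.loc[confounded, "se"]).all()
        assert (adjusted.loc[confounded, "q"] < 0.05).sum() <= 2

    def test_null_simulation_controls_fdr(self):
        rng = np.random.default_rng(5)
        rates = []
        for _ in range(10):
            values, groups = _two_group_matrix(rng, n_features=2000, n_per=6)
            res = fit_moderated_pairwise(values, groups, theta=0.0)[("a", "b")]
            rates.append((res["q"] < 0.05).mean())
        assert np.mean(rates) <= 0.05

    def test_group_with_single_sample_skipped(self, rng):
        values, groups = _two_group_matrix(rng)
        groups = groups.copy()
        groups.iloc[0] = "c"  # singleton level
        res = fit_moderated_pairwise(values, groups)
        assert ("a", "b") in res
        assert all("c" not in pair for pair in res)


class TestModerationPrior:
    def test_d0_zero_returns_raw_variances(self, rng):
        s2 = rng.chisquare(5, size=100) / 5
        out = squeeze_variances(s2, 5, ModerationPrior(1.0, 0.0))
        assert np.allclose(out, s2)

    def test_d0_infinite_collapses_to_prior(self, rng):
        s2 = rng.chisquare(5, size=100) / 5
        out = squeeze_variances(s2, 5, ModerationPrior(1.3, np.inf))
        assert np.allclose(out, 1.3)

    def test_estimated_prior_recovers_scaled_f_parameters(self):
        """Variances drawn from the scaled-F model (s0^2=2, d0=8) are
        recovered by the moment-matching estimator."""
        rng = np.random.default_rng(6)
        d, d0, s0sq = 6, 8.0, 2.0
        true_var = s0sq * d0 / rng.chisquare(d0, size=20000)
        s2 = true_var * rng.chisquare(d, size=20000) / d
        prior = estimate_moderation_prior(s2, d)
        assert prior.d0 == pytest.approx(d0, rel=0.15)
        assert prior.s0_squared == pytest.approx(s0sq, rel=0.1)

    def test_homogeneous_variances_give_infinite_prior_df(self, rng):
        s2 = np.full(500, 2.0) * rng.chisquare(10, 500) / 10
        prior = estimate_moderation_prior(s2, 10)
        assert np.isinf(prior.d0)


class TestCoreFeatures:
    def _result(self, features, bs, qs):
        return pd.DataFrame({"b": bs, "q": qs}, index=features)

    def test_intersection_rule_on_paper_style_example(self):
        pairwise = {
            ("A", "B"): self._result(["g1", "g2", "g3"], [-1, -2, -1], [0.01, 0.01, 0.5]),
            ("A", "C"): self._result(["g1", "g2", "g3"], [-1, -2, -2], [0.9, 0.01, 0.01]),
        }
        # significant vs B: {g1, g2}; vs C: {g2, g3}; intersection: {g2}
        assert core_features(pairwise, "A") == {"g2"}

    def test_empty_pairwise_set_gives_empty_core(self):
        pairwise = {
            ("A", "B"): self._result(["g1"], [2.0], [0.9]),
            ("A", "C"): self._result(["g1"], [2.0], [0.001]),
        }
        assert core_features(pairwise, "A") == set()

    def test_direction_consistency_required_by_default(self):
        pairwise = {
            ("A", "B"): self._result(["g1"], [+3.0], [0.001]),
            ("A", "C"): self._result(["g1"], [-3.0], [0.001]),
        }
        assert core_features(pairwise, "A") == set()
        assert core_features(pairwise, "A", require_direction=False) == {"g1"}

    def test_missing_pair_raises(self):
        pairwise = {("A", "B"): self._result(["g1"], [1.0], [0.01]),
                    ("B", "C"): self._result(["g1"], [1.0], [0.01])}
        with pytest.raises(ValueError):
            core_features(pairwise, "A")

    def test_planted_group_specific_genes_recovered(self):
        """Genes shifted only in the focal group are core; the core set is
        (almost) a subset of the focal-vs-rest differential set."""
        rng = np.random.default_rng(8)
        n_per, p = 12, 300
        cols = [f"s{i}" for i in range(3 * n_per)]
        values = pd.DataFrame(rng.normal(size=(p, 3 * n_per)),
                              index=[f"g{i}" for i in range(p)], columns=cols)
        planted = [f"g{i}" for i in range(15)]
        values.loc[planted, cols[:n_per]] += 4.0  # specific to group A
        groups = pd.Series(["A"] * n_per + ["B"] * n_per + ["C"] * n_per, index=cols)
        pairwise = fit_moderated_pairwise(values, groups, theta=1.0)
        core = core_features(pairwise, "A")
        assert set(planted) <= core
        rest = pd.Series(np.where(groups == "A", "A", "rest"), index=cols)
        vs_rest = fit_moderated_pairwise(values, rest, theta=1.0)[("A", "rest")]
        rest_sig = set(vs_rest[vs_rest["q"] < 0.05].index)
        assert len(core & rest_sig) / len(core) >= 0.9


class TestPromoterMapping:
    def _tables(self):
        cpgs = pd.DataFrame({
            "feature": ["cg1", "cg2", "cg3", "cg4"],
            "chrom": ["1", "1", "1", "2"],
            "position": [12000, 12001, 8000, 12000],
        })
        tss = pd.DataFrame({
            "feature": ["geneA"], "chrom": ["1"], "position": [10000],
        })
        return cpgs, tss

    def test_window_boundary_inclusive_at_2000(self):
        cpgs, tss = self._tables()
        mapping = map_cpgs_to_promoters(cpgs, tss, window=2000)
        mapped = set(mapping["cpg"])
        assert "cg1" in mapped       # distance exactly 2000
        assert "cg2" not in mapped   # 2001
        assert "cg3" in mapped       # -2000
        assert "cg4" not in mapped   # wrong chromosome

    def test_matches_all_pairs_distance_oracle(self, rng):
        cpgs = pd.DataFrame({
            "feature": [f"cg{i}" for i in range(60)],
            "chrom": rng.choice(["1", "2", "3"], 60),
            "position": rng.integers(0, 50000, 60),
        })
        tss = pd.DataFrame({
            "feature": [f"g{i}" for i in range(20)],
            "chrom": rng.choice(["1", "2", "3"], 20),
            "position": rng.integers(0, 50000, 20),
        })
        mapping = map_cpgs_to_promoters(cpgs, tss, window=2000)
        got = set(map(tuple, mapping[["cpg", "gene"]].to_numpy()))
        oracle = {
            (c.feature, g.feature)
            for c in cpgs.itertuples() for g in tss.itertuples()
            if c.chrom == g.chrom and abs(c.position - g.position) <= 2000
        }
        assert got == oracle


class TestExprMethCorrelation:
    def test_planted_methylation_driven_gene_retained_with_negative_sign(self, rng):
        n = 40
        beta_vals = rng.uniform(0.1, 0.9, n)
        expr_vals = 10 - 8 * beta_vals + rng.normal(0, 0.1, n)
        cols = [f"s{i}" for i in range(n)]
        expr = pd.DataFrame([expr_vals], index=["geneA"], columns=cols)
        beta = pd.DataFrame([beta_vals], index=["cg1"], columns=cols)
        mapping = pd.DataFrame({"cpg": ["cg1"], "gene": ["geneA"]})
        out = expr_meth_correlation(expr, beta, mapping)
        assert list(out["gene"]) == ["geneA"]
        assert out.iloc[0]["direction"] == "negative"

    def test_low_iqr_pair_rejected_despite_strong_correlation(self, rng):
        n = 40
        beta_vals = rng.uniform(0.45, 0.55, n)  # IQR << 0.25
        expr_vals = 10 - 20 * beta_vals + rng.normal(0, 0.05, n)
        cols = [f"s{i}" for i in range(n)]
        expr = pd.DataFrame([expr_vals], index=["geneA"], columns=cols)
        beta = pd.DataFrame([beta_vals], index=["cg1"], columns=cols)
        mapping = pd.DataFrame({"cpg": ["cg1"], "gene": ["geneA"]})
        out = expr_meth_correlation(expr, beta, mapping)
        assert len(out) == 0

    def test_pearson_matches_closed_form_on_five_points(self):
        b = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        e = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        expr = pd.DataFrame([e], index=["g"], columns=list("abcde"))
        beta = pd.DataFrame([b], index=["c1"], columns=list("abcde"))
        mapping = pd.DataFrame({"cpg": ["c1"], "gene": ["g"]})
        out = expr_meth_correlation(beta=beta, expression=expr, mapping=mapping,
                                    q_max=1.1, r2_min=-1, iqr_min=0)
        r_oracle = np.sum((b - b.mean()) * (e - e.mean())) / np.sqrt(
            np.sum((b - b.mean()) ** 2) * np.sum((e - e.mean()) ** 2))
        assert out.iloc[0]["r"] == pytest.approx(r_oracle, abs=1e-12)

    def test_smallest_q_cpg_reported_per_gene(self, rng):
        n = 30
        cols = [f"s{i}" for i in range(n)]
        beta1 = rng.uniform(0.1, 0.9, n)
        expr_vals = 5 - 4 * beta1 + rng.normal(0, 0.05, n)   # strong partner
        beta2 = np.clip(beta1 + rng.normal(0, 0.4, n), 0.01, 0.99)  # weak partner
        expr = pd.DataFrame([expr_vals], index=["g"], columns=cols)
        beta = pd.DataFrame([beta1, beta2], index=["cgS", "cgW"], columns=cols)
        mapping = pd.DataFrame({"cpg": ["cgS", "cgW"], "gene": ["g", "g"]})
        out = expr_meth_correlation(expr, beta, mapping, r2_min=0.1)
        assert len(out) == 1 and out.iloc[0]["cpg"] == "cgS"
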