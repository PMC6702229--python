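"""Joint factor model: SVD equivalence, missing-block recovery, associations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neomix.factors import (
    FactorModel,
    associate_factors_with_covariates,
    associate_factors_with_mutations,
    factor_stability,
    fit_joint_factors,
    loading_set_enrichment,
    principal_angles,
    select_factors,
    standardize_block,
    variance_explained,
)


def _blocks_from(x1, x2, cols=None):
    cols = cols or [f"s{i}" for i in range(x1.shape[1])]
    b1 = pd.DataFrame(x1, index=[f"a{i}" for i in range(x1.shape[0])], columns=cols)
    b2 = pd.DataFrame(x2, index=[f"b{i}" for i in range(x2.shape[0])], columns=cols)
    return {"one": b1, "two": b2}


def _centred(rng, p, n):
    x = rng.normal(size=(p, n))
    return x - x.mean(axis=1, keepdims=True)


class TestFit:
    def test_equals_truncated_svd_oracle_without_missing_data(self, rng):
        # well-separated spectrum so the factor ordering is unambiguous
        u0 = np.linalg.qr(rng.normal(size=(50, 4)))[0]
        v0 = np.linalg.qr(rng.normal(size=(15, 4)))[0]
        x = (u0 * [8.0, 4.0, 2.0, 1.0]) @ v0.T + rng.normal(0, 0.01, size=(50, 15))
        x -= x.mean(axis=1, keepdims=True)
        x1, x2 = x[:30], x[30:]
        model = fit_joint_factors(_blocks_from(x1, x2), K=4, tol=1e-10)
        stacked = np.vstack([x1, x2])
        u, s, vt = np.linalg.svd(stacked, full_matrices=False)
        z_oracle = vt[:4].T * s[:4]
        w_oracle = u[:, :4]
        w_fit = np.vstack([model.W["one"].to_numpy(), model.W["two"].to_numpy()])
        for k in range(4):
            # sign-invariant comparison per factor
            sign = np.sign(w_fit[:, k] @ w_oracle[:, k])
            assert np.allclose(w_fit[:, k], sign * w_oracle[:, k], atol=1e-8)
            assert np.allclose(model.Z.to_numpy()[:, k], sign * z_oracle[:, k], atol=1e-8)

    def test_rank_one_data_has_full_varexp_on_factor_one(self, rng):
        w = rng.normal(size=10)
        z = rng.normal(size=8)
        x = np.outer(w, z)
        x -= x.mean(axis=1, keepdims=True)
        blocks = {"only": pd.DataFrame(x, columns=[f"s{i}" for i in range(8)])}
        model = fit_joint_factors(blocks, K=2)
        assert model.varexp.loc["only", "LF1"] == pytest.approx(1.0, abs=1e-10)

    def test_missing_block_score_recovered_by_projection(self, rng):
        """Noiseless rank-2 data; one sample lacks block two; its score must
        match the closed-form least-squares projection from block one."""
        k = 2
        w1, w2 = rng.normal(size=(40, k)), rng.normal(size=(30, k))
        z = rng.normal(size=(12, k)) * [3.0, 2.0]
        x1, x2 = w1 @ z.T, w2 @ z.T
        blocks = _blocks_from(x1, x2)
        blocks["two"] = blocks["two"].drop(columns=["s5"])
        model = fit_joint_factors(blocks, K=k, tol=1e-12, max_iter=500)
        w_fit = model.W["one"].to_numpy()
        oracle, *_ = np.linalg.lstsq(w_fit, blocks["one"]["s5"].to_numpy(), rcond=None)
        assert np.allclose(model.Z.loc["s5"].to_numpy(), oracle, atol=1e-6)
        # and the recovered score reproduces the withheld block
        recon = model.W["two"].to_numpy() @ model.Z.loc["s5"].to_numpy()
        assert np.allclose(recon, x2[:, 5], atol=1e-6)

    def test_k_at_rank_bound_rejected(self, rng):
        blocks = _blocks_from(_centred(rng, 5, 4), _centred(rng, 5, 4))
        with pytest.raises(ValueError):
            fit_joint_factors(blocks, K=4)

    def test_reconstruction_error_non_increasing(self, rng):
        x1, x2 = _centred(rng, 25, 12), _centred(rng, 25, 12)
        blocks = _blocks_from(x1, x2)
        blocks["two"] = blocks["two"].drop(columns=["s0", "s1"])
        model = fit_joint_factors(blocks, K=3, tol=1e-12, max_iter=60)
        errs = np.array(model.error_history)
        assert np.all(np.diff(errs) <= 1e-10)

    def test_varexp_invariant_to_sample_permutation(self, rng):
        x1, x2 = _centred(rng, 20, 10), _centred(rng, 15, 10)
        blocks = _blocks_from(x1, x2)
        model = fit_joint_factors(blocks, K=3)
        perm = [f"s{i}" for i in [4, 2, 0, 1, 3, 9, 8, 7, 6, 5]]
        shuffled = {k: v[perm] for k, v in blocks.items()}
        model_p = fit_joint_factors(shuffled, K=3)
        assert np.allclose(
            model.varexp.to_numpy(), model_p.varexp.to_numpy(), atol=1e-10
        )


class TestVarianceExplained:
    def test_sums_to_one_when_k_equals_rank(self, rng):
        k = 3
        w = np.linalg.qr(rng.normal(size=(20, k)))[0]
        z = rng.normal(size=(10, k)) * [4, 2, 1]
        x = w @ z.T
        x -= x.mean(axis=1, keepdims=True)
        blocks = {"b": pd.DataFrame(x, columns=[f"s{i}" for i in range(10)])}
        model = fit_joint_factors(blocks, K=k)
        assert model.varexp.sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_block_specific_factor_explains_nothing_elsewhere(self, rng):
        # orthogonal scores and loadings so the SVD axes align with the
        # planted shared/specific factors
        z = np.linalg.qr(rng.normal(size=(12, 2)))[0]
        z_shared, z_only1 = 4 * z[:, 0], 3 * z[:, 1]
        w = np.linalg.qr(rng.normal(size=(20, 2)))[0]
        x1 = np.outer(w[:, 0], z_shared) + np.outer(w[:, 1], z_only1)
        x2 = np.outer(rng.normal(size=20), z_shared)
        model = fit_joint_factors(_blocks_from(x1, x2), K=2)
        # one factor is (nearly) specific to block one
        specific = model.varexp.loc["two"].min()
        assert specific < 0.02

    def test_matches_residual_ss_oracle(self, rng):
        x1, x2 = _centred(rng, 15, 9), _centred(rng, 10, 9)
        blocks = _blocks_from(x1, x2)
        model = fit_joint_factors(blocks, K=3)
        ve = variance_explained(model, blocks)
        for name, x in (("one", x1), ("two", x2)):
            w = model.W[name].to_numpy()
            z = model.Z.to_numpy()
            resid = x - w @ z.T
            oracle = 1.0 - np.sum(resid**2) / np.sum(x**2)
            assert ve.loc[name].sum() == pytest.approx(oracle, abs=1e-8)


class TestSelectFactors:
    def _model(self, varexp_rows):
        ve = pd.DataFrame(varexp_rows, index=["e", "m"])
        k = ve.shape[1]
        ve.columns = [f"LF{i + 1}" for i in range(k)]
        z = pd.DataFrame(np.zeros((4, k)), columns=ve.columns)
        w = {b: pd.DataFrame(np.zeros((3, k)), columns=ve.columns) for b in ("e", "m")}
        return FactorModel(Z=z, W=w, varexp=ve)

    def test_factor_below_threshold_in_both_blocks_dropped(self):
        model = self._model([[0.30, 0.019], [0.25, 0.018]])
        assert select_factors(model).factors == ["LF1"]

    def test_factor_reaching_threshold_in_one_block_kept(self):
        model = self._model([[0.30, 0.019], [0.25, 0.021]])
        assert select_factors(model).factors == ["LF1", "LF2"]

    def test_zero_threshold_is_identity(self):
        model = self._model([[0.30, 0.001], [0.25, 0.002]])
        assert select_factors(model, min_varexp=0.0).factors == ["LF1", "LF2"]

    def test_all_dropped_raises(self):
        model = self._model([[0.001, 0.001], [0.001, 0.001]])
        with pytest.raises(ValueError):
            select_factors(model)


class TestStability:
    def test_clean_data_gives_unit_matched_correlations(self, rng):
        x1, x2 = _centred(rng, 20, 12), _centred(rng, 15, 12)
        corr = factor_stability(_blocks_from(x1, x2), K=2, n_runs=3, seed=0)
        # no missing data: the fit is deterministic, every matched pair is 1
        for f in ("LF1", "LF2"):
            assert corr.loc[f"run1:{f}", f"run2:{f}"] == pytest.approx(1.0, abs=1e-9)

    def test_summary_symmetric_with_unit_diagonal(self, rng):
        x1, x2 = _centred(rng, 20, 12), _centred(rng, 15, 12)
        blocks = _blocks_from(x1, x2)
        blocks["two"] = blocks["two"].drop(columns=["s0"])
        corr = factor_stability(blocks, K=2, n_runs=3, seed=1)
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)

    def test_planted_orthogonal_factors_nearly_uncorrelated_within_run(self, rng):
        z = rng.normal(size=(40, 2)) * [5, 3]
        w1, w2 = rng.normal(size=(60, 2)), rng.normal(size=(50, 2))
        x1 = w1 @ z.T + rng.normal(0, 0.05, size=(60, 40))
        x2 = w2 @ z.T + rng.normal(0, 0.05, size=(50, 40))
        x1 -= x1.mean(axis=1, keepdims=True)
        x2 -= x2.mean(axis=1, keepdims=True)
        corr = factor_stability(_blocks_from(x1, x2), K=2, n_runs=2, seed=2)
        assert corr.loc["run1:LF1", "run1:LF2"] < 0.2


class TestSubspaceRecovery:
    def test_fitted_factors_align_with_planted_subspace(self, default_cohort, default_blocks, default_model):
        """Principal angles between the fitted leading factor plane and the
        planted cluster-separating score plane stay below 5 degrees."""
        truth = default_cohort.truth.set_index("sample")
        both = [s for s in default_model.Z.index
                if s in default_cohort.expression.columns
                and s in default_cohort.methylation.columns]
        z_true = truth.loc[both, ["factor1", "factor2"]].to_numpy()
        z_true = z_true - z_true.mean(axis=0)
        z_fit = default_model.Z.loc[both, ["LF1", "LF2"]].to_numpy()
        angles = principal_angles(z_fit, z_true)
        assert angles.max() < 5.0


class TestAssociations:
    def test_factor_equal_to_covariable_coding_is_significant(self, rng):
        n = 60
        sex = rng.choice(["male", "female"], size=n)
        clin = pd.DataFrame({
            "sample": [f"s{i}" for i in range(n)],
            "sex": sex,
            "age": rng.normal(60, 8, size=n).round(1),
        })
        z = (sex == "male").astype(float) + rng.normal(0, 0.01, n)
        model = FactorModel(
            Z=pd.DataFrame({"LF1": z}, index=clin["sample"]),
            W={}, varexp=pd.DataFrame({"LF1": [1.0]}, index=["e"]),
        )
        table = associate_factors_with_covariates(model, clin, ["sex", "age"])
        sex_row = table[table["covariable"].str.contains("sex")]
        assert (sex_row["q"] < 1e-10).all()

    def test_bh_adjustment_matches_textbook_oracle(self, rng):
        n = 60
        clin = pd.DataFrame({
            "sample": [f"s{i}" for i in range(n)],
            "sex": rng.choice(["male", "female"], size=n),
            "stage": rng.choice(["I", "II"], size=n),
        })
        z = pd.DataFrame(rng.normal(size=(n, 3)), index=clin["sample"],
                         columns=["LF1", "LF2", "LF3"])
        model = FactorModel(Z=z, W={}, varexp=pd.DataFrame(
            np.ones((1, 3)) / 3, index=["e"], columns=z.columns))
        table = associate_factors_with_covariates(model, clin, ["sex", "stage"])
        p = table["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        oracle = np.minimum.accumulate(ranked[::-1])[::-1]
        oracle = np.minimum(oracle, 1.0)
        assert np.allclose(table["q"].to_numpy()[order], oracle, atol=1e-12)

    def test_independent_noise_factor_false_positive_rate_controlled(self):
        """Type-I check: over 60 replicates of a pure-noise factor, the rate
        of q<0.05 flags stays at or below the nominal level."""
        flagged = 0
        total = 0
        rng = np.random.default_rng(7)
        n = 50
        for _ in range(60):
            clin = pd.DataFrame({
                "sample": [f"s{i}" for i in range(n)],
                "sex": rng.choice(["male", "female"], size=n),
                "smoking": rng.choice(["smoker", "non-smoker"], size=n),
            })
            z = pd.DataFrame({"LF1": rng.normal(size=n)}, index=clin["sample"])
            model = FactorModel(Z=z, W={}, varexp=pd.DataFrame({"LF1": [1.0]}, index=["e"]))
            table = associate_factors_with_covariates(model, clin, ["sex", "smoking"])
            flagged += int(table["significant"].sum())
            total += len(table)
        assert flagged / total <= 0.05


class TestMutationAssociations:
    def _model_with_gradient(self, n=40):
        z = pd.DataFrame({"LF1": np.linspace(-2, 2, n)},
                         index=[f"s{i}" for i in range(n)])
        return FactorModel(Z=z, W={}, varexp=pd.DataFrame({"LF1": [1.0]}, index=["e"]))

    def test_planted_association_detected(self):
        model = self._model_with_gradient()
        mut = pd.DataFrame(0, index=["gA"], columns=model.Z.index)
        mut.loc["gA", model.Z.index[-6:]] = 1  # mutations in top-coordinate samples
        table = associate_factors_with_mutations(model, mut)
        assert table.iloc[0]["q"] < 0.01
        assert table.iloc[0]["t"] > 0

    def test_gene_below_recurrence_threshold_absent(self):
        model = self._model_with_gradient()
        mut = pd.DataFrame(0, index=["gA", "gB"], columns=model.Z.index)
        mut.loc["gA", model.Z.index[:2]] = 1   # only 2 mutated samples
        mut.loc["gB", model.Z.index[:5]] = 1
        table = associate_factors_with_mutations(model, mut, min_recurrence=3)
        assert set(table["gene"]) == {"gB"}

    def test_permuted_labels_give_uniform_p_values(self):
        rng = np.random.default_rng(3)
        model = self._model_with_gradient(60)
        pvals = []
        for _ in range(400):
            flag = np.zeros(60, dtype=int)
            flag[rng.choice(60, size=8, replace=False)] = 1
            mut = pd.DataFrame([flag], index=["g"], columns=model.Z.index)
            pvals.append(associate_factors_with_mutations(model, mut).iloc[0]["p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestLoadingSetEnrichment:
    def _model(self, rng, heavy=None):
        p = 200
        w = rng.normal(0, 0.05, size=(p, 1))
        heavy = heavy or []
        for i in heavy:
            w[i, 0] = rng.choice([-1, 1]) * rng.uniform(0.5, 1.0)
        wdf = pd.DataFrame(w, index=[f"f{i}" for i in range(p)], columns=["LF1"])
        return FactorModel(
            Z=pd.DataFrame({"LF1": rng.normal(size=10)}),
            W={"e": wdf}, varexp=pd.DataFrame({"LF1": [1.0]}, index=["e"]),
        )

    def test_heavy_loading_set_enriched(self, rng):
        heavy = list(range(20))
        model = self._model(rng, heavy)
        sets = {"planted": [f"f{i}" for i in heavy]}
        table = loading_set_enrichment(model, sets)
        assert table.iloc[0]["q"] < 0.05

    def test_random_sets_rarely_flagged(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(100):
            model = self._model(rng)
            members = [f"f{i}" for i in rng.choice(200, size=15, replace=False)]
            table = loading_set_enrichment(model, {"rand": members})
            hits += int(table.iloc[0]["p"] < 0.05)
        assert hits <= 5

    def test_disjoint_set_skipped(self, rng):
        model = self._model(rng)
        table = loading_set_enrichment(model, {"ghost": ["nope1", "nope2"]})
        assert (table["status"] == "skipped").all()
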