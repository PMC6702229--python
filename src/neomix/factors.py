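"""Deterministic joint latent-factor decomposition of two omic blocks.

Model
-----
Centred, block-rescaled feature x sample matrices ``X_m`` are stacked and
approximated by a shared rank-K factorisation ``X ~ W Z^T`` with unit-norm
loadings ``W`` and sample scores ``Z``.  Samples missing a whole block are
handled by EM-style matrix completion: missing entries are imputed from the
current rank-K reconstruction (zeros initially), a truncated SVD of the
completed matrix is taken, and the two steps alternate until the
reconstruction stabilises.  With no missing data this reduces exactly to a
single truncated SVD.  The procedure is a deterministic surrogate for
variational group factor analysis: downstream analyses only consume the
factor subspace, scores, loadings and variance-explained fractions, which
the SVD supplies with a reproducible sign and ordering convention (largest-
magnitude loading positive; factors ordered by total variance explained).

Per-factor, per-block variance explained is
``varexp(m, k) = ||w_mk||^2 * sum_{j in obs(m)} z_jk^2 / ||X_m||^2``
computed over the observed entries of block m.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class FactorModel:
    Z: pd.DataFrame                      # samples x factors (LF1..LFK)
    W: dict                              # block -> features x factors
    varexp: pd.DataFrame                 # blocks x factors, fractions in [0,1]
    block_scale: dict = field(default_factory=dict)
    n_iter: int = 0
    final_delta: float = 0.0
    converged: bool = True
    error_history: list = field(default_factory=list)

    @property
    def factors(self) -> list[str]:
        return list(self.Z.columns)

    @property
    def total_varexp(self) -> pd.Series:
        return self.varexp.sum(axis=0)


def standardize_block(values: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Centre per feature and rescale the block to unit total variance.

    Returns the standardised matrix and the scale constant applied.
    """
    centred = values.sub(values.mean(axis=1), axis=0)
    total_var = float(centred.var(axis=1, ddof=1).sum())
    scale = np.sqrt(total_var) if total_var > 0 else 1.0
    return centred / scale, scale


def fit_joint_factors(
    blocks: dict,
    K: int,
    tol: float = 1e-6,
    max_iter: int = 100,
    init_rng: np.random.Generator | None = None,
    init_noise_sd: float = 0.0,
) -> FactorModel:
    """Fit the shared rank-K factorisation of the stacked blocks.

    ``blocks`` maps block name to a centred (per feature) feature x sample
    matrix; sample sets may differ between blocks, but every sample must be
    present in at least one.  ``init_rng``/``init_noise_sd`` perturb the
    initial imputation of missing entries (used by :func:`factor_stability`).
    """
    names = list(blocks)
    samples: list[str] = []
    for name in names:
        for s in blocks[name].columns:
            if s not in samples:
                samples.append(s)
    n = len(samples)
    sizes = {name: blocks[name].shape[0] for name in names}
    p_total = sum(sizes.values())
    if K >= min(p_total, n):
        raise ValueError(f"K={K} must be below min(features, samples)={min(p_total, n)}")

    present = np.zeros(n, dtype=bool)
    x = np.zeros((p_total, n))
    mask = np.ones((p_total, n), dtype=bool)  # True = missing
    row0 = 0
    for name in names:
        b = blocks[name]
        cols = [samples.index(s) for s in b.columns]
        x[row0:row0 + sizes[name], cols] = b.to_numpy()
        mask[row0:row0 + sizes[name], cols] = False
        present[cols] = True
        row0 += sizes[name]
    if not present.all():
        missing = [samples[i] for i in np.flatnonzero(~present)]
        raise ValueError(f"samples present in no block: {missing}")

    if init_noise_sd > 0 and mask.any():
        rng = init_rng if init_rng is not None else np.random.default_rng(0)
        x[mask] = rng.normal(0.0, init_noise_sd, size=int(mask.sum()))

    # convergence is tracked on the observed-entry reconstruction error,
    # which the imputation step decreases monotonically; the reconstruction
    # itself can keep rotating inside degenerate trailing-noise subspaces
    obs = ~mask
    err_prev = None
    delta = np.inf
    n_iter = 0
    errors = []
    for n_iter in range(1, max_iter + 1):
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        recon = (u[:, :K] * s[:K]) @ vt[:K]
        err = float(np.linalg.norm((x - recon)[obs]))
        errors.append(err)
        if err_prev is not None:
            delta = abs(err_prev - err) / max(err_prev, 1e-300)
        err_prev = err
        x[mask] = recon[mask]
        if not mask.any() or delta < tol:
            break
    converged = (not mask.any()) or delta < tol
    if not converged:
        warnings.warn(f"factor fit did not converge in {max_iter} iterations (delta={delta:.2e})")

    w_full = u[:, :K]
    z = vt[:K].T * s[:K]
    # Finishing step: at the EM fixed point the score of a sample missing a
    # block is the least-squares projection of its observed rows onto the
    # loadings; computing it directly removes the residual shrinkage of
    # imputed samples towards the initial zero imputation.  For fully
    # observed samples this equals the SVD score exactly (the residual is
    # orthogonal to the loading columns), so it is applied only where needed.
    for j in range(n):
        miss_rows = mask[:, j]
        if miss_rows.any():
            keep = ~miss_rows
            z[j], *_ = np.linalg.lstsq(w_full[keep], x[keep, j], rcond=None)
    # sign convention: the largest-magnitude loading of each factor is positive
    for k in range(K):
        j = int(np.argmax(np.abs(w_full[:, k])))
        if w_full[j, k] < 0:
            w_full[:, k] *= -1
            z[:, k] *= -1

    # variance explained per block over observed entries
    varexp = np.zeros((len(names), K))
    row0 = 0
    for mi, name in enumerate(names):
        rows = slice(row0, row0 + sizes[name])
        col_obs = ~mask[rows][0]  # per-block column availability (block-wise missing)
        total = float(np.sum(x[rows][:, col_obs] ** 2))
        for k in range(K):
            num = float(np.sum(w_full[rows, k] ** 2) * np.sum(z[col_obs, k] ** 2))
            varexp[mi, k] = num / total if total > 0 else 0.0
        row0 += sizes[name]

    order = np.argsort(-varexp.sum(axis=0), kind="stable")
    w_full = w_full[:, order]
    z = z[:, order]
    varexp = varexp[:, order]

    factor_names = [f"LF{k + 1}" for k in range(K)]
    w_blocks = {}
    row0 = 0
    for name in names:
        w_blocks[name] = pd.DataFrame(
            w_full[row0:row0 + sizes[name]], index=blocks[name].index, columns=factor_names
        )
        row0 += sizes[name]
    return FactorModel(
        Z=pd.DataFrame(z, index=samples, columns=factor_names),
        W=w_blocks,
        varexp=pd.DataFrame(varexp, index=names, columns=factor_names),
        n_iter=n_iter,
        final_delta=0.0 if not mask.any() else float(delta),
        converged=converged,
        error_history=errors,
    )


def variance_explained(model: FactorModel, blocks: dict) -> pd.DataFrame:
    """Recompute the block x factor variance-explained table from data."""
    out = {}
    for name, b in blocks.items():
        w = model.W[name].to_numpy()
        obs_samples = [s for s in model.Z.index if s in b.columns]
        z = model.Z.loc[obs_samples].to_numpy()
        total = float(np.sum(b[obs_samples].to_numpy() ** 2))
        out[name] = [
            float(np.sum(w[:, k] ** 2) * np.sum(z[:, k] ** 2)) / total if total > 0 else 0.0
            for k in range(z.shape[1])
        ]
    return pd.DataFrame(out, index=model.factors).T


def select_factors(model: FactorModel, min_varexp: float = 0.02) -> FactorModel:
    """Keep factors explaining >= ``min_varexp`` of variance in >= 1 block."""
    keep = [f for f in model.factors if (model.varexp[f] >= min_varexp).any()]
    if not keep:
        raise ValueError("no factor reaches the variance-explained threshold")
    return FactorModel(
        Z=model.Z[keep].copy(),
        W={name: w[keep].copy() for name, w in model.W.items()},
        varexp=model.varexp[keep].copy(),
        block_scale=model.block_scale,
        n_iter=model.n_iter,
        final_delta=model.final_delta,
        converged=model.converged,
    )


def factor_stability(
    blocks: dict, K: int, n_runs: int = 20, seed: int = 0,
    tol: float = 1e-6, max_iter: int = 100,
) -> pd.DataFrame:
    """Refit with perturbed initial imputations and correlate factors across runs.

    Returns the absolute Pearson correlation matrix of all (run, factor)
    score vectors — (n_runs*K) square, symmetric with unit diagonal.  Matched
    factors (same index, different runs) near 1 indicate a stable fit;
    cross-factor entries near 0 indicate quasi-independent axes.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be at least 2")
    rng = np.random.default_rng(seed)
    obs_sd = float(np.std(np.concatenate([b.to_numpy().ravel() for b in blocks.values()])))
    cols = {}
    for r in range(n_runs):
        model = fit_joint_factors(
            blocks, K, tol=tol, max_iter=max_iter,
            init_rng=rng, init_noise_sd=obs_sd,
        )
        for f in model.factors:
            cols[f"run{r + 1}:{f}"] = model.Z[f]
    zmat = pd.DataFrame(cols)
    return zmat.corr().abs()


def associate_factors_with_covariates(
    model: FactorModel, clinical: pd.DataFrame, covariables: list[str],
    interactions: tuple = (("sex", "smoking"), ("age_class", "smoking")),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Linear model of each factor on all covariables jointly.

    One OLS fit per factor with every covariable (categoricals dummy-coded)
    plus the sex x smoking and age x smoking interactions when those columns
    exist; per-term type-II ANOVA p-values, BH-adjusted across every
    (factor, term) pair.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    data = clinical.set_index("sample").loc[model.Z.index, covariables].copy()
    terms = []
    for c in covariables:
        if data[c].dtype == object or str(data[c].dtype) == "category":
            terms.append(f"C(Q('{c}'))")
        else:
            terms.append(f"Q('{c}')")
    for a, b in interactions:
        if a in covariables and b in covariables:
            terms.append(f"C(Q('{a}')):C(Q('{b}'))")
    rows = []
    for f in model.factors:
        data["_y"] = model.Z[f].to_numpy()
        formula = "_y ~ " + " + ".join(terms)
        fit = smf.ols(formula, data=data).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                tab = anova_lm(fit, typ=2)
            except Exception:  # singular design: fall back to type-I
                tab = anova_lm(fit, typ=1)
        for term in tab.index:
            if term in ("Residual",):
                continue
            p = tab.loc[term, "PR(>F)"]
            if np.isnan(p):
                continue
            rows.append({"factor": f, "covariable": term, "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["q"] < alpha
    return out


def associate_factors_with_mutations(
    model: FactorModel, mutations: pd.DataFrame, min_recurrence: int = 3,
) -> pd.DataFrame:
    """Welch t-test of factor coordinates in mutated vs non-mutated samples.

    Only genes mutated in at least ``min_recurrence`` samples (and not in
    all) are tested; BH adjustment across all (gene, factor) tests.
    """
    shared = [s for s in model.Z.index if s in mutations.columns]
    mut = mutations[shared] > 0
    rows = []
    for gene in mut.index:
        flag = mut.loc[gene].to_numpy()
        if flag.sum() < min_recurrence or flag.all():
            continue
        for f in model.factors:
            z = model.Z.loc[shared, f].to_numpy()
            t, p = stats.ttest_ind(z[flag], z[~flag], equal_var=False)
            rows.append({"gene": gene, "factor": f, "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def loading_set_enrichment(model: FactorModel, feature_sets: dict, block: str | None = None) -> pd.DataFrame:
    """Rank-sum test of in-set vs out-of-set loading magnitudes per factor.

    Sets with fewer than two matching features are skipped (recorded with
    status "skipped").  BH across the tested (factor, set) pairs.
    """
    if block is None:
        loadings = pd.concat(model.W.values())
    else:
        loadings = model.W[block]
    rows = []
    for set_name, members in feature_sets.items():
        in_mask = loadings.index.isin(set(members))
        if in_mask.sum() < 2:
            rows.append({"set": set_name, "factor": None, "statistic": np.nan,
                         "p": np.nan, "status": "skipped"})
            continue
        for f in model.factors:
            mag = loadings[f].abs().to_numpy()
            u, p = stats.mannwhitneyu(mag[in_mask], mag[~in_mask], alternative="two-sided")
            rows.append({"set": set_name, "factor": f, "statistic": float(u),
                         "p": float(p), "status": "tested"})
    out = pd.DataFrame(rows)
    tested = out["status"] == "tested"
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return out


def principal_angles(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Principal angles (degrees) between the column spaces of a and b."""
    qa, _ = np.linalg.qr(a)
    qb, _ = np.linalg.qr(b)
    sv = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.degrees(np.arccos(np.clip(sv, -1, 1)))
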