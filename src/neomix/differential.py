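"""Moderated pairwise differential tests with a fold-change-threshold null.

Per feature, a linear model ``value ~ group + covariables`` is fitted on
the two groups of a pair; residual variances are shrunk towards a common
prior by empirical-Bayes moderation, with the prior ``(s0^2, d0)``
estimated by moment matching of the log residual variances on
digamma/trigamma identities (the scaled-F model of array analysis).  The
test statistic embeds a fold-change threshold theta:

    t = max(|b| - theta, 0) / (s_tilde * c),    df = d0 + d

so theta = 0 recovers the ordinary moderated t, and a nonzero theta tests
the null that the effect is smaller than theta in absolute value (a
TREAT-style statistic).  BH adjustment is applied within each pairwise
comparison family.  Core features of a focal group are the intersection,
over all pairs involving it, of significant features with a consistent
effect direction relative to the focal group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ModerationPrior:
    s0_squared: float
    d0: float  # np.inf permitted


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if x <= 0:
            x = 1e-8
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_moderation_prior(s2: np.ndarray, df: float) -> ModerationPrior:
    """Fit the scaled-F prior to observed residual variances.

    Matches the mean and variance of ``log(s^2)`` to the digamma/trigamma
    moments of the scaled F distribution; a sample variance of the log
    variances at (or below) the value implied by chi^2 noise alone yields
    an infinite prior df (complete shrinkage to ``s0^2``).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        return ModerationPrior(float(np.median(s2)) if len(s2) else 1.0, 0.0)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) * (len(e) - 1) / len(e)  # biased, as in moment matching
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return ModerationPrior(float(np.exp(e_mean)), np.inf)
    d0 = 2.0 * _trigamma_inverse(excess)
    s0sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationPrior(s0sq, d0)


def squeeze_variances(s2: np.ndarray, df: float, prior: ModerationPrior) -> np.ndarray:
    """Posterior variances ``(d0 s0^2 + d s^2) / (d0 + d)``."""
    if prior.d0 == 0:
        return np.asarray(s2, dtype=float)
    if np.isinf(prior.d0):
        return np.full_like(np.asarray(s2, dtype=float), prior.s0_squared)
    return (prior.d0 * prior.s0_squared + df * s2) / (prior.d0 + df)


def fit_moderated_pairwise(
    values: pd.DataFrame,
    groups: pd.Series,
    covariables: pd.DataFrame | None = None,
    theta: float = 0.0,
    d0_override: float | None = None,
) -> dict:
    """Moderated pairwise tests for every pair of group levels.

    ``values`` is features x samples on the analysis scale (log2-normalised
    expression or M-values).  Returns ``{(level1, level2): DataFrame}`` with
    the effect ``b`` oriented as level2 minus level1 (levels sorted).
    ``d0_override`` forces the prior df (0 = no moderation, inf = full).
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    samples = [s for s in values.columns if s in groups.index and pd.notna(groups.get(s))]
    g = groups.loc[samples]
    levels = sorted(g.unique())
    results = {}
    for lev1, lev2 in itertools.combinations(levels, 2):
        pair_samples = [s for s in samples if g[s] in (lev1, lev2)]
        if (g.loc[pair_samples] == lev1).sum() < 2 or (g.loc[pair_samples] == lev2).sum() < 2:
            continue
        y = values[pair_samples].to_numpy(dtype=float)
        ind = (g.loc[pair_samples] == lev2).astype(float).to_numpy()
        design_cols = [np.ones(len(pair_samples)), ind]
        if covariables is not None:
            cov = covariables.loc[pair_samples]
            dummies = pd.get_dummies(cov, drop_first=True, dtype=float)
            # drop constant columns (collinear with the intercept)
            dummies = dummies.loc[:, dummies.std(axis=0) > 0]
            design_cols.extend(dummies.to_numpy().T)
        x = np.column_stack(design_cols)
        rank = np.linalg.matrix_rank(x)
        n_obs = x.shape[0]
        d = n_obs - rank
        if d <= 0:
            raise ValueError(f"zero residual degrees of freedom for pair ({lev1}, {lev2})")
        pinv = np.linalg.pinv(x)
        beta = pinv @ y.T                      # coefficients x features
        resid = y.T - x @ beta
        s2 = (resid ** 2).sum(axis=0) / d
        s2 = np.maximum(s2, 1e-12)
        if d0_override is not None:
            prior = ModerationPrior(float(np.median(s2)), d0_override)
        else:
            prior = estimate_moderation_prior(s2, d)
        s2_tilde = squeeze_variances(s2, d, prior)
        c = float(np.sqrt((pinv @ pinv.T)[1, 1]))  # unscaled sd of the group coefficient
        b = beta[1]
        se = np.sqrt(s2_tilde) * c
        tstat = np.maximum(np.abs(b) - theta, 0.0) / se
        df_total = prior.d0 + d if np.isfinite(prior.d0) else np.inf
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(tstat)
        else:
            p = 2.0 * stats.t.sf(tstat, df_total)
        q = multipletests(p, method="fdr_bh")[1]
        results[(lev1, lev2)] = pd.DataFrame({
            "feature": values.index,
            "b": b,
            "se": se,
            "t": np.sign(b) * tstat,
            "df": df_total,
            "p": p,
            "q": q,
            "theta": theta,
            "s0_squared": prior.s0_squared,
            "d0": prior.d0,
        }).set_index("feature")
    return results


def core_features(
    pairwise: dict,
    focal,
    q_max: float = 0.05,
    require_direction: bool = True,
) -> set:
    """Intersection of significant features across every pair involving ``focal``.

    The effect sign is re-oriented so it is the focal group relative to the
    other; with ``require_direction`` the sign must agree across all pairs.
    """
    per_pair = []
    involved = [pair for pair in pairwise if focal in pair]
    if not involved:
        raise ValueError(f"no pairwise result involves focal group {focal!r}")
    n_groups_expected = len({lev for pair in pairwise for lev in pair})
    if len(involved) < n_groups_expected - 1:
        raise ValueError(f"missing pairwise results for focal group {focal!r}")
    for pair in involved:
        res = pairwise[pair]
        sig = res[res["q"] < q_max]
        orient = 1.0 if pair[1] == focal else -1.0
        per_pair.append({f: np.sign(orient * res.loc[f, "b"]) for f in sig.index})
    core = set(per_pair[0])
    for d in per_pair[1:]:
        core &= set(d)
    if require_direction:
        core = {f for f in core if len({d[f] for d in per_pair}) == 1}
    return core


def map_cpgs_to_promoters(
    cpg_annotation: pd.DataFrame,
    tss_table: pd.DataFrame,
    window: int = 2000,
) -> pd.DataFrame:
    """Map each CpG to genes whose TSS lies within ``window`` bp (inclusive).

    ``cpg_annotation`` needs columns (feature|cpg, chrom, position);
    ``tss_table`` needs (feature|gene, chrom, position).  A CpG may map to
    several genes; chromosome mismatches simply leave a CpG unmapped.
    """
    cpg = cpg_annotation.rename(columns={"feature": "cpg"})[["cpg", "chrom", "position"]]
    tss = tss_table.rename(columns={"feature": "gene"})[["gene", "chrom", "position"]]
    merged = cpg.merge(tss, on="chrom", suffixes=("_cpg", "_tss"))
    merged = merged[(merged["position_cpg"] - merged["position_tss"]).abs() <= window]
    return merged[["cpg", "gene"]].reset_index(drop=True)


def expr_meth_correlation(
    expression: pd.DataFrame,
    beta: pd.DataFrame,
    mapping: pd.DataFrame,
    q_max: float = 0.05,
    r2_min: float = 0.5,
    iqr_min: float = 0.25,
) -> pd.DataFrame:
    """Pearson tests of promoter beta vs normalised expression, filtered.

    All mapped (gene, CpG) pairs sharing >= 3 samples are tested; BH across
    all tests; pairs surviving q < q_max, r^2 > r2_min and IQR(beta) >
    iqr_min are kept, and per gene only the smallest-q CpG is reported with
    its correlation direction.
    """
    shared = [s for s in expression.columns if s in beta.columns]
    rows = []
    for cpg, gene in mapping[["cpg", "gene"]].itertuples(index=False):
        if gene not in expression.index or cpg not in beta.index:
            continue
        e = expression.loc[gene, shared].to_numpy(dtype=float)
        b = beta.loc[cpg, shared].to_numpy(dtype=float)
        ok = np.isfinite(e) & np.isfinite(b)
        if ok.sum() < 3:
            continue
        e, b = e[ok], b[ok]
        if np.std(e) == 0 or np.std(b) == 0:
            continue
        r, p = stats.pearsonr(b, e)
        q25, q75 = np.percentile(b, [25, 75])
        rows.append({
            "gene": gene, "cpg": cpg, "r": float(r), "r2": float(r) ** 2,
            "p": float(p), "iqr_beta": float(q75 - q25),
            "direction": "negative" if r < 0 else "positive",
        })
    out = pd.DataFrame(rows)
    if not len(out):
        return out
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    kept = out[(out["q"] < q_max) & (out["r2"] > r2_min) & (out["iqr_beta"] > iqr_min)]
    best = kept.sort_values(["gene", "q"]).groupby("gene", as_index=False).first()
    return best
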