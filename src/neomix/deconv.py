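"""Immune-fraction estimation by constrained least squares, plus permutation tests.

Bulk expression over signature genes is modelled as a non-negative mixture
of cell-type reference profiles: minimise ``||S f - b||_2`` subject to
``f >= 0`` and ``sum(f) <= 1``; the slack ``1 - sum(f)`` is reported as the
non-immune ("other") fraction.  Group differences in fractions are tested
with permutation tests on the group-mean difference — exhaustive when the
number of label permutations is small, seeded Monte-Carlo with the add-one
correction otherwise — and BH-adjusted across cell types within each pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.stats.multitest import multipletests


@dataclass
class DeconvResult:
    fractions: pd.DataFrame   # samples x cell types
    other: pd.Series
    residual_norm: pd.Series


def _solve_one(s: np.ndarray, b: np.ndarray) -> np.ndarray:
    f, _ = optimize.nnls(s, b)
    if f.sum() <= 1.0 + 1e-9:
        return f
    # the simplex bound is active: refine with the inequality enforced
    x0 = f / f.sum()
    res = optimize.minimize(
        lambda x: 0.5 * np.sum((s @ x - b) ** 2),
        x0,
        jac=lambda x: s.T @ (s @ x - b),
        bounds=[(0.0, None)] * s.shape[1],
        constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x.sum(),
                      "jac": lambda x: -np.ones_like(x)}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    return np.clip(res.x, 0.0, None)


def deconvolve(bulk: pd.DataFrame, signature: pd.DataFrame) -> DeconvResult:
    """Estimate cell-type fractions per sample.

    ``bulk`` is genes x samples on the same (linear, normalised) scale as the
    ``signature`` (genes x cell types) reference profiles.
    """
    shared = [g for g in signature.index if g in bulk.index]
    if not shared:
        raise ValueError("no shared genes between bulk and signature")
    s = signature.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(s) < s.shape[1]:
        # name the collinear columns to make the failure actionable
        _, r = np.linalg.qr(s)
        bad = [signature.columns[i] for i in range(s.shape[1]) if abs(r[i, i]) < 1e-10]
        raise ValueError(f"signature matrix is rank deficient (collinear columns: {bad})")
    fractions = {}
    resid = {}
    for sample in bulk.columns:
        b = bulk.loc[shared, sample].to_numpy(dtype=float)
        f = _solve_one(s, b)
        fractions[sample] = f
        resid[sample] = float(np.linalg.norm(s @ f - b))
    frac = pd.DataFrame(fractions, index=signature.columns).T
    other = (1.0 - frac.sum(axis=1)).clip(lower=0.0).rename("other")
    return DeconvResult(fractions=frac, other=other, residual_norm=pd.Series(resid, name="residual"))


def group_fraction_tests(
    fractions: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation tests of group-mean differences per cell type and pair.

    When ``C(n, n1) <= n_perm`` the null is enumerated exhaustively and the
    p-value is exact; otherwise ``n_perm`` seeded permutations are drawn and
    the add-one-corrected estimate ``(1 + extreme) / (n_perm + 1)`` is used.
    """
    rng = np.random.default_rng(seed)
    samples = [s for s in fractions.index if s in groups.index and pd.notna(groups.get(s))]
    g = groups.loc[samples]
    levels = sorted(g.unique())
    rows = []
    for lev1, lev2 in itertools.combinations(levels, 2):
        members = [s for s in samples if g[s] in (lev1, lev2)]
        is1 = np.array([g[s] == lev1 for s in members])
        n1 = int(is1.sum())
        n_tot = len(members)
        if n1 == 0 or n1 == n_tot:
            continue
        x = fractions.loc[members]
        exhaustive = comb(n_tot, n1) <= n_perm
        for ct in fractions.columns:
            v = x[ct].to_numpy(dtype=float)
            obs = v[is1].mean() - v[~is1].mean()
            if exhaustive:
                total = extreme = 0
                for combo in itertools.combinations(range(n_tot), n1):
                    m = np.zeros(n_tot, dtype=bool)
                    m[list(combo)] = True
                    stat = v[m].mean() - v[~m].mean()
                    total += 1
                    if abs(stat) >= abs(obs) - 1e-12:
                        extreme += 1
                p = extreme / total
            else:
                extreme = 0
                for _ in range(n_perm):
                    m = np.zeros(n_tot, dtype=bool)
                    m[rng.choice(n_tot, size=n1, replace=False)] = True
                    stat = v[m].mean() - v[~m].mean()
                    if abs(stat) >= abs(obs) - 1e-12:
                        extreme += 1
                p = (1 + extreme) / (n_perm + 1)
            rows.append({"cell_type": ct, "group1": lev1, "group2": lev2,
                         "statistic": float(obs), "p": float(p),
                         "exhaustive": exhaustive})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = np.nan
        for (l1, l2), idx in out.groupby(["group1", "group2"]).groups.items():
            out.loc[idx, "q"] = multipletests(out.loc[idx, "p"], method="fdr_bh")[1]
    return out
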