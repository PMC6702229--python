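"""Fisher-exact enrichment of somatic mutations in hallmark gene sets.

For a sample group, each gene set is tested with a 2x2 table contrasting
mutation events inside vs outside the set (events counted with multiplicity
across samples and recurrently mutated genes) against the in-set vs
out-of-set composition of the declared gene universe.  A presence/absence
mode collapses multiplicities.  BH across sets within the group; flags at
both the 5% and 10% FDR thresholds.  Jackknife re-testing after removing
each sample (or each mutated gene) quantifies the leverage of individual
units on the significance calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")


@dataclass
class EnrichmentTable:
    table: pd.DataFrame            # per set: counts, odds ratio, p, q, flags
    universe_size: int
    multiplicity: bool


def hallmark_enrichment(
    mutations: pd.DataFrame,
    gene_sets: dict,
    universe: list | None = None,
    multiplicity: bool = True,
) -> EnrichmentTable:
    """Fisher-exact enrichment of the group's mutation events per gene set.

    ``mutations`` is a gene x sample count (or 0/1) matrix restricted to the
    group of interest.  The universe defaults to all genes in the mutation
    matrix union all set genes.
    """
    if universe is None:
        universe = sorted(set(mutations.index).union(*[set(v) for v in gene_sets.values()]))
    universe_set = set(universe)
    stray = set(mutations.index[mutations.sum(axis=1) > 0]) - universe_set
    if stray:
        warnings.warn(f"mutated genes outside the declared universe: {sorted(stray)[:5]}")
        universe_set |= stray
    events = mutations.sum(axis=1)
    if not multiplicity:
        events = (events > 0).astype(int)
    total_events = int(events.sum())
    rows = []
    for name, members in gene_sets.items():
        mset = set(members) & universe_set
        in_events = int(events[events.index.isin(mset)].sum())
        out_events = total_events - in_events
        in_genes = len(mset)
        out_genes = len(universe_set) - in_genes
        table = np.array([[in_events, out_events], [in_genes, out_genes]])
        if total_events == 0:
            odds, p = np.nan, 1.0
        else:
            odds, p = stats.fisher_exact(table, alternative="two-sided")
        contributing = events[(events > 0) & events.index.isin(mset)]
        rows.append({
            "set": name,
            "in_events": in_events, "out_events": out_events,
            "in_genes": in_genes, "out_genes": out_genes,
            "odds_ratio": odds, "p": float(p),
            "contributing": ";".join(f"{g}x{int(c)}" for g, c in contributing.items()),
        })
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant_q05"] = out["q"] < 0.05
    out["significant_q10"] = out["q"] < 0.10
    return EnrichmentTable(table=out, universe_size=len(universe_set), multiplicity=multiplicity)


def jackknife_leverage(
    mutations: pd.DataFrame,
    gene_sets: dict,
    universe: list | None = None,
    mode: str = "by-sample",
    multiplicity: bool = True,
) -> pd.DataFrame:
    """Leave-one-unit-out re-testing of the enrichment.

    Returns per (left-out unit, set) the recomputed q-value and whether the
    5% / 10% significance flags flip relative to the full analysis.
    """
    full = hallmark_enrichment(mutations, gene_sets, universe, multiplicity).table
    if mode == "by-sample":
        units = list(mutations.columns)
        if len(units) < 2:
            raise ValueError("need at least two samples for the by-sample jackknife")
        drop = lambda u: mutations.drop(columns=[u])
    elif mode == "by-gene":
        units = list(mutations.index[mutations.sum(axis=1) > 0])
        if len(units) < 2:
            raise ValueError("need at least two mutated genes for the by-gene jackknife")
        drop = lambda u: mutations.drop(index=[u])
    else:
        raise ValueError(f"unknown jackknife mode {mode!r}")
    rows = []
    for u in units:
        sub = hallmark_enrichment(drop(u), gene_sets, universe, multiplicity).table
        for name in full.index:
            rows.append({
                "unit": u, "set": name,
                "q_full": full.loc[name, "q"], "q_jackknife": sub.loc[name, "q"],
                "flip_q05": bool(full.loc[name, "significant_q05"] != sub.loc[name, "significant_q05"]),
                "flip_q10": bool(full.loc[name, "significant_q10"] != sub.loc[name, "significant_q10"]),
            })
    return pd.DataFrame(rows)
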