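"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order (simulate/ingest -> preprocess -> factorize
-> cluster -> classify -> diff -> deconv -> survive -> enrich); every stage
writes TSV artifacts plus a manifest recording parameters and the derived
stage seed, so an identical config + seed reproduces identical files.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from neomix import cohort as cohort_mod
from neomix.classify import ClassifierSettings, dual_omic_classify, prediction_groups
from neomix.clustering import consensus_cluster
from neomix.cohort import Cohort, SimConfig, default_gene_sets, generate_cohort, read_cohort, write_cohort
from neomix.deconv import deconvolve, group_fraction_tests
from neomix.differential import core_features, expr_meth_correlation, fit_moderated_pairwise, map_cpgs_to_promoters
from neomix.enrichment import hallmark_enrichment, read_gmt, write_gmt
from neomix.factors import fit_joint_factors, select_factors, standardize_block
from neomix.preprocess import (
    beta_to_m,
    drop_sex_chromosome_features,
    filter_low_expression,
    normalize_expression,
    select_variable_features,
)
from neomix.surv import cox_fit, km_estimate

log = logging.getLogger("neomix")

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "neomix_out",
    "simulate": {},            # SimConfig overrides; or {"ingest": path}
    "stages": {
        "preprocess": True, "factorize": True, "cluster": True,
        "classify": True, "diff": True, "deconv": True,
        "survive": True, "enrich": True,
    },
    "preprocess": {"expression_fraction": 0.5, "methylation_fraction": 0.05},
    "factorize": {"n_factors": 5, "min_varexp": 0.02},
    "cluster": {"k_min": 2, "k_max": 5, "replicates": 100, "subsample": 0.8, "mode": "kminus1"},
    "classify": {"trees": 500, "rho": 1.5},
    "diff": {"theta_expression": 2.0, "theta_methylation": 0.0, "q_max": 0.05, "window": 2000},
    "deconv": {"permutations": 2000},
    "survive": {},
    "enrich": {"multiplicity": True},
}


def stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _write_tsv(df: pd.DataFrame, path: Path, index=True, index_label=None):
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, index_label=index_label)


def run_pipeline(config: dict) -> dict:
    """Execute all enabled stages; returns a dict of in-memory artifacts."""
    config = _merge(DEFAULT_CONFIG, config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stages = config["stages"]
    artifacts: dict = {"config": config}

    def _run_stage(name, fn):
        log.info("stage %s", name)
        try:
            fn()
        except Exception:
            log.error("stage %s failed; partial artifacts retained in %s", name, out_dir)
            raise

    # --- simulate / ingest -------------------------------------------------
    sim_cfg = dict(config.get("simulate") or {})
    ingest = sim_cfg.pop("ingest", None)
    if ingest:
        cohort = read_cohort(ingest)
    else:
        sim_cfg.setdefault("seed", stage_seed(seed, "simulate"))
        cohort = generate_cohort(SimConfig(**sim_cfg))
        write_cohort(cohort, out_dir / "cohort")
    artifacts["cohort"] = cohort

    # --- preprocess ---------------------------------------------------------
    blocks = {}
    if stages.get("preprocess", True):
        def _preprocess():
            pc = config["preprocess"]
            expr = drop_sex_chromosome_features(cohort.expression, cohort.annotation)
            expr = filter_low_expression(expr)
            expr_norm = normalize_expression(expr)
            meth = drop_sex_chromosome_features(cohort.methylation, cohort.annotation)
            mvals = beta_to_m(meth)
            sel_e = select_variable_features(expr_norm, pc["expression_fraction"])
            sel_m = select_variable_features(mvals, pc["methylation_fraction"])
            be, _ = standardize_block(expr_norm.loc[sel_e])
            bm, _ = standardize_block(mvals.loc[sel_m])
            blocks["expression"] = be
            blocks["methylation"] = bm
            artifacts["expression_norm"] = expr_norm
            artifacts["mvalues"] = mvals
            _write_tsv(be, out_dir / "block_expression.tsv", index_label="feature")
            _write_tsv(bm, out_dir / "block_methylation.tsv", index_label="feature")
        _run_stage("preprocess", _preprocess)
    artifacts["blocks"] = blocks

    # --- factorize ----------------------------------------------------------
    model = None
    if stages.get("factorize", True) and blocks:
        def _factorize():
            nonlocal model
            fc = config["factorize"]
            fitted = fit_joint_factors(blocks, fc["n_factors"], tol=1e-8)
            model = select_factors(fitted, fc["min_varexp"])
            artifacts["factor_model"] = model
            _write_tsv(model.Z, out_dir / "factors_scores.tsv", index_label="sample")
            _write_tsv(model.varexp, out_dir / "factors_varexp.tsv", index_label="block")
            for name, w in model.W.items():
                _write_tsv(w, out_dir / f"factors_loadings_{name}.tsv", index_label="feature")
        _run_stage("factorize", _factorize)

    # --- cluster ------------------------------------------------------------
    cluster_labels = None
    if stages.get("cluster", True) and model is not None:
        def _cluster():
            nonlocal cluster_labels
            cc = config["cluster"]
            res = consensus_cluster(
                blocks, K_range=range(cc["k_min"], cc["k_max"] + 1),
                R=cc["replicates"], subsample=cc["subsample"], mode=cc["mode"],
                seed=stage_seed(seed, "cluster"), n_factors=config["factorize"]["n_factors"],
            )
            cluster_labels = res.labels.astype(str).rename("cluster")
            artifacts["consensus"] = res
            _write_tsv(res.consensus, out_dir / "consensus_matrix.tsv", index_label="sample")
            lab = pd.DataFrame({f"K{k}": v for k, v in res.labels_per_k.items()})
            _write_tsv(lab, out_dir / "consensus_labels.tsv", index_label="sample")
            dunn = pd.DataFrame({"K": list(res.dunn_per_k), "dunn": list(res.dunn_per_k.values())})
            _write_tsv(dunn, out_dir / "dunn_index.tsv", index=False)
        _run_stage("cluster", _cluster)

    # --- classify -----------------------------------------------------------
    predictions = None
    if stages.get("classify", True):
        def _classify():
            nonlocal predictions
            kc = config["classify"]
            labels = cohort.clinical.set_index("sample")["histology"]
            settings = ClassifierSettings(trees=kc["trees"], rho=kc["rho"])
            predictions = dual_omic_classify(
                cohort.expression, cohort.methylation, labels,
                settings=settings, seed=stage_seed(seed, "classify"),
            )
            groups = prediction_groups(predictions.merged, labels)
            artifacts["predictions"] = predictions
            artifacts["prediction_groups"] = groups
            tab = groups.copy()
            for omic, p in predictions.probabilities.items():
                for cls in p.columns:
                    tab[f"p_{omic}_{cls}"] = p[cls]
            _write_tsv(tab, out_dir / "predictions.tsv", index_label="sample")
        _run_stage("classify", _classify)

    # --- differential -------------------------------------------------------
    if stages.get("diff", True) and "expression_norm" in artifacts:
        def _diff():
            dc = config["diff"]
            if cluster_labels is not None:
                group_series = cluster_labels
            else:
                group_series = cohort.clinical.set_index("sample")["histology"]
            cov = cohort.clinical.set_index("sample")[["sex", "age_class"]]
            de = fit_moderated_pairwise(
                artifacts["expression_norm"], group_series, cov, theta=dc["theta_expression"]
            )
            dm = fit_moderated_pairwise(
                artifacts["mvalues"], group_series, cov, theta=dc["theta_methylation"]
            )
            artifacts["de"] = de
            artifacts["dmp"] = dm
            cores = {}
            for focal in sorted(set(group_series)):
                try:
                    cores[focal] = sorted(core_features(de, focal, q_max=dc["q_max"]))
                except ValueError:
                    continue
            artifacts["core_genes"] = cores
            for focal, genes in cores.items():
                path = out_dir / f"core_genes_{focal}.txt"
                path.write_text("\n".join(genes) + ("\n" if genes else ""))
            ann = cohort.annotation
            mapping = map_cpgs_to_promoters(
                ann[ann["kind"] == "cpg"], ann[ann["kind"] == "gene"], window=dc["window"]
            )
            corr = expr_meth_correlation(
                artifacts["expression_norm"], cohort.methylation, mapping
            )
            artifacts["expr_meth"] = corr
            _write_tsv(corr, out_dir / "expr_meth_correlation.tsv", index=False)
        _run_stage("diff", _diff)

    # --- deconvolution ------------------------------------------------------
    if stages.get("deconv", True) and cohort.signature is not None:
        def _deconv():
            cpm = cohort.expression / cohort.expression.sum(axis=0) * 1e6
            res = deconvolve(cpm, cohort.signature)
            artifacts["deconv"] = res
            frac = res.fractions.copy()
            frac["other"] = res.other
            _write_tsv(frac, out_dir / "immune_fractions.tsv", index_label="sample")
            if cluster_labels is not None:
                tests = group_fraction_tests(
                    res.fractions, cluster_labels,
                    n_perm=config["deconv"]["permutations"],
                    seed=stage_seed(seed, "deconv"),
                )
                artifacts["deconv_tests"] = tests
                _write_tsv(tests, out_dir / "immune_fraction_tests.tsv", index=False)
        _run_stage("deconv", _deconv)

    # --- survival -----------------------------------------------------------
    if stages.get("survive", True):
        def _survive():
            clin = cohort.clinical.set_index("sample")
            if predictions is not None:
                groups = artifacts["prediction_groups"]
                included = groups[groups["included"]]
                merged = clin.join(included["group"], how="inner")
            else:
                merged = clin.assign(group=clin["histology"])
            if merged["group"].nunique() >= 2 and merged["event"].sum() >= 1:
                ref = merged["group"].value_counts().idxmax()
                fit = cox_fit(
                    merged["survival_months"], merged["event"], merged["group"], reference=str(ref)
                )
                artifacts["survival_fit"] = fit
                _write_tsv(fit.hazard_ratios, out_dir / "hazard_ratios.tsv", index_label="group")
            km_rows = []
            for gname, sub in merged.groupby("group"):
                km = km_estimate(sub["survival_months"], sub["event"])
                km["group"] = gname
                km_rows.append(km)
            if km_rows:
                _write_tsv(pd.concat(km_rows), out_dir / "km_curves.tsv", index=False)
        _run_stage("survive", _survive)

    # --- enrichment ---------------------------------------------------------
    if stages.get("enrich", True):
        def _enrich():
            ec = config["enrich"]
            sets_path = ec.get("gene_sets")
            sets = read_gmt(sets_path) if sets_path else default_gene_sets(cohort)
            if not sets_path:
                write_gmt(sets, out_dir / "gene_sets.gmt")
            if cluster_labels is not None:
                group_series = cluster_labels
            else:
                group_series = cohort.clinical.set_index("sample")["histology"]
            tables = {}
            for gname in sorted(set(group_series)):
                members = [s for s in cohort.mutations.columns if group_series.get(s) == gname]
                if not members:
                    continue
                res = hallmark_enrichment(
                    cohort.mutations[members], sets, multiplicity=ec["multiplicity"]
                )
                tables[gname] = res.table
                _write_tsv(res.table, out_dir / f"enrichment_{gname}.tsv", index_label="set")
            artifacts["enrichment"] = tables
        _run_stage("enrich", _enrich)

    # --- manifest and report ------------------------------------------------
    recorded = {k: v for k, v in config.items() if k != "out_dir"}
    manifest = {
        "seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in
                        ("simulate", "cluster", "classify", "deconv")},
        "config": _jsonable(recorded),  # out_dir omitted: implied by location
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    report = write_report(artifacts)
    (out_dir / "report.txt").write_text(report)
    artifacts["report"] = report
    return artifacts


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(artifacts: dict) -> str:
    """Human-readable summary of the pipeline outputs (idempotent)."""
    lines = ["neomix pipeline report", "=" * 23, ""]
    res = artifacts.get("consensus")
    if res is not None:
        lines.append(f"Consensus clustering: chosen K = {res.chosen_k} ({res.mode} mode, R={res.n_replicates})")
        for k in sorted(res.dunn_per_k):
            lines.append(f"  Dunn index K={k}: {res.dunn_per_k[k]:.4f}")
        lines.append("")
    preds = artifacts.get("predictions")
    if preds is not None:
        cohort = artifacts["cohort"]
        hist = cohort.clinical.set_index("sample")["histology"]
        shared = [s for s in preds.merged.index if s in hist.index]
        conf = pd.crosstab(hist.loc[shared], preds.merged.loc[shared])
        lines.append("Confusion matrix (histology x merged prediction):")
        lines.append(conf.to_string())
        lines.append(f"  total predicted samples: {len(shared)}")
        lines.append("")
    groups = artifacts.get("prediction_groups")
    if groups is not None:
        sizes = groups.groupby("group").size().sort_values(ascending=False)
        lines.append("Prediction groups (survival comparison, >10 samples included):")
        for g, n in sizes.items():
            included = bool(groups[groups["group"] == g]["included"].iloc[0])
            lines.append(f"  {g}: n={n} {'(included)' if included else '(excluded)'}")
        lines.append("")
    cores = artifacts.get("core_genes")
    if cores:
        lines.append("Core differentially expressed genes per group:")
        for g, genes in cores.items():
            lines.append(f"  {g}: {len(genes)}")
        lines.append("")
    enr = artifacts.get("enrichment")
    if enr:
        lines.append("Mutation/hallmark enrichment flags (q<0.05):")
        for g, table in enr.items():
            hits = list(table.index[table["significant_q05"]])
            lines.append(f"  {g}: {hits if hits else 'none'}")
        lines.append("")
    return "\n".join(lines) + "\n"
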