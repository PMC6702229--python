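"""Seeded synthetic multi-omics cohorts.

The generator plants the structure that the downstream analyses assume:
three molecular clusters (two carcinoid-like groups and one high-grade,
LCNEC-like group) separated along a small number of latent factors, a small
"supra" group whose morphology label disagrees with its molecular profile,
intermediate samples that are convex mixtures of two cluster profiles,
cluster-dependent survival hazards, cluster-enriched mutations, a subset of
genes whose expression is driven by promoter methylation, an immune-cell
mixing signal on a dedicated signature gene panel, and samples missing one
omic block entirely.

Expression counts are negative-binomial with
``log mean = baseline + loadings . factor scores + log library size``;
methylation M-values are ``loadings . scores + Gaussian noise`` mapped to
beta-values by the inverse M-transform.  A fixed seed yields a
byte-identical cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

CLUSTERS = ("A", "B", "C")
HISTOLOGY = {"A": "Typical", "B": "Atypical", "C": "LCNEC"}
CELL_TYPES = (
    "B_cells", "Macrophages_M1", "Macrophages_M2", "Monocytes", "Neutrophils",
    "NK_cells", "T_CD4", "T_CD8", "T_reg", "Dendritic_cells",
)

N_SIGNATURE_GENES_PER_TYPE = 6
SIGNATURE_HIGH = 300.0  # CPM-scale expression of a marker in its own cell type
SIGNATURE_LOW = 5.0     # off-target expression
OTHER_BACKGROUND = 15.0  # CPM-scale expression contributed by non-immune content


def _default_cluster_means() -> np.ndarray:
    # clusters separate on the first two factors; the third is a shared
    # continuous axis (age-like) with no between-cluster mean difference
    return np.array([
        [2.5, 2.0, 0.0],   # A  (typical-like)
        [-2.5, 2.0, 0.0],  # B  (atypical-like)
        [0.0, -3.0, 0.0],  # C  (LCNEC-like)
    ])


def _default_immune_fractions() -> np.ndarray:
    # rows = clusters A, B, C over the ten cell types; each row sums to < 1,
    # the remainder being tumour ("other") content.  A is dendritic-cell rich,
    # B monocyte rich, C neutrophil rich.
    return np.array([
        [0.04, 0.03, 0.03, 0.02, 0.02, 0.02, 0.05, 0.04, 0.02, 0.10],
        [0.04, 0.03, 0.03, 0.10, 0.02, 0.02, 0.05, 0.04, 0.02, 0.02],
        [0.04, 0.03, 0.03, 0.02, 0.12, 0.02, 0.05, 0.04, 0.02, 0.02],
    ])


class ConfigurationError(ValueError):
    """Raised when a :class:`SimConfig` violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    ``cluster_sizes`` holds five counts: the three core clusters (A, B,
    LCNEC-like C), the supra group (morphology label of cluster B, molecular
    profile of cluster C) and the intermediate samples (convex mixtures of
    the B and C profiles).  Sizes must sum to ``n_samples``.
    """

    n_samples: int = 120
    n_genes: int = 2000
    n_cpgs: int = 2000
    n_true_factors: int = 3
    cluster_sizes: tuple = (54, 38, 24, 4, 0)  # A, B, C, supra, intermediate
    cluster_factor_means: np.ndarray = field(default_factory=_default_cluster_means)
    factor_noise_sd: float = 0.4
    loading_sparsity: float = 0.8
    nb_dispersion: float = 0.1          # variance = mu + dispersion * mu^2
    meth_noise_sd: float = 0.5          # on the M-value scale
    library_size_range: tuple = (5e5, 2e6)
    missing_block_fraction: float = 0.1  # per omic block, disjoint sample sets
    survival_log_hazards: tuple = (-3.6, -2.9, -1.6)  # per-cluster log event rate / month
    censor_rate: float = 0.3
    mutation_rates: pd.DataFrame | None = None  # gene x cluster Bernoulli probabilities
    n_methylation_driven_genes: int = 50
    intermediate_weight: float = 0.5    # mixture weight on the first mixed (B) profile
    immune_fractions: np.ndarray = field(default_factory=_default_immune_fractions)
    male_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if sum(self.cluster_sizes) != self.n_samples:
            raise ConfigurationError(
                f"cluster_sizes {self.cluster_sizes} do not sum to n_samples={self.n_samples}"
            )
        if len(self.cluster_sizes) != 5:
            raise ConfigurationError("cluster_sizes must give (A, B, C, supra, intermediate)")
        means = np.asarray(self.cluster_factor_means, dtype=float)
        if means.shape != (3, self.n_true_factors):
            raise ConfigurationError(
                f"cluster_factor_means must be 3 x n_true_factors, got {means.shape}"
            )
        imm = np.asarray(self.immune_fractions, dtype=float)
        if imm.shape != (3, len(CELL_TYPES)):
            raise ConfigurationError("immune_fractions must be 3 x 10")
        if (imm < 0).any() or (imm.sum(axis=1) > 1).any():
            raise ConfigurationError("immune_fractions rows must be non-negative and sum to <= 1")
        for name in ("loading_sparsity", "missing_block_fraction", "censor_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.nb_dispersion < 0 or self.meth_noise_sd < 0:
            raise ConfigurationError("dispersion and noise sd must be non-negative")
        n_reserved = self.n_methylation_driven_genes + N_SIGNATURE_GENES_PER_TYPE * len(CELL_TYPES) + 12
        if self.n_genes < n_reserved:
            raise ConfigurationError(
                f"n_genes={self.n_genes} below the {n_reserved} reserved for "
                "methylation-driven, immune-signature and sex-linked genes"
            )
        if self.n_cpgs < self.n_methylation_driven_genes:
            raise ConfigurationError("n_cpgs must cover the methylation-driven gene pairs")


def default_mutation_rates() -> pd.DataFrame:
    """Gene x cluster Bernoulli mutation probabilities.

    Thirty genes; the first three are strongly enriched in one cluster each
    (emulating e.g. MEN1 in the atypical-enriched cluster), the rest carry a
    low background rate.
    """
    genes = [f"MUT{i:03d}" for i in range(1, 31)]
    rates = pd.DataFrame(0.05, index=genes, columns=list(CLUSTERS))
    rates.loc["MUT001", "B"] = 0.45
    rates.loc["MUT002", "C"] = 0.45
    rates.loc["MUT003", "A"] = 0.35
    return rates


@dataclass
class Cohort:
    """Aligned multi-omics cohort.

    ``expression`` (genes x samples, raw counts) and ``methylation``
    (CpGs x samples, beta in (0,1)) may each lack some sample columns —
    missing omic blocks are absent columns, not NA cells.  ``truth`` is only
    present for synthetic cohorts.
    """

    expression: pd.DataFrame
    methylation: pd.DataFrame
    clinical: pd.DataFrame
    mutations: pd.DataFrame
    annotation: pd.DataFrame
    signature: pd.DataFrame | None = None
    truth: pd.DataFrame | None = None
    config: SimConfig | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.clinical["sample"])

    def equals(self, other: "Cohort") -> bool:
        for attr in ("expression", "methylation", "clinical", "mutations", "annotation"):
            if not getattr(self, attr).equals(getattr(other, attr)):
                return False
        if (self.truth is None) != (other.truth is None):
            return False
        if self.truth is not None and not self.truth.equals(other.truth):
            return False
        return True


def _beta_from_m(m: np.ndarray) -> np.ndarray:
    beta = 1.0 / (1.0 + np.power(2.0, -m))
    return np.clip(beta, 1e-6, 1 - 1e-6)


def generate_cohort(config: SimConfig | None = None) -> Cohort:
    """Draw a synthetic cohort under ``config`` (seeded, deterministic)."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_samples
    k = config.n_true_factors
    n_a, n_b, n_c, n_supra, n_inter = config.cluster_sizes
    means = np.asarray(config.cluster_factor_means, dtype=float)

    samples = [f"S{i + 1:04d}" for i in range(n)]
    # roles in sample order: core A, core B, core C, supra, intermediate
    roles = (["core"] * (n_a + n_b + n_c)) + ["supra"] * n_supra + ["intermediate"] * n_inter
    molecular = ["A"] * n_a + ["B"] * n_b + ["C"] * n_c + ["C"] * n_supra + ["B"] * n_inter
    morphology = (
        [HISTOLOGY["A"]] * n_a + [HISTOLOGY["B"]] * n_b + [HISTOLOGY["C"]] * n_c
        + [HISTOLOGY["B"]] * n_supra        # supra: cluster-B morphology label
        + [HISTOLOGY["B"]] * n_inter        # intermediate: label of the first mixed profile
    )

    # --- latent factor scores ---------------------------------------------
    z = np.empty((n, k))
    idx = {c: [i for i, m in enumerate(molecular) if m == c and roles[i] == "core"] for c in CLUSTERS}
    for ci, c in enumerate(CLUSTERS):
        rows = idx[c]
        z[rows] = means[ci] + rng.normal(0, config.factor_noise_sd, size=(len(rows), k))
    supra_rows = [i for i, r in enumerate(roles) if r == "supra"]
    z[supra_rows] = means[2] + rng.normal(0, config.factor_noise_sd, size=(len(supra_rows), k))
    # intermediates mix the atypical-like (B) and LCNEC-like (C) profiles —
    # the boundary where real diagnoses are hardest
    inter_rows = [i for i, r in enumerate(roles) if r == "intermediate"]
    w_mix = config.intermediate_weight
    mix_mean = w_mix * means[1] + (1 - w_mix) * means[2]
    z[inter_rows] = mix_mean + rng.normal(0, config.factor_noise_sd, size=(len(inter_rows), k))

    # --- feature annotation ------------------------------------------------
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    cpgs = [f"cg{i + 1:07d}" for i in range(config.n_cpgs)]
    n_sig = N_SIGNATURE_GENES_PER_TYPE * len(CELL_TYPES)
    n_md = config.n_methylation_driven_genes
    # layout: [0, n_md) methylation-driven; [n_md, n_md+n_sig) immune signature;
    # last 12 genes sit on the sex chromosomes (8 X + 4 Y)
    x_genes = list(range(config.n_genes - 12, config.n_genes - 4))
    y_genes = list(range(config.n_genes - 4, config.n_genes))
    gene_chrom = [str(rng.integers(1, 23)) for _ in genes]
    for gi in x_genes:
        gene_chrom[gi] = "X"
    for gi in y_genes:
        gene_chrom[gi] = "Y"
    gene_tss = rng.integers(1_000_000, 100_000_000, size=config.n_genes)
    cpg_chrom = [str(rng.integers(1, 23)) for _ in cpgs]
    cpg_pos = rng.integers(1_000_000, 100_000_000, size=config.n_cpgs)
    # pair the first n_md CpGs with the first n_md genes inside the promoter window
    for i in range(n_md):
        cpg_chrom[i] = gene_chrom[i]
        cpg_pos[i] = gene_tss[i] + rng.integers(-1500, 1501)
    annotation = pd.DataFrame({
        "feature": genes + cpgs,
        "kind": ["gene"] * config.n_genes + ["cpg"] * config.n_cpgs,
        "chrom": gene_chrom + cpg_chrom,
        "position": np.concatenate([gene_tss, cpg_pos]),
        "strand": ["+"] * (config.n_genes + config.n_cpgs),
    })

    # --- methylation --------------------------------------------------------
    # denser, smaller loadings than expression: array variance is diffuse
    # flat loading magnitudes (random sign): array variance concentrates in a
    # moderate panel of comparably informative CpGs rather than a few extremes
    meth_sparsity = max(config.loading_sparsity - 0.2, 0.0)
    w_meth = 0.6 * rng.choice([-1.0, 1.0], size=(config.n_cpgs, k))
    w_meth[rng.random((config.n_cpgs, k)) < meth_sparsity] = 0.0
    w_meth[:n_md, :] = 0.0
    w_meth[:n_md, 0] = 0.8  # driven CpGs load strongly on factor 1
    m_baseline = rng.normal(0, 1.5, size=config.n_cpgs)
    m_baseline[:n_md] = 0.0  # keep driven CpGs centred so beta spans (0, 1)
    m_values = m_baseline[:, None] + w_meth @ z.T
    if config.meth_noise_sd > 0:
        m_values = m_values + rng.normal(0, config.meth_noise_sd, size=m_values.shape)
    beta = _beta_from_m(m_values)

    # --- clinical ----------------------------------------------------------
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    age_class = rng.choice(["(15,40]", "(40,60]", "(60,90]"], size=n, p=[0.2, 0.4, 0.4])
    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=[0.4, 0.3, 0.2, 0.1])
    smoking = rng.choice(["non-smoker", "smoker"], size=n)
    batch = rng.choice(["batch1", "batch2"], size=n)

    log_h = dict(zip(CLUSTERS, config.survival_log_hazards))
    hazards = np.array([np.exp(log_h[molecular[i]]) for i in range(n)])
    t_event = rng.exponential(1.0 / hazards)
    censored = rng.random(n) < config.censor_rate
    u = rng.random(n)
    time = np.where(censored, t_event * u, t_event)
    event = (~censored).astype(int)

    clinical = pd.DataFrame({
        "sample": samples,
        "histology": morphology,
        "sex": sex,
        "age_class": age_class,
        "stage": stage,
        "smoking": smoking,
        "batch": batch,
        "survival_months": np.round(time, 4),
        "event": event,
    })

    # --- immune fractions ---------------------------------------------------
    imm_means = np.asarray(config.immune_fractions, dtype=float)
    cluster_index = {"A": 0, "B": 1, "C": 2}
    frac = np.empty((n, len(CELL_TYPES)))
    for i in range(n):
        base = imm_means[cluster_index[molecular[i]]]
        noisy = np.clip(base + rng.normal(0, 0.01, size=base.shape), 0, None)
        total = noisy.sum()
        if total > 0.95:
            noisy *= 0.95 / total
        frac[i] = noisy

    signature = pd.DataFrame(
        SIGNATURE_LOW, index=genes[n_md:n_md + n_sig], columns=list(CELL_TYPES)
    )
    for ti in range(len(CELL_TYPES)):
        block = slice(ti * N_SIGNATURE_GENES_PER_TYPE, (ti + 1) * N_SIGNATURE_GENES_PER_TYPE)
        signature.iloc[block, ti] = SIGNATURE_HIGH

    # --- expression ---------------------------------------------------------
    w_expr = rng.normal(0, 0.45, size=(config.n_genes, k))
    w_expr[rng.random((config.n_genes, k)) < config.loading_sparsity] = 0.0
    baseline = rng.normal(3.5, 1.2, size=config.n_genes)
    lib = rng.uniform(*config.library_size_range, size=n)
    log_mu = baseline[:, None] + w_expr @ z.T + np.log(lib / 1e6)[None, :]
    # methylation-driven genes: promoter M-value suppresses expression
    log_mu[:n_md, :] += -0.8 * m_values[:n_md, :]
    # immune signature genes: linear mixing of cell-type profiles on the CPM scale
    sig_rows = slice(n_md, n_md + n_sig)
    mix = signature.to_numpy() @ frac.T + OTHER_BACKGROUND * (1 - frac.sum(axis=1))[None, :]
    log_mu[sig_rows, :] = np.log(mix) + np.log(lib / 1e6)[None, :]
    # sex-linked genes
    male = (sex == "male").astype(float)
    for gi in y_genes:
        log_mu[gi, :] = 0.3 + 3.2 * male + np.log(lib / 1e6)
    for gi in x_genes:
        log_mu[gi, :] += 0.7 * (1 - male)
    mu = np.exp(log_mu)
    if config.nb_dispersion > 0:
        size = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    else:
        counts = rng.poisson(mu)

    expression = pd.DataFrame(counts, index=genes, columns=samples)
    methylation = pd.DataFrame(beta, index=cpgs, columns=samples)

    # --- missing omic blocks (disjoint sample sets) -------------------------
    n_missing = int(np.floor(config.missing_block_fraction * n))
    order = rng.permutation(n)
    miss_expr = sorted(order[:n_missing])
    miss_meth = sorted(order[n_missing:2 * n_missing])
    expression = expression.drop(columns=[samples[i] for i in miss_expr])
    methylation = methylation.drop(columns=[samples[i] for i in miss_meth])

    # --- mutations ----------------------------------------------------------
    rates = config.mutation_rates if config.mutation_rates is not None else default_mutation_rates()
    mut = np.zeros((len(rates), n), dtype=int)
    for j in range(n):
        p = rates[molecular[j]].to_numpy()
        mut[:, j] = rng.random(len(rates)) < p
    mutations = pd.DataFrame(mut, index=list(rates.index), columns=samples)

    truth = pd.DataFrame({
        "sample": samples,
        "cluster": molecular,
        "role": roles,
        **{f"factor{j + 1}": z[:, j] for j in range(k)},
        **{f"frac_{ct}": frac[:, ti] for ti, ct in enumerate(CELL_TYPES)},
    })

    return Cohort(
        expression=expression,
        methylation=methylation,
        clinical=clinical,
        mutations=mutations,
        annotation=annotation,
        signature=signature,
        truth=truth,
        config=config,
    )


def default_gene_sets(cohort: Cohort) -> dict[str, list[str]]:
    """Synthetic hallmark-like gene sets over the mutation gene universe.

    H_PROLIFERATION contains the cluster-enriched genes MUT001-MUT003 (so
    cluster-specific enrichment is plantable); the other two sets are fixed
    slices of the background genes.
    """
    genes = list(cohort.mutations.index)
    return {
        "H_PROLIFERATION": genes[0:8],
        "H_GENOME_INSTABILITY": genes[8:18],
        "H_EVASION": genes[18:30],
    }


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_FILES = {
    "expression": "expression.tsv",
    "methylation": "methylation.tsv",
    "clinical": "clinical.tsv",
    "mutations": "mutations.tsv",
    "annotation": "annotation.tsv",
    "truth": "truth.tsv",
    "signature": "signature.tsv",
}


def _config_to_dict(config: SimConfig) -> dict:
    d = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, pd.DataFrame):
            v = None  # mutation-rate tables travel in their own TSV
        elif isinstance(v, tuple):
            v = list(v)
        d[f.name] = v
    return d


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort as plain TSV matrices plus a manifest; exact round trip."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for attr, fname in _FILES.items():
        df = getattr(cohort, attr)
        if df is None:
            continue
        path = directory / fname
        index = attr not in ("clinical", "annotation", "truth")
        # %.17g guarantees bit-exact float round trips through the TSV
        df.to_csv(path, sep="\t", index=index, float_format="%.17g",
                  index_label="feature" if index else None)
        out[attr] = path
    manifest = {"format": "neomix-cohort/1"}
    if cohort.config is not None:
        manifest["seed"] = cohort.config.seed
        manifest["config"] = _config_to_dict(cohort.config)
    mpath = directory / "manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    out["manifest"] = mpath
    return out


def read_cohort(directory: str | Path) -> Cohort:
    directory = Path(directory)

    def _read(fname, index):
        path = directory / fname
        if not path.exists():
            return None
        df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                         dtype={"chrom": str} if "annotation" in fname else None)
        if index:
            df = df.set_index("feature")
            df.index.name = None
        return df

    expression = _read(_FILES["expression"], True)
    methylation = _read(_FILES["methylation"], True)
    clinical = _read(_FILES["clinical"], False)
    mutations = _read(_FILES["mutations"], True)
    annotation = _read(_FILES["annotation"], False)
    truth = _read(_FILES["truth"], False)
    signature = _read(_FILES["signature"], True)
    config = None
    mpath = directory / "manifest.yaml"
    if mpath.exists():
        with open(mpath) as fh:
            manifest = yaml.safe_load(fh)
        cd = manifest.get("config")
        if cd is not None:
            cd = dict(cd)
            cd["cluster_factor_means"] = np.asarray(cd["cluster_factor_means"], dtype=float)
            cd["immune_fractions"] = np.asarray(cd["immune_fractions"], dtype=float)
            for key in ("cluster_sizes", "survival_log_hazards", "library_size_range"):
                cd[key] = tuple(cd[key])
            if cd.get("mutation_rates") is None:
                cd["mutation_rates"] = None
            config = SimConfig(**cd)
    return Cohort(
        expression=expression,
        methylation=methylation,
        clinical=clinical,
        mutations=mutations,
        annotation=annotation,
        signature=signature,
        truth=truth,
        config=config,
    )
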