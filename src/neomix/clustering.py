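"""Subsample-replicate consensus clustering on latent factors.

Each replicate refits the joint factor model on an 80% subsample of the
cohort and k-means-partitions the resulting factor coordinates; the
consensus value of a sample pair is the fraction of co-sampled replicates
in which they co-clustered.  Final labels come from a median-linkage
hierarchy of (1 - consensus); the number of clusters is chosen by the Dunn
index of the candidate partitions in full-data factor space.

Two modes mirror the two clustering variants of the analysis: ``kminus1``
uses the K-1 leading factors for a K-cluster solution; ``weighted`` uses
all retained factors with per-factor weights equal to their total
variance-explained fraction inside the squared distance (implemented by
scaling coordinates with sqrt(weight), which turns weighted k-means into
ordinary k-means).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from neomix.factors import FactorModel, fit_joint_factors


class InsufficientReplicatesError(RuntimeError):
    pass


@dataclass
class ConsensusResult:
    consensus: pd.DataFrame                  # chosen-K consensus matrix
    cosampled: pd.DataFrame                  # co-sampling counts
    labels_per_k: dict = field(default_factory=dict)   # K -> Series of labels
    dunn_per_k: dict = field(default_factory=dict)     # K -> Dunn index
    chosen_k: int = 0
    n_replicates: int = 0
    subsample: float = 0.8
    mode: str = "kminus1"
    consensus_per_k: dict = field(default_factory=dict)
    replicates: list = field(default_factory=list)  # per replicate: (samples, {K: labels})

    @property
    def labels(self) -> pd.Series:
        return self.labels_per_k[self.chosen_k]


def _standardized_scores(model: FactorModel) -> np.ndarray:
    z = model.Z.to_numpy(dtype=float)
    sd = z.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (z - z.mean(axis=0)) / sd


def _varexp_weights(model: FactorModel) -> np.ndarray:
    w = model.total_varexp.to_numpy(dtype=float)
    return w / w.sum() if w.sum() > 0 else np.full_like(w, 1.0 / len(w))


def _coordinates(model: FactorModel, K: int, mode: str) -> np.ndarray:
    # factor scores are standardized so the clustering geometry is not
    # distorted by the per-factor scale of the decomposition
    zs = _standardized_scores(model)
    if mode == "kminus1":
        if K > 1 and zs.shape[1] < K - 1:
            raise ValueError(f"need at least K-1={K - 1} factors, model has {zs.shape[1]}")
        return zs[:, : max(K - 1, 1)]
    if mode == "weighted":
        return zs * np.sqrt(_varexp_weights(model))[None, :]
    raise ValueError(f"unknown mode {mode!r}")


def kmeans_on_factors(model: FactorModel, K: int, mode: str = "kminus1", seed: int = 0) -> pd.Series:
    """Lloyd k-means (k-means++, 25 restarts, best inertia) on standardized factor scores."""
    n = model.Z.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds the {n} samples")
    if K == 1:
        return pd.Series(0, index=model.Z.index, name="label")
    coords = _coordinates(model, K, mode)
    km = KMeans(n_clusters=K, init="k-means++", n_init=25, random_state=seed).fit(coords)
    return pd.Series(km.labels_, index=model.Z.index, name="label")


def dunn_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Min inter-cluster distance over max cluster diameter (Euclidean)."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Dunn index requires at least two clusters")
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    dist = squareform(pdist(points))
    max_diam = 0.0
    for c in uniq:
        members = np.flatnonzero(labels == c)
        if len(members) > 1:
            max_diam = max(max_diam, float(dist[np.ix_(members, members)].max()))
    min_sep = np.inf
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            ma, mb = np.flatnonzero(labels == a), np.flatnonzero(labels == b)
            min_sep = min(min_sep, float(dist[np.ix_(ma, mb)].min()))
    if max_diam == 0.0:
        return np.inf
    return min_sep / max_diam


def consensus_cluster(
    blocks: dict,
    K_range=range(2, 6),
    R: int = 100,
    subsample: float = 0.8,
    mode: str = "kminus1",
    seed: int = 0,
    n_factors: int = 5,
    min_varexp: float = 0.0,
    tol: float = 1e-6,
    full_model: FactorModel | None = None,
) -> ConsensusResult:
    """Consensus clustering over R subsample/refit/k-means replicates.

    For every replicate one 80% subsample is drawn without replacement, the
    joint factor model is refitted on it, and a k-means partition is produced
    for every K in ``K_range``.  Per K, the consensus matrix is co-clustered
    counts over co-sampled counts; its median-linkage hierarchy cut at K
    gives the candidate labels, and the Dunn index of those labels in
    full-data factor coordinates selects the final K.
    """
    if R < 2:
        raise ValueError("need at least two replicates")
    if not 0 < subsample <= 1:
        raise ValueError("subsample must lie in (0, 1]")
    K_range = list(K_range)
    rng = np.random.default_rng(seed)

    if full_model is None:
        full_model = fit_joint_factors(blocks, n_factors, tol=tol)
    samples = list(full_model.Z.index)
    n = len(samples)
    pos = {s: i for i, s in enumerate(samples)}

    m = int(np.ceil(subsample * n))
    cosampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in K_range}
    replicate_log = []
    for r in range(R):
        sub_idx = np.sort(rng.choice(n, size=m, replace=False))
        sub_samples = [samples[i] for i in sub_idx]
        sub_blocks = {
            name: b[[s for s in b.columns if s in set(sub_samples)]]
            for name, b in blocks.items()
        }
        sub_blocks = {k: v for k, v in sub_blocks.items() if v.shape[1] > 0}
        model_r = fit_joint_factors(sub_blocks, n_factors, tol=tol)
        present = [s for s in model_r.Z.index]
        ii = np.array([pos[s] for s in present])
        cosampled[np.ix_(ii, ii)] += 1
        rep_labels = {}
        for K in K_range:
            labels_r = kmeans_on_factors(model_r, K, mode=mode, seed=int(rng.integers(2**31)))
            rep_labels[K] = labels_r
            lab = labels_r.to_numpy()
            same = (lab[:, None] == lab[None, :]).astype(float)
            co_clustered[K][np.ix_(ii, ii)] += same
        replicate_log.append((present, rep_labels))

    off_diag = ~np.eye(n, dtype=bool)
    if (cosampled[off_diag] == 0).any():
        raise InsufficientReplicatesError(
            "some sample pairs were never co-sampled; increase R"
        )

    # Dunn indices for different K must be comparable, so each candidate K is
    # scored in one common space: the standardized leading factors that
    # jointly account for >= 90% of the total variance explained (minimum
    # two) — the axes that carry the biological signal — using the full-data
    # k-means partition at that K (the same operation the replicates run);
    # the returned labels still come from the consensus hierarchy
    weights = _varexp_weights(full_model)
    n_lead = max(2, int(np.searchsorted(np.cumsum(weights), 0.9) + 1))
    n_lead = min(n_lead, len(weights))
    coords = _standardized_scores(full_model)[:, :n_lead]
    labels_per_k, dunn_per_k, consensus_per_k = {}, {}, {}
    for K in K_range:
        c = co_clustered[K] / np.maximum(cosampled, 1)
        np.fill_diagonal(c, 1.0)
        c = (c + c.T) / 2
        consensus_per_k[K] = pd.DataFrame(c, index=samples, columns=samples)
        zlink = linkage(squareform(1.0 - c, checks=False), method="median")
        lab = fcluster(zlink, t=K, criterion="maxclust")
        labels_per_k[K] = pd.Series(lab, index=samples, name="label")
        km_lab = kmeans_on_factors(full_model, K, mode=mode, seed=seed).to_numpy()
        if len(np.unique(km_lab)) >= 2:
            dunn_per_k[K] = dunn_index(coords, km_lab)
        else:
            dunn_per_k[K] = -np.inf
    chosen_k = max(dunn_per_k, key=lambda k: dunn_per_k[k])
    return ConsensusResult(
        consensus=consensus_per_k[chosen_k],
        cosampled=pd.DataFrame(cosampled, index=samples, columns=samples),
        labels_per_k=labels_per_k,
        dunn_per_k=dunn_per_k,
        chosen_k=chosen_k,
        n_replicates=R,
        subsample=subsample,
        mode=mode,
        consensus_per_k=consensus_per_k,
        replicates=replicate_log,
    )
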