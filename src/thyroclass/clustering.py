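"""Cluster inference for tumor expression profiles.

The workflow answers four questions about a cohort's expression matrix:

* **Is it clusterable at all?** The Hopkins statistic H contrasts
  nearest-neighbor distances of uniform pseudo-points against those of real
  samples; 1-H < 0.5 indicates non-random structure. The statistic is
  bootstrapped (default 512 replicates) and the mean is used.
* **How many clusters?** A consensus over internal validity indices: each
  bootstrap replicate draws 10% of genes, builds WPGMA partitions for every
  candidate k, and lets each index in the panel vote for its best k; the
  modal k wins (ties toward smaller k).
* **Which samples go together?** Agglomerative clustering with the WPGMA
  (McQuitty) linkage update d(a+b, x) = (d(a,x) + d(b,x)) / 2, cut into the
  chosen number of clusters, and visualized by PCA.
* **What are the driver-negative samples?** Each cluster is typed by the
  majority driver lesion among its mutation-positive members; negatives
  inherit the cluster's type as negative-BL (BRAF-like) or negative-RL
  (RAS-like).

Distances are Euclidean on log2(FPM+1) profiles throughout; Hopkins is
computed in a reduced PCA space (default 10 components) to avoid the
distance degeneracy of very high-dimensional data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.decomposition import PCA
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .exceptions import ConfigError, UnresolvedClusterError, ValidationError


@dataclass
class ClusterResult:
    """Everything the clustering stage reports for a cohort."""

    hopkins_mean: float
    clusterable: bool
    per_k_votes: dict[int, int]
    chosen_k: int
    linkage_tree: np.ndarray
    labels: dict[str, int]
    pca_coords: pd.DataFrame
    outliers: set[str]
    negative_assignments: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Clusterability


def _sample_space(matrix: pd.DataFrame) -> np.ndarray:
    """Samples-as-rows array from a genes x samples expression frame."""
    return matrix.to_numpy(dtype=float).T


def _reduce(X: np.ndarray, n_components: int) -> np.ndarray:
    # Reduce only when the ambient dimension exceeds the target: rotating
    # low-dimensional data would put the bounding box's empty corners into
    # the pseudo-point support and bias the Hopkins null away from 0.5.
    q = min(n_components, X.shape[0] - 1)
    if q < 1 or X.shape[1] <= q:
        return X
    return PCA(n_components=q, svd_solver="full", random_state=0).fit_transform(X)


def hopkins_statistic(
    matrix: pd.DataFrame,
    probe_fraction: float = 0.1,
    seed: int | Sequence[int] | np.random.Generator | None = None,
    n_components: int = 10,
) -> float:
    """Hopkins clusterability statistic H in [0, 1].

    H = sum(u) / (sum(u) + sum(w)) where u are nearest-real-neighbor
    distances of uniform pseudo-points drawn in the bounding box of the
    PCA-reduced data and w are nearest-neighbor distances of a
    ``probe_fraction`` subsample of real points (self excluded). H near 1
    (1-H near 0) means clustered; H near 0.5 means spatially random.
    """
    n = matrix.shape[1]
    if n < 3:
        raise ValidationError(f"Hopkins statistic needs >= 3 samples, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z = _reduce(_sample_space(matrix), n_components)
    m = max(1, int(round(probe_fraction * n)))
    probes = rng.choice(n, size=m, replace=False)
    d_real = cdist(Z[probes], Z)
    d_real[np.arange(m), probes] = np.inf  # exclude self
    w = d_real.min(axis=1)
    lo, hi = Z.min(axis=0), Z.max(axis=0)
    pseudo = rng.uniform(lo, hi, size=(m, Z.shape[1]))
    u = cdist(pseudo, Z).min(axis=1)
    denom = u.sum() + w.sum()
    if denom == 0:
        return 0.5
    return float(u.sum() / denom)


def bootstrapped_clusterability(
    matrix: pd.DataFrame,
    reps: int = 512,
    seed: int = 0,
    probe_fraction: float = 0.1,
    n_components: int = 10,
) -> tuple[float, bool]:
    """Mean 1-H over ``reps`` independent Hopkins replicates.

    Returns (mean 1-H, clusterable), where clusterable means mean 1-H < 0.5.
    Replicate r uses the derived seed [seed, r], so the result is
    reproducible and a single replicate equals ``hopkins_statistic`` with
    seed [seed, 0].
    """
    values = [
        1.0 - hopkins_statistic(
            matrix, probe_fraction=probe_fraction, seed=[seed, r], n_components=n_components
        )
        for r in range(reps)
    ]
    mean = float(np.mean(values))
    return mean, mean < 0.5


# ---------------------------------------------------------------------------
# WPGMA clustering


def wpgma_linkage(dist: np.ndarray) -> np.ndarray:
    """WPGMA (McQuitty) linkage from a condensed or square distance matrix."""
    if dist.ndim == 2:
        dist = squareform(dist, checks=False)
    return linkage(dist, method="weighted")


def wpgma_cluster(
    matrix: pd.DataFrame, k: int
) -> tuple[np.ndarray, dict[str, int]]:
    """Cluster samples into ``k`` groups by WPGMA on Euclidean distances.

    Returns the scipy-format merge history and a sample -> cluster-id map
    (ids 1..k). Deterministic for a given input order.
    """
    n = matrix.shape[1]
    if k > n:
        raise ValidationError(f"cannot cut {n} samples into {k} clusters")
    X = _sample_space(matrix)
    Z = wpgma_linkage(pdist(X))
    flat = fcluster(Z, t=k, criterion="maxclust")
    return Z, dict(zip(matrix.columns, (int(c) for c in flat)))


# ---------------------------------------------------------------------------
# Consensus number of clusters


def _within_ss(X: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squared distances to centroids."""
    total = 0.0
    for c in np.unique(labels):
        sub = X[labels == c]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def _pair_masks(labels: np.ndarray) -> np.ndarray:
    """Condensed-form boolean mask: True where a pair is within one cluster."""
    return pdist(labels[:, None].astype(float), metric="hamming") == 0


def _index_calinski(X, dist_sq, labels_by_k, W, k_range, rng):
    scores = {k: calinski_harabasz_score(X, labels_by_k[k]) for k in k_range}
    return max(scores, key=lambda k: (scores[k], -k))


def _index_silhouette(X, dist_sq, labels_by_k, W, k_range, rng):
    scores = {
        k: silhouette_score(dist_sq, labels_by_k[k], metric="precomputed")
        for k in k_range
    }
    return max(scores, key=lambda k: (scores[k], -k))


def _index_davies_bouldin(X, dist_sq, labels_by_k, W, k_range, rng):
    scores = {k: davies_bouldin_score(X, labels_by_k[k]) for k in k_range}
    return min(scores, key=lambda k: (scores[k], k))


def _index_dunn(X, dist_sq, labels_by_k, W, k_range, rng):
    cond = squareform(dist_sq, checks=False)
    scores = {}
    for k in k_range:
        within = _pair_masks(labels_by_k[k])
        if within.all() or (~within).all():
            continue
        diam = cond[within].max()
        sep = cond[~within].min()
        scores[k] = sep / diam if diam > 0 else np.inf
    if not scores:
        return None
    return max(scores, key=lambda k: (scores[k], -k))


def _index_c(X, dist_sq, labels_by_k, W, k_range, rng):
    cond = np.sort(squareform(dist_sq, checks=False))
    scores = {}
    for k in k_range:
        within = _pair_masks(labels_by_k[k])
        nw = int(within.sum())
        if nw == 0:
            continue
        sw = squareform(dist_sq, checks=False)[within].sum()
        smin, smax = cond[:nw].sum(), cond[-nw:].sum()
        if smax > smin:
            scores[k] = (sw - smin) / (smax - smin)
    if not scores:
        return None
    return min(scores, key=lambda k: (scores[k], k))


def _index_mcclain_rao(X, dist_sq, labels_by_k, W, k_range, rng):
    cond = squareform(dist_sq, checks=False)
    scores = {}
    for k in k_range:
        within = _pair_masks(labels_by_k[k])
        if within.any() and (~within).any():
            scores[k] = cond[within].mean() / cond[~within].mean()
    if not scores:
        return None
    return min(scores, key=lambda k: (scores[k], k))


def _index_point_biserial(X, dist_sq, labels_by_k, W, k_range, rng):
    cond = squareform(dist_sq, checks=False)
    nt = cond.size
    scores = {}
    for k in k_range:
        within = _pair_masks(labels_by_k[k])
        nw, nb = int(within.sum()), int((~within).sum())
        if nw == 0 or nb == 0:
            continue
        scores[k] = (cond[~within].mean() - cond[within].mean()) * np.sqrt(nw * nb) / nt
    if not scores:
        return None
    return max(scores, key=lambda k: (scores[k], -k))


def _index_hartigan(X, dist_sq, labels_by_k, W, k_range, rng):
    # rule of thumb: smallest k whose Hartigan index drops to <= 10;
    # if none does, the k minimizing the index
    n = X.shape[0]
    scores = {}
    for k in k_range:
        if k + 1 not in W or W[k + 1] <= 0:
            continue
        scores[k] = (W[k] / W[k + 1] - 1.0) * (n - k - 1)
    if not scores:
        return None
    for k in sorted(scores):
        if scores[k] <= 10.0:
            return k
    return min(scores, key=lambda k: (scores[k], k))


def _index_krzanowski_lai(X, dist_sq, labels_by_k, W, k_range, rng):
    p = X.shape[1]

    def diff(k):
        return (k - 1) ** (2.0 / p) * W.get(k - 1, np.nan) - k ** (2.0 / p) * W.get(k, np.nan)

    scores = {}
    for k in k_range:
        d1, d2 = diff(k), diff(k + 1)
        if np.isfinite(d1) and np.isfinite(d2) and d2 != 0:
            scores[k] = abs(d1 / d2)
    if not scores:
        return None
    return max(scores, key=lambda k: (scores[k], -k))


def _index_gap(X, dist_sq, labels_by_k, W, k_range, rng, n_refs: int = 5):
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_wstar = {k: [] for k in k_range}
    ref_ks = sorted(set(k_range) | {max(k_range) + 1})
    for _ in range(n_refs):
        ref = rng.uniform(lo, hi, size=X.shape)
        Zr = wpgma_linkage(pdist(ref))
        for k in ref_ks:
            lab = fcluster(Zr, t=k, criterion="maxclust")
            w = _within_ss(ref, lab)
            if w > 0:
                log_wstar.setdefault(k, []).append(np.log(w))
    gap, sk = {}, {}
    for k in ref_ks:
        vals = log_wstar.get(k, [])
        if not vals or W.get(k, 0) <= 0:
            continue
        gap[k] = float(np.mean(vals) - np.log(W[k]))
        sk[k] = float(np.std(vals) * np.sqrt(1 + 1 / len(vals)))
    usable = [k for k in k_range if k in gap]
    if not usable:
        return None
    for k in usable:
        if k + 1 in gap and gap[k] >= gap[k + 1] - sk[k + 1]:
            return k
    return max(usable, key=lambda k: (gap[k], -k))


#: Default panel of internal validity indices used for the consensus vote.
DEFAULT_INDEX_PANEL: dict[str, Callable] = {
    "calinski_harabasz": _index_calinski,
    "silhouette": _index_silhouette,
    "davies_bouldin": _index_davies_bouldin,
    "dunn": _index_dunn,
    "c_index": _index_c,
    "mcclain_rao": _index_mcclain_rao,
    "point_biserial": _index_point_biserial,
    "hartigan": _index_hartigan,
    "krzanowski_lai": _index_krzanowski_lai,
    "gap": _index_gap,
}


@dataclass
class ConsensusResult:
    per_k_votes: dict[int, int]
    chosen_k: int
    n_evaluations: int
    n_invalid: int


def consensus_cluster_number(
    matrix: pd.DataFrame,
    k_range: Iterable[int] = range(2, 9),
    indices: Mapping[str, Callable] | None = None,
    reps: int = 1080,
    gene_fraction: float = 0.1,
    seed: int = 0,
) -> ConsensusResult:
    """Bootstrapped multi-index consensus for the number of clusters.

    Each replicate draws ``gene_fraction`` of genes without replacement,
    builds WPGMA partitions for every k in ``k_range``, and lets every index
    in the panel vote for one k. The chosen k is the mode over all votes,
    ties broken toward smaller k. Indices that cannot produce a valid vote
    on a replicate are counted as invalid evaluations.
    """
    k_range = sorted(k_range)
    n = matrix.shape[1]
    if not k_range or k_range[0] < 2 or k_range[-1] > n - 1:
        raise ValidationError(f"k_range must lie within [2, {n - 1}]")
    indices = dict(indices) if indices is not None else dict(DEFAULT_INDEX_PANEL)
    if not indices:
        raise ConfigError("index panel is empty")
    n_genes = matrix.shape[0]
    m = max(1, int(round(gene_fraction * n_genes)))
    votes = {k: 0 for k in k_range}
    invalid = 0
    # W is needed one k beyond the range on each side (Hartigan, KL, gap)
    eval_ks = [k for k in range(k_range[0] - 1, k_range[-1] + 2) if 1 <= k <= n]
    for r in range(reps):
        rng = np.random.default_rng([seed, r])
        gene_idx = rng.choice(n_genes, size=m, replace=False)
        X = matrix.iloc[gene_idx].to_numpy(dtype=float).T
        cond = pdist(X)
        dist_sq = squareform(cond)
        Z = linkage(cond, method="weighted")
        labels_by_k = {k: fcluster(Z, t=k, criterion="maxclust") for k in eval_ks}
        W = {k: _within_ss(X, labels_by_k[k]) for k in eval_ks}
        for fn in indices.values():
            try:
                k = fn(X, dist_sq, labels_by_k, W, list(k_range), rng)
            except Exception:
                k = None
            if k is None or k not in votes:
                invalid += 1
            else:
                votes[k] += 1
    chosen = max(votes, key=lambda k: (votes[k], -k))
    n_eval = reps * len(indices)
    return ConsensusResult(
        per_k_votes=votes, chosen_k=chosen, n_evaluations=n_eval, n_invalid=invalid
    )


# ---------------------------------------------------------------------------
# Projection, outliers, group assignment


def pca_project(matrix: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Project gene-centered sample profiles onto the top principal components.

    The sign of each component is fixed so that its largest-magnitude gene
    loading is positive, making coordinates reproducible across runs.
    """
    n, g = matrix.shape[1], matrix.shape[0]
    if n < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if n_components > min(n, g):
        raise ValidationError(f"n_components={n_components} exceeds matrix rank bound")
    X = _sample_space(matrix)
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    coords = pca.fit_transform(X)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] = -coords[:, j]
    return pd.DataFrame(
        coords, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(n_components)]
    )


def flag_outliers(matrix: pd.DataFrame, z_threshold: float = 3.0) -> set[str]:
    """Samples whose mean distance to all others is > mean + z * SD of that quantity."""
    n = matrix.shape[1]
    if n < 4:
        raise ValidationError("outlier detection needs >= 4 samples")
    d = squareform(pdist(_sample_space(matrix)))
    mean_d = d.sum(axis=1) / (n - 1)
    mu, sd = mean_d.mean(), mean_d.std(ddof=0)
    cut = mu + z_threshold * sd
    return {s for s, v in zip(matrix.columns, mean_d) if sd > 0 and v > cut}


_BRAF_DRIVERS = {"positive-BRAF"}
_RAS_DRIVERS = {"positive-RAS", "positive-PAX8-PPARg"}


def assign_negative_classes(
    labels: Mapping[str, int],
    driver_status: Mapping[str, str],
    histology: Mapping[str, str] | None = None,
    other_histologies: Iterable[str] = ("HCC",),
) -> dict[str, str]:
    """Type driver-negative samples by their cluster's majority driver lesion.

    A cluster whose driver-positive members are mostly BRAF-mutant is
    BRAF-type; mostly RAS/PAX8-PPARg-mutant is RAS-type. Negatives inherit
    the type as "negative-BL" / "negative-RL"; negatives whose histology is
    in ``other_histologies`` (e.g. Hürthle-cell carcinoma) are reported as
    "negative-other" instead. A cluster with no positives, or a tie, raises
    UnresolvedClusterError naming the affected negatives.
    """
    histology = histology or {}
    other_histologies = set(other_histologies)
    clusters: dict[int, list[str]] = {}
    for s, c in labels.items():
        if s not in driver_status:
            raise ValidationError(f"sample {s!r} has no driver status")
        clusters.setdefault(c, []).append(s)

    assignments: dict[str, str] = {}
    for c, members in sorted(clusters.items()):
        negatives = [s for s in members if driver_status[s] == "negative"]
        n_braf = sum(driver_status[s] in _BRAF_DRIVERS for s in members)
        n_ras = sum(driver_status[s] in _RAS_DRIVERS for s in members)
        if negatives and (n_braf + n_ras == 0 or n_braf == n_ras):
            raise UnresolvedClusterError(
                f"cluster {c} cannot be typed (BRAF-positive={n_braf}, "
                f"RAS-positive={n_ras}); affected negatives: {sorted(negatives)}",
                negatives=sorted(negatives),
            )
        kind = "negative-BL" if n_braf > n_ras else "negative-RL"
        for s in negatives:
            if histology.get(s) in other_histologies:
                assignments[s] = "negative-other"
            else:
                assignments[s] = kind
    return assignments
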