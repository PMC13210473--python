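"""Fuzzy c-means clustering of standardized temporal abundance profiles.

Features are summarized as their mean abundance in each condition, in
design order (control -> drought -> rewatered), z-scored per feature with
the population SD, and partitioned into ``c`` soft clusters (default 5).
The implementation is the classical Bezdek alternating scheme with
Euclidean distances; soft memberships per feature sum to one and the hard
label is the argmax cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import InputError, OmicsMatrix

# Archetypal control->drought->rewatered trajectories used to anchor cluster
# identity (c-means cluster indices are arbitrary) and to simulate profiles.
ARCHETYPES: dict[str, tuple[float, float, float]] = {
    "up_recover": (0.0, 1.0, 0.0),
    "up_persist": (0.0, 1.0, 1.0),
    "down_recover": (0.0, -1.0, 0.0),
    "down_persist": (0.0, -1.0, -1.0),
    "late_up": (0.0, 0.0, 1.0),
}


def standardize_profiles(matrix: OmicsMatrix) -> pd.DataFrame:
    """Z-score per-feature condition-mean profiles (population SD).

    Returns a feature x condition frame; zero-variance (flat) profiles are
    excluded since they carry no temporal shape.
    """
    means = matrix.condition_means()
    if means.isna().any().any():
        means = means.dropna()
    arr = means.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    keep = sd[:, 0] > 0
    z = (arr[keep] - mu[keep]) / sd[keep]
    return pd.DataFrame(z, index=means.index[keep], columns=means.columns)


def _standardize_rows(arr: np.ndarray) -> np.ndarray:
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (arr - mu) / sd


def _kmeanspp_centroids(x: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centroids across the data."""
    n = x.shape[0]
    centroids = [x[rng.integers(n)]]
    for _ in range(c - 1):
        d2 = np.min(((x[:, None, :] - np.array(centroids)[None]) ** 2).sum(axis=2), axis=1)
        total = d2.sum()
        if total == 0:
            centroids.append(x[rng.integers(n)])
            continue
        centroids.append(x[rng.choice(n, p=d2 / total)])
    return np.array(centroids)


def _memberships_from_centroids(x: np.ndarray, centroids: np.ndarray, m: float):
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    d2 = np.maximum(d2, 1e-300)
    with np.errstate(over="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    # points coincident with a centroid get crisp membership there
    hits = d2 < 1e-250
    if hits.any():
        rows = hits.any(axis=1)
        u[rows] = hits[rows] / hits[rows].sum(axis=1, keepdims=True)
    return u, d2


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int = 5,
    m: float = 1.25,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
    n_init: int = 5,
) -> "ClusterResult":
    """Fuzzy c-means with fuzzifier ``m`` on the rows of ``profiles``.

    Alternates membership and centroid updates until the largest centroid
    shift falls below ``tol``.  Runs ``n_init`` k-means++-seeded restarts
    and keeps the partition with the lowest objective ``sum(u^m * d^2)``;
    deterministic for a fixed seed.
    """
    if m <= 1:
        raise InputError("fuzzifier m must be > 1")
    x = profiles.to_numpy(dtype=float)
    n, _ = x.shape
    if c > n:
        raise InputError(f"cannot form {c} clusters from {n} profiles")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(max(1, n_init)):
        centroids = _kmeanspp_centroids(x, c, rng)
        u, d2 = _memberships_from_centroids(x, centroids, m)
        for _ in range(max_iter):
            w = u**m
            new_centroids = (w.T @ x) / w.sum(axis=0)[:, None]
            u, d2 = _memberships_from_centroids(x, new_centroids, m)
            shift = np.abs(new_centroids - centroids).max()
            centroids = new_centroids
            if shift < tol:
                break
        objective = float((u**m * d2).sum())
        if best is None or objective < best[0]:
            best = (objective, u, centroids)
    _, u, centroids = best
    memberships = pd.DataFrame(
        u, index=profiles.index, columns=[f"C{i + 1}" for i in range(c)]
    )
    hard = memberships.to_numpy().argmax(axis=1) + 1
    return ClusterResult(
        memberships=memberships,
        hard_labels=pd.Series(hard, index=profiles.index, name="hard_label"),
        centroids=pd.DataFrame(centroids, index=memberships.columns, columns=profiles.columns),
    )


@dataclass
class ClusterResult:
    """Soft memberships (rows sum to 1), hard argmax labels, and centroids."""

    memberships: pd.DataFrame
    hard_labels: pd.Series
    centroids: pd.DataFrame

    def members(self, cluster: int | str, min_membership: float = 0.0) -> pd.Index:
        """Features hard-assigned to ``cluster`` with membership above a floor."""
        name = cluster if isinstance(cluster, str) else f"C{cluster}"
        idx = int(name[1:])
        mask = (self.hard_labels == idx) & (self.memberships[name] >= min_membership)
        return self.hard_labels.index[mask]

    def archetype_names(self) -> dict[str, str]:
        """Map each cluster to the nearest standardized archetype trajectory."""
        arch = _standardize_rows(np.array(list(ARCHETYPES.values()), dtype=float))
        names = list(ARCHETYPES)
        cent = _standardize_rows(self.centroids.to_numpy())
        out = {}
        for i, row in enumerate(cent):
            d = ((arch - row) ** 2).sum(axis=1)
            out[self.centroids.index[i]] = names[int(np.argmin(d))]
        return out


def cluster_layer(
    matrix: OmicsMatrix,
    c: int = 5,
    m: float = 1.25,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> ClusterResult:
    """Standardize condition-mean profiles and run fuzzy c-means."""
    return fuzzy_cmeans(standardize_profiles(matrix), c=c, m=m, seed=seed, tol=tol, max_iter=max_iter)


def cluster_pair_overlap(
    gene_cluster,
    prot_cluster,
    id_map: pd.Series | None = None,
) -> tuple[int, float | None, float | None]:
    """Shared membership between an RNA cluster and a protein cluster.

    ``id_map`` maps protein ids to gene ids (identity when omitted).
    Returns the overlap count and its percentage of each cluster, both
    rounded to two decimals; empty clusters yield ``None`` percentages.
    """
    genes = set(gene_cluster)
    prots = list(prot_cluster)
    if id_map is not None:
        prot_genes = {id_map[p] for p in prots if p in id_map.index}
    else:
        prot_genes = set(prots)
    n_overlap = len(genes & prot_genes)
    pct_genes = round(100.0 * n_overlap / len(genes), 2) if genes else None
    pct_prots = round(100.0 * n_overlap / len(prots), 2) if prots else None
    return n_overlap, pct_genes, pct_prots


def overlap_from_sizes(n_gene_cluster: int, n_prot_cluster: int, n_overlap: int):
    """Overlap percentages from printed cluster sizes alone."""
    if n_overlap > min(n_gene_cluster, n_prot_cluster):
        raise InputError("overlap larger than a cluster")
    pct_genes = round(100.0 * n_overlap / n_gene_cluster, 2) if n_gene_cluster else None
    pct_prots = round(100.0 * n_overlap / n_prot_cluster, 2) if n_prot_cluster else None
    return pct_genes, pct_prots
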