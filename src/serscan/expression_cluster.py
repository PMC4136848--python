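"""K-means clustering of expression profiles under Pearson distance.

Pearson distance (1 - r) equals half the squared Euclidean distance
between row-standardized profiles, so the clustering loop runs as
spherical k-means on standardized rows: assignment by maximum correlation
to the centroid, centroid direction from the mean of standardized member
rows.  Both steps are monotone in the Pearson-distance objective, which
keeps the inertia non-increasing across iterations.  Reported centroids
are arithmetic means of the raw member profiles (heatmap-ready values);
correlation to a centroid is identical for either representation's
cluster, since r is affine-invariant in each argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_context import TandemArray
from .seqdata import ExpressionMatrix

__all__ = [
    "ClusterParams",
    "ClusterResult",
    "pearson_distance",
    "kmeans_pearson",
    "median_center",
    "cluster_array_concordance",
]


@dataclass(frozen=True)
class ClusterParams:
    """Parameters of the Pearson-distance k-means run."""

    k: int = 30
    seed: int = 0
    restarts: int = 10
    max_iter: int = 100
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.restarts < 1 or self.max_iter < 1:
            raise ValueError("restarts and max_iter must be >= 1")


@dataclass
class ClusterResult:
    """Clustering output; cluster ids are contiguous 1..k."""

    assignments: dict[str, int]
    centroids: np.ndarray  # k x n_conditions, raw-value space
    inertia: float
    n_iter: int
    inertia_history: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def pearson_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """1 - Pearson correlation; in [0, 2].  Constant vectors are an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles differ in length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation is undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return 1.0 - max(-1.0, min(1.0, r))


def _standardize(X: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit norm; 1 - r = ||a - b||^2 / 2."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    return Xc / norms


def _assign(Z: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign rows of Z to the nearest centroid direction; return labels, d."""
    Cn = C / np.linalg.norm(C, axis=1, keepdims=True)
    sim = Z @ Cn.T  # correlation of each gene with each centroid
    labels = np.argmax(sim, axis=1)
    dist = 1.0 - sim[np.arange(Z.shape[0]), labels]
    return labels, dist


def _single_run(
    Z: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    n = Z.shape[0]
    # k-means++-style seeding under Pearson distance
    first = int(rng.integers(n))
    centers = [Z[first]]
    d2 = 1.0 - Z @ Z[first]
    d2 = np.maximum(d2, 0.0) ** 2
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centers.append(Z[idx])
        nd = np.maximum(1.0 - Z @ Z[idx], 0.0) ** 2
        d2 = np.minimum(d2, nd)
    C = np.array(centers)

    labels = np.full(n, -1)
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new_labels, dist = _assign(Z, C)
        # repair empty clusters by seizing the point farthest from its centroid
        for c in range(k):
            if not np.any(new_labels == c):
                far = int(np.argmax(dist))
                new_labels[far] = c
                dist[far] = 0.0
        newC = np.array([
            Z[new_labels == c].mean(axis=0) for c in range(k)
        ])
        # inertia measured after the update step, so both half-steps of an
        # iteration (assignment with old centroids, recentering) have taken
        # effect and the recorded sequence is non-increasing
        Cn = newC / np.linalg.norm(newC, axis=1, keepdims=True)
        inertia = float(np.sum(1.0 - np.einsum("ij,ij->i", Z, Cn[new_labels])))
        history.append(inertia)
        shift = np.linalg.norm(newC - C) / max(np.linalg.norm(C), 1e-12)
        converged = np.array_equal(new_labels, labels) or shift < tol
        labels, C = new_labels, newC
        if converged:
            break
    return labels, C, history[-1], n_iter, history


def kmeans_pearson(
    X: ExpressionMatrix, params: ClusterParams | None = None
) -> ClusterResult:
    """Best-of-restarts k-means under Pearson distance.

    Constant-profile genes are dropped with a warning before clustering
    (their correlation is undefined).  Deterministic under a fixed seed.
    """
    params = params or ClusterParams()
    values = X.values
    keep = np.ptp(values, axis=1) > 0
    if not np.all(keep):
        dropped = [g for g, k_ in zip(X.gene_ids, keep) if not k_]
        warnings.warn(
            f"dropping {len(dropped)} constant-profile genes: {dropped[:5]}..."
            if len(dropped) > 5 else
            f"dropping constant-profile genes: {dropped}",
            stacklevel=2,
        )
    gene_ids = [g for g, k_ in zip(X.gene_ids, keep) if k_]
    values = values[keep]
    n = len(gene_ids)
    if params.k > n:
        raise ValueError(f"k = {params.k} exceeds {n} usable genes")

    Z = _standardize(values)
    best: tuple | None = None
    for restart in range(params.restarts):
        rng = np.random.default_rng((params.seed, restart))
        run = _single_run(Z, params.k, rng, params.max_iter, params.tol)
        if best is None or run[2] < best[2]:
            best = run
    labels, _, inertia, n_iter, history = best

    # relabel clusters contiguously 1..k in order of first appearance
    remap: dict[int, int] = {}
    assignments: dict[str, int] = {}
    for g, lab in zip(gene_ids, labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        assignments[g] = remap[lab]
    centroids = np.array([
        values[labels == lab].mean(axis=0)
        for lab in sorted(remap, key=remap.get)
    ])
    return ClusterResult(
        assignments=assignments,
        centroids=centroids,
        inertia=inertia,
        n_iter=n_iter,
        inertia_history=history,
    )


def median_center(X: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's row median (display transform only).

    Idempotent: the centered row has median 0, so a second application
    changes nothing.  Clustering always uses the raw log2 values.
    """
    med = np.median(X.values, axis=1, keepdims=True)
    return ExpressionMatrix(
        gene_ids=list(X.gene_ids),
        condition_ids=list(X.condition_ids),
        values=X.values - med,
    )


def cluster_array_concordance(
    result: ClusterResult | Mapping[str, int],
    arrays: Sequence[TandemArray],
) -> pd.DataFrame:
    """Per-array expression-cluster composition.

    Reports, for each tandem array, the cluster of every member and the
    size of the largest subset of members sharing one cluster.  Members
    without an expression assignment are counted separately.
    """
    assignments = (
        result.assignments if isinstance(result, ClusterResult) else dict(result)
    )
    rows = []
    for a in arrays:
        clusters = [assignments.get(m) for m in a.member_ids]
        known = [c for c in clusters if c is not None]
        comp: dict[int, int] = {}
        for c in known:
            comp[c] = comp.get(c, 0) + 1
        rows.append(
            {
                "scaffold_id": a.scaffold_id,
                "n_members": a.size,
                "n_with_expression": len(known),
                "cluster_composition": ";".join(
                    f"{c}:{comp[c]}" for c in sorted(comp)
                ),
                "largest_same_cluster": max(comp.values()) if comp else 0,
            }
        )
    return pd.DataFrame(rows)
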