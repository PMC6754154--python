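"""Subtype clustering of autoencoder activations.

Each patient's activation vector ``h`` (how strongly each learned basis
trajectory is expressed in their curve) is embedded into two dimensions with
t-SNE and clustered there with k-means.  When the number of clusters is not
fixed a priori it is chosen from the k-means inertia curve (sum of squared
distances to the closest centroid) by the knee point: the ``K`` at maximum
perpendicular distance from the straight line joining the curve's endpoints,
a reproducible stand-in for eyeballing the elbow.

Validation summaries mirror the usual practice for this kind of analysis:
reordering the activation matrix rows by cluster (within-cluster similarity
becomes visible as horizontal bands) and per-cluster mean trajectories of
both measures at each biweekly grid point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from phqtraj.cohort import ConfigurationError
from phqtraj.gpr import FittedTrajectory

__all__ = [
    "ActivationMatrix",
    "SubtypeAssignment",
    "embed_and_cluster",
    "kmeans_inertia_curve",
    "knee_point",
    "group_mean_trajectories",
    "reorder_activations",
]

logger = logging.getLogger(__name__)


@dataclass
class ActivationMatrix:
    """Patient-by-latent-pattern activation values (rows follow ``patient_ids``)."""

    values: np.ndarray  # (n_patients, H)
    patient_ids: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.patient_ids = tuple(self.patient_ids)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.patient_ids):
            raise ValueError("one activation row per patient required")


@dataclass(frozen=True)
class SubtypeAssignment:
    patient_id: str
    embedding_xy: Tuple[float, float]
    cluster: int  # 1..K


def _fit_kmeans(X: np.ndarray, k: int, seed: int, n_init: int = 10) -> KMeans:
    return KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)


def kmeans_inertia_curve(
    X: np.ndarray, k_values: Sequence[int], seed: int
) -> Dict[int, Tuple[float, np.ndarray]]:
    """Best-of-restarts k-means inertia (and labels) per candidate ``K``.

    The returned curve is non-increasing in ``K`` by construction: whenever
    the restarts at ``K+1`` land worse than the ``K`` solution, one extra
    Lloyd run is seeded with the ``K`` centers plus the point farthest from
    its center, which can only lower the objective.
    """
    out: Dict[int, Tuple[float, np.ndarray]] = {}
    prev: Optional[KMeans] = None
    for k in sorted(int(k) for k in k_values):
        if k > X.shape[0]:
            raise ConfigurationError(f"K={k} exceeds the {X.shape[0]} available patients")
        km = _fit_kmeans(X, k, seed)
        if prev is not None and km.inertia_ > out[prev.n_clusters][0]:
            centers = prev.cluster_centers_
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1).min(1)
            extra = np.vstack([centers, X[int(np.argmax(d2))]])[:k]
            km2 = KMeans(n_clusters=k, init=extra, n_init=1, random_state=seed).fit(X)
            if km2.inertia_ < km.inertia_:
                km = km2
        out[k] = (float(km.inertia_), km.labels_.copy())
        prev = km
    return out


def knee_point(k_values: Sequence[int], inertias: Sequence[float]) -> int:
    """Maximum-curvature point of an inertia curve.

    The knee is the ``K`` whose (K, inertia) point lies farthest (in
    perpendicular distance) from the straight line joining the first and
    last points of the curve.  Both axes are rescaled to [0, 1] first —
    inertia units are arbitrary, so the geometry must be scale-invariant.
    """
    ks = np.asarray(k_values, dtype=float)
    ys = np.asarray(inertias, dtype=float)
    if ks.size < 3:
        return int(ks[int(np.argmin(ys))])
    kx = (ks - ks[0]) / (ks[-1] - ks[0])
    if ys[0] == ys[-1]:
        return int(ks[0])
    yy = (ys - ys[-1]) / (ys[0] - ys[-1])
    seg = np.array([kx[-1] - kx[0], yy[-1] - yy[0]])
    pts = np.stack([kx - kx[0], yy - yy[0]], axis=1)
    dist = np.abs(pts[:, 0] * seg[1] - pts[:, 1] * seg[0]) / np.hypot(*seg)
    return int(ks[int(np.argmax(dist))])


def embed_and_cluster(
    activations: ActivationMatrix,
    K: Union[int, str] = "auto",
    seed: int = 0,
    perplexity: float = 30.0,
    tsne_iterations: int = 1000,
    k_range: Tuple[int, int] = (2, 10),
) -> Tuple[List[SubtypeAssignment], np.ndarray, Dict[int, float]]:
    """t-SNE embedding of the activations followed by k-means in 2-D.

    ``K="auto"`` picks the cluster count at the knee of the inertia curve
    over ``k_range``.  Returns the per-patient assignments (clusters numbered
    1..K in order of first appearance), the 2-D embedding, and the inertia
    curve actually computed.
    """
    X = activations.values
    n = X.shape[0]
    if isinstance(K, int) and K > n:
        raise ConfigurationError(f"K={K} exceeds the {n} available patients")

    eff_perplexity = min(perplexity, max(1.0, (n - 1) / 3.0))
    emb = TSNE(
        n_components=2,
        perplexity=eff_perplexity,
        max_iter=tsne_iterations,
        random_state=seed,
        init="pca",
    ).fit_transform(X)
    emb = np.asarray(emb, dtype=float)

    if K == "auto":
        lo, hi = k_range
        ks = list(range(lo, min(hi, n) + 1))
        curve = kmeans_inertia_curve(emb, ks, seed)
        inertias = {k: curve[k][0] for k in ks}
        chosen = knee_point(ks, [inertias[k] for k in ks])
        labels = curve[chosen][1]
    elif isinstance(K, int) and K >= 1:
        curve = kmeans_inertia_curve(emb, [K], seed)
        inertias = {K: curve[K][0]}
        chosen, labels = K, curve[K][1]
    else:
        raise ConfigurationError("K must be a positive integer or 'auto'")

    # stable 1..K numbering in order of first appearance
    remap: Dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[int(lab)] = len(remap) + 1
    assignments = [
        SubtypeAssignment(pid, (float(emb[i, 0]), float(emb[i, 1])), remap[int(labels[i])])
        for i, pid in enumerate(activations.patient_ids)
    ]
    return assignments, emb, inertias


def group_mean_trajectories(
    assignments: Sequence[SubtypeAssignment],
    fitted: Sequence[FittedTrajectory],
) -> Dict[int, Dict[str, np.ndarray]]:
    """Pointwise mean fitted curve per cluster and measure.

    PHQ-8 means are reported as the per-item average (total / 8) so both
    measures share the 0-3 scale.  Clusters with no fitted members for a
    measure are omitted with a warning.
    """
    cluster_of = {a.patient_id: a.cluster for a in assignments}
    acc: Dict[int, Dict[str, List[np.ndarray]]] = {}
    for tr in fitted:
        c = cluster_of.get(tr.patient_id)
        if c is None:
            continue
        curve = tr.mean / 8.0 if tr.measure == "phq8" else tr.mean
        acc.setdefault(c, {}).setdefault(tr.measure, []).append(curve)
    out: Dict[int, Dict[str, np.ndarray]] = {}
    for c in sorted({a.cluster for a in assignments}):
        if c not in acc:
            logger.warning("cluster %d has no fitted trajectories; omitted", c)
            continue
        out[c] = {m: np.mean(np.stack(curves), axis=0) for m, curves in acc[c].items()}
    return out


def reorder_activations(
    activations: ActivationMatrix, assignments: Sequence[SubtypeAssignment]
) -> ActivationMatrix:
    """Group the activation rows contiguously by cluster.

    Clusters appear in index order and the original row order is preserved
    within each cluster (stable), which is what makes the banded structure
    of a well-clustered cohort visible in the matrix.
    """
    cluster_of = {a.patient_id: a.cluster for a in assignments}
    missing = [pid for pid in activations.patient_ids if pid not in cluster_of]
    if missing:
        raise ValueError(f"no cluster assignment for rows: {missing[:5]}")
    order = sorted(
        range(len(activations.patient_ids)),
        key=lambda i: (cluster_of[activations.patient_ids[i]], i),
    )
    return ActivationMatrix(
        values=activations.values[order],
        patient_ids=tuple(activations.patient_ids[i] for i in order),
    )
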