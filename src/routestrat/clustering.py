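"""Grouping strategically similar pathways by clustering their embeddings.

A trained pathway encoder maps every route for a target to a latent
vector; routes that differ only in tactically minor ways (e.g. the order
of two independent assembly steps) land close together, while genuinely
different retrosynthetic designs land apart.  Density-based clustering of
those vectors organizes the large route sets produced by synthesis-
planning searches into a handful of strategy groups plus noise, and a
2-D stochastic-neighbor projection of reaction embeddings serves as a
visual diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN
from sklearn.manifold import TSNE

from .network import Pathway
from .treelstm import PathwayEmbedding

__all__ = ["ClusterAssignment", "cluster_pathways", "cluster_report", "project_2d"]


@dataclass(frozen=True)
class ClusterAssignment:
    pathway_id: str
    cluster_id: int  # -1 denotes noise
    probability: float  # membership strength in [0, 1]


def cluster_pathways(
    embs: Sequence[PathwayEmbedding],
    min_cluster_size: int = 5,
    metric: str = "euclidean",
) -> list[ClusterAssignment]:
    """Density-cluster pathway embeddings (HDBSCAN); noise is labeled -1.

    Deterministic given inputs and parameters.  All embeddings must share
    one dimensionality and there must be at least two of them.
    """
    if len(embs) < 2:
        raise ValueError("need at least 2 embeddings to cluster")
    dims = {len(e.vector) for e in embs}
    if len(dims) != 1:
        raise ValueError(f"embedding dimensionality mismatch: {sorted(dims)}")
    if len(embs) < min_cluster_size:
        # not enough points to form any cluster: everything is noise
        return [ClusterAssignment(e.pathway_id, -1, 0.0) for e in embs]
    X = np.stack([np.asarray(e.vector, dtype=float) for e in embs])
    clusterer = HDBSCAN(min_cluster_size=min_cluster_size, metric=metric, copy=True)
    labels = clusterer.fit_predict(X)
    probs = getattr(clusterer, "probabilities_", np.ones(len(embs)))
    return [
        ClusterAssignment(e.pathway_id, int(l), float(p))
        for e, l, p in zip(embs, labels, probs)
    ]


def cluster_report(
    assignments: Sequence[ClusterAssignment],
    pathways: Sequence[Pathway],
) -> pd.DataFrame:
    """Per-cluster summary: size, members, shared intermediate compounds.

    Shared compounds are the intersection of member compound sets — the
    common intermediates that define the cluster's strategy.  The
    representative pathway is the member with the lowest pathway_id.
    """
    by_id = {p.pathway_id: p for p in pathways}
    missing = [a.pathway_id for a in assignments if a.pathway_id not in by_id]
    if missing:
        raise ValueError(f"assignments without pathways: {missing[:3]}")
    rows = []
    clusters: dict[int, list[ClusterAssignment]] = {}
    for a in assignments:
        clusters.setdefault(a.cluster_id, []).append(a)
    for cid in sorted(clusters):
        members = sorted(a.pathway_id for a in clusters[cid])
        shared = set.intersection(*(by_id[m].compounds() for m in members))
        rows.append(
            {
                "cluster_id": cid,
                "size": len(members),
                "members": ";".join(members),
                "shared_compounds": ";".join(sorted(shared)),
                "representative": members[0],
            }
        )
    return pd.DataFrame(rows)


def project_2d(vectors: Sequence[np.ndarray], seed: int = 0) -> np.ndarray:
    """2-D t-SNE projection for plotting (diagnostics only).

    Stochastic-neighbor layouts are seed-dependent and not metric
    faithful; nothing downstream should consume the coordinates.
    """
    X = np.stack([np.asarray(v, dtype=float) for v in vectors])
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 vectors for a 2-D projection")
    perplexity = max(2.0, min(30.0, (n - 1) / 3.0))
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    )
    return tsne.fit_transform(X)
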