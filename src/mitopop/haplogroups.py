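"""Delimiting the divergent "cryptic" maternal lineage.

Work flow: embed the pairwise sequence distances with Kruskal non-metric
MDS, cut the samples into clusters by agglomerative clustering, label the
cluster with maximal mean divergence from the rest as *cryptic* (singleton
clusters become *outlier*), and tabulate per-population lineage
frequencies.  A neighbor-joining tree is provided for visual comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import AgglomerativeClustering
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .structure import SequenceDistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame  # one row per sample, columns axis1..axisk
    stress: float              # Kruskal stress-1 of the returned configuration
    restarts: int
    seed: int | None


def kruskal_stress(d: np.ndarray, coords: np.ndarray) -> float:
    """Stress-1 of a configuration: sqrt(sum (dist - disparity)^2 / sum dist^2)
    with disparities from isotonic regression of embedded distances on the
    input dissimilarities."""
    triu = np.triu_indices(d.shape[0], k=1)
    diss = d[triu]
    edist = pdist(coords)
    disp = IsotonicRegression().fit_transform(diss, edist)
    denom = float((edist**2).sum())
    if denom == 0:
        return 0.0
    return math.sqrt(float(((edist - disp) ** 2).sum()) / denom)


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(lam)


def nmds_embed(
    dm: SequenceDistanceMatrix,
    k: int = 2,
    restarts: int = 4,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
) -> EmbeddingResult:
    """Kruskal non-metric MDS of a sequence distance matrix.

    Runs ``restarts`` random initialisations plus one classical-scaling
    initialisation and returns the configuration with the lowest stress-1.
    """
    n = len(dm.sample_ids)
    if n < k + 1:
        raise ValueError("need at least k+1 samples")
    d = np.nan_to_num(dm.d, nan=float(np.nanmax(dm.d)) if np.isnan(dm.d).any() else 0.0)
    best: np.ndarray | None = None
    best_stress = math.inf
    mds_kwargs = dict(
        n_components=k, metric_mds=False, metric="precomputed", init="random",
        max_iter=max_iter, eps=tol, normalized_stress=True,
    )
    if d.max() > 0:
        mds = MDS(n_init=max(restarts, 1), random_state=seed, **mds_kwargs)
        emb = mds.fit_transform(d)
        s = kruskal_stress(d, emb)
        best, best_stress = emb, s
        # one run seeded from the classical (metric) solution
        init = _classical_scaling(d, k)
        mds1 = MDS(n_init=1, random_state=seed, **mds_kwargs)
        emb1 = mds1.fit_transform(d, init=init)
        s1 = kruskal_stress(d, emb1)
        if s1 < best_stress:
            best, best_stress = emb1, s1
    else:  # all distances zero: any coincident configuration is exact
        best, best_stress = np.zeros((n, k)), 0.0
    coords = pd.DataFrame(
        best, index=dm.sample_ids, columns=[f"axis{i+1}" for i in range(k)]
    )
    return EmbeddingResult(coords, float(best_stress), restarts, seed)


def cluster_lineages(
    dm: SequenceDistanceMatrix,
    embedding: EmbeddingResult | None = None,
    n_clusters: int = 2,
    linkage: str = "ward",
) -> pd.DataFrame:
    """Agglomerative clustering of samples and cryptic-lineage labelling.

    Ward linkage operates on the nMDS coordinates (computed here if not
    supplied); "average" linkage operates on the raw distances.  The
    non-singleton cluster with maximal mean distance to all other samples
    is labelled ``cryptic``, singleton clusters ``outlier``, the rest
    ``common``.  Returns a frame with sample_id, cluster, lineage.
    """
    n = len(dm.sample_ids)
    if n_clusters > n:
        raise ValueError("n_clusters exceeds sample count")
    if float(np.nanmax(dm.d)) == 0.0:
        logger.warning("all sequences identical; returning a single cluster")
        labels = np.zeros(n, dtype=int)
    elif linkage == "ward":
        if embedding is None:
            embedding = nmds_embed(dm, k=2, seed=0)
        model = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward")
        labels = model.fit_predict(embedding.coordinates.to_numpy())
    elif linkage == "average":
        model = AgglomerativeClustering(
            n_clusters=n_clusters, linkage="average", metric="precomputed"
        )
        labels = model.fit_predict(dm.d)
    else:
        raise ValueError(f"unsupported linkage {linkage!r}")

    lineage = np.full(n, "common", dtype=object)
    sizes = np.bincount(labels)
    multi = [c for c in range(len(sizes)) if sizes[c] > 1]
    for c in range(len(sizes)):
        if sizes[c] == 1:
            lineage[labels == c] = "outlier"
    if len(multi) > 1:
        # maximal mean divergence from the rest; with two clusters that
        # quantity is symmetric, so break ties towards the smaller cluster
        # (the divergent lineage is the minority) and then towards the
        # tighter one
        key = {}
        for c in multi:
            inside = labels == c
            mean_out = float(dm.d[np.ix_(inside, ~inside)].mean())
            within = (
                float(dm.d[np.ix_(inside, inside)].mean()) if sizes[c] > 1 else 0.0
            )
            key[c] = (round(mean_out, 12), -int(sizes[c]), -within)
        cryptic = max(key, key=key.get)
        lineage[labels == cryptic] = "cryptic"
    return pd.DataFrame(
        {"sample_id": dm.sample_ids, "cluster": labels, "lineage": lineage}
    )


def lineage_frequencies(
    assignments: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-population cryptic-lineage counts and percentages, ordered west
    to east by mean longitude, with a totals row."""
    merged = assignments.merge(metadata, on="sample_id", how="left")
    missing = merged["population"].isna()
    if missing.any():
        logger.warning("%d assigned samples lack metadata; excluded", int(missing.sum()))
        merged = merged[~missing]
    rows = []
    for pop, sub in merged.groupby("population"):
        rows.append(
            {
                "population": pop,
                "n": len(sub),
                "n_cryptic": int((sub["lineage"] == "cryptic").sum()),
                "mean_longitude": float(sub["longitude"].mean()),
            }
        )
    out = pd.DataFrame(rows).sort_values("mean_longitude").reset_index(drop=True)
    out["pct_cryptic"] = 100.0 * out["n_cryptic"] / out["n"]
    total = {
        "population": "ALL",
        "n": int(out["n"].sum()),
        "n_cryptic": int(out["n_cryptic"].sum()),
        "mean_longitude": math.nan,
        "pct_cryptic": 100.0 * out["n_cryptic"].sum() / out["n"].sum(),
    }
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: SequenceDistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns a newick string.

    Negative branch lengths arising from non-additive distances are clamped
    to zero with the difference moved to the sister branch, preserving the
    path length through the joined pair.
    """
    if not np.isfinite(dm.d).all():
        raise ValueError("non-finite distances")
    n = len(dm.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = dm.d.astype(float).copy()
    nodes = [f"{sid}" for sid in dm.sample_ids]  # newick fragments

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        dk = (d[i] + d[j] - d[i, j]) / 2.0
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dk[keep][None, :]])
        d = np.hstack([d, np.append(dk[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]
    # final three-node star via the three-point formulas
    (a, b, c) = range(3)
    la = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},{nodes[c]}:{lc:.10g});"
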