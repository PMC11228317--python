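"""Self-organizing DEG cluster analysis.

All pairwise Spearman correlations of DEG expression across patients,
agglomerative clustering on distance 1 - rho (sign matters: positively and
negatively correlated transcripts must not merge), cluster annotation by
the dominant atlas cell type, and inter-cluster net correlation — the
analysis that surfaces, e.g., a MAIT-cell cluster anticorrelated with a
neutrophil cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_core import ReferenceAtlas, logger


@dataclass
class CorrelationMatrix:
    gene_ids: list[str]
    rho: np.ndarray  # symmetric, unit diagonal, in [-1, 1]

    def __post_init__(self) -> None:
        r = np.asarray(self.rho, dtype=float)
        if r.shape != (len(self.gene_ids),) * 2:
            raise ValueError("correlation matrix shape mismatch")
        if np.abs(r - r.T).max() > 1e-12:
            raise ValueError("correlation matrix must be symmetric")
        if np.abs(np.diag(r) - 1.0).max() > 1e-12:
            raise ValueError("correlation matrix must have unit diagonal")
        if (np.abs(r) > 1 + 1e-12).any():
            raise ValueError("correlations must lie in [-1, 1]")
        self.rho = np.clip(r, -1.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.gene_ids, columns=self.gene_ids)


def spearman_matrix(expr) -> CorrelationMatrix:
    """Spearman rho between all gene pairs across samples (average ranks
    for ties).  A constant gene is assigned rho 0 against everything (and 1
    with itself), logged as uninformative.
    """
    if isinstance(expr, pd.DataFrame):
        gene_ids, mat = list(expr.index), expr.to_numpy(dtype=float)
    else:
        mat = np.asarray(expr, dtype=float)
        gene_ids = [f"g{i}" for i in range(mat.shape[0])]
    n_genes, n_samples = mat.shape
    if n_samples < 3:
        raise ValueError("Spearman matrix needs at least 3 samples")
    if n_genes < 2:
        raise ValueError("Spearman matrix needs at least 2 genes")
    ranks = np.apply_along_axis(stats.rankdata, 1, mat)
    constant = ranks.std(axis=1) == 0
    if constant.any():
        logger.info(
            "spearman_matrix: %d constant gene(s) set to rho 0: %s",
            constant.sum(), [g for g, c in zip(gene_ids, constant) if c][:5],
        )
    rho = np.corrcoef(ranks)
    rho = np.where(np.isfinite(rho), rho, 0.0)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(gene_ids, rho)


@dataclass
class ClusterModel:
    """Dendrogram plus flat cluster assignment (and optional annotation)."""

    gene_ids: list[str]
    linkage_matrix: np.ndarray
    labels: np.ndarray  # 1..K, parallel to gene_ids
    linkage_method: str
    cut: dict
    cluster_annotation: dict[int, tuple[str, float]] = field(default_factory=dict)
    gene_primary_type: dict[str, str] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels))

    def members(self, cluster: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == cluster]

    def assignment_table(self) -> pd.DataFrame:
        rows = []
        for g, l in zip(self.gene_ids, self.labels):
            label, frac = self.cluster_annotation.get(int(l), ("", np.nan))
            rows.append(
                {"gene": g, "cluster": int(l), "cluster_label": label,
                 "label_fraction": frac, "primary_type": self.gene_primary_type.get(g, "")}
            )
        return pd.DataFrame(rows)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node) -> str:
            if node.is_leaf():
                return self.gene_ids[node.id]
            left, right = rec(node.left), rec(node.right)
            dl = max(node.dist - node.left.dist, 0.0)
            dr = max(node.dist - node.right.dist, 0.0)
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return rec(tree) + ";"


def hierarchical_cluster(
    corr: CorrelationMatrix,
    linkage: str = "average",
    k: int | None = None,
    height: float | None = None,
) -> ClusterModel:
    """Agglomerative clustering on distance 1 - rho, cut either into ``k``
    flat clusters or at a dendrogram ``height``.  Cluster ids are renumbered
    in order of first appearance along the gene list, so the partition is
    stable under gene permutation (up to relabeling).
    """
    n = len(corr.gene_ids)
    if k is not None and k > n:
        raise ValueError(f"cannot cut {n} genes into {k} clusters")
    if (k is None) == (height is None):
        raise ValueError("specify exactly one of k or height")
    dist = 1.0 - corr.rho
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    if k is not None:
        raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    else:
        raw = hierarchy.fcluster(Z, t=height, criterion="distance")
    # renumber in order of first appearance for determinism
    mapping: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        labels[i] = mapping[r]
    cut = {"k": k} if k is not None else {"height": height}
    return ClusterModel(list(corr.gene_ids), Z, labels, linkage, cut)


def annotate_clusters(model: ClusterModel, atlas: ReferenceAtlas) -> ClusterModel:
    """Label each cluster with the modal primary cell type of its genes.

    A gene's primary type is the specific cell type with maximal atlas
    expression; genes not in the atlas are ignored for labeling.  The modal
    type wins only with a strict majority (> 0.5), otherwise the cluster is
    "mixed"; clusters with no mappable genes are "unmapped".
    """
    frame = atlas.to_frame().loc[atlas.specific_types]
    primary: dict[str, str] = {}
    for g in model.gene_ids:
        if g in frame.columns:
            primary[g] = str(frame[g].idxmax())
    annotation: dict[int, tuple[str, float]] = {}
    for cl in sorted(set(model.labels)):
        types = [primary[g] for g in model.members(int(cl)) if g in primary]
        if not types:
            annotation[int(cl)] = ("unmapped", np.nan)
            continue
        counts = pd.Series(types).value_counts()
        frac = counts.iloc[0] / len(types)
        label = str(counts.index[0]) if frac > 0.5 else "mixed"
        annotation[int(cl)] = (label, float(frac))
    model.cluster_annotation = annotation
    model.gene_primary_type = primary
    return model


def intercluster_correlation(model: ClusterModel, corr: CorrelationMatrix) -> pd.DataFrame:
    """Mean Spearman rho for every cluster pair (within-cluster pairs use
    the off-diagonal entries), plus the extreme gene pair driving each."""
    if model.n_clusters < 1:
        raise ValueError("no clusters to compare")
    idx = {g: i for i, g in enumerate(corr.gene_ids)}
    clusters = sorted(set(int(l) for l in model.labels))
    rows = []
    for ia, ca in enumerate(clusters):
        ga = [idx[g] for g in model.members(ca) if g in idx]
        for cb in clusters[ia:]:
            gb = [idx[g] for g in model.members(cb) if g in idx]
            block = corr.rho[np.ix_(ga, gb)]
            if ca == cb:
                if len(ga) < 2:
                    continue
                mask = ~np.eye(len(ga), dtype=bool)
                vals = block[mask]
                pos = np.argwhere(mask)
            else:
                vals = block.ravel()
                pos = np.argwhere(np.ones_like(block, dtype=bool))
            if vals.size == 0:
                continue
            ext = int(np.argmax(np.abs(vals)))
            i, j = pos[ext]
            rows.append(
                {
                    "cluster_a": ca,
                    "cluster_b": cb,
                    "within": ca == cb,
                    "mean_rho": float(vals.mean()),
                    "extreme_gene_a": corr.gene_ids[ga[i]],
                    "extreme_gene_b": corr.gene_ids[gb[j]],
                    "extreme_rho": float(vals[ext]),
                    "n_pairs": int(vals.size if ca != cb else vals.size // 2),
                }
            )
    return pd.DataFrame(rows)
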