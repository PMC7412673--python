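"""Iterative zero-inflation-guided hierarchical clustering.

One round = (1) test every candidate gene for zero inflation within the
cluster chosen for splitting, (2) keep genes whose statistic exceeds the
threshold, (3) log-transform and standardize the selected features,
(4) split the cluster's cells in two with PCA + K-means, (5) score every
cluster's intra-cluster variation (sum of sample variances of the leading
uncentered, unscaled PCA embeddings) and queue the most variable cluster
for the next round.  Iteration stops when K clusters exist or when fewer
than G*o candidate genes are zero-inflated (G = total genes in the input,
o = outlier gene proportion): the residual inflation is then attributed to
granular heterogeneity that further splitting cannot resolve.

The variation score deliberately skips centering and scaling so that small
clusters are not inflated relative to large ones.  An alternative score --
the mean Euclidean distance of cells from their K-means center -- is
available via ``split_criterion="kmeans_distance"``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .counts import CellLabels, CountMatrix
from .zero_model import gene_zero_stats, select_features

__all__ = [
    "HippoConfig",
    "HippoRound",
    "HippoResult",
    "DegenerateSplitError",
    "log_transform_and_standardize",
    "pca_kmeans_split",
    "intra_cluster_variation",
    "outlier_gene_allowance",
    "hippo",
]


class DegenerateSplitError(RuntimeError):
    """All cells are identical on the selected features; no split is possible."""


@dataclass
class HippoConfig:
    """Tuning knobs for the iterative clustering.

    K is the maximum number of clusters; z_threshold the feature-selection
    cutoff on the zero-inflation z (or deviance_threshold for the deviance
    method); outlier_proportion o sets the stopping bound G*o on the number
    of zero-inflated genes tolerated without further splitting.
    """

    K: int = 2
    z_threshold: float = 2.0
    outlier_proportion: float = 0.01
    n_pc_cluster: int = 10
    n_pc_variation: int = 10
    km_restarts: int = 10
    seed: int = 0
    feature_method: Literal["zero_inflation", "deviance"] = "zero_inflation"
    deviance_threshold: float = 50.0
    split_criterion: Literal["pca_variance", "kmeans_distance"] = "pca_variance"
    inherit_features: bool = True

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0 <= self.outlier_proportion < 1):
            raise ValueError("outlier_proportion must be in [0, 1)")
        if self.n_pc_cluster < 1 or self.n_pc_variation < 1:
            raise ValueError("n_pc_* must be >= 1")
        if self.km_restarts < 1:
            raise ValueError("km_restarts must be >= 1")
        if not np.isfinite(self.z_threshold) or not np.isfinite(self.deviance_threshold):
            raise ValueError("thresholds must be finite")


@dataclass
class HippoRound:
    """Audit record of one completed split."""

    round_index: int                 # 1-based
    parent_cluster: int
    selected_features: np.ndarray    # global gene indices, descending statistic
    n_inflated: int
    child_labels: np.ndarray         # 0/1 over the parent's cells
    intra_variation: dict[int, float]
    labels_after: np.ndarray         # full C-length labels, round_index+1 clusters


@dataclass
class HippoResult:
    config: HippoConfig
    rounds: list[HippoRound]
    final_labels: CellLabels
    stop_reason: Literal["reached_K", "too_few_inflated_genes"]

    @property
    def n_clusters(self) -> int:
        return len(self.rounds) + 1


def outlier_gene_allowance(n_genes: int, outlier_proportion: float) -> float:
    """Number of zero-inflated genes tolerated before splitting stops: G*o."""
    return n_genes * outlier_proportion


def log_transform_and_standardize(sub: CountMatrix) -> np.ndarray:
    """Cells x features matrix: log(1+X), then per-feature center and unit-scale.

    Scaling uses the sample standard deviation (ddof=1); constant features
    are centered but left unscaled (all-zero columns).
    """
    if sub.n_cells < 2 or sub.n_genes < 1:
        raise ValueError("need >= 2 cells and >= 1 feature")
    y = np.log1p(sub.dense().T.astype(float))  # cells x features
    y -= y.mean(axis=0)
    sd = y.std(axis=0, ddof=1)
    nz = sd > 0
    y[:, nz] /= sd[nz]
    return y


def _pca_scores(z_matrix: np.ndarray, n_pc: int, seed: int) -> np.ndarray:
    n_comp = min(n_pc, z_matrix.shape[0] - 1, z_matrix.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed)
    return pca.fit_transform(z_matrix)


def _pca_kmeans(
    z_matrix: np.ndarray, n_pc: int, restarts: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if z_matrix.shape[0] < 2 or np.allclose(z_matrix, z_matrix[0]):
        raise DegenerateSplitError("all cells identical on selected features")
    scores = _pca_scores(z_matrix, n_pc, seed)
    km = KMeans(n_clusters=2, n_init=restarts, random_state=seed)
    labels = km.fit_predict(scores)
    if len(np.unique(labels)) < 2:
        raise DegenerateSplitError("K-means produced an empty cluster")
    return labels, scores, km.cluster_centers_


def pca_kmeans_split(z_matrix: np.ndarray, n_pc: int, restarts: int, seed: int) -> np.ndarray:
    """Binary split of cells from the top-n_pc PCA scores via 2-means.

    Deterministic for a fixed seed; the best of ``restarts`` K-means
    initializations (lowest within-cluster sum of squares) is kept.
    """
    labels, _, _ = _pca_kmeans(np.asarray(z_matrix, dtype=float), n_pc, restarts, seed)
    return labels


def intra_cluster_variation(sub: CountMatrix, n_pc: int = 10) -> float:
    """Sum of sample variances of the first n_pc uncentered-PCA embeddings.

    The log(1+X) matrix (cells x features) is decomposed by plain SVD with
    no centering or scaling; embeddings are U*S.  Single-cell or
    constant-cell clusters return 0.
    """
    if sub.n_cells < 2:
        return 0.0
    y = np.log1p(sub.dense().T.astype(float))
    u, s, _ = np.linalg.svd(y, full_matrices=False)
    emb = u * s
    k = min(n_pc, emb.shape[1])
    return float(emb[:, :k].var(axis=0, ddof=1).sum())


def _round_seed(master: int, round_index: int) -> int:
    """Per-round child seed; inserting a round never reshuffles later rounds."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(round_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def _kmeans_distance_score(scores: np.ndarray, labels: np.ndarray, centers: np.ndarray, child: int) -> float:
    pts = scores[labels == child]
    if pts.shape[0] < 2:
        return 0.0
    return float(np.linalg.norm(pts - centers[child], axis=1).mean())


def hippo(m: CountMatrix, config: HippoConfig | None = None) -> HippoResult:
    """Run the full iterative feature-selection + clustering procedure.

    Returns the per-round audit trail, final labels and the stop reason.
    Candidate features for a child cluster default to the features selected
    in the round that created it (``inherit_features=True``), re-tested
    within the child's cells, so candidate sets shrink along each lineage.
    """
    cfg = config or HippoConfig()
    if m.n_cells < 4 and cfg.K > 1:
        raise ValueError("need at least 4 cells to cluster")
    G = m.n_genes
    allowance = outlier_gene_allowance(G, cfg.outlier_proportion)
    labels = np.zeros(m.n_cells, dtype=np.int64)
    candidate: dict[int, np.ndarray] = {0: np.arange(G)}
    variation: dict[int, float] = {0: 0.0}
    unsplittable: set[int] = set()
    rounds: list[HippoRound] = []
    stop_reason = "reached_K"
    t = 0
    while len(rounds) + 1 < cfg.K:
        splittable = [c for c in sorted(variation) if c not in unsplittable]
        if not splittable:
            stop_reason = "too_few_inflated_genes"
            break
        # highest intra-cluster variation first; ties -> lower cluster id
        parent = max(splittable, key=lambda c: (variation[c], -c))
        cells_p = np.flatnonzero(labels == parent)
        if cells_p.size < 4:
            unsplittable.add(parent)
            continue
        cand = candidate[parent]
        sub_all = m.subset(genes=cand, cells=cells_p)
        stats = gene_zero_stats(sub_all)
        sel_local = select_features(
            stats, cfg.feature_method, cfg.z_threshold, cfg.deviance_threshold
        )
        n_inflated = int(sel_local.size)
        if n_inflated < allowance:
            stop_reason = "too_few_inflated_genes"
            break
        if n_inflated == 0:
            unsplittable.add(parent)
            continue
        selected = cand[sel_local]
        t += 1
        seed_t = _round_seed(cfg.seed, t)
        zmat = log_transform_and_standardize(m.subset(genes=selected, cells=cells_p))
        try:
            bin_labels, scores, centers = _pca_kmeans(
                zmat, cfg.n_pc_cluster, cfg.km_restarts, seed_t
            )
        except DegenerateSplitError:
            t -= 1
            unsplittable.add(parent)
            continue
        # larger child keeps the parent id; ties -> the child holding the
        # first (lowest-index) parent cell keeps it
        n0, n1 = int(np.sum(bin_labels == 0)), int(np.sum(bin_labels == 1))
        if n0 > n1 or (n0 == n1 and bin_labels[0] == 0):
            keep, new = 0, 1
        else:
            keep, new = 1, 0
        new_id = int(labels.max()) + 1
        labels = labels.copy()
        labels[cells_p[bin_labels == new]] = new_id
        for child_id, child_bin in ((parent, keep), (new_id, new)):
            child_cells = cells_p[bin_labels == child_bin]
            if cfg.split_criterion == "kmeans_distance":
                variation[child_id] = _kmeans_distance_score(scores, bin_labels, centers, child_bin)
            else:
                variation[child_id] = intra_cluster_variation(
                    m.subset(genes=selected, cells=child_cells), cfg.n_pc_variation
                )
            candidate[child_id] = selected if cfg.inherit_features else np.arange(G)
        rounds.append(
            HippoRound(
                round_index=t,
                parent_cluster=parent,
                selected_features=selected,
                n_inflated=n_inflated,
                child_labels=bin_labels.copy(),
                intra_variation=dict(variation),
                labels_after=labels.copy(),
            )
        )
    return HippoResult(cfg, rounds, CellLabels(m.cell_ids, labels), stop_reason)


# ---------------------------------------------------------------------------
# result export


def write_result(result: HippoResult, out_dir: str | Path, gene_ids: list[str] | None = None) -> None:
    """Write labels-per-round TSV, per-round feature TSV and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells = result.final_labels.cell_ids
    with open(out / "labels.tsv", "w") as fh:
        header = ["cell_id"] + [f"round_{r.round_index}" for r in result.rounds] + ["final"]
        fh.write("\t".join(header) + "\n")
        for i, cid in enumerate(cells):
            row = [cid] + [str(int(r.labels_after[i])) for r in result.rounds]
            row.append(str(int(result.final_labels.labels[i])))
            fh.write("\t".join(row) + "\n")
    with open(out / "features.tsv", "w") as fh:
        fh.write("round\tparent_cluster\trank\tgene_index\tgene_id\n")
        for r in result.rounds:
            for rank, g in enumerate(r.selected_features):
                gid = gene_ids[g] if gene_ids else str(g)
                fh.write(f"{r.round_index}\t{r.parent_cluster}\t{rank}\t{g}\t{gid}\n")
    manifest = {
        "config": asdict(result.config),
        "stop_reason": result.stop_reason,
        "n_clusters": result.n_clusters,
        "rounds": [
            {
                "round": r.round_index,
                "parent": r.parent_cluster,
                "n_inflated": r.n_inflated,
                "cluster_sizes": {
                    str(k): int(v)
                    for k, v in zip(*np.unique(r.labels_after, return_counts=True))
                },
                "intra_variation": {str(k): v for k, v in r.intra_variation.items()},
            }
            for r in result.rounds
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


# exported for the CLI
__all__.append("write_result")
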