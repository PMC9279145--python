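"""Sequence-class vocabulary: reduction, clustering, selection, annotation.

The pipeline reduces a windows x profiles prediction matrix with a single
pass of incremental PCA over randomly permuted batches, scales the top
components to unit variance, builds an (undirected, unweighted) k-nearest-
neighbour graph, partitions it with Louvain modularity maximization, keeps
the largest clusters as the class vocabulary and annotates the genome at
the tiling resolution.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np
from sklearn.decomposition import IncrementalPCA
from sklearn.neighbors import NearestNeighbors

from .formats import Window

__all__ = [
    "ReductionModel",
    "SequenceClassModel",
    "GenomeAnnotation",
    "fit_reduction",
    "knn_graph",
    "louvain_cluster",
    "select_classes",
    "class_vectors",
    "fit_sequence_classes",
    "annotate_genome",
    "UNASSIGNED",
]

UNASSIGNED = -1


@dataclass
class ReductionModel:
    """PCA projection with per-component unit-variance scaling."""

    components: np.ndarray  # (n_components, T), orthonormal rows
    mean: np.ndarray  # (T,)
    scales: np.ndarray  # (n_components,) standard deviations, > 0

    def __post_init__(self) -> None:
        if np.any(self.scales <= 0):
            raise ValueError("component scales must be strictly positive")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x) - self.mean) @ self.components.T / self.scales


def fit_reduction(
    pred_matrix: np.ndarray,
    n_components: int = 180,
    batch_size: int = 1_000_000,
    seed: int = 0,
) -> ReductionModel:
    """Single-pass incremental PCA over randomly permuted batches.

    Rows are shuffled before batching so each partial fit sees an unbiased
    sample. The transform projects onto the top components and divides by
    each component's standard deviation.
    """
    x = np.asarray(pred_matrix)
    n, t = x.shape
    if n_components > min(n, t):
        raise ValueError(
            f"n_components={n_components} exceeds feasible rank min({n}, {t})"
        )
    batch_size = max(batch_size, n_components)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    ipca = IncrementalPCA(n_components=n_components)
    for lo in range(0, n, batch_size):
        batch = x[order[lo : lo + batch_size]]
        if batch.shape[0] < n_components:  # fold tiny tail into nothing new
            if lo == 0:
                raise ValueError("batch_size smaller than n_components")
            break
        ipca.partial_fit(batch)
    scales = np.sqrt(ipca.explained_variance_)
    if np.any(scales <= 0):
        raise ValueError("zero-variance component: reduce n_components")
    return ReductionModel(
        components=ipca.components_.copy(), mean=ipca.mean_.copy(), scales=scales
    )


def knn_graph(points: np.ndarray, k: int = 14) -> nx.Graph:
    """Undirected, unweighted union of directed k-nearest-neighbour
    relations under Euclidean distance; no self-loops."""
    x = np.asarray(points)
    n = x.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, indices = nn.kneighbors(x)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        for j in indices[i]:
            if j != i:
                graph.add_edge(i, int(j))
    # the query returns k+1 neighbours including self; for duplicate points
    # self may be absent, leaving k+1 true neighbours, which is fine for a
    # union graph
    return graph


def louvain_cluster(graph: nx.Graph, seed: int = 0) -> np.ndarray:
    """Louvain modularity clustering (resolution 1.0), deterministic under
    the seed. Returns integer labels aligned with node ids 0..n-1."""
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    communities = nx.community.louvain_communities(graph, seed=seed)
    labels = np.empty(graph.number_of_nodes(), dtype=np.int64)
    for cid, members in enumerate(communities):
        for node in members:
            labels[node] = cid
    return labels


@dataclass
class ClassSelection:
    """Ranked subset of clusters kept as the class vocabulary."""

    kept_cluster_ids: list[int]  # original cluster ids, rank order (largest first)
    sizes: list[int]  # member counts, aligned with kept_cluster_ids
    rank_of_cluster: dict[int, int]  # original id -> rank (0-based)

    @property
    def n_classes(self) -> int:
        return len(self.kept_cluster_ids)

    def rank_labels(self, labels: np.ndarray) -> np.ndarray:
        """Map original cluster labels to rank ids; dropped clusters map to
        :data:`UNASSIGNED`."""
        out = np.full(len(labels), UNASSIGNED, dtype=np.int64)
        for cid, rank in self.rank_of_cluster.items():
            out[labels == cid] = rank
        return out


def select_classes(
    labels: np.ndarray, keep: Union[int, float]
) -> ClassSelection:
    """Rank clusters by size (descending; ties broken by smaller original
    cluster id) and keep the largest.

    ``keep`` may be an integer count, or a fraction f in (0, 1): then the
    smallest clusters whose combined share of points stays below f are
    dropped and everything else kept.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels are empty")
    ids, counts = np.unique(labels, return_counts=True)
    order = np.lexsort((ids, -counts))  # size desc, id asc on ties
    ids, counts = ids[order], counts[order]
    if isinstance(keep, float):
        if not 0.0 < keep < 1.0:
            raise ValueError("fractional keep must be in (0, 1)")
        total = counts.sum()
        tail = np.cumsum(counts[::-1]) / total  # cumulative share from smallest
        n_drop = int(np.searchsorted(tail, keep, side="left"))
        n_keep = len(ids) - n_drop
    else:
        n_keep = int(keep)
        if n_keep > len(ids):
            import warnings

            warnings.warn(
                f"requested {n_keep} classes but only {len(ids)} clusters exist; "
                "keeping all"
            )
            n_keep = len(ids)
        if n_keep < 1:
            raise ValueError("must keep at least one class")
    kept = ids[:n_keep]
    sizes = counts[:n_keep]
    return ClassSelection(
        kept_cluster_ids=[int(i) for i in kept],
        sizes=[int(s) for s in sizes],
        rank_of_cluster={int(cid): rank for rank, cid in enumerate(kept)},
    )


def class_vectors(
    pred_matrix: np.ndarray, labels: np.ndarray, selection: ClassSelection
) -> np.ndarray:
    """Per-class unit vectors: the mean member prediction normalized to
    unit Euclidean norm. Shape ``(n_classes, T)``, rank order."""
    x = np.asarray(pred_matrix)
    vectors = np.zeros((selection.n_classes, x.shape[1]))
    for cid, rank in selection.rank_of_cluster.items():
        members = x[labels == cid]
        if members.shape[0] == 0:
            raise ValueError(f"kept class rank {rank} has no members")
        mean = members.mean(axis=0)
        norm = float(np.linalg.norm(mean))
        if norm == 0.0:
            raise ValueError(
                f"class rank {rank} has an all-zero mean prediction; "
                "cannot form a unit vector"
            )
        vectors[rank] = mean / norm
    return vectors


@dataclass
class SequenceClassModel:
    """Fitted vocabulary: reduction, cluster labels, ranked classes and
    their unit direction vectors."""

    reduction: ReductionModel
    labels: np.ndarray  # original cluster label per fitted point
    selection: ClassSelection
    vectors: np.ndarray  # (n_classes, T) unit vectors in rank order
    histone_mask: Optional[np.ndarray] = None  # (T,) bool
    label_map: dict[int, str] = field(default_factory=dict)  # rank -> user label

    @property
    def n_classes(self) -> int:
        return self.selection.n_classes

    @property
    def class_sizes(self) -> list[int]:
        return self.selection.sizes

    def class_name(self, rank: int) -> str:
        if rank == UNASSIGNED:
            return "unassigned"
        return self.label_map.get(rank, f"C{rank + 1}")

    def rank_labels(self) -> np.ndarray:
        return self.selection.rank_labels(self.labels)

    # -- persistence (plain-text archive directory) --------------------

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        np.savetxt(os.path.join(directory, "components.tsv"), self.reduction.components, delimiter="\t")
        np.savetxt(os.path.join(directory, "mean.tsv"), self.reduction.mean, delimiter="\t")
        np.savetxt(os.path.join(directory, "scales.tsv"), self.reduction.scales, delimiter="\t")
        np.savetxt(os.path.join(directory, "vectors.tsv"), self.vectors, delimiter="\t")
        np.savetxt(
            os.path.join(directory, "labels.tsv"), self.labels, fmt="%d", delimiter="\t"
        )
        meta = {
            "kept_cluster_ids": self.selection.kept_cluster_ids,
            "sizes": self.selection.sizes,
            "label_map": {str(k): v for k, v in self.label_map.items()},
            "histone_mask": (
                self.histone_mask.astype(int).tolist()
                if self.histone_mask is not None
                else None
            ),
        }
        with open(os.path.join(directory, "meta.json"), "w") as handle:
            json.dump(meta, handle, indent=2)

    @classmethod
    def load(cls, directory: str) -> "SequenceClassModel":
        components = np.loadtxt(os.path.join(directory, "components.tsv"), delimiter="\t", ndmin=2)
        mean = np.loadtxt(os.path.join(directory, "mean.tsv"), delimiter="\t")
        scales = np.atleast_1d(np.loadtxt(os.path.join(directory, "scales.tsv"), delimiter="\t"))
        vectors = np.loadtxt(os.path.join(directory, "vectors.tsv"), delimiter="\t", ndmin=2)
        labels = np.loadtxt(
            os.path.join(directory, "labels.tsv"), dtype=np.int64, delimiter="\t"
        )
        with open(os.path.join(directory, "meta.json")) as handle:
            meta = json.load(handle)
        selection = ClassSelection(
            kept_cluster_ids=list(meta["kept_cluster_ids"]),
            sizes=list(meta["sizes"]),
            rank_of_cluster={
                int(cid): rank for rank, cid in enumerate(meta["kept_cluster_ids"])
            },
        )
        histone_mask = (
            np.array(meta["histone_mask"], dtype=bool)
            if meta.get("histone_mask") is not None
            else None
        )
        return cls(
            reduction=ReductionModel(components, mean, scales),
            labels=labels,
            selection=selection,
            vectors=vectors,
            histone_mask=histone_mask,
            label_map={int(k): v for k, v in meta.get("label_map", {}).items()},
        )


def fit_sequence_classes(
    pred_matrix: np.ndarray,
    n_components: int = 180,
    k: int = 14,
    keep: Union[int, float] = 40,
    batch_size: int = 1_000_000,
    seed: int = 0,
    histone_mask: Optional[np.ndarray] = None,
) -> SequenceClassModel:
    """End-to-end vocabulary fit: reduce, graph, cluster, select, vectors.

    Deterministic under ``seed`` (shared between the batch permutation and
    the Louvain visitation order).
    """
    x = np.asarray(pred_matrix)
    n_components = min(n_components, min(x.shape) - 1)
    reduction = fit_reduction(x, n_components=n_components, batch_size=batch_size, seed=seed)
    reduced = reduction.transform(x)
    graph = knn_graph(reduced, k=k)
    labels = louvain_cluster(graph, seed=seed)
    selection = select_classes(labels, keep)
    vectors = class_vectors(x, labels, selection)
    return SequenceClassModel(
        reduction=reduction,
        labels=labels,
        selection=selection,
        vectors=vectors,
        histone_mask=histone_mask,
    )


@dataclass
class GenomeAnnotation:
    """Nonoverlapping class assignment at fixed bin resolution.

    ``bins`` maps contig -> (bin start array, class rank array); class rank
    :data:`UNASSIGNED` marks bins from dropped clusters.
    """

    bin_size: int
    bins: dict[str, tuple[np.ndarray, np.ndarray]]

    def class_at(self, contig: str, pos: int) -> int:
        if contig not in self.bins:
            return UNASSIGNED
        starts, ranks = self.bins[contig]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= starts[i] + self.bin_size:
            return UNASSIGNED
        return int(ranks[i])

    def n_bins(self) -> int:
        return int(sum(len(starts) for starts, _ in self.bins.values()))

    def assigned_fraction(self) -> float:
        total = self.n_bins()
        if total == 0:
            return np.nan
        assigned = sum(int((r != UNASSIGNED).sum()) for _, r in self.bins.values())
        return assigned / total

    def class_bin_counts(self, n_classes: int) -> np.ndarray:
        counts = np.zeros(n_classes + 1, dtype=np.int64)  # last slot: unassigned
        for _, ranks in self.bins.values():
            for rank in range(n_classes):
                counts[rank] += int((ranks == rank).sum())
            counts[-1] += int((ranks == UNASSIGNED).sum())
        return counts

    def to_bed(self, path: str, name_of: Optional[dict[int, str]] = None) -> None:
        with open(path, "w") as handle:
            for contig, (starts, ranks) in self.bins.items():
                for start, rank in zip(starts, ranks):
                    if name_of is not None:
                        name = name_of.get(int(rank), "unassigned")
                    elif rank == UNASSIGNED:
                        name = "unassigned"
                    else:
                        name = f"C{int(rank) + 1}"
                    handle.write(f"{contig}\t{start}\t{start + self.bin_size}\t{name}\n")


def annotate_genome(
    windows: Sequence[Window],
    rank_labels: np.ndarray,
    bin_size: int = 100,
) -> GenomeAnnotation:
    """Assign each window's centre bin the window's class rank.

    ``windows`` must come from a tiling whose step equals ``bin_size`` so
    bins are nonoverlapping; duplicated bins raise (tiling misuse).
    """
    if len(windows) != len(rank_labels):
        raise ValueError("windows and labels length mismatch")
    per_contig: dict[str, list[tuple[int, int]]] = {}
    for w, rank in zip(windows, rank_labels):
        start = w.center - bin_size // 2
        per_contig.setdefault(w.contig, []).append((start, int(rank)))
    bins: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig, items in per_contig.items():
        items.sort()
        starts = np.array([s for s, _ in items], dtype=np.int64)
        if len(starts) > 1 and np.any(np.diff(starts) < bin_size):
            raise ValueError(
                f"overlapping {bin_size}-bp bins on {contig}: windows must be "
                f"tiled with step == bin size"
            )
        ranks = np.array([r for _, r in items], dtype=np.int64)
        bins[contig] = (starts, ranks)
    return GenomeAnnotation(bin_size=bin_size, bins=bins)
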