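"""Agglomerative UPGMA clustering with Euclidean distances, from scratch.

UPGMA (unweighted pair-group method with arithmetic mean) repeatedly merges
the two closest clusters, where the distance between clusters is the
arithmetic mean of all cross-pair leaf distances.  Merge heights are
therefore non-decreasing and the resulting tree is ultrametric.  The
implementation uses the Lance-Williams update
``d(a+b, c) = (|a| d(a,c) + |b| d(b,c)) / (|a| + |b|)``, which reproduces
the all-pairs average exactly.

Determinism: among pairs tied at the minimal distance, the pair whose
(lexicographically smallest-leaf-label) representatives sort first is
merged.  Leaf seriation places the tighter (lower-height) subtree first at
every internal node, ties broken by representative label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .normalize import CohortMatrix


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite distances")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("nonzero diagonal")
        if (d < 0).any():
            raise ValueError("negative distances")
        self.d = d


def euclidean_distances(
    matrix: CohortMatrix | pd.DataFrame,
    axis: str = "antigens",
    rank_transform: bool = False,
) -> DistanceMatrix:
    """Pairwise Euclidean distances over rows (antigens) or columns (samples).

    Missing values are imputed with the antigen (row) median first.  The
    optional rank transform replaces each sample's values by their ranks
    before computing distances (a rank-based variant of the measure).
    """
    values = matrix.values if isinstance(matrix, CohortMatrix) else matrix
    df = values.copy()
    med = df.median(axis=1)
    df = df.apply(lambda col: col.fillna(med))
    if rank_transform:
        df = df.rank(axis=0)
    if axis == "antigens":
        data, labels = df.to_numpy(), list(df.index)
    elif axis == "samples":
        data, labels = df.to_numpy().T, list(df.columns)
    else:
        raise ValueError("axis must be 'antigens' or 'samples'")
    if len(labels) < 2:
        raise ValueError(f"need at least 2 items along axis {axis!r}")
    d = cdist(data, data, metric="euclidean")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix([str(x) for x in labels], d)


@dataclass
class Merge:
    a: int  # cluster ids; leaves are 0..n-1, internal nodes n, n+1, ...
    b: int
    height: float
    size: int


@dataclass
class Dendrogram:
    labels: list[str]
    merges: list[Merge]
    leaf_order: list[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_linkage(self) -> np.ndarray:
        """Merge list in scipy ``linkage`` matrix layout (for plotting)."""
        return np.array(
            [[m.a, m.b, m.height, m.size] for m in self.merges], dtype=float
        )

    def _children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {n + i: (m.a, m.b) for i, m in enumerate(self.merges)}

    def _heights(self) -> dict[int, float]:
        n = self.n_leaves
        h = {i: 0.0 for i in range(n)}
        for i, m in enumerate(self.merges):
            h[n + i] = m.height
        return h

    def node_leaves(self, node: int) -> list[int]:
        children = self._children()
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                out.append(v)
            else:
                stack.extend(children[v])
        return out

    def cophenetic(self) -> np.ndarray:
        """Matrix of merge heights at which each leaf pair first joins."""
        n = self.n_leaves
        coph = np.zeros((n, n))
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for i, m in enumerate(self.merges):
            la, lb = members.pop(m.a), members.pop(m.b)
            for x in la:
                for y in lb:
                    coph[x, y] = coph[y, x] = m.height
            members[n + i] = la + lb
        return coph


def _min_leaf_label(labels: list[str], members: list[int]) -> str:
    return min(labels[i] for i in members)


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """UPGMA merge tree over a validated distance matrix (n >= 2)."""
    labels = dm.labels
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")

    d = dm.d.copy()
    np.fill_diagonal(d, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=int)
    cluster_id = np.arange(n)  # row -> current cluster id
    reps = [labels[i] for i in range(n)]  # smallest leaf label per row
    merges: list[Merge] = []

    for step in range(n - 1):
        sub = np.where(active)[0]
        dsub = d[np.ix_(sub, sub)]
        mval = dsub.min()
        ti, tj = np.where(dsub == mval)
        pairs = [(sub[i], sub[j]) for i, j in zip(ti, tj) if sub[i] < sub[j]]
        # deterministic tie-break: lexicographically smallest label pair
        i, j = min(pairs, key=lambda p: tuple(sorted((reps[p[0]], reps[p[1]]))))

        si, sj = int(sizes[i]), int(sizes[j])
        merges.append(Merge(int(cluster_id[i]), int(cluster_id[j]), float(mval), si + sj))

        # Lance-Williams average-linkage update into row i
        new = (si * d[i, :] + sj * d[j, :]) / (si + sj)
        d[i, :] = new
        d[:, i] = new
        d[i, i] = np.inf
        d[j, :] = np.inf
        d[:, j] = np.inf
        active[j] = False
        sizes[i] = si + sj
        cluster_id[i] = n + step
        reps[i] = min(reps[i], reps[j])

    tree = Dendrogram(labels=list(labels), merges=merges)
    tree.leaf_order = [labels[i] for i in _seriate(tree)]
    return tree


def _seriate(tree: Dendrogram) -> list[int]:
    """Recursive leaf ordering: tighter (lower) subtree first at each node."""
    n = tree.n_leaves
    children = tree._children()
    heights = tree._heights()
    labels = tree.labels
    root = n + len(tree.merges) - 1

    def key(node: int) -> tuple[float, str]:
        return heights[node], _min_leaf_label(labels, tree.node_leaves(node))

    out: list[int] = []
    stack = [root]
    while stack:
        v = stack.pop()
        if v < n:
            out.append(v)
        else:
            a, b = sorted(children[v], key=key)
            stack.append(b)  # LIFO: a comes out first
            stack.append(a)
    return out


def cut_tree(tree: Dendrogram, k: int) -> dict[str, int]:
    """Cluster assignment after removing the k-1 highest merges.

    Merges are applied in merge order (which resolves tied heights
    deterministically); cluster indices follow first appearance in leaf
    order.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError("k must be between 1 and the number of leaves")
    heights = [m.height for m in tree.merges]
    if k > 1 and len(set(heights)) < len(heights):
        import warnings

        warnings.warn(
            "tied merge heights at the cut; resolved by merge order",
            stacklevel=2,
        )
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members: dict[int, int] = {i: i for i in range(n)}  # cluster id -> a leaf
    for i, m in enumerate(tree.merges[: n - k]):
        ra, rb = find(members[m.a]), find(members[m.b])
        parent[rb] = ra
        members[n + i] = ra
    # label clusters by first appearance in leaf order
    order = tree.leaf_order or tree.labels
    idx_of = {lab: i for i, lab in enumerate(tree.labels)}
    assign: dict[str, int] = {}
    next_id = 0
    root_to_cluster: dict[int, int] = {}
    for lab in order:
        r = find(idx_of[lab])
        if r not in root_to_cluster:
            root_to_cluster[r] = next_id
            next_id += 1
        assign[lab] = root_to_cluster[r]
    return assign


def to_newick(tree: Dendrogram) -> str:
    """Newick string with ultrametric branch lengths (leaf depth = height/2).

    Children are emitted in seriation order, so re-parsing reproduces both
    the merge heights (as 2x node depths) and the leaf order.
    """
    n = tree.n_leaves
    children = tree._children()
    heights = tree._heights()
    labels = tree.labels
    root = n + len(tree.merges) - 1

    def key(node: int) -> tuple[float, str]:
        return heights[node], _min_leaf_label(labels, tree.node_leaves(node))

    def render(node: int, parent_height: float) -> str:
        blen = (parent_height - heights[node]) / 2.0
        if node < n:
            return f"{labels[node]}:{blen:.10g}"
        a, b = sorted(children[node], key=key)
        h = heights[node]
        return f"({render(a, h)},{render(b, h)}):{blen:.10g}"

    return render(root, heights[root]) + ";"


def heatmap_export(
    matrix: CohortMatrix | pd.DataFrame,
    row_tree: Dendrogram,
    col_tree: Dendrogram,
    prefix: str | Path,
    png: bool = False,
) -> dict[str, Path]:
    """Write the seriated matrix (TSV), both trees (Newick), optional PNG.

    Returns the paths written, keyed by artifact name.
    """
    values = matrix.values if isinstance(matrix, CohortMatrix) else matrix
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ordered = values.loc[row_tree.leaf_order, col_tree.leaf_order]
    paths = {
        "matrix": prefix.with_suffix(".matrix.tsv"),
        "row_tree": prefix.with_suffix(".rows.nwk"),
        "col_tree": prefix.with_suffix(".cols.nwk"),
    }
    ordered.round(4).to_csv(paths["matrix"], sep="\t")
    paths["row_tree"].write_text(to_newick(row_tree) + "\n")
    paths["col_tree"].write_text(to_newick(col_tree) + "\n")
    if png:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4, 0.4 * len(ordered.columns)), 8), constrained_layout=True
        )
        im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="Reds")
        ax.set_xticks(range(len(ordered.columns)), ordered.columns, rotation=90)
        ax.set_yticks([])
        ax.set_xlabel("sample")
        ax.set_ylabel(f"{len(ordered)} antigens (seriated)")
        fig.colorbar(im, ax=ax, label="log10 normalized volume")
        paths["png"] = prefix.with_suffix(".png")
        fig.savefig(paths["png"], dpi=120)
        plt.close(fig)
    return paths
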