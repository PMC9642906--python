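"""Jaccard distances, Ward agglomeration and behavioural cluster assignment.

Participants with at least one positive trajectory bin are compared pairwise
with a Jaccard distance computed on pairwise-complete bins (bins missing in
either trajectory are ignored), then merged bottom-up by agglomerative
hierarchical clustering under the Ward criterion. Cutting the resulting
dendrogram at k clusters and appending the "never reported the behaviour"
stratum as a reserved baseline cluster 0 yields the final k+1 exposure
categories.

The agglomeration is implemented directly via the Lance-Williams recurrence
(both the "ward.D2" square-root form, the default, and the classic "ward.D"
form) with a deterministic lexicographic tie-break, so that merge order is
reproducible across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import TrajectoryMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "ClusterAssignment",
    "TrendCurves",
    "IncomparablePairError",
    "jaccard_distance",
    "pairwise_distance_matrix",
    "ward_agglomerate",
    "cut_to_k",
    "assign_baseline_cluster",
    "cluster_trend_curves",
]


class IncomparablePairError(ValueError):
    """Raised when two trajectories share no co-observed bin."""


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def jaccard_distance(x, y) -> float:
    """Jaccard distance between two {0,1,NaN} trajectory rows.

    Only bins observed in both rows are considered. Over those bins,
    ``d = (# bins with exactly one 1) / (# bins with at least one 1)``.
    If no co-observed bin carries a 1 the pair is maximally dissimilar
    (d = 1). Rows with no co-observed bin at all are incomparable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("trajectory rows must share the same grid")
    both = ~np.isnan(x) & ~np.isnan(y)
    if not both.any():
        raise IncomparablePairError("no co-observed bins between trajectories")
    xv, yv = x[both] == 1, y[both] == 1
    union = int(np.count_nonzero(xv | yv))
    if union == 0:
        return 1.0
    discordant = int(np.count_nonzero(xv ^ yv))
    return discordant / union


@dataclass
class DistanceMatrix:
    """Symmetric pairwise Jaccard distance matrix over participants."""

    ids: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.ids):
            raise ValueError("matrix must be square and match ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.nanmin(m) < 0 or np.nanmax(m) > 1:
            raise ValueError("Jaccard distances must lie in [0, 1]")
        self.matrix = m


def pairwise_distance_matrix(m: TrajectoryMatrix) -> DistanceMatrix:
    """All-pairs Jaccard distances, vectorised over the {0,1,NaN} matrix.

    Equivalent to calling :func:`jaccard_distance` on every pair; implemented
    with boolean matrix products so cohorts of thousands stay fast. Raises
    :class:`IncomparablePairError` naming the first offending pair if any two
    rows share no co-observed bin.
    """
    V = m.values
    O = (~np.isnan(V)).astype(float)  # observed
    A = (V == 1).astype(float)        # positive (implies observed)

    co_obs = O @ O.T
    n11 = A @ A.T
    n1_ = A @ O.T  # row positive, col observed
    union = n1_ + n1_.T - n11
    discordant = n1_ + n1_.T - 2.0 * n11

    bad = (co_obs == 0) & ~np.eye(len(V), dtype=bool)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise IncomparablePairError(
            f"participants {m.ids[i]!r} and {m.ids[j]!r} share no co-observed bins"
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        d = discordant / union
    d[union == 0] = 1.0  # co-observed but no positive bin anywhere
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry
    return DistanceMatrix(m.ids, d)


# ---------------------------------------------------------------------------
# Ward agglomeration
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Merge tree from agglomerative clustering.

    ``merges`` is an (n-1, 4) array in the usual linkage convention: columns
    (left id, right id, merge height, size of the new cluster), where leaves
    are 0..n-1 and the cluster created at step t has id n+t.
    """

    merges: np.ndarray
    ids: np.ndarray  # leaf participant ids, in distance-matrix order
    variant: str = "ward.D2"

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def to_linkage(self) -> np.ndarray:
        """scipy-compatible linkage matrix (float copy of ``merges``)."""
        return np.asarray(self.merges, dtype=float)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.merges, columns=["left", "right", "height", "size"])
        df.insert(0, "step", np.arange(len(df)))
        df[["left", "right", "size"]] = df[["left", "right", "size"]].astype(int)
        df.to_csv(path, index=False)

    def to_newick(self) -> str:
        n = self.n_leaves
        if n == 1:
            return f"{self.ids[0]};"
        heights = {i: 0.0 for i in range(n)}
        reps = {i: str(self.ids[i]) for i in range(n)}
        for t, (a, b, h, _s) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = h - heights[a]
            lb = h - heights[b]
            reps[n + t] = f"({reps.pop(a)}:{la:.6g},{reps.pop(b)}:{lb:.6g})"
            heights[n + t] = h
        (root,) = reps.values()
        return root + ";"


def ward_agglomerate(d, variant: str = "ward.D2") -> Dendrogram:
    """Agglomerative hierarchical clustering under the Ward criterion.

    Starts from singletons and repeatedly merges the pair of clusters with
    minimal linkage distance, updating distances by the Lance-Williams
    recurrence for Ward. The default ``"ward.D2"`` variant applies the
    recurrence to squared distances and reports square-root heights,

        d(i+j, k) = sqrt[((n_i+n_k) d_ik^2 + (n_j+n_k) d_jk^2 - n_k d_ij^2)
                         / (n_i+n_j+n_k)],

    matching modern hierarchical-clustering defaults; ``"ward.D"`` applies
    the same coefficients to the raw distances. Exact ties in the minimal
    linkage are broken by the lexicographically smallest (left id, right id)
    pair, which makes merge order deterministic.
    """
    if variant not in ("ward.D2", "ward.D"):
        raise ValueError(f"unknown Ward variant {variant!r}")
    if isinstance(d, DistanceMatrix):
        ids, mat = d.ids, d.matrix
    else:
        mat = np.asarray(d, dtype=float)
        ids = np.arange(mat.shape[0])
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(mat, mat.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if mat.size and np.min(mat) < 0:
            raise ValueError("distances must be non-negative")

    n = mat.shape[0]
    merges = np.zeros((max(n - 1, 0), 4))
    if n <= 1:
        return Dendrogram(merges, np.asarray(ids), variant)

    # working matrix: squared distances for ward.D2, raw for ward.D
    D = mat.astype(float) ** 2 if variant == "ward.D2" else mat.astype(float)
    cluster_ids = list(range(n))  # active clusters, ids strictly increasing
    sizes = np.ones(n)
    active = D.copy()
    np.fill_diagonal(active, np.inf)

    for step in range(n - 1):
        m = active.shape[0]
        # minimal linkage; ties -> lexicographically smallest id pair.
        # cluster_ids is increasing, so the first (row-major, upper triangle)
        # position attaining the minimum is the lexicographic winner.
        iu = np.triu_indices(m, k=1)
        flat = active[iu]
        pos = int(np.argmin(flat))
        i, j = int(iu[0][pos]), int(iu[1][pos])
        dij = flat[pos]

        ni, nj, nk = sizes[i], sizes[j], np.delete(sizes, [i, j])
        dik = np.delete(active[i], [i, j])
        djk = np.delete(active[j], [i, j])
        new = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)

        height = float(np.sqrt(dij)) if variant == "ward.D2" else float(dij)
        merges[step] = (cluster_ids[i], cluster_ids[j], height, ni + nj)

        keep = [x for x in range(m) if x not in (i, j)]
        active = active[np.ix_(keep, keep)]
        sizes = np.append(sizes[keep], ni + nj)
        cluster_ids = [cluster_ids[x] for x in keep] + [n + step]
        active = np.pad(active, ((0, 1), (0, 1)))
        active[-1, :-1] = new
        active[:-1, -1] = new
        active[-1, -1] = np.inf

    return Dendrogram(merges, np.asarray(ids), variant)


def cut_to_k(tree: Dendrogram, k: int, positivity: np.ndarray | None = None) -> np.ndarray:
    """Cut the dendrogram into k clusters; labels 1..k over the leaves.

    Undoes the last k-1 merges and labels the resulting components 1..k by
    ascending mean trajectory positivity of their members (``positivity`` is
    a per-leaf array, e.g. mean positivity of the clustered trajectories);
    without it, components are ordered by their smallest leaf index.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")

    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):  # replay all but the last k-1 merges
        a, b, _h, _s = tree.merges[t]
        new = n + t
        parent[find(int(a))] = new
        parent[find(int(b))] = new

    roots = [find(i) for i in range(n)]
    components: dict[int, list[int]] = {}
    for leaf, r in enumerate(roots):
        components.setdefault(r, []).append(leaf)
    assert len(components) == k

    if positivity is not None:
        positivity = np.asarray(positivity, dtype=float)
        order = sorted(components.values(), key=lambda mem: (np.mean(positivity[mem]), mem[0]))
    else:
        order = sorted(components.values(), key=lambda mem: mem[0])

    labels = np.zeros(n, dtype=int)
    for lab, mem in enumerate(order, start=1):
        labels[mem] = lab
    return labels


# ---------------------------------------------------------------------------
# Baseline cluster and trends
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """participant -> cluster label in {0, 1, ..., k}; 0 is the reserved
    baseline label for participants who never reported the behaviour."""

    labels: pd.Series  # index participant_id, values int
    k: int  # number of hierarchical (non-baseline) clusters

    def __post_init__(self) -> None:
        labs = set(self.labels.unique())
        if not labs <= set(range(self.k + 1)):
            raise ValueError(f"labels {sorted(labs)} outside 0..{self.k}")

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().reindex(range(self.k + 1), fill_value=0)

    def to_csv(self, path) -> None:
        df = self.labels.rename("cluster").rename_axis("participant_id").reset_index()
        df.to_csv(path, index=False)


def assign_baseline_cluster(m: TrajectoryMatrix, labels) -> ClusterAssignment:
    """Append the never-reported stratum as cluster 0.

    ``labels`` maps exactly the ever-positive participants to 1..k; all other
    participants (no positive bin among their observed bins) receive the
    reserved baseline label 0.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    ever = set(m.ids[m.ever_positive()])
    labelled = set(labels.index)
    if labelled - set(m.ids):
        raise ValueError("labels contain unknown participants")
    never_labelled = labelled - ever
    if never_labelled:
        raise ValueError(
            f"participants {sorted(never_labelled)[:5]} have all-zero trajectories "
            "but carry hierarchical labels (overlap with baseline cluster)"
        )
    if ever - labelled:
        raise ValueError("some ever-positive participants are unlabelled")
    k = int(labels.max()) if len(labels) else 0
    full = pd.Series(0, index=pd.Index(m.ids, name="participant_id"), dtype=int)
    full.loc[list(labels.index)] = labels.astype(int).values
    logger.info(
        "cluster assignment: %d participants, %d in baseline cluster 0, k=%d",
        len(full), int((full == 0).sum()), k,
    )
    return ClusterAssignment(full, k)


@dataclass
class TrendCurves:
    """Per-cluster, per-bin proportion of positive values among non-missing."""

    proportions: pd.DataFrame  # index cluster label, columns bin labels; NaN where no data
    counts: pd.DataFrame       # non-missing denominators, same shape

    def to_csv(self, path) -> None:
        long = (
            self.proportions.rename_axis("cluster")
            .reset_index()
            .melt(id_vars="cluster", var_name="bin", value_name="proportion")
        )
        cnt = (
            self.counts.rename_axis("cluster")
            .reset_index()
            .melt(id_vars="cluster", var_name="bin", value_name="n_observed")
        )
        long["n_observed"] = cnt["n_observed"].astype(int)
        long.to_csv(path, index=False)


def cluster_trend_curves(m: TrajectoryMatrix, a: ClusterAssignment) -> TrendCurves:
    """Behaviour prevalence over calendar time within each cluster."""
    labels = a.labels.reindex(m.ids)
    if labels.isna().any():
        raise ValueError("assignment does not cover all trajectory rows")
    props, counts = {}, {}
    for lab in range(a.k + 1):
        rows = m.values[(labels == lab).to_numpy()]
        nobs = np.count_nonzero(~np.isnan(rows), axis=0)
        with np.errstate(invalid="ignore"):
            p = np.where(nobs > 0, np.nansum(rows == 1, axis=0) / np.maximum(nobs, 1), np.nan)
        props[lab] = p
        counts[lab] = nobs
    cols = m.grid.labels
    return TrendCurves(
        proportions=pd.DataFrame.from_dict(props, orient="index", columns=cols),
        counts=pd.DataFrame.from_dict(counts, orient="index", columns=cols),
    )
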