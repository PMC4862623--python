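"""One-class session selection by clustering of finger-print models.

Individual EFPs fitted with different band schemes are brought into a
common space (expand bands to the 1 Hz grid, collapse to one uniform
scheme, flatten), compared with the correlation distance 1 - R, and merged
agglomeratively: each merge joins the two clusters whose representative
vectors (plain means of member leaf vectors) are closest.  The sessions
with the smallest maximum internal distance inside the biggest cluster are
the "positive" set used for common-model training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .bands import BandScheme
from .regression import EFPModel


@dataclass
class EFPVector:
    """A vectorized finger-print on a uniform band scheme."""

    values: np.ndarray
    session_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("EFP vector must be finite")


@dataclass
class Merge:
    """One agglomeration step."""

    child_a: frozenset
    child_b: frozenset
    distance: float
    representative: np.ndarray


@dataclass
class ClusterTree:
    """Linkage record: leaves, the merge sequence and the final clusters."""

    leaf_ids: list[str]
    leaf_vectors: dict[str, np.ndarray]
    merges: list[Merge] = field(default_factory=list)
    clusters: list[frozenset] = field(default_factory=list)

    def largest_cluster(self) -> frozenset:
        """Most leaves; ties broken by smaller mean internal distance."""
        best, best_key = None, None
        for c in self.clusters:
            size = len(c)
            if size == 1:
                mean_d = 0.0
            else:
                dists = [efp_distance_vec(self.leaf_vectors[a], self.leaf_vectors[b])
                         for a, b in combinations(sorted(c), 2)]
                mean_d = float(np.mean(dists))
            key = (-size, mean_d, tuple(sorted(c)))
            if best_key is None or key < best_key:
                best, best_key = c, key
        return best

    def merge_distances(self) -> np.ndarray:
        return np.array([m.distance for m in self.merges])

    def to_newick(self) -> str:
        """Dendrogram as a Newick string, merge distances as heights."""
        node_repr = {frozenset([s]): s for s in self.leaf_ids}
        height = {frozenset([s]): 0.0 for s in self.leaf_ids}
        for m in self.merges:
            joined = m.child_a | m.child_b
            h = m.distance
            parts = []
            for child in (m.child_a, m.child_b):
                bl = max(h - height[child], 0.0)
                parts.append(f"{node_repr[child]}:{bl:.6g}")
            node_repr[joined] = "(" + ",".join(sorted(parts)) + ")"
            height[joined] = h
        roots = [node_repr[c] for c in self.clusters]
        if len(roots) == 1:
            return roots[0] + ";"
        return "(" + ",".join(roots) + ");"


def rebin_efp(model: EFPModel, uniform_scheme: BandScheme) -> EFPVector:
    """Re-express a finger-print on a uniform band scheme and flatten it.

    Each model band row is replicated to its member 1 Hz rows, then the
    1 Hz rows are averaged within each band of ``uniform_scheme``; the
    result is flattened band-major.  Both schemes must cover the same
    frequency range.
    """
    src = model.band_scheme
    if (src.fmin, src.fmax) != (uniform_scheme.fmin, uniform_scheme.fmax):
        raise ValueError("schemes must cover the same frequency range")
    grid = np.arange(src.fmin, src.fmax)  # 1 Hz bins [f, f+1)
    expanded = np.empty((grid.size, model.coeffs.shape[1]))
    for j, f in enumerate(grid):
        expanded[j] = model.coeffs[src.band_of(f)]
    out = np.empty((uniform_scheme.n_bands, model.coeffs.shape[1]))
    for b in range(uniform_scheme.n_bands):
        sel = (grid >= uniform_scheme.edges_hz[b]) & (grid < uniform_scheme.edges_hz[b + 1])
        if not sel.any():
            raise ValueError(f"uniform band {b} contains no 1 Hz rows")
        out[b] = expanded[sel].mean(axis=0)
    return EFPVector(out.ravel(), session_id=model.fit_meta.get("session_id", ""))


def efp_distance_vec(a: np.ndarray, b: np.ndarray) -> float:
    """Correlation distance 1 - Pearson R between two flat vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("zero-variance vector has no correlation distance")
    r = float(np.corrcoef(a, b)[0, 1])
    return 1.0 - r


def efp_distance(a: EFPVector, b: EFPVector) -> float:
    return efp_distance_vec(a.values, b.values)


def cluster_efps(vectors: list[EFPVector], stop_k: int) -> ClusterTree:
    """Agglomerate by minimal representative distance until stop_k clusters.

    The representative of a cluster is the plain mean of its member leaf
    vectors (recomputed from the leaves after each merge, not a mean of
    means), so merge distances are not guaranteed monotone; they are
    recorded as computed.  Distance ties are broken by the
    lexicographically smallest (sorted session-id) pair.
    """
    n = len(vectors)
    if n < 2:
        raise ValueError("need at least two vectors")
    if not 1 <= stop_k < n:
        raise ValueError("stop_k must satisfy 1 <= stop_k < n_vectors")
    ids = [v.session_id for v in vectors]
    if len(set(ids)) != n:
        raise ValueError("session ids must be unique")
    leaf_vectors = {v.session_id: v.values for v in vectors}
    tree = ClusterTree(leaf_ids=sorted(ids), leaf_vectors=leaf_vectors)
    reps: dict[frozenset, np.ndarray] = {
        frozenset([i]): leaf_vectors[i] for i in ids}
    while len(reps) > stop_k:
        best = None
        for ca, cb in combinations(sorted(reps, key=lambda c: tuple(sorted(c))), 2):
            d = efp_distance_vec(reps[ca], reps[cb])
            key = (d, tuple(sorted(min(ca, cb, key=sorted))),
                   tuple(sorted(max(ca, cb, key=sorted))))
            if best is None or key < best[0]:
                best = (key, ca, cb, d)
        _, ca, cb, d = best
        joined = ca | cb
        rep = np.mean([leaf_vectors[i] for i in joined], axis=0)
        tree.merges.append(Merge(ca, cb, d, rep))
        del reps[ca], reps[cb]
        reps[joined] = rep
    tree.clusters = sorted(reps, key=lambda c: tuple(sorted(c)))
    return tree


def knee_index(merge_distances: np.ndarray) -> int | None:
    """Index of the largest discrete second difference of the merge curve.

    Returns None when the curve is (numerically) straight, i.e. no knee.
    """
    d = np.asarray(merge_distances, dtype=float)
    if d.size < 3:
        raise ValueError("need at least three merge steps")
    second = d[2:] - 2 * d[1:-1] + d[:-2]
    scale = max(np.abs(np.diff(d)).max(), np.finfo(float).eps)
    if second.max() <= 1e-9 * max(scale, 1.0):
        return None
    return int(np.argmax(second)) + 1


def knee_stop(
    merge_distances: np.ndarray,
    n_leaves: int,
    default_ratio: float = 24.0 / 39.0,
) -> int:
    """Cluster count at which to stop, from the knee of the merge curve.

    The knee index is the last merge on the shallow branch of the curve
    (the second difference peaks where the slope breaks), so merges
    0 .. knee are kept and n_leaves - (knee + 1) clusters remain.  A flat
    or straight curve falls back to the default ratio (24 clusters for 39
    sessions, scaled proportionally).
    """
    i = knee_index(merge_distances)
    if i is None:
        return max(1, int(round(default_ratio * n_leaves)))
    return max(1, n_leaves - (i + 1))


def select_positive(tree: ClusterTree, n_select: int) -> list[str]:
    """The n closest sessions (smallest max internal distance) of the biggest cluster.

    Greedy search: start from the closest pair, then repeatedly add the
    member that minimizes the resulting maximum pairwise distance; ties go
    to the smaller session id.  Raises when the biggest cluster is too
    small, listing all cluster sizes.
    """
    big = tree.largest_cluster()
    if len(big) < n_select:
        sizes = sorted((len(c) for c in tree.clusters), reverse=True)
        raise ValueError(
            f"largest cluster has {len(big)} members < n_select={n_select}; "
            f"cluster sizes: {sizes}")
    members = sorted(big)
    vec = {m: tree.leaf_vectors[m] for m in members}
    dist = {
        (a, b): efp_distance_vec(vec[a], vec[b])
        for a, b in combinations(members, 2)
    }

    def d(a: str, b: str) -> float:
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    pair = min(combinations(members, 2), key=lambda p: (d(*p), p))
    chosen = list(pair)
    while len(chosen) < n_select:
        best = None
        for cand in members:
            if cand in chosen:
                continue
            new_max = max(d(cand, c) for c in chosen)
            key = (new_max, cand)
            if best is None or key < best[0]:
                best = (key, cand)
        chosen.append(best[1])
    return sorted(chosen)


def max_internal_distance(vectors: dict[str, np.ndarray], subset) -> float:
    """Largest pairwise correlation distance within a subset of sessions."""
    return max(
        efp_distance_vec(vectors[a], vectors[b])
        for a, b in combinations(sorted(subset), 2)
    )
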