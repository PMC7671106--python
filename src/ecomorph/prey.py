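"""Functional-trait clustering of prey items into dietary ("synthetic") categories.

Prey items are coded as binary functional-trait vectors (armour, motility,
habitat stratum, defensive structures, trophic habit, ...).  Items are
clustered with Ward's minimum-variance method on the Euclidean distance
matrix, and the number of prey categories is chosen from the within-groups
sum-of-squares (WGSS) curve.

Ward agglomeration is implemented directly via the Lance-Williams recurrence
because two incompatible "Ward" dialects circulate (distances squared before
the recurrence versus used as-is) and because a deterministic, name-based
merge tie-break is needed for binary data, where equal merge costs are the
rule rather than the exception.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PreyTraitMatrix",
    "DistanceMatrix",
    "Dendrogram",
    "CategorySet",
    "PreyValidationError",
    "euclidean_distance_matrix",
    "ward_cluster",
    "wgss_curve",
    "select_k_inflection",
    "cut_to_categories",
]


class PreyValidationError(ValueError):
    """Raised when a prey-trait matrix or distance matrix is malformed."""


@dataclass(frozen=True)
class PreyTraitMatrix:
    """Prey items x binary functional traits (presence/absence)."""

    items: tuple[str, ...]
    traits: tuple[str, ...]
    values: np.ndarray  # shape (n_items, n_traits), entries in {0, 1}

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.items), len(self.traits)):
            raise PreyValidationError(
                f"matrix shape {vals.shape} does not match "
                f"{len(self.items)} items x {len(self.traits)} traits"
            )
        if len(set(self.items)) != len(self.items):
            raise PreyValidationError("prey-item names must be unique")
        if len(set(self.traits)) != len(self.traits):
            raise PreyValidationError("trait names must be unique")
        bad = ~np.isin(vals, (0.0, 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PreyValidationError(
                f"non-binary entry {vals[i, j]!r} at item {self.items[i]!r}, "
                f"trait {self.traits[j]!r}"
            )

    @property
    def n_items(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal."""

    items: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.items)
        if d.shape != (n, n):
            raise PreyValidationError("distance matrix shape mismatch")
        if not np.allclose(d, d.T, atol=1e-12):
            raise PreyValidationError("distance matrix is not symmetric")
        if (d < 0).any():
            raise PreyValidationError("negative distances")
        if not np.allclose(np.diag(d), 0.0):
            raise PreyValidationError("nonzero diagonal")


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge history.

    ``merges[i] = (a, b, height, size)`` with scipy-style cluster indices:
    leaves are ``0..n-1`` and the cluster created by merge ``i`` has index
    ``n + i``.  ``dialect`` records which Ward variant produced the heights.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]
    dialect: str

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise PreyValidationError("a dendrogram over n leaves needs n-1 merges")

    def cut(self, k: int) -> list[set[str]]:
        """Partition the leaves into exactly ``k`` groups."""
        n = len(self.leaves)
        if not 1 <= k <= n:
            raise PreyValidationError(f"k={k} out of range 1..{n}")
        members: dict[int, set[int]] = {i: {i} for i in range(n)}
        for i, (a, b, _h, _s) in enumerate(self.merges):
            if len(members) == k:
                break
            members[n + i] = members.pop(a) | members.pop(b)
        groups = [{self.leaves[i] for i in s} for s in members.values()]
        # canonical order: by smallest member name
        return sorted(groups, key=lambda s: min(s))

    def to_newick(self) -> str:
        """Serialize as a Newick string with merge heights as node depths."""
        n = len(self.leaves)
        height = {i: 0.0 for i in range(n)}
        node = {i: _quote_newick(self.leaves[i]) for i in range(n)}
        for i, (a, b, h, _s) in enumerate(self.merges):
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[n + i] = f"({node.pop(a)}:{la:.6g},{node.pop(b)}:{lb:.6g})"
            height[n + i] = h
        (root,) = node.values()
        return root + ";"


def _quote_newick(label: str) -> str:
    if any(c in label for c in " (),:;'\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass(frozen=True)
class CategorySet:
    """A flat partition of prey items into k named categories."""

    k: int
    membership: dict[str, str] = field(default_factory=dict)
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        used = set(self.membership.values())
        if len(used) != self.k:
            raise PreyValidationError(
                f"{len(used)} distinct labels used but k={self.k}"
            )

    def items_of(self, category: str) -> set[str]:
        return {i for i, c in self.membership.items() if c == category}

    @property
    def categories(self) -> tuple[str, ...]:
        if self.names:
            return self.names
        return tuple(sorted(set(self.membership.values())))


def euclidean_distance_matrix(m: PreyTraitMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distances between prey-item trait vectors.

    For binary traits d(i, j) = sqrt(#differing traits), bounded by sqrt(T).
    """
    if m.n_items < 2:
        raise PreyValidationError("need at least 2 prey items")
    x = m.values
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    return DistanceMatrix(items=m.items, d=np.sqrt(sq))


def ward_cluster(d: DistanceMatrix, dialect: str = "d2") -> Dendrogram:
    """Ward minimum-variance agglomeration via the Lance-Williams recurrence.

    Parameters
    ----------
    d
        Pairwise distance matrix.
    dialect
        ``"d2"`` (default): distances are squared before the recurrence and
        merge heights reported on the original distance scale (the
        ``ward.D2`` convention, matching :func:`scipy.cluster.hierarchy.linkage`).
        ``"d"``: the recurrence is applied to the distances as given
        (the historical ``ward.D`` convention).

    Ties in merge cost are broken deterministically: among tied pairs, merge
    the pair whose lexicographically smallest member name sorts first (then
    the second member).  This makes the result invariant to input row order.
    """
    if dialect not in ("d", "d2"):
        raise PreyValidationError(f"unknown Ward dialect {dialect!r}")
    names = d.items
    n = len(names)
    cur = d.d.copy() if dialect == "d" else d.d**2
    np.fill_diagonal(cur, np.inf)

    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster index -> size
    # smallest member name per cluster, for the tie-break
    minname: dict[int, str] = {i: names[i] for i in range(n)}
    pos: dict[int, int] = {i: i for i in range(n)}  # cluster index -> matrix row

    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        rows = sorted(active, key=lambda c: pos[c])
        # find the minimum-cost pair with deterministic tie-break
        best = None
        best_cost = np.inf
        for ii, ci in enumerate(rows):
            for cj in rows[ii + 1 :]:
                cost = cur[pos[ci], pos[cj]]
                key = tuple(sorted((minname[ci], minname[cj])))
                if cost < best_cost - 1e-12 or (
                    abs(cost - best_cost) <= 1e-12
                    and best is not None
                    and key < best[2]
                ):
                    best_cost = cost
                    best = (ci, cj, key)
        ci, cj, _ = best  # type: ignore[misc]
        ni, nj = active[ci], active[cj]
        new = n + step
        height = float(np.sqrt(best_cost)) if dialect == "d2" else float(best_cost)
        merges.append((ci, cj, height, ni + nj))

        # Lance-Williams update: alpha_i=(n_i+n_k)/(n_i+n_j+n_k),
        # beta=-n_k/(n_i+n_j+n_k), gamma=0
        pi, pj = pos[ci], pos[cj]
        for ck in active:
            if ck in (ci, cj):
                continue
            nk = active[ck]
            pk = pos[ck]
            tot = ni + nj + nk
            upd = (
                (ni + nk) / tot * cur[pi, pk]
                + (nj + nk) / tot * cur[pj, pk]
                - nk / tot * cur[pi, pj]
            )
            cur[pi, pk] = cur[pk, pi] = upd
        cur[pj, :] = np.inf
        cur[:, pj] = np.inf
        del active[ci], active[cj]
        active[new] = ni + nj
        minname[new] = min(minname.pop(ci), minname.pop(cj))
        pos[new] = pi

    return Dendrogram(leaves=names, merges=tuple(merges), dialect=dialect)


def wgss_curve(
    m: PreyTraitMatrix, dendro: Dendrogram, k_max: int
) -> list[tuple[int, float]]:
    """Within-groups sum of squares, in trait space, for each cut k=1..k_max.

    WGSS(k) = sum over clusters of the squared Euclidean distances of members
    to their cluster centroid.  Non-increasing in k along one dendrogram;
    WGSS(n) = 0.
    """
    n = m.n_items
    if not 1 <= k_max <= n:
        raise PreyValidationError(f"k_max={k_max} out of range 1..{n}")
    idx = {name: i for i, name in enumerate(m.items)}
    out = []
    for k in range(1, k_max + 1):
        tot = 0.0
        for group in dendro.cut(k):
            sub = m.values[[idx[g] for g in group]]
            tot += float(((sub - sub.mean(axis=0)) ** 2).sum())
        out.append((k, tot))
    return out


def select_k_inflection(
    curve: Sequence[tuple[int, float]],
) -> tuple[int, list[tuple[int, float]], bool]:
    """Pick the elbow of a (k, WGSS) curve.

    Uses the maximum perpendicular distance from each curve point to the
    chord joining the first and last points -- a parameter-free, reproducible
    surrogate for the visual "inflection point" of a scree-style plot.

    Returns ``(k, curve, degenerate)``; ``degenerate`` is True when the curve
    is flat (e.g. all items identical), in which case k = 1.
    """
    ks = np.array([k for k, _ in curve], dtype=float)
    w = np.array([v for _, v in curve], dtype=float)
    if len(ks) < 3:
        raise PreyValidationError("curve must cover at least k=1..3")
    if (np.diff(w) > 1e-9).any():
        warnings.warn("WGSS curve is not non-increasing in k", stacklevel=2)
    if np.allclose(w, w[0]):
        return int(ks[0]), list(curve), True
    p1 = np.array([ks[0], w[0]])
    p2 = np.array([ks[-1], w[-1]])
    v = p2 - p1
    v = v / np.linalg.norm(v)
    rel = np.stack([ks, w], axis=1) - p1
    perp = np.abs(rel[:, 0] * v[1] - rel[:, 1] * v[0])
    return int(ks[int(perp.argmax())]), list(curve), False


def cut_to_categories(
    dendro: Dendrogram, k: int, names: Sequence[str] | None = None
) -> CategorySet:
    """Cut the dendrogram at k groups and label them.

    Groups are ordered canonically by their smallest member name, so labels
    are stable under permutation of the input rows.  ``names``, if given,
    are applied in that canonical order.
    """
    groups = dendro.cut(k)
    if names is not None:
        if len(names) != k:
            raise PreyValidationError(f"{len(names)} names supplied for k={k}")
        labels = list(names)
    else:
        labels = [f"category_{i + 1}" for i in range(k)]
    membership = {
        item: labels[gi] for gi, group in enumerate(groups) for item in group
    }
    return CategorySet(k=k, membership=membership, names=tuple(labels))
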