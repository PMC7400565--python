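"""Low-dimensional summaries of a shared-drift matrix.

Two standard views of an outgroup-f3 matrix: classical (Torgerson) MDS of
the 1 - f3 distances, and a neighbor-joining tree of the f3^-1 distances
rooted on an outgroup for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode


@dataclass
class Embedding:
    """Coordinates from classical MDS, plus the eigenvalues of each axis."""

    labels: list[str]
    coords: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # (k,)
    rotation_degrees: float = 0.0


@dataclass
class UnrootedTree:
    """A neighbor-joining tree, serialized as Newick (rooted for display)."""

    newick: str
    negative_branches_clamped: int = 0

    def to_treenode(self) -> TreeNode:
        return TreeNode.read([self.newick])


def _check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    return d


def classical_mds(distance_matrix: np.ndarray, labels=None, k: int = 2) -> Embedding:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared distances, eigendecomposes, and keeps the
    top-k positive-eigenvalue axes. Axis signs follow a deterministic
    convention: the largest-magnitude loading on each axis is positive.
    """
    d = _check_distance_matrix(distance_matrix)
    n = d.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-12, 1e-10 * abs(vals[0])) if n else vals > 0
    k_eff = min(k, int(pos.sum()))
    coords = np.zeros((n, k))
    eig = np.zeros(k)
    for axis in range(k_eff):
        v = vecs[:, axis] * np.sqrt(vals[axis])
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, axis] = v
        eig[axis] = vals[axis]
    return Embedding(list(labels), coords, eig)


def rotate2d(embedding: Embedding, degrees: float) -> Embedding:
    """Rigid planar rotation of a 2-D embedding (distances preserved)."""
    if embedding.coords.shape[1] != 2:
        raise ValueError("rotate2d requires a 2-dimensional embedding")
    t = np.deg2rad(degrees)
    r = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    return Embedding(
        list(embedding.labels),
        embedding.coords @ r.T,
        embedding.eigenvalues.copy(),
        embedding.rotation_degrees + degrees,
    )


def neighbor_joining(
    distance_matrix: np.ndarray,
    labels: list[str],
    outgroup_label: str | None = None,
    topology_only: bool = False,
) -> UnrootedTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Agglomerates by the standard Q-criterion; ties are broken by the
    lexicographically smallest pair of subtree labels, so runs are
    reproducible regardless of input order. Negative branch lengths are
    clamped to zero with a warning. If ``outgroup_label`` is given, the
    tree is rooted on the outgroup's pendant edge (split in half) for
    display. ``topology_only`` zeroes all branch lengths in the output.
    """
    d = _check_distance_matrix(distance_matrix).copy()
    labels = list(labels)
    if len(labels) != d.shape[0]:
        raise ValueError("labels do not match matrix size")
    if len(labels) < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    if outgroup_label is not None and outgroup_label not in labels:
        raise ValueError(f"outgroup {outgroup_label!r} not among labels")

    clamped = 0

    def fmt(length: float) -> float:
        nonlocal clamped
        if length < 0:
            clamped += 1
            return 0.0
        return length

    # each active node carries a newick fragment and a sort key
    # (lexicographically smallest leaf label in its subtree) for tie-breaks
    active = list(range(len(labels)))
    frags = {i: labels[i] for i in range(len(labels))}
    keys = {i: labels[i] for i in range(len(labels))}
    dist = {(i, j): d[i, j] for i in range(len(labels)) for j in range(len(labels))}
    next_id = len(labels)

    def get(i, j):
        return dist[(i, j)] if i <= j else dist[(j, i)]

    while len(active) > 2:
        r = len(active)
        totals = {i: sum(get(i, j) for j in active if j != i) for i in active}
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                i, j = active[ii], active[jj]
                q = (r - 2) * get(i, j) - totals[i] - totals[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, (i, j))
                if best is None or cand < best:
                    best = cand
        _, _, (i, j) = best
        dij = get(i, j)
        li = 0.5 * dij + (totals[i] - totals[j]) / (2 * (r - 2))
        lj = dij - li
        li, lj = fmt(li), fmt(lj)
        new = next_id
        next_id += 1
        for m in active:
            if m in (i, j):
                continue
            dist[(min(m, new), max(m, new))] = 0.5 * (get(i, m) + get(j, m) - dij)
        a, b = sorted(((keys[i], i, li), (keys[j], j, lj)))
        frags[new] = (
            f"({frags[a[1]]}:{_L(a[2], topology_only)},"
            f"{frags[b[1]]}:{_L(b[2], topology_only)})"
        )
        keys[new] = min(keys[i], keys[j])
        active = [m for m in active if m not in (i, j)] + [new]
    i, j = active
    dij = fmt(get(i, j))
    # final edge: attach as a 2-child root representing the unrooted tree's
    # central edge; outgroup rooting splits the outgroup's pendant edge
    a, b = sorted(((keys[i], i), (keys[j], j)))
    newick = (
        f"({frags[a[1]]}:{_L(dij / 2, topology_only)},"
        f"{frags[b[1]]}:{_L(dij / 2, topology_only)});"
    )
    if clamped:
        warnings.warn(f"{clamped} negative NJ branch lengths clamped to 0", stacklevel=2)
    tree = UnrootedTree(newick, clamped)
    if outgroup_label is not None:
        tree = _root_on(tree, outgroup_label, topology_only)
    return tree


def _L(length: float, topology_only: bool) -> str:
    return "0" if topology_only else f"{length:.10g}"


def _root_on(tree: UnrootedTree, outgroup: str, topology_only: bool) -> UnrootedTree:
    t = tree.to_treenode()
    node = t.find(outgroup)
    half = (node.length or 0.0) / 2
    rooted = t.root_at(node.parent)  # unroot-style re-rooting near the outgroup
    out = rooted.find(outgroup)
    if out.parent is not rooted:
        rooted = t.root_at(out.parent)
        out = rooted.find(outgroup)
    # split the outgroup pendant edge: outgroup on one side, rest on other
    rest = [c for c in rooted.children if c is not out]
    if len(rest) == 1:
        sib = rest[0]
    else:
        sib = TreeNode(children=rest)
        sib.length = 0.0
    out = out.copy()
    sib = sib.copy()
    out.length = 0.0 if topology_only else half
    sib.length = (sib.length or 0.0) if topology_only else (sib.length or 0.0) + half
    if topology_only:
        for n in sib.traverse():
            n.length = 0.0
        sib.length = 0.0
    new_root = TreeNode(children=[out, sib])
    nwk = str(new_root).strip()
    return UnrootedTree(nwk, tree.negative_branches_clamped)
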