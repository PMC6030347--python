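"""Neighbour-joining trees and metric multidimensional scaling.

``neighbor_joining`` is the Saitou-Nei agglomeration with the usual
Q-criterion and branch-length formulas; it reconstructs additive matrices
exactly.  Ties in the Q minimum are broken by the lexicographically
smallest label pair so output is platform-independent.  Negative branch
lengths (possible for non-additive input) are clamped to zero with the
deficit transferred to the sister branch, the standard correction.

``classical_mds`` is Torgerson scaling: double-centre the squared
distances, eigendecompose, embed on the top non-negative eigenvalues.  All
eigenvalues are reported so non-Euclidean input (negative eigenvalues) is
visible rather than silently truncated; an optional SMACOF refinement
minimises raw stress from the classical start.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .model import DistanceMatrix

__all__ = [
    "neighbor_joining",
    "classical_mds",
    "Embedding",
    "cluster_report",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# neighbour joining


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Build an unrooted NJ tree (trifurcating root) from a distance matrix.

    Requires >= 3 taxa and non-negative entries.  Leaf order in the output
    follows the input label order.
    """
    if dm.size < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    if (dm.d < 0).any():
        raise ValueError("negative dissimilarities; floor Fst matrices first")

    labels = list(dm.labels)
    order = {lab: i for i, lab in enumerate(labels)}
    d = {a: {b: float(dm[a, b]) for b in labels if b != a} for a in labels}
    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    # rank for deterministic tie-breaks and input-order children
    rank: dict[str, tuple] = {lab: (order[lab],) for lab in labels}
    active = list(labels)
    internal_count = 0

    def attach(parent: TreeNode, child: TreeNode, length: float) -> None:
        child.length = max(float(length), 0.0)
        parent.append(child)

    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        best_pair = None
        for ii, a in enumerate(active):
            for b in active[ii + 1:]:
                q = (n - 2) * d[a][b] - r[a] - r[b]
                pair_rank = tuple(sorted((rank[a], rank[b])))
                if best is None or q < best - 1e-12 or (
                        abs(q - best) <= 1e-12
                        and pair_rank < best_pair_rank):
                    best = q
                    best_pair = (a, b)
                    best_pair_rank = pair_rank
        a, b = best_pair
        la = 0.5 * d[a][b] + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = d[a][b] - la
        # clamp-and-transfer for negative branch estimates
        if la < 0:
            lb += -la
            la = 0.0
            log.info("clamped negative branch at %s; moved to %s", a, b)
        if lb < 0:
            la += -lb
            lb = 0.0
            log.info("clamped negative branch at %s; moved to %s", b, a)
        internal_count += 1
        new_name = f"_nj{internal_count}"
        parent = TreeNode()
        first, second = (a, b) if rank[a] < rank[b] else (b, a)
        attach(parent, nodes[first], la if first == a else lb)
        attach(parent, nodes[second], lb if first == a else la)
        nodes[new_name] = parent
        rank[new_name] = min(rank[a], rank[b])
        d[new_name] = {}
        for c in active:
            if c in (a, b):
                continue
            dc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
            d[new_name][c] = dc
            d[c][new_name] = dc
        for c in (a, b):
            del d[c]
        for c in d:
            d[c].pop(a, None)
            d[c].pop(b, None)
        active = [x for x in active if x not in (a, b)] + [new_name]

    # final three-point star: x = (dab + dac - dbc) / 2 etc.
    a, b, c = sorted(active, key=lambda x: rank[x])
    root = TreeNode()
    la = 0.5 * (d[a][b] + d[a][c] - d[b][c])
    lb = 0.5 * (d[a][b] + d[b][c] - d[a][c])
    lc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
    for lab, ln in ((a, la), (b, lb), (c, lc)):
        if ln < 0:
            log.info("clamped negative terminal branch at %s", lab)
        attach(root, nodes[lab], ln)
    return root


# ---------------------------------------------------------------------------
# classical MDS


@dataclass
class Embedding:
    """A k-dimensional configuration recovered from distances."""

    labels: list[str]
    coordinates: np.ndarray          # len(labels) x k, centroid at origin
    eigenvalues: np.ndarray          # all eigenvalues, descending
    strain: float                    # relative magnitude of discarded part
    stress: float | None = None      # raw stress after SMACOF (if refined)

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    def coords_of(self, label: str) -> np.ndarray:
        return self.coordinates[self.labels.index(label)]

    def recovered_distances(self) -> np.ndarray:
        x = self.coordinates
        diff = x[:, None, :] - x[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=-1))


def classical_mds(dm: DistanceMatrix, k: int = 2,
                  refine: bool = False, max_iter: int = 300,
                  tol: float = 1e-6) -> Embedding:
    """Torgerson metric MDS of a symmetric distance matrix.

    If fewer than ``k`` positive eigenvalues exist the dimension is reduced
    with a warning.  ``refine`` runs SMACOF stress majorisation from the
    classical configuration (deterministic, bounded iterations).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = dm.size
    d2 = dm.d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    idx = np.argsort(evals)[::-1]
    evals = evals[idx]
    evecs = evecs[:, idx]
    n_pos = int((evals > 1e-12).sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        log.warning("only %d positive eigenvalues; embedding in %d-D",
                    n_pos, k_eff)
    if k_eff == 0:
        coords = np.zeros((n, 1))
        k_eff = 1
    else:
        coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
    total = float(np.abs(evals).sum())
    kept = float(evals[:k_eff].clip(min=0).sum())
    strain = 0.0 if total == 0 else 1.0 - kept / total
    emb = Embedding(labels=list(dm.labels), coordinates=coords,
                    eigenvalues=evals, strain=strain)
    if refine:
        emb = _smacof(dm, emb, max_iter=max_iter, tol=tol)
    return emb


def _smacof(dm: DistanceMatrix, emb: Embedding, max_iter: int,
            tol: float) -> Embedding:
    """Raw-stress majorisation from the classical start (Guttman updates)."""
    d = dm.d
    n = dm.size
    x = emb.coordinates.copy()

    def stress_of(x):
        dist = _pairwise(x)
        iu = np.triu_indices(n, 1)
        return float(((d[iu] - dist[iu]) ** 2).sum())

    def _pairwise(x):
        diff = x[:, None, :] - x[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=-1))

    prev = stress_of(x)
    for _ in range(max_iter):
        dist = _pairwise(x)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 1e-12, d / dist, 0.0)
        bmat = -ratio
        np.fill_diagonal(bmat, 0.0)
        np.fill_diagonal(bmat, -bmat.sum(axis=1))
        x = bmat @ x / n
        x -= x.mean(axis=0)
        cur = stress_of(x)
        if prev - cur < tol:
            prev = cur
            break
        prev = cur
    return Embedding(labels=emb.labels, coordinates=x,
                     eigenvalues=emb.eigenvalues, strain=emb.strain,
                     stress=prev)


# ---------------------------------------------------------------------------
# descriptive grouping


def cluster_report(obj, groups: dict[str, str] | None = None) -> str:
    """Describe an embedding (quadrant grouping) or a tree (clade list)."""
    lines: list[str] = []
    if isinstance(obj, Embedding):
        lines.append(f"{len(obj.labels)} populations embedded in "
                     f"{obj.k}-D (strain {obj.strain:.4f})")
        quadrants: dict[tuple, list[str]] = {}
        for lab in obj.labels:
            xy = obj.coords_of(lab)
            key = tuple(np.sign(xy[:2]).astype(int))
            quadrants.setdefault(key, []).append(lab)
        names = {(1, 1): "upper right", (-1, 1): "upper left",
                 (-1, -1): "lower left", (1, -1): "lower right"}
        for key, labs in sorted(quadrants.items()):
            where = names.get(key, f"quadrant {key}")
            lines.append(f"  {where}: {', '.join(labs)}")
    elif isinstance(obj, TreeNode):
        leaves = [t.name for t in obj.tips()]
        lines.append(f"tree over {len(leaves)} taxa")
        for node in obj.non_tips():
            clade = sorted(t.name for t in node.tips())
            if 1 < len(clade) < len(leaves):
                lines.append("  clade: " + ", ".join(clade))
    else:
        raise TypeError("expected an Embedding or a TreeNode")
    if groups:
        by_group: dict[str, list[str]] = {}
        for lab, grp in groups.items():
            by_group.setdefault(grp, []).append(lab)
        for grp, labs in sorted(by_group.items()):
            lines.append(f"  group {grp}: {', '.join(sorted(labs))}")
    return "\n".join(lines)
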