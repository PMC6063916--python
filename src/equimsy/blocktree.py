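"""Supermatrix phylogeny from high-mappability blocks.

The multi-sample call tables are reduced to the well-behaved fraction of
the reference: fixed 1 kbp blocks whose mean k-mer mappability meets a
cutoff (0.9 by default).  Per sample, called positions contribute their
called base and uncalled positions contribute N; the blocks concatenate
into a supermatrix.  Distances use pairwise deletion (sites with N in
either row are excluded per pair) under a p-distance or Jukes-Cantor
model, and the tree is built by canonical Saitou-Nei neighbor joining with
deterministic lexicographic tie-breaking.  NJ stands in for a full ML
search: on additive distances it recovers the generating topology exactly,
which is what the split-level comparisons downstream need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from ._seq import N, GenomeSequence, decode
from .popblocks import MappabilityTrack, SampleCalls, block_mean_mappability

__all__ = [
    "Supermatrix",
    "PhyloTree",
    "select_blocks",
    "build_supermatrix",
    "pairwise_distances",
    "nj_tree",
]


def select_blocks(track: MappabilityTrack, block: int = 1000,
                  min_map: float = 0.9) -> list[tuple[int, int]]:
    """Fixed-width blocks whose mean mappability is >= ``min_map`` (inclusive)."""
    means = block_mean_mappability(track, block)
    L = track.ref_length
    out = []
    for b, m in enumerate(means):
        if not np.isnan(m) and m >= min_map:
            out.append((b * block, min((b + 1) * block, L)))
    return out


@dataclass
class Supermatrix:
    """Per-sample concatenated sequences over selected blocks (N = missing)."""

    samples: list[str]
    matrix: np.ndarray  # (n_samples, total_length) uint8 codes
    blocks: list[tuple[int, int]]

    def row(self, sample: str) -> str:
        return decode(self.matrix[self.samples.index(sample)])

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def all_missing_samples(self) -> list[str]:
        return [s for s, r in zip(self.samples, self.matrix) if bool(np.all(r == N))]


def build_supermatrix(calls: list[SampleCalls], reference: GenomeSequence,
                      blocks: list[tuple[int, int]]) -> Supermatrix:
    """Concatenate called bases over the selected blocks for every sample."""
    if not blocks:
        raise ValueError("empty block list")
    if len(calls) < 3:
        raise ValueError("need >= 3 samples for a supermatrix phylogeny")
    samples = [c.sample for c in calls]
    cols = np.concatenate([np.arange(a, b) for a, b in blocks])
    rows = []
    for c in calls:
        row = np.where(c.called[cols], c.base[cols], np.uint8(N)).astype(np.uint8)
        rows.append(row)
    return Supermatrix(samples=samples, matrix=np.stack(rows), blocks=list(blocks))


def pairwise_distances(sm: Supermatrix, model: str = "p-distance") -> np.ndarray:
    """Symmetric distance matrix with pairwise deletion of missing sites.

    ``model`` is "p-distance" or "jc" (Jukes-Cantor, d = -3/4 ln(1-4p/3)).
    Raises on a pair with zero comparable sites, and on JC saturation
    (p >= 0.75).
    """
    if model not in ("p-distance", "jc"):
        raise ValueError(f"unknown model {model!r}")
    n = len(sm.samples)
    if n < 2:
        raise ValueError("need >= 2 samples")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sm.matrix[i], sm.matrix[j]
            valid = (a < 4) & (b < 4)
            n_valid = int(valid.sum())
            if n_valid == 0:
                raise ValueError(
                    f"no comparable sites between {sm.samples[i]} and {sm.samples[j]}")
            p = float(np.mean(a[valid] != b[valid]))
            if model == "jc":
                if p >= 0.75:
                    raise ValueError(
                        f"JC distance undefined (p={p:.3f} >= 0.75) between "
                        f"{sm.samples[i]} and {sm.samples[j]}")
                d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            else:
                d = p
            D[i, j] = D[j, i] = d
    return D


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "children", "rep")

    def __init__(self, label: str | None, children=None, rep: str = ""):
        self.label = label
        self.children: list[tuple[_Node, float]] = children or []
        self.rep = rep  # smallest descendant tip label, for deterministic ties


@dataclass
class PhyloTree:
    """An unrooted binary tree over sample tips.

    ``newick`` is the canonical serialization (children ordered by smallest
    descendant tip label, branch lengths to 6 significant digits);
    ``negatives_clamped`` flags NJ branch lengths clamped up to zero.
    """

    newick: str
    tips: list[str]
    negatives_clamped: bool = False

    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None,
                    ) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick, schema="newick",
                                 taxon_namespace=taxon_namespace)

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-or-lexic side's tip set."""
        tree = self.to_dendropy()
        all_tips = frozenset(self.tips)
        out = set()
        for node in tree.preorder_internal_node_iter():
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 1 < len(side) < len(all_tips) - 1:
                other = all_tips - side
                out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out


def _fmt_bl(x: float) -> str:
    return f"{x:.6g}"


def _newick(node: _Node, bl: float | None = None) -> str:
    if node.children:
        kids = sorted(node.children, key=lambda cb: cb[0].rep)
        inner = ",".join(_newick(c, b) for c, b in kids)
        s = f"({inner})"
    else:
        s = node.label
    return s if bl is None else f"{s}:{_fmt_bl(bl)}"


def nj_tree(D: np.ndarray, labels: list[str]) -> PhyloTree:
    """Canonical neighbor joining (Saitou-Nei Q criterion).

    Ties in the Q criterion break deterministically by the lexicographic
    order of the joined clusters' smallest tip labels.  Negative branch
    lengths are clamped to zero and flagged.  Requires a complete symmetric
    matrix with n >= 3.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix / label mismatch")
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if np.isnan(D).any():
        raise ValueError("undefined entries in distance matrix")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix not symmetric")

    nodes = [_Node(lbl, rep=lbl) for lbl in labels]
    active = list(range(n))
    Dw = D.copy()
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    next_idx = n
    # grow matrix in place by appending rows for joined nodes
    size = 2 * n
    M = np.zeros((size, size))
    M[:n, :n] = Dw

    while len(active) > 3:
        m = len(active)
        r = {i: sum(M[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for bj in range(ai + 1, m):
                i, j = active[ai], active[bj]
                q = (m - 2) * M[i, j] - r[i] - r[j]
                key = tuple(sorted((nodes[i].rep, nodes[j].rep)))
                if best is None or q < best[0] - 1e-12 or (
                        abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        li = 0.5 * M[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = M[i, j] - li
        li, lj = clamp(li), clamp(lj)
        new = _Node(None, children=[(nodes[i], li), (nodes[j], lj)],
                    rep=min(nodes[i].rep, nodes[j].rep))
        u = next_idx
        next_idx += 1
        nodes.append(new)
        for k in active:
            if k in (i, j):
                continue
            M[u, k] = M[k, u] = 0.5 * (M[i, k] + M[j, k] - M[i, j])
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = clamp(0.5 * (M[i, j] + M[i, k] - M[j, k]))
    lj = clamp(0.5 * (M[i, j] + M[j, k] - M[i, k]))
    lk = clamp(0.5 * (M[i, k] + M[j, k] - M[i, j]))
    root = _Node(None, children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)],
                 rep=min(nodes[x].rep for x in (i, j, k)))
    newick = _newick(root) + ";"
    return PhyloTree(newick=newick, tips=sorted(labels), negatives_clamped=clamped)
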