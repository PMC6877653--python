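"""Identity distances and neighbor-joining trees for homolog relatedness.

A desk-scale relatedness analysis: pairwise identity distances over an
existing alignment and a neighbor-joining (NJ) tree, sufficient to test
whether taxonomic groups fall into separate clusters. Bayesian or
maximum-likelihood inference is intentionally out of scope.
"""

from __future__ import annotations

import io
import warnings
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from epiconserve.io_core import ValidationError

GAP_CHARS = frozenset("-.")


def _as_rows(sequences) -> tuple[list[str], list[str]]:
    if isinstance(sequences, Mapping):
        pairs = list(sequences.items())
    else:
        pairs = [(str(i), s) for i, s in sequences]
    ids = [p[0] for p in pairs]
    seqs = [str(p[1]).upper() for p in pairs]
    if len(set(len(s) for s in seqs)) > 1:
        raise ValidationError("ragged alignment")
    return ids, seqs


def pairwise_identity_distance(sequences) -> DistanceMatrix:
    """Identity distances d = 1 - matches/compared over mutually ungapped columns.

    Columns with a gap in either sequence are ignored (pairwise
    deletion). A pair with no comparable columns is an error.
    """
    ids, seqs = _as_rows(sequences)
    if len(ids) < 2:
        raise ValidationError("need at least 2 sequences")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            compared = matches = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in GAP_CHARS or b in GAP_CHARS:
                    continue
                compared += 1
                if a == b:
                    matches += 1
            if compared == 0:
                raise ValidationError(
                    f"sequences {ids[i]!r} and {ids[j]!r} share no ungapped columns"
                )
            d[i, j] = d[j, i] = 1.0 - matches / compared
    return DistanceMatrix(d, ids)


def _coerce_distance_matrix(dist) -> DistanceMatrix:
    if isinstance(dist, DistanceMatrix):
        return dist
    try:
        ids, arr = dist
        return DistanceMatrix(np.asarray(arr, dtype=float), list(ids))
    except Exception as exc:  # asymmetric / non-hollow / wrong shape
        raise ValidationError(f"invalid distance matrix: {exc}") from exc


def neighbor_joining(dist) -> str:
    """Neighbor-joining tree from a distance matrix, returned as Newick.

    Standard NJ agglomeration with deterministic tie-breaking (the
    lexicographically smallest active-node index pair wins). Negative
    branch lengths are clamped to zero with a warning. The tree is
    unrooted, written with a trifurcating root.
    """
    dm = _coerce_distance_matrix(dist)
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")

    def branch(length: float) -> float:
        if length < -1e-12:
            warnings.warn(
                f"negative NJ branch length {length:.6g} clamped to 0", stacklevel=3
            )
            return 0.0
        return max(length, 0.0)

    d = dm.data.astype(float).copy()
    nodes = list(ids)  # newick fragment per active node
    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        q[np.tril_indices(n)] = np.inf
        i, j = np.unravel_index(np.argmin(q), q.shape)  # first min: smallest (i, j)
        li = branch(d[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2)))
        lj = branch(d[i, j] - (d[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))))
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d_new = np.zeros((len(keep) + 1, len(keep) + 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = np.maximum(dk[keep], 0.0)
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]
    # final three-way join via the three-point formulas
    dxy, dxz, dyz = d[0, 1], d[0, 2], d[1, 2]
    lx = branch((dxy + dxz - dyz) / 2)
    ly = branch((dxy + dyz - dxz) / 2)
    lz = branch((dxz + dyz - dxy) / 2)
    return f"({nodes[0]}:{lx:.10g},{nodes[1]}:{ly:.10g},{nodes[2]}:{lz:.10g});"


def _tip_sets(tree: TreeNode) -> list[frozenset[str]]:
    return [
        frozenset(t.name for t in node.tips())
        for node in tree.traverse(include_self=False)
        if not node.is_tip()
    ]


def monophyly_check(tree, grouping: Mapping[str, str]) -> dict[str, bool]:
    """Whether each group forms its own cluster in the (unrooted) tree.

    A group is monophyletic when some edge bipartition separates exactly
    that group's taxa from everything else. ``tree`` may be a Newick
    string or an ``skbio.TreeNode``. Every tree tip must appear in
    ``grouping`` and vice versa.
    """
    if isinstance(tree, str):
        tree = TreeNode.read(io.StringIO(tree))
    tips = frozenset(t.name for t in tree.tips())
    unknown = tips - set(grouping)
    if unknown:
        raise ValidationError(f"tree tips without group labels: {sorted(unknown)}")
    missing = set(grouping) - tips
    if missing:
        raise ValidationError(f"taxa not in the tree: {sorted(missing)}")
    clades = _tip_sets(tree)
    result = {}
    for group in sorted(set(grouping.values())):
        members = frozenset(t for t, g in grouping.items() if g == group)
        if len(members) <= 1 or members == tips:
            result[group] = True
            continue
        complement = tips - members
        result[group] = any(s == members or s == complement for s in clades)
    return result
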