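"""Distance-based genealogies: JC/K2P matrices, neighbor-joining, bootstrap.

Neighbor joining uses the standard Q-criterion agglomeration with a
documented tie rule (smallest (i, j) index pair), so topologies are
deterministic; negative branch lengths are clamped to zero and noted.
Bootstrap supports are percentages of column-resampled replicates whose
neighbor-joining tree contains each internal bipartition of the
full-data tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from exaptscan.dating import (
    MultipleAlignment,
    UndefinedDistanceError,
    jc_distance,
    k2p_distance,
    p_distance,
    ts_tv_fractions,
)


@dataclass
class DistanceMatrix:
    names: list[str]
    matrix: np.ndarray
    model: str = "JC"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.names), len(self.names)):
            raise ValueError("matrix shape does not match the name list")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        self.matrix = m


@dataclass
class TreeNode:
    name: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree stored with a trifurcating root."""

    root: TreeNode
    names: list[str]
    supports: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def bipartitions(self) -> set[frozenset]:
        """Internal-edge bipartitions, canonicalized to the side without names[0]."""
        all_names = set(self.names)
        out = set()

        def walk(node: TreeNode):
            for child, _ in node.children:
                side = frozenset(child.leaves())
                if 2 <= len(side) <= len(all_names) - 2:
                    if self.names[0] in side:
                        side = frozenset(all_names - side)
                    out.add(side)
                walk(child)

        walk(self.root)
        return out

    def newick(self, with_supports: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if not node.children:
                return node.name
            inner = ",".join(
                f"{fmt(child)}:{length:.6g}" for child, length in node.children
            )
            label = ""
            if with_supports and self.supports:
                side = frozenset(node.leaves())
                if self.names and self.names[0] in side:
                    side = frozenset(set(self.names) - side)
                if side in self.supports:
                    label = f"{self.supports[side]:.0f}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"


def distance_matrix(msa: MultipleAlignment, model: str = "JC") -> DistanceMatrix:
    """Pairwise corrected distances under pairwise gap deletion.

    A saturated pair raises an error naming the pair.
    """
    if len(msa.members) < 3:
        raise ValueError("need at least three aligned members")
    names = msa.names()
    seqs = msa.sequences()
    n = len(seqs)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                if model == "JC":
                    p, _ = p_distance(seqs[i], seqs[j])
                    d = jc_distance(p)
                elif model == "K2P":
                    P, Q, _ = ts_tv_fractions(seqs[i], seqs[j])
                    d = k2p_distance(P, Q)
                else:
                    raise ValueError(f"unknown model {model!r}")
            except UndefinedDistanceError as err:
                raise UndefinedDistanceError(
                    f"saturated pair ({names[i]}, {names[j]}): {err}"
                ) from err
            m[i, j] = m[j, i] = d
    return DistanceMatrix(names=names, matrix=m, model=model)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Standard neighbor joining; additive matrices are recovered exactly.

    Ties in the Q criterion go to the smallest (i, j) pair; negative
    branch lengths are clamped to zero with a note on the tree.
    """
    n = len(dm.names)
    if n < 3:
        raise ValueError("need at least three taxa")
    notes: list[str] = []

    def clamp(x: float, label: str) -> float:
        if x < 0:
            notes.append(f"negative branch length {x:.4g} at {label} clamped to 0")
            return 0.0
        return x

    nodes: list[TreeNode] = [TreeNode(name=nm) for nm in dm.names]
    D = dm.matrix.copy()
    idx = list(range(n))  # active rows of D
    labels = list(dm.names)

    while len(idx) > 3:
        m = len(idx)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        ia, ib = idx[a], idx[b]
        dij = sub[a, b]
        la = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lb = dij - la
        la = clamp(la, labels[ia])
        lb = clamp(lb, labels[ib])
        new = TreeNode(children=[(nodes[ia], la), (nodes[ib], lb)])
        # distances from the new node to the remaining taxa
        knew = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for c in range(m):
            if c in (a, b):
                continue
            ic = idx[c]
            D[knew, ic] = D[ic, knew] = 0.5 * (sub[a, c] + sub[b, c] - dij)
        nodes.append(new)
        labels.append(f"node{knew}")
        idx = [i for i in idx if i not in (ia, ib)] + [knew]

    ia, ib, ic = idx
    dab, dac, dbc = D[ia, ib], D[ia, ic], D[ib, ic]
    la = clamp(0.5 * (dab + dac - dbc), labels[ia])
    lb = clamp(0.5 * (dab + dbc - dac), labels[ib])
    lc = clamp(0.5 * (dac + dbc - dab), labels[ic])
    root = TreeNode(children=[(nodes[ia], la), (nodes[ib], lb), (nodes[ic], lc)])
    return Tree(root=root, names=list(dm.names), notes=notes)


def _resample(msa: MultipleAlignment, rng: np.random.Generator) -> MultipleAlignment:
    cols = rng.integers(0, msa.length, msa.length)
    members = [
        (name, "".join(seq[c] for c in cols)) for name, seq in msa.members
    ]
    return MultipleAlignment(members=members)


def bootstrap(
    msa: MultipleAlignment,
    n_reps: int = 1000,
    model: str = "JC",
    seed: int = 0,
) -> Tree:
    """Nonparametric bootstrap supports mapped onto the full-data NJ tree.

    Replicates with a saturated pair are dropped and counted; supports
    are percentages over the successful replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = neighbor_joining(distance_matrix(msa, model))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    ok = 0
    dropped = 0
    for _ in range(n_reps):
        rep = _resample(msa, rng)
        try:
            rep_tree = neighbor_joining(distance_matrix(rep, model))
        except UndefinedDistanceError:
            dropped += 1
            continue
        ok += 1
        found = rep_tree.bipartitions()
        for bp in target:
            if bp in found:
                counts[bp] += 1
    if dropped:
        tree.notes.append(f"{dropped} bootstrap replicates dropped (saturation)")
    denom = max(ok, 1)
    tree.supports = {bp: 100.0 * c / denom for bp, c in counts.items()}
    return tree


def matrix_to_phylip(dm: DistanceMatrix, path) -> None:
    lines = [f"{len(dm.names)}"]
    for name, row in zip(dm.names, dm.matrix):
        vals = " ".join(f"{v:.6f}" for v in row)
        lines.append(f"{name:<10s} {vals}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
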