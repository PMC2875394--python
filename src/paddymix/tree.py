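"""Allele-sharing distances and neighbor-joining trees.

The distance between two inbred accessions is the proportion of mismatching
calls over the SNPs observed in both (pairwise deletion of missing data).
Neighbor joining (Saitou–Nei) then builds an unrooted binary tree; ties in
the Q-criterion are broken by the smallest (i, j) index pair so the result
is deterministic, and negative branch-length estimates are clamped to zero
with the clamped amount transferred to the sibling edge so path lengths are
preserved. Newick serialization orders children lexicographically by their
smallest leaf label, giving byte-reproducible output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .panel import MISSING, GenotypePanel


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix is {self.d.shape} for {n} ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (self.d < 0).any():
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal is not zero")


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; `length` is the branch to the parent."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def min_leaf_name(self) -> str:
        return min(lf.name or "" for lf in self.leaves())


@dataclass
class PhyloTree:
    """Unrooted binary tree represented with a trifurcating root node."""

    root: TreeNode

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def leaf_names(self) -> list[str]:
        return sorted(lf.name or "" for lf in self.root.leaves())

    def path_lengths(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path-length matrix (ids sorted lexicographically)."""
        names = self.leaf_names()
        index = {nm: i for i, nm in enumerate(names)}
        n = len(names)
        D = np.zeros((n, n))

        def walk(node: TreeNode, depth: float, acc: dict[int, float]) -> None:
            if node.is_leaf():
                acc[index[node.name or ""]] = depth
                return
            for c in node.children:
                walk(c, depth + c.length, acc)

        # Distances via the (arbitrary) root: d(a,b) = da + db - 2*lca depth.
        def pairs(node: TreeNode, depth: float) -> dict[int, float]:
            if node.is_leaf():
                return {index[node.name or ""]: depth}
            below: list[dict[int, float]] = []
            for c in node.children:
                below.append(pairs(c, depth + c.length))
            for x in range(len(below)):
                for y in range(x + 1, len(below)):
                    for a, da in below[x].items():
                        for b, db in below[y].items():
                            D[a, b] = D[b, a] = da + db - 2 * depth
            merged: dict[int, float] = {}
            for m in below:
                merged.update(m)
            return merged

        pairs(self.root, 0.0)
        return names, D


def allele_sharing_distance(panel: GenotypePanel) -> DistanceMatrix:
    """Proportion of mismatching calls over jointly observed SNPs."""
    calls = panel.calls
    obs = (calls != MISSING).astype(np.float64)
    # shared[i,j] = number of SNPs observed in both
    shared = obs @ obs.T
    if (shared == 0).any():
        i, j = np.argwhere(shared == 0)[0]
        raise ValueError(
            f"accessions {panel.accession_ids[int(i)]!r} and "
            f"{panel.accession_ids[int(j)]!r} share no non-missing SNP"
        )
    g1 = ((calls == 1) & (calls != MISSING)).astype(np.float64)
    g0 = ((calls == 0)).astype(np.float64)
    mismatch = g1 @ g0.T + g0 @ g1.T
    d = mismatch / shared
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(panel.accession_ids), d=d)


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    At each step the pair (i, j) minimizing
    Q(i,j) = (m - 2) d(i,j) - r_i - r_j is joined (smallest index pair on
    ties); branch lengths use the standard formulas, with negative estimates
    clamped to 0 and the deficit moved to the sibling branch.
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = D.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in D.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        qmat = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(qmat, np.inf)
        # smallest (i, j) index pair on ties
        flat = np.argmin(qmat)
        ai, aj = divmod(int(flat), m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        li = 0.5 * sub[ai, aj] + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = sub[ai, aj] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        # distances from the new node
        dnew = 0.5 * (d[i, active] + d[j, active] - d[i, j])
        new_idx = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[new_idx, active] = dnew
        d[active, new_idx] = dnew
        d[new_idx, new_idx] = 0.0
        active = [a for a in active if a not in (i, j)] + [new_idx]

    # final three taxa joined at the trifurcating root
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    li, lj, lk = _clamp_triple(li, lj, lk)
    nodes[i].length = li
    nodes[j].length = lj
    nodes[k].length = lk
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root=root)


def _clamp_pair(a: float, b: float) -> tuple[float, float]:
    if a < 0:
        b += a
        a = 0.0
    if b < 0:
        a += b
        b = 0.0
    return max(a, 0.0), max(b, 0.0)


def _clamp_triple(a: float, b: float, c: float) -> tuple[float, float, float]:
    vals = [a, b, c]
    for x in range(3):
        if vals[x] < 0:
            deficit = vals[x]
            vals[x] = 0.0
            others = [y for y in range(3) if y != x]
            for y in others:
                vals[y] += deficit / 2
    return tuple(max(v, 0.0) for v in vals)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Newick

_RESERVED = re.compile(r"[\s()\[\]:;,']")


def _quote(name: str) -> str:
    if _RESERVED.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: PhyloTree, precision: int = 10) -> str:
    """Newick string with branch lengths; children ordered by their
    lexicographically smallest leaf label."""

    def fmt(x: float) -> str:
        return f"{x:.{precision}g}"

    def render(node: TreeNode, with_length: bool) -> str:
        if node.is_leaf():
            s = _quote(node.name or "")
        else:
            kids = sorted(node.children, key=lambda c: c.min_leaf_name())
            s = "(" + ",".join(render(c, True) for c in kids) + ")"
            if node.name:
                s += _quote(node.name)
        if with_length:
            s += f":{fmt(node.length)}"
        return s

    return render(tree.root, False) + ";"


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


def parse_newick(text: str) -> PhyloTree:
    """Minimal Newick parser (labels, quoted labels, branch lengths)."""
    pos = 0
    text = text.strip()

    def error(msg: str):
        raise ValueError(f"newick parse error at offset {pos}: {msg}")

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if text[pos] == ",":
                    pos += 1
                elif text[pos] == ")":
                    pos += 1
                    break
                else:
                    error("expected ',' or ')'")
        node.name = parse_label()
        if pos < len(text) and text[pos] == ":":
            pos += 1
            node.length = parse_number()
        return node

    def parse_label() -> str | None:
        nonlocal pos
        if pos < len(text) and text[pos] == "'":
            pos += 1
            out = []
            while True:
                if text[pos] == "'":
                    if pos + 1 < len(text) and text[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                    else:
                        pos += 1
                        break
                else:
                    out.append(text[pos])
                    pos += 1
            return "".join(out)
        m = re.match(r"[^\s()\[\]:;,]+", text[pos:])
        if m:
            pos += m.end()
            return m.group(0)
        return None

    def parse_number() -> float:
        nonlocal pos
        m = re.match(r"[-+0-9.eE]+", text[pos:])
        if not m:
            error("expected branch length")
        pos += m.end()
        return float(m.group(0))

    root = parse_node()
    if pos >= len(text) or text[pos] != ";":
        error("expected ';'")
    return PhyloTree(root=root)


def write_distance_tsv(D: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(D.ids) + "\n")
        for i, name in enumerate(D.ids):
            fh.write(name + "\t" + "\t".join(f"{x:.10g}" for x in D.d[i]) + "\n")
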