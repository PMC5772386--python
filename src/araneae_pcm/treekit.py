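"""Rooted phylogenetic trees, Newick I/O and Brownian covariance matrices.

The tree model is deliberately small: a :class:`PhyloTree` is a rooted tree
whose non-root nodes each carry an optional branch length.  Branch lengths
may be *absent* (``None``), which is distinct from zero -- a tree read from
a topology-only Newick string keeps its lengths absent until a scheme
(:func:`set_unit_branch_lengths` or :func:`grafen_branch_lengths`) assigns
them.

Under Brownian motion a trait's covariance between two tips equals the
shared root-to-MRCA path length, collected for all tip pairs by
:func:`vcv_matrix`.  Pagel's lambda rescales the off-diagonal of that
matrix (:func:`lambda_transform`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "NewickError", "TreeError", "Node", "PhyloTree", "CovarianceMatrix",
    "parse_newick", "write_newick", "set_unit_branch_lengths",
    "grafen_branch_lengths", "vcv_matrix", "lambda_transform",
]


class NewickError(ValueError):
    """Malformed Newick input; carries the offending character position."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class TreeError(ValueError):
    """Structurally invalid tree or invalid operation on a tree."""


@dataclass
class Node:
    label: Optional[str] = None
    length: Optional[float] = None
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.label or '?'} {kind} len={self.length}>"


class PhyloTree:
    """A rooted tree with uniquely labelled tips.

    Nodes are shared, mutable objects; operations that change branch
    lengths return a modified *copy* so fixtures stay pristine.
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction / validation ------------------------------------

    def _validate(self) -> None:
        labels = [n.label for n in self.tips()]
        if any(not lab for lab in labels):
            raise TreeError("every tip must carry a non-empty label")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
        for node in self.preorder():
            for child in node.children:
                if child.parent is not node:
                    raise TreeError("broken parent link")
                if child.length is not None and child.length < 0:
                    raise TreeError(f"negative branch length on {child.label!r}")

    def copy(self) -> "PhyloTree":
        def clone(n: Node, parent: Optional[Node]) -> Node:
            m = Node(label=n.label, length=n.length, parent=parent)
            m.children = [clone(c, m) for c in n.children]
            return m

        return PhyloTree(clone(self.root, None))

    # -- traversal -----------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        yield from reversed(out)

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]  # type: ignore[misc]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def has_branch_lengths(self) -> bool:
        return all(n.length is not None for n in self.preorder() if n is not self.root)

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label (lengths must be present)."""
        out: dict[str, float] = {}

        def walk(node: Node, acc: float) -> None:
            here = acc + (node.length or 0.0 if node is not self.root else 0.0)
            if node.is_tip:
                out[node.label] = here  # type: ignore[index]
            for c in node.children:
                walk(c, here)

        walk(self.root, 0.0)
        return out

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = list(self.depths().values())
        return max(d) - min(d) <= tol

    def to_table(self) -> list[tuple[str, str, Optional[float]]]:
        """(parent, child, length) rows for debugging / TSV export."""
        ids: dict[int, str] = {}
        counter = 0
        for node in self.preorder():
            if node.is_tip:
                ids[id(node)] = node.label  # type: ignore[assignment]
            else:
                ids[id(node)] = f"node{counter}"
                counter += 1
        rows = []
        for node in self.preorder():
            for child in node.children:
                rows.append((ids[id(node)], ids[id(child)], child.length))
        return rows

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {self.n_tips} tips>"


# ---------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted Newick tree.

    Branch lengths are optional and recorded as absent (``None``) when not
    written.  Comment lines starting with ``#`` are ignored, so fixture
    files may carry provenance headers.  Errors report the character
    position of the offending token.
    """
    lines = [ln for ln in text.splitlines() if not ln.lstrip().startswith("#")]
    s = "".join(lines).strip()
    if not s:
        raise NewickError("empty Newick input")
    if not s.endswith(";"):
        raise NewickError("missing trailing semicolon", len(s))
    s = s[:-1]

    pos = 0

    def error(msg: str) -> NewickError:
        return NewickError(msg, pos)

    def parse_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            end = s.find("'", pos + 1)
            if end < 0:
                raise error("unterminated quoted label")
            lab = s[pos + 1 : end]
            pos = end + 1
            return lab
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    def parse_length() -> Optional[float]:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and (s[pos].isdigit() or s[pos] in ".+-eE"):
                pos += 1
            try:
                return float(s[start:pos])
            except ValueError:
                raise error(f"bad branch length {s[start:pos]!r}")
        return None

    def parse_clade() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                child = parse_clade()
                child.parent = node
                node.children.append(child)
                if pos >= len(s):
                    raise error("unbalanced parentheses: unexpected end of input")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {s[pos]!r}")
        label = parse_label()
        node.label = label or None
        node.length = parse_length()
        return node

    root = parse_clade()
    if pos != len(s):
        raise NewickError(f"trailing characters after tree: {s[pos:]!r}", pos)
    if root.is_tip and root.label is None:
        raise NewickError("empty tree")
    try:
        return PhyloTree(root)
    except TreeError as exc:
        raise NewickError(str(exc)) from exc


def write_newick(tree: PhyloTree, precision: int = 12) -> str:
    def fmt(node: Node) -> str:
        if node.is_tip:
            core = node.label or ""
        else:
            core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                core += node.label
        if node.length is not None and node.parent is not None:
            core += f":{node.length:.{precision}g}"
        return core

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------
# Branch-length schemes
# ---------------------------------------------------------------------

def set_unit_branch_lengths(tree: PhyloTree) -> PhyloTree:
    """Return a copy with every edge length set to 1 (the study's first
    phylogram).  Idempotent; topology unchanged."""
    out = tree.copy()
    for node in out.preorder():
        if node is not out.root:
            node.length = 1.0
    return out


def grafen_branch_lengths(tree: PhyloTree, power: float = 1.0) -> PhyloTree:
    """Grafen's topology-only ultrametricization.

    Each node is placed at height ``((n_descendant_tips - 1) ** power) /
    ((n_tips - 1) ** power)``; tips sit at height 0, the root at height 1,
    and edge lengths are parent height minus child height.  The result is
    ultrametric with depth 1.  Polytomies are handled by the same
    clade-size formula.
    """
    if power <= 0:
        raise ValueError("power must be positive")
    n = tree.n_tips
    if n < 2:
        raise TreeError("Grafen heights need at least 2 tips")
    out = tree.copy()
    clade_sizes: dict[int, int] = {}
    for node in out.postorder():
        clade_sizes[id(node)] = 1 if node.is_tip else sum(
            clade_sizes[id(c)] for c in node.children
        )
    denom = float(n - 1) ** power
    heights = {
        id(node): ((clade_sizes[id(node)] - 1) ** power) / denom
        for node in out.preorder()
    }
    for node in out.preorder():
        if node is not out.root:
            node.length = heights[id(node.parent)] - heights[id(node)]
    return out


# ---------------------------------------------------------------------
# Covariance matrices
# ---------------------------------------------------------------------

@dataclass
class CovarianceMatrix:
    """Brownian-motion covariance implied by a tree.

    ``matrix[i, j]`` is the root-to-MRCA path length shared by tips
    ``labels[i]`` and ``labels[j]``; the diagonal holds root-to-tip
    distances.
    """

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")

    def reorder(self, labels: list[str]) -> "CovarianceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return CovarianceMatrix(list(labels), self.matrix[np.ix_(idx, idx)])

    def __getitem__(self, key: tuple[str, str]) -> float:
        i = self.labels.index(key[0])
        j = self.labels.index(key[1])
        return float(self.matrix[i, j])


def vcv_matrix(tree: PhyloTree) -> CovarianceMatrix:
    """Shared-path-length (Brownian) covariance matrix of the tips."""
    missing = [
        (n.parent.label or "internal", n.label or "internal")
        for n in tree.preorder()
        if n is not tree.root and n.length is None
    ]
    if missing:
        raise TreeError(f"missing branch lengths on edges: {missing}")

    tips = tree.tips()
    labels = [t.label for t in tips]
    index = {id(t): i for i, t in enumerate(tips)}
    n = len(tips)
    V = np.zeros((n, n))

    # V(i, j) is the depth of the MRCA of i and j: compute node depths,
    # then for every internal node fill the tip pairs whose MRCA it is
    # (pairs drawn from distinct child subtrees).
    depths: dict[int, float] = {}

    def set_depths(node: Node, acc: float) -> None:
        if node is not tree.root:
            acc += node.length  # type: ignore[operator]
        depths[id(node)] = acc
        for c in node.children:
            set_depths(c, acc)

    set_depths(tree.root, 0.0)

    def fill(node: Node) -> list[int]:
        if node.is_tip:
            i = index[id(node)]
            V[i, i] = depths[id(node)]
            return [i]
        groups = [fill(c) for c in node.children]
        d = depths[id(node)]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        V[i, j] = V[j, i] = d
        return [i for g in groups for i in g]

    fill(tree.root)
    return CovarianceMatrix(labels, V)  # type: ignore[arg-type]


def lambda_transform(V: CovarianceMatrix, lam: float) -> CovarianceMatrix:
    """Pagel's lambda: multiply off-diagonal entries by ``lam``.

    ``lam = 1`` leaves the Brownian structure untouched; ``lam = 0``
    removes all phylogenetic covariance (star phylogeny).
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    M = V.matrix * lam
    np.fill_diagonal(M, np.diag(V.matrix))
    return CovarianceMatrix(list(V.labels), M)
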