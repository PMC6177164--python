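"""Ultrametric phylogeny handling and phylogenetic covariance matrices.

A rooted tree with branch lengths in time units induces the Brownian-motion
trait covariance matrix ``C`` whose diagonal holds root-to-tip depths and
whose off-diagonal entry for a pair of tips is the depth of their most recent
common ancestor.  Pagel's lambda rescales the off-diagonal of ``C`` and is the
single branch-length transform supported here.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Node",
    "Phylogeny",
    "VCVMatrix",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "read_newick",
    "write_newick",
    "prune_to",
    "vcv",
    "lambda_transform",
    "is_ultrametric",
]


class NewickParseError(ValueError):
    """Malformed Newick input; message names the offending position."""


class TreeValidationError(ValueError):
    """Tree violates a structural invariant (duplicate tips, bad lengths...)."""


@dataclass
class Node:
    name: str | None = None
    length: float | None = None  # edge length to parent; None for the root
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Phylogeny:
    """Rooted phylogeny with named tips and non-negative branch lengths."""

    root: Node

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def postorder(self):
        stack, out = [self.root], []
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [nd for nd in self.postorder() if nd.is_leaf]

    @property
    def tip_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}

        def walk(nd: Node, d: float) -> None:
            d += nd.length or 0.0
            if nd.is_leaf:
                depths[nd.name] = d
            for ch in nd.children:
                walk(ch, d)

        walk(self.root, 0.0)
        return depths

    def validate(self) -> None:
        names = self.tip_names
        if any(not n for n in names):
            raise TreeValidationError("every tip must carry a nonempty label")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")
        lengths = [nd.length for nd in self.postorder() if nd is not self.root]
        if any(l is None or l < 0 for l in lengths):
            raise TreeValidationError("all non-root branch lengths must be >= 0")
        if lengths and not any(l > 0 for l in lengths):
            raise TreeValidationError("at least one branch length must be > 0")
        zero_terminal = [nd.name for nd in self.leaves() if nd.length == 0]
        if zero_terminal:
            warnings.warn(
                f"zero-length terminal branches at {zero_terminal}; the "
                "covariance matrix will be singular unless lambda < 1",
                stacklevel=3,
            )

    def copy(self) -> "Phylogeny":
        def clone(nd: Node) -> Node:
            return Node(nd.name, nd.length, [clone(c) for c in nd.children])

        return Phylogeny(clone(self.root))


@dataclass
class VCVMatrix:
    """Phylogenetic variance-covariance matrix with its species ordering."""

    species_order: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.species_order)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match species_order")
        if not np.allclose(self.values, self.values.T, rtol=1e-10, atol=0):
            raise ValueError("covariance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.species_order)

    def reorder(self, species: list[str]) -> "VCVMatrix":
        idx = [self.species_order.index(s) for s in species]
        return VCVMatrix(list(species), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Newick I/O

_TOKEN = re.compile(r"\s*([(),;:]|[^\s(),;:]+)")
_COMMENT = re.compile(r"\[[^\]]*\]")


def parse_newick(text: str) -> Phylogeny:
    """Parse a standard-dialect Newick string into a :class:`Phylogeny`.

    Square-bracket (NHX-style) comments are stripped with a warning; the
    error message for malformed input names the character position.
    """
    if _COMMENT.search(text):
        warnings.warn("square-bracket comments in Newick input were stripped")
        text = _COMMENT.sub("", text)
    s = text.strip()
    if not s.endswith(";"):
        raise NewickParseError(f"missing terminal ';' at position {len(s)}")

    pos = 0

    def error(msg: str) -> NewickParseError:
        return NewickParseError(f"{msg} at position {pos}")

    def peek() -> str:
        m = _TOKEN.match(s, pos)
        return m.group(1) if m else ""

    def take() -> str:
        nonlocal pos
        m = _TOKEN.match(s, pos)
        if not m:
            raise error("unexpected end of input")
        pos = m.end()
        return m.group(1)

    def parse_clade() -> Node:
        nd = Node()
        if peek() == "(":
            take()
            nd.children.append(parse_clade())
            while peek() == ",":
                take()
                nd.children.append(parse_clade())
            if peek() != ")":
                raise error("expected ')'")
            take()
        tok = peek()
        if tok not in ("(", ")", ",", ":", ";", ""):
            nd.name = take()
        if peek() == ":":
            take()
            tok = take()
            try:
                nd.length = float(tok)
            except ValueError:
                raise error(f"invalid branch length {tok!r}") from None
        return nd

    root = parse_clade()
    if peek() != ";":
        raise error("trailing characters before ';'")
    if root.is_leaf:
        raise NewickParseError("tree must contain more than a single node")
    return Phylogeny(root)


def read_newick(path) -> Phylogeny:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read())


def _fmt_length(x: float) -> str:
    return format(x, ".12g")


def write_newick(tree: Phylogeny) -> str:
    def emit(nd: Node, with_length: bool) -> str:
        if nd.is_leaf:
            body = nd.name or ""
        else:
            body = "(" + ",".join(emit(c, True) for c in nd.children) + ")"
            if nd.name:
                body += nd.name
        if with_length and nd.length is not None:
            body += f":{_fmt_length(nd.length)}"
        return body

    return emit(tree.root, False) + ";"


# ---------------------------------------------------------------------------
# Pruning

def prune_to(tree: Phylogeny, keep) -> Phylogeny:
    """Restrict *tree* to the tip set *keep*, preserving root-to-tip depths.

    Degree-2 internal nodes created by the pruning are collapsed with their
    branch lengths summed.  A root left with a single child keeps that child
    edge so retained depths are unchanged.
    """
    keep = set(keep)
    missing = sorted(keep - set(tree.tip_names))
    if missing:
        raise TreeValidationError(f"tips not present in tree: {missing}")
    if len(keep) < 2:
        raise TreeValidationError("need at least two tips to keep")

    def rebuild(nd: Node) -> Node | None:
        if nd.is_leaf:
            if nd.name in keep:
                return Node(nd.name, nd.length)
            return None
        kids = [k for k in (rebuild(c) for c in nd.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            child = kids[0]
            if nd.length is not None:
                child.length = (child.length or 0.0) + nd.length
            return child
        return Node(nd.name, nd.length, kids)

    new_root = rebuild(tree.root)
    assert new_root is not None
    if new_root.length is not None:
        # keep the stem as a unary root so depths are preserved
        new_root = Node(None, None, [new_root])
    return Phylogeny(new_root)


# ---------------------------------------------------------------------------
# Covariance construction

def vcv(tree: Phylogeny) -> VCVMatrix:
    """Brownian-motion covariance matrix of *tree* in tip enumeration order."""
    names = tree.tip_names
    n = len(names)
    if n < 2:
        raise TreeValidationError("covariance matrix requires at least two tips")
    index = {name: i for i, name in enumerate(names)}
    C = np.zeros((n, n))

    def walk(nd: Node, depth: float) -> list[int]:
        depth += nd.length or 0.0
        if nd.is_leaf:
            i = index[nd.name]
            C[i, i] = depth
            return [i]
        groups = [walk(ch, depth) for ch in nd.children]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        C[i, j] = C[j, i] = depth
        return [i for g in groups for i in g]

    walk(tree.root, 0.0)
    return VCVMatrix(names, C)


def lambda_transform(C: VCVMatrix, lam: float) -> VCVMatrix:
    """Multiply the off-diagonal of *C* by Pagel's lambda, 0 <= lam <= 1."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    V = lam * C.values
    np.fill_diagonal(V, np.diag(C.values))
    return VCVMatrix(list(C.species_order), V)


def is_ultrametric(tree: Phylogeny, tol: float = 1e-3) -> tuple[bool, float]:
    """Whether all root-to-tip depths agree within ``tol * max_depth``.

    Returns the verdict plus the maximum pairwise depth discrepancy.
    """
    depths = np.array(list(tree.tip_depths().values()))
    spread = float(depths.max() - depths.min())
    return spread <= tol * depths.max(), spread
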