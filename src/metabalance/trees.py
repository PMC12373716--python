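"""Shape-only rooted trees: constructors, Newick I/O, and exhaustive enumeration.

Everything in this package operates on *tree shapes*, i.e. isomorphism
classes of rooted trees in which no vertex has out-degree one.  Leaf
labels and branch lengths carry no information for balance statistics and
are discarded on input.  :class:`RootedTree` instances are immutable,
children are stored in a canonical order, and two instances compare equal
exactly when they are isomorphic as unordered rooted trees.

The module also provides the special tree families used as extremal
references throughout the literature (caterpillar, fully balanced,
maximally balanced, greedy-from-the-bottom, star) and memoized exhaustive
enumeration of all shapes with a given leaf count, which serves as the
brute-force oracle for every extremal-tree claim.
"""

from __future__ import annotations

import functools
import heapq
import io
import itertools
import warnings
from enum import Enum
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "RootedTree",
    "TreeFamily",
    "NewickError",
    "UnaryCollapseWarning",
    "LEAF",
    "parse_newick",
    "to_newick",
    "make_tree",
    "caterpillar",
    "fully_balanced",
    "maximally_balanced",
    "greedy_from_bottom",
    "gfb_by_cherry_attachment",
    "star",
    "canonical_key",
    "enumerate_binary_shapes",
    "enumerate_arbitrary_shapes",
    "replace_subtree",
    "random_binary_shape",
    "random_arbitrary_shape",
    "ceil_log2",
]


class NewickError(ValueError):
    """Raised for malformed or empty Newick input."""


class UnaryCollapseWarning(UserWarning):
    """Emitted when out-degree-one vertices in input are collapsed."""


def ceil_log2(n: int) -> int:
    """Smallest h with 2**h >= n (n >= 1)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return (n - 1).bit_length()


class RootedTree:
    """An immutable rooted tree shape (unordered children, no unary vertices).

    Children are sorted canonically at construction, so structural equality
    coincides with isomorphism of unordered rooted trees and the preorder
    traversal (used for vertex handles) is deterministic.
    """

    __slots__ = ("children", "n", "height", "key", "_hash")

    children: tuple["RootedTree", ...]
    n: int
    height: int
    key: str

    def __init__(self, children: Iterable["RootedTree"] = ()):
        kids = tuple(sorted(children, key=lambda t: (t.n, t.key)))
        if len(kids) == 1:
            raise ValueError("rooted tree shapes may not contain out-degree-one vertices")
        object.__setattr__(self, "children", kids)
        if not kids:
            object.__setattr__(self, "n", 1)
            object.__setattr__(self, "height", 0)
            object.__setattr__(self, "key", "L")
        else:
            object.__setattr__(self, "n", sum(c.n for c in kids))
            object.__setattr__(self, "height", 1 + max(c.height for c in kids))
            object.__setattr__(self, "key", "(" + "".join(c.key for c in kids) + ")")
        object.__setattr__(self, "_hash", hash(self.key))

    def __setattr__(self, name, value):  # pragma: no cover - immutability guard
        raise AttributeError("RootedTree is immutable")

    # -- basic structure -------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def num_inner(self) -> int:
        """Number of inner vertices |V_ring(T)|."""
        return sum(1 for v in self.preorder() if not v.is_leaf)

    @property
    def is_binary(self) -> bool:
        return all(v.is_leaf or len(v.children) == 2 for v in self.preorder())

    def preorder(self) -> Iterator["RootedTree"]:
        """Root-first traversal; the index of a vertex in this traversal is
        its stable integer *handle* used by :func:`replace_subtree`."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def vertex(self, handle: int) -> "RootedTree":
        """Return the pending subtree rooted at the vertex with this handle."""
        for i, v in enumerate(self.preorder()):
            if i == handle:
                return v
        raise IndexError(f"vertex handle {handle} out of range (tree has "
                         f"{2 * self.n - 1 if self.is_binary else 'fewer'} vertices)")

    def num_vertices(self) -> int:
        return sum(1 for _ in self.preorder())

    def __eq__(self, other) -> bool:
        return isinstance(other, RootedTree) and self.key == other.key

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        return f"RootedTree(n={self.n}, key={self.key!r})"


#: The unique shape with a single vertex (root == leaf).
LEAF = RootedTree()


def canonical_key(tree: RootedTree) -> str:
    """Deterministic encoding; equal iff the trees are isomorphic."""
    return tree.key


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> RootedTree:
    """Parse a Newick string into a shape.

    Labels and branch lengths are discarded.  Chains of out-degree-one
    vertices (which the shape model forbids) are collapsed, with a
    :class:`UnaryCollapseWarning`.
    """
    if text is None or not text.strip():
        raise NewickError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises assorted error types
        raise NewickError(f"malformed Newick input: {exc}") from exc
    collapsed = [0]

    def convert(node) -> RootedTree:
        kids = node.child_nodes()
        if not kids:
            return LEAF
        subs = [convert(c) for c in kids]
        if len(subs) == 1:
            collapsed[0] += 1
            return subs[0]
        return RootedTree(subs)

    shape = convert(dtree.seed_node)
    if collapsed[0]:
        warnings.warn(
            f"collapsed {collapsed[0]} out-degree-one vertex/vertices in Newick input",
            UnaryCollapseWarning,
            stacklevel=2,
        )
    return shape


def to_newick(tree: RootedTree, labels: bool = True) -> str:
    """Canonical Newick output: sorted child order, leaf labels L1..Ln."""
    counter = itertools.count(1)
    out = io.StringIO()

    def write(t: RootedTree) -> None:
        if t.is_leaf:
            out.write(f"L{next(counter)}" if labels else "")
            return
        out.write("(")
        for i, c in enumerate(t.children):
            if i:
                out.write(",")
            write(c)
        out.write(")")

    write(tree)
    out.write(";")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Special tree families
# ---------------------------------------------------------------------------

class TreeFamily(str, Enum):
    caterpillar = "caterpillar"
    fully_balanced = "fully_balanced"
    maximally_balanced = "maximally_balanced"
    greedy_from_bottom = "greedy_from_bottom"
    star = "star"


_FAMILY_ALIASES = {
    "cat": TreeFamily.caterpillar,
    "fb": TreeFamily.fully_balanced,
    "mb": TreeFamily.maximally_balanced,
    "gfb": TreeFamily.greedy_from_bottom,
}


def caterpillar(n: int) -> RootedTree:
    """The unique binary tree with exactly one cherry (the most imbalanced shape)."""
    if n < 1:
        raise ValueError(f"leaf count must be >= 1, got {n}")
    t = LEAF
    for _ in range(n - 1):
        t = RootedTree((t, LEAF))
    return t


def fully_balanced(h: int) -> RootedTree:
    """The fb-tree of height h: all 2**h leaves at depth exactly h."""
    if h < 0:
        raise ValueError(f"height must be >= 0, got {h}")
    t = LEAF
    for _ in range(h):
        t = RootedTree((t, t))
    return t


def maximally_balanced(n: int) -> RootedTree:
    """The mb-tree: every inner vertex has balance value <= 1.

    Built by the recursive ceil(n/2) / floor(n/2) split.
    """
    if n < 1:
        raise ValueError(f"leaf count must be >= 1, got {n}")
    if n == 1:
        return LEAF
    left = maximally_balanced((n + 1) // 2)
    right = maximally_balanced(n // 2)
    return RootedTree((left, right))


def greedy_from_bottom(n: int) -> RootedTree:
    """The gfb-tree: repeatedly join the two trees of minimal leaf count.

    Among trees of equal minimal leaf count, the two with lexicographically
    smallest canonical keys are joined; the result is unique up to
    isomorphism (cross-checked against :func:`gfb_by_cherry_attachment`).
    """
    if n < 1:
        raise ValueError(f"leaf count must be >= 1, got {n}")
    pool: list[tuple[int, str, RootedTree]] = [(1, LEAF.key, LEAF)] * n
    heapq.heapify(pool)
    while len(pool) > 1:
        _, _, a = heapq.heappop(pool)
        _, _, b = heapq.heappop(pool)
        joined = RootedTree((a, b))
        heapq.heappush(pool, (joined.n, joined.key, joined))
    return pool[0][2]


def gfb_by_cherry_attachment(n: int) -> RootedTree:
    """gfb-tree via the alternative construction: take the fully balanced
    tree of height h_n - 1 and attach n - 2**(h_n - 1) cherries to its
    leaves from left to right."""
    if n < 1:
        raise ValueError(f"leaf count must be >= 1, got {n}")
    if n == 1:
        return LEAF
    h = ceil_log2(n)
    p = n - 2 ** (h - 1)

    def build(depth_left: int, cherries: int) -> RootedTree:
        # subtree of the fb(h-1) scaffold with `depth_left` levels below,
        # whose leftmost `cherries` leaves become cherries
        if depth_left == 0:
            return RootedTree((LEAF, LEAF)) if cherries else LEAF
        half = 2 ** (depth_left - 1)
        left = build(depth_left - 1, min(cherries, half))
        right = build(depth_left - 1, max(0, cherries - half))
        return RootedTree((left, right))

    return build(h - 1, p)


def star(n: int) -> RootedTree:
    """All n leaves attached directly to the root."""
    if n < 1:
        raise ValueError(f"leaf count must be >= 1, got {n}")
    if n == 1:
        return LEAF
    return RootedTree((LEAF,) * n)


def make_tree(family: TreeFamily | str, size: int) -> RootedTree:
    """Construct a member of a special family.

    For ``fully_balanced`` the ``size`` parameter is the *height* h >= 0;
    for every other family it is the leaf count n >= 1.
    """
    if isinstance(family, str):
        family = _FAMILY_ALIASES.get(family, None) or TreeFamily(family)
    builders = {
        TreeFamily.caterpillar: caterpillar,
        TreeFamily.fully_balanced: fully_balanced,
        TreeFamily.maximally_balanced: maximally_balanced,
        TreeFamily.greedy_from_bottom: greedy_from_bottom,
        TreeFamily.star: star,
    }
    return builders[family](size)


# ---------------------------------------------------------------------------
# Exhaustive enumeration (the brute-force oracle substrate)
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def enumerate_binary_shapes(n: int) -> tuple[RootedTree, ...]:
    """All rooted binary tree shapes with n leaves, one per isomorphism class.

    Shapes are built from unordered pairs of smaller shapes, so duplicates
    are avoided by construction; counts follow the Wedderburn-Etherington
    numbers.  Practical up to n ~ 15.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n == 1:
        return (LEAF,)
    out: set[RootedTree] = set()
    for i in range(1, n // 2 + 1):
        left_shapes = enumerate_binary_shapes(i)
        right_shapes = enumerate_binary_shapes(n - i)
        if i == n - i:
            for a, b in itertools.combinations_with_replacement(left_shapes, 2):
                out.add(RootedTree((a, b)))
        else:
            for a in left_shapes:
                for b in right_shapes:
                    out.add(RootedTree((a, b)))
    return tuple(sorted(out, key=lambda t: t.key))


def _partitions(n: int, max_part: int) -> Iterator[tuple[int, ...]]:
    """Integer partitions of n with parts <= max_part, non-increasing."""
    if n == 0:
        yield ()
        return
    for p in range(min(n, max_part), 0, -1):
        for rest in _partitions(n - p, p):
            yield (p,) + rest


@functools.lru_cache(maxsize=None)
def enumerate_arbitrary_shapes(n: int) -> tuple[RootedTree, ...]:
    """All rooted tree shapes with n leaves and no out-degree-one vertices.

    Root children form a multiset of smaller shapes whose leaf counts are a
    partition of n into at least two parts.  Practical up to n ~ 10.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n == 1:
        return (LEAF,)
    out: set[RootedTree] = set()
    for part in _partitions(n, n - 1):  # max part n-1 forces >= 2 children
        sizes = sorted(set(part), reverse=True)
        per_size = []
        for s in sizes:
            mult = part.count(s)
            per_size.append(
                list(itertools.combinations_with_replacement(enumerate_arbitrary_shapes(s), mult))
            )
        for combo in itertools.product(*per_size):
            children = tuple(itertools.chain.from_iterable(combo))
            out.add(RootedTree(children))
    return tuple(sorted(out, key=lambda t: t.key))


# ---------------------------------------------------------------------------
# Subtree replacement and random shapes
# ---------------------------------------------------------------------------

def replace_subtree(tree: RootedTree, handle: int, replacement: RootedTree) -> RootedTree:
    """Return the tree with the pending subtree at `handle` swapped for
    `replacement` (which must have the same leaf count, so every depth
    outside the subtree is unchanged).

    Handles index the root-first traversal of :meth:`RootedTree.preorder`.
    The returned tree is re-canonicalized, so handles are not stable across
    the replacement.
    """
    target = tree.vertex(handle)
    if target.n != replacement.n:
        raise ValueError(
            f"replacement has {replacement.n} leaves but the subtree at handle "
            f"{handle} has {target.n}"
        )
    counter = itertools.count()

    def rebuild(node: RootedTree) -> RootedTree:
        idx = next(counter)
        if idx == handle:
            # consume the handles of the replaced subtree
            for _ in range(node.num_vertices() - 1):
                next(counter)
            return replacement
        if node.is_leaf:
            return node
        return RootedTree([rebuild(c) for c in node.children])

    return rebuild(tree)


def random_binary_shape(n: int, rng) -> RootedTree:
    """Uniformly random *split* binary shape (not uniform over shapes;
    adequate for randomized property checks)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n == 1:
        return LEAF
    i = rng.randint(1, n - 1)
    return RootedTree((random_binary_shape(i, rng), random_binary_shape(n - i, rng)))


def random_arbitrary_shape(n: int, rng) -> RootedTree:
    """Random rooted shape with n leaves and no unary vertices."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n == 1:
        return LEAF
    k = rng.randint(2, n)
    # random composition of n into k positive parts
    cuts = sorted(rng.sample(range(1, n), k - 1))
    parts = [b - a for a, b in zip([0] + cuts, cuts + [n])]
    return RootedTree(random_arbitrary_shape(p, rng) for p in parts)
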