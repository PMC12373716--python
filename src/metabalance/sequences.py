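"""The three ascending tree-shape sequences and their merge/shift algebra.

A rooted tree shape induces three integer sequences, each sorted in
ascending order:

* the **balance value sequence** B(T): |n_v1 - n_v2| over the inner
  vertices of a *binary* tree (length n - 1),
* the **clade size sequence** N(T): n_v over all inner vertices (length
  between 1 for the star tree and n - 1 for a binary tree),
* the **leaf depth sequence** D(T): delta_x over all leaves (length n).

Each sequence decomposes recursively over the maximal pending subtrees of
the root via an ordered union operator (merge keeping ascending order) and
a constant shift; those two operations are provided here and are the basis
of the recursive metaconcept evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .trees import RootedTree

__all__ = [
    "ShapeSequence",
    "NonBinaryError",
    "balance_sequence",
    "clade_size_sequence",
    "leaf_depth_sequence",
    "ordered_union",
    "shift",
    "KINDS",
]

KINDS = ("balance_values", "clade_sizes", "leaf_depths")

_KIND_ALIASES = {
    "B": "balance_values",
    "N": "clade_sizes",
    "D": "leaf_depths",
    "balance_values": "balance_values",
    "clade_sizes": "clade_sizes",
    "leaf_depths": "leaf_depths",
}


class NonBinaryError(ValueError):
    """Raised when a balance value sequence is requested for a non-binary tree."""


def normalize_kind(kind: str) -> str:
    try:
        return _KIND_ALIASES[kind]
    except KeyError:
        raise ValueError(f"unknown sequence kind {kind!r}; expected one of {KINDS}") from None


@dataclass(frozen=True)
class ShapeSequence:
    """An ascending integer sequence extracted from a tree shape.

    Carries the leaf count ``n`` and inner-vertex count ``ninner`` of the
    source tree so higher-order metaconcepts can consume them without
    re-walking the tree.
    """

    kind: str
    values: tuple[int, ...]
    n: int
    ninner: int

    def __post_init__(self):
        object.__setattr__(self, "kind", normalize_kind(self.kind))
        vals = tuple(self.values)
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("sequence entries must be non-decreasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self) -> Iterator[int]:
        return iter(self.values)

    def __getitem__(self, i):
        return self.values[i]

    def to_csv(self) -> str:
        return ",".join(str(v) for v in self.values)


def _leaf_depths(tree: RootedTree) -> list[int]:
    depths = []
    stack = [(tree, 0)]
    while stack:
        node, d = stack.pop()
        if node.is_leaf:
            depths.append(d)
        else:
            stack.extend((c, d + 1) for c in node.children)
    return depths


def balance_sequence(tree: RootedTree) -> ShapeSequence:
    """B(T): ascending |n_v1 - n_v2| over inner vertices (binary trees only)."""
    values = []
    for handle, v in enumerate(tree.preorder()):
        if v.is_leaf:
            continue
        if len(v.children) != 2:
            raise NonBinaryError(
                f"balance values require a binary tree; vertex at handle {handle} "
                f"has out-degree {len(v.children)}"
            )
        a, b = v.children
        values.append(abs(a.n - b.n))
    return ShapeSequence("balance_values", sorted(values), tree.n, len(values))


def clade_size_sequence(tree: RootedTree) -> ShapeSequence:
    """N(T): ascending clade sizes n_v over inner vertices (empty for n = 1)."""
    values = sorted(v.n for v in tree.preorder() if not v.is_leaf)
    return ShapeSequence("clade_sizes", values, tree.n, len(values))


def leaf_depth_sequence(tree: RootedTree) -> ShapeSequence:
    """D(T): ascending leaf depths; always length n.

    For the single-vertex tree this is (0): the sole vertex is a leaf at
    depth zero, which also fixes the start value of the recursive leaf
    depth metaconcept.
    """
    ninner = tree.num_inner
    return ShapeSequence("leaf_depths", sorted(_leaf_depths(tree)), tree.n, ninner)


def extract(kind: str, tree: RootedTree) -> ShapeSequence:
    """Dispatch helper: sequence of the given kind for a tree."""
    kind = normalize_kind(kind)
    if kind == "balance_values":
        return balance_sequence(tree)
    if kind == "clade_sizes":
        return clade_size_sequence(tree)
    return leaf_depth_sequence(tree)


def ordered_union(a: ShapeSequence, b: ShapeSequence) -> ShapeSequence:
    """Merge two same-kind sequences keeping ascending order.

    The result carries the combined leaf/inner-vertex counts, matching its
    use in the recursive decomposition over maximal pending subtrees.
    """
    if a.kind != b.kind:
        raise ValueError(f"cannot merge sequences of kinds {a.kind!r} and {b.kind!r}")
    merged = sorted(a.values + b.values)
    return ShapeSequence(a.kind, merged, a.n + b.n, a.ninner + b.ninner)


def shift(a: ShapeSequence, amount: int) -> ShapeSequence:
    """Increase every entry by a non-negative integer; order is preserved."""
    if amount < 0:
        raise ValueError(f"shift amount must be non-negative, got {amount}")
    return ShapeSequence(a.kind, tuple(v + amount for v in a.values), a.n, a.ninner)
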