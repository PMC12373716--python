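"""Closed-form extremal values, subtree-count formulas and brute-force search.

For each metaconcept the extreme values over all shapes with n leaves have
closed forms once the shape function's family is known:

* the caterpillar attains every maximum (sum of f over its sequence,
  which is explicit: B = (0..n-2), N = (2..n), D = (1,..,n-1,n-1)),
* the fully balanced tree attains the minimum at powers of two,
* for convex f the maximally balanced tree attains the minimum, for
  strictly concave f (clade sizes) the greedy-from-the-bottom tree,
  for affine f the Sackin/Colless argmin sets, and on arbitrary trees
  the star tree.

The minimum values are expressed through the minimal Colless value c_n,
the Sackin extremes, and the subtree-size counts gfb_n(i) and mb_n(i) of
the gfb- and mb-trees.  Every closed form is backed by an enumeration
route over all shapes (`extremal_sets_by_enumeration`), which is also the
instrument for locating the minimal leaf counts at which the three shape
sequences fail to determine each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from . import sequences as seqmod
from .metaconcepts import Metaconcept, ShapeFunction, as_shape_function, evaluate
from .properties import classify_function
from .trees import (LEAF, RootedTree, caterpillar, ceil_log2,
                    enumerate_arbitrary_shapes, enumerate_binary_shapes,
                    fully_balanced, greedy_from_bottom, maximally_balanced,
                    star)

__all__ = [
    "ExtremalReport",
    "colless_min",
    "sackin_extremes",
    "gfb_subtree_count",
    "mb_subtree_count",
    "mb_decomposition_remainder",
    "bvm_extremes",
    "csm_extremes",
    "ldm_extremes",
    "extremal_sets_by_enumeration",
    "sackin_min_shapes",
    "colless_min_shapes",
    "minimal_sequence_coincidence",
    "find_coincident_pair",
]

#: default enumeration bounds (configurable per call)
BINARY_ENUM_BOUND = 12
ARBITRARY_ENUM_BOUND = 8


@dataclass(frozen=True)
class ExtremalReport:
    """Extreme values and extremal shape sets of a metaconcept at leaf count n.

    ``minimizers``/``maximizers`` hold canonical keys of extremal shapes.
    For ``method='enumeration'`` they are the complete argmin/argmax sets
    over the domain; for ``method='closed_form'`` they list the provably
    extremal family representatives the formulas are built on.
    """

    description: str
    n: int
    domain: str
    min_value: float
    max_value: float
    minimizers: tuple[str, ...]
    maximizers: tuple[str, ...]
    method: str
    notes: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Classical closed forms
# ---------------------------------------------------------------------------

def _nearest_int_distance(x: float) -> float:
    return min(x - math.floor(x), math.ceil(x) - x)


def colless_min(n: int) -> int:
    """Minimum Colless value c_n over binary shapes with n leaves:
    c_n = sum_{i=1}^{h_n - 1} 2^i * s(n / 2^i), with h_n = ceil(log2 n)
    and s(x) the distance from x to its nearest integer."""
    h = ceil_log2(n)
    total = sum(2 ** i * _nearest_int_distance(n / 2 ** i) for i in range(1, h))
    return round(total)


def sackin_extremes(n: int) -> tuple[int, int]:
    """(min, max) of the Sackin index over binary shapes with n leaves.

    Minimum: -2^{h_n} + n (h_n + 1), attained by the trees using only the
    leaf depths h_n - 1 and h_n (equal to h 2^h at n = 2^h).  Maximum:
    n(n+1)/2 - 1, attained uniquely by the caterpillar.
    """
    h = ceil_log2(n)
    smin = -(2 ** h) + n * (h + 1)
    smax = n * (n + 1) // 2 - 1
    return smin, smax


def gfb_subtree_count(n: int, i: int) -> int:
    """Number of pending subtrees of the gfb-tree with n leaves that have
    exactly i leaves (closed form; h_i = ceil(log2 i))."""
    if not 1 <= i <= n:
        raise ValueError(f"subtree size i must satisfy 1 <= i <= n, got i={i}, n={n}")
    h_i = ceil_log2(i)
    if i == 2 ** h_i:
        r = n % i
        if r == 0 or r >= 2 ** (h_i - 1):
            return n // i
        return n // i - 1
    if (n - i) % (2 ** (h_i - 1)) == 0:
        return 1
    return 0


def mb_decomposition_remainder(n: int, level: int) -> int:
    """r_l^n = n - 2^l * floor(n / 2^l): the remainder of n at binary level l."""
    return n - 2 ** level * (n // 2 ** level)


@lru_cache(maxsize=None)
def _clade_size_counts(key_tree: RootedTree) -> dict[int, int]:
    counts: dict[int, int] = {}
    for v in key_tree.preorder():
        counts[v.n] = counts.get(v.n, 0) + 1
    return counts


def mb_subtree_count(n: int, i: int) -> int:
    """Number of pending subtrees of the mb-tree with n leaves that have
    exactly i leaves, counted on the constructed tree (leaves count as
    size-1 subtrees)."""
    if not 1 <= i <= n:
        raise ValueError(f"subtree size i must satisfy 1 <= i <= n, got i={i}, n={n}")
    return _clade_size_counts(maximally_balanced(n)).get(i, 0)


# ---------------------------------------------------------------------------
# Sackin / Colless argmin shape sets
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _two_depth_shapes(depth: int, n: int) -> tuple[RootedTree, ...]:
    """Binary shapes with n leaves whose leaf depths all lie in
    {depth - 1, depth}."""
    if depth == 0:
        return (LEAF,) if n == 1 else ()
    if n == 1:
        return (LEAF,) if depth == 1 else ()
    out: set[RootedTree] = set()
    for n1 in range(1, n // 2 + 1):
        for a in _two_depth_shapes(depth - 1, n1):
            for b in _two_depth_shapes(depth - 1, n - n1):
                out.add(RootedTree((a, b)))
    return tuple(sorted(out, key=lambda t: t.key))


def sackin_min_shapes(n: int) -> tuple[RootedTree, ...]:
    """All binary shapes minimizing the Sackin index at leaf count n:
    the fully balanced tree when n is a power of two, otherwise exactly
    the shapes employing the two leaf depths h_n - 1 and h_n.  Built
    constructively (fb-scaffold with cherries attached in all inequivalent
    ways); enumeration is the cross-check in the tests."""
    if n == 1:
        return (LEAF,)
    return _two_depth_shapes(ceil_log2(n), n)


def colless_min_shapes(n: int) -> tuple[RootedTree, ...]:
    """All binary shapes attaining the minimal Colless value c_n
    (filtered from the Sackin argmin set, which provably contains them)."""
    from .metaconcepts import colless  # local import to avoid cycle noise

    c = colless_min(n)
    out = [t for t in sackin_min_shapes(n) if colless(t) == c]
    return tuple(out)


# ---------------------------------------------------------------------------
# Closed-form extremal reports per metaconcept
# ---------------------------------------------------------------------------

def _is_power_of_two(n: int) -> bool:
    return n >= 1 and n & (n - 1) == 0


def _call(f: ShapeFunction, x: int) -> float:
    return f(x)


def bvm_extremes(f, n: int) -> ExtremalReport:
    """Closed-form extremes of the balance value metaconcept on binary
    shapes with n leaves.

    Maximum (increasing f): sum_{i=0}^{n-2} f(i) at the caterpillar.
    Minimum: (n-1) f(0) at the fb-tree when n = 2^h; c_n f(1) +
    (n-1-c_n) f(0) at the mb-tree for convex f; m c_n + (n-1) a for
    affine f, attained by the Colless argmin set.
    """
    f = as_shape_function(f)
    cert = classify_function(f, domain_bound=max(8, n))
    notes: list[str] = []
    if not cert.increasing:
        notes.append("f is not increasing on the scanned grid; "
                     "the extremal formulas are not guaranteed")
    max_value = sum(_call(f, i) for i in range(0, n - 1))
    maximizers = (caterpillar(n).key,)
    if _is_power_of_two(n):
        min_value = (n - 1) * _call(f, 0)
        minimizers = (fully_balanced(ceil_log2(n)).key,)
    elif cert.affine:
        m, a = cert.slope, cert.intercept
        min_value = m * colless_min(n) + (n - 1) * a
        minimizers = tuple(t.key for t in colless_min_shapes(n))
        notes.append("affine f: equivalent to the Colless index; minimizers "
                     "are the Colless argmin set")
    elif cert.convex:
        c = colless_min(n)
        min_value = c * _call(f, 1) + (n - 1 - c) * _call(f, 0)
        minimizers = (maximally_balanced(n).key,)
        if not (_call(f, 2) - _call(f, 1) > _call(f, 1) - _call(f, 0)):
            notes.append("f is convex but not locally strictly convex at 0,1,2; "
                         "the mb-tree minimizes but possibly not uniquely")
    else:
        return extremal_sets_by_enumeration(
            Metaconcept("balance_values", f), n,
            description=f"Phi^B_{f.name} (enumeration; no closed form for this f)",
        )
    return ExtremalReport(f"Phi^B_{f.name}", n, "binary", min_value, max_value,
                          minimizers, maximizers, "closed_form", tuple(notes))


def csm_extremes(f, n: int, domain: str = "binary") -> ExtremalReport:
    """Closed-form extremes of the clade size metaconcept.

    Maximum (increasing f; 2-positive on arbitrary trees):
    sum_{i=2}^n f(i) at the caterpillar.  Binary minimum: gfb-tree
    (strictly concave f, via gfb_n(i)), mb-tree (strictly convex f, via
    mb_n(i)), Sackin argmin set (affine f).  On arbitrary trees the star
    tree gives minimum f(n) for 2-positive f.
    """
    f = as_shape_function(f)
    cert = classify_function(f, domain_bound=max(8, n))
    notes: list[str] = []
    if not cert.increasing:
        notes.append("f is not increasing on the scanned grid; "
                     "the extremal formulas are not guaranteed")
    if n == 1:
        return ExtremalReport(f"Phi^N_{f.name}", 1, domain, 0.0, 0.0,
                              (LEAF.key,), (LEAF.key,), "closed_form",
                              ("single-vertex tree: empty clade size sequence",))
    max_value = sum(_call(f, i) for i in range(2, n + 1))
    maximizers = (caterpillar(n).key,)
    if domain == "arbitrary" and not cert.two_positive:
        notes.append("f is not 2-positive; the caterpillar maximum on "
                     "arbitrary trees is not guaranteed")

    if domain == "arbitrary":
        min_value = _call(f, n)
        minimizers = (star(n).key,)
        if not cert.two_positive:
            notes.append("f is not 2-positive; the star minimum is not guaranteed")
        return ExtremalReport(f"Phi^N_{f.name}", n, domain, min_value, max_value,
                              minimizers, maximizers, "closed_form", tuple(notes))

    if cert.affine:
        m, a = cert.slope, cert.intercept
        min_value = m * sackin_extremes(n)[0] + (n - 1) * a
        minimizers = tuple(t.key for t in sackin_min_shapes(n))
        notes.append("affine f: equivalent to the Sackin index on binary trees")
    elif cert.strictly_convex:
        min_value = sum(mb_subtree_count(n, i) * _call(f, i) for i in range(2, n + 1))
        minimizers = (maximally_balanced(n).key,)
    elif cert.strictly_concave:
        min_value = sum(gfb_subtree_count(n, i) * _call(f, i) for i in range(2, n + 1))
        minimizers = (greedy_from_bottom(n).key,)
    else:
        return extremal_sets_by_enumeration(
            Metaconcept("clade_sizes", f, domain), n,
            description=f"Phi^N_{f.name} (enumeration; no closed form for this f)",
        )
    return ExtremalReport(f"Phi^N_{f.name}", n, domain, min_value, max_value,
                          minimizers, maximizers, "closed_form", tuple(notes))


def ldm_extremes(f, n: int, domain: str = "binary") -> ExtremalReport:
    """Closed-form extremes of the leaf depth metaconcept.

    Affine f: maximum m (n(n+1)/2 - 1) + n a, binary minimum
    m (-2^{h_n} + n (h_n + 1)) + n a.  Convex strictly increasing f:
    maximum f(n-1) + sum_{i=1}^{n-1} f(i); binary minimum with
    n = 2^{h_n - 1} + p: (2^{h_n-1} - p) f(h_n - 1) + 2 p f(h_n).
    On arbitrary trees any increasing f has minimum n f(1) at the star.
    Strictly concave non-affine f admits no closed form (the minimizer
    depends on f) and falls back to enumeration.
    """
    f = as_shape_function(f)
    cert = classify_function(f, domain_bound=max(8, n))
    notes: list[str] = []
    if not cert.increasing:
        notes.append("f is not increasing on the scanned grid; "
                     "the extremal formulas are not guaranteed")
    if n == 1:
        v = _call(f, 0) if f.domain_min <= 0 else float("nan")
        return ExtremalReport(f"Phi^D_{f.name}", 1, domain, v, v,
                              (LEAF.key,), (LEAF.key,), "closed_form",
                              ("single-vertex tree: depth sequence (0)",))
    h = ceil_log2(n)
    if cert.affine:
        m, a = cert.slope, cert.intercept
        max_value = m * (n * (n + 1) / 2 - 1) + n * a
        min_binary = m * (-(2 ** h) + n * (h + 1)) + n * a
    elif cert.convex:
        max_value = _call(f, n - 1) + sum(_call(f, i) for i in range(1, n))
        p = n - 2 ** (h - 1)
        min_binary = (2 ** (h - 1) - p) * _call(f, h - 1) + 2 * p * _call(f, h)
    else:
        return extremal_sets_by_enumeration(
            Metaconcept("leaf_depths", f, domain), n,
            description=f"Phi^D_{f.name} (enumeration; for non-convex f the "
                        f"minimizer depends on f)",
        )
    maximizers = (caterpillar(n).key,)
    if domain == "arbitrary":
        min_value = n * _call(f, 1)
        minimizers = (star(n).key,)
    else:
        min_value = min_binary
        minimizers = ((fully_balanced(h).key,) if _is_power_of_two(n)
                      else tuple(t.key for t in sackin_min_shapes(n)))
        notes.append("binary minimizers coincide with the Sackin argmin set")
    return ExtremalReport(f"Phi^D_{f.name}", n, domain, min_value, max_value,
                          minimizers, maximizers, "closed_form", tuple(notes))


# ---------------------------------------------------------------------------
# Brute-force extremal sets
# ---------------------------------------------------------------------------

def extremal_sets_by_enumeration(metaconcept: Metaconcept, n: int,
                                 atol: float = 1e-9,
                                 description: str | None = None) -> ExtremalReport:
    """Exact min/max values with the complete argmin/argmax shape sets over
    every enumerated shape of the metaconcept's domain at leaf count n."""
    shapes = (enumerate_binary_shapes(n) if metaconcept.domain == "binary"
              else enumerate_arbitrary_shapes(n))
    values = [evaluate(metaconcept, t) for t in shapes]
    vmin, vmax = min(values), max(values)

    def close(a: float, b: float) -> bool:
        return abs(a - b) <= atol * (1.0 + abs(b))

    minimizers = tuple(t.key for t, v in zip(shapes, values) if close(v, vmin))
    maximizers = tuple(t.key for t, v in zip(shapes, values) if close(v, vmax))
    return ExtremalReport(description or metaconcept.name, n, metaconcept.domain,
                          vmin, vmax, minimizers, maximizers, "enumeration")


# ---------------------------------------------------------------------------
# Minimal non-uniqueness of the sequences (pairwise coincidence search)
# ---------------------------------------------------------------------------

_PRED_KINDS = {"B": "balance_values", "N": "clade_sizes", "D": "leaf_depths"}


def _parse_predicate(pred) -> tuple[str, bool]:
    """Accepts ('B', 'eq') / 'B_eq' / 'Beq' / 'Bneq' style predicates;
    returns (kind letter, want_equal)."""
    if isinstance(pred, tuple):
        kind, rel = pred
    else:
        text = str(pred)
        kind, rel = text[0], text[1:].lstrip("_")
    kind = kind.upper()
    if kind not in _PRED_KINDS:
        raise ValueError(f"unknown sequence {kind!r} in predicate {pred!r}")
    rel = rel.lower()
    if rel in ("eq", "equal", "="):
        return kind, True
    if rel in ("ne", "neq", "noteq", "different", "!="):
        return kind, False
    raise ValueError(f"unknown relation {rel!r} in predicate {pred!r}")


def find_coincident_pair(n: int, first, second) -> tuple[RootedTree, RootedTree] | None:
    """A pair of distinct binary shapes with n leaves satisfying both
    sequence predicates, or None."""
    k1, eq1 = _parse_predicate(first)
    k2, eq2 = _parse_predicate(second)
    shapes = enumerate_binary_shapes(n)
    seqs = {
        k: [seqmod.extract(_PRED_KINDS[k], t).values for t in shapes]
        for k in {k1, k2}
    }
    eq_kinds = [k for k, eq in ((k1, eq1), (k2, eq2)) if eq]
    ne_kinds = [k for k, eq in ((k1, eq1), (k2, eq2)) if not eq]

    groups: dict[tuple, list[int]] = {}
    for i in range(len(shapes)):
        key = tuple(seqs[k][i] for k in eq_kinds)
        groups.setdefault(key, []).append(i)
    for members in groups.values():
        if len(members) < 2:
            continue
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                i, j = members[ai], members[bi]
                if all(seqs[k][i] != seqs[k][j] for k in ne_kinds):
                    return shapes[i], shapes[j]
    return None


def minimal_sequence_coincidence(first, second, n_max: int = 14) -> int:
    """Smallest leaf count n at which two non-isomorphic binary shapes
    jointly satisfy the two sequence predicates (e.g. equal balance value
    sequences but different clade size sequences), found by exhaustive
    pairwise comparison over all enumerated shapes."""
    for n in range(2, n_max + 1):
        if find_coincident_pair(n, first, second) is not None:
            return n
    raise ValueError(
        f"no pair satisfying {first!r} and {second!r} exists for n <= {n_max}"
    )
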