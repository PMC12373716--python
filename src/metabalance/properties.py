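"""Shape-function certification and empirical index verification.

A metaconcept yields a valid imbalance index only for suitable families of
shape functions f (strictly increasing; convex, strictly concave or affine
depending on the sequence kind and domain).  Because metaconcepts only
ever evaluate f at the integers up to the leaf count, these properties are
certified by exact finite differences on an integer grid rather than
symbolically; a certificate records the grid bound it was established on.

The module also checks the two defining properties of an imbalance index
(caterpillar unique maximum, fully balanced tree unique minimum at powers
of two) by exhaustive enumeration, tests locality by randomized subtree
replacement, compares sequences entrywise (dominance), and encodes the
recommendation table mapping desired minimizing trees to the function
families that deliver them.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from . import sequences as seqmod
from .metaconcepts import Metaconcept, as_shape_function, evaluate
from .trees import (RootedTree, enumerate_arbitrary_shapes,
                    enumerate_binary_shapes, fully_balanced, caterpillar,
                    random_arbitrary_shape, random_binary_shape,
                    replace_subtree, to_newick)

__all__ = [
    "FunctionCertificate",
    "InsufficientEvidenceError",
    "classify_function",
    "ImbalanceVerification",
    "verify_imbalance_index",
    "LocalityResult",
    "check_locality",
    "DominanceVerdict",
    "dominance",
    "Recommendation",
    "RecommendationSet",
    "recommend",
    "MINIMIZER_TARGETS",
]


class InsufficientEvidenceError(ValueError):
    """Raised when the scan grid is too small to certify anything."""


@dataclass(frozen=True)
class FunctionCertificate:
    """Property flags for a shape function on the integer grid
    [domain_min, domain_bound].

    ``affine`` implies (non-strict) convex and concave; ``strictly_convex``
    and ``strictly_concave`` are mutually exclusive.  ``two_positive``
    means f(x) > 0 for every scanned x >= 2.  For affine functions the
    recovered slope and intercept are stored.
    """

    increasing: bool
    strictly_increasing: bool
    convex: bool
    strictly_convex: bool
    concave: bool
    strictly_concave: bool
    affine: bool
    two_positive: bool
    non_negative: bool
    domain_min: int
    domain_bound: int
    method: str
    slope: float | None = None
    intercept: float | None = None


def classify_function(f, domain_bound: int = 256) -> FunctionCertificate:
    """Certify monotonicity/convexity flags by exact finite differences.

    The strictness tolerance is 0 for integer-valued samples and 1e-12
    relative otherwise.  Functions undefined below their ``domain_min``
    (e.g. log(x - 1)) are scanned from that point on.
    """
    sf = as_shape_function(f)
    x0 = sf.domain_min
    if domain_bound - x0 < 3:
        raise InsufficientEvidenceError(
            f"need at least 4 grid points, got domain [{x0}, {domain_bound}]"
        )
    xs = list(range(x0, domain_bound + 1))
    vals = [sf(x) for x in xs]
    exact = all(float(v).is_integer() for v in vals)
    tol = 0.0 if exact else 1e-12 * max(1.0, max(abs(v) for v in vals))

    d1 = [b - a for a, b in zip(vals, vals[1:])]
    d2 = [b - a for a, b in zip(d1, d1[1:])]

    increasing = all(d >= -tol for d in d1)
    strictly_increasing = all(d > tol for d in d1)
    convex = all(d >= -tol for d in d2)
    strictly_convex = all(d > tol for d in d2)
    concave = all(d <= tol for d in d2)
    strictly_concave = all(d < -tol for d in d2)
    affine_flag = all(abs(d) <= tol for d in d2)

    method = "finite_difference_scan"
    slope = intercept = None
    if sf.family == "affine":
        slope, intercept = sf.params
        affine_flag = True
        method = "declared_family"
    elif affine_flag:
        slope = d1[0]
        intercept = vals[0] - slope * x0

    two_positive = all(v > tol for x, v in zip(xs, vals) if x >= 2)
    non_negative = all(v >= -tol for v in vals)
    return FunctionCertificate(
        increasing=increasing, strictly_increasing=strictly_increasing,
        convex=convex, strictly_convex=strictly_convex,
        concave=concave, strictly_concave=strictly_concave,
        affine=affine_flag, two_positive=two_positive,
        non_negative=non_negative, domain_min=x0, domain_bound=domain_bound,
        method=method, slope=slope, intercept=intercept,
    )


# ---------------------------------------------------------------------------
# Imbalance index verification (Definition: caterpillar unique max on the
# domain for every n, fb-tree unique min on binary trees at powers of two)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImbalanceVerification:
    passed: bool
    failures: tuple[tuple[int, str, str], ...]  # (n, which check, witness key)

    def __bool__(self) -> bool:
        return self.passed


def verify_imbalance_index(metaconcept: Metaconcept, n_max: int,
                           atol: float = 1e-9) -> ImbalanceVerification:
    """Empirically check the imbalance-index definition up to n_max.

    For each n the caterpillar must be the strictly unique maximizer over
    the metaconcept's domain, and for each n = 2**h <= n_max the fully
    balanced tree must be the strictly unique minimizer among binary
    shapes.  Returns the first counterexample shapes found for each n.
    """
    failures: list[tuple[int, str, str]] = []
    for n in range(2, n_max + 1):
        shapes = (enumerate_binary_shapes(n) if metaconcept.domain == "binary"
                  else enumerate_arbitrary_shapes(n))
        cat = caterpillar(n)
        v_cat = evaluate(metaconcept, cat)
        for t in shapes:
            if t == cat:
                continue
            if evaluate(metaconcept, t) >= v_cat - atol * (1 + abs(v_cat)):
                failures.append((n, "caterpillar_unique_max", t.key))
                break
        if n & (n - 1) == 0:  # power of two: fb unique min on binary shapes
            fb = fully_balanced(n.bit_length() - 1)
            v_fb = evaluate(metaconcept, fb)
            for t in enumerate_binary_shapes(n):
                if t == fb:
                    continue
                if evaluate(metaconcept, t) <= v_fb + atol * (1 + abs(v_fb)):
                    failures.append((n, "fb_unique_min", t.key))
                    break
    return ImbalanceVerification(not failures, tuple(failures))


# ---------------------------------------------------------------------------
# Locality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalityResult:
    local: bool
    trials: int
    witness: dict | None = None

    def __bool__(self) -> bool:
        return self.local


def check_locality(metaconcept: Metaconcept, trials: int = 100,
                   rng_seed: int = 0, max_leaves: int = 12,
                   atol: float = 1e-9) -> LocalityResult:
    """Randomized test of locality: replacing a pending subtree must change
    the index by exactly the difference of the subtree values,
    t(T) - t(T') = t(T_v) - t(T'_v).

    Returns a counterexample witness (both trees and the replacement, as
    Newick) on the first failing trial.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = random.Random(rng_seed)
    binary = metaconcept.domain == "binary" or metaconcept.kind == "balance_values"
    gen = random_binary_shape if binary else random_arbitrary_shape
    for trial in range(trials):
        n = rng.randint(4, max_leaves)
        tree = gen(n, rng)
        handles = [h for h, v in enumerate(tree.preorder()) if h > 0 and v.n >= 2]
        if not handles:
            continue
        handle = rng.choice(handles)
        sub = tree.vertex(handle)
        replacement = gen(sub.n, rng)
        new_tree = replace_subtree(tree, handle, replacement)
        lhs = evaluate(metaconcept, tree) - evaluate(metaconcept, new_tree)
        rhs = evaluate(metaconcept, sub) - evaluate(metaconcept, replacement)
        if abs(lhs - rhs) > atol * (1 + abs(lhs) + abs(rhs)):
            return LocalityResult(False, trial + 1, witness={
                "tree": to_newick(tree),
                "modified_tree": to_newick(new_tree),
                "subtree": to_newick(sub),
                "replacement": to_newick(replacement),
                "handle": handle,
                "index_difference": lhs,
                "subtree_difference": rhs,
            })
    return LocalityResult(True, trials)


# ---------------------------------------------------------------------------
# Dominance (entrywise sequence comparison)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DominanceVerdict:
    """Entrywise comparison of two same-length sequences.

    ``relation`` is one of ``a_dominates`` (a <= b entrywise),
    ``b_dominates``, ``equal`` or ``incomparable``; ``strict`` records
    whether at least one inequality is strict.  If a tree's sequence
    dominates (is entrywise below) another's, every increasing f values
    the first tree no higher than the second.
    """

    relation: str
    strict: bool


def dominance(a: seqmod.ShapeSequence, b: seqmod.ShapeSequence) -> DominanceVerdict:
    if a.kind != b.kind:
        raise ValueError(f"cannot compare sequences of kinds {a.kind!r} and {b.kind!r}")
    if len(a) != len(b):
        raise ValueError(f"sequences have different lengths {len(a)} and {len(b)}")
    a_le = all(x <= y for x, y in zip(a.values, b.values))
    b_le = all(y <= x for x, y in zip(a.values, b.values))
    if a_le and b_le:
        return DominanceVerdict("equal", False)
    if a_le:
        return DominanceVerdict("a_dominates", True)
    if b_le:
        return DominanceVerdict("b_dominates", True)
    return DominanceVerdict("incomparable", False)


# ---------------------------------------------------------------------------
# Recommendation logic
# ---------------------------------------------------------------------------

MINIMIZER_TARGETS = ("mb", "gfb", "argmin_S", "argmin_C", "depends")


@dataclass(frozen=True)
class Recommendation:
    """One admissible (metaconcept, f-condition) combination.

    ``minimizer`` names the binary minimizing tree(s) delivered by the
    combination: the maximally balanced tree (``mb``), the greedy-from-
    the-bottom tree (``gfb``), the Sackin or Colless argmin sets
    (``argmin_S``/``argmin_C``), or ``depends`` when the minimizer varies
    with f within the family and must be found by enumeration.
    """

    domain: str
    sequence: str
    condition: str
    minimizer: str
    flags: tuple[str, ...] = ()
    equivalence: str | None = None
    note: str | None = None


_TABLE: tuple[Recommendation, ...] = (
    # balance value metaconcept (binary trees only)
    Recommendation("binary", "balance_values",
                   "f strictly increasing",
                   "depends", ("strictly_increasing",),
                   note="a valid binary imbalance index for every strictly "
                        "increasing f, but the minimizing tree depends on f"),
    Recommendation("binary", "balance_values",
                   "f strictly increasing and convex "
                   "(locally strictly convex for uniqueness)",
                   "mb", ("strictly_increasing", "convex")),
    Recommendation("binary", "balance_values",
                   "f strictly increasing and strictly concave",
                   "depends", ("strictly_increasing", "strictly_concave"),
                   note="minimizer depends on f; use enumeration"),
    Recommendation("binary", "balance_values",
                   "f strictly increasing and affine (m > 0)",
                   "argmin_C", ("strictly_increasing", "affine"),
                   equivalence="equivalent to the Colless index"),
    # clade size metaconcept, binary domain
    Recommendation("binary", "clade_sizes",
                   "f strictly increasing and strictly convex",
                   "mb", ("strictly_increasing", "strictly_convex")),
    Recommendation("binary", "clade_sizes",
                   "f strictly increasing and strictly concave",
                   "gfb", ("strictly_increasing", "strictly_concave")),
    Recommendation("binary", "clade_sizes",
                   "f strictly increasing and affine (m > 0)",
                   "argmin_S", ("strictly_increasing", "affine"),
                   equivalence="equivalent to the Sackin index"),
    # clade size metaconcept, arbitrary domain
    Recommendation("arbitrary", "clade_sizes",
                   "f strictly increasing, strictly convex and 2-positive",
                   "mb", ("strictly_increasing", "strictly_convex", "two_positive")),
    Recommendation("arbitrary", "clade_sizes",
                   "f strictly increasing, strictly concave and 2-positive",
                   "gfb", ("strictly_increasing", "strictly_concave", "two_positive")),
    Recommendation("arbitrary", "clade_sizes",
                   "f strictly increasing and affine with intercept a >= 0",
                   "argmin_S", ("strictly_increasing", "affine", "non_negative_intercept"),
                   equivalence="a = 0 makes it equivalent to the Sackin index",
                   note="for a > 0 the index is valid but not "
                        "Sackin-equivalent on arbitrary trees"),
    # leaf depth metaconcept (same conditions on both domains)
    Recommendation("binary", "leaf_depths",
                   "f strictly increasing and convex",
                   "argmin_S", ("strictly_increasing", "convex")),
    Recommendation("binary", "leaf_depths",
                   "f strictly increasing and affine (m > 0)",
                   "argmin_S", ("strictly_increasing", "affine"),
                   equivalence="equivalent to the Sackin index"),
    Recommendation("arbitrary", "leaf_depths",
                   "f strictly increasing and convex",
                   "argmin_S", ("strictly_increasing", "convex")),
    Recommendation("arbitrary", "leaf_depths",
                   "f strictly increasing and affine (m > 0)",
                   "argmin_S", ("strictly_increasing", "affine"),
                   equivalence="equivalent to the Sackin index"),
)


@dataclass(frozen=True)
class RecommendationSet:
    items: tuple[Recommendation, ...]
    explanation: str | None = None

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __bool__(self):
        return bool(self.items)


def recommend(domain: str, minimizer: str | None = None,
              sequence: str | None = None) -> RecommendationSet:
    """All (metaconcept, f-condition) pairs consistent with the request.

    ``minimizer`` picks a desired set of binary minimizing trees
    (``mb``/``gfb``/``argmin_S``/``argmin_C``); ``sequence`` restricts the
    underlying sequence kind.  When the combination is impossible (e.g. a
    gfb-unique minimizer from the balance value metaconcept), the result
    is empty with an explanation.
    """
    if domain not in ("binary", "arbitrary"):
        raise ValueError(f"domain must be 'binary' or 'arbitrary', got {domain!r}")
    if minimizer is not None and minimizer not in MINIMIZER_TARGETS:
        raise ValueError(
            f"unknown minimizer target {minimizer!r}; expected one of {MINIMIZER_TARGETS}"
        )
    kind = seqmod.normalize_kind(sequence) if sequence is not None else None
    items = [r for r in _TABLE if r.domain == domain]
    if kind is not None:
        items = [r for r in items if r.sequence == kind]
    if minimizer is not None:
        items = [r for r in items if r.minimizer == minimizer]
    explanation = None
    if not items:
        explanation = (
            f"no function family makes the "
            f"{kind or 'requested'} metaconcept on {domain} trees deliver "
            f"minimizer target {minimizer!r}; choose a different sequence "
            f"kind or minimizer (e.g. a gfb-unique minimizer is only "
            f"available from the clade size metaconcept with strictly "
            f"concave f)"
        )
    return RecommendationSet(tuple(items), explanation)
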