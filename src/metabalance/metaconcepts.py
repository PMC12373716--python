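"""Metaconcept functionals and the classical indices they induce.

A metaconcept of order omega sums a shape function ``f`` over one of the
three tree-shape sequences::

    Phi^Seq_f(T) = sum over s in Seq(T) of f(s, o_1(T), ..., o_{omega-1}(T))

where the optional extra arguments are tree-level constants such as the
leaf count ``n`` or the number of inner vertices ``ninner``.  Choosing the
balance value sequence yields the balance value metaconcept (BVM, binary
trees only), the clade size sequence the clade size metaconcept (CSM) and
the leaf depth sequence the leaf depth metaconcept (LDM).

The seven classical indices in this module are specific members of these
families: Sackin, average leaf depth, the s-hat shape statistic and the
total cophenetic index come from the CSM/LDM, while the Colless, corrected
Colless and quadratic Colless indices come from the BVM.  Each is
implemented by its direct definition; the test suite verifies that the
metaconcept route with the corresponding ``f`` reproduces it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

from . import sequences as seqmod
from .expressions import compile_expression
from .trees import RootedTree, enumerate_arbitrary_shapes, enumerate_binary_shapes

__all__ = [
    "ShapeFunction",
    "Metaconcept",
    "DomainError",
    "UnsupportedRecursionError",
    "as_shape_function",
    "affine",
    "power",
    "log_shifted",
    "from_expression",
    "identity",
    "standard_battery",
    "evaluate",
    "recursive_evaluate",
    "sackin",
    "average_leaf_depth",
    "s_hat",
    "total_cophenetic",
    "colless",
    "corrected_colless",
    "quadratic_colless",
    "equivalent_on",
    "EquivalenceReport",
]


class DomainError(ValueError):
    """Raised when a shape function is evaluated outside its domain."""


class UnsupportedRecursionError(ValueError):
    """Raised when a metaconcept admits no recursive evaluation for this f."""


@dataclass(frozen=True)
class ShapeFunction:
    """A real-valued function on non-negative integers, plus metadata.

    ``fn`` always has the signature ``fn(x, n=None, ninner=None)``;
    ``extras`` names the tree-level values it actually consumes, so the
    metaconcept order is ``1 + len(extras)``.  ``family`` and ``params``
    record a declared parametric family (used e.g. to read off the slope
    of an affine function exactly), and ``domain_min`` is the smallest
    integer argument at which the function is defined (2 for log(x - 1),
    matching the minimal clade size).
    """

    name: str
    fn: Callable[..., float]
    extras: tuple[str, ...] = ()
    family: str | None = None
    params: tuple[float, ...] = ()
    domain_min: int = 0

    @property
    def order(self) -> int:
        return 1 + len(self.extras)

    def __call__(self, x, n=None, ninner=None) -> float:
        try:
            return self.fn(x, n=n, ninner=ninner)
        except (ValueError, ZeroDivisionError) as exc:
            raise DomainError(f"{self.name} undefined at entry {x}: {exc}") from exc

    def __repr__(self) -> str:
        return f"ShapeFunction({self.name!r})"


def as_shape_function(f, name: str | None = None) -> ShapeFunction:
    """Wrap a plain ``f(x)`` callable; ShapeFunctions pass through."""
    if isinstance(f, ShapeFunction):
        return f
    return ShapeFunction(name or getattr(f, "__name__", "f"),
                         lambda x, n=None, ninner=None: f(x))


# -- parametric families -----------------------------------------------------

def affine(m: float, a: float = 0.0, name: str | None = None) -> ShapeFunction:
    """f(x) = m * x + a (slope m, intercept a)."""
    return ShapeFunction(name or f"{m}*x+{a}",
                         lambda x, n=None, ninner=None: m * x + a,
                         family="affine", params=(m, a))


identity = affine(1.0, 0.0, name="identity")


def power(p: float, name: str | None = None) -> ShapeFunction:
    """f(x) = x**p; strictly convex on the integer grid for p > 1,
    strictly concave for 0 < p < 1."""
    return ShapeFunction(name or f"x^{p}",
                         lambda x, n=None, ninner=None: float(x) ** p,
                         family="power", params=(p,))


def log_shifted(base: float = 2.0, scale: float = 1.0, shift: float = 1.0,
                name: str | None = None) -> ShapeFunction:
    """f(x) = log_base(scale * x + shift); domain requires scale*x + shift > 0."""
    dom = 0
    while scale * dom + shift <= 0:
        dom += 1
    return ShapeFunction(
        name or f"log{base}({scale}x+{shift})",
        lambda x, n=None, ninner=None: math.log(scale * x + shift, base),
        family="log_shifted", params=(base, scale, shift), domain_min=dom,
    )


def from_expression(source: str, name: str | None = None,
                    extras: Sequence[str] = (), domain_min: int = 0) -> ShapeFunction:
    """Build a ShapeFunction from a safe arithmetic expression over
    ``x``, ``n`` and ``ninner`` (see :mod:`metabalance.expressions`)."""
    fn = compile_expression(source)
    return ShapeFunction(name or source, fn, extras=tuple(extras),
                         family="custom", params=(), domain_min=domain_min)


def standard_battery() -> dict[str, ShapeFunction]:
    """The shape functions exercised throughout the test battery:
    one affine, one strictly convex, two strictly concave and one
    piecewise-linear convexity mix around the identity."""
    return {
        "identity": identity,
        "square": from_expression("x*x", name="square"),
        "sqrt": ShapeFunction("sqrt", lambda x, n=None, ninner=None: math.sqrt(x)),
        "3x+1": affine(3.0, 1.0, name="3x+1"),
        "log(x-1)": ShapeFunction("log(x-1)",
                                  lambda x, n=None, ninner=None: math.log(x - 1),
                                  domain_min=2),
        "x+1/(x+1)": from_expression("x + 1/(x+1)", name="x+1/(x+1)"),
    }


# -- the metaconcept ---------------------------------------------------------

@dataclass(frozen=True)
class Metaconcept:
    """A (sequence kind, shape function, domain) triple evaluating to a real
    number on a tree.  The balance value kind forces the binary domain."""

    kind: str
    f: ShapeFunction
    domain: str = "binary"
    name: str = field(default="", compare=False)

    def __post_init__(self):
        kind = seqmod.normalize_kind(self.kind)
        object.__setattr__(self, "kind", kind)
        if self.domain not in ("binary", "arbitrary"):
            raise ValueError(f"domain must be 'binary' or 'arbitrary', got {self.domain!r}")
        if kind == "balance_values" and self.domain != "binary":
            raise ValueError("the balance value metaconcept is defined on binary trees only")
        if not self.name:
            sym = {"balance_values": "B", "clade_sizes": "N", "leaf_depths": "D"}[kind]
            object.__setattr__(self, "name", f"Phi^{sym}_{self.f.name}")

    def __call__(self, tree: RootedTree) -> float:
        return evaluate(self, tree)


def evaluate(metaconcept: Metaconcept, tree: RootedTree) -> float:
    """Sum f over the tree's sequence; an empty sequence gives 0."""
    seq = seqmod.extract(metaconcept.kind, tree)
    f = metaconcept.f
    total = 0.0
    for s in seq.values:
        if s < f.domain_min:
            raise DomainError(
                f"{f.name} is undefined at sequence entry {s} "
                f"(domain starts at {f.domain_min})"
            )
        total += f(s, n=seq.n, ninner=seq.ninner)
    return total


def _affine_slope_if_zero_intercept(f: ShapeFunction) -> float:
    """Slope m if f is affine with intercept 0; raises otherwise."""
    if f.family == "affine":
        m, a = f.params
        if abs(a) > 1e-12:
            raise UnsupportedRecursionError(
                "leaf depth metaconcept recursion requires an affine f with intercept 0"
            )
        return m
    # probe the integer grid: affine with f(0) = 0 means f(x) = f(1) * x
    try:
        probes = [f(x) for x in range(0, 5)]
    except DomainError as exc:
        raise UnsupportedRecursionError(
            "leaf depth metaconcept recursion requires an affine f with intercept 0"
        ) from exc
    m = probes[1] - probes[0]
    if abs(probes[0]) > 1e-12 or any(
        abs(probes[i] - m * i) > 1e-9 * (1 + abs(probes[i])) for i in range(5)
    ):
        raise UnsupportedRecursionError(
            "leaf depth metaconcept recursion requires an affine f with intercept 0"
        )
    return m


def recursive_evaluate(metaconcept: Metaconcept, tree: RootedTree) -> float:
    """Evaluate via the standard-decomposition recursions instead of the
    sequence definition (first-order metaconcepts only).

    BVM:  Phi(T) = Phi(T1) + Phi(T2) + f(|n1 - n2|)
    CSM:  Phi(T) = sum_i Phi(T_i) + f(n)
    LDM:  Phi(T) = sum_i Phi(T_i) + n * m   (affine f with intercept 0)
    """
    if metaconcept.f.extras:
        raise UnsupportedRecursionError(
            "the decomposition recursions apply to first-order metaconcepts only"
        )
    f = metaconcept.f
    kind = metaconcept.kind
    if kind == "leaf_depths":
        m = _affine_slope_if_zero_intercept(f)

        def rec_d(t: RootedTree) -> float:
            if t.is_leaf:
                return 0.0
            return sum(rec_d(c) for c in t.children) + t.n * m

        return rec_d(tree)
    if kind == "balance_values":

        def rec_b(t: RootedTree) -> float:
            if t.is_leaf:
                return 0.0
            if len(t.children) != 2:
                raise seqmod.NonBinaryError(
                    "balance value metaconcept requires a binary tree"
                )
            a, b = t.children
            return rec_b(a) + rec_b(b) + f(abs(a.n - b.n))

        return rec_b(tree)

    def rec_n(t: RootedTree) -> float:
        if t.is_leaf:
            return 0.0
        return sum(rec_n(c) for c in t.children) + f(t.n)

    return rec_n(tree)


# -- classical indices -------------------------------------------------------

def sackin(tree: RootedTree) -> int:
    """Sum of all leaf depths; equivalently the sum of all inner clade sizes."""
    return sum(seqmod.leaf_depth_sequence(tree).values)


def average_leaf_depth(tree: RootedTree) -> float:
    return sackin(tree) / tree.n


def s_hat(tree: RootedTree, base: float = math.e) -> float:
    """s-hat shape statistic: sum of log(n_v - 1) over inner vertices.

    The logarithm base is arbitrary (it rescales the index without changing
    any ranking); natural log by default.
    """
    return sum(math.log(nv - 1, base) for nv in seqmod.clade_size_sequence(tree).values)


def total_cophenetic(tree: RootedTree) -> int:
    """Total cophenetic index: sum of binomial(n_v, 2) over non-root inner
    vertices; equals the sum of the LCA depths over all leaf pairs."""
    if tree.n <= 1:
        return 0
    inner = seqmod.clade_size_sequence(tree).values
    return sum(math.comb(nv, 2) for nv in inner) - math.comb(tree.n, 2)


def colless(tree: RootedTree) -> int:
    """Colless index: sum of the balance values (binary trees only)."""
    return sum(seqmod.balance_sequence(tree).values)


def corrected_colless(tree: RootedTree) -> float:
    """Colless index normalized by 2 / ((n-1)(n-2)); defined as 0 for n <= 2
    (the 0/0 convention is hard-coded rather than left to the normalizer)."""
    if tree.n <= 2:
        # still reject non-binary input for consistency with colless
        seqmod.balance_sequence(tree)
        return 0.0
    return 2.0 / ((tree.n - 1) * (tree.n - 2)) * colless(tree)


def quadratic_colless(tree: RootedTree) -> int:
    """Sum of squared balance values (binary trees only)."""
    return sum(b * b for b in seqmod.balance_sequence(tree).values)


# -- ranking equivalence -----------------------------------------------------

@dataclass(frozen=True)
class EquivalenceReport:
    """Result of comparing two indices' rankings over all shapes at fixed n.

    ``equivalent`` follows the strict-inequality definition: the indices
    agree on every strict comparison.  ``ties_agree`` additionally reports
    whether their tie sets coincide (the definition leaves ties open; both
    facts are reported)."""

    equivalent: bool
    ties_agree: bool
    n: int
    domain: str
    witness: tuple[str, str] | None = None

    def __bool__(self) -> bool:
        return self.equivalent


def equivalent_on(index1: Callable[[RootedTree], float],
                  index2: Callable[[RootedTree], float],
                  n: int, domain: str = "binary",
                  atol: float = 1e-9) -> EquivalenceReport:
    """Do two tree shape statistics rank all n-leaf shapes identically?

    Enumerates every shape in the domain and checks that each strict
    inequality under one index is a strict inequality (same direction)
    under the other.
    """
    shapes = (enumerate_binary_shapes(n) if domain == "binary"
              else enumerate_arbitrary_shapes(n))
    v1 = [index1(t) for t in shapes]
    v2 = [index2(t) for t in shapes]

    def cmp(a: float, b: float) -> int:
        if abs(a - b) <= atol * (1.0 + max(abs(a), abs(b))):
            return 0
        return -1 if a < b else 1

    equivalent = True
    ties_agree = True
    witness = None
    for i in range(len(shapes)):
        for j in range(i + 1, len(shapes)):
            c1 = cmp(v1[i], v1[j])
            c2 = cmp(v2[i], v2[j])
            if c1 != c2:
                # the biconditional on strict inequalities fails for this pair
                equivalent = False
                if witness is None:
                    witness = (shapes[i].key, shapes[j].key)
            if (c1 == 0) != (c2 == 0):
                ties_agree = False
    return EquivalenceReport(equivalent, ties_agree, n, domain, witness)
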