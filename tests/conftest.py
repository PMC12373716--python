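"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import pytest

import metabalance as mb


@pytest.fixture(scope="session")
def battery() -> dict[str, mb.ShapeFunction]:
    """Strictly increasing shape functions spanning the families of
    interest: affine, strictly convex, strictly concave, and a convex
    perturbation of the identity."""
    return mb.standard_battery()


@pytest.fixture(scope="session")
def paper_functions() -> dict[str, mb.ShapeFunction]:
    """The worked-example functions: two concave logs, a piecewise-linear
    increasing function that is neither convex nor concave, a bounded
    concave ratio, and the plain base-2 log."""
    return {
        "f1": mb.log_shifted(2, 0.5, 1, name="f1"),
        "f2": mb.log_shifted(2, 1.5, 1, name="f2"),
        "f3": mb.from_expression("x if x <= 3 else x + 2", name="f3"),
        "f4": mb.from_expression("x/(x+0.5)", name="f4"),
        "f5": mb.from_expression("log2(x)", name="f5", domain_min=1),
    }


# ---------------------------------------------------------------------------
# Independent oracles (deliberately not using the package's own routes)
# ---------------------------------------------------------------------------

def wedderburn_etherington(n: int) -> int:
    """Number of rooted binary shapes with n leaves, by the pairing
    recurrence a(n) = sum_{i < n/2} a(i) a(n-i) + [n even] C(a(n/2)+1, 2)."""
    memo = {1: 1}

    def a(k: int) -> int:
        if k not in memo:
            total = sum(a(i) * a(k - i) for i in range(1, (k - 1) // 2 + 1))
            if k % 2 == 0:
                half = a(k // 2)
                total += half * (half + 1) // 2
            memo[k] = total
        return memo[k]

    return a(n)


def arbitrary_shape_count(n: int) -> int:
    """Number of rooted shapes (no unary vertices) with n leaves, counting
    multisets of smaller shapes over the partitions of n."""
    memo = {1: 1}

    def partitions(k: int, max_part: int):
        if k == 0:
            yield ()
            return
        for p in range(min(k, max_part), 0, -1):
            for rest in partitions(k - p, p):
                yield (p,) + rest

    def count(k: int) -> int:
        if k not in memo:
            total = 0
            for part in partitions(k, k - 1):
                prod = 1
                for s in set(part):
                    m = part.count(s)
                    prod *= math.comb(count(s) + m - 1, m)
                total += prod
            memo[k] = total
        return memo[k]

    return count(n)


def cophenetic_by_leaf_pairs(tree: mb.RootedTree) -> int:
    """Total cophenetic index summed directly over leaf pairs: the LCA
    depth of two leaves is the length of the common prefix of their
    root-to-leaf child-index paths."""
    paths: list[tuple[int, ...]] = []

    def walk(t: mb.RootedTree, path: tuple[int, ...]) -> None:
        if t.is_leaf:
            paths.append(path)
            return
        for i, c in enumerate(t.children):
            walk(c, path + (i,))

    walk(tree, ())
    total = 0
    for i in range(len(paths)):
        for j in range(i + 1, len(paths)):
            d = 0
            for a, b in zip(paths[i], paths[j]):
                if a != b:
                    break
                d += 1
            total += d
    return total


def leaf_depths_direct(tree: mb.RootedTree) -> list[int]:
    """Leaf depths via explicit path walking (independent of sequences)."""
    out: list[int] = []

    def walk(t: mb.RootedTree, d: int) -> None:
        if t.is_leaf:
            out.append(d)
        for c in t.children:
            walk(c, d + 1)

    walk(tree, 0)
    return sorted(out)
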