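# Methods

## Model

A *rooted tree shape* is an isomorphism class of rooted trees with no
out-degree-one vertices; `n` denotes the leaf count, `n_v` the clade size
of a vertex, `δ_x` the depth of a leaf, and `b_v = |n_{v1} − n_{v2}|` the
balance value of an inner vertex of a binary tree. Three ascending
sequences summarize the shape: the balance value sequence `B(T)` (length
n − 1, binary trees), the clade size sequence `N(T)` (length 1 for the
star tree up to n − 1 for binary trees), and the leaf depth sequence
`Δ(T)` (always length n). For the single-vertex tree, `B` and `N` are
empty and `Δ = (0)`: the sole vertex is a leaf at depth zero, which is
exactly the start value needed by the recursive leaf-depth evaluation.

The *metaconcept* of order ω sums a shape function `f` over a sequence,
optionally passing tree-level constants (leaf count, inner vertex count)
as extra arguments. An empty sequence sums to zero. Sums are over at
most n well-scaled terms, so the recursive and direct evaluations are
compared at 1e-9 relative tolerance, and argmin/argmax grouping in the
enumeration reports uses 1e-9 relative closeness.

Each sequence satisfies a standard-decomposition recursion over the
maximal pending subtrees of the root (`B`: merge children's sequences
plus the root balance value; `N`: merge plus n; `Δ`: merge shifted by
one), implemented with an order-preserving merge (`ordered_union`) and a
shift operator. The induced recursions evaluate the metaconcepts without
materializing sequences; for the leaf depth metaconcept this requires an
affine `f` with zero intercept (`Φ^Δ` is local/recursive only in the
affine case), which is verified either from the declared family or by
probing f on a small integer grid.

## Special trees and canonical form

Constructors are provided for the caterpillar (unique cherry), fully
balanced tree of height h, maximally balanced tree (recursive
⌈n/2⌉/⌊n/2⌋ split; the split side is irrelevant up to isomorphism but
fixed for determinism), greedy-from-the-bottom tree, and star tree. The
gfb-tree is built by repeatedly joining the two pooled trees of minimal
leaf count; ties are broken by lexicographically smallest canonical key,
which is immaterial for the isomorphism class — the tests cross-check
the greedy construction against the independent cherry-attachment
construction (fb-tree of height h_n − 1 with p = n − 2^{h_n−1} cherries
attached left to right) for every n ≤ 64.

Children are stored in a sorted canonical order, so structural equality
is isomorphism and `canonical_key` is a by-product of construction (a
nested-parenthesis string built from recursively sorted child
encodings). Vertex handles are indices into the root-first traversal of
this canonical order; `replace_subtree` re-canonicalizes, so handles are
stable within a tree but not across an edit.

Throughout, `h_n = ⌈log2 n⌉`. This single reading makes the minimal
Sackin value `−2^{h_n} + n(h_n + 1)`, the minimal Colless value
`c_n = Σ_{i=1}^{h_n−1} 2^i s(n/2^i)` (s = distance to the nearest
integer) and the leaf-depth minimum `(2^{h_n−1} − p) f(h_n−1) + 2p f(h_n)`
mutually consistent, and all three are validated against brute-force
enumeration.

## Enumeration as oracle

`enumerate_binary_shapes(n)` builds one representative per isomorphism
class from unordered pairs of memoized smaller shapes (counts follow the
Wedderburn–Etherington numbers; the test suite checks n ≤ 13, i.e. up to
983 shapes). `enumerate_arbitrary_shapes(n)` does the same over
multisets of subtrees indexed by the partitions of n (checked against an
independent multiset-counting recurrence for n ≤ 8, i.e. up to 261
shapes). Every extremal-tree statement in the package is asserted twice:
once through its closed form and once by scanning these enumerations.
Default working bounds are n ≤ 12 binary / n ≤ 8 arbitrary (configurable
per call; the CLI caps enumeration at 15/10). These bounds keep the full
suite in the low seconds while still covering every minimal
counterexample the theory predicts, e.g. the smallest pair of distinct
binary shapes with equal balance value sequences but different clade
size sequences, which first occurs at n = 13.

## Subtree counts

`gfb_n(i)` uses the four-case closed form in terms of h_i = ⌈log2 i⌉ and
n mod 2^{h_i−1}; it is tested against direct counts on the constructed
gfb-tree for all n ≤ 64. For the mb-tree no legible closed form is
asserted; `mb_subtree_count` counts clade sizes on the constructed tree,
which is exact by definition, and the level remainder
`r_l^n = n − 2^l⌊n/2^l⌋` of the underlying decomposition is exposed as a
helper.

## Function certification

Metaconcepts only ever evaluate f at integers up to n, so monotonicity
and convexity are certified by exact finite differences on an integer
grid (default bound 256) rather than symbolically; each certificate
records the grid it was established on. Strictness tolerance is 0 when
all sampled values are integers and 1e-12 relative otherwise. Affine
functions are detected by a constant first difference (slope and
intercept recovered), or read exactly from a declared `affine(m, a)`
family. Functions whose natural domain starts above 0 (log(x − 1) at 2,
log2 at 1) carry a `domain_min` and are scanned from there; evaluating a
metaconcept at a sequence entry below `domain_min` raises an error
naming the entry.

Custom functions from the CLI are compiled from a whitelisted arithmetic
expression grammar over `x`, `n`, `ninner` (with conditionals for
piecewise definitions); no attribute access, subscripts or free names
are admitted, so the CLI cannot be used to execute code.

## Extremal logic

Maximum values always come from the caterpillar's explicit sequences
(`B = (0,…,n−2)`, `N = (2,…,n)`, `Δ = (1,…,n−1,n−1)`). Minimum values
dispatch on the certificate: fully balanced tree at powers of two;
mb-tree via `c_n` (balance values) or `mb_n(i)` (clade sizes) for convex
f; gfb-tree via `gfb_n(i)` for strictly concave f; the Sackin/Colless
argmin sets for affine f; the star tree on arbitrary domains (f(n) for
2-positive f under clade sizes, n·f(1) for increasing f under leaf
depths). When no family applies (e.g. the piecewise f3, increasing but
neither convex nor concave), the report falls back to enumeration rather
than asserting a formula — this is precisely the regime where the
fb-tree can fail to be the minimizer.

The Sackin argmin set is generated constructively (all shapes whose leaf
depths lie in {h_n − 1, h_n}, built level by level and deduplicated by
canonical key) and cross-checked against the enumeration filter; the
Colless argmin set is obtained from it by filtering on `C(T) = c_n`,
which is sound because every Colless minimizer also minimizes Sackin.

`equivalent_on` applies the ranking-equivalence definition literally:
two indices are equivalent at n when every strict inequality of one is
a strict inequality (same direction) of the other over all enumerated
shape pairs. Because the definition is silent on ties, the report also
states whether the tie sets coincide.

Locality (replacing a pending subtree changes the index by exactly the
subtree difference) is proved in the theory and *verified* here by
seeded randomized replacement trials (default 100), with a concrete
counterexample witness (all four trees as Newick) returned on failure.
Random trees are drawn by recursive uniform splits — not uniform over
shapes, which is irrelevant for identity checks but noted for users.

## CLI and fixtures

The `metabalance` CLI is a thin dispatch layer: `make`, `seq`, `index`,
`phi`, `extremes`, `coincidence`, `recommend`, `check`, `fixtures`.
Output is TSV with a commented header echoing the version and
configuration; logging goes to stderr. `generate_fixtures` writes
special-family and seeded random trees with a manifest of
sequence/index values computed by the direct definitions, byte-identical
across runs with the same seed.

## Limitations

- Unrooted trees, branch-length-aware statistics and phylogenetic
  networks are out of scope; balance (as opposed to imbalance) indices
  are obtainable by negation and are not separately implemented.
- Exhaustive verification is bounded (binary n ≲ 15, arbitrary n ≲ 10 by
  shape counts); statements for larger n rest on the closed forms.
- The recommendation table covers the four canonical minimizer targets
  (mb, gfb, Sackin argmin, Colless argmin); cells where the minimizer
  genuinely depends on f return an explicit "depends — use enumeration"
  verdict instead of a guess.
- Synthetic inputs (enumerated and random shapes) exercise shape space
  exhaustively at small n, but say nothing about the distribution of
  tree shapes under any evolutionary model; passing tests certify the
  combinatorial claims, not model fit to empirical phylogenies.
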