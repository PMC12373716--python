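# metabalance

Tree balance statistics for rooted trees, organized around a single idea:
most classical (im)balance indices are sums of a function *f* over one of
three ascending shape sequences of the tree. `metabalance` makes that
functional — the *metaconcept*

```
Φ^Seq_f(T) = Σ_{s ∈ Seq(T)} f(s, o₁(T), …, o_{ω−1}(T))
```

— a first-class object. `Seq(T)` is the **balance value sequence**
`B(T)` (|n_v₁ − n_v₂| over inner vertices, binary trees only), the
**clade size sequence** `N(T)` (n_v over inner vertices) or the **leaf
depth sequence** `Δ(T)` (δ_x over leaves), and the optional extra
arguments (leaf count n, inner vertex count) give metaconcepts of higher
order ω. Choosing *f* recovers the Sackin index, average leaf depth,
ŝ-shape statistic, total cophenetic index, and the Colless, corrected
Colless and quadratic Colless indices — and opens up whole families of
new indices whose extremal trees are known as a function of *f* alone.

The package is aimed at phylogenetics / tree-shape researchers who want

- the special extremal trees (caterpillar, fully balanced `fb`,
  maximally balanced `mb`, greedy-from-the-bottom `gfb`, star) as
  programmatic constructors,
- exhaustive enumeration of rooted (binary or arbitrary) shapes as a
  brute-force oracle for extremal claims,
- closed-form minimum/maximum values (via the minimal Colless value
  `c_n`, the Sackin extremes, and the subtree-size counts `gfb_n(i)`,
  `mb_n(i)`),
- certification of which function families *f* yield valid imbalance
  indices (strictly increasing; convex / strictly concave / affine;
  2-positive), together with locality and recursiveness checks, and a
  recommender that maps a desired minimizing tree to the required
  conditions on *f*.

Trees are handled purely as shapes: Newick input is accepted (labels and
branch lengths are ignored; unary vertices are collapsed with a warning),
and two trees compare equal exactly when they are isomorphic.

## Worked example

```python
import metabalance as mb

# the three binary shapes with five leaves
gfb5 = mb.greedy_from_bottom(5)          # ((cherry, leaf), cherry)
t1   = mb.RootedTree((mb.fully_balanced(2), mb.LEAF))
cat5 = mb.caterpillar(5)

f1 = mb.log_shifted(2, 0.5, 1)           # f(x) = log2(x/2 + 1)
f2 = mb.log_shifted(2, 1.5, 1)           # f(x) = log2(3x/2 + 1)
bvm = lambda f, t: mb.evaluate(mb.Metaconcept("B", f), t)

for t, name in [(gfb5, "gfb_5"), (t1, "(fb_2,leaf)"), (cat5, "cat_5")]:
    print(f"{name:12s} {bvm(f1, t):.2f} {bvm(f2, t):.2f}")
```

prints

```
gfb_5        1.17 2.64
(fb_2,leaf)  1.32 2.46
cat_5        2.91 5.78
```

Both functions are strictly increasing and strictly concave, yet the
unique minimizer of the balance value metaconcept flips from the
gfb-tree (under `f1`) to `(fb_2, leaf)` (under `f2`): for generic
concave *f* the most balanced tree genuinely depends on *f*. By
contrast a strictly convex *f* always has the mb-tree as unique
minimizer, and any affine *f* reduces to the Colless index:

```python
rep = mb.bvm_extremes(mb.from_expression("x*x"), 12)
print(rep.min_value, rep.minimizers == (mb.maximally_balanced(12).key,))
# 4 True   (c_12 = 4 unit balance values, each contributing f(1) = 1)
```

The same queries run from the shell:

```sh
metabalance phi --seq B --f "log2(0.5*x + 1)" --tree tree.nwk
metabalance extremes --seq N --f "sqrt(x)" --n 8
metabalance recommend --domain binary --minimizer gfb
metabalance coincidence --first Beq --second Nneq
```

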