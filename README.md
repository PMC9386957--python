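# tanglefold

Prime factorization of RNA secondary structures in the Brauer monoid.

RNA secondary structures — including pseudoknotted ones — can be abstracted
to *tangles*: perfect matchings on two rows of N dots that form a monoid
B_N under diagram stacking.  The mapping drops unpaired nucleotides,
collapses each stem to a single arc (the *shape*), and folds the resulting
chord diagram in half.  Every tangle is a product of primes T_i (an
adjacent strand crossing) and U_i (an adjacent hook pair), and a *minimal*
factor word is a compact, mutation-invariant fingerprint of the fold:
stems map to U-primes, pseudoknots force T-primes, and structural elements
that cross share the T-primes that generate them.

`tanglefold` implements the whole pipeline:

* extended dot-bracket / BPSEQ parsing, shape reduction, and the fold into
  a tangle (`tanglefold.rna`);
* the diagram algebra: invariants, composition with loop counting,
  crossing numbers, classification, enumeration (`tanglefold.tangles`);
* four class-specific factorization algorithms — BubbleSort for
  permutation diagrams, a region-DAG construction for crossing-free
  (Temperley-Lieb) diagrams, and two hook heuristics — plus gen(e)
  tracking (`tanglefold.factorize`);
* a 13-rule rewriting system with a breadth-first minimizer and
  certification flag (`tanglefold.rewrite`);
* a brute-force Cayley-graph oracle for small N (`tanglefold.oracle`);
* seeded synthetic tangles and pseudoknotted structures
  (`tanglefold.synth`), and a thin CLI (`tanglefold`).

## Worked example

```python
>>> import tanglefold as tf
>>> tangle, shape, _ = tf.structure_to_tangle(tf.parse_dotbracket("(([)(])())"))
>>> tf.format_invariant(tangle)
"1:1',2:4,3:5',5:4',2':3'"
>>> word, certified, _ = tf.factorize(tangle)
>>> str(word), certified
('T3*T4*U2', True)
>>> tf.track_generators(word).to_json()["3:5'"]
['T3', 'T4']
```

The structure's five stems reduce to five arcs; the fold yields a tangle in
B_5 whose minimal factorization is T_3 ∘ T_4 ∘ U_2.  The two T-primes are
forced by the pseudoknot (the crossing edge 3:5' is generated by both),
U_2 builds the hairpin hook pair 2':3', and the vertical strand 1:1' of
the enclosing stem needs no generator at all — which is why every factor
index is ≥ 2.

The same run from the shell:

```sh
$ tanglefold map "(([)(])())"
tangle     1:1',2:4,3:5',5:4',2':3'
class      U
crossings  2
raw word   T3*T4*U2
minimized  T3*T4*U2 (minimal)
...
```

More narrative walk-throughs live in `examples/` (structure mapping,
big-hook scoring, rewrite minimization, a pseudoknot survey); each prints
the numbers it computes and one line on what they mean.

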