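# Methods

## The model

`tanglefold` treats an RNA secondary structure as a *tangle* of the Brauer
monoid B_N: a perfect matching on 2N dots arranged in two rows of N (top dots
1..N, bottom dots 1'..N').  Two tangles compose by stacking — identify the
bottom row of the first with the top row of the second, follow the strands,
and discard closed loops formed in the middle.  The discarded loops make the
composition a monoid quotient (no loop parameter), which is what validates
idempotence laws such as U_i ∘ U_i = U_i; the loop count is still returned
for diagnostics.

The monoid is generated by 2(N−1) primes: T_i (the adjacent crossing of
strands i, i+1) and U_i (the adjacent hook pair i:(i+1) on top and
i':(i+1)' below).  Every tangle is a composition of primes; the
*factorization problem* asks for a shortest such word.

Edges are classified as positive/negative/zero transversals (top-to-bottom)
or upper/lower hooks (within a row), with size |e| = |a − b|.  The
*crossing number* is defined combinatorially, not by drawing: two edges
cross iff their endpoints interleave in the cyclic boundary order
1..N, N', (N−1)', .., 1'.  This is the minimal number of crossings over all
drawings, is computable in O(N²), and for permutation diagrams reduces to
the inversion count.

## From RNA to tangle

1. Parse extended dot-bracket (pages `()`, `[]`, `{}`, `<>`, `Aa`..`Zz`,
   each matched by stack discipline) or BPSEQ.
2. Drop unpaired nucleotides; re-index the 2N paired positions.
3. Collapse stacked arcs to one arc per stem ("shape").  Stacking is tested
   in the paired-only index space, so bulges and interior loops never break
   a stem.
4. Fold the shape like closing a book: dot k ≤ N becomes top dot k, dot
   N+m becomes bottom dot (N−m+1)'.

The book-fold orientation is a genuine design choice: the geometric
description ("rotate the second half above the first") does not fix it
algebraically.  The mirrored convention (N+m → m') was tried and rejected —
it does not reproduce the worked pseudoknotted-tRNA example (it yields a
different tangle with a length-6 word instead of T_3 ∘ T_4 ∘ U_2), while
the book-fold reproduces it exactly, so the book-fold is the only
convention shipped.

Because unpaired bases are dropped and stems collapsed, the tangle is
invariant under synonymous mutations (insertion of unpaired bases,
stem widening); this is property-tested over random edits.

## Factorization

Tangles are labelled with a single class with precedence T → TL → U → H
(the underlying classes overlap; a crossing-free tangle with hooks would
also qualify as U, and the dispatcher needs one label):

* **T (all transversal):** BubbleSort of the bottom row; each adjacent swap
  at position i emits T_i.  Word length = inversion count = crossing
  number, hence minimal.
* **TL (crossing-free):** region decomposition.  Vertical lines through the
  dots cut the rectangle into N−1 columns; the strand segments crossing a
  column are vertically ordered (for a crossing-free diagram this order is
  the boundary order of their far-side endpoints, and every column has an
  even segment count).  Each cell at odd depth — depth = number of segments
  above it in its column — emits one U_column.  Cells are ordered by a DAG:
  top-to-bottom within a column, and from the cell above a shared arc to
  the cell below it in an adjacent column; emission follows a deterministic
  topological order (leftmost column, then topmost).  Verified minimal
  against the brute-force oracle for every crossing-free tangle at N ≤ 5.
* **U (size-1 lower hook at i):** write X = X′ ∘ U_i by merging the hook
  with a partner edge e.  Merge rule: for hooks and negative/zero
  transversals, a = e₁:i′ and b = (i+1)′:e₂; for positive transversals the
  hook ends swap roles.  Endpoint roles (hooks ascending; transversals top
  dot first) and the treatment of zero transversals as negative are fixed
  by requiring the worked merges (with partners 2:4 and 4:1′ in the two
  published runs) to reproduce their printed results.  The partner is
  chosen among edges meeting both imaginary verticals i:i′ and
  (i+1):(i+1)′ (a shared dot counts as one meeting per vertical), keeping
  only merges that preserve the crossing number; ties go to the candidate
  with fewest crossings in X, then canonical edge order.  Preservation of
  the crossing number is asserted on every invocation; if no candidate
  preserves it, a diagnostic `HeuristicError` is raised rather than
  degrading silently (no such failure has been observed on exhaustive
  B_3..B_5 or random N = 8 samples).
* **H (only big lower hooks):** shrink the smallest lower hook
  h = i′:(i+k)′ (ties: leftmost) to size 1 by composing with
  L = T_i..T_{i+j−2} and R = T_{i+k−1}..T_{i+j} (descending).  The
  location j is scored by the summed size change of the edges with bottom
  endpoints strictly inside the hook; minimal sum wins, ties to the lowest
  location, making the run deterministic while agreeing with the published
  choice.  The reverse word (L∘R)⁻¹ is appended to the factorization.  The
  displayed form of R in the source material contains an index repetition
  that cannot be literal; the indices used here were reverse-engineered
  from the published five-row scoring table and reproduce it cell by cell.

The dispatcher loops (H can reappear after merges create new wide hooks),
guarded by an iteration cap of 4N²+8.

## Word minimization

Ten delete rules strictly shorten a word (T_iT_i = I, U_iU_i = U_i,
T_iU_i = U_iT_i = U_i, and six adjacent-index sandwich rules), three move
rules preserve length (braid moves T_iT_jT_i = T_jT_iT_j,
T_iU_jT_i = T_jU_iT_j for |i−j| = 1, and far commutation P_iP_j = P_jP_i
for |i−j| > 1).  All thirteen are re-verified by composition in tests.

Greedy deletion is **not** confluent: from the worked reduction input, the
legal early delete T_2∘U_1∘U_2 → T_1∘U_2 leads to a length-6 word whose
move-closure admits no further delete, while the true minimum is 5.
`minimize` therefore runs a breadth-first search over the full rewrite
graph (moves and deletes together, exact-word deduplication) under a state
budget (default 10⁵ expansions).  Rewrites never lengthen a word, so the
reachable set is finite.  The result is the shortest word seen,
tie-broken by the lexicographically least representative (letter order:
index, then T before U — which coincides with the far-commutation
canonical form); when no shorter word exists the input is returned
verbatim, so already-minimal words pass through untouched.
`certified_minimal` is set only when the whole graph was exhausted within
budget; exhaustion degrades the flag, never the correctness of the word.
On exhaustive B_4 and B_5 the search always certifies and always reaches
the brute-force minimum.

The independent standard is a BFS over the Cayley graph from the identity
(right-multiplication by all primes), exact for N ≤ 5 (|B_5| = 945).

## Generator tracking

gen(e) is computed by tracing each strand of the layered composition of a
word: a strand picks up factor occurrence (t, P_t) exactly when it runs
along one of that prime's non-identity edges (the two crossing transversals
of a T_i, the two hooks of a U_i).  Crossing edges always share a T
occurrence (property-tested on random minimal words); the T-count of the
pipeline's minimal words equals the crossing number (exhaustive B_3/B_4).
Note the latter is a property of the factorizer's words, not of every
shortest word: the oracle can return equally short words that spend extra
T's (e.g. U_2T_1T_3U_2 for the crossing-free tangle 1:4,2:3,1′:4′,2′:3′).

## Synthetic data

`random_tangle` composes a seeded random prime word (default n = 8, length
8 in stress tests), so every sample is factorizable by construction.
`random_structure` emulates secondary-structure motifs: a random nesting of
stems (default 4; 1–6 in the test sweeps) expanded to helices of 1–3 base
pairs with unpaired runs of 0–3 between elements (hairpins, bulges,
multiloops arise from the nesting), plus an optional count of pseudoknot
arcs, each inserted with one endpoint strictly inside a chosen stem's span
and one outside, guaranteeing at least one crossing.  The generator does
not emulate thermodynamics, base-pair probabilities, or naturally observed
stem-length distributions; passing tests therefore demonstrate the
combinatorial laws (pseudoknot ⇔ crossing ⇔ T-prime, synonymous-mutation
invariance), not predictive claims about real RNA ensembles.  Identical
seeds reproduce identical outputs.

## Problem sizes and numerical choices

Exhaustive verification covers B_3 (15), B_4 (105) and B_5 (945 tangles);
random sweeps use N = 7–8 with words up to length 13 and 500 seeded
structures per law.  These sizes complete the whole suite in well under a
minute while the double-factorial growth of |B_N| makes N = 6 the natural
stopping point for exhaustive work.  All tie-breaks (leftmost hook, lowest
location, canonical edge order, lexicographic word order) are fixed and
deterministic; given the same input and budget, every function of the
package is bit-reproducible, and the CLI's JSON output is byte-identical
across runs.

## Known limitations

* The merge heuristic is not proven to always find a crossing-preserving
  partner; failures raise a diagnostic error (none observed).
* Minimality certification has unbounded lookahead in principle; the
  budget makes the limitation explicit via `certified_minimal` rather than
  hiding it.
* The Brauer *algebra* (linear combinations, loop parameter δ) and
  knot-theoretic invariants beyond the crossing count are out of scope, as
  is structure prediction itself: the package analyzes given structures.
* An alternative mapping in which pseudoknots become crossings between stem
  edges (rather than edges of their own) is deliberately not implemented.
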