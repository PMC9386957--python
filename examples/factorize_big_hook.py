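"""Factorize a big-hook tangle, showing the shrink-location scoring.

A tangle whose only lower hooks are wide cannot shed a U-prime directly: the
hook is first shrunk to size 1 by composing with T-primes.  The scorer below
rates every shrinkage location by how much the sizes of the edges inside the
hook would grow; the cheapest location (ties: lowest index) is used.
"""

from tanglefold import factorize, format_edge, parse_invariant, score_shrink_locations

INVARIANT = "1:2,4:1',3:3',7:4',6:5',5:6',2':7'"

x = parse_invariant(INVARIANT)
print(f"tangle {INVARIANT}  (lower hook 2':7' of size 5)\n")
print("location  per-edge size change                sum  shrink word")
for s in score_shrink_locations(x, (-2, -7)):
    deltas = ", ".join(f"{format_edge(e)}:{d:+d}" for e, d in s.per_edge_delta.items())
    print(f"   {s.location}      {deltas:38s} {s.sum:+d}   {s.factors}")

word, certified, _ = factorize(x)
print(f"\nfull factorization: {word}  (length {len(word)}, certified minimal: {certified})")
print("The first four T-primes of the tail are the reverse of the location-1")
print("shrink word; the rest is two hook merges (U1, U2) and a BubbleSort of")
print("the remaining permutation.")
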