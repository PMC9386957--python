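"""Ground-truth minimal factorizations for small monoids.

Breadth-first search from the identity over the Cayley graph of the monoid on
2N dots (right-multiplication by the 2(N-1) primes) gives, for every one of
the (2N-1)!! tangles, a provably shortest factor word.  This brute-force
standard is what the heuristic pipeline is tested against; it scales only to
N of about 5 (|B_5| = 945) and is never used as the production path.
"""

from __future__ import annotations

from collections import deque
from functools import lru_cache

from .tangles import (
    FactorList,
    PrimeFactor,
    Tangle,
    compose,
    format_invariant,
    identity,
    prime,
    T,
    U,
)

DEFAULT_ORACLE_BOUND = 5


@lru_cache(maxsize=8)
def cayley_index(n: int) -> dict[str, tuple[int, tuple[PrimeFactor, ...]]]:
    """Map every invariant string in the monoid to (minimal length, one
    shortest word), computed by BFS from the identity."""
    primes = [(T(i), prime("T", i, n)) for i in range(1, n)] + [
        (U(i), prime("U", i, n)) for i in range(1, n)
    ]
    start = identity(n)
    dist: dict[str, tuple[int, tuple[PrimeFactor, ...]]] = {
        format_invariant(start): (0, ())
    }
    queue: deque[tuple[Tangle, tuple[PrimeFactor, ...]]] = deque([(start, ())])
    while queue:
        x, word = queue.popleft()
        for sym, p in primes:
            y, _ = compose(x, p)
            key = format_invariant(y)
            if key not in dist:
                dist[key] = (len(word) + 1, word + (sym,))
                queue.append((y, word + (sym,)))
    return dist


def bfs_minimal_word(x: Tangle, bound: int = DEFAULT_ORACLE_BOUND) -> FactorList:
    """A shortest prime word composing to ``x`` (exact, exhaustive BFS)."""
    if x.n > bound:
        raise ValueError(f"oracle bound is n<={bound}, got n={x.n}")
    _, word = cayley_index(x.n)[format_invariant(x)]
    return FactorList(x.n, word)


def minimal_length(x: Tangle, bound: int = DEFAULT_ORACLE_BOUND) -> int:
    if x.n > bound:
        raise ValueError(f"oracle bound is n<={bound}, got n={x.n}")
    return cayley_index(x.n)[format_invariant(x)][0]
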