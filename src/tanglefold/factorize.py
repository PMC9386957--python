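"""Class-specific factorization of tangles into prime words.

The dispatcher peels prime factors from the right until the identity is
reached, choosing the algorithm by tangle class:

* permutation diagrams (all-transversal) are sorted by adjacent swaps
  (BubbleSort), emitting one ``T_i`` per inversion — provably minimal;
* crossing-free (Temperley-Lieb) diagrams go through the region/DAG
  construction, emitting one ``U_i`` per odd-depth region — minimal;
* tangles with a size-1 lower hook at i are written ``X = X' . U_i`` by
  merging the hook with a crossing-preserving partner edge (Heuristic 1);
* "big hook" tangles are first composed with T-primes that shrink the
  smallest lower hook to size 1 at the cheapest location (Heuristic 2).

The heuristic outputs are not always minimal; callers normally follow with
:func:`tanglefold.rewrite.minimize`.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass

from .rewrite import DEFAULT_BUDGET, RewriteTrace, minimize
from .tangles import (
    EdgeKind,
    FactorList,
    PrimeFactor,
    Tangle,
    TangleClass,
    boundary_position,
    canonical_edge,
    classify,
    compose,
    crossing_number,
    edge_kind,
    edge_size,
    edges_cross,
    format_edge,
    format_invariant,
    prime,
    T,
    U,
    _dot_key,
)


class HeuristicError(RuntimeError):
    """Raised when the size-1-hook merge heuristic finds no crossing-preserving
    candidate; carries the tangle under factorization for diagnosis."""

    def __init__(self, message: str, tangle: Tangle):
        super().__init__(f"{message} (tangle {format_invariant(tangle)})")
        self.tangle = tangle


# ---------------------------------------------------------------------------
# permutation diagrams


def sort_transversals(x: Tangle) -> FactorList:
    """BubbleSort factorization of an all-transversal tangle.

    The bottom row, read as a permutation, is sorted by adjacent swaps; a swap
    at position i emits ``T_i``.  The word (in emission order) composes to
    ``x`` and its length equals the inversion count = crossing number.
    """
    if classify(x) is not TangleClass.T_TANGLE:
        raise ValueError("sort_transversals requires an all-transversal tangle")
    row = [-x.partner(k) for k in range(1, x.n + 1)]
    word: list[PrimeFactor] = []
    swapped = True
    while swapped:
        swapped = False
        for k in range(x.n - 1):
            if row[k] > row[k + 1]:
                row[k], row[k + 1] = row[k + 1], row[k]
                word.append(T(k + 1))
                swapped = True
    return FactorList(x.n, tuple(word))


# ---------------------------------------------------------------------------
# crossing-free (Temperley-Lieb) diagrams


def _column_segments(x: Tangle, c: int) -> list[tuple[int, int]]:
    """Edges crossing the vertical strip between dots c and c+1, top-to-bottom.

    An edge crosses the strip iff exactly one endpoint lies on the far side of
    the cut chord; for a crossing-free diagram the vertical order of the
    segments equals the boundary order of their far-side endpoints.
    """
    lo, hi = c, 2 * x.n - c - 1
    segs = []
    for e in x.edges:
        inside = [boundary_position(d, x.n) for d in e if lo <= boundary_position(d, x.n) <= hi]
        if len(inside) == 1:
            segs.append((inside[0], e))
    segs.sort()
    return [e for _, e in segs]


def ernst_factorize(x: Tangle) -> FactorList:
    """Region-DAG factorization of a crossing-free tangle into U-primes.

    The diagram is cut into N-1 column strips by vertical lines through the
    dots.  Within a column the strand segments stack top-to-bottom; the cells
    between them at odd depth (counted from the top of the column) each emit
    one ``U_column``.  Odd cells are ordered by a DAG: top-to-bottom within a
    column, and across adjacent columns from the cell above a shared arc to
    the cell below it; any topological order gives a minimal word, read here
    left-to-right with ties broken top-to-bottom.
    """
    if crossing_number(x) != 0:
        raise ValueError("ernst_factorize requires a crossing-free tangle")
    if classify(x) is TangleClass.T_TANGLE:
        return FactorList(x.n)
    columns = {c: _column_segments(x, c) for c in range(1, x.n)}
    nodes = [
        (c, k)
        for c, segs in columns.items()
        for k in range(1, len(segs), 2)  # odd depth == odd number of segments above
    ]
    above = {(c, k): columns[c][k - 1] for c, k in nodes}
    below = {(c, k): columns[c][k] for c, k in nodes}
    succs: dict[tuple[int, int], list[tuple[int, int]]] = {v: [] for v in nodes}
    indeg = {v: 0 for v in nodes}

    def add_edge(u, v):
        succs[u].append(v)
        indeg[v] += 1

    for c, segs in columns.items():
        odd = [k for k in range(1, len(segs), 2)]
        for a, b in zip(odd, odd[1:]):
            add_edge((c, a), (c, b))
    for c, k in nodes:
        for c2 in (c - 1, c + 1):
            for k2 in range(1, len(columns.get(c2, ())), 2):
                if below[(c, k)] == above[(c2, k2)]:
                    add_edge((c, k), (c2, k2))
    ready = [v for v in nodes if indeg[v] == 0]
    heapq.heapify(ready)
    word: list[PrimeFactor] = []
    while ready:
        v = heapq.heappop(ready)
        word.append(U(v[0]))
        for s in succs[v]:
            indeg[s] -= 1
            if indeg[s] == 0:
                heapq.heappush(ready, s)
    if len(word) != len(nodes):
        raise RuntimeError("region DAG is cyclic; diagram was not crossing-free")
    return FactorList(x.n, tuple(word))


# ---------------------------------------------------------------------------
# size-1 lower hooks (Heuristic 1)


def merge_hook(x: Tangle, h: tuple[int, int], e: tuple[int, int]) -> Tangle:
    """Remove lower hook ``h = i':(i+1)'`` and edge ``e``, reconnecting their
    endpoints: for hooks and negative/zero transversals ``a = e1:i'`` and
    ``b = (i+1)':e2``; for positive transversals the hook ends swap roles.
    Endpoint roles: hooks keep ascending order, transversals take the top dot
    as ``e1``.
    """
    h = canonical_edge(*h)
    if h not in x.edges or edge_kind(h) is not EdgeKind.LOWER_HOOK or edge_size(h) != 1:
        raise ValueError(f"{format_edge(h)} is not a size-1 lower hook of the tangle")
    e = canonical_edge(*e)
    if e == h or e not in x.edges:
        raise ValueError(f"edge {format_edge(e)} not available for merging")
    i = -h[0] if -h[0] < -h[1] else -h[1]
    kind = edge_kind(e)
    if kind in (EdgeKind.UPPER_HOOK, EdgeKind.LOWER_HOOK):
        e1, e2 = sorted(e, key=_dot_key)
    else:
        e1, e2 = (e[0], e[1]) if e[0] > 0 else (e[1], e[0])
    if kind is EdgeKind.POSITIVE:
        a, b = (e1, -(i + 1)), (e2, -i)
    else:
        a, b = (e1, -i), (-(i + 1), e2)
    pairs = set(x.edges) - {h, e}
    pairs |= {canonical_edge(*a), canonical_edge(*b)}
    return Tangle(x.n, frozenset(pairs))


def _inter_with_verticals(x: Tangle, e: tuple[int, int], i: int) -> int:
    """Number of imaginary vertical edges in I = {i:i', i+1:(i+1)'} that e
    meets; sharing a dot with a vertical counts as meeting it."""
    count = 0
    for v in ((i, -i), (i + 1, -(i + 1))):
        if v[0] in e or v[1] in e or edges_cross(e, v, x.n):
            count += 1
    return count


def _crossings_of_edge(x: Tangle, e: tuple[int, int]) -> int:
    return sum(1 for f in x.edges if f != e and edges_cross(e, f, x.n))


def heuristic1_step(x: Tangle) -> tuple[Tangle, PrimeFactor]:
    """Peel one ``U_i`` from a tangle with a size-1 lower hook at i.

    Among the edges meeting both imaginary verticals ``i:i'`` and
    ``(i+1):(i+1)'``, merge the hook with one whose merge preserves the
    crossing number; ties go to the candidate with the fewest crossings in
    ``x``, then to canonical edge order.  Returns ``(x', U_i)`` with
    ``x' . U_i = x``.
    """
    hooks = [h for h in x.lower_hooks() if edge_size(h) == 1]
    if not hooks:
        raise ValueError("heuristic1_step requires a size-1 lower hook")
    h = min(hooks, key=lambda hk: min(-hk[0], -hk[1]))  # leftmost
    i = min(-h[0], -h[1])
    c = crossing_number(x)
    candidates = [
        e for e in x.edges if e != h and _inter_with_verticals(x, e, i) == 2
    ]
    best = None
    for e in sorted(candidates, key=lambda e: (_dot_key(e[0]), _dot_key(e[1]))):
        merged = merge_hook(x, h, e)
        if crossing_number(merged) != c:
            continue
        key = _crossings_of_edge(x, e)
        if best is None or key < best[0]:
            best = (key, e, merged)
    if best is None:
        raise HeuristicError(
            f"no crossing-preserving merge candidate for lower hook {format_edge(h)}", x
        )
    merged = best[2]
    recomposed, _ = compose(merged, prime("U", i, x.n))
    assert recomposed == x, "merge did not invert the U-prime"
    return merged, U(i)


# ---------------------------------------------------------------------------
# big lower hooks (Heuristic 2)


@dataclass(frozen=True)
class ShrinkScore:
    """Cost of shrinking a big lower hook into one location.

    ``per_edge_delta`` maps each edge with a bottom endpoint strictly inside
    the hook to its size change; ``factors`` is the T-word L.R that performs
    the shrink when composed to the right of the tangle.
    """

    location: int
    per_edge_delta: dict[tuple[int, int], int]
    sum: int
    factors: FactorList


def _shrink_word(i: int, k: int, j: int, n: int) -> tuple[FactorList, FactorList]:
    left = FactorList(n, tuple(T(m) for m in range(i, i + j - 1)))
    right = FactorList(n, tuple(T(m) for m in range(i + k - 1, i + j - 1, -1)))
    return left, right


def _bottom_relabel(word: FactorList, n: int) -> dict[int, int]:
    perm = {b: b for b in range(1, n + 1)}
    out = {}
    for b in range(1, n + 1):
        cur = b
        for f in word:
            if cur == f.i:
                cur = f.i + 1
            elif cur == f.i + 1:
                cur = f.i
        out[b] = cur
    return out


def score_shrink_locations(x: Tangle, h: tuple[int, int]) -> list[ShrinkScore]:
    """Score every shrinkage location of a lower hook ``h = i':(i+k)'``.

    Location j (1-based, j = 1..k) shrinks the hook to ``(i+j-1)':(i+j)'`` by
    composing with ``L = T_i..T_{i+j-2}`` and ``R = T_{i+k-1}..T_{i+j}``
    (descending); the score sums the size changes of the edges whose bottom
    endpoints lie strictly inside the hook.
    """
    h = canonical_edge(*h)
    if edge_kind(h) is not EdgeKind.LOWER_HOOK or edge_size(h) < 2:
        raise ValueError(f"{format_edge(h)} is not a lower hook of size > 1")
    i, top_end = sorted((-h[0], -h[1]))
    k = top_end - i
    inside = set(range(i + 1, i + k))
    tracked = [
        e for e in x.sorted_edges()
        if any(d < 0 and -d in inside for d in e)
    ]
    scores = []
    for j in range(1, k + 1):
        left, right = _shrink_word(i, k, j, x.n)
        word = left.concat(right)
        relabel = _bottom_relabel(word, x.n)
        deltas = {}
        for e in tracked:
            new = tuple(d if d > 0 else -relabel[-d] for d in e)
            deltas[e] = edge_size(new) - edge_size(e)
        scores.append(ShrinkScore(j, deltas, sum(deltas.values()), word))
    return scores


def heuristic2_step(x: Tangle) -> tuple[Tangle, FactorList]:
    """Turn a big-hook tangle into one with a size-1 lower hook.

    The smallest lower hook (ties: leftmost) is shrunk at the location with
    the minimal score sum (ties: lowest location index).  Returns
    ``(x', appended)`` with ``x = x' . appended`` where ``appended`` is the
    reverse of the shrink word.
    """
    if classify(x) is not TangleClass.H_TANGLE:
        raise ValueError("heuristic2_step requires a big-hook tangle")
    hooks = x.lower_hooks()
    h = min(hooks, key=lambda hk: (edge_size(hk), min(-hk[0], -hk[1])))
    scores = score_shrink_locations(x, h)
    best = min(scores, key=lambda s: (s.sum, s.location))
    shrunk = x
    for f in best.factors:
        shrunk, _ = compose(shrunk, f.tangle(x.n))
    appended = best.factors.inverse()
    assert any(
        edge_kind(e) is EdgeKind.LOWER_HOOK and edge_size(e) == 1 for e in shrunk.edges
    ), "shrink did not produce a size-1 lower hook"
    return shrunk, appended


# ---------------------------------------------------------------------------
# dispatcher


def factorize_raw(x: Tangle) -> FactorList:
    """Dispatcher loop: peel factors from the right until a terminal class.

    The result composes to ``x`` but is not guaranteed minimal; apply
    :func:`tanglefold.rewrite.minimize` (or use :func:`factorize`).
    """
    suffix: tuple[PrimeFactor, ...] = ()
    cur = x
    for _ in range(4 * x.n * x.n + 8):
        cls = classify(cur)
        if cls is TangleClass.T_TANGLE:
            return FactorList(x.n, sort_transversals(cur).word + suffix)
        if cls is TangleClass.TL_TANGLE:
            return FactorList(x.n, ernst_factorize(cur).word + suffix)
        if cls is TangleClass.U_TANGLE:
            cur, u = heuristic1_step(cur)
            suffix = (u,) + suffix
        else:
            cur, appended = heuristic2_step(cur)
            suffix = appended.word + suffix
    raise HeuristicError("factorization did not terminate", x)


def factorize(
    x: Tangle, budget: int = DEFAULT_BUDGET
) -> tuple[FactorList, bool, RewriteTrace]:
    """Factorize and minimize; returns ``(word, certified_minimal, trace)``."""
    raw = factorize_raw(x)
    return minimize(raw, budget=budget)


# ---------------------------------------------------------------------------
# generator tracking


@dataclass(frozen=True)
class GeneratorMap:
    """For each edge of the composed tangle, the prime occurrences that
    generate it: gen(e) = factors whose non-identity strands lie on e's path
    through the layered composition."""

    n: int
    word: FactorList
    edges: dict[tuple[int, int], frozenset[tuple[int, PrimeFactor]]]

    def factor_set(self, edge: tuple[int, int]) -> set[PrimeFactor]:
        return {f for _, f in self.edges[canonical_edge(*edge)]}

    def occurrences(self, edge: tuple[int, int]) -> set[tuple[int, PrimeFactor]]:
        return set(self.edges[canonical_edge(*edge)])

    def to_json(self) -> dict[str, list[str]]:
        return {
            format_edge(e): [str(f) for _, f in sorted(occ)]
            for e, occ in sorted(self.edges.items())
        }


def track_generators(f: FactorList) -> GeneratorMap:
    """Trace every strand of ``compose_factors(f)`` through the prime layers.

    Layer t of the stack is the diagram of factor t; a strand picks up factor
    t exactly when it runs along one of that prime's non-identity edges (the
    two crossing transversals of a ``T_i``, the two hooks of a ``U_i``).
    Zero-transversal pass-throughs contribute nothing.
    """
    n, k = f.n, len(f)
    segs: list[tuple[tuple, tuple, int, bool]] = []  # (node, node, layer pos, core?)
    for t, p in enumerate(f, start=1):
        i = p.i
        for m in range(1, n + 1):
            if m in (i, i + 1):
                continue
            segs.append(((t - 1, m), (t, m), t, False))
        if p.kind == "T":
            segs.append(((t - 1, i), (t, i + 1), t, True))
            segs.append(((t - 1, i + 1), (t, i), t, True))
        else:
            segs.append(((t - 1, i), (t - 1, i + 1), t, True))
            segs.append(((t, i), (t, i + 1), t, True))
    incident: dict[tuple, list[int]] = {}
    for idx, (u, v, _, _) in enumerate(segs):
        incident.setdefault(u, []).append(idx)
        incident.setdefault(v, []).append(idx)
    used = [False] * len(segs)
    word_list = list(f.word)
    out: dict[tuple[int, int], frozenset[tuple[int, PrimeFactor]]] = {}
    for d in range(1, n + 1):
        for start in ((0, d), (k, d)):
            if not any(not used[s] for s in incident.get(start, [])):
                continue
            node = start
            gens: set[tuple[int, PrimeFactor]] = set()
            while True:
                nxt = next(s for s in incident[node] if not used[s])
                used[nxt] = True
                u, v, t, core = segs[nxt]
                if core:
                    gens.add((t, word_list[t - 1]))
                node = v if u == node else u
                if node[0] in (0, k):
                    break
            a = start[1] if start[0] == 0 else -start[1]
            b = node[1] if node[0] == 0 else -node[1]
            out[canonical_edge(a, b)] = frozenset(gens)
    if k == 0:
        out = {canonical_edge(d, -d): frozenset() for d in range(1, n + 1)}
    return GeneratorMap(n, f, out)
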