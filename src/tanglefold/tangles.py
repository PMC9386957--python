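"""Brauer-monoid diagram algebra.

The central object is the *tangle*: a perfect matching on ``2N`` dots arranged
in two rows of ``N`` (top dots ``1..N``, bottom dots ``1'..N'``).  Tangles form
a monoid under vertical stacking: identify the bottom row of the first diagram
with the top row of the second, follow the strands, and discard (but count) any
closed loops formed in the middle.  The monoid is generated by the primes
``T_i`` (adjacent crossing of strands i, i+1) and ``U_i`` (adjacent upper and
lower hook at i, i+1).

Dots are encoded as signed integers: ``+i`` is top dot ``i``, ``-i`` is bottom
dot ``i'``.  An edge is a pair of dots in canonical order (top dots before
bottom dots, ascending index).  The textual *invariant* of a tangle lists its
edges, e.g. ``"1:2,3:2',4:3',1':4'"``.
"""

from __future__ import annotations

import enum
import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Iterator


class ParseError(ValueError):
    """Raised on malformed invariant strings, dot-bracket or BPSEQ input."""


class EdgeKind(enum.Enum):
    POSITIVE = "positive"      # transversal a:b' with a > b
    NEGATIVE = "negative"      # transversal a:b' with a < b
    ZERO = "zero"              # vertical transversal a:a'
    UPPER_HOOK = "upper_hook"  # a:b, both in the top row
    LOWER_HOOK = "lower_hook"  # a':b', both in the bottom row


class TangleClass(enum.Enum):
    """Factorization class of a tangle (single label, fixed precedence).

    T_TANGLE   all edges transversal (a permutation diagram);
    TL_TANGLE  crossing-free (Temperley-Lieb), factorizable by U-primes alone;
    U_TANGLE   has a size-1 lower hook (and at least one crossing);
    H_TANGLE   the rest: every lower hook has size > 1 ("big hook").
    """

    T_TANGLE = "T"
    TL_TANGLE = "TL"
    U_TANGLE = "U"
    H_TANGLE = "H"


def _dot_key(dot: int) -> tuple[int, int]:
    # top dots sort before bottom dots, each ascending by index
    return (0, dot) if dot > 0 else (1, -dot)


def canonical_edge(a: int, b: int) -> tuple[int, int]:
    """Return the edge (a, b) with endpoints in canonical order."""
    if a == b:
        raise ValueError(f"edge endpoints must differ, got {a!r} twice")
    return (a, b) if _dot_key(a) <= _dot_key(b) else (b, a)


def edge_kind(edge: tuple[int, int]) -> EdgeKind:
    a, b = edge
    if a > 0 and b > 0:
        return EdgeKind.UPPER_HOOK
    if a < 0 and b < 0:
        return EdgeKind.LOWER_HOOK
    top, bot = (a, -b) if a > 0 else (b, -a)
    if top > bot:
        return EdgeKind.POSITIVE
    if top < bot:
        return EdgeKind.NEGATIVE
    return EdgeKind.ZERO


def edge_size(edge: tuple[int, int]) -> int:
    """|e| = |index(a) - index(b)| (hooks always have size >= 1)."""
    a, b = edge
    return abs(abs(a) - abs(b))


def format_dot(dot: int) -> str:
    return str(dot) if dot > 0 else f"{-dot}'"


def format_edge(edge: tuple[int, int]) -> str:
    return f"{format_dot(edge[0])}:{format_dot(edge[1])}"


@dataclass(frozen=True)
class Tangle:
    """A perfect matching on the 2N dots of two rows of N.

    ``edges`` is a frozenset of N canonical dot pairs in which every dot
    occurs exactly once.
    """

    n: int
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        seen: set[int] = set()
        for a, b in self.edges:
            for d in (a, b):
                if not (1 <= abs(d) <= self.n):
                    raise ValueError(f"dot {format_dot(d)} out of range 1..{self.n}")
                if d in seen:
                    raise ValueError(f"dot {format_dot(d)} occurs in more than one edge")
                seen.add(d)
        if len(self.edges) != self.n:
            raise ValueError(f"expected {self.n} edges, got {len(self.edges)}")

    @classmethod
    def from_pairs(cls, n: int, pairs: Iterable[tuple[int, int]]) -> "Tangle":
        return cls(n, frozenset(canonical_edge(a, b) for a, b in pairs))

    def partner(self, dot: int) -> int:
        for a, b in self.edges:
            if a == dot:
                return b
            if b == dot:
                return a
        raise KeyError(dot)

    def sorted_edges(self) -> list[tuple[int, int]]:
        return sorted(self.edges, key=lambda e: (_dot_key(e[0]), _dot_key(e[1])))

    def lower_hooks(self) -> list[tuple[int, int]]:
        return [e for e in self.sorted_edges() if edge_kind(e) is EdgeKind.LOWER_HOOK]

    def is_identity(self) -> bool:
        return all(a == -b for a, b in self.edges)

    def to_json(self) -> dict:
        return {"n": self.n, "edges": [list(e) for e in self.sorted_edges()]}

    @classmethod
    def from_json(cls, obj: dict) -> "Tangle":
        return cls.from_pairs(obj["n"], [tuple(e) for e in obj["edges"]])

    def __str__(self) -> str:
        return format_invariant(self)


_TOKEN = re.compile(r"^(\d+)('?)$")


def _parse_dot(token: str, context: str) -> int:
    m = _TOKEN.match(token.strip())
    if not m:
        raise ParseError(f"malformed dot {token.strip()!r} in edge {context!r}")
    idx = int(m.group(1))
    if idx == 0:
        raise ParseError(f"dot index must be >= 1 in edge {context!r}")
    return -idx if m.group(2) else idx


def parse_invariant(text: str, n: int | None = None) -> Tangle:
    """Parse an invariant string such as ``"1:2,3:2',4:3',1':4'"``.

    Bottom dots carry an ASCII apostrophe.  ``n`` is inferred from the largest
    index when not given.  Duplicate, missing or out-of-range dots raise
    :class:`ParseError` naming the offending token.
    """
    pairs: list[tuple[int, int]] = []
    seen: set[int] = set()
    for chunk in text.split(","):
        chunk = chunk.strip()
        if not chunk:
            raise ParseError("empty edge token in invariant")
        parts = chunk.split(":")
        if len(parts) != 2:
            raise ParseError(f"malformed edge {chunk!r}: expected 'a:b'")
        a = _parse_dot(parts[0], chunk)
        b = _parse_dot(parts[1], chunk)
        if a == b:
            raise ParseError(f"dot {format_dot(a)} repeated within edge {chunk!r}")
        for d in (a, b):
            if d in seen:
                raise ParseError(f"duplicate dot {format_dot(d)} in edge {chunk!r}")
            seen.add(d)
        pairs.append((a, b))
    inferred = max((abs(d) for d in seen), default=0)
    if n is None:
        n = inferred
    elif inferred > n:
        raise ParseError(f"dot index {inferred} out of range for n={n}")
    missing = [d for d in range(1, n + 1) if d not in seen] + \
              [-d for d in range(1, n + 1) if -d not in seen]
    if missing:
        raise ParseError(f"missing dot {format_dot(missing[0])} in invariant")
    return Tangle.from_pairs(n, pairs)


def format_invariant(x: Tangle) -> str:
    """Canonical invariant string; ``parse_invariant(format_invariant(x)) == x``."""
    return ",".join(format_edge(e) for e in x.sorted_edges())


def identity(n: int) -> Tangle:
    return Tangle.from_pairs(n, [(i, -i) for i in range(1, n + 1)])


def prime(kind: str, i: int, n: int) -> Tangle:
    """The prime tangle ``T_i`` or ``U_i`` in the monoid on 2n dots.

    ``T_i`` crosses strands i and i+1; ``U_i`` joins i:(i+1) on top and
    i':(i+1)' on the bottom.  Requires ``1 <= i <= n-1``.
    """
    if kind not in ("T", "U"):
        raise ValueError(f"prime kind must be 'T' or 'U', got {kind!r}")
    if not 1 <= i <= n - 1:
        raise ValueError(f"prime index {i} out of range 1..{n - 1}")
    pairs = [(k, -k) for k in range(1, n + 1) if k not in (i, i + 1)]
    if kind == "T":
        pairs += [(i, -(i + 1)), (i + 1, -i)]
    else:
        pairs += [(i, i + 1), (-i, -(i + 1))]
    return Tangle.from_pairs(n, pairs)


@dataclass(frozen=True)
class PrimeFactor:
    """A prime symbol ``T_i`` or ``U_i`` in a factor word."""

    kind: str  # "T" or "U"
    i: int

    def __post_init__(self) -> None:
        if self.kind not in ("T", "U"):
            raise ValueError(f"kind must be 'T' or 'U', got {self.kind!r}")
        if self.i < 1:
            raise ValueError(f"index must be >= 1, got {self.i}")

    def tangle(self, n: int) -> Tangle:
        return prime(self.kind, self.i, n)

    def sort_key(self) -> tuple[int, str]:
        return (self.i, self.kind)

    def __str__(self) -> str:
        return f"{self.kind}{self.i}"


def T(i: int) -> PrimeFactor:
    return PrimeFactor("T", i)


def U(i: int) -> PrimeFactor:
    return PrimeFactor("U", i)


@dataclass(frozen=True)
class FactorList:
    """An ordered word of primes over a fixed n; the empty word is the identity."""

    n: int
    word: tuple[PrimeFactor, ...] = ()

    def __post_init__(self) -> None:
        for f in self.word:
            if f.i >= self.n:
                raise ValueError(f"factor {f} requires n > {f.i}, got n={self.n}")

    @classmethod
    def from_string(cls, text: str, n: int | None = None) -> "FactorList":
        """Parse the ASCII form ``"T3*T4*U2"`` (empty string = identity word)."""
        word = []
        for tok in filter(None, (t.strip() for t in text.split("*"))):
            m = re.match(r"^([TU])(\d+)$", tok)
            if not m:
                raise ParseError(f"malformed factor token {tok!r}")
            word.append(PrimeFactor(m.group(1), int(m.group(2))))
        if n is None:
            n = max((f.i for f in word), default=0) + 1
        return cls(n, tuple(word))

    def __len__(self) -> int:
        return len(self.word)

    def __iter__(self) -> Iterator[PrimeFactor]:
        return iter(self.word)

    def __str__(self) -> str:
        return "*".join(str(f) for f in self.word)

    def inverse(self) -> "FactorList":
        """The reversed word; composing a word with its reverse gives back the
        starting tangle because every prime is (up to loops) self-inverse."""
        return FactorList(self.n, tuple(reversed(self.word)))

    def concat(self, other: "FactorList") -> "FactorList":
        if other.n != self.n:
            raise ValueError("factor lists over different n")
        return FactorList(self.n, self.word + other.word)

    def count_kind(self, kind: str) -> int:
        return sum(1 for f in self.word if f.kind == kind)

    def to_json(self) -> list[dict]:
        return [{"kind": f.kind, "i": f.i} for f in self.word]

    @classmethod
    def from_json(cls, obj: list[dict], n: int) -> "FactorList":
        return cls(n, tuple(PrimeFactor(d["kind"], d["i"]) for d in obj))


def compose(x: Tangle, y: Tangle) -> tuple[Tangle, int]:
    """Stack ``x`` on top of ``y``: identify x's bottom row with y's top row,
    follow strands between the remaining boundary dots, and return the result
    together with the number of closed middle loops that were discarded.

    The loop quotient is what makes e.g. ``U_i . U_i = U_i`` hold.
    """
    if x.n != y.n:
        raise ValueError(f"cannot compose tangles with n={x.n} and n={y.n}")
    n = x.n
    # nodes: ("t", i) x-top boundary, ("b", i) y-bottom boundary, ("m", i) middle
    edges: list[tuple[tuple, tuple]] = []
    for a, b in x.edges:
        edges.append((("t", a) if a > 0 else ("m", -a),
                      ("t", b) if b > 0 else ("m", -b)))
    for a, b in y.edges:
        edges.append((("m", a) if a > 0 else ("b", -a),
                      ("m", b) if b > 0 else ("b", -b)))
    incident: dict[tuple, list[int]] = {}
    for idx, (u, v) in enumerate(edges):
        incident.setdefault(u, []).append(idx)
        incident.setdefault(v, []).append(idx)
    used = [False] * len(edges)

    def walk(start: tuple) -> tuple:
        node = start
        while True:
            nxt = next(i for i in incident[node] if not used[i])
            used[nxt] = True
            u, v = edges[nxt]
            node = v if u == node else u
            if node[0] != "m":
                return node

    pairs = []
    for i in range(1, n + 1):
        for start in (("t", i), ("b", i)):
            if any(not used[e] for e in incident[start]):
                end = walk(start)
                a = start[1] if start[0] == "t" else -start[1]
                b = end[1] if end[0] == "t" else -end[1]
                pairs.append((a, b))
    loops = 0
    for idx in range(len(edges)):
        if not used[idx]:
            loops += 1
            used[idx] = True
            u, node = edges[idx]
            while node != u:
                nxt = next(i for i in incident[node] if not used[i])
                used[nxt] = True
                p, q = edges[nxt]
                node = q if p == node else p
    # each boundary pair was discovered twice (once from each endpoint)
    dedup = {canonical_edge(a, b) for a, b in pairs}
    return Tangle(n, frozenset(dedup)), loops


def compose_factors(f: FactorList) -> Tangle:
    """Left-to-right composition of a prime word; the empty word gives the identity."""
    x = identity(f.n)
    for p in f:
        x, _ = compose(x, p.tangle(f.n))
    return x


def boundary_position(dot: int, n: int) -> int:
    """Position of a dot in the cyclic boundary order 1..N, N', (N-1)', .., 1'."""
    return dot - 1 if dot > 0 else 2 * n + dot


def edges_cross(e: tuple[int, int], f: tuple[int, int], n: int) -> bool:
    """Chord-diagram crossing test: do the two edges interleave on the boundary
    circle?  Edges sharing a dot never cross."""
    p1, p2 = sorted(boundary_position(d, n) for d in e)
    q1, q2 = (boundary_position(d, n) for d in f)
    return (p1 < q1 < p2) != (p1 < q2 < p2)


def crossing_number(x: Tangle) -> int:
    """Number of interleaving edge pairs: the minimal number of crossings in a
    drawing of the tangle, equal to the number of T-primes in a minimal word."""
    es = x.sorted_edges()
    return sum(
        1
        for e, f in itertools.combinations(es, 2)
        if edges_cross(e, f, x.n)
    )


def classify(x: Tangle) -> TangleClass:
    """Assign the factorization class with precedence T, TL, U, H.

    The classes overlap by definition (every crossing-free tangle with hooks
    also has a size-1 lower hook); the precedence makes the label unique and
    steers the dispatcher.
    """
    kinds = [edge_kind(e) for e in x.edges]
    if all(k in (EdgeKind.POSITIVE, EdgeKind.NEGATIVE, EdgeKind.ZERO) for k in kinds):
        return TangleClass.T_TANGLE
    if crossing_number(x) == 0:
        return TangleClass.TL_TANGLE
    if any(edge_size(e) == 1 for e in x.edges if edge_kind(e) is EdgeKind.LOWER_HOOK):
        return TangleClass.U_TANGLE
    return TangleClass.H_TANGLE


DEFAULT_ENUMERATION_BOUND = 5


def enumerate_tangles(n: int, bound: int = DEFAULT_ENUMERATION_BOUND) -> Iterator[Tangle]:
    """Yield every tangle on 2n dots exactly once ((2n-1)!! of them).

    Intended as a small-n test oracle; refuses n beyond ``bound``.
    """
    if n > bound:
        raise ValueError(f"n={n} exceeds enumeration bound {bound}")
    dots = [i for i in range(1, n + 1)] + [-i for i in range(1, n + 1)]

    def matchings(remaining: tuple[int, ...]) -> Iterator[frozenset[tuple[int, int]]]:
        if not remaining:
            yield frozenset()
            return
        first, rest = remaining[0], remaining[1:]
        for k, other in enumerate(rest):
            sub = rest[:k] + rest[k + 1:]
            e = canonical_edge(first, other)
            for m in matchings(sub):
                yield m | {e}

    for m in matchings(tuple(dots)):
        yield Tangle(n, m)
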