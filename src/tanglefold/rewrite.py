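"""Rewriting system on prime factor words.

Thirteen identities hold among the monoid generators: ten *delete* rules that
strictly shorten a word (e.g. ``T_i T_i = I``, ``U_i U_j U_i = U_i`` for
adjacent i, j) and three *move* rules that preserve length (braid-like moves
``R11``/``R12`` and far commutation ``R13``).  A word is minimal when no
sequence of moves can enable a delete.

Greedy deletion is not confluent here: a legal early delete can strand the
search in a longer word whose move-closure contains no further deletes.
``minimize`` therefore explores the full rewrite graph breadth-first (moves
and deletes together) under a state budget, and returns the best word found
with a step-by-step trace.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable

from .tangles import FactorList, PrimeFactor

Word = tuple[PrimeFactor, ...]


def _adj(a: PrimeFactor, b: PrimeFactor) -> bool:
    return abs(a.i - b.i) == 1


@dataclass(frozen=True)
class RewriteRule:
    """One oriented rewrite rule: a fixed-width pattern with index constraints."""

    id: str
    kind: str  # "delete" or "move"
    width: int
    description: str
    _match: Callable[[Word], Word | None]

    def try_match(self, word: Word, pos: int) -> Word | None:
        """Replacement for the span ``word[pos:pos+width]``, or None."""
        if pos < 0 or pos + self.width > len(word):
            return None
        return self._match(word[pos:pos + self.width])


def _mk(idx: str, kind: str, width: int, desc: str, fn) -> RewriteRule:
    return RewriteRule(idx, kind, width, desc, fn)


def _r1(s: Word) -> Word | None:
    a, b = s
    return () if a.kind == b.kind == "T" and a.i == b.i else None


def _r2(s: Word) -> Word | None:
    a, b = s
    return (a,) if a.kind == b.kind == "U" and a.i == b.i else None


def _r3(s: Word) -> Word | None:
    a, b = s
    return (b,) if a.kind == "T" and b.kind == "U" and a.i == b.i else None


def _r4(s: Word) -> Word | None:
    a, b = s
    return (a,) if a.kind == "U" and b.kind == "T" and a.i == b.i else None


def _r5(s: Word) -> Word | None:
    a, b, c = s
    ok = a.kind == b.kind == c.kind == "U" and a.i == c.i and _adj(a, b)
    return (a,) if ok else None


def _r6(s: Word) -> Word | None:
    a, b, c = s
    ok = a.kind == c.kind == "U" and b.kind == "T" and a.i == c.i and _adj(a, b)
    return (a,) if ok else None


def _r7(s: Word) -> Word | None:
    a, b, c = s
    ok = a.kind == "T" and b.kind == c.kind == "U" and a.i == c.i and _adj(a, b)
    return (PrimeFactor("T", b.i), c) if ok else None


def _r8(s: Word) -> Word | None:
    a, b, c = s
    ok = a.kind == b.kind == "U" and c.kind == "T" and a.i == c.i and _adj(a, b)
    return (a, PrimeFactor("T", b.i)) if ok else None


def _r9(s: Word) -> Word | None:
    a, b, c = s
    ok = a.kind == "U" and b.kind == c.kind == "T" and a.i == c.i and _adj(a, b)
    return (a, PrimeFactor("U", b.i)) if ok else None


def _r10(s: Word) -> Word | None:
    a, b, c = s
    ok = a.kind == b.kind == "T" and c.kind == "U" and a.i == c.i and _adj(a, b)
    return (PrimeFactor("U", b.i), c) if ok else None


def _r11(s: Word) -> Word | None:
    a, b, c = s
    ok = a.kind == b.kind == c.kind == "T" and a.i == c.i and _adj(a, b)
    return (b, a, b) if ok else None


def _r12(s: Word) -> Word | None:
    a, b, c = s
    ok = a.kind == c.kind == "T" and b.kind == "U" and a.i == c.i and _adj(a, b)
    return (PrimeFactor("T", b.i), PrimeFactor("U", a.i), PrimeFactor("T", b.i)) if ok else None


def _r13(s: Word) -> Word | None:
    a, b = s
    return (b, a) if abs(a.i - b.i) > 1 else None


RULES: dict[str, RewriteRule] = {
    r.id: r
    for r in [
        _mk("R1", "delete", 2, "T_i T_i = I", _r1),
        _mk("R2", "delete", 2, "U_i U_i = U_i", _r2),
        _mk("R3", "delete", 2, "T_i U_i = U_i", _r3),
        _mk("R4", "delete", 2, "U_i T_i = U_i", _r4),
        _mk("R5", "delete", 3, "U_i U_j U_i = U_i  (|i-j|=1)", _r5),
        _mk("R6", "delete", 3, "U_i T_j U_i = U_i  (|i-j|=1)", _r6),
        _mk("R7", "delete", 3, "T_i U_j U_i = T_j U_i  (|i-j|=1)", _r7),
        _mk("R8", "delete", 3, "U_i U_j T_i = U_i T_j  (|i-j|=1)", _r8),
        _mk("R9", "delete", 3, "U_i T_j T_i = U_i U_j  (|i-j|=1)", _r9),
        _mk("R10", "delete", 3, "T_i T_j U_i = U_j U_i  (|i-j|=1)", _r10),
        _mk("R11", "move", 3, "T_i T_j T_i = T_j T_i T_j  (|i-j|=1)", _r11),
        _mk("R12", "move", 3, "T_i U_j T_i = T_j U_i T_j  (|i-j|=1)", _r12),
        _mk("R13", "move", 2, "P_i P_j = P_j P_i  (|i-j|>1)", _r13),
    ]
}

DELETE_RULES = [r for r in RULES.values() if r.kind == "delete"]
MOVE_RULES = [r for r in RULES.values() if r.kind == "move"]


def apply_rule(w: FactorList, rule: RewriteRule | str, pos: int) -> FactorList:
    """Apply one rule at ``pos``; raises ValueError when the pattern does not match."""
    if isinstance(rule, str):
        rule = RULES[rule]
    repl = rule.try_match(w.word, pos)
    if repl is None:
        raise ValueError(f"rule {rule.id} does not match {w} at position {pos}")
    return FactorList(w.n, w.word[:pos] + repl + w.word[pos + rule.width:])


@dataclass(frozen=True)
class RewriteStep:
    rule_id: str
    pos: int
    before: FactorList
    after: FactorList

    def to_json(self) -> dict:
        return {
            "rule": self.rule_id,
            "pos": self.pos,
            "before": str(self.before),
            "after": str(self.after),
        }


@dataclass
class RewriteTrace:
    steps: list[RewriteStep] = field(default_factory=list)

    def rule_ids(self) -> list[str]:
        return [s.rule_id for s in self.steps]

    def to_json(self) -> list[dict]:
        return [s.to_json() for s in self.steps]


DEFAULT_BUDGET = 100_000


def _word_key(word: Word):
    return tuple(f.sort_key() for f in word)


def _successors(word: Word):
    for rule in RULES.values():
        for pos in range(len(word) - rule.width + 1):
            repl = rule.try_match(word, pos)
            if repl is not None:
                yield rule.id, pos, word[:pos] + repl + word[pos + rule.width:]


def minimize(
    w: FactorList, budget: int = DEFAULT_BUDGET
) -> tuple[FactorList, bool, RewriteTrace]:
    """Search the rewrite graph of ``w`` for a shortest equivalent word.

    Breadth-first over all single-rule applications, deduplicating exact
    words; rewrites never lengthen a word, so the reachable set is finite.
    Returns ``(best, certified_minimal, trace)`` where ``certified_minimal``
    is True only when the whole reachable graph fit in the state budget, and
    the trace replays one rule application per step from ``w`` to ``best``.
    If no shorter word is reachable, ``w`` itself is returned untouched.
    """
    start = w.word
    parents: dict[Word, tuple[Word, str, int] | None] = {start: None}
    queue: deque[Word] = deque([start])
    expanded = 0
    certified = True
    while queue:
        if expanded >= budget:
            certified = False
            break
        cur = queue.popleft()
        expanded += 1
        for rule_id, pos, nxt in _successors(cur):
            if nxt not in parents:
                parents[nxt] = (cur, rule_id, pos)
                queue.append(nxt)
    best = min(parents, key=lambda word: (len(word), _word_key(word)))
    if len(best) == len(start):
        return w, certified, RewriteTrace()
    chain: list[tuple[Word, str, int, Word]] = []
    node = best
    while parents[node] is not None:
        prev, rule_id, pos = parents[node]  # type: ignore[misc]
        chain.append((prev, rule_id, pos, node))
        node = prev
    trace = RewriteTrace(
        [
            RewriteStep(rule_id, pos, FactorList(w.n, before), FactorList(w.n, after))
            for before, rule_id, pos, after in reversed(chain)
        ]
    )
    return FactorList(w.n, best), certified, trace


def commutation_canonical(w: FactorList) -> FactorList:
    """Lexicographically least word reachable by far-commutation (R13) alone.

    Greedy normal form of the trace monoid: at each step emit the smallest
    letter not blocked by an earlier non-commuting letter.  Idempotent, and
    composes to the same tangle as ``w``.
    """
    remaining = list(w.word)
    out: list[PrimeFactor] = []
    while remaining:
        best_k = None
        for k, letter in enumerate(remaining):
            if any(abs(remaining[m].i - letter.i) <= 1 for m in range(k)):
                continue
            if best_k is None or letter.sort_key() < remaining[best_k].sort_key():
                best_k = k
        out.append(remaining.pop(best_k))  # a leftmost letter is always available
    return FactorList(w.n, tuple(out))
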