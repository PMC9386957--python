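"""From RNA secondary structure to tangle.

The mapping goes in five steps: flatten the structure to a chord ("arc")
diagram over the sequence positions, discard unpaired nucleotides, abbreviate
every run of stacked arcs (a stem) to a single arc — the result is the
*shape* — then fold the shape in half like closing a book, so that the second
half of the dots becomes the bottom row of a tangle read right-to-left.

Because unpaired nucleotides are dropped and stems are collapsed, the
resulting tangle is invariant under synonymous mutations: edits that add
unpaired positions or lengthen a stem leave shape, tangle and factorization
unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .tangles import ParseError, Tangle

#: bracket alphabet: each page is (open, close); beyond these, letter pairs Aa..Zz
_BRACKET_PAGES = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")] + [
    (chr(ord("A") + k), chr(ord("a") + k)) for k in range(26)
]
_OPEN = {o: k for k, (o, c) in enumerate(_BRACKET_PAGES)}
_CLOSE = {c: k for k, (o, c) in enumerate(_BRACKET_PAGES)}


@dataclass(frozen=True)
class SecondaryStructure:
    """Base pairs of an RNA string: each position is in at most one pair."""

    length: int
    pairs: frozenset[tuple[int, int]]
    sequence: str | None = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"pair ({i},{j}) out of range for length {self.length}")
            for p in (i, j):
                if p in seen:
                    raise ValueError(f"position {p} occurs in more than one pair")
                seen.add(p)
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length does not match structure length")

    def is_pseudoknotted(self) -> bool:
        ps = sorted(self.pairs)
        return any(
            a < c < b < d
            for k, (a, b) in enumerate(ps)
            for (c, d) in ps[k + 1:]
            if c < b
        )


@dataclass(frozen=True)
class ArcDiagram:
    """N arcs on 2N consecutively numbered dots (every dot in exactly one arc).

    ``origins`` maps each arc to the original base pairs it abbreviates, so a
    shape arc can be traced back to the stem it came from.
    """

    num_dots: int
    arcs: frozenset[tuple[int, int]]
    origins: dict[tuple[int, int], tuple[tuple[int, int], ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for p, q in self.arcs:
            if not (1 <= p < q <= self.num_dots):
                raise ValueError(f"arc ({p},{q}) out of range for {self.num_dots} dots")
            for d in (p, q):
                if d in seen:
                    raise ValueError(f"dot {d} occurs in more than one arc")
                seen.add(d)
        if len(seen) != self.num_dots:
            raise ValueError("every dot must lie on exactly one arc")

    def sorted_arcs(self) -> list[tuple[int, int]]:
        return sorted(self.arcs)


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse (extended) dot-bracket notation.

    ``.`` is unpaired; bracket pages ``()``, ``[]``, ``{}``, ``<>`` and letter
    pairs ``Aa``..``Zz`` are matched independently by stack discipline, which
    is how crossing (pseudoknotted) pairings are written down linearly.
    Accepts an optional FASTA-style header line and an optional sequence line.
    """
    structure, sequence = _split_dotbracket_input(text)
    stacks: dict[int, list[int]] = {}
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(structure, start=1):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks.setdefault(_OPEN[ch], []).append(pos)
        elif ch in _CLOSE:
            page = _CLOSE[ch]
            if not stacks.get(page):
                raise ParseError(f"unmatched closing bracket {ch!r} at position {pos}")
            pairs.append((stacks[page].pop(), pos))
        else:
            raise ParseError(f"unexpected character {ch!r} at position {pos}")
    for page, stack in stacks.items():
        if stack:
            o = _BRACKET_PAGES[page][0]
            raise ParseError(f"unclosed bracket {o!r} at position {stack[0]}")
    return SecondaryStructure(len(structure), frozenset(pairs), sequence)


def _split_dotbracket_input(text: str) -> tuple[str, str | None]:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        return "", None
    if lines[0].startswith(">"):
        lines = lines[1:]
    # a leading line of pure nucleotide codes followed by another line is a
    # sequence; letters alone are ambiguous (Aa..Zz are also bracket pages),
    # so the sequence reading wins only when a structure line follows
    if len(lines) >= 2 and re.fullmatch(r"[ACGTUNRYSWKMBDHVacgtunryswkmbdhv]+", lines[0]):
        return lines[1], lines[0]
    return (lines[0] if lines else ""), None


def parse_bpseq(lines: str | list[str]) -> SecondaryStructure:
    """Parse BPSEQ triples ``index base partner`` (partner 0 = unpaired)."""
    if isinstance(lines, str):
        lines = lines.splitlines()
    partner: dict[int, int] = {}
    bases: dict[int, str] = {}
    for raw in lines:
        raw = raw.strip()
        if not raw or raw.startswith("#"):
            continue
        parts = raw.split()
        if len(parts) != 3:
            raise ParseError(f"malformed BPSEQ line {raw!r}")
        try:
            idx, base, par = int(parts[0]), parts[1], int(parts[2])
        except ValueError as exc:
            raise ParseError(f"malformed BPSEQ line {raw!r}") from exc
        if idx in partner:
            raise ParseError(f"duplicate BPSEQ index {idx}")
        partner[idx] = par
        bases[idx] = base
    if not partner:
        return SecondaryStructure(0, frozenset())
    length = max(partner)
    if sorted(partner) != list(range(1, length + 1)):
        raise ParseError("BPSEQ indices must cover 1..length without gaps")
    pairs = set()
    for i, j in partner.items():
        if j == 0:
            continue
        if partner.get(j) != i:
            raise ParseError(f"asymmetric pairing: partner({i})={j} but partner({j})={partner.get(j)}")
        if i < j:
            pairs.add((i, j))
    seq = "".join(bases[i] for i in range(1, length + 1))
    return SecondaryStructure(length, frozenset(pairs), seq)


def to_arc_diagram(s: SecondaryStructure) -> ArcDiagram:
    """Drop unpaired positions and re-index the 2N paired ones as dots 1..2N."""
    paired = sorted(p for pair in s.pairs for p in pair)
    index = {p: k + 1 for k, p in enumerate(paired)}
    arcs = {}
    for i, j in s.pairs:
        arcs[(index[i], index[j])] = ((i, j),)
    return ArcDiagram(2 * len(s.pairs), frozenset(arcs), arcs)


def reduce_to_shape(d: ArcDiagram) -> ArcDiagram:
    """Abbreviate stacked arcs until no stack remains.

    Two arcs stack when they are nested and adjacent on both sides *in the
    paired-only index space* — so bulges of unpaired nucleotides (already
    discarded) never break a stem.  Each merge removes the inner arc and
    re-indexes; the merged arc inherits the origins of both.
    """
    arcs = {a: tuple(d.origins.get(a, (a,))) for a in d.arcs}
    while True:
        partner = {}
        for p, q in arcs:
            partner[p] = q
            partner[q] = p
        stacked = None
        for p, q in sorted(arcs):
            if partner.get(p + 1) == q - 1 and p + 1 < q - 1:
                stacked = (p, q)
                break
        if stacked is None:
            break
        p, q = stacked
        inner = (p + 1, q - 1)
        merged_origin = arcs.pop((p, q)) + arcs.pop(inner)
        dropped = sorted([p + 1, q - 1])

        def reindex(dot: int) -> int:
            return dot - sum(1 for x in dropped if x < dot)

        arcs = {(reindex(a), reindex(b)): o for (a, b), o in arcs.items()}
        arcs[(reindex(p), reindex(q))] = merged_origin
    num = 2 * len(arcs)
    return ArcDiagram(num, frozenset(arcs), arcs)


def fold_to_tangle(d: ArcDiagram) -> tuple[Tangle, dict[int, int]]:
    """Fold a (stack-free) 2N-dot shape into a tangle.

    Book-fold convention: dot ``k <= N`` becomes top dot ``k``; dot ``N+m``
    becomes bottom dot ``(N-m+1)'`` — the second half is rotated above the
    first, reversing its reading order.  Returns the tangle and a map from
    tangle dots (signed ints) back to shape dots.
    """
    if d.num_dots % 2:
        raise ValueError("shape diagram must have an even number of dots")
    n = d.num_dots // 2

    def fold(dot: int) -> int:
        return dot if dot <= n else -(2 * n - dot + 1)

    position_map = {fold(dot): dot for dot in range(1, 2 * n + 1)}
    if n == 0:
        raise ValueError("empty diagram has no tangle")
    tangle = Tangle.from_pairs(n, [(fold(p), fold(q)) for p, q in d.arcs])
    return tangle, position_map


def structure_to_tangle(s: SecondaryStructure) -> tuple[Tangle, ArcDiagram, dict[int, int]]:
    """Full mapping: structure -> arc diagram -> shape -> tangle."""
    shape = reduce_to_shape(to_arc_diagram(s))
    tangle, position_map = fold_to_tangle(shape)
    return tangle, shape, position_map


def write_dotbracket(s: SecondaryStructure) -> str:
    """Render a structure in extended dot-bracket form.

    Pages are assigned greedily: each pair goes on the first page where it
    crosses no pair already placed there, so a pseudoknot-free structure uses
    only ``()``.
    """
    pages: list[list[tuple[int, int]]] = []
    chars = ["."] * s.length
    for i, j in sorted(s.pairs):
        for k, page in enumerate(pages):
            if all(not (a < i < b < j or i < a < j < b) for a, b in page):
                page.append((i, j))
                chars[i - 1], chars[j - 1] = _BRACKET_PAGES[k]
                break
        else:
            if len(pages) >= len(_BRACKET_PAGES):
                raise ValueError("structure needs more bracket pages than available")
            pages.append([(i, j)])
            o, c = _BRACKET_PAGES[len(pages) - 1]
            chars[i - 1], chars[j - 1] = o, c
    return "".join(chars)
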