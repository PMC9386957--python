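"""Seeded synthetic inputs: random tangles and random secondary structures.

Random tangles are built by composing a random prime word, so every sample is
reachable by factorization by construction.  Random structures emulate the
motifs of real secondary structures — nested stems (hairpins, bulges,
multiloops, with unpaired spacer runs) plus an optional number of pseudoknot
arcs that are guaranteed to cross an existing stem.  Identical seeds give
identical outputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .rna import SecondaryStructure
from .tangles import FactorList, PrimeFactor, Tangle, compose_factors

_PAIR_LETTERS = [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the generators; identical configs reproduce identical outputs."""

    seed: int = 0
    n: int = 6                 # tangle rows
    word_length: int = 8       # prime word length for random tangles
    stems: int = 4             # nested stems in a random structure
    pseudoknots: int = 0       # crossing arcs added on top of the stems
    max_stem_len: int = 3      # base pairs per stem
    max_unpaired: int = 3      # unpaired run between structural elements


def random_word(cfg: SyntheticConfig) -> FactorList:
    rng = random.Random(cfg.seed)
    if cfg.n < 2 and cfg.word_length > 0:
        raise ValueError("prime words need n >= 2")
    word = tuple(
        PrimeFactor(rng.choice("TU"), rng.randrange(1, cfg.n))
        for _ in range(cfg.word_length)
    )
    return FactorList(cfg.n, word)


def random_tangle(cfg: SyntheticConfig) -> Tangle:
    """Composition of a seeded random prime word of the requested length."""
    return compose_factors(random_word(cfg))


def _stem_skeleton(rng: random.Random, stems: int) -> list[tuple[int, str]]:
    """Token list of (arc_id, 'open'|'close') for a random nesting of arcs,
    built by inserting each new arc pair at a random position."""
    tokens: list[tuple[int, str]] = []
    for arc in range(stems):
        at = rng.randrange(len(tokens) + 1)
        tokens[at:at] = [(arc, "open"), (arc, "close")]
    return tokens


def _add_pseudoknot(rng: random.Random, tokens: list[tuple[int, str]], arc_id: int) -> None:
    """Insert one arc that crosses a randomly chosen existing arc: one endpoint
    strictly between the victim's tokens, the other outside its span."""
    victims = sorted({a for a, _ in tokens})
    victim = rng.choice(victims)
    o = tokens.index((victim, "open"))
    c = tokens.index((victim, "close"))
    inside = rng.randrange(o + 1, c + 1)
    if rng.random() < 0.5:
        tokens.insert(inside, (arc_id, "open"))
        # victim's close is now at c+1; any slot strictly after it is outside
        outside = rng.randrange(c + 2, len(tokens) + 1)
        tokens.insert(outside, (arc_id, "close"))
    else:
        outside = rng.randrange(0, o + 1)
        tokens.insert(inside, (arc_id, "close"))
        tokens.insert(outside, (arc_id, "open"))


def random_structure(cfg: SyntheticConfig) -> SecondaryStructure:
    """A seeded secondary structure with ``cfg.stems`` nested stems and
    ``cfg.pseudoknots`` crossing arcs.

    With ``pseudoknots=0`` the pair set is strictly nested, so the derived
    tangle is crossing-free; each added pseudoknot crosses some stem, so the
    tangle then has at least one crossing.
    """
    if cfg.stems < 1:
        raise ValueError("need at least one stem")
    rng = random.Random(cfg.seed)
    tokens = _stem_skeleton(rng, cfg.stems)
    for k in range(cfg.pseudoknots):
        _add_pseudoknot(rng, tokens, cfg.stems + k)
    widths = {
        arc: rng.randint(1, max(1, cfg.max_stem_len))
        for arc in {a for a, _ in tokens}
    }
    seq: list[str] = []
    open_positions: dict[int, list[int]] = {}
    pairs: list[tuple[int, int]] = []
    letters: dict[int, str] = {}

    def spacer() -> None:
        for _ in range(rng.randint(0, cfg.max_unpaired)):
            seq.append(rng.choice("ACGU"))

    spacer()
    for arc, side in tokens:
        w = widths[arc]
        if side == "open":
            open_positions[arc] = []
            for _ in range(w):
                seq.append("")  # placeholder, letter chosen at close time
                open_positions[arc].append(len(seq))
        else:
            for opened in reversed(open_positions[arc]):
                a, b = rng.choice(_PAIR_LETTERS)
                seq.append(b)
                letters[opened] = a
                pairs.append((opened, len(seq)))
        spacer()
    chars = [letters.get(k + 1, ch) or rng.choice("ACGU") for k, ch in enumerate(seq)]
    return SecondaryStructure(len(chars), frozenset(pairs), "".join(chars))
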