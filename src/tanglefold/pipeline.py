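"""End-to-end pipeline: input → shape → tangle → minimal factor word → report."""

from __future__ import annotations

from dataclasses import dataclass

from . import rna
from .factorize import GeneratorMap, factorize_raw, track_generators
from .rewrite import DEFAULT_BUDGET, RewriteTrace, minimize
from .tangles import (
    FactorList,
    Tangle,
    TangleClass,
    classify,
    compose_factors,
    crossing_number,
    format_invariant,
    parse_invariant,
)


@dataclass
class Report:
    """Everything the pipeline derives from one input structure or tangle."""

    source: str
    format: str                       # "dotbracket" | "bpseq" | "invariant"
    tangle: Tangle | None
    tangle_class: TangleClass | None
    shape: rna.ArcDiagram | None      # None for raw-invariant input
    raw_word: FactorList | None
    minimized: FactorList | None
    certified_minimal: bool
    crossing_number: int
    generators: GeneratorMap | None
    trace: RewriteTrace | None

    def to_json(self, include_trace: bool = False) -> dict:
        obj: dict = {
            "input": self.source,
            "format": self.format,
            "tangle": format_invariant(self.tangle) if self.tangle else None,
            "class": self.tangle_class.value if self.tangle_class else None,
            "crossing_number": self.crossing_number,
            "raw_factorization": str(self.raw_word) if self.raw_word is not None else None,
            "minimal_factorization": str(self.minimized) if self.minimized is not None else None,
            "factors": self.minimized.to_json() if self.minimized is not None else None,
            "certified_minimal": self.certified_minimal,
            "generators": self.generators.to_json() if self.generators else None,
        }
        if self.shape is not None:
            obj["shape"] = {
                "arcs": [list(a) for a in self.shape.sorted_arcs()],
                "origins": {
                    f"{p}-{q}": [list(pair) for pair in org]
                    for (p, q), org in sorted(self.shape.origins.items())
                },
            }
        if include_trace and self.trace is not None:
            obj["trace"] = self.trace.to_json()
        return obj


def _parse_source(source: str, fmt: str) -> tuple[Tangle | None, rna.ArcDiagram | None]:
    if fmt == "invariant":
        return parse_invariant(source), None
    structure = rna.parse_dotbracket(source) if fmt == "dotbracket" else rna.parse_bpseq(source)
    if not structure.pairs:
        return None, None
    tangle, shape, _ = rna.structure_to_tangle(structure)
    return tangle, shape


def run_pipeline(
    source: str,
    fmt: str = "dotbracket",
    budget: int = DEFAULT_BUDGET,
) -> Report:
    """Parse, map, classify, factorize, minimize and annotate one input.

    ``fmt`` is one of ``dotbracket``, ``bpseq``, ``invariant``.  A structure
    with no pairs yields an empty report (no tangle, empty word).
    """
    tangle, shape = _parse_source(source, fmt)
    if tangle is None:
        return Report(source, fmt, None, None, shape, None, None, True, 0, None, None)
    raw = factorize_raw(tangle)
    minimized, certified, trace = minimize(raw, budget=budget)
    assert compose_factors(minimized) == tangle, "minimized word must compose back"
    return Report(
        source=source,
        format=fmt,
        tangle=tangle,
        tangle_class=classify(tangle),
        shape=shape,
        raw_word=raw,
        minimized=minimized,
        certified_minimal=certified,
        crossing_number=crossing_number(tangle),
        generators=track_generators(minimized),
        trace=trace,
    )
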