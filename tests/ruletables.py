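"""All valid instantiations of each rewrite-rule pattern, for soundness checks."""

import itertools

from tanglefold import T, U


def rule_instances(rule_id: str, n: int):
    idx = range(1, n)
    if rule_id == "R1":
        return [((T(i), T(i)), ()) for i in idx]
    if rule_id == "R2":
        return [((U(i), U(i)), (U(i),)) for i in idx]
    if rule_id == "R3":
        return [((T(i), U(i)), (U(i),)) for i in idx]
    if rule_id == "R4":
        return [((U(i), T(i)), (U(i),)) for i in idx]
    pairs = [(i, j) for i, j in itertools.product(idx, idx) if abs(i - j) == 1]
    far = [(i, j) for i, j in itertools.product(idx, idx) if abs(i - j) > 1]
    table = {
        "R5": [((U(i), U(j), U(i)), (U(i),)) for i, j in pairs],
        "R6": [((U(i), T(j), U(i)), (U(i),)) for i, j in pairs],
        "R7": [((T(i), U(j), U(i)), (T(j), U(i))) for i, j in pairs],
        "R8": [((U(i), U(j), T(i)), (U(i), T(j))) for i, j in pairs],
        "R9": [((U(i), T(j), T(i)), (U(i), U(j))) for i, j in pairs],
        "R10": [((T(i), T(j), U(i)), (U(j), U(i))) for i, j in pairs],
        "R11": [((T(i), T(j), T(i)), (T(j), T(i), T(j))) for i, j in pairs],
        "R12": [((T(i), U(j), T(i)), (T(j), U(i), T(j))) for i, j in pairs],
        "R13": [
            ((a(i), b(j)), (b(j), a(i)))
            for i, j in far
            for a, b in itertools.product((T, U), repeat=2)
        ],
    }
    return table[rule_id]
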