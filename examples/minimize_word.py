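"""Minimize a redundant factor word with the rewrite system.

Delete rules (R1-R10) shorten a word; move rules (R11-R13) rearrange it so
that further deletes become possible.  The search explores the whole rewrite
graph, so an unlucky early delete can never trap it in a non-minimal word.
"""

from tanglefold import FactorList, minimize

word = FactorList.from_string("T2*U1*U1*U2*U3*U1*U2*T4", n=5)
out, certified, trace = minimize(word)

print(f"input     {word}  (length {len(word)})")
for step in trace.steps:
    print(f"  {step.rule_id:>4} at {step.pos}: {step.before} -> {step.after}")
print(f"minimal   {out}  (length {len(out)}, certified: {certified})")
print()
print("R2 collapses the doubled U1, R13 commutes the far pair U3/U1, and R5")
print("absorbs the U1*U2*U1 sandwich - three letters saved in total.")
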