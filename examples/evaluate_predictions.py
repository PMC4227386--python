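"""Score a predicted complex set against a reference catalogue.

Shows the three matching metrics on a tiny hand-built example: one exact
hit, one partial hit, and one spurious prediction.
"""

from plsmc import ComplexSet, EvalConfig, evaluate

reference = ComplexSet([
    {"YKL018W", "YPL138C", "YBR175W", "YDR469W"},   # recovered exactly
    {"YHR119W", "YLR015W", "YAR003W"},              # partially recovered
    {"YBR258C", "YOR123C", "YDL005C"},              # missed entirely
])
predicted = ComplexSet([
    {"YKL018W", "YPL138C", "YBR175W", "YDR469W"},   # perfect match
    {"YHR119W", "YLR015W", "YGL127C"},              # 2 of 3 members + 1 wrong
    {"YML010W", "YJL085W", "YPR070W"},              # not in the reference
])

report = evaluate(predicted, reference, EvalConfig(ov=0.25))
for key, value in report.to_dict().items():
    print(f"{key:16s} {value:.4f}" if isinstance(value, float) else f"{key:16s} {value}")

print()
print("precision/recall count matched complexes at overlap score >= 0.25;")
print("Sn/PPV/Acc count matched proteins; MMR averages each reference")
print("complex's best overlap score. composite = f_measure + acc + mmr.")
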