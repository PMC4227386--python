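"""Detect protein complexes in a small synthetic PPI network.

Builds a noisy planted-complex benchmark (6 complexes of 5-8 proteins,
90% intra-complex edge density, sparse background), runs the full
detection pipeline, and compares the predictions with the planted truth.
"""

from plsmc import (
    PipelineConfig,
    SyntheticSpec,
    detect_complexes,
    evaluate,
    filter_min_size,
    generate,
)

spec = SyntheticSpec(
    n_complexes=6, size_range=(5, 8), overlap_prob=0.0,
    p_in=0.9, p_out=0.005, n_background=8, seed=42,
)
network, gold = generate(spec)
print(f"network: {network.n_nodes} proteins, {network.n_edges} interactions")

# Small ridge penalty: intra-complex weights are ~1/m for a complex of m
# proteins, so member propensities land near sqrt((1-lambda)/m) > tau.
config = PipelineConfig(lam=2**-5, tau=0.2, restarts=10, seed=0)
predicted, summary = detect_complexes(network, config)

print(f"predicted {len(predicted)} complexes "
      f"({summary['n_subnetworks']} subnetwork(s) fitted):")
for c in predicted:
    print("  ", " ".join(sorted(c)))

report = evaluate(predicted, filter_min_size(gold, 3))
print(f"f-measure={report.f_measure:.3f}  Acc={report.acc:.3f}  "
      f"MMR={report.mmr:.3f}  composite={report.composite:.3f}")
print("A composite of 3.0 means every planted complex was recovered exactly;")
print(f"{report.perfect_matches}/{len(gold)} complexes matched perfectly (os = 1).")
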