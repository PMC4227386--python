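"""Generate a synthetic planted-complex benchmark and write it to disk.

The generator plants dense complexes (edge probability p_in inside a
complex) against a sparse background (p_out elsewhere) and returns the
planted complexes as the gold standard for evaluation.
"""

from plsmc import SyntheticSpec, generate, write_complexes

spec = SyntheticSpec(
    n_complexes=10, size_range=(5, 10), overlap_prob=0.1,
    p_in=0.9, p_out=0.005, n_background=10, seed=7,
)
network, gold = generate(spec)

with open("benchmark.network.sif", "w") as fh:
    for edge in sorted(tuple(sorted(e)) for e in network.edges):
        fh.write(f"{edge[0]}\tpp\t{edge[1]}\n")
    for node in network.nodes:
        if network.graph.degree(node) == 0:
            fh.write(f"{node}\n")
write_complexes(gold, "benchmark.gold.txt")

n_overlapping = len(gold.proteins()) < sum(len(c) for c in gold)
print(f"wrote {network.n_nodes} proteins / {network.n_edges} interactions "
      f"to benchmark.network.sif")
print(f"wrote {len(gold)} planted complexes to benchmark.gold.txt "
      f"(proteins shared between complexes: {'yes' if n_overlapping else 'no'})")
print("the same files are produced by: plsmc synth --out-prefix benchmark --seed 7 "
      "--overlap-prob 0.1")
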