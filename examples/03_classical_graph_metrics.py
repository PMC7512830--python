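"""Connectedness-based binarization and the classical comparison metrics.

Takes one 10 s window of a synthetic recording, finds the largest
binarization threshold that keeps the graph connected (Fiedler-value
search) and prints the four classical metrics of the resulting binary
network.
"""

from fcgbnet import (
    SynthSpec,
    compute_metrics,
    connectivity_matrix,
    find_threshold,
    generate,
)

rec, _ = generate(SynthSpec(duration_s=30.0, event_times_s=[], seed=5))
window = rec.data[:, : int(10 * rec.fs)]

F = connectivity_matrix(window)
g = find_threshold(F, step=0.01)
print(f"threshold T = {g.threshold_T:.2f} (step {g.step_used:g}); "
      f"{int(g.adjacency.sum() / 2)} edges survive")

row = compute_metrics(g)
print(f"clustering coefficient : {row.clustering:.3f}")
print(f"characteristic path len: {row.char_path_length:.3f}")
print(f"global efficiency      : {row.global_efficiency:.3f}")
print(f"vulnerability          : {row.vulnerability:.3f}")

# T is the largest grid threshold at which no electrode is isolated: edges
# with weight > T form a connected graph. The metrics describe that binary
# network: how clustered it is, how many hops separate typical node pairs,
# how efficiently information spreads, and how much efficiency the worst
# single-node failure would cost.
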