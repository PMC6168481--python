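"""Run the spike-in recovery benchmark and compare ranking methods.

Generates seeded synthetic cases — a causative variant pair inserted into a
background of benign-looking variants over a random gene network — and
measures how often each method recovers the full pair at the top of its
ranking ('top set') or within the top ten. The truth pair here is scored at
the 95th percentile of the background distribution — high but not
unbeatable, so the flat ranking must fight through distractors while the
tuple ranking also exploits the pair's interaction in a sparse network.
"""

from oligorank import compare_rank_distributions, run_benchmark
from oligorank.benchmark import metrics_frame

params = {
    "n_background": 100,
    "n_genes": 20,
    "edge_prob": 0.05,
    "truth_size": 2,
    "truth_score_quantile": 0.95,
    "truth_connected": True,
}
metrics = run_benchmark(params, n_cases=50, seed=42)
print(metrics_frame(metrics).to_string(index=False))
print()
print("Each row: recoveries out of n_cases; 'interacting_only' restricts to")
print("cases whose causative genes interact in the network (all of them here,")
print("because the generator wires the truth pair together).")

# Mann-Whitney comparison of two rank samples, as used to compare methods
ranks_method_a = [1, 1, 2, 3, 3, 5, 8, 13]
ranks_method_b = [2, 4, 6, 9, 11, 14, 17, 21]
res = compare_rank_distributions(ranks_method_a, ranks_method_b)
print()
print(f"Mann-Whitney U = {res['U']:.1f}, two-sided p = {res['p']:.4f}")
print("(exact permutation null; small U means method A ranks truths higher)")
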