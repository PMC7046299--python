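"""WAP-vs-DEG reproducibility benchmark over random dataset splits.

Repeatedly halves a synthetic study with a network-localized module,
measures the cross-half overlap (maxR) of WAP and DEG orderings, and
repeats the WAP scoring on a degree-preserving rewired network — the
control showing that the advantage relies on true interactions, not on
the scoring machinery itself.
"""

import warnings

import wapscore as w

warnings.filterwarnings("ignore", category=w.TerminalWeightFallback)

config = w.SyntheticConfig(n_genes=1000, n_de_genes=80, effect_size=1.5, seed=7)
network = w.generate_network(config)
dataset = w.generate_expression(network, config)

result = w.benchmark_splits(
    dataset, network, n_splits=50, seed=17, include_rewired=True, a=20, b=500
)
s = result.summary
print(f"{result.n_splits} random splits of a "
      f"{dataset.n_disease}+{dataset.n_control}-sample study:")
print(f"  median maxR, WAP ordering      = {s['median_maxr_wap']:.3f}")
print(f"  median maxR, DEG ordering      = {s['median_maxr_deg']:.3f}")
print(f"  median paired difference       = {s['median_maxr_diff']:+.3f}")
print(f"  median maxR, rewired network   = {s['median_maxr_wap_rewired']:.3f}")
lo, hi = s["ci99_median_maxr_diff"]
print(f"  99% bootstrap CI on the median difference: [{lo:+.3f}, {hi:+.3f}]")
print("\npositive paired differences: the network-aware ordering is the")
print("more reproducible one when the signal sits on real interactions.")
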