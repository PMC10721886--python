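"""Full five-group analysis: double-control gating, condition contrast,
robust-change clustering and QC, from one config.

The simulated layout mirrors a DNA-damage pulldown: three target groups
(no DNA, undamaged DNA, double-strand-break DNA) plus an untagged-ubiquitin
background control and an E1-inhibited control. The manifest counts trace
each filtering stage.
"""

from ubiquant import run_pipeline

config = {
    "simulate": {"n_proteins": 500, "n_regulated": 50, "missing_rate": 0.1},
    "parameters": {"s0": 0.1, "fdr": 0.05, "n_perm": 2500},
    "contrasts": [["DSB", "DNA"]],
    "n_clusters": 2,
    "seed": 7,
}

manifest, tables = run_pipeline(config)
print("stage counts:")
for key, value in manifest.counts.items():
    print(f"  {key}: {value}")

gate = tables["enrichment_calls"]
print(f"\nproteins passing the double-control gate: {int(gate['gated'].sum())}")
# 'gated' requires one-tailed enrichment (q <= fdr, positive difference)
# over BOTH the background and the E1-inhibited control in some target group.

volcano = tables["contrast_DSB_vs_DNA"]
top = volcano[volcano["label"] == "enriched"].nlargest(5, "neg_log10_p")
print("\ntop DSB-enriched proteins (diff = log2 DSB - DNA):")
print(top[["diff", "q", "label"]])
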