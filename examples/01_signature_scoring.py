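"""Derive MES/ADRN signatures from isogenic pairs and score a cell-line panel.

Simulates the default panel (four isogenic MES/ADRN pairs plus eight
unpaired lines, 5000 probesets, 300 planted MES and 250 planted ADRN
genes), derives the signatures with the four selection criteria, and
prints per-sample rank-percentile scores.  A MES-state sample should score
high on the MES signature and low on the ADRN signature, and vice versa.
"""

from adrnmes import SimulationConfig, derive_signature, score_panel, simulate_expression_panel

config = SimulationConfig(seed=1)
panel, truth = simulate_expression_panel(config)
signature = derive_signature(panel)

tp = len(signature.mes_genes & truth.planted_mes_genes) + len(
    signature.adrn_genes & truth.planted_adrn_genes
)
n_called = len(signature.mes_genes) + len(signature.adrn_genes)
n_planted = len(truth.planted_mes_genes) + len(truth.planted_adrn_genes)

print(f"derived {len(signature.mes_genes)} MES and {len(signature.adrn_genes)} ADRN genes")
print(f"precision {tp / n_called:.3f}  recall {tp / n_planted:.3f} against planted truth")
print()
scores = score_panel(panel, signature).join(panel.samples["lineage"])
print(scores.round(3).to_string())
print()
print(
    "Each score is the mean within-sample expression percentile of the"
    " signature genes; MES samples separate cleanly from ADRN samples."
)
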