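"""Annotate a signature gene list: SL/SDL pair mapping and enrichment.

Maps drug targets x signature genes onto a toy synthetic-lethality pair
list (the classic example: over-activity of EGFR making IGFBP3 essential,
relevant to gefitinib sensitivity), then runs a hypergeometric
over-representation test of the signature in a small gene-set collection.
"""

import drugsig as ds
from drugsig.annotate import SLPair

signature = {f"G{i:03d}" for i in range(12)} | {"IGFBP3"}
universe = {f"G{i:03d}" for i in range(60)} | {"IGFBP3", "EGFR"}

pairs = [SLPair("EGFR", "IGFBP3", "SDL"), SLPair("BRCA1", "PARP1", "SL")]
mapping = ds.map_sl_pairs({"gefitinib": {"EGFR"}, "olaparib": {"PARP1"}},
                          signature, pairs)
print("SL/SDL matches per interaction:", mapping.counts())
for drug, matched in mapping.per_drug.items():
    for p in matched:
        print(f"  {drug}: {p.gene_a} -> {p.gene_b} ({p.interaction})")

gene_sets = {
    "pathway_A": {f"G{i:03d}" for i in range(8)},        # heavy overlap
    "pathway_B": {f"G{i:03d}" for i in range(40, 55)},   # background
}
results = ds.hypergeometric_enrichment(signature, gene_sets, universe)
for r in results:
    print(f"{r.set_name}: overlap {r.overlap_count}/{r.set_size}, "
          f"p = {r.p_value:.3g}, significant = {r.significant}")
print("A set is significant when p < 0.05 AND more than two genes overlap.")
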