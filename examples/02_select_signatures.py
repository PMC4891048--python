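"""Select per-cancer-type signature genes with the sparse group lasso.

The generator plants, for each cancer type, a small set of driver genes
whose (centered) expression linearly determines the cell-line factors V.
Regressing V onto all genes with a row-grouped penalty should concentrate
the surviving rows on those drivers.  Overlap statistics between the two
types' signatures are printed the way multi-cancer signature studies
report specificity.
"""

import numpy as np

import drugsig as ds
from drugsig.grouplasso import select_signatures, signature_overlap_stats

panel, truth = ds.simulate_panel(
    n_drugs=10, n_cells=60, n_genes=200, k_true=3, n_types=2,
    driver_count=8, seed=11, n_bits=64, resist_drugs=1)

sigs = []
for ctype in panel.annotation.types:
    cells = panel.annotation.cells_of_type(ctype)
    idx = [panel.expression.cell_line_ids.index(c) for c in cells]
    sig = select_signatures(
        truth.V_true[idx], panel.expression, ctype,
        lambdas=np.geomspace(0.05, 20, 12), cell_lines=cells,
        target_size=16)  # ~2x the planted driver count
    drivers = truth.Q_support[ctype]
    recall = len(sig.genes & drivers) / len(drivers)
    print(f"{ctype}: {len(sig)} signature genes, "
          f"driver recall {recall:.2f} (lambda={sig.provenance['lambda_group']:.3g})")
    sigs.append(sig)

stats = signature_overlap_stats(sigs)["per_type"]
for ctype, row in stats.items():
    print(f"{ctype}: {row['unique']} of {row['total']} genes are type-specific "
          f"({row['unique_pct']}%)")
print("High recall shows the grouped penalty recovers the planted drivers;")
print("the unique percentages quantify how type-specific each signature is.")
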