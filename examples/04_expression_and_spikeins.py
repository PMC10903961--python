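"""Single-cell expression matrices, saturation, and spike-in calibration.

Builds gene and isoform UMI matrices with CPM/10 normalization, plots a
saturation curve for one cell (textually), and evaluates spike-in molecules
of known abundance.
"""

import numpy as np

import scisote as sc
from scisote.matrices import evaluate_spikeins, per_cell_stats, saturation_curve
from scisote.pipeline import spikein_assignments
from scisote.simulate import truth_alignments_in_memory

reference = sc.build_toy_reference(seed=3, n_chromosomes=1, n_genes=10, n_te_loci=15)
design = sc.default_design(reference, seed=4, cells_per_stage=5, stages=("A", "B"))
reads, truth, segments = sc.simulate_molecules(reference, design)
result = sc.run_pipeline(
    reference, reads, truth_alignments_in_memory(segments),
    set(design.whitelist), design.cell_stage,
)

stats = per_cell_stats(result.gene_matrix)
print(stats.head(4).to_string(index=False))
r = np.corrcoef(stats["n_features_detected"], stats["n_umis"])[0, 1]
print(f"genes-vs-molecules correlation across cells: r = {r:.3f}")

# saturation: genes detected while subsampling one cell's reads
cell = result.gene_matrix.cells[0]
records = [
    (r.umi, t.gene_id)
    for r in reads
    for t in [r.truth]
    if t.cell_barcode == cell and t.feature_kind == "isoform"
]
for depth, n_genes in saturation_curve(records, [0.1, 0.25, 0.5, 1.0], seed=0):
    print(f"depth {depth:>4.0%}: {n_genes} genes detected")

pairs = spikein_assignments(result, reference, truth)
ev = evaluate_spikeins(result.spikein_matrix, reference.spikein_designs, pairs)
print(f"spike-in abundance correlation (log10, Pearson): {ev.correlation:.3f}")
print(f"isoform confusion off-diagonal molecules: {ev.off_diagonal_total}")
# correlation near 1 means observed UMIs track the known input copies;
# off-diagonal 0 means no spike-in molecule was assigned the wrong isoform.
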