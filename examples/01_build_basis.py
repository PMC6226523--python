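"""Build a hierarchical basis matrix from a synthetic sorted-cell compendium.

Simulates a multi-platform compendium of 20 sorted blood cell types with
planted marker genes, runs the two-stage signature search (cell types within
lineages, then lineages against one another), and reports how many of the
planted markers the selection recovered.
"""

import warnings

import decomix as dx
from decomix.synthetic import marker_recovery_config

warnings.filterwarnings("ignore", category=UserWarning)

cfg = marker_recovery_config(seed=42)
compendium, truth = dx.simulate_sorted_compendium(cfg)
print(f"compendium: {compendium.n_genes} genes x {compendium.n_samples} sorted samples, "
      f"{len(cfg.cell_types)} cell types / {len(cfg.lineages)} lineages")

basis = dx.build_basis(compendium, dict(cfg.hierarchy))
stage_counts = {}
for stage in basis.stage_of.values():
    stage_counts[stage] = stage_counts.get(stage, 0) + 1
print(f"basis matrix: {len(basis.gene_ids)} signature genes x "
      f"{len(basis.cell_types)} cell types "
      f"({stage_counts.get('cell_type_stage', 0)} cell-type stage + "
      f"{stage_counts.get('lineage_stage', 0)} lineage stage)")

selected = set(basis.gene_ids)
recovery = [
    sum(g in selected for g in markers) / len(markers)
    for markers in truth.markers.values()
]
print(f"planted-marker recovery: mean {sum(recovery) / len(recovery):.0%}, "
      f"minimum over cell types {min(recovery):.0%}")
# a recovery near 100% means the effect-size ranking put the planted markers
# at the top and the stepwise AUROC search kept them
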