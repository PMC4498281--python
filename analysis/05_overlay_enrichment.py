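#!/usr/bin/env python
"""Project the planted gene sets on the network and test hub enrichment
and per-class over-representation.

Overlays report how much of the network each set covers and how its hits
split over the ER/LR regions; enrichment within the 100 hubs uses the
hypergeometric upper tail (significance at P < 0.01); ORA of the DEG
list against the class annotation applies Bonferroni control at 0.05.
Writes tables under results/enrichment/.
"""

import argparse
from pathlib import Path

import pandas as pd

from abanet import enrichment as enr
from abanet import io as aio
from abanet import network as nm
from abanet import qc_deg, som
from abanet.pipeline import stage_seeds
from abanet.synthetic import read_truth

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
parser.add_argument("--deg-dir", type=Path, default=Path("results/deg"))
parser.add_argument("--out-dir", type=Path, default=Path("results/enrichment"))
args = parser.parse_args()

matrix = qc_deg.floor_transform(aio.read_matrix(args.data_dir / "matrix.tsv"))
design = aio.read_design(args.data_dir / "design.tsv")
table = qc_deg.read_deg_table(args.deg_dir / "deg_table.tsv")
truth = read_truth(args.data_dir / "truth_classes.tsv")
sets = aio.read_gmt(args.data_dir / "planted_sets.gmt")

corr = nm.correlation_matrix(matrix, design, table.deg_genes)
net = nm.build_network(corr.r)
nm.identify_hubs(net, hub_k=100)
z = som.standardize_profiles(matrix.subset_genes(net.nodes), design)
model = som.train_som(z, seed=stage_seeds(args.seed)["som"])
assignment = som.assign_som_bins(model, z)
nm.partition_regions(net, assignment.unit_of(), matrix, design)

overlays = enr.project_gene_sets(net, sets)
print("set overlays on the network:")
for name, entry in sorted(overlays.items()):
    print(f"  {name}: {entry.nodes_hit} nodes ({100 * entry.fraction:.1f} % of network), "
          f"ER {entry.region_counts.get('ER', 0)} / LR {entry.region_counts.get('LR', 0)}, "
          f"{entry.absent} absent")

core = enr.intersect_overlays(sets, scope=net.nodes)
print(f"\ngenes shared by all {len(sets)} projected sets within the network: {len(core)}")

hub_rows = enr.hub_set_enrichment(net, sets)
print("\nenrichment within the 100 hubs (hypergeometric, P < 0.01):")
for row in hub_rows:
    mark = "*" if row.significant else " "
    print(f" {mark}{row.category}: {row.k}/{row.K} in hubs, expected {row.expected:.1f}, "
          f"P = {row.p:.3g}")

annotation = pd.DataFrame(sorted(truth.items()), columns=["gene", "category"])
ora_rows = enr.run_ora(table.deg_genes, matrix.gene_ids, annotation)
print("\nORA of the DEG list against planted classes (Bonferroni 0.05):")
for row in ora_rows:
    mark = "*" if row.significant else " "
    print(f" {mark}{row.category}: k={row.k}, expected {row.expected:.1f}, "
          f"obs/exp {row.ratio_obs_exp:.2f}, adjusted P = {row.p_adj:.3g}")

args.out_dir.mkdir(parents=True, exist_ok=True)
pd.DataFrame([o.as_dict() for o in overlays.values()]).sort_values("set").to_csv(
    args.out_dir / "overlays.tsv", sep="\t", index=False, float_format="%.10g"
)
enr.enrichment_frame(hub_rows).to_csv(
    args.out_dir / "hub_enrichment.tsv", sep="\t", index=False, float_format="%.10g"
)
enr.enrichment_frame(ora_rows).to_csv(
    args.out_dir / "ora.tsv", sep="\t", index=False, float_format="%.10g"
)
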