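#!/usr/bin/env python
"""Bin network genes into six temporal patterns with a 2x3 SOM and split
the network into early- and late-response regions.

Genes are standardized to z-profiles over the five time points, mapped
onto a 2x3 Kohonen grid, and each bin is labeled ER (>= half of its
dynamic range completed by 2 h) or LR.  Writes assignments, codebook and
a per-bin mean-profile figure under results/som/.
"""

import argparse
from pathlib import Path

import pandas as pd

from abanet import io as aio
from abanet import network as nm
from abanet import qc_deg, som
from abanet.pipeline import stage_seeds
from abanet.synthetic import read_truth

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
parser.add_argument("--deg-dir", type=Path, default=Path("results/deg"))
parser.add_argument("--out-dir", type=Path, default=Path("results/som"))
args = parser.parse_args()

matrix = qc_deg.floor_transform(aio.read_matrix(args.data_dir / "matrix.tsv"))
design = aio.read_design(args.data_dir / "design.tsv")
table = qc_deg.read_deg_table(args.deg_dir / "deg_table.tsv")
truth = read_truth(args.data_dir / "truth_classes.tsv")

corr = nm.correlation_matrix(matrix, design, table.deg_genes)
net = nm.build_network(corr.r)

z = som.standardize_profiles(matrix.subset_genes(net.nodes), design)
model = som.train_som(z, seed=stage_seeds(args.seed)["som"])
assignment = som.assign_som_bins(model, z)
print(f"SOM bin sizes: {list(map(int, assignment.counts))}")
print(f"quantization error: {model.initial_quantization_error:.4f} -> "
      f"{model.final_quantization_error:.4f}")
print(f"bin-vs-class purity: {som.bin_purity(assignment.units, truth):.3f}")

regions, bin_label, bin_e = nm.partition_regions(net, assignment.unit_of(), matrix, design)
for unit in sorted(bin_label):
    print(f"  bin {unit}: {int(assignment.counts[unit])} genes, "
          f"earliness {bin_e[unit]:.2f} -> {bin_label[unit]}")
sizes = {r: sum(1 for v in regions.values() if v == r) for r in ("ER", "LR", "none")}
print(f"region sizes: {sizes}")

args.out_dir.mkdir(parents=True, exist_ok=True)
assignment.to_frame(model).to_csv(args.out_dir / "som_assignment.tsv", sep="\t", index=False)
pd.DataFrame(
    model.codebook, columns=[f"t{t:g}h" for t in design.times]
).to_csv(args.out_dir / "som_codebook.tsv", sep="\t", index_label="unit", float_format="%.10g")
pd.DataFrame(
    sorted(regions.items()), columns=["gene", "region"]
).to_csv(args.out_dir / "regions.tsv", sep="\t", index=False)

try:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    times = design.times
    fig, axes = plt.subplots(model.rows, model.cols, figsize=(9, 5), sharey=True)
    for unit, ax in enumerate(axes.ravel()):
        mean = assignment.mean_profiles[unit]
        sd = assignment.sd_profiles[unit]
        if not pd.isna(mean).all():
            ax.errorbar(range(len(times)), mean, yerr=sd, marker="o", lw=1.5)
        ax.set_title(f"bin {unit} (n={int(assignment.counts[unit])}, "
                     f"{bin_label.get(unit, '-')})", fontsize=9)
        ax.set_xticks(range(len(times)), [f"{t:g}" for t in times])
    fig.supxlabel("hours in ABA")
    fig.supylabel("z-scored log2 expression")
    fig.tight_layout()
    fig.savefig(args.out_dir / "som_profiles.png", dpi=150)
    print(f"wrote {args.out_dir / 'som_profiles.png'}")
except ImportError:
    print("matplotlib unavailable; skipping the profile figure")
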