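#!/usr/bin/env python
"""Floor the matrix, screen replicates by PCA, and call time-point DEGs.

Each treated time point is contrasted against the 0 h control with a
per-gene pooled-variance linear model; a gene is a DEG when
|log2FC| >= 2.0 and P <= 0.01 at one or more time points.  Prints the
per-time-point accumulating/declining table and writes the full DEG
table under results/deg/.
"""

import argparse
from pathlib import Path

from abanet import io as aio
from abanet import qc_deg

parser = argparse.ArgumentParser()
parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
parser.add_argument("--out-dir", type=Path, default=Path("results/deg"))
args = parser.parse_args()

matrix = qc_deg.floor_transform(aio.read_matrix(args.data_dir / "matrix.tsv"))
design = aio.read_design(args.data_dir / "design.tsv")

qc = qc_deg.detect_outlier_samples(matrix, design)
print(f"PC1 explains {qc.pc_variance_fractions[0] * 100:.1f} % of the variance")
if qc.flagged_samples:
    print(f"dropping flagged replicate(s): {qc.flagged_samples}")
    matrix = matrix.drop_samples(qc.flagged_samples)
    design = design.drop_samples(qc.flagged_samples)
else:
    print("no replicate outliers flagged")

table = qc_deg.call_degs(qc_deg.fit_timepoint_contrasts(matrix, design))
summary = qc_deg.summarize_degs(table)

args.out_dir.mkdir(parents=True, exist_ok=True)
qc_deg.write_deg_table(table, args.out_dir / "deg_table.tsv")
summary.table.to_csv(args.out_dir / "deg_summary.tsv", sep="\t")
qc.to_frame().to_csv(args.out_dir / "qc_outliers.tsv", sep="\t", index=False)

print("\nDEGs per time point (vs 0 h control):")
print(summary.table.to_string())
print(f"\nunion over all time points: {summary.union} DEGs")
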