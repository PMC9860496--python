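#!/usr/bin/env python
"""Stage 4 — weighted colocalization on a synthetic per-cell manifest.

Generates three conditions of five synthetic cells each, with planted
channel-overlap fractions mimicking strong, partial and absent recruitment
of a tagged enzyme to a marker-defined compartment, then computes the
per-cell weighted colocalization coefficient and per-condition mean ± SD.

Writes results/coloc_per_cell.tsv and results/coloc_summary.tsv.
"""

from pathlib import Path

import pandas as pd

from e2face.coloc import batch_coloc
from e2face.synthetic import simulate_image_pair

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

CONDITIONS = {"strong": 0.85, "partial": 0.45, "none": 0.05}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    seed = 100
    for condition, fraction in CONDITIONS.items():
        for i in range(5):
            d = SCRATCH / "coloc" / f"{condition}_{i}"
            # cell-to-cell biological variation around the condition mean
            cell_fraction = min(1.0, max(0.0, fraction + 0.02 * (i - 2)))
            simulate_image_pair(seed, overlap_fraction=cell_fraction, noise_sd=2.0,
                                out_dir=d)
            rows.append({
                "cell_id": f"{condition}_{i}", "condition": condition,
                "path_a": str(d / "channel_a.tif"),
                "path_b": str(d / "channel_b.tif"),
                "path_mask": str(d / "mask.tif"),
                "thr_a": 50, "thr_b": 50,
            })
            seed += 1
    manifest = pd.DataFrame(rows)
    per_cell, summary = batch_coloc(manifest)
    per_cell.to_csv(RESULTS / "coloc_per_cell.tsv", sep="\t", index=False)
    summary.to_csv(RESULTS / "coloc_summary.tsv", sep="\t", index=False)
    print("weighted colocalization per condition (mean ± SD of 5 cells):")
    for _, row in summary.iterrows():
        planted = CONDITIONS[row["condition"]]
        print(f"  {row['condition']:>8s}: {row['mean']:.3f} ± {row['sd']:.3f} "
              f"(planted overlap {planted})")


if __name__ == "__main__":
    main()
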