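#!/usr/bin/env python
"""Normalize every cohort, remove contamination outliers, residualize, PCA.

Reads results/study/data (written by 01_simulate_cohorts.py); writes per-
cohort corrected log2 matrices, a contamination report, and PCA sample
coordinates under results/study/preprocess.
"""

import json
import sys
from pathlib import Path

import pandas as pd

import proteorank as pr
from proteorank import io as prio
from proteorank.simulate import load_truth

ROOT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    data = ROOT / "data"
    out = ROOT / "preprocess"
    out.mkdir(parents=True, exist_ok=True)
    truth = load_truth(data / "truth.json")
    manifest = json.loads((data / "manifest.json").read_text())

    rows = []
    for ds_id in manifest["datasets"]:
        ds = prio.read_dataset(data / f"{ds_id}.matrix.tsv", data / f"{ds_id}.samples.tsv")
        res = pr.preprocess_dataset(ds, truth.contamination_marker_ids, outlier_k=3.0)
        prio.write_table(res.corrected, out / f"{ds_id}.corrected.tsv", index_name="protein_id")
        scores, var = pr.pca_qc(res.corrected)
        scores["group"] = [res.groups[s] for s in scores.index]
        prio.write_table(scores, out / f"{ds_id}.pca.tsv", index_name="sample_id")
        rows.append(
            {
                "dataset_id": ds_id,
                "outliers_removed": ";".join(res.outliers) or "none",
                "score_group_confounded": res.confounded,
                "pc1_var_pct": round(100 * var[0], 1),
                "pc2_var_pct": round(100 * var[1], 1) if len(var) > 1 else None,
            }
        )
        print(f"{ds_id}: removed {len(res.outliers)} outlier(s) "
              f"[planted: {sorted(set(res.outliers) & set(truth.outlier_sample_ids))}], "
              f"PC1 {100 * var[0]:.1f}% of variance")
    prio.write_table(pd.DataFrame(rows), out / "qc_summary.tsv")


if __name__ == "__main__":
    sys.exit(main())
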