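#!/usr/bin/env python
"""Cross-tissue and cross-species DE-set overlap with direction patterns.

Intersects the per-tissue DE sets (relaxed integration threshold), labels
every shared protein's direction profile, and reports the mitochondrial
fraction of each overlap region — the desk-scale analog of the
mitochondria-dominated three-proteome overlap.
"""

import sys
from pathlib import Path

import pandas as pd

import proteorank as pr
from proteorank import io as prio
from proteorank.simulate import load_truth

ROOT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    de_dir, out = ROOT / "de", ROOT / "overlap"
    out.mkdir(parents=True, exist_ok=True)
    truth = load_truth(ROOT / "data" / "truth.json")
    annotation = prio.read_annotation(ROOT / "data" / "annotation.tsv")

    sets = {}
    de_tables = {}
    for ds_id, tissue in (("ctx_disc", "cortex"), ("csf_disc", "csf"), ("serum_disc", "serum")):
        members = (de_dir / f"{ds_id}.de_set.integration.txt").read_text().split()
        sets[tissue] = set(members)
        de_tables[tissue] = pd.read_csv(de_dir / f"{ds_id}.de.tsv", sep="\t",
                                        index_col=0, na_values=["", "NA"],
                                        keep_default_na=False)

    universe = set.intersection(*(set(t.index) for t in de_tables.values()))
    report = pr.overlap_de_sets(sets, universe_size=len(universe))
    pr.annotate_overlap(report, annotation)
    prio.write_table(report.to_table(), out / "overlap_regions.tsv")
    prio.write_table(report.pairwise, out / "pairwise_overlap.tsv")

    three_way = report.intersection_all()
    count, frac = report.mito[frozenset(report.set_names)] if three_way else (0, None)
    print(f"DE sets: " + ", ".join(f"{k}={len(v)}" for k, v in sets.items()))
    print(f"three-tissue overlap: {len(three_way)} proteins, "
          f"{count} mitochondrial"
          + (f" ({100 * frac:.0f}%)" if frac is not None else ""))

    rows = []
    for p in sorted(set.union(*sets.values())):
        z = {t: de_tables[t].at[p, "z"] if p in de_tables[t].index else None
             for t in de_tables}
        try:
            pattern = pr.direction_pattern(z)
        except Exception:
            continue
        rows.append({"protein_id": p, "pattern": pattern,
                     "planted": p in truth.planted_ids(),
                     "mitochondrial": annotation.is_mitochondrial(p)})
    patterns = pd.DataFrame(rows)
    prio.write_table(patterns, out / "direction_patterns.tsv")
    print("\ndirection patterns of DE-union proteins:")
    print(patterns["pattern"].value_counts().to_string())


if __name__ == "__main__":
    sys.exit(main())
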