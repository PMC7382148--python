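"""Cross-dataset DE-set integration: Venn decomposition, direction patterns,
mitochondrial annotation of overlap regions.

Overlap is computed on protein identifiers; for cross-species comparisons
an explicit homolog map (mouse id -> human id) is applied first, defaulting
to identity. A hypergeometric enrichment p-value is attached to each
pairwise overlap as context for whether the observed sharing exceeds
chance given the quantified universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DataError, ProteinAnnotation


@dataclass
class OverlapReport:
    """Exact Venn decomposition of 2–4 named DE sets."""

    set_names: list
    set_sizes: dict
    regions: dict  # frozenset of set names -> sorted member list
    pairwise: pd.DataFrame | None = None  # overlap sizes + hypergeometric p
    mito: dict = field(default_factory=dict)  # region -> (count, fraction)

    def region(self, *names) -> list:
        """Members exactly in ``names`` and in no other input set."""
        return self.regions.get(frozenset(names), [])

    def intersection_all(self) -> list:
        return self.region(*self.set_names)

    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def to_table(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.regions, key=lambda k: (len(k), sorted(k))):
            count, frac = self.mito.get(key, (None, None))
            rows.append(
                {
                    "region": "&".join(sorted(key)),
                    "n": len(self.regions[key]),
                    "n_mito": count,
                    "mito_fraction": frac,
                    "mito_percent": display_percent(frac) if frac is not None else None,
                    "members": ";".join(self.regions[key]),
                }
            )
        return pd.DataFrame(rows)


def overlap_de_sets(named_sets: dict, universe_size: int | None = None) -> OverlapReport:
    """Venn decomposition of 2–4 named sets with deterministic member order.

    ``universe_size`` (number of jointly quantified proteins) enables the
    pairwise hypergeometric overlap test.
    """
    names = list(named_sets)
    if len(names) != len(set(names)):
        raise DataError(f"duplicate set names: {names}")
    if not (2 <= len(names) <= 4):
        raise DataError("overlap needs 2-4 named sets")
    sets = {k: set(v) for k, v in named_sets.items()}
    regions: dict[frozenset, list] = {}
    for p in sorted(set().union(*sets.values())):
        key = frozenset(k for k in names if p in sets[k])
        regions.setdefault(key, []).append(p)

    pairwise = None
    rows = []
    for a, b in combinations(names, 2):
        inter = len(sets[a] & sets[b])
        row = {"set_a": a, "set_b": b, "n_a": len(sets[a]), "n_b": len(sets[b]), "n_overlap": inter}
        if universe_size is not None:
            row["hypergeom_p"] = hypergeometric_overlap_p(
                len(sets[a]), len(sets[b]), inter, universe_size
            )
        rows.append(row)
    if rows:
        pairwise = pd.DataFrame(rows)
    return OverlapReport(
        set_names=names,
        set_sizes={k: len(v) for k, v in sets.items()},
        regions=regions,
        pairwise=pairwise,
    )


def hypergeometric_overlap_p(n_a: int, n_b: int, n_overlap: int, universe: int) -> float:
    """P(overlap ≥ observed) when two sets of these sizes are drawn at random."""
    if universe < max(n_a, n_b):
        raise DataError("universe smaller than an input set")
    return float(stats.hypergeom.sf(n_overlap - 1, universe, n_a, n_b))


_FLUIDS = ("csf", "serum")


def direction_pattern(z_by_tissue: dict) -> str:
    """Classify a protein's cross-tissue direction profile.

    ``z_by_tissue`` maps tissue -> Z-scored fold change (missing tissues
    omitted or NaN). Fluid = CSF and/or serum agreeing in sign. Labels:
    all-up, all-down, cortex-up/fluid-down, cortex-down/fluid-up, mixed.
    """
    z = {t: v for t, v in z_by_tissue.items() if v is not None and np.isfinite(v)}
    if len(z) < 2:
        raise DataError("need Z in at least 2 tissues")
    signs = {t: np.sign(v) for t, v in z.items()}
    vals = list(signs.values())
    if all(s > 0 for s in vals):
        return "all-up"
    if all(s < 0 for s in vals):
        return "all-down"
    fluid_signs = [signs[t] for t in _FLUIDS if t in signs]
    ctx = signs.get("cortex")
    if ctx is not None and fluid_signs:
        if ctx > 0 and all(s < 0 for s in fluid_signs):
            return "cortex-up/fluid-down"
        if ctx < 0 and all(s > 0 for s in fluid_signs):
            return "cortex-down/fluid-up"
    return "mixed"


def display_percent(fraction: float) -> int:
    """Round-half-up integer percent for display (0.5946 -> 59)."""
    return int(np.floor(fraction * 100.0 + 0.5))


def annotate_overlap(report: OverlapReport, annotation: ProteinAnnotation) -> OverlapReport:
    """Attach mitochondrial count/fraction to every Venn region (in place)."""
    for key, members in report.regions.items():
        if not members:
            report.mito[key] = (0, None)
            continue
        count = sum(annotation.is_mitochondrial(p) for p in members)
        report.mito[key] = (count, count / len(members))
    return report
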