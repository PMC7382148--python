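"""Preranked permutation enrichment (GSEA-style) on the integrated ranking.

A gene set concentrated near the top of the prioritized list is detected
by the weighted Kolmogorov–Smirnov running sum: walking down the ranking,
hits increment by |score|^w (score = −log10 of the integrated empirical p,
w = 1 by default; w = 0 recovers the classical KS statistic) normalized to
sum to one, misses decrement by 1/(N − n_set); the enrichment score is the
signed maximum deviation. Significance comes from a set-permutation null —
random same-size sets drawn from the ranked universe — with the add-one
empirical p on |ES|, and BH FDR across sets. Phenotype permutation is not
applicable here: the ranking is an integrated statistic, not a per-sample
measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import DataError
from .diffexp import bh_adjust


@dataclass
class GeneSetCollection:
    """Named protein/gene sets (GMT-style), members deduplicated."""

    sets: dict  # name -> set of ids
    descriptions: dict
    source: str = ""

    def filtered(self, universe, min_size: int = 5, max_size: int | None = None) -> "GeneSetCollection":
        """Intersect with the ranked universe and drop out-of-size sets."""
        uni = set(universe)
        keep, desc = {}, {}
        for name, members in self.sets.items():
            inter = members & uni
            if len(inter) < min_size:
                continue
            if max_size is not None and len(inter) > max_size:
                continue
            if len(inter) >= len(uni):
                continue
            keep[name] = inter
            desc[name] = self.descriptions.get(name, "")
        return GeneSetCollection(sets=keep, descriptions=desc, source=self.source)


def load_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member..."""
    path = Path(path)
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataError(f"{path.name}:{ln}: GMT line needs >=3 tab-separated fields")
        name, desc, *members = fields
        if name in sets:
            raise DataError(f"{path.name}:{ln}: duplicate set name {name!r}")
        sets[name] = {m for m in members if m}
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> Path:
    path = Path(path)
    lines = []
    for name in collection.sets:
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *sorted(collection.sets[name])]))
    path.write_text("\n".join(lines) + "\n")
    return path


def _es_from_hits(hits: np.ndarray, weights: np.ndarray) -> tuple[float, int, np.ndarray]:
    """Running-sum ES given a hit indicator over the ranking.

    ``weights`` are |score|^w per position (used at hit positions only).
    Returns (es, extremum position, running profile).
    """
    N = hits.size
    nh = int(hits.sum())
    hw = np.where(hits, weights, 0.0)
    denom = hw.sum()
    if denom <= 0:
        # all hit weights zero (e.g. w>0 with zero scores): fall back to equal steps
        hw = hits.astype(float)
        denom = hw.sum()
    step_hit = hw / denom
    step_miss = np.where(hits, 0.0, 1.0 / (N - nh))
    running = np.cumsum(step_hit - step_miss)
    imax = int(np.argmax(np.abs(running)))
    return float(running[imax]), imax, running


@dataclass
class EnrichmentScoreResult:
    es: float
    running: np.ndarray
    extremum_index: int
    leading_edge: list


def enrichment_score(
    ranking: list, gene_set, scores=None, weight_exponent: float = 1.0
) -> EnrichmentScoreResult:
    """Weighted KS enrichment score of ``gene_set`` in an ordered ranking.

    ``scores`` aligns with ``ranking`` (e.g. −log10 empirical p); ignored
    when ``weight_exponent`` is 0. Leading edge: the hit members at or
    before the extremum for a positive ES, at or after it for a negative.
    """
    members = set(gene_set)
    N = len(ranking)
    hits = np.fromiter((p in members for p in ranking), dtype=bool, count=N)
    nh = int(hits.sum())
    if nh == 0:
        raise DataError("gene set does not intersect the ranking")
    if nh == N:
        raise DataError("set equals universe: enrichment undefined")
    if weight_exponent == 0 or scores is None:
        w = np.ones(N)
    else:
        w = np.abs(np.asarray(scores, dtype=float)) ** weight_exponent
    es, imax, running = _es_from_hits(hits, w)
    if es >= 0:
        lead = [p for i, p in enumerate(ranking[: imax + 1]) if hits[i]]
    else:
        lead = [p for i, p in enumerate(ranking) if i > imax and hits[i]]
    return EnrichmentScoreResult(es=es, running=running, extremum_index=imax, leading_edge=lead)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per set: size, es, p_emp, fdr, leading_edge
    n_permutations: int
    seed: int

    def enriched(self, fdr_max: float = 0.05) -> list:
        t = self.table
        return list(t.index[t["fdr"] < fdr_max])


def enrichment_permutation(
    ranking: list,
    collection: GeneSetCollection,
    B: int = 1000,
    seed: int = 0,
    scores=None,
    weight_exponent: float = 1.0,
    min_size: int = 5,
    max_size: int | None = None,
) -> EnrichmentResult:
    """Set-permutation significance for every set in the collection.

    The null for a set of size n is the |ES| of B random n-member sets
    drawn from the ranked universe; empirical p uses the add-one rule and
    BH FDR is applied across sets. Nulls are shared between sets of equal
    size, so the permutation budget is spent once per distinct size.
    """
    if B < 1:
        raise DataError("B must be >= 1")
    coll = collection.filtered(ranking, min_size=min_size, max_size=max_size)
    if not coll.sets:
        raise DataError("no gene set passes the size filter against this ranking")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 55001]))
    N = len(ranking)
    if weight_exponent == 0 or scores is None:
        w = np.ones(N)
    else:
        w = np.abs(np.asarray(scores, dtype=float)) ** weight_exponent

    null_by_size: dict[int, np.ndarray] = {}
    sizes = sorted({len(s) for s in coll.sets.values()})
    for n_set in sizes:
        null_abs = np.empty(B)
        for b in range(B):
            idx = rng.choice(N, size=n_set, replace=False)
            hits = np.zeros(N, dtype=bool)
            hits[idx] = True
            es_b, _, _ = _es_from_hits(hits, w)
            null_abs[b] = abs(es_b)
        null_by_size[n_set] = np.sort(null_abs)

    rows = []
    for name in sorted(coll.sets):
        res = enrichment_score(ranking, coll.sets[name], scores=scores,
                               weight_exponent=weight_exponent)
        null_abs = null_by_size[len(coll.sets[name])]
        # add-one tail count of |null ES| >= |observed ES|
        n_ge = null_abs.size - np.searchsorted(null_abs, abs(res.es), side="left")
        p_emp = (1.0 + n_ge) / (1.0 + null_abs.size)
        rows.append(
            {
                "set": name,
                "size": len(coll.sets[name]),
                "es": res.es,
                "p_emp": p_emp,
                "leading_edge": ";".join(res.leading_edge),
            }
        )
    tbl = pd.DataFrame(rows).set_index("set")
    tbl["fdr"] = bh_adjust(tbl["p_emp"].to_numpy())
    tbl = tbl.sort_values(["p_emp", "es"])
    return EnrichmentResult(table=tbl, n_permutations=B, seed=seed)
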