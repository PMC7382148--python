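"""Rank aggregation across datasets by uniform order statistics.

Each dataset contributes a significance-ordered protein list with ranks
normalized to (0, 1]. For a protein seen in N lists with sorted normalized
ranks r₁ ≤ … ≤ r_N, the Q statistic is the joint probability that N
independent U(0,1) draws have their i-th order statistic below rᵢ for
every i, computed by the recursion

    V₀ = 1,   V_k = Σ_{i=1..k} (−1)^{i−1} · r_{N−k+1}^i / i! · V_{k−i},
    Q = N! · V_N

Small Q marks proteins consistently near the top of every list. Because
Q's scale depends on N, significance is calibrated by permutation:
protein labels are shuffled independently within every list, null Q
values are pooled per N-available stratum, and the empirical p uses the
add-one rule so it is never zero. Integration is tiered — cohorts within
a tissue first, then tissues, then a final combination restricted to
proteins with at least nominal evidence of change in a biofluid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd

from .datamodel import DataError
from .diffexp import DEResult, bh_adjust


# ---------------------------------------------------------------------------
# ranked lists


@dataclass
class RankedList:
    """One dataset's proteins ordered most-significant-first."""

    dataset_id: str
    proteins: list  # ordered, unique

    def __post_init__(self) -> None:
        if not self.proteins:
            raise DataError(f"{self.dataset_id}: empty ranked list")
        if len(set(self.proteins)) != len(self.proteins):
            raise DataError(f"{self.dataset_id}: duplicate proteins in ranked list")

    @property
    def n(self) -> int:
        return len(self.proteins)

    def normalized_ranks(self) -> pd.Series:
        """rank/N in (0, 1], most significant smallest."""
        n = self.n
        return pd.Series(
            (np.arange(1, n + 1)) / n, index=self.proteins, name=self.dataset_id
        )

    def restrict(self, keep) -> "RankedList":
        """Subset to ``keep`` preserving order (ranks renormalize on use)."""
        keep = set(keep)
        sub = [p for p in self.proteins if p in keep]
        if not sub:
            raise DataError(f"{self.dataset_id}: restriction removed all proteins")
        return RankedList(self.dataset_id, sub)


def rank_proteins(de: DEResult) -> RankedList:
    """Significance order: ascending p, ties by descending |Z| then id."""
    t = de.table
    ok = t.index[np.isfinite(t["p_raw"])]
    if len(ok) == 0:
        raise DataError(f"{de.dataset_id}: no protein with a defined p-value")
    sub = t.loc[ok]
    absz = sub["z"].abs().fillna(0.0)
    order = sorted(ok, key=lambda p: (sub.at[p, "p_raw"], -absz.at[p], str(p)))
    return RankedList(de.dataset_id or "de", order)


# ---------------------------------------------------------------------------
# Q statistic


def _q_rows(R: np.ndarray) -> np.ndarray:
    """Vectorized Q for rows of sorted normalized ranks (shape n × m)."""
    n, m = R.shape
    V = [np.ones(n)]
    for k in range(1, m + 1):
        r = R[:, m - k]
        acc = np.zeros(n)
        rp = np.ones(n)
        fact = 1.0
        for i in range(1, k + 1):
            rp = rp * r
            fact *= i
            acc += ((-1.0) ** (i - 1)) * rp / fact * V[k - i]
        V.append(acc)
    return np.clip(factorial(m) * V[m], 0.0, 1.0)


def q_statistic(sorted_ranks) -> float:
    """Q for one protein's sorted normalized ranks r₁ ≤ … ≤ r_N in (0, 1]."""
    r = np.asarray(sorted_ranks, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise DataError("ranks must be a nonempty 1-d sequence")
    if np.any(~np.isfinite(r)) or np.any(r <= 0) or np.any(r > 1):
        raise DataError("normalized ranks must lie in (0, 1]")
    if np.any(np.diff(r) < 0):
        raise DataError("ranks must be sorted nondecreasing")
    return float(_q_rows(r[None, :])[0])


def _q_by_stratum(R: np.ndarray, navail: np.ndarray) -> np.ndarray:
    """Q per row of a NaN-padded rank matrix; NaNs sort to the end."""
    S = np.sort(R, axis=1)
    q = np.full(R.shape[0], np.nan)
    for m in np.unique(navail):
        if m == 0:
            continue
        rows = navail == m
        q[rows] = _q_rows(S[rows, :m])
    return q


# ---------------------------------------------------------------------------
# permutation null + empirical p


def build_rank_matrix(lists: list[RankedList]) -> tuple[pd.DataFrame, np.ndarray]:
    """Union-of-proteins × lists matrix of normalized ranks (NaN = absent)."""
    names = [lst.dataset_id for lst in lists]
    if len(set(names)) != len(names):
        raise DataError(f"duplicate list names: {names}")
    proteins = sorted(set().union(*(lst.proteins for lst in lists)))
    R = pd.DataFrame(np.nan, index=proteins, columns=names)
    for lst in lists:
        R.loc[lst.proteins, lst.dataset_id] = lst.normalized_ranks().to_numpy()
    navail = np.isfinite(R.to_numpy()).sum(axis=1)
    return R, navail


def permutation_null(
    lists: list[RankedList], B: int, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Null Q samples per n-available stratum from within-list label shuffles.

    Each permutation independently shuffles which protein holds which rank
    within every list (membership patterns stay fixed), recomputes Q for
    all proteins, and pools the draws by the number of lists the protein
    appears in. Returned arrays are sorted.
    """
    if B < 1:
        raise DataError("B must be >= 1")
    Rdf, navail = build_rank_matrix(lists)
    R = Rdf.to_numpy()
    finite_rows = [np.flatnonzero(np.isfinite(R[:, j])) for j in range(R.shape[1])]
    null: dict[int, list] = {int(m): [] for m in np.unique(navail) if m > 0}
    Rb = np.empty_like(R)
    for _ in range(B):
        Rb[:] = R
        for j, idx in enumerate(finite_rows):
            Rb[idx, j] = R[rng.permutation(idx), j]
        qb = _q_by_stratum(Rb, navail)
        for m in null:
            null[m].append(qb[navail == m])
    return {m: np.sort(np.concatenate(v)) for m, v in null.items()}


def empirical_p(q, null_samples: np.ndarray):
    """Add-one empirical p: (1 + #{null ≤ q}) / (1 + #null); never zero."""
    null_samples = np.asarray(null_samples, dtype=float)
    if null_samples.size == 0:
        raise DataError("empty null stratum")
    counts = np.searchsorted(null_samples, np.atleast_1d(np.asarray(q, dtype=float)), side="right")
    p = (1.0 + counts) / (1.0 + null_samples.size)
    return float(p[0]) if np.isscalar(q) or np.ndim(q) == 0 else p


def combine_lists(
    lists: list[RankedList], B: int, rng: np.random.Generator, name: str = "combined"
) -> tuple[RankedList, pd.DataFrame]:
    """One aggregation step: Q per protein, permutation null, empirical p.

    Returns the new ranked list (ordered by p_emp, ties by q then id) and
    a per-protein table (n_avail, q, p_emp).
    """
    Rdf, navail = build_rank_matrix(lists)
    q = _q_by_stratum(Rdf.to_numpy(), navail)
    null = permutation_null(lists, B, rng)
    p = np.empty_like(q)
    for m, samples in null.items():
        rows = navail == m
        p[rows] = empirical_p(q[rows], samples)
    tbl = pd.DataFrame({"n_avail": navail, "q": q, "p_emp": p}, index=Rdf.index)
    order = sorted(tbl.index, key=lambda pr: (tbl.at[pr, "p_emp"], tbl.at[pr, "q"], str(pr)))
    return RankedList(name, order), tbl


# ---------------------------------------------------------------------------
# pre-final filter + tiered integration


def filter_unchanged(
    universe, fluid_de_results: list[DEResult], p_max: float = 0.05
) -> set:
    """Keep proteins with nominal evidence of change in ≥1 biofluid dataset.

    "Change" is the weakest defensible bar: raw p < ``p_max`` in at least
    one CSF or serum dataset. Proteins flat in every biofluid are dropped
    before the final integration — the goal is fluid-measurable markers.
    """
    if not fluid_de_results:
        raise DataError("need at least one CSF/serum DE result for the filter")
    retained = set()
    for de in fluid_de_results:
        t = de.table
        hit = t.index[np.isfinite(t["p_raw"]) & (t["p_raw"] < p_max)]
        retained.update(hit)
    retained &= set(universe)
    if not retained:
        raise DataError("filter removed all proteins")
    return retained


@dataclass
class TierPlan:
    """3-level aggregation plan: cohorts → tissue → final."""

    level1: dict  # group name -> list of dataset_ids
    level2: dict  # tissue name -> list of level-1 group names
    apply_fluid_filter: bool = True

    def validate(self, dataset_ids) -> None:
        seen = []
        for members in self.level1.values():
            seen.extend(members)
        if sorted(seen) != sorted(set(seen)):
            raise DataError("a dataset appears in more than one level-1 group")
        missing = set(dataset_ids) - set(seen)
        if missing:
            raise DataError(f"tier plan missing dataset(s): {sorted(missing)}")
        unknown = set(seen) - set(dataset_ids)
        if unknown:
            raise DataError(f"tier plan references unknown dataset(s): {sorted(unknown)}")
        l2_members = [g for groups in self.level2.values() for g in groups]
        unknown2 = set(l2_members) - set(self.level1)
        if unknown2:
            raise DataError(f"level-2 references unknown group(s): {sorted(unknown2)}")


def default_tier_plan(datasets_meta: dict) -> TierPlan:
    """Group datasets by (tissue, cohort_role) then by tissue.

    ``datasets_meta`` maps dataset_id -> (tissue, species, cohort_role).
    Mouse datasets join their tissue at level 2 as their own level-1 group.
    """
    level1: dict[str, list] = {}
    for ds_id, (tissue, species, role) in datasets_meta.items():
        key = f"{tissue}_{role}" if species == "human" else f"{species}_{tissue}"
        level1.setdefault(key, []).append(ds_id)
    level2: dict[str, list] = {}
    for ds_id, (tissue, _species, _role) in datasets_meta.items():
        for g, members in level1.items():
            if ds_id in members:
                level2.setdefault(tissue, [])
                if g not in level2[tissue]:
                    level2[tissue].append(g)
    return TierPlan(level1={k: sorted(v) for k, v in level1.items()},
                    level2={k: sorted(v) for k, v in level2.items()})


@dataclass
class IntegratedRanking:
    """Final prioritization: per-protein Q, empirical p, FDR, final rank."""

    table: pd.DataFrame  # n_avail, q, p_emp, fdr, final_rank (+ tissue ranks)
    tier_tables: dict = field(default_factory=dict)  # level name -> per-protein table
    seed: int | None = None
    n_permutations: int | None = None

    def top(self, k: int = 20) -> pd.DataFrame:
        return self.table.sort_values("final_rank").head(k)


def tiered_integration(
    ranked_lists: dict,
    plan: TierPlan,
    B: int = 1000,
    seed: int = 0,
    fluid_de_results: list[DEResult] | None = None,
) -> IntegratedRanking:
    """3-step aggregation: cohort groups → tissues → final ranking.

    Before the final step, if ``plan.apply_fluid_filter`` and biofluid DE
    results are supplied, proteins without nominal change in any CSF/serum
    dataset are dropped and the tissue lists renormalized over the
    retained universe (so the final permutation null stays calibrated).
    """
    plan.validate(list(ranked_lists))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 40427]))
    tier_tables: dict[str, pd.DataFrame] = {}

    level1_lists: dict[str, RankedList] = {}
    for gname in sorted(plan.level1):
        members = [ranked_lists[d] for d in plan.level1[gname]]
        combined, tbl = combine_lists(members, B, rng, name=gname)
        level1_lists[gname] = combined
        tier_tables[f"level1/{gname}"] = tbl

    level2_lists: dict[str, RankedList] = {}
    for tissue in sorted(plan.level2):
        members = [level1_lists[g] for g in plan.level2[tissue]]
        combined, tbl = combine_lists(members, B, rng, name=tissue)
        level2_lists[tissue] = combined
        tier_tables[f"level2/{tissue}"] = tbl

    final_inputs = list(level2_lists.values())
    if plan.apply_fluid_filter and fluid_de_results:
        universe = set().union(*(lst.proteins for lst in final_inputs))
        retained = filter_unchanged(universe, fluid_de_results)
        final_inputs = [lst.restrict(retained) for lst in final_inputs]

    final_list, final_tbl = combine_lists(final_inputs, B, rng, name="final")
    final_tbl = final_tbl.copy()
    final_tbl["fdr"] = bh_adjust(final_tbl["p_emp"].to_numpy())
    rank_pos = {p: i + 1 for i, p in enumerate(final_list.proteins)}
    final_tbl["final_rank"] = [rank_pos[p] for p in final_tbl.index]
    for tissue, lst in level2_lists.items():
        nr = lst.normalized_ranks()
        final_tbl[f"rank_{tissue}"] = nr.reindex(final_tbl.index)
    tier_tables["final"] = final_tbl
    return IntegratedRanking(
        table=final_tbl.sort_values("final_rank"),
        tier_tables=tier_tables,
        seed=seed,
        n_permutations=B,
    )
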