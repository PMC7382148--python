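"""End-to-end orchestration of the synthetic study.

``run_study`` executes simulate → preprocess → differential expression →
cross-tissue overlap → tiered rank integration → enrichment in memory and
(optionally) writes every stage artifact plus a provenance manifest to an
output directory. Stages communicate through plain tables, so any stage
can be rerun from files via the CLI.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as prio
from .datamodel import DE_SPEC_PRESETS, DECallSpec, RunConfig, make_manifest
from .diffexp import DEResult, fit_moderated_t
from .enrichment import EnrichmentResult, GeneSetCollection, enrichment_permutation, write_gmt
from .overlap import OverlapReport, annotate_overlap, overlap_de_sets
from .preprocess import PreprocessResult, preprocess_dataset
from .rank import IntegratedRanking, default_tier_plan, rank_proteins, tiered_integration
from .simulate import (
    SimConfig,
    SyntheticTruth,
    default_study_config,
    generate_mouse_counterpart,
    generate_study,
    make_annotation,
    write_fixture_bundle,
)


@dataclass
class StudyResult:
    """Everything the pipeline produced, keyed for downstream scoring."""

    datasets: list
    truth: SyntheticTruth
    preprocessed: dict  # dataset_id -> PreprocessResult
    de_results: dict  # dataset_id -> DEResult
    de_sets: dict  # dataset_id -> set of called proteins
    overlap: OverlapReport | None
    ranking: IntegratedRanking
    enrichment: EnrichmentResult | None
    timings: dict = field(default_factory=dict)


def _truth_gene_sets(truth: SyntheticTruth, rng: np.random.Generator,
                     n_random: int = 20, random_size: int = 30) -> GeneSetCollection:
    """Planted signature + module sets plus random decoys of matched scale."""
    sets = {}
    desc = {}
    if truth.signature_ids:
        sets["planted_signature"] = set(truth.signature_ids)
        desc["planted_signature"] = "cross-tissue planted signature proteins"
    if truth.mito_module_ids:
        sets["mito_module"] = set(truth.mito_module_ids)
        desc["mito_module"] = "planted correlated mitochondrial module"
    # decoys avoid planted proteins so they carry no signal by construction
    decoy_pool = sorted(set(truth.baseline_log2) - truth.planted_ids())
    for i in range(n_random):
        name = f"random_{i + 1:02d}"
        sets[name] = set(rng.choice(decoy_pool, size=random_size, replace=False))
        desc[name] = "random decoy set"
    return GeneSetCollection(sets=sets, descriptions=desc, source="synthetic")


def run_study(
    sim_config: SimConfig | None = None,
    seed: int = 0,
    B: int = 200,
    out_dir=None,
    de_preset: str = "default",
    overlap_preset: str = "integration",
    include_mouse: bool = True,
    correct_contamination: bool = True,
    gene_sets: GeneSetCollection | None = None,
    enrichment_B: int | None = None,
) -> StudyResult:
    """Run the full synthetic study; see module docstring for the stages.

    ``seed`` drives the simulator (if ``sim_config`` is None) and every
    permutation stage. Identical (config, seed, B) reproduce identical
    outputs.
    """
    timings: dict[str, float] = {}
    t0 = time.time()
    config = sim_config if sim_config is not None else default_study_config(seed=seed)
    datasets, truth = generate_study(config)
    if include_mouse:
        datasets = datasets + [generate_mouse_counterpart(config, truth)]
        truth.observed_proteins["mouse_csf"] = datasets[-1].proteins
    timings["simulate"] = time.time() - t0

    t0 = time.time()
    panel = truth.contamination_marker_ids if correct_contamination else None
    preprocessed: dict[str, PreprocessResult] = {}
    for ds in datasets:
        preprocessed[ds.dataset_id] = preprocess_dataset(ds, panel, outlier_k=3.0)
    timings["preprocess"] = time.time() - t0

    t0 = time.time()
    de_results: dict[str, DEResult] = {}
    for ds in datasets:
        pre = preprocessed[ds.dataset_id]
        de_results[ds.dataset_id] = fit_moderated_t(
            pre.corrected, pre.groups, dataset_id=ds.dataset_id, tissue=ds.tissue
        )
    spec: DECallSpec = DE_SPEC_PRESETS[de_preset]
    de_sets = {k: de.de_set(spec) for k, de in de_results.items()}
    timings["diffexp"] = time.time() - t0

    # cross-tissue overlap on the discovery cohorts, one set per tissue
    t0 = time.time()
    overlap_spec: DECallSpec = DE_SPEC_PRESETS[overlap_preset]
    tissue_sets = {}
    shared_universe: set | None = None
    for ds in datasets:
        if ds.cohort_role != "discovery" or ds.species != "human":
            continue
        if ds.tissue in tissue_sets:
            continue
        tissue_sets[ds.tissue] = de_results[ds.dataset_id].de_set(overlap_spec)
        shared_universe = (
            set(ds.proteins) if shared_universe is None else shared_universe & set(ds.proteins)
        )
    report = None
    if len(tissue_sets) >= 2:
        report = overlap_de_sets(tissue_sets, universe_size=len(shared_universe))
        annotate_overlap(report, make_annotation(config, truth))
    timings["overlap"] = time.time() - t0

    t0 = time.time()
    ranked = {k: rank_proteins(de) for k, de in de_results.items()}
    meta = {ds.dataset_id: (ds.tissue, ds.species, ds.cohort_role) for ds in datasets}
    plan = default_tier_plan(meta)
    fluid_de = [de for de in de_results.values() if de.tissue in ("csf", "serum")]
    ranking = tiered_integration(ranked, plan, B=B, seed=seed, fluid_de_results=fluid_de)
    timings["rank"] = time.time() - t0

    t0 = time.time()
    enr = None
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 90011]))
    coll = gene_sets if gene_sets is not None else _truth_gene_sets(truth, rng)
    if coll.sets:
        ordered = list(ranking.table.sort_values("final_rank").index)
        scores = -np.log10(ranking.table.sort_values("final_rank")["p_emp"].to_numpy())
        try:
            enr = enrichment_permutation(
                ordered, coll, B=enrichment_B or B, seed=seed, scores=scores
            )
        except Exception:
            enr = None  # e.g. every set filtered out against a small universe
    timings["enrichment"] = time.time() - t0

    result = StudyResult(
        datasets=datasets,
        truth=truth,
        preprocessed=preprocessed,
        de_results=de_results,
        de_sets=de_sets,
        overlap=report,
        ranking=ranking,
        enrichment=enr,
        timings=timings,
    )
    if out_dir is not None:
        write_study_outputs(result, config, out_dir, seed=seed, B=B, coll=coll)
    return result


def write_study_outputs(result: StudyResult, config: SimConfig, out_dir,
                        seed: int, B: int, coll: GeneSetCollection | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fixture_bundle(result.datasets, result.truth, out / "data")
    for ds_id, de in result.de_results.items():
        prio.write_table(de.table, out / f"{ds_id}.de.tsv", index_name="protein_id")
    meta = pd.DataFrame(
        [
            {
                "dataset_id": ds.dataset_id,
                "tissue": ds.tissue,
                "species": ds.species,
                "cohort_role": ds.cohort_role,
                "n_samples": ds.n_samples,
                "n_proteins": ds.n_proteins,
            }
            for ds in result.datasets
        ]
    )
    prio.write_table(meta, out / "datasets.tsv")
    if result.overlap is not None:
        prio.write_table(result.overlap.to_table(), out / "overlap.tsv")
    prio.write_table(result.ranking.table, out / "integrated_ranking.tsv",
                     index_name="protein_id")
    if result.enrichment is not None:
        prio.write_table(result.enrichment.table, out / "enrichment.tsv", index_name="set")
    if coll is not None and coll.sets:
        write_gmt(coll, out / "gene_sets.gmt")
    rc = RunConfig(seed=seed, n_permutations=B)
    prio.write_manifest(
        make_manifest(rc, "all", timings={k: round(v, 3) for k, v in result.timings.items()}),
        out / "manifest.json",
    )
    return out
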