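"""Synthetic multi-dataset proteome studies with planted ground truth.

The generator emulates the structure of a multi-cohort AD tissue/biofluid
TMT study at desk scale:

* a shared protein universe whose baseline abundances are evenly spaced on
  log10 over a configurable dynamic range (default 5 decades), so abundance
  ranks are exact and depth censoring is reproducible;
* per-dataset profiling depth — only the top ``depth`` most abundant
  proteins are quantified, the rest are absent from that cohort's matrix
  (this is what makes a low-abundance module invisible to shallow
  profiling);
* a set of cross-tissue signature proteins whose group means shift in AD
  samples, signed per tissue (default: up in cortex, down in CSF and
  serum, mirroring amyloid-like mirrored expression);
* a correlated "mitochondrial module" planted in a mid/low-abundance band
  with the same tissue-signed shift plus equicorrelated within-module
  noise;
* a blood-contamination covariate loading strongly on a marker panel of
  high-abundance proteins (hemoglobin-like) and weakly on everything else,
  with optional gross outlier samples;
* independent Gaussian noise on the log2 scale; intensities are exported
  as ``2**log2``.

Every planted choice is recorded in a :class:`SyntheticTruth` manifest so
downstream recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ProteinAnnotation, ProteomeDataset
from . import io as prio

LOG2_PER_LOG10 = np.log2(10.0)


@dataclass(frozen=True)
class DatasetSpec:
    """Shape of one synthetic cohort."""

    dataset_id: str
    tissue: str  # cortex | csf | serum
    species: str = "human"
    cohort_role: str = "discovery"
    n_ad: int = 10
    n_ctl: int = 10
    n_mci: int = 0
    depth: int = 2000  # number of proteins quantified (top by abundance)


@dataclass
class SimConfig:
    """Full specification of a synthetic study.

    ``effect_size_sd`` is the AD-vs-Ctl mean shift in units of the
    within-group SD (``noise_sd``); MCI samples receive half the shift.
    ``mito_band`` gives the abundance-rank band (as fractions of the
    universe) in which the mitochondrial module lives.
    """

    n_proteins: int = 2000
    datasets: tuple[DatasetSpec, ...] = ()
    abundance_range_log10: float = 5.0
    n_signature: int = 20
    effect_size_sd: float = 1.5
    mito_module_size: int = 60
    mito_module_rho: float = 0.3
    mito_band: tuple[float, float] = (0.40, 0.70)
    direction_map: dict = field(
        default_factory=lambda: {"cortex": 1.0, "csf": -1.0, "serum": -1.0}
    )
    n_markers: int = 8
    contamination_strength: float = 1.0
    contamination_bleed: float = 0.02
    n_outlier_samples: int = 3
    outlier_shift_sd: float = 5.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.datasets:
            self.datasets = _default_datasets(self.n_proteins)
        for ds in self.datasets:
            if ds.depth > self.n_proteins:
                raise ValueError(
                    f"dataset {ds.dataset_id}: depth {ds.depth} exceeds universe "
                    f"size {self.n_proteins}"
                )
        if not (0.0 <= self.mito_module_rho < 1.0):
            raise ValueError("mito_module_rho must be in [0, 1)")
        if self.effect_size_sd < 0:
            raise ValueError("effect_size_sd must be >= 0")
        lo, hi = self.mito_band
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("mito_band must be an increasing pair in [0, 1]")
        if self.mito_module_size > self.n_proteins:
            raise ValueError("mitochondrial module larger than the protein universe")
        band_size = int(self.mito_band[1] * self.n_proteins) - int(self.mito_band[0] * self.n_proteins)
        if self.mito_module_size > band_size:
            raise ValueError("mitochondrial module does not fit in its abundance band")


def _default_datasets(n: int) -> tuple[DatasetSpec, ...]:
    """Five-cohort layout: two cortex, two CSF, one serum, mixed depths."""
    return (
        DatasetSpec("ctx_disc", "cortex", "human", "discovery", depth=n),
        DatasetSpec("ctx_ref", "cortex", "human", "reference", depth=int(0.7 * n)),
        DatasetSpec("csf_disc", "csf", "human", "discovery", n_mci=4, depth=n),
        DatasetSpec("csf_ref", "csf", "human", "reference", depth=int(0.5 * n)),
        DatasetSpec("serum_disc", "serum", "human", "discovery", depth=int(0.9 * n)),
    )


def default_study_config(n_proteins: int = 2000, seed: int = 0, **overrides) -> SimConfig:
    """The standard synthetic study: 5 cohorts, planted signature + module."""
    return SimConfig(n_proteins=n_proteins, seed=seed, **overrides)


def null_study_config(n_proteins: int = 2000, seed: int = 0) -> SimConfig:
    """A global-null study: no effects, no contamination, no correlation.

    Used for calibration checks — every protein's AD/Ctl contrast is pure
    independent Gaussian noise, so DE p-values must be uniform.
    """
    return SimConfig(
        n_proteins=n_proteins,
        seed=seed,
        n_signature=0,
        effect_size_sd=0.0,
        mito_module_size=0,
        mito_module_rho=0.0,
        contamination_strength=0.0,
        contamination_bleed=0.0,
        n_outlier_samples=0,
    )


@dataclass
class SyntheticTruth:
    """Planted-effect manifest for scoring recovery."""

    signature_ids: list
    signature_effects: dict  # tissue -> signed log2 shift applied to AD samples
    mito_module_ids: list
    contamination_marker_ids: list
    outlier_sample_ids: list
    observed_proteins: dict  # dataset_id -> list of quantified protein ids
    baseline_log2: dict  # protein -> baseline log2 abundance
    seed: int

    def planted_ids(self) -> set:
        return set(self.signature_ids) | set(self.mito_module_ids)

    def abundance_order(self) -> list:
        """Universe protein ids from most to least abundant."""
        return sorted(self.baseline_log2, key=lambda p: (-self.baseline_log2[p], p))


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def generate_study(config: SimConfig) -> tuple[list[ProteomeDataset], SyntheticTruth]:
    """Draw the full synthetic study and its ground-truth manifest.

    Deterministic under ``config.seed``: the same config yields
    byte-identical matrices.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    proteins = _protein_ids(n)
    # evenly spaced baselines, descending: protein index == abundance rank
    top_log10 = 7.0  # arbitrary high anchor on the reporter-intensity scale
    base_log10 = np.linspace(top_log10, top_log10 - config.abundance_range_log10, n)
    base_log2 = base_log10 * LOG2_PER_LOG10

    min_depth = min(ds.depth for ds in config.datasets)
    band_lo = int(config.mito_band[0] * n)
    band_hi = int(config.mito_band[1] * n)
    mito_idx = np.sort(
        rng.choice(np.arange(band_lo, band_hi), size=config.mito_module_size, replace=False)
    ) if config.mito_module_size else np.array([], dtype=int)

    # markers are high-abundance (top 2%), so every cohort observes them
    n_top = max(config.n_markers, int(0.02 * n))
    marker_idx = np.sort(rng.choice(np.arange(n_top), size=config.n_markers, replace=False)) \
        if config.n_markers else np.array([], dtype=int)

    # signature proteins: observed in every cohort, outside module and panel
    sig_pool = np.setdiff1d(np.arange(min_depth), np.concatenate([mito_idx, marker_idx]))
    if config.n_signature > sig_pool.size:
        raise ValueError("n_signature exceeds the pool of universally observed proteins")
    sig_idx = np.sort(rng.choice(sig_pool, size=config.n_signature, replace=False)) \
        if config.n_signature else np.array([], dtype=int)

    effect = config.effect_size_sd * config.noise_sd
    effect_idx = np.concatenate([sig_idx, mito_idx]).astype(int)

    datasets: list[ProteomeDataset] = []
    observed: dict[str, list[str]] = {}
    outlier_ids: list[str] = []
    for ds in config.datasets:
        sign = float(config.direction_map.get(ds.tissue, 0.0))
        groups = ["AD"] * ds.n_ad + ["MCI"] * ds.n_mci + ["Ctl"] * ds.n_ctl
        m = len(groups)
        sample_ids = [f"{ds.dataset_id}_s{j + 1:02d}" for j in range(m)]
        # group dose: AD full effect, MCI half, Ctl none
        dose = np.array([1.0 if g == "AD" else 0.5 if g == "MCI" else 0.0 for g in groups])

        X = np.tile(base_log2[:, None], (1, m))
        if effect_idx.size and effect > 0 and sign != 0.0:
            X[effect_idx, :] += sign * effect * dose[None, :]

        # equicorrelated module noise: shared per-sample factor inside the block
        eps = rng.normal(0.0, 1.0, size=(n, m))
        if mito_idx.size and config.mito_module_rho > 0:
            f = rng.normal(0.0, 1.0, size=m)
            rho = config.mito_module_rho
            eps[mito_idx, :] = (
                np.sqrt(rho) * f[None, :] + np.sqrt(1.0 - rho) * eps[mito_idx, :]
            )
        X += config.noise_sd * eps

        # blood-contamination covariate: strong on the panel, weak bleed elsewhere
        scores = rng.normal(0.0, 1.0, size=m)
        if ds.tissue == "csf" and ds.cohort_role == "discovery" and config.n_outlier_samples:
            chosen = sorted(rng.choice(m, size=config.n_outlier_samples, replace=False))
            scores[chosen] += config.outlier_shift_sd
            outlier_ids.extend(sample_ids[j] for j in chosen)
        if config.contamination_strength > 0:
            loading = np.full(n, config.contamination_strength * config.contamination_bleed)
            loading[marker_idx] = config.contamination_strength
            X += loading[:, None] * scores[None, :]

        keep = np.arange(ds.depth)  # top-depth proteins by baseline abundance
        obs_ids = [proteins[i] for i in keep]
        observed[ds.dataset_id] = obs_ids
        mat = pd.DataFrame(
            np.exp2(X[keep, :]), index=pd.Index(obs_ids, name="protein_id"),
            columns=sample_ids,
        )
        datasets.append(
            ProteomeDataset(
                dataset_id=ds.dataset_id,
                tissue=ds.tissue,
                species=ds.species,
                cohort_role=ds.cohort_role,
                intensities=mat,
                sample_groups=pd.Series(groups, index=sample_ids),
            )
        )

    sig_ids = [proteins[i] for i in sig_idx]
    truth = SyntheticTruth(
        signature_ids=sig_ids,
        signature_effects={
            t: float(config.direction_map.get(t, 0.0)) * effect for t in ("cortex", "csf", "serum")
        },
        mito_module_ids=[proteins[i] for i in mito_idx],
        contamination_marker_ids=[proteins[i] for i in marker_idx],
        outlier_sample_ids=outlier_ids,
        observed_proteins=observed,
        baseline_log2={p: float(b) for p, b in zip(proteins, base_log2)},
        seed=config.seed,
    )
    return datasets, truth


def generate_mouse_counterpart(
    config: SimConfig,
    truth: SyntheticTruth,
    depth: int | None = None,
    n_ad: int = 6,
    n_ctl: int = 5,
    shared_fraction: float = 1.0,
    dataset_id: str = "mouse_csf",
) -> ProteomeDataset:
    """A small mouse-CSF cohort sharing part of the human signature.

    Emulates a transgenic-amyloidosis (5xFAD vs wild-type) CSF proteome of
    roughly a thousand proteins: 5xFAD maps to the AD label, WT to Ctl.
    ``shared_fraction`` of the human signature proteins observed at this
    depth carry the same CSF-signed shift; the rest are null in the mouse.
    """
    if depth is None:
        # ~1000-protein shallow cohort, or half the universe when it is small
        depth = min(1000, config.n_proteins // 2)
    if depth > config.n_proteins:
        raise ValueError("mouse depth exceeds the protein universe")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7001]))
    order = truth.abundance_order()
    obs = order[:depth]
    obs_set = set(obs)
    sig_obs = [p for p in truth.signature_ids if p in obs_set]
    n_shared = int(round(shared_fraction * len(sig_obs)))
    shared = list(rng.choice(sig_obs, size=n_shared, replace=False)) if n_shared else []

    effect = truth.signature_effects.get("csf", 0.0)
    groups = ["AD"] * n_ad + ["Ctl"] * n_ctl
    m = n_ad + n_ctl
    sample_ids = [f"{dataset_id}_s{j + 1:02d}" for j in range(m)]
    dose = np.array([1.0 if g == "AD" else 0.0 for g in groups])

    base = np.array([truth.baseline_log2[p] for p in obs])
    X = np.tile(base[:, None], (1, m))
    if shared and effect != 0.0:
        pos = {p: i for i, p in enumerate(obs)}
        idx = np.array([pos[p] for p in shared])
        X[idx, :] += effect * dose[None, :]
    X += config.noise_sd * rng.normal(0.0, 1.0, size=(depth, m))

    mat = pd.DataFrame(np.exp2(X), index=pd.Index(obs, name="protein_id"), columns=sample_ids)
    return ProteomeDataset(
        dataset_id=dataset_id,
        tissue="csf",
        species="mouse",
        cohort_role="discovery",
        intensities=mat,
        sample_groups=pd.Series(groups, index=sample_ids),
    )


def make_annotation(config: SimConfig, truth: SyntheticTruth) -> ProteinAnnotation:
    """Annotation table for the synthetic universe.

    Gene symbols are one-to-one with protein ids; module members carry the
    mitochondrial flag, panel members a blood-marker functional class.
    """
    proteins = sorted(truth.baseline_log2)
    mito = set(truth.mito_module_ids)
    markers = set(truth.contamination_marker_ids)
    tbl = pd.DataFrame(
        {
            "gene_symbol": [p.replace("P", "GENE", 1) for p in proteins],
            "is_mitochondrial": [p in mito for p in proteins],
            "functional_class": [
                "energy metabolism" if p in mito else ("blood marker" if p in markers else "")
            for p in proteins],
        },
        index=pd.Index(proteins, name="protein_id"),
    )
    return ProteinAnnotation(table=tbl)


def write_fixture_bundle(datasets, truth: SyntheticTruth, out_dir) -> dict:
    """Write every cohort + truth manifest + annotation as reloadable TSVs."""
    if not datasets:
        raise ValueError("empty dataset list")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for ds in datasets:
        mp = out / f"{ds.dataset_id}.matrix.tsv"
        sp = out / f"{ds.dataset_id}.samples.tsv"
        prio.write_dataset(ds, mp, sp)
        paths[ds.dataset_id] = {"matrix": str(mp), "samples": str(sp)}
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(asdict(truth), indent=2) + "\n")
    paths["truth"] = str(truth_path)
    manifest = out / "manifest.json"
    prio.write_manifest({"seed": truth.seed, "datasets": sorted(p for p in paths if p != "truth")}, manifest)
    paths["manifest"] = str(manifest)
    return paths


def load_truth(path) -> SyntheticTruth:
    return SyntheticTruth(**json.loads(Path(path).read_text()))
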