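"""Core domain types shared by every pipeline stage.

A study is a collection of :class:`ProteomeDataset` objects — one per cohort —
each holding a protein-by-sample intensity matrix (TMT reporter-ion scale,
strictly positive where observed) together with sample group labels
(AD / MCI / Ctl) and optional per-sample covariates. Missing quantifications
are represented internally as NaN and never as zero: intensities feed log
transforms, so a zero is always a data error, not a small value.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

VALID_GROUPS = ("AD", "MCI", "Ctl")
VALID_TISSUES = ("cortex", "csf", "serum")
VALID_SPECIES = ("human", "mouse")
VALID_ROLES = ("discovery", "reference")


class DataError(ValueError):
    """Malformed input data (duplicate ids, nonpositive intensity, ...)."""


@dataclass
class ProteomeDataset:
    """One cohort's protein×sample quantification matrix plus metadata.

    Parameters
    ----------
    dataset_id : short label, e.g. ``"csf_disc"`` or the study's i–x codes.
    tissue : one of ``cortex``, ``csf``, ``serum``.
    species : ``human`` or ``mouse``.
    cohort_role : ``discovery`` or ``reference``.
    intensities : DataFrame indexed by protein id with sample-id columns;
        present values strictly positive, missing values NaN.
    sample_groups : Series mapping sample id -> group label.
    sample_covariates : optional DataFrame (sample id × covariate name).
    """

    dataset_id: str
    tissue: str
    species: str
    cohort_role: str
    intensities: pd.DataFrame
    sample_groups: pd.Series
    sample_covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def proteins(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_proteins(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.sample_groups[s] == group]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.tissue not in VALID_TISSUES:
            raise DataError(f"unknown tissue {self.tissue!r}")
        if self.species not in VALID_SPECIES:
            raise DataError(f"unknown species {self.species!r}")
        if self.cohort_role not in VALID_ROLES:
            raise DataError(f"unknown cohort_role {self.cohort_role!r}")
        idx = self.intensities.index
        cols = self.intensities.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise DataError(f"duplicate protein ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise DataError(f"duplicate sample ids: {dups}")
        vals = self.intensities.to_numpy(dtype=float)
        bad = np.nonzero(~np.isnan(vals) & (vals <= 0))
        if bad[0].size:
            p, s = idx[bad[0][0]], cols[bad[1][0]]
            raise DataError(
                f"nonpositive intensity at protein {p!r}, sample {s!r} "
                "(missing values must be empty/NA, never 0)"
            )
        missing_meta = [s for s in cols if s not in self.sample_groups.index]
        if missing_meta:
            raise DataError(f"samples without group label: {missing_meta}")
        self.sample_groups = self.sample_groups.reindex(cols)
        unknown = sorted(set(self.sample_groups) - set(VALID_GROUPS))
        if unknown:
            raise DataError(
                f"unknown group label(s) {unknown}; expected one of {VALID_GROUPS}"
            )
        if self.sample_covariates is not None:
            self.sample_covariates = self.sample_covariates.reindex(cols)

    def equals(self, other: "ProteomeDataset") -> bool:
        same_meta = (
            self.dataset_id == other.dataset_id
            and self.tissue == other.tissue
            and self.species == other.species
            and self.cohort_role == other.cohort_role
        )
        if not same_meta:
            return False
        if list(self.intensities.index) != list(other.intensities.index):
            return False
        if list(self.intensities.columns) != list(other.intensities.columns):
            return False
        a = self.intensities.to_numpy(float)
        b = other.intensities.to_numpy(float)
        if not np.allclose(a, b, rtol=1e-12, atol=0.0, equal_nan=True):
            return False
        if list(self.sample_groups) != list(other.sample_groups):
            return False
        ca, cb = self.sample_covariates, other.sample_covariates
        if (ca is None) != (cb is None):
            return False
        if ca is not None:
            if sorted(ca.columns) != sorted(cb.columns):
                return False
            if not np.allclose(
                ca.to_numpy(float), cb[ca.columns].to_numpy(float),
                rtol=1e-12, atol=0.0, equal_nan=True,
            ):
                return False
        return True


@dataclass
class ProteinAnnotation:
    """Protein id -> gene symbol and mitochondrial flag.

    Unannotated proteins default to non-mitochondrial when queried, so a
    partial annotation table is usable against a full proteome.
    """

    table: pd.DataFrame  # index protein_id; columns gene_symbol, is_mitochondrial[, functional_class]

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = sorted(self.table.index[self.table.index.duplicated()].unique())
            raise DataError(f"duplicate protein_id in annotation: {dups}")

    def is_mitochondrial(self, protein_id: str) -> bool:
        if protein_id in self.table.index:
            return bool(self.table.loc[protein_id, "is_mitochondrial"])
        return False

    def gene_symbol(self, protein_id: str) -> str:
        if protein_id in self.table.index:
            return str(self.table.loc[protein_id, "gene_symbol"])
        return protein_id

    def mitochondrial_ids(self) -> set[str]:
        flags = self.table["is_mitochondrial"].astype(bool)
        return set(self.table.index[flags])


@dataclass(frozen=True)
class DECallSpec:
    """Thresholds for calling a protein differentially expressed.

    Exactly one of ``p_max`` / ``fdr_max`` is set; ``z_min`` bounds the
    absolute standardized log2 fold change.
    """

    z_min: float
    p_max: float | None = None
    fdr_max: float | None = None
    direction: str = "both"

    def __post_init__(self) -> None:
        if self.z_min <= 0:
            raise ValueError("z_min must be > 0")
        if (self.p_max is None) == (self.fdr_max is None):
            raise ValueError("exactly one of p_max / fdr_max must be set")
        if self.direction not in ("both", "up", "down"):
            raise ValueError(f"unknown direction {self.direction!r}")


#: Named threshold presets used throughout the analysis.
DE_SPEC_PRESETS: Mapping[str, DECallSpec] = {
    # primary per-dataset call: |Z| > 2 and FDR < 0.05
    "default": DECallSpec(z_min=2.0, fdr_max=0.05),
    # stringent top-hit call: |Z| > 5 and FDR < 0.01
    "stringent": DECallSpec(z_min=5.0, fdr_max=0.01),
    # looser nominal-p call used for shallow datasets: |Z| > 2 and p < 0.05
    "loose": DECallSpec(z_min=2.0, p_max=0.05),
    # relaxed call used when intersecting multiple proteomes: |Z| > 2 and FDR < 0.2
    "integration": DECallSpec(z_min=2.0, fdr_max=0.2),
}


@dataclass
class RunConfig:
    """Stage parameters + provenance for a pipeline run."""

    seed: int = 0
    n_permutations: int = 1000
    outlier_k: float = 3.0
    de_spec: str = "default"
    marker_panel: tuple[str, ...] = ()
    out_dir: str = "results"
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(self).items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def make_manifest(config: RunConfig, stage: str, **fields) -> dict:
    """Provenance record written next to each stage output."""
    m = {
        "stage": stage,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": "proteorank-0.1.0",
    }
    m.update(fields)
    return m
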