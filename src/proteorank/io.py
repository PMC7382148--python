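"""TSV readers/writers for datasets, sample sheets, annotations and manifests.

Formats are deliberately plain: a tab-delimited matrix with protein ids in
the first column and sample ids in the header, a sample sheet keyed by
sample_id, and an annotation table keyed by protein_id. Missing
quantifications are written as ``NA`` (empty string also accepted on read)
and surface as NaN in memory — never 0.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datamodel import DataError, ProteinAnnotation, ProteomeDataset

MISSING_TOKEN = "NA"
_NA_VALUES = ["", "NA", "NaN", "nan"]

# sample-sheet columns that are metadata, not covariates
_META_COLS = {"sample_id", "group", "tissue", "species", "cohort_role", "dataset_id"}


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={0: str}, na_values=_NA_VALUES,
        keep_default_na=False, index_col=0,
    )


def read_dataset(matrix_path, sample_sheet_path) -> ProteomeDataset:
    """Load one cohort from a matrix TSV + sample sheet TSV.

    Raises :class:`DataError` on duplicate protein/sample ids, unknown group
    labels, or nonpositive intensities (0 is never a valid measurement).
    """
    matrix_path, sample_sheet_path = Path(matrix_path), Path(sample_sheet_path)
    raw = _read_tsv(matrix_path)
    if raw.index.has_duplicates:
        dups = sorted(raw.index[raw.index.duplicated()].unique())
        raise DataError(f"{matrix_path.name}: duplicate protein ids {dups}")
    if raw.columns.has_duplicates:
        dups = sorted(raw.columns[raw.columns.duplicated()].unique())
        raise DataError(f"{matrix_path.name}: duplicate sample ids {dups}")
    try:
        mat = raw.astype(float)
    except ValueError as exc:
        raise DataError(f"{matrix_path.name}: non-numeric cell ({exc})") from exc

    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str,
                        na_values=_NA_VALUES, keep_default_na=False)
    if "sample_id" not in sheet.columns or "group" not in sheet.columns:
        raise DataError(f"{sample_sheet_path.name}: needs sample_id and group columns")
    if sheet["sample_id"].duplicated().any():
        dups = sorted(sheet.loc[sheet["sample_id"].duplicated(), "sample_id"])
        raise DataError(f"{sample_sheet_path.name}: duplicate sample ids {dups}")
    sheet = sheet.set_index("sample_id")

    def _meta(col: str, default: str) -> str:
        if col in sheet.columns:
            vals = sheet[col].dropna().unique()
            if len(vals) > 1:
                raise DataError(f"{sample_sheet_path.name}: conflicting {col} values {sorted(vals)}")
            if len(vals) == 1:
                return str(vals[0])
        return default

    cov_cols = [c for c in sheet.columns if c not in _META_COLS]
    covariates = None
    if cov_cols:
        covariates = sheet[cov_cols].astype(float)

    return ProteomeDataset(
        dataset_id=_meta("dataset_id", matrix_path.stem),
        tissue=_meta("tissue", "csf"),
        species=_meta("species", "human"),
        cohort_role=_meta("cohort_role", "discovery"),
        intensities=mat,
        sample_groups=sheet["group"],
        sample_covariates=covariates,
    )


def write_dataset(dataset: ProteomeDataset, matrix_path, sample_sheet_path) -> tuple[Path, Path]:
    """Write a dataset in the format :func:`read_dataset` accepts (round-trips)."""
    matrix_path, sample_sheet_path = Path(matrix_path), Path(sample_sheet_path)
    mat = dataset.intensities.copy()
    mat.index.name = "protein_id"
    # %.17g: shortest round-trippable representation of a double
    mat.to_csv(matrix_path, sep="\t", na_rep=MISSING_TOKEN, float_format="%.17g")

    sheet = pd.DataFrame(
        {
            "sample_id": dataset.samples,
            "group": [dataset.sample_groups[s] for s in dataset.samples],
            "dataset_id": dataset.dataset_id,
            "tissue": dataset.tissue,
            "species": dataset.species,
            "cohort_role": dataset.cohort_role,
        }
    )
    if dataset.sample_covariates is not None:
        for c in dataset.sample_covariates.columns:
            sheet[c] = dataset.sample_covariates[c].to_numpy()
    sheet.to_csv(sample_sheet_path, sep="\t", index=False, na_rep=MISSING_TOKEN)
    return matrix_path, sample_sheet_path


def read_annotation(path) -> ProteinAnnotation:
    """Load a protein annotation TSV (protein_id, gene_symbol, is_mitochondrial)."""
    path = Path(path)
    tbl = pd.read_csv(path, sep="\t", dtype=str, na_values=_NA_VALUES,
                      keep_default_na=False)
    required = {"protein_id", "gene_symbol", "is_mitochondrial"}
    if not required.issubset(tbl.columns):
        raise DataError(f"{path.name}: annotation needs columns {sorted(required)}")
    if tbl["protein_id"].duplicated().any():
        dups = sorted(tbl.loc[tbl["protein_id"].duplicated(), "protein_id"])
        raise DataError(f"{path.name}: duplicate protein_id {dups}")
    tbl = tbl.set_index("protein_id")
    flag = tbl["is_mitochondrial"].str.strip().str.lower()
    valid = {"true": True, "false": False, "1": True, "0": False}
    bad = sorted(set(flag) - set(valid))
    if bad:
        raise DataError(f"{path.name}: unparseable is_mitochondrial values {bad}")
    tbl["is_mitochondrial"] = flag.map(valid)
    return ProteinAnnotation(table=tbl)


def write_annotation(annotation: ProteinAnnotation, path) -> Path:
    path = Path(path)
    tbl = annotation.table.copy()
    tbl["is_mitochondrial"] = tbl["is_mitochondrial"].map({True: "true", False: "false"})
    tbl.index.name = "protein_id"
    tbl.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)
    return path


def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def write_table(df: pd.DataFrame, path, index_name: str | None = None) -> Path:
    """Write a results table as TSV with NA for missing values."""
    path = Path(path)
    out = df.copy()
    if index_name is not None:
        out.index.name = index_name
        out.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, float_format="%.10g")
    else:
        out.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index=False, float_format="%.10g")
    return path
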