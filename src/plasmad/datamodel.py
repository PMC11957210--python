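"""Shared data model and tab-separated I/O.

All tables are TSV with a single header row.  The designated missing token
on write is the empty cell; both the empty cell and ``NA`` are accepted on
read.  Dates, when present, must be ISO-8601; internally everything is
expressed as age-in-years at event.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

MISSING_TOKEN = ""
NA_VALUES = ("", "NA")

CLINICAL_STATUSES = frozenset({"CO", "AD", "FTD", "DLB", "PD"})
SEXES = frozenset({"female", "male"})

#: optional per-sample biomarker columns understood by downstream modules
BIOMARKER_COLUMNS = ("csf_abeta42", "csf_ptau181", "pet_composite", "plasma_ptau217")

CDR_GLOBAL_LEVELS = (0.0, 0.5, 1.0, 2.0, 3.0)


class DataValidationError(ValueError):
    """Raised when an input table violates a data-model invariant."""


@dataclasses.dataclass
class ProteomicsMatrix:
    """A samples x analytes abundance matrix with plate annotations.

    Parameters
    ----------
    values
        Wide DataFrame (rows = samples, columns = analytes) of non-negative
        relative fluorescence units; ``NaN`` marks missing measurements.
        After z-score normalization (``scale == "zscore"``) values may be
        negative.
    plate_of_sample
        Plate label per sample, indexed like ``values``.
    scale_factor, lod
        Optional per-(analyte, plate) tables (rows = analytes, columns =
        plate labels).
    """

    values: pd.DataFrame
    plate_of_sample: pd.Series
    scale_factor: pd.DataFrame | None = None
    lod: pd.DataFrame | None = None
    scale: str = "rfu"  # "rfu" (raw, non-negative) or "zscore"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def plates(self) -> list[str]:
        return sorted(set(self.plate_of_sample))

    def validate(self) -> None:
        vals = self.values
        if vals.index.has_duplicates:
            dups = vals.index[vals.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicated sample id(s): {dups}")
        if vals.columns.has_duplicates:
            dups = vals.columns[vals.columns.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicated analyte id(s): {dups}")
        arr = vals.to_numpy(dtype=float)
        if self.scale == "rfu" and np.nanmin(arr, initial=np.inf) < 0:
            bad = vals.columns[(arr < 0).any(axis=0)].tolist()
            raise DataValidationError(f"negative abundance in analyte(s): {bad}")
        if not self.plate_of_sample.index.equals(vals.index):
            self.plate_of_sample = self.plate_of_sample.reindex(vals.index)
        if self.plate_of_sample.isna().any():
            bad = self.plate_of_sample.index[self.plate_of_sample.isna()].tolist()
            raise DataValidationError(f"sample(s) without plate label: {bad}")
        for name, table in (("scale_factor", self.scale_factor), ("lod", self.lod)):
            if table is None:
                continue
            missing_analytes = set(vals.columns) - set(table.index)
            missing_plates = set(self.plate_of_sample) - set(table.columns)
            if missing_analytes or missing_plates:
                raise DataValidationError(
                    f"{name} table does not cover analytes {sorted(missing_analytes)} "
                    f"/ plates {sorted(missing_plates)}"
                )
            if name == "lod" and (table.to_numpy(dtype=float) < 0).any():
                raise DataValidationError("negative LOD value")

    def copy(self) -> "ProteomicsMatrix":
        return ProteomicsMatrix(
            values=self.values.copy(),
            plate_of_sample=self.plate_of_sample.copy(),
            scale_factor=None if self.scale_factor is None else self.scale_factor.copy(),
            lod=None if self.lod is None else self.lod.copy(),
            scale=self.scale,
        )

    def subset(self, sample_ids=None, analyte_ids=None) -> "ProteomicsMatrix":
        """Return a new matrix restricted to the given samples/analytes."""
        vals = self.values
        if sample_ids is not None:
            vals = vals.loc[list(sample_ids)]
        if analyte_ids is not None:
            vals = vals[list(analyte_ids)]
        sf = self.scale_factor
        lod = self.lod
        if analyte_ids is not None:
            if sf is not None:
                sf = sf.loc[list(analyte_ids)]
            if lod is not None:
                lod = lod.loc[list(analyte_ids)]
        return ProteomicsMatrix(
            values=vals.copy(),
            plate_of_sample=self.plate_of_sample.loc[vals.index].copy(),
            scale_factor=sf,
            lod=lod,
            scale=self.scale,
        )


class GeneSetCollection(dict):
    """Mapping of set name -> ordered, de-duplicated member symbols."""

    def __init__(self, sets=None, descriptions=None):
        super().__init__()
        self.descriptions: dict[str, str] = dict(descriptions or {})
        for name, members in (sets or {}).items():
            self.add(name, members, self.descriptions.get(name, ""))

    def add(self, name: str, members, description: str = "") -> None:
        if name in self:
            raise DataValidationError(f"duplicate gene set name: {name!r}")
        deduped = list(dict.fromkeys(str(m) for m in members))
        if not deduped or any(not m for m in deduped):
            raise DataValidationError(f"gene set {name!r} empty or has empty member")
        self[name] = deduped
        self.descriptions[name] = description


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(
        path,
        sep="\t",
        na_values=list(NA_VALUES),
        keep_default_na=False,
        float_precision="round_trip",
        **kwargs,
    )


def _coerce_numeric(df: pd.DataFrame, context: str) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise DataValidationError(
                f"non-numeric value in {context} column {col!r}: {exc}"
            ) from None
    return pd.DataFrame(out, index=df.index)


def load_matrix(
    matrix_path, scale_factor_path=None, lod_path=None, scale: str = "rfu"
) -> ProteomicsMatrix:
    """Read a wide abundance matrix TSV (columns: sample_id, plate, analytes...).

    Pass ``scale="zscore"`` for an already-normalized matrix (negative values
    allowed); the default ``"rfu"`` scale rejects negative abundances.
    """
    raw = _read_tsv(matrix_path, dtype=str)
    for required in ("sample_id", "plate"):
        if required not in raw.columns:
            raise DataValidationError(f"matrix file lacks required column {required!r}")
    raw = raw.set_index("sample_id")
    plates = raw.pop("plate")
    values = _coerce_numeric(raw, "abundance")
    sf = lod = None
    if scale_factor_path is not None:
        sf = _read_tsv(scale_factor_path).set_index("analyte_id").astype(float)
    if lod_path is not None:
        lod = _read_tsv(lod_path).set_index("analyte_id").astype(float)
    return ProteomicsMatrix(
        values=values, plate_of_sample=plates, scale_factor=sf, lod=lod, scale=scale
    )


def load_samples(metadata_path) -> pd.DataFrame:
    """Read and validate the sample-metadata TSV."""
    df = _read_tsv(metadata_path)
    for required in ("sample_id", "age_at_draw", "sex", "clinical_status"):
        if required not in df.columns:
            raise DataValidationError(f"metadata lacks required column {required!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataValidationError(f"duplicated sample id(s) in metadata: {dups}")
    df = df.set_index("sample_id")
    df["age_at_draw"] = pd.to_numeric(df["age_at_draw"])
    if (df["age_at_draw"] <= 0).any():
        bad = df.index[df["age_at_draw"] <= 0].tolist()
        raise DataValidationError(f"non-positive age_at_draw for: {bad}")
    bad_sex = set(df["sex"].dropna()) - SEXES
    if bad_sex:
        raise DataValidationError(f"unknown sex label(s): {sorted(bad_sex)}")
    bad_status = set(df["clinical_status"].dropna()) - CLINICAL_STATUSES
    if bad_status:
        raise DataValidationError(f"unknown clinical_status label(s): {sorted(bad_status)}")
    for col in BIOMARKER_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    return df


def load_cdr(cdr_path) -> pd.DataFrame:
    """Read the longitudinal CDR visit TSV (sample_id, visit_age, cdr_global, cdr_sb)."""
    df = _read_tsv(cdr_path)
    for required in ("sample_id", "visit_age", "cdr_global", "cdr_sb"):
        if required not in df.columns:
            raise DataValidationError(f"CDR file lacks required column {required!r}")
    df["visit_age"] = pd.to_numeric(df["visit_age"])
    df["cdr_global"] = pd.to_numeric(df["cdr_global"])
    df["cdr_sb"] = pd.to_numeric(df["cdr_sb"])
    bad = set(df["cdr_global"].dropna().unique()) - set(CDR_GLOBAL_LEVELS)
    if bad:
        raise DataValidationError(f"invalid cdr_global value(s): {sorted(bad)}")
    if (df["cdr_sb"].dropna() < 0).any():
        raise DataValidationError("negative cdr_sb value")
    return df.sort_values(["sample_id", "visit_age"], kind="stable").reset_index(drop=True)


def load_study(
    matrix_path,
    metadata_path,
    cdr_path=None,
    scale_factor_path=None,
    lod_path=None,
    scale: str = "rfu",
):
    """Load a full study: abundance matrix, sample metadata, optional CDR visits.

    Returns ``(ProteomicsMatrix, samples, cdr_visits_or_None)``.  Metadata must
    cover every matrix sample; the offending sample is named otherwise.
    """
    matrix = load_matrix(matrix_path, scale_factor_path, lod_path, scale=scale)
    samples = load_samples(metadata_path)
    missing = [s for s in matrix.sample_ids if s not in samples.index]
    if missing:
        raise DataValidationError(f"metadata missing matrix sample(s): {missing}")
    cdr = load_cdr(cdr_path) if cdr_path is not None else None
    return matrix, samples, cdr


def write_matrix(matrix: ProteomicsMatrix, matrix_path, scale_factor_path=None, lod_path=None):
    """Write a ProteomicsMatrix as wide TSV (plus optional sf/LOD tables)."""
    out = matrix.values.copy()
    out.insert(0, "plate", matrix.plate_of_sample)
    out.index.name = "sample_id"
    out.to_csv(matrix_path, sep="\t", na_rep=MISSING_TOKEN)
    if scale_factor_path is not None and matrix.scale_factor is not None:
        sf = matrix.scale_factor.copy()
        sf.index.name = "analyte_id"
        sf.to_csv(scale_factor_path, sep="\t", na_rep=MISSING_TOKEN)
    if lod_path is not None and matrix.lod is not None:
        lod = matrix.lod.copy()
        lod.index.name = "analyte_id"
        lod.to_csv(lod_path, sep="\t", na_rep=MISSING_TOKEN)


def write_samples(samples: pd.DataFrame, path) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)


def write_results_table(records, path) -> None:
    """Write a homogeneous record table as TSV (full float precision, '' for NaN).

    ``records`` may be a DataFrame or an iterable of dicts sharing one schema.
    """
    if not isinstance(records, pd.DataFrame):
        records = list(records)
        if records:
            keys = set(records[0])
            for rec in records[1:]:
                if set(rec) != keys:
                    raise DataValidationError("heterogeneous record schema")
        records = pd.DataFrame(records)
    records.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def read_results_table(path) -> pd.DataFrame:
    return _read_tsv(path)


def read_gene_sets_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB member...`` per line.

    Duplicate members within one line are de-duplicated; duplicate set names
    are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataValidationError(
                    f"{path}:{lineno}: GMT line has fewer than 3 fields"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            collection.add(name, members, description)
    return collection


def write_gene_sets_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
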