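"""Core containers and TSV/GMT readers and writers.

The central container is :class:`OmicsMatrix`, a feature x sample table of
log2 intensities with per-feature annotations (gene symbol, modified site,
modification type).  Missing measurements are encoded as NaN in memory and as
empty cells on disk; they are never imputed at this layer.

Sample metadata travels as a plain :class:`pandas.DataFrame` with a fixed
column schema (:data:`METADATA_COLUMNS`), indexed by ``sample_id``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

#: Annotation columns stored alongside the numeric matrix, in file order.
ANNOTATION_COLUMNS = ("gene", "site", "modification")

#: Recognised modification types for matrix features.
MODIFICATION_TYPES = ("phospho", "acetyl", "methyl", "protein", "mRNA")

#: Fixed metadata schema.  ``qc_flags`` holds a semicolon-joined flag list.
METADATA_COLUMNS = (
    "sample_id",
    "centre",
    "tissue",
    "karyotype",
    "kmt2a_partner",
    "qc_flags",
    "split",
    "group",
)

#: Valid QC exclusion flags (see :mod:`phosphostrat.qc`).
QC_FLAGS = ("mislabelled", "high_rbc", "high_tcell", "low_viability")

#: Cohort group labels used throughout the analysis.
GROUP_LABELS = ("MLLGA", "MLLGB", "No-MLL", "Normal")


@dataclass
class OmicsMatrix:
    """Feature x sample log2 intensity matrix with feature annotations.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, features as rows, samples as columns.
        NaN marks a missing measurement; infinities are rejected.
    annotations
        DataFrame indexed by feature id with (a subset of) the columns in
        :data:`ANNOTATION_COLUMNS`.  Annotation index must be a subset of the
        matrix feature ids.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=self.values.index.copy())
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate feature id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        vals = self.values.to_numpy(dtype=float, copy=False)
        if np.isinf(vals).any():
            raise ValidationError("matrix contains non-finite (infinite) values")
        unknown = self.annotations.index.difference(idx)
        if len(unknown):
            raise ValidationError(
                f"annotation for unknown feature id: {unknown[0]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask, True where the measurement is missing."""
        return self.values.isna()

    def subset(
        self,
        features: Iterable[str] | None = None,
        samples: Iterable[str] | None = None,
    ) -> "OmicsMatrix":
        """Return a sub-matrix; unknown ids raise :class:`ValidationError`."""
        values = self.values
        if features is not None:
            features = list(features)
            missing = set(features) - set(values.index)
            if missing:
                raise ValidationError(f"unknown feature id(s): {sorted(missing)[:5]}")
            values = values.loc[features]
        if samples is not None:
            samples = list(samples)
            missing = set(samples) - set(values.columns)
            if missing:
                raise ValidationError(f"unknown sample id(s): {sorted(missing)[:5]}")
            values = values[samples]
        ann = self.annotations.loc[self.annotations.index.intersection(values.index)]
        return OmicsMatrix(values.copy(), ann.copy())

    def equals(self, other: "OmicsMatrix") -> bool:
        """Exact equality including the missing-value mask and annotations."""
        if list(self.values.index) != list(other.values.index):
            return False
        if list(self.values.columns) != list(other.values.columns):
            return False
        a, b = self.values.to_numpy(float), other.values.to_numpy(float)
        same = (a == b) | (np.isnan(a) & np.isnan(b))
        if not same.all():
            return False
        ann_a = self.annotations.reindex(self.values.index)
        ann_b = other.annotations.reindex(other.values.index)
        return ann_a.fillna("").astype(str).equals(ann_b.fillna("").astype(str))


def read_matrix(path: str | Path, layer: str | None = None) -> OmicsMatrix:
    """Read an :class:`OmicsMatrix` from TSV.

    The file has a ``feature_id`` index column, optional annotation columns
    (any of :data:`ANNOTATION_COLUMNS`) and one numeric column per sample.
    Empty cells are missing values.  Duplicated sample columns or non-numeric
    cells raise :class:`ParseError` naming the location.

    ``layer``, when given, overrides the ``modification`` annotation for all
    features (convenience for single-layer files).
    """
    path = Path(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter="\t"))
    if not header or header[0] != "feature_id":
        raise ParseError(f"{path}: first column must be 'feature_id', got {header[:1]}")
    seen: set[str] = set()
    for name in header[1:]:
        if name in seen:
            raise ParseError(f"{path}: duplicated column {name!r}")
        seen.add(name)
    df = pd.read_csv(path, sep="\t", index_col="feature_id", dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated feature id {dup!r}")
    ann_cols = [c for c in ANNOTATION_COLUMNS if c in df.columns]
    sample_cols = [c for c in df.columns if c not in ANNOTATION_COLUMNS]
    values = pd.DataFrame(index=df.index, columns=sample_cols, dtype=float)
    for col in sample_cols:
        raw = df[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            row = bad.idxmax()
            raise ParseError(
                f"{path}: non-numeric cell at feature {row!r}, column {col!r}: "
                f"{raw[row]!r}"
            )
        # numpy's parser is correctly rounded (exact text round-trip);
        # pd.to_numeric's fast path can be off by one ulp
        values[col] = raw.fillna("").str.strip().replace("", np.nan).astype(float)
    annotations = df[ann_cols].copy()
    if layer is not None:
        annotations["modification"] = layer
    values.index.name = "feature_id"
    return OmicsMatrix(values, annotations)


def write_matrix(m: OmicsMatrix, path: str | Path) -> None:
    """Write an :class:`OmicsMatrix` to TSV; missing cells become empty."""
    ann = m.annotations.reindex(m.values.index)
    ann = ann[[c for c in ANNOTATION_COLUMNS if c in ann.columns]]
    out = pd.concat([ann, m.values], axis=1)
    out.index.name = "feature_id"
    # %.17g guarantees exact binary round-trip of doubles through text
    out.to_csv(path, sep="\t", na_rep="", float_format="%.17g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV into a DataFrame indexed by ``sample_id``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata column(s) {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicated sample id {dup!r}")
    return df.set_index("sample_id", drop=False)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def qc_flag_set(cell: str) -> set[str]:
    """Parse a semicolon-joined ``qc_flags`` metadata cell into a set."""
    return {f for f in str(cell).split(";") if f}


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read named feature sets from a GMT file.

    Each line: set name, description, then one member per tab field.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {ln}: expected >=3 tab-separated fields")
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}: line {ln}: duplicated set name {name!r}")
            members = [p for p in parts[2:] if p]
            if not members:
                raise ParseError(f"{path}: line {ln}: set {name!r} is empty")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
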