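"""Cohort quality control and intensity normalization.

QC consumes pre-computed boolean exclusion flags rather than raw cytometry
values: a sample is removed when it carries any flag in
:data:`phosphostrat.omics.QC_FLAGS` (mislabelled diagnosis, red-blood-cell or
T-cell contamination, low viability).  A helper derives those flags from
user-chosen thresholds on numeric metadata columns, so the cut-offs stay
explicit and under the caller's control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .omics import QC_FLAGS, OmicsMatrix, qc_flag_set


@dataclass
class QcReport:
    """Outcome of :func:`apply_qc`."""

    retained: list[str]
    excluded: list[str]
    #: flag -> number of samples carrying it (a doubly-flagged sample counts
    #: under every flag it carries but only once in ``excluded``).
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def apply_qc(meta: pd.DataFrame) -> QcReport:
    """Drop flagged samples and report exclusion counts per reason.

    Idempotent: re-applying to the retained subset removes nothing further.
    """
    retained: list[str] = []
    excluded: list[str] = []
    counts = {flag: 0 for flag in QC_FLAGS}
    for sample_id, cell in meta["qc_flags"].items():
        flags = qc_flag_set(cell)
        unknown = flags - set(QC_FLAGS)
        if unknown:
            raise ValidationError(
                f"sample {sample_id!r}: unknown QC flag(s) {sorted(unknown)}"
            )
        if flags:
            excluded.append(sample_id)
            for flag in flags:
                counts[flag] += 1
        else:
            retained.append(sample_id)
    return QcReport(retained=retained, excluded=excluded, counts=counts)


def derive_qc_flags(
    meta: pd.DataFrame,
    *,
    mislabelled_ids: Iterable[str] = (),
    rbc_max: float | None = None,
    tcell_max: float | None = None,
    viability_min: float | None = None,
    rbc_column: str = "rbc_fraction",
    tcell_column: str = "tcell_fraction",
    viability_column: str = "viability",
) -> pd.DataFrame:
    """Return a copy of ``meta`` with ``qc_flags`` filled from thresholds.

    Each threshold is optional; the corresponding numeric column must exist
    when the threshold is given.  Existing flags are replaced.
    """
    meta = meta.copy()
    mislabelled = set(mislabelled_ids)
    unknown = mislabelled - set(meta.index)
    if unknown:
        raise ValidationError(f"mislabelled ids not in metadata: {sorted(unknown)}")
    rules: list[tuple[str, pd.Series]] = []
    if rbc_max is not None:
        rules.append(("high_rbc", meta[rbc_column].astype(float) > rbc_max))
    if tcell_max is not None:
        rules.append(("high_tcell", meta[tcell_column].astype(float) > tcell_max))
    if viability_min is not None:
        rules.append(("low_viability", meta[viability_column].astype(float) < viability_min))
    flags: list[str] = []
    for sample_id in meta.index:
        sample_flags = []
        if sample_id in mislabelled:
            sample_flags.append("mislabelled")
        for name, mask in rules:
            if bool(mask.loc[sample_id]):
                sample_flags.append(name)
        flags.append(";".join(sample_flags))
    meta["qc_flags"] = flags
    return meta


def normalize(m: OmicsMatrix, method: str = "median_center") -> OmicsMatrix:
    """Normalize sample columns.

    ``median_center`` subtracts each column's median over observed values, so
    every sample has median 0 afterwards; missing cells are untouched and
    within-column differences are preserved exactly.  ``none`` is the
    identity.
    """
    if method == "none":
        return OmicsMatrix(m.values.copy(), m.annotations.copy())
    if method != "median_center":
        raise ValidationError(f"unknown normalization method {method!r}")
    values = m.values.copy()
    all_missing = values.isna().all(axis=0)
    if all_missing.any():
        sample = values.columns[all_missing.to_numpy()][0]
        raise DegenerateInputError(f"sample {sample!r} has no observed values")
    values = values - values.median(axis=0, skipna=True)
    return OmicsMatrix(values, m.annotations.copy())
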