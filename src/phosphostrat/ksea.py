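"""Kinase-substrate enrichment analysis (KSEA).

A kinase's activity is inferred from the aggregate behaviour of its
substrates' phosphorylation relative to the global score distribution.  For
kinase K with m observed substrate scores S within a score vector v:

    z(K) = (mean(S) - mean(v)) * sqrt(m) / sd(v)

with sd the sample standard deviation of all scores.  Under the null
(substrates drawn from the global distribution) z is approximately standard
normal, so a two-sided normal p-value is attached and Benjamini-Hochberg
adjusted across kinases.  Kinases with fewer than ``min_substrates`` observed
substrates are reported with null statistics.

Two entry modes:

* per sample — the score vector is the sample's row-centered log2 intensity
  (value minus the per-feature mean across samples, i.e. a per-sample
  fold-change against the cohort average);
* per contrast — the score vector is the log2 fold-change column of a
  differential result table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .errors import DegenerateInputError, ValidationError
from .omics import OmicsMatrix


@dataclass
class KinaseActivityMatrix:
    """Kinase x column (sample or contrast) activity z-scores."""

    z: pd.DataFrame
    m: pd.DataFrame        # substrate counts used
    p: pd.DataFrame
    fdr: pd.DataFrame


def ksea_zscore(
    values: pd.Series,
    kinase_sets: Mapping[str, Sequence[str]],
    min_substrates: int = 3,
) -> pd.DataFrame:
    """KSEA z-scores for one score vector.

    Returns a DataFrame indexed by kinase with columns ``z, m, p, fdr``;
    kinases with ``m < min_substrates`` carry NaN statistics but report m.
    """
    values = values.dropna().astype(float)
    if len(values) < 2:
        raise ValidationError("need at least 2 observed feature scores")
    sd = float(values.std(ddof=1))
    if sd == 0:
        raise DegenerateInputError("global score distribution has zero variance")
    mean_all = float(values.mean())
    rows = []
    for kinase, substrates in kinase_sets.items():
        s = values.reindex(pd.unique(pd.Index(substrates))).dropna()
        m = int(len(s))
        if m < min_substrates:
            rows.append((kinase, np.nan, m, np.nan))
            continue
        z = (float(s.mean()) - mean_all) * np.sqrt(m) / sd
        rows.append((kinase, z, m, 2.0 * float(stats.norm.sf(abs(z)))))
    out = pd.DataFrame(rows, columns=["kinase", "z", "m", "p"]).set_index("kinase")
    out["fdr"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "fdr"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out


def ksea_per_sample(
    m: OmicsMatrix,
    kinase_sets: Mapping[str, Sequence[str]],
    min_substrates: int = 3,
) -> KinaseActivityMatrix:
    """Per-sample kinase activities from a (normalized) intensity matrix.

    Each sample's score vector is its column minus the per-feature mean over
    all samples (row-centering), scoring each sample against the cohort
    average.
    """
    centered = m.values.sub(m.values.mean(axis=1, skipna=True), axis=0)
    z, cnt, p, fdr = {}, {}, {}, {}
    for sample in centered.columns:
        res = ksea_zscore(centered[sample], kinase_sets, min_substrates)
        z[sample], cnt[sample] = res["z"], res["m"]
        p[sample], fdr[sample] = res["p"], res["fdr"]
    return KinaseActivityMatrix(
        z=pd.DataFrame(z), m=pd.DataFrame(cnt), p=pd.DataFrame(p), fdr=pd.DataFrame(fdr)
    )


def ksea_contrast(
    results: pd.DataFrame,
    kinase_sets: Mapping[str, Sequence[str]],
    min_substrates: int = 3,
) -> pd.DataFrame:
    """Kinase activities for a two-group contrast (log2 fold-change scores)."""
    if "log2fc" not in results.columns:
        raise ValidationError("differential results must carry a log2fc column")
    return ksea_zscore(results["log2fc"], kinase_sets, min_substrates)


def write_activity_matrix(kam: KinaseActivityMatrix, path) -> None:
    """Write the z-score matrix (kinase x sample) to TSV."""
    out = kam.z.copy()
    out.index.name = "kinase"
    out.to_csv(path, sep="\t", na_rep="")
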