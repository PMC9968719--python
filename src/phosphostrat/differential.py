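"""Two-group differential statistics, counting rules and set enrichment.

The workhorse is a classic pooled-variance (Student) two-sample t-test run
feature-by-feature on the observed values only, with a minimum-observation
rule: features seen in fewer than ``min_obs`` samples per group are reported
as untested rather than given a p-value.  Effect sizes are differences of
group means on the log2 scale (the data are already log2 intensities), so
``log2fc = mean(group A) - mean(group B)``.

Counting rules mirror the usual volcano-plot thresholds: a feature counts as
up when ``p < p_max`` and ``log2fc > lfc_min``, down when ``p < p_max`` and
``log2fc < -lfc_min`` (strict inequalities).

Set enrichment is a one-sided hypergeometric (upper tail) test of the overlap
between a selected feature list and each named set within a stated universe,
Benjamini-Hochberg adjusted across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .omics import OmicsMatrix

#: Columns of the per-feature differential result table.
RESULT_COLUMNS = ("log2fc", "t", "p", "fdr", "n_a", "n_b", "tested")


@dataclass(frozen=True)
class CountRule:
    """Significance-counting thresholds (strict inequalities)."""

    p_max: float = 0.05
    lfc_min: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.p_max <= 1):
            raise ValidationError(f"p_max must be in (0, 1], got {self.p_max}")
        if self.lfc_min < 0:
            raise ValidationError(f"lfc_min must be >= 0, got {self.lfc_min}")


def ttest_two_group(
    m: OmicsMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_obs: int = 3,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-feature unpaired two-sided t-test between two sample groups.

    Parameters
    ----------
    m
        Intensity matrix (log2 scale).
    group_a, group_b
        Disjoint sample id lists, each with at least 2 members.
    min_obs
        Minimum observed values per group for a feature to be tested.
    equal_var
        Pooled-variance Student test when True (default); Welch otherwise.

    Returns
    -------
    DataFrame indexed by feature with columns ``log2fc, t, p, fdr, n_a, n_b,
    tested``.  Untested features carry NaN statistics.  FDR is
    Benjamini-Hochberg across tested features.
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)[:5]}")
    for name, grp in (("A", group_a), ("B", group_b)):
        unknown = set(grp) - set(m.sample_ids)
        if unknown:
            raise ValidationError(f"group {name}: unknown sample id(s) {sorted(unknown)[:5]}")
        if len(grp) < 2:
            raise ValidationError(f"group {name} needs >=2 samples, got {len(grp)}")
    if min_obs < 2:
        raise ValidationError(f"min_obs must be >= 2, got {min_obs}")

    a = m.values[group_a].to_numpy(dtype=float)
    b = m.values[group_b].to_numpy(dtype=float)
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    tested = (n_a >= min_obs) & (n_b >= min_obs)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = np.nanmean(np.where(np.isnan(a), np.nan, a), axis=1)
        mean_b = np.nanmean(np.where(np.isnan(b), np.nan, b), axis=1)
        var_a = _nanvar(a, n_a)
        var_b = _nanvar(b, n_b)
        diff = mean_a - mean_b
        if equal_var:
            df = n_a + n_b - 2
            pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / np.where(df > 0, df, 1)
            se = np.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
        else:
            se = np.sqrt(var_a / n_a + var_b / n_b)
            num = (var_a / n_a + var_b / n_b) ** 2
            den = (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
            df = np.where(den > 0, num / np.where(den > 0, den, 1), n_a + n_b - 2)
        zero_se = ~(se > 0)
        t = np.where(zero_se, np.sign(diff) * np.inf, diff / np.where(zero_se, 1.0, se))
        t = np.where(zero_se & (diff == 0), 0.0, t)
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
        p = np.where(np.isinf(t), 0.0, p)

    res = pd.DataFrame(
        {
            "log2fc": np.where(tested, diff, np.nan),
            "t": np.where(tested, t, np.nan),
            "p": np.where(tested, p, np.nan),
            "fdr": np.nan,
            "n_a": n_a,
            "n_b": n_b,
            "tested": tested,
        },
        index=m.values.index,
    )
    if tested.any():
        res.loc[tested, "fdr"] = bh_adjust(res.loc[tested, "p"].to_numpy())
    return res


def _nanvar(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Row-wise sample variance (ddof=1) ignoring NaN; 0 where n < 2."""
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(x, axis=1, keepdims=True)
        ss = np.nansum((x - mean) ** 2, axis=1)
    return np.where(n > 1, ss / np.where(n > 1, n - 1, 1), 0.0)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def count_significant(results: pd.DataFrame, rule: CountRule) -> dict[str, int]:
    """Count up-/down-regulated features under a :class:`CountRule`.

    Untested features never count.  Returns ``{"n_up": ..., "n_down": ...}``.
    """
    if len(results) == 0:
        return {"n_up": 0, "n_down": 0}
    tested = results["tested"].astype(bool)
    sig = tested & (results["p"] < rule.p_max)
    return {
        "n_up": int((sig & (results["log2fc"] > rule.lfc_min)).sum()),
        "n_down": int((sig & (results["log2fc"] < -rule.lfc_min)).sum()),
    }


def count_in_set(
    results: pd.DataFrame,
    rule: CountRule,
    feature_set: Iterable[str],
    annotations: pd.DataFrame | None = None,
) -> dict[str, int]:
    """:func:`count_significant` restricted to features in a named set.

    Membership is checked on the annotated gene symbol when ``annotations``
    (with a ``gene`` column) is supplied, else on the feature id itself.
    """
    members = set(feature_set)
    if annotations is not None and "gene" in annotations.columns:
        genes = annotations["gene"].reindex(results.index)
        keep = genes.isin(members).to_numpy()
    else:
        keep = results.index.isin(members)
    return count_significant(results.loc[keep], rule)


def enrich_sets(
    selected: Iterable[str],
    universe: Iterable[str],
    sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per feature set.

    ``selected`` must be a subset of ``universe``.  For each set the overlap
    with the selection is scored with the hypergeometric upper tail
    P(X >= overlap) given the universe size, the set size within the universe
    and the selection size; p-values are BH-adjusted across sets.

    Returns a DataFrame indexed by set name with columns
    ``overlap, set_size, selected_size, universe_size, p, fdr``.
    """
    selected = set(selected)
    universe = set(universe)
    stray = selected - universe
    if stray:
        raise ValidationError(f"selected features outside universe: {sorted(stray)[:5]}")
    if not sets:
        raise ValidationError("no feature sets supplied")
    N, n = len(universe), len(selected)
    rows = []
    for name, members in sets.items():
        in_universe = set(members) & universe
        K = len(in_universe)
        k = len(in_universe & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        rows.append((name, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "selected_size", "universe_size", "p"]
    ).set_index("set")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def write_results(results: pd.DataFrame, path) -> None:
    """Write a differential result table to TSV (feature id as first column)."""
    out = results.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep="")
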