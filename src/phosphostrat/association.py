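"""Spearman correlation analyses linking drug response to molecular features.

Rank correlations use midranks for ties.  P-values switch methods by sample
size: for n <= 9 pairs an exact permutation p-value is computed by full
enumeration of the n! orderings (cheap there, and the t-approximation is poor
for the small patient groups typical of these cohorts); for larger n the
usual t-approximation with n - 2 degrees of freedom is used.

Missing data are handled pairwise-complete: each (drug, feature) cell drops
the samples missing in either vector and reports the n actually used.  No
multiple-testing adjustment is applied inside correlation matrices by
default (per-test significance masks), with BH available per drug row.
"""

from __future__ import annotations

from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .errors import ValidationError
from .omics import OmicsMatrix

#: Largest n for which the exact permutation p-value is used.
EXACT_PERMUTATION_MAX_N = 9


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p over all orderings of one rank vector."""
    n = len(rx)
    perms = np.array(list(permutations(range(n))))
    ry_perm = ry[perms]                        # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        rhos = (ryc @ rxc) / denom
    rhos = np.nan_to_num(rhos, nan=0.0)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    min_pairs: int = 5,
) -> tuple[float, float, int]:
    """Spearman rho, p-value and number of complete pairs.

    Pairs with a missing value in either vector are dropped.  Fewer than
    ``min_pairs`` remaining pairs raise :class:`ValidationError` (matrix
    callers mark such cells untested instead of raising).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(keep.sum())
    if n < min_pairs:
        raise ValidationError(f"only {n} complete pairs, need >= {min_pairs}")
    rx, ry = _rank(x), _rank(y)
    rho = _rho_from_ranks(rx, ry)
    if np.isnan(rho):
        return np.nan, np.nan, n
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_perm_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
            p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return rho, p, n


def correlate_matrix(
    dss: pd.DataFrame,
    m: OmicsMatrix | pd.DataFrame,
    alpha: float = 0.05,
    adjust: str = "none",
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Pairwise Spearman correlation of drug response against features.

    Parameters
    ----------
    dss
        Drug x sample DSS matrix (wide).
    m
        Feature x sample matrix (:class:`OmicsMatrix` or DataFrame).
    alpha
        Significance level for the mask column.
    adjust
        'none' (default, per-test p) or 'BH' (adjust within each drug row;
        the mask then uses FDR < alpha).

    Returns a long DataFrame with columns row, col, rho, p, n, fdr,
    significant.  Cells with fewer than ``min_pairs`` shared observations are
    reported untested (NaN statistics).
    """
    if adjust not in ("none", "BH"):
        raise ValidationError(f"adjust must be 'none' or 'BH', got {adjust!r}")
    feat = m.values if isinstance(m, OmicsMatrix) else m
    shared = [s for s in dss.columns if s in set(feat.columns)]
    if len(shared) < min_pairs:
        raise ValidationError(
            f"only {len(shared)} shared samples between DSS and matrix"
        )
    rows = []
    for drug in dss.index:
        dvals = dss.loc[drug, shared].to_numpy(dtype=float)
        drug_rows = []
        for feature in feat.index:
            fvals = feat.loc[feature, shared].to_numpy(dtype=float)
            try:
                rho, p, n = spearman(dvals, fvals, min_pairs=min_pairs)
            except ValidationError:
                n = int((~(np.isnan(dvals) | np.isnan(fvals))).sum())
                rho, p = np.nan, np.nan
            drug_rows.append([drug, feature, rho, p, n, np.nan])
        ps = np.array([r[3] for r in drug_rows], dtype=float)
        tested = ~np.isnan(ps)
        if adjust == "BH" and tested.any():
            fdr = np.full(ps.shape, np.nan)
            fdr[tested] = bh_adjust(ps[tested])
            for r, f in zip(drug_rows, fdr):
                r[5] = f
        rows.extend(drug_rows)
    out = pd.DataFrame(rows, columns=["row", "col", "rho", "p", "n", "fdr"])
    crit = out["fdr"] if adjust == "BH" else out["p"]
    out["significant"] = crit.notna() & (crit < alpha)
    return out


def correlated_sets(
    cm: pd.DataFrame,
    drug: str,
    alpha: float = 0.05,
    use_fdr: bool = False,
) -> tuple[set[str], set[str]]:
    """Features whose correlation with ``drug`` is significant, by sign.

    Returns (positive set, negative set); the two are always disjoint.
    """
    sub = cm[cm["row"] == drug]
    if sub.empty:
        raise ValidationError(f"drug {drug!r} not present in correlation matrix")
    crit = sub["fdr"] if use_fdr else sub["p"]
    sig = crit.notna() & (crit < alpha)
    positive = set(sub.loc[sig & (sub["rho"] > 0), "col"])
    negative = set(sub.loc[sig & (sub["rho"] < 0), "col"])
    return positive, negative
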