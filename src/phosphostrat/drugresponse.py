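"""Dose-response analysis: plate normalization, curve fitting, DSS scoring,
proliferation estimation and group-wise drug comparisons.

**Well normalization.**  Viability signals are converted to percent
inhibition with the per-sample controls:

    inhibition% = 100 * (vehicle - signal) / (vehicle - positive)

so vehicle (DMSO) wells map to 0% and positive-control (full-kill) wells to
100%.

**Curve model.**  Inhibition versus log10 concentration x follows a
four-parameter log-logistic (4PL) with positive slope:

    y(x) = bottom + (top - bottom) / (1 + 10^(slope * (log10_ic50 - x)))

fitted by bounded least squares from three fixed starting points.

**Drug sensitivity score.**  DSS is the normalized area between the fitted
curve and an activity threshold t over the tested window [x1, x2]:

    A    = integral over {x in [x1,x2] : y(x) >= t} of (y(x) - t) dx
    DSS1 = 100 * A / ((100 - t) * (x2 - x1))
    DSS2 = DSS1 * 100 / max(top, 1)

clipped to [0, 100]; higher means more sensitive.  The integral has a closed
form for the 4PL, used here (tests cross-check against fine-grid numerical
integration).

**Proliferation.**  The luminescence ratio is day0/day3 * 100 exactly (note:
larger values mean *slower* growth); ``growth_fold = day3/day0`` is also
reported for interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .differential import bh_adjust
from .errors import DegenerateInputError, ValidationError

#: Parameter bounds for the 4PL fit: bottom, top, log10 IC50 offset handled
#: separately, slope.
BOTTOM_BOUNDS = (-10.0, 50.0)
TOP_BOUNDS = (0.0, 120.0)
SLOPE_BOUNDS = (0.2, 10.0)
LOG10 = np.log(10.0)


@dataclass
class CurveFit:
    """Fitted 4PL parameters for one drug/sample dose-response."""

    bottom: float
    top: float
    log10_ic50: float
    slope: float
    residual: float          # root-mean-square residual of the best fit
    converged: bool
    at_bounds: tuple[str, ...] = ()

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return _four_pl(np.asarray(x, dtype=float), self.bottom, self.top,
                        self.log10_ic50, self.slope)


def _four_pl(x, bottom, top, log10_ic50, slope):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (log10_ic50 - x)))


def normalize_wells(screen: pd.DataFrame) -> pd.DataFrame:
    """Convert raw screen signals to percent inhibition per drug and sample.

    ``screen`` is the long-format table with columns drug, sample,
    dose_index, concentration, signal, well_type, day (see the simulator).
    Controls are taken per sample from day-3 vehicle and positive wells.

    Returns a long table (drug, sample, dose_index, concentration,
    inhibition) for treatment wells.
    """
    required = {"drug", "sample", "dose_index", "concentration", "signal", "well_type", "day"}
    missing = required - set(screen.columns)
    if missing:
        raise ValidationError(f"screen table lacks column(s) {sorted(missing)}")
    day3 = screen[screen["day"] == 3]
    controls = {}
    for sample, sub in day3.groupby("sample"):
        veh = sub.loc[sub["well_type"] == "vehicle", "signal"]
        pos = sub.loc[sub["well_type"] == "positive", "signal"]
        if veh.empty or pos.empty:
            raise ValidationError(f"sample {sample!r}: missing control wells")
        v, p = float(veh.mean()), float(pos.mean())
        if v <= p:
            raise DegenerateInputError(
                f"sample {sample!r}: vehicle mean <= positive-control mean (dead plate)"
            )
        controls[sample] = (v, p)
    treat = day3[day3["well_type"] == "treatment"].copy()
    v = treat["sample"].map(lambda s: controls[s][0]).astype(float)
    p = treat["sample"].map(lambda s: controls[s][1]).astype(float)
    treat["inhibition"] = 100.0 * (v - treat["signal"]) / (v - p)
    return treat[["drug", "sample", "dose_index", "concentration", "inhibition"]].reset_index(drop=True)


def fit_curve(concentrations: Sequence[float], inhibition: Sequence[float]) -> CurveFit:
    """Bounded least-squares 4PL fit of inhibition vs log10 concentration.

    Three fixed multi-starts (IC50 at the window edges and midpoint); the
    best solution by cost wins.  ``converged`` reflects optimizer success;
    parameters pinned at a bound are listed in ``at_bounds`` so a poor fit is
    never silent.
    """
    conc = np.asarray(concentrations, dtype=float)
    y = np.asarray(inhibition, dtype=float)
    if conc.shape != y.shape or conc.size < 2:
        raise ValidationError("need >= 2 (concentration, inhibition) pairs")
    if not (np.isfinite(conc).all() and np.isfinite(y).all()) or (conc <= 0).any():
        raise ValidationError("concentrations must be positive and inputs finite")
    x = np.log10(conc)
    x1, x2 = float(x.min()), float(x.max())
    if x1 == x2:
        raise ValidationError("need >= 2 distinct concentrations")

    lo = np.array([BOTTOM_BOUNDS[0], TOP_BOUNDS[0], x1 - 5.0, SLOPE_BOUNDS[0]])
    hi = np.array([BOTTOM_BOUNDS[1], TOP_BOUNDS[1], x2 + 5.0, SLOPE_BOUNDS[1]])

    def resid(theta):
        return _four_pl(x, *theta) - y

    top0 = float(np.clip(y.max(), TOP_BOUNDS[0] + 1e-6, TOP_BOUNDS[1]))
    best = None
    for mid in (x1, 0.5 * (x1 + x2), x2):
        theta0 = np.clip(np.array([0.0, top0, mid, 1.0]), lo + 1e-9, hi - 1e-9)
        sol = least_squares(resid, theta0, bounds=(lo, hi), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
    theta = best.x
    at = tuple(
        name
        for name, val, l, h in zip(("bottom", "top", "log10_ic50", "slope"), theta, lo, hi)
        if np.isclose(val, l, atol=1e-8) or np.isclose(val, h, atol=1e-8)
    )
    rmse = float(np.sqrt(2.0 * best.cost / y.size))
    return CurveFit(
        bottom=float(theta[0]), top=float(theta[1]), log10_ic50=float(theta[2]),
        slope=float(theta[3]), residual=rmse,
        converged=bool(best.success) and rmse < 10.0 and "slope" not in at,
        at_bounds=at,
    )


def dss(fit: CurveFit, window: tuple[float, float], t: float = 10.0,
        variant: str = "DSS2") -> float:
    """Drug sensitivity score of a fitted curve over a log10 window.

    ``window`` is (x1, x2) in log10 concentration, normally the lowest and
    highest tested dose.  ``t`` is the activity threshold in percent
    inhibition.  See the module docstring for the DSS1/DSS2 definitions.
    """
    x1, x2 = float(window[0]), float(window[1])
    if x1 >= x2:
        raise ValidationError(f"window must satisfy x1 < x2, got {window}")
    if not (0 <= t < 100):
        raise ValidationError(f"threshold t must be in [0, 100), got {t}")
    if variant not in ("DSS1", "DSS2"):
        raise ValidationError(f"unknown DSS variant {variant!r}")
    area = _area_above(fit, x1, x2, t)
    score = 100.0 * area / ((100.0 - t) * (x2 - x1))
    if variant == "DSS2":
        score = score * 100.0 / max(fit.top, 1.0)
    return float(np.clip(score, 0.0, 100.0))


def _area_above(fit: CurveFit, x1: float, x2: float, t: float) -> float:
    """Closed-form integral of max(y(x) - t, 0) over [x1, x2] for the 4PL."""
    b, T, m, s = fit.bottom, fit.top, fit.log10_ic50, fit.slope
    if abs(T - b) < 1e-12:
        return max(T - t, 0.0) * (x2 - x1)
    lo, hi = min(b, T), max(b, T)
    if t >= hi:
        return 0.0
    if t <= lo:
        a1, a2 = x1, x2
    else:
        # crossing point: y(xc) = t  =>  xc = m - log10((T - t)/(t - b)) / s
        xc = m - np.log10((T - t) / (t - b)) / s
        if T > b:        # increasing curve: region is [xc, x2]
            a1, a2 = max(xc, x1), x2
        else:            # decreasing (fit pinned at bounds): region is [x1, xc]
            a1, a2 = x1, min(xc, x2)
        if a1 >= a2:
            return 0.0

    def anti(x):
        # antiderivative of (b - t) + (T - b) * sigma(x)
        return (b - t) * x + (T - b) / (s * LOG10) * np.log1p(10.0 ** (s * (x - m)))

    return float(max(anti(a2) - anti(a1), 0.0))


def compute_dss(
    screen: pd.DataFrame,
    t: float = 10.0,
    variant: str = "DSS2",
) -> pd.DataFrame:
    """Normalize, fit and score every drug x sample in a raw screen table.

    Returns a long DataFrame with columns drug, sample, dss, and the fit
    parameters (bottom, top, log10_ic50, slope, residual, converged).
    """
    inhib = normalize_wells(screen)
    rows = []
    for (drug, sample), sub in inhib.groupby(["drug", "sample"], sort=True):
        fit = fit_curve(sub["concentration"].to_numpy(), sub["inhibition"].to_numpy())
        x = np.log10(sub["concentration"].to_numpy(dtype=float))
        score = dss(fit, (float(x.min()), float(x.max())), t=t, variant=variant)
        rows.append((drug, sample, score, fit.bottom, fit.top, fit.log10_ic50,
                     fit.slope, fit.residual, fit.converged))
    return pd.DataFrame(
        rows,
        columns=["drug", "sample", "dss", "bottom", "top", "log10_ic50", "slope",
                 "residual", "converged"],
    )


def dss_wide(dss_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long DSS table to drug x sample."""
    return dss_table.pivot(index="drug", columns="sample", values="dss")


def proliferation(day0: float | Sequence[float], day3: float | Sequence[float]) -> pd.DataFrame:
    """Luminescence ratio (day0/day3 * 100) and growth fold (day3/day0).

    The ratio follows the screen convention, in which higher values mean
    slower growth; ``growth_fold`` is the intuitive inverse.  The two satisfy
    ``ratio * growth_fold == 100`` identically.
    """
    d0 = np.atleast_1d(np.asarray(day0, dtype=float))
    d3 = np.atleast_1d(np.asarray(day3, dtype=float))
    if (d0 <= 0).any() or (d3 <= 0).any():
        raise ValidationError("luminescence values must be positive")
    return pd.DataFrame({"ratio": d0 / d3 * 100.0, "growth_fold": d3 / d0})


def proliferation_from_screen(screen: pd.DataFrame) -> pd.DataFrame:
    """Per-sample proliferation from the untreated wells of a screen table."""
    veh = screen[(screen["well_type"] == "vehicle")]
    rows = []
    for sample, sub in veh.groupby("sample"):
        d0 = sub.loc[sub["day"] == 0, "signal"]
        d3 = sub.loc[sub["day"] == 3, "signal"]
        if d0.empty or d3.empty:
            raise ValidationError(f"sample {sample!r}: missing day-0 or day-3 vehicle wells")
        res = proliferation(float(d0.mean()), float(d3.mean()))
        rows.append((sample, float(res["ratio"].iloc[0]), float(res["growth_fold"].iloc[0])))
    return pd.DataFrame(rows, columns=["sample", "ratio", "growth_fold"]).set_index("sample")


def compare_groups(
    dss_table: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_n: int = 5,
    min_patients: int | None = None,
) -> pd.DataFrame:
    """Per-drug two-sided Student t-test of DSS between two sample groups.

    Drugs tested in fewer than ``min_n`` samples in either group are excluded
    (flagged ``tested=False``).  ``min_patients`` optionally pre-filters to
    drugs measured in at least that many samples overall.  BH adjustment runs
    across tested drugs; the output is sorted by p.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValidationError("groups overlap")
    wide = dss_wide(dss_table) if "dss" in dss_table.columns else dss_table
    if min_patients is not None:
        wide = wide[wide.notna().sum(axis=1) >= min_patients]
    rows = []
    for drug, row in wide.iterrows():
        a = row.reindex(group_a).dropna().to_numpy(dtype=float)
        b = row.reindex(group_b).dropna().to_numpy(dtype=float)
        if len(a) < min_n or len(b) < min_n:
            rows.append((drug, np.nan, np.nan, np.nan, len(a), len(b), False))
            continue
        diff = float(a.mean() - b.mean())
        df = len(a) + len(b) - 2
        pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
        se = np.sqrt(pooled * (1 / len(a) + 1 / len(b)))
        if se == 0:
            tstat = 0.0 if diff == 0 else np.inf * np.sign(diff)
        else:
            tstat = diff / se
        p = 2.0 * float(stats.t.sf(abs(tstat), df)) if np.isfinite(tstat) else 0.0
        rows.append((drug, diff, tstat, p, len(a), len(b), True))
    out = pd.DataFrame(
        rows, columns=["drug", "mean_diff", "t", "p", "n_a", "n_b", "tested"]
    ).set_index("drug")
    out["fdr"] = np.nan
    tested = out["tested"]
    if tested.any():
        out.loc[tested, "fdr"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out.sort_values("p", kind="mergesort", na_position="last")


def stratify_by_proliferation(
    rates: pd.Series,
    reference_ids: Sequence[str],
) -> pd.Series:
    """Split samples into High/Low proliferation around the reference mean.

    The threshold is the arithmetic mean of ``rates`` over ``reference_ids``;
    samples at or above the mean are 'High pro', strictly below are
    'Low pro' (ties go to High).
    """
    reference_ids = list(reference_ids)
    if not reference_ids:
        raise DegenerateInputError("empty reference group")
    missing = set(reference_ids) - set(rates.index)
    if missing:
        raise ValidationError(f"no proliferation rate for: {sorted(missing)[:5]}")
    threshold = float(rates.loc[reference_ids].mean())
    return pd.Series(
        np.where(rates >= threshold, "High pro", "Low pro"), index=rates.index
    )
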