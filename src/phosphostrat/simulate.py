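"""Synthetic cohort and drug-screen generator.

Generates cohorts with the statistical structure the downstream analysis
assumes so that every stage of the pipeline is testable without patient data:

* log-normal-scale phosphopeptide intensities (log2 values around 22 +/- 2,
  a typical MS dynamic range) with missing values completely at random;
* karyotype-labelled samples with a planted two-subgroup structure among
  KMT2A-rearranged cases: exactly ``n_signature_features`` features are
  shifted by ``effect_size`` log2 units in the MLLGA group relative to all
  other groups;
* disjoint kinase-substrate feature sets, with optional planted activity
  shifts (all substrates of a chosen kinase shifted in a target group);
* an ex vivo drug screen: per drug and sample, viability across
  ``n_doses`` concentrations in ``dilution_factor``-fold dilutions follows a
  log-logistic dose-response curve, with planted drugs made more potent in
  MLLGA by ``potency_shift`` log10 concentration units.  Vehicle
  (negative-control) and full-kill positive-control wells are emitted per
  sample, plus day-0 and day-3 untreated luminescence for proliferation
  estimation.

All randomness flows from one ``seed`` through named child streams, so a
cohort reproduces as a unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .omics import GROUP_LABELS, METADATA_COLUMNS, OmicsMatrix

#: Order of the screen table columns.
SCREEN_COLUMNS = ("drug", "sample", "dose_index", "concentration", "signal", "well_type", "day")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the cohort geometry of the stratification study design:
    8 MLLGA + 4 MLLGB KMT2A-rearranged cases, 20 other poor-risk cases, 4
    healthy donors (36 samples), 2000 phosphopeptides of which 18 carry the
    subgroup signal, and a 5-dose 10-fold-dilution drug screen.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"MLLGA": 8, "MLLGB": 4, "No-MLL": 20, "Normal": 4}
    )
    n_features: int = 2000
    n_signature_features: int = 18
    effect_size: float = 2.0          # log2 shift of planted features in MLLGA
    noise_sd: float = 0.5             # log2 residual SD
    missing_rate: float = 0.1
    intensity_dependent_missing: bool = False
    n_kinases: int = 50
    substrates_per_kinase: int = 10
    planted_kinase_shifts: Mapping[str, float] = field(default_factory=dict)
    kinase_shift_group: str = "MLLGA"
    n_drugs: int = 60
    planted_sensitive_drugs: int = 10
    potency_shift: float = 1.0        # log10 IC50 shift in MLLGA for planted drugs
    conc_top: float = 1e-5            # molar
    n_doses: int = 5
    dilution_factor: float = 10.0
    screen_noise_cv: float = 0.1      # multiplicative noise CV on well signals
    ic50_sample_sd: float = 0.3       # log10 between-sample IC50 spread
    validation_fraction: float = 0.0  # per-group fraction held out as 'validation'
    seed: int = 0

    def validate(self) -> None:
        for grp in self.n_per_group:
            if grp not in GROUP_LABELS:
                raise ConfigurationError(f"n_per_group: unknown group label {grp!r}")
        for name in (
            "n_features", "n_signature_features", "n_kinases",
            "substrates_per_kinase", "n_drugs", "planted_sensitive_drugs",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if any(v < 0 for v in self.n_per_group.values()):
            raise ConfigurationError("n_per_group: counts must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.dilution_factor <= 1:
            raise ConfigurationError(f"dilution_factor must be > 1, got {self.dilution_factor}")
        if self.n_doses < 2:
            raise ConfigurationError(f"n_doses must be >= 2, got {self.n_doses}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.conc_top <= 0:
            raise ConfigurationError(f"conc_top must be > 0, got {self.conc_top}")
        if self.n_signature_features > self.n_features:
            raise ConfigurationError("n_signature_features exceeds n_features")
        if (self.n_features - self.n_signature_features
                < self.n_kinases * self.substrates_per_kinase):
            raise ConfigurationError(
                "n_features too small for disjoint kinase substrate sets "
                "(need n_signature_features + n_kinases*substrates_per_kinase)"
            )
        if self.planted_sensitive_drugs > self.n_drugs:
            raise ConfigurationError("planted_sensitive_drugs exceeds n_drugs")
        if self.kinase_shift_group not in GROUP_LABELS:
            raise ConfigurationError(f"kinase_shift_group: unknown group {self.kinase_shift_group!r}")
        kin_names = set(_kinase_names(self.n_kinases))
        unknown = set(self.planted_kinase_shifts) - kin_names
        if unknown:
            raise ConfigurationError(
                f"planted_kinase_shifts: unknown kinase(s) {sorted(unknown)[:5]}"
            )
        if not (0 <= self.validation_fraction < 1):
            raise ConfigurationError("validation_fraction must be in [0, 1)")


@dataclass
class CohortTruth:
    """Ground-truth record of everything the generator planted."""

    planted_features: list[str]
    planted_kinases: dict[str, float]
    group_of_sample: dict[str, str]
    #: drug -> (base log10 IC50, log10 potency shift applied in MLLGA)
    drug_potency: dict[str, tuple[float, float]]
    planted_drugs: list[str]


@dataclass
class SyntheticCohort:
    """A simulated cohort: omics layer, metadata, kinase sets and truth."""

    phospho: OmicsMatrix
    metadata: pd.DataFrame
    kinase_sets: dict[str, list[str]]
    truth: CohortTruth
    config: SimulationConfig


def _kinase_names(n: int) -> list[str]:
    return [f"KIN{i + 1:03d}" for i in range(n)]


def _drug_names(n: int) -> list[str]:
    return [f"DRUG{i + 1:03d}" for i in range(n)]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(6)
    names = ("layout", "intensity", "missing", "kinase", "drug", "screen")
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _drug_truth(config: SimulationConfig) -> tuple[dict[str, tuple[float, float]], list[str]]:
    """Deterministic per-drug base potency and planted-shift assignment."""
    rng = _streams(config.seed)["drug"]
    drugs = _drug_names(config.n_drugs)
    base = rng.uniform(-7.0, -5.0, size=config.n_drugs)  # log10 molar IC50
    planted = list(rng.choice(config.n_drugs, size=config.planted_sensitive_drugs, replace=False))
    potency: dict[str, tuple[float, float]] = {}
    planted_names = []
    for i, name in enumerate(drugs):
        shift = config.potency_shift if i in planted else 0.0
        potency[name] = (float(base[i]), float(shift))
        if i in planted:
            planted_names.append(name)
    return potency, planted_names


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a cohort per ``config``; deterministic given ``config.seed``."""
    config.validate()
    rng = _streams(config.seed)

    # --- samples and metadata -------------------------------------------------
    sample_ids: list[str] = []
    records: list[dict] = []
    counter = 0
    for grp in GROUP_LABELS:
        n = config.n_per_group.get(grp, 0)
        n_val = int(np.floor(config.validation_fraction * n))
        for j in range(n):
            counter += 1
            sid = f"S{counter:03d}"
            sample_ids.append(sid)
            if grp in ("MLLGA", "MLLGB"):
                karyotype = "KMT2Ar"
                partner = ("MLLT4" if grp == "MLLGA" else "ELL")
            elif grp == "Normal":
                karyotype, partner = "Normal", ""
            else:
                karyotype = ["complex", "-7/del(7)", "t(6;9)"][j % 3]
                partner = ""
            records.append(
                {
                    "sample_id": sid,
                    "centre": "BCI" if j % 4 != 3 else "FIMM",
                    "tissue": "PB" if j % 2 == 0 else "BM",
                    "karyotype": karyotype,
                    "kmt2a_partner": partner,
                    "qc_flags": "",
                    "split": "validation" if j >= n - n_val else "train",
                    "group": grp,
                }
            )
    metadata = pd.DataFrame(records, columns=list(METADATA_COLUMNS))
    metadata = metadata.set_index("sample_id", drop=False)
    group_of = dict(zip(metadata["sample_id"], metadata["group"]))

    # --- features -------------------------------------------------------------
    n_feat = config.n_features
    feature_ids = [f"pp{i + 1:05d}" for i in range(n_feat)]
    order = rng["layout"].permutation(n_feat)
    planted_idx = np.sort(order[: config.n_signature_features])
    planted = [feature_ids[i] for i in planted_idx]
    non_planted_idx = np.sort(order[config.n_signature_features:])

    annotations = pd.DataFrame(
        {
            "gene": [f"GENE{i // 2 + 1}" for i in range(n_feat)],
            "site": [f"GENE{i // 2 + 1} S{100 + i}" for i in range(n_feat)],
            "modification": "phospho",
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )

    # --- kinase-substrate sets (disjoint, never the planted signature) -------
    kin_names = _kinase_names(config.n_kinases)
    pool = rng["kinase"].permutation(non_planted_idx)
    kinase_sets: dict[str, list[str]] = {}
    for k, name in enumerate(kin_names):
        idx = pool[k * config.substrates_per_kinase: (k + 1) * config.substrates_per_kinase]
        kinase_sets[name] = [feature_ids[i] for i in np.sort(idx)]

    # --- intensities ----------------------------------------------------------
    n_samp = len(sample_ids)
    baseline = rng["intensity"].normal(22.0, 2.0, size=n_feat)
    values = baseline[:, None] + rng["intensity"].normal(0.0, config.noise_sd, size=(n_feat, n_samp))
    is_mllga = np.array([group_of[s] == "MLLGA" for s in sample_ids])
    values[np.ix_(planted_idx, np.where(is_mllga)[0])] += config.effect_size
    shift_cols = np.array([group_of[s] == config.kinase_shift_group for s in sample_ids])
    feat_pos = {f: i for i, f in enumerate(feature_ids)}
    for kin, shift in config.planted_kinase_shifts.items():
        rows = [feat_pos[f] for f in kinase_sets[kin]]
        values[np.ix_(rows, np.where(shift_cols)[0])] += shift

    # --- missingness ----------------------------------------------------------
    if config.missing_rate > 0:
        if config.intensity_dependent_missing:
            # lower-intensity cells are more likely to be missing, while the
            # overall missing fraction stays at missing_rate on average
            ranks = _global_ranks(values)
            prob = config.missing_rate * 2.0 * (1.0 - ranks)
            mask = rng["missing"].random(values.shape) < prob
        else:
            mask = rng["missing"].random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)

    phospho = OmicsMatrix(
        pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"), columns=sample_ids),
        annotations,
    )
    drug_potency, planted_drugs = _drug_truth(config)
    truth = CohortTruth(
        planted_features=planted,
        planted_kinases=dict(config.planted_kinase_shifts),
        group_of_sample=group_of,
        drug_potency=drug_potency,
        planted_drugs=planted_drugs,
    )
    return SyntheticCohort(phospho=phospho, metadata=metadata, kinase_sets=kinase_sets,
                           truth=truth, config=config)


def _global_ranks(values: np.ndarray) -> np.ndarray:
    """Global fractional ranks of a matrix in (0, 1)."""
    flat = values.ravel()
    order = np.argsort(flat, kind="mergesort")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, flat.size + 1)
    return (ranks / (flat.size + 1)).reshape(values.shape)


def simulate_screen(config: SimulationConfig, metadata: pd.DataFrame) -> pd.DataFrame:
    """Simulate the drug screen for the samples in ``metadata``.

    Returns a long-format table with columns :data:`SCREEN_COLUMNS`.  Per
    drug and sample the treated-well signal is
    ``vehicle_luminescence * viability(c) / 100`` with viability following a
    log-logistic curve on the sample-specific IC50; positive-control wells
    are full kill (signal 0 before noise).  Day-0 vehicle wells and day-3
    vehicle wells allow proliferation-rate estimation downstream.
    """
    config.validate()
    if "group" not in metadata.columns or (metadata["group"] == "").any():
        raise ValidationError("metadata must carry group labels for every sample")
    rng = _streams(config.seed)["screen"]
    drug_potency, _ = _drug_truth(config)
    doses = config.conc_top / config.dilution_factor ** np.arange(config.n_doses)

    def noisy(x: float) -> float:
        if config.screen_noise_cv <= 0:
            return x
        return float(x * rng.lognormal(0.0, config.screen_noise_cv))

    rows: list[tuple] = []
    for sid, grp in zip(metadata["sample_id"], metadata["group"]):
        lum_day0 = float(rng.uniform(0.8e6, 1.2e6))
        growth = float(rng.lognormal(np.log(1.8), 0.25))
        if grp == "MLLGA":
            growth *= 1.3  # faster ex vivo proliferation in the planted subgroup
        lum_day3 = lum_day0 * growth
        for _ in range(2):
            rows.append(("", sid, 0, 0.0, noisy(lum_day0), "vehicle", 0))
            rows.append(("", sid, 0, 0.0, noisy(lum_day3), "vehicle", 3))
            rows.append(("", sid, 0, 0.0, noisy(0.0), "positive", 3))
        for drug, (base_ic50, shift) in drug_potency.items():
            log_ic50 = base_ic50 - (shift if grp == "MLLGA" else 0.0)
            if config.ic50_sample_sd > 0:
                log_ic50 += float(rng.normal(0.0, config.ic50_sample_sd))
            for di, conc in enumerate(doses, start=1):
                viability = 100.0 / (1.0 + conc / 10.0 ** log_ic50)
                signal = lum_day3 * viability / 100.0
                rows.append((drug, sid, di, float(conc), noisy(signal), "treatment", 3))
    return pd.DataFrame(rows, columns=list(SCREEN_COLUMNS))


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write matrix, metadata and kinase sets of a cohort to a directory."""
    from pathlib import Path

    from .omics import write_gmt, write_matrix, write_metadata

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.phospho, out / "phospho.tsv")
    write_metadata(cohort.metadata, out / "metadata.tsv")
    write_gmt(cohort.kinase_sets, out / "kinase_sets.gmt")
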