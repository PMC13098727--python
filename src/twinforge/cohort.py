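"""Synthetic two-wave cohort generation.

Emulates a paired longitudinal panel in the style of a midlife health
survey: one baseline wave (W2) and one follow-up wave (W3) roughly a
decade later, mixed continuous/ordinal/binary/categorical variables
spanning biological, behavioral, psychosocial and socioeconomic domains,
plus administrative bookkeeping variables that carry no outcome signal.
The follow-up disease outcome is drawn from a known logistic model on
baseline values, which makes the generator a ground-truth oracle for
recovery, calibration and monotonicity tests downstream.

Default marginals are anchored to a real midlife cohort's descriptive
statistics (e.g. BMI mean 27.9, SD 5.7; ~14.7% follow-up diabetes
incidence; mean age 56 at baseline) so that models trained on the
synthetic panel face a realistic class imbalance and feature scale mix.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .catalog import (
    VariableMetadata,
    catalog_by_name,
    read_catalog,
    validate_catalog,
)

__all__ = [
    "CohortSpec",
    "CohortPanel",
    "MissingSpec",
    "generate_cohort",
    "true_risk",
    "inject_missingness",
    "write_panel",
    "read_panel",
    "DEFAULT_SIGNAL_COEFFICIENTS",
]


class CohortSpecError(ValueError):
    """Unsatisfiable or inconsistent cohort specification."""


class PanelSchemaError(ValueError):
    """Panel table and data dictionary disagree."""


# Log-odds weights of the true outcome model, on raw variable scales.
# Signal deliberately spans all four substantive domains so that the
# incremental-domain evaluation has something to find in each block.
DEFAULT_SIGNAL_COEFFICIENTS: dict[str, float] = {
    "age": 0.035,
    "bmi": 0.11,
    "hypertension": 0.65,
    "physical_activity": -0.28,
    "current_smoker": 0.50,
    "alcohol_drinks_week": 0.04,
    "anxiety_score": 0.18,
    "depression_score": 0.12,
    "education_years": -0.07,
    "household_income": -4.0e-6,
}

# Baseline -> follow-up mean shifts (the panel's only explicit dynamics).
DEFAULT_DRIFT: dict[str, float] = {
    "age": 8.0,
    "bmi": 0.3,
    "education_years": 0.3,
    "household_income": 11000.0,
}

# Fraction of the cross-sectional SD used for wave-3 innovations.
_INNOVATION_FRACTION = 0.3


@dataclass(frozen=True)
class MissingSpec:
    """Per-variable missingness: fraction and mechanism.

    ``MCAR`` deletes uniformly at random; ``MAR`` scales the deletion
    probability linearly with the named covariate's empirical quantile
    (higher covariate -> more missing), preserving the marginal rate.
    """

    fraction: float
    mechanism: str = "MCAR"
    covariate: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction < 1.0:
            raise CohortSpecError(f"missing fraction must be in [0,1), got {self.fraction}")
        if self.mechanism not in ("MCAR", "MAR"):
            raise CohortSpecError(f"unknown missingness mechanism {self.mechanism!r}")
        if self.mechanism == "MAR" and not self.covariate:
            raise CohortSpecError("MAR missingness requires a covariate name")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort draw."""

    n_participants: int = 4174
    seed: int = 42
    target_incidence: float = 0.147
    signal_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGNAL_COEFFICIENTS)
    )
    intercept: float | None = None  # calibrated to target_incidence when None
    n_noise_vars: int = 2
    drift: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DRIFT))
    missingness: Mapping[str, MissingSpec] = field(default_factory=dict)
    attrition_fraction: float = 0.0
    confounded_admin: bool = False

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise CohortSpecError("n_participants must be positive")
        if not 0.0 < self.target_incidence < 1.0:
            raise CohortSpecError(
                f"target_incidence must lie strictly in (0,1); {self.target_incidence} "
                "is unsatisfiable"
            )
        if self.n_noise_vars < 0:
            raise CohortSpecError("n_noise_vars must be non-negative")
        if not 0.0 <= self.attrition_fraction < 1.0:
            raise CohortSpecError("attrition_fraction must be in [0,1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["missingness"] = {
            k: dataclasses.asdict(m) for k, m in self.missingness.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        d = dict(d)
        d["missingness"] = {
            k: MissingSpec(**m) for k, m in d.get("missingness", {}).items()
        }
        return cls(**d)


def build_catalog(spec: CohortSpec) -> list[VariableMetadata]:
    """The data dictionary of the generated panel."""
    V = VariableMetadata
    cat = [
        V("age", "Age at interview (years)", "biological", "continuous"),
        V("sex_male", "Sex: male", "biological", "binary"),
        V("height_inches", "Standing height (inches)", "biological", "continuous"),
        V("bmi", "Body mass index (kg/m2)", "biological", "continuous", modifiable=True),
        V("weight_lbs", "Current weight (pounds)", "biological", "continuous", modifiable=True),
        V("hypertension", "Hypertension ever diagnosed (12 mo)", "biological", "binary"),
        V(
            "prescription_meds",
            "Prescription medication checklist: any diabetes-related medication",
            "biological",
            "binary",
        ),
        V(
            "physical_activity",
            "Frequency of moderate physical activity (1-6 scale)",
            "behavioral",
            "ordinal",
            scale_min=1,
            scale_max=6,
            modifiable=True,
        ),
        V("current_smoker", "Currently smokes cigarettes", "behavioral", "binary", modifiable=True),
        V("ever_smoked", "Ever smoked cigarettes regularly", "behavioral", "binary"),
        V(
            "alcohol_drinks_week",
            "Alcoholic drinks per week",
            "behavioral",
            "continuous",
            modifiable=True,
        ),
        V("depression_score", "Depressive symptom score", "psychosocial", "continuous", modifiable=True),
        V("anxiety_score", "Anxiety symptom score", "psychosocial", "continuous", modifiable=True),
        V("perceived_stress", "Perceived stress scale score", "psychosocial", "continuous", modifiable=True),
        V("education_years", "Education completed (category scale)", "socioeconomic", "continuous"),
        V("household_income", "Total household income ($)", "socioeconomic", "continuous"),
        V("interviewer_id", "Interviewer ID", "administrative", "categorical"),
        V("data_collection_site", "Data collection site", "administrative", "categorical"),
    ]
    for i in range(spec.n_noise_vars):
        cat.append(
            V(
                f"admin_noise_{i + 1:02d}",
                f"Administrative processing code {i + 1}",
                "administrative",
                "continuous",
            )
        )
    if spec.confounded_admin:
        # Administrative variable deliberately entangled with the linear
        # predictor: a sampling artifact that statistical selectors latch
        # onto but a domain-aware relevance agent rejects.
        cat.append(
            V(
                "admin_batch_code",
                "Administrative batch assignment code",
                "administrative",
                "continuous",
            )
        )
    return validate_catalog(cat)


@dataclass
class CohortPanel:
    """Paired two-wave records plus their data dictionary.

    ``data`` is long format: one row per participant per wave, columns
    ``participant_id``, ``wave`` and one column per catalog variable.
    Missing values are ``NaN`` (the sentinel is outside every declared
    scale, so round-tripping is unambiguous).
    """

    data: pd.DataFrame
    outcome_w3: pd.Series
    catalog: list[VariableMetadata]
    provenance: CohortSpec | str = "external"

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.catalog]

    def wave(self, wave: str) -> pd.DataFrame:
        """Feature frame of one wave, indexed by participant id."""
        sub = self.data[self.data["wave"] == wave]
        return sub.set_index("participant_id")[self.variable_names]

    @property
    def ids(self) -> np.ndarray:
        return np.unique(self.data["participant_id"].to_numpy())

    def pair(self) -> "CohortPanel":
        """Keep only participants present in both waves."""
        w2_ids = set(self.data.loc[self.data["wave"] == "W2", "participant_id"])
        w3_ids = set(self.data.loc[self.data["wave"] == "W3", "participant_id"])
        keep = sorted(w2_ids & w3_ids)
        data = self.data[self.data["participant_id"].isin(keep)].reset_index(drop=True)
        outcome = self.outcome_w3.loc[self.outcome_w3.index.isin(keep)]
        return CohortPanel(data, outcome, self.catalog, self.provenance)

    @property
    def n_participants(self) -> int:
        return len(self.ids)

    def copy(self) -> "CohortPanel":
        return CohortPanel(
            self.data.copy(), self.outcome_w3.copy(), list(self.catalog), self.provenance
        )


def _linear_predictor(values: pd.DataFrame, spec: CohortSpec) -> np.ndarray:
    lp = np.zeros(len(values))
    for name, coef in spec.signal_coefficients.items():
        lp += coef * values[name].to_numpy(dtype=float)
    return lp


def _calibrate_intercept(lp: np.ndarray, target: float) -> float:
    """1-D root finding on mean predicted risk (monotone in the intercept)."""
    f = lambda b0: float(np.mean(expit(b0 + lp))) - target
    return float(brentq(f, -40.0, 40.0, xtol=1e-10))


def generate_cohort(spec: CohortSpec) -> CohortPanel:
    """Draw a complete paired panel; deterministic given ``spec.seed``."""
    catalog = build_catalog(spec)
    names = {v.name for v in catalog}
    for key in spec.signal_coefficients:
        if key not in names:
            raise CohortSpecError(f"signal coefficient names unknown variable {key!r}")

    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    w2 = pd.DataFrame(index=pd.RangeIndex(n))

    w2["age"] = rng.normal(56.0, 12.4, n)
    w2["sex_male"] = rng.binomial(1, 0.452, n)
    w2["height_inches"] = rng.normal(66.5, 3.8, n)
    w2["bmi"] = np.clip(rng.normal(27.9, 5.7, n), 15.0, None)
    w2["weight_lbs"] = w2["bmi"] * w2["height_inches"] ** 2 / 703.0
    w2["hypertension"] = rng.binomial(1, 0.303, n)
    latent_act = rng.normal(3.5, 1.5, n)
    w2["physical_activity"] = np.clip(np.rint(latent_act), 1, 6).astype(int)
    w2["current_smoker"] = rng.binomial(1, 0.20, n)
    w2["ever_smoked"] = np.maximum(w2["current_smoker"], rng.binomial(1, 0.45, n))
    w2["alcohol_drinks_week"] = np.clip(rng.normal(4.0, 3.5, n), 0.0, None)
    w2["depression_score"] = np.clip(rng.normal(0.6, 1.7, n), 0.0, None)
    w2["anxiety_score"] = np.clip(rng.normal(1.2, 1.1, n), 0.0, None)
    w2["perceived_stress"] = rng.normal(2.5, 1.0, n)
    w2["education_years"] = np.clip(rng.normal(7.3, 2.5, n), 1.0, 12.0)
    w2["household_income"] = np.exp(rng.normal(np.log(57500.0), 0.88, n))
    w2["interviewer_id"] = rng.integers(1, 26, n)
    w2["data_collection_site"] = rng.integers(1, 6, n)
    for i in range(spec.n_noise_vars):
        w2[f"admin_noise_{i + 1:02d}"] = rng.normal(0.0, 1.0, n)

    lp = _linear_predictor(w2, spec)
    intercept = spec.intercept if spec.intercept is not None else _calibrate_intercept(
        lp, spec.target_incidence
    )
    p = expit(intercept + lp)
    outcome = pd.Series(rng.binomial(1, p), index=w2.index, name="outcome_w3")

    # Downstream proxy: medication checklist tracks realized risk, mirroring
    # the proxy/outcome entanglement that makes it non-actionable.
    w2["prescription_meds"] = rng.binomial(1, np.clip(0.05 + 0.6 * p, 0, 1), n)
    if spec.confounded_admin:
        lp_sd = float(np.std(lp)) or 1.0
        w2["admin_batch_code"] = lp + rng.normal(0.0, 0.5 * lp_sd, n)

    # Wave 3: baseline value + configured drift + Gaussian innovation.
    w3 = w2.copy()
    drift = dict(spec.drift)
    for v in catalog:
        d = drift.get(v.name, 0.0)
        if v.dtype == "continuous":
            sd = float(np.std(w2[v.name].to_numpy(dtype=float)))
            w3[v.name] = (
                w2[v.name] + d + rng.normal(0.0, _INNOVATION_FRACTION * sd, n)
            )
        elif v.dtype == "ordinal":
            shifted = w2[v.name] + d + rng.normal(0.0, 0.8, n)
            w3[v.name] = np.clip(np.rint(shifted), v.scale_min, v.scale_max).astype(int)
    # Binary dynamics: hypertension onset and smoking cessation/initiation.
    onset = rng.binomial(1, 0.123, n)
    w3["hypertension"] = np.maximum(w2["hypertension"], onset)
    quit_ = rng.binomial(1, 0.25, n)
    start = rng.binomial(1, 0.02, n)
    w3["current_smoker"] = np.where(
        w2["current_smoker"] == 1, 1 - quit_, start
    )
    w3["ever_smoked"] = np.maximum(w2["ever_smoked"], w3["current_smoker"])
    w3["prescription_meds"] = np.maximum(
        w2["prescription_meds"], rng.binomial(1, np.clip(0.4 * p, 0, 1), n)
    )
    w3["weight_lbs"] = w3["bmi"] * w3["height_inches"] ** 2 / 703.0
    w3["interviewer_id"] = rng.integers(1, 26, n)

    cols = [v.name for v in catalog]
    ids = np.arange(1, n + 1)
    long = pd.concat(
        [
            w2[cols].assign(participant_id=ids, wave="W2"),
            w3[cols].assign(participant_id=ids, wave="W3"),
        ],
        ignore_index=True,
    )[["participant_id", "wave"] + cols]
    outcome.index = pd.Index(ids, name="participant_id")

    calibrated = dataclasses.replace(spec, intercept=intercept)
    return CohortPanel(long, outcome, catalog, provenance=calibrated)


def true_risk(panel: CohortPanel, spec: CohortSpec | None = None) -> np.ndarray:
    """Ground-truth outcome probability per participant (wave-2 model).

    Only defined for panels this generator produced; externally ingested
    panels have no oracle.
    """
    if spec is None:
        spec = panel.provenance if isinstance(panel.provenance, CohortSpec) else None
    if not isinstance(spec, CohortSpec):
        raise ValueError("true_risk is undefined for panels with external provenance")
    if spec.intercept is None:
        raise ValueError("spec has no calibrated intercept; pass panel.provenance")
    w2 = panel.wave("W2")
    return expit(spec.intercept + _linear_predictor(w2, spec))


def inject_missingness(panel: CohortPanel, spec: CohortSpec) -> CohortPanel:
    """Apply item-level missingness and wave-3 attrition.

    Deterministic given ``spec.seed`` (a separate stream from generation,
    so the complete-data panel is unchanged by adding missingness).
    """
    out = panel.copy()
    rng = np.random.default_rng([spec.seed, 104729])
    names = {v.name for v in out.catalog}
    data = out.data
    for var, ms in spec.missingness.items():
        if var not in names:
            raise CohortSpecError(f"missingness names unknown variable {var!r}")
        if ms.mechanism == "MAR":
            if ms.covariate not in names:
                raise CohortSpecError(
                    f"MAR covariate {ms.covariate!r} not in catalog"
                )
            cov = data[ms.covariate].to_numpy(dtype=float)
            ranks = pd.Series(cov).rank(method="average").to_numpy()
            u = (ranks - 0.5) / len(ranks)
            prob = np.clip(2.0 * ms.fraction * u, 0.0, 0.999)
        else:
            prob = np.full(len(data), ms.fraction)
        mask = rng.random(len(data)) < prob
        col = data[var].astype(float)
        col[mask] = np.nan
        data[var] = col
    if spec.attrition_fraction > 0:
        ids = out.ids
        dropped = ids[rng.random(len(ids)) < spec.attrition_fraction]
        keep = ~(
            (data["wave"] == "W3") & data["participant_id"].isin(dropped)
        )
        out.data = data[keep].reset_index(drop=True)
        out.outcome_w3 = out.outcome_w3.drop(index=dropped, errors="ignore")
    return out


def write_panel(panel: CohortPanel, path: str | Path, dict_path: str | Path) -> None:
    """Write the long table (CSV or Parquet by suffix) and the dictionary.

    The dictionary JSON carries the catalog and, for generator-born
    panels, the provenance spec, so a round trip restores the oracle.
    """
    path = Path(path)
    table = panel.data.copy()
    outcome_map = panel.outcome_w3.reindex(
        table.loc[table["wave"] == "W3", "participant_id"]
    ).to_numpy()
    table["outcome_w3"] = np.nan
    table.loc[table["wave"] == "W3", "outcome_w3"] = outcome_map
    if path.suffix == ".parquet":
        table.to_parquet(path, index=False)
    else:
        table.to_csv(path, index=False)
    meta = {
        "catalog": [dataclasses.asdict(v) for v in panel.catalog],
        "provenance": (
            panel.provenance.to_dict()
            if isinstance(panel.provenance, CohortSpec)
            else "external"
        ),
    }
    Path(dict_path).write_text(json.dumps(meta, indent=1))


def read_panel(path: str | Path, dict_path: str | Path) -> CohortPanel:
    path = Path(path)
    if path.suffix == ".parquet":
        table = pd.read_parquet(path)
    else:
        table = pd.read_csv(path)
    meta = json.loads(Path(dict_path).read_text())
    catalog = validate_catalog(
        VariableMetadata(**entry) for entry in meta["catalog"]
    )
    var_names = [v.name for v in catalog]
    required = {"participant_id", "wave"}
    table_vars = set(table.columns) - required - {"outcome_w3"}
    for name in var_names:
        if name not in table_vars:
            raise PanelSchemaError(f"data dictionary column {name!r} missing from table")
    for col in sorted(table_vars):
        if col not in var_names:
            raise PanelSchemaError(f"table column {col!r} missing from data dictionary")
    w3 = table[table["wave"] == "W3"]
    outcome = pd.Series(
        w3["outcome_w3"].to_numpy(),
        index=pd.Index(w3["participant_id"].to_numpy(), name="participant_id"),
        name="outcome_w3",
    ).dropna().astype(int)
    provenance: CohortSpec | str = (
        "external"
        if meta.get("provenance") == "external"
        else CohortSpec.from_dict(meta["provenance"])
    )
    data = table.drop(columns=["outcome_w3"])
    return CohortPanel(data.reset_index(drop=True), outcome, catalog, provenance)
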