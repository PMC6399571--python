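"""Seeded synthetic inpatient cohort generator.

Real inpatient fall cohorts are confidential hospital extracts, so every
downstream stage of this package is exercised on cohorts drawn from a
*planted* Bayesian network whose structure mirrors the guideline-derived
model schema: demographics and admission characteristics feed patient
contributing factors (mobility, cognition, elimination, medication), which
feed risk-tool subscores and the risk-tool score, which (with mitigating
nursing interventions) feed the daily fall hazard. Because the data are
sampled from that network, the statistical dependencies every later stage
assumes hold by construction, and the planted truth is available for
parameter-recovery tests.

Generating process per admission: static fields are sampled once from
configured marginals (the two site profiles ship as defaults); daily
contributing-factor states follow a first-order carryover chain (state kept
with the configured persistence probability, else redrawn from the planted
conditional — marginals are preserved); risk-tool subscores, scores and
interventions are redrawn each day from their planted conditionals given
that day's factors; the fall is a per-day Bernoulli with probability given
by the planted fall CPT. The fall CPT is logistic in its parents with
configurable per-factor log odds, and its intercept is solved exactly
(against the enumerated parent joint) so the expected fall rate equals the
configured falls-per-1000-hospital-days target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special

from .bayesnet import BayesNet, CPT, NodeSpec

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "AdmissionRecord",
    "FallEvent",
    "ConfigurationError",
    "development_config",
    "validation_config",
    "ground_truth_network",
    "sample_cohort",
    "mask_missing",
    "write_cohort",
    "read_cohort",
]

AGE_STATES = ("lt50", "50_60", "60_70", "70_80", "gt80")
AGE_VALUES = (40.0, 55.0, 65.0, 75.0, 85.0)
DX_STATES = (
    "neoplasm",
    "benign",
    "circulatory",
    "resp_gi",
    "surgical",
    "neurological",
    "infectious",
    "other",
)
KPCS_STATES = ("g1", "g2", "g3", "g4", "g5_6")
KPCS_VALUES = (1.0, 2.0, 3.0, 4.0, 5.5)

#: Table-1-style factor categories and their generator variables.
FACTOR_CATEGORIES = {
    "physiological": ("mobility_impairment", "elimination_problem"),
    "cognitive": ("cognitive_impairment",),
    "behavioral": ("fall_history",),
    "therapeutic": ("sedative_use",),
    "mitigating": ("fall_precaution", "toileting_assist"),
}

#: fall-node parent per category (risk-tool score is always a parent)
_FALL_PARENT = {
    "physiological": "mobility_impairment",
    "cognitive": "cognitive_impairment",
    "behavioral": "fall_history",
    "therapeutic": "sedative_use",
    "mitigating": "fall_precaution",
}


class ConfigurationError(ValueError):
    pass


def _check_marginal(name: str, marginal: Mapping[str, float], states) -> np.ndarray:
    if set(marginal) != set(states):
        raise ConfigurationError(
            f"marginal {name!r}: categories {sorted(marginal)} do not match "
            f"states {list(states)}"
        )
    vec = np.array([float(marginal[s]) for s in states])
    if np.any(vec < 0) or np.any(vec > 1):
        raise ConfigurationError(f"marginal {name!r} has probabilities outside [0,1]")
    if abs(vec.sum() - 1.0) > 1e-9:
        raise ConfigurationError(
            f"marginal {name!r} sums to {vec.sum():.12f}, not 1"
        )
    return vec


@dataclass(frozen=True)
class DailyVariableSpec:
    """One contributing-factor variable: its category and baseline rate."""

    category: str
    baseline: float
    enabled: bool = True


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic site's cohort."""

    n_admissions: int
    seed: int = 0
    style: str = "development"  # risk tool flavor: development | validation
    length_of_stay_distribution: dict = field(
        default_factory=lambda: {
            "name": "negative_binomial", "mean": 8.54, "sd": 11.52, "max_days": 120,
        }
    )
    demographic_marginals: dict = field(default_factory=dict)
    diagnosis_marginals: dict = field(default_factory=dict)
    kpcs_marginals: dict = field(default_factory=dict)
    target_fall_rate: float = 1.95  # falls per 1000 hospital days
    injurious_fraction: float = 54 / 238
    minor_fraction: float = 49 / 54  # of injurious falls; remainder moderate
    daily_variable_specs: dict = field(default_factory=dict)
    missingness_rates: dict = field(default_factory=dict)
    missingness_mode: str = "mcar"  # mcar | policy
    persistence: float = 0.8  # day-to-day carryover of factor states
    fall_log_odds: dict = field(default_factory=dict)
    subscore_noise: float = 0.1
    readmission_rate: float = 0.05

    def enabled_categories(self) -> set[str]:
        out = set()
        for spec in self.daily_variable_specs.values():
            if spec.enabled:
                out.add(spec.category)
        return out

    def validate(self) -> None:
        if self.n_admissions < 0:
            raise ConfigurationError("n_admissions must be >= 0")
        if self.target_fall_rate <= 0:
            raise ConfigurationError("target_fall_rate must be > 0")
        if self.style not in ("development", "validation"):
            raise ConfigurationError(f"unknown style {self.style!r}")
        _check_marginal("sex", self.demographic_marginals["sex"], ("male", "female"))
        _check_marginal("age_bin", self.demographic_marginals["age_bin"], AGE_STATES)
        _check_marginal("diagnosis_group", self.diagnosis_marginals, DX_STATES)
        _check_marginal("kpcs_group", self.kpcs_marginals, KPCS_STATES)
        for k in ("injurious_fraction", "minor_fraction", "persistence",
                  "readmission_rate", "subscore_noise"):
            v = getattr(self, k)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{k} must be in [0,1], got {v}")
        for var, rate in self.missingness_rates.items():
            if not 0 <= rate <= 1:
                raise ConfigurationError(
                    f"missingness rate for {var!r} must be in [0,1], got {rate}"
                )
        for var, spec in self.daily_variable_specs.items():
            if spec.category not in FACTOR_CATEGORIES:
                raise ConfigurationError(
                    f"variable {var!r}: unknown category {spec.category!r}"
                )
            if not 0 <= spec.baseline <= 1:
                raise ConfigurationError(
                    f"variable {var!r}: baseline outside [0,1]"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["daily_variable_specs"] = {
            k: asdict(v) if not isinstance(v, dict) else v
            for k, v in self.daily_variable_specs.items()
        }
        return d


def _default_daily_specs() -> dict[str, DailyVariableSpec]:
    return {
        "mobility_impairment": DailyVariableSpec("physiological", 0.30),
        "elimination_problem": DailyVariableSpec("physiological", 0.25),
        "cognitive_impairment": DailyVariableSpec("cognitive", 0.20),
        "fall_history": DailyVariableSpec("behavioral", 0.08),
        "sedative_use": DailyVariableSpec("therapeutic", 0.25),
        "fall_precaution": DailyVariableSpec("mitigating", 0.15),
        "toileting_assist": DailyVariableSpec("mitigating", 0.10),
    }


_OR20 = float(np.log(20.0))


def _default_fall_log_odds() -> dict[str, float]:
    # strong-signal planted effects: odds ratio 20 per contributing factor,
    # risk-tool high score likewise; effective mitigation (OR 1/4)
    return {
        "mobility_impairment": _OR20,
        "cognitive_impairment": _OR20,
        "fall_history": _OR20,
        "sedative_use": _OR20,
        "risk_tool_score": _OR20,
        "fall_precaution": -float(np.log(4.0)),
    }


def development_config(n_admissions: int = 2000, seed: int = 0) -> GeneratorConfig:
    """Development-site profile: Hendrich II risk tool, site-1 marginals."""
    kpcs = np.array([227, 8197, 3898, 1627, 262], float)
    kpcs /= kpcs.sum()
    age = np.array([0.2212, 0.2272, 0.2346, 0.2293, 0.0876])
    age /= age.sum()
    dx = np.array([0.324, 0.027, 0.396, 0.046, 0.036, 0.070, 0.008, 0.093])
    dx /= dx.sum()
    return GeneratorConfig(
        n_admissions=n_admissions,
        seed=seed,
        style="development",
        demographic_marginals={
            "sex": {"male": 0.5697, "female": 0.4303},
            "age_bin": dict(zip(AGE_STATES, age.tolist())),
            "secondary_dx": {"no": 0.004, "yes": 0.996},
        },
        diagnosis_marginals=dict(zip(DX_STATES, dx.tolist())),
        kpcs_marginals=dict(zip(KPCS_STATES, kpcs.tolist())),
        target_fall_rate=1.95,
        injurious_fraction=54 / 238,
        minor_fraction=49 / 54,
        daily_variable_specs=_default_daily_specs(),
        fall_log_odds=_default_fall_log_odds(),
        missingness_rates={},
    )


def validation_config(n_admissions: int = 2000, seed: int = 0) -> GeneratorConfig:
    """Validation-site profile: STRATIFY risk tool, site-2 marginals, and
    the site's documented risk-tool-score missingness."""
    kpcs = np.array([377, 11349, 5630, 1332, 0], float)
    kpcs /= kpcs.sum()
    age = np.array([0.2642, 0.1816, 0.1661, 0.2380, 0.1502])
    age /= age.sum()
    dx = np.array([0.2300, 0.0503, 0.0363, 0.2660, 0.1022, 0.0124, 0.0384, 0.2645])
    dx /= dx.sum()
    cfg = GeneratorConfig(
        n_admissions=n_admissions,
        seed=seed,
        style="validation",
        length_of_stay_distribution={
            "name": "negative_binomial", "mean": 8.15, "sd": 11.28, "max_days": 120,
        },
        demographic_marginals={
            "sex": {"male": 0.4710, "female": 0.5290},
            "age_bin": dict(zip(AGE_STATES, age.tolist())),
            "secondary_dx": {"no": 0.366, "yes": 0.634},
        },
        diagnosis_marginals=dict(zip(DX_STATES, dx.tolist())),
        kpcs_marginals=dict(zip(KPCS_STATES, kpcs.tolist())),
        target_fall_rate=1.69,
        injurious_fraction=69 / 292,
        minor_fraction=52 / 69,
        daily_variable_specs=_default_daily_specs(),
        fall_log_odds=_default_fall_log_odds(),
        missingness_rates={"stratify_score": 0.6465},
    )
    return cfg


# ---------------------------------------------------------------------------
# planted network


def _scaled_rates(base: float, mult, parent_marginal: np.ndarray) -> np.ndarray:
    """Per-parent-state rates with weighted mean exactly ``base``."""
    m = np.asarray(mult, float)
    m = m / float(parent_marginal @ m)
    return np.clip(base * m, 0.0, 0.95)


def _binary_cpt(p_yes: np.ndarray) -> np.ndarray:
    p = np.asarray(p_yes, float).reshape(-1)
    return np.column_stack([1 - p, p])


def risk_tool_node(style: str) -> str:
    return "hendrich_score" if style == "development" else "stratify_score"


def ground_truth_network(config: GeneratorConfig) -> BayesNet:
    """The planted data-generating network for a configuration.

    The fall node has one parent per enabled factor category plus the
    risk-tool score; its CPT is logistic in the parents with the configured
    log odds, intercept calibrated so that the marginal daily fall
    probability equals ``target_fall_rate / 1000``.
    """
    config.validate()
    enabled = config.enabled_categories()
    specs = config.daily_variable_specs

    def on(var: str) -> bool:
        return var in specs and specs[var].enabled

    sex_p = _check_marginal("sex", config.demographic_marginals["sex"], ("male", "female"))
    age_p = _check_marginal("age_bin", config.demographic_marginals["age_bin"], AGE_STATES)
    sec_p = _check_marginal(
        "secondary_dx", config.demographic_marginals["secondary_dx"], ("no", "yes")
    )
    dx_p = _check_marginal("diagnosis_group", config.diagnosis_marginals, DX_STATES)
    kpcs_p = _check_marginal("kpcs_group", config.kpcs_marginals, KPCS_STATES)

    nodes: list[NodeSpec] = []
    cpts: dict[str, np.ndarray] = {}

    def add(name, states, parents=(), subgroup="assessment_diagnosis",
            numeric_values=None, table=None):
        nodes.append(NodeSpec(name, tuple(states), tuple(parents), subgroup,
                              numeric_values))
        cpts[name] = np.asarray(table, float)

    add("sex", ("male", "female"), subgroup="demographics", table=[sex_p])
    add("age_bin", AGE_STATES, subgroup="demographics",
        numeric_values=AGE_VALUES, table=[age_p])
    add("diagnosis_group", DX_STATES, subgroup="administrative", table=[dx_p])
    add("secondary_dx", ("no", "yes"), subgroup="administrative", table=[sec_p])
    add("kpcs_group", KPCS_STATES, subgroup="kpcs",
        numeric_values=KPCS_VALUES, table=[kpcs_p])

    age_mult = [0.5, 0.75, 1.0, 1.35, 1.8]
    if on("mobility_impairment"):
        add("mobility_impairment", ("no", "yes"), ("age_bin",),
            table=_binary_cpt(_scaled_rates(
                specs["mobility_impairment"].baseline, age_mult, age_p)))
    if on("cognitive_impairment"):
        add("cognitive_impairment", ("no", "yes"), ("age_bin",),
            table=_binary_cpt(_scaled_rates(
                specs["cognitive_impairment"].baseline, age_mult, age_p)))
    if on("elimination_problem"):
        add("elimination_problem", ("no", "yes"), ("kpcs_group",),
            table=_binary_cpt(_scaled_rates(
                specs["elimination_problem"].baseline,
                [0.5, 0.8, 1.2, 1.7, 2.2], kpcs_p)))
    if on("fall_history"):
        b = specs["fall_history"].baseline
        add("fall_history", ("no", "yes"), table=[[1 - b, b]])
    if on("sedative_use"):
        add("sedative_use", ("no", "yes"), ("diagnosis_group",),
            subgroup="medication",
            table=_binary_cpt(_scaled_rates(
                specs["sedative_use"].baseline,
                [1.3, 0.8, 1.2, 0.9, 1.1, 1.4, 0.8, 0.8], dx_p)))

    # risk-tool subscores: noisy indicators of their source factors
    eps = config.subscore_noise
    noisy = _binary_cpt([eps, 1 - eps])
    score_name = risk_tool_node(config.style)
    sub_parents: list[str] = []
    if config.style == "development":
        if on("cognitive_impairment"):
            add("hendrich_confusion", ("s0", "s1"), ("cognitive_impairment",),
                subgroup="risk_tool", table=noisy)
            sub_parents.append("hendrich_confusion")
        if on("mobility_impairment"):
            add("hendrich_mobility", ("s0", "s1"), ("mobility_impairment",),
                subgroup="risk_tool", table=noisy)
            sub_parents.append("hendrich_mobility")
        if on("sedative_use"):
            sub_parents.append("sedative_use")
    else:
        if on("fall_history"):
            add("stratify_fallhx", ("s0", "s1"), ("fall_history",),
                subgroup="risk_tool", table=noisy)
            sub_parents.append("stratify_fallhx")
        if on("elimination_problem"):
            add("stratify_toileting", ("s0", "s1"), ("elimination_problem",),
                subgroup="risk_tool", table=noisy)
            sub_parents.append("stratify_toileting")
        if on("mobility_impairment"):
            add("stratify_mobility", ("s0", "s1"), ("mobility_impairment",),
                subgroup="risk_tool", table=noisy)
            sub_parents.append("stratify_mobility")

    # P(high) by count of positive subscore parents
    by_count = {0: 0.03, 1: 0.35, 2: 0.85, 3: 0.97}
    n_rows = 2 ** len(sub_parents)
    p_high = np.empty(n_rows)
    for r in range(n_rows):
        k = bin(r).count("1")
        p_high[r] = by_count.get(k, 0.97)
    add(score_name, ("low", "high"), tuple(sub_parents),
        subgroup="risk_tool", table=_binary_cpt(p_high))

    if on("fall_precaution"):
        add("fall_precaution", ("no", "yes"), (score_name,),
            subgroup="intervention", table=_binary_cpt([0.15, 0.70]))
    if on("toileting_assist") and on("elimination_problem"):
        add("toileting_assist", ("no", "yes"), ("elimination_problem",),
            subgroup="intervention", table=_binary_cpt([0.10, 0.60]))

    fall_parents = [
        _FALL_PARENT[c] for c in
        ("physiological", "cognitive", "behavioral", "therapeutic", "mitigating")
        if c in enabled and on(_FALL_PARENT[c])
    ]
    fall_parents.append(score_name)
    betas = np.array([
        config.fall_log_odds.get(
            "risk_tool_score" if p == score_name else p, 0.0
        )
        for p in fall_parents
    ])

    # enumerate the fall-parent joint under the planted net (without the
    # fall node) and solve the logistic intercept for the target hazard
    partial = BayesNet(list(nodes), {n: CPT(n, t) for n, t in cpts.items()},
                       name=f"{config.style}-truth")
    from .inference import joint_distribution  # local: avoid import cycle

    joint = joint_distribution(partial, fall_parents, max_size=2**24).reshape(-1)
    cards = tuple(2 for _ in fall_parents)
    configs = np.stack(
        np.unravel_index(np.arange(joint.size), cards), axis=1
    ).astype(float)
    lin = configs @ betas
    target = config.target_fall_rate / 1000.0

    def gap(b0):
        return float(joint @ special.expit(b0 + lin)) - target

    b0 = optimize.brentq(gap, -40.0, 10.0, xtol=1e-12)
    add("fall", ("no", "yes"), tuple(fall_parents), subgroup="outcome",
        table=_binary_cpt(special.expit(b0 + lin)))

    return BayesNet(list(nodes), {n: CPT(n, t) for n, t in cpts.items()},
                    name=f"{config.style}-truth")


# ---------------------------------------------------------------------------
# cohort containers


@dataclass(frozen=True)
class FallEvent:
    admission_id: int
    day_index: int
    hour: int
    injury_level: str  # none | minor | moderate | major


@dataclass
class AdmissionRecord:
    patient_id: int
    admission_id: int
    admit_day: int
    length_of_stay: int
    static_fields: dict
    daily_observations: dict  # day -> {variable: state}


@dataclass
class SyntheticCohort:
    """Columnar cohort: long-format observations, events, planted truth."""

    static: pd.DataFrame        # admission_id, patient_id, length_of_stay, ...
    observations: pd.DataFrame  # patient_id, admission_id, day, variable, value
    events: pd.DataFrame        # admission_id, day, hour, injury_level
    generator_truth: BayesNet | None = None
    config: GeneratorConfig | None = None

    @property
    def n_admissions(self) -> int:
        return len(self.static)

    @property
    def total_hospital_days(self) -> int:
        return int(self.static["length_of_stay"].sum())

    @property
    def n_falls(self) -> int:
        return len(self.events)

    def fall_rate_per_1000(self) -> float:
        return 1000.0 * self.n_falls / self.total_hospital_days

    def fall_events(self) -> list[FallEvent]:
        return [
            FallEvent(int(r.admission_id), int(r.day), int(r.hour), r.injury_level)
            for r in self.events.itertuples()
        ]

    def iter_admissions(self):
        obs_by_adm = dict(iter(self.observations.groupby("admission_id", sort=False))) \
            if len(self.observations) else {}
        static_cols = [
            c for c in self.static.columns
            if c not in ("admission_id", "patient_id", "admit_day", "length_of_stay")
        ]
        for row in self.static.itertuples():
            daily: dict[int, dict[str, str]] = {}
            sub = obs_by_adm.get(row.admission_id)
            if sub is not None:
                for day, var, val in zip(sub["day"], sub["variable"], sub["value"]):
                    daily.setdefault(int(day), {})[var] = val
            yield AdmissionRecord(
                patient_id=int(row.patient_id),
                admission_id=int(row.admission_id),
                admit_day=int(row.admit_day),
                length_of_stay=int(row.length_of_stay),
                static_fields={c: getattr(row, c) for c in static_cols},
                daily_observations=daily,
            )

    @property
    def admissions(self) -> list[AdmissionRecord]:
        return list(self.iter_admissions())


# ---------------------------------------------------------------------------
# sampling


def _sample_los(rng: np.random.Generator, spec: Mapping, n: int) -> np.ndarray:
    name = spec.get("name", "negative_binomial")
    max_days = int(spec.get("max_days", 120))
    if name == "fixed":
        los = np.full(n, int(spec["mean"]))
    elif name == "poisson":
        los = 1 + rng.poisson(max(float(spec["mean"]) - 1, 0.0), size=n)
    elif name == "negative_binomial":
        mean, sd = float(spec["mean"]), float(spec["sd"])
        mu = mean - 1.0
        var = sd ** 2
        if var <= mu:
            los = 1 + rng.poisson(mu, size=n)
        else:
            r = mu * mu / (var - mu)
            p = r / (r + mu)
            los = 1 + rng.negative_binomial(r, p, size=n)
    else:
        raise ConfigurationError(f"unknown length-of-stay distribution {name!r}")
    return np.clip(los, 1, max_days).astype(np.int64)


def sample_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw one cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = ground_truth_network(config)
    A = config.n_admissions

    empty_obs = pd.DataFrame(
        columns=["patient_id", "admission_id", "day", "variable", "value"]
    )
    empty_ev = pd.DataFrame(columns=["admission_id", "day", "hour", "injury_level"])
    if A == 0:
        static = pd.DataFrame(
            columns=["admission_id", "patient_id", "admit_day", "length_of_stay"]
        )
        return SyntheticCohort(static, empty_obs, empty_ev, truth, config)

    los = _sample_los(rng, config.length_of_stay_distribution, A)
    L = int(los.max())
    valid = np.arange(L)[None, :] < los[:, None]

    admission_id = np.arange(A, dtype=np.int64)
    patient_id = admission_id.copy()
    readmit = rng.random(A) < config.readmission_rate
    readmit[0] = False
    for i in np.flatnonzero(readmit):
        patient_id[i] = patient_id[rng.integers(0, i)]

    # static nodes: roots sampled once per admission
    static_nodes = ["sex", "age_bin", "diagnosis_group", "secondary_dx",
                    "kpcs_group"]
    if "fall_history" in truth.nodes:
        static_nodes.append("fall_history")
    codes2d: dict[str, np.ndarray] = {}
    for name in static_nodes:
        p = truth.cpts[name].table[0]
        codes2d[name] = rng.choice(len(p), size=A, p=p)

    def fresh_2d(name: str) -> np.ndarray:
        """(A, L) draws from the node's CPT rows given current parents."""
        spec = truth.nodes[name]
        if spec.parents:
            cards = truth.parent_cards(name)
            parent_vals = []
            for pnode in spec.parents:
                v = codes2d[pnode]
                parent_vals.append(
                    np.broadcast_to(v[:, None], (A, L)) if v.ndim == 1 else v
                )
            rows = np.ravel_multi_index(
                tuple(v.reshape(-1) for v in parent_vals), cards
            ).reshape(A, L)
        else:
            rows = np.zeros((A, L), dtype=np.intp)
        cum = np.cumsum(truth.cpts[name].table, axis=1)
        cum[:, -1] = 1.0
        u = rng.random((A, L))
        return (u[:, :, None] > cum[rows]).sum(axis=2).astype(np.int8)

    factor_daily = [
        v for v in ("mobility_impairment", "cognitive_impairment",
                    "elimination_problem", "sedative_use")
        if v in truth.nodes
    ]
    for name in factor_daily:
        fresh = fresh_2d(name)
        keep = rng.random((A, L)) < config.persistence
        vals = fresh.copy()
        for d in range(1, L):
            vals[:, d] = np.where(keep[:, d], vals[:, d - 1], fresh[:, d])
        codes2d[name] = vals

    downstream = [
        v for v in truth.topological_order()
        if v not in codes2d and v != "fall"
    ]
    for name in downstream:
        codes2d[name] = fresh_2d(name)

    # per-day fall hazard from the planted fall CPT
    fall_spec = truth.nodes["fall"]
    cards = truth.parent_cards("fall")
    parent_vals = []
    for pnode in fall_spec.parents:
        v = codes2d[pnode]
        parent_vals.append(
            np.broadcast_to(v[:, None], (A, L)) if v.ndim == 1 else v
        )
    rows = np.ravel_multi_index(
        tuple(v.reshape(-1) for v in parent_vals), cards
    ).reshape(A, L)
    p_fall = truth.cpts["fall"].table[rows, 1]
    fall_mask = (rng.random((A, L)) < p_fall) & valid

    ev_adm, ev_day = np.nonzero(fall_mask)
    n_ev = len(ev_adm)
    ev_hour = rng.integers(0, 24, size=n_ev)
    injured = rng.random(n_ev) < config.injurious_fraction
    minor = rng.random(n_ev) < config.minor_fraction
    level = np.where(injured, np.where(minor, "minor", "moderate"), "none")
    events = pd.DataFrame({
        "admission_id": admission_id[ev_adm],
        "day": ev_day.astype(np.int64),
        "hour": ev_hour.astype(np.int64),
        "injury_level": level,
    })

    # static table
    static = pd.DataFrame({
        "admission_id": admission_id,
        "patient_id": patient_id,
        "admit_day": np.zeros(A, dtype=np.int64),
        "length_of_stay": los,
    })
    for name in static_nodes:
        static[name] = np.asarray(truth.nodes[name].states, object)[codes2d[name]]

    # long-format observations: statics at day 0, dailies every stay day
    frames = []
    a_idx, d_idx = np.nonzero(valid)
    for name in static_nodes:
        frames.append(pd.DataFrame({
            "patient_id": patient_id,
            "admission_id": admission_id,
            "day": np.zeros(A, dtype=np.int64),
            "variable": name,
            "value": np.asarray(truth.nodes[name].states, object)[codes2d[name]],
        }))
    for name in factor_daily + downstream:
        frames.append(pd.DataFrame({
            "patient_id": patient_id[a_idx],
            "admission_id": admission_id[a_idx],
            "day": d_idx.astype(np.int64),
            "variable": name,
            "value": np.asarray(truth.nodes[name].states, object)[
                codes2d[name][a_idx, d_idx]
            ],
        }))
    observations = pd.concat(frames, ignore_index=True)
    observations.sort_values(
        ["admission_id", "day", "variable"], inplace=True, kind="stable",
        ignore_index=True,
    )
    return SyntheticCohort(static, observations, events, truth, config)


def mask_missing(
    cohort: SyntheticCohort,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Apply per-variable daily missingness to the observations.

    MCAR mode drops each targeted variable-day cell independently with its
    configured probability. Policy mode emulates reassessment schedules for
    the risk-tool score: scores are retained only every 2-3 days (high
    scores) or every 7 days (low scores), dropped otherwise. Fall events
    and non-targeted variables are untouched.
    """
    config = config or cohort.config
    if config is None:
        raise ConfigurationError("no generator config available for masking")
    for var, rate in config.missingness_rates.items():
        if not 0 <= rate <= 1:
            raise ConfigurationError(
                f"missingness rate for {var!r} must be in [0,1], got {rate}"
            )
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    obs = cohort.observations
    keep = np.ones(len(obs), dtype=bool)
    if config.missingness_mode == "mcar":
        for var, rate in config.missingness_rates.items():
            target = (obs["variable"] == var).to_numpy()
            drop = rng.random(len(obs)) < rate
            keep &= ~(target & drop)
    elif config.missingness_mode == "policy":
        score = risk_tool_node(config.style)
        target = (obs["variable"] == score).to_numpy()
        high = (obs["value"] == "high").to_numpy()
        day = obs["day"].to_numpy()
        interval = rng.integers(2, 4, size=len(obs))
        due = np.where(high, day % interval == 0, day % 7 == 0)
        keep &= ~target | due
    else:
        raise ConfigurationError(
            f"unknown missingness mode {config.missingness_mode!r}"
        )
    return SyntheticCohort(
        static=cohort.static,
        observations=obs.loc[keep].reset_index(drop=True),
        events=cohort.events,
        generator_truth=cohort.generator_truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# file interface


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "observations": out / "observations.csv",
        "events": out / "events.csv",
        "static": out / "static.csv",
        "config": out / "config.yaml",
    }
    cohort.observations.to_csv(paths["observations"], index=False)
    cohort.events.to_csv(paths["events"], index=False)
    cohort.static.to_csv(paths["static"], index=False)
    if cohort.config is not None:
        paths["config"].write_text(yaml.safe_dump(cohort.config.to_dict()))
    return paths


def read_cohort(in_dir: str | Path) -> SyntheticCohort:
    d = Path(in_dir)
    config = None
    if (d / "config.yaml").exists():
        raw = yaml.safe_load((d / "config.yaml").read_text())
        raw["daily_variable_specs"] = {
            k: DailyVariableSpec(**v)
            for k, v in raw.get("daily_variable_specs", {}).items()
        }
        config = GeneratorConfig(**raw)
    return SyntheticCohort(
        static=pd.read_csv(d / "static.csv"),
        observations=pd.read_csv(d / "observations.csv"),
        events=pd.read_csv(d / "events.csv") if (d / "events.csv").exists()
        else pd.DataFrame(columns=["admission_id", "day", "hour", "injury_level"]),
        config=config,
    )
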