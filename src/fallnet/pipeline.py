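"""End-to-end orchestration: simulate -> window -> fit -> predict ->
evaluate -> sensitivity -> cohort summary, from one seeded configuration.

Per-stage seeds derive from the master seed via the same affine counter
scheme as cross-validation folds (:func:`fallnet.windowing.fold_seed` with
reserved stage counters), so any stage can be re-run in isolation and
reproduce its output exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import synthetic
from .bayesnet import BayesNet, load_schema, bundled_schema_path
from .cohort_stats import cohort_summary
from .evaluation import cross_validate
from .learning import DirichletPrior, fit_cpts, fit_em
from .sensitivity import analyze
from .windowing import build_all_windows, fold_seed

__all__ = ["ExperimentConfig", "ReportBundle", "run_experiment",
           "cross_site_validate"]

log = logging.getLogger("fallnet")

# reserved stage counters for seed derivation
_STAGE = {"simulate": 900001, "mask": 900002, "folds": 900003}


@dataclass
class ExperimentConfig:
    """One site's full experiment: generator, schema, prior, evaluation."""

    site: str = "development"  # generator + schema style
    n_admissions: int = 2000
    seed: int = 0
    n0: float = 1.0
    folds: int = 10
    train_fraction: float = 0.9
    threshold: float = 0.5
    cv_mode: str = "subsample"  # subsample | kfold
    keep_post_fall: bool = False
    apply_missingness: bool = True
    schema_path: str | None = None  # defaults to the bundled style schema
    generator_overrides: dict = field(default_factory=dict)
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown experiment config fields: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.schema_path is not None and not Path(self.schema_path).exists():
            raise FileNotFoundError(
                f"schema file not found: {self.schema_path}"
            )
        self.generator_config()  # raises on bad overrides

    def generator_config(self) -> synthetic.GeneratorConfig:
        maker = (
            synthetic.development_config
            if self.site == "development"
            else synthetic.validation_config
        )
        cfg = maker(
            n_admissions=self.n_admissions,
            seed=fold_seed(self.seed, _STAGE["simulate"]),
        )
        for k, v in self.generator_overrides.items():
            if not hasattr(cfg, k):
                raise synthetic.ConfigurationError(
                    f"unknown generator override {k!r}"
                )
            setattr(cfg, k, v)
        cfg.validate()
        return cfg

    def schema(self) -> BayesNet:
        path = self.schema_path or bundled_schema_path(self.site)
        return load_schema(path)

    def to_dict(self) -> dict:
        return {
            "site": self.site,
            "n_admissions": self.n_admissions,
            "seed": self.seed,
            "n0": self.n0,
            "folds": self.folds,
            "train_fraction": self.train_fraction,
            "threshold": self.threshold,
            "cv_mode": self.cv_mode,
            "keep_post_fall": self.keep_post_fall,
            "apply_missingness": self.apply_missingness,
            "schema_path": self.schema_path,
            "generator_overrides": self.generator_overrides,
        }

    def provenance_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Machine-readable record of one experiment run."""

    config: dict
    provenance: dict
    cohort_summary: dict | None = None
    evaluation: dict | None = None
    sensitivity: dict | None = None
    model_summary: dict | None = None
    partial: bool = False
    failed_stage: str | None = None

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "provenance": self.provenance,
            "cohort_summary": self.cohort_summary,
            "evaluation": self.evaluation,
            "sensitivity": self.sensitivity,
            "model_summary": self.model_summary,
            "partial": self.partial,
            "failed_stage": self.failed_stage,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _stage(bundle: ReportBundle, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage=%s ok wall=%.2fs", name, dt)
                return False
            bundle.partial = True
            bundle.failed_stage = name
            bundle.provenance["error"] = f"{exc_type.__name__}: {exc}"
            log.error("stage=%s failed: %s", name, exc)
            return True  # suppress: caller receives the partial bundle

    return _Ctx()


def run_experiment(config: ExperimentConfig) -> ReportBundle:
    """Execute the full pipeline for one site configuration.

    All stage outputs are deterministic functions of the config; the bundle
    carries a provenance hash of the config so any change is visible.
    """
    config.validate()
    bundle = ReportBundle(
        config=config.to_dict(),
        provenance={
            "config_hash": config.provenance_hash(),
            "seed": config.seed,
        },
    )

    with _stage(bundle, "simulate"):
        gen = config.generator_config()
        cohort = synthetic.sample_cohort(gen)
        if config.apply_missingness and gen.missingness_rates:
            cohort = synthetic.mask_missing(
                cohort, seed=fold_seed(config.seed, _STAGE["mask"])
            )
        bundle.cohort_summary = cohort_summary(cohort)
        log.info(
            "stage=simulate admissions=%d days=%d falls=%d",
            cohort.n_admissions, cohort.total_hospital_days, cohort.n_falls,
        )
    if bundle.partial:
        return bundle

    with _stage(bundle, "prepare"):
        windows = build_all_windows(cohort, keep_post_fall=config.keep_post_fall)
        n_pos = sum(w.label for w in windows)
        bundle.cohort_summary["n_windows"] = len(windows)
        bundle.cohort_summary["n_positive_windows"] = n_pos
        log.info("stage=prepare windows=%d positives=%d", len(windows), n_pos)
    if bundle.partial:
        return bundle

    schema = config.schema()
    prior = DirichletPrior(n0=config.n0)

    with _stage(bundle, "evaluate"):
        report = cross_validate(
            schema, windows, prior,
            k=config.folds,
            seed=fold_seed(config.seed, _STAGE["folds"]),
            train_fraction=config.train_fraction,
            threshold=config.threshold,
            mode=config.cv_mode,
        )
        bundle.evaluation = report.to_dict()
    if bundle.partial:
        return bundle

    with _stage(bundle, "sensitivity"):
        complete = all(
            n in w.evidence for w in windows for n in schema.nodes if n != "fall"
        )
        if complete:
            full_net = fit_cpts(schema, windows, prior)
        else:
            full_net = fit_em(schema, windows, prior).net
        bundle.model_summary = full_net.summary()
        sens = analyze(full_net, target="fall", measure="entropy_reduction")
        bundle.sensitivity = sens.to_dict()
    if bundle.partial:
        return bundle

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.write(out / "report.json")
        full_net.to_json(out / "model.json")
    return bundle


class SchemaMismatchError(ValueError):
    pass


def cross_site_validate(
    config_dev: ExperimentConfig, config_val: ExperimentConfig
) -> dict:
    """Run two sites independently under a shared concept core and pair the
    reports (side-by-side metrics and sensitivity subgroup totals).

    The two schemas may differ in their risk-tool nodes and arcs but must
    agree on the outcome node and the non-risk-tool concept set.
    """
    s_dev, s_val = config_dev.schema(), config_val.schema()

    def core(net: BayesNet) -> set[str]:
        return {
            n for n, s in net.nodes.items() if s.subgroup != "risk_tool"
        }

    diff = core(s_dev) ^ core(s_val)
    if diff:
        raise SchemaMismatchError(
            f"site schemas disagree on concept nodes: {sorted(diff)}"
        )
    dev = run_experiment(config_dev)
    val = run_experiment(config_val)
    paired = {
        "site1": dev.to_dict(),
        "site2": val.to_dict(),
        "comparison": {},
    }
    if dev.evaluation and val.evaluation:
        paired["comparison"]["metrics"] = {
            m: {"site1": dev.evaluation[m], "site2": val.evaluation[m]}
            for m in ("error_rate", "log_loss", "spherical_payoff", "auc")
        }
    if dev.sensitivity and val.sensitivity:
        groups = set(dev.sensitivity["per_subgroup"]) | set(
            val.sensitivity["per_subgroup"]
        )
        paired["comparison"]["sensitivity_subgroups"] = {
            g: {
                "site1": dev.sensitivity["per_subgroup"].get(g, 0.0),
                "site2": val.sensitivity["per_subgroup"].get(g, 0.0),
            }
            for g in sorted(groups)
        }
    return paired
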