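"""End-to-end orchestration: configuration, provenance, and the
simulate -> select instruments -> MR suite -> sensitivity -> mediation
chain, with every intermediate persisted as a delimited table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError
from .instruments import select_instruments
from .mediation import MediationScreen, screen_mediators
from .mr import MRModel, MRReport, PRIMARY_METHODS
from .sensitivity import SensitivityReport, sensitivity_suite
from .simulate import SimulationConfig, simulate_chain, study_pairs
from .sumstats import LDInfo, read_sumstats, write_sumstats

_STOCHASTIC = {"weighted_median", "simple_mode", "weighted_mode"}


@dataclass
class Thresholds:
    exposure_p: float = 5e-8
    mediator_p: float = 5e-6
    r2_max: float = 0.001
    window_kb: int = 10_000
    min_f: float = 10.0
    outcome_assoc_p: float = 5e-8

    def validate(self) -> None:
        for name in ("exposure_p", "mediator_p", "outcome_assoc_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0,1), got {v}")
        if not 0.0 <= self.r2_max <= 1.0:
            raise ConfigurationError("r2_max must be in [0,1]")
        if self.window_kb <= 0 or self.min_f < 0:
            raise ConfigurationError("window_kb must be positive and min_f non-negative")


@dataclass
class TableSource:
    """A summary-statistic table on disk plus how to read it."""

    path: str
    trait_id: str
    trait_type: str = "continuous"
    column_map: Optional[dict | str] = None

    def load(self):
        return read_sumstats(
            self.path, column_map=self.column_map,
            trait_id=self.trait_id, trait_type=self.trait_type,
        )


@dataclass
class RunConfig:
    output_dir: str = "mrmediate_out"
    seed: Optional[int] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    methods: tuple = PRIMARY_METHODS
    include_robust: bool = False
    simulation: Optional[SimulationConfig] = None
    exposure: Optional[TableSource] = None
    outcome: Optional[TableSource] = None
    mediators: list = field(default_factory=list)
    ld_path: Optional[str] = None

    def validate(self) -> None:
        self.thresholds.validate()
        if any(m in _STOCHASTIC for m in self.methods) and self.seed is None:
            raise ConfigurationError(
                "a seed is required when bootstrap-based methods are requested"
            )
        if self.simulation is None and (self.exposure is None or self.outcome is None):
            raise ConfigurationError(
                "either a simulation block or exposure+outcome tables are required"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("output_dir", "seed", "include_robust", "ld_path"):
            if key in raw:
                kwargs[key] = raw[key]
        if "methods" in raw:
            kwargs["methods"] = tuple(raw["methods"])
        if "thresholds" in raw:
            kwargs["thresholds"] = Thresholds(**raw["thresholds"])
        if "simulation" in raw:
            sim = dict(raw["simulation"])
            if "seed" not in sim and "seed" in raw:
                sim["seed"] = raw["seed"]
            pl = sim.pop("pleiotropy", None)
            cfg = SimulationConfig(**sim)
            if pl:
                from .simulate import PleiotropyConfig
                cfg.pleiotropy = PleiotropyConfig(**pl)
            kwargs["simulation"] = cfg
        for key in ("exposure", "outcome"):
            if key in raw:
                kwargs[key] = TableSource(**raw[key])
        if "mediators" in raw:
            kwargs["mediators"] = [TableSource(**m) for m in raw["mediators"]]
        return cls(**kwargs)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(outdir: Path, config: RunConfig, inputs: dict) -> None:
    manifest = {
        "package": "mrmediate",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {**config.thresholds.__dict__},
        "methods": list(config.methods),
        "include_robust": config.include_robust,
        "inputs": inputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _load_leg(config: RunConfig, outdir: Path):
    """Resolve inputs: simulate (persisting the generated tables) or load."""
    inputs: dict = {}
    if config.simulation is not None:
        study = simulate_chain(config.simulation)
        for name, sset in (
            ("exposure", study.exposure_gwas),
            ("mediator", study.mediator_gwas),
            ("outcome", study.outcome_gwas),
        ):
            p = outdir / f"simulated_{name}.tsv"
            write_sumstats(sset, p)
            inputs[name] = {"path": str(p), "sha256": _digest(p)}
        truth = {
            k: v for k, v in study.truth.items()
            if k not in ("true_gamma", "true_delta")
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
        return study.exposure_gwas, study.outcome_gwas, [study.mediator_gwas], inputs
    exposure = config.exposure.load()
    outcome = config.outcome.load()
    mediators = [m.load() for m in config.mediators]
    for src in [config.exposure, config.outcome, *config.mediators]:
        inputs[src.trait_id] = {"path": src.path, "sha256": _digest(Path(src.path))}
    return exposure, outcome, mediators, inputs


@dataclass
class MRRunResult:
    report: MRReport
    sensitivity: SensitivityReport
    pairs: object
    output_dir: Path


def run_mr(config: RunConfig) -> MRRunResult:
    """Exposure -> outcome MR with sensitivity analyses, persisted.

    Writes: selected-instrument table, exclusion log, per-method estimate
    table, sensitivity report, leave-one-out table, and a run manifest.
    Reruns with an identical config are bit-identical.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    exposure, outcome, _, inputs = _load_leg(config, outdir)
    ld = LDInfo.from_table(config.ld_path) if config.ld_path else None
    t = config.thresholds
    pairs = select_instruments(
        exposure, outcome,
        pvalue_threshold=t.exposure_p, ld=ld, r2_max=t.r2_max,
        window_kb=t.window_kb, outcome_assoc_p=t.outcome_assoc_p, min_f=t.min_f,
    )
    pairs.df.to_csv(outdir / "instruments.tsv", sep="\t", index=False)
    pairs.write_exclusion_log(outdir / "exclusions.tsv")
    model = MRModel(pairs)
    report = model.fit_all(
        seed=config.seed, methods=config.methods, include_robust=config.include_robust
    )
    report.to_frame().to_csv(outdir / "mr_estimates.tsv", sep="\t", index=False)
    sens = sensitivity_suite(pairs, seed=config.seed)
    (outdir / "sensitivity.txt").write_text(sens.to_text() + "\n")
    sens.loo.to_csv(outdir / "leave_one_out.tsv", sep="\t", index=False)
    _write_manifest(outdir, config, inputs)
    return MRRunResult(report=report, sensitivity=sens, pairs=pairs, output_dir=outdir)


def run_mediation(config: RunConfig) -> MediationScreen:
    """Two-step mediation over the configured mediators, persisted.

    For each candidate mediator the exposure->mediator and
    mediator->outcome legs are instrumented with the pipeline's thresholds
    (the relaxed mediator p-value threshold instruments the mediator leg),
    screened by significance and direction consistency, and decomposed
    with delta-method inference. The screening funnel and mediation table
    are written alongside the MR outputs.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    exposure, outcome, mediators, inputs = _load_leg(config, outdir)
    if not mediators:
        raise ConfigurationError("run_mediation requires at least one mediator")
    ld = LDInfo.from_table(config.ld_path) if config.ld_path else None
    t = config.thresholds
    total = MRModel(
        select_instruments(
            exposure, outcome, pvalue_threshold=t.exposure_p, ld=ld,
            r2_max=t.r2_max, window_kb=t.window_kb,
            outcome_assoc_p=t.outcome_assoc_p, min_f=t.min_f,
        )
    ).fit("ivw")

    exp_to_med, med_to_out = [], []
    for i, med in enumerate(mediators):
        if med.trait_id == exposure.trait_id:
            continue  # degenerate candidate: identical to the exposure
        sub_seed = None if config.seed is None else config.seed + 7919 * (i + 1)
        em_pairs = select_instruments(
            exposure, med, pvalue_threshold=t.exposure_p, ld=ld,
            r2_max=t.r2_max, window_kb=t.window_kb,
            outcome_assoc_p=1e-300, min_f=t.min_f,
        )
        mo_pairs = select_instruments(
            med, outcome, pvalue_threshold=t.mediator_p, ld=ld,
            r2_max=t.r2_max, window_kb=t.window_kb,
            outcome_assoc_p=t.outcome_assoc_p, min_f=t.min_f,
        )
        exp_to_med.append(MRModel(em_pairs).fit_all(seed=sub_seed, methods=config.methods))
        med_to_out.append(MRModel(mo_pairs).fit_all(seed=sub_seed, methods=config.methods))

    screen = screen_mediators(exp_to_med, med_to_out, total)
    screen.to_frame().to_csv(outdir / "mediation.tsv", sep="\t", index=False)
    screen.exclusions.to_csv(outdir / "mediation_exclusions.tsv", sep="\t", index=False)
    (outdir / "mediation_funnel.json").write_text(
        json.dumps(screen.funnel, indent=2) + "\n"
    )
    _write_manifest(outdir, config, inputs)
    return screen
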