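"""Synthetic GWAS summary statistics for an exposure -> mediator -> outcome
causal chain with known ground truth.

The generator works entirely at the summary level: true per-variant
effects are drawn, then observed effects are the truth plus sampling noise
with standard errors set by the GWAS sample sizes (unit-variance traits,
standardized genotypes: ``se = 1/sqrt(n)`` for continuous traits and
``se = 1/sqrt(n * cf * (1-cf))`` for a binary outcome with case fraction
``cf``, whose effects are emitted directly on the log-odds scale under a
rare-disease approximation).

Structure of the chain, for exposure instruments g_j with true effects
gamma_j and mediator instruments d_k with true effects delta_k:

- effect of g_j on X: gamma_j
- effect of g_j on M: beta1 * gamma_j
- effect of g_j on Y: (beta_direct + beta1*beta2) * gamma_j + alpha_j
- effect of d_k on M: delta_k        (d_k has no effect on X)
- effect of d_k on Y: beta2 * delta_k

``alpha_j`` is a direct (horizontally pleiotropic) effect on the outcome
carried by a configurable fraction of exposure instruments: ``balanced``
draws are zero-mean, ``directional`` draws have a nonzero mean, and
``inside_violating`` draws are correlated with instrument strength
gamma_j. Instruments are simulated unlinked, on chromosomes/positions
spaced beyond the clumping window.

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawning, so sub-streams are independent and a given seed reproduces the
study bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .sumstats import SummaryStatSet

# non-palindromic allele pairs only, so simulated variants survive harmonization
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

PLEIOTROPY_MODES = ("balanced", "directional", "inside_violating")


@dataclass
class PleiotropyConfig:
    """Horizontal pleiotropy acting directly on the outcome path."""

    proportion_invalid: float = 0.0
    mode: str = "balanced"
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion_invalid <= 1.0:
            raise ConfigurationError("proportion_invalid must be in [0,1]")
        if self.mode not in PLEIOTROPY_MODES:
            raise ConfigurationError(f"pleiotropy mode must be one of {PLEIOTROPY_MODES}")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic chain.

    Defaults encode the real study's scale: a protein GWAS of n=5440, an
    immune-phenotype GWAS of n=3757, and a binary liver-disease outcome
    GWAS of n=500,348 with 3504 cases; a total causal effect of 0.145
    (log-odds per unit exposure) split into a direct effect of 0.128 and
    an indirect effect 0.2 x 0.085 = 0.017 (11.7% mediated); and a target
    mean instrument F of 100.
    """

    j_exp: int = 30
    j_med: int = 30
    n_exp: int = 5440
    n_med: int = 3757
    n_out: int = 500_348
    beta_direct: float = 0.128
    beta1: float = 0.2
    beta2: float = 0.085
    instrument_strength: float = 100.0
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    outcome_binary: bool = True
    case_fraction: float = 3504 / 500_348
    seed: int = 0

    @property
    def beta_total(self) -> float:
        return self.beta_direct + self.beta1 * self.beta2

    def validate(self) -> None:
        for name in ("j_exp", "j_med", "n_exp", "n_med", "n_out"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.instrument_strength <= 1.0:
            raise ConfigurationError(
                "instrument_strength must exceed 1 (expected F of a null variant)"
            )
        if self.outcome_binary and not 0.0 < self.case_fraction < 1.0:
            raise ConfigurationError("case_fraction must be in (0,1)")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pl = raw.pop("pleiotropy", None)
        cfg = cls(**raw)
        if pl:
            cfg = replace(cfg, pleiotropy=PleiotropyConfig(**pl))
        return cfg

    def to_yaml(self, path) -> None:
        d = {**self.__dict__}
        d["pleiotropy"] = {**self.pleiotropy.__dict__}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class SimulatedStudy:
    """Generated summary-statistic triplet plus the ground truth."""

    exposure_gwas: SummaryStatSet
    mediator_gwas: SummaryStatSet
    outcome_gwas: SummaryStatSet
    truth: dict
    config: SimulationConfig

    @property
    def exposure_instrument_ids(self) -> list[str]:
        return list(self.truth["exposure_instruments"])

    @property
    def mediator_instrument_ids(self) -> list[str]:
        return list(self.truth["mediator_instruments"])


def _pvalue(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    z = np.abs(beta / se)
    return np.clip(2 * stats.norm.sf(z), np.finfo(float).tiny, 1.0)


def _variant_frame(ids, chroms, poss, eas, oas, beta, se, eaf, n) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": chroms,
            "pos": poss,
            "effect_allele": eas,
            "other_allele": oas,
            "beta": beta,
            "se": se,
            "pvalue": _pvalue(beta, np.asarray(se, dtype=float)),
            "eaf": eaf,
            "n": float(n),
        }
    )


def simulate_chain(config: SimulationConfig) -> SimulatedStudy:
    """Generate the three summary-statistic sets of the causal chain."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_exp, rng_med, rng_pleio, rng_noise, rng_meta = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    se_x = 1.0 / np.sqrt(config.n_exp)
    se_m = 1.0 / np.sqrt(config.n_med)
    if config.outcome_binary:
        cf = config.case_fraction
        se_y = 1.0 / np.sqrt(config.n_out * cf * (1 - cf))
    else:
        se_y = 1.0 / np.sqrt(config.n_out)

    j_e, j_m = config.j_exp, config.j_med
    n_snps = j_e + j_m

    # true instrument effects scaled so E[gammahat^2/se^2] = instrument_strength
    var_gamma = (config.instrument_strength - 1.0) * se_x**2
    var_delta = (config.instrument_strength - 1.0) * se_m**2
    gamma = rng_exp.normal(0.0, np.sqrt(var_gamma), size=j_e)
    delta = rng_med.normal(0.0, np.sqrt(var_delta), size=j_m)

    # pleiotropy: direct outcome effects on a subset of exposure instruments
    pl = config.pleiotropy
    n_invalid = int(round(pl.proportion_invalid * j_e))
    invalid_idx = rng_pleio.choice(j_e, size=n_invalid, replace=False) if n_invalid else np.array([], dtype=int)
    alpha = np.zeros(j_e)
    if n_invalid:
        if pl.mode == "balanced":
            alpha[invalid_idx] = rng_pleio.normal(0.0, pl.alpha_sd, size=n_invalid)
        elif pl.mode == "directional":
            alpha[invalid_idx] = rng_pleio.normal(pl.alpha_mean, pl.alpha_sd, size=n_invalid)
        else:  # inside_violating: alpha tracks instrument strength
            scale = pl.alpha_mean / np.sqrt(var_gamma) if var_gamma > 0 else 0.0
            alpha[invalid_idx] = scale * gamma[invalid_idx] + rng_pleio.normal(
                0.0, pl.alpha_sd, size=n_invalid
            )

    beta_total = config.beta_total
    # true effects on each trait, exposure instruments then mediator instruments
    true_x = np.concatenate([gamma, np.zeros(j_m)])
    true_m = np.concatenate([config.beta1 * gamma, delta])
    true_y = np.concatenate([beta_total * gamma + alpha, config.beta2 * delta])

    obs_x = true_x + rng_noise.normal(0.0, se_x, size=n_snps)
    obs_m = true_m + rng_noise.normal(0.0, se_m, size=n_snps)
    obs_y = true_y + rng_noise.normal(0.0, se_y, size=n_snps)

    ids = [f"rs{100000 + i}" for i in range(n_snps)]
    chroms = [str(i % 22 + 1) for i in range(n_snps)]
    poss = [1_000_000 + (i // 22) * 20_000_000 for i in range(n_snps)]  # > clump window apart
    pair_idx = rng_meta.integers(0, len(_ALLELE_PAIRS), size=n_snps)
    eas = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oas = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    eaf = rng_meta.uniform(0.05, 0.95, size=n_snps)

    exposure = SummaryStatSet(
        _variant_frame(ids, chroms, poss, eas, oas, obs_x, se_x, eaf, config.n_exp),
        trait_id="exposure", trait_type="continuous", provenance="simulate_chain",
        validate=False,
    )
    mediator = SummaryStatSet(
        _variant_frame(ids, chroms, poss, eas, oas, obs_m, se_m, eaf, config.n_med),
        trait_id="mediator", trait_type="continuous", provenance="simulate_chain",
        validate=False,
    )
    outcome = SummaryStatSet(
        _variant_frame(ids, chroms, poss, eas, oas, obs_y, se_y, eaf, config.n_out),
        trait_id="outcome",
        trait_type="binary" if config.outcome_binary else "continuous",
        provenance="simulate_chain", validate=False,
    )
    truth = {
        "beta_total": beta_total,
        "beta_direct": config.beta_direct,
        "beta1": config.beta1,
        "beta2": config.beta2,
        "proportion_mediated_pct": 100.0 * config.beta1 * config.beta2 / beta_total
        if beta_total != 0 else np.nan,
        "invalid_snp_ids": [ids[i] for i in sorted(invalid_idx)],
        "exposure_instruments": ids[:j_e],
        "mediator_instruments": ids[j_e:],
        "true_gamma": gamma,
        "true_delta": delta,
        "se_exp": se_x, "se_med": se_m, "se_out": se_y,
    }
    return SimulatedStudy(exposure, mediator, outcome, truth, config)


def inject_outlier(study: SimulatedStudy, snp_id: str, shift_in_ses: float) -> SimulatedStudy:
    """Return a copy with one variant's outcome effect shifted by
    ``shift_in_ses`` times its standard error (a gross pleiotropic
    outlier); the truth record's invalid set is updated."""
    rec = study.outcome_gwas.records
    if snp_id not in set(rec["snp_id"]):
        raise KeyError(f"unknown snp_id {snp_id!r}")
    rec = rec.copy()
    m = rec["snp_id"] == snp_id
    rec.loc[m, "beta"] = rec.loc[m, "beta"] + shift_in_ses * rec.loc[m, "se"]
    rec.loc[m, "pvalue"] = _pvalue(
        rec.loc[m, "beta"].to_numpy(), rec.loc[m, "se"].to_numpy()
    )
    outcome = SummaryStatSet(
        rec, study.outcome_gwas.trait_id, study.outcome_gwas.trait_type,
        study.outcome_gwas.provenance, validate=False,
    )
    truth = dict(study.truth)
    invalid = list(truth["invalid_snp_ids"])
    if shift_in_ses != 0 and snp_id not in invalid:
        invalid = sorted(invalid + [snp_id])
    truth["invalid_snp_ids"] = invalid
    return SimulatedStudy(
        study.exposure_gwas, study.mediator_gwas, outcome, truth, study.config
    )


def study_pairs(study: SimulatedStudy, direction: str = "exposure_outcome"):
    """Shortcut used by tests and the acceptance script: harmonized-pairs
    arrays for one leg of the chain, restricted to that leg's instruments,
    bypassing the selection pipeline (the simulated variants are already
    aligned and unlinked)."""
    from .instruments import HarmonizedPairs

    exp_ids = set(study.exposure_instrument_ids)
    med_ids = set(study.mediator_instrument_ids)
    legs = {
        "exposure_outcome": (study.exposure_gwas, study.outcome_gwas, exp_ids),
        "exposure_mediator": (study.exposure_gwas, study.mediator_gwas, exp_ids),
        "mediator_outcome": (study.mediator_gwas, study.outcome_gwas, med_ids),
    }
    try:
        src, dst, keep = legs[direction]
    except KeyError:
        raise ValueError(f"direction must be one of {sorted(legs)}") from None
    s = src.records[src.records["snp_id"].isin(keep)]
    d = dst.records[dst.records["snp_id"].isin(keep)]
    merged = s.merge(d, on="snp_id", suffixes=("_exp", "_out"))
    return HarmonizedPairs.from_arrays(
        merged["beta_exp"], merged["se_exp"], merged["beta_out"], merged["se_out"],
        snp_ids=merged["snp_id"],
        exposure_id=src.trait_id, outcome_id=dst.trait_id,
        outcome_binary=dst.trait_type == "binary",
    )
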