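"""Instrumental-variable selection for two-sample MR.

Implements the four-step selection pipeline used throughout the package:

1. genome-wide significance filter (strict ``p < threshold``);
2. greedy LD clumping (rank by p-value, prune neighbours with
   r-squared at or above the cutoff inside a distance window);
3. harmonization of exposure instruments against the outcome table —
   allele alignment with sign flips and strand complements, unconditional
   removal of palindromic (A/T, C/G) variants, and exclusion of variants
   already associated with the outcome;
4. weak-instrument removal by the per-variant F-statistic
   ``F = beta^2 / se^2`` with the conventional cutoff of 10.

Every drop at every stage is recorded in an exclusion log so that the
union of survivors and exclusions always equals the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyInstrumentsError
from .sumstats import LDInfo, SummaryStatSet

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PAIR_COLUMNS = [
    "snp_id",
    "beta_exp",
    "se_exp",
    "beta_out",
    "se_out",
    "pval_exp",
    "pval_out",
    "f_stat",
    "flipped",
]


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G pairs are strand-ambiguous."""
    return COMPLEMENT.get(a1) == a2


@dataclass
class HarmonizedPairs:
    """Aligned exposure/outcome effects per instrument — the substrate of
    every MR estimator.

    ``df`` has one row per surviving instrument with columns
    :data:`PAIR_COLUMNS`; ``exclusions`` records every variant dropped on
    the way (columns: snp_id, stage, reason).
    """

    df: pd.DataFrame
    exposure_id: str = "exposure"
    outcome_id: str = "outcome"
    outcome_binary: bool = False
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "stage", "reason"])
    )

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        if len(self.df):
            if (self.df["se_exp"] <= 0).any() or (self.df["se_out"] <= 0).any():
                raise ConfigurationError("standard errors must be positive")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df["snp_id"])

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        d = self.df
        return (
            d["beta_exp"].to_numpy(float),
            d["se_exp"].to_numpy(float),
            d["beta_out"].to_numpy(float),
            d["se_out"].to_numpy(float),
        )

    def subset(self, mask_or_ids) -> "HarmonizedPairs":
        if isinstance(mask_or_ids, (list, set, tuple, pd.Index)):
            mask = self.df["snp_id"].isin(set(mask_or_ids))
        else:
            mask = np.asarray(mask_or_ids, dtype=bool)
        return HarmonizedPairs(
            self.df[mask].copy(),
            self.exposure_id,
            self.outcome_id,
            self.outcome_binary,
            self.exclusions,
        )

    def write_exclusion_log(self, path) -> None:
        self.exclusions.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_arrays(
        cls,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        snp_ids=None,
        **kwargs,
    ) -> "HarmonizedPairs":
        """Build directly from aligned effect arrays (simulation shortcut)."""
        beta_exp = np.asarray(beta_exp, dtype=float)
        if snp_ids is None:
            snp_ids = [f"snp{i}" for i in range(len(beta_exp))]
        df = pd.DataFrame(
            {
                "snp_id": list(snp_ids),
                "beta_exp": beta_exp,
                "se_exp": np.asarray(se_exp, dtype=float),
                "beta_out": np.asarray(beta_out, dtype=float),
                "se_out": np.asarray(se_out, dtype=float),
            }
        )
        df["pval_exp"] = np.nan
        df["pval_out"] = np.nan
        df["f_stat"] = (df["beta_exp"] / df["se_exp"]) ** 2
        df["flipped"] = False
        return cls(df, **kwargs)


def select_by_pvalue(sset: SummaryStatSet, threshold: float) -> SummaryStatSet:
    """Keep exactly the records with ``pvalue < threshold`` (strict)."""
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError(f"threshold must be in (0,1), got {threshold}")
    keep = sset.records[sset.records["pvalue"] < threshold]
    return SummaryStatSet(
        keep, sset.trait_id, sset.trait_type, sset.provenance,
        validate=False, allow_empty=True,
    )


def ld_clump(
    candidates: SummaryStatSet,
    ld: Optional[LDInfo] = None,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
) -> tuple[SummaryStatSet, pd.DataFrame]:
    """Greedy LD clumping.

    Candidates are ranked by ascending p-value (ties broken by snp_id);
    the best is kept and every remaining candidate on the same chromosome
    within ``window_kb`` (centre-to-centre, 1-based coordinates) whose
    r-squared with a kept variant is at least ``r2_max`` is discarded.
    Pairs missing from ``ld`` are treated as unlinked.

    Returns the surviving set and an exclusion log (snp_id, stage, reason).
    """
    if len(candidates) == 0:
        raise ConfigurationError("ld_clump requires a non-empty candidate set")
    ld = ld or LDInfo()
    df = candidates.records.sort_values(
        ["pvalue", "snp_id"], kind="mergesort"
    ).reset_index(drop=True)
    kept: list[int] = []
    dropped: list[tuple[str, str, str]] = []
    window_bp = window_kb * 1000
    for i in df.index:
        row = df.loc[i]
        clumped_by = None
        for k in kept:
            krow = df.loc[k]
            if row["chrom"] != krow["chrom"]:
                continue
            if abs(int(row["pos"]) - int(krow["pos"])) > window_bp:
                continue
            if ld.r2(row["snp_id"], krow["snp_id"]) >= r2_max:
                clumped_by = krow["snp_id"]
                break
        if clumped_by is None:
            kept.append(i)
        else:
            dropped.append((row["snp_id"], "ld_clump", f"clumped_by:{clumped_by}"))
    surv = candidates.subset(df.loc[kept, "snp_id"])
    log = pd.DataFrame(dropped, columns=["snp_id", "stage", "reason"])
    return surv, log


def harmonize(
    exposure_ivs: SummaryStatSet,
    outcome: SummaryStatSet,
    outcome_assoc_p: float = 5e-8,
) -> HarmonizedPairs:
    """Align outcome effects to the exposure's effect alleles.

    Per instrument: variants absent from the outcome set are dropped;
    palindromic (A/T or C/G) variants are removed unconditionally;
    swapped alleles flip the outcome beta's sign (and complement eaf);
    alleles that match only after strand complementing are complemented
    then aligned; irreconcilable pairs are dropped; finally, variants
    whose *outcome* p-value is below ``outcome_assoc_p`` are excluded as
    outcome-associated. Every drop is logged with its reason.
    """
    out_by_snp = outcome.records.set_index("snp_id")
    rows = []
    excl: list[tuple[str, str, str]] = []
    for rec in exposure_ivs.records.itertuples(index=False):
        snp = rec.snp_id
        if snp not in out_by_snp.index:
            excl.append((snp, "harmonize", "missing_in_outcome"))
            continue
        if is_palindromic(rec.effect_allele, rec.other_allele):
            excl.append((snp, "harmonize", "palindromic"))
            continue
        orec = out_by_snp.loc[snp]
        ea, oa = rec.effect_allele, rec.other_allele
        oea, ooa = orec["effect_allele"], orec["other_allele"]
        flipped = False
        if (oea, ooa) == (ea, oa):
            beta_out = orec["beta"]
        elif (oea, ooa) == (oa, ea):
            beta_out = -orec["beta"]
            flipped = True
        else:
            cea, coa = COMPLEMENT[oea], COMPLEMENT[ooa]
            if (cea, coa) == (ea, oa):
                beta_out = orec["beta"]
            elif (cea, coa) == (oa, ea):
                beta_out = -orec["beta"]
                flipped = True
            else:
                excl.append((snp, "harmonize", "allele_mismatch"))
                continue
        if orec["pvalue"] < outcome_assoc_p:
            excl.append((snp, "harmonize", "outcome_associated"))
            continue
        rows.append(
            {
                "snp_id": snp,
                "beta_exp": rec.beta,
                "se_exp": rec.se,
                "beta_out": beta_out,
                "se_out": orec["se"],
                "pval_exp": rec.pvalue,
                "pval_out": orec["pvalue"],
                "f_stat": (rec.beta / rec.se) ** 2,
                "flipped": flipped,
            }
        )
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return HarmonizedPairs(
        df,
        exposure_id=exposure_ivs.trait_id,
        outcome_id=outcome.trait_id,
        outcome_binary=outcome.trait_type == "binary",
        exclusions=pd.DataFrame(excl, columns=["snp_id", "stage", "reason"]),
    )


def f_filter(pairs: HarmonizedPairs, min_f: float = 10.0) -> HarmonizedPairs:
    """Drop weak instruments with ``F = beta_exp^2 / se_exp^2 < min_f``."""
    f = (pairs.df["beta_exp"] / pairs.df["se_exp"]) ** 2
    keep = f >= min_f
    dropped = pairs.df.loc[~keep, "snp_id"]
    log = pd.concat(
        [
            pairs.exclusions,
            pd.DataFrame(
                {"snp_id": dropped, "stage": "f_filter", "reason": "weak_instrument"}
            ),
        ],
        ignore_index=True,
    )
    if not keep.any():
        raise EmptyInstrumentsError(
            f"all {len(pairs)} instruments removed by F < {min_f} filter"
        )
    return HarmonizedPairs(
        pairs.df[keep].copy(),
        pairs.exposure_id,
        pairs.outcome_id,
        pairs.outcome_binary,
        log,
    )


def select_instruments(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    pvalue_threshold: float = 5e-8,
    ld: Optional[LDInfo] = None,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
    outcome_assoc_p: float = 5e-8,
    min_f: float = 10.0,
) -> HarmonizedPairs:
    """Full four-step selection: p-value filter, LD clump, harmonize,
    F-statistic filter. Convenience wrapper used by the pipeline."""
    sig = select_by_pvalue(exposure, pvalue_threshold)
    if len(sig) == 0:
        raise EmptyInstrumentsError(
            f"no variants pass p < {pvalue_threshold} for {exposure.trait_id!r}"
        )
    clumped, clump_log = ld_clump(sig, ld=ld, r2_max=r2_max, window_kb=window_kb)
    pairs = harmonize(clumped, outcome, outcome_assoc_p=outcome_assoc_p)
    pairs.exclusions = pd.concat([clump_log, pairs.exclusions], ignore_index=True)
    return f_filter(pairs, min_f=min_f)
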