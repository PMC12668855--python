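"""Reading, validating and writing GWAS summary-statistic tables.

The data model is a :class:`SummaryStatSet` — one row per variant with the
fields every downstream estimator needs (effect size, standard error,
p-value, alleles) plus optional effect-allele frequency and sample size.
Linkage-disequilibrium information is carried separately by :class:`LDInfo`
as pairwise r-squared values; a missing pair means "assume unlinked".
"""

from __future__ import annotations

import sys
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyInputError

VALID_ALLELES = frozenset("ACGT")

#: canonical column order for on-disk tables
COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "eaf",
    "n",
]

MANDATORY = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pvalue"]

#: named column-map presets for common summary-statistic dialects
COLUMN_PRESETS: dict[str, dict[str, str]] = {
    "gwas-ssf": {
        "snp_id": "rsid",
        "chrom": "chromosome",
        "pos": "base_pair_location",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "beta": "beta",
        "se": "standard_error",
        "pvalue": "p_value",
        "eaf": "effect_allele_frequency",
        "n": "n",
    },
    "finngen": {
        "snp_id": "rsids",
        "chrom": "#chrom",
        "pos": "pos",
        "effect_allele": "alt",
        "other_allele": "ref",
        "beta": "beta",
        "se": "sebeta",
        "pvalue": "pval",
        "eaf": "af_alt",
    },
    "ieu": {
        "snp_id": "SNP",
        "chrom": "chr",
        "pos": "position",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "beta": "beta",
        "se": "se",
        "pvalue": "pval",
        "eaf": "eaf",
        "n": "samplesize",
    },
}


@dataclass
class IngestReport:
    """Accounting of what happened during ingestion."""

    n_read: int = 0
    n_valid: int = 0
    n_dropped: int = 0
    drop_reasons: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {
            "n_read": self.n_read,
            "n_valid": self.n_valid,
            "n_dropped": self.n_dropped,
            "drop_reasons": dict(self.drop_reasons),
        }


class SummaryStatSet:
    """A validated set of per-variant associations for one trait.

    Parameters
    ----------
    records
        DataFrame with (at least) the mandatory columns in :data:`COLUMNS`.
        ``eaf`` and ``n`` are optional and filled with NaN when absent.
    trait_id
        Identifier of the trait the effects refer to.
    trait_type
        ``"continuous"`` or ``"binary"``; binary-trait betas are log odds
        ratios and results are additionally reported on the OR scale.
    provenance
        Free-text source tag.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        trait_id: str,
        trait_type: str = "continuous",
        provenance: str = "",
        validate: bool = True,
        allow_empty: bool = False,
    ) -> None:
        if trait_type not in ("continuous", "binary"):
            raise ConfigurationError(f"trait_type must be continuous or binary, got {trait_type!r}")
        df = records.copy()
        for col in ("eaf", "n"):
            if col not in df.columns:
                df[col] = np.nan
        missing = [c for c in MANDATORY if c not in df.columns]
        if missing:
            raise ConfigurationError(f"records missing mandatory columns: {missing}")
        df = df[COLUMNS].reset_index(drop=True)
        self.report = IngestReport(n_read=len(df))
        if validate:
            df = _validate(df, self.report)
        else:
            self.report.n_valid = len(df)
        if len(df) == 0 and not allow_empty:
            raise EmptyInputError(f"no valid records for trait {trait_id!r}")
        self.records = df
        self.trait_id = trait_id
        self.trait_type = trait_type
        self.provenance = provenance

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in set(self.records["snp_id"])

    def subset(self, snp_ids) -> "SummaryStatSet":
        """Return a new set restricted to ``snp_ids`` (order preserved)."""
        keep = self.records[self.records["snp_id"].isin(set(snp_ids))]
        return SummaryStatSet(
            keep, self.trait_id, self.trait_type, self.provenance,
            validate=False, allow_empty=True,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SummaryStatSet(trait_id={self.trait_id!r}, trait_type={self.trait_type!r}, "
            f"n_records={len(self)})"
        )


def _validate(df: pd.DataFrame, report: IngestReport) -> pd.DataFrame:
    """Enforce record invariants, dropping and counting failing rows."""
    df = df.copy()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for allele_col in ("effect_allele", "other_allele"):
        df[allele_col] = df[allele_col].astype(str).str.upper().str.strip()

    for col in ("pos", "beta", "se", "pvalue", "eaf", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    n_zero = int((df["pvalue"] == 0).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} p-value(s) of exactly 0 clamped to {sys.float_info.min:g}",
            stacklevel=3,
        )
        df["pvalue"] = df["pvalue"].where(df["pvalue"] != 0, sys.float_info.min)

    checks = [
        ("bad_position", (df["pos"] > 0) & (df["pos"] == df["pos"].round())),
        (
            "bad_allele",
            df["effect_allele"].isin(VALID_ALLELES) & df["other_allele"].isin(VALID_ALLELES),
        ),
        ("identical_alleles", df["effect_allele"] != df["other_allele"]),
        ("bad_beta", np.isfinite(df["beta"])),
        ("nonpositive_se", np.isfinite(df["se"]) & (df["se"] > 0)),
        ("bad_pvalue", (df["pvalue"] > 0) & (df["pvalue"] <= 1)),
        ("duplicate_snp_id", ~df["snp_id"].duplicated()),
    ]
    keep = pd.Series(True, index=df.index)
    for reason, ok in checks:
        ok = ok.fillna(False) & keep
        failed = keep & ~ok
        if failed.any():
            report.drop_reasons[reason] += int(failed.sum())
        keep = ok

    out = df[keep].copy()
    out["pos"] = out["pos"].astype(int)
    # eaf outside (0,1) is treated as missing rather than invalidating the row
    bad_eaf = out["eaf"].notna() & ~((out["eaf"] > 0) & (out["eaf"] < 1))
    out.loc[bad_eaf, "eaf"] = np.nan
    bad_n = out["n"].notna() & ~(out["n"] > 0)
    out.loc[bad_n, "n"] = np.nan

    report.n_valid = len(out)
    report.n_dropped = report.n_read - len(out)
    return out.reset_index(drop=True)


def read_sumstats(
    table_path,
    column_map: Mapping[str, str] | str | None = None,
    trait_id: str = "trait",
    trait_type: str = "continuous",
    sep: str | None = None,
) -> SummaryStatSet:
    """Read a delimited summary-statistic table into a validated set.

    ``column_map`` maps the standard field names in :data:`COLUMNS` to the
    source file's column names; it may also be the name of a preset in
    :data:`COLUMN_PRESETS`, or ``None`` when the file already uses the
    standard names. The separator is sniffed from the extension (``.csv``
    means comma, anything else tab) unless given explicitly.
    """
    path = Path(table_path)
    if not path.exists():
        raise ConfigurationError(f"summary-statistic table not found: {path}")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype={"chrom": str})
    if isinstance(column_map, str):
        try:
            column_map = COLUMN_PRESETS[column_map]
        except KeyError:
            raise ConfigurationError(
                f"unknown column preset {column_map!r}; available: {sorted(COLUMN_PRESETS)}"
            ) from None
    if column_map:
        missing = [src for std, src in column_map.items() if std in MANDATORY and src not in raw.columns]
        if missing:
            raise ConfigurationError(f"mapped columns absent from {path.name}: {missing}")
        raw = raw.rename(columns={src: std for std, src in column_map.items()})
    missing = [c for c in MANDATORY if c not in raw.columns]
    if missing:
        raise ConfigurationError(f"table {path.name} lacks mandatory columns: {missing}")
    return SummaryStatSet(raw, trait_id=trait_id, trait_type=trait_type, provenance=str(path))


def write_sumstats(sset: SummaryStatSet, table_path) -> None:
    """Write a set as a tab-delimited table; round-trips through
    :func:`read_sumstats` field-for-field. Missing optional values are
    written as ``NA``."""
    path = Path(table_path)
    df = sset.records[COLUMNS]
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


class LDInfo:
    """Pairwise linkage-disequilibrium r-squared lookups.

    Symmetric; a pair absent from the table is treated as unlinked
    (r-squared 0), which matches summary-only workflows without a
    reference panel. ``r2(a, a)`` is 1 by definition.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None) -> None:
        self._r2: dict[frozenset, float] = {}
        for (a, b), r2 in (pairs or {}).items():
            self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ConfigurationError(f"r2 must be in [0,1], got {r2} for ({a},{b})")
        if a == b:
            return
        self._r2[frozenset((a, b))] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_table(cls, path, sep: str = "\t") -> "LDInfo":
        """Load from a three-column table (snp_a, snp_b, r2)."""
        df = pd.read_csv(path, sep=sep)
        cols = list(df.columns[:3])
        info = cls()
        for a, b, r2 in df[cols].itertuples(index=False):
            info.set(str(a), str(b), float(r2))
        return info

    def to_table(self, path, sep: str = "\t") -> None:
        rows = [(*sorted(k), v) for k, v in self._r2.items()]
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).sort_values(
            ["snp_a", "snp_b"]
        ).to_csv(path, sep=sep, index=False)
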