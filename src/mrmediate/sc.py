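"""Single-cell QC filtering and marker-positive proportion comparison.

The container is an :class:`anndata.AnnData` with raw counts in ``X``
(dense or sparse), per-cell metadata in ``obs`` (``sample_id``, ``group``,
``cell_type``) and gene identifiers in ``var_names``. QC metrics
(``n_genes_detected``, ``mito_fraction``) are computed from the matrix.

The scientific content here is deliberately narrow: the cell-level QC
rule (mitochondrial fraction above 5%, or fewer than 200 / more than
10,000 detected genes, excludes a cell) and the comparison of
marker-positive fractions (e.g. Il3ra+ dendritic cells) between a control
and a disease group. Clustering, batch correction and annotation are
upstream concerns; cell-type labels are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import sparse, stats

import anndata as ad

from .exceptions import ConfigurationError


def _to_dense_col(X, j: int) -> np.ndarray:
    col = X[:, j]
    if sparse.issparse(col):
        return np.asarray(col.todense()).ravel()
    return np.asarray(col).ravel()


def compute_qc_metrics(adata: ad.AnnData, mito_prefix: str = "mt-") -> ad.AnnData:
    """Attach ``n_genes_detected`` and ``mito_fraction`` to ``obs``.

    Mitochondrial genes are identified by a case-insensitive gene-id
    prefix (default ``mt-``, the murine convention).
    """
    X = adata.X
    if sparse.issparse(X):
        n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
        total = np.asarray(X.sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        n_genes = (X > 0).sum(axis=1)
        total = X.sum(axis=1)
    mito_mask = np.array(
        [g.lower().startswith(mito_prefix.lower()) for g in adata.var_names]
    )
    if mito_mask.any():
        sub = X[:, mito_mask]
        mito = np.asarray(sub.sum(axis=1)).ravel() if sparse.issparse(sub) else np.asarray(sub).sum(axis=1)
    else:
        mito = np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / total, 0.0)
    adata.obs["n_genes_detected"] = n_genes.astype(int)
    adata.obs["mito_fraction"] = frac
    return adata


def qc_filter(
    adata: ad.AnnData,
    max_mito: float = 0.05,
    min_genes: int = 200,
    max_genes: int = 10_000,
    mito_prefix: str = "mt-",
) -> tuple[ad.AnnData, dict]:
    """Remove cells failing QC; returns (filtered view copy, removal counts).

    A cell is excluded when its mitochondrial fraction exceeds
    ``max_mito`` (strictly: exactly 5% is retained) or its detected-gene
    count is below ``min_genes`` or above ``max_genes``.
    """
    if "mito_fraction" not in adata.obs or "n_genes_detected" not in adata.obs:
        adata = compute_qc_metrics(adata.copy(), mito_prefix=mito_prefix)
    mito = adata.obs["mito_fraction"].to_numpy()
    ngenes = adata.obs["n_genes_detected"].to_numpy()
    fail_mito = mito > max_mito
    fail_low = ngenes < min_genes
    fail_high = ngenes > max_genes
    keep = ~(fail_mito | fail_low | fail_high)
    counts = {
        "n_input": int(adata.n_obs),
        "n_retained": int(keep.sum()),
        "removed_mito": int(fail_mito.sum()),
        "removed_low_genes": int(fail_low.sum()),
        "removed_high_genes": int(fail_high.sum()),
    }
    return adata[keep].copy(), counts


@dataclass
class GroupFraction:
    group: str
    positive: int
    total: int

    @property
    def fraction(self) -> float:
        return self.positive / self.total if self.total else float("nan")


def marker_positive_fraction(
    adata: ad.AnnData,
    cell_type: str,
    marker_gene: str,
    group_key: str = "group",
    cell_type_key: str = "cell_type",
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Fraction of ``cell_type`` cells with marker count above
    ``threshold`` (default: any nonzero count), per group.

    Returns a table with both the pooled per-group fraction and the mean
    of per-sample fractions (columns ``fraction`` and
    ``fraction_sample_mean``); a group without cells of the type yields
    NaN fractions.
    """
    if marker_gene not in adata.var_names:
        raise ConfigurationError(f"marker gene {marker_gene!r} absent from matrix")
    if cell_type_key not in adata.obs or group_key not in adata.obs:
        raise ConfigurationError(f"obs must carry {cell_type_key!r} and {group_key!r}")
    j = list(adata.var_names).index(marker_gene)
    expr = _to_dense_col(adata.X, j)
    obs = adata.obs
    sel = (obs[cell_type_key] == cell_type).to_numpy()
    pos = expr > threshold
    rows = []
    for group in pd.unique(obs[group_key]):
        in_g = sel & (obs[group_key] == group).to_numpy()
        total = int(in_g.sum())
        positive = int((pos & in_g).sum())
        per_sample = []
        for sample in pd.unique(obs.loc[in_g, "sample_id"]) if "sample_id" in obs else []:
            in_s = in_g & (obs["sample_id"] == sample).to_numpy()
            if in_s.sum():
                per_sample.append((pos & in_s).sum() / in_s.sum())
        rows.append(
            {
                "group": group,
                "cell_type": cell_type,
                "marker": marker_gene,
                "positive": positive,
                "total": total,
                "fraction": positive / total if total else np.nan,
                "fraction_sample_mean": float(np.mean(per_sample)) if per_sample else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ProportionComparison:
    difference: float
    z_stat: float
    z_pvalue: float
    exact_pvalue: Optional[float]
    pvalue: float
    test_used: str


def compare_proportions(a: tuple[int, int], b: tuple[int, int]) -> ProportionComparison:
    """Two-proportion comparison of (positive, total) pairs.

    The primary test is the pooled two-proportion z-test; when any
    expected cell count under the pooled rate is below 5, Fisher's exact
    test supplies the operative p-value (both are reported).
    """
    (x1, n1), (x2, n2) = a, b
    if n1 <= 0 or n2 <= 0:
        raise ConfigurationError("totals must be positive")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        z = 0.0
        z_p = 1.0
    else:
        z = (p1 - p2) / se
        z_p = float(2 * stats.norm.sf(abs(z)))
    expected = [n * p for n in (n1, n2) for p in (pooled, 1 - pooled)]
    exact_p = None
    test_used = "two_proportion_z"
    pvalue = z_p
    if min(expected) < 5:
        table = [[x1, n1 - x1], [x2, n2 - x2]]
        exact_p = float(stats.fisher_exact(table)[1])
        pvalue = exact_p
        test_used = "fisher_exact"
    return ProportionComparison(
        difference=p1 - p2, z_stat=float(z), z_pvalue=z_p,
        exact_pvalue=exact_p, pvalue=pvalue, test_used=test_used,
    )


def simulate_counts(
    n_cells: Mapping[str, Mapping[str, int]],
    positivity: Mapping[str, float],
    marker_gene: str = "Il3ra",
    target_cell_type: str = "DC",
    n_genes: int = 1000,
    n_mito: int = 10,
    mean_counts_per_gene: float = 0.5,
    dispersion: float = 0.5,
    qc_fail_mito_frac: float = 0.0,
    qc_fail_genes_frac: float = 0.0,
    n_samples_per_group: int = 3,
    seed: int = 0,
) -> ad.AnnData:
    """Simulate a sparse count matrix with programmed marker positivity.

    ``n_cells`` maps group -> cell_type -> cell count; ``positivity`` maps
    group -> probability that a ``target_cell_type`` cell expresses
    ``marker_gene``. Counts are negative binomial with mean
    ``mean_counts_per_gene`` and the given dispersion (NB size
    ``1/dispersion``). ``qc_fail_mito_frac`` / ``qc_fail_genes_frac`` of
    cells are perturbed to violate the mitochondrial and detected-gene QC
    rules; the designated fail labels are stored in
    ``obs["programmed_qc_fail"]``. Deterministic for a given seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = [f"mt-gene{i}" for i in range(n_mito)] + [
        f"gene{i}" for i in range(n_genes - n_mito - 1)
    ] + [marker_gene]
    size = 1.0 / dispersion

    blocks, obs_rows = [], []
    for group, by_type in n_cells.items():
        for cell_type, n in by_type.items():
            # NB via gamma-Poisson for vectorized generation
            lam = rng.gamma(size, mean_counts_per_gene / size, size=(n, len(genes)))
            counts = rng.poisson(lam)
            # marker column programmed explicitly
            jm = len(genes) - 1
            if cell_type == target_cell_type:
                p = positivity.get(group, 0.0)
                positive = rng.random(n) < p
                counts[:, jm] = np.where(positive, rng.poisson(2.0, size=n) + 1, 0)
            else:
                counts[:, jm] = rng.poisson(0.2, size=n)
            # programmed QC failures
            fail_mito = rng.random(n) < qc_fail_mito_frac
            fail_genes = (~fail_mito) & (rng.random(n) < qc_fail_genes_frac)
            if fail_mito.any():
                counts[fail_mito, :n_mito] = counts[fail_mito, :n_mito] * 10 + 20
            if fail_genes.any():
                # silence most genes so the detected count drops below 200
                zero = rng.random((int(fail_genes.sum()), len(genes))) < 0.95
                sub = counts[fail_genes]
                sub[zero] = 0
                counts[fail_genes] = sub
            samples = rng.integers(0, n_samples_per_group, size=n)
            for i in range(n):
                obs_rows.append(
                    {
                        "sample_id": f"{group}_s{samples[i]}",
                        "group": group,
                        "cell_type": cell_type,
                        "programmed_qc_fail": (
                            "mito" if fail_mito[i] else "genes" if fail_genes[i] else "none"
                        ),
                    }
                )
            blocks.append(counts)
    X = sparse.csr_matrix(np.vstack(blocks))
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell{i}" for i in range(len(obs))]
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))
    return compute_qc_metrics(adata, mito_prefix="mt-")
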