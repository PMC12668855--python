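import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.sparse import csr_matrix

import anndata as ad

from mrmediate.exceptions import ConfigurationError
from mrmediate.sc import (
    compare_proportions,
    compute_qc_metrics,
    marker_positive_fraction,
    qc_filter,
    simulate_counts,
)


def _adata_from_counts(counts, obs=None, genes=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[1])]
    obs = obs if obs is not None else pd.DataFrame(index=[f"c{i}" for i in range(counts.shape[0])])
    obs.index = [f"c{i}" for i in range(counts.shape[0])]
    return ad.AnnData(X=csr_matrix(counts), obs=obs, var=pd.DataFrame(index=genes))


class TestQCFilter:
    def test_boundary_conventions(self):
        # 20 genes, two mitochondrial; craft exact metric values
        genes = ["mt-a", "mt-b"] + [f"g{i}" for i in range(18)]
        rows = [
            np.r_[5, 1, np.ones(18) * 6],    # mito 6/114 ~ 5.26% > 5% -> excluded
            np.r_[3, 2, np.ones(18) * 5],    # mito 5/95 ~ 5.26%... compute below
        ]
        counts = np.array(
            [
                np.r_[6, 0, np.full(18, 19.0)],   # mito = 6, total 348 -> 1.7% retained
                np.r_[10, 10, np.full(18, 20.0)],  # mito 20/380 = 5.26% -> excluded
                np.r_[1, 0, np.full(18, 1.0)],    # mito 1/19 ... also few genes
            ]
        )
        # explicit fraction-boundary case: exactly 5% retained
        counts = np.vstack([counts, np.r_[19, 0, np.full(18, 20.0)]])  # 19/379?
        adata = _adata_from_counts(counts, genes=genes)
        adata = compute_qc_metrics(adata, mito_prefix="mt-")
        # set boundary exactly: overwrite with crafted metrics
        adata.obs["mito_fraction"] = [0.04, 0.06, 0.05, 0.051]
        adata.obs["n_genes_detected"] = [300, 300, 300, 300]
        kept, counts_report = qc_filter(adata, min_genes=200)
        assert list(kept.obs_names) == ["c0", "c2"]  # 0.05 exactly is retained
        assert counts_report["removed_mito"] == 2

    def test_gene_count_bounds(self):
        adata = _adata_from_counts(np.ones((3, 5)))
        adata.obs["mito_fraction"] = 0.0
        adata.obs["n_genes_detected"] = [150, 200, 10001]
        kept, rep = qc_filter(adata, min_genes=200, max_genes=10_000)
        assert list(kept.obs_names) == ["c1"]
        assert rep["removed_low_genes"] == 1 and rep["removed_high_genes"] == 1

    def test_constructed_pass_fail_labels(self):
        adata = simulate_counts(
            {"control": {"DC": 400}}, {"control": 0.2},
            qc_fail_mito_frac=0.1, qc_fail_genes_frac=0.1, seed=11,
        )
        kept, _ = qc_filter(adata)
        # every programmed failure is removed; survivors are programmed passes
        assert (kept.obs["programmed_qc_fail"] == "none").all()
        programmed_fail = (adata.obs["programmed_qc_fail"] != "none").sum()
        removed = adata.n_obs - kept.n_obs
        assert removed >= programmed_fail

    def test_idempotent(self):
        adata = simulate_counts({"g": {"DC": 300}}, {"g": 0.15},
                                qc_fail_mito_frac=0.05, seed=3)
        once, _ = qc_filter(adata)
        twice, rep = qc_filter(once)
        assert twice.n_obs == once.n_obs
        assert rep["n_retained"] == rep["n_input"]

    def test_programmed_fail_fraction_recovered(self):
        adata = simulate_counts({"g": {"DC": 2000}}, {"g": 0.15},
                                qc_fail_mito_frac=0.05, qc_fail_genes_frac=0.05, seed=5)
        _, rep = qc_filter(adata)
        removed_frac = 1 - rep["n_retained"] / rep["n_input"]
        # programmed 10% total, binomial tolerance
        assert abs(removed_frac - 0.10) < 0.025


class TestMarkerFractions:
    def test_fraction_arithmetic(self):
        counts = np.zeros((1000, 3))
        counts[:173, 2] = 1  # marker column
        obs = pd.DataFrame({
            "group": ["chow"] * 1000,
            "cell_type": ["DC"] * 1000,
            "sample_id": ["s1"] * 1000,
        })
        adata = _adata_from_counts(counts, obs=obs, genes=["a", "b", "Il3ra"])
        frac = marker_positive_fraction(adata, "DC", "Il3ra")
        row = frac.iloc[0]
        assert (row["positive"], row["total"]) == (173, 1000)
        assert row["fraction"] == pytest.approx(0.173)

    def test_absent_marker_expression_gives_zero(self):
        counts = np.zeros((10, 2))
        obs = pd.DataFrame({"group": ["a"] * 5 + ["b"] * 5,
                            "cell_type": ["DC"] * 10, "sample_id": ["s"] * 10})
        adata = _adata_from_counts(counts, obs=obs, genes=["x", "Il3ra"])
        frac = marker_positive_fraction(adata, "DC", "Il3ra")
        assert (frac["fraction"] == 0).all()

    def test_unknown_marker_errors(self):
        adata = _adata_from_counts(np.ones((4, 2)))
        adata.obs["group"] = "a"
        adata.obs["cell_type"] = "DC"
        with pytest.raises(ConfigurationError):
            marker_positive_fraction(adata, "DC", "Nope")

    def test_programmed_positivity_recovered(self):
        adata = simulate_counts(
            {"chow": {"DC": 2000}, "nash": {"DC": 2000}},
            {"chow": 0.173, "nash": 0.129}, seed=21,
        )
        frac = marker_positive_fraction(adata, "DC", "Il3ra").set_index("group")
        for group, p in (("chow", 0.173), ("nash", 0.129)):
            n = frac.loc[group, "total"]
            tol = 3 * np.sqrt(p * (1 - p) / n)
            assert abs(frac.loc[group, "fraction"] - p) < tol

    def test_invariant_to_cell_and_gene_order(self):
        adata = simulate_counts({"g": {"DC": 300, "T": 100}}, {"g": 0.3}, seed=8)
        rng = np.random.default_rng(0)
        cells = rng.permutation(adata.n_obs)
        genes = rng.permutation(adata.n_vars)
        shuffled = adata[cells, :][:, genes].copy()
        a = marker_positive_fraction(adata, "DC", "Il3ra").set_index("group")
        b = marker_positive_fraction(shuffled, "DC", "Il3ra").set_index("group")
        pd.testing.assert_frame_equal(a, b)


class TestCompareProportions:
    def test_identical_proportions(self):
        r = compare_proportions((50, 100), (50, 100))
        assert r.z_stat == 0.0 and r.pvalue == 1.0

    def test_matches_chi2_oracle(self):
        r = compare_proportions((129, 1000), (173, 1000))
        chi2, p, *_ = stats.chi2_contingency(
            [[129, 871], [173, 827]], correction=False
        )
        assert r.z_stat**2 == pytest.approx(chi2, rel=1e-10)
        assert r.pvalue == pytest.approx(p, rel=1e-10)
        assert r.pvalue < 0.05

    def test_exact_fallback_matches_hypergeometric_enumeration(self):
        r = compare_proportions((2, 10), (3, 10))
        assert r.test_used == "fisher_exact"
        # brute-force two-sided Fisher: sum hypergeometric probabilities
        # of tables at most as probable as the observed one
        total_pos = 5
        probs = [stats.hypergeom.pmf(k, 20, total_pos, 10) for k in range(6)]
        p_obs = stats.hypergeom.pmf(2, 20, total_pos, 10)
        p_enum = sum(p for p in probs if p <= p_obs + 1e-12)
        assert r.exact_pvalue == pytest.approx(p_enum, rel=1e-8)

    def test_symmetry_up_to_sign(self):
        a, b = (129, 1000), (173, 1000)
        r1, r2 = compare_proportions(a, b), compare_proportions(b, a)
        assert r1.difference == -r2.difference
        assert r1.pvalue == pytest.approx(r2.pvalue, rel=1e-12)


class TestSimulateCounts:
    def test_zero_positivity(self):
        adata = simulate_counts({"g": {"DC": 200}}, {"g": 0.0}, seed=2)
        frac = marker_positive_fraction(adata, "DC", "Il3ra")
        assert frac.iloc[0]["positive"] == 0

    def test_seeded_determinism(self):
        a = simulate_counts({"g": {"DC": 100}}, {"g": 0.2}, seed=4)
        b = simulate_counts({"g": {"DC": 100}}, {"g": 0.2}, seed=4)
        assert (a.X != b.X).nnz == 0
        pd.testing.assert_frame_equal(a.obs, b.obs)

    def test_metrics_consistent_with_matrix(self):
        adata = simulate_counts({"g": {"DC": 150}}, {"g": 0.2}, seed=6)
        X = np.asarray(adata.X.todense())
        assert (adata.obs["n_genes_detected"].to_numpy() == (X > 0).sum(axis=1)).all()
        mito_cols = [i for i, g in enumerate(adata.var_names) if g.startswith("mt-")]
        frac = X[:, mito_cols].sum(axis=1) / X.sum(axis=1)
        assert np.allclose(adata.obs["mito_fraction"], frac)
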