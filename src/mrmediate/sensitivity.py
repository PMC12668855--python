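"""Sensitivity analyses for two-sample MR.

Covers the standard quartet: Cochran's Q heterogeneity test on the
per-variant ratio estimates, the MR-Egger intercept test for directional
pleiotropy, the MR-PRESSO global/outlier/distortion procedure, and
leave-one-out IVW re-estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientInstrumentsError
from .instruments import HarmonizedPairs
from .mr import MRResults, ivw, mr_egger, _as_arrays


def cochran_q(pairs) -> tuple[float, int, float]:
    """Cochran's Q over the per-variant ratio estimates.

    ``Q = sum_j w_j (b_j - b_IVW_fixed)^2`` with ``b_j = Gamma_j/gamma_j``
    and ``w_j`` their inverse first-order variances; p from chi-square with
    J-1 degrees of freedom. Identical to the Q stored in the IVW aux.
    """
    bx, sx, by, sy = _as_arrays(pairs)
    j = len(bx)
    if j < 2:
        raise InsufficientInstrumentsError("cochran_q requires at least 2 instruments")
    ratios = by / bx
    w = (bx / sy) ** 2
    beta_fixed = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - beta_fixed) ** 2))
    df = j - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(pairs) -> tuple[float, float, float]:
    """Egger intercept, its SE, and two-sided p — directional pleiotropy."""
    fit = mr_egger(pairs)
    return fit.aux["intercept"], fit.aux["intercept_se"], fit.aux["intercept_p"]


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outlier_p: pd.Series  # Bonferroni-adjusted per-variant p, indexed by snp_id
    outliers: list[str]
    corrected: Optional[MRResults]
    distortion_p: Optional[float]
    n_sim: int


def _loo_fixed_slopes(bx, by, w):
    """Leave-one-out fixed-effects IVW slopes, closed form."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx**2)
    return (s_xy - w * bx * by) / (s_xx - w * bx**2)


def mr_presso(pairs, n_sim: int = 1000, outlier_alpha: float = 0.05,
              seed: Optional[int] = None) -> PressoResult:
    """MR-PRESSO global test with outlier detection and correction.

    The observed statistic is the weighted residual sum of squares of each
    variant against the IVW slope fitted *without* it. The null
    distribution comes from ``n_sim`` parametric simulations drawing both
    exposure and outcome effects from their sampling normals around the
    leave-one-out fits; the global p is the add-one-corrected exceedance
    fraction. Per-variant outlier p-values use the analogous
    per-observation comparison with Bonferroni adjustment across
    instruments; flagged outliers are removed and IVW re-fit for the
    corrected estimate. The distortion p contrasts the raw-vs-corrected
    shift with the same shift under random same-size removals in the
    simulations.
    """
    bx, sx, by, sy = _as_arrays(pairs)
    j = len(bx)
    if j < 4:
        raise InsufficientInstrumentsError("mr_presso requires at least 4 instruments")
    snp_ids = pairs.snp_ids if isinstance(pairs, HarmonizedPairs) else [f"snp{i}" for i in range(j)]
    w = 1.0 / sy**2
    slopes_loo = _loo_fixed_slopes(bx, by, w)
    obs_contrib = w * (by - slopes_loo * bx) ** 2
    rss_obs = float(obs_contrib.sum())

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, j))
    by_sim = rng.normal(slopes_loo * bx, sy, size=(n_sim, j))
    s_xy = (w * bx_sim * by_sim).sum(axis=1, keepdims=True)
    s_xx = (w * bx_sim**2).sum(axis=1, keepdims=True)
    slopes_sim = (s_xy - w * bx_sim * by_sim) / (s_xx - w * bx_sim**2)
    sim_contrib = w * (by_sim - slopes_sim * bx_sim) ** 2
    rss_sim = sim_contrib.sum(axis=1)

    global_p = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))
    p_raw = (np.sum(sim_contrib >= obs_contrib[None, :], axis=0) + 1) / (n_sim + 1)
    p_adj = np.minimum(p_raw * j, 1.0)
    outlier_p = pd.Series(p_adj, index=snp_ids, name="presso_outlier_p")
    outlier_mask = p_adj < outlier_alpha
    outliers = [s for s, o in zip(snp_ids, outlier_mask) if o]

    corrected = None
    distortion_p = None
    if outliers and j - len(outliers) >= 2:
        keep = ~outlier_mask
        corrected = ivw((bx[keep], sx[keep], by[keep], sy[keep]))
        corrected.aux["removed"] = outliers
        raw = ivw((bx, sx, by, sy))
        d_obs = abs(raw.beta - corrected.beta)
        # same-size random removals on the simulated datasets
        n_out = len(outliers)
        d_sim = np.empty(n_sim)
        for i in range(n_sim):
            drop = rng.choice(j, size=n_out, replace=False)
            keep_i = np.ones(j, dtype=bool)
            keep_i[drop] = False
            num = (w * bx_sim[i] * by_sim[i])[keep_i].sum()
            den = (w * bx_sim[i] ** 2)[keep_i].sum()
            full = s_xy[i, 0] / s_xx[i, 0]
            d_sim[i] = abs(full - num / den)
        distortion_p = float((np.sum(d_sim >= d_obs) + 1) / (n_sim + 1))

    return PressoResult(
        global_rss=rss_obs, global_p=global_p, outlier_p=outlier_p,
        outliers=outliers, corrected=corrected, distortion_p=distortion_p,
        n_sim=n_sim,
    )


def leave_one_out(pairs) -> pd.DataFrame:
    """IVW re-fit leaving each instrument out in turn.

    Returns a table (snp_left_out, beta, se, ci_low, ci_high, p,
    sign_flip, significance_flip) where the flags compare each reduced fit
    with the full-sample IVW.
    """
    bx, sx, by, sy = _as_arrays(pairs)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError("leave_one_out requires at least 3 instruments")
    snp_ids = pairs.snp_ids if isinstance(pairs, HarmonizedPairs) else [f"snp{i}" for i in range(j)]
    full = ivw(pairs)
    rows = []
    for i in range(j):
        keep = np.ones(j, dtype=bool)
        keep[i] = False
        fit = ivw((bx[keep], sx[keep], by[keep], sy[keep]))
        rows.append(
            {
                "snp_left_out": snp_ids[i],
                "beta": fit.beta,
                "se": fit.se,
                "ci_low": fit.ci_low,
                "ci_high": fit.ci_high,
                "pvalue": fit.pvalue,
                "sign_flip": np.sign(fit.beta) != np.sign(full.beta),
                "significance_flip": (fit.pvalue < 0.05) != (full.pvalue < 0.05),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SensitivityReport:
    """Bundle of the four sensitivity analyses for one instrument set."""

    q_stat: float
    q_df: int
    q_pvalue: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    presso: Optional[PressoResult]
    loo: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def heterogeneous(self) -> bool:
        return self.q_pvalue < 0.05

    @property
    def pleiotropic(self) -> bool:
        return self.egger_intercept_p < 0.05

    def to_text(self) -> str:
        lines = [
            "Sensitivity report",
            f"cochran_q\t{self.q_stat:.6g}",
            f"q_df\t{self.q_df}",
            f"q_pvalue\t{self.q_pvalue:.6g}",
            f"egger_intercept\t{self.egger_intercept:.6g}",
            f"egger_intercept_se\t{self.egger_intercept_se:.6g}",
            f"egger_intercept_p\t{self.egger_intercept_p:.6g}",
        ]
        if self.presso is not None:
            lines += [
                f"presso_global_p\t{self.presso.global_p:.6g}",
                f"presso_outliers\t{','.join(self.presso.outliers) or 'none'}",
            ]
            if self.presso.distortion_p is not None:
                lines.append(f"presso_distortion_p\t{self.presso.distortion_p:.6g}")
        if len(self.loo):
            lines.append("")
            lines.append("leave-one-out:")
            lines.append(self.loo.to_string(index=False))
        return "\n".join(lines)


def sensitivity_suite(pairs, n_sim: int = 1000, seed: Optional[int] = None) -> SensitivityReport:
    """Run all four sensitivity analyses (MR-PRESSO only when J >= 4)."""
    q, df, qp = cochran_q(pairs)
    b0, se0, p0 = egger_intercept_test(pairs)
    bx = _as_arrays(pairs)[0]
    presso = mr_presso(pairs, n_sim=n_sim, seed=seed) if len(bx) >= 4 else None
    return SensitivityReport(
        q_stat=q, q_df=df, q_pvalue=qp,
        egger_intercept=b0, egger_intercept_se=se0, egger_intercept_p=p0,
        presso=presso, loo=leave_one_out(pairs),
    )
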