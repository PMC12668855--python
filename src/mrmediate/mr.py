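"""Two-sample Mendelian randomization estimators.

The model object is :class:`MRModel`, built from per-instrument exposure
and outcome associations (a :class:`~mrmediate.instruments.HarmonizedPairs`
or raw arrays). ``MRModel.fit(method=...)`` returns an :class:`MRResults`
carrying the causal estimate, its standard error, 95% confidence interval,
p-value, odds-ratio scale values for binary outcomes, and method-specific
auxiliaries. ``MRModel.fit_all`` runs the whole suite and returns an
:class:`MRReport` with the direction-consistency and significance flags
used for mediator screening.

Notation: for instrument j, ``gamma_j`` (beta_exp) is the variant-exposure
effect with standard error ``s_xj``, and ``Gamma_j`` (beta_out) the
variant-outcome effect with standard error ``s_yj``. The per-variant Wald
ratio is ``Gamma_j / gamma_j``; IVW is the inverse-variance-weighted
combination of those ratios, equivalently weighted least squares of Gamma
on gamma through the origin with weights ``1/s_yj^2``.

Estimators implemented:

- ``wald`` — single-variant ratio with first-order delta SE;
- ``ivw`` — fixed or multiplicative-random-effects inverse variance
  weighting (the primary method);
- ``egger`` — weighted regression with an intercept absorbing directional
  pleiotropy (InSIDE assumption);
- ``weighted_median`` / ``simple_median`` — consistent with up to 50%
  invalid instruments; bootstrap SE;
- ``weighted_mode`` / ``simple_mode`` — kernel-density mode of the ratio
  estimates (modified Silverman bandwidth); bootstrap SE;
- ``raps`` — robust adjusted profile score with optional overdispersion
  and Huber loss;
- ``conmix`` — contamination-mixture profile likelihood over a grid;
- ``cml_ma`` — constrained maximum likelihood with BIC model averaging
  over the number of invalid instruments;
- ``mvmr_ivw`` — multivariable IVW (see :class:`MVMRModel`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import (
    CollinearityError,
    ConvergenceError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from .instruments import HarmonizedPairs

Z95 = stats.norm.ppf(0.975)

PRIMARY_METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")
ROBUST_METHODS = ("raps", "conmix", "cml_ma")


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class MRResults:
    """A single method's causal estimate with normal-theory inference.

    ``beta`` is on the outcome scale per unit exposure (log odds ratio per
    unit exposure for binary outcomes); ``or_value`` is ``exp(beta)`` and
    is meaningful only for binary outcomes.
    """

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)
    outcome_binary: bool = False
    exposure_id: str = "exposure"
    outcome_id: str = "outcome"
    aux: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isnan(self.ci_low):
            self.ci_low = self.beta - Z95 * self.se
        if np.isnan(self.ci_high):
            self.ci_high = self.beta + Z95 * self.se

    # -- derived quantities -------------------------------------------------
    @property
    def or_value(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def conf_int(self) -> tuple[float, float]:
        return self.ci_low, self.ci_high

    def as_dict(self) -> dict:
        d = {
            "method": self.method,
            "exposure": self.exposure_id,
            "outcome": self.outcome_id,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
        }
        if self.outcome_binary:
            lo, hi = self.or_ci
            d.update({"or": self.or_value, "or_ci_low": lo, "or_ci_high": hi})
        return d

    def summary(self) -> str:
        lines = [
            f"MR estimate [{self.method}]  {self.exposure_id} -> {self.outcome_id}",
            f"  instruments : {self.n_snps}",
            f"  beta        : {self.beta: .6f}  (se {self.se:.6f})",
            f"  95% CI      : ({self.ci_low:.6f}, {self.ci_high:.6f})",
            f"  p-value     : {self.pvalue:.4g}",
        ]
        if self.outcome_binary:
            lo, hi = self.or_ci
            lines.append(f"  OR (95% CI) : {self.or_value:.3f} ({lo:.3f}, {hi:.3f})")
        for k, v in self.aux.items():
            if np.isscalar(v):
                lines.append(f"  {k:<12}: {v:.6g}" if isinstance(v, float) else f"  {k:<12}: {v}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MRResults {self.method}: beta={self.beta:.4f} se={self.se:.4f} "
            f"p={self.pvalue:.3g} n_snps={self.n_snps}>"
        )


@dataclass
class MRReport:
    """Suite-level report: one estimate per method plus the decision flags
    used for screening (IVW p < 0.05 and shared effect direction across the
    five primary methods)."""

    estimates: list[MRResults]
    exposure_id: str = "exposure"
    outcome_id: str = "outcome"
    consistency_methods: tuple = PRIMARY_METHODS

    def __getitem__(self, method: str) -> MRResults:
        for est in self.estimates:
            if est.method == method:
                return est
        raise KeyError(method)

    @property
    def ivw(self) -> MRResults:
        return self["ivw"]

    @property
    def significant(self) -> bool:
        return bool(self.ivw.pvalue < 0.05)

    @property
    def direction_consistent(self) -> bool:
        betas = [self[m].beta for m in self.consistency_methods if self._has(m)]
        return bool(all(b > 0 for b in betas) or all(b < 0 for b in betas))

    def _has(self, method: str) -> bool:
        return any(e.method == method for e in self.estimates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.as_dict() for e in self.estimates])

    def summary(self) -> str:
        head = (
            f"MR suite  {self.exposure_id} -> {self.outcome_id}\n"
            f"  significant (IVW p<0.05): {self.significant}\n"
            f"  direction consistent    : {self.direction_consistent}\n"
        )
        return head + self.to_frame().to_string(index=False)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _as_arrays(pairs) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(pairs, HarmonizedPairs):
        return pairs.arrays()
    bx, sx, by, sy = (np.asarray(a, dtype=float) for a in pairs)
    return bx, sx, by, sy


def _require(n: int, needed: int, method: str) -> None:
    if n < needed:
        raise InsufficientInstrumentsError(
            f"{method} requires at least {needed} instruments, got {n}"
        )


def _ratio_estimates(bx, sx, by, sy) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant Wald ratios and their first-order delta SEs."""
    if np.any(bx == 0):
        raise UndefinedRatioError("zero exposure effect; Wald ratio undefined")
    return by / bx, np.abs(sy / bx)


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float = 0.5) -> float:
    """Weighted quantile with linear interpolation between bracketing
    order statistics (midpoint convention on the cumulative weights)."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(q, cum, v))


def _weighted_quantile_rows(values: np.ndarray, weights: np.ndarray, q: float = 0.5) -> np.ndarray:
    """Row-wise weighted quantile for (n_boot, J) arrays."""
    order = np.argsort(values, axis=1)
    v = np.take_along_axis(values, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) - 0.5 * w
    out = np.empty(values.shape[0])
    for i in range(values.shape[0]):  # np.interp is 1-D only
        out[i] = np.interp(q, cum[i], v[i])
    return out


# ---------------------------------------------------------------------------
# estimators (array-level implementations)
# ---------------------------------------------------------------------------


def wald_ratio(beta_exp, se_exp, beta_out, se_out, **meta) -> MRResults:
    """Single-variant causal estimate ``Gamma/gamma`` with first-order
    delta-method SE ``se_out/|gamma|``."""
    if beta_exp == 0:
        raise UndefinedRatioError("beta_exp = 0")
    beta = beta_out / beta_exp
    se = abs(se_out / beta_exp)
    return MRResults(
        method="wald", beta=float(beta), se=float(se),
        pvalue=_normal_p(beta, se), n_snps=1, **meta,
    )


def ivw(pairs, model: str = "multiplicative_random", **meta) -> MRResults:
    """Inverse-variance-weighted estimate: weighted least squares of the
    outcome effects on the exposure effects through the origin, weights
    ``1/se_out^2``. ``model="multiplicative_random"`` inflates the SE by
    ``max(1, sqrt(Q/(J-1)))`` so it never falls below the fixed-effects SE.
    """
    bx, sx, by, sy = _as_arrays(pairs)
    j = len(bx)
    _require(j, 1, "ivw")
    if j == 1:
        res = wald_ratio(bx[0], sx[0], by[0], sy[0], **meta)
        res.method = "ivw"
        return res
    w = 1.0 / sy**2
    s_xy = float(np.sum(w * bx * by))
    s_xx = float(np.sum(w * bx**2))
    beta = s_xy / s_xx
    se_fixed = s_xx**-0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    scale = max(1.0, np.sqrt(q / (j - 1))) if model == "multiplicative_random" else 1.0
    se = se_fixed * scale
    return MRResults(
        method="ivw", beta=beta, se=se, pvalue=_normal_p(beta, se), n_snps=j,
        aux={"Q": q, "Q_df": j - 1, "re_scale": scale, "se_fixed": se_fixed,
             "model": model},
        **meta,
    )


def mr_egger(pairs, **meta) -> MRResults:
    """MR-Egger: weighted regression of outcome on exposure effects *with*
    an intercept, after orienting every instrument to a positive exposure
    effect. The slope is the causal estimate; a nonzero intercept captures
    directional pleiotropy under InSIDE."""
    bx, sx, by, sy = _as_arrays(pairs)
    j = len(bx)
    _require(j, 3, "egger")
    sign = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * sign, by * sign
    w = 1.0 / sy**2
    # closed-form weighted least squares with intercept
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = y - intercept - slope * x
    q = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(q / (j - 2)))
    var_slope = sw / det * scale**2
    var_int = swxx / det * scale**2
    se_slope, se_int = np.sqrt(var_slope), np.sqrt(var_int)
    return MRResults(
        method="egger", beta=float(slope), se=float(se_slope),
        pvalue=_normal_p(slope, se_slope), n_snps=j,
        aux={
            "intercept": float(intercept),
            "intercept_se": float(se_int),
            "intercept_p": _normal_p(intercept, se_int),
            "Q": q, "Q_df": j - 2, "re_scale": float(scale),
        },
        **meta,
    )


def _bootstrap_draws(bx, sx, by, sy, n_boot, rng):
    bxs = rng.normal(bx, sx, size=(n_boot, len(bx)))
    bys = rng.normal(by, sy, size=(n_boot, len(by)))
    return bxs, bys


def weighted_median(pairs, n_boot: int = 1000, seed: Optional[int] = None,
                    weighted: bool = True, **meta) -> MRResults:
    """Weighted-median estimator: the inverse-variance-weighted 50th
    percentile of the per-variant ratio estimates, consistent when valid
    instruments carry a majority of the weight. SE from a seeded
    parametric bootstrap (weights recomputed per draw)."""
    bx, sx, by, sy = _as_arrays(pairs)
    j = len(bx)
    _require(j, 3, "weighted_median")
    ratios, ratio_se = _ratio_estimates(bx, sx, by, sy)
    w = 1.0 / ratio_se**2 if weighted else np.ones(j)
    beta = _weighted_quantile(ratios, w)
    rng = np.random.default_rng(seed)
    bxs, bys = _bootstrap_draws(bx, sx, by, sy, n_boot, rng)
    bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
    r_b = bys / bxs
    w_b = (bxs / sy) ** 2 if weighted else np.ones_like(r_b)
    boots = _weighted_quantile_rows(r_b, w_b)
    se = float(np.std(boots, ddof=1))
    return MRResults(
        method="weighted_median" if weighted else "simple_median",
        beta=float(beta), se=se, pvalue=_normal_p(beta, se), n_snps=j,
        aux={"n_boot": n_boot}, **meta,
    )


def _mode_bandwidth(ratios: np.ndarray) -> float:
    """Modified Silverman rule on the ratio estimates:
    ``0.9 * min(sd, mad) * J^(-1/5)`` with the consistency-scaled MAD."""
    sd = np.std(ratios, ddof=1)
    mad = stats.median_abs_deviation(ratios, scale="normal")
    s = min(sd, mad) if mad > 0 else sd
    return 0.9 * s * len(ratios) ** (-1 / 5)


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, h: float) -> float:
    if h <= 0 or np.ptp(ratios) == 0:
        # degenerate: all ratios (effectively) identical
        vals, idx = np.unique(ratios, return_inverse=True)
        wsum = np.bincount(idx, weights=weights)
        return float(vals[np.argmax(wsum)])
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 2048)
    dens = (weights[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_estimator(pairs, weighted: bool = True, bandwidth_factor: float = 1.0,
                   n_boot: int = 1000, seed: Optional[int] = None, **meta) -> MRResults:
    """Mode-based estimator: the argmax of a normal-kernel density over the
    per-variant ratio estimates (inverse-variance weights when
    ``weighted``), robust when the largest cluster of instruments is
    valid. SE from a seeded parametric bootstrap."""
    bx, sx, by, sy = _as_arrays(pairs)
    j = len(bx)
    _require(j, 3, "mode")
    ratios, ratio_se = _ratio_estimates(bx, sx, by, sy)
    w = 1.0 / ratio_se**2 if weighted else np.ones(j)
    w = w / w.sum()
    h = _mode_bandwidth(ratios) * bandwidth_factor
    beta = _kde_mode(ratios, w, h)
    rng = np.random.default_rng(seed)
    bxs, bys = _bootstrap_draws(bx, sx, by, sy, n_boot, rng)
    bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        r_b = bys[i] / bxs[i]
        w_b = (bxs[i] / sy) ** 2 if weighted else np.ones(j)
        w_b = w_b / w_b.sum()
        h_b = _mode_bandwidth(r_b) * bandwidth_factor
        boots[i] = _kde_mode(r_b, w_b, h_b)
    se = float(np.std(boots, ddof=1))
    return MRResults(
        method="weighted_mode" if weighted else "simple_mode",
        beta=float(beta), se=se, pvalue=_normal_p(beta, se), n_snps=j,
        aux={"bandwidth": float(h), "n_boot": n_boot}, **meta,
    )


_HUBER_K = 1.345
_HUBER_DELTA = 2 * stats.norm.cdf(_HUBER_K) - 1  # E[psi_k(Z) Z] for Z ~ N(0,1)


def mr_raps(pairs, overdispersion: bool = True, loss: str = "huber",
            max_iter: int = 200, tol: float = 1e-9, **meta) -> MRResults:
    """Robust adjusted profile score.

    Solves the profile-score estimating equations in (beta, tau2) where the
    standardized residual is ``t_j = (Gamma_j - beta*gamma_j) /
    sqrt(se_out_j^2 + beta^2 se_exp_j^2 + tau2)``; ``tau2`` is a systematic
    (overdispersed) pleiotropy variance, fixed at 0 when ``overdispersion``
    is off. ``loss="huber"`` (tuning 1.345) bounds the influence of
    outlying instruments; ``loss="l2"`` is the plain profile score. SE by
    the empirical sandwich of the beta-score."""
    bx, sx, by, sy = _as_arrays(pairs)
    j = len(bx)
    _require(j, 3, "raps")
    if loss not in ("l2", "huber"):
        raise ValueError(f"unknown loss {loss!r}")

    def psi(t):
        return t if loss == "l2" else np.clip(t, -_HUBER_K, _HUBER_K)

    delta = 1.0 if loss == "l2" else _HUBER_DELTA

    def t_and_parts(beta, tau2):
        v = sy**2 + beta**2 * sx**2 + tau2
        s = np.sqrt(v)
        r = by - beta * bx
        t = r / s
        dt_dbeta = -bx / s - t * (beta * sx**2) / v
        return t, dt_dbeta, v

    def g_beta(beta, tau2):
        t, dt, _ = t_and_parts(beta, tau2)
        return np.sum(psi(t) * dt)

    def g_tau2(beta, tau2):
        t, _, v = t_and_parts(beta, tau2)
        return np.sum((psi(t) * t - delta) / v)

    def solve_beta(tau2, beta_start):
        sol = optimize.root_scalar(
            g_beta, args=(tau2,), x0=beta_start, x1=beta_start + 0.1,
            method="secant", maxiter=max_iter,
        )
        if not sol.converged:
            raise ConvergenceError("mr_raps: beta step did not converge")
        return sol.root

    # alternate: beta given tau2, then tau2 given beta; g_tau2 is
    # decreasing in tau2, so a sign check at 0 decides the boundary case
    beta_hat = solve_beta(0.0, ivw(pairs).beta)
    tau2_hat = 0.0
    converged = True
    if overdispersion:
        for _ in range(max_iter):
            if g_tau2(beta_hat, 0.0) <= 0:
                tau2_new = 0.0
            else:
                hi = float(np.max(sy**2 + beta_hat**2 * sx**2))
                while g_tau2(beta_hat, hi) > 0:
                    hi *= 4
                    if hi > 1e8:
                        raise ConvergenceError("mr_raps: tau2 bracket failed")
                tau2_new = optimize.brentq(lambda u: g_tau2(beta_hat, u), 0.0, hi)
            beta_new = solve_beta(tau2_new, beta_hat)
            done = abs(beta_new - beta_hat) < tol and abs(tau2_new - tau2_hat) < tol
            beta_hat, tau2_hat = beta_new, tau2_new
            if done:
                break
        else:
            converged = False
    if not converged or not np.isfinite(beta_hat):
        raise ConvergenceError(
            f"mr_raps failed to converge (loss={loss}, overdispersion={overdispersion})"
        )
    # sandwich SE for beta at the solution, tau2 treated as fixed
    t, dt, _ = t_and_parts(beta_hat, tau2_hat)
    u = psi(t) * dt
    eps = 1e-6 * (1 + abs(beta_hat))
    tp, dtp, _ = t_and_parts(beta_hat + eps, tau2_hat)
    tm, dtm, _ = t_and_parts(beta_hat - eps, tau2_hat)
    a = (np.sum(psi(tp) * dtp) - np.sum(psi(tm) * dtm)) / (2 * eps)
    b = np.sum(u**2)
    se = float(np.sqrt(b) / abs(a))
    return MRResults(
        method="raps", beta=float(beta_hat), se=se,
        pvalue=_normal_p(beta_hat, se), n_snps=j,
        aux={"tau2": float(tau2_hat), "loss": loss,
             "overdispersion": overdispersion},
        **meta,
    )


def conmix(pairs, psi: float = 0.0, grid_halfwidth_sds: float = 5.0,
           grid_points: int = 1001, **meta) -> MRResults:
    """Contamination-mixture estimator.

    Per-variant ratio estimates are modelled as a mixture: valid
    instruments are normal about the causal effect theta with their delta
    SEs, invalid ones normal about 0 with variance inflated by ``psi^2``
    (``psi=0`` means the automatic rule 1.5 x SD of the ratio estimates).
    The profile log-likelihood assigns each variant to its better
    component at each grid theta; the estimate is the grid argmax and the
    95% CI is the theta set within 1.92 log-likelihood units of the
    maximum (the enclosing interval is reported and non-contiguity is
    flagged as multimodality)."""
    bx, sx, by, sy = _as_arrays(pairs)
    j = len(bx)
    if j == 1:
        res = wald_ratio(bx[0], sx[0], by[0], sy[0], **meta)
        res.method = "conmix"
        return res
    _require(j, 3, "conmix")
    ratios, sig = _ratio_estimates(bx, sx, by, sy)
    sd_r = float(np.std(ratios, ddof=1))
    psi_eff = psi if psi > 0 else 1.5 * sd_r
    if psi_eff <= 0:
        psi_eff = 1.0  # all ratios identical; any positive value works
    center = float(np.median(ratios))
    half = grid_halfwidth_sds * (sd_r if sd_r > 0 else np.mean(sig))
    grid = np.linspace(center - half, center + half, grid_points)

    def profile_ll(thetas):
        thetas = np.atleast_1d(thetas)
        ll_valid = stats.norm.logpdf(ratios[None, :], loc=thetas[:, None], scale=sig[None, :])
        ll_invalid = stats.norm.logpdf(
            ratios[None, :], loc=0.0, scale=np.sqrt(sig**2 + psi_eff**2)[None, :]
        )
        return np.maximum(ll_valid, ll_invalid).sum(axis=1), ll_valid >= ll_invalid

    ll, valid_mask = profile_ll(grid)
    i_max = int(np.argmax(ll))
    beta = float(grid[i_max])
    in_ci = ll >= ll[i_max] - 1.92
    ci_low = float(grid[in_ci].min())
    ci_high = float(grid[in_ci].max())
    # multimodal if the CI index set is non-contiguous
    idx = np.flatnonzero(in_ci)
    multimodal = bool(len(idx) and (np.diff(idx) > 1).any())
    se = (ci_high - ci_low) / (2 * Z95)
    ll0, _ = profile_ll(np.array([0.0]))
    lr = max(0.0, 2 * (ll[i_max] - ll0[0]))
    pvalue = float(stats.chi2.sf(lr, 1))
    return MRResults(
        method="conmix", beta=beta, se=float(se), pvalue=pvalue, n_snps=j,
        ci_low=ci_low, ci_high=ci_high,
        aux={
            "psi": float(psi_eff),
            "multimodal": multimodal,
            "n_valid": int(valid_mask[i_max].sum()),
            "valid_mask": valid_mask[i_max],
        },
        **meta,
    )


def _cml_fit_k(bx, sx, by, sy, k: int, beta0: float,
               max_iter: int = 200, tol: float = 1e-10):
    """Constrained ML with exactly k invalid instruments (free pleiotropy
    intercepts), by coordinate descent with the invalid set re-selected as
    the k largest standardized residuals each iterate."""
    j = len(bx)
    beta = beta0
    gamma = bx.copy()
    invalid = np.zeros(j, dtype=bool)
    for _ in range(max_iter):
        resid2 = (by - beta * gamma) ** 2 / sy**2
        new_invalid = np.zeros(j, dtype=bool)
        if k > 0:
            new_invalid[np.argsort(resid2)[-k:]] = True
        r = np.where(new_invalid, by - beta * gamma, 0.0)
        gamma = (bx / sx**2 + beta * (by - r) / sy**2) / (1 / sx**2 + beta**2 / sy**2)
        valid = ~new_invalid
        denom = np.sum(gamma[valid] ** 2 / sy[valid] ** 2)
        if denom <= 0:
            raise ConvergenceError(f"cml: degenerate valid set at k={k}")
        beta_new = np.sum(gamma[valid] * by[valid] / sy[valid] ** 2) / denom
        done = np.array_equal(new_invalid, invalid) and abs(beta_new - beta) < tol
        beta, invalid = beta_new, new_invalid
        if done:
            break
    else:
        raise ConvergenceError(f"cml coordinate descent did not converge at k={k}")
    r = np.where(invalid, by - beta * gamma, 0.0)
    nll = 0.5 * np.sum((bx - gamma) ** 2 / sx**2) + 0.5 * np.sum(
        (by - beta * gamma - r) ** 2 / sy**2
    )
    valid = ~invalid
    se = float(np.sum(gamma[valid] ** 2 / (sy[valid] ** 2 + beta**2 * sx[valid] ** 2)) ** -0.5)
    return beta, se, nll, invalid


def cml_ma(pairs, max_invalid: Optional[int] = None, n: Optional[float] = None,
           seed: Optional[int] = None, **meta) -> MRResults:
    """Constrained maximum likelihood with model averaging.

    For each candidate count K of invalid instruments the constrained
    Gaussian likelihood is maximized (K variants get free pleiotropy
    parameters, selected as the largest standardized residuals during
    coordinate descent); the per-K estimates are averaged with BIC
    weights. ``n`` is the GWAS sample size in the BIC penalty ``K log(n)``
    (the method's consistency argument is in the sample size, not the
    instrument count); when not supplied it defaults to 10,000, a typical
    GWAS scale — pass the smaller of the two study sizes when known."""
    bx, sx, by, sy = _as_arrays(pairs)
    j = len(bx)
    _require(j, 3, "cml_ma")
    if max_invalid is None:
        max_invalid = j - 2
    max_invalid = int(min(max_invalid, j - 2))
    n_eff = float(n) if n else 10_000.0
    beta0 = ivw(pairs).beta
    rows = []
    for k in range(0, max_invalid + 1):
        try:
            beta_k, se_k, nll_k, invalid_k = _cml_fit_k(bx, sx, by, sy, k, beta0)
        except ConvergenceError:
            continue
        bic = 2 * nll_k + k * np.log(n_eff)
        rows.append((k, beta_k, se_k, bic, invalid_k))
    if not rows:
        raise ConvergenceError("cml_ma: no K converged")
    bics = np.array([r[3] for r in rows])
    wts = np.exp(-(bics - bics.min()) / 2)
    wts = wts / wts.sum()
    betas = np.array([r[1] for r in rows])
    ses = np.array([r[2] for r in rows])
    beta = float(np.sum(wts * betas))
    # Buckland model-averaged SE: weighted sqrt of (within + between) variance
    se = float(np.sum(wts * np.sqrt(ses**2 + (betas - beta) ** 2)))
    k_best = rows[int(np.argmax(wts))][0]
    invalid_best = rows[int(np.argmax(wts))][4]
    snp_ids = pairs.snp_ids if isinstance(pairs, HarmonizedPairs) else list(range(j))
    return MRResults(
        method="cml_ma", beta=beta, se=se, pvalue=_normal_p(beta, se), n_snps=j,
        aux={
            "k_best": int(k_best),
            "bic_weights": {int(r[0]): float(w) for r, w in zip(rows, wts)},
            "invalid_snps": [snp_ids[i] for i in np.flatnonzero(invalid_best)],
            "n_eff": n_eff,
        },
        **meta,
    )


# ---------------------------------------------------------------------------
# model objects
# ---------------------------------------------------------------------------

_METHOD_FUNCS = {
    "ivw": ivw,
    "egger": mr_egger,
    "weighted_median": lambda pairs, seed=None, **kw: weighted_median(pairs, seed=seed, **kw),
    "simple_mode": lambda pairs, seed=None, **kw: mode_estimator(pairs, weighted=False, seed=seed, **kw),
    "weighted_mode": lambda pairs, seed=None, **kw: mode_estimator(pairs, weighted=True, seed=seed, **kw),
    "raps": mr_raps,
    "conmix": conmix,
    "cml_ma": cml_ma,
}

_STOCHASTIC_METHODS = {"weighted_median", "simple_mode", "weighted_mode"}


class MRModel:
    """Two-sample MR model for one exposure-outcome pair.

    Parameters
    ----------
    pairs
        A :class:`HarmonizedPairs`, or a 4-tuple of arrays
        ``(beta_exp, se_exp, beta_out, se_out)``.
    outcome_binary
        When True, results additionally report odds-ratio scale values.
    """

    def __init__(self, pairs, outcome_binary: Optional[bool] = None,
                 exposure_id: Optional[str] = None, outcome_id: Optional[str] = None):
        if isinstance(pairs, HarmonizedPairs):
            self.pairs = pairs
            self.exposure_id = exposure_id or pairs.exposure_id
            self.outcome_id = outcome_id or pairs.outcome_id
            self.outcome_binary = (
                pairs.outcome_binary if outcome_binary is None else outcome_binary
            )
        else:
            bx, sx, by, sy = _as_arrays(pairs)
            self.pairs = HarmonizedPairs.from_arrays(bx, sx, by, sy)
            self.exposure_id = exposure_id or "exposure"
            self.outcome_id = outcome_id or "outcome"
            self.outcome_binary = bool(outcome_binary)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, beta_exp: str = "beta_exp",
                       se_exp: str = "se_exp", beta_out: str = "beta_out",
                       se_out: str = "se_out", snp_id: str = "snp_id",
                       **kwargs) -> "MRModel":
        ids = df[snp_id] if snp_id in df.columns else None
        pairs = HarmonizedPairs.from_arrays(
            df[beta_exp], df[se_exp], df[beta_out], df[se_out], snp_ids=ids
        )
        return cls(pairs, **kwargs)

    @property
    def n_snps(self) -> int:
        return len(self.pairs)

    def _meta(self) -> dict:
        return {
            "outcome_binary": self.outcome_binary,
            "exposure_id": self.exposure_id,
            "outcome_id": self.outcome_id,
        }

    def fit(self, method: str = "ivw", seed: Optional[int] = None, **kwargs) -> MRResults:
        """Fit one estimator. ``seed`` is required by the bootstrap-based
        methods (median/mode) and forwarded to them."""
        if method == "wald":
            bx, sx, by, sy = self.pairs.arrays()
            _require(len(bx), 1, "wald")
            return wald_ratio(bx[0], sx[0], by[0], sy[0], **self._meta())
        try:
            func = _METHOD_FUNCS[method]
        except KeyError:
            raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHOD_FUNCS)}") from None
        if method in _STOCHASTIC_METHODS:
            kwargs["seed"] = seed
        elif method == "cml_ma" and seed is not None:
            kwargs.setdefault("seed", seed)
        return func(self.pairs, **kwargs, **self._meta())

    def fit_all(self, seed: Optional[int] = None,
                methods: Sequence[str] = PRIMARY_METHODS,
                include_robust: bool = False,
                consistency_methods: Sequence[str] = PRIMARY_METHODS) -> MRReport:
        """Run the estimator suite and return an :class:`MRReport`.

        Direction consistency is judged across ``consistency_methods``
        (by default the five primary methods, as in the screening rule)."""
        methods = list(methods)
        if include_robust:
            methods += [m for m in ROBUST_METHODS if m not in methods]
        estimates = []
        for i, m in enumerate(methods):
            sub_seed = None if seed is None else seed + 1000 * i
            estimates.append(self.fit(m, seed=sub_seed))
        return MRReport(
            estimates, exposure_id=self.exposure_id, outcome_id=self.outcome_id,
            consistency_methods=tuple(m for m in consistency_methods if m in methods),
        )


def run_suite(pairs, seed: Optional[int] = None, **kwargs) -> MRReport:
    """Functional wrapper: ``MRModel(pairs).fit_all(seed=seed)``."""
    return MRModel(pairs).fit_all(seed=seed, **kwargs)


class MVMRModel:
    """Multivariable MR: joint direct effects of E exposures.

    ``exposure_betas`` is a (J x E) matrix of per-variant exposure effects;
    the fit is weighted multiple regression of the outcome effects on the
    exposure columns without intercept, weights ``1/se_out^2``, with
    multiplicative random-effects SE inflation from the residual Q.
    """

    def __init__(self, exposure_betas, beta_out, se_out,
                 exposure_ids: Optional[Sequence[str]] = None,
                 outcome_id: str = "outcome", outcome_binary: bool = False,
                 snp_ids: Optional[Sequence[str]] = None):
        X = np.asarray(exposure_betas, dtype=float)
        self.X = X[:, None] if X.ndim == 1 else X
        self.by = np.asarray(beta_out, dtype=float)
        self.sy = np.asarray(se_out, dtype=float)
        if self.X.shape[0] != len(self.by):
            raise ValueError("exposure_betas rows must match beta_out length")
        self.exposure_ids = list(exposure_ids or [f"x{i}" for i in range(self.X.shape[1])])
        self.outcome_id = outcome_id
        self.outcome_binary = outcome_binary
        self.snp_ids = list(snp_ids or [f"snp{i}" for i in range(self.X.shape[0])])

    def fit(self) -> list[MRResults]:
        j, e = self.X.shape
        if j <= e:
            raise InsufficientInstrumentsError(
                f"MVMR needs more instruments ({j}) than exposures ({e})"
            )
        w = 1.0 / self.sy**2
        sw = np.sqrt(w)
        xw = self.X * sw[:, None]
        yw = self.by * sw
        if np.linalg.matrix_rank(xw) < e:
            raise CollinearityError("exposure design matrix is rank deficient")
        xtx = xw.T @ xw
        coefs = np.linalg.solve(xtx, xw.T @ yw)
        resid = yw - xw @ coefs
        q = float(resid @ resid)
        scale = max(1.0, np.sqrt(q / (j - e)))
        cov = np.linalg.inv(xtx) * scale**2
        out = []
        for i, xid in enumerate(self.exposure_ids):
            se = float(np.sqrt(cov[i, i]))
            out.append(
                MRResults(
                    method="mvmr_ivw", beta=float(coefs[i]), se=se,
                    pvalue=_normal_p(coefs[i], se), n_snps=j,
                    outcome_binary=self.outcome_binary,
                    exposure_id=xid, outcome_id=self.outcome_id,
                    aux={"Q": q, "Q_df": j - e, "re_scale": float(scale),
                         "adjusted_for": [x for x in self.exposure_ids if x != xid]},
                )
            )
        return out


def mvmr_ivw(exposure_betas, beta_out, se_out, **kwargs) -> list[MRResults]:
    """Functional wrapper around :class:`MVMRModel`."""
    return MVMRModel(exposure_betas, beta_out, se_out, **kwargs).fit()
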