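"""Two-step MR mediation with delta-method inference.

The indirect (mediated) effect of an exposure X on an outcome Y through a
mediator M is the product ``beta1 * beta2`` of the X->M and M->Y IVW
estimates; its standard error comes from the delta method, and the
proportion mediated divides the product by the total X->Y effect.
Candidate mediators are screened by the significance and
direction-consistency rules of the MR suite before the decomposition is
computed, and reverse-direction (bidirectional) checks flag possible
reverse causation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import MRMediateError
from .mr import MRReport, MRResults, Z95, ivw


def delta_product_se(beta1: float, se1: float, beta2: float, se2: float,
                     order: str = "first") -> tuple[float, float, float, float]:
    """Delta-method inference for the product ``beta1 * beta2``.

    First order: ``se = sqrt(beta1^2 se2^2 + beta2^2 se1^2)``; second
    order adds ``se1^2 se2^2`` under the root. Returns
    ``(se, ci_low, ci_high, pvalue)`` with a normal 95% CI and two-sided
    normal p.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    var = beta1**2 * se2**2 + beta2**2 * se1**2
    if order == "second":
        var += se1**2 * se2**2
    elif order != "first":
        raise ValueError(f"order must be 'first' or 'second', got {order!r}")
    se = float(np.sqrt(var))
    prod = beta1 * beta2
    ci_low, ci_high = prod - Z95 * se, prod + Z95 * se
    if se == 0:
        p = 1.0 if prod == 0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(prod) / se))
    return se, float(ci_low), float(ci_high), p


def proportion_mediated(mediation_effect: float, beta_total: float) -> float:
    """Mediated proportion as a percent: ``100 * (beta1*beta2) / beta_total``.

    Negative when the indirect and total effects have opposite signs
    (inconsistent mediation); the sign is preserved, not truncated.
    """
    if beta_total == 0:
        raise MRMediateError("proportion mediated undefined: total effect is 0")
    return 100.0 * mediation_effect / beta_total


@dataclass
class MediationResult:
    """Decomposition of one exposure -> mediator -> outcome chain."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta_total: float
    total_ci: tuple[float, float]
    beta1: float
    se1: float
    beta2: float
    se2: float
    mediation_effect: float
    mediation_se: float
    mediation_ci: tuple[float, float]
    mediation_p: float
    proportion_pct: float
    retained: bool = True
    reason: str = "retained"
    inconsistent: bool = False

    @classmethod
    def from_estimates(cls, total: MRResults, step1: MRResults, step2: MRResults,
                       order: str = "first") -> "MediationResult":
        se, lo, hi, p = delta_product_se(step1.beta, step1.se, step2.beta, step2.se, order)
        prod = step1.beta * step2.beta
        prop = proportion_mediated(prod, total.beta)
        return cls(
            exposure_id=step1.exposure_id,
            mediator_id=step1.outcome_id,
            outcome_id=step2.outcome_id,
            beta_total=total.beta, total_ci=total.conf_int(),
            beta1=step1.beta, se1=step1.se, beta2=step2.beta, se2=step2.se,
            mediation_effect=prod, mediation_se=se, mediation_ci=(lo, hi),
            mediation_p=p, proportion_pct=prop,
            inconsistent=bool(np.sign(prod) != np.sign(total.beta)),
        )

    def as_row(self) -> dict:
        return {
            "exposure": self.exposure_id,
            "mediator": self.mediator_id,
            "outcome": self.outcome_id,
            "total_effect": self.beta_total,
            "total_ci_low": self.total_ci[0],
            "total_ci_high": self.total_ci[1],
            "mediation_effect": self.mediation_effect,
            "mediation_ci_low": self.mediation_ci[0],
            "mediation_ci_high": self.mediation_ci[1],
            "mediation_p": self.mediation_p,
            "proportion_mediated_pct": self.proportion_pct,
            "retained": self.retained,
            "reason": self.reason,
        }


@dataclass
class MediationScreen:
    """Outcome of the three-step mediator screen with its funnel counts."""

    results: list[MediationResult]
    funnel: dict
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["mediator", "step", "reason"])
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_row() for r in self.results])

    def summary(self) -> str:
        funnel = " -> ".join(f"{k}:{v}" for k, v in self.funnel.items())
        body = self.to_frame().to_string(index=False) if self.results else "(none retained)"
        return f"Mediator screen funnel  {funnel}\n{body}"


def screen_mediators(
    exposure_to_candidates: Sequence[MRReport],
    candidates_to_outcome: Sequence[MRReport],
    total: MRResults,
    alpha: float = 0.05,
    order: str = "first",
    familywise: bool = False,
) -> MediationScreen:
    """Three-step mediator screen.

    Step 1 keeps candidates whose candidate->outcome IVW p is below
    ``alpha`` with direction consistency across the five primary methods;
    step 2 applies the same rule to exposure->candidate; step 3 keeps
    candidates whose indirect effect ``beta1*beta2`` shares the sign of
    the total effect. Retained candidates get a full delta-method
    decomposition; every exclusion is logged with its failing step.
    ``familywise=True`` Bonferroni-adjusts ``alpha`` by the candidate
    count in steps 1 and 2 (off by default: the screen is exploratory).
    """
    step1_by_med = {r.exposure_id: r for r in candidates_to_outcome}
    step2_by_med = {r.outcome_id: r for r in exposure_to_candidates}
    candidates = list(step1_by_med)
    missing = [m for m in candidates if m not in step2_by_med]
    if missing:
        raise MRMediateError(f"candidates missing exposure->candidate reports: {missing}")
    alpha_eff = alpha / len(candidates) if familywise and candidates else alpha

    excl: list[tuple[str, str, str]] = []
    results: list[MediationResult] = []
    n_pass1 = n_pass2 = n_pass3 = 0
    for med in candidates:
        r_mo = step1_by_med[med]
        if not (r_mo.ivw.pvalue < alpha_eff and r_mo.direction_consistent):
            excl.append((med, "candidate_to_outcome", "not_significant_or_inconsistent"))
            continue
        n_pass1 += 1
        r_em = step2_by_med[med]
        if not (r_em.ivw.pvalue < alpha_eff and r_em.direction_consistent):
            excl.append((med, "exposure_to_candidate", "not_significant_or_inconsistent"))
            continue
        n_pass2 += 1
        res = MediationResult.from_estimates(total, r_em.ivw, r_mo.ivw, order=order)
        if res.inconsistent:
            excl.append((med, "sign_consistency", "direction_inconsistent"))
            continue
        n_pass3 += 1
        results.append(res)
    funnel = {
        "candidates": len(candidates),
        "outcome_associated": n_pass1,
        "exposure_associated": n_pass2,
        "direction_consistent": n_pass3,
    }
    return MediationScreen(
        results=results, funnel=funnel,
        exclusions=pd.DataFrame(excl, columns=["mediator", "step", "reason"]),
    )


@dataclass
class BidirectionalReport:
    """Reverse-direction MR check for one trait pair."""

    forward: Optional[MRResults]
    reverse: Optional[MRResults]
    testable: bool
    reverse_flag: bool  # True when reverse IVW p < alpha

    def summary(self) -> str:
        if not self.testable:
            return "bidirectional check: untestable (no reverse instruments)"
        flag = "POSSIBLE REVERSE CAUSATION" if self.reverse_flag else "no reverse signal"
        return (
            f"bidirectional check: forward beta={self.forward.beta:.4f} "
            f"(p={self.forward.pvalue:.3g}); reverse beta={self.reverse.beta:.4f} "
            f"(p={self.reverse.pvalue:.3g}) -> {flag}"
        )


def bidirectional_check(forward_pairs, reverse_pairs, alpha: float = 0.05) -> BidirectionalReport:
    """IVW in both directions; flags the pair when the reverse-direction
    IVW p-value is below ``alpha``. An empty reverse instrument set is
    reported as untestable, not an error."""
    forward = ivw(forward_pairs) if forward_pairs is not None and len(forward_pairs) else None
    if reverse_pairs is None or len(reverse_pairs) == 0:
        return BidirectionalReport(forward=forward, reverse=None, testable=False, reverse_flag=False)
    reverse = ivw(reverse_pairs)
    return BidirectionalReport(
        forward=forward, reverse=reverse, testable=True,
        reverse_flag=bool(reverse.pvalue < alpha),
    )
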