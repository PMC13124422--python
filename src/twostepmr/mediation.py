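"""Two-step mediation analysis by the product-of-coefficients method.

The total causal effect beta of the exposure on the outcome is decomposed
into an indirect effect routed through a mediator (beta1 * beta2, the
product of the exposure->mediator and mediator->outcome effects) and a
direct effect (total - indirect). The mediated proportion is the indirect
effect as a share of the total, reported in percent. Confidence intervals
use the first-order delta method treating the three estimates as
independent, which the two-sample design with non-overlapping samples
justifies; a Monte-Carlo interval is available as a cross-check.

A pathway is flagged valid only when the indirect effect has the same sign
as the total effect and both step estimates pass the screening threshold;
invalid pathways are retained with a reason rather than dropped, so
sign-discordant products remain visible in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .mr_core import MREstimate, Z95

__all__ = [
    "MediationResult",
    "UndefinedProportionError",
    "mediate_pathway",
    "monte_carlo_proportion_ci",
    "screen_mediators",
]


class UndefinedProportionError(ValueError):
    """The total effect is zero; a mediated proportion is undefined."""


@dataclass
class MediationResult:
    exposure: str
    mediator: str
    outcome: str
    total: float
    total_p: float
    step1: float
    step1_p: float
    step2: float
    step2_p: float
    indirect: float
    indirect_se: float
    indirect_ci: tuple[float, float]
    direct: float
    proportion: float  # percent of the total effect
    proportion_se: float
    proportion_ci: tuple[float, float]
    valid: bool
    invalid_reason: str | None = None

    def __post_init__(self) -> None:
        if abs(self.indirect - self.step1 * self.step2) > 1e-12:
            raise ValueError("indirect must equal step1*step2")
        if abs(self.direct - (self.total - self.indirect)) > 1e-12:
            raise ValueError("direct must equal total - indirect")
        if abs(self.proportion * self.total - self.indirect * 100.0) > 1e-9:
            raise ValueError("proportion inconsistent with indirect/total")


def mediate_pathway(
    total: MREstimate,
    step1: MREstimate,
    step2: MREstimate,
    exposure: str = "",
    mediator: str = "",
    outcome: str = "",
    screen_p: float = 0.05,
) -> MediationResult:
    """Decompose a total effect through one mediator.

    ``total`` is the exposure->outcome estimate, ``step1`` the
    exposure->mediator estimate (beta1), ``step2`` the mediator->outcome
    estimate (beta2). Delta-method variances:

    * var(beta1*beta2) = beta1^2 var(beta2) + beta2^2 var(beta1)
    * the proportion p = 100*beta1*beta2/beta uses the first-order gradient
      over (beta1, beta2, beta), all treated as independent.
    """
    if total.beta == 0:
        raise UndefinedProportionError("total effect is zero")
    b, b1, b2 = total.beta, step1.beta, step2.beta
    v, v1, v2 = total.se**2, step1.se**2, step2.se**2

    indirect = b1 * b2
    direct = b - indirect
    var_ind = b1**2 * v2 + b2**2 * v1
    se_ind = float(np.sqrt(var_ind))

    proportion = 100.0 * indirect / b
    grad = np.array([100.0 * b2 / b, 100.0 * b1 / b, -100.0 * indirect / b**2])
    var_prop = float(grad @ (np.array([v1, v2, v]) * grad))
    se_prop = float(np.sqrt(var_prop))

    reasons = []
    if np.sign(indirect) != np.sign(b):
        reasons.append("indirect effect opposite in sign to total effect")
    if step1.pvalue >= screen_p:
        reasons.append(f"step-1 p {step1.pvalue:.3g} above screen {screen_p:g}")
    if step2.pvalue >= screen_p:
        reasons.append(f"step-2 p {step2.pvalue:.3g} above screen {screen_p:g}")

    return MediationResult(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        total=b,
        total_p=total.pvalue,
        step1=b1,
        step1_p=step1.pvalue,
        step2=b2,
        step2_p=step2.pvalue,
        indirect=indirect,
        indirect_se=se_ind,
        indirect_ci=(indirect - Z95 * se_ind, indirect + Z95 * se_ind),
        direct=direct,
        proportion=proportion,
        proportion_se=se_prop,
        proportion_ci=(proportion - Z95 * se_prop, proportion + Z95 * se_prop),
        valid=not reasons,
        invalid_reason="; ".join(reasons) or None,
    )


def monte_carlo_proportion_ci(
    total: MREstimate,
    step1: MREstimate,
    step2: MREstimate,
    n_draws: int = 1_000_000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Monte-Carlo CI for the mediated proportion (percent), as a delta-method check.

    Draws the three estimates independently from their normal sampling
    distributions and takes quantiles of 100*b1*b2/b.
    """
    rng = np.random.default_rng(seed)
    b = rng.normal(total.beta, total.se, n_draws)
    b1 = rng.normal(step1.beta, step1.se, n_draws)
    b2 = rng.normal(step2.beta, step2.se, n_draws)
    prop = 100.0 * b1 * b2 / b
    a = (1 - level) / 2
    return float(np.quantile(prop, a)), float(np.quantile(prop, 1 - a))


def screen_mediators(
    step1_results: Mapping[str, MREstimate] | Iterable[tuple[str, MREstimate]],
    p_threshold: float = 0.01,
) -> dict:
    """Select mediators whose step-1 estimate passes the p-value screen.

    Returns the passing labels partitioned by effect direction:
    ``{"selected": [...], "positive": [...], "negative": [...]}`` where
    positive/negative refer to the sign of the step-1 effect (OR above or
    below 1 on the odds scale).
    """
    items = step1_results.items() if isinstance(step1_results, Mapping) else step1_results
    selected, positive, negative = [], [], []
    for label, est in items:
        if est.pvalue < p_threshold:
            selected.append(label)
            (positive if est.beta > 0 else negative).append(label)
    return {"selected": selected, "positive": positive, "negative": negative}
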