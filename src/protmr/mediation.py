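"""Network (two-step) MR mediation: proportion of a total effect carried
through a mediator, with delta-method uncertainty."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MediationResult:
    beta1: float
    se1: float
    beta2: float
    se2: float
    beta_te: float
    se_te: float
    pm: float
    se_pm: float
    ci95: tuple[float, float]
    pm_capped: float  # display value clipped to [0, 1]
    consistent: bool


def consistency_check(beta1: float, beta2: float, beta_te: float) -> bool:
    """True when the indirect (beta1*beta2) and total effects share sign and
    all three estimates are nonzero."""
    if beta1 == 0 or beta2 == 0 or beta_te == 0:
        return False
    return bool(np.sign(beta1 * beta2) == np.sign(beta_te))


def proportion_mediated(
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    beta_te: float,
    se_te: float,
) -> MediationResult:
    """Proportion mediated beta1*beta2/beta_te with first-order delta-method
    variance, treating the three estimates as independent (non-overlapping
    GWAS cohorts)."""
    if beta_te == 0:
        raise ZeroDivisionError("proportion mediated undefined: beta_te = 0")
    for name, s in (("se1", se1), ("se2", se2), ("se_te", se_te)):
        if s <= 0:
            raise ValueError(f"{name} must be positive")
    pm = beta1 * beta2 / beta_te
    var_pm = (
        (beta2 / beta_te) ** 2 * se1**2
        + (beta1 / beta_te) ** 2 * se2**2
        + (beta1 * beta2 / beta_te**2) ** 2 * se_te**2
    )
    se_pm = float(np.sqrt(var_pm))
    ci = (pm - 1.96 * se_pm, pm + 1.96 * se_pm)
    return MediationResult(
        beta1=beta1,
        se1=se1,
        beta2=beta2,
        se2=se2,
        beta_te=beta_te,
        se_te=se_te,
        pm=pm,
        se_pm=se_pm,
        ci95=ci,
        pm_capped=float(np.clip(pm, 0.0, 1.0)),
        consistent=consistency_check(beta1, beta2, beta_te),
    )
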