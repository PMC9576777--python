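"""Two-step MR mediation: decompose a total effect into indirect and direct.

With a total exposure-to-outcome effect beta_EO from the primary MR, an
exposure-to-mediator effect beta_EM and a mediator-to-outcome effect
beta_MO from the two-step MR, the indirect effect through the mediator
is the product beta_EM * beta_MO (the product method) with the
delta-method standard error, and the proportion mediated is
indirect / beta_EO.  All arithmetic is on the linear (log-odds for
binary outcomes) scale; odds ratios must be logged on ingestion — the
product method is not coherent on the OR scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import Z95, MREstimate

__all__ = ["MediationResult", "product_indirect", "proportion_mediated", "mediate"]


@dataclass(frozen=True)
class MediationResult:
    """Full decomposition for one exposure-mediator-outcome triple."""

    beta_EO: float
    se_EO: float
    beta_EM: float
    se_EM: float
    beta_MO: float
    se_MO: float
    indirect: float
    se_indirect: float
    ci_indirect: tuple[float, float]
    proportion: float
    ci_proportion: tuple[float, float] | None
    sign_mismatch: bool
    proportion_out_of_range: bool
    proportion_unstable: bool


def product_indirect(
    beta_EM: float, se_EM: float, beta_MO: float, se_MO: float
) -> tuple[float, float, tuple[float, float]]:
    """Indirect effect by the product method with its delta-method SE.

    indirect = beta_EM * beta_MO;
    se = sqrt(beta_EM^2 se_MO^2 + beta_MO^2 se_EM^2); 95% normal CI.
    """
    if se_EM <= 0 or se_MO <= 0:
        raise ValueError("standard errors must be positive")
    indirect = beta_EM * beta_MO
    se = float(np.sqrt(beta_EM**2 * se_MO**2 + beta_MO**2 * se_EM**2))
    ci = (indirect - Z95 * se, indirect + Z95 * se)
    return float(indirect), se, ci


def proportion_mediated(indirect: float, beta_EO: float) -> tuple[float, dict[str, bool]]:
    """Proportion of the total effect running through the mediator.

    Computed on the log-odds/linear scale as indirect / total.  Flags:
    ``sign_mismatch`` when indirect and total point in opposite
    directions, ``proportion_out_of_range`` when |proportion| > 1.
    """
    if beta_EO == 0:
        raise ZeroDivisionError("total effect is zero; proportion undefined")
    prop = indirect / beta_EO
    flags = {
        "sign_mismatch": bool(indirect * beta_EO < 0),
        "proportion_out_of_range": bool(abs(prop) > 1),
    }
    return float(prop), flags


def mediate(
    total: MREstimate | tuple[float, float],
    exposure_mediator: MREstimate | tuple[float, float],
    mediator_outcome: MREstimate | tuple[float, float],
) -> MediationResult:
    """Assemble the full mediation decomposition from three MR estimates.

    Accepts :class:`~pqtlmr.estimators.MREstimate` objects or bare
    ``(beta, se)`` tuples for the total (E->O), exposure->mediator and
    mediator->outcome effects.  The proportion CI is a delta-method ratio
    CI, flagged unstable when the total effect's |z| < 2.
    """
    def unpack(x):
        return (x.theta, x.se) if isinstance(x, MREstimate) else (float(x[0]), float(x[1]))

    beta_EO, se_EO = unpack(total)
    beta_EM, se_EM = unpack(exposure_mediator)
    beta_MO, se_MO = unpack(mediator_outcome)

    indirect, se_ind, ci_ind = product_indirect(beta_EM, se_EM, beta_MO, se_MO)
    prop, flags = proportion_mediated(indirect, beta_EO)

    unstable = abs(beta_EO / se_EO) < 2
    # delta-method variance of a ratio, treating numerator and denominator
    # as independent (they come from separate MR fits)
    var_ratio = (se_ind**2 / beta_EO**2) + (indirect**2 * se_EO**2 / beta_EO**4)
    se_prop = float(np.sqrt(var_ratio))
    ci_prop = (prop - Z95 * se_prop, prop + Z95 * se_prop)

    return MediationResult(
        beta_EO=beta_EO, se_EO=se_EO, beta_EM=beta_EM, se_EM=se_EM,
        beta_MO=beta_MO, se_MO=se_MO,
        indirect=indirect, se_indirect=se_ind, ci_indirect=ci_ind,
        proportion=prop, ci_proportion=ci_prop,
        sign_mismatch=flags["sign_mismatch"],
        proportion_out_of_range=flags["proportion_out_of_range"],
        proportion_unstable=bool(unstable),
    )
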