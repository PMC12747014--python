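"""Two-step mediation decomposition with delta-method proportion intervals.

A two-step MR mediation analysis combines three causal estimates obtained
from separate GWAS samples:

* beta1 — exposure -> mediator (step 1, univariable MR),
* beta2 — mediator -> outcome adjusted for the exposure (step 2,
  multivariable MR),
* beta0 — total exposure -> outcome effect.

The indirect (mediated) effect is the product beta1*beta2, the direct
effect is the remainder beta0 - beta1*beta2, and the proportion mediated is
beta1*beta2/beta0.  Standard errors propagate by the delta method assuming
the three estimates are independent (they come from non-overlapping GWAS
samples); the proportion SE uses the full three-term form

    se(p)^2 = (beta2/beta0)^2 se1^2 + (beta1/beta0)^2 se2^2
              + (beta1 beta2 / beta0^2)^2 se0^2

which reduces to p * sqrt((se1/b1)^2 + (se2/b2)^2 + (se0/b0)^2) away from
zeros and degrades gracefully (product-term only) when beta1 or beta2 is 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

logger = logging.getLogger("mrmediate")

Z95 = 1.959963984540054


class MediationError(ValueError):
    """Mediation preconditions violated (zero total effect, bad SEs)."""


@dataclass(frozen=True)
class MediationEstimate:
    """Effect decomposition for one (exposure, mediator, outcome) triple."""

    beta1: float
    se1: float
    beta2: float
    se2: float
    beta0: float
    se0: float
    indirect: float
    indirect_se: float
    direct: float
    proportion: float
    proportion_se: float
    prop_ci_low: float
    prop_ci_high: float
    sign_inconsistent: bool


def two_step_mediation(
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    beta0: float,
    se0: float,
) -> MediationEstimate:
    """Decompose a total effect into mediated and direct components.

    The decomposition identities (direct + indirect = beta0 and
    proportion * beta0 = indirect) hold to machine precision by
    construction.  Opposite signs of the indirect and total effects are
    flagged (``sign_inconsistent``), not suppressed: the proportion is then
    negative and should be interpreted with care.
    """
    if se1 <= 0 or se2 <= 0 or se0 <= 0:
        raise MediationError("all standard errors must be strictly positive")
    if beta0 == 0:
        raise MediationError("total effect beta0 must be nonzero")
    indirect = beta1 * beta2
    indirect_se = math.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2)
    direct = beta0 - indirect
    proportion = indirect / beta0
    # Full three-term delta method; the partial derivatives below are exact
    # at beta1=0 or beta2=0, where only the product term survives.
    var = (
        (beta2 / beta0) ** 2 * se1**2
        + (beta1 / beta0) ** 2 * se2**2
        + (indirect / beta0**2) ** 2 * se0**2
    )
    proportion_se = math.sqrt(var)
    sign_inconsistent = indirect != 0 and (indirect > 0) != (beta0 > 0)
    if sign_inconsistent:
        logger.warning(
            "mediation: indirect effect (%.4g) and total effect (%.4g) have "
            "opposite signs; proportion is negative",
            indirect,
            beta0,
        )
    return MediationEstimate(
        beta1=beta1,
        se1=se1,
        beta2=beta2,
        se2=se2,
        beta0=beta0,
        se0=se0,
        indirect=indirect,
        indirect_se=indirect_se,
        direct=direct,
        proportion=proportion,
        proportion_se=proportion_se,
        prop_ci_low=proportion - Z95 * proportion_se,
        prop_ci_high=proportion + Z95 * proportion_se,
        sign_inconsistent=sign_inconsistent,
    )


def mediation_table(
    rows: Sequence[tuple[str, str, str, float, float, float, float, float, float]],
) -> pd.DataFrame:
    """Batch mediation report, one row per (exposure, mediator, outcome).

    Each input row is (exposure, mediator, outcome, beta1, se1, beta2, se2,
    beta0, se0).  Output rows are sorted by descending proportion within
    each outcome, with proportions formatted as percentages with 95% CIs.
    Malformed rows are recorded in ``df.attrs['errors']`` (list of
    (row_index, message)) and the remainder processed.
    """
    out = []
    errors: list[tuple[int, str]] = []
    for i, (exposure, mediator, outcome, b1, s1, b2, s2, b0, s0) in enumerate(rows):
        try:
            m = two_step_mediation(b1, s1, b2, s2, b0, s0)
        except MediationError as exc:
            errors.append((i, str(exc)))
            logger.warning("mediation_table: row %d skipped (%s)", i, exc)
            continue
        out.append(
            {
                "exposure": exposure,
                "beta1": m.beta1,
                "se1": m.se1,
                "mediator": mediator,
                "beta2": m.beta2,
                "se2": m.se2,
                "outcome": outcome,
                "beta0": m.beta0,
                "se0": m.se0,
                "indirect": m.indirect,
                "indirect_se": m.indirect_se,
                "direct": m.direct,
                "proportion": m.proportion,
                "proportion_se": m.proportion_se,
                "prop_ci_low": m.prop_ci_low,
                "prop_ci_high": m.prop_ci_high,
                "sign_inconsistent": m.sign_inconsistent,
                "proportion_pct": (
                    f"{100 * m.proportion:.2f}% "
                    f"({100 * m.prop_ci_low:.2f}%, {100 * m.prop_ci_high:.2f}%)"
                ),
            }
        )
    df = pd.DataFrame(out)
    if not df.empty:
        df = (
            df.sort_values(
                ["outcome", "proportion"], ascending=[True, False], kind="mergesort"
            )
            .reset_index(drop=True)
        )
    df.attrs["errors"] = errors
    return df
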