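"""Heterogeneity, pleiotropy, and influence diagnostics for an MR analysis.

Cochran's Q measures dispersion of the per-SNP Wald ratios around the
pooled estimate (excess Q suggests pleiotropy or invalid instruments), the
MR-Egger intercept tests for directional pleiotropy, and leave-one-out
re-estimation flags results driven by a single SNP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .estimators import EstimationError, MREstimate, ivw, mr_egger
from .sumstats import HarmonizedInstrument, usable_instruments


def cochran_q(
    instruments: Sequence[HarmonizedInstrument], pooled_beta: float
) -> tuple[float, int, float, float]:
    """Cochran's Q over per-SNP Wald ratios against a pooled estimate.

    Q = sum w_j (r_j - pooled)^2 with r_j = Gamma_j/gamma_j and
    w_j = gamma_j^2/se_out_j^2 (the inverse first-order ratio variance, i.e.
    the IVW weight).  Returns (q, df, pvalue, i2) with df = n - 1 and
    I^2 = max(0, (Q - df)/Q).
    """
    use = usable_instruments(instruments)
    n = len(use)
    if n < 2:
        raise EstimationError("cochran_q requires at least 2 usable instruments")
    bx = np.array([h.beta_exp for h in use])
    by = np.array([h.beta_out for h in use])
    sy = np.array([h.se_out for h in use])
    ratios = by / bx
    w = bx**2 / sy**2
    q = float(np.sum(w * (ratios - pooled_beta) ** 2))
    df = n - 1
    pvalue = float(min(max(stats.chi2.sf(q, df), 1e-300), 1.0))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return q, df, pvalue, i2


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument],
    re_mode: str = "multiplicative_random",
) -> dict[str, MREstimate]:
    """IVW re-estimated with each SNP left out in turn; one entry per SNP."""
    use = usable_instruments(instruments)
    if len(use) < 2:
        raise EstimationError("leave_one_out requires at least 2 usable instruments")
    out: dict[str, MREstimate] = {}
    for i, h in enumerate(use):
        rest = use[:i] + use[i + 1 :]
        out[h.snp_id] = ivw(rest, re_mode=re_mode)
    return out


def pleiotropy_test(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[float, float, float]:
    """MR-Egger intercept test for directional pleiotropy.

    Returns (intercept, se, pvalue); the p-value is two-sided t with n-2 df.
    """
    _, intercept = mr_egger(instruments)
    return intercept.beta, intercept.se, intercept.pvalue


@dataclass
class SensitivityReport:
    """Bundled diagnostics for one exposure/outcome instrument set."""

    q: float
    q_df: int
    q_pvalue: float
    i2: float
    egger_intercept: float = math.nan
    egger_intercept_se: float = math.nan
    egger_intercept_p: float = math.nan
    loo: dict[str, MREstimate] = field(default_factory=dict)


def sensitivity_report(
    instruments: Sequence[HarmonizedInstrument],
    pooled_beta: Optional[float] = None,
    re_mode: str = "multiplicative_random",
) -> SensitivityReport:
    """Q, Egger intercept (when >= 3 instruments), and leave-one-out map.

    ``pooled_beta`` defaults to the headline IVW estimate on the same
    instruments.
    """
    use = usable_instruments(instruments)
    if pooled_beta is None:
        pooled_beta = ivw(use, re_mode=re_mode).beta
    q, df, p, i2 = cochran_q(use, pooled_beta)
    report = SensitivityReport(q=q, q_df=df, q_pvalue=p, i2=i2)
    if len(use) >= 3:
        b, se, pv = pleiotropy_test(use)
        report.egger_intercept = b
        report.egger_intercept_se = se
        report.egger_intercept_p = pv
    report.loo = leave_one_out(use, re_mode=re_mode)
    return report
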