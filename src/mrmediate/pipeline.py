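"""End-to-end screening pipeline: total effects, mediator screen, mediation report.

The study design this orchestrates:

1. *Total effect* (beta0): univariable MR of the outcome on the exposure
   using genome-wide-significant, clumped, strong instruments.
2. *Step 1* (beta1): univariable MR of each candidate mediator on the
   exposure, with the relaxed p-value fallback when instruments are scarce.
3. *Reverse-MR guard*: mediator -> exposure MR; mediators with a
   significant reverse effect are disqualified (reverse causation).
4. *Step 2* (beta2): multivariable IVW of the outcome on (exposure,
   mediator) jointly, so beta2 is the mediator's effect adjusted for the
   exposure.
5. *Mediation report*: beta1*beta2/beta0 with delta-method CIs for every
   qualified (mediator, outcome) pair; outcomes with a non-significant
   total effect get no rows.

Qualification requires significant IVW estimates at steps 1 and 2 and a
non-significant reverse estimate.  Significance is nominal (alpha) by
default, mirroring screens that apply no multiplicity correction;
Benjamini-Hochberg FDR across mediators is available via ``mtc='bh_fdr'``
and is the recommended setting for wide panels.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy
from scipy.stats import false_discovery_control

from . import __version__
from .estimators import (
    EstimationError,
    MREstimate,
    ivw,
    mode_estimate,
    mr_egger,
    mvmr_ivw,
    wald_ratio,
    weighted_median,
)
from .instruments import (
    InstrumentSelection,
    LDMatrix,
    filter_weak,
    ld_clump,
    select_by_pvalue,
)
from .mediation import mediation_table
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import (
    HarmonizedInstrument,
    SummaryStatsTable,
    _harmonize_pair,
    harmonize,
    usable_instruments,
)

logger = logging.getLogger("mrmediate")


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and method settings for the full screen (defaults per the design)."""

    p_threshold: float = 5e-8
    fallback_p: float = 1e-5
    clump_r2: float = 0.01
    clump_kb: int = 10_000
    f_min: float = 10.0
    min_snps: int = 3
    alpha: float = 0.05
    mtc: str = "none"
    seed: int = 0
    re_mode: str = "multiplicative_random"
    phi: float = 1.0
    n_boot: int = 1000
    palindrome_eaf_window: float = 0.08

    def validate(self) -> None:
        problems = []
        if not (0 < self.p_threshold <= self.fallback_p < 1):
            problems.append("need 0 < p_threshold <= fallback_p < 1")
        if not (0 <= self.clump_r2 <= 1):
            problems.append("clump_r2 must be in [0, 1]")
        if self.clump_kb < 0 or self.f_min < 0 or self.min_snps < 1:
            problems.append("clump_kb, f_min >= 0 and min_snps >= 1 required")
        if not (0 < self.alpha < 1):
            problems.append("alpha must be in (0, 1)")
        if self.mtc not in ("none", "bh_fdr"):
            problems.append("mtc must be 'none' or 'bh_fdr'")
        if self.re_mode not in ("fixed", "multiplicative_random"):
            problems.append("re_mode must be 'fixed' or 'multiplicative_random'")
        if self.phi <= 0 or self.n_boot < 1:
            problems.append("phi > 0 and n_boot >= 1 required")
        if problems:
            raise ValueError("; ".join(problems))


def select_instruments(
    table: SummaryStatsTable, ld: LDMatrix, cfg: ScreenConfig
) -> InstrumentSelection:
    """The full instrument ladder: p-value filter, LD clumping, weak-F filter.

    The returned selection partitions every SNP in the table between
    ``kept`` and ``dropped`` (reasons: p_threshold, no_ld_info,
    clumped_with:<snp>, weak_instrument).
    """
    cfg.validate()
    subset, fallback_used = select_by_pvalue(
        table, cfg.p_threshold, cfg.fallback_p, cfg.min_snps
    )
    threshold = cfg.fallback_p if fallback_used else cfg.p_threshold
    dropped = {v.snp_id: "p_threshold" for v in table if v.pvalue >= threshold}
    clumped = ld_clump(subset, ld, cfg.clump_r2, cfg.clump_kb, dropped=dropped)
    weak = filter_weak(clumped, cfg.f_min)
    dropped.update(weak.dropped)
    sel = InstrumentSelection(
        kept=weak.kept,
        p_threshold_used=threshold,
        fallback_used=fallback_used,
        f_statistics=weak.f_statistics,
        dropped=dropped,
        flag=None if weak.kept else "no_instruments",
    )
    assert len(sel.kept) + len(sel.dropped) == len(table), "selection must partition"
    return sel


@dataclass
class TotalEffectResult:
    """All-method estimates plus diagnostics for one exposure -> outcome pair."""

    estimates: dict[str, MREstimate]
    diagnostics: Optional[SensitivityReport]
    selection: InstrumentSelection
    instruments: list[HarmonizedInstrument]
    flag: Optional[str] = None

    @property
    def headline(self) -> Optional[MREstimate]:
        return self.estimates.get("ivw")


def run_total_effect(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LDMatrix,
    cfg: ScreenConfig,
) -> TotalEffectResult:
    """Univariable MR with the full estimator battery and sensitivity checks.

    IVW (in the configured random-effects flavor) is the headline estimate;
    MR-Egger, weighted median, and the two modes run when >= 3 instruments
    are available, the single-instrument Wald ratio otherwise.
    """
    sel = select_instruments(exposure, ld, cfg)
    if not sel.kept:
        return TotalEffectResult({}, None, sel, [], flag="no_instruments")
    harmonized = harmonize(sel.kept, outcome, cfg.palindrome_eaf_window)
    use = usable_instruments(harmonized)
    if not use:
        return TotalEffectResult({}, None, sel, harmonized, flag="no_instruments")
    estimates: dict[str, MREstimate] = {}
    estimates["ivw"] = ivw(use, re_mode=cfg.re_mode)
    if len(use) == 1:
        estimates["wald"] = wald_ratio(use[0])
        return TotalEffectResult(estimates, None, sel, harmonized)
    if len(use) >= 3:
        slope, intercept = mr_egger(use)
        estimates["egger_slope"] = slope
        estimates["egger_intercept"] = intercept
        estimates["weighted_median"] = weighted_median(
            use, n_boot=cfg.n_boot, seed=cfg.seed
        )
        estimates["simple_mode"] = mode_estimate(
            use, "simple", phi=cfg.phi, n_boot=cfg.n_boot, seed=cfg.seed
        )
        estimates["weighted_mode"] = mode_estimate(
            use, "weighted", phi=cfg.phi, n_boot=cfg.n_boot, seed=cfg.seed
        )
    diagnostics = sensitivity_report(
        use, pooled_beta=estimates["ivw"].beta, re_mode=cfg.re_mode
    )
    return TotalEffectResult(estimates, diagnostics, sel, harmonized)


def _mvmr_step2(
    exposure: SummaryStatsTable,
    mediator: SummaryStatsTable,
    outcome: SummaryStatsTable,
    exp_kept,
    med_kept,
    cfg: ScreenConfig,
) -> tuple[MREstimate, MREstimate]:
    """Multivariable IVW of the outcome on (exposure, mediator).

    Instruments are the union of the exposure's and the mediator's selected
    SNPs; every SNP must resolve in all three tables and is oriented to the
    exposure table's effect allele.  Returns (exposure direct-effect
    estimate, mediator adjusted-effect estimate beta2).
    """
    snp_ids = list(dict.fromkeys([v.snp_id for v in exp_kept] + [v.snp_id for v in med_kept]))
    bx, bm, by, sy = [], [], [], []
    for sid in snp_ids:
        exp_rec = exposure.get(sid)
        med_rec = mediator.get(sid)
        out_rec = outcome.get(sid)
        if exp_rec is None or med_rec is None or out_rec is None:
            continue
        hm = _harmonize_pair(exp_rec, med_rec, cfg.palindrome_eaf_window)
        ho = _harmonize_pair(exp_rec, out_rec, cfg.palindrome_eaf_window)
        if not (hm.usable and ho.usable):
            continue
        bx.append(exp_rec.beta)
        bm.append(hm.beta_out)
        by.append(ho.beta_out)
        sy.append(ho.se_out)
    if len(bx) <= 2:
        raise EstimationError("mvmr step 2 needs more than 2 resolvable instruments")
    X = np.column_stack([bx, bm])
    direct_est, med_est = mvmr_ivw(
        X, np.array(by), np.array(sy), ["exposure", "mediator"], re_mode=cfg.re_mode
    )
    return direct_est, med_est


def _adjust(pvalues: list[float], mtc: str) -> list[float]:
    if mtc == "bh_fdr" and pvalues:
        return list(false_discovery_control(np.asarray(pvalues), method="bh"))
    return list(pvalues)


@dataclass
class ScreenResult:
    """Everything the mediator screen produced, plus filter-count bookkeeping."""

    config: ScreenConfig
    total: dict[str, MREstimate] = field(default_factory=dict)
    total_diagnostics: dict[str, SensitivityReport] = field(default_factory=dict)
    step1: dict[str, MREstimate] = field(default_factory=dict)
    step1_adj_p: dict[str, float] = field(default_factory=dict)
    step1_diagnostics: dict[str, SensitivityReport] = field(default_factory=dict)
    reverse: dict[str, Optional[MREstimate]] = field(default_factory=dict)
    step2: dict[tuple[str, str], MREstimate] = field(default_factory=dict)
    step2_direct: dict[tuple[str, str], MREstimate] = field(default_factory=dict)
    step2_adj_p: dict[tuple[str, str], float] = field(default_factory=dict)
    qualified: list[tuple[str, str]] = field(default_factory=list)
    qualified_mediators: list[str] = field(default_factory=list)
    mediation_report: pd.DataFrame = field(default_factory=pd.DataFrame)
    errors: dict[str, str] = field(default_factory=dict)
    counts: dict[str, dict] = field(default_factory=dict)


def screen_mediators(
    exposure: SummaryStatsTable,
    mediators: Sequence[SummaryStatsTable],
    outcomes: Sequence[SummaryStatsTable],
    ld: LDMatrix,
    cfg: ScreenConfig,
) -> ScreenResult:
    """Run the full two-step screen over a panel of candidate mediators.

    Per-mediator failures (no instruments, collinearity...) are recorded in
    ``result.errors`` and never abort the run.  The screening steps use the
    headline IVW estimator; run :func:`run_total_effect` for the full
    estimator battery on any single pair.
    """
    cfg.validate()
    if not mediators or not outcomes:
        raise ValueError("need at least one mediator and one outcome")
    result = ScreenResult(config=cfg)

    exp_sel = select_instruments(exposure, ld, cfg)
    result.counts["exposure_selection"] = _selection_counts(exp_sel, len(exposure))
    exp_kept = exp_sel.kept

    # Total effects (beta0) per outcome.
    for out_tab in outcomes:
        if not exp_kept:
            result.errors[f"total:{out_tab.trait_id}"] = "no_instruments"
            continue
        use = usable_instruments(
            harmonize(exp_kept, out_tab, cfg.palindrome_eaf_window)
        )
        if not use:
            result.errors[f"total:{out_tab.trait_id}"] = "no_usable_instruments"
            continue
        result.total[out_tab.trait_id] = ivw(use, re_mode=cfg.re_mode)
        if len(use) >= 2:
            result.total_diagnostics[out_tab.trait_id] = sensitivity_report(
                use, pooled_beta=result.total[out_tab.trait_id].beta, re_mode=cfg.re_mode
            )

    # Step 1 (beta1) and the reverse-MR guard, per mediator.
    med_selections: dict[str, InstrumentSelection] = {}
    for med in mediators:
        mid = med.trait_id
        try:
            if not exp_kept:
                raise EstimationError("no exposure instruments")
            use = usable_instruments(
                harmonize(exp_kept, med, cfg.palindrome_eaf_window)
            )
            if not use:
                raise EstimationError("no usable step-1 instruments")
            result.step1[mid] = ivw(use, re_mode=cfg.re_mode)
            if len(use) >= 2:
                result.step1_diagnostics[mid] = sensitivity_report(
                    use, pooled_beta=result.step1[mid].beta, re_mode=cfg.re_mode
                )
        except (EstimationError, ValueError) as exc:
            result.errors[f"step1:{mid}"] = str(exc)
            continue
        try:
            med_sel = select_instruments(med, ld, cfg)
            med_selections[mid] = med_sel
            result.counts[f"mediator_selection:{mid}"] = _selection_counts(
                med_sel, len(med)
            )
            if med_sel.kept:
                rev_use = usable_instruments(
                    harmonize(med_sel.kept, exposure, cfg.palindrome_eaf_window)
                )
                result.reverse[mid] = (
                    ivw(rev_use, re_mode=cfg.re_mode) if rev_use else None
                )
            else:
                result.reverse[mid] = None
        except (EstimationError, ValueError) as exc:
            result.errors[f"reverse:{mid}"] = str(exc)
            result.reverse[mid] = None

    # Step 2 (beta2): multivariable IVW per (mediator, outcome).
    for med in mediators:
        mid = med.trait_id
        if mid not in result.step1:
            continue
        med_sel = med_selections.get(mid)
        med_kept = med_sel.kept if med_sel else []
        for out_tab in outcomes:
            key = (mid, out_tab.trait_id)
            try:
                direct_est, med_est = _mvmr_step2(
                    exposure, med, out_tab, exp_kept, med_kept, cfg
                )
                result.step2[key] = med_est
                result.step2_direct[key] = direct_est
            except (EstimationError, ValueError) as exc:
                result.errors[f"step2:{mid}:{out_tab.trait_id}"] = str(exc)

    # Multiplicity adjustment and qualification.
    step1_ids = list(result.step1)
    adj1 = _adjust([result.step1[m].pvalue for m in step1_ids], cfg.mtc)
    result.step1_adj_p = dict(zip(step1_ids, adj1))
    for out_tab in outcomes:
        keys = [k for k in result.step2 if k[1] == out_tab.trait_id]
        adj2 = _adjust([result.step2[k].pvalue for k in keys], cfg.mtc)
        result.step2_adj_p.update(dict(zip(keys, adj2)))

    for key, p2 in result.step2_adj_p.items():
        mid, oid = key
        p1 = result.step1_adj_p.get(mid, 1.0)
        rev = result.reverse.get(mid)
        reverse_significant = rev is not None and rev.pvalue < cfg.alpha
        if p1 < cfg.alpha and p2 < cfg.alpha and not reverse_significant:
            result.qualified.append(key)
    result.qualified.sort()
    result.qualified_mediators = sorted({m for m, _ in result.qualified})

    # Mediation report for qualified pairs with a significant total effect.
    rows = []
    for mid, oid in result.qualified:
        total = result.total.get(oid)
        if total is None or total.pvalue >= cfg.alpha:
            continue
        b1 = result.step1[mid]
        b2 = result.step2[(mid, oid)]
        rows.append(
            (exposure.trait_id, mid, oid, b1.beta, b1.se, b2.beta, b2.se, total.beta, total.se)
        )
    result.mediation_report = mediation_table(rows)
    result.counts["n_mediators"] = len(mediators)
    result.counts["n_outcomes"] = len(outcomes)
    result.counts["n_qualified_pairs"] = len(result.qualified)
    result.counts["n_mediation_rows"] = int(len(result.mediation_report))
    return result


def _selection_counts(sel: InstrumentSelection, n_candidates: int) -> dict:
    reasons: dict[str, int] = {}
    for reason in sel.dropped.values():
        key = reason.split(":")[0]
        reasons[key] = reasons.get(key, 0) + 1
    return {
        "candidates": n_candidates,
        "kept": len(sel.kept),
        "dropped": len(sel.dropped),
        "dropped_by_reason": dict(sorted(reasons.items())),
        "p_threshold_used": sel.p_threshold_used,
        "fallback_used": sel.fallback_used,
    }


def _estimate_row(exposure: str, outcome: str, est: MREstimate) -> dict:
    return {
        "exposure": exposure,
        "outcome": outcome,
        "method": est.method,
        "nsnp": est.n_snp,
        "b": est.beta,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "pval": est.pvalue,
    }


def estimates_frame(result: ScreenResult, exposure_id: str = "exposure") -> pd.DataFrame:
    """Tidy results table: exposure, outcome, method, nsnp, b, se, ci, pval."""
    rows = []
    for oid, est in sorted(result.total.items()):
        rows.append(_estimate_row(exposure_id, oid, est))
    for mid, est in sorted(result.step1.items()):
        rows.append(_estimate_row(exposure_id, mid, est))
    for mid, est in sorted(result.reverse.items()):
        if est is not None:
            rows.append(_estimate_row(mid, exposure_id, est))
    for (mid, oid), est in sorted(result.step2.items()):
        rows.append(_estimate_row(mid, f"{oid}|adj:{exposure_id}", est))
    cols = ["exposure", "outcome", "method", "nsnp", "b", "se", "ci_low", "ci_high", "pval"]
    return pd.DataFrame(rows, columns=cols)


def diagnostics_frame(result: ScreenResult) -> pd.DataFrame:
    rows = []
    items = [("total", k, v) for k, v in sorted(result.total_diagnostics.items())]
    items += [("step1", k, v) for k, v in sorted(result.step1_diagnostics.items())]
    for stage, key, rep in items:
        rows.append(
            {
                "stage": stage,
                "pair": key,
                "q": rep.q,
                "q_df": rep.q_df,
                "q_pvalue": rep.q_pvalue,
                "i2": rep.i2,
                "egger_intercept": rep.egger_intercept,
                "egger_intercept_se": rep.egger_intercept_se,
                "egger_intercept_p": rep.egger_intercept_p,
            }
        )
    cols = ["stage", "pair", "q", "q_df", "q_pvalue", "i2",
            "egger_intercept", "egger_intercept_se", "egger_intercept_p"]
    return pd.DataFrame(rows, columns=cols)


def loo_frame(result: ScreenResult) -> pd.DataFrame:
    rows = []
    items = [("total", k, v) for k, v in sorted(result.total_diagnostics.items())]
    items += [("step1", k, v) for k, v in sorted(result.step1_diagnostics.items())]
    for stage, key, rep in items:
        for snp, est in sorted(rep.loo.items()):
            rows.append(
                {"stage": stage, "pair": key, "snp": snp,
                 "b": est.beta, "se": est.se, "p": est.pvalue}
            )
    return pd.DataFrame(rows, columns=["stage", "pair", "snp", "b", "se", "p"])


def serialize_result(result: ScreenResult) -> str:
    """Deterministic text serialization of a screen (same seed -> same bytes)."""
    parts = [
        estimates_frame(result).to_csv(sep="\t", index=False, float_format="%.12g"),
        diagnostics_frame(result).to_csv(sep="\t", index=False, float_format="%.12g"),
        result.mediation_report.to_csv(sep="\t", index=False, float_format="%.12g"),
        json.dumps(result.counts, sort_keys=True),
        json.dumps(sorted(result.qualified)),
    ]
    return "\n".join(parts)


def summarize(result: ScreenResult, out_dir: str | Path) -> dict[str, Path]:
    """Write tidy results, mediation table, diagnostics, LOO table, and a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "estimates": out_dir / "estimates.tsv",
        "mediation": out_dir / "mediation.tsv",
        "diagnostics": out_dir / "diagnostics.tsv",
        "loo": out_dir / "loo.tsv",
        "manifest": out_dir / "manifest.json",
    }
    estimates_frame(result).to_csv(paths["estimates"], sep="\t", index=False)
    result.mediation_report.to_csv(paths["mediation"], sep="\t", index=False)
    diagnostics_frame(result).to_csv(paths["diagnostics"], sep="\t", index=False)
    loo_frame(result).to_csv(paths["loo"], sep="\t", index=False)
    manifest = {
        "config": dataclasses.asdict(result.config),
        "seed": result.config.seed,
        "versions": {
            "mrmediate": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "counts": result.counts,
        "qualified": [list(k) for k in result.qualified],
        "errors": result.errors,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
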