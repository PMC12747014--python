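"""Synthetic GWAS summary statistics for an exposure -> mediator -> outcome system.

Summary statistics are simulated directly — no individual-level genotypes —
because two-sample MR consumes nothing else.  Per-SNP true effects follow a
linear causal chain:

* exposure: gamma_j ~ N(0, gamma_sd^2) on a set of exposure-causal SNPs;
* mediator: beta1 * gamma_j (the mediated path) plus delta_j ~ N(0,
  delta_sd^2) on a disjoint set of mediator-specific causal SNPs — without
  those, every instrument's exposure and mediator effects would be exactly
  proportional and the multivariable regression separating the direct and
  mediated paths would be unidentified;
* outcome: (direct + beta1*beta2) * gamma_j + beta2 * delta_j, plus optional
  per-SNP pleiotropy (a N(directional_pleiotropy, pleiotropy_sd^2) term on
  exposure-causal SNPs, violating the exclusion restriction on purpose).

Observed betas add independent noise with the standardized-trait standard
error se_j = 1/sqrt(2 n eaf_j (1-eaf_j)); p-values come from the normal
distribution.  The LD matrix is block-exchangeable (r^2 = ld_r2_within
inside blocks, 0 between) — enough to exercise clumping, with no claim of
realism.  ``reverse_mediation`` swaps the exposure and mediator true-effect
vectors so the trait labelled "mediator" is the upstream cause, which the
pipeline's reverse-MR guard should detect.

All traits are in SD units.  Everything is driven by a single seed; the
same config yields byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from .instruments import LDMatrix
from .sumstats import P_FLOOR, SummaryStatsTable, VariantAssociation


class ConfigError(ValueError):
    """Scenario configuration violates its invariants."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of the generator; defaults are the study conditions.

    Sample sizes default to 50,000 per trait and 50 causal SNPs per trait
    with per-variant effect scales gamma_sd=0.05 (exposure) and
    delta_sd=0.1 (mediator-specific) — a realistic mix of genome-wide
    significant and sub-threshold variants at these sample sizes.
    """

    n_snps: int = 200
    n_causal_exp: int = 50
    n_causal_med: int = 50
    eaf_range: tuple[float, float] = (0.05, 0.95)
    gamma_sd: float = 0.05
    delta_sd: float = 0.1
    beta1: float = 0.3
    beta2: float = 0.4
    direct: float = 0.2
    pleiotropy_sd: float = 0.0
    directional_pleiotropy: float = 0.0
    reverse_mediation: bool = False
    n_exp: int = 50_000
    n_med: int = 50_000
    n_out: int = 50_000
    ld_block_size: int = 1
    ld_r2_within: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_snps < 1:
            problems.append("n_snps must be >= 1")
        if not (0 <= self.n_causal_exp <= self.n_snps):
            problems.append("n_causal_exp must be in [0, n_snps]")
        if not (0 <= self.n_causal_med <= self.n_snps - self.n_causal_exp):
            problems.append("n_causal_med must fit beside the exposure-causal set")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            problems.append("eaf_range must satisfy 0 < low < high < 1")
        for name in ("gamma_sd", "delta_sd", "pleiotropy_sd"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        for name in ("n_exp", "n_med", "n_out"):
            if getattr(self, name) < 2:
                problems.append(f"{name} must be >= 2")
        if self.ld_block_size < 1:
            problems.append("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_r2_within <= 1.0):
            problems.append("ld_r2_within must be in [0, 1]")
        if problems:
            raise ConfigError("; ".join(problems))


@dataclass(frozen=True)
class Truth:
    """Ground-truth record for recovery tests."""

    beta1: float
    beta2: float
    direct: float
    total: float
    proportion: float
    causal_exp_snps: tuple[str, ...]
    causal_med_snps: tuple[str, ...]
    reverse_mediation: bool = False


@dataclass
class SimulatedTriplet:
    exposure: SummaryStatsTable
    mediator: SummaryStatsTable
    outcome: SummaryStatsTable
    ld: LDMatrix
    truth: Truth


@dataclass
class PanelSimulation:
    """One causal-path mediator (index 0) plus null mediators on a shared SNP set."""

    exposure: SummaryStatsTable
    mediators: list[SummaryStatsTable]
    outcome: SummaryStatsTable
    ld: LDMatrix
    truth: Truth
    causal_index: int = 0


_ALLELES = ("A", "G")  # non-palindromic pair, harmonization is then trivial


def _positions(cfg: ScenarioConfig) -> tuple[list[str], list[int]]:
    """Block b lives on chromosome (b mod 22)+1, blocks far apart, SNPs 1 kb apart."""
    chroms, positions = [], []
    for j in range(cfg.n_snps):
        b, within = divmod(j, cfg.ld_block_size)
        chroms.append(str(b % 22 + 1))
        positions.append(1_000_000 + (b // 22) * 50_000_000 + within * 1000)
    return chroms, positions


def _se(n: int, eaf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def _table(
    trait_id: str,
    snp_ids: list[str],
    chroms: list[str],
    positions: list[int],
    eaf: np.ndarray,
    true_beta: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> SummaryStatsTable:
    se = _se(n, eaf)
    beta = true_beta + rng.normal(0.0, se)
    p = np.maximum(2.0 * stats.norm.sf(np.abs(beta / se)), P_FLOOR)
    records = [
        VariantAssociation(
            snp_id=snp_ids[j],
            effect_allele=_ALLELES[0],
            other_allele=_ALLELES[1],
            beta=float(beta[j]),
            se=float(se[j]),
            pvalue=float(p[j]),
            eaf=float(eaf[j]),
            n=n,
            chrom=chroms[j],
            pos=positions[j],
        )
        for j in range(len(snp_ids))
    ]
    table = SummaryStatsTable(trait_id=trait_id, records=records, sample_size=n)
    bad = [r.snp_id for r in records if not r.is_valid]
    assert not bad, f"generator produced invalid records: {bad[:5]}"
    return table


def _ld_matrix(cfg: ScenarioConfig, snp_ids: list[str], chroms, positions) -> LDMatrix:
    n = cfg.n_snps
    r2 = np.zeros((n, n))
    for start in range(0, n, cfg.ld_block_size):
        stop = min(start + cfg.ld_block_size, n)
        r2[start:stop, start:stop] = cfg.ld_r2_within
    np.fill_diagonal(r2, 1.0)
    pos = {s: (chroms[j], positions[j]) for j, s in enumerate(snp_ids)}
    return LDMatrix(snp_ids=list(snp_ids), r2=r2, pos=pos)


def _true_effects(
    cfg: ScenarioConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP true effect vectors (exposure, mediator, outcome) plus gamma, delta."""
    gamma = np.zeros(cfg.n_snps)
    delta = np.zeros(cfg.n_snps)
    exp_idx = np.arange(cfg.n_causal_exp)
    med_idx = np.arange(cfg.n_causal_exp, cfg.n_causal_exp + cfg.n_causal_med)
    gamma[exp_idx] = rng.normal(0.0, cfg.gamma_sd, size=len(exp_idx))
    delta[med_idx] = rng.normal(0.0, cfg.delta_sd, size=len(med_idx))

    exposure_true = gamma.copy()
    mediator_true = cfg.beta1 * gamma + delta
    outcome_true = (cfg.direct + cfg.beta1 * cfg.beta2) * gamma + cfg.beta2 * delta
    if cfg.pleiotropy_sd > 0 or cfg.directional_pleiotropy != 0:
        pleio = np.zeros(cfg.n_snps)
        pleio[exp_idx] = rng.normal(
            cfg.directional_pleiotropy, cfg.pleiotropy_sd, size=len(exp_idx)
        )
        outcome_true = outcome_true + pleio
    if cfg.reverse_mediation:
        exposure_true, mediator_true = mediator_true, exposure_true
    return exposure_true, mediator_true, outcome_true, gamma, delta


def simulate_triplet(cfg: ScenarioConfig) -> SimulatedTriplet:
    """Generate (exposure, mediator, outcome) tables, LD matrix, and the truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    snp_ids = [f"rs{j + 1:06d}" for j in range(cfg.n_snps)]
    chroms, positions = _positions(cfg)
    eaf = rng.uniform(*cfg.eaf_range, size=cfg.n_snps)
    exposure_true, mediator_true, outcome_true, _, _ = _true_effects(cfg, rng)

    exposure = _table("exposure", snp_ids, chroms, positions, eaf, exposure_true, cfg.n_exp, rng)
    mediator = _table("mediator", snp_ids, chroms, positions, eaf, mediator_true, cfg.n_med, rng)
    outcome = _table("outcome", snp_ids, chroms, positions, eaf, outcome_true, cfg.n_out, rng)
    ld = _ld_matrix(cfg, snp_ids, chroms, positions)
    total = cfg.direct + cfg.beta1 * cfg.beta2
    truth = Truth(
        beta1=cfg.beta1,
        beta2=cfg.beta2,
        direct=cfg.direct,
        total=total,
        proportion=cfg.beta1 * cfg.beta2 / total if total != 0 else math.nan,
        causal_exp_snps=tuple(snp_ids[: cfg.n_causal_exp]),
        causal_med_snps=tuple(
            snp_ids[cfg.n_causal_exp : cfg.n_causal_exp + cfg.n_causal_med]
        ),
        reverse_mediation=cfg.reverse_mediation,
    )
    return SimulatedTriplet(exposure, mediator, outcome, ld, truth)


def simulate_mediator_panel(
    cfg: ScenarioConfig, n_null_mediators: int
) -> PanelSimulation:
    """The causal-path triplet plus heritable mediators with no causal connection.

    Null mediators get their own causal SNPs (drawn from SNPs causal for
    neither the exposure nor the true mediator) so they are instrumentable,
    but neither receive an effect from the exposure nor transmit one to the
    outcome; their step-1 p-values are uniform by construction.
    """
    if n_null_mediators < 0:
        raise ConfigError("n_null_mediators must be >= 0")
    trip = simulate_triplet(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x9E3779B9]))
    snp_ids = trip.ld.snp_ids
    chroms = [trip.ld.pos[s][0] for s in snp_ids]
    positions = [trip.ld.pos[s][1] for s in snp_ids]
    eaf = np.array([trip.exposure.get(s).eaf for s in snp_ids])
    pool = np.arange(cfg.n_causal_exp + cfg.n_causal_med, cfg.n_snps)

    mediators = [trip.mediator]
    causal = replace(trip.mediator, trait_id="mediator_causal")
    mediators[0] = causal
    for k in range(n_null_mediators):
        true = np.zeros(cfg.n_snps)
        if len(pool):
            chosen = rng.choice(pool, size=min(cfg.n_causal_med, len(pool)), replace=False)
            true[chosen] = rng.normal(0.0, cfg.delta_sd, size=len(chosen))
        mediators.append(
            _table(
                f"mediator_null_{k + 1}",
                snp_ids, chroms, positions, eaf, true, cfg.n_med, rng,
            )
        )
    return PanelSimulation(
        exposure=trip.exposure,
        mediators=mediators,
        outcome=trip.outcome,
        ld=trip.ld,
        truth=trip.truth,
        causal_index=0,
    )
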