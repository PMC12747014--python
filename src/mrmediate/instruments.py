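"""Genetic-instrument selection: significance filtering, LD clumping, F statistics.

Instruments for a two-sample MR analysis are SNPs robustly associated with
the exposure (p below genome-wide significance, 5e-8, with a relaxed
fallback of 1e-5 when too few pass), mutually independent (greedy LD
clumping at r-squared < 0.01 within a 10,000 kb window), and strong
(F statistic >= 10, with F = (beta/se)^2 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sumstats import SummaryStatsTable, VariantAssociation


class LDMatrixError(ValueError):
    """The supplied r-squared matrix violates its invariants."""


@dataclass
class LDMatrix:
    """Symmetric SNP-by-SNP r-squared matrix with optional genomic positions.

    ``pos`` maps snp_id -> (chrom, bp); SNPs on different chromosomes are
    never considered linked regardless of the matrix entry, and SNPs with
    unknown positions fall back to the r-squared entry alone.
    """

    snp_ids: list[str]
    r2: np.ndarray
    pos: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise LDMatrixError("r2 shape does not match snp_ids")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise LDMatrixError("r2 diagonal must be 1")
        if not np.allclose(self.r2, self.r2.T):
            raise LDMatrixError("r2 must be symmetric")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise LDMatrixError("r2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])


def read_ld_matrix(path: str | Path, pos: Optional[dict] = None) -> LDMatrix:
    """Read a tab-delimited square r-squared matrix with SNP-id header row/column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise LDMatrixError("row and column SNP ids differ")
    return LDMatrix(snp_ids=[str(s) for s in df.columns], r2=df.to_numpy(), pos=pos or {})


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )


@dataclass
class InstrumentSelection:
    """Outcome of the selection ladder: kept SNPs, drop reasons, F statistics."""

    kept: list[VariantAssociation]
    p_threshold_used: float = math.nan
    fallback_used: bool = False
    f_statistics: dict[str, float] = field(default_factory=dict)
    dropped: dict[str, str] = field(default_factory=dict)
    flag: Optional[str] = None


def select_by_pvalue(
    table: SummaryStatsTable,
    primary_threshold: float = 5e-8,
    fallback_threshold: float = 1e-5,
    min_snps: int = 3,
) -> tuple[list[VariantAssociation], bool]:
    """SNPs with p below the primary threshold, relaxing to the fallback.

    Returns ``(subset, fallback_used)``.  The fallback threshold applies only
    when fewer than ``min_snps`` pass the primary one; an empty selection
    under both is returned empty (callers flag it), never raised.
    """
    if not (0 < primary_threshold <= fallback_threshold < 1):
        raise ValueError("need 0 < primary <= fallback < 1")
    primary = [v for v in table if v.pvalue < primary_threshold]
    if len(primary) >= min_snps:
        return primary, False
    fallback = [v for v in table if v.pvalue < fallback_threshold]
    if len(fallback) > len(primary):
        return fallback, True
    return primary, False


def _sort_key(v: VariantAssociation):
    # Deterministic clumping order: ascending p, then (chrom, pos, snp_id).
    return (v.pvalue, v.chrom or "", v.pos or 0, v.snp_id)


def ld_clump(
    candidates: Sequence[VariantAssociation],
    ld: LDMatrix,
    r2_max: float = 0.01,
    window_kb: int = 10_000,
    dropped: Optional[dict[str, str]] = None,
) -> list[VariantAssociation]:
    """Greedy LD clumping: keep the most significant SNP of every linked group.

    Candidates are visited by ascending p (ties broken by chrom, pos,
    snp_id); a SNP is accepted iff its r-squared with every already-accepted
    SNP within ``window_kb`` is below ``r2_max``.  Candidates absent from the
    LD matrix are dropped.  ``dropped`` (optional dict) collects
    snp_id -> reason for everything not kept.
    """
    if dropped is None:
        dropped = {}
    accepted: list[VariantAssociation] = []
    for v in sorted(candidates, key=_sort_key):
        if v.snp_id not in ld:
            dropped[v.snp_id] = "no_ld_info"
            continue
        clumped = False
        for kept in accepted:
            if not _within_window(v, kept, ld, window_kb):
                continue
            if ld.r2_between(v.snp_id, kept.snp_id) >= r2_max:
                dropped[v.snp_id] = f"clumped_with:{kept.snp_id}"
                clumped = True
                break
        if not clumped:
            accepted.append(v)
    return accepted


def _within_window(
    a: VariantAssociation, b: VariantAssociation, ld: LDMatrix, window_kb: int
) -> bool:
    pa = ld.pos.get(a.snp_id) or ((a.chrom, a.pos) if a.pos is not None else None)
    pb = ld.pos.get(b.snp_id) or ((b.chrom, b.pos) if b.pos is not None else None)
    if pa is None or pb is None:
        return True  # unknown positions: rely on the r2 entry alone
    if pa[0] != pb[0]:
        return False  # different chromosomes are never mutually exclusive
    return abs(int(pa[1]) - int(pb[1])) <= window_kb * 1000


def f_statistic(v: VariantAssociation) -> float:
    """Instrument-strength F statistic, (beta/se)^2."""
    if v.se <= 0:
        raise ValueError("se must be strictly positive")
    return (v.beta / v.se) ** 2


def f_statistic_r2(v: VariantAssociation) -> float:
    """Variance-explained form F = (n-2) R^2 / (1 - R^2).

    Uses R^2 = 2 eaf (1-eaf) beta^2 for a standardized trait; requires both
    ``n`` and ``eaf``.  Documented alternative to :func:`f_statistic` for
    tables that carry per-SNP sample sizes.
    """
    if v.n is None or v.eaf is None:
        raise ValueError("f_statistic_r2 requires n and eaf")
    r2 = 2.0 * v.eaf * (1.0 - v.eaf) * v.beta**2
    if r2 >= 1.0:
        raise ValueError("implied R^2 >= 1")
    return (v.n - 2) * r2 / (1.0 - r2)


def filter_weak(
    candidates: Sequence[VariantAssociation], f_min: float = 10.0
) -> InstrumentSelection:
    """Partition candidates into strong (F >= f_min) and weak instruments."""
    if f_min < 0:
        raise ValueError("f_min must be >= 0")
    sel = InstrumentSelection(kept=[])
    for v in candidates:
        f = f_statistic(v)
        sel.f_statistics[v.snp_id] = f
        if f >= f_min:
            sel.kept.append(v)
        else:
            sel.dropped[v.snp_id] = "weak_instrument"
    return sel
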