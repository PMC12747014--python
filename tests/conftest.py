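"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mrmediate import (
    HarmonizedInstrument,
    SummaryStatsTable,
    VariantAssociation,
)


def make_instruments(bx, by, sx=None, sy=None) -> list[HarmonizedInstrument]:
    """Build harmonized instruments from effect arrays (default SEs 0.05/0.02)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sx = np.full_like(bx, 0.05) if sx is None else np.asarray(sx, dtype=float)
    sy = np.full_like(by, 0.02) if sy is None else np.asarray(sy, dtype=float)
    return [
        HarmonizedInstrument(
            snp_id=f"rs{i + 1}",
            beta_exp=float(bx[i]),
            se_exp=float(sx[i]),
            beta_out=float(by[i]),
            se_out=float(sy[i]),
        )
        for i in range(len(bx))
    ]


def make_variant(
    snp_id="rs1",
    beta=0.1,
    se=0.01,
    pvalue=1e-10,
    ea="A",
    oa="G",
    eaf=0.3,
    chrom="1",
    pos=1_000_000,
    n=None,
) -> VariantAssociation:
    return VariantAssociation(
        snp_id=snp_id,
        effect_allele=ea,
        other_allele=oa,
        beta=beta,
        se=se,
        pvalue=pvalue,
        eaf=eaf,
        n=n,
        chrom=chrom,
        pos=pos,
    )


def make_table(records, trait_id="trait") -> SummaryStatsTable:
    return SummaryStatsTable(trait_id=trait_id, records=list(records))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
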