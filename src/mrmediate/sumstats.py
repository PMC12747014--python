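"""GWAS summary-statistics containers, tab-delimited I/O, and allele harmonization.

A two-sample Mendelian randomization analysis consumes nothing but per-SNP
summary associations (effect allele, beta, standard error, p-value) for an
exposure and an outcome measured in separate GWAS samples.  This module
defines the record types those tables decompose into, reads and writes them
as tab-delimited text, and aligns exposure and outcome effects onto a common
effect allele so that downstream estimators can treat each SNP as a single
instrument with a pair of effects (gamma on the exposure, Gamma on the
outcome).

Harmonization follows the standard ladder: direct allele match, allele swap
(flip the outcome beta sign and complement its allele frequency), strand
flip (complement both alleles), and strand flip plus swap.  Palindromic
variants (A/T or C/G), whose strand cannot be resolved from allele labels,
are oriented by allele frequency when it is informative and excluded when
either frequency sits near 0.5 or is missing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mrmediate")

#: Canonical column order for tab-delimited summary-statistics files.
CANONICAL_COLUMNS = ("SNP", "EA", "OA", "EAF", "BETA", "SE", "P", "N", "CHR", "POS")

#: Sentinel written for missing optional values.
NA_SENTINEL = "NA"

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Floor applied to p-values so the (0, 1] invariant survives extreme z-scores.
P_FLOOR = 1e-300


class SumstatsError(ValueError):
    """Base class for summary-statistics errors."""


class SumstatsFormatError(SumstatsError):
    """A required column is missing or unparseable."""


class EmptyTableError(SumstatsError):
    """No valid rows survived validation."""


def complement_allele(allele: str) -> Optional[str]:
    """Reverse-strand complement of a single-base allele; None for indels."""
    if len(allele) == 1 and allele in _COMPLEMENT:
        return _COMPLEMENT[allele]
    return None


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and C/G pairs, whose strand is ambiguous from labels."""
    return complement_allele(effect_allele) == other_allele


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait in
    trait-SD units; ``se`` its standard error; ``eaf`` the effect-allele
    frequency.  ``chrom``/``pos``/``eaf``/``n`` are optional.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: Optional[float] = None
    n: Optional[int] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None

    def violations(self) -> list[str]:
        """Invariant violations, empty when the record is valid."""
        out: list[str] = []
        if not self.snp_id:
            out.append("empty snp_id")
        if not math.isfinite(self.beta):
            out.append("beta not finite")
        if not (math.isfinite(self.se) and self.se > 0):
            out.append("se not strictly positive")
        if not (0.0 < self.pvalue <= 1.0):
            out.append("pvalue outside (0, 1]")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            out.append("eaf outside (0, 1)")
        ea, oa = self.effect_allele, self.other_allele
        if not ea or not oa or ea != ea.upper() or oa != oa.upper():
            out.append("alleles must be uppercase")
        elif any(c not in "ACGT" for c in ea + oa):
            out.append("alleles must be over {A,C,G,T}")
        elif ea == oa:
            out.append("effect_allele equals other_allele")
        return out

    @property
    def is_valid(self) -> bool:
        return not self.violations()


@dataclass
class SummaryStatsTable:
    """An ordered collection of :class:`VariantAssociation` for one trait."""

    trait_id: str
    records: list[VariantAssociation] = field(default_factory=list)
    trait_label: str = ""
    sample_size: Optional[int] = None

    def __post_init__(self) -> None:
        self._index: dict[str, VariantAssociation] = {}
        for rec in self.records:
            if rec.snp_id in self._index:
                raise SumstatsError(
                    f"duplicate snp_id {rec.snp_id!r} in table {self.trait_id!r}"
                )
            self._index[rec.snp_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_id: str) -> Optional[VariantAssociation]:
        return self._index.get(snp_id)

    def to_frame(self) -> pd.DataFrame:
        """Canonical-column DataFrame view (optional fields as NaN)."""
        rows = [
            {
                "SNP": r.snp_id,
                "EA": r.effect_allele,
                "OA": r.other_allele,
                "EAF": np.nan if r.eaf is None else r.eaf,
                "BETA": r.beta,
                "SE": r.se,
                "P": r.pvalue,
                "N": np.nan if r.n is None else r.n,
                "CHR": "" if r.chrom is None else r.chrom,
                "POS": np.nan if r.pos is None else r.pos,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


@dataclass(frozen=True)
class ColumnDialect:
    """Maps canonical fields onto a file's column names.

    Either ``beta``+``se`` or ``odds_ratio``+``ci_low``+``ci_high`` must be
    mapped; the latter is converted as beta = ln(OR),
    se = (ln UCI - ln LCI) / (2 * 1.96).
    """

    snp: str = "SNP"
    effect_allele: str = "EA"
    other_allele: str = "OA"
    pvalue: str = "P"
    beta: Optional[str] = "BETA"
    se: Optional[str] = "SE"
    odds_ratio: Optional[str] = None
    ci_low: Optional[str] = None
    ci_high: Optional[str] = None
    eaf: Optional[str] = "EAF"
    n: Optional[str] = "N"
    chrom: Optional[str] = "CHR"
    pos: Optional[str] = "POS"

    @classmethod
    def canonical(cls) -> "ColumnDialect":
        return cls()


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_sumstats(
    path: str | Path,
    dialect: Optional[ColumnDialect] = None,
    trait_id: Optional[str] = None,
) -> SummaryStatsTable:
    """Read a tab-delimited summary-statistics file into a validated table.

    Rows violating record invariants are dropped with a logged count.
    Raises :class:`SumstatsFormatError` naming the first missing required
    column, and :class:`EmptyTableError` when no valid row remains.
    """
    path = Path(path)
    dialect = dialect or ColumnDialect.canonical()
    df = pd.read_csv(path, sep="\t", na_values=[NA_SENTINEL], dtype={dialect.snp: str})

    for name, col in (
        ("snp", dialect.snp),
        ("effect_allele", dialect.effect_allele),
        ("other_allele", dialect.other_allele),
        ("p", dialect.pvalue),
    ):
        if col not in df.columns:
            raise SumstatsFormatError(f"missing required column {name!r} ({col})")

    use_or = False
    if dialect.beta in df.columns and dialect.se in df.columns:
        pass
    elif (
        dialect.odds_ratio is not None
        and dialect.odds_ratio in df.columns
        and dialect.ci_low in df.columns
        and dialect.ci_high in df.columns
    ):
        use_or = True
    else:
        raise SumstatsFormatError("missing required column 'se' (or OR with CI bounds)")

    def col(name: Optional[str]):
        return df[name] if name is not None and name in df.columns else None

    eaf_c, n_c, chrom_c, pos_c = (
        col(dialect.eaf),
        col(dialect.n),
        col(dialect.chrom),
        col(dialect.pos),
    )

    records: list[VariantAssociation] = []
    n_dropped = 0
    for i in range(len(df)):
        try:
            if use_or:
                or_v = float(df[dialect.odds_ratio].iloc[i])
                lci = float(df[dialect.ci_low].iloc[i])
                uci = float(df[dialect.ci_high].iloc[i])
                beta = math.log(or_v)
                se = (math.log(uci) - math.log(lci)) / (2.0 * 1.959963984540054)
            else:
                beta = float(df[dialect.beta].iloc[i])
                se = float(df[dialect.se].iloc[i])
            n_val = _opt_float(None if n_c is None else n_c.iloc[i])
            pos_val = _opt_float(None if pos_c is None else pos_c.iloc[i])
            chrom_val = None
            if chrom_c is not None and not pd.isna(chrom_c.iloc[i]):
                chrom_val = str(chrom_c.iloc[i])
            rec = VariantAssociation(
                snp_id=str(df[dialect.snp].iloc[i]),
                effect_allele=str(df[dialect.effect_allele].iloc[i]).upper(),
                other_allele=str(df[dialect.other_allele].iloc[i]).upper(),
                beta=beta,
                se=se,
                pvalue=float(df[dialect.pvalue].iloc[i]),
                eaf=_opt_float(None if eaf_c is None else eaf_c.iloc[i]),
                n=None if n_val is None else int(n_val),
                chrom=chrom_val,
                pos=None if pos_val is None else int(pos_val),
            )
        except (ValueError, TypeError):
            n_dropped += 1
            continue
        if rec.is_valid:
            records.append(rec)
        else:
            n_dropped += 1
    if n_dropped:
        logger.warning("%s: dropped %d invalid rows", path.name, n_dropped)
    if not records:
        raise EmptyTableError(f"{path}: zero valid rows")
    return SummaryStatsTable(trait_id=trait_id or path.stem, records=records)


def write_sumstats(table: SummaryStatsTable, path: str | Path) -> None:
    """Write a table in the canonical tab-delimited dialect.

    Floats are written with 17 significant digits so a read/write round trip
    preserves every numeric field to better than 1e-12.
    """
    df = table.to_frame()
    df.to_csv(
        path,
        sep="\t",
        index=False,
        na_rep=NA_SENTINEL,
        float_format="%.17g",
    )


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure/outcome-aligned SNP, both betas on the exposure's effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf: Optional[float] = None
    flipped: bool = False
    palindromic: bool = False
    excluded_reason: Optional[str] = None

    @property
    def usable(self) -> bool:
        return self.excluded_reason is None


def usable_instruments(
    instruments: Iterable[HarmonizedInstrument],
) -> list[HarmonizedInstrument]:
    """Instruments with no exclusion reason, in input order."""
    return [h for h in instruments if h.usable]


def _near_half(eaf: Optional[float], window: float) -> bool:
    return eaf is None or abs(eaf - 0.5) <= window


def harmonize(
    exposure_snps: Sequence[VariantAssociation],
    outcome_table: SummaryStatsTable,
    palindrome_eaf_window: float = 0.08,
) -> list[HarmonizedInstrument]:
    """Align outcome effects onto each exposure SNP's effect allele.

    Returns one :class:`HarmonizedInstrument` per exposure SNP.  Exclusions
    (recorded, never silent): ``missing_in_outcome``, ``ambiguous_palindrome``
    (palindromic SNP with eaf within ``palindrome_eaf_window`` of 0.5, or
    missing, on either trait), ``allele_mismatch``.
    """
    out: list[HarmonizedInstrument] = []
    for exp in exposure_snps:
        rec = outcome_table.get(exp.snp_id)
        if rec is None:
            out.append(
                HarmonizedInstrument(
                    snp_id=exp.snp_id,
                    beta_exp=exp.beta,
                    se_exp=exp.se,
                    beta_out=math.nan,
                    se_out=math.nan,
                    eaf=exp.eaf,
                    excluded_reason="missing_in_outcome",
                )
            )
            continue
        out.append(_harmonize_pair(exp, rec, palindrome_eaf_window))
    return out


def _harmonize_pair(
    exp: VariantAssociation,
    out: VariantAssociation,
    window: float,
) -> HarmonizedInstrument:
    ea, oa = exp.effect_allele, exp.other_allele
    o_ea, o_oa = out.effect_allele, out.other_allele
    pal = is_palindromic(ea, oa)

    def make(beta_out, eaf_out, flipped, reason=None):
        return HarmonizedInstrument(
            snp_id=exp.snp_id,
            beta_exp=exp.beta,
            se_exp=exp.se,
            beta_out=beta_out,
            se_out=out.se,
            eaf=exp.eaf if exp.eaf is not None else eaf_out,
            flipped=flipped,
            palindromic=pal,
            excluded_reason=reason,
        )

    if pal:
        if {o_ea, o_oa} != {ea, oa}:
            return make(math.nan, None, False, "allele_mismatch")
        if _near_half(exp.eaf, window) or _near_half(out.eaf, window):
            return make(math.nan, None, False, "ambiguous_palindrome")
        # Frequency of the exposure's effect allele in the outcome, taking
        # allele labels at face value; strand flips cannot change which
        # allele is the minor one, so disagreeing frequency sides mean the
        # labels point at opposite alleles.
        f = out.eaf if o_ea == ea else 1.0 - out.eaf
        b = out.beta if o_ea == ea else -out.beta
        label_flip = o_ea != ea
        if (exp.eaf < 0.5) != (f < 0.5):
            return make(-b, 1.0 - f, not label_flip)
        return make(b, f, label_flip)

    # Non-palindromic ladder: direct, swap, strand flip, strand flip + swap.
    if (o_ea, o_oa) == (ea, oa):
        return make(out.beta, out.eaf, False)
    if (o_ea, o_oa) == (oa, ea):
        return make(-out.beta, None if out.eaf is None else 1.0 - out.eaf, True)
    c_ea, c_oa = complement_allele(o_ea), complement_allele(o_oa)
    if c_ea is not None and c_oa is not None:
        if (c_ea, c_oa) == (ea, oa):
            return make(out.beta, out.eaf, False)
        if (c_ea, c_oa) == (oa, ea):
            return make(-out.beta, None if out.eaf is None else 1.0 - out.eaf, True)
    return make(math.nan, None, False, "allele_mismatch")
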