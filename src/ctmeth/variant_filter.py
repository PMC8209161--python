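"""CHIP variant filtering over annotated variant records.

Clonal hematopoiesis of indeterminate potential (CHIP) — somatic clonal
expansion in blood — is a potential source of background methylation signal
in healthy controls, so candidate CHIP variants called from buffy-coat DNA
are screened with a fixed rule set: a variant is kept only when it is exonic,
non-synonymous, called at p < 0.01 with coverage > 50, and sits in the
somatic VAF window 0.02–0.43 (inclusive: germline heterozygous variants
cluster near 0.5); it is discarded when flagged in a common-SNP database or
when any provided population minor allele frequency exceeds 0.02.  A
user-supplied blacklist of (chrom, pos, alt) stands in for visual review of
alignment artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["VariantRecord", "FilterOutcome", "filter_chip", "read_variant_tsv"]

VAF_MIN = 0.02
VAF_MAX = 0.43
P_MAX = 0.01
COVERAGE_MIN = 50  # strict: coverage must exceed this
MAF_MAX = 0.02

# rejection attribution follows this order; the first failing rule is charged
RULE_ORDER = [
    "unannotated",
    "blacklist",
    "not_exonic",
    "synonymous",
    "p_value",
    "coverage",
    "vaf_range",
    "common_snp",
    "maf",
]


@dataclass
class VariantRecord:
    """One annotated SNV/indel call.  Missing annotations are None and make
    the record unannotated (rejected, never guessed)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    exonic: bool | None = None
    nonsynonymous: bool | None = None
    p_value: float | None = None
    coverage: int | None = None
    vaf: float | None = None
    common_snp: bool | None = None
    maf_global: float | None = None
    maf_population: float | None = None

    def __post_init__(self) -> None:
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf={self.vaf} outside [0, 1]")
        if self.coverage is not None and self.coverage < 0:
            raise ValueError("coverage must be non-negative")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


@dataclass
class FilterOutcome:
    passed: list[VariantRecord]
    tally: dict[str, int] = field(default_factory=dict)

    @property
    def n_pass(self) -> int:
        return len(self.passed)


def _first_failure(rec: VariantRecord, blacklist: set | None) -> str | None:
    required = (
        rec.exonic,
        rec.nonsynonymous,
        rec.p_value,
        rec.coverage,
        rec.vaf,
        rec.common_snp,
    )
    if any(v is None for v in required):
        return "unannotated"
    if blacklist and rec.key in blacklist:
        return "blacklist"
    if not rec.exonic:
        return "not_exonic"
    if not rec.nonsynonymous:
        return "synonymous"
    if not rec.p_value < P_MAX:
        return "p_value"
    if not rec.coverage > COVERAGE_MIN:
        return "coverage"
    if not (VAF_MIN <= rec.vaf <= VAF_MAX):
        return "vaf_range"
    if rec.common_snp:
        return "common_snp"
    for maf in (rec.maf_global, rec.maf_population):
        if maf is not None and maf > MAF_MAX:
            return "maf"
    return None


def filter_chip(
    records: list[VariantRecord],
    blacklist: list[tuple[str, int, str]] | None = None,
) -> FilterOutcome:
    """Apply the CHIP inclusion/exclusion rules.

    The pass condition is a pure conjunction — record order and rule order
    never change the pass set.  The rejection tally charges each rejected
    record to its first failing rule in :data:`RULE_ORDER`.  MAF fields are
    optional: a missing MAF is not a rejection, but a provided MAF above 0.02
    is.
    """
    bset = set(blacklist) if blacklist else None
    tally = {r: 0 for r in RULE_ORDER}
    passed = []
    for rec in records:
        why = _first_failure(rec, bset)
        if why is None:
            passed.append(rec)
        else:
            tally[why] += 1
    return FilterOutcome(passed=passed, tally=tally)


# ---------------------------------------------------------------------------
# I/O

TSV_COLUMNS = {
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "gene": "gene",
    "exonic": "exonic",
    "nonsynonymous": "nonsynonymous",
    "p_value": "p_value",
    "coverage": "coverage",
    "vaf": "vaf",
    "common_snp": "common_snp",
    "maf_global": "maf_global",
    "maf_population": "maf_population",
}


def _maybe(row, col, cast):
    v = row.get(col)
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    return cast(v)


def read_variant_tsv(path, columns: dict[str, str] | None = None) -> list[VariantRecord]:
    """Read variants from a flat TSV; ``columns`` remaps field names."""
    cols = dict(TSV_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype={cols["chrom"]: str})
    records = []
    for _, row in df.iterrows():
        records.append(
            VariantRecord(
                chrom=str(row[cols["chrom"]]),
                pos=int(row[cols["pos"]]),
                ref=str(row[cols["ref"]]),
                alt=str(row[cols["alt"]]),
                gene=_maybe(row, cols["gene"], str),
                exonic=_maybe(row, cols["exonic"], lambda v: bool(int(v))),
                nonsynonymous=_maybe(row, cols["nonsynonymous"], lambda v: bool(int(v))),
                p_value=_maybe(row, cols["p_value"], float),
                coverage=_maybe(row, cols["coverage"], int),
                vaf=_maybe(row, cols["vaf"], float),
                common_snp=_maybe(row, cols["common_snp"], lambda v: bool(int(v))),
                maf_global=_maybe(row, cols["maf_global"], float),
                maf_population=_maybe(row, cols["maf_population"], float),
            )
        )
    return records


VCF_INFO_KEYS = {
    "gene": "GENE",
    "exonic": "EXONIC",
    "nonsynonymous": "NONSYN",
    "p_value": "PVAL",
    "coverage": "DP",
    "vaf": "AF",
    "common_snp": "COMMON",
    "maf_global": "MAF",
    "maf_population": "MAF_POP",
}


def read_variant_vcf(path, info_keys: dict[str, str] | None = None) -> list[VariantRecord]:
    """Read variants from a VCF; annotations come from INFO fields whose key
    names are configurable via ``info_keys``."""
    from cyvcf2 import VCF

    keys = dict(VCF_INFO_KEYS)
    if info_keys:
        keys.update(info_keys)
    records = []
    for v in VCF(str(path)):
        info = dict(v.INFO)

        def get(field, cast):
            raw = info.get(keys[field])
            return None if raw is None else cast(raw)

        for alt in v.ALT:
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    gene=get("gene", str),
                    exonic=get("exonic", lambda x: bool(int(x))),
                    nonsynonymous=get("nonsynonymous", lambda x: bool(int(x))),
                    p_value=get("p_value", float),
                    coverage=get("coverage", int),
                    vaf=get("vaf", float),
                    # flag semantics: absent means not in the database
                    common_snp=bool(info.get(keys["common_snp"], False)),
                    maf_global=get("maf_global", float),
                    maf_population=get("maf_population", float),
                )
            )
    return records
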