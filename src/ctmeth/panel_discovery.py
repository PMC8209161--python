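"""Discovery of tumour-specific hypermethylated panel regions from array data.

Input is a 450k-style beta matrix (per-CpG methylation level in [0, 1] across
a tumour cohort and several normal-tissue cohorts).  A CpG is a candidate when
it is hypermethylated in at least half of the tumours while every normal
tissue is essentially unmethylated on average; candidates within 300 bp of
each other are chained into regions, regions overlapping a user-supplied
exclusion mask (e.g. blood-methylated intervals) are removed, and primer
pairs proposed for the surviving regions are checked against the assay's
design constraints (product 75-150 bp, primer 21-31 bp, Tm 64-72 degC with at
most 5 degC differential, at least two CpGs between the primers).

Thresholds are expressed on a centered beta scale beta' = beta - c with
c = 0.5 by default, so the printed selection thresholds -0.1 (tumour) and
-0.3 (normal mean) correspond to beta > 0.4 and mean beta < 0.2.  The
centering constant is configurable so an M-value-style recoding can be
swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp

from .bisref import revcomp

__all__ = [
    "BetaMatrix",
    "DmrCandidate",
    "PrimerConstraints",
    "PrimerReport",
    "select_dmr_cpgs",
    "pair_cpgs_to_regions",
    "apply_exclusion_mask",
    "validate_primer_pair",
]

TUMOUR_GROUP = "tumour"


@dataclass
class BetaMatrix:
    """Per-CpG methylation betas across a cohort, with genomic coordinates.

    Rows are CpG probes sorted by (chrom, pos); columns are samples, each
    tagged with a cohort group ("tumour" or a normal-tissue label).  Missing
    betas are NaN and are excluded pairwise from every statistic.
    """

    cpg_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    values: np.ndarray  # (n_cpgs, n_samples), NaN = missing
    sample_ids: list[str]
    group_labels: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if not (len(self.cpg_ids) == len(self.chrom) == len(self.pos) == n):
            raise ValueError("row metadata and value matrix sizes disagree")
        if not (len(self.sample_ids) == len(self.group_labels) == m):
            raise ValueError("column metadata and value matrix sizes disagree")
        if len(set(self.cpg_ids)) != n:
            raise ValueError("cpg_ids are not unique")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1] (or be NaN)")
        order = sorted(range(n), key=lambda i: (self.chrom[i], self.pos[i]))
        if order != list(range(n)):
            raise ValueError("rows must be sorted by (chrom, pos)")

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[0]

    def columns_for(self, group: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.group_labels) if g == group])

    @property
    def normal_groups(self) -> list[str]:
        seen = []
        for g in self.group_labels:
            if g != TUMOUR_GROUP and g not in seen:
                seen.append(g)
        return seen

    @classmethod
    def from_tsv(cls, beta_path, samples_path) -> "BetaMatrix":
        """Load from a beta TSV (cpg_id, chrom, pos, one column per sample)
        and a sample sheet TSV (sample_id, group)."""
        df = pd.read_csv(beta_path, sep="\t", dtype={"chrom": str})
        sheet = pd.read_csv(samples_path, sep="\t")
        group_of = dict(zip(sheet["sample_id"].astype(str), sheet["group"].astype(str)))
        sample_cols = [c for c in df.columns if c not in ("cpg_id", "chrom", "pos")]
        missing = [c for c in sample_cols if c not in group_of]
        if missing:
            raise ValueError(f"samples absent from sample sheet: {missing}")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        return cls(
            cpg_ids=df["cpg_id"].astype(str).tolist(),
            chrom=df["chrom"].to_numpy(dtype=object),
            pos=df["pos"].to_numpy(dtype=np.int64),
            values=df[sample_cols].to_numpy(dtype=float),
            sample_ids=sample_cols,
            group_labels=[group_of[c] for c in sample_cols],
        )

    def coordinates_of(self, cpg_ids) -> pd.DataFrame:
        """Coordinate table (cpg_id, chrom, pos) for a subset, matrix order."""
        wanted = set(cpg_ids)
        rows = [
            (cid, self.chrom[i], int(self.pos[i]))
            for i, cid in enumerate(self.cpg_ids)
            if cid in wanted
        ]
        return pd.DataFrame(rows, columns=["cpg_id", "chrom", "pos"])


@dataclass
class DmrCandidate:
    """A run of selected CpGs on one chromosome, all within ``max_gap`` links.

    ``tumour_frequency`` is the smallest per-member fraction of tumour
    samples exceeding the tumour criterion (NaN when not supplied).
    """

    chrom: str
    start: int
    end: int  # half-open; spans first to last member CpG
    member_cpgs: list[str]
    tumour_frequency: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.member_cpgs) < 2:
            raise ValueError("a DMR candidate needs at least 2 member CpGs")


@dataclass
class PrimerConstraints:
    """Design constraints for bisulfite PCR primer pairs (lengths in bp,
    temperatures in degC)."""

    product_min: int = 75
    product_max: int = 150
    tm_min: float = 64.0
    tm_opt: float = 68.0
    tm_max: float = 72.0
    tm_diff_max: float = 5.0
    primer_min: int = 21
    primer_opt: int = 28
    primer_max: int = 31
    min_inter_primer_cpgs: int = 2

    def __post_init__(self) -> None:
        if not self.product_min < self.product_max:
            raise ValueError("product_min must be < product_max")
        if not (self.tm_min <= self.tm_opt <= self.tm_max):
            raise ValueError("require tm_min <= tm_opt <= tm_max")
        for name in (
            "product_min", "product_max", "tm_min", "tm_opt", "tm_max",
            "tm_diff_max", "primer_min", "primer_opt", "primer_max",
            "min_inter_primer_cpgs",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def select_dmr_cpgs(
    beta: BetaMatrix,
    tumour_threshold: float = -0.1,
    normal_threshold: float = -0.3,
    min_tumour_fraction: float = 0.5,
    center: float = 0.5,
) -> list[str]:
    """CpGs hypermethylated in tumours but unmethylated in every normal tissue.

    A CpG is selected when the fraction of tumour samples with centered beta
    (beta - ``center``) above ``tumour_threshold`` is at least
    ``min_tumour_fraction`` AND the mean centered beta of *each* normal-tissue
    group is below ``normal_threshold``.  Missing betas are excluded from both
    numerator and denominator.

    Returns the selected CpG ids in matrix (coordinate) order.
    """
    for name, thr in (("tumour_threshold", tumour_threshold),
                      ("normal_threshold", normal_threshold)):
        if not (-center <= thr <= 1 - center):
            raise ValueError(
                f"{name}={thr} outside the centered-beta range "
                f"[{-center}, {1 - center}]"
            )
    tum_cols = beta.columns_for(TUMOUR_GROUP)
    if tum_cols.size == 0:
        raise ValueError("no samples in group 'tumour'")
    normals = beta.normal_groups
    if not normals:
        raise ValueError("no normal-tissue groups present")

    centered = beta.values - center
    tum = centered[:, tum_cols]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        n_obs = np.isfinite(tum).sum(axis=1)
        n_hit = np.nansum(tum > tumour_threshold, axis=1)
        frac = np.where(n_obs > 0, n_hit / np.maximum(n_obs, 1), 0.0)
        keep = frac >= min_tumour_fraction
        for g in normals:
            cols = beta.columns_for(g)
            gmean = np.nanmean(centered[:, cols], axis=1)
            keep &= np.isfinite(gmean) & (gmean < normal_threshold)
    return [cid for cid, k in zip(beta.cpg_ids, keep) if k]


def tumour_frequencies(
    beta: BetaMatrix, tumour_threshold: float = -0.1, center: float = 0.5
) -> dict[str, float]:
    """Per-CpG fraction of tumour samples exceeding the tumour criterion."""
    tum = beta.values[:, beta.columns_for(TUMOUR_GROUP)] - center
    n_obs = np.isfinite(tum).sum(axis=1)
    n_hit = np.nansum(tum > tumour_threshold, axis=1)
    frac = np.where(n_obs > 0, n_hit / np.maximum(n_obs, 1), np.nan)
    return dict(zip(beta.cpg_ids, frac))


def pair_cpgs_to_regions(
    selected: pd.DataFrame,
    max_gap: int = 300,
    frequencies: dict[str, float] | None = None,
) -> list[DmrCandidate]:
    """Chain selected CpGs into regions; singletons are discarded.

    ``selected`` is a coordinate-sorted table with columns cpg_id, chrom, pos
    (e.g. from :meth:`BetaMatrix.coordinates_of`).  Consecutive CpGs on the
    same chromosome at most ``max_gap`` bp apart (C-to-C distance, single
    linkage) join one region; a region needs at least two members.  The
    region interval spans the first to one past the last member C.
    """
    required = {"cpg_id", "chrom", "pos"}
    if not required.issubset(selected.columns):
        raise ValueError(f"selected table needs columns {sorted(required)}")
    keys = list(zip(selected["chrom"], selected["pos"]))
    if keys != sorted(keys):
        raise ValueError("selected CpGs must be coordinate-sorted (no silent re-sort)")

    candidates: list[DmrCandidate] = []
    run: list[tuple[str, str, int]] = []

    def _flush() -> None:
        if len(run) >= 2:
            members = [cid for cid, _, _ in run]
            freq = float("nan")
            if frequencies is not None:
                freq = min(frequencies.get(cid, float("nan")) for cid in members)
            candidates.append(
                DmrCandidate(
                    chrom=run[0][1],
                    start=run[0][2],
                    end=run[-1][2] + 1,
                    member_cpgs=members,
                    tumour_frequency=freq,
                )
            )

    for cid, chrom, pos in selected.itertuples(index=False):
        pos = int(pos)
        if run and (chrom != run[-1][1] or pos - run[-1][2] > max_gap):
            _flush()
            run = []
        run.append((str(cid), str(chrom), pos))
    _flush()
    return candidates


def apply_exclusion_mask(
    candidates: list[DmrCandidate],
    mask: list[tuple[str, int, int]],
) -> list[DmrCandidate]:
    """Drop candidates overlapping any mask interval by >= 1 bp.

    Intervals are 0-based half-open on both sides, so abutting intervals do
    not overlap.  A mask chromosome never seen in the candidate set (or vice
    versa) triggers a warning listing the unmatched names.
    """
    cand_chroms = {c.chrom for c in candidates}
    mask_chroms = {m[0] for m in mask}
    unmatched = sorted(cand_chroms ^ mask_chroms)
    if unmatched and cand_chroms and mask_chroms:
        warnings.warn(
            f"chromosomes present on only one side of the mask comparison: {unmatched}",
            stacklevel=2,
        )
    kept = []
    for c in candidates:
        hit = any(
            mc == c.chrom and c.start < me and ms < c.end for mc, ms, me in mask
        )
        if not hit:
            kept.append(c)
    return kept


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a BED file's first three columns as half-open intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_candidates_bed(candidates: list[DmrCandidate], path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(candidates, start=1):
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\tregion_{i:03d}\t"
                f"{len(c.member_cpgs)}\t{c.tumour_frequency:.3f}\n"
            )


# ---------------------------------------------------------------------------
# primer validation

# nearest-neighbour Tm parameters: 250 nM primer, 50 mM Na+ (Biopython NN
# table 4 defaults otherwise); commercial design tools differ by a few degC
TM_DNAC1 = 250.0
TM_DNAC2 = 0.0
TM_NA = 50.0


def primer_tm(seq: str) -> float:
    """Nearest-neighbour melting temperature (degC) of a primer."""
    return float(
        MeltingTemp.Tm_NN(seq, dnac1=TM_DNAC1, dnac2=TM_DNAC2, Na=TM_NA)
    )


@dataclass
class PrimerReport:
    """Per-constraint pass/fail report for one primer pair on one amplicon."""

    probe_id: str
    product_length: int
    fwd_len: int
    rev_len: int
    fwd_tm: float
    rev_tm: float
    inter_primer_cpgs: int
    fwd_primer_cpgs: int
    rev_primer_cpgs: int
    product_length_ok: bool
    primer_length_ok: bool
    tm_ok: bool
    tm_diff_ok: bool
    cpg_count_ok: bool
    fwd_3prime_on_cpg: bool
    rev_3prime_on_cpg: bool
    checks: dict = field(default_factory=dict)

    @property
    def all_ok(self) -> bool:
        return (
            self.product_length_ok
            and self.primer_length_ok
            and self.tm_ok
            and self.tm_diff_ok
            and self.cpg_count_ok
        )


def validate_primer_pair(
    fwd: str,
    rev: str,
    amplicon: str,
    cpg_offsets: list[int],
    constraints: PrimerConstraints | None = None,
    probe_id: str = ".",
) -> PrimerReport:
    """Check a primer pair against the panel design constraints.

    ``amplicon`` is the fully-methylated converted top strand of the product;
    ``cpg_offsets`` are the CpG cytosine offsets within it (primer-footprint
    CpGs included).  The forward primer must be a prefix-anchored substring of
    the amplicon and the reverse primer must match as reverse-complement at
    the 3' end.  A 3'-terminal base on a CpG cytosine is flagged (advisory):
    design practice avoids it so that amplification bias stays moderate.
    """
    constraints = constraints or PrimerConstraints()
    fwd = fwd.upper()
    rev = rev.upper()
    amplicon = amplicon.upper()
    if amplicon.find(fwd) != 0:
        if fwd not in amplicon:
            raise ValueError(f"forward primer not found on converted amplicon: {fwd}")
    rev_site = revcomp(rev)
    if rev_site not in amplicon:
        raise ValueError(f"reverse primer not found on converted amplicon: {rev}")
    f_start = amplicon.index(fwd)
    r_start = amplicon.rindex(rev_site)
    product_length = r_start + len(rev_site) - f_start

    inner_lo = f_start + len(fwd)
    inner_hi = r_start
    cpg_set = set(cpg_offsets)
    inter = [o for o in cpg_offsets if inner_lo <= o < inner_hi]
    fwd_cpgs = [o for o in cpg_offsets if f_start <= o < inner_lo]
    rev_cpgs = [o for o in cpg_offsets if r_start <= o < r_start + len(rev_site)]

    fwd_tm = primer_tm(fwd)
    rev_tm = primer_tm(rev)

    # forward 3' end is the last base of its footprint; reverse 3' end pairs
    # with the first base of its footprint on the top strand -- the G of a
    # CpG, i.e. offset r_start-1 holds the C
    fwd_3prime_on_cpg = (inner_lo - 1) in cpg_set
    rev_3prime_on_cpg = (r_start - 1) in cpg_set or r_start in cpg_set

    report = PrimerReport(
        probe_id=probe_id,
        product_length=product_length,
        fwd_len=len(fwd),
        rev_len=len(rev),
        fwd_tm=fwd_tm,
        rev_tm=rev_tm,
        inter_primer_cpgs=len(inter),
        fwd_primer_cpgs=len(fwd_cpgs),
        rev_primer_cpgs=len(rev_cpgs),
        product_length_ok=constraints.product_min
        <= product_length
        <= constraints.product_max,
        primer_length_ok=all(
            constraints.primer_min <= n <= constraints.primer_max
            for n in (len(fwd), len(rev))
        ),
        tm_ok=all(
            constraints.tm_min <= t <= constraints.tm_max for t in (fwd_tm, rev_tm)
        ),
        tm_diff_ok=abs(fwd_tm - rev_tm) <= constraints.tm_diff_max,
        cpg_count_ok=len(inter) >= constraints.min_inter_primer_cpgs,
        fwd_3prime_on_cpg=fwd_3prime_on_cpg,
        rev_3prime_on_cpg=rev_3prime_on_cpg,
    )
    report.checks = {
        "product_length": report.product_length_ok,
        "primer_length": report.primer_length_ok,
        "tm_range": report.tm_ok,
        "tm_differential": report.tm_diff_ok,
        "inter_primer_cpgs": report.cpg_count_ok,
    }
    return report
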