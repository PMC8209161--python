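"""In-silico bisulfite conversion and per-probe converted reference sequences.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as T by
the polymerase) while 5-methylcytosine is protected.  On the top strand this
turns every C outside a CpG context into T; a CpG cytosine stays C when the
template molecule is methylated and becomes T when it is not.  Methylation is
thereby made readable as plain sequence, and each amplicon needs two reference
variants: the fully-methylated conversion (CpG cytosines retained) and the
fully-unmethylated conversion (every C gone).

The model here is top-strand only: the assay's primers define one converted
strand and reads are expected in its orientation (reverse-complement reads are
rescued downstream during demultiplexing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "bisulfite_convert",
    "cpg_positions",
    "revcomp",
    "PanelProbe",
    "PanelDefinition",
    "build_probe",
]

_VALID = set("ACGTN")

# warning band for inter-primer CpG counts: the panel design rule requires at
# least 2, and deployed amplicons carry between 3 and 21
CPG_COUNT_MIN = 2
CPG_COUNT_MAX = 21


def _check_alphabet(seq: str) -> None:
    for i, base in enumerate(seq):
        if base not in _VALID:
            raise ValueError(
                f"invalid base {base!r} at position {i}; expected one of A,C,G,T,N"
            )


def bisulfite_convert(seq: str, template_methylated: bool) -> str:
    """Convert a top-strand DNA sequence as bisulfite treatment would.

    Every cytosine not followed by G becomes T.  A CpG cytosine is retained
    as C when ``template_methylated`` is true, otherwise it also becomes T.
    A, G, T and N are unchanged; a terminal C (no next base) is treated as
    non-CpG and converted.

    Parameters
    ----------
    seq : str
        Sequence over the alphabet {A, C, G, T, N}.
    template_methylated : bool
        Whether CpG cytosines on this template are 5-methylated.

    Returns
    -------
    str
        The converted sequence, same length as the input.
    """
    seq = seq.upper()
    _check_alphabet(seq)
    out = []
    n = len(seq)
    for i, base in enumerate(seq):
        if base != "C":
            out.append(base)
        elif i + 1 < n and seq[i + 1] == "G" and template_methylated:
            out.append("C")
        else:
            out.append("T")
    return "".join(out)


def cpg_positions(seq: str) -> list[int]:
    """0-based positions of CpG cytosines in ``seq`` (the C of each CG)."""
    seq = seq.upper()
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class PanelProbe:
    """One amplicon of the panel: primers, converted references, CpG index.

    ``cpg_offsets`` are 0-based offsets of inter-primer CpG cytosines within
    the amplicon; only those CpGs are scored.  ``ref_methylated`` and
    ``ref_unmethylated`` differ exactly at the amplicon's CpG cytosines
    (C vs T).  Coordinates are genomic, 0-based half-open.
    """

    probe_id: str
    region_id: str
    chrom: str
    start: int
    end: int
    fwd_primer: str
    rev_primer: str
    ref_methylated: str
    ref_unmethylated: str
    cpg_offsets: list[int] = field(default_factory=list)
    # genomic non-CpG cytosine offsets (read as T post-conversion); kept so a
    # simulator can model conversion failure at the right positions
    noncpg_c_offsets: list[int] = field(default_factory=list)
    is_brca1: bool = False

    def __post_init__(self) -> None:
        amp_len = len(self.ref_methylated)
        if len(self.ref_unmethylated) != amp_len:
            raise ValueError("reference variants differ in length")
        diff = [
            i
            for i, (a, b) in enumerate(zip(self.ref_methylated, self.ref_unmethylated))
            if a != b
        ]
        for i in diff:
            if not (self.ref_methylated[i] == "C" and self.ref_unmethylated[i] == "T"):
                raise ValueError(
                    "reference variants may differ only as C (methylated) vs T"
                )
        lo = len(self.fwd_primer)
        hi = amp_len - len(self.rev_primer)
        for off in self.cpg_offsets:
            if not (lo <= off < hi):
                raise ValueError(
                    f"CpG offset {off} falls inside a primer footprint of {self.probe_id}"
                )
        n_cpg = len(self.cpg_offsets)
        if not (CPG_COUNT_MIN <= n_cpg <= CPG_COUNT_MAX):
            warnings.warn(
                f"probe {self.probe_id}: {n_cpg} inter-primer CpGs is outside the "
                f"panel design band [{CPG_COUNT_MIN}, {CPG_COUNT_MAX}]",
                stacklevel=2,
            )

    @property
    def amplicon_length(self) -> int:
        return len(self.ref_methylated)

    @property
    def inter_primer_ref(self) -> str:
        """Fully-methylated reference between the primer footprints."""
        return self.ref_methylated[
            len(self.fwd_primer) : len(self.ref_methylated) - len(self.rev_primer)
        ]


@dataclass
class PanelDefinition:
    """An ordered collection of panel probes with a version tag.

    Probes flagged ``is_brca1`` are carried in the panel (the BRCA1 promoter
    has treatment relevance) but are excluded from the Methylation Index.
    """

    probes: list[PanelProbe]
    version: str = "0"

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate probe_id in panel")

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    def get(self, probe_id: str) -> PanelProbe:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    @property
    def mi_eligible(self) -> list[str]:
        """Probe ids counting toward the Methylation Index (non-BRCA1)."""
        return [p.probe_id for p in self.probes if not p.is_brca1]

    @property
    def n_mi_eligible(self) -> int:
        return len(self.mi_eligible)

    def drop(self, probe_ids) -> "PanelDefinition":
        """Return a new panel without the given probes."""
        drop = set(probe_ids)
        return PanelDefinition(
            [p for p in self.probes if p.probe_id not in drop],
            version=self.version + "+qc",
        )

    # ---- I/O -------------------------------------------------------------

    def to_tsv(self, path) -> None:
        rows = [
            {
                "probe_id": p.probe_id,
                "region_id": p.region_id,
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "fwd_primer": p.fwd_primer,
                "rev_primer": p.rev_primer,
                "ref_methylated": p.ref_methylated,
                "ref_unmethylated": p.ref_unmethylated,
                "cpg_offsets": ",".join(map(str, p.cpg_offsets)),
                "noncpg_c_offsets": ",".join(map(str, p.noncpg_c_offsets)),
                "is_brca1": int(p.is_brca1),
            }
            for p in self.probes
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PanelDefinition":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        probes = []
        has_nc = "noncpg_c_offsets" in df.columns
        for row in df.itertuples(index=False):
            offsets = [int(x) for x in str(row.cpg_offsets).split(",") if x != ""]
            nc_raw = str(row.noncpg_c_offsets) if has_nc else ""
            nc = [int(x) for x in nc_raw.split(",") if x not in ("", "nan")]
            probes.append(
                PanelProbe(
                    probe_id=str(row.probe_id),
                    region_id=str(row.region_id),
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    fwd_primer=row.fwd_primer,
                    rev_primer=row.rev_primer,
                    ref_methylated=row.ref_methylated,
                    ref_unmethylated=row.ref_unmethylated,
                    cpg_offsets=offsets,
                    noncpg_c_offsets=nc,
                    is_brca1=bool(row.is_brca1),
                )
            )
        return cls(probes)

    def write_fasta(self, path) -> None:
        """Write the fully-methylated amplicon references as FASTA."""
        records = [
            SeqRecord(Seq(p.ref_methylated), id=p.probe_id, description="methylated")
            for p in self.probes
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for p in self.probes:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.probe_id}\n")


def build_probe(
    genomic_seq: str,
    fwd_primer: str,
    rev_primer: str,
    probe_id: str,
    region_id: str,
    chrom: str = ".",
    genomic_start: int = 0,
    is_brca1: bool = False,
) -> PanelProbe:
    """Build a :class:`PanelProbe` from genomic sequence and converted primers.

    The primers are given on the fully-methylated converted top strand (the
    reverse primer as its own sequence, i.e. the reverse-complement of the
    converted top strand at its binding site).  Each must occur exactly once
    on the converted ``genomic_seq``.

    ``cpg_offsets`` enumerates CpG dinucleotides of the *original* genomic
    sequence strictly between the primer footprints; CpGs overlapping a
    primer footprint are not scored.  A CpG whose dinucleotide contains N is
    dropped with a warning.
    """
    genomic_seq = genomic_seq.upper()
    conv_meth = bisulfite_convert(genomic_seq, True)
    conv_unmeth = bisulfite_convert(genomic_seq, False)

    fwd = fwd_primer.upper()
    rev_site = revcomp(rev_primer.upper())

    def _locate(sub: str, name: str) -> int:
        count = conv_meth.count(sub)
        if count != 1:
            raise ValueError(
                f"{name} primer for {probe_id} found {count} times on the "
                "converted reference (expected exactly once)"
            )
        return conv_meth.index(sub)

    f_start = _locate(fwd, "forward")
    r_start = _locate(rev_site, "reverse")
    amp_start, amp_end = f_start, r_start + len(rev_site)
    if amp_end <= amp_start + len(fwd) + len(rev_site) - 1:
        raise ValueError(f"primers for {probe_id} overlap or are mis-ordered")

    inner_lo = amp_start + len(fwd)
    inner_hi = r_start
    offsets = []
    for pos in range(inner_lo, inner_hi):
        dinuc = genomic_seq[pos : pos + 2]
        if dinuc == "CG":
            offsets.append(pos - amp_start)
        elif dinuc in ("CN", "NG"):
            # ambiguous CpG — cannot be scored
            warnings.warn(
                f"probe {probe_id}: possible CpG with N at genomic offset {pos}; dropped",
                stacklevel=2,
            )

    noncpg_c = [
        pos - amp_start
        for pos in range(amp_start, amp_end)
        if genomic_seq[pos] == "C"
        and not (pos + 1 < len(genomic_seq) and genomic_seq[pos + 1] == "G")
    ]

    return PanelProbe(
        probe_id=probe_id,
        region_id=region_id,
        chrom=chrom,
        start=genomic_start + amp_start,
        end=genomic_start + amp_end,
        fwd_primer=fwd,
        rev_primer=rev_primer.upper(),
        ref_methylated=conv_meth[amp_start:amp_end],
        ref_unmethylated=conv_unmeth[amp_start:amp_end],
        cpg_offsets=offsets,
        noncpg_c_offsets=noncpg_c,
        is_brca1=is_brca1,
    )
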