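"""From raw targeted bisulfite sequencing reads to per-read CpG calls.

The stages mirror a BiQ-style amplicon workflow: a strict length filter
(retain reads > 100 bp), demultiplexing by forward-primer prefix match,
semi-global alignment of each primer-trimmed read against its probe's
fully-methylated converted reference, and per-CpG state read-out.  At a CpG
cytosine offset a read T is the unmethylated epiallele, not a sequencing
error, so the aligner scores T against reference C as a match at those
offsets.  A read passes when its alignment identity is at least 0.90 and
every inter-primer CpG is identifiable (aligned to C or T, no gap); a passing
read methylated at every CpG is a fully-methylated read — the quantity the
assay counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .bisref import PanelDefinition, PanelProbe, revcomp

__all__ = [
    "ReadRecord",
    "ReadCall",
    "ReadCallSet",
    "length_filter",
    "demultiplex",
    "align_and_call",
    "aggregate",
    "read_fastq",
    "process_reads",
]

DEFAULT_MIN_LEN = 100
DEFAULT_MIN_IDENTITY = 0.90
MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_SCORE = -2

METHYLATED = "M"
UNMETHYLATED = "U"
AMBIGUOUS = "?"


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    qualities: list[int] | None = None
    assigned_probe_id: str | None = None
    orientation: str = "as-is"  # or "revcomp"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id} has an empty sequence")


@dataclass
class ReadCall:
    """Alignment identity and per-CpG states for one read on one probe."""

    read_id: str
    probe_id: str
    identity: float
    cpg_states: list[str]
    passes_filter: bool
    fully_methylated: bool
    fail_reason: str | None = None

    @property
    def state_string(self) -> str:
        return "".join(self.cpg_states)


@dataclass
class ReadCallSet:
    """Per-probe read tallies: total demultiplexed, passing, fully methylated."""

    probe_id: str
    total_reads: int
    pass_reads: int
    fully_methylated_reads: int

    def __post_init__(self) -> None:
        if not (0 <= self.fully_methylated_reads <= self.pass_reads <= self.total_reads):
            raise ValueError(
                "require fully_methylated_reads <= pass_reads <= total_reads"
            )


def read_fastq(path) -> list[ReadRecord]:
    """Load a FASTQ file (plain or .gz) into ReadRecords."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    records = []
    with opener(str(path), "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            records.append(
                ReadRecord(
                    read_id=rec.id,
                    sequence=str(rec.seq),
                    qualities=rec.letter_annotations.get("phred_quality"),
                )
            )
    return records


def sam_to_reads(path) -> list[ReadRecord]:
    """Extract reads from a SAM/BAM file (the SAM-to-FASTQ step)."""
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.query_sequence:
                reads.append(
                    ReadRecord(
                        read_id=aln.query_name,
                        sequence=aln.query_sequence,
                        qualities=list(aln.query_qualities)
                        if aln.query_qualities is not None
                        else None,
                    )
                )
    return reads


@dataclass
class FilterStats:
    retained: int
    removed: int


def length_filter(
    reads: list[ReadRecord], min_len: int = DEFAULT_MIN_LEN
) -> tuple[list[ReadRecord], FilterStats]:
    """Retain reads strictly longer than ``min_len`` (default: > 100 bp)."""
    kept = [r for r in reads if len(r.sequence) > min_len]
    return kept, FilterStats(retained=len(kept), removed=len(reads) - len(kept))


def _hamming_prefix(seq: str, primer: str) -> int:
    """Mismatches of ``primer`` against the start of ``seq``; missing bases
    (read shorter than primer) count as mismatches."""
    k = min(len(seq), len(primer))
    d = sum(1 for a, b in zip(seq[:k], primer[:k]) if a != b)
    return d + (len(primer) - k)


@dataclass
class DemuxResult:
    assigned: dict[str, list[ReadRecord]]
    unassigned: list[ReadRecord]

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())


def demultiplex(
    reads: list[ReadRecord],
    panel: PanelDefinition,
    max_mismatches: int = 2,
) -> DemuxResult:
    """Assign reads to probes by forward-primer prefix match.

    Both the read and its reverse complement are tried; the best orientation
    per probe is kept.  A read goes to the unique probe whose forward primer
    matches within ``max_mismatches``; ties between probes, or no match, put
    the read in the unassigned bin.  The matched primer bases are trimmed and
    the chosen orientation recorded.  ``max_mismatches=0`` recovers exact
    prefix splitting.
    """
    assigned: dict[str, list[ReadRecord]] = {p.probe_id: [] for p in panel}
    unassigned: list[ReadRecord] = []
    primers = [(p.probe_id, p.fwd_primer) for p in panel]

    for read in reads:
        rc = revcomp(read.sequence)
        best: list[tuple[int, str, str]] = []  # (dist, probe_id, orientation)
        for pid, primer in primers:
            for orient, seq in (("as-is", read.sequence), ("revcomp", rc)):
                d = _hamming_prefix(seq, primer)
                if d <= max_mismatches:
                    best.append((d, pid, orient))
        if not best:
            unassigned.append(read)
            continue
        best.sort(key=lambda t: t[0])
        top = [b for b in best if b[0] == best[0][0]]
        top_probes = {b[1] for b in top}
        if len(top_probes) > 1:
            unassigned.append(read)  # ambiguous between probes
            continue
        d, pid, orient = top[0]
        seq = read.sequence if orient == "as-is" else rc
        primer_len = len(dict(primers)[pid])
        assigned[pid].append(
            ReadRecord(
                read_id=read.read_id,
                sequence=seq[primer_len:],
                qualities=None if orient == "revcomp" else (
                    read.qualities[primer_len:] if read.qualities else None
                ),
                assigned_probe_id=pid,
                orientation=orient,
            )
        )
    return DemuxResult(assigned=assigned, unassigned=unassigned)


# ---------------------------------------------------------------------------
# alignment

def _ungapped_call(read: str, probe: PanelProbe, offset: int):
    """Identity and states for a gap-free placement of ``read`` at ``offset``
    on the reference.  Returns None unless the placement is mismatch-free
    (an optimal alignment cannot beat identity 1)."""
    ref = probe.ref_methylated
    span = min(len(read), len(ref) - offset)
    if span <= 0:
        return None
    cpgs = set(probe.cpg_offsets)
    for i in range(span):
        r, q = ref[offset + i], read[i]
        if q != r and not (offset + i in cpgs and r == "C" and q == "T"):
            return None
    if len(read) > span:  # read overhangs the reference; not mismatch-free
        return None
    states = []
    for o in probe.cpg_offsets:
        i = o - offset
        if 0 <= i < span:
            states.append(METHYLATED if read[i] == "C" else UNMETHYLATED)
        else:
            states.append(AMBIGUOUS)
    return 1.0, states


def _dp_align(read: str, probe: PanelProbe):
    """Semi-global alignment (free end gaps on both sequences) of the read
    against ref_methylated, with T-vs-C scored as a match at CpG offsets.

    Returns (identity, states): identity is matching columns over alignment
    columns, end-gap columns excluded; states holds one of M/U/? per CpG
    offset (gap or non-C/T base → ambiguous).
    """
    ref = probe.ref_methylated
    cpgs = set(probe.cpg_offsets)
    n, m = len(read), len(ref)

    match_ok = np.zeros((n, m), dtype=bool)
    ref_arr = np.frombuffer(ref.encode(), dtype="S1")
    read_arr = np.frombuffer(read.encode(), dtype="S1")
    eq = read_arr[:, None] == ref_arr[None, :]
    if cpgs:
        cpg_cols = np.array(sorted(c for c in cpgs if ref[c] == "C"), dtype=int)
        t_rows = read_arr == b"T"
        eq[np.ix_(t_rows, cpg_cols)] = True
    sub = np.where(eq, MATCH_SCORE, MISMATCH_SCORE).astype(np.int32)

    S = np.zeros((n + 1, m + 1), dtype=np.int64)
    # free end gaps: first row and column stay zero
    j_idx = np.arange(1, m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        diag = S[i - 1, :-1] + sub[i - 1]
        up = S[i - 1, 1:] + GAP_SCORE
        best = np.maximum(diag, up)
        # horizontal gap chain: S[i][j] = max_k<=j (entry[k] + (j-k)*gap),
        # with entry[0] = S[i][0]; linear gap cost makes this a running max
        chain = np.empty(m + 1, dtype=np.int64)
        chain[0] = S[i, 0]
        chain[1:] = best - j_idx * GAP_SCORE
        np.maximum.accumulate(chain, out=chain)
        S[i, 1:] = chain[1:] + j_idx * GAP_SCORE

    # alignment may end anywhere on the last row or last column
    end_i, end_j = n, int(np.argmax(S[n, :]))
    best_score = S[n, end_j]
    col_best = int(np.argmax(S[:, m]))
    if S[col_best, m] > best_score:
        end_i, end_j, best_score = col_best, m, S[col_best, m]

    # traceback
    i, j = end_i, end_j
    matches = 0
    columns = 0
    aligned_base: dict[int, str] = {}  # ref offset -> read base or "-"
    while i > 0 and j > 0:
        s = S[i, j]
        if s == S[i - 1, j - 1] + sub[i - 1, j - 1]:
            aligned_base[j - 1] = read[i - 1]
            matches += int(sub[i - 1, j - 1] == MATCH_SCORE)
            columns += 1
            i, j = i - 1, j - 1
        elif s == S[i - 1, j] + GAP_SCORE:
            columns += 1  # read base against ref gap
            i -= 1
        elif s == S[i, j - 1] + GAP_SCORE:
            aligned_base[j - 1] = "-"
            columns += 1
            j -= 1
        else:  # free end gap region reached (score 0 row/col)
            break

    identity = matches / columns if columns else 0.0
    states = []
    for o in probe.cpg_offsets:
        base = aligned_base.get(o)
        if base == "C":
            states.append(METHYLATED)
        elif base == "T":
            states.append(UNMETHYLATED)
        else:
            states.append(AMBIGUOUS)
    return identity, states


def align_and_call(
    read: ReadRecord,
    probe: PanelProbe,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> ReadCall:
    """Align a demultiplexed, primer-trimmed read and call its CpG states.

    The read is aligned against the probe's fully-methylated reference with
    free end gaps; T against reference C at a CpG offset counts as a match
    (unmethylated state, not an error).  A read shorter than half the
    amplicon fails outright with reason ``short_alignment``.  The call
    passes when identity >= ``min_identity`` and no CpG state is ambiguous;
    it is fully methylated when additionally every state is methylated.
    """
    seq = read.sequence.upper()
    if len(seq) < probe.amplicon_length / 2:
        return ReadCall(
            read_id=read.read_id,
            probe_id=probe.probe_id,
            identity=0.0,
            cpg_states=[AMBIGUOUS] * len(probe.cpg_offsets),
            passes_filter=False,
            fully_methylated=False,
            fail_reason="short_alignment",
        )

    # fast path: mismatch-free gapless placement just after the forward primer
    fast = _ungapped_call(seq, probe, len(probe.fwd_primer))
    if fast is None:
        identity, states = _dp_align(seq, probe)
    else:
        identity, states = fast

    ambiguous = AMBIGUOUS in states
    passes = identity >= min_identity and not ambiguous
    fully = passes and len(states) > 0 and all(s == METHYLATED for s in states)
    reason = None
    if not passes:
        reason = "ambiguous_cpg" if identity >= min_identity else "low_identity"
    return ReadCall(
        read_id=read.read_id,
        probe_id=probe.probe_id,
        identity=identity,
        cpg_states=states,
        passes_filter=passes,
        fully_methylated=fully,
        fail_reason=reason,
    )


def aggregate(calls: list[ReadCall], probe_id: str) -> ReadCallSet:
    """Tally a probe's calls into (total, passing, fully methylated)."""
    for c in calls:
        if c.probe_id != probe_id:
            raise ValueError(
                f"call for probe {c.probe_id} mixed into aggregate for {probe_id}"
            )
    return ReadCallSet(
        probe_id=probe_id,
        total_reads=len(calls),
        pass_reads=sum(c.passes_filter for c in calls),
        fully_methylated_reads=sum(c.fully_methylated for c in calls),
    )


@dataclass
class RunLog:
    n_input: int = 0
    n_after_length: int = 0
    n_assigned: int = 0
    n_unassigned: int = 0
    n_pass: int = 0


def process_reads(
    reads: list[ReadRecord],
    panel: PanelDefinition,
    min_len: int = DEFAULT_MIN_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_primer_mismatches: int = 2,
) -> tuple[dict[str, ReadCallSet], dict[str, list[ReadCall]], RunLog]:
    """Full read-processing pipeline for one sample.

    length filter → demultiplex → align & call → aggregate per probe.
    Returns (callsets per probe, calls per probe, run log).
    """
    log = RunLog(n_input=len(reads))
    kept, _ = length_filter(reads, min_len=min_len)
    log.n_after_length = len(kept)
    demux = demultiplex(kept, panel, max_mismatches=max_primer_mismatches)
    log.n_assigned = demux.n_assigned
    log.n_unassigned = len(demux.unassigned)
    callsets: dict[str, ReadCallSet] = {}
    calls_by_probe: dict[str, list[ReadCall]] = {}
    for probe in panel:
        calls = [
            align_and_call(r, probe, min_identity=min_identity)
            for r in demux.assigned[probe.probe_id]
        ]
        calls_by_probe[probe.probe_id] = calls
        callsets[probe.probe_id] = aggregate(calls, probe.probe_id)
        log.n_pass += callsets[probe.probe_id].pass_reads
    return callsets, calls_by_probe, log
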