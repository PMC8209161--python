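"""Length filtering, demultiplexing, alignment and CpG calling."""

import warnings

import numpy as np
import pytest

from ctmeth.bisref import PanelProbe, bisulfite_convert, cpg_positions, revcomp
from ctmeth.readproc import (
    ReadCall,
    ReadRecord,
    aggregate,
    align_and_call,
    demultiplex,
    length_filter,
    process_reads,
    _dp_align,
)
from ctmeth.simulator import SimConfig, simulate_reads

from oracles import oracle_align_identity


def _read(seq, rid="r1"):
    return ReadRecord(read_id=rid, sequence=seq)


class TestLengthFilter:
    def test_strictly_greater_boundary(self):
        reads = [_read("A" * n, f"r{n}") for n in (99, 100, 101)]
        kept, stats = length_filter(reads, min_len=100)
        assert [r.read_id for r in kept] == ["r101"]
        assert (stats.retained, stats.removed) == (1, 2)

    def test_empty_input(self):
        kept, stats = length_filter([])
        assert kept == [] and stats.retained == 0

    def test_simulated_mixture_recounted(self, small_panel):
        cfg = SimConfig(
            seed=5, depth_per_probe=100, short_read_fraction=0.1, short_read_len=80
        )
        reads, truth = simulate_reads(small_panel, cfg)
        kept, stats = length_filter(reads)
        # independent recount from the truth table: a read survives when its
        # full amplicon exceeds 100 bp and it was not truncated to 80 bp
        amp_len = {p.probe_id: p.amplicon_length for p in small_panel}
        n_expected = sum(
            1
            for row in truth.reads.itertuples(index=False)
            if not row.truncated and amp_len[row.probe_id] > 100
        )
        assert stats.retained == sum(1 for r in reads if len(r.sequence) > 100)
        assert stats.retained == n_expected
        assert stats.retained + stats.removed == len(reads)


class TestDemultiplex:
    def test_exact_prefix_assigns(self, small_panel):
        p = small_panel.probes[0]
        read = _read(p.ref_methylated)
        result = demultiplex([read], small_panel)
        (got,) = result.assigned[p.probe_id]
        assert got.assigned_probe_id == p.probe_id
        # primer trimmed
        assert got.sequence == p.ref_methylated[len(p.fwd_primer):]
        assert got.orientation == "as-is"

    def test_revcomp_read_rescued(self, small_panel):
        p = small_panel.probes[1]
        read = _read(revcomp(p.ref_methylated))
        result = demultiplex([read], small_panel)
        (got,) = result.assigned[p.probe_id]
        assert got.orientation == "revcomp"
        assert got.sequence == p.ref_methylated[len(p.fwd_primer):]

    def test_tie_between_probes_goes_unassigned(self):
        probes = []
        for pid, primer_tail in (("A", "AAAA"), ("B", "TTTT")):
            region = "ATTAGATTAGATTAGATTAGA" + "TTACGTTACGTTTTTTTTTTTTTTTTTTTTTTTTTTTTT" + "TAATCTAATCTAATCTAATCT"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                probes.append(
                    PanelProbe(
                        probe_id=pid, region_id=pid, chrom=".", start=0, end=0,
                        fwd_primer="ATTAGATTAGATTAGATTAG" + ("A" if pid == "A" else "T"),
                        rev_primer="AGATTAGATTAGATTAGATTA",
                        ref_methylated=bisulfite_convert(region, True),
                        ref_unmethylated=bisulfite_convert(region, False),
                        cpg_offsets=[],
                    )
                )
        from ctmeth.bisref import PanelDefinition

        panel = PanelDefinition(probes)
        # read prefix within 1 mismatch of both probes' primers
        read = _read("ATTAGATTAGATTAGATTAGC" + "T" * 80)
        result = demultiplex([read], panel, max_mismatches=2)
        assert len(result.unassigned) == 1
        assert result.n_assigned == 0

    def test_no_match_routed_to_unassigned(self, small_panel):
        read = _read("G" * 120)
        result = demultiplex([read], small_panel)
        assert result.unassigned == [read]

    def test_simulated_assignment_accuracy(self, small_panel):
        cfg = SimConfig(seed=6, depth_per_probe=1000, seq_error=0.005,
                        tumour_fraction=0.5)
        reads, truth = simulate_reads(small_panel, cfg)
        result = demultiplex(reads, small_panel)
        true_probe = dict(zip(truth.reads.read_id, truth.reads.probe_id))
        n_correct = sum(
            1
            for pid, rs in result.assigned.items()
            for r in rs
            if true_probe[r.read_id] == pid
        )
        assert n_correct / len(reads) >= 0.99
        # nothing is ever mis-assigned, only unassigned
        assert n_correct == result.n_assigned


def _toy_probe(genomic, fwd_len=0, rev_len=0, pid="toy"):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PanelProbe(
            probe_id=pid, region_id=pid, chrom=".", start=0, end=len(genomic),
            fwd_primer=genomic[:fwd_len] and bisulfite_convert(genomic[:fwd_len], True),
            rev_primer=rev_len and revcomp(bisulfite_convert(genomic, True)[-rev_len:]) or "",
            ref_methylated=bisulfite_convert(genomic, True),
            ref_unmethylated=bisulfite_convert(genomic, False),
            cpg_offsets=[
                p for p in cpg_positions(genomic)
                if fwd_len <= p < len(genomic) - rev_len
            ],
        )


class TestAlignAndCall:
    GENOMIC = "ATTAGGACGTTTACGTTAGGTTCGTTTTAGGATTTTACGTTTAGGGTTATTTACGTTTAGGATTTAGGTTTTAGTTAGGATTTAGGCGTTAGGATTTAGGTTATTAGGATTTAGGTTATTT"

    def test_perfect_methylated_read(self):
        probe = _toy_probe(self.GENOMIC, 20, 20)
        read = _read(probe.ref_methylated[20:])
        call = align_and_call(read, probe)
        assert call.identity == 1.0
        assert call.passes_filter and call.fully_methylated
        assert set(call.cpg_states) == {"M"}

    def test_perfect_unmethylated_read_counts_cpg_t_as_match(self):
        probe = _toy_probe(self.GENOMIC, 20, 20)
        read = _read(probe.ref_unmethylated[20:])
        call = align_and_call(read, probe)
        assert call.identity == 1.0
        assert call.passes_filter and not call.fully_methylated
        assert set(call.cpg_states) == {"U"}

    def test_heavily_mutated_read_fails(self, rng):
        probe = _toy_probe(self.GENOMIC, 20, 20)
        ref = probe.ref_methylated[20:]
        seq = list(ref)
        for i in rng.choice(len(seq), size=int(0.15 * len(seq)), replace=False):
            seq[i] = {"A": "G", "C": "A", "G": "T", "T": "G"}[seq[i]]
        call = align_and_call(_read("".join(seq)), probe)
        assert not call.passes_filter
        assert call.identity < 0.90

    def test_short_read_fails_with_reason(self):
        probe = _toy_probe(self.GENOMIC, 20, 20)
        call = align_and_call(_read(probe.ref_methylated[20:60]), probe)
        assert not call.passes_filter
        assert call.fail_reason == "short_alignment"

    def test_gap_over_cpg_is_ambiguous(self):
        probe = _toy_probe(self.GENOMIC, 20, 20)
        ref = probe.ref_methylated[20:]
        off = probe.cpg_offsets[2] - 20
        read = _read(ref[:off] + ref[off + 1:])  # delete one CpG cytosine
        call = align_and_call(read, probe)
        assert call.cpg_states[2] == "?"
        assert not call.passes_filter
        assert call.fail_reason == "ambiguous_cpg"

    def test_mixed_states_read(self):
        probe = _toy_probe(self.GENOMIC, 20, 20)
        ref = list(probe.ref_methylated[20:])
        off = probe.cpg_offsets[0] - 20
        ref[off] = "T"  # first CpG unmethylated
        call = align_and_call(_read("".join(ref)), probe)
        assert call.passes_filter and not call.fully_methylated
        assert call.cpg_states[0] == "U"
        assert set(call.cpg_states[1:]) == {"M"}


@pytest.mark.parametrize("with_cpgs", [True, False])
def test_dp_identity_matches_bruteforce_oracle(rng, with_cpgs):
    """The vectorised aligner reproduces a plain-Python DP on short toys."""
    bases = np.array(list("ACGT"))
    for trial in range(150):
        n_ref = int(rng.integers(30, 61))
        genomic = "".join(rng.choice(bases, size=n_ref))
        if not with_cpgs:
            genomic = genomic.replace("CG", "CT")
        probe = _toy_probe(genomic, 0, 0, pid=f"t{trial}")
        ref = probe.ref_methylated if rng.random() < 0.5 else probe.ref_unmethylated
        seq = list(ref)
        for _ in range(int(rng.integers(0, 6))):  # substitutions
            i = int(rng.integers(len(seq)))
            seq[i] = str(rng.choice(bases))
        for _ in range(int(rng.integers(0, 3))):  # indels
            i = int(rng.integers(len(seq)))
            if rng.random() < 0.5 and len(seq) > 25:
                del seq[i]
            else:
                seq.insert(i, str(rng.choice(bases)))
        read = "".join(seq)
        identity, states = _dp_align(read, probe)
        oracle_id, aligned = oracle_align_identity(
            read, probe.ref_methylated, set(probe.cpg_offsets)
        )
        assert identity == pytest.approx(oracle_id, abs=0), (
            f"trial {trial}: {identity} != {oracle_id}"
        )


class TestAggregate:
    def _call(self, passes, fully, pid="p", rid="r"):
        return ReadCall(
            read_id=rid, probe_id=pid, identity=1.0, cpg_states=["M"],
            passes_filter=passes, fully_methylated=fully,
        )

    def test_counts(self):
        calls = (
            [self._call(True, True) for _ in range(6)]
            + [self._call(True, False) for _ in range(2)]
            + [self._call(False, False) for _ in range(2)]
        )
        cs = aggregate(calls, "p")
        assert (cs.total_reads, cs.pass_reads, cs.fully_methylated_reads) == (10, 8, 6)

    def test_empty(self):
        cs = aggregate([], "p")
        assert (cs.total_reads, cs.pass_reads, cs.fully_methylated_reads) == (0, 0, 0)

    def test_mixed_probe_ids_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            aggregate([self._call(True, True, pid="other")], "p")

    def test_permutation_invariance(self, rng, small_panel):
        cfg = SimConfig(seed=8, depth_per_probe=80, tumour_fraction=0.4,
                        seq_error=0.01)
        reads, _ = simulate_reads(small_panel, cfg)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        a, _, _ = process_reads(reads, small_panel)
        b, _, _ = process_reads(shuffled, small_panel)
        for pid in small_panel.probe_ids:
            assert (a[pid].total_reads, a[pid].pass_reads,
                    a[pid].fully_methylated_reads) == (
                b[pid].total_reads, b[pid].pass_reads,
                b[pid].fully_methylated_reads)


def test_noise_free_reads_are_all_or_none(small_panel):
    """With no noise, methylated-template reads are fully methylated and
    unmethylated-template reads pass with zero methylated CpGs."""
    cfg = SimConfig(
        seed=10, depth_per_probe=60, tumour_fraction=0.5,
        conversion_rate=1.0, meth_cpg_error=0.0, seq_error=0.0,
    )
    reads, truth = simulate_reads(small_panel, cfg)
    callsets, calls, _ = process_reads(reads, small_panel)
    meth = dict(zip(truth.reads.read_id, truth.reads.template_methylated))
    for pid, probe_calls in calls.items():
        for c in probe_calls:
            assert c.passes_filter
            if meth[c.read_id]:
                assert c.fully_methylated
            else:
                assert set(c.cpg_states) == {"U"}
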