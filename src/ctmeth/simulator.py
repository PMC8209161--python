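"""Synthetic data with the statistical structure the assay assumes.

Three generators make every stage testable without external data:

* a synthetic genome + panel whose amplicons satisfy the design constraints
  (product 75-150 bp, 21-31 bp primers, a chosen number of inter-primer CpGs);
* bisulfite amplicon read sets drawn as mixtures of fully-methylated (tumour)
  and unmethylated (background) templates, with conversion-failure,
  CpG-readout and substitution noise, optional truncation to exercise the
  length filter, an optional methylated-template amplification bias, and an
  optional finite genome-equivalent template pool per probe (at low ctDNA
  input individual targets may simply be absent from the tube);
* 450k-style beta matrices with planted hypermethylated DMR clusters against
  clean normals.

Templates are strictly all-or-none methylated by default, matching the
assay's observed epiallele structure.  Every generator records a truth table
and draws all randomness from one seeded generator, so identical seeds give
identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .bisref import (
    PanelDefinition,
    PanelProbe,
    bisulfite_convert,
    build_probe,
    revcomp,
)
from .panel_discovery import BetaMatrix

__all__ = [
    "SimConfig",
    "ReadTruth",
    "BetaTruth",
    "SimulatedSample",
    "simulate_genome_and_panel",
    "simulate_reads",
    "simulate_beta_matrix",
    "simulate_cohort",
    "write_fastq",
]


@dataclass
class SimConfig:
    """Knobs of the read simulator.

    ``tumour_fraction`` is the proportion of templates from the methylated
    (tumour) compartment.  ``probe_meth_prob`` models inter-tumour
    heterogeneity: each probe's tumour compartment is methylated with this
    probability per sample (real tumours are positive for only a subset of
    panel probes).  ``methylation_bias`` multiplies the sampling weight of
    methylated templates — the methylation-biased primers amplify
    preferentially but not exclusively; its true magnitude is unquantified,
    so the default is 1 (off).  ``templates_per_probe`` switches to a finite
    genome-equivalent pool per probe (None = effectively infinite pool,
    per-read Bernoulli sampling).  ``conversion_rate`` is the probability
    that an unmethylated cytosine converts; ``meth_cpg_error`` the
    probability a methylated CpG reads out as converted; ``seq_error`` the
    per-base substitution rate.
    """

    seed: int = 0
    n_probes: int = 20
    cpgs_per_probe: tuple[int, int] = (3, 21)
    amplicon_len: tuple[int, int] = (75, 150)
    primer_len: tuple[int, int] = (21, 31)
    depth_per_probe: float = 300.0
    tumour_fraction: float = 0.0
    conversion_rate: float = 0.99
    meth_cpg_error: float = 0.005
    seq_error: float = 0.002
    short_read_fraction: float = 0.0
    short_read_len: int = 80
    probe_meth_prob: float = 1.0
    methylation_bias: float = 1.0
    templates_per_probe: int | None = None
    include_brca1: bool = False

    def __post_init__(self) -> None:
        for name in (
            "tumour_fraction",
            "conversion_rate",
            "meth_cpg_error",
            "seq_error",
            "short_read_fraction",
            "probe_meth_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must be a probability in [0, 1]")
        if self.methylation_bias <= 0:
            raise ValueError("methylation_bias must be positive")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ReadTruth:
    """Ground truth for one simulated read set."""

    reads: pd.DataFrame  # read_id, probe_id, origin, template_methylated, truncated
    probe_methylated: dict[str, bool]  # tumour-compartment flag per probe
    tumour_fraction: float
    seed: int

    def tumour_read_fraction(self, probe_id: str) -> float:
        """Fraction of this probe's reads drawn from methylated templates."""
        sub = self.reads[self.reads.probe_id == probe_id]
        if len(sub) == 0:
            return float("nan")
        return float(sub.template_methylated.mean())


# ---------------------------------------------------------------------------
# genome + panel

def _random_seq_no_cpg(n: int, rng: np.random.Generator) -> list[str]:
    """Random DNA of length n containing no CG dinucleotide."""
    seq: list[str] = []
    prev = ""
    for _ in range(n):
        choices = "ACT" if prev == "C" else "ACGT"
        base = choices[rng.integers(len(choices))]
        seq.append(base)
        prev = base
    return seq


def _plant_cpgs(
    seq: list[str], lo: int, hi: int, k: int, rng: np.random.Generator
) -> None:
    """Plant k CpG dinucleotides at grid-spaced positions in seq[lo:hi).

    Slots are 3 bp apart so planted dinucleotides never overlap and never
    create accidental CpGs with their neighbours.
    """
    if k <= 0:
        return
    grid = np.arange(lo, hi - 1, 3)
    if len(grid) < k:
        raise ValueError(f"cannot place {k} CpGs in seq[{lo}:{hi})")
    slots = np.sort(rng.choice(len(grid), size=k, replace=False))
    for s in slots:
        p = int(grid[s])
        seq[p] = "C"
        seq[p + 1] = "G"


def simulate_genome_and_panel(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[str, PanelDefinition]:
    """Synthetic genome carrying ``n_probes`` non-overlapping legal amplicons.

    Each amplicon gets 21-31 bp primers copied from its fully-methylated
    converted strand (with 1-3 CpGs planted per primer footprint, mirroring
    the methylation-biased primer design) and a chosen number of inter-primer
    CpGs.  Infeasible requests — more CpGs than fit between the primers at
    the maximum product size — raise before anything is emitted.  With
    ``include_brca1`` the last probe is tagged BRCA1 (excluded from the MI).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    k_lo, k_hi = config.cpgs_per_probe
    len_lo, len_hi = config.amplicon_len
    p_lo, p_hi = config.primer_len
    if len_hi < 2 * p_lo + 3 * k_lo + 2:
        raise ValueError(
            f"infeasible: {k_lo} CpGs plus two >={p_lo}-bp primers cannot fit "
            f"in a {len_hi}-bp product"
        )

    genome_parts: list[str] = []
    probes: list[PanelProbe] = []
    offset = 0
    for idx in range(config.n_probes):
        k = int(rng.integers(k_lo, k_hi + 1))
        probe = None
        for _attempt in range(100):
            lf = int(rng.integers(p_lo, p_hi + 1))
            lr = int(rng.integers(p_lo, p_hi + 1))
            min_len = max(len_lo, lf + lr + 3 * k + 2)
            if min_len > len_hi:
                continue
            amp_len = int(rng.integers(min_len, len_hi + 1))
            seq = _random_seq_no_cpg(amp_len, rng)
            _plant_cpgs(seq, lf + 1, amp_len - lr - 1, k, rng)
            for flo, fhi in ((1, lf - 2), (amp_len - lr + 1, amp_len - 2)):
                try:
                    _plant_cpgs(seq, flo, fhi, int(rng.integers(1, 4)), rng)
                except ValueError:
                    pass  # footprint too short for that many; skip
            genomic = "".join(seq)
            conv = bisulfite_convert(genomic, True)
            fwd = conv[:lf]
            rev = revcomp(conv[amp_len - lr :])
            spacer = "".join(_random_seq_no_cpg(40, rng))
            pid = (
                "BRCA1"
                if (config.include_brca1 and idx == config.n_probes - 1)
                else f"probe_{idx + 1:03d}"
            )
            try:
                probe = build_probe(
                    genomic,
                    fwd,
                    rev,
                    probe_id=pid,
                    region_id=f"region_{idx + 1:03d}",
                    chrom="chrS",
                    genomic_start=offset + len(spacer),
                    is_brca1=(pid == "BRCA1"),
                )
            except ValueError:
                continue
            if len(probe.cpg_offsets) != k:
                probe = None
                continue
            genome_parts.extend((spacer, genomic))
            offset += len(spacer) + len(genomic)
            probes.append(probe)
            break
        if probe is None:
            raise ValueError(f"could not construct a legal amplicon for probe {idx}")

    genome = "".join(genome_parts)
    panel = PanelDefinition(probes, version=f"sim-seed{config.seed}")
    conv_genome = bisulfite_convert(genome, True)
    for p in panel:
        if conv_genome.count(p.fwd_primer) != 1:
            raise RuntimeError(f"forward primer of {p.probe_id} not unique in genome")
    return genome, panel


# ---------------------------------------------------------------------------
# reads

_BASE_CODES = np.frombuffer(b"ACGT", dtype="S1")


def _make_reads_batch(
    probe: PanelProbe,
    template_methylated: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[str], np.ndarray]:
    """Vectorised read synthesis for one probe.

    ``template_methylated`` is a boolean vector (one per read).  Returns the
    read sequences and the per-read truncation flags.
    """
    n = len(template_methylated)
    L = probe.amplicon_length
    if n == 0:
        return [], np.zeros(0, dtype=bool)
    meth = np.frombuffer(probe.ref_methylated.encode(), dtype="S1")
    unmeth = np.frombuffer(probe.ref_unmethylated.encode(), dtype="S1")
    M = np.tile(unmeth, (n, 1))
    cpg_cols = np.where(meth != unmeth)[0]  # every CpG cytosine of the amplicon
    meth_rows = np.where(template_methylated)[0]
    unmeth_rows = np.where(~template_methylated)[0]

    if cpg_cols.size:
        if meth_rows.size:
            # methylated CpGs stay C except for read-out error
            err = rng.random((meth_rows.size, cpg_cols.size)) < config.meth_cpg_error
            M[np.ix_(meth_rows, cpg_cols)] = np.where(err, b"T", b"C")
        if unmeth_rows.size:
            # unmethylated CpGs escape conversion with 1 - conversion_rate
            fail = (
                rng.random((unmeth_rows.size, cpg_cols.size)) >= config.conversion_rate
            )
            block = M[np.ix_(unmeth_rows, cpg_cols)]
            M[np.ix_(unmeth_rows, cpg_cols)] = np.where(fail, b"C", block)
    nc = np.asarray(probe.noncpg_c_offsets, dtype=int)
    if nc.size:
        # non-CpG cytosines escape conversion with 1 - conversion_rate
        fail = rng.random((n, nc.size)) >= config.conversion_rate
        block = M[:, nc]
        M[:, nc] = np.where(fail, b"C", block)

    # PCR products carry the primers' own sequence (the methylated converted
    # strand) regardless of template state — that is the methylation bias's
    # mechanism — so the footprints are stamped after template noise
    lf, lr = len(probe.fwd_primer), len(probe.rev_primer)
    M[:, :lf] = meth[:lf]
    M[:, L - lr :] = meth[L - lr :]

    if config.seq_error > 0:
        hit = rng.random((n, L)) < config.seq_error
        if hit.any():
            rows, cols = np.where(hit)
            cur = M[rows, cols]
            codes = np.searchsorted(_BASE_CODES, cur)
            new = (codes + rng.integers(1, 4, size=codes.size)) % 4
            M[rows, cols] = _BASE_CODES[new]

    truncated = rng.random(n) < config.short_read_fraction
    seqs = []
    for i in range(n):
        row = M[i, : config.short_read_len] if truncated[i] else M[i]
        seqs.append(row.tobytes().decode())
    return seqs, truncated


def simulate_reads(
    panel: PanelDefinition,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "S1",
    probe_methylated: dict[str, bool] | None = None,
) -> tuple[list, ReadTruth]:
    """Draw one sample's read set across the panel.

    Per probe the read count is Poisson(``depth_per_probe``).  Each read
    descends from a tumour template with a probability set by
    ``tumour_fraction``, the methylation bias, and (optionally) a finite
    template pool; tumour templates are fully methylated iff the probe's
    tumour-compartment flag is set, background templates are unmethylated.
    """
    from .readproc import ReadRecord

    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if probe_methylated is None:
        probe_methylated = {
            p.probe_id: bool(rng.random() < config.probe_meth_prob) for p in panel
        }
    reads = []
    truth_rows = []
    tf = config.tumour_fraction
    for probe in panel:
        n_reads = int(rng.poisson(config.depth_per_probe))
        meth_flag = probe_methylated[probe.probe_id]
        bias = config.methylation_bias if meth_flag else 1.0
        if config.templates_per_probe is None:
            p_tum = (bias * tf) / (bias * tf + (1 - tf)) if tf > 0 else 0.0
        else:
            m = config.templates_per_probe
            k = int(rng.binomial(m, tf))
            p_tum = (bias * k) / (bias * k + (m - k)) if k > 0 else 0.0
        is_tumour = rng.random(n_reads) < p_tum
        tmpl_meth = is_tumour & meth_flag
        seqs, truncated = _make_reads_batch(probe, tmpl_meth, config, rng)
        for r, seq in enumerate(seqs):
            rid = f"{sample_id}:{probe.probe_id}:{r:06d}"
            reads.append(ReadRecord(read_id=rid, sequence=seq))
            truth_rows.append(
                (rid, probe.probe_id,
                 "tumour" if is_tumour[r] else "background",
                 bool(tmpl_meth[r]), bool(truncated[r]))
            )
    truth = ReadTruth(
        reads=pd.DataFrame(
            truth_rows,
            columns=[
                "read_id", "probe_id", "origin", "template_methylated", "truncated",
            ],
        ),
        probe_methylated=probe_methylated,
        tumour_fraction=tf,
        seed=config.seed,
    )
    return reads, truth


# ---------------------------------------------------------------------------
# beta matrices

@dataclass
class BetaTruth:
    planted_cpgs: list[str]
    planted_regions: list[tuple[str, int, int, list[str]]]  # chrom, start, end, members
    seed: int


def simulate_beta_matrix(
    n_tumour: int = 20,
    n_normal_per_tissue: int = 8,
    n_cpgs: int = 1000,
    n_dmrs: int = 7,
    dmr_size: tuple[int, int] = (2, 4),
    tumour_beta: float = 0.9,
    normal_beta: float = 0.05,
    noise_sd: float = 0.02,
    planted_tumour_frequency: float = 1.0,
    normal_tissues: tuple[str, ...] = (
        "normal-breast",
        "normal-lung",
        "normal-colon",
        "normal-prostate",
    ),
    seed: int = 0,
) -> tuple[BetaMatrix, BetaTruth]:
    """450k-style beta matrix with planted hypermethylated DMR clusters.

    Background CpGs are low-beta (mean ``normal_beta``) in every group and
    sit 400 bp apart, so no background pair can chain at the 300 bp rule;
    planted clusters have intra-cluster gaps of 50-250 bp and are high-beta
    (mean ``tumour_beta``) in a ``planted_tumour_frequency`` fraction of
    tumour samples only.  Betas are clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    sizes = rng.integers(dmr_size[0], dmr_size[1] + 1, size=n_dmrs)
    n_planted = int(sizes.sum())
    if n_planted > n_cpgs:
        raise ValueError("more planted CpGs than total CpGs requested")
    n_background = n_cpgs - n_planted
    if n_background < n_dmrs + 1:
        raise ValueError("too few background CpGs to separate the planted clusters")

    insert_at = set(
        int(x)
        for x in rng.choice(np.arange(1, n_background), size=n_dmrs, replace=False)
    )
    positions: list[int] = []
    planted_idx: list[int] = []
    regions: list[tuple[int, int]] = []
    size_iter = iter(sizes)
    pos = 1000
    for bg in range(n_background):
        if bg in insert_at:
            csize = int(next(size_iter))
            start_idx = len(positions)
            for j in range(csize):
                pos += 400 if j == 0 else int(rng.integers(50, 251))
                positions.append(pos)
                planted_idx.append(len(positions) - 1)
            regions.append((start_idx, len(positions)))
        positions.append(pos + 400)
        pos += 400
    n_rows = len(positions)

    cpg_ids = [f"cg{i:07d}" for i in range(n_rows)]
    groups = ["tumour"] * n_tumour + [
        t for t in normal_tissues for _ in range(n_normal_per_tissue)
    ]
    sample_ids = [f"T{i:02d}" for i in range(n_tumour)] + [
        f"{t}-{i:02d}" for t in normal_tissues for i in range(n_normal_per_tissue)
    ]
    values = rng.normal(normal_beta, noise_sd, size=(n_rows, len(sample_ids)))
    n_high = max(1, int(round(planted_tumour_frequency * n_tumour)))
    for row in planted_idx:
        high_cols = rng.choice(n_tumour, size=n_high, replace=False)
        values[row, high_cols] = rng.normal(tumour_beta, noise_sd, size=n_high)
    values = np.clip(values, 0.0, 1.0)

    beta = BetaMatrix(
        cpg_ids=cpg_ids,
        chrom=np.array(["chr4"] * n_rows, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        values=values,
        sample_ids=sample_ids,
        group_labels=groups,
    )
    truth = BetaTruth(
        planted_cpgs=[cpg_ids[i] for i in planted_idx],
        planted_regions=[
            ("chr4", positions[a], positions[b - 1] + 1, [cpg_ids[i] for i in range(a, b)])
            for a, b in regions
        ],
        seed=seed,
    )
    return beta, truth


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class SimulatedSample:
    sample_id: str
    label: str  # "case" or "control"
    tumour_fraction: float
    reads: list
    truth: ReadTruth


def simulate_cohort(
    panel: PanelDefinition,
    n_cases: int,
    n_controls: int,
    tumour_fractions,
    config: SimConfig,
    control_background_rate: float = 0.0,
    background_fraction: float = 0.5,
    rng: np.random.Generator | None = None,
) -> list[SimulatedSample]:
    """Simulate a case/control cohort of per-sample read sets.

    ``tumour_fractions`` is a scalar, a sequence of length ``n_cases``, or a
    callable drawing one fraction per case from ``rng``.  Controls run at
    tumour fraction 0, but each control probe independently acquires sporadic
    background with probability ``control_background_rate`` (healthy-cohort
    positives occur randomly, with no association between probes); a struck
    probe behaves as if ``background_fraction`` of its templates were
    methylated.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if callable(tumour_fractions):
        fracs = [float(tumour_fractions(rng)) for _ in range(n_cases)]
    elif np.isscalar(tumour_fractions):
        fracs = [float(tumour_fractions)] * n_cases
    else:
        fracs = [float(f) for f in tumour_fractions]
        if len(fracs) != n_cases:
            raise ValueError("tumour_fractions length must equal n_cases")

    samples = []
    for i in range(n_cases):
        sid = f"case_{i + 1:03d}"
        cfg = config.replace(tumour_fraction=fracs[i])
        reads, truth = simulate_reads(panel, cfg, rng=rng, sample_id=sid)
        samples.append(SimulatedSample(sid, "case", fracs[i], reads, truth))
    for i in range(n_controls):
        sid = f"control_{i + 1:03d}"
        struck = {
            p.probe_id: bool(rng.random() < control_background_rate) for p in panel
        }
        all_reads: list = []
        frames = []
        for probe in panel:
            tf = background_fraction if struck[probe.probe_id] else 0.0
            cfg = config.replace(tumour_fraction=tf)
            reads, truth = simulate_reads(
                PanelDefinition([probe], version=panel.version),
                cfg,
                rng=rng,
                sample_id=sid,
                probe_methylated={probe.probe_id: struck[probe.probe_id]},
            )
            all_reads.extend(reads)
            frames.append(truth.reads)
        truth = ReadTruth(
            reads=pd.concat(frames, ignore_index=True),
            probe_methylated=struck,
            tumour_fraction=0.0,
            seed=config.seed,
        )
        samples.append(SimulatedSample(sid, "control", 0.0, all_reads, truth))
    return samples


def write_fastq(reads, path) -> None:
    """Write ReadRecords as FASTQ (constant quality)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
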