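"""End-to-end conveniences: reads in, sample reports and cohort metrics out."""

from __future__ import annotations

from .bisref import PanelDefinition
from .readproc import process_reads
from .scoring import (
    CohortMatrix,
    RocResult,
    SampleReport,
    build_sample_report,
    roc,
)

__all__ = ["run_sample", "run_cohort"]


def run_sample(
    reads,
    panel: PanelDefinition,
    sample_id: str = "sample",
    min_len: int = 100,
    min_identity: float = 0.90,
    max_primer_mismatches: int = 2,
    min_reads: int = 100,
    fraction_threshold: float = 0.1,
    mi_threshold: float = 2.5,
) -> SampleReport:
    """Process one sample's reads through calling and scoring."""
    callsets, _, _ = process_reads(
        reads,
        panel,
        min_len=min_len,
        min_identity=min_identity,
        max_primer_mismatches=max_primer_mismatches,
    )
    return build_sample_report(
        sample_id,
        callsets,
        panel,
        min_reads=min_reads,
        fraction_threshold=fraction_threshold,
        mi_threshold=mi_threshold,
    )


def run_cohort(
    samples,
    panel: PanelDefinition,
    **kwargs,
) -> tuple[list[SampleReport], CohortMatrix, RocResult]:
    """Process a list of simulated (or loaded) samples and summarise.

    ``samples`` holds objects with ``sample_id``, ``label`` ("case" or
    "control") and ``reads``.  Returns the per-sample reports, the cohort
    fraction/positivity matrix with per-sample MI, and the ROC summary.
    """
    reports = []
    groups = {}
    for s in samples:
        reports.append(run_sample(s.reads, panel, sample_id=s.sample_id, **kwargs))
        groups[s.sample_id] = s.label
    cohort = CohortMatrix.from_reports(reports, groups)
    result = roc(cohort.mi.to_numpy(), cohort.groups.to_numpy())
    return reports, cohort, result
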