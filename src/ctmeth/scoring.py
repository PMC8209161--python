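"""Per-probe fractions, the Methylation Index, QC, and cohort metrics.

For each probe in each sample the fully-methylated-read fraction
f = fully_methylated_reads / pass_reads is computed over BiQ-filtered reads.
A probe is evaluable only with at least 100 passing reads (low-count probes
show spurious signal from partially converted templates) and positive when
f >= 0.1.  The per-sample Methylation Index (MI) is the count of positive
MI-eligible probes (BRCA1 is excluded), and a sample is called positive when
MI exceeds 2.5 — i.e. three or more positive probes.  Probe-level QC drops
probes positive in three or more control samples (BRCA1 exempt).  Cohort
performance is summarised by the rank-based AUC and the sensitivity at 100%
specificity (fraction of cases strictly above the maximum control MI).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .bisref import PanelDefinition
from .readproc import ReadCallSet

__all__ = [
    "ProbeResult",
    "SampleReport",
    "CohortMatrix",
    "RocResult",
    "score_probe",
    "methylation_index",
    "classify",
    "build_sample_report",
    "qc_probes",
    "roc",
    "correlate",
]

DEFAULT_MIN_READS = 100
DEFAULT_FRACTION_THRESHOLD = 0.1
DEFAULT_MI_THRESHOLD = 2.5
DEFAULT_MAX_CONTROL_POSITIVES = 3


@dataclass
class ProbeResult:
    """One probe's read counts, methylated fraction and positivity in one sample."""

    probe_id: str
    pass_reads: int
    fully_methylated_reads: int
    fraction: float  # NaN when pass_reads == 0
    evaluable: bool
    positive: bool


@dataclass
class SampleReport:
    """Per-sample scoring summary across the panel."""

    sample_id: str
    probe_results: list[ProbeResult]
    methylation_index: int
    call: bool
    brca1_methylated: bool
    brca1_caveat: bool  # BRCA1 positive while the panel call is negative
    n_evaluable: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "probe_id": r.probe_id,
                    "pass_reads": r.pass_reads,
                    "fully_methylated_reads": r.fully_methylated_reads,
                    "fraction": r.fraction,
                    "evaluable": r.evaluable,
                    "positive": r.positive,
                }
                for r in self.probe_results
            ]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "sample_id": self.sample_id,
                "methylation_index": self.methylation_index,
                "call": "positive" if self.call else "negative",
                "brca1_methylated": self.brca1_methylated,
                "brca1_caveat": self.brca1_caveat,
                "n_evaluable": self.n_evaluable,
            }
        )


def score_probe(
    calls: ReadCallSet,
    min_reads: int = DEFAULT_MIN_READS,
    fraction_threshold: float = DEFAULT_FRACTION_THRESHOLD,
) -> ProbeResult:
    """Fraction and positivity for one probe.

    f is fully_methylated_reads over pass_reads (NaN when no reads pass);
    the probe is evaluable with pass_reads >= ``min_reads`` and positive when
    evaluable and f is at or above ``fraction_threshold``.
    """
    if calls.pass_reads > 0:
        fraction = calls.fully_methylated_reads / calls.pass_reads
    else:
        fraction = float("nan")
    evaluable = calls.pass_reads >= min_reads
    positive = bool(evaluable and fraction >= fraction_threshold)
    return ProbeResult(
        probe_id=calls.probe_id,
        pass_reads=calls.pass_reads,
        fully_methylated_reads=calls.fully_methylated_reads,
        fraction=fraction,
        evaluable=evaluable,
        positive=positive,
    )


def methylation_index(results: list[ProbeResult], panel: PanelDefinition) -> int:
    """Count of positive MI-eligible (non-BRCA1) probes."""
    known = set(panel.probe_ids)
    eligible = set(panel.mi_eligible)
    mi = 0
    for r in results:
        if r.probe_id not in known:
            raise ValueError(f"result for unknown probe id {r.probe_id!r}")
        if r.positive and r.probe_id in eligible:
            mi += 1
    return mi


def classify(mi: int, mi_threshold: float = DEFAULT_MI_THRESHOLD) -> bool:
    """Sample call: positive iff MI strictly exceeds the threshold
    (default 2.5, so MI >= 3 is positive and MI <= 2 negative)."""
    return mi > mi_threshold


def build_sample_report(
    sample_id: str,
    callsets: dict[str, ReadCallSet],
    panel: PanelDefinition,
    min_reads: int = DEFAULT_MIN_READS,
    fraction_threshold: float = DEFAULT_FRACTION_THRESHOLD,
    mi_threshold: float = DEFAULT_MI_THRESHOLD,
) -> SampleReport:
    """Score every panel probe for one sample and assemble the report.

    A probe with no callset is scored as zero reads (not evaluable).  BRCA1
    methylation is reported, but flagged with a caveat when the panel call is
    negative: in isolation it may reflect hematopoietic rather than tumour
    signal.
    """
    results = []
    for probe in panel:
        cs = callsets.get(
            probe.probe_id, ReadCallSet(probe.probe_id, 0, 0, 0)
        )
        results.append(
            score_probe(cs, min_reads=min_reads, fraction_threshold=fraction_threshold)
        )
    mi = methylation_index(results, panel)
    call = classify(mi, mi_threshold)
    brca1_ids = {p.probe_id for p in panel if p.is_brca1}
    brca1_pos = any(r.positive for r in results if r.probe_id in brca1_ids)
    return SampleReport(
        sample_id=sample_id,
        probe_results=results,
        methylation_index=mi,
        call=call,
        brca1_methylated=brca1_pos,
        brca1_caveat=brca1_pos and not call,
        n_evaluable=sum(r.evaluable for r in results),
    )


@dataclass
class CohortMatrix:
    """Fractions and positivity across a cohort (rows = samples, cols = probes).

    ``fractions`` holds NaN where a probe was not evaluable; ``positivity``
    is boolean.  ``groups`` maps each sample to "case" or "control"; ``mi``
    holds the per-sample Methylation Index.
    """

    fractions: pd.DataFrame
    positivity: pd.DataFrame
    groups: pd.Series
    mi: pd.Series = None

    def __post_init__(self) -> None:
        if not self.fractions.shape == self.positivity.shape:
            raise ValueError("fractions and positivity dimensions disagree")
        if not set(self.groups.unique()) <= {"case", "control"}:
            raise ValueError("group labels must be 'case' or 'control'")

    @classmethod
    def from_reports(
        cls, reports: list[SampleReport], groups: dict[str, str]
    ) -> "CohortMatrix":
        frac = {}
        pos = {}
        mi = {}
        for rep in reports:
            frac[rep.sample_id] = {
                r.probe_id: (r.fraction if r.evaluable else float("nan"))
                for r in rep.probe_results
            }
            pos[rep.sample_id] = {r.probe_id: r.positive for r in rep.probe_results}
            mi[rep.sample_id] = rep.methylation_index
        fractions = pd.DataFrame.from_dict(frac, orient="index")
        positivity = pd.DataFrame.from_dict(pos, orient="index")
        return cls(
            fractions=fractions,
            positivity=positivity,
            groups=pd.Series({s: groups[s] for s in fractions.index}),
            mi=pd.Series(mi),
        )

    def controls(self) -> "CohortMatrix":
        idx = self.groups[self.groups == "control"].index
        return CohortMatrix(
            fractions=self.fractions.loc[idx],
            positivity=self.positivity.loc[idx],
            groups=self.groups.loc[idx],
            mi=self.mi.loc[idx] if self.mi is not None else None,
        )


def qc_probes(
    controls: CohortMatrix,
    max_control_positives: int = DEFAULT_MAX_CONTROL_POSITIVES,
    panel: PanelDefinition | None = None,
) -> list[str]:
    """Probes positive in >= ``max_control_positives`` control samples.

    Run on a control-only cohort; returns the probes to drop.  A BRCA1 probe
    is never dropped (it is retained in the assay for its treatment relevance
    even with sporadic control positivity).
    """
    if len(controls.positivity) == 0:
        raise ValueError("empty control cohort")
    if (controls.groups != "control").any():
        raise ValueError("qc_probes expects a control-only cohort")
    counts = controls.positivity.sum(axis=0)
    drop = [str(p) for p, c in counts.items() if c >= max_control_positives]
    if panel is not None:
        brca1 = {p.probe_id for p in panel if p.is_brca1}
        drop = [p for p in drop if p not in brca1]
    return drop


@dataclass
class RocResult:
    auc: float
    sensitivity_at_full_specificity: float
    table: pd.DataFrame = field(repr=False, default=None)


def roc(scores, labels) -> RocResult:
    """Rank-based ROC of per-sample scores (MI) against case/control labels.

    AUC is the concordance of case-vs-control score pairs with ties counted
    one half.  Sensitivity at 100% specificity is the fraction of cases whose
    score strictly exceeds the maximum control score.  The operating table
    lists sensitivity/specificity at every distinct threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_case = labels == "case"
    if is_case.all() or (~is_case).all():
        raise ValueError("need at least one case and one control")
    auc = float(roc_auc_score(is_case.astype(int), scores))
    max_control = scores[~is_case].max()
    sens100 = float(np.mean(scores[is_case] > max_control))
    rows = []
    for thr in np.concatenate(([-np.inf], np.unique(scores))):
        called = scores > thr  # positive = strictly above threshold
        rows.append(
            {
                "threshold": float(thr),
                "sensitivity": float(np.mean(called[is_case])),
                "specificity": float(np.mean(~called[~is_case])),
            }
        )
    return RocResult(
        auc=auc,
        sensitivity_at_full_specificity=sens100,
        table=pd.DataFrame(rows),
    )


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n: int


def correlate(x, y) -> CorrelationResult:
    """Pearson correlation between two per-sample score vectors.

    Missing values are dropped pairwise; at least 3 complete pairs are
    required and either vector being constant is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("score vectors must be paired (same length)")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), r_squared=float(r) ** 2, p_value=float(p), n=len(x))


def plot_cohort_heatmap(cohort: CohortMatrix, path) -> None:
    """Save a samples-by-probes heatmap of methylated fractions (0 to 1).

    Non-evaluable probes render blank.  Rows are ordered controls first,
    mirroring the usual presentation of cohort fraction matrices.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = cohort.groups.sort_values(kind="mergesort").index
    data = cohort.fractions.loc[order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.18 * data.shape[1]), max(3, 0.18 * data.shape[0]))
    )
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="Reds", vmin=0, vmax=1)
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(data.shape[0]), data.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="fully-methylated read fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
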