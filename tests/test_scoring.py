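"""Probe positivity, Methylation Index, QC, ROC and correlation."""

import numpy as np
import pandas as pd
import pytest

from ctmeth.readproc import ReadCallSet
from ctmeth.scoring import (
    CohortMatrix,
    ProbeResult,
    build_sample_report,
    classify,
    correlate,
    methylation_index,
    qc_probes,
    roc,
    score_probe,
)

from oracles import oracle_auc


def _cs(pid, npass, nfull, total=None):
    return ReadCallSet(pid, total if total is not None else npass, npass, nfull)


class TestScoreProbe:
    @pytest.mark.parametrize(
        "npass,nfull,evaluable,positive",
        [
            (150, 15, True, True),    # f = 0.10 exactly: at-or-above is positive
            (99, 99, False, False),   # below the 100-read floor
            (100, 10, True, True),    # boundary reads, boundary fraction
            (200, 10, True, False),   # f = 0.05
            (200, 19, True, False),   # f = 0.095 just under
            (0, 0, False, False),
        ],
    )
    def test_thresholds(self, npass, nfull, evaluable, positive):
        res = score_probe(_cs("p", npass, nfull))
        assert res.evaluable is evaluable
        assert res.positive is positive

    def test_fraction_nan_when_no_pass_reads(self):
        res = score_probe(_cs("p", 0, 0, total=5))
        assert np.isnan(res.fraction)

    def test_monotone_in_thresholds(self):
        res = score_probe(_cs("p", 80, 8), min_reads=50)
        assert res.positive
        # raising min_reads can only lose positivity
        assert not score_probe(_cs("p", 80, 8), min_reads=100).positive
        # lowering the fraction threshold can only gain it
        assert score_probe(_cs("p", 200, 10), fraction_threshold=0.05).positive


class TestMethylationIndex:
    def _results(self, panel, positives):
        return [
            ProbeResult(p.probe_id, 200, 100 if p.probe_id in positives else 0,
                        0.5 if p.probe_id in positives else 0.0,
                        True, p.probe_id in positives)
            for p in panel
        ]

    def test_counts_positive_probes(self, small_panel):
        pos = set(small_panel.probe_ids[:3])
        assert methylation_index(self._results(small_panel, pos), small_panel) == 3

    def test_brca1_excluded(self, brca1_panel):
        pos = set(brca1_panel.probe_ids[:2]) | {"BRCA1"}
        assert methylation_index(self._results(brca1_panel, pos), brca1_panel) == 2

    def test_all_negative(self, small_panel):
        assert methylation_index(self._results(small_panel, set()), small_panel) == 0

    def test_unknown_probe_rejected(self, small_panel):
        bogus = [ProbeResult("nope", 200, 0, 0.0, True, False)]
        with pytest.raises(ValueError, match="unknown probe"):
            methylation_index(bogus, small_panel)


@pytest.mark.parametrize("mi,call", [(0, False), (2, False), (3, True), (10, True)])
def test_classify_strict_threshold(mi, call):
    """MI 2 is negative and MI 3 positive at the 2.5-probe threshold."""
    assert classify(mi) is call


class TestSampleReport:
    def test_brca1_caveat_when_panel_negative(self, brca1_panel):
        callsets = {p.probe_id: _cs(p.probe_id, 200, 0) for p in brca1_panel}
        callsets["BRCA1"] = _cs("BRCA1", 200, 100)
        rep = build_sample_report("s1", callsets, brca1_panel)
        assert rep.brca1_methylated and not rep.call
        assert rep.brca1_caveat
        assert rep.methylation_index == 0

    def test_brca1_no_caveat_when_panel_positive(self, brca1_panel):
        callsets = {p.probe_id: _cs(p.probe_id, 200, 100) for p in brca1_panel}
        rep = build_sample_report("s1", callsets, brca1_panel)
        assert rep.call and rep.brca1_methylated and not rep.brca1_caveat
        assert rep.methylation_index == brca1_panel.n_mi_eligible

    def test_missing_probe_counts_as_not_evaluable(self, small_panel):
        callsets = {small_panel.probe_ids[0]: _cs(small_panel.probe_ids[0], 200, 100)}
        rep = build_sample_report("s1", callsets, small_panel)
        assert rep.n_evaluable == 1
        assert rep.methylation_index == 1


def _control_matrix(pos_df):
    n = len(pos_df)
    return CohortMatrix(
        fractions=pos_df.astype(float),
        positivity=pos_df,
        groups=pd.Series(["control"] * n, index=pos_df.index),
    )


class TestQcProbes:
    def test_three_or_more_dropped_two_kept(self):
        pos = pd.DataFrame(
            {"a": [True] * 3 + [False] * 17, "b": [True] * 2 + [False] * 18},
            index=[f"c{i}" for i in range(20)],
        )
        assert qc_probes(_control_matrix(pos)) == ["a"]

    def test_synthetic_68_probe_cohort(self, rng):
        """Planted elevated-background probes are exactly the ones dropped."""
        n_controls, n_probes = 25, 68
        elevated = set(rng.choice(n_probes, size=14, replace=False))
        mat = np.zeros((n_controls, n_probes), dtype=bool)
        for j in range(n_probes):
            k = int(rng.integers(3, 8)) if j in elevated else int(rng.integers(0, 3))
            mat[rng.choice(n_controls, size=k, replace=False), j] = True
        pos = pd.DataFrame(
            mat,
            index=[f"c{i}" for i in range(n_controls)],
            columns=[f"p{j:02d}" for j in range(n_probes)],
        )
        dropped = qc_probes(_control_matrix(pos))
        # column-count oracle
        expected = [c for c in pos.columns if int(pos[c].sum()) >= 3]
        assert dropped == expected
        assert set(dropped) == {f"p{j:02d}" for j in sorted(elevated)}

    def test_never_drops_zero_positive_probe(self, rng):
        pos = pd.DataFrame(
            rng.random((10, 5)) < 0.5, index=[f"c{i}" for i in range(10)],
            columns=list("abcde"),
        )
        pos["clean"] = False
        assert "clean" not in qc_probes(_control_matrix(pos))

    def test_brca1_exempt(self, brca1_panel):
        pos = pd.DataFrame(
            {"BRCA1": [True] * 4 + [False] * 16, "x": [True] * 4 + [False] * 16},
            index=[f"c{i}" for i in range(20)],
        )
        assert qc_probes(_control_matrix(pos), panel=brca1_panel) == ["x"]

    def test_requires_controls(self):
        empty = pd.DataFrame(columns=["a"], dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            qc_probes(_control_matrix(empty))


class TestRoc:
    def _run(self, cases, controls):
        scores = list(cases) + list(controls)
        labels = ["case"] * len(cases) + ["control"] * len(controls)
        return roc(scores, labels)

    def test_perfect_separation(self):
        res = self._run([10, 20], [0, 1])
        assert res.auc == 1.0
        assert res.sensitivity_at_full_specificity == 1.0

    def test_all_ties(self):
        res = self._run([1, 1], [1, 1])
        assert res.auc == 0.5
        assert res.sensitivity_at_full_specificity == 0.0

    def test_matches_pairwise_concordance(self):
        cases, controls = [3, 2, 0, 5], [0, 1, 0, 2]
        res = self._run(cases, controls)
        assert res.auc == pytest.approx(oracle_auc(cases, controls))

    def test_random_cohorts_match_oracle(self, rng):
        for _ in range(100):
            n_case = int(rng.integers(1, 11))
            n_ctrl = int(rng.integers(1, 11))
            cases = rng.integers(0, 8, size=n_case)
            controls = rng.integers(0, 8, size=n_ctrl)
            res = self._run(cases, controls)
            assert res.auc == pytest.approx(oracle_auc(cases, controls))
            assert res.sensitivity_at_full_specificity == pytest.approx(
                np.mean(cases > controls.max())
            )

    def test_operating_table_contains_default_threshold_point(self):
        res = self._run([5, 4, 3], [0, 1, 2])
        row = res.table[res.table.threshold == 2.0]
        assert float(row.sensitivity.iloc[0]) == 1.0
        assert float(row.specificity.iloc[0]) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="case and one control"):
            roc([1, 2], ["case", "case"])


class TestCorrelate:
    def test_perfect_linear(self):
        res = correlate([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_orthogonal(self):
        x = [-1, -1, 1, 1]
        y = [-1, 1, -1, 1]
        assert correlate(x, y).r == pytest.approx(0.0)

    def test_planted_correlation_recovered(self, rng):
        n = 100
        x = rng.normal(size=n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
        res = correlate(x, y)
        # closed-form check against direct covariance computation
        direct = float(np.cov(x, y)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1)))
        assert res.r == pytest.approx(direct)
        assert abs(res.r - 0.5) < 0.25  # within sampling error at n=100

    def test_pairwise_complete(self):
        x = [1, 2, 3, np.nan, 5]
        y = [2, 4, 6, 8, np.nan]
        assert correlate(x, y).n == 3

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="3 complete"):
            correlate([1, 2], [3, 4])


def test_heatmap_renders(tmp_path, rng):
    from ctmeth.scoring import plot_cohort_heatmap

    frac = pd.DataFrame(rng.random((6, 10)),
                        index=[f"s{i}" for i in range(6)],
                        columns=[f"p{j}" for j in range(10)])
    cohort = CohortMatrix(
        fractions=frac,
        positivity=frac >= 0.1,
        groups=pd.Series(["case"] * 3 + ["control"] * 3, index=frac.index),
    )
    out = tmp_path / "cohort.png"
    plot_cohort_heatmap(cohort, out)
    assert out.stat().st_size > 0
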