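"""Eligibility filtering, transition tabulation and baseline summaries."""

import numpy as np
import pandas as pd
import pytest

from metatrans import (
    PanelDataset,
    baseline_summary,
    filter_eligible,
    round_half_up,
    stratify,
    tabulate_transitions,
)
from metatrans.datasets import (
    reference_baseline_panel,
    reference_transition_counts,
    reference_transition_panel,
)
from tests.conftest import make_panel


def _record(sid, t, **over):
    base = dict(
        subject_id=sid, visit_time=t, sex="male", age=30, bmi=22.0, sbp=110,
        dbp=70, fpg=5.0, tg=1.0, hdl=1.4, alt=20, ast=20, scr=80, ua=300,
        excluded_disease_history=False,
    )
    base.update(over)
    return base


def test_round_half_up_is_not_bankers():
    assert round_half_up(1.665, 2) == 1.67
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(2.5, 0) == 3.0


class TestFilterEligible:
    def test_rules_apply_in_order(self):
        rows = []
        # eligible subjects 1-4
        for sid in (1, 2, 3, 4):
            rows += [_record(sid, 0.0), _record(sid, 1.0)]
        # 5: underweight at baseline
        rows += [_record(5, 0.0, bmi=18.2), _record(5, 1.0)]
        # 6: only one visit
        rows += [_record(6, 0.0)]
        panel, report = filter_eligible(pd.DataFrame(rows))
        assert panel.n_subjects == 4
        assert report["underweight"] == 1
        assert report["too_few_visits"] == 1
        assert report["eligible"] == 4

    def test_disease_flag_during_followup_excludes_whole_subject(self):
        rows = [_record(1, 0.0), _record(1, 1.0), _record(1, 2.0, excluded_disease_history=True)]
        rows += [_record(2, 0.0), _record(2, 1.0)]
        panel, report = filter_eligible(pd.DataFrame(rows))
        assert report["disease_history"] == 1
        assert panel.n_subjects == 1

    def test_age_window_inclusive(self):
        rows = [_record(1, 0.0, age=20), _record(1, 1.0, age=21)]
        rows += [_record(2, 0.0, age=60), _record(2, 1.0, age=61)]
        rows += [_record(3, 0.0, age=19.5), _record(3, 1.0, age=20.5)]
        rows += [_record(4, 0.0, age=61), _record(4, 1.0, age=62)]
        panel, report = filter_eligible(pd.DataFrame(rows))
        assert panel.n_subjects == 2
        assert report["age_out_of_range"] == 2

    def test_missing_baseline_measurement_excludes(self):
        rows = [_record(1, 0.0, tg=np.nan), _record(1, 1.0)]
        rows += [_record(2, 0.0), _record(2, 1.0)]
        panel, report = filter_eligible(pd.DataFrame(rows))
        assert report["missing_baseline"] == 1
        assert panel.n_subjects == 1

    def test_all_eligible_is_identity_and_empty_is_empty(self):
        rows = [_record(1, 0.0), _record(1, 1.0), _record(2, 0.0), _record(2, 1.0)]
        panel, report = filter_eligible(pd.DataFrame(rows))
        assert panel.n_subjects == 2 and sum(
            v for k, v in report.items() if k != "eligible"
        ) == 0
        empty, report = filter_eligible(pd.DataFrame(columns=list(rows[0])))
        assert empty.n_subjects == 0 and report["eligible"] == 0


class TestTabulateTransitions:
    def test_single_pair_and_three_visit_chain(self):
        tcm = tabulate_transitions(make_panel([(1, 1)]))
        assert tcm.counts[0, 0] == 1 and tcm.row_percent[0, 0] == 100.00
        tcm = tabulate_transitions(make_panel([(1, 2, 1)]))
        assert tcm.counts[0, 1] == 1 and tcm.counts[1, 0] == 1
        assert tcm.counts.sum() == 2  # 3 visits -> 2 transitions

    def test_total_count_identity(self):
        panel = make_panel([(1, 2), (3, 3, 4), (5, 6, 5, 2)])
        assert tabulate_transitions(panel).counts.sum() == panel.n_transitions == 6

    def test_invariant_to_subject_order_and_time_shift(self):
        seqs = [(1, 4, 4), (2, 2), (6, 5)]
        a = tabulate_transitions(make_panel(seqs))
        b = tabulate_transitions(make_panel(list(reversed(seqs))))
        shifted = make_panel(seqs, times=[[10, 11, 12], [3, 4.5], [0.5, 9]])
        c = tabulate_transitions(shifted)
        assert (a.counts == b.counts).all() and (a.counts == c.counts).all()

    def test_reference_counts_reproduced(self):
        tcm = tabulate_transitions(reference_transition_panel())
        assert (tcm.counts == reference_transition_counts()).all()
        # row percentages sum to 100 within rounding
        assert np.abs(tcm.row_percent.sum(axis=1) - 100).max() < 0.03


class TestBaselineSummary:
    def test_reference_composition(self):
        s = baseline_summary(reference_baseline_panel())
        assert s.n_total == 9742
        assert s.unhealthy_percent == 33.29
        assert s.unhealthy_percent_by_weight["obese"] == 68.77
        assert s.unhealthy_percent_by_weight["overweight"] == 46.85

    def test_single_subject(self):
        s = baseline_summary(make_panel([(6, 6)]))
        assert s.percent[5] == 100.00 and s.unhealthy_percent == 100.00


class TestStratify:
    def _covpanel(self, female, middle):
        return make_panel(
            [(1, 1)] * len(female),
            covariates={"female": female, "middle_aged": middle},
        )

    def test_one_subject_per_stratum(self):
        panel = self._covpanel([0, 1, 0, 1], [0, 0, 1, 1])
        strata = stratify(panel)
        assert len(strata) == 4
        assert all(s.n_subjects == 1 for s in strata.values())

    def test_all_female_gives_two_nonempty_strata(self):
        panel = self._covpanel([1, 1, 1], [0, 1, 0])
        strata = stratify(panel)
        nonempty = {k for k, s in strata.items() if s.n_subjects}
        assert nonempty == {(1, 0), (1, 1)}

    def test_empty_panel_gives_four_empty_strata(self):
        empty = PanelDataset(
            pd.DataFrame(columns=["subject_id", "time", "state", "female", "middle_aged"])
        )
        strata = stratify(empty)
        assert len(strata) == 4 and all(s.n_subjects == 0 for s in strata.values())


def test_panel_validation_rejects_bad_input():
    with pytest.raises(ValueError):
        make_panel([(1,)])  # single visit
    with pytest.raises(ValueError):
        make_panel([(0, 1)])  # state out of range
    with pytest.raises(ValueError):
        make_panel([(1, 2)], times=[[1.0, 1.0]])  # non-increasing times
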