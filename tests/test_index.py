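"""Index combination logic, load portions, cohort tables, and the ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dfhm.errors import ValidationError
from dfhm.index import (
    IndexEntry,
    TaskPortions,
    WorkloadIndexSeries,
    cohort_table,
    combine,
    index_series,
    rm_anova_gg,
    task_portions,
)
from dfhm.classifier import train_pair
from dfhm.synthetic import generate_labeled_dfhm_set, generate_map_cohort


class TestCombine:
    @pytest.mark.parametrize("is_low,is_high,expected", [
        (True, False, "low"),
        (False, True, "high"),
        (False, False, "moderate"),
        (True, True, "moderate"),  # conflict resolved conservatively
    ])
    def test_truth_table(self, is_low, is_high, expected):
        assert combine(is_low, is_high) == expected

    def test_conflict_can_be_audited(self):
        with pytest.raises(ValidationError):
            combine(True, True, conflict="error")


def _series(labels, task="t", cadence=5.0):
    entries = [IndexEntry(time_s=i * cadence, task_id=task, label=l)
               for i, l in enumerate(labels)]
    return WorkloadIndexSeries(entries=entries, cadence_s=cadence)


class TestPortions:
    def test_arithmetic(self):
        labels = ["high"] * 6 + ["low"] * 3 + ["moderate"] * 3
        p = task_portions(_series(labels))
        assert (p.pct_low, p.pct_moderate, p.pct_high) == (25.0, 25.0, 50.0)
        assert p.n_segments == 12

    def test_all_low(self):
        p = task_portions(_series(["low"] * 8))
        assert (p.pct_low, p.pct_moderate, p.pct_high) == (100.0, 0.0, 0.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValidationError):
            task_portions(WorkloadIndexSeries(entries=[]))

    def test_portions_must_sum_to_100(self):
        with pytest.raises(ValidationError):
            TaskPortions(pct_low=50.0, pct_moderate=0.0, pct_high=40.0, n_segments=5)

    def test_training_entries_excluded(self):
        entries = [IndexEntry(0.0, "t", "high", is_training=True),
                   IndexEntry(5.0, "t", "low"), IndexEntry(10.0, "t", "low")]
        s = WorkloadIndexSeries(entries=entries)
        assert task_portions(s).pct_low == 100.0
        assert task_portions(s, exclude_training=False).pct_high == pytest.approx(100 / 3)


@pytest.fixture(scope="module")
def pair(labeled_set):
    return train_pair(labeled_set)


class TestIndexSeries:
    def test_cadence_and_length(self, montage, pair):
        # one 300 s block -> 59 entries at 5 s cadence
        cohort = generate_map_cohort(
            1, battery=None, montage=montage, seed=0)
        maps = [m for m in cohort["sub00"] if m.task_id == "zero_back"]
        assert len(maps) == 59
        series = index_series(maps, pair)
        assert len(series) == 59
        times = [e.time_s for e in series.entries]
        assert np.allclose(np.diff(times), 5.0)

    def test_archetypal_high_signal_all_high(self, montage, pair):
        # constant archetypal input: no jitter, every map at the high archetype
        cohort = generate_map_cohort(1, montage=montage, seed=1,
                                     region_jitter=0.0, electrode_jitter=0.0)
        maps = [m for m in cohort["sub00"] if m.task_id == "aospan"]
        series = index_series(maps, pair)
        labels = {e.label for e in series.entries}
        assert labels == {"high"}

    def test_empty(self, pair):
        assert len(index_series([], pair)) == 0

    def test_strictly_increasing_times_enforced(self):
        entries = [IndexEntry(0.0, "t", "low"), IndexEntry(0.0, "t", "low")]
        with pytest.raises(ValidationError):
            WorkloadIndexSeries(entries=entries)


class TestCohortTable:
    @staticmethod
    def _portions(pct_high):
        return TaskPortions(pct_low=100.0 - pct_high, pct_moderate=0.0,
                            pct_high=pct_high, n_segments=10)

    def test_wide_shape(self):
        tasks = [f"t{i}" for i in range(11)]
        cohort = {f"s{j}": {t: self._portions(10.0 * j) for t in tasks} for j in range(8)}
        table = cohort_table(cohort, "pct_high")
        assert table.shape == (8, 11)
        assert table.loc["s3", "t5"] == 30.0

    def test_missing_cell_is_nan(self):
        cohort = {"s0": {"a": self._portions(10.0), "b": self._portions(20.0)},
                  "s1": {"a": self._portions(30.0)}}
        table = cohort_table(cohort)
        assert np.isnan(table.loc["s1", "b"])

    def test_single_subject(self):
        table = cohort_table({"s0": {"a": self._portions(5.0)}})
        assert table.shape == (1, 1)


class TestRmAnova:
    def test_two_level_equals_squared_paired_t(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(rng.normal(0, 1, (12, 2)) + [0.0, 1.0],
                           index=[f"s{i}" for i in range(12)], columns=["a", "b"])
        res = rm_anova_gg(tab)
        t, p = stats.ttest_rel(tab["a"], tab["b"])
        assert res.F == pytest.approx(float(t) ** 2, abs=1e-6)
        assert res.p == pytest.approx(float(p), rel=1e-6)

    def test_compound_symmetry_epsilon_near_one(self):
        """Under compound symmetry sphericity holds, so epsilon -> 1."""
        rng = np.random.default_rng(1)
        n = 300
        base = rng.normal(0, 1, (n, 1))
        tab = pd.DataFrame(base + rng.normal(0, 1, (n, 4)),
                           index=[f"s{i}" for i in range(n)])
        res = rm_anova_gg(tab)
        assert res.epsilon == pytest.approx(1.0, abs=0.05)

    def test_bonferroni_pairwise_family(self):
        rng = np.random.default_rng(2)
        tab = pd.DataFrame(rng.normal(0, 1, (10, 4)) + [0, 0, 0, 3.0],
                           index=[f"s{i}" for i in range(10)])
        res = rm_anova_gg(tab)
        assert len(res.pairwise) == 6  # all pairs of 4 levels
        assert (res.pairwise["p_bonf"] >= res.pairwise["p_uncorrected"] - 1e-12).all()
        assert "Greenhouse-Geisser" in res.summary()

    def test_too_few_subjects_or_incomplete(self):
        with pytest.raises(ValidationError):
            rm_anova_gg(pd.DataFrame([[1.0, 2.0]], index=["s0"]))
        tab = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)),
                           index=[f"s{i}" for i in range(5)])
        tab.iloc[2, 1] = np.nan
        with pytest.raises(ValidationError):
            rm_anova_gg(tab)
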