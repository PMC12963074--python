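"""Cohort scoring, paired changes, transitions, subgroups, group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctbmd import (
    CohortError,
    chi_squared,
    classify,
    kruskal_wallis,
    mann_whitney,
    misclassification_report,
    paired_changes,
    score_cohort,
    subgroup_split,
    t_score,
    transition_table,
    unique_patient_change_rate,
    wilcoxon_signed_rank,
    example_reclassification_cohort,
)
from conftest import measurements_frame


def patients_frame(rows):
    return pd.DataFrame([dict(patient_id=p, age=a, sex=s) for p, a, s in rows])


class TestScoreCohort:
    def test_hu_at_young_mean_scores_zero_normal(self, toy_ref):
        pats = patients_frame([("a", 40, "female"), ("b", 55, "male")])
        meas = measurements_frame(
            [("a", "noncontrast", "L1", 160.0), ("b", "noncontrast", "L1", 170.0)]
        )
        scored = score_cohort(meas, pats, toy_ref)
        assert (scored["t"] == 0).all()
        assert (scored["category"] == "normal").all()

    def test_orphan_measurement_lists_ids(self, toy_ref):
        pats = patients_frame([("a", 40, "female")])
        meas = measurements_frame([("ghost", "noncontrast", "L1", 100.0)])
        with pytest.raises(CohortError, match="ghost"):
            score_cohort(meas, pats, toy_ref)

    def test_missing_measurements_become_unknown_not_dropped(self, toy_ref):
        pats = patients_frame([(f"p{i}", 60, "male") for i in range(6)])
        rows = [(f"p{i}", "noncontrast", "L1", 120.0) for i in range(6)]
        meas = measurements_frame(rows)
        meas.loc[:2, ["median_hu", "mean_hu"]] = np.nan  # 3 unusable measurements
        scored = score_cohort(meas, pats, toy_ref)
        assert len(scored) == 6
        assert (scored["category"] == "unknown").sum() == 3

    def test_rowwise_oracle(self, toy_ref, rng):
        n = 40
        pats = patients_frame(
            [(f"p{i}", float(rng.uniform(25, 90)),
              "female" if rng.random() < 0.5 else "male") for i in range(n)]
        )
        meas = measurements_frame(
            [(f"p{i}", "noncontrast", "L1", float(rng.uniform(20, 250))) for i in range(n)]
        )
        scored = score_cohort(meas, pats, toy_ref)
        for _, row in scored.iterrows():
            t = t_score(row["median_hu"], row["sex"], toy_ref)
            assert row["t"] == pytest.approx(t, nan_ok=True)
            assert row["category"] == classify(t)

    def test_statistic_choice_mean(self, toy_ref):
        pats = patients_frame([("a", 40, "female")])
        meas = measurements_frame([("a", "noncontrast", "L1", 0.0)])
        meas["mean_hu"] = 160.0
        meas["median_hu"] = 125.0
        by_mean = score_cohort(meas, pats, toy_ref, statistic="mean")
        by_median = score_cohort(meas, pats, toy_ref, statistic="median")
        assert by_mean.loc[0, "t"] == pytest.approx(0.0)
        assert by_median.loc[0, "t"] == pytest.approx(-1.0)

    def test_minor_rejected(self, toy_ref):
        pats = patients_frame([("kid", 12, "male")])
        meas = measurements_frame([("kid", "noncontrast", "L1", 150.0)])
        with pytest.raises(CohortError, match="under 18"):
            score_cohort(meas, pats, toy_ref)


def scored_from_hu(hu_by_phase, toy_ref, sex="male", age=60):
    """Score a cohort given {phase: [hu per patient]} (patient ids p0..)."""
    rows, pats = [], []
    n = len(next(iter(hu_by_phase.values())))
    pats = patients_frame([(f"p{i}", age, sex) for i in range(n)])
    for phase, values in hu_by_phase.items():
        for i, v in enumerate(values):
            if v is not None:
                rows.append((f"p{i}", phase, "L1", float(v)))
    return score_cohort(measurements_frame(rows), pats, toy_ref), pats


class TestPairedChanges:
    def test_hand_computation(self, toy_ref):
        scored, _ = scored_from_hu(
            {"noncontrast": [100, 120, 140], "arterial": [110, 140, 170]}, toy_ref
        )
        s = paired_changes(scored, "noncontrast", "arterial", "L1", "HU")
        assert s.median_abs_change == pytest.approx(20.0)
        assert s.median_rel_change_pct == pytest.approx(100 * 20 / 120, abs=1e-9)
        assert s.n_pairs == 3

    def test_identical_phases_degenerate(self, toy_ref):
        scored, _ = scored_from_hu(
            {"noncontrast": [100, 120], "arterial": [100, 120]}, toy_ref
        )
        s = paired_changes(scored, "noncontrast", "arterial", "L1", "HU")
        assert s.median_abs_change == 0.0
        assert s.p_value == 1.0 and s.p_degenerate

    def test_zero_baseline_excluded_from_relative_only(self, toy_ref):
        scored, _ = scored_from_hu(
            {"noncontrast": [0.0, 100.0], "arterial": [10.0, 120.0]}, toy_ref
        )
        s = paired_changes(scored, "noncontrast", "arterial", "L1", "HU")
        assert s.n_rel_excluded == 1
        assert s.median_abs_change == pytest.approx(15.0)  # both kept for abs
        assert s.median_rel_change_pct == pytest.approx(20.0)

    def test_missing_phase_dropped_pairwise(self, toy_ref):
        scored, _ = scored_from_hu(
            {"noncontrast": [100, 120, 130], "arterial": [110, None, 140]}, toy_ref
        )
        s = paired_changes(scored, "noncontrast", "arterial", "L1", "HU")
        assert s.n_pairs == 2

    def test_t_change_scales_by_young_sd(self, toy_ref):
        # HU +35 on a male (sd 35) is exactly +1.0 in T
        scored, _ = scored_from_hu(
            {"noncontrast": [100, 120], "arterial": [135, 155]}, toy_ref
        )
        s = paired_changes(scored, "noncontrast", "arterial", "L1", "T")
        assert s.median_abs_change == pytest.approx(1.0)

    def test_no_pairs_is_error(self, toy_ref):
        scored, _ = scored_from_hu({"noncontrast": [100]}, toy_ref)
        with pytest.raises(CohortError, match="no complete"):
            paired_changes(scored, "noncontrast", "venous", "L1", "HU")


class TestTransitions:
    def test_identical_phases_diagonal(self, toy_ref):
        scored, _ = scored_from_hu(
            {"noncontrast": [60, 100, 150], "arterial": [60, 100, 150]}, toy_ref
        )
        t = transition_table(scored, "noncontrast", "arterial", "L1")
        off = t.counts.to_numpy().sum() - np.trace(t.counts.to_numpy())
        assert off == 0 and t.n_eligible == 3

    def test_hand_built_five_patients(self, toy_ref):
        # male young mean 170 sd 35: normal > 135; osteoporosis < 82.5
        scored, _ = scored_from_hu(
            {
                "noncontrast": [70, 80, 100, 120, 150],
                "arterial": [95, 100, 140, 125, 160],
            },
            toy_ref,
        )
        t = transition_table(scored, "noncontrast", "arterial", "L1")
        assert t.counts.loc["osteoporosis", "osteopenia"] == 2
        assert t.counts.loc["osteopenia", "normal"] == 1
        assert t.counts.loc["osteopenia", "osteopenia"] == 1
        assert t.counts.loc["normal", "normal"] == 1

    def test_conservation(self, toy_ref, rng):
        nc = rng.uniform(40, 200, size=30)
        art = nc + rng.normal(20, 10, size=30)
        scored, pats = scored_from_hu({"noncontrast": nc, "arterial": art}, toy_ref)
        t = transition_table(scored, "noncontrast", "arterial", "L1")
        assert t.counts.to_numpy().sum() == t.n_eligible == 30

    def test_antisymmetry(self, toy_ref, rng):
        nc = rng.uniform(40, 200, size=25)
        art = nc + rng.normal(20, 15, size=25)
        scored, _ = scored_from_hu({"noncontrast": nc, "arterial": art}, toy_ref)
        fwd = transition_table(scored, "noncontrast", "arterial", "L1")
        rev = transition_table(scored, "arterial", "noncontrast", "L1")
        assert np.array_equal(fwd.counts.to_numpy().T, rev.counts.to_numpy())
        s_fwd = paired_changes(scored, "noncontrast", "arterial", "L1", "HU")
        s_rev = paired_changes(scored, "arterial", "noncontrast", "L1", "HU")
        assert s_rev.median_abs_change == pytest.approx(-s_fwd.median_abs_change)


class TestMisclassificationReport:
    def test_rates_match_independent_loop(self, toy_ref, rng):
        nc = rng.uniform(40, 200, size=50)
        scored, pats = scored_from_hu(
            {"noncontrast": nc,
             "arterial": nc + rng.normal(24, 8, 50),
             "venous": nc + rng.normal(16, 6, 50)},
            toy_ref,
        )
        tables = {
            ph: transition_table(scored, "noncontrast", ph, "L1")
            for ph in ("arterial", "venous")
        }
        rep = misclassification_report(tables, subgroup_n=50)

        # independent recomputation straight off the tables
        for ph in ("arterial", "venous"):
            c = tables[ph].counts
            expected = sum(
                int(c.loc[b, cc])
                for b in ("normal", "osteopenia", "osteoporosis")
                for cc in ("normal", "osteopenia", "osteoporosis")
                if b != cc
            )
            row = rep[(rep.kind == "pair_total") & (rep.phase_pair == ph)].iloc[0]
            assert row["count"] == expected
            assert row["pct"] == pytest.approx(100 * expected / 50)
        overall = rep[rep.kind == "overall"].iloc[0]
        assert overall["count"] == rep[rep.kind == "pair_total"]["count"].sum()

    def test_event_sum_vs_unique_patients(self, toy_ref):
        # one patient changes in BOTH comparisons -> events 2, unique 1
        scored, pats = scored_from_hu(
            {"noncontrast": [100.0], "arterial": [140.0], "venous": [140.0]}, toy_ref
        )
        tables = {
            ph: transition_table(scored, "noncontrast", ph, "L1")
            for ph in ("arterial", "venous")
        }
        rep = misclassification_report(tables, subgroup_n=1)
        assert rep[rep.kind == "overall"].iloc[0]["pct"] == pytest.approx(200.0)
        assert unique_patient_change_rate(tables, scored, None, 1) == pytest.approx(100.0)

    def test_zero_offdiagonal_all_zero(self, toy_ref):
        scored, _ = scored_from_hu(
            {"noncontrast": [100, 150], "arterial": [100, 150]}, toy_ref
        )
        tables = {"arterial": transition_table(scored, "noncontrast", "arterial", "L1")}
        rep = misclassification_report(tables, subgroup_n=2)
        assert (rep["count"] == 0).all()


class TestSubgroups:
    def test_example_cohort_marginals(self):
        patients, _ = example_reclassification_cohort()
        split = subgroup_split(patients, age_threshold=50)
        assert len(split["all"]) == 597
        assert len(split["under"]) == 78
        assert len(split["over"]) == 519
        assert len(split["female-over"]) == 140
        assert len(split["male-over"]) == 379
        assert len(split["female"]) == 157
        assert len(split["male"]) == 440

    def test_partitions_exhaustive(self):
        patients, _ = example_reclassification_cohort()
        split = subgroup_split(patients)
        assert len(split["under"]) + len(split["over"]) == len(split["all"])
        assert len(split["female"]) + len(split["male"]) == len(split["all"])

    def test_empty_subgroup_no_crash(self, toy_ref):
        pats = patients_frame([("a", 30, "male")])
        split = subgroup_split(pats)
        assert len(split["female"]) == 0

    def test_threshold_validated(self, toy_ref):
        pats = patients_frame([("a", 30, "male")])
        with pytest.raises(ValueError):
            subgroup_split(pats, age_threshold=150)


class TestGroupTests:
    def test_identical_groups_not_significant(self, rng):
        x = rng.normal(0, 1, 100)
        assert mann_whitney(x, x) > 0.9

    def test_shifted_distributions_detected(self):
        r = np.random.default_rng(42)
        x = r.normal(0, 1, 200)
        y = r.normal(1, 1, 200)  # 1 SD shift
        assert mann_whitney(x, y) < 0.05
        assert kruskal_wallis(x, y, r.normal(0, 1, 200)) < 0.05

    def test_chi_squared_textbook_2x2(self):
        stat, p = chi_squared([[50, 50], [80, 20]])
        assert stat == pytest.approx(19.780, abs=1e-2)
        assert p < 0.05

    def test_chi_squared_matches_hand_formula(self, rng):
        for _ in range(20):
            tab = rng.integers(5, 80, size=(2, 3)).astype(float)
            stat, _ = chi_squared(tab)
            total = tab.sum()
            expected = np.outer(tab.sum(1), tab.sum(0)) / total
            by_hand = ((tab - expected) ** 2 / expected).sum()
            assert stat == pytest.approx(by_hand, abs=1e-8)

    def test_mann_whitney_statistic_matches_pairwise_count(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 15)
            y = rng.normal(0.3, 1, 12)
            u_scipy = float(stats.mannwhitneyu(x, y, alternative="two-sided").statistic)
            u_brute = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
            assert u_scipy == pytest.approx(u_brute, abs=1e-8)

    def test_kruskal_statistic_matches_rank_formula(self, rng):
        for _ in range(20):
            groups = [rng.normal(rng.uniform(-1, 1), 1, rng.integers(8, 15))
                      for _ in range(3)]
            h_scipy = float(stats.kruskal(*groups).statistic)
            pooled = np.concatenate(groups)
            ranks = stats.rankdata(pooled)
            n = len(pooled)
            idx = np.cumsum([0] + [len(g) for g in groups])
            h = 12 / (n * (n + 1)) * sum(
                ranks[idx[i]:idx[i + 1]].sum() ** 2 / len(g)
                for i, g in enumerate(groups)
            ) - 3 * (n + 1)
            # tie correction
            _, counts = np.unique(pooled, return_counts=True)
            h /= 1 - ((counts ** 3 - counts).sum() / (n ** 3 - n))
            assert h_scipy == pytest.approx(h, abs=1e-8)

    def test_wilcoxon_all_tied_convention(self):
        p, degenerate = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert p == 1.0 and degenerate

    def test_wilcoxon_statistic_matches_signed_rank_sum(self, rng):
        for _ in range(20):
            d = rng.normal(0.5, 1, 20)
            d = d[d != 0]
            w_scipy = float(stats.wilcoxon(d, zero_method="wilcox").statistic)
            ranks = stats.rankdata(np.abs(d))
            w_plus = ranks[d > 0].sum()
            w_minus = ranks[d < 0].sum()
            assert w_scipy == pytest.approx(min(w_plus, w_minus), abs=1e-8)
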