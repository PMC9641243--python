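import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fluxkin.cohort_stats import (
    grubbs_outliers,
    group_subset_comparisons,
    paired_mixed_comparisons,
    percentage,
    required_sample_size,
    sidak_adjust,
)


def _long_table(data: dict[tuple[str, str], np.ndarray], parameter="auc"):
    rows = []
    for (group, subset), values in data.items():
        for i, v in enumerate(values):
            rows.append(
                {"sample_id": f"{group}_{subset}_{i}", "group": group,
                 "subject_id": f"{group}_{i}", "subset": subset,
                 "parameter": parameter, "value": float(v)}
            )
    return pd.DataFrame(rows)


class TestGrubbs:
    def test_constant_values_no_outlier(self):
        assert grubbs_outliers([5.0] * 10) == []

    def test_obvious_outlier_flagged(self):
        values = list(range(1, 11)) + [50]
        assert grubbs_outliers(values, alpha=0.01) == [10]

    def test_flagged_statistic_exceeds_critical(self):
        # independent oracle: recompute G and the t-based critical value
        values = np.array(list(range(1, 11)) + [50], dtype=float)
        n = len(values)
        g = np.max(np.abs(values - values.mean())) / values.std(ddof=1)
        t = stats.t.ppf(1 - 0.01 / (2 * n), n - 2)
        crit = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
        assert g > crit
        assert grubbs_outliers(values, alpha=0.01) == [10]

    def test_requires_three_values(self):
        with pytest.raises(ValueError):
            grubbs_outliers([1.0, 2.0])

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(17)
        alpha = 0.05
        flagged = sum(
            bool(grubbs_outliers(rng.standard_normal(12), alpha=alpha))
            for _ in range(1000)
        )
        rate = flagged / 1000
        # Grubbs' critical value is slightly conservative (Bonferroni bound)
        assert rate <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / 1000)

    def test_removal_cap(self):
        # at most floor(n/5) removals even for pathological data
        values = np.concatenate([np.zeros(8), np.array([100.0, 200.0, 300.0])])
        out = grubbs_outliers(values, alpha=0.5)
        assert len(out) <= len(values) // 5

    def test_removal_never_raises_statistic(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.standard_normal(15), [8.0]])

        def gstat(x):
            return np.max(np.abs(x - x.mean())) / x.std(ddof=1)

        out = grubbs_outliers(values, alpha=0.05)
        if out:
            remaining = np.delete(values, out)
            assert gstat(remaining) <= gstat(values) + 1e-12


class TestGroupSubsetComparisons:
    def test_self_comparison_is_zero(self):
        rng = np.random.default_rng(2)
        base = rng.normal(10.0, 2.0, 12)
        table = _long_table({("A", "s1"): base, ("B", "s1"): base})
        results = group_subset_comparisons(table, "auc")
        overall = [r for r in results if r.level == "groups-overall"]
        assert overall[0].estimate == 0.0
        assert overall[0].p_adjusted == pytest.approx(1.0, abs=1e-9)

    def test_matches_oneway_tukey(self):
        # balanced single-subset design reduces to one-way ANOVA + Tukey HSD
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(7)
        data = {
            ("A", "s"): rng.normal(0.0, 1.0, 10),
            ("B", "s"): rng.normal(0.5, 1.0, 10),
            ("C", "s"): rng.normal(1.0, 1.0, 10),
        }
        table = _long_table(data)
        mine = {
            r.label: r
            for r in group_subset_comparisons(table, "auc")
            if r.level == "groups-within-subset"
        }
        flat = pd.concat(
            [pd.DataFrame({"g": g, "v": v}) for (g, _), v in data.items()]
        )
        ref = pairwise_tukeyhsd(flat["v"], flat["g"], alpha=0.05)
        for (ga, gb), diff, p in zip(
            ref._multicomp.pairindices and
            [(ref.groupsunique[i], ref.groupsunique[j])
             for i, j in zip(*ref._multicomp.pairindices)],
            ref.meandiffs, ref.pvalues,
        ):
            r = mine[f"{ga}-{gb}|s"]
            assert r.estimate == pytest.approx(-diff, rel=1e-9)  # sign: A-B vs B-A
            assert r.p_adjusted == pytest.approx(p, abs=1e-6)

    def test_symmetry_under_group_relabeling(self):
        rng = np.random.default_rng(11)
        data = {
            ("A", "s"): rng.normal(0, 1, 8),
            ("B", "s"): rng.normal(1, 1, 8),
        }
        table = _long_table(data)
        swapped = table.replace({"group": {"A": "Z", "B": "A"}})
        swapped = swapped.replace({"group": {"Z": "B"}})
        r1 = [r for r in group_subset_comparisons(table, "auc")
              if r.level == "groups-overall"][0]
        r2 = [r for r in group_subset_comparisons(swapped, "auc")
              if r.level == "groups-overall"][0]
        assert r1.estimate == pytest.approx(-r2.estimate)
        assert r1.p_adjusted == pytest.approx(r2.p_adjusted)

    def test_three_levels_present(self):
        rng = np.random.default_rng(3)
        data = {
            (g, s): rng.normal(0, 1, 6)
            for g in ("A", "B") for s in ("s1", "s2")
        }
        results = group_subset_comparisons(_long_table(data), "auc")
        levels = {r.level for r in results}
        assert levels == {
            "groups-overall", "groups-within-subset", "subsets-within-group",
        }

    def test_sparse_cell_not_estimable(self):
        rng = np.random.default_rng(4)
        data = {
            ("A", "s1"): rng.normal(0, 1, 6),
            ("B", "s1"): np.array([1.0]),  # single observation
            ("A", "s2"): rng.normal(0, 1, 6),
            ("B", "s2"): rng.normal(0, 1, 6),
        }
        results = group_subset_comparisons(_long_table(data), "auc")
        bad = [r for r in results if r.label == "A-B|s1"][0]
        assert not bad.estimable
        assert math.isnan(r := bad.p_adjusted) or r != r

    def test_shifted_group_detected(self):
        # one group +3 pooled SD: essentially always significant at n=12
        rng = np.random.default_rng(19)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            data = {
                ("A", "s"): rng.normal(0, 1, 12),
                ("B", "s"): rng.normal(0, 1, 12),
                ("C", "s"): rng.normal(3, 1, 12),
            }
            results = group_subset_comparisons(_long_table(data), "auc")
            ps = [r.p_adjusted for r in results
                  if r.level == "groups-overall" and "C" in r.label]
            if all(p < 0.05 for p in ps):
                hits += 1
        assert hits / n_rep > 0.99

    def test_null_familywise_error(self):
        rng = np.random.default_rng(23)
        alpha = 0.05
        n_rep = 500
        false_pos = 0
        for _ in range(n_rep):
            data = {
                (g, "s"): rng.normal(0, 1, 12) for g in ("A", "B", "C", "D")
            }
            results = group_subset_comparisons(_long_table(data), "auc")
            ps = [r.p_adjusted for r in results if r.level == "groups-overall"]
            if any(p < alpha for p in ps):
                false_pos += 1
        rate = false_pos / n_rep
        assert rate <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / n_rep)

    def test_requires_two_groups(self):
        table = _long_table({("A", "s"): np.arange(5.0)})
        with pytest.raises(ValueError):
            group_subset_comparisons(table, "auc")


def _paired_table(pre, post, subset="s", parameter="auc"):
    rows = []
    for subj, v in pre.items():
        rows.append({"sample_id": f"pre_{subj}", "group": "H1",
                     "subject_id": subj, "subset": subset,
                     "parameter": parameter, "value": v})
    for subj, v in post.items():
        rows.append({"sample_id": f"post_{subj}", "group": "H2",
                     "subject_id": subj, "subset": subset,
                     "parameter": parameter, "value": v})
    return pd.DataFrame(rows)


class TestPairedMixedComparisons:
    def test_identical_visits_give_zero_effect(self):
        rng = np.random.default_rng(31)
        vals = {f"s{i}": float(v) for i, v in enumerate(rng.normal(10, 2, 8))}
        table = _paired_table(vals, vals)
        res = paired_mixed_comparisons(table, "H1", "H2", "auc")
        assert len(res) == 1
        assert res[0].estimate == pytest.approx(0.0, abs=1e-9)
        assert res[0].p_adjusted == pytest.approx(1.0, abs=0.01)

    def test_location_invariance(self):
        rng = np.random.default_rng(37)
        pre = {f"s{i}": float(v) for i, v in enumerate(rng.normal(10, 2, 10))}
        post = {k: v + rng.normal(1.0, 0.5) for k, v in pre.items()}
        t1 = _paired_table(pre, post)
        t2 = t1.copy()
        t2["value"] = t2["value"] + 1000.0
        r1 = paired_mixed_comparisons(t1, "H1", "H2", "auc")[0]
        r2 = paired_mixed_comparisons(t2, "H1", "H2", "auc")[0]
        assert r1.estimate == pytest.approx(r2.estimate, rel=1e-6)

    def test_incomplete_subjects_still_contribute(self):
        rng = np.random.default_rng(41)
        pre = {f"s{i}": float(rng.normal(10, 1)) for i in range(14)}
        post = {f"s{i}": pre[f"s{i}"] + 1.0 for i in range(11)}
        post["s_extra"] = 11.5  # post-only subject
        table = _paired_table(pre, post)
        res = paired_mixed_comparisons(table, "H1", "H2", "auc")
        assert res[0].estimable
        assert res[0].estimate == pytest.approx(1.0, abs=0.8)

    def test_detection_matches_paired_t_oracle(self):
        # shift of 1 within-subject SD, 14 pre / 12 post: the mixed model's
        # detection rate should track a paired t-test on complete pairs
        rng = np.random.default_rng(43)
        n_rep = 120
        mixed_hits = t_hits = 0
        for _ in range(n_rep):
            subj_fx = rng.normal(0.0, 1.0, 15)
            pre = {f"s{i}": float(subj_fx[i] + rng.normal(0, 1)) for i in range(14)}
            post = {
                f"s{i}": float(subj_fx[i] + 1.0 + rng.normal(0, 1))
                for i in list(range(11)) + [14]
            }
            table = _paired_table(pre, post)
            res = paired_mixed_comparisons(table, "H1", "H2", "auc")
            if res[0].estimable and res[0].p_adjusted < 0.05:
                mixed_hits += 1
            common = [f"s{i}" for i in range(11)]
            t_p = stats.ttest_rel(
                [post[s] for s in common], [pre[s] for s in common]
            ).pvalue
            if t_p < 0.05:
                t_hits += 1
        assert abs(mixed_hits - t_hits) / n_rep <= 0.10

    def test_requires_three_subjects(self):
        table = _paired_table({"a": 1.0}, {"a": 2.0})
        with pytest.raises(ValueError):
            paired_mixed_comparisons(table, "H1", "H2", "auc")

    def test_sidak_across_subsets(self):
        rng = np.random.default_rng(47)
        frames = []
        for s in ("s1", "s2", "s3"):
            pre = {f"s{i}": float(rng.normal(10, 1)) for i in range(10)}
            post = {k: v + float(rng.normal(0, 0.5)) for k, v in pre.items()}
            frames.append(_paired_table(pre, post, subset=s))
        table = pd.concat(frames, ignore_index=True)
        res = paired_mixed_comparisons(table, "H1", "H2", "auc")
        assert len(res) == 3
        assert all(r.method == "sidak" for r in res)


class TestRequiredSampleSize:
    def test_paper_design_effect_gives_twelve(self):
        # effect size 1.2, alpha 0.05, power 0.80 -> 12 per group
        assert required_sample_size(1.2, 1.0, alpha=0.05, power=0.80) == 12

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.power import TTestIndPower

        solver = TTestIndPower()
        for d in (0.5, 0.8, 1.0, 1.5, 2.0):
            n = required_sample_size(d, 1.0, alpha=0.05, power=0.80)
            n_ref = math.ceil(
                solver.solve_power(effect_size=d, alpha=0.05, power=0.80)
            )
            assert abs(n - n_ref) <= 1

    def test_saturates_at_floor(self):
        assert required_sample_size(10.0, 1.0) == 2

    def test_monotone_in_effect_size(self):
        assert required_sample_size(0.5, 1.0) > required_sample_size(1.0, 1.0)

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            required_sample_size(0.0, 1.0)

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            required_sample_size(1.0, 0.0)


class TestPercentage:
    @pytest.mark.parametrize(
        "num, den, expected",
        [(2, 7, "29%"), (5, 7, "71%"), (3, 8, "37.5%"), (2, 8, "25%"),
         (3, 3, "100%"), (0, 7, "0%"), (1, 8, "12.5%")],
    )
    def test_reporting_format(self, num, den, expected):
        assert percentage(num, den) == expected

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            percentage(1, 0)

    def test_numerator_bounds(self):
        with pytest.raises(ValueError):
            percentage(5, 3)


class TestSidak:
    def test_known_value(self):
        assert sidak_adjust(0.01, 3) == pytest.approx(1 - 0.99**3)

    @settings(max_examples=50, deadline=None)
    @given(p=st.floats(0.0, 1.0), m=st.integers(1, 50))
    def test_adjustment_never_decreases(self, p, m):
        assert sidak_adjust(p, m) >= p - 1e-12
        assert 0.0 <= sidak_adjust(p, m) <= 1.0
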