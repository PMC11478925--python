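import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from mrsdss.stats import (certainty_change, certainty_summary,
                          diagnostic_accuracy, kruskal_wallis, levene_test,
                          metabolite_group_comparison, table2_summary,
                          truth_is_max, strict_over_50, wilcoxon_signed_rank)
from mrsdss.synthesize import REVIEW_STAGES, sample_certainty_table

S0, S1, S2 = REVIEW_STAGES


def make_table(rows):
    """rows: list of (rater, case, stage, pa, ep, mb, truth)."""
    return pd.DataFrame(rows, columns=["rater", "case", "stage", "cert_PA",
                                       "cert_EP", "cert_MB", "truth"])


class TestDiagnosticAccuracy:
    def test_fourteen_of_thirtythree_gives_42(self):
        rows = []
        for i in range(33):
            pa = 60 if i < 14 else 40
            rows.append(("R", f"C{i}", S0, pa, 100 - pa, 0, "PA"))
        acc = diagnostic_accuracy(make_table(rows), "R", S0)
        assert (acc.percent, acc.n_correct, acc.n_total) == (42, 14, 33)

    def test_exactly_50_counts_incorrect(self):
        rows = [("R", "C0", S0, 50, 30, 20, "PA")]
        acc = diagnostic_accuracy(make_table(rows), "R", S0)
        assert acc.n_correct == 0

    def test_matches_bruteforce_count(self, rng):
        rows = []
        for i in range(40):
            c = rng.integers(0, 101)
            rest = 100 - c
            truth = str(rng.choice(["PA", "EP", "MB"]))
            trip = {"PA": 0, "EP": 0, "MB": 0}
            trip[truth] = c
            others = [k for k in trip if k != truth]
            trip[others[0]] = rest
            rows.append(("R", f"C{i}", S0, trip["PA"], trip["EP"], trip["MB"],
                         truth))
        table = make_table(rows)
        expected = sum(
            1 for _, r in table.iterrows()
            if r[f"cert_{r['truth']}"] > 50
        )
        assert diagnostic_accuracy(table, "R", S0).n_correct == expected

    def test_missing_stage_rejected(self):
        table = make_table([("R", "C0", S0, 50, 30, 20, "PA")])
        with pytest.raises(ValueError, match="no rows"):
            diagnostic_accuracy(table, "R", S2)

    def test_bad_sum_rejected(self):
        table = make_table([("R", "C0", S0, 50, 30, 30, "PA")])
        with pytest.raises(ValueError, match="sum"):
            diagnostic_accuracy(table, "R", S0)


class TestCertaintySummary:
    def test_single_correct_case(self):
        table = make_table([("R", "C0", S0, 80, 10, 10, "PA")])
        s = certainty_summary(table, "R", S0)
        assert (s.mean_correct, s.sd_correct, s.n_correct) == (80.0, 0.0, 1)
        assert s.mean_incorrect is None

    def test_highest_certainty_at_or_below_50_still_correct(self):
        # (40, 35, 25) with truth first: counted in the correct stratum
        table = make_table([("R", "C0", S0, 40, 35, 25, "PA")])
        s = certainty_summary(table, "R", S0)
        assert s.n_correct == 1
        assert s.mean_correct == 40.0

    def test_tie_counts_incorrect(self):
        table = make_table([("R", "C0", S0, 50, 50, 0, "PA")])
        assert certainty_summary(table, "R", S0).n_incorrect == 1

    def test_stratum_means_match_bruteforce(self, rng):
        table = sample_certainty_table(["PA", "EP", "MB"] * 8, seed=4,
                                       n_raters=1)
        s = certainty_summary(table, "Rad1", S1)
        rows = table[table.stage == S1]
        cor, inc = [], []
        for _, r in rows.iterrows():
            tc = r[f"cert_{r['truth']}"]
            others = max(v for k, v in
                         [("PA", r.cert_PA), ("EP", r.cert_EP),
                          ("MB", r.cert_MB)] if k != r["truth"])
            (cor if tc > others else inc).append(tc)
        assert s.mean_correct == pytest.approx(np.mean(cor))
        assert s.mean_incorrect == pytest.approx(np.mean(inc))

    def test_predicate_disagreement_cases(self):
        """The two correctness definitions disagree exactly when the truth
        class holds the strict maximum at <= 50% certainty."""
        rows = [
            ("R", "C0", S0, 40, 35, 25, "PA"),   # truth-max but <= 50
            ("R", "C1", S0, 60, 30, 10, "PA"),   # both correct
            ("R", "C2", S0, 20, 55, 25, "PA"),   # both incorrect
            ("R", "C3", S0, 50, 25, 25, "PA"),   # exactly 50, truth-max
        ]
        table = make_table(rows)
        sub = table[(table.rater == "R") & (table.stage == S0)]
        a = strict_over_50(sub)
        b = truth_is_max(sub)
        disagree = sub[a != b]["case"].tolist()
        assert disagree == ["C0", "C3"]


class TestCertaintyChange:
    def test_identical_stages_give_zero_deltas(self):
        rows = [("R", f"C{i}", s, 40, 30, 30, "PA")
                for i in range(5) for s in (S0, S1)]
        d = certainty_change(make_table(rows), "R", S0, S1)
        assert (d == 0).all()

    def test_constructed_shifts_recovered(self):
        rows = []
        shifts = [5, -10, 20]
        for i, sh in enumerate(shifts):
            rows.append(("R", f"C{i}", S0, 40, 30, 30, "PA"))
            rows.append(("R", f"C{i}", S2, 40 + sh, 30 - sh, 30, "PA"))
        d = certainty_change(make_table(rows), "R", S0, S2)
        assert sorted(d.tolist()) == sorted(shifts)

    def test_unpaired_case_rejected(self):
        rows = [("R", "C0", S0, 40, 30, 30, "PA"),
                ("R", "C1", S2, 40, 30, 30, "PA")]
        with pytest.raises(ValueError, match="unpaired"):
            certainty_change(make_table(rows), "R", S0, S2)

    def test_deltas_bounded(self):
        table = sample_certainty_table(["MB"] * 50, seed=1, n_raters=1)
        d = certainty_change(table, "Rad1", S0, S2)
        assert d.between(-100, 100).all()

    def test_reordering_cases_leaves_statistics_unchanged(self):
        table = sample_certainty_table(["PA", "EP", "MB"] * 6, seed=2,
                                       n_raters=1)
        shuffled = table.sample(frac=1.0, random_state=7).reset_index(drop=True)
        d1 = certainty_change(table, "Rad1", S0, S2)
        d2 = certainty_change(shuffled, "Rad1", S0, S2)
        r1 = wilcoxon_signed_rank(d1.to_numpy())
        r2 = wilcoxon_signed_rank(d2.sort_index().to_numpy())
        assert r1.statistic == r2.statistic and r1.p_value == r2.p_value


class TestWilcoxon:
    def test_six_positive_distinct_exact_p(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                                   mode="exact")
        assert res.p_value == pytest.approx(2.0 / 64.0)
        assert res.statistic == 21.0

    def test_symmetric_deltas_give_p_one(self):
        res = wilcoxon_signed_rank([3.0, -3.0, 5.0, -5.0], mode="exact")
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_full_enumeration_oracle(self, rng):
        for n in (5, 8, 12):
            d = np.round(rng.normal(3.0, 6.0, size=n), 0)
            d = d[d != 0]
            if len(d) < 2:
                continue
            res = wilcoxon_signed_rank(d, mode="exact")
            ranks = sstats.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            dist = [np.sum(np.array(signs) * ranks) for signs in
                    itertools.product([0, 1], repeat=len(d))]
            dist = np.array(dist, dtype=float)
            p_le = np.mean(dist <= w_obs + 1e-12)
            p_ge = np.mean(dist >= w_obs - 1e-12)
            expected = min(1.0, 2 * min(p_le, p_ge))
            assert res.p_value == pytest.approx(expected)

    def test_exact_agrees_with_scipy_on_tie_free_data(self, rng):
        d = rng.normal(1.0, 2.0, size=10)
        res = wilcoxon_signed_rank(d, mode="exact")
        ref = sstats.wilcoxon(d, method="exact")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_exact_and_normal_agree_at_n15(self, rng):
        d = rng.normal(2.0, 4.0, size=15)
        p_exact = wilcoxon_signed_rank(d, mode="exact").p_value
        p_norm = wilcoxon_signed_rank(d, mode="normal").p_value
        assert abs(p_exact - p_norm) <= 0.02

    def test_zero_policy_wilcoxon_drops_zeros(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0, 3.0], mode="exact")
        assert res.n_used == 3

    def test_pratt_keeps_zero_ranks(self):
        d = [0.0, 1.0, 2.0, 3.0]
        res_w = wilcoxon_signed_rank(d, zero_policy="wilcoxon", mode="exact")
        res_p = wilcoxon_signed_rank(d, zero_policy="pratt", mode="exact")
        assert res_p.statistic > res_w.statistic  # zeros inflate the ranks

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_hodges_lehmann_matches_walsh_average_median(self, rng):
        d = rng.normal(5.0, 3.0, size=12)
        res = wilcoxon_signed_rank(d)
        walsh = [(d[i] + d[j]) / 2 for i in range(len(d))
                 for j in range(i, len(d))]
        assert res.hl_estimate == pytest.approx(np.median(walsh))
        assert res.ci_low <= res.hl_estimate <= res.ci_high


class TestLevene:
    def test_identical_groups_statistic_zero(self):
        g = [1.0, 2.0, 3.0, 4.0]
        stat, p = levene_test([g, list(g)])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_group_toy_matches_direct_formula(self):
        a = np.array([1.0, 3.0, 5.0, 7.0])
        b = np.array([2.0, 2.5, 3.0, 3.5])
        stat, _ = levene_test([a, b], center="median")
        za = np.abs(a - np.median(a))
        zb = np.abs(b - np.median(b))
        n, k = 8, 2
        zbar_a, zbar_b = za.mean(), zb.mean()
        zbar = np.r_[za, zb].mean()
        num = (n - k) * (4 * (zbar_a - zbar) ** 2 + 4 * (zbar_b - zbar) ** 2)
        den = (k - 1) * (np.sum((za - zbar_a) ** 2) + np.sum((zb - zbar_b) ** 2))
        assert stat == pytest.approx(num / den)

    def test_scaling_one_group_increases_statistic(self):
        a = [1.0, 3.0, 5.0, 7.0, 2.0]
        b = [2.0, 4.0, 6.0, 8.0, 3.0]
        s1, _ = levene_test([a, b])
        s2, _ = levene_test([a, list(5 * np.array(b))])
        assert s2 > s1

    def test_mean_centred_variant(self):
        a, b = [1.0, 3.0, 5.0], [2.0, 2.1, 2.2]
        stat_m, _ = levene_test([a, b], center="mean")
        ref = sstats.levene(a, b, center="mean")
        assert stat_m == pytest.approx(ref.statistic)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match="two observations"):
            levene_test([[1.0], [2.0, 3.0]])


class TestKruskalWallis:
    def test_hand_computed_value(self):
        H, p = kruskal_wallis([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        # tie-free closed form: 12/(6*7) * (3*2^2 + 3*5^2) - 3*7
        expected = 12.0 / 42.0 * (3 * 4 + 3 * 25) - 21.0
        assert H == pytest.approx(expected)
        assert expected == pytest.approx(3.857, abs=1e-3)

    def test_identical_group_contents_give_zero(self):
        H, _ = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert H == pytest.approx(0.0, abs=1e-12)

    def test_exact_and_chisquare_agree_at_n10(self, rng):
        groups = [list(rng.normal(0, 1, 5)), list(rng.normal(2.5, 1, 5))]
        H1, p_chi = kruskal_wallis(groups)
        H2, p_exact = kruskal_wallis(groups, exact=True)
        assert H1 == H2
        assert abs(p_exact - p_chi) <= 0.05

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])


class TestMetaboliteComparison:
    def test_identical_groups_give_null_results(self):
        df = pd.DataFrame({
            "group": ["a"] * 4 + ["b"] * 4,
            "NAA": [1.0, 2.0, 3.0, 4.0] * 2,
        })
        res = metabolite_group_comparison(df, "group")
        assert res.loc["NAA", "F"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["NAA", "p_a_vs_b"] == pytest.approx(1.0)

    def test_strong_effect_detected_reliably(self, rng):
        hits = 0
        for _ in range(100):
            a = rng.normal(0.0, 1.0, 20)
            b = rng.normal(3.0, 1.0, 20)
            df = pd.DataFrame({"group": ["a"] * 20 + ["b"] * 20,
                               "m": np.r_[a, b]})
            res = metabolite_group_comparison(df, "group")
            if res.loc["m", "p"] < 0.001:
                hits += 1
        assert hits >= 95

    def test_f_matches_longhand_mean_squares(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0],
                  "c": [5.0, 6.0, 7.0]}
        df = pd.DataFrame({
            "group": sum([[k] * 3 for k in groups], []),
            "x": sum(groups.values(), []),
        })
        res = metabolite_group_comparison(df, "group")
        all_vals = np.array(sum(groups.values(), []))
        grand = all_vals.mean()
        ss_between = sum(3 * (np.mean(v) - grand) ** 2
                         for v in groups.values())
        ss_within = sum(np.sum((np.array(v) - np.mean(v)) ** 2)
                        for v in groups.values())
        expected = (ss_between / 2) / (ss_within / 6)
        assert res.loc["x", "F"] == pytest.approx(expected)

    def test_bonferroni_adjustment_applied(self, rng):
        df = pd.DataFrame({
            "group": ["a"] * 10 + ["b"] * 10 + ["c"] * 10,
            "m": np.r_[rng.normal(0, 1, 10), rng.normal(0.8, 1, 10),
                       rng.normal(0.4, 1, 10)],
        })
        res = metabolite_group_comparison(df, "group")
        raw = sstats.ttest_ind(df[df.group == "a"]["m"],
                               df[df.group == "b"]["m"]).pvalue
        assert res.loc["m", "p_a_vs_b"] == pytest.approx(min(1.0, raw * 3))


def test_table2_summary_covers_all_raters_and_stages():
    table = sample_certainty_table(["PA", "EP", "MB"] * 5, seed=0)
    out = table2_summary(table)
    assert len(out) == 3 * 3
    assert set(out["stage"]) == set(REVIEW_STAGES)
    assert out["accuracy_percent"].between(0, 100).all()
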