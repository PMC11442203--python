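"""Median screening and the four coverage ratios plus CombinedRatio."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cellfp.clustering import ClusterAssignment
from cellfp.coverage import (
    atc_coverage,
    combined_ratio,
    drug_coverage,
    global_median_threshold,
    go_term_coverage,
    group_coverage,
    indication_coverage,
    read_indication_table,
    screen_similar_drugs,
    write_indication_table,
)


def cross_df(values, tcm, wm):
    """Full distance matrix from the tcm x wm cross block (rest filled 1)."""
    ids = sorted(tcm) + sorted(wm)
    D = pd.DataFrame(1.0, index=ids, columns=ids)
    for i, t in enumerate(sorted(tcm)):
        for j, w in enumerate(sorted(wm)):
            D.loc[t, w] = D.loc[w, t] = values[i][j]
    np.fill_diagonal(D.values, 0.0)
    return D


class TestGlobalMedian:
    def test_odd_count(self):
        D = cross_df([[0.2, 0.5, 0.8]], ["x"], ["w1", "w2", "w3"])
        assert global_median_threshold(D, ["x"], ["w1", "w2", "w3"]) == 0.5

    def test_even_count_mean_of_central_pair(self):
        D = cross_df([[0.2, 0.4, 0.6, 0.8]], ["x"], ["w1", "w2", "w3", "w4"])
        assert global_median_threshold(D, ["x"], ["w1", "w2", "w3", "w4"]) == 0.5

    def test_1000_random_match_full_sort_oracle(self, rng):
        vals = rng.uniform(0, 1, (20, 50))
        tcm = [f"x{i:02d}" for i in range(20)]
        wm = [f"w{j:02d}" for j in range(50)]
        D = cross_df(vals, tcm, wm)
        med = global_median_threshold(D, tcm, wm)
        flat = sorted(vals.ravel())
        expected = (flat[499] + flat[500]) / 2  # even count: mean of central pair
        assert med == pytest.approx(expected, abs=0)

    def test_empty_cross_set_rejected(self):
        D = cross_df([[0.5]], ["x"], ["w"])
        with pytest.raises(ValueError):
            global_median_threshold(D, [], ["w"])


class TestScreen:
    def test_strict_less_than(self):
        D = cross_df([[0.52, 0.53]], ["x"], ["w_in", "w_out"])
        screen = screen_similar_drugs(D, ["x"], {"I": {"w_in", "w_out"}}, 0.53)
        assert screen.similar_wm_ids["I"] == {"w_in"}

    def test_boundary_value_excluded(self):
        D = cross_df([[0.53]], ["x"], ["w"])
        screen = screen_similar_drugs(D, ["x"], {"I": {"w"}}, 0.53)
        assert screen.similar_wm_ids["I"] == set()

    def test_similar_everywhere_it_appears(self):
        D = cross_df([[0.1, 0.9]], ["x"], ["w1", "w2"])
        screen = screen_similar_drugs(
            D, ["x"], {"A": {"w1"}, "B": {"w1", "w2"}}, 0.5
        )
        assert screen.similar_wm_ids == {"A": {"w1"}, "B": {"w1"}}

    def test_random_screen_equals_double_loop(self, rng):
        vals = rng.uniform(0, 1, (4, 12))
        tcm = [f"x{i}" for i in range(4)]
        wm = [f"w{j:02d}" for j in range(12)]
        D = cross_df(vals, tcm, wm)
        thr = 0.5
        screen = screen_similar_drugs(D, tcm, {"I": set(wm)}, thr)
        expected = set()
        for j, w in enumerate(wm):  # exhaustive pair scan
            if any(vals[i][j] < thr for i in range(4)):
                expected.add(w)
        assert screen.similar_wm_ids["I"] == expected

    def test_threshold_monotone(self, rng):
        vals = rng.uniform(0, 1, (3, 10))
        tcm = [f"x{i}" for i in range(3)]
        wm = [f"w{j}" for j in range(10)]
        D = cross_df(vals, tcm, wm)
        prev: set = set()
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            cur = screen_similar_drugs(D, tcm, {"I": set(wm)}, thr).similar_wm_ids["I"]
            assert prev <= cur
            prev = cur

    def test_bad_threshold_rejected(self):
        D = cross_df([[0.5]], ["x"], ["w"])
        with pytest.raises(ValueError):
            screen_similar_drugs(D, ["x"], {"I": {"w"}}, 1.5)


class TestAtcCoverage:
    def test_identical_sets(self):
        n, N, r = atc_coverage({"M01AB05"}, {"M01AB05"}, level=3)
        assert (n, N, r) == (1, 1, 1.0)

    def test_disjoint(self):
        assert atc_coverage({"M01A"}, {"N02B"}, level=3)[2] == 0.0

    def test_truncation_merges_codes(self):
        # distinct level-5 codes share the level-3 class M01A
        n, N, r = atc_coverage({"M01AB05"}, {"M01AE01", "N02BA01"}, level=3)
        assert (n, N) == (1, 2) and r == 0.5

    def test_random_sets_match_intersection_oracle(self, rng):
        letters = "MNAB"
        for _ in range(20):
            pred = {f"{letters[i % 4]}{i:02d}A{chr(65 + i % 3)}{i % 9 + 1:02d}"
                    for i in rng.integers(0, 20, 6)}
            ind = {f"{letters[i % 4]}{i:02d}A{chr(65 + i % 3)}{i % 9 + 1:02d}"
                   for i in rng.integers(0, 20, 6)}
            n, N, r = atc_coverage(pred, ind, level=3)
            p3 = {c[:4] for c in pred}
            i3 = {c[:4] for c in ind}
            assert n == len(p3 & i3) and N == len(i3) and r == n / N

    def test_empty_indication_rejected(self):
        with pytest.raises(ValueError):
            atc_coverage({"M01A"}, set())


class TestGoTermCoverage:
    def test_identical(self):
        assert go_term_coverage({"a", "b"}, {"a", "b"})[2] == 1.0

    def test_disjoint(self):
        assert go_term_coverage({"a"}, {"b"})[2] == 0.0

    def test_random_match_set_oracle(self, rng):
        for _ in range(20):
            pred = {f"GO:{i}" for i in rng.integers(0, 30, 10)}
            ind = {f"GO:{i}" for i in rng.integers(0, 30, 10)}
            m, M, r = go_term_coverage(pred, ind)
            assert m == len(pred & ind) and M == len(ind) and r == m / M


class TestDrugCoverage:
    def test_printed_ldh_counts(self):
        d, D, r = drug_coverage({f"w{i}" for i in range(23)}, {f"w{i}" for i in range(32)})
        assert (d, D) == (23, 32)
        assert round(r, 2) == 0.72

    def test_none_similar(self):
        assert drug_coverage(set(), {"w1"})[2] == 0.0

    def test_all_similar(self):
        assert drug_coverage({"w1"}, {"w1"})[2] == 1.0

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError):
            drug_coverage({"w_other"}, {"w1"})


class TestGroupCoverage:
    def test_all_seven_groups_hit(self):
        wms = {f"w{i}" for i in range(7)}
        labels = {f"w{i}": i + 1 for i in range(7)}
        g, G, r = group_coverage(labels, wms, wms)
        assert (g, G, r) == (7, 7, 1.0)

    def test_no_similar_drugs(self):
        labels = {"w1": 1, "w2": 2}
        assert group_coverage(labels, {"w1", "w2"}, set())[2] == 0.0

    def test_random_assignment_matches_group_scan(self, rng):
        for _ in range(20):
            wms = {f"w{i}" for i in range(12)}
            labels = {w: int(rng.integers(1, 5)) for w in wms}
            similar = {w for w in wms if rng.random() < 0.5}
            g, G, r = group_coverage(labels, wms, similar)
            groups_all = {labels[w] for w in wms}
            groups_sim = {labels[w] for w in similar}
            assert G == len(groups_all) and g == len(groups_sim & groups_all)

    def test_unlabeled_wm_rejected(self):
        with pytest.raises(ValueError, match="unlabeled"):
            group_coverage({"w1": 1}, {"w1", "w2"}, set())


class TestCombinedRatio:
    @pytest.mark.parametrize(
        "triple,expected", [((1, 1, 1), 1.0), ((0, 0, 0), 0.0), ((0.6, 0.9, 0.3), 0.6)]
    )
    def test_examples(self, triple, expected):
        assert combined_ratio(*triple) == pytest.approx(expected, abs=1e-15)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_equals_arithmetic_mean(self, a, g, d):
        assert combined_ratio(a, g, d) == (a + g + d) / 3.0
        assert 0.0 <= combined_ratio(a, g, d) <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combined_ratio(1.2, 0.5, 0.5)


class TestIndicationReport:
    def test_full_report_assembly(self):
        wms = {f"w{i}" for i in range(4)}
        labels = {w: (1 if w < "w2" else 2) for w in wms}
        rep = indication_coverage(
            "IND",
            predicted_atc={"M01A"},
            indication_atc={"M01AB05", "N02BA01"},
            predicted_terms={"GO:1"},
            indication_terms={"GO:1", "GO:2"},
            similar_set={"w0", "w2"},
            indication_wm_ids=wms,
            assignment=ClusterAssignment(labels=labels, k=2),
        )
        assert (rep.n, rep.N, rep.m, rep.M, rep.d, rep.D, rep.g, rep.G) == (
            1, 2, 1, 2, 2, 4, 2, 2,
        )
        assert rep.combined_ratio == pytest.approx((0.5 + 0.5 + 0.5) / 3)

    def test_indication_table_round_trip(self, tmp_path):
        table = {"A": {"w1", "w2"}, "B": {"w2"}}
        p = tmp_path / "ind.tsv"
        write_indication_table(table, p)
        assert read_indication_table(p) == table
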