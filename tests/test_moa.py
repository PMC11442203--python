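"""Mechanism transfer, common processes and regulation direction calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cellfp.hetnet import TermSource
from cellfp.moa import (
    ExpressionSignature,
    RegulationCall,
    common_processes,
    direction_report,
    group_direction,
    make_call,
    nearest_wm,
    read_signatures,
    regulation_call,
    regulation_score,
    transfer_atc,
    transfer_go_terms,
    write_signatures,
)

from conftest import make_network
from cellfp.hetnet import Role


def sim_df(rows, tcm, wm):
    ids = sorted(tcm) + sorted(wm)
    S = pd.DataFrame(0.0, index=ids, columns=ids)
    np.fill_diagonal(S.values, 1.0)
    for (x, y), v in rows.items():
        S.loc[x, y] = S.loc[y, x] = v
    return S


class TestNearestWm:
    def test_argmax(self):
        S = sim_df({("c", "wmA"): 0.9, ("c", "wmB"): 0.4}, ["c"], ["wmA", "wmB"])
        assert nearest_wm(S, ["c"], ["wmA", "wmB"], floor=0.5) == {"c": ("wmA", 0.9)}

    def test_below_floor_omitted(self):
        S = sim_df({("c", "wmA"): 0.3, ("c", "wmB"): 0.4}, ["c"], ["wmA", "wmB"])
        assert nearest_wm(S, ["c"], ["wmA", "wmB"], floor=0.5) == {}

    def test_tie_goes_to_smallest_id(self):
        S = sim_df({("c", "wmB"): 0.7, ("c", "wmA"): 0.7}, ["c"], ["wmA", "wmB"])
        assert nearest_wm(S, ["c"], ["wmA", "wmB"])["c"][0] == "wmA"

    def test_random_matches_full_scan(self, rng):
        tcm = [f"c{i}" for i in range(5)]
        wm = [f"w{j}" for j in range(8)]
        vals = rng.uniform(0, 1, (5, 8))
        S = sim_df(
            {(c, w): vals[i, j] for i, c in enumerate(tcm) for j, w in enumerate(wm)},
            tcm, wm,
        )
        nmap = nearest_wm(S, tcm, wm, floor=0.5)
        for i, c in enumerate(tcm):  # exhaustive argmax oracle
            best = max(range(8), key=lambda j: (vals[i, j], -ord(wm[j][1])))
            if vals[i, best] >= 0.5:
                assert nmap[c] == (wm[best], pytest.approx(vals[i, best]))
            else:
                assert c not in nmap

    def test_overlapping_id_sets_rejected(self):
        S = sim_df({}, ["a"], ["b"])
        with pytest.raises(ValueError):
            nearest_wm(S, ["a"], ["a", "b"])


class TestTransferAtc:
    def test_truncation_to_level3(self):
        out = transfer_atc({"c": ("w", 0.9)}, {"w": {"M01AB05"}}, level=3)
        assert out == {"c": {"M01A"}}

    def test_empty_codes_warn(self, caplog):
        with caplog.at_level("WARNING"):
            out = transfer_atc({"c": ("w", 0.9)}, {"w": set()})
        assert out == {"c": set()}
        assert any("no ATC" in r.message for r in caplog.records)

    def test_union_equals_per_compound_union(self, rng):
        wm_atc = {f"w{j}": {f"M{j:02d}A"} for j in range(5)}
        nmap = {f"c{i}": (f"w{int(rng.integers(5))}", 0.9) for i in range(8)}
        out = transfer_atc(nmap, wm_atc, level=3)
        union = set().union(*out.values())
        assert union == {next(iter(wm_atc[w])) for w, _ in nmap.values()}


class TestTransferGoTerms:
    def net(self):
        return make_network(
            ct=[("c", "t1"), ("c", "t2"), ("w", "t1"), ("v", "t3")],
            tp=[("t1", "p1"), ("t2", "p2"), ("t3", "p3")],
        )

    def test_identical_target_sets_full_share(self):
        net = make_network(
            ct=[("c", "t1"), ("w", "t1")], tp=[("t1", "p1"), ("t1", "p2")]
        )
        assert transfer_go_terms("c", "w", net) == {"p1", "p2"}

    def test_disjoint_reach_empty(self):
        assert transfer_go_terms("c", "v", self.net()) == set()

    def test_symmetric_and_bounded_by_supports(self):
        net = self.net()
        shared = transfer_go_terms("c", "w", net)
        assert shared == transfer_go_terms("w", "c", net)
        assert shared <= net.term_support("c") and shared <= net.term_support("w")

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            transfer_go_terms("c", "nope", self.net())

    def test_random_equals_bfs_reachability_oracle(self, rng):
        from conftest import random_network

        for _ in range(10):
            net = random_network(rng)
            cids = net.compound_ids()
            x, y = cids[0], cids[-1]
            # per-node breadth-first reachability over the bipartite layers
            def reach(c):
                targets = {e.target_id for e in net.ct_edges if e.compound_id == c}
                return {p for t, p in net.tp_edges if t in targets}

            assert transfer_go_terms(x, y, net) == reach(x) & reach(y)


class TestCommonProcesses:
    def test_single_shared_term(self):
        net = make_network(
            ct=[("c", "t1"), ("w", "t2")], tp=[("t1", "p1"), ("t2", "p1")]
        )
        assert common_processes(["w"], ["c"], net) == {"p1"}

    def test_no_overlap_empty(self):
        net = make_network(
            ct=[("c", "t1"), ("w", "t2")], tp=[("t1", "p1"), ("t2", "p2")]
        )
        assert common_processes(["w"], ["c"], net) == set()

    def test_source_filter_drops_other_sources(self):
        from conftest import make_network as mk
        net = mk(ct=[("c", "t1"), ("w", "t1")], tp=[("t1", "p1")])
        assert common_processes(["w"], ["c"], net, source_filter=TermSource.KEGG) == set()
        assert common_processes(["w"], ["c"], net, source_filter=None) == {"p1"}

    def test_synthetic_planted_pool_recovered(self):
        from cellfp.synthetic import SyntheticConfig, generate

        bundle = generate(SyntheticConfig(K=3, noise_rate=0.0, seed=5))
        net = bundle.network
        tcm = net.compound_ids(Role.TCM_COMPONENT)
        wm = net.compound_ids(Role.WESTERN_DRUG)
        planted = {p for pool in bundle.truth.group_terms.values() for p in pool}
        assert common_processes(wm, tcm, net, source_filter=TermSource.GO_BP) == planted


class TestRegulationScore:
    def sig(self, z):
        return ExpressionSignature("drug", z)

    def test_uniform_shift(self):
        s = self.sig({"g1": 2.0, "g2": 2.0, "g3": 2.0})
        assert regulation_score(s, {"g1", "g2", "g3"}) == 2.0

    def test_zero(self):
        s = self.sig({"g1": 0.0, "g2": 0.0, "g3": 0.0})
        assert regulation_score(s, {"g1", "g2", "g3"}) == 0.0

    def test_hand_mean(self):
        s = self.sig({"g1": 2.0, "g2": 2.0, "g3": -1.0})
        assert regulation_score(s, {"g1", "g2", "g3"}) == pytest.approx(1.0)

    def test_no_call_below_min_overlap(self):
        s = self.sig({"g1": 2.0, "g2": 2.0})
        assert regulation_score(s, {"g1", "g2", "g_absent"}, min_overlap=3) is None
        assert make_call(s, "p", {"g1"}, min_overlap=3) is None

    def test_signature_validation(self):
        with pytest.raises(ValueError):
            ExpressionSignature("d", {})
        with pytest.raises(ValueError):
            ExpressionSignature("d", {"g": float("nan")})


class TestRegulationCall:
    @pytest.mark.parametrize(
        "score,expected", [(2.0, "up"), (-2.0, "down"), (0.3, "flat"), (0.5, "flat")]
    )
    def test_thresholding(self, score, expected):
        assert regulation_call(score, tau=0.5) == expected

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.floats(-5, 5, allow_nan=False), st.floats(0.01, 2))
    def test_antisymmetry(self, score, tau):
        flipped = {"up": "down", "down": "up", "flat": "flat"}
        assert regulation_call(-score, tau) == flipped[regulation_call(score, tau)]

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            regulation_call(1.0, tau=0.0)


class TestGroupDirection:
    def calls(self, scores):
        return [RegulationCall("d", "p", s, regulation_call(s)) for s in scores]

    def test_all_up(self):
        assert group_direction(self.calls([2.0, 1.5, 1.0])) == "up"

    def test_cancellation_flat(self):
        assert group_direction(self.calls([2.0, -2.0])) == "flat"

    def test_random_matches_mean_then_threshold(self, rng):
        for _ in range(50):
            scores = rng.normal(0, 2, size=int(rng.integers(1, 8)))
            got = group_direction(self.calls(list(scores)), tau=0.5)
            mean = float(np.mean(scores))
            expected = "up" if mean > 0.5 else "down" if mean < -0.5 else "flat"
            assert got == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            group_direction([])

    def test_direction_report_shape(self):
        grouped = {(1, "p1"): self.calls([2.0, 1.0]), (2, "p1"): self.calls([-2.0])}
        df = direction_report(grouped)
        assert list(df.columns) == ["group", "term", "n_drugs", "mean_score", "direction"]
        assert df.loc[df.group == 1, "direction"].iloc[0] == "up"
        assert df.loc[df.group == 2, "direction"].iloc[0] == "down"


class TestSignatureIO:
    def test_round_trip(self, tmp_path):
        sigs = {
            "d1": ExpressionSignature("d1", {"g1": 1.25, "g2": -0.5}),
            "d2": ExpressionSignature("d2", {"g1": 0.0}),
        }
        p = tmp_path / "sigs.tsv"
        write_signatures(sigs, p)
        back = read_signatures(p)
        assert back.keys() == sigs.keys()
        for d in sigs:
            assert back[d].zscores == pytest.approx(sigs[d].zscores)
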