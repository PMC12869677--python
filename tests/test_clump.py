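import numpy as np
import pytest

from bottomline import (SimConfig, UsageError, adaptive_clump, append_singletons,
                        greedy_clump, merge_by_shared_variants,
                        simulate_ld_panel)
from bottomline.clump import Clump
from conftest import make_panel, make_study
from oracles import brute_force_clump, union_find_components


def _clump_pairs(clumps):
    return [(c.lead, c.members) for c in clumps]


class TestGreedyClump:
    def test_hand_example(self):
        # A(p=1e-10), B(p=1e-9, r2=0.5, 10 kb away), C(p=1e-7, r2=0)
        s = make_study([
            {"chrom": 1, "pos": 100_000, "log10p": -10, "beta": 0.64, "se": 0.1},
            {"chrom": 1, "pos": 110_000, "log10p": -9, "beta": 0.61, "se": 0.1},
            {"chrom": 1, "pos": 120_000, "log10p": -7, "beta": 0.52, "se": 0.1},
        ])
        panel = make_panel([(1, 100_000), (1, 110_000), (1, 120_000)],
                           [("1:100000:A:G", "1:110000:A:G", 0.5)])
        clumps = greedy_clump(s, panel)
        assert len(clumps) == 1
        assert clumps[0].lead == "1:100000:A:G"
        assert clumps[0].members == {"1:100000:A:G", "1:110000:A:G"}

    def test_no_eligible_lead(self):
        s = make_study([{"chrom": 1, "pos": 1, "log10p": -6, "beta": 0.1, "se": 0.02}])
        panel = make_panel([(1, 1)])
        assert greedy_clump(s, panel) == []

    def test_window_excludes_distant_variants(self):
        s = make_study([
            {"chrom": 1, "pos": 1_000_000, "log10p": -10, "beta": 0.6, "se": 0.1},
            {"chrom": 1, "pos": 7_000_000, "log10p": -9, "beta": 0.6, "se": 0.1},
        ])
        panel = make_panel([(1, 1_000_000), (1, 7_000_000)],
                           [("1:1000000:A:G", "1:7000000:A:G", 0.9)])
        clumps = greedy_clump(s, panel)
        assert len(clumps) == 2  # 6 Mb apart: outside the ±2.5 Mb window
        assert all(len(c.members) == 1 for c in clumps)

    def test_member_requires_p2(self):
        s = make_study([
            {"chrom": 1, "pos": 100, "log10p": -9, "beta": 0.6, "se": 0.1},
            {"chrom": 1, "pos": 200, "log10p": -4, "beta": 0.4, "se": 0.1},
        ])
        panel = make_panel([(1, 100), (1, 200)], [("1:100:A:G", "1:200:A:G", 0.9)])
        clumps = greedy_clump(s, panel)
        assert clumps[0].members == {"1:100:A:G"}

    def test_ancestry_mismatch_rejected(self, tiny_study):
        panel = make_panel([(1, 100)], ancestry="EA")
        with pytest.raises(UsageError):
            greedy_clump(tiny_study, panel)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            n = int(rng.integers(5, 120))
            mismatch = _random_instance(rng, n)
            assert mismatch is None, mismatch

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        s, panel = _random_study_panel(rng, 80)
        a = _clump_pairs(greedy_clump(s, panel))
        b = _clump_pairs(greedy_clump(s, panel))
        assert a == b


def _random_study_panel(rng, n):
    chroms = rng.choice(["1", "2"], size=n)
    pos = rng.integers(1, 8_000_000, size=n)
    keys = {}
    rows = []
    for i in range(n):
        vid = (chroms[i], int(pos[i]))
        if vid in keys:
            continue
        keys[vid] = True
        rows.append({"chrom": chroms[i], "pos": int(pos[i]),
                     "log10p": float(-12 * rng.random()),
                     "beta": 0.1, "se": 0.1})
    s = make_study(rows)
    panel_rows = [(r["chrom"], r["pos"]) for r in rows if rng.random() < 0.9]
    vids = [f"{c}:{p}:A:G" for c, p in panel_rows]
    pairs = []
    for i in range(len(vids)):
        for j in range(i + 1, len(vids)):
            if rng.random() < 0.1:
                pairs.append((vids[i], vids[j], float(rng.random())))
    return s, make_panel(panel_rows, pairs)


def _random_instance(rng, n):
    s, panel = _random_study_panel(rng, n)
    p1 = float(rng.choice([5e-8, 5e-7, 1e-6]))
    p2 = 5e-6
    r2 = float(rng.choice([0.01, 0.2, 0.5]))
    kb = float(rng.choice([100, 1000, 5000]))
    got = _clump_pairs(greedy_clump(s, panel, p1, p2, r2, kb))
    want = brute_force_clump(s.df, panel, p1, p2, r2, kb)
    if got != want:
        return f"mismatch: got {got}, want {want}"
    return None


class TestAdaptiveClump:
    def _fixture(self, n_sig, n_weak, weak_l10):
        rows = []
        for i in range(n_sig):
            rows.append({"chrom": 1, "pos": 10_000_000 * (i + 1), "log10p": -9.0,
                         "beta": 0.6, "se": 0.1})
        for i in range(n_weak):
            rows.append({"chrom": 2, "pos": 10_000_000 * (i + 1),
                         "log10p": weak_l10, "beta": 0.5, "se": 0.1})
        s = make_study(rows)
        panel = make_panel([(r["chrom"], r["pos"]) for r in rows])
        return s, panel

    def test_no_relaxation_when_enough_clumps(self):
        s, panel = self._fixture(60, 0, -7.0)
        clumps, p1_used = adaptive_clump(s, panel, min_clumps=50)
        assert p1_used == 5e-8
        assert len(clumps) == 60

    def test_relaxes_tenfold_until_enough(self):
        # 10 clumps at 5e-8 but 65 at 5e-7 (weak set has p = 1e-7)
        s, panel = self._fixture(10, 55, -7.0)
        clumps, p1_used = adaptive_clump(s, panel, min_clumps=50)
        assert p1_used == 5e-7
        assert len(clumps) == 65

    def test_capped_at_p2(self):
        s, panel = self._fixture(20, 0, -7.0)
        clumps, p1_used = adaptive_clump(s, panel, min_clumps=50)
        assert p1_used == 5e-6
        assert len(clumps) == 20


class TestAppendSingletons:
    def test_distant_absent_variant_appended(self):
        s = make_study([
            {"chrom": 1, "pos": 1_000_000, "log10p": -10, "beta": 0.6, "se": 0.1},
            {"chrom": 1, "pos": 20_000_000, "log10p": -9, "beta": 0.6, "se": 0.1},
        ])
        panel = make_panel([(1, 1_000_000)])
        clumps = greedy_clump(s, panel)
        out = append_singletons(clumps, s, panel, 5e-8)
        assert len(out) == 2
        assert out[-1].members == {"1:20000000:A:G"}

    def test_interior_absent_variant_attached_not_appended(self):
        s = make_study([
            {"chrom": 1, "pos": 1_000_000, "log10p": -10, "beta": 0.6, "se": 0.1},
            {"chrom": 1, "pos": 1_200_000, "log10p": -9, "beta": 0.6, "se": 0.1},
            {"chrom": 1, "pos": 1_100_000, "log10p": -9, "beta": 0.6, "se": 0.1},
        ])
        panel = make_panel([(1, 1_000_000), (1, 1_200_000)],
                           [("1:1000000:A:G", "1:1200000:A:G", 0.8)])
        clumps = greedy_clump(s, panel)
        assert clumps[0].span == (1_000_000, 1_200_000)
        out = append_singletons(clumps, s, panel, 5e-8)
        assert len(out) == 1
        assert "1:1100000:A:G" in out[0].members

    def test_panel_covered_variant_unaffected(self):
        s = make_study([
            {"chrom": 1, "pos": 1_000_000, "log10p": -10, "beta": 0.6, "se": 0.1},
            {"chrom": 1, "pos": 20_000_000, "log10p": -9, "beta": 0.6, "se": 0.1},
        ])
        panel = make_panel([(1, 1_000_000), (1, 20_000_000)])
        clumps = greedy_clump(s, panel)
        out = append_singletons(clumps, s, panel, 5e-8)
        assert _clump_pairs(out) == _clump_pairs(clumps)


def _mk_clump(members, lead=None):
    members = set(members)
    lead = lead or sorted(members)[0]
    positions = [int(m.split(":")[1]) for m in members]
    return Clump(lead=lead, lead_log10p=-9.0, members=frozenset(members),
                 chrom=lead.split(":")[0], span=(min(positions), max(positions)))


class TestMergeSignals:
    def test_shared_variant_merges_across_labels(self):
        v = [f"1:{i}:A:G" for i in (1, 2, 3)]
        signals = merge_by_shared_variants({
            "X": [_mk_clump(v[:2])], "Y": [_mk_clump(v[1:])],
        })
        assert len(signals) == 1
        assert signals[0].variants == set(v)
        assert signals[0].labels == {"X", "Y"}

    def test_disjoint_clumps_stay_separate(self):
        signals = merge_by_shared_variants({
            "X": [_mk_clump(["1:1:A:G"])], "Y": [_mk_clump(["1:9:A:G"])],
        })
        assert len(signals) == 2
        assert all(len(sig.labels) == 1 for sig in signals)

    def test_chain_across_three_labels(self):
        signals = merge_by_shared_variants({
            "L1": [_mk_clump(["1:1:A:G", "1:2:A:G"])],
            "L2": [_mk_clump(["1:2:A:G", "1:3:A:G"])],
            "L3": [_mk_clump(["1:3:A:G", "1:4:A:G"])],
        })
        assert len(signals) == 1
        assert len(signals[0].variants) == 4
        assert signals[0].labels == {"L1", "L2", "L3"}

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            universe = [f"1:{i}:A:G" for i in range(1, 40)]
            clump_sets = {}
            member_sets = []
            for label in ("A", "B", "C"):
                clumps = []
                for _ in range(int(rng.integers(1, 6))):
                    size = int(rng.integers(1, 6))
                    members = list(rng.choice(universe, size=size, replace=False))
                    clumps.append(_mk_clump(members, lead=members[0]))
                    member_sets.append(frozenset(members))
                clump_sets[label] = clumps
            got = sorted((sig.variants for sig in merge_by_shared_variants(clump_sets)),
                         key=lambda c: sorted(c))
            assert got == union_find_components(member_sets)

    def test_idempotent_under_remerge(self):
        signals = merge_by_shared_variants({
            "X": [_mk_clump(["1:1:A:G", "1:2:A:G"])],
            "Y": [_mk_clump(["1:2:A:G", "1:3:A:G"]), _mk_clump(["1:7:A:G"])],
        })
        again = merge_by_shared_variants({
            "merged": [_mk_clump(sig.variants, lead=sorted(sig.variants)[0])
                       for sig in signals],
        })
        assert sorted(sig.variants for sig in signals) == \
            sorted(sig.variants for sig in again)

    def test_partition_of_union(self):
        clump_sets = {
            "X": [_mk_clump(["1:1:A:G", "1:2:A:G"]), _mk_clump(["1:5:A:G"])],
            "Y": [_mk_clump(["1:2:A:G", "1:3:A:G"])],
        }
        signals = merge_by_shared_variants(clump_sets)
        union = set().union(*(c.members for cl in clump_sets.values() for c in cl))
        got = [v for sig in signals for v in sig.variants]
        assert sorted(got) == sorted(union)


class TestSimulatedPanelClumping:
    def test_block_structure_round_trips_through_files(self, tmp_path):
        cfg = SimConfig(seed=2, n_variants=30, block_size=3, ld_rho=0.9)
        panel = simulate_ld_panel(cfg)
        vp, pp = tmp_path / "v.tsv", tmp_path / "p.tsv"
        panel.to_files(vp, pp)
        from bottomline import LDPanel
        back = LDPanel.from_files(vp, pp, panel.ancestry)
        ids = list(panel.variants.index)
        assert list(back.variants.index) == ids
        assert back.r2(ids[0], ids[1]) == pytest.approx(0.81)
        assert back.r2(ids[0], ids[3]) == 0.0
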