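import numpy as np
import pytest
from scipy import stats

from aimpanel import (
    Panel,
    ScoreTable,
    consensus_panel,
    random_panel,
    rerank_panel,
    subset_genotypes,
)

from conftest import random_genotype_matrix
from oracles import consensus_tally_bruteforce


def _panel(name, ids):
    return Panel(name=name, snp_ids=list(ids))


class TestConsensus:
    def test_threshold_membership(self):
        panels = [_panel(f"m{k}", ids) for k, ids in enumerate(
            [["a", "b", "c"], ["a", "b"], ["a", "b"], ["a", "d"]]
        )]
        got = consensus_panel(panels, min_methods=3)
        assert set(got.snp_ids) == {"a", "b"}  # a in 4/4 kept, b in 3/4 kept, c/d dropped

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(13)
        universe = [f"s{j}" for j in range(200)]
        panels = [
            _panel(f"m{k}", rng.choice(universe, size=rng.integers(20, 120), replace=False))
            for k in range(50)
        ]
        for min_methods in (1, 5, 12, 25, 50):
            got = set(consensus_panel(panels, min_methods).snp_ids)
            want = consensus_tally_bruteforce(universe, [p.snp_ids for p in panels], min_methods)
            assert got == want

    def test_monotone_union_intersection(self):
        rng = np.random.default_rng(4)
        universe = [f"s{j}" for j in range(60)]
        panels = [_panel(f"m{k}", rng.choice(universe, size=25, replace=False)) for k in range(4)]
        sizes = [len(consensus_panel(panels, k)) for k in range(1, 5)]
        assert sizes == sorted(sizes, reverse=True)
        union = set().union(*(set(p.snp_ids) for p in panels))
        inter = set(panels[0].snp_ids).intersection(*(set(p.snp_ids) for p in panels[1:]))
        assert set(consensus_panel(panels, 1).snp_ids) == union
        assert set(consensus_panel(panels, 4).snp_ids) == inter

    def test_input_order_invariance(self):
        rng = np.random.default_rng(8)
        universe = [f"s{j}" for j in range(40)]
        panels = [_panel(f"m{k}", rng.choice(universe, size=15, replace=False)) for k in range(4)]
        a = consensus_panel(panels, 2).snp_ids
        b = consensus_panel(panels[::-1], 2).snp_ids
        assert a == b

    def test_ordered_by_count_then_coordinates(self):
        G = random_genotype_matrix(seed=0, n=4, m=6, missing_rate=0.0)
        ids = G.snp_ids
        panels = [
            _panel("m0", [ids[5], ids[1]]),
            _panel("m1", [ids[1], ids[5], ids[3]]),
            _panel("m2", [ids[1], ids[3]]),
        ]
        got = consensus_panel(panels, 2, universe=G)
        assert got.snp_ids == [ids[1], ids[3], ids[5]]  # count 3 first, then position

    def test_errors(self):
        with pytest.raises(ValueError, match="at least one"):
            consensus_panel([], 1)
        with pytest.raises(ValueError, match="min_methods"):
            consensus_panel([_panel("m0", ["a"])], 2)


class TestRandomPanel:
    def test_seed_determinism_and_boundary(self):
        G = random_genotype_matrix(seed=2, n=4, m=10)
        p1 = random_panel(G, size=4, seed=9)
        p2 = random_panel(G, size=4, seed=9)
        assert p1.snp_ids == p2.snp_ids
        assert p1.provenance["seed"] == 9
        assert set(random_panel(G, size=10, seed=0).snp_ids) == set(G.snp_ids)
        with pytest.raises(ValueError, match="requested 11"):
            random_panel(G, size=11, seed=0)

    def test_uniform_sampling(self):
        """Each of 10 SNPs drawn with frequency 1/10 within 3-sigma binomial bounds."""
        G = random_genotype_matrix(seed=3, n=4, m=10)
        draws = 10_000
        counts = {sid: 0 for sid in G.snp_ids}
        for seed in range(draws):
            counts[random_panel(G, size=1, seed=seed).snp_ids[0]] += 1
        expected = draws / 10
        sigma = np.sqrt(draws * 0.1 * 0.9)
        for sid, c in counts.items():
            assert abs(c - expected) < 3 * sigma, sid

    def test_overlap_near_hypergeometric_expectation(self):
        G = random_genotype_matrix(seed=4, n=4, m=20)
        size = 8
        overlaps = [
            len(set(random_panel(G, size, seed=2 * t).snp_ids)
                & set(random_panel(G, size, seed=2 * t + 1).snp_ids))
            for t in range(300)
        ]
        expected = size * size / 20  # hypergeometric mean
        sd = np.sqrt(stats.hypergeom(20, size, size).var() / len(overlaps))
        assert abs(np.mean(overlaps) - expected) < 4 * sd


class TestRerank:
    def _scores(self, ids, values):
        return ScoreTable(
            snp_ids=ids, chromosomes=["1"] * len(ids), positions=list(range(len(ids))),
            method="informativeness", scores=np.array(values, dtype=float),
        )

    def test_orders_by_score(self):
        panel = _panel("p", ["a", "b", "c", "d", "e"])
        scores = self._scores(["a", "b", "c", "d", "e"], [1, 5, 3, 2, 4])
        assert rerank_panel(panel, scores, 2).snp_ids == ["b", "e"]

    def test_full_size_is_reordering(self):
        panel = _panel("p", ["a", "b", "c"])
        scores = self._scores(["a", "b", "c"], [1, 3, 2])
        out = rerank_panel(panel, scores, 3)
        assert out.snp_ids == ["b", "c", "a"]
        assert set(out.snp_ids) == set(panel.snp_ids)

    def test_matches_independent_sort(self):
        rng = np.random.default_rng(17)
        ids = [f"s{j}" for j in range(40)]
        vals = rng.uniform(size=40)
        panel = _panel("p", rng.choice(ids, size=25, replace=False))
        out = rerank_panel(panel, self._scores(ids, vals), 10)
        lookup = dict(zip(ids, vals))
        want = sorted(panel.snp_ids, key=lambda s: -lookup[s])[:10]
        assert out.snp_ids == want

    def test_missing_score_errors(self):
        panel = _panel("p", ["a", "b"])
        scores = self._scores(["a", "b"], [1.0, np.nan])
        with pytest.raises(ValueError, match="b"):
            rerank_panel(panel, scores, 1)
        with pytest.raises(ValueError, match="exceeds"):
            rerank_panel(panel, self._scores(["a", "b"], [1, 2]), 3)


class TestSubset:
    def test_projection_preserves_cells_and_order(self):
        G = random_genotype_matrix(seed=5, n=5, m=10)
        panel = _panel("p", [G.snp_ids[7], G.snp_ids[2], G.snp_ids[4]])
        sub = subset_genotypes(G, panel)
        assert sub.snp_ids == [G.snp_ids[2], G.snp_ids[4], G.snp_ids[7]]  # source order
        np.testing.assert_array_equal(sub.genotypes, G.genotypes[:, [2, 4, 7]])
        assert sub.individual_ids == G.individual_ids

    def test_identity_and_errors(self):
        G = random_genotype_matrix(seed=6, n=4, m=6)
        full = subset_genotypes(G, _panel("all", list(G.snp_ids)))
        np.testing.assert_array_equal(full.genotypes, G.genotypes)
        with pytest.raises(ValueError, match="empty"):
            subset_genotypes(G, _panel("none", []))
        with pytest.raises(ValueError, match="nope"):
            subset_genotypes(G, _panel("bad", ["nope"]))


def test_panel_file_round_trip(tmp_path):
    panel = Panel(
        name="consensus",
        snp_ids=["s3", "s1", "s2"],
        provenance={"method": "consensus", "min_methods": 3, "seed": 7},
    )
    panel.write(tmp_path / "panel.txt")
    back = Panel.read(tmp_path / "panel.txt")
    assert back.name == panel.name
    assert back.snp_ids == panel.snp_ids
    assert back.provenance == panel.provenance
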