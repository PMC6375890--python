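import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aimpanel import (
    AlleleFrequencyTable,
    GenotypeMatrix,
    MISSING,
    PMatrix,
    SelectionConfig,
    compute_allele_freqs,
    informativeness,
    k_variance,
    pca_snp_weights,
    threshold_panel,
    top_n,
    wc_fst,
)
from aimpanel.scoring import genome_fst, normalize_genotypes

from conftest import random_genotype_matrix
from oracles import informativeness_bruteforce, pca_eigh_bruteforce, wc_theta_bruteforce


def _freq_table(p_alt: np.ndarray) -> AlleleFrequencyTable:
    m, K = p_alt.shape
    return AlleleFrequencyTable(
        snp_ids=[f"s{j}" for j in range(m)],
        population_labels=[f"p{i}" for i in range(K)],
        p_alt=p_alt,
        counts=np.full((m, K), 20),
        chromosomes=["1"] * m,
        positions=list(range(1, m + 1)),
    )


class TestAlleleFrequencies:
    def test_direct_count_and_missing_exclusion(self):
        G = GenotypeMatrix(
            individual_ids=["a", "b", "c", "d", "e"],
            family_ids=["p1", "p1", "p1", "p2", "p2"],
            snp_ids=["s1"],
            chromosomes=["1"],
            positions=[1],
            genotypes=np.array([[0], [1], [2], [2], [MISSING]]),
        )
        ft = compute_allele_freqs(G)
        # p1: (0+1+2)/6 = 0.5; p2: 2/2 = 1.0 with the missing call excluded.
        np.testing.assert_allclose(ft.p_alt[0], [0.5, 1.0])
        assert ft.counts[0].tolist() == [6, 2]
        # pooled mean is the unweighted mean over populations
        np.testing.assert_allclose(ft.p_mean, [0.75])

    def test_all_missing_population_is_nan(self):
        G = GenotypeMatrix(
            individual_ids=["a", "b"],
            family_ids=["p1", "p2"],
            snp_ids=["s1"],
            chromosomes=["1"],
            positions=[1],
            genotypes=np.array([[1], [MISSING]]),
        )
        ft = compute_allele_freqs(G)
        assert np.isnan(ft.p_alt[0, 1])


class TestInformativeness:
    def test_printed_examples(self):
        ft = _freq_table(np.array([[0.3, 0.3], [1.0, 0.0], [0.8, 0.2]]))
        scores = informativeness(ft).scores
        assert scores[0] == 0.0                                  # identical frequencies
        np.testing.assert_allclose(scores[1], np.log(2), atol=1e-12)  # fixed difference
        np.testing.assert_allclose(scores[2], 0.19274476, atol=1e-7)

    @pytest.mark.parametrize("K", [2, 3, 5])
    def test_matches_bruteforce(self, K):
        rng = np.random.default_rng(100 + K)
        p = rng.uniform(0, 1, size=(60, K))
        scores = informativeness(_freq_table(p)).scores
        expected = [informativeness_bruteforce(list(row)) for row in p]
        np.testing.assert_allclose(scores, expected, atol=1e-10)

    @given(st.integers(min_value=0, max_value=2**31 - 1), st.sampled_from([2, 3, 5]))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_bounds(self, seed, K):
        """0 <= I <= ln K on arbitrary frequency tables."""
        rng = np.random.default_rng(seed)
        scores = informativeness(_freq_table(rng.uniform(0, 1, size=(10, K)))).scores
        assert np.all(scores >= 0)
        assert np.all(scores <= np.log(K) + 1e-12)

    def test_monotone_as_populations_separate(self):
        """I increases as two populations' frequencies pull apart symmetrically."""
        deltas = np.linspace(0, 0.45, 10)
        p = np.stack([0.5 + deltas, 0.5 - deltas], axis=1)
        scores = informativeness(_freq_table(p)).scores
        assert np.all(np.diff(scores) > 0)

    def test_undefined_population_gives_nan(self):
        p = np.array([[0.5, np.nan], [0.2, 0.7]])
        scores = informativeness(_freq_table(p)).scores
        assert np.isnan(scores[0]) and np.isfinite(scores[1])

    def test_requires_two_populations(self):
        with pytest.raises(ValueError, match="K >= 2"):
            informativeness(_freq_table(np.array([[0.5]])))


def _matrix_from_pop_genotypes(pop_lists):
    """Genotype matrix with one SNP from per-population genotype lists."""
    genos, fids = [], []
    for idx, lst in enumerate(pop_lists):
        genos.extend(lst)
        fids.extend([f"p{idx}"] * len(lst))
    return GenotypeMatrix(
        individual_ids=[f"i{k}" for k in range(len(genos))],
        family_ids=fids,
        snp_ids=["s1"],
        chromosomes=["1"],
        positions=[1],
        genotypes=np.array(genos).reshape(-1, 1),
    )


class TestWcFst:
    def test_fixed_difference_is_one(self):
        G = _matrix_from_pop_genotypes([[2] * 10, [0] * 10])
        assert wc_fst(G).scores[0] == 1.0

    def test_identical_populations_not_positive(self):
        G = _matrix_from_pop_genotypes([[0, 1, 1, 2], [0, 1, 1, 2]])
        assert wc_fst(G).scores[0] <= 0

    def test_matches_bruteforce_on_random_configs(self):
        rng = np.random.default_rng(77)
        for _ in range(60):
            r = rng.integers(2, 5)
            pops = [list(rng.integers(0, 3, size=rng.integers(2, 12))) for _ in range(r)]
            got = wc_fst(_matrix_from_pop_genotypes(pops)).scores[0]
            want = wc_theta_bruteforce(pops)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                np.testing.assert_allclose(got, want, atol=1e-10)

    def test_allele_relabelling_invariance(self):
        rng = np.random.default_rng(5)
        G = random_genotype_matrix(seed=8, missing_rate=0.0)
        flipped = GenotypeMatrix(
            individual_ids=G.individual_ids,
            family_ids=G.family_ids,
            snp_ids=G.snp_ids,
            chromosomes=G.chromosomes,
            positions=G.positions,
            genotypes=(2 - G.genotypes).astype(np.int8),
        )
        np.testing.assert_allclose(wc_fst(G).scores, wc_fst(flipped).scores, atol=1e-12)

    def test_single_population_error(self):
        G = _matrix_from_pop_genotypes([[0, 1, 2]])
        with pytest.raises(ValueError, match=">=2 populations"):
            wc_fst(G)

    def test_negative_estimates_kept_unless_clamped(self):
        G = _matrix_from_pop_genotypes([[0, 1, 1, 2], [0, 1, 1, 2]])
        raw = wc_fst(G).scores[0]
        clamped = wc_fst(G, clamp_negative=True).scores[0]
        assert raw < 0 and clamped == 0.0

    def test_hudson_estimator_available(self):
        G = _matrix_from_pop_genotypes([[2] * 10, [0] * 10])
        assert wc_fst(G, estimator="hudson").scores[0] == pytest.approx(1.0)


class TestPcaWeights:
    def test_matches_eigendecomposition_oracle(self):
        G = random_genotype_matrix(seed=3, n=5, m=10, missing_rate=0.0)
        X = normalize_genotypes(G)
        _, loadings, _ = pca_eigh_bruteforce(X)
        for pc in (1, 2, 3):
            w = pca_snp_weights(G, pc_index=pc).scores
            ref = loadings[:, pc - 1]
            assert min(np.abs(w - ref).max(), np.abs(w + ref).max()) < 1e-8

    def test_monomorphic_snp_gets_zero_weight(self):
        G = random_genotype_matrix(seed=4, n=6, m=8, missing_rate=0.0)
        gt = G.genotypes.copy()
        gt[:, 0] = 1
        G2 = GenotypeMatrix(
            individual_ids=G.individual_ids, family_ids=G.family_ids,
            snp_ids=G.snp_ids, chromosomes=G.chromosomes, positions=G.positions,
            genotypes=gt,
        )
        assert abs(pca_snp_weights(G2).scores[0]) < 1e-12

    def test_ranking_invariant_to_individual_order_and_sign(self):
        G = random_genotype_matrix(seed=6, n=8, m=15, missing_rate=0.0)
        w = pca_snp_weights(G).scores
        perm = np.random.default_rng(0).permutation(G.n_individuals)
        G2 = GenotypeMatrix(
            individual_ids=[G.individual_ids[i] for i in perm],
            family_ids=[G.family_ids[i] for i in perm],
            snp_ids=G.snp_ids, chromosomes=G.chromosomes, positions=G.positions,
            genotypes=G.genotypes[perm],
        )
        w2 = pca_snp_weights(G2).scores
        np.testing.assert_allclose(np.abs(w), np.abs(w2), atol=1e-10)
        assert np.argsort(-np.abs(w)).tolist() == np.argsort(-np.abs(w2)).tolist()

    def test_pc_index_out_of_range(self):
        G = random_genotype_matrix(seed=1, n=4, m=10)
        with pytest.raises(ValueError, match="out of range"):
            pca_snp_weights(G, pc_index=4)


class TestKVariance:
    def test_hand_values(self):
        P = PMatrix(["s1", "s2"], np.array([[0.4, 0.4, 0.4], [1.0, 0.0, 0.5]]))
        scores = k_variance(P).scores
        np.testing.assert_allclose(scores, [0.0, 0.25], atol=1e-12)

    def test_threshold_filter(self):
        # variances 0.25 and 0.10: only the first survives the 0.15 rule
        P = PMatrix(["s1", "s2"], np.array([[1.0, 0.0, 0.5], [0.8, 0.55, 0.35]]))
        scores = k_variance(P)
        assert abs(scores.scores[1] - 0.10) < 0.05
        panel = threshold_panel(scores, 0.15)
        assert panel.snp_ids == ["s1"]

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(2)
        freqs = rng.uniform(0, 1, size=(20, 4))
        P1 = PMatrix([f"s{j}" for j in range(20)], freqs)
        P2 = PMatrix([f"s{j}" for j in range(20)], freqs[:, [2, 0, 3, 1]])
        np.testing.assert_allclose(k_variance(P1).scores, k_variance(P2).scores, atol=1e-12)

    def test_single_cluster_error(self):
        with pytest.raises(ValueError, match="K >= 2"):
            k_variance(PMatrix(["s1"], np.array([[0.5]])))


class TestTopN:
    def _table(self, scores, **kw):
        from aimpanel import ScoreTable

        m = len(scores)
        return ScoreTable(
            snp_ids=kw.get("snp_ids", [f"s{j}" for j in range(m)]),
            chromosomes=kw.get("chromosomes", ["1"] * m),
            positions=kw.get("positions", list(range(1, m + 1))),
            method="informativeness",
            scores=np.array(scores, dtype=float),
        )

    def test_direct_ordering(self):
        panel = top_n(self._table([3.0, 2.0, 1.0]), 2)
        assert panel.snp_ids == ["s0", "s1"]

    def test_tie_break_by_coordinates(self):
        t = self._table([3.0, 2.0, 2.0], positions=[30, 20, 10])
        assert top_n(t, 2).snp_ids == ["s0", "s2"]  # tie broken by position

    def test_boundary_and_errors(self):
        t = self._table([1.0, np.nan, 2.0])
        assert set(top_n(t, 2).snp_ids) == {"s0", "s2"}  # NaN excluded before ranking
        with pytest.raises(ValueError, match="exceeds the 2 scorable"):
            top_n(t, 3)
        assert top_n(self._table([1.0, 2.0]), SelectionConfig(top_n=2)).snp_ids == ["s1", "s0"]

    def test_pca_ranking_uses_absolute_weight(self):
        from aimpanel import ScoreTable

        t = ScoreTable(["a", "b"], ["1", "1"], [1, 2], "pca_weight", np.array([-0.9, 0.1]))
        assert top_n(t, 1).snp_ids == ["a"]


class TestScoreSeparation:
    def test_differentiated_snps_score_higher_all_methods(self, two_pop_dataset):
        """Mean score over truly differentiated SNPs beats undifferentiated ones.

        Half the SNPs are replaced by draws from a shared frequency, so the
        truth is known by construction.
        """
        ds = two_pop_dataset
        rng = np.random.default_rng(0)
        m = ds.genotypes.n_snps
        undiff = np.arange(m // 2, m)
        gt = ds.genotypes.genotypes.copy()
        shared = ds.true_P.frequencies[undiff].mean(axis=1)
        gt[:, undiff] = rng.binomial(2, shared, size=(gt.shape[0], undiff.size)).astype(np.int8)
        G = GenotypeMatrix(
            individual_ids=ds.genotypes.individual_ids,
            family_ids=ds.genotypes.family_ids,
            snp_ids=ds.genotypes.snp_ids,
            chromosomes=ds.genotypes.chromosomes,
            positions=ds.genotypes.positions,
            genotypes=gt,
        )
        diff = np.arange(0, m // 2)
        ft = compute_allele_freqs(G)
        from aimpanel import fit_admixture

        fit = fit_admixture(G, K=2, seed=0, n_restarts=1)
        for table in (
            informativeness(ft),
            wc_fst(G),
            pca_snp_weights(G),
            k_variance(fit.P, snp_meta=G),
        ):
            s = np.abs(table.scores) if table.method == "pca_weight" else table.scores
            assert np.nanmean(s[diff]) > np.nanmean(s[undiff]), table.method


def test_genome_fst_tracks_generating_parameter():
    """Ratio-of-sums theta-hat recovers the Balding-Nichols F of the cohort."""
    from aimpanel import GroupSpec, SimulationConfig, simulate

    groups = [GroupSpec(n=30, label="a", q=[1.0, 0.0]), GroupSpec(n=30, label="b", q=[0.0, 1.0])]
    ds = simulate(SimulationConfig(K=2, groups=groups, m=4000, F=0.25, seed=21))
    assert genome_fst(ds.genotypes) == pytest.approx(0.25, abs=0.03)
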