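"""Per-locus statistics, F_ST, HWP exact test, relatedness, PCA."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

import panelkin as pk
from panelkin import HET, HOMALT, HOMREF, MISSING
from panelkin.exceptions import UsageError


def _matrix(calls, pops=None, samples=None):
    calls = np.array(calls, dtype=np.int8)
    samples = samples or [f"s{i}" for i in range(calls.shape[0])]
    loci = [f"L{j}" for j in range(calls.shape[1])]
    popmap = {}
    if pops is not None:
        popmap = dict(zip(samples, pops))
    return pk.GenotypeMatrix(samples, loci, calls, popmap)


class TestAlleleFreqStats:
    def test_hand_counts(self):
        m = _matrix([[HOMREF], [HET], [HOMALT]])
        (s,) = pk.allele_freq_stats(m)
        assert s.p_alt == pytest.approx(0.5)
        assert s.h_obs == pytest.approx(1 / 3)
        assert s.h_exp == pytest.approx(0.5)
        assert s.maf == pytest.approx(0.5)

    def test_all_het(self):
        m = _matrix([[HET], [HET]])
        (s,) = pk.allele_freq_stats(m)
        assert s.h_obs == 1.0
        assert s.p_alt == 0.5

    def test_matches_bruteforce_tally(self, rng):
        col = rng.integers(-1, 3, size=50).astype(np.int8)
        m = _matrix(col[:, None])
        (s,) = pk.allele_freq_stats(m)
        typed = [int(c) for c in col if c != MISSING]
        alt = sum({0: 0, 1: 1, 2: 2}[c] for c in typed)
        assert s.n_typed == len(typed)
        assert s.p_alt == pytest.approx(alt / (2 * len(typed)))
        assert s.h_obs == pytest.approx(sum(c == 1 for c in typed) / len(typed))

    def test_untyped_locus_flagged_undefined(self):
        m = _matrix([[MISSING, HET], [MISSING, HET]])
        stats = pk.allele_freq_stats(m)
        assert not stats[0].defined and stats[1].defined

    def test_invariants_on_random_data(self, random_matrix):
        for s in pk.allele_freq_stats(random_matrix):
            if s.defined:
                assert s.maf <= 0.5
                assert s.h_exp <= 0.5 + 1e-12
                assert 0 <= s.h_obs <= 1


class TestMafFilter:
    def test_boundary(self):
        stats = [
            pk.LocusStats("a", 100, 0.009, 0.009, 0.1, 0.1),
            pk.LocusStats("b", 100, 0.01, 0.01, 0.1, 0.1),
        ]
        assert pk.filter_maf(stats, 0.01) == {"b"}

    def test_planted_frequencies(self, rng):
        mafs = rng.uniform(0, 0.5, 200)
        stats = [pk.LocusStats(f"L{i}", 50, m, m, 0.2, 0.2) for i, m in enumerate(mafs)]
        expected = {f"L{i}" for i, m in enumerate(mafs) if m >= 0.01}
        assert pk.filter_maf(stats) == expected


def _wc84_anova_oracle(calls, pops):
    """Independent WC84 theta: allele-indicator nested ANOVA on raw calls.

    Decomposes allele-indicator variance into between-population (a),
    between-individual-within-population (b), and within-individual (c)
    components from sums of squares, never touching p/h summary formulas.
    """
    groups = {}
    for row, pop in zip(calls, pops):
        if row != MISSING:
            groups.setdefault(pop, []).append(row)
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    r = len(groups)
    n = np.array([len(v) for v in groups.values()], dtype=float)
    S1 = n.sum()
    nc = (S1 - (n**2).sum() / S1) / (r - 1)
    # individual allele indicators: genotype code / 2 is the individual mean
    ssg = ssi = ssp = 0.0
    overall = sum(sum(v) for v in groups.values()) / (2 * S1)
    for ni, members in zip(n, groups.values()):
        pop_mean = sum(members) / (2 * ni)
        ssp += 2 * ni * (pop_mean - overall) ** 2
        for g in members:
            ind_mean = g / 2
            ssi += 2 * (ind_mean - pop_mean) ** 2
            for allele in ([0, 0], [0, 1], [1, 1])[g]:
                ssg += (allele - ind_mean) ** 2
    msg = ssg / S1
    msi = ssi / (S1 - r)
    msp = ssp / (r - 1)
    sig_g = msg
    sig_i = (msi - msg) / 2
    sig_p = (msp - msi) / (2 * nc)
    return sig_p / (sig_p + sig_i + sig_g)


class TestWeirCockerhamFst:
    def test_fixed_difference_limit(self):
        calls = [[HOMREF]] * 4 + [[HOMALT]] * 4
        m = _matrix(calls, pops=["A"] * 4 + ["B"] * 4)
        assert pk.per_locus_fst(m)["L0"] == pytest.approx(1.0)

    def test_no_differentiation_near_zero(self, rng):
        # identical frequencies, HWE genotypes, n=200/pop
        p = 0.4
        draws = rng.choice([0, 1, 2], size=(400, 1),
                           p=[(1 - p) ** 2, 2 * p * (1 - p), p**2])
        m = _matrix(draws, pops=["A"] * 200 + ["B"] * 200)
        assert abs(pk.per_locus_fst(m)["L0"]) < 0.05

    def test_matches_indicator_anova_oracle(self, rng):
        # 2-pop toys with planted genotype counts, plus random draws
        toys = [
            ([0] * 4 + [1] * 4 + [2] * 2, [2] * 6 + [1] * 3 + [0] * 1),
            ([0] * 7 + [1] * 3, [1] * 5 + [2] * 5),
        ]
        for ga, gb in toys:
            calls = np.array(ga + gb)[:, None]
            pops = ["A"] * len(ga) + ["B"] * len(gb)
            m = _matrix(calls, pops=pops)
            expected = _wc84_anova_oracle(list(calls[:, 0]), pops)
            assert pk.per_locus_fst(m)["L0"] == pytest.approx(expected, abs=1e-12)
        for _ in range(5):
            calls = rng.integers(-1, 3, size=(30, 1)).astype(np.int8)
            pops = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
            m = _matrix(calls, pops=pops)
            got = pk.per_locus_fst(m)["L0"]
            want = _wc84_anova_oracle(list(calls[:, 0]), pops)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_invariant_to_allele_relabeling(self, rng):
        calls = rng.integers(0, 3, size=(40, 6)).astype(np.int8)
        pops = ["A"] * 20 + ["B"] * 20
        m = _matrix(calls, pops=pops)
        flipped = _matrix(2 - calls, pops=pops)
        for l, v in pk.per_locus_fst(m).items():
            assert pk.per_locus_fst(flipped)[l] == pytest.approx(v, abs=1e-12)

    def test_single_population_rejected(self):
        m = _matrix([[0], [1]], pops=["A", "A"])
        with pytest.raises(UsageError):
            pk.per_locus_fst(m)


class TestPairwiseFstCI:
    def test_balding_nichols_recovery(self):
        spec = pk.SimulationSpec(
            n_loci=400, populations=[("A", 50, 0.03), ("B", 50, 0.03)],
            seed=11, freq_dist=("uniform", 0.2, 0.8),
        )
        b = pk.simulate(spec)
        (res,) = pk.pairwise_pop_fst_ci(b.matrix, min_n=15, n_boot=200, seed=1)
        assert 0.01 <= res["fst"] <= 0.05

    def test_split_halves_ci_contains_zero(self, rng):
        p = rng.uniform(0.2, 0.8, 300)
        calls = (rng.random((60, 300, 2)) < p[None, :, None]).sum(-1).astype(np.int8)
        pops = ["A"] * 30 + ["B"] * 30
        m = _matrix(calls, pops=pops)
        (res,) = pk.pairwise_pop_fst_ci(m, min_n=15, n_boot=200, seed=2)
        assert res["ci_low"] <= 0 <= res["ci_high"]

    def test_bootstrap_deterministic_under_seed(self, rng):
        calls = rng.integers(0, 3, size=(40, 50)).astype(np.int8)
        m = _matrix(calls, pops=["A"] * 20 + ["B"] * 20)
        r1 = pk.pairwise_pop_fst_ci(m, n_boot=100, seed=5)
        r2 = pk.pairwise_pop_fst_ci(m, n_boot=100, seed=5)
        assert r1 == r2

    def test_parameter_recovery_across_drift_levels(self):
        """Mean multilocus F_ST within 30% relative error of the planted F."""
        for F in (0.01, 0.05, 0.15):
            spec = pk.SimulationSpec(
                n_loci=500, populations=[("A", 50, F), ("B", 50, F)],
                seed=7, freq_dist=("uniform", 0.2, 0.8),
            )
            b = pk.simulate(spec)
            (res,) = pk.pairwise_pop_fst_ci(b.matrix, n_boot=50, seed=1)
            assert abs(res["fst"] - F) / F < 0.30


def _hwe_enumeration_oracle(n_homref, n_het, n_homalt):
    """Exact-arithmetic enumeration over heterozygote configurations."""
    n = n_homref + n_het + n_homalt
    n_a = 2 * n_homalt + n_het
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)

    def ways(h):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            Fraction(math.factorial(n),
                     math.factorial(hom_rare) * math.factorial(h) * math.factorial(hom_common))
            * 2**h
        )

    total = sum(ways(h) for h in range(rare % 2, rare + 1, 2))
    p_obs = Fraction(ways(n_het), total)
    p = sum(Fraction(ways(h), total) for h in range(rare % 2, rare + 1, 2)
            if Fraction(ways(h), total) <= p_obs)
    return float(p)


class TestHWPExactTest:
    def test_perfect_proportions(self):
        assert pk.hwe_exact_pvalue(25, 50, 25) == pytest.approx(1.0)

    def test_total_heterozygote_deficit(self):
        assert pk.hwe_exact_pvalue(50, 0, 50) < 1e-3

    @pytest.mark.parametrize("counts", [(3, 5, 2), (10, 2, 8), (0, 9, 1), (7, 7, 7)])
    def test_matches_exact_enumeration_oracle(self, counts):
        assert pk.hwe_exact_pvalue(*counts) == pytest.approx(
            _hwe_enumeration_oracle(*counts), rel=1e-9
        )

    def test_monomorphic_convention(self):
        assert pk.hwe_exact_pvalue(10, 0, 0) == 1.0

    def test_flags_only_not_removal(self):
        m = _matrix([[HOMREF]] * 10 + [[HOMALT]] * 10, pops=["A"] * 20)
        pvals, flags = pk.hwp_test(m)
        assert ("L0", "A") in flags
        assert pvals[("L0", "A")] < 0.05


class TestPrivateAlleles:
    def test_private_allele_with_copy_count(self):
        # alt allele only in group X: 3 hets + 1 homalt in X -> 5 copies? no: 2+...
        calls = [[HET], [HET], [HOMALT], [HOMREF], [HOMREF]]
        m = _matrix(calls)
        groups = {"s0": "X", "s1": "X", "s2": "X", "s3": "Y", "s4": "Y"}
        out = pk.private_alleles(m, groups)
        assert ("L0", "alt", "X", 4) in out

    def test_shared_allele_not_private(self):
        m = _matrix([[HET], [HET]])
        out = pk.private_alleles(m, {"s0": "X", "s1": "Y"})
        assert out == []

    def test_planted_private_allele_recovered(self, rng):
        calls = np.zeros((30, 20), dtype=np.int8)
        calls[:, :] = rng.choice([0, 1], size=(30, 20))  # ref/het everywhere
        calls[calls == 1] = 1
        calls[5, 7] = HOMALT  # only alt copies at L7 live in group X
        calls[:, 7][calls[:, 7] == HET] = HOMREF
        calls[5, 7] = HOMALT
        m = _matrix(calls)
        groups = {f"s{i}": ("X" if i < 10 else "Y") for i in range(30)}
        out = pk.private_alleles(m, groups)
        assert ("L7", "alt", "X", 2) in out


class TestRitland:
    def test_hand_evaluated_values(self):
        # both homref at p_alt=0.5 -> r = 2*[(1*1)/0.5 - 1]/1 = 2
        m = _matrix([[HOMREF], [HOMREF]])
        (pair,) = pk.ritland_relatedness(m, {"L0": 0.5})
        assert pair.r == pytest.approx(2.0)
        # both het at p=0.5 -> 2*[(0.25/0.5)+(0.25/0.5) - 1]/1 = 0
        m = _matrix([[HET], [HET]])
        (pair,) = pk.ritland_relatedness(m, {"L0": 0.5})
        assert pair.r == pytest.approx(0.0)

    def test_symmetry_and_shared_locus_count(self, random_matrix):
        pairs = pk.ritland_relatedness(random_matrix)
        seen = {(p.sample_a, p.sample_b) for p in pairs}
        assert all((b, a) not in seen for a, b in seen)
        for p in pairs:
            assert p.n_loci_used <= random_matrix.n_loci

    def test_unrelated_pairs_unbiased(self):
        spec = pk.SimulationSpec(
            n_loci=500, populations=[("P", 40, 0.0)], seed=13,
            freq_dist=("uniform", 0.1, 0.5),
        )
        b = pk.simulate(spec)
        freqs = dict(zip(b.matrix.locus_ids, b.ancestral_freqs))
        pairs = pk.ritland_relatedness(b.matrix, freqs)
        mean_r = np.mean([p.r for p in pairs])
        assert abs(mean_r) < 0.02

    def test_fullsib_relatedness_elevated(self):
        spec = pk.SimulationSpec(
            n_loci=500, populations=[("P", 20, 0.0)], seed=3,
            families=[("P_1", "P_2", 10)], freq_dist=("uniform", 0.1, 0.5),
        )
        b = pk.simulate(spec)
        freqs = dict(zip(b.matrix.locus_ids, b.ancestral_freqs))
        pairs = pk.ritland_relatedness(b.matrix, freqs)
        fs = [p.r for p in pairs
              if p.sample_a.startswith("F") and p.sample_b.startswith("F")]
        assert np.mean(fs) > 0.3

    def test_zero_shared_loci_undefined(self):
        m = _matrix([[HET, MISSING], [MISSING, HET]])
        (pair,) = pk.ritland_relatedness(m, {"L0": 0.5, "L1": 0.5})
        assert math.isnan(pair.r) and pair.n_loci_used == 0


class TestPurgeFirstDegree:
    def test_one_of_pair_removed(self):
        pairs = [pk.RelatednessPair("A", "B", 0.4, 100)]
        retained = pk.purge_first_degree(pairs)
        assert len(retained) == 1

    def test_nothing_above_threshold(self):
        pairs = [pk.RelatednessPair("A", "B", 0.2, 100)]
        assert pk.purge_first_degree(pairs) == {"A", "B"}

    def test_postcondition_on_simulated_families(self):
        spec = pk.SimulationSpec(
            n_loci=400, populations=[("P", 12, 0.0)], seed=5,
            families=[(f"P_{2 * i + 1}", f"P_{2 * i + 2}", 6) for i in range(5)],
            freq_dist=("uniform", 0.1, 0.5),
        )
        b = pk.simulate(spec)
        freqs = dict(zip(b.matrix.locus_ids, b.ancestral_freqs))
        pairs = pk.ritland_relatedness(b.matrix, freqs)
        pop_of = {s: "one" for s in b.matrix.sample_ids}
        retained = pk.purge_first_degree(pairs, 0.26, population_of=pop_of)
        for p in pairs:
            if p.sample_a in retained and p.sample_b in retained and np.isfinite(p.r):
                assert p.r <= 0.26

    def test_cross_population_pairs_ignored(self):
        pairs = [pk.RelatednessPair("A", "B", 0.9, 100)]
        retained = pk.purge_first_degree(
            pairs, population_of={"A": "X", "B": "Y"}
        )
        assert retained == {"A", "B"}


class TestPCA:
    def test_two_clusters_separate_on_pc1(self):
        calls = np.vstack([np.zeros((5, 20)), np.full((5, 20), 2)]).astype(np.int8)
        m = _matrix(calls)
        with pytest.warns(UserWarning, match="non-degenerate components"):
            res = pk.pca_dosage(m, 2)  # rank-1 data: only PC1 exists
        assert res.explained_var_frac[0] > 0.99
        side = np.sign(res.scores[:, 0])
        assert len(set(side[:5])) == 1 and side[0] != side[-1]

    def test_duplicate_samples_identical_scores(self, random_matrix):
        dup = pk.GenotypeMatrix(
            random_matrix.sample_ids + ["dup"],
            random_matrix.locus_ids,
            np.vstack([random_matrix.calls, random_matrix.calls[:1]]),
        )
        res = pk.pca_dosage(dup, 3)
        np.testing.assert_allclose(res.scores[0], res.scores[-1], atol=1e-9)

    def test_matches_svd_reference(self, rng):
        calls = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
        m = _matrix(calls)
        res = pk.pca_dosage(m, 4)
        X = calls.astype(float)
        X = X - X.mean(axis=0)
        _, S, _ = np.linalg.svd(X, full_matrices=False)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        ref_scores = U[:, :4] * s[:4]
        # agreement up to per-component sign
        for c in range(4):
            assert (
                np.allclose(res.scores[:, c], ref_scores[:, c], atol=1e-8)
                or np.allclose(res.scores[:, c], -ref_scores[:, c], atol=1e-8)
            )
        np.testing.assert_allclose(
            res.explained_var_frac, (S[:4] ** 2) / (S**2).sum(), atol=1e-12
        )

    def test_too_few_samples_rejected(self):
        m = _matrix(np.zeros((3, 10), dtype=np.int8))
        with pytest.raises(UsageError):
            pk.pca_dosage(m)
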