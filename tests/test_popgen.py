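import itertools
import math

import numpy as np
import pytest

from serialsfs.popgen import (
    GenotypeMatrix,
    apply_standard_filters,
    filter_individuals_by_missingness,
    filter_loci_by_presence,
    first_snp_per_contig,
    heterozygosity_stats,
    hwe_exact_pvalue,
    hwp_filter,
    pi_bootstrap_ci,
    read_cohort_table,
    read_vcf,
    remove_het_outlier_individuals,
    windowed_pi,
    write_vcf,
)
from serialsfs.synth import generate_filter_testset


def matrix(calls, contigs=None, positions=None, cohorts=None):
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_loc = calls.shape
    return GenotypeMatrix(
        calls,
        tuple(f"s{i}" for i in range(n_ind)),
        tuple(contigs or (f"ctg{j}" for j in range(n_loc))),
        tuple(positions or (1 for _ in range(n_loc))),
        tuple(cohorts) if cohorts else None,
    )


class TestMissingnessFilter:
    def test_boundary_is_strict(self):
        calls = [
            [-1, -1, -1, 0, 0],  # 60% missing: out
            [-1, -1, 0, 0, 0, ],  # 40%: kept
        ]
        calls = np.array(calls, dtype=np.int8)
        g = matrix(calls)
        out = filter_individuals_by_missingness(g)
        assert out.samples == ("s1",)

    def test_exactly_half_retained(self):
        calls = np.array([[-1, -1, 0, 0], [0, 0, 0, 0]], dtype=np.int8)
        out = filter_individuals_by_missingness(matrix(calls))
        assert out.n_individuals == 2

    def test_planted_matrix_survivors(self, rng):
        calls = rng.integers(0, 3, size=(10, 10)).astype(np.int8)
        miss = rng.random((10, 10)) < 0.2
        calls[miss] = -1
        g = matrix(calls)
        out = filter_individuals_by_missingness(g, 0.25)
        expect = [
            f"s{i}" for i in range(10) if (calls[i] == -1).mean() <= 0.25
        ]
        assert list(out.samples) == expect


class TestPresenceFilter:
    def test_boundaries(self):
        # 20 individuals: 1 missing -> 95% kept; 2 missing -> 90% dropped
        calls = np.zeros((20, 2), dtype=np.int8)
        calls[0, 0] = -1
        calls[0, 1] = -1
        calls[1, 1] = -1
        out = filter_loci_by_presence(matrix(calls))
        assert out.n_loci == 1 and out.contigs == ("ctg0",)


class TestFirstSnpPerContig:
    def test_keeps_smallest_position(self):
        g = matrix(
            np.zeros((2, 3), dtype=np.int8),
            contigs=["A", "A", "B"],
            positions=[50, 10, 7],
        )
        out = first_snp_per_contig(g)
        assert set(zip(out.contigs, out.positions)) == {("A", 10), ("B", 7)}

    def test_order_invariant(self, rng):
        n = 12
        contigs = [f"c{j % 4}" for j in range(n)]
        positions = list(rng.choice(1000, size=n, replace=False))
        calls = np.zeros((2, n), dtype=np.int8)
        g = first_snp_per_contig(matrix(calls, contigs, positions))
        perm = rng.permutation(n)
        g2 = first_snp_per_contig(
            matrix(calls[:, perm], list(np.array(contigs)[perm]),
                   [positions[i] for i in perm])
        )
        assert set(zip(g.contigs, g.positions)) == set(
            zip(g2.contigs, g2.positions)
        )


class TestHetOutliers:
    def test_single_extreme_individual_removed(self):
        # 19 individuals at het proportion 0.1, one at 0.9
        calls = np.zeros((20, 10), dtype=np.int8)
        calls[:19, 0] = 1
        calls[19, :9] = 1
        g = matrix(calls)
        out = remove_het_outlier_individuals(g)
        assert "s19" not in out.samples and out.n_individuals == 19

    def test_uniform_proportions_none_removed(self):
        calls = np.tile(np.array([1, 0, 0, 0], dtype=np.int8), (6, 1))
        assert remove_het_outlier_individuals(matrix(calls)).n_individuals == 6

    def test_single_individual_kept(self):
        calls = np.ones((1, 4), dtype=np.int8)
        assert remove_het_outlier_individuals(matrix(calls)).n_individuals == 1


def exact_pvalue_bruteforce(n_het, n_hom_alt, n_hom_ref):
    """Enumerate all genotype configurations with the same allele counts."""
    n = n_het + n_hom_alt + n_hom_ref
    n_alt = 2 * n_hom_alt + n_het
    probs = {}
    for h in range(min(n_alt, 2 * n - n_alt) + 1):
        if (n_alt - h) % 2:
            continue
        aa = (n_alt - h) // 2
        rr = n - h - aa
        if aa < 0 or rr < 0:
            continue
        probs[h] = (
            math.factorial(n)
            / (math.factorial(h) * math.factorial(aa) * math.factorial(rr))
            * 2**h
            * math.factorial(n_alt)
            * math.factorial(2 * n - n_alt)
            / math.factorial(2 * n)
        )
    tot = sum(probs.values())
    p_obs = probs[n_het] / tot
    return sum(p for p in probs.values() if p / tot <= p_obs * (1 + 1e-12)) / tot


class TestHwp:
    def test_perfect_proportions_retained(self):
        col = np.array([1] * 50 + [0] * 25 + [2] * 25, dtype=np.int8)
        g = matrix(col[:, None])
        assert hwp_filter(g).n_loci == 1

    def test_no_heterozygotes_removed(self):
        col = np.array([0] * 50 + [2] * 50, dtype=np.int8)
        g = matrix(col[:, None])
        assert hwe_exact_pvalue(0, 50, 50) < 1e-3
        assert hwp_filter(g).n_loci == 0

    def test_monomorphic_retained_untested(self):
        g = matrix(np.zeros((30, 1), dtype=np.int8))
        assert hwp_filter(g).n_loci == 1

    @pytest.mark.parametrize(
        "het,alt,ref",
        [(5, 2, 13), (0, 3, 7), (10, 0, 0), (4, 4, 4), (1, 9, 0)],
    )
    def test_matches_enumeration_oracle(self, het, alt, ref):
        assert hwe_exact_pvalue(het, alt, ref) == pytest.approx(
            exact_pvalue_bruteforce(het, alt, ref), rel=1e-9
        )


class TestHeterozygosityStats:
    def test_all_heterozygote_locus(self):
        g = matrix(np.ones((10, 1), dtype=np.int8))
        per_locus, means = heterozygosity_stats(g, by_cohort=False)
        row = per_locus.iloc[0]
        assert row.h_obs == 1.0
        assert row.h_exp == pytest.approx(0.5)
        assert row.f_is == pytest.approx(-1.0)

    def test_no_heterozygotes(self):
        col = np.array([0] * 6 + [2] * 4, dtype=np.int8)
        per_locus, _ = heterozygosity_stats(matrix(col[:, None]), by_cohort=False)
        row = per_locus.iloc[0]
        # n=10, p=0.4: Hexp = 10/9 * (1 - .16 - .36) = 0.5333
        assert row.h_obs == 0.0
        assert row.h_exp == pytest.approx(0.53333333, abs=1e-8)
        assert row.f_is == pytest.approx(1.0)

    def test_monomorphic_locus_excluded_from_fis_mean(self):
        calls = np.array([[0, 1], [0, 1], [0, 0], [0, 2]], dtype=np.int8)
        per_locus, means = heterozygosity_stats(matrix(calls), by_cohort=False)
        assert per_locus.h_exp.iloc[0] == 0.0
        assert np.isnan(per_locus.f_is.iloc[0])
        assert means.f_is.iloc[0] == pytest.approx(
            per_locus.f_is.dropna().mean()
        )

    def test_allele_label_swap_invariance(self, rng):
        calls = rng.integers(0, 3, size=(12, 8)).astype(np.int8)
        g1 = matrix(calls)
        g2 = matrix(2 - calls)
        _, m1 = heterozygosity_stats(g1, by_cohort=False)
        _, m2 = heterozygosity_stats(g2, by_cohort=False)
        assert m1.h_exp.iloc[0] == pytest.approx(m2.h_exp.iloc[0], abs=1e-12)


class TestWindowedPi:
    def test_single_snp_window(self):
        # 2 diploids = 4 chromosomes, alt count 1: pi_site = 2*1*3/(4*3) = 0.5
        calls = np.array([[1], [0]], dtype=np.int8)
        df = windowed_pi(matrix(calls), by_cohort=False)
        assert df.pi.iloc[0] == pytest.approx(0.5 / 140)

    def test_pairwise_difference_oracle(self, rng):
        # pi at a site equals the mean pairwise difference among chromosomes
        calls = rng.integers(0, 3, size=(5, 6)).astype(np.int8)
        g = matrix(calls, contigs=["c"] * 6, positions=list(range(1, 7)))
        df = windowed_pi(g, window=140, by_cohort=False)
        total = 0.0
        for j in range(6):
            hap = []
            for i in range(5):
                v = calls[i, j]
                hap += [1, 1] if v == 2 else ([1, 0] if v == 1 else [0, 0])
            diffs = [
                a != b for a, b in itertools.combinations(hap, 2)
            ]
            total += float(np.mean(diffs))
        assert df.pi.iloc[0] == pytest.approx(total / 140, abs=1e-12)

    def test_two_identical_snps_double_pi(self):
        one = matrix(np.array([[1], [0]], dtype=np.int8), contigs=["c"], positions=[1])
        two = matrix(
            np.array([[1, 1], [0, 0]], dtype=np.int8),
            contigs=["c", "c"],
            positions=[1, 2],
        )
        p1 = windowed_pi(one, by_cohort=False).pi.iloc[0]
        p2 = windowed_pi(two, by_cohort=False).pi.iloc[0]
        assert p2 == pytest.approx(2 * p1)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            windowed_pi(matrix(np.zeros((2, 1), dtype=np.int8)), window=0)


class TestPiBootstrap:
    def test_degenerate_matrix_zero_width(self):
        calls = np.ones((4, 3), dtype=np.int8)  # identical individuals
        ci = pi_bootstrap_ci(matrix(calls), reps=50, seed=1, by_cohort=False)
        lo, hi = ci["all"]
        assert lo == pytest.approx(hi)

    def test_seed_reproducible(self, rng):
        calls = rng.integers(0, 3, size=(8, 5)).astype(np.int8)
        g = matrix(calls)
        a = pi_bootstrap_ci(g, reps=40, seed=9, by_cohort=False)
        b = pi_bootstrap_ci(g, reps=40, seed=9, by_cohort=False)
        assert a == b


class TestFilterChain:
    def test_planted_survivor_sets_recovered_exactly(self):
        g, truth = generate_filter_testset(seed=3)
        stages = truth.stage_survivors
        g1 = filter_individuals_by_missingness(g)
        assert list(g1.samples) == stages["individual_missingness"]
        g2 = filter_loci_by_presence(g1)
        assert [f"{c}:{p}" for c, p in zip(g2.contigs, g2.positions)] == stages[
            "locus_presence"
        ]
        g3 = first_snp_per_contig(g2)
        assert [f"{c}:{p}" for c, p in zip(g3.contigs, g3.positions)] == stages[
            "first_snp_per_contig"
        ]
        g4 = remove_het_outlier_individuals(g3)
        assert list(g4.samples) == stages["het_outliers"]
        g5 = hwp_filter(g4)
        assert [f"{c}:{p}" for c, p in zip(g5.contigs, g5.positions)] == stages[
            "hwp"
        ]
        # one-call chain agrees
        chained = apply_standard_filters(g)
        assert list(chained.samples) == truth.surviving_individuals
        assert [
            f"{c}:{p}" for c, p in zip(chained.contigs, chained.positions)
        ] == truth.surviving_loci

    def test_filters_are_subsets(self):
        g, _ = generate_filter_testset(seed=5)
        out = apply_standard_filters(g)
        assert set(out.samples) <= set(g.samples)
        assert set(zip(out.contigs, out.positions)) <= set(
            zip(g.contigs, g.positions)
        )


class TestVcfRoundtrip:
    def test_write_read_preserves_genotypes(self, tmp_path, rng):
        calls = rng.integers(-1, 3, size=(6, 9)).astype(np.int8)
        g = matrix(
            calls,
            contigs=[f"c{j // 3}" for j in range(9)],
            positions=[10 + 5 * (j % 3) for j in range(9)],
            cohorts=["x"] * 3 + ["y"] * 3,
        )
        vcf = tmp_path / "t.vcf"
        write_vcf(g, vcf)
        cohort_tsv = tmp_path / "c.tsv"
        cohort_tsv.write_text(
            "sample\tcohort\n"
            + "\n".join(f"{s}\t{c}" for s, c in zip(g.samples, g.cohorts))
            + "\n"
        )
        back = read_vcf(vcf, read_cohort_table(cohort_tsv))
        np.testing.assert_array_equal(back.calls, g.calls)
        assert back.samples == g.samples
        assert back.cohorts == g.cohorts
        assert back.contigs == g.contigs
        assert back.positions == g.positions
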