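"""Uniqueness, polymorphism, region and Poisson-stability filtering."""

import numpy as np
import pytest

from niptkmer.kmer_core import KmerCountList, KmerSet, enumerate_kmers
from niptkmer.list_builder import (
    GenomicRegionSet,
    PoissonFilterParams,
    Region,
    Variant,
    VariantSet,
    build_initial_lists,
    filter_nonunique,
    finalize_lists,
    poisson_bounds,
    polymorphic_kmers,
    region_kmers,
    stable_kmers_for_control,
)
from conftest import random_dna
from naive import naive_canonical, naive_enumerate, naive_poisson_ppf

K = 11


def genome_multiplicity(genome: dict, k: int) -> dict[str, int]:
    """Oracle: canonical k-mer -> genome-wide occurrence count."""
    total: dict[str, int] = {}
    for seq in genome.values():
        for km, c in naive_enumerate(seq, k).items():
            total[km] = total.get(km, 0) + c
    return total


class TestInitialLists:
    def test_matches_naive_enumeration(self, rng):
        genome = {"chrA": random_dna(rng, 300), "chrB": random_dna(rng, 200)}
        lists = build_initial_lists(genome, K)
        for chrom, seq in genome.items():
            assert lists[chrom].to_dict() == naive_enumerate(seq, K)

    def test_window_count_bound(self, rng):
        genome = {"chr1": random_dna(rng, 100), "chr2": random_dna(rng, 100)}
        lists = build_initial_lists(genome, 25)
        for lst in lists.values():
            assert len(lst) <= 76

    def test_all_n_chromosome_empty(self):
        lists = build_initial_lists({"chrN": "N" * 100}, K)
        assert len(lists["chrN"]) == 0

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError, match="empty genome"):
            build_initial_lists({}, K)


class TestUniquenessFilter:
    def test_matches_multiplicity_oracle_with_planted_duplication(self, rng):
        chrA = random_dna(rng, 400)
        block = chrA[100:160]  # 60 bp duplicated block
        chrA = chrA[:300] + block + chrA[360:]
        genome = {"chrA": chrA, "chrB": random_dna(rng, 250)}
        unique = filter_nonunique(build_initial_lists(genome, K))
        mult = genome_multiplicity(genome, K)
        for chrom, seq in genome.items():
            expected = {
                km for km in naive_enumerate(seq, K) if mult[km] == 1
            }
            assert set(unique[chrom].to_strings()) == expected
        # every k-mer fully inside the duplicated block is gone
        for i in range(len(block) - K + 1):
            km = naive_canonical(block[i : i + K])
            assert km not in unique["chrA"]

    def test_cross_chromosome_duplicate_removed_from_both(self, rng):
        shared = random_dna(rng, 40)
        genome = {"chr1": random_dna(rng, 80) + shared, "chr2": shared + random_dna(rng, 80)}
        unique = filter_nonunique(build_initial_lists(genome, K))
        for i in range(len(shared) - K + 1):
            km = naive_canonical(shared[i : i + K])
            assert km not in unique["chr1"]
            assert km not in unique["chr2"]

    def test_within_chromosome_repeat_removed(self):
        # k-mer appearing twice on one chromosome is removed
        seq = "ACGTACGTACG"  # contains repeated 4-mers
        unique = filter_nonunique(build_initial_lists({"c": seq}, 4))
        mult = genome_multiplicity({"c": seq}, 4)
        assert set(unique["c"].to_strings()) == {km for km, c in mult.items() if c == 1}


class TestPolymorphicKmers:
    def test_single_snp_window_hand_enumeration(self):
        # 10 bp toy sequence, SNP A->G at 1-based position 5, k=3
        seq = "ACGTATGCAT"
        genome = {"c": seq}
        variants = VariantSet([Variant("c", 5, "A", ("G",), 0.2)])
        got = set(polymorphic_kmers(genome, variants, k=3).to_strings())
        alt = seq[:4] + "G" + seq[5:]
        expected = set()
        for hap in (seq, alt):
            window = hap[max(0, 4 - 2) : 5 + 2]  # pos0 4, +/- (k-1)
            for i in range(len(window) - 2):
                expected.add(naive_canonical(window[i : i + 3]))
        assert got == expected

    def test_low_maf_variant_contributes_nothing(self):
        genome = {"c": "ACGTATGCAT"}
        variants = VariantSet([Variant("c", 5, "A", ("G",), 0.005)])
        assert len(polymorphic_kmers(genome, variants, k=3, maf_min=0.01)) == 0

    def test_unknown_maf_treated_as_common(self):
        genome = {"c": "ACGTATGCAT"}
        variants = VariantSet([Variant("c", 5, "A", ("G",), None)])
        assert len(polymorphic_kmers(genome, variants, k=3)) > 0

    def test_zero_variants_empty(self):
        assert len(polymorphic_kmers({"c": "ACGTACGT"}, VariantSet([]), k=3)) == 0

    def test_ref_mismatch_names_variant(self):
        genome = {"c": "ACGTATGCAT"}
        variants = VariantSet([Variant("c", 5, "C", ("G",), 0.2)])
        with pytest.raises(ValueError, match="c:5"):
            polymorphic_kmers(genome, variants, k=3)

    def test_insertion_allele_kmers_included(self):
        seq = "ACGTATGCAT"
        genome = {"c": seq}
        variants = VariantSet([Variant("c", 5, "A", ("ATT",), 0.3)])
        got = set(polymorphic_kmers(genome, variants, k=3).to_strings())
        alt_window = (seq[2:4] + "ATT" + seq[5:7])
        for i in range(len(alt_window) - 2):
            assert naive_canonical(alt_window[i : i + 3]) in got

    def test_haplotype_cap_falls_back_to_reference_window(self, rng):
        seq = random_dna(rng, 40)
        # dense cluster of SNPs inside one window
        variants = VariantSet(
            [Variant("c", p, seq[p - 1], ("ACGT".replace(seq[p - 1], "")[0],), 0.3)
             for p in range(10, 16)]
        )
        capped = polymorphic_kmers({"c": seq}, variants, k=7, max_haplotypes=4)
        full = polymorphic_kmers({"c": seq}, variants, k=7, max_haplotypes=4096)
        # the fallback only contains reference k-mers, so it is smaller
        assert len(capped) < len(full)
        capped_strings = set(capped.to_strings())
        for i in range(len(seq) - 6):
            km = naive_canonical(seq[i : i + 7])
            # windows covering a variant position start in [p0 - (k-1), p0]
            if any((p - 1) - 6 <= i <= (p - 1) for p in range(10, 16)):
                assert km in capped_strings


class TestRegionKmers:
    def test_overlap_arithmetic_oracle(self, rng):
        seq = random_dna(rng, 100)
        regions = GenomicRegionSet([Region("c", 40, 50)])  # 10 bp region, k=5
        got = set(region_kmers({"c": seq}, regions, k=5).to_strings())
        expected = {
            naive_canonical(seq[i : i + 5])
            for i in range(len(seq) - 4)
            if i < 50 and i + 5 > 40  # window overlaps region by >= 1 base
        }
        assert got == expected
        assert len(expected) <= 14

    def test_whole_chromosome_region(self, rng):
        seq = random_dna(rng, 60)
        regions = GenomicRegionSet([Region("c", 0, 60)])
        got = region_kmers({"c": seq}, regions, k=5)
        assert set(got.to_strings()) == set(naive_enumerate(seq, 5))

    def test_empty_region_set(self):
        assert len(region_kmers({"c": "ACGTACGT"}, GenomicRegionSet([]), k=3)) == 0

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chrZ"):
            region_kmers({"c": "ACGTACGT"}, GenomicRegionSet([Region("chrZ", 0, 4)]), k=3)

    def test_degenerate_region_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            Region("c", 5, 5)


class TestPoissonBounds:
    @pytest.mark.parametrize("lam", [0.5, 1.0, 4.0, 17.5, 30.0])
    def test_matches_term_summation_oracle(self, lam):
        low, high = poisson_bounds(lam, 0.01, 0.99)
        assert low == naive_poisson_ppf(0.01, lam)
        assert high == naive_poisson_ppf(0.99, lam)

    def test_tiny_p_low_gives_zero(self):
        low, _ = poisson_bounds(4.0, 1e-12, 0.99)
        assert low == 0

    def test_monotone_in_lambda(self):
        lows, highs = zip(*(poisson_bounds(lam, 0.01, 0.99) for lam in np.linspace(0.5, 40, 60)))
        assert all(a <= b for a, b in zip(lows, lows[1:]))
        assert all(a <= b for a, b in zip(highs, highs[1:]))

    @pytest.mark.parametrize("p_low,p_high", [(0.0, 0.99), (0.5, 0.5), (0.01, 1.0), (-0.1, 0.9)])
    def test_invalid_probabilities_rejected(self, p_low, p_high):
        with pytest.raises(ValueError):
            poisson_bounds(4.0, p_low, p_high)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            poisson_bounds(0.0)


def counts_list(k: int, kmers: list[str], counts: np.ndarray) -> KmerCountList:
    return KmerCountList.from_dict(k, dict(zip(kmers, counts.astype(int).tolist())))


class TestStabilityFilter:
    def make_candidates(self, rng, n=4000):
        kmers = set()
        while len(kmers) < n:
            kmers.add(naive_canonical(random_dna(rng, K)))
        return sorted(kmers)[:n]

    def test_retention_matches_poisson_interval_mass(self, rng):
        lam = 17.5
        kmers = self.make_candidates(rng)
        counts = rng.poisson(lam, size=len(kmers))
        present = counts > 0
        control = counts_list(K, [km for km, p in zip(kmers, present) if p], counts[present])
        candidates = KmerSet.from_strings(K, kmers)
        stable = stable_kmers_for_control(control, candidates, PoissonFilterParams())
        lam_hat = counts[present].mean()
        low, high = poisson_bounds(lam_hat, 0.01, 0.99)
        from scipy.stats import poisson as pois

        mass = pois.cdf(high, lam_hat) - pois.cdf(low - 1, lam_hat)
        frac = len(stable) / len(candidates)
        se = np.sqrt(mass * (1 - mass) / len(candidates))
        assert abs(frac - mass) <= 3 * se

    def test_two_copy_region_rejected(self, rng):
        # deep control (25x): a duplicated region's counts ~ 2*lambda fall
        # almost entirely above the 0.99 quantile of Poisson(lambda)
        lam = 25.0
        kmers = self.make_candidates(rng, 2000)
        counts = rng.poisson(lam, size=len(kmers))
        dup = slice(0, 200)  # planted CNV
        counts[dup] = rng.poisson(2 * lam, size=200)
        control = counts_list(K, kmers, np.maximum(counts, 1))
        candidates = KmerSet.from_strings(K, kmers)
        stable = stable_kmers_for_control(control, candidates, PoissonFilterParams(lam=lam))
        dup_kept = sum(km in stable for km in kmers[dup])
        normal_kept = sum(km in stable for km in kmers[200:]) / (len(kmers) - 200)
        assert dup_kept / 200 < 0.1
        assert normal_kept > 0.9

    def test_absent_kmer_rejected_when_low_positive(self, rng):
        kmers = self.make_candidates(rng, 100)
        control = counts_list(K, kmers[:50], np.full(50, 20))
        candidates = KmerSet.from_strings(K, kmers)
        stable = stable_kmers_for_control(control, candidates, PoissonFilterParams(lam=20.0))
        assert len(stable) == 50

    def test_empty_candidates_rejected(self, rng):
        control = counts_list(K, ["A" * K], np.array([5]))
        with pytest.raises(ValueError, match="empty"):
            stable_kmers_for_control(control, KmerSet(K), PoissonFilterParams())


class TestFinalize:
    def setup_sets(self, rng):
        genome = {"chr1": random_dna(rng, 400), "chr2": random_dna(rng, 300)}
        unique = filter_nonunique(build_initial_lists(genome, K))
        return genome, unique

    def test_final_lists_disjoint_and_exclude_filters(self, rng):
        genome, unique = self.setup_sets(rng)
        poly = KmerSet.from_codes(K, unique["chr1"].codes[:20])
        reg = KmerSet.from_codes(K, unique["chr2"].codes[:20])
        final = finalize_lists(unique, poly, reg, per_control_stable=[], strict=False)
        assert final["chr1"].kmers.isdisjoint(final["chr2"].kmers)
        for ckl in final.values():
            assert ckl.kmers.isdisjoint(poly)
            assert ckl.kmers.isdisjoint(reg)
            assert ckl.L_c == len(ckl.kmers)

    def test_subtractions_commute(self, rng):
        _, unique = self.setup_sets(rng)
        poly = KmerSet.from_codes(K, unique["chr1"].codes[5:25])
        reg = KmerSet.from_codes(K, unique["chr1"].codes[15:40])
        a = finalize_lists(unique, poly, reg, strict=False)
        b = finalize_lists(unique, reg, poly, strict=False)
        for chrom in unique:
            assert a[chrom].kmers == b[chrom].kmers

    def test_more_controls_never_grow_lists(self, rng):
        _, unique = self.setup_sets(rng)
        stable1 = {c: KmerSet.from_codes(K, s.codes[::2]) for c, s in unique.items()}
        stable2 = {c: KmerSet.from_codes(K, s.codes[::3]) for c, s in unique.items()}
        one = finalize_lists(unique, per_control_stable=[stable1])
        two = finalize_lists(unique, per_control_stable=[stable1, stable2])
        for chrom in unique:
            assert two[chrom].L_c <= one[chrom].L_c
            assert len(two[chrom].kmers - one[chrom].kmers) == 0

    def test_empty_final_list_is_error(self, rng):
        _, unique = self.setup_sets(rng)
        everything = unique["chr1"] | unique["chr2"]
        with pytest.raises(ValueError, match="empty"):
            finalize_lists(unique, polymorphic=everything, strict=False)

    def test_zero_controls_requires_strict_false(self, rng):
        _, unique = self.setup_sets(rng)
        with pytest.raises(ValueError, match="control"):
            finalize_lists(unique)
        final = finalize_lists(unique, strict=False)
        for chrom in unique:
            assert final[chrom].kmers == unique[chrom]
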