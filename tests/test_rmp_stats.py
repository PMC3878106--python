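"""Hypergeometric association test, Bonferroni, shuffling null, Spearman."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from msatpair.rmp_core import RMPFamily, adjacent_pairs, group_rmp_families
from msatpair.rmp_stats import (
    AssociationResult,
    HypergeomCounts,
    association_counts,
    hypergeom_tail,
    shuffle_and_sample,
    significant_fraction,
    spearman,
)
from msatpair.rmp_stats import test_all_families as run_family_tests
from msatpair.ssr_scan import GenomeSequence, scan_genome
from msatpair.synthetic_data import GenomeBuilder, random_genome

from test_rmp_core import mk_pair


def subset_enumeration_tail(n, n1, n2, n3):
    """Independent oracle: enumerate every n2-subset of n items of which n1
    are 'successes' and count subsets with >= n3 successes."""
    items = [1] * n1 + [0] * (n - n1)
    hits = total = 0
    for combo in itertools.combinations(range(n), n2):
        total += 1
        if sum(items[i] for i in combo) >= n3:
            hits += 1
    return hits / total


def comb_sum_tail(n, n1, n2, n3):
    """Exact integer-arithmetic tail sum (independent of scipy)."""
    num = sum(
        math.comb(n1, k) * math.comb(n - n1, n2 - k)
        for k in range(n3, min(n1, n2) + 1)
    )
    return num / math.comb(n, n2)


class TestAssociationCounts:
    def _pairs(self):
        # 10 pairs: 4 at distance 79, of which 2 have motif pair (AC, AT);
        # one extra (AC, AT) pair at a different distance
        pairs = []
        for i in range(2):
            pairs.append(mk_pair("c", i * 1000 + 1, i * 1000 + 20,
                                 i * 1000 + 100, i * 1000 + 130))  # d=79, (AC,AT)
        for i in range(2, 4):
            pairs.append(mk_pair("c", i * 1000 + 1, i * 1000 + 20,
                                 i * 1000 + 100, i * 1000 + 130, "A", "AAG"))  # d=79
        pairs.append(mk_pair("c", 9001, 9020, 9500, 9530))  # (AC,AT), d != 79
        for i in range(5, 10):
            pairs.append(mk_pair("c", i * 1000 + 1, i * 1000 + 20,
                                 i * 1000 + 300, i * 1000 + 330, "A", "C"))
        return pairs

    def test_direct_counting(self):
        pairs = self._pairs()
        fam = RMPFamily(("AC", "AT"), 79, tuple(pairs[:2]))
        c = association_counts(fam, pairs)
        assert (c.n, c.n1, c.n2, c.n3) == (10, 4, 3, 2)

    def test_n2_equals_n3_when_combo_unique_to_distance(self):
        pairs = self._pairs()[:4]
        fam = RMPFamily(("AC", "AT"), 79, tuple(pairs[:2]))
        c = association_counts(fam, pairs)
        assert c.n2 == c.n3 == 2

    def test_single_scaffold_pair_count_is_loci_minus_one(self):
        builder = GenomeBuilder([random_genome(60_000, 0.5, 3, "s")], 4)
        for motif, d in (("AC", 100), ("AAG", 250)):
            builder.plant_family(("A", motif), d, 2)
        loci = scan_genome(builder.sequences())
        pairs = adjacent_pairs(loci)
        assert len(pairs) == len(loci) - 1


class TestHypergeomTail:
    def test_derived_example(self):
        assert hypergeom_tail(HypergeomCounts(10, 4, 3, 2)) == pytest.approx(40 / 120, abs=1e-12)

    def test_zero_overlap_gives_one(self):
        assert hypergeom_tail(HypergeomCounts(10, 4, 3, 0)) == 1.0

    def test_all_pairs_same_distance_gives_one(self):
        assert hypergeom_tail(HypergeomCounts(10, 10, 3, 3)) == 1.0

    def test_matches_subset_enumeration_small_n(self):
        for n in (4, 6, 8):
            for n1 in range(n + 1):
                for n2 in range(n + 1):
                    for n3 in range(min(n1, n2) + 1):
                        expected = subset_enumeration_tail(n, n1, n2, n3)
                        got = hypergeom_tail(HypergeomCounts(n, n1, n2, n3))
                        assert got == pytest.approx(expected, abs=1e-9), (n, n1, n2, n3)

    def test_monotone_decreasing_in_n3(self):
        vals = [hypergeom_tail(HypergeomCounts(40, 12, 9, k)) for k in range(10)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_pmf_sums_to_one(self):
        n, n1, n2 = 25, 9, 11
        total = sum(
            comb_sum_tail(n, n1, n2, k) - comb_sum_tail(n, n1, n2, k + 1)
            for k in range(min(n1, n2) + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_large_population_stability(self):
        p = hypergeom_tail(HypergeomCounts(1_000_000, 50, 40, 5))
        assert 0.0 < p < 1e-10  # far-tail value, finite and positive

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            HypergeomCounts(10, 4, 3, 5)
        with pytest.raises(ValueError):
            HypergeomCounts(5, 7, 2, 1)


class TestTestAllFamilies:
    def _planted(self, seed=11):
        builder = GenomeBuilder([random_genome(2_000_000, 0.5, seed, "g")], seed + 1)
        builder.plant_family(("AC", "AAT"), 138, 20)
        builder.plant_family(("A", "AG"), 420, 2)
        loci = scan_genome(builder.sequences())
        pairs = adjacent_pairs(loci)
        return group_rmp_families(pairs), pairs

    def test_single_family_unadjusted(self):
        fams, pairs = self._planted()
        res = run_family_tests(fams[:1], pairs)
        assert res[0].p_adjusted == pytest.approx(res[0].p_tail)

    def test_bonferroni_multiplies_by_family_count(self):
        fams, pairs = self._planted()
        res = run_family_tests(fams, pairs)
        m = len(fams)
        for r in res:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_tail * m))

    def test_planted_high_copy_family_significant(self):
        """A 20-copy planted family in 2 Mb of background must survive
        Bonferroni; its counts agree with the exact integer oracle."""
        fams, pairs = self._planted()
        by_key = {f.key: f for f in fams}
        target = by_key["AC|AAT|138"]
        res = run_family_tests(fams, pairs)
        r = next(x for x in res if x.family.key == target.key)
        assert r.significant
        oracle = comb_sum_tail(r.counts.n, r.counts.n1, r.counts.n2, r.counts.n3)
        assert r.p_tail == pytest.approx(oracle, rel=1e-9)


class TestShuffleAndSample:
    def test_composition_preserved(self):
        g = [GenomeSequence("a", "ACGTN" * 400), GenomeSequence("b", "AATT" * 500)]
        frags = shuffle_and_sample(g, n_samples=4, fragment=1000, seed=5)
        pooled = Counter("".join(f.sequence for f in frags))
        # fragments come from shuffles of the sources, so only source letters appear
        assert set(pooled) <= set("ACGTN")
        assert all(len(f.sequence) == 1000 for f in frags)

    def test_whole_sequence_shuffle_is_permutation(self):
        g = [GenomeSequence("a", "ACGT" * 250)]
        (frag,) = shuffle_and_sample(g, n_samples=1, fragment=1000, seed=9)
        assert Counter(frag.sequence) == Counter(g[0].sequence)

    def test_seed_reproducibility(self):
        g = [GenomeSequence("a", "ACGTTGCA" * 2000)]
        f1 = shuffle_and_sample(g, 5, 1000, seed=42)
        f2 = shuffle_and_sample(g, 5, 1000, seed=42)
        assert [x.sequence for x in f1] == [x.sequence for x in f2]

    def test_disjoint_demand_exceeding_sequence_raises(self):
        g = [GenomeSequence("a", "ACGT" * 1000)]
        with pytest.raises(ValueError):
            shuffle_and_sample(g, 10, 1000, seed=0)


class TestSpearman:
    def test_monotone_perfect(self):
        x = [1.0, 2.0, 5.0, 9.0, 12.0]
        rho, p = spearman(x, [v * 3 + 1 for v in x])
        assert rho == pytest.approx(1.0)
        rho_rev, _ = spearman(x, [-v for v in x])
        assert rho_rev == pytest.approx(-1.0)

    def test_matches_rank_formula_without_ties(self, rng):
        x = rng.permutation(20).astype(float)
        y = rng.permutation(20).astype(float)
        rank = lambda v: np.argsort(np.argsort(v)) + 1
        d = rank(x) - rank(y)
        expected = 1 - 6 * float(np.sum(d * d)) / (20 * (400 - 1))
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])
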