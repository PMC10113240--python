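"""Copy-number indices, gene projection, similarity, and trend tests."""

import itertools

import numpy as np
import pytest
from scipy.special import comb

import pdokit as pk
from pdokit.copynumber import GeneCnMatrix


def profile(segments, sample_id="S", purity=0.8, tumor_class=pk.TumorClass.MIBC):
    return pk.SegmentProfile(
        sample_id=sample_id,
        sample_class=pk.SampleClass.PT,
        tumor_class=tumor_class,
        purity=purity,
        segments=[pk.Segment(*s) for s in segments],
    )


MB = 1_000_000


class TestPloidyAndBurden:
    def test_diploid_genome_has_asp_two_and_gb_zero(self, diploid_profile):
        assert pk.compute_asp(diploid_profile) == pytest.approx(2.0)
        assert pk.compute_gb(diploid_profile) == pytest.approx(0.0)

    def test_single_segment_asp_is_total_copy_number(self):
        p = profile([("chr1", 0, MB, 2, 1)])
        assert pk.compute_asp(p) == pytest.approx(3.0)

    def test_asp_is_length_weighted(self):
        p = profile([("chr1", 0, MB, 2, 1), ("chr1", MB, 4 * MB, 1, 1)])
        # (3*1 + 2*3) / 4
        assert pk.compute_asp(p) == pytest.approx(2.25)

    def test_uniform_triploid_gb_is_one(self, triploid_profile):
        assert pk.compute_gb(triploid_profile) == pytest.approx(1.0)

    def test_gb_is_length_weighted(self):
        p = profile([("chr1", 0, MB, 2, 1), ("chr1", MB, 2 * MB, 1, 1)])
        assert pk.compute_gb(p) == pytest.approx(0.5)

    def test_empty_profile_rejected(self):
        p = profile([("chr1", 0, MB, 1, 1)])
        p.segments = []
        with pytest.raises(ValueError):
            pk.compute_asp(p)
        with pytest.raises(ValueError):
            pk.compute_gb(p)

    def test_asp_gb_internal_consistency(self, cohort):
        """asP decomposes as 2*(1-GB) + (mean total CN over aberrant bases)*GB."""
        for p in cohort.profiles:
            gb = pk.compute_gb(p)
            asp = pk.compute_asp(p)
            ab = [s for s in p.segments if (s.cn_a, s.cn_b) != (1, 1)]
            if not ab:
                assert asp == pytest.approx(2.0)
                continue
            w = np.array([s.length for s in ab], dtype=float)
            mean_ab = float(np.sum([s.total_cn for s in ab] * w) / w.sum())
            assert asp == pytest.approx(2.0 * (1 - gb) + mean_ab * gb)


class TestGeneProjection:
    PANEL = pk.GenePanel(
        [
            pk.GeneRecord("G1", "chr1", 100, 200),
            pk.GeneRecord("G2", "chr1", 900, 1100),  # midpoint 1000
            pk.GeneRecord("G3", "chr2", 0, 100),
        ]
    )

    def test_gene_takes_state_of_midpoint_segment(self):
        p = profile([("chr1", 0, 1000, 2, 1), ("chr1", 1000, 2000, 3, 1), ("chr2", 0, 500, 1, 1)])
        m = pk.project_to_genes([p], self.PANEL)
        assert m.genes == ["G1", "G2", "G3"]
        # G2 midpoint 1000 falls in the second (3,1) segment
        assert (m.cn_a[0].tolist(), m.cn_b[0].tolist()) == ([2, 3, 1], [1, 1, 1])

    def test_uncovered_gene_dropped_cohort_wide(self):
        full = profile([("chr1", 0, 2000, 2, 1), ("chr2", 0, 500, 1, 1)], sample_id="A")
        partial = profile([("chr1", 0, 2000, 1, 1)], sample_id="B")  # chr2 uncovered
        with pytest.warns(UserWarning, match="dropped"):
            m = pk.project_to_genes([full, partial], self.PANEL)
        assert m.genes == ["G1", "G2"]

    def test_continuous_copy_numbers_rounded_half_away(self):
        p = profile([("chr1", 0, 2000, 2.5, 0.4), ("chr2", 0, 500, 1, 1)])
        m = pk.project_to_genes([p], self.PANEL)
        assert m.cn_a[0, 0] == 3 and m.cn_b[0, 0] == 0


def matrix_from(vectors: dict[str, tuple[list[int], list[int]]]) -> GeneCnMatrix:
    samples = list(vectors)
    return GeneCnMatrix(
        samples=samples,
        genes=[f"g{i}" for i in range(len(next(iter(vectors.values()))[0]))],
        cn_a=np.array([vectors[s][0] for s in samples]),
        cn_b=np.array([vectors[s][1] for s in samples]),
    )


class TestDistanceAndSimilarity:
    def test_identical_vectors_have_zero_distance(self):
        m = matrix_from({"a": ([1, 1, 1], [1, 1, 1]), "b": ([1, 1, 1], [1, 1, 1])})
        assert pk.cn_distance(m, "a", "b") == 0.0

    def test_single_allele_difference_is_unit_distance(self):
        m = matrix_from({"a": ([1, 1, 1], [1, 1, 1]), "b": ([2, 1, 1], [1, 1, 1])})
        assert pk.cn_distance(m, "a", "b") == pytest.approx(1.0)

    def test_two_unit_differences_give_sqrt_two(self):
        m = matrix_from({"a": ([2, 1, 1], [1, 1, 1]), "b": ([1, 2, 1], [1, 1, 1])})
        assert pk.cn_distance(m, "a", "b") == pytest.approx(np.sqrt(2))

    def test_similarity_anchors_min_and_max_pairs(self):
        m = matrix_from(
            {
                "a": ([1, 1], [1, 1]),
                "dup": ([1, 1], [1, 1]),  # duplicate of a -> min distance
                "far": ([4, 4], [3, 3]),  # max distance
                "mid": ([2, 2], [1, 1]),
            }
        )
        res = pk.similarity(m)
        assert res.pair_similarity("a", "dup") == pytest.approx(1.0)
        assert res.pair_similarity("a", "far") == pytest.approx(0.0)
        assert np.all(res.similarity >= 0) and np.all(res.similarity <= 1)
        assert np.allclose(res.similarity, res.similarity.T)

    def test_midpoint_distance_maps_to_half_similarity(self):
        # colinear single-gene states 2,2,3,4: distances {0,1,2}
        m = matrix_from(
            {
                "a": ([2], [1]),
                "dup": ([2], [1]),  # d(a,dup)=0 -> min
                "mid": ([3], [1]),  # d=1 -> midpoint of [0,2]
                "far": ([4], [1]),  # d(a,far)=2 -> max
            }
        )
        res = pk.similarity(m)
        assert res.pair_similarity("a", "mid") == pytest.approx(0.5)

    def test_equal_distances_are_rejected(self):
        m = matrix_from({"a": ([1, 1], [1, 1]), "b": ([1, 1], [1, 1])})
        with pytest.raises(ValueError, match="rescal"):
            pk.similarity(m)

    def test_similarity_invariant_under_sample_reordering(self, cohort):
        matrix = pk.project_to_genes(cohort.profiles, cohort.panel)
        res = pk.similarity(matrix)
        perm = list(reversed(range(len(matrix.samples))))
        permuted = GeneCnMatrix(
            samples=[matrix.samples[i] for i in perm],
            genes=matrix.genes,
            cn_a=matrix.cn_a[perm],
            cn_b=matrix.cn_b[perm],
        )
        res_p = pk.similarity(permuted)
        for i, a in enumerate(matrix.samples):
            for b in matrix.samples[i + 1 :]:
                assert res.pair_similarity(a, b) == pytest.approx(
                    res_p.pair_similarity(a, b)
                )


def exact_ranksum_p(x, y):
    """Brute-force two-sided rank-sum p: enumerate all group assignments."""
    pooled = sorted(x) + sorted(y)
    n, m = len(x), len(y)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in x)
    mean = n * (n + m + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, n + m + 1), n):
        s = sum(combo)
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


class TestMatchedVsRandom:
    def test_p_matches_exact_enumeration_for_separated_groups(self, cohort):
        matrix = pk.project_to_genes(cohort.profiles, cohort.panel)
        res = pk.similarity(matrix, matched_pairs=cohort.matched_pairs)
        p, n_matched, n_random = pk.matched_vs_random_test(res)
        assert n_matched == len(cohort.matched_pairs)
        n = len(matrix.samples)
        assert n_random == comb(n, 2, exact=True) - n_matched
        # independent check on small constructed groups
        matched = [0.99, 0.98, 0.97, 0.96]
        rand = [0.5, 0.4, 0.3, 0.2]
        assert pk._stats.rank_sum_test(matched, rand) == pytest.approx(
            exact_ranksum_p(matched, rand)
        )

    def test_degenerate_one_vs_one_has_no_resolution(self):
        # a single similarity per group carries no rank information
        assert pk._stats.rank_sum_test([0.9], [0.1]) == pytest.approx(1.0)

    def test_matched_pairs_required(self):
        res = pk.similarity(
            matrix_from(
                {"a": ([2], [1]), "b": ([3], [1]), "c": ([5], [1])}
            )
        )
        with pytest.raises(ValueError):
            pk.matched_vs_random_test(res)


class TestClustering:
    def test_duplicate_samples_merge_first_at_zero_height(self):
        m = matrix_from(
            {
                "a": ([1, 1], [1, 1]),
                "dup": ([1, 1], [1, 1]),
                "far": ([5, 5], [4, 4]),
            }
        )
        dendro = pk.cluster_profiles(pk.similarity(m))
        assert dendro.merge_heights()[0] == pytest.approx(0.0)

    def test_merge_heights_non_decreasing(self, cohort):
        matrix = pk.project_to_genes(cohort.profiles, cohort.panel)
        dendro = pk.cluster_profiles(pk.similarity(matrix))
        heights = dendro.merge_heights()
        assert np.all(np.diff(heights) >= -1e-9)
        newick = dendro.to_newick()
        assert newick.endswith(";") and all(s in newick for s in matrix.samples)

    def test_planted_blocks_separate_at_first_bipartition(self):
        rng = np.random.default_rng(5)
        vec = {}
        for i in range(4):
            vec[f"lo{i}"] = (list(rng.integers(1, 3, 6)), [1] * 6)
        for i in range(4):
            vec[f"hi{i}"] = (list(rng.integers(6, 8, 6)), [2] * 6)
        vectors = {k: (a, [min(x, y) for x, y in zip(a, b)]) for k, (a, b) in vec.items()}
        dendro = pk.cluster_profiles(pk.similarity(matrix_from(vectors)))
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(dendro.linkage, t=2, criterion="maxclust")
        lo = {l for l, s in zip(labels, dendro.labels) if s.startswith("lo")}
        hi = {l for l, s in zip(labels, dendro.labels) if s.startswith("hi")}
        assert lo.isdisjoint(hi)

    def test_requires_three_samples(self):
        res = pk.similarity(
            matrix_from({"a": ([2], [1]), "b": ([3], [1]), "c": ([5], [1])})
        )
        res.samples = res.samples[:2]
        res.distance = res.distance[:2, :2]
        with pytest.raises(ValueError):
            pk.cluster_profiles(res)


def brute_force_tau_b(x, y):
    """Tau-b from explicit concordant/discordant pair counts with tie terms."""
    nc = nd = tx = ty = 0
    for (xi, yi), (xj, yj) in itertools.combinations(zip(x, y), 2):
        if xi == xj and yi == yj:
            continue
        if xi == xj:
            tx += 1
        elif yi == yj:
            ty += 1
        elif (xi - xj) * (yi - yj) > 0:
            nc += 1
        else:
            nd += 1
    denom = np.sqrt((nc + nd + tx) * (nc + nd + ty))
    return (nc - nd) / denom


class TestOrdinalTrend:
    CLASSES = ["NMIBC_LG", "NMIBC_LG", "NMIBC_HG", "NMIBC_HG", "MIBC", "MIBC"]

    def test_strictly_increasing_values_give_tau_one(self):
        # one sample per class: no ties, perfect concordance
        tau, _ = pk.ordinal_trend([1.0, 2.0, 3.0], ["NMIBC_LG", "NMIBC_HG", "MIBC"])
        assert tau == pytest.approx(1.0)

    def test_strictly_decreasing_values_give_tau_minus_one(self):
        tau, _ = pk.ordinal_trend([3.0, 2.0, 1.0], ["NMIBC_LG", "NMIBC_HG", "MIBC"])
        assert tau == pytest.approx(-1.0)

    def test_within_class_ties_attenuate_tau(self):
        # increasing values inside tied classes: tau-b < 1 by the tie term
        tau, _ = pk.ordinal_trend([1, 2, 3, 4, 5, 6], self.CLASSES)
        ranks = [pk.TumorClass(c).rank for c in self.CLASSES]
        assert tau == pytest.approx(brute_force_tau_b(ranks, [1, 2, 3, 4, 5, 6]))
        assert 0 < tau < 1

    def test_tau_matches_brute_force_with_ties(self):
        values = [1.0, 2.0, 2.0, 3.0, 2.5, 4.0]
        ranks = [pk.TumorClass(c).rank for c in self.CLASSES]
        tau, _ = pk.ordinal_trend(values, self.CLASSES)
        assert tau == pytest.approx(brute_force_tau_b(ranks, values))

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            pk.ordinal_trend([1, 1, 1, 1, 1, 1], self.CLASSES)
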