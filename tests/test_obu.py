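"""OBU clustering, Chao1 richness, rarefaction and shared-OBU counts."""

import itertools

import numpy as np
import pytest

from _oracles import greedy_cluster_oracle
from pksurvey import synth
from pksurvey.obu import (
    chao1,
    cluster_obus,
    rarefy_sequences,
    richness_by_biome,
    shared_obus,
)
from pksurvey.seqio import SequenceRecord


def _rec(i, seq):
    return SequenceRecord(id=f"s{i:03d}", residues=seq, alphabet="protein")


def _lineage_set(rng, n_lineages=4, per_lineage=6, length=200, identity=0.92):
    """Well-separated lineages with tight within-lineage clouds."""
    records = []
    i = 0
    for _ in range(n_lineages):
        seed = synth._random_domain(rng, length)
        for _ in range(per_lineage):
            seq, _ = synth.mutate_to_identity(seed, identity, rng)
            records.append(_rec(i, seq))
            i += 1
    return records


class TestClusterObus:
    def test_identical_sequences_one_cluster(self):
        recs = [_rec(i, "MKVL" * 60) for i in range(5)]
        for thr in (0.7, 0.95, 1.0):
            table = cluster_obus(recs, thr)
            assert len(table.clusters) == 1
            assert table.clusters[0].size == 5

    def test_threshold_bracketing(self, rng):
        seed = synth._random_domain(rng, 200)
        var, realized = synth.mutate_to_identity(seed, 0.85, rng)
        assert realized == pytest.approx(0.85, abs=0.03)
        recs = [_rec(0, seed), _rec(1, var)]
        assert len(cluster_obus(recs, 0.80).clusters) == 1
        assert len(cluster_obus(recs, 0.90).clusters) == 2

    def test_partition_invariant(self, rng):
        from pksurvey.align import global_identity

        recs = _lineage_set(rng)
        table = cluster_obus(recs, 0.85)
        members = [m for c in table.clusters for m in c.member_ids]
        assert sorted(members) == sorted(r.id for r in recs)  # exact partition
        seqs = {r.id: r.residues for r in recs}
        for cl in table.clusters:
            assert cl.centroid_id in cl.member_ids
            for m in cl.member_ids:
                assert global_identity(seqs[m], seqs[cl.centroid_id]) >= 0.85

    def test_matches_exhaustive_greedy_oracle(self, rng):
        """Greedy clustering equals an independent all-pairs oracle."""
        recs = _lineage_set(rng, n_lineages=3, per_lineage=5, length=150)
        for thr in (0.80, 0.90):
            table = cluster_obus(recs, thr)
            oracle = greedy_cluster_oracle(recs, thr)
            assert [(c.centroid_id, c.member_ids) for c in table.clusters] == oracle


class TestRarefy:
    def test_depth_equal_n_is_permutation(self, rng):
        recs = [_rec(i, "MKVL" * 60) for i in range(10)]
        sub = rarefy_sequences(recs, 10, rng)
        assert sorted(r.id for r in sub) == sorted(r.id for r in recs)

    def test_seeded_determinism(self):
        recs = [_rec(i, "MKVL" * 60) for i in range(30)]
        a = rarefy_sequences(recs, 10, np.random.default_rng(3))
        b = rarefy_sequences(recs, 10, np.random.default_rng(3))
        assert [r.id for r in a] == [r.id for r in b]

    def test_too_shallow_pool_rejected(self, rng):
        with pytest.raises(ValueError, match="depth"):
            rarefy_sequences([_rec(0, "MKVL" * 60)], 5, rng)

    def test_inclusion_frequencies_uniform(self):
        """Each element's inclusion rate ~ depth/n within 3 sigma binomial."""
        recs = [_rec(i, "MKVL" * 60) for i in range(20)]
        depth, draws = 5, 1000
        rng = np.random.default_rng(17)
        counts = np.zeros(20)
        for _ in range(draws):
            for r in rarefy_sequences(recs, depth, rng):
                counts[int(r.id[1:])] += 1
        p = depth / 20
        sigma = np.sqrt(draws * p * (1 - p))
        assert np.all(np.abs(counts - draws * p) < 3.5 * sigma)


class TestChao1:
    @pytest.mark.parametrize(
        "sizes,expected",
        [
            ([3, 4, 5], 3.0),
            ([1, 1, 1, 1, 1, 2, 2, 3, 3, 3], 10 + 5 * 4 / (2 * 3)),
            ([1], 1.0),
        ],
    )
    def test_closed_form(self, sizes, expected):
        assert chao1(sizes) == pytest.approx(expected)

    def test_lower_bounded_by_observed_richness(self, rng):
        for _ in range(20):
            sizes = rng.integers(1, 6, size=rng.integers(1, 30)).tolist()
            assert chao1(sizes) >= len(sizes)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            chao1([])


class TestRichnessByBiome:
    def test_identical_sequences_give_chao1_one(self, rng):
        biomes = {"b": [_rec(i, "MKVL" * 60) for i in range(12)]}
        ests = richness_by_biome(biomes, thresholds=[0.9], depth=10, replicates=3, seed=1)
        assert len(ests) == 1
        assert ests[0].chao1_mean == 1.0
        assert ests[0].chao1_sd == 0.0

    def test_more_lineages_more_richness(self):
        """A biome drawn from 5x more lineages shows higher Chao1 at 0.90."""
        rng = np.random.default_rng(23)
        rich = _lineage_set(rng, n_lineages=10, per_lineage=3, length=150, identity=0.97)
        poor = _lineage_set(rng, n_lineages=2, per_lineage=15, length=150, identity=0.97)
        ests = richness_by_biome(
            {"rich": rich, "poor": poor}, thresholds=[0.9], depth=24, replicates=4, seed=5
        )
        by = {e.biome: e.chao1_mean for e in ests}
        assert by["rich"] > by["poor"]

    def test_single_replicate_zero_sd(self, rng):
        biomes = {"b": _lineage_set(rng, 2, 4, 120)}
        ests = richness_by_biome(biomes, thresholds=[0.8], depth=6, replicates=1, seed=2)
        assert ests[0].chao1_sd == 0.0


class TestSharedObus:
    def test_identical_biomes_share_everything(self, rng):
        recs = _lineage_set(rng, 3, 4, 120)
        biomes = {"a": recs, "b": list(recs)}
        results = shared_obus(biomes, thresholds=[1.0], seed=0)
        (res,) = results
        # every OBU contains the same sequence from both biomes
        assert res.shared_domain_count == 2 * len(recs)
        assert res.shared_obu_count >= 1

    def test_disjoint_lineages_share_nothing(self, rng):
        a = _lineage_set(rng, 3, 5, 150)
        b = _lineage_set(rng, 3, 5, 150)  # fresh random lineages, unrelated
        results = shared_obus({"a": a, "b": b}, thresholds=[0.9], seed=0)
        assert results[0].shared_obu_count == 0
        assert results[0].shared_domain_count == 0

    def test_counts_match_exhaustive_enumeration(self, rng):
        """Hand-built 9-sequence, 3-biome fixture: counts equal brute force."""
        s1 = synth._random_domain(rng, 120)
        s2 = synth._random_domain(rng, 120)
        s3 = synth._random_domain(rng, 120)
        mk = lambda seed: synth.mutate_to_identity(seed, 0.95, rng)[0]
        biomes = {
            "x": [_rec(0, mk(s1)), _rec(1, mk(s2)), _rec(2, mk(s3))],
            "y": [_rec(3, mk(s1)), _rec(4, mk(s1)), _rec(5, mk(s2))],
            "z": [_rec(6, mk(s3)), _rec(7, mk(s3)), _rec(8, mk(s3))],
        }
        results = shared_obus(biomes, thresholds=[0.85], seed=0)
        by_pair = {r.biome_pair: r for r in results}
        # lineage membership is the ground truth clustering at 0.85
        lineage = {"s000": 1, "s001": 2, "s002": 3, "s003": 1, "s004": 1,
                   "s005": 2, "s006": 3, "s007": 3, "s008": 3}
        biome_of = {r.id: b for b, rs in biomes.items() for r in rs}
        for pair in by_pair:
            b1, b2 = pair
            shared_lin = set()
            for lin in (1, 2, 3):
                ids = [i for i, l in lineage.items() if l == lin]
                present = {biome_of[i] for i in ids}
                if b1 in present and b2 in present:
                    shared_lin.add(lin)
            n_dom = sum(
                1 for i, l in lineage.items()
                if l in shared_lin and biome_of[i] in (b1, b2)
            )
            assert by_pair[pair].shared_obu_count == len(shared_lin)
            assert by_pair[pair].shared_domain_count == n_dom

    def test_symmetry_and_pair_coverage(self, rng):
        a = _lineage_set(rng, 2, 4, 120)
        b = _lineage_set(rng, 2, 4, 120)
        c = _lineage_set(rng, 2, 4, 120)
        results = shared_obus({"a": a, "b": b, "c": c}, thresholds=[0.8, 0.9], seed=1)
        pairs = {(r.biome_pair, r.threshold) for r in results}
        expected = {
            (p, t) for p in itertools.combinations("abc", 2) for t in (0.8, 0.9)
        }
        assert pairs == expected
        for r in results:
            if r.shared_obu_count > 0:
                assert r.shared_domain_count >= 2 * r.shared_obu_count
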