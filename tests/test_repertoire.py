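"""Cluster similarity, conservation inference and the RC statistic."""

import numpy as np
import pytest

from bgcrep import (
    ClusterType,
    ConservationMap,
    GeneCluster,
    Orf,
    StrainInventory,
    UnknownClusterId,
    cluster_similarity,
    compute_rc,
    infer_conservation,
    parse_domain_string,
    read_conservation_map,
    write_conservation_map,
)
from bgcrep.repertoire import (
    DEFAULT_THRESHOLD,
    brute_force_conservation,
    load_fixture_map,
    similarity_matrix,
)
from bgcrep.simulate import GeneratorConfig, generate_pair


def cluster(cid, ctype, *orf_texts, product=None):
    orfs = [
        Orf(locus_tag=f"orf{i}", modules=tuple(parse_domain_string(t)))
        for i, t in enumerate(orf_texts)
    ]
    return GeneCluster(
        cluster_id=cid, ctype=ClusterType.parse(ctype), orfs=orfs, known_product=product
    )


def inv(sid, *clusters):
    return StrainInventory(strain_id=sid, clusters=list(clusters))


FOUR_MOD = ("C/A(leu)/T-C/A(val)/T-C/A(thr)/T-C/A(ser)/T",)


class TestClusterSimilarity:
    def test_identical_clusters_score_one(self):
        c1 = cluster("a", "nrps", *FOUR_MOD)
        c2 = cluster("b", "nrps", *FOUR_MOD)
        assert cluster_similarity(c1, c2) == 1.0

    def test_fixture_nrps1_identical_between_strains(self, tp_a0598, nbrc3934):
        assert (
            cluster_similarity(tp_a0598.cluster("nrps-1"), nbrc3934.cluster("nrps-1"))
            == 1.0
        )

    def test_type_mismatch_scores_zero(self, tp_a0598):
        assert (
            cluster_similarity(tp_a0598.cluster("nrps-1"), tp_a0598.cluster("t2pks-1"))
            == 0.0
        )

    def test_one_substrate_swap_in_four_modules(self):
        # hand-derived: three identical signatures plus one same-class
        # different-substrate pair: (3*1 + 0.25) / 4
        c1 = cluster("a", "nrps", *FOUR_MOD)
        c2 = cluster("b", "nrps", "C/A(leu)/T-C/A(val)/T-C/A(thr)/T-C/A(gly)/T")
        assert cluster_similarity(c1, c2) == pytest.approx(0.8125)

    def test_symmetry(self, tp_a0598, nbrc3934):
        for ca in tp_a0598.clusters:
            for cb in nbrc3934.clusters:
                assert cluster_similarity(ca, cb) == cluster_similarity(cb, ca)

    def test_known_products_decide_when_both_present(self):
        arch = ("KSa", "KSb(CLF)", "ACP")
        spore1 = cluster("a", "t2pks", *arch, product="Spore pigment")
        spore2 = cluster("b", "t2pks", *arch, product="Spore pigment")
        oxy = cluster("c", "t2pks", *arch, product="Oxytetracycline")
        assert cluster_similarity(spore1, spore2) == 1.0
        assert cluster_similarity(spore1, oxy) == 0.0  # same architecture!

    def test_partial_product_suffix_ignored(self):
        c1 = cluster("a", "nrps", "C/A/T", product="Guadinomine, partial")
        c2 = cluster("b", "nrps", "C/A/T", product="Guadinomine")
        assert cluster_similarity(c1, c2) == 1.0


class TestInferConservation:
    def test_identical_inventories_fully_matched(self, tp_a0598):
        cmap = infer_conservation(tp_a0598, tp_a0598)
        assert len(cmap.pairs) == len(tp_a0598)
        assert all(a == b and s == 1.0 for a, b, s in cmap.pairs)

    def test_fixture_pair_recovers_published_conserved_set(self, tp_a0598, nbrc3934):
        cmap = infer_conservation(tp_a0598, nbrc3934)
        assert {(a, b) for a, b, _ in cmap.pairs} == {
            ("t1pks-1", "t1pks-1"),
            ("t1pks-2", "t1pks-2"),
            ("t2pks-1", "t2pks-1"),
            ("t3pks-1", "t3pks-1"),
            ("nrps-1", "nrps-1"),
        }

    def test_disjoint_inventories_empty_map(self):
        a = inv("A", cluster("nrps-1", "nrps", "C/A(leu)/T"))
        b = inv("B", cluster("t1pks-1", "t1pks", "KS/AT/ACP"))
        assert infer_conservation(a, b).pairs == []

    def test_threshold_validated(self, tp_a0598):
        with pytest.raises(ValueError):
            infer_conservation(tp_a0598, tp_a0598, threshold=0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_assignment_matches_brute_force_on_5x5(self, seed):
        cfg = GeneratorConfig(
            n_a=5, n_b=5, n_shared=int(np.random.default_rng(seed).integers(0, 6)),
            divergence=0.35, seed=seed,
        )
        a, b, _ = generate_pair(cfg)
        cmap = infer_conservation(a, b)
        total = sum(s for _, _, s in cmap.pairs)
        assert total == pytest.approx(brute_force_conservation(a, b))


class TestComputeRc:
    def test_published_pair_numbers(self, tp_a0598, nbrc3934):
        res = compute_rc(tp_a0598, nbrc3934, load_fixture_map())
        assert (res.a_count, res.b_count, res.cab) == (9, 13, 5)
        assert res.rc == 45
        assert float(res.rc_exact) == pytest.approx(45.4545, abs=1e-3)
        assert (res.frac_shared_a, res.frac_specific_a) == (56, 44)
        assert (res.frac_shared_b, res.frac_specific_b) == (38, 62)
        assert res.specific_a == ["nrps-2", "pks/nrps-1", "pks/nrps-2", "t2pks-2"]
        assert len(res.specific_b) == 8

    def test_identical_repertoires_give_100(self, tp_a0598):
        cmap = infer_conservation(tp_a0598, tp_a0598)
        assert compute_rc(tp_a0598, tp_a0598, cmap).rc == 100

    def test_empty_map_gives_0(self, tp_a0598, nbrc3934):
        res = compute_rc(tp_a0598, nbrc3934, ConservationMap([], source="given"))
        assert res.rc == 0 and res.cab == 0

    def test_symmetry_under_strain_swap(self, tp_a0598, nbrc3934):
        fwd = load_fixture_map()
        rev = ConservationMap([(b, a, s) for a, b, s in fwd.pairs], source="given")
        r1 = compute_rc(tp_a0598, nbrc3934, fwd)
        r2 = compute_rc(nbrc3934, tp_a0598, rev)
        assert r1.rc_exact == r2.rc_exact
        assert r1.shared_a == r2.shared_b and r1.specific_a == r2.specific_b

    def test_bounds_and_monotonicity(self):
        # RC in [0,100]; adding one conserved pair strictly increases RC
        clusters_a = [cluster(f"nrps-{i}", "nrps", "C/A(leu)/T") for i in range(1, 5)]
        clusters_b = [cluster(f"nrps-{i}", "nrps", "C/A(leu)/T") for i in range(1, 5)]
        a, b = inv("A", *clusters_a), inv("B", *clusters_b)
        prev = -1
        for k in range(5):
            cmap = ConservationMap(
                [(f"nrps-{i}", f"nrps-{i}", 1.0) for i in range(1, k + 1)],
                source="given",
            )
            rc = compute_rc(a, b, cmap).rc_exact
            assert 0 <= rc <= 100
            assert rc > prev
            prev = rc
        assert prev == 100  # A = B = Cab

    def test_unknown_id_rejected(self, tp_a0598, nbrc3934):
        cmap = ConservationMap([("nope-1", "nrps-1", 1.0)], source="given")
        with pytest.raises(UnknownClusterId):
            compute_rc(tp_a0598, nbrc3934, cmap)

    def test_partition_covers_all_ids(self, tp_a0598, nbrc3934):
        res = compute_rc(tp_a0598, nbrc3934, load_fixture_map())
        assert sorted(res.shared_a + res.specific_a) == sorted(tp_a0598.cluster_ids)
        assert sorted(res.shared_b + res.specific_b) == sorted(nbrc3934.cluster_ids)


def test_map_not_one_to_one_rejected():
    with pytest.raises(ValueError):
        ConservationMap([("a", "x", 1.0), ("a", "y", 1.0)])


def test_map_tsv_round_trip(tmp_path):
    cmap = load_fixture_map()
    p = tmp_path / "map.tsv"
    write_conservation_map(cmap, p)
    back = read_conservation_map(p, source="given")
    assert back.pairs == cmap.pairs


def test_similarity_matrix_margin(tp_a0598, nbrc3934):
    # conserved pairs sit at >= 0.625; everything else at <= 0.25, so the
    # default cutoff separates them with a wide margin
    m = similarity_matrix(tp_a0598, nbrc3934)
    below = m[m < DEFAULT_THRESHOLD]
    assert below.max() <= 0.25
    assert (m >= DEFAULT_THRESHOLD).sum() == 5
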