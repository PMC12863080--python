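import numpy as np
import pytest
from oracles import (
    as_core_order,
    brute_force_block_counts,
    random_signed_circular_perm,
)

from synbreak import block_finder as bf
from synbreak.genome_io import ValidationError


def order_from_ints(ints, gid="g"):
    return as_core_order(
        [(f"f{abs(x)}", 1 if x > 0 else -1) for x in ints], genome_id=gid
    )


IDENT6 = [1, 2, 3, 4, 5, 6]


class TestFindBlocks:
    def test_identity_is_one_block(self):
        part = bf.find_blocks(order_from_ints(IDENT6, "r"), order_from_ints(IDENT6, "q"))
        assert part.n_blocks == 1
        assert part.n_singletons_discarded == 0
        assert part.blocks[0].is_backbone

    def test_internal_inversion_gives_two_blocks(self):
        part = bf.find_blocks(
            order_from_ints(IDENT6, "r"), order_from_ints([1, 2, -4, -3, 5, 6], "q")
        )
        assert part.n_blocks == 2
        sizes = sorted(b.n_core for b in part.blocks)
        assert sizes == [2, 4]
        small = min(part.blocks, key=lambda b: b.n_core)
        assert small.orientation == "reverted"
        assert bf.classify_block(small, part) == "inversion"

    def test_internal_translocation_gives_three_blocks(self):
        part = bf.find_blocks(
            order_from_ints(list(range(1, 9)), "r"),
            order_from_ints([1, 2, 5, 6, 3, 4, 7, 8], "q"),
        )
        assert part.n_blocks == 3
        assert sorted(b.n_core for b in part.blocks) == [2, 2, 4]
        assert all(
            cls == "translocation" for cls in part.classifications.values()
        )

    def test_translocation_leaving_singleton(self):
        part = bf.find_blocks(
            order_from_ints(IDENT6, "r"), order_from_ints([1, 2, 5, 3, 4, 6], "q")
        )
        assert part.n_blocks == 2
        assert part.n_singletons_discarded == 1

    def test_reverse_complement_deposit_is_not_an_inversion(self):
        part = bf.find_blocks(
            order_from_ints(IDENT6, "r"),
            order_from_ints([-6, -5, -4, -3, -2, -1], "q"),
        )
        assert part.n_blocks == 1
        assert part.blocks[0].orientation == "forward"  # canonicalized
        assert part.classifications == {}

    def test_too_few_shared_families_raises(self):
        with pytest.raises(ValidationError, match="shared"):
            bf.find_blocks(
                order_from_ints([1, 2], "r"), order_from_ints([3, 4], "q")
            )


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_small_permutations(self):
        rng = np.random.default_rng(42)
        for _ in range(800):
            size = int(rng.integers(4, 13))
            ref = random_signed_circular_perm(rng, size)
            qry = random_signed_circular_perm(rng, size)
            want = brute_force_block_counts(ref, qry)
            part = bf.find_blocks(as_core_order(ref, "r"), as_core_order(qry, "q"))
            assert (part.n_blocks, part.n_singletons_discarded) == want

    def test_partition_conserves_shared_core(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            size = int(rng.integers(4, 20))
            ref = random_signed_circular_perm(rng, size)
            qry = random_signed_circular_perm(rng, size)
            part = bf.find_blocks(as_core_order(ref, "r"), as_core_order(qry, "q"))
            total = sum(b.n_core for b in part.blocks) + part.n_singletons_discarded
            assert total == part.n_shared_core == size

    def test_block_count_is_symmetric(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            size = int(rng.integers(4, 16))
            a = random_signed_circular_perm(rng, size)
            b = random_signed_circular_perm(rng, size)
            pab = bf.find_blocks(as_core_order(a, "a"), as_core_order(b, "b"))
            pba = bf.find_blocks(as_core_order(b, "b"), as_core_order(a, "a"))
            assert pab.n_blocks == pba.n_blocks
            assert pab.n_singletons_discarded == pba.n_singletons_discarded


class TestBackboneAndDedup:
    def test_single_block_genome_has_no_rearranged_blocks(self):
        part = bf.find_blocks(order_from_ints(IDENT6, "r"), order_from_ints(IDENT6, "q"))
        assert bf.rearranged_blocks(part) == []

    def test_rearranged_are_all_but_largest(self):
        part = bf.find_blocks(
            order_from_ints(list(range(1, 9)), "r"),
            order_from_ints([1, 2, 5, 6, 3, 4, 7, 8], "q"),
        )
        rearr = bf.rearranged_blocks(part)
        assert len(rearr) == 2
        assert all(b.n_core == 2 for b in rearr)

    def test_backbone_tie_broken_deterministically(self):
        # two blocks of equal core size: smaller reference start wins
        part = bf.find_blocks(
            order_from_ints([1, 2, 3, 4], "r"), order_from_ints([1, 2, -4, -3], "q")
        )
        assert part.n_blocks == 2
        backbone = [b for b in part.blocks if b.is_backbone]
        assert len(backbone) == 1
        assert backbone[0].ref_span[0] <= min(b.ref_span[0] for b in part.blocks)

    def test_dedup_removes_identities_seen_more_than_twice(self):
        part = bf.find_blocks(
            order_from_ints(IDENT6, "r"), order_from_ints([1, 2, -4, -3, 5, 6], "q")
        )
        blk = [b for b in part.blocks if not b.is_backbone][0]
        import copy

        twice = [blk, copy.deepcopy(blk)]
        assert len(bf.dedup_blocks(twice)) == 2
        thrice = twice + [copy.deepcopy(blk)]
        assert bf.dedup_blocks(thrice) == []

    def test_identity_key_is_orientation_invariant(self):
        fwd = [("f3", 1), ("f4", 1)]
        rev = [("f4", -1), ("f3", -1)]
        assert bf.canonical_identity_key(fwd) == bf.canonical_identity_key(rev)


class TestReferenceSelection:
    def test_all_identical_picks_lexicographic_smallest(self):
        orders = [order_from_ints(IDENT6, g) for g in ("gb", "ga", "gc")]
        assert bf.select_reference(orders) == "ga"

    def test_unrearranged_ancestor_selected(self):
        anc = order_from_ints(list(range(1, 13)), "g2")
        s1 = order_from_ints([1, 2, -4, -3] + list(range(5, 13)), "g1")  # inversion
        s2 = order_from_ints([1, 2, 3, 4, 5, 6, 7, 10, 11, 8, 9, 12], "g3")  # translocation
        # exhaustive check of all candidate averages
        averages = {}
        for cand in (anc, s1, s2):
            others = [o for o in (anc, s1, s2) if o.genome_id != cand.genome_id]
            averages[cand.genome_id] = np.mean(
                [bf.find_blocks(cand, o).n_blocks for o in others]
            )
        assert min(averages, key=averages.get) == "g2"
        assert bf.select_reference([anc, s1, s2]) == "g2"

    def test_two_genomes_tie_resolved_lexicographically(self):
        a = order_from_ints(IDENT6, "gb")
        b = order_from_ints([1, 2, -4, -3, 5, 6], "ga")
        assert bf.select_reference([a, b]) == "ga"


class TestSpeciesSummary:
    def test_zero_event_species_all_single_blocks(self, quiet_bundle):
        from synbreak import pipeline

        _core, ref, parts = pipeline.compute_partitions(quiet_bundle.species)
        summary = bf.summarize_species("sp", ref, parts)
        assert all(n == 1 for n in summary.n_blocks_per_genome.values())
        assert summary.mean_blocks == 1.0

    def test_single_planted_inversion_classified(self):
        from synbreak.synthetic_data import SynthParams, make_species
        from synbreak import pipeline

        bundle = make_species(
            SynthParams(seed=2, n_genomes=5, C=50, rearr_per_branch=0.0,
                        genome_length_bp=150_000, with_sequences=False),
            events_per_genome={"g02": [("inversion", 10, 5)]},
        )
        _core, ref, parts = pipeline.compute_partitions(bundle.species)
        assert ref != "g02"
        summary = bf.summarize_species("sp", ref, parts)
        assert summary.n_blocks_per_genome["g02"] == 2
        assert summary.inversions_per_genome["g02"] == 1
        assert summary.translocations_per_genome["g02"] == 0

    def test_reference_self_comparison_rejected(self):
        part = bf.find_blocks(order_from_ints(IDENT6, "r"), order_from_ints(IDENT6, "q"))
        with pytest.raises(ValidationError):
            bf.summarize_species("sp", "q", {"q": part})


def test_monotone_degradation_with_more_events():
    """More random events never decrease the expected block count."""
    from synbreak.rates import SimParams, simulate_rearrangements
    from synbreak.block_finder import count_blocks_raw

    rng = np.random.default_rng(3)
    params = SimParams(C=100)
    means = []
    for k in (0, 2, 5, 10):
        counts = [
            count_blocks_raw(simulate_rearrangements(100, k, params, rng))[0]
            for _ in range(120)
        ]
        means.append(np.mean(counts))
    assert all(b >= a for a, b in zip(means, means[1:]))
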