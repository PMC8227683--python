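"""Gene-order representation and rearrangement-event inference."""

import numpy as np
import pytest

from mitokit.alphabet import ALL_GENES
from mitokit.gene_order import (
    GeneOrder,
    OrderExtractionError,
    ancestral_pancrustacean_order,
    apply_events,
    derived_megabelesesinae_order,
    gene_order_of,
    infer_events,
    make_gene_order,
    min_relocated_oracle,
    order_from_string,
    order_to_string,
    shared_derived_events,
)
from mitokit.records import rotate_record


@pytest.fixture(scope="module")
def ancestral():
    return ancestral_pancrustacean_order()


@pytest.fixture(scope="module")
def derived():
    return derived_megabelesesinae_order()


def _subsequence(order, genes):
    names = [g for g, _ in order.order]
    idx = [names.index(g) for g in genes]
    return idx == sorted(idx) and all(
        idx[i + 1] - idx[i] == 1 for i in range(len(idx) - 1)
    )


class TestAncestralOrder:
    def test_has_37_genes_each_once(self, ancestral):
        assert len(ancestral.order) == 37
        assert set(ancestral.genes) == set(ALL_GENES)

    def test_iqm_cluster_with_strands(self, ancestral):
        assert _subsequence(ancestral, ["trnI", "trnQ", "trnM"])
        assert ancestral.sign_of("trnI") == 1
        assert ancestral.sign_of("trnQ") == -1
        assert ancestral.sign_of("trnM") == 1

    def test_arns1ef_cluster(self, ancestral):
        assert _subsequence(ancestral, ["trnA", "trnR", "trnN", "trnS1", "trnE", "trnF"])

    def test_wcy_cluster(self, ancestral):
        assert _subsequence(ancestral, ["trnW", "trnC", "trnY"])


class TestGeneOrderOf:
    def test_reference_record_recovers_planted_order(self, small_dataset, ancestral):
        plain = [r for r in small_dataset.records if r.taxon == "outgroup"][0]
        assert gene_order_of(plain).order == ancestral.order

    def test_rotated_record_gives_identical_order(self, small_dataset):
        rec = small_dataset.records[0]
        base = gene_order_of(rec)
        for offset in (100, rec.length // 3):
            assert gene_order_of(rotate_record(rec, offset)).order == base.order

    def test_planted_rearrangement_changes_only_hotspots(self, small_dataset, ancestral):
        clade_rec = [r for r in small_dataset.records if r.taxon in small_dataset.clade_taxa][0]
        events = infer_events(gene_order_of(clade_rec), ancestral)
        assert {e.cluster for e in events} == {"IQM", "ARNS1EF"}

    def test_missing_gene_is_extraction_error(self, small_dataset):
        from mitokit.records import MitogenomeRecord

        rec = small_dataset.records[0]
        pruned = MitogenomeRecord(
            taxon=rec.taxon,
            sequence=rec.sequence,
            annotations=[a for a in rec.annotations if a.name != "trnW"],
        )
        with pytest.raises(OrderExtractionError, match="trnW"):
            gene_order_of(pruned)


class TestWorkedExamples:
    def test_identity_gives_no_events(self, ancestral):
        assert infer_events(ancestral, ancestral) == []

    def test_iqm_event_set(self, derived, ancestral):
        """Ancestral I(+) Q(-) M(+) to derived M(+) Q(+) I(+): trnQ inverted
        in place, trnM and trnI transposed around it."""
        events = {
            (e.kind, e.genes)
            for e in infer_events(derived, ancestral)
            if e.cluster == "IQM"
        }
        assert events == {
            ("inversion", ("trnQ",)),
            ("transposition", ("trnM",)),
            ("transposition", ("trnI",)),
        }

    def test_arns1ef_single_reverse_transposition(self, derived, ancestral):
        events = [e for e in infer_events(derived, ancestral) if e.cluster == "ARNS1EF"]
        assert len(events) == 1
        assert events[0].kind == "reverse_transposition"
        assert events[0].genes == ("trnR",)
        assert events[0].to_context == ("trnE", "trnF")

    def test_replay_reproduces_query(self, derived, ancestral):
        events = infer_events(derived, ancestral)
        assert apply_events(ancestral, events).order == derived.order

    def test_derived_order_reads_mqi_and_ans1erf(self, derived):
        assert _subsequence(derived, ["trnM", "trnQ", "trnI"])
        assert _subsequence(derived, ["trnA", "trnN", "trnS1", "trnE", "trnR", "trnF"])
        assert derived.sign_of("trnQ") == 1
        assert derived.sign_of("trnR") == -1


def _random_signed_order(rng, n):
    genes = [f"g{i}" for i in range(n)]
    perm = rng.permutation(n)
    signs = rng.choice([-1, 1], size=n)
    return GeneOrder(taxon="q", order=tuple((genes[perm[i]], int(signs[i])) for i in range(n)))


class TestOracleEquivalence:
    """The DP backbone must relocate exactly as few genes as exhaustive
    search over stationary subsets, and replay must reproduce the query."""

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_brute_force_on_random_signed_permutations(self, n):
        rng = np.random.default_rng(n)
        ref = GeneOrder(taxon="r", order=tuple((f"g{i}", 1) for i in range(n)))
        for _ in range(60):
            qry = _random_signed_order(rng, n)
            events = infer_events(qry, ref, max_events=n + 1)
            relocated = sum(
                len(e.genes)
                for e in events
                if e.kind in ("transposition", "reverse_transposition")
            )
            oracle = min_relocated_oracle(list(ref.genes), list(qry.genes))
            assert relocated == oracle, (ref.order, qry.order)
            assert apply_events(ref, events).order == qry.order

    def test_exhaustive_three_gene_orders(self):
        from itertools import permutations, product

        ref = GeneOrder(taxon="r", order=(("g0", 1), ("g1", 1), ("g2", 1)))
        for perm in permutations(range(3)):
            for signs in product([1, -1], repeat=3):
                qry = GeneOrder(
                    taxon="q", order=tuple((f"g{perm[i]}", signs[i]) for i in range(3))
                )
                events = infer_events(qry, ref, max_events=6)
                assert apply_events(ref, events).order == qry.order
                relocated = sum(
                    len(e.genes)
                    for e in events
                    if e.kind in ("transposition", "reverse_transposition")
                )
                assert relocated == min_relocated_oracle(
                    list(ref.genes), list(qry.genes)
                )


class TestBlocksAndFallback:
    def test_contiguous_block_moves_as_one_event(self):
        ref = order_from_string("r", "a b c d e f")
        qry = order_from_string("q", "a d e b c f")
        events = infer_events(qry, ref)
        kinds = sorted((e.kind, e.genes) for e in events)
        assert kinds == [("transposition", ("d", "e"))] or kinds == [
            ("transposition", ("b", "c"))
        ]
        assert apply_events(ref, events).order == qry.order

    def test_flipped_reversed_block_is_one_reverse_transposition(self):
        ref = order_from_string("r", "a b c d e f")
        qry = order_from_string("q", "a d e -c -b f")
        events = infer_events(qry, ref)
        assert [(e.kind, e.genes) for e in events] == [
            ("reverse_transposition", ("c", "b"))
        ]
        assert apply_events(ref, events).order == qry.order

    def test_anchored_gene_between_exchanged_neighbours_is_inverted_in_place(self):
        """A flipped gene that keeps its index while its neighbours swap is
        described as an in-place inversion (the MQI pattern), not as a
        relocation with flip."""
        ref = order_from_string("r", "a b -c d e")
        qry = order_from_string("q", "a d c b e")
        kinds = {(e.kind, e.genes) for e in infer_events(qry, ref)}
        assert kinds == {
            ("inversion", ("c",)),
            ("transposition", ("b",)),
            ("transposition", ("d",)),
        }

    def test_budget_exceeded_collapses_to_unresolved_block(self):
        ref = order_from_string("r", "a b c d e f g h")
        qry = order_from_string("q", "a h -g c -b f d e")
        events = infer_events(qry, ref, max_events=2)
        assert len(events) == 1
        assert events[0].kind == "unresolved_block"
        with pytest.raises(ValueError):
            apply_events(ref, events)

    def test_order_string_round_trip(self, derived):
        text = order_to_string(derived)
        assert order_from_string("x", text).order == derived.order


class TestSharedDerivedEvents:
    def test_clade_events_flagged_synapomorphic(self, small_dataset, ancestral):
        orders = [gene_order_of(r) for r in small_dataset.records]
        shared = shared_derived_events(orders, ancestral, clade=small_dataset.clade_taxa)
        syn = [s for s in shared if s.synapomorphic]
        assert len(syn) == 4  # inversion Q, transpositions M and I, revtransp R
        for s in syn:
            assert set(s.taxa) == small_dataset.clade_taxa

    def test_event_shared_with_outsider_not_flagged(self, ancestral, derived):
        orders = [
            GeneOrder(taxon=t, order=derived.order) for t in ("c1", "c2", "outsider")
        ]
        shared = shared_derived_events(orders, ancestral, clade={"c1", "c2"})
        assert all(not s.synapomorphic for s in shared)

    def test_empty_taxon_list_gives_empty_mapping(self, ancestral):
        assert shared_derived_events([], ancestral) == []


def test_make_gene_order_normalizes_rotation(ancestral):
    rolled = list(ancestral.order[5:]) + list(ancestral.order[:5])
    assert make_gene_order("x", rolled).order == ancestral.order
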