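"""Splicing simulation: stepwise excision, graphs, skips, order enumeration."""

import pytest

import stwinscan as sw
from stwinscan.rules import RELAXED
from stwinscan.motifs import matches_at
from stwinscan.simulate import (
    GuardExceeded,
    RnaSpecies,
    classify_products,
    detect_second_order,
    enumerate_orders,
    splice_step,
    splice_to_completion,
)


def _primary(genome):
    return RnaSpecies.primary(genome)


class TestSpliceStep:
    def test_internal_intron_excised_first(self, plain_fixture):
        genome, truth = plain_fixture
        children = splice_step(_primary(genome))
        assert len(children) == 1
        event, child = children[0]
        internal = truth.stwintrons[0].internal.intron_span
        assert event.intron.intron_span == internal
        assert "internal_of_stwintron" in event.flags
        # the re-joined external donor matches the uninterrupted profile
        ext_start = truth.stwintrons[0].total_span[0]
        assert matches_at(RELAXED.donor, child.seq, ext_start)

    def test_branch_over_alternative_acceptors(self, aniger_fixture):
        """The secondary internal intron is 29 nt longer at its 3' end."""
        genome, _ = aniger_fixture
        children = splice_step(_primary(genome), branch=True)
        assert len(children) == 2
        (e1, _), (e2, _) = children
        s1, s2 = e1.intron.intron_span, e2.intron.intron_span
        assert s1[0] == s2[0]
        assert s2[1] - s1[1] == 29
        assert "alternative_acceptor" in e2.flags
        assert "alternative_acceptor" not in e1.flags

    def test_intron_free_species_yields_nothing(self):
        seq = sw.random_background(300, seed=4)
        assert splice_step(_primary(seq)) == []


class TestSpliceToCompletion:
    def test_two_step_stwintron_chain(self, plain_fixture):
        genome, truth = plain_fixture
        graph = splice_to_completion(_primary(genome))
        assert graph.graph.number_of_nodes() == 3
        assert graph.graph.number_of_edges() == 2
        events = sorted(graph.events(), key=lambda e: e.order_index)
        assert "internal_of_stwintron" in events[0].flags
        assert "external_of_stwintron" in events[1].flags
        (leaf,) = graph.leaves()
        assert leaf.seq == truth.mature_seq

    def test_dual_is_four_reactions_last_second_order(self, dual_fixture):
        genome, truth = dual_fixture
        graph = splice_to_completion(_primary(genome))
        assert graph.graph.number_of_nodes() == 5
        assert graph.graph.number_of_edges() == 4
        events = sorted(graph.events(), key=lambda e: e.order_index)
        assert "second_order" in events[-1].flags
        assert len(events[-1].primary_footprint) == 3
        (leaf,) = graph.leaves()
        assert leaf.seq == truth.mature_seq

    @pytest.mark.parametrize("fixture_name,exon_len",
                             [("aniger_fixture", 15), ("ncrassa_fixture", 33)])
    def test_branching_gives_two_mature_products(self, request, fixture_name, exon_len):
        genome, truth = request.getfixturevalue(fixture_name)
        graph = splice_to_completion(_primary(genome), branch=True)
        products = {leaf.seq for leaf in graph.leaves()}
        assert len(products) == 2
        assert products == {truth.notes["mature_retained"], truth.notes["mature_skipped"]}
        lengths = sorted(len(p) for p in products)
        assert lengths[1] - lengths[0] == exon_len

    def test_guard(self, plain_fixture):
        genome, _ = plain_fixture
        with pytest.raises(GuardExceeded) as exc:
            splice_to_completion(_primary(genome), max_nodes=1)
        assert exc.value.partial is not None


class TestDetectSecondOrder:
    def test_final_dual_event_three_segments(self, dual_fixture):
        genome, _ = dual_fixture
        graph = splice_to_completion(_primary(genome))
        events = sorted(graph.events(), key=lambda e: e.order_index)
        assert detect_second_order(events[-1]) == (True, 3)

    def test_external_of_plain_stwintron_is_discontiguous(self, plain_fixture):
        """The external intron's donor was split by the internal intron, so
        its material maps to two primary segments."""
        genome, _ = plain_fixture
        graph = splice_to_completion(_primary(genome))
        events = sorted(graph.events(), key=lambda e: e.order_index)
        assert detect_second_order(events[1]) == (True, 2)
        # but it is classified as an external excision, not second-order
        assert "second_order" not in events[1].flags

    def test_standard_intron_single_segment(self):
        genome, truth = sw.plant_stwintron(
            sw.FixtureSpec(seed=21, background_len=700,
                           features=(sw.StandardIntronGeometry(60),))
        )
        graph = splice_to_completion(_primary(genome))
        (event,) = graph.events()
        assert detect_second_order(event) == (False, 1)
        assert "standard" in event.flags


class TestClassifyProducts:
    @pytest.mark.parametrize("fixture_name,exon_len",
                             [("aniger_fixture", 15), ("ncrassa_fixture", 33)])
    def test_exon_skip_reported(self, request, fixture_name, exon_len):
        genome, truth = request.getfixturevalue(fixture_name)
        graph = splice_to_completion(_primary(genome), branch=True)
        report = classify_products(graph)
        skips = [s for s in report.skips if s.length == exon_len]
        assert len(skips) == 1
        assert skips[0].primary_span == tuple(truth.notes["exon2_span"])

    def test_single_leaf_reports_no_skip(self, plain_fixture):
        genome, _ = plain_fixture
        graph = splice_to_completion(_primary(genome))
        report = classify_products(graph)
        assert report.skips == ()
        assert len(report.leaves) == 1


class TestEnumerateOrders:
    def test_dual_is_orders(self, dual_fixture):
        """Every order ends with the second-order intron; orders exist in
        which intron 2 precedes the external intron."""
        genome, _ = dual_fixture
        orders = enumerate_orders(_primary(genome))
        assert len(orders) == 3
        found_i2_before_external = False
        for order in orders:
            flags_seq = [flags for _, flags in order]
            assert "second_order" in flags_seq[-1]
            ext_pos = next(i for i, f in enumerate(flags_seq) if "external_of_stwintron" in f)
            int_pos = next(i for i, f in enumerate(flags_seq) if "internal_of_stwintron" in f)
            assert int_pos < ext_pos  # inside-out constraint
            std_pos = next(i for i, f in enumerate(flags_seq) if not f)
            if std_pos < ext_pos:
                found_i2_before_external = True
        assert found_i2_before_external

    def test_plain_intron_single_order(self):
        genome, _ = sw.plant_stwintron(
            sw.FixtureSpec(seed=21, background_len=700,
                           features=(sw.StandardIntronGeometry(60),))
        )
        orders = enumerate_orders(_primary(genome))
        assert len(orders) == 1
        (order,) = orders
        assert len(order) == 1


class TestInvariants:
    @pytest.mark.parametrize(
        "fixture_name,branch",
        [
            ("plain_fixture", False),
            ("dual_fixture", False),
            ("aniger_fixture", True),
            ("ncrassa_fixture", True),
        ],
    )
    def test_conservation_and_gt_ag(self, request, fixture_name, branch):
        """Length conservation at every node; every excised intron begins
        GT and ends AG on its parent species."""
        genome, _ = request.getfixturevalue(fixture_name)
        graph = splice_to_completion(_primary(genome), branch=branch)
        graph.check_conservation()
        for a, b, data in graph.graph.edges(data=True):
            parent = graph.species(a)
            s, e = data["event"].intron.intron_span
            assert parent.seq[s : s + 2] == "GT"
            assert parent.seq[e - 2 : e] == "AG"
            assert e - s >= 42

    def test_mature_provenance_maps_to_exons(self, dual_fixture):
        """Every mature-mRNA base maps back to a planted exon coordinate."""
        genome, truth = dual_fixture
        graph = splice_to_completion(_primary(genome))
        (leaf,) = graph.leaves()
        so = truth.notes["second_order_spans"]
        removed_span = (so["donor"][0], so["acceptor"][1])
        expected = [i for i in range(len(genome)) if not removed_span[0] <= i < removed_span[1]]
        assert list(leaf.provenance) == expected
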