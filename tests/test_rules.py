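"""The U2 intron model: distance-rule validation and nearest-pair calling."""

import dataclasses

import pytest

import stwinscan as sw
from stwinscan.rules import (
    DEFAULT_RULES,
    RELAXED,
    STRICT,
    ConsensusProfile,
    DistanceRules,
    IntronCall,
    find_introns,
    validate_intron,
)
from stwinscan.motifs import compile_motif


def _call(g1, g2, donor_start=0):
    """An intron call with the given element-to-element distances."""
    d = (donor_start, donor_start + 6)
    b = (d[1] + g1, d[1] + g1 + 6)
    a = (b[1] + g2, b[1] + g2 + 3)
    return IntronCall(d, b, a)


WIDE = DistanceRules(donor_bp_gap=(5, 200), bp_acc_gap=(2, 100))


class TestValidateIntron:
    def test_minimum_length_is_42(self):
        # 6+22+6+4+3 = 41 nt; distances satisfy the (widened) windows so
        # only the length floor is violated
        ok, why = validate_intron(_call(22, 4), WIDE)
        assert (ok, why) == (False, ["min_len"])
        ok, _ = validate_intron(_call(23, 4), WIDE)  # 42 nt
        assert ok

    def test_donor_bp_window(self):
        ok, why = validate_intron(_call(24, 4))
        assert not ok and "donor_bp_gap" in why
        ok, why = validate_intron(_call(121, 24))
        assert not ok and "donor_bp_gap" in why

    def test_bp_acc_window(self):
        ok, why = validate_intron(_call(30, 3))
        assert not ok and why == ["bp_acc_gap"]
        ok, why = validate_intron(_call(30, 25))
        assert not ok and why == ["bp_acc_gap"]

    def test_boundary_values_pass(self):
        # donor→BP 25, BP→acceptor 24, length 64: every rule at its edge
        assert validate_intron(_call(25, 24)) == (True, [])

    def test_principle3_strict_inequality(self):
        ok, why = validate_intron(_call(24, 24), WIDE)
        assert not ok and why == ["principle3"]
        assert validate_intron(_call(25, 24), WIDE) == (True, [])
        relaxed = dataclasses.replace(WIDE, enforce_principle3=False)
        assert validate_intron(_call(24, 24), relaxed) == (True, [])


class TestProfiles:
    def test_shipped_profiles(self):
        assert STRICT.donor.pattern == "GTRWGY"
        assert STRICT.branchpoint.pattern == "RYTRAY"
        assert STRICT.acceptor.pattern == "YAG"
        assert RELAXED.donor.pattern == "GTRWGH"
        assert RELAXED.branchpoint.pattern == "DYTRAY"
        assert RELAXED.acceptor.pattern == "HAG"

    def test_branch_adenosine_enforced(self):
        with pytest.raises(ValueError, match="adenosine"):
            ConsensusProfile(
                name="bad",
                donor=compile_motif("GTRWGY"),
                branchpoint=compile_motif("RYTRYA"),  # A not at position 5
                acceptor=compile_motif("YAG"),
            )

    def test_branch_a_coordinate(self):
        call = _call(30, 10)
        assert call.branch_a == call.bp_span[0] + 4


class TestFindIntrons:
    def test_two_planted_disjoint_introns(self):
        spec = sw.FixtureSpec(
            seed=11,
            background_len=900,
            features=(sw.StandardIntronGeometry(60), sw.StandardIntronGeometry(80)),
        )
        genome, truth = sw.plant_stwintron(spec)
        calls = find_introns(genome)
        assert [c.intron_span for c in calls] == [c.intron_span for c in truth.introns]
        assert [c.donor_span for c in calls] == [c.donor_span for c in truth.introns]
        assert [c.bp_span for c in calls] == [c.bp_span for c in truth.introns]

    def test_stwintron_yields_only_internal_intron(self, plain_fixture):
        """The interrupted external donor cannot match the 6-nt motif."""
        genome, truth = plain_fixture
        calls = find_introns(genome)
        assert len(calls) == 1
        assert calls[0].intron_span == truth.stwintrons[0].internal.intron_span

    def test_donor_free_sequence_is_empty(self):
        seq = sw.random_background(1000, seed=2, motif_free=True)
        assert find_introns(seq) == []

    def test_every_call_validates(self, dual_fixture):
        genome, _ = dual_fixture
        for call in find_introns(genome):
            assert validate_intron(call)[0]

    def test_nearest_pairing(self, aniger_fixture):
        """No valid acceptor exists strictly inside a returned intron."""
        genome, _ = aniger_fixture
        for call in find_introns(genome):
            d = call.donor_span[0]
            alts = sw.find_acceptor_alternatives(genome, d)
            assert alts[0].intron_span == call.intron_span
            assert all(a.length >= call.length for a in alts)

    def test_monotonicity_under_relaxation(self, plain_fixture):
        """Widening the windows never loses a donor; its chosen acceptor
        can only move nearer, never farther."""
        genome, _ = plain_fixture
        base = {c.donor_span: c for c in find_introns(genome)}
        wider = DistanceRules(donor_bp_gap=(20, 160), bp_acc_gap=(4, 40))
        relaxed = {c.donor_span: c for c in find_introns(genome, rules=wider)}
        for donor, call in base.items():
            assert donor in relaxed
            assert relaxed[donor].length <= call.length
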