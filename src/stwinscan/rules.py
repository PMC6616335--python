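"""Canonical U2 intron model: consensus profiles, distance rules, pairing.

Fungal (ascomycete) introns are small and are excised under *intron
definition*: the 5' donor, the branchpoint element carrying the lariat
adenosine, and the 3' acceptor pair across the intron, and the paired
sites are the nearest compatible ones.  This module encodes that model as
data (:class:`ConsensusProfile`, :class:`DistanceRules`) plus two
operations: :func:`validate_intron`, which checks a candidate call against
the distance rules and enumerates the violated ones, and
:func:`find_introns`, which calls introns on a sequence by nearest-pair
scanning.

The default rule set is the operational definition used for whole-genome
stwintron screens in *Aspergillus nidulans*:

* minimum intron length 42 nt;
* donor-element end to branchpoint-element start: 25–120 nt;
* branchpoint-element end to acceptor start: 4–24 nt;
* the donor→branchpoint distance is strictly greater than the
  branchpoint→acceptor distance.

Two consensus profiles are shipped: ``strict`` (donor GTRWGY, branchpoint
RYTRAY, acceptor YAG) and ``relaxed`` (GTRWGH / DYTRAY / HAG), the latter
being the one used in the published [D5,6] genome screen pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .motifs import DegenerateMotif, compile_motif, matches_at, normalize_sequence, _occurrences

__all__ = [
    "ConsensusProfile",
    "DistanceRules",
    "IntronCall",
    "STRICT",
    "RELAXED",
    "PROFILES",
    "DEFAULT_RULES",
    "validate_intron",
    "find_introns",
    "find_acceptor_alternatives",
]

Span = tuple[int, int]


@dataclass(frozen=True)
class ConsensusProfile:
    """The three splice-element motifs of a U2 intron.

    Invariants: the donor and branchpoint are 6 nt, the acceptor 3 nt; the
    branchpoint's fifth position is exactly A (the branch adenosine) and
    the acceptor ends in G.
    """

    name: str
    donor: DegenerateMotif
    branchpoint: DegenerateMotif
    acceptor: DegenerateMotif

    def __post_init__(self) -> None:
        if self.donor.length != 6:
            raise ValueError("donor motif must be 6 nt")
        if self.branchpoint.length != 6:
            raise ValueError("branchpoint motif must be 6 nt")
        if self.branchpoint.allowed[4] != frozenset("A"):
            raise ValueError("branchpoint position 5 must be the branch adenosine (A)")
        if self.acceptor.length != 3:
            raise ValueError("acceptor motif must be 3 nt")
        if self.acceptor.allowed[2] != frozenset("G"):
            raise ValueError("acceptor must end in G")


STRICT = ConsensusProfile(
    name="strict",
    donor=compile_motif("GTRWGY"),
    branchpoint=compile_motif("RYTRAY"),
    acceptor=compile_motif("YAG"),
)

RELAXED = ConsensusProfile(
    name="relaxed",
    donor=compile_motif("GTRWGH"),
    branchpoint=compile_motif("DYTRAY"),
    acceptor=compile_motif("HAG"),
)

PROFILES = {"strict": STRICT, "relaxed": RELAXED}


@dataclass(frozen=True)
class DistanceRules:
    """Intron-definition distance constraints (all distances in nt).

    Distances are measured element-end (exclusive) to element-start, the
    same arithmetic the textual gap windows ``(25,120)`` / ``(4,24)`` use.
    ``enforce_principle3`` requires the donor→branchpoint distance to be
    strictly greater than the branchpoint→acceptor distance.
    """

    min_intron_len: int = 42
    donor_bp_gap: Span = (25, 120)
    bp_acc_gap: Span = (4, 24)
    enforce_principle3: bool = True

    def __post_init__(self) -> None:
        for lo, hi in (self.donor_bp_gap, self.bp_acc_gap):
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid distance window ({lo},{hi})")
        if self.min_intron_len < 0:
            raise ValueError("min_intron_len must be non-negative")


DEFAULT_RULES = DistanceRules()


@dataclass(frozen=True)
class IntronCall:
    """A called U2 intron: donor, branchpoint element, acceptor spans.

    Spans are 0-based half-open on the sequence the call was made on.  The
    branch adenosine sits at ``bp_span.start + 4`` (fifth position of the
    branchpoint element).  ``phase`` (0/1/2 relative to codon boundaries)
    is ``None`` until coding context is established.
    """

    donor_span: Span
    bp_span: Span
    acceptor_span: Span
    phase: int | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        d, b, a = self.donor_span, self.bp_span, self.acceptor_span
        for s, e in (d, b, a):
            if s < 0 or s >= e:
                raise ValueError(f"degenerate span ({s},{e})")
        if self.strand == "+":
            ordered = d[1] <= b[0] and b[1] <= a[0]
        else:  # minus strand: forward coordinates, acceptor leftmost
            ordered = a[1] <= b[0] and b[1] <= d[0]
        if not ordered:
            raise ValueError("donor, branchpoint, acceptor spans must be ordered and disjoint")

    @property
    def intron_span(self) -> Span:
        if self.strand == "+":
            return (self.donor_span[0], self.acceptor_span[1])
        return (self.acceptor_span[0], self.donor_span[1])

    @property
    def length(self) -> int:
        s, e = self.intron_span
        return e - s

    @property
    def branch_a(self) -> int:
        """Coordinate of the branch adenosine (fifth bp-element position)."""
        if self.strand == "+":
            return self.bp_span[0] + 4
        return self.bp_span[1] - 5

    @property
    def donor_bp_distance(self) -> int:
        if self.strand == "+":
            return self.bp_span[0] - self.donor_span[1]
        return self.donor_span[0] - self.bp_span[1]

    @property
    def bp_acc_distance(self) -> int:
        if self.strand == "+":
            return self.acceptor_span[0] - self.bp_span[1]
        return self.bp_span[0] - self.acceptor_span[1]


def validate_intron(call: IntronCall, rules: DistanceRules = DEFAULT_RULES) -> tuple[bool, list[str]]:
    """Check ``call`` against ``rules``; return (ok, violated-rule labels).

    Labels: ``min_len``, ``donor_bp_gap``, ``bp_acc_gap``, ``principle3``.
    """
    violations: list[str] = []
    if call.length < rules.min_intron_len:
        violations.append("min_len")
    g1, g2 = call.donor_bp_distance, call.bp_acc_distance
    if not rules.donor_bp_gap[0] <= g1 <= rules.donor_bp_gap[1]:
        violations.append("donor_bp_gap")
    if not rules.bp_acc_gap[0] <= g2 <= rules.bp_acc_gap[1]:
        violations.append("bp_acc_gap")
    if rules.enforce_principle3 and not g1 > g2:
        violations.append("principle3")
    return (not violations, violations)


def _element_occurrences(seq: str, profile: ConsensusProfile):
    donors = _occurrences(profile.donor, seq)
    bps = _occurrences(profile.branchpoint, seq)
    accs = _occurrences(profile.acceptor, seq)
    return donors, bps, accs


def _best_call_for_acceptor(
    donor: int, acc: int, bps: list[int], profile: ConsensusProfile, rules: DistanceRules
) -> IntronCall | None:
    """Best valid call pairing a fixed donor and acceptor, or None.

    When several branchpoint placements serve the pair, the one nearest the
    acceptor wins (U2 scans proximal to the 3' site).
    """
    donor_end = donor + profile.donor.length
    if acc + profile.acceptor.length - donor < rules.min_intron_len:
        return None
    best: IntronCall | None = None
    for b in bps:
        if b < donor_end or b + profile.branchpoint.length > acc:
            continue
        call = IntronCall(
            donor_span=(donor, donor_end),
            bp_span=(b, b + profile.branchpoint.length),
            acceptor_span=(acc, acc + profile.acceptor.length),
        )
        if validate_intron(call, rules)[0]:
            if best is None or call.bp_span[0] > best.bp_span[0]:
                best = call
    return best


def find_acceptor_alternatives(
    seq: str,
    donor: int,
    profile: ConsensusProfile = RELAXED,
    rules: DistanceRules = DEFAULT_RULES,
) -> list[IntronCall]:
    """All valid introns for one donor, one per workable acceptor.

    Sorted by acceptor position (nearest first), so element ``[0]`` is the
    intron-definition choice and the rest are alternative 3' splice sites.
    ``seq`` must be normalized uppercase DNA.
    """
    seq = normalize_sequence(seq)
    if not matches_at(profile.donor, seq, donor):
        return []
    _, bps, accs = _element_occurrences(seq, profile)
    calls = []
    for a in accs:
        if a <= donor:
            continue
        call = _best_call_for_acceptor(donor, a, bps, profile, rules)
        if call is not None:
            calls.append(call)
    return calls


def find_introns(
    seq: str,
    profile: ConsensusProfile = RELAXED,
    rules: DistanceRules = DEFAULT_RULES,
) -> list[IntronCall]:
    """Call introns by nearest-pair intron definition.

    For every donor-motif occurrence, scanned 5'→3', the unique valid
    intron ending at the nearest workable acceptor is returned (smallest
    possible intron, subject to all distance rules); donors with no valid
    partner yield nothing.  Every donor gets at most one call; overlapping
    calls from different donors are all reported.  Result is sorted by
    intron start.
    """
    seq = normalize_sequence(seq)
    donors, bps, accs = _element_occurrences(seq, profile)
    calls: list[IntronCall] = []
    for d in donors:
        for a in accs:
            if a <= d:
                continue
            call = _best_call_for_acceptor(d, a, bps, profile, rules)
            if call is not None:
                calls.append(call)
                break
    calls.sort(key=lambda c: c.intron_span)
    return calls
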