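"""In-silico splicing under intron definition, with coordinate provenance.

The simulator treats a primary transcript as an :class:`RnaSpecies` whose
every nucleotide remembers its primary-transcript coordinate.  One
splicing reaction (:func:`splice_step`) excises one valid U2 intron —
found by nearest-pair intron definition on the *current* sequence — and
yields a child species with the excised footprint deleted from the
provenance map.  Because each step re-scans the whole current sequence,
splice sites that only come into existence after an excision (the
re-joined donor of a stwintron's external intron; a "second-order" intron
whose elements were separated by nested introns in the primary
transcript) are discovered rather than tracked.

:func:`splice_to_completion` expands breadth-first into a splice graph
(a DAG: different excision orders converge on identical intermediates).
With ``branch=True`` each step branches over every workable alternative
3' splice site of the current leftmost donor, which is the mechanism that
turns a donor-class stwintron into an exon-skipping switch.

Event flags
-----------
``standard``
    a plain contiguous intron.
``internal_of_stwintron``
    the excision re-joined a splice element that now belongs to a valid
    intron spanning the junction (it *enabled* an external intron).
``external_of_stwintron``
    one of the excised intron's own elements was discontiguous in the
    primary transcript (it had been interrupted by a nested intron).
``second_order``
    every element is contiguous in primary coordinates but the intron as
    a whole maps to >= 2 primary segments: it never existed contiguously
    in the primary transcript and was assembled by earlier excisions.
``alternative_acceptor``
    branch-mode child that did not use the nearest workable acceptor.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import networkx as nx

from .motifs import normalize_sequence
from .rules import (
    DEFAULT_RULES,
    RELAXED,
    ConsensusProfile,
    DistanceRules,
    IntronCall,
    find_acceptor_alternatives,
    find_introns,
)

__all__ = [
    "RnaSpecies",
    "SpliceEvent",
    "SpliceGraph",
    "GuardExceeded",
    "splice_step",
    "splice_to_completion",
    "detect_second_order",
    "classify_products",
    "enumerate_orders",
]

Span = tuple[int, int]


class GuardExceeded(RuntimeError):
    """Raised when graph expansion exceeds the node guard."""

    def __init__(self, message: str, partial: "SpliceGraph | None" = None):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class RnaSpecies:
    """A (possibly partially spliced) transcript with provenance.

    ``provenance[i]`` is the primary-transcript coordinate of base ``i``;
    it is strictly increasing and has one entry per base.
    """

    seq: str
    provenance: tuple[int, ...]
    label: str = "rna"

    def __post_init__(self) -> None:
        if len(self.provenance) != len(self.seq):
            raise ValueError("provenance length must equal sequence length")
        if any(b <= a for a, b in zip(self.provenance, self.provenance[1:])):
            raise ValueError("provenance must be strictly increasing")

    @classmethod
    def primary(cls, seq: str, label: str = "primary") -> "RnaSpecies":
        seq = normalize_sequence(seq)
        return cls(seq=seq, provenance=tuple(range(len(seq))), label=label)

    @property
    def key(self) -> tuple[str, tuple[int, ...]]:
        return (self.seq, self.provenance)


def _runs(coords: tuple[int, ...]) -> tuple[Span, ...]:
    """Collapse sorted primary coordinates into half-open segments."""
    if not coords:
        return ()
    segs = []
    start = prev = coords[0]
    for c in coords[1:]:
        if c != prev + 1:
            segs.append((start, prev + 1))
            start = c
        prev = c
    segs.append((start, prev + 1))
    return tuple(segs)


@dataclass(frozen=True)
class SpliceEvent:
    """One excision: the intron (parent coordinates) and its primary footprint."""

    intron: IntronCall
    primary_footprint: tuple[Span, ...]
    order_index: int = 0
    flags: frozenset[str] = frozenset()

    def signature(self) -> tuple:
        """Order-independent identity of the excised material."""
        return (self.primary_footprint, frozenset(self.flags - {"standard"}))


def detect_second_order(event: SpliceEvent) -> tuple[bool, int]:
    """Was the excised intron discontiguous in the primary transcript?

    Returns ``(flag, segment_count)``: True iff the intron's material maps
    to >= 2 distinct primary segments.  Note this is raw discontiguity —
    the external intron of a donor-class stwintron also reports True with
    2 segments (its donor was split by the internal intron); the stricter
    ``second_order`` event flag additionally requires every individual
    element to be contiguous.
    """
    n = len(event.primary_footprint)
    return (n >= 2, n)


def _segments_of_span(prov: tuple[int, ...], span: Span) -> int:
    return len(_runs(prov[span[0] : span[1]]))


def _structural_flags(parent: RnaSpecies, intron: IntronCall) -> set[str]:
    prov = parent.provenance
    s, e = intron.intron_span
    footprint_segs = len(_runs(prov[s:e]))
    elem_discontiguous = any(
        _segments_of_span(prov, sp) > 1
        for sp in (intron.donor_span, intron.bp_span, intron.acceptor_span)
    )
    flags: set[str] = set()
    if elem_discontiguous:
        flags.add("external_of_stwintron")
    elif footprint_segs >= 2:
        flags.add("second_order")
    return flags


def _enables_element(child: RnaSpecies, junction: int,
                     profile: ConsensusProfile, rules: DistanceRules) -> bool:
    """Did the excision create a splice element straddling the junction
    that belongs to a valid intron of the child?"""
    for call in find_introns(child.seq, profile, rules):
        for sp in (call.donor_span, call.bp_span, call.acceptor_span):
            if sp[0] < junction < sp[1]:
                return True
    return False


def _excise(parent: RnaSpecies, intron: IntronCall, order_index: int,
            profile: ConsensusProfile, rules: DistanceRules,
            alternative: bool = False,
            child_label: str | None = None) -> tuple[SpliceEvent, RnaSpecies]:
    s, e = intron.intron_span
    footprint = _runs(parent.provenance[s:e])
    child = RnaSpecies(
        seq=parent.seq[:s] + parent.seq[e:],
        provenance=parent.provenance[:s] + parent.provenance[e:],
        label=child_label or f"{parent.label}.x",
    )
    flags = _structural_flags(parent, intron)
    if not flags and _enables_element(child, s, profile, rules):
        flags.add("internal_of_stwintron")
    if alternative:
        flags.add("alternative_acceptor")
    if not flags - {"alternative_acceptor"}:
        flags.add("standard")
    event = SpliceEvent(
        intron=intron,
        primary_footprint=footprint,
        order_index=order_index,
        flags=frozenset(flags),
    )
    return event, child


def splice_step(
    species: RnaSpecies,
    profile: ConsensusProfile = RELAXED,
    rules: DistanceRules = DEFAULT_RULES,
    branch: bool = False,
    order_index: int = 1,
) -> list[tuple[SpliceEvent, RnaSpecies]]:
    """One round of splicing on ``species``.

    ``branch=False``: excise the leftmost valid intron (at most one
    child).  ``branch=True``: one child per workable (branchpoint,
    acceptor) choice of the leftmost donor that has any valid intron;
    children beyond the nearest acceptor are flagged
    ``alternative_acceptor``.  Empty list when no intron remains.
    """
    introns = find_introns(species.seq, profile, rules)
    if not introns:
        return []
    leftmost = introns[0]
    if not branch:
        chosen = [(leftmost, False)]
    else:
        donor = leftmost.donor_span[0]
        alts = find_acceptor_alternatives(species.seq, donor, profile, rules)
        chosen = [(call, i > 0) for i, call in enumerate(alts)]
    out = []
    for i, (intron, is_alt) in enumerate(chosen):
        out.append(
            _excise(species, intron, order_index, profile, rules,
                    alternative=is_alt, child_label=f"{species.label}.{i}")
        )
    return out


@dataclass
class SpliceGraph:
    """DAG of RNA species connected by single-excision events."""

    graph: nx.DiGraph
    root: tuple

    def species(self, key) -> RnaSpecies:
        return self.graph.nodes[key]["species"]

    @property
    def root_species(self) -> RnaSpecies:
        return self.species(self.root)

    def leaves(self) -> list[RnaSpecies]:
        return [
            self.species(n) for n in self.graph.nodes if self.graph.out_degree(n) == 0
        ]

    def events(self) -> list[SpliceEvent]:
        return [d["event"] for _, _, d in self.graph.edges(data=True)]

    def n_events_to(self, key) -> int:
        return nx.shortest_path_length(self.graph, self.root, key)

    def check_conservation(self) -> None:
        """Assert length conservation at every node.

        For every species, its length plus the total length excised along
        any path from the root equals the primary length.  With
        provenance this reduces to: the provenance of each node is a
        subset of the root's, and each edge removes exactly the parent
        minus the child coordinates (>= min intron length).
        """
        root_len = len(self.root_species.seq)
        for key in self.graph.nodes:
            sp = self.species(key)
            assert len(sp.seq) == len(sp.provenance)
            excised = root_len - len(sp.seq)
            if key != self.root:
                path = nx.shortest_path(self.graph, self.root, key)
                total = 0
                for a, b in zip(path, path[1:]):
                    ev = self.graph.edges[a, b]["event"]
                    total += sum(e - s for s, e in ev.primary_footprint)
                assert total == excised, "length conservation violated"


def splice_to_completion(
    primary: RnaSpecies,
    profile: ConsensusProfile = RELAXED,
    rules: DistanceRules = DEFAULT_RULES,
    branch: bool = False,
    max_nodes: int = 10_000,
) -> SpliceGraph:
    """Breadth-first splice-graph expansion until all leaves are intron-free.

    Duplicate species (identical sequence + provenance) are merged, so the
    result is a DAG.  Raises :class:`GuardExceeded` (carrying the partial
    graph) if more than ``max_nodes`` species are created.
    """
    if max_nodes <= 0:
        raise ValueError("max_nodes guard must be positive")
    g = nx.DiGraph()
    root_key = primary.key
    g.add_node(root_key, species=primary, depth=0)
    queue = [root_key]
    while queue:
        key = queue.pop(0)
        sp = g.nodes[key]["species"]
        depth = g.nodes[key]["depth"]
        for event, child in splice_step(sp, profile, rules, branch,
                                        order_index=depth + 1):
            ckey = child.key
            if ckey not in g:
                if g.number_of_nodes() >= max_nodes:
                    raise GuardExceeded(
                        f"splice graph exceeded {max_nodes} nodes",
                        partial=SpliceGraph(graph=g, root=root_key),
                    )
                g.add_node(ckey, species=child, depth=depth + 1)
                queue.append(ckey)
            if not g.has_edge(key, ckey):
                g.add_edge(key, ckey, event=event)
    return SpliceGraph(graph=g, root=root_key)


@dataclass(frozen=True)
class ExonSkip:
    """One leaf equals another minus one contiguous internal segment."""

    retained_label: str
    skipped_label: str
    primary_span: Span
    length: int


@dataclass(frozen=True)
class ProductReport:
    leaves: tuple[tuple[str, int, int], ...]  # (label, length, n_events)
    skips: tuple[ExonSkip, ...]


def classify_products(graph: SpliceGraph) -> ProductReport:
    """Compare mature products pairwise and report exon-skipping.

    A skip is reported when one leaf's provenance equals another's with a
    single contiguous, strictly internal block of primary coordinates
    deleted.
    """
    leaves = graph.leaves()
    skips: list[ExonSkip] = []
    for a, b in itertools.permutations(leaves, 2):
        pa, pb = set(a.provenance), set(b.provenance)
        if not (pb < pa):
            continue
        diff = sorted(pa - pb)
        runs = _runs(tuple(diff))
        if len(runs) != 1:
            continue
        # strictly internal: the deleted block is not a prefix/suffix of a
        idx = {c: i for i, c in enumerate(a.provenance)}
        lo, hi = idx[diff[0]], idx[diff[-1]]
        if lo == 0 or hi == len(a.provenance) - 1:
            continue
        skips.append(
            ExonSkip(
                retained_label=a.label,
                skipped_label=b.label,
                primary_span=runs[0],
                length=len(diff),
            )
        )
    leaf_info = tuple(
        (leaf.label, len(leaf.seq), graph.n_events_to(leaf.key)) for leaf in leaves
    )
    return ProductReport(leaves=leaf_info, skips=tuple(skips))


def enumerate_orders(
    primary: RnaSpecies,
    profile: ConsensusProfile = RELAXED,
    rules: DistanceRules = DEFAULT_RULES,
    max_states: int = 10_000,
) -> set[tuple[tuple, ...]]:
    """All orders in which the valid introns can be excised.

    At every intermediate, *each* currently valid intron (nearest-pair
    choice per donor, no alternative acceptors) may be excised next; the
    recursion enumerates every complete order down to an intron-free
    product.  Orders are returned as tuples of event signatures
    (primary footprint + structural flags), so the same excision is
    recognizable across orders.
    """
    orders: set[tuple[tuple, ...]] = set()
    states = 0

    def rec(species: RnaSpecies, prefix: tuple, depth: int) -> None:
        nonlocal states
        states += 1
        if states > max_states:
            raise GuardExceeded(f"order enumeration exceeded {max_states} states")
        introns = find_introns(species.seq, profile, rules)
        if not introns:
            orders.add(prefix)
            return
        for intron in introns:
            event, child = _excise(species, intron, depth + 1, profile, rules)
            rec(child, prefix + (event.signature(),), depth + 1)

    rec(primary, (), 0)
    return orders


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def graph_to_json(graph: SpliceGraph) -> str:
    labels = {key: graph.species(key).label for key in graph.graph.nodes}
    nodes = [
        {
            "label": labels[key],
            "seq": graph.species(key).seq,
            "provenance_runs": [list(r) for r in _runs(graph.species(key).provenance)],
            "is_root": key == graph.root,
            "is_leaf": graph.graph.out_degree(key) == 0,
        }
        for key in graph.graph.nodes
    ]
    edges = [
        {
            "parent": labels[a],
            "child": labels[b],
            "intron_span": list(d["event"].intron.intron_span),
            "primary_footprint": [list(r) for r in d["event"].primary_footprint],
            "order_index": d["event"].order_index,
            "flags": sorted(d["event"].flags),
        }
        for a, b, d in graph.graph.edges(data=True)
    ]
    return json.dumps({"nodes": nodes, "edges": edges}, indent=2, sort_keys=True)


def graph_to_dot(graph: SpliceGraph) -> str:
    lines = ["digraph splice {"]
    labels = {key: graph.species(key).label for key in graph.graph.nodes}
    for key in graph.graph.nodes:
        lines.append(f'  "{labels[key]}" [label="{labels[key]}\\n{len(graph.species(key).seq)} nt"];')
    for a, b, d in graph.graph.edges(data=True):
        flags = ",".join(sorted(d["event"].flags))
        lines.append(f'  "{labels[a]}" -> "{labels[b]}" [label="{flags}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
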