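"""Stwintron discovery: hybrid pattern construction, scanning, curation.

A spliceosomal twin intron (stwintron) is a complex intervening sequence
in which an *internal* U2 intron interrupts one of the three canonical
splice elements of an *external* U2 intron.  The three classes are named
for the interrupted element: [D] (donor), [L] (lariat branchpoint
element), [A] (acceptor); the split index records where within the element
the internal intron sits, so e.g. ``[D5,6]`` means the internal intron
lies between the fifth and sixth nucleotide of the external donor.

The scan works in two stages.  :func:`build_stwintron_pattern` assembles a
five-element gapped pattern whose first/last elements around the internal
intron are *hybrid* motifs (a piece of the interrupted external element
fused to an intact internal element).  :func:`scan_for_stwintrons` runs
that pattern, then verifies every raw hit by actually excising the
internal intron in silico: the re-joined external element must match the
uninterrupted consensus and the external intron must satisfy the distance
rules on the re-joined sequence.  The raw pattern is only a pre-filter;
the splicing model is the definition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

from .motifs import (
    GappedPattern,
    compile_motif,
    matches_at,
    normalize_sequence,
    reverse_complement,
    scan_gapped,
)
from .rules import (
    DEFAULT_RULES,
    RELAXED,
    ConsensusProfile,
    DistanceRules,
    IntronCall,
    validate_intron,
)

__all__ = [
    "StwintronClass",
    "StwintronCall",
    "build_stwintron_pattern",
    "call_from_elements",
    "scan_for_stwintrons",
    "curate_orf_context",
    "write_calls_gff",
    "read_calls_gff",
]

Span = tuple[int, int]

_SPLIT_RANGE = {"D": (1, 5), "L": (1, 5), "A": (1, 2)}


@dataclass(frozen=True)
class StwintronClass:
    """Stwintron class: which external element is interrupted, and where.

    ``kind`` is one of ``D`` (donor), ``L`` (branchpoint element,
    hypothetical — no published evidence), ``A`` (acceptor).  ``split`` is
    the number of element nucleotides 5' of the internal intron, so
    ``StwintronClass("D", 5)`` is the [D5,6] type.
    """

    kind: str
    split: int

    def __post_init__(self) -> None:
        if self.kind not in _SPLIT_RANGE:
            raise ValueError(f"unknown stwintron class kind {self.kind!r}")
        lo, hi = _SPLIT_RANGE[self.kind]
        if not lo <= self.split <= hi:
            raise ValueError(
                f"[{self.kind}] split must be in {lo}..{hi}, got {self.split}"
            )

    @property
    def label(self) -> str:
        return f"{self.kind}{self.split},{self.split + 1}"

    @property
    def hypothetical(self) -> bool:
        """[L] stwintrons have never been demonstrated experimentally."""
        return self.kind == "L"


D56 = StwintronClass("D", 5)


@dataclass(frozen=True)
class StwintronCall:
    """A verified stwintron candidate on a primary sequence.

    ``internal`` is an ordinary :class:`IntronCall`.  ``external`` is
    expressed in primary coordinates, so the span of its interrupted
    element *covers* the nested internal intron; the two real pieces of
    that element are in ``hybrid_spans``.  ``element_spans`` are the five
    matched pattern elements, in scan order.
    """

    stw_class: StwintronClass
    element_spans: tuple[Span, Span, Span, Span, Span]
    internal: IntronCall
    external: IntronCall
    hybrid_spans: tuple[Span, Span]
    seq_id: str | None = None
    strand: str = "+"
    orf_phases: tuple[int, ...] | None = None

    @property
    def total_span(self) -> Span:
        starts = [s for s, _ in self.element_spans]
        ends = [e for _, e in self.element_spans]
        return (min(starts), max(ends))

    @property
    def label(self) -> str:
        return self.stw_class.label


def build_stwintron_pattern(
    stw_class: StwintronClass,
    profile: ConsensusProfile = RELAXED,
    rules: DistanceRules = DEFAULT_RULES,
) -> GappedPattern:
    """Five-element hybrid pattern for one stwintron class.

    For class [D] with split s the elements are::

        donor[:s]+donor , BP , acceptor+donor[s:] , BP , acceptor

    i.e. the interrupted external donor contributes its prefix to the
    first hybrid element and its suffix to the third; gap windows come
    from ``rules``.  [L] and [A] place the interrupted element's pieces
    around the internal intron analogously.  For [L] and [A] the internal
    intron sits downstream of the pieces removed, so every pre-excision
    gap in the pattern equals the corresponding post-excision rule
    distance.
    """
    donor = profile.donor.pattern
    bp = profile.branchpoint.pattern
    acc = profile.acceptor.pattern
    g1, g2 = rules.donor_bp_gap, rules.bp_acc_gap
    s = stw_class.split
    if stw_class.kind == "D":
        elements = [donor[:s] + donor, bp, acc + donor[s:], bp, acc]
        gaps = [g1, g2, g1, g2]
    elif stw_class.kind == "L":
        elements = [donor, bp[:s] + donor, bp, acc + bp[s:], acc]
        gaps = [g1, g1, g2, g2]
    else:  # A
        elements = [donor, bp, acc[:s] + donor, bp, acc + acc[s:]]
        gaps = [g1, g2, g1, g2]
    return GappedPattern(
        elements=tuple(compile_motif(e) for e in elements), gaps=tuple(gaps)
    )


def call_from_elements(
    stw_class: StwintronClass,
    spans: Sequence[Span],
    seq_id: str | None = None,
    strand: str = "+",
) -> StwintronCall:
    """Assemble a :class:`StwintronCall` from the five element spans.

    ``spans`` are given in scan (biological 5'→3') order.  On the minus
    strand they carry forward coordinates, so scan order runs right to
    left along the sequence.
    """
    e1, e2, e3, e4, e5 = (tuple(s) for s in spans)
    s = stw_class.split

    if strand == "+":
        def sub(span: Span, i: int, j: int) -> Span:
            return (span[0] + i, span[0] + j)

        def cover(first: Span, last: Span) -> Span:
            return (first[0], last[1])
    else:
        def sub(span: Span, i: int, j: int) -> Span:
            return (span[1] - j, span[1] - i)

        def cover(first: Span, last: Span) -> Span:
            return (last[0], first[1])

    def intron(d: Span, b: Span, a: Span) -> IntronCall:
        return IntronCall(d, b, a, strand=strand)

    if stw_class.kind == "D":
        w = s + 6  # hybrid element 1 width: donor prefix + internal donor
        internal = intron(sub(e1, s, w), e2, sub(e3, 0, 3))
        external = intron(cover(e1, e3), e4, e5)
        hybrid = (sub(e1, 0, s), sub(e3, 3, 3 + (6 - s)))
    elif stw_class.kind == "L":
        w = s + 6
        internal = intron(sub(e2, s, w), e3, sub(e4, 0, 3))
        external = intron(e1, cover(e2, e4), e5)
        hybrid = (sub(e2, 0, s), sub(e4, 3, 3 + (6 - s)))
    else:  # A
        w = s + 6
        internal = intron(sub(e3, s, w), e4, sub(e5, 0, 3))
        external = intron(e1, e2, cover(e3, e5))
        hybrid = (sub(e3, 0, s), sub(e5, 3, 3 + (3 - s)))
    return StwintronCall(
        stw_class=stw_class,
        element_spans=(e1, e2, e3, e4, e5),
        internal=internal,
        external=external,
        hybrid_spans=hybrid,
        seq_id=seq_id,
        strand=strand,
    )


def rejoined_external(call: StwintronCall, seq: str) -> tuple[str, IntronCall]:
    """Excise the internal intron; return (re-joined seq, external call).

    The returned :class:`IntronCall` is in re-joined coordinates with the
    interrupted element made contiguous again.
    """
    i0, i1 = call.internal.intron_span
    rejoined = seq[:i0] + seq[i1:]
    shift = i1 - i0

    def m(span: Span) -> Span:
        return span if span[1] <= i0 else (span[0] - shift, span[1] - shift)

    h1, _h2 = call.hybrid_spans
    if call.stw_class.kind == "D":
        ext = IntronCall(
            (h1[0], h1[0] + 6), m(call.element_spans[3]), m(call.element_spans[4])
        )
    elif call.stw_class.kind == "L":
        ext = IntronCall(
            call.element_spans[0], (h1[0], h1[0] + 6), m(call.element_spans[4])
        )
    else:  # A
        ext = IntronCall(
            call.element_spans[0], call.element_spans[1], (h1[0], h1[0] + 3)
        )
    return rejoined, ext


def verify_call(
    call: StwintronCall,
    seq: str,
    profile: ConsensusProfile = RELAXED,
    rules: DistanceRules = DEFAULT_RULES,
) -> bool:
    """Mandatory post-filter: the splicing model, not just the pattern.

    The internal intron must be valid as-is, and after in-silico excision
    the re-joined external element must match the *uninterrupted* consensus
    motif and the external intron must pass the distance rules on the
    re-joined sequence.
    """
    if not validate_intron(call.internal, rules)[0]:
        return False
    rejoined, ext = rejoined_external(call, seq)
    for motif, span in (
        (profile.donor, ext.donor_span),
        (profile.branchpoint, ext.bp_span),
        (profile.acceptor, ext.acceptor_span),
    ):
        if span[1] > len(rejoined) or not matches_at(motif, rejoined, span[0]):
            return False
    return validate_intron(ext, rules)[0]


def _flip(span: Span, length: int) -> Span:
    """Map a reverse-complement-coordinate span onto the forward strand."""
    return (length - span[1], length - span[0])


def reverse_call_to_forward(call: StwintronCall, seq_len: int) -> StwintronCall:
    """Re-express a call made on the reverse complement in forward coords.

    Element spans stay in scan order (element 1 is the biological 5'-most
    element, which on the forward strand has the highest coordinates);
    internal/external sub-calls carry ``strand="-"`` and the
    reversed-orientation span invariant.
    """
    spans = tuple(_flip(sp, seq_len) for sp in call.element_spans)
    return call_from_elements(call.stw_class, spans, call.seq_id, "-")


def scan_for_stwintrons(
    seq: str,
    stw_class: StwintronClass = D56,
    profile: ConsensusProfile = RELAXED,
    rules: DistanceRules = DEFAULT_RULES,
    seq_id: str | None = None,
    strand: str = "+",
) -> list[StwintronCall]:
    """Scan one sequence for stwintrons of one class.

    ``strand`` is ``"+"`` (forward only, the default), ``"-"``, or
    ``"both"``; reverse-strand hits are reported with forward-strand
    coordinates and ``strand="-"``.  Hits failing excision-and-rejoin
    verification are dropped.
    """
    seq = normalize_sequence(seq)
    pattern = build_stwintron_pattern(stw_class, profile, rules)
    calls: list[StwintronCall] = []

    if strand in ("+", "both"):
        for match in scan_gapped(pattern, seq):
            call = call_from_elements(stw_class, match.element_spans, seq_id, "+")
            if verify_call(call, seq, profile, rules):
                calls.append(call)
    if strand in ("-", "both"):
        rc = reverse_complement(seq)
        for match in scan_gapped(pattern, rc):
            call = call_from_elements(stw_class, match.element_spans, seq_id, "+")
            if verify_call(call, rc, profile, rules):
                calls.append(reverse_call_to_forward(call, len(seq)))
    calls.sort(key=lambda c: (min(c.total_span), c.strand))
    return calls


_STOPS = {"TAA", "TAG", "TGA"}


def curate_orf_context(
    calls: Iterable[StwintronCall],
    seq: str,
    window: int = 60,
) -> list[StwintronCall]:
    """Keep calls that plausibly separate coding sequence.

    For each call the whole complex intervening sequence is excised in
    silico and the junction is examined: the call is retained iff at least
    one reading frame crosses the junction without a stop codon within
    ``window`` nt on either side.  Surviving frames are annotated on the
    call as intron phases (junction offset within the codon).
    """
    if window < 3:
        raise ValueError("window must be at least 3 nt")
    seq = normalize_sequence(seq)
    kept: list[StwintronCall] = []
    for call in calls:
        s, e = call.total_span
        spliced = seq[:s] + seq[e:]
        j = s
        lo = max(0, j - window)
        hi = min(len(spliced), j + window)
        phases: list[int] = []
        for f in range(3):
            # codon starts at absolute spliced positions ≡ f (mod 3)
            start = lo + ((f - lo) % 3)
            ok = True
            for p in range(start, hi - 2, 3):
                if spliced[p : p + 3] in _STOPS:
                    ok = False
                    break
            if ok:
                phases.append((j - f) % 3)
        if phases:
            kept.append(dataclasses.replace(call, orf_phases=tuple(sorted(set(phases)))))
    return kept


# ---------------------------------------------------------------------------
# GFF3 emission.  Feature types: `twin_intron` parent, `intron` children,
# element children typed splice_donor / branch_point / splice_acceptor.
# Internal coordinates are 0-based half-open; GFF3 is 1-based inclusive.
# ---------------------------------------------------------------------------

_ELEMENT_TYPES = {
    "D": ("splice_donor", "branch_point", "splice_acceptor", "branch_point", "splice_acceptor"),
    "L": ("splice_donor", "branch_point", "branch_point", "splice_acceptor", "splice_acceptor"),
    "A": ("splice_donor", "branch_point", "splice_acceptor", "branch_point", "splice_acceptor"),
}


def _gff_line(seqid, ftype, span, attrs, strand="+"):
    s, e = span
    attr = ";".join(f"{k}={v}" for k, v in attrs)
    return f"{seqid}\t{'stwinscan'}\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attr}"


def write_calls_gff(calls: Sequence[StwintronCall], seq_id: str, handle: TextIO) -> None:
    """Write calls as GFF3 (deterministic ordering, round-trippable)."""
    handle.write("##gff-version 3\n")
    for i, call in enumerate(sorted(calls, key=lambda c: (c.strand, c.total_span)), 1):
        sid = call.seq_id or seq_id
        pid = f"stw{i}"
        attrs = [("ID", pid), ("stw_class", call.label)]
        if call.stw_class.hypothetical:
            attrs.append(("status", "hypothetical"))
        if call.orf_phases is not None:
            attrs.append(("orf_phases", ",".join(str(p) for p in call.orf_phases)))
        handle.write(_gff_line(sid, "twin_intron", call.total_span, attrs, call.strand) + "\n")
        handle.write(
            _gff_line(
                sid,
                "intron",
                call.internal.intron_span,
                [("ID", f"{pid}.internal"), ("Parent", pid), ("role", "internal")],
                call.strand,
            )
            + "\n"
        )
        handle.write(
            _gff_line(
                sid,
                "intron",
                call.external.intron_span,
                [("ID", f"{pid}.external"), ("Parent", pid), ("role", "external")],
                call.strand,
            )
            + "\n"
        )
        types = _ELEMENT_TYPES[call.stw_class.kind]
        for k, (span, ftype) in enumerate(zip(call.element_spans, types), 1):
            handle.write(
                _gff_line(
                    sid,
                    ftype,
                    span,
                    [("ID", f"{pid}.e{k}"), ("Parent", pid), ("element_index", k)],
                    call.strand,
                )
                + "\n"
            )


def read_calls_gff(handle: TextIO) -> list[StwintronCall]:
    """Read GFF3 written by :func:`write_calls_gff` back into calls."""
    parents: dict[str, dict] = {}
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        seqid, _src, ftype, start, end, _score, strand, _phase, attr = cols
        attrs = dict(kv.split("=", 1) for kv in attr.split(";") if kv)
        span = (int(start) - 1, int(end))
        if ftype == "twin_intron":
            parents[attrs["ID"]] = {
                "seqid": seqid,
                "strand": strand,
                "stw_class": attrs["stw_class"],
                "orf_phases": attrs.get("orf_phases"),
                "elements": {},
            }
        elif "Parent" in attrs and "element_index" in attrs:
            parents[attrs["Parent"]]["elements"][int(attrs["element_index"])] = span
    calls = []
    for pid in sorted(parents):
        rec = parents[pid]
        label = rec["stw_class"]
        kind, nums = label[0], label[1:]
        split = int(nums.split(",")[0])
        spans = tuple(rec["elements"][k] for k in range(1, 6))
        call = call_from_elements(
            StwintronClass(kind, split), spans, seq_id=rec["seqid"], strand=rec["strand"]
        )
        if rec["orf_phases"]:
            call = dataclasses.replace(
                call, orf_phases=tuple(int(x) for x in rec["orf_phases"].split(","))
            )
        calls.append(call)
    calls.sort(key=lambda c: (c.strand, c.total_span))
    return calls
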