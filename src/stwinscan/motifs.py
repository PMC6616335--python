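"""Degenerate IUPAC nucleotide motifs and gapped multi-element patterns.

A :class:`DegenerateMotif` is a fixed-length word over the IUPAC nucleotide
alphabet (e.g. ``GTRWGY`` for the canonical U2 donor site).  A
:class:`GappedPattern` strings several motifs together with bounded spacer
windows and is the search unit used to screen genomic sequence for nested
(twin) introns.  Pattern strings are accepted verbatim in the textual
format used for genome screens, e.g.::

    GTRWGGTRWGH(25,120)DYTRAY(4,24)HAGH(25,120)DYTRAY(4,24)HAG

where ``(min,max)`` is the allowed distance in nucleotides from the end of
one motif element to the start of the next.

Two scanners are provided: :func:`scan_gapped`, the production scanner that
joins per-element occurrence lists, and :func:`brute_force_scan`, a
deliberately naive exhaustive enumeration kept as an independent reference
oracle for property tests.  Both obey the same ordering contract so their
outputs are directly comparable.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "IUPAC_DNA",
    "DegenerateMotif",
    "GappedPattern",
    "PatternMatch",
    "compile_motif",
    "matches_at",
    "parse_pattern_string",
    "scan_gapped",
    "brute_force_scan",
    "normalize_sequence",
    "reverse_complement",
]

#: Per-code allowed base sets over {A,C,G,T}.
IUPAC_DNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and fold RNA (U) onto DNA (T)."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return normalize_sequence(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DegenerateMotif:
    """A fixed-length degenerate nucleotide word.

    ``allowed[i]`` holds the set of concrete bases accepted at position
    ``i``.  The base ``N`` in a *sequence* never matches any motif
    position, regardless of the motif code: a scanner must not call splice
    elements inside undetermined stretches of a draft assembly.
    """

    pattern: str
    allowed: tuple[frozenset[str], ...]

    @property
    def length(self) -> int:
        return len(self.pattern)

    def to_regex(self) -> str:
        """Translate to a concrete-base regex (no N on the sequence side)."""
        return "".join("[" + "".join(sorted(s)) + "]" for s in self.allowed)


@dataclass(frozen=True)
class GappedPattern:
    """Ordered motif elements separated by (min, max) gap windows."""

    elements: tuple[DegenerateMotif, ...]
    gaps: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.gaps) != len(self.elements) - 1:
            raise ValueError(
                f"need {len(self.elements) - 1} gap windows for "
                f"{len(self.elements)} elements, got {len(self.gaps)}"
            )
        for lo, hi in self.gaps:
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid gap window ({lo},{hi})")

    @property
    def min_total_span(self) -> int:
        return sum(e.length for e in self.elements) + sum(lo for lo, _ in self.gaps)

    def serialize(self) -> str:
        """Render back to the textual pattern format."""
        parts = [self.elements[0].pattern]
        for (lo, hi), elem in zip(self.gaps, self.elements[1:]):
            parts.append(f"({lo},{hi})")
            parts.append(elem.pattern)
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()


@dataclass(frozen=True)
class PatternMatch:
    """One placement of every element of a :class:`GappedPattern`."""

    element_spans: tuple[tuple[int, int], ...]

    @property
    def total_span(self) -> tuple[int, int]:
        return (self.element_spans[0][0], self.element_spans[-1][1])

    def _sort_key(self) -> tuple:
        return (self.total_span[0], tuple(s for s, _ in self.element_spans))


def compile_motif(pattern: str) -> DegenerateMotif:
    """Compile an IUPAC string (DNA or RNA alphabet, any case) to a motif.

    Raises :class:`ValueError` naming the 1-based position of the first
    character that is not a valid IUPAC nucleotide code.
    """
    if not pattern:
        raise ValueError("empty motif pattern")
    norm = normalize_sequence(pattern)
    allowed = []
    for i, ch in enumerate(norm):
        try:
            allowed.append(IUPAC_DNA[ch])
        except KeyError:
            raise ValueError(
                f"invalid IUPAC code {ch!r} at position {i + 1} in motif {pattern!r}"
            ) from None
    return DegenerateMotif(pattern=norm, allowed=tuple(allowed))


def matches_at(motif: DegenerateMotif, seq: str, pos: int) -> bool:
    """Does ``motif`` match (normalized, uppercase) ``seq`` at ``pos``?

    ``pos`` must satisfy ``0 <= pos <= len(seq) - motif.length``; anything
    else is a caller error, not a mismatch.
    """
    if pos < 0 or pos > len(seq) - motif.length:
        raise IndexError(
            f"position {pos} out of range for motif of length {motif.length} "
            f"on sequence of length {len(seq)}"
        )
    return all(seq[pos + i] in motif.allowed[i] for i in range(motif.length))


_TOKEN = re.compile(r"([A-Za-z]+)|\((\d+),(\d+)\)")


def parse_pattern_string(text: str) -> GappedPattern:
    """Parse ``MOTIF(min,max)MOTIF...`` into a :class:`GappedPattern`."""
    text = text.strip()
    if not text:
        raise ValueError("empty pattern string")
    elements: list[DegenerateMotif] = []
    gaps: list[tuple[int, int]] = []
    pos = 0
    expect_motif = True
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            raise ValueError(f"malformed pattern string at offset {pos}: {text[pos:pos+12]!r}")
        if m.group(1) is not None:
            if not expect_motif:
                raise ValueError("two adjacent motif literals without a gap token")
            elements.append(compile_motif(m.group(1)))
            expect_motif = False
        else:
            if expect_motif:
                raise ValueError("gap token where a motif literal was expected")
            lo, hi = int(m.group(2)), int(m.group(3))
            if lo > hi:
                raise ValueError(f"gap window ({lo},{hi}) has min > max")
            gaps.append((lo, hi))
            expect_motif = True
        pos = m.end()
    if expect_motif:
        raise ValueError("pattern string ends with a trailing gap token")
    return GappedPattern(elements=tuple(elements), gaps=tuple(gaps))


def _occurrences(motif: DegenerateMotif, seq: str) -> list[int]:
    """All (overlapping) start positions of ``motif`` in normalized ``seq``."""
    rx = re.compile("(?=" + motif.to_regex() + ")")
    return [m.start() for m in rx.finditer(seq)]


def scan_gapped(pattern: GappedPattern, seq: str) -> list[PatternMatch]:
    """All placements of ``pattern`` in ``seq``.

    Every combination of element placements that satisfies the motifs and
    the declared gap windows is reported, including overlapping ones;
    downstream modules decide which survive.  Output is deterministic:
    sorted by total-span start, then lexicographically by element starts.
    """
    seq = normalize_sequence(seq)
    if len(seq) < pattern.min_total_span:
        return []
    occ = [_occurrences(e, seq) for e in pattern.elements]
    if any(not o for o in occ):
        return []
    results: list[PatternMatch] = []
    n = len(pattern.elements)
    lengths = [e.length for e in pattern.elements]

    def extend(idx: int, spans: list[tuple[int, int]]) -> None:
        if idx == n:
            results.append(PatternMatch(element_spans=tuple(spans)))
            return
        lo, hi = pattern.gaps[idx - 1]
        prev_end = spans[-1][1]
        import bisect

        starts = occ[idx]
        i = bisect.bisect_left(starts, prev_end + lo)
        while i < len(starts) and starts[i] <= prev_end + hi:
            s = starts[i]
            spans.append((s, s + lengths[idx]))
            extend(idx + 1, spans)
            spans.pop()
            i += 1

    for s in occ[0]:
        extend(1, [(s, s + lengths[0])])
    results.sort(key=PatternMatch._sort_key)
    return results


#: brute_force_scan refuses sequences longer than this.
BRUTE_FORCE_GUARD = 10_000


def brute_force_scan(pattern: GappedPattern, seq: str) -> list[PatternMatch]:
    """Reference oracle: exhaustive nested enumeration of element starts.

    Loops over every start position for every element with only
    :func:`matches_at` and an explicit gap-window check — no occurrence
    indexing, no regex — so it shares no machinery with
    :func:`scan_gapped`.  Guarded to sequences of at most
    ``BRUTE_FORCE_GUARD`` nt.
    """
    seq = normalize_sequence(seq)
    if len(seq) > BRUTE_FORCE_GUARD:
        raise ValueError(
            f"brute_force_scan guard exceeded: {len(seq)} > {BRUTE_FORCE_GUARD} nt"
        )
    n = len(pattern.elements)
    lengths = [e.length for e in pattern.elements]
    results: list[PatternMatch] = []

    def recurse(idx: int, spans: list[tuple[int, int]]) -> None:
        if idx == n:
            results.append(PatternMatch(element_spans=tuple(spans)))
            return
        elem = pattern.elements[idx]
        for start in range(0, len(seq) - lengths[idx] + 1):
            if idx > 0:
                gap = start - spans[-1][1]
                lo, hi = pattern.gaps[idx - 1]
                if gap < lo or gap > hi:
                    continue
            if matches_at(elem, seq, start):
                spans.append((start, start + lengths[idx]))
                recurse(idx + 1, spans)
                spans.pop()

    recurse(0, [])
    results.sort(key=PatternMatch._sort_key)
    return results
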