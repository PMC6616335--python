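"""Synthetic genomes with planted introns, stwintrons and truth annotations.

Every other module is tested against sequence this module fabricates: a
random background with splice features planted at known coordinates, plus
a machine-readable :class:`TruthAnnotation` stating exactly what a scanner
must recover and what shape the splice graph must take.

Backgrounds are *motif-free* by default: donor- and branchpoint-motif
occurrences outside planted elements are repaired away (one base of each
stray occurrence is resampled), and acceptor motifs are likewise repaired
inside and for a margin around each planted feature.  A donor-free
background cannot produce an intron call or a gapped-pattern hit, so on
these fixtures a zero-false-positive assertion is meaningful and exact
single-hit recovery of each planted feature is guaranteed by construction
— which each ``plant_*`` function verifies by actually scanning and
splicing its own output before returning it.

Default geometries mirror the experimentally characterized loci:

* plain [D5,6] stwintron: internal intron 75 nt, external 76 nt;
* alternative-acceptor fixture ("black-Aspergillus style"): a second CAG
  26 nt downstream of the internal intron's acceptor with its own
  branchpoint element, a 15-nt skippable exon, and a 60-nt standard
  intron behind it — the 3'-extended secondary internal intron is 29 nt
  longer;
* the "crassa" variant re-uses the external intron's acceptor as the
  alternative internal 3' splice site and skips a 33-nt exon;
* dual intervening sequence: a [D5,6] stwintron and a standard intron
  nested inside a discontinuous second-order intron whose donor,
  branchpoint element and acceptor only become contiguous after three
  prior excisions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .motifs import DegenerateMotif, _occurrences
from .rules import (
    DEFAULT_RULES,
    RELAXED,
    ConsensusProfile,
    DistanceRules,
    IntronCall,
    find_introns,
    validate_intron,
)
from .scanner import (
    D56,
    StwintronCall,
    StwintronClass,
    call_from_elements,
    scan_for_stwintrons,
    write_calls_gff,
)
from .simulate import RnaSpecies, classify_products, splice_to_completion

__all__ = [
    "FixtureError",
    "FixtureSpec",
    "StwintronGeometry",
    "StandardIntronGeometry",
    "TruthAnnotation",
    "random_background",
    "plant_stwintron",
    "plant_alt_acceptor_fixture",
    "plant_dual_is_fixture",
    "write_fixture",
    "read_fixture",
]

Span = tuple[int, int]


class FixtureError(ValueError):
    """A requested fixture geometry is impossible or failed verification."""


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardIntronGeometry:
    """A plain U2 intron of the given total length."""

    length: int = 60
    gaps: Span | None = None  # (donor→BP, BP→acceptor); derived if None


@dataclass(frozen=True)
class StwintronGeometry:
    """A stwintron: class, split, and internal/external intron lengths."""

    stw_class: StwintronClass = D56
    internal_len: int = 75
    external_len: int = 76
    int_gaps: Span | None = None
    ext_gaps: Span | None = None


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic genome.

    ``background_len`` is the total non-feature sequence; features are
    placed in order with background chunks between and around them.
    ``coding`` plants a coding context across the first feature's junction:
    ``"clean"`` leaves exactly one reading frame (of the requested
    ``phase``) stop-free through the junction, ``"stops"`` plants stop
    codons in all three frames just downstream.
    """

    seed: int = 0
    background_len: int = 2000
    gc: float = 0.5
    motif_free_background: bool = True
    features: tuple = (StwintronGeometry(),)
    coding: str | None = None
    phase: int = 1

    def __post_init__(self) -> None:
        if self.background_len <= 0:
            raise FixtureError("background_len must be positive")
        if not 0.0 <= self.gc <= 1.0:
            raise FixtureError("gc must be a fraction in [0,1]")
        if self.coding not in (None, "clean", "stops"):
            raise FixtureError("coding must be None, 'clean' or 'stops'")


def derive_intron_gaps(
    length: int, rules: DistanceRules = DEFAULT_RULES, large_donor_gap: bool = False
) -> Span:
    """Pick (donor→BP, BP→acceptor) distances realizing a total length.

    The element lengths 6+6+3 are fixed, so the two gaps must sum to
    ``length - 15``.  ``large_donor_gap`` pushes the donor→BP distance to
    >= 52 nt when possible (used for external introns so that an internal
    donor cannot legally reach past the whole stwintron).  Raises
    :class:`FixtureError` naming the violated rule when no valid split
    exists.
    """
    if length < rules.min_intron_len:
        raise FixtureError(
            f"min_len: intron of {length} nt is shorter than the "
            f"{rules.min_intron_len} nt minimum"
        )
    g_sum = length - 15
    lo2, hi2 = rules.bp_acc_gap
    if large_donor_gap:
        g2 = max(lo2, min(hi2, g_sum - 52))
    else:
        g2 = max(lo2, min(hi2, g_sum - rules.donor_bp_gap[0], (g_sum - 1) // 2))
    g1 = g_sum - g2
    probe = IntronCall((0, 6), (6 + g1, 12 + g1), (12 + g1 + g2, 15 + g1 + g2))
    ok, violations = validate_intron(probe, rules)
    if not ok:
        raise FixtureError(
            f"{violations[0]}: no valid gap split for a {length} nt intron"
        )
    return (g1, g2)


# ---------------------------------------------------------------------------
# Sequence sampling and motif repair
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _rng_for(seed, attempt: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, attempt])


def sample_motif(motif: DegenerateMotif, rng: np.random.Generator) -> str:
    """One concrete word, per-position uniform over the allowed sets."""
    return "".join(
        sorted(allowed)[rng.integers(len(allowed))] for allowed in motif.allowed
    )


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(_BASES, size=n, p=p))


def _scrub(
    chars: list[str],
    protected: list[Span],
    rng: np.random.Generator,
    global_motifs: tuple[DegenerateMotif, ...],
    zoned_motifs: tuple[DegenerateMotif, ...] = (),
    zones: tuple[Span, ...] = (),
    max_passes: int = 400,
) -> None:
    """Repair stray motif occurrences in place.

    ``global_motifs`` are removed everywhere, ``zoned_motifs`` only where
    they intersect one of ``zones``.  An occurrence wholly inside a
    protected interval is planted and left alone; otherwise one mutable
    base is resampled to a base the motif forbids at that position.
    """

    def is_protected(pos: int) -> bool:
        return any(s <= pos < e for s, e in protected)

    def offending():
        seq = "".join(chars)
        for motif in global_motifs:
            for start in _occurrences(motif, seq):
                span = (start, start + motif.length)
                if all(is_protected(p) for p in range(*span)):
                    continue
                yield motif, span
        for motif in zoned_motifs:
            for start in _occurrences(motif, seq):
                span = (start, start + motif.length)
                if not any(s < span[1] and span[0] < e for s, e in zones):
                    continue
                if all(is_protected(p) for p in range(*span)):
                    continue
                yield motif, span

    for _ in range(max_passes):
        hit = next(iter(offending()), None)
        if hit is None:
            return
        motif, (start, end) = hit
        mutable = [p for p in range(start, end) if not is_protected(p)]
        if not mutable:
            raise FixtureError(
                "cannot repair a stray motif occurrence inside planted elements"
            )
        p = mutable[rng.integers(len(mutable))]
        forbidden = sorted(set("ACGT") - motif.allowed[p - start])
        chars[p] = forbidden[rng.integers(len(forbidden))]
    raise FixtureError("motif repair did not converge")


def random_background(
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    motif_free: bool = True,
    profile: ConsensusProfile = RELAXED,
) -> str:
    """Reproducible random sequence, optionally donor/branchpoint-free."""
    if length <= 0:
        raise FixtureError("background length must be positive")
    rng = _rng_for(seed)
    chars = _random_bases(length, gc, rng)
    if motif_free:
        _scrub(chars, [], rng, (profile.donor, profile.branchpoint))
    return "".join(chars)


# ---------------------------------------------------------------------------
# Truth annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthAnnotation:
    """Everything a test needs to judge scanner and simulator output."""

    seq_id: str
    genome_len: int
    stwintrons: tuple[StwintronCall, ...] = ()
    introns: tuple[IntronCall, ...] = ()
    mature_seq: str = ""
    expected_nodes: int | None = None
    expected_events: int | None = None
    expected_last_flags: frozenset | None = None
    expected_leaves: int | None = None
    skip_length: int | None = None
    phase: int | None = None
    notes: dict = field(default_factory=dict)


def _mature_from_removals(genome: str, removals: list[Span]) -> str:
    keep = []
    pos = 0
    for s, e in sorted(removals):
        keep.append(genome[pos:s])
        pos = e
    keep.append(genome[pos:])
    return "".join(keep)


# ---------------------------------------------------------------------------
# Feature builders (relative coordinates; element spans in scan order)
# ---------------------------------------------------------------------------

@dataclass
class _Built:
    seq: list[str]
    element_spans: list[Span]       # protected motif spans, relative
    stw_elements: list[Span] | None = None  # the 5 scan-order spans
    intron_spans: list[Span] = field(default_factory=list)  # standalone introns


def _build_standard_intron(
    geom: StandardIntronGeometry, profile: ConsensusProfile,
    rules: DistanceRules, rng: np.random.Generator, gc: float,
) -> _Built:
    g1, g2 = geom.gaps or derive_intron_gaps(geom.length, rules)
    donor = sample_motif(profile.donor, rng)
    bp = sample_motif(profile.branchpoint, rng)
    acc = sample_motif(profile.acceptor, rng)
    seq = (
        list(donor) + _random_bases(g1, gc, rng) + list(bp)
        + _random_bases(g2, gc, rng) + list(acc)
    )
    spans = [(0, 6), (6 + g1, 12 + g1), (12 + g1 + g2, 15 + g1 + g2)]
    return _Built(seq=seq, element_spans=spans, intron_spans=[(0, len(seq))])


_CLASS_GAP_ORDER = {
    # which concrete gap value sits between consecutive pattern elements
    "D": ("g1i", "g2i", "g1e", "g2e"),
    "L": ("g1e", "g1i", "g2i", "g2e"),
    "A": ("g1e", "g2e", "g1i", "g2i"),
}


def _build_stwintron(
    geom: StwintronGeometry, profile: ConsensusProfile,
    rules: DistanceRules, rng: np.random.Generator, gc: float,
) -> _Built:
    cls = geom.stw_class
    g1i, g2i = geom.int_gaps or derive_intron_gaps(geom.internal_len, rules)
    g1e, g2e = geom.ext_gaps or derive_intron_gaps(
        geom.external_len, rules, large_donor_gap=(cls.kind == "D")
    )
    gaps = {"g1i": g1i, "g2i": g2i, "g1e": g1e, "g2e": g2e}
    s = cls.split
    donor_ext = sample_motif(profile.donor, rng)
    bp_ext = sample_motif(profile.branchpoint, rng)
    acc_ext = sample_motif(profile.acceptor, rng)
    donor_int = sample_motif(profile.donor, rng)
    bp_int = sample_motif(profile.branchpoint, rng)
    acc_int = sample_motif(profile.acceptor, rng)
    if cls.kind == "D":
        elements = [donor_ext[:s] + donor_int, bp_int, acc_int + donor_ext[s:],
                    bp_ext, acc_ext]
    elif cls.kind == "L":
        elements = [donor_ext, bp_ext[:s] + donor_int, bp_int,
                    acc_int + bp_ext[s:], acc_ext]
    else:  # A
        elements = [donor_ext, bp_ext, acc_ext[:s] + donor_int,
                    bp_int, acc_int + acc_ext[s:]]
    gap_values = [gaps[k] for k in _CLASS_GAP_ORDER[cls.kind]]
    seq: list[str] = []
    spans: list[Span] = []
    for i, elem in enumerate(elements):
        if i > 0:
            seq.extend(_random_bases(gap_values[i - 1], gc, rng))
        spans.append((len(seq), len(seq) + len(elem)))
        seq.extend(elem)
    return _Built(seq=seq, element_spans=list(spans), stw_elements=list(spans))


# ---------------------------------------------------------------------------
# Assembly and verification
# ---------------------------------------------------------------------------

_ACC_MARGIN = 160  # acceptor repair margin past each feature (covers the
                   # longest reachable pattern tail: 120 + 6 + 24 + slack)


def _assemble(
    spec: FixtureSpec,
    builds: list[_Built],
    profile: ConsensusProfile,
    rules: DistanceRules,
    rng: np.random.Generator,
    min_chunk: int = 130,
) -> tuple[str, list[dict]]:
    """Interleave background chunks and features; repair stray motifs.

    Returns the genome string and, per feature, its absolute element /
    intron spans.  Background chunks are at least ``min_chunk`` nt so
    that no donor in one feature can legally pair into the next.
    """
    n = len(builds)
    base = spec.background_len // (n + 1)
    if base < min_chunk:
        raise FixtureError(
            f"background_len {spec.background_len} too small for {n} feature(s)"
        )
    jitter = base // 5
    chunk_lens = [
        base + int(rng.integers(-jitter, jitter + 1)) for _ in range(n)
    ]
    chunk_lens.append(spec.background_len - sum(chunk_lens))
    if min(chunk_lens) < min_chunk:
        chunk_lens = [base] * n + [spec.background_len - base * n]

    chars: list[str] = []
    protected: list[Span] = []
    zones: list[Span] = []
    placed: list[dict] = []
    for built, clen in zip(builds, chunk_lens[:-1]):
        chars.extend(_random_bases(clen, spec.gc, rng))
        offset = len(chars)
        chars.extend(built.seq)
        end = len(chars)
        protected.extend((offset + s, offset + e) for s, e in built.element_spans)
        zones.append((offset, min(end + _ACC_MARGIN, None or 10**9)))
        placed.append(
            {
                "span": (offset, end),
                "elements": [(offset + s, offset + e) for s, e in built.element_spans],
                "stw_elements": None
                if built.stw_elements is None
                else [(offset + s, offset + e) for s, e in built.stw_elements],
                "introns": [(offset + s, offset + e) for s, e in built.intron_spans],
            }
        )
    chars.extend(_random_bases(chunk_lens[-1], spec.gc, rng))
    genome_len = len(chars)
    zones = [(s, min(e, genome_len)) for s, e in zones]

    if spec.motif_free_background:
        _scrub(
            chars,
            protected,
            rng,
            global_motifs=(profile.donor, profile.branchpoint),
            zoned_motifs=(profile.acceptor,),
            zones=tuple(zones),
        )
    if spec.coding is not None:
        _plant_coding_context(chars, placed[0], spec, protected, profile, rng)
    return "".join(chars), placed


def _plant_coding_context(
    chars: list[str],
    placed: dict,
    spec: FixtureSpec,
    protected: list[Span],
    profile: ConsensusProfile,
    rng: np.random.Generator,
) -> None:
    """Overwrite exon sequence around the first feature's junction.

    Upstream: 75 nt of C (stop-free in every frame, motif-inert).
    Downstream, ``coding="clean"``: a C-padded block with TAA planted in
    the two frames that must die, leaving exactly the frame whose intron
    phase equals ``spec.phase``; ``coding="stops"``: TAA in all three
    frames.  The blocks contain no G, so they cannot seed donor motifs or
    complete acceptor motifs; boundary artifacts are repaired afterwards.
    """
    f_start, f_end = placed["span"]
    up_len, down_len = 75, 75
    if f_start < up_len or f_end + down_len > len(chars):
        raise FixtureError("not enough background around the feature for a coding context")
    chars[f_start - up_len : f_start] = ["C"] * up_len
    j = f_start  # junction position in the spliced sequence
    down = ["C"] * down_len
    if spec.coding == "stops":
        block = "TAATTAATTAA"
        down[2 : 2 + len(block)] = list(block)
    else:
        f_keep = (j - spec.phase) % 3
        o1 = next(o for o in range(3) if (j + o) % 3 == (f_keep + 1) % 3)
        down[o1 : o1 + 3] = list("TAA")
        down[o1 + 7 : o1 + 10] = list("TAA")  # spacing 7 ≡ 1 (mod 3): next frame
    chars[f_end : f_end + down_len] = down
    protected.extend([(f_start - up_len, f_start), (f_end, f_end + down_len)])
    # boundary repair: the flanks may now complete a donor/BP across the edge
    _scrub(chars, protected, rng, (profile.donor, profile.branchpoint))


def _verify_scan(genome: str, truth: TruthAnnotation,
                 profile: ConsensusProfile, rules: DistanceRules) -> None:
    by_class: dict[StwintronClass, list[StwintronCall]] = {}
    for call in truth.stwintrons:
        by_class.setdefault(call.stw_class, []).append(call)
    for cls, expected in by_class.items():
        got = scan_for_stwintrons(genome, cls, profile, rules,
                                  seq_id=truth.seq_id)
        if got != sorted(expected, key=lambda c: c.total_span):
            raise FixtureError(
                f"scan verification failed for class {cls.label}: "
                f"expected {len(expected)} call(s), got {len(got)}"
            )


def _truth_call(cls: StwintronClass, spans: list[Span], seq_id: str) -> StwintronCall:
    return call_from_elements(cls, spans, seq_id=seq_id)


# ---------------------------------------------------------------------------
# plant_*
# ---------------------------------------------------------------------------

def plant_stwintron(
    spec: FixtureSpec = FixtureSpec(),
    profile: ConsensusProfile = RELAXED,
    rules: DistanceRules = DEFAULT_RULES,
    seq_id: str = "fixture",
    max_attempts: int = 20,
) -> tuple[str, TruthAnnotation]:
    """Genome with planted stwintrons (and/or standard introns) + truth.

    The generated genome is verified before being returned: the class
    scan must recover exactly the planted calls, plain intron calling
    must see exactly the internal/standalone introns, and (when no coding
    blocks were planted) leftmost-first splicing must run to the expected
    mature sequence.  Degenerate-base sampling is retried with a derived
    seed on the rare occasions verification fails.
    """
    last: Exception | None = None
    for attempt in range(max_attempts):
        rng = _rng_for(spec.seed, attempt)
        try:
            builds = []
            for geom in spec.features:
                if isinstance(geom, StwintronGeometry):
                    builds.append(_build_stwintron(geom, profile, rules, rng, spec.gc))
                elif isinstance(geom, StandardIntronGeometry):
                    builds.append(_build_standard_intron(geom, profile, rules, rng, spec.gc))
                else:
                    raise FixtureError(f"unknown feature geometry {geom!r}")
            genome, placed = _assemble(spec, builds, profile, rules, rng)
            stw_calls = []
            plain_introns = []
            removals = []
            n_events = 0
            for geom, info in zip(spec.features, placed):
                if info["stw_elements"] is not None:
                    call = _truth_call(geom.stw_class, info["stw_elements"], seq_id)
                    stw_calls.append(call)
                    removals.append(call.total_span)
                    n_events += 2
                else:
                    d, b, a = info["elements"]
                    plain_introns.append(IntronCall(d, b, a))
                    removals.append(info["introns"][0])
                    n_events += 1
            truth = TruthAnnotation(
                seq_id=seq_id,
                genome_len=len(genome),
                stwintrons=tuple(stw_calls),
                introns=tuple(plain_introns),
                mature_seq=_mature_from_removals(genome, removals),
                expected_nodes=n_events + 1,
                expected_events=n_events,
                expected_leaves=1,
                phase=spec.phase if spec.coding == "clean" else None,
            )
            _verify_scan(genome, truth, profile, rules)
            _verify_intron_calls(genome, truth, profile, rules)
            _verify_chain(genome, truth, profile, rules)
            return genome, truth
        except FixtureError as exc:
            last = exc
    raise FixtureError(f"fixture generation failed after {max_attempts} attempts: {last}")


def _verify_intron_calls(genome, truth, profile, rules):
    expected = sorted(
        [c.internal.intron_span for c in truth.stwintrons]
        + [c.intron_span for c in truth.introns]
    )
    got = [c.intron_span for c in find_introns(genome, profile, rules)]
    if got != expected:
        raise FixtureError(f"intron-call verification failed: {got} != {expected}")


def _verify_chain(genome, truth, profile, rules):
    graph = splice_to_completion(RnaSpecies.primary(genome), profile, rules)
    leaves = graph.leaves()
    if (
        graph.graph.number_of_nodes() != truth.expected_nodes
        or graph.graph.number_of_edges() != truth.expected_events
        or len(leaves) != 1
        or leaves[0].seq != truth.mature_seq
    ):
        raise FixtureError("splice-chain verification failed")


# -- alternative 3' acceptor fixtures ---------------------------------------

_ALT_VARIANTS = ("a_niger", "n_crassa")


def plant_alt_acceptor_fixture(
    variant: str = "a_niger",
    seed: int = 0,
    background_len: int = 1200,
    gc: float = 0.5,
    acc2_offset: int = 26,
    seq_id: str | None = None,
    profile: ConsensusProfile = RELAXED,
    rules: DistanceRules = DEFAULT_RULES,
    max_attempts: int = 20,
) -> tuple[str, TruthAnnotation]:
    """Exon-skipping fixture: stwintron + skippable exon + standard intron.

    ``a_niger``: a second acceptor for the internal intron sits
    ``acc2_offset`` nt downstream of the primary one (inside the external
    intron) with a distinct branchpoint element; using it extends the
    internal intron by ``acc2_offset + 3`` nt at its 3' end, after which
    the re-joined external donor can no longer reach its own branchpoint
    (the blocking rule is recorded in ``truth.notes``) and instead pairs
    with the downstream standard intron's 3' splice sites — skipping the
    15-nt exon between them.

    ``n_crassa``: no second acceptor; the alternative internal 3' splice
    site *is* the external intron's acceptor, and the re-formed donor
    (external donor prefix + first exon base) drives the skip of a 33-nt
    exon.

    Branch-mode simulation of the returned genome yields exactly two
    mature products differing by the skipped exon.
    """
    if variant not in _ALT_VARIANTS:
        raise FixtureError(f"variant must be one of {_ALT_VARIANTS}")
    seq_id = seq_id or f"alt_{variant}"
    if variant == "a_niger":
        ext_gaps, exon2_len = (52, 9), 15
        if acc2_offset < 17:
            raise FixtureError(
                "bp_acc_gap: the secondary acceptor is too close to the primary "
                "one to carry a distinct branchpoint element downstream of the "
                "interrupted donor"
            )
        if acc2_offset + 3 >= ext_gaps[0]:
            raise FixtureError("secondary acceptor does not fit inside the external intron")
    else:
        ext_gaps, exon2_len = (40, 21), 33

    last: Exception | None = None
    for attempt in range(max_attempts):
        rng = _rng_for(seed, attempt)
        try:
            return _build_alt_fixture(
                variant, rng, background_len, gc, acc2_offset, exon2_len,
                ext_gaps, seq_id, profile, rules,
            )
        except FixtureError as exc:
            last = exc
    raise FixtureError(f"fixture generation failed after {max_attempts} attempts: {last}")


def _build_alt_fixture(
    variant, rng, background_len, gc, acc2_offset, exon2_len, ext_gaps,
    seq_id, profile, rules,
):
    stw_geom = StwintronGeometry(ext_gaps=ext_gaps)
    built = _build_stwintron(stw_geom, profile, rules, rng, gc)
    e1, e2, e3, e4, e5 = built.stw_elements
    protected_rel = list(built.element_spans)
    acc1_end = e3[0] + 3  # e3 is internal acceptor + external-donor suffix
    if variant == "a_niger":
        # plant BP2 + acc2 + donor-completing T inside the external
        # donor→BP spacer; acc2 starts acc2_offset nt after the primary
        # acceptor's end, its own BP element 10 nt upstream of it
        bp2 = sample_motif(profile.branchpoint, rng)
        acc2_start = acc1_end + acc2_offset
        bp2_start = acc2_start - 10 - 6
        built.seq[bp2_start : bp2_start + 6] = list(bp2)
        built.seq[acc2_start : acc2_start + 3] = list("CAG")
        built.seq[acc2_start + 3] = "T"  # completes GTRWG|T after excision
        protected_rel += [
            (bp2_start, bp2_start + 6),
            (acc2_start, acc2_start + 4),
        ]
        alt_note = {"bp2_span": (bp2_start, bp2_start + 6),
                    "acc2_span": (acc2_start, acc2_start + 3)}
    else:
        alt_note = {}

    # exon II and the downstream standard intron
    exon2 = _random_bases(exon2_len, gc, rng)
    if variant == "n_crassa":
        exon2[0] = "A"  # re-formed donor: external donor prefix + A
    i2 = _build_standard_intron(
        StandardIntronGeometry(length=60, gaps=(30, 15)), profile, rules, rng, gc
    )
    stw_len = len(built.seq)
    feature = built.seq + exon2 + i2.seq
    i2_rel = [(stw_len + exon2_len + s, stw_len + exon2_len + e)
              for s, e in i2.element_spans]
    protected_rel += i2_rel
    if variant == "n_crassa":
        protected_rel.append((stw_len, stw_len + 1))

    spec = FixtureSpec(seed=0, background_len=background_len, gc=gc)
    combined = _Built(seq=feature, element_spans=protected_rel,
                      stw_elements=built.stw_elements)
    genome, placed = _assemble(spec, [combined], profile, rules, rng)
    off = placed[0]["span"][0]

    def ab(span: Span) -> Span:
        return (off + span[0], off + span[1])

    primary_call = _truth_call(D56, [ab(sp) for sp in built.stw_elements], seq_id)
    i2_abs = [ab(sp) for sp in i2_rel]
    i2_call = IntronCall(*i2_abs)
    exon2_span = (off + stw_len, off + stw_len + exon2_len)

    # the 3'-extended secondary stwintron is a bona fide second scan hit:
    # same hybrid donor, alternative acceptor for the internal intron, and
    # the downstream standard intron's BP/acceptor as external 3' sites
    if variant == "a_niger":
        e3_alt = ab((acc2_start, acc2_start + 4))
        e2_alt = ab((bp2_start, bp2_start + 6))
    else:
        e3_alt = ab((e5[0], e5[1] + 1))  # external acceptor + first exon base
        e2_alt = ab(e4)
    secondary_call = _truth_call(
        D56, [ab(e1), e2_alt, e3_alt, i2_abs[1], i2_abs[2]], seq_id
    )

    retained = _mature_from_removals(
        genome, [primary_call.total_span, i2_call.intron_span]
    )
    skipped = _mature_from_removals(
        genome, [(primary_call.total_span[0], i2_call.intron_span[1])]
    )
    truth = TruthAnnotation(
        seq_id=seq_id,
        genome_len=len(genome),
        stwintrons=(primary_call, secondary_call),
        introns=(i2_call,),
        mature_seq=retained,
        expected_leaves=2,
        skip_length=exon2_len,
        notes={
            "variant": variant,
            "exon2_span": exon2_span,
            "mature_retained": retained,
            "mature_skipped": skipped,
            "secondary_extension_nt": acc2_offset + 3 if variant == "a_niger" else None,
            **alt_note,
        },
    )
    # verification: branch simulation must give exactly the two products
    graph = splice_to_completion(RnaSpecies.primary(genome), profile, rules, branch=True)
    products = sorted({leaf.seq for leaf in graph.leaves()})
    if products != sorted({retained, skipped}):
        raise FixtureError("alternative-acceptor fixture verification failed")
    report = classify_products(graph)
    if not any(s.length == exon2_len for s in report.skips):
        raise FixtureError("expected exon-skip not detected during verification")
    _verify_scan(genome, truth, profile, rules)
    return genome, truth


# -- dual intervening sequence ----------------------------------------------

def plant_dual_is_fixture(
    seed: int = 5,
    background_len: int = 1200,
    gc: float = 0.5,
    seq_id: str = "dual_is",
    profile: ConsensusProfile = RELAXED,
    rules: DistanceRules = DEFAULT_RULES,
    max_attempts: int = 20,
) -> tuple[str, TruthAnnotation]:
    """A discontinuous second-order intron wrapped around a stwintron.

    Layout on the primary transcript::

        [exon] SO-donor ..80.. [D5,6 stwintron] ..30.. SO-BP ..10..
               [standard intron 2] ..8.. SO-acceptor [exon]

    The second-order (SO) intron's three elements are separated by the
    nested intervening sequences; only after the stwintron (two
    reactions) and intron 2 (one reaction) are gone do they become
    contiguous and excisable, for four U2 reactions in total.  The
    geometry guarantees no premature pairing at any intermediate (the
    generator simulates its own output and raises otherwise).
    """
    gap_a, gap_b, gap_c, gap_d = 80, 30, 10, 8
    last: Exception | None = None
    for attempt in range(max_attempts):
        rng = _rng_for(seed, attempt)
        try:
            stw = _build_stwintron(StwintronGeometry(), profile, rules, rng, gc)
            i2 = _build_standard_intron(
                StandardIntronGeometry(length=60, gaps=(30, 15)), profile, rules, rng, gc
            )
            so_donor = sample_motif(profile.donor, rng)
            so_bp = sample_motif(profile.branchpoint, rng)
            so_acc = sample_motif(profile.acceptor, rng)
            parts: list[tuple[list[str], bool]] = [
                (list(so_donor), True),
                (_random_bases(gap_a, gc, rng), False),
                (stw.seq, None),        # None: carries its own protected spans
                (_random_bases(gap_b, gc, rng), False),
                (list(so_bp), True),
                (_random_bases(gap_c, gc, rng), False),
                (i2.seq, None),
                (_random_bases(gap_d, gc, rng), False),
                (list(so_acc), True),
            ]
            feature: list[str] = []
            protected_rel: list[Span] = []
            offsets = []
            for part, protect in parts:
                offsets.append(len(feature))
                if protect is True:
                    protected_rel.append((len(feature), len(feature) + len(part)))
                feature.extend(part)
            stw_off, i2_off = offsets[2], offsets[6]
            protected_rel += [(stw_off + s, stw_off + e) for s, e in stw.element_spans]
            protected_rel += [(i2_off + s, i2_off + e) for s, e in i2.element_spans]

            spec = FixtureSpec(seed=0, background_len=background_len, gc=gc)
            combined = _Built(seq=feature, element_spans=protected_rel,
                              stw_elements=[(stw_off + s, stw_off + e)
                                            for s, e in stw.stw_elements])
            genome, placed = _assemble(spec, [combined], profile, rules, rng)
            off = placed[0]["span"][0]

            def ab(rel: Span) -> Span:
                return (off + rel[0], off + rel[1])

            stw_call = _truth_call(
                D56, [ab((stw_off + s, stw_off + e)) for s, e in stw.stw_elements],
                seq_id,
            )
            i2_call = IntronCall(
                *[ab((i2_off + s, i2_off + e)) for s, e in i2.element_spans]
            )
            so_spans = {
                "donor": ab((offsets[0], offsets[0] + 6)),
                "bp": ab((offsets[4], offsets[4] + 6)),
                "acceptor": ab((offsets[8], offsets[8] + 3)),
            }
            total = (so_spans["donor"][0], so_spans["acceptor"][1])
            truth = TruthAnnotation(
                seq_id=seq_id,
                genome_len=len(genome),
                stwintrons=(stw_call,),
                introns=(i2_call,),
                mature_seq=_mature_from_removals(genome, [total]),
                expected_nodes=5,
                expected_events=4,
                expected_last_flags=frozenset({"second_order"}),
                expected_leaves=1,
                notes={"second_order_spans": so_spans,
                       "second_order_segments": 3},
            )
            _verify_dual(genome, truth, profile, rules)
            return genome, truth
        except FixtureError as exc:
            last = exc
    raise FixtureError(f"fixture generation failed after {max_attempts} attempts: {last}")


def _verify_dual(genome, truth, profile, rules):
    graph = splice_to_completion(RnaSpecies.primary(genome), profile, rules)
    if (
        graph.graph.number_of_nodes() != 5
        or graph.graph.number_of_edges() != 4
        or len(graph.leaves()) != 1
        or graph.leaves()[0].seq != truth.mature_seq
    ):
        raise FixtureError("premature or missing splicing in dual-IS fixture")
    # linear chain: the last event must be the second-order excision
    order = sorted(graph.events(), key=lambda e: e.order_index)
    if "second_order" not in order[-1].flags or len(order[-1].primary_footprint) != 3:
        raise FixtureError("dual-IS fixture's final event is not second-order")
    _verify_scan(genome, truth, profile, rules)


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

def _call_to_dict(call: StwintronCall) -> dict:
    return {
        "stw_class": {"kind": call.stw_class.kind, "split": call.stw_class.split},
        "element_spans": [list(s) for s in call.element_spans],
        "seq_id": call.seq_id,
        "strand": call.strand,
    }


def _call_from_dict(d: dict) -> StwintronCall:
    return call_from_elements(
        StwintronClass(d["stw_class"]["kind"], d["stw_class"]["split"]),
        [tuple(s) for s in d["element_spans"]],
        seq_id=d["seq_id"],
        strand=d["strand"],
    )


def write_fixture(genome: str, truth: TruthAnnotation, outdir: str | Path) -> dict[str, Path]:
    """Write genome.fa, truth.gff3 and truth.json (deterministic bytes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fa = outdir / "genome.fa"
    with open(fa, "w") as fh:
        fh.write(f">{truth.seq_id}\n")
        for i in range(0, len(genome), 70):
            fh.write(genome[i : i + 70] + "\n")
    gff = outdir / "truth.gff3"
    with open(gff, "w") as fh:
        write_calls_gff(truth.stwintrons, truth.seq_id, fh)
        for i, intron in enumerate(truth.introns, 1):
            s, e = intron.intron_span
            fh.write(
                f"{truth.seq_id}\tstwinscan\tintron\t{s + 1}\t{e}\t.\t+\t.\t"
                f"ID=std{i}\n"
            )
    js = outdir / "truth.json"
    payload = {
        "seq_id": truth.seq_id,
        "genome_len": truth.genome_len,
        "stwintrons": [_call_to_dict(c) for c in truth.stwintrons],
        "introns": [
            [list(c.donor_span), list(c.bp_span), list(c.acceptor_span)]
            for c in truth.introns
        ],
        "mature_seq": truth.mature_seq,
        "expected_nodes": truth.expected_nodes,
        "expected_events": truth.expected_events,
        "expected_last_flags": sorted(truth.expected_last_flags)
        if truth.expected_last_flags
        else None,
        "expected_leaves": truth.expected_leaves,
        "skip_length": truth.skip_length,
        "phase": truth.phase,
        "notes": _jsonable(truth.notes),
    }
    with open(js, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"fasta": fa, "gff3": gff, "json": js}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    return obj


def read_fixture(outdir: str | Path) -> tuple[str, TruthAnnotation]:
    """Round-trip reader for :func:`write_fixture` output."""
    outdir = Path(outdir)
    from .io import read_fasta

    records = read_fasta(outdir / "genome.fa")
    seq_id, genome = records[0]
    with open(outdir / "truth.json") as fh:
        d = json.load(fh)
    truth = TruthAnnotation(
        seq_id=d["seq_id"],
        genome_len=d["genome_len"],
        stwintrons=tuple(_call_from_dict(c) for c in d["stwintrons"]),
        introns=tuple(
            IntronCall(tuple(ds), tuple(bs), tuple(as_))
            for ds, bs, as_ in d["introns"]
        ),
        mature_seq=d["mature_seq"],
        expected_nodes=d["expected_nodes"],
        expected_events=d["expected_events"],
        expected_last_flags=frozenset(d["expected_last_flags"])
        if d["expected_last_flags"]
        else None,
        expected_leaves=d["expected_leaves"],
        skip_length=d["skip_length"],
        phase=d["phase"],
        notes=d["notes"],
    )
    return genome, truth
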