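# Methods

This note documents the models implemented in `stwinscan`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical/design choices made where the design was
genuinely open.

## The intron model

A U2 intron is represented by three degenerate elements and two
distances:

| element | motif (strict) | motif (relaxed) | length |
|---|---|---|---|
| 5′ donor | `GTRWGY` | `GTRWGH` | 6 nt |
| branchpoint element | `RYTRAY` | `DYTRAY` | 6 nt |
| 3′ acceptor | `YAG` | `HAG` | 3 nt |

The branch adenosine is the fifth branchpoint position and is invariant
(`A`); the acceptor invariably ends in `G`. Both constraints are enforced
on any `ConsensusProfile`. Two profiles ship because the donor consensus
is quoted in the literature both as `GURWGY` and with a relaxed final
position (`H`); rather than resolving the discrepancy we expose both as
named profiles (`strict`, `relaxed`) and default to `relaxed`, which is
the profile embedded in the operational genome-screen pattern.

Distance rules (defaults, all configurable via `DistanceRules` or a YAML
file):

* `min_intron_len = 42` nt — the shortest credible fungal U2 intron;
* `donor_bp_gap = (25, 120)` nt, measured donor-element end (exclusive)
  to branchpoint-element start — chosen around the ~73 nt mean fungal
  intron length, with introns > 160 nt being rare;
* `bp_acc_gap = (4, 24)` nt — the prose constraint is only the 4-nt
  minimum; the 24-nt ceiling is taken from the screen pattern's `(4,24)`
  window because the pattern is the operational definition actually used
  in whole-genome screens;
* principle 3: the donor→branchpoint distance must be **strictly**
  greater than the branchpoint→acceptor distance ("always bigger" read
  literally as a strict inequality).

Distances are element-to-element (end-exclusive to start), the same
arithmetic the textual `(min,max)` windows use. The alternative reading
(donor start to branch adenosine) was rejected because it breaks the
identity between rule windows and pattern windows.

**Intron definition.** `find_introns` pairs, for each donor occurrence
scanned 5′→3′, the nearest acceptor that yields a valid intron (smallest
intron wins). When two branchpoint placements serve the same acceptor,
the one nearest the acceptor wins — consistent with U2 scanning proximal
to the 3′ site; the sources do not specify this tie-break. Each donor
yields at most one call; overlapping calls from different donors are all
reported (downstream simulation or manual curation decides).

## Stwintron patterns

`build_stwintron_pattern` assembles, for class `[X s,s+1]`, a five-element
gapped pattern in which the interrupted element contributes its first
`s` nt to the element preceding the internal intron and its remainder to
the element following it. For `[D5,6]` with the relaxed profile and
default rules this serializes exactly to

```
GTRWGGTRWGH(25,120)DYTRAY(4,24)HAGH(25,120)DYTRAY(4,24)HAG
```

For every class the pre-excision pattern windows coincide with the
post-excision rule distances, because the material removed by the
internal excision never separates the measured element boundaries. For
`[A]`-class externals this means the branchpoint→acceptor window is
applied to the post-excision distance (an assumption, consistent with the
`[D]`-class treatment). `[L]`-class patterns are generated but flagged
`hypothetical` in output — that class has never been demonstrated.

**Verification is mandatory.** The raw pattern is only a pre-filter: a
hit becomes a `StwintronCall` only if (i) the internal intron validates
as-is, (ii) after in-silico internal excision the re-joined element
matches the *uninterrupted* consensus, and (iii) the external intron
validates on the re-joined sequence. This matters for non-default rules,
where the pattern windows no longer guarantee the external geometry.

## The splicing simulator

An `RnaSpecies` carries, besides its sequence, a strictly increasing
provenance map (current position → primary-transcript coordinate). One
step excises one valid intron found by re-scanning the **current**
sequence — re-scanning, rather than coordinate patching, is what lets
re-joined donors and newly contiguous second-order introns be
*discovered*. Without branching, the leftmost valid intron is excised;
with `branch=True` the step branches over every workable
(branchpoint, acceptor) pair of the leftmost donor. Branching is limited
to alternative 3′ sites because that is the documented exon-skipping
mechanism; alternative donors are out of scope.

Graph expansion is breadth-first with duplicate species merged (a DAG:
different orders converge on identical intermediates), guarded by
`max_nodes = 10,000` against branch explosion on low-complexity input.

Event flags are derived from provenance, not bookkeeping:

* an element discontiguous in primary coordinates ⇒
  `external_of_stwintron` (its element had been interrupted);
* all elements contiguous but the intron spanning ≥ 2 primary segments ⇒
  `second_order` (the intron never existed contiguously);
* an excision that creates a splice element straddling the junction and
  belonging to a valid intron of the child ⇒ `internal_of_stwintron`;
* otherwise `standard`; non-nearest branch children additionally carry
  `alternative_acceptor`.

`detect_second_order` reports raw discontiguity (segment count ≥ 2); note
a plain `[D5,6]` external excision is discontiguous with 2 segments but
is *classified* as external, not second-order.

Exon skipping is detected on provenance: leaf B is a skip product of leaf
A when B's provenance is A's minus one contiguous, strictly internal
block of primary coordinates.

`enumerate_orders` explores every order of nearest-pair excisions and is
used to check two structural facts: the internal intron always precedes
its external intron, and the second-order intron is always last.

## The synthetic-data generator

Backgrounds are sampled i.i.d. with a GC parameter (default 0.50,
roughly fungal genome-wide GC) and made *motif-free* by repair: every
donor- or branchpoint-motif occurrence outside planted elements has one
base resampled to a forbidden base until none remain; acceptor motifs are
likewise repaired within each planted feature and a 160-nt downstream
margin (the farthest a pattern tail can reach). Donor-free background
implies zero possible intron calls and zero pattern hits outside planted
loci, so recovery tests can assert exact-coordinate recovery with zero
false positives. A "natural" mode (`motif_free=False`) skips repair for
realism tests in which false positives are tallied rather than asserted.

Planted element sequences are sampled per-position uniformly from each
motif's allowed sets (exercising degeneracy); each generator *verifies
its own output* — scanning, intron-calling and splicing it against the
truth annotation — and resamples with a derived seed in the rare case a
degenerate draw creates an unintended interaction.

Default geometries and the reasoning behind the open choices:

* **Plain `[D5,6]`**: internal 75 nt, external 76 nt (the characterized
  locus geometry). Gap splits are derived: internal (36, 24); external
  (52, 9). The external donor→BP distance is deliberately ≥ 52 so that
  the internal donor cannot legally pair past the internal acceptor
  (64 + 1 + 52 = 117 … > 120 for the relevant pairing), keeping the
  planted locus's pattern hit unique — required for exact-recovery
  assertions. With default windows the smallest plantable intron is
  6 + 25 + 6 + 4 + 3 = 44 nt.
* **Alternative acceptor ("a_niger")**: a second `CAG` 26 nt downstream
  of the internal intron's acceptor (inside the external intron), with
  its own branchpoint element 10 nt upstream, and a `T` immediately after
  it so that excision re-forms a canonical `GTRWG|T` donor. The secondary
  internal intron is therefore 29 nt longer. After that excision the
  re-formed donor sits 23 nt from the external branchpoint element —
  inside the forbidden < 25 nt zone — so the simulator *derives* that the
  primary external pairing is blocked (the implementation reports the
  violated rule rather than hard-coding the outcome; under a 76-nt
  external a pure principle-3 failure is arithmetically impossible) and
  the donor instead pairs with the standard intron's 3′ sites, skipping
  the 15-nt exon. The downstream standard intron is 60 nt with gaps
  (30, 15), chosen so the *retained*-path donor cannot also reach the
  standard intron's branchpoint (139 > 120), keeping exactly two mature
  products.
* **"n_crassa" variant**: no second acceptor; the alternative internal 3′
  site is the external intron's own acceptor (external gaps (40, 21) so
  that pairing is reachable: 110 ≤ 120), the skippable exon is 33 nt and
  begins with `A` (re-formed donor `GTRWG|A`).
* **Dual intervening sequence**: second-order donor 80 nt upstream of the
  stwintron, branchpoint element 30 nt behind it, the 60-nt standard
  intron 10 nt further, acceptor 8 nt behind that. These spacings make
  the second-order intron valid only once fully contiguous
  (donor→BP 110 nt, BP→acceptor 18 nt, 143 nt total) while every
  premature pairing at every intermediate violates a window (checked by
  simulation inside the generator).

What the fixtures do **not** emulate: real base composition beyond a GC
dial (no isochores, repeats or codon bias), degenerate splice sites that
deviate from the consensus (real introns often do; the scanner is
consensus-bound by design), overlapping genes, sequencing noise or
N-runs, and multi-intron gene models beyond the planted features. A
passing recovery test therefore demonstrates correctness of the search
and splicing logic under the model's own assumptions, not sensitivity on
real genomes — on real sequence the consensus profiles govern
sensitivity, exactly as in manual screens.

## Numerical and interface choices

* Coordinates are 0-based half-open everywhere internally; GFF3 output is
  1-based inclusive, BED 0-based half-open. Minus-strand calls keep
  forward-strand coordinates with reversed element order and a strand
  field.
* Sequence `N` never matches any motif position — conservative calling in
  draft assemblies.
* Scanner ordering is deterministic: matches sorted by total-span start,
  then lexicographically by element starts; GFF3/BED emission is
  byte-deterministic.
* The brute-force oracle shares no machinery with the production scanner
  (full positional enumeration with per-position set membership vs
  regex occurrence lists joined under gap windows) and is guarded to
  10 kb.
* GFF3 feature types: `twin_intron` parent, `intron` children, element
  children typed `splice_donor`/`branch_point`/`splice_acceptor`, with a
  `stw_class=D5,6`-style attribute — no Sequence Ontology term covers
  stwintrons, so this documented mapping is used.
* Problem sizes in the test-suite and acceptance script (2-kb
  backgrounds, 100 oracle sequences, 50 recovery fixtures) were chosen as
  the smallest sizes at which every geometry and every interaction the
  models describe (multiple features per genome, all fixture classes) is
  exercised; all quantities are invariant to the seed.

## Known limitations

* Exon-definition pairing is deliberately absent (not described in
  ascomycetes); the simulator will not discover pairings across exons.
* U12 (minor-spliceosome) introns are out of scope.
* Probabilistic splice-site scoring (PWMs) is out of scope; matching is
  deterministic consensus matching, as in the manual screens the package
  automates.
* Minus-strand `StwintronCall`s carry coordinates but sub-call sequence
  detail is best inspected on the reverse complement.
* `curate_orf_context` is a local heuristic (stop-free frame through the
  junction within a window), not a gene model; it mirrors the manual
  "separates coding sequence" curation criterion, not ortholog- or
  expression-based criteria, which require external data.
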