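# stwinscan

Discovery and in-silico splicing of **spliceosomal twin introns
(stwintrons)** in fungal genomes.

A stwintron is a complex intervening sequence in which an *internal* U2
intron interrupts one of the three canonical splice elements of an
*external* U2 intron — the 5′ donor (`GURWGY`), the branchpoint element
carrying the lariat adenosine (`RYURAY`), or the 3′ acceptor (`YAG`).
Because the interrupted element is non-functional until the internal
intron is gone, the two introns must be excised strictly inside-out, and
in ascomycete fungi each excision obeys **intron definition**: the paired
splice sites are the nearest compatible donor/branchpoint/acceptor,
subject to

1. minimum intron length 42 nt,
2. branchpoint→acceptor distance ≥ 4 nt (operationally 4–24 nt),
3. donor→branchpoint distance (25–120 nt) strictly greater than the
   branchpoint→acceptor distance,
4. nearest-pair splice-site pairing across the intron.

`stwinscan` is aimed at people who curate intron–exon structure in
fungal (and other intron-definition) genomes and want to (i) screen
sequence for stwintron candidates of any class — `[D]`, `[L]`
(hypothetical), `[A]` — with any split index, and (ii) simulate the
multi-step splicing such regions imply, including alternative 3′ splice
sites that turn a donor-class stwintron into an exon-skipping switch, and
"second-order" introns whose donor, branchpoint element and acceptor are
discontinuous in the primary transcript and only become contiguous after
earlier excisions.

## How the scan works

For a `[D5,6]` stwintron (internal intron between the 5th and 6th donor
nucleotide, `GURWG|U`) the scanner screens with a five-element degenerate
gapped pattern whose first and third elements are *hybrid* motifs —
pieces of the interrupted external donor fused to intact internal
elements:

```
GTRWGGTRWGH(25,120)DYTRAY(4,24)HAGH(25,120)DYTRAY(4,24)HAG
```

`(min,max)` is the distance in nt from the end of one element to the
start of the next. Every raw hit is then verified against the splicing
model itself: the internal intron is excised in silico, the re-joined
external element must match the uninterrupted consensus, and the external
intron must satisfy the distance rules on the re-joined sequence.

## Worked example

```python
import stwinscan as sw
from stwinscan.simulate import RnaSpecies, splice_to_completion, classify_products

# a synthetic locus: [D5,6] stwintron (internal 75 nt / external 76 nt)
# with an alternative acceptor 26 nt downstream of the internal intron's
# 3' splice site, a 15-nt skippable exon, and a 60-nt standard intron
genome, truth = sw.plant_alt_acceptor_fixture(variant="a_niger", seed=1)

calls = sw.scan_for_stwintrons(genome, sw.D56, seq_id="locus")
for c in calls:
    print(c.label, c.total_span, "internal", c.internal.length, "nt")

graph = splice_to_completion(RnaSpecies.primary(genome), branch=True)
report = classify_products(graph)
print("mature products:", sorted(len(leaf.seq) for leaf in graph.leaves()))
for skip in report.skips:
    print(f"exon skip: {skip.length} nt at {skip.primary_span}")
```

Output:

```
D5,6 (511, 662) internal 75 nt
D5,6 (511, 737) internal 104 nt
mature products: [1200, 1215]
exon skip: 15 nt at (662, 677)
```

The scan finds both the primary stwintron and its 3′-extended secondary
form (internal intron 29 nt longer, using the alternative acceptor).
Branch-mode splicing produces two mature mRNAs: one retaining the 15-nt
exon (three splicing reactions) and one skipping it (two reactions,
because the secondary external intron swallows the exon and the standard
intron behind it).

The same machinery handles the four-reaction "dual intervening sequence":

```python
genome, truth = sw.plant_dual_is_fixture(seed=5)
graph = splice_to_completion(RnaSpecies.primary(genome))
for e in sorted(graph.events(), key=lambda e: e.order_index):
    print(e.order_index, sorted(e.flags), len(e.primary_footprint), "segment(s)")
```

```
1 ['internal_of_stwintron'] 1 segment(s)
2 ['external_of_stwintron'] 2 segment(s)
3 ['standard'] 1 segment(s)
4 ['second_order'] 3 segment(s)
```

The last excision is always the second-order intron: its donor,
branchpoint element and acceptor lie in three separate pieces of the
primary transcript and only become one contiguous intron after the
stwintron (two reactions) and the standard intron (one reaction) are
removed.

## Command line

```sh
stwinscan scan --fasta genome.fa --class D --split 5 --profile relaxed \
               --strand both --out calls.gff3 --orf-filter --window 60
stwinscan splice --fasta transcript.fa --branch --out graph.json --dot graph.dot
stwinscan fixtures --kind dual-is --seed 5 --outdir fixtures/
stwinscan validate --fasta genome.fa --gff calls.gff3
```

Exit codes: 0 success (even with zero calls), 2 usage error, 3 input
error.

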