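# Methods

## Problem and model

Conserved-miRNA discovery by homology rests on two observations: plant
mature miRNAs (18–26 nt) are nearly invariant across species, and genuine
pre-miRNAs fold into a thermodynamically stable single stem-loop that is
rare among arbitrary transcript fragments of the same composition. The
pipeline therefore (a) locates near-exact copies of known matures on
candidate transcripts, (b) discards transcripts that are protein-coding,
and (c) accepts a locus only if the excised window folds into a hairpin
satisfying the standard five criteria, quantified with the folding-energy
statistics AMFE = (MFE/LP)·100 and MFEI = AMFE/GC%.

All sequences are held internally in the DNA alphabet (U→T on ingest) so
transcripts and references compare directly; mature and precursor sequences
are re-emitted in RNA in reports. Coordinates are 0-based half-open
internally and printed 1-based inclusive.

## Homology scan

A hit is a **full-length, ungapped** alignment of a reference mature
(≥ 18 nt) on either strand with at most `max_mismatches` (default 2)
substitutions, anchored by at least one exact word of `word_size`
(default 7) inside the alignment. This is the decision rule that a
short-word nucleotide-blast screen followed by stringent re-filtering
("mismatch < 3, length > 17") implements; because those filters fully
determine the surviving set, no alignment statistics (e-values) are
computed. End-truncated alignments do not exist: a copy overlapping a
transcript end is simply not found. The implementation is seed-and-verify
over a transcript k-mer index; an exhaustive sliding-window oracle is kept
in the test suite and the two are asserted equal on randomized instances.

Overlapping hits (≥ 50% of the shorter interval, same transcript and
strand) are collapsed by greedy non-maximum suppression: fewest mismatches,
then longer alignment, then lexicographically smallest reference id. Hits
on opposite strands are never collapsed — a planted hairpin is typically
found twice, once through its mature and once through its (intact) star
arm, which is biologically meaningful (miR/miR\* arms).

## Coding filter

In place of a protein-database search, which cannot ship in a
self-contained package, coding evidence is (a) an ATG-initiated,
stop-terminated open reading frame of ≥ `orf_threshold_aa` (default 100)
amino acids in any of the six frames, or (b) membership in a user-supplied
hit table from an external protein search (plain ids or blast
outfmt-6-like TSV). External evidence takes precedence in the verdict.
ORFs running off the transcript end are not counted; alternative start
codons are not considered.

## Folding and precursor trimming

The excised window is mature ± `flank` (default 80 nt), clipped at
transcript ends and rejected below mature + 20 nt; minus-strand hits are
reverse-complemented so every candidate reads 5′→3′ on its own strand.
Folding is a pluggable contract. The production backend is the ViennaRNA
MFE fold at 37 °C; ionic conditions (1 M NaCl, no divalents) are recorded
as metadata because Turner-parameter sets do not expose them (warned once,
not an error). A bundled stacking-count model (Nussinov-style DP, pair
scores GC 3 / AU 2 / GU 1, minimum loop 3, deterministic traceback) serves
unit tests that assert structure topology rather than energies. A fold
with no base pairs or non-negative energy is "no structure" and the
candidate is discarded.

The ~180-nt window is wider than a plant pre-miRNA, so before screening the
candidate is trimmed to the stem that actually carries the mature duplex:
the mature's pairing partners are clustered (split at gaps > 8 nt) and the
largest cluster taken as the duplex — a few mature bases pairing spurious
distant partners would otherwise drag the trim anchor onto a
multiloop-closing pair; the trim then extends outward along enclosing
pairs until a sibling branch (multiloop) appears, keeps 5-nt soft flanks,
and refolds. LP and all composition/energy statistics refer to this
trimmed, refolded precursor.

## Hairpin screen

The five criteria and their quantification:

| criterion | rule | default |
|---|---|---|
| substitutions vs reference | hit mismatch count ≤ | 2 |
| proper stem-loop | dominant stem (exterior-most pair enclosing ≥ 80% of paired positions) containing exactly one hairpin loop | — |
| mature in one arm | ≤ `loop_overlap_tolerance` mature bases inside the hairpin loop | 2 |
| mature/star mismatches | unpaired mature positions interior to the duplex ≤ | 5 |
| energy | MFE ≤ −18 kcal/mol and \|MFEI\| ≥ 0.5 | — |

Two conventions deserve note. *Loop tolerance*: under a thermodynamic
folder a single substitution near the loop-proximal end of the mature
unpairs its terminal base, which a literal "no mature base in the loop"
rule would reject; terminal breathing of up to 2 nt is therefore tolerated,
while a mature genuinely straddling the loop overlaps it by far more and is
rejected. *Star mismatches*: the count covers unpaired mature positions
between its outermost paired bases — interior bulges and internal loops —
because dangling overhang ends (the 2-nt 3′ overhang of the Dicer duplex)
are not mismatches between mature and star. The star sequence itself is
read 5′→3′ over the partner interval, extended 2 nt at its 3′ end
(canonical overhang convention; the magnitude convention for MFEI is
negative internally, printed as magnitude to 2 dp).

The MFE ≤ −18 / |MFEI| ≥ 0.5 defaults bracket the accepted precursor range
observed for conserved plant pre-miRNAs (MFEI ≈ 0.57–1.03) with headroom;
both are screening parameters, not constants.

Criteria are applied hierarchically: STAR_MM is only evaluated once a
hairpin exists and the mature lies in one arm, so a construct whose mature
straddles the loop fails with exactly MATURE_IN_LOOP.

Passing precursors receive deterministic miRBase-style names
(`mun-miR<family><letter>-<arm>`), letter-disambiguated in report order.

## Target prediction

Allen-style plant scoring, ungapped: per miRNA position (1-based from the
5′ end) a Watson–Crick pair costs 0, a G:U wobble 0.5, a mismatch 1.0,
multiplied by 2 inside seed positions 2–13; the sum is the site's
expectation. Sites are kept when expectation ≤ 3 and mismatches ≤ 4, at
most 2 per (miRNA, target) and 10 per miRNA, ascending by expectation.
Any non-Watson–Crick position in the central window 9–11 classifies the
site as translational inhibition, otherwise cleavage. Targets are scanned
on the given (sense) strand only, since inputs are mRNA/cDNA. Indel
penalties exist in the scheme (2.0) but gapped alignment is not active;
the operative constraint is "≤ 4 mismatches without gap".

## Summary statistics and census

Standard deviations use the sample (n−1) denominator — this reproduces the
published precursor-length summary from its printed inputs. A single
observation reports sd 0 with a logged caveat. The miRNA frequency
denominator is `ceil(total candidates / n miRNAs)` (29,047 candidates and
15 miRNAs give 1937). Printed tables round percentages and energies to
2 dp, MFEI to 2-dp magnitude and sd to 3 dp; TSVs keep full precision.

The bundled published records contain known internal inconsistencies
(three precursor rows whose printed base counts or AU% contradict
themselves, and a printed MFE column that duplicates GC% sign-flipped);
these rows are flagged and excluded from exact composition cross-checks,
while their printed column values still enter the summary-statistics
recomputation, which is defined over the printed table.

## Synthetic corpora — what they emulate and what they do not

A corpus mixes (i) planted transcripts carrying a constructed precursor
`mature + loop + star` (star = reverse complement of the reference with a
2-nt trim on the star side, mirrored for the 3p arm, so the mature sits
wholly in one arm; loop drawn over {A, C}, which cannot pair internally),
(ii) coding decoys with a ≥ 150-codon ORF, (iii) dinucleotide-shuffled
hairpin decoys (Altschul–Erickson edge shuffle: exact mono- and
dinucleotide counts, destroyed stem), and (iv) i.i.d. background. Plants
are recoverable by construction: mature substitutions (uniform 0..2 by
default) are placed so an exact 7-nt word survives; synthetic references
carry an exact G+C count (10–11 of 21 nt) so planted stems always clear the
default energy screen; backgrounds of transcripts labelled noncoding are
rejection-sampled below the ORF threshold so truth labels hold exactly.

This is deliberately idealised. The generator emulates the *decision
structure* of the funnel — detectability, coding exclusion, stem-loop
validation — not the sequence statistics of real transcriptomes: the
background is i.i.d. rather than Markov, planted stems are perfect outside
the introduced substitutions, and no sequencing error, expression levels or
isoform redundancy are simulated. Passing the recovery property therefore
demonstrates correctness of the pipeline's logic, not its yield on real
EST/TSA data, where hit counts are dominated by reference-set size and
transcriptome quality.

Default corpus scale (30 transcripts of 150–400 nt, 10 plants, 3 + 3
decoys) keeps a full end-to-end run below a second, so the recovery
property is checked over 20 independent seeds as a matter of course.

## Numerical and degenerate-input choices

- Records with > 10% ambiguous bases are dropped on ingest with a warning;
  ambiguity codes in composition statistics are a hard error.
- 100%-identity reference clustering treats equality and substring
  containment identically; ties go to the lexicographically smallest id;
  output order is first-appearance; the operation is idempotent.
- Empty inputs abort the pipeline with a stage-named error; a transcript
  shorter than a reference yields no hits rather than an error.
- All randomness flows through a single seeded NumPy generator per corpus;
  reruns are byte-identical, and every synthetic artifact embeds its seed
  (ids and the truth-table header).

## Known limitations

- Homology-only: novel (non-conserved) miRNAs are out of reach by design.
- Ungapped scanning misses homologs with indels relative to the reference.
- The ORF heuristic is a proxy for a protein-database search; borderline
  coding transcripts (short ORFs, no externally supplied hits) pass.
- MFEI/MFE thresholds are calibrated for plant precursors; animal miRNA
  screening would need different defaults.
- Secondary-structure validation uses the single MFE structure; suboptimal
  folds and shuffling-based significance (randfold-style p-values) are not
  computed.
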