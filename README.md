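# mirhom

Homology-based discovery of conserved microRNAs in unannotated transcript
collections — ESTs and transcriptome shotgun assemblies (TSA) of species
without a sequenced genome, such as horsegram (*Macrotyloma uniflorum*).

Plant mature miRNAs are strongly conserved across species while their
precursors are not, so a transcript collection can be mined by locating
near-exact copies of known mature miRNAs and then asking whether the
surrounding sequence folds into a genuine pre-miRNA stem-loop. `mirhom`
implements that funnel as a tested, reusable library:

1. **Reference preparation** — mature-miRNA FASTA normalised to a
   non-redundant set (100% identity clustering with containment, the
   CD-HIT-EST convention).
2. **Homology scan** — seeded ungapped alignment of every reference on both
   strands of every transcript (exact word of length 7, full-length
   alignment, ≤ 2 substitutions, reference ≥ 18 nt).
3. **Coding filter** — transcripts with protein-coding evidence are removed
   (six-frame ORF heuristic and/or an external protein-search hit table).
4. **Precursor excision and folding** — a window of mature ± 80 nt is
   excised on the hit strand and folded to its minimum-free-energy (MFE)
   structure at 37 °C (ViennaRNA).
5. **Hairpin screen** — candidates must satisfy the five standard criteria:
   ≤ 2 substitutions versus the reference; a proper single stem-loop; the
   mature localised in one arm; < 6 mismatches between mature and star
   (miRNA\*); and strongly negative MFE and MFEI, where

   ```
   AMFE = (MFE / LP) × 100          [kcal/mol per 100 nt]
   MFEI = AMFE / GC%                [dimensionless]
   ```

   with LP the precursor length. |MFEI| ≥ 0.5 and MFE ≤ −18 kcal/mol by
   default, both configurable.
6. **Target prediction** — expectation-scored complementarity search with
   the plant-style penalty scheme (mismatch 1.0, G:U wobble 0.5, doubled in
   seed positions 2–13; sites with expectation > 3 rejected; central
   non-complementarity at positions 9–11 ⇒ translational inhibition,
   otherwise cleavage).
7. **Reporting** — per-precursor characteristics table, summary statistics
   (mean / sample sd / min / max) and the run census with the miRNA
   frequency, `ceil(candidates / miRNAs)`.

A synthetic-data module generates corpora with planted precursors, coding
decoys and dinucleotide-shuffled hairpin decoys so every stage — and the
pipeline end to end — is testable without any downloads. A bundled dataset
of the fifteen previously reported horsegram miRNAs and their ten precursor
records doubles as a demonstration reference set.

## Worked example

```sh
python examples/discover_from_synthetic.py
```

```
funnel (survivors per stage):
  input_transcripts    30
  hits                 20
  hits_deduped         20
  noncoding            10
  candidates           20
  passed               20

planted precursors recovered: 10/10
decoys surviving the screen:  0/20

named miRNAs (first five):
  mun-miR9000-5p     LP= 58 MFE= -31.7 MFEI=1.17 arm=5p
  mun-miR9000a-5p    LP= 92 MFE= -40.3 MFEI=0.92 arm=5p
  ...
```

Ten transcripts carried planted hairpins; the scan finds each mature (and
usually its star arm, hence 20 hits from 10 transcripts), the coding filter
removes the long-ORF decoys, and every planted precursor passes the
five-criterion screen while no shuffled or coding decoy survives. Each
surviving precursor is reported with its length (LP), folding energy (MFE)
and MFEI, and receives a deterministic miRBase-style name.

The other examples show one stage each: `screen_one_precursor.py` (fold and
characterise a single hairpin), `predict_targets.py` (expectation scoring
and the cleavage / translational-inhibition call) and
`reproduce_published_summary.py` (summary statistics and census from the
bundled published records). A thin CLI mirrors the stages
(`mirhom synth | prep | scan | codingfilter | fold | targets | report | run`).

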