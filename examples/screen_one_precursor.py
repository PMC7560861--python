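"""Fold and screen a single candidate precursor.

Builds a precursor hairpin around one of the bundled horsegram mature
miRNAs, folds it with the ViennaRNA backend and prints the statistics a
characterisation table reports: precursor length (LP), base composition,
MFE, AMFE = MFE/LP x 100 and MFEI = AMFE/GC%.
"""

from mirhom import ReferenceMature, ViennaBackend, build_report, fold
from mirhom.fold import PrecursorCandidate
from mirhom.published import MATURES
from mirhom.synth import make_precursor

mature = next(m for m in MATURES if m.name == "mun-miR482a-5p")
ref = ReferenceMature(id=mature.name, seq=mature.seq_dna)
seq, offset = make_precursor(ref, loop_len=8, arm="5p", mutations=0)

cand = PrecursorCandidate("demo", 0, len(seq), seq, offset, len(ref.seq))
backend = ViennaBackend()
report = build_report(cand, fold(cand, backend), backend, family="482")

print(f"precursor ({report.lp} nt): {report.precursor_seq}")
print(f"structure:           {report.dotbracket}")
print(f"mature ({report.lm} nt, {report.arm} arm): {report.mature_seq}")
print(f"star:                {report.star_seq}  ({report.star_mismatches} unpaired mature bases)")
print(f"composition: AU% {report.au_pct}  GC% {report.gc_pct}  counts {report.counts}")
print(f"MFE {report.mfe:.2f} kcal/mol  AMFE {report.amfe_val:.2f}  MFEI {abs(report.mfei_val):.2f}")
print(f"screen: {'PASS' if report.passed else 'FAIL'} {[f.value for f in report.fail_reasons]}")
# A strongly negative MFE with |MFEI| >= 0.5 distinguishes miRNA precursors
# from tRNA/rRNA/mRNA fragments of similar composition.
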