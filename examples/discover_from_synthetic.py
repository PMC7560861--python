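"""End-to-end discovery on a synthetic corpus with known truth.

Generates 30 transcripts (10 carrying planted stem-loop precursors built
from known reference matures, plus coding and shuffled-hairpin decoys),
runs the full funnel — homology scan, coding filter, fold, hairpin screen —
and compares the surviving precursors against the truth table.
"""

import numpy as np

from mirhom import run_discovery
from mirhom.synth import SynthConfig, make_corpus, make_reference_set

cfg = SynthConfig(seed=11)
refs = make_reference_set(np.random.default_rng(cfg.seed))
transcripts, truth = make_corpus(cfg, refs)

result = run_discovery(transcripts, refs)

print("funnel (survivors per stage):")
for stage in ("input_transcripts", "hits", "hits_deduped", "noncoding", "candidates", "passed"):
    print(f"  {stage:20s} {result.funnel[stage]}")

planted = {t.transcript_id for t in truth if t.planted}
decoys = {t.transcript_id for t in truth if not t.planted}
recovered = {r.candidate_id.split(":")[0] for r in result.passing}
print(f"\nplanted precursors recovered: {len(planted & recovered)}/{len(planted)}")
print(f"decoys surviving the screen:  {len(decoys & recovered)}/{len(decoys)}")
print("\nnamed miRNAs (first five):")
for r in result.passing[:5]:
    name = result.names[r.candidate_id]
    print(f"  {name:18s} LP={r.lp:3d} MFE={r.mfe:6.1f} MFEI={abs(r.mfei_val):.2f} arm={r.arm}")
# A recovery of 10/10 with 0 decoys shows every planted hairpin passed all
# five structural criteria and nothing without a real stem-loop slipped through.
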