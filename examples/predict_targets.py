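"""Target prediction for a mature miRNA against a small mRNA set.

Plants one perfect and one degraded complementary site into synthetic
mRNAs, then scores every window with the plant-style expectation scheme
(mismatch 1.0, G:U 0.5, doubled in seed positions 2-13; sites above
expectation 3 rejected).  Non-complementarity in miRNA positions 9-11
classifies a site as translational inhibition rather than cleavage.
"""

import numpy as np

from mirhom import TranscriptRecord, find_targets
from mirhom.published import MATURES
from mirhom.seqio import Source, revcomp
from mirhom.targets import TargetConfig

rng = np.random.default_rng(3)
bases = np.array(list("ACGT"))
bg = lambda n: "".join(rng.choice(bases, size=n))

mature = next(m for m in MATURES if m.name == "mun-miR168a-5p")
mirna = mature.seq_dna

perfect = revcomp(mirna)
degraded = list(perfect)
degraded[len(mirna) - 10] = "A"  # breaks pairing at miRNA position 10 (central)
mrnas = [
    TranscriptRecord("mRNA-perfect", Source.OTHER, bg(80) + perfect + bg(80)),
    TranscriptRecord("mRNA-central-mm", Source.OTHER, bg(80) + "".join(degraded) + bg(80)),
]

for hit in find_targets(mature.name, mirna, mrnas, TargetConfig()):
    print(f"{hit.mirna_id} -> {hit.target_id} @ {hit.target_start + 1}-{hit.target_end}")
    print(f"  expectation {hit.expectation:.1f}  mode {hit.mode.value}")
    print("  " + hit.alignment.replace("\n", "\n  "))
# The perfect duplex scores 0 (cleavage); the single central mismatch costs
# 2.0 (1.0 doubled in the seed) and flips the mode to translational inhibition.
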