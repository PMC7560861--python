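"""Recompute the published summary statistics from printed inputs.

The bundled dataset carries the printed characteristics of the ten
horsegram precursor miRNAs and fifteen matures.  The reporting layer
recomputes the summary table (mean, sample sd, min, max) and the run
census — including the miRNA frequency denominator by the ceiling rule —
from those inputs alone.
"""

from mirhom.published import CENSUS_COUNTS, MATURES, PRECURSORS
from mirhom.report import census, family_histogram, stats_frame, summarize

stats = summarize(
    columns={
        "LP": [p.lp for p in PRECURSORS],
        "AU_pct": [p.au_pct for p in PRECURSORS],
        "GC_pct": [p.gc_pct for p in PRECURSORS],
        "MFEI": [p.mfei for p in PRECURSORS],
    },
    mature_lengths=[m.lm for m in MATURES],
)
print(stats_frame(stats).to_string(index=False))

fams = family_histogram([m.name for m in MATURES])
print("\nfamily sizes:", dict(sorted(fams.items(), key=lambda kv: -kv[1])))

c = census(
    CENSUS_COUNTS["n_candidate_est"],
    CENSUS_COUNTS["n_candidate_tsa"],
    CENSUS_COUNTS["n_precursors"],
    CENSUS_COUNTS["n_mirnas"],
    len(fams),
)
print(f"\ntotal candidate sequences: {c.n_candidate_total}")
print(f"frequency: {c.frequency_text}")
# LP mean 111.4 and MFEI mean 0.752 match the printed summary; the census
# reproduces 29,047 candidates and 1 miRNA per 1937 sequences (ceiling rule).
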