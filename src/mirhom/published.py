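"""Bundled reference dataset: previously reported horsegram
(*Macrotyloma uniflorum*) conserved miRNAs.

These published records serve two purposes: a small built-in mature-miRNA
reference set for demonstration runs of the homology scanner, and the
printed inputs from which the reporting layer's summary statistics can be
recomputed and checked.

``CONSISTENT_COMPOSITION`` / ``CONSISTENT_MFEI`` flag the precursor rows
whose printed base counts (resp. AMFE/GC%/MFEI triples) are internally
consistent; the remaining rows carry typographical inconsistencies in the
published table and are excluded from exact cross-checks while still
contributing their printed column values to the published summary
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import ReferenceMature, normalize_seq


@dataclass(frozen=True)
class PublishedPrecursor:
    tsa_id: str
    families: tuple[str, ...]
    lp: int
    au_pct: float
    gc_pct: float
    a: int
    c: int
    g: int
    u: int
    mfe: float       # printed value, sign-normalised to ≤ 0 (kcal/mol)
    amfe: float      # printed value, sign-normalised to ≤ 0 (kcal/mol per 100 nt)
    mfei: float      # printed magnitude


#: Ten predicted precursor records (printed characteristics).
PRECURSORS: tuple[PublishedPrecursor, ...] = (
    PublishedPrecursor("GANR01006328", ("482",), 119, 57.99, 42.01, 38, 28, 22, 31, -42.01, -31.34, 0.74),
    PublishedPrecursor("GANR01007318", ("482",), 130, 39.24, 40.76, 38, 21, 32, 39, -40.76, -35.61, 0.87),
    PublishedPrecursor("GANR01008465", ("156",), 100, 50.0, 50.0, 31, 19, 19, 31, -50.0, -39.0, 0.78),
    PublishedPrecursor("GANR01009673", ("2673",), 118, 53.39, 46.61, 28, 17, 38, 35, -46.61, -26.77, 0.57),
    PublishedPrecursor("GANR01016903", ("5653",), 119, 52.11, 47.89, 36, 25, 32, 26, -47.89, -28.49, 0.59),
    PublishedPrecursor("GANR01019897", ("156",), 107, 56.08, 43.92, 30, 26, 21, 30, -43.92, -26.82, 0.61),
    PublishedPrecursor("GANR01022354", ("1507",), 91, 54.45, 45.05, 31, 23, 18, 19, -45.05, -36.04, 0.8),
    PublishedPrecursor("GANR01022920", ("168",), 122, 41.81, 58.19, 19, 36, 35, 32, -58.19, -48.85, 0.83),
    PublishedPrecursor("GANR01023649", ("2118", "482"), 106, 60.38, 39.62, 36, 19, 23, 28, -39.62, -29.05, 0.7),
    PublishedPrecursor("GANR01024080", ("390",), 102, 56.87, 43.13, 24, 24, 20, 29, -43.13, -44.41, 1.03),
)

#: Rows whose printed base counts reproduce their own LP and AU%/GC%.
CONSISTENT_COMPOSITION = frozenset(
    {"GANR01006328", "GANR01009673", "GANR01016903", "GANR01019897",
     "GANR01022920", "GANR01023649"}
)

#: Rows whose printed MFEI equals |AMFE|/GC% at two decimals.
CONSISTENT_MFEI = frozenset({"GANR01007318", "GANR01009673", "GANR01022354"})


@dataclass(frozen=True)
class PublishedMature:
    name: str          # assigned horsegram name
    homolog: str       # closest reference mature miRNA
    seq_rna: str       # printed mature sequence (RNA alphabet)
    lm: int            # printed mature length
    nm: int            # printed mismatches vs the reference homolog
    arm: str           # "5p" | "3p"
    strand: str        # "+" | "-"

    @property
    def seq_dna(self) -> str:
        return normalize_seq(self.seq_rna)


#: Fifteen predicted mature miRNAs (printed records).
MATURES: tuple[PublishedMature, ...] = (
    PublishedMature("mun-miR482d-3p", "gma-miR482d-3p", "gguaugggagguguagggaaga", 22, 0, "3p", "-"),
    PublishedMature("mun-miR482b-5p", "gma-miR482b-5p", "uuccuucccaauccccccaua", 21, 0, "5p", "-"),
    PublishedMature("mun-miR482a-5p", "gma-miR482a-5p", "agaauuugugggaaugggcuga", 22, 0, "5p", "+"),
    PublishedMature("mun-miR482-5p", "pvu-miR482-5p", "ggaaugggcugauugggaagca", 22, 0, "5p", "+"),
    PublishedMature("mun-miR482a-3p", "gma-miR482a-3p", "ucuucccaauuccgcccauuccua", 24, 0, "3p", "+"),
    PublishedMature("mun-miR156r", "gma-miR156r", "ugcucucuaucuucugucag", 20, 0, "5p", "-"),
    PublishedMature("mun-miR2673a", "mtr-miR2673a", "ucuuccucuuccucuucc", 18, 0, "3p", "+"),
    PublishedMature("mun-miR5653", "ath-miR5653", "ugaguugaguugaguugag", 19, 1, "3p", "+"),
    PublishedMature("mun-miR156k", "osa-miR156k", "gacagaagagagagagcaca", 20, 0, "5p", "+"),
    PublishedMature("mun-miR1507a", "gma-miR1507a", "agacgauguauggaaugaga", 20, 0, "3p", "-"),
    PublishedMature("mun-miR168a-5p", "ath-miR168a-5p", "ucgcuuggugcaggucgggaa", 21, 0, "5p", "+"),
    PublishedMature("mun-miR2118", "pvu-miR2118a", "ggaauggguggaaucggcaa", 21, 0, "3p", "-"),
    PublishedMature("mun-miR482a", "sly-miR482a", "aggaauggguggaauuggaaa", 21, 2, "3p", "-"),
    PublishedMature("mun-miR390b-5p", "gma-miR390b-5p", "gugcuaucccuccugagcuu", 20, 0, "5p", "-"),
    PublishedMature("mun-miR390a-5p", "ath-miR390a-5p", "gcgcuaucccuccugagcuu", 20, 1, "5p", "-"),
)

#: Study-scale census inputs (candidate collection sizes).
CENSUS_COUNTS = {
    "n_candidate_est": 1050,
    "n_candidate_tsa": 27997,
    "n_reference_matures": 8496,
    "n_precursors": 10,
    "n_mirnas": 15,
}


def reference_set() -> list[ReferenceMature]:
    """The bundled mature reference set as scanner-ready records."""
    return [ReferenceMature(id=m.name, seq=m.seq_dna) for m in MATURES]
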