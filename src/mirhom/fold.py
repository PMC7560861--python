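"""Precursor excision and RNA secondary-structure folding.

A candidate precursor window is excised around each surviving homology hit
(mature ± ``flank`` nt, clipped at transcript ends; minus-strand hits are
reverse-complemented so the window reads 5′→3′ on the hit strand) and folded
to its minimum-free-energy structure at 37 °C.

Folding is a pluggable contract.  The production adapter wraps the
ViennaRNA thermodynamic folder (Zuker-class MFE prediction).  A simplified
stacking-count model — a Nussinov-style dynamic program with pair scores
GC 3, AU 2, GU 1 and minimum loop 3 — is bundled for unit tests where
absolute energies are not asserted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol

from .scan import HomologyHit
from .seqio import TranscriptRecord, revcomp, to_rna

log = logging.getLogger(__name__)

#: minimum window worth folding: a mature plus minimal stem/loop headroom
MIN_FOLDABLE = 30


@dataclass(frozen=True)
class PrecursorCandidate:
    """An excised precursor window on the hit strand, 5′→3′."""

    transcript_id: str
    window_start: int
    window_end: int
    seq: str
    mature_offset: int
    mature_len: int
    strand: str = "+"
    ref_id: str = ""
    mismatches: int = 0

    @property
    def id(self) -> str:
        return f"{self.transcript_id}:{self.window_start}-{self.window_end}({self.strand})"


@dataclass(frozen=True)
class FoldResult:
    """MFE structure of a candidate: dot-bracket string plus free energy."""

    dotbracket: str
    mfe: float  # kcal/mol (score units for the test backend), ≤ 0
    temperature_c: float = 37.0
    backend: str = "vienna"


class FoldBackend(Protocol):
    name: str

    def fold(self, seq: str) -> tuple[str, float]:
        """Return (dotbracket, mfe) for a DNA-alphabet sequence."""
        ...


class FoldError(RuntimeError):
    """Backend failure, carrying backend diagnostics."""


class ViennaBackend:
    """ViennaRNA MFE folding at 37 °C.

    Ionic conditions (1 M NaCl, no divalent ions) are recorded as metadata
    only: the Turner parameter set does not expose them, which is logged as
    a warning once rather than treated as an error.
    """

    name = "vienna"
    _warned = False

    def __init__(self, temperature_c: float = 37.0):
        try:
            import RNA  # ViennaRNA python bindings
        except ImportError as exc:  # pragma: no cover
            raise FoldError("ViennaRNA python bindings not available") from exc
        self._RNA = RNA
        self.temperature_c = temperature_c
        if not ViennaBackend._warned:
            log.warning(
                "thermodynamic parameters assume standard Turner conditions; "
                "requested ionic conditions (1 M NaCl) are metadata only"
            )
            ViennaBackend._warned = True

    def fold(self, seq: str) -> tuple[str, float]:
        try:
            md = self._RNA.md()
            md.temperature = self.temperature_c
            fc = self._RNA.fold_compound(to_rna(seq), md)
            db, mfe = fc.mfe()
        except Exception as exc:  # pragma: no cover
            raise FoldError(f"ViennaRNA failure on {seq[:30]}…: {exc}") from exc
        return db, float(mfe)


_PAIR_SCORE = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}


class StackingBackend:
    """Nussinov-style maximum pair-score DP (GC 3, AU 2, GU 1, min loop 3).

    Deterministic traceback: leaving ``j`` unpaired is preferred on ties,
    then pairing ``j`` with the smallest admissible ``k``.  The "energy"
    returned is the negated pair score — not kcal/mol, but it orders
    structures the same way for the unit-test properties that use it.
    """

    name = "stacking"
    min_loop = 3

    def fold(self, seq: str) -> tuple[str, float]:
        n = len(seq)
        score = [[0] * n for _ in range(n)]
        for span in range(self.min_loop + 1, n):
            for i in range(n - span):
                j = i + span
                best = score[i][j - 1]  # j unpaired
                for k in range(i, j - self.min_loop):
                    p = _PAIR_SCORE.get((seq[k], seq[j]))
                    if p is None:
                        continue
                    left = score[i][k - 1] if k > i else 0
                    inner = score[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    best = max(best, left + inner + p)
                score[i][j] = best
        structure = ["."] * n
        stack = [(0, n - 1)] if n else []
        while stack:
            i, j = stack.pop()
            if i >= j or score[i][j] == 0:
                continue
            if score[i][j] == score[i][j - 1]:
                stack.append((i, j - 1))
                continue
            for k in range(i, j - self.min_loop):
                p = _PAIR_SCORE.get((seq[k], seq[j]))
                if p is None:
                    continue
                left = score[i][k - 1] if k > i else 0
                inner = score[k + 1][j - 1] if k + 1 <= j - 1 else 0
                if left + inner + p == score[i][j]:
                    structure[k] = "("
                    structure[j] = ")"
                    if k > i:
                        stack.append((i, k - 1))
                    if k + 1 <= j - 1:
                        stack.append((k + 1, j - 1))
                    break
        total = score[0][n - 1] if n else 0
        return "".join(structure), -float(total)


def excise_window(
    t: TranscriptRecord, hit: HomologyHit, flank: int = 80
) -> PrecursorCandidate | None:
    """Excise the precursor window ``[hit.start − flank, hit.end + flank)``,
    clipped to transcript bounds.

    For minus-strand hits the returned sequence is the reverse complement of
    the window and the mature offset is recomputed on that strand.  Returns
    ``None`` when the clipped window is shorter than mature length + 20.
    """
    if not (0 <= hit.start < hit.end <= len(t.seq)):
        raise ValueError(
            f"hit {hit.ref_id}@[{hit.start},{hit.end}) outside transcript {t.id}"
        )
    mature_len = hit.align_len
    lo = max(0, hit.start - flank)
    hi = min(len(t.seq), hit.end + flank)
    if hi - lo < mature_len + 20:
        return None
    window = t.seq[lo:hi]
    if hit.strand == "+":
        seq = window
        mature_offset = hit.start - lo
    else:
        seq = revcomp(window)
        mature_offset = hi - hit.end
    return PrecursorCandidate(
        transcript_id=t.id,
        window_start=lo,
        window_end=hi,
        seq=seq,
        mature_offset=mature_offset,
        mature_len=mature_len,
        strand=hit.strand,
        ref_id=hit.ref_id,
        mismatches=hit.mismatches,
    )


def fold(c: PrecursorCandidate, backend: FoldBackend) -> FoldResult | None:
    """Fold a candidate to its MFE structure.

    Returns ``None`` ("no structure") when the optimal structure has no base
    pairs or non-negative energy — such candidates are discarded upstream of
    screening.  Deterministic for a fixed backend and input.
    """
    if len(c.seq) < MIN_FOLDABLE:
        raise ValueError(f"candidate {c.id} shorter than {MIN_FOLDABLE} nt")
    db, mfe = backend.fold(c.seq)
    if len(db) != len(c.seq):
        raise FoldError(f"backend {backend.name}: structure length mismatch")
    if "(" not in db or mfe >= 0:
        return None
    temp = getattr(backend, "temperature_c", 37.0)
    return FoldResult(dotbracket=db, mfe=mfe, temperature_c=temp, backend=backend.name)
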