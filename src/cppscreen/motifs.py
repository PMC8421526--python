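"""Nuclear-trafficking and molecular-sled motif scanners.

Two motif grammars are screened on candidate peptides:

* the classical NLS consensus K-K/R-X-K/R, where X is any residue or a
  short span of residues (capped at ``max_span``, default 10 — the scale of
  a bipartite-NLS linker);
* "molecular sled" motifs — runs of basic residues (K/R) of length >= 3,
  reported as one match per maximal run (``sled4`` when the run is >= 4
  residues long, ``sled3`` for a run of exactly 3).

Coordinates are 1-based inclusive within the scanned sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import PeptideWindow, ValidationError, _check_sequence

__all__ = [
    "MotifMatch",
    "MotifAnnotation",
    "find_nls_consensus",
    "find_sled_motifs",
    "annotate_peptide",
    "sequence_has_motif",
]

_SLED_RE = re.compile(r"[KR]{3,}")
_BASIC = frozenset("KR")


@dataclass(frozen=True)
class MotifMatch:
    kind: str
    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError("motif match with end < start")


def find_nls_consensus(sequence: str, max_span: int = 10) -> list[MotifMatch]:
    """All matches of K, then K/R, then 1..max_span residues, then K/R.

    Overlapping matches at different start positions are all reported; per
    start position only the shortest satisfying span is reported, keeping
    the output finite and canonical.
    """
    if max_span < 1:
        raise ValidationError("max_span must be >= 1")
    seq = _check_sequence(sequence)
    matches = []
    for i in range(len(seq) - 3):
        if seq[i] != "K" or seq[i + 1] not in _BASIC:
            continue
        for span in range(1, max_span + 1):
            j = i + 2 + span  # index of the final K/R
            if j >= len(seq):
                break
            if seq[j] in _BASIC:
                matches.append(
                    MotifMatch("nls_consensus", i + 1, j + 1, seq[i : j + 1])
                )
                break
    return matches


def find_sled_motifs(sequence: str) -> list[MotifMatch]:
    """Maximal K/R runs of length >= 3, one disjoint match per run."""
    seq = _check_sequence(sequence)
    out = []
    for m in _SLED_RE.finditer(seq):
        kind = "sled4" if m.end() - m.start() >= 4 else "sled3"
        out.append(MotifMatch(kind, m.start() + 1, m.end(), m.group()))
    return out


@dataclass(frozen=True)
class MotifAnnotation:
    """Per-peptide motif summary used in screening reports."""

    has_nls_consensus: bool
    has_sled3: bool
    has_sled4: bool
    overlaps_user_interval: bool
    nls_matches: tuple[MotifMatch, ...] = field(default_factory=tuple)
    sled_matches: tuple[MotifMatch, ...] = field(default_factory=tuple)

    @property
    def has_any_motif(self) -> bool:
        return self.has_nls_consensus or self.has_sled3 or self.has_sled4


def annotate_peptide(
    window: PeptideWindow,
    user_intervals: Optional[Sequence[tuple[int, int]]] = None,
    max_span: int = 10,
) -> MotifAnnotation:
    """Scan one window for both motif grammars and user-supplied intervals.

    ``user_intervals`` are known functional regions (e.g. curated NLS
    annotations) given as 1-based inclusive (start, end) pairs in parent
    coordinates; the flag records whether the window overlaps any of them.
    """
    nls = tuple(find_nls_consensus(window.sequence, max_span=max_span))
    sleds = tuple(find_sled_motifs(window.sequence))
    overlaps = False
    for iv in user_intervals or ():
        s, e = iv
        if s > e:
            raise ValidationError(f"malformed interval {iv}: start > end")
        if window.start <= e and s <= window.end:
            overlaps = True
    return MotifAnnotation(
        has_nls_consensus=bool(nls),
        has_sled3=any(m.kind == "sled3" for m in sleds),
        has_sled4=any(m.kind == "sled4" for m in sleds),
        overlaps_user_interval=overlaps,
        nls_matches=nls,
        sled_matches=sleds,
    )


def sequence_has_motif(sequence: str, max_span: int = 10) -> bool:
    """True when the bare sequence contains any NLS-consensus or sled motif."""
    return bool(find_sled_motifs(sequence)) or bool(
        find_nls_consensus(sequence, max_span=max_span)
    )
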