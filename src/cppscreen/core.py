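"""Sequence data model, FASTA I/O, window enumeration, and peptide calculators.

Coordinates are 1-based inclusive throughout, matching the convention used
for protein-derived peptide names such as ``Tat_48-60`` (residues 48..60 of
the parent protein). Non-canonical residues (B, J, O, U, X, Z, ...) are
rejected at ingest: every downstream encoder assumes the 20-letter alphabet.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

from ._tables import AMINO_ACIDS

__all__ = [
    "ValidationError",
    "ProteinRecord",
    "PeptideWindow",
    "ScanConfig",
    "MassOptions",
    "read_fasta",
    "write_fasta",
    "read_peptide_list",
    "enumerate_windows",
    "expected_window_count",
    "peptide_mass",
    "net_charge",
    "windows_to_frame",
    "write_windows_tsv",
]

_ALPHABET = frozenset(AMINO_ACIDS)

# Average / monoisotopic mass shift of C-terminal amidation: -OH replaced
# by -NH2 (O -> NH, i.e. -15.9994 + 15.0146 average).
_AMIDE_SHIFT_AVG = -0.9848
_AMIDE_SHIFT_MONO = -0.98402


class ValidationError(ValueError):
    """An input violates a sequence, label, or configuration contract."""


def _check_sequence(sequence: str, context: str = "sequence") -> str:
    seq = sequence.upper()
    if not seq:
        raise ValidationError(f"{context}: empty sequence")
    for ch in seq:
        if ch not in _ALPHABET:
            raise ValidationError(
                f"{context}: non-canonical residue {ch!r} "
                f"(allowed: {AMINO_ACIDS})"
            )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """A validated protein sequence, the substrate of the screen."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", _check_sequence(self.sequence, f"record {self.id!r}")
        )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideWindow:
    """A peptide subsequence with 1-based inclusive parent coordinates."""

    parent_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValidationError(
                f"window {self.parent_id}: bad coordinates {self.start}-{self.end}"
            )
        if self.end - self.start + 1 != len(self.sequence):
            raise ValidationError(
                f"window {self.parent_id}_{self.start}-{self.end}: coordinate span "
                f"does not match sequence length {len(self.sequence)}"
            )

    @property
    def name(self) -> str:
        return f"{self.parent_id}_{self.start}-{self.end}"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScanConfig:
    """Window-length bounds for protein fragmentation (default 5..30 aa)."""

    min_len: int = 5
    max_len: int = 30

    def __post_init__(self) -> None:
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValidationError(
                f"invalid scan bounds min_len={self.min_len}, max_len={self.max_len}"
            )


@dataclass(frozen=True)
class MassOptions:
    """Mass-calculation options.

    ``c_term_amide`` defaults to False (free-acid C terminus) for generic
    calculations; synthesized peptides on Rink-amide resin are C-terminally
    amidated and should use :meth:`synthesized`.
    """

    c_term_amide: bool = False
    mass_kind: str = "average"

    def __post_init__(self) -> None:
        if self.mass_kind not in ("average", "monoisotopic"):
            raise ValidationError(f"unknown mass_kind {self.mass_kind!r}")

    @classmethod
    def synthesized(cls, mass_kind: str = "average") -> "MassOptions":
        return cls(c_term_amide=True, mass_kind=mass_kind)


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into validated :class:`ProteinRecord`\\ s.

    Sequences are uppercased; file order is preserved. A record containing
    a residue outside the canonical 20-letter alphabet raises
    :class:`ValidationError` naming the record and the offending character.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq), description=rec.description)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | os.PathLike) -> None:
    """Write records to FASTA (inverse of :func:`read_fasta` on id+sequence)."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_peptide_list(path: str | os.PathLike) -> list[str]:
    """Read peptides from FASTA or plain one-sequence-per-line text."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if stripped.startswith(">"):
        return [r.sequence for r in read_fasta(path)]
    peptides = []
    for i, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if line:
            peptides.append(_check_sequence(line, f"line {i}"))
    return peptides


def enumerate_windows(
    protein: ProteinRecord, cfg: ScanConfig = ScanConfig()
) -> list[PeptideWindow]:
    """Enumerate every subsequence with length in [min_len, max_len].

    Output is ordered by start position, then by length. A protein shorter
    than ``min_len`` yields an empty list.
    """
    seq = protein.sequence
    L = len(seq)
    windows = []
    for start0 in range(L):
        max_l = min(cfg.max_len, L - start0)
        for length in range(cfg.min_len, max_l + 1):
            windows.append(
                PeptideWindow(
                    parent_id=protein.id,
                    start=start0 + 1,
                    end=start0 + length,
                    sequence=seq[start0 : start0 + length],
                )
            )
    return windows


def expected_window_count(L: int, cfg: ScanConfig = ScanConfig()) -> int:
    """Closed-form window count: sum over lengths l of max(0, L - l + 1).

    Under the default 5..30 bounds this equals ``26 L - 429`` for L >= 30.
    """
    return sum(
        max(0, L - l + 1) for l in range(cfg.min_len, cfg.max_len + 1)
    )


def peptide_mass(sequence: str, opts: MassOptions = MassOptions()) -> float:
    """Peptide mass in Da: residue masses plus one water, optionally amidated.

    Average masses by default; C-terminal amidation substitutes -NH2 for the
    free-acid -OH and shifts the mass by about -0.98 Da.
    """
    seq = _check_sequence(sequence)
    mono = opts.mass_kind == "monoisotopic"
    mass = molecular_weight(seq, seq_type="protein", monoisotopic=mono)
    if opts.c_term_amide:
        mass += _AMIDE_SHIFT_MONO if mono else _AMIDE_SHIFT_AVG
    return float(mass)


def net_charge(sequence: str) -> int:
    """Formal net charge at neutral pH: (K + R) - (D + E); histidine neutral."""
    seq = _check_sequence(sequence)
    return (
        seq.count("K") + seq.count("R") - seq.count("D") - seq.count("E")
    )


def windows_to_frame(windows: Sequence[PeptideWindow]) -> pd.DataFrame:
    """Tabulate windows: parent_id, name, start, end, length, sequence."""
    return pd.DataFrame(
        {
            "parent_id": [w.parent_id for w in windows],
            "name": [w.name for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "length": [len(w) for w in windows],
            "sequence": [w.sequence for w in windows],
        }
    )


def write_windows_tsv(windows: Sequence[PeptideWindow], path: str | os.PathLike) -> None:
    windows_to_frame(windows).to_csv(path, sep="\t", index=False)
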