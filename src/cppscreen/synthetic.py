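"""Seeded synthetic data: labeled CPP/non-CPP sets and planted-region proteins.

The original predictors were trained on curated CPP collections that are
not redistributable, and the screened proteins were database isoforms. This
module stands in for both with fully seeded generators:

* the **CPP class** is cationic — each peptide carries a K/R fraction drawn
  from a configured range (default 0.30-0.60), optionally with an
  amphipathic hydrophobic spacing — reflecting the charge signal shared by
  the classical CPPs;
* the **non-CPP class** is drawn i.i.d. from a packaged SwissProt-like
  background composition;
* **planted proteins** are background sequences with CPP-class segments
  inserted at recorded positions, emulating nuclear proteins of a few
  hundred to ~1,400 residues with known ground truth.

Everything is fully determined by the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._tables import AMINO_ACIDS, BACKGROUND_FREQS
from .core import ProteinRecord, ValidationError
from .predictors import LabeledPeptideSet

__all__ = [
    "GeneratorSpec",
    "PlantedProtein",
    "generate_training_set",
    "generate_planted_protein",
    "table2_fixture",
    "intervals_to_tsv",
]

_AA = np.array(list(AMINO_ACIDS))
_BG_P = np.array([BACKGROUND_FREQS[aa] for aa in AMINO_ACIDS])
_NONBASIC = np.array([aa for aa in AMINO_ACIDS if aa not in "KR"])
_NONBASIC_P = np.array([BACKGROUND_FREQS[aa] for aa in _NONBASIC])
_NONBASIC_P = _NONBASIC_P / _NONBASIC_P.sum()
_HYDROPHOBIC = np.array(list("LIVFM"))


@dataclass(frozen=True)
class GeneratorSpec:
    """Stated world of the synthetic training sets.

    Defaults: peptide lengths 5-30 aa (the screening window range), CPP
    basic-residue fraction 0.30-0.60, non-amphipathic, SwissProt-like
    background.
    """

    seed: int = 0
    n_cpp: int = 100
    n_noncpp: int = 100
    min_len: int = 5
    max_len: int = 30
    basic_fraction: tuple[float, float] = (0.30, 0.60)
    amphipathic: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.basic_fraction
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("basic_fraction range must be ordered within [0, 1]")
        if not 1 <= self.min_len <= self.max_len:
            raise ValidationError("length range must satisfy 1 <= min_len <= max_len")
        if self.n_cpp < 0 or self.n_noncpp < 0:
            raise ValidationError("counts must be non-negative")


@dataclass(frozen=True)
class PlantedProtein:
    """A background protein with CPP-like segments at known positions."""

    record: ProteinRecord
    truth: tuple[tuple[int, int], ...]  # 1-based inclusive, non-overlapping


def _draw_cpp_peptide(rng: np.random.Generator, length: int, spec: GeneratorSpec) -> str:
    lo, hi = spec.basic_fraction
    n_lo = int(np.ceil(lo * length))
    n_hi = int(np.floor(hi * length))
    if n_lo > n_hi:
        raise ValidationError(
            f"no integer basic count satisfies fraction range {spec.basic_fraction} "
            f"at length {length}"
        )
    n_basic = int(rng.integers(n_lo, n_hi + 1))
    residues = rng.choice(_NONBASIC, size=length, p=_NONBASIC_P)
    if spec.amphipathic:
        # hydrophobic residue every 3-4 positions, giving a crude helical face
        pos = int(rng.integers(0, 3))
        while pos < length:
            residues[pos] = rng.choice(_HYDROPHOBIC)
            pos += int(rng.integers(3, 5))
    # Stratified placement: one basic residue per length block, so the
    # cationic character is carried along the whole peptide (as in Tat or
    # penetratin) rather than clumped at one end with a background-like tail.
    edges = np.linspace(0, length, n_basic + 1)
    basic_pos = np.array(
        [int(rng.integers(int(edges[k]), int(edges[k + 1]))) for k in range(n_basic)]
    )
    basics = rng.choice(np.array(["K", "R"]), size=n_basic)
    residues[basic_pos] = basics
    return "".join(residues)


def _draw_background(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length, p=_BG_P))


def generate_training_set(spec: GeneratorSpec) -> LabeledPeptideSet:
    """Draw a labeled CPP/non-CPP peptide set, fully determined by the seed.

    CPP-class peptides (label 1) come first, then background peptides
    (label 0).
    """
    if spec.n_cpp == 0 and spec.n_noncpp == 0:
        raise ValidationError("at least one class must have a positive count")
    rng = np.random.default_rng(spec.seed)
    peptides, labels = [], []
    for _ in range(spec.n_cpp):
        length = int(rng.integers(spec.min_len, spec.max_len + 1))
        peptides.append(_draw_cpp_peptide(rng, length, spec))
        labels.append(1)
    for _ in range(spec.n_noncpp):
        length = int(rng.integers(spec.min_len, spec.max_len + 1))
        peptides.append(_draw_background(rng, length))
        labels.append(0)
    return LabeledPeptideSet(peptides=peptides, labels=np.array(labels))


def generate_planted_protein(
    length: int,
    n_segments: int,
    seed: int,
    spec: Optional[GeneratorSpec] = None,
    segment_len_range: tuple[int, int] = (15, 30),
    min_gap: int = 10,
    protein_id: str = "planted",
) -> PlantedProtein:
    """Background protein with ``n_segments`` planted CPP-like segments.

    Segments are drawn from the CPP generator (non-amphipathic by default,
    so recovery tests measure the shared charge signal), are 15-30 aa long,
    non-overlapping, and separated from each other and the termini by at
    least ``min_gap`` residues. Raises on infeasible packing.
    """
    if spec is None:
        spec = GeneratorSpec(seed=seed, amphipathic=False)
    rng = np.random.default_rng(seed)
    seg_lens = [
        int(rng.integers(segment_len_range[0], segment_len_range[1] + 1))
        for _ in range(n_segments)
    ]
    slack = length - sum(seg_lens) - (n_segments + 1) * min_gap
    if n_segments > 0 and slack < 0:
        raise ValidationError(
            f"cannot pack {n_segments} segments of total {sum(seg_lens)} aa "
            f"plus gaps into length {length}"
        )
    sequence = list(_draw_background(rng, length))
    truth = []
    if n_segments:
        # distribute the slack over the n_segments + 1 gaps
        extra = rng.multinomial(slack, np.full(n_segments + 1, 1.0 / (n_segments + 1)))
        pos = 0
        for k, seg_len in enumerate(seg_lens):
            pos += min_gap + int(extra[k])
            segment = _draw_cpp_peptide(rng, seg_len, spec)
            sequence[pos : pos + seg_len] = list(segment)
            truth.append((pos + 1, pos + seg_len))
            pos += seg_len
    record = ProteinRecord(id=protein_id, sequence="".join(sequence))
    return PlantedProtein(record=record, truth=tuple(truth))


#: The 12 peptides of the published screen (name, sequence), in table order.
#: Tat is the literature control; VP8 is an additional basic control.
_TABLE2 = (
    ("Tat_48-60", "GRKKRRQRRRPPQ"),
    ("AKIP1_27-37", "VLERAKRRAV"),
    ("CASC3_251-264", "PDDIKPRRIRKPRY"),
    ("CCNL2_354-365", "NTKRRLEGAKKA"),
    ("DAPK1_40-52", "AAKFIKKRRTKSS"),
    ("ING4_134-145", "TQKEKKAARARSK"),
    ("DMAP1_459-467", "RKRRESASSSSSVKKAKKP"),
    ("VP8", "KRKGRLRSKGKK"),
    ("NOP53_397-410", "AEADKPRRLGRLK"),
    ("AHRR_8-24", "GECTYAGRKRRRPLQK"),
    ("CUL4B_48-59", "TPPTSAKKRKL"),
    ("FBXO32_59-69", "VAAKKRKKDML"),
)


def table2_fixture() -> list[tuple[str, str]]:
    """The 12 published peptide (name, sequence) pairs, validated."""
    for _, seq in _TABLE2:
        ProteinRecord(id="check", sequence=seq)  # alphabet validation
    return list(_TABLE2)


def intervals_to_tsv(
    intervals: Sequence[tuple[int, int]],
    parent_id: str,
    path: str | os.PathLike,
) -> None:
    """Write truth intervals as a 3-column TSV (id, start, end; 1-based)."""
    with open(path, "w") as fh:
        for s, e in intervals:
            fh.write(f"{parent_id}\t{s}\t{e}\n")
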