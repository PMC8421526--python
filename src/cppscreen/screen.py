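"""Two-round consensus screening, CPP-dense region calling, and reporting.

The workflow mirrors a protein-wide CPP hunt:

1. **Round 1** — every 5-30 aa window of the protein is scored 0-3 by the
   z-scale predictor; windows scoring >= 2 pass.
2. **Round 2** — round-1 passers are re-evaluated by the composition SVM
   (CPP iff decision >= tau, default 0.0) and the skip-gram random forest
   (keep iff confidence >= 0.7). Windows shorter than 10 aa fail round 2
   with an explicit reason code rather than being silently dropped,
   mirroring the input-length limit of composition-SVM-style predictors.
3. **Region calling** — per-residue coverage by surviving candidates is
   thresholded to map CPP-dense regions of the protein.
4. **Ranking** — candidates are ordered by a combined score, the mean of
   the three predictors' outputs brought to a common [0, 1] scale.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import (
    PeptideWindow,
    ProteinRecord,
    ScanConfig,
    ValidationError,
    enumerate_windows,
)
from .motifs import MotifAnnotation, annotate_peptide
from .predictors import (
    CompositionSvmModel,
    SkipGramRfModel,
    ZScaleModel,
    _require_fitted,
)

__all__ = [
    "ConsensusConfig",
    "ScoredWindow",
    "RegionCall",
    "ScreenReport",
    "run_first_round",
    "run_second_round",
    "call_regions",
    "rank_candidates",
    "screen_protein",
]

REPORT_SCHEMA_VERSION = 1

# round-2 reason codes
REASON_PASS = "pass"
REASON_NOT_EVALUATED = "failed_round1"
REASON_TOO_SHORT = "below_svm_min_len"
REASON_SVM_NON_CPP = "svm_non_cpp"
REASON_RF_BELOW_CUTOFF = "rf_confidence_below_cutoff"


@dataclass(frozen=True)
class ConsensusConfig:
    """Thresholds of the two-round consensus filter.

    ``first_round_min_score``: keep windows scoring >= this (0-3 scale).
    ``svm_min_len``: windows shorter than this fail round 2 (input-length
    limit of the composition predictor).
    ``rf_cutoff``: keep windows with forest confidence >= this (boundary
    kept: "below 0.7 excluded" means keep-if >= 0.7).
    ``svm_threshold``: CPP iff SVM decision value >= tau.
    """

    first_round_min_score: int = 2
    svm_min_len: int = 10
    rf_cutoff: float = 0.7
    svm_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.first_round_min_score not in (0, 1, 2, 3):
            raise ValidationError("first_round_min_score must be in {0..3}")
        if not 0.0 <= self.rf_cutoff <= 1.0:
            raise ValidationError("rf_cutoff must be in [0, 1]")
        if self.svm_min_len < 1:
            raise ValidationError("svm_min_len must be >= 1")


@dataclass
class ScoredWindow:
    """One window with every score the pipeline assigned to it."""

    window: PeptideWindow
    zscale_score: int
    passed_round1: bool
    svm_decision: Optional[float] = None
    svm_label: Optional[int] = None
    rf_confidence: Optional[float] = None
    annotation: Optional[MotifAnnotation] = None
    passed_round2: bool = False
    round2_reason: str = REASON_NOT_EVALUATED


@dataclass(frozen=True)
class RegionCall:
    """A CPP-dense protein region (1-based inclusive coordinates)."""

    parent_id: str
    start: int
    end: int
    peak_coverage: int
    mean_coverage: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ScreenReport:
    """Self-describing result of screening one protein."""

    protein_id: str
    protein_length: int
    windows: list[ScoredWindow]
    candidates: list[ScoredWindow]
    regions: list[RegionCall]
    scan_config: ScanConfig
    consensus_config: ConsensusConfig
    seeds: dict[str, int] = field(default_factory=dict)
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        def sw(s: ScoredWindow) -> dict:
            d = {
                "name": s.window.name,
                "start": s.window.start,
                "end": s.window.end,
                "sequence": s.window.sequence,
                "zscale_score": s.zscale_score,
                "passed_round1": s.passed_round1,
                "svm_decision": s.svm_decision,
                "svm_label": s.svm_label,
                "rf_confidence": s.rf_confidence,
                "passed_round2": s.passed_round2,
                "round2_reason": s.round2_reason,
            }
            if s.annotation is not None:
                d["motifs"] = {
                    "has_nls_consensus": s.annotation.has_nls_consensus,
                    "has_sled3": s.annotation.has_sled3,
                    "has_sled4": s.annotation.has_sled4,
                    "overlaps_user_interval": s.annotation.overlaps_user_interval,
                }
            return d

        return {
            "schema_version": self.schema_version,
            "protein_id": self.protein_id,
            "protein_length": self.protein_length,
            "scan_config": asdict(self.scan_config),
            "consensus_config": asdict(self.consensus_config),
            "seeds": dict(self.seeds),
            "n_windows": len(self.windows),
            "n_round1_passed": sum(s.passed_round1 for s in self.windows),
            "candidates": [sw(s) for s in self.candidates],
            "regions": [asdict(r) for r in self.regions],
        }

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def candidates_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.candidates:
            rows.append(
                {
                    "name": s.window.name,
                    "start": s.window.start,
                    "end": s.window.end,
                    "length": len(s.window),
                    "sequence": s.window.sequence,
                    "zscale_score": s.zscale_score,
                    "svm_decision": s.svm_decision,
                    "rf_confidence": s.rf_confidence,
                    "combined_score": combined_score(s),
                    "has_nls_consensus": s.annotation.has_nls_consensus
                    if s.annotation
                    else None,
                    "has_sled3": s.annotation.has_sled3 if s.annotation else None,
                    "has_sled4": s.annotation.has_sled4 if s.annotation else None,
                }
            )
        return pd.DataFrame(rows)

    def regions_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.regions])


def run_first_round(
    protein: ProteinRecord,
    zmodel: ZScaleModel,
    scan_cfg: ScanConfig = ScanConfig(),
    cfg: ConsensusConfig = ConsensusConfig(),
) -> list[ScoredWindow]:
    """Enumerate and score every window; flag those scoring >= the cutoff."""
    _require_fitted(zmodel)
    windows = enumerate_windows(protein, scan_cfg)
    if not windows:
        return []
    scores = zmodel.predict_scores([w.sequence for w in windows])
    return [
        ScoredWindow(
            window=w,
            zscale_score=int(s),
            passed_round1=bool(s >= cfg.first_round_min_score),
        )
        for w, s in zip(windows, scores)
    ]


def run_second_round(
    scored: Sequence[ScoredWindow],
    svm_model: CompositionSvmModel,
    rf_model: SkipGramRfModel,
    cfg: ConsensusConfig = ConsensusConfig(),
    user_intervals: Optional[Sequence[tuple[int, int]]] = None,
) -> list[ScoredWindow]:
    """Re-evaluate round-1 passers with the SVM and the random forest.

    Only round-1 passers are evaluated. Windows shorter than ``svm_min_len``
    fail with an explicit reason code. A window passes round 2 iff it passed
    round 1, is long enough, the SVM labels it CPP at ``svm_threshold``, and
    the forest confidence is >= ``rf_cutoff``. Motif annotation is attached
    to every evaluated (round-1-passing) window.
    """
    _require_fitted(svm_model)
    _require_fitted(rf_model)
    evaluable = [
        s for s in scored if s.passed_round1 and len(s.window) >= cfg.svm_min_len
    ]
    peptides = [s.window.sequence for s in evaluable]
    if peptides:
        decisions = svm_model.decision_values(peptides)
        confidences = rf_model.predict_confidence(peptides)
    else:
        decisions = confidences = np.zeros(0)

    it = iter(zip(decisions, confidences))
    out = []
    for s in scored:
        if not s.passed_round1:
            out.append(s)
            continue
        annotation = annotate_peptide(s.window, user_intervals)
        if len(s.window) < cfg.svm_min_len:
            out.append(
                ScoredWindow(
                    window=s.window,
                    zscale_score=s.zscale_score,
                    passed_round1=True,
                    annotation=annotation,
                    passed_round2=False,
                    round2_reason=REASON_TOO_SHORT,
                )
            )
            continue
        dec, conf = next(it)
        label = int(dec >= cfg.svm_threshold)
        if not label:
            reason = REASON_SVM_NON_CPP
        elif conf < cfg.rf_cutoff:
            reason = REASON_RF_BELOW_CUTOFF
        else:
            reason = REASON_PASS
        out.append(
            ScoredWindow(
                window=s.window,
                zscale_score=s.zscale_score,
                passed_round1=True,
                svm_decision=float(dec),
                svm_label=label,
                rf_confidence=float(conf),
                annotation=annotation,
                passed_round2=(reason == REASON_PASS),
                round2_reason=reason,
            )
        )
    return out


def call_regions(
    protein: ProteinRecord,
    candidates: Sequence[ScoredWindow],
    min_cov_fraction: float = 0.5,
    min_region_len: int = 10,
    max_gap: int = 5,
) -> list[RegionCall]:
    """Map CPP-dense regions from candidate-window coverage.

    Per-residue coverage counts the candidate windows overlapping each
    residue. Coverage splits into contiguous covered stretches (components);
    within each component, maximal runs with coverage >= ``min_cov_fraction``
    times that component's peak are kept — thresholding against the local
    peak rather than the protein-wide maximum, so dense regions of unequal
    strength (the common case when several regions exist) are all called.
    Runs separated by gaps <= ``max_gap`` residues are merged, and merged
    runs shorter than ``min_region_len`` are dropped.
    """
    L = protein.length
    cov = np.zeros(L, dtype=int)
    for s in candidates:
        w = s.window
        if w.parent_id != protein.id or w.end > L:
            raise ValidationError(f"candidate {w.name} does not belong to {protein.id}")
        cov[w.start - 1 : w.end] += 1
    if cov.max() == 0:
        return []

    # per-component threshold mask
    mask = np.zeros(L, dtype=bool)
    i = 0
    while i < L:
        if cov[i] > 0:
            j = i
            while j + 1 < L and cov[j + 1] > 0:
                j += 1
            threshold = min_cov_fraction * cov[i : j + 1].max()
            mask[i : j + 1] = cov[i : j + 1] >= threshold
            i = j + 1
        else:
            i += 1

    # maximal runs of True
    runs: list[list[int]] = []
    i = 0
    while i < L:
        if mask[i]:
            j = i
            while j + 1 < L and mask[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    # merge runs separated by small gaps
    merged = [runs[0]]
    for s0, e0 in runs[1:]:
        if s0 - merged[-1][1] - 1 <= max_gap:
            merged[-1][1] = e0
        else:
            merged.append([s0, e0])
    return [
        RegionCall(
            parent_id=protein.id,
            start=s0 + 1,
            end=e0 + 1,
            peak_coverage=int(cov[s0 : e0 + 1].max()),
            mean_coverage=float(cov[s0 : e0 + 1].mean()),
        )
        for s0, e0 in merged
        if e0 - s0 + 1 >= min_region_len
    ]


def combined_score(s: ScoredWindow) -> float:
    """Mean of the three predictor outputs on a common [0, 1] scale."""
    return float(
        np.mean(
            [s.zscale_score / 3.0, expit(s.svm_decision), s.rf_confidence]
        )
    )


def rank_candidates(candidates: Sequence[ScoredWindow]) -> list[ScoredWindow]:
    """Order candidates by combined score (desc), ties by (start, length)."""
    return sorted(
        candidates,
        key=lambda s: (-combined_score(s), s.window.start, len(s.window)),
    )


def screen_protein(
    protein: ProteinRecord,
    zmodel: ZScaleModel,
    svm_model: CompositionSvmModel,
    rf_model: SkipGramRfModel,
    scan_cfg: ScanConfig = ScanConfig(),
    cfg: ConsensusConfig = ConsensusConfig(),
    user_intervals: Optional[Sequence[tuple[int, int]]] = None,
    region_kwargs: Optional[dict] = None,
) -> ScreenReport:
    """Run the full two-round screen on one protein and assemble the report."""
    scored = run_first_round(protein, zmodel, scan_cfg, cfg)
    scored = run_second_round(scored, svm_model, rf_model, cfg, user_intervals)
    candidates = rank_candidates([s for s in scored if s.passed_round2])
    regions = call_regions(protein, candidates, **(region_kwargs or {}))
    return ScreenReport(
        protein_id=protein.id,
        protein_length=protein.length,
        windows=scored,
        candidates=candidates,
        regions=regions,
        scan_config=scan_cfg,
        consensus_config=cfg,
        seeds={"rf_seed": rf_model.seed},
    )
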