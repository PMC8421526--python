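"""Two-round consensus pipeline, region calling, ranking, and reports."""

import json

import numpy as np
import pytest

from cppscreen import (
    ConsensusConfig,
    PeptideWindow,
    ProteinRecord,
    ScanConfig,
    ScoredWindow,
    ValidationError,
    call_regions,
    combined_score,
    rank_candidates,
    run_first_round,
    run_second_round,
    screen_protein,
)
from cppscreen.screen import REASON_TOO_SHORT


def _candidate(parent, start, end, z=3, dec=1.0, conf=0.9):
    seq = "K" * (end - start + 1)
    return ScoredWindow(
        window=PeptideWindow(parent, start, end, seq),
        zscale_score=z,
        passed_round1=True,
        svm_decision=dec,
        svm_label=1,
        rf_confidence=conf,
        passed_round2=True,
        round2_reason="pass",
    )


class TestFirstRound:
    def test_short_protein_empty(self, zscale_model):
        assert run_first_round(ProteinRecord("p", "ACD"), zscale_model) == []

    def test_zero_min_score_passes_everything(self, zscale_model, planted_seed1):
        cfg = ConsensusConfig(first_round_min_score=0)
        scored = run_first_round(planted_seed1.record, zscale_model, cfg=cfg)
        assert all(s.passed_round1 for s in scored)

    def test_planted_segment_windows_pass(self, zscale_model, planted_seed1):
        """>= 80% of windows fully inside each planted segment pass round 1."""
        scored = run_first_round(planted_seed1.record, zscale_model)
        for a, b in planted_seed1.truth:
            inside = [
                s.passed_round1
                for s in scored
                if s.window.start >= a and s.window.end <= b
            ]
            assert np.mean(inside) >= 0.8


class TestSecondRound:
    def test_only_round1_passers_evaluated(
        self, zscale_model, svm_model, rf_model, planted_seed1
    ):
        scored = run_first_round(planted_seed1.record, zscale_model)
        out = run_second_round(scored, svm_model, rf_model)
        for s in out:
            if not s.passed_round1:
                assert s.rf_confidence is None and s.svm_decision is None
                assert not s.passed_round2

    def test_short_windows_fail_with_reason(
        self, zscale_model, svm_model, rf_model, planted_seed1
    ):
        scored = run_first_round(planted_seed1.record, zscale_model)
        out = run_second_round(scored, svm_model, rf_model)
        short_passers = [
            s for s in out if s.passed_round1 and len(s.window) < 10
        ]
        assert short_passers, "expected some short round-1 passers"
        assert all(
            not s.passed_round2 and s.round2_reason == REASON_TOO_SHORT
            for s in short_passers
        )

    def test_round2_invariant(
        self, zscale_model, svm_model, rf_model, planted_seed1
    ):
        scored = run_first_round(planted_seed1.record, zscale_model)
        out = run_second_round(scored, svm_model, rf_model)
        for s in out:
            if s.passed_round2:
                assert s.passed_round1
                assert len(s.window) >= 10
                assert s.svm_label == 1 and s.svm_decision >= 0.0
                assert s.rf_confidence >= 0.7

    def test_unanimity_required_at_cutoff_one(
        self, zscale_model, svm_model, rf_model, planted_seed1
    ):
        scored = run_first_round(planted_seed1.record, zscale_model)
        out = run_second_round(
            scored, svm_model, rf_model, ConsensusConfig(rf_cutoff=1.0)
        )
        for s in out:
            if s.passed_round2:
                assert s.rf_confidence == 1.0

    def test_rf_cutoff_monotonicity(
        self, zscale_model, svm_model, rf_model, planted_seed1
    ):
        scored = run_first_round(planted_seed1.record, zscale_model)
        counts = []
        for cutoff in (0.0, 0.5, 0.7, 0.9):
            out = run_second_round(
                scored, svm_model, rf_model, ConsensusConfig(rf_cutoff=cutoff)
            )
            counts.append(sum(s.passed_round2 for s in out))
        assert counts == sorted(counts, reverse=True)

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            ConsensusConfig(rf_cutoff=1.5)
        with pytest.raises(ValidationError):
            ConsensusConfig(first_round_min_score=5)


class TestRegions:
    def test_no_candidates_empty(self):
        assert call_regions(ProteinRecord("p", "A" * 50), []) == []

    def test_single_candidate_exact_region(self):
        protein = ProteinRecord("p", "A" * 50)
        (region,) = call_regions(protein, [_candidate("p", 10, 20)])
        assert (region.start, region.end) == (10, 20)
        assert region.peak_coverage == 1

    def test_coverage_conservation(self):
        protein = ProteinRecord("p", "A" * 100)
        cands = [
            _candidate("p", 5, 20),
            _candidate("p", 10, 30),
            _candidate("p", 60, 75),
        ]
        cov = np.zeros(100)
        for c in cands:
            cov[c.window.start - 1 : c.window.end] += 1
        assert cov.sum() == sum(len(c.window) for c in cands)

    def test_regions_disjoint_ordered_in_bounds(self, planted_seed1, screen_report):
        rep = screen_report
        L = planted_seed1.record.length
        for r in rep.regions:
            assert 1 <= r.start <= r.end <= L
        for a, b in zip(rep.regions, rep.regions[1:]):
            assert a.end < b.start

    def test_wrong_parent_rejected(self):
        with pytest.raises(ValidationError):
            call_regions(ProteinRecord("p", "A" * 50), [_candidate("q", 1, 10)])


class TestRanking:
    def test_single_candidate(self):
        c = _candidate("p", 1, 10)
        assert rank_candidates([c]) == [c]

    def test_tie_broken_by_start(self):
        a = _candidate("p", 5, 14)
        b = _candidate("p", 1, 10)
        assert rank_candidates([a, b]) == [b, a]

    def test_monotone_in_rf_confidence(self):
        lo = _candidate("p", 1, 10, conf=0.7)
        hi = _candidate("p", 1, 10, conf=0.9)
        assert combined_score(hi) > combined_score(lo)
        assert rank_candidates([lo, hi])[0] is hi


@pytest.fixture(scope="module")
def screen_report(zscale_model, svm_model, rf_model, planted_seed1):
    return screen_protein(
        planted_seed1.record, zscale_model, svm_model, rf_model
    )


class TestScreenProtein:
    def test_deterministic_replay(
        self, zscale_model, svm_model, rf_model, planted_seed1, screen_report
    ):
        rep2 = screen_protein(
            planted_seed1.record, zscale_model, svm_model, rf_model
        )
        assert rep2.to_dict() == screen_report.to_dict()

    def test_candidates_satisfy_round2_invariant(self, screen_report):
        for s in screen_report.candidates:
            assert s.passed_round2 and s.passed_round1
            assert len(s.window) >= 10 and s.rf_confidence >= 0.7

    def test_candidates_are_ranked(self, screen_report):
        scores = [combined_score(s) for s in screen_report.candidates]
        assert scores == sorted(scores, reverse=True)

    def test_report_serializable_and_self_describing(self, screen_report, tmp_path):
        path = tmp_path / "report.json"
        screen_report.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["schema_version"] == 1
        assert payload["consensus_config"]["rf_cutoff"] == 0.7
        assert payload["scan_config"] == {"min_len": 5, "max_len": 30}
        assert payload["n_windows"] == 26 * 800 - 429
        assert "rf_seed" in payload["seeds"]

    def test_each_planted_segment_has_candidate(self, screen_report, planted_seed1):
        for a, b in planted_seed1.truth:
            assert any(
                c.window.start <= b and a <= c.window.end
                for c in screen_report.candidates
            )

    def test_frames_exportable(self, screen_report):
        cand = screen_report.candidates_frame()
        assert {"name", "combined_score", "rf_confidence"} <= set(cand.columns)
        regs = screen_report.regions_frame()
        assert len(regs) == len(screen_report.regions)
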