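"""Three trainable CPP predictor architectures and their scoring contracts.

The screening workflow combines three independent predictor families:

* :class:`ZScaleModel` — z-scale physicochemical encoding reduced by PCA
  and regressed with PLS; the continuous response is clipped to [0, 1] and
  discretized to a 0-3 score (2 and 3 mean "likely CPP"). Accepts peptides
  of any length, so it drives the whole-protein first round.
* :class:`CompositionSvmModel` — an RBF support-vector machine on 20-dim
  amino-acid composition; the signed decision value is thresholded at
  tau (default 0.0), optionally boosted by a fixed amount for peptides
  carrying an NLS-consensus or sled motif.
* :class:`SkipGramRfModel` — k-skip bigram features restricted to an
  mRMR-selected subset, classified by a seeded random forest; the reported
  confidence is the fraction of trees voting CPP, in [0, 1].

All three are deterministic functions of (training data, config, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .core import PeptideWindow, ValidationError
from .features import (
    SkipGramConfig,
    ZScaleConfig,
    aa_composition,
    encode_matrix,
    mrmr_rank,
    skip_gram_features,
    zscale_encode,
)
from .motifs import sequence_has_motif

__all__ = [
    "FitError",
    "NotFittedError",
    "LabeledPeptideSet",
    "ZScaleModel",
    "CompositionSvmModel",
    "SkipGramRfModel",
    "train_zscale",
    "score_zscale",
    "train_composition_svm",
    "train_skipgram_rf",
    "predict_confidence",
    "save_model",
    "load_model",
]

_SCORE_CUTS = (0.25, 0.5, 0.75)  # fixed cut points on the clipped response

MODEL_FORMAT_VERSION = 1


class FitError(RuntimeError):
    """Training failed on degenerate input."""


class NotFittedError(RuntimeError):
    """A prediction was requested from an unfitted model."""


@dataclass
class LabeledPeptideSet:
    """Parallel peptides and binary labels (CPP=1, non-CPP=0)."""

    peptides: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.peptides) != len(self.labels):
            raise ValidationError("peptides and labels differ in length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.peptides)

    def require_both_classes(self) -> None:
        if len(np.unique(self.labels)) < 2:
            raise ValidationError("training set must contain both classes")


def _require_fitted(model, flag: str = "_fitted") -> None:
    if not getattr(model, flag, False):
        raise NotFittedError(f"{type(model).__name__} is not fitted")


# ---------------------------------------------------------------------------
# First-round predictor: z-scales -> PCA -> PLS -> discrete 0-3 score


@dataclass
class ZScaleModel:
    cfg: ZScaleConfig = field(default_factory=ZScaleConfig)
    n_components: Optional[int] = None
    pca: Optional[PCA] = None
    pls: Optional[PLSRegression] = None
    calibrator: Optional[LogisticRegression] = None
    _fitted: bool = False

    def predict_continuous(self, peptides: Sequence[str]) -> np.ndarray:
        """[0, 1]-clipped CPP propensity, one value per peptide.

        The PLS latent response is read out as a class posterior through a
        logistic calibration fitted on the training set (PLS-DA style), so
        peptides well inside the CPP class map near 1 rather than to the
        shrunken raw regression value.
        """
        _require_fitted(self)
        if len(peptides) == 0:
            return np.zeros(0)
        X = encode_matrix(peptides, lambda p: zscale_encode(p, self.cfg))
        t = self.pls.predict(self.pca.transform(X)).reshape(-1, 1)
        resp = self.calibrator.predict_proba(t)[:, 1]
        return np.clip(resp, 0.0, 1.0)

    def predict_scores(self, peptides: Sequence[str]) -> np.ndarray:
        """Discrete 0-3 scores at the fixed 0.25/0.5/0.75 cut points."""
        cont = self.predict_continuous(peptides)
        return np.digitize(cont, _SCORE_CUTS).astype(int)


def train_zscale(
    train: LabeledPeptideSet,
    cfg: ZScaleConfig = ZScaleConfig(),
    n_components: Optional[int] = None,
) -> ZScaleModel:
    """Fit the z-scale/PCA/PLS predictor. Deterministic given its inputs."""
    train.require_both_classes()
    X = encode_matrix(train.peptides, lambda p: zscale_encode(p, cfg))
    if not np.any(X.std(axis=0) > 0):
        raise FitError(
            "all z-scale features are constant on this training set; "
            "PCA/PLS cannot be fitted"
        )
    n_feat = X.shape[1]
    if n_components is None:
        n_components = min(n_feat, 5)
    if not 1 <= n_components <= n_feat:
        raise ValidationError(f"n_components must be in [1, {n_feat}]")
    pca = PCA(n_components=n_components, svd_solver="full")
    Z = pca.fit_transform(X)
    pls = PLSRegression(n_components=min(2, n_components), scale=False)
    pls.fit(Z, train.labels.astype(float))
    t = pls.predict(Z).reshape(-1, 1)
    calibrator = LogisticRegression(C=10.0)
    calibrator.fit(t, train.labels)
    return ZScaleModel(
        cfg=cfg,
        n_components=n_components,
        pca=pca,
        pls=pls,
        calibrator=calibrator,
        _fitted=True,
    )


def score_zscale(
    model: ZScaleModel, windows: Sequence[PeptideWindow]
) -> list[tuple[PeptideWindow, int]]:
    """Score peptide windows 0-3, preserving input order."""
    _require_fitted(model)
    scores = model.predict_scores([w.sequence for w in windows])
    return list(zip(windows, (int(s) for s in scores)))


# ---------------------------------------------------------------------------
# Second-round predictor A: composition SVM with optional motif boost


@dataclass
class CompositionSvmModel:
    svm: Optional[SVC] = None
    tau: float = 0.0
    motif_boost: bool = False
    beta: float = 0.5
    _fitted: bool = False

    def decision_values(self, peptides: Sequence[str]) -> np.ndarray:
        """Signed margin per peptide; positive side is the CPP class.

        With ``motif_boost`` the margin is incremented by ``beta`` for any
        peptide containing an NLS-consensus or sled motif.
        """
        _require_fitted(self)
        if len(peptides) == 0:
            return np.zeros(0)
        X = encode_matrix(peptides, aa_composition)
        dec = self.svm.decision_function(X)
        if self.motif_boost:
            boost = np.array([sequence_has_motif(p) for p in peptides])
            dec = dec + self.beta * boost
        return dec

    def predict_labels(self, peptides: Sequence[str]) -> np.ndarray:
        """CPP (1) iff decision value >= tau."""
        return (self.decision_values(peptides) >= self.tau).astype(int)


def train_composition_svm(
    train: LabeledPeptideSet,
    motif_boost: bool = False,
    beta: float = 0.5,
    tau: float = 0.0,
    C: float = 1.0,
    gamma: str | float = "scale",
) -> CompositionSvmModel:
    """Fit the RBF-SVM on 20-dim amino-acid composition vectors."""
    train.require_both_classes()
    X = encode_matrix(train.peptides, aa_composition)
    svm = SVC(kernel="rbf", C=C, gamma=gamma)
    svm.fit(X, train.labels)
    return CompositionSvmModel(
        svm=svm, tau=tau, motif_boost=motif_boost, beta=beta, _fitted=True
    )


# ---------------------------------------------------------------------------
# Second-round predictor B: skip-gram features + mRMR subset + random forest


@dataclass
class SkipGramRfModel:
    sg_cfg: SkipGramConfig = field(default_factory=SkipGramConfig)
    selected: Optional[list[int]] = None
    forest: Optional[RandomForestClassifier] = None
    seed: int = 0
    _fitted: bool = False

    def _features(self, peptides: Sequence[str]) -> np.ndarray:
        for p in peptides:
            if len(p) < 2:
                raise ValidationError(
                    f"peptide {p!r} too short for skip-gram features"
                )
        X = encode_matrix(peptides, lambda p: skip_gram_features(p, self.sg_cfg))
        return X[:, self.selected]

    def predict_confidence(self, peptides: Sequence[str]) -> np.ndarray:
        """Fraction of trees voting CPP, in [0, 1], one value per peptide."""
        _require_fitted(self)
        if len(peptides) == 0:
            return np.zeros(0)
        X = self._features(peptides)
        votes = np.stack([tree.predict(X) for tree in self.forest.estimators_])
        return votes.mean(axis=0)

    def predict_labels(self, peptides: Sequence[str]) -> np.ndarray:
        return (self.predict_confidence(peptides) >= 0.5).astype(int)


def train_skipgram_rf(
    train: LabeledPeptideSet,
    sg_cfg: SkipGramConfig = SkipGramConfig(),
    n_select: int = 100,
    n_trees: int = 200,
    seed: int = 0,
) -> SkipGramRfModel:
    """Fit the skip-gram/mRMR/random-forest predictor with a fixed seed."""
    train.require_both_classes()
    X = encode_matrix(train.peptides, lambda p: skip_gram_features(p, sg_cfg))
    if not 1 <= n_select <= X.shape[1]:
        raise ValidationError(
            f"n_select must be in [1, {X.shape[1]}] (got {n_select})"
        )
    selected = mrmr_rank(X, train.labels, n_select=n_select)
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(X[:, selected], train.labels)
    return SkipGramRfModel(
        sg_cfg=sg_cfg, selected=selected, forest=forest, seed=seed, _fitted=True
    )


def predict_confidence(
    model: SkipGramRfModel, peptides: Sequence[str]
) -> list[float]:
    """Module-level convenience wrapper preserving input order."""
    return [float(c) for c in model.predict_confidence(peptides)]


# ---------------------------------------------------------------------------
# Persistence: one versioned archive per model


_MODEL_KINDS = {
    "zscale": ZScaleModel,
    "composition_svm": CompositionSvmModel,
    "skipgram_rf": SkipGramRfModel,
}


def save_model(model, path: str | os.PathLike) -> None:
    """Persist a fitted model as a single versioned joblib archive."""
    kind = next(
        (k for k, cls in _MODEL_KINDS.items() if isinstance(model, cls)), None
    )
    if kind is None:
        raise ValidationError(f"unknown model type {type(model).__name__}")
    joblib.dump(
        {"format_version": MODEL_FORMAT_VERSION, "kind": kind, "model": model}, path
    )


def load_model(path: str | os.PathLike):
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"unsupported model archive version {payload.get('format_version')!r}"
        )
    return payload["model"]
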