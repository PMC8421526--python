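"""Peptide-to-vector encoders and mRMR feature ranking.

All encoders use a fixed alphabetical feature-name order, so two calls on
the same input are bit-identical. Composition-style vectors are normalized
to sum to 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from ._tables import AMINO_ACIDS, ZSCALES_5
from .core import ValidationError, _check_sequence

__all__ = [
    "FeatureVector",
    "SkipGramConfig",
    "ZScaleConfig",
    "aa_composition",
    "dipeptide_composition",
    "skip_gram_features",
    "zscale_encode",
    "encode_matrix",
    "mrmr_rank",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_PAIR_NAMES = tuple(a + b for a, b in itertools.product(AMINO_ACIDS, repeat=2))
_ZMATRIX = np.array([ZSCALES_5[aa] for aa in AMINO_ACIDS])  # 20 x 5


@dataclass(frozen=True)
class FeatureVector:
    """Named numeric encoding of one peptide."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(self.names) != len(set(self.names)):
            raise ValidationError("feature names are not unique")
        if values.shape != (len(self.names),):
            raise ValidationError("feature values do not match names")
        if not np.all(np.isfinite(values)):
            raise ValidationError("non-finite feature value")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


@dataclass(frozen=True)
class SkipGramConfig:
    """k-skip bigram settings: pairs separated by 0..max_skip positions."""

    max_skip: int = 3
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.max_skip < 0:
            raise ValidationError("max_skip must be >= 0")


@dataclass(frozen=True)
class ZScaleConfig:
    """Z-scale encoding settings: 3 or 5 scales, mean or mean-and-sd pooling."""

    n_scales: int = 5
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        if self.n_scales not in (3, 5):
            raise ValidationError("n_scales must be 3 or 5")
        if self.aggregation not in ("mean", "mean-and-sd"):
            raise ValidationError("aggregation must be 'mean' or 'mean-and-sd'")


def aa_composition(sequence: str) -> FeatureVector:
    """Fraction of each of the 20 amino acids; entries sum to 1."""
    seq = _check_sequence(sequence)
    counts = np.zeros(20)
    for ch in seq:
        counts[_AA_INDEX[ch]] += 1
    return FeatureVector(tuple(AMINO_ACIDS), counts / len(seq))


def _pair_counts(seq: str, skips: range) -> np.ndarray:
    counts = np.zeros(400)
    for s in skips:
        step = s + 1
        for i in range(len(seq) - step):
            counts[_AA_INDEX[seq[i]] * 20 + _AA_INDEX[seq[i + step]]] += 1
    return counts


def dipeptide_composition(sequence: str) -> FeatureVector:
    """Fraction of each ordered residue pair among the L-1 adjacent pairs."""
    seq = _check_sequence(sequence)
    if len(seq) < 2:
        raise ValidationError("dipeptide composition requires length >= 2")
    counts = _pair_counts(seq, range(1))
    return FeatureVector(_PAIR_NAMES, counts / counts.sum())


def skip_gram_features(
    sequence: str, cfg: SkipGramConfig = SkipGramConfig()
) -> FeatureVector:
    """k-skip bigram composition over the 400 ordered residue pairs.

    Pairs (i, i+s+1) are counted for every skip s in 0..max_skip and pooled
    into a single 400-entry vector; with ``normalize`` the pooled counts are
    divided by their total, so the entries sum to 1. ``max_skip=0``
    reproduces :func:`dipeptide_composition` exactly.
    """
    seq = _check_sequence(sequence)
    if len(seq) < 2:
        raise ValidationError("skip-gram features require length >= 2")
    counts = _pair_counts(seq, range(cfg.max_skip + 1))
    if cfg.normalize:
        total = counts.sum()
        if total > 0:
            counts = counts / total
    return FeatureVector(_PAIR_NAMES, counts)


def zscale_encode(sequence: str, cfg: ZScaleConfig = ZScaleConfig()) -> FeatureVector:
    """Aggregate per-residue z-scale descriptor rows over the peptide.

    ``mean`` pooling yields n_scales entries; ``mean-and-sd`` appends the
    per-scale population standard deviation (2 * n_scales entries).
    """
    seq = _check_sequence(sequence)
    rows = _ZMATRIX[[_AA_INDEX[ch] for ch in seq], : cfg.n_scales]
    mean = rows.mean(axis=0)
    names = tuple(f"z{i + 1}" for i in range(cfg.n_scales))
    if cfg.aggregation == "mean-and-sd":
        sd = rows.std(axis=0)
        names = names + tuple(f"z{i + 1}_sd" for i in range(cfg.n_scales))
        return FeatureVector(names, np.concatenate([mean, sd]))
    return FeatureVector(names, mean)


def encode_matrix(
    peptides: Sequence[str], encoder: Callable[[str], FeatureVector]
) -> np.ndarray:
    """Stack encoder outputs into an (n_peptides, n_features) matrix."""
    if not peptides:
        raise ValidationError("no peptides to encode")
    return np.vstack([encoder(p).values for p in peptides])


# ---------------------------------------------------------------------------
# mRMR feature ranking


def _discretize(X: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Equal-width binning per column; constant columns collapse to bin 0."""
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    out = np.zeros(X.shape, dtype=np.int64)
    nonconst = span > 0
    scaled = (X[:, nonconst] - lo[nonconst]) / span[nonconst]
    out[:, nonconst] = np.minimum((scaled * n_bins).astype(np.int64), n_bins - 1)
    return out


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI in nats from the joint contingency table of two discrete arrays."""
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb)
    joint = joint / joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log(joint[mask] / (pa @ pb)[mask])))


def mrmr_rank(
    X: np.ndarray,
    y: Sequence[int],
    n_select: int,
    n_bins: int = 5,
) -> list[int]:
    """Greedy minimum-redundancy maximum-relevance feature ranking.

    The first feature maximizes MI with the labels; each subsequent pick
    maximizes ``MI(f; y) - mean MI(f; already selected)`` (the difference
    form). Continuous features are discretized into ``n_bins`` equal-width
    bins. Deterministic; ties broken by lowest feature index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X and y shapes do not match")
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 samples")
    if len(np.unique(y)) < 2:
        raise ValidationError("labels contain a single class")
    n_features = X.shape[1]
    if not 1 <= n_select <= n_features:
        raise ValidationError(f"n_select must be in [1, {n_features}]")

    Xd = _discretize(X, n_bins=n_bins)
    relevance = np.array(
        [_mutual_information(Xd[:, j], y) for j in range(n_features)]
    )

    selected: list[int] = [int(np.argmax(relevance))]
    remaining = [j for j in range(n_features) if j != selected[0]]
    red_sum = np.zeros(n_features)
    while len(selected) < n_select:
        last = selected[-1]
        for j in remaining:
            red_sum[j] += _mutual_information(Xd[:, j], Xd[:, last])
        scores = relevance[remaining] - red_sum[remaining] / len(selected)
        best = remaining[int(np.argmax(scores))]
        selected.append(best)
        remaining.remove(best)
    return selected
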