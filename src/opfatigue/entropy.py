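"""Entropy-weight method and the composite fatigue index F.

The entropy weight method assigns each feature an objective weight from
the dispersion of its normalized values: per feature j, with n samples,

    x'_ij = (x_ij - min_j) / (max_j - min_j)        (min-max normalize)
    x''_ij = x'_ij + 0.001                          (shift off zero)
    p_ij = x''_ij / sum_i x''_ij                    (proportions)
    e_j  = -(1/ln n) * sum_i p_ij ln p_ij           (entropy, in [0, 1])
    g_j  = 1 - e_j                                  (difference coeff.)
    w_j  = g_j / sum_j g_j                          (weights, sum to 1)

A near-uniform feature has entropy near 1 and hence weight near 0; the
more dispersed a feature, the more weight it receives.

The composite fatigue index combines the normalized reaction time R and
normalized Borg rating B as ``F = w_R R + w_B B`` and is banded into
three levels: mild [0, 0.27), moderate [0.27, 0.66), severe [0.66, 1].
The band edges and the reference weights (0.39, 0.61) recorded from the
original treadmill study live in :mod:`opfatigue.reference`; weights are
always keyed by feature name, never by column position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "EntropyWeights",
    "FatigueIndex",
    "minmax_normalize",
    "shift",
    "entropy_weights",
    "composite_index",
    "classify_level",
    "LEVEL_NAMES",
]

SHIFT = 0.001

Stage = Literal["raw", "normalized", "shifted"]

LEVEL_NAMES = {1: "mild", 2: "moderate", 3: "severe"}


@dataclass(frozen=True)
class FeatureMatrix:
    """An n x m feature table tagged with its processing stage."""

    values: pd.DataFrame
    stage: Stage = "raw"

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValueError("feature matrix must be non-empty")
        if self.stage == "normalized":
            v = self.values.to_numpy()
            if v.min() < -1e-12 or v.max() > 1 + 1e-12:
                raise ValueError("normalized values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return int(self.values.shape[0])

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


def minmax_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Per-feature min-max normalization onto [0, 1].

    A constant feature (max == min) maps to all zeros; after the shift
    and proportion steps it then receives entropy 1 and weight 0, the
    only internally consistent treatment of a feature carrying no
    information.
    """
    if matrix.n < 2:
        raise ValueError("normalization requires at least 2 samples")
    v = matrix.values
    lo, hi = v.min(axis=0), v.max(axis=0)
    span = hi - lo
    out = pd.DataFrame(0.0, index=v.index, columns=v.columns)
    varying = span > 0
    out.loc[:, varying] = (v.loc[:, varying] - lo[varying]) / span[varying]
    return FeatureMatrix(out, stage="normalized")


def shift(matrix: FeatureMatrix) -> FeatureMatrix:
    """Add 0.001 to every normalized entry so all proportions are positive."""
    if matrix.stage != "normalized":
        raise ValueError(
            f"shift expects a normalized matrix, got stage={matrix.stage!r}"
        )
    return FeatureMatrix(matrix.values + SHIFT, stage="shifted")


@dataclass(frozen=True)
class EntropyWeights:
    """Per-feature proportions, entropies, difference coefficients, weights."""

    p: pd.DataFrame  # n x m proportions, columns sum to 1
    e: pd.Series  # entropy per feature, in [0, 1]
    g: pd.Series  # difference coefficient 1 - e
    w: pd.Series  # weights, >= 0, sum to 1

    def weight(self, name: str) -> float:
        return float(self.w[name])

    @staticmethod
    def from_mapping(weights: Mapping[str, float]) -> "EntropyWeights":
        """Wrap externally recorded weights (e.g. published constants)."""
        w = pd.Series(weights, dtype=float)
        if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")
        nan = pd.Series(math.nan, index=w.index)
        return EntropyWeights(p=pd.DataFrame(columns=w.index), e=nan, g=nan, w=w)


def entropy_weights(matrix: FeatureMatrix) -> EntropyWeights:
    """Entropy-method feature weights from a shifted feature matrix."""
    if matrix.stage != "shifted":
        raise ValueError(
            f"entropy_weights expects a shifted matrix, got stage={matrix.stage!r}"
        )
    v = matrix.values
    n = matrix.n
    if n < 2:
        raise ValueError("entropy weighting requires at least 2 samples")
    if (v.to_numpy() <= 0).any():
        raise ValueError("shifted matrix must be strictly positive")

    p = v / v.sum(axis=0)
    e = -(p * np.log(p)).sum(axis=0) / np.log(n)
    g = 1.0 - e
    # entropy can exceed 1 by floating error only; clamp tiny negatives of g
    g = g.clip(lower=0.0)
    total = g.sum()
    if total <= 1e-12:
        raise ValueError("no discriminating feature: every feature is constant")
    w = g / total
    return EntropyWeights(p=p, e=e, g=g, w=w)


@dataclass(frozen=True)
class FatigueIndex:
    """Composite fatigue index F with its components and weights."""

    F: float
    R: float  # normalized reaction time
    B: float  # normalized Borg rating
    w_R: float
    w_B: float


def composite_index(
    R: float, B: float, weights: EntropyWeights | Mapping[str, float]
) -> FatigueIndex:
    """F = w_R * R + w_B * B from normalized components in [0, 1].

    *weights* must carry entries named ``"rt"`` and ``"borg"`` summing
    to 1 (matching by name guards against transposed columns).
    """
    w = weights.w if isinstance(weights, EntropyWeights) else pd.Series(weights)
    try:
        w_R, w_B = float(w["rt"]), float(w["borg"])
    except KeyError as err:
        raise ValueError(f"weights must be keyed 'rt' and 'borg'; missing {err}")
    if abs(w_R + w_B - 1.0) > 1e-9:
        raise ValueError("the two weights must sum to 1")
    for name, val in (("R", R), ("B", B)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"component {name}={val} lies outside [0, 1]")
    F = w_R * R + w_B * B
    if F < 0.0 or F > 1.0:
        if F < -1e-9 or F > 1.0 + 1e-9:
            raise ValueError(f"composite index {F} outside [0, 1]")
        F = float(np.clip(F, 0.0, 1.0))
    return FatigueIndex(F=F, R=R, B=B, w_R=w_R, w_B=w_B)


def classify_level(
    F: float | FatigueIndex, bands: Sequence[float] = (0.0, 0.27, 0.66, 1.0)
) -> int:
    """Three-level fatigue grade of F: 1 mild, 2 moderate, 3 severe.

    Bands are half-open (a boundary belongs to the upper level) except
    that F = 1 is level 3.
    """
    f = F.F if isinstance(F, FatigueIndex) else float(F)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"F={f} lies outside [0, 1]")
    if f >= bands[2]:
        return 3
    if f >= bands[1]:
        return 2
    return 1
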