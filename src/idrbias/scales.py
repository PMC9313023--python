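"""Rank-correlation comparison of propensity scales.

Scales computed for different disorder collections (and published propensity
scales) span different value ranges, so they are compared by how they *rank*
the 20 amino acids: Kendall's tau (tie-corrected tau-b by default, since
computed enrichments can tie).  A separate helper correlates predictor
accuracy with scale agreement (Pearson).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._aa import AA_ORDER
from .io import PropensityScale

__all__ = ["ScaleMatrix", "kendall_tau", "scale_matrix", "bias_performance_correlation"]


def kendall_tau(x: Sequence[float], y: Sequence[float], *, variant: str = "b") -> float:
    """Kendall rank correlation of two aligned vectors.

    ``variant="b"`` applies the tie correction; ``"a"`` is the raw
    (concordant - discordant) / n(n-1)/2 count (untied data makes both equal).
    Raises on length mismatch or an all-constant vector (undefined ranking).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("kendall_tau needs two equal-length 1-d vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("kendall_tau undefined for an all-constant vector")
    if variant == "b":
        return float(stats.kendalltau(x, y, variant="b").statistic)
    if variant == "a":
        n = len(x)
        dx = np.sign(x[:, None] - x[None, :])
        dy = np.sign(y[:, None] - y[None, :])
        s = np.sum(np.triu(dx * dy, k=1))
        return float(2.0 * s / (n * (n - 1)))
    raise ValueError(f"unknown kendall_tau variant {variant!r}")


@dataclass
class ScaleMatrix:
    """Symmetric Kendall correlation matrix over a list of named scales."""

    names: list[str]
    kcc: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.kcc, dtype=float)
        if k.shape != (len(self.names), len(self.names)):
            raise ValueError("matrix shape does not match the name list")
        self.kcc = k

    def value(self, a: str, b: str) -> float:
        return float(self.kcc[self.names.index(a), self.names.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.kcc, index=self.names, columns=self.names)

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"name_a": a, "name_b": b, "kcc": float(self.kcc[i, j])}
            for i, a in enumerate(self.names)
            for j, b in enumerate(self.names)
            if i < j
        ]
        return pd.DataFrame(rows, columns=["name_a", "name_b", "kcc"])


def scale_matrix(
    scales: Sequence[PropensityScale], *, variant: str = "b"
) -> ScaleMatrix:
    """Pairwise Kendall correlation of scales, aligned by amino acid.

    The diagonal is exactly 1 and each off-diagonal pair is computed once and
    mirrored, so the matrix is exactly symmetric.  Ordering follows the input.
    """
    if len(scales) < 2:
        raise ValueError("need at least two scales")
    names = [s.name for s in scales]
    if len(set(names)) != len(names):
        raise ValueError("scale names must be unique")
    vecs = [s.vector(AA_ORDER) for s in scales]
    n = len(scales)
    kcc = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            kcc[i, j] = kcc[j, i] = kendall_tau(vecs[i], vecs[j], variant=variant)
    return ScaleMatrix(names, kcc)


def bias_performance_correlation(
    predictor_aucs: Mapping[str, float],
    predictor_kccs: Mapping[str, float],
) -> float:
    """Pearson correlation between predictor accuracy and scale agreement.

    ``predictor_aucs`` maps predictor name to its AUC; ``predictor_kccs`` maps
    the same names to the Kendall correlation of the predictor's putative
    disorder scale with the native disorder scale.
    """
    if set(predictor_aucs) != set(predictor_kccs):
        raise ValueError("the two maps must cover the same predictors")
    if len(predictor_aucs) < 3:
        raise ValueError("need at least three predictors")
    names = sorted(predictor_aucs)
    a = np.array([predictor_aucs[n] for n in names], dtype=float)
    k = np.array([predictor_kccs[n] for n in names], dtype=float)
    if np.ptp(a) == 0 or np.ptp(k) == 0:
        raise ValueError("Pearson correlation undefined for a zero-variance vector")
    return float(stats.pearsonr(a, k).statistic)
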