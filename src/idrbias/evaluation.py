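"""Predictor evaluation, bootstrap significance and the class-routed meta-predictor.

Metrics are computed on residues pooled across the proteins of a subset
(not averaged per protein): disordered residues are the positive class,
unannotated residues are excluded.  AUC is the Mann-Whitney rank statistic
with ties averaged; AUPR is the step integration of the precision-recall
curve; MCC and F1 come from binary calls (the predictor's native calls when
present, else scores thresholded at 0.5).

The significance protocol repeatedly draws half of the proteins (without
replacement by default), re-assesses both predictors on each draw, and tests
the paired per-draw metric values: a paired Student t-test when the
Anderson-Darling test does not reject normality of the differences at 0.05,
otherwise a Wilcoxon signed-rank test.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score

from .io import AnnotatedProtein, PredictionTrack, UNANNOTATED
from .regions import IDPClass

__all__ = [
    "EvalResult",
    "BootstrapComparison",
    "MetaRouting",
    "auc_score",
    "evaluate",
    "evaluate_by_class",
    "bootstrap_compare",
    "assemble_meta",
    "normalize_min_max",
]

METRICS = ("auc", "aupr", "mcc", "f1")


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the rank (Mann-Whitney) statistic, ties averaged."""
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need both positive and negative residues")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _binary_metrics(calls: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(MCC, F1) from binary calls; degenerate denominators give 0.0."""
    calls = np.asarray(calls).astype(bool)
    labels = np.asarray(labels).astype(bool)
    tp = int(np.count_nonzero(calls & labels))
    fp = int(np.count_nonzero(calls & ~labels))
    fn = int(np.count_nonzero(~calls & labels))
    tn = int(np.count_nonzero(~calls & ~labels))
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return float(mcc), float(f1)


@dataclass
class EvalResult:
    """AUC/AUPR/MCC/F1 of one predictor on one protein subset."""

    predictor: str
    subset: str
    auc: float
    aupr: float
    mcc: float
    f1: float
    n_residues: int
    n_positive: int


def _pool(
    track: PredictionTrack,
    proteins: Sequence[AnnotatedProtein],
    subset: set[str] | None,
    threshold: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled (scores, labels, calls) over annotated residues of the subset."""
    scores_parts, labels_parts, calls_parts = [], [], []
    for p in proteins:
        if subset is not None and p.id not in subset:
            continue
        if p.id not in track:
            raise ValueError(f"predictor {track.name!r} has no scores for {p.id!r}")
        s = track.scores[p.id]
        if len(s) != len(p):
            raise ValueError(f"predictor {track.name!r}: score length mismatch for {p.id!r}")
        annotated = p.disorder_track != UNANNOTATED
        scores_parts.append(s[annotated])
        labels_parts.append(p.disorder_track[annotated] == 1)
        c = track.calls.get(p.id)
        calls_parts.append(
            (c[annotated] == 1) if c is not None else (s[annotated] >= threshold)
        )
    if not scores_parts:
        raise ValueError("empty protein subset")
    return (
        np.concatenate(scores_parts),
        np.concatenate(labels_parts),
        np.concatenate(calls_parts),
    )


def evaluate(
    track: PredictionTrack,
    proteins: Sequence[AnnotatedProtein],
    subset: set[str] | None = None,
    *,
    subset_name: str = "all",
    threshold: float = 0.5,
) -> EvalResult:
    """Score one predictor on the pooled residues of a protein subset."""
    scores, labels, calls = _pool(track, proteins, subset, threshold)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError(
            f"subset {subset_name!r} has a single class "
            f"({n_pos} of {len(labels)} residues positive)"
        )
    mcc, f1 = _binary_metrics(calls, labels)
    return EvalResult(
        predictor=track.name,
        subset=subset_name,
        auc=auc_score(scores, labels),
        aupr=float(average_precision_score(labels, scores)),
        mcc=mcc,
        f1=f1,
        n_residues=len(labels),
        n_positive=n_pos,
    )


def evaluate_by_class(
    tracks: Sequence[PredictionTrack],
    proteins: Sequence[AnnotatedProtein],
    classes: Mapping[str, IDPClass],
    *,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """One row per (predictor, class) plus per (predictor, complete dataset).

    Classes with no evaluable residues (absent, or single-class) are reported
    with NaN metrics rather than zeros.
    """
    rows = []
    subsets: list[tuple[str, set[str] | None]] = [("all", None)]
    for cls in IDPClass:
        ids = {pid for pid, c in classes.items() if c is cls}
        if ids:
            subsets.append((cls.value, ids))
    for track in tracks:
        for label, ids in subsets:
            try:
                r = evaluate(track, proteins, ids, subset_name=label, threshold=threshold)
                rows.append(vars(r))
            except ValueError:
                rows.append(
                    {
                        "predictor": track.name, "subset": label,
                        "auc": np.nan, "aupr": np.nan, "mcc": np.nan, "f1": np.nan,
                        "n_residues": 0, "n_positive": 0,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bootstrap significance protocol


def anderson_darling_pvalue(x: np.ndarray) -> float:
    """Approximate p-value of the Anderson-Darling normality test.

    Uses the D'Agostino-Stephens approximation on the statistic corrected for
    estimated mean and variance.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    w = (x - x.mean()) / x.std(ddof=1)
    logcdf = stats.norm.logcdf(w)
    logsf = stats.norm.logsf(w)
    i = np.arange(1, n + 1)
    a2 = -n - np.sum((2 * i - 1) * (logcdf + logsf[::-1])) / n
    a2 *= 1 + 0.75 / n + 2.25 / n**2
    if a2 >= 0.6:
        return float(math.exp(1.2937 - 5.709 * a2 + 0.0186 * a2**2))
    if a2 > 0.34:
        return float(math.exp(0.9177 - 4.279 * a2 - 1.38 * a2**2))
    if a2 > 0.2:
        return float(1 - math.exp(-8.318 + 42.796 * a2 - 59.938 * a2**2))
    return float(1 - math.exp(-13.436 + 101.14 * a2 - 223.73 * a2**2))


class SignificanceTest(enum.Enum):
    T_TEST = "t_test"
    WILCOXON = "wilcoxon"


@dataclass
class BootstrapComparison:
    """Outcome of the repeated half-sample significance protocol."""

    metric: str
    method_a: str
    method_b: str
    n_iter: int
    sample_fraction: float
    values_a: np.ndarray
    values_b: np.ndarray
    normality_p: float
    test_used: SignificanceTest
    p_value: float
    seed: int | None

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def _metric_fn(metric: str):
    if metric == "auc":
        return lambda s, l, c: auc_score(s, l)
    if metric == "aupr":
        return lambda s, l, c: float(average_precision_score(l, s))
    if metric == "mcc":
        return lambda s, l, c: _binary_metrics(c, l)[0]
    if metric == "f1":
        return lambda s, l, c: _binary_metrics(c, l)[1]
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def bootstrap_compare(
    track_a: PredictionTrack,
    track_b: PredictionTrack,
    proteins: Sequence[AnnotatedProtein],
    *,
    metric: str = "auc",
    n_iter: int = 100,
    fraction: float = 0.5,
    seed: int | np.random.Generator | None = None,
    replace: bool = False,
    threshold: float = 0.5,
    max_redraws: int = 1000,
) -> BootstrapComparison:
    """Repeatedly assess both predictors on random half-samples and test.

    Each iteration draws ``floor(fraction * N)`` proteins (without replacement
    by default; ``replace=True`` for a classical bootstrap), evaluates the
    metric for both predictors on the identical draw, and the paired per-draw
    values are tested (t-test or Wilcoxon, chosen by Anderson-Darling
    normality of the differences at 0.05).  Draws on which the metric is
    undefined (single-class sample) are redrawn, up to ``max_redraws``.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fn = _metric_fn(metric)

    # Pre-pool per protein once; iterations concatenate views.
    per_protein = []
    for p in proteins:
        s, l, c = _pool_single(track_a, track_b, p, threshold)
        per_protein.append((s, l, c))
    n = len(per_protein)
    k = max(1, int(math.floor(fraction * n)))

    vals_a, vals_b = [], []
    redraws = 0
    while len(vals_a) < n_iter:
        idx = rng.choice(n, size=k, replace=replace)
        labels = np.concatenate([per_protein[i][1] for i in idx])
        if labels.all() or not labels.any():
            redraws += 1
            if redraws > max_redraws:
                raise ValueError(
                    "too many single-class half-samples; the dataset is too imbalanced"
                )
            continue
        sa = np.concatenate([per_protein[i][0][0] for i in idx])
        sb = np.concatenate([per_protein[i][0][1] for i in idx])
        ca = np.concatenate([per_protein[i][2][0] for i in idx])
        cb = np.concatenate([per_protein[i][2][1] for i in idx])
        vals_a.append(fn(sa, labels, ca))
        vals_b.append(fn(sb, labels, cb))

    a = np.asarray(vals_a)
    b = np.asarray(vals_b)
    d = a - b
    if np.ptp(d) == 0:
        # all differences identical: no variability to test against
        normality_p = 1.0
        test_used = SignificanceTest.T_TEST
        p_value = 1.0 if d[0] == 0 else 0.0
    else:
        normality_p = anderson_darling_pvalue(d)
        if normality_p >= 0.05:
            test_used = SignificanceTest.T_TEST
            p_value = float(stats.ttest_rel(a, b).pvalue)
        else:
            test_used = SignificanceTest.WILCOXON
            p_value = float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
    return BootstrapComparison(
        metric=metric,
        method_a=track_a.name,
        method_b=track_b.name,
        n_iter=n_iter,
        sample_fraction=fraction,
        values_a=a,
        values_b=b,
        normality_p=normality_p,
        test_used=test_used,
        p_value=p_value,
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )


def _pool_single(
    track_a: PredictionTrack,
    track_b: PredictionTrack,
    p: AnnotatedProtein,
    threshold: float,
):
    for t in (track_a, track_b):
        if p.id not in t:
            raise ValueError(f"predictor {t.name!r} has no scores for {p.id!r}")
    annotated = p.disorder_track != UNANNOTATED
    labels = p.disorder_track[annotated] == 1
    scores = tuple(t.scores[p.id][annotated] for t in (track_a, track_b))
    calls = tuple(
        (t.calls.get(p.id)[annotated] == 1)
        if t.calls.get(p.id) is not None
        else (t.scores[p.id][annotated] >= threshold)
        for t in (track_a, track_b)
    )
    return scores, labels, calls


# ---------------------------------------------------------------------------
# Class-routed meta-predictor


@dataclass
class MetaRouting:
    """Which predictor serves each protein class, plus a default."""

    mapping: dict[IDPClass, str]
    default: str

    def predictor_for(self, cls: IDPClass) -> str:
        return self.mapping.get(cls, self.default)

    def validate(self, available: set[str]) -> None:
        needed = set(self.mapping.values()) | {self.default}
        missing = needed - available
        if missing:
            raise ValueError(f"routing names unknown predictors: {sorted(missing)}")
        routable = set(self.mapping) | {IDPClass.UNASSIGNED}
        unmapped = {c for c in IDPClass if c not in routable and c is not IDPClass.UNASSIGNED}
        if unmapped:
            raise ValueError(f"routing leaves classes unmapped: {sorted(c.value for c in unmapped)}")


def normalize_min_max(track: PredictionTrack, proteins: Sequence[AnnotatedProtein]) -> PredictionTrack:
    """Min-max normalize a predictor's scores over all residues of the dataset.

    The map (s - min) / (max - min) is monotone, so rank metrics (AUC, AUPR)
    are unchanged; it only puts predictors on a common [0, 1] range so their
    scores can be stitched together.
    """
    pooled = np.concatenate([track.scores[p.id] for p in proteins])
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi == lo:
        raise ValueError(f"predictor {track.name!r} has constant scores; cannot normalize")
    out = PredictionTrack(track.name)
    for p in proteins:
        out.add(p.id, (track.scores[p.id] - lo) / (hi - lo), track.calls.get(p.id))
    return out


def assemble_meta(
    tracks: Sequence[PredictionTrack],
    routing: MetaRouting,
    classes: Mapping[str, IDPClass],
    proteins: Sequence[AnnotatedProtein],
    *,
    name: str = "meta",
) -> PredictionTrack:
    """Stitch a class-routed meta-predictor from individual prediction tracks.

    Every predictor's scores are min-max normalized over the whole dataset;
    each protein then takes the normalized scores (and native binary calls)
    of the predictor routed for its class.
    """
    by_name = {t.name: t for t in tracks}
    routing.validate(set(by_name))
    normalized = {n: normalize_min_max(t, proteins) for n, t in by_name.items()}
    meta = PredictionTrack(name)
    for p in proteins:
        if p.id not in classes:
            raise ValueError(f"protein {p.id!r} has no class assignment")
        src = normalized[routing.predictor_for(classes[p.id])]
        meta.add(p.id, src.scores[p.id], src.calls.get(p.id))
    return meta
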