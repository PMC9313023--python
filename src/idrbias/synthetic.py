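"""CAID-like synthetic datasets with controllable composition and difficulty.

The generator emulates the structure of a per-residue disorder benchmark:
proteins built from ordered / disordered / binding segments whose architecture
provably satisfies a requested protein class, residues drawn i.i.d. from
per-state composition vectors (with optional injected enrichments), and
predictor score tracks whose per-class discrimination follows the binormal
model:

    negatives ~ N(0, 1),  positives ~ N(delta, 1),
    delta = sqrt(2) * Phi^-1(AUC_target),

so a target AUC maps to a score-shift in closed form (AUC = Phi(delta/sqrt(2))).
Scores are squashed to [0, 1] by a logistic; binary calls threshold the raw
score at the class midpoint delta/2.

Everything is deterministic given the seed.  Ground truth (intended class,
content, segment layout) is returned beside the proteins and is re-derived
from the annotation tracks as a self-check before returning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._aa import AA_ORDER, DISORDER_COMPOSITION, ORDER_COMPOSITION, validate_composition
from .io import AnnotatedProtein, PredictionTrack
from .regions import ClassThresholds, IDPClass, classify_idps, disorder_content

__all__ = [
    "PredictorProfile",
    "SyntheticConfig",
    "GroundTruth",
    "generate_reference",
    "generate_predictions",
    "preset",
    "PRESETS",
]

_DELTA_CAP = 40.0  # AUC target 1.0 handled as the separation limit


@dataclass(frozen=True)
class PredictorProfile:
    """Name and per-class target AUC of one synthetic predictor."""

    name: str
    auc_by_class: Mapping[IDPClass, float] = field(default_factory=dict)
    default_auc: float = 0.7

    def validate(self) -> None:
        for cls, auc in self.auc_by_class.items():
            if not isinstance(cls, IDPClass):
                raise ValueError(f"profile {self.name!r}: unknown class {cls!r}")
            if not (0.5 <= auc <= 1.0):
                raise ValueError(f"profile {self.name!r}: target AUC {auc} outside [0.5, 1]")
        if not (0.5 <= self.default_auc <= 1.0):
            raise ValueError(f"profile {self.name!r}: default AUC outside [0.5, 1]")

    def target(self, cls: IDPClass) -> float:
        return float(self.auc_by_class.get(cls, self.default_auc))


@dataclass
class SyntheticConfig:
    """Study conditions of a synthetic dataset.

    ``class_disorder_enrichment`` maps a class to per-amino-acid
    multiplicative factors applied to the disorder composition of that
    class's proteins (renormalized); ``disorder_enrichment`` applies to all
    classes.
    """

    n_per_class: dict[IDPClass, int]
    length_range: tuple[int, int] = (120, 400)
    order_composition: dict[str, float] = field(default_factory=lambda: dict(ORDER_COMPOSITION))
    disorder_composition: dict[str, float] = field(default_factory=lambda: dict(DISORDER_COMPOSITION))
    disorder_enrichment: dict[str, float] = field(default_factory=dict)
    class_disorder_enrichment: dict[IDPClass, dict[str, float]] = field(default_factory=dict)
    binding_length_range: tuple[int, int] = (8, 40)
    predictor_profiles: list[PredictorProfile] = field(default_factory=list)
    seed: int | None = None

    def validate(self) -> None:
        validate_composition(self.order_composition, "order_composition")
        validate_composition(self.disorder_composition, "disorder_composition")
        if not self.n_per_class:
            raise ValueError("n_per_class is empty")
        for cls, n in self.n_per_class.items():
            if not isinstance(cls, IDPClass) or cls is IDPClass.UNASSIGNED:
                raise ValueError(f"cannot request proteins of class {cls!r}")
            if n < 0:
                raise ValueError("negative protein count")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad length range {self.length_range}")
        low_content_classes = {
            IDPClass.C2_LOW_SHORT,
            IDPClass.C3_LOW_BINDING_LONG,
            IDPClass.C4_LOW_NONBINDING_LONG,
        }
        if any(self.n_per_class.get(c, 0) for c in low_content_classes) and lo < 56:
            raise ValueError(
                "length_range minimum must be >= 56 to fit a long IDR (>= 16 residues) "
                "under the low-content ceiling of 0.3"
            )
        if self.n_per_class.get(IDPClass.C1_FULLY_DISORDERED, 0) and lo < 13:
            raise ValueError("proteins too short for a fully disordered architecture")
        high_content_classes = (IDPClass.C5_HIGH_BINDING, IDPClass.C6_HIGH_NONBINDING)
        if any(self.n_per_class.get(c, 0) for c in high_content_classes) and lo < 24:
            raise ValueError(
                "length_range minimum must be >= 24 for high-content architectures "
                "(a 16-residue IDR must stay under the content ceiling of 0.8)"
            )
        blo, bhi = self.binding_length_range
        if not (1 <= blo <= bhi):
            raise ValueError(f"bad binding length range {self.binding_length_range}")
        for prof in self.predictor_profiles:
            prof.validate()

    def disorder_freqs(self, cls: IDPClass) -> np.ndarray:
        factors = dict(self.disorder_enrichment)
        for aa, f in self.class_disorder_enrichment.get(cls, {}).items():
            factors[aa] = factors.get(aa, 1.0) * f
        raw = np.array(
            [self.disorder_composition[aa] * factors.get(aa, 1.0) for aa in AA_ORDER]
        )
        return raw / raw.sum()

    def order_freqs(self) -> np.ndarray:
        return np.array([self.order_composition[aa] for aa in AA_ORDER])


@dataclass
class GroundTruth:
    """Intended class, content and architecture of every generated protein."""

    classes: dict[str, IDPClass]
    contents: dict[str, float]
    proteins: pd.DataFrame
    regions: pd.DataFrame


# ---------------------------------------------------------------------------
# Architecture construction


def _place_segments(
    L: int, seg_lengths: Sequence[int], rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Place non-adjacent segments (1-based inclusive) at random offsets."""
    k = len(seg_lengths)
    slack = L - sum(seg_lengths) - (k - 1)
    if slack < 0:
        raise ValueError("segments do not fit the protein")
    # distribute slack across the k+1 gaps uniformly at random
    cuts = np.sort(rng.integers(0, slack + 1, size=k)) if k else np.array([], dtype=int)
    gaps = np.diff(np.concatenate(([0], cuts, [slack])))
    segs = []
    pos = 1
    for i, ln in enumerate(seg_lengths):
        pos += int(gaps[i]) + (1 if i > 0 else 0)
        segs.append((pos, pos + ln - 1))
        pos += ln
    return segs


def _architecture(
    cls: IDPClass, L: int, cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(disorder segments, binding segments) realizing a class on length L."""
    blo, bhi = cfg.binding_length_range

    def binding_inside(seg: tuple[int, int]) -> tuple[int, int]:
        s, e = seg
        ln = int(rng.integers(blo, min(bhi, e - s + 1) + 1))
        off = int(rng.integers(0, (e - s + 1) - ln + 1))
        return (s + off, s + off + ln - 1)

    if cls is IDPClass.C1_FULLY_DISORDERED:
        frac = rng.uniform(0.82, 0.95)
        seg = [min(L, int(math.ceil(frac * L)))]
        return _place_segments(L, seg, rng), []

    if cls is IDPClass.C2_LOW_SHORT:
        budget = int(math.floor(0.28 * L))
        k = int(rng.integers(1, 4))
        lengths: list[int] = []
        for _ in range(k):
            ln = int(rng.integers(10, 15))
            if sum(lengths) + ln + len(lengths) <= budget:
                lengths.append(ln)
        if not lengths:
            lengths = [10]
        return _place_segments(L, lengths, rng), []

    if cls in (IDPClass.C3_LOW_BINDING_LONG, IDPClass.C4_LOW_NONBINDING_LONG):
        cap = min(60, int(math.floor(0.28 * L)))
        ln = int(rng.integers(16, cap + 1))
        segs = _place_segments(L, [ln], rng)
        if cls is IDPClass.C3_LOW_BINDING_LONG:
            return segs, [binding_inside(segs[0])]
        return segs, []

    if cls in (IDPClass.C5_HIGH_BINDING, IDPClass.C6_HIGH_NONBINDING):
        frac = rng.uniform(0.36, 0.72)
        total = max(16, int(round(frac * L)))
        if total >= 48 and rng.random() < 0.5:
            a = int(rng.integers(16, total - 16 + 1))
            lengths = [a, total - a]
        else:
            lengths = [total]
        segs = _place_segments(L, lengths, rng)
        if cls is IDPClass.C5_HIGH_BINDING:
            return segs, [binding_inside(segs[0])]
        return segs, []

    raise ValueError(f"cannot generate proteins of class {cls!r}")


def generate_reference(
    config: SyntheticConfig,
    *,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[AnnotatedProtein], GroundTruth]:
    """Generate annotated proteins whose derived class equals the intended one.

    The returned ground truth carries the intended classes and the segment
    layout; the function re-derives the class of every protein from its
    annotation tracks and raises if any differs from the request.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    aa_arr = np.array(list(AA_ORDER))
    order_freqs = config.order_freqs()
    proteins: list[AnnotatedProtein] = []
    classes: dict[str, IDPClass] = {}
    contents: dict[str, float] = {}
    prot_rows, region_rows = [], []
    idx = 0
    for cls in IDPClass:
        n = config.n_per_class.get(cls, 0)
        dis_freqs = config.disorder_freqs(cls)
        for _ in range(n):
            idx += 1
            pid = f"SYN{idx:05d}"
            L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
            dsegs, bsegs = _architecture(cls, L, config, rng)
            dis = np.zeros(L, dtype=np.int8)
            for s, e in dsegs:
                dis[s - 1 : e] = 1
            bind = np.zeros(L, dtype=np.int8)
            for s, e in bsegs:
                bind[s - 1 : e] = 1
            seq = np.where(
                dis == 1,
                rng.choice(aa_arr, size=L, p=dis_freqs),
                rng.choice(aa_arr, size=L, p=order_freqs),
            )
            p = AnnotatedProtein(pid, "".join(seq), dis, bind)
            proteins.append(p)
            classes[pid] = cls
            contents[pid] = disorder_content(p)
            prot_rows.append({"protein_id": pid, "class": cls.value,
                              "length": L, "content": contents[pid]})
            for s, e in dsegs:
                region_rows.append({"protein_id": pid, "start": s, "end": e, "kind": "disorder"})
            for s, e in bsegs:
                region_rows.append({"protein_id": pid, "start": s, "end": e, "kind": "binding"})

    derived = classify_idps(proteins)
    mismatches = {pid: (classes[pid], derived[pid]) for pid in classes if derived[pid] != classes[pid]}
    if mismatches:
        raise AssertionError(f"generated architecture violates its class for {mismatches}")

    truth = GroundTruth(
        classes=classes,
        contents=contents,
        proteins=pd.DataFrame(prot_rows, columns=["protein_id", "class", "length", "content"]),
        regions=pd.DataFrame(region_rows, columns=["protein_id", "start", "end", "kind"]),
    )
    return proteins, truth


# ---------------------------------------------------------------------------
# Predictor score tracks


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def generate_predictions(
    proteins: Sequence[AnnotatedProtein],
    profile: PredictorProfile,
    classes: Mapping[str, IDPClass],
    *,
    seed: int | np.random.Generator | None = None,
) -> PredictionTrack:
    """Binormal score track with the profile's per-class target AUC.

    A target of 1.0 is the separation limit: every disordered residue scores
    above every ordered one.
    """
    profile.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    track = PredictionTrack(profile.name)
    for p in proteins:
        cls = classes.get(p.id, IDPClass.UNASSIGNED)
        target = profile.target(cls)
        delta = _DELTA_CAP if target >= 1.0 else math.sqrt(2.0) * float(norm.ppf(target))
        z = rng.standard_normal(len(p))
        z[p.disorder_track == 1] += delta
        track.add(p.id, _logistic(z), (z > delta / 2).astype(np.int8))
    return track


# ---------------------------------------------------------------------------
# Presets

_SPECIALIST_CLASSES = [
    IDPClass.C1_FULLY_DISORDERED,
    IDPClass.C2_LOW_SHORT,
    IDPClass.C3_LOW_BINDING_LONG,
    IDPClass.C4_LOW_NONBINDING_LONG,
    IDPClass.C5_HIGH_BINDING,
    IDPClass.C6_HIGH_NONBINDING,
]


def _preset_null() -> SyntheticConfig:
    # No compositional difference between states; one mediocre predictor.
    # 100 proteins x ~100 residues at ~50% disorder give a 5,000 + 5,000
    # residue sample/background split.
    return SyntheticConfig(
        n_per_class={IDPClass.C6_HIGH_NONBINDING: 100},
        length_range=(100, 100),
        disorder_composition=dict(ORDER_COMPOSITION),
        predictor_profiles=[PredictorProfile("mediocre", default_auc=0.7)],
    )


def _preset_biased_scales() -> SyntheticConfig:
    # Three distinct injected bias profiles: fully disordered proteins,
    # short IDRs, and the long+binding group sharing one profile.
    return SyntheticConfig(
        n_per_class={
            IDPClass.C1_FULLY_DISORDERED: 30,
            IDPClass.C2_LOW_SHORT: 60,
            IDPClass.C5_HIGH_BINDING: 30,
            IDPClass.C6_HIGH_NONBINDING: 30,
        },
        class_disorder_enrichment={
            IDPClass.C1_FULLY_DISORDERED: {"Q": 1.6, "N": 1.5, "G": 1.3},
            IDPClass.C2_LOW_SHORT: {"G": 1.6, "A": 1.4, "D": 1.3},
            IDPClass.C5_HIGH_BINDING: {"P": 1.6, "E": 1.3},
            IDPClass.C6_HIGH_NONBINDING: {"P": 1.6, "E": 1.3},
        },
        predictor_profiles=[PredictorProfile("generic", default_auc=0.8)],
    )


def _preset_class_specialists() -> SyntheticConfig:
    profiles = [
        PredictorProfile(
            f"specialist_{cls.value}", auc_by_class={cls: 0.95}, default_auc=0.55
        )
        for cls in _SPECIALIST_CLASSES
    ]
    return SyntheticConfig(
        n_per_class={cls: 15 for cls in _SPECIALIST_CLASSES},
        length_range=(120, 240),
        predictor_profiles=profiles,
    )


def _preset_caid_like() -> SyntheticConfig:
    # Class mix and lengths chosen so the region-length statistics loosely
    # track the reference benchmark: short IDRs dominate the low-content
    # proteins, a modest number of fully disordered proteins contribute the
    # very long regions, and binding IDRs are common among high-content
    # proteins.
    return SyntheticConfig(
        n_per_class={
            IDPClass.C1_FULLY_DISORDERED: 15,
            IDPClass.C2_LOW_SHORT: 45,
            IDPClass.C3_LOW_BINDING_LONG: 20,
            IDPClass.C4_LOW_NONBINDING_LONG: 20,
            IDPClass.C5_HIGH_BINDING: 40,
            IDPClass.C6_HIGH_NONBINDING: 25,
        },
        length_range=(100, 350),
        predictor_profiles=[
            PredictorProfile("strong", default_auc=0.85),
            PredictorProfile("fair", default_auc=0.75),
        ],
    )


PRESETS = {
    "null": _preset_null,
    "biased_scales": _preset_biased_scales,
    "class_specialists": _preset_class_specialists,
    "caid_like": _preset_caid_like,
}


def preset(name: str) -> SyntheticConfig:
    """A named study configuration; see :data:`PRESETS` for the choices."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
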