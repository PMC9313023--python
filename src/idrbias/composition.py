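"""Amino-acid compositional enrichment with permutation significance.

A residue *sample* (e.g. residues inside binding IDRs) is compared against a
*background* pool (by convention the non-disordered residues of the same
dataset, so that scales computed for different samples are directly
comparable).  For each amino acid ``a``:

    enrichment(a) = (f_sample(a) - f_background(a)) / f_background(a)

which is >= -1 by construction, 0 when the pools agree and +1 when the
sample frequency doubles the background.

Significance is a two-sided permutation test on the frequency difference.
Under a random re-split of the pooled residues into groups of the original
sizes, the sample count of one amino acid is exactly hypergeometric
(N = pooled total, K = pooled count of that amino acid, n = sample size);
the test draws from that null directly, which is distributionally identical
to reshuffling residue labels and is deterministic given the seed.  P-values
use the add-one smoothing (b + 1) / (n_resamples + 1).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from ._aa import AA_ORDER, AA_SET
from .io import AnnotatedProtein, PropensityScale, UNANNOTATED
from .regions import CategoryThresholds, IDRCategory, categorize_idrs

__all__ = [
    "ResiduePool",
    "Call",
    "CompositionScale",
    "build_pools",
    "enrichment",
    "compute_scale",
]


class Call(enum.Enum):
    DEPLETED = "depleted"
    NEUTRAL = "neutral"
    ENRICHED = "enriched"


@dataclass
class ResiduePool:
    """Amino-acid counts over a selection of residues."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        extra = set(self.counts) - AA_SET
        if extra:
            raise ValueError(f"non-standard amino acids in pool: {sorted(extra)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative counts")
        self.counts = {aa: int(self.counts.get(aa, 0)) for aa in AA_ORDER}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequency(self, aa: str) -> float:
        return self.counts[aa] / self.total

    def vector(self) -> np.ndarray:
        return np.array([self.counts[aa] for aa in AA_ORDER], dtype=np.int64)

    @classmethod
    def from_residues(cls, residues: str) -> "ResiduePool":
        c = Counter(residues)
        return cls({aa: c.get(aa, 0) for aa in AA_ORDER})


# Built-in residue selectors: name -> mask function over one protein.
def _mask_disorder(p: AnnotatedProtein) -> np.ndarray:
    return p.disorder_track == 1


def _mask_order(p: AnnotatedProtein) -> np.ndarray:
    return p.disorder_track == 0


def _mask_binding(p: AnnotatedProtein) -> np.ndarray:
    return p.binding_track == 1


Selector = Callable[[AnnotatedProtein], np.ndarray]

_BUILTIN_SELECTORS: dict[str, Selector] = {
    "disorder": _mask_disorder,
    "order": _mask_order,
    "nondisordered": _mask_order,
    "binding": _mask_binding,
}

_CATEGORY_SELECTORS = {
    "fully_disordered_idrs": IDRCategory.FULLY_DISORDERED,
    "short_idrs": IDRCategory.SHORT,
    "long_idrs": IDRCategory.LONG,
    "binding_idrs": IDRCategory.BINDING,
}


def _category_masks(
    proteins: Sequence[AnnotatedProtein],
    category: IDRCategory,
    thresholds: CategoryThresholds,
) -> dict[str, np.ndarray]:
    cats = categorize_idrs(proteins, thresholds=thresholds)
    masks = {p.id: np.zeros(len(p), dtype=bool) for p in proteins}
    for region, assigned in cats.items():
        if category in assigned:
            masks[region.protein_id][region.start - 1 : region.end] = True
    return masks


def resolve_selector(
    name_or_fn: str | Selector,
    proteins: Sequence[AnnotatedProtein],
    thresholds: CategoryThresholds = CategoryThresholds(),
) -> dict[str, np.ndarray]:
    """Turn a selector (built-in name or callable) into per-protein masks.

    Built-ins: ``disorder``, ``order``/``nondisordered``, ``binding`` (the
    binding-annotated residues), and the region-category selectors
    ``fully_disordered_idrs``, ``short_idrs``, ``long_idrs``, ``binding_idrs``
    (residues inside IDRs carrying that category).
    """
    if callable(name_or_fn):
        return {p.id: np.asarray(name_or_fn(p), dtype=bool) for p in proteins}
    if name_or_fn in _BUILTIN_SELECTORS:
        fn = _BUILTIN_SELECTORS[name_or_fn]
        return {p.id: fn(p) for p in proteins}
    if name_or_fn in _CATEGORY_SELECTORS:
        return _category_masks(proteins, _CATEGORY_SELECTORS[name_or_fn], thresholds)
    raise ValueError(
        f"unknown selector {name_or_fn!r}; built-ins: "
        f"{sorted(_BUILTIN_SELECTORS) + sorted(_CATEGORY_SELECTORS)}"
    )


def build_pools(
    proteins: Sequence[AnnotatedProtein],
    sample_selector: str | Selector,
    background_selector: str | Selector = "nondisordered",
    *,
    thresholds: CategoryThresholds = CategoryThresholds(),
) -> tuple[ResiduePool, ResiduePool]:
    """Count amino acids over two disjoint residue selections.

    Unannotated and non-standard residues are excluded from both pools.
    Raises if either selection is empty or the selections overlap.
    """
    sample_masks = resolve_selector(sample_selector, proteins, thresholds)
    bg_masks = resolve_selector(background_selector, proteins, thresholds)
    sample_parts: list[str] = []
    bg_parts: list[str] = []
    for p in proteins:
        sm, bm = sample_masks[p.id], bg_masks[p.id]
        if np.any(sm & bm):
            raise ValueError(
                f"sample and background selections overlap in protein {p.id!r}"
            )
        seq = np.frombuffer(p.sequence.encode("ascii"), dtype="S1").astype("U1")
        std = np.isin(seq, list(AA_SET))
        sample_parts.append("".join(seq[sm & std]))
        bg_parts.append("".join(seq[bm & std]))
    sample = ResiduePool.from_residues("".join(sample_parts))
    background = ResiduePool.from_residues("".join(bg_parts))
    if sample.total == 0:
        raise ValueError("sample selection is empty")
    if background.total == 0:
        raise ValueError("background selection is empty")
    return sample, background


def enrichment(sample: ResiduePool, background: ResiduePool, aa: str) -> float:
    """Relative frequency difference (f_sample - f_background) / f_background."""
    if aa not in AA_SET:
        raise ValueError(f"unknown amino acid {aa!r}")
    fb = background.frequency(aa)
    if fb == 0:
        raise ValueError(f"background frequency of {aa!r} is zero; enrichment undefined")
    fs = sample.frequency(aa)
    return (fs - fb) / fb


@dataclass
class CompositionScale(PropensityScale):
    """A computed enrichment scale with per-amino-acid significance.

    ``values`` holds the enrichment (so any :class:`PropensityScale` consumer,
    e.g. the rank-correlation matrix, can use it directly); ``p_values`` and
    ``calls`` hold the permutation test results.
    """

    p_values: dict[str, float] = field(default_factory=dict)
    calls: dict[str, Call] = field(default_factory=dict)
    sample_freqs: dict[str, float] = field(default_factory=dict)
    background_freqs: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def compute_scale(
    sample: ResiduePool,
    background: ResiduePool,
    *,
    n_resamples: int = 10_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    name: str = "scale",
) -> CompositionScale:
    """Enrichment scale with two-sided permutation p-values and calls.

    For each amino acid, the observed |f_sample - f_background| is compared
    with its distribution under random re-splits of the pooled residues into
    groups of the original sizes (see module docstring for the sampling
    scheme).  Calls: ENRICHED/DEPLETED when p < alpha, by the sign of the
    frequency difference; NEUTRAL otherwise.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    ns, nb = sample.total, background.total
    pooled = sample.vector() + background.vector()
    values: dict[str, float] = {}
    p_values: dict[str, float] = {}
    calls: dict[str, Call] = {}
    for i, aa in enumerate(AA_ORDER):
        fs, fb = sample.frequency(aa), background.frequency(aa)
        values[aa] = enrichment(sample, background, aa)
        obs = abs(fs - fb)
        K = int(pooled[i])
        # Count in the smaller group under a random re-split:
        # Hypergeometric(N, K, m).  Drawing for the smaller group makes the
        # resampled null identical (given the seed) when sample and
        # background are swapped.
        m = min(ns, nb)
        cs = rng.hypergeometric(K, ns + nb - K, m, size=n_resamples)
        diff = np.abs(cs / m - (K - cs) / (ns + nb - m))
        b = int(np.count_nonzero(diff >= obs - 1e-15))
        p = (b + 1) / (n_resamples + 1)
        p_values[aa] = p
        if p < alpha and fs > fb:
            calls[aa] = Call.ENRICHED
        elif p < alpha and fs < fb:
            calls[aa] = Call.DEPLETED
        else:
            calls[aa] = Call.NEUTRAL

    return CompositionScale(
        name=name,
        values=values,
        significance={aa: calls[aa].name for aa in AA_ORDER},
        p_values=p_values,
        calls=calls,
        sample_freqs={aa: sample.frequency(aa) for aa in AA_ORDER},
        background_freqs={aa: background.frequency(aa) for aa in AA_ORDER},
        metadata={
            "sample_total": ns,
            "background_total": nb,
            "n_resamples": n_resamples,
            "alpha": alpha,
            "seed": None if isinstance(seed, np.random.Generator) else seed,
        },
    )
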