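"""Region extraction, IDR categories and protein-level disorder classes.

An IDR is operationally a maximal run of at least ``min_len`` (default 10)
consecutive disordered residues.  IDRs fall into overlapping categories by
length and the disorder content of their protein:

* ``FULLY_DISORDERED`` — IDRs of proteins with disorder content >= 0.8;
* ``SHORT`` — length in [10, 15) in proteins with content < 0.3;
* ``LONG`` — length > 70 in proteins with content in [0.3, 0.8];
* ``BINDING`` — overlaps an annotated binding region by >= 1 residue
  (assigned in addition to any size category);
* ``OTHER`` — matches no size rule.

Proteins are routed to six mutually exclusive classes for predictor
evaluation; note the class rules use a different "long" threshold (> 15
residues) than the LONG region category (> 70 residues) — both are kept as
separate, configurable parameters.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AnnotatedProtein, BindingState, DisorderState, UNANNOTATED

__all__ = [
    "Region",
    "IDRCategory",
    "IDPClass",
    "CategoryThresholds",
    "ClassThresholds",
    "extract_regions",
    "disorder_content",
    "categorize_idrs",
    "classify_idps",
    "region_summary",
]


@dataclass(frozen=True)
class Region:
    """A maximal annotated segment, 1-based inclusive coordinates."""

    protein_id: str
    start: int
    end: int
    kind: str  # "disorder" | "binding"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid region coordinates {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Region") -> bool:
        return self.protein_id == other.protein_id and not (
            self.end < other.start or other.end < self.start
        )


class IDRCategory(enum.Enum):
    FULLY_DISORDERED = "fully_disordered"
    SHORT = "short"
    LONG = "long"
    BINDING = "binding"
    OTHER = "other"


class IDPClass(enum.Enum):
    C1_FULLY_DISORDERED = "fully_disordered"
    C2_LOW_SHORT = "low_short"
    C3_LOW_BINDING_LONG = "low_binding_long"
    C4_LOW_NONBINDING_LONG = "low_nonbinding_long"
    C5_HIGH_BINDING = "high_binding"
    C6_HIGH_NONBINDING = "high_nonbinding"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class CategoryThresholds:
    """Thresholds of the four IDR categories."""

    idr_min_len: int = 10
    short_max_len: int = 14          # SHORT: 10 <= length <= 14 (i.e. < 15)
    long_region_min: int = 71        # LONG: length > 70
    fully_content: float = 0.8       # FULLY_DISORDERED: content >= 0.8
    short_content_max: float = 0.3   # SHORT: content < 0.3
    long_content_lo: float = 0.3     # LONG: 0.3 <= content <= 0.8 (inclusive)
    long_content_hi: float = 0.8


@dataclass(frozen=True)
class ClassThresholds:
    """Thresholds and precedence of the six protein-level classes.

    Low-content eligibility is content <= 0.3; high-content is strict
    0.3 < content < 0.8; fully disordered is content >= 0.8.  ``class_long_min``
    is the minimum IDR length (> 15, i.e. >= 16) that triggers the long-IDR
    classes 3/4.  Within low content the routing precedence is configurable;
    the default prefers binding-long over non-binding-long over short.
    """

    idr_min_len: int = 10
    low_content_max: float = 0.3
    high_content_min: float = 0.3
    high_content_max: float = 0.8
    fully_content: float = 0.8
    class_short_min: int = 10
    class_short_max: int = 14
    class_long_min: int = 16
    low_precedence: tuple[IDPClass, ...] = (
        IDPClass.C3_LOW_BINDING_LONG,
        IDPClass.C4_LOW_NONBINDING_LONG,
        IDPClass.C2_LOW_SHORT,
    )


def extract_regions(
    protein: AnnotatedProtein,
    kind: str = "disorder",
    min_len: int | None = None,
) -> list[Region]:
    """Maximal runs of the positive state with length >= ``min_len``.

    ``min_len`` defaults to 10 for disorder and 1 for binding.  Unannotated
    residues break a run.  Returned sorted by start coordinate.
    """
    if kind == "disorder":
        track = protein.disorder_track
        min_len = 10 if min_len is None else min_len
    elif kind == "binding":
        track = protein.binding_track
        min_len = 1 if min_len is None else min_len
    else:
        raise ValueError(f"unknown region kind {kind!r}")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")

    pos = track == 1
    # run boundaries via diff on the padded boolean mask
    padded = np.concatenate(([False], pos, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2] + 1, edges[1::2]  # 1-based inclusive
    return [
        Region(protein.id, int(s), int(e), kind)
        for s, e in zip(starts, ends)
        if e - s + 1 >= min_len
    ]


def disorder_content(protein: AnnotatedProtein) -> float:
    """Fraction of all residues annotated disordered (runs < 10 included)."""
    n = len(protein)
    if n == 0:
        raise ValueError(f"protein {protein.id!r} has zero length")
    return float(np.count_nonzero(protein.disorder_track == 1)) / n


def categorize_idrs(
    proteins: Sequence[AnnotatedProtein],
    *,
    thresholds: CategoryThresholds = CategoryThresholds(),
) -> dict[Region, set[IDRCategory]]:
    """Assign the overlapping IDR categories to every IDR of the dataset."""
    t = thresholds
    out: dict[Region, set[IDRCategory]] = {}
    for p in proteins:
        content = disorder_content(p)
        binding = extract_regions(p, "binding", min_len=1)
        for idr in extract_regions(p, "disorder", min_len=t.idr_min_len):
            cats: set[IDRCategory] = set()
            if content >= t.fully_content:
                cats.add(IDRCategory.FULLY_DISORDERED)
            if t.idr_min_len <= idr.length <= t.short_max_len and content < t.short_content_max:
                cats.add(IDRCategory.SHORT)
            if idr.length >= t.long_region_min and t.long_content_lo <= content <= t.long_content_hi:
                cats.add(IDRCategory.LONG)
            if not cats:
                cats.add(IDRCategory.OTHER)
            if any(idr.overlaps(b) for b in binding):
                cats.add(IDRCategory.BINDING)
            out[idr] = cats
    return out


def classify_idps(
    proteins: Sequence[AnnotatedProtein],
    *,
    thresholds: ClassThresholds = ClassThresholds(),
) -> dict[str, IDPClass]:
    """Route every protein to exactly one of the six classes (or UNASSIGNED).

    The assignment is a pure function of (disorder content, IDR lengths,
    binding overlap), so it is independent of protein order.
    """
    t = thresholds
    out: dict[str, IDPClass] = {}
    for p in proteins:
        content = disorder_content(p)
        idrs = extract_regions(p, "disorder", min_len=t.idr_min_len)
        binding = extract_regions(p, "binding", min_len=1)

        def has_long(require_binding: bool) -> bool:
            for r in idrs:
                if r.length < t.class_long_min:
                    continue
                overlaps = any(r.overlaps(b) for b in binding)
                if overlaps == require_binding:
                    return True
            return False

        has_short = any(t.class_short_min <= r.length <= t.class_short_max for r in idrs)

        if content >= t.fully_content:
            out[p.id] = IDPClass.C1_FULLY_DISORDERED
        elif content <= t.low_content_max:
            eligible = {
                IDPClass.C2_LOW_SHORT: has_short,
                IDPClass.C3_LOW_BINDING_LONG: has_long(True),
                IDPClass.C4_LOW_NONBINDING_LONG: has_long(False),
            }
            for cls in t.low_precedence:
                if eligible.get(cls, False):
                    out[p.id] = cls
                    break
            else:
                out[p.id] = IDPClass.UNASSIGNED
        elif t.high_content_min < content < t.high_content_max:
            if not idrs:
                out[p.id] = IDPClass.UNASSIGNED
            elif any(any(r.overlaps(b) for b in binding) for r in idrs):
                out[p.id] = IDPClass.C5_HIGH_BINDING
            else:
                out[p.id] = IDPClass.C6_HIGH_NONBINDING
        else:
            out[p.id] = IDPClass.UNASSIGNED
    return out


def _length_stats(lengths: list[int]) -> tuple[float, float]:
    if not lengths:
        return float("nan"), float("nan")
    arr = np.asarray(lengths)
    return float(np.median(arr)), round(float(arr.mean()), 1)


def region_summary(
    proteins: Sequence[AnnotatedProtein],
    *,
    thresholds: CategoryThresholds = CategoryThresholds(),
) -> pd.DataFrame:
    """Per-category counts and length statistics of the dataset's regions.

    Rows: the complete IDR set, the three size categories, and the binding
    regions themselves (maximal binding runs).  Residue counts are residues
    inside the qualifying regions.
    """
    cats = categorize_idrs(proteins, thresholds=thresholds)
    rows = []

    def add_row(label: str, regions: list[Region]) -> None:
        lengths = [r.length for r in regions]
        med, mean = _length_stats(lengths)
        rows.append(
            {
                "set": label,
                "n_proteins": len({r.protein_id for r in regions}),
                "n_regions": len(regions),
                "n_residues": int(sum(lengths)),
                "median_length": med,
                "mean_length": mean,
            }
        )

    add_row("complete", list(cats))
    for label, cat in (
        ("fully_disordered", IDRCategory.FULLY_DISORDERED),
        ("short", IDRCategory.SHORT),
        ("long", IDRCategory.LONG),
    ):
        add_row(label, [r for r, c in cats.items() if cat in c])
    binding_regions = [
        r for p in proteins for r in extract_regions(p, "binding", min_len=1)
    ]
    add_row("binding", binding_regions)
    df = pd.DataFrame(rows, columns=[
        "set", "n_proteins", "n_regions", "n_residues", "median_length", "mean_length",
    ])
    if not proteins:
        return df.iloc[0:0]
    return df
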