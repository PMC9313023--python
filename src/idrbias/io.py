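"""Readers and writers for CAID-style reference and prediction files.

Three on-disk formats are handled here:

* **Reference files** — FASTA-like text with three physical lines per entry:
  a ``>accession`` header, the amino-acid sequence, and a per-residue label
  string of equal length (``1`` positive state, ``0`` negative state, ``-``
  unannotated).  One file annotates disorder, an optional second file
  annotates binding.
* **Prediction files** — per-protein blocks: a ``>accession`` header followed
  by one line per residue with tab-separated fields
  ``index  residue  score  [binary call]``.
* **Propensity-scale tables** — TSV with columns ``aa``, ``value`` and an
  optional ``significance`` column.

All residue coordinates exposed to users are 1-based inclusive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from ._aa import AA_ORDER, AA_SET, NONSTANDARD

__all__ = [
    "DisorderState",
    "BindingState",
    "Dialect",
    "AnnotatedProtein",
    "PredictionTrack",
    "PropensityScale",
    "ParseError",
    "read_reference",
    "merge_binding",
    "load_dataset",
    "read_predictions",
    "write_predictions",
    "read_scale",
    "write_scale",
    "builtin_scale",
]

# Track encodings (int8): UNANNOTATED shared between the two tracks.
UNANNOTATED = -1


class DisorderState(enum.IntEnum):
    ORDER = 0
    DISORDER = 1


class BindingState(enum.IntEnum):
    NONBINDING = 0
    BINDING = 1


class ParseError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class Dialect:
    """Label alphabet of a reference file."""

    positive: str = "1"
    negative: str = "0"
    unannotated: str = "-"

    def decode(self, labels: str, entry: str) -> np.ndarray:
        table = {self.positive: 1, self.negative: 0, self.unannotated: UNANNOTATED}
        out = np.empty(len(labels), dtype=np.int8)
        for i, ch in enumerate(labels):
            try:
                out[i] = table[ch]
            except KeyError:
                raise ParseError(
                    f"entry {entry!r}: unknown label character {ch!r} at position {i + 1}"
                ) from None
        return out

    def encode(self, track: np.ndarray) -> str:
        table = {1: self.positive, 0: self.negative, UNANNOTATED: self.unannotated}
        return "".join(table[int(v)] for v in track)


@dataclass
class AnnotatedProtein:
    """A protein sequence with per-residue disorder and binding annotation.

    Tracks are int8 arrays of the sequence length with values 1 (positive
    state), 0 (negative state) or -1 (unannotated).
    """

    id: str
    sequence: str
    disorder_track: np.ndarray
    binding_track: np.ndarray

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        n = len(self.sequence)
        if n == 0:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        for name in ("disorder_track", "binding_track"):
            track = np.asarray(getattr(self, name), dtype=np.int8)
            if track.shape != (n,):
                raise ValueError(
                    f"protein {self.id!r}: {name} length {track.shape} != sequence length {n}"
                )
            setattr(self, name, track)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PredictionTrack:
    """Per-residue scores (and optional binary calls) of one predictor."""

    name: str
    scores: dict[str, np.ndarray] = field(default_factory=dict)
    calls: dict[str, np.ndarray | None] = field(default_factory=dict)

    def ids(self) -> list[str]:
        return list(self.scores)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.scores

    def add(self, protein_id: str, scores: np.ndarray, calls: np.ndarray | None) -> None:
        if protein_id in self.scores:
            raise ParseError(f"duplicate prediction block for {protein_id!r}")
        scores = np.asarray(scores, dtype=float)
        if not np.all(np.isfinite(scores)):
            raise ParseError(f"{protein_id!r}: non-finite score")
        if calls is not None:
            calls = np.asarray(calls, dtype=np.int8)
            if not np.isin(calls, (0, 1)).all():
                raise ParseError(f"{protein_id!r}: binary calls must be 0/1")
            if calls.shape != scores.shape:
                raise ParseError(f"{protein_id!r}: calls/scores length mismatch")
        self.scores[protein_id] = scores
        self.calls[protein_id] = calls


@dataclass
class PropensityScale:
    """Twenty per-amino-acid propensity values, optionally with significance."""

    name: str
    values: dict[str, float]
    significance: dict[str, str] | None = None

    def __post_init__(self) -> None:
        missing = AA_SET - set(self.values)
        extra = set(self.values) - AA_SET
        if missing:
            raise ValueError(f"scale {self.name!r}: missing amino acid(s) {sorted(missing)}")
        if extra:
            raise ValueError(f"scale {self.name!r}: unexpected key(s) {sorted(extra)}")

    def vector(self, order: Sequence[str] = AA_ORDER) -> np.ndarray:
        """Values as a 20-vector aligned to ``order`` (default alphabetical)."""
        return np.array([self.values[aa] for aa in order], dtype=float)


# ---------------------------------------------------------------------------
# Reference files


def _iter_entries(path: Path) -> Iterator[tuple[str, str, str]]:
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise ParseError(f"{path}: expected '>' header at line {i + 1}, got {header!r}")
        if i + 2 >= len(lines):
            raise ParseError(f"{path}: truncated entry {header!r}")
        yield header[1:].split()[0], lines[i + 1].strip(), lines[i + 2].strip()
        i += 3


def read_reference(
    path: str | Path,
    *,
    kind: str = "disorder",
    dialect: Dialect = Dialect(),
) -> list[AnnotatedProtein]:
    """Read a CAID-style reference file into annotated proteins.

    ``kind`` selects which track the label line fills (``"disorder"`` or
    ``"binding"``); the other track is left fully unannotated so that a later
    :func:`merge_binding` can combine two files.
    """
    if kind not in ("disorder", "binding"):
        raise ValueError(f"kind must be 'disorder' or 'binding', got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    proteins: list[AnnotatedProtein] = []
    seen: set[str] = set()
    n_entries = 0
    for pid, seq, labels in _iter_entries(path):
        n_entries += 1
        if pid in seen:
            raise ParseError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        if len(seq) != len(labels):
            raise ParseError(
                f"{path}: entry {pid!r}: sequence length {len(seq)} != label length {len(labels)}"
            )
        track = dialect.decode(labels, pid)
        blank = np.full(len(seq), UNANNOTATED, dtype=np.int8)
        if kind == "disorder":
            proteins.append(AnnotatedProtein(pid, seq, track, blank))
        else:
            proteins.append(AnnotatedProtein(pid, seq, blank, track))
    if len(proteins) != n_entries:  # pragma: no cover - defensive
        raise ParseError(f"{path}: parsed {len(proteins)} of {n_entries} entries")
    return proteins


def merge_binding(
    proteins: Sequence[AnnotatedProtein],
    binding: Sequence[AnnotatedProtein],
    *,
    strict: bool = False,
) -> list[AnnotatedProtein]:
    """Merge binding annotation into a disorder-annotated protein set.

    Proteins absent from the binding set get an all-NONBINDING track by
    default (binding is a subset annotation); with ``strict=True`` they stay
    unannotated for binding.
    """
    by_id = {p.id: p for p in binding}
    out = []
    for p in proteins:
        b = by_id.get(p.id)
        if b is None:
            fill = UNANNOTATED if strict else int(BindingState.NONBINDING)
            track = np.full(len(p), fill, dtype=np.int8)
        else:
            if b.sequence != p.sequence:
                raise ParseError(f"binding reference sequence mismatch for {p.id!r}")
            track = b.binding_track
        out.append(replace(p, binding_track=track))
    return out


def load_dataset(
    disorder_path: str | Path,
    binding_path: str | Path | None = None,
    *,
    dialect: Dialect = Dialect(),
    strict_binding: bool = False,
) -> list[AnnotatedProtein]:
    """Read the disorder reference and, optionally, merge a binding reference."""
    proteins = read_reference(disorder_path, kind="disorder", dialect=dialect)
    if binding_path is not None:
        binding = read_reference(binding_path, kind="binding", dialect=dialect)
        proteins = merge_binding(proteins, binding, strict=strict_binding)
    else:
        proteins = merge_binding(proteins, [], strict=strict_binding)
    return proteins


def write_reference(
    proteins: Iterable[AnnotatedProtein],
    path: str | Path,
    *,
    kind: str = "disorder",
    dialect: Dialect = Dialect(),
) -> None:
    """Serialize proteins back to the three-line reference format."""
    path = Path(path)
    with path.open("w") as fh:
        for p in proteins:
            track = p.disorder_track if kind == "disorder" else p.binding_track
            fh.write(f">{p.id}\n{p.sequence}\n{dialect.encode(track)}\n")


# ---------------------------------------------------------------------------
# Prediction files


def read_predictions(
    path: str | Path,
    *,
    name: str | None = None,
    sep: str | None = "\t",
    reference: Sequence[AnnotatedProtein] | None = None,
) -> PredictionTrack:
    """Read a CAID-style per-residue prediction file.

    Each block is a ``>id`` header followed by one line per residue with
    fields ``index residue score [call]``.  Residue indices must be 1..L with
    no gaps.  When ``reference`` is given, residue letters and lengths are
    checked against it.
    """
    path = Path(path)
    track = PredictionTrack(name or path.stem)
    ref = {p.id: p for p in reference} if reference is not None else None

    cur_id: str | None = None
    scores: list[float] = []
    calls: list[int] = []
    letters: list[str] = []
    have_calls = True

    def flush() -> None:
        nonlocal cur_id, scores, calls, letters, have_calls
        if cur_id is None:
            return
        if not scores:
            raise ParseError(f"{path}: empty block for {cur_id!r}")
        arr_calls = np.array(calls, dtype=np.int8) if have_calls else None
        track.add(cur_id, np.array(scores), arr_calls)
        if ref is not None:
            p = ref.get(cur_id)
            if p is None:
                raise ParseError(f"{path}: {cur_id!r} not in the reference")
            if len(scores) != len(p):
                raise ParseError(
                    f"{path}: {cur_id!r}: {len(scores)} residue lines for a "
                    f"{len(p)}-residue reference protein"
                )
            for i, ch in enumerate(letters):
                if ch and p.sequence[i] != ch:
                    raise ParseError(
                        f"{path}: {cur_id!r}: residue {i + 1} is {ch!r}, "
                        f"reference has {p.sequence[i]!r}"
                    )
        cur_id, scores, calls, letters, have_calls = None, [], [], [], True

    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            flush()
            cur_id = line[1:].split()[0]
            continue
        if cur_id is None:
            raise ParseError(f"{path}:{lineno}: residue line before any header")
        fields = line.split(sep) if sep else line.split()
        fields = [f for f in fields if f != ""]
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 'index residue score [call]'")
        try:
            idx = int(fields[0])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: bad residue index {fields[0]!r}") from None
        if idx != len(scores) + 1:
            raise ParseError(
                f"{path}:{lineno}: non-contiguous residue index {idx} "
                f"(expected {len(scores) + 1})"
            )
        try:
            score = float(fields[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: bad score {fields[2]!r}") from None
        scores.append(score)
        letters.append(fields[1])
        if len(fields) >= 4:
            try:
                calls.append(int(fields[3]))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad call {fields[3]!r}") from None
        else:
            have_calls = False
    flush()
    return track


def write_predictions(
    track: PredictionTrack,
    path: str | Path,
    *,
    proteins: Sequence[AnnotatedProtein] | None = None,
    sep: str = "\t",
) -> None:
    """Serialize a prediction track to the per-residue block format."""
    seqs = {p.id: p.sequence for p in proteins} if proteins is not None else {}
    with Path(path).open("w") as fh:
        for pid, scores in track.scores.items():
            fh.write(f">{pid}\n")
            seq = seqs.get(pid, "")
            calls = track.calls.get(pid)
            for i, s in enumerate(scores):
                letter = seq[i] if i < len(seq) else "X"
                row = [str(i + 1), letter, f"{s:.6g}"]
                if calls is not None:
                    row.append(str(int(calls[i])))
                fh.write(sep.join(row) + "\n")


# ---------------------------------------------------------------------------
# Propensity-scale tables


def read_scale(path: str | Path, *, name: str | None = None) -> PropensityScale:
    """Read a TSV propensity scale (columns: aa, value, optional significance)."""
    path = Path(path)
    values: dict[str, float] = {}
    significance: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0].strip().lower() in ("aa", "amino_acid", "residue"):
            continue
        aa = fields[0].strip().upper()
        if aa not in AA_SET:
            raise ParseError(f"{path}:{lineno}: unknown amino acid {aa!r}")
        if aa in values:
            raise ParseError(f"{path}:{lineno}: duplicated amino acid {aa!r}")
        try:
            values[aa] = float(fields[1])
        except (IndexError, ValueError):
            raise ParseError(f"{path}:{lineno}: bad value for {aa!r}") from None
        if len(fields) >= 3 and fields[2].strip():
            significance[aa] = fields[2].strip().upper()
    missing = AA_SET - set(values)
    if missing:
        raise ParseError(f"{path}: missing amino acid(s) {sorted(missing)}")
    return PropensityScale(name or path.stem, values, significance or None)


def write_scale(scale: PropensityScale, path: str | Path, *, precision: int = 6) -> None:
    """Write a propensity scale as TSV; round-trips through :func:`read_scale`."""
    with Path(path).open("w") as fh:
        cols = "aa\tvalue" + ("\tsignificance" if scale.significance else "")
        fh.write(cols + "\n")
        for aa in AA_ORDER:
            row = f"{aa}\t{scale.values[aa]:.{precision}g}"
            if scale.significance:
                row += f"\t{scale.significance.get(aa, '')}"
            fh.write(row + "\n")


def builtin_scale(name: str = "disprot_propensity") -> PropensityScale:
    """Load a propensity scale shipped with the package.

    ``disprot_propensity`` is a published DisProt-derived per-amino-acid
    disorder propensity ranking (proline most disorder-promoting; tryptophan
    and cysteine least), used as the external comparison scale.
    """
    from importlib import resources

    ref = resources.files("idrbias").joinpath(f"data/{name}.tsv")
    with resources.as_file(ref) as fp:
        if not fp.exists():
            raise ValueError(f"unknown builtin scale {name!r}")
        return read_scale(fp, name=name)


def residue_count(proteins: Iterable[AnnotatedProtein]) -> int:
    """Total number of residues across a protein set."""
    return sum(len(p) for p in proteins)
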