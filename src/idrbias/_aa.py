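"""Amino-acid alphabet and reference composition vectors.

The 20-letter standard alphabet is the universe for every composition and
propensity computation in this package; non-standard letters (X, U, B, Z, O, J)
are tolerated in sequences but excluded from residue pools.
"""

from __future__ import annotations

import numpy as np

#: Standard amino acids in a fixed, alphabetical one-letter order.  Every
#: 20-vector in the package (scales, composition frequencies) is aligned to
#: this order unless stated otherwise.
AA_ORDER: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

AA_SET = frozenset(AA_ORDER)

#: Letters tolerated in input sequences but never counted in pools.
NONSTANDARD = frozenset("XUBZOJ")

# Average composition of well-folded/ordered protein sequence, close to the
# Swiss-Prot background; renormalized below so the fractions sum to 1 exactly.
_ORDER_RAW: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

# Disordered-state composition: the ordered background reweighted by the
# canonical disorder biases (enriched P/E/S/K/Q/G/D, depleted W/C/F/Y/I/L/V)
# and renormalized.  These factors emulate the direction and rough size of
# biases reported for experimentally annotated disorder.
_DISORDER_FACTORS: dict[str, float] = {
    "P": 1.9, "E": 1.5, "S": 1.4, "K": 1.4, "Q": 1.3, "G": 1.2, "D": 1.2,
    "A": 1.1, "T": 1.1, "R": 1.0, "N": 0.9, "H": 0.8, "M": 0.7, "V": 0.6,
    "L": 0.55, "I": 0.45, "F": 0.45, "Y": 0.5, "C": 0.35, "W": 0.35,
}


def _reweight(base: dict[str, float], factors: dict[str, float]) -> dict[str, float]:
    raw = {aa: base[aa] * factors.get(aa, 1.0) for aa in AA_ORDER}
    tot = sum(raw.values())
    return {aa: v / tot for aa, v in raw.items()}


ORDER_COMPOSITION: dict[str, float] = _reweight(_ORDER_RAW, {})
DISORDER_COMPOSITION: dict[str, float] = _reweight(ORDER_COMPOSITION, _DISORDER_FACTORS)


def composition_vector(freqs: dict[str, float]) -> np.ndarray:
    """Return a composition dict as a 20-vector aligned to :data:`AA_ORDER`."""
    return np.array([freqs[aa] for aa in AA_ORDER], dtype=float)


def validate_composition(freqs: dict[str, float], name: str = "composition") -> None:
    missing = AA_SET - set(freqs)
    if missing:
        raise ValueError(f"{name} is missing amino acids: {sorted(missing)}")
    extra = set(freqs) - AA_SET
    if extra:
        raise ValueError(f"{name} has non-standard keys: {sorted(extra)}")
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {total!r})")
    if any(v < 0 for v in freqs.values()):
        raise ValueError(f"{name} has negative frequencies")
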