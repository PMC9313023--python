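"""Shared fixtures: tiny hand-built proteins and synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from idrbias import AnnotatedProtein, generate_predictions, generate_reference, preset
from idrbias.io import UNANNOTATED


def make_protein(
    pid: str,
    disorder: str,
    binding: str | None = None,
    sequence: str | None = None,
) -> AnnotatedProtein:
    """Build a protein from label strings ('1'/'0'/'-')."""

    def decode(labels: str) -> np.ndarray:
        table = {"1": 1, "0": 0, "-": UNANNOTATED}
        return np.array([table[c] for c in labels], dtype=np.int8)

    n = len(disorder)
    if sequence is None:
        sequence = ("ACDEFGHIKLMNPQRSTVWY" * (n // 20 + 1))[:n]
    if binding is None:
        binding = "0" * n
    return AnnotatedProtein(pid, sequence, decode(disorder), decode(binding))


@pytest.fixture(scope="session")
def caid_like_dataset():
    """One seeded caid_like synthetic dataset with its tracks and truth."""
    cfg = preset("caid_like")
    rng = np.random.default_rng(20_260_926)
    proteins, truth = generate_reference(cfg, seed=rng)
    tracks = [
        generate_predictions(proteins, prof, truth.classes, seed=rng)
        for prof in cfg.predictor_profiles
    ]
    return proteins, truth, tracks


@pytest.fixture(scope="session")
def specialists_dataset():
    """Class-specialist benchmark: six predictors, each strong on one class."""
    cfg = preset("class_specialists")
    rng = np.random.default_rng(77)
    proteins, truth = generate_reference(cfg, seed=rng)
    tracks = [
        generate_predictions(proteins, prof, truth.classes, seed=rng)
        for prof in cfg.predictor_profiles
    ]
    return proteins, truth, tracks
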