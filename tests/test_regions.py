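"""Region extraction, category rules and protein-class routing."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idrbias import (
    IDPClass,
    IDRCategory,
    Region,
    categorize_idrs,
    classify_idps,
    disorder_content,
    extract_regions,
    region_summary,
)

from .conftest import make_protein


def brute_force_regions(labels: str, min_len: int) -> list[tuple[int, int]]:
    """Every (start, end) pair that is a maximal all-positive run."""
    n = len(labels)
    out = []
    for s in range(n):
        for e in range(s, n):
            seg = labels[s : e + 1]
            if set(seg) != {"1"} or e - s + 1 < min_len:
                continue
            if (s > 0 and labels[s - 1] == "1") or (e < n - 1 and labels[e + 1] == "1"):
                continue  # not maximal
            out.append((s + 1, e + 1))
    return out


class TestExtractRegions:
    def test_short_runs_filtered(self):
        labels = "0" + "1" * 11 + "00" + "1" * 9 + "0"
        p = make_protein("P", labels)
        regions = extract_regions(p, "disorder", min_len=10)
        assert [(r.start, r.end, r.length) for r in regions] == [(2, 12, 11)]

    def test_all_order_gives_empty(self):
        assert extract_regions(make_protein("P", "0" * 30)) == []

    def test_unannotated_breaks_runs(self):
        p = make_protein("P", "111-111")
        assert [(r.start, r.end) for r in extract_regions(p, min_len=3)] == [(1, 3), (5, 7)]

    @given(st.text(alphabet="01-", min_size=1, max_size=50), st.integers(1, 12))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_agrees_with_brute_force(self, labels, min_len):
        p = make_protein("P", labels)
        got = [(r.start, r.end) for r in extract_regions(p, min_len=min_len)]
        assert got == brute_force_regions(labels, min_len)

    def test_region_lengths_bounded_by_positive_count(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            labels = "".join(rng.choice(list("011"), size=40))
            p = make_protein("P", labels)
            n_pos = labels.count("1")
            assert sum(r.length for r in extract_regions(p, min_len=3)) <= n_pos
            assert sum(r.length for r in extract_regions(p, min_len=1)) == n_pos


class TestDisorderContent:
    @pytest.mark.parametrize(
        "labels, expected",
        [("1" * 85 + "0" * 15, 0.85), ("0" * 40, 0.0), ("11111" + "0" * 5, 0.5)],
    )
    def test_direct_ratio(self, labels, expected):
        assert disorder_content(make_protein("P", labels)) == pytest.approx(expected)

    def test_short_runs_counted(self):
        # content counts every disordered residue, also runs shorter than an IDR
        p = make_protein("P", "11" + "0" * 8)
        assert disorder_content(p) == pytest.approx(0.2)
        assert extract_regions(p) == []


class TestCategories:
    def test_short_idr(self):
        # 12-residue IDR, protein content 0.2
        p = make_protein("P", "1" * 12 + "0" * 48)
        cats = categorize_idrs([p])
        assert list(cats.values()) == [{IDRCategory.SHORT}]

    def test_long_binding_idr(self):
        # 80-residue IDR in a 160-residue protein (content 0.5) with binding overlap
        dis = "1" * 80 + "0" * 80
        bind = "0" * 40 + "1" * 10 + "0" * 110
        cats = categorize_idrs([make_protein("P", dis, bind)])
        assert list(cats.values()) == [{IDRCategory.LONG, IDRCategory.BINDING}]

    def test_fully_disordered(self):
        p = make_protein("P", "1" * 90 + "0" * 10)
        cats = categorize_idrs([p])
        assert list(cats.values()) == [{IDRCategory.FULLY_DISORDERED}]

    def test_no_size_rule_gives_other(self):
        # 30-residue IDR at content 0.15: neither short (>14) nor long (<71)
        p = make_protein("P", "1" * 30 + "0" * 170)
        cats = categorize_idrs([p])
        assert list(cats.values()) == [{IDRCategory.OTHER}]

    def test_order_invariance(self, caid_like_dataset):
        proteins, _, _ = caid_like_dataset
        forward = categorize_idrs(proteins)
        backward = categorize_idrs(list(reversed(proteins)))
        assert forward == backward


class TestClassification:
    @pytest.mark.parametrize(
        "dis, bind, expected",
        [
            ("1" * 85 + "0" * 15, None, IDPClass.C1_FULLY_DISORDERED),
            ("1" * 12 + "0" * 48, None, IDPClass.C2_LOW_SHORT),
            ("1" * 20 + "0" * 80, "0" * 5 + "1" * 10 + "0" * 85, IDPClass.C3_LOW_BINDING_LONG),
            ("1" * 20 + "0" * 80, None, IDPClass.C4_LOW_NONBINDING_LONG),
            ("1" * 50 + "0" * 50, "1" * 10 + "0" * 90, IDPClass.C5_HIGH_BINDING),
            ("1" * 50 + "0" * 50, None, IDPClass.C6_HIGH_NONBINDING),
            ("0" * 100, None, IDPClass.UNASSIGNED),
        ],
    )
    def test_threshold_rules(self, dis, bind, expected):
        p = make_protein("P", dis, bind)
        assert classify_idps([p])["P"] is expected

    def test_binding_long_precedence_over_short(self):
        # a protein with both a short IDR and a binding long IDR routes to C3
        dis = "1" * 12 + "0" * 10 + "1" * 20 + "0" * 158
        bind = "0" * 22 + "1" * 8 + "0" * 170
        p = make_protein("P", dis, bind)
        assert classify_idps([p])["P"] is IDPClass.C3_LOW_BINDING_LONG

    def test_length_15_idr_matches_no_low_content_class(self):
        # 15 residues is outside both the short (<15) and long (>15) triggers
        p = make_protein("P", "1" * 15 + "0" * 85)
        assert classify_idps([p])["P"] is IDPClass.UNASSIGNED

    def test_output_is_partition(self, caid_like_dataset):
        proteins, _, _ = caid_like_dataset
        classes = classify_idps(proteins)
        assert set(classes) == {p.id for p in proteins}
        assert all(isinstance(c, IDPClass) for c in classes.values())


class TestSummary:
    def test_short_row_statistics(self):
        proteins = [
            make_protein(f"P{i}", "1" * n + "0" * (n * 9))
            for i, n in enumerate((10, 12, 14))
        ]
        df = region_summary(proteins).set_index("set")
        row = df.loc["short"]
        assert row.n_regions == 3
        assert row.n_residues == 36
        assert row.median_length == 12
        assert row.mean_length == 12.0

    def test_empty_dataset(self):
        df = region_summary([])
        assert len(df) == 0

    def test_complete_row_counts_all_idrs(self, caid_like_dataset):
        proteins, truth, _ = caid_like_dataset
        df = region_summary(proteins).set_index("set")
        n_idrs = sum(
            len(extract_regions(p, "disorder", min_len=10)) for p in proteins
        )
        assert df.loc["complete"].n_regions == n_idrs
        assert df.loc["complete"].n_proteins <= len(proteins)
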