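"""Subsite frame, residue classes and position-matrix arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cleavescan as cs
from cleavescan.alphabet import ResidueAlphabetError
from cleavescan.core import (
    AlignedPeptide,
    AlignedPeptideBlock,
    ClassScheme,
    PositionMatrix,
    build_pfm,
    class_collapse,
    classify_residue,
    information_content,
    score_window,
)
from conftest import random_block

AA = cs.AMINO_ACIDS
LOG2_20 = math.log2(20)


# ---------------------------------------------------------------------------
# residue classes
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "aa,expected",
    [
        ("F", "aromatic"), ("Y", "aromatic"), ("W", "aromatic"),
        ("D", "negative"), ("E", "negative"),
        ("K", "positive"), ("R", "positive"),
        ("G", "small_aliphatic"), ("A", "small_aliphatic"),
        ("V", "larger_aliphatic"), ("P", "larger_aliphatic"),
        ("S", "hydrophilic"), ("M", "hydrophilic"), ("C", "hydrophilic"),
    ],
)
def test_classify_residue(aa, expected):
    assert classify_residue(aa) == expected


@pytest.mark.parametrize("bad", ["B", "Z", "X", "U", "*", "v", "FY"])
def test_classify_rejects_nonstandard(bad):
    with pytest.raises(ResidueAlphabetError):
        classify_residue(bad)


def test_scheme_partitions_all_residues(scheme):
    members = "".join(scheme.classes.values())
    assert sorted(members) == sorted(AA)  # union = 20, pairwise disjoint
    assert len(scheme.classes) == 6


def test_scheme_rejects_bad_partitions():
    with pytest.raises(ValueError):
        ClassScheme(classes={"a": "FYW", "b": "DE"})  # misses residues
    with pytest.raises(ValueError):
        ClassScheme(classes={"a": AA, "b": "F"})  # duplicate F


def test_frame_is_fixed():
    assert cs.FRAME.labels[4] == "P1" and cs.FRAME.labels[5] == "P1'"
    with pytest.raises(ValueError):
        cs.SubsiteFrame(labels=("P6",) + cs.FRAME.labels[:-1], p1_index=5)


# ---------------------------------------------------------------------------
# block / PFM construction
# ---------------------------------------------------------------------------


def test_pfm_unanimous_p1():
    block = AlignedPeptideBlock(
        [AlignedPeptide("GGGGVGGGG", 1, 0), AlignedPeptide("AAAAVAAAA", 1, 0)],
        mode="mask",
    )
    m = build_pfm(block, alpha=0.0)
    assert m.freq[4, AA.index("V")] == 1.0


def test_pfm_single_peptide_unit_columns():
    block = AlignedPeptideBlock([AlignedPeptide("GLLAVSGRE", 1, 0)], mode="mask")
    m = build_pfm(block, alpha=0.0)
    assert np.all(np.sort(m.freq, axis=1)[:, -1] == 1.0)


def test_pfm_matches_hand_computed_table(simple_block):
    """alpha=1, uniform background: freq = (count + 0.05) / (N + 1)."""
    m = build_pfm(simple_block, alpha=1.0)
    # independent hand count, column by column
    for j in range(9):
        col_residues = [
            (p.sequence[j], p.count) for p in simple_block.peptides
        ]
        n = sum(c for _, c in col_residues)
        for k, aa in enumerate(AA):
            count = sum(c for r, c in col_residues if r == aa)
            expected = (count + 1.0 * 0.05) / (n + 1.0)
            assert m.freq[j, k] == pytest.approx(expected, abs=1e-12)


def test_pfm_errors():
    with pytest.raises(ValueError):
        build_pfm(AlignedPeptideBlock([], mode="mask"))
    block = AlignedPeptideBlock([AlignedPeptide("GGGGVGGGG", 1, 0)])
    with pytest.raises(ValueError):
        build_pfm(block, alpha=-0.5)
    # offset 4 leaves the left columns unresolved in mask mode
    edge = AlignedPeptideBlock([AlignedPeptide("VGGGGGGGG", 1, -4)], mode="mask")
    with pytest.raises(ValueError):
        build_pfm(edge, alpha=0.0)


def test_context_fill_resolves_his_tag_cells():
    # anchor at nonamer index 8: P1'..P4' come from the His6 suffix
    block = AlignedPeptideBlock([AlignedPeptide("GGGGGGGGV", 1, 4)], mode="context")
    cells = block.rows()[0]
    assert cells[4] == "V" and cells[5:] == ["H", "H", "H", "H"]
    masked = AlignedPeptideBlock([AlignedPeptide("GGGGGGGGV", 1, 4)], mode="mask")
    assert masked.rows()[0][5:] == [None] * 4


# ---------------------------------------------------------------------------
# information content / collapse / scoring
# ---------------------------------------------------------------------------


def _matrix_with_column(col, fill=None):
    freq = np.tile(fill if fill is not None else np.full(20, 0.05), (9, 1))
    freq[4] = col
    return PositionMatrix(freq)


def test_information_content_reference_columns():
    unit = np.zeros(20)
    unit[0] = 1.0
    half = np.zeros(20)
    half[:2] = 0.5
    m = _matrix_with_column(unit)
    ic = information_content(m)
    assert ic[4] == pytest.approx(LOG2_20)
    assert ic[0] == pytest.approx(0.0)  # uniform rows
    assert information_content(_matrix_with_column(half))[4] == pytest.approx(
        LOG2_20 - 1.0
    )


def test_class_collapse_reference_columns(scheme):
    col = np.zeros(20)
    col[AA.index("V")] = 0.6
    col[AA.index("L")] = 0.4
    collapsed = class_collapse(_matrix_with_column(col), scheme)
    assert collapsed.loc["P1", "larger_aliphatic"] == pytest.approx(1.0)
    # uniform column collapses to class sizes / 20
    expected = {"aromatic": 3, "negative": 2, "positive": 2,
                "small_aliphatic": 2, "larger_aliphatic": 4, "hydrophilic": 7}
    for cls, size in expected.items():
        assert collapsed.loc["P5", cls] == pytest.approx(size / 20)
    assert np.allclose(collapsed.sum(axis=1), 1.0)


def test_score_window_background_matrix_is_zero():
    m = PositionMatrix.background_matrix()
    assert score_window(m, "ACDEFGHIK") == pytest.approx(0.0)
    assert score_window(m, "VVVVVVVVV") == pytest.approx(0.0)


def test_score_window_consensus_is_maximal(hne_truth):
    m = hne_truth.pwm
    best = score_window(m, m.consensus_window())
    rng = np.random.default_rng(42)
    for _ in range(200):
        w = "".join(rng.choice(list(AA), size=9))
        assert score_window(m, w) <= best + 1e-12


def test_score_window_additivity(hne_truth):
    m = hne_truth.pwm
    window = "GLVAVSEKH"
    partial = sum(
        m.logodds[j, AA.index(aa)] for j, aa in enumerate(window)
    )
    assert score_window(m, window) == pytest.approx(partial)


def test_score_window_errors(hne_truth):
    with pytest.raises(ValueError):
        score_window(hne_truth.pwm, "SHORT")
    with pytest.raises(ResidueAlphabetError):
        score_window(hne_truth.pwm, "GLVAVSEKX")


# ---------------------------------------------------------------------------
# serialization round trips
# ---------------------------------------------------------------------------


def test_matrix_roundtrips(tmp_path, simple_block):
    m = build_pfm(simple_block, alpha=1.0)
    tsv = tmp_path / "m.tsv"
    m.to_tsv(tsv)
    m2 = PositionMatrix.from_tsv(tsv, alpha=1.0)
    assert np.allclose(m.freq, m2.freq, atol=1e-5)
    js = tmp_path / "m.json"
    m.to_json(js)
    m3 = PositionMatrix.from_json(js)
    assert np.allclose(m.freq, m3.freq)
    assert m3.alpha == m.alpha


def test_class_scheme_json_roundtrip(tmp_path, scheme):
    path = tmp_path / "scheme.json"
    scheme.to_json(path)
    again = ClassScheme.from_json(path)
    assert again.classes == dict(scheme.classes)


def test_bundled_scheme_matches_default(scheme):
    import importlib.resources

    ref = importlib.resources.files("cleavescan.data") / "class_scheme.json"
    shipped = ClassScheme.from_json(str(ref))
    assert shipped.residue_to_class == scheme.residue_to_class


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), alpha=st.floats(0.0, 5.0))
def test_pfm_columns_normalized(seed, alpha):
    rng = np.random.default_rng(seed)
    block = random_block(rng)
    m = build_pfm(block, alpha=alpha)
    assert np.allclose(m.freq.sum(axis=1), 1.0, atol=1e-9)
    ic = information_content(m)
    assert np.all(ic >= 0.0) and np.all(ic <= LOG2_20 + 1e-12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_ic_decreases_with_smoothing(seed):
    rng = np.random.default_rng(seed)
    block = random_block(rng)
    sharp = information_content(build_pfm(block, alpha=0.5)).sum()
    smooth = information_content(build_pfm(block, alpha=2.0)).sum()
    assert smooth <= sharp + 1e-9


def test_scores_invariant_to_copy_count_rescaling():
    rng = np.random.default_rng(3)
    block = random_block(rng)
    scaled = AlignedPeptideBlock(
        [AlignedPeptide(p.sequence, p.count * 3, p.offset)
         for p in block.peptides],
        mode="mask",
    )
    m1 = build_pfm(block, alpha=0.0)
    m2 = build_pfm(scaled, alpha=0.0)
    assert np.allclose(m1.freq, m2.freq)
    window = block.peptides[0].sequence  # observed residues, finite score
    assert score_window(m1, window) == pytest.approx(score_window(m2, window))
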