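"""Subsite frames, residue classes and position matrices.

This module holds the coordinate system and matrix arithmetic that the
rest of the package is built on:

* :class:`SubsiteFrame` — the Schechter–Berger P5…P1|P1′…P4′ frame around
  the scissile bond (cleavage occurs between P1 and P1′).
* :class:`ClassScheme` — a partition of the 20 standard residues into six
  physicochemical classes (aromatic, negatively/positively charged, small
  aliphatic, larger aliphatic, hydrophilic).
* :class:`AlignedPeptideBlock` — selected nonamer peptides placed in the
  frame via per-peptide offsets, with the phage capsid context
  (``PGG…HHHHHH``) available to fill frame cells that fall outside the
  randomized nonamer.
* :class:`PositionMatrix` — per-subsite residue frequencies with
  pseudocount smoothing, their log-odds transform against a background
  composition, information content, class collapse and window scoring.

Frequencies are column-normalized (each subsite sums to 1) and log-odds
are in bits (log base 2) throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import (
    AA_INDEX,
    AMINO_ACIDS,
    N_RESIDUES,
    ResidueAlphabetError,
    check_sequence,
)

__all__ = [
    "SubsiteFrame",
    "FRAME",
    "ClassScheme",
    "DEFAULT_CLASS_SCHEME",
    "CLASS_NAMES",
    "classify_residue",
    "PrimarySpecificity",
    "AlignedPeptide",
    "AlignedPeptideBlock",
    "PositionMatrix",
    "build_pfm",
    "information_content",
    "class_collapse",
    "score_window",
    "uniform_background",
]


# ---------------------------------------------------------------------------
# Subsite frame
# ---------------------------------------------------------------------------

_SUBSITE_LABELS = ("P5", "P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")


@dataclass(frozen=True)
class SubsiteFrame:
    """The fixed 9-wide subsite coordinate system around the scissile bond.

    The scissile bond lies between ``labels[p1_index]`` (P1) and
    ``labels[p1_index + 1]`` (P1′). Only the canonical P5–P4′ frame is
    accepted; wider or shifted frames are rejected rather than truncated.
    """

    labels: tuple[str, ...] = _SUBSITE_LABELS
    p1_index: int = 4

    def __post_init__(self) -> None:
        if self.labels != _SUBSITE_LABELS or self.p1_index != 4:
            raise ValueError(
                "only the canonical P5..P4' frame (9 subsites, P1 at index 4) "
                "is supported"
            )

    @property
    def width(self) -> int:
        return len(self.labels)


FRAME = SubsiteFrame()


# ---------------------------------------------------------------------------
# Residue class scheme
# ---------------------------------------------------------------------------

CLASS_NAMES = (
    "aromatic",
    "negative",
    "positive",
    "small_aliphatic",
    "larger_aliphatic",
    "hydrophilic",
)

_DEFAULT_CLASSES: dict[str, str] = {
    "aromatic": "FYW",
    "negative": "DE",
    "positive": "KR",
    "small_aliphatic": "GA",
    "larger_aliphatic": "VLIP",
    "hydrophilic": "STHNQCM",
}


@dataclass(frozen=True)
class ClassScheme:
    """A partition of the 20 standard residues into named classes.

    The default scheme groups residues by side-chain character: aromatic
    (Phe, Tyr, Trp); negatively charged (Asp, Glu); positively charged
    (Lys, Arg); small aliphatic (Gly, Ala); larger aliphatic (Val, Leu,
    Ile, Pro); hydrophilic (Ser, Thr, His, Asn, Gln, Cys, Met).
    """

    classes: Mapping[str, str]
    residue_to_class: Mapping[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        mapping: dict[str, str] = {}
        for cls, members in self.classes.items():
            for aa in members:
                if aa not in AA_INDEX:
                    raise ResidueAlphabetError(f"non-standard residue {aa!r}")
                if aa in mapping:
                    raise ValueError(f"residue {aa!r} assigned to two classes")
                mapping[aa] = cls
        if len(mapping) != N_RESIDUES:
            missing = sorted(set(AMINO_ACIDS) - set(mapping))
            raise ValueError(f"scheme does not cover residues: {missing}")
        object.__setattr__(self, "residue_to_class", mapping)

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(self.classes)

    def class_of(self, aa: str) -> str:
        try:
            return self.residue_to_class[aa]
        except KeyError:
            raise ResidueAlphabetError(f"non-standard residue {aa!r}") from None

    def class_index(self, aa: str) -> int:
        return self.class_names.index(self.class_of(aa))

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps({"classes": {k: v for k, v in self.classes.items()}},
                         indent=2)
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc

    @classmethod
    def from_json(cls, source: str | Path) -> "ClassScheme":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls(classes=json.loads(text)["classes"])


DEFAULT_CLASS_SCHEME = ClassScheme(classes=_DEFAULT_CLASSES)


def classify_residue(aa: str, scheme: ClassScheme = DEFAULT_CLASS_SCHEME) -> str:
    """Return the class name of a single standard residue."""
    if len(aa) != 1:
        raise ResidueAlphabetError(f"expected a single residue, got {aa!r}")
    return scheme.class_of(aa)


# ---------------------------------------------------------------------------
# Primary specificity (P1 anchor sets)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrimarySpecificity:
    """P1 residues accepted by an enzyme, split into strong and weak tiers.

    The strong tier holds the residues the enzyme cleaves after
    efficiently; the weak tier holds residues that are tolerated but
    disfavored (alignment and site prediction penalize them).
    """

    name: str
    strong: frozenset[str]
    weak: frozenset[str] = frozenset()
    notes: str = ""

    def __post_init__(self) -> None:
        for aa in self.strong | self.weak:
            if aa not in AA_INDEX:
                raise ResidueAlphabetError(f"non-standard residue {aa!r}")
        if not self.strong:
            raise ValueError("anchor set must be non-empty")
        if self.strong & self.weak:
            raise ValueError("strong and weak tiers must be disjoint")

    @property
    def anchor_set(self) -> frozenset[str]:
        return self.strong | self.weak


# ---------------------------------------------------------------------------
# Aligned peptide block
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignedPeptide:
    """A nonamer with a copy count and a frame offset.

    ``offset`` shifts the peptide against the frame: frame column ``j``
    maps to nonamer index ``j + offset``, so the residue at nonamer index
    ``4 + offset`` sits at P1. Valid offsets are −4…4.
    """

    sequence: str
    count: int = 1
    offset: int = 0

    def __post_init__(self) -> None:
        check_sequence(self.sequence)
        if len(self.sequence) != 9:
            raise ValueError(f"nonamer must have length 9, got {self.sequence!r}")
        if self.count < 1:
            raise ValueError("copy count must be >= 1")
        if not -4 <= self.offset <= 4:
            raise ValueError(f"offset {self.offset} places P1 outside the nonamer")

    @property
    def p1_residue(self) -> str:
        return self.sequence[4 + self.offset]


class AlignedPeptideBlock:
    """Peptides placed in the P5–P4′ frame.

    Frame cells that fall outside the 9-residue nonamer are filled from
    the displayed capsid context (``PGG`` prefix, ``HHHHHH`` suffix) in
    ``"context"`` mode, or left empty in ``"mask"`` mode. Cells beyond
    the 18-residue displayed peptide are always empty — context is never
    invented.
    """

    def __init__(
        self,
        peptides: Iterable[AlignedPeptide | tuple],
        *,
        context_prefix: str = "PGG",
        context_suffix: str = "HHHHHH",
        mode: str = "context",
        frame: SubsiteFrame = FRAME,
    ) -> None:
        if mode not in ("context", "mask"):
            raise ValueError(f"unknown fill mode {mode!r}")
        self.peptides: list[AlignedPeptide] = [
            p if isinstance(p, AlignedPeptide) else AlignedPeptide(*p)
            for p in peptides
        ]
        self.context_prefix = check_sequence(context_prefix)
        self.context_suffix = check_sequence(context_suffix)
        self.mode = mode
        self.frame = frame

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def total_count(self) -> int:
        return sum(p.count for p in self.peptides)

    def cell(self, peptide: AlignedPeptide, column: int) -> str | None:
        """Residue occupying frame ``column`` for ``peptide``, or None."""
        i = column + peptide.offset
        if 0 <= i < 9:
            return peptide.sequence[i]
        if self.mode == "mask":
            return None
        ext = self.context_prefix + peptide.sequence + self.context_suffix
        j = i + len(self.context_prefix)
        if 0 <= j < len(ext):
            return ext[j]
        return None

    def rows(self) -> list[list[str | None]]:
        """One frame row (9 cells, None = gap) per peptide."""
        return [
            [self.cell(p, j) for j in range(self.frame.width)]
            for p in self.peptides
        ]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: peptide, count, offset, one column per subsite."""
        rows = []
        for p, cells in zip(self.peptides, self.rows()):
            row = {"peptide": p.sequence, "count": p.count, "offset": p.offset}
            row.update(
                {lab: (c if c is not None else "-")
                 for lab, c in zip(self.frame.labels, cells)}
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, *, mode: str = "context") -> "AlignedPeptideBlock":
        df = pd.read_csv(path, sep="\t")
        peptides = [
            AlignedPeptide(str(r.peptide), int(r.count), int(r.offset))
            for r in df.itertuples()
        ]
        return cls(peptides, mode=mode)


# ---------------------------------------------------------------------------
# Position matrix
# ---------------------------------------------------------------------------


def uniform_background() -> np.ndarray:
    """Uniform residue composition (1/20 each)."""
    return np.full(N_RESIDUES, 1.0 / N_RESIDUES)


def _check_background(background: np.ndarray | None) -> np.ndarray:
    if background is None:
        return uniform_background()
    background = np.asarray(background, dtype=float)
    if background.shape != (N_RESIDUES,):
        raise ValueError("background must be a 20-vector")
    if np.any(background <= 0) or not math.isclose(background.sum(), 1.0,
                                                   abs_tol=1e-9):
        raise ValueError("background must be positive and sum to 1")
    return background


class PositionMatrix:
    """A 9 × 20 per-subsite residue frequency matrix with log-odds scoring.

    Parameters
    ----------
    freq
        Row ``j`` holds the residue frequencies at subsite ``FRAME.labels[j]``
        (columns in :data:`~cleavescan.alphabet.AMINO_ACIDS` order); each row
        sums to 1.
    alpha
        The pseudocount the matrix was built with (recorded for provenance;
        ``build_pfm`` applies it).
    background
        Background residue composition used for the log-odds transform.
    """

    def __init__(
        self,
        freq: np.ndarray,
        *,
        alpha: float = 0.0,
        background: np.ndarray | None = None,
        frame: SubsiteFrame = FRAME,
        metadata: dict | None = None,
    ) -> None:
        freq = np.asarray(freq, dtype=float)
        if freq.shape != (frame.width, N_RESIDUES):
            raise ValueError(
                f"frequency matrix must be {frame.width} x {N_RESIDUES}, "
                f"got {freq.shape}"
            )
        if np.any(freq < 0):
            raise ValueError("frequencies must be non-negative")
        if not np.allclose(freq.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each subsite row must sum to 1")
        if alpha < 0:
            raise ValueError("pseudocount must be >= 0")
        self.freq = freq
        self.alpha = float(alpha)
        self.background = _check_background(background)
        self.frame = frame
        self.metadata = dict(metadata or {})

    # -- derived quantities ----------------------------------------------
    @property
    def logodds(self) -> np.ndarray:
        """log2(freq / background); −inf where a frequency is exactly 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.freq / self.background)

    def information_content(self) -> np.ndarray:
        return information_content(self)

    def class_collapse(self, scheme: ClassScheme = DEFAULT_CLASS_SCHEME) -> pd.DataFrame:
        return class_collapse(self, scheme)

    def score_window(self, window: str) -> float:
        return score_window(self, window)

    def consensus_window(self) -> str:
        """Per-column argmax residue string (the maximal-score window)."""
        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.logodds, axis=1))

    # -- serialization ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.freq, index=list(self.frame.labels), columns=list(AMINO_ACIDS)
        )

    def to_tsv(self, path: str | Path) -> None:
        """Rows = subsites P5…P4′, columns = residues, 6-decimal frequencies."""
        df = self.to_frame().round(6)
        df.index.name = "subsite"
        df.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        *,
        alpha: float = 0.0,
        background: np.ndarray | None = None,
    ) -> "PositionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(FRAME.labels) or list(df.columns) != list(AMINO_ACIDS):
            raise ValueError(f"{path}: unexpected row/column labels")
        freq = df.to_numpy(dtype=float)
        # renormalize away 6-decimal rounding
        freq = freq / freq.sum(axis=1, keepdims=True)
        return cls(freq, alpha=alpha, background=background)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {
                "frame": list(self.frame.labels),
                "alphabet": AMINO_ACIDS,
                "alpha": self.alpha,
                "background": self.background.tolist(),
                "freq": self.freq.tolist(),
                "metadata": self.metadata,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc

    @classmethod
    def from_json(cls, source: str | Path) -> "PositionMatrix":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        if doc.get("alphabet", AMINO_ACIDS) != AMINO_ACIDS:
            raise ValueError("unexpected residue alphabet")
        return cls(
            np.asarray(doc["freq"], dtype=float),
            alpha=float(doc.get("alpha", 0.0)),
            background=np.asarray(doc["background"], dtype=float),
            metadata=doc.get("metadata"),
        )

    @classmethod
    def background_matrix(cls, background: np.ndarray | None = None) -> "PositionMatrix":
        """A matrix equal to its own background (every window scores 0)."""
        bg = _check_background(background)
        return cls(np.tile(bg, (FRAME.width, 1)), background=bg)


# ---------------------------------------------------------------------------
# Matrix operations
# ---------------------------------------------------------------------------


def build_pfm(
    block: AlignedPeptideBlock,
    alpha: float = 1.0,
    background: np.ndarray | None = None,
) -> PositionMatrix:
    """Build a position frequency matrix from an aligned block.

    Each peptide contributes its copy count to every frame cell it
    resolves. With pseudocount ``alpha`` and background ``b``::

        freq[j][a] = (count_j(a) + alpha * b[a]) / (N_j + alpha)

    where ``N_j`` is the total (copy-weighted) number of resolved cells
    in column ``j``. Gap cells (outside the displayed 18-mer, or outside
    the nonamer in ``"mask"`` mode) contribute nothing.
    """
    if len(block) == 0:
        raise ValueError("cannot build a matrix from an empty block")
    if alpha < 0:
        raise ValueError("pseudocount must be >= 0")
    background = _check_background(background)
    counts = np.zeros((block.frame.width, N_RESIDUES))
    for p, cells in zip(block.peptides, block.rows()):
        for j, aa in enumerate(cells):
            if aa is not None:
                counts[j, AA_INDEX[aa]] += p.count
    totals = counts.sum(axis=1, keepdims=True)
    if alpha == 0 and np.any(totals == 0):
        raise ValueError(
            "a frame column has no resolved residues; use alpha > 0 or "
            "context fill"
        )
    freq = (counts + alpha * background) / (totals + alpha)
    meta = {"n_peptides": len(block), "total_count": block.total_count,
            "fill_mode": block.mode}
    return PositionMatrix(freq, alpha=alpha, background=background, metadata=meta)


def information_content(m: PositionMatrix) -> np.ndarray:
    """Per-subsite information content in bits.

    ``IC_j = log2(20) + sum_a freq[j][a] * log2 freq[j][a]``, bounded by
    [0, log2 20]; a uniform column carries 0 bits, a unit column log2 20.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(m.freq > 0, m.freq * np.log2(m.freq), 0.0)
    ic = np.log2(N_RESIDUES) + plogp.sum(axis=1)
    return np.clip(ic, 0.0, np.log2(N_RESIDUES))


def class_collapse(
    m: PositionMatrix, scheme: ClassScheme = DEFAULT_CLASS_SCHEME
) -> pd.DataFrame:
    """Collapse residue frequencies to class frequencies (9 × n_classes)."""
    data = {
        cls: m.freq[:, [AA_INDEX[aa] for aa in members]].sum(axis=1)
        for cls, members in scheme.classes.items()
    }
    return pd.DataFrame(data, index=list(m.frame.labels))


def score_window(m: PositionMatrix, window: str) -> float:
    """Additive log-odds score (bits) of a 9-residue window.

    The window is read in frame order P5…P4′ with its fifth residue at P1.
    """
    check_sequence(window)
    if len(window) != m.frame.width:
        raise ValueError(f"window must have length {m.frame.width}, got {len(window)}")
    lo = m.logodds
    return float(sum(lo[j, AA_INDEX[aa]] for j, aa in enumerate(window)))
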