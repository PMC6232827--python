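"""Anchored placement of selected nonamers into the P5–P4′ frame.

Phage-selected nonamers do not reveal where the enzyme cut them; the
frame placement has to be inferred. Following the elastase primary
specificity, each peptide may only be anchored with an allowed P1
residue (e.g. Val/Ile, weakly Ala, for human neutrophil elastase), and
among the possible anchors the placement is chosen to maximize
cross-peptide agreement of residue *classes* per frame column — the
algorithmic form of aligning unambiguous sequences first and fitting
multi-anchor sequences to the emerging pattern.

The objective is a weighted count of same-class peptide pairs per
column (copy counts included, P1-proximal columns up-weighted), with
weak-tier anchors down-weighted. Peptides are seeded in order of
ascending anchor count (forced placements first), added greedily, and
refined by coordinate ascent; small instances are finished with exact
enumeration over all anchor combinations. Peptides with no admissible
anchor (or non-standard residues) are reported as discarded, never
silently dropped.

By default the objective and the resulting block use gap-mask mode:
frame cells outside the randomized nonamer stay empty rather than being
filled from the constant ``PGG``/``HHHHHH`` capsid context. Context fill
is available (``fill_mode="context"``) but biases anchors toward the
nonamer edges — the shared constant residues score as spurious
class agreement, and the His-tag floods the primed columns of the
inferred matrix.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import is_standard
from .core import (
    DEFAULT_CLASS_SCHEME,
    FRAME,
    AlignedPeptide,
    AlignedPeptideBlock,
    ClassScheme,
    PrimarySpecificity,
)
from .presets import HNE

__all__ = [
    "AlignmentParams",
    "AlignmentResult",
    "DiscardedPeptide",
    "candidate_anchors",
    "alignment_objective",
    "align_nonamers",
    "consensus_report",
    "ConsensusReport",
]


def default_column_weights() -> np.ndarray:
    """Unit weights with the P1-proximal columns (P2–P2′) up-weighted 2x."""
    w = np.ones(FRAME.width)
    w[3:7] = 2.0
    return w


@dataclass(frozen=True)
class AlignmentParams:
    """Knobs of the anchored alignment.

    ``specificity`` supplies the P1 anchor tiers; ``weak_penalty``
    multiplies the objective weight of peptides anchored on a weak-tier
    residue. ``exact_limit`` caps the number of anchor combinations for
    which the search is finished exactly.
    """

    specificity: PrimarySpecificity = HNE
    weights: np.ndarray = field(default_factory=default_column_weights)
    weak_penalty: float = 0.5
    max_iters: int = 20
    exact_limit: int = 20_000
    fill_mode: str = "mask"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (FRAME.width,) or np.any(w <= 0):
            raise ValueError("weights must be 9 positive values")
        object.__setattr__(self, "weights", w)
        if not 0 < self.weak_penalty <= 1:
            raise ValueError("weak_penalty must be in (0, 1]")


@dataclass(frozen=True)
class DiscardedPeptide:
    sequence: str
    count: int
    reason: str


@dataclass
class AlignmentResult:
    block: AlignedPeptideBlock
    discarded: list[DiscardedPeptide]
    objective: float
    exact: bool

    def discard_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"sequence": d.sequence, "count": d.count, "reason": d.reason}
             for d in self.discarded],
            columns=["sequence", "count", "reason"],
        )


def candidate_anchors(nonamer: str, anchor_set: Sequence[str] | frozenset[str]) -> list[int]:
    """0-based nonamer indices whose residue may serve as P1."""
    if len(nonamer) != 9:
        raise ValueError("nonamer must have length 9")
    return [i for i, aa in enumerate(nonamer) if aa in anchor_set]


def _anchor_order(anchors: list[int]) -> list[int]:
    # tie-break: closest to the nonamer center, then leftmost
    return sorted(anchors, key=lambda i: (abs(i - 4), i))


def _class_codes(
    nonamer: str, offset: int, scheme: ClassScheme, mode: str
) -> np.ndarray:
    """Per-column class index (−1 for gaps) of a peptide at an offset."""
    block = AlignedPeptideBlock([AlignedPeptide(nonamer, 1, offset)], mode=mode)
    cells = block.rows()[0]
    names = scheme.class_names
    return np.array(
        [names.index(scheme.class_of(c)) if c is not None else -1 for c in cells],
        dtype=np.int64,
    )


def alignment_objective(
    block: AlignedPeptideBlock,
    scheme: ClassScheme = DEFAULT_CLASS_SCHEME,
    weights: np.ndarray | None = None,
    *,
    weak_set: frozenset[str] = frozenset(),
    weak_penalty: float = 0.5,
) -> float:
    """Weighted same-class pair count of an aligned block.

    Every peptide copy is an item; a copy of a peptide anchored on a
    weak-tier residue carries weight ``weak_penalty`` instead of 1. For
    column ``j`` the score adds ``w_j`` times the summed weight products
    over all same-class item pairs (``C(n, 2)`` per class for unit
    weights, copy counts included). Higher means a more coherent block.
    """
    weights = default_column_weights() if weights is None else np.asarray(weights, float)
    n_classes = len(scheme.class_names)
    s = np.zeros((FRAME.width, n_classes))   # summed copy weights
    q = np.zeros((FRAME.width, n_classes))   # summed per-copy squared weights
    for p in block.peptides:
        u = weak_penalty if p.p1_residue in weak_set else 1.0
        codes = _class_codes(p.sequence, p.offset, scheme, block.mode)
        for j, c in enumerate(codes):
            if c >= 0:
                s[j, c] += p.count * u
                q[j, c] += p.count * u * u
    pairs = (s * s - q) / 2.0
    return float((weights[:, None] * pairs).sum())


class _SearchState:
    """Incremental column/class mass bookkeeping for the anchor search.

    An item is one peptide placed at one anchor: summed copy weight
    ``w = count * u`` and internal pair mass ``self_pairs = C(count,2)*u^2``
    per resolved column (``u`` is the weak-tier factor).
    """

    def __init__(self, n_classes: int, weights: np.ndarray) -> None:
        self.s = np.zeros((FRAME.width, n_classes))
        self.weights = weights
        self.objective = 0.0

    def gain(self, codes: np.ndarray, w: float, self_pairs: float) -> float:
        cols = codes >= 0
        return float(
            (self.weights[cols]
             * (w * self.s[cols, codes[cols]] + self_pairs)).sum()
        )

    def add(self, codes: np.ndarray, w: float, self_pairs: float) -> None:
        self.objective += self.gain(codes, w, self_pairs)
        cols = codes >= 0
        self.s[cols, codes[cols]] += w

    def remove(self, codes: np.ndarray, w: float, self_pairs: float) -> None:
        cols = codes >= 0
        self.s[cols, codes[cols]] -= w
        self.objective -= self.gain(codes, w, self_pairs)


def align_nonamers(
    peptides: Sequence[str | tuple[str, int]],
    params: AlignmentParams = AlignmentParams(),
    scheme: ClassScheme = DEFAULT_CLASS_SCHEME,
) -> AlignmentResult:
    """Place nonamers in the frame by choosing a P1 anchor per peptide.

    Returns the aligned block together with the attained objective and
    the list of discarded peptides. Deterministic for a fixed input
    order; ties between anchors prefer the one closest to the nonamer
    center, then the leftmost.
    """
    spec = params.specificity
    entries: list[tuple[str, int]] = []
    discarded: list[DiscardedPeptide] = []
    for item in peptides:
        seq, count = (item, 1) if isinstance(item, str) else (item[0], int(item[1]))
        if len(seq) != 9:
            discarded.append(DiscardedPeptide(seq, count, "wrong_length"))
            continue
        if not is_standard(seq):
            discarded.append(DiscardedPeptide(seq, count, "non_standard_residue"))
            continue
        if not candidate_anchors(seq, spec.anchor_set):
            discarded.append(DiscardedPeptide(seq, count, "no_anchor"))
            continue
        entries.append((seq, count))
    if not entries:
        raise ValueError("no peptide carries an admissible P1 anchor")

    n_classes = len(scheme.class_names)
    # candidate placements per peptide, in tie-break preference order
    cand: list[list[dict]] = []
    for seq, count in entries:
        options = []
        for a in _anchor_order(candidate_anchors(seq, spec.anchor_set)):
            offset = a - FRAME.p1_index
            u = params.weak_penalty if seq[a] in spec.weak else 1.0
            options.append(
                {
                    "anchor": a,
                    "offset": offset,
                    "w": count * u,
                    "self": count * (count - 1) / 2.0 * u * u,
                    "codes": _class_codes(seq, offset, scheme, params.fill_mode),
                }
            )
        cand.append(options)

    order = sorted(range(len(entries)), key=lambda i: (len(cand[i]), i))
    state = _SearchState(n_classes, params.weights)
    chosen: dict[int, int] = {}

    # greedy seeding: forced placements first, then best-gain anchors
    for i in order:
        best_k, best_gain = 0, -math.inf
        for k, opt in enumerate(cand[i]):
            g = state.gain(opt["codes"], opt["w"], opt["self"])
            if g > best_gain + 1e-12:
                best_k, best_gain = k, g
        picked = cand[i][best_k]
        chosen[i] = best_k
        state.add(picked["codes"], picked["w"], picked["self"])

    # coordinate ascent: re-place one peptide at a time
    for _ in range(params.max_iters):
        improved = False
        obj_before_pass = state.objective
        for i in order:
            if len(cand[i]) == 1:
                continue
            cur = cand[i][chosen[i]]
            state.remove(cur["codes"], cur["w"], cur["self"])
            best_k = chosen[i]
            best_gain = state.gain(cur["codes"], cur["w"], cur["self"])
            for k, opt in enumerate(cand[i]):
                g = state.gain(opt["codes"], opt["w"], opt["self"])
                if g > best_gain + 1e-9:
                    best_k, best_gain = k, g
            if best_k != chosen[i]:
                improved = True
                chosen[i] = best_k
            picked = cand[i][chosen[i]]
            state.add(picked["codes"], picked["w"], picked["self"])
        # ascent is monotone by construction; guard against regressions
        assert state.objective >= obj_before_pass - 1e-9
        if not improved:
            break

    # exact enumeration for small instances
    n_combos = math.prod(len(c) for c in cand)
    exact = n_combos <= params.exact_limit
    if exact and len(cand) > 1:
        best_combo, best_obj = None, state.objective
        for combo in itertools.product(*(range(len(c)) for c in cand)):
            st = _SearchState(n_classes, params.weights)
            for i, k in enumerate(combo):
                st.add(cand[i][k]["codes"], cand[i][k]["w"], cand[i][k]["self"])
            if st.objective > best_obj + 1e-9:
                best_combo, best_obj = combo, st.objective
        if best_combo is not None:
            chosen = dict(enumerate(best_combo))
            state = _SearchState(n_classes, params.weights)
            for i, k in chosen.items():
                state.add(cand[i][k]["codes"], cand[i][k]["w"], cand[i][k]["self"])

    aligned = [
        AlignedPeptide(entries[i][0], entries[i][1], cand[i][chosen[i]]["offset"])
        for i in range(len(entries))
    ]
    block = AlignedPeptideBlock(aligned, mode=params.fill_mode)
    return AlignmentResult(
        block=block, discarded=discarded, objective=state.objective, exact=exact
    )


# ---------------------------------------------------------------------------
# Consensus reporting
# ---------------------------------------------------------------------------


@dataclass
class ConsensusReport:
    """Duplicate-marked peptide listing plus per-column majority summary."""

    peptides: pd.DataFrame
    majority: pd.DataFrame

    def to_text(self) -> str:
        lines = ["# aligned peptides (count > 1 marks duplicates)"]
        lines.append(self.peptides.to_string(index=False))
        lines.append("")
        lines.append("# per-column majority (ties joined with '/')")
        lines.append(self.majority.to_string(index=False))
        return "\n".join(lines) + "\n"


def _majority(weighted: dict[str, float]) -> str:
    if not weighted:
        return "-"
    top = max(weighted.values())
    winners = sorted(k for k, v in weighted.items() if math.isclose(v, top))
    return "/".join(winners)


def consensus_report(
    block: AlignedPeptideBlock, scheme: ClassScheme = DEFAULT_CLASS_SCHEME
) -> ConsensusReport:
    """Summarize an aligned block: per-column majority residue and class.

    Majorities are copy-count weighted over resolved cells; exact ties
    are reported as ties (``"A/V"``), never broken arbitrarily.
    """
    if len(block) == 0:
        raise ValueError("cannot summarize an empty block")
    table = block.to_frame()
    res_rows, cls_rows = [], []
    for j, label in enumerate(block.frame.labels):
        res_w: dict[str, float] = {}
        cls_w: dict[str, float] = {}
        for p in block.peptides:
            aa = block.cell(p, j)
            if aa is None:
                continue
            res_w[aa] = res_w.get(aa, 0.0) + p.count
            c = scheme.class_of(aa)
            cls_w[c] = cls_w.get(c, 0.0) + p.count
        res_rows.append(_majority(res_w))
        cls_rows.append(_majority(cls_w))
    majority = pd.DataFrame(
        {
            "subsite": list(block.frame.labels),
            "majority_residue": res_rows,
            "majority_class": cls_rows,
        }
    )
    return ConsensusReport(peptides=table, majority=majority)
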