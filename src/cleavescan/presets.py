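"""Enzyme presets: primary specificities and simulation ground truths.

The three elastase-family enzymes the package models:

* **hNE** — human neutrophil elastase: broad elastase, cleaves after
  Val, Ile and (weakly) Ala at P1; disfavors aromatics at P1.
* **hPR3** — human proteinase 3: prefers Val, cleaves after Ala better
  than Ile (which it does not accept); tolerates aromatics and Thr.
* **xPR3** — *Xenopus tropicalis* PR3: Ala over Val, no Ile, no
  aromatics.

Each preset carries a :class:`~cleavescan.core.PrimarySpecificity`
(anchor tiers used for alignment and site prediction) and a ground-truth
position matrix used by the biopanning simulator. The hNE matrix puts
mass 0.55/0.25/0.10 on Val/Ile/Ala at P1, elevates Ser at P1′ and gives
every other subsite a mild aliphatic bias — the regime inferred from the
selection and substrate-panel behavior the method was developed on.
"""

from __future__ import annotations

import numpy as np

from .alphabet import AA_INDEX, N_RESIDUES
from .core import PositionMatrix, PrimarySpecificity

__all__ = [
    "HNE",
    "HPR3",
    "XPR3",
    "PRESETS",
    "get_preset",
    "truth_matrix",
]

HNE = PrimarySpecificity(
    name="hNE",
    strong=frozenset("VI"),
    weak=frozenset("A"),
    notes="broad elastase; Val/Ile strong, Ala tolerated, no aromatics at P1",
)

HPR3 = PrimarySpecificity(
    name="hPR3",
    strong=frozenset("V"),
    weak=frozenset("AFYWT"),
    notes="Val preferred, Ala over Ile (Ile not accepted); "
    "tolerates aromatics and Thr at P1; ~40x less active than hNE",
)

XPR3 = PrimarySpecificity(
    name="xPR3",
    strong=frozenset("A"),
    weak=frozenset("V"),
    notes="Ala over Val, no Ile, no aromatics at P1; "
    "slightly more restricted than hPR3",
)

PRESETS: dict[str, PrimarySpecificity] = {"hNE": HNE, "hPR3": HPR3, "xPR3": XPR3}


def get_preset(name: str) -> PrimarySpecificity:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown enzyme preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None


def _column(assignments: dict[str, float]) -> np.ndarray:
    """A frequency 20-vector with named residues fixed, remainder uniform."""
    col = np.zeros(N_RESIDUES)
    for aa, f in assignments.items():
        col[AA_INDEX[aa]] = f
    rest = 1.0 - col.sum()
    if rest < 0:
        raise ValueError("column assignments exceed 1")
    free = col == 0
    col[free] = rest / free.sum()
    return col


def _matrix(p1: dict[str, float], p1p: dict[str, float],
            flank: dict[str, float]) -> np.ndarray:
    freq = np.tile(_column(flank), (9, 1))
    freq[4] = _column(p1)
    freq[5] = _column(p1p)
    return freq


_MILD_ALIPHATIC_FLANK = {"V": 0.09, "L": 0.09, "I": 0.09, "A": 0.09}

_TRUTH_SPECS: dict[str, dict] = {
    # P1 mass: V 0.55, I 0.25, A 0.10; Ser-elevated P1'; mildly
    # aliphatic-biased flanks.
    "hNE": dict(
        p1={"V": 0.55, "I": 0.25, "A": 0.10},
        p1p={"S": 0.30},
        flank=_MILD_ALIPHATIC_FLANK,
    ),
    # Val > Ala, no Ile; aromatics and Thr tolerated at P1; aromatic
    # residues also admitted in the flanks.
    "hPR3": dict(
        p1={"V": 0.45, "A": 0.20, "T": 0.08, "F": 0.06, "Y": 0.05, "W": 0.03},
        p1p={"S": 0.25},
        flank={"V": 0.07, "L": 0.07, "I": 0.07, "A": 0.07,
               "F": 0.05, "Y": 0.05, "W": 0.03, "T": 0.05},
    ),
    # Ala > Val, no Ile, no aromatics.
    "xPR3": dict(
        p1={"A": 0.45, "V": 0.30},
        p1p={"S": 0.30},
        flank=_MILD_ALIPHATIC_FLANK,
    ),
}


def truth_matrix(enzyme: str = "hNE") -> PositionMatrix:
    """Ground-truth specificity matrix for the biopanning simulator."""
    if enzyme not in _TRUTH_SPECS:
        raise ValueError(
            f"no ground-truth matrix for {enzyme!r}; choose from "
            f"{sorted(_TRUTH_SPECS)}"
        )
    spec = _TRUTH_SPECS[enzyme]
    freq = _matrix(spec["p1"], spec["p1p"], spec["flank"])
    return PositionMatrix(freq, metadata={"enzyme": enzyme, "kind": "ground_truth"})
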