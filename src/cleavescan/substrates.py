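"""Tandem-thioredoxin reporter substrates and cleavage-site prediction.

The reporter is two *E. coli* thioredoxin (Trx) domains in tandem,
joined by a short cleavable linker and carrying a C-terminal His6 tag::

    M - Trx1 - GS - insert(6..9 aa) - VD - Trx2 - HHHHHH

``GS`` and ``VD`` are the residues encoded by the BamHI and SalI cloning
frames that flank the inserted test sequence. The intact protein runs at
~25 kDa; a single cut in the linker yields two fragments of roughly
12–13 kDa, so a gel directly reads out whether — and where — an enzyme
cleaved.

Site prediction scores every 9-residue window whose P1 lies in the
insert against a specificity matrix, restricted to P1 residues the
enzyme accepts. The folded Trx domains are masked (they resist cleavage
under native conditions); when no insert site passes the threshold the
Val encoded by the SalI frame is evaluated as the fallback site — the
cleavage pattern observed for poor inserts. An ``sds_mode`` lifts the
accessibility mask to emulate detergent-opened domains.

Masses are average isotopic (gel scale), via Biopython. The exact
vector-derived residues beyond Met/GS/VD/His6 are not modeled; absolute
masses carry a ±1 kDa tolerance.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.SeqUtils import molecular_weight

from .alphabet import check_sequence
from .core import PositionMatrix, PrimarySpecificity, score_window

__all__ = [
    "TRX_SEQUENCE",
    "TrxConstruct",
    "CleavageSite",
    "CleavagePrediction",
    "build_construct",
    "peptide_mass",
    "construct_mass",
    "fragment_masses",
    "predict_cleavage",
    "load_panel",
]

# Canonical mature E. coli thioredoxin A (108 aa).
TRX_SEQUENCE = (
    "SDKIIHLTDDSFDTDVLKADGAILVDFWAEWCGPCKMIAPILDEIADEYQGKLTVAKLN"
    "IDQNPGTAPKYGIRGIPTLLLFKNGEVAATKVGALSKGQLKEFLDANLA"
)

BAMHI_FRAME = "GS"
SALI_FRAME = "VD"
HIS_TAG = "HHHHHH"

WATER_KDA = 0.018  # one water added per hydrolyzed bond


@dataclass(frozen=True)
class TrxConstruct:
    """A 2×Trx reporter with a specific insert (0-based coordinates)."""

    insert: str
    sequence: str
    linker_start: int   # index of the BamHI 'G'
    insert_start: int
    linker_end: int     # one past the SalI 'D'
    sal_val_index: int  # index of the SalI-encoded Val

    def __post_init__(self) -> None:
        if self.sequence[self.sal_val_index] != "V":
            raise ValueError("SalI coordinate does not point at a Val")

    @property
    def insert_end(self) -> int:
        return self.insert_start + len(self.insert)


def build_construct(insert: str) -> TrxConstruct:
    """Assemble the reporter for a 6–9 residue insert."""
    check_sequence(insert)
    if not 6 <= len(insert) <= 9:
        raise ValueError(
            f"insert must have 6-9 residues, got {len(insert)} ({insert!r})"
        )
    pre = "M" + TRX_SEQUENCE
    seq = pre + BAMHI_FRAME + insert + SALI_FRAME + TRX_SEQUENCE + HIS_TAG
    linker_start = len(pre)
    insert_start = linker_start + len(BAMHI_FRAME)
    sal_val_index = insert_start + len(insert)
    linker_end = sal_val_index + len(SALI_FRAME)
    return TrxConstruct(
        insert=insert,
        sequence=seq,
        linker_start=linker_start,
        insert_start=insert_start,
        linker_end=linker_end,
        sal_val_index=sal_val_index,
    )


def peptide_mass(seq: str) -> float:
    """Average-isotopic mass of a peptide chain in Da (one water included)."""
    check_sequence(seq)
    return float(molecular_weight(seq, seq_type="protein", monoisotopic=False))


def construct_mass(c: TrxConstruct) -> float:
    """Intact reporter mass in kDa."""
    return peptide_mass(c.sequence) / 1000.0


def fragment_masses(c: TrxConstruct, p1: int) -> tuple[float, float]:
    """Masses (kDa) of the two chains from hydrolysis after residue ``p1``.

    The N fragment is ``sequence[:p1+1]``, the C fragment the rest; the
    two masses sum to the construct mass plus one water (0.018 kDa).
    """
    if not 0 <= p1 < len(c.sequence) - 1:
        raise ValueError(f"cleavage coordinate {p1} out of range")
    n_frag = c.sequence[: p1 + 1]
    c_frag = c.sequence[p1 + 1:]
    return peptide_mass(n_frag) / 1000.0, peptide_mass(c_frag) / 1000.0


@dataclass(frozen=True)
class CleavageSite:
    p1: int            # 0-based coordinate; cleavage after this residue
    residue: str
    score: float       # bits (weak-tier penalty already applied)
    kind: str          # "insert" | "sal_fallback" | "trx"
    fragments_kda: tuple[float, float]


@dataclass
class CleavagePrediction:
    construct: TrxConstruct
    threshold: float
    sites: list[CleavageSite]

    @property
    def top_site(self) -> CleavageSite | None:
        return self.sites[0] if self.sites else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "p1": s.p1,
                    "residue": s.residue,
                    "score_bits": s.score,
                    "kind": s.kind,
                    "fragment_n_kda": s.fragments_kda[0],
                    "fragment_c_kda": s.fragments_kda[1],
                }
                for s in self.sites
            ],
            columns=["p1", "residue", "score_bits", "kind",
                     "fragment_n_kda", "fragment_c_kda"],
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "insert": self.construct.insert,
                "threshold_bits": self.threshold,
                "sites": self.to_frame().to_dict(orient="records"),
            },
            indent=1,
        )


def _site(c: TrxConstruct, m: PositionMatrix, p1: int, kind: str,
          penalty: float) -> CleavageSite:
    window = c.sequence[p1 - 4: p1 + 5]
    score = score_window(m, window) - penalty
    return CleavageSite(
        p1=p1,
        residue=c.sequence[p1],
        score=score,
        kind=kind,
        fragments_kda=fragment_masses(c, p1),
    )


def predict_cleavage(
    c: TrxConstruct,
    m: PositionMatrix,
    anchors: PrimarySpecificity | None = None,
    threshold: float = 0.0,
    *,
    weak_penalty_bits: float = 3.0,
    include_sal: bool = True,
    sds_mode: bool = False,
) -> CleavagePrediction:
    """Rank candidate cleavage sites of a reporter under a specificity matrix.

    Insert positions whose residue the enzyme accepts at P1 are scored
    (weak-tier residues are penalized by ``weak_penalty_bits``, default
    3 bits — enough that a weak-tier site loses to a strong-tier site
    elsewhere in the linker, reproducing the observed redirection of
    cleavage away from Ala); sites at or above ``threshold`` are
    reported ranked by score. If no insert
    site passes, the SalI-frame Val is evaluated and reported as
    ``sal_fallback`` when it passes (set ``include_sal=False`` to mask
    it). ``sds_mode`` additionally scores accepted P1 residues inside
    the otherwise-masked Trx domains (kind ``"trx"``).
    """

    def accepted(aa: str) -> bool:
        return anchors is None or aa in anchors.anchor_set

    def penalty(aa: str) -> float:
        return weak_penalty_bits if anchors is not None and aa in anchors.weak else 0.0

    sites: list[CleavageSite] = []
    for p1 in range(c.insert_start, c.insert_end):
        aa = c.sequence[p1]
        if accepted(aa):
            site = _site(c, m, p1, "insert", penalty(aa))
            if site.score >= threshold:
                sites.append(site)

    if not sites and include_sal and accepted("V"):
        sal = _site(c, m, c.sal_val_index, "sal_fallback", penalty("V"))
        if sal.score >= threshold:
            sites.append(sal)

    if sds_mode:
        for p1 in range(4, len(c.sequence) - 5):
            if c.linker_start <= p1 < c.linker_end:
                continue
            aa = c.sequence[p1]
            if accepted(aa):
                site = _site(c, m, p1, "trx", penalty(aa))
                if site.score >= threshold:
                    sites.append(site)

    sites.sort(key=lambda s: (-s.score, s.p1))
    return CleavagePrediction(construct=c, threshold=threshold, sites=sites)


def load_panel() -> pd.DataFrame:
    """The printed reporter-substrate panel (TSV bundled with the package).

    Rows flagged ``inferred=yes`` reconstruct short figure names (VV,
    VS, ...) on the Arg-Gly-Gly scaffold; their exact flanks were not
    printed.
    """
    ref = importlib.resources.files("cleavescan.data") / "substrate_panel.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
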