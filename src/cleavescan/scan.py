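"""Sliding-window cleavage-site scanning of protein sequences.

Applies an inferred specificity matrix to arbitrary protein sequences to
rank candidate cleavage sites — the screening application the profiling
method exists for. Every 9-residue window is scored by its additive
log-odds (bits) with the window's fifth residue as P1; hits at or above
a threshold are reported ranked by score.

Coordinates are 1-based P1 residue indices with cleavage between P1 and
P1+1, the protease-literature convention. Scores are sequence-only: no
structural-accessibility correction is applied, and folded proteins may
resist cleavage at high-scoring sites.

Windows containing non-standard residues are skipped (with a logged
count) rather than rejected, since real proteome FASTA records contain
X/B/Z placeholders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import AA_INDEX, N_RESIDUES, is_standard
from .core import FRAME, PositionMatrix

__all__ = [
    "ScanHit",
    "scan_sequence",
    "scan_fasta",
    "default_threshold",
]

logger = logging.getLogger(__name__)

WINDOW = FRAME.width  # 9
P1_OFFSET = FRAME.p1_index  # 4


@dataclass(frozen=True)
class ScanHit:
    """One candidate cleavage site in a scanned protein."""

    protein_id: str
    p1_pos: int      # 1-based; cleavage after this residue
    window: str      # P5..P4'
    score: float     # bits
    rank: int


def scan_sequence(
    protein: str,
    m: PositionMatrix,
    threshold: float = 0.0,
    mode: str = "full",
    *,
    protein_id: str = "seq",
) -> tuple[list[ScanHit], int]:
    """Score every full 9-window of ``protein``; return (hits, n_skipped).

    Hits with score >= ``threshold`` are sorted by score descending,
    then position ascending, and ranked from 1. Windows containing
    non-standard residues are skipped and counted. A protein shorter
    than 9 residues yields no hits (a warning is logged).
    """
    if mode != "full":
        raise ValueError(f"unknown scan mode {mode!r}")
    protein = protein.upper()
    n = len(protein)
    if n < WINDOW:
        if n:
            logger.warning(
                "%s: length %d < window size %d; no windows scored",
                protein_id, n, WINDOW,
            )
        return [], 0

    skipped = 0
    scored: list[tuple[int, str, float]] = []
    lo = m.logodds
    for start in range(n - WINDOW + 1):
        window = protein[start: start + WINDOW]
        if not is_standard(window):
            skipped += 1
            continue
        score = float(sum(lo[j, AA_INDEX[aa]] for j, aa in enumerate(window)))
        if score >= threshold:
            p1_pos = start + P1_OFFSET + 1  # 1-based
            scored.append((p1_pos, window, score))
    if skipped:
        logger.info("%s: skipped %d windows with non-standard residues",
                    protein_id, skipped)

    scored.sort(key=lambda t: (-t[2], t[0]))
    hits = [
        ScanHit(protein_id=protein_id, p1_pos=pos, window=win, score=s, rank=r)
        for r, (pos, win, s) in enumerate(scored, start=1)
    ]
    return hits, skipped


def scan_fasta(
    path: str | Path,
    m: PositionMatrix,
    threshold: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Scan every record of a FASTA file.

    Returns a hits table (protein_id, p1_pos, window, score, rank; ranks
    are per record) and a summary dict with records processed, windows
    scored and windows skipped. Duplicate record ids are rejected.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate record ids {dupes}")

    rows = []
    windows_scored = 0
    windows_skipped = 0
    for rec in records:
        seq = str(rec.seq)
        hits, skipped = scan_sequence(seq, m, threshold, protein_id=rec.id)
        windows_skipped += skipped
        n_windows = max(len(seq) - WINDOW + 1, 0)
        windows_scored += n_windows - skipped
        rows.extend(
            {
                "protein_id": h.protein_id,
                "p1_pos": h.p1_pos,
                "window": h.window,
                "score": h.score,
                "rank": h.rank,
            }
            for h in hits
        )
    hits_df = pd.DataFrame(
        rows, columns=["protein_id", "p1_pos", "window", "score", "rank"]
    )
    summary = {
        "records": len(records),
        "windows_scored": int(windows_scored),
        "windows_skipped": int(windows_skipped),
        "hits": len(hits_df),
        "threshold": float(threshold),
    }
    return hits_df, summary


def default_threshold(
    m: PositionMatrix,
    *,
    quantile: float = 0.999,
    n_samples: int = 100_000,
    seed: int = 0,
) -> float:
    """Score threshold at a background quantile (default 99.9th percentile).

    Random 9-windows are drawn from the matrix's background composition
    and scored; the returned threshold admits roughly the top
    ``1 - quantile`` fraction of background windows.
    """
    rng = np.random.default_rng(seed)
    draws = rng.choice(N_RESIDUES, size=(n_samples, WINDOW), p=m.background)
    lo = m.logodds
    scores = np.zeros(n_samples)
    for j in range(WINDOW):
        scores += lo[j, draws[:, j]]
    return float(np.quantile(scores, quantile))
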