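"""Report/export helpers: logo data, provenance blocks, peptide IO."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__
from .alphabet import AMINO_ACIDS
from .core import (
    DEFAULT_CLASS_SCHEME,
    ClassScheme,
    PositionMatrix,
    information_content,
)

__all__ = [
    "export_logo_data",
    "provenance",
    "read_peptides",
    "write_peptides_fasta",
]


def export_logo_data(
    m: PositionMatrix, scheme: ClassScheme = DEFAULT_CLASS_SCHEME
) -> pd.DataFrame:
    """Per-column stacked residue heights for a sequence logo.

    Height of residue ``a`` in column ``j`` is ``freq[j][a] * IC_j``
    (bits), so the stacked heights of a column sum to its information
    content. Residues are annotated with their class so any renderer can
    color by side-chain character.
    """
    ic = information_content(m)
    rows = []
    for j, label in enumerate(m.frame.labels):
        for k, aa in enumerate(AMINO_ACIDS):
            rows.append(
                {
                    "subsite": label,
                    "residue": aa,
                    "class": scheme.class_of(aa),
                    "height_bits": m.freq[j, k] * ic[j],
                }
            )
    return pd.DataFrame(rows)


def provenance(config: dict, seed: int | None = None) -> dict:
    """A provenance block to embed in every output artifact."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    block = {
        "tool": "cleavescan",
        "version": __version__,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
    }
    if seed is not None:
        block["seed"] = int(seed)
    return block


def read_peptides(path: str | Path) -> list[tuple[str, int]]:
    """Read (sequence, count) pairs from FASTA or TSV.

    FASTA headers may carry a duplicate count as ``count=N`` in the
    description (default 1). TSV needs columns ``sequence`` and,
    optionally, ``count``.
    """
    path = Path(path)
    if path.suffix.lower() in (".fa", ".fasta", ".faa"):
        out = []
        for rec in SeqIO.parse(str(path), "fasta"):
            count = 1
            for token in rec.description.split():
                if token.startswith("count="):
                    count = int(token.split("=", 1)[1])
            out.append((str(rec.seq), count))
        return out
    df = pd.read_csv(path, sep="\t")
    if "sequence" not in df.columns:
        raise ValueError(f"{path}: expected a 'sequence' column")
    counts = df["count"] if "count" in df.columns else [1] * len(df)
    return [(str(s), int(c)) for s, c in zip(df["sequence"], counts)]


def write_peptides_fasta(
    peptides: list[tuple[str, int]], path: str | Path
) -> None:
    lines = []
    for i, (seq, count) in enumerate(peptides, start=1):
        lines.append(f">clone_{i} count={count}")
        lines.append(seq)
    Path(path).write_text("\n".join(lines) + "\n")
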