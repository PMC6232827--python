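"""Stochastic simulator of substrate phage-display biopanning.

The simulated experiment mirrors the selection that the inference stages
are designed to analyze: a library of unique nonamer peptides displayed
on the phage capsid as ``PGG(X)9HHHHHH``, immobilized on a Ni-NTA matrix
via the C-terminal His6 tag. An enzyme releases a phage by cleaving
inside the randomized nonamer; released phages are amplified and carried
into the next round. Five rounds of selection against a no-enzyme
control yield per-round enrichment factors, and clones picked from the
final pool give the sequenced peptide sample handed to the alignment
stage.

Release model
-------------
A clone's release probability combines a background leak ``p_bg``
(non-specific loss from the matrix; washes are absorbed here) with a
specificity-driven term that saturates in the clone's best window score
``s_max`` (the maximal position-matrix log-odds over all fully displayed
9-windows whose P1 lies inside the randomized nonamer)::

    p = p_bg + (1 - p_bg) * (1 - exp(-beta * dose * softplus(s_max - s0)))

``beta`` is the effect-size slope (scaled by the relative enzyme
``dose``) and ``s0`` the score offset where susceptibility turns on.
The link is monotone and bounded in [p_bg, 1); at ``beta = 0`` (or for
hopeless substrates, ``s_max → −∞``) it reduces exactly to the
background leak, so a no-specificity enzyme enriches nothing relative
to the control.

Default sizes are desk-scale (``N0 = B = 1e5``) stand-ins for the
experimental library of ~5 × 10⁷ unique clones and ~10⁸–10⁹ bound pfu
per round; the full-scale values can be requested through
:class:`PanningParams`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np

from .alphabet import AMINO_ACIDS, N_RESIDUES, decode, encode
from .core import PositionMatrix
from .presets import truth_matrix

__all__ = [
    "PhageClone",
    "PhagePool",
    "GroundTruthModel",
    "PanningParams",
    "BiopanningResult",
    "SelectionCollapseError",
    "generate_library",
    "max_window_scores",
    "release_probability",
    "simulate_round",
    "amplify",
    "run_biopanning",
    "default_ground_truth",
]

CONTEXT_PREFIX = "PGG"
CONTEXT_SUFFIX = "HHHHHH"

# Fully displayed 9-windows of the 18-mer PGG(X)9HHHHHH whose P1 (window
# position 5) falls inside the randomized nonamer: window starts 0..7.
_WINDOW_STARTS = range(8)


class SelectionCollapseError(RuntimeError):
    """No phages were released in a selection round; the panning cannot continue."""


@dataclass(frozen=True)
class PhageClone:
    """A single clone: randomized nonamer plus its displayed context."""

    nonamer: str
    abundance: int = 1

    def __post_init__(self) -> None:
        if len(self.nonamer) != 9:
            raise ValueError("nonamer must have length 9")
        encode(self.nonamer)
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")

    @property
    def extended(self) -> str:
        return CONTEXT_PREFIX + self.nonamer + CONTEXT_SUFFIX


@dataclass
class PhagePool:
    """An abundance-weighted set of clones at one biopanning round.

    ``sequences`` is an (n_clones, 9) int8 array of alphabet codes;
    ``abundances`` the matching clone counts.
    """

    sequences: np.ndarray
    abundances: np.ndarray
    round_index: int = 0

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=np.int8)
        self.abundances = np.asarray(self.abundances, dtype=np.int64)
        if self.sequences.ndim != 2 or self.sequences.shape[1] != 9:
            raise ValueError("sequences must be an (n, 9) code array")
        if self.abundances.shape != (self.sequences.shape[0],):
            raise ValueError("abundances must match sequences")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be >= 0")

    @property
    def n_clones(self) -> int:
        return self.sequences.shape[0]

    @property
    def total(self) -> int:
        return int(self.abundances.sum())

    def clones(self) -> Iterator[PhageClone]:
        for row, ab in zip(self.sequences, self.abundances):
            yield PhageClone(decode(row), int(ab))

    def nonamers(self) -> list[str]:
        return [decode(row) for row in self.sequences]

    def compact(self) -> "PhagePool":
        """Drop zero-abundance clones."""
        keep = self.abundances > 0
        return PhagePool(self.sequences[keep], self.abundances[keep],
                         self.round_index)

    @classmethod
    def from_clones(cls, clones: list[PhageClone], round_index: int = 0) -> "PhagePool":
        seqs = np.stack([encode(c.nonamer) for c in clones])
        ab = np.array([c.abundance for c in clones], dtype=np.int64)
        return cls(seqs, ab, round_index)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "sequence": self.nonamers(),
                "abundance": self.abundances,
                "round": self.round_index,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GroundTruthModel:
    """The true specificity and release parameters driving a simulation."""

    pwm: PositionMatrix
    p_bg: float = 1e-3
    beta: float = 0.1
    s0: float = 4.0
    dose: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_bg < 1:
            raise ValueError("p_bg must be in [0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


@dataclass(frozen=True)
class PanningParams:
    """Experiment sizes for a biopanning run.

    Scaled defaults keep desk runtimes; the experimental scale is
    ``library_complexity=5e7`` with ~1e8–1e9 bound pfu per round.
    """

    library_complexity: int = 100_000
    bound_per_round: int = 100_000
    rounds: int = 5
    wash_count: int = 10
    clones_picked: int = 120
    clones_sequenced: int = 96
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("library_complexity", "bound_per_round", "rounds",
                     "wash_count", "clones_picked", "clones_sequenced"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.clones_sequenced > self.clones_picked:
            raise ValueError("clones_sequenced cannot exceed clones_picked")


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------


def generate_library(
    n0: int,
    residue_distribution: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> PhagePool:
    """Draw ``n0`` i.i.d. random nonamers and merge duplicates.

    Residues are drawn independently per position from
    ``residue_distribution`` (default uniform over the 20 standard
    residues). Duplicate nonamers are merged with summed abundance.
    """
    if n0 < 1:
        raise ValueError("library complexity must be >= 1")
    if residue_distribution is None:
        p = np.full(N_RESIDUES, 1.0 / N_RESIDUES)
    else:
        p = np.asarray(residue_distribution, dtype=float)
        if p.shape != (N_RESIDUES,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("residue distribution must be a 20-vector summing to 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    draws = rng.choice(N_RESIDUES, size=(n0, 9), p=p).astype(np.int8)
    uniq, counts = np.unique(draws, axis=0, return_counts=True)
    return PhagePool(uniq, counts.astype(np.int64), round_index=0)


# ---------------------------------------------------------------------------
# Release model
# ---------------------------------------------------------------------------


def _extended_codes(pool: PhagePool) -> np.ndarray:
    n = pool.n_clones
    prefix = np.tile(encode(CONTEXT_PREFIX), (n, 1))
    suffix = np.tile(encode(CONTEXT_SUFFIX), (n, 1))
    return np.hstack([prefix, pool.sequences, suffix])


def max_window_scores(pool: PhagePool, pwm: PositionMatrix) -> np.ndarray:
    """Best log-odds score per clone over displayed windows with P1 in the nonamer."""
    ext = _extended_codes(pool)
    lo = pwm.logodds
    best = np.full(pool.n_clones, -np.inf)
    for s in _WINDOW_STARTS:
        scores = np.zeros(pool.n_clones)
        for j in range(9):
            scores += lo[j, ext[:, s + j]]
        np.maximum(best, scores, out=best)
    return best


def _softplus(x: np.ndarray | float) -> np.ndarray | float:
    return np.logaddexp(0.0, x)


def release_probabilities(pool: PhagePool, truth: GroundTruthModel) -> np.ndarray:
    """Vectorized per-clone release probability under the truth model."""
    s_max = max_window_scores(pool, truth.pwm)
    drive = truth.beta * truth.dose * _softplus(s_max - truth.s0)
    return truth.p_bg + (1.0 - truth.p_bg) * (1.0 - np.exp(-drive))


def release_probability(clone: PhageClone, truth: GroundTruthModel) -> float:
    """Release probability of a single clone (see module docstring)."""
    pool = PhagePool.from_clones([clone])
    return float(release_probabilities(pool, truth)[0])


# ---------------------------------------------------------------------------
# Selection rounds
# ---------------------------------------------------------------------------


def simulate_round(
    pool: PhagePool,
    truth: GroundTruthModel,
    params: PanningParams,
    control: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[PhagePool, int]:
    """One binding/release step.

    ``min(B, total)`` phages are bound: all of them when the matrix
    capacity ``B`` covers the pool, otherwise a without-replacement draw
    on clone abundances (so ``bound_i <= abundance_i`` always). Each
    bound phage is released independently with its clone's release
    probability (just the background leak ``p_bg`` for the no-enzyme
    control). Returns the released pool (same round index) and the
    released count.
    """
    if pool.total == 0:
        raise ValueError("cannot pan an empty pool")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    if pool.total <= params.bound_per_round:
        bound = pool.abundances.copy()
    else:
        bound = rng.multivariate_hypergeometric(
            pool.abundances, params.bound_per_round, method="marginals"
        )
    if control:
        p = np.full(pool.n_clones, truth.p_bg)
    else:
        p = release_probabilities(pool, truth)
    released = rng.binomial(bound, p)
    released_pool = PhagePool(pool.sequences, released.astype(np.int64),
                              pool.round_index).compact()
    return released_pool, int(released.sum())


def amplify(
    pool: PhagePool, size: int, rng: np.random.Generator
) -> PhagePool:
    """Unbiased amplification: multinomial resampling of clones up to ``size``."""
    if pool.total == 0:
        raise SelectionCollapseError(
            f"no phages to amplify after round {pool.round_index}"
        )
    frac = pool.abundances / pool.total
    grown = rng.multinomial(size, frac)
    return PhagePool(pool.sequences, grown.astype(np.int64),
                     pool.round_index + 1).compact()


@dataclass
class BiopanningResult:
    """Everything a biopanning run produced, ground truth included."""

    pools: list[PhagePool]
    enrichment: list[float]
    released_protease: list[int]
    released_control: list[int]
    sequenced_sample: list[tuple[str, int]]
    truth: GroundTruthModel
    params: PanningParams

    @property
    def final_pool(self) -> PhagePool:
        return self.pools[-1]

    def sample_fasta(self, path: str | Path) -> None:
        """Sequenced clones as FASTA, duplicate count in the header."""
        lines = []
        for i, (seq, count) in enumerate(self.sequenced_sample, start=1):
            lines.append(f">clone_{i} count={count}")
            lines.append(seq)
        Path(path).write_text("\n".join(lines) + "\n")


def run_biopanning(
    params: PanningParams,
    truth: GroundTruthModel,
) -> BiopanningResult:
    """Run the full selection: R rounds of panning against a no-enzyme control.

    Per round, the current pool is panned twice from the same input: once
    with the enzyme and once as the background-leak control; the
    enrichment factor is their released-count ratio (reported as ``inf``
    with a warning if the control released nothing). The enzyme-released
    pool is amplified back to the per-round bound size to seed the next
    round. After the last round ``clones_picked`` phages are drawn by
    abundance and the first ``clones_sequenced`` reported with duplicate
    counts.
    """
    rng = np.random.default_rng(params.seed)
    pool = generate_library(params.library_complexity, seed=rng)
    pools = [pool]
    enrichment: list[float] = []
    rel_p: list[int] = []
    rel_c: list[int] = []
    for _ in range(params.rounds):
        released, n_p = simulate_round(pool, truth, params, control=False, rng=rng)
        _, n_c = simulate_round(pool, truth, params, control=True, rng=rng)
        rel_p.append(n_p)
        rel_c.append(n_c)
        if n_c == 0:
            warnings.warn(
                f"round {pool.round_index + 1}: control released no phages; "
                "enrichment undefined (reported as inf)",
                stacklevel=2,
            )
            enrichment.append(float("inf"))
        else:
            enrichment.append(n_p / n_c)
        if n_p == 0:
            raise SelectionCollapseError(
                f"round {pool.round_index + 1}: protease released no phages"
            )
        pool = amplify(released, params.bound_per_round, rng)
        pools.append(pool)

    final = pools[-1]
    picks = rng.choice(
        final.n_clones, size=params.clones_picked,
        p=final.abundances / final.total,
    )
    sequenced = picks[: params.clones_sequenced]
    order: dict[str, int] = {}
    for idx in sequenced:
        seq = decode(final.sequences[idx])
        order[seq] = order.get(seq, 0) + 1
    sample = list(order.items())
    return BiopanningResult(
        pools=pools,
        enrichment=enrichment,
        released_protease=rel_p,
        released_control=rel_c,
        sequenced_sample=sample,
        truth=truth,
        params=params,
    )


def default_ground_truth(enzyme: str = "hNE", dose: float = 1.0) -> GroundTruthModel:
    """The preset ground truth for an enzyme at a relative dose."""
    return GroundTruthModel(pwm=truth_matrix(enzyme), dose=dose)
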