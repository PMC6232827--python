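# Methods

`cleavescan` models the determination of a serine protease's *extended*
cleavage specificity by substrate phage display, and the two downstream
uses of that specificity: designing recombinant reporter substrates and
scanning protein sequences for candidate cleavage sites. This note
records the models, the parameters that matter, and the design choices
made where the procedure left them open.

## Coordinate system and residue classes

All profiles live in the Schechter–Berger frame P5…P1 | P1′…P4′: nine
substrate positions counted outward from the scissile bond, which lies
between P1 and P1′. The frame is fixed at width 9; wider frames are
rejected rather than truncated.

Residues are grouped into six side-chain classes: aromatic (F, Y, W),
negatively charged (D, E), positively charged (K, R), small aliphatic
(G, A), larger aliphatic (V, L, I, P) and hydrophilic (S, T, H, N, Q, C,
M). The partition is validated (20 residues, each in exactly one class)
and shipped as JSON. Non-standard residues (B, Z, X, U, `*`) are hard
errors in matrix construction and alignment, but scanned proteins merely
have the affected windows skipped, since proteome FASTA files routinely
contain placeholders.

## Position matrices

A profile is a 9 × 20 position frequency matrix. From an aligned peptide
block with copy counts, column `j` is estimated with a pseudocount
`α` against a background composition `b`:

    freq[j][a] = (count_j(a) + α·b[a]) / (N_j + α)

Defaults are `α = 1` with a uniform background (1/20). The pseudocount
avoids −∞ log-odds for residues unobserved among ~100 sequenced clones;
the background is configurable (e.g. a proteome composition for
scanning). Scoring is additive log-odds in bits,
`score(w) = Σ_j log2(freq[j][w_j] / b[w_j])`, and per-column information
content is `log2(20) + Σ_a f log2 f ∈ [0, log2 20]`. Logo export writes
heights `freq × IC` per column, so stacked heights sum to the column's
information content.

## The biopanning simulator

The generator emulates the selection experiment end to end so that the
inference stages can be tested against a known truth:

* a library of unique random nonamers displayed as `PGG(X)9HHHHHH` and
  immobilized via the C-terminal His6 tag (scaled default complexity
  `N0 = 1e5`, standing in for the experimental ~5 × 10⁷; the full scale
  is available by configuration),
* five rounds of selection, each binding `min(B, pool)` phages
  (without replacement, so per-clone bound ≤ abundance), releasing each
  bound phage independently, amplifying the released clones back to `B`
  by multinomial resampling, and
* a parallel no-enzyme control per round whose release probability is
  only the background leak `p_bg`; the enrichment factor is the
  released-count ratio of the two arms. After the last round 120 clones
  are picked by abundance and the first 96 reported with duplicate
  counts — the sequenced sample.

A clone's release probability combines the background leak with a
saturating, score-driven term:

    p = p_bg + (1 − p_bg) · (1 − exp(−β · dose · softplus(s_max − s0)))

where `s_max` is the clone's best log-odds window score over the eight
fully displayed 9-windows whose P1 lies inside the randomized nonamer
(cleavage in the constant regions would release every clone equally and
is absorbed into `p_bg`). The link is monotone and bounded in
`[p_bg, 1)`; at `β = 0`, or for hopeless substrates (`s_max → −∞`), it
reduces exactly to the background leak, so a specificity-free enzyme
shows enrichment ≈ 1 against the control — the model's null
calibration.

Parameter defaults and why:

| parameter | default | meaning |
|---|---|---|
| `p_bg` | 1e-3 | per-round background release (washes absorbed here) |
| `β` | 0.1 | effect-size slope, scaled by relative enzyme `dose` |
| `s0` | 4.0 bits | score offset where susceptibility turns on |
| `N0`, `B` | 1e5 | scaled library complexity and binding capacity |

Under the hNE-like truth matrix, best-window scores of random clones
center near 0 bits while the library's upper tail reaches ~7–9 bits;
`β` and `s0` were fixed, by forward simulation at design time, in the
regime the experiment reports: selection still enriching at round five
and a final-round release enhancement of order 10² over the control
(the reported values for the two human enzymes were 71× and 106×).
Note that with `B = N0` the per-round control releases only ~100
phages, so late-round enrichment ratios carry ~10% noise; calibration
experiments that probe round-over-round monotonicity use a binding
capacity of 4×`N0`, a scaled version of the experimental ~20×
pfu-to-complexity oversampling.

Ground-truth matrices are provided per enzyme. The hNE truth puts
P1 mass 0.55/0.25/0.10 on Val/Ile/Ala, elevates Ser to 0.30 at P1′, and
gives every other column a mild aliphatic bias (V, L, I, A at 0.09
each); hPR3 admits aromatics and Thr at P1 (no Ile), and xPR3 prefers
Ala over Val with neither Ile nor aromatics.

What the generator does **not** model: phage growth-rate differences
between clones (amplification is unbiased), per-wash losses, enzyme
self-cleavage or inactivation over rounds, and sequencing errors.
Passing recovery tests therefore show that the inference is consistent
with this idealized selection — not that it is robust to amplification
bias or noisy reads.

## Anchored consensus alignment

Selected nonamers do not reveal the cut position; the alignment layer
reconstructs it. Each peptide may be placed only with an allowed P1
residue (the enzyme's primary specificity: strong tier {V, I} and weak
tier {A} for hNE). Among admissible placements the method maximizes a
coherence objective: per frame column, the weighted number of same-class
peptide-copy pairs, with the P1-proximal columns (P2–P2′) up-weighted
2× and copies anchored on weak-tier residues down-weighted by 0.5. This
formalizes the manual procedure of fixing unambiguous peptides first and
fitting multi-anchor peptides to the emerging pattern: peptides are
seeded in order of ascending anchor count, added greedily, refined by
coordinate ascent (provably non-decreasing per pass), and finished with
exact enumeration whenever the total number of anchor combinations is
small (≤ 20 000), so small instances are solved to optimality.
Tie-breaks prefer the anchor closest to the nonamer center, then the
leftmost — centering the informative flanks in the frame. Peptides with
no admissible anchor, non-standard residues, or the wrong length are
reported in a discard table, never silently dropped.

Frame cells outside the nonamer are left empty by default (gap-mask
mode). Context fill from the displayed `PGG`/`HHHHHH` is supported but
not the default: the constant residues are shared by every clone, so
they register as spurious class agreement that drags anchors toward the
nonamer edges, and the His tag floods the primed columns of the
resulting matrix. In design-stage simulations the masked alignment
recovered the generating truth at Pearson r ≈ 0.87 versus ≈ 0.64 with
context fill.

The consensus report lists each unique peptide with its duplicate count
and frame cells, plus per-column majority residue and class; exact ties
are reported as ties (`A/V`), never broken arbitrarily.

## Reporter substrates

The reporter is two *E. coli* thioredoxin domains in tandem with a
C-terminal His6 tag and the test sequence in the linker:
`M–Trx–GS–insert(6–9 aa)–VD–Trx–HHHHHH`, where GS and VD are the
BamHI and SalI cloning frames. The canonical mature thioredoxin A
sequence (108 aa) is embedded; vector-derived residues beyond
Met/GS/VD/His6 are not modeled, so absolute masses carry a ±1 kDa
tolerance. Masses are average-isotopic (gel scale): the intact
VLLVSEVL reporter computes to 25.5 kDa, and the central cut (VLLV|SEVL)
gives 12.38 and 13.14 kDa chains — the ~25 kDa band and the 12–13 kDa
doublet the gels show. Fragment masses always sum to the construct mass
plus one water (18 Da).

Site prediction scores every window whose P1 lies in the insert,
restricted to P1 residues the enzyme accepts; the folded thioredoxin
domains are masked, reflecting their resistance to cleavage under
native conditions (an `sds_mode` lifts the mask to emulate
detergent-opened domains). Weak-tier P1 residues are penalized by 3
bits — calibrated on the printed gel outcomes, where cleavage of the
Ala and Phe variants of VLLVSEVL is redirected to a Val elsewhere in
the linker and the Ala variant of the Arg-Gly-Gly scaffold is cleaved
only at the SalI-frame Val. When no insert site passes the threshold,
that SalI Val is evaluated and reported as the fallback site. A known
limitation: for VLLASEVL the additive model places the redirected cut
at the first Val (in the VLL context) rather than the downstream Val
suggested by the fragment sizes on the gel; the model is sequence-only
and additive, with no pairwise interactions between subsites.

The printed substrate panel ships as a fixture table; rows
reconstructing short figure names (VV, VS, …) on the `GRGG…GRG`
scaffold are flagged `inferred=yes` because their exact flanks were not
printed.

## Scanning

Scanning slides the 9-residue frame over a protein and reports windows
scoring at or above a threshold, ranked by score then position, with
1-based P1 coordinates (cleavage between P1 and P1+1). The default
threshold is matrix-specific: the 99.9th percentile of scores of 10⁵
background-composition windows (seeded, reproducible). Scores are
sequence-only; no structural-accessibility correction is applied, and
folded proteins can resist cleavage at high-scoring sites, so scan
output ranks candidates rather than asserting cleavage.

## Problem sizes and determinism

Simulation-backed tests and the acceptance script run at the scaled
study conditions: library and binding capacity 10⁵ (4 × 10⁵ bound for
the monotonicity calibration), five rounds, 96 sequenced clones, 50
replicates for selection calibration, 100 trials for planted-site
recovery. Every stochastic component draws from a single seeded
generator; fixed seeds reproduce pools, samples and output files
byte-identically.
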