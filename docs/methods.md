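# Methods

`psrkit` analyses multiple sequence alignments of bacterial receiver-like
domains to contrast true receiver domains with pseudo-receivers (PsRs) —
domains recognized as receivers but lacking at least one of the five
conserved active-site residues.  This note documents the models, the
parameter choices, the synthetic data used for validation, and the known
limitations.

## Coordinate system and landmarks

All positional output is reported in the residue numbering of a reference
sequence, by default *E. coli* CheY (129 residues), the model receiver
domain.  The five active-site landmarks are the acidic metal-binding pair
DD1/DD2 (CheY Asp12/Asp13), the Asp phosphorylation site D (Asp57), the
conserved Ser/Thr T (Thr87), and the conserved Lys K (Lys109).  The fixture
file `psrkit/data/chey_landmarks.yaml` carries the reference sequence and
landmark numbers, so another reference can be swapped in without touching
code.

Relative labels such as `T+1` or `K-3` count *reference residues* from a
landmark; alignment columns that are insertions relative to the reference
are skipped.  `DD±k` labels anchor at DD1.  The two acidic residues are
adjacent in CheY but not guaranteed to be in every family, and usage of
labels like `DD+5` (an α1 position) is consistent with an α1-proximal
anchor; anchoring at DD1 is a documented assumption.  Column indices are
0-based internally; every user-facing table uses 1-based reference numbers.

## Classification

A domain is called a pseudo-receiver when any landmark column holds a
residue outside that landmark's allowed class.  Defaults:

| landmark | allowed | rationale |
|----------|---------|-----------|
| DD1, DD2 | D, E    | the pair is essentially 100% acidic in true receivers |
| D        | D only  | Glu at D is the hallmark aspartate-less (ALR) substitution and must count as missing |
| T        | S, T    | either hydroxyl residue supports phosphoryl-oxygen binding |
| K        | K only  | the conserved lysine |

A gap at a landmark always counts as missing: a domain that fails to align
a landmark cannot present the catalytic residue.  Classification is binary
(no soft calls) and per-sequence, independent of the rest of the alignment.
All classes are overridable; a single-position rule with allowed = {H}
counts missing His phosphorylation sites in HisKA / HisKA_3 / Hpt
alignments.

## Composition profiles

Percent abundance at a column is computed over non-gap residues; the gap
fraction is reported separately per column.  The gap-exclusive denominator
is what makes statements like "100% acidic at DD" attainable and is a
documented assumption.  Sequences are uniformly weighted by default, on the
assumption that inputs are redundancy-reduced representative sets; Henikoff
position-based weights are available behind a flag for sensitivity
analysis.  Fully gapped columns are excluded and flagged.

Group differences are receiver-minus-PsR percent differences per (position,
amino acid).  For display they are clipped at ±20 percentage points
(raw values are always retained), matching the scale on which the biggest
group differences — e.g. the β3α3 and β4α4 loops — are inspected.

## Covariation

Raw mutual information between columns *i* and *j* is

    MI(i,j) = Σ_ab p(a,b) log2[ p(a,b) / (p(a) p(b)) ]    (bits),

over residue pairs observed at the two columns.  Rows gapped at either
column are dropped pairwise (default); treating the gap as a 21st symbol is
available but inflates MI with alignment artifacts.  The pseudocount
default is 0; an additive λ = 0.5 per joint-table cell is available behind
a flag.  Pairs with fewer than two usable rows are flagged and excluded.
Columns gapped in more than 50% of sequences (`max_gap_fraction`) are
excluded from the analysis; the threshold is a declared assumption.

Raw MI carries a strong background component (per-column entropy, shared
phylogeny, and finite-sample bias).  The average-product correction

    APC(i,j) = MI(i,·) · MI(·,j) / ⟨MI⟩,     corrected = MI − APC

removes it; a constant background corrects to exactly zero, and an all-zero
matrix is defined to correct to zero.  APC is the declared interpretation
of "corrected mutual information" here; corrected scores may be negative.

Significance is a global z-score of the corrected score over all
off-diagonal pairs (sample standard deviation), with default threshold
z ≥ 6.5.  A degenerate (zero-spread) distribution yields a warning and no
significant pairs.  Percentile ranks (0–100, higher score → higher rank)
use mean shared ranks for ties; top-x% selections take ceil(x·n) items and
include all pairs tied at the boundary, so counts are reproducible.

**Rank shift.**  MI scores are not comparable across alignments, but
within-group percentile ranks are, provided both groups are analysed over
the identical reference column set.  shift = receiver percentile − PsR
percentile; pairs significant in at least one group are ranked by |shift|
and the top 2% retained by default.  Positive shifts mark interactions
relatively stronger in receivers.  Pairs with shift exactly zero are never
selected (required so identical inputs produce an empty selection).

## Networks

Core networks are the top 1% of all analysable pairs by corrected MI,
intersected with the significant set; extended networks are the 1–2% band,
likewise intersected.  Clusters are connected components of the core graph
with at least three members (`min_size = 3`); extended edges attach to a
cluster when incident on a member (first-order neighbors only).

Design choice: clusters are components of the *unfiltered* core graph.  A
best-neighbor edge filter (keep an edge iff it is the best-scoring incident
edge of at least one endpoint) is provided as a separate operation and as a
`build_networks(best_neighbor=True)` option for sparsifying dense cores
before manual inspection, but it does not define cluster membership: for a
4-clique with near-equal edge scores the per-node best-edge graph splits
into two 2-node components with probability 1/5 under score-noise, which
would make cluster recovery non-deterministic and would break the guarantee
that raising the core percentage never removes previously clustered nodes.
With unfiltered components both properties hold and planted coupled blocks
are recovered exactly.

Hub statistics: each position's cumulative corrected MI over its
significant pairs (each edge credits both endpoints, so the positional sum
is twice the edge sum) and its degree; the top-k table includes boundary
ties.

## Synthetic data

The generator emulates the statistical structure the analyses consume:

* per-column categorical backgrounds over the 20 amino acids (default
  uniform, per-column overrides for planted composition biases);
* landmark sites drawing their conserved class with probability *p* and a
  substitute class (default: complement) otherwise, so planted missing
  rates are exact Binomial(n, 1−p) quantities;
* coupled pairs/blocks: with probability `coupling` a row draws all block
  columns jointly from one of two designated residue states (50/50),
  otherwise independently from the background — a two-component mixture
  with analytically tractable MI, monotone in `coupling`;
* gaps injected independently per cell after the residue draws.

Generation is a pure function of (spec, seed): one PRNG per call, fixed
draw order, byte-identical repeats.  The truth record (per-row planted
missing landmarks, hence true calls, plus planted couplings) is sufficient
to score recovery exactly.

Preset study conditions (fixed once, not tuned): the receiver-like preset
conserves all five landmarks and plants receiver-typical marginals — Ala+Gly
74% at T+1, Phe/Tyr 86% at K−3, Phe 40% vs. Ala/Ile/Leu/Val 39% at K+2,
Pro 71% at D+4, Gly 71% at D+8.  The PsR-like preset degrades landmark
retention to DD1 80%, DD2 20%, D 65% (substitute fixed to Glu, the dominant
natural replacement), T 70%, K 65%, and plants PsR-typical marginals —
Ala+Gly 43% at T+1, Phe/Tyr 65% at K−3, Phe 20% vs. A/I/L/V 55% at K+2.
The representative mixed set uses per-landmark missing rates of 0.5–2%,
giving ~2% missing-D and ~6% PsR overall.  Sites are drawn independently,
so planted joint quantities are products of marginals: the PsR Y-T
retention, for instance, is 0.70 × 0.65 ≈ 45.5%, slightly below the ~47%
observed in real PsR sets where the two sites covary weakly.  Covariation
validation uses 60-column, 500-sequence alignments with coupling 0.9 and
20 replicate seeds — large enough for the planted signal to stand ~10
standard deviations above the corrected-MI background, small enough that
the whole validation battery runs in seconds.

What the generator does *not* emulate: phylogenetic correlation between
sequences (no tree-based simulation), insertion/deletion structure beyond
i.i.d. gaps, multiple distinct PsR sub-families with their own conserved
sets, and covariation between landmark sites and planted blocks.  Passing
tests therefore demonstrate that each stage recovers the structure it
models, not that real alignments satisfy those models; on real data,
shared ancestry inflates raw MI (mitigated but not removed by APC and
available Henikoff weighting), and composition statistics inherit whatever
redundancy the input set retains.

## Numerical choices and degenerate inputs

* MI is computed in bits (log base 2); the unit is recorded on results.
* Ambiguity codes (X/B/Z/U/O) are rejected at parse time rather than
  recoded, keeping the alphabet at exactly 20 + gap.
* Empty alignments, empty rule sets, ragged inputs, unresolvable labels,
  and non-overlapping column sets raise immediately with specific messages.
* Ranking ties share the mean rank; selection boundaries include ties.
* The z-score uses the sample standard deviation (ddof = 1).
* All randomness flows from a single `numpy` Generator per generation call.

## Limitations

* APC-corrected MI is one of several covariation estimators; direct-
  coupling methods (pseudo-likelihood DCA and relatives) are out of scope.
* The significance model (global z over corrected scores) treats pairs as
  exchangeable; heavy-tailed score distributions make the z ≥ 6.5 cut
  conservative rather than calibrated.
* Exact membership of covariation networks in real data depends on
  alignment construction and trimming choices; network outputs are
  hypothesis generators, not structure predictions.
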