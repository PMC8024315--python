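# Methods

This note documents the models implemented in `crmnet`, the conventions
and numerical choices behind them, what the synthetic generator does and
does not emulate, and the package's known limitations.

## Coordinates and formats

All interval arithmetic uses 0-based, half-open coordinates; a 1-bp
interval [x, x+1) covers base x only. Text citations such as
`chr1:100-200` are parsed as already half-open. BED3–5, chrom.sizes,
JASPAR count matrices, TSV expression matrices, TSV SNP tables (chrom,
pos, rsid, ref, alt, one p-value column per trait), TSV edge lists and
the triplet network TSV (TF, TG, score, semicolon-joined intervals) are
the supported dialects; scores round-trip at six significant digits.
JASPAR counts become log-odds with pseudocount 1 per cell against a
uniform background unless another background is supplied.

## Single-replicate network construction

The trans-regulation score combines five ingredients (README for the
formula). Conventions that the score leaves open:

- **Motif scanning.** Both strands, every offset; a window scores the sum
  of per-base log-odds and counts as a site when it reaches the PWM
  threshold, by default 60% of the PWM's maximum achievable score
  (configurable). `B_ik` sums the scores of all passing sites. Windows
  containing non-ACGT bases never score.
- **Candidate elements `D_j`.** Elements within a window (default 200 kb,
  configurable; the synthetic instances use 10 kb to match their scaled
  genome) of the gene's TSS, or an externally supplied table.
- **Element→gene weights `I_kj`.** Ordinary least squares of panel gene
  expression on candidate-element accessibility, intercept unpenalized.
  Rank-deficient designs receive a minimal ridge (1e-8); fewer samples
  than parameters is an error unless a ridge penalty is requested.
  The regression is sign-unconstrained; score inner sums that come out
  negative are clamped to zero, keeping the score inside the consensus
  model's feasible set (S ≥ 0).
- **TF activity.** √(expression × motif enrichment), where enrichment is
  the hit density on open elements divided by the mean density over
  dinucleotide-preserving shuffles (Altschul–Erickson Eulerian-walk
  shuffle; 10 rounds by default, one shared background per round for all
  PWMs), floored at 1e-3. A TF with zero expression has zero activity.
- **Edge retention.** Edges at or above the `s_quantile` quantile
  (default 0.5) of positive scores survive; `>=` rather than `>` so that
  quantile 0 keeps every positive edge. Scores below 1e-9 × max(S) are
  treated as numerically zero — regression round-off, not regulation.
  A retained edge's CRM is the merged set of candidate elements the TF
  binds (`B_ik > 0`).

## Consensus optimization

The objective (README) is solved after relaxing the binary CRM variables
to [0, 1]. Solver choices:

- **Projected Jacobi iteration.** Both stationarity updates are evaluated
  on the previous iterate, then projected (S to [0, ∞), C to [0, 1]).
  Initialization is the ω-weighted replicate mean — the exact optimum at
  β = γ = μ = 0, which therefore converges in one iteration.
- **Convergence** requires max |ΔS| < ε and additionally max |ΔC| < ε
  (default ε = 1e-8); both residuals are reported. Non-convergence at
  `max_iter` returns the current iterate with a warning flag.
- **Layout.** All pairs' CRM base vectors are concatenated into one
  global array with zero guard bases after every chromosome piece and
  every pair, so the continuity term's neighbour sums are two shifted
  adds and cannot couple across pairs or chromosomes; the boundary
  convention C_0 = C_{L+1} = 0 falls out of the guards. Vectors are
  stored densely: at the spans this package targets (tens of kb per
  pair) dense is exact and faster than run-length bookkeeping.
- **Absent pairs** contribute S^r = 0 and an all-zero base vector — the
  sum over replicates runs over all of them; absence is lack of support.
- **α = 0** is rejected whenever β > 0 or γ > 0 (both C-update terms
  divide by 2ωα).
- **Finalization.** Relaxed bases at or above `c_threshold` (default 0.5)
  become 1; maximal runs become CRM intervals; triplets with strength ≤
  `keep_s_min` or an empty binarized CRM are dropped.
- **Parameter selection** scans a grid and keeps the setting with the
  best directed-edge F1 against a gold standard inside an explicit gene
  universe; ties break toward larger recall, then smaller μ. The library
  default grid is {0, 0.1, 1} per parameter. For the recovery study the
  μ ladder is {0, 1, 2, 4}: with unit weights the sparsity penalty acts
  as an edge threshold of μ/(2ω), ω = Σω_r = 6, and that ladder spans
  the range from no pruning to just above the clamped-noise mean
  (≈ 0.4 σ_S) up to the truth-score scale — chosen from that analytic
  argument, not tuned.

## Architecture analysis

TF modules come from agglomerative clustering of the TF × TG strength
rows (Euclidean, complete linkage — the defaults of the heatmap tooling
this follows; both configurable), cut at k = 2 by default and renumbered
so module 1 holds the broadest regulators. The dense TF subnetwork
maximizes Σ S⁰_ij u_i v_j over non-negative unit vectors by alternating
projected power iteration (tolerance 1e-10, 5 seeded restarts); for a
non-negative matrix the optimum is the leading singular pair, which the
test suite verifies against a full singular decomposition. Roles use
cutoffs μ_c = 0.1, v_c = 0.05: upstream (u high, v low), core (both
high), downstream (u low, v high). S⁰ is used raw; a normalization flag
exists. Density significance compares the mean off-diagonal weight of
the selected set against uniformly drawn same-size sets (one-tailed
t-test plus the empirical exceedance fraction).

## Annotation

Subnetworks are extracted by target-gene membership, by SNPs whose
position lies on a binarized CRM base, or by regions overlapping a CRM
by ≥ 1 bp (the overlap reading of the region selector; base-weighted
semantics are not implemented). The per-gene z-score filter uses the
population standard deviation over a gene's CRM strengths and drops
CRMs with z < λ; genes with fewer than two CRMs or zero spread are kept
untouched (z := 0 — no spread, nothing to rank).

SNP enrichment takes each SNP's minimum p-value over traits, then for
each threshold of a decreasing ladder (default 1.0 down to 1e-9)
computes FC = (P_r/L_r)/(P/L) with regions merged before length
measurement; FC is reported missing where no SNP passes.

Element-overlap significance relocates every element uniformly on its
own chromosome (a genome-wide placement flag exists), lengths preserved
and collisions allowed, and counts elements overlapping any regulatory
element by ≥ 1 bp. Both the standard `>=`-exceedance p-value and the
strict `>` variant are reported, along with the plus-one-corrected p —
published empirical p-values are sometimes quoted under either rule, so
both are exposed rather than guessed between.

Allele rescans restrict both-strand best-hit scoring to windows covering
the variant; a motif is gained when only the alternate allele reaches
the PWM threshold, lost when only the reference does, and Δ is the
best-score difference.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
a uniform-random genome, non-overlapping elements with log-normal
accessibility, one sharply informative PWM per TF (distinct consensus,
count 12 vs pseudocount 1, scan threshold 80% of maximum so only exact
matches score), genes anchored near elements so every gene has
candidates, seeded edges whose CRM elements receive a planted motif and
a positive element→gene weight, log-normal latent strengths, and a
paired panel in which gene expression follows the linear model with
Gaussian noise and TF expression tracks its targets. The truth network
is the closure of the implied relation — TF i regulates gene j exactly
when some candidate element of j hosts i's motif and carries positive
weight — because genes that share elements genuinely share regulators
under the score formula; seeding alone would understate the truth.

Replicates add clamped Gaussian noise (default σ_S = 0.2 × mean truth
strength) to every TF–TG pair, jitter CRM endpoints (±20 bp default),
and draw one decoy candidate element per spurious pair, shared across
replicates — replicate CRMs stem from the same candidate structure, so
replicates disagree by jitter, not by unrelated elements. SNP panels
place causal variants uniformly on CRM bases with lead-trait p ~
10^−U(5,9) and background variants uniformly on the genome with U(0,1]
p-values.

Default scale is 2 chromosomes × 100 kb, 20 TFs, 100 TGs, 300 elements,
R = 6, a 148-sample panel; the recovery and calibration studies run a
half-size instance (10 TFs, 50 TGs, 150 elements, 2 × 50 kb, 20 seeds,
solver ε = 1e-6) so the whole suite completes in well under a minute of
solver time. What the generator does **not** emulate: real motif
degeneracy and families sharing motifs, linkage disequilibrium among
SNPs, correlated replicate noise, mappability/GC structure, and
genome-scale element counts — so passing tests demonstrate correctness
of the machinery and calibration of the statistics under the stated
noise model, not performance on real epigenomes.

## Limitations

Exact 0–1 optimization of the consensus objective is NP-hard; the
projected fixed-point iteration inherits no optimality guarantee beyond
the fixed-point property the tests check. The binarization rule for
relaxed CRMs (threshold 0.5) and the within-iteration use of relaxed
‖C‖₁ are conventions; results at other thresholds are one flag away.
The nearest-TSS baseline deliberately ignores basal-plus-extension
association rules, and the panel regression assumes additive,
element-independent contributions to expression.
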