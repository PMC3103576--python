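# Methods

## The model

Amino-acid evolution is described by a stationary, reversible continuous-time
Markov process on the 20 residues (canonical PAML `dat` ordering
A R N D C Q E G H I L K M F P S T W Y V).  A model is parameterised by
equilibrium frequencies π and a symmetric exchangeability matrix s; the
instantaneous rates are

    q_ij = s_ij · π_j   (i ≠ j),

with the diagonal closing each row to zero.  Reversibility (detailed balance
π_i q_ij = π_j q_ji) is forced by this construction.  At build time the
generator is rescaled so that −Σ_i π_i q_ii = 1: one expected substitution
per site per unit time, so branch lengths read as substitutions per site.
Transition probabilities P(t) = exp(Qt) come from the symmetric
eigendecomposition of diag(√π) Q diag(1/√π); this is exact for reversible
generators and also drives the E-step integrals below.

The mixed **DO** description applies one such matrix (D) to alignment
columns annotated as intrinsically disordered and another (O) to structured
columns.  A single-matrix fit over all annotated columns is the nested
comparison point; with 208 free parameters per matrix
(190 − 1 exchangeabilities under the scale constraint plus 19 frequencies),
the DO fit carries 416 and the comparison is made by AIC = 2k − 2 lnL.

## Annotation handling

Disorder annotations are 1-based inclusive intervals on the *ungapped*
reference sequence (DisProt convention) or an inline O/D mask string.  They
project onto alignment columns through the reference row; columns where the
reference is gapped carry no annotation and are excluded from estimation,
testing and decoding.  Ambiguity codes (B, Z, X, …) and gaps in non-reference
rows are missing data: their pruning partial vector is all ones.

## EM estimation

**E-step.**  For each branch of length T and each column, the posterior
expectations of (a) the number of i→j substitution events and (b) the time
spent in each state are computed in closed form.  With Q = U Λ U⁻¹ the
integral ∫₀ᵀ P(u) E_ij P(T−u) du reduces to the auxiliary matrix
J_kl = (e^{λ_k T} − e^{λ_l T})/(λ_k − λ_l), with the limit T·e^{λ_k T} for
coincident eigenvalues.  Branch endpoint posteriors come from an inside
("down") and an outside ("up") pruning pass, both vectorised over columns
with per-column log-scale tracking, so the per-branch cost is a handful of
dense 20×20 products regardless of column count.  Two identities are
asserted in tests: dwell times sum to (tree length × columns) at unit rates,
and the 2-state expectations match direct numerical quadrature of the path
integral to 1e-6.

**M-step.**  π_i ∝ w_i (dwell), floored at 1e-6 and renormalized, and
s_ij = (c_ij + c_ji + κ)/(w_i π_j + w_j π_i + κ).  The pseudocount κ
(default 2 virtual events per residue pair) shrinks weakly observed
exchangeabilities toward the neutral value instead of letting them collapse
to the zero boundary — the same motivation as the frequency floor (an
irreducible generator) plus a mild empirical-Bayes prior.  κ is irrelevant
for well-observed pairs (hundreds of expected events).

**Convergence.**  The reversible M-step is a fixed-point update, not an
exact maximizer of the expected complete-data log-likelihood (the root-state
term and the frequency/exchangeability coupling are not jointly solved), and
with κ > 0 the iteration ascends a penalized objective rather than the raw
likelihood.  Consequently the data log-likelihood can dip by less than the
convergence tolerance near the optimum.  The iteration therefore stops when
the gain falls below the tolerance (default 1e-3 log-units, at most 200
iterations); a *negative* sub-tolerance gain additionally rolls the model
back to the previous (better) iterate, so the accepted trace is monotone by
construction.  Decreases far beyond that scale abort with a diagnostic —
they indicate a genuine E-step defect, not fixed-point overshoot.

**Rate heterogeneity.**  Among-site variation uses k = 4 equal-probability
discrete-gamma categories (category means, renormalized to average 1).  The
gamma shape is fitted per group by maximizing the mixture likelihood under a
preliminary single-rate EM fit; assigning classes under a uniform matrix
instead would track raw column diversity and measurably biases rare
exchangeabilities downward.  By default the E-step then *integrates* over
classes with per-column posterior weights (`rate_mode="soft"`, a proper
mixture EM).  The two-stage alternative — condition each column on its
single most probable class — is available as `rate_mode="hard"`; it mirrors
the assign-then-estimate workflow of PhyML-based pipelines but pays a small
additional downward bias on rarely exchanged pairs, because assignment
correlates with the very substitutions being counted.

**DO fitting order.**  `fit_do_model` fits the single matrix first, then
starts the D and O fits from it with the per-group rate models (shape and
class assignments, computed once on all annotated columns) shared by all
three fits.  EM monotonicity then guarantees lnL(DO) ≥ lnL(single), making
the AIC comparison well-posed.

## Comparing the two estimates

Frequency vectors and substitution-count vectors of the two fits are
compared with Pearson's χ² and the G-test on the 2×C homogeneity table with
pooled-margin expectations; EM expected counts enter as real numbers without
rounding.  Cells empty in both vectors leave the degrees of freedom;
categories whose pooled expectation falls below 1 merge into a rest
category.  Component-wise uncertainty comes from re-estimating the models on
column-bootstrap and row-jackknife replicates (jackknife drops 25% of rows
and prunes the tree to the surviving taxa); replicate seeds derive from
(seed, scheme, replicate, group id), so variances do not depend on group
processing order.

**Class rates.**  For residue classes A, B (order-promoting
I L V W Y F C; disorder-promoting R K E Q A G S P; remainder neutral — the
partition is user-configurable), the raw class rate is the stationary flux
Σ_{i∈A, j∈B, i≠j} π_i q_ij.  The normalized rate divides by the matching
frequency mass Σ π_i π_j over the same index set, i.e. it is the
frequency-weighted mean exchangeability of the block.  This makes the
statistic exactly composition-free: under a fully exchangeable model every
class pair receives the same normalized rate, which is asserted in tests.
A one-residue class has no within-class pairs; its within-class rate is
reported as NaN rather than zero.

## Phylo-HMM annotation

Four states: start, an O-emitting state, a D-emitting state, end.  Emissions
are phylogenetic column likelihoods under the corresponding matrix, with the
same rate-class handling as estimation (classes assigned once per alignment
under a uniform reference model so both states share the assignment);
fully-gapped columns emit probability 1 in both states.  Transitions
(including start and end probabilities) are trained by Baum–Welch with
emissions frozen; all dynamic programs run in log space, and forward and
backward total likelihoods are asserted to agree to 1e-8.  Default decoding
is per-column posterior argmax; Viterbi is available.  The frequency-only
baseline keeps the chain but replaces emissions with products of stationary
frequencies over the column's residues, ignoring the tree — the margin over
this baseline is what the phylogeny buys.

Evaluation normalizes each group's confusion counts by its number of
sequences before pooling, so one large family cannot dominate the benchmark;
raw totals are reported alongside.  Disorder is the positive class;
undefined ratios (e.g. precision with no disorder calls) are reported as
absent, not zero.  A seeded group-level train/test split utility keeps
training and evaluation families disjoint.

## Rate comparison

For each group, the ordered and disordered column sets are summarized by the
total length of their own distance trees: pairwise ML distances (1-D
likelihood maximization per pair, bracketed in [1e-6, 20], saturated pairs
capped at 20), NJ topology, ordinary-least-squares branch lengths with
negatives clamped to zero.  For a fixed taxon set tree length is
proportional to the average evolutionary rate.  A `shared_topology` mode
(ML branch lengths on the group tree by coordinate ascent) is provided for
short regions where distance trees are noisy.

Columns are bootstrapped separately within each region (default 200
replicates).  The Mann–Whitney U statistic on the two replicate samples
gives U/(n·m), the bootstrap estimate of P(r_D* > r_O*); the two-sided
p-value is the percentile form 2·min(θ, 1−θ).  A naive two-sample MWU
p-value on the replicate samples would treat n_boot resamples as independent
observations and reject almost every null group; the percentile form uses
the same statistic but stays calibrated (approximately uniform p under equal
rates), which the null-calibration check verifies.  The standalone
`mann_whitney_u` function implements the classical test (exact enumeration
for small tie-free samples, otherwise the normal approximation with tie and
continuity corrections, via scipy) for ordinary two-sample questions.
Groups classify as `greater` / `less` (direction from the point estimates)
when p < α (default 0.05), else `indistinct`; a census over groups, and a
3×3 overlap table when two models' classifications are compared, summarize a
cohort.

## Synthetic data

The generator emulates collections of homologous protein families:

- **Trees**: pure-birth topologies (dendropy), rescaled to a mean
  root-to-tip depth of 1.0 substitutions/site — moderate divergence typical
  of curated family alignments.
- **Masks**: alternating ordered/disordered blocks with geometric lengths,
  disordered mean block 40 columns, expected disordered fraction 0.35.
- **Columns**: per column a rate class (k = 4, shape α = 1) is drawn, the
  root residue is sampled from the region model's stationary distribution,
  and states propagate down the tree; disordered columns can additionally be
  scaled by a D/O rate ratio.  Truth records (per-column labels, classes,
  rates, root states, trees) accompany every corpus.
- **Defaults**: 30 groups, 6–12 taxa, 200–600 columns, written as FASTA +
  Newick + interval TSV + truth JSON, byte-identical under a fixed seed.

The packaged "distinct D/O" fixture models are synthetic empirical-style
matrices built deterministically in code: base exchangeabilities are
log-normal with log-SD 0.8 around typical proteome frequencies, and the D/O
pair perturbs them with opposite within-class biases (within-disorder
exchange suppressed ×0.5 in D and raised ×1.3 in O; within-order raised in
D; order-promoting frequencies depleted in D and enriched in O), so every
class-ratio contrast has a known sign.  The moderate spread is a deliberate
design choice: published general matrices span several more orders of
magnitude, and corpora of the size used here would leave their rarest
residue pairs with essentially no substitution events, making uniform
recovery impossible for any estimator.

What the generator does *not* emulate: indels (alignments are gap-free, so
gap handling is exercised only by hand-written fixtures), alignment error,
non-stationary composition, site-specific selective constraints beyond the
gamma rates, and annotation noise.  Passing the recovery and calibration
checks therefore demonstrates correctness of the estimators under their own
assumptions, not robustness to real-data violations of them.

## Benchmark design and problem sizes

The end-to-end checks (tests/test_acceptance.py, scripts/acceptance.py) use
these study sizes: E-step quadrature on a 2-letter alphabet over branch
lengths 0.01–2; pruning vs explicit enumeration on 100 random 4-taxon
columns; EM recovery on 30 groups × 8 taxa × 400 columns of constant-rate
columns (the clean parameter-recovery experiment; adding gamma heterogeneity
to the corpus dilutes the per-column information — slow classes carry few
events, fast classes saturate — so recovery under heterogeneity is
intrinsically weaker, an information loss rather than an estimator defect); AIC behavior over 25 replicates each of two-matrix and one-matrix
corpora (8 groups × 6 taxa × 500 columns per replicate, enough columns that
the 208-parameter penalty is decisive exactly when it should be);
homogeneity-test calibration on 2000 null multinomials; HMM training on 10
and evaluation on 15 block-structured groups; rate classification on 12
two-fold-rate and 12 equal-rate groups (1100 columns, 200 bootstrap
replicates per region); and 20 refit replicates for the class-ratio sign.

## Numerical choices and degenerate inputs

- Eigendecomposition-based P(t): negative entries from rounding (≥ −1e-12)
  are clipped to zero.
- Coincident eigenvalues in the E-step integral use the analytic limit.
- Pruning partials are rescaled per column by their maximum, with log scale
  factors accumulated separately; likelihoods of arbitrarily long alignments
  and deep trees do not underflow.
- `build_model` rejects nonpositive frequencies, asymmetric or negative
  exchangeabilities, and an all-zero exchangeability set; parsed dat
  frequencies are renormalized when within 1e-3 of unity and rejected
  otherwise.
- Rate-class ties resolve to the lower class index; HMM emission ties are
  resolved by the transition structure.
- NJ trees with 2 taxa are built directly; OLS branch lengths clamp
  negatives to zero before tree lengths are summed.
- Saturated pairwise distances cap at 20 substitutions/site with a warning.

## Known limitations

- The M-step is the standard fixed-point update; its stall-and-rollback
  termination means the returned model can sit a sub-tolerance step away
  from the exact penalized ML.
- Tree topologies and branch lengths are taken as given during EM
  (re-optimization is available only in the rate-comparison module's
  `shared_topology` mode); errors in the input trees propagate into the
  matrices.
- The bootstrap rate-comparison inherits the caveat printed in its output:
  resampling columns within one alignment measures estimation noise around
  that alignment, not biological variability across groups.
- Exchangeabilities between residues that are rare in a data set are
  dominated by the shrinkage prior; their reported values should be read as
  regularized, not as data-driven point estimates.
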