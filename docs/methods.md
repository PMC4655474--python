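# Methods

## Model

A TF binding motif of width L is modeled as a penalized logistic
regression over two feature families:

- **Coded single-base features** `Z_1..Z_3L`. Each position contributes
  three columns under a sum-to-zero dummy coding: A→(1,0,0), C→(0,1,0),
  G→(0,0,1), T→(−1,−1,−1), laid out at n = 3(p−1)+1. The coding is
  injective and the T row is the negative sum of the other three, which is
  what makes the decode below exact.
- **Association features** `A_1..A_K`. Binary indicators of mined
  dependence structures: `A_j = 1` iff every member item (base, position)
  of feature j is present in the sequence.

The fit minimizes per-observation negative log-likelihood plus
`λ[α‖β‖₁ + (1−α)/2‖β‖₂²]`, intercept unpenalized. α = 0.5 balances
lasso's selection against ridge's retention of correlated groups — the
mined features are correlated by construction (nested itemsets share
members), and pure lasso would arbitrarily keep single representatives.

After fitting, the three coded coefficients of each position decode to
four per-base coefficients, with `a_T = −(a_A + a_C + a_G)`. Because
`a_T` is computed as the exact negation of the same partial sums the
row-sum later re-evaluates, decoded rows sum to zero *exactly* in
IEEE arithmetic, not just approximately; a test asserts `== 0.0`.

## Candidate mining

Mining operates on the *unique genome windows whose PWM log-odds exceed
zero*, not on the positive set alone: the positives (4–236 sequences for
typical prokaryotic TFs) are too few to support itemset statistics, while
the genome supplies hundreds-to-thousands of motif-like windows whose
co-variation reflects both true site structure and the threshold-induced
dependence among windows that compensate a mismatch at one position with
matches elsewhere.

Supports use the standard transaction semantics; candidate generation is
levelwise with (k−1)-prefix joins, anti-monotone pruning, and an a-priori
prune of candidates holding two bases at one position (impossible in any
transaction). Rules are tested over every ordered bipartition (A, B) of
every frequent itemset in four polarities; negative-polarity confidences
are computed on complemented events (e.g. `conf(A→¬B) = (sup(A) −
sup(A∪B))/sup(A)`), and the correlation strength of every polarity is the
same φ coefficient of (A, B) up to sign (negated when exactly one side is
complemented). φ is defined as 0 when a marginal support is 0 or 1.
Features integrate rules by their base itemset regardless of polarity or
direction; the regression's signed coefficients then express whether a
dependence is favorable or avoided.

`max_itemset_size` defaults to 6. The frequent lattice of a highly
conserved motif explodes combinatorially (every subset of the conserved
core is frequent); 6 is comfortably above the dependence sizes reported
for dependence-rich TFs (typically three to four member bases) and a
warning reports when the cap truncates.

## Negative set

Three procedures, 10 per positive each, drawn with *exclusion chaining*
(each pool avoids the positives and every earlier pool), so the union is
exactly 30 non-redundant negatives per positive whenever the genome can
supply them; shortfalls are logged and reported, never fatal:

1. unique windows of a column-permuted PWM scoring above 0 (permutation
   seeded, identity excluded; one permutation per run);
2. random sequences matching the positives' pooled GC fraction, drawn
   distinct;
3. unique genome windows scoring in [−2, 0) (closed lower bound).

The permuted pool contributes motif-composition-like but
arrangement-scrambled sequences, the GC pool composition-matched noise,
and the low-score pool near-miss windows; together they make the
classifier's negative class both hard and diverse.

## λ path and selection

The λ grid is geometric with 100 values from λ_max (the smallest λ
zeroing all penalized coefficients, computed from the null-model gradient)
down to `1e-4·λ_max` (`1e-2` when columns outnumber rows). λ is chosen at
the minimum mean cross-validated binomial deviance over stratified folds
(10 by default, capped at the minority-class count; the 1-SE rule is
available but not default). Exact ties resolve to the larger λ — the
sparser model.

The path solver is an iteratively-reweighted-least-squares coordinate
descent (weights floored at 1e-5; working response from the current
linear predictor; full sweeps establish the active set and check KKT
conditions, inner sweeps iterate the active set to a weighted-squared-
change tolerance of 1e-7). Coordinate descent is used deliberately: with
an ℓ1 penalty it yields exact zeros and concentrates duplicated columns
onto one representative; an activation slack of 1e-10 keeps exact
gradient ties (duplicated columns, the λ_max boundary) at zero instead of
letting them drift in on rounding noise. Two path-level early stops bound
work in the separable regime, where coefficients would diverge: the path
halts once the explained-deviance ratio exceeds 0.995 or a λ step
improves deviance by less than 1e-5 of the null deviance, and later grid
points repeat the last solution. Predictors are standardized internally
(population SD; constant columns left unscaled) with coefficients
reported on the original coding scale. The solver is cross-checked
against R glmnet on a shared λ sequence in the test suite (agreement
≲ 5e-4 along the path, limited by glmnet's own convergence threshold).

## Cross-validation and evaluation

Folds follow the positive-set size: leave-one-out up to 10 positives,
stratified 10-fold otherwise. The *entire* pipeline — PWM, background,
scan, mining, negative generation, fitting — is re-run inside each
training fold, with fold-specific seeds derived from the master seed, so
held-out positives cannot influence the trained fold model (a test
poisons a held-out sequence with a sentinel and asserts the fold model is
bit-identical). Held-out positives are scored together with fold-local
evaluation negatives (30 per held-out positive, same three procedures,
distinct seeds from the training negatives) and all out-of-fold scores
pool into one rank-based (Mann–Whitney, midrank-tie) AUC, computed by the
rank formula so separable inputs give exactly 1.0.

Threshold screening evaluates the 3×4×4 grid (support 0.1/0.15/0.2,
confidence 0.5–0.8, correlation strength 0.05–0.2). Per case and fold,
scans, negative sets and the frequent lattice (mined once at the smallest
grid support and filtered per setting — exact, by anti-monotonicity) are
fixed across settings, isolating the thresholds' effect. A setting is
*stable* when its per-case AUCs have at most `ceil(6/86·n_cases)` low
outliers (Tukey's rule, below Q1 − 1.5·IQR — the outlier definition is
ours, the source being silent) and the worst case exceeds 0.8; the
optimum minimizes the AUC standard deviation among stable settings, ties
to the larger mean.

`detect_multi_config` reports positions contributing two or more distinct
bases to the selected association features — the situation where a motif
admits more than one binding configuration at a position. (Counting
positions with ≥2 nonzero *decoded* coefficients would flag nearly every
active position, since decoded rows sum to zero.)

## Synthetic data

The generator plants n aligned sites into an i.i.d. or first-order-Markov
background genome (background distributions drawn from a Dirichlet around
uniform, concentration 30 — mild, realistic compositional bias).
Independent positions follow consensus-biased marginals at a chosen
per-position information content; dependency groups draw jointly from a
user-specified distribution (e.g. positions (2,5) ∈ {CG, AT} with equal
probability, an inverted-repeat-like constraint). Everything is
deterministic given the seed.

The standard recovery fixture (`dependence_recovery_case`) uses width 12,
200 sites, a 100 kb genome, four invariant core positions (2 bits) and six
degenerate two-base columns (IUPAC R/Y/W/S style, 1 bit) around the
dependent pair — the invariant-core/degenerate-flank architecture real
TFBS sequence logos show. The architecture is load-bearing, not cosmetic.
With two-valued balanced positions, every rule over the pair has
confidence ≈ 0.5 + 0.5·φ_planted, where φ_planted is the planted fraction
among the *unique* candidate windows; `mc = 0.6` therefore demands that
planted instances make up a substantial share of the pool. A homogeneous
consensus profile cannot deliver that at this width: sharp motifs dedup
their own planted instances away (few unique transactions) while weak
ones drown them in partial-match background windows. Invariant cores
suppress background windows (one core mismatch costs ≈ 4 nats) and
degenerate columns keep the planted instances diverse, which together
keep the planted dependence above the mining thresholds.

What the generator does *not* emulate: overlapping or nested real sites,
genomic repeats and mobile elements (which dominate real hit pools for
low-information motifs), sequencing or curation noise in site alignments,
and any DNA-shape signal. Passing tests therefore demonstrate the
machinery recovers known statistical structure under the stated
conditions, not that mined dependencies on real genomes are binding
contacts.

## Problem sizes in the test suite

The acceptance checks run at sizes chosen to exercise the full pipeline
while staying desk-scale: 200 random databases (widths 2–6, ≤60
transactions) for the exhaustive mining oracles; 20 recovery fixtures at
the standard size above (the fit uses a 12-value λ grid with
`lambda_min_ratio = 0.01` — the CV optimum sits well inside this range);
a 10-case screening panel of width-8, 6-site, 12 kb cases; and a 500 kb
genome with 20 width-15 sites for the 30:1 negative-assembly check.

## Known limitations

- Gapped or variable-length motifs are out of scope; sites must be
  aligned and equal-length.
- Background models above first order are not implemented.
- Scan thresholds are raw log-odds cutoffs (no p-value calibration).
- Mining deduplicates hit windows as exact strings; a window and its
  reverse complement are distinct unless `collapse_revcomp` is set.
- With small positive sets the models overfit (by design they still fit);
  the leave-one-out AUC is then the honest performance summary.
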