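# Methods

## Model

The package couples three data blocks measured on the same n subjects:
imaging features **X** (n×p, e.g. mean fractional anisotropy per brain
region), additively coded genotypes **Y** (n×q, minor-allele counts
0/1/2), and a scalar clinical objective **Z** (n, e.g. age at onset in
years). The objective-specific sparse CCA estimates one pair of sparse
canonical loading vectors (u, v) by minimizing

    f(u, v) = −uᵀXᵀYv − w·vᵀYᵀZ − w·ZᵀXu + λᵤ‖u‖₁ + λᵥ‖v‖₁

subject to ‖u‖₂ ≤ 1 and ‖v‖₂ ≤ 1. The three bilinear terms are the
empirical imaging–genetic, genetic–target and imaging–target covariances
of the projected data; on standardized columns they are proportional to
correlations. The model is a three-way sparse CCA whose third block has
collapsed to a scalar weight w because Z is a single column. Only the
first canonical pair is estimated; no deflation for higher-order pairs
is provided.

Assumptions: columns of all blocks are centered and scaled (the package
standardizes internally, reusing training statistics on held-out rows);
associations are linear in the projections; one dominant shared factor
links the blocks; variants act additively.

## Optimization

With v fixed, minimizing f over the u-ball is the classic penalized-
matrix-decomposition update u ← S(XᵀYv + w·XᵀZ, λᵤ)/‖·‖₂, where S is the
elementwise soft-threshold; symmetrically for v. Each update is an exact
block minimization, so the objective trajectory is non-increasing by
construction (asserted in tests to 1e-9). Iteration stops when the
sup-norm change of both loading vectors falls below `tol` (default 1e-6)
or after `max_iter` (default 100) sweeps.

The alternating scheme is only guaranteed to find a block-coordinate
stationary point. With a single start at the leading right singular
vector of XᵀY it measurably lands in sign-related local optima whenever
the linear target terms disagree with the leading singular pair (the
q = 1 case makes this obvious: v ∈ {±1} and the singular vector's sign
is arbitrary). The deterministic initialization is therefore a four-point
multi-start — both signs of the leading singular vector plus both signs
of the normalized YᵀZ direction — keeping the run with the best final
objective; ties go to the first candidate, so results remain fully
deterministic. A random unit start (`init="random"`, seeded) is available
for robustness experiments. On small problems the solver's objective is
verified against a 20,000-restart randomized global search to 1e-3.

Sign convention: the reported pair satisfies corr(Xu, Z) ≥ 0 whenever
flipping (u, v) jointly does not worsen the objective. At w = 0 the
objective is flip-invariant, and the model reduces exactly to two-way
PMD sparse CCA (verified against an independently coded reference).

λ is the soft-threshold level of the block update (the Lagrangian form
of the l1 constraint). The mapping to an l1-ball radius is monotone:
larger λ, smaller ball, sparser loadings.

## Hyperparameter tuning

Penalty pairs are scored by five-fold internal cross-validation: fit on
four folds, project the held-out fold, and average the three held-out
Pearson correlations

    (1/3) [ corr(Xᵢu₋ᵢ, Yᵢv₋ᵢ) + corr(Xᵢu₋ᵢ, Zᵢ) + corr(Yᵢv₋ᵢ, Zᵢ) ],

then average over folds. A zero-variance projection (over-shrunk λ)
contributes 0 to its term, so degenerate pairs are valid but
unattractive. The default grid is data-adaptive: 8 log-spaced values per
penalty spanning [0.01·g*, g*], where g* is the sup-norm of the initial
block gradient (at λ = g* the first update is already all-zero).

Three selection rules are implemented:

- `mean-score` (default): argmax of the fold-averaged score; exact ties
  break toward larger λᵤ + λᵥ (sparser, reproducible).
- `mean-score-1se`: sparsest pair within one standard error of the
  maximum. The mean score is empirically almost flat in λᵥ — many pairs
  differ by less than the fold noise — so the plain argmax tends to
  over-select genetic features; the 1-SE rule is the standard parsimony
  correction and is offered for interpretation-focused analyses.
- `average-lambda`: average of the per-fold best pairs, an alternative
  reading of "choose the average as the hyperparameters".

## Nested cross-validation, prediction, reporting

The outer loop is a seeded five-fold split. Per outer fold: standardize
on the outer-training rows only (missing genotypes mean-imputed with
training means); tune (λᵤ, λᵥ) by the inner five-fold criterion above;
refit on the whole outer-training set; select the features with non-zero
loadings; train random forests (default 500 trees, other
hyperparameters at library defaults, fixed seeds) on the selected
imaging, genetic, and concatenated feature sets; evaluate Pearson r, its
two-sided p, and RMSE on the held-out fold. A constant mean-of-target
predictor provides the baseline RMSE. Fold metrics are averaged
arithmetically (including p-values — a reporting convention, not a
combined test; the pooled-across-folds correlation is exposed separately
and never substituted). A fold whose selection is empty has its model
metrics recorded as undefined and excluded from averages, with a
warning. The headline feature set is the consensus: features selected in
every outer fold.

Held-out rows never influence standardization statistics, the tuning
grid, penalty choice, fitting, or selection; a mutation test (perturbing
a held-out subject and asserting bit-identical fold loadings) enforces
this.

## Comparison selectors

LASSO: per block, l1-penalized regression of Z with the penalty chosen
by internal five-fold CV (minimum MSE) over 50 log-spaced values
descending from the smallest penalty that zeroes all coefficients; the
non-zero coefficients are the selection, and an empty selection is legal
and flagged. mRMR: the classic MID (difference) variant — greedily add
the feature maximizing MI(f, Z) minus the mean MI to already-selected
features. Continuous features are discretized to three levels at
mean ± 0.5·sd; allele counts are used on their native {0,1,2} scale. MI
is the plug-in estimate on the discretized contingency table (nats), so
the absolute FS-score scale depends on this discretization; the 0.2
screening threshold used for imaging features is a configuration value,
not hard-coded. In the nested pipeline the mRMR feature count is matched
per fold and per block to the sparse-CCA selection size.

## Quality control

Per variant: minor-allele frequency over non-missing calls
(maf = min(f, 1−f)), call rate, and the exact conditional
Hardy–Weinberg test (sum of the probabilities of all heterozygote counts
no more probable than the observed one, given the allele counts; no
mid-p). Defaults: drop when MAF < 0.01, call rate < 0.95, or HWE
p < 1e-6; per-call genotype-quality masking at GQ < 20 sets calls to
missing beforehand. Monomorphic sites get HWE p = 1 by convention so the
MAF filter, not the HWE filter, removes them. Missing genotypes are
mean-imputed after QC — the simplest choice approximately preserving the
dosage semantics; the QC report records every per-variant decision with
its reasons.

## Enrichment

Selected variants map to genes through a user-supplied rsID→gene table
(slash-separated multi-gene entries split, order-preserving
deduplication). Over-representation of the mapped genes in each gene set
is the upper-tail hypergeometric probability against a user-supplied
reference universe (genes outside the universe are dropped and counted);
Benjamini–Hochberg adjustment is applied across the tested sets only. No
gene-set database is bundled.

## Synthetic data generator

The generator emulates the motivating cohort's shape — defaults n = 146
subjects, p = 90 imaging regions, q = 72 variants, planted supports of
s_x = 14 imaging features and s_y = 24 variants — with a causal chain
chosen so all three pairwise associations are simultaneously positive,
the regime the three-term model assumes: independent genotypes
Y_ij ~ Binomial(2, maf_j); a latent factor L = standardized
(β_g·Σ_{j∈support} Y_j + ε_L); true imaging columns γ_x·L + ε_X (mapped
affinely onto a plausible mean-FA scale), other columns unit noise; and
target Z = 61.35 + δ_z·L + ε_Z in years, anchored at a realistic mean
age at onset. Named regimes fix the effect/noise levels: `strong` uses
common variants (MAF 0.2–0.5) and small noise (δ_z = 9, σ_Z = 3.5 years,
target–latent correlation ≈ 0.93); `moderate` (default) δ_z = 5,
σ_Z = 8; `weak` δ_z = 2.5; `null` δ_z = 0. A uniform genotype dropout
rate is available (default 0).

Deliberately not modeled: linkage disequilibrium, population structure,
spatially correlated imaging noise, non-additive genetic effects, and
informative missingness. Passing tests on these data therefore
demonstrate the pipeline's statistical behavior under a clean rank-1
cross-modal signal, not robustness to the confounding structure of real
cohorts.

The annotation generator maps the true-support variants into one planted
gene set (plus random decoy sets over the same universe), so enrichment
can be validated end to end.

## Numerical and degenerate-input conventions

- Standardization uses the sample (n−1) standard deviation;
  zero-variance columns are flagged and scaled by 1, yielding all-zero
  columns.
- A correlation of a constant vector is undefined: the tuning score
  counts it as 0 (flagged), while prediction metrics report it as
  missing (`None`) rather than 0 — the mean baseline therefore has an
  undefined r by design.
- All-zero loadings are a legal solver output (penalty dominates); the
  selection is then empty and downstream models are skipped with a
  warning.
- Solver convergence: sup-norm change < 1e-6, ≤ 100 sweeps; multi-start
  tie-break keeps the first-listed start; tuning tie-break prefers
  larger λᵤ + λᵥ, then lexicographically larger pairs.
- mRMR ties break toward the lower feature index; rankings are exactly
  reproducible.

## Known limitations

- Support recovery of many small equal effects is information-limited.
  With s_y = 24 variants contributing equally to one latent factor, each
  per-variant correlation with that factor is at most 1/√24 ≈ 0.20, a
  detection z-score of ≈ 2.5 at n = 146 against 48 null variants.
  Maximizing the expected F1 over all magnitude thresholds under these
  conditions yields ≈ 0.79 even for an oracle that sees the true
  correlations — so no tuning rule can reliably exceed F1 ≈ 0.8 for the
  genetic support at this sample size, and the tuned selection is denser
  than the planted support (the held-out correlation score is nearly
  flat in λᵥ). The imaging support (14 near-noiseless columns) is
  recovered exactly in the same runs. Larger cohorts, fewer/stronger
  true effects, or common variants all move the ceiling up.
- The fold-averaged p-value mirrors a common reporting convention but
  has no inferential calibration.
- Only the first canonical pair is estimated; signals orthogonal to the
  dominant shared factor are invisible.
- The w weight is a free scalar (default 1, equal weighting of the three
  association terms); no data-driven rule for it is implemented.
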