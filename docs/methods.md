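# Methods

## Model

Bulk RNA-seq measurements are modelled as mixtures of latent cell-type-
specific counts. For gene *i*, cell type *l* and unit *j* (a unit is either
a single reference cell or a bulk replicate) the latent readout
Z<sub>ilj</sub> follows a **scaled Poisson** law,

    T_il · Z_ilj  ~  Poisson( T_il · X_il · W̄_lj · G_j ),

with mean expression X (genes × cell types), readout precision T (inverse
dispersion; variance of Z is mean/T, so T < 1 is overdispersion, T > 1
underdispersion, T = 1 exactly Poisson), simplex composition W̄ (cell
types × units) and per-unit scale factor G absorbing sequencing depth and
sampling efficiency. Only the observed sums y<sub>ij</sub> = Σ_l Z_ilj are
seen. The underlying physical quantities (cell numbers, capture
efficiency, per-gene burst parameters) are not separately identifiable and
are never represented; (X, T, W̄, G) is the identifiable parameterization.
The remaining joint scale ambiguity (X → cX, G → G/c) is fixed by the
gauge convention that the geometric mean of the *reference* scale factors
is 1, which makes fitted profiles comparable across samples and runs.

Counts are non-negative *reals* (quantification pipelines emit fractional
"effective counts"), so all likelihood code uses the continuous log-gamma
extension of the Poisson log-pmf.

### Two likelihood conventions

The quasi-log-likelihood of one entry is

    ll(z; λ, t) = t·z·log(t·λ) − t·λ − lgamma(t·z + 1),

the Poisson log-pmf of t·Z evaluated at t·z. This form is used, summed
over both data blocks, as the objective of the joint decomposition: its
coordinate updates in X, W̄ and G are exact maximizers and only relative
values at fixed T matter.

As a function of t, however, this unnormalized form is essentially
monotone decreasing (the t-lattice spacing shrinks), so it cannot rank
models with different precisions. Wherever models with different T must
be compared — trimmed-gene ranking, clustering likelihoods and BIC — the
normalized log-density

    llpdf(z; λ, t) = log t + ll(z; λ, t)

is used instead (the log t Jacobian accounts for the 1/t lattice spacing).
Under this convention the moment-matching precision update is, to good
numerical accuracy, the maximum-likelihood update, and merging two
genuinely different clusters always loses likelihood — both properties the
algorithms below rely on. The point mass λ = 0 contributes 0 at z = 0
(no Jacobian) and −∞ at z > 0 under both conventions.

## Joint decomposition

Each bulk sample (optionally with replicates sharing profiles) is fitted
jointly with the labelled reference. Profiles (X, T) are shared between
the blocks: the reference anchors them, the bulk adapts them. The fit is
a deterministic block-coordinate ascent:

- **Allocation (E-like step).** Each observed count is split across cell
  types proportionally to X<sub>il</sub>·w̄<sub>l</sub> (the scale cancels),
  which conserves the observed count exactly and is the exact conditional
  mean at T ≡ 1 (multinomial conditioning). For labelled reference cells
  with preset one-hot composition the allocation is the observation itself.
  A count the current profiles cannot explain (zero model mean) is
  allocated proportionally to the composition alone and logged.
- **Expression.** X_il = Σ_j Ẑ_ilj / Σ_j W̄_lj G_j pooled over all units;
  T cancels in the stationarity condition, so this is exact for any T.
- **Composition and bulk scale.** The objective is separable and concave
  in v_l = w̄_l·G, maximized in closed form; v is split into the simplex
  composition and the scale (the scale absorbs the pre-normalization
  total). Because allocation/composition/scale passes are cheap (O(mk))
  but converge slowly when profiles overlap, they are iterated to their
  joint fixed point inside each outer iteration.
- **Reference scales.** Closed-form per-cell update, followed by the
  gauge renormalization (likelihood-invariant).
- **Precision.** Moment matching T_il = Σλ / Σ E[(Z−λ)²], clamped to
  [1e-3, 1e3], pooling reference cells (directly observed, zero
  conditional variance) and bulk allocations (dispersion-scaled
  multinomial conditional variance y·p(1−p)/T around the allocated mean).
  Entries with no information keep their value; zero empirical variance
  clamps to the upper bound.

**Monotone trace.** The recorded joint quasi-log-likelihood is
non-decreasing by construction: every closed-form update is an exact
block maximizer; the inner composition loop is guarded by a snapshot
(reverting to a single damped line-search step if a pass would lower the
bulk objective — the objective is concave along the allocation segment);
and the precision update is accepted *entrywise* only where it does not
lower the traced objective. The last guard means that within the joint
fit T acts as a downward-adaptive weighting (raising T never increases
the unnormalized objective); genuine dispersion estimation is the
standalone moment-matching operation, which the recovery tests exercise
directly. Convergence is declared when the relative trace change falls
below 1e-8 (default; max 1000 outer iterations).

Because T is free per gene and cell type, genes that discriminate cell
types receive more weight, and pure-noise genes (equal means, high
dispersion) are automatically down-weighted.

Final allocations are recomputed from the fitted parameters, so
conservation Σ_l ŷ_ilr = y_ir holds to machine precision. Initialization
is data-driven (per-type scale-normalized reference means, T = 1, uniform
composition, scales from column totals) and nothing draws random numbers:
repeated runs are bit-identical.

## Trimmed scale factors

For panels of *pure* samples the relative scales G_j are estimated by
fitting a common subprofile (x, t) on a per-sample trimmed gene set
Ω_j of size round(α·m) (default α = 0.5): alternately (1) refit (x, t)
on retained entries, (2) refit each G_j on its retained genes, (3)
re-select Ω_j as the genes with the highest per-gene normalized
log-density contribution (ties broken by gene index). Every step —
including re-selection, by the standard trimmed-likelihood argument —
can only increase the trimmed objective, so the trace is monotone.

The alternation is staged: t is held at 1 until the trimmed objective
stabilizes, then released (with a per-gene ascent guard). Releasing t
from a badly initialized scale conflates scale misfit with dispersion —
t collapses, the objective flattens, and the fit freezes in a spurious
optimum far from the global one. With t held, trimming separates
perturbed from unperturbed genes first; both phases ascend the same
objective, so monotonicity survives the switch.

Residual bias: with heavy contamination (e.g. 30% of genes perturbed
8-fold) a handful of *low-count* perturbed genes still enter the retained
set (an 8-fold change on a count of ~3 is only mildly improbable),
leaving a few-percent upward bias in the recovered ratio. The untrimmed
fit (α = 1) instead follows the inflated column totals and misses such a
ratio severalfold — the trimming is what carries the robustness.

Samples with all-zero counts have no defined scale; they are excluded,
reported, and carry NaN in the output. Oscillating trim sets (cycle over
the last 4 configurations without objective improvement) terminate the
fit at the best objective seen.

## Phenotype clustering

Without labels, a binary composition over reference cells is built
agglomeratively: every cell starts as its own component (profile fitted
by the closed-form M-steps; a singleton with zero residual variance gets
the upper precision bound), and each step merges the pair whose merge
maximizes the resulting model log-density (equivalently, loses the
least), refitting the merged profile. Equal-loss ties break
lexicographically by node id, making the tree a deterministic function of
the input. BIC = −2·loglik + p·ln(n·m) is recorded at every cut, with
p = k·2m + n (an x and t per component per gene, plus the n scales) and
n·m observed entries; the same counting at every k means only differences
matter. The chosen k minimizes BIC (smallest k on ties), and the labels
at that cut feed directly into the decomposition.

Cell scale factors default to gauge-fixed column totals. The trimmed
common-profile estimator assumes all samples share one profile, which a
*mixed-phenotype* panel violates — its retained set then degenerates to
near-zero-count genes and the scales become uninformative — so it is
opt-in here (`scales="trimmed"`) rather than the default.

Above 2000 starting clusters the exact all-pairs rule becomes expensive;
columns are first collapsed by exact duplication and a coarse greedy pass
restricted to each cluster's 20 most similar neighbours (cosine on log1p
profiles) reduces the count to the threshold before the exact phase.
Both approximations are recorded in the merge history.

## Synthetic data

The generator runs the model forward and is the source of every fixture:

- **Reference profiles**: a shared log-normal baseline (sdlog 1.0) with
  per-type log-normal fold deviations (sdlog 0.7), column-normalized; or
  disjoint marker blocks (50 genes/type at mean 20 against background
  0.1) for clustering scenarios. Per-cell depths are log-normal (mean
  2000 counts, sdlog 0.25).
- **Bulk mixtures**: compositions on the simplex (Dirichlet draws in the
  cohort presets), depth 1e6; optional per-sample profile perturbation
  (log-normal fold noise, sd 0.5, on 10% of genes of the cancer
  component) provides the ground truth for profile adaptation.
- **Noise model**: t = 1 exact Poisson; t < 1 gamma-Poisson with gamma
  shape λt/(1−t) and scale (1−t)/t, making the compound variance exactly
  λ/t; t > 1 round(Poisson(tλ)/t), moment-matched approximately. The
  scaled-Poisson law has no standard sampler; matching the first two
  moments is the testable contract.
- Presets: `baseline` (3 samples, Dirichlet(2.0, 1.2, 0.8) compositions),
  `shifted-composition` (treatment-naive-like ~70% vs post-chemotherapy-
  like ~40% cancer), `perturbed-profiles`, `pure-samples`,
  `two-type-markers`, `one-type`. All randomness flows from one seeded
  generator; identical seeds give identical cohorts.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects between reference platforms, gene-length effects, or dropout
beyond the count model itself. Passing recovery tests therefore
demonstrates correctness of the estimator under its own model class, not
robustness to every artefact of real single-cell data.

## Default problem sizes

Recovery checks run at 500 genes × 3 types × 300 reference cells with
bulk depth 1e6 (composition: 20 cohorts; adaptation: 20 seeds), 1000
genes × 2 samples for scale factors (10 seeds), 2000 units for
dispersion recovery, and 100 cells for clustering (10 + 10 seeds) —
sizes chosen so a full desk-scale validation completes in minutes while
keeping the per-quantity sampling error well below the acceptance
margins.

## Known limitations

- Composition estimates are RNA fractions, not cell fractions; converting
  requires per-type RNA content, which is not identifiable here.
- Components with identical profiles are unidentifiable in their split;
  only their summed fraction is stable (the symmetric-profile unit test
  pins this behavior).
- Profile estimates for rare components (small w̄·depth) are noisy; the
  reference then dominates them.
- The proportional allocation is the exact conditional mean only at
  T ≡ 1; elsewhere it is the same approximation the estimator is defined
  with, and the exact-enumeration oracle is used in tests only at T = 1.
- Within the joint fit the precision guard permits only likelihood-
  improving (in practice: downward) precision moves; strongly
  underdispersed data are better served by fitting T standalone.
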