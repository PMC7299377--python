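# Methods

## Model

For n subjects with p concatenated multi-omic features (SNP minor-allele
dosages coded 0/1/2, continuous gene- and protein-expression values) and a
continuous trait y, the modularity-constrained Lasso minimizes

    f(w) = ½‖y − Xw‖² + (λ/2) wᵀ(λ_B I − B) w + (ridge/2)‖w‖² + θ‖w‖₁

with `B` the Newman modularity matrix of the prior trans-omic network,
`B_ij = G_ij − h_i h_j/(2m)`, and `λ_B = max_i |eig_i(B)|`.  The raw reward
−wᵀBw is indefinite (B has positive and negative eigenvalues); subtracting
`λ_B I` makes `λ_B I − B` positive semidefinite so the objective is convex.
Because every row of B sums to zero, a constant weight vector is penalty-
neutral; supports concentrated on densely connected node sets receive
`wᵀBw > 0` and are therefore shrunk *less* than scattered supports of equal
size.  The GraphNet comparator replaces `λ_B I − B` with the combinatorial
Laplacian `L = diag(h) − G` (penalizing coefficient differences across
edges); plain Lasso and elastic net drop the network term.

The trans-omic network is stored undirected: the biological relations are
directed (SNP upstream of gene, gene regulates protein), but modularity is
defined through a single degree per node, so direction is kept only as edge
metadata (`tfbs`, `interacts`, `regulates`) and G, B, L are computed on the
symmetrized graph.  B is computed once on the full prior network, not per
component.

## Solvers

* `closed_form` — solve the smooth part exactly,
  `w̃ = (XᵀX + λ(λ_B I − B) + ridge·I)⁻¹ Xᵀy`, then apply one
  soft-thresholding pass `w = S(w̃, θ)`.  One linear solve; deterministic.
  This scheme is exact when the effective design is orthonormal or when
  θ = 0; otherwise it is a fast approximation.  In particular, at p > n
  with only numerical ridge the smooth stage is a near-interpolating
  minimum-norm solution that spreads weight over correlated features, so
  the thresholded support is *not* a consistent selector.
* `proximal` — ISTA with fixed step 1/L on the composite objective, where
  L is the largest eigenvalue of `XᵀX + λ(λ_B I − B) + ridge·I`.  The
  majorization step guarantees a monotone objective; iteration stops when
  the sup-norm change falls below `tol` (default 1e−8, relative).  This is
  the exact optimizer and the mode used for support-recovery benchmarks.

Both modes share standardization (z-scored X columns, centred y — on by
default, necessary because genotype and expression features live on
incomparable scales), record the standardization for prediction, and
default to `ridge = 1e−8` purely as protection against exact singularity.
Ties in every reported ranking are broken by node/feature identifier.

## Evaluation protocol

Stratified k-fold assignment shuffles each diagnosis stratum with the run
seed and deals subjects round-robin, rotating the starting fold across
strata; within every stratum fold sizes differ by at most one.  A stratum
smaller than k triggers a recorded warning, not an error.  Nested CV picks
hyperparameters per outer fold by mean inner-fold RMSE (ties resolved
toward smaller λ, then larger θ, i.e. the sparser model) and reuses one
fold plan across all models being compared.  RMSE and MAE are reported per
fold and as arithmetic means.

The degree–weight analysis correlates node degree with |coefficient| over
the selected features, with degree taken in the subgraph induced on the
selection (full-network degree available via `scope="full"`); it refuses to
report a coefficient from fewer than three points or zero variance.

Enrichment uses the hypergeometric upper tail P[X ≥ k] (over-representation)
with Bonferroni correction over the pathways that remain testable after
restriction to the background universe, which defaults to the genes of the
prior network.  Gene symbols are matched case-insensitively.  SNP markers
map to their downstream gene neighbours, peptides/proteins to their
encoding gene (explicit map, else network neighbours).

## Synthetic cohorts

The generator emulates the data-generating structure the method assumes,
not any specific cohort:

* **Network** — genes partitioned into `n_modules` modules; each SNP
  attached upstream of exactly one gene (inheriting its module); gene–gene
  and gene–protein edges drawn with `within_module_edge_prob = 0.15` vs
  `between_module_edge_prob = 0.005`; every protein has a primary
  "encoded-by" gene drawn uniformly over genes, so module sizes scale with
  their gene counts.  The planted module is deliberately smaller than the
  rest: 15 of 150 genes, which with its attached SNPs and proteins gives
  ≈ 30 of ≈ 300 features.
* **Data cascade** — MAF ~ U(0.05, 0.5); dosage ~ Binomial(2, MAF); gene
  expression = 0.8 × Σ(parent dosages) + N(0, 1); protein abundance =
  0.8 × mean(partner gene expression) + N(0, 1).
* **Outcome** — the whole planted module is causal
  (`causal_fraction = 1.0`): w\*ⱼ = ±1 on standardized features,
  y = X_std w\* + N(0, 2).  This keeps the benchmark solvable (OLS
  restricted to the true support recovers the signs of w\* in > 95% of
  coefficients across 20 seeds) but non-trivial (SNR such that prediction
  R² ≈ 0.85 and naive dense fits over-select heavily).  Diagnosis labels
  (CN/MCI/AD) are outcome tertiles, used only to exercise stratified folds.

Presets: `default` (n = 200, 100 SNPs / 150 genes / 50 proteins, 5 modules),
`small` (n = 40, p = 30, for fast tests), `null` (`true_weight_scale = 0`).

What the generator does **not** emulate: linkage disequilibrium, population
structure, count-based RNA-seq noise, peptide-level measurement error, or
any disease model.  Passing benchmarks therefore demonstrate correctness of
the optimization and the claimed selection behaviour under the model's own
assumptions, not performance on real cohort data.

## Benchmark protocol and its rationale

Support recovery is scored **path-wise**: F1 between the true module and
the best support over the hyperparameter grid
(λ ∈ {0.01, 1, 10}, θ ∈ {10, 30, 60, 100, 150}, proximal solver — θ on the
gradient scale, since for standardized data the L1 subgradient bound
max|Xᵀy| is of order n).  The inner-RMSE-selected fit is computed and
reported alongside, but prediction-optimal L1 tuning is well known to
over-select by a factor of 2–3, which caps its support F1 near 0.5
regardless of signal strength; path-wise recovery is the standard way to
ask whether the method *can* identify the structure.  The closed-form
default grids (λ ∈ 10^{−3..2}, θ ∈ 10^{−3..1} on the coefficient scale)
remain the CLI defaults for prediction-oriented use.

The connectivity contrast runs M-Lasso at λ = n/λ_B — the strength at
which the network penalty's curvature is comparable to that of the
least-squares term — with θ = 30, and compares the prior-network edge count
of its support against a plain-Lasso support matched to the same size
(nearest-size fit on the θ grid, trimmed by |weight|).  In this regime the
modularity term visibly relocates the ambiguous tail of the support into
modules, which is the behaviour the penalty exists to produce.

Problem sizes throughout (20 seeds, n = 200, p ≈ 300, 3-fold inner CV in
the scripted benchmarks) were chosen so the full suite and the acceptance
script each run in a few minutes on a single CPU.

## Known limitations

* Single outcome only; no multi-task extension.
* The closed-form mode's support is unreliable for p ≫ n (see above); use
  the proximal mode when selection matters.
* ISTA is adequate at p ≤ a few thousand; no acceleration or screening
  rules are implemented.
* The modularity reward is global: with very strong λ it favours large
  modules wholesale, inflating supports when only part of a module is
  causal.
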