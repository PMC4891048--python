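# Methods

## Model and pipeline

The package operates on a drug x cell-line panel: a partially observed
response matrix `S` in pIC50 units (−log10 of IC50 in molar; a reader flag
accepts nM-based values, which differ by the additive constant 9), gene x
cell-line expression (log2 array-intensity scale) and copy-number matrices,
per-cell-line mutation calls labelled silent/nonsilent, binary structural
fingerprints per drug, and cancer-type / drug-target annotation. Drugs with
more than 40% missing responses are dropped at load time (boundary
inclusive: exactly 40% missing is kept); all containers are aligned to the
common cell-line set in lexicographic order for determinism.

### Collaborative filtering

`fit_cf` minimizes, over elementwise-nonnegative `U` (drugs x k) and `V`
(cells x k),

    J = || M ∘ (S − U Vᵀ) ||_F²
        + α_D tr(Uᵀ L_D U) + α_C tr(Vᵀ L_C V) + γ (||U||² + ||V||²)

with `M` the observed mask and `L_D`, `L_C` unnormalized Laplacians of the
drug-Tanimoto and cell-cosine similarity graphs (entries clipped at zero
and the diagonal zeroed before Laplacian construction, since Laplacian
regularization needs nonnegative edge weights). The Laplacian terms pull
factor rows of similar drugs/cell lines together; the small ridge `γ` keeps
the problem well posed under heavy masking.

The solver is multiplicative updates (the masked, graph-regularized variant
of the classic nonnegative-factorization updates), which preserve
nonnegativity and never increase `J`; the objective trace is stored on the
model and asserted non-increasing in the tests. A projected-gradient solver
with backtracking (`solver="pgd"`) is available as a fallback.
Initialization is uniform on (0, mean(S_obs)/√k) from the model seed, so
fits are reproducible; an explicit `init=(U0, V0)` bypasses it (used by the
permutation-equivariance tests). Convergence: relative objective change
below `tol` (default 1e−6) or `max_iter` (default 500). Defaults k = 10,
α_D = α_C = 0.1, γ = 0.01; the appropriate rank is data-dependent and
`cross_validate` selects hyperparameters by entry-wise cross-validation
stratified per drug (ties break to the first grid point).

### Evaluation metrics

`rmse` on value pairs; `c_index` as the fraction of concordantly ordered
pairs with the Harrell 0.5-credit convention for ties in either list;
`probabilistic_c_index` credits a concordant pair `Φ(|o_i − o_j|/(√2 σ))`
and a discordant pair the complement, so pairs whose observed separation is
small relative to the measurement noise σ count near 0.5 either way and the
σ→0 limit is the plain c-index; `wpc_index` averages per-drug pc-indices
under nonnegative drug weights (uniform by default, with a hook for
externally derived weight schemes).

### Sparse group lasso

`fit_group_sparse_lasso` minimizes
`||Y − X W||_F² + λ_g Σ_j ||W_j·||₂ + λ₁ ||W||₁` by block-coordinate
descent with the exact row-wise proximal update (soft-threshold then group
shrink), precomputed Gram matrices, and warm starts along the penalty path.
The derivation in the module docstring gives the exact all-zero threshold
`λ_g ≥ 2·max_j ||soft(2 x_jᵀ Y, λ₁)||₂` (the factor 2 comes from using the
unhalved squared loss), which the tests verify, along with KKT residuals at
convergence and agreement with a dense lattice search on tiny instances.
λ₁ defaults to 0, i.e. the pure group lasso; the sparse-group combination
is available. `zero_tol = 1e−8` on row norms defines "selected", safely
above solver tolerance.

`select_signatures` restricts `V` and expression to one cancer type's cell
lines (the global `V` is row-restricted, not refit), standardizes the gene
features and centers the targets — the model has no intercept, and support
recovery is invariant to a constant target shift — then picks λ either by
k-fold cross-validated reconstruction error or by closest support size to a
`target_size` (ties toward the sparser model). With fewer cell lines than
genes the exact-size support is unstable while modest supersets are
reliable, so recovery-oriented uses should budget roughly twice the
expected driver count; the recovery contract is recall (signature ⊇
drivers), not precision.

### Resistance screen

Stages, in order: (1) silent mutation records are dropped; (2) outlier
cell lines are detected separately on the CNV matrix and on the binary
nonsilent-mutation matrix as the `ceil(fraction·n)` lines (default fraction
0.10) furthest in Euclidean distance from the componentwise mean, exact
ties broken lexicographically by id, and the union is removed; (3) the
drug's remaining pIC50 values are discretized — default "quantile" method
labels the lowest `floor(q·n)` lines resistant (−1) and the highest
`floor(q·n)` sensitive (+1) with q = 0.25, a z-score method (cut 1.0) is
the alternative; (4) over the sensitive∪resistant lines, each candidate
gene's expression and CNV are Spearman-correlated with pIC50. A gene
passes iff |ρ_expr| > 0.7 AND |ρ_cnv| > 0.7 AND the two correlations share
a sign. Cutoffs are on absolute values because resistance markers can be
up- or down-regulated; the CNV cutoff is configurable down to 0
(sign-concordance only). Zero-variance genes are reported as failed with a
reason rather than silently dropped.

### Annotation

SL/SDL pairs are ordered (A→B): a pair matches a drug when gene A is among
the drug's targets and gene B in the signature set; non-redundant pair and
contributing-drug counts are reported per interaction type. Enrichment is
the one-sided hypergeometric upper tail; significance requires p < 0.05
and an overlap of strictly more than two genes (the literal reading of
"more than two"); no multiple-testing correction is applied by default, to
match the raw-p convention of the screen this follows, and both thresholds
are arguments.

## Synthetic panel generator

`simulate_panel` emulates a public-screen-like panel at desk scale.
Defaults: 30 drugs x 120 cell lines x 500 genes, rank 4, 3 cancer types,
10 driver genes per type, 5 resistance genes per drug, 4 outlier lines,
20% missing responses, response noise sd 0.1 pIC50 units.

* Expression is normal(7, 2) in log2 units (array-intensity-like), with a
  mean-shifted gene block per cancer type.
* Within each type, `V = v_base + (E − mean)ᵀ Q` with `v_base = 1`,
  a signed row-sparse `Q` supported on the drivers, and amplitude scaled to
  0.25 (≈4 sd below the baseline, so the nonnegativity clip is inactive).
  Signed loadings keep the k factor columns distinguishable; all-positive
  loadings on positively shifted expression would make them nearly
  collinear and the support unidentifiable.
* `U` is uniform nonnegative, scaled so `U Vᵀ` sits in a realistic pIC50
  range (~6).
* CNV equals scaled centered expression plus noise for a 75% coupled gene
  fraction (motivated by reported lung-cancer CNV–expression concordance
  near that level), independent noise otherwise.
* Outlier lines receive a ±3 CNV shift on a third of genes and a burst of
  nonsilent mutations; background mutation calls are sparse Poisson.
* Resistance genes (disjoint from drivers) have expression
  `7 ± 1.5·z(pIC50) + noise(0.15)` and CNV `± 0.8·z(pIC50) + noise(0.075)`
  with a shared random sign per gene, planted before the outlier
  aberration so the outlier stage genuinely disturbs them.
* Fingerprints have family block structure (shared base pattern per family
  plus 5% bit flips) so Tanimoto similarity is informative.

All randomness flows through one `SeedSequence`, spawned into fixed-order
per-stage streams: outputs are bit-identical for a given seed.

What the generator does *not* emulate: pathway co-expression structure,
linkage/segment-level CNV correlation, assay batch effects, heavy-tailed
IC50 error, or dose–response curve fitting. Passing recovery tests
therefore demonstrates correctness of the algorithms under their own
modeling assumptions, not performance on real panels.

A note on "false positives" in screen recovery: planted *driver* genes
generate the response, so their expression (and coupled CNV) legitimately
correlates with activity and they can pass the screen. Recovery tests that
assert exact planted-set recovery exclude drivers from the candidate pool;
the false-positive-rate tests over all genes bound the rate at 1%.
Recovery tests also plant resistance genes for the focal drug only: with
planting across all drugs, the drugs' mutually correlated responses make
genes planted for one drug genuine hits for another.

## Problem sizes and test design

Tests run on small instances chosen so each property is sharply decided:
factorization recovery at 20x30 rank 2, group-lasso recovery at n = 60,
h = 500, |support| = 10, SNR 10, screen recovery at 80 lines x 300 genes
over 20 seeds, brute-force oracles at n ≤ 6 (c-index) and universes ≤ 15
(enrichment). `scripts/acceptance.py` uses a 20 x 100 x 400 panel for
prediction quality and the same screen conditions as the tests, and
derives all stream seeds from its `--seed` argument.

## Known limitations

* The factorization objective is one standard reading of
  similarity-regularized collaborative filtering; other weightings of the
  Laplacian terms (e.g. normalized Laplacians) would change the fitted
  factors.
* The pc-index noise model is a Gaussian pair-weighting; external
  challenge-specific weighting schemes can be supplied as drug weights but
  are not re-derived here.
* Activity discretization offers two declared methods (quantile tails,
  z-score); both are distribution-aware but simple, and the tail fraction
  q = 0.25 is a convention, not a fitted quantity.
* `select_signatures` reuses the globally fitted `V` restricted to a
  cancer type; refitting the factorization per type is possible upstream
  but not automated.
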