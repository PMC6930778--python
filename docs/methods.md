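# Methods

## Model and procedure

The pipeline targets a two-cohort design. A **cross-sectional cohort**
(cases with the disease versus controls) establishes which genes are
differentially expressed and in which direction; a **longitudinal cohort**
(patients under treatment, split into responders and nonresponders, sampled
at T ordered time points) establishes which of those genes change
monotonically over treatment. The two are joined by the discordance rule: a
gene that is underexpressed in disease and rises monotonically under
treatment (or overexpressed and falls) is moving back toward control levels
and is called a *good response* gene; a gene moving further away is a *bad
response* gene.

### Stage 1 — moderated t-test

For gene g with group sizes n₁, n₂ and pooled variance s²_g on
d = n₁ + n₂ − 2 residual degrees of freedom, the empirical-Bayes moderated
statistic is

    s̃²_g = (d₀ s₀² + d s²_g) / (d₀ + d),
    t_g  = (x̄₁ − x̄₂) / (s̃_g √(1/n₁ + 1/n₂)),

referred to a t distribution with d₀ + d degrees of freedom. The prior
(d₀, s₀²) is estimated by moment matching on z_g = log s²_g: since
marginally s²_g/s₀² ~ F(d, d₀),

    E[z] = log s₀² + ψ(d/2) − log(d/2) − ψ(d₀/2) + log(d₀/2),
    Var[z] = ψ′(d/2) + ψ′(d₀/2),

so ψ′(d₀/2) is the empirical variance of z minus ψ′(d/2), inverted with a
Newton iteration on the trigamma function. If the empirical variance does
not exceed ψ′(d/2) — no evidence of gene-to-gene variance heterogeneity —
d₀ = ∞ and every gene is tested against the common variance s₀². Genes with
zero sample variance are excluded from the moment matching (their log
variance is undefined) but still receive a positive moderated variance
whenever d₀ > 0. Fewer than four informative genes also collapse to d₀ = ∞,
with a logged notice. A `plain_t` switch replaces the moderated statistic
with the ordinary pooled-variance t for diagnostics.

Directions are fixed as *case minus control*: "up" means overexpressed in
disease. No fold-change filter is applied; selection uses only the
Benjamini–Hochberg adjusted p (step-up, delegated to statsmodels) at the
default cutoff 0.1 — deliberately less stringent than 0.05 because the
longitudinal cohort it feeds is small.

### Stage 2 — network weighting

Per longitudinal sample, the weighted expression solves
(I − dWD⁻¹) r = (1 − d)·exp over the genes under consideration. The columns
of WD⁻¹ sum to 1 (connected genes) or 0 (isolated genes), so the spectral
radius of dWD⁻¹ is at most d < 1: the system is nonsingular, the Neumann
series r = (1 − d)Σ(dWD⁻¹)ᵏ exp converges, and nonnegative expression gives
nonnegative ranks — which is why the readers reject negative intensities at
the boundary. D⁻¹ entries for degree-0 genes are defined as 0; their whole
row reduces to r = (1 − d)·exp and they are kept, so the DEG set is
preserved end to end.

By default W is the *induced subgraph on the DEG set* (`rank_scope="degs"`):
the screen operates on DEG-dimension vectors, and restricting first keeps
the weighting interpretable as a blend of the DEGs among themselves. The
alternative (`rank_scope="full"`) ranks within the full network and subsets
afterwards; both modes are exposed because either reading of the procedure
is defensible. Expression is not rescaled per sample before ranking; raw
log2 intensities enter the system directly.

The production solver is one sparse LU factorization per system, reused
across all sample columns, with a single refinement step guarding the
residual contract ‖(I − dWD⁻¹)r − (1 − d)exp‖∞ ≤ 1e−10·max(1, ‖exp‖∞). A
Jacobi fixed-point iteration (r ← (1 − d)exp + dWD⁻¹r) is retained as an
independent cross-check, never the production path.

### Stage 3 — across-time screen

Within one response group, each gene's weighted values are compared across
time points with a Kruskal–Wallis test (mid-ranks, standard tie correction,
chi-square approximation on T − 1 df; delegated to scipy with the all-tied
input mapped to H = 0, p = 1). BH adjustment runs over exactly the genes
tested within that group, never pooled across groups; adjusted p < 0.1 flags
a gene. The test deliberately ignores the pairing of repeated measures
within a patient, mirroring the original screening procedure; a
patient-blocked Friedman test (`screen_method="friedman"`) is exposed as a
clearly labelled deviation for sensitivity analysis. Exact small-sample
permutation p-values are out of scope.

### Stage 4 — monotone filter

For the flagged genes only, the per-timepoint means w̄₁…w̄_T are classified:
monotonically increasing (MIE) if every consecutive difference ≥ −ε with at
least one > ε; monotonically decreasing (MDE) symmetrically; otherwise
`none`. ε defaults to 0. The printed inequalities are non-strict, so a fully
constant chain satisfies both at once; such a gene is labelled `none` — this
convention is a design choice, adopted because a constant gene exhibits no
trend to classify (and exact floating-point ties are measure-zero on real
data anyway).

### Stage 5 — classification

`good` iff the monotone direction differs from the DEG direction (an XOR:
flipping exactly one direction flips the class). Output is sorted
good-before-bad, then by gene symbol. Group sizes are never enforced — the
9/9 responder/nonresponder split of the motivating study is data, not
algorithm; sizes are reported in the run log. The screen's alpha is a flag
rather than a constant because borderline genes appear at 0.2 that are
absent at 0.1.

## Synthetic-data generator

The generator emulates the study design, not microarray physics: nonnegative
log2 intensities with Gaussian noise (sd 0.5 by default) around a baseline
of 8.0; 26 cases vs 18 controls cross-sectionally; two response groups of 9
patients at 5 ordered time points longitudinally; an Erdős–Rényi interaction
network (edge probability 0.05) with a forced isolated subset (10%) to
exercise the degree-0 branch. A fraction `de_fraction` (default 0.1) of
genes is planted as DE with a ±1.0 log2 shift in cases, split between up and
down; planted monotone genes follow population means baseline + k·trend_step
(default 0.5 per time point, k = 0…T−1). Real sampling times are unevenly
spaced but enter the analysis only as ordered categories, so the generator
uses indices 0…4. Values are clipped at 0 (with a logged warning) rather
than rejection-sampled, guaranteeing the weighting precondition. One seed
drives four named substreams (network, cross-sectional, longitudinal,
trend-to-DEG linking), so identical configurations give byte-identical
outputs and each piece can be regenerated independently.

In full-study mode the monotone trends are planted *on the planted DE
genes*, so the funnel DEG → flagged → MEG → classification is exercisable;
`generate_longitudinal` also accepts an explicit planting map for
constructed scenarios (e.g. all-good-response structure).

What the generator does **not** emulate — probe-level effects, batch
effects, dropout, correlated noise, heavy tails, scale-free network
topology — bounds what passing tests show: recovery rates measured here
(≈93% sensitivity for planted monotone genes at trend 0.5 / noise 0.5, 100%
direction agreement, essentially zero MEGs under the null) are calibrated to
this Gaussian model, not to microarray reality.

## Numerical and interface choices

- Trigamma inversion: Newton from x = 0.5 + 1/y (the function is positive,
  decreasing, convex), with asymptotic shortcuts for extreme arguments; the
  test oracle uses plain bisection instead.
- All tables are TSV with `#` provenance comments (package version, config
  hash over the scientific parameters only, seed); floats at repr precision
  so write∘read is the identity. Readers reject duplicate identifiers,
  missing or non-numeric cells, negative intensities and self-loop edges,
  naming the offending row/column; duplicated undirected edge pairs collapse
  to one edge.
- An empty DEG set terminates the pipeline gracefully with empty downstream
  tables and a logged notice. A network sharing no identifiers with the
  expression matrix is rejected with the overlap size, since it almost
  certainly indicates mismatched namespaces rather than a sparse graph.
- Default problem sizes (150 genes; 10 recovery seeds and 20 null seeds in
  the acceptance checks) are chosen so the whole suite runs in well under a
  minute while leaving the planted/null contrast unambiguous.

## Known limitations

- The Kruskal–Wallis screen treats repeated measures as independent; the
  Friedman option quantifies, but does not remove, this simplification.
- The empirical-Bayes moment matching assumes equal residual df across genes
  (true for complete two-group designs, the only design supported).
- Monotonicity is assessed on means only; a gene could be monotone in means
  yet wildly variable per patient. The screen's KW gate mitigates but does
  not eliminate this.
- Good/bad classification is binary and direction-based; it does not measure
  how far expression returns toward control levels.
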