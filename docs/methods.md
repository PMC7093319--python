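# Methods

This note documents the models, defaults, and numerical choices behind
`prsnet`, and what the synthetic-data tests do and do not establish.

## Data model

A cohort is a subject-by-variable table: p ordinal symptom items scored
0–3 plus one continuous risk-score column.  The generative model behind
both the synthetic-data module and the estimation theory is the
**latent-Gaussian threshold model**: a multivariate normal vector with
unit variances and a sparse precision matrix κ; each symptom item is the
latent variable cut at three ordered thresholds into four levels; the
risk column is the latent variable itself.  Under this model, rank-based
(Spearman) correlations of the observed data consistently estimate a
monotone transform of the latent correlations, which is why the pipeline
feeds Spearman matrices into the Gaussian likelihood.

**What the generator emulates**: the dimensions and scale types of a
psychosis-spectrum cohort (the `cape_like` preset: 42 items in domains
of 20/14/8, skewed item marginals with level probabilities
0.55/0.25/0.13/0.07, n = 2180, four weak direct risk→symptom partial
correlations of 0.07–0.10, denser within-domain than between-domain
connectivity, 0.12 vs 0.03 edge probability).  **What it does not
emulate**: item-specific marginal shapes beyond the two threshold
presets, missing-data structure other than MCAR, measurement error
beyond discretization, cohort substructure (patients/relatives/controls
are not distinguished), and any genetic architecture — the risk score is
drawn directly as a continuous latent variable.  Consequently, passing
tests show the *pipeline* recovers what was planted under its own
assumptions; they say nothing about unmodeled features of real cohorts.

Two systematic effects of discretization matter when interpreting
results on the synthetic truth scale:

1. **Attenuation** — rank correlations of discretized variables shrink
   toward zero (≈ ×0.75–0.85 for 4-level items); planted weights are
   recovered on this attenuated scale, so weight-recovery tests compare
   against an attenuated oracle estimated once at very large n.
2. **Null distortion** — because attenuation differs across pairs, the
   inverse of the Spearman matrix carries small nonzero values
   (≲ 0.02 in the population limit at the default weight ranges) on
   planted-null entries.  This bounds how clean structure recovery can
   be and is the reason weak spurious edges occasionally survive BIC at
   n in the thousands.

### Positive-definiteness repair (generator)

Target partial correlations are written into a unit-diagonal precision
matrix (off-diagonal −ρ).  If the smallest eigenvalue falls below 1e−6,
all off-diagonal entries are shrunk by a common factor (0.95 per step)
until it does not; the cumulative factor is recorded and the *realized*
partial correlations, recomputed from the final precision, become the
ground truth.  This repair is deterministic and transparent, unlike
rejection sampling.

## Estimation

**Input correlations.**  Pairwise-complete Spearman with average ranks;
with no missing cells all columns are ranked once and correlated in one
pass, otherwise each pair is re-ranked on its complete cases.  The
effective sample size is the *minimum* pairwise-complete count
(conservative: all likelihood and threshold formulas use it).  A matrix
that is genuinely indefinite is projected to the nearest correlation
matrix (eigenvalue clipping at 1e−8, re-standardization) and flagged;
singular-but-PSD matrices (e.g. perfectly monotone column pairs) are
left untouched.

**Constrained maximum likelihood.**  The GGM MLE under a fixed edge
pattern maximizes (n/2)(log det K − tr(S K)) with K zero on excluded
pairs, by block-coordinate ascent on the model-implied covariance W:
for each variable, the free entries of its column are matched to S over
its neighborhood (one small linear solve per variable per sweep).  At
convergence the moment conditions hold — (K⁻¹)ᵢⱼ = Sᵢⱼ on modeled pairs
and the diagonal, Kᵢⱼ = 0 elsewhere — and the fit refuses to return if
the largest violation exceeds the tolerance (default 1e−10).  Additive
constants are dropped from the log-likelihood consistently, so BIC
*differences* are exact; parameter count is p + (number of edges).

**Stepwise search (`modselect`).**  Initialized from the EBIC (γ = 0.5)
winner along the graphical-lasso path (or from the empty graph); each
sweep evaluates all single-edge toggles with warm-started refits at a
screening tolerance (1e−5) and the best move is confirmed by a
full-tolerance refit before acceptance, so the recorded BIC sequence is
strictly decreasing regardless of screening error.  Ties prefer
removal, then the lexicographically smallest pair — the search is fully
deterministic.  A candidate move's refit failure names the offending
edge.

**EBIC path (`ebic_path`).**  100 penalties log-spaced from λ_max (the
largest absolute off-diagonal of S, which empties the graph) down to
λ_max/100.  Each *distinct* nonzero pattern along the path is refit
without penalty and scored by EBIC = −2ℓ + k log n + 4γ k log p;
scoring refits rather than penalized fits avoids the shrinkage bias
that otherwise favors dense small-λ models.  The winning pattern's
unpenalized refit provides the reported weights.

**Threshold (`threshold`).**  Saturated partial correlations from S⁻¹;
edge (i,j) kept iff |atanh ρ|·√(n − (p−2) − 3) exceeds the two-sided
normal critical value (default α = 0.01), with p the number of nodes
and p−2 the conditioning count.  Retained edges keep their saturated
values; the reported log-likelihood/BIC come from the retained
pattern's ML refit so all three estimators are comparable on fit.

## Path analytics

Edge traversal cost is 1/|ρ| — strong associations are short.  Levels
of the predictive path diagram use *unweighted hop counts* (matching
the recursive "neighbors of neighbors" definition), while shortest
pathways use the weighted distance; the two are reported separately.
All tied shortest paths are tracked (Dijkstra predecessor DAG);
betweenness uses Brandes-style fractional credit (1/m per tied path)
by default, with a binary membership rule available for sensitivity
analysis.  Negative edges are traversable via |ρ| but flagged on every
path that uses one, and can be excluded entirely; association sign does
not affect path existence, only interpretation.  All analytics are
invariant to positive rescaling of the weight matrix.

## Bootstraps

Nonparametric: resample n rows with replacement, re-run the full chain
(Spearman → estimator → betweenness), summarize per-edge quantiles and
inclusion proportions and per-node betweenness quantiles.  Case-drop:
for each drop fraction q, re-estimate on n − ⌊qn⌋ rows and rank-correlate
the betweenness profile with the full-sample profile; the CS-coefficient
is the largest q with ≥95% of correlations ≥0.7.  Conventions: at q = 0
the subsample *is* the full sample, so the correlation is 1 by
construction; for q > 0 a constant profile on either side yields 0 (rank
correlation undefined).  Child seeds derive from the master seed and
resample index via `SeedSequence` spawn keys, so summaries are
reproducible and independent of execution order; failed resamples are
excluded with explicit counts, never silently.  Default B = 1000
(nonparametric) and a 10-point drop grid up to 0.75 (B = 100), following
common practice.

## Problem sizes and defaults

The cohort-scale configuration exercised by the test suite and the
acceptance script uses the `cape_like` preset at its full n = 2180 and
43 nodes with the stepwise-BIC estimator for the main network (a single
fit evaluates ~900 candidate refits per accepted move), and the
thresholded-partial-correlation estimator inside the bootstrap stages
(B = 200 nonparametric; 4-point drop grid, B = 20 per point).  Running
hundreds of stepwise searches at p = 43 is a long offline job by design;
the per-stage estimator override is an explicit configuration field, and
small-p bootstrap tests do use the stepwise estimator throughout.

## Known limitations

- Polychoric/polyserial input correlations are not implemented (rank
  correlations only), and edges are not moderated by the risk score.
- The stepwise search takes the single best move per sweep; other
  stepwise variants (all-improving moves) can reach different local
  optima of BIC.  Results are labelled with the estimator and settings.
- Inclusion proportions and CS-coefficients are descriptive stability
  summaries, not significance tests.
- The generator's MCAR missingness and preset thresholds are
  simplifications; see the emulation caveats above.
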