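# Methods

## Data model and normalization

A study holds one items × participants rating matrix per domain.  Raw
scales are `raw_monetary` (subjective prices) or `raw_rank` (within-block
ranks, 1 = most preferred).  The pipeline first orients all responses so
that larger means more preferred (ranks are negated), then z-scores each
participant's column within each domain using the population SD.  Missing
responses are explicit NaN and are excluded from every mean, correlation
and fit; item-level train/test splits (default 75/25) move whole rows so
the same items are held out for every participant.

Two normalization choices deserve note:

* **Per-participant centering.**  The domain-level z-score is applied per
  participant column, not pooled over the domain: the CF formula and the
  similarity measure both center per participant, and pooled centering
  would leave participant offsets that double-count.
* **log10 for monetary responses (default on).**  Prices spanning
  JPY 100–10⁷ are log10-transformed before z-scoring.  Beyond robustness
  to the extreme right tail, there is a structural reason: the Pearson
  correlation of two log-normal variables is a *convex* function of their
  latent correlation, so on a multiplicative scale a cohort with
  symmetric ± latent correlations acquires a spurious positive mean
  correlation (Jensen's inequality).  The log transform restores a scale
  on which the analysis is linear in the latent response.  It can be
  disabled (`zscore_normalize(..., log10_monetary=False)`).

## Predictors

**Neighborhood CF.**  `r̂_ui = r̄_u + Σ_v sim_uv (r_vi − r̄_v) / Σ_v |sim_uv|`
over all other participants with an observed response (no k-NN truncation;
there is no principled cutoff, and the learned-weight model handles
sparsity).  On normalized data the `r̄` terms are zero.  If the similarity
mass is zero the prediction falls back to `r̄_u` and the event is logged.

**SLIM.**  `min ½‖A−AW‖²_F + (β/2)‖W‖²_F + λ‖W‖₁, W ≥ 0, diag(W)=0`.
The problem is column-separable: participant u's column of W is a
nonnegative elastic-net regression of u's responses on all peers'
responses, with the self column excluded (this enforces the zero diagonal
exactly and is equivalent to the joint problem).  The solver is
scikit-learn's coordinate descent; since `ElasticNet` minimizes
`1/(2m)‖y−Xw‖² + α l₁‖w‖₁ + α(1−l₁)/2‖w‖²`, the mapping is
`α = (β+λ)/m`, `l₁ = λ/(β+λ)` (m = rows used by that column).  The
`β = λ = 0` corner uses `scipy.optimize.nnls`.  Solver tolerance is 1e-8
with up to 20,000 iterations; the tests verify per-column objectives
against an independent projected-gradient solver (1e-4 relative) and
first-order KKT residuals (≤ 1e-3).

**Prediction and the self-exclusion guarantee.**  `r̂_ui = Σ_{v≠u} W[v,u] r_vi`
over peers' observed target responses.  The diagonal of W is masked *at
prediction time*, so even externally manipulated weight matrices (as in
the permutation test, where a row permutation can move mass onto the
diagonal) can never leak a participant's own response into their
prediction.  This masking is what keeps the permutation null calibrated.

**Hyperparameter search.**  Decade-spaced grids, β ∈ [10⁻⁴, 10¹²] and
λ ∈ [10⁻³, 10²] (17 × 6 pairs), with repeated half-splits of the training
items (default 20 repeats); the selection metric is the Fisher-averaged
per-participant correlation (MSE selectable).  Multi-cohort study runs
use reduced grids (4 β × 3 λ, 2–3 repeats) — the selected optima on these
synthetic cohorts sit in the interior of that reduced range, and the
sweeps repeat the fit hundreds of times.

## Evaluation and statistics

* Per-participant Pearson r between predicted and observed held-out
  responses; participants with undefined correlations (zero-variance
  predictions, < 3 observed test items) are excluded from the group
  average and logged.  Group r = `tanh(mean(atanh(r)))` with r clipped at
  ±(1 − 10⁻⁷) to keep the transform finite.  MSE is computed on the
  normalized scale and pooled over participant-item pairs.
* Paired condition comparisons: two-tailed paired t-test
  (`t = d̄/(s_d/√n)`, sample SD) on Fisher-transformed correlations or on
  per-participant MSE.
* Permutation test: W is fit on all source-domain items (no split);
  predictions cover all target items; each of B (default 1,000)
  iterations permutes the rows of W — peer identities — and re-scores.
  `p = #(null ≥ observed)/B`; an add-one convention `(1+#)/(B+1)` is used
  for calibration studies, where raw p = 0 breaks uniformity.  Row
  permutation preserves each column's weight multiset; per-column and
  whole-matrix entry shuffles are selectable alternatives.

## Synthetic cohorts

The generator emulates a 37-participant study (9 male, 28 female) with
art 400 / faces 80+80 / scene 400 items.  Participant u carries a shared
trait `p_u ∈ R^k` (k = 8, i.i.d. standard normal); the effective trait in
domain d is

    q_du = c·p_u + γ·g_{gender(u),d} + √(1 − c² − γ²)·e_du

with per-(gender, domain) directions g and independent domain-specific
residuals e.  Item attributes are i.i.d. standard normal k-vectors; the
latent response is `⟨q_du, a_dj⟩ + σ·ε` (default σ = 0.3, small relative
to the √k signal scale).  Defaults c = 0.7, γ = 0.3 give moderate
cross-domain transfer and a visible gender-block motif in the similarity
matrices.

Raw-scale transforms mimic the tasks.  Monetary: a per-participant
exponential map `price = 10^(4 + 0.4·z)` clipped to [10², 10⁷] (median
anchored at the task's 10,000 start value; the 0.4 decades/SD slope gives
a realistic ~1.5-decade typical spread — a much steeper map would make
the multiplicative distortion, not rank coarsening, the dominant
information loss).  Ranks: within consecutive blocks of 80 items,
descending rank of the latent response, ties broken by item order.

An optional `opposite_gender_attraction` component models the
attractiveness-gap account of gender effects: when rating the
opposite-gender face set, a shared consensus direction of strength a
*displaces* invariant-trait share (`c_eff = √(c² − a²)`), so those
responses carry less of the transferable trait.  With a = 0 the two face
subsets are statistically exchangeable — a scalar gender modulation alone
cannot produce a same/opposite asymmetry, which is why the null
calibration of the gender contrast holds exactly there.

A second generator (`generate_feature_linked_cohort`) produces ratings
linear in observable item features with per-domain feature-to-trait maps:
with disjoint maps, feature regression cannot transfer across domains
while the inter-subject structure is fully preserved — the construction
behind the feature-baseline comparison.

**What the generator does not emulate.**  Real cohorts share substantial
taste consensus (positive mean inter-subject correlation); here traits
are zero-mean, so absolute similarity levels and the nonnegative model's
small-signal behavior differ from real data (below).  Sequential rating
drift, block-order effects, and within-session noise correlations are
absent.  Passing tests therefore certify the machinery and its
statistical calibration, not empirical effect sizes.

## Feature baseline

Per participant, ridge regression maps item features to responses.
Features are standardized per column and the response centered using
source-domain statistics; α ∈ [10⁻³, 10⁴] (decade grid) is selected by
leave-one-item-out CV via the closed-form hat-matrix identity
`e_i = (y_i − ŷ_i)/(1 − H_ii)` (exact under these conventions; verified
against explicit refits to 1e-8).  Cross-domain use refits on all source
items at the selected α and applies the model to the target domain's
features.

## Known limitations and estimator behavior

* **SLIM is insensitive to weak shared structure in zero-consensus
  cohorts.**  Nonnegative weights cannot exploit anti-correlated peers,
  and in a cohort whose latent similarities are symmetric around zero
  roughly half the informative relations are negative.  Measured on this
  generator, SLIM's cross-domain group r is indistinguishable from zero
  for c ≤ 0.25 and rises steeply above c ≈ 0.5, while the signed
  neighborhood predictor recovers the trait from c ≈ 0.25 on
  (`analysis/08_consistency_recovery.py` prints both curves).  The
  consistency-recovery property is therefore asserted on the
  neighborhood estimator, with levels compared on common cohort seeds
  (paired Monte-Carlo design); SLIM remains the predictor for the
  headline conditions, permutation and ablation analyses, where its
  signal is strong.
* The second-order (inter-domain) correlation is attenuated by
  similarity-estimator noise: with 80-item domains the ceiling under
  identical traits is ≈ 0.92, reaching ≥ 0.95 only at ~400 items.
* MSE comparisons across transfer conditions are sensitive to
  prediction-variance (weight-norm) differences; correlation-based
  contrasts are the stable readout for the gender analysis.
* Problem sizes in the shipped sweeps (cohorts per level, permutation
  B = 200 in calibration studies, reduced grids) are the package's
  default study sizes; all are configurable upward.
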