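# Methods

## Data structure and likelihood

A sequential lineup of I faces with a stopping rule yields one categorical
observation per witness: "first yes at position i" (i = 1..I, optionally
split into K ordered confidence levels) or "rejected all".  Because lures
are exchangeable there are I+1 distinguishable conditions — target shown at
position h = 1..I, or target absent — and the data form an
(I·K + 1) × (I + 1) count matrix with (I+1)·I·K non-redundant cells.
Conditions are modeled as independent multinomials; the fit statistic is
the deviance against the saturated model, G² = 2·Σ O·ln(O/E), which is
asymptotically χ² with (I+1)·I·K − p degrees of freedom for a p-parameter
model.  Zero observed cells contribute nothing; a structural zero under a
positive count is an error, not a silent infinity.

## The SDT model family

Latent strengths are Gaussian.  The anchoring is symmetric: lures at
−μ_T,i, targets at +μ_T,i, with the lure variance σ²_L = 1 as the unit of
the scale and σ²_T free.  Position effects enter through factors α_i on the
means (α_1 = 1) and ξ_i on both variances (ξ_1 = 1).  Criteria τ_0,i are
compared to the strength of the face at position i; in the shift-kernel
variants a previously *rejected* target moves the criterion to
τ_0,i + δ·exp(λ(h−i)), an effect of size δ decaying geometrically with lag
at rate λ ≥ 0 (δ may take either sign).  The factorial crossing of
{τ1, τ2, τ3, τ4} × {∅, μ1, σ1, μ2, σ2} gives twenty binary models with
3–15 free parameters.

Confidence ratings partition the "yes" region with ordered criteria built
from nonnegative increments: τ_k,i = τ_0,i + Σ_{m≤k} κ_m,i.  After a target
rejection the increments rescale as κ*_m,i,h = κ_m,i · ω·exp(η(h−i)) ·
exp(−γm).  Setting (ω, η, γ) = (1, 0, 0) shifts the whole criterion ladder
rigidly by the binary kernel.  The two-component mixture replaces a
fraction 1 − π of responses with an "unserious" process that always picks
the first face, with confidence distributed as
exp(−ζk)/Σ exp(−ζk′) — for ζ = 0.89 and K = 4 that is (.61, .25, .10, .04).

Uncensored (no-stopping-rule) sequences are products of per-position
terms in which positions up to and including the first "yes" follow one
parameter set and later positions another; marginalizing the 2^I sequence
probabilities to the first-"yes" position recovers the censored model
exactly.  This identity is what makes "within-subjects" analyses of full
sequences a superset, not an alternative, of censored-sequence analyses.

Discriminability is summarized by the unequal-variance index
d_a = (μ_T,i − μ_L,i) / sqrt((σ²_T,i + σ²_L,i)/2).

## Estimation

Free parameters live on an unconstrained scale: log transforms for
variances, factors, κ, ω, ζ and λ; a logistic transform for π; criterion
order by construction (cumulative nonnegative increments), which also
implements the monotone-criteria restrictions.  Log-scale values are
clipped at ±700 so optimizer excursions stay finite.  Probabilities are
computed with vectorized normal log-CDFs; survival products are
accumulated in log space so extreme criteria cannot underflow.

Optimization is multistart L-BFGS-B (objective tolerance 1e-10, numerical
gradients) from seeded scattered starts around a mildly informative
anchor, with the best optimum polished once more.  The shift-kernel models
are mildly multimodal — the binary likelihood for the free-criteria kernel
model has two modes along a very flat σ²_T ridge (near σ²_T ≈ 0.5 and
σ²_T ≈ 1, about 1.2 deviance units apart) — so headline fits use ≥ 20
restarts; simulation studies use 2–3 restarts plus warm starts (nested
fits start from the parent solution, joint two-group fits from the
averaged separate solutions), which also keeps likelihood-ratio statistics
nonnegative.  Fits are deterministic given (options, seed).

Monotone-criteria restrictions reparameterize rather than remove
parameters, so their comparisons report the raw deviance difference; the
usual χ² calibration does not apply to such order constraints.

## Synthetic data

`simulate_table` draws independent multinomials from any model's cell
probabilities — the homogeneous-witness idealization used for power and
recovery studies.  `simulate_population` instead samples one (μ_T, τ_0)
per witness — point values, uniform ranges, or criteria placed where the
target/lure likelihood ratio equals a drawn value (closed form
ln(LR)·σ²/(2μ_T) under equal variances, numerical root otherwise) — and
walks each witness through the lineup with fixed parameters.  Its default
scenario set reproduces the three published heterogeneity scenarios
(τ_0 ~ U[−0.25, 1] with μ_T = 0.75; plus μ_T ~ U[0.10, 1.40]; plus
likelihood-ratio placement with LR ~ U[0.75, 2]).  An optional contaminant
class always chooses face 1.  `simulate_uncensored` samples full 2^I
sequences with distinct pre/post-first-"yes" regimes.  All generators
derive per-condition substreams from a single seed, so adding conditions
never perturbs earlier ones.  The witness-total split across the I+1
conditions is equal by default; the sign-of-effect conclusions do not
depend on that allocation.

What these generators deliberately do not emulate: stimulus ("item")
effects, response times, within-lineup dependence beyond the criterion
kernels, and trial-order learning beyond the pre/post regimes.  Passing
tests therefore validate the estimation machinery under the model's own
assumptions, not the model's adequacy for any particular real dataset.

## Simulation studies

Default generating parameters are the published confidence-data estimates
of the free-criteria kernel model (μ_T = 0.77, σ²_T = 0.51,
τ_0 = 0.13/0.22/0.08/0.05/0.20/0.25, δ = 1.04, λ = 0.49), which define a
realistic operating point.  Study defaults: position-effect (DFD) power
studies use the pooled study's condition sizes (709/696/691/699/696/701
target-present, 4151 target-absent); the two-group study uses 500 or 1000
responses per condition per group, a 10% reduction of μ_T and/or ±0.20
criterion shifts; d_a recovery draws μ_T ~ U[0.2, 1.4] and σ²_T ~
U[0.3, 1.2] at 100 or 1000 responses per condition; selection-bias
populations use 100,000 witnesses.  Tests are likelihood-ratio at p < .05
throughout.  In the two-group study each equality hypothesis is tested
against the fully free two-group model: discriminability block (μ_T, σ²_T)
on 2 df, criteria block (τ_0, δ, λ) on 8 df.  Because the package's
confidence-criterion increments for generating confidence-rating data are
a package default (equal spacing, κ = 0.35) rather than published values,
confidence-mode power results are indicative, not reproductions.

The uncensored-sequence diagnostics are the i.i.d. test — a G²
independence test of "yes"/"no" at position i against the 2^(i−1)
preceding histories (empty strata dropped with a warning, df adjusted) —
and the pre/post-first-"yes" SDT analysis, which pools hit/false-alarm
pairs per (position 2..I, stratum) and fits a conventional unequal-variance
yes/no model (lures N(0,1)) with stratum-specific (μ, σ²) and per-pair
criteria, reporting d_a and mean-criterion differences with LR tests.
Degenerate empirical proportions are handled by the binomial likelihood
itself; reported empirical points use a 0.5/(n+1) continuity adjustment.

## Expected utility

A procedure's outcome triple (hit / known-lure false alarm / miss in
target-present; known-lure false alarm / innocent-suspect false alarm /
correct rejection in target-absent) combines with outcome utilities into
U(p) = p·Σ P_TPi·U_TPi + (1−p)·Σ P_TAi·U_TAi, affine in the prior
probability of guilt p, so procedure crossovers solve a linear equation
exactly.  The target-present rates are unweighted means over target
positions (positions treated as equiprobable); the target-absent "yes"
rate splits 1/I to the designated innocent suspect and (I−1)/I to known
lures.  Default utilities (2, −5, −1, −1, −20, 2) encode that implicating
an innocent suspect is by far the worst outcome; they are illustrative,
not normative, and are fully configurable.  The showup and
no-stopping-rule outcome triples ship as published data (their raw counts
are not available); the stopping-rule lineup triple is computed from the
packaged table and matches the published column at printed rounding.

## Known limitations and deviations

* On the packaged binary data our multistart fits find optima equal to or
  better than previously reported values.  Three reported quantities are
  not reproducible at their printed values under the model as stated: the
  free-criteria kernel model's G² (we find 42.7 at the global mode — whose
  estimates coincide with the published confidence-data estimates — vs 44
  at the σ²_T ≈ 1 local mode), and the two monotone-criteria deviance
  differences (our verified restricted-model optima imply 43.4 and 53.6 vs
  reported 38.6 and 48.4, values that are infeasibly small for the stated
  restriction).  The zero-decay test reproduces (15.80 vs 15.82).
* The criteria-equality columns of the two-group study have lower power
  here (~30–35%) than reported (71–99%): under symmetric lure anchoring a
  uniform criterion shift is largely absorbable by the free
  discriminability block.  The discriminability-equality column, the
  study's headline, reproduces (≈90–92% at n = 500).
* d_a recovery at n = 100 yields rank correlations around 0.93–0.95,
  slightly above the reported 0.91, consistent with the optimizer
  differences above.
* Binary-judgment σ²_T is weakly identified (the flat ridge); interpret
  binary-only σ²_T and the derived d_a with care, and prefer
  confidence-rating designs when discriminability is the estimand.
* Published AIC/BIC table values are consistent with being derived from
  integer-rounded G²; `FitResult` reports exact values.
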