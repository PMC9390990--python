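# Methods

This note documents the model, the estimation machinery, the synthetic
study designs, and the numerical choices behind `beliefnet`, in the spirit
of a statistical package's methods appendix.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model

A person's attitude toward one topic is a network of K beliefs
`b ∈ [−1, 1]^K` (moral concerns plus perceived beliefs of social contacts
and information sources).  Three constructs are defined on it:

* **Ties** `ω_ij`: partial correlations between beliefs controlling for all
  others; symmetric, zero diagonal.
* **Belief-specific dissonance** `H_i = Σ_{j≠i} ω_ij |b_i − b_j|`, and the
  configuration dissonance `H(b) = Σ_i H_i` (each unordered pair counted
  twice; person-level scores default to the pairwise-once sum `H(b)/2`,
  which changes no downstream correlation).  Negative ties make
  disagreement consonant: `H_i` can be negative.
* **Interdependence** `β ≥ 0`: inverse-temperature analogue; any process
  (attention, deliberation) that suppresses randomness among beliefs.

Dynamics: single-node Glauber updates.  A proposal `b_i → b_i'` drawn
uniformly from the grid of admissible values (excluding the current one) is
accepted with probability `1/(1 + exp(β·ΔH))` where `ΔH` is the resulting
change in `H(b)`.  The stationary distribution is `P(b) = exp(−β·H(b))/Z`,
which `boltzmann_exact` enumerates for small K.  There is no external-field
term; an intervention is modeled as an exogenous additive shift of selected
nodes.

### Energy conventions (a deliberate reconciliation)

Two textually natural conventions disagree by a factor of two: the node-sum
energy `H(b) = Σ_i H_i` counts each pair twice, while the node-level change
`ΔH_i` counts the affected pairs once.  A chain that plugs the node-level
`ΔH_i` into the logistic acceptance is stationary for
`exp(−(β/2)·H_node_sum)`, not for `exp(−β·H_node_sum)`.  `beliefnet`
resolves this by always using the change of the *configuration* energy in
the acceptance under a single `energy_convention` switch:

* `node_sum` (default): `H(b) = Σ_i H_i`, acceptance uses `ΔH = 2·ΔH_i`.
  The chain and the exact enumeration then agree by construction (verified
  to total-variation < 0.02 in the acceptance suite).
* `pairwise`: each pair once, acceptance uses `ΔH_i` itself — the literal
  node-level-update reading, identical in law to `node_sum` at half the β.

A second textual ambiguity concerns whether the *proposed* state's node
dissonance is the absolute-distance form or an Ising product form
`−Σ ω_ij b_i' b_j`.  The absolute-distance form of `H_i` is the package's
definition throughout (it is what the dissonance scores implement); the
product form is available via `delta_H(..., convention="product")` for
comparison.

Local (adjacent-step) proposal kernels were considered and rejected: with
symmetric ± proposals the two acceptance probabilities sum exactly to one,
so the expected move rate is 0.5 for every node regardless of its
dissonance and the dissonance→change prediction vanishes.  The
uniform-over-grid proposal is what gives high-dissonance configurations
their larger expected moves (accepted long jumps toward tied neighbors).

## Estimation

### Constrained Gaussian graphical model

Per wave t the covariance is parameterized as
`Σ_t = Δ_t (I − Ω_t)^{-1} Δ_t`, equivalently precision
`K_t = Δ_t^{-1}(I − Ω_t)Δ_t^{-1}` with `ω_ij = −K_ij/√(K_ii K_jj)` and
`δ_i = K_ii^{-1/2}`.  Wave-level interdependence is reported as
`β_t = 1/mean(δ_·,t)` (the inverse of the mean scaling value); the
alternative mean-of-inverses convention is computed on request.

The stacked multigroup Gaussian likelihood is maximized over
(Ω, log δ, μ) with optional equality constraints per block across waves and
an optional zero mask on ties.  Numerical choices:

* The likelihood is written in terms of the stored unbiased (n−1) sample
  covariance, so the unconstrained per-wave maximum coincides *exactly*
  with the closed-form decomposition of the sample covariance (tested to
  1e−6; the round-trip Σ ↔ (Ω, Δ) itself holds to 1e−10).
* μ is profiled out analytically (sample means when free; the GLS common
  mean when constrained equal), with the envelope theorem supplying the
  gradient of the profiled objective.
* δ is optimized on the log scale; `−log|I − Ω|` diverges at the boundary
  of the positive-definite cone and acts as a natural barrier.  If a
  line-search iterate leaves the cone, a smallest-eigenvalue penalty with
  its analytic gradient (outer product of the bottom eigenvector) pushes
  back.
* L-BFGS-B with analytic gradients, `ftol 1e−12`, `gtol 1e−7`, at most
  5000 iterations; warm starts from the closed-form per-wave solutions
  (averaged under equality constraints, shrunk into the cone if needed).
  Non-convergence is reported via a warning and the model's `converged`
  flag, never silently.
* BIC = −2·loglik + n_params·log(Σ_t n_t): the sample size is the total
  number of stacked person×wave observations, matching the likelihood.

### Prune step-up

Backward phase: repeatedly fix the smallest-magnitude free tie to zero
(magnitude averaged over waves; ties broken by row/column order), refit
with warm start, keep the pruned model iff BIC strictly decreases, stop at
the first non-improvement.  Step-up phase: repeatedly re-free the zeroed
tie whose release most improves BIC while an improvement exists.  The
decision rule is strict BIC comparison, not a significance test.  Note an
intrinsic property of BIC pruning: a true-zero tie survives with
probability ≈ P(χ²₁ > log N) per attempt (≈ 0.4% at N = 5000), so perfect
structure recovery over many replicates is probabilistic, not guaranteed.

### Specification grid

The 2³ equality-constraint combinations × {dense, sparse} give 16
candidates; all are fitted and tabulated, and the global BIC minimizer is
selected.  The configuration that mirrors a constant belief-network
structure with wave-varying attention — sparse, equal ties, equal
intercepts, free scaling — is the pipeline's default single fit when the
full grid is not requested.

## Preprocessing

Likert 1..7 responses map affinely to beliefs, `b = (v − 4)/3`; the inverse
rounds half away from zero and clips — an exact bijection on the grid.
Before estimation each belief is regressed on person indicators
(`person_only`, the default) or person and wave indicators
(`person_and_wave`), which for complete balanced panels reduces to exact
demeaning.  `person_only` preserves wave-level means up to a constant, so
the intercept-equality constraint of the specification search remains
meaningful; full two-way residualization is retained for strict
measurement-invariance-style analyses.  Dissonance is always computed from
the recorded (non-residualized) rescaled values; dissonance is translation
invariant and positively homogeneous, so the Likert-vs-[−1,1] scale choice
cannot affect any downstream correlation.

With T waves, per-person demeaning shrinks the within-wave covariance: for
wave-proportional scaling profiles the model form `Δ̃_t(I−Ω)^{-1}Δ̃_t` is
preserved exactly with `c̃_t² = (1 − 2/T)c_t² + T^{-2}Σ_s c_s²`, an
increasing function of `c_t²` — so tie estimates are unbiased and the
rank order of the wave-level interdependence estimates is preserved, while
their absolute spread is compressed.  This is why recovery tests check the
β *ranking*, not its level.

## Statistical layer

* **Change scores**: per person, signed and absolute change of the belief
  average (opposite-signed belief changes cancel) or per (person, belief).
* **Multilevel correlation**: Pearson correlation of within-person-centered
  variables (the repeated-measures correlation); persons without
  within-person variance are excluded with a warning.
* **Random-effects meta-analysis**: correlations → Fisher z with variance
  1/(n−3); DerSimonian–Laird τ²; inverse-variance pooling; Q with df = k−1;
  back-transform by tanh.  Moderators (indicator-coded topic and
  experimental-vs-control) enter a weighted meta-regression with
  method-of-moments τ² and a Wald omnibus QM.  Implemented as explicit
  closed forms; cross-checked against `statsmodels` in the test suite.
* **Standardized mean change**: `d = mean(pre − post)/sd(pre − post)`
  (positive = decrease), variance `1/n + d²/(2n)`.
* **Weighted vs unweighted dissonance**: the unweighted baseline sets every
  tie to 1 (the classic structure-free dissonance).  Overlapping dependent
  correlations are compared with the Meng–Rosenthal–Rubin z.
* **Direction summary**: persons classified by the sign of their mean
  signed change; initial-belief strata on the raw scale with cutoffs 3.5
  and 4.5 (negative / neutral / positive).
* Two-sided p-values throughout; no multiple-testing correction.

## Synthetic study designs

The generator emulates a two-topic longitudinal survey: K = 20 beliefs
(10 moral + 10 social), 979 persons split 549/430 across topics, a control
plus 5 (resp. 4) experimental groups per topic (11 meta-analytic units),
four occasions W1, W2a, W2b, W3 with an intervention shock between the two
wave-2 measurements.  Tie magnitudes are uniform on [0.05, 0.30] with ~15%
negative signs and a 3:1 within/between-cluster density bias at 50%
overall sparsity; positive definiteness of (I − Ω) is repaired by uniform
0.95-shrinkage (≤ 50 iterations, deterministic).  Scaling follows the
wave profile (1.0, 1.45, 1.55, 1.35) — a sharp rise after the first
measurement, near-constancy across the intervention, partial decay at
follow-up — applied to per-belief base values near 0.4.  Person effects
are a scalar N(0, 0.3²) shift common to all of a person's beliefs: exactly
the component the person-residualization is designed to remove.  Waves are
unevenly spaced in update time: the two wave-2 measurements bracket the
intervention minutes apart (one Glauber sweep), the other intervals are
days to weeks (more sweeps; default 2).

What the generator does **not** emulate: real marginal response
distributions beyond Likert bounding, attrition or missingness, individual
differences in network structure, or temporal autocorrelation beyond the
person effect and the dynamics themselves.  Passing tests therefore
certify the machinery and the model's internal logic, not the empirical
claims about any real population.

### Designs behind the acceptance numbers

* *Sampler agreement*: K = 4 dense network, 5-level grid,
  β ∈ {0.5, 1, 2}; 10⁶ sweeps after 10⁴ burn-in; total-variation distance
  against the 625-state exact enumeration.
* *Tie recovery*: K = 10, 4 waves, n = 2000/wave, shared-tie fit on
  person-residualized pre-rounding draws (Likert rounding adds roughly
  uniform noise of sd ≈ 0.1 on the [−1,1] scale and attenuates ties by a
  few percent; recovery bounds are defined on the continuous draws).
* *Specification selection*: K = 6, n = 1000/wave, 10 replicates; the
  sparse/equal-ties/equal-intercepts/free-scaling truth must win BIC.
* *Prune recovery*: K = 5, one tie ω = 0.3, n = 5000, 10 replicates.
* *End-to-end prediction*: 10 replicate studies, each with one ground
  truth, 10 groups × 100 persons evolving at β = 1 with the uneven wave
  spacing above; ties estimated on the pooled sample (as a group-level
  network should be), per-group Pearson correlations between wave-2a
  weighted dissonance and each person's mean absolute belief change across
  the intervention interval, pooled by Fisher-z random effects; the
  unweighted baseline is computed identically.  Absolute change of the
  belief *average* is not used here: alignment moves change beliefs in
  compensating directions, so the average is approximately conserved by
  the dynamics and carries no person-level signal.
* *Dissonance reduction*: 6 groups × 100 persons, β raised to 2 during
  wave 2; standardized mean change of person-level dissonance W2a → W2b,
  pooled.

Problem sizes were chosen so the whole suite and the acceptance script run
in minutes on a single core while keeping Monte-Carlo error well inside
the asserted bounds.

## Known limitations

* Group-level ties are assumed representative of every person; no
  per-individual networks.
* No regularized (lasso) estimation, latent variables, or temporal VAR
  structure; waves are treated as independent samples given the person
  effect.
* The likelihood treats residualized observations as independent across
  waves; the small cross-wave dependence induced by demeaning is absorbed
  into the effective scaling (see above) and ignored otherwise.
* The Meng test at the belief level treats within-person-centered pooled
  observations as n independent persons — an approximation, flagged in the
  output rather than hidden.
* Glauber dynamics with uniform proposals couple expected move size to a
  belief's distance from the rest of the grid; the unweighted dissonance
  partially proxies this geometry, which is why weighted-vs-unweighted
  contrasts are evaluated on person-level totals under the uneven wave
  spacing rather than on node-level scores.
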