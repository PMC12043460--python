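# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the limitations of the package. It is the place
where genuinely open design decisions are recorded.

## 1. The decision process

One episode is one ICU stay: 18 windows of 4 hours (24 h before sepsis
onset to 48 h after). The state is a 47-vector — SOFA (column 0) plus 46
vitals — z-normalized per feature with statistics fitted on the training
split only. Actions are pairs (IV bin, VP bin) ∈ {0..4}², flattened to
0..24 by `5·iv + vp`. Bin 0 means zero dose; bins 1–4 are quartiles of the
*nonzero* training doses per drug, fitted on the training split, with a
dose exactly on a cut point assigned to the lower bin (deterministic
closed-left tie-break). Rewards are terminal-only, ±15 by survival.
SOFA strata are low < 5, medium ∈ [5, 15], high > 15; the two boundary
scores are assigned to medium so the strata are exhaustive.

## 2. Q-network and training

A fully connected network with leaky-ReLU hidden layers (default widths
128 × 128; the experiment runner uses 64 × 64 or 32 × 32 at desk scale) and
dueling heads: a scalar value stream V(s) and an advantage stream A(s, ·)
combined as Q = V + A − mean(A). Targets use double-DQN decoupling with a
hard target sync every `target_sync_period` steps; the TD loss is Huber
(κ = 1), importance-weighted under prioritized replay. Discount γ = 0.99.

Parameters live in a single flat vector; gradients are computed by hand so
the private step can obtain *per-example* gradients. A fused path computes
per-example gradient norms from the layer factorization
‖a_prev‖²·‖δ‖² (+ ‖δ‖² for biases) and forms the clipped gradient sum by
weighted matrix products without materializing the (n × p) gradient matrix;
a test pins it to the explicit per-example path to machine precision.

Offline max-bootstrapping with sparse terminal rewards is prone to
overestimation collapse: bootstrap targets inflate poorly supported
actions until the greedy policy concentrates on them (we observed mean Q
drifting past the +15 feasibility bound). Four stabilizers, all on by
default and all acting on released quantities only (hence privacy-neutral
post-processing):

* **weight decay** (1e-3) added to the averaged (noisy) gradient — the
  decisive one: shrinking the advantage stream toward zero suppresses
  noise-driven argmaxes while the systematic treatment signal survives;
* **target clamping** to [−15, +15], the exact return range implied by
  terminal-only ±15 rewards;
* **learning-rate decay** (×0.2 at 60% of training; Adam, base lr 1e-3);
* **tail iterate averaging** over the final 25% of steps — the greedy
  argmax is far less noisy under averaged parameters.

## 3. The private gradient step

Per-example gradients of the weighted Huber TD loss are clipped to L2 norm
C (default 1.0), summed, perturbed with N(0, σ²C²**I**), and divided by
the *expected* lot size L before the Adam update. Adjacency is
add/remove-one-record, so the clipped sum has sensitivity C, matching the
subsampled Gaussian analysis. Clipping is global over the concatenated
parameter gradient (one clip, one ledger entry per step), not per-layer.
Lots are Poisson-subsampled: each transition enters independently with
probability q = L/N.

Prioritized replay and Poisson subsampling cannot both drive the sampling
without breaking the amplification analysis. Resolution: when σ = 0 the
buffer does classic proportional PER (sum-tree sampling, IS weights
(N·P(i))^−β normalized by the lot max, β annealed 0.4 → 1); when σ > 0 the
lot stays Poisson and prioritization is applied as per-example loss
weights (priority normalized to (0, 1]). In both modes weights are capped
at 1 *before* clipping so they can only shrink, never inflate, the
sensitivity bound. An empty Poisson lot still releases (pure noise) and
still consumes one accounting step.

The target network is synced from already-noisy parameters, so it is
post-processing and consumes no extra privacy; the ledger is written only
by the private step function.

## 4. Privacy accounting

Per-step log moments α(λ) of the privacy-loss variable of one subsampled
Gaussian release are computed exactly for the hypothesis pair
μ₀ = N(0, σ²) vs μ = (1−q)·μ₀ + q·N(1, σ²):
E[(μ/μ₀)^{λ+1}]_{μ₀} in closed form (binomial sum over
exp(k(k−1)/2σ²) terms, evaluated with log-sum-exp), and
E[(μ₀/μ)^λ]_{μ₀} by adaptive quadrature split at 0 and 1 with a
log-stable integrand; α(λ) = log max of the two. At q = 1 both reduce to
the pure Gaussian moment λ(λ+1)/(2σ²), which serves as an exact unit test.
Moments compose additively over steps; conversion to ε uses the tail bound
ε = min_λ (Σα(λ) + ln(1/δ))/λ over integer orders λ = 1..64. A Monte-Carlo
moment estimator (300k likelihood-ratio samples) is the independent oracle
in the tests, and the accountant is verified to never exceed naive
(ε, δ)-composition built from the classical calibration
σ = √(2 ln(1.25/δ))·S/ε (stated for ε < 1; a warning is emitted outside
that range). With zero steps the ledger reports ε = 0 with a warning.

Named budgets (ε = 2, 8, …) are realized by bisecting σ (geometric
midpoint, 2% relative tolerance) at fixed (q, T, δ); the achieved ε is
then re-certified from the ledger, never assumed.

## 5. The synthetic cohort generator

What it emulates, per patient: a latent severity s* ~ N(7, 4) clipped to
[0, 24]; SOFA as a bounded integer random walk
`SOFA_{t+1} = clip(SOFA_t + 0.3(s* − SOFA_t) + 0.7(mismatch_t − 2.3) + N(0,1))`
— mean-reverting toward s*, *worsened* by treatment mismatch and improved
by optimal treatment; a clinician who doses by severity stratum with
per-window noise (sd 1.0), a per-patient practice-style offset (sd 1.0 per
drug) and 20% fully random windows; continuous doses drawn from the bin's
quarter of an exponential reference distribution (IV scale 500 mL,
VP scale 0.5 µg/kg/min); and death with probability
`expit(−5.4 + 0.25·SOFA_T + 0.06·Σ_t mismatch_t)`, where mismatch is the
L1 bin distance to the planted optimum of the window's stratum
(low → (1,0), medium → (2,1), high → (3,3)). Under these defaults the
filtered cohort's mortality is ≈35% overall with a strong severity
gradient, and an oracle policy that always takes the planted optimum
scores ≈0.23 estimated mortality versus ≈0.34 for the clinician.

Three structural choices matter more than any constant:

1. **The clinician conditions on the stratum, not the raw score.** Within
   a stratum the action is then independent of severity, so conditional
   death rates by action identify the planted optimum; with dosing linear
   in raw SOFA, severity confounds dose and the marginal "best" action is
   not the planted one.
2. **Pooled nonzero-bin occupancy is near-uniform** (the stratum means
   (1.2, 0.5)/(2.6, 2.3)/(3.4, 3.2) and dispersions were chosen for this).
   Downstream empirical quartiles equalize occupancy by construction, so
   they align with the generative bin edges only under near-uniform
   occupancy; misalignment acts as ~40% action-label noise and destroys
   the planted signal. With these defaults fitted and generative bins
   agree on ≈95% of windows.
3. **Dosing style is patient-consistent.** The action-matched mortality
   estimator selects patients whose clinician agrees with the policy; if
   the simulated clinician were independent across windows, every policy's
   matched subset would be a random draw of patients and every policy
   would score the cohort mortality. The per-patient style offset is what
   gives the estimator its selection power — worth noting because the same
   assumption (clinician consistency within a patient) is implicitly load-
   bearing for this estimator on real data too.

Actions must influence the state dynamics for any of this to be
learnable: with terminal-only rewards and action-independent transitions,
Bellman targets are identical across actions at every non-terminal state
and no planted optimum is recoverable even in principle. Hence the
mismatch term in the SOFA walk.

What the generator does **not** emulate: real physiological feature
semantics (the 46 vitals are severity-correlated Gaussian channels),
missing data (real cohorts exclude high-missingness patients instead),
inter-drug interactions, and time-varying treatment effects. Passing the
recovery tests therefore shows the *pipeline* is sound — discretization,
replay, private optimization, accounting, evaluation — not that the
learned policies would transfer to real patients.

## 6. Evaluation conventions

* Estimated mortality is **patient-weighted**: among transitions whose
  clinician action matches the policy's greedy action (exact bin equality
  by default; a "within one bin per drug" rule is available for
  sensitivity analysis), we take the death fraction of the distinct
  patients contributing matched transitions. A stratum with no matches is
  reported as undefined, not an error. The behavior policy scores exactly
  the cohort mortality under this estimator.
* One "episode" of the learning curve is one periodic evaluation (every
  `eval_period` = 500 gradient steps) of the held-out survival rate
  (1 − estimated mortality; an evaluation with no matched patients counts
  as zero survival). FAE(φ) is the first episode at or above φ, +∞ if
  never; φ defaults to 0.7, the survival scale of the synthetic cohort.
* Across repeated runs, medians over seeds are reported (5 seeds at desk
  scale).
* Greedy argmax ties break to the lowest flat action index everywhere, so
  policies are deterministic and test-stable.

## 7. Problem sizes

The shipped experiment and test scales are: cohorts of 150–5,000 patients
(18 windows each, so up to 90k transitions), networks of 32 × 32 or
64 × 64 hidden units, lots of 256, and 1,500–4,000 gradient steps per run;
end-to-end comparisons use 3 arms × 5 seeds. The reference accounting
configuration is q = 0.01, σ = 4, T = 10,000, δ = 10⁻⁶, orders 1..64,
which the accountant certifies at ε ≈ 1.38 — comfortably strong privacy
(ε < 10). These sizes were chosen so the full study runs on a single CPU
in minutes; all of them are configuration values, not code constants.

## 8. Known limitations

* Offline DQN has no explicit conservatism (no CQL/BCQ-style penalty);
  stability rests on the shrinkage/clamping/averaging stabilizers above,
  which bias Q magnitudes toward zero — rankings, not calibrated values,
  should be read from the learned Q.
* The accountant covers the Poisson-subsampled Gaussian mechanism only; in
  the σ > 0 + PER mode the prioritized *weights* depend on data through
  earlier released (noisy) gradients, which is post-processing, but users
  who enable classic PER *sampling* together with σ > 0 by modifying the
  estimator would void the amplification analysis.
* `sigma_for_epsilon` assumes ε decreases monotonically in σ (true for
  this mechanism) and searches σ ∈ [10⁻³, 10³].
* The high-SOFA stratum is rare (~5% of windows) by construction; its
  per-stratum estimates are noisy at desk scale, mirroring the thin
  high-severity subcohorts of real registries.
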