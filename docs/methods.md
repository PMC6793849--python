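# Methods

## The model

Each of the `n` regions of a directed, weighted, delayed connectome carries a
planar neural-mass oscillator for its mean membrane potential `V_i` and slow
recovery variable `W_i`:

    dV_i/dt = 20 ( W_i + 3 V_i^2 - V_i^3 + gamma * I_i ) + xi_i(t)
    dW_i/dt = 20 ( -W_i - 10 V_i )                      + eta_i(t)

with independent Wiener noises `xi, eta` and synaptic current

    I_i(t) = sum_j A_ij S_j(t - tau_ij),
    S(V)   = 1 / (1 + exp(-sigma (V - m))),   m = 1.5.

`A_ij` is the coupling weight of the edge *j → i* (row = target throughout the
package) and `tau_ij` the axonal conduction delay in ms.  The two control
parameters are the **gain** `sigma` (nonlinearity of the stimulus–response
sigmoid) and the **excitability** `gamma` (amplification of synaptic input),
both swept over [0, 1].

**Units.** The rate constant 20 is interpreted per *second*.  The linearized
node at the origin then oscillates at `sqrt(4000 − 100)/(2π) ≈ 10 Hz` — the
alpha-band rhythm this oscillator family is built to produce — and a 150 ms
embedding window covers roughly 1.5 subcritical oscillation periods, exactly
as expected for these dynamics.  Interpreting the constant per millisecond
would put the rhythm at ~10 kHz, aliased beyond recognition at the 2 kHz
sampling rate; we therefore carry configuration times (dt, duration, delays)
in ms and convert to seconds inside the integrator.

**Integration** is stochastic Heun: an Euler predictor and trapezoidal
corrector share one Wiener increment per step (standard deviation
`noise_scale * sqrt(dt)` with dt in seconds, applied to both V and W;
`noise_scale` defaults to 1 in model units).  The integration step equals the
0.5 ms sampling step by default; `sub_steps` integrates finer and records at
the sampling step.  Delays are discretized as the smallest integer number of
steps strictly exceeding the delay (minimum one step), and the delay buffer
is pre-filled with the initial condition so the synaptic current is defined
from the first step.  Initial states are drawn uniformly from
[−0.1, 0.1]² per region and seed; a 2 s transient is discarded before any
estimation (the information measures assume stationarity).  A divergence
guard aborts a run if |V| exceeds 100 model units and reports the
(sigma, gamma) point; sweep drivers record such points as missing and
continue.

**Synchrony** is summarized by the order parameter R: instantaneous phases
from the analytic signal (Hilbert transform) of each demeaned voltage series,
R = time average of the modulus of the mean unit phase vector.  R ≈ 0.89/√n
for n independent phases (≈ 0.10 at n = 76, ≈ 0.28 at n = 10) — the
finite-size floor, not zero.

## Information dynamics

All measures are conditional mutual informations (CMI) among lagged
coordinates, estimated under a linear-coupling multivariate-Gaussian model:
`I(X;Y|Z) = ½ log2(|Σ_XZ||Σ_YZ| / (|Σ_Z||Σ_XYZ|))`.  The transfer entropy
computed this way equals the Granger-causality log-likelihood-ratio statistic
up to the factor `1/(2 ln 2)` (verified by an explicit nested-OLS route in the
tests).  Estimates are invariant under affine rescaling of any series.

At 0.5 ms sampling the per-step storage and transfer quantities diverge as
dt → 0, so the continuous-time-safe quantities are *rates*:

* **Active information storage** `A_X = I(X_n^(k,τ); X_{n+1})` over a Takens
  embedding of the target's past (dimension k, delay τ) decomposes exactly
  (for plug-in estimates from one joint covariance) as
  `A_X = I_X + Ṁ_X·Δt`, where `I_X = I(X_n; X_{n+1})` is the instantaneous
  predictive capacity (divergent) and `Ṁ_X` — the **active memory
  utilization rate**, in bits/s — is the convergent storage measure used in
  the maps.
* **Transfer entropy rate** `T_{Y→X} = I(Y_{n−u+1}; X_{n+1} | X_n^(k,τ))/Δt`
  with a single lagged source value (l = 1, matching the model's coupling
  structure) at the discretized structural delay u.  Sources are restricted
  to *causal parents* — regions with a structural edge into the target.
  The **complete conditional** TE additionally conditions on one lagged
  value of every other causal parent at its own delay; the **collective**
  TE is one joint CMI from all parents (no double-counting of redundancy;
  equals the sum of incremental conditional TEs over any ordering, exactly
  for plug-in estimates).
* **Significance**: under the no-coupling null the deviance `2 n ln2 · TE`
  is chi-square with the source-block dimension as degrees of freedom; the
  all-pairs scan Bonferroni-corrects over all directed non-self pairs.  A
  permutation surrogate (resampling lagged-source rows) is kept as a
  cross-check and agrees within Monte-Carlo error.  The test's empirical
  type-I rate on independent pairs is calibrated in the acceptance suite.
* **Degenerate covariances**: hyper-synchronized regimes make the joint
  covariance near-singular.  A configurable diagonal jitter (default 1e-9 of
  the mean variance, applied only when the smallest eigenvalue falls below
  1e-12 of it) regularizes such estimates; they are flagged and a warning is
  logged.
* Pairs without a structural edge (all-pairs scan) have no tract delay; they
  fall back to the connectome's mean non-self delay.  The affected pairs are
  recorded in the result object.  (A coordinate-based fallback is not
  possible for the synthetic network, which has no region positions.)

**Embedding selection** maximizes bias-corrected AIS over (k, τ) ≤ (30, 30).
The correction subtracts the analytic null mean of the plug-in Gaussian MI,
`k·1/(2 n ln2)` bits.  Because adding useless lags then changes the score by
zero-mean chi-square fluctuations, a bare argmax wanders over plateaus; the
selection therefore takes the smallest k (then smallest τ) whose deficit
against the top scorer is within the 5% chi-square quantile for the extra
dimensions — a larger embedding must earn its keep at the 5% level.  On
Markov-1 data this selects k = 1; on the neural voltages at the subcritical
working point (sigma 0.3, gamma 0.5, 10000 samples) per-region optima
concentrate near k ≈ 21–25, τ ≈ 12–13 (the defaults k = 25, τ = 12 are used
for all maps).

## Network structure measures

For each target, non-self in-weights are normalized to unit sum
(`C = D⁻¹(A − diag A)`); in-degree-0 rows are zero (such regions contribute
no network-supported storage).  The **local network support**
`Ψ_a = Σ C_ba C_ab + Σ C_ba C_cb C_ac + Σ C_bc C_ab C_ac + Σ C_cd C_bc C_ab C_ad`
counts (weighted, as unrestricted walks) the 2- and 3-cycles through a node
and the 2- and 3-step feedforward paths terminating at it alongside a direct
edge — the shortest motif families supporting storage; longer motifs decay
under the normalization and are omitted.  The walk (unrestricted-index)
reading makes Ψ identical to
`diag(C²) + diag(C³) + rowsum(C∘C²) + rowsum(C∘C³)`, and a quadruple-loop
oracle enforces that identity in the tests.  Self-loop support is analysed
separately via `F_ii = A_ii / Σ_j A_ij` (self-loop share of total in-weight,
self-inclusive).  Per grid point, Pearson correlations across regions relate
Ψ and F_ii to the AM rate, and in-degree to outgoing pairwise/conditional TE
(per source) and to collective TE (per target).

## Synthetic data

**Connectome generator.**  Two hemisphere blocks (first half left).  The
default specification reproduces the 76-region macaque-derived network's
summary statistics: 1494 non-self directed links (38 inter-hemispheric, both
counts hit exactly by placing inter-hemispheric edges first and topping up
within hemispheres), self-loops on 66 of 76 regions, in-degree spread
19.7 ± 7.65 (dispersed per-target in-degree sequence), link weights from
moment-matched log-normals — the target moments are mean 1.91 / SD 0.63
overall and 1.07 / 0.86 on the inter-hemispheric subset, so the
within-hemisphere component is solved from the mixture identity — and
conduction delays from a positive-truncated normal whose *truncated* mean is
19.8 ms (SD 8.32 ms).  Self-loop weights reuse the within-hemisphere
distribution (their distribution is not separately constrained); self-loop
delays are zero (one discrete step).  The generator is deterministic per
seed and is a synthetic stand-in: it does not reproduce the real network's
topology beyond these statistics.

**Scaled-down stand-in** (`SyntheticConnectomeSpec.scaled_down`): shrinking
the network at fixed per-edge weights starves regions of synaptic drive
(expected total in-weight falls from ≈ 37.6 to a few units) and the
synchronization transition disappears.  The 10-region preset therefore
preserves `density·(n−1)·weight_mean` at its 76-region value (density 0.5,
per-edge weights scaled up accordingly), keeps the weight CV, the
inter-hemispheric weight ratio and fraction, and the delay distribution, and
caps the in-degree CV at 0.2 — at the full network's relative spread a
10-node graph routinely contains one-parent nodes that decouple from the
collective oscillation, a finite-size artifact.

**VAR oracle.**  A stable VAR(1) `x_t = Φ x_{t−1} + ε_t` has stationary lag
covariances from the discrete Lyapunov equation (`Γ_0 = ΦΓ_0Φᵀ + Σ`,
`Γ_h = ΦΓ_{h−1}`), from which the joint covariance of any set of lagged
coordinates — and hence every information measure — follows in closed form.
This is the implementation-independent check on the estimators: analytic
covariance vs sample covariance through the same CMI formula, with agreement
required within 3 asymptotic standard errors
(`SE = sqrt(2·df + 8 n ln2 · I)/(2 n ln2)`, the noncentral-chi-square
variance) after subtracting the plug-in bias `df/(2 n ln2)`.

## Study sizes and what they show

The full-scale study behind the published maps used the real 76-region
connectome, 50 s runs (100 000 samples at 2 kHz) and a fine parameter grid.
This package's desk-scale preset — chosen as a size a single workstation
sweeps in minutes — uses the 10-region drive-preserving connectome, an 8×8
grid over [0,1]², and 10 s of analyzed activity per point.  At that scale the
qualitative structure reproduces: the AM rate peaks at low sigma and
intermediate gamma with sharp drop-offs on either side; the order parameter
shows abrupt sigma transitions (single-grid-step rises of 0.3–0.6 in R); TE
is at the estimator bias floor in the fully segregated regime and one to two
orders of magnitude higher in the supercritical wedge; collective TE runs
about an order of magnitude above pairwise.  Two full-scale features do
*not* survive the shrinking: (i) with only ~1 inter-hemispheric causal link,
the integrated regime synchronizes as hemisphere clusters, so global R
understates integration and the TE maximum sits at high gamma where global R
is modest — an R-threshold split of the grid then yields a TE contrast of
only ~1.4–2.7× rather than the ≥ 5× seen between the regimes at full scale;
(ii) per-region embedding optima select slightly shallower histories
(mean k ≈ 21 vs the full-scale ≈ 24), though τ (≈ 13) and the medians
(τ median 12) match.  Passing the scaled-down checks shows the pipeline
reproduces the mechanism, not the printed surfaces.

The synthetic generator emulates summary statistics only; real connectomes
have lobe/community structure, reciprocity and weight–distance correlations
that the stand-in lacks, so tests passing here do not certify behaviour on
empirical tractography data.

## Numerical choices

* Per-grid-point seeds derive from the master seed via `SeedSequence
  [master, i_sigma, i_gamma]`, so any point is reproducible in isolation;
  identical config + seed ⇒ bit-identical sweeps.
* Critical boundaries are operationalized per grid line as the first index
  where R crosses the midpoint of that line's min/max; lines without a
  crossing are excluded from boundary profiles with a warning.
* The inter-hemispheric significant-TE proportion is set to 0 at grid points
  with ≤ 1 significant pair (a proportion from a single pair is noise).
* Tolerances: closed-form checks at 0.005–0.01 bits; oracle agreement at
  3 SE; type-I calibration 0.05 ± 0.015 over 1000 replicates; exact
  identities (chain rules, motif dual forms) at 1e-8–1e-12.

## Known limitations

* The linear-Gaussian estimator captures only the linear component of the
  interactions; it is a descriptive statistic, not a nonlinear TE estimate.
* The noise amplitude is a free parameter (default 1.0); the sweep's phase
  boundaries move with it.
* No BOLD/haemodynamic forward model; measures are computed on membrane
  voltages directly.
* The all-pairs delay fallback (mean tract delay) is a placeholder where no
  structural delay exists.
* At n = 10, hemisphere-level cluster synchronization limits how faithfully
  the global order parameter separates the regimes (see above).
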