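# gaindyn

**Information dynamics of gain-modulated whole-brain network models.**

The brain shifts between *segregated* states (regions talking mostly to their
local neighbourhood) and *integrated* states (strong cross-regional
coordination), plausibly under control of ascending neuromodulation — e.g.
noradrenaline changing the gain of cortical populations.  This package is for
computational neuroscientists who want to ask what that transition does to
the brain's *computation*: it simulates a delayed stochastic neural-mass
network on a directed connectome while sweeping two gain parameters, and
quantifies, with continuous-time information-theoretic measures, where the
dynamics store information and where they transfer it.

Each region obeys

    dV_i/dt = 20 (W_i + 3V_i² − V_i³ + γ I_i) + ξ_i,   dW_i/dt = 20 (−W_i − 10 V_i) + η_i,
    I_i = Σ_j A_ij S_j(t − τ_ij),   S(V) = 1 / (1 + e^{−σ(V−m)}),

with gain σ (sigmoid nonlinearity) and excitability γ (input amplification)
swept over [0,1]².  On the simulated voltages (0.5 ms sampling) it estimates,
with a linear-Gaussian (Granger-equivalent) estimator:

* the **active memory utilization rate** Ṁ_X = I(X_{n−1}^{(k−1)}; X_{n+1} | X_n)/Δt,
  the convergent continuous-time part of active information storage;
* **transfer entropy rates** T_{Y→X} = I(Y_{n−u+1}; X_{n+1} | X_n^{(k,τ)})/Δt over
  the structural causal edges, plus complete-conditional and collective variants
  and an analytic chi-square significance test with Bonferroni correction;
* phase-synchrony order parameter, critical-boundary profiles, correlations of
  storage with network motif support (Ψ) and self-loop weight, of transfer with
  node degree, and inter-hemispheric transfer summaries.

A synthetic-connectome generator (matching the 76-region macaque-derived
network's edge counts, weight/delay statistics and hemispheric structure) and
an analytic VAR oracle (closed-form information values via the discrete
Lyapunov equation) make every stage testable offline.

## Layout

    src/gaindyn/       library: connectome, simulator, estimators, analysis,
                       synthetic, workflows, io
    analysis/          numbered drivers (01 connectome, 02 estimator
                       validation, 03 sweep, 04 report) writing to results/
    scripts/           acceptance.py (see below)
    tests/             pytest suite

## Worked example

```python
import numpy as np
from gaindyn import (SyntheticConnectomeSpec, generate_connectome,
                     SimConfig, simulate, order_parameter,
                     EmbeddingSpec, active_memory_rate, te_rate)
from gaindyn.connectome import delay_steps_matrix

c = generate_connectome(SyntheticConnectomeSpec.scaled_down(10, seed=0))
spec = EmbeddingSpec(k=25, tau_embed=12)
U = delay_steps_matrix(c.tau, 0.5)
edges = [(i, j) for i, j in c.causal_edges if i != j]

for sigma in (0.1, 0.5, 1.0):
    run = simulate(c, SimConfig(sigma=sigma, gamma=0.45, duration=8_000,
                                transient=2_000, seed=7))
    am = np.mean([active_memory_rate(v, spec, 0.5).am_rate.value for v in run.V])
    te = np.mean([te_rate(run.V[j], run.V[i], spec.with_u(int(U[i, j])), 0.5).value
                  for i, j in edges])
    print(f"sigma={sigma:.1f}  R={order_parameter(run):.2f}  "
          f"AM rate={am:6.1f} bits/s  mean TE rate={te:5.2f} bits/s")
```

prints

    sigma=0.1  R=0.23  AM rate=1657.6 bits/s  mean TE rate= 0.71 bits/s
    sigma=0.5  R=0.95  AM rate=1441.0 bits/s  mean TE rate= 1.37 bits/s
    sigma=1.0  R=0.98  AM rate=1355.2 bits/s  mean TE rate= 1.12 bits/s

Reading: at weak gain the 10-region network is unsynchronized (R below its
independent-phase floor of ≈ 0.28) and storage-dominated — each region's
deeper past contributes ≈ 1.7 kbit/s about its next sample.  Crossing the
gain-mediated transition, synchrony jumps (R ≈ 0.95), per-region storage
falls, and mean transfer on the structural edges roughly doubles: the
segregated-to-integrated shift re-expressed as a shift from memory toward
communication.  (In the fully segregated corner of a whole sweep, TE sits at
the estimator's bias floor of ≈ 0.1 bits/s — run `analysis/03_sweep.py` for
the full maps.)

The numbered drivers run the full desk-scale study:

```bash
python analysis/01_make_connectome.py      # networks + structural stats tables
python analysis/02_validate_estimators.py  # estimator-vs-oracle table
python analysis/03_sweep.py                # 8x8 sigma-gamma sweep -> results/sweep.h5
python analysis/04_report.py               # phase maps, correlations, profiles
```

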