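# filostoch

Stochastic modelling and quantitative image analysis of filopodial growth
dynamics.

Filopodia and filopodia-like structures (FLS) grown in vitro on supported
lipid bilayers elongate and shrink erratically, yet their measured growth
velocities collapse onto a strikingly simple law: a Laplace (bi-exponential)
distribution, with exponentially distributed lengths as a consequence. This
package implements the theory that explains the observation, the inference
machinery around it, and the bespoke image- and table-processing pipelines
used to extract the quantities from microscopy data — together with
synthetic-data generators that reproduce every input with known ground
truth, so the whole chain is testable end to end.

## The model

Concentrations of actin regulators at the tip complex relax toward baselines
`Ã_i` as independent Ornstein–Uhlenbeck processes,

    dA_i = θ (Ã_i − A_i) dt + dW,     ⟨W(t) W(s)⟩ = 2 θ η² δ(t − s),

so the deviations `X_i = A_i − Ã_i` are stationary Gaussians with variance
η² and relaxation rate θ (min⁻¹). Regulators act in complexes: the growth
force (equal to the growth velocity in the overdamped limit) is a sum of M
products of N fluctuating deviations,

    F_{M,N}(t) = Σ_{i=1..M} Π_{j=1..N} X_{N(i−1)+j}(t).

For M = N = 2 the stationary velocity is *exactly* Laplace distributed
(the product of two standard normals is Bessel-K₀ distributed; the sum of
two such products is `½ e^{−|w|}`). Lengths follow `dL/dt = F` with
`L ≥ 0`, producing the long exponential length tails seen in snapshots.
A mass-action reaction network (production σ, pairing ρ, complex decay)
reduces to the same sum-of-products force in the large-fluctuation limit.

On top of the simulator the package provides:

- **Inference** — Laplace MLE for velocities, doubly truncated exponential
  MLE for lengths/areas, exponential Q–Q plots, persistence-time
  extraction, a Kolmogorov–Smirnov scan over model structures (M, N), a
  grid fit of the single free parameter θ from 20-min length snapshots,
  and the fluctuation-timescale prediction τ ∝ N/λ linking velocity
  relaxation to FRAP turnover.
- **Postprocessing** — diameter/length filters, local-background
  correction, greedy repair of broken trajectories, Savitzky–Golay
  smoothing/velocities, per-field-of-view Spearman matrices, enrichment
  cohorts (top-half and 70th/30th-percentile), velocity–intensity
  cross-correlation, and shaft-profile decay fits with residual bootstrap.
- **FRAP** — four-ROI normalization (background subtraction, acquisition
  bleach correction, prebleach→1 / bleach-frame→0) and single-exponential
  recovery fits (half-time, percent recovery).
- **Image pipelines** — DoG-based z-stack segmentation with greedy z
  tracing and ring-background intensity measurement, and the 2D movie
  tracer: local thresholding, random-forest pixel classification, DBSCAN
  clustering, skeletonization, gated tip joining, longest-path length
  measurement, Hungarian frame linking and track velocity extraction.
- **Synthetic data** — generators for trajectory sets, per-field intensity
  tables with planted rank correlations and enrichment effects, FRAP
  traces, 3D rod stacks and 2D filament movies, each a pure function of
  (parameters, seed) with a ground-truth record.

## Worked example

```python
import numpy as np
from scipy import stats
from filostoch import (GrowthModelParams, simulate_length, fit_laplace,
                       stationary_velocity_sample, fit_exponential,
                       predict_fluctuation_timescale, simulate_length_ensemble)

params = GrowthModelParams(M=2, N=2, theta=11.0, eta=2.0, duration=20.0, seed=1)
traj = simulate_length(params)
print(f"final length at 20 min: {traj.lengths[-1]:.2f} um")

v = stationary_velocity_sample(2, 2, 100_000, theta=11.0, eta=2.0,
                               seed=1, method="euler")
fit = fit_laplace(v)
ks = stats.kstest(v, stats.laplace(fit.location, fit.scale).cdf).statistic
print(f"Laplace fit: location={fit.location:.3f}, scale b={fit.scale:.3f}, KS={ks:.4f}")

rng = np.random.default_rng(2)
lengths = simulate_length_ensemble(params, rng.uniform(0, 20, 5000), rng=rng)[:, -1]
efit = fit_exponential(lengths, lower=5.0, upper=20.0)
print(f"truncated-exponential characteristic length: {efit.scale:.2f} um")

p = predict_fluctuation_timescale(22.0, 2)
print(f"per-protein relaxation rate: {p.per_protein_rate:.1f} /min "
      f"-> turnover time {p.characteristic_time_s:.1f} s")
```

prints

```
final length at 20 min: 6.15 um
Laplace fit: location=0.004, scale b=4.408, KS=0.0025
truncated-exponential characteristic length: 3.76 um
per-protein relaxation rate: 11.0 /min -> turnover time 5.5 s
```

The simulated stationary velocities are statistically indistinguishable
from a Laplace law (KS ≈ 0.003 at n = 10⁵); for M = N = 2 its scale is
b = η² (here 4, plus a few percent of explicit-scheme discretization
inflation at θ·dt = 0.18), the single parameter setting the velocity
spread. Lengths sampled at 20 min with random initiation
are right-skewed with a roughly exponential tail, and a shared velocity
relaxation rate of 22 min⁻¹ split over N = 2 factors per complex predicts a
per-protein turnover of ~5 s, the order observed for the fast tip-complex
components by photobleaching.

A thin CLI mirrors the main entry points:

```bash
filostoch simulate --n 1000 --seed 7 --out traj.csv
filostoch fit --what laplace --input traj.csv --column velocity_um_per_min
filostoch scan-mn --ref traj.csv --m 1:6 --n 1:6 --nsim 20000 --seed 1
filostoch frap --input trace.csv
```

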