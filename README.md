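# ktzlog

A tested implementation and analysis toolkit for the **logistic KT/KTz
map**, a discrete-time excitable-cell model in which the membrane
potential evolves through a saturating gain function rather than an ODE.
The package is aimed at computational neuroscientists and dynamical-systems
researchers who want a neuron/cardiac-cell model that is cheap enough for
large networks yet analytically tractable: every fixed point and Jacobian
eigenvalue has a closed form.

## The model

The state is (x, y, z): membrane potential, recovery variable and slow
total ionic current. One time step (ts) is

    x(t+1) = f( (x(t) − K·y(t) + z(t) + H + I(t)) / T )
    y(t+1) = x(t)
    z(t+1) = (1 − δ)·z(t) − λ·(x(t) − x_R)

with the logistic gain f(u) = u/(1+|u|) (a tanh variant is included for
comparison).  K, T > 0 control the fast spiking dynamics, H is a bias,
δ is the inverse recovery time of z, and λ, x_R shape slow spiking and
bursting.  Two regimes are distinguished:

* **fast subsystem** (δ = λ = 0): a 2-D map with pitchfork and
  Neimark-Sacker bifurcations, Arnold tongues with winding number
  w = arccos(1/2K)/2π on the supercritical line T = K, and strange
  attractors;
* **full 3-D map** (H = 0): the slow current z turns the fast subsystem's
  bistability into cardiac spikes, bursts, subthreshold and aperiodic
  oscillations.

What the library computes:

* exact one-step updates, stimulus protocols, bit-reproducible
  trajectories (`ktzlog.model`);
* closed-form equilibria, 2-D/3-D Jacobian spectra, stability classes and
  analytic stability-limit curves, e.g. T = 1−K, T = K and
  T = 1/K + K − 2 at H = 0 (`ktzlog.equilibria`);
* spike/ISI statistics, regime classification (FP, SO, FS, CS, ACS, BS,
  SB, dust), phase diagrams, winding numbers (`ktzlog.phases`);
* Lyapunov exponents by twin-orbit divergence and by tangent-space
  (Eckmann-Ruelle) products, box-counting and Kaplan-Yorke dimensions,
  bifurcation location by bisection and power-law scaling fits
  (`ktzlog.chaos`);
* a gallery of 19 excitable behaviors with machine-checkable verdicts,
  f-I curves and rheobase search (`ktzlog.behaviors`);
* gap-junction networks: chain propagation thresholds and complete-graph
  synchronization (`ktzlog.network`).

## Worked example

Equilibria of the fast subsystem at K = 0.6, T = 0.3, H = 0:

```sh
$ ktzlog fixed-points --K 0.6 --T 0.3 --H 0
```

returns three records: x* = −0.25, 0 and +0.25.  The outer pair carries
the complex eigenvalue pair 0.9375 ± 0.4961i (modulus 1.0607 — unstable:
these parameters sit in the oscillatory region below the subcritical
Neimark-Sacker line T = 1/K + K − 2 ≈ 0.267), and the origin has real
eigenvalues {2.549, 0.785}.

Largest Lyapunov exponent of the strange attractor at K = 0.89,
T = 0.009, H = 0 from x(0) = y(0) = 1:

```sh
$ ktzlog lyapunov --K 0.89 --T 0.009 --method er --steps 1000000
{"method": "eckmann_ruelle", "lambda_max": 0.1209...,
 "spectrum": [0.1209..., -0.7675...]}
```

λ₁ ≈ 0.121 per ts (chaotic); the Kaplan-Yorke dimension from this
spectrum is 1 + λ₁/|λ₂| ≈ 1.158.

In Python:

```python
from ktzlog import ModelParams, State, simulate
from ktzlog.phases import classify_params, ClassifierConfig

cell = ModelParams(K=0.6, T=0.2, delta=0.001, lam=0.001, xR=-0.2)
label, stats = classify_params(cell, ClassifierConfig())
# label == "CS": cardiac spikes with mean period ~378 ts
```

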