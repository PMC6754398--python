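# desensgate

Kinetic modelling and fluctuation analysis of AMPA-type glutamate receptors
whose **desensitized channels still conduct**.

Q/R-edited homomeric GluA2 receptors (expressed with the auxiliary subunit
γ-2) behave unlike every other AMPA-receptor assembly: a 100 ms pulse of
10 mM glutamate leaves a large (~40–50 % of peak) non-decaying steady-state
current, and non-stationary fluctuation analysis (NSFA) of the desensitizing
current yields "right-shifted" current–variance relationships that no
origin-crossing parabola can fit.  Both observations follow quantitatively
if the desensitized receptor retains a small unitary conductance — about
670 fS against 3.9 pS for the fully open channel — so that at steady state
~90 % of receptors sit in conducting desensitized states and carry most of
the current at very low noise.

This package implements that analysis end to end, for use with synthetic or
recorded patch-clamp sweep ensembles:

* **`desensgate.scheme`** — declarative continuous-time Markov gating
  schemes (states, transitions with statistical multiplicities, rate sets,
  occupancy-proportional conductances), generator (Q) matrices, stationary
  distributions, microscopic-reversibility tools, and the shipped 17-state
  receptor scheme plus its desensitized-only restriction (a cross-linked
  receptor).
* **`desensgate.macro`** — deterministic Q-matrix simulation of
  concentration-jump protocols, ensemble-variance prediction
  (σ² = N Σ iⱼ²pⱼ(1−pⱼ), exact multinomial optional), current
  decompositions by state class and ligand saturation.
* **`desensgate.stochastic`** — exact event-driven per-channel simulation
  (numba-accelerated), Gaussian background noise, zero-phase Bessel-type
  filtering, seeded and byte-reproducible; single-channel amplitude
  mixtures; columnar sweep-file IO.
* **`desensgate.nsfa`** — pairwise variance estimation, amplitude binning,
  the parabolic fit σ² = iĪ − Ī²/N + σ_B², the origin-consistency
  diagnostic that detects conducting desensitized channels, activation-phase
  NSFA with an onset-stability screen, and doubly normalized averaging.
* **`desensgate.waveform`** — biexponential decay fits with weighted time
  constants, steady-state fractions, paired-pulse recovery curves, and
  common-SD Gaussian-mixture fits to single-channel amplitude histograms.
* **`desensgate.globalfit`** — simultaneous fit of ten rate constants and
  two conductances to six kinetic/noise targets (Model → `fit()` → Results
  with `summary()`), with the dissociation rate of desensitized receptors
  constrained by cycle balance and per-condition channel counts re-derived
  from peak currents.
* **`desensgate.permeability`** — bi-ionic reversal potentials and
  chloride/cesium permeability ratios.
* **`desensgate.structure`** — residue-pair atom distances (e.g. the
  Pro632 Cα–Cα separation across a ligand-binding-domain dimer) from PDB
  files.

A `desensgate` console script wraps the library
(`scheme validate/steady`, `simulate`, `synth`, `nsfa`, `fitwave`,
`histfit`, `globalfit`, `perm`, `structdist`).

## Worked example

Simulate a 100-sweep synthetic patch (200 channels, 100 ms of 10 mM
glutamate at −60 mV, 0.3 pA background noise) and analyse it:

```python
from desensgate import (GatingProtocol, NoiseModel, fit_decay, scheme1,
                        simulate_sweeps, steady_state, steady_state_fraction)
from desensgate.nsfa import nsfa

s1 = scheme1()

pi = steady_state(s1, 10e-3)
des = sum(pi[k] for k, s in enumerate(s1.states)
          if s.state_class in ("desensitized", "deep_desensitized") and s.n_bound > 0)
print(f"desensitized occupancy at 10 mM: {des*100:.1f}%")

protocol = GatingProtocol.pulse(100e-3, 10e-3, washout=5e-3, pre=5e-3,
                                sample_interval=1e-4)
ens = simulate_sweeps(s1, protocol, n_channels=200, n_sweeps=100,
                      noise=NoiseModel(background_sd=0.3e-12), seed=7)
mean = ens.mean()
fit = fit_decay(ens.times, mean, window=(5e-3, 105e-3))
print(f"tau_w,des = {fit.tau_w*1e3:.1f} ms")
print(f"I_ss = {steady_state_fraction(ens.times, mean, 0.105):.0f}% of peak")
print(nsfa(ens).summary())
```

Output:

```
desensitized occupancy at 10 mM: 89.6%
tau_w,des = 6.5 ms
I_ss = 46% of peak
Non-stationary fluctuation analysis
--------------------------------------
parabolic fit did not converge (no conductance reported)
background variance   : 9.297e-26 A^2
residual SS           : 1.116e-23
origin consistency    : deficit 0.96 (FAIL (right-shifted))
```

Reading: the receptor desensitizes with τ_w ≈ 6.5 ms but the current settles
at 46 % of peak, because ~90 % of receptors end up in conducting
desensitized states.  Conventional NSFA of the desensitizing phase fails on
exactly this kind of data — the steady-state limb carries too little
variance for its current, flagged by the origin-consistency deficit (0.96,
far above the 0.5 threshold).  Setting the desensitized conductance to zero
(`dataclasses.replace` on `s1.conductances`) restores an ordinary parabolic
relation that passes the diagnostic; NSFA of the *activation* phase
(`desensgate.activation_nsfa`) recovers a weighted conductance near the
3.9 pS open channel even for the conducting-desensitized receptor.

The model's science and every numerical choice are documented in
[`docs/methods.md`](docs/methods.md).

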