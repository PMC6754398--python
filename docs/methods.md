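# Methods

`desensgate` models the gating of Q/R-edited homomeric GluA2 AMPA receptors
(with the auxiliary subunit γ-2), whose defining peculiarity is that the
desensitized channel is not fully shut: occupied desensitized receptors
retain a small unitary conductance (~670 fS, about one sixth of the 3.9 pS
fully open state), which produces a large non-decaying steady-state current
and "right-shifted" current–variance relationships that defeat conventional
non-stationary fluctuation analysis (NSFA).

## The gating scheme

The receptor is a tetramer with four independent glutamate-binding sites.
The shipped scheme (`schemes/scheme1.cfg`) has 17 states:

* a closed row `C0–C4` (0–4 glutamates bound) with sequential binding,
  association `k1 = 1.3×10⁶ M⁻¹s⁻¹` per free site (statistical factors
  4,3,2,1) and dissociation `k₋1 = 350 s⁻¹` per bound site;
* open states `O1–O4` reached from the liganded closed states with opening
  rate `i·β` (`β = 1000 s⁻¹` per bound agonist — opening efficacy grows with
  occupancy) and closing rate `α = 3100 s⁻¹`;
* desensitized states `D1*–D4*` entered **from the open states** at `i·δ1`
  (`δ1 = 110 s⁻¹` per bound agonist) and left at `γ1 = 88 s⁻¹`: the
  conformational change that desensitizes the receptor fails to shut the
  pore completely, so these states conduct;
* a deep desensitized row `D2_2*–D2_4*` (`2·δ2 = 78 s⁻¹` in, `γ2 = 36 s⁻¹`
  out; the factor 2 counts the two relaxable dimer interfaces of the
  dimer-of-dimers);
* a small resting desensitized pool `D0` (`δ0 = 0.48 s⁻¹` in, `γ0 = 8 s⁻¹`
  out; 5.7 % of resting receptors);
* glutamate binding within the desensitized row `D0⇌D1*⇌…⇌D4*` with the
  same `k1` but a distinct dissociation rate `k₋2 = 870 s⁻¹`, one site at a
  time.

Conducting states have unitary conductance `(n_bound/4) × g_class`, with
`g_open_max = 3.9 pS` and `g_des_max = 670 fS`.

**Provenance of the topology.** The rate constants, the conductances, and a
set of derived model outputs (steady-state occupancies of 90 % desensitized
and 6 % open at 10 mM glutamate; a 27 % open-state share of the
steady-state current; a deactivation decomposition) are published numbers;
the wiring of the scheme itself had to be reconstructed.  We searched the
space of ladder topologies (vertical attachment points, rate-pair
assignments, direction conventions, statistical multiplicities,
desensitized-row binding) and fixed the remaining freedom by requiring the
stationary outputs above.  The reconstruction reproduces the stationary
triple (89.6 % / 5.8 % / 27.2 %), a fractional steady-state current of
~46 % of peak, a weighted desensitization time constant of ~6.5 ms, and a
functional desensitized-only restriction (below).  It does **not** reproduce
the published deactivation decomposition (desensitized/non-saturated current
shares of 11 %/6 % at the peak and 25 %/77 % at mid-decay; this
reconstruction gives 5.9 %/11.4 % and 19.6 %/59.0 %).  No ladder variant we
found meets both sets of numbers simultaneously, so the stationary set —
which identifies the conducting-desensitized mechanism — was given priority.
`decompose_deactivation` computes the decomposition faithfully for whatever
scheme it is handed; mid-decay is defined as the first post-peak time at
which the total current has fallen to 50 % of peak, located by linear
interpolation.

**Microscopic reversibility.** The printed steady-state occupancies
themselves prove that the published model cannot satisfy detailed balance
globally: with `α = 3100 s⁻¹` and `β = 1000 s⁻¹`, any scheme obeying
Kolmogorov's cycle criterion pins π(O4)/π(C4) ≤ 4β/α ≈ 1.29 per unit of
occupancy scaling, yet more receptors are open (6 %) than closed (~4 %) at
saturation.  The scheme is therefore flux-carrying, and the dissociation
rate of desensitized receptors is fixed by balancing a *designated* loop:
the monoliganded activation/desensitization/dissociation cycle, which gives

    k₋2 = k₋1 · α · γ1 / (β · δ1) = 868 s⁻¹  (870 at two figures).

This constraint is declared in the scheme file and is re-applied at every
iteration of the global fit.  The general
`enforce_microscopic_reversibility` operation solves cycle balance exactly
on schemes where it is well-posed (and is tested against brute-force cycle
enumeration); on the full scheme it raises, by design, listing the
conflicting cycles.

**The desensitized-only scheme** (`scheme2`, mimicking a receptor whose
ligand-binding-domain dimer is trapped in the desensitized arrangement by a
disulfide cross-link) is the restriction of scheme 1 to its desensitized
states.  It rests in `D0`, responds to glutamate through the
desensitized-row binding chain, and produces a non-decaying current of
reduced amplitude (peak ratio ~0.37 relative to scheme 1 under a 100 ms
pulse) — the functional signature of a conducting desensitized receptor that
survives cross-linking.

## Deterministic simulation and noise prediction

Occupancies evolve as `dp/dt = p Q(c)` with piecewise-constant agonist
concentration; each segment is solved through the spectral decomposition of
the generator, evaluated at all sample times at once, with a
matrix-exponential fallback if the eigenbasis is ill-conditioned (condition
number above 1e10).  Solution exchange is instantaneous by default; an
exponential exchange filter (10–90 % rise ≈ 2.2 τ, default off) is available
because real fast-perfusion systems exchange in 150–250 µs.  Halving the
sample interval changes reported values only through sampling, not through
the solution.

The ensemble variance of N independent channels is, by default, the
per-state binomial sum σ² = N Σⱼ iⱼ² pⱼ(1−pⱼ) (the printed formula carries a
typographically duplicated N, which we drop so that the multi-state
expression reduces to the single-state σ² = i²Np(1−p)).  This expression
neglects the negative covariances between mutually exclusive states of one
channel; the exact multinomial variance σ² = N[Σ iⱼ²pⱼ − (Σ iⱼpⱼ)²] is
available via `exact_variance=True` and is what event-driven simulations
actually produce — the difference is a few standard errors at desk scale, so
recovery tests against simulated data use the exact form.

## Stochastic synthesis (the synthetic-data generator)

`simulate_sweeps` draws exact event-driven (Gillespie) trajectories per
channel — exponential waiting times from the current state's total exit
rate, categorical next-state choice — so no time-step parameter exists and
rates spanning 0.48–52 000 s⁻¹ are handled exactly.  Channels are
independent and identical; unitary currents are summed, white Gaussian
background noise is added *after* summation, and an optional zero-phase
4-pole Bessel-type low-pass mimics the analysis filter, in that order,
matching a recording chain.  Everything derives from one integer seed
(byte-identical reruns).  Default desk-scale conditions: 200 channels,
~100 sweeps, 0.2–0.5 pA background noise, −60 mV, 10 mM glutamate pulses of
1 or 100 ms — emulating outside-out patch recordings with 35–300 repeated
applications.  What the generator does *not* emulate: correlated (flicker)
noise, series-resistance and liquid-junction artifacts, rundown (a drift can
be injected manually to exercise the onset-stability screen), and TARP
stoichiometry heterogeneity.  Tests passing on this synthetic data therefore
validate the estimators' statistical behaviour, not their robustness to
every artifact of real recordings.

Single-channel amplitude data are drawn from a four-component Gaussian
mixture with means 3.5/6.9/10.3/14.1 pS and common SD 1.2 pS.  The
component weights are not published (only that 3.5 pS openings are the most
prevalent); the generator uses (0.4, 0.3, 0.2, 0.1) — fixed once.  At
n = 392 events the sparsest component carries ~39 events, so its fitted
mean has a standard error of ~0.3–0.4 pS; per-seed worst-component errors
of ~1 pS are expected, while the principal 3.5 pS component is located
within half a bin in ≥90 % of seeds and all four means are recovered to
<0.5 pS in the per-component median.  The acceptance script reports the
median smallest mean over 11 seeded draws for this reason.

## Non-stationary fluctuation analysis

Variance is estimated from successive sweep pairs,
σ²(t) = Σₖ(xₖ−xₖ₊₁)²/(2(M−1)), which cancels slow drift; the background
variance comes from a ≥2 ms pre-stimulus window and is *fixed* in the fit.
The decay phase is grouped into ten equal-count amplitude bins (equal-width
optional) and fitted with σ² = iĪ − Ī²/N + σ_B², a bounded linear
least-squares problem in (|i|, 1/N) with non-negativity enforced — the best
*physical* parabola.  A fit is declined (no conductance reported) when
1/N ≤ 0, N < 1, or the fitted unitary current exceeds the peak ensemble
current.

The `origin_consistency` deficit is the summed shortfall of the observed
variance below the fitted parabola over the lowest-current fifth of the
bins, normalized by the parabola's prediction (with a 5 % floor to keep the
statistic finite near the origin).  Conducting desensitized channels
produce a large steady-state current whose variance sits near background,
so the deficit approaches 1; ordinary channels give ≈0.  The default
threshold of 0.5 cleanly separates synthetic cohorts (deficits ≈0.95 vs
≈0.05–0.09) and the statistic increases monotonically with the desensitized
conductance.

Activation-phase analysis uses unaligned sweeps (aligning on onsets distorts
rising-phase noise): sweeps are screened by a Spearman rank-correlation test
of onset latency against sweep index (retain while trend p > 0.05; when the
whole record drifts, the longest stable contiguous block is kept), the
rising 5–95 % of the ensemble mean is binned, and the same parabola is
fitted.  On the full scheme this recovers a weighted conductance near the
fully open 3.9 pS, as it should — activation noise is dominated by the open
channel before desensitized states populate.

Doubly normalized averaging scales each patch's currents by its peak mean
current and its variances by that factor squared (shape-preserving up to i
and N), rebins onto a common ten-bin grid and averages with s.e.m.  The
published figure does not define its normalization; this rule is our
interpretation and is unit-tested for scale invariance.

## Waveform metrics

Decays are fitted with two exponentials plus (for sustained pulses) a free
baseline, summarized by the amplitude-weighted τ_w = (A1τ1+A2τ2)/(A1+A2);
when the two components degenerate (amplitude ratio < 1e−3 or τ ratio
< 1.05) a single exponential is refitted and τ_w = τ.  Steady-state
fraction is the mean current over the last 10 % of the pulse relative to
peak.  Recovery from desensitization uses paired pulses (100 ms
conditioning, 2–200 ms intervals, test pulse), with the recovery deficit
fitted (bi)exponentially.  Amplitude histograms (0.5 pS bins) are fitted by
least squares with K Gaussians sharing one SD — as the source fitted the
histogram, not the raw values — with Poisson-motivated per-bin weighting,
an ordered-gap parameterization of the means to prevent component
crossings, and multiple starts (quantiles, equal spacing, smoothed-histogram
peaks); K = 4 by default with no model selection.

## Global fit

Six targets (normalized waveform + current–variance relation for
desensitization, deactivation and activation), each parsed to 35 points —
log-spaced over decays, linear over the rising phase.  Free parameters: ten
rate constants and both maximal conductances; k₋2 is eliminated by the
reversibility constraint at every iteration; N per condition is re-derived
from the measured peak current and the model's peak per-state currents, so
it is never fitted.  Residuals: unit-normalized waveform differences, plus
variance differences weighted per point by the target variance (with a 5 %
floor) — the pairwise variance estimator's uncertainty scales with the
variance itself, and this keeps the information-rich low-variance
steady-state limb in play — plus a current-mismatch term; datasets weigh
equally.  Optimizers: bounded Nelder–Mead, trust-region least squares on
log-parameters, or a hybrid (simplex exploration, least-squares polish);
failures inside a candidate evaluation return a large finite penalty.

Identifiability, measured on this reconstruction: from noiseless six-target
data all parameters return to within 10 % of truth from ±30 % perturbed
starts **except** the resting pair (γ0, δ0), of which only the ratio is
identifiable — the targets span ~100 ms while the resting loop's absolute
rates set a seconds-long relaxation the protocols never observe.  Under
realistic noise the desensitized conductance is recovered with a median
error below 30 %, provided the experiment is adequately powered: the
recovery experiment uses patch-scale ensembles (1000 channels, 150 sweeps,
0.25 pA background noise), because at 200 channels the desensitized-channel
variance lies far below the background-subtraction noise and the parameter
is then practically unidentifiable from noise data.

## Permeability and structure

The bi-ionic reversal potential uses activities (coefficient ×
concentration; Cs⁺ coefficients 0.714/0.824 for the 145/35 mM solutions,
chloride from all chloride salts at the bulk coefficient) at 295.15 K.
With these assumptions the predicted high→low shift for a Cs⁺-selective
channel is −32.5 mV; the corresponding published expectation (−30.4 mV)
depends on unstated internal-solution activities and temperature, so the
module exposes every assumption rather than matching that number, and the
permeability ratio is obtained by monotone bisection of the measured shift.

Distances are measured between named atoms of a residue in two explicitly
chosen chains of a PDB file (alternate locations resolved by occupancy,
ties alphabetically; residue-name mismatches are errors).  Only deposited
chains are measured; files whose biological dimer is completed by
crystallographic symmetry are reported as single-chain and must be
pre-expanded.  No structure files ship with the package (tests use
synthetic coordinates); point the CLI at locally downloaded files.

## Problem sizes and numerical defaults

Deterministic solves use 17-state dense linear algebra (microseconds per
segment).  Stochastic tests use 200–2000 channels × 60–300 sweeps; the
largest single experiment in the test suite (oracle comparison, 2000 × 300
× 100 ms) and the ten-seed noisy-recovery experiment each run in a few
minutes on one core.  Occupancy conservation is enforced to 1e−8; stationary
solves use a null-space least-squares with uniqueness checked through the
recurrent communicating classes of the transition graph; cycle-balance
tolerances are 1e−9 relative.
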