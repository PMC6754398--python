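"""Simultaneous fit of the gating model to six kinetic and noise targets.

The model is constrained by three protocols — entry into desensitization
(100 ms of 10 mM glutamate), deactivation (1 ms pulse) and activation (the
rising phase) — each contributing a normalized waveform and a
current-variance relation, six datasets in all, parsed to 35 points apiece
to keep the computation manageable.  Ten rate constants and the two maximal
conductances are free; glutamate dissociation within the desensitized rows
(k_minus2) is eliminated through the scheme's microscopic-reversibility
constraint at every iteration, and the channel count N of each condition is
re-derived from that condition's measured peak current and the model's peak
occupancies and conductances, so N is never a fitted parameter.

Organisation follows the Model/Results convention: build a
:class:`GlobalFitProblem` from targets, call :meth:`fit`, inspect the
returned :class:`GlobalFitResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares, minimize

from desensgate.macro import GatingProtocol, predict_current_and_variance, propagate
from desensgate.scheme import KineticScheme, RateSet

__all__ = [
    "FitTarget",
    "GlobalFitProblem",
    "GlobalFitResult",
    "make_synthetic_targets",
    "FREE_PARAMETERS",
]

FREE_PARAMETERS = (
    "k1",
    "k_minus1",
    "alpha",
    "beta",
    "gamma1",
    "delta1",
    "gamma2",
    "delta2",
    "gamma0",
    "delta0",
    "g_open_max",
    "g_des_max",
)

N_POINTS = 35

_PROTOCOLS = {
    "desensitization": dict(pulse=100e-3, washout=5e-3),
    "deactivation": dict(pulse=1e-3, washout=30e-3),
    "activation": dict(pulse=1e-3, washout=30e-3),
}


@dataclass
class FitTarget:
    """One condition's parsed data: waveform and current-variance pairs.

    ``times`` are the 35 parsed sample times; ``waveform`` is the mean
    current normalized to its own peak magnitude; ``cv_current`` /
    ``cv_variance`` hold the current-variance relation at the same times
    (absolute units); ``peak_current`` is the measured peak (A), used to
    re-derive N.
    """

    phase: str
    times: np.ndarray
    waveform: np.ndarray
    cv_current: np.ndarray
    cv_variance: np.ndarray
    peak_current: float
    background_variance: float = 0.0
    weight: float = 1.0


def _parse_times(phase: str, sample_interval=2e-5) -> np.ndarray:
    """35 sample times per condition: linear over the rising phase for
    activation, logarithmically spaced over the decay otherwise."""
    if phase == "activation":
        return np.linspace(1e-5, 1.2e-3, N_POINTS)
    if phase == "desensitization":
        return 5e-4 + np.geomspace(1e-4, 99e-3, N_POINTS)
    return 1e-3 + np.geomspace(5e-5, 25e-3, N_POINTS)  # deactivation


def _simulate_phase(scheme: KineticScheme, phase: str, times: np.ndarray,
                    exact_variance: bool = False):
    spec = _PROTOCOLS[phase]
    protocol = GatingProtocol.pulse(
        spec["pulse"], 10e-3, washout=spec["washout"], sample_interval=1e-5
    )
    traj = propagate(scheme, protocol)
    pred = predict_current_and_variance(traj, exact_variance=exact_variance)  # N = 1
    current = np.interp(times, pred.times, pred.current)
    variance = np.interp(times, pred.times, pred.variance)
    peak = np.abs(pred.current).max()
    # peak per-state occupancies for the N re-derivation
    k_peak = int(np.argmax(np.abs(pred.current)))
    return current, variance, peak, pred, k_peak


@dataclass
class GlobalFitResult:
    rates: RateSet
    conductances: dict
    params: dict
    per_dataset_rss: dict
    n_per_condition: dict
    objective: float
    n_evaluations: int
    success: bool
    message: str = ""
    history: list = field(default_factory=list, repr=False)

    def summary(self) -> str:
        lines = ["Global kinetic fit", "=" * 40]
        for name in FREE_PARAMETERS:
            v = self.params[name]
            if name.startswith("g_"):
                lines.append(f"{name:12s} = {v * 1e12:.3f} pS")
            else:
                lines.append(f"{name:12s} = {v:.4g} s^-1" + (" M^-1" if name == "k1" else ""))
        lines.append(f"{'k_minus2':12s} = {self.rates.k_minus2:.4g} s^-1 (constrained)")
        lines.append("-" * 40)
        for phase, rss in self.per_dataset_rss.items():
            lines.append(f"RSS {phase:22s}: {rss:.4g}")
        lines.append(f"objective = {self.objective:.6g} after {self.n_evaluations} evaluations")
        return "\n".join(lines)


class GlobalFitProblem:
    """Fit the gating scheme's rates and conductances to six datasets.

    Parameters
    ----------
    scheme : KineticScheme
        Topology template (with a declared reversibility constraint);
        its rates are replaced during fitting.
    targets : dict
        ``phase -> FitTarget`` for the three phases.
    bounds : dict, optional
        ``name -> (lo, hi)``; defaults to a factor of 30 around the
        template's values.
    """

    def __init__(self, scheme: KineticScheme, targets: dict, bounds: dict | None = None,
                 exact_variance: bool = False):
        missing = set(_PROTOCOLS) - set(targets)
        if missing:
            raise ValueError(f"missing targets for phases: {sorted(missing)}")
        for t in targets.values():
            if len(t.times) != N_POINTS:
                raise ValueError(f"targets must be parsed to {N_POINTS} points")
        self.scheme = scheme
        self.targets = targets
        # per-state binomial noise sum by default (source fidelity); the exact
        # multinomial is appropriate when fitting stochastic-simulation data
        self.exact_variance = exact_variance
        ref = self._param_dict(scheme)
        self.bounds = bounds or {
            name: (ref[name] / 30.0, ref[name] * 30.0) for name in FREE_PARAMETERS
        }
        self.n_evaluations = 0

    @staticmethod
    def _param_dict(scheme) -> dict:
        d = {name: getattr(scheme.rates, name) for name in FREE_PARAMETERS if hasattr(scheme.rates, name)}
        d["g_open_max"] = scheme.conductances.g_open_max
        d["g_des_max"] = scheme.conductances.g_des_max
        return d

    def _scheme_for(self, params: dict) -> KineticScheme:
        rate_kwargs = {k: v for k, v in params.items() if not k.startswith("g_")}
        rates = replace(self.scheme.rates, **rate_kwargs)
        scheme = replace(
            self.scheme,
            rates=rates,
            conductances=replace(
                self.scheme.conductances,
                g_open_max=params["g_open_max"],
                g_des_max=params["g_des_max"],
            ),
        )
        # enforce the reversibility constraint at every iteration
        k2 = scheme.constrained_k_minus2()
        return scheme.with_rates(replace(rates, k_minus2=k2))

    def residuals(self, params: dict):
        """Residual vector across the six datasets (normalized per dataset)."""
        self.n_evaluations += 1
        try:
            scheme = self._scheme_for(params)
        except Exception:
            return np.full(6 * N_POINTS, 1e3)
        res = []
        n_cond = {}
        for phase, target in self.targets.items():
            try:
                current, variance, peak, _, _ = _simulate_phase(
                    scheme, phase, target.times, self.exact_variance
                )
            except Exception:
                res.append(np.full(2 * N_POINTS, 1e3))
                continue
            if peak <= 0:
                res.append(np.full(2 * N_POINTS, 1e3))
                continue
            # waveform residual (both model and target unit-normalized)
            wf_model = current / peak
            res.append((wf_model - target.waveform) * target.weight)
            # N re-derived from the measured peak current
            n_chan = np.abs(target.peak_current) / peak
            n_cond[phase] = n_chan
            cv_model_current = current * n_chan
            cv_model_var = variance * n_chan + target.background_variance
            scale_i = np.abs(target.cv_current).max()
            scale_v = np.abs(target.cv_variance).max()
            mismatch = np.abs(cv_model_current - target.cv_current) / scale_i
            # per-point relative weighting (with a floor) so the low-variance
            # steady-state limb keeps leverage: the estimator's uncertainty
            # scales with the variance itself
            denom = np.abs(target.cv_variance) + 0.05 * scale_v
            res.append(
                ((cv_model_var - target.cv_variance) / denom + mismatch) * target.weight
            )
        self._last_n = n_cond
        return np.concatenate(res)

    def objective(self, params: dict) -> float:
        r = self.residuals(params)
        return float(r @ r)

    # -- optimization --------------------------------------------------------

    def fit(
        self,
        start: dict | str = "template",
        method: str = "hybrid",
        seed: int | None = None,
        n_starts: int = 1,
        maxiter: int = 2000,
        max_nfev: int | None = None,
    ) -> GlobalFitResult:
        """Bounded minimization of the global misfit.

        ``method`` is ``'neldermead'`` (derivative-free simplex),
        ``'least_squares'`` (trust-region on the residual vector) or
        ``'hybrid'`` (simplex exploration polished by least squares).
        Multi-start perturbs the start point log-uniformly within +-30%
        using ``seed``.
        """
        if start == "template":
            start = self._param_dict(self.scheme)
        names = list(FREE_PARAMETERS)
        rng = np.random.default_rng(seed)
        starts = [dict(start)]
        for _ in range(n_starts - 1):
            starts.append(
                {
                    k: np.clip(
                        v * np.exp(rng.uniform(-0.26, 0.26)),
                        self.bounds[k][0],
                        self.bounds[k][1],
                    )
                    for k, v in start.items()
                }
            )
        best = None
        history = []
        for s in starts:
            x0 = np.log([s[n] for n in names])
            lo = np.log([self.bounds[n][0] for n in names])
            hi = np.log([self.bounds[n][1] for n in names])

            def vec(x):
                return self.residuals({n: float(np.exp(v)) for n, v in zip(names, x)})

            def scalar(x):
                r = vec(np.clip(x, lo, hi))
                return float(r @ r)

            if method in ("neldermead", "hybrid"):
                out = minimize(
                    scalar,
                    x0,
                    method="Nelder-Mead",
                    options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-12},
                )
                x0 = np.clip(out.x, lo, hi)
            if method in ("least_squares", "hybrid"):
                out = least_squares(
                    vec, x0, bounds=(lo, hi), xtol=1e-10, ftol=1e-10, gtol=1e-10,
                    max_nfev=max_nfev,
                )
                x_fin, cost, ok, msg = out.x, 2 * out.cost, out.status > 0, out.message
            else:
                x_fin, cost, ok, msg = out.x, out.fun, out.success, out.message
            history.append((dict(zip(names, np.exp(x_fin))), cost))
            if best is None or cost < best[1]:
                best = (x_fin, cost, ok, str(msg))
        x_fin, cost, ok, msg = best
        params = {n: float(np.exp(v)) for n, v in zip(names, x_fin)}
        scheme = self._scheme_for(params)
        per_rss = {}
        for phase, target in self.targets.items():
            current, variance, peak, _, _ = _simulate_phase(scheme, phase, target.times)
            wf = current / peak - target.waveform
            per_rss[phase] = float(wf @ wf)
        self.residuals(params)
        return GlobalFitResult(
            rates=scheme.rates,
            conductances={
                "g_open_max": scheme.conductances.g_open_max,
                "g_des_max": scheme.conductances.g_des_max,
            },
            params=params,
            per_dataset_rss=per_rss,
            n_per_condition=dict(self._last_n),
            objective=float(cost),
            n_evaluations=self.n_evaluations,
            success=bool(ok),
            message=str(msg),
            history=history,
        )


def make_synthetic_targets(
    scheme: KineticScheme,
    n_channels: int = 200,
    ensembles: dict | None = None,
) -> dict:
    """Build six noiseless targets from a scheme (or noisy ones from ensembles).

    Noiseless mode evaluates the deterministic model at the parsed times.
    If ``ensembles`` maps phases to :class:`~desensgate.stochastic.SweepEnsemble`
    objects, waveforms and variances are instead measured from the sweeps by
    the pairwise estimator, emulating analysis of real recordings.
    """
    from desensgate.nsfa import pairwise_variance

    if scheme.reversibility_constraint:
        # evaluate the same k_minus2 constraint the fit enforces
        scheme = scheme.with_rates(
            replace(scheme.rates, k_minus2=scheme.constrained_k_minus2())
        )
    targets = {}
    for phase in _PROTOCOLS:
        times = _parse_times(phase)
        if ensembles is None:
            current, variance, peak, _, _ = _simulate_phase(scheme, phase, times)
            targets[phase] = FitTarget(
                phase=phase,
                times=times,
                waveform=current / peak,
                cv_current=current * n_channels,
                cv_variance=variance * n_channels,
                peak_current=peak * n_channels,
                background_variance=0.0,
            )
        else:
            ens = ensembles[phase]
            t, mean, var, bg = pairwise_variance(ens)
            t0 = ens.pre_stimulus
            current = np.interp(times, t - t0, mean)
            variance = np.interp(times, t - t0, var) - bg
            peak = np.abs(mean).max()
            targets[phase] = FitTarget(
                phase=phase,
                times=times,
                waveform=current / peak,
                cv_current=current,
                cv_variance=variance,
                peak_current=peak,
                background_variance=0.0,
            )
    return targets
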