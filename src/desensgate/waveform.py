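"""Descriptive waveform metrics and amplitude-histogram fitting.

Macroscopic decays (entry into desensitization during a long pulse,
deactivation after a brief one) are fitted with the sum of two exponentials
and summarized by the amplitude-weighted time constant
``tau_w = (A1 tau1 + A2 tau2) / (A1 + A2)``.  Recovery from steady-state
desensitization is measured with paired pulses over 2-200 ms intervals.
Single-channel conductance histograms are fitted with K Gaussians sharing a
common standard deviation, as is conventional for multi-conductance
channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize as lm_minimize

from desensgate.macro import GatingProtocol, predict_current_and_variance, propagate
from desensgate.scheme import KineticScheme

__all__ = [
    "DecayFit",
    "WaveformMetrics",
    "RecoveryCurve",
    "MixtureFit",
    "fit_decay",
    "steady_state_fraction",
    "recovery_curve",
    "fit_amplitude_histogram",
]


@dataclass
class DecayFit:
    """Biexponential decay fit with weighted time constant."""

    amplitudes: tuple  # (A1, A2), amperes
    time_constants: tuple  # (tau1, tau2), seconds
    baseline: float
    tau_w: float
    n_components: int = 2
    residual_ss: float = np.nan

    def summary(self) -> str:
        a, tau = self.amplitudes, self.time_constants
        lines = ["Exponential decay fit", "-" * 30]
        for k in range(self.n_components):
            lines.append(f"A{k+1} = {a[k]:.3e} A, tau{k+1} = {tau[k]*1e3:.3f} ms")
        lines.append(f"baseline = {self.baseline:.3e} A")
        lines.append(f"tau_w = {self.tau_w*1e3:.3f} ms")
        return "\n".join(lines)


@dataclass
class WaveformMetrics:
    peak_current: float
    steady_state_current: float
    steady_state_percent: float
    tau_w_des: float | None = None
    tau_w_deact: float | None = None


@dataclass
class RecoveryCurve:
    intervals: np.ndarray
    fractional_recovery: np.ndarray
    tau_w_recov: float | None = None
    fit: DecayFit | None = None


@dataclass
class MixtureFit:
    """Common-SD Gaussian mixture fitted to a binned amplitude histogram."""

    means: np.ndarray  # sorted ascending, conductance units
    common_sd: float
    weights: np.ndarray  # normalized component weights
    bin_width: float
    n_components: int
    bin_centers: np.ndarray = field(repr=False, default=None)
    bin_counts: np.ndarray = field(repr=False, default=None)
    residual_ss: float = np.nan
    converged: bool = True
    cost_path: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [f"{self.n_components}-component common-SD Gaussian mixture", "-" * 42]
        for m, w in zip(self.means, self.weights):
            lines.append(f"mean = {m:6.2f}   weight = {w:.3f}")
        lines.append(f"common sd = {self.common_sd:.2f}")
        lines.append(f"bin width = {self.bin_width:.2f}, residual SS = {self.residual_ss:.3g}")
        return "\n".join(lines)

    def density(self, x: np.ndarray, n_events: int) -> np.ndarray:
        """Expected histogram counts at ``x`` for ``n_events`` events."""
        out = np.zeros_like(np.asarray(x, dtype=float))
        for m, w in zip(self.means, self.weights):
            out += (
                w
                * n_events
                * self.bin_width
                / (self.common_sd * np.sqrt(2 * np.pi))
                * np.exp(-((x - m) ** 2) / (2 * self.common_sd**2))
            )
        return out


# -- exponential decay fits ---------------------------------------------------


def _biexp(t, a1, tau1, a2, tau2, c):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


def fit_decay(
    times: np.ndarray,
    trace: np.ndarray,
    window: tuple | None = None,
    fit_baseline: bool = True,
) -> DecayFit:
    """Fit a decaying current from its peak with a biexponential.

    The fit runs from the (magnitude) peak to the end of ``window``
    (defaults to the full trace).  When the two components are degenerate
    (amplitude ratio < 1e-3 or time-constant ratio < 1.05) the fit falls
    back to a single exponential and reports ``tau_w = tau``.
    """
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if window is not None:
        sel = (times >= window[0]) & (times <= window[1])
        times, trace = times[sel], trace[sel]
    k_peak = int(np.argmax(np.abs(trace)))
    t = times[k_peak:] - times[k_peak]
    y = trace[k_peak:]
    if len(t) < 5:
        raise ValueError("decay window too short to fit")
    tail = np.abs(y[-max(len(y) // 20, 1):]).mean()
    peak = np.abs(y[0])
    if tail > 0.95 * peak:
        raise ValueError("no decay to fit: trace does not decline from its peak")
    span = t[-1]
    sign = np.sign(y[0]) if y[0] != 0 else 1.0

    def residual(params):
        return (
            _biexp(t, params["a1"], params["tau1"], params["a2"], params["tau2"], params["c"])
            - y
        )

    params = Parameters()
    amp0 = y[0] - (y[-1] if fit_baseline else 0.0)
    params.add("a1", value=0.6 * amp0)
    params.add("a2", value=0.4 * amp0)
    params.add("tau1", value=span / 20.0, min=1e-7, max=10 * span)
    params.add("tau2", value=span / 3.0, min=1e-7, max=10 * span)
    params.add("c", value=y[-1] if fit_baseline else 0.0, vary=fit_baseline)
    out = lm_minimize(residual, params, method="leastsq")
    p = out.params
    a1, a2 = p["a1"].value, p["a2"].value
    tau1, tau2 = p["tau1"].value, p["tau2"].value
    c = p["c"].value
    # order by time constant
    if tau1 > tau2:
        a1, a2, tau1, tau2 = a2, a1, tau2, tau1
    amp_total = abs(a1) + abs(a2)
    degenerate = (
        amp_total == 0
        or min(abs(a1), abs(a2)) / amp_total < 1e-3
        or tau2 / tau1 < 1.05
        or a1 * sign < 0
        or a2 * sign < 0
    )
    if degenerate:
        params = Parameters()
        params.add("a1", value=amp0)
        params.add("tau1", value=span / 5.0, min=1e-7, max=10 * span)
        params.add("a2", value=0.0, vary=False)
        params.add("tau2", value=span, vary=False)
        params.add("c", value=c, vary=fit_baseline)
        out = lm_minimize(residual, params, method="leastsq")
        p = out.params
        return DecayFit(
            amplitudes=(p["a1"].value,),
            time_constants=(p["tau1"].value,),
            baseline=p["c"].value,
            tau_w=p["tau1"].value,
            n_components=1,
            residual_ss=float(np.sum(out.residual**2)),
        )
    tau_w = (abs(a1) * tau1 + abs(a2) * tau2) / amp_total
    return DecayFit(
        amplitudes=(a1, a2),
        time_constants=(tau1, tau2),
        baseline=c,
        tau_w=tau_w,
        n_components=2,
        residual_ss=float(np.sum(out.residual**2)),
    )


def steady_state_fraction(
    times: np.ndarray,
    trace: np.ndarray,
    pulse_end: float,
    ss_window_fraction: float = 0.1,
) -> float:
    """Steady-state current as a percentage of the peak.

    The steady-state level is the mean current over the last
    ``ss_window_fraction`` of the pulse.
    """
    times = np.asarray(times)
    trace = np.asarray(trace)
    in_pulse = times <= pulse_end
    mag = np.abs(trace[in_pulse])
    peak = mag.max()
    if peak == 0:
        return 0.0
    t0 = pulse_end * (1.0 - ss_window_fraction)
    ss = np.abs(trace[(times >= t0) & in_pulse]).mean()
    return float(100.0 * ss / peak)


# -- recovery from desensitization -------------------------------------------


def recovery_curve(
    scheme: KineticScheme,
    intervals=None,
    conditioning: float = 100e-3,
    test_pulse: float = 10e-3,
    conc: float = 10e-3,
    sample_interval: float = 5e-5,
) -> RecoveryCurve:
    """Paired-pulse recovery from steady-state desensitization.

    A conditioning pulse equilibrates the receptor in desensitization; after
    each recovery interval a test pulse measures the recovered peak.  The
    fractional recovery (test peak / conditioning peak) is fitted with a
    (bi)exponential approach to 1 and summarized by ``tau_w_recov``.
    """
    if intervals is None:
        intervals = np.array([2, 5, 10, 20, 50, 100, 200]) * 1e-3
    intervals = np.asarray(intervals, dtype=float)
    fractions = []
    for gap in intervals:
        protocol = GatingProtocol(
            segments=[(conditioning, conc), (gap, 0.0), (test_pulse, conc)],
            sample_interval=sample_interval,
        )
        pred = predict_current_and_variance(propagate(scheme, protocol))
        t = pred.times
        mag = np.abs(pred.current)
        first = mag[t <= conditioning].max()
        second = mag[t >= conditioning + gap].max()
        ratio = second / first
        if ratio > 1.2:
            raise ValueError("second peak exceeds 1.2 x first peak: protocol violation")
        fractions.append(ratio)
    fractions = np.array(fractions)
    # fit deficit (1 - recovery) as a decaying (bi)exponential in the interval
    deficit = 1.0 - fractions
    try:
        fit = fit_decay(
            np.concatenate([[0.0], intervals]),
            np.concatenate([[max(deficit.max(), deficit[0])], deficit]),
            fit_baseline=False,
        )
        tau_w = fit.tau_w
    except ValueError:
        fit, tau_w = None, None
    return RecoveryCurve(
        intervals=intervals,
        fractional_recovery=fractions,
        tau_w_recov=tau_w,
        fit=fit,
    )


# -- amplitude histogram mixture fit ------------------------------------------


def fit_amplitude_histogram(
    events: np.ndarray,
    n_components: int = 4,
    bin_width: float = 0.5,
    common_sd_init: float | None = None,
) -> MixtureFit:
    """Fit a binned amplitude histogram with K common-SD Gaussians.

    The histogram (default 0.5-unit bins) is fitted by least squares;
    component means are initialized at equally spaced sample quantiles and
    reported sorted.  Weights are free and normalized afterwards; no
    baseline term is included.
    """
    events = np.asarray(events, dtype=float)
    if len(events) < 10 * n_components:
        raise ValueError("need at least 10 events per mixture component")
    lo = np.floor(events.min() / bin_width) * bin_width
    hi = np.ceil(events.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(events, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n = len(events)
    q = np.quantile(events, (np.arange(n_components) + 1) / (n_components + 1))
    sd0 = common_sd_init or max(np.std(events) / n_components, bin_width)
    cost_path = []

    def _means(params):
        # ordered parameterization: m_k = m_0 + sum of positive gaps
        m = np.empty(n_components)
        m[0] = params["m0"].value
        for k in range(1, n_components):
            m[k] = m[k - 1] + params[f"d{k}"].value
        return m

    def model_counts(params):
        sd = params["sd"].value
        out = np.zeros_like(centers)
        for k, m in enumerate(_means(params)):
            out += params[f"a{k}"].value * np.exp(-((centers - m) ** 2) / (2 * sd**2))
        return out

    def residual(params):
        mod = model_counts(params)
        # Poisson-motivated weighting: low-count tail bins keep leverage
        r = (mod - counts) / np.sqrt(np.maximum(mod, 1.0))
        cost_path.append(float((r**2).sum()))
        return r

    span = events.max() - events.min()
    starts = [np.sort(q)]
    if n_components > 1:
        starts.append(np.linspace(events.min() + sd0, events.max() - sd0, n_components))
        from scipy.signal import find_peaks

        smoothed = np.convolve(counts, np.ones(3) / 3.0, mode="same")
        peaks, _ = find_peaks(smoothed, distance=2)
        if len(peaks) >= n_components:
            top = peaks[np.argsort(smoothed[peaks])[::-1][:n_components]]
            starts.append(np.sort(centers[top]))
    out = None
    for m0 in starts:
        params = Parameters()
        params.add("m0", value=m0[0], min=lo - bin_width, max=hi)
        for k in range(n_components):
            params.add(f"a{k}", value=counts.max() / n_components, min=0.0)
            if k > 0:
                gap0 = max(m0[k] - m0[k - 1], bin_width)
                params.add(f"d{k}", value=gap0, min=bin_width / 2.0, max=span)
        params.add("sd", value=sd0, min=bin_width / 10.0, max=span)
        attempt = lm_minimize(residual, params, method="leastsq")
        if out is None or np.sum(attempt.residual**2) < np.sum(out.residual**2):
            out = attempt
    p = out.params
    amps = np.array([p[f"a{k}"].value for k in range(n_components)])
    means = _means(p)
    sd = p["sd"].value
    order = np.argsort(means)
    amps, means = amps[order], means[order]
    areas = amps * sd * np.sqrt(2 * np.pi)
    weights = areas / areas.sum() if areas.sum() > 0 else np.full(n_components, np.nan)
    return MixtureFit(
        means=means,
        common_sd=float(sd),
        weights=weights,
        bin_width=bin_width,
        n_components=n_components,
        bin_centers=centers,
        bin_counts=counts,
        residual_ss=float(np.sum(out.residual**2)),
        converged=bool(out.success),
        cost_path=np.array(cost_path),
    )
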