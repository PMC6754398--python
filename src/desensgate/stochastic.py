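"""Stochastic synthetic-data generator: per-channel gating and sweep ensembles.

This module stands in for the patch-clamp rig: it draws exact event-driven
(Gillespie) trajectories for N independent, identical channels through a
concentration protocol, sums their unitary currents, adds Gaussian
background noise and optionally applies a zero-phase low-pass (Bessel-type)
filter, producing ensembles of repeated sweeps like those recorded with
35-300 successive glutamate applications.

Event-driven sampling draws an exponential waiting time from the current
state's total exit rate and a categorical next state, so it is exact for
arbitrary rate magnitudes; no time step is involved.  Everything is
reproducible from a single integer seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import signal

from desensgate.macro import GatingProtocol, _segment_concentrations
from desensgate.scheme import KineticScheme

__all__ = [
    "NoiseModel",
    "SweepEnsemble",
    "simulate_sweeps",
    "sample_amplitude_events",
    "write_sweeps",
    "read_sweeps",
]


@dataclass
class NoiseModel:
    """Recording noise: white Gaussian background, optional low-pass filter.

    ``background_sd`` is the standard deviation of the baseline current (A);
    noise is added to the summed trace before filtering, mimicking the
    recording chain.  ``filter_cutoff`` (Hz) applies a zero-phase 4-pole
    Bessel-type low-pass; it must be below Nyquist.
    """

    background_sd: float = 0.0
    filter_cutoff: float | None = None

    def __post_init__(self):
        if self.background_sd < 0:
            raise ValueError("background_sd must be non-negative")

    def apply(self, sweeps: np.ndarray, sample_interval: float, rng) -> np.ndarray:
        out = sweeps
        if self.background_sd > 0:
            out = out + rng.normal(0.0, self.background_sd, size=out.shape)
        if self.filter_cutoff is not None:
            nyquist = 0.5 / sample_interval
            if self.filter_cutoff >= nyquist:
                raise ValueError("filter cutoff must be below Nyquist")
            sos = signal.bessel(
                4, self.filter_cutoff / nyquist, btype="low", output="sos", norm="mag"
            )
            out = signal.sosfiltfilt(sos, out, axis=-1)
        return out


@dataclass
class SweepEnsemble:
    """Repeated current sweeps with acquisition metadata."""

    times: np.ndarray
    sweeps: np.ndarray  # (n_sweeps, n_times), amperes
    sample_interval: float
    holding_potential: float = -0.060
    background_sd: float = 0.0
    pre_stimulus: float = 0.0  # duration of the zero-agonist baseline (s)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if self.sweeps.shape[1] != self.times.size:
            raise ValueError("sweep length does not match time base")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    def mean(self) -> np.ndarray:
        return self.sweeps.mean(axis=0)


def _segment_arrays(scheme: KineticScheme, protocol: GatingProtocol):
    """Per-segment transition tables for the jitted kernel."""
    segs = _segment_concentrations(protocol)
    n = scheme.n_states
    durations = np.array([d for d, _ in segs])
    rate_mats = np.empty((len(segs), n, n))
    for k, (_, conc) in enumerate(segs):
        Q = scheme.generator(conc)
        np.fill_diagonal(Q, 0.0)
        rate_mats[k] = Q
    return durations, rate_mats


@njit(cache=True)
def _simulate_sweep(durations, rate_mats, i_unit, p0_cum, n_channels, dt, n_samples, seed):
    """One sweep: sum of n_channels exact event-driven trajectories.

    Returns the summed current sampled every ``dt`` (piecewise-constant
    between transitions, value at the left edge of each sample).
    """
    np.random.seed(seed)
    n_states = rate_mats.shape[1]
    trace = np.zeros(n_samples)
    t_edges = np.empty(len(durations) + 1)
    t_edges[0] = 0.0
    for k in range(len(durations)):
        t_edges[k + 1] = t_edges[k] + durations[k]
    total = t_edges[-1]
    for _ in range(n_channels):
        # initial state from the resting distribution
        u = np.random.random()
        state = 0
        for s in range(n_states):
            if u <= p0_cum[s]:
                state = s
                break
        t = 0.0
        seg = 0
        while t < total:
            # total exit rate in the current segment
            rates = rate_mats[seg, state]
            r_tot = 0.0
            for s in range(n_states):
                r_tot += rates[s]
            if r_tot <= 0.0:
                t_next = t_edges[seg + 1]
            else:
                wait = np.random.exponential(1.0 / r_tot)
                t_next = t + wait
            if t_next >= t_edges[seg + 1]:
                # state persists to the segment boundary; no transition drawn
                t_next = t_edges[seg + 1]
                crossed = True
            else:
                crossed = False
            # accumulate current for samples in [t, t_next); the final sample
            # of the record belongs to the state occupied on arrival
            if i_unit[state] != 0.0:
                k0 = int(np.ceil(t / dt - 1e-9))
                if crossed and seg == len(durations) - 1:
                    k1 = n_samples
                else:
                    k1 = int(np.ceil(t_next / dt - 1e-9))
                if k1 > n_samples:
                    k1 = n_samples
                for k in range(k0, k1):
                    trace[k] += i_unit[state]
            if crossed:
                seg += 1
                t = t_next
                if seg >= len(durations):
                    break
                continue
            # draw the next state
            u = np.random.random() * r_tot
            acc = 0.0
            new_state = state
            for s in range(n_states):
                acc += rates[s]
                if u <= acc:
                    new_state = s
                    break
            state = new_state
            t = t_next
    return trace


def simulate_sweeps(
    scheme: KineticScheme,
    protocol: GatingProtocol,
    n_channels: int,
    n_sweeps: int,
    noise: NoiseModel | None = None,
    seed: int = 0,
    initial="rest",
    onset_drift: float = 0.0,
) -> SweepEnsemble:
    """Simulate an ensemble of repeated sweeps from a patch of N channels.

    Each channel follows an exact continuous-time Markov trajectory through
    the protocol; unitary currents are summed, background noise added and
    the optional analysis filter applied.  The ensemble is reproducible for
    a given ``seed``.

    ``onset_drift`` (seconds per sweep) delays the stimulus of sweep j by
    ``j * onset_drift``, emulating a perfusion pipette drifting over the
    recording - the failure mode the activation-phase onset-stability screen
    is designed to catch.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if n_sweeps < 2:
        raise ValueError("need at least 2 sweeps for any variance analysis")
    noise = noise or NoiseModel()
    if isinstance(initial, str):
        p0 = scheme.stationary(0.0)
    else:
        p0 = np.asarray(initial, dtype=float)
    p0_cum = np.cumsum(p0)
    p0_cum[-1] = 1.0
    durations, rate_mats = _segment_arrays(scheme, protocol)
    i_unit = scheme.unitary_currents(
        protocol.holding_potential, protocol.reversal_potential
    )
    dt = protocol.sample_interval
    n_samples = int(np.floor(protocol.duration / dt)) + 1
    times = np.arange(n_samples) * dt
    ss = np.random.SeedSequence(seed)
    sweep_seeds = ss.generate_state(n_sweeps) % (2**31 - 1)
    sweeps = np.empty((n_sweeps, n_samples))
    for j in range(n_sweeps):
        sweeps[j] = _simulate_sweep(
            durations, rate_mats, i_unit, p0_cum, n_channels, dt, n_samples,
            int(sweep_seeds[j]),
        )
        if onset_drift:
            sweeps[j] = np.roll(sweeps[j], int(round(j * onset_drift / dt)))
    rng = np.random.default_rng(ss.spawn(1)[0])
    sweeps = noise.apply(sweeps, dt, rng)
    pre = protocol.segments[0][0] if protocol.segments[0][1] == 0 else 0.0
    return SweepEnsemble(
        times=times,
        sweeps=sweeps,
        sample_interval=dt,
        holding_potential=protocol.holding_potential,
        background_sd=noise.background_sd,
        pre_stimulus=pre,
        metadata={
            "scheme": scheme.name,
            "n_channels": n_channels,
            "seed": seed,
            "protocol_segments": list(protocol.segments),
        },
    )


def sample_amplitude_events(
    mixture,
    common_sd: float,
    n_events: int,
    seed: int = 0,
) -> np.ndarray:
    """Draw single-channel conductance amplitudes from a Gaussian mixture.

    ``mixture`` is a list of ``(mean, weight)`` pairs (conductance units,
    e.g. pS); all components share ``common_sd``.  Weights are normalized.
    """
    means = np.array([m for m, _ in mixture], dtype=float)
    weights = np.array([w for _, w in mixture], dtype=float)
    if np.any(weights < 0) or weights.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    if common_sd <= 0:
        raise ValueError("common_sd must be positive")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(means), size=n_events, p=weights)
    return rng.normal(means[comp], common_sd)


# -- columnar sweep-file round trip ------------------------------------------


def write_sweeps(ensemble: SweepEnsemble, path) -> None:
    """Write an ensemble as columnar text: time then one column per sweep."""
    header = [
        f"# sample_interval = {ensemble.sample_interval!r}",
        f"# holding_potential = {ensemble.holding_potential!r}",
        f"# background_sd = {ensemble.background_sd!r}",
        f"# pre_stimulus = {ensemble.pre_stimulus!r}",
        f"# seed = {ensemble.metadata.get('seed', 'none')!r}",
        "# columns: time_s sweep_1..sweep_n (A)",
    ]
    data = np.column_stack([ensemble.times, ensemble.sweeps.T])
    buf = io.StringIO()
    np.savetxt(buf, data, fmt="%.17g", delimiter="\t")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n" + buf.getvalue())


def read_sweeps(path) -> SweepEnsemble:
    meta = {}
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("#") and "=" in line:
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip().strip("'\"")
    data = np.loadtxt(io.StringIO(text), delimiter="\t")
    data = np.atleast_2d(data)
    seed = meta.get("seed", "none")
    return SweepEnsemble(
        times=data[:, 0],
        sweeps=data[:, 1:].T,
        sample_interval=float(meta["sample_interval"]),
        holding_potential=float(meta["holding_potential"]),
        background_sd=float(meta["background_sd"]),
        pre_stimulus=float(meta.get("pre_stimulus", 0.0)),
        metadata={"seed": None if seed == "none" else int(seed)},
    )
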