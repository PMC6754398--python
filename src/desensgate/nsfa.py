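"""Non-stationary fluctuation analysis (NSFA).

The ensemble variance of repeated responses is estimated from successive
sweep pairs (robust to slow drift), binned against the mean current, and
fitted with the parabola

    sigma^2 = i * I - I^2 / N + sigma_B^2

with the background variance fixed at its pre-stimulus estimate.  The fit
yields the unitary current i, the functional channel count N, and the
weighted-mean single-channel conductance i / (V - E_rev).

Receptors that keep conducting while desensitized break this analysis in a
characteristic way: the steady-state limb of the desensitizing relation
carries a large mean current with anomalously low variance, so the relation
is "right-shifted" and cannot pass through the origin.  The
``origin_consistency`` diagnostic quantifies this as the relative variance
deficit of the low-current limb against the fitted parabola.

For the rising (activation) phase, aligning sweeps on their onsets distorts
the noise, so the analysis runs on unaligned sweeps from a stretch of the
recording in which the onset latency shows no trend (a Spearman
rank-correlation screen).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from desensgate.stochastic import SweepEnsemble

__all__ = [
    "CurrentVarianceRelation",
    "NSFAResult",
    "pairwise_variance",
    "bin_relation",
    "fit_parabola",
    "activation_nsfa",
    "doubly_normalize_and_average",
]


@dataclass
class CurrentVarianceRelation:
    """Binned mean-current vs variance pairs, with background variance.

    Bins are ordered by mean-current magnitude.  Background-subtracted bin
    variances may dip below zero from sampling noise; they are preserved,
    not clipped.
    """

    bin_mean_current: np.ndarray
    bin_variance: np.ndarray
    background_variance: float
    segment: str = "desensitization"
    peak_mean_current: float | None = None
    bin_sem: np.ndarray | None = None

    def __post_init__(self):
        self.bin_mean_current = np.asarray(self.bin_mean_current, dtype=float)
        self.bin_variance = np.asarray(self.bin_variance, dtype=float)
        if self.n_bins < 3:
            raise ValueError("need at least 3 bins")
        order = np.argsort(np.abs(self.bin_mean_current))
        self.bin_mean_current = self.bin_mean_current[order]
        self.bin_variance = self.bin_variance[order]
        if self.bin_sem is not None:
            self.bin_sem = np.asarray(self.bin_sem, dtype=float)[order]
        if self.peak_mean_current is None:
            self.peak_mean_current = self.bin_mean_current[
                np.argmax(np.abs(self.bin_mean_current))
            ]

    @property
    def n_bins(self) -> int:
        return len(self.bin_mean_current)


@dataclass
class NSFAResult:
    """Parabolic-fit estimates: unitary current, channel count, conductance."""

    unitary_current: float | None
    n_channels: float | None
    weighted_conductance: float | None
    background_variance: float
    residual_ss: float
    converged: bool
    origin_consistency: float = np.nan
    origin_consistent: bool = True
    relation: CurrentVarianceRelation | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = ["Non-stationary fluctuation analysis", "-" * 38]
        if self.converged:
            lines.append(f"unitary current i     : {self.unitary_current:.3e} A")
            lines.append(f"channel count N       : {self.n_channels:.1f}")
            lines.append(
                f"weighted conductance  : {self.weighted_conductance * 1e12:.2f} pS"
            )
        else:
            lines.append("parabolic fit did not converge (no conductance reported)")
        lines.append(f"background variance   : {self.background_variance:.3e} A^2")
        lines.append(f"residual SS           : {self.residual_ss:.3e}")
        lines.append(f"origin consistency    : deficit {self.origin_consistency:.2f} "
                     f"({'pass' if self.origin_consistent else 'FAIL (right-shifted)'})")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        r = self.relation
        x = np.abs(r.bin_mean_current)
        ax.plot(x * 1e12, r.bin_variance * 1e24, "o", color="k")
        if self.converged:
            xx = np.linspace(0, x.max(), 200) * np.sign(r.peak_mean_current)
            yy = (
                self.unitary_current * xx
                - xx**2 / self.n_channels
                + self.background_variance
            )
            ax.plot(np.abs(xx) * 1e12, yy * 1e24, "-", color="r")
        ax.axhline(self.background_variance * 1e24, ls=":", color="grey")
        ax.set_xlabel("mean current (pA)")
        ax.set_ylabel("variance (pA$^2$)")
        return ax


# -- variance estimation ------------------------------------------------------


def _onset_indices(ensemble: SweepEnsemble, frac: float = 0.5):
    """Per-sweep onset sample (first crossing of `frac` x sweep peak magnitude)."""
    onsets = np.empty(ensemble.n_sweeps, dtype=int)
    for j, sweep in enumerate(ensemble.sweeps):
        mag = np.abs(sweep - np.median(sweep[: max(int(0.5 + ensemble.pre_stimulus / ensemble.sample_interval), 1)]))
        # light 3-point smoothing to de-noise the crossing
        sm = np.convolve(mag, np.ones(3) / 3.0, mode="same")
        thr = frac * sm.max()
        above = np.where(sm >= thr)[0]
        onsets[j] = above[0] if len(above) else 0
    return onsets


def pairwise_variance(
    ensemble: SweepEnsemble,
    alignment: str = "none",
    background_variance: float | None = None,
):
    """Per-time ensemble mean and pairwise variance.

    The variance at each time point is computed from the M-1 successive
    sweep pairs, ``var(t) = sum_k (x_k - x_{k+1})^2 / (2 (M-1))``, which
    cancels slow rundown.  ``alignment='onset'`` shifts sweeps to align
    their rising phases (used for desensitization and deactivation);
    ``'none'`` leaves them untouched (required for activation noise).
    Background variance is estimated from the pre-stimulus window unless
    supplied.
    """
    if ensemble.n_sweeps < 2:
        raise ValueError("need at least 2 sweeps")
    sweeps = ensemble.sweeps
    if alignment == "onset":
        onsets = _onset_indices(ensemble)
        ref = int(np.median(onsets))
        sweeps = np.array(
            [np.roll(s, ref - o) for s, o in zip(sweeps, onsets)]
        )
    elif alignment != "none":
        raise ValueError("alignment must be 'none' or 'onset'")
    diffs = np.diff(sweeps, axis=0)
    variance = (diffs**2).sum(axis=0) / (2.0 * (ensemble.n_sweeps - 1))
    mean = sweeps.mean(axis=0)
    if background_variance is None:
        n_pre = int(ensemble.pre_stimulus / ensemble.sample_interval)
        if n_pre < 2:
            raise ValueError(
                "no pre-stimulus window; supply background_variance explicitly"
            )
        background_variance = float(variance[:n_pre].mean())
    return ensemble.times, mean, variance, background_variance


def bin_relation(
    mean: np.ndarray,
    variance: np.ndarray,
    background_variance: float,
    window: slice | np.ndarray,
    n_bins: int = 10,
    segment: str = "desensitization",
    rule: str = "equal_count",
) -> CurrentVarianceRelation:
    """Group a (mean, variance) trace segment into amplitude bins.

    Default is ten equal-count bins ordered by mean-current magnitude;
    ``rule='equal_width'`` uses equal-width amplitude bins instead.
    """
    m = np.asarray(mean)[window]
    v = np.asarray(variance)[window]
    if len(m) < n_bins:
        raise ValueError("fewer samples than bins in the analysis window")
    mag = np.abs(m)
    if rule == "equal_count":
        order = np.argsort(mag)
        groups = np.array_split(order, n_bins)
    elif rule == "equal_width":
        edges = np.linspace(mag.min(), mag.max() + 1e-30, n_bins + 1)
        which = np.digitize(mag, edges) - 1
        groups = [np.where(which == k)[0] for k in range(n_bins)]
        groups = [g for g in groups if len(g)]
    else:
        raise ValueError("rule must be 'equal_count' or 'equal_width'")
    bm = np.array([m[g].mean() for g in groups])
    bv = np.array([v[g].mean() for g in groups])
    sem = np.array([v[g].std(ddof=1) / np.sqrt(len(g)) if len(g) > 1 else np.nan for g in groups])
    return CurrentVarianceRelation(
        bin_mean_current=bm,
        bin_variance=bv,
        background_variance=background_variance,
        segment=segment,
        peak_mean_current=m[np.argmax(mag)],
        bin_sem=sem,
    )


# -- parabolic fit ------------------------------------------------------------


def fit_parabola(
    relation: CurrentVarianceRelation,
    voltage: float = -0.060,
    reversal: float = 0.0,
    deficit_threshold: float = 0.5,
) -> NSFAResult:
    """Least-squares fit of the current-variance parabola.

    The background variance is fixed (not fitted).  The fit is linear in
    ``(i, 1/N)`` and solved in closed form.  A negative fitted 1/N or a
    degenerate relation yields a flagged, non-converged result with no
    conductance.  The ``origin_consistency`` deficit compares the observed
    variance of the low-current (steady-state) limb with the fitted
    parabola's prediction; a deficit above ``deficit_threshold`` marks the
    relation as right-shifted (incompatible with an origin-crossing
    parabola).
    """
    x = relation.bin_mean_current
    y = relation.bin_variance - relation.background_variance
    sign = -1.0 if x.sum() < 0 else 1.0
    u = np.abs(x)
    # physical parabola: |i| >= 0 and 1/N >= 0 (bounded linear least squares)
    from scipy.optimize import lsq_linear

    A = np.column_stack([u, -(u**2)])
    sol = lsq_linear(A, y, bounds=(0.0, np.inf))
    i_mag, inv_n = sol.x
    i_unit = sign * i_mag
    fitted = A @ sol.x
    rss = float(((y - fitted) ** 2).sum())
    # plausibility gates: at least one channel, and a unitary current no
    # larger than the peak ensemble current
    ok = (
        bool(sol.success)
        and inv_n > 1e-30
        and 1.0 / inv_n >= 1.0
        and 0 < i_mag <= np.abs(relation.peak_mean_current)
    )
    # variance-deficit diagnostic on the lowest-|current| fifth of the bins
    n_low = max(relation.n_bins // 5, 1)
    pred_low = fitted[:n_low]
    obs_low = y[:n_low]
    scale = np.abs(fitted).max()
    if scale == 0.0:
        deficit = 0.0
    else:
        deficit = float(
            (pred_low - obs_low).sum() / (np.abs(pred_low).sum() + 0.05 * scale)
        )
    if not ok:
        return NSFAResult(
            unitary_current=None,
            n_channels=None,
            weighted_conductance=None,
            background_variance=relation.background_variance,
            residual_ss=rss,
            converged=False,
            origin_consistency=deficit,
            origin_consistent=deficit <= deficit_threshold,
            relation=relation,
        )
    return NSFAResult(
        unitary_current=float(i_unit),
        n_channels=float(1.0 / inv_n),
        weighted_conductance=float(i_unit / (voltage - reversal)),
        background_variance=relation.background_variance,
        residual_ss=rss,
        converged=True,
        origin_consistency=deficit,
        origin_consistent=deficit <= deficit_threshold,
        relation=relation,
    )


def nsfa(
    ensemble: SweepEnsemble,
    segment: str = "desensitization",
    n_bins: int = 10,
    voltage: float | None = None,
    reversal: float = 0.0,
) -> NSFAResult:
    """End-to-end NSFA of a sweep ensemble for a decay phase.

    ``segment`` selects the analysis window on the ensemble mean:
    ``'desensitization'`` (peak to end of pulse) or ``'deactivation'``
    (peak to end of record).
    """
    times, mean, variance, bg = pairwise_variance(ensemble)
    mag = np.abs(mean)
    k_peak = int(np.argmax(mag))
    window = slice(k_peak, len(mean))
    relation = bin_relation(mean, variance, bg, window, n_bins=n_bins, segment=segment)
    return fit_parabola(
        relation,
        voltage=ensemble.holding_potential if voltage is None else voltage,
        reversal=reversal,
    )


# -- activation-phase analysis ------------------------------------------------


def onset_stability_screen(
    ensemble: SweepEnsemble, p_threshold: float = 0.05, min_block: int = 10
):
    """Select a stretch of sweeps whose onset latency shows no trend.

    Spearman rank correlation of onset latency against sweep index; when
    the whole recording shows a significant trend (p <= threshold), the
    longest contiguous block without one is retained.
    """
    onsets = _onset_indices(ensemble)
    idx = np.arange(ensemble.n_sweeps)

    def stable(sel):
        if len(sel) < 3 or np.ptp(onsets[sel]) == 0:
            return True
        rho, p = stats.spearmanr(idx[sel], onsets[sel])
        return bool(np.isnan(rho) or p > p_threshold)

    if stable(idx):
        return idx
    best = np.array([], dtype=int)
    n = ensemble.n_sweeps
    for start in range(0, n - min_block + 1):
        for stop in range(n, start + min_block - 1, -1):
            sel = idx[start:stop]
            if len(sel) <= len(best):
                break
            if stable(sel):
                best = sel
                break
    if len(best) < 2:
        raise ValueError("onset-stability screen retained fewer than 2 sweeps")
    return best


def activation_nsfa(
    ensemble: SweepEnsemble,
    n_bins: int = 10,
    rise_range=(0.05, 0.95),
    p_threshold: float = 0.05,
) -> NSFAResult:
    """NSFA of the current rising phase on unaligned, onset-stable sweeps.

    Requires a sampling rate high enough that the rising phase spans at
    least ``n_bins`` samples.
    """
    retained = onset_stability_screen(ensemble, p_threshold=p_threshold)
    sub = SweepEnsemble(
        times=ensemble.times,
        sweeps=ensemble.sweeps[retained],
        sample_interval=ensemble.sample_interval,
        holding_potential=ensemble.holding_potential,
        background_sd=ensemble.background_sd,
        pre_stimulus=ensemble.pre_stimulus,
        metadata=dict(ensemble.metadata, retained=len(retained)),
    )
    times, mean, variance, bg = pairwise_variance(sub, alignment="none")
    mag = np.abs(mean)
    k_peak = int(np.argmax(mag))
    lo, hi = rise_range
    rising = np.where(
        (mag[: k_peak + 1] >= lo * mag[k_peak]) & (mag[: k_peak + 1] <= hi * mag[k_peak])
    )[0]
    # exclude the pre-stimulus baseline
    n_pre = int(sub.pre_stimulus / sub.sample_interval)
    rising = rising[rising >= n_pre]
    if len(rising) < n_bins:
        raise ValueError(
            "rising phase spans fewer samples than bins; increase the sampling rate"
        )
    relation = bin_relation(mean, variance, bg, rising, n_bins=n_bins, segment="activation")
    return fit_parabola(relation, voltage=ensemble.holding_potential)


# -- doubly normalized averaging ---------------------------------------------


def doubly_normalize_and_average(
    relations, n_bins: int = 10
) -> CurrentVarianceRelation:
    """Average current-variance relations across patches.

    Each relation's currents are scaled by its peak mean current and its
    variances by that factor squared, which preserves the parabolic shape
    (up to i and N) and removes the amplitude scale; the scaled relations
    are then rebinned onto a common grid and averaged with s.e.m.
    """
    relations = list(relations)
    if len(relations) < 2:
        raise ValueError("need at least 2 relations to average")
    xs, ys = [], []
    for r in relations:
        scale = np.abs(r.peak_mean_current)
        xs.append(np.abs(r.bin_mean_current) / scale)
        ys.append((r.bin_variance - r.background_variance) / scale**2)
    x_all = np.concatenate(xs)
    y_all = np.concatenate(ys)
    edges = np.linspace(0.0, x_all.max() * (1 + 1e-12), n_bins + 1)
    which = np.digitize(x_all, edges) - 1
    bm, bv, sem = [], [], []
    for k in range(n_bins):
        sel = which == k
        if not sel.any():
            continue
        bm.append(x_all[sel].mean())
        bv.append(y_all[sel].mean())
        sem.append(y_all[sel].std(ddof=1) / np.sqrt(sel.sum()) if sel.sum() > 1 else 0.0)
    return CurrentVarianceRelation(
        bin_mean_current=np.array(bm),
        bin_variance=np.array(bv),
        background_variance=0.0,
        segment=relations[0].segment,
        peak_mean_current=1.0,
        bin_sem=np.array(sem),
    )
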