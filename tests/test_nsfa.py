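"""Fluctuation analysis: estimators, parabola fits, screens, averaging."""

import numpy as np
import pytest
from dataclasses import replace

from desensgate import (
    CurrentVarianceRelation,
    GatingProtocol,
    NoiseModel,
    SweepEnsemble,
    activation_nsfa,
    bin_relation,
    doubly_normalize_and_average,
    fit_parabola,
    pairwise_variance,
    predict_current_and_variance,
    propagate,
    simulate_sweeps,
)
from desensgate.nsfa import nsfa, onset_stability_screen
from tests.conftest import make_control_scheme


def _flat_ensemble(values, sample_interval=1e-4, pre=1e-3):
    n_pre = int(pre / sample_interval)
    n = n_pre + 50
    sweeps = np.tile(np.asarray(values, dtype=float)[:, None], (1, n))
    return SweepEnsemble(
        times=np.arange(n) * sample_interval,
        sweeps=sweeps,
        sample_interval=sample_interval,
        pre_stimulus=pre,
    )


class TestPairwiseVariance:
    def test_identical_sweeps_have_zero_variance(self):
        ens = _flat_ensemble([1e-12] * 6)
        _, _, var, bg = pairwise_variance(ens)
        assert np.abs(var).max() == 0.0 and bg == 0.0

    def test_constant_offset_pair(self):
        c = 3e-12
        ens = _flat_ensemble([0.0, c])
        _, _, var, _ = pairwise_variance(ens, background_variance=0.0)
        assert np.allclose(var, c**2 / 2.0)

    def test_unbiased_on_stationary_noise(self):
        rng = np.random.default_rng(7)
        sd = 1.0
        estimates = [
            np.diff(rng.normal(0, sd, size=(30, 40)), axis=0).__pow__(2).sum(0).mean()
            / (2 * 29)
            for _ in range(200)
        ]
        se = np.std(estimates) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - sd**2) < 2 * se

    def test_matches_predicted_ensemble_variance(self, s1, brief_pulse, ensemble_s1):
        times, mean, var, bg = pairwise_variance(ensemble_s1)
        pred = predict_current_and_variance(
            propagate(s1, brief_pulse), n_channels=200, exact_variance=True
        )
        det = np.interp(times, pred.times, pred.variance) + ensemble_s1.background_sd**2
        idx = np.linspace(40, len(times) - 1, 20).astype(int)
        # standard error of the pairwise variance estimate
        m = ensemble_s1.n_sweeps
        se = det[idx] * np.sqrt(3.0 / m)
        z = (var[idx] - det[idx]) / se
        assert (np.abs(z) < 3).mean() >= 0.85
        assert np.abs(z).max() < 5

    def test_too_few_sweeps_rejected(self):
        with pytest.raises(ValueError):
            pairwise_variance(_flat_ensemble([0.0]))


class TestParabolaFit:
    def test_noiseless_points_recover_exactly(self):
        i_true, n_true = -0.24e-12, 100.0
        x = np.linspace(-0.5e-12, -20e-12, 10)
        y = i_true * x - x**2 / n_true
        res = fit_parabola(CurrentVarianceRelation(x, y, background_variance=0.0))
        assert res.converged
        assert res.unitary_current == pytest.approx(i_true, rel=1e-9)
        assert res.n_channels == pytest.approx(n_true, rel=1e-9)
        assert res.weighted_conductance == pytest.approx(i_true / -0.060, rel=1e-9)

    def test_recovery_within_15_percent_at_100_sweeps(self, control_scheme):
        protocol = GatingProtocol.pulse(
            20e-3, 10e-3, washout=10e-3, pre=5e-3, sample_interval=1e-4
        )
        ens = simulate_sweeps(
            control_scheme, protocol, n_channels=100, n_sweeps=100,
            noise=NoiseModel(background_sd=0.5e-12), seed=21,
        )
        res = nsfa(ens, segment="deactivation")
        assert res.converged
        assert res.weighted_conductance == pytest.approx(32.8e-12, rel=0.15)

    def test_degenerate_noiseless_trace_declines(self, s1, brief_pulse):
        pred = predict_current_and_variance(propagate(s1, brief_pulse))
        n = len(pred.times)
        ens = SweepEnsemble(
            times=pred.times,
            sweeps=np.tile(pred.current, (4, 1)),
            sample_interval=brief_pulse.sample_interval,
            pre_stimulus=2e-3,
        )
        res = nsfa(ens)
        assert not res.converged
        assert res.weighted_conductance is None


class TestOriginConsistency:
    def test_deficit_monotone_in_desensitized_conductance(self, s1, long_pulse):
        deficits = []
        for g_des in (0.0, 300e-15, 670e-15):
            s = replace(
                s1,
                conductances=replace(s1.conductances, g_des_max=g_des),
                name=f"g{g_des}",
            )
            ens = simulate_sweeps(
                s, long_pulse, n_channels=200, n_sweeps=60,
                noise=NoiseModel(background_sd=0.3e-12), seed=1,
            )
            deficits.append(nsfa(ens).origin_consistency)
        assert deficits[0] < deficits[1] < deficits[2]


class TestActivationAnalysis:
    def test_constant_onsets_keep_all_sweeps(self, ensemble_s1):
        retained = onset_stability_screen(ensemble_s1)
        assert len(retained) == ensemble_s1.n_sweeps

    def test_drift_screen_removes_drifting_block(self, s1):
        protocol = GatingProtocol.pulse(
            1e-3, 10e-3, washout=4e-3, pre=2e-3, sample_interval=1e-5
        )
        stable = simulate_sweeps(
            s1, protocol, n_channels=300, n_sweeps=20,
            noise=NoiseModel(background_sd=0.3e-12), seed=13,
        )
        # generator's drift option: onset latency grows linearly with sweep
        drifting = simulate_sweeps(
            s1, protocol, n_channels=300, n_sweeps=20,
            noise=NoiseModel(background_sd=0.3e-12), seed=14, onset_drift=8e-5,
        )
        bad = SweepEnsemble(
            times=stable.times,
            sweeps=np.vstack([stable.sweeps, drifting.sweeps]),
            sample_interval=stable.sample_interval,
            pre_stimulus=stable.pre_stimulus,
            background_sd=stable.background_sd,
        )
        retained = onset_stability_screen(bad)
        assert len(retained) < 40
        assert np.mean(retained < 20) > 0.7  # mostly the stable early block

    def test_activation_conductance_near_open_channel_value(self, s1):
        protocol = GatingProtocol.pulse(
            1e-3, 10e-3, washout=2e-3, pre=1e-3, sample_interval=1e-5
        )
        ens = simulate_sweeps(
            s1, protocol, n_channels=300, n_sweeps=120,
            noise=NoiseModel(background_sd=0.2e-12), seed=17,
        )
        res = activation_nsfa(ens)
        assert res.converged
        # plausibility band around the fully open conductance (3.9 pS)
        assert 1.5e-12 < res.weighted_conductance < 6.5e-12


class TestDoublyNormalizedAveraging:
    def _relation(self, i_unit, n_chan, peak, bg=0.0, n_bins=10):
        x = np.linspace(peak / n_bins, peak, n_bins)
        y = i_unit * x - x**2 / n_chan + bg
        return CurrentVarianceRelation(x, y, background_variance=bg)

    def test_identical_relations_average_to_themselves(self):
        r = self._relation(-0.2e-12, 150, -30e-12)
        avg = doubly_normalize_and_average([r, r, r])
        expected = (r.bin_variance) / (30e-12) ** 2
        assert np.allclose(np.sort(avg.bin_variance), np.sort(expected))
        assert np.abs(avg.bin_sem).max() < 1e-12 * np.abs(avg.bin_variance).max()

    def test_scale_invariance(self):
        # same channel count and open probability, doubled unitary current:
        # the doubly normalized relations coincide
        r1 = self._relation(-0.2e-12, 150, -30e-12)
        r2 = self._relation(-0.4e-12, 150, -60e-12)
        avg = doubly_normalize_and_average([r1, r2])
        assert np.abs(avg.bin_sem).max() < 1e-12 * np.abs(avg.bin_variance).max()

    def test_rebinning_merges_unequal_grids(self):
        r1 = self._relation(-0.2e-12, 150, -30e-12, n_bins=10)
        r2 = self._relation(-0.2e-12, 150, -30e-12, n_bins=14)
        avg = doubly_normalize_and_average([r1, r2])
        assert avg.n_bins >= 3
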