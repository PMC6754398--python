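"""Shared fixtures: toy schemes, reusable synthetic ensembles, PDB snippets.

Expensive stochastic ensembles are session-scoped so several tests can
analyse the same simulated patch.
"""

import numpy as np
import pytest

from desensgate import (
    ConductanceModel,
    GatingProtocol,
    KineticScheme,
    NoiseModel,
    RateSet,
    State,
    Transition,
    scheme1 as _scheme1,
    simulate_sweeps,
)


@pytest.fixture(scope="session")
def s1():
    return _scheme1()


@pytest.fixture(scope="session")
def two_state():
    """Minimal C <-> O scheme: opening beta = 1000/s, closing alpha = 3100/s."""
    return KineticScheme(
        states=[State("C", 4, "closed"), State("O", 4, "open")],
        transitions=[
            Transition("C", "O", "beta", 1, False),
            Transition("O", "C", "alpha", 1, False),
        ],
        rates=RateSet(),
        conductances=ConductanceModel(),
        name="two-state",
    )


def make_control_scheme(g_open=32.8e-12, rates=None):
    """Binding + single conducting state: C0 <-> C4 <-> O4.

    Used for parameter-recovery experiments where the true unitary current
    is known and unique.
    """
    return KineticScheme(
        states=[
            State("C0", 0, "closed"),
            State("C4", 4, "closed"),
            State("O4", 4, "open"),
        ],
        transitions=[
            Transition("C0", "C4", "k1", 4, True),
            Transition("C4", "C0", "k_minus1", 1, False),
            Transition("C4", "O4", "beta", 1, False),
            Transition("O4", "C4", "alpha", 1, False),
        ],
        rates=rates or RateSet(),
        conductances=ConductanceModel(g_open_max=g_open, g_des_max=0.0),
        name="control",
    )


@pytest.fixture(scope="session")
def control_scheme():
    return make_control_scheme()


@pytest.fixture(scope="session")
def brief_pulse():
    return GatingProtocol.pulse(
        1e-3, 10e-3, washout=9e-3, pre=2e-3, sample_interval=5e-5
    )


@pytest.fixture(scope="session")
def ensemble_s1(s1, brief_pulse):
    """200-channel patch, 80 sweeps of a brief saturating pulse."""
    return simulate_sweeps(
        s1, brief_pulse, n_channels=200, n_sweeps=80,
        noise=NoiseModel(background_sd=0.2e-12), seed=11,
    )


@pytest.fixture(scope="session")
def long_pulse():
    return GatingProtocol.pulse(
        100e-3, 10e-3, washout=5e-3, pre=5e-3, sample_interval=1e-4
    )


SYNTHETIC_PDB = """\
CRYST1  100.000  100.000  100.000  90.00  90.00  90.00 P 1           1
ATOM      1  CA  PRO A 632       0.000   0.000   0.000  1.00  1.00           C
ATOM      2  CB  PRO A 632       1.000   0.000   0.000  1.00  1.00           C
ATOM      3  CA  PRO B 632       3.000   4.000   0.000  1.00  1.00           C
ATOM      4  CA  GLY A 700       9.000   9.000   9.000  1.00  1.00           C
ATOM      5  CA  GLY B 700       9.000   9.000  11.000  1.00  1.00           C
END
"""

ALTLOC_PDB = """\
CRYST1  100.000  100.000  100.000  90.00  90.00  90.00 P 1           1
ATOM      1  CA APRO A 632       0.000   0.000   0.000  0.30  1.00           C
ATOM      2  CA BPRO A 632       1.000   0.000   0.000  0.70  1.00           C
ATOM      3  CA  PRO B 632       5.000   0.000   0.000  1.00  1.00           C
END
"""


@pytest.fixture()
def synthetic_pdb(tmp_path):
    p = tmp_path / "synthetic_dimer.pdb"
    p.write_text(SYNTHETIC_PDB)
    return p


@pytest.fixture()
def altloc_pdb(tmp_path):
    p = tmp_path / "synthetic_altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p
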