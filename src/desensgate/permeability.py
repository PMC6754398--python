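"""Bi-ionic reversal potentials and relative chloride permeability.

For a channel exposed to CsCl solutions on both sides, the reversal
potential under the bi-ionic Goldman-Hodgkin-Katz assumption is

    V_rev = (RT/F) ln[ (aCs_o + r * aCl_i) / (aCs_i + r * aCl_o) ]

where ``r = P_Cl / P_Cs`` and the ``a`` are ion activities (mean activity
coefficient times concentration).  ``r = 0`` reduces to the Cs+ Nernst
potential.  The shift in reversal potential between a high- and a low-CsCl
external solution brackets the permeability ratio, which is recovered by
monotone inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["IonicCondition", "reversal_potential", "reversal_shift", "infer_p_ratio"]

R_GAS = 8.31446261815324  # J mol^-1 K^-1
FARADAY = 96485.33212  # C mol^-1


@dataclass
class IonicCondition:
    """Effective ion activities (mM-equivalent) on both membrane faces.

    Activities are activity coefficient x concentration.  Chloride enters
    from every chloride salt in the solution (CsCl plus CaCl2 and the
    like), using the bulk-solution coefficient unless overridden.
    """

    aCs_out: float
    aCs_in: float
    aCl_out: float
    aCl_in: float
    temperature: float = 295.15  # kelvin (22 C)

    def __post_init__(self):
        for name in ("aCs_out", "aCs_in", "aCl_out", "aCl_in"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 273.0 <= self.temperature <= 320.0:
            raise ValueError("temperature out of physiological range (273-320 K)")

    @classmethod
    def from_concentrations(
        cls,
        cs_out_mM: float,
        cs_in_mM: float,
        coef_out: float,
        coef_in: float,
        cl_out_extra_mM: float = 0.0,
        cl_in_extra_mM: float = 0.0,
        temperature: float = 295.15,
    ) -> "IonicCondition":
        """Build activities from CsCl concentrations and coefficients.

        ``cl_*_extra_mM`` adds chloride from other salts (e.g. 2 mM from
        1 mM CaCl2), scaled by the same coefficient as the bulk solution.
        """
        return cls(
            aCs_out=coef_out * cs_out_mM,
            aCs_in=coef_in * cs_in_mM,
            aCl_out=coef_out * (cs_out_mM + cl_out_extra_mM),
            aCl_in=coef_in * (cs_in_mM + cl_in_extra_mM),
            temperature=temperature,
        )


def reversal_potential(cond: IonicCondition, p_ratio: float) -> float:
    """Bi-ionic reversal potential (volts) for P_Cl/P_Cs = ``p_ratio``."""
    if p_ratio < 0:
        raise ValueError("p_ratio must be non-negative")
    rt_f = R_GAS * cond.temperature / FARADAY
    return rt_f * np.log(
        (cond.aCs_out + p_ratio * cond.aCl_in)
        / (cond.aCs_in + p_ratio * cond.aCl_out)
    )


def reversal_shift(
    cond_high: IonicCondition, cond_low: IonicCondition, p_ratio: float
) -> float:
    """Predicted reversal-potential shift (volts) on switching high -> low."""
    return reversal_potential(cond_low, p_ratio) - reversal_potential(cond_high, p_ratio)


def infer_p_ratio(
    shift: float,
    cond_high: IonicCondition,
    cond_low: IonicCondition,
    upper: float = 50.0,
) -> float:
    """Invert the measured shift for P_Cl/P_Cs.

    The shift is monotone in the permeability ratio, so bisection applies.
    A shift outside the achievable range raises with the attainable bounds.
    """
    lo = reversal_shift(cond_high, cond_low, 0.0)
    hi = reversal_shift(cond_high, cond_low, upper)
    lo_b, hi_b = sorted((lo, hi))
    if not lo_b <= shift <= hi_b:
        raise ValueError(
            f"shift {shift * 1e3:.2f} mV outside the achievable range "
            f"[{lo_b * 1e3:.2f}, {hi_b * 1e3:.2f}] mV for p_ratio in [0, {upper}]"
        )
    f = lambda r: reversal_shift(cond_high, cond_low, r) - shift
    if f(0.0) == 0.0:
        return 0.0
    return float(brentq(f, 0.0, upper, xtol=1e-12, rtol=1e-10))
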