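"""Ion selectivity: Pitzer activities, reversal potential, GHK ratio.

The charge selectivity of the pore is measured under a salt gradient
(0.1 M KCl cis / 3 M KCl trans): the applied potential at which the net
current vanishes (reversal potential, trans relative to grounded cis)
feeds an alternative form of the Goldman-Hodgkin-Katz equation,

    P_K/P_Cl = (a_Cl^trans - a_Cl^cis * exp(psi*F/RT))
             / (a_K^trans * exp(psi*F/RT) - a_K^cis),

with single-salt chemical activities a = gamma*c from the Pitzer
1:1-electrolyte model. Molarity and molality are treated
interchangeably for KCl <= 3 M (a documented approximation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .constants import FARADAY_C_PER_MOL, GAS_CONSTANT_J_PER_MOL_K

# Pitzer coefficients for KCl at 25 C (1:1 electrolyte)
PITZER_KCL = {
    "beta0": 0.04835,
    "beta1": 0.2122,
    "C_phi": -0.00084,
    "A_phi": 0.392,
    "b": 1.2,
    "alpha": 2.0,
}

DEFAULT_TEMPERATURE_K = 295.0


def pitzer_activity(
    molality: float, params: dict[str, float] | None = None
) -> tuple[float, float]:
    """Mean activity coefficient and activity of a 1:1 salt (KCl default).

        ln gamma = f_gamma + m*B_gamma + m^2*C_gamma
        f_gamma  = -A_phi * [sqrt(I)/(1+b*sqrt(I)) + (2/b)*ln(1+b*sqrt(I))]
        B_gamma  = 2*beta0 + (2*beta1/(alpha^2*I))
                   * [1 - (1 + alpha*sqrt(I) - alpha^2*I/2)*exp(-alpha*sqrt(I))]
        C_gamma  = 1.5 * C_phi

    Returns (gamma, activity = gamma*m). Valid for 0 < m <= 6 mol/kg
    (the parameterization's range); the coefficients are 25 C values.
    """
    if not 0 < molality <= 6:
        raise ValueError(
            f"molality must be in (0, 6] mol/kg for this parameterization, "
            f"got {molality}"
        )
    p = params or PITZER_KCL
    ionic = molality  # 1:1 salt: I = m
    sqrt_i = np.sqrt(ionic)
    b, alpha = p["b"], p["alpha"]
    f_gamma = -p["A_phi"] * (
        sqrt_i / (1 + b * sqrt_i) + (2 / b) * np.log(1 + b * sqrt_i)
    )
    b_gamma = 2 * p["beta0"] + (2 * p["beta1"] / (alpha**2 * ionic)) * (
        1 - (1 + alpha * sqrt_i - alpha**2 * ionic / 2) * np.exp(-alpha * sqrt_i)
    )
    c_gamma = 1.5 * p["C_phi"]
    gamma = float(np.exp(f_gamma + molality * b_gamma + molality**2 * c_gamma))
    return gamma, gamma * molality


@dataclass(frozen=True)
class SaltActivities:
    """Single-ion activities on each side; for one symmetric salt the
    cation and anion activities coincide on each side."""

    a_K_cis: float
    a_K_trans: float
    a_Cl_cis: float
    a_Cl_trans: float

    def __post_init__(self) -> None:
        for name in ("a_K_cis", "a_K_trans", "a_Cl_cis", "a_Cl_trans"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_concentrations(
        cls, c_cis_M: float, c_trans_M: float
    ) -> "SaltActivities":
        """KCl activities on both sides from the Pitzer model."""
        _, a_cis = pitzer_activity(c_cis_M)
        _, a_trans = pitzer_activity(c_trans_M)
        return cls(
            a_K_cis=a_cis, a_K_trans=a_trans, a_Cl_cis=a_cis, a_Cl_trans=a_trans
        )


def reversal_potential_mV(
    iv_points: list[tuple[float, float]], method: str = "interpolate"
) -> float:
    """Zero-current crossing of an I-V series (voltage_mV, current_pA).

    'interpolate': linear interpolation between the bracketing points;
    'fit': root of a straight-line fit through all points. Convention:
    the returned potential is the applied trans potential with cis
    grounded. Raises when the current does not change sign in range.
    """
    pts = np.asarray(sorted(iv_points), dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 I-V points")
    v, i = pts[:, 0], pts[:, 1]
    if method == "fit":
        slope, intercept = np.polyfit(v, i, 1)
        root = -intercept / slope
        if not v.min() <= root <= v.max():
            raise ValueError("no reversal in range (fitted root outside data)")
        return float(root)
    zero = np.flatnonzero(i == 0)
    if zero.size:
        return float(v[zero[0]])
    sign_change = np.flatnonzero(np.diff(np.sign(i)) != 0)
    if sign_change.size == 0:
        raise ValueError("no reversal in range: current does not change sign")
    k = sign_change[0]
    return float(v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k]))


def ghk_permeability_ratio(
    psi_rev_mV: float,
    activities: SaltActivities,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """P_K+/P_Cl- from the reversal potential under a salt gradient.

    Ratio < 1 means anion selectivity. Raises a domain error when the
    reversal potential lies outside the Nernst window for the given
    activities (non-positive ratio).
    """
    x = np.exp(
        psi_rev_mV * 1e-3 * FARADAY_C_PER_MOL
        / (GAS_CONSTANT_J_PER_MOL_K * temperature_K)
    )
    num = activities.a_Cl_trans - activities.a_Cl_cis * x
    den = activities.a_K_trans * x - activities.a_K_cis
    scale = max(
        activities.a_K_cis, activities.a_K_trans,
        activities.a_Cl_cis, activities.a_Cl_trans,
    )
    if abs(num) < 1e-12 * scale and abs(den) < 1e-12 * scale:
        # symmetric activities at zero potential: the equation is 0/0
        # (any ratio reverses at 0 mV); return the non-selective limit
        return 1.0
    if den == 0:
        raise ZeroDivisionError("GHK denominator is zero at this potential")
    ratio = num / den
    if ratio <= 0:
        raise ValueError(
            f"psi_rev={psi_rev_mV:g} mV lies outside the Nernst window for "
            "these activities (non-positive permeability ratio)"
        )
    return float(ratio)


def reversal_from_permeability_ratio(
    ratio: float,
    activities: SaltActivities,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Inverse of :func:`ghk_permeability_ratio`: psi_rev (mV) for a ratio.

    Closed form: with r = P_K/P_Cl,
    exp(psi*F/RT) = (a_Cl_trans + r*a_K_cis) / (a_Cl_cis + r*a_K_trans).
    """
    if ratio <= 0:
        raise ValueError("permeability ratio must be positive")
    x = (activities.a_Cl_trans + ratio * activities.a_K_cis) / (
        activities.a_Cl_cis + ratio * activities.a_K_trans
    )
    rt_f = GAS_CONSTANT_J_PER_MOL_K * temperature_K / FARADAY_C_PER_MOL
    return float(np.log(x) * rt_f * 1e3)


@dataclass(frozen=True)
class SelectivityResult:
    reversal_potential_mV: float
    permeability_ratio: float
    temperature_K: float
    activities: SaltActivities


def selectivity_from_iv(
    iv_points: list[tuple[float, float]],
    c_cis_M: float = 0.1,
    c_trans_M: float = 3.0,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> SelectivityResult:
    """Full selectivity analysis: I-V -> reversal potential -> GHK ratio."""
    activities = SaltActivities.from_concentrations(c_cis_M, c_trans_M)
    psi = reversal_potential_mV(iv_points)
    ratio = ghk_permeability_ratio(psi, activities, temperature_K)
    return SelectivityResult(
        reversal_potential_mV=psi,
        permeability_ratio=ratio,
        temperature_K=temperature_K,
        activities=activities,
    )
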