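"""Physical transport layer: charge, screening, drift-diffusion first passage.

Converts observed residence times into an intrapore diffusion
coefficient via a one-dimensional drift-diffusion first-passage model:
the captured analyte starts at the pore entry (reflecting boundary,
x = 0) and must reach the far end (absorbing boundary, x = L = pore
length) under a constant drift velocity set by the electrophoretic
force, Einstein mobility, and an opposing electro-osmotic slip.
Because the dwell time also includes unmodelled in-pore interactions,
the inverted D is a lower-limit estimate.

Also houses the Henderson-Hasselbalch protonation model for the analyte
net charge vs pH, Debye and Bjerrum screening lengths, Stokes-Einstein
conversion between D and hydrodynamic radius, and the excluded-volume
blockade proportionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .constants import (
    AVOGADRO_PER_MOL,
    BOLTZMANN_J_PER_K,
    ELEMENTARY_CHARGE_C,
    VACUUM_PERMITTIVITY_F_PER_M,
    WATER_REL_PERMITTIVITY,
    require_positive,
    thermal_energy_J,
)

# ---------------------------------------------------------------------------
# Analyte charge vs pH
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChargeModel:
    """Titratable basic groups: (count, pKa), each +1 when protonated."""

    groups: tuple[tuple[int, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        for count, _ in self.groups:
            if count <= 0:
                raise ValueError("group counts must be positive integers")


def pamam_g1_charge_model() -> ChargeModel:
    """Default generation-1 PAMAM dendrimer protonation model.

    8 primary surface amines plus 6 internal tertiary amines (4 outer,
    2 core). The pKa values are a calibration chosen to reproduce the
    net charges +12 at pH 3, +8 at pH 7 and ~0 at pH 10.3 — not a
    literature table — and are fully overridable.
    """
    return ChargeModel(
        groups=((8, 9.0), (4, 6.0), (2, 1.5)), label="PAMAM-G1"
    )


def net_charge(model: ChargeModel, pH: float) -> float:
    """Net valence: sum of count x protonated fraction over basic groups.

    Protonated fraction from Henderson-Hasselbalch: 1/(1 + 10^(pH-pKa)).
    """
    if not 0 < pH < 14:
        raise ValueError(f"pH must be in (0, 14), got {pH}")
    return float(
        sum(count / (1.0 + 10.0 ** (pH - pKa)) for count, pKa in model.groups)
    )


# ---------------------------------------------------------------------------
# Electrolyte screening
# ---------------------------------------------------------------------------


def debye_length_nm(
    ionic_strength_M: float,
    temperature_K: float = 300.0,
    rel_permittivity: float = WATER_REL_PERMITTIVITY,
) -> float:
    """Debye screening length of a 1:1 electrolyte in nm; ~0.3 nm at 1 M.

    kappa^-1 = sqrt(eps0*eps_r*kB*T / (2*NA*e^2*I*1e3)); scales as
    I^(-1/2).
    """
    require_positive(
        ionic_strength_M=ionic_strength_M,
        temperature_K=temperature_K,
        rel_permittivity=rel_permittivity,
    )
    num = (
        VACUUM_PERMITTIVITY_F_PER_M
        * rel_permittivity
        * BOLTZMANN_J_PER_K
        * temperature_K
    )
    den = 2 * AVOGADRO_PER_MOL * ELEMENTARY_CHARGE_C**2 * ionic_strength_M * 1e3
    return float(np.sqrt(num / den) * 1e9)


def bjerrum_length_nm(
    temperature_K: float = 300.0,
    rel_permittivity: float = WATER_REL_PERMITTIVITY,
) -> float:
    """Bjerrum length e^2/(4*pi*eps0*eps_r*kB*T) in nm; ~0.7 nm in water."""
    require_positive(
        temperature_K=temperature_K, rel_permittivity=rel_permittivity
    )
    return float(
        ELEMENTARY_CHARGE_C**2
        / (
            4
            * np.pi
            * VACUUM_PERMITTIVITY_F_PER_M
            * rel_permittivity
            * thermal_energy_J(temperature_K)
        )
        * 1e9
    )


# ---------------------------------------------------------------------------
# Pore geometry and charge map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoreModel:
    """alpha-hemolysin geometry and pH-dependent charge map.

    Default length 10 nm (overall channel length), beta-barrel diameter
    2.0 nm (analyte diameter ~1.8 nm). ``charges_by_pH`` maps pH to
    (q_ring, q_constriction, q_vestibule) in units of |e|: at pH 3 the
    barrel mouth, constriction and vestibule carry +5.5, +6.5, +28; at
    pH 7 the mouth is -7 and the rest neutral.
    """

    length_nm: float = 10.0
    barrel_diameter_nm: float = 2.0
    charges_by_pH: dict[float, tuple[float, float, float]] = field(
        default_factory=lambda: {3.0: (5.5, 6.5, 28.0), 7.0: (-7.0, 0.0, 0.0)}
    )

    def __post_init__(self) -> None:
        require_positive(
            length_nm=self.length_nm, barrel_diameter_nm=self.barrel_diameter_nm
        )


# ---------------------------------------------------------------------------
# Drift-diffusion first passage
# ---------------------------------------------------------------------------


def mean_first_passage_time(
    v_cm_s: float, D_cm2_s: float, L_cm: float
) -> float:
    """MFPT on [0, L], reflecting at 0, absorbing at L, constant drift v.

        tau = L/v - (D/v^2) * (1 - exp(-v*L/D))

    evaluated as (D/v^2)*(u + expm1(-u)) with u = vL/D to avoid
    catastrophic cancellation, and by series expansion for |u| < 1e-4,
    recovering the diffusive limit L^2/(2D) at v = 0. v may have either
    sign (negative drift pushes away from the absorbing end and
    lengthens the passage).
    """
    require_positive(D_cm2_s=D_cm2_s, L_cm=L_cm)
    u = v_cm_s * L_cm / D_cm2_s
    if abs(u) < 1e-4:
        # tau = (L^2/D) * (1/2 - u/6 + u^2/24 - u^3/120)
        poly = 0.5 - u / 6.0 + u**2 / 24.0 - u**3 / 120.0
        return float(L_cm**2 / D_cm2_s * poly)
    return float((D_cm2_s / v_cm_s**2) * (u + np.expm1(-u)))


def drift_velocity_cm_s(
    z_eff: float,
    voltage_mV: float,
    pore: PoreModel,
    D_cm2_s: float,
    temperature_K: float = 295.0,
    v_eo_cm_s: float = 0.0,
) -> float:
    """Analyte drift velocity in the pore, cm/s, positive = trans->cis.

    Einstein mobility times the electrophoretic force, minus the
    opposing electro-osmotic slip:

        v = (D / kB*T) * (z_eff * e * dV / l_p) - v_eo

    The potential is assumed to drop uniformly over the pore length.
    v_eo is an explicit per-condition scalar (no microscopic water-flux
    model is attempted).
    """
    require_positive(pore_length=pore.length_nm)
    force_N = (
        z_eff
        * ELEMENTARY_CHARGE_C
        * (voltage_mV * 1e-3)
        / (pore.length_nm * 1e-9)
    )
    # D in cm^2/s -> m^2/s, velocity m/s -> cm/s
    v_m_s = (D_cm2_s * 1e-4) / thermal_energy_J(temperature_K) * force_N
    return float(v_m_s * 1e2 - v_eo_cm_s)


@dataclass(frozen=True)
class TransportEstimate:
    D_cm2_s: float
    D_se: float
    per_point_D: tuple[float, ...]
    drift_velocity_cm_s_at: dict[float, float]  # voltage_mV -> v
    v_eo_cm_s: float
    model_variant: str = "reflect-absorb-constant-drift"


def _tau_model(D: float, voltage_mV: float, z_eff: float, pore: PoreModel,
               temperature_K: float, v_eo_cm_s: float) -> float:
    L_cm = pore.length_nm * 1e-7
    v = drift_velocity_cm_s(z_eff, voltage_mV, pore, D, temperature_K, v_eo_cm_s)
    return mean_first_passage_time(v, D, L_cm)


def estimate_diffusion(
    points: list[tuple[float, float]],
    z_eff: float,
    pore: PoreModel | None = None,
    temperature_K: float = 295.0,
    v_eo_cm_s: float = 0.0,
) -> TransportEstimate:
    """Invert the first-passage model for D from (voltage_mV, tau_off_s).

    Least-squares over log-residuals of the modelled vs observed dwell
    times, solved by bounded scalar minimization over log10(D); exact on
    noiseless forward-generated data. A per-point exact solve (bisection
    on the monotone tau(D)) provides the scatter-based standard error.
    The result is a lower-limit estimate of the intrapore D.
    """
    pore = pore or PoreModel()
    pts = np.asarray(points, dtype=float)
    if len(pts) < 1:
        raise ValueError("need at least one (voltage, tau_off) point")
    if np.any(pts[:, 1] <= 0):
        raise ValueError("tau_off values must be positive")

    def solve_single(voltage: float, tau_obs: float) -> float:
        def g(log10D: float) -> float:
            return np.log(
                _tau_model(10.0**log10D, voltage, z_eff, pore,
                           temperature_K, v_eo_cm_s)
            ) - np.log(tau_obs)

        lo, hi = -14.0, -1.0
        if g(lo) * g(hi) > 0:
            raise ValueError(
                f"no D in [1e-14, 1e-1] cm^2/s reproduces tau={tau_obs:g} s "
                f"at {voltage:g} mV"
            )
        return float(10.0 ** optimize.brentq(g, lo, hi, xtol=1e-13))

    per_point = tuple(solve_single(v, tau) for v, tau in pts)

    if len(pts) == 1:
        D_hat = per_point[0]
    else:
        def sse(log10D: float) -> float:
            D = 10.0**log10D
            r = [
                np.log(_tau_model(D, v, z_eff, pore, temperature_K, v_eo_cm_s))
                - np.log(tau)
                for v, tau in pts
            ]
            return float(np.dot(r, r))

        res = optimize.minimize_scalar(
            sse, bounds=(-14.0, -1.0), method="bounded",
            options={"xatol": 1e-12},
        )
        D_hat = float(10.0**res.x)

    D_se = (
        float(np.std(per_point, ddof=1) / np.sqrt(len(per_point)))
        if len(per_point) > 1
        else 0.0
    )
    velocities = {
        float(v): drift_velocity_cm_s(
            z_eff, float(v), pore, D_hat, temperature_K, v_eo_cm_s
        )
        for v in pts[:, 0]
    }
    return TransportEstimate(
        D_cm2_s=D_hat,
        D_se=D_se,
        per_point_D=per_point,
        drift_velocity_cm_s_at=velocities,
        v_eo_cm_s=v_eo_cm_s,
    )


# ---------------------------------------------------------------------------
# Stokes-Einstein and excluded-volume blockade
# ---------------------------------------------------------------------------


def stokes_einstein_radius_nm(
    D_cm2_s: float, viscosity_Pa_s: float = 8.9e-4, temperature_K: float = 295.0
) -> float:
    """Hydrodynamic radius r = kB*T/(6*pi*eta*D) in nm."""
    require_positive(
        D_cm2_s=D_cm2_s, viscosity_Pa_s=viscosity_Pa_s, temperature_K=temperature_K
    )
    r_m = thermal_energy_J(temperature_K) / (
        6 * np.pi * viscosity_Pa_s * D_cm2_s * 1e-4
    )
    return float(r_m * 1e9)


def stokes_einstein_diffusion_cm2_s(
    radius_nm: float, viscosity_Pa_s: float = 8.9e-4, temperature_K: float = 295.0
) -> float:
    """Inverse of :func:`stokes_einstein_radius_nm`."""
    require_positive(
        radius_nm=radius_nm,
        viscosity_Pa_s=viscosity_Pa_s,
        temperature_K=temperature_K,
    )
    D_m2_s = thermal_energy_J(temperature_K) / (
        6 * np.pi * viscosity_Pa_s * radius_nm * 1e-9
    )
    return float(D_m2_s * 1e4)


def excluded_volume_blockade_pA(
    sigma_buffer_S_cm: float,
    voltage_mV: float,
    delta_volume_nm3: float,
    pore_length_nm: float,
) -> float:
    """Order-of-magnitude blockade amplitude from excluded electrolyte volume.

        dI ~ sigma * dV * delta / l_p^2

    for an analyte excluding volume delta inside a cylindrical pore of
    length l_p in an electrolyte of conductivity sigma. A proportionality
    only: for non-cylindrical pores the blockade varies with analyte
    position, and analyte charge contributes — do not invert this for
    a precise analyte volume.
    """
    require_positive(
        sigma_buffer_S_cm=sigma_buffer_S_cm, pore_length_nm=pore_length_nm
    )
    if delta_volume_nm3 < 0:
        raise ValueError("delta_volume_nm3 must be non-negative")
    sigma_S_m = sigma_buffer_S_cm * 1e2
    amps = (
        sigma_S_m
        * (voltage_mV * 1e-3)
        * (delta_volume_nm3 * 1e-27)
        / (pore_length_nm * 1e-9) ** 2
    )
    return float(amps * 1e12)
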