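"""Voltage dependence of capture: Arrhenius/Kramers fits and barrier deltas.

Capture of a charged analyte by the pore is barrier-limited: the mean
inter-event time shortens exponentially with applied voltage,

    tau_on = a * exp(-dV / b),

equivalently (Kramers / van't Hoff-Arrhenius form for the rate)

    rate_on = r0 * exp(z_eff * e * dV / (kB * T)),

where r0 is the extrapolated zero-voltage capture rate and z_eff the
effective valence coupling the analyte to the field at the pore mouth.
The prefactor A and barrier height U* entering r0 = A*exp(-U*/kBT) are
not separately identifiable; only r0 and barrier *differences* between
conditions with equal prefactor (same analyte concentration and bulk
diffusivity) are reported:

    dU* = kB*T * ln(r0_A / r0_B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import kBT_to_kcal_per_mol, thermal_voltage_mV


@dataclass(frozen=True)
class ArrheniusFit:
    """tau_on = a * exp(-dV/b); a in seconds, b in mV (both positive when
    capture accelerates with positive voltage)."""

    a_s: float
    b_mV: float
    a_se: float
    b_se: float


@dataclass(frozen=True)
class KramersFit:
    r0_per_s: float
    r0_se: float
    z_eff: float
    z_eff_se: float
    temperature_K: float

    @property
    def b_mV(self) -> float:
        """Equivalent Arrhenius voltage scale kB*T/(z_eff*e)."""
        return thermal_voltage_mV(self.temperature_K) / self.z_eff


@dataclass(frozen=True)
class BarrierDelta:
    """dU* = U*(A) - U*(B), antisymmetric under swapping the pair."""

    delta_kBT: float
    delta_kcal_per_mol: float
    conditions: tuple[str, str]
    temperature_K: float


def _weighted_linfit(
    x: np.ndarray, y: np.ndarray, w: np.ndarray | None
) -> tuple[float, float, float, float]:
    """Weighted straight-line fit; returns slope, intercept and their SEs.

    With fewer points than needed for a residual variance (n=2) the
    covariance is taken from the weights alone.
    """
    if w is None:
        w = np.ones_like(x)
    W = np.sum(w)
    xbar = np.sum(w * x) / W
    ybar = np.sum(w * y) / W
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = np.sum(w * (x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    dof = len(x) - 2
    s2 = np.sum(w * resid**2) / dof if dof > 0 else 1.0
    slope_se = np.sqrt(s2 / sxx)
    intercept_se = np.sqrt(s2 * (1.0 / W + xbar**2 / sxx))
    return float(slope), float(intercept), float(slope_se), float(intercept_se)


def fit_arrhenius_tau(
    points: list[tuple[float, float]], weights: np.ndarray | None = None
) -> ArrheniusFit:
    """Fit tau_on = a*exp(-dV/b) to (voltage_mV, tau_on_s) points.

    Linear regression of ln(tau) on dV (exact for multiplicative noise);
    requires >= 3 voltages unless the two-point closed form suffices
    (n = 2 is allowed and exact).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 (voltage, tau) points")
    v, tau = pts[:, 0], pts[:, 1]
    if np.any(tau <= 0):
        raise ValueError("tau_on values must be positive")
    slope, intercept, slope_se, int_se = _weighted_linfit(v, np.log(tau), weights)
    b = -1.0 / slope
    a = float(np.exp(intercept))
    b_se = abs(slope_se / slope**2)
    return ArrheniusFit(a_s=a, b_mV=float(b), a_se=a * int_se, b_se=float(b_se))


def fit_kramers_rate(
    points: list[tuple[float, float]],
    temperature_K: float = 295.0,
    weights: np.ndarray | None = None,
) -> KramersFit:
    """Fit rate_on = r0*exp(z_eff*e*dV/kBT) to (voltage_mV, rate) points.

    Weighted linear regression of ln(rate) on dV; the slope times the
    thermal voltage (kB*T/e, 25.4 mV at 295 K) gives z_eff and the
    exponentiated intercept gives r0. ``weights`` should be
    inverse-variance weights of ln(rate) when rates carry uncertainty.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 (voltage, rate) points")
    if temperature_K <= 0:
        raise ValueError("temperature_K must be positive")
    v, rate = pts[:, 0], pts[:, 1]
    if np.any(rate <= 0):
        raise ValueError("rates must be positive")
    slope, intercept, slope_se, int_se = _weighted_linfit(v, np.log(rate), weights)
    vt = thermal_voltage_mV(temperature_K)
    r0 = float(np.exp(intercept))
    return KramersFit(
        r0_per_s=r0,
        r0_se=r0 * int_se,
        z_eff=float(slope * vt),
        z_eff_se=float(slope_se * vt),
        temperature_K=temperature_K,
    )


def kramers_rate(
    voltage_mV: float | np.ndarray,
    r0_per_s: float,
    z_eff: float,
    temperature_K: float = 295.0,
) -> float | np.ndarray:
    """Forward evaluation rate_on(dV) = r0*exp(z_eff*dV/Vt)."""
    return r0_per_s * np.exp(
        z_eff * np.asarray(voltage_mV, dtype=float) / thermal_voltage_mV(temperature_K)
    )


def barrier_difference(
    r0_A_per_s: float,
    r0_B_per_s: float,
    temperature_K: float = 295.0,
    labels: tuple[str, str] = ("A", "B"),
) -> BarrierDelta:
    """Barrier difference between two conditions from zero-voltage rates.

    dU* = U*(B) - U*(A) = kB*T*ln(r0_A/r0_B): condition A's r0 in the
    numerator, so the result is positive when A captures faster at zero
    voltage, i.e. B has the higher entry barrier. Antisymmetric under
    swapping the arguments. Assumes equal prefactor across the two
    conditions (equal analyte concentration and bulk diffusivity).
    """
    if r0_A_per_s <= 0 or r0_B_per_s <= 0:
        raise ValueError("zero-voltage rates must be positive")
    delta_kBT = float(np.log(r0_A_per_s / r0_B_per_s))
    return BarrierDelta(
        delta_kBT=delta_kBT,
        delta_kcal_per_mol=kBT_to_kcal_per_mol(delta_kBT, temperature_K),
        conditions=labels,
        temperature_K=temperature_K,
    )


def escape_monotonicity(points: list[tuple[float, float]]) -> str:
    """Classify the voltage dependence of the escape time tau_off.

    'translocation' when tau_off decreases with voltage (the analyte is
    driven through), 'return-to-trans' when it increases (the analyte
    backs out against the field), 'flat' otherwise. Qualitative only.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 (voltage, tau_off) points")
    slope = np.polyfit(pts[:, 0], np.log(pts[:, 1]), 1)[0]
    # threshold: a factor-e change over a 500 mV span counts as flat
    if slope < -0.002:
        return "translocation"
    if slope > 0.002:
        return "return-to-trans"
    return "flat"
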