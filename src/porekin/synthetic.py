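"""Synthetic single-channel current traces with ground truth.

A two-state (open/blocked) renewal process stands in for recordings of
reversible analyte capture by a protein nanopore: inter-event (capture)
waiting times are exponential with ``rate_on_true`` and blockade dwell
times exponential with ``rate_off_true``.  Per-sample Gaussian noise is
added after level assignment and the result is optionally low-pass
filtered with a 4-pole Bessel digital filter, the patch-clamp hardware
convention (80 kHz sampling, 10 kHz cutoff by default).

The continuous-time state sequence is kept as ground truth, so events
shorter than the sampling interval or the filter rise time remain in the
annotations even when invisible in the samples — downstream estimators
must handle this censoring explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .constants import require_positive

#: open-pore conductance, pA/mV, chosen so the open current is ~100 pA at
#: +100 mV in 1 M KCl; scaled linearly with salt concentration.
OPEN_CONDUCTANCE_PA_PER_MV_PER_M = 1.0

DEFAULT_SAMPLING_RATE_HZ = 80e3
DEFAULT_FILTER_CUTOFF_HZ = 10e3

#: 10–90% rise time of a 4-pole Bessel low-pass, as a multiple of 1/cutoff
BESSEL4_RISE_TIME_FACTOR = 0.34

OPEN, BLOCKED = "open", "blocked"


@dataclass(frozen=True)
class Condition:
    """Experimental context attached to a trace or fit.

    voltage_mV uses the trans-positive convention (cis grounded); the
    regime of interest is +50…+100 mV.
    """

    pH: float = 7.0
    salt_M: float = 1.0
    voltage_mV: float = 100.0
    analyte_conc_M: float = 500e-6
    temperature_K: float = 295.0

    def __post_init__(self) -> None:
        require_positive(salt_M=self.salt_M, temperature_K=self.temperature_K)
        if not 0 < self.pH < 14:
            raise ValueError(f"pH must be in (0, 14), got {self.pH}")
        if self.analyte_conc_M < 0:
            raise ValueError("analyte_conc_M must be non-negative")


def default_open_current_pA(voltage_mV: float, salt_M: float = 1.0) -> float:
    """Open-pore current from the linear conductance model I_o = G(salt)*V."""
    return OPEN_CONDUCTANCE_PA_PER_MV_PER_M * salt_M * voltage_mV


@dataclass(frozen=True)
class SimParams:
    """Generator settings for one two-state trace."""

    open_current_pA: float = 100.0
    blocked_current_pA: float = 50.0
    rate_on_true: float = 6.0  # 1/s, capture rate (k_on * concentration)
    rate_off_true: float = 2.2e3  # 1/s, escape rate
    noise_sd_pA: float = 1.5  # RMS, added before filtering
    sampling_rate_Hz: float = DEFAULT_SAMPLING_RATE_HZ
    filter_cutoff_Hz: float | None = DEFAULT_FILTER_CUTOFF_HZ
    duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        require_positive(
            rate_on_true=self.rate_on_true,
            rate_off_true=self.rate_off_true,
            sampling_rate_Hz=self.sampling_rate_Hz,
            duration_s=self.duration_s,
        )
        if self.noise_sd_pA < 0:
            raise ValueError("noise_sd_pA must be non-negative")
        if not abs(self.blocked_current_pA) < abs(self.open_current_pA):
            raise ValueError(
                "|blocked_current_pA| must be smaller than |open_current_pA| "
                f"(got {self.blocked_current_pA} vs {self.open_current_pA})"
            )
        if self.filter_cutoff_Hz is not None:
            require_positive(filter_cutoff_Hz=self.filter_cutoff_Hz)
            if self.sampling_rate_Hz < 2 * self.filter_cutoff_Hz:
                raise ValueError(
                    "sampling_rate_Hz must be at least twice filter_cutoff_Hz"
                )


@dataclass
class Trace:
    """Uniformly sampled current record with optional ground truth.

    ``truth`` is a list of (state, start_s, end_s) intervals tiling
    [0, duration] without overlap, recording the unfiltered state
    sequence in continuous time.
    """

    samples_pA: np.ndarray
    dt_s: float
    condition: Condition = field(default_factory=Condition)
    truth: list[tuple[str, float, float]] | None = None

    @property
    def duration_s(self) -> float:
        return len(self.samples_pA) * self.dt_s

    @property
    def sampling_rate_Hz(self) -> float:
        return 1.0 / self.dt_s

    def time_s(self) -> np.ndarray:
        return np.arange(len(self.samples_pA)) * self.dt_s

    def truth_events(self) -> list[tuple[float, float]]:
        """(start, end) of every blocked interval in the ground truth."""
        if self.truth is None:
            raise ValueError("trace carries no ground-truth annotations")
        return [(s, e) for st, s, e in self.truth if st == BLOCKED]


def _draw_state_sequence(
    rng: np.random.Generator, params: SimParams
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating open/blocked interval boundaries covering the duration.

    Returns (boundaries, states): ``boundaries`` are interval end times
    (last one >= duration), ``states[i]`` is 0 (open) or 1 (blocked) for
    the i-th interval. The sequence starts open.
    """
    mean_cycle = 1.0 / params.rate_on_true + 1.0 / params.rate_off_true
    ends: list[np.ndarray] = []
    states: list[np.ndarray] = []
    t = 0.0
    while t < params.duration_s:
        n = max(16, int(2 * params.duration_s / mean_cycle) + 16)
        opens = rng.exponential(1.0 / params.rate_on_true, size=n)
        blocks = rng.exponential(1.0 / params.rate_off_true, size=n)
        durs = np.empty(2 * n)
        durs[0::2] = opens
        durs[1::2] = blocks
        ends.append(t + np.cumsum(durs))
        states.append(np.tile([0, 1], n))
        t = ends[-1][-1]
    boundaries = np.concatenate(ends)
    state_seq = np.concatenate(states)
    keep = np.searchsorted(boundaries, params.duration_s, side="left") + 1
    return boundaries[:keep], state_seq[:keep]


def simulate_two_state_trace(
    params: SimParams, condition: Condition | None = None
) -> Trace:
    """Simulate one two-state blockade trace with ground-truth annotations.

    Identical (params, seed) give byte-identical output. Events shorter
    than the sampling interval are retained in the truth but may not be
    visible in the samples.
    """
    condition = condition or Condition()
    rng = np.random.default_rng(params.seed)
    boundaries, states = _draw_state_sequence(rng, params)

    dt = 1.0 / params.sampling_rate_Hz
    n_samples = round(params.duration_s / dt)
    t = np.arange(n_samples) * dt
    interval_idx = np.searchsorted(boundaries, t, side="right")
    levels = np.array([params.open_current_pA, params.blocked_current_pA])
    samples = levels[states[interval_idx]].astype(float)
    if params.noise_sd_pA > 0:
        samples += rng.normal(0.0, params.noise_sd_pA, size=n_samples)

    starts = np.concatenate([[0.0], boundaries[:-1]])
    truth = [
        (BLOCKED if s else OPEN, float(a), float(min(b, params.duration_s)))
        for s, a, b in zip(states, starts, boundaries)
        if a < params.duration_s
    ]
    trace = Trace(samples_pA=samples, dt_s=dt, condition=condition, truth=truth)
    if params.filter_cutoff_Hz is not None:
        trace = apply_lowpass(trace, params.filter_cutoff_Hz)
    return trace


def bessel_rise_time_s(cutoff_Hz: float) -> float:
    """Approximate 10–90% rise time of the 4-pole Bessel low-pass."""
    require_positive(cutoff_Hz=cutoff_Hz)
    return BESSEL4_RISE_TIME_FACTOR / cutoff_Hz


def apply_lowpass(trace: Trace, cutoff_Hz: float) -> Trace:
    """4-pole Bessel low-pass (-3 dB at ``cutoff_Hz``), causal.

    The filter is initialized at steady state for the first sample, so a
    constant trace passes through unchanged (DC gain 1). Long events keep
    their full amplitude; the step response has a 10–90% rise time of
    about 0.34/cutoff.
    """
    fs = trace.sampling_rate_Hz
    if not 0 < cutoff_Hz < fs / 2:
        raise ValueError(
            f"cutoff_Hz must lie in (0, Nyquist={fs / 2:g} Hz), got {cutoff_Hz}"
        )
    sos = signal.bessel(4, cutoff_Hz, btype="low", fs=fs, output="sos", norm="mag")
    zi = signal.sosfilt_zi(sos) * trace.samples_pA[0]
    filtered, _ = signal.sosfilt(sos, trace.samples_pA, zi=zi)
    return replace(trace, samples_pA=filtered)


# ---------------------------------------------------------------------------
# Trace I/O: CSV (portable) and NPZ (compact container)
# ---------------------------------------------------------------------------

def write_trace_csv(trace: Trace, path: str | Path) -> None:
    """Two-column CSV: time_s, current_pA, with a header line."""
    df = pd.DataFrame({"time_s": trace.time_s(), "current_pA": trace.samples_pA})
    df.to_csv(path, index=False)


def read_trace_csv(path: str | Path, condition: Condition | None = None) -> Trace:
    df = pd.read_csv(path)
    if not {"time_s", "current_pA"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s, current_pA")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = float(np.median(np.diff(t)))
    return Trace(
        samples_pA=df["current_pA"].to_numpy(dtype=float),
        dt_s=dt,
        condition=condition or Condition(),
    )


def write_truth_csv(trace: Trace, path: str | Path) -> None:
    """Ground truth as a 3-column interval table (state, start_s, end_s)."""
    if trace.truth is None:
        raise ValueError("trace carries no ground-truth annotations")
    pd.DataFrame(trace.truth, columns=["state", "start_s", "end_s"]).to_csv(
        path, index=False
    )


def write_trace_npz(trace: Trace, path: str | Path) -> None:
    np.savez_compressed(
        path,
        samples_pA=trace.samples_pA,
        dt_s=trace.dt_s,
        condition=np.array(
            [
                trace.condition.pH,
                trace.condition.salt_M,
                trace.condition.voltage_mV,
                trace.condition.analyte_conc_M,
                trace.condition.temperature_K,
            ]
        ),
    )


def read_trace_npz(path: str | Path) -> Trace:
    with np.load(path) as data:
        pH, salt, v, conc, temp = data["condition"]
        return Trace(
            samples_pA=data["samples_pA"],
            dt_s=float(data["dt_s"]),
            condition=Condition(
                pH=float(pH),
                salt_M=float(salt),
                voltage_mV=float(v),
                analyte_conc_M=float(conc),
                temperature_K=float(temp),
            ),
        )
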