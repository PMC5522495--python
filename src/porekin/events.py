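"""Event detection: idealize a two-level trace into an event table.

A blockade event is a transient excursion of the current from the open
level toward the blocked level. Detection uses hysteresis thresholding
at 75%/25% of the level gap: the detector enters an event when the
current crosses three quarters of the way toward the blocked level and
leaves it when the current recovers past one quarter. The two thresholds
make detection robust to noise without biasing dwell durations of events
much longer than the filter rise time, because the entry and exit delays
cancel to first order.

Events shorter than ``min_duration_s`` are discarded and the cutoff is
recorded as ``censor_floor_s``, which the censored maximum-likelihood
dwell estimator consumes downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .synthetic import Condition, Trace, bessel_rise_time_s


class NoBlockadesError(ValueError):
    """Histogram is unimodal: no blocked level to detect (not an I/O failure)."""


class LevelSeparationError(ValueError):
    """Open and blocked levels are closer than 4x the noise SD."""


@dataclass
class EventTable:
    """Detected blockade events and the waiting times between them.

    ``inter_event_s`` (tau_on) are the gaps preceding each event after
    the first; the leading gap from trace start to the first event is
    discarded (renewal-process convention), so there is one fewer
    inter-event time than events.  ``dwell_s`` (tau_off) are blockade
    durations, all >= ``censor_floor_s``.  Amplitudes are stored signed
    (mean in-event current minus the open level; negative for downward
    blockades at positive voltage) and reported as magnitudes.
    """

    start_s: np.ndarray
    end_s: np.ndarray
    amplitude_pA: np.ndarray
    open_level_pA: float
    blocked_level_pA: float
    censor_floor_s: float = 0.0
    condition: Condition = field(default_factory=Condition)

    @property
    def n_events(self) -> int:
        return len(self.start_s)

    @property
    def dwell_s(self) -> np.ndarray:
        return self.end_s - self.start_s

    @property
    def inter_event_s(self) -> np.ndarray:
        return self.start_s[1:] - self.end_s[:-1]

    def to_frame(self) -> pd.DataFrame:
        tau_on = np.concatenate([[np.nan], self.inter_event_s])
        return pd.DataFrame(
            {
                "start_s": self.start_s,
                "end_s": self.end_s,
                "dwell_s": self.dwell_s,
                "tau_on_s": tau_on,
                "dI_pA": self.amplitude_pA,
            }
        )

    def write_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Event CSV plus a JSON sidecar with levels and condition metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            meta = {
                "open_level_pA": self.open_level_pA,
                "blocked_level_pA": self.blocked_level_pA,
                "censor_floor_s": self.censor_floor_s,
                "condition": vars(self.condition),
            }
            path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def all_points_histogram(
    trace: Trace | np.ndarray, bin_width_pA: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """All-points (every sample) current histogram.

    Returns (bin centers, counts); counts sum to the number of samples
    and the bin grid covers the full data range.
    """
    if bin_width_pA <= 0:
        raise ValueError(f"bin_width_pA must be positive, got {bin_width_pA}")
    x = trace.samples_pA if isinstance(trace, Trace) else np.asarray(trace)
    if x.size == 0:
        raise ValueError("empty trace")
    # bins centred on multiples of the width, so exact discrete levels
    # land on bin centres
    lo = np.floor(x.min() / bin_width_pA + 0.5) * bin_width_pA - 0.5 * bin_width_pA
    hi = np.ceil(x.max() / bin_width_pA - 0.5) * bin_width_pA + 0.5 * bin_width_pA
    n_bins = max(1, int(round((hi - lo) / bin_width_pA)))
    edges = lo + bin_width_pA * np.arange(n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts


def detect_levels(
    histogram: tuple[np.ndarray, np.ndarray],
    snr: float = 5.0,
    min_separation_bins: int = 4,
    top_two: bool = True,
) -> tuple[float, float]:
    """Open and blocked current levels from an all-points histogram.

    A mode is significant when its prominence exceeds ``snr`` Poisson
    standard deviations of its own height (prominence >= snr*sqrt(h+1)),
    so a sparsely occupied blocked level is still found next to a
    dominant open peak while counting fluctuations on the peak flanks
    are rejected. Picks the two most prominent significant modes at
    least ``min_separation_bins`` apart; the larger-magnitude one is
    the open level. With more than two modes, ``top_two=True`` (default)
    keeps the two most prominent, otherwise a ValueError is raised.
    Raises NoBlockadesError when the histogram is unimodal.
    """
    centers, counts = histogram
    padded = np.concatenate([[0.0], counts.astype(float), [0.0]])
    peaks, props = _signal.find_peaks(padded, prominence=0)
    peaks = peaks - 1
    prom = props["prominences"]
    significant = prom >= snr * np.sqrt(counts[peaks] + 1.0)
    peaks, prom = peaks[significant], prom[significant]
    order = np.argsort(prom)[::-1]
    chosen: list[int] = []
    for k in order:
        if all(abs(peaks[k] - peaks[j]) >= min_separation_bins for j in chosen):
            chosen.append(k)
    if len(chosen) < 2:
        raise NoBlockadesError(
            "all-points histogram is unimodal: no blockades detected"
        )
    if len(chosen) > 2 and not top_two:
        raise ValueError(f"histogram has {len(chosen)} modes; expected 2")
    modes = centers[peaks[chosen[:2]]]
    i_open = modes[np.argmax(np.abs(modes))]
    i_blocked = modes[np.argmin(np.abs(modes))]
    return float(i_open), float(i_blocked)


def _estimate_noise_sd(samples: np.ndarray) -> float:
    """Robust noise SD from first differences (MAD-based).

    Level transitions are rare, so the median absolute difference is set
    by the noise; for white noise sd(diff) = sqrt(2)*sd. Correlated
    (filtered) noise is under-estimated, which only makes the level
    separation check more permissive.
    """
    d = np.diff(samples)
    if d.size < 10:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return 1.4826 * mad / np.sqrt(2.0)


def detect_events(
    trace: Trace,
    levels: tuple[float, float] | None = None,
    min_duration_s: float | None = None,
    enter_frac: float = 0.75,
    exit_frac: float = 0.25,
    filter_cutoff_Hz: float | None = None,
) -> EventTable:
    """Hysteresis-threshold event detection on a two-level trace.

    ``levels`` defaults to :func:`detect_levels` on the all-points
    histogram. ``min_duration_s`` defaults to twice the filter rise time
    (~68 us at 10 kHz) when a cutoff is known, else 2 samples; it is
    recorded as the censoring floor for downstream dwell fits.
    """
    if levels is None:
        levels = detect_levels(all_points_histogram(trace))
    i_open, i_blocked = levels
    gap = i_open - i_blocked
    if gap == 0:
        raise LevelSeparationError("open and blocked levels are identical")

    x = trace.samples_pA
    noise_sd = _estimate_noise_sd(x)
    if noise_sd > 0 and abs(gap) < 4 * noise_sd:
        raise LevelSeparationError(
            f"insufficient separation: |gap|={abs(gap):.3g} pA < 4 x noise "
            f"sd={noise_sd:.3g} pA"
        )

    if min_duration_s is None:
        if filter_cutoff_Hz is not None:
            min_duration_s = 2 * bessel_rise_time_s(filter_cutoff_Hz)
        else:
            min_duration_s = 2 * trace.dt_s
    if min_duration_s < 2 * trace.dt_s:
        raise ValueError("min_duration_s must be at least 2 samples")

    thr_enter = i_open - enter_frac * gap
    thr_exit = i_open - exit_frac * gap
    # hysteresis state machine, vectorized: mark definite-blocked (+1) and
    # definite-open (-1) samples, forward-fill the last definite mark
    sign = 1.0 if gap > 0 else -1.0
    marks = np.zeros(len(x), dtype=np.int8)
    marks[sign * x < sign * thr_enter] = 1
    marks[sign * x > sign * thr_exit] = -1
    nz = np.flatnonzero(marks)
    if nz.size == 0:
        return EventTable(
            start_s=np.empty(0),
            end_s=np.empty(0),
            amplitude_pA=np.empty(0),
            open_level_pA=i_open,
            blocked_level_pA=i_blocked,
            censor_floor_s=min_duration_s,
            condition=trace.condition,
        )
    idx = np.zeros(len(x), dtype=np.int64)
    idx[nz] = nz
    np.maximum.accumulate(idx, out=idx)
    blocked = np.zeros(len(x), dtype=bool)
    blocked[nz[0]:] = marks[idx[nz[0]:]] == 1

    edges = np.diff(blocked.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    # drop partial events at the trace boundaries
    if blocked[0] and len(ends) > len(starts):
        ends = ends[1:]
    if len(starts) > len(ends):
        starts = starts[: len(ends)]

    dwell = (ends - starts) * trace.dt_s
    keep = dwell >= min_duration_s
    starts, ends = starts[keep], ends[keep]
    # amplitude from the event core: trim half the censoring floor (one
    # filter rise time at the default) from each end so the filter's
    # settling edges do not dilute the mean toward the open level
    margin = int(round(0.5 * min_duration_s / trace.dt_s))
    amps = []
    for a, b in zip(starts, ends):
        lo, hi = a + margin, b - margin
        if hi - lo < 2:  # short event: plateau barely develops, use center
            mid = (a + b) // 2
            lo, hi = mid, mid + 1
        amps.append(x[lo:hi].mean() - i_open)
    amp = np.asarray(amps, dtype=float)
    return EventTable(
        start_s=starts * trace.dt_s,
        end_s=ends * trace.dt_s,
        amplitude_pA=amp,
        open_level_pA=i_open,
        blocked_level_pA=i_blocked,
        censor_floor_s=min_duration_s,
        condition=trace.condition,
    )


def relative_blockade(table: EventTable) -> tuple[float, float]:
    """Mean relative blockade |dI_block|/|I_o| and its standard error.

    Invariant under rescaling of the current units; an empty table is an
    error, distinct from a genuine ratio of zero.
    """
    if table.n_events == 0:
        raise ValueError("empty event table: relative blockade undefined")
    ratios = np.abs(table.amplitude_pA) / abs(table.open_level_pA)
    se = ratios.std(ddof=1) / np.sqrt(len(ratios)) if len(ratios) > 1 else 0.0
    return float(ratios.mean()), float(se)
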