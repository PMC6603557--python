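"""Averaging good epochs and measuring the N30 peak-to-peak amplitude.

The N30 is the frontal negative SEP deflection near 30 ms after median-nerve
stimulation, quantified here — as is conventional for this component —
peak-to-peak against the preceding positive deflection: the most positive
sample in 15–25 ms and the most negative sample in 25–35 ms are located on
the averaged trace (channel F3, contralateral to the stimulated wrist) and
the amplitude is the absolute difference of the two.  Window boundaries are
inclusive; ties break toward the earlier latency.  An expert may override
either peak latency, which re-reads the amplitudes at the supplied latencies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .epochs import EpochSet

__all__ = ["N30Measurement", "average_good_epochs", "measure_n30", "override_peaks"]


@dataclass(frozen=True)
class N30Measurement:
    channel: str
    pos_latency_ms: float
    pos_amplitude_uv: float
    neg_latency_ms: float
    neg_amplitude_uv: float
    amplitude_uv: float
    manual_adjusted: bool = False
    n_epochs_averaged: int = 0

    def __post_init__(self) -> None:
        expected = abs(self.pos_amplitude_uv - self.neg_amplitude_uv)
        if self.amplitude_uv != expected:
            raise ValueError("amplitude_uv must equal |pos − neg| exactly")


def average_good_epochs(epochs: EpochSet) -> tuple[np.ndarray, int]:
    """Pointwise mean over epochs with empty flag sets.

    Returns (channels x samples mean trace, number of epochs averaged).
    """
    good = epochs.good_mask()
    n = int(good.sum())
    if n == 0:
        raise ValueError("no good epochs to average")
    return epochs.data[good].mean(axis=0), n


def _extremum(
    trace: np.ndarray, time_ms: np.ndarray, window: tuple[float, float], sign: float
) -> tuple[float, float]:
    sel = np.flatnonzero((time_ms >= window[0]) & (time_ms <= window[1]))
    if sel.size == 0:
        raise ValueError(f"window {window} ms contains no samples")
    values = sign * trace[sel]
    best = sel[int(np.argmax(values))]  # argmax takes the first = earliest tie
    return float(time_ms[best]), float(trace[best])


def measure_n30(
    trace: np.ndarray,
    time_ms: np.ndarray,
    channel: str = "F3",
    pos_window_ms: tuple[float, float] = (15.0, 25.0),
    neg_window_ms: tuple[float, float] = (25.0, 35.0),
    n_epochs_averaged: int = 0,
) -> N30Measurement:
    """Locate the positive (15–25 ms) and negative (25–35 ms) peaks on a
    single-channel trace and return their absolute difference."""
    trace = np.asarray(trace, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    for window in (pos_window_ms, neg_window_ms):
        if window[0] < time_ms.min() or window[1] > time_ms.max():
            raise ValueError(f"peak window {window} ms outside the trace span")
    pos_lat, pos_amp = _extremum(trace, time_ms, pos_window_ms, +1.0)
    neg_lat, neg_amp = _extremum(trace, time_ms, neg_window_ms, -1.0)
    return N30Measurement(
        channel=channel,
        pos_latency_ms=pos_lat,
        pos_amplitude_uv=pos_amp,
        neg_latency_ms=neg_lat,
        neg_amplitude_uv=neg_amp,
        amplitude_uv=abs(pos_amp - neg_amp),
        n_epochs_averaged=n_epochs_averaged,
    )


def override_peaks(
    measurement: N30Measurement,
    trace: np.ndarray,
    time_ms: np.ndarray,
    pos_latency_ms: float | None = None,
    neg_latency_ms: float | None = None,
    pos_window_ms: tuple[float, float] = (15.0, 25.0),
    neg_window_ms: tuple[float, float] = (25.0, 35.0),
) -> N30Measurement:
    """Expert override of either peak latency.

    The amplitude is re-read from the trace at the nearest sample to each
    supplied latency; latencies outside their windows are rejected.  With no
    latency supplied the measurement is returned unchanged.
    """
    if pos_latency_ms is None and neg_latency_ms is None:
        return measurement
    trace = np.asarray(trace, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)

    def read_at(lat: float, window: tuple[float, float]) -> tuple[float, float]:
        if not window[0] <= lat <= window[1]:
            raise ValueError(f"override latency {lat} ms outside window {window}")
        i = int(np.argmin(np.abs(time_ms - lat)))
        return float(time_ms[i]), float(trace[i])

    pos_lat, pos_amp = measurement.pos_latency_ms, measurement.pos_amplitude_uv
    neg_lat, neg_amp = measurement.neg_latency_ms, measurement.neg_amplitude_uv
    if pos_latency_ms is not None:
        pos_lat, pos_amp = read_at(pos_latency_ms, pos_window_ms)
    if neg_latency_ms is not None:
        neg_lat, neg_amp = read_at(neg_latency_ms, neg_window_ms)
    return replace(
        measurement,
        pos_latency_ms=pos_lat,
        pos_amplitude_uv=pos_amp,
        neg_latency_ms=neg_lat,
        neg_amplitude_uv=neg_amp,
        amplitude_uv=abs(pos_amp - neg_amp),
        manual_adjusted=True,
    )
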