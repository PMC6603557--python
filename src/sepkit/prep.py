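"""Simplified recording standardization: truncation, bad-channel flagging,
line-noise removal, average reference.

This stage deliberately trades sophistication for determinism: bad channels
are flagged from a robust z-score of per-channel standard deviations (no
RANSAC), line noise is removed by sliding-window sinusoidal regression at the
mains frequency and its harmonics (no notch filtering, which rings badly on
transient-rich data), and the reference is a plain mean over good channels.
"""

from __future__ import annotations

import numpy as np

from .recording import ContinuousRecording

__all__ = [
    "truncate",
    "flag_bad_channels",
    "remove_line_noise",
    "average_reference",
]


def truncate(
    recording: ContinuousRecording, pre_s: float = 30.0, post_s: float = 30.0
) -> ContinuousRecording:
    """Keep data from ``pre_s`` before the first stimulus to ``post_s`` after
    the last, clamped to the recording bounds; events are re-based."""
    if recording.events.size == 0:
        raise ValueError("cannot truncate a recording without events")
    fs = recording.sample_rate_hz
    start = max(0, int(recording.events[0] - round(pre_s * fs)))
    stop = min(recording.n_samples, int(recording.events[-1] + round(post_s * fs)))
    stop = max(stop, int(recording.events[-1]) + 1)  # never cut the last event
    return recording.with_data(
        recording.data[:, start:stop].copy(), events=recording.events - start
    )


def flag_bad_channels(recording: ContinuousRecording, z_thresh: float = 5.0) -> set[str]:
    """Channels whose standard deviation is a robust outlier, or constant.

    The robust z-score is (sd − median sd) / (1.4826·MAD of sd) across
    channels; one-sided (only abnormally large deviation flags a channel),
    plus any channel with zero variance.  Deterministic.
    """
    if recording.n_channels < 3:
        raise ValueError("bad-channel flagging needs at least 3 channels")
    sd = recording.data.std(axis=1)
    med = np.median(sd)
    mad = np.median(np.abs(sd - med))
    flagged = set()
    for label, s in zip(recording.channel_labels, sd):
        if s == 0.0:
            flagged.add(label)
        elif mad > 0 and (s - med) / (1.4826 * mad) > z_thresh:
            flagged.add(label)
    return flagged


def remove_line_noise(
    recording: ContinuousRecording,
    line_hz: float = 50.0,
    n_harmonics: int = 3,
    window_s: float = 4.0,
    significance: float = 10.0,
) -> ContinuousRecording:
    """Subtract least-squares sine/cosine fits at the mains frequency and its
    harmonics, window by window, when the fitted amplitude is significant.

    Each non-overlapping window of ``window_s`` seconds gets its own fit, so
    slow drifts of line amplitude/phase are tracked.  A harmonic is only
    subtracted from a channel when the energy its fit captures exceeds
    ``significance`` times the local noise level, estimated from identical
    sine/cosine fits at probe frequencies ±1.5 and ±3 Hz around the
    harmonic; without such a gate any least-squares fit would shave
    ~sqrt(2k/n) of the RMS off a perfectly clean recording.  Deterministic.
    """
    fs = recording.sample_rate_hz
    nyq = fs / 2.0
    harmonics = [line_hz * k for k in range(1, n_harmonics + 1)]
    if any(h >= nyq for h in harmonics):
        raise ValueError("line-noise harmonic at or above Nyquist")
    probe_offsets = (-3.0, -1.5, 1.5, 3.0)
    data = recording.data.copy()
    n = recording.n_samples
    win = int(round(window_s * fs))
    for start in range(0, n, win):
        stop = min(n, start + win)
        n_win = stop - start
        if n_win < 8 * len(harmonics):
            continue
        t = np.arange(start, stop) / fs
        freqs = [h for h in harmonics]
        freqs += [h + d for h in harmonics for d in probe_offsets if 0 < h + d < nyq]
        design = np.column_stack(
            [f(2.0 * np.pi * fr * t) for fr in freqs for f in (np.sin, np.cos)]
        )
        segment = data[:, start:stop]
        coef, *_ = np.linalg.lstsq(design, segment.T, rcond=None)  # (2 n_freq) x channels
        captures = (coef.reshape(len(freqs), 2, -1) ** 2).sum(axis=1) * n_win / 2.0
        for k, h in enumerate(harmonics):
            probe_idx = [
                i for i, fr in enumerate(freqs[len(harmonics):], start=len(harmonics))
                if abs(fr - h) <= max(abs(d) for d in probe_offsets) + 1e-9
                and any(abs(fr - (h + d)) < 1e-9 for d in probe_offsets)
            ]
            baseline = np.median(captures[probe_idx], axis=0)
            keep = captures[k] > significance * np.maximum(baseline, 1e-300)
            if keep.any():
                fitted = design[:, 2 * k : 2 * k + 2] @ coef[2 * k : 2 * k + 2][:, keep]
                data[keep, start:stop] -= fitted.T
    return recording.with_data(data)


def average_reference(recording: ContinuousRecording) -> ContinuousRecording:
    """Subtract the instantaneous mean over good channels from every channel.

    Bad channels are excluded from the mean but still re-referenced, matching
    their later removal before ICA.  Idempotent.
    """
    good = recording.good_indices()
    if good.size == 0:
        raise ValueError("all channels are bad; no reference can be formed")
    mean = recording.data[good].mean(axis=0)
    return recording.with_data(recording.data - mean, reference="average")
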