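"""Stimulus-locked epoching and baseline correction.

Epochs span −100 to +150 ms around each stimulus (half-open in samples, so
the count is exactly ``round(0.250 · fs)``); the pre-stimulus interval
[−100, 0) ms is the baseline.  Artifact flags are carried per epoch as a set
of rule identifiers; epochs are only ever *marked*, never deleted, and manual
mark/unmark actions are kept in an append-only override log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .recording import ContinuousRecording

__all__ = ["EpochSet", "extract_epochs", "baseline_correct"]

logger = logging.getLogger(__name__)

#: identifiers of the automatic artifact rules plus the manual mark
RULE_VOCABULARY = frozenset({"abs", "p2p", "step", "diff", "flat", "manual"})


@dataclass
class EpochSet:
    """Epochs x channels x samples in μV with per-epoch artifact flags."""

    data: np.ndarray
    time_ms: np.ndarray
    sample_rate_hz: float
    channel_labels: list[str]
    baseline_window_ms: tuple[float, float] = (-100.0, 0.0)
    exclusion_window_ms: tuple[float, float] = (-2.0, 2.0)
    artifact_flags: list[set[str]] = field(default_factory=list)
    manual_overrides: list[tuple[int, str, str]] = field(default_factory=list)
    auto_flags: list[set[str]] = field(default_factory=list)
    bad_channels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if self.data.shape[2] != len(self.time_ms):
            raise ValueError("time axis length mismatch")
        if not (self.time_ms.min() <= 0.0 <= self.time_ms.max()):
            raise ValueError("time axis must include 0 (the stimulus)")
        if not self.artifact_flags:
            self.artifact_flags = [set() for _ in range(self.n_epochs)]
        if not self.auto_flags:
            self.auto_flags = [set(f) for f in self.artifact_flags]
        if len(self.artifact_flags) != self.n_epochs:
            raise ValueError("one flag set per epoch required")
        for flags in self.artifact_flags:
            unknown = flags - RULE_VOCABULARY
            if unknown:
                raise ValueError(f"unknown artifact rule ids: {sorted(unknown)}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}") from None

    def good_mask(self) -> np.ndarray:
        """Boolean mask of epochs with an empty flag set."""
        return np.array([not f for f in self.artifact_flags], dtype=bool)

    def exclusion_mask(self) -> np.ndarray:
        """Boolean mask, True where a sample is *usable* (outside the
        stimulus-artifact exclusion window, endpoints excluded)."""
        lo, hi = self.exclusion_window_ms
        return ~((self.time_ms >= lo) & (self.time_ms <= hi))

    def copy(self, **kwargs) -> "EpochSet":
        kwargs.setdefault("data", self.data.copy())
        kwargs.setdefault("artifact_flags", [set(f) for f in self.artifact_flags])
        kwargs.setdefault("auto_flags", [set(f) for f in self.auto_flags])
        kwargs.setdefault("manual_overrides", list(self.manual_overrides))
        return replace(self, **kwargs)

    def flags_frame(self) -> pd.DataFrame:
        """Per-epoch flags as a TSV-ready table."""
        return pd.DataFrame(
            {
                "epoch_index": np.arange(self.n_epochs),
                "rules": [",".join(sorted(f)) for f in self.artifact_flags],
                "manual": ["manual" in f for f in self.artifact_flags],
            }
        )


def extract_epochs(
    recording: ContinuousRecording,
    window_ms: tuple[float, float] = (-100.0, 150.0),
    baseline_window_ms: tuple[float, float] = (-100.0, 0.0),
) -> EpochSet:
    """Cut stimulus-locked epochs out of a continuous recording.

    The window is half-open in samples: ``round(window·fs)`` samples starting
    at ``event + round(win_lo·fs)``.  Events whose window does not fit inside
    the recording are dropped with a logged warning; the sample at time 0 is
    the event sample.
    """
    if recording.events.size == 0:
        raise ValueError("no events to epoch around")
    fs = recording.sample_rate_hz
    start_off = int(round(window_ms[0] / 1000.0 * fs))
    n_samp = int(round((window_ms[1] - window_ms[0]) / 1000.0 * fs))
    epochs = []
    n_dropped = 0
    for ev in recording.events:
        a = ev + start_off
        if a < 0 or a + n_samp > recording.n_samples:
            n_dropped += 1
            continue
        epochs.append(recording.data[:, a : a + n_samp])
    if n_dropped:
        logger.warning("dropped %d event(s) with incomplete epoch windows", n_dropped)
    if not epochs:
        raise ValueError("no event has a complete epoch window")
    time_ms = (np.arange(n_samp) + start_off) / fs * 1000.0
    return EpochSet(
        data=np.stack(epochs),
        time_ms=time_ms,
        sample_rate_hz=fs,
        channel_labels=list(recording.channel_labels),
        baseline_window_ms=baseline_window_ms,
        bad_channels=set(recording.bad_channels),
    )


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract the mean over the pre-stimulus baseline window, per epoch and
    channel.  Idempotent."""
    lo, hi = epochs.baseline_window_ms
    sel = (epochs.time_ms >= lo) & (epochs.time_ms < hi)
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    baseline = epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    return epochs.copy(data=epochs.data - baseline)
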