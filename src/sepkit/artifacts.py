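"""Epoch-level artifact rules with a stimulus-window exclusion.

Five rules run on every tested channel of every epoch; an epoch is flagged
if any channel violates any rule:

* ``abs``  — absolute voltage above 100 μV;
* ``p2p``  — peak-to-peak above 150 μV in a 200 ms window, 100 ms steps;
* ``step`` — half-window mean difference above 100 μV in a 200 ms window,
  50 ms steps (catches step-like baseline jumps);
* ``diff`` — sample-to-sample difference above 50 μV;
* ``flat`` — absolute voltage under 2 μV for more than 125 ms of
  consecutive samples (flatline / blocking).

Samples inside the stimulus-artifact exclusion window (−2 to 2 ms by
default) are masked out of every computation; sliding windows evaluate only
their unmasked samples and a masked gap breaks a flatline run.  Epochs are
marked, never deleted; manual mark/unmark actions go through an append-only
override log and the automatic flags stay in provenance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet

__all__ = [
    "ArtifactRuleSet",
    "detect_artifacts",
    "sliding_p2p",
    "step_statistic",
    "apply_manual_overrides",
    "count_artifacts",
]


@dataclass
class ArtifactRuleSet:
    """Thresholds and window geometry of the five rules (μV / ms)."""

    abs_thresh_uv: float = 100.0
    p2p_thresh_uv: float = 150.0
    p2p_window_ms: float = 200.0
    p2p_step_ms: float = 100.0
    step_thresh_uv: float = 100.0
    step_window_ms: float = 200.0
    step_step_ms: float = 50.0
    s2s_thresh_uv: float = 50.0
    flat_thresh_uv: float = 2.0
    flat_min_dur_ms: float = 125.0
    exclusion_ms: tuple[float, float] = (-2.0, 2.0)

    def __post_init__(self) -> None:
        for name in (
            "abs_thresh_uv",
            "p2p_thresh_uv",
            "p2p_window_ms",
            "p2p_step_ms",
            "step_thresh_uv",
            "step_window_ms",
            "step_step_ms",
            "s2s_thresh_uv",
            "flat_thresh_uv",
            "flat_min_dur_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _window_starts(n: int, window: int, step: int) -> list[int]:
    """Window anchors: epoch start, advancing by ``step``, plus one final
    window flush with the epoch end so the tail is always covered."""
    starts = list(range(0, n - window + 1, step))
    flush = n - window
    if flush >= 0 and flush not in starts:
        starts.append(flush)
    return starts


def _to_samples(ms: float, fs: float) -> int:
    return max(1, int(round(ms / 1000.0 * fs)))


def sliding_p2p(
    trace: np.ndarray,
    window_ms: float,
    step_ms: float,
    mask: np.ndarray,
    sample_rate_hz: float,
) -> float:
    """Maximum peak-to-peak (max − min of unmasked samples) over sliding
    windows.  ``mask`` is True where a sample is usable."""
    trace = np.asarray(trace, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 unmasked samples")
    n = len(trace)
    window = min(n, _to_samples(window_ms, sample_rate_hz))
    step = _to_samples(step_ms, sample_rate_hz)
    if window > n:
        raise ValueError("rule window longer than the epoch")
    best = 0.0
    for start in _window_starts(n, window, step):
        seg = trace[start : start + window][mask[start : start + window]]
        if seg.size >= 2:
            best = max(best, float(seg.max() - seg.min()))
    return best


def step_statistic(
    trace: np.ndarray,
    window_ms: float,
    step_ms: float,
    mask: np.ndarray,
    sample_rate_hz: float,
) -> float:
    """Maximum |mean(second half) − mean(first half)| over sliding windows,
    the step-function statistic; halves are split at the window midpoint and
    use unmasked samples only."""
    trace = np.asarray(trace, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 unmasked samples")
    n = len(trace)
    window = min(n, _to_samples(window_ms, sample_rate_hz))
    step = _to_samples(step_ms, sample_rate_hz)
    half = window // 2
    best = 0.0
    for start in _window_starts(n, window, step):
        first = trace[start : start + half][mask[start : start + half]]
        second = trace[start + half : start + window][mask[start + half : start + window]]
        if first.size and second.size:
            best = max(best, abs(float(second.mean() - first.mean())))
    return best


def _flatline_max_run_ms(
    trace: np.ndarray, thresh_uv: float, mask: np.ndarray, fs: float
) -> float:
    """Longest run of consecutive unmasked samples with |v| < thresh, in ms.
    A masked gap breaks the run."""
    quiet = (np.abs(trace) < thresh_uv) & mask
    best = run = 0
    for q in quiet:
        run = run + 1 if q else 0
        best = max(best, run)
    return best / fs * 1000.0


def _max_abs_diff(trace: np.ndarray, mask: np.ndarray) -> float:
    """Largest |difference| between adjacent samples, both unmasked."""
    both = mask[:-1] & mask[1:]
    if not both.any():
        return 0.0
    return float(np.max(np.abs(np.diff(trace))[both]))


def detect_artifacts(
    epochs: EpochSet,
    rules: ArtifactRuleSet | None = None,
    channels: list[str] | None = None,
) -> EpochSet:
    """Run the five rules and return a copy with flags set.

    ``channels`` defaults to all channels not in ``bad_channels``.  Existing
    manual flags survive; automatic flags are recomputed and also stored in
    ``auto_flags`` for provenance.
    """
    rules = rules or ArtifactRuleSet()
    if channels is None:
        channels = [c for c in epochs.channel_labels if c not in epochs.bad_channels]
    if not channels:
        raise ValueError("no channels to test")
    idx = [epochs.channel_index(c) for c in channels]
    fs = epochs.sample_rate_hz
    lo, hi = rules.exclusion_ms
    mask = ~((epochs.time_ms >= lo) & (epochs.time_ms <= hi))
    n = epochs.n_samples
    for w_ms in (rules.p2p_window_ms, rules.step_window_ms):
        if _to_samples(w_ms, fs) > n:
            raise ValueError("rule window longer than the epoch")
    out = epochs.copy(exclusion_window_ms=rules.exclusion_ms)
    for e in range(out.n_epochs):
        flags: set[str] = set()
        for ch in idx:
            trace = out.data[e, ch]
            if np.max(np.abs(trace[mask])) > rules.abs_thresh_uv:
                flags.add("abs")
            if (
                sliding_p2p(trace, rules.p2p_window_ms, rules.p2p_step_ms, mask, fs)
                > rules.p2p_thresh_uv
            ):
                flags.add("p2p")
            if (
                step_statistic(trace, rules.step_window_ms, rules.step_step_ms, mask, fs)
                > rules.step_thresh_uv
            ):
                flags.add("step")
            if _max_abs_diff(trace, mask) > rules.s2s_thresh_uv:
                flags.add("diff")
            if _flatline_max_run_ms(trace, rules.flat_thresh_uv, mask, fs) > rules.flat_min_dur_ms:
                flags.add("flat")
        manual = out.artifact_flags[e] & {"manual"}
        out.auto_flags[e] = set(flags)
        out.artifact_flags[e] = flags | manual
    return out


def apply_manual_overrides(
    epochs: EpochSet, overrides: list[tuple[int, str, str]]
) -> EpochSet:
    """Apply (epoch, action, reason) overrides; action is ``mark`` or
    ``unmark``.

    Unmarking clears the epoch's current flags (the automatic flags stay in
    ``auto_flags`` provenance); marking adds the ``manual`` flag.  Every
    action is appended to the override log.
    """
    out = epochs.copy()
    for epoch_idx, action, reason in overrides:
        if not 0 <= epoch_idx < out.n_epochs:
            raise IndexError(f"unknown epoch index {epoch_idx}")
        if action == "mark":
            out.artifact_flags[epoch_idx].add("manual")
        elif action == "unmark":
            out.artifact_flags[epoch_idx].clear()
        else:
            raise ValueError(f"unknown override action {action!r}")
        out.manual_overrides.append((epoch_idx, action, reason))
    return out


def count_artifacts(epochs: EpochSet) -> int:
    """Number of epochs currently carrying a non-empty flag set."""
    return int(sum(1 for f in epochs.artifact_flags if f))
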