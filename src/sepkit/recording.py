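"""Continuous multi-channel EEG container and delimited-text I/O.

A :class:`ContinuousRecording` holds a channels x samples voltage matrix in
microvolts together with the sampling rate, channel labels (10-20 names),
stimulus events as sample indices, and bookkeeping about bad channels and the
reference state.  On disk a recording is a plain-text triple: a TSV sample
matrix (one column per channel, header row of labels), a two-column events TSV
(sample_index, code) and a small JSON sidecar with the scalar metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ContinuousRecording", "load_recording", "save_recording"]


@dataclass
class ContinuousRecording:
    """Continuous EEG: ``data[ch, t]`` in μV at ``sample_rate_hz``.

    ``events`` are stimulus onsets as strictly increasing sample indices into
    the data.  ``bad_channels`` is a subset of ``channel_labels``; bad
    channels are kept in the matrix but excluded from referencing and ICA.
    """

    sample_rate_hz: float
    channel_labels: list[str]
    data: np.ndarray
    events: np.ndarray
    bad_channels: set[str] = field(default_factory=set)
    reference: str = "raw"  # {"raw", "average"}

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")
        self.events = np.asarray(self.events, dtype=np.int64)
        if self.events.size:
            if np.any(np.diff(self.events) <= 0):
                raise ValueError("events must be strictly increasing")
            if self.events[0] < 0 or self.events[-1] >= self.n_samples:
                raise ValueError("events outside the data range")
        unknown = set(self.bad_channels) - set(self.channel_labels)
        if unknown:
            raise ValueError(f"bad_channels not in channel_labels: {sorted(unknown)}")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}") from None

    @property
    def good_channels(self) -> list[str]:
        return [c for c in self.channel_labels if c not in self.bad_channels]

    def good_indices(self) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.channel_labels) if c not in self.bad_channels],
            dtype=np.intp,
        )

    def with_data(self, data: np.ndarray, **kwargs) -> "ContinuousRecording":
        """Copy of this recording with a replaced data matrix."""
        return replace(self, data=data, **kwargs)


def save_recording(rec: ContinuousRecording, prefix: str | Path) -> None:
    """Write ``<prefix>.tsv``, ``<prefix>.events.tsv`` and ``<prefix>.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rec.data.T, columns=rec.channel_labels).to_csv(
        prefix.with_suffix(".tsv"), sep="\t", index=False, float_format="%.6f"
    )
    pd.DataFrame({"sample_index": rec.events, "code": 1}).to_csv(
        prefix.parent / (prefix.name + ".events.tsv"), sep="\t", index=False
    )
    meta = {
        "sample_rate_hz": rec.sample_rate_hz,
        "bad_channels": sorted(rec.bad_channels),
        "reference": rec.reference,
    }
    (prefix.with_suffix(".json")).write_text(json.dumps(meta, indent=1))


def load_recording(prefix: str | Path) -> ContinuousRecording:
    """Read the triple written by :func:`save_recording`."""
    prefix = Path(prefix)
    frame = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    events = pd.read_csv(prefix.parent / (prefix.name + ".events.tsv"), sep="\t")
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return ContinuousRecording(
        sample_rate_hz=float(meta["sample_rate_hz"]),
        channel_labels=list(frame.columns),
        data=frame.to_numpy().T,
        events=events["sample_index"].to_numpy(),
        bad_channels=set(meta.get("bad_channels", [])),
        reference=meta.get("reference", "raw"),
    )
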