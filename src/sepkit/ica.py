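"""Applying a precomputed ICA unmixing and removing labelled components.

The decomposition algorithm itself is a pluggable contract: this module only
needs an unmixing matrix (components x channels), its pseudo-inverse mixing
matrix, and one label per component.  Non-brain components (muscle, eye,
channel noise, line noise) are removed by back-projecting the retained
components onto the modelled channel subset.  Ground-truth mixing matrices
from :mod:`sepkit.synth` exercise the whole path in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .epochs import EpochSet, extract_epochs
from .filters import FilterClass, FilterMode, FilterSpec, apply_zero_phase, design_fir
from .recording import ContinuousRecording

__all__ = [
    "COMPONENT_LABELS",
    "NON_BRAIN_LABELS",
    "ICAModel",
    "prepare_for_ica",
    "apply_ica_weights",
    "remove_components",
    "read_ica_model",
    "write_ica_model",
]

COMPONENT_LABELS = ("brain", "muscle", "eye", "channel_noise", "line_noise")
NON_BRAIN_LABELS = frozenset({"muscle", "eye", "channel_noise", "line_noise"})


@dataclass
class ICAModel:
    """Unmixing/mixing pair with per-component labels.

    ``unmixing`` maps the modelled channels to component activations;
    ``mixing`` (its pseudo-inverse by default) back-projects activations to
    channels.  ``unmixing · mixing`` must be the identity on component space.
    """

    unmixing: np.ndarray
    channel_subset: list[str]
    labels: list[str]
    mixing: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.unmixing = np.asarray(self.unmixing, dtype=np.float64)
        n_comp, n_chan = self.unmixing.shape
        if n_chan != len(self.channel_subset):
            raise ValueError("unmixing columns must match channel_subset")
        if len(self.labels) != n_comp:
            raise ValueError("one label per component required")
        unknown = set(self.labels) - set(COMPONENT_LABELS)
        if unknown:
            raise ValueError(f"unknown component labels: {sorted(unknown)}")
        if self.mixing is None:
            self.mixing = np.linalg.pinv(self.unmixing)
        else:
            self.mixing = np.asarray(self.mixing, dtype=np.float64)
        ident = self.unmixing @ self.mixing
        if not np.allclose(ident, np.eye(n_comp), atol=1e-8):
            raise ValueError("mixing is not a (pseudo-)inverse of unmixing")

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def component_indices(self, labels: frozenset[str] | set[str]) -> np.ndarray:
        return np.array(
            [i for i, lab in enumerate(self.labels) if lab in labels], dtype=np.intp
        )


def prepare_for_ica(
    recording: ContinuousRecording,
    epoch_flags: list[set[str]] | None = None,
    target_rate_hz: float = 512.0,
    window_ms: tuple[float, float] = (-100.0, 150.0),
    anti_alias_transition_hz: float | None = None,
) -> EpochSet:
    """Downsample, epoch, drop flagged epochs and bad channels.

    The decimation factor must be an integer (2048→512 is 4).  An anti-alias
    Kaiser FIR low-pass at 0.8x the target Nyquist runs before decimation.
    ``epoch_flags`` are per-epoch flag sets aligned with the recording's
    events (flagged epochs are excluded from the output).
    """
    fs = recording.sample_rate_hz
    factor = fs / target_rate_hz
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(f"decimation factor {factor} is not a positive integer")
    factor = int(round(factor))
    if factor > 1:
        cutoff = 0.8 * (target_rate_hz / 2.0)
        transition = anti_alias_transition_hz or 0.2 * (target_rate_hz / 2.0)
        aa = design_fir(
            FilterSpec(
                filter_class=FilterClass.FIR_KAISER,
                mode=FilterMode.LOWPASS,
                cutoffs_hz=(cutoff,),
                sample_rate_hz=fs,
                transition_bw_hz=transition,
            )
        )
        recording = apply_zero_phase(aa, recording)
    down = recording.with_data(
        np.ascontiguousarray(recording.data[:, ::factor]),
        events=recording.events // factor,
        sample_rate_hz=recording.sample_rate_hz / factor,
    )
    epochs = extract_epochs(down, window_ms=window_ms)
    if epoch_flags is not None:
        if len(epoch_flags) != epochs.n_epochs:
            raise ValueError("epoch_flags length must match the epoch count")
        keep = [i for i, f in enumerate(epoch_flags) if not f]
        epochs = epochs.copy(
            data=epochs.data[keep],
            artifact_flags=[set() for _ in keep],
            auto_flags=[set() for _ in keep],
        )
    good = [c for c in epochs.channel_labels if c not in epochs.bad_channels]
    keep_idx = [epochs.channel_index(c) for c in good]
    return epochs.copy(
        data=epochs.data[:, keep_idx], channel_labels=good, bad_channels=set()
    )


def apply_ica_weights(epochs: EpochSet, model: ICAModel) -> np.ndarray:
    """Component activations, epochs x components x samples."""
    missing = [c for c in model.channel_subset if c not in epochs.channel_labels]
    if missing:
        raise ValueError(f"epochs lack modelled channels: {missing}")
    idx = [epochs.channel_index(c) for c in model.channel_subset]
    return np.einsum("kc,ecs->eks", model.unmixing, epochs.data[:, idx])


def remove_components(
    epochs: EpochSet,
    model: ICAModel,
    remove_labels: frozenset[str] | set[str] = NON_BRAIN_LABELS,
) -> EpochSet:
    """Back-project with the labelled components removed.

    Channels in the model's subset are replaced by
    ``mixing[:, retained] · activations[retained]``; channels outside the
    subset are untouched.  Removing nothing reproduces the input on the
    modelled subspace.
    """
    drop = model.component_indices(remove_labels)
    retained = np.setdiff1d(np.arange(model.n_components), drop)
    if retained.size == 0:
        raise ValueError("cannot remove every component")
    activations = apply_ica_weights(epochs, model)
    cleaned_subset = np.einsum(
        "ck,eks->ecs", model.mixing[:, retained], activations[:, retained]
    )
    idx = [epochs.channel_index(c) for c in model.channel_subset]
    out = epochs.copy()
    out.data[:, idx] = cleaned_subset
    return out


def write_ica_model(model: ICAModel, weights_path: str | Path, labels_path: str | Path) -> None:
    """Unmixing as TSV (header = channel subset) and one label per line."""
    frame = pd.DataFrame(model.unmixing, columns=model.channel_subset)
    frame.to_csv(weights_path, sep="\t", index=False, float_format="%.12e")
    Path(labels_path).write_text("\n".join(model.labels) + "\n")


def read_ica_model(weights_path: str | Path, labels_path: str | Path) -> ICAModel:
    frame = pd.read_csv(weights_path, sep="\t")
    labels = Path(labels_path).read_text().split()
    return ICAModel(
        unmixing=frame.to_numpy(),
        channel_subset=list(frame.columns),
        labels=labels,
    )
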