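"""Synthetic multi-channel EEG with ground-truth SEPs, artifacts and mixing.

The generator emulates a median-nerve SEP session: stimuli at 2.3 Hz, an
evoked complex with a positive lobe near 20 ms and a negative lobe near
30 ms maximal at F3, 1/f background activity on every channel, eye-blink
pulses with a frontal topography, band-limited muscle bursts, a 50 Hz mains
line, a brief biphasic stimulus artifact at each onset, and optionally flat
channels.  Everything except the stimulus artifact and the flat channels is
produced as ``mixing · sources`` from a known square mixing matrix, so the
true unmixing (and true component labels) come for free and the ICA-cleanup
path can be tested against ground truth.

The evoked template is a pair of Gaussian lobes with deliberately unequal
widths (5 ms positive, 8 ms negative FWHM): the resulting complex has
non-zero net area, hence substantial spectral energy below 30 Hz, which is
what makes a 30 Hz high-pass attenuate the measured peak-to-peak amplitude —
the physiologically relevant regime for comparing passbands.

Each source type draws from its own RNG stream split off the master seed, so
enabling or re-parameterizing one artifact type never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .artifacts import ArtifactRuleSet, detect_artifacts
from .epochs import EpochSet, baseline_correct, extract_epochs
from .filters import FilterClass, FilterMode, FilterSpec, apply_zero_phase, design_filter
from .ica import ICAModel, remove_components
from .prep import remove_line_noise
from .quantify import average_good_epochs, measure_n30
from .recording import ContinuousRecording

__all__ = [
    "CHANNEL_LABELS_62",
    "SyntheticConfig",
    "GroundTruth",
    "sep_template",
    "generate_recording",
    "generate_condition_grid",
    "BANDS",
]

#: 62-channel 10-10 montage, ordered roughly front to back so that truncated
#: montages (n_channels < 62) stay frontal-heavy and always contain F3.
CHANNEL_LABELS_62 = [
    "Fz", "F3", "F4", "F1", "F2", "F5", "F6", "F7", "F8",
    "Fp1", "Fp2", "Fpz", "AF3", "AF4", "AF7", "AF8",
    "FC1", "FC2", "FC3", "FC4", "FC5", "FC6", "FT7", "FT8",
    "Cz", "C1", "C2", "C3", "C4", "C5", "C6", "T7", "T8",
    "CP1", "CP2", "CP3", "CP4", "CP5", "CP6", "TP7", "TP8",
    "Pz", "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8",
    "PO3", "PO4", "PO7", "PO8", "POz", "Oz", "O1", "O2",
    "PO9", "PO10", "TP9", "TP10",
]

#: the three passbands of the condition grid, Hz
BANDS = ((0.5, 1000.0), (3.0, 1000.0), (30.0, 1000.0))


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the generator.

    Defaults mirror the acquisition being emulated: 62 channels at 2048 Hz,
    1000 median-nerve stimuli at 2.3 Hz, with 31 s of padding on both sides
    so a 30 s truncation margin survives.  Amplitudes are in μV.
    """

    n_channels: int = 62
    sample_rate_hz: float = 2048.0
    n_stimuli: int = 1000
    stim_rate_hz: float = 2.3
    #: uniform stimulus-timing jitter (±ms): real stimulators are not sample
    #: exact, and exact periodicity would beat coherently against the mains
    stim_jitter_ms: float = 2.0
    edge_s: float = 31.0
    #: evoked lobes as (center_ms, fwhm_ms, amplitude_uv), peak channel F3
    sep_lobes: tuple[tuple[float, float, float], ...] = ((20.0, 5.0, 2.0), (30.0, 8.0, -2.5))
    noise_exponent: float = 1.0
    noise_rms_uv: float = 8.0
    blink_rate_per_min: float = 4.0
    blink_amplitude_uv: float = 150.0
    blink_duration_ms: float = 300.0
    muscle_rate_per_min: float = 3.0
    muscle_amplitude_uv: float = 30.0
    muscle_band_hz: tuple[float, float] = (20.0, 300.0)
    muscle_duration_ms: float = 250.0
    #: stimulus-locked reflex EMG (motor-threshold stimulation twitches the
    #: thumb): trial-invariant biphasic mean waveform on the muscle source,
    #: lobes near 22/32 ms, μV at source level
    reflex_emg_uv: float = 1.5
    line_hz: float = 50.0
    line_amplitude_uv: float = 5.0
    stim_artifact_uv: float = 50.0
    flat_channels: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 5:
            raise ValueError("generator needs at least 5 channels")
        if self.n_stimuli < 1 or self.stim_rate_hz <= 0:
            raise ValueError("need a positive stimulus count and rate")
        for name in ("noise_rms_uv", "blink_amplitude_uv", "muscle_amplitude_uv",
                     "line_amplitude_uv", "stim_artifact_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for center, _width, _amp in self.sep_lobes:
            if not -100.0 < center < 150.0:
                raise ValueError("evoked template lobe outside the epoch window")

    @property
    def channel_labels(self) -> list[str]:
        return CHANNEL_LABELS_62[: self.n_channels]


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would not."""

    sources: np.ndarray  # sources x samples, μV
    mixing: np.ndarray  # channels x sources
    source_labels: list[str]
    events: np.ndarray
    epoch_labels: list[set[str]]  # per stimulus: {"eye", "muscle", ...}
    flat_channels: list[str]
    stim_template: np.ndarray  # per-sample biphasic artifact kernel
    stim_topography: np.ndarray
    true_n30_uv: float
    sep_kernel: np.ndarray  # evoked template at the peak channel
    sep_kernel_time_ms: np.ndarray
    config: SyntheticConfig = field(repr=False, default=None)


def sep_template(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Evoked kernel at the peak channel, sampled on [0, 60] ms."""
    fs = config.sample_rate_hz
    t_ms = np.arange(int(round(0.060 * fs))) / fs * 1000.0
    kernel = np.zeros_like(t_ms)
    for center, fwhm, amp in config.sep_lobes:
        sigma = fwhm / 2.3548200450309493  # FWHM -> Gaussian σ
        kernel += amp * np.exp(-0.5 * ((t_ms - center) / sigma) ** 2)
    return kernel, t_ms


def _one_over_f_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with a |f|^(−exponent) power spectrum via FFT shaping."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC blow-up
    shaped = np.fft.irfft(spectrum * shaping, n=n)
    return shaped / shaped.std()


def _event_samples(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    fs = config.sample_rate_hz
    times = config.edge_s * fs + np.arange(config.n_stimuli) * fs / config.stim_rate_hz
    if config.stim_jitter_ms > 0:
        jitter = rng.uniform(-config.stim_jitter_ms, config.stim_jitter_ms, config.n_stimuli)
        times = times + jitter / 1000.0 * fs
    events = np.round(times).astype(np.int64)
    n_samples = int(events[-1] + round(config.edge_s * fs))
    return events, n_samples


def _burst_starts(
    rate_per_min: float, n_samples: int, fs: float, burst_len: int, rng: np.random.Generator
) -> np.ndarray:
    expected = rate_per_min * (n_samples / fs) / 60.0
    count = rng.poisson(expected)
    if count == 0:
        return np.array([], dtype=np.int64)
    starts = rng.integers(0, max(1, n_samples - burst_len), size=count)
    return np.sort(starts)


def generate_recording(
    config: SyntheticConfig,
) -> tuple[ContinuousRecording, GroundTruth, ICAModel]:
    """Generate a recording with ground truth and the true ICA model.

    The recording is ``mixing · sources`` plus the (post-mixing) stimulus
    artifact, with flat channels zeroed last.  Identical seeds give
    byte-identical output.
    """
    fs = config.sample_rate_hz
    labels = config.channel_labels
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_blink, rng_muscle, rng_line, rng_noise, rng_mixing, rng_timing = (
        np.random.default_rng(s) for s in streams
    )
    events, n_samples = _event_samples(config, rng_timing)

    n_bg = config.n_channels - 4
    n_src = config.n_channels
    sources = np.zeros((n_src, n_samples))
    source_labels = ["brain", "eye", "muscle", "line_noise"] + ["brain"] * n_bg

    # --- evoked source -----------------------------------------------------
    kernel, kernel_t = sep_template(config)
    for ev in events:
        stop = min(n_samples, ev + len(kernel))
        sources[0, ev:stop] += kernel[: stop - ev]

    # --- eye blinks: smoothed step pulses, frontal topography --------------
    blink_len = max(4, int(round(config.blink_duration_ms / 1000.0 * fs)))
    blink_shape = scipy.signal.windows.tukey(blink_len, alpha=0.5)
    blink_starts = _burst_starts(config.blink_rate_per_min, n_samples, fs, blink_len, rng_blink)
    for start in blink_starts:
        stop = min(n_samples, start + blink_len)
        sources[1, start:stop] += config.blink_amplitude_uv * blink_shape[: stop - start]

    # --- muscle bursts: band-limited noise under a smooth envelope ---------
    burst_len = max(8, int(round(config.muscle_duration_ms / 1000.0 * fs)))
    lo, hi = config.muscle_band_hz
    hi = min(hi, 0.45 * fs)
    sos = scipy.signal.butter(4, (lo, hi), "bandpass", fs=fs, output="sos")
    muscle_starts = _burst_starts(
        config.muscle_rate_per_min, n_samples, fs, burst_len, rng_muscle
    )
    envelope = scipy.signal.windows.hann(burst_len)
    for start in muscle_starts:
        burst = scipy.signal.sosfilt(sos, rng_muscle.standard_normal(burst_len))
        rms = burst.std() or 1.0
        burst = burst / rms * config.muscle_amplitude_uv * envelope
        stop = min(n_samples, start + burst_len)
        sources[2, start:stop] += burst[: stop - start]

    # stimulus-locked reflex EMG: the same biphasic mean waveform after every
    # stimulus (motor-threshold stimulation evokes a consistent twitch), so it
    # survives epoch averaging and inflates the apparent evoked amplitude
    # until the muscle component is removed
    if config.reflex_emg_uv > 0:
        reflex_t = kernel_t
        reflex = config.reflex_emg_uv * (
            np.exp(-0.5 * ((reflex_t - 22.0) / 2.0) ** 2)
            - np.exp(-0.5 * ((reflex_t - 32.0) / 2.5) ** 2)
        )
        for ev in events:
            stop = min(n_samples, ev + len(reflex))
            sources[2, ev:stop] += reflex[: stop - ev]

    # --- mains line --------------------------------------------------------
    phase = rng_line.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n_samples) / fs
    sources[3] = config.line_amplitude_uv * np.sin(2.0 * np.pi * config.line_hz * t + phase)

    # --- 1/f background, one source per remaining channel ------------------
    for j in range(n_bg):
        sources[4 + j] = config.noise_rms_uv * _one_over_f_noise(
            n_samples, config.noise_exponent, rng_noise
        )

    # --- mixing matrix -----------------------------------------------------
    mixing = _build_mixing(config, rng_mixing)

    data = mixing @ sources

    # --- stimulus artifact (post-mixing, broad topography) -----------------
    stim_len = max(2, int(round(0.002 * fs)))  # one full cycle over ±1 ms
    stim_t = (np.arange(stim_len) - stim_len // 2) / fs * 1000.0
    stim_template = config.stim_artifact_uv * np.sin(np.pi * stim_t / 1.0)
    stim_template[np.abs(stim_t) > 1.0] = 0.0
    stim_topo = np.ones(config.n_channels)
    for ev in events:
        a = ev - stim_len // 2
        b = a + stim_len
        if 0 <= a and b <= n_samples:
            data[:, a:b] += np.outer(stim_topo, stim_template)

    # --- flat channels -----------------------------------------------------
    flat_labels = [labels[i] for i in config.flat_channels]
    for i in config.flat_channels:
        data[i] = 0.0

    recording = ContinuousRecording(
        sample_rate_hz=fs,
        channel_labels=labels,
        data=data,
        events=events,
        bad_channels=set(flat_labels),
    )

    # --- per-epoch ground-truth labels -------------------------------------
    pre = int(round(0.100 * fs))
    post = int(round(0.150 * fs))
    blink_iv = [(s, s + blink_len) for s in blink_starts]
    muscle_iv = [(s, s + burst_len) for s in muscle_starts]
    epoch_labels: list[set[str]] = []
    for ev in events:
        a, b = ev - pre, ev + post
        tags = set()
        if any(s < b and e > a for s, e in blink_iv):
            tags.add("eye")
        if any(s < b and e > a for s, e in muscle_iv):
            tags.add("muscle")
        epoch_labels.append(tags)

    # --- true unmixing on the non-flat subset ------------------------------
    # with f flat channels dropped, the last f background sources are dropped
    # too so the restricted mixing stays square and invertible
    keep = [i for i in range(config.n_channels) if i not in set(config.flat_channels)]
    keep_src = list(range(n_src - len(config.flat_channels)))
    model = ICAModel(
        unmixing=np.linalg.pinv(mixing[np.ix_(keep, keep_src)]),
        mixing=mixing[np.ix_(keep, keep_src)],
        channel_subset=[labels[i] for i in keep],
        labels=[source_labels[j] for j in keep_src],
    )

    f3 = labels.index("F3")
    w_f3 = mixing[f3, 0]
    trace = kernel * w_f3
    pos = trace[(kernel_t >= 15) & (kernel_t <= 25)].max()
    neg = trace[(kernel_t >= 25) & (kernel_t <= 35)].min()
    truth = GroundTruth(
        sources=sources,
        mixing=mixing,
        source_labels=source_labels,
        events=events,
        epoch_labels=epoch_labels,
        flat_channels=flat_labels,
        stim_template=stim_template,
        stim_topography=stim_topo,
        true_n30_uv=float(abs(pos - neg)),
        sep_kernel=kernel * w_f3,
        sep_kernel_time_ms=kernel_t,
        config=config,
    )
    return recording, truth, model


def _build_mixing(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Square channels x sources mixing with schematic topographies.

    Column 0: evoked, Gaussian fall-off around F3.  Column 1: blinks,
    front-loaded exponential (the montage is ordered front to back).
    Column 2: muscle, back/temporal-loaded.  Column 3: line, broad.
    Background columns: each background source loads mainly on its home
    channel plus small random cross-talk; jitter is re-drawn if the matrix
    is ill-conditioned.
    """
    n_ch = config.n_channels
    n_bg = n_ch - 4
    labels = config.channel_labels
    i_f3 = labels.index("F3")
    idx = np.arange(n_ch)
    w_sep = np.exp(-((idx - i_f3) / 2.5) ** 2)
    w_blink = np.exp(-idx / 3.0)
    # EMG fields are spatially broad: strongest over posterior/temporal sites
    # but with a floor everywhere (neck/jaw/frontalis all contribute)
    w_muscle = 0.15 + 0.85 * np.exp(-(n_ch - 1 - idx) / 3.0)
    bg_home = np.rint(np.linspace(0, n_bg - 1, n_ch)).astype(int)
    # line pick-up varies with per-electrode impedance; redraw until the
    # mixing is well conditioned (a near-degenerate mixing is unidentifiable
    # and amplifies any model mismatch in the unmixed components)
    for _ in range(50):
        w_line = 0.4 + 0.6 * rng.uniform(size=n_ch)
        a_bg = 0.15 * rng.standard_normal((n_ch, n_bg))
        a_bg[idx, bg_home] += 1.0
        mixing = np.column_stack([w_sep, w_blink, w_muscle, w_line, a_bg])
        if np.linalg.cond(mixing) < 150.0:
            return mixing
    raise RuntimeError("could not build a well-conditioned mixing matrix")


# ---------------------------------------------------------------------------
# The 2 x 3 x 2 condition grid
# ---------------------------------------------------------------------------

def _band_filter(
    recording: ContinuousRecording,
    filter_class: FilterClass,
    band: tuple[float, float],
    fir_order: int,
) -> ContinuousRecording:
    spec = FilterSpec(
        filter_class=filter_class,
        mode=FilterMode.BANDPASS,
        cutoffs_hz=band,
        sample_rate_hz=recording.sample_rate_hz,
        fir_order=fir_order if filter_class is FilterClass.FIR_KAISER else None,
    )
    return apply_zero_phase(design_filter(spec), recording)


def _detect_flags(
    recording: ContinuousRecording,
    filter_class: FilterClass,
    fir_order: int,
    rules: ArtifactRuleSet,
) -> list[set[str]]:
    """Artifact flags computed, as in the processing convention, on 1 Hz
    high-pass filtered data of the same filter class."""
    spec = FilterSpec(
        filter_class=filter_class,
        mode=FilterMode.HIGHPASS,
        cutoffs_hz=(1.0,),
        sample_rate_hz=recording.sample_rate_hz,
        fir_order=fir_order if filter_class is FilterClass.FIR_KAISER else None,
    )
    hp = apply_zero_phase(design_filter(spec), recording)
    epochs = detect_artifacts(extract_epochs(hp), rules)
    return [set(f) for f in epochs.artifact_flags]


def generate_condition_grid(
    config: SyntheticConfig,
    dataset_id: str = "synthetic-0",
    subject_id: str = "S01",
    fir_order_band: int = 7420,
    fir_order_detect: int = 4948,
    bands: tuple[tuple[float, float], ...] = BANDS,
    rules: ArtifactRuleSet | None = None,
    channel: str = "F3",
) -> pd.DataFrame:
    """Process one synthetic dataset through all 12 conditions.

    Grid: {FIR, IIR} x three passbands x {no ICA, ICA}, in that
    deterministic order.  Artifact flags per filter class come from 1 Hz
    high-pass data; ICA removal uses the ground-truth non-brain components.
    Returns one row per condition with the measured N30 amplitude, matching
    the input schema of :mod:`sepkit.stats`.
    """
    rules = rules or ArtifactRuleSet()
    recording, truth, model = generate_recording(config)
    # standardization before filtering: mains removal (the line component a
    # decomposition sees afterwards is whatever regression residual is left)
    recording = remove_line_noise(recording, line_hz=config.line_hz)
    rows = []
    for filter_class, filter_name in (
        (FilterClass.FIR_KAISER, "FIR"),
        (FilterClass.IIR_BUTTERWORTH, "IIR"),
    ):
        flags = _detect_flags(recording, filter_class, fir_order_detect, rules)
        for band in bands:
            band_name = f"{band[0]:g}-{band[1]:g}"
            filtered = _band_filter(recording, filter_class, band, fir_order_band)
            epochs = baseline_correct(extract_epochs(filtered))
            epochs.artifact_flags = [set(f) for f in flags[: epochs.n_epochs]]
            for use_ica in ("no", "yes"):
                cleaned = (
                    remove_components(epochs, model) if use_ica == "yes" else epochs
                )
                mean_trace, n_good = average_good_epochs(cleaned)
                measurement = measure_n30(
                    mean_trace[cleaned.channel_index(channel)],
                    cleaned.time_ms,
                    channel=channel,
                    n_epochs_averaged=n_good,
                )
                rows.append(
                    {
                        "subject_id": subject_id,
                        "dataset_id": dataset_id,
                        "filter": filter_name,
                        "band": band_name,
                        "ica": use_ica,
                        "n30_amplitude_uv": measurement.amplitude_uv,
                        "pos_latency_ms": measurement.pos_latency_ms,
                        "neg_latency_ms": measurement.neg_latency_ms,
                        "n_epochs": n_good,
                    }
                )
    return pd.DataFrame(rows)
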