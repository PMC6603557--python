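"""The five artifact rules against a literal nested-loop oracle."""

import numpy as np
import pytest

from sepkit.artifacts import (
    ArtifactRuleSet,
    apply_manual_overrides,
    count_artifacts,
    detect_artifacts,
    sliding_p2p,
    step_statistic,
)
from sepkit.epochs import EpochSet

FS = 2048.0
N_SAMP = 512
TIME_MS = (np.arange(N_SAMP) - 205) / FS * 1000.0  # −100 .. 150 ms


def make_epochs(data: np.ndarray) -> EpochSet:
    if data.ndim == 2:
        data = data[:, np.newaxis, :]
    return EpochSet(
        data=data,
        time_ms=TIME_MS,
        sample_rate_hz=FS,
        channel_labels=[f"CH{i}" for i in range(data.shape[1])],
    )


def ms_index(ms: float) -> int:
    return int(np.argmin(np.abs(TIME_MS - ms)))


# ---------------------------------------------------------------------------
# Literal brute-force oracle
# ---------------------------------------------------------------------------

def oracle_mask(rules: ArtifactRuleSet) -> np.ndarray:
    lo, hi = rules.exclusion_ms
    return ~((TIME_MS >= lo) & (TIME_MS <= hi))


def oracle_windows(n, window, step):
    starts = []
    s = 0
    while s + window <= n:
        starts.append(s)
        s += step
    if n - window >= 0 and (n - window) not in starts:
        starts.append(n - window)
    return starts


def oracle_p2p(trace, mask, rules):
    window = int(round(rules.p2p_window_ms / 1000 * FS))
    step = int(round(rules.p2p_step_ms / 1000 * FS))
    best = 0.0
    for s in oracle_windows(len(trace), window, step):
        vals = [trace[i] for i in range(s, s + window) if mask[i]]
        if len(vals) >= 2:
            best = max(best, max(vals) - min(vals))
    return best


def oracle_step(trace, mask, rules):
    window = int(round(rules.step_window_ms / 1000 * FS))
    step = int(round(rules.step_step_ms / 1000 * FS))
    half = window // 2
    best = 0.0
    for s in oracle_windows(len(trace), window, step):
        first = [trace[i] for i in range(s, s + half) if mask[i]]
        second = [trace[i] for i in range(s + half, s + window) if mask[i]]
        if first and second:
            best = max(best, abs(np.mean(second) - np.mean(first)))
    return best


def oracle_flags(trace, rules):
    mask = oracle_mask(rules)
    flags = set()
    if max(abs(trace[i]) for i in range(len(trace)) if mask[i]) > rules.abs_thresh_uv:
        flags.add("abs")
    if oracle_p2p(trace, mask, rules) > rules.p2p_thresh_uv:
        flags.add("p2p")
    if oracle_step(trace, mask, rules) > rules.step_thresh_uv:
        flags.add("step")
    for i in range(len(trace) - 1):
        if mask[i] and mask[i + 1] and abs(trace[i + 1] - trace[i]) > rules.s2s_thresh_uv:
            flags.add("diff")
    run = best_run = 0
    for i in range(len(trace)):
        run = run + 1 if (mask[i] and abs(trace[i]) < rules.flat_thresh_uv) else 0
        best_run = max(best_run, run)
    if best_run / FS * 1000.0 > rules.flat_min_dur_ms:
        flags.add("flat")
    return flags


# ---------------------------------------------------------------------------
# Constructed epochs
# ---------------------------------------------------------------------------

class TestConstructedEpochs:
    def test_all_zero_epoch_flat_only(self):
        epochs = detect_artifacts(make_epochs(np.zeros((1, N_SAMP))))
        assert epochs.artifact_flags[0] == {"flat"}

    def test_spike_outside_exclusion(self):
        trace = np.zeros((1, N_SAMP))
        trace[0, ms_index(50.0)] = 101.0
        epochs = detect_artifacts(make_epochs(trace))
        # |v|>100 and the 101 jump; quiet runs are all shorter than 125 ms
        # because the spike and the stimulus gap both break them
        assert epochs.artifact_flags[0] == {"abs", "diff"}
        assert epochs.artifact_flags[0] == oracle_flags(trace[0], ArtifactRuleSet())

    def test_spike_inside_exclusion_is_silent(self):
        trace = np.zeros((1, N_SAMP))
        trace[0, ms_index(1.0)] = 101.0
        epochs = detect_artifacts(make_epochs(trace))
        for rule in ("abs", "p2p", "step", "diff"):
            assert rule not in epochs.artifact_flags[0]

    def test_square_wave_step_and_diff(self):
        # switch placed on a half-window boundary of the 50 ms step grid so
        # one window's halves straddle it exactly: statistic = full swing
        switch = 307  # start 102 + half-window 205
        trace = np.where(np.arange(N_SAMP) < switch, -60.0, 60.0)[np.newaxis, :]
        epochs = detect_artifacts(make_epochs(trace.copy()))
        assert epochs.artifact_flags[0] == {"step", "diff"}
        assert epochs.artifact_flags[0] == oracle_flags(trace[0], ArtifactRuleSet())

    def test_unaligned_square_wave_matches_oracle(self):
        # switching at 25 ms falls between grid half-windows: the best
        # window mixes the two levels and the statistic stays below 120
        trace = np.where(TIME_MS < 25.0, -60.0, 60.0)[np.newaxis, :]
        epochs = detect_artifacts(make_epochs(trace.copy()))
        assert epochs.artifact_flags[0] == oracle_flags(trace[0], ArtifactRuleSet())


class TestSlidingStatistics:
    def test_p2p_sawtooth(self):
        trace = np.linspace(-80, 80, N_SAMP)
        mask = np.ones(N_SAMP, bool)
        assert sliding_p2p(trace, 200.0, 100.0, mask, FS) == pytest.approx(
            oracle_p2p(trace, mask, ArtifactRuleSet()), abs=1e-12
        )

    def test_p2p_constant_zero(self):
        assert sliding_p2p(np.full(N_SAMP, 3.0), 200.0, 100.0, np.ones(N_SAMP, bool), FS) == 0.0

    def test_p2p_random_matches_oracle(self, rng):
        rules = ArtifactRuleSet()
        mask = oracle_mask(rules)
        for _ in range(20):
            trace = rng.standard_normal(N_SAMP) * 40
            got = sliding_p2p(trace, 200.0, 100.0, mask, FS)
            assert got == pytest.approx(oracle_p2p(trace, mask, rules), abs=1e-12)

    def test_step_ramp_closed_form(self):
        window = int(round(0.200 * FS))
        rise = 80.0
        trace = np.zeros(N_SAMP)
        trace[:window] = np.linspace(0, rise, window)
        trace[window:] = rise
        mask = np.ones(N_SAMP, bool)
        got = step_statistic(trace, 200.0, 50.0, mask, FS)
        assert got == pytest.approx(rise / 2, rel=0.01)

    def test_step_constant_zero(self):
        assert step_statistic(np.full(N_SAMP, 9.0), 200.0, 50.0, np.ones(N_SAMP, bool), FS) == 0.0

    def test_step_late_shelf_matches_oracle(self):
        # a 0→120 μV shelf at 125 ms: no window on the 50 ms grid splits at
        # the edge, so the maximum is set by the best partial alignment
        trace = np.where(TIME_MS < 25.0, 0.0, 120.0)
        mask = np.ones(N_SAMP, bool)
        got = step_statistic(trace, 200.0, 50.0, mask, FS)
        assert got == pytest.approx(oracle_step(trace, mask, ArtifactRuleSet()), abs=1e-12)

    def test_fully_masked_rejected(self):
        with pytest.raises(ValueError):
            sliding_p2p(np.zeros(N_SAMP), 200.0, 100.0, np.zeros(N_SAMP, bool), FS)


class TestOracleEquivalence:
    def test_200_random_epochs_exact_match(self):
        rng = np.random.default_rng(99)
        rules = ArtifactRuleSet()
        scales = rng.choice([1.0, 20.0, 60.0], size=200)
        data = rng.standard_normal((200, 1, N_SAMP)) * scales[:, None, None]
        # sprinkle structured artifacts: steps, spikes, flat stretches
        for e in range(0, 200, 7):
            data[e, 0, 250:] += rng.choice([-1, 1]) * rng.uniform(40, 300)
        for e in range(3, 200, 11):
            data[e, 0, rng.integers(0, N_SAMP)] += rng.uniform(60, 400)
        for e in range(5, 200, 13):
            data[e, 0, 230:] = rng.uniform(0, 1.5)
        epochs = detect_artifacts(make_epochs(data.copy()))
        for e in range(200):
            assert epochs.artifact_flags[e] == oracle_flags(data[e, 0], rules), f"epoch {e}"

    def test_exclusion_window_soundness(self, rng):
        """Arbitrary contamination confined to [−2, 2] ms never triggers
        abs/p2p/step/diff on an otherwise quiet-noise epoch."""
        sel = (TIME_MS >= -2.0) & (TIME_MS <= 2.0)
        for _ in range(30):
            data = rng.standard_normal((1, 1, N_SAMP)) * 3.0
            data[0, 0, sel] = rng.uniform(-1e4, 1e4, size=sel.sum())
            epochs = detect_artifacts(make_epochs(data))
            assert not epochs.artifact_flags[0] - {"flat"}

    def test_threshold_monotonicity(self, rng):
        data = rng.standard_normal((80, 2, N_SAMP)) * 45
        strict = detect_artifacts(make_epochs(data.copy()))
        relaxed = detect_artifacts(
            make_epochs(data.copy()),
            ArtifactRuleSet(
                abs_thresh_uv=200, p2p_thresh_uv=300, step_thresh_uv=200,
                s2s_thresh_uv=100, flat_thresh_uv=1.0,
            ),
        )
        assert count_artifacts(relaxed) <= count_artifacts(strict)

    def test_synthetic_recovery_sensitivity_specificity(self):
        rng = np.random.default_rng(4)
        n = 200
        data = rng.standard_normal((n, 1, N_SAMP)) * 5.0  # clean background
        bad = rng.choice(n, size=30, replace=False)
        for e in bad:
            data[e, 0, 300:] += 250.0  # >2x every relevant threshold
        epochs = detect_artifacts(make_epochs(data))
        flagged = {e for e in range(n) if epochs.artifact_flags[e]}
        assert set(bad) <= flagged  # sensitivity 1.0
        clean = set(range(n)) - set(bad)
        specificity = len(clean - flagged) / len(clean)
        assert specificity >= 0.99


class TestOverridesAndCounting:
    def _flagged_epochs(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((3, 1, N_SAMP)) * 3.0
        # step-like frontal eye-blink morphology: ±55 μV swing aligned with a
        # half-window boundary fires step (110 > 100) but not abs (55 < 100)
        data[0, 0, :307] -= 55.0
        data[0, 0, 307:] += 55.0
        return detect_artifacts(make_epochs(data))

    def test_unmark_keeps_provenance(self):
        epochs = self._flagged_epochs()
        assert "step" in epochs.artifact_flags[0]
        out = apply_manual_overrides(epochs, [(0, "unmark", "frontal eye-blink")])
        assert out.artifact_flags[0] == set()
        assert "step" in out.auto_flags[0]
        assert out.manual_overrides == [(0, "unmark", "frontal eye-blink")]

    def test_mark_previously_good(self):
        epochs = self._flagged_epochs()
        out = apply_manual_overrides(epochs, [(1, "mark", "visual inspection")])
        assert out.artifact_flags[1] == {"manual"}

    def test_empty_override_list_identity(self):
        epochs = self._flagged_epochs()
        out = apply_manual_overrides(epochs, [])
        assert out.artifact_flags == epochs.artifact_flags

    def test_unknown_epoch_rejected(self):
        with pytest.raises(IndexError):
            apply_manual_overrides(self._flagged_epochs(), [(99, "mark", "x")])

    def test_count_matches_enumeration(self, rng):
        data = rng.standard_normal((50, 1, N_SAMP)) * 40
        epochs = detect_artifacts(make_epochs(data))
        assert count_artifacts(epochs) == sum(1 for f in epochs.artifact_flags if f)
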