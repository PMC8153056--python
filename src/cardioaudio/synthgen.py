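"""Synthetic cardio-audio study generator.

Emulates the recordings the analysis pipeline expects: a QRS-bearing
two-lead ECG with stochastic interbeat intervals; multichannel EEG built
from 1/f background noise, a per-channel cardiac field artifact (a scaled
copy of the cardiac template at every heartbeat), a heartbeat-locked
evoked component, tone-evoked deflections, a condition-dependent
omission-locked component, and optional blink/bad-channel artifacts; tone
trains of 7-10 tones triggered by successive heartbeats at the short
(R + 287 ms) or long (R + 587 ms) cardio-audio delay with 30-ms Gaussian
jitter and the third-from-last tone omitted in half of the trials; and
yes/no + confidence behavior from a Gaussian signal-detection model with
adjustable sensitivity and metacognitive noise.

Everything is a pure function of (config, seed): identical configurations
give byte-identical on-disk output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cardiac_events import (DELAY_MEANS, JITTER_SD, TrialSpec,
                             build_session_sequence, schedule_trial)
from .containers import EVENT_COLUMNS, ContinuousRecording, SensorLayout

_GOLDEN = np.pi * (3.0 - np.sqrt(5.0))
#: disc radius of the generated layouts; at 128 channels this reproduces
#: the reference montage's neighborhood statistics (median degree 11 at
#: the 0.15 adjacency distance).
_LAYOUT_RADIUS = 0.46


def make_layout(n_channels: int = 128, radius: float = _LAYOUT_RADIUS) -> SensorLayout:
    """Quasi-uniform sunflower-spiral layout on a disc (unit-disc units)."""
    k = np.arange(n_channels)
    r = radius * np.sqrt((k + 0.5) / n_channels)
    th = k * _GOLDEN
    pos = np.column_stack([r * np.cos(th), r * np.sin(th)])
    return SensorLayout([f"E{i + 1}" for i in range(n_channels)], pos)


MASTOID_POS = {"M1": (-0.48, -0.25), "M2": (0.48, -0.25)}


@dataclass
class BehaviorParams:
    """Gaussian SDT generator for the two tasks.

    Defaults reproduce the group-mean sensitivities of the paradigm this
    package models: weak heartbeat discrimination (internal d' ~ 0.22) and
    easy omission detection (external d' ~ 3.1).
    """

    d_internal: float = 0.218
    d_external: float = 3.091
    criterion_internal: float = 0.0
    criterion_external: float = 0.0
    meta_noise_sd: float = 0.3
    confidence_thresholds: tuple[float, ...] = (0.5, 1.0, 1.5)

    def __post_init__(self) -> None:
        th = np.asarray(self.confidence_thresholds, dtype=float)
        if np.any(np.diff(th) <= 0):
            raise ValueError("confidence thresholds must be strictly increasing")
        if self.meta_noise_sd < 0:
            raise ValueError("metacognitive noise SD must be >= 0")


@dataclass
class SimulationConfig:
    """Study-level generator parameters; defaults mirror the paradigm."""

    n_subjects: int = 34
    fs: float = 512.0
    n_blocks: int = 4
    trials_per_block: int = 56
    tones_per_trial: tuple[int, int] = (7, 10)
    delay_mean_s: dict = field(default_factory=lambda: dict(DELAY_MEANS))
    delay_jitter_sd_s: float = JITTER_SD
    iti_range_s: tuple[float, float] = (2.0, 3.0)
    ibi_mean_s: float = 0.8
    ibi_sd_s: float = 0.05
    n_channels: int = 128
    cfa_gain: Optional[np.ndarray] = None       # µV per mV of ECG, per channel
    cfa_amplitude_uv: float = 8.0
    hep_amplitude_uv: float = 1.0
    hep_latency_s: float = 0.30
    hep_width_s: float = 0.05
    tone_amplitude_uv: float = 4.0
    omission_effect_uv: dict = field(
        default_factory=lambda: {("internal", "short"): 4.0})
    omission_window_s: tuple[float, float] = (0.095, 0.138)
    noise_exponent: float = 1.0
    noise_sd_uv: float = 5.0
    white_sd_uv: float = 1.0
    blink_rate_hz: float = 0.10
    blink_amplitude_uv: float = 60.0
    bad_channels: list = field(default_factory=list)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    rest_duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if any(v <= 0 for v in self.delay_mean_s.values()):
            raise ValueError("delay means must be positive")
        if self.delay_jitter_sd_s < 0:
            raise ValueError("delay jitter SD must be >= 0")
        if self.tones_per_trial[0] < 5:
            raise ValueError("tone trains need at least 5 tones")
        if not (0.4 < self.ibi_mean_s < 1.5):
            raise ValueError("mean IBI must lie in (0.4, 1.5) s")
        if self.ibi_sd_s < 0:
            raise ValueError("IBI SD must be >= 0")

    def layout(self) -> SensorLayout:
        return make_layout(self.n_channels)


# ---------------------------------------------------------------------------
# ECG

def _gauss(t: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sd) ** 2)


def qrs_template(fs: float) -> tuple[np.ndarray, int]:
    """P-QRS-T template (mV) sampled at fs; returns (waveform, R index)."""
    t = np.arange(int(-0.25 * fs), int(0.45 * fs)) / fs
    w = (0.15 * _gauss(t, -0.16, 0.025)
         - 0.15 * _gauss(t, -0.018, 0.008)
         + 1.00 * _gauss(t, 0.0, 0.010)
         - 0.25 * _gauss(t, 0.020, 0.009)
         + 0.35 * _gauss(t, 0.28, 0.060))
    return w, int(0.25 * fs)


def draw_ibis(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Gaussian IBIs truncated at +/-3 SD (always positive for valid configs)."""
    if mean <= 0 or sd < 0:
        raise ValueError("IBI parameters must be positive")
    ibis = mean + np.clip(rng.normal(0.0, sd, size=n), -3 * sd, 3 * sd)
    return np.maximum(ibis, 0.05)


def simulate_ecg(
    config: SimulationConfig,
    subject_seed: int,
    duration_s: float,
) -> tuple[ContinuousRecording, np.ndarray]:
    """Two-lead ECG of the given duration; returns ground-truth R-peaks."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(subject_seed)
    fs = config.fs
    n_samp = int(round(duration_s * fs))

    n_beats_max = int(duration_s / max(config.ibi_mean_s - 3 * config.ibi_sd_s, 0.05)) + 3
    ibis = draw_ibis(rng, n_beats_max, config.ibi_mean_s, config.ibi_sd_s)
    times = 0.5 + np.concatenate([[0.0], np.cumsum(ibis)])
    times = times[times < duration_s - 0.5]
    rpeaks = np.round(times * fs).astype(int)

    tmpl, r_idx = qrs_template(fs)
    clean = np.zeros(n_samp)
    for p in rpeaks:
        a, b = p - r_idx, p - r_idx + tmpl.size
        ta, tb = max(0, -a), tmpl.size - max(0, b - n_samp)
        clean[max(0, a):min(n_samp, b)] += tmpl[ta:tb]
    lead1 = clean + 0.02 * rng.standard_normal(n_samp)
    lead2 = -0.6 * clean + 0.02 * rng.standard_normal(n_samp)
    rec = ContinuousRecording(np.vstack([lead1, lead2]), fs,
                              ["ECG1", "ECG2"], ["ecg", "ecg"])
    return rec, rpeaks


# ---------------------------------------------------------------------------
# EEG

def pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
               fs: float, exponent: float, sd: float) -> np.ndarray:
    """1/f^exponent Gaussian noise, scaled to the requested per-channel SD."""
    if sd == 0:
        return np.zeros((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * shaping
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return sd * x


def default_cfa_profile(layout: SensorLayout, amplitude_uv: float) -> np.ndarray:
    """Left-inferior-dominant cardiac-field gain map (µV per mV of ECG)."""
    x, y = layout.pos[:, 0], layout.pos[:, 1]
    w = np.exp(-(((x + 0.25) ** 2 + (y + 0.30) ** 2) / (2 * 0.35 ** 2)))
    return amplitude_uv * (0.3 + 0.7 * w / w.max()) * np.sign(-x + 0.01)


def scalp_topography(layout: SensorLayout, center: tuple[float, float],
                     width: float = 0.25) -> np.ndarray:
    """Smooth unit-peak spatial weighting centered on a layout location."""
    d2 = ((layout.pos - np.asarray(center)) ** 2).sum(axis=1)
    w = np.exp(-d2 / (2 * width ** 2))
    return w / w.max()


def _add_component(data: np.ndarray, topo: np.ndarray, wave: np.ndarray,
                   onsets: np.ndarray) -> None:
    n_samp = data.shape[1]
    for on in onsets:
        a, b = on, on + wave.size
        if a >= n_samp or b <= 0:
            continue
        wa, wb = max(0, -a), wave.size - max(0, b - n_samp)
        data[:, max(0, a):min(n_samp, b)] += topo[:, None] * wave[wa:wb]


def simulate_eeg(
    config: SimulationConfig,
    rpeaks: np.ndarray,
    events: pd.DataFrame,
    seed: int,
    ecg_clean: Optional[np.ndarray] = None,
    n_samples: Optional[int] = None,
    layout: Optional[SensorLayout] = None,
) -> ContinuousRecording:
    """Scalp EEG (µV) implied by the cardiac and stimulus event streams.

    ``ecg_clean`` is the noise-free cardiac trace in mV used for the
    cardiac field artifact; if omitted it is rebuilt from the template at
    the given R-peaks.
    """
    rng = np.random.default_rng(seed)
    fs = config.fs
    layout = layout or config.layout()
    if n_samples is None:
        n_samples = int(events["sample"].max() + 2 * fs) if len(events) else \
            int(rpeaks.max() + 2 * fs)
    rpeaks = np.asarray(rpeaks, dtype=int)
    if len(events) and events["sample"].max() >= n_samples:
        raise ValueError("events extend past the requested record length")

    n_ch = layout.n_channels
    data = pink_noise(rng, n_ch, n_samples, fs, config.noise_exponent,
                      config.noise_sd_uv)
    if config.white_sd_uv:
        data += config.white_sd_uv * rng.standard_normal((n_ch, n_samples))

    # cardiac field artifact: scaled cardiac waveform on every channel
    gains = config.cfa_gain if config.cfa_gain is not None else \
        default_cfa_profile(layout, config.cfa_amplitude_uv)
    gains = np.asarray(gains, dtype=float)
    if gains.shape != (n_ch,):
        raise ValueError("cfa_gain length does not match the layout")
    if np.any(gains != 0):
        if ecg_clean is None:
            tmpl, r_idx = qrs_template(fs)
            ecg_clean = np.zeros(n_samples)
            for p in rpeaks:
                a, b = p - r_idx, p - r_idx + tmpl.size
                ta, tb = max(0, -a), tmpl.size - max(0, b - n_samples)
                ecg_clean[max(0, a):min(n_samples, b)] += tmpl[ta:tb]
        data += gains[:, None] * ecg_clean[None, :n_samples]

    # heartbeat-locked evoked component
    if config.hep_amplitude_uv:
        t = np.arange(0, int(0.6 * fs)) / fs
        wave = config.hep_amplitude_uv * _gauss(t, config.hep_latency_s,
                                                config.hep_width_s)
        topo = scalp_topography(layout, (0.0, 0.15))
        _add_component(data, topo, wave, rpeaks)

    # tone-evoked deflection (N1-P2-like)
    tones = events.loc[events["kind"] == "tone", "sample"].to_numpy(int) \
        if len(events) else np.array([], dtype=int)
    if config.tone_amplitude_uv and tones.size:
        t = np.arange(0, int(0.35 * fs)) / fs
        wave = config.tone_amplitude_uv * (-_gauss(t, 0.10, 0.03)
                                           + 0.6 * _gauss(t, 0.20, 0.04))
        topo = scalp_topography(layout, (0.0, 0.05))
        _add_component(data, topo, wave, tones)

    # omission-locked component, condition dependent
    if len(events):
        omissions = events[events["kind"] == "omission"]
        w0, w1 = config.omission_window_s
        t = np.arange(0, int((w1 + 0.06) * fs)) / fs
        shape = _gauss(t, (w0 + w1) / 2, (w1 - w0) / 4)
        topo = scalp_topography(layout, (0.0, 0.05))
        for (att, dly), grp in omissions.groupby(["attention", "delay"]):
            amp = config.omission_effect_uv.get((att, dly), 0.0)
            if amp:
                _add_component(data, topo, amp * shape,
                               grp["sample"].to_numpy(int))

    # blinks: frontal biphasic low-frequency transients at Poisson times
    if config.blink_rate_hz > 0:
        n_blinks = rng.poisson(config.blink_rate_hz * n_samples / fs)
        onsets = np.sort(rng.integers(0, max(1, n_samples - int(0.5 * fs)),
                                      size=n_blinks))
        t = np.arange(0, int(0.5 * fs)) / fs
        wave = config.blink_amplitude_uv * (_gauss(t, 0.12, 0.05)
                                            - 0.35 * _gauss(t, 0.28, 0.09))
        fr = np.maximum(layout.pos[:, 1] - 0.05, 0.0)
        topo = fr / max(fr.max(), 1e-12)
        _add_component(data, topo, wave, onsets)

    # bad channels: swamp with broadband noise and drift
    for name in config.bad_channels:
        i = layout.ch_names.index(name)
        data[i] += 10 * config.noise_sd_uv * rng.standard_normal(n_samples)
        data[i] += pink_noise(rng, 1, n_samples, fs, 2.0,
                              5 * config.noise_sd_uv)[0]

    return ContinuousRecording(data, fs, list(layout.ch_names),
                               ["eeg"] * n_ch)


# ---------------------------------------------------------------------------
# behavior

def simulate_behavior(
    config: SimulationConfig,
    trial_specs: list[TrialSpec],
    seed: int,
) -> pd.DataFrame:
    """Yes/no + confidence responses from the Gaussian SDT model.

    Internal trials judge cardio-audio synchronicity (signal = short
    delay); external trials judge omission presence (signal = omission
    trial).  Confidence comes from the distance of metacognitively
    noisy evidence to the criterion, cut at the configured thresholds.
    """
    bp = config.behavior
    rng = np.random.default_rng(seed)
    th = np.asarray(bp.confidence_thresholds, dtype=float)
    rows = []
    for i, spec in enumerate(trial_specs):
        if spec.attention == "internal":
            signal = spec.delay == "short"
            d, c = bp.d_internal, bp.criterion_internal
        else:
            signal = spec.omission
            d, c = bp.d_external, bp.criterion_external
        x = rng.normal(d / 2 if signal else -d / 2, 1.0)
        yes = x > c
        x2 = x + (rng.normal(0.0, bp.meta_noise_sd) if bp.meta_noise_sd else 0.0)
        conf = 1 + int(np.sum(np.abs(x2 - c) > th))
        rows.append({
            "trial": i, "block": spec.block,
            "attention": spec.attention, "delay": spec.delay,
            "omission_trial": int(spec.omission),
            "response": "yes" if yes else "no", "confidence": conf,
            "evidence": x, "conf_evidence": x2,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-subject assembly

@dataclass
class SubjectData:
    """In-memory bundle for one synthetic subject."""

    recording: ContinuousRecording      # EEG + mastoids + ECG stacked
    events: pd.DataFrame
    behavior: pd.DataFrame
    ground_truth: dict
    layout: SensorLayout                # EEG + mastoid positions


def _subject_rngs(config: SimulationConfig, subject: int) -> list[int]:
    ss = np.random.SeedSequence([config.seed, subject])
    return [int(s) for s in ss.generate_state(4) >> 1]   # keep below 2^31


def simulate_subject(config: SimulationConfig, subject: int) -> SubjectData:
    """One subject's session: ECG, EEG, events, behavior, ground truth."""
    seed_ecg, seed_seq, seed_sched, seed_beh = _subject_rngs(config, subject)
    fs = config.fs
    specs = build_session_sequence(seed_seq, config.n_blocks,
                                   config.trials_per_block,
                                   config.tones_per_trial)
    max_tones = config.tones_per_trial[1]
    est = (config.rest_duration_s
           + len(specs) * (1.0 + (max_tones + 1) * (config.ibi_mean_s
                                                    + 3 * config.ibi_sd_s)
                           + config.iti_range_s[1] + 1.5) + 30.0)
    ecg, rpeaks = simulate_ecg(config, seed_ecg, est)
    rpeak_times = rpeaks / fs

    rng = np.random.default_rng(seed_sched)
    rows = []
    cursor = config.rest_duration_s
    for i, spec in enumerate(specs):
        cue_t = cursor
        rows.append({"sample": int(round(cue_t * fs)), "onset_s": cue_t,
                     "kind": "cue", "trial": i, "block": spec.block,
                     "attention": spec.attention, "delay": spec.delay,
                     "omission_trial": int(spec.omission)})
        first = int(np.searchsorted(rpeak_times, cue_t + 0.3))
        if first + spec.n_tones > len(rpeaks):
            raise RuntimeError("ran out of simulated heartbeats")
        trig = rpeaks[first:first + spec.n_tones]
        ev = schedule_trial(trig, spec, fs, rng, config.delay_mean_s,
                            config.delay_jitter_sd_s)
        ev["trial"] = i
        ev["block"] = spec.block
        rows.extend(ev.to_dict("records"))
        last_tone = ev["onset_s"].max()
        resp_t = last_tone + 1.5
        rows.append({"sample": int(round(resp_t * fs)), "onset_s": resp_t,
                     "kind": "response", "trial": i, "block": spec.block,
                     "attention": spec.attention, "delay": spec.delay,
                     "omission_trial": int(spec.omission)})
        cursor = resp_t + rng.uniform(*config.iti_range_s)

    n_samples = int(round((cursor + 2.0) * fs))
    n_samples = min(n_samples, ecg.n_samples)
    rpeaks = rpeaks[rpeaks < n_samples - 1]
    for p in rpeaks:
        rows.append({"sample": int(p), "onset_s": p / fs, "kind": "rpeak",
                     "trial": -1, "block": -1, "attention": "",
                     "delay": "", "omission_trial": 0})
    events = pd.DataFrame(rows)[EVENT_COLUMNS].sort_values(
        ["sample", "kind"], kind="stable").reset_index(drop=True)
    eeg_layout = config.layout()
    tmpl_train = None  # rebuilt inside simulate_eeg from rpeaks
    eeg = simulate_eeg(config, rpeaks, events, seed_ecg + 1,
                       ecg_clean=None, n_samples=n_samples, layout=eeg_layout)

    # mastoids: weak far-field cardiac artifact plus noise
    rng_m = np.random.default_rng(seed_ecg + 2)
    mast = pink_noise(rng_m, 2, n_samples, fs, config.noise_exponent,
                      config.noise_sd_uv * 0.8)
    full_names = eeg.ch_names + list(MASTOID_POS) + ecg.ch_names
    full_kinds = ["eeg"] * eeg.n_channels + ["mastoid", "mastoid", "ecg", "ecg"]
    data = np.vstack([eeg.data, mast, ecg.data[:, :n_samples]])
    recording = ContinuousRecording(data, fs, full_names, full_kinds)

    behavior = simulate_behavior(config, specs, seed_beh)
    layout_full = SensorLayout(
        eeg_layout.ch_names + list(MASTOID_POS),
        np.vstack([eeg_layout.pos, np.array(list(MASTOID_POS.values()))]))

    gt = {
        "subject": subject,
        "seed": config.seed,
        "rpeak_samples": [int(p) for p in rpeaks if p < n_samples],
        "bad_channels": list(config.bad_channels),
        "omission_effect_uv": {f"{a}/{d}": v for (a, d), v
                               in config.omission_effect_uv.items()},
        "omission_window_s": list(config.omission_window_s),
        "evidence": behavior["evidence"].round(6).tolist(),
    }
    return SubjectData(recording, events, behavior.drop(
        columns=["evidence", "conf_evidence"]), gt, layout_full)


def simulate_dataset(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Write a synthetic study to disk.

    Layout: ``layout.tsv`` at the study root; per subject ``sub-NN/`` with
    ``recording.edf`` (EEG in µV, ECG in mV), ``events.tsv``,
    ``behavior.tsv`` and a ``ground_truth.json`` sidecar.
    """
    from .io import write_edf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for subject in range(config.n_subjects):
        sub = simulate_subject(config, subject)
        sdir = out / f"sub-{subject:02d}"
        sdir.mkdir(exist_ok=True)
        write_edf(sub.recording, sdir / "recording.edf")
        sub.events.to_csv(sdir / "events.tsv", sep="\t", index=False)
        sub.behavior.to_csv(sdir / "behavior.tsv", sep="\t", index=False)
        with open(sdir / "ground_truth.json", "w") as fh:
            json.dump(sub.ground_truth, fh, indent=1, sort_keys=True)
        if subject == 0:
            sub.layout.to_frame().to_csv(out / "layout.tsv", sep="\t",
                                         index=False)
    return out
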