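"""Shared test utilities: independent oracles and simulation helpers."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from cardioaudio.containers import ContinuousRecording, SensorLayout
from cardioaudio.hep_preprocess import cfa_correct, make_epochs, robust_average
from cardioaudio.cluster_stats import build_adjacency, interaction_contrast
from cardioaudio.synthgen import SimulationConfig, make_layout, simulate_subject


def fbm_davies_harte(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Fractional Brownian motion by circulant embedding of the fGn
    autocovariance (Davies-Harte); an oracle independent of the estimator."""
    def gamma(k):
        k = np.abs(k).astype(float)
        return 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
                      + np.abs(k - 1) ** (2 * hurst))
    g = gamma(np.arange(n))
    row = np.concatenate([g, g[-2:0:-1]])
    lam = np.fft.rfft(row).real
    if np.any(lam < -1e-8):
        raise ValueError("embedding not nonneg definite at this n/H")
    lam = np.maximum(lam, 0.0)
    m = row.size
    w = rng.standard_normal(lam.size) + 1j * rng.standard_normal(lam.size)
    spec = np.sqrt(lam * m) * w
    fgn = np.fft.irfft(spec, n=m)[:n] / np.sqrt(2)
    return np.cumsum(fgn)


def ring_layout(n: int = 8, radius: float = 0.3) -> SensorLayout:
    ang = 2 * np.pi * np.arange(n) / n
    return SensorLayout([f"C{i}" for i in range(n)],
                        radius * np.column_stack([np.cos(ang), np.sin(ang)]))


def smooth_null_field(rng: np.random.Generator, layout: SensorLayout,
                      n_subj: int, n_t: int,
                      spatial_scale: float = 1.0,
                      temporal_sigma: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Exchangeable spatio-temporally correlated null data for two paired
    conditions (EEG-like smoothness so the cluster machinery is exercised)."""
    d = np.linalg.norm(layout.pos[:, None] - layout.pos[None, :], axis=2)
    L = np.linalg.cholesky(np.exp(-d / spatial_scale))
    x = rng.standard_normal((2, n_subj, layout.n_channels, n_t))
    x = gaussian_filter1d(x, temporal_sigma, axis=-1)
    x = np.einsum("ij,csjt->csit", L, x)
    return x[0], x[1]


def scaled_power_config(seed: int) -> SimulationConfig:
    """Desk-scale study conditions used for the end-to-end power check:
    generator defaults (effect amplitude, noise, delays) untouched, with a
    16-channel montage, 4 blocks of 24 trials, 5-6 tones per trial, no
    blink artifacts, and a 60-s rest period for the CFA template."""
    return SimulationConfig(
        n_subjects=10, n_channels=16, n_blocks=4, trials_per_block=24,
        tones_per_trial=(5, 6), blink_rate_hz=0.0, rest_duration_s=60.0,
        seed=seed)


def run_power_study(seed: int, n_perm: int = 500, adjacency_dist: float = 0.25):
    """One scaled-down synthetic study through the omission analysis chain:
    simulate -> omission-locked epochs -> resting-template CFA correction ->
    robust averages -> double-subtraction interaction + simple effects."""
    cfg = scaled_power_config(seed)
    lay = make_layout(cfg.n_channels)
    cells = []
    for s in range(cfg.n_subjects):
        sub = simulate_subject(cfg, s)
        eeg_idx = [i for i, k in enumerate(sub.recording.ch_kinds) if k == "eeg"]
        rec = ContinuousRecording(
            sub.recording.data[eeg_idx], cfg.fs,
            [sub.recording.ch_names[i] for i in eeg_idx],
            ["eeg"] * len(eeg_idx))
        ev = sub.events
        first_cue = ev.loc[ev["kind"] == "cue", "onset_s"].min()
        rest_r = ev[(ev["kind"] == "rpeak") & (ev["onset_s"] < first_cue - 1.0)]
        ep_rest = make_epochs(rec, ev, "rpeak", -0.3, 0.45, lock_events=rest_r)
        resting = robust_average(ep_rest, "rest", lowpass_hz=None)
        ep = make_epochs(rec, ev, "omission", -0.3, 0.45)
        ep = cfa_correct(ep, resting)
        mat = []
        for att in ("internal", "external"):
            row = []
            for dly in ("short", "long"):
                m = ((ep.metadata["attention"] == att)
                     & (ep.metadata["delay"] == dly)).to_numpy()
                evk = robust_average(ep.select(m))
                w = (evk.times >= 0) & (evk.times < 0.213)
                row.append(evk.data[:, w])
            mat.append(row)
        cells.append(mat)
    adj = build_adjacency(lay, adjacency_dist)
    return interaction_contrast(np.asarray(cells), adj, n_perm=n_perm,
                                seed=seed, run_simple_effects=True)
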