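"""Cardiac event handling: R-peak detection, tone scheduling, QC, IBIs.

The paradigm triggers a tone off each detected heartbeat: an online
detector emulates the real-time variance-threshold trigger, tones follow
the trigger at a condition-specific delay (short 287 ms / long 587 ms,
Gaussian jitter SD 30 ms truncated at +/-3 SD), and in omission trials the
third-from-last tone is withheld.  Offline detection, per-block R-R
quality control and interbeat-interval extraction support the downstream
evoked and cardiac-dynamics analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from ._filters import bandpass

#: Condition-specific mean cardio-audio delays (s).
DELAY_MEANS = {"short": 0.287, "long": 0.587}
#: Trigger-to-sound jitter SD (s), truncated at +/-3 SD.
JITTER_SD = 0.030
#: Online-detector variance window (s).
ONLINE_WINDOW = 0.033
#: Online-detector refractory period (s); below the 0.4-s minimum plausible IBI.
REFRACTORY = 0.250
#: Per-block R-R interval QC bounds (s).
RR_BOUNDS = (0.4, 1.5)


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the session: condition cell plus tone-train shape."""

    attention: str            # "internal" | "external"
    delay: str                # "short" | "long"
    n_tones: int
    omission: bool
    block: int

    def __post_init__(self) -> None:
        if self.attention not in ("internal", "external"):
            raise ValueError(f"unknown attention condition {self.attention!r}")
        if self.delay not in ("short", "long"):
            raise ValueError(f"unknown delay condition {self.delay!r}")
        if self.n_tones < 5:
            raise ValueError("trials need at least 5 tones")

    @property
    def omission_position(self) -> int:
        """1-based position of the (possibly omitted) third-from-last tone."""
        return self.n_tones - 2


def _rolling_variance(x: np.ndarray, w: int) -> np.ndarray:
    """Population variance of the preceding ``w`` samples (inclusive).

    The first ``w - 1`` samples, where no full window exists, get variance 0.
    """
    x = np.asarray(x, dtype=float)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    v = np.zeros_like(x)
    v[w - 1:] = np.maximum(s2 / w - (s1 / w) ** 2, 0.0)
    return v


def _window_samples(fs: float) -> int:
    """Online variance window in samples, rounded to the nearest odd count."""
    w = int(round(ONLINE_WINDOW * fs))
    if w % 2 == 0:
        w += 1
    if w < 2:
        raise ValueError(f"sampling rate {fs} Hz too low for a {ONLINE_WINDOW*1e3:.0f}-ms window")
    return w


def detect_rpeaks_offline(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Locate R-peaks in a single-lead ECG trace.

    Band-pass (5-30 Hz), squared derivative, 150-ms moving-window
    integration, adaptive amplitude threshold, then refinement to the
    R maximum of the dominant polarity.  Polarity-robust: an inverted
    trace yields identical detections.

    Returns sorted 0-based sample indices.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size == 0 or not np.any(np.isfinite(ecg)) or np.ptp(ecg[np.isfinite(ecg)]) == 0:
        warnings.warn("flat or empty ECG signal; no R-peaks detected")
        return np.array([], dtype=int)
    if ecg.size < 5 * fs:
        raise ValueError("offline detection requires at least 5 s of signal")

    bp = bandpass(ecg, fs, 5.0, 30.0)
    energy = np.gradient(bp) ** 2
    w = max(2, int(round(0.150 * fs)))
    integ = np.convolve(energy, np.ones(w) / w, mode="same")
    height = 0.2 * np.percentile(integ, 99)
    cand, _ = find_peaks(integ, distance=int(round(0.25 * fs)), height=height)
    if cand.size == 0:
        warnings.warn("no QRS candidates above adaptive threshold")
        return np.array([], dtype=int)

    half = int(round(0.060 * fs))
    maxima, minima = [], []
    for c in cand:
        seg = bp[max(0, c - half):c + half + 1]
        maxima.append(seg.max())
        minima.append(seg.min())
    polarity = 1.0 if np.median(np.abs(maxima)) >= np.median(np.abs(minima)) else -1.0

    peaks = []
    for c in cand:
        lo = max(0, c - half)
        seg = polarity * bp[lo:c + half + 1]
        peaks.append(lo + int(np.argmax(seg)))
    return np.unique(np.asarray(peaks, dtype=int))


def calibrate_online_threshold(ecg: np.ndarray, fs: float) -> float:
    """Individually adjusted variance threshold for the online trigger.

    Rule: midpoint between the 95th percentile of baseline sliding-window
    variance (outside +/-100 ms of any beat) and the median per-beat peak
    window variance.  Quadratic in signal scale, deterministic.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < 10 * fs:
        raise ValueError("calibration requires at least 10 s of ECG")
    if np.ptp(ecg) == 0:
        raise ValueError("flat calibration signal")
    w = _window_samples(fs)
    v = _rolling_variance(ecg, w)
    peaks = detect_rpeaks_offline(ecg, fs)
    if peaks.size == 0:
        # no QRS present: place the threshold above everything the noise does
        return 4.0 * float(v.max())
    guard = int(round(0.100 * fs))
    near = np.zeros(ecg.size, dtype=bool)
    for p in peaks:
        near[max(0, p - guard):p + guard + 1] = True
    baseline = v[~near]
    base95 = np.percentile(baseline, 95) if baseline.size else 0.0
    halfpk = int(round(0.050 * fs))
    peak_vars = [v[max(0, p - halfpk):p + halfpk + 1].max() for p in peaks]
    return float((base95 + np.median(peak_vars)) / 2.0)


def run_online_detector(ecg: np.ndarray, fs: float, threshold: float) -> np.ndarray:
    """Simulated real-time trigger: fires at the first sample whose
    preceding 33-ms window variance exceeds ``threshold``; a 250-ms
    refractory period suppresses re-triggering within the same beat.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ecg = np.asarray(ecg, dtype=float)
    w = _window_samples(fs)
    v = _rolling_variance(ecg, w)
    above = np.flatnonzero(v > threshold)
    refr = int(round(REFRACTORY * fs))
    triggers = []
    last = -np.inf
    for i in above:
        if i - last >= refr:
            triggers.append(i)
            last = i
    return np.asarray(triggers, dtype=int)


def build_session_sequence(
    seed: int,
    n_blocks: int = 4,
    trials_per_block: int = 56,
    tone_range: tuple[int, int] = (7, 10),
    max_run: int = 3,
    max_tries: int = 1000,
) -> list[TrialSpec]:
    """Randomized balanced session: attention x delay x omission cells equal
    within every block, with no more than ``max_run`` consecutive trials of
    the same attention x delay condition (checked across block boundaries).
    """
    cells = [(a, d, o) for a in ("internal", "external")
             for d in ("short", "long") for o in (False, True)]
    if trials_per_block % len(cells):
        raise ValueError("trials per block must divide into 8 condition cells")
    rng = np.random.default_rng(seed)
    per_cell = trials_per_block // len(cells)

    specs: list[TrialSpec] = []
    for block in range(n_blocks):
        tail = [(s.attention, s.delay) for s in specs[-max_run:]]
        for attempt in range(max_tries):
            order = [c for c in cells for _ in range(per_cell)]
            rng.shuffle(order)
            conds = tail + [(a, d) for a, d, _ in order]
            run, ok = 1, True
            for i in range(1, len(conds)):
                run = run + 1 if conds[i] == conds[i - 1] else 1
                if run > max_run:
                    ok = False
                    break
            if ok:
                break
        else:
            raise RuntimeError("could not satisfy run-length constraint")
        for a, d, o in order:
            n_tones = int(rng.integers(tone_range[0], tone_range[1] + 1))
            specs.append(TrialSpec(a, d, n_tones, o, block))
    return specs


def schedule_trial(
    triggers: np.ndarray,
    spec: TrialSpec,
    fs: float,
    rng: np.random.Generator,
    delay_means: dict[str, float] = DELAY_MEANS,
    jitter_sd: float = JITTER_SD,
) -> pd.DataFrame:
    """Schedule one trial's tone/omission events off successive triggers.

    Each tone occurs at ``trigger + delay_mean + jitter`` with the jitter
    truncated at +/-3 SD so no tone can precede its trigger.  In omission
    trials the third-from-last tone is replaced by an omission event at its
    scheduled time.  Returns rows in the events-table dialect (trial/block
    annotations filled by the caller).
    """
    triggers = np.asarray(triggers)
    if triggers.size < spec.n_tones:
        raise ValueError(
            f"trial needs {spec.n_tones} triggers, got {triggers.size}")
    mean = delay_means[spec.delay]
    rows = []
    for pos in range(1, spec.n_tones + 1):
        trig = triggers[pos - 1]
        jit = np.clip(rng.normal(0.0, jitter_sd), -3 * jitter_sd, 3 * jitter_sd) \
            if jitter_sd > 0 else 0.0
        onset = trig / fs + mean + jit
        kind = "omission" if (spec.omission and pos == spec.omission_position) \
            else "tone"
        rows.append({
            "sample": int(round(onset * fs)), "onset_s": onset, "kind": kind,
            "attention": spec.attention, "delay": spec.delay,
            "omission_trial": int(spec.omission),
        })
    return pd.DataFrame(rows)


def qc_blocks(
    rpeak_times: np.ndarray,
    block_bounds: list[tuple[float, float]],
    rr_bounds: tuple[float, float] = RR_BOUNDS,
) -> np.ndarray:
    """Per-block keep flag: a block is rejected iff any within-block R-R
    interval falls outside ``rr_bounds`` (default 0.4-1.5 s), which signals
    online detection errors (missed or doubled triggers)."""
    t = np.asarray(rpeak_times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("R-peak times must be sorted")
    keep = np.ones(len(block_bounds), dtype=bool)
    lo, hi = rr_bounds
    for b, (t0, t1) in enumerate(block_bounds):
        peaks = t[(t >= t0) & (t < t1)]
        if peaks.size < 2:
            raise ValueError(f"block {b} has fewer than 2 R-peaks")
        rr = np.diff(peaks)
        keep[b] = not np.any((rr > hi) | (rr < lo))
    return keep


def compute_ibis(rpeaks: np.ndarray, omission_events: pd.DataFrame | None = None) -> pd.DataFrame:
    """Interbeat intervals in ms, with post-omission intervals labeled.

    For every omission event, the interval from its triggering R-peak (the
    last peak at or before the omission's scheduled onset) to the next peak
    is labeled ``"omission to 1"`` and the following one ``"1 to 2"``.
    Intervals that would extend past the last detected beat are emitted as
    flagged missing rows.
    """
    t = np.asarray(rpeaks, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("R-peak times must be sorted")
    if t.size < 2:
        warnings.warn("fewer than 2 R-peaks: empty IBI series")
        return pd.DataFrame(columns=["t_start", "t_end", "ibi_ms", "label", "missing"])
    ibis = pd.DataFrame({
        "t_start": t[:-1], "t_end": t[1:],
        "ibi_ms": np.diff(t) * 1e3,
        "label": "", "missing": False,
    })
    if omission_events is not None and len(omission_events):
        extra = []
        for onset in omission_events["onset_s"]:
            k = int(np.searchsorted(t, onset + 1e-9) - 1)
            if k < 0:
                continue
            for off, label in ((0, "omission to 1"), (1, "1 to 2")):
                i = k + off
                if i < len(ibis):
                    ibis.loc[i, "label"] = label
                else:
                    extra.append({"t_start": t[-1] if i == len(ibis) else np.nan,
                                  "t_end": np.nan, "ibi_ms": np.nan,
                                  "label": label, "missing": True})
        if extra:
            ibis = pd.concat([ibis, pd.DataFrame(extra)], ignore_index=True)
    return ibis
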