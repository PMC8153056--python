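"""Continuous filtering, epoching, artifact rejection, and robust averaging.

The stage order mirrors the heartbeat-evoked potential workflow this
package implements: zero-phase FIR band-pass on the continuous data,
epoching around R-peaks or omitted-sound onsets, mastoid re-referencing, a
three-stage z-score rejection cascade (raw channels, trials, ERP-level
channels), linear-decomposition removal of stationary artifacts (blinks),
spherical-spline interpolation of removed channels, whole-head average
reference, heartbeat-locked cardiac-field-artifact subtraction, and
iteratively reweighted robust averaging with a 20-Hz low-pass.  No
baseline correction is applied anywhere: cardiac activity is cyclical, so
pre-event baselines contain structured signal.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import eval_legendre
from scipy.stats import kurtosis as _kurtosis
from sklearn.decomposition import FastICA

from ._filters import bandpass, lowpass_kernel, apply_fir
from .containers import (ArtifactReport, ContinuousRecording, EpochSet,
                         Evoked, SensorLayout)

logger = logging.getLogger(__name__)

Z_THRESHOLD = 3.0


# ---------------------------------------------------------------------------
# continuous filtering and epoching

def filter_continuous(rec: ContinuousRecording, hp: float, lp: float) -> ContinuousRecording:
    """Two-step zero-phase FIR band-pass (high-pass then low-pass)."""
    if not (0 < hp < lp < rec.fs / 2):
        raise ValueError("need 0 < hp < lp < Nyquist")
    out = rec.copy()
    out.data = bandpass(out.data, rec.fs, hp, lp)
    return out


def make_epochs(
    rec: ContinuousRecording,
    events: pd.DataFrame,
    lock: str,
    tmin: float,
    tmax: float,
    picks: Optional[Sequence[str]] = None,
    lock_events: Optional[pd.DataFrame] = None,
) -> EpochSet:
    """Cut half-open windows [tmin, tmax) around events of kind ``lock``.

    Events whose window would extend past the record edges are dropped and
    counted in the log.  Each epoch's metadata records the latencies
    (seconds, relative to the lock event) of all R-peak events falling
    inside its window, for later heartbeat-locked artifact correction.
    ``lock_events`` overrides the kind-based selection (e.g. to lock on a
    labeled subset of R-peaks) while latencies still come from ``events``.
    """
    if tmin >= tmax:
        raise ValueError("tmin must be < tmax")
    sel = lock_events if lock_events is not None else events[events["kind"] == lock]
    if sel.empty:
        raise ValueError(f"no events of kind {lock!r}")
    fs = rec.fs
    if picks is None:
        idx = list(range(rec.n_channels))
    else:
        idx = [rec.ch_names.index(n) for n in picks]
    names = [rec.ch_names[i] for i in idx]

    off0 = int(round(tmin * fs))
    n_samp = int(np.floor((tmax - tmin) * fs))
    times = (np.arange(n_samp) + off0) / fs
    rsamples = events.loc[events["kind"] == "rpeak", "sample"].to_numpy()

    data, meta_rows, dropped = [], [], 0
    for _, ev in sel.iterrows():
        start = int(ev["sample"]) + off0
        if start < 0 or start + n_samp > rec.n_samples:
            dropped += 1
            continue
        data.append(rec.data[idx, start:start + n_samp])
        lat = (rsamples[(rsamples >= start) & (rsamples < start + n_samp)]
               - ev["sample"]) / fs
        row = {c: ev[c] for c in ev.index if c != "kind"}
        row["rpeak_latencies"] = list(lat)
        meta_rows.append(row)
    if dropped:
        logger.info("make_epochs: dropped %d events too close to record edges", dropped)
    if not data:
        raise ValueError("all events fell outside the record")
    return EpochSet(np.stack(data), times, fs, names, lock,
                    pd.DataFrame(meta_rows).reset_index(drop=True))


# ---------------------------------------------------------------------------
# artifact scanning cascade

def hurst_exponent(x: np.ndarray) -> float:
    """Self-similarity index via discrete second-order differences.

    H = 0.5 * log2(S2 / S1) where S_a is the mean squared second-order
    difference at dyadic lag a; exact for fractional Brownian motion, where
    E[S_a] scales as a^(2H).  Clipped to [0, 1].  An exactly linear input
    (zero second differences) is degenerate and returns the upper boundary
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValueError("need at least 16 samples for the Hurst estimate")
    s = []
    for a in (1, 2):
        d = x[2 * a:] - 2 * x[a:-a] + x[:-2 * a]
        s.append(np.mean(d * d))
    if s[0] == 0 or s[1] == 0:
        warnings.warn("zero second-order differences: degenerate Hurst input")
        return 1.0
    return float(np.clip(0.5 * np.log2(s[1] / s[0]), 0.0, 1.0))


def _zscore_or_zero(m: np.ndarray) -> np.ndarray:
    sd = np.std(m, axis=0)
    mean = np.mean(m, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (m - mean) / sd
    z[:, sd == 0] = 0.0 if m.ndim > 1 else 0.0
    return np.where(np.isfinite(z), z, 0.0)


def scan_artifacts(stage: str, epochs: EpochSet,
                   threshold: float = Z_THRESHOLD) -> ArtifactReport:
    """One stage of the three-stage rejection cascade.

    ``channels_raw``: per channel -- variance over all time points, mean
    absolute correlation with the other channels, and the Hurst exponent.
    ``trials``: per epoch -- channel means of the within-trial voltage
    range, of the within-trial variance, and of the absolute deviation of
    the trial-mean voltage from the all-trial mean voltage.
    ``channels_erp``: per channel of the all-condition average -- variance
    across time, median absolute gradient, and voltage range.

    Metrics are z-scored across the scanned axis; a label is flagged if any
    |z| exceeds ``threshold``.  Zero spread on a metric yields z = 0.
    """
    x = epochs.data
    if stage in ("channels_raw", "channels_erp"):
        if epochs.n_channels < 3:
            raise ValueError("channel scans need at least 3 channels")
    elif stage == "trials":
        if epochs.n_epochs < 3:
            raise ValueError("trial scan needs at least 3 epochs")
    else:
        raise ValueError(f"unknown stage {stage!r}")

    if stage == "channels_raw":
        flat = np.swapaxes(x, 0, 1).reshape(epochs.n_channels, -1)
        var = flat.var(axis=1)
        cc = np.corrcoef(flat)
        np.fill_diagonal(cc, np.nan)
        meancorr = np.nanmean(np.abs(cc), axis=1)
        hurst = np.array([hurst_exponent(ch) for ch in flat])
        metrics = pd.DataFrame({"variance": var, "mean_corr": meancorr,
                                "hurst": hurst})
        labels = list(epochs.ch_names)
    elif stage == "trials":
        rng_ = np.ptp(x, axis=2).mean(axis=1)
        var = x.var(axis=2).mean(axis=1)
        trial_mean = x.mean(axis=2)                      # epochs x channels
        dev = np.abs(trial_mean - trial_mean.mean(axis=0)).mean(axis=1)
        metrics = pd.DataFrame({"range": rng_, "variance": var, "deviation": dev})
        labels = list(range(epochs.n_epochs))
    else:  # channels_erp
        erp = x.mean(axis=0)
        metrics = pd.DataFrame({
            "variance": erp.var(axis=1),
            "median_gradient": np.median(np.abs(np.diff(erp, axis=1)), axis=1),
            "range": np.ptp(erp, axis=1),
        })
        labels = list(epochs.ch_names)

    z = pd.DataFrame(_zscore_or_zero(metrics.to_numpy()), columns=metrics.columns)
    flagged = [labels[i] for i in np.flatnonzero((z.abs() > threshold).any(axis=1))]
    return ArtifactReport(stage, labels, metrics, z, flagged, threshold)


# ---------------------------------------------------------------------------
# stationary artifact removal (linear decomposition)

def default_component_classifier(features: pd.DataFrame) -> np.ndarray:
    """Flag components that look like blinks/eye movements.

    A component is flagged when it is frontally dominant, low-frequency
    dominated, and sparse in time (leptokurtic) -- the stereotypical blink
    signature.  Thresholds are heuristics; substitute your own callable for
    a different rule set.
    """
    return ((features["frontal_share"] > 0.45)
            & (features["lf_ratio"] > 0.5)
            & (features["kurtosis"] > 3.0)).to_numpy()


def remove_stationary_artifacts(
    epochs: EpochSet,
    layout: SensorLayout,
    classifier: Optional[Callable[[pd.DataFrame], np.ndarray]] = default_component_classifier,
    random_state: int = 0,
) -> tuple[EpochSet, pd.DataFrame]:
    """Subtract artifact components found by a linear decomposition.

    Independent component analysis is run on the concatenated epochs; each
    component is scored on frontal topography dominance, low-frequency
    (<5 Hz) power share, and kurtosis, and the ``classifier`` decides which
    components to remove.  ``classifier=None`` is an identity transform.
    """
    if classifier is None:
        return epochs.copy(), pd.DataFrame()
    n_ep, n_ch, n_t = epochs.data.shape
    if n_ep * n_t <= n_ch:
        raise ValueError("need more samples than channels for decomposition")
    X = np.swapaxes(epochs.data, 0, 1).reshape(n_ch, -1)
    if np.linalg.matrix_rank(np.cov(X)) < n_ch:
        raise ValueError("rank-deficient data; drop or interpolate channels first")

    ica = FastICA(n_components=n_ch, whiten="unit-variance",
                  random_state=random_state, max_iter=1000, tol=1e-4)
    S = ica.fit_transform(X.T).T                          # comp x samples
    A = ica.mixing_                                       # ch x comp

    lay = layout.subset(epochs.ch_names)
    frontal = lay.pos[:, 1] > 0.25
    absA = np.abs(A)
    frontal_share = absA[frontal].sum(axis=0) / np.maximum(absA.sum(axis=0), 1e-12)
    freqs = np.fft.rfftfreq(n_t, 1.0 / epochs.fs)
    # power spectrum per component, averaged over epochs
    Sep = S.reshape(n_ch, n_ep, n_t)
    P = np.abs(np.fft.rfft(Sep, axis=2)) ** 2
    Pm = P.mean(axis=1)
    lf_ratio = Pm[:, freqs < 5.0].sum(axis=1) / np.maximum(Pm.sum(axis=1), 1e-12)
    kurt = _kurtosis(S, axis=1, fisher=True)

    features = pd.DataFrame({"frontal_share": frontal_share,
                             "lf_ratio": lf_ratio, "kurtosis": kurt})
    flags = np.asarray(classifier(features), dtype=bool)
    features["flagged"] = flags

    out = epochs.copy()
    if flags.any():
        X_clean = X - A[:, flags] @ S[flags]
        out.data = np.swapaxes(X_clean.reshape(n_ch, n_ep, n_t), 0, 1)
    return out, features


# ---------------------------------------------------------------------------
# spherical spline interpolation

_SPLINE_ORDER = 4
_SPLINE_REG = 1e-5
_SPLINE_LMAX = 7
#: polar angle assigned to the layout rim (unit-disc radius 0.5).
_THETA_MAX = 2.0 * np.pi / 3.0


def _layout_to_sphere(pos: np.ndarray) -> np.ndarray:
    """Inverse azimuthal projection of the 2-D layout onto the unit sphere."""
    r = np.linalg.norm(pos, axis=1)
    rmax = max(r.max(), 0.5)
    theta = r / rmax * _THETA_MAX
    phi = np.arctan2(pos[:, 1], pos[:, 0])
    return np.column_stack([np.sin(theta) * np.cos(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(theta)])


def _g_matrix(cosang: np.ndarray, m: int = _SPLINE_ORDER,
              lmax: int = _SPLINE_LMAX) -> np.ndarray:
    g = np.zeros_like(cosang, dtype=float)
    for l in range(1, lmax + 1):
        g += (2 * l + 1) / (l * (l + 1)) ** m * eval_legendre(l, cosang)
    return g / (4 * np.pi)


def interpolate_channels(epochs: EpochSet, layout: SensorLayout,
                         bad: Sequence[str]) -> EpochSet:
    """Replace bad channels by spherical-spline estimates from the rest."""
    bad = list(bad)
    if not bad:
        return epochs.copy()
    unknown = set(bad) - set(epochs.ch_names)
    if unknown:
        raise ValueError(f"bad channels not in data: {sorted(unknown)}")
    good_idx = [i for i, n in enumerate(epochs.ch_names) if n not in set(bad)]
    bad_idx = [epochs.ch_names.index(n) for n in bad]
    if len(good_idx) < 4:
        raise ValueError("need at least 4 good channels to interpolate")

    lay = layout.subset(epochs.ch_names)
    xyz = _layout_to_sphere(lay.pos)
    xg, xb = xyz[good_idx], xyz[bad_idx]
    Ggg = _g_matrix(np.clip(xg @ xg.T, -1, 1))
    Gbg = _g_matrix(np.clip(xb @ xg.T, -1, 1))
    ng = len(good_idx)
    K = np.zeros((ng + 1, ng + 1))
    K[:ng, :ng] = Ggg + np.eye(ng) * _SPLINE_REG
    K[:ng, ng] = 1.0
    K[ng, :ng] = 1.0
    Kinv = np.linalg.inv(K)
    M = np.hstack([Gbg, np.ones((len(bad_idx), 1))]) @ Kinv[:, :ng]

    out = epochs.copy()
    Zg = out.data[:, good_idx]                       # epochs x good x time
    out.data[:, bad_idx] = np.einsum("bg,egt->ebt", M, Zg)
    return out


# ---------------------------------------------------------------------------
# referencing

def rereference(obj, scheme: str, mastoid_names: Sequence[str] = ("M1", "M2"),
                exclude: Optional[Sequence[str]] = None):
    """Subtract a reference per sample.

    ``scheme="mastoids"``: average of the mastoid channels.
    ``scheme="average"``: whole-head average over EEG channels.
    ECG channels (kind "ecg" on recordings, or names in ``exclude``) never
    enter the reference and are left untouched.
    """
    if isinstance(obj, ContinuousRecording):
        names, kinds = obj.ch_names, obj.ch_kinds
        eeg_idx = [i for i, k in enumerate(kinds) if k != "ecg"]
    elif isinstance(obj, EpochSet):
        names = obj.ch_names
        excl = set(exclude or [n for n in names if n.upper().startswith("ECG")])
        eeg_idx = [i for i, n in enumerate(names) if n not in excl]
    else:
        raise TypeError("rereference expects a recording or an epoch set")

    if scheme == "mastoids":
        missing = [m for m in mastoid_names if m not in names]
        if missing:
            raise ValueError(f"missing mastoid channels: {missing}")
        ref_idx = [names.index(m) for m in mastoid_names]
    elif scheme == "average":
        ref_idx = eeg_idx
    else:
        raise ValueError(f"unknown reference scheme {scheme!r}")

    out = obj.copy()
    if isinstance(obj, ContinuousRecording):
        ref = out.data[ref_idx].mean(axis=0)
        out.data[eeg_idx] -= ref
    else:
        ref = out.data[:, ref_idx].mean(axis=1, keepdims=True)
        out.data[:, eeg_idx] -= ref
    return out


# ---------------------------------------------------------------------------
# cardiac field artifact correction

def cfa_correct(epochs: EpochSet, resting_hep: Evoked,
                rpeak_latencies: Optional[Sequence[Sequence[float]]] = None) -> EpochSet:
    """Subtract the resting heartbeat-locked template at every heartbeat.

    For each R-peak latency recorded in an epoch's metadata, the resting
    template (defined on its own time axis relative to the R-peak) is
    subtracted at the matching lag, truncated at the epoch edges.  This
    removes the cardiac field artifact of every heartbeat in the epoch, not
    just the locking one.
    """
    if list(resting_hep.ch_names) != list(epochs.ch_names):
        raise ValueError("resting template montage does not match epochs")
    if abs(resting_hep.fs - epochs.fs) > 1e-9:
        raise ValueError("sampling-rate mismatch between template and epochs")
    if rpeak_latencies is None:
        if "rpeak_latencies" not in epochs.metadata:
            raise ValueError("no R-peak latencies available")
        rpeak_latencies = epochs.metadata["rpeak_latencies"]

    fs = epochs.fs
    tmpl = resting_hep.data
    n_t = epochs.data.shape[2]
    n_tmpl = tmpl.shape[1]
    out = epochs.copy()
    for i, lats in enumerate(rpeak_latencies):
        for lat in lats:
            start = int(round((lat + resting_hep.times[0] - epochs.times[0]) * fs))
            a, b = max(0, start), min(n_t, start + n_tmpl)
            if a >= b:
                continue
            out.data[i, :, a:b] -= tmpl[:, a - start:b - start]
    return out


# ---------------------------------------------------------------------------
# robust averaging

def robust_average(
    epochs: EpochSet,
    condition: str = "",
    k: float = 3.0,
    max_iter: int = 50,
    tol: float = 1e-6,
    lowpass_hz: Optional[float] = 20.0,
) -> Evoked:
    """Iteratively reweighted average with Huber-type weights per time point.

    At each (channel, time) point, residuals from the current weighted mean
    are scaled by 1.4826 x the median absolute deviation across epochs;
    values beyond ``k`` robust-SD units get weight k*s/|r|, others weight 1.
    Without outliers all weights stay 1 and the result is the arithmetic
    mean.  The converged average is low-pass filtered below ``lowpass_hz``
    (pass ``None`` to skip).  No baseline correction is applied.
    """
    x = epochs.data
    if x.shape[0] == 0:
        raise ValueError("no epochs to average")
    if x.shape[0] == 1:
        w = np.ones_like(x)
        avg = x[0].copy()
    else:
        med = np.median(x, axis=0)
        s = 1.4826 * np.median(np.abs(x - med), axis=0)
        w = np.ones_like(x)
        avg = x.mean(axis=0)
        converged = False
        for _ in range(max_iter):
            r = np.abs(x - avg)
            with np.errstate(divide="ignore", invalid="ignore"):
                w_new = np.minimum(1.0, k * s / r)
            w_new = np.where((s == 0) | (r == 0), 1.0, w_new)
            avg = (w_new * x).sum(axis=0) / w_new.sum(axis=0)
            if np.max(np.abs(w_new - w)) < tol:
                w = w_new
                converged = True
                break
            w = w_new
        if not converged:
            logger.warning("robust_average: weights did not converge in %d "
                           "iterations; returning last iterate", max_iter)
    if lowpass_hz is not None:
        avg = apply_fir(avg, lowpass_kernel(epochs.fs, lowpass_hz))
    return Evoked(avg, epochs.times.copy(), epochs.fs, list(epochs.ch_names),
                  condition, x.shape[0], weights=w)
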