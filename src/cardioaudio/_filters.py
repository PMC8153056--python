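"""Zero-phase windowed-sinc FIR filtering used across the pipeline.

High-pass and low-pass are applied as two separate linear-phase FIR stages
(Hamming window).  Kernels have odd length, so applying them with a
'same'-mode convolution after reflection padding compensates the group
delay exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import firwin, fftconvolve

#: Hamming-window fractional transition width (normalized frequency units).
_HAMMING_BW = 3.3


def _numtaps(fs: float, trans_hz: float) -> int:
    n = int(np.ceil(_HAMMING_BW * fs / trans_hz))
    return n + 1 if n % 2 == 0 else n


def highpass_kernel(fs: float, hp: float) -> np.ndarray:
    trans = max(0.25 * hp, 0.25)
    n = _numtaps(fs, trans)
    return firwin(n, hp, pass_zero=False, window="hamming", fs=fs)


def lowpass_kernel(fs: float, lp: float) -> np.ndarray:
    trans = min(0.25 * lp, 10.0)
    n = _numtaps(fs, trans)
    return firwin(n, lp, pass_zero=True, window="hamming", fs=fs)


def apply_fir(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-phase application of an odd-length symmetric FIR along last axis.

    The signal is reflection-padded by half the kernel length on each side
    so edges see a continuation rather than zeros.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    half = (len(kernel) - 1) // 2
    if x.shape[-1] <= half:
        raise ValueError(
            f"record of {x.shape[-1]} samples shorter than filter half-order {half}")
    pad = np.concatenate(
        [x[..., 1:half + 1][..., ::-1], x, x[..., -half - 1:-1][..., ::-1]], axis=-1)
    out = fftconvolve(pad, kernel[None, :], mode="same", axes=-1)
    return out[..., half:half + x.shape[-1]]


def bandpass(x: np.ndarray, fs: float, hp: float | None, lp: float | None) -> np.ndarray:
    """High-pass then low-pass, each zero-phase; either edge may be None."""
    squeeze = np.asarray(x).ndim == 1
    y = np.atleast_2d(np.asarray(x, dtype=float))
    if hp is not None:
        y = apply_fir(y, highpass_kernel(fs, hp))
    if lp is not None:
        y = apply_fir(y, lowpass_kernel(fs, lp))
    return y[0] if squeeze else y
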