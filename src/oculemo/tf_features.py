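"""Short-time Fourier transform features for EOG traces.

A preprocessed trace is cut into 1-s windows hopping by 0.5 s.  Each window
is linearly resampled to ``L`` (default 64) samples, tapered with an L-point
Hamming window and transformed with an L-point DFT; the magnitudes of the
first L/2 bins (DC included, Nyquist excluded) form one spectrogram column.
Under the defaults a 60-s trial at any sampling rate yields a 32 x 119
magnitude matrix, and flattening bin-major gives the 3808-long
time-frequency observation vector.

Resampling every window to L samples is what bridges "1-s window" with an
"L-point transform" at an arbitrary sampling rate: the effective rate inside
a window becomes L Hz, so bin ``l`` sits at ``l`` Hz and the retained bins
span 0-31 Hz, comfortably containing the 0.01-10 Hz EOG band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

DEFAULT_WINDOW_S = 1.0
DEFAULT_HOP_S = 0.5
DEFAULT_L = 64


@dataclass
class Spectrogram:
    """STFT magnitudes: ``magnitudes[l, m]`` = bin ``l`` of frame ``m``."""

    magnitudes: np.ndarray  # (bins, frames), nonnegative
    bin_freqs: np.ndarray  # Hz per bin
    frame_times: np.ndarray  # window start time per frame, s

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.magnitudes.ndim != 2:
            raise ValidationError("magnitudes must be bins x frames")
        if np.any(self.magnitudes < 0):
            raise ValidationError("magnitudes must be nonnegative")
        self.bin_freqs = np.asarray(self.bin_freqs, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if len(self.bin_freqs) != self.magnitudes.shape[0]:
            raise ValidationError("one frequency per bin required")
        if len(self.frame_times) != self.magnitudes.shape[1]:
            raise ValidationError("one time per frame required")

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitudes.shape


def n_frames(n_samples: int, fs: float, window_s: float, hop_s: float) -> int:
    """Number of full windows: floor((T − window)/hop) + 1, in samples."""
    win = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    if n_samples < win:
        return 0
    return (n_samples - win) // hop + 1


def stft(
    trace: np.ndarray,
    fs: float,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
    L: int = DEFAULT_L,
) -> Spectrogram:
    """Compute the magnitude spectrogram of a 1-D trace.

    Parameters
    ----------
    trace : real 1-D series.
    fs : sampling rate, Hz.
    window_s, hop_s : window length and hop, s.
    L : transform length; each window is resampled to L samples first.

    Raises
    ------
    ValidationError
        If the trace is shorter than one window.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValidationError("trace must be 1-D")
    win = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    if win < 2 or hop < 1 or L < 2:
        raise ValidationError("window/hop/L too small")
    m = n_frames(len(trace), fs, window_s, hop_s)
    if m == 0:
        raise ValidationError(
            f"trace of {len(trace)} samples is shorter than one "
            f"{win}-sample window"
        )
    taper = np.hamming(L)
    # linear resampling grid: window endpoints map onto L evenly spaced points
    src = np.arange(win)
    dst = np.linspace(0.0, win - 1, L)
    n_bins = L // 2
    mags = np.empty((n_bins, m))
    for k in range(m):
        frame = trace[k * hop : k * hop + win]
        resampled = np.interp(dst, src, frame)
        spectrum = np.fft.fft(resampled * taper, n=L)
        mags[:, k] = np.abs(spectrum[:n_bins])
    bin_freqs = np.arange(n_bins) * (L / window_s) / L  # = l / window_s Hz
    frame_times = np.arange(m) * hop / fs
    return Spectrogram(mags, bin_freqs, frame_times)


def tf_feature_vector(spectrograms: list[Spectrogram] | Spectrogram) -> np.ndarray:
    """Average spectrograms over channels and flatten bin-major.

    The per-bin time series are concatenated in bin order, so the vector is
    ``[X(f_0, t_0..t_{M-1}), X(f_1, ...), ...]`` with length bins x frames
    (3808 under the defaults for a 60-s trial).
    """
    if isinstance(spectrograms, Spectrogram):
        spectrograms = [spectrograms]
    if not spectrograms:
        raise ValidationError("need at least one spectrogram")
    shape = spectrograms[0].shape
    for s in spectrograms[1:]:
        if s.shape != shape:
            raise ValidationError(
                f"spectrogram shape mismatch: {s.shape} vs {shape}"
            )
    mean = np.mean([s.magnitudes for s in spectrograms], axis=0)
    return mean.ravel(order="C")
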