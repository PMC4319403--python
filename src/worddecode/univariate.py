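"""Univariate analyses: ERP and event-related spectral perturbation (ERSP).

The ERP is the trial-averaged time-domain response per channel.  The ERSP
is the trial-averaged time-frequency power change relative to the
pre-stimulus baseline, in dB, computed with a Hanning-tapered sliding FFT
filter bank on a linear frequency axis from 1 to 60 Hz in 2 Hz steps
(30 bins).  Group statistics are two-sided Wilcoxon signed-rank tests per
point against baseline with Benjamini-Hochberg FDR at 5%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import EpochedDataset
from .stats import wilcoxon_map

__all__ = [
    "ErpResult",
    "ErspResult",
    "default_ersp_freqs",
    "compute_erp",
    "compute_ersp",
    "group_test_vs_baseline",
]


@dataclass
class ErpResult:
    """Trial-averaged evoked response."""

    mean: np.ndarray  # channels x samples, microvolt
    sem: np.ndarray   # standard error of the mean, same shape
    n_trials: int
    times_ms: np.ndarray


@dataclass
class ErspResult:
    """Baseline-normalized time-frequency power (dB), channel-averaged."""

    power_db: np.ndarray          # frequencies x samples
    freqs: np.ndarray             # Hz, 30 bins (1, 3, ..., 59)
    times_ms: np.ndarray
    sig_mask: np.ndarray | None = None  # group-level FDR mask, same shape


def default_ersp_freqs() -> np.ndarray:
    """Bin centers 1, 3, ..., 59 Hz (30 bins covering 1-60 Hz in 2 Hz steps)."""
    return np.arange(1.0, 60.0, 2.0)


def compute_erp(epochs: EpochedDataset) -> ErpResult:
    """Mean and SEM over trials; requires >= 2 trials for the SEM."""
    if epochs.n_trials < 2:
        raise ValueError("ERP needs >= 2 trials (SEM undefined otherwise)")
    mean = epochs.data.mean(axis=0)
    sem = epochs.data.std(axis=0, ddof=1) / np.sqrt(epochs.n_trials)
    return ErpResult(mean=mean, sem=sem, n_trials=epochs.n_trials,
                     times_ms=epochs.times_ms)


def compute_ersp(epochs: EpochedDataset,
                 freqs: np.ndarray | None = None,
                 window_ms: float = 250.0,
                 baseline_ms: tuple[float, float] = (-1000.0, 0.0)) -> ErspResult:
    """Hanning-taper FFT-filter ERSP, averaged over trials and channels.

    For each frequency, power over time is obtained by convolving the
    signal with a Hanning-windowed complex exponential of length
    ``window_ms`` (an STFT evaluated at every sample at arbitrary bin
    centers), averaging |.|^2 over trials and channels, and expressing it
    as 10*log10(P / P_baseline) with the baseline mean taken per frequency
    over ``baseline_ms``.  The 250 ms default window trades resolution at
    the 1 Hz end against temporal resolution.
    """
    if freqs is None:
        freqs = default_ersp_freqs()
    freqs = np.asarray(freqs, dtype=float)
    nyq = epochs.sampling_rate / 2.0
    if np.any(freqs >= nyq):
        raise ValueError(f"frequencies must lie below Nyquist ({nyq} Hz)")
    n_win = int(round(window_ms / 1000.0 * epochs.sampling_rate))
    n_win += (n_win + 1) % 2  # odd length keeps 'same' convolution centered
    taper = np.hanning(n_win + 2)[1:-1]
    t = (np.arange(n_win) - n_win // 2) / epochs.sampling_rate

    a = epochs.sample_at(baseline_ms[0])
    b = epochs.sample_at(baseline_ms[1])
    if b <= a:
        raise ValueError("empty baseline window")

    power = np.empty((len(freqs), epochs.n_samples))
    for fi, f in enumerate(freqs):
        kernel = taper * np.exp(-2j * np.pi * f * t)
        kernel /= np.abs(kernel).sum() / 2.0  # unit gain for an in-bin sinusoid
        resp = signal.fftconvolve(
            epochs.data, kernel[None, None, :], mode="same", axes=2
        )
        power[fi] = np.mean(np.abs(resp) ** 2, axis=(0, 1))
    base = power[:, a:b].mean(axis=1, keepdims=True)
    power_db = 10.0 * np.log10(power / base)
    return ErspResult(power_db=power_db, freqs=freqs, times_ms=epochs.times_ms)


def group_test_vs_baseline(values: np.ndarray,
                           alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Group (random-effects) test of subjects x points values against zero.

    Two-sided Wilcoxon signed-rank per point, BH-FDR corrected at
    ``alpha``.  Returns ``(sig_mask, pvals)`` in the point shape.
    """
    return wilcoxon_map(values, mu=0.0, alpha=alpha)
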