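"""Filtering, epoching, baseline correction and artifact-epoch rejection.

Conventions (used everywhere in the package): epochs are half-open sample
windows ``[tmin, tmax)``, 0-based, with time in ms relative to word onset;
filtering is zero-phase (forward-backward), so no latency shift is
introduced.  Artifact handling is deterministic peak-to-peak thresholding;
independent-component-based correction of stereotyped artifacts is out of
scope (it requires manual component categorization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .containers import ContinuousRecording, EpochedDataset

__all__ = [
    "RejectionLog",
    "bandpass",
    "extract_epochs",
    "baseline_correct",
    "reject_epochs",
    "read_edf",
]


@dataclass
class RejectionLog:
    """Record of trials removed by peak-to-peak rejection."""

    rejected_indices: np.ndarray
    threshold: float

    @property
    def n_rejected(self) -> int:
        return len(self.rejected_indices)


def bandpass(rec: ContinuousRecording, low: float = 0.1, high: float = 100.0,
             order: int = 4) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass (default 0.1-100 Hz).

    Applied forward-backward (``sosfiltfilt``), which squares the magnitude
    response and cancels the phase response; the effective roll-off is
    2 x ``order``.  Length and events are preserved.
    """
    nyq = rec.sampling_rate / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz >= Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.sampling_rate,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return ContinuousRecording(
        data=filtered, sampling_rate=rec.sampling_rate, events=rec.events.copy()
    )


def extract_epochs(rec: ContinuousRecording, tmin_ms: float = -1000.0,
                   tmax_ms: float = 1000.0,
                   events: pd.DataFrame | None = None) -> EpochedDataset:
    """Cut epochs ``[tmin_ms, tmax_ms)`` around each event onset.

    Events whose window extends past either end of the recording are dropped
    with a warning (they cannot be epoched).  Defaults to ``rec.events``;
    pass a filtered table to epoch a subset (e.g. animal trials only).
    """
    if events is None:
        events = rec.events
    fs = rec.sampling_rate
    s_lo = int(round(tmin_ms / 1000.0 * fs))
    s_hi = int(round(tmax_ms / 1000.0 * fs))
    if s_hi <= s_lo:
        raise ValueError("empty epoch window")
    n_samples = s_hi - s_lo

    keep_rows = []
    epochs = []
    n_dropped = 0
    for _, row in events.iterrows():
        a = int(row["sample"]) + s_lo
        b = a + n_samples
        if a < 0 or b > rec.n_samples:
            n_dropped += 1
            continue
        epochs.append(rec.data[:, a:b])
        keep_rows.append(row)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} event(s) too close to the recording edge",
            stacklevel=2,
        )
    if not epochs:
        raise ValueError("no events could be epoched")
    meta = pd.DataFrame(keep_rows).reset_index(drop=True)
    return EpochedDataset(
        data=np.stack(epochs), meta=meta, sampling_rate=fs,
        tmin_ms=s_lo / fs * 1000.0, tmax_ms=s_hi / fs * 1000.0,
    )


def baseline_correct(epochs: EpochedDataset,
                     window_ms: tuple[float, float] = (-1000.0, 0.0)) -> EpochedDataset:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    a = epochs.sample_at(window_ms[0])
    b = epochs.sample_at(window_ms[1])
    if b <= a:
        raise ValueError("empty baseline window")
    base = epochs.data[:, :, a:b].mean(axis=2, keepdims=True)
    return epochs.copy_with(epochs.data - base)


def reject_epochs(epochs: EpochedDataset,
                  ptp_threshold: float = 150.0) -> tuple[EpochedDataset, RejectionLog]:
    """Remove trials whose peak-to-peak amplitude exceeds the threshold
    on any channel; metadata stays aligned with the retained trials."""
    if not ptp_threshold > 0:
        raise ValueError("ptp_threshold must be positive")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # trials x channels
    bad = np.where((ptp > ptp_threshold).any(axis=1))[0]
    if len(bad) == epochs.n_trials:
        raise ValueError(
            f"all {epochs.n_trials} trials exceed {ptp_threshold} uV peak-to-peak; "
            f"smallest trial maximum is {ptp.max(axis=1).min():.1f} uV"
        )
    keep = np.setdiff1d(np.arange(epochs.n_trials), bad)
    return epochs.select(keep), RejectionLog(rejected_indices=bad,
                                             threshold=ptp_threshold)


def read_edf(path: str | Path) -> ContinuousRecording:
    """Read a continuous EDF recording (requires the optional mne extra).

    Events are taken from the file's annotations: ``sample`` is the
    annotation onset rounded to the nearest sample and ``word_form`` the
    annotation description.
    """
    import mne  # deferred: heavy import, optional dependency

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = raw.info["sfreq"]
    events = pd.DataFrame(
        {
            "sample": (raw.annotations.onset * fs).round().astype(int),
            "word_form": list(raw.annotations.description),
        }
    )
    return ContinuousRecording(
        data=raw.get_data() * 1e6,  # volts -> microvolt
        sampling_rate=fs,
        events=events,
    )
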