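"""SEP analysis: trial averaging, Morlet time-frequency maps, band power, rest RMS."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal

from .recording import (
    BASELINE_LEN,
    FS_HZ,
    INIT_OFFSET,
    STIM_OFFSET,
    ConditionLabel,
    EpochSet,
    Recording,
    label_from_code,
)

#: analysed CWT frequencies: 30 log-spaced points over 10-1000 Hz, covering
#: the slow (~40-50 Hz), high-gamma (80-200 Hz) and very fast (300-800 Hz)
#: response components.
DEFAULT_TF_FREQS = np.logspace(np.log10(10.0), np.log10(1000.0), 30)

#: Morlet centre-frequency parameter omega0 = 6 expressed as the pywt
#: complex-Morlet "cmorB-C" bandwidth/centre pair (B = 2, C = omega0 / 2pi).
_MORLET_WAVELET = "cmor2.0-0.9549296585513721"

HIGH_GAMMA_BAND = (80.0, 200.0)
#: 33 ms following t_init, in samples
POWER_WINDOW = (INIT_OFFSET, INIT_OFFSET + 201)


@dataclass
class AveragedSEP:
    """Across-trial mean SEP of one condition (channels x samples)."""

    mean_uv: np.ndarray
    n_averaged: int
    condition: ConditionLabel
    channel_ids: np.ndarray
    pre: int
    fs_hz: float = FS_HZ

    @property
    def n_channels(self) -> int:
        return self.mean_uv.shape[0]

    @property
    def n_samples(self) -> int:
        return self.mean_uv.shape[1]


@dataclass
class TFMap:
    """Normalized CWT power map (frequencies x time) for one channel."""

    power: np.ndarray
    freqs_hz: np.ndarray
    pre: int
    fs_hz: float = FS_HZ
    channel: int | None = None


def average_epochs(epochs: EpochSet, condition) -> AveragedSEP:
    """Pointwise mean over all trials of one condition."""
    if not isinstance(condition, ConditionLabel):
        condition = label_from_code(condition)
    idx = epochs.trials_of(condition)
    if idx.size == 0:
        raise ValueError(f"no trials for condition {condition}")
    mean = epochs.data_uv[idx].mean(axis=0, dtype=np.float64)
    return AveragedSEP(
        mean_uv=mean,
        n_averaged=int(idx.size),
        condition=condition,
        channel_ids=epochs.channel_ids.copy(),
        pre=epochs.pre,
        fs_hz=epochs.fs_hz,
    )


def morlet_tf(waveform: np.ndarray, fs: float = FS_HZ,
              freqs: np.ndarray | None = None, pre: int = BASELINE_LEN,
              channel: int | None = None) -> TFMap:
    """Continuous Morlet wavelet power of one epoch, baseline-normalized.

    ``waveform`` is a single-channel epoch whose first ``pre`` samples are the
    pre-stimulus baseline; each frequency row of the squared-magnitude CWT is
    divided by its mean over that baseline, so pre-stimulus normalized power
    is ~1 per row.
    """
    freqs = DEFAULT_TF_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    if np.any(freqs >= fs / 2.0):
        raise ValueError(f"analysis frequency above Nyquist ({fs / 2.0:g} Hz)")
    if pre < 2:
        raise ValueError("epoch must cover a pre-stimulus baseline")
    scales = pywt.frequency2scale(_MORLET_WAVELET, freqs / fs)
    coef, _ = pywt.cwt(np.asarray(waveform, dtype=float), scales,
                       _MORLET_WAVELET, sampling_period=1.0 / fs)
    power = np.abs(coef) ** 2
    baseline = power[:, :pre].mean(axis=1)
    power /= baseline[:, None]
    return TFMap(power=power, freqs_hz=freqs, pre=pre, fs_hz=fs, channel=channel)


def _band_power(x: np.ndarray, band, fs: float, window, method: str) -> np.ndarray:
    """Mean power of ``x`` (channels x samples) inside ``band`` over ``window``.

    ``method='filter'``: zero-phase 4th-order Butterworth band-pass of the full
    trace, then the mean square over the window (the deterministic default).
    ``method='periodogram'``: integral of the windowed periodogram over the
    band (additive across disjoint bands by Parseval).
    """
    lo, hi = band
    if not (0.0 <= lo < hi < fs / 2.0):
        raise ValueError("band must lie within (0, Nyquist)")
    i0, i1 = int(window[0]), int(window[1])
    if i1 <= i0:
        raise ValueError("empty power window")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if method == "filter":
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        y = signal.sosfiltfilt(sos, x, axis=1)
        return np.mean(y[:, i0:i1] ** 2, axis=1)
    if method == "periodogram":
        f, pxx = signal.periodogram(x[:, i0:i1], fs=fs, axis=1)
        sel = (f >= lo) & (f < hi)
        df = f[1] - f[0]
        return pxx[:, sel].sum(axis=1) * df
    raise ValueError(f"unknown band power method {method!r}")


def band_power_map(avg, band=HIGH_GAMMA_BAND, window=POWER_WINDOW,
                   method: str = "filter") -> pd.Series:
    """Per-channel mean band power over a post-trigger window.

    ``avg`` is an :class:`AveragedSEP` or an :class:`EpochSet` (epochs are
    averaged across trials first).  ``window`` is in post-trigger sample
    offsets; the default is the 33 ms period following ``t_init``.
    """
    if isinstance(avg, EpochSet):
        data = avg.data_uv.mean(axis=0, dtype=np.float64)
        pre, fs, ids = avg.pre, avg.fs_hz, avg.channel_ids
    else:
        data, pre, fs, ids = avg.mean_uv, avg.pre, avg.fs_hz, avg.channel_ids
    win = (pre + window[0], pre + window[1])
    if win[1] > data.shape[1]:
        raise ValueError("power window extends past the epoch")
    p = _band_power(data, band, fs, win, method)
    return pd.Series(p, index=ids, name=f"power_{band[0]:g}-{band[1]:g}Hz")


def rest_rms(rec: Recording, chunk: int = 512) -> pd.Series:
    """Per-channel rest-state RMS voltage (uV), averaged over stimuli.

    For every trigger a 98 ms (598-sample) segment starting 100 ms before
    stimulus onset (``t_stim``) is taken, mean-zeroed, and its RMS computed;
    segment RMS values are averaged per channel.
    """
    seg_len = BASELINE_LEN
    pre_stim = int(round(0.100 * rec.fs_hz))          # 100 ms before t_stim
    starts = rec.trigger_idx + STIM_OFFSET - pre_stim
    if np.any(starts < 0):
        raise ValueError("a trigger lacks 100 ms of pre-stimulus data")

    acc = np.zeros(rec.n_channels, dtype=np.float64)
    for k0 in range(0, starts.size, chunk):
        s = starts[k0:k0 + chunk]
        idx = s[:, None] + np.arange(seg_len)[None, :]
        seg = rec.voltage_uv[:, idx].astype(np.float64)   # (ch, trig, samp)
        seg -= seg.mean(axis=2, keepdims=True)
        acc += np.sqrt(np.mean(seg ** 2, axis=2)).sum(axis=1)
    rms = acc / starts.size
    return pd.Series(rms, index=np.arange(rec.n_channels), name="rest_rms_uv")
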