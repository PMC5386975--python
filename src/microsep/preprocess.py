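"""Common preprocessing: re-referencing, epoching, trial selection, z-scoring.

Order of operations is fixed: common average reference -> per-trial baseline
correction -> epoch extraction -> (feature construction) -> z-scoring.
CAR and baseline correction are both linear mean-subtracting maps, so they
commute on a fixed channel set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .recording import BASELINE_LEN, CONDITIONS, EpochSet, Recording

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocConfig:
    """Preprocessing options.

    ``car_channels`` is the channel set averaged for the common reference;
    ``None`` means all channels of the array, including broken ones (the raw
    signal is re-referenced before dead channels are dropped).
    """

    exclude_broken: bool = True
    baseline_len: int = BASELINE_LEN
    car_channels: tuple | None = None


def common_average_reference(rec: Recording,
                             car_channels=None,
                             copy: bool = True) -> Recording:
    """Subtract the instantaneous mean over ``car_channels`` from every channel.

    With ``copy=False`` the voltage matrix is re-referenced in place (useful
    for long recordings).
    """
    if car_channels is None:
        car = np.arange(rec.n_channels)
    else:
        car = np.asarray(sorted(car_channels), dtype=np.int64)
    if car.size < 2:
        raise ValueError("common average needs at least 2 channels")
    v = rec.voltage_uv.copy() if copy else rec.voltage_uv
    v -= v[car].mean(axis=0, dtype=np.float64).astype(v.dtype)
    return Recording(
        fs_hz=rec.fs_hz,
        voltage_uv=v,
        trigger_idx=rec.trigger_idx.copy(),
        label_codes=rec.label_codes.copy(),
        geometry=rec.geometry,
    )


def extract_epochs(rec: Recording,
                   span: tuple = (BASELINE_LEN, 250),
                   cfg: PreprocConfig | None = None) -> EpochSet:
    """Cut per-trigger windows ``[t_trig - pre, t_trig + post)`` and baseline-correct.

    The per-trial, per-channel mean of the ``cfg.baseline_len`` samples before
    ``t_trig`` is subtracted.  Triggers that do not fit the span (or the
    baseline window) are dropped with a logged count.  Broken channels are
    removed when ``cfg.exclude_broken``.
    """
    cfg = cfg or PreprocConfig()
    pre, post = int(span[0]), int(span[1])
    margin = max(pre, cfg.baseline_len)

    keep = (rec.trigger_idx >= margin) & (rec.trigger_idx + post <= rec.n_samples)
    dropped = int(np.count_nonzero(~keep))
    if dropped:
        log.info("extract_epochs: dropped %d of %d triggers at the edges",
                 dropped, rec.n_triggers)
    trig = rec.trigger_idx[keep]
    codes = rec.label_codes[keep]

    if cfg.exclude_broken:
        channel_ids = rec.geometry.retained_channels
    else:
        channel_ids = np.arange(rec.n_channels)

    n_trials = trig.shape[0]
    data = np.empty((n_trials, channel_ids.size, pre + post), dtype=np.float32)
    v = rec.voltage_uv
    for i, t0 in enumerate(trig):
        seg = v[channel_ids, t0 - pre:t0 + post]
        base = v[channel_ids, t0 - cfg.baseline_len:t0].mean(
            axis=1, dtype=np.float64)
        data[i] = seg - base[:, None].astype(np.float32)

    return EpochSet(
        data_uv=data,
        label_codes=codes,
        channel_ids=channel_ids,
        pre=pre,
        fs_hz=rec.fs_hz,
        trigger_idx=trig,
    )


def select_decode_trials(epochs: EpochSet, n_per_condition: int = 100) -> EpochSet:
    """Keep exactly the first ``n_per_condition`` trials of every condition.

    Trials stay in chronological order; with the default this yields the
    balanced 1,000-sample decode set (10 conditions x 100 stimuli).
    """
    keep = []
    for code in range(len(CONDITIONS)):
        idx = epochs.trials_of(code)
        if idx.size < n_per_condition:
            raise ValueError(
                f"condition {CONDITIONS[code]} has only {idx.size} trials, "
                f"need {n_per_condition}"
            )
        keep.append(idx[:n_per_condition])
    keep = np.sort(np.concatenate(keep))
    return epochs.select_trials(keep)


def zscore_features(X: np.ndarray, mode: str = "global") -> np.ndarray:
    """Convert features to z-scores using all-sample statistics (population SD).

    ``mode='global'`` (the default) standardizes with one scalar mean and SD
    computed over every value of every sample, train and test together: a
    single affine rescaling of the feature space that maps voltages to
    z-units without re-weighting features against each other.
    ``mode='columns'`` standardizes each feature column separately with its
    all-sample mean and SD.  Zero-variance values map to 0 in both modes.
    ``mode='none'`` returns the input unchanged.  Fold-safe standardization
    is available through the decoder (``standardize='fold'``), which applies
    training-fold statistics to the test fold.
    """
    if mode == "none":
        return X
    if X.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    if mode == "global":
        mu = float(X.mean(dtype=np.float64))
        sd = float(X.std(dtype=np.float64))
        if sd <= 1e-12 * max(abs(mu), 1.0):          # constant input
            return np.zeros_like(X, dtype=np.float32)
        return ((X - mu) / sd).astype(np.float32, copy=False)
    if mode == "columns":
        mu = X.mean(axis=0, dtype=np.float64)
        sd = X.std(axis=0, dtype=np.float64)
        # columns constant up to rounding count as zero-variance
        const = sd <= 1e-12 * np.maximum(np.abs(mu), 1.0)
        sd[const] = 1.0
        Z = ((X - mu) / sd).astype(np.float32, copy=False)
        Z[:, const] = 0.0
        return Z
    raise ValueError(f"unknown z-scoring mode {mode!r}")


def zscore_fit(X: np.ndarray) -> tuple:
    """Population mean/SD of the columns of ``X`` (for fold-safe scaling)."""
    mu = X.mean(axis=0, dtype=np.float64)
    sd = X.std(axis=0, dtype=np.float64)
    sd[sd == 0.0] = 1.0
    return mu, sd


def zscore_apply(X: np.ndarray, stats: tuple) -> np.ndarray:
    mu, sd = stats
    return ((X - mu) / sd).astype(np.float32, copy=False)
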