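"""Shared data model: condition labels, the time-mark scheme, recordings, epochs.

The canonical time unit throughout the package is SAMPLES at the acquisition
rate of 6,103.52 Hz; millisecond values are labels only.  Per-trigger marks:

====================  =======================================================
``t_trig``            trigger sample emitted by the stimulator
``t_stim``            stimulus arrival, ``t_trig + 16`` samples (~2.6 ms)
``t_init``            earliest decode sample, ``t_trig + 50`` (clears the
                      5.2 ms stimulation-artifact guard)
``t_full``            end of the full-length decode window, ``t_trig + 250``
====================  =======================================================

so the full-length window ``[t_init, t_full)`` is exactly 200 samples
(about 33 ms).  Baseline correction uses the 598 samples (~98 ms) preceding
``t_trig``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ArrayGeometry

FS_HZ = 6103.52
STIM_OFFSET = 16        # round(2.6 ms * 6103.52 Hz)
INIT_OFFSET = 50
FULL_OFFSET = 250
BASELINE_LEN = 598      # ~98 ms
ARTIFACT_GUARD_MS = 5.2
ISI_MS = 305.0

FINGERS = ("D1", "D2", "D3", "D4", "D5")
INTENSITIES_MA = (1, 4)


@dataclass(frozen=True, order=True)
class ConditionLabel:
    """A stimulation condition: finger (D1..D5) x intensity (1 or 4 mA)."""

    finger: str
    intensity_ma: int

    def __post_init__(self):
        if self.finger not in FINGERS:
            raise ValueError(f"unknown finger {self.finger!r}")
        if self.intensity_ma not in INTENSITIES_MA:
            raise ValueError(f"unknown intensity {self.intensity_ma!r}")

    @property
    def finger_index(self) -> int:
        return FINGERS.index(self.finger)

    @property
    def code(self) -> int:
        """Canonical class code 0..9 (finger-major, 1 mA before 4 mA)."""
        return self.finger_index * 2 + INTENSITIES_MA.index(self.intensity_ma)

    def __str__(self) -> str:
        return f"{self.finger}x{self.intensity_ma}mA"


#: the 10 conditions in canonical code order
CONDITIONS = tuple(
    ConditionLabel(f, i) for f in FINGERS for i in INTENSITIES_MA
)


def label_from_code(code: int) -> ConditionLabel:
    return CONDITIONS[int(code)]


@dataclass(frozen=True)
class TimeMarks:
    """Per-trigger sample marks (see module docstring)."""

    t_trig: int
    stim_offset: int = STIM_OFFSET
    init_offset: int = INIT_OFFSET
    full_offset: int = FULL_OFFSET
    baseline_len: int = BASELINE_LEN
    artifact_guard_ms: float = ARTIFACT_GUARD_MS

    @property
    def t_stim(self) -> int:
        return self.t_trig + self.stim_offset

    @property
    def t_init(self) -> int:
        return self.t_trig + self.init_offset

    @property
    def t_full(self) -> int:
        return self.t_trig + self.full_offset

    @property
    def full_window(self) -> tuple:
        """Half-open full-length decode window ``[t_init, t_full)``."""
        return (self.t_init, self.t_full)


def marks_from_trigger(t_trig: int, fs: float = FS_HZ,
                       baseline_len: int = BASELINE_LEN) -> TimeMarks:
    """Build the time marks for one trigger.

    Raises ``ValueError`` when the trigger sits too close to the start of the
    recording for the 598-sample baseline window (such trials are rejected).
    """
    if t_trig < baseline_len:
        raise ValueError(
            f"trigger at sample {t_trig} has less than {baseline_len} "
            "samples of pre-trigger data"
        )
    return TimeMarks(t_trig=int(t_trig), baseline_len=baseline_len)


@dataclass
class Recording:
    """Continuous multichannel voltage with stimulation triggers.

    ``voltage_uv`` is channels x samples in microvolts (float32);
    ``trigger_idx`` holds the t_trig sample of every stimulus in order and
    ``label_codes`` the matching condition code (see ``ConditionLabel.code``).
    """

    fs_hz: float
    voltage_uv: np.ndarray
    trigger_idx: np.ndarray
    label_codes: np.ndarray
    geometry: ArrayGeometry

    def __post_init__(self):
        self.trigger_idx = np.asarray(self.trigger_idx, dtype=np.int64)
        self.label_codes = np.asarray(self.label_codes, dtype=np.int64)
        if self.trigger_idx.shape != self.label_codes.shape:
            raise ValueError("every trigger needs a condition label")
        if np.any(np.diff(self.trigger_idx) <= 0):
            raise ValueError("trigger indices must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.voltage_uv.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltage_uv.shape[1]

    @property
    def n_triggers(self) -> int:
        return self.trigger_idx.shape[0]

    def labels(self):
        return [label_from_code(c) for c in self.label_codes]


@dataclass
class EpochSet:
    """Trials x channels x samples, cut and aligned on the trigger marks.

    Sample axis index ``pre`` corresponds to ``t_trig``; post-trigger offset
    ``k`` lives at index ``pre + k``.
    """

    data_uv: np.ndarray            # (n_trials, n_channels, n_samples) float32
    label_codes: np.ndarray        # (n_trials,)
    channel_ids: np.ndarray        # (n_channels,) ids into the geometry
    pre: int                       # samples kept before t_trig
    fs_hz: float = FS_HZ
    trigger_idx: np.ndarray | None = None   # original trigger sample per trial

    def __post_init__(self):
        self.label_codes = np.asarray(self.label_codes, dtype=np.int64)
        self.channel_ids = np.asarray(self.channel_ids, dtype=np.int64)
        n, c, _ = self.data_uv.shape
        if self.label_codes.shape[0] != n or self.channel_ids.shape[0] != c:
            raise ValueError("inconsistent EpochSet shapes")

    @property
    def n_trials(self) -> int:
        return self.data_uv.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data_uv.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data_uv.shape[2]

    @property
    def post(self) -> int:
        return self.n_samples - self.pre

    def index_of(self, post_trigger_offset: int) -> int:
        """Sample-axis index of a post-trigger offset (0 == t_trig)."""
        i = self.pre + post_trigger_offset
        if not 0 <= i <= self.n_samples:
            raise ValueError("offset outside the epoch window")
        return i

    def counts_per_condition(self) -> np.ndarray:
        return np.bincount(self.label_codes, minlength=len(CONDITIONS))

    def trials_of(self, condition) -> np.ndarray:
        code = condition.code if isinstance(condition, ConditionLabel) else int(condition)
        return np.flatnonzero(self.label_codes == code)

    def select_trials(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            data_uv=self.data_uv[idx],
            label_codes=self.label_codes[idx],
            channel_ids=self.channel_ids.copy(),
            pre=self.pre,
            fs_hz=self.fs_hz,
            trigger_idx=None if self.trigger_idx is None else self.trigger_idx[idx],
        )
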