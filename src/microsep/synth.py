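"""Synthetic micro-ECoG recordings with the structure the analysis assumes.

The generator emulates electrical finger stimulation over the hand
representation of somatosensory cortex as seen by the 96-channel array:

* per stimulus, a deterministic noiseless SEP template per channel made of
  an early biphasic (sulcal) component onsetting ~9 ms and peaking ~12 ms
  after the stimulus, and a main slow positive/negative complex (plus a
  small high-gamma burst) peaking ~19 ms;
* finger-specific Gaussian source foci 700 um (one electrode pitch) apart,
  ordered D1 -> D5 along the lateral -> medial (+x) axis, whose main source
  drifts anterior -> posterior (+y) over time;
* a sharp 2-sample biphasic stimulation artifact at ``t_stim``;
* additive rest noise (spatially correlated AR(1) slow band + white)
  calibrated to an 18 uV RMS rest level, and two broken channels carrying
  wide-band noise with no evoked component;
* stimuli in contiguous per-condition blocks at a 305 ms interval.

Intensity is coded multiplicatively: 1 mA responses are ``intensity_gain``
times the 4 mA responses.  The early component shares one topography across
fingers but has finger-specific amplitude, so decoding from short
(<15 ms post-stimulus) windows is solvable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .geometry import ArrayGeometry, default_geometry
from .recording import (
    CONDITIONS,
    FINGERS,
    FS_HZ,
    ISI_MS,
    STIM_OFFSET,
    ConditionLabel,
    Recording,
)

#: 4 mA amplitude of the early shared-topography component per finger, uV.
#: The ladder is spaced so that, with the 0.4 intensity gain, all ten
#: condition levels on the shared early template stay mutually separated by
#: >= 30 uV at the template's best contact -- about five matched-filter
#: standard deviations against the rest-noise model, which is what makes
#: short-window and single-channel decoding solvable by design.
DEFAULT_EARLY_AMP_UV = (250.0, 325.0, 400.0, 475.0, 550.0)


def default_finger_centers(geometry: ArrayGeometry) -> dict:
    """Finger source centres: five consecutive contact columns of patch B.

    Centres are one pitch (700 um) apart, ordered D1 -> D5 laterally to
    medially (+x), on the y = 2 contact row (the main source crosses this
    nominal centre at its peak time while drifting posteriorly).
    """
    patch_b = geometry.channels_of_patch(1)
    xs = np.unique(geometry.pos_um[patch_b, 0])
    ys = np.unique(geometry.pos_um[patch_b, 1])
    # columns 2..6 of the 8-column patch, row index 2
    cols = xs[2:7]
    y = ys[2]
    return {f: (float(cols[i]), float(y)) for i, f in enumerate(FINGERS)}


def default_early_center(geometry: ArrayGeometry) -> tuple:
    """Shared centre of the early (sulcal) component.

    Placed on a contact in the medial, anterior part of patch B (column 6,
    row 1), next to the D5 focus: the sulcal wall is anterior of the finger
    foci and the most medial contacts carry the most predictive signal.
    """
    patch_b = geometry.channels_of_patch(1)
    xs = np.unique(geometry.pos_um[patch_b, 0])
    ys = np.unique(geometry.pos_um[patch_b, 1])
    return (float(xs[6]), float(ys[1]))


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic experiment (defaults = study conditions)."""

    seed: int = 0
    n_trials_per_condition: int = 200
    isi_ms: float = ISI_MS
    fs_hz: float = FS_HZ
    # spatial source model
    finger_centers_um: dict | None = None    # None -> default_finger_centers
    spatial_sigma_um: float = 600.0
    early_sigma_um: float = 1000.0           # wider footprint of the deep source
    drift_um_per_ms: float = 50.0            # anterior -> posterior (+y)
    early_center_um: tuple | None = None     # None -> default_early_center
    # waveform model
    amp_peak_uv: float = 300.0               # main-complex peak at 4 mA, on-centre
    intensity_gain: float = 0.4              # 1 mA / 4 mA amplitude ratio
    early_onset_ms: float = 9.0
    early_peak_ms: float = 12.0
    main_peak_ms: float = 19.0
    early_amp_uv: tuple = DEFAULT_EARLY_AMP_UV
    hg_rel_amp: float = 0.35                 # high-gamma burst vs slow complex
    artifact_amp_uv: float = 1000.0
    # noise model
    noise_rms_uv: float = 18.0
    noise_spatial_corr: float = 0.3          # inter-channel corr of slow band
    slow_noise_fraction: float = 0.5         # share of variance in slow band
    noise_ar_coeff: float = 0.97
    broken_channels: tuple | None = None     # None -> geometry default
    broken_noise_rms_uv: float = 50.0
    kernel_len: int = 600                    # post-trigger template samples
    start_offset: int = 700                  # sample of the first trigger

    def __post_init__(self):
        if not (0.0 < self.intensity_gain < 1.0):
            raise ValueError("intensity_gain must lie in (0, 1)")
        if self.noise_rms_uv <= 0:
            raise ValueError("noise_rms_uv must be positive")
        for name in ("isi_ms", "early_onset_ms", "early_peak_ms",
                     "main_peak_ms", "spatial_sigma_um", "early_sigma_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.noise_spatial_corr <= 1.0):
            raise ValueError("noise_spatial_corr must lie in [0, 1]")
        if not (0.0 <= self.slow_noise_fraction <= 1.0):
            raise ValueError("slow_noise_fraction must lie in [0, 1]")


def _resolve(cfg: SynthConfig, geometry: ArrayGeometry):
    centers = cfg.finger_centers_um or default_finger_centers(geometry)
    early_center = cfg.early_center_um or default_early_center(geometry)
    broken = frozenset(cfg.broken_channels) if cfg.broken_channels is not None \
        else geometry.broken
    return centers, early_center, broken


def sep_kernel(channel: int, label: ConditionLabel, cfg: SynthConfig,
               geometry: ArrayGeometry, n_samples: int | None = None) -> np.ndarray:
    """Deterministic noiseless SEP template for one channel and condition.

    Returns the post-trigger waveform in uV (length ``cfg.kernel_len`` by
    default); identically zero before ``t_stim`` and outside the compact
    supports of the two components.  Amplitudes scale with the channel's
    Gaussian distance to the (time-drifting) finger source and, for 1 mA,
    by ``cfg.intensity_gain``.
    """
    centers, early_center, broken = _resolve(cfg, geometry)
    if channel in broken:
        raise ValueError(f"channel {channel} is broken")
    if label.finger not in centers:
        raise ValueError(f"no source centre for finger {label.finger!r}")
    n = n_samples or cfg.kernel_len

    # time after the stimulus, in ms
    t = (np.arange(n) - STIM_OFFSET) / cfg.fs_hz * 1e3
    pos = geometry.pos_um[channel]
    sig2 = 2.0 * cfg.spatial_sigma_um ** 2

    # main slow complex: Hann-windowed ~45 Hz carrier peaking at main_peak_ms,
    # with a small Hann-windowed high-gamma (~140 Hz) burst; compact support.
    mp = cfg.main_peak_ms
    half = 7.0
    u = (t - (mp - half)) / (2 * half)
    env_slow = np.where((u >= 0) & (u <= 1), 0.5 * (1 - np.cos(2 * np.pi * u)), 0.0)
    uf = (t - (mp - 4.0)) / 8.0
    env_fast = np.where((uf >= 0) & (uf <= 1), 0.5 * (1 - np.cos(2 * np.pi * uf)), 0.0)
    w_main = env_slow * np.cos(2 * np.pi * 0.045 * (t - mp)) \
        + cfg.hg_rel_amp * env_fast * np.cos(2 * np.pi * 0.140 * (t - mp))
    w_main /= w_main.max()

    cx, cy = centers[label.finger]
    dy = cfg.drift_um_per_ms * (t - mp)       # source crosses (cx, cy) at mp
    d2 = (pos[0] - cx) ** 2 + (pos[1] - (cy + dy)) ** 2
    main = cfg.amp_peak_uv * w_main * np.exp(-d2 / sig2)

    # early biphasic component: one Hann-windowed sine cycle (negative lobe
    # leading, as on the far sulcal wall) on the compact support
    # [onset, onset + 1.5*(peak-onset)].  sin(2*pi*u)*sin^2(pi*u) has its
    # extrema at exactly u = 1/3 and 2/3, so the positive lobe peaks exactly
    # at early_peak_ms; the zero integral keeps slow (drift-like) rest noise
    # from projecting onto the amplitude code.
    eon, epk = cfg.early_onset_ms, cfg.early_peak_ms
    span = 1.5 * (epk - eon)
    ue = (t - eon) / span
    w_early = np.where((ue >= 0) & (ue <= 1),
                       -np.sin(2 * np.pi * ue) * np.sin(np.pi * ue) ** 2, 0.0)
    w_early /= w_early.max()
    ex, ey = early_center
    esig2 = 2.0 * cfg.early_sigma_um ** 2
    g_early = np.exp(-((pos[0] - ex) ** 2 + (pos[1] - ey) ** 2) / esig2)
    early = cfg.early_amp_uv[label.finger_index] * w_early * g_early

    k = main + early
    if label.intensity_ma == 1:
        k = k * cfg.intensity_gain
    k[t < 0] = 0.0
    return k


def _ar1_noise(rng: np.random.Generator, n: int, phi: float,
               burn: int = 2000) -> np.ndarray:
    """Unit-variance stationary AR(1) sequence (slow band)."""
    e = rng.standard_normal(n + burn).astype(np.float32)
    x = lfilter([1.0], [1.0, -phi], e) * np.sqrt(1.0 - phi ** 2)
    return x[burn:].astype(np.float32)


def generate_recording(cfg: SynthConfig,
                       geometry: ArrayGeometry | None = None) -> Recording:
    """Generate a continuous synthetic recording (fully seeded).

    Triggers are blocked by condition in the canonical condition order, at the
    configured inter-stimulus interval.  Broken channels carry only wide-band
    noise.  Identical configs (same seed) produce bit-identical recordings.
    """
    geometry = geometry or default_geometry()
    centers, early_center, broken = _resolve(cfg, geometry)
    rng = np.random.default_rng(cfg.seed)

    n_cond = len(CONDITIONS)
    n_trig = n_cond * cfg.n_trials_per_condition
    codes = np.repeat(np.arange(n_cond), cfg.n_trials_per_condition)
    isi = cfg.isi_ms / 1e3 * cfg.fs_hz
    trig = cfg.start_offset + np.rint(np.arange(n_trig) * isi).astype(np.int64)
    n_samples = int(trig[-1] + max(cfg.kernel_len, 700))
    if n_samples * geometry.n_channels > 2 ** 32:
        raise ValueError("requested recording duration overflows the container")

    # --- noise -------------------------------------------------------------
    w_slow = cfg.noise_rms_uv * np.sqrt(cfg.slow_noise_fraction)
    w_white = cfg.noise_rms_uv * np.sqrt(1.0 - cfg.slow_noise_fraction)
    a_shared = np.sqrt(cfg.noise_spatial_corr)
    a_indep = np.sqrt(1.0 - cfg.noise_spatial_corr)
    shared = _ar1_noise(rng, n_samples, cfg.noise_ar_coeff)

    volt = np.empty((geometry.n_channels, n_samples), dtype=np.float32)
    for ch in range(geometry.n_channels):
        if ch in broken:
            volt[ch] = cfg.broken_noise_rms_uv * \
                rng.standard_normal(n_samples).astype(np.float32)
            continue
        white = rng.standard_normal(n_samples).astype(np.float32)
        slow = a_shared * shared + a_indep * _ar1_noise(
            rng, n_samples, cfg.noise_ar_coeff)
        volt[ch] = w_white * white + w_slow * slow

    # --- evoked templates and artifact ------------------------------------
    ok = np.array([ch for ch in range(geometry.n_channels) if ch not in broken])
    kernels = np.zeros((n_cond, geometry.n_channels, cfg.kernel_len),
                       dtype=np.float32)
    for code, label in enumerate(CONDITIONS):
        for ch in ok:
            kernels[code, ch] = sep_kernel(ch, label, cfg, geometry)

    art = np.float32(cfg.artifact_amp_uv)
    for t0, code in zip(trig, codes):
        volt[:, t0:t0 + cfg.kernel_len] += kernels[code]
        if art != 0:
            volt[ok, t0 + STIM_OFFSET] += art
            volt[ok, t0 + STIM_OFFSET + 1] -= art

    return Recording(
        fs_hz=cfg.fs_hz,
        voltage_uv=volt,
        trigger_idx=trig,
        label_codes=codes,
        geometry=replace_broken(geometry, broken),
    )


def replace_broken(geometry: ArrayGeometry, broken) -> ArrayGeometry:
    """Return the geometry with its broken-channel set replaced."""
    if frozenset(broken) == geometry.broken:
        return geometry
    return replace(geometry, broken=frozenset(broken))
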