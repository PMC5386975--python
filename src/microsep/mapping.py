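"""Canvas interpolation, surface-map frames and the thresholded COG trajectory.

Per time sample, the channel voltages are placed at their canvas pixels and
interpolated over the 800 x 513 canvas by linear barycentric interpolation on
the Delaunay triangulation of the used contacts (no extrapolation outside the
hull).  The centre of gravity of the peak-response area at time t is the
voltage-weighted mean pixel coordinate over the pixels whose interpolated
voltage reaches the threshold (150 uV by default):

    COG(t)_x = sum_j x_j V_j(t) / sum_j V_j(t),   j = { j | V_j(t) >= theta }

and likewise for y; the COG is undefined at times with no suprathreshold
pixel.  The two broken contacts plus one configurable "overlapping" contact
at the A/B patch seam are excluded from the interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .geometry import ArrayGeometry
from .sep import AveragedSEP

#: COG voltage threshold, uV
COG_THRESHOLD_UV = 150.0


def default_overlap_channel(geometry: ArrayGeometry) -> int:
    """The contact dropped as overlapping the neighbouring patch.

    Deterministic default: the patch-B contact closest to patch A (smallest x;
    ties broken by smallest y).
    """
    patch_b = geometry.channels_of_patch(1)
    pos = geometry.pos_um[patch_b]
    order = np.lexsort((pos[:, 1], pos[:, 0]))
    return int(patch_b[order[0]])


def default_excluded(geometry: ArrayGeometry) -> frozenset:
    """Broken contacts plus the overlapping contact (3 channels)."""
    return frozenset(geometry.broken) | {default_overlap_channel(geometry)}


@dataclass
class InterpolatedMap:
    """One interpolated canvas frame; NaN outside the interpolation hull."""

    grid_uv: np.ndarray            # (canvas_h, canvas_w) float32
    time: int | None = None        # post-trigger sample offset

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.grid_uv)

    def plot(self, ax=None, **imshow_kw):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.grid_uv, origin="upper", **imshow_kw)
        ax.set_xlabel("x (px, lateral → medial)")
        ax.set_ylabel("y (px, anterior → posterior)")
        return im


@dataclass
class CogTrajectory:
    """Sequence of defined COG points over time."""

    times: np.ndarray              # post-trigger sample offsets with a COG
    points_px: np.ndarray          # (n, 2) canvas-pixel coordinates
    threshold_uv: float = COG_THRESHOLD_UV

    def __len__(self) -> int:
        return self.times.shape[0]

    def to_dataframe(self, geometry: ArrayGeometry | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time": self.times,
             "x_px": self.points_px[:, 0],
             "y_px": self.points_px[:, 1]}
        )
        if geometry is not None:
            um = geometry.px_to_um(self.points_px)
            df["x_um"] = um[:, 0]
            df["y_um"] = um[:, 1]
        return df


class CanvasInterpolator:
    """Reusable channel-values -> canvas interpolator.

    Precomputes the Delaunay triangulation of the used contacts' canvas pixels
    and the barycentric weights of every in-hull canvas pixel, so one frame is
    a sparse matrix-vector product.
    """

    def __init__(self, geometry: ArrayGeometry, excluded=None):
        self.geometry = geometry
        self.excluded = frozenset(default_excluded(geometry) if excluded is None
                                  else excluded)
        self.channels = np.array(
            [c for c in range(geometry.n_channels) if c not in self.excluded])
        if self.channels.size < 3:
            raise ValueError("interpolation needs at least 3 usable channels")
        pts = geometry.canvas_px[self.channels].astype(float)
        self._tri = Delaunay(pts)

        w, h = geometry.canvas_size
        gx, gy = np.meshgrid(np.arange(w), np.arange(h))
        grid = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
        simplex = self._tri.find_simplex(grid)
        self.inside = simplex >= 0
        sid = simplex[self.inside]
        # barycentric coordinates of each in-hull pixel
        T = self._tri.transform[sid, :2, :2]
        r = self._tri.transform[sid, 2]
        b = np.einsum("ijk,ik->ij", T, grid[self.inside] - r)
        bary = np.column_stack([b, 1.0 - b.sum(axis=1)])
        self._verts = self._tri.simplices[sid]        # (m, 3) into channels
        self._bary = bary                              # (m, 3)
        self._grid_xy = grid
        self.canvas_shape = (h, w)

    def _values_for(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if values.shape[0] == self.geometry.n_channels:
            return values[self.channels]
        if values.shape[0] == self.channels.size:
            return values
        raise ValueError("values must cover all channels or the used subset")

    def __call__(self, values, time: int | None = None) -> InterpolatedMap:
        """Interpolate one frame of per-channel values onto the canvas."""
        v = self._values_for(values)
        flat = np.full(self._grid_xy.shape[0], np.nan, dtype=np.float32)
        flat[self.inside] = np.einsum("ij,ij->i", self._bary, v[self._verts])
        return InterpolatedMap(grid_uv=flat.reshape(self.canvas_shape), time=time)

    def flat_values(self, values_matrix: np.ndarray) -> np.ndarray:
        """Interpolate many frames at once: (channels, t) -> (in-hull px, t)."""
        v = self._values_for(values_matrix)
        return np.einsum("ij,ijt->it", self._bary, v[self._verts])

    def cog_batch(self, values_matrix: np.ndarray,
                  threshold_uv: float = COG_THRESHOLD_UV) -> np.ndarray:
        """COG per frame of a (channels, t) matrix; NaN rows where undefined."""
        flat = self.flat_values(values_matrix)
        xy = self._grid_xy[self.inside]
        out = np.full((flat.shape[1], 2), np.nan)
        for k in range(flat.shape[1]):
            sel = flat[:, k] >= threshold_uv
            if not np.any(sel):
                continue
            w = flat[sel, k]
            out[k] = (xy[sel] * w[:, None]).sum(axis=0) / w.sum()
        return out


def interpolate_surface(values, geometry: ArrayGeometry,
                        excluded=None, time: int | None = None) -> InterpolatedMap:
    """One-shot interpolation of per-channel values onto the canvas."""
    return CanvasInterpolator(geometry, excluded=excluded)(values, time=time)


def cog(map_: InterpolatedMap | np.ndarray,
        threshold_uv: float = COG_THRESHOLD_UV):
    """Voltage-weighted mean pixel coordinate over suprathreshold pixels.

    Returns ``(x, y)`` in canvas pixels, or ``None`` when no defined pixel
    reaches the threshold.
    """
    grid = map_.grid_uv if isinstance(map_, InterpolatedMap) else np.asarray(map_)
    sel = np.isfinite(grid) & (grid >= threshold_uv)
    if not np.any(sel):
        return None
    ys, xs = np.nonzero(sel)
    w = grid[sel].astype(float)
    return (float((xs * w).sum() / w.sum()), float((ys * w).sum() / w.sum()))


def _avg_values(avg: AveragedSEP, geometry: ArrayGeometry,
                offsets: np.ndarray) -> np.ndarray:
    """Per-channel values for the requested post-trigger offsets, indexed by
    geometry channel id (excluded/absent channels left at 0, they are unused)."""
    values = np.zeros((geometry.n_channels, offsets.size))
    idx = avg.pre + offsets
    if idx.min() < 0 or idx.max() >= avg.n_samples:
        raise ValueError("requested span outside the averaged epoch")
    values[avg.channel_ids] = avg.mean_uv[:, idx]
    return values


def cog_trajectory(avg: AveragedSEP, geometry: ArrayGeometry,
                   time_range: tuple = (0, 600),
                   threshold_uv: float = COG_THRESHOLD_UV,
                   excluded=None,
                   interpolator: CanvasInterpolator | None = None,
                   chunk: int = 64) -> CogTrajectory:
    """COG per time sample of an averaged SEP; undefined frames are skipped.

    ``time_range`` is a half-open post-trigger offset range.
    """
    interp = interpolator or CanvasInterpolator(geometry, excluded=excluded)
    offsets = np.arange(int(time_range[0]), int(time_range[1]))
    pts = np.full((offsets.size, 2), np.nan)
    for k0 in range(0, offsets.size, chunk):
        off = offsets[k0:k0 + chunk]
        vals = _avg_values(avg, geometry, off)
        pts[k0:k0 + off.size] = interp.cog_batch(vals, threshold_uv)
    defined = np.isfinite(pts[:, 0])
    return CogTrajectory(times=offsets[defined], points_px=pts[defined],
                         threshold_uv=threshold_uv)


def frame_sequence(avg: AveragedSEP, geometry: ArrayGeometry,
                   span: tuple = (0, 600), step: int = 1,
                   excluded=None,
                   interpolator: CanvasInterpolator | None = None) -> list:
    """Ordered interpolated canvas frames over a post-trigger span.

    The default span reproduces the 600-frame (98 ms) evoked-response map
    sequence.  Note a full-resolution 600-frame stack is ~1 GB; use ``step``
    or a narrower span when memory matters.
    """
    interp = interpolator or CanvasInterpolator(geometry, excluded=excluded)
    offsets = np.arange(int(span[0]), int(span[1]), int(step))
    if offsets.size == 0:
        raise ValueError("empty frame span")
    vals = _avg_values(avg, geometry, offsets)
    return [interp(vals[:, k], time=int(offsets[k]))
            for k in range(offsets.size)]


def export_frames(frames, out_dir, vmin=None, vmax=None, cmap="viridis"):
    """Write frames as a numbered PNG stack (frame_0000.png, ...)."""
    import pathlib

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vals = np.concatenate([f.grid_uv[np.isfinite(f.grid_uv)] for f in frames])
    vmin = float(vals.min()) if vmin is None else vmin
    vmax = float(vals.max()) if vmax is None else vmax
    paths = []
    for i, f in enumerate(frames):
        p = out / f"frame_{i:04d}.png"
        plt.imsave(p, np.nan_to_num(f.grid_uv, nan=vmin), vmin=vmin, vmax=vmax,
                   cmap=cmap)
        paths.append(p)
    return paths
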