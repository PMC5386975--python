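"""Physical and canvas layout of the 96-channel micro-ECoG array.

The array consists of three flexible patches (A, B, C) of 32 contacts each,
700 um inter-electrode pitch, 350 um square recording sites.  Each patch is
laid out as 8 columns x 4 rows of contacts; patches sit left to right on a
common plane with a configurable inter-patch gap.  For surface mapping every
contact is also assigned an integer pixel on an 800 x 513 canvas via a single
frozen affine placement (uniform scale, centred, 20 px margin).

Coordinate conventions: origin top-left, x increases rightward (the medial
direction in the rendered maps), y increases downward (posterior); positions
in micrometres, canvas in pixels, 0-based indices throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

N_CHANNELS = 96
N_PATCHES = 3
CHANNELS_PER_PATCH = 32
PATCH_COLS = 8
PATCH_ROWS = 4
PITCH_UM = 700.0
CONTACT_UM = 350.0

CANVAS_W = 800
CANVAS_H = 513
CANVAS_MARGIN_PX = 20

#: default pair of dead contacts (one in patch A, one in patch C); the real
#: array had exactly two broken channels at unreported positions, so these
#: are configurable, not asserted.
DEFAULT_BROKEN = (5, 70)

PATCH_LABELS = ("A", "B", "C")


@dataclass(frozen=True)
class ArrayGeometry:
    """Channel positions, patch membership and canvas mapping of the array."""

    pos_um: np.ndarray            # (96, 2) float, (x, y) in micrometres
    patch_of: np.ndarray          # (96,) int in {0, 1, 2}
    canvas_px: np.ndarray         # (96, 2) int, (x, y) pixel on the canvas
    broken: frozenset = frozenset(DEFAULT_BROKEN)
    pitch_um: float = PITCH_UM
    contact_um: float = CONTACT_UM
    canvas_size: tuple = (CANVAS_W, CANVAS_H)
    # affine canvas placement: px = pos_um * px_per_um + offset (then rounded)
    px_per_um: float = 1.0
    canvas_offset_px: tuple = (0.0, 0.0)

    @property
    def n_channels(self) -> int:
        return self.pos_um.shape[0]

    def patch_label(self, channel: int) -> str:
        return PATCH_LABELS[int(self.patch_of[channel])]

    def channels_of_patch(self, patch: int | str) -> np.ndarray:
        if isinstance(patch, str):
            patch = PATCH_LABELS.index(patch)
        return np.flatnonzero(self.patch_of == patch)

    @property
    def retained_channels(self) -> np.ndarray:
        """Channel ids with the broken contacts removed (default 94)."""
        mask = np.ones(self.n_channels, dtype=bool)
        mask[list(self.broken)] = False
        return np.flatnonzero(mask)

    def px_to_um(self, px_xy) -> np.ndarray:
        """Invert the affine canvas placement (pixel -> micrometre plane)."""
        px_xy = np.asarray(px_xy, dtype=float)
        return (px_xy - np.asarray(self.canvas_offset_px)) / self.px_per_um

    def um_to_px(self, um_xy) -> np.ndarray:
        um_xy = np.asarray(um_xy, dtype=float)
        return um_xy * self.px_per_um + np.asarray(self.canvas_offset_px)

    # --- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "pos_um": self.pos_um.tolist(),
                "patch_of": self.patch_of.tolist(),
                "canvas_px": self.canvas_px.tolist(),
                "broken": sorted(self.broken),
                "pitch_um": self.pitch_um,
                "contact_um": self.contact_um,
                "canvas_size": list(self.canvas_size),
                "px_per_um": self.px_per_um,
                "canvas_offset_px": list(self.canvas_offset_px),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ArrayGeometry":
        d = json.loads(text)
        return cls(
            pos_um=np.asarray(d["pos_um"], dtype=float),
            patch_of=np.asarray(d["patch_of"], dtype=np.int64),
            canvas_px=np.asarray(d["canvas_px"], dtype=np.int64),
            broken=frozenset(d["broken"]),
            pitch_um=float(d["pitch_um"]),
            contact_um=float(d["contact_um"]),
            canvas_size=tuple(d["canvas_size"]),
            px_per_um=float(d["px_per_um"]),
            canvas_offset_px=tuple(d["canvas_offset_px"]),
        )

    def __post_init__(self):
        if self.pos_um.shape != (self.patch_of.shape[0], 2):
            raise ValueError("pos_um and patch_of are inconsistent")
        if not set(self.broken) <= set(range(self.n_channels)):
            raise ValueError("broken channel id out of range")


def default_geometry(gap_um: float | None = None,
                     broken=DEFAULT_BROKEN) -> ArrayGeometry:
    """Canonical 3-patch, 96-channel layout with its frozen canvas mapping.

    Parameters
    ----------
    gap_um
        Horizontal gap between neighbouring patches.  Defaults to one patch
        width (the x-extent of a patch, 7 * 700 um).
    broken
        Ids of the two dead contacts.
    """
    patch_w = (PATCH_COLS - 1) * PITCH_UM
    if gap_um is None:
        gap_um = patch_w

    pos = np.zeros((N_CHANNELS, 2), dtype=float)
    patch_of = np.zeros(N_CHANNELS, dtype=np.int64)
    for ch in range(N_CHANNELS):
        p, k = divmod(ch, CHANNELS_PER_PATCH)
        row, col = divmod(k, PATCH_COLS)
        pos[ch, 0] = p * (patch_w + gap_um) + col * PITCH_UM
        pos[ch, 1] = row * PITCH_UM
        patch_of[ch] = p

    # frozen affine placement on the canvas: uniform scale, centred
    extent = pos.max(axis=0) - pos.min(axis=0)
    scale = min(
        (CANVAS_W - 2 * CANVAS_MARGIN_PX) / extent[0],
        (CANVAS_H - 2 * CANVAS_MARGIN_PX) / extent[1],
    )
    offset = (
        (CANVAS_W - scale * extent[0]) / 2.0,
        (CANVAS_H - scale * extent[1]) / 2.0,
    )
    canvas = np.rint(pos * scale + np.asarray(offset)).astype(np.int64)

    return ArrayGeometry(
        pos_um=pos,
        patch_of=patch_of,
        canvas_px=canvas,
        broken=frozenset(broken),
        canvas_size=(CANVAS_W, CANVAS_H),
        px_per_um=scale,
        canvas_offset_px=offset,
    )
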