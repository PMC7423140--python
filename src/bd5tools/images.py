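"""Import labeled segmentation images (TIFF label rasters) as BD5 records.

Coordinate convention: x = column index, y = row index, origin at the
top-left pixel center, 0-based; z = slice index for 3D stacks.  Background
is label 0; every distinct positive label is one region of interest.

Two import modes:

point
    one point record per label at the region's pixel-coordinate centroid.
face
    one face entity per label tracing the region's outer boundary pixel
    ring — Moore-neighbour tracing over the 4-connected region, clockwise
    (in image axes, y down) from the topmost-leftmost boundary pixel.
    Face mode is 2D-only and needs regions of at least 3 boundary pixels.
"""

from __future__ import annotations

import numpy as np
import tifffile

from .geometry import make_entity
from .model import SpatialRecord

__all__ = ["import_labeled_image", "read_label_tiff", "trace_boundary"]

# Moore neighbourhood in clockwise order starting East, as (drow, dcol).
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def trace_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """Ordered outer-boundary pixel ring of a binary region.

    Moore-neighbour tracing with Jacob's stopping criterion, clockwise in
    image coordinates, starting at the topmost-leftmost region pixel.
    Returns (row, col) pixels; the starting pixel is not repeated at the
    end.  One- and two-pixel regions return rings shorter than 3.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return []
    start = (int(rows[0]), int(cols[0]))  # np.nonzero scans row-major
    if rows.size == 1:
        return [start]

    def inside(p):
        r, c = p
        return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and bool(mask[r, c])

    # The pixel left of the topmost-leftmost region pixel is outside by
    # construction; tracing "entered" start from there.
    ring = [start]
    current, backtrack = start, (start[0], start[1] - 1)
    first_move = None
    for _ in range(4 * int(rows.size) + 8):
        k = _MOORE.index((backtrack[0] - current[0], backtrack[1] - current[1]))
        nxt = None
        for i in range(1, 9):
            d = _MOORE[(k + i) % 8]
            cand = (current[0] + d[0], current[1] + d[1])
            if inside(cand):
                nxt = cand
                new_backtrack = (current[0] + _MOORE[(k + i - 1) % 8][0],
                                 current[1] + _MOORE[(k + i - 1) % 8][1])
                break
        if nxt is None:  # no traceable neighbour: treat as isolated pixel
            break
        # Stop when the walk repeats its first move out of the start pixel.
        move = (current, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:
            break
        if nxt != start:
            ring.append(nxt)
        current, backtrack = nxt, new_backtrack
    else:
        raise RuntimeError("boundary trace failed to terminate")
    return ring


def import_labeled_image(
    image: np.ndarray,
    t: float,
    mode: str = "point",
    oID: int = 0,
) -> list[SpatialRecord]:
    """Convert a labeled raster into spatial records at time ``t``.

    Each distinct nonzero label becomes one record (point mode) or one face
    entity (face mode); the record ID is the label number as text.  2D
    arrays are (row, col); 3D arrays are (slice, row, col) and are
    supported in point mode only.
    """
    image = np.asarray(image)
    if image.dtype.kind not in "iu":
        raise TypeError(f"label image must be an integer array, got dtype {image.dtype}")
    if image.ndim not in (2, 3):
        raise ValueError(f"label image must be 2D or 3D, got {image.ndim}D")
    if mode not in ("point", "face"):
        raise ValueError(f"mode must be 'point' or 'face', got {mode!r}")
    labels = np.unique(image)
    labels = labels[labels > 0]
    records: list[SpatialRecord] = []
    for lab in labels:
        mask = image == lab
        if mode == "point":
            coords = np.nonzero(mask)
            if image.ndim == 2:
                y, x = (float(c.mean()) for c in coords)
                vertex = (x, y)
            else:
                z, y, x = (float(c.mean()) for c in coords)
                vertex = (x, y, z)
            records += make_entity("point", str(int(lab)), t, [vertex])
        else:
            if image.ndim != 2:
                raise ValueError("face mode supports 2D label images only")
            ring = trace_boundary(mask)
            if len(ring) < 3:
                raise ValueError(
                    f"label {int(lab)}: region boundary has {len(ring)} pixel(s); "
                    f"a face needs at least 3 (use point mode for tiny regions)")
            vertices = [(float(c), float(r)) for r, c in ring]
            records += make_entity("face", str(int(lab)), t, vertices)
    return records


def read_label_tiff(path, pages_as: str = "z"):
    """Read a single- or multi-page TIFF label raster.

    ``pages_as="z"`` stacks pages into one 3D volume at a single time;
    ``pages_as="t"`` returns a list of 2D frames for successive times.
    """
    if pages_as not in ("z", "t"):
        raise ValueError(f"pages_as must be 'z' or 't', got {pages_as!r}")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        return arr if pages_as == "z" else [arr]
    if pages_as == "z":
        return arr
    return [arr[i] for i in range(arr.shape[0])]
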