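"""Test objects and motion trajectories.

Binary phantoms mimicking the black-rubber absorbers used to validate
the imaging system: block letters placed in a single depth slice,
multi-object scenes at different depths, a thin disk for tracking, and
an upward-spiral motion path. All phantoms are deterministic and
refuse to silently clip against the grid.
"""

from __future__ import annotations

import numpy as np

from .core_model import VolumeGrid, VolumeImage

__all__ = [
    "letter_phantom",
    "two_depth_scene",
    "disk_phantom",
    "spiral_trajectory",
    "point_target",
]

# aspect ratio (width / height) of the block letters
_LETTER_ASPECT = 0.7


def _letter_rects(letter: str, s: float):
    """Letter strokes as rectangles (x0, x1, y0, y1) in a unit-height box
    of width `_LETTER_ASPECT`; ``s`` is the normalized stroke width.
    y runs upward from the letter's bottom."""
    w = _LETTER_ASPECT
    if letter == "U":
        return [
            (0.0, s, 0.0, 1.0),          # left stroke
            (w - s, w, 0.0, 1.0),        # right stroke
            (0.0, w, 0.0, s),            # bottom joint
        ]
    if letter == "B":
        return [
            (0.0, s, 0.0, 1.0),                          # spine
            (0.0, w, 1.0 - s, 1.0),                      # top bar
            (0.0, w, 0.5 - s / 2.0, 0.5 + s / 2.0),      # middle bar
            (0.0, w, 0.0, s),                            # bottom bar
            (w - s, w, 0.0, 1.0),                        # right bowls
        ]
    raise ValueError(f"unsupported letter {letter!r} (supported: B, U)")


def letter_phantom(letter: str, height_mm: float, stroke_mm: float,
                   depth_mm: float, grid: VolumeGrid,
                   center_mm: tuple | None = None) -> VolumeImage:
    """Binary block-letter raster in the single Z slice nearest ``depth_mm``.

    ``depth_mm`` is measured from the first grid plane. The letter is
    centred laterally on the grid unless ``center_mm = (cx, cy)`` is
    given. Errors if the letter's bounding box leaves the grid.
    """
    rects = _letter_rects(letter, stroke_mm / height_mm)
    width_mm = _LETTER_ASPECT * height_mm

    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    if center_mm is None:
        cx = 0.5 * (xs[0] + xs[-1])
        cy = 0.5 * (ys[0] + ys[-1])
    else:
        cx, cy = center_mm

    x0, x1 = cx - width_mm / 2.0, cx + width_mm / 2.0
    y0, y1 = cy - height_mm / 2.0, cy + height_mm / 2.0
    tol = 1e-9
    if x0 < xs[0] - tol or x1 > xs[-1] + tol or y0 < ys[0] - tol or y1 > ys[-1] + tol:
        raise ValueError(
            f"letter {letter!r} bounding box x[{x0:.2f},{x1:.2f}] "
            f"y[{y0:.2f},{y1:.2f}] mm exceeds the grid")
    z_target = zs[0] + depth_mm
    if z_target < zs[0] - tol or z_target > zs[-1] + tol:
        raise ValueError(f"depth {depth_mm} mm outside the grid Z range")
    iz = int(np.argmin(np.abs(zs - z_target)))

    # normalized in-letter coordinates of the lateral voxel centres
    u = (xs - x0) / height_mm
    v = (ys - y0) / height_mm
    uu, vv = np.meshgrid(u, v, indexing="xy")  # (ny, nx)
    mask = np.zeros_like(uu, dtype=bool)
    for (rx0, rx1, ry0, ry1) in rects:
        mask |= ((uu >= rx0 - tol) & (uu <= rx1 + tol)
                 & (vv >= ry0 - tol) & (vv <= ry1 + tol))

    arr = np.zeros((grid.nz, grid.ny, grid.nx))
    arr[iz][mask] = 1.0
    return VolumeImage.from_array(arr, grid)


def two_depth_scene(grid: VolumeGrid, spec: list) -> VolumeImage:
    """Union of letter phantoms at distinct depths.

    ``spec`` is a list of ``(letter, depth_mm, height_mm)``; stroke
    width defaults to a fifth of the letter height. Overlapping voxels
    take the maximum intensity.
    """
    depths = [d for (_, d, _) in spec]
    if len(set(depths)) != len(depths):
        raise ValueError(f"depths must be distinct, got {depths}")
    arr = np.zeros((grid.nz, grid.ny, grid.nx))
    for (letter, depth_mm, height_mm) in spec:
        ph = letter_phantom(letter, height_mm, height_mm / 5.0, depth_mm, grid)
        arr = np.maximum(arr, ph.as_array())
    return VolumeImage.from_array(arr, grid)


def disk_phantom(center_mm, diameter_mm: float, thickness_mm: float,
                 grid: VolumeGrid) -> VolumeImage:
    """Binary flat disk (axis along Z) centred at ``center_mm``.

    A zero diameter degenerates to the single nearest lateral voxel
    column over the slab thickness.
    """
    if diameter_mm < 0 or thickness_mm < 0:
        raise ValueError("diameter and thickness must be >= 0")
    cx, cy, cz = center_mm
    if not grid.contains_point(center_mm):
        raise ValueError(f"disk centre {center_mm} mm outside the grid")
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    tol = 1e-9
    r = diameter_mm / 2.0
    if (cx - r < xs[0] - tol or cx + r > xs[-1] + tol
            or cy - r < ys[0] - tol or cy + r > ys[-1] + tol):
        raise ValueError("disk exceeds the lateral grid extent")

    if thickness_mm == 0:
        z_ok = np.zeros(zs.size, dtype=bool)
        z_ok[int(np.argmin(np.abs(zs - cz)))] = True
    else:
        z_ok = np.abs(zs - cz) <= thickness_mm / 2.0 + tol
        if not z_ok.any():
            z_ok[int(np.argmin(np.abs(zs - cz)))] = True

    if diameter_mm == 0:
        lat = np.zeros((ys.size, xs.size), dtype=bool)
        ix, iy, _ = grid.nearest_voxel((cx, cy, zs[0]))
        lat[iy, ix] = True
    else:
        xx, yy = np.meshgrid(xs, ys, indexing="xy")
        lat = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2 + tol

    arr = np.zeros((grid.nz, grid.ny, grid.nx))
    arr[z_ok] = lat.astype(float)
    return VolumeImage.from_array(arr, grid)


def spiral_trajectory(center_mm, radius_mm: float, z_start_mm: float,
                      z_end_mm: float, n_turns: float, n_frames: int,
                      grid: VolumeGrid | None = None) -> np.ndarray:
    """Upward spiral path: (n_frames, 3) centre coordinates in mm.

    Frame k sits at angle ``2*pi*n_turns*k/(n_frames-1)`` on a cylinder
    of the given radius around the vertical axis through ``center_mm``,
    with Z linear from ``z_start_mm`` to ``z_end_mm`` (endpoints exact).
    If a grid is given, every point must lie inside it.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    cx, cy = center_mm[0], center_mm[1]
    k = np.arange(n_frames)
    ang = 2.0 * np.pi * n_turns * k / (n_frames - 1)
    pts = np.column_stack([
        cx + radius_mm * np.cos(ang),
        cy + radius_mm * np.sin(ang),
        np.linspace(z_start_mm, z_end_mm, n_frames),
    ])
    if grid is not None:
        bad = [int(i) for i in range(n_frames) if not grid.contains_point(pts[i])]
        if bad:
            raise ValueError(f"trajectory leaves the grid at frames {bad}")
    return pts


def point_target(coord_mm, grid: VolumeGrid) -> VolumeImage:
    """Single-voxel absorber: the voxel nearest ``coord_mm`` set to 1.

    Exact midpoints break deterministically toward the lower index.
    Stands in for the sub-wavelength point object used in calibration.
    """
    if not grid.contains_point(coord_mm):
        raise ValueError(f"point {coord_mm} mm outside the grid")
    ix, iy, iz = grid.nearest_voxel(coord_mm)
    values = np.zeros(grid.n_voxels)
    values[grid.linear_index((ix, iy, iz))] = 1.0
    return VolumeImage(values, grid)
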