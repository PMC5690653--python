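"""Synthetic voxel phantoms of tubule populations with known ground truth.

The generator emulates the imaging substrate this package analyses: a
micro-CT volume of a renal medullo-papillary complex containing populations
of roughly co-oriented, near-straight tubules (uriniferous tubules and vasa
recta) in two registered channels — an unstained channel in which mineralized
tubules are bright, and a contrast-stained channel in which a controlled
fraction of the same tubules reappear at identical geometry.  Every rendered
tubule is recorded in a ground-truth table so each downstream stage
(segmentation, diametry, co-localization, zonal histograms) can be validated
against known geometry.

Tubules are straight circular cylinders: either solid ("filled", a
mineral-occluded lumen) or hollow ("shell", a stained wall around a patent
lumen whose ends are capped so the lumen is an enclosed void).  Overlap
between tubules is forbidden via rejection sampling so the ground-truth
instance labeling is unambiguous.  Noise is additive Gaussian; CT artifacts
are out of scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .histomorphometry import assign_zone_positions
from .volume_io import LabelVolume, VoxelVolume

__all__ = [
    "PhantomSpec",
    "rasterize_cylinder",
    "generate_phantom",
    "paraboloid_mask",
    "rasterize_truth_labels",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = [
    "tubule_id",
    "true_diameter_um",
    "axis_z",
    "axis_y",
    "axis_x",
    "center_z_um",
    "center_y_um",
    "center_x_um",
    "length_um",
    "zone",
    "in_channel_a",
    "in_channel_b",
]

_MAX_PLACEMENT_ATTEMPTS = 1000


@dataclass
class PhantomSpec:
    """Parameters of a two-channel tubule phantom.

    Axis vectors use ``(z, y, x)`` component order to match the ``zyx`` array
    convention; the default main axis points along z, the scan's page axis.
    ``diameter_mixture`` is a list of ``(weight, mean_um, sd_um)`` Gaussian
    components; drawn diameters are truncated (redrawn) below two voxel
    widths, the smallest diameter the grid can represent.  ``coloc_fraction``
    of the channel-A tubules are duplicated into channel B at identical
    geometry.  ``length_um=None`` defaults to 60% of the axial grid extent.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_um: float = 5.0
    n_tubules: int = 50
    diameter_mixture: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(0.5, 25.0, 2.0), (0.5, 45.0, 4.0)]
    )
    main_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    tilt_jitter_deg: float = 10.0
    wall_mode: str = "filled"
    wall_thickness_um: float = 10.0
    intensity_fg: float = 800.0
    intensity_bg: float = 200.0
    noise_sd: float = 30.0
    coloc_fraction: float = 0.5
    organ_mask: str = "none"
    seed: int = 0
    length_um: float | None = None

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 1 for n in self.grid_shape):
            raise ValueError("grid_shape must be three positive ints")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")
        if self.n_tubules < 0:
            raise ValueError("n_tubules must be non-negative")
        w = sum(c[0] for c in self.diameter_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {w!r}")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if not 0.0 <= self.tilt_jitter_deg < 90.0:
            raise ValueError("tilt_jitter_deg must be in [0, 90)")
        if self.wall_mode not in ("filled", "shell"):
            raise ValueError("wall_mode must be 'filled' or 'shell'")
        if self.wall_mode == "shell" and self.wall_thickness_um <= 0:
            raise ValueError("wall_thickness_um must be positive in shell mode")
        if self.organ_mask not in ("none", "paraboloid"):
            raise ValueError("organ_mask must be 'none' or 'paraboloid'")
        if np.linalg.norm(self.main_axis) == 0:
            raise ValueError("main_axis must be nonzero")

    @property
    def min_diameter_um(self) -> float:
        return 2.0 * self.spacing_um


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length axis vector")
    return v / n


def _cylinder_bbox(grid_shape, spacing_um, p0, p1, radius_um):
    """Voxel-index bounding box (lo, hi exclusive) of a cylinder segment."""
    pad = radius_um + spacing_um
    lo_um = np.minimum(p0, p1) - pad
    hi_um = np.maximum(p0, p1) + pad
    lo = np.maximum(np.floor(lo_um / spacing_um).astype(int), 0)
    hi = np.minimum(np.ceil(hi_um / spacing_um).astype(int) + 1, np.asarray(grid_shape))
    return lo, hi


def _segment_distance_field(lo, hi, spacing_um, p0, p1, axis):
    """Distance from each voxel center in the bbox to the axis segment."""
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]) * spacing_um,
        np.arange(lo[1], hi[1]) * spacing_um,
        np.arange(lo[2], hi[2]) * spacing_um,
        indexing="ij",
    )
    length = float(np.linalg.norm(p1 - p0))
    t = (zz - p0[0]) * axis[0] + (yy - p0[1]) * axis[1] + (xx - p0[2]) * axis[2]
    t = np.clip(t, 0.0, length)
    dz = zz - (p0[0] + t * axis[0])
    dy = yy - (p0[1] + t * axis[1])
    dx = xx - (p0[2] + t * axis[2])
    return np.sqrt(dz * dz + dy * dy + dx * dx)


def rasterize_cylinder(
    grid_shape,
    spacing_um: float,
    center_um,
    axis,
    diameter_um: float,
    length_um: float,
    wall_mode: str = "filled",
    wall_thickness_um: float | None = None,
) -> np.ndarray:
    """Rasterize one cylinder into a boolean mask over the full grid.

    A voxel belongs to the mask when its center's distance to the cylinder's
    axis segment is ``<= diameter/2`` (filled) or within
    ``[diameter/2 - wall_thickness, diameter/2]`` (shell); shell cylinders are
    therefore capped at both ends, enclosing their lumen.  ``center_um`` is
    the segment midpoint in physical (z, y, x) coordinates; voxel ``(0,0,0)``
    center sits at physical origin 0.

    A cylinder entirely outside the grid yields an empty mask with a warning.
    """
    if diameter_um < 2.0 * spacing_um:
        raise ValueError(
            f"diameter {diameter_um} um below the 2-voxel minimum "
            f"({2.0 * spacing_um} um at {spacing_um} um spacing)"
        )
    if length_um <= 0:
        raise ValueError("length_um must be positive")
    u = _unit(axis)
    c = np.asarray(center_um, dtype=float)
    half = 0.5 * length_um
    p0, p1 = c - half * u, c + half * u
    r = 0.5 * diameter_um

    mask = np.zeros(tuple(int(n) for n in grid_shape), dtype=bool)
    lo, hi = _cylinder_bbox(grid_shape, spacing_um, p0, p1, r)
    if np.any(lo >= hi):
        warnings.warn("cylinder lies entirely outside the grid; empty mask", stacklevel=2)
        return mask
    dist = _segment_distance_field(lo, hi, spacing_um, p0, p1, u)
    if wall_mode == "filled":
        sub = dist <= r
    elif wall_mode == "shell":
        if wall_thickness_um is None or wall_thickness_um <= 0:
            raise ValueError("shell mode requires a positive wall_thickness_um")
        inner = max(r - wall_thickness_um, 0.0)
        sub = (dist <= r) & (dist >= inner)
    elif wall_mode == "lumen":
        if wall_thickness_um is None or wall_thickness_um <= 0:
            raise ValueError("lumen extraction requires a positive wall_thickness_um")
        sub = dist < max(r - wall_thickness_um, 0.0)
    else:
        raise ValueError(f"unknown wall_mode {wall_mode!r}")
    if not sub.any():
        warnings.warn("cylinder rasterized to an empty mask", stacklevel=2)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = sub
    return mask


def paraboloid_mask(grid_shape, spacing_um: float, main_axis=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Boolean organ mask shaped like a paraboloid of revolution.

    The paraboloid is aligned with the grid axis closest to ``main_axis``;
    its circular base fills the proximal face and its apex (the papillary
    tip) sits at the distal face: ``r(s)² = r_max² (1 - s/S)`` for axial
    position ``s``.
    """
    shape = tuple(int(n) for n in grid_shape)
    ax = int(np.argmax(np.abs(np.asarray(main_axis, dtype=float))))
    other = [i for i in range(3) if i != ax]
    n_ax = shape[ax]
    coords = [np.arange(n) * spacing_um for n in shape]
    grids = np.meshgrid(*coords, indexing="ij")
    s = grids[ax]
    centers = [(shape[i] - 1) * spacing_um / 2.0 for i in range(3)]
    r2 = (grids[other[0]] - centers[other[0]]) ** 2 + (grids[other[1]] - centers[other[1]]) ** 2
    r_max = 0.48 * min((shape[i] - 1) * spacing_um for i in other)
    extent = (n_ax - 1) * spacing_um
    radial2 = r_max**2 * np.clip(1.0 - s / extent, 0.0, 1.0)
    return r2 <= radial2


def _perturbed_axis(rng, main_axis, tilt_jitter_deg):
    """Unit vector within ``tilt_jitter_deg`` of the main axis."""
    u = _unit(main_axis)
    if tilt_jitter_deg == 0:
        return u.copy()
    # orthonormal frame around u
    helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(u, helper))
    e2 = np.cross(u, e1)
    tilt = math.radians(rng.uniform(0.0, tilt_jitter_deg))
    az = rng.uniform(0.0, 2.0 * math.pi)
    return math.cos(tilt) * u + math.sin(tilt) * (math.cos(az) * e1 + math.sin(az) * e2)


def _draw_diameter(rng, mixture, min_um):
    weights = np.array([c[0] for c in mixture])
    for _ in range(10_000):
        k = rng.choice(len(mixture), p=weights / weights.sum())
        d = rng.normal(mixture[k][1], mixture[k][2])
        if d >= min_um:
            return float(d)
    raise RuntimeError("could not draw a diameter above the 2-voxel minimum")


def generate_phantom(spec: PhantomSpec):
    """Generate a two-channel phantom and its ground-truth table.

    Returns
    -------
    channel_a : VoxelVolume
        All tubules rendered bright over background (the unstained/mineral
        channel).
    channel_b : VoxelVolume
        The duplicated co-localized subset (the stained channel); exactly
        ``round(coloc_fraction * n_tubules)`` tubules, at identical geometry.
    truth : DataFrame
        One row per tubule with true diameter, axis, centerline midpoint,
        length, zone, and channel membership.  Deterministic given the seed.

    Raises
    ------
    RuntimeError
        When a tubule cannot be placed without overlap within 1000 attempts;
        the message names the count achieved.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.grid_shape)
    sp = float(spec.spacing_um)
    u_main = _unit(spec.main_axis)

    organ = None
    if spec.organ_mask == "paraboloid":
        organ = paraboloid_mask(shape, sp, u_main)

    extent_um = np.array([(n - 1) * sp for n in shape])
    axial_extent = float(abs(extent_um @ np.abs(u_main)))
    length_um = spec.length_um if spec.length_um is not None else 0.6 * axial_extent

    occupied = np.zeros(shape, dtype=bool)
    label_a = np.zeros(shape, dtype=np.uint32)
    rows = []
    for tid in range(1, spec.n_tubules + 1):
        placed = False
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            d_um = _draw_diameter(rng, spec.diameter_mixture, spec.min_diameter_um)
            axis = _perturbed_axis(rng, u_main, spec.tilt_jitter_deg)
            r = 0.5 * d_um
            margin = r + 2.0 * sp
            half_span = 0.5 * length_um * np.abs(axis) + margin
            lo_c = half_span
            hi_c = extent_um - half_span
            if np.any(hi_c <= lo_c):
                raise RuntimeError(
                    f"grid too small for tubule of length {length_um:.0f} um; "
                    f"placed {tid - 1} of {spec.n_tubules}"
                )
            center = rng.uniform(lo_c, hi_c)
            mask = rasterize_cylinder(
                shape, sp, center, axis, d_um, length_um,
                wall_mode=spec.wall_mode,
                wall_thickness_um=spec.wall_thickness_um,
            )
            if not mask.any():
                continue
            if organ is not None:
                # tubule must lie wholly inside the organ (use the full
                # cylinder, not just the wall, so lumina stay inside too)
                full = (
                    mask
                    if spec.wall_mode == "filled"
                    else rasterize_cylinder(shape, sp, center, axis, d_um, length_um, "filled")
                )
                if np.any(full & ~organ):
                    continue
            if _touches_occupied(mask, occupied):
                continue
            occupied |= mask
            label_a[mask] = tid
            rows.append(
                {
                    "tubule_id": tid,
                    "true_diameter_um": d_um,
                    "axis_z": axis[0],
                    "axis_y": axis[1],
                    "axis_x": axis[2],
                    "center_z_um": center[0],
                    "center_y_um": center[1],
                    "center_x_um": center[2],
                    "length_um": length_um,
                }
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place tubule {tid} without overlap after "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts; placed {tid - 1} of {spec.n_tubules}"
            )

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS[:9])
    if len(truth):
        s = (
            truth["center_z_um"] * u_main[0]
            + truth["center_y_um"] * u_main[1]
            + truth["center_x_um"] * u_main[2]
        )
        truth["zone"] = assign_zone_positions(s.to_numpy(), 0.0, axial_extent, n_zones=3)
    else:
        truth["zone"] = pd.Series(dtype=object)
    truth["in_channel_a"] = True

    n_coloc = int(round(spec.coloc_fraction * spec.n_tubules))
    coloc_ids = set(rng.permutation(np.arange(1, spec.n_tubules + 1))[:n_coloc].tolist())
    truth["in_channel_b"] = truth["tubule_id"].isin(coloc_ids)

    fg_a = label_a > 0
    fg_b = np.isin(label_a, list(coloc_ids)) if coloc_ids else np.zeros(shape, dtype=bool)

    def _render(fg):
        img = np.full(shape, spec.intensity_bg, dtype=np.float64)
        img[fg] = spec.intensity_fg
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=shape)
        return np.clip(img, 0, np.iinfo(np.uint16).max).astype(np.uint16)

    vol_a = VoxelVolume(data=_render(fg_a), spacing_um=(sp, sp, sp))
    vol_b = VoxelVolume(data=_render(fg_b), spacing_um=(sp, sp, sp))
    return vol_a, vol_b, truth


def _touches_occupied(mask: np.ndarray, occupied: np.ndarray) -> bool:
    """True if mask overlaps or 26-touches already-occupied voxels.

    A one-voxel clearance keeps distinct tubules in separate connected
    components under 26-connectivity.
    """
    idx = np.argwhere(mask)
    if idx.size == 0:
        return True
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = np.minimum(idx.max(axis=0) + 2, mask.shape)
    sub = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    occ = occupied[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    if not occ.any():
        return False
    from scipy.ndimage import binary_dilation

    grown = binary_dilation(sub, structure=np.ones((3, 3, 3), dtype=bool))
    return bool(np.any(grown & occ))


def rasterize_truth_labels(
    truth: pd.DataFrame,
    grid_shape,
    spacing_um: float,
    wall_mode: str = "filled",
    wall_thickness_um: float | None = None,
    channel: str = "a",
    region: str | None = None,
) -> LabelVolume:
    """Re-render the ground-truth tubules as an instance label volume.

    ``region`` overrides ``wall_mode`` per tubule: pass ``"lumen"`` to get the
    enclosed lumen of shell tubules (the void channel's ground truth) or
    ``"filled"`` for the outer envelope.  ``channel`` selects which channel's
    tubules ("a" or "b") are rendered.
    """
    shape = tuple(int(n) for n in grid_shape)
    labels = np.zeros(shape, dtype=np.uint32)
    mode = region if region is not None else wall_mode
    col = f"in_channel_{channel}"
    for row in truth.itertuples(index=False):
        if col in truth.columns and not getattr(row, col):
            continue
        mask = rasterize_cylinder(
            shape,
            spacing_um,
            (row.center_z_um, row.center_y_um, row.center_x_um),
            (row.axis_z, row.axis_y, row.axis_x),
            row.true_diameter_um,
            row.length_um,
            wall_mode=mode,
            wall_thickness_um=wall_thickness_um,
        )
        labels[mask] = row.tubule_id
    return LabelVolume(labels=labels, spacing_um=(spacing_um,) * 3)
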