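"""Tilt/pitch restriction analysis from oriented-sample ¹⁵N shifts.

Each labeled amide contributes one measured shift with an error band; the
(tilt, pitch) grid is scanned with the motionally averaged forward model
and every orientation whose predicted shift falls inside the band is marked
compatible.  Intersecting the per-restraint maps and enumerating connected
regions (8-connectivity, with wrap-around on the periodic pitch axis)
yields the candidate helix topologies.  Note the intrinsic degeneracy of
the observable under field inversion, shift(τ, ρ) = shift(180°−τ, ρ+180°):
degenerate solution pairs are reported, not collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import constants as C
from .csa import CSATensor, MotionModel, Orientation, amide_frame, averaged_shift_surface
from .helix import HelixModel


@dataclass(frozen=True)
class ShiftRestraint:
    """Measured ¹⁵N shift of one labeled residue with its half-width error."""

    residue_index: int
    observed: float
    error: float

    def __post_init__(self):
        if self.error <= 0:
            raise ValueError("restraint error must be positive")


@dataclass
class CompatibilityMap:
    """Boolean (tilt × pitch) grid of orientations compatible with restraints."""

    tilt_grid: np.ndarray
    pitch_grid: np.ndarray
    mask: np.ndarray
    restraint_ids: list = field(default_factory=list)

    def __post_init__(self):
        if self.mask.shape != (self.tilt_grid.size, self.pitch_grid.size):
            raise ValueError("mask shape must match (tilt, pitch) grids")


@dataclass
class SolutionRegion:
    """One connected compatible region on the (tilt, pitch) grid."""

    label: str
    cells: list            # (tilt, pitch) degree pairs
    centroid: Orientation  # circular mean on the pitch axis
    area: float            # deg²

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def make_grids(grid_step: float) -> tuple[np.ndarray, np.ndarray]:
    """Tilt grid [0, 180] (inclusive) and periodic pitch grid [0, 360)."""
    if not (np.isclose(180.0 % grid_step, 0) or np.isclose(180.0 % grid_step, grid_step)):
        raise ValueError("grid_step must divide 180")
    tilt = np.arange(0.0, 180.0 + grid_step / 2, grid_step)
    pitch = np.arange(0.0, 360.0, grid_step)
    return tilt, pitch


def scan_restraint(model: HelixModel, tensor: CSATensor, motion: MotionModel,
                   restraint: ShiftRestraint, grid_step: float = 1.0) -> CompatibilityMap:
    """Compatibility map of one restraint over the full (tilt, pitch) grid.

    A cell is compatible iff |averaged_shift − observed| <= error.
    """
    if not 1 <= restraint.residue_index <= len(model):
        raise ValueError(f"residue {restraint.residue_index} not in model "
                         f"(1..{len(model)})")
    frame = amide_frame(model, restraint.residue_index)
    tilt_grid, pitch_grid = make_grids(grid_step)
    surface = averaged_shift_surface(frame, tensor, tilt_grid, pitch_grid, motion)
    mask = np.abs(surface - restraint.observed) <= restraint.error
    return CompatibilityMap(tilt_grid=tilt_grid, pitch_grid=pitch_grid,
                            mask=mask, restraint_ids=[restraint.residue_index])


def intersect_maps(maps: list[CompatibilityMap]) -> CompatibilityMap:
    """Cell-wise AND of compatibility maps sharing one grid."""
    if not maps:
        raise ValueError("need at least one map")
    first = maps[0]
    mask = first.mask.copy()
    ids = list(first.restraint_ids)
    for m in maps[1:]:
        if (m.tilt_grid.shape != first.tilt_grid.shape
                or not np.allclose(m.tilt_grid, first.tilt_grid)
                or not np.allclose(m.pitch_grid, first.pitch_grid)):
            raise ValueError("compatibility maps are on different grids")
        mask &= m.mask
        ids.extend(m.restraint_ids)
    return CompatibilityMap(tilt_grid=first.tilt_grid, pitch_grid=first.pitch_grid,
                            mask=mask, restraint_ids=ids)


def _label_with_wraparound(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected component labels with wrap-around on the pitch (axis 1)."""
    structure = np.ones((3, 3), dtype=bool)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0 or mask.shape[1] < 2:
        return labels, n

    # merge labels touching across the pitch seam (columns -1 and 0)
    parent = list(range(n + 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    left, right = labels[:, 0], labels[:, -1]
    n_rows = mask.shape[0]
    for i in range(n_rows):
        if right[i] == 0:
            continue
        for di in (-1, 0, 1):
            j = i + di
            if 0 <= j < n_rows and left[j] != 0:
                union(right[i], left[j])

    remap = np.zeros(n + 1, dtype=int)
    next_label = 0
    for lab in range(1, n + 1):
        root = find(lab)
        if remap[root] == 0:
            next_label += 1
            remap[root] = next_label
        remap[lab] = remap[root]
    return remap[labels], next_label


_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def _roman(k: int) -> str:
    return _ROMAN[k] if k < len(_ROMAN) else str(k + 1)


def find_regions(cmap: CompatibilityMap, min_area: float = 3.0) -> list[SolutionRegion]:
    """Connected compatible regions with area >= ``min_area`` deg².

    Regions are sorted by area (descending) and labeled I, II, ...;
    the centroid pitch is a circular mean.
    """
    labels, n = _label_with_wraparound(cmap.mask)
    step_t = cmap.tilt_grid[1] - cmap.tilt_grid[0] if cmap.tilt_grid.size > 1 else 1.0
    step_p = cmap.pitch_grid[1] - cmap.pitch_grid[0] if cmap.pitch_grid.size > 1 else 1.0
    cell_area = float(step_t * step_p)

    regions = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        area = rows.size * cell_area
        if area < min_area:
            continue
        tilts = cmap.tilt_grid[rows]
        pitches = cmap.pitch_grid[cols]
        rad = np.deg2rad(pitches)
        mean_pitch = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0
        regions.append(SolutionRegion(
            label="", cells=list(zip(tilts.tolist(), pitches.tolist())),
            centroid=Orientation(tilt=float(tilts.mean()), pitch=float(mean_pitch)),
            area=area))
    regions.sort(key=lambda r: -r.area)
    for k, r in enumerate(regions):
        r.label = _roman(k)
    return regions


def classify_topology(region: SolutionRegion,
                      in_plane_range: tuple = C.IN_PLANE_TILT_RANGE,
                      tm_max: float = C.TRANSMEMBRANE_TILT_MAX) -> str:
    """Classify a solution region as in-plane, transmembrane or tilted."""
    tilt = region.centroid.tilt
    if in_plane_range[0] <= tilt <= in_plane_range[1]:
        return "in-plane"
    if tilt <= tm_max or tilt >= 180.0 - tm_max:
        return "transmembrane"
    return "tilted"


def degeneracy_classes(regions: list[SolutionRegion],
                       tol: float = 5.0) -> list[tuple[SolutionRegion, ...]]:
    """Group regions into field-inversion degeneracy classes.

    The oriented-sample shift is invariant under B̂ → −B̂, which maps the
    orientation (tilt, pitch) to (180°−tilt, pitch+180°).  Solution regions
    therefore come in spectroscopically indistinguishable pairs (a region
    straddling tilt = 90° can be self-paired).  Classes are returned largest
    first; the number of classes is the number of distinguishable solutions.
    """
    unused = list(regions)
    classes = []
    while unused:
        r = unused.pop(0)
        mate = None
        for s in unused:
            d_tilt = abs((180.0 - r.centroid.tilt) - s.centroid.tilt)
            d_pitch = abs((r.centroid.pitch + 180.0 - s.centroid.pitch + 180.0) % 360.0 - 180.0)
            if d_tilt <= tol and d_pitch <= tol:
                mate = s
                break
        if mate is not None:
            unused.remove(mate)
            classes.append((r, mate))
        else:
            classes.append((r,))
    classes.sort(key=lambda c: -max(x.area for x in c))
    return classes


def restriction_analysis(model: HelixModel, restraints: list[ShiftRestraint],
                         tensor: CSATensor | None = None,
                         motion: MotionModel | None = None,
                         grid_step: float = 1.0,
                         min_area: float = 3.0) -> tuple[CompatibilityMap, list[SolutionRegion]]:
    """Full pipeline: scan every restraint, intersect, enumerate regions."""
    tensor = tensor or CSATensor()
    motion = motion or MotionModel()
    maps = [scan_restraint(model, tensor, motion, r, grid_step) for r in restraints]
    combined = intersect_maps(maps)
    return combined, find_regions(combined, min_area=min_area)
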