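"""Leaflet assignment, area-per-lipid maps, lipid tail order and z-density.

The membrane is a planar patch with its normal fixed to +z.  Lipids are
anchored by their phosphate atom: leaflets are split by the sign of the
phosphate z relative to the global phosphate mean, and the midplane is
the mean of the two leaflet planes.

Area per lipid (APL) is computed as an exact periodic 2D Voronoi
partition of the phosphate XY positions (each cell area is the lipid's
area; cells tile the box exactly, which is asserted on every call).
Local packing defects induced by a bound peptide appear as elevated APL
near the binding site.

The nematic order parameter of one lipid is S = <(3 cos^2 theta - 1)/2>
over all consecutive tail-bead bond vectors of all its chains, where
theta is the angle between a bond vector and the membrane normal:
S = 1 for tails along the normal, 0 at the magic angle (54.74 deg) or in
an isotropic ensemble, -0.5 for tails lying in the membrane plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi, cKDTree

from .errors import InputError
from .model import Topology, TrajectoryFrame, minimum_image_displacement

__all__ = [
    "LeafletAssignment",
    "APLMap",
    "OrderParameterResult",
    "NearFarOrder",
    "assign_leaflets",
    "area_per_lipid",
    "nematic_order",
    "nematic_order_frame",
    "near_far_histogram",
    "z_density",
]


@dataclass(frozen=True)
class LeafletAssignment:
    leaflet_of: dict[int, str]       # lipid molecule_id -> upper | lower
    midplane_z: float                # A
    degenerate: bool = False

    def lipids(self, leaflet: str) -> list[int]:
        return [lid for lid, l in self.leaflet_of.items() if l == leaflet]


@dataclass(frozen=True)
class APLMap:
    """Per-lipid Voronoi areas (A^2) for one leaflet plus a raster map."""

    area_of: dict[int, float]
    leaflet: str
    grid: np.ndarray                 # (nx_bins, ny_bins) of areas; NaN = peptide
    grid_bin: float                  # A
    box_xy: tuple[float, float]

    @property
    def total_area(self) -> float:
        return float(sum(self.area_of.values()))


@dataclass(frozen=True)
class OrderParameterResult:
    lipid_id: int
    S: float                         # in [-0.5, 1]
    mean_tilt_deg: float


@dataclass(frozen=True)
class NearFarOrder:
    edges: np.ndarray
    hist_near: np.ndarray
    hist_far: np.ndarray
    mean_near: float
    mean_far: float
    n_near: int
    n_far: int


def assign_leaflets(frame: TrajectoryFrame, topology: Topology) -> LeafletAssignment:
    """Split lipids into leaflets by phosphate z vs the global phosphate mean."""
    lipid_ids = topology.lipid_ids
    if len(lipid_ids) < 2:
        raise InputError("need at least 2 lipids to assign leaflets")
    phos = topology.phosphate_indices(lipid_ids)
    z = frame.coords[phos, 2]
    dz = z - z.mean()
    upper = dz >= 0
    leaflet_of = {
        lid: ("upper" if u else "lower") for lid, u in zip(lipid_ids, upper)
    }
    n_up, n_lo = int(upper.sum()), int((~upper).sum())
    degenerate = False
    if n_up == 0 or n_lo == 0 or abs(np.ptp(z)) < 2.0:
        degenerate = True
        warnings.warn(
            "degenerate bilayer: all phosphates on one side; treating as a "
            "single leaflet",
            stacklevel=2,
        )
        leaflet_of = {lid: "upper" for lid in lipid_ids}
        midplane = float(z.mean())
    else:
        midplane = float((z[upper].mean() + z[~upper].mean()) / 2.0)
    return LeafletAssignment(leaflet_of=leaflet_of, midplane_z=midplane,
                             degenerate=degenerate)


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _periodic_voronoi_areas(seeds_xy: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    """Exact per-seed cell areas of the periodic 2D Voronoi tessellation."""
    n = len(seeds_xy)
    shifts = np.array([[i, j] for i in (-1, 0, 1) for j in (-1, 0, 1)
                       if (i, j) != (0, 0)])
    tiled = np.vstack([seeds_xy] + [seeds_xy + s * box_xy for s in shifts])
    vor = Voronoi(tiled)
    areas = np.empty(n)
    for k in range(n):
        region = vor.regions[vor.point_region[k]]
        if -1 in region or len(region) == 0:  # pragma: no cover - padded
            raise InputError("unbounded Voronoi cell despite periodic padding")
        areas[k] = _polygon_area(vor.vertices[region])
    return areas


def area_per_lipid(
    frame: TrajectoryFrame,
    topology: Topology,
    assignment: LeafletAssignment | None = None,
    leaflet: str = "upper",
    peptide_seeds: bool = False,
    peptide_band: float = 10.0,
    grid_bin: float = 2.0,
) -> APLMap:
    """Periodic Voronoi area per lipid for one leaflet.

    With ``peptide_seeds`` the heavy atoms of membrane-inserted peptides
    (on the leaflet's side, within ``peptide_band`` A of the leaflet
    phosphate plane) are added as area-excluding seeds; their cells are
    discarded from the lipid areas, so the partition then covers less
    than the box.  By default the partition is exact and the areas sum to
    the box XY area.
    """
    assignment = assignment or assign_leaflets(frame, topology)
    lipids = assignment.lipids(leaflet)
    if len(lipids) < 4:
        raise InputError(f"leaflet {leaflet!r} has fewer than 4 lipids")
    box_xy = frame.box[:2]
    phos = topology.phosphate_indices(lipids)
    xy = np.mod(frame.coords[phos, :2], box_xy)

    seeds = xy
    n_pep = 0
    if peptide_seeds and topology.peptide_ids:
        pep_idx = topology.select(kind="peptide", heavy=True)
        z = frame.coords[pep_idx, 2]
        plane = frame.coords[phos, 2].mean()
        side = 1.0 if plane >= assignment.midplane_z else -1.0
        keep = (side * (z - assignment.midplane_z) > 0) & \
            (np.abs(z - plane) <= peptide_band)
        pep_xy = np.mod(frame.coords[pep_idx[keep], :2], box_xy)
        n_pep = len(pep_xy)
        if n_pep:
            seeds = np.vstack([xy, pep_xy])

    # deterministically separate coincident XY seeds
    rounded = np.round(seeds / 1e-4).astype(np.int64)
    _, first, counts = np.unique(rounded, axis=0, return_index=True,
                                 return_counts=True)
    if np.any(counts > 1):
        warnings.warn("coincident XY seeds perturbed by 1e-6 A", stacklevel=2)
        seen: dict[tuple, int] = {}
        for i, key in enumerate(map(tuple, rounded)):
            k = seen.get(key, 0)
            if k:
                ang = 2.399963 * (i + k)  # golden-angle spread
                seeds[i] = seeds[i] + 1e-6 * k * np.array(
                    [np.cos(ang), np.sin(ang)]
                )
            seen[key] = k + 1

    areas = _periodic_voronoi_areas(seeds, np.asarray(box_xy, float))
    box_area = float(box_xy[0] * box_xy[1])
    if not np.isclose(areas.sum(), box_area, rtol=1e-6):
        raise InputError(
            f"Voronoi partition lost area: {areas.sum():.6f} != {box_area:.6f}"
        )
    area_of = {lid: float(a) for lid, a in zip(lipids, areas[: len(lipids)])}

    # raster: nearest periodic seed, peptide cells -> NaN
    nx = max(int(np.floor(box_xy[0] / grid_bin)), 1)
    ny = max(int(np.floor(box_xy[1] / grid_bin)), 1)
    gx = (np.arange(nx) + 0.5) * box_xy[0] / nx
    gy = (np.arange(ny) + 0.5) * box_xy[1] / ny
    centers = np.stack(np.meshgrid(gx, gy, indexing="ij"), axis=-1).reshape(-1, 2)
    shifts = np.array([[i, j] for i in (-1, 0, 1) for j in (-1, 0, 1)])
    tiled = np.vstack([seeds + s * np.asarray(box_xy) for s in shifts])
    owner = cKDTree(tiled).query(centers)[1] % len(seeds)
    values = np.concatenate([areas[: len(lipids)], np.full(n_pep, np.nan)])
    grid = values[owner].reshape(nx, ny)
    return APLMap(area_of=area_of, leaflet=leaflet, grid=grid,
                  grid_bin=grid_bin, box_xy=(float(box_xy[0]), float(box_xy[1])))


def nematic_order(
    frame: TrajectoryFrame, topology: Topology, lipid_id: int
) -> OrderParameterResult:
    """Order parameter of one lipid's tail bonds against the +z normal."""
    pairs = topology.tail_bond_pairs(lipid_id)
    if len(pairs) == 0:
        raise InputError(f"lipid {lipid_id} has no tail bonds")
    vec = frame.coords[pairs[:, 1]] - frame.coords[pairs[:, 0]]
    norms = np.linalg.norm(vec, axis=1)
    if np.any(norms < 1e-12):
        raise InputError(f"lipid {lipid_id} has zero-length tail bonds")
    cos_t = vec[:, 2] / norms
    s = float(np.mean((3.0 * cos_t**2 - 1.0) / 2.0))
    tilt = float(np.degrees(np.mean(np.arccos(np.abs(np.clip(cos_t, -1, 1))))))
    return OrderParameterResult(lipid_id=lipid_id, S=s, mean_tilt_deg=tilt)


def nematic_order_frame(
    frame: TrajectoryFrame,
    topology: Topology,
    lipid_ids: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Per-lipid order parameters as a DataFrame (lipid_id, species, S, tilt)."""
    ids = topology.lipid_ids if lipid_ids is None else list(lipid_ids)
    rows = []
    for lid in ids:
        r = nematic_order(frame, topology, lid)
        rows.append((lid, topology.lipid_species[lid], r.S, r.mean_tilt_deg))
    return pd.DataFrame(rows, columns=["lipid_id", "species", "S", "mean_tilt_deg"])


def near_far_histogram(
    frame: TrajectoryFrame,
    topology: Topology,
    order: Mapping[int, float] | pd.DataFrame | None = None,
    near_cutoff: float = 10.0,
    far_cutoff: float = 25.0,
    bins: np.ndarray | int = 30,
) -> NearFarOrder:
    """Order-parameter histograms for lipids near vs far from the peptide.

    A lipid is "near" when the lateral (XY, minimum-image) distance from
    its phosphate to the closest peptide heavy atom is <= near_cutoff and
    "far" when >= far_cutoff; intermediate lipids are excluded.  Without
    any peptide all lipids count as far.
    """
    if not 0 < near_cutoff < far_cutoff:
        raise InputError("cutoffs must satisfy 0 < near < far")
    if order is None:
        order = {r.lipid_id: r.S
                 for r in nematic_order_frame(frame, topology).itertuples()}
    elif isinstance(order, pd.DataFrame):
        order = dict(zip(order["lipid_id"], order["S"]))
    lids = list(order)
    phos = topology.phosphate_indices(lids)
    pep_idx = topology.select(kind="peptide", heavy=True)
    if len(pep_idx) == 0:
        dmin = np.full(len(lids), np.inf)
    else:
        d = minimum_image_displacement(
            frame.coords[phos, None, :2] - frame.coords[None, pep_idx, :2],
            frame.box[:2],
        )
        dmin = np.linalg.norm(d, axis=-1).min(axis=1)
    s_vals = np.array([order[l] for l in lids])
    near = s_vals[dmin <= near_cutoff]
    far = s_vals[dmin >= far_cutoff]
    if len(near) == 0 or len(far) == 0:
        warnings.warn("empty near or far partition", stacklevel=2)
    edges = (np.asarray(bins, float) if np.ndim(bins)
             else np.linspace(-0.5, 1.0, int(bins) + 1))
    hist_near = np.histogram(near, bins=edges)[0]
    hist_far = np.histogram(far, bins=edges)[0]
    return NearFarOrder(
        edges=edges, hist_near=hist_near, hist_far=hist_far,
        mean_near=float(near.mean()) if len(near) else float("nan"),
        mean_far=float(far.mean()) if len(far) else float("nan"),
        n_near=len(near), n_far=len(far),
    )


def z_density(
    frames: Sequence[TrajectoryFrame],
    topology: Topology,
    selection: np.ndarray,
    bin_width: float = 1.0,
    z_range: tuple[float, float] = (-60.0, 60.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of selected atoms' z minus the per-frame midplane.

    Returns (bin_edges, counts) pooled over frames; ``selection`` holds
    0-based atom indices (e.g. phosphates, or a peptide's heavy atoms).
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise InputError("empty selection")
    frames = list(frames)
    edges = np.arange(z_range[0], z_range[1] + bin_width / 2, bin_width)
    counts = np.zeros(len(edges) - 1)
    for f in frames:
        if topology.lipid_ids:
            mid = assign_leaflets(f, topology).midplane_z
        else:
            mid = 0.0
        counts += np.histogram(f.coords[selection, 2] - mid, bins=edges)[0]
    return edges, counts
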