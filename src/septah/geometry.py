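"""Helix bending profiles, global curvature fit and backbone helicity.

Bending is quantified the way helix-axis tools do it: a smooth axis
polyline is built from sliding-window centroids of the CA positions, and
at each axis point the local bending angle is the turning angle between
two chords of fixed arc length ("side", default 7.2 A -- roughly the CA-CA
chord across one helical turn) anchored at that point.  A straight axis
gives 0 degrees; for an axis on a circular arc of radius R the angle is
2*arcsin(side/2R) and the associated radius of curvature is recovered as
side / angle.

The overall curvature of a bent peptide is measured independently by
projecting the CA positions onto their PCA best-fit plane and fitting a
circle (algebraic fit refined geometrically).

Helicity uses a dihedral-basin criterion: a residue is helical in a frame
when (phi, psi) falls in [-100, -30] x [-80, -5] degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DegenerateGeometryError, InputError
from .model import Topology, TrajectoryFrame

__all__ = [
    "BendingParams",
    "BendingProfile",
    "CurvatureFit",
    "helix_axis_points",
    "local_bending_angles",
    "bending_profile",
    "bending_heatmap_table",
    "fit_circle_pca",
    "helicity_profile",
    "dihedral",
]

PHI_RANGE = (-100.0, -30.0)
PSI_RANGE = (-80.0, -5.0)


@dataclass(frozen=True)
class BendingParams:
    """side: chord arc length (A); axis_window: residues per centroid.

    ``smooth_passes`` extra same-length averaging passes damp the residual
    helical ripple of the centroid axis (a 4-residue window spans 400 deg
    of twist, not exactly one turn, leaving a ~0.26 A wobble that would
    otherwise leak into the bending angles); they do not change the axis
    point count.
    """

    side: float = 7.2        # chord arc length, A
    axis_window: int = 4     # residues per axis centroid
    smooth_passes: int = 2

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise InputError("side must be positive")
        if self.axis_window < 3:
            raise InputError("axis_window must be >= 3")
        if self.smooth_passes < 0:
            raise InputError("smooth_passes must be >= 0")


@dataclass(frozen=True)
class BendingProfile:
    """Per-axis-point bending angles (deg, 0 = straight) and radii (A).

    Axis points are anchored at the first residue of their centroid
    window; points closer than ``side`` (arc length) to either end of the
    axis cannot carry a full chord pair and hold NaN.  ``radius_A`` is
    side / angle_in_radians, infinite where the angle is zero.
    """

    angles_deg: np.ndarray
    radius_A: np.ndarray
    anchor_residues: np.ndarray


@dataclass(frozen=True)
class CurvatureFit:
    radius: float            # A
    center: np.ndarray       # 3-vector, A
    normal: np.ndarray       # unit plane normal
    rms_residual: float      # in-plane RMS distance to the circle, A


def helix_axis_points(
    calpha_coords: np.ndarray, params: BendingParams | None = None
) -> np.ndarray:
    """Axis polyline: point i = centroid of CA[i .. i+window-1]."""
    params = params or BendingParams()
    ca = np.asarray(calpha_coords, dtype=float)
    w = params.axis_window
    if len(ca) < w + 1:
        raise InputError(f"need at least {w + 1} residues for the axis")
    kernel = np.ones(w) / w
    out = np.stack(
        [np.convolve(ca[:, k], kernel, mode="valid") for k in range(3)], axis=1
    )
    for _ in range(params.smooth_passes):
        smoothed = np.empty_like(out)
        n = len(out)
        half = w // 2
        for i in range(n):
            lo = max(0, i - half + (0 if w % 2 else 1))
            hi = min(n, i + half + 1)
            smoothed[i] = out[lo:hi].mean(axis=0)
        out = smoothed
    return out


def local_bending_angles(
    axis: np.ndarray, params: BendingParams | None = None,
    anchor_offset: int = 1,
) -> BendingProfile:
    """Chord-turning bending angle at every axis point.

    At axis point p, the chord endpoints are taken at arc positions
    +/- side along the polyline (linear interpolation between axis
    points); the bending angle is 180 deg minus the interior angle of the
    two chords, so a straight axis scores 0.
    """
    params = params or BendingParams()
    axis = np.asarray(axis, dtype=float)
    if len(axis) < 3:
        raise InputError("axis needs at least 3 points")
    seg = np.linalg.norm(np.diff(axis, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] < 2 * params.side:
        raise InputError(
            f"axis arc length {s[-1]:.2f} A shorter than 2*side = {2 * params.side} A"
        )

    def interp(arc: float) -> np.ndarray:
        return np.array([np.interp(arc, s, axis[:, k]) for k in range(3)])

    angles = np.full(len(axis), np.nan)
    for i, si in enumerate(s):
        if si - params.side < 0 or si + params.side > s[-1]:
            continue
        p = axis[i]
        u = interp(si - params.side) - p
        v = interp(si + params.side) - p
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-12 or nv < 1e-12:
            continue
        interior = np.degrees(
            np.arccos(np.clip(u @ v / (nu * nv), -1.0, 1.0))
        )
        angles[i] = 180.0 - interior
    with np.errstate(divide="ignore", invalid="ignore"):
        radius = params.side / np.radians(angles)
    radius[angles == 0] = np.inf
    anchors = np.arange(anchor_offset, anchor_offset + len(axis))
    return BendingProfile(angles_deg=angles, radius_A=radius,
                          anchor_residues=anchors)


def bending_profile(
    frame: TrajectoryFrame,
    topology: Topology,
    peptide_id: int,
    params: BendingParams | None = None,
) -> BendingProfile:
    """Bending profile of one peptide in one frame."""
    params = params or BendingParams()
    ca = frame.coords[topology.calpha_indices(peptide_id)]
    axis = helix_axis_points(ca, params)
    return local_bending_angles(axis, params)


def bending_heatmap_table(
    frames: Sequence[TrajectoryFrame],
    topology: Topology,
    peptide_id: int,
    params: BendingParams | None = None,
) -> pd.DataFrame:
    """time x axis-point matrix of bending angles (deg); one row per frame."""
    frames = list(frames)
    if not frames:
        raise InputError("no frames")
    rows = []
    times = []
    anchors = None
    for f in frames:
        prof = bending_profile(f, topology, peptide_id, params)
        rows.append(prof.angles_deg)
        anchors = prof.anchor_residues
        times.append(f.time_ns)
    df = pd.DataFrame(np.array(rows),
                      index=pd.Index(times, name="time_ns"),
                      columns=pd.Index(anchors, name="anchor_residue"))
    return df


# ---------------------------------------------------------------------------
# circle fit


def fit_circle_pca(calpha_coords: np.ndarray) -> CurvatureFit:
    """Circle fit to points projected onto their PCA best-fit plane.

    The plane is spanned by the two leading principal directions of the
    centered coordinates; the in-plane circle is fitted algebraically
    (Kasa) and refined geometrically.  Collinear input raises
    :class:`DegenerateGeometryError` (the radius is unbounded).
    """
    pts = np.asarray(calpha_coords, dtype=float)
    if len(pts) < 4:
        raise InputError("need at least 4 points for a circle fit")
    centroid = pts.mean(axis=0)
    q = pts - centroid
    _, svals, vt = np.linalg.svd(q, full_matrices=False)
    if svals[0] < 1e-12 or svals[1] / svals[0] < 1e-8:
        raise DegenerateGeometryError(
            "points are collinear; circle radius is unbounded"
        )
    e1, e2, normal = vt[0], vt[1], vt[2]
    x = q @ e1
    y = q @ e2

    # Kasa algebraic fit: x^2 + y^2 = 2 a x + 2 b y + c
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    (a0, b0, c0), *_ = np.linalg.lstsq(A, b, rcond=None)
    r0 = np.sqrt(max(c0 + a0**2 + b0**2, 1e-300))

    def residual(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    sol = least_squares(residual, x0=[a0, b0, r0], method="lm")
    cx, cy, radius = sol.x
    res = residual(sol.x)
    center = centroid + cx * e1 + cy * e2
    return CurvatureFit(
        radius=float(abs(radius)),
        center=center,
        normal=normal / np.linalg.norm(normal),
        rms_residual=float(np.sqrt(np.mean(res**2))),
    )


# ---------------------------------------------------------------------------
# helicity


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees for four points."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    return float(np.degrees(np.arctan2(np.cross(b1n, v) @ w, v @ w)))


def helicity_profile(
    frames: Sequence[TrajectoryFrame],
    topology: Topology,
    peptide_id: int,
) -> np.ndarray:
    """Per-residue helical fraction over frames.

    A residue is helical in a frame when (phi, psi) lies in the
    alpha-helical basin [-100, -30] x [-80, -5] degrees.  Terminal
    residues, which lack one dihedral, are reported as NaN.
    """
    frames = list(frames)
    if not frames:
        raise InputError("no frames")
    n_idx = topology.backbone_indices(peptide_id, "N")
    ca_idx = topology.backbone_indices(peptide_id, "CA")
    c_idx = topology.backbone_indices(peptide_id, "C")
    n_res = topology.n_residues(peptide_id)
    if not (len(n_idx) == len(ca_idx) == len(c_idx) == n_res):
        raise InputError(
            f"peptide {peptide_id}: N/CA/C backbone atoms required for every residue"
        )
    counts = np.zeros(n_res)
    for f in frames:
        xyz = f.coords
        for i in range(1, n_res - 1):
            phi = dihedral(xyz[c_idx[i - 1]], xyz[n_idx[i]],
                           xyz[ca_idx[i]], xyz[c_idx[i]])
            psi = dihedral(xyz[n_idx[i]], xyz[ca_idx[i]],
                           xyz[c_idx[i]], xyz[n_idx[i + 1]])
            if PHI_RANGE[0] <= phi <= PHI_RANGE[1] and \
                    PSI_RANGE[0] <= psi <= PSI_RANGE[1]:
                counts[i] += 1
    frac = counts / len(frames)
    frac[0] = np.nan
    frac[-1] = np.nan
    return frac
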