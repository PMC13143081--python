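"""Peptide pair orientation analysis and z-positioning.

Each peptide gets an axis vector v: the (unweighted) heavy-atom
centre-of-mass vector from its N-terminal patch to its C-terminal patch.
For a pair of peptides, cos(theta) between the two axes distinguishes
antiparallel (cos ~ -1) from parallel (cos ~ +1) arrangements.

Frames are classified as "interacting" when the patch contact count
T = A + P exceeds a threshold (strict inequality, default T > 5), where
A counts residue pairs between the N-patch of either peptide and the
second half of the other (heavy atoms < 4.5 A) and P is the C-patch
analogue.  Interacting frames are labelled antiparallel_like (A > P),
parallel_like (P > A) or mixed (A = P).

Z-positioning reports heavy-atom COM height above the bilayer midplane,
per peptide or per residue (quartile summaries).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, InputError
from .membrane import assign_leaflets
from .model import PeptideRegions, Topology, TrajectoryFrame

__all__ = [
    "OrientationRecord",
    "axis_vector",
    "patch_contact_counts",
    "orientation_records",
    "classify_frames",
    "zcom_distribution",
    "per_residue_zcom",
]


@dataclass(frozen=True)
class OrientationRecord:
    frame: int
    v1: np.ndarray
    v2: np.ndarray
    cos_theta: float
    A: int
    P: int
    interacting: bool
    label: str            # antiparallel_like | parallel_like | mixed | none

    @property
    def T(self) -> int:
        return self.A + self.P


def _region_heavy_indices(topology: Topology, peptide_id: int,
                          region: tuple[int, int]) -> np.ndarray:
    idx = topology.select(molecule_id=peptide_id, heavy=True)
    res = topology.residue_index_per_atom[idx]
    out = idx[(res >= region[0]) & (res <= region[1])]
    if len(out) == 0:
        raise InputError(
            f"peptide {peptide_id}: no heavy atoms in residues {region}"
        )
    return out


def axis_vector(
    frame: TrajectoryFrame,
    topology: Topology,
    peptide_id: int,
    regions: PeptideRegions | None = None,
) -> np.ndarray:
    """Unit N-patch -> C-patch heavy-atom COM vector of one peptide."""
    regions = regions or topology.regions
    n_com = frame.coords[
        _region_heavy_indices(topology, peptide_id, regions.n_patch)
    ].mean(axis=0)
    c_com = frame.coords[
        _region_heavy_indices(topology, peptide_id, regions.c_patch)
    ].mean(axis=0)
    v = c_com - n_com
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise DegenerateGeometryError(
            f"peptide {peptide_id}: patch COMs coincide, axis undefined"
        )
    return v / norm


def _residue_pair_contact_count(
    frame: TrajectoryFrame,
    topology: Topology,
    pid_a: int,
    region_a: tuple[int, int],
    pid_b: int,
    region_b: tuple[int, int],
    cutoff: float,
) -> int:
    ia = _region_heavy_indices(topology, pid_a, region_a)
    ib = _region_heavy_indices(topology, pid_b, region_b)
    ra = topology.residue_index_per_atom[ia]
    rb = topology.residue_index_per_atom[ib]
    d = np.linalg.norm(
        frame.coords[ia][:, None, :] - frame.coords[None, ib, :], axis=-1
    )
    hit = d < cutoff
    pairs = {(int(ra[i]), int(rb[j])) for i, j in zip(*np.nonzero(hit))}
    return len(pairs)


def patch_contact_counts(
    frame: TrajectoryFrame,
    topology: Topology,
    regions: PeptideRegions | None = None,
    cutoff: float = 4.5,
    peptide_pair: tuple[int, int] | None = None,
) -> tuple[int, int]:
    """(A, P) patch contact counts, both peptide directions summed.

    A contact is a residue pair (patch residue, second-half residue of
    the other peptide) with any heavy-atom pair strictly below the
    cutoff; a residue pair with several close atom pairs counts once.
    """
    regions = regions or topology.regions
    if peptide_pair is None:
        if len(topology.peptide_ids) < 2:
            raise InputError("need two peptides for patch contact counts")
        p1, p2 = topology.peptide_ids[:2]
    else:
        p1, p2 = peptide_pair
    A = (
        _residue_pair_contact_count(frame, topology, p1, regions.n_patch,
                                    p2, regions.second_half, cutoff)
        + _residue_pair_contact_count(frame, topology, p2, regions.n_patch,
                                      p1, regions.second_half, cutoff)
    )
    P = (
        _residue_pair_contact_count(frame, topology, p1, regions.c_patch,
                                    p2, regions.second_half, cutoff)
        + _residue_pair_contact_count(frame, topology, p2, regions.c_patch,
                                      p1, regions.second_half, cutoff)
    )
    return A, P


def orientation_records(
    frames: Sequence[TrajectoryFrame],
    topology: Topology,
    regions: PeptideRegions | None = None,
    cutoff: float = 4.5,
    threshold: int = 5,
    peptide_pair: tuple[int, int] | None = None,
) -> list[OrientationRecord]:
    """Per-frame axis vectors, cos(theta), (A, P) and orientation label."""
    regions = regions or topology.regions
    if peptide_pair is None:
        if len(topology.peptide_ids) < 2:
            raise InputError("need two peptides")
        peptide_pair = tuple(topology.peptide_ids[:2])
    p1, p2 = peptide_pair
    out = []
    for t, f in enumerate(frames):
        v1 = axis_vector(f, topology, p1, regions)
        v2 = axis_vector(f, topology, p2, regions)
        cos_t = float(np.clip(v1 @ v2, -1.0, 1.0))
        A, P = patch_contact_counts(f, topology, regions, cutoff,
                                    (p1, p2))
        interacting = (A + P) > threshold
        if not interacting:
            label = "none"
        elif A > P:
            label = "antiparallel_like"
        elif P > A:
            label = "parallel_like"
        else:
            label = "mixed"
        out.append(OrientationRecord(frame=t, v1=v1, v2=v2, cos_theta=cos_t,
                                     A=A, P=P, interacting=interacting,
                                     label=label))
    return out


def classify_frames(
    records: Sequence[OrientationRecord],
    bins: np.ndarray | int = 20,
) -> dict:
    """Summarise orientation records: label counts, a per-frame table and
    pooled cos(theta) histograms split by the interacting flag."""
    records = list(records)
    if not records:
        raise InputError("no orientation records")
    edges = (np.asarray(bins, float) if np.ndim(bins)
             else np.linspace(-1.0, 1.0, int(bins) + 1))
    cos_int = np.array([r.cos_theta for r in records if r.interacting])
    cos_non = np.array([r.cos_theta for r in records if not r.interacting])
    table = pd.DataFrame(
        [(r.frame, r.cos_theta, r.A, r.P, r.T, r.interacting, r.label)
         for r in records],
        columns=["frame", "cos_theta", "A", "P", "T", "interacting", "label"],
    )
    counts = table["label"].value_counts().to_dict()
    return {
        "table": table,
        "label_counts": counts,
        "edges": edges,
        "hist_interacting": np.histogram(cos_int, bins=edges)[0],
        "hist_non_interacting": np.histogram(cos_non, bins=edges)[0],
        "fraction_interacting": float(table["interacting"].mean()),
    }


# ---------------------------------------------------------------------------
# z-positioning


def _midplane(frame: TrajectoryFrame, topology: Topology,
              midplane: float | None) -> float:
    if midplane is not None:
        return midplane
    if topology.lipid_ids:
        return assign_leaflets(frame, topology).midplane_z
    return 0.0


def zcom_distribution(
    frames: Sequence[TrajectoryFrame],
    topology: Topology,
    peptide_id: int,
    region: tuple[int, int] | None = None,
    midplane: float | None = None,
    bin_width: float = 1.0,
    z_range: tuple[float, float] = (-60.0, 60.0),
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Per-frame heavy-atom COM height above the midplane + histogram.

    ``region`` optionally restricts the COM to a residue range (e.g. the
    AH core).  Without lipids (and no explicit midplane) heights are
    absolute z.
    """
    frames = list(frames)
    if region is None:
        idx = topology.select(molecule_id=peptide_id, heavy=True)
    else:
        idx = _region_heavy_indices(topology, peptide_id, region)
    rows = []
    for t, f in enumerate(frames):
        mid = _midplane(f, topology, midplane)
        rows.append((t, f.time_ns,
                     float(f.coords[idx, 2].mean() - mid)))
    df = pd.DataFrame(rows, columns=["frame", "time_ns", "z_com"])
    edges = np.arange(z_range[0], z_range[1] + bin_width / 2, bin_width)
    counts = np.histogram(df["z_com"], bins=edges)[0]
    return df, edges, counts


def per_residue_zcom(
    frames: Sequence[TrajectoryFrame],
    topology: Topology,
    peptide_id: int,
    midplane: float | None = None,
) -> pd.DataFrame:
    """Quartile summary (min/Q1/median/Q3/max) of per-residue heavy-atom
    COM heights above the midplane over frames."""
    frames = list(frames)
    if not frames:
        raise InputError("no frames")
    res_atoms = topology.residue_atom_indices(peptide_id, heavy=True)
    residues = sorted(res_atoms)
    per_res = {r: [] for r in residues}
    for f in frames:
        mid = _midplane(f, topology, midplane)
        for r in residues:
            per_res[r].append(float(f.coords[res_atoms[r], 2].mean() - mid))
    rows = []
    for r in residues:
        z = np.array(per_res[r])
        rows.append((r, z.min(), *np.percentile(z, [25, 50, 75]), z.max()))
    return pd.DataFrame(
        rows, columns=["residue", "min", "q1", "median", "q3", "max"]
    ).set_index("residue")
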