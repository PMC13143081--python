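"""Synthetic peptide/bilayer scenes with exact ground truth.

Every downstream analysis in this package is validated closed-loop against
scenes built here: ideal and arc-bent alpha-helices, planar two-leaflet
bead bilayers on a lattice with prescribed tail-tilt distributions,
two-peptide scenes with a prescribed inter-axis angle and forced patch
contacts, and two-state (telegraph) contact time series.  Generators are
seed-deterministic and carry a ground-truth manifest sufficient to verify
the analysis that consumes them.

No physical realism is attempted: there is no force field, no thermal
ensemble and no solvent.  Side chains are a single pseudo-heavy bead at the
C-beta position; charged residues (D/E/K/R) additionally carry one named
charged-tip bead (OD1/OE1/NZ/NH1) so that salt-bridge criteria are testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

from .errors import ConstructionError, InputError
from .model import (
    AtomRecord,
    LipidAnnotation,
    ONE_TO_THREE,
    PeptideRegions,
    Topology,
    TrajectoryFrame,
)

__all__ = [
    "HelixSpec",
    "BilayerSpec",
    "TiltDistribution",
    "TwoPeptideSceneSpec",
    "TelegraphSpec",
    "make_helix",
    "make_bilayer",
    "make_two_peptide_scene",
    "make_telegraph_series",
    "set_lipid_tilt",
    "merge_systems",
    "compose_peptide_bilayer",
]

_TAIL_BOND = 1.5          # A, bead-bead bond along a lipid tail
_CB_BOND = 1.53           # A, CA-CB
_TIP_EXT = 1.2            # A, charged-tip bead beyond CB
_CHARGED_TIP = {"D": ("OD1", "O"), "E": ("OE1", "O"),
                "K": ("NZ", "N"), "R": ("NH1", "N")}


# ---------------------------------------------------------------------------
# ideal alpha-helix template (internal-coordinate build, cylindrical extract)


def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement of atom d bonded to c with given internal coordinates."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * math.cos(ang),
         bond * math.sin(ang) * math.cos(dih),
         bond * math.sin(ang) * math.sin(dih)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_ideal_backbone(n_res: int, phi=-57.0, psi=-47.0, omega=180.0):
    """Ideal alpha-helix N/CA/C/O/CB coordinates via internal coordinates."""
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))
    CB = np.zeros((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (1.458, 0.0, 0.0)
    ang = math.radians(111.2)
    C[0] = CA[0] + 1.525 * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(n_res - 1):
        N[i + 1] = _place_atom(N[i], CA[i], C[i], 1.329, 116.2, psi)
        CA[i + 1] = _place_atom(CA[i], C[i], N[i + 1], 1.458, 121.7, omega)
        C[i + 1] = _place_atom(C[i], N[i + 1], CA[i + 1], 1.525, 111.2, phi)
        O[i] = _place_atom(N[i + 1], CA[i], C[i], 1.231, 120.8, 180.0)
    O[n_res - 1] = _place_atom(N[n_res - 1], CA[n_res - 1], C[n_res - 1],
                               1.231, 120.8, 135.0)
    for i in range(n_res):
        CB[i] = _place_atom(C[i], N[i], CA[i], _CB_BOND, 110.4, -122.6)
    return {"N": N, "CA": CA, "C": C, "O": O, "CB": CB}


@lru_cache(maxsize=1)
def _helix_template():
    """Cylindrical parameters (radius, phase and axial offsets vs CA) of an
    ideal alpha-helix, extracted from an internal-coordinate build."""
    M = 20
    atoms = _build_ideal_backbone(M)
    ca = atoms["CA"]
    cent = np.stack([ca[i : i + 4].mean(axis=0) for i in range(M - 3)])
    c0 = cent.mean(axis=0)
    _, _, vt = np.linalg.svd(cent - c0)
    d = vt[0]
    if np.dot(d, cent[-1] - cent[0]) < 0:
        d = -d
    e1 = np.cross(d, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(d, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)

    def cyl(p):
        q = p - c0
        z = q @ d
        u1, u2 = q @ e1, q @ e2
        return z, np.hypot(u1, u2), np.arctan2(u2, u1)

    lo, hi = 6, 14  # interior residues, away from chain ends
    z_ca = np.array([cyl(ca[i])[0] for i in range(M)])
    ph_ca = np.unwrap(np.array([cyl(ca[i])[2] for i in range(M)]))
    rise = float(np.mean(np.diff(z_ca[lo:hi])))
    twist = float(np.mean(np.diff(ph_ca[lo:hi])))  # signed, radians
    params = {}
    for name, arr in atoms.items():
        zs, rs, dps = [], [], []
        for i in range(lo, hi):
            z, r, ph = cyl(arr[i])
            zs.append(z - z_ca[i])
            rs.append(r)
            dps.append(np.angle(np.exp(1j * (ph - ph_ca[i]))))
        params[name] = (float(np.mean(rs)), float(np.mean(dps)),
                        float(np.mean(zs)))
    return {"rise": rise, "twist": twist, "atoms": params}


# ---------------------------------------------------------------------------
# helices


@dataclass(frozen=True)
class HelixSpec:
    """Geometry of a synthetic alpha-helix.

    ``bend_radius`` (A), when set, bends the helix *axis* along a circular
    arc in the xz-plane while parallel-transporting the local helical frame,
    so local rise/twist are preserved and the arc is the only curvature
    signal.  Must exceed contour length / pi (arc spans less than half a
    circle).
    """

    n_residues: int = 34
    rise_per_residue: float = 1.5       # A
    twist_per_residue: float = 100.0    # degrees
    backbone_radius: float = 2.3        # A, CA helix radius
    bend_radius: float | None = None    # A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise InputError("n_residues must be >= 4")
        if self.rise_per_residue <= 0 or self.backbone_radius <= 0:
            raise InputError("rise and backbone_radius must be positive")
        if self.bend_radius is not None:
            length = (self.n_residues - 1) * self.rise_per_residue
            if self.bend_radius <= length / math.pi:
                raise InputError(
                    f"bend_radius must exceed contour length/pi = {length / math.pi:.1f} A"
                )


def _helix_coords(spec: HelixSpec, sequence: str):
    """Canonical helix coordinates: axis along +x, CA centroid at origin.

    Returns (atom_rows, coords) where atom_rows are (name, element,
    residue_index, residue_name) tuples.
    """
    tpl = _helix_template()
    sgn = 1.0 if tpl["twist"] >= 0 else -1.0
    twist = sgn * math.radians(spec.twist_per_residue)
    rise = spec.rise_per_residue
    scale = spec.backbone_radius / tpl["atoms"]["CA"][0]

    rows: list[tuple[str, str, int, str]] = []
    coords: list[np.ndarray] = []
    for i, aa in enumerate(sequence):
        if aa not in ONE_TO_THREE:
            raise InputError(f"unknown residue letter {aa!r}")
        resname = ONE_TO_THREE[aa]
        placed: dict[str, np.ndarray] = {}
        for name in ("N", "CA", "C", "O", "CB"):
            if name == "CB" and aa == "G":
                continue
            r, dph, dz = tpl["atoms"][name]
            ph = twist * i + dph
            p = np.array(
                [rise * i + dz, r * scale * math.cos(ph), r * scale * math.sin(ph)]
            )
            placed[name] = p
            rows.append((name, "C" if name in ("CA", "C", "CB") else name, i + 1, resname))
            coords.append(p)
        if aa in _CHARGED_TIP:
            tip_name, tip_el = _CHARGED_TIP[aa]
            v = placed["CB"] - placed["CA"]
            v = v / np.linalg.norm(v)
            p = placed["CB"] + _TIP_EXT * v
            rows.append((tip_name, tip_el, i + 1, resname))
            coords.append(p)
    xyz = np.array(coords)
    ca_mask = np.array([r[0] == "CA" for r in rows])
    xyz -= xyz[ca_mask].mean(axis=0)

    if spec.bend_radius is not None:
        R = spec.bend_radius
        phi = xyz[:, 0] / R
        y, z = xyz[:, 1].copy(), xyz[:, 2].copy()
        bent = np.empty_like(xyz)
        bent[:, 0] = R * np.sin(phi) - z * np.sin(phi)
        bent[:, 1] = y
        bent[:, 2] = R * (1.0 - np.cos(phi)) + z * np.cos(phi)
        xyz = bent
        xyz -= xyz[ca_mask].mean(axis=0)
    return rows, xyz


def make_helix(
    spec: HelixSpec,
    sequence: str,
    regions: PeptideRegions | None = None,
    box: Sequence[float] = (400.0, 400.0, 400.0),
) -> tuple[Topology, TrajectoryFrame, dict]:
    """Build one hydrogen-free helical peptide (N, CA, C, O + CB pseudo side
    chain per non-Gly residue, plus a charged-tip bead on D/E/K/R).

    The helix axis lies along +x with the CA centroid at the origin; a set
    ``bend_radius`` bends the axis onto a circular arc in the xz-plane.
    Returns (topology, frame, ground-truth manifest).
    """
    if len(sequence) != spec.n_residues:
        raise InputError(
            f"sequence length {len(sequence)} != n_residues {spec.n_residues}"
        )
    rows, xyz = _helix_coords(spec, sequence)
    atoms = [
        AtomRecord(
            atom_id=k + 1, name=nm, element=el, residue_index=ri,
            residue_name=rn, molecule_id=1, molecule_kind="peptide",
        )
        for k, (nm, el, ri, rn) in enumerate(rows)
    ]
    topology = Topology(atoms=atoms, lipid_annotations={},
                        regions=regions or PeptideRegions())
    frame = TrajectoryFrame(time_ns=0.0, box=np.asarray(box, float), coords=xyz)
    manifest = {
        "kind": "helix",
        "sequence": sequence,
        "n_residues": spec.n_residues,
        "rise_per_residue_A": spec.rise_per_residue,
        "twist_per_residue_deg": spec.twist_per_residue,
        "bend_radius_A": spec.bend_radius,
        "seed": spec.seed,
    }
    return topology, frame, manifest


# ---------------------------------------------------------------------------
# bilayers


@dataclass(frozen=True)
class TiltDistribution:
    """Per-lipid tail tilt (angle to the membrane normal, degrees).

    kinds: ``fixed`` (theta0 for every lipid), ``gaussian`` (theta drawn
    from N(mu, sigma), untruncated -- the order parameter only sees
    cos^2 theta), ``isotropic`` (uniform on the hemisphere: cos theta
    uniform on [0, 1]).
    """

    kind: str = "fixed"
    theta0_deg: float = 0.0
    mu_deg: float = 0.0
    sigma_deg: float = 0.0

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, math.radians(self.theta0_deg))
        if self.kind == "gaussian":
            return rng.normal(math.radians(self.mu_deg),
                              math.radians(self.sigma_deg), n)
        if self.kind == "isotropic":
            return np.arccos(rng.uniform(0.0, 1.0, n))
        raise InputError(f"unknown tilt distribution kind {self.kind!r}")

    def analytic_order(self) -> float:
        """Expectation of (3 cos^2 theta - 1)/2 under this distribution."""
        if self.kind == "fixed":
            c = math.cos(math.radians(self.theta0_deg))
            return (3 * c * c - 1) / 2
        if self.kind == "gaussian":
            mu = math.radians(self.mu_deg)
            sg = math.radians(self.sigma_deg)
            # E[cos 2theta] = exp(-2 sigma^2) cos 2mu for theta ~ N(mu, sigma)
            return (1.0 + 3.0 * math.exp(-2 * sg * sg) * math.cos(2 * mu)) / 4.0
        if self.kind == "isotropic":
            return 0.0
        raise InputError(f"unknown tilt distribution kind {self.kind!r}")


@dataclass(frozen=True)
class BilayerSpec:
    """Planar two-leaflet bead bilayer on a square lattice.

    Each lipid is one phosphate bead plus ``tail_beads`` collinear tail
    beads along a single director drawn from ``tilt``; the per-lipid order
    parameter is therefore an exact function of its tilt angle.
    """

    nx: int = 8
    ny: int = 8
    spacing: float = 8.0                 # A
    composition: float = 0.75            # DOPC fraction; remainder PLPI
    tail_beads: int = 6
    tilt: TiltDistribution = field(default_factory=TiltDistribution)
    leaflet_separation: float = 38.0     # A between leaflet phosphate planes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nx * self.ny < 16:
            raise InputError("need nx*ny >= 16 lipids per leaflet")
        if not 0.0 <= self.composition <= 1.0:
            raise InputError("composition must be in [0, 1]")
        if self.spacing <= 0 or self.leaflet_separation <= 0:
            raise InputError("spacing and leaflet_separation must be positive")
        if self.tail_beads < 4:
            raise InputError("tail_beads must be >= 4")


def _tail_chain_names(n: int) -> tuple[str, ...]:
    return tuple(f"C{k}" for k in range(1, n + 1))


def make_bilayer(spec: BilayerSpec) -> tuple[Topology, TrajectoryFrame, dict]:
    """Build the bilayer; returns (topology, frame, ground-truth manifest).

    The manifest records, per leaflet, lipid ids, species counts, drawn tilt
    angles, exact per-lipid order parameters and the lattice area per lipid
    (spacing^2), plus the analytic ensemble order parameter.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.nx * spec.ny
    n_dopc = int(math.floor(spec.composition * n))  # floor then fill
    a = spec.spacing
    tail_len = spec.tail_beads * _TAIL_BOND
    lz = spec.leaflet_separation + 2 * tail_len + 40.0
    box = np.array([spec.nx * a, spec.ny * a, lz])
    mid_z = lz / 2.0

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    manifest_leaflets = {}
    mol_id = 0
    atom_id = 0
    tilts_all: list[float] = []
    for leaflet, sign in (("upper", +1.0), ("lower", -1.0)):
        species = np.array(["PLPI"] * n, dtype=object)
        order = rng.permutation(n)
        species[order[:n_dopc]] = "DOPC"
        thetas = spec.tilt.draw(rng, n)
        azimuths = rng.uniform(0.0, 2 * math.pi, n)
        lip_ids = []
        for k in range(n):
            i, j = divmod(k, spec.ny)
            mol_id += 1
            lip_ids.append(mol_id)
            px = (i + 0.5) * a
            py = (j + 0.5) * a
            pz = mid_z + sign * spec.leaflet_separation / 2.0
            th, az = thetas[k], azimuths[k]
            director = np.array(
                [math.sin(th) * math.cos(az),
                 math.sin(th) * math.sin(az),
                 -sign * math.cos(th)]          # tails point to the midplane
            )
            atom_id += 1
            atoms.append(AtomRecord(atom_id, "P", "P", 1, str(species[k]),
                                    mol_id, "lipid"))
            coords.append(np.array([px, py, pz]))
            for b in range(1, spec.tail_beads + 1):
                atom_id += 1
                atoms.append(AtomRecord(atom_id, f"C{b}", "C", 1,
                                        str(species[k]), mol_id, "lipid"))
                coords.append(np.array([px, py, pz]) + b * _TAIL_BOND * director)
        s_vals = (3 * np.cos(thetas) ** 2 - 1) / 2
        manifest_leaflets[leaflet] = {
            "lipid_ids": lip_ids,
            "n_dopc": int(np.sum(species == "DOPC")),
            "n_plpi": int(np.sum(species == "PLPI")),
            "tilt_deg": [float(np.degrees(t)) for t in thetas],
            "per_lipid_S": [float(s) for s in s_vals],
        }
        tilts_all.extend(thetas.tolist())

    ann = LipidAnnotation(phosphate_atom="P",
                          tail_chains=(_tail_chain_names(spec.tail_beads),))
    topology = Topology(
        atoms=atoms,
        lipid_annotations={"DOPC": ann, "PLPI": ann},
    )
    frame = TrajectoryFrame(time_ns=0.0, box=box, coords=np.array(coords))
    tilts_arr = np.array(tilts_all)
    manifest = {
        "kind": "bilayer",
        "nx": spec.nx, "ny": spec.ny,
        "spacing_A": a,
        "area_per_lipid_A2": a * a,
        "composition_dopc": spec.composition,
        "leaflet_separation_A": spec.leaflet_separation,
        "midplane_z_A": mid_z,
        "tilt": {"kind": spec.tilt.kind},
        "mean_S_drawn": float(np.mean((3 * np.cos(tilts_arr) ** 2 - 1) / 2)),
        "analytic_S": spec.tilt.analytic_order(),
        "leaflets": manifest_leaflets,
        "seed": spec.seed,
    }
    return topology, frame, manifest


def set_lipid_tilt(
    topology: Topology,
    frame: TrajectoryFrame,
    lipid_id: int,
    theta_deg: float,
    azimuth_deg: float = 0.0,
) -> TrajectoryFrame:
    """Return a frame with one lipid's tail rebuilt at a new tilt angle.

    Used to plant local order signals (e.g. disordered lipids near a
    peptide) into an otherwise uniform bilayer.
    """
    coords = frame.coords.copy()
    p_idx = topology.phosphate_index(lipid_id)
    tail_idx = [i for i in topology.select(molecule_id=lipid_id)
                if i != p_idx]
    p = coords[p_idx]
    sign = 1.0 if p[2] > frame.box[2] / 2.0 else -1.0
    th = math.radians(theta_deg)
    az = math.radians(azimuth_deg)
    director = np.array([math.sin(th) * math.cos(az),
                         math.sin(th) * math.sin(az),
                         -sign * math.cos(th)])
    for b, i in enumerate(sorted(tail_idx), start=1):
        coords[i] = p + b * _TAIL_BOND * director
    return TrajectoryFrame(time_ns=frame.time_ns, box=frame.box, coords=coords)


# ---------------------------------------------------------------------------
# two-peptide scenes


@dataclass(frozen=True)
class TwoPeptideSceneSpec:
    """Two identical helices at a prescribed inter-axis angle with forced
    heavy-atom patch contacts.

    ``n_forced_contacts_A`` residue pairs are created between one peptide's
    N-patch and the other's second half (``P``: C-patch analogue) by pulling
    the CB pseudo-side-chain beads of the paired residues to 4.0 A (< the
    4.5 A classifier cutoff); all non-forced inter-peptide heavy-atom pairs
    stay above 4.5 A, which the generator verifies by brute force.
    """

    inter_axis_angle: float = 180.0     # degrees, in [0, 180]
    center_separation: float = 18.0     # A between the two helix axes
    n_forced_contacts_A: int = 0
    n_forced_contacts_P: int = 0
    above_membrane: bool = False
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inter_axis_angle <= 180.0:
            raise InputError("inter_axis_angle must be in [0, 180] degrees")
        if self.n_forced_contacts_A < 0 or self.n_forced_contacts_P < 0:
            raise InputError("forced contact counts must be >= 0")
        if self.center_separation <= 0:
            raise InputError("center_separation must be positive")
        if self.n_frames < 1:
            raise InputError("n_frames must be >= 1")


_MAX_CB_REACH = 15.0      # A, sanity bound on how far a pulled CB may sit from its CA
_CONTACT_DIST = 4.0       # A, forced heavy-atom pair distance
_CLASSIFIER_CUTOFF = 4.5  # A, exclusion distance for non-forced pairs
_STAGGER = 2.8            # A, alternating lateral offset between forced pairs


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _patch_com(xyz, topology, mol_id, lo, hi):
    idx = topology.select(molecule_id=mol_id, heavy=True)
    res = topology.residue_index_per_atom[idx]
    sel = idx[(res >= lo) & (res <= hi)]
    return xyz[sel].mean(axis=0)


def _residue_pair_contacts(xyz, top, mol1, res_lo1, res_hi1, mol2,
                           res_lo2, res_hi2, cutoff):
    """Brute-force set of residue pairs with any heavy-atom pair < cutoff."""
    i1 = top.select(molecule_id=mol1, heavy=True)
    i2 = top.select(molecule_id=mol2, heavy=True)
    r1 = top.residue_index_per_atom[i1]
    r2 = top.residue_index_per_atom[i2]
    m1 = (r1 >= res_lo1) & (r1 <= res_hi1)
    m2 = (r2 >= res_lo2) & (r2 <= res_hi2)
    i1, r1 = i1[m1], r1[m1]
    i2, r2 = i2[m2], r2[m2]
    if len(i1) == 0 or len(i2) == 0:
        return set()
    d = np.linalg.norm(xyz[i1][:, None, :] - xyz[i2][None, :, :], axis=-1)
    hit = d < cutoff
    return {(int(r1[a]), int(r2[b])) for a, b in zip(*np.nonzero(hit))}


def _count_patch_contacts(xyz, top, regions, cutoff=_CLASSIFIER_CUTOFF):
    """(A, P) patch contact counts, both peptide directions summed."""
    p1, p2 = top.peptide_ids[:2]
    npat, sh, cpat = regions.n_patch, regions.second_half, regions.c_patch
    A = len(_residue_pair_contacts(xyz, top, p1, *npat, p2, *sh, cutoff)) + \
        len(_residue_pair_contacts(xyz, top, p2, *npat, p1, *sh, cutoff))
    P = len(_residue_pair_contacts(xyz, top, p1, *cpat, p2, *sh, cutoff)) + \
        len(_residue_pair_contacts(xyz, top, p2, *cpat, p1, *sh, cutoff))
    return A, P


def make_two_peptide_scene(
    spec: TwoPeptideSceneSpec,
    sequence: str,
    helix_spec: HelixSpec | None = None,
    regions: PeptideRegions | None = None,
) -> tuple[Topology, list[TrajectoryFrame], dict]:
    """Build a two-peptide scene; returns (topology, frames, manifest).

    The realized inter-axis angle (heavy-atom patch-COM definition) is
    brought within 0.5 degrees of the request by iteratively correcting the
    second peptide's orientation for the small COM shifts the forced-contact
    side-chain pulls introduce.  The manifest records the realized cos(theta)
    and brute-force-verified (A, P).
    """
    regions = regions or PeptideRegions()
    if len(sequence) < regions.c_patch[1]:
        raise InputError("sequence shorter than the configured regions")
    hspec = helix_spec or HelixSpec(n_residues=len(sequence))
    if hspec.n_residues != len(sequence):
        raise InputError("helix_spec.n_residues must match sequence length")

    rows, base = _helix_coords(hspec, sequence)
    n_atoms_1 = len(rows)

    atoms: list[AtomRecord] = []
    for pep in (1, 2):
        for k, (nm, el, ri, rn) in enumerate(rows):
            atoms.append(AtomRecord(
                atom_id=pep * n_atoms_1 - n_atoms_1 + k + 1, name=nm,
                element=el, residue_index=ri, residue_name=rn,
                molecule_id=pep, molecule_kind="peptide"))
    top = Topology(atoms=atoms, lipid_annotations={}, regions=regions)

    # residue -> pullable side-bead offset within one peptide (CB, or the
    # carbonyl O for Gly, which has no side chain)
    cb_of: dict[int, int] = {}
    for k, (nm, el, ri, rn) in enumerate(rows):
        if nm == "O" and ri not in cb_of:
            cb_of[ri] = k
        if nm == "CB":
            cb_of[ri] = k

    angle = math.radians(spec.inter_axis_angle)
    rot2 = _rotation([0.0, 0.0, 1.0], angle)
    offset = np.array([0.0, 0.0, spec.center_separation])
    corr = np.eye(3)

    def build(corr_matrix):
        xyz = np.empty((2 * n_atoms_1, 3))
        xyz[:n_atoms_1] = base
        xyz[n_atoms_1:] = (corr_matrix @ rot2 @ base.T).T + offset
        pulled = []
        # forced A contacts: peptide-1 N-patch residue i vs peptide-2
        # second-half residue j; forced P: peptide-1 C-patch vs peptide-2
        # second-half residues outside the C-patch (avoids double counting
        # through the reverse direction).
        for kind, n_forced, patch in (
            ("A", spec.n_forced_contacts_A, regions.n_patch),
            ("P", spec.n_forced_contacts_P, regions.c_patch),
        ):
            if n_forced == 0:
                continue
            cand_i = [i for i in range(patch[0], patch[1] + 1) if i in cb_of]
            if kind == "P":
                cand_j = [j for j in range(regions.second_half[0],
                                           regions.second_half[1] + 1)
                          if j in cb_of and not
                          (regions.c_patch[0] <= j <= regions.c_patch[1])
                          and not (regions.n_patch[0] <= j <= regions.n_patch[1])]
            else:
                cand_j = [j for j in range(regions.second_half[0],
                                           regions.second_half[1] + 1)
                          if j in cb_of and not
                          (regions.n_patch[0] <= j <= regions.n_patch[1])]
            if n_forced > min(len(cand_i), len(cand_j)):
                raise ConstructionError(
                    f"cannot force {n_forced} {kind}-contacts: only "
                    f"{min(len(cand_i), len(cand_j))} usable residue pairs"
                )
            ca1 = {ri: xyz[k] for k, (nm, _, ri, _) in enumerate(rows) if nm == "CA"}
            ca2 = {ri: xyz[n_atoms_1 + k] for k, (nm, _, ri, _)
                   in enumerate(rows) if nm == "CA"}
            # pair contiguous windows of both residue sets, matched in
            # axis order (x is peptide 1's axis): the pairing is monotone
            # along the contact seam, so anchors of successive forced
            # pairs stay spatially ordered and cannot collide
            ci_sorted = sorted(cand_i, key=lambda i: ca1[i][0])
            cj_sorted = sorted(cand_j, key=lambda j: ca2[j][0])
            best = None
            for a0 in range(len(ci_sorted) - n_forced + 1):
                ii = ci_sorted[a0 : a0 + n_forced]
                for b0 in range(len(cj_sorted) - n_forced + 1):
                    jj = cj_sorted[b0 : b0 + n_forced]
                    total = sum(
                        abs(ca1[i][0] - ca2[j][0])
                        + 0.01 * np.linalg.norm(ca1[i] - ca2[j])
                        for i, j in zip(ii, jj)
                    )
                    if best is None or total < best[0]:
                        best = (total, list(zip(ii, jj)))
            chosen = best[1]
            # contact anchors sit on a regular seam line at half the axis
            # gap, staggered laterally, with the paired beads offset along
            # the inter-axis direction: pulled beads of different pairs are
            # then guaranteed >= 5 A apart
            u = offset / np.linalg.norm(offset)
            lateral = np.array([0.0, 1.0, 0.0])
            for k_pair, (i, j) in enumerate(chosen):
                q1, q2 = ca1[i], ca2[j]
                anchor = np.array([0.5 * (q1[0] + q2[0]), 0.0, 0.0]) \
                    + 0.5 * np.linalg.norm(offset) * u \
                    + (_STAGGER if k_pair % 2 else -_STAGGER) * lateral
                cb1 = anchor - 0.5 * _CONTACT_DIST * u
                cb2 = anchor + 0.5 * _CONTACT_DIST * u
                if (np.linalg.norm(cb1 - q1) > _MAX_CB_REACH
                        or np.linalg.norm(cb2 - q2) > _MAX_CB_REACH):
                    raise ConstructionError(
                        f"forced {kind}-contact ({i}, {j}) needs a side-chain "
                        f"reach beyond {_MAX_CB_REACH} A; peptides too far apart"
                    )
                xyz[cb_of[i]] = cb1
                xyz[n_atoms_1 + cb_of[j]] = cb2
                pulled.append((kind, i, j))
        return xyz, pulled

    target_cos = math.cos(angle)
    xyz = pulled = None
    realized = None
    for _ in range(60):
        xyz, pulled = build(corr)
        v1 = _patch_com(xyz, top, 1, *regions.c_patch) - \
            _patch_com(xyz, top, 1, *regions.n_patch)
        v2 = _patch_com(xyz, top, 2, *regions.c_patch) - \
            _patch_com(xyz, top, 2, *regions.n_patch)
        v1 /= np.linalg.norm(v1)
        v2 /= np.linalg.norm(v2)
        realized = math.degrees(math.acos(np.clip(v1 @ v2, -1, 1)))
        err = spec.inter_axis_angle - realized
        if abs(err) < 0.05:
            break
        ax = np.cross(v1, v2)
        if np.linalg.norm(ax) < 1e-9:
            ax = np.cross(v1, [0.0, 1.0, 0.0])
            if np.linalg.norm(ax) < 1e-9:
                ax = np.cross(v1, [0.0, 0.0, 1.0])
        corr = _rotation(ax, math.radians(err) * 0.9) @ corr
    if abs(spec.inter_axis_angle - realized) > 0.5:
        raise ConstructionError(
            f"could not realise inter-axis angle {spec.inter_axis_angle} deg "
            f"(got {realized:.2f})"
        )

    if spec.above_membrane:
        xyz = xyz + np.array([0.0, 0.0, 30.0])

    # verify ground truth by brute force
    A, P = _count_patch_contacts(xyz, top, regions)
    if A != spec.n_forced_contacts_A or P != spec.n_forced_contacts_P:
        raise ConstructionError(
            f"scene self-check failed: counted (A={A}, P={P}), forced "
            f"(A={spec.n_forced_contacts_A}, P={spec.n_forced_contacts_P}); "
            "accidental contacts -- increase center_separation"
        )

    box = np.array([300.0, 300.0, 300.0])
    frames = [
        TrajectoryFrame(time_ns=float(t), box=box, coords=xyz.copy())
        for t in range(spec.n_frames)
    ]
    manifest = {
        "kind": "two_peptide_scene",
        "sequence": sequence,
        "inter_axis_angle_deg": spec.inter_axis_angle,
        "realized_angle_deg": float(realized),
        "cos_theta": float(math.cos(math.radians(realized))),
        "A": int(A),
        "P": int(P),
        "forced_pairs": [(k, int(i), int(j)) for k, i, j in pulled],
        "center_separation_A": spec.center_separation,
        "above_membrane": spec.above_membrane,
        "seed": spec.seed,
    }
    return top, frames, manifest


# ---------------------------------------------------------------------------
# telegraph (two-state) contact series


@dataclass(frozen=True)
class TelegraphSpec:
    """Alternating exponential on/off process sampled on a frame grid."""

    n_frames: int = 100_000
    dt_ns: float = 1.0
    mean_on_ns: float = 20.0
    mean_off_ns: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_frames, self.dt_ns, self.mean_on_ns, self.mean_off_ns) <= 0:
            raise InputError("all telegraph parameters must be positive")


def make_telegraph_series(spec: TelegraphSpec) -> tuple[np.ndarray, dict]:
    """Sample a two-state process; returns (boolean series, ground truth).

    The ground-truth summary records the stationary occupancy
    mean_on / (mean_on + mean_off) and the true mean on-duration.
    """
    rng = np.random.default_rng(spec.seed)
    total_t = spec.n_frames * spec.dt_ns
    occ = spec.mean_on_ns / (spec.mean_on_ns + spec.mean_off_ns)
    state = bool(rng.random() < occ)
    # draw alternating exponential dwell times until the window is covered
    bounds = [0.0]
    states = []
    s = state
    t = 0.0
    while t < total_t:
        mean = spec.mean_on_ns if s else spec.mean_off_ns
        dwell = rng.exponential(mean)
        t += dwell
        bounds.append(t)
        states.append(s)
        s = not s
    times = (np.arange(spec.n_frames) + 0.5) * spec.dt_ns
    seg = np.searchsorted(np.array(bounds), times, side="right") - 1
    series = np.array([states[k] for k in seg], dtype=bool)
    summary = {
        "true_occupancy": occ,
        "true_mean_on_ns": spec.mean_on_ns,
        "true_mean_off_ns": spec.mean_off_ns,
        "n_frames": spec.n_frames,
        "dt_ns": spec.dt_ns,
        "empirical_occupancy": float(series.mean()),
        "seed": spec.seed,
    }
    return series, summary


# ---------------------------------------------------------------------------
# composition helpers


def merge_systems(
    systems: Sequence[tuple[Topology, TrajectoryFrame]],
    box: Sequence[float] | None = None,
) -> tuple[Topology, TrajectoryFrame]:
    """Concatenate several (topology, frame) systems into one, renumbering
    atom and molecule ids.  The box defaults to the first system's box."""
    if not systems:
        raise InputError("nothing to merge")
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    annotations: dict[str, LipidAnnotation] = {}
    regions = systems[0][0].regions
    mol_offset = 0
    atom_id = 0
    for top, frame in systems:
        remap: dict[int, int] = {}
        for a, xyz in zip(top.atoms, frame.coords):
            if a.molecule_id not in remap:
                mol_offset += 1
                remap[a.molecule_id] = mol_offset
            atom_id += 1
            atoms.append(AtomRecord(
                atom_id=atom_id, name=a.name, element=a.element,
                residue_index=a.residue_index, residue_name=a.residue_name,
                molecule_id=remap[a.molecule_id],
                molecule_kind=a.molecule_kind))
            coords.append(xyz)
        annotations.update(top.lipid_annotations)
        if top.peptide_ids:
            regions = top.regions
    out_box = np.asarray(box if box is not None else systems[0][1].box, float)
    top_out = Topology(atoms=atoms, lipid_annotations=annotations,
                       regions=regions)
    frame_out = TrajectoryFrame(time_ns=systems[0][1].time_ns, box=out_box,
                                coords=np.array(coords))
    return top_out, frame_out


def compose_peptide_bilayer(
    bilayer: tuple[Topology, TrajectoryFrame],
    peptide: tuple[Topology, TrajectoryFrame],
    z_above_midplane: float = 15.0,
    xy: tuple[float, float] | None = None,
) -> tuple[Topology, TrajectoryFrame]:
    """Place a peptide with its heavy-atom COM at a height above the bilayer
    midplane (box-centered XY unless given) and merge the systems."""
    btop, bframe = bilayer
    ptop, pframe = peptide
    heavy = ptop.heavy_mask
    com = pframe.coords[heavy].mean(axis=0)
    mid_z = bframe.box[2] / 2.0
    target_xy = np.array(xy) if xy is not None else bframe.box[:2] / 2.0
    shift = np.array([target_xy[0] - com[0], target_xy[1] - com[1],
                      mid_z + z_above_midplane - com[2]])
    moved = TrajectoryFrame(time_ns=pframe.time_ns, box=bframe.box,
                            coords=pframe.coords + shift)
    return merge_systems([(btop, bframe), (ptop, moved)], box=bframe.box)
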