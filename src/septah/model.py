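"""Core data model and trajectory I/O.

The package works on multi-frame coordinate sets of peptide + planar-bilayer
systems.  The interchange format is multi-model PDB (one ``MODEL``/``ENDMDL``
block per frame) plus a YAML topology sidecar that carries what PDB cannot:
molecule kinds, lipid species annotations (phosphate atom name, tail-chain
atom names) and peptide region definitions.

Internal units are Angstrom for length and nanoseconds for time; angles are
reported in degrees.  Boxes are orthorhombic; triclinic input is rejected.
Residue numbering is 1-based and ranges are inclusive on both ends.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import (
    FormatOverflowError,
    InputError,
    ParseError,
    StructuralError,
)

__all__ = [
    "AtomRecord",
    "LipidAnnotation",
    "PeptideRegions",
    "Topology",
    "TrajectoryFrame",
    "minimum_image_displacement",
    "minimum_image_distance",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_topology_sidecar",
    "write_topology_sidecar",
    "load_system",
    "save_system",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
]

# ---------------------------------------------------------------------------
# residue-name tables

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

WATER_RESNAMES = {"HOH", "SOL", "TIP3", "TIP3P", "WAT", "SPC"}
ION_RESNAMES = {"NA", "CL", "K", "POT", "CLA", "SOD", "MG", "CAL"}

MOLECULE_KINDS = ("peptide", "lipid", "water", "ion")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, residue/molecule membership and element.

    ``is_heavy`` is derived from the element (everything but hydrogen);
    "heavy-atom" selections throughout the package mean exactly this flag.
    """

    atom_id: int                # 1-based, unique within the system
    name: str
    element: str
    residue_index: int          # 1-based within its molecule
    residue_name: str
    molecule_id: int
    molecule_kind: str          # peptide | lipid | water | ion

    def __post_init__(self) -> None:
        if self.molecule_kind not in MOLECULE_KINDS:
            raise InputError(
                f"unknown molecule kind {self.molecule_kind!r} for atom {self.atom_id}"
            )

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass(frozen=True)
class LipidAnnotation:
    """Per-species lipid annotation: headgroup anchor and tail-chain atom names."""

    phosphate_atom: str = "P"
    tail_chains: tuple[tuple[str, ...], ...] = ()


@dataclass(frozen=True)
class PeptideRegions:
    """Inclusive 1-based residue ranges partitioning an extended AH peptide.

    Defaults follow the 34-residue extended construct: an N-terminal patch
    (1-8), the amphipathic core (9-26), a C-terminal patch (27-34) and the
    "second half" (17-34) used by the orientation classifier.
    """

    n_patch: tuple[int, int] = (1, 8)
    ah_core: tuple[int, int] = (9, 26)
    c_patch: tuple[int, int] = (27, 34)
    second_half: tuple[int, int] = (17, 34)

    def __post_init__(self) -> None:
        for name in ("n_patch", "ah_core", "c_patch", "second_half"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise InputError(f"invalid residue range {name}={lo, hi}")
        if self.n_patch[1] >= self.c_patch[0]:
            raise InputError("n_patch must precede c_patch")

    def residues(self, name: str) -> range:
        lo, hi = getattr(self, name)
        return range(lo, hi + 1)

    def validate_length(self, n_residues: int) -> None:
        for name in ("n_patch", "ah_core", "c_patch", "second_half"):
            if getattr(self, name)[1] > n_residues:
                raise InputError(
                    f"region {name} exceeds peptide length {n_residues}"
                )


@dataclass(frozen=True)
class TrajectoryFrame:
    """One time point: orthorhombic box lengths (A) and per-atom coordinates (A)."""

    time_ns: float
    box: np.ndarray            # shape (3,)
    coords: np.ndarray         # shape (n_atoms, 3)

    def __post_init__(self) -> None:
        object.__setattr__(self, "box", np.asarray(self.box, dtype=float).reshape(3))
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InputError("coords must have shape (n_atoms, 3)")
        if self.time_ns < 0:
            raise InputError("time_ns must be non-negative")
        if not np.all(self.box > 0):
            raise InputError("box lengths must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


@dataclass
class Topology:
    """Static annotation of all atoms plus lipid species and peptide regions."""

    atoms: list[AtomRecord]
    lipid_annotations: dict[str, LipidAnnotation] = field(
        default_factory=lambda: {"DOPC": LipidAnnotation(), "PLPI": LipidAnnotation()}
    )
    regions: PeptideRegions = field(default_factory=PeptideRegions)

    # -- cached numpy views -------------------------------------------------

    @cached_property
    def names(self) -> np.ndarray:
        return np.array([a.name for a in self.atoms], dtype=object)

    @cached_property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms], dtype=object)

    @cached_property
    def molecule_id_per_atom(self) -> np.ndarray:
        return np.array([a.molecule_id for a in self.atoms], dtype=int)

    @cached_property
    def residue_index_per_atom(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    @cached_property
    def residue_name_per_atom(self) -> np.ndarray:
        return np.array([a.residue_name for a in self.atoms], dtype=object)

    @cached_property
    def kind_per_atom(self) -> np.ndarray:
        return np.array([a.molecule_kind for a in self.atoms], dtype=object)

    @cached_property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    # -- molecule-level accessors ------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def _molecule_ids(self, kind: str) -> list[int]:
        seen: list[int] = []
        for a in self.atoms:
            if a.molecule_kind == kind and a.molecule_id not in seen:
                seen.append(a.molecule_id)
        return seen

    @cached_property
    def peptide_ids(self) -> list[int]:
        return self._molecule_ids("peptide")

    @cached_property
    def lipid_ids(self) -> list[int]:
        return self._molecule_ids("lipid")

    @cached_property
    def lipid_species(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for a in self.atoms:
            if a.molecule_kind == "lipid":
                out.setdefault(a.molecule_id, a.residue_name)
        return out

    # -- selections ---------------------------------------------------------

    def select(
        self,
        molecule_id: int | Iterable[int] | None = None,
        names: Iterable[str] | None = None,
        heavy: bool = False,
        kind: str | None = None,
    ) -> np.ndarray:
        """Atom indices (0-based) matching all given filters."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if molecule_id is not None:
            mids = {molecule_id} if np.isscalar(molecule_id) else set(molecule_id)
            mask &= np.isin(self.molecule_id_per_atom, list(mids))
        if names is not None:
            mask &= np.isin(self.names, list(names))
        if kind is not None:
            mask &= self.kind_per_atom == kind
        if heavy:
            mask &= self.heavy_mask
        return np.flatnonzero(mask)

    def residue_atom_indices(
        self, molecule_id: int, heavy: bool = False
    ) -> dict[int, np.ndarray]:
        """Map residue index -> 0-based atom indices for one molecule."""
        idx = self.select(molecule_id=molecule_id, heavy=heavy)
        res = self.residue_index_per_atom[idx]
        return {int(r): idx[res == r] for r in np.unique(res)}

    def n_residues(self, molecule_id: int) -> int:
        idx = self.select(molecule_id=molecule_id)
        if len(idx) == 0:
            raise InputError(f"unknown molecule id {molecule_id}")
        return int(self.residue_index_per_atom[idx].max())

    def calpha_indices(self, molecule_id: int) -> np.ndarray:
        """Ordered CA atom indices of one peptide."""
        idx = self.select(molecule_id=molecule_id, names=["CA"])
        order = np.argsort(self.residue_index_per_atom[idx], kind="stable")
        return idx[order]

    def backbone_indices(self, molecule_id: int, name: str) -> np.ndarray:
        idx = self.select(molecule_id=molecule_id, names=[name])
        order = np.argsort(self.residue_index_per_atom[idx], kind="stable")
        return idx[order]

    def peptide_sequence(self, molecule_id: int) -> str:
        ca = self.calpha_indices(molecule_id)
        return "".join(
            THREE_TO_ONE.get(str(rn), "X") for rn in self.residue_name_per_atom[ca]
        )

    def phosphate_index(self, lipid_id: int) -> int:
        species = self.lipid_species[lipid_id]
        ann = self.lipid_annotations.get(species)
        if ann is None:
            raise InputError(f"no annotation for lipid species {species!r}")
        idx = self.select(molecule_id=lipid_id, names=[ann.phosphate_atom])
        if len(idx) != 1:
            raise InputError(
                f"lipid {lipid_id} ({species}) must have exactly one "
                f"{ann.phosphate_atom!r} atom, found {len(idx)}"
            )
        return int(idx[0])

    def phosphate_indices(self, lipid_ids: Iterable[int] | None = None) -> np.ndarray:
        ids = self.lipid_ids if lipid_ids is None else list(lipid_ids)
        return np.array([self.phosphate_index(i) for i in ids], dtype=int)

    def tail_bond_pairs(self, lipid_id: int) -> np.ndarray:
        """(m, 2) atom-index pairs of consecutive tail beads, all chains."""
        species = self.lipid_species[lipid_id]
        ann = self.lipid_annotations.get(species)
        if ann is None or not ann.tail_chains:
            raise InputError(
                f"lipid species {species!r} has no tail-chain annotation"
            )
        name_to_idx = {
            str(self.names[i]): int(i) for i in self.select(molecule_id=lipid_id)
        }
        pairs = []
        for chain in ann.tail_chains:
            try:
                chain_idx = [name_to_idx[n] for n in chain]
            except KeyError as exc:
                raise InputError(
                    f"lipid {lipid_id} ({species}) is missing tail atom {exc.args[0]!r}"
                ) from None
            pairs.extend(zip(chain_idx[:-1], chain_idx[1:]))
        return np.array(pairs, dtype=int)

    # -- validation ---------------------------------------------------------

    def validate(self, require_tails: bool = True) -> None:
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise StructuralError("atom_id values are not unique")
        last_res: dict[int, int] = {}
        for a in self.atoms:
            if a.residue_index < last_res.get(a.molecule_id, 1):
                raise StructuralError(
                    f"residue_index decreases within molecule {a.molecule_id}"
                )
            last_res[a.molecule_id] = a.residue_index
        for lid in self.lipid_ids:
            self.phosphate_index(lid)  # raises if absent / ambiguous
            if require_tails:
                species = self.lipid_species[lid]
                ann = self.lipid_annotations.get(species)
                if ann is None or not ann.tail_chains:
                    raise StructuralError(
                        f"lipid species {species!r} lacks tail-chain annotation"
                    )
                if any(len(c) < 3 for c in ann.tail_chains):
                    raise StructuralError(
                        f"lipid species {species!r}: tail chains need >= 3 atoms"
                    )
                self.tail_bond_pairs(lid)


# ---------------------------------------------------------------------------
# periodic-boundary helpers


def minimum_image_displacement(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the orthorhombic minimum image."""
    box = np.asarray(box, dtype=float)
    if not np.all(box > 0):
        raise InputError("box lengths must be positive")
    d = np.asarray(d, dtype=float)
    return d - box * np.round(d / box)


def minimum_image_distance(a, b, box) -> np.ndarray | float:
    """Euclidean distance under the orthorhombic minimum-image convention.

    Broadcasts over leading dimensions; ``a`` and ``b`` are points or arrays
    of points in Angstrom.
    """
    d = minimum_image_displacement(np.asarray(b, float) - np.asarray(a, float), box)
    out = np.linalg.norm(d, axis=-1)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# multi-model PDB I/O (backed by MDAnalysis)

_PDB_COORD_LIMITS = (-999.999, 9999.999)


def _chain_letter(kind: str, peptide_rank: int) -> str:
    if kind == "peptide":
        return "ABCDEFGHIJ"[peptide_rank % 10]
    return {"lipid": "L", "water": "W", "ion": "Z"}[kind]


def write_multimodel_pdb(
    topology: Topology, frames: Sequence[TrajectoryFrame], path: os.PathLike | str
) -> None:
    """Write frames as a standard multi-model PDB (MODEL/ENDMDL per frame).

    The CRYST1 record carries the orthorhombic box of each frame.  Raises
    :class:`FormatOverflowError` when a coordinate cannot fit the fixed-width
    PDB coordinate field.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    frames = list(frames)
    if not frames:
        raise InputError("no frames to write")
    for k, f in enumerate(frames):
        if f.n_atoms != topology.n_atoms:
            raise StructuralError(
                f"frame {k} has {f.n_atoms} atoms, topology has {topology.n_atoms}"
            )
    coords = np.stack([f.coords for f in frames])
    lo, hi = _PDB_COORD_LIMITS
    if coords.min() < lo or coords.max() > hi:
        raise FormatOverflowError(
            "coordinates exceed the PDB fixed-width field range "
            f"[{lo}, {hi}] A"
        )

    atoms = topology.atoms
    n_atoms = len(atoms)

    # Build per-atom residue entities: peptide residues keep their indices,
    # every non-peptide molecule is one residue.
    res_keys: list[tuple] = []
    resindex = np.empty(n_atoms, dtype=int)
    resnames: list[str] = []
    resids: list[int] = []
    chain_per_res: list[str] = []
    peptide_rank = {mid: r for r, mid in enumerate(topology.peptide_ids)}
    nonpep_counter: dict[str, int] = {}
    key_to_idx: dict[tuple, int] = {}
    for i, a in enumerate(atoms):
        key = (a.molecule_id, a.residue_index)
        if key not in key_to_idx:
            key_to_idx[key] = len(res_keys)
            res_keys.append(key)
            resnames.append(a.residue_name)
            if a.molecule_kind == "peptide":
                resids.append(a.residue_index)
            else:
                n = nonpep_counter.get(a.molecule_kind, 0) + 1
                nonpep_counter[a.molecule_kind] = n
                resids.append(((n - 1) % 9999) + 1)
            chain_per_res.append(
                _chain_letter(a.molecule_kind, peptide_rank.get(a.molecule_id, 0))
            )
        resindex[i] = key_to_idx[key]

    seg_letters = sorted(set(chain_per_res))
    seg_of = {c: k for k, c in enumerate(seg_letters)}
    residue_segindex = np.array([seg_of[c] for c in chain_per_res], dtype=int)

    u = mda.Universe.empty(
        n_atoms,
        n_residues=len(res_keys),
        n_segments=len(seg_letters),
        atom_resindex=resindex,
        residue_segindex=residue_segindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in atoms])
    u.add_TopologyAttr("elements", [a.element for a in atoms])
    u.add_TopologyAttr("chainIDs", [chain_per_res[r] for r in resindex])
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr("segids", seg_letters)
    u.add_TopologyAttr("occupancies", np.ones(n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(n_atoms))

    dims = np.array(
        [[*f.box, 90.0, 90.0, 90.0] for f in frames], dtype=np.float32
    )
    u.load_new(coords.astype(np.float32), format=MemoryReader, dimensions=dims)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms, multiframe=True) as w:
            for ts in u.trajectory:
                w.write(u.atoms)


def _scan_models(path: str) -> None:
    """Pre-scan a PDB file: per-MODEL atom counts and coordinate fields.

    Produces the diagnostics the reader contract promises (model number for
    count mismatches, line number for unparseable ATOM records); the actual
    parsing is done by MDAnalysis.
    """
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(f"{path}:{lineno}: truncated ATOM record")
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: unparseable coordinates in ATOM record"
                    ) from None
                current += 1
    if saw_model and in_model:
        counts.append(current)
    if not saw_model:
        counts.append(current)
    if not counts or counts[0] == 0:
        raise ParseError(f"{path}: no ATOM records found")
    for m, c in enumerate(counts, start=1):
        if c != counts[0]:
            raise StructuralError(
                f"{path}: MODEL {m} has {c} atoms, MODEL 1 has {counts[0]}"
            )


def _guess_element(name: str) -> str:
    stripped = "".join(ch for ch in name if ch.isalpha())
    return (stripped[:1] or "X").upper()


def read_multimodel_pdb(
    path: os.PathLike | str,
    lipid_annotations: Mapping[str, LipidAnnotation] | None = None,
    regions: PeptideRegions | None = None,
    dt_ns: float = 1.0,
    stride: int = 1,
) -> tuple[Topology, list[TrajectoryFrame]]:
    """Read a (multi-model) PDB into a Topology and a list of frames.

    Molecule kinds are inferred from residue names: annotated lipid species
    become lipids (one molecule per residue), recognised water/ion names
    their kinds, everything else peptide (one molecule per chain).  Frame
    times are assigned as ``frame_index * dt_ns``.
    """
    import MDAnalysis as mda

    path = str(path)
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    if stride < 1:
        raise InputError("stride must be >= 1")
    _scan_models(path)

    annotations = dict(
        lipid_annotations
        if lipid_annotations is not None
        else {"DOPC": LipidAnnotation(), "PLPI": LipidAnnotation()}
    )
    species = set(annotations)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(path)
        except Exception as exc:  # pragma: no cover - MDAnalysis detail
            raise ParseError(f"{path}: {exc}") from exc

    try:
        elements = [str(e) for e in u.atoms.elements]
    except mda.exceptions.NoDataError:
        elements = [_guess_element(str(n)) for n in u.atoms.names]
    elements = [
        e if e else _guess_element(str(n)) for e, n in zip(elements, u.atoms.names)
    ]
    try:
        chain_ids = [str(c) for c in u.atoms.chainIDs]
    except mda.exceptions.NoDataError:
        chain_ids = ["A"] * len(u.atoms)

    atoms: list[AtomRecord] = []
    mol_id = 0
    prev_key: tuple | None = None
    pep_first_resid: dict[int, int] = {}
    atom_i = 0
    for res in u.residues:
        rn = str(res.resname).strip()
        if rn in species:
            kind = "lipid"
        elif rn in WATER_RESNAMES:
            kind = "water"
        elif rn in ION_RESNAMES:
            kind = "ion"
        else:
            kind = "peptide"
        chain = chain_ids[res.atoms.ix[0]]
        if kind == "peptide":
            key = ("peptide", chain)
            if key != prev_key:
                mol_id += 1
                pep_first_resid[mol_id] = int(res.resid)
            res_index = int(res.resid) - pep_first_resid[mol_id] + 1
        else:
            mol_id += 1
            key = (kind, mol_id)
            res_index = 1
        prev_key = key
        for a in res.atoms:
            atoms.append(
                AtomRecord(
                    atom_id=atom_i + 1,
                    name=str(a.name).strip(),
                    element=elements[a.ix],
                    residue_index=res_index,
                    residue_name=rn,
                    molecule_id=mol_id,
                    molecule_kind=kind,
                )
            )
            atom_i += 1

    topology = Topology(
        atoms=atoms,
        lipid_annotations=annotations,
        regions=regions or PeptideRegions(),
    )

    frames: list[TrajectoryFrame] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, ts in enumerate(u.trajectory):
            if k % stride:
                continue
            dims = ts.dimensions
            if dims is None or not np.all(np.asarray(dims[:3]) > 0):
                span = np.ptp(ts.positions, axis=0)
                box = span + 200.0  # no CRYST1: PBC-neutral fallback box
            else:
                if not np.allclose(dims[3:6], 90.0, atol=1e-3):
                    raise InputError(
                        f"{path}: only orthorhombic boxes are supported "
                        f"(angles {tuple(float(x) for x in dims[3:6])})"
                    )
                box = np.asarray(dims[:3], dtype=float)
            frames.append(
                TrajectoryFrame(
                    time_ns=k * dt_ns,
                    box=box,
                    coords=ts.positions.astype(float).copy(),
                )
            )
    topology.validate(require_tails=False)
    return topology, frames


# ---------------------------------------------------------------------------
# topology sidecar (YAML)

_SIDECAR_SCHEMA = "septah-topology/1"


def write_topology_sidecar(topology: Topology, path: os.PathLike | str) -> None:
    """Write the YAML sidecar: lipid annotations and peptide regions."""
    doc = {
        "schema": _SIDECAR_SCHEMA,
        "lipid_species": {
            sp: {
                "phosphate": ann.phosphate_atom,
                "tail_chains": [list(c) for c in ann.tail_chains],
            }
            for sp, ann in topology.lipid_annotations.items()
        },
        "peptide_regions": {
            name: list(getattr(topology.regions, name))
            for name in ("n_patch", "ah_core", "c_patch", "second_half")
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_topology_sidecar(
    path: os.PathLike | str,
) -> tuple[dict[str, LipidAnnotation], PeptideRegions]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("schema") != _SIDECAR_SCHEMA:
        raise ParseError(f"{path}: not a {_SIDECAR_SCHEMA} sidecar")
    annotations = {
        sp: LipidAnnotation(
            phosphate_atom=entry.get("phosphate", "P"),
            tail_chains=tuple(tuple(c) for c in entry.get("tail_chains", [])),
        )
        for sp, entry in (doc.get("lipid_species") or {}).items()
    }
    regs = doc.get("peptide_regions") or {}
    regions = PeptideRegions(
        **{k: tuple(v) for k, v in regs.items()}
    )
    return annotations, regions


def save_system(
    topology: Topology,
    frames: Sequence[TrajectoryFrame],
    pdb_path: os.PathLike | str,
    sidecar_path: os.PathLike | str | None = None,
) -> None:
    write_multimodel_pdb(topology, frames, pdb_path)
    if sidecar_path is not None:
        write_topology_sidecar(topology, sidecar_path)


def load_system(
    pdb_path: os.PathLike | str,
    sidecar_path: os.PathLike | str | None = None,
    dt_ns: float = 1.0,
    stride: int = 1,
) -> tuple[Topology, list[TrajectoryFrame]]:
    annotations = None
    regions = None
    if sidecar_path is not None:
        annotations, regions = read_topology_sidecar(sidecar_path)
    return read_multimodel_pdb(
        pdb_path, lipid_annotations=annotations, regions=regions,
        dt_ns=dt_ns, stride=stride,
    )
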