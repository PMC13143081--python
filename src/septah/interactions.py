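"""Residue contact maps, residue-class contacts and salt-bridge statistics.

Contact criteria follow common trajectory-analysis practice for this
system: residue-residue contact maps use a 7.5 A cutoff on CA distances
(generous enough to catch side-chain-mediated interactions) or a
heavy-atom mode; residue-class contact counting uses heavy atoms at
3.5 A; salt bridges are side-chain carboxylate O (Asp OD1/OD2, Glu
OE1/OE2) to basic side-chain N (Lys NZ; Arg NH1/NH2/NE) within 3.2 A,
deduplicated to the residue pair.  Histidine is treated as neutral and
excluded from salt bridges.

Salt-bridge kinetics are summarised as per-pair occupancy (fraction of
frames active, mean +/- sd across replicas) and lifetime statistics:
maximal runs of consecutive active frames (optionally merging gaps up to
``gap_tolerance`` frames) become events with duration run_length * dt;
the 95th percentile uses linear interpolation between order statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constructs import RESIDUE_CLASSES, classify_residue
from .errors import InputError
from .model import THREE_TO_ONE, Topology, TrajectoryFrame, minimum_image_displacement

__all__ = [
    "ContactMapResult",
    "DomainContactMap",
    "SaltBridgePair",
    "SaltBridgeEvent",
    "contact_map",
    "domain_contact_map",
    "residue_class_contacts",
    "headgroup_contact_profile",
    "detect_salt_bridges",
    "salt_bridge_series",
    "bridge_occupancy",
    "bridge_lifetimes",
    "events_from_series",
    "top_pairs_timeseries",
]

ACIDIC_O_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_N_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE")}


# ---------------------------------------------------------------------------
# contact maps


@dataclass(frozen=True)
class ContactMapResult:
    """Contact frequencies over frames between residues of two peptides
    (or within one peptide; intra maps are symmetric with unit diagonal)."""

    freq: pd.DataFrame               # residues x residues, values in [0, 1]
    per_frame: np.ndarray            # (n_frames, n1, n2) boolean
    cutoff: float
    mode: str                        # calpha | heavy
    peptides: tuple[int, int]


@dataclass(frozen=True)
class DomainContactMap:
    """Region-level (N-term / AH / C-term) contact means per time window."""

    windows: list[pd.DataFrame]
    window_frames: list[tuple[int, int]]     # inclusive frame ranges
    window_times: list[tuple[float, float]]  # ns


def _residue_min_distances(
    coords: np.ndarray,
    box: np.ndarray,
    idx1: np.ndarray,
    res1: np.ndarray,
    idx2: np.ndarray,
    res2: np.ndarray,
    n1: int,
    n2: int,
) -> np.ndarray:
    """(n1, n2) matrix of minimum atom-atom distances (minimum image)."""
    d = minimum_image_displacement(
        coords[idx1][:, None, :] - coords[None, idx2, :], box
    )
    dist = np.linalg.norm(d, axis=-1)
    out = np.full((n1, n2), np.inf)
    np.minimum.at(out, (res1[:, None] * np.ones_like(res2),
                        np.ones_like(res1)[:, None] * res2), dist)
    return out


def contact_map(
    frames: Sequence[TrajectoryFrame],
    topology: Topology,
    peptide_1: int,
    peptide_2: int | None = None,
    mode: str = "calpha",
    cutoff: float = 7.5,
) -> ContactMapResult:
    """Residue-residue contact frequency map.

    A residue pair is in contact in a frame when the minimum distance
    between its selected atoms (CA only, or all heavy atoms) is <= cutoff
    under the minimum-image convention.
    """
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    if mode not in ("calpha", "heavy"):
        raise InputError(f"unknown selection mode {mode!r}")
    frames = list(frames)
    if not frames:
        raise InputError("no frames")
    intra = peptide_2 is None or peptide_2 == peptide_1
    p2 = peptide_1 if intra else peptide_2

    def selection(pid):
        if mode == "calpha":
            idx = topology.calpha_indices(pid)
        else:
            idx = topology.select(molecule_id=pid, heavy=True)
        if len(idx) == 0:
            raise InputError(f"empty {mode} selection for peptide {pid}")
        return idx, topology.residue_index_per_atom[idx] - 1

    idx1, res1 = selection(peptide_1)
    idx2, res2 = selection(p2)
    n1 = topology.n_residues(peptide_1)
    n2 = topology.n_residues(p2)
    per_frame = np.zeros((len(frames), n1, n2), dtype=bool)
    for t, f in enumerate(frames):
        dmin = _residue_min_distances(f.coords, f.box, idx1, res1, idx2, res2,
                                      n1, n2)
        per_frame[t] = dmin <= cutoff
    freq = per_frame.mean(axis=0)
    freq_df = pd.DataFrame(
        freq,
        index=pd.Index(np.arange(1, n1 + 1), name=f"residue_p{peptide_1}"),
        columns=pd.Index(np.arange(1, n2 + 1), name=f"residue_p{p2}"),
    )
    return ContactMapResult(freq=freq_df, per_frame=per_frame, cutoff=cutoff,
                            mode=mode, peptides=(peptide_1, p2))


def domain_contact_map(
    result: ContactMapResult,
    topology: Topology,
    n_windows: int = 4,
    dt_ns: float | None = None,
    times: Sequence[float] | None = None,
) -> DomainContactMap:
    """Coarse-grain a residue contact map over peptide regions and time.

    Frames are split into ``n_windows`` contiguous equal blocks (the last
    absorbs the remainder); each coarse cell is the mean of its
    constituent residue-pair contact frequencies within the window.
    """
    n_frames = result.per_frame.shape[0]
    if not 1 <= n_windows <= n_frames:
        raise InputError(
            f"n_windows must be in [1, {n_frames}] for {n_frames} frames"
        )
    regions = topology.regions
    blocks = {
        "N-term": regions.residues("n_patch"),
        "AH": regions.residues("ah_core"),
        "C-term": regions.residues("c_patch"),
    }
    labels = list(blocks)
    size = n_frames // n_windows
    windows = []
    frame_ranges = []
    time_ranges = []
    for w in range(n_windows):
        lo = w * size
        hi = n_frames if w == n_windows - 1 else (w + 1) * size
        freq = result.per_frame[lo:hi].mean(axis=0)
        coarse = np.zeros((len(labels), len(labels)))
        for a, la in enumerate(labels):
            ra = np.array(list(blocks[la])) - 1
            for b, lb in enumerate(labels):
                rb = np.array(list(blocks[lb])) - 1
                coarse[a, b] = freq[np.ix_(ra, rb)].mean()
        windows.append(pd.DataFrame(coarse, index=labels, columns=labels))
        frame_ranges.append((lo, hi - 1))
        if times is not None:
            time_ranges.append((float(times[lo]), float(times[hi - 1])))
        else:
            dt = dt_ns if dt_ns is not None else 1.0
            time_ranges.append((lo * dt, (hi - 1) * dt))
    return DomainContactMap(windows=windows, window_frames=frame_ranges,
                            window_times=time_ranges)


# ---------------------------------------------------------------------------
# residue-class contacts


def residue_class_contacts(
    frames: Sequence[TrajectoryFrame],
    topology: Topology,
    peptide_1: int,
    peptide_2: int,
    cutoff: float = 3.5,
) -> dict:
    """Inter-peptide residue-pair contacts aggregated by residue class.

    A residue pair counts (once per frame) when any heavy-atom pair is
    <= cutoff.  Returns class-pair totals (peptide-1 class x peptide-2
    class), per-residue totals for both peptides, and the overall count;
    class totals partition the total exactly.
    """
    frames = list(frames)
    if not frames:
        raise InputError("no frames")
    hm = contact_map(frames, topology, peptide_1, peptide_2, mode="heavy",
                     cutoff=cutoff)
    seq1 = topology.peptide_sequence(peptide_1)
    seq2 = topology.peptide_sequence(peptide_2)
    class_mat = pd.DataFrame(0, index=list(RESIDUE_CLASSES),
                             columns=list(RESIDUE_CLASSES))
    per_res1 = np.zeros(len(seq1), dtype=int)
    per_res2 = np.zeros(len(seq2), dtype=int)
    counts = hm.per_frame.sum(axis=0)   # frames in contact per residue pair
    for (i, j), c in np.ndenumerate(counts):
        if c == 0:
            continue
        class_mat.loc[classify_residue(seq1[i]), classify_residue(seq2[j])] += int(c)
        per_res1[i] += int(c)
        per_res2[j] += int(c)
    return {
        "class_matrix": class_mat,
        "per_residue_1": per_res1,
        "per_residue_2": per_res2,
        "total": int(counts.sum()),
        "cutoff": cutoff,
        "n_frames": len(frames),
    }


def headgroup_contact_profile(
    frames: Sequence[TrajectoryFrame],
    topology: Topology,
    peptide_id: int,
    cutoff: float = 6.0,
) -> pd.DataFrame:
    """Per-residue contact frequency with lipid headgroups, by species.

    A residue is in contact in a frame when any of its heavy atoms is
    within ``cutoff`` of the headgroup (phosphate) atom of a lipid of the
    given species.  Species without lipids yield a zero column.
    """
    frames = list(frames)
    if not frames:
        raise InputError("no frames")
    n_res = topology.n_residues(peptide_id)
    species_list = sorted(topology.lipid_annotations)
    res_atoms = topology.residue_atom_indices(peptide_id, heavy=True)
    phos_by_species: dict[str, np.ndarray] = {}
    for sp in species_list:
        lids = [lid for lid, s in topology.lipid_species.items() if s == sp]
        if not lids:
            warnings.warn(f"no lipids of species {sp}", stacklevel=2)
            phos_by_species[sp] = np.array([], dtype=int)
        else:
            phos_by_species[sp] = topology.phosphate_indices(lids)
    out = np.zeros((n_res, len(species_list)))
    for f in frames:
        for s_i, sp in enumerate(species_list):
            phos = phos_by_species[sp]
            if phos.size == 0:
                continue
            for r in range(1, n_res + 1):
                idx = res_atoms.get(r)
                if idx is None or len(idx) == 0:
                    continue
                d = minimum_image_displacement(
                    f.coords[idx][:, None, :] - f.coords[None, phos, :], f.box
                )
                if np.linalg.norm(d, axis=-1).min() <= cutoff:
                    out[r - 1, s_i] += 1
    out /= len(frames)
    return pd.DataFrame(
        out, index=pd.Index(np.arange(1, n_res + 1), name="residue"),
        columns=species_list,
    )


# ---------------------------------------------------------------------------
# salt bridges


@dataclass(frozen=True, order=True)
class SaltBridgePair:
    acidic_peptide: int
    acidic_residue: int
    basic_peptide: int
    basic_residue: int
    acidic_resname: str = "GLU"
    basic_resname: str = "LYS"

    @property
    def label(self) -> str:
        b = THREE_TO_ONE.get(self.basic_resname, "X")
        a = THREE_TO_ONE.get(self.acidic_resname, "X")
        return f"{b}{self.basic_residue}-{a}{self.acidic_residue}"


@dataclass(frozen=True)
class SaltBridgeEvent:
    pair: SaltBridgePair
    start_frame: int
    end_frame: int          # inclusive
    duration_ns: float


def _charged_atom_sets(topology: Topology, peptide_ids: Iterable[int]):
    """Per-peptide acidic-O and basic-N atom groups, validated."""
    acid, base = [], []
    missing = []
    for pid in peptide_ids:
        res_atoms = topology.residue_atom_indices(pid)
        for r, idx in res_atoms.items():
            rn = str(topology.residue_name_per_atom[idx[0]])
            names = set(map(str, topology.names[idx]))
            if rn in ACIDIC_O_ATOMS:
                found = [i for i in idx
                         if str(topology.names[i]) in ACIDIC_O_ATOMS[rn]]
                if not found:
                    missing.append(f"{rn}{r} (peptide {pid})")
                else:
                    acid.append((pid, r, rn, np.array(found)))
            elif rn in BASIC_N_ATOMS:
                found = [i for i in idx
                         if str(topology.names[i]) in BASIC_N_ATOMS[rn]]
                if not found:
                    missing.append(f"{rn}{r} (peptide {pid})")
                else:
                    base.append((pid, r, rn, np.array(found)))
    if missing:
        raise InputError(
            "charged residues lack named side-chain O/N atoms: "
            + ", ".join(missing)
        )
    return acid, base


def detect_salt_bridges(
    frame: TrajectoryFrame,
    topology: Topology,
    on_cutoff: float = 3.2,
    inter_only: bool = True,
) -> set[SaltBridgePair]:
    """Salt-bridge pairs active in one frame (residue-level dedup).

    A pair is active when any acidic side-chain O to basic side-chain N
    distance is <= on_cutoff (minimum image).  With ``inter_only`` only
    pairs on different peptides are reported.
    """
    acid, base = _charged_atom_sets(topology, topology.peptide_ids)
    active: set[SaltBridgePair] = set()
    for apid, ares, arn, aidx in acid:
        for bpid, bres, brn, bidx in base:
            if inter_only and apid == bpid:
                continue
            d = minimum_image_displacement(
                frame.coords[aidx][:, None, :] - frame.coords[None, bidx, :],
                frame.box,
            )
            if np.linalg.norm(d, axis=-1).min() <= on_cutoff:
                active.add(SaltBridgePair(apid, ares, bpid, bres, arn, brn))
    return active


def salt_bridge_series(
    frames: Sequence[TrajectoryFrame],
    topology: Topology,
    on_cutoff: float = 3.2,
    inter_only: bool = True,
) -> dict[SaltBridgePair, np.ndarray]:
    """Boolean activity series per pair over frames (pairs ever active)."""
    frames = list(frames)
    per_frame = [detect_salt_bridges(f, topology, on_cutoff, inter_only)
                 for f in frames]
    pairs = sorted({p for s in per_frame for p in s})
    return {
        p: np.array([p in s for s in per_frame], dtype=bool) for p in pairs
    }


def bridge_occupancy(
    replicas: Mapping[SaltBridgePair, np.ndarray]
    | Sequence[Mapping[SaltBridgePair, np.ndarray]],
) -> pd.DataFrame:
    """Per-pair occupancy (active frames / total frames), aggregated as
    mean +/- sd across replicas; pairs never active are omitted."""
    if isinstance(replicas, Mapping):
        replicas = [replicas]
    if not replicas:
        raise InputError("no replicas")
    pairs = sorted({p for rep in replicas for p in rep})
    rows = []
    for p in pairs:
        occ = [float(np.mean(rep[p])) if p in rep else 0.0 for rep in replicas]
        rows.append((
            p.label, p,
            float(np.mean(occ)),
            float(np.std(occ, ddof=1)) if len(occ) > 1 else float("nan"),
        ))
    df = pd.DataFrame(rows, columns=["pair", "pair_obj", "occupancy_mean",
                                     "occupancy_sd"])
    return df.sort_values("occupancy_mean", ascending=False,
                          ignore_index=True)


def events_from_series(
    series: np.ndarray, gap_tolerance: int = 0
) -> list[tuple[int, int]]:
    """Maximal on-runs as inclusive (start, end) frame pairs; runs
    separated by <= gap_tolerance off-frames are merged."""
    series = np.asarray(series, dtype=bool)
    if series.size == 0:
        return []
    padded = np.concatenate([[False], series, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    runs = list(zip(starts, ends))
    if gap_tolerance > 0 and len(runs) > 1:
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            if s - pe - 1 <= gap_tolerance:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        runs = merged
    return [(int(s), int(e)) for s, e in runs]


def bridge_lifetimes(
    series: Mapping[SaltBridgePair, np.ndarray] | np.ndarray,
    dt_ns: float,
    gap_tolerance: int = 0,
) -> pd.DataFrame:
    """Per-pair event statistics: n_events, total on-time, median and
    95th-percentile event duration (ns).

    Event duration is (end - start + 1) * dt; the 95th percentile is the
    linear-interpolation (inclusive) quantile of the event durations.
    """
    if dt_ns <= 0:
        raise InputError("dt_ns must be positive")
    if not isinstance(series, Mapping):
        series = {SaltBridgePair(0, 0, 0, 0): np.asarray(series)}
    rows = []
    for p, s in sorted(series.items()):
        runs = events_from_series(s, gap_tolerance)
        if not runs:
            continue
        durations = np.array([(e - st + 1) * dt_ns for st, e in runs])
        rows.append((
            p.label, p, len(runs),
            float(durations.sum()),
            float(np.median(durations)),
            float(np.percentile(durations, 95)),
            float(durations.mean()),
        ))
    return pd.DataFrame(rows, columns=[
        "pair", "pair_obj", "n_events", "total_on_ns", "median_ns",
        "p95_ns", "mean_ns",
    ])


def top_pairs_timeseries(
    frames: Sequence[TrajectoryFrame],
    topology: Topology,
    k: int = 5,
    on_cutoff: float = 3.2,
) -> pd.DataFrame:
    """Per-frame minimum O-N distance traces for the k highest-occupancy
    salt-bridge pairs (ties broken by acidic then basic residue index)."""
    if k < 1:
        raise InputError("k must be >= 1")
    frames = list(frames)
    series = salt_bridge_series(frames, topology, on_cutoff)
    if not series:
        warnings.warn("no salt bridges observed", stacklevel=2)
        return pd.DataFrame(index=pd.Index(
            [f.time_ns for f in frames], name="time_ns"))
    ranked = sorted(
        series.items(),
        key=lambda kv: (-float(np.mean(kv[1])),
                        kv[0].acidic_residue, kv[0].basic_residue),
    )
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} pairs observed (k={k})", stacklevel=2
        )
    chosen = [p for p, _ in ranked[:k]]
    acid, base = _charged_atom_sets(topology, topology.peptide_ids)
    atoms_a = {(pid, r): idx for pid, r, _, idx in acid}
    atoms_b = {(pid, r): idx for pid, r, _, idx in base}
    data = {}
    for p in chosen:
        aidx = atoms_a[(p.acidic_peptide, p.acidic_residue)]
        bidx = atoms_b[(p.basic_peptide, p.basic_residue)]
        trace = []
        for f in frames:
            d = minimum_image_displacement(
                f.coords[aidx][:, None, :] - f.coords[None, bidx, :], f.box
            )
            trace.append(float(np.linalg.norm(d, axis=-1).min()))
        data[p.label] = trace
    return pd.DataFrame(
        data, index=pd.Index([f.time_ns for f in frames], name="time_ns")
    )
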