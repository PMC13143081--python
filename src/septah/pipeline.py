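"""Run all analyses over a trajectory with one config; emit a CSV bundle.

This is the batch face of the library: a single :class:`AnalysisConfig`
collects every cutoff and threshold (with the package defaults), and
:func:`run_all` executes the applicable stages -- peptide geometry,
membrane organisation, inter-peptide interactions, salt bridges and
orientation -- writing CSV tables plus a YAML run manifest (config echo,
package version, per-stage status, collected warnings).  Stages that do
not apply to the input (no lipids, a single peptide) are skipped and
noted in the manifest.

:func:`generate` writes named synthetic fixtures (scene PDB + topology
sidecar + ground-truth manifest) for testing and demonstration.
"""

from __future__ import annotations

import dataclasses
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constructs as cons
from . import geometry as geo
from . import interactions as inter
from . import membrane as mem
from . import orientation as orient
from . import synthetic as syn
from .errors import InputError
from .model import (
    Topology,
    TrajectoryFrame,
    load_system,
    save_system,
    write_topology_sidecar,
)

__all__ = ["AnalysisConfig", "run_all", "generate", "FIXTURES"]


@dataclass
class AnalysisConfig:
    """All inputs and tunables of a full analysis run.

    Cutoffs (A): residue contact maps 7.5 (CA), patch contacts 4.5
    (heavy), residue-class contacts 3.5 (heavy), salt bridges 3.2 (O-N);
    interaction threshold T > 5; bending chord 7.2; near/far lipid
    cutoffs 10/25; 4 contact-map time windows.
    """

    trajectory: str = ""
    topology: str | None = None      # sidecar path
    output_dir: str = "septah_out"
    dt_ns: float = 1.0
    stride: int = 1
    seed: int = 0
    contact_cutoff: float = 7.5
    patch_cutoff: float = 4.5
    class_cutoff: float = 3.5
    saltbridge_cutoff: float = 3.2
    interaction_threshold: int = 5
    bending_side: float = 7.2
    axis_window: int = 4
    near_cutoff: float = 10.0
    far_cutoff: float = 25.0
    n_windows: int = 4
    gap_tolerance: int = 0

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "patch_cutoff", "class_cutoff",
                     "saltbridge_cutoff", "bending_side", "near_cutoff",
                     "far_cutoff", "dt_ns"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.interaction_threshold < 0 or self.n_windows < 1:
            raise InputError("bad threshold or window count")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(doc) - known
        if bad:
            raise InputError(f"unknown config keys: {sorted(bad)}")
        return cls(**doc)


def _bending_params(cfg: AnalysisConfig) -> geo.BendingParams:
    return geo.BendingParams(side=cfg.bending_side, axis_window=cfg.axis_window)


def run_all(
    config: AnalysisConfig,
    system: tuple[Topology, list[TrajectoryFrame]] | None = None,
) -> dict:
    """Run every applicable stage; returns the manifest dict.

    ``system`` may supply an in-memory (topology, frames) pair; otherwise
    the trajectory/topology paths in the config are read.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if system is None:
        topology, frames = load_system(
            config.trajectory, config.topology, dt_ns=config.dt_ns,
            stride=config.stride,
        )
    else:
        topology, frames = system
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "package": "septah",
        "version": __import__("septah").__version__,
        "n_frames": len(frames),
        "n_atoms": topology.n_atoms,
        "peptides": topology.peptide_ids,
        "n_lipids": len(topology.lipid_ids),
        "stages": {},
        "warnings": [],
    }

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fn()
            for w in caught:
                manifest["warnings"].append(f"{name}: {w.message}")
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            raise

    peptides = topology.peptide_ids
    has_membrane = bool(topology.lipid_ids)
    params = _bending_params(config)

    # -- geometry ----------------------------------------------------------
    if peptides:
        def run_geometry():
            pid = peptides[0]
            table = geo.bending_heatmap_table(frames, topology, pid, params)
            table.to_csv(out / "bending_heatmap.csv")
            mean_prof = table.mean(axis=0)
            mean_prof.rename("mean_angle_deg").to_csv(out / "bending_profile.csv")
            fits = []
            for t, f in enumerate(frames):
                axis = geo.helix_axis_points(
                    f.coords[topology.calpha_indices(pid)], params)
                try:
                    fit = geo.fit_circle_pca(axis)
                    fits.append((t, fit.radius, fit.rms_residual))
                except geo.DegenerateGeometryError:
                    fits.append((t, np.inf, np.nan))
            pd.DataFrame(fits, columns=["frame", "radius_A", "rms_A"]).to_csv(
                out / "curvature_fit.csv", index=False)
            hel = geo.helicity_profile(frames, topology, pid)
            pd.Series(hel, index=pd.RangeIndex(1, len(hel) + 1, name="residue"),
                      name="helical_fraction").to_csv(out / "helicity.csv")
        stage("geometry", run_geometry)
    else:
        manifest["stages"]["geometry"] = {"status": "skipped",
                                          "reason": "no peptides"}

    # -- membrane ----------------------------------------------------------
    if has_membrane:
        def run_membrane():
            f0 = frames[0]
            la = mem.assign_leaflets(f0, topology)
            apl = mem.area_per_lipid(f0, topology, la)
            pd.Series(apl.area_of, name="area_A2").rename_axis("lipid_id") \
                .to_csv(out / "apl_upper.csv")
            pd.DataFrame(apl.grid).to_csv(out / "apl_grid_upper.csv")
            order = mem.nematic_order_frame(f0, topology)
            order.to_csv(out / "lipid_order.csv", index=False)
            if peptides:
                nf = mem.near_far_histogram(
                    f0, topology, order,
                    near_cutoff=config.near_cutoff,
                    far_cutoff=config.far_cutoff)
                pd.DataFrame({
                    "bin_lo": nf.edges[:-1], "bin_hi": nf.edges[1:],
                    "near": nf.hist_near, "far": nf.hist_far,
                }).to_csv(out / "order_near_far.csv", index=False)
            edges, counts = mem.z_density(frames, topology,
                                          topology.phosphate_indices())
            pd.DataFrame({"z_lo": edges[:-1], "z_hi": edges[1:],
                          "count": counts}).to_csv(
                out / "phosphate_z_density.csv", index=False)
        stage("membrane", run_membrane)
    else:
        manifest["stages"]["membrane"] = {"status": "skipped",
                                          "reason": "no lipids"}

    # -- interactions / orientation (need two peptides) ---------------------
    if len(peptides) >= 2:
        p1, p2 = peptides[:2]

        def run_contacts():
            cm = inter.contact_map(frames, topology, p1, p2,
                                   mode="calpha", cutoff=config.contact_cutoff)
            cm.freq.to_csv(out / "contact_map.csv")
            n_win = min(config.n_windows, len(frames))
            dom = inter.domain_contact_map(cm, topology, n_windows=n_win,
                                           dt_ns=config.dt_ns)
            for w, df in enumerate(dom.windows):
                df.to_csv(out / f"domain_contacts_w{w}.csv")
            cls = inter.residue_class_contacts(frames, topology, p1, p2,
                                               cutoff=config.class_cutoff)
            cls["class_matrix"].to_csv(out / "class_contacts.csv")
        stage("contacts", run_contacts)

        def run_saltbridges():
            series = inter.salt_bridge_series(
                frames, topology, on_cutoff=config.saltbridge_cutoff)
            occ = inter.bridge_occupancy(series)
            occ.drop(columns="pair_obj").to_csv(out / "saltbridge_occupancy.csv",
                                                index=False)
            lt = inter.bridge_lifetimes(series, dt_ns=config.dt_ns,
                                        gap_tolerance=config.gap_tolerance)
            lt.drop(columns="pair_obj").to_csv(out / "saltbridge_lifetimes.csv",
                                               index=False)
            if len(series):
                traces = inter.top_pairs_timeseries(
                    frames, topology, k=min(5, len(series)),
                    on_cutoff=config.saltbridge_cutoff)
                traces.to_csv(out / "saltbridge_traces.csv")
        stage("saltbridges", run_saltbridges)

        def run_orientation():
            recs = orient.orientation_records(
                frames, topology, cutoff=config.patch_cutoff,
                threshold=config.interaction_threshold)
            res = orient.classify_frames(recs)
            res["table"].to_csv(out / "orientation_records.csv", index=False)
            pd.DataFrame({
                "bin_lo": res["edges"][:-1], "bin_hi": res["edges"][1:],
                "interacting": res["hist_interacting"],
                "non_interacting": res["hist_non_interacting"],
            }).to_csv(out / "cos_theta_hist.csv", index=False)
        stage("orientation", run_orientation)
    else:
        for name in ("contacts", "saltbridges", "orientation"):
            manifest["stages"][name] = {"status": "skipped",
                                        "reason": "fewer than two peptides"}

    # -- z positioning (any peptide) ----------------------------------------
    if peptides:
        def run_zcom():
            for pid in peptides:
                df, edges, counts = orient.zcom_distribution(frames, topology, pid)
                df.to_csv(out / f"zcom_p{pid}.csv", index=False)
                orient.per_residue_zcom(frames, topology, pid).to_csv(
                    out / f"zcom_residues_p{pid}.csv")
        stage("zcom", run_zcom)

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


# ---------------------------------------------------------------------------
# fixture generation


def _pyify(obj):
    if isinstance(obj, dict):
        return {k: _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _fixture_straight_helix(seed, **kw):
    seq = cons.build_construct("extended_AH").sequence
    top, frame, man = syn.make_helix(syn.HelixSpec(seed=seed, **kw), seq)
    return top, [frame], man


def _fixture_bent_helix(seed, bend_radius=60.0, **kw):
    seq = cons.build_construct("extended_AH").sequence
    top, frame, man = syn.make_helix(
        syn.HelixSpec(bend_radius=bend_radius, seed=seed, **kw), seq)
    return top, [frame], man


def _fixture_bilayer(seed, **kw):
    top, frame, man = syn.make_bilayer(syn.BilayerSpec(seed=seed, **kw))
    return top, [frame], man


def _fixture_scene(angle, A, P):
    def build(seed, **kw):
        seq = cons.build_construct("extended_AH").sequence
        spec = syn.TwoPeptideSceneSpec(
            inter_axis_angle=angle, n_forced_contacts_A=A,
            n_forced_contacts_P=P, seed=seed, **kw)
        return syn.make_two_peptide_scene(spec, seq)
    return build


def _fixture_peptide_on_bilayer(seed, **kw):
    seq = cons.build_construct("extended_AH").sequence
    btop, bframe, bman = syn.make_bilayer(syn.BilayerSpec(seed=seed))
    ptop, pframe, _ = syn.make_helix(syn.HelixSpec(seed=seed), seq)
    top, frame = syn.compose_peptide_bilayer((btop, bframe), (ptop, pframe),
                                             z_above_midplane=15.0)
    man = {"kind": "peptide_on_bilayer", "bilayer": bman,
           "z_above_midplane_A": 15.0}
    return top, [frame], man


FIXTURES = {
    "straight_helix": _fixture_straight_helix,
    "bent_helix_r60": _fixture_bent_helix,
    "bilayer_75_25": _fixture_bilayer,
    "antiparallel_scene": _fixture_scene(180.0, 8, 0),
    "parallel_scene": _fixture_scene(0.0, 0, 6),
    "peptide_on_bilayer": _fixture_peptide_on_bilayer,
}


def generate(name: str, output_dir, seed: int = 0, **overrides) -> dict:
    """Write a named synthetic fixture: multi-model PDB + topology sidecar
    + ground-truth manifest.  Returns the manifest."""
    if name not in FIXTURES:
        raise InputError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        )
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    top, frames, man = FIXTURES[name](seed, **overrides)
    save_system(top, frames, out / f"{name}.pdb", out / f"{name}.topology.yaml")
    man = _pyify(man)
    man["files"] = {"trajectory": f"{name}.pdb",
                    "topology": f"{name}.topology.yaml"}
    with open(out / f"{name}.manifest.yaml", "w") as fh:
        yaml.safe_dump(man, fh, sort_keys=False)
    return man
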