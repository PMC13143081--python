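"""Leaflets, Voronoi APL conservation, nematic order, z-density."""

import numpy as np
import pytest

from septah.errors import InputError
from septah.membrane import (
    area_per_lipid,
    assign_leaflets,
    near_far_histogram,
    nematic_order,
    nematic_order_frame,
    z_density,
)
from septah.model import AtomRecord, Topology, TrajectoryFrame
from septah.synthetic import (
    BilayerSpec,
    HelixSpec,
    TiltDistribution,
    compose_peptide_bilayer,
    make_bilayer,
    make_helix,
    set_lipid_tilt,
)


def drop_molecule(topology, frame, molecule_id):
    """Rebuild the system without one molecule (test helper)."""
    keep = [a for a in topology.atoms if a.molecule_id != molecule_id]
    idx = [a.atom_id - 1 for a in keep]
    atoms = [
        AtomRecord(k + 1, a.name, a.element, a.residue_index,
                   a.residue_name, a.molecule_id, a.molecule_kind)
        for k, a in enumerate(keep)
    ]
    top = Topology(atoms=atoms,
                   lipid_annotations=topology.lipid_annotations,
                   regions=topology.regions)
    return top, TrajectoryFrame(frame.time_ns, frame.box, frame.coords[idx])


class TestLeaflets:
    def test_generator_counts_split_evenly(self, lattice_bilayer):
        top, frame, _ = lattice_bilayer
        la = assign_leaflets(frame, top)
        assert len(la.lipids("upper")) == len(la.lipids("lower")) == 100

    def test_midplane_at_box_center(self, lattice_bilayer):
        top, frame, _ = lattice_bilayer
        la = assign_leaflets(frame, top)
        assert la.midplane_z == pytest.approx(frame.box[2] / 2, abs=1e-9)

    def test_flat_single_plane_warns_degenerate(self, lattice_bilayer):
        top, frame, _ = lattice_bilayer
        coords = frame.coords.copy()
        coords[top.phosphate_indices(), 2] = 20.0
        flat = TrajectoryFrame(0.0, frame.box, coords)
        with pytest.warns(UserWarning, match="degenerate"):
            la = assign_leaflets(flat, top)
        assert la.degenerate
        assert len(la.lipids("upper")) == 200


class TestAreaPerLipid:
    def test_uniform_lattice_gives_spacing_squared(self, lattice_bilayer):
        top, frame, _ = lattice_bilayer
        apl = area_per_lipid(frame, top)
        areas = np.array(list(apl.area_of.values()))
        np.testing.assert_allclose(areas, 64.0, atol=1e-6)

    def test_partition_sums_to_box_area(self, lattice_bilayer):
        top, frame, _ = lattice_bilayer
        apl = area_per_lipid(frame, top)
        assert apl.total_area == pytest.approx(
            frame.box[0] * frame.box[1], rel=1e-9)

    def test_vacancy_redistributes_to_neighbors(self, lattice_bilayer):
        # oracle: re-tessellation after removing one lattice lipid must
        # hand its 64 A^2 to the four XY neighbours, conserving the total
        top, frame, _ = lattice_bilayer
        la = assign_leaflets(frame, top)
        victim = la.lipids("upper")[44]
        vic_xy = frame.coords[top.phosphate_index(victim), :2]
        top2, frame2 = drop_molecule(top, frame, victim)
        apl = area_per_lipid(frame2, top2)
        assert apl.total_area == pytest.approx(
            frame.box[0] * frame.box[1], rel=1e-9)
        gained = {lid: a for lid, a in apl.area_of.items()
                  if a > 64.0 + 1e-9}
        assert len(gained) == 4
        for lid in gained:
            d = np.linalg.norm(
                frame2.coords[top2.phosphate_index(lid), :2] - vic_xy)
            assert d == pytest.approx(8.0, abs=1e-6)
            assert gained[lid] == pytest.approx(64.0 + 16.0, abs=1e-6)

    def test_coincident_seeds_perturbed_with_warning(self, lattice_bilayer):
        top, frame, _ = lattice_bilayer
        la = assign_leaflets(frame, top)
        up = la.lipids("upper")
        coords = frame.coords.copy()
        i, j = top.phosphate_index(up[0]), top.phosphate_index(up[1])
        coords[j, :2] = coords[i, :2]
        clash = TrajectoryFrame(0.0, frame.box, coords)
        with pytest.warns(UserWarning, match="coincident"):
            apl = area_per_lipid(clash, top, la)
        assert apl.total_area == pytest.approx(
            frame.box[0] * frame.box[1], rel=1e-9)

    def test_small_leaflet_rejected(self, straight_helix):
        top, frame, _ = straight_helix
        with pytest.raises(InputError):
            area_per_lipid(frame, top)


class TestNematicOrder:
    @pytest.mark.parametrize("theta, expected", [
        (0.0, 1.0), (54.7356103, 0.0), (90.0, -0.5),
    ])
    def test_exact_values_at_reference_tilts(self, theta, expected):
        top, frame, _ = make_bilayer(
            BilayerSpec(nx=5, ny=5, tilt=TiltDistribution("fixed",
                                                          theta0_deg=theta),
                        seed=3))
        for lid in top.lipid_ids[:5]:
            assert nematic_order(frame, top, lid).S == \
                pytest.approx(expected, abs=1e-6)

    def test_gaussian_ensemble_matches_analytic_within_three_se(self):
        tilt = TiltDistribution("gaussian", mu_deg=25.0, sigma_deg=10.0)
        top, frame, man = make_bilayer(
            BilayerSpec(nx=16, ny=16, tilt=tilt, seed=0))
        df = nematic_order_frame(frame, top)
        se = df.S.std(ddof=1) / np.sqrt(len(df))
        assert abs(df.S.mean() - man["analytic_S"]) < 3 * se

    def test_invariant_to_xy_translation_and_z_inversion(
        self, gaussian_bilayer
    ):
        top, frame, _ = gaussian_bilayer
        base = nematic_order_frame(frame, top).S.values
        shifted = TrajectoryFrame(
            0.0, frame.box, frame.coords + np.array([13.0, -7.0, 0.0]))
        flipped = TrajectoryFrame(
            0.0, frame.box,
            frame.coords * np.array([1.0, 1.0, -1.0])
            + np.array([0.0, 0.0, frame.box[2]]))
        np.testing.assert_allclose(
            nematic_order_frame(shifted, top).S.values, base, atol=1e-12)
        np.testing.assert_allclose(
            nematic_order_frame(flipped, top).S.values, base, atol=1e-12)


class TestNearFar:
    def test_planted_disorder_near_peptide(self, lattice_bilayer,
                                           ah_sequence):
        top_b, frame_b, _ = lattice_bilayer
        ptop, pframe, _ = make_helix(HelixSpec(seed=1), ah_sequence)
        top, frame = compose_peptide_bilayer((top_b, frame_b),
                                             (ptop, pframe), 15.0)
        pep = top.select(kind="peptide", heavy=True)
        phos = top.phosphate_indices()
        d = np.linalg.norm(
            (frame.coords[phos, None, :2] - frame.coords[None, pep, :2]),
            axis=-1).min(axis=1)
        near_ids = [lid for lid, dd in zip(top.lipid_ids, d) if dd <= 10.0]
        assert near_ids
        for lid in near_ids:
            frame = set_lipid_tilt(top, frame, lid, 80.0, azimuth_deg=30.0)
        nf = near_far_histogram(frame, top)
        assert nf.mean_near < nf.mean_far
        assert nf.mean_far == pytest.approx(1.0, abs=1e-9)

    def test_no_peptide_all_far(self, lattice_bilayer):
        top, frame, _ = lattice_bilayer
        with pytest.warns(UserWarning, match="empty near"):
            nf = near_far_histogram(frame, top)
        assert nf.n_near == 0
        assert nf.n_far == len(top.lipid_ids)

    def test_bad_cutoffs_rejected(self, lattice_bilayer):
        top, frame, _ = lattice_bilayer
        with pytest.raises(InputError):
            near_far_histogram(frame, top, near_cutoff=25.0, far_cutoff=10.0)


class TestZDensity:
    def test_two_modes_at_half_separation(self, lattice_bilayer):
        top, frame, man = lattice_bilayer
        edges, counts = z_density([frame], top, top.phosphate_indices())
        centers = (edges[:-1] + edges[1:]) / 2
        occupied = centers[counts > 0]
        half = man["leaflet_separation_A"] / 2
        assert np.all(np.abs(np.abs(occupied) - half) < 1.0)

    def test_doubling_frames_doubles_counts(self, lattice_bilayer):
        top, frame, _ = lattice_bilayer
        sel = top.phosphate_indices()
        _, once = z_density([frame], top, sel)
        _, twice = z_density([frame, frame], top, sel)
        np.testing.assert_array_equal(twice, 2 * once)

    def test_empty_selection_rejected(self, lattice_bilayer):
        top, frame, _ = lattice_bilayer
        with pytest.raises(InputError):
            z_density([frame], top, np.array([], dtype=int))
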