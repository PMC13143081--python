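"""Axis vectors, patch contact counts, frame classification, z-COM."""

import numpy as np
import pytest

from conftest import brute_force_residue_contacts
from septah.errors import DegenerateGeometryError, InputError
from septah.model import TrajectoryFrame
from septah.orientation import (
    OrientationRecord,
    axis_vector,
    classify_frames,
    orientation_records,
    patch_contact_counts,
    per_residue_zcom,
    zcom_distribution,
)
from septah.synthetic import HelixSpec, make_helix, merge_systems


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


class TestAxisVector:
    def test_straight_helix_points_along_x(self, straight_helix):
        top, frame, _ = straight_helix
        v = axis_vector(frame, top, 1)
        assert np.linalg.norm(v - np.array([1.0, 0.0, 0.0])) < 0.05

    def test_rotation_equivariance(self, straight_helix):
        top, frame, _ = straight_helix
        r = rotation_matrix([1.0, 2.0, 3.0], 1.1)
        rotated = TrajectoryFrame(0.0, frame.box, frame.coords @ r.T)
        v0 = axis_vector(frame, top, 1)
        v1 = axis_vector(rotated, top, 1)
        np.testing.assert_allclose(v1, r @ v0, atol=1e-12)

    def test_bent_helix_matches_direct_com_chord(self, bent_helix_r60):
        # oracle: recompute both patch COMs directly and normalise
        top, frame, _ = bent_helix_r60
        regions = top.regions
        idx = top.select(molecule_id=1, heavy=True)
        res = top.residue_index_per_atom[idx]

        def com(lo, hi):
            return frame.coords[idx[(res >= lo) & (res <= hi)]].mean(axis=0)

        chord = com(*regions.c_patch) - com(*regions.n_patch)
        chord /= np.linalg.norm(chord)
        np.testing.assert_allclose(axis_vector(frame, top, 1), chord,
                                   atol=1e-12)

    def test_coincident_patches_degenerate(self, straight_helix):
        top, frame, _ = straight_helix
        coords = frame.coords.copy()
        idx = top.select(molecule_id=1, heavy=True)
        coords[idx] = 0.0
        flat = TrajectoryFrame(0.0, frame.box, coords)
        with pytest.raises(DegenerateGeometryError):
            axis_vector(flat, top, 1)


class TestPatchContacts:
    def test_scene_manifest_recovered(self, antiparallel_scene):
        top, frames, man = antiparallel_scene
        a, p = patch_contact_counts(frames[0], top)
        assert (a, p) == (man["A"], man["P"]) == (8, 0)

    def test_matches_brute_force_oracle(self, antiparallel_scene):
        top, frames, _ = antiparallel_scene
        regions = top.regions
        a_oracle = len(brute_force_residue_contacts(
            frames[0].coords, top, 1, regions.n_patch, 2,
            regions.second_half, 4.5, strict=True)) + \
            len(brute_force_residue_contacts(
                frames[0].coords, top, 2, regions.n_patch, 1,
                regions.second_half, 4.5, strict=True))
        p_oracle = len(brute_force_residue_contacts(
            frames[0].coords, top, 1, regions.c_patch, 2,
            regions.second_half, 4.5, strict=True)) + \
            len(brute_force_residue_contacts(
                frames[0].coords, top, 2, regions.c_patch, 1,
                regions.second_half, 4.5, strict=True))
        assert patch_contact_counts(frames[0], top) == (a_oracle, p_oracle)

    def test_separated_peptides_zero(self, ah_sequence):
        t1, f1, _ = make_helix(HelixSpec(seed=1), ah_sequence)
        t2, f2, _ = make_helix(HelixSpec(seed=1), ah_sequence)
        f2 = TrajectoryFrame(0.0, f2.box, f2.coords + np.array([0, 0, 100.0]))
        top, frame = merge_systems([(t1, f1), (t2, f2)], box=(400, 400, 400))
        assert patch_contact_counts(frame, top) == (0, 0)

    def test_raising_cutoff_never_decreases(self, antiparallel_scene):
        top, frames, _ = antiparallel_scene
        a1, p1 = patch_contact_counts(frames[0], top, cutoff=4.5)
        a2, p2 = patch_contact_counts(frames[0], top, cutoff=6.5)
        assert a2 >= a1 and p2 >= p1


def _record(A, P, cos_theta=-0.95, threshold=5):
    interacting = (A + P) > threshold
    if not interacting:
        label = "none"
    elif A > P:
        label = "antiparallel_like"
    elif P > A:
        label = "parallel_like"
    else:
        label = "mixed"
    return OrientationRecord(0, np.array([1.0, 0, 0]),
                             np.array([-1.0, 0, 0]), cos_theta, A, P,
                             interacting, label)


class TestClassification:
    def test_antiparallel_scene_all_frames(self, antiparallel_scene):
        top, frames, _ = antiparallel_scene
        recs = orientation_records(frames, top)
        assert all(r.label == "antiparallel_like" for r in recs)
        assert all(r.cos_theta < -0.99 for r in recs)
        res = classify_frames(recs)
        assert res["fraction_interacting"] == 1.0

    def test_parallel_scene_all_frames(self, parallel_scene):
        top, frames, _ = parallel_scene
        recs = orientation_records(frames, top)
        assert all(r.label == "parallel_like" for r in recs)
        assert all(r.cos_theta > 0.99 for r in recs)

    def test_threshold_is_strict_inequality(self, ah_sequence):
        from septah.synthetic import TwoPeptideSceneSpec, make_two_peptide_scene

        top5, f5, _ = make_two_peptide_scene(
            TwoPeptideSceneSpec(inter_axis_angle=180.0,
                                n_forced_contacts_A=3,
                                n_forced_contacts_P=2, seed=3), ah_sequence)
        r5 = orientation_records(f5, top5)[0]
        assert r5.T == 5 and not r5.interacting and r5.label == "none"

        top6, f6, _ = make_two_peptide_scene(
            TwoPeptideSceneSpec(inter_axis_angle=180.0,
                                n_forced_contacts_A=4,
                                n_forced_contacts_P=2, seed=3), ah_sequence)
        r6 = orientation_records(f6, top6)[0]
        assert r6.T == 6 and r6.interacting and r6.label == "antiparallel_like"

    def test_tie_labelled_mixed(self):
        r = _record(4, 4)
        assert r.interacting and r.label == "mixed"

    def test_histograms_split_by_flag(self):
        recs = [_record(8, 0, -0.97), _record(0, 0, 0.2), _record(0, 0, 0.4)]
        res = classify_frames(recs, bins=np.linspace(-1, 1, 5))
        assert res["hist_interacting"].sum() == 1
        assert res["hist_non_interacting"].sum() == 2

    def test_empty_records_rejected(self):
        with pytest.raises(InputError):
            classify_frames([])


class TestZcom:
    def test_fixed_height_reported(self, straight_helix):
        top, frame, _ = straight_helix
        idx = top.select(molecule_id=1, heavy=True)
        coords = frame.coords.copy()
        coords[:, 2] += 30.0 - frame.coords[idx, 2].mean()
        f = TrajectoryFrame(0.0, frame.box, coords)
        df, edges, counts = zcom_distribution([f] * 4, top, 1)
        np.testing.assert_allclose(df["z_com"], 30.0, atol=1e-9)
        assert counts.sum() == 4

    def test_z_inversion_negates(self, straight_helix):
        top, frame, _ = straight_helix
        df1, _, _ = zcom_distribution([frame], top, 1)
        flipped = TrajectoryFrame(0.0, frame.box,
                                  frame.coords * np.array([1.0, 1.0, -1.0]))
        df2, _, _ = zcom_distribution([flipped], top, 1)
        assert df2["z_com"].iloc[0] == pytest.approx(-df1["z_com"].iloc[0])

    def test_tilted_helix_monotone_residue_heights(self, straight_helix):
        # spin the helix about its own axis across frames so the median
        # per-residue height reflects the axis, then tilt N-term down:
        # medians must increase with residue index
        top, frame, _ = straight_helix
        tilt = rotation_matrix([0.0, 1.0, 0.0], -np.radians(30.0))
        frames = []
        for k, phase in enumerate(np.linspace(0, 2 * np.pi, 12,
                                              endpoint=False)):
            spin = rotation_matrix([1.0, 0.0, 0.0], phase)
            frames.append(TrajectoryFrame(
                float(k), frame.box, frame.coords @ spin.T @ tilt.T))
        df = per_residue_zcom(frames, top, 1)
        medians = df["median"].values
        assert np.all(np.diff(medians) > 0)

    def test_single_frame_quartiles_collapse(self, straight_helix):
        top, frame, _ = straight_helix
        df = per_residue_zcom([frame], top, 1)
        np.testing.assert_allclose(df["min"], df["max"], atol=1e-12)
        np.testing.assert_allclose(df["q1"], df["median"], atol=1e-12)
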