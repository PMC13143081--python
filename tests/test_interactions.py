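"""Contact maps, class contacts and salt-bridge statistics vs oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_residue_contacts
from septah.errors import InputError
from septah.interactions import (
    SaltBridgePair,
    bridge_lifetimes,
    bridge_occupancy,
    contact_map,
    detect_salt_bridges,
    domain_contact_map,
    events_from_series,
    headgroup_contact_profile,
    residue_class_contacts,
    salt_bridge_series,
    top_pairs_timeseries,
)
from septah.model import AtomRecord, Topology, TrajectoryFrame
from septah.synthetic import (
    HelixSpec,
    TelegraphSpec,
    compose_peptide_bilayer,
    make_bilayer,
    BilayerSpec,
    make_helix,
    make_telegraph_series,
    make_two_peptide_scene,
    merge_systems,
    TwoPeptideSceneSpec,
)


def separated_pair(ah_sequence, offset=(0.0, 0.0, 100.0)):
    t1, f1, _ = make_helix(HelixSpec(seed=1), ah_sequence)
    t2, f2, _ = make_helix(HelixSpec(seed=1), ah_sequence)
    f2 = TrajectoryFrame(0.0, f2.box, f2.coords + np.asarray(offset))
    return merge_systems([(t1, f1), (t2, f2)], box=(300, 300, 300))


class TestContactMap:
    def test_far_separated_peptides_no_contacts(self, ah_sequence):
        top, frame = separated_pair(ah_sequence)
        cm = contact_map([frame], top, 1, 2, mode="calpha", cutoff=7.5)
        assert cm.freq.values.sum() == 0

    def test_intra_diagonal_is_unity(self, straight_helix):
        top, frame, _ = straight_helix
        cm = contact_map([frame], top, 1, mode="calpha", cutoff=7.5)
        assert np.all(np.diag(cm.freq.values) == 1.0)
        np.testing.assert_array_equal(cm.freq.values, cm.freq.values.T)

    def test_heavy_mode_matches_brute_force_oracle(self, antiparallel_scene):
        top, frames, _ = antiparallel_scene
        n = top.n_residues(1)
        cm = contact_map(frames[:1], top, 1, 2, mode="heavy", cutoff=4.5)
        oracle = brute_force_residue_contacts(
            frames[0].coords, top, 1, (1, n), 2, (1, n), 4.5)
        got = {(i + 1, j + 1) for i, j in zip(*np.nonzero(cm.freq.values))}
        assert got == oracle

    def test_calpha_mode_matches_brute_force_oracle(self, antiparallel_scene):
        top, frames, _ = antiparallel_scene
        n = top.n_residues(1)
        cm = contact_map(frames[:1], top, 1, 2, mode="calpha", cutoff=7.5)
        ca1 = top.calpha_indices(1)
        ca2 = top.calpha_indices(2)
        oracle = {
            (i + 1, j + 1)
            for i in range(n) for j in range(n)
            if np.linalg.norm(frames[0].coords[ca1[i]]
                              - frames[0].coords[ca2[j]]) <= 7.5
        }
        got = {(i + 1, j + 1) for i, j in zip(*np.nonzero(cm.freq.values))}
        assert got == oracle

    def test_monotone_in_cutoff(self, antiparallel_scene):
        top, frames, _ = antiparallel_scene
        small = contact_map(frames, top, 1, 2, mode="heavy", cutoff=4.0)
        large = contact_map(frames, top, 1, 2, mode="heavy", cutoff=6.0)
        assert np.all(small.freq.values <= large.freq.values + 1e-12)

    def test_bad_cutoff_rejected(self, antiparallel_scene):
        top, frames, _ = antiparallel_scene
        with pytest.raises(InputError):
            contact_map(frames, top, 1, 2, cutoff=-1.0)


class TestDomainMap:
    def test_uniform_map_gives_unit_cells(self, antiparallel_scene):
        top, frames, _ = antiparallel_scene
        cm = contact_map(frames, top, 1, 2, mode="heavy", cutoff=500.0)
        dom = domain_contact_map(cm, top, n_windows=3)
        for df in dom.windows:
            np.testing.assert_allclose(df.values, 1.0)

    def test_single_window_equals_whole_mean(self, antiparallel_scene):
        top, frames, _ = antiparallel_scene
        cm = contact_map(frames, top, 1, 2, mode="heavy", cutoff=4.5)
        dom = domain_contact_map(cm, top, n_windows=1)
        regions = top.regions
        blocks = {"N-term": regions.residues("n_patch"),
                  "AH": regions.residues("ah_core"),
                  "C-term": regions.residues("c_patch")}
        for la, ra in blocks.items():
            for lb, rb in blocks.items():
                expect = cm.freq.values[np.ix_(
                    np.array(list(ra)) - 1, np.array(list(rb)) - 1)].mean()
                assert dom.windows[0].loc[la, lb] == pytest.approx(expect)

    def test_planted_block_isolated(self, antiparallel_scene):
        # the antiparallel scene forces N-patch(1) x C-term-region(2)
        # contacts only; at the forcing cutoff the coarse map must be zero
        # outside rows involving those regions
        top, frames, _ = antiparallel_scene
        cm = contact_map(frames, top, 1, 2, mode="heavy", cutoff=4.5)
        dom = domain_contact_map(cm, top, n_windows=1)
        df = dom.windows[0]
        assert df.loc["N-term", "C-term"] > 0
        assert df.loc["AH", "AH"] == 0
        assert df.loc["C-term", "N-term"] == 0

    def test_more_windows_than_frames_rejected(self, antiparallel_scene):
        top, frames, _ = antiparallel_scene
        cm = contact_map(frames, top, 1, 2)
        with pytest.raises(InputError):
            domain_contact_map(cm, top, n_windows=len(frames) + 1)


class TestClassContacts:
    def test_single_salt_pair_counts_one_acidic_basic(self, ah_sequence):
        top, frame = separated_pair(ah_sequence)
        coords = frame.coords.copy()
        e10 = [i for i in top.select(molecule_id=1, names=["OE1"])
               if top.residue_index_per_atom[i] == 10][0]
        k18 = [i for i in top.select(molecule_id=2, names=["NZ"])
               if top.residue_index_per_atom[i] == 18][0]
        coords[e10] = coords[k18] + np.array([3.0, 0.0, 0.0])
        f = TrajectoryFrame(0.0, frame.box, coords)
        res = residue_class_contacts([f], top, 1, 2, cutoff=3.5)
        assert res["total"] == 1
        assert res["class_matrix"].loc["acidic", "basic"] == 1
        assert res["per_residue_1"][9] == 1

    def test_no_close_atoms_no_counts(self, ah_sequence):
        top, frame = separated_pair(ah_sequence)
        res = residue_class_contacts([frame], top, 1, 2)
        assert res["total"] == 0

    def test_class_totals_partition_total(self, antiparallel_scene):
        top, frames, _ = antiparallel_scene
        res = residue_class_contacts(frames, top, 1, 2, cutoff=4.5)
        assert res["class_matrix"].values.sum() == res["total"]
        assert res["per_residue_1"].sum() == res["total"]


class TestHeadgroupProfile:
    @pytest.fixture()
    def peptide_over_bilayer(self, ah_sequence):
        # the box must exceed the ~51 A helix span so periodic images of
        # the peptide termini cannot create wrap-around contacts
        btop, bframe, _ = make_bilayer(BilayerSpec(nx=9, ny=6, seed=4))
        ptop, pframe, _ = make_helix(HelixSpec(seed=1), ah_sequence)
        return compose_peptide_bilayer((btop, bframe), (ptop, pframe), 40.0)

    def test_distant_peptide_all_zero(self, peptide_over_bilayer):
        top, frame = peptide_over_bilayer
        prof = headgroup_contact_profile([frame], top, top.peptide_ids[0],
                                         cutoff=6.0)
        assert (prof.values == 0).all()

    def test_planted_contact_localised_to_species_and_residue(
        self, peptide_over_bilayer
    ):
        top, frame = peptide_over_bilayer
        pid = top.peptide_ids[0]
        plpi = [lid for lid, sp in top.lipid_species.items()
                if sp == "PLPI"][0]
        # plant the phosphate 3 A beyond the terminal lysine's charged
        # tip, pointing radially away from the helix, so only residue 34
        # can be within the 3.5 A cutoff
        nz34 = [i for i in top.select(molecule_id=pid, names=["NZ"])
                if top.residue_index_per_atom[i] == 34][0]
        ca34 = [i for i in top.select(molecule_id=pid, names=["CA"])
                if top.residue_index_per_atom[i] == 34][0]
        out_dir = frame.coords[nz34] - frame.coords[ca34]
        out_dir /= np.linalg.norm(out_dir)
        coords = frame.coords.copy()
        coords[top.phosphate_index(plpi)] = coords[nz34] + 3.0 * out_dir
        f = TrajectoryFrame(0.0, frame.box, coords)
        prof = headgroup_contact_profile([f], top, pid, cutoff=3.5)
        assert prof.loc[34, "PLPI"] == 1.0
        assert prof["PLPI"].drop(34).sum() == 0
        assert prof["DOPC"].sum() == 0


def _two_residue_system(distances):
    """One GLU (OE1/OE2) and one ARG (NH1/NH2/NE) on separate peptides,
    O-N distances prescribed per (O, N) pair."""
    atoms = [
        AtomRecord(1, "CA", "C", 1, "GLU", 1, "peptide"),
        AtomRecord(2, "OE1", "O", 1, "GLU", 1, "peptide"),
        AtomRecord(3, "OE2", "O", 1, "GLU", 1, "peptide"),
        AtomRecord(4, "CA", "C", 1, "ARG", 2, "peptide"),
        AtomRecord(5, "NH1", "N", 1, "ARG", 2, "peptide"),
        AtomRecord(6, "NH2", "N", 1, "ARG", 2, "peptide"),
        AtomRecord(7, "NE", "N", 1, "ARG", 2, "peptide"),
    ]
    top = Topology(atoms=atoms, lipid_annotations={})
    coords = np.array([
        [0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0],
        [50.0, 0.0, 0.0],
        [10.0, 10.0, 10.0],
        [distances.get("OE1-NH1", 50.0), 0.0, 0.0],
        [distances.get("OE1-NH2", 50.0), 5.0, 0.0],
        [distances.get("OE1-NE", 50.0), -5.0, 0.0],
    ])
    frame = TrajectoryFrame(0.0, (300, 300, 300), coords)
    return top, frame


class TestSaltBridges:
    def test_active_at_three_angstrom(self, ah_sequence):
        top, frame = _two_residue_system({"OE1-NH1": 3.0})
        active = detect_salt_bridges(frame, top)
        assert len(active) == 1
        assert next(iter(active)).label == "R1-E1"

    def test_inactive_at_three_point_five(self):
        top, frame = _two_residue_system({"OE1-NH1": 3.5})
        assert detect_salt_bridges(frame, top) == set()

    def test_residue_level_dedup_over_multiple_atom_pairs(self):
        # three O-N atom pairs below cutoff must still yield one pair
        top, frame = _two_residue_system(
            {"OE1-NH1": 3.0, "OE1-NH2": 2.5, "OE1-NE": 3.1})
        assert len(detect_salt_bridges(frame, top)) == 1

    def test_missing_named_atoms_reported(self):
        atoms = [
            AtomRecord(1, "CA", "C", 1, "GLU", 1, "peptide"),
            AtomRecord(2, "CA", "C", 1, "LYS", 2, "peptide"),
        ]
        top = Topology(atoms=atoms, lipid_annotations={})
        frame = TrajectoryFrame(0.0, (100, 100, 100), np.zeros((2, 3)))
        with pytest.raises(InputError, match="GLU1"):
            detect_salt_bridges(frame, top)


class TestOccupancyAndLifetimes:
    def test_always_on_occupancy_one(self):
        p = SaltBridgePair(1, 10, 2, 18)
        df = bridge_occupancy({p: np.ones(400, dtype=bool)})
        assert df.loc[0, "occupancy_mean"] == 1.0

    def test_never_active_pairs_absent(self, antiparallel_scene):
        top, frames, _ = antiparallel_scene
        series = salt_bridge_series(frames, top)
        for s in series.values():
            assert s.any()

    def test_replica_mean_and_sd(self):
        p = SaltBridgePair(1, 10, 2, 18)
        reps = [{p: np.array([True, True, False, False])},
                {p: np.array([True, False, False, False])}]
        df = bridge_occupancy(reps)
        assert df.loc[0, "occupancy_mean"] == pytest.approx(0.375)
        assert df.loc[0, "occupancy_sd"] == pytest.approx(
            np.std([0.5, 0.25], ddof=1))

    def test_hand_pattern_two_events(self):
        s = np.array([True] * 10 + [False] * 5 + [True] * 10)
        df = bridge_lifetimes(s, dt_ns=1.0)
        row = df.iloc[0]
        assert row["n_events"] == 2
        assert row["total_on_ns"] == 20.0
        assert row["median_ns"] == 10.0

    def test_gap_tolerance_merges_events(self):
        s = np.array([True] * 10 + [False] * 5 + [True] * 10)
        df = bridge_lifetimes(s, dt_ns=1.0, gap_tolerance=5)
        assert df.iloc[0]["n_events"] == 1
        assert df.iloc[0]["total_on_ns"] == 25.0

    def test_telegraph_mean_on_time_within_three_se(self):
        spec = TelegraphSpec(n_frames=100_000, dt_ns=0.25, mean_on_ns=20.0,
                             mean_off_ns=20.0, seed=9)
        series, summary = make_telegraph_series(spec)
        df = bridge_lifetimes(series, dt_ns=spec.dt_ns)
        runs = events_from_series(series)
        durations = np.array([(e - s + 1) * spec.dt_ns for s, e in runs])
        se = durations.std(ddof=1) / np.sqrt(len(durations))
        assert abs(df.iloc[0]["mean_ns"] - summary["true_mean_on_ns"]) \
            < 3 * se

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=200),
           st.floats(0.1, 10.0))
    def test_event_durations_partition_on_time(self, bits, dt):
        series = np.array(bits, dtype=bool)
        runs = events_from_series(series, gap_tolerance=0)
        total = sum((e - s + 1) * dt for s, e in runs)
        assert total == pytest.approx(series.sum() * dt)


class TestTopPairs:
    def test_single_pair_with_warning(self):
        top, frame = _two_residue_system({"OE1-NH1": 2.9})
        with pytest.warns(UserWarning, match="only 1 pairs"):
            traces = top_pairs_timeseries([frame] * 3, top, k=3)
        assert traces.shape == (3, 1)

    def test_constant_distance_flat_trace(self):
        top, frame = _two_residue_system({"OE1-NH1": 2.9})
        traces = top_pairs_timeseries([frame] * 4, top, k=1)
        np.testing.assert_allclose(traces.values, 2.9, atol=1e-9)

    def test_ranking_matches_occupancy_order(self, ah_sequence):
        p_hi = SaltBridgePair(1, 10, 2, 18)
        p_lo = SaltBridgePair(1, 21, 2, 4, "GLU", "ARG")
        series = {p_hi: np.array([True, True, True]),
                  p_lo: np.array([True, False, False])}
        occ = bridge_occupancy(series)
        assert list(occ["pair"]) == [p_hi.label, p_lo.label]
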