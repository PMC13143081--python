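import numpy as np
import pytest

from septah.constructs import build_construct
from septah.synthetic import (
    BilayerSpec,
    HelixSpec,
    TiltDistribution,
    TwoPeptideSceneSpec,
    make_bilayer,
    make_helix,
    make_two_peptide_scene,
)


@pytest.fixture(scope="session")
def ah_sequence():
    return build_construct("extended_AH").sequence


@pytest.fixture(scope="session")
def straight_helix(ah_sequence):
    top, frame, man = make_helix(HelixSpec(seed=1), ah_sequence)
    return top, frame, man


@pytest.fixture(scope="session")
def bent_helix_r60(ah_sequence):
    top, frame, man = make_helix(HelixSpec(bend_radius=60.0, seed=1),
                                 ah_sequence)
    return top, frame, man


@pytest.fixture(scope="session")
def lattice_bilayer():
    """10x10 per leaflet, 8 A spacing, tails straight down (S = 1)."""
    top, frame, man = make_bilayer(
        BilayerSpec(nx=10, ny=10, spacing=8.0, seed=1))
    return top, frame, man


@pytest.fixture(scope="session")
def gaussian_bilayer():
    tilt = TiltDistribution("gaussian", mu_deg=25.0, sigma_deg=10.0)
    top, frame, man = make_bilayer(
        BilayerSpec(nx=12, ny=12, tilt=tilt, seed=7))
    return top, frame, man


@pytest.fixture(scope="session")
def antiparallel_scene(ah_sequence):
    """cos(theta) = -1 scene with 8 forced A-contacts, 3 static frames."""
    top, frames, man = make_two_peptide_scene(
        TwoPeptideSceneSpec(inter_axis_angle=180.0, n_forced_contacts_A=8,
                            n_frames=3, seed=2),
        ah_sequence,
    )
    return top, frames, man


@pytest.fixture(scope="session")
def parallel_scene(ah_sequence):
    top, frames, man = make_two_peptide_scene(
        TwoPeptideSceneSpec(inter_axis_angle=0.0, n_forced_contacts_P=6,
                            n_frames=2, seed=2),
        ah_sequence,
    )
    return top, frames, man


def brute_force_residue_contacts(coords, topology, pid_a, range_a, pid_b,
                                 range_b, cutoff, heavy=True,
                                 strict=False):
    """Independent all-pairs oracle: residue pairs with any qualifying
    atom-atom distance below (<) or at/below (<=) the cutoff."""
    res_a = topology.residue_atom_indices(pid_a, heavy=heavy)
    res_b = topology.residue_atom_indices(pid_b, heavy=heavy)
    pairs = set()
    for ra in range(range_a[0], range_a[1] + 1):
        for rb in range(range_b[0], range_b[1] + 1):
            hit = False
            for i in res_a.get(ra, []):
                for j in res_b.get(rb, []):
                    d = float(np.linalg.norm(coords[i] - coords[j]))
                    if (d < cutoff) if strict else (d <= cutoff):
                        hit = True
                        break
                if hit:
                    break
            if hit:
                pairs.add((ra, rb))
    return pairs
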