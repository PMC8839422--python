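import numpy as np
import pytest

import mgatekit as mg


def make_ca_structure(res_numbers, coords, res_names=None, chain="A"):
    """One-CA-per-residue structure from explicit coordinates."""
    res_names = res_names or {}
    residues = []
    for i, (num, xyz) in enumerate(zip(res_numbers, coords), start=1):
        residues.append(mg.Residue(
            int(num), res_names.get(int(num), "ALA"), chain,
            [mg.Atom(i, "CA", "C", np.asarray(xyz, dtype=float))],
        ))
    return mg.Structure(residues)


def make_arg_guanidinium(resnum, centroid, normal, serial_start=1):
    """An ARG residue whose guanidinium plane has the given centroid/normal."""
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    # two orthonormal in-plane directions
    helper = np.array([1.0, 0.0, 0.0])
    if abs(helper @ normal) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    centroid = np.asarray(centroid, dtype=float)
    # CZ, NH1, NH2, NE placed symmetrically in the plane around the centroid
    offsets = [0.65 * e1, -0.65 * e1 + 1.1 * e2, -0.65 * e1 - 1.1 * e2, 0.65 * e2]
    mean_off = np.mean(offsets, axis=0)
    atoms = []
    for k, (name, off) in enumerate(zip(("CZ", "NH1", "NH2", "NE"), offsets)):
        atoms.append(mg.Atom(serial_start + k, name, name[0],
                             centroid + off - mean_off))
    return mg.Residue(resnum, "ARG", "A", atoms)


@pytest.fixture
def aac_helix_map():
    """Transmembrane helix ranges of the bovine carrier fold used for
    intra-/inter-helical classification fixtures."""
    return mg.HelixMap(segments={
        "H1": (5, 36),
        "H2": (73, 98),
        "C1": (99, 106),
        "H3": (107, 140),
        "H4": (176, 210),
        "H5": (223, 256),
        "H6": (270, 290),
    })


@pytest.fixture
def toy_spec_plain():
    return mg.ToyCarrierSpec(helix_length=12, n_frames=1, seed=11)


@pytest.fixture
def toy_channels_spec():
    return mg.ToyCarrierSpec(
        helix_length=12, n_frames=400, seed=5, noise_sigma=0.15,
        channels=[
            mg.ChannelSpec(res_a=3, res_b=27, k_on=0.3, k_off=0.2),
            mg.ChannelSpec(res_a=5, res_b=53, k_on=0.1, k_off=0.3),
        ],
    )
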