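import numpy as np
import pytest

from qdpr.geometry import build_backbone
from qdpr.synthetic import DynamicsModel, make_toy_protein
from qdpr.trajectory import DEFAULT_VDW_RADII, Topology, TrajectoryEnsemble

GB1_SEQUENCE = "MTYKLILNGKTLKGETTTEAVDAATAEKVFKQYANDNGVDGEWTYDDATKTFTVTE"


@pytest.fixture(scope="session")
def toy_protein():
    return make_toy_protein(24, seed=11)


@pytest.fixture(scope="session")
def dynamics_model(toy_protein):
    return DynamicsModel(toy_protein)


@pytest.fixture(scope="session")
def helix_trajectory():
    """Single-frame ideal alpha-helix with full backbone + amide hydrogens."""
    n_res = 12
    bb = build_backbone([-57.0] * n_res, [-47.0] * n_res)
    names, elements, res_idx, coords = [], [], [], []
    for i in range(n_res):
        atoms = ["N", "CA", "C", "O"] + (["H"] if i > 0 else [])
        for nm in atoms:
            names.append(nm)
            elements.append(nm[0])
            res_idx.append(i + 1)
            coords.append(bb[nm][i])
    top = Topology(
        atom_names=tuple(names),
        elements=tuple(elements),
        radii=np.array([DEFAULT_VDW_RADII[e] for e in elements]),
        residue_indices=np.array(res_idx),
        residue_names=tuple(["ALA"] * n_res),
    )
    return TrajectoryEnsemble(np.asarray(coords)[None], top)


def single_atom_trajectory(radius=1.6, n_frames=1):
    top = Topology(("X",), ("C",), np.array([radius]), np.array([1]))
    return TrajectoryEnsemble(np.zeros((n_frames, 1, 3)), top)
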