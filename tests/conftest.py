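import numpy as np
import pytest

import biotite.structure.info as ccd_info

from g4kit import quadruplex, synthetic_data
from g4kit.structure_io import Atom, Residue, StructureModel


@pytest.fixture(scope="session")
def parallel_monomer() -> StructureModel:
    return synthetic_data.build_g4(synthetic_data.G4BuildSpec(topology="parallel"))


@pytest.fixture(scope="session")
def antiparallel_monomer() -> StructureModel:
    return synthetic_data.build_g4(synthetic_data.G4BuildSpec(topology="antiparallel"))


@pytest.fixture(scope="session")
def hybrid_monomer() -> StructureModel:
    return synthetic_data.build_g4(synthetic_data.G4BuildSpec(topology="hybrid"))


@pytest.fixture(scope="session")
def parallel_dimer() -> StructureModel:
    return synthetic_data.build_g4(
        synthetic_data.G4BuildSpec(topology="parallel", dimer=True, register=0)
    )


@pytest.fixture(scope="session")
def parallel_core(parallel_monomer):
    tetrads = quadruplex.detect_tetrads(parallel_monomer)
    core = quadruplex.assemble_cores(tetrads)[0]
    quadruplex.classify_topology(core)
    quadruplex.groove_widths(core)
    return core


def residue_from_ccd(res_name: str, chain_id: str = "A", seq_num: int = 1) -> Residue:
    """A complete residue built from the ideal CCD heavy-atom coordinates."""
    arr = ccd_info.residue(res_name)
    res = Residue(chain_id=chain_id, seq_num=seq_num, res_name=res_name)
    for i in range(arr.array_length()):
        if arr.element[i] == "H":
            continue
        res.atoms.append(
            Atom(str(arr.atom_name[i]), str(arr.element[i]), np.array(arr.coord[i], float))
        )
    return res


@pytest.fixture()
def ideal_dg_residue() -> Residue:
    return residue_from_ccd("DG")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
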