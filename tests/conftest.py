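import numpy as np
import pytest

from ppigcn.structures import Atom, ProteinStructure, Residue
from ppigcn.synthetic import GeneratorSpec, make_structure


def pdb_atom_line(serial, name, resname, chain, resnum, x, y, z,
                  occ=1.00, b=0.00, element=None, altloc=" ", record="ATOM  "):
    element = element or name[0]
    name_field = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"{record}{serial:>5d} {name_field:<4s}{altloc}{resname:<3s} {chain}"
        f"{resnum:>4d}    {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def toy_pdb_text():
    """ALA-GLY-SER single chain with full backbone."""
    lines = []
    serial = 1
    for i, resname in enumerate(("ALA", "GLY", "SER")):
        x0 = 3.8 * i
        for name, dx, dy in (("N", -1.2, 0.8), ("CA", 0.0, 0.0),
                             ("C", 1.2, 0.8), ("O", 1.45, 2.0)):
            lines.append(pdb_atom_line(serial, name, resname, "A", i + 1,
                                       x0 + dx, dy, 0.0))
            serial += 1
    lines += ["TER", "END"]
    return "\n".join(lines) + "\n"


@pytest.fixture
def extended_chain():
    return make_structure(GeneratorSpec(
        n_residues=6, geometry="extended_chain", seed=0, protein_id="ext6"))


@pytest.fixture
def ideal_helix():
    return make_structure(GeneratorSpec(
        n_residues=10, geometry="ideal_helix", seed=1, protein_id="helix10"))


@pytest.fixture
def random_walks():
    """A batch of small self-avoiding-walk structures for oracle tests."""
    structures = []
    rng = np.random.default_rng(42)
    for i in range(8):
        n = int(rng.integers(5, 25))
        structures.append(make_structure(GeneratorSpec(
            n_residues=n, geometry="self_avoiding_walk",
            seed=int(rng.integers(0, 2**31 - 1)), protein_id=f"walk{i}")))
    return structures


def single_atom_structure(coord, element="C", aa="ALA", pid="atom"):
    atom = Atom(name="CA", element=element, coord=np.asarray(coord, float))
    res = Residue(chain_id="A", author_number=1, insertion_code="",
                  seq_index=0, aa=aa, atoms=[atom])
    return ProteinStructure(id=pid, residues=[res])


def rigid_motion(structure, rng):
    """Apply a random rotation + translation; returns a new structure."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.normal(scale=20.0, size=3)
    residues = []
    for res in structure.residues:
        atoms = [Atom(name=a.name, element=a.element, coord=R @ a.coord + t)
                 for a in res.atoms]
        residues.append(Residue(
            chain_id=res.chain_id, author_number=res.author_number,
            insertion_code=res.insertion_code, seq_index=res.seq_index,
            aa=res.aa, atoms=atoms))
    return ProteinStructure(id=structure.id, residues=residues)
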