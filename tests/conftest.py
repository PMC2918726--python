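import numpy as np
import pytest

from ensmap.structure_io import AtomRecord, Structure


def make_atom(
    serial,
    xyz,
    name="SCA",
    element="C",
    residue_seq=1,
    chain_id="A",
    atom_class="SCA",
    charge=0.0,
    residue_name="PSR",
):
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_name=residue_name,
        residue_seq=residue_seq,
        chain_id=chain_id,
        coords=np.asarray(xyz, dtype=float),
        atom_class=atom_class,
        is_heavy=element.upper() != "H",
        charge=charge,
    )


@pytest.fixture
def toy_structure():
    """3 residues x 2 atoms (CA + sidechain bead) on a line."""
    atoms = []
    serial = 0
    for res in range(1, 4):
        for name, cls in (("CA", "CAB"), ("SCA", "SCA")):
            serial += 1
            atoms.append(
                make_atom(
                    serial,
                    [3.0 * res, 0.0 if name == "CA" else 2.8, 0.0],
                    name=name,
                    residue_seq=res,
                    atom_class=cls,
                )
            )
    return Structure(0, atoms)


@pytest.fixture
def random_receptor():
    """10 random beads with mixed classes/charges in an 8 A cube."""
    rng = np.random.default_rng(0)
    classes = ["SCA", "SCP", "SCN", "CAB"]
    charges = [0.0, -0.25, 0.45, 0.0]
    atoms = [
        make_atom(
            i + 1,
            rng.uniform(-4, 4, 3),
            residue_seq=i + 1,
            atom_class=classes[i % 4],
            charge=charges[i % 4],
        )
        for i in range(10)
    ]
    return Structure(0, atoms)
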