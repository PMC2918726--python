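"""The 16-fragment organic probe library.

The probes span a range of sizes, hydrophobicities and hydrogen-bonding
capabilities: ethanol, isopropanol, isobutanol, acetone, acetaldehyde,
dimethyl ether, cyclohexane, ethane, acetonitrile, urea, methylamine,
phenol, benzaldehyde, benzene, acetamide and N,N-dimethylformamide.

Each probe is a *rigid, heavy-atom-only* body: geometries are embedded
from SMILES with RDKit (ETKDG, fixed seed) and relaxed with MMFF94, then
hydrogens are folded into their heavy atoms united-atom style — their
Gasteiger charges are added to the parent heavy atom, and the heavy
atom's nonbonded class encodes its hydrogen count.  The body frame is
centered on the heavy-atom centroid.

Nonbonded parameters are a small internal atom-class table (Angstrom,
kJ/mol) with Lorentz–Berthelot combining, in the spirit of united-atom
force fields.  They are deliberately generic: the scoring function they
feed is a transparent stand-in for empirical hot-spot scoring functions,
not a re-derivation of one.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

__all__ = ["ProbeType", "ATOM_CLASSES", "default_probe_library", "get_probe"]

#: atom class -> (sigma A, epsilon kJ/mol).  Probe classes are united-atom
#: carbons/oxygens/nitrogens; SCA/SCP/SCN/CAB are the pseudo-receptor beads.
ATOM_CLASSES: dict[str, tuple[float, float]] = {
    "C3": (3.775, 0.695),   # CH3
    "C2": (3.905, 0.494),   # CH2
    "C1": (3.850, 0.335),   # CH / quaternary C
    "CAR": (3.750, 0.460),  # aromatic CH
    "CO": (3.750, 0.440),   # sp2 carbonyl/amide carbon
    "O": (2.960, 0.879),    # carbonyl oxygen
    "OH": (3.070, 0.711),   # hydroxyl oxygen
    "OE": (3.000, 0.711),   # ether oxygen
    "N": (3.250, 0.711),    # amine/amide nitrogen
    "NC": (3.200, 0.711),   # nitrile nitrogen
    "H": (0.0, 0.0),        # hydrogens carry no LJ term of their own
    "CAB": (3.800, 0.450),  # pseudo-receptor backbone bead
    "SCA": (3.900, 0.900),  # apolar sidechain bead
    "SCP": (3.100, 0.700),  # polar sidechain bead
    "SCN": (3.250, 0.750),  # charged sidechain bead
    "SCG": (3.400, 2.000),  # strongly apolar pocket-lining bead
    "SCW": (3.000, 0.100),  # passivated (weakly interacting) bead
}

#: name -> (SMILES, 3-letter residue code)
PROBE_SMILES: dict[str, tuple[str, str]] = {
    "ethanol": ("CCO", "EOL"),
    "isopropanol": ("CC(C)O", "IPA"),
    "isobutanol": ("CC(C)CO", "IBA"),
    "acetone": ("CC(C)=O", "ACE"),
    "acetaldehyde": ("CC=O", "AAL"),
    "dimethyl ether": ("COC", "DME"),
    "cyclohexane": ("C1CCCCC1", "CHX"),
    "ethane": ("CC", "ETH"),
    "acetonitrile": ("CC#N", "ACN"),
    "urea": ("NC(N)=O", "URE"),
    "methylamine": ("CN", "MAM"),
    "phenol": ("Oc1ccccc1", "PHN"),
    "benzaldehyde": ("O=Cc1ccccc1", "BZA"),
    "benzene": ("c1ccccc1", "BNZ"),
    "acetamide": ("CC(N)=O", "ACM"),
    "N,N-dimethylformamide": ("CN(C)C=O", "DMF"),
}

_EMBED_SEED = 0xE05  # fixed: probe geometries are part of the protocol


@dataclass(frozen=True)
class ProbeType:
    """A rigid heavy-atom fragment with per-atom nonbonded parameters.

    ``coords`` is the (A, 3) body frame with the centroid at the origin;
    ``atom_classes`` indexes :data:`ATOM_CLASSES`; ``charges`` are
    Gasteiger charges with hydrogens folded in (sum equals ``net_charge``).
    """

    name: str
    code: str
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray
    atom_classes: tuple[str, ...]
    charges: np.ndarray
    net_charge: float = 0.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        charges = np.asarray(self.charges, dtype=float)
        if len(coords) < 1:
            raise ValueError(f"probe {self.name}: needs at least one heavy atom")
        centroid = coords.mean(axis=0)
        if np.abs(centroid).max() > 1e-8:
            raise ValueError(f"probe {self.name}: body frame not centered")
        if abs(charges.sum() - self.net_charge) > 1e-6:
            raise ValueError(f"probe {self.name}: charges do not sum to net charge")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "charges", charges)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def radius(self) -> float:
        """Largest atom distance from the body-frame origin."""
        return float(np.linalg.norm(self.coords, axis=1).max())


def _classify_heavy_atom(atom: Chem.Atom) -> str:
    """United-atom nonbonded class from element, bonding and H count."""
    sym = atom.GetSymbol()
    nH = atom.GetTotalNumHs() + sum(
        1 for nb in atom.GetNeighbors() if nb.GetSymbol() == "H"
    )
    if sym == "C":
        if atom.GetIsAromatic():
            return "CAR"
        if any(
            b.GetBondType() == Chem.BondType.DOUBLE
            and b.GetOtherAtom(atom).GetSymbol() in ("O", "N")
            for b in atom.GetBonds()
        ):
            return "CO"
        if any(b.GetBondType() == Chem.BondType.TRIPLE for b in atom.GetBonds()):
            return "CO"  # nitrile carbon: slim sp carbon, reuse sp2 params
        return {3: "C3", 2: "C2"}.get(nH, "C1")
    if sym == "O":
        if nH > 0:
            return "OH"
        if any(b.GetBondType() == Chem.BondType.DOUBLE for b in atom.GetBonds()):
            return "O"
        return "OE"
    if sym == "N":
        if any(b.GetBondType() == Chem.BondType.TRIPLE for b in atom.GetBonds()):
            return "NC"
        return "N"
    raise ValueError(f"unsupported probe element {sym}")


def _build_probe(name: str) -> ProbeType:
    smiles, code = PROBE_SMILES[name]
    mol = Chem.MolFromSmiles(smiles)
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = _EMBED_SEED
    if AllChem.EmbedMolecule(mol, params) != 0:  # pragma: no cover
        raise RuntimeError(f"embedding failed for probe {name}")
    AllChem.MMFFOptimizeMolecule(mol)
    AllChem.ComputeGasteigerCharges(mol)

    conf = mol.GetConformer()
    coords, classes, charges, names, elements = [], [], [], [], []
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "H":
            continue
        q = float(atom.GetDoubleProp("_GasteigerCharge"))
        for nb in atom.GetNeighbors():
            if nb.GetSymbol() == "H":
                q += float(nb.GetDoubleProp("_GasteigerCharge"))
        pos = conf.GetAtomPosition(atom.GetIdx())
        coords.append([pos.x, pos.y, pos.z])
        classes.append(_classify_heavy_atom(atom))
        charges.append(q)
        sym = atom.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
        names.append(f"{sym}{counts[sym]}")
        elements.append(sym)

    coords = np.asarray(coords)
    coords = coords - coords.mean(axis=0)
    charges = np.asarray(charges)
    net = float(Chem.GetFormalCharge(mol))
    charges = charges - (charges.sum() - net) / len(charges)  # remove residual
    return ProbeType(
        name=name,
        code=code,
        atom_names=tuple(names),
        elements=tuple(elements),
        coords=coords,
        atom_classes=tuple(classes),
        charges=charges,
        net_charge=net,
    )


@lru_cache(maxsize=1)
def default_probe_library() -> tuple[ProbeType, ...]:
    """The 16 standard probes, in a fixed deterministic order."""
    return tuple(_build_probe(name) for name in PROBE_SMILES)


@lru_cache(maxsize=None)
def get_probe(name: str) -> ProbeType:
    if name not in PROBE_SMILES:
        raise KeyError(f"unknown probe {name!r}")
    for p in default_probe_library():
        if p.name == name:
            return p
    raise KeyError(name)  # pragma: no cover
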