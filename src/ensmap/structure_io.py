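"""Molecular structure containers and multi-model PDB input/output.

Every stage of the pipeline moves data through three containers defined
here: :class:`AtomRecord` (one atom), :class:`Structure` (one conformer)
and :class:`ConformerEnsemble` (an ordered list of conformers with
identical atom ordering).  PDB parsing and writing are delegated to
``gemmi``; this module adds the indexing, consistency checks and selection
grammar the rest of the package relies on.

Conventions
-----------
* Coordinates and distances are in Angstrom, energies in kJ/mol.
* Residue keys are ``(chain_id, residue_seq, insertion_code)`` tuples with
  1-based PDB residue numbering; atom indices are internal 0-based
  half-open ranges.
* Partial charges of package-generated pseudo-structures (receptors,
  probes, reference ligands) are carried in the B-factor column, quantized
  to 0.01 e so the 2-decimal PDB field is lossless.  For structures from
  other sources the column is an ordinary temperature factor and the
  charges read from it are meaningless; energy evaluation is only defined
  for package-generated structures.
* Alternate locations: the highest-occupancy conformer of each atom is
  kept (ties: first encountered).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "ConformerEnsemble",
    "ResidueKey",
    "PdbFormatError",
    "EnsembleConsistencyError",
    "SelectionError",
    "read_pdb_models",
    "write_structure_pdb",
    "write_ensemble_pdb",
    "write_pdb_with_probes",
    "select_atoms",
]

ResidueKey = tuple[str, int, str]

#: atom-name based nonbonded-class assignment for package conventions;
#: anything else falls back to an element default.
NAME_CLASSES = {
    "CA": "CAB",   # backbone bead of pseudo-residues
    "SCA": "SCA",  # apolar sidechain bead
    "SCP": "SCP",  # polar sidechain bead
    "SCN": "SCN",  # charged sidechain bead
    "SCG": "SCG",  # strongly apolar pocket-lining bead
    "SCW": "SCW",  # passivated (weakly interacting) bead
}
ELEMENT_CLASSES = {"C": "C2", "N": "N", "O": "OH", "S": "C2", "H": "H"}


class PdbFormatError(ValueError):
    """Unparseable or structurally invalid PDB content."""


class EnsembleConsistencyError(PdbFormatError):
    """Models of a multi-model file disagree in atom count or ordering."""


class SelectionError(ValueError):
    """Malformed atom-selection expression."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom with the nonbonded metadata used by the energy model."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    coords: np.ndarray
    atom_class: str
    is_heavy: bool
    charge: float = 0.0
    icode: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise PdbFormatError(
                f"atom {self.serial} ({self.name}): coordinates must be a finite 3-vector"
            )
        object.__setattr__(self, "coords", coords)
        if self.is_heavy != (self.element.upper() != "H"):
            raise PdbFormatError(
                f"atom {self.serial} ({self.name}): is_heavy inconsistent with element"
            )

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_seq, self.icode)


class Structure:
    """One conformer: an ordered atom list plus residue indexing.

    Parameters
    ----------
    model_id:
        Integer identifier (PDB MODEL number, or a synthetic conformer id).
    atoms:
        Ordered atoms.  Atoms of each residue must be contiguous.
    """

    def __init__(self, model_id: int, atoms: Sequence[AtomRecord]):
        self.model_id = int(model_id)
        self.atoms: list[AtomRecord] = list(atoms)
        self.residue_index: dict[ResidueKey, tuple[int, int]] = {}
        last_key = None
        start = 0
        for i, atom in enumerate(self.atoms):
            key = atom.residue_key
            if key != last_key:
                if key in self.residue_index:
                    raise PdbFormatError(
                        f"model {model_id}: atoms of residue {key} are not contiguous"
                    )
                if last_key is not None:
                    self.residue_index[last_key] = (start, i)
                last_key, start = key, i
        if last_key is not None:
            self.residue_index[last_key] = (start, len(self.atoms))
        self._coords = np.array([a.coords for a in self.atoms], dtype=float).reshape(
            len(self.atoms), 3
        )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array (a view; treat structures as immutable)."""
        return self._coords

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def residue_keys(self) -> list[ResidueKey]:
        return list(self.residue_index)

    def with_coords(self, coords: np.ndarray, model_id: int | None = None) -> "Structure":
        """A copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self._coords.shape:
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coords=c) for a, c in zip(self.atoms, coords)]
        return Structure(self.model_id if model_id is None else model_id, atoms)

    def atom_signature(self) -> list[tuple]:
        """Per-atom identity tuple used for cross-model consistency checks."""
        return [
            (a.name, a.residue_name, a.chain_id, a.residue_seq, a.icode)
            for a in self.atoms
        ]


@dataclass
class ConformerEnsemble:
    """Ordered conformers with identical atom ordering.

    ``alignment_selection`` lists the atom indices used for superposition
    (and for RMSD measurement) by the reduction stage.
    """

    models: list[Structure]
    alignment_selection: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.models:
            raise EnsembleConsistencyError("ensemble must contain at least one model")
        ref = self.models[0].atom_signature()
        for m in self.models[1:]:
            sig = m.atom_signature()
            if len(sig) != len(ref):
                raise EnsembleConsistencyError(
                    f"model {m.model_id}: atom count {len(sig)} differs from "
                    f"model {self.models[0].model_id} ({len(ref)})"
                )
            for i, (a, b) in enumerate(zip(ref, sig)):
                if a != b:
                    raise EnsembleConsistencyError(
                        f"model {m.model_id}: atom {i} {b} does not match "
                        f"model {self.models[0].model_id} atom {a}"
                    )
        n = len(self.models[0])
        for idx in self.alignment_selection:
            if not (0 <= idx < n):
                raise EnsembleConsistencyError(
                    f"alignment_selection index {idx} out of range for {n} atoms"
                )

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)


# ---------------------------------------------------------------------------
# reading


def _flatten_gemmi_model(model: gemmi.Model, model_id: int) -> Structure:
    atoms: list[AtomRecord] = []
    serial = 0
    for chain in model:
        for res in chain:
            # altloc: keep highest occupancy per atom name, tie -> first.
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for at in res:
                if at.name not in best:
                    best[at.name] = at
                    order.append(at.name)
                elif at.occ > best[at.name].occ:
                    best[at.name] = at
            for name in order:
                at = best[name]
                serial += 1
                element = at.element.name if at.element.name else "C"
                atom_class = NAME_CLASSES.get(
                    name, ELEMENT_CLASSES.get(element.upper(), "C2")
                )
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=name,
                        element=element,
                        residue_name=res.name,
                        residue_seq=res.seqid.num,
                        chain_id=chain.name,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        atom_class=atom_class,
                        is_heavy=element.upper() != "H",
                        charge=round(float(at.b_iso), 2),
                        icode=(res.seqid.icode or " ").strip(),
                        is_hetero=res.het_flag == "H",
                    )
                )
    return Structure(model_id, atoms)


def read_pdb_models(path: str | Path) -> ConformerEnsemble:
    """Read a (multi-model) PDB file into a :class:`ConformerEnsemble`.

    Hydrogens are retained but flagged ``is_heavy=False``.  The alignment
    selection defaults to all heavy atoms named ``CA``.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    EnsembleConsistencyError
        If models disagree in atom count or ordering (the first offending
        model and atom are named).
    PdbFormatError
        If no atoms could be parsed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PdbFormatError(f"{path}: {exc}") from exc
    models = []
    for i, model in enumerate(st):
        model_id = model.num if model.num > 0 else i + 1
        models.append(_flatten_gemmi_model(model, model_id))
    if not models or not len(models[0]):
        raise PdbFormatError(f"{path}: no ATOM/HETATM records found")
    ensemble = ConformerEnsemble(models=models)
    ensemble.alignment_selection = select_atoms(models[0], "name CA and heavy")
    return ensemble


# ---------------------------------------------------------------------------
# writing


def _gemmi_from_atoms(atoms: Iterable[AtomRecord], model_id: int) -> gemmi.Model:
    model = gemmi.Model(model_id)
    chain = None
    res = None
    res_key = None
    for a in atoms:
        if chain is None or chain.name != a.chain_id:
            chain = gemmi.Chain(a.chain_id)
            model.add_chain(chain)
            chain = model[len(model) - 1]
            res_key = None
        key = (a.residue_seq, a.icode, a.residue_name)
        if key != res_key:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_seq, a.icode or " ")
            res.het_flag = "H" if a.is_hetero else "A"
            chain.add_residue(res)
            res = chain[len(chain) - 1]
            res_key = key
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.coords)
        at.occ = 1.0
        at.b_iso = float(a.charge)
        res.add_atom(at)
    return model


def _write_models(models: list[tuple[int, list[AtomRecord]]], path: str | Path) -> None:
    # PDB MODEL serials are 1-based and must be unique; in-memory model
    # ids (0-based conformer positions) are not preserved through files
    st = gemmi.Structure()
    st.name = "ensmap"
    for i, (_model_id, atoms) in enumerate(models):
        st.add_model(_gemmi_from_atoms(atoms, i + 1))
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write PDB to {path}: {exc}") from exc


def write_structure_pdb(structure: Structure, path: str | Path) -> None:
    """Write a single conformer as a fixed-column PDB file."""
    _write_models([(structure.model_id, structure.atoms)], path)


def write_ensemble_pdb(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Write all conformers as a MODEL/ENDMDL multi-model PDB file."""
    _write_models([(m.model_id, m.atoms) for m in ensemble.models], path)


def write_pdb_with_probes(structure: Structure, sites, path: str | Path) -> None:
    """Write the mapped protein plus representative probe poses.

    The protein is emitted as ATOM records; every member pose of every
    consensus site becomes one HETATM residue whose residue name is the
    3-letter probe code.  The chain id encodes the consensus-site rank
    ('1'..'9', then '0' for rank 10, letters beyond).

    Parameters
    ----------
    structure:
        The mapped conformer.
    sites:
        Iterable of :class:`ensmap.probe_mapping.ConsensusSite`.
    """
    atoms = list(structure.atoms)
    serial = len(atoms)
    resseq = 0
    for site in sites:
        rank = site.rank
        if rank < 10:
            chain_id = str(rank)
        elif rank == 10:
            chain_id = "0"
        else:
            chain_id = chr(ord("a") + rank - 11)
        for cluster in site.member_clusters:
            pose = cluster.center
            resseq += 1
            for name, element, xyz, q in pose.placed_atoms():
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=name,
                        element=element,
                        residue_name=pose.probe.code,
                        residue_seq=resseq,
                        chain_id=chain_id,
                        coords=xyz,
                        atom_class="C2",
                        is_heavy=element.upper() != "H",
                        charge=round(float(q), 2),
                        is_hetero=True,
                    )
                )
    _write_models([(structure.model_id, atoms)], path)


# ---------------------------------------------------------------------------
# selection grammar
#
#   expr    := or_expr
#   or_expr := and_expr ('or' and_expr)*
#   and_expr:= unary ('and' unary)*
#   unary   := 'not' unary | '(' expr ')' | primary
#   primary := 'name' IDENT+ | 'chain' IDENT+ | 'resid' RANGE+
#            | 'heavy' | 'all'
#   RANGE   := INT | INT '-' INT          (inclusive)

_KEYWORDS = {"and", "or", "not", "name", "chain", "resid", "heavy", "all", "(", ")"}


def _tokenize(expression: str) -> list[str]:
    return expression.replace("(", " ( ").replace(")", " ) ").split()


class _Parser:
    def __init__(self, structure: Structure, tokens: list[str]):
        self.s = structure
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.take()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() == "and":
            self.take()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.unary()
        if tok == "(":
            self.take()
            mask = self.or_expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parenthesis")
            return mask
        return self.primary()

    def _arguments(self) -> list[str]:
        args = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            args.append(self.take())
        if not args:
            raise SelectionError("selection keyword requires at least one argument")
        return args

    def primary(self) -> np.ndarray:
        tok = self.take()
        atoms = self.s.atoms
        if tok == "name":
            names = set(self._arguments())
            return np.array([a.name in names for a in atoms])
        if tok == "chain":
            chains = set(self._arguments())
            return np.array([a.chain_id in chains for a in atoms])
        if tok == "resid":
            ranges = []
            for arg in self._arguments():
                lo, sep, hi = arg.partition("-")
                try:
                    ranges.append((int(lo), int(hi) if sep else int(lo)))
                except ValueError as exc:
                    raise SelectionError(f"bad residue range {arg!r}") from exc
            return np.array(
                [any(lo <= a.residue_seq <= hi for lo, hi in ranges) for a in atoms]
            )
        if tok == "heavy":
            return np.array([a.is_heavy for a in atoms])
        if tok == "all":
            return np.ones(len(atoms), dtype=bool)
        raise SelectionError(f"unknown selection token {tok!r}")


def select_atoms(structure: Structure, expression: str) -> list[int]:
    """Evaluate a selection expression to an ordered list of atom indices.

    The grammar supports atom names (``name CA``), chains (``chain A``),
    inclusive residue ranges (``resid 10-12``), ``heavy``, ``all`` and the
    boolean operators ``and``/``or``/``not`` with parentheses.  The result
    preserves atom order and is deterministic; an empty selection emits a
    warning and returns ``[]``.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(structure, tokens).parse()
    indices = [int(i) for i in np.flatnonzero(mask)]
    if not indices:
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    return indices
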