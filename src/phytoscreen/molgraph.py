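"""Molecular graphs for topological descriptor computation.

A :class:`MolecularGraph` is a hydrogen-suppressed colored graph: heavy atoms
carry their element, formal charge, attached-hydrogen count, aromatic flag and
principal quantum number; bonds carry an integer order and an aromatic flag.
Hydrogens live as counts on heavy atoms rather than as graph nodes — the
electrotopological-state, connectivity and Balaban indices all operate on the
hydrogen-suppressed skeleton, while composition descriptors expand hydrogens
on the fly.

Structure input (SMILES, SDF) and aromaticity perception are delegated to
RDKit; everything downstream of the parsed graph is computed in this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse.csgraph import shortest_path

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")  # parse failures are reported as our own errors

#: Elements supported by the E-state / connectivity machinery.
SUPPORTED_ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")

#: Principal quantum number of the valence shell.
PRINCIPAL_QUANTUM_NUMBER = {
    "H": 1,
    "C": 2, "N": 2, "O": 2, "F": 2,
    "P": 3, "S": 3, "Cl": 3,
    "Br": 4,
    "I": 5,
}

#: Valence (outer-shell) electron counts.
VALENCE_ELECTRONS = {
    "C": 4, "N": 5, "O": 6, "F": 7,
    "P": 5, "S": 6, "Cl": 7, "Br": 7, "I": 7,
}

_PERIODIC_TABLE = Chem.GetPeriodicTable()


class MolGraphError(ValueError):
    """Structured error raised for invalid structures or parse failures."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a hydrogen-suppressed molecular graph."""

    element: str
    charge: int = 0
    n_hydrogens: int = 0
    aromatic: bool = False
    quantum_number: int = 2


@dataclass(frozen=True)
class Bond:
    """Bond between heavy atoms ``i < j`` with integer order 1, 2 or 3."""

    i: int
    j: int
    order: int = 1
    aromatic: bool = False


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed colored molecular graph.

    ``annotations`` holds externally supplied per-compound scalars such as a
    logP value used by the rule-of-five filter.
    """

    atoms: list[Atom]
    bonds: list[Bond]
    name: str = ""
    annotations: dict[str, float] = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == i:
                out.append(b.j)
            elif b.j == i:
                out.append(b.i)
        return out

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_atoms, self.n_atoms), dtype=int)
        for b in self.bonds:
            a[b.i, b.j] = a[b.j, b.i] = 1
        return a

    def degrees(self) -> np.ndarray:
        """Heavy-atom degree of every atom."""
        return self.adjacency().sum(axis=1)

    def multiset_key(self):
        """Order-independent (atom multiset, bond multiset) signature.

        Two SMILES spellings of the same molecule yield equal keys; used by
        the round-trip tests and by equality checks in the screening audit.
        """
        atom_key = tuple(sorted(
            (a.element, a.charge, a.n_hydrogens, a.aromatic) for a in self.atoms
        ))
        akeys = [(a.element, a.charge, a.n_hydrogens, a.aromatic) for a in self.atoms]
        bond_key = tuple(sorted(
            (tuple(sorted((akeys[b.i], akeys[b.j]))), b.order, b.aromatic)
            for b in self.bonds
        ))
        return atom_key, bond_key

    def validate(self) -> None:
        n = self.n_atoms
        if n == 0:
            raise MolGraphError("empty molecular graph")
        seen = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise MolGraphError(f"bond ({b.i},{b.j}) out of range")
            if b.i >= b.j:
                raise MolGraphError(f"bond ({b.i},{b.j}) must have i < j")
            if (b.i, b.j) in seen:
                raise MolGraphError(f"duplicate bond ({b.i},{b.j})")
            seen.add((b.i, b.j))
        if n > 1:
            d = graph_distances(self, _validate=False)
            if np.isinf(d).any():
                raise MolGraphError(
                    "graph is disconnected over heavy atoms "
                    "(salts/fragments must be stripped upstream)"
                )


@dataclass
class EStateTypedGraph:
    """A molecular graph with Kier–Hall atom-type codes and connectivities.

    ``delta`` is the heavy-atom degree; ``delta_v`` the valence connectivity
    (valence electrons − attached hydrogens, adjusted by formal charge).
    """

    base: MolecularGraph
    type_codes: list[str]
    delta: np.ndarray
    delta_v: np.ndarray


def _from_rdkit(mol: Chem.Mol, name: str) -> MolecularGraph:
    atoms = []
    for a in mol.GetAtoms():
        el = a.GetSymbol()
        atoms.append(Atom(
            element=el,
            charge=a.GetFormalCharge(),
            n_hydrogens=a.GetTotalNumHs(),
            aromatic=a.GetIsAromatic(),
            quantum_number=PRINCIPAL_QUANTUM_NUMBER.get(el, 2),
        ))
    bonds = []
    order_map = {
        Chem.BondType.SINGLE: 1,
        Chem.BondType.DOUBLE: 2,
        Chem.BondType.TRIPLE: 3,
        Chem.BondType.AROMATIC: 1,
    }
    for b in mol.GetBonds():
        i, j = sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        if b.GetBondType() not in order_map:
            raise MolGraphError(f"unsupported bond type {b.GetBondType()} in {name!r}")
        bonds.append(Bond(i, j, order_map[b.GetBondType()], b.GetIsAromatic()))
    g = MolecularGraph(atoms=atoms, bonds=bonds, name=name)
    g.validate()
    return g


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    """Convert common zwitterions / simple ions to neutral forms.

    Protonated N (with an H to give up) loses a proton; deprotonated O/N/S
    gains one. Ionization-state modeling is out of scope: descriptors are
    computed on the neutral species.
    """
    mol = Chem.RWMol(mol)
    changed = False
    for a in mol.GetAtoms():
        q = a.GetFormalCharge()
        if q == 1 and a.GetSymbol() == "N" and a.GetTotalNumHs() > 0:
            a.SetFormalCharge(0)
            a.SetNumExplicitHs(max(a.GetNumExplicitHs() - 1, 0))
            a.SetNoImplicit(False)
            changed = True
        elif q == -1 and a.GetSymbol() in ("O", "S", "N"):
            a.SetFormalCharge(0)
            a.SetNumExplicitHs(a.GetNumExplicitHs() + 1)
            changed = True
    out = mol.GetMol()
    if changed:
        Chem.SanitizeMol(out)
    return out


def read_smiles(text: str, name: str = "", neutralize: bool = True) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Implicit hydrogens are filled in, aromaticity is perceived on rings, and
    stereochemistry is discarded (all descriptors in this package are 2-D
    topological). Multi-fragment inputs are rejected.
    """
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise MolGraphError(f"SMILES parse failure for {name or text!r}: {text!r}")
    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        raise MolGraphError(
            f"{name or text!r} contains {len(frags)} disconnected fragments; "
            "strip salts upstream"
        )
    if neutralize:
        mol = _neutralize(mol)
    return _from_rdkit(mol, name or text)


def read_smiles_file(path) -> list[MolecularGraph]:
    """Read a .smi file: one ``SMILES<whitespace>name`` record per line.

    Lines starting with ``#`` are comments.
    """
    graphs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            graphs.append(read_smiles(smiles, name))
    return graphs


def read_sdf(path) -> list[MolecularGraph]:
    """Read all molecules of an SDF (V2000) file."""
    graphs = []
    for idx, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            raise MolGraphError(f"SDF record {idx} of {path} failed to parse")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{idx}"
        graphs.append(_from_rdkit(_neutralize(mol), name))
    return graphs


# Kier–Hall bond-symbol ordering as used in published atom-type codes
# (e.g. tsC, dssC, aasC, sssCH): triple, double, aromatic, then single.
_BOND_SYMBOL_ORDER = {"t": 0, "d": 1, "a": 2, "s": 3}


def _bond_symbol(b: Bond) -> str:
    if b.aromatic:
        return "a"
    return {1: "s", 2: "d", 3: "t"}[b.order]


def assign_estate_types(g: MolecularGraph) -> EStateTypedGraph:
    """Assign a Kier–Hall atom-type code, δ and δv to every heavy atom.

    The code concatenates one bond symbol per heavy-atom bond (s/d/t/a,
    ordered t < d < a < s), the element symbol, and an H/H2/H3 suffix for
    attached hydrogens — e.g. ``sssCH`` for a branched methine, ``aaN`` for
    a pyridine-type nitrogen, ``aaNH`` for a pyrrole-type one.
    """
    for idx, a in enumerate(g.atoms):
        if a.element not in SUPPORTED_ELEMENTS:
            raise MolGraphError(
                f"atom {idx} ({a.element}) of {g.name!r} outside the supported "
                f"element set {SUPPORTED_ELEMENTS}"
            )
    codes: list[str] = []
    bond_syms: list[list[str]] = [[] for _ in g.atoms]
    for b in g.bonds:
        s = _bond_symbol(b)
        bond_syms[b.i].append(s)
        bond_syms[b.j].append(s)
    for idx, a in enumerate(g.atoms):
        syms = sorted(bond_syms[idx], key=_BOND_SYMBOL_ORDER.__getitem__)
        h = a.n_hydrogens
        suffix = "" if h == 0 else ("H" if h == 1 else f"H{h}")
        codes.append("".join(syms) + a.element + suffix)
    delta = g.degrees()
    delta_v = np.array([
        VALENCE_ELECTRONS[a.element] - a.n_hydrogens - a.charge
        for a in g.atoms
    ], dtype=float)
    return EStateTypedGraph(base=g, type_codes=codes, delta=delta.astype(float), delta_v=delta_v)


def graph_distances(g: MolecularGraph, _validate: bool = True) -> np.ndarray:
    """Bond-count shortest-path distance matrix over heavy atoms."""
    if _validate:
        g.validate()
    if g.n_atoms == 1:
        return np.zeros((1, 1))
    d = shortest_path(g.adjacency(), method="D", directed=False, unweighted=True)
    return d


def atomic_mass(element: str) -> float:
    return _PERIODIC_TABLE.GetAtomicWeight(element)


def physchem_counts(g: MolecularGraph) -> tuple[float, int, int]:
    """Molecular weight (g/mol, hydrogens included), HBD and HBA counts.

    HBD = number of N/O atoms bearing at least one hydrogen; HBA = total
    number of N + O atoms — the counting scheme of the rule-of-five filter.
    """
    mw = 0.0
    hbd = hba = 0
    h_mass = atomic_mass("H")
    for a in g.atoms:
        mw += atomic_mass(a.element) + a.n_hydrogens * h_mass
        if a.element in ("N", "O"):
            hba += 1
            if a.n_hydrogens > 0:
                hbd += 1
    return mw, hbd, hba


def permute_atoms(g: MolecularGraph, perm: list[int]) -> MolecularGraph:
    """Relabel atoms by ``perm`` (new index of old atom ``i`` is ``perm[i]``).

    Utility for permutation-invariance tests.
    """
    inv = [0] * len(perm)
    for old, new in enumerate(perm):
        inv[new] = old
    atoms = [g.atoms[inv[k]] for k in range(len(perm))]
    bonds = []
    for b in g.bonds:
        i, j = sorted((perm[b.i], perm[b.j]))
        bonds.append(Bond(i, j, b.order, b.aromatic))
    return replace(g, atoms=atoms, bonds=list(bonds))
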