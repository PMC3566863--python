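"""Molecular graphs, formula arithmetic, H-bond atom typing, and pseudo-cycle
ring sizes.

This module provides the 2D (topological) substrate for the turn analysis:

* :class:`Composition` / :func:`parse_formula` / :func:`monoisotopic_mass` —
  exact-mass arithmetic against a small hard-coded table of most-abundant
  isotope masses, matching printed HRMS "calcd" values for neutral molecules.
* :class:`MolecularGraph` / :func:`load_structure` — a thin wrapper over an
  RDKit molecule with explicit hydrogens materialised on heteroatom donors.
* :func:`hbond_typing` — rule-based donor/acceptor enumeration.
* :func:`pseudo_ring_size` — the size of the pseudo-cycle closed by an
  intramolecular H···O contact, counted along the shortest covalent path and
  inclusive of both the hydrogen and the acceptor, so that the classic
  gamma-turn contact is C7 and the alpha-turn contact is C13.
* :class:`RoleMap` / :func:`derive_role_map` — mapping of scaffold atoms onto
  pseudo-residue positions 1-5 of a five-residue reverse turn.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import yaml
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ChemError",
    "Composition",
    "parse_formula",
    "monoisotopic_mass",
    "MolecularGraph",
    "load_structure",
    "hbond_typing",
    "pseudo_ring_size",
    "RoleMap",
    "derive_role_map",
    "SMILES_1A",
    "SMILES_1B",
]


class ChemError(ValueError):
    """Raised for malformed formulas, structures, or atom-role queries."""


# Most-abundant-isotope masses (Da).  Hard-coded for bit-stable arithmetic;
# printed HRMS "calcd" values are neutral-molecule monoisotopic masses, so no
# electron-mass correction is applied.
ISOTOPE_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207069,
    "F": 18.99840322,
    "Cl": 34.96885271,
    "Br": 78.91833760,
}

# Reference fixture: compound 1a reconstructed from its printed IUPAC name,
# benzyl (((3S,6S,12aS)-3-methyl-2-(2-(methylamino)-2-oxoethyl)-1,4-dioxo-
# 1,2,3,4,6,7,12,12a-octahydropyrazino[1',2':1,6]pyrido[3,4-b]indol-6-yl)-
# methyl)carbamate.  Validate by formula/exact mass before trusting.
SMILES_1A = (
    "O=C(OCc1ccccc1)NC[C@H]2c3[nH]c4ccccc4c3C[C@H]5"
    "C(=O)N(CC(=O)NC)[C@@H](C)C(=O)N25"
)
# 6R epimer (3S,6R,12aS).
SMILES_1B = (
    "O=C(OCc1ccccc1)NC[C@@H]2c3[nH]c4ccccc4c3C[C@H]5"
    "C(=O)N(CC(=O)NC)[C@@H](C)C(=O)N25"
)


# ---------------------------------------------------------------------------
# Formula arithmetic
# ---------------------------------------------------------------------------

_HILL_FIRST = ("C", "H")
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Composition(Mapping[str, int]):
    """Elemental composition: element symbol -> count (counts >= 1)."""

    def __init__(self, counts: Mapping[str, int]):
        clean: dict[str, int] = {}
        for el, n in counts.items():
            if el not in ISOTOPE_MASS:
                raise ChemError(f"unsupported element symbol: {el!r}")
            n = int(n)
            if n < 1:
                raise ChemError(f"count for {el} must be >= 1, got {n}")
            clean[el] = clean.get(el, 0) + n
        if not clean:
            raise ChemError("empty composition")
        self._counts = clean

    def __getitem__(self, el: str) -> int:
        return self._counts[el]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Composition):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == dict(other)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __add__(self, other: "Composition") -> "Composition":
        merged = dict(self._counts)
        for el, n in other.items():
            merged[el] = merged.get(el, 0) + n
        return Composition(merged)

    def hill(self) -> str:
        """Canonical Hill-order formula string (C, H, then alphabetical)."""
        parts = []
        for el in _HILL_FIRST:
            if el in self._counts:
                n = self._counts[el]
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(set(self._counts) - set(_HILL_FIRST)):
            n = self._counts[el]
            parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Composition({self.hill()!r})"


def parse_formula(text: str) -> Composition:
    """Parse a molecular-formula string such as ``"C27H29N5O5"``.

    Hill order is not required; repeated symbols accumulate.  Raises
    :class:`ChemError` on empty input, unknown symbols, or explicit zero
    counts.
    """
    if not text or not text.strip():
        raise ChemError("empty formula string")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ChemError(f"unparseable formula fragment: {text[pos:]!r}")
        el, digits = m.group(1), m.group(2)
        if el not in ISOTOPE_MASS:
            raise ChemError(f"unknown element symbol: {el!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise ChemError(f"zero count for element {el}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    if pos != len(text):
        raise ChemError(f"unparseable formula fragment: {text[pos:]!r}")
    return Composition(counts)


def monoisotopic_mass(c: Composition) -> float:
    """Neutral-molecule monoisotopic mass in Da (sum of most-abundant-isotope
    masses), the quantity printed as HRMS ``[M+] calcd``."""
    return sum(ISOTOPE_MASS[el] * n for el, n in c.items())


# ---------------------------------------------------------------------------
# Molecular graph
# ---------------------------------------------------------------------------


class MolecularGraph:
    """A molecule as an attributed graph, backed by an RDKit ``Mol``.

    Hydrogens on N/O/S donors are explicit (so H-bond geometry has atom ids
    to talk about); carbon hydrogens stay implicit unless
    :meth:`with_all_hydrogens` is called, e.g. before 3D embedding.
    """

    def __init__(self, mol: Chem.Mol):
        Chem.SanitizeMol(mol)
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
        self._mol = mol

    # -- construction -------------------------------------------------------

    @classmethod
    def from_smiles(cls, smiles: str) -> "MolecularGraph":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ChemError(f"SMILES parse failure: {smiles!r}")
        return cls(_explicit_hetero_hydrogens(mol))

    @classmethod
    def from_molblock(cls, block: str) -> "MolecularGraph":
        mol = Chem.MolFromMolBlock(block, removeHs=False)
        if mol is None:
            raise ChemError("MOL/SDF record parse failure")
        return cls(_explicit_hetero_hydrogens(mol))

    # -- views ---------------------------------------------------------------

    @property
    def mol(self) -> Chem.Mol:
        return self._mol

    @property
    def n_atoms(self) -> int:
        return self._mol.GetNumAtoms()

    @property
    def atoms(self) -> list[tuple[int, str, int, int]]:
        """(index, element, formal charge, total H count) per atom."""
        return [
            (a.GetIdx(), a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
            for a in self._mol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[tuple[int, int, float]]:
        """(begin, end, order) per bond."""
        return [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in self._mol.GetBonds()
        ]

    @property
    def stereocenters(self) -> dict[int, str]:
        """Assigned stereocenters as atom index -> 'R' | 'S'."""
        out = {}
        for a in self._mol.GetAtoms():
            if a.HasProp("_CIPCode"):
                out[a.GetIdx()] = a.GetProp("_CIPCode")
        return out

    def composition(self) -> Composition:
        return parse_formula(rdMolDescriptors.CalcMolFormula(self._mol))

    def with_all_hydrogens(self) -> "MolecularGraph":
        """All hydrogens explicit; existing atom indices are preserved and new
        hydrogens are appended, so role-map ids on ``self`` stay valid."""
        return MolecularGraph(Chem.AddHs(self._mol))

    # -- serialisation -------------------------------------------------------

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self._mol)

    def to_molblock(self) -> str:
        return Chem.MolToMolBlock(self._mol, includeStereo=True)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MolecularGraph({self.composition().hill()}, {self.n_atoms} atoms)"


def _explicit_hetero_hydrogens(mol: Chem.Mol) -> Chem.Mol:
    """Materialise explicit H on N/O/S atoms that carry hydrogens."""
    Chem.SanitizeMol(mol)
    targets = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() in ("N", "O", "S") and a.GetTotalNumHs() > 0
    ]
    if targets:
        mol = Chem.AddHs(mol, onlyOnAtoms=targets)
    return mol


def load_structure(record: str, fmt: str | None = None) -> MolecularGraph:
    """Load a structure from a SMILES string or an SDF/MOL V2000 record.

    ``fmt`` may be ``"smiles"`` or ``"sdf"``; if omitted, records containing a
    V2000 counts line are treated as MOL blocks and anything else as SMILES.
    """
    if fmt is None:
        fmt = "sdf" if ("V2000" in record or "V3000" in record) else "smiles"
    if fmt == "smiles":
        return MolecularGraph.from_smiles(record.strip())
    if fmt in ("sdf", "mol"):
        return MolecularGraph.from_molblock(record)
    raise ChemError(f"unknown structure format: {fmt!r}")


# ---------------------------------------------------------------------------
# H-bond typing and pseudo-cycle ring size
# ---------------------------------------------------------------------------


def hbond_typing(g: MolecularGraph) -> tuple[list[tuple[int, int]], list[int]]:
    """Enumerate H-bond donors and acceptors on a molecular graph.

    Donors are (heavy atom, explicit hydrogen) pairs for N-H and O-H groups.
    Acceptors are oxygen atoms (carbonyl, carbamate, ester/ether alike) plus
    basic nitrogens: non-aromatic N with no hydrogens, neutral or anionic,
    and not adjacent to a carbonyl carbon (amide/carbamate N lone pairs are
    delocalised and excluded).
    """
    mol = g.mol
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    for a in mol.GetAtoms():
        sym = a.GetSymbol()
        if sym in ("N", "O"):
            for nb in a.GetNeighbors():
                if nb.GetAtomicNum() == 1:
                    donors.append((a.GetIdx(), nb.GetIdx()))
        if sym == "O":
            acceptors.append(a.GetIdx())
        elif sym == "N":
            if (
                not a.GetIsAromatic()
                and a.GetTotalNumHs() == 0
                and a.GetFormalCharge() <= 0
                and not _adjacent_to_carbonyl(a)
            ):
                acceptors.append(a.GetIdx())
    return donors, acceptors


def _adjacent_to_carbonyl(atom: Chem.Atom) -> bool:
    for nb in atom.GetNeighbors():
        if nb.GetSymbol() != "C":
            continue
        for b in nb.GetBonds():
            other = b.GetOtherAtom(nb)
            if b.GetBondTypeAsDouble() == 2.0 and other.GetSymbol() == "O":
                return True
    return False


def pseudo_ring_size(g: MolecularGraph, donor_h: int, acceptor: int) -> int:
    """Size of the pseudo-cycle closed by the H···acceptor contact.

    Counted as the number of atoms on the shortest covalent path from the
    donor hydrogen to the acceptor, inclusive of both endpoints; with this
    convention the gamma-turn contact is a 7-ring and the alpha-turn contact
    a 13-ring.  Ties between equal-length paths do not affect the size.
    """
    mol = g.mol
    if donor_h < 0 or donor_h >= mol.GetNumAtoms():
        raise ChemError(f"invalid atom id {donor_h}")
    if acceptor < 0 or acceptor >= mol.GetNumAtoms():
        raise ChemError(f"invalid atom id {acceptor}")
    if mol.GetAtomWithIdx(donor_h).GetAtomicNum() != 1:
        raise ChemError(f"atom {donor_h} is not a hydrogen")
    path = Chem.GetShortestPath(mol, donor_h, acceptor)
    if not path:
        raise ChemError(
            f"atoms {donor_h} and {acceptor} are not in the same component"
        )
    return len(path)


# ---------------------------------------------------------------------------
# Role map: scaffold atoms -> pseudo-residue positions 1..5
# ---------------------------------------------------------------------------


@dataclass
class RoleMap:
    """Assignment of scaffold atoms to the five pseudo-residues of a turn.

    ``backbone_paths[k]`` holds the (N, C-alpha, C') atom triple of
    pseudo-residue ``k`` (entries may be ``None`` where the chain terminates,
    e.g. N of residue 1 or C' of residue 5).  ``calpha_surrogates`` runs from
    position 1 (the benzyl oxygen of the Cbz group, standing in for
    C-alpha-1) to position 5 (the terminal methylamide carbon).
    """

    donor_n: int
    donor_h: int
    acceptor_o_pos3: int
    acceptor_o_pos1: int
    calpha_surrogates: list[int]
    backbone_paths: dict[int, tuple[int | None, int, int | None]] = field(
        default_factory=dict
    )

    def validate(self, g: MolecularGraph) -> None:
        mol = g.mol
        n = mol.GetNumAtoms()
        ids = [self.donor_n, self.donor_h, self.acceptor_o_pos3, self.acceptor_o_pos1]
        ids += list(self.calpha_surrogates)
        for triple in self.backbone_paths.values():
            ids += [i for i in triple if i is not None]
        for i in ids:
            if not (0 <= i < n):
                raise ChemError(f"role-map atom id {i} outside graph")
        if self.donor_h not in [
            a.GetIdx() for a in mol.GetAtomWithIdx(self.donor_n).GetNeighbors()
        ]:
            raise ChemError("donor_h is not bonded to donor_n")
        for o in (self.acceptor_o_pos3, self.acceptor_o_pos1):
            a = mol.GetAtomWithIdx(o)
            if a.GetSymbol() != "O":
                raise ChemError(f"acceptor atom {o} is not oxygen")
        if len(set(self.calpha_surrogates)) != len(self.calpha_surrogates):
            raise ChemError("C-alpha surrogate ids are not distinct")

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "donor_n": self.donor_n,
            "donor_h": self.donor_h,
            "acceptor_o_pos3": self.acceptor_o_pos3,
            "acceptor_o_pos1": self.acceptor_o_pos1,
            "calpha_surrogates": list(self.calpha_surrogates),
            "backbone_paths": {
                k: [v for v in triple] for k, triple in self.backbone_paths.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RoleMap":
        return cls(
            donor_n=int(d["donor_n"]),
            donor_h=int(d["donor_h"]),
            acceptor_o_pos3=int(d["acceptor_o_pos3"]),
            acceptor_o_pos1=int(d["acceptor_o_pos1"]),
            calpha_surrogates=[int(i) for i in d["calpha_surrogates"]],
            backbone_paths={
                int(k): tuple(None if v is None else int(v) for v in triple)
                for k, triple in d.get("backbone_paths", {}).items()
            },
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RoleMap":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _carbonyl_oxygen(mol: Chem.Mol, c_idx: int) -> int | None:
    a = mol.GetAtomWithIdx(c_idx)
    for b in a.GetBonds():
        o = b.GetOtherAtom(a)
        if b.GetBondTypeAsDouble() == 2.0 and o.GetSymbol() == "O":
            return o.GetIdx()
    return None


_METHYLAMIDE = Chem.MolFromSmarts("[CH3][NH1]C(=O)[CH2]")
_CBZ = Chem.MolFromSmarts("[OX1]=[CX3]([OX2][CH2])[NH1][CH2]")


def derive_role_map(g: MolecularGraph) -> RoleMap:
    """Derive the pseudo-residue role map for a THBC-DKP scaffold.

    The walk is anchored on two substructures that are unique in the
    scaffold: the methylamide cap CH3-NH-C(=O)-CH2 (position-5 side) and the
    Cbz carbamate O=C(O-CH2)N-H (position-1 side); the diketopiperazine ring
    is then traversed between them.  Raises :class:`ChemError` when either
    anchor is missing or ambiguous.
    """
    mol = g.mol
    cap = mol.GetSubstructMatches(_METHYLAMIDE)
    if len(cap) != 1:
        raise ChemError(f"expected one methylamide cap, found {len(cap)}")
    ca5, n5, c4p, _o4, ca4 = cap[0]

    h5s = [a.GetIdx() for a in mol.GetAtomWithIdx(n5).GetNeighbors() if a.GetAtomicNum() == 1]
    if not h5s:
        raise ChemError("methylamide N has no explicit hydrogen")
    h5 = h5s[0]

    n4 = next(
        a.GetIdx()
        for a in mol.GetAtomWithIdx(ca4).GetNeighbors()
        if a.GetSymbol() == "N" and a.GetIdx() != n5
    )
    # C'3: the DKP carbonyl carbon bonded to the glycine-bearing ring N.
    c3p = next(
        a.GetIdx()
        for a in mol.GetAtomWithIdx(n4).GetNeighbors()
        if a.GetSymbol() == "C"
        and a.GetIdx() != c4p
        and _carbonyl_oxygen(mol, a.GetIdx()) is not None
    )
    o3 = _carbonyl_oxygen(mol, c3p)
    ca3 = next(
        a.GetIdx() for a in mol.GetAtomWithIdx(c3p).GetNeighbors() if a.GetSymbol() == "C"
    )
    n3 = next(
        a.GetIdx() for a in mol.GetAtomWithIdx(ca3).GetNeighbors() if a.GetSymbol() == "N"
    )

    cbz = mol.GetSubstructMatches(_CBZ)
    if len(cbz) != 1:
        raise ChemError(f"expected one Cbz carbamate, found {len(cbz)}")
    o1, c1p, ca1, _benzyl_c, n2, ca2 = cbz[0]
    c2p = next(
        a.GetIdx()
        for a in mol.GetAtomWithIdx(ca2).GetNeighbors()
        if a.GetSymbol() == "C"
        and n3 in [x.GetIdx() for x in a.GetNeighbors()]
    )

    roles = RoleMap(
        donor_n=n5,
        donor_h=h5,
        acceptor_o_pos3=o3,
        acceptor_o_pos1=o1,
        calpha_surrogates=[ca1, ca2, ca3, ca4, ca5],
        backbone_paths={
            1: (None, ca1, c1p),
            2: (n2, ca2, c2p),
            3: (n3, ca3, c3p),
            4: (n4, ca4, c4p),
            5: (n5, ca5, None),
        },
    )
    roles.validate(g)
    return roles
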