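"""Per-conformer geometric analysis of reverse turns.

Given 3D coordinates for a molecular graph and a role map assigning scaffold
atoms to pseudo-residue positions 1-5, this module detects intramolecular
hydrogen bonds (with their pseudo-cycle ring size), measures the generic
turn probe d_alpha (the distance between the position-1 and position-5
C-alpha surrogates; < 7 A indicates a reverse turn), and computes the
virtual phi/psi torsions of the amide backbone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import ChemError, MolecularGraph, RoleMap, hbond_typing, pseudo_ring_size

__all__ = [
    "GeometryError",
    "HBondCriteria",
    "HBondContact",
    "TurnFlags",
    "measure_distance",
    "bond_angle",
    "dihedral",
    "kabsch_rmsd",
    "detect_hbonds",
    "virtual_torsions",
    "flag_turns",
    "DALPHA_CUTOFF",
]

#: Generic reverse-turn probe: d_alpha strictly below this passes.
DALPHA_CUTOFF = 7.0


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Vector primitives
# ---------------------------------------------------------------------------


def _coords(c) -> np.ndarray:
    """Accept a Conformer-like object (``.coords``) or a plain (n,3) array."""
    xyz = getattr(c, "coords", c)
    return np.asarray(xyz, dtype=float)


def measure_distance(c, i: int, j: int) -> float:
    """Euclidean distance (A) between atoms ``i`` and ``j``."""
    xyz = _coords(c)
    n = len(xyz)
    for k in (i, j):
        if not (0 <= k < n):
            raise GeometryError(f"invalid atom id {k}")
    return float(np.linalg.norm(xyz[i] - xyz[j]))


def bond_angle(p0, p1, p2) -> float:
    """Angle at ``p1`` in degrees."""
    u = np.asarray(p0, float) - np.asarray(p1, float)
    v = np.asarray(p2, float) - np.asarray(p1, float)
    cosa = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosa))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention,
    wrapped to (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    ang = math.degrees(math.atan2(np.dot(np.cross(b1n, v), w), np.dot(v, w)))
    return 180.0 if ang == -180.0 else ang


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Best-fit RMSD between two equally-indexed coordinate sets."""
    p = np.asarray(p, float) - np.asarray(p, float).mean(axis=0)
    q = np.asarray(q, float) - np.asarray(q, float).mean(axis=0)
    v, _s, wt = np.linalg.svd(p.T @ q)
    d = np.sign(np.linalg.det(v @ wt))
    rot = v @ np.diag([1.0, 1.0, d]) @ wt
    return float(np.sqrt(((p @ rot - q) ** 2).sum() / len(p)))


# ---------------------------------------------------------------------------
# H-bond detection
# ---------------------------------------------------------------------------


@dataclass
class HBondCriteria:
    """Geometric criteria for an intramolecular H-bond.

    ``mode="hydrogen"`` uses the H···acceptor distance plus the D-H···A
    angle; ``mode="heavy"`` uses only the donor···acceptor heavy-atom
    distance (for ensembles without reliable hydrogen coordinates).
    """

    max_ha_distance: float = 2.5  # A
    min_dha_angle: float = 120.0  # degrees
    max_heavy_distance: float = 3.5  # A, heavy-atom mode
    mode: str = "hydrogen"

    def __post_init__(self):
        if self.max_ha_distance <= 0 or self.max_heavy_distance <= 0:
            raise GeometryError("distance cutoffs must be positive")
        if not (0 < self.min_dha_angle <= 180):
            raise GeometryError("angle cutoff must be in (0, 180]")
        if self.mode not in ("hydrogen", "heavy"):
            raise GeometryError(f"unknown criteria mode {self.mode!r}")


@dataclass
class HBondContact:
    donor_n: int
    donor_h: int
    acceptor: int
    distance: float  # H···A (hydrogen mode) or D···A (heavy mode), A
    angle: float | None  # D-H···A, degrees (None in heavy mode)
    ring_size: int
    label: str  # "5→3" | "5→1" | "other"


def detect_hbonds(
    c,
    g: MolecularGraph,
    crit: HBondCriteria | None = None,
    roles: RoleMap | None = None,
) -> list[HBondContact]:
    """All donor/acceptor pairs satisfying the geometric criteria.

    Pairs whose covalent H→acceptor path is 3 bonds or fewer (pseudo-ring
    size < 5) are skipped: this excludes the trivial contact of an amide
    hydrogen with its own carbonyl oxygen.  Contacts are annotated with the
    pseudo-cycle ring size and, when a role map is given, the positional
    label of the turn taxonomy; output is sorted by ring size.
    """
    crit = crit or HBondCriteria()
    xyz = _coords(c)
    if len(xyz) != g.n_atoms:
        raise GeometryError(
            f"coordinate count {len(xyz)} != atom count {g.n_atoms}"
        )
    donors, acceptors = hbond_typing(g)
    out: list[HBondContact] = []
    for d_heavy, d_h in donors:
        for a in acceptors:
            if a == d_heavy:
                continue
            ring = pseudo_ring_size(g, d_h, a)
            if ring < 5:
                continue
            if crit.mode == "hydrogen":
                dist = measure_distance(xyz, d_h, a)
                if dist > crit.max_ha_distance:
                    continue
                ang = bond_angle(xyz[d_heavy], xyz[d_h], xyz[a])
                if ang < crit.min_dha_angle:
                    continue
            else:
                dist = measure_distance(xyz, d_heavy, a)
                if dist > crit.max_heavy_distance:
                    continue
                ang = None
            label = "other"
            if roles is not None and d_h == roles.donor_h:
                if a == roles.acceptor_o_pos3:
                    label = "5→3"
                elif a == roles.acceptor_o_pos1:
                    label = "5→1"
            out.append(
                HBondContact(
                    donor_n=d_heavy,
                    donor_h=d_h,
                    acceptor=a,
                    distance=dist,
                    angle=ang,
                    ring_size=ring,
                    label=label,
                )
            )
    out.sort(key=lambda hb: (hb.ring_size, hb.donor_h, hb.acceptor))
    return out


# ---------------------------------------------------------------------------
# Virtual torsions and turn flags
# ---------------------------------------------------------------------------


def virtual_torsions(c, roles: RoleMap) -> dict[int, tuple[float | None, float | None]]:
    """Virtual phi/psi pairs per pseudo-residue.

    phi(k) = dihedral(C'(k-1), N(k), CA(k), C'(k));
    psi(k) = dihedral(N(k), CA(k), C'(k), N(k+1)).
    Entries are ``None`` where the chain terminates (no preceding C' or no
    following N).  Angles are wrapped to (-180, 180].
    """
    xyz = _coords(c)
    paths = roles.backbone_paths
    if not paths:
        raise ChemError("role map has no backbone paths")
    out: dict[int, tuple[float | None, float | None]] = {}
    for k in sorted(paths):
        n_k, ca_k, cp_k = paths[k]
        phi = psi = None
        prev = paths.get(k - 1)
        nxt = paths.get(k + 1)
        if prev is not None and prev[2] is not None and None not in (n_k, ca_k, cp_k):
            phi = dihedral(xyz[prev[2]], xyz[n_k], xyz[ca_k], xyz[cp_k])
        if nxt is not None and nxt[0] is not None and None not in (n_k, ca_k, cp_k):
            psi = dihedral(xyz[n_k], xyz[ca_k], xyz[cp_k], xyz[nxt[0]])
        out[k] = (phi, psi)
    return out


@dataclass
class TurnFlags:
    """Per-conformer turn descriptors (one row of the ensemble table)."""

    has_hbond_a: bool  # 7-ring, 5→3 (gamma-type)
    has_hbond_b: bool  # 13-ring, 5→1 (alpha-type)
    dalpha: float
    dalpha_probe_pass: bool  # strictly d_alpha < 7 A
    torsions: dict[int, tuple[float | None, float | None]] = field(default_factory=dict)
    contacts: list[HBondContact] = field(default_factory=list)


def flag_turns(
    c,
    g: MolecularGraph,
    crit: HBondCriteria | None = None,
    roles: RoleMap | None = None,
    dalpha_cutoff: float = DALPHA_CUTOFF,
) -> TurnFlags:
    """Assemble the turn flags of one conformer.

    H-bond A is the 7-ring 5→3 contact (gamma-turn signature) and H-bond B
    the 13-ring 5→1 contact (alpha-turn signature); d_alpha is measured
    between the position-1 and position-5 C-alpha surrogates.
    """
    if roles is None:
        raise ChemError("flag_turns requires a role map")
    contacts = detect_hbonds(c, g, crit, roles)
    has_a = any(hb.label == "5→3" and hb.ring_size == 7 for hb in contacts)
    has_b = any(hb.label == "5→1" and hb.ring_size == 13 for hb in contacts)
    da = measure_distance(c, roles.calpha_surrogates[0], roles.calpha_surrogates[-1])
    return TurnFlags(
        has_hbond_a=has_a,
        has_hbond_b=has_b,
        dalpha=da,
        dalpha_probe_pass=da < dalpha_cutoff,
        torsions=virtual_torsions(c, roles),
        contacts=contacts,
    )
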