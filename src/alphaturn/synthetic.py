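"""Synthetic inputs: ideal peptide backbones from internal coordinates,
random-torsion decoy sets, labelled energy sets, and noisy NMR series.

The turn-detection logic is scaffold-agnostic, so ideal polyalanine-free
(backbone-only) peptides built from standard internal coordinates are the
cleanest test substrate: an all-(-63, -42) pentapeptide closes the
13-membered 5→1 H-bond of an alpha-turn, a central (-75, 65) tripeptide
closes the 7-membered contact of an inverse gamma-turn, and an extended
chain closes nothing.  Amides are fixed trans (omega = 180 deg); the
carbonyl O and amide H are placed trans across the amide plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from rdkit import Chem

from .chem import ChemError, MolecularGraph, RoleMap
from .conformers import Conformer
from .nmr import NmrSeries

__all__ = [
    "BackboneSpec",
    "BackboneResult",
    "build_backbone",
    "DecoySet",
    "make_decoys",
    "EnergySet",
    "make_energy_set",
    "make_nmr_series",
]

# Standard backbone internal coordinates (lengths in A, angles in degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_C_N_H = 119.0


@dataclass
class BackboneSpec:
    """Number of residues and per-residue (phi, psi); omega fixed at 180."""

    torsions: list[tuple[float, float]]  # (phi, psi) per residue
    omega: float = 180.0

    def __post_init__(self):
        if len(self.torsions) < 2:
            raise ValueError("need at least 2 residues")
        for phi, psi in self.torsions:
            for a in (phi, psi):
                if not (-180.0 < a <= 180.0 or a == -180.0):
                    raise ValueError(f"torsion {a} outside (-180, 180]")

    @property
    def n_residues(self) -> int:
        return len(self.torsions)


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, chi: float) -> np.ndarray:
    """Place atom d with |c-d| = r, angle(b,c,d) = theta and dihedral
    (a,b,c,d) = chi (degrees) — natural-extension reference frame."""
    th, ch = np.radians(theta), np.radians(chi)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = r * np.array(
        [-np.cos(th), np.sin(th) * np.cos(ch), np.sin(th) * np.sin(ch)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


class BackboneResult(NamedTuple):
    graph: MolecularGraph
    conformer: Conformer
    roles: RoleMap


def build_backbone(
    spec: BackboneSpec,
    jitter_deg: float = 0.0,
    seed: int | None = None,
) -> BackboneResult:
    """Build an ideal backbone (atoms N, H, CA, C', O per residue) by
    sequential internal-coordinate placement.

    Recomputing phi/psi from the coordinates reproduces the spec within
    0.5 degrees (exactly, up to float error).  ``jitter_deg`` adds uniform
    torsional noise (seeded) and is used by the decoy generator.  The
    returned role map assigns the last residue's NH as the donor, the first
    residue's carbonyl O as the position-1 acceptor and the third-from-last
    carbonyl O as the position-3 acceptor, with CA atoms as their own
    surrogates.
    """
    n = spec.n_residues
    torsions = [list(t) for t in spec.torsions]
    if jitter_deg:
        rng = np.random.default_rng(seed)
        for t in torsions:
            t[0] = (t[0] + rng.uniform(-jitter_deg, jitter_deg) + 180.0) % 360.0 - 180.0
            t[1] = (t[1] + rng.uniform(-jitter_deg, jitter_deg) + 180.0) % 360.0 - 180.0

    # index bookkeeping: per residue i (0-based): N, H, CA, C, O
    N, H, CA, C, O = {}, {}, {}, {}, {}
    coords: list[np.ndarray] = []

    def add(p: np.ndarray) -> int:
        coords.append(np.asarray(p, float))
        return len(coords) - 1

    for i in range(n):
        phi, psi = torsions[i]
        if i == 0:
            N[0] = add([0.0, 0.0, 0.0])
            CA[0] = add([BOND_N_CA, 0.0, 0.0])
            ang = np.radians(ANGLE_N_CA_C)
            C[0] = add(
                coords[CA[0]]
                + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
            )
            H[0] = add(
                _nerf(coords[C[0]], coords[CA[0]], coords[N[0]], BOND_N_H, ANGLE_C_N_H, 180.0)
            )
        else:
            prev_phi, prev_psi = torsions[i - 1]
            N[i] = add(
                _nerf(coords[N[i - 1]], coords[CA[i - 1]], coords[C[i - 1]], BOND_C_N, ANGLE_CA_C_N, prev_psi)
            )
            CA[i] = add(
                _nerf(coords[CA[i - 1]], coords[C[i - 1]], coords[N[i]], BOND_N_CA, ANGLE_C_N_CA, spec.omega)
            )
            # amide H trans to the carbonyl O of the previous residue
            H[i] = add(
                _nerf(coords[CA[i - 1]], coords[C[i - 1]], coords[N[i]], BOND_N_H, ANGLE_C_N_H, 0.0)
            )
            C[i] = add(
                _nerf(coords[C[i - 1]], coords[N[i]], coords[CA[i]], BOND_CA_C, ANGLE_N_CA_C, phi)
            )
        # carbonyl O trans (in the amide plane) to the next N
        O[i] = add(
            _nerf(coords[N[i]], coords[CA[i]], coords[C[i]], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        )

    graph = _backbone_graph(n, N, H, CA, C, O)
    conf = Conformer(coords=np.array(coords), energy=0.0, source="build_backbone")

    donor_res = n - 1
    pos3_res = max(0, n - 3)
    roles = RoleMap(
        donor_n=N[donor_res],
        donor_h=H[donor_res],
        acceptor_o_pos3=O[pos3_res],
        acceptor_o_pos1=O[0],
        calpha_surrogates=[CA[i] for i in range(n)],
        backbone_paths={
            i + 1: (N[i], CA[i], C[i]) for i in range(n)
        },
    )
    roles.validate(graph)
    return BackboneResult(graph, conf, roles)


def _backbone_graph(n, N, H, CA, C, O) -> MolecularGraph:
    """RDKit graph matching the builder's atom order."""
    rw = Chem.RWMol()
    idx = {}
    total = 5 * n
    order = [None] * total
    for i in range(n):
        order[N[i]] = "N"
        order[H[i]] = "H"
        order[CA[i]] = "C"
        order[C[i]] = "C"
        order[O[i]] = "O"
    for sym in order:
        a = Chem.Atom(sym)
        if sym == "H":
            a.SetNoImplicit(True)
        rw.AddAtom(a)
    for i in range(n):
        rw.AddBond(N[i], H[i], Chem.BondType.SINGLE)
        rw.AddBond(N[i], CA[i], Chem.BondType.SINGLE)
        rw.AddBond(CA[i], C[i], Chem.BondType.SINGLE)
        rw.AddBond(C[i], O[i], Chem.BondType.DOUBLE)
        if i + 1 < n:
            rw.AddBond(C[i], N[i + 1], Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return MolecularGraph(mol)


class DecoySet(NamedTuple):
    graph: MolecularGraph
    roles: RoleMap
    conformers: list[Conformer]


def make_decoys(n: int, seed: int, n_residues: int = 5) -> DecoySet:
    """``n`` backbones with phi/psi drawn uniformly on (-180, 180];
    deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    graph = roles = None
    confs: list[Conformer] = []
    for k in range(n):
        torsions = [
            (float(rng.uniform(-180.0, 180.0)), float(rng.uniform(-180.0, 180.0)))
            for _ in range(n_residues)
        ]
        g, c, r = build_backbone(BackboneSpec(torsions))
        c.source = f"decoy:{k}"
        if graph is None:
            graph, roles = g, r
        confs.append(c)
    return DecoySet(graph, roles, confs)


class EnergySet(NamedTuple):
    labels: list[str]
    relative_energies: np.ndarray

    def members(self, label: str) -> np.ndarray:
        return np.array([lab == label for lab in self.labels])


def make_energy_set(spec: Sequence[tuple[str, float]]) -> EnergySet:
    """Labelled relative energies, e.g. [("alpha", 0.0), ("gamma", 3.0)].
    Requires one ΔE = 0 member (the global minimum)."""
    if not spec:
        raise ValueError("empty energy spec")
    energies = np.array([de for _lab, de in spec], dtype=float)
    if not np.any(energies == 0.0):
        raise ValueError("energy set must contain a ΔE = 0 member")
    return EnergySet([lab for lab, _de in spec], energies)


def make_nmr_series(
    slope_ppb_per_k: float,
    intercept_ppm: float,
    sigma_ppm: float,
    t_range: tuple[float, float] = (263.0, 328.0),
    n_points: int = 8,
    seed: int = 0,
    label: str = "NH",
) -> NmrSeries:
    """Linear-with-noise variable-temperature series:
    δ_i = intercept + slope·(T_i − T_min)/1000 + ε_i, ε ~ N(0, σ²)."""
    if n_points < 3:
        raise ValueError("need at least 3 points")
    lo, hi = t_range
    if not (hi > lo):
        raise ValueError("invalid temperature range")
    rng = np.random.default_rng(seed)
    temps = np.linspace(lo, hi, n_points)
    shifts = intercept_ppm + slope_ppb_per_k * (temps - lo) / 1000.0
    if sigma_ppm:
        shifts = shifts + rng.normal(0.0, sigma_ppm, size=n_points)
    return NmrSeries(label=label, points=list(zip(temps.tolist(), shifts.tolist())))
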