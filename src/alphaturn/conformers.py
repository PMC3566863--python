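"""Conformer ensemble generation: stochastic multi-start search with local
minimization, duplicate removal, and energy-window filtering.

The search driver is backend-agnostic.  A backend supplies three things:
random starting coordinates, a local minimizer, and a single-point energy.
The default :class:`MMFFBackend` uses distance-geometry (ETKDG) embedding —
which honours stereo descriptors, as required for the fused-tetracycle
epimers — followed by MMFF94 minimization.  The
:class:`TorsionPotentialBackend` drives a toy one-torsion molecule on an
analytic potential and exists so the driver can be validated against a grid
scan.

Energies are reported relative to the ensemble minimum; absolute backend
zeros are never compared across backends.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolTransforms
from rdkit.Chem.Lipinski import RotatableBondSmarts
from scipy.optimize import minimize as _sp_minimize

from .chem import ChemError, MolecularGraph
from .geometry import dihedral, kabsch_rmsd

__all__ = [
    "ConformerError",
    "Conformer",
    "Ensemble",
    "SearchConfig",
    "MMFFBackend",
    "TorsionPotentialBackend",
    "three_well_potential",
    "mc_search",
    "deduplicate",
    "energy_window",
    "rotatable_torsion_quads",
    "write_sdf",
    "read_sdf",
    "write_xyz",
]


class ConformerError(RuntimeError):
    pass


@dataclass
class Conformer:
    """Cartesian coordinates (A) with an energy (kcal/mol, backend zero)."""

    coords: np.ndarray
    energy: float
    source: str = ""
    minimized: bool = True

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)


@dataclass
class Ensemble:
    """Energy-sorted, deduplicated conformer collection for one graph."""

    graph: MolecularGraph | None
    conformers: list[Conformer]

    def __post_init__(self):
        self.conformers = sorted(self.conformers, key=lambda c: c.energy)

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def __getitem__(self, i):
        return self.conformers[i]

    @property
    def relative_energies(self) -> np.ndarray:
        if not self.conformers:
            return np.empty(0)
        e = np.array([c.energy for c in self.conformers])
        return e - e[0]


@dataclass
class SearchConfig:
    """Search parameters.  Defaults mirror the study conditions: 972 starts
    and a 6 kcal/mol retention window; duplicate tolerances (20 deg circular
    torsion difference, 0.5 A heavy-atom RMSD) merge vibrational noise
    without merging distinct wells."""

    n_starts: int = 972
    energy_window: float = 6.0  # kcal/mol
    torsion_tol: float = 20.0  # degrees
    rmsd_tol: float = 0.5  # A
    seed: int = 11
    backend: str = "mmff"
    max_embed_retries: int = 3

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.energy_window <= 0:
            raise ValueError("energy window must be positive")
        if self.torsion_tol <= 0 or self.rmsd_tol <= 0:
            raise ValueError("duplicate tolerances must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d) -> "SearchConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SearchConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------


class MMFFBackend:
    """Torsional Monte Carlo starts + MMFF94 minimization (RDKit).

    Start generation embeds the molecule a few times with ETKDG distance
    geometry — which fixes the (rigid) ring-system geometry and honours the
    stereo descriptors — and then sets every rotatable-bond torsion to a
    uniform random angle for each start.  Random torsional starts sample
    folded, H-bonded arrangements evenly, which the knowledge-based torsion
    priors of plain distance-geometry embedding strongly under-sample.  For
    molecules without rotatable bonds the generator falls back to one
    embedding per start.

    The graph must carry all hydrogens explicitly (``with_all_hydrogens``)
    so that coordinates line up with role-map atom ids.
    """

    name = "mmff"

    def __init__(self, variant: str = "MMFF94", max_iters: int = 2000, n_embed_bases: int = 8):
        self.variant = variant
        self.max_iters = max_iters
        self.n_embed_bases = n_embed_bases

    @staticmethod
    def _check_protonated(g: MolecularGraph) -> Chem.Mol:
        mol = g.mol
        if Chem.AddHs(mol).GetNumAtoms() != mol.GetNumAtoms():
            raise ConformerError(
                "graph has implicit hydrogens; call with_all_hydrogens() first"
            )
        return mol

    def _embed(
        self, mol: Chem.Mol, n: int, seed: int, max_retries: int
    ) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        attempt = 0
        while len(out) < n and attempt <= max_retries:
            params = AllChem.ETKDGv3()
            params.randomSeed = int(seed) + 7919 * attempt
            params.numThreads = 1
            probe = Chem.Mol(mol)
            cids = AllChem.EmbedMultipleConfs(
                probe, numConfs=n - len(out), params=params
            )
            for cid in cids:
                out.append(np.array(probe.GetConformer(cid).GetPositions()))
            attempt += 1
        if not out:
            raise ConformerError(
                f"distance-geometry embedding failed after {max_retries} retries"
            )
        return out[:n]

    def generate_starts(
        self, g: MolecularGraph, n: int, seed: int, max_retries: int = 3
    ) -> list[np.ndarray]:
        mol = Chem.Mol(self._check_protonated(g))
        quads = rotatable_torsion_quads(g)
        if not quads:
            return self._embed(mol, n, seed, max_retries)
        bases = self._embed(mol, min(n, self.n_embed_bases), seed, max_retries)
        rng = np.random.default_rng(int(seed))
        work = Chem.Mol(mol)
        work.RemoveAllConformers()
        conf = Chem.Conformer(mol.GetNumAtoms())
        starts: list[np.ndarray] = []
        for i in range(n):
            base = bases[i % len(bases)]
            for k, p in enumerate(base):
                conf.SetAtomPosition(k, p.tolist())
            work.RemoveAllConformers()
            cid = work.AddConformer(conf, assignId=True)
            wconf = work.GetConformer(cid)
            for q in quads:
                rdMolTransforms.SetDihedralDeg(
                    wconf, *q, float(rng.uniform(-180.0, 180.0))
                )
            starts.append(np.array(wconf.GetPositions()))
        return starts

    def _ff(self, mol: Chem.Mol, conf_id: int):
        props = AllChem.MMFFGetMoleculeProperties(mol, mmffVariant=self.variant)
        if props is None:
            raise ConformerError("MMFF parameters unavailable for this molecule")
        return AllChem.MMFFGetMoleculeForceField(mol, props, confId=conf_id)

    def _mol_with_coords(self, g: MolecularGraph, coords_list) -> Chem.Mol:
        mol = Chem.Mol(self._check_protonated(g))
        mol.RemoveAllConformers()
        for k, xyz in enumerate(coords_list):
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, p in enumerate(np.asarray(xyz, float)):
                conf.SetAtomPosition(i, p.tolist())
            conf.SetId(k)
            mol.AddConformer(conf, assignId=False)
        return mol

    def energy(self, g: MolecularGraph, coords: np.ndarray) -> float:
        mol = self._mol_with_coords(g, [coords])
        return float(self._ff(mol, 0).CalcEnergy())

    def minimize(self, g: MolecularGraph, coords: np.ndarray):
        return self.minimize_many(g, [coords])[0]

    def minimize_many(self, g: MolecularGraph, coords_list):
        """Minimize a batch of starts; returns [(coords, energy), ...]."""
        mol = self._mol_with_coords(g, coords_list)
        results = AllChem.MMFFOptimizeMoleculeConfs(
            mol, mmffVariant=self.variant, maxIters=self.max_iters, numThreads=1
        )
        out = []
        for cid, (_converged, energy) in enumerate(results):
            xyz = np.array(mol.GetConformer(cid).GetPositions())
            out.append((xyz, float(energy)))
        return out


def three_well_potential(theta_deg: float) -> float:
    """Analytic one-torsion test potential, kcal/mol:
    E(theta) = 2.0*(1 + cos theta) + 0.6*(1 - cos 3*theta)."""
    t = np.radians(theta_deg)
    return float(2.0 * (1 + np.cos(t)) + 0.6 * (1 - np.cos(3 * t)))


class TorsionPotentialBackend:
    """Analytic torsional potential on a 4-atom toy chain.

    The single degree of freedom is the central dihedral; coordinates are
    rebuilt from it with fixed 1.53 A bonds and 111 deg angles.  Local
    minimization runs on the torsion via Nelder-Mead, so a start relaxes
    into its own basin — exactly what a grid-scan oracle can cross-check.
    """

    name = "torsion"

    _L = 1.53
    _ANG = 111.0

    def __init__(self, potential=three_well_potential):
        self.potential = potential

    @staticmethod
    def toy_graph() -> MolecularGraph:
        return MolecularGraph.from_smiles("CCCC")

    def coords_from_theta(self, theta_deg: float) -> np.ndarray:
        l, ang = self._L, np.radians(self._ANG)
        p1 = np.array([0.0, 0.0, 0.0])
        p2 = np.array([l, 0.0, 0.0])
        p0 = p1 + l * np.array([np.cos(ang), np.sin(ang), 0.0])
        # place p3 off p2 with the requested dihedral p0-p1-p2-p3
        t = np.radians(theta_deg)
        d = np.array(
            [
                -np.cos(ang),
                np.sin(ang) * np.cos(t),
                np.sin(ang) * np.sin(t),
            ]
        )
        p3 = p2 + l * d
        return np.array([p0, p1, p2, p3])

    @staticmethod
    def theta_from_coords(coords: np.ndarray) -> float:
        c = np.asarray(coords, float)
        return dihedral(c[0], c[1], c[2], c[3])

    def generate_starts(self, g, n: int, seed: int, max_retries: int = 0):
        rng = np.random.default_rng(seed)
        thetas = rng.uniform(-180.0, 180.0, size=n)
        return [self.coords_from_theta(t) for t in thetas]

    def energy(self, g, coords) -> float:
        return self.potential(self.theta_from_coords(coords))

    def minimize(self, g, coords):
        t0 = self.theta_from_coords(coords)
        res = _sp_minimize(
            lambda x: self.potential(x[0]),
            x0=[t0],
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12},
        )
        theta = (res.x[0] + 180.0) % 360.0 - 180.0
        return self.coords_from_theta(theta), float(res.fun)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def rotatable_torsion_quads(g: MolecularGraph) -> list[tuple[int, int, int, int]]:
    """One representative dihedral atom quadruple per rotatable bond."""
    mol = g.mol
    quads = []
    for i, j in mol.GetSubstructMatches(RotatableBondSmarts):
        ai, aj = mol.GetAtomWithIdx(i), mol.GetAtomWithIdx(j)
        ni = min(
            (a.GetIdx() for a in ai.GetNeighbors() if a.GetIdx() != j),
            default=None,
        )
        nj = min(
            (a.GetIdx() for a in aj.GetNeighbors() if a.GetIdx() != i),
            default=None,
        )
        if ni is not None and nj is not None:
            quads.append((ni, i, j, nj))
    return quads


def _circ_diff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def deduplicate(
    conformers: list[Conformer],
    graph: MolecularGraph | None = None,
    torsion_tol: float = 20.0,
    rmsd_tol: float = 0.5,
) -> Ensemble:
    """Greedy keep-lowest-energy-first duplicate removal.

    A candidate is a duplicate of a kept member if every rotatable-torsion
    difference is below ``torsion_tol`` (circular), or if the heavy-atom
    best-fit RMSD is below ``rmsd_tol``.  The torsion criterion only applies
    when the graph has at least one rotatable bond.
    """
    if not conformers:
        return Ensemble(graph, [])
    n_atoms = {c.coords.shape[0] for c in conformers}
    if len(n_atoms) > 1:
        raise ConformerError(f"mixed parent graphs: atom counts {sorted(n_atoms)}")
    if graph is not None and n_atoms != {graph.n_atoms}:
        raise ConformerError("conformer atom count does not match graph")

    quads = rotatable_torsion_quads(graph) if graph is not None else []
    if graph is not None:
        heavy = [
            a.GetIdx() for a in graph.mol.GetAtoms() if a.GetAtomicNum() > 1
        ]
    else:
        heavy = list(range(conformers[0].coords.shape[0]))

    def torsions(c: Conformer):
        return [dihedral(*(c.coords[k] for k in q)) for q in quads]

    ordered = sorted(conformers, key=lambda c: c.energy)
    kept: list[tuple[Conformer, list[float]]] = []
    for cand in ordered:
        ct = torsions(cand)
        dup = False
        for ref, rt in kept:
            if quads and all(_circ_diff(a, b) < torsion_tol for a, b in zip(ct, rt)):
                dup = True
                break
            if kabsch_rmsd(cand.coords[heavy], ref.coords[heavy]) < rmsd_tol:
                dup = True
                break
        if not dup:
            kept.append((cand, ct))
    return Ensemble(graph, [c for c, _t in kept])


def mc_search(
    g: MolecularGraph, cfg: SearchConfig, backend
) -> Ensemble:
    """Multi-start stochastic search: ``cfg.n_starts`` random starts, each
    locally minimized, then deduplicated.  The energy window is applied
    separately (:func:`energy_window`).  Reproducible for a fixed
    (graph, config, backend, seed)."""
    starts = backend.generate_starts(
        g, cfg.n_starts, cfg.seed, max_retries=cfg.max_embed_retries
    )
    results = []
    if hasattr(backend, "minimize_many"):
        results = backend.minimize_many(g, starts)
    else:
        for k, xyz in enumerate(starts):
            try:
                results.append(backend.minimize(g, xyz))
            except Exception as exc:  # noqa: BLE001 - annotate start index
                raise ConformerError(f"minimization failed at start {k}: {exc}") from exc
    confs = [
        Conformer(coords=xyz, energy=e, source=f"start:{k}", minimized=True)
        for k, (xyz, e) in enumerate(results)
        if np.isfinite(e)
    ]
    if not confs:
        raise ConformerError("no finite-energy minima produced")
    return deduplicate(confs, g, cfg.torsion_tol, cfg.rmsd_tol)


def energy_window(e: Ensemble, window: float) -> Ensemble:
    """Members with relative energy <= ``window`` (boundary inclusive; the
    global minimum is always retained)."""
    if window <= 0:
        raise ValueError("window must be positive")
    if not e.conformers:
        raise ConformerError("cannot window an empty ensemble")
    rel = e.relative_energies
    kept = [c for c, de in zip(e.conformers, rel) if de <= window]
    out = Ensemble(e.graph, copy.copy(kept))
    return out


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

ENERGY_PROP = "energy_kcal"
REL_ENERGY_PROP = "rel_energy_kcal"


def write_sdf(ensemble: Ensemble, path) -> None:
    """Multi-record SDF with absolute and relative energy property fields."""
    if ensemble.graph is None:
        raise ConformerError("ensemble has no parent graph to serialise")
    mol = Chem.Mol(ensemble.graph.mol)
    mol.RemoveAllConformers()
    rel = ensemble.relative_energies
    with Chem.SDWriter(str(path)) as writer:
        for k, (c, de) in enumerate(zip(ensemble.conformers, rel)):
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, p in enumerate(c.coords):
                conf.SetAtomPosition(i, p.tolist())
            conf.SetId(0)
            m = Chem.Mol(mol)
            m.RemoveAllConformers()
            m.AddConformer(conf, assignId=False)
            m.SetProp(ENERGY_PROP, f"{c.energy:.6f}")
            m.SetProp(REL_ENERGY_PROP, f"{de:.6f}")
            m.SetProp("_Name", f"conformer_{k}")
            writer.write(m)


def read_sdf(path) -> Ensemble:
    """Read a multi-record SDF written by :func:`write_sdf` (or any SDF whose
    records share one molecule and carry an energy property)."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    graph: MolecularGraph | None = None
    confs: list[Conformer] = []
    for k, mol in enumerate(supplier):
        if mol is None:
            raise ConformerError(f"unreadable SDF record {k}")
        if graph is None:
            graph = MolecularGraph(Chem.Mol(mol))
        if not mol.HasProp(ENERGY_PROP):
            raise ConformerError(f"SDF record {k} lacks {ENERGY_PROP!r}")
        xyz = np.array(mol.GetConformer().GetPositions())
        confs.append(
            Conformer(coords=xyz, energy=float(mol.GetProp(ENERGY_PROP)), source=f"sdf:{k}")
        )
    if graph is None:
        raise ConformerError("empty SDF")
    return Ensemble(graph, confs)


def write_xyz(ensemble: Ensemble, path) -> None:
    """Multi-frame XYZ (element symbols from the parent graph)."""
    if ensemble.graph is None:
        raise ConformerError("ensemble has no parent graph to serialise")
    symbols = [a.GetSymbol() for a in ensemble.graph.mol.GetAtoms()]
    with open(path, "w") as fh:
        for k, c in enumerate(ensemble.conformers):
            fh.write(f"{len(symbols)}\n")
            fh.write(f"conformer {k} energy_kcal {c.energy:.6f}\n")
            for sym, p in zip(symbols, c.coords):
                fh.write(f"{sym} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
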