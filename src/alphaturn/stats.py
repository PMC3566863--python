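"""Boltzmann ensemble statistics and the turn-analysis summary table.

Populations follow w_i ∝ exp(-ΔE_i / RT) with R = 0.0019872 kcal/(mol·K);
the default temperature of 298.15 K matches the room-temperature NMR
comparison.  Torsion averages are circular means; the reported averages are
Boltzmann-weighted, because the study's printed averages are taken over the
conformers dominating the Boltzmann population (unweighted variants are
reported alongside).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .classify import RegionMap, classify_gamma, turn_designation
from .conformers import Ensemble
from .geometry import TurnFlags

__all__ = [
    "R_KCAL",
    "ClassAbsentError",
    "boltzmann_weights",
    "class_fraction",
    "class_min_gap",
    "circular_mean",
    "BoltzmannSummary",
    "EnsembleReport",
    "table1_report",
]

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 0.0019872


class ClassAbsentError(ValueError):
    """Raised when a statistic is requested for an empty conformer class."""


def boltzmann_weights(relative_energies: Sequence[float], temperature: float = 298.15) -> np.ndarray:
    """Normalised Boltzmann weights of relative energies (kcal/mol)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    de = np.asarray(relative_energies, dtype=float)
    if de.size == 0:
        raise ValueError("empty energy list")
    if not np.all(np.isfinite(de)):
        raise ValueError("energies must be finite")
    # subtract the minimum for overflow safety; weights are shift-invariant
    w = np.exp(-(de - de.min()) / (R_KCAL * temperature))
    return w / w.sum()


def class_fraction(weights: Sequence[float], members: Sequence[bool]) -> float:
    """Summed weight of the flagged class."""
    w = np.asarray(weights, dtype=float)
    m = np.asarray(members, dtype=bool)
    if w.shape != m.shape:
        raise ValueError(f"length mismatch: {w.shape} vs {m.shape}")
    return float(w[m].sum())


def class_min_gap(relative_energies: Sequence[float], members: Sequence[bool]) -> float:
    """Minimum relative energy over class members (kcal/mol above the global
    minimum).  Raises :class:`ClassAbsentError` for an empty class."""
    de = np.asarray(relative_energies, dtype=float)
    m = np.asarray(members, dtype=bool)
    if de.shape != m.shape:
        raise ValueError(f"length mismatch: {de.shape} vs {m.shape}")
    if not m.any():
        raise ClassAbsentError("class has no members")
    return float(de[m].min())


def circular_mean(angles_deg: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """(Weighted) circular mean of angles in degrees, wrapped to (-180, 180]."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("empty angle list")
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != a.shape:
        raise ValueError("weights/angles length mismatch")
    mean = math.degrees(
        math.atan2(float((w * np.sin(a)).sum()), float((w * np.cos(a)).sum()))
    )
    return 180.0 if mean == -180.0 else mean


@dataclass
class BoltzmannSummary:
    temperature: float
    weights: np.ndarray
    class_fractions: dict[str, float] = field(default_factory=dict)
    top_k_fraction: float | None = None


@dataclass
class EnsembleReport:
    """Summary of a windowed, flagged ensemble — one table row per compound:
    conformer count, H-bond A/B and d_alpha-probe counts, global-minimum
    class membership (the "+" marks), Boltzmann class fractions, mean
    d_alpha over the alpha-turn class, per-residue circular-mean torsions,
    the composed designation, and the alpha-class energy gap."""

    n_conformers: int
    temperature: float
    count_hbond_a: int
    count_hbond_b: int
    count_dalpha_probe: int
    global_min_hbond_a: bool
    global_min_hbond_b: bool
    global_min_dalpha_probe: bool
    fraction_hbond_a: float
    fraction_hbond_b: float
    fraction_hbond_a_of_all: float | None
    fraction_hbond_b_of_all: float | None
    mean_dalpha_alpha_class: float | None
    mean_dalpha_alpha_class_weighted: float | None
    alpha_class_min_gap: float | None
    gamma_class_min_gap: float | None
    torsion_means_alpha: dict[int, tuple[float, float]]
    torsion_means_gamma: dict[int, tuple[float, float]]
    torsion_means_alpha_unweighted: dict[int, tuple[float, float]]
    torsion_means_gamma_unweighted: dict[int, tuple[float, float]]
    designation: str | None
    gamma_type: str | None

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in (
            "torsion_means_alpha",
            "torsion_means_gamma",
            "torsion_means_alpha_unweighted",
            "torsion_means_gamma_unweighted",
        ):
            d[key] = {str(k): list(v) for k, v in d[key].items()}
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, ensure_ascii=False, **kwargs)


def _class_circular_means(
    flags: Sequence[TurnFlags],
    members: np.ndarray,
    weights: np.ndarray | None,
) -> dict[int, tuple[float, float]]:
    out: dict[int, tuple[float, float]] = {}
    sel = [f for f, m in zip(flags, members) if m]
    if not sel:
        return out
    wsel = (
        None
        if weights is None
        else np.asarray([w for w, m in zip(weights, members) if m])
    )
    for k in sorted(sel[0].torsions):
        phis = [f.torsions[k][0] for f in sel]
        psis = [f.torsions[k][1] for f in sel]
        if any(v is None for v in phis) or any(v is None for v in psis):
            continue
        out[k] = (circular_mean(phis, wsel), circular_mean(psis, wsel))
    return out


def table1_report(
    ensemble: Ensemble,
    flags: Sequence[TurnFlags],
    temperature: float = 298.15,
    region_map: RegionMap | None = None,
    all_relative_energies: Sequence[float] | None = None,
    designation_residues: tuple[int, int, int] = (2, 3, 4),
    gamma_center_residue: int = 4,
) -> EnsembleReport:
    """Summarise a windowed ensemble whose members carry turn flags.

    ``all_relative_energies`` may give the relative energies of the full
    deduplicated ensemble (window included), in which case class fractions
    are also reported against that wider denominator.  The designation is
    composed from the alpha-class weighted torsion means; the gamma type is
    classified from the gamma-class central residue.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    if len(flags) != len(ensemble):
        raise ValueError("one TurnFlags per windowed conformer required")

    rel = ensemble.relative_energies
    w = boltzmann_weights(rel, temperature)
    in_a = np.array([f.has_hbond_a for f in flags], dtype=bool)
    in_b = np.array([f.has_hbond_b for f in flags], dtype=bool)
    in_da = np.array([f.dalpha_probe_pass for f in flags], dtype=bool)

    frac_a_all = frac_b_all = None
    if all_relative_energies is not None:
        de_all = np.asarray(all_relative_energies, dtype=float)
        w_all = np.exp(-de_all / (R_KCAL * temperature))
        z = w_all.sum()
        # windowed members are a subset of the full set: match by energy rank
        frac_a_all = float(
            sum(
                math.exp(-de / (R_KCAL * temperature))
                for de, m in zip(rel, in_a)
                if m
            )
            / z
        )
        frac_b_all = float(
            sum(
                math.exp(-de / (R_KCAL * temperature))
                for de, m in zip(rel, in_b)
                if m
            )
            / z
        )

    dalpha_b = np.array([f.dalpha for f, m in zip(flags, in_b) if m])
    wb = w[in_b]

    tm_a = _class_circular_means(flags, in_b, w)
    tm_g = _class_circular_means(flags, in_a, w)
    tm_a_u = _class_circular_means(flags, in_b, None)
    tm_g_u = _class_circular_means(flags, in_a, None)

    designation = None
    if all(k in tm_a for k in designation_residues):
        designation = turn_designation(
            [tm_a[k] for k in designation_residues], region_map
        )
    gamma_type = None
    if gamma_center_residue in tm_g:
        gamma_type = classify_gamma(*tm_g[gamma_center_residue])

    def _gap(members: np.ndarray) -> float | None:
        try:
            return class_min_gap(rel, members)
        except ClassAbsentError:
            return None

    return EnsembleReport(
        n_conformers=len(ensemble),
        temperature=temperature,
        count_hbond_a=int(in_a.sum()),
        count_hbond_b=int(in_b.sum()),
        count_dalpha_probe=int(in_da.sum()),
        global_min_hbond_a=bool(in_a[0]),
        global_min_hbond_b=bool(in_b[0]),
        global_min_dalpha_probe=bool(in_da[0]),
        fraction_hbond_a=class_fraction(w, in_a),
        fraction_hbond_b=class_fraction(w, in_b),
        fraction_hbond_a_of_all=frac_a_all,
        fraction_hbond_b_of_all=frac_b_all,
        mean_dalpha_alpha_class=float(dalpha_b.mean()) if dalpha_b.size else None,
        mean_dalpha_alpha_class_weighted=(
            float((dalpha_b * wb / wb.sum()).sum()) if dalpha_b.size else None
        ),
        alpha_class_min_gap=_gap(in_b),
        gamma_class_min_gap=_gap(in_a),
        torsion_means_alpha=tm_a,
        torsion_means_gamma=tm_g,
        torsion_means_alpha_unweighted=tm_a_u,
        torsion_means_gamma_unweighted=tm_g_u,
        designation=designation,
        gamma_type=gamma_type,
    )
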