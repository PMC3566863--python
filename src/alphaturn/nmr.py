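"""Amide-NH hydrogen-bond evidence from solution NMR.

Two classic experiments are quantified:

* variable-temperature series — the temperature coefficient Δδ/ΔT of an
  amide proton (ppb/K).  In a low-polarity solvent (CDCl3 mode) a large
  magnitude indicates an equilibrium between H-bonded and free states,
  while a small magnitude indicates a fully non-H-bonded proton;
* DMSO titration in CDCl3 — the chemical-shift excursion on adding up to
  30% of the competitive acceptor solvent.  A small excursion marks a
  proton shielded by an intramolecular H-bond, a large one a
  solvent-exposed proton.

Thresholds (|Δδ/ΔT| ≥ 4 ppb/K bonded-equilibrium, ≤ 3 non-bonded;
0.5 ppm titration cut) follow common practice for CDCl3 and are exposed as
arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NmrError",
    "NmrSeries",
    "TitrationSeries",
    "temp_coefficient",
    "classify_nh_state",
    "titration_delta",
    "classify_exposure",
    "read_temperature_table",
    "read_titration_table",
]


class NmrError(ValueError):
    pass


@dataclass
class NmrSeries:
    """Variable-temperature chemical shifts of one proton."""

    label: str
    points: list[tuple[float, float]]  # (temperature K, shift ppm)
    solvent: str = "CDCl3"
    concentration_mm: float = 2.0

    def validate(self) -> None:
        if len(self.points) < 3:
            raise NmrError("need at least 3 points for a slope fit")
        temps = [t for t, _ in self.points]
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise NmrError("temperatures must be strictly increasing")
        if not all(np.isfinite(s) for _, s in self.points):
            raise NmrError("non-finite chemical shift")


@dataclass
class TitrationSeries:
    """DMSO-titration chemical shifts of one proton (%DMSO v/v in CDCl3)."""

    label: str
    points: list[tuple[float, float]] = field(default_factory=list)

    def validate(self) -> None:
        if len(self.points) < 2:
            raise NmrError("need at least 2 titration points")
        if self.points[0][0] != 0:
            raise NmrError("titration must anchor at 0% DMSO")
        if any(not (0 <= p <= 30) for p, _ in self.points):
            raise NmrError("DMSO fractions must lie in [0, 30]%")


def temp_coefficient(s: NmrSeries) -> float:
    """Δδ/ΔT in ppb/K: ordinary least-squares slope of δ(ppm) vs T(K), times
    1000.  Signed; classification uses the magnitude."""
    s.validate()
    t = np.array([p[0] for p in s.points])
    d = np.array([p[1] for p in s.points])
    if np.ptp(t) == 0:
        raise NmrError("zero temperature variance")
    slope = np.polyfit(t, d, 1)[0]
    return float(slope * 1000.0)


def classify_nh_state(
    coefficient_ppb_per_k: float,
    solvent: str = "CDCl3",
    bonded_min: float = 4.0,
    non_bonded_max: float = 3.0,
) -> str:
    """Classify an amide NH from |Δδ/ΔT| (CDCl3-mode semantics):
    ``"equilibrium_bonded"`` | ``"non_bonded"`` | ``"indeterminate"``."""
    if solvent.upper().replace("-", "") not in ("CDCL3", "CHCL3"):
        raise NmrError(
            f"classification rules are defined for CDCl3-mode only, got {solvent!r}"
        )
    mag = abs(coefficient_ppb_per_k)
    if mag >= bonded_min:
        return "equilibrium_bonded"
    if mag <= non_bonded_max:
        return "non_bonded"
    return "indeterminate"


def titration_delta(t: TitrationSeries) -> float:
    """δ(max %DMSO) − δ(0%), ppm (signed; depends only on the endpoints)."""
    t.validate()
    pts = sorted(t.points, key=lambda p: p[0])
    return float(pts[-1][1] - pts[0][1])


def classify_exposure(delta_ppm: float, threshold: float = 0.5) -> str:
    """``"shielded"`` (intramolecularly H-bonded, |Δδ| < threshold) or
    ``"exposed"`` (boundary counts as exposed)."""
    return "shielded" if abs(delta_ppm) < threshold else "exposed"


# ---------------------------------------------------------------------------
# Tabular IO: (label, T_K, delta_ppm) and (label, pct_dmso, delta_ppm)
# ---------------------------------------------------------------------------


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_temperature_table(path) -> list[NmrSeries]:
    df = _read_table(path)
    required = {"label", "T_K", "delta_ppm"}
    if not required.issubset(df.columns):
        raise NmrError(f"temperature table needs columns {sorted(required)}")
    out = []
    for label, grp in df.groupby("label", sort=False):
        pts = sorted(zip(grp["T_K"].astype(float), grp["delta_ppm"].astype(float)))
        out.append(NmrSeries(label=str(label), points=[tuple(p) for p in pts]))
    return out


def read_titration_table(path) -> list[TitrationSeries]:
    df = _read_table(path)
    required = {"label", "pct_dmso", "delta_ppm"}
    if not required.issubset(df.columns):
        raise NmrError(f"titration table needs columns {sorted(required)}")
    out = []
    for label, grp in df.groupby("label", sort=False):
        pts = sorted(zip(grp["pct_dmso"].astype(float), grp["delta_ppm"].astype(float)))
        out.append(TitrationSeries(label=str(label), points=[tuple(p) for p in pts]))
    return out
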