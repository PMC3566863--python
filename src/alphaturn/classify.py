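"""phi/psi conformational-region labelling and turn designation.

An alpha-turn is designated by the region labels of its three central
pseudo-residues (2-4), joined with "-" — e.g. "B-αL-X".  A separate
classifier assigns gamma-turn type from the central residue alone:
inverse (phi ~ -75, psi ~ +65) or classic (the mirror image).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import yaml

__all__ = [
    "Region",
    "RegionMap",
    "classify_region",
    "turn_designation",
    "classify_gamma",
    "wrap_angle",
]


def wrap_angle(a: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    w = (a + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


def _in_interval(x: float, lo: float, hi: float) -> bool:
    # closed-low / open-high; an upper bound of 180 is closed because
    # 180 == -180 on the circle and would otherwise be unreachable.
    if lo <= x < hi:
        return True
    return hi == 180.0 and x == 180.0


@dataclass(frozen=True)
class Region:
    label: str
    phi: tuple[float, float]
    psi: tuple[float, float]

    def __post_init__(self):
        for lo, hi in (self.phi, self.psi):
            if not (-180.0 <= lo < hi <= 180.0):
                raise ValueError(f"bad interval [{lo}, {hi}) in region {self.label}")

    def contains(self, phi: float, psi: float) -> bool:
        return _in_interval(phi, *self.phi) and _in_interval(psi, *self.psi)


@dataclass(frozen=True)
class RegionMap:
    """Ordered rectangles; first match wins, else the fallback label."""

    regions: tuple[Region, ...]
    fallback: str = "X"

    @classmethod
    def default(cls) -> "RegionMap":
        with resources.files("alphaturn.data").joinpath("regions.yaml").open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_dict(cls, d) -> "RegionMap":
        regions = tuple(
            Region(r["label"], tuple(map(float, r["phi"])), tuple(map(float, r["psi"])))
            for r in d["regions"]
        )
        return cls(regions=regions, fallback=d.get("fallback", "X"))

    @classmethod
    def from_yaml(cls, path) -> "RegionMap":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "fallback": self.fallback,
            "regions": [
                {"label": r.label, "phi": list(r.phi), "psi": list(r.psi)}
                for r in self.regions
            ],
        }


def classify_region(phi: float, psi: float, m: RegionMap | None = None) -> str:
    """Label of the first rectangle containing (phi, psi), else the fallback.

    Total: every finite pair receives exactly one label."""
    m = m or RegionMap.default()
    phi, psi = wrap_angle(phi), wrap_angle(psi)
    for r in m.regions:
        if r.contains(phi, psi):
            return r.label
    return m.fallback


def turn_designation(
    pairs: Sequence[tuple[float, float]], m: RegionMap | None = None
) -> str:
    """Compose the three-label designation of pseudo-residues 2-4."""
    if len(pairs) != 3:
        raise ValueError(f"need exactly 3 (phi, psi) pairs, got {len(pairs)}")
    return "-".join(classify_region(phi, psi, m) for phi, psi in pairs)


# gamma-turn windows: symmetric about the canonical (±75, ∓65) ideals.
_INV_PHI = (-110.0, -50.0)
_INV_PSI = (40.0, 110.0)


def classify_gamma(phi: float, psi: float) -> str:
    """Gamma-turn type from the central-residue torsions:
    ``"inverse"`` | ``"classic"`` | ``"none"``."""
    phi, psi = wrap_angle(phi), wrap_angle(psi)
    if _in_interval(phi, *_INV_PHI) and _in_interval(psi, *_INV_PSI):
        return "inverse"
    if _in_interval(phi, -_INV_PHI[1], -_INV_PHI[0]) and _in_interval(
        psi, -_INV_PSI[1], -_INV_PSI[0]
    ):
        return "classic"
    return "none"
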