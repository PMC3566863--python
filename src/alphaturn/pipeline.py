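"""One-command orchestration of the turn analysis.

structure + role map + config in → conformer ensemble (SDF), per-conformer
turn flags (TSV), Table-1-style summary (JSON/TSV), turn designation, and —
when NMR tables are supplied — H-bond evidence verdicts (JSON).  A run
manifest records the seed, backend and a config hash so a run can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chem import MolecularGraph, RoleMap, derive_role_map, load_structure
from .classify import RegionMap
from .conformers import (
    Ensemble,
    MMFFBackend,
    SearchConfig,
    energy_window,
    mc_search,
    write_sdf,
)
from .geometry import HBondCriteria, TurnFlags, flag_turns
from .nmr import (
    classify_exposure,
    classify_nh_state,
    read_temperature_table,
    read_titration_table,
    temp_coefficient,
    titration_delta,
)
from .stats import EnsembleReport, table1_report

__all__ = ["PipelineError", "RunConfig", "run_pipeline", "analyze_ensemble", "nmr_verdicts"]

logger = logging.getLogger("alphaturn")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    structure: str  # SMILES string or path to an SDF/MOL file
    out_dir: str = "alphaturn_out"
    roles_path: str | None = None  # derive from the scaffold when omitted
    regions_path: str | None = None
    search: SearchConfig = field(default_factory=SearchConfig)
    criteria: HBondCriteria = field(default_factory=HBondCriteria)
    temperature: float = 298.15
    nmr_temperature_table: str | None = None
    nmr_titration_table: str | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("roles_path", "regions_path", "nmr_temperature_table", "nmr_titration_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError("config", f"{name} does not exist: {p}")
        if self.temperature <= 0:
            raise PipelineError("config", "temperature must be positive")

    def to_dict(self) -> dict:
        return {
            "structure": self.structure,
            "out_dir": self.out_dir,
            "roles_path": self.roles_path,
            "regions_path": self.regions_path,
            "search": self.search.to_dict(),
            "criteria": {
                "max_ha_distance": self.criteria.max_ha_distance,
                "min_dha_angle": self.criteria.min_dha_angle,
                "max_heavy_distance": self.criteria.max_heavy_distance,
                "mode": self.criteria.mode,
            },
            "temperature": self.temperature,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_graph(cfg: RunConfig) -> MolecularGraph:
    src = cfg.structure
    if Path(src).exists():
        return load_structure(Path(src).read_text())
    return load_structure(src, fmt="smiles")


def analyze_ensemble(
    ensemble: Ensemble,
    roles: RoleMap,
    criteria: HBondCriteria | None = None,
    temperature: float = 298.15,
    window: float | None = 6.0,
    region_map: RegionMap | None = None,
) -> tuple[Ensemble, list[TurnFlags], EnsembleReport]:
    """Window an ensemble, flag every retained conformer, and summarise."""
    windowed = energy_window(ensemble, window) if window else ensemble
    flags = [
        flag_turns(c, ensemble.graph, criteria, roles) for c in windowed
    ]
    report = table1_report(
        windowed,
        flags,
        temperature=temperature,
        region_map=region_map,
        all_relative_energies=ensemble.relative_energies,
    )
    return windowed, flags, report


def _flags_frame(windowed: Ensemble, flags: list[TurnFlags]) -> pd.DataFrame:
    rows = []
    rel = windowed.relative_energies
    for k, (de, f) in enumerate(zip(rel, flags)):
        row = {
            "conformer": k,
            "rel_energy_kcal": round(float(de), 4),
            "hbond_A": f.has_hbond_a,
            "hbond_B": f.has_hbond_b,
            "dalpha_A": round(f.dalpha, 3),
            "dalpha_lt_7": f.dalpha_probe_pass,
        }
        for res, (phi, psi) in sorted(f.torsions.items()):
            row[f"phi_{res}"] = None if phi is None else round(phi, 2)
            row[f"psi_{res}"] = None if psi is None else round(psi, 2)
        rows.append(row)
    return pd.DataFrame(rows)


def nmr_verdicts(
    temperature_table: str | None, titration_table: str | None
) -> dict:
    """Temperature-coefficient and DMSO-titration verdicts per proton."""
    out: dict[str, dict] = {}
    if temperature_table:
        for s in read_temperature_table(temperature_table):
            coef = temp_coefficient(s)
            out.setdefault(s.label, {})["temp_coefficient_ppb_per_K"] = round(coef, 3)
            out[s.label]["nh_state"] = classify_nh_state(coef)
    if titration_table:
        for t in read_titration_table(titration_table):
            delta = titration_delta(t)
            out.setdefault(t.label, {})["titration_delta_ppm"] = round(delta, 3)
            out[t.label]["exposure"] = classify_exposure(delta)
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns a dict of output paths and the report."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        graph = _load_graph(cfg).with_all_hydrogens()
    except Exception as exc:
        raise PipelineError("structure", str(exc)) from exc

    try:
        roles = (
            RoleMap.from_yaml(cfg.roles_path)
            if cfg.roles_path
            else derive_role_map(graph)
        )
        roles.validate(graph)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("roles", str(exc)) from exc

    region_map = (
        RegionMap.from_yaml(cfg.regions_path) if cfg.regions_path else RegionMap.default()
    )

    try:
        backend = MMFFBackend()
        logger.info(
            "search: %d starts, seed %d, backend %s",
            cfg.search.n_starts,
            cfg.search.seed,
            backend.name,
        )
        ensemble = mc_search(graph, cfg.search, backend)
    except Exception as exc:
        raise PipelineError("search", str(exc)) from exc

    try:
        windowed, flags, report = analyze_ensemble(
            ensemble,
            roles,
            cfg.criteria,
            cfg.temperature,
            cfg.search.energy_window,
            region_map,
        )
    except Exception as exc:
        raise PipelineError("analysis", str(exc)) from exc

    write_sdf(windowed, out / "ensemble.sdf")
    frame = _flags_frame(windowed, flags)
    frame.to_csv(out / "flags.tsv", sep="\t", index=False)
    (out / "report.json").write_text(report.to_json())
    pd.DataFrame([{
        "conf_within_window": report.n_conformers,
        "hbond_A": report.count_hbond_a,
        "hbond_B": report.count_hbond_b,
        "dalpha_probe": report.count_dalpha_probe,
        "global_min_A": report.global_min_hbond_a,
        "global_min_B": report.global_min_hbond_b,
        "designation": report.designation,
        "gamma_type": report.gamma_type,
    }]).to_csv(out / "report.tsv", sep="\t", index=False)
    roles.to_yaml(out / "roles.yaml")

    manifest = {
        "seed": cfg.search.seed,
        "backend": "mmff",
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "n_unique_conformers": len(ensemble),
        "n_within_window": len(windowed),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    result = {
        "out_dir": str(out),
        "report": report,
        "manifest": manifest,
        "ensemble": windowed,
        "flags": flags,
    }

    if cfg.nmr_temperature_table or cfg.nmr_titration_table:
        try:
            verdicts = nmr_verdicts(cfg.nmr_temperature_table, cfg.nmr_titration_table)
        except Exception as exc:
            raise PipelineError("nmr", str(exc)) from exc
        (out / "nmr_verdicts.json").write_text(json.dumps(verdicts, indent=2))
        result["nmr"] = verdicts

    return result
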