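"""Config-driven study orchestration.

``run_study`` chains phantom generation (or volume loading), segmentation,
VOI extraction, morphometry, the micro-FE solve at the applied load levels,
per-VOI strain summaries, and — when an outcome table is supplied — AST
identification, writing CSV/JSON outputs plus a reproducibility manifest.

Because the model is linear, the default is a single FE solve at the first
load level with the remaining levels obtained by exact load-ratio scaling
(``scale_mode``); solving every level independently is available for
verification.  Units: voxels um, geometry mm, loads N, moduli MPa,
strains ue; every CSV column header carries its unit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adaptation import identify_ast, outcomes_from_table
from .microfe import (
    apply_axial_compression,
    assign_materials,
    solve_linear_elasticity,
    voxel_mesh,
)
from .morphometry import cancellous_indices, cortical_indices
from .phantoms import PhantomSpec, make_synthetic_tibia
from .strainstats import scale_summary, strain_field_from_solution, voi_strain_summary
from .volumes import (
    CANCELLOUS_THRESHOLD,
    CORTICAL_THRESHOLD,
    VOISpec,
    bone_length,
    extract_voi,
    read_volume,
    segment,
)

__all__ = ["StudyConfig", "run_study", "protocol_cycles"]

log = logging.getLogger("osteoadapt")

#: In vivo loading protocol: cycles per burst x bursts per session.
DEFAULT_CYCLES_PER_BURST = 4
DEFAULT_BURSTS_PER_SESSION = 54


def protocol_cycles(cycles_per_burst: int, bursts_per_session: int) -> int:
    """Total load events in one session (e.g. 4 cycles x 54 bursts = 216)."""
    if cycles_per_burst <= 0 or bursts_per_session <= 0:
        raise ValueError("protocol counts must be positive integers")
    return int(cycles_per_burst) * int(bursts_per_session)


@dataclass
class StudyConfig:
    """Everything needed to reproduce a study run."""

    phantom: Optional[PhantomSpec] = None
    volume_path: Optional[str] = None
    growth_plate_slice: Optional[int] = None
    cortical_threshold: float = CORTICAL_THRESHOLD  # g HA/cm^3
    cancellous_threshold: float = CANCELLOUS_THRESHOLD  # g HA/cm^3
    midshaft_fraction: float = 0.025
    proximal_fraction: float = 0.10
    material_model: str = "homogeneous"
    e0: float = 17000.0  # MPa
    nu: float = 0.3
    power_a: float = 15000.0
    power_b: float = 2.0
    loads: tuple = (-3.5, -5.2, -7.0)  # N
    scale_mode: bool = True
    rel_tol: float = 1e-6
    max_iter: int = 40000
    percentile: float = 95.0
    bin_width: float = 150.0  # ue
    abs_threshold: float = 1500.0  # ue
    outcomes_csv: Optional[str] = None
    primary_measures: dict = field(
        default_factory=lambda: {"midshaft_cortical": "Ct.Ar", "proximal_cancellous": "BV/TV"}
    )
    seed: int = 0
    out_dir: str = "study_out"

    def __post_init__(self) -> None:
        mags = [abs(l) for l in self.loads]
        if sorted(mags) != mags or len(set(mags)) != len(mags):
            raise ValueError("load levels must be strictly ordered by magnitude")
        if self.phantom is None and self.volume_path is None:
            raise ValueError("config needs either a phantom spec or a volume path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "phantom" in raw and raw["phantom"] is not None:
            raw["phantom"] = PhantomSpec(**raw["phantom"])
        if "loads" in raw:
            raw["loads"] = tuple(raw["loads"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["loads"] = list(self.loads)
        return d


def _config_hash(cfg: StudyConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def run_study(config: StudyConfig) -> dict:
    """Run the full pipeline; returns the report bundle as a dict and writes
    it under ``config.out_dir``.  Any stage failure leaves a FAILED marker
    naming the stage alongside whatever partial outputs were written."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        return _run_study_inner(config, out)
    except Exception as exc:  # noqa: BLE001 - marker file then re-raise
        stage = getattr(exc, "_stage", stage)
        (out / "FAILED").write_text(f"stage: {getattr(exc, '_stage', 'unknown')}\nerror: {exc}\n")
        raise


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage: %s", name)
                return fn(*args, **kwargs)
            except Exception as exc:
                exc._stage = name
                raise

        return wrapped

    return deco


def _run_study_inner(config: StudyConfig, out: Path) -> dict:
    # --- volume ----------------------------------------------------------
    @_stage("volume")
    def get_volume():
        if config.phantom is not None:
            spec = dataclasses.replace(config.phantom, seed=config.seed)
            return make_synthetic_tibia(spec)
        vol = read_volume(config.volume_path)
        if config.growth_plate_slice is None:
            raise ValueError("growth_plate_slice required when loading a volume")
        return vol, int(config.growth_plate_slice)

    vol, gp = get_volume()

    # --- segmentation & VOIs ---------------------------------------------
    @_stage("segmentation")
    def do_segment():
        cort = segment(vol, config.cortical_threshold, compartment="cortical")
        canc = segment(vol, config.cancellous_threshold, compartment="cancellous")
        return cort, canc

    cort_mask, canc_mask = do_segment()
    length_mm = bone_length(cort_mask)

    @_stage("voi_extraction")
    def do_vois():
        mid = extract_voi(cort_mask, VOISpec.midshaft(config.midshaft_fraction))
        canc = extract_voi(
            canc_mask, VOISpec.proximal_cancellous(config.proximal_fraction), gp
        )
        cc = extract_voi(
            canc_mask, VOISpec.proximal_cortico_cancellous(config.proximal_fraction), gp
        )
        return {"midshaft_cortical": mid, "proximal_cancellous": canc,
                "proximal_cortico_cancellous": cc}

    vois = do_vois()

    # --- morphometry ------------------------------------------------------
    @_stage("morphometry")
    def do_morpho():
        ci = cortical_indices(vois["midshaft_cortical"])
        canci = cancellous_indices(vois["proximal_cancellous"])
        rows = [
            {
                "voi": "midshaft_cortical",
                "Ct.Ar_mm2": ci.ct_ar, "Tt.Ar_mm2": ci.tt_ar, "Ma.Ar_mm2": ci.ma_ar,
                "Ct.Th_mm": ci.ct_th, "Imax_mm4": ci.imax, "Imin_mm4": ci.imin,
                "BV/TV_pct": np.nan, "Tb.Th_mm": np.nan, "Tb.Sp_mm": np.nan,
                "threshold_gHAcm3": config.cortical_threshold,
                "voxel_size_um": vol.voxel_size, "bone_length_mm": length_mm,
            },
            {
                "voi": "proximal_cancellous",
                "Ct.Ar_mm2": np.nan, "Tt.Ar_mm2": np.nan, "Ma.Ar_mm2": np.nan,
                "Ct.Th_mm": np.nan, "Imax_mm4": np.nan, "Imin_mm4": np.nan,
                "BV/TV_pct": canci.bv_tv, "Tb.Th_mm": canci.tb_th, "Tb.Sp_mm": canci.tb_sp,
                "threshold_gHAcm3": config.cancellous_threshold,
                "voxel_size_um": vol.voxel_size, "bone_length_mm": length_mm,
            },
        ]
        df = pd.DataFrame(rows)
        df.to_csv(out / "morphometry.csv", index=False)
        return df

    morpho = do_morpho()

    # --- micro-FE ---------------------------------------------------------
    @_stage("microfe")
    def do_fe():
        mesh = voxel_mesh(cort_mask)
        mats = assign_materials(
            vol, mesh, model=config.material_model, e0=config.e0, nu=config.nu,
            a=config.power_a, b=config.power_b,
        )
        solves = {}
        levels = config.loads if not config.scale_mode else config.loads[:1]
        for load in levels:
            lc = apply_axial_compression(mesh, load)
            disp = solve_linear_elasticity(
                mesh, mats, lc, rel_tol=config.rel_tol, max_iter=config.max_iter
            )
            log.info("FE solve at %.2f N: %d iterations, residual %.2e",
                     load, disp.iterations, disp.residual)
            solves[load] = disp
        return mesh, mats, solves

    mesh, mats, solves = do_fe()

    # --- strain summaries -------------------------------------------------
    @_stage("strain_summary")
    def do_summaries():
        summaries = {}
        base_load = config.loads[0]
        fields = {ld: strain_field_from_solution(mesh, d) for ld, d in solves.items()}
        for voi_name in ("midshaft_cortical", "proximal_cancellous",
                         "proximal_cortico_cancellous"):
            voi = vois[voi_name]
            if not voi.values.any():
                continue
            for load in config.loads:
                if load in fields:
                    s = voi_strain_summary(
                        fields[load], voi, mesh, load, name=voi_name,
                        percentile=config.percentile, bin_width=config.bin_width,
                        abs_threshold=config.abs_threshold,
                    )
                else:
                    s = scale_summary(summaries[(voi_name, base_load)], load / base_load)
                summaries[(voi_name, load)] = s
        rows = []
        hrows = []
        for (voi_name, load), s in summaries.items():
            rows.append({
                "voi": voi_name, "load_N": load,
                "peak_tensile_ue": s.peak_tensile, "peak_compressive_ue": s.peak_compressive,
                "mean_tensile_ue": s.mean_tensile, "mean_compressive_ue": s.mean_compressive,
                "fraction_above_%s_ue_pct" % int(s.abs_threshold): s.fraction_above,
                "n_elements": s.n_elements,
            })
            for lo, pct in zip(s.bin_edges, s.histogram):
                hrows.append({"voi": voi_name, "load_N": load,
                              "bin_lower_ue": lo, "percent_volume_pct": pct})
        pd.DataFrame(rows).to_csv(out / "strain_summary.csv", index=False)
        pd.DataFrame(hrows).to_csv(out / "strain_histogram.csv", index=False)
        return summaries

    summaries = do_summaries()

    # --- AST --------------------------------------------------------------
    ast_reports = {}
    if config.outcomes_csv is not None:

        @_stage("ast")
        def do_ast():
            table = pd.read_csv(config.outcomes_csv)
            outcomes = outcomes_from_table(table)
            reports = {}
            for voi_name, measure in config.primary_measures.items():
                per_voi = [s for (vn, _), s in summaries.items() if vn == voi_name]
                if not per_voi:
                    continue
                rep = identify_ast(per_voi, outcomes, voi_name, measure)
                reports[voi_name] = dataclasses.asdict(rep)
            (out / "ast.json").write_text(json.dumps(reports, indent=2, default=float))
            return reports

        ast_reports = do_ast()

    # --- manifest ---------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "package_version": __version__,
        "bone_length_mm": length_mm,
        "growth_plate_slice": gp,
        "n_elements": mesh.n_elements,
        "n_nodes": mesh.n_nodes,
        "protocol_load_events": protocol_cycles(
            DEFAULT_CYCLES_PER_BURST, DEFAULT_BURSTS_PER_SESSION
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))

    return {
        "manifest": manifest,
        "morphometry": morpho,
        "summaries": summaries,
        "ast": ast_reports,
        "mesh": mesh,
        "vois": vois,
    }
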