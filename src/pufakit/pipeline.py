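"""End-to-end reproducible pipeline: phantom -> segmentation -> cohort ->
screening -> randomization -> trajectory simulation -> analysis.

Each stochastic stage derives its RNG stream deterministically from the
single global seed plus the stage name, so stages can be re-run
independently and the whole run is reproducible.  Every artifact written is
recorded in a manifest with its SHA-256 content hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import analysis, power
from .cohort import CohortSpec, TrajectorySpec, generate_cohort, simulate_trajectories
from .phantom import LesionSpec, PhantomSpec, generate_phantom, save_phantom
from .randomization import RandomizationState, assign_cohort
from .screening import apply_eligibility
from .segmentation import SegmentationParams, segment_wmh

logger = logging.getLogger(__name__)

ALL_STAGES = ("phantom", "segment", "cohort", "screen", "randomize", "simulate", "power", "analyze")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (below 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "pufa_run"
    stages: tuple = ALL_STAGES
    phantom: dict = field(default_factory=dict)       # PhantomSpec overrides
    lesions: list = field(default_factory=list)       # LesionSpec dicts
    segmentation: dict = field(default_factory=dict)  # SegmentationParams overrides
    cohort: dict = field(default_factory=lambda: {"n": 20})
    trajectory: dict = field(default_factory=dict)
    randomization: dict = field(default_factory=dict)  # p_best override
    power_scenarios: list = field(default_factory=list)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.stages = tuple(cfg.stages)
        return cfg


def default_power_scenarios() -> list:
    """The trial's design scenarios: primary WMH, sICAM-1, trails B, digit symbol."""
    return [
        {"name": "wmh_primary", "delta": 3.5, "sd1": 5.0, "sd2": 5.0},
        {"name": "sicam", "delta": 50.15, "sd1": 39.12, "sd2": 78.89},
        {"name": "trails_b", "delta": 12.0 - 3.7, "sd1": 13.0, "sd2": 13.0},
        {"name": "digit_symbol", "delta": 2.3 - 0.7, "sd1": 2.0, "sd2": 2.0},
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns (and writes) the manifest."""
    os.makedirs(config.outdir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    def record(stage: str, params: dict, files: dict) -> None:
        manifest["stages"][stage] = {"params": params}
        for name, path in files.items():
            manifest["files"][f"{stage}/{name}"] = {"path": path, "sha256": _sha256(path)}

    flair = tissue = truth = None
    cohort_df = None
    eligible = None
    assigned = None
    visits = None

    if "phantom" in config.stages:
        lesions = tuple(LesionSpec(**d) for d in config.lesions) or (
            LesionSpec(center=(20, 20, 20), semi_axes=(3, 3, 3), z=4.0, intended_class="deep"),
        )
        pspec = PhantomSpec(
            noise_seed=stage_seed(config.seed, "phantom"), lesions=lesions, **config.phantom
        )
        flair, tissue, truth = generate_phantom(pspec)
        pdir = os.path.join(config.outdir, "phantom")
        os.makedirs(pdir, exist_ok=True)
        paths = save_phantom(flair, tissue, truth, pdir)
        record("phantom", {"spec": str(pspec)}, paths)

    if "segment" in config.stages:
        if flair is None:
            raise RuntimeError("segment stage requires the phantom stage")
        params = SegmentationParams(**config.segmentation)
        result = segment_wmh(flair, tissue, params)
        seg_json = os.path.join(config.outdir, "segmentation.json")
        with open(seg_json, "w") as fh:
            json.dump(
                {
                    "total_cm3": round(result.total_cm3, 3),
                    "deep_cm3": round(result.deep_cm3, 3),
                    "periventricular_cm3": round(result.periventricular_cm3, 3),
                    "qc": result.qc,
                    "wm_stats": asdict(result.stats),
                },
                fh,
                indent=2,
            )
        import nibabel as nib

        mask_path = os.path.join(config.outdir, "wmh_mask.nii")
        nib.save(nib.Nifti1Image(result.mask, flair.affine), mask_path)
        record("segment", asdict(params) | {"allowed_labels": sorted(params.allowed_labels)},
               {"volumes": seg_json, "mask": mask_path})

    if "cohort" in config.stages:
        cspec = CohortSpec(seed=stage_seed(config.seed, "cohort"), **config.cohort)
        cohort_df = generate_cohort(cspec)
        cohort_csv = os.path.join(config.outdir, "cohort.csv")
        cohort_df.to_csv(cohort_csv, index=False)
        record("cohort", {"n": cspec.n}, {"cohort": cohort_csv})

    if "screen" in config.stages:
        if cohort_df is None:
            raise RuntimeError("screen stage requires the cohort stage")
        report = apply_eligibility(cohort_df)
        screen_json = os.path.join(config.outdir, "screening.json")
        with open(screen_json, "w") as fh:
            json.dump(
                {
                    "n_assessed": report.n_assessed,
                    "n_invalid": report.n_invalid,
                    "n_eligible": report.n_eligible,
                    "funnel": report.funnel.to_dict(orient="records"),
                },
                fh,
                indent=2,
            )
        eligible = cohort_df[cohort_df["id"].isin(report.eligible_ids)].reset_index(drop=True)
        eligible_csv = os.path.join(config.outdir, "eligible.csv")
        eligible.to_csv(eligible_csv, index=False)
        record("screen", {}, {"report": screen_json, "eligible": eligible_csv})

    if "randomize" in config.stages:
        if eligible is None:
            raise RuntimeError("randomize stage requires the screen stage")
        state = RandomizationState(
            seed=stage_seed(config.seed, "randomize"), **config.randomization
        )
        assigned = assign_cohort(eligible, state)
        assign_csv = os.path.join(config.outdir, "assignments.csv")
        state.log_frame().to_csv(assign_csv, index=False)
        record("randomize", {"p_best": state.p_best}, {"log": assign_csv})

    if "simulate" in config.stages:
        if assigned is None:
            raise RuntimeError("simulate stage requires the randomize stage")
        tspec = TrajectorySpec(seed=stage_seed(config.seed, "simulate"), **config.trajectory)
        visits = simulate_trajectories(assigned, tspec, dict(zip(assigned["id"], assigned["arm"])))
        visits_csv = os.path.join(config.outdir, "visits.csv")
        visits.to_csv(visits_csv, index=False)
        record("simulate", {"treatment_effect_fraction": tspec.treatment_effect_fraction,
                            "three_year_attrition": tspec.three_year_attrition},
               {"visits": visits_csv})

    if "power" in config.stages:
        scenarios = config.power_scenarios or default_power_scenarios()
        rows = []
        for sc in scenarios:
            sc = dict(sc)
            name = sc.pop("name")
            n = power.sample_size_two_arm(method="normal_approx", **sc)
            n_t = power.sample_size_two_arm(method="noncentral_t", **sc)
            rows.append({
                "scenario": name, **sc,
                "n_per_arm_normal": n,
                "n_per_arm_t": n_t,
                "power_at_35": power.power_two_arm(35, 35, **sc),
                "standardized_effect": power.standardized_effect(sc["delta"], sc["sd1"], sc.get("sd2")),
            })
        power_json = os.path.join(config.outdir, "power.json")
        with open(power_json, "w") as fh:
            json.dump(rows, fh, indent=2)
        record("power", {"n_scenarios": len(rows)}, {"scenarios": power_json})

    if "analyze" in config.stages:
        if visits is None:
            raise RuntimeError("analyze stage requires the simulate stage")
        mitt = analysis.mitt_filter(visits)
        fit = analysis.fit_treatment_model(
            visits[visits["id"].isin(mitt)], covariates=assigned, outcome="wmh_total"
        )
        fit_json = os.path.join(config.outdir, "analysis.json")
        with open(fit_json, "w") as fh:
            json.dump(
                {
                    "population": "mitt",
                    "n_mitt": len(mitt),
                    "converged": fit.converged,
                    "coefficients": fit.coefficient_table().to_dict(orient="index"),
                    "treatment_time_estimate": fit.treatment_time_estimate,
                    "treatment_time_p": fit.treatment_time_pvalue,
                },
                fh,
                indent=2,
            )
        record("analyze", {"outcome": "wmh_total"}, {"fit": fit_json})

    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
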