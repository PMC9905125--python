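"""End-to-end orchestration: simulate -> subgroup -> AI -> GLM -> GRF ->
brain-behavior, as one reproducible, manifest-stamped run."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asymmetry import (
    build_symmetric_template,
    compute_ai,
    flip_lr,
    gaussian_smooth,
    make_right_mask,
)
from .behavior import run_brain_behavior
from .cohort import CohortConfig, EffectSpec, SimulatedCohort, simulate_cohort
from .glm import build_design, fit_glm_voxelwise
from .grf import ClusterResult, significant_clusters
from .subgroups import (
    assign_subgroups_table,
    chi_square_2x2,
    match_controls,
    records_from_table,
    two_sample_t,
)
from .volume import save_volume

__all__ = ["RunConfig", "AnalysisResult", "run_full_pipeline"]

log = logging.getLogger("asymvbm")

ANALYSES = ("general", "SI", "VA", "RRB")


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    effects: list[EffectSpec] = field(default_factory=list)
    analyses: tuple[str, ...] = ("general",)
    instrument: str = "adir"
    voxel_p: float = 0.005
    cluster_p: float = 0.05
    fwhm_mm: float = 8.0
    gm_threshold: float = 0.2
    age_tolerance: float = 2.0
    connectivity: int = 18
    behavior_predictors: tuple[str, ...] = ("ADOS_SOCIAL", "age")
    match_td_controls: bool = True
    write_volumes: bool = False

    def __post_init__(self) -> None:
        for p in (self.voxel_p, self.cluster_p):
            if not 0 < p < 1:
                raise ValueError("p thresholds must lie in (0, 1)")
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("cohort", {}) or {}).items()
        })
        effects = [
            EffectSpec(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in e.items()
            })
            for e in raw.pop("effects", []) or []
        ]
        for key in ("analyses", "behavior_predictors"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(cohort=cohort, effects=effects, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {"cohort": asdict(self.cohort), "effects": [asdict(e) for e in self.effects],
             **{k: v for k, v in asdict(self).items() if k not in ("cohort", "effects")}},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class AnalysisResult:
    analysis: str
    case_ids: list[str]
    control_ids: list[str]
    clusters: ClusterResult
    behavior: dict[str, pd.DataFrame] = field(default_factory=dict)


def _case_ids(
    pheno: pd.DataFrame, assignments: pd.DataFrame, analysis: str
) -> list[str]:
    asd = pheno[pheno["DX_GROUP"] == 1]
    if analysis == "general":
        return list(asd["SUB_ID"].astype(str))
    keep = set(assignments.loc[assignments["label"] == analysis, "subject_id"])
    return [s for s in asd["SUB_ID"].astype(str) if s in keep]


def _analysis_groups(
    pheno: pd.DataFrame,
    assignments: pd.DataFrame,
    config: RunConfig,
) -> dict[str, tuple[list[str], list[str]]]:
    """Case and control subject ids per analysis.

    With ``match_td_controls`` each analysis gets an independently matched
    (site/gender/age) TD group, controls reusable across analyses;
    otherwise every TD subject serves as a control everywhere.
    """
    td_ids = list(pheno.loc[pheno["DX_GROUP"] == 2, "SUB_ID"].astype(str))
    cases = {a: _case_ids(pheno, assignments, a) for a in config.analyses}
    if not config.match_td_controls:
        return {a: (cases[a], td_ids) for a in config.analyses}
    records = {r.subject_id: r for r in records_from_table(pheno)}
    pool = [records[s] for s in td_ids]
    matched = match_controls(
        {a: [records[s] for s in ids] for a, ids in cases.items()},
        pool,
        age_tolerance=config.age_tolerance,
        seed=config.cohort.seed,
    )
    out = {}
    for a in config.analyses:
        if matched[a]["unmatched"]:
            log.warning(
                "analysis %s: %d unmatched cases dropped from control matching",
                a, len(matched[a]["unmatched"]),
            )
        out[a] = (cases[a], matched[a]["controls"])
    return out


def compute_ai_maps(
    cohort: SimulatedCohort,
    sub_ids: Sequence[str],
    gm_threshold: float = 0.2,
    fwhm_mm: float = 8.0,
):
    """Template, mask and smoothed AI maps for the given subjects.

    The symmetric template is the voxel-wise mean of every subject's volume
    and its flip; AI is computed on raw segments and smoothed afterwards.
    """
    volumes = {sid: vol for sid, vol in cohort.iter_volumes(sub_ids)}
    template = build_symmetric_template(list(volumes.values()))
    mask = make_right_mask(template, gm_threshold)
    ai_maps = {}
    for sid, vol in volumes.items():
        ai = compute_ai(vol, flip_lr(vol), mask)
        ai_maps[sid] = gaussian_smooth(ai, fwhm_mm)
    return template, mask, ai_maps


def run_full_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute every configured stage and write reports under ``out_dir``.

    Produces phenotype.csv, ground_truth.json, assignments.csv,
    demographics_report.tsv, per-analysis clusters_<name>.tsv and
    brain_behavior_<name>_<predictor>.tsv, and manifest.json. Rerunning
    with the same config reproduces every numeric output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage simulate: n_asd=%d n_td=%d", config.cohort.n_asd, config.cohort.n_td)
    cohort = simulate_cohort(config.cohort, config.effects)
    cohort.phenotypes.to_csv(out / "phenotype.csv", index=False)
    cohort.manifest.to_json(str(out / "ground_truth.json"))

    assignments = assign_subgroups_table(cohort.phenotypes, config.instrument)
    assignments.to_csv(out / "assignments.csv", index=False)
    _write_demographics(cohort.phenotypes, assignments, out)

    sub_ids = list(cohort.phenotypes["SUB_ID"].astype(str))
    template, mask, ai_maps = compute_ai_maps(
        cohort, sub_ids, config.gm_threshold, config.fwhm_mm
    )
    if config.write_volumes:
        vol_dir = out / "ai_maps"
        vol_dir.mkdir(exist_ok=True)
        for sid, ai in ai_maps.items():
            save_volume(
                template.like(ai.data), str(vol_dir / f"{sid}_ai.nii.gz")
            )
    log.info("stage asym: %d AI maps on %d mask voxels", len(ai_maps), mask.n_voxels)

    groups = _analysis_groups(cohort.phenotypes, assignments, config)
    results: dict[str, AnalysisResult] = {}
    for analysis in config.analyses:
        cases, controls = groups[analysis]
        ids = cases + controls
        labels = np.r_[np.ones(len(cases)), np.zeros(len(controls))]
        sub_pheno = (
            cohort.phenotypes.set_index("SUB_ID").loc[ids].reset_index()
        )
        design = build_design(sub_pheno, labels)
        tmap = fit_glm_voxelwise([ai_maps[s] for s in ids], design)
        clusters = significant_clusters(
            tmap,
            voxel_p=config.voxel_p,
            cluster_p=config.cluster_p,
            connectivity=config.connectivity,
        )
        clusters.table.to_csv(out / f"clusters_{analysis}.tsv", sep="\t", index=False)
        log.info(
            "stage glm/grf[%s]: n=%d df=%d clusters=%d",
            analysis, len(ids), tmap.df, len(clusters),
        )
        res = AnalysisResult(analysis, cases, controls, clusters)
        if len(clusters):
            case_pheno = sub_pheno.iloc[: len(cases)]
            case_maps = [ai_maps[s] for s in cases]
            for predictor in config.behavior_predictors:
                try:
                    bb = run_brain_behavior(clusters, case_maps, case_pheno, predictor)
                except (ValueError, KeyError) as exc:
                    log.warning("brain-behavior[%s/%s] skipped: %s",
                                analysis, predictor, exc)
                    continue
                bb.to_csv(
                    out / f"brain_behavior_{analysis}_{predictor}.tsv",
                    sep="\t",
                    index=False,
                )
                res.behavior[predictor] = bb
        results[analysis] = res

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config_hash": config.config_hash(),
        "seed": config.cohort.seed,
        "n_subjects": len(sub_ids),
        "mask_voxels": mask.n_voxels,
        "clusters": {a: len(r.clusters) for a, r in results.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return {"results": results, "manifest": manifest, "cohort": cohort,
            "ai_maps": ai_maps, "mask": mask}


def _write_demographics(
    pheno: pd.DataFrame, assignments: pd.DataFrame, out: Path
) -> None:
    """Gender chi-squared and age t-test per subgroup-vs-TD pair."""
    td = pheno[pheno["DX_GROUP"] == 2]
    rows = []
    groups = {"general": pheno[pheno["DX_GROUP"] == 1]}
    for lbl in ("SI", "VA", "RRB"):
        ids = set(assignments.loc[assignments["label"] == lbl, "subject_id"])
        groups[lbl] = pheno[pheno["SUB_ID"].astype(str).isin(ids)]
    for name, grp in groups.items():
        if len(grp) < 2:
            continue
        table = [
            [int((grp["SEX"] == 1).sum()), int((grp["SEX"] == 2).sum())],
            [int((td["SEX"] == 1).sum()), int((td["SEX"] == 2).sum())],
        ]
        try:
            chi, chi_p = chi_square_2x2(table)
        except ValueError:
            chi, chi_p = np.nan, np.nan
        t, t_p = two_sample_t(grp["AGE_AT_SCAN"], td["AGE_AT_SCAN"])
        rows.append(
            {"comparison": f"{name} vs TD", "gender_chi2": round(chi, 4),
             "gender_p": round(chi_p, 4), "age_t": round(t, 4),
             "age_p": round(t_p, 4)}
        )
    pd.DataFrame(rows).to_csv(out / "demographics_report.tsv", sep="\t", index=False)
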