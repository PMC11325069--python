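"""End-to-end orchestration: cohort -> cleaning -> networks -> communities ->
scaled inclusivity -> distance regression -> FDR, with seeded reproducibility
and per-stage provenance.

Each (template network, condition) pair gets its own distance-regression
model; the FDR family pools the covariate-of-interest p-values across all of
those models.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .community_detect import CommunityPartition, detect_communities
from .distance_stats import (
    DistanceModelResult,
    brain_distance_matrix,
    covariate_distance_matrix,
    fit_distance_regression,
    results_to_table,
)
from .network_build import build_network
from .scaled_inclusivity import SIMap, TemplateSet, group_si_map, subject_si_map, tertile_maps
from .signal_cleaning import CleaningConfig, clean_subject
from .synthetic_cohort import (
    CohortConfig,
    SubjectRecord,
    generate_conditions,
    plant_partition,
    write_cohort,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("netsi")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries stage and subject context."""

    def __init__(self, stage: str, subject_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for subject {subject_id!r}: {cause}")
        self.stage = stage
        self.subject_id = subject_id


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = CohortConfig()
    cleaning: CleaningConfig = CleaningConfig()
    mode: str = "synthetic"
    s_value: float = 2.5
    n_community_runs: int = 100
    #: condition label -> (jitter_intercept, jitter_slope)
    conditions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"rest": (0.35, 1.5), "task": (0.35, 1.5)}
    )
    apply_cleaning: bool = True
    n_permutations: int = 0
    fdr_term: str = "cs"
    seed: int = 0
    real_manifest: Optional[str] = None

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["cohort"]["community_sizes"] = list(d["cohort"]["community_sizes"])
        d["cleaning"]["confound_names"] = list(d["cleaning"]["confound_names"])
        d["conditions"] = {k: list(v) for k, v in d["conditions"].items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if "cohort" in d:
            d["cohort"]["community_sizes"] = tuple(d["cohort"]["community_sizes"])
            d["cohort"] = CohortConfig(**d["cohort"])
        if "cleaning" in d:
            d["cleaning"]["confound_names"] = tuple(d["cleaning"]["confound_names"])
            d["cleaning"] = CleaningConfig(**d["cleaning"])
        if "conditions" in d:
            d["conditions"] = {k: tuple(v) for k, v in d["conditions"].items()}
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    results: list[DistanceModelResult]
    templates: TemplateSet
    si_maps: dict[tuple[str, str], list[SIMap]]      # (condition, template) -> maps
    partitions: dict[str, list[CommunityPartition]]  # condition -> per-subject
    covariates: dict[str, dict[str, list]]           # condition -> columns
    provenance: dict

    def table(self, fdr_term: str = "cs"):
        return results_to_table(self.results, fdr_term=fdr_term)


def _timed(stage: str):
    start = time.perf_counter()

    def done(extra: str = ""):
        log.info("stage %-12s %6.2fs %s", stage, time.perf_counter() - start, extra)

    return done


def load_real_cohort(manifest_path: str | Path) -> tuple[dict[str, list[SubjectRecord]], TemplateSet]:
    """Load a real-mode cohort from a JSON manifest.

    The manifest maps condition labels to per-subject entries holding paths to
    a node x time matrix (TSV, or a NIfTI image + mask pair), a 6-column
    motion TSV, and per-subject covariates (cs, sex).
    """
    from .signal_cleaning import load_nifti_series

    manifest = json.loads(Path(manifest_path).read_text())
    base = Path(manifest_path).parent
    templates = TemplateSet.from_tsv(base / manifest["template"])
    cohorts: dict[str, list[SubjectRecord]] = {}
    for cond, entries in manifest["conditions"].items():
        subjects = []
        for e in entries:
            if "timeseries" in e:
                ts = np.loadtxt(base / e["timeseries"], delimiter="\t", ndmin=2)
            else:
                ts = load_nifti_series(base / e["image"], base / e["mask"])
            motion = np.loadtxt(base / e["motion"], delimiter="\t", ndmin=2)
            subjects.append(SubjectRecord(
                subject_id=e["subject_id"], cs=float(e["cs"]), sex=int(e["sex"]),
                volumes_removed=0, timeseries=ts, motion_params=motion,
            ))
        cohorts[cond] = subjects
    return cohorts, templates


def run_pipeline(
    config: PipelineConfig,
    output_dir: Optional[str | Path] = None,
    write_cohort_files: bool = False,
) -> PipelineResult:
    """Execute the full analysis and optionally serialize every stage."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s %(message)s")
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    done = _timed("cohort")
    if config.mode == "synthetic":
        cohorts = generate_conditions(config.cohort, config.conditions)
        template_partition = plant_partition(config.cohort.community_sizes,
                                             config.cohort.seed)
        templates = TemplateSet.from_partition(template_partition)
    elif config.mode == "real":
        if config.real_manifest is None:
            raise ValueError("real mode requires a manifest path")
        cohorts, templates = load_real_cohort(config.real_manifest)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    n_subjects = len(next(iter(cohorts.values())))
    done(f"{n_subjects} subjects x {len(cohorts)} conditions")

    if out is not None and write_cohort_files:
        for cond, subjects in cohorts.items():
            write_cohort(out / "cohort" / cond, subjects,
                         config.cohort if config.mode == "synthetic" else None)
        templates.to_tsv(out / "template.tsv")

    detect_seeds = np.random.SeedSequence(config.seed).generate_state(
        len(cohorts) * n_subjects
    )

    results: list[DistanceModelResult] = []
    all_maps: dict[tuple[str, str], list[SIMap]] = {}
    all_parts: dict[str, list[CommunityPartition]] = {}
    all_covs: dict[str, dict[str, list]] = {}
    for ci, (cond, subjects) in enumerate(cohorts.items()):
        done = _timed(f"process[{cond}]")
        partitions = []
        vols_removed = []
        for si_idx, subj in enumerate(subjects):
            try:
                if config.apply_cleaning:
                    cleaned = clean_subject(subj.timeseries, subj.motion_params,
                                            config.cohort.tr_seconds, config.cleaning)
                    ts, vols = cleaned.timeseries, cleaned.volumes_removed
                else:
                    ts, vols = subj.timeseries, subj.volumes_removed
                net = build_network(ts, config.s_value)
                part = detect_communities(
                    net, config.n_community_runs,
                    seed=int(detect_seeds[ci * n_subjects + si_idx]),
                )
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                raise StageError(f"process[{cond}]", subj.subject_id, exc) from exc
            partitions.append(part)
            vols_removed.append(vols)
        all_parts[cond] = partitions
        all_covs[cond] = {
            "subject_id": [s.subject_id for s in subjects],
            "cs": [s.cs for s in subjects],
            "sex": [s.sex for s in subjects],
            "volumes_removed": vols_removed,
        }
        done()

        done = _timed(f"si+fit[{cond}]")
        ids = tuple(s.subject_id for s in subjects)
        d_cs = covariate_distance_matrix([s.cs for s in subjects], "abs_numeric", ids)
        d_mot = covariate_distance_matrix(vols_removed, "abs_numeric", ids)
        d_sex = covariate_distance_matrix([s.sex for s in subjects],
                                          "binary_mismatch", ids)
        for ti, tname in enumerate(templates.names):
            t_nodes = templates.nodes_of(tname)
            maps = [
                subject_si_map(part, t_nodes, subject_id=s.subject_id,
                               template_name=tname)
                for part, s in zip(partitions, subjects)
            ]
            all_maps[(cond, tname)] = maps
            d_brain = brain_distance_matrix(maps)
            results.append(fit_distance_regression(
                d_brain, [d_cs, d_mot, d_sex], ["cs", "motion", "sex"],
                network=tname, condition=cond,
                permute_term=config.fdr_term if config.n_permutations else None,
                n_permutations=config.n_permutations,
                seed=int(np.random.SeedSequence((config.seed, ci, ti)).generate_state(1)[0]),
            ))
        done()

    table = results_to_table(results, fdr_term=config.fdr_term)

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": n_subjects,
        "conditions": list(cohorts.keys()),
        "n_models": len(results),
        "fdr_family_size": len(results),
        "n_nodes": templates.n_nodes,
    }
    result = PipelineResult(results, templates, all_maps, all_parts, all_covs,
                            provenance)

    if out is not None:
        table.to_csv(out / "results.tsv", sep="\t", index=False,
                     float_format="%.10g")
        si_dir = out / "si"
        si_dir.mkdir(exist_ok=True)
        for (cond, tname), maps in all_maps.items():
            np.savetxt(si_dir / f"group_{cond}_{tname}.tsv",
                       np.column_stack((np.arange(templates.n_nodes),
                                        group_si_map(maps))),
                       fmt=("%d", "%.10g"), delimiter="\t",
                       header="node\tsi_mean", comments="")
            cs = all_covs[cond]["cs"]
            if len(set(cs)) >= 3 and len(maps) >= 3:
                upper, lower = tertile_maps(maps, cs)
                np.savetxt(si_dir / f"tertiles_{cond}_{tname}.tsv",
                           np.column_stack((np.arange(templates.n_nodes),
                                            upper, lower)),
                           fmt=("%d", "%.10g", "%.10g"), delimiter="\t",
                           header="node\tsi_upper_tertile\tsi_lower_tertile",
                           comments="")
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    return result
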