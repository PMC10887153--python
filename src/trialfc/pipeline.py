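"""End-to-end driver: simulate -> preprocess -> FC maps -> similarity ->
identification -> group commonality, with reproducible file outputs.

`analyze_subject` and `analyze_cohort` are the in-memory entry points used
by the CLI, tests and the acceptance script; `run_pipeline` additionally
writes every table (tab-separated, stamped with a hash of the full
configuration) and the task-mean maps as NIfTI.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import group as group_mod
from . import niio
from .fcmap import critical_r, fc_maps_for_run
from .hrf import TASK_ORDER
from .identify import (IdentificationResult, associate_R_with_CR,
                       chance_rate, run_identification, test_vs_chance)
from .preprocess import Band, BrainMask, preprocess_run
from .similarity import BlockSummary, SCMatrix, pairwise_blocks
from .simulate import SubjectData, SyntheticSpec, make_cohort

__all__ = ["PipelineConfig", "StageError", "SubjectReport", "CohortReport",
           "analyze_subject", "analyze_cohort", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters of one reproducible pipeline run."""

    seed: int = 0
    n_subjects: int = 9
    fwhm: float = 4.0
    band: tuple[float, float] | None = (0.009, 0.08)
    mask_fraction: float = 0.3
    alpha: float = 0.05
    filter_template: bool = False
    task_mean_display_threshold: float = 0.3
    simulate: dict[str, Any] = field(default_factory=dict)
    version: str = "trialfc-0.1.0"

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        if raw.get("band") is not None:
            raw["band"] = tuple(raw["band"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if d["band"] is not None:
            d["band"] = list(d["band"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def synthetic_spec(self) -> SyntheticSpec:
        return SyntheticSpec(seed=self.seed, **self.simulate)


@dataclass
class SubjectReport:
    subject_id: str
    mask: BrainMask
    sc: SCMatrix
    blocks: list[BlockSummary]
    identification: IdentificationResult
    task_means: dict[str, group_mod.TaskMeanMap]


@dataclass
class CohortReport:
    subjects: list[SubjectReport]
    group_blocks: list[BlockSummary]
    group_identification: dict[str, float]
    association_r: float
    association_p: float
    t_vs_chance: dict[str, tuple[float, float]]
    config_hash: str = ""

    def rates_frame(self) -> pd.DataFrame:
        rows = {
            s.subject_id: s.identification.per_category_correct_rate
            for s in self.subjects
        }
        return pd.DataFrame(rows).T[list(TASK_ORDER)]

    def blocks_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for b in s.blocks:
                rows.append({"subject": s.subject_id, "block": b.block_kind,
                             "n_pairs": b.n_pairs, "min": b.min, "max": b.max,
                             "mean": b.mean, "sd": b.sd})
        return pd.DataFrame(rows)

    def mean_block_R(self, kind: str) -> float:
        """Cohort mean of one block's mean R, e.g. ``within:FT``."""
        vals = [b.mean for s in self.subjects for b in s.blocks
                if b.block_kind == kind]
        return float(pd.Series(vals).mean())

    def association_points(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            within = {b.block_kind.split(":")[1]: b.mean for b in s.blocks
                      if b.block_kind.startswith("within:")}
            for t in TASK_ORDER:
                rows.append({
                    "subject": s.subject_id, "task": t,
                    "mean_within_R": within[t],
                    "correct_rate": s.identification.per_category_correct_rate[t],
                })
        return pd.DataFrame(rows)


def analyze_subject(
    subject: SubjectData, config: PipelineConfig
) -> SubjectReport:
    """Preprocess one subject's run and compute maps, similarity, rates."""
    band = Band(*config.band) if config.band is not None else None
    psc, mask = preprocess_run(
        subject.run, fwhm=config.fwhm, band=band,
        mask_fraction=config.mask_fraction,
    )
    maps, common_mask = fc_maps_for_run(
        psc, mask, subject.truth.paradigm, subject_id=subject.subject_id,
        filter_template=band if config.filter_template else None,
    )
    sc, blocks = pairwise_blocks(maps, subject_id=subject.subject_id)
    ident = run_identification(maps, subject_id=subject.subject_id, sc=sc)
    by_task: dict[str, list] = {t: [] for t in TASK_ORDER}
    for m in maps:
        by_task[m.window.task_label].append(m)
    task_means = {t: group_mod.task_mean_map(ms) for t, ms in by_task.items()}
    return SubjectReport(
        subject_id=subject.subject_id, mask=common_mask, sc=sc,
        blocks=blocks, identification=ident, task_means=task_means,
    )


def _finalize(
    subjects: list[SubjectReport],
    group_blocks: list[BlockSummary],
    group_ident: dict[str, float],
    config_hash: str,
) -> CohortReport:
    report = CohortReport(
        subjects=subjects, group_blocks=group_blocks,
        group_identification=group_ident,
        association_r=0.0, association_p=1.0, t_vs_chance={},
        config_hash=config_hash,
    )
    points = report.association_points()
    assoc = associate_R_with_CR(points["mean_within_R"],
                                points["correct_rate"])
    report.association_r = assoc.pearson_r
    report.association_p = assoc.p_value
    chance = chance_rate(len(TASK_ORDER))
    report.t_vs_chance = {
        t: test_vs_chance(report.rates_frame()[t], chance)
        for t in TASK_ORDER
    }
    return report


def analyze_cohort(
    subjects: list[SubjectData], config: PipelineConfig
) -> CohortReport:
    """Per-subject analysis plus group commonality and cohort statistics."""
    reports = [analyze_subject(s, config) for s in subjects]
    task_means = {r.subject_id: r.task_means for r in reports}
    return _finalize(
        reports,
        group_mod.cross_subject_blocks(task_means),
        group_mod.cross_subject_identification(task_means),
        config.config_hash(),
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> CohortReport:
    """Run every stage in order, writing tables and maps under ``out_dir``.

    Any stage failure raises `StageError` naming the stage; preprocessing
    parameter problems (e.g. a passband reaching the Nyquist frequency)
    are validated up front under the ``preprocess`` stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    log: list[str] = [f"config_hash={h}",
                      f"config={json.dumps(config.to_dict(), sort_keys=True)}"]

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - report stage and cause
            raise StageError(name, exc) from exc
        log.append(f"stage={name} seconds={time.perf_counter() - t0:.2f}")
        return result

    subjects = stage("simulate", lambda: make_cohort(
        config.synthetic_spec(), config.n_subjects))

    def check_band():
        if config.band is not None:
            Band(*config.band).validate_for(subjects[0].run.tr)

    stage("preprocess", check_band)
    reports = stage("fcmap+identify", lambda: [
        analyze_subject(s, config) for s in subjects
    ])

    def group_stage():
        task_means = {r.subject_id: r.task_means for r in reports}
        return (group_mod.cross_subject_blocks(task_means),
                group_mod.cross_subject_identification(task_means))

    group_blocks, group_ident = stage("group", group_stage)
    report = stage("statistics", lambda: _finalize(
        reports, group_blocks, group_ident, h))

    def write_stage():
        voxel = subjects[0].run.voxel_size
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        for r in report.subjects:
            niio.write_table(r.sc.to_frame(),
                             out / f"sc_matrix_{r.subject_id}.tsv",
                             config_hash=h)
            for t, tm in r.task_means.items():
                niio.write_map(tm.values,
                               maps_dir / f"{r.subject_id}_{t}_mean.nii",
                               voxel_size=voxel)
        niio.write_table(report.blocks_frame(), out / "similarity_blocks.tsv",
                         config_hash=h, index=False)
        niio.write_table(report.rates_frame(), out / "correct_rates.tsv",
                         config_hash=h)
        niio.write_table(report.association_points(),
                         out / "association_points.tsv",
                         config_hash=h, index=False)
        gb = pd.DataFrame(
            [{"block": b.block_kind, "n_pairs": b.n_pairs, "min": b.min,
              "max": b.max, "mean": b.mean, "sd": b.sd}
             for b in report.group_blocks]
        )
        niio.write_table(gb, out / "group_blocks.tsv", config_hash=h,
                         index=False)
        gi = pd.DataFrame([report.group_identification])[list(TASK_ORDER)]
        niio.write_table(gi, out / "group_identification.tsv",
                         config_hash=h, index=False)
        n_win = subjects[0].truth.paradigm.volumes_per_trial
        stats = pd.DataFrame([{
            "task": t,
            "t_vs_chance": report.t_vs_chance[t][0],
            "p_one_sided": report.t_vs_chance[t][1],
            "association_r": report.association_r,
            "association_p": report.association_p,
            "critical_r_trial": critical_r(n_win, config.alpha),
        } for t in TASK_ORDER])
        niio.write_table(stats, out / "statistics.tsv", config_hash=h,
                         index=False)

    stage("write", write_stage)
    (out / "pipeline_log.txt").write_text("\n".join(log) + "\n")
    return report
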