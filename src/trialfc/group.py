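"""Group commonality: task-mean maps and cross-subject similarity/decoding.

A subject's eight trial FC maps for one task average into a task-mean FC
map, a stable summary of that subject's typical whole-brain response to the
task.  With all subjects' maps on one voxel grid, cross-subject spatial
correlations within and between task categories quantify how much of the
task response is shared across brains, and each subject's three task-mean
maps can serve as markers to decode the task identity of every other
subject's maps.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .fcmap import FCMap
from .hrf import TASK_ORDER
from .preprocess import BrainMask
from .similarity import BlockSummary, summarize_block

__all__ = [
    "TaskMeanMap",
    "task_mean_map",
    "cross_subject_blocks",
    "cross_subject_identification",
]


@dataclass
class TaskMeanMap:
    """Voxelwise mean of one subject's trial FC maps for one task."""

    values: np.ndarray
    task_label: str
    subject_id: str
    mask: BrainMask

    def in_mask(self) -> np.ndarray:
        return self.values[self.mask.inside]


def task_mean_map(
    maps: Sequence[FCMap], require_eight: bool = True
) -> TaskMeanMap:
    """Average trial FC maps of one task category voxel by voxel.

    The full design has exactly 8 trials per category; pass
    ``require_eight=False`` to average other counts.
    """
    if not maps:
        raise ValueError("no maps to average")
    if require_eight and len(maps) != 8:
        raise ValueError(f"expected 8 trial maps, got {len(maps)}")
    labels = {m.window.task_label for m in maps}
    if len(labels) != 1:
        raise ValueError(f"maps span multiple task labels: {sorted(labels)}")
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("maps must share one grid")
    mask = maps[0].mask
    for m in maps[1:]:
        if not np.array_equal(m.mask.inside, mask.inside):
            raise ValueError("maps must share one mask")
    values = np.mean([m.values for m in maps], axis=0)
    return TaskMeanMap(
        values=values,
        task_label=labels.pop(),
        subject_id=maps[0].window.subject_id,
        mask=mask,
    )


def _group_grid(
    task_mean_maps: Mapping[str, Mapping[str, TaskMeanMap]],
) -> tuple[np.ndarray, list[tuple[str, str]], BrainMask]:
    """Stack all subjects' task-mean maps over the group mask.

    Group mask = intersection of every subject's mask, so all spatial
    correlations are computed over identical voxel sets.
    """
    subjects = list(task_mean_maps)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    shapes = set()
    inter = None
    for s in subjects:
        for t in TASK_ORDER:
            if t not in task_mean_maps[s]:
                raise ValueError(f"subject {s} missing task {t}")
            m = task_mean_maps[s][t]
            shapes.add(m.values.shape)
            inter = m.mask.inside if inter is None else inter & m.mask.inside
    if len(shapes) != 1:
        raise ValueError("all maps must share one grid")
    group_mask = BrainMask(inter)
    rows, meta = [], []
    for s in subjects:
        for t in TASK_ORDER:
            rows.append(task_mean_maps[s][t].values[group_mask.inside])
            meta.append((s, t))
    grid = np.stack(rows)
    if not np.isfinite(grid).all():
        raise ValueError("NaN inside the group mask")
    return grid, meta, group_mask


def _group_R(grid: np.ndarray) -> np.ndarray:
    if np.any(grid.std(axis=1) == 0):
        raise ValueError("constant task-mean map: correlation undefined")
    R = np.corrcoef(grid)
    R = (R + R.T) / 2.0
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    return R


def cross_subject_blocks(
    task_mean_maps: Mapping[str, Mapping[str, TaskMeanMap]],
) -> list[BlockSummary]:
    """Within/between-category similarity blocks over the cohort.

    Within-category blocks hold the C(S, 2) subject pairs for one task;
    a between-category block for tasks (A, B) holds every pair of one
    subject's A map with any subject's B map (S x S pairs, the analog of
    the 8 x 8 within-subject between-category block).
    """
    grid, meta, _ = _group_grid(task_mean_maps)
    R = _group_R(grid)
    subj = [s for s, _ in meta]
    task = [t for _, t in meta]
    out: list[BlockSummary] = []
    for t in TASK_ORDER:
        rows = [i for i in range(len(meta)) if task[i] == t]
        vals = [R[i, j] for i, j in itertools.combinations(rows, 2)]
        out.append(summarize_block(vals, f"within:{t}"))
    for ta, tb in itertools.combinations(TASK_ORDER, 2):
        ra = [i for i in range(len(meta)) if task[i] == ta]
        rb = [i for i in range(len(meta)) if task[i] == tb]
        vals = R[np.ix_(ra, rb)].ravel()
        out.append(summarize_block(vals, f"between:{ta}-{tb}"))
    return out


def cross_subject_identification(
    task_mean_maps: Mapping[str, Mapping[str, TaskMeanMap]],
) -> dict[str, float]:
    """Decode every subject's task-mean maps with every other subject's.

    Each subject in turn provides the three marker maps; all remaining
    subjects' task-mean maps (3 per subject, 24 for a 9-subject cohort)
    are classified by argmax spatial R.  Rates are pooled per category
    over all reference subjects, in percent.
    """
    grid, meta, _ = _group_grid(task_mean_maps)
    R = _group_R(grid)
    subjects = list(dict.fromkeys(s for s, _ in meta))
    index = {(s, t): i for i, (s, t) in enumerate(meta)}
    correct = {t: 0 for t in TASK_ORDER}
    total = {t: 0 for t in TASK_ORDER}
    for ref in subjects:
        marker_rows = [index[(ref, t)] for t in TASK_ORDER]
        for s in subjects:
            if s == ref:
                continue
            for true_t in TASK_ORDER:
                row = index[(s, true_t)]
                scores = R[row, marker_rows]
                pred = TASK_ORDER[int(np.argmax(scores))]
                total[true_t] += 1
                correct[true_t] += pred == true_t
    return {t: 100.0 * correct[t] / total[t] for t in TASK_ORDER}
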