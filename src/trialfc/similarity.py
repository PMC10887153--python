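"""Spatial-correlation similarity between trial FC maps.

The similarity of the whole brain's activity on two trials — same task or
not — is the Pearson correlation R of their two FC maps over all brain-mask
voxels.  For a 3 x 8 trial design this yields a 24 x 24 symmetric matrix
with a block structure: three within-category blocks of C(8,2) = 28 pairs
and three between-category blocks of 8 x 8 = 64 pairs, each summarized by
min / max / mean / sd.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fcmap import FCMap
from .hrf import TASK_ORDER
from .preprocess import BrainMask

__all__ = [
    "SCMatrix",
    "BlockSummary",
    "spatial_correlation",
    "sc_matrix",
    "pairwise_blocks",
    "summarize_block",
]


@dataclass
class SCMatrix:
    """All-pairs spatial correlation between one subject's trial FC maps."""

    R: np.ndarray
    trial_meta: list[tuple[str, int]]  # (task_label, trial_index), row order
    subject_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.trial_meta)
        if self.R.shape != (n, n):
            raise ValueError("R must be square and match trial_meta")
        if not np.allclose(self.R, self.R.T):
            raise ValueError("R must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        names = [f"{t}{i:02d}" for t, i in self.trial_meta]
        return pd.DataFrame(self.R, index=names, columns=names)


@dataclass
class BlockSummary:
    """Summary of one within- or between-category block of R values."""

    block_kind: str  # "within:FT" or "between:WR-PV"
    n_pairs: int
    min: float
    max: float
    mean: float
    sd: float
    degenerate: bool = False  # single-pair block: sd reported as 0

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError("need min <= mean <= max")


def _paired_values(a: FCMap, b: FCMap) -> tuple[np.ndarray, np.ndarray]:
    if a.values.shape != b.values.shape:
        raise ValueError("maps must share one grid")
    both = a.mask.inside & b.mask.inside & np.isfinite(a.values) & np.isfinite(b.values)
    if both.sum() < 3:
        raise ValueError("need at least 3 shared in-mask voxels")
    return a.values[both], b.values[both]


def spatial_correlation(a: FCMap, b: FCMap, mask: BrainMask | None = None) -> float:
    """Pearson R between two FC maps over their shared in-mask voxels.

    Voxels are flattened in a fixed C order (last axis fastest) so the
    result is reproducible across runs and serializations.
    """
    va, vb = _paired_values(a, b)
    if mask is not None:
        both = a.mask.inside & b.mask.inside & np.isfinite(a.values) \
            & np.isfinite(b.values) & mask.inside
        if both.sum() < 3:
            raise ValueError("need at least 3 shared in-mask voxels")
        va, vb = a.values[both], b.values[both]
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("constant map: spatial correlation undefined")
    return float(np.corrcoef(va, vb)[0, 1])


def _canonical_order(maps: list[FCMap]) -> list[FCMap]:
    rank = {t: i for i, t in enumerate(TASK_ORDER)}
    return sorted(
        maps,
        key=lambda m: (rank.get(m.window.task_label, len(rank)),
                       m.window.trial_index),
    )


def sc_matrix(maps: list[FCMap], subject_id: str = "") -> SCMatrix:
    """All-pairs spatial correlation, rows in canonical task/trial order."""
    maps = _canonical_order(maps)
    grid = np.stack([m.in_mask() for m in maps])
    if not np.isfinite(grid).all():
        raise ValueError("maps contain NaN inside the mask; use a common mask")
    if np.any(grid.std(axis=1) == 0):
        raise ValueError("constant map: spatial correlation undefined")
    R = np.corrcoef(grid)
    R = (R + R.T) / 2.0
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    meta = [(m.window.task_label, m.window.trial_index) for m in maps]
    return SCMatrix(R=R, trial_meta=meta, subject_id=subject_id)


def summarize_block(values: np.ndarray | list[float],
                    block_kind: str = "") -> BlockSummary:
    """Min / max / mean / sample sd (n-1 denominator) of one block."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty block")
    degenerate = values.size == 1
    sd = 0.0 if degenerate else float(values.std(ddof=1))
    return BlockSummary(
        block_kind=block_kind,
        n_pairs=int(values.size),
        min=float(values.min()),
        max=float(values.max()),
        mean=float(values.mean()),
        sd=sd,
        degenerate=degenerate,
    )


def block_values(sc: SCMatrix) -> dict[str, np.ndarray]:
    """Unique off-diagonal R values of each within/between block."""
    labels = [t for t, _ in sc.trial_meta]
    idx = {t: [i for i, lab in enumerate(labels) if lab == t]
           for t in dict.fromkeys(labels)}
    out: dict[str, np.ndarray] = {}
    for t, rows in idx.items():
        pairs = [sc.R[i, j] for i, j in itertools.combinations(rows, 2)]
        out[f"within:{t}"] = np.asarray(pairs)
    for ta, tb in itertools.combinations(idx, 2):
        block = sc.R[np.ix_(idx[ta], idx[tb])]
        out[f"between:{ta}-{tb}"] = block.ravel()
    return out


def pairwise_blocks(
    maps: list[FCMap], subject_id: str = "", n_per_task: int = 8
) -> tuple[SCMatrix, list[BlockSummary]]:
    """SC matrix plus per-block summaries for one subject's trial maps.

    Requires the full design: ``n_per_task`` maps for each task category
    (28 within-pairs and 64 between-pairs per block for the 3 x 8 design).
    """
    counts: dict[str, int] = {}
    for m in maps:
        counts[m.window.task_label] = counts.get(m.window.task_label, 0) + 1
    expected = {t: n_per_task for t in TASK_ORDER}
    if counts != expected:
        raise ValueError(
            f"need {n_per_task} maps per category {TASK_ORDER}, got {counts}"
        )
    sc = sc_matrix(maps, subject_id=subject_id)
    summaries = [summarize_block(v, kind)
                 for kind, v in block_values(sc).items()]
    return sc, summaries
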