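"""Per-trial whole-brain temporal-correlation (FC) maps.

Each trial of the block design spans a fixed window of volumes (12 for the
6 s task / 24 s rest design at TR 2.5 s).  For each in-mask voxel, the
Pearson correlation r between the voxel's windowed time course and the
trial's segment of the ideal response yields a 3D map of functional
co-activity relative to the task-evoked template.  Eight such maps per task
category quantify how the whole brain's response to the same task varies
from trial to trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import t as _t_dist

from .hrf import (HemodynamicModel, IdealResponse, StimulusParadigm,
                  ideal_response, trial_template)
from .preprocess import Band, BoldRun, BrainMask, bandpass

__all__ = [
    "TrialWindow",
    "FCMap",
    "segment_trials",
    "temporal_correlation_map",
    "fc_maps_for_run",
    "critical_r",
    "threshold_map",
]


@dataclass(frozen=True)
class TrialWindow:
    """One trial's location in the run: which volumes, which task."""

    subject_id: str
    task_label: str
    trial_index: int  # 1-based ordinal within its task category
    start_volume: int
    n_volumes: int

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise ValueError("trial_index is 1-based")
        if self.start_volume < 0 or self.n_volumes < 3:
            raise ValueError("invalid trial window")


@dataclass
class FCMap:
    """One trial's 3D map of temporal Pearson r (NaN outside the mask)."""

    values: np.ndarray
    mask: BrainMask
    window: TrialWindow
    n_samples: int

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.inside.shape:
            raise ValueError("map grid must match mask grid")
        in_mask = self.values[self.mask.inside]
        finite = in_mask[np.isfinite(in_mask)]
        if finite.size and np.abs(finite).max() > 1 + 1e-9:
            raise ValueError("correlation values must lie in [-1, 1]")

    def in_mask(self) -> np.ndarray:
        """In-mask values flattened in fixed C order (x fastest last axis)."""
        return self.values[self.mask.inside]


def segment_trials(
    paradigm: StimulusParadigm, subject_id: str = ""
) -> list[TrialWindow]:
    """One window per trial, starting at the volume nearest each onset."""
    n_win = paradigm.volumes_per_trial
    windows: list[TrialWindow] = []
    counters: dict[str, int] = {}
    prev_end = -1
    for onset, label in zip(paradigm.trial_onsets, paradigm.trial_labels):
        start = int(round(onset / paradigm.tr))
        if start + n_win > paradigm.n_volumes:
            raise ValueError("trial window exceeds the run")
        if start < prev_end:
            raise ValueError("overlapping trial windows")
        prev_end = start + n_win
        counters[label] = counters.get(label, 0) + 1
        windows.append(
            TrialWindow(
                subject_id=subject_id,
                task_label=label,
                trial_index=counters[label],
                start_volume=start,
                n_volumes=n_win,
            )
        )
    return windows


def _window_matrix(run: BoldRun, mask: BrainMask, window: TrialWindow) -> np.ndarray:
    if window.start_volume + window.n_volumes > run.n_volumes:
        raise ValueError("trial window does not fit the run")
    if mask.inside.shape != run.grid_shape:
        raise ValueError("mask grid must match the run grid")
    s = window.start_volume
    return run.data[mask.inside][:, s : s + window.n_volumes]


def temporal_correlation_map(
    run: BoldRun,
    mask: BrainMask,
    window: TrialWindow,
    template: np.ndarray,
) -> FCMap:
    """Pearson r between each in-mask voxel's windowed series and the template.

    Voxels whose windowed series has zero variance get NaN (and should be
    excluded from downstream spatial comparisons; `fc_maps_for_run` handles
    this with a subject-level intersection mask).
    """
    template = np.asarray(template, dtype=np.float64)
    if len(template) != window.n_volumes:
        raise ValueError("template length must equal the window length")
    tc = template - template.mean()
    t_norm = np.sqrt((tc**2).sum())
    if t_norm == 0:
        raise ValueError("template is constant; correlation undefined")
    x = _window_matrix(run, mask, window)
    xc = x - x.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((xc**2).sum(axis=1))
    r = np.full(x.shape[0], np.nan)
    ok = x_norm > 0
    r[ok] = (xc[ok] @ tc) / (x_norm[ok] * t_norm)
    np.clip(r, -1.0, 1.0, out=r)
    values = np.full(mask.inside.shape, np.nan)
    values[mask.inside] = r
    return FCMap(values=values, mask=mask, window=window,
                 n_samples=window.n_volumes)


def fc_maps_for_run(
    psc_run: BoldRun,
    mask: BrainMask,
    paradigm: StimulusParadigm,
    model: HemodynamicModel | None = None,
    subject_id: str = "",
    filter_template: Band | None = None,
) -> tuple[list[FCMap], BrainMask]:
    """All trial FC maps of one run over a common voxel set.

    Voxels with zero windowed variance in *any* trial are removed from the
    subject mask first, so every map (and hence every spatial correlation)
    is computed over an identical voxel set.  ``filter_template`` optionally
    bandpasses the ideal response like the data before correlation
    (off by default).
    """
    ideal = ideal_response(paradigm, model)
    if filter_template is not None:
        filtered = bandpass(ideal.samples, ideal.tr, filter_template)
        ideal = IdealResponse(samples=filtered, tr=ideal.tr,
                              n_volumes=ideal.n_volumes)
    windows = segment_trials(paradigm, subject_id=subject_id)
    ok = np.ones(mask.n_voxels, dtype=bool)
    for w in windows:
        x = _window_matrix(psc_run, mask, w)
        ok &= x.std(axis=1) > 0
    common = np.zeros_like(mask.inside)
    common[mask.inside] = ok
    common_mask = BrainMask(common)
    maps = []
    for w in windows:
        template = trial_template(ideal, w.start_volume * psc_run.tr,
                                  w.n_volumes)
        maps.append(temporal_correlation_map(psc_run, common_mask, w, template))
    return maps, common_mask


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-tailed critical Pearson r for sample size ``n``.

    Inverts the exact t distribution on n-2 degrees of freedom:
    r* = t* / sqrt(t*^2 + n - 2).  For n = 12, alpha = 0.05 this gives
    0.576, the |r| > 0.58 display threshold for 12-volume trial windows.
    Assumes temporally independent samples.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    t_star = _t_dist.ppf(1 - alpha / 2, n - 2)
    return float(t_star / np.sqrt(t_star**2 + n - 2))


def threshold_map(fc: FCMap, r_crit: float) -> FCMap:
    """Display copy with |r| <= r_crit blanked to NaN; input untouched.

    Similarity and identification always use unthresholded maps; this is
    for visualization only.
    """
    if not (0 <= r_crit <= 1):
        raise ValueError("r_crit must be in [0, 1]")
    values = fc.values.copy()
    values[np.abs(values) <= r_crit] = np.nan
    return FCMap(values=values, mask=fc.mask, window=fc.window,
                 n_samples=fc.n_samples)
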