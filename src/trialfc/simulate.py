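"""Synthetic 4D BOLD runs with trial-to-trial and subject-to-subject structure.

The generator emulates a 12-minute block-design session: three task types
presented 8 times each in interleaved order, every trial 6 s of task
followed by 24 s of rest (12 volumes at TR 2.5 s).  Each task has a smooth
spatial activation pattern inside an ellipsoidal "brain"; the pattern
realized on a given trial is a convex mixture of the task's stable core
pattern and a fresh random pattern, weighted by a per-task
``pattern_consistency`` in [0, 1].  This single knob reproduces the central
empirical phenomenon the analysis is built to measure: tasks whose
whole-brain response repeats faithfully (high consistency, the
finger-tapping analog) yield high within-category map similarity and high
identification rates, while low-consistency tasks (the word-reading analog)
do not.  Trials also vary in overall response amplitude; cohorts add an
independent per-subject deviation to each core pattern.  Noise is
voxelwise AR(1) Gaussian plus a slow cosine drift below the analysis
passband; everything rides on a flat baseline so percent signal change is
well defined.

Everything is deterministic given the spec's seed; ground truth sufficient
to rebuild the noiseless signal is returned alongside each run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage, signal as _signal

from .hrf import (HemodynamicModel, StimulusParadigm, TASK_ORDER,
                  default_paradigm, ideal_response)
from .preprocess import BoldRun, BrainMask

__all__ = ["SyntheticSpec", "GroundTruth", "SubjectData",
           "make_subject_run", "make_cohort"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic session.

    Amplitudes are in percent signal change at the trial-response peak;
    ``pattern_consistency`` maps each task label to the fraction of its
    spatial pattern that is stable across trials (scalar = same for all
    tasks).  ``consistency_jitter_sd`` perturbs those values per subject in
    cohort mode, giving the across-subject spread of map reliability that
    drives the similarity-vs-correct-rate association.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 18)
    voxel_size: float = 3.5
    paradigm: StimulusParadigm = field(default_factory=default_paradigm)
    hemodynamics: HemodynamicModel = field(default_factory=HemodynamicModel)
    pattern_consistency: Mapping[str, float] | float = field(
        default_factory=lambda: {"WR": 0.4, "PV": 0.6, "FT": 0.9}
    )
    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.25
    shared_pattern_weight: float = 0.55
    n_coactivity_modes: int = 6
    subject_deviation_sd: float = 0.7
    consistency_jitter_sd: float = 0.08
    noise_sd: float = 1.0
    structured_noise_sd: float = 0.9
    n_noise_modes: int = 8
    ar1_coef: float = 0.3
    drift_amplitude: float = 0.5
    drift_freq: float = 0.005
    baseline: float = 1000.0
    pattern_smooth_sigma: float = 1.5  # voxels
    seed: int = 0

    def __post_init__(self) -> None:
        cons = self.consistency_by_task()
        for t, c in cons.items():
            if not (0 <= c <= 1):
                raise ValueError(f"pattern_consistency[{t}] must be in [0, 1]")
        if min(self.noise_sd, self.amplitude_sd,
               self.structured_noise_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_noise_modes < 1:
            raise ValueError("need at least one noise mode")
        if not (0 <= self.shared_pattern_weight < 1):
            raise ValueError("shared_pattern_weight must be in [0, 1)")
        if self.n_coactivity_modes < 1:
            raise ValueError("need at least one co-activity mode")
        if not (-1 < self.ar1_coef < 1):
            raise ValueError("|ar1_coef| must be < 1")
        if self.baseline <= 0:
            raise ValueError("baseline must be > 0")

    def consistency_by_task(self) -> dict[str, float]:
        tasks = tuple(dict.fromkeys(self.paradigm.trial_labels)) or TASK_ORDER
        if isinstance(self.pattern_consistency, (int, float)):
            return {t: float(self.pattern_consistency) for t in tasks}
        missing = set(tasks) - set(self.pattern_consistency)
        if missing:
            raise ValueError(f"pattern_consistency missing tasks: {missing}")
        return {t: float(self.pattern_consistency[t]) for t in tasks}


@dataclass
class GroundTruth:
    """Everything needed to rebuild the noiseless percent-signal grid."""

    seed_lineage: tuple[int, ...]
    paradigm: StimulusParadigm
    trial_labels: tuple[str, ...]
    trial_onsets: tuple[float, ...]
    amplitudes: np.ndarray  # % signal, one per trial
    consistency: dict[str, float]  # values actually used for this subject
    core_patterns: dict[str, np.ndarray]  # brain-voxel vectors, unit sd
    trial_patterns: np.ndarray  # (n_trials, n_brain_voxels), realized mixes
    brain_mask: BrainMask

    def noiseless_pct(self, response_rows: np.ndarray) -> np.ndarray:
        """Percent-signal grid rebuilt from the stored draws."""
        weighted = self.trial_patterns * self.amplitudes[:, None]
        return weighted.T @ response_rows


@dataclass
class SubjectData:
    subject_id: str
    run: BoldRun
    mask: BrainMask
    truth: GroundTruth


def _ellipsoid_mask(shape: tuple[int, int, int]) -> BrainMask:
    center = [(n - 1) / 2.0 for n in shape]
    semi = [0.85 * (n - 1) / 2.0 for n in shape]
    coords = np.indices(shape).astype(float)
    d2 = sum(((coords[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return BrainMask(d2 <= 1.0)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int, int],
                  sigma: float, inside: np.ndarray) -> np.ndarray:
    """Standardized smooth Gaussian random field over the brain voxels."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma,
                                mode="nearest")
    v = f[inside]
    return (f[inside] - v.mean()) / v.std()


def _ar1_noise(rng: np.random.Generator, n_series: int, n_time: int,
               sd: float, coef: float, burn_in: int = 50) -> np.ndarray:
    """Stationary AR(1) Gaussian noise with marginal sd ``sd``."""
    if sd == 0:
        return np.zeros((n_series, n_time))
    innov_sd = sd * np.sqrt(1.0 - coef**2)
    e = rng.standard_normal((n_series, n_time + burn_in)) * innov_sd
    x = _signal.lfilter([1.0], [1.0, -coef], e, axis=1)
    return x[:, burn_in:]


def _trial_response_rows(spec: SyntheticSpec) -> np.ndarray:
    """(n_trials, n_volumes) matrix of peak-normalized trial responses.

    Row k is the HRF response of trial k alone; onsets on the TR grid make
    every row a shifted copy of the onset-0 single-trial response
    (time invariance of the convolution).
    """
    p = spec.paradigm
    base = ideal_response(
        replace(p, trial_onsets=(0.0,), trial_labels=(p.trial_labels[0],)),
        spec.hemodynamics,
    ).samples
    rows = np.zeros((p.n_trials, p.n_volumes))
    for k, onset in enumerate(p.trial_onsets):
        s = int(round(onset / p.tr))
        rows[k, s:] = base[: p.n_volumes - s]
    return rows


def _make_run(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    core_patterns: dict[str, np.ndarray],
    consistency: dict[str, float],
    seed_lineage: tuple[int, ...],
    subject_id: str = "S01",
) -> SubjectData:
    p = spec.paradigm
    brain = _ellipsoid_mask(spec.grid_shape)
    inside = brain.inside
    n_vox = brain.n_voxels
    n_trials = p.n_trials
    n_time = p.n_volumes

    # draw order is fixed: amplitudes, trial jitters, drift phase, noise,
    # background — so ground truth fully determines the run for one seed
    amplitudes = np.clip(
        rng.normal(spec.amplitude_mean, spec.amplitude_sd, n_trials), 0, None
    )
    # trial-varying activity lives in a low-dimensional space of shared
    # co-activity modes, so any two trials' deviations can correlate
    # appreciably regardless of task — the structured trial-to-trial
    # variation the analysis is designed to measure
    n_modes = spec.n_coactivity_modes
    modes = np.stack([
        _smooth_field(rng, spec.grid_shape, spec.pattern_smooth_sigma, inside)
        for _ in range(n_modes)
    ])
    mode_weights = rng.standard_normal((n_trials, n_modes))
    jitters = (mode_weights @ modes) / np.sqrt(n_modes)
    trial_patterns = np.empty((n_trials, n_vox))
    for k, label in enumerate(p.trial_labels):
        c = consistency[label]
        trial_patterns[k] = c * core_patterns[label] + (1.0 - c) * jitters[k]

    response_rows = _trial_response_rows(spec)
    pct = (trial_patterns * amplitudes[:, None]).T @ response_rows

    t_sec = np.arange(n_time) * p.tr
    phase = rng.uniform(0, 2 * np.pi)
    pct = pct + spec.drift_amplitude * np.cos(
        2 * np.pi * spec.drift_freq * t_sec + phase
    )
    pct = pct + _ar1_noise(rng, n_vox, n_time, spec.noise_sd, spec.ar1_coef)
    if spec.structured_noise_sd > 0:
        # spatially structured noise (physiological fluctuations, residual
        # motion): smooth spatial modes with AR(1) time courses; this is
        # what keeps map-to-map correlations from being arbitrarily precise
        kn = spec.n_noise_modes
        noise_modes = np.stack([
            _smooth_field(rng, spec.grid_shape, spec.pattern_smooth_sigma,
                          inside)
            for _ in range(kn)
        ])
        z = _ar1_noise(rng, kn, n_time, spec.structured_noise_sd,
                       spec.ar1_coef)
        pct = pct + (noise_modes.T @ z) / np.sqrt(kn)

    data = np.zeros((*spec.grid_shape, n_time))
    data[inside] = spec.baseline * (1.0 + pct / 100.0)
    # air background: magnitude-only thermal noise, scaled with noise_sd
    # so the noiseless limit is exactly silent
    background = np.abs(
        rng.standard_normal((int((~inside).sum()), n_time))
    ) * (0.01 * spec.baseline * spec.noise_sd)
    data[~inside] = background

    run = BoldRun(
        data=data,
        voxel_size=(spec.voxel_size,) * 3,
        tr=p.tr,
        provenance=[f"synthetic: seed lineage {seed_lineage}"],
    )
    truth = GroundTruth(
        seed_lineage=seed_lineage,
        paradigm=p,
        trial_labels=p.trial_labels,
        trial_onsets=p.trial_onsets,
        amplitudes=amplitudes,
        consistency=dict(consistency),
        core_patterns=core_patterns,
        trial_patterns=trial_patterns,
        brain_mask=brain,
    )
    return SubjectData(subject_id=subject_id, run=run, mask=brain, truth=truth)


def _mix_shared(spec: SyntheticSpec, shared: np.ndarray,
                task_cores: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Blend a task-nonspecific pattern into every task core.

    Real tasks share activation (visual input, arousal, task-general
    control), so FC maps of *different* tasks correlate positively; weight
    w gives an expected between-task core correlation of w^2 while keeping
    each core at unit sd.
    """
    w = spec.shared_pattern_weight
    return {t: w * shared + np.sqrt(1.0 - w**2) * core
            for t, core in task_cores.items()}


def make_subject_run(spec: SyntheticSpec) -> SubjectData:
    """Generate one subject's 4D run, brain mask and ground truth."""
    rng = np.random.default_rng(spec.seed)
    brain = _ellipsoid_mask(spec.grid_shape)
    tasks = tuple(dict.fromkeys(spec.paradigm.trial_labels))
    shared = _smooth_field(rng, spec.grid_shape, spec.pattern_smooth_sigma,
                           brain.inside)
    cores = {t: _smooth_field(rng, spec.grid_shape,
                              spec.pattern_smooth_sigma, brain.inside)
             for t in tasks}
    return _make_run(spec, rng, _mix_shared(spec, shared, cores),
                     spec.consistency_by_task(), seed_lineage=(spec.seed,))


def make_cohort(spec: SyntheticSpec, n_subjects: int = 9) -> list[SubjectData]:
    """Generate a cohort on one grid with shared task structure.

    All subjects share a common core pattern per task; each subject's own
    core adds an independent smooth deviation field
    (sd = ``subject_deviation_sd``) and is re-standardized to unit sd, so
    the expected cross-subject core correlation is
    1 / (1 + subject_deviation_sd^2).  Per-subject consistency values are
    the spec's per-task values plus Gaussian jitter
    (sd = ``consistency_jitter_sd``), clipped to [0.05, 1].
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(n_subjects + 1)
    rng_common = np.random.default_rng(children[0])
    brain = _ellipsoid_mask(spec.grid_shape)
    tasks = tuple(dict.fromkeys(spec.paradigm.trial_labels))
    common_shared = _smooth_field(rng_common, spec.grid_shape,
                                  spec.pattern_smooth_sigma, brain.inside)
    common = {t: _smooth_field(rng_common, spec.grid_shape,
                               spec.pattern_smooth_sigma, brain.inside)
              for t in tasks}
    base_consistency = spec.consistency_by_task()
    dev = spec.subject_deviation_sd
    norm = np.sqrt(1.0 + dev**2)

    cohort = []
    for s, child in enumerate(children[1:], start=1):
        rng = np.random.default_rng(child)
        shared_s = (common_shared + dev * _smooth_field(
            rng, spec.grid_shape, spec.pattern_smooth_sigma, brain.inside
        )) / norm
        cores = {}
        for t in tasks:
            field_ = _smooth_field(rng, spec.grid_shape,
                                   spec.pattern_smooth_sigma, brain.inside)
            cores[t] = (common[t] + dev * field_) / norm
        cores = _mix_shared(spec, shared_s, cores)
        consistency = {
            t: float(np.clip(
                base_consistency[t]
                + spec.consistency_jitter_sd * rng.standard_normal(),
                0.05, 1.0,
            ))
            for t in tasks
        }
        cohort.append(
            _make_run(spec, rng, cores, consistency,
                      seed_lineage=(spec.seed, s), subject_id=f"S{s:02d}")
        )
    return cohort
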