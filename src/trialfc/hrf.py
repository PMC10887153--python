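"""Hemodynamic response modelling and the task-evoked ideal time signal.

A brief sensory or motor event does not change the BOLD signal instantly:
the vascular response peaks several seconds after neural activity and shows
a small late undershoot.  This module builds a canonical two-gamma
hemodynamic response function (HRF), convolves it with the task on/off
boxcar of a block paradigm, and samples the result at the scanner TR to
produce the *ideal response* — the template time course a task-driven voxel
is expected to follow.  Per-trial segments of this regressor are the
templates against which voxelwise temporal correlation maps are computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "TASK_ORDER",
    "HemodynamicModel",
    "StimulusParadigm",
    "IdealResponse",
    "hrf_kernel",
    "ideal_response",
    "trial_template",
    "default_paradigm",
    "read_paradigm",
    "write_paradigm",
    "export_regressor",
]

#: Canonical ordering of the three task categories: word reading,
#: pattern viewing, visually cued finger tapping.  Used everywhere a
#: deterministic category order (e.g. tie-breaking) is required.
TASK_ORDER: tuple[str, ...] = ("WR", "PV", "FT")


@dataclass(frozen=True)
class HemodynamicModel:
    """Two-gamma HRF shape parameters.

    The kernel is the difference of two gamma densities, each rescaled to
    unit peak: a positive lobe with mode at ``peak_delay`` and a negative
    undershoot with mode at ``undershoot_delay`` weighted by
    ``undershoot_ratio``.  ``undershoot_ratio = 0`` disables the undershoot.

    All times are in seconds.  ``dt`` is the internal fine sampling step
    used for convolution before decimation to the TR grid.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_length: float = 32.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        for name in ("peak_delay", "undershoot_delay", "peak_dispersion",
                     "undershoot_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.kernel_length < self.undershoot_delay:
            raise ValueError("kernel_length must cover the undershoot delay")


@dataclass(frozen=True)
class StimulusParadigm:
    """Timing of an interleaved block design.

    Each trial is ``task_duration`` seconds of stimulation followed by
    ``rest_duration`` seconds of rest; ``trial_onsets`` are task-onset times
    in seconds with one category label per trial.
    """

    trial_onsets: tuple[float, ...]
    trial_labels: tuple[str, ...]
    task_duration: float
    rest_duration: float
    run_length: float
    tr: float

    def __post_init__(self) -> None:
        onsets = np.asarray(self.trial_onsets, dtype=float)
        if len(onsets) != len(self.trial_labels):
            raise ValueError("one label per trial onset required")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.task_duration < 0 or self.rest_duration < 0:
            raise ValueError("durations must be >= 0")
        n_vol = self.run_length / self.tr
        if abs(n_vol - round(n_vol)) > 1e-9:
            raise ValueError("run_length must be an integer number of TRs")
        if len(onsets):
            if np.any(np.diff(onsets) <= 0):
                raise ValueError("trial onsets must be strictly increasing")
            span = self.task_duration + self.rest_duration
            bounds = np.append(onsets[1:], self.run_length)
            if np.any(onsets + span > bounds + 1e-9):
                raise ValueError(
                    "run too short: a trial window extends past the next "
                    "onset or the run end"
                )

    @property
    def n_volumes(self) -> int:
        return int(round(self.run_length / self.tr))

    @property
    def volumes_per_trial(self) -> int:
        """Number of volumes spanned by one trial (task + rest)."""
        n = (self.task_duration + self.rest_duration) / self.tr
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial span is not an integer number of TRs")
        return int(round(n))

    @property
    def n_trials(self) -> int:
        return len(self.trial_onsets)


@dataclass(frozen=True)
class IdealResponse:
    """The HRF-convolved task regressor sampled at the TR grid.

    ``samples`` is peak-normalized (max |value| = 1) whenever the paradigm
    contains any stimulation, and all-zero otherwise.
    """

    samples: np.ndarray
    tr: float
    n_volumes: int

    def __post_init__(self) -> None:
        if len(self.samples) != self.n_volumes:
            raise ValueError("samples length must equal n_volumes")


def hrf_kernel(model: HemodynamicModel) -> np.ndarray:
    """Sample the two-gamma HRF at the model's fine step ``dt``.

    Each gamma density is parameterized so its mode falls exactly at the
    stated delay (shape = 1 + delay/dispersion, scale = dispersion) and is
    rescaled to unit peak before mixing; the final kernel is renormalized
    to peak amplitude 1.
    """
    t = np.arange(0.0, model.kernel_length + model.dt / 2, model.dt)

    def lobe(delay: float, disp: float) -> np.ndarray:
        pdf = _gamma_dist.pdf(t, 1.0 + delay / disp, scale=disp)
        return pdf / pdf.max()

    k = lobe(model.peak_delay, model.peak_dispersion)
    if model.undershoot_ratio > 0:
        k = k - model.undershoot_ratio * lobe(
            model.undershoot_delay, model.undershoot_dispersion
        )
    return k / np.abs(k).max()


def _boxcar(paradigm: StimulusParadigm, dt: float) -> np.ndarray:
    n_fine = int(round(paradigm.run_length / dt))
    box = np.zeros(n_fine)
    for onset in paradigm.trial_onsets:
        i0 = int(round(onset / dt))
        i1 = int(round((onset + paradigm.task_duration) / dt))
        box[i0:i1] = 1.0
    return box


def ideal_response(
    paradigm: StimulusParadigm, model: HemodynamicModel | None = None
) -> IdealResponse:
    """Convolve the task boxcar train with the HRF and sample at the TR.

    The convolution runs on the fine ``dt`` grid to avoid aliasing the 6 s
    task block onto the 2.5 s TR grid, is decimated at volume times k*TR,
    and peak-normalized.  Deterministic for fixed inputs.
    """
    model = model or HemodynamicModel()
    if model.dt > paradigm.tr:
        raise ValueError("model dt must not exceed the TR")
    box = _boxcar(paradigm, model.dt)
    kernel = hrf_kernel(model)
    fine = np.convolve(box, kernel)[: len(box)] * model.dt
    idx = np.round(np.arange(paradigm.n_volumes) * paradigm.tr / model.dt)
    samples = fine[idx.astype(int)]
    peak = np.abs(samples).max()
    if peak > 0:
        samples = samples / peak
    return IdealResponse(samples=samples, tr=paradigm.tr,
                         n_volumes=paradigm.n_volumes)


def trial_template(
    ideal: IdealResponse, trial_onset: float, n_volumes: int
) -> np.ndarray:
    """Extract one trial's segment of the full-run ideal response.

    The segment starts at the volume nearest ``trial_onset`` and spans
    ``n_volumes`` volumes; it must lie entirely inside the run.
    """
    start = int(round(trial_onset / ideal.tr))
    if start < 0 or start + n_volumes > ideal.n_volumes:
        raise ValueError("trial window exceeds the run")
    return ideal.samples[start : start + n_volumes].copy()


def default_paradigm(
    n_per_task: int = 8,
    task_duration: float = 6.0,
    rest_duration: float = 24.0,
    tr: float = 2.5,
    tasks: tuple[str, ...] = TASK_ORDER,
) -> StimulusParadigm:
    """The study design: 3 tasks x 8 trials interleaved, 6 s on / 24 s off.

    With the defaults this is a 12-minute run of 288 volumes at TR 2.5 s,
    12 volumes per trial.
    """
    span = task_duration + rest_duration
    labels = tuple(tasks) * n_per_task
    onsets = tuple(i * span for i in range(len(labels)))
    return StimulusParadigm(
        trial_onsets=onsets,
        trial_labels=labels,
        task_duration=task_duration,
        rest_duration=rest_duration,
        run_length=span * len(labels),
        tr=tr,
    )


def write_paradigm(paradigm: StimulusParadigm, path: str | Path) -> None:
    """Serialize a paradigm to the plain key-value text format."""
    lines = [
        f"tr = {paradigm.tr}",
        f"run_length = {paradigm.run_length}",
        f"task_duration = {paradigm.task_duration}",
        f"rest_duration = {paradigm.rest_duration}",
    ]
    for onset, label in zip(paradigm.trial_onsets, paradigm.trial_labels):
        lines.append(f"trial = {onset} {label}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_paradigm(path: str | Path) -> StimulusParadigm:
    """Parse the plain key-value paradigm file written by `write_paradigm`."""
    scalars: dict[str, float] = {}
    onsets: list[float] = []
    labels: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if key == "trial":
            onset_s, label = value.split()
            onsets.append(float(onset_s))
            labels.append(label)
        elif key in ("tr", "run_length", "task_duration", "rest_duration"):
            scalars[key] = float(value)
        else:
            raise ValueError(f"unknown paradigm key: {key!r}")
    missing = {"tr", "run_length", "task_duration", "rest_duration"} - set(scalars)
    if missing:
        raise ValueError(f"paradigm file missing keys: {sorted(missing)}")
    return StimulusParadigm(
        trial_onsets=tuple(onsets),
        trial_labels=tuple(labels),
        task_duration=scalars["task_duration"],
        rest_duration=scalars["rest_duration"],
        run_length=scalars["run_length"],
        tr=scalars["tr"],
    )


def export_regressor(ideal: IdealResponse, path: str | Path) -> None:
    """Write the regressor as one-column text, one row per volume."""
    np.savetxt(path, ideal.samples, fmt="%.8f")
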