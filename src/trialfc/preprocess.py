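"""Preprocessing of 4D BOLD runs: smoothing, bandpass, percent signal change.

The chain mirrors a conventional task-fMRI pipeline operating on data that
have already been despiked, slice-time corrected and motion corrected:
isotropic Gaussian spatial smoothing (FWHM in mm), a brick-wall Fourier
bandpass of each voxel time course (0.009-0.08 Hz by default), and
conversion to percent signal change relative to the voxel's mean intensity.
A simple intensity-threshold brain mask builder is included for data that
arrive without one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "BoldRun",
    "BrainMask",
    "Band",
    "gaussian_smooth",
    "bandpass",
    "percent_signal_change",
    "make_brain_mask",
    "preprocess_run",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class BoldRun:
    """A 4D voxel time-series grid (x, y, z, volume)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    tr: float
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("BoldRun data must be 4D (x, y, z, volume)")
        if self.n_volumes <= 3:
            raise ValueError("a run needs more than 3 volumes")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")
        if self.tr <= 0:
            raise ValueError("TR must be > 0")
        if not np.isfinite(self.data).all():
            raise ValueError("run contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray, note: str) -> "BoldRun":
        return BoldRun(
            data=data,
            voxel_size=self.voxel_size,
            tr=self.tr,
            provenance=[*self.provenance, note],
        )


@dataclass
class BrainMask:
    """Boolean 3D grid marking in-brain voxels."""

    inside: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.n_voxels == 0:
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.inside.sum())

    def intersect(self, other: "BrainMask") -> "BrainMask":
        return BrainMask(self.inside & other.inside)


@dataclass(frozen=True)
class Band:
    """A passband in Hz; must sit strictly below the Nyquist frequency."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValueError("need 0 <= low < high")

    def validate_for(self, tr: float) -> None:
        nyquist = 1.0 / (2.0 * tr)
        if self.high >= nyquist:
            raise ValueError(
                f"band high {self.high} Hz >= Nyquist {nyquist} Hz at TR {tr}"
            )


def gaussian_smooth(run: BoldRun, fwhm: float) -> BoldRun:
    """Smooth each volume with an isotropic Gaussian of FWHM ``fwhm`` mm.

    The FWHM is converted to a per-axis sigma in voxels via the voxel size;
    boundaries use nearest-edge replication.  ``fwhm = 0`` is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return run.with_data(run.data.copy(), "smooth: fwhm=0 (identity)")
    sigma_vox = tuple(fwhm * _FWHM_TO_SIGMA / v for v in run.voxel_size)
    out = ndimage.gaussian_filter(run.data, sigma=(*sigma_vox, 0.0),
                                  mode="nearest")
    return run.with_data(out, f"smooth: gaussian fwhm={fwhm}mm")


def bandpass(series: np.ndarray, tr: float, band: Band) -> np.ndarray:
    """Brick-wall Fourier bandpass along the last (time) axis.

    Frequency bins with f < low or f > high are zeroed exactly; the 0 Hz
    (mean) component is always removed.  The operation is an orthogonal
    projection, hence linear and exactly idempotent.
    """
    band.validate_for(tr)
    series = np.asarray(series, dtype=np.float64)
    n = series.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= band.low) & (freqs <= band.high) & (freqs > 0)
    spec = np.fft.rfft(series, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def bandpass_run(run: BoldRun, band: Band) -> BoldRun:
    """`bandpass` applied to a whole run."""
    out = bandpass(run.data, run.tr, band)
    return run.with_data(out, f"bandpass: {band.low}-{band.high} Hz")


def percent_signal_change(run: BoldRun, baseline: np.ndarray) -> BoldRun:
    """Express each voxel's series as a percentage of its baseline mean.

    Voxels with non-positive baseline are set to zero; callers that track a
    brain mask should drop those voxels from it (see `preprocess_run`).
    """
    baseline = np.asarray(baseline, dtype=np.float64)
    if baseline.shape != run.grid_shape:
        raise ValueError("baseline grid must match the run grid")
    valid = baseline > 0
    out = np.zeros_like(run.data)
    out[valid] = 100.0 * run.data[valid] / baseline[valid][:, None]
    return run.with_data(out, "psc: 100*x/baseline")


def make_brain_mask(mean_volume: np.ndarray, fraction: float = 0.3) -> BrainMask:
    """Threshold the mean volume at ``fraction`` of its robust maximum.

    The robust maximum is the 98th intensity percentile (guards against
    isolated bright voxels); only the largest 26-connected component is
    retained.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    mean_volume = np.asarray(mean_volume, dtype=np.float64)
    if mean_volume.ndim != 3:
        raise ValueError("mean volume must be 3D")
    robust_max = np.percentile(mean_volume, 98)
    if robust_max <= 0:
        raise ValueError("mask is empty: no positive intensities")
    candidate = mean_volume >= fraction * robust_max
    if not candidate.any():
        raise ValueError("mask is empty at this threshold")
    labels, n_comp = ndimage.label(candidate, structure=np.ones((3, 3, 3)))
    if n_comp > 1:
        sizes = ndimage.sum_labels(candidate, labels, range(1, n_comp + 1))
        candidate = labels == (1 + int(np.argmax(sizes)))
    return BrainMask(candidate)


def preprocess_run(
    run: BoldRun,
    fwhm: float = 4.0,
    band: Band | None = Band(0.009, 0.08),
    mask: BrainMask | None = None,
    mask_fraction: float = 0.3,
) -> tuple[BoldRun, BrainMask]:
    """Full in-scope chain: smooth -> mean/mask -> bandpass -> PSC.

    The PSC baseline is the per-voxel mean of the smoothed (pre-bandpass)
    series, i.e. the mean volume image.  ``band=None`` skips the temporal
    filter (useful for calibration runs with white noise).  Voxels whose
    baseline is non-positive are removed from the returned mask.
    """
    smoothed = gaussian_smooth(run, fwhm)
    baseline = smoothed.data.mean(axis=3)
    if mask is None:
        mask = make_brain_mask(baseline, mask_fraction)
    if band is not None:
        filtered = bandpass_run(smoothed, band)
    else:
        filtered = smoothed.with_data(smoothed.data.copy(), "bandpass: skipped")
    psc = percent_signal_change(filtered, baseline)
    ok = mask.inside & (baseline > 0)
    n_dropped = mask.n_voxels - int(ok.sum())
    if n_dropped:
        psc.provenance.append(f"mask: dropped {n_dropped} non-positive-baseline voxels")
    return psc, BrainMask(ok)
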