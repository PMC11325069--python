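"""Motion-aware cleaning of node time-series.

Implements the numerically defined preprocessing stages: framewise
displacement (FD) and DVARS traces, volume scrubbing at fixed thresholds,
zero-phase band-pass filtering, and confound regression. Stage order follows
scrub -> band-pass -> confound regression, with the scrub *decision* taken on
the raw series; by default the flagged frames are dropped after filtering the
full-length series (flag-controlled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "CleaningConfig",
    "CleanedSeries",
    "framewise_displacement",
    "dvars",
    "scrub_volumes",
    "bandpass",
    "regress_confounds",
    "clean_subject",
    "load_nifti_series",
]


@dataclass(frozen=True)
class CleaningConfig:
    fd_threshold_mm: float = 0.5
    dv_threshold: float = 0.5          # percent-signal-change units
    band_low_hz: float = 0.009
    band_high_hz: float = 0.08
    head_radius_mm: float = 50.0
    confound_names: tuple[str, ...] = ()
    filter_order: int = 4
    scrub_before_filter: bool = False

    def __post_init__(self) -> None:
        if self.fd_threshold_mm <= 0 or self.dv_threshold <= 0:
            raise ValueError("scrub thresholds must be positive")
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low_hz < band_high_hz")

    def validate_band(self, tr_seconds: float) -> None:
        nyquist = 0.5 / tr_seconds
        if self.band_high_hz >= nyquist:
            raise ValueError(
                f"band_high_hz={self.band_high_hz} not below Nyquist {nyquist}"
            )


@dataclass
class CleanedSeries:
    timeseries: np.ndarray          # n_nodes x n_kept
    kept_frame_indices: np.ndarray  # into the original frame axis
    volumes_removed: int

    def __post_init__(self) -> None:
        if self.timeseries.shape[1] != len(self.kept_frame_indices):
            raise ValueError("kept frame index list does not match series length")


def framewise_displacement(motion_params: np.ndarray, head_radius_mm: float = 50.0) -> np.ndarray:
    """FD_t = sum |d translation| + radius * sum |d rotation| (first frame 0).

    ``motion_params`` is T x 6: three translations in mm then three rotations
    in radians; rotations are converted to arc length at ``head_radius_mm``.
    """
    mp = np.asarray(motion_params, dtype=float)
    if mp.ndim != 2 or mp.shape[1] != 6:
        raise ValueError("motion_params must be a T x 6 matrix")
    if mp.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    d = np.abs(np.diff(mp, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate(([0.0], fd))


def dvars(timeseries: np.ndarray) -> np.ndarray:
    """Frame-to-frame RMS signal change in percent of the global mean signal."""
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 2:
        raise ValueError("timeseries must be 2-D with at least 2 frames")
    global_mean = ts.mean()
    if global_mean == 0:
        raise ValueError("global mean signal is zero; DVARS undefined")
    rms = np.sqrt(np.mean(np.diff(ts, axis=1) ** 2, axis=0))
    return np.concatenate(([0.0], 100.0 * rms / abs(global_mean)))


def scrub_volumes(
    timeseries: np.ndarray,
    fd_trace: np.ndarray,
    dv_trace: np.ndarray,
    config: CleaningConfig = CleaningConfig(),
) -> CleanedSeries:
    """Drop frames exceeding the FD or DVARS threshold."""
    ts = np.asarray(timeseries, dtype=float)
    fd = np.asarray(fd_trace, dtype=float)
    dv = np.asarray(dv_trace, dtype=float)
    if not (ts.shape[1] == fd.size == dv.size):
        raise ValueError("FD/DVARS traces do not align with the frame axis")
    bad = (fd > config.fd_threshold_mm) | (dv > config.dv_threshold)
    kept = np.flatnonzero(~bad)
    if kept.size == 0:
        raise ValueError("scrubbing removed every frame")
    return CleanedSeries(ts[:, kept], kept, int(bad.sum()))


def _bandpass_sos(tr_seconds: float, config: CleaningConfig):
    nyquist = 0.5 / tr_seconds
    return signal.butter(
        config.filter_order,
        [config.band_low_hz / nyquist, config.band_high_hz / nyquist],
        btype="bandpass",
        output="sos",
    )


def bandpass(
    timeseries: np.ndarray,
    tr_seconds: float,
    config: CleaningConfig = CleaningConfig(),
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis; removes the mean."""
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim == 1:
        ts = ts[None, :]
    if ts.shape[1] < 30:
        raise ValueError("band-pass requires at least 30 frames")
    config.validate_band(tr_seconds)
    sos = _bandpass_sos(tr_seconds, config)
    demeaned = ts - ts.mean(axis=1, keepdims=True)
    out = signal.sosfiltfilt(sos, demeaned, axis=1)
    return out if timeseries.ndim == 2 else out[0]


def regress_confounds(timeseries: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Per-node least-squares residuals after projecting out confound columns.

    ``confounds`` is T x p and must have full column rank; collinear columns
    are reported by index in the error message.
    """
    ts = np.asarray(timeseries, dtype=float)
    X = np.asarray(confounds, dtype=float)
    if X.ndim != 2 or X.shape[0] != ts.shape[1]:
        raise ValueError("confounds must be T x p aligned with the frame axis")
    if X.shape[1] >= X.shape[0]:
        raise ValueError("more confounds than frames")
    # rank check; pivoted QR diagnoses which columns are collinear
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    if np.any(diag <= tol):
        from scipy.linalg import qr as _sqr

        _, _, piv = _sqr(X, pivoting=True)
        rank = int(np.sum(diag > tol))
        bad = sorted(int(c) for c in piv[rank:])
        raise ValueError(f"rank-deficient confound matrix; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, ts.T, rcond=None)
    return ts - (X @ beta).T


def clean_subject(
    timeseries: np.ndarray,
    motion_params: np.ndarray,
    tr_seconds: float,
    config: CleaningConfig = CleaningConfig(),
    extra_confounds: Optional[np.ndarray] = None,
) -> CleanedSeries:
    """Full cleaning chain for one subject.

    FD/DVARS are computed on the raw series; the series (and all non-constant
    confound columns, to avoid reintroducing filtered-out frequencies) is
    band-pass filtered, confounds are regressed out, and flagged frames are
    dropped. With ``config.scrub_before_filter`` the flagged frames are
    removed before filtering instead.
    """
    ts = np.asarray(timeseries, dtype=float)
    fd = framewise_displacement(motion_params, config.head_radius_mm)
    dv = dvars(ts)
    bad = (fd > config.fd_threshold_mm) | (dv > config.dv_threshold)
    if np.all(bad):
        raise ValueError("scrubbing removed every frame")
    kept = np.flatnonzero(~bad)

    confounds = [np.ones(ts.shape[1]), np.asarray(motion_params, dtype=float)]
    if extra_confounds is not None:
        confounds.append(np.asarray(extra_confounds, dtype=float).reshape(ts.shape[1], -1))
    X = np.column_stack(confounds)

    if config.scrub_before_filter:
        ts, X = ts[:, kept], X[kept]
    filtered = bandpass(ts, tr_seconds, config)
    # constant columns (the intercept) would be zeroed by the filter; keep as-is
    const = X.std(axis=0) == 0
    Xf = X.copy()
    Xf[:, ~const] = bandpass(X[:, ~const].T, tr_seconds, config).T
    residuals = regress_confounds(filtered, Xf)
    if not config.scrub_before_filter:
        residuals = residuals[:, kept]
    return CleanedSeries(residuals, kept, int(bad.sum()))


def load_nifti_series(image_path: str | Path, mask_path: str | Path) -> np.ndarray:
    """Extract a node x time matrix from a 4-D NIfTI image and a 3-D mask.

    Node order is the ascending linear (C-order) voxel index within the mask.
    """
    import nibabel as nib

    img = nib.load(str(image_path))
    mask = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=float)
    m = np.asarray(mask.dataobj) > 0
    if data.ndim != 4:
        raise ValueError("image must be 4-D")
    if m.shape != data.shape[:3]:
        raise ValueError("mask grid does not match image grid")
    flat = data.reshape(-1, data.shape[3])
    return flat[m.reshape(-1)]
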