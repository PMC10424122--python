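"""Functional preprocessing for within-tissue BOLD analysis.

The chain is: discard initial volumes -> joint detrend + nuisance
regression (24 motion parameters, mean CSF signal, one spike regressor per
high-motion frame) -> ideal band-pass filter -> Gaussian smoothing
restricted to a tissue mask.  The linear trend is a column of the nuisance
design rather than a separate pass; the two are algebraically identical and
this avoids an extra copy of the 4-D data.

Head-motion spikes are *regressed*, not deleted: a one-hot column per
flagged frame forces the residual at that frame to zero while leaving the
temporal structure of the remaining frames untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass
class Volume4D:
    """A BOLD series on a fixed voxel grid.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        BOLD intensities.
    affine : ndarray, shape (4, 4)
        Voxel-to-world map (NIfTI convention, mm).
    tr_s : float
        Repetition time in seconds.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 time points")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if not self.tr_s > 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class MotionTrace:
    """Rigid-body motion parameters with framewise displacement.

    ``params`` is a (t, 6) array: three translations in mm followed by
    three rotations in radians.  ``fd`` is the Power-style framewise
    displacement (mm), with ``fd[0] = 0`` by convention.
    """

    params: np.ndarray
    fd_threshold_mm: float = 1.0
    rotation_radius_mm: float = 50.0
    fd: np.ndarray = field(init=False)
    flagged: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion params must have shape (t, 6)")
        self.fd = compute_fd(self.params, self.rotation_radius_mm)
        self.flagged = self.fd > self.fd_threshold_mm

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    def discard_initial(self, n: int) -> "MotionTrace":
        """Motion trace aligned with a volume whose first *n* frames were dropped."""
        return MotionTrace(self.params[n:], self.fd_threshold_mm, self.rotation_radius_mm)


@dataclass
class NuisanceDesign:
    """Design matrix for the joint detrend + nuisance regression.

    Columns (t rows): intercept, linear trend, 6 motion parameters, their
    one-frame-lagged values (zero at the first frame), the 12 squares of
    both sets, the mean CSF signal, and one one-hot indicator per
    motion-flagged frame — 27 + n_flagged columns in total.
    """

    columns: np.ndarray
    names: list[str]
    n_flagged: int

    def __post_init__(self) -> None:
        if self.columns.shape[1] != len(self.names):
            raise ValueError("column/name count mismatch")

    @property
    def n_frames(self) -> int:
        return self.columns.shape[0]


def discard_initial_volumes(vol: Volume4D, n: int) -> Volume4D:
    """Drop the first *n* frames (scanner equilibration)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= vol.n_timepoints:
        raise ValueError(f"cannot discard {n} of {vol.n_timepoints} frames")
    return Volume4D(vol.data[..., n:], vol.affine, vol.tr_s)


def compute_fd(params: np.ndarray, rotation_radius_mm: float = 50.0) -> np.ndarray:
    """Power-style framewise displacement.

    fd[i] = sum of absolute backward differences of the three translations
    (mm) plus ``rotation_radius_mm`` times the absolute differences of the
    three rotations (rad), i.e. rotations converted to arc length on a
    sphere of the given radius.  fd[0] = 0.
    """
    params = np.asarray(params, dtype=np.float64)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion params must have shape (t, 6)")
    if params.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite motion parameters")
    d = np.abs(np.diff(params, axis=0))
    fd = d[:, :3].sum(axis=1) + rotation_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def build_nuisance_design(
    motion: MotionTrace,
    csf_signal: np.ndarray,
    fd_threshold_mm: float = 1.0,
) -> NuisanceDesign:
    """Assemble intercept + trend + 24 motion regressors + CSF + spike columns.

    The 24-parameter motion model is the 6 rigid-body parameters, the same
    6 at the previous frame (zero for the first frame), and the squares of
    all 12.  Frames with FD above ``fd_threshold_mm`` each contribute a
    one-hot spike regressor.
    """
    p = motion.params
    t = p.shape[0]
    csf_signal = np.asarray(csf_signal, dtype=np.float64).ravel()
    if csf_signal.shape[0] != t:
        raise ValueError("CSF signal length does not match motion frames")
    lagged = np.vstack([np.zeros((1, 6)), p[:-1]])
    cols = [np.ones(t), np.linspace(-1.0, 1.0, t)]
    names = ["intercept", "trend"]
    cols += [p[:, j] for j in range(6)]
    names += [f"mot{j}" for j in range(6)]
    cols += [lagged[:, j] for j in range(6)]
    names += [f"mot{j}_lag" for j in range(6)]
    cols += [p[:, j] ** 2 for j in range(6)]
    names += [f"mot{j}_sq" for j in range(6)]
    cols += [lagged[:, j] ** 2 for j in range(6)]
    names += [f"mot{j}_lag_sq" for j in range(6)]
    cols.append(csf_signal)
    names.append("csf")
    flagged = np.flatnonzero(motion.fd > fd_threshold_mm)
    for k in flagged:
        onehot = np.zeros(t)
        onehot[k] = 1.0
        cols.append(onehot)
        names.append(f"spike{k}")
    X = np.column_stack(cols)
    # Rank check ignoring all-zero columns (zero motion is legitimate input).
    nonzero = [i for i in range(X.shape[1]) if np.any(X[:, i] != 0)]
    rank = np.linalg.matrix_rank(X[:, nonzero])
    if rank < len(nonzero):
        logger.warning(
            "nuisance design rank-deficient: rank %d < %d informative columns (%s)",
            rank, len(nonzero), names,
        )
    return NuisanceDesign(X, names, len(flagged))


def regress_nuisance(
    vol: Volume4D, design: NuisanceDesign, mask: np.ndarray | None = None
) -> Volume4D:
    """Voxel-wise OLS residuals against the nuisance design.

    Near-singular designs are handled by the least-squares pseudoinverse
    (``numpy.linalg.lstsq``); residuals are orthogonal to every design
    column by construction, so the one-hot spike columns zero out the
    flagged frames exactly.
    """
    if design.n_frames != vol.n_timepoints:
        raise ValueError("design rows do not match number of frames")
    X = design.columns
    shape = vol.data.shape
    Y = vol.data.reshape(-1, shape[3]).T  # (t, n_vox)
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        resid = np.zeros_like(Y)
        beta, *_ = np.linalg.lstsq(X, Y[:, m], rcond=None)
        resid[:, m] = Y[:, m] - X @ beta
    else:
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
    return Volume4D(resid.T.reshape(shape), vol.affine, vol.tr_s)


def bandpass_filter(vol: Volume4D, low_hz: float = 0.01, high_hz: float = 0.1) -> Volume4D:
    """Ideal (frequency-domain) band-pass: DFT bins with low <= f <= high kept.

    The DC bin is removed whenever ``low_hz > 0``.  An ideal filter is used
    (rather than an IIR design) because the downstream amplitude statistic
    is itself defined on the DFT spectrum; in-band content is preserved
    bit-for-bit up to FFT round-off.
    """
    t = vol.n_timepoints
    nyquist = 1.0 / (2.0 * vol.tr_s)
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz {high_hz} >= Nyquist {nyquist:.4f}")
    freqs = np.fft.rfftfreq(t, d=vol.tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(vol.data, axis=3)
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=t, axis=3)
    return Volume4D(out, vol.affine, vol.tr_s)


def smooth_within_mask(
    data: np.ndarray,
    mask: np.ndarray,
    fwhm_mm: float = 4.0,
    voxel_size_mm: float = 3.0,
) -> np.ndarray:
    """Gaussian smoothing restricted to a tissue mask (no cross-tissue leakage).

    Computed as smooth(data * mask) / smooth(mask) inside the mask, zero
    outside, so values never bleed across the mask boundary and a constant
    field stays constant right up to the edge.  Works on 3-D maps or 4-D
    series (time axis untouched).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if data.shape[:3] != mask.shape:
        raise ValueError("data and mask grids differ")
    if fwhm_mm < voxel_size_mm:
        logger.warning("FWHM %.2f mm below voxel size %.2f mm", fwhm_mm, voxel_size_mm)
    sigma = fwhm_mm * GAUSS_FWHM_TO_SIGMA / voxel_size_mm
    sm_mask = ndimage.gaussian_filter(mask.astype(np.float64), sigma)
    if data.ndim == 3:
        num = ndimage.gaussian_filter(np.where(mask, data, 0.0), sigma)
        out = np.zeros_like(num)
        out[mask] = num[mask] / sm_mask[mask]
        return out
    if data.ndim == 4:
        masked = np.where(mask[..., None], data, 0.0)
        num = ndimage.gaussian_filter(masked, sigma=(sigma, sigma, sigma, 0.0))
        out = np.zeros_like(num)
        out[mask] = num[mask] / sm_mask[mask, None]
        return out
    raise ValueError("data must be 3-D or 4-D")


def preprocess_subject(
    bold: Volume4D,
    motion: MotionTrace,
    tpm_csf: np.ndarray,
    n_discard: int = 5,
    fd_threshold_mm: float = 1.0,
    band_hz: tuple[float, float] = (0.01, 0.1),
    csf_prob_threshold: float = 0.5,
) -> tuple[Volume4D, MotionTrace, NuisanceDesign]:
    """Run discard -> nuisance regression -> band-pass for one subject.

    The mean CSF signal is taken over voxels whose CSF tissue probability
    exceeds ``csf_prob_threshold``.  Smoothing is tissue-specific and is
    applied by the caller per analysis mask.  Returns the filtered volume,
    the trimmed motion trace and the design used.
    """
    vol = discard_initial_volumes(bold, n_discard)
    mot = motion.discard_initial(n_discard) if motion.n_frames == bold.n_timepoints else motion
    if mot.n_frames != vol.n_timepoints:
        raise ValueError("motion frames do not match BOLD frames after discard")
    csf_mask = np.asarray(tpm_csf) > csf_prob_threshold
    if csf_mask.any():
        csf_signal = vol.data[csf_mask].mean(axis=0)
    else:
        logger.warning("no CSF voxels above %.2f; CSF regressor set to zero", csf_prob_threshold)
        csf_signal = np.zeros(vol.n_timepoints)
    design = build_nuisance_design(mot, csf_signal, fd_threshold_mm)
    resid = regress_nuisance(vol, design)
    filtered = bandpass_filter(resid, *band_hz)
    return filtered, mot, design
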