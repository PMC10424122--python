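"""Amplitude of low-frequency fluctuations (ALFF).

ALFF at a voxel is the average square root of the DFT power spectrum over
the frequency bins falling in the low-frequency band (0.01-0.1 Hz by
default).  The one-sided amplitude convention ``2 |X(f)| / t`` is used, so
a unit-amplitude sinusoid at a bin frequency contributes unit amplitude at
that bin; only group contrasts of ALFF matter downstream, so any fixed
scaling would do, but this one makes the statistic directly interpretable
as a signal amplitude.  No taper is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preproc import Volume4D


@dataclass
class ALFFMap:
    """Voxel-wise ALFF on a 3-D grid: amplitudes >= 0 inside the mask, 0 outside."""

    data: np.ndarray
    band_hz: tuple[float, float]
    tr_s: float
    mask: np.ndarray
    standardized: bool = False


def band_bins(n: int, tr_s: float, band_hz: tuple[float, float]) -> np.ndarray:
    """Indices of rfft bins with low <= f <= high (inclusive edges)."""
    low, high = band_hz
    nyquist = 1.0 / (2.0 * tr_s)
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyquist:
        raise ValueError(f"band edge {high} >= Nyquist {nyquist:.4f}")
    freqs = np.fft.rfftfreq(n, d=tr_s)
    idx = np.flatnonzero((freqs >= low) & (freqs <= high))
    if idx.size == 0:
        raise ValueError("no DFT bins inside band; series too short")
    return idx


def compute_alff(
    vol: Volume4D,
    mask: np.ndarray | None = None,
    band_hz: tuple[float, float] = (0.01, 0.1),
) -> ALFFMap:
    """Mean in-band amplitude-spectrum value per voxel.

    For each in-mask voxel the series is Fourier transformed and ALFF is
    the mean over in-band bins of sqrt(power) = 2 |X(f)| / t.  An all-zero
    series yields ALFF 0; NaNs are rejected.
    """
    t = vol.n_timepoints
    if t < 16:
        raise ValueError("need at least 16 time points")
    if mask is None:
        mask = np.ones(vol.shape3d, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape3d:
        raise ValueError("mask grid does not match volume")
    series = vol.data[mask]  # (n_vox, t)
    if not np.all(np.isfinite(series)):
        raise ValueError("non-finite values in BOLD series")
    idx = band_bins(t, vol.tr_s, band_hz)
    amp = 2.0 * np.abs(np.fft.rfft(series, axis=1)[:, idx]) / t
    out = np.zeros(vol.shape3d)
    out[mask] = amp.mean(axis=1)
    return ALFFMap(out, band_hz, vol.tr_s, mask)


def standardize_alff(alff: ALFFMap) -> ALFFMap:
    """Divide by the in-mask mean so the map averages to 1 over the mask.

    Optional (off by default in the pipeline); idempotent.
    """
    m = alff.mask
    mean = alff.data[m].mean()
    if not mean > 0:
        raise ValueError("in-mask mean must be positive to standardize")
    out = np.zeros_like(alff.data)
    out[m] = alff.data[m] / mean
    return ALFFMap(out, alff.band_hz, alff.tr_s, m, standardized=True)
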