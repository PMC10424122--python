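"""Structure-function coupling: the voxel-wise ALFF / tissue-density ratio.

The coupling index divides each voxel's ALFF value by its tissue density
(the VBM-style map, assumed already on the functional grid).  Voxels whose
density falls below a floor are dropped from the coupling mask rather than
producing unbounded ratios; the number of dropped voxels is reported so a
cohort with widespread near-zero density is conspicuous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alff import ALFFMap


@dataclass
class TissueDensityMap:
    """VBM-style 3-D tissue density in [0, 1+eps] (modulated maps may exceed 1)."""

    data: np.ndarray
    tissue: str  # "gm" | "wm"
    smoothing_fwhm_mm: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("tissue density map must be 3-D")
        if self.data.min() < 0:
            raise ValueError("tissue density must be nonnegative")


@dataclass
class CouplingMap:
    """Voxel-wise ALFF/density ratio, defined on ``mask``; 0 elsewhere."""

    data: np.ndarray
    mask: np.ndarray
    denom_floor: float
    n_excluded: int  # in-mask voxels dropped for density below the floor


def coupling_ratio(
    alff: ALFFMap,
    vbm: TissueDensityMap,
    mask: np.ndarray,
    denom_floor: float = 0.1,
    affines: tuple[np.ndarray, np.ndarray] | None = None,
) -> CouplingMap:
    """Divide ALFF by tissue density inside ``mask``.

    Both maps must share the grid (and, if ``affines`` is given, agree in
    affine to 1e-4) — resampling is the caller's responsibility.  Voxels
    with density below ``denom_floor`` are removed from the coupling mask
    and counted in ``n_excluded``.
    """
    mask = np.asarray(mask, dtype=bool)
    if alff.data.shape != vbm.data.shape or alff.data.shape != mask.shape:
        raise ValueError(
            f"grid mismatch: alff {alff.data.shape}, vbm {vbm.data.shape}, "
            f"mask {mask.shape}"
        )
    if affines is not None:
        a, b = affines
        if not np.allclose(a, b, atol=1e-4):
            raise ValueError("affines differ beyond 1e-4; maps are not co-registered")
    valid = mask & (vbm.data >= denom_floor)
    out = np.zeros_like(alff.data)
    out[valid] = alff.data[valid] / vbm.data[valid]
    return CouplingMap(out, valid, denom_floor, int(mask.sum() - valid.sum()))
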