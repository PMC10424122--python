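"""Subject- and group-level tissue mask construction.

Subject masks assign each voxel to the tissue class (GM/WM/CSF) with the
greatest probability; ties are broken by a fixed GM > WM > CSF priority and
voxels where every probability is below a background floor belong to no
tissue.  Group analysis masks then combine an anatomical consensus
threshold (fraction of subjects whose max-probability mask contains the
voxel) with a functional-coverage threshold (fraction of subjects with
usable BOLD signal there), and — for white matter — a subcortical exclusion
mask.  Thresholds are strict inequalities: "more than 60%" means > 0.60.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

DEFAULT_BACKGROUND_FLOOR = 0.05
TISSUE_PRIORITY = ("gm", "wm", "csf")


@dataclass
class GroupMask:
    """Binary group analysis mask with the thresholds that produced it."""

    data: np.ndarray
    tissue: str  # "gm" | "wm"
    anat_threshold: float
    func_threshold: float
    n_subjects: int
    excluded_atlas: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if not self.data.any():
            raise ValueError(f"empty group {self.tissue} mask")
        for thr in (self.anat_threshold, self.func_threshold):
            if not (0 < thr <= 1):
                raise ValueError("thresholds must be in (0, 1]")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def subject_maxprob_masks(
    tpm_gm: np.ndarray,
    tpm_wm: np.ndarray,
    tpm_csf: np.ndarray,
    background_floor: float = DEFAULT_BACKGROUND_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Binarize tissue-probability maps by per-voxel maximum probability.

    Returns (gm_mask, wm_mask).  A voxel joins the tissue with the strictly
    greatest probability; exact ties go to the earlier tissue in the
    GM > WM > CSF priority; voxels with all probabilities below
    ``background_floor`` are background.
    """
    maps = {"gm": np.asarray(tpm_gm), "wm": np.asarray(tpm_wm), "csf": np.asarray(tpm_csf)}
    shapes = {m.shape for m in maps.values()}
    if len(shapes) != 1:
        raise ValueError(f"tissue maps on different grids: {shapes}")
    for name, m in maps.items():
        if m.min() < 0 or m.max() > 1 + 1e-6:
            raise ValueError(f"{name} probabilities outside [0, 1]")
    stack = np.stack([maps[t] for t in TISSUE_PRIORITY])  # priority order
    # argmax returns the first maximum -> ties resolve by priority order.
    winner = np.argmax(stack, axis=0)
    background = stack.max(axis=0) < background_floor
    gm = (winner == 0) & ~background
    wm = (winner == 1) & ~background
    return gm, wm


def functional_coverage(bold_stack: Sequence[np.ndarray]) -> np.ndarray:
    """Per-voxel fraction of subjects with usable functional signal.

    A subject covers a voxel iff the temporal standard deviation of its
    BOLD series there is positive.  Accepts 4-D arrays (x, y, z, t) or
    precomputed boolean coverage maps.
    """
    if len(bold_stack) == 0:
        raise ValueError("empty subject list")
    counts = None
    for arr in bold_stack:
        arr = np.asarray(arr)
        cov = arr if arr.dtype == bool else arr.std(axis=-1) > 0
        if counts is None:
            counts = np.zeros(cov.shape)
        elif counts.shape != cov.shape:
            raise ValueError("subjects on different grids")
        counts += cov
    return counts / len(bold_stack)


def _group_mask(
    subject_masks: Sequence[np.ndarray],
    coverage: np.ndarray,
    tissue: str,
    anat_threshold: float,
    func_threshold: float,
    exclusion_mask: np.ndarray | None,
    excluded_atlas: str | None,
) -> GroupMask:
    if len(subject_masks) < 2:
        raise ValueError("need at least 2 subjects")
    anat_frac = np.mean([np.asarray(m, dtype=bool) for m in subject_masks], axis=0)
    if anat_frac.shape != np.asarray(coverage).shape:
        raise ValueError("coverage grid does not match subject masks")
    data = (anat_frac > anat_threshold) & (np.asarray(coverage) > func_threshold)
    if exclusion_mask is not None:
        data &= ~np.asarray(exclusion_mask, dtype=bool)
    if not data.any():
        raise ValueError(
            f"group {tissue} mask empty: max anat fraction "
            f"{anat_frac.max():.2f} (threshold {anat_threshold}), max coverage "
            f"{np.max(coverage):.2f} (threshold {func_threshold})"
        )
    return GroupMask(data, tissue, anat_threshold, func_threshold,
                     len(subject_masks), excluded_atlas)


def build_group_wm_mask(
    subject_wm_masks: Sequence[np.ndarray],
    coverage: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
    anat_threshold: float = 0.60,
    func_threshold: float = 0.80,
    excluded_atlas: str | None = None,
) -> GroupMask:
    """Group WM mask: anatomical consensus > 60%, coverage > 80%, subcortex removed."""
    return _group_mask(subject_wm_masks, coverage, "wm", anat_threshold,
                       func_threshold, exclusion_mask, excluded_atlas)


def build_group_gm_mask(
    subject_gm_masks: Sequence[np.ndarray],
    coverage: np.ndarray,
    anat_threshold: float = 0.20,
    func_threshold: float = 0.80,
) -> GroupMask:
    """Group GM mask: loose anatomical consensus > 20%, coverage > 80%."""
    return _group_mask(subject_gm_masks, coverage, "gm", anat_threshold,
                       func_threshold, None, None)
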