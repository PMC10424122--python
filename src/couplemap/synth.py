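"""Synthetic cohort generator.

Produces complete three-group (NC / VMCI / MCI) cohorts — band-limited BOLD
series, GM/WM/CSF tissue-probability maps, rigid-body motion traces with
calibrated spikes, and a phenotype table — with the statistical structure
the downstream analysis assumes, so the whole pipeline is testable without
any imaging download.

Anatomy is a concentric "head" on the analysis grid: a CSF core, a WM
band, a GM shell and a subcortical blob (for exclusion-mask testing),
perturbed per subject by a smooth random field.  BOLD at each voxel is a
sum of randomized-phase sinusoids at the DFT bin frequencies inside the
low-frequency band, scaled by a per-tissue amplitude, plus white noise:
with this construction the mean in-band amplitude spectrum of a noiseless
voxel equals its configured amplitude exactly, which pins down the ALFF
scale.  Group effects are injected as regional amplitude shifts (ALFF /
coupling effects) or regional tissue-density reductions (VBM atrophy).
MMSE is drawn from a linear model on the subject's latent regional
coupling (regional amplitude / regional density) with configurable slope
and residual spread, on top of group-specific baselines.

Reproducibility: one seed per cohort; subject k uses the independent
stream ``default_rng([seed, k])`` so any subject can be regenerated in
isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preproc import MotionTrace, Volume4D
from .tissue_masks import subject_maxprob_masks

GROUP_LEVELS = ("NC", "VMCI", "MCI")
CDR_BY_GROUP = {"NC": 0.0, "VMCI": 0.5, "MCI": 1.0}

# Cohort demographics: group means/SDs chosen to mimic an elderly
# memory-clinic sample (ages ~74-76, ~14.5 y education, MMSE declining
# from ~29 to ~22 across NC -> VMCI -> MCI).
AGE_MEAN = {"NC": 74.4, "VMCI": 74.8, "MCI": 75.9}
AGE_SD = 8.0
EDUCATION_MEAN, EDUCATION_SD, EDUCATION_MIN = 14.5, 2.5, 8
MMSE_GROUP_MEANS = {"NC": 28.9, "VMCI": 26.0, "MCI": 22.1}


@dataclass
class EffectRegion:
    """A spherical region carrying a per-group injected effect.

    modality: "alff" and "coupling" add the group delta to the BOLD band
    amplitude inside the region (a coupling effect is an amplitude change
    over unchanged density, so the ratio moves); "vbm" subtracts the group
    delta from the tissue density (atrophy).  ``deltas`` are ordered
    (NC, VMCI, MCI).
    """

    center_vox: tuple[int, int, int]
    radius_vox: float
    modality: str  # "alff" | "vbm" | "coupling"
    deltas: tuple[float, float, float]
    tissue: str = "wm"

    def __post_init__(self) -> None:
        if self.modality not in ("alff", "vbm", "coupling"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.deltas)):
            raise ValueError("effect sizes must be finite")

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        c = np.asarray(self.center_vox, dtype=float)
        if np.any(c < 0) or np.any(c >= np.asarray(grid_shape)):
            raise ValueError(f"effect region center {self.center_vox} outside grid {grid_shape}")
        grids = np.indices(grid_shape, dtype=float)
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        return d2 <= self.radius_vox ** 2

    def delta_for(self, group: str) -> float:
        return float(self.deltas[GROUP_LEVELS.index(group)])


@dataclass
class MMSEModel:
    """Linear link from latent regional coupling to MMSE.

    mmse = group baseline + slope * (coupling - cohort mean coupling)
           + N(0, residual_sd), clipped to [0, 30].
    """

    slope: float = 0.0
    residual_sd: float = 2.0
    group_means: dict = field(default_factory=lambda: dict(MMSE_GROUP_MEANS))


@dataclass
class CohortConfig:
    """Everything needed to generate one synthetic cohort."""

    n_per_group: tuple[int, int, int] = (100, 90, 53)
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 3.0
    tr_s: float = 2.2
    n_timepoints: int = 164
    effect_regions: list[EffectRegion] = field(default_factory=list)
    alff_band_power: dict = field(
        default_factory=lambda: {"gm": 1.0, "wm": 0.6, "csf": 0.3}
    )
    subject_amplitude_sd: float = 0.1  # between-subject amplitude scatter (fraction)
    noise_sd: float = 0.2              # wide-band white noise on each voxel series
    band_hz: tuple[float, float] = (0.01, 0.1)
    motion_spike_rate: float = 0.02
    motion_spike_magnitude_mm: float = 2.0
    motion_jitter_sd_mm: float = 0.01
    tissue_noise_sd: float = 0.05
    mmse_model: MMSEModel = field(default_factory=MMSEModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("need at least 2 subjects per group")
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("degenerate grid: need >= 8 voxels per axis")
        if not self.tr_s > 0:
            raise ValueError("tr_s must be positive")
        if self.n_timepoints < 16:
            raise ValueError("need at least 16 time points")
        nyq = 1.0 / (2.0 * self.tr_s)
        lo, hi = self.band_hz
        if not (0 < lo < hi < nyq):
            raise ValueError(f"band {self.band_hz} outside (0, Nyquist={nyq:.4f})")
        for reg in self.effect_regions:
            reg.mask(self.grid_shape)  # raises if outside grid

    @property
    def n_subjects(self) -> int:
        return sum(self.n_per_group)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -(np.asarray(self.grid_shape) - 1) / 2.0 * self.voxel_size_mm
        return aff

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        d = json.loads(text)
        d["effect_regions"] = [EffectRegion(**{**r, "center_vox": tuple(r["center_vox"]),
                                               "deltas": tuple(r["deltas"])})
                               for r in d["effect_regions"]]
        d["mmse_model"] = MMSEModel(**d["mmse_model"])
        for key in ("n_per_group", "grid_shape", "band_hz"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Subject:
    """One synthetic subject: BOLD, tissue maps, motion and phenotype."""

    subject_id: str
    bold: Volume4D
    tpm_gm: np.ndarray
    tpm_wm: np.ndarray
    tpm_csf: np.ndarray
    motion: MotionTrace
    phenotype_row: dict
    latent: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# Anatomy
# --------------------------------------------------------------------------

def _radial_distance(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Distance from grid center, normalized by the brain radius."""
    center = (np.asarray(grid_shape) - 1) / 2.0
    brain_radius = 0.45 * min(grid_shape)
    grids = np.indices(grid_shape, dtype=float)
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    return r / brain_radius


def subcortical_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """The generator's 'subcortical' blob, usable as an exclusion-mask input."""
    center = (np.asarray(grid_shape) - 1) / 2.0
    brain_radius = 0.45 * min(grid_shape)
    offset = center + np.array([0.30 * brain_radius, 0.0, 0.0])
    grids = np.indices(grid_shape, dtype=float)
    d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, offset)))
    return d <= 0.22 * brain_radius


def _smooth_field(rng: np.random.Generator, shape, sigma_vox: float = 1.5) -> np.ndarray:
    from scipy import ndimage

    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_tissue_maps(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GM/WM/CSF probability maps: concentric ribbons + smooth subject noise.

    Per voxel the three probabilities sum to at most 0.98; outside the
    head all are ~0 so the max-probability rule leaves background
    unassigned.
    """
    d = _radial_distance(config.grid_shape)
    p_csf = np.exp(-((d / 0.30) ** 2))
    p_wm = np.exp(-(((d - 0.55) / 0.22) ** 2))
    p_gm = np.exp(-(((d - 0.85) / 0.14) ** 2))
    outside = d > 1.05
    maps = []
    for base in (p_gm, p_wm, p_csf):
        noisy = base * (1.0 + config.tissue_noise_sd * _smooth_field(rng, config.grid_shape))
        noisy = np.clip(noisy, 0.0, 1.0)
        noisy[outside] = 0.0
        maps.append(noisy)
    total = maps[0] + maps[1] + maps[2]
    scale = np.where(total > 0.98, 0.98 / np.where(total > 0, total, 1.0), 1.0)
    gm, wm, csf = (m * scale for m in maps)
    return gm, wm, csf


# --------------------------------------------------------------------------
# Signals
# --------------------------------------------------------------------------

def _band_bin_freqs(n: int, tr_s: float, band_hz: tuple[float, float]) -> np.ndarray:
    nyq = 1.0 / (2.0 * tr_s)
    lo, hi = band_hz
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band_hz} outside (0, Nyquist={nyq:.4f})")
    freqs = np.fft.rfftfreq(n, d=tr_s)
    return freqs[(freqs >= lo) & (freqs <= hi)]


def generate_bold_timeseries(
    n: int,
    tr_s: float,
    band_amplitude: float,
    band_hz: tuple[float, float] = (0.01, 0.1),
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One band-limited series: randomized-phase sinusoids plus white noise.

    Every DFT bin inside the band carries a sinusoid of amplitude
    ``band_amplitude`` with an independent uniform phase, so the mean
    in-band amplitude spectrum (2|X|/n convention) equals
    ``band_amplitude`` exactly when ``noise_sd`` is 0.
    """
    if n < 16:
        raise ValueError("need n >= 16")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    series = generate_bold_voxels(1, n, tr_s, np.array([band_amplitude]), band_hz, noise_sd, rng)
    return series[0]


def generate_bold_voxels(
    n_voxels: int,
    n: int,
    tr_s: float,
    amplitudes: np.ndarray,
    band_hz: tuple[float, float],
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized band-limited series for many voxels (independent phases)."""
    freqs = _band_bin_freqs(n, tr_s, band_hz)
    t = np.arange(n) * tr_s
    phases = rng.uniform(0, 2 * np.pi, size=(n_voxels, freqs.size))
    # (v, t) = sum_k sin(2 pi f_k t + phi_vk)
    series = np.einsum(
        "vk,kt->vt",
        np.sin(phases)[:, :],
        np.cos(2 * np.pi * freqs[:, None] * t[None, :]),
    ) + np.einsum(
        "vk,kt->vt",
        np.cos(phases),
        np.sin(2 * np.pi * freqs[:, None] * t[None, :]),
    )
    series *= np.asarray(amplitudes, dtype=float)[:, None]
    if noise_sd > 0:
        series += noise_sd * rng.standard_normal((n_voxels, n))
    return series


def generate_motion(
    n_timepoints: int,
    spike_rate: float,
    spike_magnitude_mm: float = 2.0,
    jitter_sd_mm: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> MotionTrace:
    """Rigid-body motion: small random-walk jitter plus calibrated FD spikes.

    Each frame after the first independently receives, with probability
    ``spike_rate``, a persistent translation step of ``spike_magnitude_mm``
    (random axis and sign), producing framewise displacement above 1 mm at
    exactly that frame; baseline jitter keeps FD well below 1 mm.
    """
    if not spike_magnitude_mm > 1:
        raise ValueError("spike magnitude must exceed the 1 mm FD threshold")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    steps = np.zeros((n_timepoints, 6))
    steps[1:, :3] = jitter_sd_mm * rng.standard_normal((n_timepoints - 1, 3))
    steps[1:, 3:] = (jitter_sd_mm / 50.0) * rng.standard_normal((n_timepoints - 1, 3))
    spikes = rng.random(n_timepoints - 1) < spike_rate
    for k in np.flatnonzero(spikes) + 1:
        axis = rng.integers(0, 3)
        steps[k, axis] += spike_magnitude_mm * (1 if rng.random() < 0.5 else -1)
    return MotionTrace(np.cumsum(steps, axis=0))


# --------------------------------------------------------------------------
# Cohort
# --------------------------------------------------------------------------

def _subject_rng(config: CohortConfig, index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, index])


def generate_subject(config: CohortConfig, index: int, group: str) -> Subject:
    """Generate subject ``index`` of the cohort (reproducible in isolation)."""
    rng = _subject_rng(config, index)
    gm, wm, csf = generate_tissue_maps(config, rng)

    # VBM atrophy effects reduce tissue density inside the region.
    for reg in config.effect_regions:
        if reg.modality == "vbm":
            target = {"gm": gm, "wm": wm, "csf": csf}[reg.tissue]
            m = reg.mask(config.grid_shape)
            target[m] = np.clip(target[m] - reg.delta_for(group), 0.0, None)

    gm_mask, wm_mask = subject_maxprob_masks(gm, wm, csf)
    csf_mask = (csf > gm) & (csf > wm) & (csf >= 0.05)

    # Per-voxel band amplitude: tissue baseline x subject factor (+ effects).
    amp = np.zeros(config.grid_shape)
    subject_factor = 1.0 + config.subject_amplitude_sd * rng.standard_normal()
    amp[gm_mask] = config.alff_band_power["gm"]
    amp[wm_mask] = config.alff_band_power["wm"]
    amp[csf_mask] = config.alff_band_power["csf"]
    amp *= max(subject_factor, 0.05)
    for reg in config.effect_regions:
        if reg.modality in ("alff", "coupling"):
            amp[reg.mask(config.grid_shape)] += reg.delta_for(group)
    amp = np.clip(amp, 0.0, None)

    flat_amp = amp.ravel()
    series = generate_bold_voxels(
        flat_amp.size, config.n_timepoints, config.tr_s, flat_amp,
        config.band_hz, config.noise_sd, rng,
    )
    data = series.reshape(*config.grid_shape, config.n_timepoints)

    motion = generate_motion(
        config.n_timepoints, config.motion_spike_rate,
        config.motion_spike_magnitude_mm, config.motion_jitter_sd_mm, rng,
    )
    # Motion spikes leave a global intensity artifact at the flagged frames,
    # which the one-hot spike regressors remove exactly.
    if motion.flagged.any():
        data[..., motion.flagged] += 5.0 * config.noise_sd

    bold = Volume4D(data, config.affine, config.tr_s)

    # Latent regional coupling drives MMSE.
    latent: dict = {"subject_factor": subject_factor}
    coupling_regions = [r for r in config.effect_regions if r.modality in ("alff", "coupling")]
    if coupling_regions:
        reg = coupling_regions[0]
        m = reg.mask(config.grid_shape)
        density = {"gm": gm, "wm": wm, "csf": csf}[reg.tissue]
        denom = max(density[m].mean(), 1e-6)
        latent["regional_amplitude"] = float(amp[m].mean())
        latent["regional_density"] = float(denom)
        latent["regional_coupling"] = float(amp[m].mean() / denom)

    age = rng.normal(AGE_MEAN[group], AGE_SD)
    gender = int(rng.random() < 0.5)
    education = int(np.clip(round(rng.normal(EDUCATION_MEAN, EDUCATION_SD)), EDUCATION_MIN, None))
    phenotype_row = {
        "subject": f"sub-{index:03d}",
        "group": group,
        "age": float(age),
        "gender": gender,
        "education": education,
        "cdr": CDR_BY_GROUP[group],
        "_mmse_noise": float(rng.normal(0.0, 1.0)),  # scaled in generate_cohort
    }
    return Subject(f"sub-{index:03d}", bold, gm, wm, csf, motion, phenotype_row, latent)


def cohort_group_labels(config: CohortConfig) -> list[str]:
    """Group label of each subject index, NC block first, then VMCI, then MCI."""
    labels = []
    for group, n in zip(GROUP_LEVELS, config.n_per_group):
        labels.extend([group] * n)
    return labels


def finalize_phenotype(
    rows: list[dict], couplings: np.ndarray, model: MMSEModel
) -> pd.DataFrame:
    """Assign MMSE from the latent-coupling link and build the phenotype table.

    MMSE is assigned after all subjects exist so the coupling term can be
    centered on the cohort mean.  Mutates the row dicts (adds ``mmse``,
    removes the pre-drawn noise).
    """
    couplings = np.asarray(couplings, dtype=float)
    center = np.nanmean(couplings) if np.any(np.isfinite(couplings)) else 0.0
    for row, c in zip(rows, couplings):
        base = model.group_means[row["group"]]
        link = model.slope * (c - center) if np.isfinite(c) else 0.0
        noise = model.residual_sd * row.pop("_mmse_noise")
        row["mmse"] = float(np.clip(base + link + noise, 0.0, 30.0))
    return pd.DataFrame(
        [dict(r) for r in rows],
        columns=["subject", "group", "age", "gender", "education", "mmse", "cdr"],
    )


def generate_cohort(config: CohortConfig) -> tuple[list[Subject], pd.DataFrame]:
    """Generate the full cohort and its phenotype table."""
    subjects: list[Subject] = []
    index = 0
    for group in cohort_group_labels(config):
        subjects.append(generate_subject(config, index, group))
        index += 1
    couplings = np.array([s.latent.get("regional_coupling", np.nan) for s in subjects])
    phenotype = finalize_phenotype(
        [s.phenotype_row for s in subjects], couplings, config.mmse_model
    )
    return subjects, phenotype


def default_wm_effect_region(
    grid_shape: tuple[int, int, int],
    deltas: tuple[float, float, float],
    modality: str = "coupling",
    radius_vox: float = 3.0,
) -> EffectRegion:
    """A sphere centered in the WM band on the -x side (away from the
    subcortical blob), convenient for injected-effect studies."""
    center = (np.asarray(grid_shape) - 1) / 2.0
    brain_radius = 0.45 * min(grid_shape)
    pos = center - np.array([0.55 * brain_radius, 0.0, 0.0])
    return EffectRegion(tuple(int(round(v)) for v in pos), radius_vox, modality,
                        deltas, tissue="wm")


# --------------------------------------------------------------------------
# On-disk cohort layout
# --------------------------------------------------------------------------

def write_cohort(
    subjects: list[Subject], phenotype: pd.DataFrame, config: CohortConfig, out_dir: str | Path
) -> Path:
    """Write NIfTI volumes, motion TSVs, the phenotype table and the config."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        nib.save(nib.Nifti1Image(s.bold.data.astype(np.float32), s.bold.affine),
                 out / f"{s.subject_id}_bold.nii.gz")
        for tissue, arr in (("gm", s.tpm_gm), ("wm", s.tpm_wm), ("csf", s.tpm_csf)):
            nib.save(nib.Nifti1Image(arr.astype(np.float32), s.bold.affine),
                     out / f"{s.subject_id}_tpm-{tissue}.nii.gz")
        np.savetxt(out / f"{s.subject_id}_motion.tsv", s.motion.params, delimiter="\t")
    phenotype.to_csv(out / "phenotype.tsv", sep="\t", index=False)
    (out / "cohort_config.json").write_text(config.to_json())
    return out


def load_cohort(in_dir: str | Path) -> tuple[list[Subject], pd.DataFrame, CohortConfig]:
    """Read a cohort written by :func:`write_cohort`."""
    import nibabel as nib

    src = Path(in_dir)
    config = CohortConfig.from_json((src / "cohort_config.json").read_text())
    phenotype = pd.read_csv(src / "phenotype.tsv", sep="\t")
    subjects = []
    for _, row in phenotype.iterrows():
        sid = row["subject"]
        img = nib.load(src / f"{sid}_bold.nii.gz")
        bold = Volume4D(np.asarray(img.dataobj, dtype=np.float64), img.affine, config.tr_s)
        tpms = {
            tissue: np.asarray(
                nib.load(src / f"{sid}_tpm-{tissue}.nii.gz").dataobj, dtype=np.float64
            )
            for tissue in ("gm", "wm", "csf")
        }
        motion = MotionTrace(np.loadtxt(src / f"{sid}_motion.tsv", delimiter="\t"))
        subjects.append(Subject(sid, bold, tpms["gm"], tpms["wm"], tpms["csf"],
                                motion, row.to_dict()))
    return subjects, phenotype, config
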