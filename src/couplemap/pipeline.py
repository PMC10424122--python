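"""End-to-end pipeline: cohort -> preprocessing -> masks -> ALFF ->
coupling -> group inference, as one reproducible, seeded run.

Subjects are processed one at a time (BOLD series are dropped as soon as
the subject's statistic maps exist) so cohort size is limited by the map
stack, not the 4-D data.  Every run emits a provenance record — the full
configuration, the seed, and content hashes of all tables and maps — and
two runs with the same configuration hash to the same value.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, synth
from .alff import compute_alff
from .coupling import TissueDensityMap, coupling_ratio
from .preproc import MotionTrace, Volume4D, preprocess_subject, smooth_within_mask
from .tissue_masks import (
    GroupMask,
    build_group_gm_mask,
    build_group_wm_mask,
    functional_coverage,
    subject_maxprob_masks,
)

logger = logging.getLogger(__name__)

PAIR_NAMES = {("NC", "VMCI"): "nc_vs_vmci", ("NC", "MCI"): "nc_vs_mci",
              ("VMCI", "MCI"): "vmci_vs_mci"}


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run (JSON round-trippable)."""

    cohort: synth.CohortConfig = field(default_factory=synth.CohortConfig)
    input_dir: str | None = None       # load a written cohort instead of simulating
    output_dir: str | None = None
    tissues: tuple[str, ...] = ("gm", "wm")
    measures: tuple[str, ...] = ("alff", "coupling")
    n_discard: int = 5
    fd_threshold_mm: float = 1.0
    band_hz: tuple[float, float] = (0.01, 0.1)
    fwhm_mm: float = 4.0
    subject_tissue_threshold: float = 0.5
    wm_anat_threshold: float = 0.60
    gm_anat_threshold: float = 0.20
    func_threshold: float = 0.80
    use_subcortical_exclusion: bool = True
    denom_floor: float = 0.1
    voxel_p: float = 0.001
    cluster_p: float = 0.01
    connectivity: int = 26
    posthoc_method: str = "mannwhitney"
    run_permutation: bool = False
    n_perm: int = 1000
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        cohort = d.pop("cohort")
        cfg = cls(cohort=synth.CohortConfig.from_json(json.dumps(cohort)), **{
            k: tuple(v) if isinstance(v, list) else v for k, v in d.items()
        })
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class AnalysisResult:
    """Inference output for one (tissue, measure) map."""

    tissue: str
    measure: str
    mask: GroupMask
    analysis_mask: np.ndarray
    stat_map: inference.StatMap
    smoothness: inference.SmoothnessEstimate
    clusters: list[inference.ClusterResult]
    posthoc: dict[int, list[inference.PosthocResult]]
    correlations: dict[int, dict[str, inference.CorrelationResult]]
    permutation_clusters: list[inference.ClusterResult] | None = None


@dataclass
class RunReport:
    """Tables, masks and provenance for one pipeline run."""

    cluster_table: pd.DataFrame
    analyses: dict[tuple[str, str], AnalysisResult]
    group_masks: dict[str, GroupMask]
    phenotype: pd.DataFrame
    provenance: dict

    @property
    def report_hash(self) -> str:
        return self.provenance["report_hash"]


def _array_hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _process_subject(
    subject: synth.Subject, config: RunConfig
) -> dict:
    """Preprocess one subject and compute its per-tissue statistic maps."""
    filtered, motion, design = preprocess_subject(
        subject.bold, subject.motion, subject.tpm_csf,
        n_discard=config.n_discard, fd_threshold_mm=config.fd_threshold_mm,
        band_hz=config.band_hz,
    )
    gm_mask, wm_mask = subject_maxprob_masks(subject.tpm_gm, subject.tpm_wm, subject.tpm_csf)
    voxel_mm = float(np.mean(filtered.voxel_size_mm))
    out: dict = {
        "maxprob": {"gm": gm_mask, "wm": wm_mask},
        "coverage": filtered.data.std(axis=-1) > 0,
        "n_flagged": int(motion.flagged.sum()),
        "mean_fd": float(motion.fd.mean()),
        "maps": {},
    }
    tpms = {"gm": subject.tpm_gm, "wm": subject.tpm_wm}
    for tissue in config.tissues:
        smooth_mask = tpms[tissue] > config.subject_tissue_threshold
        if not smooth_mask.any():
            raise ValueError(f"subject {subject.subject_id}: empty {tissue} smoothing mask")
        smoothed = smooth_within_mask(filtered.data, smooth_mask, config.fwhm_mm, voxel_mm)
        vol = Volume4D(smoothed, filtered.affine, filtered.tr_s)
        alff = compute_alff(vol, smooth_mask, config.band_hz)
        out["maps"][("alff", tissue)] = alff
        if "coupling" in config.measures:
            density = TissueDensityMap(tpms[tissue], tissue)
            cpl = coupling_ratio(alff, density, smooth_mask, config.denom_floor)
            out["maps"][("coupling", tissue)] = cpl
    return out


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the whole analysis and return the cluster table and report.

    Deterministic given the configuration (which includes the seed).  If
    ``output_dir`` is set, tables, masks, statistic maps and the
    provenance JSON are written there; a stage marker lets a re-run with
    the same cohort configuration reuse the written cohort.
    """
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # ---- cohort ----------------------------------------------------------
    if config.input_dir:
        subjects, phenotype, cohort_cfg = synth.load_cohort(config.input_dir)
        subject_iter = iter(subjects)
        labels = list(phenotype["group"])
        n_subjects = len(labels)

        def next_subject(i: int, g: str) -> synth.Subject:
            return next(subject_iter)
    else:
        cohort_cfg = config.cohort
        labels = synth.cohort_group_labels(cohort_cfg)
        n_subjects = len(labels)
        phenotype = None

        def next_subject(i: int, g: str) -> synth.Subject:
            return synth.generate_subject(cohort_cfg, i, g)

    # ---- per-subject preprocessing and maps (streaming) ------------------
    per_subject: list[dict] = []
    rows: list[dict] = []
    couplings: list[float] = []
    for i, g in enumerate(labels):
        s = next_subject(i, g)
        per_subject.append(_process_subject(s, config))
        rows.append(dict(s.phenotype_row))
        couplings.append(s.latent.get("regional_coupling", np.nan))
        logger.debug("processed %s (%s)", s.subject_id, g)
        del s
    if phenotype is None:
        phenotype = synth.finalize_phenotype(rows, np.asarray(couplings), cohort_cfg.mmse_model)

    # ---- group masks -----------------------------------------------------
    coverage = functional_coverage([p["coverage"] for p in per_subject])
    exclusion = (synth.subcortical_mask(cohort_cfg.grid_shape)
                 if config.use_subcortical_exclusion else None)
    group_masks: dict[str, GroupMask] = {}
    if "gm" in config.tissues:
        group_masks["gm"] = build_group_gm_mask(
            [p["maxprob"]["gm"] for p in per_subject], coverage,
            config.gm_anat_threshold, config.func_threshold)
    if "wm" in config.tissues:
        group_masks["wm"] = build_group_wm_mask(
            [p["maxprob"]["wm"] for p in per_subject], coverage, exclusion,
            config.wm_anat_threshold, config.func_threshold,
            excluded_atlas="synthetic subcortical blob" if exclusion is not None else None)

    # ---- group inference per (tissue, measure) ---------------------------
    design = inference.build_design(phenotype)
    affine = cohort_cfg.affine
    voxel_mm = cohort_cfg.voxel_size_mm
    analyses: dict[tuple[str, str], AnalysisResult] = {}
    table_rows = []
    for tissue in config.tissues:
        for measure in config.measures:
            key = (measure, tissue)
            stack = np.stack([
                p["maps"][key].data for p in per_subject
            ])
            analysis_mask = group_masks[tissue].data.copy()
            if measure == "coupling":
                # restrict to voxels where every subject's density clears the floor
                valid_all = np.all([p["maps"][key].mask for p in per_subject], axis=0)
                analysis_mask &= valid_all
            if not analysis_mask.any():
                raise ValueError(f"empty analysis mask for {measure}/{tissue}")
            stat, resid = inference.fit_voxelwise_ancova(stack, design, analysis_mask)
            smooth = inference.estimate_smoothness(resid, analysis_mask, voxel_mm)
            clusters = inference.grf_cluster_correct(
                stat, smooth, affine, config.voxel_p, config.cluster_p,
                config.connectivity, map_stack=stack)
            perm_clusters = None
            if config.run_permutation:
                perm_clusters = inference.permutation_cluster_correct(
                    stack, design, analysis_mask, affine, config.voxel_p,
                    config.n_perm, config.seed, config.connectivity)
            n_regions = max(len(clusters), 1)
            posthoc: dict[int, list] = {}
            correlations: dict[int, dict] = {}
            for c in clusters:
                posthoc[c.label] = inference.posthoc_pairwise(
                    c.per_subject_means, design, n_regions, method=config.posthoc_method)
                correlations[c.label] = {}
                for grp in ("VMCI", "MCI"):
                    try:
                        correlations[c.label][grp] = inference.correlate_with_mmse(
                            c.per_subject_means, phenotype["mmse"].to_numpy(),
                            design.groups, grp)
                    except ValueError:
                        pass
                row = {
                    "tissue": tissue, "measure": measure, "cluster": c.label,
                    "peak_x_mm": c.peak_coordinate_mm[0],
                    "peak_y_mm": c.peak_coordinate_mm[1],
                    "peak_z_mm": c.peak_coordinate_mm[2],
                    "peak_F": c.peak_stat, "cluster_size": c.cluster_size_voxels,
                    "cluster_p": c.cluster_p,
                }
                for ph in posthoc[c.label]:
                    name = PAIR_NAMES[ph.pair]
                    row[f"{name}_U"] = ph.u_stat
                    row[f"{name}_p"] = ph.p_raw
                    row[f"{name}_t"] = ph.t_stat
                    row[f"{name}_significant"] = ph.significant
                for grp, corr in correlations[c.label].items():
                    row[f"mmse_r_{grp.lower()}"] = corr.r
                    row[f"mmse_p_{grp.lower()}"] = corr.p_two_tailed
                table_rows.append(row)
            analyses[key] = AnalysisResult(
                tissue, measure, group_masks[tissue], analysis_mask, stat, smooth,
                clusters, posthoc, correlations, perm_clusters)

    cluster_table = pd.DataFrame(table_rows)

    # ---- provenance ------------------------------------------------------
    hasher = hashlib.sha256()
    hasher.update(cluster_table.to_csv(index=False).encode())
    for tissue in sorted(group_masks):
        hasher.update(group_masks[tissue].data.tobytes())
    for key in sorted(analyses):
        hasher.update(np.ascontiguousarray(analyses[key].stat_map.data).tobytes())
    provenance = {
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": n_subjects,
        "mask_hashes": {t: _array_hash(m.data) for t, m in group_masks.items()},
        "report_hash": hasher.hexdigest()[:16],
    }

    if out_dir:
        _write_outputs(out_dir, config, cluster_table, group_masks, analyses,
                       phenotype, provenance, affine)

    return RunReport(cluster_table, analyses, group_masks, phenotype, provenance)


def _write_outputs(out_dir, config, cluster_table, group_masks, analyses,
                   phenotype, provenance, affine) -> None:
    import nibabel as nib

    cluster_table.to_csv(out_dir / "cluster_table.tsv", sep="\t", index=False)
    phenotype.to_csv(out_dir / "phenotype.tsv", sep="\t", index=False)
    file_hashes = {}
    for tissue, m in group_masks.items():
        path = out_dir / f"group_mask_{tissue}.nii.gz"
        nib.save(nib.Nifti1Image(m.data.astype(np.uint8), affine), path)
        file_hashes[path.name] = _array_hash(m.data)
    for (measure, tissue), res in analyses.items():
        path = out_dir / f"stat_F_{measure}_{tissue}.nii.gz"
        nib.save(nib.Nifti1Image(res.stat_map.data.astype(np.float32), affine), path)
        file_hashes[path.name] = _array_hash(res.stat_map.data)
    provenance = dict(provenance, file_hashes=file_hashes)
    (out_dir / "run_report.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    # stage marker: a re-run with the same config can detect completion
    (out_dir / ".stage_complete").write_text(provenance["config_hash"])
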