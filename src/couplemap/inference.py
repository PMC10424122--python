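"""Group inference: voxel-wise ANCOVA, random-field cluster correction,
permutation oracle, post-hoc contrasts and clinical correlations.

The omnibus test at each voxel is the partial F for the three-level group
factor given age, gender and education (full-vs-reduced model comparison,
df = (2, n - 5)).  Cluster-level multiple-comparison control follows
Gaussian random field theory: the F map is Gaussianized through its
voxel-wise p-values, field smoothness (per-axis FWHM, hence RESELs) is
estimated from the standardized model residuals, and each suprathreshold
cluster receives a family-wise corrected p from the expected Euler
characteristic and the exponential cluster-extent approximation
(P(extent >= k resels) = exp(-beta k^(2/3))).  A Freedman-Lane label
permutation of the same statistic provides a distribution-free oracle for
the cluster-level p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

GROUP_LEVELS = ("NC", "VMCI", "MCI")
COVARIATES = ("age", "gender", "education")

_4LN2 = 4.0 * np.log(2.0)


# --------------------------------------------------------------------------
# Design
# --------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Full and reduced (covariates-only) design matrices for the group ANCOVA."""

    full: np.ndarray        # intercept, 2 group dummies, covariates
    reduced: np.ndarray     # intercept, covariates
    groups: np.ndarray      # string labels per subject
    subject_ids: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.full.shape[0]

    @property
    def df(self) -> tuple[int, int]:
        return (len(GROUP_LEVELS) - 1, self.n_subjects - self.full.shape[1])


def build_design(phenotype: pd.DataFrame) -> DesignMatrix:
    """Design from a phenotype table with columns group/age/gender/education.

    Group is dummy-coded against NC; covariates are mean-centered so the
    intercept is the adjusted NC mean.
    """
    groups = phenotype["group"].to_numpy()
    unknown = set(groups) - set(GROUP_LEVELS)
    if unknown:
        raise ValueError(f"unknown group labels: {unknown}")
    n = len(phenotype)
    dummies = np.column_stack([(groups == g).astype(float) for g in GROUP_LEVELS[1:]])
    covs = phenotype[list(COVARIATES)].to_numpy(dtype=float)
    covs = covs - covs.mean(axis=0)
    full = np.column_stack([np.ones(n), dummies, covs])
    reduced = np.column_stack([np.ones(n), covs])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates or empty group)")
    ids = phenotype["subject"].to_numpy() if "subject" in phenotype else np.arange(n)
    return DesignMatrix(full, reduced, groups, ids)


# --------------------------------------------------------------------------
# Voxel-wise ANCOVA
# --------------------------------------------------------------------------

@dataclass
class StatMap:
    """3-D statistic map (partial F for the group factor) with its df and mask."""

    data: np.ndarray
    df: tuple[int, int]
    mask: np.ndarray
    stat: str = "F"


def _residual_maker(X: np.ndarray) -> np.ndarray:
    """Annihilator matrix M = I - X (X'X)^-1 X'."""
    return np.eye(X.shape[0]) - X @ np.linalg.pinv(X)


def fit_voxelwise_ancova(
    map_stack: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray,
) -> tuple[StatMap, np.ndarray]:
    """Partial F for group at every in-mask voxel, plus full-model residuals.

    ``map_stack`` is (n_subjects, x, y, z) in the same subject order as the
    design.  Returns the F map and the (n_subjects, x, y, z) residual stack
    used for smoothness estimation.
    """
    for g in GROUP_LEVELS:
        if (design.groups == g).sum() < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects")
    mask = np.asarray(mask, dtype=bool)
    n = design.n_subjects
    if map_stack.shape[0] != n:
        raise ValueError("map stack subject count does not match design")
    Y = map_stack[:, mask]  # (n, v)
    M_full = _residual_maker(design.full)
    M_red = _residual_maker(design.reduced)
    R_full = M_full @ Y
    R_red = M_red @ Y
    rss_full = np.einsum("ij,ij->j", R_full, R_full)
    rss_red = np.einsum("ij,ij->j", R_red, R_red)
    df1, df2 = design.df
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_red - rss_full) / df1) / (rss_full / df2)
    F = np.where(np.isfinite(F), F, 0.0)
    fmap = np.zeros(mask.shape)
    fmap[mask] = F
    resid = np.zeros_like(map_stack)
    resid[:, mask] = R_full
    return StatMap(fmap, (df1, df2), mask), resid


# --------------------------------------------------------------------------
# Smoothness / RESELs
# --------------------------------------------------------------------------

@dataclass
class SmoothnessEstimate:
    """Per-axis field FWHM (mm) and the RESEL count of the search mask."""

    fwhm_mm: np.ndarray          # (3,)
    resels: float
    voxel_size_mm: float
    method: str = "residual-gradient"

    @property
    def fwhm_vox(self) -> np.ndarray:
        return self.fwhm_mm / self.voxel_size_mm


def estimate_smoothness(
    residual_stack: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm: float,
) -> SmoothnessEstimate:
    """Estimate field smoothness from standardized residual gradients.

    Residuals are normalized to unit sum of squares across images at each
    voxel; for each axis the mean squared forward difference of the
    normalized residuals (over in-mask voxel pairs, summed over images)
    estimates the derivative variance Lambda of the unit-variance field,
    giving FWHM = sqrt(4 ln 2 / Lambda) voxels.  RESELs = mask volume in
    voxels divided by the product of the per-axis FWHMs.
    """
    if residual_stack.shape[0] < 10:
        raise ValueError("need at least 10 residual images")
    mask = np.asarray(mask, dtype=bool)
    ss = np.sqrt((residual_stack[:, mask] ** 2).sum(axis=0))
    ok = ss > 0
    u = np.zeros_like(residual_stack)
    in_idx = np.where(mask)
    u[:, mask] = np.where(ok, residual_stack[:, mask] / np.where(ok, ss, 1.0), 0.0)
    valid = np.zeros(mask.shape, dtype=bool)
    valid[in_idx] = ok
    fwhm_vox = np.empty(3)
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        pair = valid[tuple(sl_lo)] & valid[tuple(sl_hi)]
        if not pair.any():
            raise ValueError(f"no in-mask voxel pairs along axis {ax}")
        du = (u[(slice(None), *sl_hi)] - u[(slice(None), *sl_lo)])[:, pair]
        lam = (du ** 2).sum(axis=0).mean()
        fwhm_vox[ax] = np.sqrt(_4LN2 / lam) if lam > 0 else np.inf
    resels = valid.sum() / np.prod(fwhm_vox)
    return SmoothnessEstimate(fwhm_vox * voxel_size_mm, float(resels), voxel_size_mm)


# --------------------------------------------------------------------------
# GRF cluster-level correction
# --------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """One suprathreshold cluster with its corrected cluster-level p."""

    label: int
    peak_coordinate_mm: tuple[float, float, float]
    peak_stat: float
    cluster_size_voxels: int
    cluster_p: float
    voxel_indices: tuple[np.ndarray, ...] = field(repr=False, default=())
    per_subject_means: np.ndarray | None = field(repr=False, default=None)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6, 18 or 26")


def _ec_density_3d_gauss(u: float) -> float:
    """3-D Euler-characteristic density of a unit Gaussian field at height u."""
    return (_4LN2 ** 1.5) / (2.0 * np.pi) ** 2 * (u * u - 1.0) * np.exp(-u * u / 2.0)


def _ec_density_3d_f(u: float, k: int, v: int) -> float:
    """3-D EC density of an F field with (k, v) degrees of freedom
    (Worsley's unified RFT densities) at height u."""
    from scipy.special import gammaln

    x = k * u / v
    a = _4LN2 / (2.0 * np.pi)
    lg = gammaln((v + k - 3) / 2.0) - gammaln(v / 2.0) - gammaln(k / 2.0)
    poly = ((v - 1.0) * (v - 2.0) * x * x
            - (2.0 * v * k - v - k - 1.0) * x
            + (k - 1.0) * (k - 2.0))
    return (a ** 1.5 * np.exp(lg) / np.sqrt(2.0)
            * x ** ((k - 3) / 2.0) * (1.0 + x) ** (-(v + k - 2) / 2.0) * poly)


def grf_cluster_p(
    cluster_size_voxels: int,
    smoothness: SmoothnessEstimate,
    voxel_p: float,
    n_mask_voxels: int,
    df: tuple[int, int] | None = None,
    stat: str = "Z",
) -> float:
    """Family-wise corrected p for one cluster under random-field theory.

    The height threshold u is the ``voxel_p`` upper quantile of the field's
    marginal (Gaussian, or F with ``df``).  The expected cluster count is
    m = RESELs * rho_3(u), with rho_3 the field type's 3-D EC density and
    RESELs from the component-field (residual) smoothness; the expected
    suprathreshold volume is S * P(field > u).  A cluster of k resels has
    P(extent >= k) = exp(-beta k^(2/3)), beta = (Gamma(5/2) m / E[N])^(2/3)
    with E[N] in resels (the exponential extent approximation applied to
    non-Gaussian fields as well); the corrected p is
    1 - exp(-m P(extent >= k)).  Only the 3-D EC term is used (boundary
    terms omitted).
    """
    if stat == "F":
        if df is None:
            raise ValueError("F-field cluster p needs df")
        u = stats.f.isf(voxel_p, *df)
        rho3 = _ec_density_3d_f(u, *df)
        tail = stats.f.sf(u, *df)
    else:
        u = stats.norm.isf(voxel_p)
        rho3 = _ec_density_3d_gauss(u)
        tail = stats.norm.sf(u)
    fwhm_prod = np.prod(smoothness.fwhm_vox)
    resels = n_mask_voxels / fwhm_prod
    m = resels * rho3
    en_resels = n_mask_voxels * tail / fwhm_prod
    if m <= 0 or en_resels <= 0:
        return 1.0
    k_resels = cluster_size_voxels / fwhm_prod
    beta = (math.gamma(2.5) * m / en_resels) ** (2.0 / 3.0)
    p_unc = np.exp(-beta * k_resels ** (2.0 / 3.0))
    return float(1.0 - np.exp(-m * p_unc))


def gaussianize_f(stat: StatMap) -> np.ndarray:
    """Map F values to Z scores with the same upper-tail probability."""
    pvals = stats.f.sf(stat.data, *stat.df)
    z = stats.norm.isf(np.clip(pvals, 1e-300, 1.0))
    return np.where(stat.mask, z, -np.inf)


def grf_cluster_correct(
    stat: StatMap,
    smoothness: SmoothnessEstimate,
    affine: np.ndarray,
    voxel_p: float = 0.001,
    cluster_p: float = 0.01,
    connectivity: int = 26,
    map_stack: np.ndarray | None = None,
) -> list[ClusterResult]:
    """Threshold the stat map at the voxel-level p and keep RFT-significant clusters.

    F maps are thresholded at the F quantile of ``voxel_p`` (equivalently:
    Gaussianized and thresholded at the normal quantile); connected
    components (26-connectivity by default) whose corrected cluster-level p
    is below ``cluster_p`` are returned sorted by decreasing size.  If
    ``map_stack`` is given, each cluster carries the per-subject mean of
    the analyzed map over its voxels, for post-hoc tests and correlations.
    """
    if stat.stat == "F":
        thresh = stats.f.isf(voxel_p, *stat.df)
    else:
        thresh = stats.norm.isf(voxel_p)
    supra = (stat.data > thresh) & stat.mask
    if not supra.any():
        return []
    labels, n_labels = ndimage.label(supra, structure=_connectivity_structure(connectivity))
    n_mask = int(stat.mask.sum())
    results = []
    for lab in range(1, n_labels + 1):
        idx = np.where(labels == lab)
        size = idx[0].size
        p = grf_cluster_p(size, smoothness, voxel_p, n_mask,
                          df=stat.df, stat=stat.stat)
        if p >= cluster_p:
            continue
        vals = stat.data[idx]
        k = int(np.argmax(vals))
        peak_vox = np.array([idx[0][k], idx[1][k], idx[2][k], 1.0])
        peak_mm = tuple((np.asarray(affine) @ peak_vox)[:3])
        means = map_stack[:, idx[0], idx[1], idx[2]].mean(axis=1) if map_stack is not None else None
        results.append(ClusterResult(lab, peak_mm, float(vals[k]), int(size), p, idx, means))
    results.sort(key=lambda c: c.cluster_size_voxels, reverse=True)
    return results


# --------------------------------------------------------------------------
# Permutation oracle (Freedman-Lane)
# --------------------------------------------------------------------------

def permutation_cluster_correct(
    map_stack: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray,
    affine: np.ndarray,
    voxel_p: float = 0.001,
    n_perm: int = 1000,
    seed: int = 0,
    connectivity: int = 26,
    cluster_p: float = 1.0,
) -> list[ClusterResult]:
    """Cluster-extent family-wise p-values by Freedman-Lane permutation.

    The reduced (covariates-only) model is fit once; permuting its
    residuals and adding back the reduced fit gives surrogate data with
    group effects destroyed but covariate structure intact.  The null
    distribution of the maximum suprathreshold cluster size yields
    corrected p = (1 + #{perm max >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    mask = np.asarray(mask, dtype=bool)
    structure = _connectivity_structure(connectivity)
    n = design.n_subjects
    Y = map_stack[:, mask]
    M_full = _residual_maker(design.full)
    M_red = _residual_maker(design.reduced)
    df1, df2 = design.df
    f_thresh = stats.f.isf(voxel_p, df1, df2)

    def f_values(Ymat: np.ndarray) -> np.ndarray:
        R_full = M_full @ Ymat
        rss_full = np.einsum("ij,ij->j", R_full, R_full)
        R_red = M_red @ Ymat
        rss_red = np.einsum("ij,ij->j", R_red, R_red)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ((rss_red - rss_full) / df1) / (rss_full / df2)
        return np.where(np.isfinite(F), F, 0.0)

    def max_cluster(Fvals: np.ndarray) -> int:
        supra = np.zeros(mask.shape, dtype=bool)
        supra[mask] = Fvals > f_thresh
        if not supra.any():
            return 0
        labels, n_labels = ndimage.label(supra, structure=structure)
        return int(np.bincount(labels.ravel())[1:].max())

    # Observed clusters.
    F_obs = f_values(Y)
    supra = np.zeros(mask.shape, dtype=bool)
    supra[mask] = F_obs > f_thresh
    obs_labels, n_labels = ndimage.label(supra, structure=structure)
    obs_sizes = np.bincount(obs_labels.ravel())[1:] if n_labels else np.array([], dtype=int)

    # Freedman-Lane surrogate data.
    fit_red = Y - M_red @ Y
    resid_red = M_red @ Y
    null_max = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        perm = rng.permutation(n)
        null_max[i] = max_cluster(f_values(fit_red + resid_red[perm]))

    fmap = np.zeros(mask.shape)
    fmap[mask] = F_obs
    results = []
    for lab in range(1, n_labels + 1):
        idx = np.where(obs_labels == lab)
        size = int(obs_sizes[lab - 1])
        p = (1 + int((null_max >= size).sum())) / (n_perm + 1)
        if p >= cluster_p:
            continue
        vals = fmap[idx]
        k = int(np.argmax(vals))
        peak_vox = np.array([idx[0][k], idx[1][k], idx[2][k], 1.0])
        peak_mm = tuple((np.asarray(affine) @ peak_vox)[:3])
        means = map_stack[:, idx[0], idx[1], idx[2]].mean(axis=1)
        results.append(ClusterResult(lab, peak_mm, float(vals[k]), size, p, idx, means))
    results.sort(key=lambda c: c.cluster_size_voxels, reverse=True)
    return results


# --------------------------------------------------------------------------
# Post-hoc contrasts
# --------------------------------------------------------------------------

@dataclass
class PosthocResult:
    """Pairwise group contrast on cluster-mean values.

    Both the covariate-adjusted t and the Mann-Whitney U are computed;
    ``method`` selects which p is Bonferroni-corrected as primary.
    """

    pair: tuple[str, str]
    t_stat: float
    p_t: float
    u_stat: float
    p_u: float
    method: str
    p_raw: float
    p_bonferroni: float
    significant: bool


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U (min-U convention) with a two-tailed p.

    U counts favorable cross-pairs (ties half); the reported statistic is
    min(U_x, U_y).  The p-value uses exact enumeration for group sizes up
    to 20 without ties, and the tie-corrected normal approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)  # pairs with x > y (+ half ties)
    u_min = min(u1, x.size * y.size - u1)
    return u_min, float(res.pvalue)


def posthoc_pairwise(
    cluster_means: np.ndarray,
    design: DesignMatrix,
    n_regions: int,
    alpha: float = 0.05,
    method: str = "mannwhitney",
) -> list[PosthocResult]:
    """All three pairwise group contrasts on per-subject cluster means.

    The parametric route regresses the cluster means of the two groups on
    an intercept, a group indicator and the centered covariates and tests
    the indicator's t; the nonparametric route is the Mann-Whitney U.  The
    primary p (chosen by ``method``: "mannwhitney" or "ancova_t") is
    Bonferroni-corrected by ``n_regions``.
    """
    values = np.asarray(cluster_means, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite cluster means")
    if method not in ("mannwhitney", "ancova_t"):
        raise ValueError(f"unknown post-hoc method {method!r}")
    covs = design.full[:, len(GROUP_LEVELS):]
    results = []
    pairs = [("NC", "VMCI"), ("NC", "MCI"), ("VMCI", "MCI")]
    for a, b in pairs:
        sel = (design.groups == a) | (design.groups == b)
        if sel.sum() < 3:
            raise ValueError(f"pair {a}/{b} has fewer than 3 subjects")
        yv = values[sel]
        ind = (design.groups[sel] == b).astype(float)
        C = covs[sel]
        C = C - C.mean(axis=0)
        C = C[:, C.std(axis=0) > 0]  # constant covariates carry no information
        X = np.column_stack([np.ones(sel.sum()), ind, C])
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ beta
        dof = sel.sum() - X.shape[1]
        s2 = resid @ resid / dof
        xtx_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(s2 * xtx_inv[1, 1]) if s2 > 0 else 0.0
        t = beta[1] / se if se > 0 else 0.0
        p_t = 2 * stats.t.sf(abs(t), dof) if se > 0 else 1.0
        u, p_u = mann_whitney_u(values[design.groups == a], values[design.groups == b])
        p_raw = p_u if method == "mannwhitney" else p_t
        p_bonf = min(1.0, p_raw * n_regions)
        results.append(PosthocResult((a, b), float(t), float(p_t), u, p_u,
                                     method, p_raw, p_bonf, p_raw < alpha / n_regions))
    return results


# --------------------------------------------------------------------------
# Clinical correlations
# --------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    """Pearson correlation of cluster means with a clinical score."""

    r: float
    n: int
    t_stat: float
    p_two_tailed: float


def pearson_r_to_p(r: float, n: int) -> float:
    """Two-tailed p for a Pearson r via the exact Student-t transform.

    t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1:
        import warnings

        warnings.warn("|r| = 1: p is exactly 0 only for noiseless data")
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def correlate_with_mmse(
    cluster_means: np.ndarray,
    mmse: np.ndarray,
    groups: np.ndarray | None = None,
    group_filter: str | None = None,
) -> CorrelationResult:
    """Pearson r between per-subject cluster means and MMSE, optionally per group."""
    x = np.asarray(cluster_means, dtype=float)
    y = np.asarray(mmse, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if group_filter is not None:
        if groups is None:
            raise ValueError("group_filter requires group labels")
        sel = np.asarray(groups) == group_filter
        x, y = x[sel], y[sel]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 subjects after filtering")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    p = pearson_r_to_p(r, n)
    t = r * np.sqrt((n - 2) / (1.0 - r * r)) if abs(r) < 1 else np.inf
    return CorrelationResult(r, n, float(t), p)
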