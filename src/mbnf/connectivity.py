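"""Offline resting-state analysis around the feedback session.

Covers the denoising chain (motion metrics, outlier flagging, anatomical
CompCor, confound regression, band-pass), spherical-seed Fisher-z
connectivity maps, pre/post change with small-volume FDR correction,
voxelwise brain-behavior maps, and within-network summary connectivity.

Filtering is a spectral projection (hard frequency mask on the real FFT),
and confound regressors are passed through the same projection before the
voxelwise regression; with that ordering — filter confounds, regress,
filter residuals — the whole denoise step is exactly idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import SeedSpec
from .errors import DegenerateDataError, ShapeMismatchError
from .images import VolumeSeries, voxel_world_coordinates

logger = logging.getLogger(__name__)

_26CONN = np.ones((3, 3, 3), dtype=int)


# ---------------------------------------------------------------------------
# motion metrics and outliers


def framewise_displacement(motion_params: np.ndarray, head_radius: float = 50.0) -> np.ndarray:
    """Power-style framewise displacement in mm.

    ``fd[t] = sum |Δ translation_i| + head_radius * sum |Δ rotation_j|``
    with rotations in radians converted to arc length on a sphere of
    ``head_radius`` mm; ``fd[0] = 0`` by convention.
    """
    p = np.asarray(motion_params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ShapeMismatchError("motion_params must be T x 6")
    if p.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    d = np.abs(np.diff(p, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def global_signal_z(series: VolumeSeries, brain_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-TR mean in-brain intensity, z-scored across TRs."""
    if brain_mask is None:
        brain_mask = np.ones(series.grid_shape, dtype=bool)
    gs = series.voxel_timecourses(brain_mask).mean(axis=1)
    sd = gs.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero-variance global signal")
    return (gs - gs.mean()) / sd


def flag_outliers(
    series: VolumeSeries,
    fd: np.ndarray,
    gs_thresh: float = 5.0,
    fd_thresh: float = 0.9,
    brain_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Artifact-detection outlier flags: |global signal z| > threshold OR FD > threshold.

    Defaults are the lenient preset (z 5, 0.9 mm); pass ``gs_thresh=3,
    fd_thresh=0.5`` for the stringent preset.  Returns (flags, gs_z).
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size != series.n_vols:
        raise ShapeMismatchError("fd length does not match series")
    gz = global_signal_z(series, brain_mask)
    flags = (np.abs(gz) > gs_thresh) | (fd > fd_thresh)
    return flags, gz


# ---------------------------------------------------------------------------
# confounds


@dataclass
class ConfoundSet:
    """Everything regressed out of a resting run."""

    motion_params: np.ndarray  # T x 6
    fd: np.ndarray
    global_signal_z: np.ndarray
    outlier_flags: np.ndarray  # T bool
    compcor_wm: np.ndarray | None = None  # T x 5
    compcor_csf: np.ndarray | None = None  # T x 5

    @property
    def n_vols(self) -> int:
        return self.motion_params.shape[0]

    def design_matrix(self) -> np.ndarray:
        """Intercept, linear drift, 12 motion regressors (6 parameters and
        their first differences), CompCor components, and one spike
        regressor per flagged outlier frame."""
        T = self.n_vols
        cols = [np.ones(T), np.arange(T, dtype=float)]
        m = self.motion_params
        dm = np.vstack([np.zeros((1, 6)), np.diff(m, axis=0)])
        cols.extend(m.T)
        cols.extend(dm.T)
        for cc in (self.compcor_wm, self.compcor_csf):
            if cc is not None:
                cols.extend(np.asarray(cc).T)
        for t in np.flatnonzero(self.outlier_flags):
            spike = np.zeros(T)
            spike[t] = 1.0
            cols.append(spike)
        return np.column_stack(cols)


def compcor_components(series: VolumeSeries, tissue_mask: np.ndarray,
                       n_components: int = 5) -> np.ndarray:
    """Anatomical CompCor: top principal timecourses of a noise tissue.

    In-mask voxel series are linearly detrended and the first
    ``n_components`` left singular vectors of the T x V matrix are
    returned (T x n, orthonormal).
    """
    mask = np.asarray(tissue_mask, dtype=bool)
    if mask.sum() < n_components:
        raise ValueError("tissue mask smaller than n_components")
    X = series.voxel_timecourses(mask)  # T x V
    T = X.shape[0]
    design = np.column_stack([np.ones(T), np.arange(T, dtype=float)])
    X = X - design @ np.linalg.lstsq(design, X, rcond=None)[0]
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :n_components]


# ---------------------------------------------------------------------------
# filtering and denoising


def bandpass_projection(X: np.ndarray, band: tuple[float, float], tr: float) -> np.ndarray:
    """Hard spectral band-pass along the first axis (a true projection).

    Real-FFT bins with frequency inside [low, high] Hz are kept, everything
    else (including DC) is zeroed.  Applying it twice equals applying it
    once, which is what makes the denoising pipeline idempotent.
    """
    lo, hi = band
    T = X.shape[0]
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= lo) & (freqs <= hi)
    F = np.fft.rfft(X, axis=0)
    F[~keep] = 0.0
    return np.fft.irfft(F, n=T, axis=0)


def _prune_collinear(X: np.ndarray) -> np.ndarray:
    """Drop zero-norm and linearly dependent columns (warn when it happens)."""
    norms = np.linalg.norm(X, axis=0)
    keep = norms > 1e-10
    if not keep.all():
        # the intercept (and any other pure-DC column) always lands here
        # after band-pass filtering; that is expected, not a data problem
        logger.debug("dropping %d zero confound columns after filtering", int((~keep).sum()))
    X = X[:, keep]
    # greedy rank-revealing QR prune
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    dep = diag <= tol
    if dep.any():
        logger.warning("dropping %d collinear confound columns", int(dep.sum()))
        X = X[:, ~dep]
    return X


def denoise(
    series: VolumeSeries,
    confounds: ConfoundSet,
    band: tuple[float, float] = (0.008, 0.09),
    tr: float | None = None,
) -> VolumeSeries:
    """Confound regression followed by band-pass filtering.

    The confound design (intercept, drift, 12 motion regressors, CompCor,
    spike regressors) is band-pass projected, voxel series are residualized
    against it by OLS, and the residuals are band-pass projected.  The
    operation is exactly idempotent and removes constants and linear drift
    entirely (DC sits outside the pass band).
    """
    if tr is None:
        tr = series.tr
    if confounds.n_vols != series.n_vols:
        raise ShapeMismatchError("confound rows do not match series length")
    X = confounds.design_matrix()
    Xf = bandpass_projection(X, band, tr)
    Xf = _prune_collinear(Xf)
    Y = series.data.reshape(-1, series.n_vols).T  # T x V
    if Xf.shape[1] > 0:
        beta, *_ = np.linalg.lstsq(Xf, Y, rcond=None)
        Y = Y - Xf @ beta
    Y = bandpass_projection(Y, band, tr)
    out = Y.T.reshape(series.data.shape)
    return VolumeSeries(out, tr=series.tr, affine=series.affine.copy())


def smooth_series(series: VolumeSeries, fwhm_mm: float) -> VolumeSeries:
    """Gaussian spatial smoothing; ``fwhm_mm <= 0`` is a no-op."""
    if fwhm_mm <= 0:
        return series
    vox = np.sqrt((series.affine[:3, :3] ** 2).sum(axis=0))
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vox
    sm = ndimage.gaussian_filter(series.data, sigma=(*sigma, 0.0))
    return VolumeSeries(sm, tr=series.tr, affine=series.affine.copy())


# ---------------------------------------------------------------------------
# seeds and connectivity maps


def make_sphere_seed(spec: SeedSpec, affine: np.ndarray,
                     grid_dims: tuple[int, int, int]) -> np.ndarray:
    """Boolean mask of voxels whose world-space center lies within the sphere."""
    world = voxel_world_coordinates(grid_dims, affine)
    d2 = ((world - np.asarray(spec.center_world)) ** 2).sum(axis=-1)
    mask = d2 <= spec.radius_mm**2
    if not mask.any():
        raise ValueError(f"seed sphere {spec.label} does not intersect the grid")
    return mask


@dataclass
class ConnectivityMap:
    """Voxelwise Fisher-z connectivity with one seed."""

    fisher_z_field: np.ndarray
    seed_mask: np.ndarray
    n_usable_vols: int
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def values(self) -> np.ndarray:
        return self.fisher_z_field


_R_CAP = 1.0 - 1e-7


def seed_connectivity(series: VolumeSeries, seed_voxels: np.ndarray) -> ConnectivityMap:
    """Fisher-z map of each voxel's correlation with the mean seed timecourse.

    Correlations with |r| at 1 are capped just inside the open interval so
    the map stays finite (flagged degenerate); zero-variance voxels get
    z = 0 with a flag.  Seed voxels report their own correlation as
    computed, not masked out.
    """
    seed_voxels = np.asarray(seed_voxels, dtype=bool)
    T = series.n_vols
    if T < 10:
        raise ValueError("need at least 10 usable volumes")
    seed_tc = series.voxel_timecourses(seed_voxels).mean(axis=1)
    s_sd = seed_tc.std()
    if s_sd == 0:
        raise DegenerateDataError("seed timecourse has zero variance")
    Y = series.data.reshape(-1, T)  # V x T
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sc = seed_tc - seed_tc.mean()
    denom = np.sqrt((Yc**2).sum(axis=1)) * np.sqrt((sc**2).sum())
    zero_var = denom == 0
    denom[zero_var] = 1.0
    r = (Yc @ sc) / denom
    r[zero_var] = 0.0
    capped = np.abs(r) >= _R_CAP
    r = np.clip(r, -_R_CAP, _R_CAP)
    z = np.arctanh(r)
    z[zero_var] = 0.0
    return ConnectivityMap(
        fisher_z_field=z.reshape(series.grid_shape),
        seed_mask=seed_voxels,
        n_usable_vols=T,
        degenerate=(capped | zero_var).reshape(series.grid_shape),
    )


# ---------------------------------------------------------------------------
# group maps


def _extract_clusters(surviving: np.ndarray, stat_map: np.ndarray,
                      affine: np.ndarray | None) -> list[dict]:
    labels, n = ndimage.label(surviving, structure=_26CONN)
    clusters = []
    for lb in range(1, n + 1):
        in_cluster = labels == lb
        masked = np.where(in_cluster, np.abs(stat_map), -np.inf)
        peak_ijk = np.unravel_index(int(np.argmax(masked)), stat_map.shape)
        entry = {
            "size": int(in_cluster.sum()),
            "peak_ijk": tuple(int(v) for v in peak_ijk),
            "peak_stat": float(stat_map[tuple(peak_ijk)]),
        }
        if affine is not None:
            w = np.asarray(affine) @ np.array([*peak_ijk, 1.0])
            entry["peak_world_mm"] = tuple(float(v) for v in w[:3])
        clusters.append(entry)
    clusters.sort(key=lambda c: -c["size"])
    return clusters


@dataclass
class VoxelwiseResult:
    """A voxelwise statistical map restricted to a search region."""

    stat_map: np.ndarray
    p_map: np.ndarray
    surviving: np.ndarray
    clusters: list[dict]
    region_mask: np.ndarray
    df: int


def prepost_change(
    pre_maps: list[ConnectivityMap],
    post_maps: list[ConnectivityMap],
    region_mask: np.ndarray,
    covariate=None,
    q: float = 0.05,
    affine: np.ndarray | None = None,
) -> VoxelwiseResult:
    """Paired pre/post change with small-volume FDR correction.

    Per in-region voxel, the Fisher-z change (post - pre) is regressed on an
    intercept and an optional centered covariate (e.g. framewise
    displacement); the intercept's t statistic tests the adjusted mean
    change.  Benjamini–Hochberg is applied across the region's voxels at
    level ``q`` and surviving voxels are grouped into 26-connected clusters.
    """
    if len(pre_maps) != len(post_maps):
        raise ValueError("pre and post map lists differ in length")
    n = len(pre_maps)
    if n < 3:
        raise ValueError("need at least 3 paired subjects")
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("empty region mask")
    delta = np.stack(
        [post.fisher_z_field[region_mask] - pre.fisher_z_field[region_mask]
         for pre, post in zip(pre_maps, post_maps)]
    )  # n x V
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if cov.size != n:
            raise ShapeMismatchError("covariate length does not match subjects")
        X = np.column_stack([np.ones(n), cov - cov.mean()])
    else:
        X = np.ones((n, 1))
    df = n - X.shape[1]
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ delta  # p x V
    resid = delta - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[0, 0], 1e-300))
    t = beta[0] / se
    p = 2.0 * sps.t.sf(np.abs(t), df)
    rej, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")

    t_map = np.zeros(region_mask.shape)
    p_map = np.ones(region_mask.shape)
    surv = np.zeros(region_mask.shape, dtype=bool)
    t_map[region_mask] = t
    p_map[region_mask] = p
    surv[region_mask] = rej
    return VoxelwiseResult(
        stat_map=t_map,
        p_map=p_map,
        surviving=surv,
        clusters=_extract_clusters(surv, t_map, affine),
        region_mask=region_mask,
        df=df,
    )


def brain_behavior_map(
    maps: list[ConnectivityMap],
    scores,
    covariate=None,
    p_thresh: float = 0.001,
    region_mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> VoxelwiseResult:
    """Voxelwise (partial) correlation of connectivity with a behavioral score.

    With a covariate, both the score and each voxel's values are
    residualized against it and the correlation of residuals is tested with
    n - 3 degrees of freedom.  Voxels with p below ``p_thresh``
    (uncorrected) form the reported 26-connected clusters.
    """
    n = len(maps)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    scores = np.asarray(scores, dtype=float)
    if scores.size != n:
        raise ShapeMismatchError("scores length does not match number of maps")
    if scores.std() == 0:
        raise DegenerateDataError("constant behavioral scores")
    grid = maps[0].fisher_z_field.shape
    if region_mask is None:
        region_mask = np.ones(grid, dtype=bool)
    V = np.stack([m.fisher_z_field[region_mask] for m in maps])  # n x V

    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        X = np.column_stack([np.ones(n), cov - cov.mean()])
        hat = X @ np.linalg.inv(X.T @ X) @ X.T
        V = V - hat @ V
        s = scores - hat @ scores
        df = n - 3
    else:
        V = V - V.mean(axis=0)
        s = scores - scores.mean()
        df = n - 2
    s_norm = np.sqrt((s**2).sum())
    v_norm = np.sqrt((V**2).sum(axis=0))
    zero = v_norm == 0
    v_norm[zero] = 1.0
    r = (V * s[:, None]).sum(axis=0) / (v_norm * s_norm)
    r[zero] = 0.0
    r = np.clip(r, -_R_CAP, _R_CAP)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
    p = 2.0 * sps.t.sf(np.abs(t), df)

    r_map = np.zeros(grid)
    p_map = np.ones(grid)
    surv = np.zeros(grid, dtype=bool)
    r_map[region_mask] = r
    p_map[region_mask] = p
    surv[region_mask] = p < p_thresh
    return VoxelwiseResult(
        stat_map=r_map,
        p_map=p_map,
        surviving=surv,
        clusters=_extract_clusters(surv, r_map, affine),
        region_mask=region_mask,
        df=df,
    )


def within_network_connectivity(series: VolumeSeries, roi_masks: list[np.ndarray]) -> float:
    """Mean pairwise Fisher-z connectivity among ROI-mean timecourses."""
    if len(roi_masks) < 2:
        raise ValueError("need at least 2 ROIs")
    masks = [np.asarray(m, dtype=bool) for m in roi_masks]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if (masks[i] & masks[j]).any():
                logger.warning("ROIs %d and %d overlap", i, j)
    tcs = [series.voxel_timecourses(m).mean(axis=1) for m in masks]
    zs = []
    for i in range(len(tcs)):
        for j in range(i + 1, len(tcs)):
            a, b = tcs[i], tcs[j]
            if a.std() == 0 or b.std() == 0:
                raise DegenerateDataError("zero-variance ROI timecourse")
            r = float(np.corrcoef(a, b)[0, 1])
            zs.append(np.arctanh(np.clip(r, -_R_CAP, _R_CAP)))
    return float(np.mean(zs))
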