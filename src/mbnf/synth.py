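"""Synthetic BOLD, motion, and behavioral data with known ground truth.

Everything downstream — localizer, real-time engine, connectivity change,
mediation — is exercised on data produced here, so each generator returns
its ground truth alongside the data and is bit-reproducible under a seed.

The spatial model is deliberately simple: each "network" is a sum of
Gaussian blobs confined to its own slab of the grid, so network supports are
disjoint by construction.  Voxel signal is loading-weighted network
timecourse plus linear scanner drift plus Gaussian (optionally AR(1)) noise.
No hemodynamic convolution or physiological noise is modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ShapeMismatchError
from .images import VolumeSeries


@dataclass
class GroundTruth:
    """What was planted in a simulated run."""

    network_maps: list[np.ndarray]
    network_timecourses: np.ndarray  # T x K, signal units
    within_network_r: float
    between_network_r: float
    drift_slope: float
    noise_sd: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        d = {
            "within_network_r": self.within_network_r,
            "between_network_r": self.between_network_r,
            "drift_slope": self.drift_slope,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "n_networks": len(self.network_maps),
            "n_vols": int(self.network_timecourses.shape[0]),
        }
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


@dataclass
class BehaviorCohort:
    """A three-variable cohort: performance -> connectivity change -> mindfulness change.

    ``x``, ``m``, ``y`` are the population-standardized variables the
    generative chain is defined on; the table adds display-scale columns
    (a time-in-target fraction, a Fisher-z change, an SMS score change)
    that are affine transforms of them.
    """

    x: np.ndarray
    m: np.ndarray
    y: np.ndarray
    true_path_a: float
    true_path_b: float
    true_direct_c_prime: float
    noise_sd_m: float
    noise_sd_y: float
    seed: int
    table: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_subjects(self) -> int:
        return len(self.x)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# spatial maps


def make_network_maps(
    grid_dims: tuple[int, int, int],
    n_networks: int = 2,
    blobs_per_network: int = 3,
    seed: int = 0,
) -> list[np.ndarray]:
    """Smooth non-negative loading fields with disjoint supports.

    The longest grid axis is partitioned into one slab per network (with a
    one-voxel gap) and each network's Gaussian blobs live strictly inside
    its slab, so supra-threshold supports can never overlap.
    """
    grid_dims = tuple(int(d) for d in grid_dims)
    if len(grid_dims) != 3 or any(d < 8 for d in grid_dims):
        raise ValueError(f"grid_dims must be 3 values each >= 8, got {grid_dims}")
    if n_networks < 2:
        raise ValueError("n_networks must be >= 2")
    if blobs_per_network < 1:
        raise ValueError("blobs_per_network must be >= 1")

    rng = np.random.default_rng(seed)
    axis = int(np.argmax(grid_dims))
    n_axis = grid_dims[axis]
    edges = np.linspace(0, n_axis, n_networks + 1).astype(int)

    coords = np.meshgrid(*(np.arange(d) for d in grid_dims), indexing="ij")
    maps: list[np.ndarray] = []
    for k in range(n_networks):
        lo, hi = edges[k], edges[k + 1]
        lo_in = lo + 1 if k > 0 else lo  # one-voxel gap between slabs
        field_k = np.zeros(grid_dims)
        for _ in range(blobs_per_network):
            center = [rng.uniform(0.2 * d, 0.8 * d) for d in grid_dims]
            center[axis] = rng.uniform(lo_in + 0.25 * (hi - lo_in), hi - 0.25 * (hi - lo_in))
            sigma = [max(1.0, 0.12 * d) for d in grid_dims]
            sigma[axis] = max(1.0, 0.12 * (hi - lo_in))
            sq = sum(((coords[a] - center[a]) / sigma[a]) ** 2 for a in range(3))
            field_k += np.exp(-0.5 * sq)
        # hard-confine to the slab: guarantees disjoint supports
        slab = (coords[axis] >= lo_in) & (coords[axis] < hi)
        field_k = np.where(slab, field_k, 0.0)
        field_k[field_k < 1e-6] = 0.0
        maps.append(field_k)
    return maps


def top_fraction_mask(loading: np.ndarray, fraction: float = 0.5) -> np.ndarray:
    """Boolean support of the top ``fraction`` of strictly positive loadings."""
    pos = loading[loading > 0]
    if pos.size == 0:
        return np.zeros_like(loading, dtype=bool)
    thresh = np.quantile(pos, 1.0 - fraction)
    return loading > thresh


# ---------------------------------------------------------------------------
# volumetric runs


def _calibrate_amplitude(rel: np.ndarray, target_r: float, noise_sd: float) -> float:
    """Signal amplitude such that the mean pairwise correlation of voxels with
    relative loadings ``rel`` (signal = amp*rel*latent + noise) hits ``target_r``.

    The correlation of voxels i, j sharing one latent is sqrt(g_i*g_j) with
    g_i = (amp*rel_i)^2 / ((amp*rel_i)^2 + noise_sd^2); the pair mean is
    monotone in amp, so a bisection suffices.
    """
    if noise_sd == 0:
        return 1.0  # noise-free: correlations are 1 regardless of scale

    def mean_pair_r(amp: float) -> float:
        g = (amp * rel) ** 2 / ((amp * rel) ** 2 + noise_sd**2)
        s = np.sqrt(g)
        n = s.size
        return float((s.sum() ** 2 - (s**2).sum()) / (n * (n - 1)))

    lo, hi = 0.0, 1e3 * noise_sd
    if mean_pair_r(hi) < target_r:
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_pair_r(mid) < target_r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float, ar_coef: float) -> np.ndarray:
    eps = rng.standard_normal(shape)
    if ar_coef == 0.0:
        return sd * eps
    out = np.empty_like(eps)
    out[..., 0] = eps[..., 0]
    scale = np.sqrt(1.0 - ar_coef**2)
    for t in range(1, shape[-1]):
        out[..., t] = ar_coef * out[..., t - 1] + scale * eps[..., t]
    return sd * out  # stationary variance sd^2


def simulate_run(
    maps: list[np.ndarray],
    timecourses: np.ndarray | None = None,
    *,
    within_network_r: float = 0.0,
    between_network_r: float = 0.0,
    drift_slope: float = 0.0,
    noise_sd: float = 1.0,
    n_vols: int = 125,
    tr: float = 1.2,
    ar_coef: float = 0.0,
    affine: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[VolumeSeries, GroundTruth]:
    """Simulate one run: loading-weighted network signals + drift + noise.

    Parameters
    ----------
    maps
        Per-network 3-D loading fields (e.g. from :func:`make_network_maps`).
    timecourses
        Optional T x K explicit mean timecourses in signal units.  When
        omitted, latent Gaussian timecourses are drawn whose amplitude is set
        so that the mean pairwise correlation of in-network voxels matches
        ``within_network_r`` and the latent cross-correlation matches
        ``between_network_r``.
    n_vols, tr
        125 volumes at TR 1.2 s is one 2.5-minute feedback run; 250 volumes
        is one 5-minute rest run.

    Within-network correlation control: each voxel carries the network's
    latent timecourse scaled by its relative loading, and the network's
    global amplitude is calibrated (bisection on the closed-form pairwise
    correlation) so that the mean pairwise correlation over the map's
    top-50% core equals ``within_network_r``.
    """
    if n_vols < 10:
        raise ValueError("n_vols must be >= 10")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    K = len(maps)
    grid = maps[0].shape
    rng = np.random.default_rng(seed)

    if timecourses is not None:
        timecourses = np.asarray(timecourses, dtype=float)
        if timecourses.ndim == 1:
            timecourses = timecourses[:, None]
        if timecourses.shape != (n_vols, K):
            raise ShapeMismatchError(
                f"timecourses shape {timecourses.shape} != (n_vols={n_vols}, K={K})"
            )
        tcs = timecourses
    else:
        latent = rng.standard_normal((n_vols, K))
        if K >= 2 and between_network_r != 0.0 and within_network_r > 0.0:
            rho = np.clip(between_network_r / within_network_r, -1.0, 1.0)
            C = np.full((K, K), rho) + (1 - rho) * np.eye(K)
            latent = latent @ np.linalg.cholesky(C).T
        tcs = latent  # per-network amplitude applied below

    planted = np.zeros((n_vols, K))
    data = np.zeros(grid + (n_vols,))
    for k, m in enumerate(maps):
        support = m > 0
        if not support.any():
            continue
        rel = np.zeros_like(m)
        core = top_fraction_mask(m, 0.5)
        ref = m[core].mean() if core.any() else m[support].mean()
        rel[support] = m[support] / ref
        if timecourses is None:
            if within_network_r > 0.0:
                # calibrate so the mean pairwise correlation over the map's
                # top-50% core matches the request despite loading spread
                amp = _calibrate_amplitude(rel[core], within_network_r, noise_sd)
            else:
                amp = 0.0
            tc_k = amp * tcs[:, k]
        else:
            tc_k = tcs[:, k]
        planted[:, k] = tc_k
        data[support] += rel[support][:, None] * tc_k[None, :]

    t = np.arange(n_vols, dtype=float)
    data += drift_slope * t
    if noise_sd > 0:
        data += _ar1_noise(rng, grid + (n_vols,), noise_sd, ar_coef)

    if affine is None:
        affine = np.eye(4)
    series = VolumeSeries(data, tr=tr, affine=np.asarray(affine, dtype=float))
    truth = GroundTruth(
        network_maps=[m.copy() for m in maps],
        network_timecourses=planted,
        within_network_r=within_network_r,
        between_network_r=between_network_r,
        drift_slope=drift_slope,
        noise_sd=noise_sd,
        seed=seed,
    )
    return series, truth


def mind_wandering_timecourses(
    n_vols: int,
    n_baseline_vols: int,
    *,
    burst_prob: float = 0.12,
    burst_len_trs: int = 2,
    burst_amp: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Mean timecourses (T x 2: DMN, CEN) for a successful-modulation run.

    Successful mindfulness is modeled as a DMN held at baseline except for
    sparse positive "mind-wandering" reactivation bursts, with a quiescent
    CEN.  Against the incremental drift model this puts DMN below its own
    fitted trend most of the time, so CEN - DMN activation is positive on
    most feedback TRs — transient events are the only signals a
    trend-discounting estimator can register, a sustained shift being
    absorbed into the fit.
    """
    rng = np.random.default_rng(seed)
    dmn = np.zeros(n_vols)
    t = n_baseline_vols
    while t < n_vols:
        if rng.random() < burst_prob:
            dmn[t : t + burst_len_trs] = burst_amp
            t += burst_len_trs + 1
        else:
            t += 1
    return np.column_stack([dmn, np.zeros(n_vols)])


# ---------------------------------------------------------------------------
# motion


def simulate_motion(
    n_vols: int,
    spike_prob: float = 0.0,
    spike_scale: float = 2.0,
    *,
    walk_step_mm: float = 0.02,
    walk_step_rad: float = 2e-4,
    seed: int = 0,
) -> tuple[np.ndarray, list[int]]:
    """Realignment-parameter trace: bounded random walk plus sparse spikes.

    Returns a T x 6 array (3 translations mm, 3 rotations radians) and the
    list of frames where a spike of ``spike_scale`` mm was planted (the
    head jumps at the spike frame and returns the frame after).
    Walk increments are uniform on ±step, so with no spikes the
    frame-to-frame change per axis is bounded by the step size.
    """
    if not 0.0 <= spike_prob <= 1.0:
        raise ValueError("spike_prob must be in [0, 1]")
    if spike_scale < 0:
        raise ValueError("spike_scale must be >= 0")
    rng = np.random.default_rng(seed)
    steps = np.column_stack(
        [
            rng.uniform(-walk_step_mm, walk_step_mm, size=(n_vols, 3)),
            rng.uniform(-walk_step_rad, walk_step_rad, size=(n_vols, 3)),
        ]
    )
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    candidates = [int(i) for i in np.nonzero(rng.random(n_vols) < spike_prob)[0] if i >= 1]
    spikes: list[int] = []
    for i in candidates:
        # keep spikes >= 2 frames apart so each excursion is a clean
        # single-frame jump-and-return in the frame-to-frame differences
        if not spikes or i - spikes[-1] >= 2:
            spikes.append(i)
    for i in spikes:
        axis = rng.integers(0, 3)
        params[i, axis] += spike_scale  # single-frame excursion
    return params, spikes


def motion_to_frame(params: np.ndarray) -> pd.DataFrame:
    """Wrap a T x 6 motion array in the confound-table column dialect."""
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    return pd.DataFrame(np.asarray(params, dtype=float), columns=cols)


# ---------------------------------------------------------------------------
# behavioral cohort


def simulate_behavior_cohort(
    n_subjects: int = 9,
    true_path_a: float = -0.67,
    true_path_b: float = -0.76,
    true_direct_c_prime: float = 0.18,
    noise_sd_m: float | None = None,
    noise_sd_y: float | None = None,
    seed: int = 0,
) -> BehaviorCohort:
    """Draw a cohort from the mediation chain X -> M -> Y.

    X ~ N(0,1); M = a X + sd_m eps; Y = b M + c' X + sd_y eps.  With the
    default noise scales (chosen so Var(M) = Var(Y) = 1) the path
    coefficients are the population standardized paths.  Default paths are
    the study-scale effects: strong negative performance->connectivity and
    connectivity->mindfulness paths with a small direct remainder.
    """
    if n_subjects < 4:
        raise ValueError("n_subjects must be >= 4")
    a, b, cp = true_path_a, true_path_b, true_direct_c_prime
    if noise_sd_m is None:
        noise_sd_m = float(np.sqrt(max(0.0, 1.0 - a**2)))
    if noise_sd_y is None:
        var_struct = b**2 + cp**2 + 2 * a * b * cp
        noise_sd_y = float(np.sqrt(max(0.0, 1.0 - var_struct)))
    if noise_sd_m < 0 or noise_sd_y < 0:
        raise ValueError("noise SDs must be >= 0")

    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_subjects)
    m = a * x + noise_sd_m * rng.standard_normal(n_subjects)
    y = b * m + cp * x + noise_sd_y * rng.standard_normal(n_subjects)

    table = pd.DataFrame(
        {
            "nf_performance": 0.5 + 0.1 * x,  # time-in-target fraction scale
            "conn_change": -0.10 + 0.05 * m,  # Fisher-z change scale
            "sms_change": 8.0 + 11.0 * y,  # SMS score-point scale
        }
    )
    return BehaviorCohort(
        x=x,
        m=m,
        y=y,
        true_path_a=a,
        true_path_b=b,
        true_direct_c_prime=cp,
        noise_sd_m=noise_sd_m,
        noise_sd_y=noise_sd_y,
        seed=seed,
        table=table,
    )
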