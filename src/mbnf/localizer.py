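"""Personalized network localization.

A spatial source separation of concatenated resting runs yields ~30
component maps; each template network (DMN, CEN) is matched to the
component with the highest absolute spatial correlation, the winning map is
thresholded to its top 10% of in-brain loadings, and the binarized result is
the participant-specific network-of-interest mask that drives feedback.

Source separation itself is delegated to FastICA; only the selection and
thresholding logic is owned here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA

from .errors import DegenerateDataError, ShapeMismatchError
from .images import VolumeSeries
from .stats import paired_t

logger = logging.getLogger(__name__)


@dataclass
class ComponentSet:
    """Spatial maps and timecourses from one decomposition."""

    spatial_maps: list[np.ndarray]  # each 3-D, z-scored loadings in-brain
    timecourses: np.ndarray  # T x K
    brain_mask: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.spatial_maps)


@dataclass
class NetworkMask:
    """A binarized personalized network-of-interest."""

    binary_field: np.ndarray  # 3-D bool
    network_label: str  # "DMN" or "CEN"
    source_component: int
    match_r: float

    @property
    def voxel_count(self) -> int:
        return int(self.binary_field.sum())


def decompose(series: VolumeSeries, n_components: int = 30, seed: int = 0,
              brain_mask: np.ndarray | None = None) -> ComponentSet:
    """Spatial ICA of the in-brain voxel x time matrix.

    Components are returned as 3-D loading maps (z-scored over in-brain
    voxels) with their associated timecourses.  Ordering is deterministic
    for a fixed seed; signs are arbitrary, which downstream matching
    resolves explicitly.
    """
    T = series.n_vols
    if n_components > T:
        raise ValueError(f"n_components={n_components} exceeds T={T}")
    if brain_mask is None:
        brain_mask = np.ones(series.grid_shape, dtype=bool)
    X = series.voxel_timecourses(brain_mask)  # T x V
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds number of in-brain voxels")

    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=2000, tol=1e-4)
    sources = ica.fit_transform(X.T)  # V x K spatial sources
    timecourses = ica.mixing_  # T x K

    maps: list[np.ndarray] = []
    for k in range(n_components):
        s = sources[:, k]
        sd = s.std()
        if sd > 0:
            s = (s - s.mean()) / sd
        vol = np.zeros(series.grid_shape)
        vol[brain_mask] = s
        maps.append(vol)
    return ComponentSet(spatial_maps=maps, timecourses=timecourses, brain_mask=brain_mask)


def spatial_correlation(map_a: np.ndarray, map_b: np.ndarray,
                        brain_mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two maps over in-mask voxels."""
    if map_a.shape != map_b.shape:
        raise ShapeMismatchError("maps have different shapes")
    if brain_mask is None:
        brain_mask = np.ones(map_a.shape, dtype=bool)
    if brain_mask.shape != map_a.shape:
        raise ShapeMismatchError("brain_mask shape mismatch")
    a = map_a[brain_mask].astype(float)
    b = map_b[brain_mask].astype(float)
    if a.size < 2:
        raise ValueError("mask must contain at least 2 voxels")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateDataError("zero-variance map within mask")
    return float(np.corrcoef(a, b)[0, 1])


def select_components(
    components: ComponentSet,
    templates: dict[str, np.ndarray],
    brain_mask: np.ndarray | None = None,
) -> dict[str, dict]:
    """Match each template network to its best component by |spatial r|.

    Returns, per template label, the winning component index, the signed
    match correlation, and the loading map sign-flipped so its match with
    the template is positive (source separation has a sign ambiguity).
    If one component wins two templates it is assigned to the template with
    the larger |r| and the runner-up serves the other, so the feedback
    targets are always distinct components.
    """
    if components.n_components < 2:
        raise ValueError("need at least 2 components")
    if brain_mask is None:
        brain_mask = components.brain_mask

    corr: dict[str, list[float]] = {}
    for label, tmpl in templates.items():
        rs = []
        for cmap in components.spatial_maps:
            try:
                rs.append(spatial_correlation(cmap, tmpl, brain_mask))
            except DegenerateDataError:
                rs.append(0.0)
        if not any(np.isfinite(r) and r != 0.0 for r in rs):
            raise DegenerateDataError("all components degenerate against template " + label)
        corr[label] = rs

    # greedy assignment by descending |r|, one component per template
    chosen: dict[str, dict] = {}
    taken: set[int] = set()
    order = sorted(templates, key=lambda lb: -max(abs(r) for r in corr[lb]))
    for label in order:
        rs = corr[label]
        ranked = sorted(range(len(rs)), key=lambda i: (-abs(rs[i]), i))
        idx = next(i for i in ranked if i not in taken)
        taken.add(idx)
        r = rs[idx]
        cmap = components.spatial_maps[idx]
        chosen[label] = {
            "component": idx,
            "match_r": float(r),
            "map": cmap if r >= 0 else -cmap,
        }
    return chosen


def threshold_and_binarize(
    loading_map: np.ndarray,
    brain_mask: np.ndarray | None = None,
    top_fraction: float = 0.10,
    *,
    network_label: str = "",
    source_component: int = -1,
    match_r: float = np.nan,
) -> NetworkMask:
    """Keep exactly ceil(top_fraction * n_inbrain) highest-loading voxels.

    Ties are broken by lexicographic (flat C-order) voxel index so the mask
    is deterministic for any input.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    if brain_mask is None:
        brain_mask = np.ones(loading_map.shape, dtype=bool)
    idx_flat = np.flatnonzero(brain_mask.ravel())
    n_in = idx_flat.size
    if n_in == 0:
        raise ValueError("empty brain mask")
    k = int(np.ceil(top_fraction * n_in))
    vals = loading_map.ravel()[idx_flat]
    # sort by (-loading, voxel index): lexsort keys are last-key-primary
    order = np.lexsort((idx_flat, -vals))
    keep = idx_flat[order[:k]]
    binary = np.zeros(loading_map.size, dtype=bool)
    binary[keep] = True
    return NetworkMask(
        binary_field=binary.reshape(loading_map.shape),
        network_label=network_label,
        source_component=source_component,
        match_r=float(match_r),
    )


def localize_networks(
    series: VolumeSeries,
    templates: dict[str, np.ndarray],
    *,
    n_components: int = 30,
    top_fraction: float = 0.10,
    brain_mask: np.ndarray | None = None,
    seed: int = 0,
) -> dict[str, NetworkMask]:
    """decompose -> select -> threshold, returning one mask per template."""
    comp = decompose(series, n_components=n_components, seed=seed, brain_mask=brain_mask)
    picks = select_components(comp, templates, brain_mask)
    masks = {}
    for label, pick in picks.items():
        masks[label] = threshold_and_binarize(
            pick["map"],
            comp.brain_mask,
            top_fraction,
            network_label=label,
            source_component=pick["component"],
            match_r=pick["match_r"],
        )
    return masks


def compare_mask_sizes(counts_a, counts_b):
    """Paired t-test on per-subject mask voxel counts (e.g. DMN vs CEN)."""
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if counts_a.shape != counts_b.shape:
        raise ShapeMismatchError("count vectors differ in length")
    return paired_t(counts_a, counts_b, alternative="two-sided")


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * (a & b).sum() / denom)
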