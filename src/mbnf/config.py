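"""Single source of truth for every paradigm constant.

All stage modules pull their defaults from :class:`ParadigmConfig` so that a
study variant (different TR, circle geometry, filter band, ...) is expressed
as one config file rather than scattered edits.  Values are validated against
their documented ranges at load time and serialization round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import json
import typing
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class SeedSpec:
    """A spherical seed region in world (scanner) coordinates."""

    label: str
    center_world: tuple[float, float, float]
    radius_mm: float = 8.0


def _default_seed_specs() -> dict[str, SeedSpec]:
    # sgACC and MPFC spheres used for seed-based connectivity.
    return {
        "sgACC": SeedSpec("sgACC", (-2.0, 22.0, -16.0), 8.0),
        "MPFC": SeedSpec("MPFC", (-1.0, 53.0, -3.0), 8.0),
    }


@dataclass
class ParadigmConfig:
    """Every tunable constant of the neurofeedback paradigm and its analysis.

    Timing
    ------
    tr : repetition time in seconds (1.2 s EPI).
    baseline_sec : crosshair rest period opening each feedback run (30 s).
    run_sec : total duration of one feedback run (150 s = 2.5 min).
    n_runs : back-to-back feedback runs per session (5).
    rest_sec : duration of each pre/post resting-state scan (300 s = 5 min).

    Display / staircase
    -------------------
    dot_radius_px : white feedback dot radius (12 px).
    circle_radius_px : initial radius of the upper/lower target circles (56 px).
    center_distance_px : distance between the two circle centers (472 px);
        half of it maps screen pixels onto the unit dot ordinate.
    shrink_factor : multiplicative radius change on each shrink event (0.9).
    shrink_trigger_trs : qualifying TRs accumulated before a shrink (5).
    max_shrinks : shrink cap per circle per run (5).
    display_gain : converts a PDA value in baseline-SD units into dot
        ordinate units per TR (0.1; the screen scaling is a free choice and
        never affects the time-in-target metric, which depends only on sign).
    feedback_lag_trs : integer volume-to-display lag (0 = same TR).

    Localizer
    ---------
    n_components : source-separation dimensionality (~30).
    top_fraction : fraction of in-brain voxels kept when binarizing (0.10).

    Denoising / motion
    ------------------
    band_hz : band-pass edges in Hz (0.008, 0.09).
    fd_thresh_mm / gs_z_thresh : lenient outlier thresholds (0.9 mm, z 5).
    fd_thresh_strict_mm / gs_z_thresh_strict : stringent preset (0.5 mm, z 3).
    head_radius_mm : sphere radius converting rotations to arc length (50 mm).
    n_compcor : principal components kept per tissue (5 WM + 5 CSF).
    smooth_fwhm_mm : Gaussian smoothing kernel (6 mm; skipped on toy grids).

    Inference
    ---------
    fdr_q : FDR level for small-volume-corrected change maps (0.05).
    behavior_p_thresh : uncorrected voxel threshold for brain-behavior maps.
    n_subjects : cohort size used by synthetic replications (9).
    """

    tr: float = 1.2
    baseline_sec: float = 30.0
    run_sec: float = 150.0
    n_runs: int = 5
    rest_sec: float = 300.0

    dot_radius_px: float = 12.0
    circle_radius_px: float = 56.0
    center_distance_px: float = 472.0
    shrink_factor: float = 0.9
    shrink_trigger_trs: int = 5
    max_shrinks: int = 5
    display_gain: float = 0.1
    feedback_lag_trs: int = 0

    n_components: int = 30
    top_fraction: float = 0.10

    band_hz: tuple[float, float] = (0.008, 0.09)
    fd_thresh_mm: float = 0.9
    gs_z_thresh: float = 5.0
    fd_thresh_strict_mm: float = 0.5
    gs_z_thresh_strict: float = 3.0
    head_radius_mm: float = 50.0
    n_compcor: int = 5
    smooth_fwhm_mm: float = 6.0

    fdr_q: float = 0.05
    behavior_p_thresh: float = 0.001
    n_subjects: int = 9

    seed_specs: dict[str, SeedSpec] = field(default_factory=_default_seed_specs)
    rng_seed: int = 0

    # -- validation ---------------------------------------------------------

    _RANGES: typing.ClassVar[tuple] = (
        ("tr", 0.0, 30.0, False),
        ("baseline_sec", 0.0, None, False),
        ("run_sec", 0.0, None, False),
        ("rest_sec", 0.0, None, False),
        ("n_runs", 1, None, True),
        ("dot_radius_px", 0.0, None, False),
        ("circle_radius_px", 0.0, None, False),
        ("center_distance_px", 0.0, None, False),
        ("shrink_factor", 0.0, 1.0, False),
        ("shrink_trigger_trs", 1, None, True),
        ("max_shrinks", 0, None, True),
        ("display_gain", 0.0, None, False),
        ("feedback_lag_trs", 0, None, True),
        ("n_components", 2, None, True),
        ("top_fraction", 0.0, 1.0, False),
        ("fd_thresh_mm", 0.0, None, False),
        ("gs_z_thresh", 0.0, None, False),
        ("fd_thresh_strict_mm", 0.0, None, False),
        ("gs_z_thresh_strict", 0.0, None, False),
        ("head_radius_mm", 0.0, None, False),
        ("n_compcor", 1, None, True),
        ("smooth_fwhm_mm", 0.0, None, True),  # inclusive lower: 0 disables
        ("fdr_q", 0.0, 1.0, False),
        ("behavior_p_thresh", 0.0, 1.0, False),
        ("n_subjects", 2, None, True),
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, lo, hi, inclusive_lo in self._RANGES:
            v = getattr(self, name)
            if inclusive_lo:
                ok = v >= lo
            else:
                ok = v > lo
            if hi is not None:
                ok = ok and v < hi
            if not ok:
                raise ConfigError(
                    f"{name}={v!r} outside its allowed range "
                    f"({'[' if inclusive_lo else '('}{lo}, {hi if hi is not None else 'inf'})"
                )
        lo, hi = self.band_hz
        if not (0.0 < lo < hi):
            raise ConfigError(f"band_hz={self.band_hz!r} must satisfy 0 < low < high")
        if self.run_sec <= self.baseline_sec:
            raise ConfigError("run_sec must exceed baseline_sec")

    # -- derived quantities -------------------------------------------------

    @property
    def n_baseline_vols(self) -> int:
        """Number of volumes in the opening rest baseline (ceil(30 s / TR))."""
        import math

        return math.ceil(self.baseline_sec / self.tr)

    @property
    def n_run_vols(self) -> int:
        """Volumes per feedback run (150 s at the configured TR)."""
        return round(self.run_sec / self.tr)

    @property
    def n_rest_vols(self) -> int:
        return round(self.rest_sec / self.tr)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["band_hz"] = list(self.band_hz)
        d["seed_specs"] = {
            k: {"label": s.label, "center_world": list(s.center_world), "radius_mm": s.radius_mm}
            for k, s in self.seed_specs.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ParadigmConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "band_hz" in d:
            d["band_hz"] = tuple(d["band_hz"])
        if "seed_specs" in d:
            d["seed_specs"] = {
                k: SeedSpec(v["label"], tuple(v["center_world"]), v.get("radius_mm", 8.0))
                for k, v in d["seed_specs"].items()
            }
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> ParadigmConfig:
    """Load a YAML config; an empty file yields all paradigm defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return ParadigmConfig.from_dict(data)
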