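"""The closed-loop neurofeedback core.

Per arriving volume, an incremental GLM regresses every network voxel on an
intercept and a linear drift term; the residual of the newest volume, scaled
by the frozen baseline residual SD, is that voxel's activation estimate in
baseline-SD units.  Estimates are averaged over each network-of-interest
(DMN, CEN) and differenced into the positive diametric activity metric

    PDA = CEN activation estimate - DMN activation estimate,

which drives a vertical dot on screen: positive PDA moves the dot up toward
the upper target circle.  Sustained occupancy of a circle shrinks it by 10%
(at most 5 times per run) and recenters the dot — an adaptive staircase that
titrates difficulty.  Time-in-target is the fraction of feedback TRs with
PDA > 0, i.e. DMN below CEN.

The incremental accumulators reproduce batch ordinary least squares on all
volumes seen so far at every TR; this equivalence is the engine's defining
contract and is enforced by tests against a brute-force refit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ShapeMismatchError
from .images import VolumeSeries
from .localizer import NetworkMask
from .stats import TTestResult, one_sample_t

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# incremental GLM engine


class NeurofeedbackEngine:
    """Streaming activation estimator for two networks-of-interest.

    Parameters
    ----------
    dmn_mask, cen_mask
        Binary 3-D fields (or :class:`NetworkMask`).  Overlapping voxels are
        logged and assigned to neither network summary.
    n_baseline_vols
        Length of the opening rest baseline in volumes; defaults to
        ceil(30 s / tr) — 25 volumes at TR 1.2 s.  The baseline defines the
        residual-SD scale, frozen when it ends.
    sd_floor
        Voxels whose baseline residual SD falls below this are degenerate
        (e.g. noise-free synthetic data); their estimates are reported as 0.
    """

    def __init__(
        self,
        dmn_mask,
        cen_mask,
        n_baseline_vols: int | None = None,
        tr: float = 1.2,
        sd_floor: float = 1e-8,
    ) -> None:
        dmn = self._as_bool(dmn_mask)
        cen = self._as_bool(cen_mask)
        if dmn.shape != cen.shape:
            raise ShapeMismatchError("DMN and CEN masks have different shapes")
        if not dmn.any() or not cen.any():
            raise ValueError("empty network mask")
        overlap = dmn & cen
        if overlap.any():
            logger.warning(
                "DMN and CEN masks overlap in %d voxels; overlap assigned to neither",
                int(overlap.sum()),
            )
            dmn = dmn & ~overlap
            cen = cen & ~overlap
            if not dmn.any() or not cen.any():
                raise ValueError("mask empty after removing overlap")
        if n_baseline_vols is None:
            n_baseline_vols = math.ceil(30.0 / tr)
        if n_baseline_vols < 2:
            raise ValueError("n_baseline_vols must be >= 2")

        self.tr = float(tr)
        self.n_baseline_vols = int(n_baseline_vols)
        self.sd_floor = float(sd_floor)
        self.grid_shape = dmn.shape
        self.union_mask = dmn | cen
        union_idx = np.flatnonzero(self.union_mask.ravel())
        self._union_idx = union_idx
        self._dmn_cols = np.isin(union_idx, np.flatnonzero(dmn.ravel()))
        self._cen_cols = np.isin(union_idx, np.flatnonzero(cen.ravel()))

        n_vox = union_idx.size
        self.n_vols_seen = 0
        self._s_t = 0.0
        self._s_tt = 0.0
        self._s_y = np.zeros(n_vox)
        self._s_ty = np.zeros(n_vox)
        self._baseline_buf: list[np.ndarray] = []
        self.baseline_residual_sd: np.ndarray | None = None

    @staticmethod
    def _as_bool(mask) -> np.ndarray:
        if isinstance(mask, NetworkMask):
            mask = mask.binary_field
        return np.asarray(mask, dtype=bool)

    # -- core ---------------------------------------------------------------

    @property
    def in_baseline(self) -> bool:
        return self.n_vols_seen < self.n_baseline_vols

    def coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        """Current (intercept, drift slope) per voxel, solved from accumulators."""
        n = self.n_vols_seen
        if n == 0:
            raise DegenerateDataError("no volumes seen yet")
        det = n * self._s_tt - self._s_t**2
        if det <= 0:  # only one distinct time point
            b1 = np.zeros_like(self._s_y)
            b0 = self._s_y / n
        else:
            b1 = (n * self._s_ty - self._s_t * self._s_y) / det
            b0 = (self._s_y - b1 * self._s_t) / n
        return b0, b1

    def update(self, volume: np.ndarray) -> tuple[float, float]:
        """Ingest one volume; return (dmn_estimate, cen_estimate) in baseline-SD units.

        The volume is folded into the accumulators first, so the nuisance
        fit at TR t is the batch OLS over volumes 0..t; the estimate is the
        newest volume's residual under that fit, divided by the frozen
        baseline residual SD.  During the baseline block a provisional
        running SD is used and ``in_baseline`` flags the output.
        """
        volume = np.asarray(volume, dtype=float)
        if volume.shape != self.grid_shape:
            raise ShapeMismatchError(
                f"volume shape {volume.shape} != mask grid {self.grid_shape}"
            )
        y = volume.ravel()[self._union_idx]
        t = float(self.n_vols_seen)
        self.n_vols_seen += 1
        self._s_t += t
        self._s_tt += t * t
        self._s_y += y
        self._s_ty += t * y

        if len(self._baseline_buf) < self.n_baseline_vols:
            self._baseline_buf.append(y)

        b0, b1 = self.coefficients()
        resid = y - (b0 + b1 * t)

        if self.baseline_residual_sd is None and self.n_vols_seen == self.n_baseline_vols:
            self._freeze_baseline(b0, b1)

        sd = self.baseline_residual_sd
        if sd is None:
            sd = self._running_sd(b0, b1)
        z = np.where(sd > self.sd_floor, resid / np.maximum(sd, self.sd_floor), 0.0)
        return float(z[self._dmn_cols].mean()), float(z[self._cen_cols].mean())

    def _freeze_baseline(self, b0: np.ndarray, b1: np.ndarray) -> None:
        B = np.stack(self._baseline_buf)  # n_base x n_vox
        tt = np.arange(B.shape[0], dtype=float)[:, None]
        resid = B - (b0[None, :] + b1[None, :] * tt)
        ddof = 2 if B.shape[0] > 2 else 0
        self.baseline_residual_sd = resid.std(axis=0, ddof=ddof)
        self._baseline_buf = []

    def _running_sd(self, b0: np.ndarray, b1: np.ndarray) -> np.ndarray:
        B = np.stack(self._baseline_buf)
        if B.shape[0] < 3:
            return np.zeros(b0.shape)
        tt = np.arange(B.shape[0], dtype=float)[:, None]
        resid = B - (b0[None, :] + b1[None, :] * tt)
        return resid.std(axis=0, ddof=2)


def init_engine(dmn_mask, cen_mask, n_baseline_vols: int | None = None,
                tr: float = 1.2) -> NeurofeedbackEngine:
    """Functional alias for constructing a :class:`NeurofeedbackEngine`."""
    return NeurofeedbackEngine(dmn_mask, cen_mask, n_baseline_vols=n_baseline_vols, tr=tr)


def compute_pda(cen_estimate: float, dmn_estimate: float) -> float:
    """Positive diametric activity: CEN minus DMN activation estimate.

    Positive values indicate the target state (DMN below CEN) and move the
    feedback dot upward; negative values move it downward.
    """
    if not (np.isfinite(cen_estimate) and np.isfinite(dmn_estimate)):
        raise ValueError("non-finite activation estimate")
    return float(cen_estimate - dmn_estimate)


# ---------------------------------------------------------------------------
# adaptive display staircase


@dataclass
class FeedbackState:
    """The visual staircase: dot ordinate, circle radii, counters, event log.

    The dot ordinate is expressed in circle-center units: the upper circle
    center sits at +1, the lower at -1, and one unit equals half the
    pixel distance between the circle centers (472 px / 2 = 236 px).
    Circle radii are derived from the shrink counts so that after k shrinks
    the radius is exactly ``initial * factor**k``.
    """

    dot_y: float = 0.0
    dot_radius_px: float = 12.0
    initial_circle_radius_px: float = 56.0
    center_distance_px: float = 472.0
    shrink_factor: float = 0.9
    shrink_trigger_trs: int = 5
    max_shrinks: int = 5
    accum_counter: dict = field(default_factory=lambda: {"upper": 0, "lower": 0})
    shrink_count: dict = field(default_factory=lambda: {"upper": 0, "lower": 0})
    event_log: list = field(default_factory=list)

    @property
    def circle_radius_px(self) -> dict:
        return {
            side: self.initial_circle_radius_px * self.shrink_factor ** self.shrink_count[side]
            for side in ("upper", "lower")
        }

    @property
    def unit_px(self) -> float:
        return self.center_distance_px / 2.0

    def circle_radius_units(self, side: str) -> float:
        return self.circle_radius_px[side] / self.unit_px


def step_display(state: FeedbackState, pda: float, gain: float = 0.1,
                 tr_index: int | None = None) -> FeedbackState:
    """Advance the staircase by one TR (mutates and returns ``state``).

    The PDA (baseline-SD units) scaled by the display gain is added to the
    dot ordinate.  The dot qualifies for a circle when its center has
    reached the circle's near edge (|dot_y| >= 1 - radius in units; the
    dot's own radius is ignored).  Each qualifying TR increments that
    circle's counter; at ``shrink_trigger_trs`` accumulated TRs the circle
    shrinks by the shrink factor, the dot recenters, and the counter resets
    — unless the circle has already shrunk ``max_shrinks`` times, in which
    case nothing changes.
    """
    state.dot_y += pda * gain
    upper_edge = 1.0 - state.circle_radius_units("upper")
    lower_edge = -(1.0 - state.circle_radius_units("lower"))
    side = None
    if state.dot_y >= upper_edge:
        side = "upper"
    elif state.dot_y <= lower_edge:
        side = "lower"
    if side is not None:
        state.accum_counter[side] += 1
        if state.accum_counter[side] >= state.shrink_trigger_trs:
            if state.shrink_count[side] < state.max_shrinks:
                state.shrink_count[side] += 1
                state.dot_y = 0.0
                state.accum_counter[side] = 0
                state.event_log.append((tr_index, f"shrink_{side}"))
            else:
                state.accum_counter[side] = 0  # cap reached: no change
    return state


# ---------------------------------------------------------------------------
# full run


@dataclass
class RunResult:
    """Per-TR traces and summary of one feedback run."""

    dmn_estimate: np.ndarray
    cen_estimate: np.ndarray
    pda: np.ndarray
    dot_y: np.ndarray
    is_baseline: np.ndarray
    state: FeedbackState
    time_in_target: float
    n_feedback_trs: int

    @property
    def shrink_events(self) -> list:
        return list(self.state.event_log)

    def to_frame(self) -> pd.DataFrame:
        events = {tr: ev for tr, ev in self.state.event_log}
        return pd.DataFrame(
            {
                "tr": np.arange(self.pda.size),
                "is_baseline": self.is_baseline.astype(int),
                "dmn": self.dmn_estimate,
                "cen": self.cen_estimate,
                "pda": self.pda,
                "dot_y": self.dot_y,
                "event": [events.get(t, "") for t in range(self.pda.size)],
            }
        )

    def summary(self) -> dict:
        return {
            "n_trs": int(self.pda.size),
            "n_feedback_trs": int(self.n_feedback_trs),
            "time_in_target": float(self.time_in_target),
            "shrinks_upper": int(self.state.shrink_count["upper"]),
            "shrinks_lower": int(self.state.shrink_count["lower"]),
            "final_radius_upper_px": float(self.state.circle_radius_px["upper"]),
            "final_radius_lower_px": float(self.state.circle_radius_px["lower"]),
        }


def run_feedback_run(
    engine: NeurofeedbackEngine,
    series: VolumeSeries,
    *,
    gain: float = 0.1,
    lag_trs: int = 0,
    state: FeedbackState | None = None,
) -> RunResult:
    """Stream a run through the engine, PDA, and display staircase.

    ``lag_trs`` delays the display update relative to volume arrival by an
    integer number of TRs (default 0).  Time-in-target is the fraction of
    feedback (post-baseline) TRs with PDA > 0 and does not depend on the
    display gain or lag.
    """
    T = series.n_vols
    nb = engine.n_baseline_vols
    if T < nb + 1:
        raise ValueError(f"series has {T} volumes; need more than baseline {nb}")
    if state is None:
        state = FeedbackState()
    dmn = np.zeros(T)
    cen = np.zeros(T)
    pda = np.zeros(T)
    dot = np.zeros(T)
    base = np.zeros(T, dtype=bool)
    for t in range(T):
        was_baseline = engine.in_baseline
        d, c = engine.update(series.data[..., t])
        dmn[t], cen[t] = d, c
        base[t] = was_baseline
        if not was_baseline:
            pda[t] = compute_pda(c, d)
            t_disp = t - lag_trs
            shown = pda[t_disp] if (lag_trs == 0 or (t_disp >= 0 and not base[t_disp])) else 0.0
            step_display(state, shown, gain=gain, tr_index=t)
        dot[t] = state.dot_y
    fb = ~base
    n_fb = int(fb.sum())
    tit = float((pda[fb] > 0).mean()) if n_fb else 0.0
    return RunResult(
        dmn_estimate=dmn,
        cen_estimate=cen,
        pda=pda,
        dot_y=dot,
        is_baseline=base,
        state=state,
        time_in_target=tit,
        n_feedback_trs=n_fb,
    )


def group_target_test(fractions) -> TTestResult:
    """One-tailed one-sample t of time-in-target fractions against 0.5 chance."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size < 2:
        raise ValueError("need at least 2 subjects")
    return one_sample_t(fractions, null_value=0.5, alternative="greater")
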