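"""End-to-end synthetic session: localize -> feedback -> connectivity -> stats.

Mirrors the study session order — a resting localizer personalizes the
DMN/CEN masks, five feedback runs stream through the closed-loop engine, and
pre/post resting runs are denoised and compared for seed-connectivity change
— all on synthetic subjects with planted ground truth, then the behavioral
mediation is fit on a synthetic cohort.  Every artifact is reproducible
bit-for-bit under the session seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import connectivity as conn
from . import localizer as loc
from . import realtime as rt
from . import stats as st
from . import synth
from .config import ParadigmConfig, SeedSpec
from .images import save_mask
from .tables import write_cluster_tsv, write_motion_tsv

logger = logging.getLogger(__name__)

# Synthetic study conditions: toy grid, 2-mm voxels, planted network
# correlations stable across sessions with a uniform post-feedback reduction.
GRID = (20, 20, 10)
VOXEL_MM = 2.0
WITHIN_R_BASE = 0.55
WITHIN_R_SPREAD = 0.15
POST_REDUCTION = 0.30
BETWEEN_R = -0.1


@dataclass
class SubjectResult:
    subject: int
    dmn_mask: loc.NetworkMask
    cen_mask: loc.NetworkMask
    dice_dmn: float
    dice_cen: float
    run_results: list[rt.RunResult]
    time_in_target_mean: float
    time_in_target_last: float
    pre_map: conn.ConnectivityMap
    post_map: conn.ConnectivityMap
    mean_fd: float
    within_dmn_z_session1: float
    within_dmn_z_session2: float


def _split_rois(support: np.ndarray) -> list[np.ndarray]:
    """Split a network support into two ROIs along its widest axis."""
    idx = np.argwhere(support)
    axis = int(np.argmax(idx.max(axis=0) - idx.min(axis=0)))
    median = np.median(idx[:, axis])
    lo = np.zeros_like(support)
    hi = np.zeros_like(support)
    for v in idx:
        (lo if v[axis] <= median else hi)[tuple(v)] = True
    if not hi.any():  # degenerate split: fall back to halves of the list
        half = len(idx) // 2
        lo[:] = False
        for v in idx[:half]:
            lo[tuple(v)] = True
        for v in idx[half:]:
            hi[tuple(v)] = True
    return [lo, hi]


def simulate_subject(config: ParadigmConfig, seed: int, subject: int) -> SubjectResult:
    """Run the whole imaging chain for one synthetic subject."""
    ss = np.random.SeedSequence([seed, subject])
    seeds = ss.generate_state(12).tolist()
    rng = np.random.default_rng(seeds[0])

    maps = synth.make_network_maps(GRID, 2, 3, seed=seeds[1])
    dmn_truth, cen_truth = maps[0], maps[1]
    affine = np.diag([VOXEL_MM, VOXEL_MM, VOXEL_MM, 1.0])

    within_r = WITHIN_R_BASE + WITHIN_R_SPREAD * (rng.random() - 0.5)
    post_r = max(0.05, within_r - POST_REDUCTION)

    # Session-1 localizer rest run
    loc_series, _ = synth.simulate_run(
        maps, within_network_r=within_r, between_network_r=BETWEEN_R,
        noise_sd=1.0, n_vols=config.n_rest_vols, tr=config.tr,
        affine=affine, seed=seeds[2],
    )
    n_comp = min(config.n_components, max(5, config.n_rest_vols // 10))
    masks = loc.localize_networks(
        loc_series, {"DMN": dmn_truth, "CEN": cen_truth},
        n_components=n_comp, top_fraction=config.top_fraction, seed=seeds[3],
    )
    n_in = int(np.prod(GRID))
    k = int(np.ceil(config.top_fraction * n_in))
    truth_masks = {}
    for label, tm in (("DMN", dmn_truth), ("CEN", cen_truth)):
        truth_masks[label] = loc.threshold_and_binarize(tm, top_fraction=config.top_fraction).binary_field
    dice_dmn = loc.dice(masks["DMN"].binary_field, truth_masks["DMN"])
    dice_cen = loc.dice(masks["CEN"].binary_field, truth_masks["CEN"])

    # Five feedback runs; subject skill varies through the burst amplitude
    skill = 1.0 + rng.random()
    run_results = []
    for r in range(config.n_runs):
        tcs = synth.mind_wandering_timecourses(
            config.n_run_vols, config.n_baseline_vols,
            burst_amp=2.0 * skill, seed=seeds[4] + r,
        )
        fb_series, _ = synth.simulate_run(
            maps, timecourses=tcs, noise_sd=1.0,
            n_vols=config.n_run_vols, tr=config.tr, affine=affine,
            seed=seeds[5] + r,
        )
        engine = rt.NeurofeedbackEngine(
            masks["DMN"], masks["CEN"],
            n_baseline_vols=config.n_baseline_vols, tr=config.tr,
        )
        run_results.append(
            rt.run_feedback_run(engine, fb_series, gain=config.display_gain,
                                lag_trs=config.feedback_lag_trs)
        )
    tit = [r.time_in_target for r in run_results]

    # Pre/post rest runs with planted connectivity reduction
    pre_series, _ = synth.simulate_run(
        maps, within_network_r=within_r, between_network_r=BETWEEN_R,
        noise_sd=1.0, n_vols=config.n_rest_vols, tr=config.tr,
        affine=affine, seed=seeds[6],
    )
    post_series, _ = synth.simulate_run(
        maps, within_network_r=post_r, between_network_r=BETWEEN_R,
        noise_sd=1.0, n_vols=config.n_rest_vols, tr=config.tr,
        affine=affine, seed=seeds[7],
    )
    motion, _ = synth.simulate_motion(config.n_rest_vols, spike_prob=0.01,
                                      spike_scale=1.5, seed=seeds[8])
    fd = conn.framewise_displacement(motion, config.head_radius_mm)

    def _denoise(series, mseed):
        flags, gz = conn.flag_outliers(series, fd, config.gs_z_thresh, config.fd_thresh_mm)
        cs = conn.ConfoundSet(motion_params=motion, fd=fd, global_signal_z=gz,
                              outlier_flags=flags)
        return conn.denoise(series, cs, band=config.band_hz, tr=config.tr)

    pre_dn = _denoise(pre_series, seeds[9])
    post_dn = _denoise(post_series, seeds[10])

    # Seed sphere centered on the planted DMN's center of mass (world mm)
    com_vox = np.array(np.nonzero(truth_masks["DMN"])).mean(axis=1)
    com_world = (affine @ np.array([*com_vox, 1.0]))[:3]
    seed_spec = SeedSpec("sgACC", tuple(float(v) for v in com_world), 8.0)
    seed_vox = conn.make_sphere_seed(seed_spec, affine, GRID)
    pre_map = conn.seed_connectivity(pre_dn, seed_vox)
    post_map = conn.seed_connectivity(post_dn, seed_vox)

    rois = _split_rois(synth.top_fraction_mask(dmn_truth, 0.5))
    loc_dn = _denoise(loc_series, seeds[11])
    z_s1 = conn.within_network_connectivity(loc_dn, rois)
    z_s2 = conn.within_network_connectivity(pre_dn, rois)

    return SubjectResult(
        subject=subject,
        dmn_mask=masks["DMN"],
        cen_mask=masks["CEN"],
        dice_dmn=dice_dmn,
        dice_cen=dice_cen,
        run_results=run_results,
        time_in_target_mean=float(np.mean(tit)),
        time_in_target_last=float(tit[-1]),
        pre_map=pre_map,
        post_map=post_map,
        mean_fd=float(fd.mean()),
        within_dmn_z_session1=z_s1,
        within_dmn_z_session2=z_s2,
    )


def run_session(config: ParadigmConfig, seed: int, outdir: str | Path) -> dict:
    """Full synthetic study: cohort imaging, group maps, behavior, report.

    Writes masks, per-run feedback traces, motion tables, cluster tables, a
    JSON summary, and a markdown report under ``outdir``; returns the
    summary dict.  The same (config, seed) reproduces every artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.save(outdir / "config.yaml")

    subjects = [simulate_subject(config, seed, s) for s in range(config.n_subjects)]

    # --- group feedback performance
    tit_mean = [s.time_in_target_mean for s in subjects]
    target_test = rt.group_target_test(tit_mean)

    # --- group connectivity change within the union DMN search region
    affine = np.diag([VOXEL_MM, VOXEL_MM, VOXEL_MM, 1.0])
    region = np.zeros(GRID, dtype=bool)
    for s in subjects:
        region |= s.dmn_mask.binary_field
    change = conn.prepost_change(
        [s.pre_map for s in subjects],
        [s.post_map for s in subjects],
        region,
        covariate=[s.mean_fd for s in subjects],
        q=config.fdr_q,
        affine=affine,
    )
    delta_region = [
        float((s.post_map.fisher_z_field - s.pre_map.fisher_z_field)[region].mean())
        for s in subjects
    ]

    # --- reliability across sessions
    icc = st.icc_absolute_agreement(
        [s.within_dmn_z_session1 for s in subjects],
        [s.within_dmn_z_session2 for s in subjects],
    )

    # --- behavioral cohort and mediation
    cohort = synth.simulate_behavior_cohort(n_subjects=config.n_subjects,
                                            seed=int(np.random.SeedSequence([seed, 999]).generate_state(1)[0] % (2**31)))
    med = st.mediate(cohort.x, cohort.m, cohort.y)

    summary = {
        "seed": seed,
        "config_hash": config.config_hash(),
        "n_subjects": config.n_subjects,
        "localizer": {
            "dice_dmn": [round(s.dice_dmn, 6) for s in subjects],
            "dice_cen": [round(s.dice_cen, 6) for s in subjects],
            "mask_voxels_dmn": [s.dmn_mask.voxel_count for s in subjects],
            "mask_voxels_cen": [s.cen_mask.voxel_count for s in subjects],
        },
        "feedback": {
            "time_in_target_mean": [round(v, 6) for v in tit_mean],
            "time_in_target_last_run": [round(s.time_in_target_last, 6) for s in subjects],
            "group_vs_chance_t": round(target_test.t, 6),
            "group_vs_chance_p_one_tailed": round(target_test.p, 6),
            "n_runs": config.n_runs,
        },
        "connectivity": {
            "mean_region_delta_z": [round(v, 6) for v in delta_region],
            "group_mean_delta_z": round(float(np.mean(delta_region)), 6),
            "n_fdr_surviving_voxels": int(change.surviving.sum()),
            "n_clusters": len(change.clusters),
            "icc_within_dmn": round(icc.icc, 6) if np.isfinite(icc.icc) else None,
            "icc_p": round(icc.p, 6) if np.isfinite(icc.p) else None,
        },
        "mediation": {
            "beta_a": round(med.path_a.beta, 6),
            "beta_b": round(med.path_b.beta, 6),
            "beta_c": round(med.path_c.beta, 6),
            "beta_c_prime": round(med.path_c_prime.beta, 6),
            "sobel_z": round(med.sobel_z, 6),
            "sobel_p": round(med.sobel_p, 6),
        },
    }

    # --- artifacts
    for s in subjects:
        sdir = outdir / f"sub-{s.subject + 1:02d}"
        sdir.mkdir(exist_ok=True)
        save_mask(s.dmn_mask.binary_field, affine, sdir / "dmn_mask.nii.gz")
        save_mask(s.cen_mask.binary_field, affine, sdir / "cen_mask.nii.gz")
        for i, rr in enumerate(s.run_results):
            rr.to_frame().to_csv(sdir / f"feedback_run-{i + 1}.tsv", sep="\t", index=False)
    write_cluster_tsv(change.clusters, outdir / "prepost_clusters.tsv")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (outdir / "report.md").write_text(_report_md(summary))
    return summary


def _report_md(s: dict) -> str:
    fb = s["feedback"]
    cn = s["connectivity"]
    md = s["mediation"]
    lines = [
        "# Synthetic neurofeedback session report",
        "",
        f"Seed {s['seed']}, {s['n_subjects']} synthetic subjects, config {s['config_hash']}.",
        "",
        "## Feedback performance",
        f"- mean time-in-target per subject: {fb['time_in_target_mean']}",
        f"- group one-tailed t vs 50% chance: t = {fb['group_vs_chance_t']}, "
        f"p = {fb['group_vs_chance_p_one_tailed']}",
        "",
        "## Connectivity change (pre vs post)",
        f"- group mean Fisher-z change in the DMN region: {cn['group_mean_delta_z']}",
        f"- FDR-surviving voxels: {cn['n_fdr_surviving_voxels']} in {cn['n_clusters']} cluster(s)",
        f"- within-DMN connectivity ICC across sessions: {cn['icc_within_dmn']}"
        f" (p = {cn['icc_p']})",
        "",
        "## Mediation (performance -> connectivity change -> mindfulness change)",
        f"- standardized paths: a = {md['beta_a']}, b = {md['beta_b']}, "
        f"c = {md['beta_c']}, c' = {md['beta_c_prime']}",
        f"- Sobel z = {md['sobel_z']}, p = {md['sobel_p']}",
        "",
    ]
    return "\n".join(lines)
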