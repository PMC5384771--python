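"""End-to-end simulated experiments: FRAP, distribution scoring, inference.

Each cohort function runs the full loop the analyses assume — generate a
nucleus, perturb it (bleach / break assignment / enrichment), render it
to voxels, and quantify the render with the measurement operators — and
returns tidy per-nucleus tables. ``run_pipeline`` chains them and writes
the report.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import distribution as dist
from . import frap as frapq
from . import stats as infer
from .config import RunConfig, config_hash, scenario_genotype
from .geometry import CircularSegmentROI, EllipseROI, RectangleROI, corner_background_rois
from .kinetics import (
    BleachSpec,
    KineticParams,
    bleach,
    state_from_nucleus,
)
from .render import ImagingParams, geometry_for_radius, render_series, render_state
from .kinetics import simulate_recovery
from .synthetic import (
    GonadLayout,
    GonadSpec,
    GenotypeParams,
    apply_enrichment,
    assign_breaks,
    build_layout,
    nucleus_rng,
    occupancy_from_counts,
    simulate_break_counts,
)

log = logging.getLogger(__name__)

__all__ = [
    "default_time_grid",
    "simulate_frap_nucleus",
    "simulate_frap_cohort",
    "simulate_strong_recovery_cohort",
    "simulate_distribution_cohort",
    "simulate_enriched_count_cohort",
    "build_report",
    "run_pipeline",
]


def default_time_grid(pre_min: float = -2.5, t_max: float = 30.0, dt: float = 2.5):
    """Sampling grid: one pre-bleach point, bleach at 0, then 2.5-min spacing."""
    post = np.arange(0.0, t_max + 1e-9, dt)
    return pre_min, post


def _bleach_roi_for_fraction(
    state, geom, target_fraction: float
) -> Tuple[RectangleROI, float]:
    """Rectangle covering the left part of the volume so that the bleached
    share of nuclear content is close to ``target_fraction``."""
    order = np.argsort(state.points[:, 0])
    cum = np.cumsum(state.B[order])
    x_cut = state.points[order][np.searchsorted(cum, target_fraction * cum[-1])][0]
    nz, ny, nx = geom.shape
    px_cut = int(np.ceil((x_cut - geom.origin_um[0]) / geom.voxel_xy_um))
    px_cut = int(np.clip(px_cut, 2, nx - 2))
    return RectangleROI(x0=0, x1=px_cut, y0=0, y1=ny), float(x_cut)


def _measurement_rois(geom, radius_um: float, x_cut_um: float, margin_um: float = 0.5):
    nz, ny, nx = geom.shape
    vxy = geom.voxel_xy_um
    cx = (0.0 - geom.origin_um[0]) / vxy
    cy = (0.0 - geom.origin_um[1]) / vxy
    r_px = (radius_um + 0.6) / vxy
    x_inset_px = (x_cut_um - margin_um - geom.origin_um[0]) / vxy
    roi_bleach = CircularSegmentROI(
        cx=cx, cy=cy, radius=r_px, nx_=-1.0, ny_=0.0, offset=cx - x_inset_px
    )
    roi_nucleus = EllipseROI(cx=cx, cy=cy, rx=r_px, ry=r_px)
    return roi_bleach, roi_nucleus


def simulate_frap_nucleus(
    nucleus,
    imaging: ImagingParams,
    rng: np.random.Generator,
    survival_s: float = 0.25,
    bleach_fraction: Optional[float] = None,
    analysis: frapq.AnalysisConfig = frapq.AnalysisConfig(),
) -> Dict:
    """One full z-stack-bleach FRAP experiment on one nucleus.

    Renders a pre-bleach frame and a 0–30 min post-bleach series, then
    quantifies extent of recovery, plateau, and the exponential fit with
    closed-form mobile-fraction inversion. Returns a record with measured
    and ground-truth quantities.
    """
    if bleach_fraction is None:
        bleach_fraction = float(rng.uniform(0.3, 0.5))
    state = state_from_nucleus(nucleus)
    geom = geometry_for_radius(nucleus.radius_um, imaging)
    roi, x_cut = _bleach_roi_for_fraction(state, geom, bleach_fraction)
    spec = BleachSpec(roi=roi, mode="zstack", survival_s=survival_s, time_min=0.0)
    bleached = bleach(state, spec, geom)
    a = float((state.total - bleached.total) / (state.total * (1.0 - survival_s)))

    kin = KineticParams(
        mobile_fraction_f=nucleus.mobile_fraction_f,
        exchange_rate_k=nucleus.exchange_rate_k,
    )
    pre_min, post = default_time_grid()
    pre_state = state.copy()
    pre_state.time_min = pre_min
    states = [pre_state] + simulate_recovery(bleached, kin, post)
    series = render_series(
        states, imaging, geom, rng if imaging.noise != "none" else None
    )
    roi_b, roi_n = _measurement_rois(geom, nucleus.radius_um, x_cut)
    bg_rois = corner_background_rois(geom.shape[1:], size=6)
    curve = frapq.extent_of_recovery(
        series, roi_b, roi_n, pre_index=0, background_rois=bg_rois,
        nucleus_id=nucleus.nucleus_id,
    )
    curve.stage, curve.x = nucleus.stage, nucleus.x
    curve.plateau = frapq.plateau(curve, analysis)
    fit = frapq.fit_recovery(curve, bleach_fraction_a=a, survival_s=survival_s)
    return dict(
        nucleus_id=nucleus.nucleus_id, stage=nucleus.stage, x=nucleus.x,
        a=a, s=survival_s, f_true=nucleus.mobile_fraction_f,
        k_true=nucleus.exchange_rate_k, plateau=curve.plateau,
        E0_hat=fit.E0, Einf_hat=fit.E_inf, k_hat=fit.k_hat, f_hat=fit.f_hat,
        fit_clipped=fit.clipped, curve=curve,
    )


def _layout_for_cohort(
    genotype: GenotypeParams,
    spec: GonadSpec,
    n_per_stage: int,
    seed: int,
    stages: Optional[Sequence[str]] = None,
) -> GonadLayout:
    per_stage_rows = max(1, spec.n_rows // 3)
    need_per_row = int(np.ceil(n_per_stage / per_stage_rows))
    spec = dataclasses.replace(
        spec, nuclei_per_row=max(spec.nuclei_per_row, need_per_row), seed=seed
    )
    return build_layout(spec, genotype, seed, stages=stages)


def simulate_frap_cohort(
    scenario: str | GenotypeParams,
    stages: Sequence[str] = ("early", "late"),
    n_per_stage: int = 20,
    seed: int = 1,
    noise: bool = True,
    imaging: Optional[ImagingParams] = None,
    spec: Optional[GonadSpec] = None,
    survival_s: float = 0.25,
) -> pd.DataFrame:
    """FRAP experiments across pachytene stages for one genotype.

    Returns one row per nucleus with plateau, fitted (f, k), ground truth,
    and normalized gonad position.
    """
    genotype = (
        scenario_genotype(scenario) if isinstance(scenario, str) else scenario
    )
    spec = spec or GonadSpec()
    imaging = imaging or ImagingParams(
        noise="poisson_gaussian" if noise else "none"
    )
    layout = _layout_for_cohort(genotype, spec, n_per_stage, seed, stages=stages)
    rows = []
    for stage in stages:
        nuclei = layout.nuclei_in_stage(stage)[:n_per_stage]
        if len(nuclei) < n_per_stage:
            raise ValueError(f"layout provides only {len(nuclei)} {stage} nuclei")
        for nuc in nuclei:
            rng = nucleus_rng(seed * 1000003 + 1, nuc.nucleus_id)
            rec = simulate_frap_nucleus(nuc, imaging, rng, survival_s=survival_s)
            rec.pop("curve")
            rec["genotype"] = genotype.label
            rows.append(rec)
            log.info(
                "frap genotype=%s nucleus=%d stage=%s plateau=%.3f",
                genotype.label, nuc.nucleus_id, stage, rec["plateau"],
            )
    return pd.DataFrame(rows)


def simulate_strong_recovery_cohort(
    scenario: str | GenotypeParams,
    stages: Sequence[str] = ("early", "mid", "late"),
    n_per_stage: int = 12,
    seed: int = 1,
    noise: bool = True,
    imaging: Optional[ImagingParams] = None,
    spec: Optional[GonadSpec] = None,
    tau: float = 0.8,
    survival_s: float = 0.25,
) -> pd.DataFrame:
    """Single-plane small-ROI bleach experiments scored as strong/weak.

    Emulates the widefield protocol: a small (~1.5 × 1.5 µm) region at one
    focal plane is bleached and recovery is scored at 30 min as the
    evening-out of fluorescence between bleached and unbleached SC
    segments.
    """
    genotype = (
        scenario_genotype(scenario) if isinstance(scenario, str) else scenario
    )
    spec = spec or GonadSpec()
    imaging = imaging or ImagingParams(
        noise="poisson_gaussian" if noise else "none"
    )
    layout = _layout_for_cohort(genotype, spec, n_per_stage, seed, stages=stages)
    rows = []
    for stage in stages:
        nuclei = layout.nuclei_in_stage(stage)[:n_per_stage]
        for nuc in nuclei:
            rng = nucleus_rng(seed * 1000003 + 2, nuc.nucleus_id)
            state = state_from_nucleus(nuc)
            geom = geometry_for_radius(nuc.radius_um, imaging)
            # bleach a 1.5 µm square at the focal plane of a trace midpoint
            t0 = nuc.traces[0]
            mid = t0.point_at_arclength(t0.length_um / 2.0)
            half_px = int(0.75 / geom.voxel_xy_um)
            iz, iy, ix = geom.index_of(mid[None, :])[0]
            nzs, nys, nxs = geom.shape
            roi = RectangleROI(
                x0=int(np.clip(ix - half_px, 0, nxs - 2)),
                x1=int(np.clip(ix + half_px, 2, nxs)),
                y0=int(np.clip(iy - half_px, 0, nys - 2)),
                y1=int(np.clip(iy + half_px, 2, nys)),
            )
            spec_b = BleachSpec(
                roi=roi, mode="single_plane", survival_s=survival_s,
                focal_plane_z_um=float(mid[2]), depth_sigma_um=0.5,
            )
            bleached = bleach(state, spec_b, geom)
            factor = np.divide(
                bleached.B, state.B, out=np.ones_like(state.B), where=state.B > 0
            )
            kin = KineticParams(nuc.mobile_fraction_f, nuc.exchange_rate_k)
            states = simulate_recovery(bleached, kin, [1e-6, 30.0])
            series = render_series(
                states, imaging, geom, rng if imaging.noise != "none" else None
            )
            from .render import _splat  # voxel masks of segment classes

            bleached_mask = _splat((factor < 0.5).astype(float), state.points, geom) > 0
            unbleached_mask = (
                _splat((factor > 0.95).astype(float), state.points, geom) > 0
            ) & ~bleached_mask
            strong = frapq.strong_recovery_call(
                series, bleached_mask, unbleached_mask, t_eval_min=30.0, tau=tau
            )
            rows.append(
                dict(
                    nucleus_id=nuc.nucleus_id, genotype=genotype.label,
                    stage=stage, x=nuc.x, f_true=nuc.mobile_fraction_f,
                    strong=bool(strong),
                )
            )
    return pd.DataFrame(rows)


def simulate_distribution_cohort(
    scenario: str | GenotypeParams,
    n_nuclei: int = 20,
    seed: int = 1,
    noise: bool = True,
    imaging: Optional[ImagingParams] = None,
    spec: Optional[GonadSpec] = None,
    theta: float = 1.5,
) -> pd.DataFrame:
    """Rendered late-pachytene nuclei scored for evenness and foci.

    For each nucleus: assign breaks, apply enrichment, render both the
    central-region and focus channels with noise, measure per-trace
    intensities through ground-truth masks, classify evenness, detect and
    assign foci. One row per nucleus, including truth columns.
    """
    genotype = (
        scenario_genotype(scenario) if isinstance(scenario, str) else scenario
    )
    spec = spec or GonadSpec()
    imaging = imaging or ImagingParams(
        noise="poisson_gaussian" if noise else "none"
    )
    layout = _layout_for_cohort(genotype, spec, n_nuclei, seed, stages=("late",))
    break_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(999,))
    )
    assign_breaks(layout, break_rng)
    apply_enrichment(layout)
    nuclei = layout.nuclei_in_stage("late")[:n_nuclei]
    rows = []
    for nuc in nuclei:
        rng = nucleus_rng(seed * 1000003 + 3, nuc.nucleus_id)
        state = state_from_nucleus(nuc)
        geom = geometry_for_radius(nuc.radius_um, imaging)
        frame = render_state(
            state, imaging, geom, rng if imaging.noise != "none" else None,
            channels=("syp", "foci"),
        )
        masks = dist.trace_masks_from_truth(nuc.traces, geom)
        intensities = dist.trace_mean_intensities(
            frame["syp"], masks, background=imaging.background_level
        )
        call = dist.classify_evenness(intensities, theta=theta, nucleus_id=nuc.nucleus_id)
        foci = dist.detect_foci(frame["foci"], geom)
        assigned = dist.assign_foci(foci, nuc.traces)
        focus_traces_detected = sorted(
            {f.trace_id for f in assigned if f.trace_id is not None}
        )
        focus_traces_true = sorted(t.trace_id for t in nuc.traces if t.foci)
        enriched_ids = [
            t.trace_id
            for t, I in zip(nuc.traces, intensities)
            if I > theta * np.median(intensities)
        ]
        single_label = ""
        if call.n_enriched == 1 and len(focus_traces_true) >= 1:
            tid = enriched_ids[0]
            if tid in focus_traces_true:
                single_label = next(
                    t.chromosome_label for t in nuc.traces if t.trace_id == tid
                )
        rows.append(
            dict(
                nucleus_id=nuc.nucleus_id, genotype=genotype.label, x=nuc.x,
                stage=nuc.stage, classification=call.classification,
                evenness_ratio=call.evenness_ratio, n_enriched=call.n_enriched,
                n_foci_true=nuc.n_foci, n_focus_traces_true=len(focus_traces_true),
                n_foci_detected=len(foci),
                detected_on_true_traces=sum(
                    1 for f in assigned if f.trace_id in focus_traces_true
                ),
                enriched_match_focus=sum(
                    1 for tid in enriched_ids if tid in focus_traces_true
                ),
                single_enriched_label=single_label,
            )
        )
        log.info(
            "distribution genotype=%s nucleus=%d foci=%d detected=%d call=%s",
            genotype.label, nuc.nucleus_id, nuc.n_foci, len(foci),
            call.classification,
        )
    return pd.DataFrame(rows)


def simulate_enriched_count_cohort(
    scenario: str | GenotypeParams,
    n_nuclei: int = 2000,
    seed: int = 1,
    n_pairs: int = 6,
) -> np.ndarray:
    """Per-nucleus enriched-chromosome counts at inference scale.

    Samples effective break counts through the same Poisson-thinning rule
    as the geometric generator and converts them to occupancy (distinct
    focus-bearing pairs); used for zero-class estimation where rendering
    thousands of nuclei would add nothing.
    """
    genotype = (
        scenario_genotype(scenario) if isinstance(scenario, str) else scenario
    )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7,)))
    counts = simulate_break_counts(genotype, n_nuclei, rng)
    return occupancy_from_counts(
        counts, n_pairs, rng, max_per_trace=genotype.max_foci_per_trace
    )


def build_report(outputs: Dict[str, object], out_dir, seed: int, cfg_hash: str):
    """Write the figure-level summary tables: JSON plus per-table CSVs.

    ``outputs`` maps table names to DataFrames or JSON-serialisable
    objects. Regeneration from identical inputs is byte-identical.
    """
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: Dict[str, object] = {"seed": seed, "config_hash": cfg_hash}
    for name, obj in sorted(outputs.items()):
        if isinstance(obj, pd.DataFrame):
            df = obj.copy()
            df["seed"] = seed
            df["config_hash"] = cfg_hash
            df.to_csv(out / f"{name}.csv", index=False)
            summary[name] = f"{name}.csv"
        else:
            summary[name] = obj
    (out / "report.json").write_text(
        json.dumps(_round_floats(summary), indent=2, sort_keys=True)
    )
    return out / "report.json"


def _round_floats(obj, sig: int = 6):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def run_pipeline(cfg: RunConfig) -> Path:
    """simulate → quantify → classify → infer → report for one scenario."""
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    genotype = cfg.resolved_genotype()
    chash = config_hash(cfg)
    imaging = cfg.imaging
    noise = imaging.noise != "none"

    frap_df = simulate_frap_cohort(
        genotype, stages=("early", "late"),
        n_per_stage=cfg.cohorts.frap_n_per_stage, seed=cfg.seed, noise=noise,
        imaging=imaging, spec=cfg.gonad, survival_s=cfg.bleach.survival_s,
    )
    early = frap_df[frap_df.stage == "early"].plateau
    late = frap_df[frap_df.stage == "late"].plateau
    rank = infer.rank_sum_test(early, late)
    decline = infer.percent_decline(float(early.median()), float(late.median()))
    trend = infer.position_trend(frap_df.plateau, frap_df.x)

    dist_df = simulate_distribution_cohort(
        genotype, n_nuclei=cfg.cohorts.distribution_n_rendered, seed=cfg.seed,
        noise=noise, imaging=imaging, spec=cfg.gonad,
        theta=1.5,
    )
    uneven_fraction = float((dist_df.classification == "uneven").mean())

    counts = simulate_enriched_count_cohort(
        genotype, n_nuclei=cfg.cohorts.break_cohort_n, seed=cfg.seed,
        n_pairs=cfg.gonad.n_pairs,
    )
    if genotype.designated_co_per_pair:
        break_est = None  # constant counts; zero-class inference not applicable
    else:
        break_est = infer.break_rate_from_zero_class(counts)

    outputs: Dict[str, object] = {
        "frap_plateaus": frap_df,
        "distribution_calls": dist_df,
        "summary_stats": {
            "genotype": genotype.label,
            "plateau_median_early": float(early.median()),
            "plateau_median_late": float(late.median()),
            "percent_decline_early_to_late": decline,
            "rank_sum_p_early_vs_late": rank.p_value,
            "significant_decline": bool(rank.p_value < 0.01 and decline > 0),
            "position_trend_slope": trend.slope,
            "position_trend_r2": trend.r_squared,
            "uneven_fraction_late": uneven_fraction,
            "enriched_count_histogram": {
                str(k): int(v)
                for k, v in zip(*np.unique(counts, return_counts=True))
            },
            **(
                {
                    "lambda_hat": break_est.lambda_hat,
                    "lambda_ci": [break_est.ci_low, break_est.ci_high],
                }
                if break_est is not None
                else {}
            ),
        },
    }
    return build_report(outputs, Path(cfg.out_dir), cfg.seed, chash)
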