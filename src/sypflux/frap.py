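"""FRAP quantification: projections, ROI fluorometry, extent of recovery.

The central statistic is the extent of recovery

    E(t) = [F_bl(t) / F_nuc(t)] / [F_bl(pre) / F_nuc(pre)],

the ratio of background-corrected fluorescence in an ROI confined to the
bleached portion of the nucleus to that of the whole nucleus, normalized
to the same ratio before the bleach. E is 1 before the bleach by
construction, drops on bleaching, and recovers toward a plateau set by
the mobile fraction of the bound protein.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .geometry import GeometryError, ROI
from .render import TimeSeriesStack

__all__ = [
    "AnalysisConfig",
    "RecoveryCurve",
    "KineticFit",
    "sum_projection",
    "roi_measure",
    "extent_of_recovery",
    "plateau",
    "fit_recovery",
    "position_and_stage",
    "strong_recovery_call",
    "reference_normalized_total",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Tunables of the FRAP analysis.

    ``tau_strong`` operationalises the "evening-out of fluorescence"
    strong-recovery call: bleached/unbleached mean-intensity ratio at the
    evaluation time must reach this value. ``plateau_rule`` is either the
    mean of E at t ≥ 25 min or the fitted exponential asymptote.
    """

    tau_strong: float = 0.8
    plateau_rule: str = "mean_after_25min"  # or "fit_asymptote"
    plateau_t_min: float = 25.0
    strong_recovery_t_min: float = 30.0
    stage_boundaries: Tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)

    def validate(self) -> None:
        if not 0 < self.tau_strong <= 1:
            raise ValueError("tau_strong must be in (0, 1]")
        if self.plateau_rule not in ("mean_after_25min", "fit_asymptote"):
            raise ValueError(f"unknown plateau rule '{self.plateau_rule}'")


@dataclasses.dataclass
class RecoveryCurve:
    """Per-nucleus extent-of-recovery series."""

    nucleus_id: int
    times_min: np.ndarray
    E: np.ndarray  # extent of recovery, NaN where the measurement failed
    pre_ratio: float
    pre_index: int
    stage: Optional[str] = None
    x: Optional[float] = None
    plateau: Optional[float] = None

    @property
    def post_mask(self) -> np.ndarray:
        m = np.ones(len(self.times_min), dtype=bool)
        m[: self.pre_index + 1] = False
        return m


@dataclasses.dataclass
class KineticFit:
    """Exponential-recovery fit E(t) = E_inf − (E_inf − E0)·e^(−k t)."""

    E0: float
    E_inf: float
    k_hat: float
    f_hat: float
    rss: float
    clipped: bool = False
    converged: bool = True


def sum_projection(
    stack: np.ndarray, z_range: Optional[Tuple[int, int]] = None
) -> np.ndarray:
    """Pixelwise sum over a half-open z range (whole stack by default)."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a 3D ZYX stack")
    if z_range is None:
        z0, z1 = 0, stack.shape[0]
    else:
        z0, z1 = z_range
    if z1 <= z0 or z0 < 0 or z1 > stack.shape[0]:
        raise GeometryError(f"empty or out-of-range z range ({z0}, {z1})")
    return stack[z0:z1].sum(axis=0)


def roi_measure(
    image: np.ndarray,
    roi: ROI,
    background_rois: Sequence[ROI] = (),
) -> Tuple[float, int]:
    """Background-corrected total fluorescence and pixel area of an ROI.

    The background is the mean per-pixel intensity pooled over the
    background ROIs, recomputed for every image (time point), and is
    subtracted as ``area × background`` from the ROI total.
    """
    image = np.asarray(image, dtype=float)
    fp = roi.footprint(image.shape)
    area = int(fp.sum())
    total = float(image[fp].sum())
    if background_rois:
        bg_pixels = []
        for b in background_rois:
            bfp = b.footprint(image.shape)
            if (bfp & fp).any():
                log.warning("background ROI overlaps measurement ROI")
            bg_pixels.append(image[bfp])
        bg = float(np.concatenate(bg_pixels).mean())
        total -= area * bg
    return total, area


def _frame_projection(stack_or_frame: np.ndarray, z_range) -> np.ndarray:
    if stack_or_frame.ndim == 3:
        return sum_projection(stack_or_frame, z_range)
    return np.asarray(stack_or_frame, dtype=float)


def extent_of_recovery(
    series: TimeSeriesStack,
    roi_bleach: ROI,
    roi_nucleus: ROI,
    pre_index: int = 0,
    background_rois: Sequence[ROI] = (),
    channel: str = "syp",
    z_range: Optional[Tuple[int, int]] = None,
    nucleus_id: int = 0,
) -> RecoveryCurve:
    """Extent of recovery for one nucleus from a rendered/acquired series.

    Each frame is sum-projected, both ROIs are measured with background
    correction, and the bleached/whole-nucleus ratio is normalized to its
    pre-bleach value. Time points where the corrected whole-nucleus
    fluorescence is non-positive are flagged as NaN.
    """
    stacks = series.channel(channel)
    times = np.asarray(series.times_min, dtype=float)
    if not 0 <= pre_index < len(stacks):
        raise ValueError("pre_index outside the series")
    ratios = np.full(len(stacks), np.nan)
    for i, stack in enumerate(stacks):
        img = _frame_projection(stack, z_range)
        f_bl, _ = roi_measure(img, roi_bleach, background_rois)
        f_nuc, _ = roi_measure(img, roi_nucleus, background_rois)
        if f_nuc <= 0:
            log.warning("non-positive nucleus fluorescence at t=%s", times[i])
            continue
        ratios[i] = f_bl / f_nuc
    pre_ratio = ratios[pre_index]
    if not np.isfinite(pre_ratio) or pre_ratio <= 0:
        raise ValueError("pre-bleach ratio is not positive; cannot normalize")
    return RecoveryCurve(
        nucleus_id=nucleus_id,
        times_min=times,
        E=ratios / pre_ratio,
        pre_ratio=float(pre_ratio),
        pre_index=pre_index,
    )


def plateau(curve: RecoveryCurve, config: AnalysisConfig = AnalysisConfig()) -> float:
    """Plateau of the recovery curve under the configured rule."""
    config.validate()
    post = curve.post_mask & np.isfinite(curve.E)
    if config.plateau_rule == "mean_after_25min":
        late = post & (curve.times_min >= config.plateau_t_min)
        if not late.any():
            raise ValueError(
                f"no post-bleach points at t >= {config.plateau_t_min} min "
                "(rule mean_after_25min)"
            )
        return float(curve.E[late].mean())
    fit = fit_recovery(curve)
    if not fit.converged:
        raise ValueError("fit_asymptote rule: exponential fit did not converge")
    return float(fit.E_inf)


def _exp_model(t, e_inf, e0, k):
    return e_inf - (e_inf - e0) * np.exp(-k * t)


def fit_recovery(
    curve: RecoveryCurve,
    bleach_fraction_a: Optional[float] = None,
    survival_s: Optional[float] = None,
) -> KineticFit:
    """Least-squares exponential fit of the post-bleach recovery.

    When the bleach geometry ``(a, s)`` is supplied, the mobile fraction
    is recovered by the closed-form inversion
    ``f = (E_inf·T − s)/(T − s)`` with ``T = 1 − a(1 − s)``, clipped to
    [0, 1] with a flag.
    """
    post = curve.post_mask & np.isfinite(curve.E)
    t = curve.times_min[post] - curve.times_min[post][0]
    y = curve.E[post]
    if len(t) < 4:
        raise ValueError("need at least 4 post-bleach points to fit")
    e0_guess = float(y[0])
    einf_guess = float(y[-1])
    k_guess = 0.1
    try:
        popt, _ = optimize.curve_fit(
            _exp_model,
            t,
            y,
            p0=(max(einf_guess, e0_guess + 1e-6), e0_guess, k_guess),
            bounds=([0.0, 0.0, 0.0], [5.0, 5.0, 10.0]),
            maxfev=20000,
        )
        e_inf, e0, k = (float(v) for v in popt)
        converged = True
    except RuntimeError:
        e_inf, e0, k = einf_guess, e0_guess, 0.0
        converged = False
    if abs(e_inf - e0) < 1e-6:  # flat curve: the rate is unidentifiable
        k = 0.0
    rss = float(np.sum((y - _exp_model(t, e_inf, e0, k)) ** 2))
    f_hat, clipped = np.nan, False
    if bleach_fraction_a is not None and survival_s is not None:
        T = 1.0 - bleach_fraction_a * (1.0 - survival_s)
        if T - survival_s > 1e-9:
            f_hat = (e_inf * T - survival_s) / (T - survival_s)
            if f_hat < 0 or f_hat > 1:
                clipped = True
                f_hat = float(np.clip(f_hat, 0.0, 1.0))
        # else: fully bleached nucleus — E is identically 1 and f is
        # unidentifiable from it; absolute recovery must be used instead
    return KineticFit(
        E0=e0, E_inf=e_inf, k_hat=k, f_hat=float(f_hat), rss=rss,
        clipped=clipped, converged=converged,
    )


def position_and_stage(
    row: int, n_rows: int, boundaries: Tuple[float, float] = (1 / 3, 2 / 3)
) -> Tuple[float, str]:
    """Normalized gonad position x = row/n_rows and its pachytene stage."""
    if not 1 <= row <= n_rows:
        raise ValueError(f"row {row} outside 1..{n_rows}")
    x = row / n_rows
    b1, b2 = boundaries
    stage = "early" if x <= b1 else ("mid" if x <= b2 else "late")
    return x, stage


def strong_recovery_call(
    series: TimeSeriesStack,
    bleached_mask: np.ndarray,
    unbleached_mask: np.ndarray,
    t_eval_min: float = 30.0,
    tau: float = 0.8,
    channel: str = "syp",
    background: Optional[float] = None,
) -> bool:
    """Strong-recovery call: has fluorescence evened out between segments?

    True iff the ratio of mean background-corrected intensity over the
    bleached-segment mask to that over the unbleached-segment mask reaches
    ``tau`` at the evaluation time. Background defaults to the imaging
    background level.
    """
    if bleached_mask.sum() == 0 or unbleached_mask.sum() == 0:
        raise ValueError("masks must be nonempty")
    if (bleached_mask & unbleached_mask).any():
        raise ValueError("masks must be disjoint")
    i = series.index_at_time(t_eval_min)
    stack = series.channel(channel)[i]
    bg = series.imaging.background_level if background is None else background
    num = float(stack[bleached_mask].mean() - bg)
    den = float(stack[unbleached_mask].mean() - bg)
    if den <= 0:
        raise ValueError("unbleached-segment mean is not positive")
    return (num / den) >= tau


def reference_normalized_total(
    series: TimeSeriesStack,
    nucleus_roi: ROI,
    reference_nucleus_roi: ROI,
    pre_index: int = 0,
    background_rois: Sequence[ROI] = (),
    channel: str = "syp",
    z_range: Optional[Tuple[int, int]] = None,
) -> np.ndarray:
    """Per-time total of a bleached nucleus relative to an unbleached one.

    Both totals are background-corrected and the ratio is normalized to
    its pre-bleach value; with no import the ratio drops at the bleach and
    then stays constant, the conservation check of the recovery model.
    """
    ratios = np.full(len(series.frames), np.nan)
    for i, frame in enumerate(series.frames):
        img = _frame_projection(frame[channel], z_range)
        f_nuc, _ = roi_measure(img, nucleus_roi, background_rois)
        f_ref, _ = roi_measure(img, reference_nucleus_roi, background_rois)
        if f_ref <= 0:
            continue
        ratios[i] = f_nuc / f_ref
    if not np.isfinite(ratios[pre_index]) or ratios[pre_index] <= 0:
        raise ValueError("pre-bleach reference ratio is not positive")
    return ratios / ratios[pre_index]
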