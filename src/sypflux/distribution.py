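"""Per-chromosome SYP signal: evenness scoring, foci, and the gonad ramp.

A nucleus is scored *uneven* when at least one SC carries a mean
intensity above ``theta`` times the median across its SCs; the number of
such SCs is the enriched count. Recombination foci are detected as 3D
local maxima in the focus-marker channel and assigned to the nearest SC
trace within a capture radius.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from scipy.stats import linregress

from .geometry import VolumeGeometry
from .synthetic import Nucleus, SCTrace

__all__ = [
    "EvennessCall",
    "FocusCall",
    "RampFit",
    "nucleus_mean_intensity",
    "ramp_fit",
    "trace_masks_from_truth",
    "trace_mean_intensities",
    "classify_evenness",
    "window_filter",
    "detect_foci",
    "assign_foci",
    "x_association_tally",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class EvennessCall:
    nucleus_id: int
    intensities: np.ndarray
    evenness_ratio: float  # max / median
    theta: float
    classification: str  # "even" | "uneven"
    n_enriched: int


@dataclasses.dataclass
class FocusCall:
    position_um: np.ndarray
    intensity: float
    trace_id: Optional[int] = None
    distance_um: float = np.inf


@dataclasses.dataclass
class RampFit:
    intercept: float
    slope: float
    fold_change: float
    r_squared: float
    n: int


def nucleus_mean_intensity(
    projection: np.ndarray,
    center_px: Tuple[float, float],
    radius_px: float,
    background: float = 0.0,
) -> Tuple[float, bool]:
    """Mean intensity in the smallest circle enclosing the nucleus.

    Returns ``(total / area − background, clipped)``; ``clipped`` flags a
    circle truncated by the image border, where the mean is unreliable.
    """
    img = np.asarray(projection, dtype=float)
    cy, cx = center_px
    ny, nx = img.shape
    clipped = (
        cx - radius_px < 0 or cy - radius_px < 0
        or cx + radius_px > nx or cy + radius_px > ny
    )
    y, x = np.ogrid[:ny, :nx]
    mask = (x + 0.5 - cx) ** 2 + (y + 0.5 - cy) ** 2 <= radius_px**2
    if not mask.any():
        raise ValueError("enclosing circle contains no pixels")
    return float(img[mask].sum() / mask.sum() - background), clipped


def ramp_fit(means: Sequence[float], positions: Sequence[float]) -> RampFit:
    """OLS of per-nucleus mean intensity against normalized position.

    ``fold_change`` is the fitted value at x = 1 over the fitted value at
    x = 0, the position-profile counterpart of the ~two-fold rise of
    central-region signal across pachytene.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(means, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 nuclei for a ramp fit")
    if x.max() - x.min() < 0.5:
        raise ValueError("positions must span at least half the gonad axis")
    res = linregress(x, y)
    intercept, slope = float(res.intercept), float(res.slope)
    if intercept <= 0:
        raise ValueError("non-positive fitted intercept; fold change undefined")
    return RampFit(
        intercept=intercept,
        slope=slope,
        fold_change=(intercept + slope) / intercept,
        r_squared=float(res.rvalue**2),
        n=len(x),
    )


def trace_masks_from_truth(
    traces: Sequence[SCTrace],
    geom: VolumeGeometry,
    mask_radius_um: float = 0.15,
) -> List[np.ndarray]:
    """Disjoint voxel masks per trace: nearest trace within the mask radius.

    Ground-truth stand-in for manual SC segmentation; voxels closer than
    ``mask_radius_um`` to more than one trace go to the nearest.
    """
    zs, ys, xs = geom.voxel_centers_um()
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    vox = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    best_d = np.full(len(vox), np.inf)
    best_t = np.full(len(vox), -1, dtype=int)
    for i, t in enumerate(traces):
        d = cdist(vox, t.points).min(axis=1)
        closer = d < best_d
        best_d[closer] = d[closer]
        best_t[closer] = i
    masks = []
    for i in range(len(traces)):
        m = (best_t == i) & (best_d <= mask_radius_um)
        masks.append(m.reshape(geom.shape))
    return masks


def trace_mean_intensities(
    stack: np.ndarray,
    masks: Sequence[np.ndarray],
    background: float = 0.0,
) -> np.ndarray:
    """Background-corrected mean voxel intensity per trace mask."""
    out = np.empty(len(masks))
    for i, m in enumerate(masks):
        if m.sum() == 0:
            raise ValueError(f"trace mask {i} is empty")
        out[i] = float(np.asarray(stack, dtype=float)[m].mean() - background)
    return out


def classify_evenness(
    intensities: Sequence[float], theta: float = 1.5, nucleus_id: int = 0
) -> EvennessCall:
    """Even/uneven call from per-trace mean intensities.

    ``theta`` (default 1.5) is the enrichment threshold on the
    per-nucleus median; a nucleus is uneven iff any trace exceeds it.
    The max/median ratio is robust to a single enriched SC among six.
    """
    I = np.asarray(intensities, dtype=float)
    if len(I) < 2:
        raise ValueError("need at least 2 traces")
    if np.any(I < 0):
        raise ValueError("negative corrected intensity")
    med = float(np.median(I))
    r = float(I.max() / med) if med > 0 else np.inf
    n_enriched = int(np.sum(I > theta * med))
    return EvennessCall(
        nucleus_id=nucleus_id,
        intensities=I,
        evenness_ratio=r,
        theta=theta,
        classification="uneven" if n_enriched >= 1 else "even",
        n_enriched=n_enriched,
    )


def window_filter(nuclei: Sequence, window: str) -> list:
    """Keep nuclei in the scored gonad window (half-open thresholds).

    ``second_half`` keeps x > 0.5 (presence/absence scoring window);
    ``last_quarter`` keeps x > 0.75 (enriched-SC counting window).
    """
    thresholds = {"second_half": 0.5, "last_quarter": 0.75}
    if window not in thresholds:
        raise ValueError(f"unknown window '{window}'")
    thr = thresholds[window]
    return [n for n in nuclei if _get_x(n) > thr]


def _get_x(n) -> float:
    return n.x if hasattr(n, "x") else float(n)


def detect_foci(
    stack: np.ndarray,
    geom: VolumeGeometry,
    threshold_sd: float = 5.0,
    min_separation_um: float = 0.4,
    background_stats: Optional[Tuple[float, float]] = None,
    smooth_sigma_um: Tuple[float, float] = (0.1, 0.24),
) -> List[FocusCall]:
    """3D local-maximum focus detection with non-maximum suppression.

    The stack is first smoothed with a small Gaussian (defaults of one
    voxel per axis) to suppress single-voxel shot noise. Voxels must then
    exceed ``background mean + threshold_sd × background sd`` (background
    estimated from a 3-pixel border frame of every slice when not
    supplied, on the smoothed stack) and be the maximum within an
    anisotropic neighbourhood; surviving peaks closer than
    ``min_separation_um`` to a brighter peak are suppressed.
    Deterministic given the stack.
    """
    img = np.asarray(stack, dtype=float)
    sxy, sz = smooth_sigma_um
    if sxy > 0 or sz > 0:
        img = ndimage.gaussian_filter(
            img,
            sigma=(sz / geom.voxel_z_um, sxy / geom.voxel_xy_um, sxy / geom.voxel_xy_um),
        )
    if background_stats is None:
        border = np.zeros(img.shape, dtype=bool)
        border[:, :3, :] = border[:, -3:, :] = True
        border[:, :, :3] = border[:, :, -3:] = True
        bg_mean, bg_sd = float(img[border].mean()), float(img[border].std())
    else:
        bg_mean, bg_sd = background_stats
    if img.max() >= np.finfo(np.float32).max:
        log.warning("stack appears saturated")
    threshold = bg_mean + threshold_sd * max(bg_sd, 1e-12)

    # anisotropic neighbourhood roughly min_separation in each physical axis
    nz = max(1, int(min_separation_um / geom.voxel_z_um))
    nxy = max(1, int(min_separation_um / geom.voxel_xy_um))
    footprint = np.ones((2 * nz + 1, 2 * nxy + 1, 2 * nxy + 1), dtype=bool)
    local_max = (img == ndimage.maximum_filter(img, footprint=footprint)) & (
        img > threshold
    )
    # border voxels are unreliable (smoothing edge effects) and serve as the
    # background reference; exclude them from peak candidacy
    local_max[:1] = local_max[-1:] = False
    local_max[:, :3, :] = local_max[:, -3:, :] = False
    local_max[:, :, :3] = local_max[:, :, -3:] = False
    peaks = np.argwhere(local_max)
    if len(peaks) == 0:
        return []
    values = img[peaks[:, 0], peaks[:, 1], peaks[:, 2]]
    order = np.argsort(values)[::-1]
    peaks, values = peaks[order], values[order]
    # voxel centre positions in µm (xyz)
    ox, oy, oz = geom.origin_um
    pos = np.stack(
        [
            ox + (peaks[:, 2] + 0.5) * geom.voxel_xy_um,
            oy + (peaks[:, 1] + 0.5) * geom.voxel_xy_um,
            oz + (peaks[:, 0] + 0.5) * geom.voxel_z_um,
        ],
        axis=1,
    )
    kept: List[FocusCall] = []
    for p, v in zip(pos, values):
        if all(np.linalg.norm(p - k.position_um) >= min_separation_um for k in kept):
            kept.append(FocusCall(position_um=p, intensity=float(v)))
    return kept


def assign_foci(
    foci: Sequence[FocusCall],
    traces: Sequence[SCTrace],
    d_max_um: float = 0.3,
) -> List[FocusCall]:
    """Assign each focus to the nearest trace within ``d_max_um``.

    Ties (equal distances) break toward the lower trace id; foci farther
    than the capture radius from every trace stay unassigned.
    """
    out = []
    for f in foci:
        best_d, best_id = np.inf, None
        for t in sorted(traces, key=lambda t: t.trace_id):
            d = float(cdist(f.position_um[None, :], t.points).min())
            if d < best_d:
                best_d, best_id = d, t.trace_id
        if best_d <= d_max_um:
            out.append(
                FocusCall(
                    position_um=f.position_um,
                    intensity=f.intensity,
                    trace_id=best_id,
                    distance_um=best_d,
                )
            )
        else:
            out.append(
                FocusCall(position_um=f.position_um, intensity=f.intensity)
            )
    return out


def x_association_tally(enriched_trace_labels: Sequence[str]) -> Tuple[int, int]:
    """Tally X-chromosome association among single-focus enriched nuclei.

    Input: per qualifying nucleus (exactly one focus-bearing enriched SC),
    the chromosome label of that SC. Returns ``(k_X, n)``.
    """
    labels = list(enriched_trace_labels)
    return sum(1 for l in labels if l == "X"), len(labels)
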