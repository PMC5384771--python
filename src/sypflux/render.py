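"""Rendering of nuclei into 3D fluorescence image stacks.

Trace segments are splatted into the voxel grid by arc-length density,
blurred with an anisotropic Gaussian point-spread function, offset by a
constant background, and optionally corrupted with Poisson shot noise
plus Gaussian read noise. Noise-free rendering is linear in the
underlying densities.

The recombination-focus marker is rendered as a separate channel
("foci"), mimicking a second fluorophore imaged alongside the SC
central-region channel ("syp").
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .geometry import VolumeGeometry
from .kinetics import NucleusState

__all__ = [
    "ImagingParams",
    "TimeSeriesStack",
    "ResourceError",
    "geometry_for_radius",
    "render_state",
    "render_series",
]


class ResourceError(RuntimeError):
    """Requested volume exceeds the configured voxel budget."""


@dataclasses.dataclass(frozen=True)
class ImagingParams:
    """Acquisition calibration and noise model.

    Defaults mirror a high-NA widefield/confocal setup: 0.1 µm lateral
    pixels, 0.24 µm z steps, PSF sigmas 0.15 µm lateral / 0.4 µm axial.
    ``focus_intensity`` is the integrated brightness of one rendered
    recombination focus in the focus channel.
    """

    voxel_xy_um: float = 0.1
    voxel_z_um: float = 0.24
    psf_sigma_xy_um: float = 0.15
    psf_sigma_z_um: float = 0.4
    background_level: float = 10.0
    noise: str = "none"  # "none" | "poisson_gaussian"
    read_noise_sd: float = 2.0
    focus_intensity: float = 5000.0
    pad_um: float = 0.75
    max_voxels: int = 50_000_000

    def validate(self) -> None:
        for name in ("voxel_xy_um", "voxel_z_um", "psf_sigma_xy_um", "psf_sigma_z_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.noise not in ("none", "poisson_gaussian"):
            raise ValueError(f"unknown noise model '{self.noise}'")


@dataclasses.dataclass
class TimeSeriesStack:
    """Timestamped 3D stacks sharing one calibration.

    ``frames[i]`` maps channel label → float64 ZYX array at ``times_min[i]``.
    """

    times_min: List[float]
    frames: List[Dict[str, np.ndarray]]
    imaging: ImagingParams
    geometry: VolumeGeometry
    channels: Tuple[str, ...] = ("syp",)

    def __post_init__(self) -> None:
        if len(self.times_min) != len(self.frames):
            raise ValueError("times and frames must align")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        shapes = {f[c].shape for f in self.frames for c in f}
        if len(shapes) > 1:
            raise ValueError("all stacks must share one shape")

    def channel(self, label: str) -> List[np.ndarray]:
        return [f[label] for f in self.frames]

    def index_at_time(self, t_min: float) -> int:
        return int(np.argmin(np.abs(np.asarray(self.times_min) - t_min)))


def geometry_for_radius(radius_um: float, imaging: ImagingParams) -> VolumeGeometry:
    """Voxel grid for a single nucleus centred at the origin, with padding."""
    imaging.validate()
    half = radius_um + imaging.pad_um
    nx = int(np.ceil(2 * half / imaging.voxel_xy_um))
    nz = int(np.ceil(2 * half / imaging.voxel_z_um))
    geom = VolumeGeometry(
        origin_um=(-half, -half, -half),
        voxel_xy_um=imaging.voxel_xy_um,
        voxel_z_um=imaging.voxel_z_um,
        shape=(nz, nx, nx),
    )
    if geom.n_voxels > imaging.max_voxels:
        raise ResourceError(
            f"volume of {geom.n_voxels} voxels exceeds budget {imaging.max_voxels}"
        )
    return geom


def _splat(
    values: np.ndarray, points: np.ndarray, geom: VolumeGeometry
) -> np.ndarray:
    vol = np.zeros(geom.shape, dtype=float)
    idx = geom.index_of(points)
    inside = geom.contains_index(idx)
    idx = idx[inside]
    np.add.at(vol, (idx[:, 0], idx[:, 1], idx[:, 2]), np.asarray(values)[inside])
    return vol


def _blur(vol: np.ndarray, imaging: ImagingParams) -> np.ndarray:
    sig = (
        imaging.psf_sigma_z_um / imaging.voxel_z_um,
        imaging.psf_sigma_xy_um / imaging.voxel_xy_um,
        imaging.psf_sigma_xy_um / imaging.voxel_xy_um,
    )
    return ndimage.gaussian_filter(vol, sigma=sig, mode="constant")


def _add_noise(
    vol: np.ndarray, imaging: ImagingParams, rng: Optional[np.random.Generator]
) -> np.ndarray:
    if imaging.noise == "none":
        return vol
    if rng is None:
        raise ValueError("rng required for noisy rendering")
    noisy = rng.poisson(np.clip(vol, 0, None)).astype(float)
    if imaging.read_noise_sd > 0:
        noisy += rng.normal(0.0, imaging.read_noise_sd, size=vol.shape)
    return noisy


def render_state(
    state: NucleusState,
    imaging: ImagingParams,
    geom: Optional[VolumeGeometry] = None,
    rng: Optional[np.random.Generator] = None,
    channels: Sequence[str] = ("syp",),
) -> Dict[str, np.ndarray]:
    """Render one kinetic state into per-channel ZYX stacks.

    The "syp" channel carries the bound fluorescence plus the pool spread
    uniformly through the nucleus sphere; the "foci" channel carries the
    planted recombination foci as point sources.
    """
    imaging.validate()
    if geom is None:
        geom = geometry_for_radius(state.radius_um, imaging)
    out: Dict[str, np.ndarray] = {}
    for ch in channels:
        if ch == "syp":
            vol = _splat(state.B, state.points, geom)
            if state.pool > 0:
                sphere = geom.sphere_mask((0.0, 0.0, 0.0), state.radius_um)
                vol[sphere] += state.pool / sphere.sum()
        elif ch == "foci":
            if state.foci:
                pts = np.stack([p for p, _ in state.foci])
                vals = np.full(len(state.foci), imaging.focus_intensity)
                vol = _splat(vals, pts, geom)
            else:
                vol = np.zeros(geom.shape, dtype=float)
        else:
            raise ValueError(f"unknown channel '{ch}'")
        vol = _blur(vol, imaging) + imaging.background_level
        out[ch] = _add_noise(vol, imaging, rng)
    return out


def render_series(
    states: Sequence[NucleusState],
    imaging: ImagingParams,
    geom: Optional[VolumeGeometry] = None,
    rng: Optional[np.random.Generator] = None,
    channels: Sequence[str] = ("syp",),
) -> TimeSeriesStack:
    """Render a sequence of states (e.g. a FRAP time course) to a stack series."""
    if not states:
        raise ValueError("need at least one state")
    if geom is None:
        geom = geometry_for_radius(states[0].radius_um, imaging)
    frames = [render_state(s, imaging, geom, rng, channels) for s in states]
    times = [s.time_min for s in states]
    return TimeSeriesStack(
        times_min=times,
        frames=frames,
        imaging=imaging,
        geometry=geom,
        channels=tuple(channels),
    )
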