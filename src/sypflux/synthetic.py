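"""Synthetic pachytene gonads with ground truth.

The generator emulates the structure the downstream analyses assume: a
gonad of nuclei ordered along the distal→proximal axis with a roughly
two-fold ramp in synaptonemal-complex (SC) central-region fluorescence,
six SC stretches per nucleus (one per homolog pair, exactly one labelled
X), Poisson-distributed recombination foci with genotype-dependent rates,
and chromosome-autonomous enrichment of central-region protein on
focus-bearing SCs in late pachytene.

Randomness: a single top-level seed; each nucleus draws from a child
stream derived from ``(seed, nucleus_index)`` so any subset of nuclei is
reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import interpolate
from scipy.spatial.distance import cdist

__all__ = [
    "GonadSpec",
    "GenotypeParams",
    "SCTrace",
    "Nucleus",
    "GonadLayout",
    "ConfigurationError",
    "GenerationError",
    "sample_sc_traces",
    "build_layout",
    "assign_breaks",
    "apply_enrichment",
    "simulate_break_counts",
    "occupancy_from_counts",
    "position_to_stage",
]

CHROMOSOME_LABELS = ("I", "II", "III", "IV", "V", "X")

STAGES = ("early", "mid", "late")


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


class GenerationError(RuntimeError):
    """Raised when stochastic geometry generation cannot satisfy constraints."""


@dataclasses.dataclass(frozen=True)
class GonadSpec:
    """Layout of the simulated pachytene region.

    ``ramp_fold`` is the fluorescence density of the most-proximal row
    relative to the most-distal row (default 2.1, the observed ~two-fold
    rise of central-region signal across pachytene). ``stage_boundaries``
    split the normalized position axis into early/mid/late.
    """

    n_rows: int = 24
    nuclei_per_row: int = 3
    nucleus_radius_um: float = 2.0
    n_pairs: int = 6
    ramp_fold: float = 2.1
    stage_boundaries: Tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    base_density: float = 20000.0  # fluorescence (photons) per µm of SC at the distal end
    min_trace_separation_um: float = 0.3
    total_length_range_um: Tuple[float, float] = (20.0, 28.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_rows < 1:
            raise ConfigurationError("n_rows must be a positive integer")
        if self.nuclei_per_row < 1:
            raise ConfigurationError("nuclei_per_row must be a positive integer")
        if self.nucleus_radius_um <= 0:
            raise ConfigurationError("nucleus_radius_um must be positive")
        if self.n_pairs < 1:
            raise ConfigurationError("n_pairs must be >= 1")
        if self.ramp_fold <= 0:
            raise ConfigurationError("ramp_fold must be positive")
        b1, b2 = self.stage_boundaries
        if not (0 < b1 < b2 < 1):
            raise ConfigurationError(
                "stage_boundaries must be strictly increasing fractions in (0, 1)"
            )
        if self.base_density <= 0:
            raise ConfigurationError("base_density must be positive")


@dataclasses.dataclass(frozen=True)
class GenotypeParams:
    """Recombination and enrichment behaviour of a simulated genotype.

    ``break_rate_lambda`` is the Poisson mean number of breaks per nucleus;
    a break is *effective* (able to seed a focus) with probability
    ``1 - heterosynapsis_fraction_h``, modelling breaks landing in
    non-homologously synapsed regions. ``designated_co_per_pair`` encodes
    the wild-type rule of exactly one crossover-designated focus per
    homolog pair in late pachytene. ``enrichment_active`` is switched off
    for polo-like-kinase-deficient genotypes, in which focus-bearing SCs
    do not accumulate extra central-region protein.
    """

    label: str = "wt"
    break_rate_lambda: float = 0.2
    heterosynapsis_fraction_h: float = 0.0
    designated_co_per_pair: bool = False
    enrichment_active: bool = True
    enrichment_factor: float = 2.0
    max_foci_per_trace: int = 4
    stage_kinetics: Optional[Dict[str, Tuple[float, float]]] = None  # stage -> (f, k)
    kinetic_jitter_sd: float = 0.05

    def validate(self) -> None:
        if self.break_rate_lambda < 0:
            raise ConfigurationError("break_rate_lambda must be >= 0")
        if not 0 <= self.heterosynapsis_fraction_h < 1:
            raise ConfigurationError("heterosynapsis_fraction_h must be in [0, 1)")
        if self.enrichment_factor < 1:
            raise ConfigurationError("enrichment_factor must be >= 1")
        if self.max_foci_per_trace < 1:
            raise ConfigurationError("max_foci_per_trace must be >= 1")
        if self.stage_kinetics is not None:
            for stage, (f, k) in self.stage_kinetics.items():
                if stage not in STAGES:
                    raise ConfigurationError(f"unknown stage '{stage}' in stage_kinetics")
                if not 0 <= f <= 1:
                    raise ConfigurationError("mobile fraction f must be in [0, 1]")
                if k < 0:
                    raise ConfigurationError("exchange rate k must be >= 0")


# Wild-type stage kinetics: mobile fraction drops steeply from early to late
# pachytene so that, with the standard partial-bleach geometry, the closed-form
# recovery plateau declines by about half between early and late nuclei.
WT_STAGE_KINETICS: Dict[str, Tuple[float, float]] = {
    "early": (0.80, 0.12),
    "mid": (0.45, 0.10),
    "late": (0.10, 0.08),
}
# Genotypes that never stabilise the SC keep early-pachytene kinetics throughout.
FLAT_STAGE_KINETICS: Dict[str, Tuple[float, float]] = {
    "early": (0.80, 0.12),
    "mid": (0.80, 0.12),
    "late": (0.80, 0.12),
}


@dataclasses.dataclass
class SCTrace:
    """One SC stretch: a smooth space curve inside the nucleus.

    ``points`` are (M, 3) xyz µm relative to the nucleus centre.
    ``enrichment`` (≥ 1) is the preferential-accumulation factor on
    focus-bearing traces; ``conservation_scale`` carries the compensating
    down-scaling that keeps total nuclear signal constant, so the
    effective density multiplier is ``enrichment * conservation_scale``.
    ``foci`` are arc-length positions (µm from the trace start).
    """

    trace_id: int
    chromosome_label: str
    points: np.ndarray
    density: float
    enrichment: float = 1.0
    conservation_scale: float = 1.0
    foci: List[float] = dataclasses.field(default_factory=list)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def length_um(self) -> float:
        return float(self.segment_lengths.sum())

    @property
    def intensity_multiplier(self) -> float:
        return self.enrichment * self.conservation_scale

    @property
    def total_intensity(self) -> float:
        return self.length_um * self.density * self.intensity_multiplier

    def point_at_arclength(self, s: float) -> np.ndarray:
        """Interpolate the 3D position at arc length ``s`` along the trace."""
        cum = np.concatenate([[0.0], np.cumsum(self.segment_lengths)])
        s = float(np.clip(s, 0.0, cum[-1]))
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(cum) - 2)
        seg = cum[i + 1] - cum[i]
        t = 0.0 if seg == 0 else (s - cum[i]) / seg
        return self.points[i] + t * (self.points[i + 1] - self.points[i])


@dataclasses.dataclass
class Nucleus:
    nucleus_id: int
    row: int
    index_in_row: int
    x: float  # normalized distal→proximal position, row / n_rows
    stage: str
    center_um: Tuple[float, float, float]  # position within the gonad
    radius_um: float
    base_density: float
    traces: List[SCTrace]
    mobile_fraction_f: float
    exchange_rate_k: float

    @property
    def total_trace_intensity(self) -> float:
        return sum(t.total_intensity for t in self.traces)

    @property
    def n_foci(self) -> int:
        return sum(len(t.foci) for t in self.traces)

    @property
    def n_focus_traces(self) -> int:
        return sum(1 for t in self.traces if t.foci)


@dataclasses.dataclass
class GonadLayout:
    spec: GonadSpec
    genotype: GenotypeParams
    nuclei: List[Nucleus]
    seed: int

    def nuclei_in_stage(self, stage: str) -> List[Nucleus]:
        return [n for n in self.nuclei if n.stage == stage]


def position_to_stage(x: float, boundaries: Sequence[float]) -> str:
    """Stage from normalized position: early if x ≤ b1, mid if b1 < x ≤ b2."""
    b1, b2 = boundaries
    if x <= b1:
        return "early"
    if x <= b2:
        return "mid"
    return "late"


def nucleus_rng(seed: int, nucleus_index: int) -> np.random.Generator:
    """Child random stream for one nucleus, stable under subsetting."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(nucleus_index),))
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _territory_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Well-separated unit directions, one territory per chromosome pair.

    SC stretches occupy largely distinct nuclear territories; anchoring
    each trace's waypoint cloud to a separated direction makes the
    pairwise-separation rejection sampling converge quickly.
    """
    dirs: List[np.ndarray] = []
    min_cos = np.cos(np.deg2rad(55.0))
    for _ in range(n):
        for attempt in range(500):
            d = _random_unit(rng)
            if all(float(d @ e) < min_cos for e in dirs):
                dirs.append(d)
                break
        else:  # crowded sphere: accept the best effort
            dirs.append(_random_unit(rng))
    return np.stack(dirs)


def _waypoint_count(target_length: float, cloud_radius: float) -> int:
    """Waypoints needed for a spline of roughly the target arc length:
    consecutive ordered waypoints in the cloud are ~0.9·cloud_radius apart."""
    return int(np.clip(round(target_length / (0.9 * cloud_radius)) + 1, 4, 12))


def _trace_waypoints(
    radius: float,
    rng: np.random.Generator,
    direction: Optional[np.ndarray] = None,
    n_way: int = 5,
    z_flatten: float = 2.0,
) -> np.ndarray:
    """Random waypoints in an oblate territory cloud, ordered along an axis.

    The cloud is compressed axially by ``z_flatten`` so candidate curves
    wander mostly laterally; this keeps them self-separated in the
    PSF-scaled metric that the rejection sampling enforces.
    """
    inner = 0.85 * radius
    center = np.zeros(3) if direction is None else 0.45 * radius * direction
    cloud = 0.55 * radius if direction is not None else inner
    stretch = np.array([1.0, 1.0, z_flatten])
    pts = np.empty((n_way, 3))
    got = 0
    while got < n_way:
        cand = rng.uniform(-cloud, cloud, size=(4 * n_way, 3))
        cand[:, 2] /= z_flatten
        cand = center + cand
        keep = cand[
            (np.linalg.norm((cand - center) * stretch, axis=1) <= cloud)
            & (np.linalg.norm(cand, axis=1) <= inner)
        ]
        take = keep[: n_way - got]
        pts[got : got + len(take)] = take
        got += len(take)
    axis = _random_unit(rng)
    order = np.argsort(pts @ axis)
    return pts[order]


def _spline_through(waypoints: np.ndarray, n_samples: int) -> np.ndarray:
    tck, _ = interpolate.splprep(waypoints.T, s=0, k=min(3, len(waypoints) - 1))
    u = np.linspace(0, 1, n_samples)
    return np.stack(interpolate.splev(u, tck), axis=1)


def sample_sc_traces(
    radius_um: float,
    n_pairs: int,
    rng: np.random.Generator,
    *,
    density: float = 1.0,
    min_separation_um: float = 0.3,
    total_length_range_um: Tuple[float, float] = (20.0, 28.0),
    n_samples: int = 60,
    max_trace_retries: int = 600,
    max_restarts: int = 60,
    psf_z_anisotropy: float = 2.0,
) -> List[SCTrace]:
    """Sample ``n_pairs`` smooth, mutually separated space curves in a sphere.

    Curves are interpolating cubic splines through random interior
    waypoints, rescaled into 0.92·radius when they overshoot. Rejection
    sampling enforces a per-trace length between ``total_range/(3·n_pairs)``
    and ``3·total_range_max/n_pairs`` plus minimum separation — both
    between traces and between non-neighbouring points of the same trace.
    Separation is measured in PSF-scaled coordinates (z compressed by
    ``psf_z_anisotropy``, the axial/lateral PSF ratio), so the constraint
    bounds optical cross-bleed rather than bare distance. Raises
    :class:`GenerationError` when constraints cannot be met after bounded
    retries.
    """
    if radius_um <= 0:
        raise ConfigurationError("radius_um must be positive")
    lo_total, hi_total = total_length_range_um
    # per-trace bounds slightly wider than the equal share, so per-trace
    # rejection does most of the work of hitting the total-length window
    lo_trace = 0.85 * lo_total / n_pairs
    hi_trace = 1.15 * hi_total / n_pairs
    labels = _chromosome_labels(n_pairs)
    zscale = np.array([1.0, 1.0, 1.0 / psf_z_anisotropy])
    n_way = _waypoint_count(
        (lo_total + hi_total) / (2.0 * n_pairs), 0.55 * radius_um
    )

    for _ in range(max_restarts):
        dirs = _territory_directions(n_pairs, rng)
        traces: List[SCTrace] = []
        ok = True
        for t_idx in range(n_pairs):
            placed = False
            for _ in range(max_trace_retries):
                pts = _spline_through(
                    _trace_waypoints(
                        radius_um, rng, dirs[t_idx], n_way,
                        z_flatten=psf_z_anisotropy,
                    ),
                    n_samples,
                )
                maxnorm = float(np.linalg.norm(pts, axis=1).max())
                if maxnorm > 0.92 * radius_um:
                    pts = pts * (0.92 * radius_um / maxnorm)
                length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
                if not (lo_trace <= length <= hi_trace):
                    continue
                if min_separation_um > 0:
                    scaled = pts * zscale
                    if not _self_separated(
                        scaled, length / (n_samples - 1), min_separation_um
                    ):
                        continue
                    if traces and (
                        min(cdist(scaled, t.points * zscale).min() for t in traces)
                        < min_separation_um
                    ):
                        continue
                traces.append(
                    SCTrace(
                        trace_id=t_idx,
                        chromosome_label=labels[t_idx],
                        points=pts,
                        density=density,
                    )
                )
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            total = sum(t.length_um for t in traces)
            if lo_total <= total <= hi_total:
                return traces
    raise GenerationError(
        f"could not place {n_pairs} traces with separation "
        f">= {min_separation_um} µm in a radius-{radius_um} µm nucleus; "
        "try fewer pairs or a larger radius"
    )


def _self_separated(
    scaled_pts: np.ndarray, step_um: float, min_sep: float
) -> bool:
    """No two points farther than ~2·min_sep apart along the curve may come
    closer than ``min_sep`` in PSF-scaled space (rejects self-coiling)."""
    d = cdist(scaled_pts, scaled_pts)
    n = len(scaled_pts)
    skip = max(1, int(np.ceil(2.0 * min_sep / max(step_um, 1e-9))))
    i, j = np.triu_indices(n, k=skip + 1)
    if len(i) == 0:
        return True
    return bool(d[i, j].min() >= min_sep)


def _chromosome_labels(n_pairs: int) -> List[str]:
    """Labels with exactly one X; extra pairs beyond six get synthetic names."""
    if n_pairs <= len(CHROMOSOME_LABELS):
        autosomes = list(CHROMOSOME_LABELS[:-1])[: n_pairs - 1]
        return autosomes + ["X"]
    extra = [f"A{i}" for i in range(6, n_pairs)]
    return list(CHROMOSOME_LABELS[:-1]) + extra + ["X"]


def build_layout(
    spec: GonadSpec,
    genotype: GenotypeParams,
    seed: Optional[int] = None,
    stages: Optional[Sequence[str]] = None,
) -> GonadLayout:
    """Deterministically build a gonad of nuclei with traces and kinetics.

    The staging position is ``x = row / n_rows`` (the row-number rule used
    for position profiling); the fluorescence ramp is linear over the ramp
    coordinate ``(row − 1)/(n_rows − 1)`` so the most-distal row is the
    reference density and the most-proximal row is exactly ``ramp_fold``
    brighter. ``stages`` restricts construction to rows in the given
    stages without changing nucleus ids or their random streams, so a
    subset layout agrees exactly with the corresponding full layout.
    """
    spec.validate()
    genotype.validate()
    seed = spec.seed if seed is None else int(seed)
    kinetics = genotype.stage_kinetics
    if kinetics is None:
        kinetics = WT_STAGE_KINETICS if genotype.label == "wt" else FLAT_STAGE_KINETICS

    row_pitch = 2.4 * spec.nucleus_radius_um
    nuclei: List[Nucleus] = []
    nucleus_index = 0
    for row in range(1, spec.n_rows + 1):
        x = row / spec.n_rows
        ramp_x = 0.0 if spec.n_rows == 1 else (row - 1) / (spec.n_rows - 1)
        density = spec.base_density * (1.0 + (spec.ramp_fold - 1.0) * ramp_x)
        stage = position_to_stage(x, spec.stage_boundaries)
        if stages is not None and stage not in stages:
            nucleus_index += spec.nuclei_per_row
            continue
        f_stage, k_stage = kinetics[stage]
        for j in range(spec.nuclei_per_row):
            rng = nucleus_rng(seed, nucleus_index)
            traces = sample_sc_traces(
                spec.nucleus_radius_um,
                spec.n_pairs,
                rng,
                density=density,
                min_separation_um=spec.min_trace_separation_um,
                total_length_range_um=spec.total_length_range_um,
            )
            f = float(np.clip(rng.normal(f_stage, genotype.kinetic_jitter_sd), 0.0, 1.0))
            center = (row * row_pitch, j * row_pitch, 0.0)
            nuclei.append(
                Nucleus(
                    nucleus_id=nucleus_index,
                    row=row,
                    index_in_row=j,
                    x=x,
                    stage=stage,
                    center_um=center,
                    radius_um=spec.nucleus_radius_um,
                    base_density=density,
                    traces=traces,
                    mobile_fraction_f=f,
                    exchange_rate_k=k_stage,
                )
            )
            nucleus_index += 1
    return GonadLayout(spec=spec, genotype=genotype, nuclei=nuclei, seed=seed)


def simulate_break_counts(
    genotype: GenotypeParams, n_nuclei: int, rng: np.random.Generator
) -> np.ndarray:
    """Effective break counts for ``n_nuclei`` nuclei, without geometry.

    Raw counts are Poisson(``break_rate_lambda``); each break is thinned
    with probability ``heterosynapsis_fraction_h`` (breaks engaged in
    non-homologous synapsis never mature into foci). The wild-type
    designated-crossover rule yields a constant count of one per pair and
    is not Poisson; callers wanting that rule should use
    :func:`assign_breaks` on a layout.
    """
    genotype.validate()
    raw = rng.poisson(genotype.break_rate_lambda, size=n_nuclei)
    if genotype.heterosynapsis_fraction_h > 0:
        return rng.binomial(raw, 1.0 - genotype.heterosynapsis_fraction_h)
    return raw


def occupancy_from_counts(
    counts: np.ndarray,
    n_pairs: int,
    rng: np.random.Generator,
    max_per_trace: int = 4,
) -> np.ndarray:
    """Number of distinct focus-bearing chromosome pairs per nucleus.

    Each effective break lands on a uniformly chosen pair, capped at
    ``max_per_trace`` breaks per pair (excess breaks re-draw among pairs
    still under the cap).
    """
    out = np.empty(len(counts), dtype=int)
    for i, c in enumerate(np.asarray(counts, dtype=int)):
        per_trace = np.zeros(n_pairs, dtype=int)
        for _ in range(min(c, n_pairs * max_per_trace)):
            open_traces = np.flatnonzero(per_trace < max_per_trace)
            per_trace[rng.choice(open_traces)] += 1
        out[i] = int((per_trace > 0).sum())
    return out


def assign_breaks(layout: GonadLayout, rng: np.random.Generator) -> GonadLayout:
    """Place recombination foci on traces, in place; returns the layout.

    Wild-type designated-crossover rule: exactly one focus per trace in
    late-pachytene nuclei (early/mid nuclei have none — bright
    crossover-site foci are a late-pachytene feature). Otherwise the
    per-nucleus break count is Poisson(``break_rate_lambda``); each break
    is effective with probability ``1 − h`` and effective breaks land on
    uniformly chosen traces, at most ``max_foci_per_trace`` each.
    """
    g = layout.genotype
    for nuc in layout.nuclei:
        for t in nuc.traces:
            t.foci = []
        if g.designated_co_per_pair:
            if nuc.stage == "late":
                for t in nuc.traces:
                    t.foci = [float(rng.uniform(0.15, 0.85) * t.length_um)]
            continue
        n_breaks = rng.poisson(g.break_rate_lambda)
        for _ in range(n_breaks):
            if rng.uniform() < g.heterosynapsis_fraction_h:
                continue  # ineffective break: no focus
            open_traces = [
                t for t in nuc.traces if len(t.foci) < g.max_foci_per_trace
            ]
            if not open_traces:
                continue
            t = open_traces[rng.integers(len(open_traces))]
            t.foci.append(float(rng.uniform(0.1, 0.9) * t.length_um))
    return layout


def apply_enrichment(layout: GonadLayout, conserve_total: bool = True) -> GonadLayout:
    """Enrich focus-bearing traces in late-pachytene nuclei, in place.

    When the genotype's enrichment pathway is active, every focus-bearing
    trace in a late-stage nucleus gains ``enrichment_factor``; with
    ``conserve_total`` (default) all traces are then rescaled so the total
    nuclear trace fluorescence is unchanged — enrichment redistributes
    subunits rather than creating them. With the pathway inactive
    (polo-like-kinase-deficient genotypes) all factors stay 1.
    """
    g = layout.genotype
    for nuc in layout.nuclei:
        for t in nuc.traces:
            t.enrichment = 1.0
            t.conservation_scale = 1.0
        if not g.enrichment_active or nuc.stage != "late":
            continue
        focus_traces = [t for t in nuc.traces if t.foci]
        if not focus_traces:
            continue
        before = nuc.total_trace_intensity
        for t in focus_traces:
            t.enrichment = g.enrichment_factor
        if conserve_total:
            after = nuc.total_trace_intensity
            scale = before / after
            for t in nuc.traces:
                t.conservation_scale = scale
    return layout
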