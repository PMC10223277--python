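"""Synthetic FAZ-like data with known ground truth.

Real study data are manually annotated OCTA exports that are not publicly
deposited, so this module generates stand-ins at three levels:

* **Shapes** — star-shaped boundaries ``r(θ) = R0·(1 + Σ a_k·cos(kθ + φ_k))``
  built from a few low-order Fourier harmonics.  This is the lowest-order
  family that spans realistic FAZ irregularity while keeping a closed-form
  enclosed area, ``π·R0²·(1 + ½·Σ a_k²)``, which every downstream
  measurement can be checked against.
* **Images** — the shape rendered over a flat-grey or procedural
  vessel-texture background (dark avascular core, a transition band of
  configurable width, a bright filamentary annulus) with the perimeter drawn
  in a solid colour, emulating a Paint-annotated angiogram.
* **Observer sets** — multiple observers tracing each shape under the two
  delimitation criteria.  The initial criterion follows the enclosing
  vessels (multiplicative radial bias > 1, spikier boundaries); the final
  criterion slightly enters the FAZ limits (bias < 1, smoother boundaries,
  tighter agreement).

All randomness flows through :class:`numpy.random.Generator`; one stream per
record is derived from the master seed by stable hashing of the record key,
so any subset of a cohort is reproducible independently of generation order.
"""
from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import InvalidSpec, ShapeOutOfBounds
from .geometry import sort_by_azimuth
from .types import AnnotatedImage, Cohort, ContourMeta, Criterion, Plexus, PointSet

__all__ = [
    "SyntheticShape",
    "ObserverModel",
    "CohortShapeParams",
    "ObserverSetup",
    "SyntheticCohortSpec",
    "CohortDataset",
    "default_cohort_spec",
    "sample_shape",
    "shape_to_points",
    "render_annotated",
    "simulate_observer_tracing",
    "generate_cohort",
    "stable_record_seed",
]

TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# shapes


@dataclass(frozen=True)
class SyntheticShape:
    """Parametric radial boundary r(θ) with analytically known area.

    ``harmonics`` is a tuple of (k, a_k, φ_k) triples with integer k ≥ 2;
    amplitudes are fractions of the base radius and must satisfy
    Σ|a_k| < 1 so the radius stays positive.
    """

    r0: float
    harmonics: Tuple[Tuple[int, float, float], ...] = ()
    centre: Tuple[float, float] = (160.0, 160.0)
    n_samples: int = 2000

    def __post_init__(self):
        if self.r0 <= 0:
            raise InvalidSpec(f"base radius must be positive, got {self.r0}")
        total = sum(abs(a) for _, a, _ in self.harmonics)
        if total >= 1.0:
            raise InvalidSpec(f"sum of |harmonic amplitudes| must be < 1, got {total:.3f}")
        for k, _, _ in self.harmonics:
            if int(k) < 2:
                raise InvalidSpec(f"harmonic order must be >= 2, got {k}")

    def radii(self, theta: np.ndarray) -> np.ndarray:
        r = np.ones_like(theta, dtype=float)
        for k, a, phi in self.harmonics:
            r = r + a * np.cos(k * theta + phi)
        return self.r0 * r

    @property
    def analytic_area_px2(self) -> float:
        """Enclosed area ½∫r(θ)²dθ = π·R0²·(1 + ½Σa_k²)."""
        return math.pi * self.r0**2 * (1.0 + 0.5 * sum(a * a for _, a, _ in self.harmonics))

    @property
    def max_radius(self) -> float:
        return self.r0 * (1.0 + sum(abs(a) for _, a, _ in self.harmonics))

    def boundary_points(self, n_samples: Optional[int] = None) -> np.ndarray:
        """Real-valued (x, y) samples at uniform azimuths, shape (n, 2)."""
        n = self.n_samples if n_samples is None else int(n_samples)
        theta = np.arange(n) * (TWO_PI / n)
        r = self.radii(theta)
        cx, cy = self.centre
        return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def _dedupe_stable(points: np.ndarray) -> np.ndarray:
    """Drop duplicate rows, keeping first occurrences in original order."""
    _, idx = np.unique(points, axis=0, return_index=True)
    return points[np.sort(idx)]


def shape_to_points(
    shape: SyntheticShape,
    meta: Optional[ContourMeta] = None,
    n_samples: Optional[int] = None,
) -> PointSet:
    """Integer-rounded boundary pixels at uniform azimuths, duplicates removed."""
    pts = np.rint(shape.boundary_points(n_samples)).astype(np.int64)
    return PointSet(_dedupe_stable(pts), meta)


# ---------------------------------------------------------------------------
# observers


@dataclass(frozen=True)
class ObserverModel:
    """Statistical model of one observer tracing under one criterion.

    The traced boundary is
    ``r'(θ) = r(θ) · radial_bias · (1 + η) · (1 + spike(θ) + ε(θ))`` where

    * ``radial_bias`` is the systematic placement of the line: > 1 when the
      observer follows the enclosing vessels (initial criterion), < 1 when
      slightly entering the FAZ limits (final criterion);
    * ``η ~ N(0, bias_jitter_sd)`` is a per-tracing radial offset — the
      record-to-record disagreement about where the boundary sits, the
      mechanism behind inter- and intra-observer variability;
    * ``spike(θ)`` is one high-frequency harmonic (order drawn from 15–40,
      random phase) of amplitude ``spike_amp``, mimicking vessel-following
      scallops rather than white noise;
    * ``ε(θ) ~ N(0, noise_sd)`` is independent per-point radial jitter.
    """

    criterion: Criterion
    radial_bias: float
    spike_amp: float
    noise_sd: float = 0.01
    bias_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.radial_bias <= 0:
            raise InvalidSpec("radial_bias must be > 0")
        if self.spike_amp < 0 or self.noise_sd < 0 or self.bias_jitter_sd < 0:
            raise InvalidSpec("spike_amp, noise_sd and bias_jitter_sd must be >= 0")

    @classmethod
    def default(cls, criterion: Criterion, seed: int = 0) -> "ObserverModel":
        criterion = Criterion(criterion)
        if criterion is Criterion.INITIAL:
            return cls(criterion, radial_bias=1.12, spike_amp=0.06,
                       noise_sd=0.01, bias_jitter_sd=0.04, seed=seed)
        return cls(criterion, radial_bias=0.97, spike_amp=0.02,
                   noise_sd=0.01, bias_jitter_sd=0.015, seed=seed)


SPIKE_ORDER_RANGE = (15, 40)


def simulate_observer_tracing(
    shape: SyntheticShape,
    model: ObserverModel,
    rng: Optional[np.random.Generator] = None,
    meta: Optional[ContourMeta] = None,
    n_samples: Optional[int] = None,
) -> PointSet:
    """One manual tracing of ``shape`` under ``model``; reproducible by seed.

    With ``radial_bias=1`` and all perturbation amplitudes zero this is
    identical to :func:`shape_to_points`.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    n = shape.n_samples if n_samples is None else int(n_samples)
    theta = np.arange(n) * (TWO_PI / n)
    r = shape.radii(theta)

    factor = model.radial_bias
    if model.bias_jitter_sd > 0:
        factor = factor * (1.0 + model.bias_jitter_sd * rng.standard_normal())
    mult = np.ones(n)
    if model.spike_amp > 0:
        k = int(rng.integers(SPIKE_ORDER_RANGE[0], SPIKE_ORDER_RANGE[1] + 1))
        phi = rng.uniform(0.0, TWO_PI)
        mult = mult + model.spike_amp * np.cos(k * theta + phi)
    if model.noise_sd > 0:
        mult = mult + model.noise_sd * rng.standard_normal(n)

    rr = np.maximum(r * factor * mult, 0.5)
    cx, cy = shape.centre
    pts = np.rint(
        np.column_stack([cx + rr * np.cos(theta), cy + rr * np.sin(theta)])
    ).astype(np.int64)
    return PointSet(_dedupe_stable(pts), meta)


# ---------------------------------------------------------------------------
# rendering


def render_annotated(
    source: Union[SyntheticShape, PointSet],
    meta: ContourMeta,
    background: str = "vessels",
    line_colour: Tuple[int, int, int] = (255, 0, 0),
    line_thickness: int = 1,
    image_shape: Tuple[int, int] = (320, 320),
    transition_width: float = 0.12,
    rng: Optional[np.random.Generator] = None,
) -> AnnotatedImage:
    """Render an OCTA-like image with the FAZ perimeter drawn over it.

    ``background="flat"`` gives a uniform grey; ``"vessels"`` a procedural
    texture with a dark avascular core inside r(θ), a linear transition band
    of relative width ``transition_width`` and a bright filamentary annulus
    outside — enough structure to exercise overlay extraction, with no claim
    of vascular realism.  ``line_thickness=0`` draws no line.
    """
    from skimage.draw import line as draw_line
    from skimage.morphology import binary_dilation, disk

    rows, cols = image_shape
    if rng is None:
        rng = np.random.default_rng(0)

    if isinstance(source, SyntheticShape):
        shape = source
        verts = np.rint(shape.boundary_points()).astype(np.int64)
    else:
        shape = None
        verts = sort_by_azimuth(source).points.astype(np.int64)

    margin = max(2, line_thickness)
    if (
        verts[:, 0].min() < margin or verts[:, 1].min() < margin
        or verts[:, 0].max() >= cols - margin or verts[:, 1].max() >= rows - margin
    ):
        raise ShapeOutOfBounds(
            f"boundary does not fit a {rows}x{cols} image with margin {margin}"
        )

    if background == "flat":
        grey = np.full((rows, cols), 90.0)
    elif background == "vessels":
        if shape is None:
            raise ValueError("vessel background requires a SyntheticShape source")
        grey = _vessel_background(shape, rows, cols, transition_width, rng)
    else:
        raise ValueError(f"unknown background mode {background!r}")

    img = np.repeat(grey[:, :, None], 3, axis=2).astype(np.uint8)

    if line_thickness > 0:
        mask = np.zeros((rows, cols), dtype=bool)
        closed = np.vstack([verts, verts[:1]])
        for (x0, y0), (x1, y1) in zip(closed[:-1], closed[1:]):
            rr, cc = draw_line(int(y0), int(x0), int(y1), int(x1))
            mask[rr, cc] = True
        radius = (line_thickness - 1) // 2
        if radius > 0:
            mask = binary_dilation(mask, disk(radius))
        img[mask] = np.asarray(line_colour, dtype=np.uint8)

    return AnnotatedImage(img, meta)


def _vessel_background(shape, rows, cols, transition_width, rng):
    from scipy.ndimage import gaussian_filter

    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    cx, cy = shape.centre
    dist = np.hypot(xx - cx, yy - cy)
    rb = shape.radii(np.arctan2(yy - cy, xx - cx))
    # 0 inside the avascular core, ramps to 1 across the transition band
    t = np.clip((dist - rb) / np.maximum(rb * transition_width, 1e-9), 0.0, 1.0)
    tex = gaussian_filter(rng.standard_normal((rows, cols)), sigma=2.0)
    vessel = np.where(tex > 0.25, 215.0, 45.0)
    core = 18.0
    return core + t * (vessel - core)


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortShapeParams:
    """Per-cohort sampling ranges for the ground-truth FAZ shapes.

    Radii are in pixels of the rendered field; amplitudes are fractions of
    the base radius, drawn uniformly per harmonic.
    """

    r0_range: Tuple[float, float]
    amp_range: Tuple[float, float]
    n_harmonics: int = 3
    k_range: Tuple[int, int] = (2, 6)

    def __post_init__(self):
        lo, hi = self.r0_range
        alo, ahi = self.amp_range
        if not (0 < lo <= hi):
            raise InvalidSpec(f"bad r0_range {self.r0_range}")
        if not (0 <= alo <= ahi):
            raise InvalidSpec(f"bad amp_range {self.amp_range}")
        if self.n_harmonics * ahi >= 1.0:
            raise InvalidSpec(
                "n_harmonics x max amplitude must stay < 1 to keep r(θ) > 0"
            )
        if self.k_range[1] - self.k_range[0] + 1 < self.n_harmonics:
            raise InvalidSpec("k_range too narrow for the number of harmonics")


@dataclass(frozen=True)
class ObserverSetup:
    """One observer: how many series they traced, and their per-criterion model."""

    n_series: int
    models: Dict[Criterion, ObserverModel]

    def __post_init__(self):
        if self.n_series < 1:
            raise InvalidSpec("n_series must be >= 1")
        for crit in Criterion:
            if crit not in self.models:
                raise InvalidSpec(f"observer setup missing a model for {crit.value}")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Full factorial synthetic study: eyes × plexus × observer × series × criterion."""

    shape_params: Dict[Cohort, CohortShapeParams]
    n_eyes: Dict[Cohort, int]
    observers: Dict[str, ObserverSetup]
    plexuses: Tuple[Plexus, ...] = (Plexus.SCP, Plexus.DCP)
    plexus_r0_scale: Dict[Plexus, float] = field(
        default_factory=lambda: {Plexus.SCP: 1.0, Plexus.DCP: 1.05}
    )
    image_cols: int = 320
    image_rows: int = 320
    width_mm: float = 3.0
    n_samples: int = 2000
    master_seed: int = 0

    def __post_init__(self):
        if not self.observers:
            raise InvalidSpec("at least one observer required")
        for cohort in self.n_eyes:
            if Cohort(cohort) not in self.shape_params:
                raise InvalidSpec(f"no shape parameters for cohort {cohort}")
            if self.n_eyes[cohort] < 1:
                raise InvalidSpec("n_eyes must be >= 1 per cohort")

    @property
    def n_records(self) -> int:
        series_slots = sum(o.n_series for o in self.observers.values())
        eyes = sum(self.n_eyes.values())
        return eyes * len(self.plexuses) * series_slots * len(Criterion)


def default_cohort_spec(
    master_seed: int = 0,
    n_eyes: Optional[Dict[Cohort, int]] = None,
) -> SyntheticCohortSpec:
    """The default synthetic study, sized and structured like the clinical one.

    167 eyes (73 healthy, 40 type-1, 54 type-2 with NPDR), two plexuses,
    four observers of whom two traced twice (series labels C1, C2, E1, G1,
    G2, S1), two criteria — 4008 segmentation records.  Type-2 shapes are
    drawn from a wider irregularity range, echoing the greater FAZ changes
    seen in damaged retinas.
    """
    shape_params = {
        Cohort.HEALTHY: CohortShapeParams(r0_range=(18.0, 30.0), amp_range=(0.02, 0.10)),
        Cohort.DM1: CohortShapeParams(r0_range=(15.0, 26.0), amp_range=(0.02, 0.11)),
        Cohort.DM2: CohortShapeParams(r0_range=(14.0, 32.0), amp_range=(0.03, 0.15)),
    }
    if n_eyes is None:
        n_eyes = {Cohort.HEALTHY: 73, Cohort.DM1: 40, Cohort.DM2: 54}
    models = {c: ObserverModel.default(c) for c in Criterion}
    observers = {
        "C": ObserverSetup(2, models),
        "E": ObserverSetup(1, models),
        "G": ObserverSetup(2, models),
        "S": ObserverSetup(1, models),
    }
    return SyntheticCohortSpec(
        shape_params=shape_params,
        n_eyes=n_eyes,
        observers=observers,
        master_seed=master_seed,
    )


def stable_record_seed(master_seed: int, *keys) -> np.random.SeedSequence:
    """Seed for one record, stable across generation order and platforms."""
    digest = hashlib.sha256("|".join(str(k) for k in keys).encode()).digest()
    h = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.SeedSequence((int(master_seed), h))


def sample_shape(
    spec: SyntheticCohortSpec,
    cohort: Cohort,
    rng: np.random.Generator,
    plexus: Optional[Plexus] = None,
) -> SyntheticShape:
    """Draw one ground-truth FAZ shape from the cohort's parameter ranges."""
    params = spec.shape_params[Cohort(cohort)]
    scale = spec.plexus_r0_scale.get(Plexus(plexus), 1.0) if plexus is not None else 1.0
    r0 = float(rng.uniform(*params.r0_range)) * scale
    ks = rng.choice(
        np.arange(params.k_range[0], params.k_range[1] + 1),
        size=params.n_harmonics,
        replace=False,
    )
    amps = rng.uniform(params.amp_range[0], params.amp_range[1], params.n_harmonics)
    phis = rng.uniform(0.0, TWO_PI, params.n_harmonics)
    cx = spec.image_cols / 2.0 + float(rng.uniform(-5.0, 5.0))
    cy = spec.image_rows / 2.0 + float(rng.uniform(-5.0, 5.0))
    return SyntheticShape(
        r0=r0,
        harmonics=tuple((int(k), float(a), float(p)) for k, a, p in zip(ks, amps, phis)),
        centre=(cx, cy),
        n_samples=spec.n_samples,
    )


@dataclass
class CohortDataset:
    """Generated synthetic study: tracings plus the ground-truth registry."""

    records: list  # list[PointSet]
    ground_truth: pd.DataFrame
    shapes: Dict[Tuple[str, Plexus], SyntheticShape]


def generate_cohort(spec: SyntheticCohortSpec) -> CohortDataset:
    """Expand a cohort spec into the full factorial set of tracings.

    Deterministic under the master seed: each shape and each tracing has its
    own RNG stream derived by stable hashing of its key, so regenerating any
    subset yields identical records.
    """
    px_area = (spec.width_mm / spec.image_cols) * (spec.width_mm / spec.image_rows)
    records, gt_rows = [], []
    shapes: Dict[Tuple[str, Plexus], SyntheticShape] = {}
    for cohort, n in spec.n_eyes.items():
        cohort = Cohort(cohort)
        for i in range(1, n + 1):
            eye_id = f"{cohort.value}_{i:03d}"
            for plexus in spec.plexuses:
                shape_rng = np.random.default_rng(
                    stable_record_seed(spec.master_seed, "shape", eye_id, plexus.value)
                )
                shape = sample_shape(spec, cohort, shape_rng, plexus)
                shapes[(eye_id, plexus)] = shape
                for label, setup in spec.observers.items():
                    for series in range(1, setup.n_series + 1):
                        for criterion in Criterion:
                            meta = ContourMeta(
                                eye_id=eye_id, plexus=plexus, cohort=cohort,
                                observer=label, series=series, criterion=criterion,
                                width_mm=spec.width_mm,
                                image_cols=spec.image_cols, image_rows=spec.image_rows,
                            )
                            rng = np.random.default_rng(
                                stable_record_seed(
                                    spec.master_seed, "trace", eye_id, plexus.value,
                                    label, series, criterion.value,
                                )
                            )
                            ps = simulate_observer_tracing(
                                shape, setup.models[criterion], rng, meta
                            )
                            records.append(ps)
                            gt_rows.append({
                                "record_id": meta.record_id,
                                "eye_id": eye_id,
                                "cohort": cohort.value,
                                "plexus": plexus.value,
                                "observer": label,
                                "series": series,
                                "criterion": criterion.value,
                                "r0_px": shape.r0,
                                "harmonics": ";".join(
                                    f"{k}:{a:.6f}:{p:.6f}" for k, a, p in shape.harmonics
                                ),
                                "analytic_area_px2": shape.analytic_area_px2,
                                "analytic_area_mm2": shape.analytic_area_px2 * px_area,
                                "radial_bias": setup.models[criterion].radial_bias,
                            })
    return CohortDataset(records, pd.DataFrame(gt_rows), shapes)
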