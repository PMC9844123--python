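"""Ground-truth-annotated synthetic inputs for the sorter pipeline.

Three generators, each deterministic under a fixed seed:

* :func:`generate_population` — per-event feature tables (area,
  deformation, area ratio, brightness, diameter) drawn from parametric
  population specs, emulating the scatter structure of deformability
  cytometry of beads and blood;
* :func:`generate_arrival_stream` — homogeneous Poisson arrival times at
  the rate set by cell concentration x volumetric flow;
* :func:`render_frames` — grayscale frame stacks with anti-aliased
  elliptical "cells" over a uniform noisy background, with the exact
  rendered geometry retained as ground truth for benchmarking the
  feature extractor.

Shapes are sampled, not computed from flow physics, and the optics are
idealised (no defocus or diffraction).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import ellipe

__all__ = [
    "Distribution",
    "PopulationSpec",
    "ArrivalStream",
    "EllipseObject",
    "FrameStack",
    "generate_population",
    "generate_arrival_stream",
    "sample_events_for_stream",
    "render_frames",
    "write_frame_stack",
    "read_frame_stack",
    "bead_mixture_populations",
    "blood_populations",
    "whole_blood_populations",
]

#: canonical event-table columns (the CSV interchange dialect)
EVENT_COLUMNS = [
    "id", "time_s", "label", "area_um2", "deformation",
    "area_ratio", "brightness_au", "diameter_um",
]


@dataclass(frozen=True)
class Distribution:
    """A 1-D sampling distribution given by mean and coefficient of variation.

    kind is 'normal', 'lognormal' (moments matched to mean/CV) or
    'constant' (CV ignored).  Optional lower/upper bounds are enforced by
    rejection resampling, so e.g. deformation stays in [0, 1) and area
    ratio stays >= 1 without distorting the bulk of the distribution.
    """

    mean: float
    cv: float = 0.0
    kind: str = "normal"
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.kind not in ("normal", "lognormal", "constant"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "lognormal" and self.mean <= 0:
            raise ValueError("lognormal mean must be positive")

    def _draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        scale = abs(self.mean) * self.cv
        if self.kind == "constant" or scale == 0:
            return np.full(n, float(self.mean))
        if self.kind == "normal":
            return rng.normal(self.mean, scale, size=n)
        # lognormal parameterised so the arithmetic mean and CV match
        sigma2 = math.log(1.0 + self.cv**2)
        mu = math.log(self.mean) - sigma2 / 2.0
        return rng.lognormal(mu, math.sqrt(sigma2), size=n)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        values = self._draw(rng, n)
        if self.lower is None and self.upper is None:
            return values
        lo = -np.inf if self.lower is None else self.lower
        hi = np.inf if self.upper is None else self.upper
        for _ in range(100):
            bad = (values < lo) | (values >= hi)
            if not bad.any():
                return values
            values[bad] = self._draw(rng, int(bad.sum()))
        # pathological spec (bounds exclude nearly all mass): clip remainder
        return np.clip(values, lo, np.nextafter(hi, -np.inf))


@dataclass(frozen=True)
class PopulationSpec:
    """One synthetic particle/cell population.

    Either ``size_dist`` (projected area, um^2) or ``diameter_dist``
    (physical diameter, um) must be set; the missing one is derived via
    the projected-circle relation A = pi d^2 / 4.
    """

    label: str
    n: int = 0
    size_dist: Distribution | None = None
    deformation_dist: Distribution = field(
        default_factory=lambda: Distribution(0.05, 0.4, lower=0.0, upper=1.0))
    brightness_dist: Distribution = field(
        default_factory=lambda: Distribution(100.0, 0.05))
    area_ratio_dist: Distribution = field(
        default_factory=lambda: Distribution(1.01, 0.005, lower=1.0))
    diameter_dist: Distribution | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.size_dist is None and self.diameter_dist is None:
            raise ValueError("one of size_dist or diameter_dist is required")


def generate_population(spec: PopulationSpec,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample ``spec.n`` event records carrying the true population label.

    Returns a DataFrame with the canonical event columns; ``time_s`` is
    NaN (arrival times belong to the stream generator).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n
    if spec.diameter_dist is not None:
        diameter = spec.diameter_dist.sample(rng, n)
        if np.any(diameter <= 0):
            raise ValueError("sampled non-positive diameter; check distribution scale")
        area = math.pi * diameter**2 / 4.0
    else:
        area = spec.size_dist.sample(rng, n)
        if np.any(area <= 0):
            raise ValueError("sampled non-positive area; check distribution scale")
        diameter = 2.0 * np.sqrt(area / math.pi)
    table = pd.DataFrame({
        "id": np.arange(n),
        "time_s": np.full(n, np.nan),
        "label": spec.label,
        "area_um2": area,
        "deformation": spec.deformation_dist.sample(rng, n),
        "area_ratio": spec.area_ratio_dist.sample(rng, n),
        "brightness_au": spec.brightness_dist.sample(rng, n),
        "diameter_um": diameter,
    })
    if n and (table["deformation"].min() < 0 or table["deformation"].max() >= 1):
        raise ValueError("deformation distribution must be bounded to [0, 1)")
    return table


@dataclass(frozen=True)
class ArrivalStream:
    """Poisson arrival instants with per-arrival population labels."""

    times: np.ndarray
    labels: np.ndarray
    duration: float
    rate: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "labels", np.asarray(self.labels))
        if times.size and (np.any(np.diff(times) <= 0) or times[0] < 0
                           or times[-1] > self.duration):
            raise ValueError("times must be strictly increasing within [0, duration]")
        if len(times) != len(self.labels):
            raise ValueError("times and labels must have equal length")

    def __len__(self) -> int:
        return int(self.times.size)


def generate_arrival_stream(
    concentration: float,
    flow_rate: float,
    duration: float,
    mixture: dict[str, float] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ArrivalStream:
    """Homogeneous Poisson arrivals at rate = concentration x flow_rate.

    Parameters
    ----------
    concentration:
        Cells per m^3 (SI; divide a per-ml figure by 1e-6).
    flow_rate:
        Volumetric flow in m^3/s.
    duration:
        Simulated time, s.  ``duration == 0`` gives an empty stream.
    mixture:
        Population label -> weight (must sum to 1).  Labels are i.i.d.
    """
    if concentration < 0 or flow_rate < 0 or duration < 0:
        raise ValueError("concentration, flow_rate and duration must be >= 0")
    mixture = mixture or {"target": 1.0}
    weights = np.array(list(mixture.values()), dtype=float)
    if weights.size == 0 or abs(weights.sum() - 1.0) > 1e-9 or np.any(weights < 0):
        raise ValueError("mixture weights must be non-negative and sum to 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    rate = concentration * flow_rate
    if rate == 0 or duration == 0:
        return ArrivalStream(np.empty(0), np.empty(0, dtype=object), duration, rate)
    # draw inter-arrival gaps in blocks until duration is exceeded
    times: list[np.ndarray] = []
    t, block = 0.0, max(int(rate * duration * 1.2) + 16, 16)
    while t <= duration:
        gaps = rng.exponential(1.0 / rate, size=block)
        chunk = t + np.cumsum(gaps)
        times.append(chunk)
        t = chunk[-1]
    all_times = np.concatenate(times)
    all_times = all_times[all_times <= duration]
    labels = rng.choice(np.array(list(mixture.keys()), dtype=object),
                        size=all_times.size, p=weights)
    return ArrivalStream(all_times, labels, duration, rate)


def sample_events_for_stream(
    stream: ArrivalStream,
    populations: dict[str, PopulationSpec],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One event record per arrival, features drawn from its population.

    Aligns an arrival stream with a feature table so the sorter can be
    driven end-to-end: row i of the result carries ``stream.times[i]``
    and features sampled from ``populations[stream.labels[i]]``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(stream)
    frames = []
    order = np.arange(n)
    for label in populations:
        idx = order[stream.labels == label]
        if idx.size == 0:
            continue
        spec = populations[label]
        sub = generate_population(
            PopulationSpec(label=spec.label, n=idx.size, size_dist=spec.size_dist,
                           deformation_dist=spec.deformation_dist,
                           brightness_dist=spec.brightness_dist,
                           area_ratio_dist=spec.area_ratio_dist,
                           diameter_dist=spec.diameter_dist),
            rng=rng)
        sub.index = idx
        frames.append(sub)
    unknown = set(np.unique(stream.labels).tolist()) - set(populations)
    if unknown:
        raise ValueError(f"stream labels without a population spec: {sorted(unknown)}")
    if not frames:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    events = pd.concat(frames).sort_index()
    events["id"] = order
    events["time_s"] = stream.times
    events["label"] = np.asarray(stream.labels, dtype=object)
    return events.reset_index(drop=True)


# ---------------------------------------------------------------------------
# image rendering


@dataclass(frozen=True)
class EllipseObject:
    """A rendered object: an (optionally bullet-shaped) filled ellipse.

    center is (row, col) in pixels; a and b are the semi-axes along the
    rotated x'/y' axes; theta rotates x' from the column axis (radians).
    ``asymmetry`` linearly tapers the half-width front-to-rear to mimic
    the bullet shapes of advected cells (0 = true ellipse).
    """

    center: tuple[float, float]
    a: float
    b: float
    theta: float = 0.0
    intensity: float = 100.0
    asymmetry: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("semi-axes must be positive")
        if not -0.9 <= self.asymmetry <= 0.9:
            raise ValueError("asymmetry must be in [-0.9, 0.9]")


@dataclass
class FrameStack:
    """Grayscale frames plus calibration and per-frame ground truth."""

    frames: np.ndarray          # (n, h, w) uint8
    pixel_size: float           # um per pixel
    frame_rate: float           # frames per second
    ground_truth: list[list[dict]]
    background_level: float = 50.0

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if self.pixel_size <= 0 or self.frame_rate <= 0:
            raise ValueError("pixel_size and frame_rate must be positive")


def _coverage(obj: EllipseObject, shape: tuple[int, int],
              supersample: int = 4) -> tuple[np.ndarray, tuple[int, int]]:
    """Sub-pixel area coverage of the object over its bounding box."""
    r0, c0 = obj.center
    extent = max(obj.a, obj.b) * (1.0 + abs(obj.asymmetry)) + 2.0
    rmin = max(int(math.floor(r0 - extent)), 0)
    rmax = min(int(math.ceil(r0 + extent)) + 1, shape[0])
    cmin = max(int(math.floor(c0 - extent)), 0)
    cmax = min(int(math.ceil(c0 + extent)) + 1, shape[1])
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    rows = np.arange(rmin, rmax)[:, None] + offs[None, :]   # (H, s)
    cols = np.arange(cmin, cmax)[:, None] + offs[None, :]   # (W, s)
    rr = rows.reshape(-1)[:, None] - r0                     # (H*s, 1)
    cc = cols.reshape(-1)[None, :] - c0                     # (1, W*s)
    ct, st = math.cos(obj.theta), math.sin(obj.theta)
    xp = cc * ct + rr * st
    yp = -cc * st + rr * ct
    u = np.clip(xp / obj.a, -1.0, 1.0)
    b_eff = obj.b * (1.0 + obj.asymmetry * u)
    inside = (xp / obj.a) ** 2 + (yp / b_eff) ** 2 <= 1.0
    h, w = rmax - rmin, cmax - cmin
    cov = inside.reshape(h, supersample, w, supersample).mean(axis=(1, 3))
    return cov, (rmin, cmin)


def _ellipse_perimeter(a: float, b: float) -> float:
    big, small = max(a, b), min(a, b)
    return 4.0 * big * float(ellipe(1.0 - (small / big) ** 2))


def render_frames(
    objects: list[list[EllipseObject]],
    shape: tuple[int, int] = (128, 128),
    pixel_size: float = 0.34,
    frame_rate: float = 2700.0,
    noise_sd: float = 0.0,
    background_level: float = 50.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    supersample: int = 4,
) -> FrameStack:
    """Rasterise per-frame object lists into a noisy 8-bit frame stack.

    Each object is rendered with sub-pixel coverage anti-aliasing
    (``supersample`` x ``supersample`` samples per pixel; 1 gives a
    hard-edged binary fill): pixel value = background + (intensity -
    background) * coverage, then additive Gaussian noise of ``noise_sd``,
    clipped to [0, 255].
    Objects whose bounding box leaves the field are rejected with a
    warning (never silently cropped).  Ground truth records the rendered
    area (coverage sum) and, for true ellipses, the analytic perimeter
    and the resulting deformation.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(objects)
    frames = np.empty((n, *shape), dtype=np.uint8)
    ground_truth: list[list[dict]] = []
    for i, frame_objects in enumerate(objects):
        img = np.full(shape, float(background_level))
        truth: list[dict] = []
        for obj in frame_objects:
            extent = max(obj.a, obj.b) * (1.0 + abs(obj.asymmetry)) + 1.0
            r0, c0 = obj.center
            if (r0 - extent < 0 or r0 + extent > shape[0] - 1
                    or c0 - extent < 0 or c0 + extent > shape[1] - 1):
                warnings.warn(
                    f"object at {obj.center} extends outside the {shape} field; "
                    "skipped", stacklevel=2)
                continue
            cov, (rmin, cmin) = _coverage(obj, shape, supersample=supersample)
            h, w = cov.shape
            img[rmin:rmin + h, cmin:cmin + w] += (obj.intensity - background_level) * cov
            area_px2 = float(cov.sum())
            record = asdict(obj) | {"frame": i, "area_px2": area_px2}
            if obj.asymmetry == 0.0:
                perimeter = _ellipse_perimeter(obj.a, obj.b)
                record["perimeter_px"] = perimeter
                analytic_area = math.pi * obj.a * obj.b
                record["deformation"] = max(
                    0.0, 1.0 - 2.0 * math.sqrt(math.pi * analytic_area) / perimeter)
            truth.append(record)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=shape)
        frames[i] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        ground_truth.append(truth)
    return FrameStack(frames, pixel_size, frame_rate, ground_truth,
                      background_level=background_level)


def write_frame_stack(stack: FrameStack, tiff_path, sidecar_path=None) -> None:
    """Write frames as a multi-page TIFF plus a JSON ground-truth sidecar."""
    import tifffile

    tifffile.imwrite(tiff_path, stack.frames)
    if sidecar_path is None:
        sidecar_path = str(tiff_path) + ".json"
    meta = {
        "pixel_size_um": stack.pixel_size,
        "frame_rate_fps": stack.frame_rate,
        "background_level": stack.background_level,
        "ground_truth": stack.ground_truth,
    }
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)


def read_frame_stack(tiff_path, sidecar_path=None) -> FrameStack:
    import tifffile

    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    if sidecar_path is None:
        sidecar_path = str(tiff_path) + ".json"
    try:
        with open(sidecar_path, encoding="utf-8") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        meta = {}
    return FrameStack(
        frames=np.asarray(frames),
        pixel_size=meta.get("pixel_size_um", 0.34),
        frame_rate=meta.get("frame_rate_fps", 2700.0),
        ground_truth=meta.get("ground_truth", [[] for _ in range(len(frames))]),
        background_level=meta.get("background_level", 50.0),
    )


# ---------------------------------------------------------------------------
# canned study populations


def bead_mixture_populations(n_each: int = 10_000, seed: int = 0,
                             delta_d: float = 1.7,
                             cv: float = 0.032) -> dict[str, PopulationSpec]:
    """Two closely-sized microgel bead populations, modal diameters 1.7 um apart.

    The smaller population sits at 12.6 um (projected area ~125 um^2, in
    the middle of a 115-135 um^2 sorting gate); the larger at 14.3 um.
    Size CV defaults to 3.2 %.
    """
    d_small = 12.6
    return {
        "small": PopulationSpec(
            label="small", n=n_each, seed=seed,
            diameter_dist=Distribution(d_small, cv),
            deformation_dist=Distribution(0.02, 0.4, lower=0.0, upper=1.0),
            brightness_dist=Distribution(90.0, 0.04),
            area_ratio_dist=Distribution(1.01, 0.005, lower=1.0)),
        "large": PopulationSpec(
            label="large", n=n_each, seed=None if seed is None else seed + 1,
            diameter_dist=Distribution(d_small + delta_d, cv),
            deformation_dist=Distribution(0.02, 0.4, lower=0.0, upper=1.0),
            brightness_dist=Distribution(90.0, 0.04),
            area_ratio_dist=Distribution(1.01, 0.005, lower=1.0)),
    }


def blood_populations(n_total: int = 10_000, seed: int = 0) -> dict[str, PopulationSpec]:
    """RBC-depleted blood as three populations in the deformation-size plane.

    Modes sit at the centres of the published sorting gates (lymphocytes
    23-45 um^2 / deformation < 0.1; myeloid 50-100 um^2 / < 0.12) with
    red cells larger-deformation, and brightness modes that separate
    neutrophils (100-115 a.u.) from platelets (80-110 a.u.).
    """

    def spec(label, frac, area_mean, area_cv, defo_mean, bright_mean):
        return PopulationSpec(
            label=label, n=int(round(n_total * frac)), seed=seed,
            size_dist=Distribution(area_mean, area_cv),
            deformation_dist=Distribution(defo_mean, 0.35, lower=0.0, upper=1.0),
            brightness_dist=Distribution(bright_mean, 0.03),
            area_ratio_dist=Distribution(1.02, 0.01, lower=1.0))

    return {
        "lymphocyte": spec("lymphocyte", 0.25, 34.0, 0.12, 0.05, 95.0),
        "myeloid": spec("myeloid", 0.35, 75.0, 0.12, 0.07, 107.5),
        "rbc": spec("rbc", 0.40, 40.0, 0.15, 0.25, 120.0),
    }


def whole_blood_populations(n_total: int = 100_000, wbc_fraction: float = 0.0009,
                            seed: int = 0) -> dict[str, PopulationSpec]:
    """Diluted whole blood: a rare WBC fraction (0.09 %) among red cells."""
    wbc = PopulationSpec(
        label="wbc", n=int(round(n_total * wbc_fraction)), seed=seed,
        size_dist=Distribution(60.0, 0.25),
        deformation_dist=Distribution(0.05, 0.4, lower=0.0, upper=1.0),
        brightness_dist=Distribution(105.0, 0.04),
        area_ratio_dist=Distribution(1.02, 0.01, lower=1.0))
    rbc = PopulationSpec(
        label="rbc", n=n_total - wbc.n, seed=None if seed is None else seed + 1,
        size_dist=Distribution(40.0, 0.15),
        deformation_dist=Distribution(0.25, 0.3, lower=0.0, upper=1.0),
        brightness_dist=Distribution(120.0, 0.04),
        area_ratio_dist=Distribution(1.02, 0.01, lower=1.0))
    return {"wbc": wbc, "rbc": rbc}
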