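"""Gates, event classification and sorting performance metrics.

A :class:`Gate` combines axis-interval criteria (area, deformation,
brightness) and/or a polygon in the deformation-size plane.  The area
ratio bound is not a selection criterion but a data-quality pre-filter:
events failing it are excluded from both the numerator and denominator
of purity, mirroring its role as a plotting/filtering gate.

Metric conventions:

* initial purity IP  = % of (quality-filtered) events inside the gate
  before sorting;
* target purity TP   = same percentage in the sorted sample;
* enrichment         = TP / IP (fold);
* recovery           = 100 x collected / reported-sorted;
* CV                 = 100 x sample SD (n-1) / mean.

Interval criteria are half-open [lo, hi); "< x" bounds are strict.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Gate",
    "SortReport",
    "apply_gate",
    "purity",
    "enrichment",
    "recovery",
    "coefficient_of_variation",
    "kde_density",
    "find_modes",
]


@dataclass(frozen=True)
class Gate:
    """A multi-parameter selection predicate over an event table.

    At least one selection criterion (area_range, deformation_max,
    brightness_range or polygon) must be set.  ``polygon`` is a list of
    (area_um2, deformation) vertices of a simple polygon.
    """

    label: str = "target"
    area_range: tuple[float, float] | None = None      # [lo, hi) um^2
    deformation_max: float | None = None                # strict upper bound
    brightness_range: tuple[float, float] | None = None  # [lo, hi) a.u.
    area_ratio_max: float = 1.08                        # quality pre-filter
    polygon: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        for name in ("area_range", "brightness_range"):
            rng = getattr(self, name)
            if rng is not None:
                lo, hi = rng
                if not lo < hi:
                    raise ValueError(f"{name} must be ordered (lo < hi), got {rng}")
                object.__setattr__(self, name, (float(lo), float(hi)))
        if self.polygon is not None:
            poly = tuple((float(a), float(d)) for a, d in self.polygon)
            if len(poly) < 3:
                raise ValueError("polygon needs >= 3 vertices")
            object.__setattr__(self, "polygon", poly)
        if (self.area_range is None and self.deformation_max is None
                and self.brightness_range is None and self.polygon is None):
            raise ValueError("gate must set at least one selection criterion")
        if self.area_ratio_max < 1:
            raise ValueError("area_ratio_max must be >= 1")

    # -- masks -------------------------------------------------------------

    def _column(self, events: pd.DataFrame, name: str) -> np.ndarray:
        if name not in events.columns:
            raise KeyError(f"gate references column {name!r} absent from the table")
        return events[name].to_numpy(dtype=float)

    def quality_mask(self, events: pd.DataFrame) -> np.ndarray:
        """Events passing the area-ratio quality filter (strict '<' bound)."""
        return self._column(events, "area_ratio") < self.area_ratio_max

    def criteria_mask(self, events: pd.DataFrame) -> np.ndarray:
        """Events satisfying every set selection criterion."""
        mask = np.ones(len(events), dtype=bool)
        if self.area_range is not None:
            a = self._column(events, "area_um2")
            mask &= (a >= self.area_range[0]) & (a < self.area_range[1])
        if self.deformation_max is not None:
            mask &= self._column(events, "deformation") < self.deformation_max
        if self.brightness_range is not None:
            b = self._column(events, "brightness_au")
            mask &= (b >= self.brightness_range[0]) & (b < self.brightness_range[1])
        if self.polygon is not None:
            from matplotlib.path import Path

            pts = np.column_stack([self._column(events, "area_um2"),
                                   self._column(events, "deformation")])
            mask &= Path(np.asarray(self.polygon)).contains_points(pts)
        return mask

    def to_dict(self) -> dict:
        return asdict(self)


def apply_gate(events: pd.DataFrame, gate: Gate) -> np.ndarray:
    """Boolean mask of events selected by the gate.

    The quality pre-filter is applied first; an event passes iff it
    survives the filter AND meets all selection criteria.
    """
    return gate.quality_mask(events) & gate.criteria_mask(events)


def purity(events: pd.DataFrame, gate: Gate) -> float:
    """Percentage of events inside the gate.

    Quality-filter failures are excluded from numerator and denominator
    alike.  Raises on an empty table (or one entirely removed by the
    quality filter) since the ratio is undefined.
    """
    if len(events) == 0:
        raise ValueError("purity of an empty event table is undefined")
    quality = gate.quality_mask(events)
    n_quality = int(quality.sum())
    if n_quality == 0:
        raise ValueError("no events pass the area-ratio quality filter")
    n_in = int((quality & gate.criteria_mask(events)).sum())
    return 100.0 * n_in / n_quality


def enrichment(initial_purity: float, target_purity: float) -> float:
    """Fold enrichment TP / IP.

    IP = 0 (a vanishingly rare target) is reported as +inf with a
    warning rather than an error, matching how a measured-zero initial
    fraction is treated in practice.
    """
    if initial_purity < 0 or target_purity < 0:
        raise ValueError("purities must be non-negative percentages")
    if initial_purity == 0:
        warnings.warn("initial purity is 0 %; enrichment reported as inf",
                      stacklevel=2)
        return math.inf
    return target_purity / initial_purity


def recovery(n_collected: int, n_reported_sorted: int) -> float:
    """Percentage of reported-sorted cells actually collected in the target tube."""
    if n_reported_sorted <= 0:
        raise ValueError("n_reported_sorted must be positive")
    if n_collected < 0:
        raise ValueError("n_collected must be >= 0")
    return 100.0 * n_collected / n_reported_sorted


def coefficient_of_variation(values) -> float:
    """Sample CV in percent: 100 x SD(n-1) / mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * values.std(ddof=1) / abs(mean)


def kde_density(values, bandwidth: float, grid: np.ndarray | None = None,
                n_grid: int = 2048) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density estimate with an absolute bandwidth.

    ``bandwidth`` is the kernel standard deviation in data units (not a
    Scott/Silverman factor).  Returns ``(grid, density)``; the trapezoidal
    integral of the density over the returned grid is 1 to ~1e-3.
    """
    from scipy.stats import gaussian_kde

    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("KDE needs at least 2 values")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    sd = values.std(ddof=1)
    if sd == 0:
        # degenerate sample: the KDE is a single Gaussian bump
        if grid is None:
            c = values[0]
            grid = np.linspace(c - 6 * bandwidth, c + 6 * bandwidth, n_grid)
        density = np.exp(-0.5 * ((grid - values[0]) / bandwidth) ** 2)
        density /= bandwidth * math.sqrt(2 * math.pi)
        return grid, density
    kde = gaussian_kde(values, bw_method=bandwidth / sd)
    if grid is None:
        lo = values.min() - 5 * bandwidth
        hi = values.max() + 5 * bandwidth
        grid = np.linspace(lo, hi, n_grid)
    return grid, kde(grid)


def find_modes(grid: np.ndarray, density: np.ndarray,
               min_prominence_frac: float = 0.05) -> np.ndarray:
    """Abscissae of local maxima of a density curve, by peak prominence."""
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(density, prominence=min_prominence_frac * density.max())
    return np.asarray(grid)[peaks]


@dataclass
class SortReport:
    """Aggregated outcome of one sorting run."""

    n_total: int
    n_gated: int
    n_actuated: int
    n_aborted: int
    n_target_outlet: int
    n_cosorted: int
    initial_purity: float
    target_purity: float | None
    enrichment: float | None
    recovery: float | None
    throughput: float
    pulse_contamination_rate: float | None
    duration_s: float
    seed: int | None = None
    config_hash: str | None = None
    cv_before: float | None = None
    cv_after: float | None = None

    def __post_init__(self) -> None:
        for name in ("initial_purity", "target_purity", "recovery"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 100 + 1e-9:
                raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")

    def to_dict(self) -> dict:
        return asdict(self)
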