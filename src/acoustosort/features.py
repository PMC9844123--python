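"""Real-time deformability-cytometry image pipeline, re-implemented offline.

The measurement chain mirrors the on-line system: temporal-median
background estimation, background subtraction, thresholding, connected
components, a sub-pixel (marching squares) boundary per component plus
its convex hull, and four morphometric features per detected object:

* projected area A (um^2),
* deformation D = 1 - 2 sqrt(pi A) / l (circularity complement),
* area ratio = hull area / raw contour area (a quality score >= 1),
* mean brightness inside the raw contour (a.u., raw grayscale).

Gating features (area, perimeter and hence deformation) are computed on
the convex hull; the area ratio quantifies how far the raw contour
departs from it, which is exactly what the downstream quality filter
(area ratio < 1.05-1.08) bounds.  Raw-contour values are kept alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from skimage import measure

__all__ = [
    "Contour",
    "Detection",
    "FeatureConfig",
    "estimate_background",
    "detect_contour",
    "deformation",
    "area_ratio",
    "brightness",
    "extract_events",
]


@dataclass(frozen=True)
class Contour:
    """A closed polygon in pixel coordinates (row, col), 0-based.

    Vertices need not repeat the first point; area and perimeter treat
    the polygon as closed.
    """

    vertices: np.ndarray
    is_hull: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("a contour needs >= 3 (row, col) vertices")
        object.__setattr__(self, "vertices", v)

    @property
    def area(self) -> float:
        """Enclosed area by the shoelace formula (px^2)."""
        r, c = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))

    @property
    def perimeter(self) -> float:
        """Closed polygonal arc length (px)."""
        diffs = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())

    @property
    def centroid(self) -> tuple[float, float]:
        """Area centroid (row, col) of the closed polygon."""
        v = np.vstack([self.vertices, self.vertices[:1]])
        r, c = v[:, 0], v[:, 1]
        cross = r[:-1] * c[1:] - r[1:] * c[:-1]
        a = cross.sum() / 2.0
        if abs(a) < 1e-12:
            return tuple(self.vertices.mean(axis=0))
        cr = ((r[:-1] + r[1:]) * cross).sum() / (6.0 * a)
        cc = ((c[:-1] + c[1:]) * cross).sum() / (6.0 * a)
        return (float(cr), float(cc))

    def convex_hull(self) -> "Contour":
        hull = ConvexHull(self.vertices)
        return Contour(self.vertices[hull.vertices], is_hull=True)


@dataclass(frozen=True)
class Detection:
    """One object in one frame: raw boundary, its hull, and pixel support."""

    raw: Contour
    hull: Contour
    pixel_count: int


def estimate_background(frames: np.ndarray, window: int | None = None) -> np.ndarray:
    """Per-pixel temporal median background.

    With ``window=None`` (default) the median is taken over the whole
    stack and a single 2-D image is returned; a finite window returns one
    background per frame (median over the centred window, truncated at
    the stack edges).  The median tolerates sparse moving objects: a cell
    present in a minority of frames at a given pixel does not shift it.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError(
            "background estimation needs >= 2 frames; for single images "
            "supply an explicit background to detect_contour")
    if window is None:
        return np.median(frames, axis=0)
    if window < 2:
        raise ValueError("window must be >= 2")
    n = frames.shape[0]
    half = window // 2
    out = np.empty_like(frames, dtype=float)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i - half + window)
        out[i] = np.median(frames[lo:hi], axis=0)
    return out


def _component_contour(diff: np.ndarray, component: np.ndarray,
                       bbox: tuple[int, int, int, int]) -> Contour | None:
    """Sub-pixel boundary of one connected component.

    Marching squares is run on the component's |difference| image at half
    its peak contrast, which places the polygon on the mid-level edge of
    the object rather than on the detection-threshold level set.  The
    sub-image is zero-padded so contours always close.
    """
    rmin, cmin, rmax, cmax = bbox
    sub = np.where(component[rmin:rmax, cmin:cmax],
                   diff[rmin:rmax, cmin:cmax], 0.0)
    sub = np.pad(sub, 1)
    level = 0.5 * float(sub.max())
    contours = measure.find_contours(sub, level=level)
    if not contours:
        return None
    longest = max(contours, key=len)
    if len(longest) < 3:
        return None
    verts = longest[:-1] if np.allclose(longest[0], longest[-1]) else longest
    verts = verts + np.array([rmin - 1.0, cmin - 1.0])
    return Contour(verts)


def detect_contour(
    frame: np.ndarray,
    background: np.ndarray,
    threshold: float = 10.0,
    min_area_px: int = 10,
) -> list[Detection]:
    """Detect objects in one frame against a background image.

    The absolute background-subtracted image is binarised at
    ``threshold`` intensity units; connected components smaller than
    ``min_area_px`` pixels are discarded; each surviving component yields
    its raw sub-pixel boundary and the boundary's convex hull.  Results
    are ordered by enclosed area, largest first.  A blank frame gives an
    empty list.  Objects must be brighter or darker than background by
    about twice the threshold for the half-contrast boundary to be
    meaningful.
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background must have the same shape")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    diff = np.abs(frame - background)
    mask = diff >= threshold
    labels, n_labels = measure.label(mask, return_num=True)
    detections: list[Detection] = []
    for lab in range(1, n_labels + 1):
        component = labels == lab
        count = int(component.sum())
        if count < min_area_px:
            continue
        rows, cols = np.nonzero(component)
        bbox = (rows.min(), cols.min(), rows.max() + 1, cols.max() + 1)
        raw = _component_contour(diff, component, bbox)
        if raw is None:
            continue
        try:
            hull = raw.convex_hull()
        except Exception:
            continue
        detections.append(Detection(raw=raw, hull=hull, pixel_count=count))
    detections.sort(key=lambda d: d.raw.area, reverse=True)
    return detections


def deformation(area: float, perimeter: float) -> float:
    """Deformation D = 1 - 2 sqrt(pi A) / l.

    Zero for a circle, approaching 1 for extreme shapes.  Discretised
    perimeters can underestimate l and make D slightly negative; the raw
    value is returned so callers can decide whether to clamp (reports do,
    stored tables keep the raw number).
    """
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return 1.0 - 2.0 * math.sqrt(math.pi * area) / perimeter


def area_ratio(hull: Contour, raw: Contour) -> float:
    """Convex-hull area over raw contour area (>= 1 up to 1e-9 tolerance)."""
    raw_area = raw.area
    if raw_area <= 0:
        raise ValueError("raw contour encloses zero area")
    ratio = hull.area / raw_area
    if ratio < 1.0 - 1e-9:
        raise ValueError(
            f"hull area smaller than raw area (ratio {ratio}); "
            "is 'hull' really the convex hull of 'raw'?")
    return max(ratio, 1.0)


def brightness(frame: np.ndarray, contour: Contour) -> float:
    """Mean raw grayscale over the pixels inside the (raw) contour.

    Uses the original image, not the background-subtracted one.  Pixels
    whose centres fall strictly inside the polygon count.
    """
    from skimage.draw import polygon as draw_polygon

    frame = np.asarray(frame)
    rr, cc = draw_polygon(contour.vertices[:, 0], contour.vertices[:, 1],
                          shape=frame.shape)
    if rr.size == 0:
        raise ValueError("contour encloses no pixels")
    return float(frame[rr, cc].mean())


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the extraction pipeline.

    pixel_size in um/px (default 0.34), detection threshold in intensity
    units above background, minimum component size in pixels.  Tracking
    merges re-detections of one object across consecutive frames when the
    centroid moves less than ``track_max_move_px`` (set
    ``track_max_frame_gap=0`` to disable); the representative frame is
    the one whose centroid is nearest the image centre column, standing
    in for the single evaluation point of the real-time system.
    """

    threshold: float = 10.0
    min_area_px: int = 10
    pixel_size: float = 0.34
    frame_rate: float = 2700.0
    track_max_frame_gap: int = 1
    track_max_move_px: float = 20.0
    clamp_deformation: bool = True


def _detection_features(det: Detection, frame: np.ndarray,
                        cfg: FeatureConfig) -> dict:
    hull_area_px = det.hull.area
    hull_perim_px = det.hull.perimeter
    raw_area_px = det.raw.area
    px2 = cfg.pixel_size**2
    d_raw = deformation(hull_area_px, hull_perim_px)
    area_um2 = hull_area_px * px2
    cr, cc = det.hull.centroid
    return {
        "area_um2": area_um2,
        "perimeter_um": hull_perim_px * cfg.pixel_size,
        "deformation": max(0.0, d_raw) if cfg.clamp_deformation else d_raw,
        "deformation_raw": d_raw,
        "area_ratio": area_ratio(det.hull, det.raw),
        "brightness_au": brightness(frame, det.raw),
        "area_raw_um2": raw_area_px * px2,
        "diameter_um": 2.0 * math.sqrt(area_um2 / math.pi),
        "centroid_row_px": cr,
        "centroid_col_px": cc,
    }


def extract_events(
    stack,
    config: FeatureConfig | None = None,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run the full pipeline over a frame stack.

    Parameters
    ----------
    stack:
        A :class:`~acoustosort.synthetic.FrameStack` or a bare (n, h, w)
        array (then the default pixel size / frame rate apply).
    config:
        :class:`FeatureConfig`; defaults used when omitted.
    background:
        Explicit background image; estimated from the stack (full-stack
        temporal median) when omitted.

    Returns one row per deduplicated object with times derived from the
    frame rate.  An empty stack yields an empty table.
    """
    cfg = config or FeatureConfig()
    if hasattr(stack, "frames"):
        frames = np.asarray(stack.frames)
        pixel_size = stack.pixel_size
        frame_rate = stack.frame_rate
        if pixel_size != cfg.pixel_size or frame_rate != cfg.frame_rate:
            cfg = FeatureConfig(
                threshold=cfg.threshold, min_area_px=cfg.min_area_px,
                pixel_size=pixel_size, frame_rate=frame_rate,
                track_max_frame_gap=cfg.track_max_frame_gap,
                track_max_move_px=cfg.track_max_move_px,
                clamp_deformation=cfg.clamp_deformation)
    else:
        frames = np.asarray(stack)
    columns = ["id", "time_s", "frame_index", "area_um2", "perimeter_um",
               "deformation", "deformation_raw", "area_ratio", "brightness_au",
               "area_raw_um2", "diameter_um", "centroid_row_px",
               "centroid_col_px", "n_frames"]
    if frames.size == 0 or frames.shape[0] == 0:
        return pd.DataFrame(columns=columns)
    if background is None:
        background = estimate_background(frames)
    rows: list[dict] = []
    for i in range(frames.shape[0]):
        bg_i = background[i] if background.ndim == 3 else background
        for det in detect_contour(frames[i], bg_i, threshold=cfg.threshold,
                                  min_area_px=cfg.min_area_px):
            rec = _detection_features(det, frames[i], cfg)
            rec["frame_index"] = i
            rows.append(rec)
    if not rows:
        return pd.DataFrame(columns=columns)
    table = pd.DataFrame(rows)
    table = _deduplicate(table, cfg, frames.shape[2])
    table["time_s"] = table["frame_index"] / cfg.frame_rate
    table.insert(0, "id", np.arange(len(table)))
    return table[columns].reset_index(drop=True)


def _deduplicate(table: pd.DataFrame, cfg: FeatureConfig,
                 frame_width: int) -> pd.DataFrame:
    """Merge per-frame detections of the same object into one event.

    Greedy nearest-neighbour tracking: a detection joins an open track if
    the frame gap is within ``track_max_frame_gap`` and its centroid is
    within ``track_max_move_px`` of the track's last position.  Each
    track keeps the detection closest to the image centre column (the
    stand-in for the ROI midpoint).
    """
    if cfg.track_max_frame_gap <= 0:
        table = table.copy()
        table["n_frames"] = 1
        return table
    table = table.sort_values(["frame_index", "centroid_row_px"]).reset_index(drop=True)
    track_id = np.full(len(table), -1, dtype=int)
    open_tracks: list[dict] = []   # {'id', 'frame', 'row', 'col'}
    next_id = 0
    for idx in range(len(table)):
        f = int(table.at[idx, "frame_index"])
        r, c = table.at[idx, "centroid_row_px"], table.at[idx, "centroid_col_px"]
        best, best_dist = None, np.inf
        for tr in open_tracks:
            gap = f - tr["frame"]
            if gap < 1 or gap > cfg.track_max_frame_gap:
                continue
            dist = math.hypot(r - tr["row"], c - tr["col"])
            if dist <= cfg.track_max_move_px and dist < best_dist:
                best, best_dist = tr, dist
        if best is None:
            best = {"id": next_id}
            next_id += 1
            open_tracks.append(best)
        best.update(frame=f, row=r, col=c)
        track_id[idx] = best["id"]
        open_tracks = [tr for tr in open_tracks
                       if f - tr["frame"] <= cfg.track_max_frame_gap]
        if best not in open_tracks:
            open_tracks.append(best)
    table = table.assign(_track=track_id)
    centre = frame_width / 2.0
    table["_off_centre"] = (table["centroid_col_px"] - centre).abs()
    sizes = table.groupby("_track")["_track"].transform("size")
    table["n_frames"] = sizes
    best_rows = table.sort_values("_off_centre").groupby("_track", as_index=False).head(1)
    return (best_rows.sort_values("frame_index")
            .drop(columns=["_track", "_off_centre"])
            .reset_index(drop=True))
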