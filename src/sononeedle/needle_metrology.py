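"""Edge-based needle length measurement from B-mode frames.

The readout chain is: Sobel gradient magnitude -> threshold (Otsu by
default) -> connected components -> tip = topmost supra-threshold pixel of
each component (apex of the triangular footprint), with a one-row gray
mid-level refinement that removes the half-kernel bias of gradient-based
localisation -> length = (base_row - tip_row) * pixel pitch -> temporal
average over frames acquired in a short interval -> SR = (l1 - l0)/l0
against the same needle's own baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import InvalidGeometryError, InvalidInputError
from .ultrasound_sim import BModeFrame, NeedleGeometry

__all__ = [
    "EdgeMap",
    "TipDetection",
    "LengthMeasurement",
    "SRReading",
    "sobel_edges",
    "locate_needles",
    "measure_length",
    "temporal_average",
    "compute_sr",
    "measure_frame",
    "measure_sequence",
]


@dataclass
class EdgeMap:
    """Gradient magnitude of a frame plus the binarisation threshold used."""

    gradient_magnitude: np.ndarray
    threshold: float | None = None
    source: np.ndarray | None = None  # gray frame, for tip refinement


@dataclass(frozen=True)
class TipDetection:
    """One needle: tip and base pixel coordinates, detection confidence."""

    tip: tuple
    base: tuple
    confidence: float
    needle_id: int

    def __post_init__(self):
        if self.tip[0] >= self.base[0]:
            raise InvalidGeometryError("tip row must be above the base row")
        if not 0.0 <= self.confidence <= 1.0:
            raise InvalidInputError("confidence must lie in [0, 1]")


@dataclass(frozen=True)
class LengthMeasurement:
    """Temporal average of per-frame lengths of one needle (mm)."""

    length: float
    n_frames: int
    per_frame_lengths: tuple
    needle_id: int = 0


@dataclass(frozen=True)
class SRReading:
    """Swelling ratio of one needle against its own baseline length."""

    l0: float
    l1: float
    sr: float
    timestamp: float = 0.0

    @property
    def sr_percent(self) -> float:
        return 100.0 * self.sr


# ---------------------------------------------------------------------------

def _frame_pixels(frame) -> np.ndarray:
    return frame.pixels if isinstance(frame, BModeFrame) else np.asarray(frame)


def sobel_edges(frame) -> EdgeMap:
    """Gradient magnitude from the standard (unnormalised) 3x3 Sobel
    kernels with reflective border handling.

    A vertical step edge of height h responds with magnitude 4h on the
    columns bounding the step.
    """
    px = _frame_pixels(frame).astype(float)
    if px.ndim != 2 or min(px.shape) < 3:
        raise InvalidInputError("frame must be 2-D and at least 3x3")
    gr = ndimage.sobel(px, axis=0, mode="reflect")
    gc = ndimage.sobel(px, axis=1, mode="reflect")
    return EdgeMap(gradient_magnitude=np.hypot(gr, gc), source=px)


def _refine_tip(gray: np.ndarray, row: int, col: int, peak_gray: float,
                max_descent: int = 12, col_halfwin: int = 2) -> tuple[int, int]:
    """Move the tip to the first row whose gray crosses the mid level.

    Gradient magnitude peaks on the background pixel adjacent to a bright
    apex (the 3x3 kernel straddles the edge), so the raw topmost
    supra-threshold pixel sits above the needle -- by one row on clean
    frames, occasionally more when a speckle grain touches the tip.  The
    apex is a single pixel wide, so a small column window around the
    candidate is scanned; the first half-maximum gray fixes the tip row
    (and column) with pixel accuracy.
    """
    level = 0.5 * (float(np.median(gray)) + peak_gray)
    c0 = max(col - col_halfwin, 0)
    c1 = min(col + col_halfwin + 1, gray.shape[1])
    for r in range(max(row - 1, 0), min(row + max_descent, gray.shape[0])):
        strip = gray[r, c0:c1]
        if strip.max() >= level:
            return r, c0 + int(np.argmax(strip))
    return row, col


def locate_needles(edges: EdgeMap, expected: NeedleGeometry, substrate_row: int,
                   threshold: float | str = "otsu", min_area: int = 30,
                   pixel_pitch: float = 0.015, refine: bool = True,
                   gray_floor: float | None = 75.0) -> list[TipDetection]:
    """Detect needle footprints in an edge map and localise their apices.

    Candidate components are connected supra-threshold regions above the
    substrate row.  Speckle rejection uses two cues: a brightness gate
    (edge pixels must border pixels brighter than ``gray_floor`` -- the
    silica contrast contract puts needle echoes at gray >= 80 while fully
    developed speckle almost never exceeds ~70; pass ``None`` to disable,
    e.g. for pristine-hydrogel frames) and extent (a component must span
    at least a third of the expected needle height; speckle grains are
    point-spread-function sized).  Components
    whose column spans substantially overlap are merged with a confidence
    penalty.  The tip is the topmost supra-threshold pixel of the
    component, ties broken by the column nearest the component centroid.
    Detections are sorted by column.  Returns an empty list when nothing
    exceeds the threshold.
    """
    grad = edges.gradient_magnitude
    rows, cols = grad.shape
    if not 0 <= substrate_row < rows:
        raise InvalidInputError("substrate_row outside frame")
    if threshold == "otsu":
        thr = float(threshold_otsu(grad))
    else:
        thr = float(threshold)
    edges.threshold = thr

    binary = grad > thr
    if gray_floor is not None and edges.source is not None:
        bright = edges.source >= gray_floor
        binary &= ndimage.binary_dilation(bright, iterations=2)
    binary[substrate_row + 1:, :] = False
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []

    min_extent = max(3, int(round(expected.height / pixel_pitch / 3.0)))
    comps = []
    for lab in range(1, n + 1):
        rr, cc = np.nonzero(labels == lab)
        if rr.size < min_area or np.ptp(rr) < min_extent:
            continue
        comps.append({"rows": rr, "cols": cc, "penalty": 1.0})
    # merge components whose column spans mostly coincide (split outlines
    # of one needle)
    comps.sort(key=lambda c: c["cols"].min())
    merged = []
    for comp in comps:
        if merged:
            prev = merged[-1]
            overlap = prev["cols"].max() - comp["cols"].min() + 1
            width = min(np.ptp(prev["cols"]), np.ptp(comp["cols"])) + 1
            if overlap > 0.5 * width:
                prev["rows"] = np.concatenate([prev["rows"], comp["rows"]])
                prev["cols"] = np.concatenate([prev["cols"], comp["cols"]])
                prev["penalty"] *= 0.5
                continue
        merged.append(comp)

    detections = []
    for i, comp in enumerate(merged):
        rr, cc = comp["rows"], comp["cols"]
        top = rr.min()
        top_cols = cc[rr == top]
        centroid_col = cc.mean()
        tip_col = int(top_cols[np.argmin(np.abs(top_cols - centroid_col))])
        tip_row = int(top)
        peak = float(grad[rr, cc].max())
        if refine and edges.source is not None:
            region = edges.source[rr, cc]
            tip_row, tip_col = _refine_tip(edges.source, tip_row, tip_col,
                                           float(region.max()))
        if tip_row >= substrate_row:
            continue
        confidence = max(0.0, 1.0 - thr / peak) * comp["penalty"]
        detections.append(TipDetection(tip=(tip_row, tip_col),
                                       base=(int(substrate_row), tip_col),
                                       confidence=confidence, needle_id=i))
    detections.sort(key=lambda d: d.tip[1])
    return [TipDetection(d.tip, d.base, d.confidence, i)
            for i, d in enumerate(detections)]


def measure_length(detection: TipDetection, pitch: float) -> float:
    """Needle length in mm: (base_row - tip_row) * pitch."""
    if pitch <= 0:
        raise InvalidInputError("pixel pitch must be > 0")
    d_rows = detection.base[0] - detection.tip[0]
    if d_rows < 0:
        raise InvalidGeometryError("tip lies below the base")
    return d_rows * pitch


def temporal_average(per_frame_lengths, needle_id: int = 0) -> LengthMeasurement:
    """Arithmetic mean of per-frame lengths (the multi-frame acquisition
    average); the individual values are retained."""
    vals = [float(v) for v in per_frame_lengths]
    if not vals:
        raise InvalidInputError("need at least one per-frame length")
    return LengthMeasurement(length=float(np.mean(vals)), n_frames=len(vals),
                             per_frame_lengths=tuple(vals), needle_id=needle_id)


def compute_sr(l0: float, l1: float, timestamp: float = 0.0) -> SRReading:
    """Swelling ratio (l1 - l0)/l0 against the needle's own baseline."""
    if l0 <= 0:
        raise InvalidInputError("baseline length l0 must be > 0")
    return SRReading(l0=l0, l1=l1, sr=(l1 - l0) / l0, timestamp=timestamp)


# ---------------------------------------------------------------------------
# frame-level conveniences
# ---------------------------------------------------------------------------

def measure_frame(frame, geometry: NeedleGeometry, substrate_row: int,
                  threshold: float | str = "otsu", refine: bool = True,
                  gray_floor: float | None = "auto") -> list[tuple[int, float]]:
    """Detect and measure every needle in one frame.

    The brightness gate is applied only to silica-loaded arrays (pristine
    hydrogel sits below it by design).  Returns ``(needle_index,
    length_mm)`` pairs sorted by column.
    """
    pitch = frame.pixel_pitch if isinstance(frame, BModeFrame) else 0.015
    if gray_floor == "auto":
        gray_floor = 75.0 if geometry.has_silica else None
    edges = sobel_edges(frame)
    dets = locate_needles(edges, geometry, substrate_row, threshold=threshold,
                          refine=refine, pixel_pitch=pitch, gray_floor=gray_floor)
    return [(d.needle_id, measure_length(d, pitch)) for d in dets]


def measure_sequence(frames, geometry: NeedleGeometry, substrate_row: int,
                     threshold: float | str = "otsu") -> list[LengthMeasurement]:
    """Measure each needle across a short frame sequence and average.

    Needles are matched across frames by column order; frames where the
    detection count differs from the expected needle count are skipped
    (occluded or failed detections) as long as at least one frame remains.
    """
    per_needle: dict[int, list[float]] = {}
    for frame in frames:
        results = measure_frame(frame, geometry, substrate_row, threshold)
        if geometry.count and len(results) != geometry.count:
            continue
        for needle_id, length in results:
            per_needle.setdefault(needle_id, []).append(length)
    if not per_needle:
        raise InvalidInputError("no frame yielded a complete set of detections")
    return [temporal_average(lengths, needle_id=nid)
            for nid, lengths in sorted(per_needle.items())]
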