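"""Synthetic B-mode rendering of microneedle arrays in a speckle background.

The image model is incoherent: a Rayleigh speckle envelope for the tissue
background, deterministic triangular echo footprints for the needles (the
vertical cross-section of a pyramidal needle), and optional hyperechoic
tissue blobs.  Envelope amplitudes are mapped to 8-bit gray through a
log-compression curve parameterised by scanner gain and dynamic range.
Amplitude constants are chosen so that, at the default gain/dynamic range,
silica-loaded needle tips render in the 80-180 gray band and pristine
hydrogel needles stay below gray 100 -- the contrast contract the length
readout relies on.  No physical acoustics (attenuation, refraction,
beamforming) is modelled: only gray-level geometry matters downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .errors import InvalidInputError
from ._seeding import derive_seed, rng_for

__all__ = [
    "ProbeConfig",
    "NeedleGeometry",
    "TissueFeature",
    "ScenePhantom",
    "BModeFrame",
    "FrameSequence",
    "NeedleOverlay",
    "speckle_field",
    "echogenicity_map",
    "log_compress",
    "render_frame",
    "render_sequence",
    "write_frames",
    "read_frames",
]

# Envelope amplitude levels (arbitrary units; 1.0 = silica tip).  The gaps
# between levels, in dB, set the gray-level separation after compression.
TIP_AMPLITUDE_SILICA = 1.0
BODY_AMPLITUDE_SILICA = 0.30
TIP_AMPLITUDE_PRISTINE = 0.15
BODY_AMPLITUDE_PRISTINE = 0.112
BACKGROUND_MEAN_AMPLITUDE = 0.057
TIP_FRACTION = 0.25          # top fraction of the needle length counted as tip
#: Display reference: a unit-amplitude reflector at gain 30 / dynamic range
#: 65 maps to gray 130, the centre of the silica tip band.
REF_AMPLITUDE = 1175.0
PSF_SIGMA_PX = (1.7, 3.3)    # axial (row), lateral (col) resolution, pixels


@dataclass(frozen=True)
class ProbeConfig:
    """Scanner settings: mm/pixel pitch, display gain, dynamic range (dB),
    frame shape (rows, cols)."""

    pixel_pitch: float = 0.015
    gain: float = 30.0
    dynamic_range: float = 65.0
    frame_shape: tuple = (160, 320)

    def __post_init__(self):
        if self.pixel_pitch <= 0:
            raise InvalidInputError("pixel_pitch must be > 0")
        if self.gain <= 0 or self.dynamic_range <= 0:
            raise InvalidInputError("gain and dynamic_range must be > 0")
        if min(self.frame_shape) < 64:
            raise InvalidInputError("frame_shape must be at least 64x64")


@dataclass(frozen=True)
class NeedleGeometry:
    """Microneedle array geometry in mm: 1.2 mm tall, 0.4 mm base, 1.2 mm
    tip-to-tip pitch by default."""

    height: float = 1.2
    base_width: float = 0.4
    pitch: float = 1.2
    count: int = 3
    has_silica: bool = True

    def __post_init__(self):
        if min(self.height, self.base_width, self.pitch) <= 0:
            raise InvalidInputError("height, base_width and pitch must be > 0")
        if self.count < 0:
            raise InvalidInputError("count must be >= 0")


@dataclass(frozen=True)
class TissueFeature:
    """Hyperechoic blob (e.g. a vessel wall) that may oscillate frame to
    frame, emulating cardiac motion."""

    row: float
    col: float
    radius_mm: float = 0.1
    amplitude: float = 0.4
    motion_amplitude_mm: float = 0.0
    period_frames: int = 8


@dataclass(frozen=True)
class ScenePhantom:
    """Tissue-like background: scatterer density (per mm^2), optional
    moving features, and the row of the patch substrate line."""

    background_scatterer_density: float = 50.0
    tissue_features: tuple = ()
    substrate_row: int = 150

    def __post_init__(self):
        if self.background_scatterer_density < 0:
            raise InvalidInputError("scatterer density must be >= 0")


@dataclass(frozen=True)
class BModeFrame:
    """8-bit gray frame plus acquisition metadata."""

    pixels: np.ndarray
    pixel_pitch: float
    seed: int
    timestamp: float = 0.0

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.dtype != np.uint8:
            raise InvalidInputError("frame pixels must be uint8 (0-255)")


@dataclass
class FrameSequence:
    frames: list
    geometry: NeedleGeometry = field(default_factory=NeedleGeometry)

    def __len__(self):
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


@dataclass(frozen=True)
class NeedleOverlay:
    """Echo source overlay: amplitude map plus label masks used by tests
    and by truth bookkeeping (0 = background, i = needle i)."""

    amplitude: np.ndarray
    needle_labels: np.ndarray
    tip_mask: np.ndarray
    tip_rows: tuple
    base_cols: tuple


# ---------------------------------------------------------------------------
# speckle
# ---------------------------------------------------------------------------

def speckle_field(shape, density: float, seed: int,
                  pixel_pitch: float = 0.015) -> np.ndarray:
    """Fully developed speckle envelope, unit mean, Rayleigh amplitudes.

    The scattering medium is modelled in the continuum limit: per-pixel
    complex circular Gaussian reflectivity with variance proportional to
    the expected scatterer count per pixel (``density * pitch^2``),
    low-pass filtered by a Gaussian point-spread function.  The envelope of
    a filtered circular Gaussian field is exactly Rayleigh, which is the
    fully-developed-speckle statistics B-mode backgrounds exhibit.
    """
    if len(shape) != 2 or min(shape) < 3:
        raise InvalidInputError("shape must be 2-D and at least 3x3")
    if density < 0:
        raise InvalidInputError("density must be >= 0")
    if density == 0:
        return np.zeros(shape, dtype=float)
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(density * pixel_pitch**2 / 2.0)
    re = gaussian_filter(rng.normal(0.0, sigma, shape), PSF_SIGMA_PX, mode="wrap")
    im = gaussian_filter(rng.normal(0.0, sigma, shape), PSF_SIGMA_PX, mode="wrap")
    env = np.hypot(re, im)
    return env / env.mean()


# ---------------------------------------------------------------------------
# needle footprints
# ---------------------------------------------------------------------------

def _needle_columns(geometry: NeedleGeometry, probe: ProbeConfig) -> np.ndarray:
    """Needle axis columns, centred in the frame at the array pitch."""
    cols = probe.frame_shape[1]
    pitch_px = geometry.pitch / probe.pixel_pitch
    offsets = (np.arange(geometry.count) - (geometry.count - 1) / 2.0) * pitch_px
    return np.rint(cols / 2.0 + offsets).astype(int)


def echogenicity_map(geometry: NeedleGeometry, lengths, scene: ScenePhantom,
                     probe: ProbeConfig, texture_rng=None) -> NeedleOverlay:
    """Triangular needle echo footprints with apex at the tip.

    ``lengths`` is the current per-needle length in mm.  Needles sit on the
    substrate row and point upward (row 0 at top).  With silica the tip
    region (top ``TIP_FRACTION`` of the needle) is rendered at elevated
    source amplitude; optional mild dB texture emulates frame-to-frame echo
    variation.  Needles whose tips would leave the frame are clipped.
    """
    lengths = np.atleast_1d(np.asarray(lengths, dtype=float))
    if geometry.count and lengths.size != geometry.count:
        raise InvalidInputError("one length per needle required")
    if np.any(lengths <= 0):
        raise InvalidInputError("needle lengths must be > 0")

    rows, cols = probe.frame_shape
    amp = np.zeros((rows, cols), dtype=float)
    labels = np.zeros((rows, cols), dtype=np.int32)
    tip_mask = np.zeros((rows, cols), dtype=bool)
    if geometry.count == 0:
        return NeedleOverlay(amp, labels, tip_mask, (), ())

    base_row = int(scene.substrate_row)
    if not 0 <= base_row < rows:
        raise InvalidInputError("substrate_row outside frame")
    half_base_px = 0.5 * geometry.base_width / probe.pixel_pitch
    body_a = BODY_AMPLITUDE_SILICA if geometry.has_silica else BODY_AMPLITUDE_PRISTINE
    tip_a = TIP_AMPLITUDE_SILICA if geometry.has_silica else TIP_AMPLITUDE_PRISTINE

    tip_rows, base_cols = [], []
    for idx, (c, length) in enumerate(zip(_needle_columns(geometry, probe), lengths), 1):
        n_px = int(round(length / probe.pixel_pitch))
        tip_row = base_row - n_px
        if tip_row < 0:
            import warnings
            warnings.warn("needle extends above frame; clipping", stacklevel=2)
        tip_cut = base_row - n_px * (1.0 - TIP_FRACTION)  # rows above are "tip"
        per_needle_db = 0.0
        if texture_rng is not None:
            per_needle_db = texture_rng.uniform(-3.0, 3.0)
        for r in range(max(tip_row, 0), base_row + 1):
            frac = (r - tip_row) / max(n_px, 1)
            half_w = int(round(frac * half_base_px))
            c0, c1 = max(c - half_w, 0), min(c + half_w, cols - 1)
            level = tip_a if r <= tip_cut else body_a
            row_amp = level * 10.0 ** (per_needle_db / 20.0)
            if texture_rng is not None:
                px_db = texture_rng.normal(0.0, 1.0, c1 - c0 + 1)
                amp[r, c0:c1 + 1] = np.maximum(
                    amp[r, c0:c1 + 1], row_amp * 10.0 ** (px_db / 20.0))
            else:
                amp[r, c0:c1 + 1] = np.maximum(amp[r, c0:c1 + 1], row_amp)
            labels[r, c0:c1 + 1] = idx
            if r <= tip_cut:
                tip_mask[r, c0:c1 + 1] = True
        tip_rows.append(max(tip_row, 0))
        base_cols.append(int(c))
    return NeedleOverlay(amp, labels, tip_mask, tuple(tip_rows), tuple(base_cols))


# ---------------------------------------------------------------------------
# compression and frame composition
# ---------------------------------------------------------------------------

def log_compress(amplitude: np.ndarray, probe: ProbeConfig) -> np.ndarray:
    """Map envelope amplitude to 8-bit gray.

    ``gray = 255 (20 log10(gain * A / REF) + DR) / DR`` clipped to [0, 255]
    -- the standard dB display mapping.  Monotone in both the amplitude and
    the gain.
    """
    amp = np.asarray(amplitude, dtype=float)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(probe.gain * amp / REF_AMPLITUDE)
    gray = 255.0 * (db + probe.dynamic_range) / probe.dynamic_range
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def render_frame(scene: ScenePhantom, geometry: NeedleGeometry, lengths,
                 probe: ProbeConfig, seed: int, timestamp: float = 0.0,
                 frame_index: int = 0) -> BModeFrame:
    """Compose speckle + needles + tissue features and log-compress.

    Deterministic for identical inputs and seed.  ``frame_index`` advances
    the phase of moving tissue features (used by :func:`render_sequence`).
    """
    spk_seed = derive_seed(seed, "speckle", frame_index)
    speckle = speckle_field(probe.frame_shape, scene.background_scatterer_density,
                            spk_seed, probe.pixel_pitch)
    texture_rng = rng_for(seed, "texture", frame_index)
    overlay = echogenicity_map(geometry, lengths, scene, probe, texture_rng)

    intensity = (BACKGROUND_MEAN_AMPLITUDE * speckle) ** 2 + overlay.amplitude**2
    rows, cols = probe.frame_shape
    if scene.tissue_features:
        rr, cc = np.mgrid[0:rows, 0:cols]
        for feat in scene.tissue_features:
            dr = (feat.motion_amplitude_mm / probe.pixel_pitch) * math.sin(
                2.0 * math.pi * frame_index / feat.period_frames)
            rad_px = feat.radius_mm / probe.pixel_pitch
            blob = feat.amplitude * np.exp(
                -((rr - feat.row - dr) ** 2 + (cc - feat.col) ** 2) / (2 * rad_px**2))
            intensity += blob**2
    pixels = log_compress(np.sqrt(intensity), probe)
    return BModeFrame(pixels=pixels, pixel_pitch=probe.pixel_pitch,
                      seed=seed, timestamp=timestamp)


def render_sequence(scene: ScenePhantom, geometry: NeedleGeometry, length_series,
                    probe: ProbeConfig, n_frames: int, seed: int,
                    frame_interval_s: float = 1.0) -> FrameSequence:
    """Render ``n_frames`` frames with independent speckle realisations.

    ``length_series`` is either one length per needle (static needles, the
    acquisition protocol: several frames in a short interval) or an
    ``(n_frames, count)`` array.  Needles stay put; tissue features may
    oscillate.
    """
    if n_frames < 1:
        raise InvalidInputError("n_frames must be >= 1")
    lengths = np.asarray(length_series, dtype=float)
    if lengths.ndim == 1:
        lengths = np.broadcast_to(lengths, (n_frames, lengths.size))
    elif lengths.shape[0] != n_frames:
        raise InvalidInputError("length_series first axis must match n_frames")
    frames = [
        render_frame(scene, geometry, lengths[i], probe,
                     seed=derive_seed(seed, "frame", i),
                     timestamp=i * frame_interval_s, frame_index=i)
        for i in range(n_frames)
    ]
    return FrameSequence(frames=frames, geometry=geometry)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_frames(path, frames) -> None:
    """Write frames as an 8-bit single-channel TIFF stack; pitch, seeds and
    timestamps go into the image description tag as JSON."""
    frames = list(frames)
    stack = np.stack([f.pixels for f in frames])
    meta = {
        "pixel_pitch_mm": frames[0].pixel_pitch,
        "seeds": [f.seed for f in frames],
        "timestamps": [f.timestamp for f in frames],
    }
    tifffile.imwrite(path, stack, photometric="minisblack",
                     description=json.dumps(meta))


def read_frames(path) -> list:
    """Read a TIFF stack written by :func:`write_frames`."""
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    if stack.ndim == 2:
        stack = stack[None]
    return [
        BModeFrame(pixels=stack[i], pixel_pitch=meta["pixel_pitch_mm"],
                   seed=meta["seeds"][i], timestamp=meta["timestamps"][i])
        for i in range(stack.shape[0])
    ]
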