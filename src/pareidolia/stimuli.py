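"""Synthesis of face/flower-in-pink-noise stimuli.

The stimulus construction chain: a grayscale signal image (schematic face or
flower) is placed at one of eight lateralized locations inside a square field
of 1/f ("pink") noise; a companion noise-only field is matched to the same
mean and RMS contrast; the two are combined pixel-by-pixel so that a fixed
proportion of pixel positions carry noise and the remainder carry the
signal-in-noise image; the result is band-pass filtered (octave bandwidth at
half-height, centred on 1.5 cycles/degree), re-normalized to the legal RMS
contrast range and quantized to 8 bits.

All spatial-frequency arithmetic uses the stimulus-intrinsic scale
``image_px / image_deg`` (95.24 px/deg at defaults), the only scale
consistent with a 4.2 deg / 400 px image and a 6.3 cycles-per-image centre
frequency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "GeometryConfig",
    "FilterSpec",
    "NoiseField",
    "SignalImage",
    "CompositeStimulus",
    "StimulusSet",
    "DEFAULT_NOISE_LEVELS",
    "RMS_RANGE",
    "generate_pink_noise",
    "prepare_signal_image",
    "place_signal",
    "pixel_mix",
    "compute_rms_contrast",
    "scale_to_rms",
    "bandpass_filter",
    "angular_size",
    "location_side",
    "build_stimulus_set",
]

#: Legal RMS contrast range for every emitted image.
RMS_RANGE = (0.25, 0.35)

#: Default RMS contrast the pipeline normalizes to (midpoint of the range).
DEFAULT_TARGET_RMS = 0.30

#: Noise-pixel proportions per category: 16 images per identity per level.
DEFAULT_NOISE_LEVELS = {
    "face": (0.44, 0.46, 0.48, 0.50),
    "flower": (0.38, 0.40, 0.42, 0.44),
}

ELEVATIONS = ("top", "mid_top", "mid_bottom", "bottom")


@dataclass(frozen=True)
class GeometryConfig:
    """Spatial geometry of the stimulus.

    The full image subtends ``image_deg`` degrees of visual angle over
    ``image_px`` pixels; the embedded signal is ``signal_height_px`` tall
    (1.57 deg at defaults). ``eccentricity_deg`` is the offset of the inner
    stimulus edge from fixation in the divided-field presentation.
    """

    image_px: int = 400
    image_deg: float = 4.2
    signal_height_px: int = 150
    eccentricity_deg: float = 1.96
    viewing_distance_mm: float = 570.0
    duration_ms: float = 180.0

    def __post_init__(self) -> None:
        if not (self.image_px > self.signal_height_px > 0):
            raise ValueError("require image_px > signal_height_px > 0")
        if self.image_deg <= 0:
            raise ValueError("image_deg must be positive")

    @property
    def pixels_per_degree(self) -> float:
        return self.image_px / self.image_deg


@dataclass(frozen=True)
class FilterSpec:
    """Octave band-pass filter: gain 1 at ``center_cpd``, 0.5 one half-octave
    below and above (half-height frequency ratio exactly 2)."""

    center_cpd: float = 1.5
    bandwidth_octaves_at_half_height: float = 1.0

    def __post_init__(self) -> None:
        if self.center_cpd <= 0 or self.bandwidth_octaves_at_half_height <= 0:
            raise ValueError("center_cpd and bandwidth must be positive")

    @property
    def half_height_cpd(self) -> tuple[float, float]:
        half = self.bandwidth_octaves_at_half_height / 2.0
        return (self.center_cpd * 2.0 ** -half, self.center_cpd * 2.0 ** half)


@dataclass
class NoiseField:
    pixels: np.ndarray
    seed: int | None
    mean_level: float


@dataclass
class SignalImage:
    pixels: np.ndarray
    category: str
    identity: int
    width_px: int


@dataclass
class CompositeStimulus:
    pixels: np.ndarray
    stimulus_type: str          # "signal" | "noise_only"
    category: str | None
    identity: int | None
    noise_fraction: float | None
    location_id: int | None
    rms_contrast: float
    seed: int | None
    image_id: str = ""
    clip_fraction: float = 0.0


@dataclass
class StimulusSet:
    composites: list
    noise_only: list
    manifest: list = field(default_factory=list)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)

    def all_images(self):
        return list(self.composites) + list(self.noise_only)

    def save(self, out_dir: str | Path) -> None:
        """Write 8-bit grayscale PNGs and a JSON-lines manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for stim, rec in zip(self.all_images(), self.manifest):
            Image.fromarray(stim.pixels, mode="L").save(out / f"{rec['image_id']}.png")
        with open(out / "manifest.jsonl", "w") as fh:
            for rec in self.manifest:
                fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# primitive operations


def generate_pink_noise(
    width: int,
    height: int,
    mean_level: float = 128.0,
    seed=None,
    target_rms: float = DEFAULT_TARGET_RMS,
) -> NoiseField:
    """Generate a 2-D pink-noise field with a 1/f amplitude spectrum.

    Construction is in the frequency domain: a unit 1/f amplitude envelope
    with uniform random phase (hermitian symmetry via the real inverse FFT),
    zero DC, inverse-transformed and affinely mapped to the requested mean
    and RMS contrast.  Because the envelope is deterministic, the radially
    averaged log-amplitude spectrum has slope -1 by construction.
    """
    if width < 8 or height < 8:
        raise ValueError("noise field dimensions must be at least 8 px")
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.rfftfreq(width)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf  # zero DC in the envelope
    phase = rng.uniform(0.0, 2.0 * np.pi, size=f.shape)
    spectrum = (1.0 / f) * np.exp(1j * phase)
    field_ = np.fft.irfft2(spectrum, s=(height, width))
    sd = field_.std()
    pixels = mean_level + field_ * (target_rms * mean_level / sd)
    return NoiseField(pixels=pixels, seed=seed, mean_level=mean_level)


def prepare_signal_image(
    raw: np.ndarray,
    target_height: int = 150,
    reference_mean: float = 128.0,
    category: str = "face",
    identity: int = 0,
) -> SignalImage:
    """Standardize a raw grayscale image: resize to ``target_height`` pixels
    (aspect preserved, bilinear) and offset-match its mean luminance to
    ``reference_mean``."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty signal image")
    h, w = raw.shape
    new_w = max(1, round(w * target_height / h))
    resized = np.asarray(
        Image.fromarray(raw).resize((new_w, target_height), Image.BILINEAR),
        dtype=float,
    )
    matched = resized + (reference_mean - resized.mean())
    return SignalImage(pixels=matched, category=category, identity=identity, width_px=new_w)


def location_side(location_id: int) -> str:
    """Map location id 0-7 to its hemifield: 0-3 left, 4-7 right."""
    if not 0 <= location_id <= 7:
        raise ValueError("location_id must be in 0..7")
    return "left" if location_id < 4 else "right"


def _location_origin(signal_shape, image_px: int, location_id: int) -> tuple[int, int]:
    sig_h, sig_w = signal_shape
    half = image_px // 2
    elev = location_id % 4
    ys = np.linspace(0, image_px - sig_h, 4)
    y0 = int(round(ys[elev]))
    # centre the footprint within its half-field, strictly off the midline
    margin = (half - sig_w) // 2
    if margin < 0:
        raise ValueError("signal image too wide for half-field placement")
    x0 = margin if location_id < 4 else half + margin
    return y0, x0


def place_signal(signal: SignalImage, field_: NoiseField, location_id: int) -> np.ndarray:
    """Insert the signal image into the noise field at one of the eight
    lateralized locations (4 elevations per side of the vertical midline)."""
    grid = field_.pixels.copy()
    y0, x0 = _location_origin(signal.pixels.shape, grid.shape[1], location_id)
    h, w = signal.pixels.shape
    grid[y0 : y0 + h, x0 : x0 + w] = signal.pixels
    return grid


def pixel_mix(
    signal_in_noise: np.ndarray,
    noise_only: np.ndarray,
    noise_fraction: float,
    seed=None,
) -> np.ndarray:
    """Pixel-by-pixel combination: exactly ``round(noise_fraction * N)``
    positions (uniform without replacement) take their value from the
    noise-only image, the remainder from the signal-in-noise image."""
    if signal_in_noise.shape != noise_only.shape:
        raise ValueError("grids must share a shape")
    if not 0.0 <= noise_fraction <= 1.0:
        raise ValueError("noise_fraction must lie in [0, 1]")
    n = signal_in_noise.size
    k = round(noise_fraction * n)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)[:k]
    out = signal_in_noise.ravel().copy()
    out[idx] = noise_only.ravel()[idx]
    return out.reshape(signal_in_noise.shape)


def compute_rms_contrast(image: np.ndarray) -> float:
    """RMS contrast: standard deviation of luminance divided by its mean."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    mean = image.mean()
    if mean == 0:
        raise ZeroDivisionError("zero-mean image has undefined RMS contrast")
    return float(image.std() / mean)


def scale_to_rms(image: np.ndarray, target_rms: float) -> np.ndarray:
    """Rescale deviations about the mean so the RMS contrast hits
    ``target_rms``; the mean is preserved exactly."""
    image = np.asarray(image, dtype=float)
    current = compute_rms_contrast(image)
    if current == 0:
        raise ValueError("cannot scale a constant image to a nonzero contrast")
    mean = image.mean()
    return mean + (image - mean) * (target_rms / current)


def bandpass_filter(
    image: np.ndarray,
    spec: FilterSpec = FilterSpec(),
    geometry: GeometryConfig = GeometryConfig(),
    target_rms: float | None = None,
) -> np.ndarray:
    """Isotropic band-pass Gaussian filter on radial spatial frequency.

    The gain is Gaussian in log2 frequency, 1 at ``center_cpd`` and exactly
    0.5 one half-octave below and above, which realizes "an octave bandwidth
    at half-height" with the half-height frequency ratio exactly 2.  The DC
    component is removed by the filter and the output is re-centred on the
    input mean; if ``target_rms`` is given the output is rescaled to it.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square")
    ppd = geometry.pixels_per_degree
    if spec.center_cpd >= ppd / 2.0:
        raise ValueError("filter centre frequency exceeds the Nyquist limit")
    n = image.shape[0]
    fy = np.fft.fftfreq(n)[:, None] * ppd
    fx = np.fft.fftfreq(n)[None, :] * ppd
    f = np.hypot(fy, fx)
    gain = filter_gain(f, spec)
    mean = image.mean()
    filtered = np.real(np.fft.ifft2(np.fft.fft2(image - mean) * gain)) + mean
    if target_rms is not None:
        filtered = scale_to_rms(filtered, target_rms)
    return filtered


def filter_gain(freq_cpd, spec: FilterSpec = FilterSpec()):
    """Gain of the octave band-pass filter at radial frequency (cpd)."""
    freq_cpd = np.asarray(freq_cpd, dtype=float)
    sigma = (spec.bandwidth_octaves_at_half_height / 2.0) / np.sqrt(2.0 * np.log(2.0))
    with np.errstate(divide="ignore"):
        octaves = np.log2(np.where(freq_cpd > 0, freq_cpd, np.nan) / spec.center_cpd)
    gain = np.exp(-(octaves**2) / (2.0 * sigma**2))
    return np.where(freq_cpd > 0, gain, 0.0)


def angular_size(pixels: float, geometry: GeometryConfig = GeometryConfig()) -> float:
    """Visual angle (degrees) subtended by ``pixels`` at the intrinsic
    stimulus scale ``image_deg / image_px``."""
    if pixels < 0:
        raise ValueError("pixels must be non-negative")
    return pixels * geometry.image_deg / geometry.image_px


def _quantize(image: np.ndarray) -> tuple[np.ndarray, float]:
    clipped = np.clip(image, 0, 255)
    clip_fraction = float(np.mean((image < 0) | (image > 255)))
    return np.round(clipped).astype(np.uint8), clip_fraction


# ---------------------------------------------------------------------------
# full stimulus set


def _finalize(
    pixels: np.ndarray,
    spec: FilterSpec,
    geometry: GeometryConfig,
    target_rms: float,
) -> tuple[np.ndarray, float, float]:
    """Filter, renormalize contrast, quantize; return (uint8, rms, clip)."""
    filtered = bandpass_filter(pixels, spec, geometry, target_rms=target_rms)
    quantized, clip_fraction = _quantize(filtered)
    rms = compute_rms_contrast(quantized)
    return quantized, rms, clip_fraction


def default_signal_images(
    geometry: GeometryConfig = GeometryConfig(), mean_level: float = 128.0
) -> dict:
    """The two schematic identities per category shipped with the package."""
    from .signals import draw_face, draw_flower

    raws = {
        "face": [draw_face(0), draw_face(1)],
        "flower": [draw_flower(0), draw_flower(1)],
    }
    prepared = {}
    for category, images in raws.items():
        prepared[category] = [
            prepare_signal_image(
                img, geometry.signal_height_px, mean_level, category, i
            )
            for i, img in enumerate(images)
        ]
    return prepared


def build_stimulus_set(
    geometry: GeometryConfig = GeometryConfig(),
    filter_spec: FilterSpec = FilterSpec(),
    noise_levels: dict | None = None,
    seed=0,
    images_per_cell: int = 16,
    extra_noise_per_category: int = 0,
    mean_level: float = 128.0,
    target_rms: float = DEFAULT_TARGET_RMS,
    signal_images: dict | None = None,
    experiment: int = 1,
) -> StimulusSet:
    """Generate the full stimulus set with a machine-readable manifest.

    Per category: 2 identities x 4 noise levels x ``images_per_cell`` signal
    composites (128 at defaults), each with a paired unique noise-only image
    (256 noise-only across both categories at defaults).  Locations cycle
    through the 8 lateralized positions so every (identity, level) cell is
    balanced across hemifields.  ``extra_noise_per_category`` adds further
    unique noise-only images (the 1:3 signal:noise design needs 192 noise
    trials per block).
    """
    noise_levels = dict(noise_levels or DEFAULT_NOISE_LEVELS)
    signal_images = signal_images or default_signal_images(geometry, mean_level)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    lo, hi = RMS_RANGE

    composites: list[CompositeStimulus] = []
    noise_only: list[CompositeStimulus] = []
    manifest: list[dict] = []
    n = geometry.image_px

    def _check(rms: float, image_id: str) -> None:
        if not lo <= rms <= hi:
            raise RuntimeError(
                f"image {image_id}: RMS contrast {rms:.4f} outside [{lo}, {hi}]"
            )

    for category in sorted(noise_levels):
        levels = noise_levels[category]
        identities = signal_images[category]
        index = 0
        for identity, sig in enumerate(identities):
            for level in levels:
                for j in range(images_per_cell):
                    # deterministic balanced location assignment: cycle 0..7
                    location_id = j % 8
                    sub = rng.integers(0, 2**31)
                    child = np.random.default_rng(sub)
                    bg = generate_pink_noise(n, n, mean_level, child, target_rms)
                    sig_in_noise = place_signal(sig, bg, location_id)
                    companion = generate_pink_noise(
                        n, n, mean_level, np.random.default_rng(rng.integers(0, 2**31)),
                        target_rms,
                    )
                    companion_px = scale_to_rms(
                        companion.pixels, compute_rms_contrast(sig_in_noise)
                    )
                    mixed = pixel_mix(
                        sig_in_noise, companion_px, level, rng.integers(0, 2**31)
                    )
                    pixels, rms, clip = _finalize(
                        mixed, filter_spec, geometry, target_rms
                    )
                    image_id = (
                        f"exp{experiment}_{category}_signal_{identity}"
                        f"_{int(round(level * 100))}_{location_id}_{index}"
                    )
                    _check(rms, image_id)
                    composites.append(
                        CompositeStimulus(
                            pixels, "signal", category, identity, level,
                            location_id, rms, int(sub), image_id, clip,
                        )
                    )
                    # unique paired noise-only counterpart, same mean and RMS
                    pair_seed = rng.integers(0, 2**31)
                    pair = generate_pink_noise(
                        n, n, mean_level, np.random.default_rng(pair_seed), target_rms
                    )
                    npix, nrms, nclip = _finalize(
                        pair.pixels, filter_spec, geometry, target_rms
                    )
                    pair_id = (
                        f"exp{experiment}_{category}_noise_{identity}"
                        f"_{int(round(level * 100))}_x_{index}"
                    )
                    _check(nrms, pair_id)
                    noise_only.append(
                        CompositeStimulus(
                            npix, "noise_only", category, None, None, None,
                            nrms, int(pair_seed), pair_id, nclip,
                        )
                    )
                    index += 1
        for j in range(extra_noise_per_category):
            pair_seed = rng.integers(0, 2**31)
            pair = generate_pink_noise(
                n, n, mean_level, np.random.default_rng(pair_seed), target_rms
            )
            npix, nrms, nclip = _finalize(pair.pixels, filter_spec, geometry, target_rms)
            image_id = f"exp{experiment}_{category}_noise_extra_x_x_{j}"
            _check(nrms, image_id)
            noise_only.append(
                CompositeStimulus(
                    npix, "noise_only", category, None, None, None,
                    nrms, int(pair_seed), image_id, nclip,
                )
            )

    for stim in composites + noise_only:
        manifest.append(
            {
                "image_id": stim.image_id,
                "stimulus_type": stim.stimulus_type,
                "category": stim.category,
                "identity": stim.identity,
                "noise_fraction": stim.noise_fraction,
                "location_id": stim.location_id,
                "rms_contrast": stim.rms_contrast,
                "clip_fraction": stim.clip_fraction,
                "seed": stim.seed,
            }
        )
    return StimulusSet(composites, noise_only, manifest, geometry)
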