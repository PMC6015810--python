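"""Visual input generation: Gabor encoding and Poisson spike realization.

A bank of Gabor filters (4 orientations x 2 phases by default) models V1
simple cells.  Each retinal location carries one input unit per filter;
filter responses are half-rectified, normalized by the maximum response
across the whole bank for the image, and scaled to a maximum firing rate
(100 Hz).  Spike times are then drawn from homogeneous Poisson processes,
so repeated presentations of the same image with different seeds are
independent "transforms" of the same stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import binary_dilation
from scipy.signal import fftconvolve
from skimage.draw import circle_perimeter, polygon_perimeter

from .records import SpikeRecord

__all__ = [
    "GaborParams",
    "RateMap",
    "gabor_sigma",
    "gabor_kernel",
    "default_gabor_bank",
    "encode_image",
    "generate_poisson_trains",
    "make_shape_image",
    "make_flat_stimulus",
    "write_pgm",
    "read_pgm",
]

SHAPE_LABELS = ("circle", "heart", "star")


def gabor_sigma(wavelength: float, bandwidth_octaves: float) -> float:
    """Gaussian envelope width from the half-response spatial-frequency
    bandwidth in octaves (the standard octave-bandwidth relation)."""
    b = 2.0 ** bandwidth_octaves
    return (wavelength / np.pi) * np.sqrt(np.log(2) / 2.0) * (b + 1) / (b - 1)


@dataclass(frozen=True)
class GaborParams:
    """One oriented, phase-tuned Gabor filter."""

    wavelength: float = 2.0
    theta: float = 0.0
    psi: float = 0.0
    bandwidth_octaves: float = 1.5
    aspect_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.aspect_ratio <= 0:
            raise ValueError("aspect ratio must be positive")

    @property
    def sigma(self) -> float:
        return gabor_sigma(self.wavelength, self.bandwidth_octaves)


def gabor_kernel(params: GaborParams, radius: int | None = None) -> np.ndarray:
    """Gabor kernel on a square support grid.

    value(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) cos(2 pi x'/lambda + psi)
    with x' = x cos(theta) + y sin(theta), y' = -x sin(theta) + y cos(theta).
    """
    sigma = params.sigma
    if radius is None:
        radius = max(1, int(np.ceil(2.5 * sigma)))
    if radius < 2 * sigma:
        raise ValueError("support radius must be at least 2 sigma")
    coords = np.arange(-radius, radius + 1, dtype=np.float64)
    x, y = np.meshgrid(coords, coords)
    xp = x * np.cos(params.theta) + y * np.sin(params.theta)
    yp = -x * np.sin(params.theta) + y * np.cos(params.theta)
    env = np.exp(-(xp ** 2 + (params.aspect_ratio ** 2) * yp ** 2)
                 / (2.0 * sigma ** 2))
    return env * np.cos(2.0 * np.pi * xp / params.wavelength + params.psi)


def default_gabor_bank() -> tuple[GaborParams, ...]:
    """The published bank: theta in {0, pi/4, pi/2, 3pi/4}, psi in {0, pi},
    wavelength 2, aspect ratio 0.5, bandwidth 1.5 octaves (8 filters)."""
    return tuple(
        GaborParams(wavelength=2.0, theta=theta, psi=psi,
                    bandwidth_octaves=1.5, aspect_ratio=0.5)
        for theta in (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
        for psi in (0.0, np.pi)
    )


@dataclass
class RateMap:
    """Firing rate per input unit (Hz), channel-major over the retina.

    ``rates_hz`` has shape (n_channels, height, width) for Gabor-encoded
    images, or (1, 1, n_units) for flat stimuli.  ``flat()`` yields the 1-D
    unit ordering used by the network builders.
    """

    rates_hz: np.ndarray
    label: str = "custom"
    max_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        self.rates_hz = np.asarray(self.rates_hz, dtype=np.float64)
        if self.rates_hz.min(initial=0.0) < 0:
            raise ValueError("rates must be non-negative")
        if self.rates_hz.size and self.rates_hz.max() > self.max_rate_hz + 1e-9:
            raise ValueError("rates exceed the maximum rate")

    @property
    def n_units(self) -> int:
        return self.rates_hz.size

    def flat(self) -> np.ndarray:
        return self.rates_hz.reshape(-1)

    def write_tsv(self, path) -> None:
        import pandas as pd
        df = pd.DataFrame({"unit_id": np.arange(self.n_units),
                           "rate_hz": self.flat()})
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def encode_image(image: np.ndarray, bank=None, max_rate_hz: float = 100.0,
                 norm_percentile: float = 99.0,
                 label: str = "custom") -> RateMap:
    """Convolve an intensity image with the Gabor bank and map responses to
    firing rates in [0, max_rate].

    Responses are half-rectified and normalized across the whole bank for
    this image; the normalizer is the ``norm_percentile`` percentile of the
    positive responses, so that the population of well-matched filters
    saturates at the maximum rate rather than only the single best one
    (rates above the ceiling are clipped).  An all-zero image yields an
    all-zero rate map.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be a 2-D intensity grid")
    if bank is None:
        bank = default_gabor_bank()
    responses = np.stack([
        fftconvolve(image, gabor_kernel(p), mode="same") for p in bank
    ])
    responses = np.clip(responses, 0.0, None)
    positive = responses[responses > 0]
    if positive.size:
        norm = np.percentile(positive, norm_percentile)
        if norm <= 0:
            norm = positive.max()
        responses = np.clip(responses / norm, 0.0, 1.0) * max_rate_hz
    return RateMap(responses, label=label, max_rate_hz=max_rate_hz)


def make_flat_stimulus(n_units: int, rate_hz: float) -> RateMap:
    """Every input unit active at the same rate (the all-units-active
    stimulus of the two-layer experiments uses 1000 units at 50 Hz)."""
    if n_units <= 0:
        raise ValueError("n_units must be positive")
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    return RateMap(np.full((1, 1, n_units), rate_hz), label="flat",
                   max_rate_hz=max(100.0, rate_hz))


def generate_poisson_trains(rates: RateMap | np.ndarray, duration_ms: float,
                            seed) -> SpikeRecord:
    """Homogeneous Poisson spike trains, one per input unit.

    Returns a single-trial :class:`SpikeRecord` over unit indices.  Distinct
    seeds give independent realizations of the same rate map.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    flat = rates.flat() if isinstance(rates, RateMap) else np.asarray(rates, float)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    counts = rng.poisson(flat * duration_ms / 1000.0)
    units = np.repeat(np.arange(flat.size), counts)
    times = rng.uniform(0.0, duration_ms, size=int(counts.sum()))
    return SpikeRecord.single_trial(units, times,
                                    meta={"duration_ms": duration_ms})


def _star_vertices(size: int) -> tuple[np.ndarray, np.ndarray]:
    c = (size - 1) / 2.0
    r_out, r_in = 0.42 * size, 0.17 * size
    ang = -np.pi / 2 + np.arange(10) * np.pi / 5
    r = np.where(np.arange(10) % 2 == 0, r_out, r_in)
    return c + r * np.sin(ang), c + r * np.cos(ang)


def _heart_vertices(size: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
    x = 16 * np.sin(t) ** 3
    y = 13 * np.cos(t) - 5 * np.cos(2 * t) - 2 * np.cos(3 * t) - np.cos(4 * t)
    scale = 0.42 * size / 17.0
    c = (size - 1) / 2.0
    return c - y * scale, c + x * scale  # rows grow downward


def make_shape_image(label: str, size: int = 128,
                     stroke_px: int = 3) -> np.ndarray:
    """Centered binary outline drawing (circle | heart | star) on a
    size x size grid with values in {0, 1}.

    The stroke width is in pixels regardless of the grid size: the Gabor
    wavelength of the encoder is fixed at 2 px, so a ~3 px stroke drives the
    filter bank strongly and uniformly along the outline.
    """
    img = np.zeros((size, size), dtype=np.float64)
    if label == "circle":
        c = (size - 1) // 2
        rr, cc = circle_perimeter(c, c, int(round(0.35 * size)), shape=img.shape)
    elif label == "star":
        rr, cc = polygon_perimeter(*_star_vertices(size), shape=img.shape)
    elif label == "heart":
        rr, cc = polygon_perimeter(*_heart_vertices(size), shape=img.shape)
    else:
        raise ValueError(f"unknown stimulus label: {label!r}")
    img[rr, cc] = 1.0
    if stroke_px > 1:
        img = binary_dilation(img > 0, iterations=stroke_px - 1).astype(float)
    return img


def write_pgm(image: np.ndarray, path) -> None:
    """Persist an intensity image in [0, 1] as 8-bit binary PGM."""
    arr = np.clip(np.asarray(image) * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path), format="PPM")


def read_pgm(path) -> np.ndarray:
    with Image.open(Path(path)) as im:
        return np.asarray(im.convert("L"), dtype=np.float64) / 255.0
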