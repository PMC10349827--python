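"""Reading, writing and centroiding of mass spectrometry imaging data.

Datasets are exchanged as imzML 1.1 (continuous or processed mode) through
``pyimzml``; in memory a dataset is a grid of per-pixel spectra with pixel
size, polarity, mass range and free-form metadata.  Pixel coordinates are
0-based internally (x rightward, y downward); imzML's 1-based indices are
converted at the boundary.  m/z arrays are stored as float64 and
intensities as float32, matching common imzML practice, so a
write-then-read round trip is bitwise on both.
"""

from __future__ import annotations

import contextlib
import hashlib
import json
import os
import uuid as _uuid
from dataclasses import dataclass, field

import numpy as np
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter

__all__ = ["Spectrum", "MSIDataset", "read_imzml", "write_imzml", "centroid"]


@dataclass
class Spectrum:
    """One pixel's mass spectrum (parallel m/z and intensity arrays)."""

    x: int
    y: int
    mode: str  # "profile" | "centroid"
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError(f"m/z not strictly ascending at pixel ({self.x},{self.y})")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class MSIDataset:
    """Grid of per-pixel spectra plus acquisition metadata."""

    width: int
    height: int
    spectra: list[Spectrum]
    pixel_size_um: float = 50.0
    polarity: str = "positive"
    mass_range: tuple[float, float] = (100.0, 1000.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for s in self.spectra:
            if not (0 <= s.x < self.width and 0 <= s.y < self.height):
                raise ValueError(f"spectrum at ({s.x},{s.y}) outside {self.width}x{self.height} grid")
            if (s.x, s.y) in seen:
                raise ValueError(f"duplicate spectrum coordinate ({s.x},{s.y})")
            seen.add((s.x, s.y))

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def spectrum_at(self, x: int, y: int) -> Spectrum | None:
        for s in self.spectra:
            if s.x == x and s.y == y:
                return s
        return None

    def tic_image(self) -> np.ndarray:
        img = np.zeros((self.height, self.width))
        for s in self.spectra:
            img[s.y, s.x] = s.tic
        return img

    def peak_count_image(self) -> np.ndarray:
        img = np.zeros((self.height, self.width))
        for s in self.spectra:
            img[s.y, s.x] = s.mz.size
        return img


@contextlib.contextmanager
def _fixed_uuid(seed_bytes: bytes):
    """Pin the file UUID the imzML writer draws, so identical datasets
    serialize byte-identically."""
    import pyimzml.ImzMLWriter as _w

    fixed = _uuid.UUID(bytes=hashlib.md5(seed_bytes).digest())
    orig = _w.uuid.uuid4
    _w.uuid.uuid4 = lambda: fixed
    try:
        yield
    finally:
        _w.uuid.uuid4 = orig


def write_imzml(dataset: MSIDataset, path: str) -> None:
    """Write a dataset as processed-mode imzML (.imzML + .ibd pair).

    Free-form metadata is stored in a ``<path>.meta.json`` sidecar since
    the imzML writer has no slot for arbitrary keys.  The binary UUID is
    derived from the spectral content, making writes deterministic.
    """
    if not dataset.spectra:
        raise ValueError("refusing to write an empty dataset")
    digest = hashlib.md5()
    for s in sorted(dataset.spectra, key=lambda s: (s.y, s.x)):
        digest.update(np.float64(s.x).tobytes() + np.float64(s.y).tobytes())
        digest.update(s.mz.tobytes())
    with _fixed_uuid(digest.digest()):
        with ImzMLWriter(
            path,
            mode="processed",
            polarity=dataset.polarity,
            mz_dtype=np.float64,
            intensity_dtype=np.float32,
        ) as writer:
            for s in sorted(dataset.spectra, key=lambda s: (s.y, s.x)):
                writer.addSpectrum(s.mz, s.intensity, (s.x + 1, s.y + 1, 1))
    sidecar = {
        "pixel_size_um": dataset.pixel_size_um,
        "polarity": dataset.polarity,
        "mass_range": list(dataset.mass_range),
        "mode": dataset.metadata.get("mode", "centroid"),
        "metadata": dataset.metadata,
    }
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def read_imzml(path: str) -> MSIDataset:
    """Read an imzML/.ibd pair (continuous or processed mode).

    The grid is inferred from the maximum pixel indices; per-spectrum m/z
    axes are preserved (processed mode may be ragged).
    """
    ibd = os.path.splitext(str(path))[0] + ".ibd"
    if not os.path.exists(ibd):
        raise FileNotFoundError(f"binary file missing: {ibd}")
    parser = ImzMLParser(str(path))
    mode = "processed" if "processed" in parser.metadata.file_description.param_by_name else "continuous"
    sidecar_path = str(path) + ".meta.json"
    sidecar = {}
    if os.path.exists(sidecar_path):
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
    spectra = []
    spec_mode = sidecar.get("mode", "centroid")
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        spectra.append(
            Spectrum(
                x=int(x) - 1,
                y=int(y) - 1,
                mode=spec_mode,
                mz=np.asarray(mz, dtype=np.float64),
                intensity=np.asarray(inten, dtype=np.float32),
            )
        )
    width = max(s.x for s in spectra) + 1
    height = max(s.y for s in spectra) + 1
    pixel_size = sidecar.get("pixel_size_um")
    if pixel_size is None:
        pixel_size = float(parser.imzmldict.get("pixel size x", 50.0)) or 50.0
    polarity = sidecar.get("polarity", "positive")
    if "mass_range" in sidecar:
        mass_range = tuple(sidecar["mass_range"])
    else:
        lo = min((s.mz[0] for s in spectra if s.mz.size), default=100.0)
        hi = max((s.mz[-1] for s in spectra if s.mz.size), default=1000.0)
        mass_range = (float(lo), float(hi))
    return MSIDataset(
        width=width,
        height=height,
        spectra=spectra,
        pixel_size_um=float(pixel_size),
        polarity=polarity,
        mass_range=mass_range,
        metadata=sidecar.get("metadata", {"mode": spec_mode}),
    )


def centroid(spectrum: Spectrum, min_snr: float = 3.0, noise_window: int = 51) -> Spectrum:
    """Centroid a profile spectrum.

    Local maxima above ``min_snr`` times the local noise (median absolute
    deviation over a sliding window, Gaussian-scaled) are kept; the apex
    m/z is refined by 3-point parabolic interpolation.
    """
    if spectrum.mode != "profile":
        raise ValueError("spectrum is already centroided")
    y = spectrum.intensity.astype(np.float64)
    x = spectrum.mz
    n = y.size
    if n < 3:
        return Spectrum(spectrum.x, spectrum.y, "centroid", np.empty(0), np.empty(0))
    # sliding-window MAD noise estimate
    from scipy.ndimage import median_filter

    med = median_filter(y, size=noise_window, mode="nearest")
    mad = median_filter(np.abs(y - med), size=noise_window, mode="nearest")
    noise = 1.4826 * mad
    floor = max(1e-12, float(np.median(noise[noise > 0])) if np.any(noise > 0) else 1e-12)
    noise = np.maximum(noise, floor)

    peaks_mz, peaks_int = [], []
    for i in range(1, n - 1):
        if y[i] <= 0 or y[i] < y[i - 1] or y[i] <= y[i + 1]:
            continue
        if y[i] < min_snr * noise[i]:
            continue
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        if denom < 0:
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        # local m/z spacing for apex shift
        dx = 0.5 * (x[i + 1] - x[i - 1])
        peaks_mz.append(float(x[i] + delta * dx))
        peaks_int.append(float(y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta))
    return Spectrum(
        spectrum.x,
        spectrum.y,
        "centroid",
        np.asarray(peaks_mz),
        np.asarray(peaks_int),
    )
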