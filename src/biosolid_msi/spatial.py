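"""Spatial distribution metrics for annotated ions.

Because the deposition solvent forces migration, where an ion sits on the
deposit carries chemical information: hydrophilic, weakly adsorbing
compounds ride the solvent front to the rim while hydrophobic, strongly
adsorbing ones stay central.  This module measures that: sample coverage
(% of sample pixels above a relative threshold), a radial intensity
profile, a peripheral index (rim vs. core mean intensity), a
periphery/center/uniform classification, and rank correlations of the
peripheral index against water solubility and the soil adsorption
coefficient Koc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .screening import AnnotationHit
from .segmentation import SegmentationMask

__all__ = [
    "SpatialProfile",
    "coverage",
    "radial_profile",
    "peripheral_index",
    "classify",
    "profile_ion",
    "attach_spatial",
    "physchem_correlation",
]

# Shared with the phantom's placement convention.
PI_PERIPHERY = 0.65
PI_CENTER = 0.35
COVERAGE_UNIFORM = 70.0
OUTER_BAND = (0.7, 1.05)  # r/R range counted as rim
INNER_BAND = 0.5  # r/R limit counted as core


@dataclass
class SpatialProfile:
    bin_edges: np.ndarray  # r/R, 11 edges for 10 bins
    bin_means: np.ndarray
    coverage_pct: float
    peripheral_index: float
    spatial_class: str


def _mask_geometry(mask: SegmentationMask) -> tuple[float, float, float]:
    """Deposit center (mask centroid) and equivalent-area radius."""
    ys, xs = np.nonzero(mask.labels)
    if xs.size < 10:
        raise ValueError("degenerate mask: fewer than 10 sample pixels")
    cx, cy = float(xs.mean()), float(ys.mean())
    radius = float(np.sqrt(xs.size / np.pi))
    return cx, cy, radius


def coverage(image: np.ndarray, mask: SegmentationMask, rel_threshold: float = 0.05) -> float:
    """Percent of sample pixels at or above ``rel_threshold`` times the
    image maximum.  An all-zero image covers 0%."""
    sample = mask.labels
    n = int(sample.sum())
    if n == 0:
        raise ValueError("sample region is empty")
    peak = float(image.max())
    if peak <= 0:
        return 0.0
    return 100.0 * float((image[sample] >= rel_threshold * peak).sum()) / n


def _radius_map(image: np.ndarray, mask: SegmentationMask) -> np.ndarray:
    cx, cy, radius = _mask_geometry(mask)
    yy, xx = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
    return np.hypot(xx - cx, yy - cy) / radius


def radial_profile(image: np.ndarray, mask: SegmentationMask, n_bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Mean intensity in ``n_bins`` equal r/R bins over [0, 1]."""
    r = _radius_map(image, mask)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    means = np.zeros(n_bins)
    inside = mask.labels
    for i in range(n_bins):
        sel = inside & (r >= edges[i]) & (r < edges[i + 1] if i < n_bins - 1 else r <= edges[i + 1])
        means[i] = image[sel].mean() if sel.any() else 0.0
    return edges, means


def peripheral_index(image: np.ndarray, mask: SegmentationMask) -> float:
    """Rim-vs-core intensity balance in [0, 1].

    PI = mean(outer band) / (mean(outer band) + mean(core)), with the
    outer band r/R in [0.7, 1.05] and the core r/R <= 0.5 measured from
    the mask centroid and equivalent-area radius; 0/0 maps to 0.5.
    """
    r = _radius_map(image, mask)
    # band means are taken over sample pixels only, so off-sample zeros do
    # not dilute the rim estimate
    outer = (r >= OUTER_BAND[0]) & (r <= OUTER_BAND[1]) & mask.labels
    inner = (r <= INNER_BAND) & mask.labels
    i_out = float(image[outer].mean()) if outer.any() else 0.0
    i_in = float(image[inner].mean()) if inner.any() else 0.0
    if i_out + i_in <= 0:
        return 0.5
    return i_out / (i_out + i_in)


def classify(profile: SpatialProfile | None = None, *, pi: float | None = None, coverage_pct: float | None = None) -> str:
    """Periphery / center / uniform decision.

    Uniform when coverage >= 70%; otherwise periphery when PI >= 0.65,
    center when PI <= 0.35, and uniform in between.
    """
    if profile is not None:
        pi, coverage_pct = profile.peripheral_index, profile.coverage_pct
    if coverage_pct >= COVERAGE_UNIFORM:
        return "uniform"
    if pi >= PI_PERIPHERY:
        return "periphery"
    if pi <= PI_CENTER:
        return "center"
    return "uniform"


def profile_ion(image: np.ndarray, mask: SegmentationMask, rel_threshold: float = 0.05) -> SpatialProfile:
    cov = coverage(image, mask, rel_threshold)
    pi = peripheral_index(image, mask)
    edges, means = radial_profile(image, mask)
    prof = SpatialProfile(
        bin_edges=edges,
        bin_means=means,
        coverage_pct=cov,
        peripheral_index=pi,
        spatial_class="",
    )
    prof.spatial_class = classify(prof)
    return prof


def attach_spatial(
    hits: list[AnnotationHit],
    dataset,
    mask: SegmentationMask,
    window_ppm: float = 3.0,
    rel_threshold: float = 0.05,
) -> list[AnnotationHit]:
    """Fill coverage, peripheral index and spatial class on each hit from
    its +/- ``window_ppm`` ion image."""
    from .screening import ion_image

    for h in hits:
        img = ion_image(dataset, h.measured_mz, window_ppm)
        prof = profile_ion(img, mask, rel_threshold)
        h.coverage_pct = prof.coverage_pct
        h.peripheral_index = prof.peripheral_index
        h.spatial_class = prof.spatial_class
    return hits


def physchem_correlation(hits: list[AnnotationHit]) -> dict:
    """Spearman rank correlation (average ranks on ties) of the peripheral
    index against log10 water solubility and log10 Koc over hits carrying
    both properties.  Fewer than 5 usable hits reports nulls."""
    rows = []
    for h in hits:
        s = h.suspect.water_solubility_mg_l
        k = h.suspect.log_koc
        if s is None or k is None or h.peripheral_index is None:
            continue
        rows.append((h.peripheral_index, np.log10(s), k))
    n = len(rows)
    if n < 5:
        return {"n": n, "rho_s": None, "p_s": None, "rho_koc": None, "p_koc": None}
    pi, log_s, log_k = map(np.asarray, zip(*rows))
    rho_s, p_s = stats.spearmanr(pi, log_s)
    rho_k, p_k = stats.spearmanr(pi, log_k)
    return {
        "n": n,
        "rho_s": float(rho_s),
        "p_s": float(p_s),
        "rho_koc": float(rho_k),
        "p_koc": float(p_k),
    }


def spatial_report(hits: list[AnnotationHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        s = h.suspect.water_solubility_mg_l
        rows.append(
            dict(
                name=h.suspect.name,
                mz=h.measured_mz,
                coverage_pct=h.coverage_pct,
                peripheral_index=h.peripheral_index,
                spatial_class=h.spatial_class,
                log_s=(np.log10(s) if s else None),
                log_koc=h.suspect.log_koc,
            )
        )
    return pd.DataFrame(rows)
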