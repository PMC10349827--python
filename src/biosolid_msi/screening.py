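"""Suspect screening of the segmented sample region.

Peaks from all sample-region pixels are clustered on the m/z axis (3 ppm
single linkage) into features; features are matched against suspect lists
over an adduct set at a <= 3 ppm mass gate, and candidates with an
elemental composition are additionally gated on the isotope-fit sigma
score (<= 30) computed on the mean sample-region spectrum.  Surviving
hits are tentative identifications (Schymanski level 3 with isotope
evidence, level 5 on exact mass alone) that external chromatographic
confirmation can promote to level 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem
from .io import MSIDataset
from .segmentation import SegmentationMask

__all__ = [
    "SuspectEntry",
    "Feature",
    "FeatureTable",
    "AnnotationHit",
    "load_suspects",
    "extract_features",
    "annotate",
    "ion_image",
    "apply_confirmations",
    "family_summary",
]

PPM_EPS = 1e-9  # absorb float roundoff at the inclusive ppm boundary
SIGMA_EPS = 1e-9


@dataclass
class SuspectEntry:
    """A screened compound: formula or neutral mass, plus optional
    physico-chemical context used by the spatial stage."""

    name: str
    formula: str | None = None
    neutral_mass: float | None = None
    family: str = ""
    water_solubility_mg_l: float | None = None
    log_koc: float | None = None
    identifier: str = ""

    def __post_init__(self):
        if not self.formula and self.neutral_mass is None:
            raise ValueError(f"suspect {self.name!r} needs a formula or a neutral mass")

    def mass(self, table: chem.ElementIsotopeTable | None = None) -> float:
        if self.formula:
            return chem.parse_formula(self.formula).monoisotopic_mass(table)
        return float(self.neutral_mass)


@dataclass
class Feature:
    mz: float  # intensity-weighted representative m/z
    max_intensity: float
    pixel_count: int  # pixels with this feature at or above the intensity threshold
    mean_intensity: float  # mean over all sample-region pixels


@dataclass
class FeatureTable:
    features: list[Feature]
    n_sample_pixels: int
    intensity_threshold: float
    mean_spectrum: list[tuple[float, float]]  # all clusters, unfiltered

    def __len__(self):
        return len(self.features)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    mz=f.mz,
                    max_intensity=f.max_intensity,
                    pixel_count=f.pixel_count,
                    mean_intensity=f.mean_intensity,
                )
                for f in self.features
            ]
        )


@dataclass
class AnnotationHit:
    suspect: SuspectEntry
    ion_label: str
    theoretical_mz: float
    measured_mz: float
    ppm_error: float
    sigma: float | None
    level: int = 3
    ambiguous: bool = False
    coverage_pct: float | None = None
    peripheral_index: float | None = None
    spatial_class: str | None = None


def load_suspects(path) -> list[SuspectEntry]:
    """Read a suspect list CSV/TSV with columns name, formula, neutral_mass,
    family, water_solubility_mg_L, log_koc, id (extra columns ignored)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    out = []
    for _, row in df.iterrows():
        def get(col):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) or v == "" else v

        out.append(
            SuspectEntry(
                name=str(row["name"]),
                formula=get("formula"),
                neutral_mass=float(get("neutral_mass")) if get("neutral_mass") is not None else None,
                family=str(get("family") or ""),
                water_solubility_mg_l=float(get("water_solubility_mg_L")) if get("water_solubility_mg_L") is not None else None,
                log_koc=float(get("log_koc")) if get("log_koc") is not None else None,
                identifier=str(get("id") or ""),
            )
        )
    return out


def _cluster_peaks(
    mzs: np.ndarray, ints: np.ndarray, px: np.ndarray, linkage_ppm: float
) -> list[tuple[float, np.ndarray]]:
    """Single-linkage clustering along the m/z axis: a sorted run is split
    wherever the gap between neighbours exceeds ``linkage_ppm``."""
    order = np.argsort(mzs)
    mzs, ints, px = mzs[order], ints[order], px[order]
    if mzs.size == 0:
        return []
    gaps = np.diff(mzs) / mzs[:-1] * 1e6
    breaks = np.flatnonzero(gaps > linkage_ppm) + 1
    clusters = []
    for idx in np.split(np.arange(mzs.size), breaks):
        clusters.append((mzs[idx], ints[idx], px[idx]))
    return clusters


def extract_features(
    dataset: MSIDataset,
    mask: SegmentationMask,
    intensity_threshold: float = 500.0,
    min_pixels: int = 5,
    linkage_ppm: float = 3.0,
) -> FeatureTable:
    """Cluster sample-region peaks into m/z features.

    Features whose maximum pixel intensity falls below the intensity
    threshold, or that reach the threshold in fewer than ``min_pixels``
    pixels (the stand-in for a proprietary speckle filter), are dropped.
    The unfiltered cluster list doubles as the mean sample-region
    spectrum used for isotope-fit scoring.
    """
    sample = mask.labels
    n_px = int(sample.sum())
    if n_px == 0:
        raise ValueError("sample region is empty")
    all_mz, all_int, all_px = [], [], []
    for s in dataset.spectra:
        if not sample[s.y, s.x] or s.mz.size == 0:
            continue
        all_mz.append(s.mz)
        all_int.append(s.intensity.astype(np.float64))
        all_px.append(np.full(s.mz.size, s.y * dataset.width + s.x))
    if not all_mz:
        return FeatureTable([], n_px, intensity_threshold, [])
    mzs = np.concatenate(all_mz)
    ints = np.concatenate(all_int)
    px = np.concatenate(all_px)

    features = []
    mean_spec = []
    for cmz, cint, cpx in _cluster_peaks(mzs, ints, px, linkage_ppm):
        tot = cint.sum()
        rep = float(np.average(cmz, weights=cint)) if tot > 0 else float(cmz.mean())
        mean_spec.append((rep, tot / n_px))
        max_i = float(cint.max())
        hot = cint >= intensity_threshold
        n_hot = len(np.unique(cpx[hot]))
        if max_i < intensity_threshold or n_hot < min_pixels:
            continue
        features.append(
            Feature(
                mz=rep,
                max_intensity=max_i,
                pixel_count=n_hot,
                mean_intensity=tot / n_px,
            )
        )
    mean_spec.sort()
    return FeatureTable(features, n_px, intensity_threshold, mean_spec)


def annotate(
    features: FeatureTable,
    suspects: list[SuspectEntry],
    adducts: list[chem.Adduct] | None = None,
    ppm_tol: float = 3.0,
    sigma_max: float = 30.0,
    polarity: str = "positive",
    table: chem.ElementIsotopeTable | None = None,
) -> list[AnnotationHit]:
    """Match features against suspect x adduct candidates.

    The ppm gate is inclusive (a deviation of exactly ``ppm_tol`` passes).
    Suspects with a formula are isotope-scored on the mean sample-region
    spectrum and emitted at level 3 when sigma <= ``sigma_max``; mass-only
    suspects cannot be isotope-scored and are emitted at level 5.  When two
    suspects claim one feature, both are reported and flagged ambiguous.
    """
    table = table or chem.ElementIsotopeTable.default()
    if adducts is None:
        adducts = chem.load_adducts()[polarity]
    for a in adducts:
        if (a.charge > 0) != (polarity == "positive"):
            raise ValueError(f"adduct {a.label} charge inconsistent with {polarity} polarity")
    hits: list[AnnotationHit] = []
    feature_claims: dict[int, list[int]] = {}
    for suspect in suspects:
        neutral_formula = chem.parse_formula(suspect.formula) if suspect.formula else None
        for adduct in adducts:
            if neutral_formula is not None:
                species = adduct.apply(neutral_formula)
                theo_mz = chem.ion_mz(species, table)
            else:
                theo_mz = suspect.mass(table) + adduct.mass_shift(table)
                species = None
            for fi, feature in enumerate(features.features):
                ppm = (feature.mz - theo_mz) / theo_mz * 1e6
                if abs(ppm) > ppm_tol + PPM_EPS:
                    continue
                sigma = None
                level = 5
                if species is not None:
                    pattern = chem.theoretical_pattern(species, table)
                    sigma = chem.sigma_fit(features.mean_spectrum, pattern, ppm_tol)
                    if sigma > sigma_max + SIGMA_EPS:
                        continue
                    level = 3
                hits.append(
                    AnnotationHit(
                        suspect=suspect,
                        ion_label=adduct.label,
                        theoretical_mz=theo_mz,
                        measured_mz=feature.mz,
                        ppm_error=ppm,
                        sigma=sigma,
                        level=level,
                    )
                )
                feature_claims.setdefault(fi, []).append(len(hits) - 1)
    for fi, claim in feature_claims.items():
        names = {hits[i].suspect.name for i in claim}
        if len(names) > 1:
            for i in claim:
                hits[i].ambiguous = True
    return hits


def ion_image(dataset: MSIDataset, center_mz: float, window_ppm: float = 3.0) -> np.ndarray:
    """Per-pixel summed intensity within +/- ``window_ppm`` of ``center_mz``."""
    img = np.zeros((dataset.height, dataset.width))
    half = center_mz * window_ppm * 1e-6
    lo, hi = center_mz - half, center_mz + half
    for s in dataset.spectra:
        if s.mz.size == 0:
            continue
        a = np.searchsorted(s.mz, lo, side="left")
        b = np.searchsorted(s.mz, hi, side="right")
        if b > a:
            img[s.y, s.x] = float(s.intensity[a:b].sum())
    return img


def apply_confirmations(hits: list[AnnotationHit], confirmed_names: list[str]) -> list[AnnotationHit]:
    """Promote externally confirmed annotations from level 3 (or 5) to
    level 1; unknown names warn and change nothing.  Idempotent."""
    import warnings

    known = {h.suspect.name for h in hits}
    for name in confirmed_names:
        if name not in known:
            warnings.warn(f"confirmed compound {name!r} not among hits", stacklevel=2)
    for h in hits:
        if h.suspect.name in confirmed_names:
            h.level = 1
    return hits


def hits_to_frame(hits: list[AnnotationHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                name=h.suspect.name,
                family=h.suspect.family,
                ion=h.ion_label,
                theoretical_mz=h.theoretical_mz,
                measured_mz=h.measured_mz,
                ppm_error=h.ppm_error,
                sigma=(h.sigma if h.sigma is not None and math.isfinite(h.sigma) else ""),
                level=h.level,
                ambiguous=h.ambiguous,
                coverage_pct=h.coverage_pct,
                peripheral_index=h.peripheral_index,
                spatial_class=h.spatial_class,
            )
            for h in hits
        ]
    )


def family_summary(hits: list[AnnotationHit]) -> pd.DataFrame:
    """Contaminant-family tabulation: one row per family with the number of
    distinct annotated compounds."""
    seen: dict[str, set] = {}
    for h in hits:
        seen.setdefault(h.suspect.family or "unclassified", set()).add(h.suspect.name)
    rows = [(fam, len(names)) for fam, names in sorted(seen.items())]
    return pd.DataFrame(rows, columns=["family", "n_compounds"])
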