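"""Sample / off-sample segmentation of MSI grids.

Spectra are RMS-normalized, per-pixel summary images (log total ion
current and peak count) are weakly denoised with a median filter, and the
pixels are split into two clusters by iterative centroid reassignment
with a deterministic initialization.  The higher-TIC cluster is the
sample; the largest connected sample component is kept and small holes
are filled, mimicking the manual ROI curation a GUI workflow performs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import MSIDataset, Spectrum

__all__ = ["SegmentationMask", "rms_normalize", "segment", "jaccard"]


@dataclass
class SegmentationMask:
    labels: np.ndarray  # bool (H, W); True = sample
    provenance: dict = field(default_factory=dict)

    @property
    def sample(self) -> np.ndarray:
        return self.labels

    @property
    def n_sample(self) -> int:
        return int(self.labels.sum())

    def to_tsv(self, path) -> None:
        ys, xs = np.nonzero(self.labels)
        with open(path, "w") as fh:
            fh.write("x\ty\n")
            for x, y in zip(xs, ys):
                fh.write(f"{x}\t{y}\n")

    def to_png(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plt.imsave(path, self.labels.astype(np.uint8) * 255, cmap="gray", vmin=0, vmax=255)


def rms_normalize(dataset: MSIDataset) -> MSIDataset:
    """Divide every spectrum by its root-mean-square intensity.

    All-zero spectra are left unchanged and their coordinates recorded in
    ``metadata["rms_zero_flagged"]``.
    """
    spectra = []
    flagged = []
    for s in dataset.spectra:
        inten = s.intensity.astype(np.float64)
        rms = float(np.sqrt(np.mean(inten**2))) if inten.size else 0.0
        if rms <= 0:
            flagged.append((s.x, s.y))
            spectra.append(Spectrum(s.x, s.y, s.mode, s.mz.copy(), s.intensity.copy()))
        else:
            spectra.append(Spectrum(s.x, s.y, s.mode, s.mz.copy(), inten / rms))
    meta = dict(dataset.metadata)
    meta["rms_zero_flagged"] = flagged
    return MSIDataset(
        width=dataset.width,
        height=dataset.height,
        spectra=spectra,
        pixel_size_um=dataset.pixel_size_um,
        polarity=dataset.polarity,
        mass_range=dataset.mass_range,
        metadata=meta,
    )


def _two_means(features: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic 2-cluster partition: centroids initialized at the
    10th and 90th percentile feature vectors, then iterative reassignment.
    Returns integer labels (0/1)."""
    lo = np.percentile(features, 10, axis=0)
    hi = np.percentile(features, 90, axis=0)
    if np.allclose(lo, hi):
        return np.zeros(len(features), dtype=int)
    centroids = np.stack([lo, hi])
    labels = np.zeros(len(features), dtype=int)
    for _ in range(max_iter):
        d = np.linalg.norm(features[:, None, :] - centroids[None, :, :], axis=2)
        new = np.argmin(d, axis=1)
        if np.array_equal(new, labels) and _ > 0:
            break
        labels = new
        for c in (0, 1):
            if (labels == c).any():
                centroids[c] = features[labels == c].mean(axis=0)
    return labels


def _fill_small_holes(mask: np.ndarray, max_hole_px: int = 2) -> np.ndarray:
    """Fill enclosed off-sample pockets of at most ``max_hole_px`` pixels."""
    inv = ~mask
    lab, n = ndimage.label(inv)
    out = mask.copy()
    h, w = mask.shape
    for i in range(1, n + 1):
        comp = lab == i
        size = int(comp.sum())
        touches_border = (
            comp[0, :].any() or comp[-1, :].any() or comp[:, 0].any() or comp[:, -1].any()
        )
        if not touches_border and size <= max_hole_px:
            out |= comp
    return out


def segment(dataset: MSIDataset, denoise_radius: int = 1) -> SegmentationMask:
    """Partition pixels into sample and off-sample regions.

    Summary features (log TIC, peak count) are median-filtered with the
    given radius (radius 1 is the "weak" default), clustered into two
    groups, and the cluster with the higher mean TIC becomes the sample;
    when the clusters tie (all spectra identical), the whole grid is
    sample.  The largest connected sample component is kept and holes of
    at most 2 pixels are filled.
    """
    if len(dataset) < 2:
        raise ValueError("cannot segment a single-pixel dataset")
    tic = dataset.tic_image()
    counts = dataset.peak_count_image()
    size = 2 * denoise_radius + 1
    log_tic = ndimage.median_filter(np.log1p(tic), size=size, mode="nearest")
    counts_f = ndimage.median_filter(counts, size=size, mode="nearest")

    feats = np.stack([log_tic.ravel(), counts_f.ravel()], axis=1)
    # standardize so the two features weigh equally
    std = feats.std(axis=0)
    std[std == 0] = 1.0
    feats_z = (feats - feats.mean(axis=0)) / std
    labels = _two_means(feats_z).reshape(tic.shape)

    means = [tic[labels == c].mean() if (labels == c).any() else -np.inf for c in (0, 1)]
    if not (labels == 1).any() or means[0] == means[1]:
        sample = np.ones_like(labels, dtype=bool)  # tie: whole grid is sample
    else:
        sample = labels == int(np.argmax(means))

    lab, n = ndimage.label(sample)
    if n > 1:
        sizes = ndimage.sum(sample, lab, index=range(1, n + 1))
        sample = lab == (1 + int(np.argmax(sizes)))
    sample = _fill_small_holes(sample, max_hole_px=2)
    if not sample.any():
        sample = np.ones_like(sample)
    return SegmentationMask(
        labels=sample,
        provenance={"denoise_radius": denoise_radius, "features": ["log_tic", "peak_count"]},
    )


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard overlap of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
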