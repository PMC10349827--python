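"""Synthetic biosolid-deposit phantoms with known ground truth.

A phantom emulates one deposited biosolid droplet imaged by MALDI-MSI at a
50 µm raster: a roughly circular deposit on a rectangular grid, analyte
maps whose radial placement is driven by water solubility and soil
adsorption (solvent-forced migration pushes polar, weakly adsorbing
compounds to the rim), isotopically resolved peaks with sub-ppm mass
jitter, matrix and baseline noise, a slight accumulation of material on
the deposit periphery, and optional calibration spots (a dilution series
on the bare slide plus an attenuated spike on the sample) for
extinction-factor quantification.

Every stochastic choice flows from one seed, so a scene renders
byte-identically under fixed encoder settings, and the true spatial
class, peripheral index, amounts and extinction factor are emitted
alongside the dataset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import chem
from .io import MSIDataset, Spectrum

__all__ = [
    "PhantomAnalyte",
    "QuantSpot",
    "QuantLayout",
    "SceneConfig",
    "PhantomScene",
    "placement_index",
    "build_scene",
    "render",
]

# Shared placement convention: the classifier in spatial metrics uses the
# same thresholds, so ground-truth recovery closes the loop.
PI_PERIPHERY = 0.65
PI_CENTER = 0.35


def placement_index(
    s_mg_l: float,
    koc_l_kg: float,
    alpha: float = 1.0,
    beta: float = 1.0,
    mu_log_s: float = 2.0,
    mu_log_koc: float = 3.0,
) -> float:
    """Peripheral placement index in [0, 1] from physico-chemical properties.

    logistic(alpha*(log10 S - mu_S) - beta*(log10 Koc - mu_K)): highly
    soluble, weakly adsorbing compounds migrate with the solvent front to
    the deposit rim (index -> 1); hydrophobic, strongly adsorbing compounds
    stay central (index -> 0).  Defaults put the midpoint at S = 100 mg/L
    and Koc = 1000 L/kg.
    """
    if s_mg_l <= 0 or koc_l_kg <= 0:
        raise ValueError("solubility and Koc must be positive")
    z = alpha * (math.log10(s_mg_l) - mu_log_s) - beta * (math.log10(koc_l_kg) - mu_log_koc)
    return 1.0 / (1.0 + math.exp(-z))


def class_from_pi(pi: float) -> str:
    if pi >= PI_PERIPHERY:
        return "periphery"
    if pi <= PI_CENTER:
        return "center"
    return "uniform"


@dataclass
class PhantomAnalyte:
    """One compound planted in a scene, with its ground truth."""

    name: str
    formula: str
    ion_label: str = "[M+H]+"
    s_mg_l: float = 100.0
    koc_l_kg: float = 1000.0
    amplitude: float = 5000.0
    family: str = "unclassified"

    def ion(self, adducts=None) -> chem.IonSpecies:
        adducts = adducts or chem.load_adducts()
        table = {a.label: a for pol in adducts.values() for a in pol}
        if self.ion_label not in table:
            raise ValueError(f"unknown ion label {self.ion_label!r}")
        return table[self.ion_label].apply(chem.parse_formula(self.formula))


@dataclass
class QuantSpot:
    """A calibration spot: dilution-series point on the slide, the spike on
    the sample, or the on-sample background ROI (amount 0)."""

    kind: str  # "slide" | "sample_spike" | "sample_background"
    cx: int
    cy: int
    radius_px: int
    amount: float = 0.0


@dataclass
class QuantLayout:
    """Quantification scene layout and signal model parameters."""

    analyte: str
    unit: str  # "ug" | "pmol"
    spots: list[QuantSpot]
    extinction: float = 0.5  # true matrix attenuation E on the sample
    sensitivity: float = 2000.0  # total spot signal per unit amount, bare slide
    true_amount_per_deposit: float = 5.0  # analyte native to the whole deposit
    deposit_mass_g: float = 0.08
    molar_mass: float | None = None  # g/mol, needed when unit is molar

    def spot(self, kind: str) -> QuantSpot:
        matches = [s for s in self.spots if s.kind == kind]
        if not matches:
            raise ValueError(f"layout has no {kind!r} spot")
        return matches[0]

    def slide_spots(self) -> list[QuantSpot]:
        return [s for s in self.spots if s.kind == "slide"]


@dataclass
class SceneConfig:
    """Everything needed to build a scene, JSON-serializable."""

    width: int = 60
    height: int = 60
    pixel_size_um: float = 50.0
    polarity: str = "positive"
    mass_range: tuple[float, float] = (100.0, 1000.0)
    center: tuple[float, float] | None = None  # defaults to grid center
    radius_px: float | None = None  # defaults to 0.4 * min(width, height)
    rim_band: tuple[float, float] = (0.7, 1.0)  # annulus support, r/R
    blob_sigma_frac: float = 0.2  # central blob sigma as fraction of R
    blob_cutoff_frac: float = 0.5  # central blob truncated at this r/R
    rim_thickness_gain: float = 0.1  # extra material on the outer rim
    rim_thickness_band: tuple[float, float] = (0.85, 1.0)
    analytes: list[PhantomAnalyte] = field(default_factory=list)
    matrix_peaks: list[tuple[float, float]] | None = None  # (m/z, amplitude)
    deposit_background_peaks: list[tuple[float, float]] | None = None
    baseline_level: float = 30.0
    n_baseline_peaks: int = 20
    lognormal_sigma: float = 0.2
    mz_jitter_ppm: float = 0.5
    quant: QuantLayout | None = None
    placement_alpha: float = 1.0
    placement_beta: float = 1.0
    placement_mu_log_s: float = 2.0
    placement_mu_log_koc: float = 3.0

    def resolved_center(self) -> tuple[float, float]:
        return self.center or ((self.width - 1) / 2.0, (self.height - 1) / 2.0)

    def resolved_radius(self) -> float:
        return self.radius_px or 0.4 * min(self.width, self.height)

    def default_matrix_peaks(self) -> list[tuple[float, float]]:
        if self.matrix_peaks is not None:
            return self.matrix_peaks
        lo, hi = self.mass_range
        # generic matrix-cluster peaks spread over the acquired range
        anchors = [0.12, 0.27, 0.45, 0.63, 0.81]
        return [(lo + f * (hi - lo), 1500.0) for f in anchors]

    def default_background_peaks(self) -> list[tuple[float, float]]:
        if self.deposit_background_peaks is not None:
            return self.deposit_background_peaks
        lo, hi = self.mass_range
        # biosolids are chemically rich: a dozen ubiquitous sample ions keep
        # the deposit's TIC and peak count well above the bare slide even
        # where no screened analyte lives
        anchors = np.linspace(0.05, 0.97, 24)
        return [(lo + float(f) * (hi - lo), 3000.0) for f in anchors]


@dataclass
class PhantomScene:
    """A built scene: config plus derived ground truth, ready to render."""

    config: SceneConfig
    seed: int
    deposit_mask: np.ndarray  # bool (H, W), True on the deposit
    radius_map: np.ndarray  # r/R per pixel
    analyte_truth: pd.DataFrame  # name, family, pi, spatial_class, S, Koc
    analyte_maps: dict[str, np.ndarray]  # noiseless intensity maps

    def truth_for(self, name: str) -> pd.Series:
        return self.analyte_truth.set_index("name").loc[name]


def _geometry(config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    cx, cy = config.resolved_center()
    R = config.resolved_radius()
    yy, xx = np.mgrid[0 : config.height, 0 : config.width]
    r = np.hypot(xx - cx, yy - cy) / R
    return r, (r <= 1.0)


def _component_maps(config: SceneConfig, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central blob and rim annulus, each normalized to unit mean over its
    reference region so a placement-index mixture reads back as roughly the
    same index from the rendered image."""
    blob = np.exp(-0.5 * (r / config.blob_sigma_frac) ** 2)
    blob[r > config.blob_cutoff_frac] = 0.0
    inner = r <= config.blob_cutoff_frac
    if blob[inner].mean() > 0:
        blob = blob / blob[inner].mean()
    lo, hi = config.rim_band
    ann = ((r >= lo) & (r <= hi)).astype(float)
    band = ann > 0
    if band.any():
        ann = ann / ann[band].mean()
    return blob, ann


def build_scene(config: SceneConfig, seed: int = 0) -> PhantomScene:
    """Derive ground truth (placement, classes, noiseless maps) from a config.

    Each analyte map is ``amplitude * ((1-PI)*blob + PI*annulus)`` with a
    global rim-thickness multiplier applied to every analyte, emulating the
    slight accumulation of material on the deposit periphery.
    """
    R = config.resolved_radius()
    if R <= 0:
        raise ValueError("deposit radius must be positive")
    cx, cy = config.resolved_center()
    if cx - R < -0.5 or cy - R < -0.5 or cx + R > config.width - 0.5 or cy + R > config.height - 0.5:
        raise ValueError("deposit does not fit inside the grid")
    r, mask = _geometry(config)
    blob, ann = _component_maps(config, r)
    rim_lo, rim_hi = config.rim_thickness_band
    thickness = 1.0 + config.rim_thickness_gain * ((r >= rim_lo) & (r <= rim_hi))

    rows = []
    maps: dict[str, np.ndarray] = {}
    adducts = chem.load_adducts()
    lo_m, hi_m = config.mass_range
    for a in config.analytes:
        ion = a.ion(adducts)
        if (ion.charge > 0) != (config.polarity == "positive"):
            raise ValueError(f"{a.name}: ion {a.ion_label} charge inconsistent with {config.polarity} polarity")
        mz = chem.ion_mz(ion)
        if not (lo_m <= mz <= hi_m):
            raise ValueError(f"{a.name}: ion m/z {mz:.4f} outside mass range {config.mass_range}")
        pi = placement_index(
            a.s_mg_l,
            a.koc_l_kg,
            config.placement_alpha,
            config.placement_beta,
            config.placement_mu_log_s,
            config.placement_mu_log_koc,
        )
        amap = a.amplitude * ((1.0 - pi) * blob + pi * ann) * thickness
        amap[~mask] = 0.0
        maps[a.name] = amap
        rows.append(
            dict(
                name=a.name,
                family=a.family,
                ion_label=a.ion_label,
                mz=mz,
                pi=pi,
                spatial_class=class_from_pi(pi),
                s_mg_l=a.s_mg_l,
                koc_l_kg=a.koc_l_kg,
            )
        )
    truth = pd.DataFrame(
        rows,
        columns=["name", "family", "ion_label", "mz", "pi", "spatial_class", "s_mg_l", "koc_l_kg"],
    )
    if config.quant is not None:
        _validate_quant(config)
    return PhantomScene(
        config=config,
        seed=seed,
        deposit_mask=mask,
        radius_map=r,
        analyte_truth=truth,
        analyte_maps=maps,
    )


def _validate_quant(config: SceneConfig) -> None:
    q = config.quant
    if not 0 < q.extinction <= 1.0:
        raise ValueError("true extinction factor must lie in (0, 1]")
    _, mask = _geometry(config)
    for s in q.spots:
        if not (0 <= s.cx < config.width and 0 <= s.cy < config.height):
            raise ValueError(f"spot {s.kind} center outside grid")
        on_sample = bool(mask[s.cy, s.cx])
        if s.kind == "slide" and on_sample:
            raise ValueError("slide calibration spot overlaps the deposit")
        if s.kind in ("sample_spike", "sample_background") and not on_sample:
            raise ValueError(f"{s.kind} spot must sit on the deposit")
    if len(q.slide_spots()) < 2:
        raise ValueError("need at least two slide spots for a standard curve")


def _spot_mask(config: SceneConfig, spot: QuantSpot) -> np.ndarray:
    yy, xx = np.mgrid[0 : config.height, 0 : config.width]
    return np.hypot(xx - spot.cx, yy - spot.cy) <= spot.radius_px


def _quant_signal_map(scene: PhantomScene) -> tuple[np.ndarray, chem.IonSpecies]:
    """Noiseless per-pixel signal of the quantification analyte: native
    sample signal (attenuated by E), slide dilution series (linear in
    amount), and the E-attenuated on-sample spike."""
    config = scene.config
    q = config.quant
    analyte = next(a for a in config.analytes if a.name == q.analyte)
    species = analyte.ion()
    sig = np.zeros((config.height, config.width))
    # native analyte spread uniformly over the whole deposit: the deposited
    # suspension carries true_amount_per_deposit of the analyte in total,
    # and its on-sample response is attenuated by E like the spike
    n_deposit_px = int(scene.deposit_mask.sum())
    density = q.extinction * q.sensitivity * q.true_amount_per_deposit / n_deposit_px
    sig[scene.deposit_mask] += density
    for s in q.spots:
        m = _spot_mask(config, s)
        if s.kind == "slide":
            sig[m] += q.sensitivity * s.amount / m.sum()
        elif s.kind == "sample_spike":
            sig[m] += q.extinction * q.sensitivity * s.amount / m.sum()
    return sig, species


def render(scene: PhantomScene) -> tuple[MSIDataset, dict]:
    """Render a scene to an in-memory MSI dataset plus ground-truth tables.

    Per pixel: each analyte contributes its ion's isotope pattern (base
    peak scaled to the map value), modulated by one multiplicative
    lognormal factor per analyte-pixel and jittered in m/z by a centered
    Gaussian of the configured ppm width; matrix peaks appear everywhere,
    deposit-background peaks on the sample only, and an exponential-
    intensity chemical baseline is strewn across the mass range.
    """
    config = scene.config
    rng = np.random.default_rng(scene.seed)
    H, W = config.height, config.width
    sigma = config.lognormal_sigma
    jit = config.mz_jitter_ppm * 1e-6
    lo_m, hi_m = config.mass_range

    def noise_field() -> np.ndarray:
        if sigma <= 0:
            return np.ones((H, W))
        return np.exp(rng.normal(0.0, sigma, size=(H, W)))

    def jitter_field() -> np.ndarray:
        if jit <= 0:
            return np.zeros((H, W))
        return rng.normal(0.0, jit, size=(H, W))

    # (theo m/z, per-pixel intensity field, per-pixel jitter field)
    channels: list[tuple[float, np.ndarray, np.ndarray]] = []
    patterns: dict[str, chem.IsotopePattern] = {}
    quant_name = config.quant.analyte if config.quant is not None else None
    for a in config.analytes:
        pattern = chem.theoretical_pattern(a.ion())
        patterns[a.name] = pattern
        if a.name == quant_name:
            continue  # rendered through the quant signal model below
        base = pattern.base_peak()[1]
        amap = scene.analyte_maps[a.name] * noise_field()
        for mz_p, ab_p in pattern.peaks:
            channels.append((mz_p, amap * (ab_p / base), jitter_field()))

    if config.quant is not None:
        qsig, qspecies = _quant_signal_map(scene)
        pattern = chem.theoretical_pattern(qspecies)
        base = pattern.base_peak()[1]
        qsig = qsig * noise_field()
        for mz_p, ab_p in pattern.peaks:
            channels.append((mz_p, qsig * (ab_p / base), jitter_field()))

    deposit = scene.deposit_mask.astype(float)
    for mz_p, amp in config.default_matrix_peaks():
        channels.append((mz_p, np.full((H, W), amp) * noise_field(), jitter_field()))
    for mz_p, amp in config.default_background_peaks():
        channels.append((mz_p, deposit * amp * noise_field(), jitter_field()))

    n_base = config.n_baseline_peaks
    if n_base > 0 and config.baseline_level > 0:
        base_mz = rng.uniform(lo_m, hi_m, size=(H, W, n_base))
        base_int = rng.exponential(config.baseline_level, size=(H, W, n_base))
    else:
        base_mz = np.empty((H, W, 0))
        base_int = np.empty((H, W, 0))

    ch_mz = np.array([c[0] for c in channels])
    ch_int = np.stack([c[1] for c in channels], axis=-1) if channels else np.empty((H, W, 0))
    ch_jit = np.stack([c[2] for c in channels], axis=-1) if channels else np.empty((H, W, 0))

    spectra = []
    for y in range(H):
        for x in range(W):
            inten = ch_int[y, x]
            keep = inten > 1e-9
            mzs = ch_mz[keep] * (1.0 + ch_jit[y, x][keep])
            ints = inten[keep]
            mzs = np.concatenate([mzs, base_mz[y, x]])
            ints = np.concatenate([ints, base_int[y, x]])
            order = np.argsort(mzs)
            mzs, ints = mzs[order], ints[order]
            # enforce strictly ascending axis (rare jitter collisions)
            if mzs.size > 1:
                close = np.diff(mzs) < 1e-9
                if close.any():
                    keep2 = np.concatenate([[True], ~close])
                    ints = np.add.reduceat(ints, np.flatnonzero(keep2))
                    mzs = mzs[keep2]
            spectra.append(Spectrum(x=x, y=y, mode="centroid", mz=mzs, intensity=ints))

    dataset = MSIDataset(
        width=W,
        height=H,
        spectra=spectra,
        pixel_size_um=config.pixel_size_um,
        polarity=config.polarity,
        mass_range=config.mass_range,
        metadata={"mode": "centroid", "phantom_seed": scene.seed},
    )
    truth = {
        "analytes": scene.analyte_truth,
        "deposit_mask": scene.deposit_mask,
        "maps": scene.analyte_maps,
        "patterns": patterns,
    }
    if config.quant is not None:
        q = config.quant
        truth["quant"] = {
            "analyte": q.analyte,
            "unit": q.unit,
            "extinction": q.extinction,
            "sensitivity": q.sensitivity,
            "true_amount_per_deposit": q.true_amount_per_deposit,
            "deposit_mass_g": q.deposit_mass_g,
        }
    return dataset, truth


# ---------------------------------------------------------------------------
# Serialization helpers
# ---------------------------------------------------------------------------

def scene_config_to_json(config: SceneConfig, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True)


def scene_config_from_json(path: str) -> SceneConfig:
    with open(path) as fh:
        raw = json.load(fh)
    raw["analytes"] = [PhantomAnalyte(**a) for a in raw.get("analytes", [])]
    if raw.get("quant"):
        raw["quant"]["spots"] = [QuantSpot(**s) for s in raw["quant"]["spots"]]
        raw["quant"] = QuantLayout(**raw["quant"])
    for key in ("mass_range", "rim_band", "rim_thickness_band"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    if raw.get("center") is not None:
        raw["center"] = tuple(raw["center"])
    if raw.get("matrix_peaks") is not None:
        raw["matrix_peaks"] = [tuple(p) for p in raw["matrix_peaks"]]
    if raw.get("deposit_background_peaks") is not None:
        raw["deposit_background_peaks"] = [tuple(p) for p in raw["deposit_background_peaks"]]
    return SceneConfig(**raw)


def truth_to_tsv(truth: dict, path: str) -> None:
    truth["analytes"].to_csv(path, sep="\t", index=False)


def suspect_list_from_scene(
    scene: PhantomScene, decoys: list[PhantomAnalyte] | None = None
) -> pd.DataFrame:
    """Suspect-list table (screening input) for a scene's analytes plus
    optional decoy compounds not actually rendered."""
    rows = []
    for a in list(scene.config.analytes) + list(decoys or []):
        rows.append(
            dict(
                name=a.name,
                formula=a.formula,
                neutral_mass="",
                family=a.family,
                water_solubility_mg_L=a.s_mg_l,
                log_koc=math.log10(a.koc_l_kg),
                id="",
            )
        )
    return pd.DataFrame(rows)
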