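"""Shared fixtures: phantom scenes and cached pipeline recovery runs.

The heavy fixtures run the full pipeline over many seeds once per session;
tests then assert recovery statistics against the phantom ground truth.
"""

from __future__ import annotations

import numpy as np
import pytest

import biosolid_msi as b
from biosolid_msi import phantom, screening, segmentation, spatial
from biosolid_msi.cli import (
    RunConfig,
    demo_quant_scene_config,
    demo_scene_config,
    run_quant,
    run_screen,
)

# Suspects never planted in any scene; their adduct masses are all >= 10 ppm
# from every rendered peak (analyte isotopologues, matrix and background
# ions), so any hit on them is a false positive.
DECOY_ANALYTES = [
    phantom.PhantomAnalyte("atrazine-like", "C8H14ClN5", "[M+H]+", 35.0, 100.0, family="pesticides"),
    phantom.PhantomAnalyte("diuron-like", "C9H10Cl2N2O", "[M+H]+", 42.0, 813.0, family="pesticides"),
    phantom.PhantomAnalyte("bisphenolA-like", "C15H16O2", "[M+H]+", 120.0, 715.0, family="plastics additives"),
    phantom.PhantomAnalyte("caffeine-like", "C8H10N4O2", "[M+H]+", 21600.0, 22.0, family="stimulants"),
    phantom.PhantomAnalyte("naproxen-like", "C14H14O3", "[M+H]+", 15.9, 870.0, family="pharmaceuticals"),
]


def suspect_entries(scene: phantom.PhantomScene, decoys=()) -> list[screening.SuspectEntry]:
    entries = []
    for a in list(scene.config.analytes) + list(decoys):
        entries.append(
            screening.SuspectEntry(
                name=a.name,
                formula=a.formula,
                family=a.family,
                water_solubility_mg_l=a.s_mg_l,
                log_koc=float(np.log10(a.koc_l_kg)),
            )
        )
    return entries


@pytest.fixture(scope="session")
def recovery_runs():
    """Screen 20 independently seeded phantoms against planted + decoy
    suspects; keep the per-seed mask overlap, hits and spatial report."""
    runs = []
    for seed in range(20):
        cfg = demo_scene_config()
        scene = b.build_scene(cfg, seed)
        dataset, truth = b.render(scene)
        suspects = suspect_entries(scene, DECOY_ANALYTES)
        res = run_screen(dataset, suspects, RunConfig())
        runs.append(
            dict(
                seed=seed,
                truth=scene.analyte_truth,
                planted={a.name for a in cfg.analytes},
                decoys={a.name for a in DECOY_ANALYTES},
                jaccard=segmentation.jaccard(res["mask"].labels, truth["deposit_mask"]),
                hits=res["hits"],
                spatial=res["spatial_report"],
                correlation=spatial.physchem_correlation(res["hits"]),
            )
        )
    return runs


TRUE_EXTINCTION = 0.4
TRUE_CONC_MG_KG = 91.48


@pytest.fixture(scope="session")
def quant_runs():
    """Extinction-factor quantification on 200 independently seeded
    phantom replicates at default noise (copper scene, planted E = 0.4
    and 91.48 mg/kg)."""
    theo = b.ion_mz(b.metal_chloride_ion("Cu", 2))
    out = []
    for seed in range(200):
        cfg = demo_quant_scene_config(extinction=TRUE_EXTINCTION, concentration_mg_per_kg=TRUE_CONC_MG_KG)
        scene = b.build_scene(cfg, seed)
        dataset, _ = b.render(scene)
        res = run_quant(dataset, cfg.quant, theo)
        out.append((res.extinction, res.concentration_mg_per_kg))
    return np.asarray(out)


@pytest.fixture()
def noiseless_quant_scene():
    cfg = demo_quant_scene_config(extinction=TRUE_EXTINCTION, concentration_mg_per_kg=TRUE_CONC_MG_KG)
    cfg.lognormal_sigma = 0.0
    cfg.mz_jitter_ppm = 0.0
    cfg.baseline_level = 0.0
    cfg.n_baseline_peaks = 0
    return cfg


def tiny_scene_config(**overrides) -> phantom.SceneConfig:
    """A fast 30x30 scene with two well-separated analytes."""
    cfg = phantom.SceneConfig(
        width=30,
        height=30,
        radius_px=12.0,
        analytes=[
            phantom.PhantomAnalyte("rim-compound", "C8H10N4O2", "[M+H]+", 2.16e4, 22.0, family="A"),
            phantom.PhantomAnalyte("core-compound", "C16H10", "[M+H]+", 0.1, 9e4, family="B"),
        ],
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg
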