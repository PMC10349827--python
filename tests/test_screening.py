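"""Feature extraction, suspect annotation, ion images, confirmations."""

import warnings

import numpy as np
import pytest

import biosolid_msi as b
from biosolid_msi import chem, screening
from biosolid_msi.io import MSIDataset, Spectrum
from biosolid_msi.segmentation import SegmentationMask
from conftest import tiny_scene_config

TABLE = chem.ElementIsotopeTable.default()


def _grid_dataset(width, height, peak_lists):
    """Dataset with identical or per-pixel peak lists on a full grid."""
    spectra = []
    for y in range(height):
        for x in range(width):
            peaks = peak_lists(x, y) if callable(peak_lists) else peak_lists
            if peaks:
                mz, inten = map(np.asarray, zip(*sorted(peaks)))
            else:
                mz, inten = np.empty(0), np.empty(0)
            spectra.append(Spectrum(x, y, "centroid", mz, inten))
    return MSIDataset(width=width, height=height, spectra=spectra)


def _full_mask(width, height):
    return SegmentationMask(labels=np.ones((height, width), bool))


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def test_intensity_threshold_is_inclusive_at_500():
    """A feature peaking at 499 is dropped at the 500 threshold; at 500 it
    is kept."""
    for peak_int, expected in [(499.0, 0), (500.0, 1)]:
        ds = _grid_dataset(3, 3, [(300.0, peak_int)])
        table = screening.extract_features(
            ds, _full_mask(3, 3), intensity_threshold=500.0, min_pixels=1
        )
        assert len(table) == expected


def test_min_pixels_speckle_filter():
    def peaks(x, y):
        return [(300.0, 600.0)] if (x, y) in {(0, 0), (1, 1)} else [(300.0, 10.0)]

    ds = _grid_dataset(3, 3, peaks)
    ok = screening.extract_features(ds, _full_mask(3, 3), 500.0, min_pixels=2)
    assert len(ok) == 1
    dropped = screening.extract_features(ds, _full_mask(3, 3), 500.0, min_pixels=3)
    assert len(dropped) == 0


def test_close_masses_form_distinct_features():
    mz0 = 400.0
    mz1 = 400.0 * (1 + 10e-6)  # 10 ppm apart: beyond the 3 ppm linkage
    ds = _grid_dataset(3, 3, [(mz0, 800.0), (mz1, 900.0)])
    table = screening.extract_features(ds, _full_mask(3, 3), 500.0, min_pixels=1)
    assert len(table) == 2


def test_jittered_peaks_merge_into_one_feature():
    def peaks(x, y):
        return [(400.0 * (1 + 0.4e-6 * (x - 1)), 800.0)]

    ds = _grid_dataset(3, 3, peaks)
    table = screening.extract_features(ds, _full_mask(3, 3), 500.0, min_pixels=1)
    assert len(table) == 1
    assert table.features[0].mz == pytest.approx(400.0, abs=0.001)


def test_empty_sample_region_raises():
    ds = _grid_dataset(2, 2, [(300.0, 600.0)])
    empty = SegmentationMask(labels=np.zeros((2, 2), bool))
    with pytest.raises(ValueError):
        screening.extract_features(ds, empty)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _feature_table_at(mzs, pattern=None):
    """FeatureTable with one feature per m/z; the mean spectrum mirrors a
    theoretical pattern when given (so sigma is 0)."""
    feats = [screening.Feature(mz, 1000.0, 10, 100.0) for mz in mzs]
    mean = pattern if pattern is not None else [(mz, 1.0) for mz in mzs]
    return screening.FeatureTable(feats, 100, 500.0, sorted(mean))


def test_ppm_gate_boundary_inclusive():
    suspect = screening.SuspectEntry("caffeine-like", formula="C8H10N4O2")
    species = chem.load_adducts()["positive"][0].apply(chem.parse_formula("C8H10N4O2"))
    theo = chem.ion_mz(species, TABLE)
    pattern = chem.theoretical_pattern(species, TABLE)

    at_3 = _feature_table_at([theo * (1 + 3.0e-6)], pattern=[(m * (1 + 3.0e-6), a) for m, a in pattern.peaks])
    hits = screening.annotate(at_3, [suspect], ppm_tol=3.0)
    assert [h.suspect.name for h in hits] == ["caffeine-like"]

    at_31 = _feature_table_at([theo * (1 + 3.1e-6)], pattern=[(m * (1 + 3.1e-6), a) for m, a in pattern.peaks])
    assert screening.annotate(at_31, [suspect], ppm_tol=3.0) == []


def test_sigma_gate_boundary_at_30():
    """A fit of exactly sigma 30 passes; 30.01 fails."""
    formula = "C8H14ClN5"
    suspect = screening.SuspectEntry("atrazine-like", formula=formula)
    species = chem.load_adducts()["positive"][0].apply(chem.parse_formula(formula))
    theo_mz = chem.ion_mz(species, TABLE)
    pattern = chem.theoretical_pattern(species, TABLE)
    top3 = sorted(pattern.peaks, key=lambda p: -p[1])[:3]
    norm = sum(ab for _, ab in top3)
    target = [ab / norm for _, ab in top3]

    def measured(sigma):
        a = (sigma / 1000.0) * np.sqrt(3.0 / 2.0)
        perturbed = [target[0] + a, target[1] - a, target[2]]
        return sorted((mz, p) for (mz, _), p in zip(top3, perturbed))

    for sigma, n_expected in [(30.0, 1), (30.01, 0)]:
        table = _feature_table_at([theo_mz], pattern=measured(sigma))
        hits = screening.annotate(table, [suspect], sigma_max=30.0)
        assert len(hits) == n_expected, f"sigma {sigma}"
        if hits:
            assert hits[0].sigma == pytest.approx(sigma, abs=1e-9)
            assert hits[0].level == 3


def test_mass_only_suspect_annotated_at_level_5():
    neutral = 310.1234
    adduct = chem.load_adducts()["positive"][0]
    suspect = screening.SuspectEntry("unknown-pop", neutral_mass=neutral)
    table = _feature_table_at([neutral + adduct.mass_shift(TABLE)])
    hits = screening.annotate(table, [suspect])
    assert len(hits) == 1
    assert hits[0].level == 5
    assert hits[0].sigma is None


def test_ambiguous_suspects_both_reported():
    f = "C8H10N4O2"
    species = chem.load_adducts()["positive"][0].apply(chem.parse_formula(f))
    theo = chem.ion_mz(species, TABLE)
    pattern = chem.theoretical_pattern(species, TABLE)
    table = _feature_table_at([theo], pattern=list(pattern.peaks))
    suspects = [
        screening.SuspectEntry("isomer-a", formula=f),
        screening.SuspectEntry("isomer-b", formula=f),
    ]
    hits = screening.annotate(table, suspects)
    assert {h.suspect.name for h in hits} == {"isomer-a", "isomer-b"}
    assert all(h.ambiguous for h in hits)


def test_annotation_matches_brute_force_enumeration():
    """Hit set equals an independent exhaustive scan over all suspect x
    adduct x feature pairs on a constructed spectrum."""
    formulas = {
        "s1": "C8H10N4O2",
        "s2": "C16H10",
        "s3": "C9H10Cl2N2O",
        "s4": "C15H16O2",
        "s5": "C8H14ClN5",
    }
    adducts = chem.load_adducts()["positive"]
    rendered = ["s1", "s3"]  # planted as [M+H]+ with exact patterns
    mean_spec = []
    feature_mzs = []
    for name in rendered:
        species = adducts[0].apply(chem.parse_formula(formulas[name]))
        pattern = chem.theoretical_pattern(species, TABLE)
        mean_spec += list(pattern.peaks)
        feature_mzs.append(chem.ion_mz(species, TABLE))
    table = _feature_table_at(feature_mzs, pattern=mean_spec)
    suspects = [screening.SuspectEntry(n, formula=f) for n, f in formulas.items()]
    hits = screening.annotate(table, suspects, ppm_tol=3.0, sigma_max=30.0)
    got = {(h.suspect.name, h.ion_label) for h in hits}

    expected = set()
    for name, formula in formulas.items():
        for adduct in adducts:
            species = adduct.apply(chem.parse_formula(formula))
            theo = chem.ion_mz(species, TABLE)
            for fmz in feature_mzs:
                if abs(fmz - theo) / theo * 1e6 <= 3.0 + 1e-9:
                    sig = chem.sigma_fit(
                        table.mean_spectrum, chem.theoretical_pattern(species, TABLE), 3.0
                    )
                    if sig <= 30.0 + 1e-9:
                        expected.add((name, adduct.label))
    assert got == expected
    assert {n for n, _ in got} == set(rendered)


def test_polarity_adduct_consistency_enforced():
    table = _feature_table_at([200.0])
    with pytest.raises(ValueError):
        screening.annotate(
            table,
            [screening.SuspectEntry("x", formula="C16H10")],
            adducts=chem.load_adducts()["negative"],
            polarity="positive",
        )


# ---------------------------------------------------------------------------
# ion images
# ---------------------------------------------------------------------------

def test_ion_image_empty_window_is_zero():
    ds = _grid_dataset(3, 3, [(300.0, 100.0)])
    img = screening.ion_image(ds, 500.0)
    assert not img.any()


def test_ion_image_tracks_ground_truth_map():
    cfg = tiny_scene_config()
    cfg.lognormal_sigma = 0.0
    cfg.mz_jitter_ppm = 0.0
    cfg.baseline_level = 0.0
    cfg.n_baseline_peaks = 0
    scene = b.build_scene(cfg, 0)
    ds, truth = b.render(scene)
    for a in cfg.analytes:
        theo = chem.ion_mz(a.ion())
        img = screening.ion_image(ds, theo, 3.0)
        amap = scene.analyte_maps[a.name]
        r = np.corrcoef(img.ravel(), amap.ravel())[0, 1]
        assert r >= 0.99


def test_ion_image_window_monotone():
    scene = b.build_scene(tiny_scene_config(), seed=8)
    ds, _ = b.render(scene)
    theo = chem.ion_mz(scene.config.analytes[0].ion())
    wide = screening.ion_image(ds, theo, 3.0)
    narrow = screening.ion_image(ds, theo, 1.5)
    assert np.all(narrow <= wide + 1e-9)


# ---------------------------------------------------------------------------
# confirmations
# ---------------------------------------------------------------------------

def _toy_hits():
    return [
        screening.AnnotationHit(
            screening.SuspectEntry("cmpd-a", formula="C16H10"), "[M+H]+", 203.0, 203.0, 0.1, 5.0
        ),
        screening.AnnotationHit(
            screening.SuspectEntry("cmpd-b", formula="C15H16O2"), "[M+H]+", 229.1, 229.1, 0.2, 4.0
        ),
    ]


def test_confirmations_empty_list_is_noop():
    hits = _toy_hits()
    screening.apply_confirmations(hits, [])
    assert [h.level for h in hits] == [3, 3]


def test_confirmation_promotes_to_level_1_idempotently():
    hits = _toy_hits()
    screening.apply_confirmations(hits, ["cmpd-b"])
    assert [h.level for h in hits] == [3, 1]
    screening.apply_confirmations(hits, ["cmpd-b"])
    assert [h.level for h in hits] == [3, 1]


def test_unknown_confirmation_warns_without_change():
    hits = _toy_hits()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        screening.apply_confirmations(hits, ["never-seen"])
    assert any("never-seen" in str(w.message) for w in caught)
    assert [h.level for h in hits] == [3, 3]


def test_family_summary_counts_distinct_compounds():
    hits = _toy_hits() + [
        screening.AnnotationHit(
            screening.SuspectEntry("cmpd-a", formula="C16H10"), "[M+Na]+", 225.0, 225.0, 0.1, 5.0
        )
    ]
    hits[0].suspect.family = "A"
    hits[2].suspect.family = "A"
    hits[1].suspect.family = "B"
    summary = screening.family_summary(hits)
    assert dict(zip(summary["family"], summary["n_compounds"])) == {"A": 1, "B": 1}
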