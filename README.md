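# biosolid-msi

Suspect screening, spatial profiling and quantification of **heavy metals
(HMs)** and **persistent organic pollutants (POPs)** in MALDI mass
spectrometry images of biosolid deposits.

Biosolids — the stabilized residue of wastewater treatment — are reused in
agriculture and engineering, so their contaminant load must be
characterized before reuse. MALDI-MSI records one high-resolution mass
spectrum per 50 µm raster pixel of a dried biosolid deposit and can screen
hundreds of contaminants at once: organic pollutants appear in positive
mode as [M+H]⁺ / [M+Na]⁺ / [M+K]⁺ / [M+NH₄]⁺ adducts, while heavy metals
appear in negative mode as chloride adduct anions ([MCl₂]⁻, [MCl₃]⁻)
formed with chloride released by the NEDC matrix, whose distinctive
isotope patterns confirm the metal.

The package implements the full desk-side workflow:

* **`chem`** — exact ion m/z (principal isotope of each element, electron
  mass included: m/z = (Σmᵢ − z·mₑ)/|z|), theoretical isotope patterns by
  exhaustive multinomial enumeration, and an isotope-fit score
  σ = 1000·√(Σ(Îₘ − Îₜ)²/k) over the k ≤ 3 most abundant isotopologues,
  gated at σ ≤ 30 ("0 = perfect fit").
* **`io`** — imzML 1.1 read/write (continuous + processed) via pyimzML,
  plus MAD-noise peak picking with parabolic apex interpolation.
* **`segmentation`** — RMS normalization, weakly denoised (median-filtered)
  log-TIC/peak-count features, deterministic 2-means sample vs. off-sample
  partition with connected-component cleanup.
* **`screening`** — 3 ppm single-linkage feature building over the sample
  region (intensity threshold 500, ≥ 5 pixels), suspect × adduct matching
  at ≤ 3 ppm with the σ ≤ 30 isotope gate, Schymanski confidence levels
  (3 tentative with isotope evidence, 5 exact mass only, promoted to 1 by
  external confirmation), ±3 ppm ion images and contaminant-family
  summaries.
* **`spatial`** — sample coverage (% of sample pixels ≥ 5% of the image
  maximum), radial profiles, a peripheral index
  PI = Ī(0.7 ≤ r/R ≤ 1.05) / (Ī(outer) + Ī(r/R ≤ 0.5)), a
  periphery/center/uniform classification, and Spearman correlations of PI
  with water solubility and the soil adsorption coefficient K_oc. The
  deposition solvent forces migration: polar, weakly adsorbing compounds
  ride to the rim, hydrophobic strongly adsorbing ones stay central, so
  the spatial class itself carries chemical evidence.
* **`quant`** — standard-curve quantification with a per-sample
  **extinction factor** E = (I_spike-on-sample − I_background)/I_top-on-slide
  (the MSI analogue of an LC matrix effect); the calibration curve is
  rescaled by E and the sample's background signal is read off it,
  yielding mg/kg via the deposited biosolid dry mass (default 0.08 g).
* **`phantom`** — a synthetic scene generator with full ground truth
  (deposit geometry, per-analyte placement driven by solubility/K_oc
  through a logistic placement index, isotope-resolved peaks with 0.5 ppm
  mass jitter, multiplicative lognormal noise, matrix/baseline ions,
  calibration spot layouts with a planted E), used to validate every stage
  by recovery.
* **`cli`** — `biosolid-msi simulate | segment | screen | quant | all`.

## Worked example

Simulate a phantom deposit with six organic pollutants spanning the
solubility/K_oc plane, then screen and spatialize it end to end:

```sh
$ biosolid-msi all --seed 1 --out demo_out
6 hits; Spearman(PI, logS)=1.0
```

`demo_out/spatial_report.tsv` then starts:

```text
name                mz          coverage_pct  peripheral_index  spatial_class  log_s  log_koc
carbamazepine-like  237.102242  51.44         0.976             periphery      4.26   1.60
metformin-like      130.108718  51.22         0.993             periphery      5.00   1.08
```

All six planted compounds are annotated at level 3 with ≤ 3 ppm mass error,
their periphery/center/uniform classes match the generator's ground truth,
and `physchem_correlation.json` reports ρ(PI, log S) = 1.0 and
ρ(PI, log K_oc) = −1.0 — the hydrophilic compounds sit on the rim, exactly
as solvent-forced migration predicts.

Quantification against a copper chloride-adduct calibration scene (planted
E = 0.4 and 91.48 mg/kg, default noise):

```sh
$ biosolid-msi quant --input q.imzML --layout layout.json --formula Cu --ion "[MCl2]-" --out out
copper: E=0.408, 7.192 ug/deposit, 89.9 mg/kg
```

The extinction factor and concentration are recovered within a few
percent; at zero noise the inversion is exact.

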