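# Methods

This note records the models, conventions and numerical choices behind
`biosolid-msi`, and what the phantom-based validation does and does not
demonstrate.

## Ion mass arithmetic

Ion m/z is computed as (Σ principal-isotope masses − z·mₑ)/|z| with
mₑ = 0.00054858 Da. The electron mass is always applied: the published
chloride-adduct calibration series (NiCl₂⁻ at 127.8735 through CdCl₃⁻ at
218.8104) is reproduced only when the anion gains one electron mass.
"Principal isotope" means the most abundant, not the lightest — for
cadmium that is ¹¹⁴Cd, which is what the CdCl₂⁻/CdCl₃⁻ values require.
Printed calibration masses behave as values truncated (not rounded) to
four decimals; comparisons therefore truncate, with a ±0.0002 Da guard.
Isotope masses and abundances are pinned to a vendored NIST-derived
constants file (`data/isotopes.tsv`, 27 elements) so results do not drift
with library versions; per-element abundances are normalized to sum to 1
within 1e-6 on load.

## Isotope patterns and the sigma score

Theoretical patterns are exact: per-element multinomial distributions over
isotope count vectors are convolved across elements (terms below 1e-12
pruned), isotopologues closer than `merge_tol` (default 0.005 Da, below
FT-ICR peak spacing and above mass-jitter scale) are merged to an
abundance-weighted centroid, and entries below `min_abundance` (default
0.01) are dropped *without* renormalizing, with the retained fraction
recorded. The test suite checks the enumeration against an independent
per-atom cartesian oracle to 1e-9 in abundance.

Commercial software reports a proprietary isotope-fit statistic with the
convention "0 is perfect, ≤ 30 is a good fit". We adopt an open
definition with the same semantics: match the k = min(3, available) most
abundant theoretical peaks to the nearest measured centroids within the
ppm tolerance, normalize both matched intensity vectors to unit sum, and
score 1000·√(Σ(Îₘ − Îₜ)²/k). A required isotopologue with no measured
partner yields an "unmatched" sentinel (+∞) that fails any finite cap.
The score is invariant to uniform intensity scaling and is computed on
the mean sample-region spectrum, which stabilizes low-abundance patterns
relative to per-pixel scoring.

## Annotation gates

All gates are inclusive caps: |ppm error| ≤ 3.0 passes (a 1e-9 epsilon
absorbs float roundoff at the boundary), σ ≤ 30 passes, and a feature
whose maximum pixel intensity reaches 500 is kept. The speckle filter of
the commercial feature finder is proprietary; a minimum-pixel count
(default 5 sample pixels at or above the intensity threshold) stands in
for it and is stated as such. Suspects with only a neutral mass cannot be
isotope-scored and are emitted at Schymanski level 5; suspects with a
formula that pass the isotope gate are level 3; external chromatographic
confirmation promotes a named hit to level 1. Ion images integrate ±3 ppm
about the annotated m/z ("3 ppm window" read as a half-width; the
alternative total-width reading would only narrow images, not change
annotations).

## Segmentation

Spectra are divided by their root-mean-square intensity (all-zero spectra
flagged, not altered). Per-pixel log(1+TIC) and peak count are median
filtered ("weak denoising" = radius 1, configurable), z-scored, and split
by 2-means with deterministic centroids at the 10th/90th percentile
feature vectors. The higher-TIC cluster is the sample; ties label the
whole grid sample. The largest connected sample component is kept and
enclosed holes of ≤ 2 pixels are filled — the programmatic counterpart of
the manual ROI curation a GUI workflow performs. The median filter erodes
a few single pixels at the extreme tips of a circular deposit (their 3×3
neighborhoods are background-dominated); this costs a fraction of a
percent of deposit area and is visible only in zero-noise tests.

## Spatial metrics

Deposit geometry is estimated from the mask itself (centroid +
equivalent-area radius), which is robust to asymmetric deposits. Coverage
is the percentage of sample pixels at or above 5% of the image maximum —
a declared convention, since published coverage figures do not state
their threshold. The peripheral index PI = Ī_outer/(Ī_outer + Ī_inner)
uses rim band r/R ∈ [0.7, 1.05] and core r/R ≤ 0.5, both restricted to
sample pixels (0/0 ↦ 0.5). Classification: coverage ≥ 70% ⇒ uniform,
else PI ≥ 0.65 ⇒ periphery, PI ≤ 0.35 ⇒ center, else uniform. The class
thresholds are repo-defined (published classes are qualitative) and are
deliberately shared with the phantom generator so that recovery is a
closed, testable loop. Property links use Spearman rank correlation
(average ranks on ties) of PI against log₁₀S and log₁₀K_oc, reported with
n and requiring ≥ 5 usable hits.

## Quantification

The slide dilution series is fit by ordinary least squares I = a·q + b.
Spot signal is the *summed* ion-image intensity over the spot ROI (robust
to spot-size variation; mean vs. max vs. sum is unstated in published
workflows). The sample's own analyte signal ("background") is measured as
the mean per-pixel intensity over the segmented sample region excluding
the spike ROI (+2 px margin), scaled to the spike ROI area for the
extinction estimate and to the whole sample region for the deposit
total — averaging over the full deposit rather than one spot-sized ROI
substantially reduces estimator variance without changing its noiseless
value. The extinction factor E = (I_spike − I_background)/I_top-slide;
E ≤ 0 is an error (spike indistinguishable from background), E ∈ (1, 1.5]
is flagged as matrix enhancement, E > 1.5 is rejected as implausible.
Both slope and intercept are scaled by E (intercept handling is unstated
in published descriptions; scaling both keeps the calibration
ratio-consistent and is exactly invertible). The amount per deposit
q_s = (I_background − E·b)/(E·a) is clipped at zero (flagged) and
converted to mg/kg with the deposited dry mass, default 0.08 g — derived
as 160 µL of a 1 g / 2 mL suspension, exposed as a parameter since the
per-deposit mass is never printed. Concentrations are invariant to a
uniform rescaling of all intensities because E and the curve rescale
together.

## The phantom generator

The phantom is the package's validation instrument: a deposit disk
(default 60×60 px at 50 µm, radius 0.4·min(W,H)) on a bare slide.

*Placement.* Each analyte gets a peripheral placement index
PI = logistic(α(log₁₀S − μ_S) − β(log₁₀K_oc − μ_K)) with α = β = 1,
μ_S = 2 (100 mg/L), μ_K = 3 (10³ L/kg) — a stand-in functional form
consistent with the qualitative observation that polar, weakly adsorbing
compounds are pushed to the border during solvent-forced migration; no
published quantitative migration model exists. The intensity map is
amplitude·((1−PI)·blob + PI·annulus), where the blob is a σ = 0.2R
Gaussian truncated at r = 0.5R and the annulus spans r/R ∈ [0.7, 1.0],
each normalized to unit mean over its reference band so the rendered
image reads back approximately the same index. A global ×1.1 multiplier
on r/R ∈ [0.85, 1.0] emulates the slight accumulation of material on the
deposit periphery. True class labels use the same 0.65/0.35 thresholds
as the classifier.

*Spectra.* Per pixel, each analyte contributes its ion's isotope pattern
(base peak scaled to the map value) under one multiplicative lognormal
factor (σ = 0.2) per analyte-pixel and a per-peak Gaussian m/z jitter of
0.5 ppm — the scale of an FT-ICR instrument under online calibration,
comfortably inside the 3 ppm matching gate. Five matrix ions appear
everywhere; 24 "biosolid background" ions (amplitude 3000) appear on the
deposit only, reflecting how chemically rich real biosolids are — they
keep deposit TIC and peak count well above the bare slide even where no
screened analyte lives, which is what makes TIC-based segmentation work;
20 exponential baseline peaks (scale 30, far below the 500 intensity
threshold) land at random masses. All randomness flows from one seed;
fixed seed ⇒ byte-identical rendering and (at a fixed output name)
byte-identical imzML.

*Quantification scenes.* Slide spots are linear in amount
(signal = sensitivity·q, default 2000 per µg); the on-sample spike and
the native analyte (spread uniformly over the deposit, amount expressed
per whole deposit) are both attenuated by the planted E ∈ (0, 1]. Spot
radii of 6–7 px (~0.6–0.7 mm) reflect sub-µL deposition volumes. The
demonstration scene plants copper at E = 0.4 and 91.48 mg/kg of a 0.08 g
deposit, measured as the [CuCl₂]⁻ adduct in negative mode.

*What the phantom does not emulate.* Real fluid dynamics of solvent
migration, matrix crystallization heterogeneity ("hot spots"), detector
saturation, chemical noise correlated across pixels, and isobaric
interferences near suspect masses. Passing recovery tests therefore shows
the pipeline's logic and statistics are sound under realistic noise and
geometry — not that instrument data will be this clean.

## Validation conditions and problem sizes

Recovery suites run the full pipeline on 20 independently seeded phantoms
(screening sensitivity/specificity with five decoy suspects placed
≥ 10 ppm from every rendered peak; segmentation Jaccard ≥ 0.95;
spatial-class agreement ≥ 90% with significant PI–property correlations)
and on 200 quantification replicates at default noise (per-seed E and
concentration within 10%, |mean bias| < 3%, exact inversion at zero
noise). Scene sizes (60×60 screening, 98×48 quantification) are chosen so
the whole validation runs in about a minute on a laptop while every ROI
still contains enough pixels for the statistics to be meaningful.

## Known limitations

* One deposit per dataset; multi-spot slides need an external splitter.
* Suspect lists with formulas get isotope scoring; mass-only entries are
  exact-mass (level 5) annotations only.
* The mean-spectrum sigma score can mask strongly heterogeneous isotope
  ratios across the deposit.
* imzML metadata beyond the standard vocabulary travels in a JSON sidecar
  (`<file>.imzML.meta.json`); third-party readers will see only the
  standard fields.
* The 0.08 g deposit mass is an inference, not a measurement; absolute
  concentrations scale inversely with it.
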