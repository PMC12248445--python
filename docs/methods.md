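# Methods

## Scope and model

The package reconstructs a complete negative-mode MALDI-MSI lipidomics
analysis for bronchial biopsy sections. The measurement model is a grid of
centroided spectra, one per 25 µm pixel, over *m/z* 550–1000, covering the
lipid classes detected reliably in negative mode: diacyl PE, alkyl-ether
PE O, plasmalogen PE P, PI, PS and SM. Species are treated at the shorthand
level "class C:D" (total chain carbons : chain double bonds); chains are not
resolved, and for plasmalogens the vinyl-ether double bond is not counted in
D, which makes PE P c:d exactly isobaric with PE O c:(d+1).

The analysis quantity is compositional: each species is expressed as a
percentage of its class total over a pixel set,
speciesᵢ% = Iᵢ/ΣI · 100. Percentages are computed from intensities summed
over pixels (intensity-weighted), not from averaged per-pixel percentages;
the two coincide exactly when pixels are homogeneous, which the test suite
asserts on noiseless simulations. Working with class percentages removes
per-pixel scale and per-class ionization-efficiency factors, which is why no
absolute quantification is attempted.

## Lipid database

Elemental compositions come from closed-form class backbone rules (head
group + glycerophosphate + chains, one H₂O per condensation). Monoisotopic
masses are sums of atomic masses stored as compile-time constants. The test
suite checks the rules against an independent building-block oracle
(glycerol + phosphoric acid + head alcohol + fatty acids − nH₂O) and a
frozen table of curated species-level reference masses, at 5·10⁻⁴ Da.

Adducts: glycerophospholipids ionize as [M−H]⁻. SM is zwitterionic with a
quaternary amine and cannot deprotonate at the head group; its default
adduct is acetate [M+CH₃COO]⁻ (ammonium acetate is present in the protocol
this pipeline mirrors), with chloride and demethylated [M−CH₃]⁻ selectable.
The electron mass is included in every adduct delta.

The default panel holds the 29 species used by the region profiles. Its
minimum pairwise spacing is >1000 ppm, far beyond both the 5 ppm alignment
tolerance and the 9 ppm annotation bound, so panel species can never merge
or cross-match. Isobaric PE P/PE O pairs are a single panel entry assigned
to PE P, with the suppressed PE O name recorded in an isobar ledger.

## Synthetic data generator

The generator is the test bed for every downstream stage; its defaults are
the study conditions.

**Geometry.** The banded phantom stacks an epithelial band (25% of tissue
rows) over cellular stroma (40%) over fibrous stroma (rest), with ~10% of
the raster left as background (no spectrum, processed-mode semantics). A
nested layout and arbitrary label masks are also supported. Geometry is
deterministic.

**Region profiles.** Epithelial species percentages encode the reported
group values for control, smoker, non-tumor, tumor and COPD cohorts
(e.g. tumor epithelium PI 38:4 = 67.3, non-tumor 41.5; PE 38:4 = 27.7 vs
14.5; SM d34:1 = 58.5 vs 70.7). Species without a reported value absorb the
residual of their class, split according to the stated qualitative ranges
(each 5–10% of PI, 10–20% of PE), and are flagged `assumed` in the profile
metadata. Stromal profiles are derived from the epithelial ones by explicit
rules: the arachidonic-acid carriers PI 38:4 and PE 38:4 are enriched at
least 2-fold (factor 2.15 capped at 85% for cellular, 2.05/82% for fibrous
stroma), the DHA carriers (PE 38:6, PE 40:6, PE P 38:6, PE P 40:6, PS 40:6)
are depleted by 50–60% (inside the stated 30–90% range), PE 36:1 is reduced
more sharply in fibrous stroma, and the remaining species renormalize each
class to 100.

Two profile choices deserve a note:

* One reported relative change implies a control epithelial PI 38:4 near
  47.6%, but a ≥2-fold stromal enrichment in class percentage is then
  impossible (it would exceed 95%). The control epithelium is set to 40.0%
  (assumed) so that the stromal 2-fold relation — the property the
  end-to-end acceptance checks — holds with margin.
* The fibrous stroma additionally receives a distinct sphingomyelin
  chain-length signature (20 percentage points moved from SM d34:1 to the
  very-long-chain d42:1/d42:2) and its own class weights (less PE/PE P, more
  SM). Fibrous stroma is collagen-rich and cell-poor, and its lipid signal
  in real sections is visibly distinct; without a distinct signature the two
  stromata would be statistically indistinguishable at the default noise
  level and no segmentation method could recover what pathologists can see.

**Class weights** (share of total signal per region) are fixed plausible
values — epithelium PE 0.35 / PI 0.25 / SM 0.15 / PS 0.15 / PE P 0.10, with
stroma-specific variants. They cancel out of all class-percentage results
and only shape segmentation contrast and the intensity filter.

**Noise model.** Per pixel: species fractions within each class are drawn
from a Dirichlet centered on the region profile (concentration 200, giving
~3.5% relative compositional noise for a 40% species); intensities are
scaled by a log-normal TIC factor (σ = 0.3); each peak's m/z is jittered by
Gaussian ppm noise (σ = 2 ppm, inside the instrument's typical <3 ppm
accuracy and well below the 9 ppm assignment bound); a Poisson number
(mean 10) of noise peaks lands uniformly in the scan range with ~2% of the
median true peak intensity. `AcquisitionParams.zero_noise()` gives the
degenerate settings (infinite concentration, zero jitter/TIC-σ/noise) under
which the pipeline must return the generator profiles exactly.

**Between-subject variation** is Gaussian on the logit of the species
fractions (σ = 0.06, renormalized per class), which keeps compositions valid
and yields section-level SDs of roughly 1–2 percentage points for the major
species — SEMs over 5 sections of order half a point, the order of magnitude
read off published group bar charts. `simulate_cohort` derives per-section
seeds deterministically from the master seed; the default cohort is 5 tumor,
5 non-tumor, 4 COPD, 5 smoker and 4 control sections.

**What the generator does not emulate:** profile-mode peak shapes, isotope
envelopes, matrix cluster ions, detector saturation, spatial autocorrelation
of biology within a region, and partial-volume mixing at region boundaries.
Passing tests therefore demonstrate correctness of the computational chain
under a controlled compositional model, not robustness to every artifact of
real acquisitions.

## Preprocessing

Order: normalize → align → filter.

* **TIC normalization** divides by the per-pixel TIC and multiplies by the
  mean TIC (global scale preserved). Zero-TIC pixels are dropped with a
  logged count.
* **Alignment** pools all peaks, sorts by m/z, and opens a new feature
  whenever the next peak is more than `tolerance_ppm` (default 5) above the
  running intensity-weighted centroid. 5 ppm sits between the typical <3 ppm
  accuracy and the 9 ppm assignment bound. Each pixel contributes at most
  one peak per feature — the most intense, ties broken toward lower m/z.
  With 2 ppm jitter a species' peak cloud spans more than 5 ppm, so a small
  satellite feature can split off a main feature's tail; satellites annotate
  to the same species and are pooled at the profiling stage, so no signal is
  lost. The pre-filter matrix is held sparse because noise peaks generate
  thousands of singleton features.
* **Filtering** drops features whose dataset-mean intensity is below
  `threshold_fraction` (default 0.005) of the strongest mean-spectrum peak.
  The filter deliberately operates on the dataset mean spectrum, not per
  pixel: per-pixel filtering would delete genuine low-abundance species from
  individual pixels and bias class percentages. One structural consequence:
  a species at 0.3% of a class whose top species reaches 67% of the same
  class (tumor PI 32:0 vs PI 38:4) is mathematically always below 0.5% of
  the strongest peak and is removed by the default filter, shifting tumor
  PI 38:4 by +0.2 points. Exact-recovery checks therefore run with the
  filter disabled (threshold 0 is the identity), while default-noise
  recovery checks run the full default chain and absorb the shift inside
  their ±1.5-point band.

## Segmentation

Each pixel's feature vector is replaced by its within-pixel ranks (average
ranks on ties), which makes segmentation invariant to per-pixel intensity
scaling and robust to heavy-tailed intensities. Starting from one segment,
the segment with the largest heterogeneity — the sum of squared deviations
of member rank vectors from the segment mean — is bisected by 2-means until
k segments exist or nothing remains splittable (heterogeneity ≤ 10⁻⁹, or
size ≤ `min_segment_size` = 10).

The bisection is initialized by the sign of the projection onto the leading
principal component of the segment (eigenvector sign fixed deterministically),
then refined by Lloyd iterations with ties assigned to the first cluster.
An initialization from the two farthest-apart member pixels was evaluated
first but proved fragile: the farthest pair is outlier-driven, and on a
minority of noise realizations the refined split cut a stromal segment along
a noise direction instead of the tissue boundary. The PC initialization
targets the dominant variance direction directly, is equally deterministic,
and recovers the three tissue types on every tested realization. A `seed`
parameter is accepted for interface stability but unused — the procedure
contains no randomness.

When k exceeds the number of tissue types, segments are collapsed onto their
majority histology label before profiling, so profiles are keyed by tissue
type. Agreement with a mask is reported as per-segment purity and ARI.

## Statistics

Group aggregation averages section-level percentages; SEM = sd/√n with
n = number of sections (the biological replicate — never pixels). Sections
are compared species-wise with two-sample unpaired t-tests, pooled-variance
by default with Welch selectable; the degenerate all-equal case returns
t = 0, p = 1. Raw p-values are reported by default with the conventional
tiers (p ≤ 0.05/0.01/0.001); Benjamini–Hochberg adjusted p-values are
available behind a flag but do not change the tiers, keeping the default
output aligned with how such panels are conventionally reported. Percent
change (B−A)/A·100 is rounded to one decimal.

## Numerical and interface choices

* Internal coordinates are 0-based (row, col); imzML files are 1-based with
  x = col+1, y = row+1. m/z is float64 on disk, intensities float32 on disk
  and float64 in memory. Only processed-mode imzML is accepted. Trailing
  background rows/columns are not representable in imzML, so `read_imzml`
  accepts an explicit grid shape.
* All simulation randomness flows through `numpy.random.Generator` seeded
  from user-supplied integers; re-running any stage with the same inputs is
  byte-identical.
* Exact m/z collisions in a simulated spectrum (measure-zero) are resolved
  by nudging one value by one ulp to preserve the strictly-ascending
  invariant.

## Known limitations

* The divisive rank-based segmentation is an interpretation of a
  hierarchical divisive scheme described only by name in the protocol line
  this pipeline mirrors; equivalence with that implementation cannot be
  verified, only the qualitative behavior (tissue-type recovery).
* Annotation is by accurate mass alone; isobars outside the panel, and
  isomers generally, are indistinguishable — the isobar ledger records only
  the known PE P/PE O ambiguity.
* The t-tests treat species independently; compositional dependence between
  species of one class is ignored, as in the conventional presentation.
* Synthetic validation bounds what can be claimed about real tissue; see
  the generator's non-goals above.
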