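# lipidmsi

A tested, reusable pipeline for MALDI mass spectrometry imaging (MSI)
lipidomics of bronchial tissue: from per-pixel negative-mode peak lists to
tissue-type segments, per-segment lipid-class percentage profiles, and
between-group differential comparisons. It is aimed at analysts working with
spatial lipidomics of biopsy sections (lung cancer, COPD and related
respiratory pathology) who need a transparent, scriptable alternative to
vendor software — and at method developers who need ground-truthed synthetic
datacubes to validate each stage.

## What it computes

An MSI experiment records one centroided mass spectrum per raster position
(here 25 µm pixels, *m/z* 550–1000, negative-ion mode). The pipeline:

1. **Normalizes** each spectrum by its total ion current (TIC), rescaled by
   the mean TIC so every pixel has the same intensity sum.
2. **Aligns** peaks across pixels into features by greedy ppm-window
   clustering (default tolerance 5 ppm, intensity-weighted centroids).
3. **Filters** features whose dataset-mean intensity falls below 0.5% of the
   strongest mean-spectrum peak.
4. **Segments** pixels into tissue types by hierarchical divisive clustering
   of within-pixel rank-transformed spectra (bisecting 2-means,
   deterministic), matched to histology masks by majority overlap (scored by
   the adjusted Rand index, ARI).
5. **Annotates** features against a computed panel of PE, ether/plasmalogen
   PE, PI, PS and SM species by minimal |ppm error|, accepted below 9 ppm,
   where ppm = (observed − theoretical)/theoretical × 10⁶. Plasmalogen
   PE P *c*:*d* is isobaric with alkyl-ether PE O *c*:(*d*+1); assignments go
   to PE P and the suppressed alternative is kept in an isobar ledger.
6. **Profiles** each segment as species percentages of class totals,

       speciesᵢ% = Iᵢ / Σⱼ Iⱼ · 100   (j over the species of the same class),

   aggregates sections into group mean ± SEM (n = sections), and compares
   groups species-wise with unpaired t-tests, starred at p ≤ 0.05 / 0.01 /
   0.001.

Because no public MSI dataset accompanies this design, the package ships a
first-class synthetic-data module: phantoms of bronchoscopic biopsies with
epithelium, cellular stroma and fibrous stroma; region lipid profiles
encoding the reported group percentages (e.g. tumor epithelium PI 38:4 at
67.3% of PI vs 41.5% in non-tumor); Dirichlet compositional noise, log-normal
TIC variation, Gaussian ppm jitter, and uniform noise peaks. Every simulated
section carries its full ground truth.

## Worked example

```python
import lipidmsi as lm
from lipidmsi import preprocess as pp, profiles_stats as ps, \
    segmentation as seg, synthetic_data as sd

phantom = lm.make_phantom(64, 64, "banded")
cube, truth = lm.simulate_section(phantom, lm.default_group_profiles("control"),
                                  sd.AcquisitionParams(), seed=1, group="control")
matrix = pp.run_preprocessing(cube)
ann = ps.annotate_features(matrix, lm.default_panel())
result = seg.divisive_rank_segment(matrix, k=3)
tissue, report = seg.merge_segments_by_tissue(result, truth.phantom)
profiles = ps.profiles_for_tissues(matrix, ann, tissue, sd.REGION_LABELS)
```

prints (via the obvious `print` statements):

```
pixels: 3712, features kept: 30, annotated: 30
segmentation ARI vs ground truth: 0.977
epithelium: PI 38:4 = 40.2% of PI, PE 38:4 = 15.3% of PE
cellular_stroma: PI 38:4 = 85.1% of PI, PE 38:4 = 32.6% of PE
stromal/epithelial PI 38:4 ratio: 2.12
```

That is: the three tissue bands are recovered almost perfectly from the lipid
signal alone (ARI 0.977), and the stroma shows the expected ≥2-fold
enrichment of the arachidonic-acid carrier PI 38:4 relative to the
epithelium. The same workflow is available from the shell:

```bash
lipidmsi pipeline --seed 1 --out-dir out/        # simulate → compare, TSV outputs
lipidmsi simulate --seed 1 --out-dir out/        # or stage by stage
lipidmsi preprocess out/control_0.imzML --out-dir out/
```

## Layout

- `src/lipidmsi/lipid_db.py` — compositions, monoisotopic masses, adducts, species panel
- `src/lipidmsi/synthetic_data.py` — phantoms, group profiles, noise model, cohorts
- `src/lipidmsi/msi_io.py` — datacube/feature-matrix types, imzML and mask I/O
- `src/lipidmsi/preprocess.py` — TIC normalization, alignment, filtering
- `src/lipidmsi/segmentation.py` — divisive rank-based segmentation, mask matching
- `src/lipidmsi/profiles_stats.py` — annotation, class percentages, group statistics
- `src/lipidmsi/cli.py`, `viz.py` — command-line stages, ion images, segment maps

See `docs/methods.md` for the modelling choices and their rationale.
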