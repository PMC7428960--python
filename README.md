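# gaquant

Automatic quantification of **geographic atrophy (GA)** — the end-stage
atrophic lesion of age-related macular degeneration — from macular
swept-source OCT volumes, together with the method-agreement statistics
used to validate such software against manual grading.

The package is aimed at retinal image-analysis researchers who need a
transparent, fully testable reference implementation of an
attenuation-based GA pipeline: every stage can be exercised against a
synthetic OCT phantom with known ground truth, so accuracy claims are
reproducible without access to proprietary device data.

## The method

GA destroys the retinal pigment epithelium (RPE) while Bruch's membrane
(BM) persists. Two optical signatures follow: the bright RPE band
disappears, and light penetrates deeper, brightening the sub-RPE
choroid–scleral signal (*hypertransmission*). The pipeline turns a
3-D volume `I(x, y, z)` into an en-face GA map in five steps:

1. **Layer segmentation** — ILM, the OS/RPE junction and BM are detected
   per B-scan (shortest-path band search with bounded axial jump), and
   BM is re-estimated by low-order interpolation where the RPE band is
   weak or absent; an optic-disc exclusion mask is built from the
   disc location when present.
2. **Integrated attenuation map** — per A-scan,

   `R(x, y) = mean I over [OS/RPE, BM+10 µm] / mean I over [BM+20 µm, BM+220 µm]`

   i.e. the RPE-complex signal normalised by the choroid–scleral
   signal. Atrophy lowers the numerator and raises the denominator, so
   low `R` flags GA. The ratio is invariant to the device's global gain.
3. **Enhancement** — a sliding-window order filter (5 × 5 median by
   default) that ignores invalid pixels.
4. **Extraction** — Otsu thresholding of the enhanced ratio histogram
   (or a fixed threshold), morphological closing/opening, hole filling,
   and removal of components below the definitional minimum GA diameter
   of 175 µm.
5. **Confirmation** — each candidate component must show sub-RPE
   hypertransmission: its mean sub-RPE intensity must exceed the
   background by a configurable factor (default 1.3×).

Lesions are then measured en face (area in mm², perimeter in mm from the
sub-pixel iso-contour, circularity `4πA/P²`) and classified as
single/multiple and regular/irregular.

The agreement toolbox implements Lin's concordance correlation
coefficient `CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)` with a Fisher-z
confidence interval, the two-way ANOVA intraclass correlation
coefficients (random-effects/absolute-agreement and
mixed-effects/consistency; single and average-of-k units) with F-based
CIs, the conventional agreement categories
(poor < 0.90 ≤ moderate < 0.95 ≤ substantial < 0.99 ≤ almost perfect),
and the Mann–Whitney U comparison — plus a report generator that runs
the whole grid overall and stratified by lesion shape and count.

## Worked example

```python
from gaquant import (LesionTruthSpec, PhantomSpec, analyze_volume,
                     make_truth, render_volume)

spec = PhantomSpec(                      # 7 x 7 mm cube, 256 x 320 x 256
    ga_lesions=[LesionTruthSpec(center_xy_mm=(3.2, 3.8), base_radius_mm=1.25,
                                radial_harmonics=[(3, 0.08)])],
    speckle_looks=4.0, seed=7,
)
truth = make_truth(spec)
vol = render_volume(truth, spec)
result = analyze_volume(vol)
ls = result["lesions"]
print(f"true area      : {truth.lesion_areas_mm2[0]:.3f} mm^2")
print(f"measured area  : {ls.total_area_mm2:.3f} mm^2")
print(f"perimeter      : {ls.total_perimeter_mm:.3f} mm")
print(f"classification : {ls.number_class}, {ls.shape_class}")
```

prints

```
true area      : 4.924 mm^2
measured area  : 4.929 mm^2
perimeter      : 8.006 mm
classification : single, regular
```

— the speckled phantom's lesion is recovered to 0.1 % in area. The
agreement side works from an eye × rater/replicate table:

```python
from gaquant import StudySpec, simulate_study, validation_report

df = simulate_study(StudySpec(seed=1))   # 46 eyes, 3 raters, 3 replicates
report = validation_report(df)
print(report["ccc"].head(1).to_string(index=False))
```

```
sample  estimate    ci_lo   ci_hi    category  n
 whole  0.985109 0.973447 0.99167 substantial 46
```

The same pipeline is available from the shell:

```bash
gaquant simulate spec.yaml --out sim/
gaquant analyze sim/volume.tiff --out analysis/ --save-intermediates
gaquant validate measurements.csv --strata strata.csv --out report/
```

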