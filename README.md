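# fetquant

Quantification and evaluation tools for amino-acid ([18F]FET) PET of brain
tumors, aimed at neuro-oncology imaging researchers who need a reproducible,
scriptable version of the standard clinical reading: delineate the
biological tumor volume (BTV), extract the semi-quantitative metrics used in
diagnostic workflows, characterise tracer kinetics from dynamic
acquisitions, and evaluate candidate segmentations (for example the output
of a neural network) against a reference.

## What it computes

**Delineation.** Tumor tissue is auto-contoured at a fixed ratio above the
mean uptake of a background region of interest (ROI) placed in
healthy-appearing gray and white matter:

    BTV = { v : U(v) ≥ 1.6 · Ū_bg }  ∩  domain

where `U(v)` is the uptake at voxel `v` and `Ū_bg` the background-ROI mean.
The search domain is the union of brain and medulla masks dilated 20
iterations; extratumoral high-uptake structures (vascular structures,
pineal body, skin) are removed with explicit exclusion masks, and
26-connected components no larger than 0.1 ml are discarded.

**Clinical metrics.** Over the BTV: volume in ml, TBR_mean and TBR_max
(mean and maximum uptake divided by `Ū_bg`), and the world-mm location of
the peak-uptake voxel (the usual biopsy planning target).

**Kinetics.** From a 40-min dynamic series, the time-activity curve (TAC)
is the per-frame mean uptake in the BTV; the late (20–40 min) frames give
the static summed image. Each TAC gets a time-to-peak (TTP, minutes) and a
kinetic pattern: I — constantly increasing without an identifiable peak;
II — peak after 20 min followed by a plateau or small descent; III — early
peak (<20 min) followed by a constant descent. Later patterns suggest more
aggressive biology.

**Evaluation.** Dice similarity coefficient `DSC = 2|A∩B|/(|A|+|B|)`,
voxel-level confusion counts (TP/FP/FN/TN) restricted to the brain+medulla
domain with sensitivity/specificity/PPV/NPV under both pooled and per-scan
aggregation, bootstrap confidence intervals, representative-case selection
at DSC percentiles, Pearson/linear-fit concordance of clinical metrics
between two methods, and direction-of-change congruence across longitudinal
series.

**Phantoms.** Patient FET data cannot be redistributed, so the package
ships a synthetic generator: ellipsoidal brain support, homogeneous
background uptake, lesions with controlled true TBR, volume and kinetic
pattern, confounding hotspots, Gaussian point-spread blurring and voxel
noise — with ground-truth masks defined before degradation.

## Worked example

```python
import fetquant as fq

spec = fq.PhantomSpec(noise_sigma=0.0, psf_fwhm_mm=0.0)   # clean phantom
ph   = fq.generate_static(spec)                           # 96³ grid, 2 mm
dom  = fq.build_domain([ph.brain_mask], dilation_iterations=20)
roi  = fq.default_background_roi(spec)

res = fq.delineate(ph.image, roi, dom)                    # 1.6 × background
m   = fq.lesion_metrics(ph.image, res.btv_mask, res.background_mean)
print(res.background_mean, round(res.btv_ml, 3), fq.dsc(res.btv_mask, ph.lesion_union))
print(m.tbr_mean, m.tbr_max, m.peak_location_mm)

dyn = fq.generate_dynamic(spec)                           # 8 × 5-min frames
tac = fq.extract_tac(dyn.series, res.btv_mask)
cls = fq.classify_pattern(tac)
print(cls.pattern, cls.ttp_min)
```

prints

```
1.0 4.288 1.0
2.0 2.0 (27.0, 15.0, 7.0)
II 27.5
```

The background mean is recovered exactly (1.0), the delineated BTV
(4.288 ml) matches the voxelized ground truth with DSC 1.0, the TBR values
equal the lesion's true contrast of 2.0, and the default pattern-II lesion
kinetics are classified as pattern II with its peak in the 25–30 min frame
(mid-time 27.5 min). With the default degradation (5 mm PSF, 5% noise) the
same pipeline recovers DSC ≈ 0.84 and TBR_max within 0.16 of truth.

A command-line interface mirrors the library
(`fetquant simulate|delineate|metrics|tac|evaluate|longitudinal|run-scan|run-cohort`);
all volumes are NIfTI-1, timing sidecars are BIDS-PET-style JSON or CSV,
and reports embed their resolved configuration.

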