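# Methods

This note documents the models and procedures implemented in `fetquant`,
the parameter choices that matter, and what the synthetic phantoms do and
do not demonstrate about real data.

## Delineation model

The biological tumor volume (BTV) is the set of voxels whose uptake is at
least `ratio × Ū_bg`, where `Ū_bg` is the arithmetic mean uptake of a
background ROI in healthy-appearing tissue and `ratio` defaults to 1.6, the
established tumor-to-background cut for FET. Because the threshold is a
ratio, delineation is invariant to global rescaling of the image
(calibration, injected dose and body weight cancel), which is why no SUV
normalisation is performed anywhere in the package.

Stages and the choices behind them:

- **Threshold comparison** is at-or-above (`≥`), not strictly above. On
  continuous-valued data the two differ on a measure-zero set; `≥` makes
  integer-valued test fixtures deterministic. A `strict=True` switch is
  provided.
- **Search domain**: union of the brain and medulla masks (inputs,
  co-registered to the PET grid) dilated 20 iterations with a 6-connected
  structuring element, clipped at the grid boundary. The 6-connected
  element is the smallest isotropic choice, so 20 iterations grow the
  domain by 20 voxels of Manhattan radius — a deliberate, generous margin
  for registration and brain-extraction error. Connectivity and iteration
  count are configurable.
- **Exclusions** (vascular structures, pineal body, skin, pituitary
  region) are explicit input masks: in clinical practice these are expert
  manual edits, and no attempt is made to automate that judgement.
  Exclusions are applied to the thresholded mask *before* component
  labelling, because an exclusion can split a thresholded region in two;
  labelling afterwards is the only order under which the reported
  components partition the final BTV.
- **Components** use 26-connectivity (corner-touching voxels belong to one
  lesion — the inclusive choice for contiguous tumor tissue), sorted by
  descending volume with ties broken by first-voxel scan order.
- **Minimum volume filter**: components strictly larger than 0.1 ml are
  kept, matching the inclusion criterion for FET-active pediatric lesions
  (the adult criterion is 1 ml; the parameter is exposed).
- **Background ROI**: an explicit mask or a sphere in world mm, rasterized
  as voxels whose centres fall within the radius. A floor of 50 voxels
  (configurable) rejects ROIs too small for a stable mean.

## Clinical metrics

`TBR_mean = mean(U | BTV) / Ū_bg`, `TBR_max = max(U | BTV) / Ū_bg`,
`BTV_ml = N_voxels × voxel volume / 1000`. The peak location is the world
coordinate of the hottest BTV voxel; ties are broken by lowest linear scan
index and the tie count is reported, so "identical peak location between
two methods" is a well-defined, reproducible statement (distance 0 mm, the
default tolerance). An empty BTV yields NaN metrics rather than zeros —
"no FET-positive lesion" is a missing value, and concordance analyses drop
such scans pairwise instead of biasing fits toward the origin. For
multi-lesion scans the union values are the scan-level values; per-component
metrics are additionally available.

## Dynamic analysis

A frame measures mean activity over its interval, so all model curves are
compared to data as *frame averages*, not point samples. The summed image
is the duration-weighted mean of frames whose mid-time falls in the closed
20–40 min window (frames may be unequal). TTP is the mid-time of the
maximum-value frame, at frame resolution — sub-frame interpolation would
claim precision the data does not have, and agreement between methods is
therefore reported as identical / within one frame / discordant. Ties at
the peak take the earliest frame, which favours detecting early peaks, the
clinically aggressive presentation.

### Pattern classification

The verbal pattern definitions (I: constantly increasing, no identifiable
peak; II: peak after 20 min, then plateau or small descent; III: peak
before 20 min, then constant descent) need an operational rule. The
package's default is least-squares model selection between two shape
families fitted to the whole curve:

- monotone saturating uptake `a·(1 − e^(−t/k))`, k on a log grid 2–200 min;
- rise–fall: linear rise to a peak at `t_p`, linear descent to
  `r × peak` at the end of the acquisition, with `t_p` gridded over the
  acquisition and `r ≤ 1 − increasing_tol` (default 0.95), so a fitted
  descent shallower than the tolerance never counts as an identifiable
  peak.

If the monotone family fits at least as well, the curve is pattern I;
otherwise the fitted peak time against the 20-min cutoff separates II from
III. The rationale for preferring this over a simple end-to-peak-ratio
rule is bias, not only noise: frame-averaging over 5-min frames raises the
apparent end/peak ratio of a genuinely peaked curve (a canonical pattern-II
curve peaking at 25 min and descending to 0.93 of peak has a *frame-level*
end/peak ratio of ≈0.957), so an endpoint rule with a 5% tolerance
misclassifies it as pattern I even on noise-free data, and 3-frame
smoothing pushes the ratio further up (≈0.98). The fit rule uses all
frames, is exact on noise-free frame-averaged curves, and recovers ≈99% of
generator curves at 5% frame noise. The endpoint rule remains available as
`method="ratio"` for comparison with simpler implementations.

Optional centred 3-frame moving-average smoothing (reflected edges) can be
applied before classification; under the fit rule the candidate shapes are
smoothed identically, so smoothing reduces noise without introducing model
bias. The end-to-peak ratio is always computed and reported for audit.

## Evaluation

DSC uses the convention both-empty → 1 (flagged as trivial; one empty → 0,
the missed-lesion case). Voxel confusion counts are restricted to the
evaluation domain, and summary metrics are reported under **both** pooled
(summed counts) and per-scan-averaged aggregation, labelled: the two
differ when lesion sizes vary across scans and reporting only one invites
misreading. Confidence intervals are nonparametric percentile bootstrap
over scans (default 10,000 resamples, seeded). Representative cases are
selected by nearest rank at the requested DSC percentiles (defaults 2, 50,
98: worst/median/best). Longitudinal congruence compares the sign of each
metric's change from baseline between two methods, with changes below 5%
of baseline treated as "no change" on either side so that noise-level
wiggles do not count as discordance. Statistical comparison between two
candidate methods (e.g. Wilcoxon signed rank) is delegated to stock
routines (`scipy.stats`) and is not re-implemented here.

## Synthetic phantoms

The generator emulates the imaging substrate the pipeline expects: an
ellipsoidal brain (default semi-axes 70 × 85 × 65 mm on a 96³ grid at 2 mm
— PET-like resolution at desktop memory), homogeneous background uptake
(1.0 arbitrary units), ellipsoidal lesions at a controlled true TBR
(default 2.0, ≈4.3 ml), optional confounders (superior vascular rim,
pituitary-region hotspot, scalp shell), Gaussian PSF blurring (default
5 mm FWHM; σ = FWHM/2.355) and additive Gaussian voxel noise (default 5%
of background, truncated at zero). Noise defaults reflect typical
late-frame FET image quality; the acquisition default is 8 × 5-min frames
over 0–40 min, a plausible uniform stand-in where real protocols vary.

Ground-truth masks are the lesion supports **before** blur and noise, so
recovery experiments quantify partial-volume and noise effects honestly:
with degradation disabled the pipeline recovers truth exactly (DSC 1.0,
TBR_max = true TBR); with the default degradation it recovers DSC ≈ 0.84
and TBR_max within ≈0.16 — the gap *is* the partial-volume/noise effect,
not an implementation error. Recovered TBR_max is monotonically
non-increasing in PSF width, the expected partial-volume behaviour.

Dynamic phantoms assign every region a kinetic shape (background: mild
saturating uptake; lesions: their pattern's generator with defaults
t_p = 25 min, r = 0.93 for II and t_p = 10 min, r = 0.6 for III;
confounders: early vascular-like washout), normalised so each region's
duration-weighted 20–40 min mean equals its static value — the late summed
image of a noise-free dynamic phantom therefore reproduces the static
phantom exactly, by construction.

The longitudinal cohort generator randomizes baseline lesion location,
size (radius ≈ 7–11 mm for the default brain) and TBR (1.8–2.5) per
patient, then scales follow-up volumes by a configurable factor (default:
doubling per timepoint, three timepoints — the usual minimum for a
longitudinal series).

**What phantom results do not show.** The phantoms are homogeneous-plateau
lesions in a homogeneous brain: no gray/white-matter contrast, no uptake
heterogeneity or infiltrative margins, Gaussian rather than Poisson noise,
no motion or reconstruction artefacts, and geometric rather than
atlas-based confounders. Passing recovery tests demonstrates the
correctness of the computational pipeline under controlled conditions, not
clinical performance on patient data.

## Numerical choices

- Grid compatibility: equal shapes and element-wise affine agreement
  within 1e-3 mm (configurable); world coordinates via the affine, all
  distances Euclidean in mm; voxel indices 0-based.
- Frame schedules must be strictly increasing, non-overlapping, and within
  the configured acquisition span (default 40 min).
- All randomness flows from explicit seeds (`numpy` Generators); phantom
  and bootstrap outputs are bit-reproducible under a fixed seed. Cohort
  generation spawns per-patient child seeds from a `SeedSequence`.
- Problem sizes in the validation suite (96³ phantoms, 20 degraded
  repeats, 200 curves per pattern, 10 longitudinal patients) were chosen
  as the smallest sizes at which the tested properties are stable.

## Known limitations

- No DICOM ingestion, PET reconstruction, attenuation/decay correction,
  SUV normalisation, or MRI handling beyond carrying co-registered masks.
- No learned segmentation: candidate masks from external models are
  evaluated, not produced.
- The pattern taxonomy is the three-class clinical scheme; no compartment
  modelling or Patlak/Logan analysis.
- Surface-distance metrics (e.g. Hausdorff) are not implemented.
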