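# evquant

Single-particle fluorescence quantification for tyramide-signal-amplified
(TSA) staining of extracellular vesicles (EVs) and circulating tumour
cells (CTCs).

Most EVs are smaller than the diffraction limit, so in fluorescence
microscopy each vesicle is a PSF-limited spot whose brightness encodes how
many labelled protein copies it carries. Conventional staining (a
dye-conjugated primary antibody, DS, or a dye-conjugated secondary, PSS)
often leaves low-abundance markers below the background; TSA staining lets
one HRP-conjugated secondary antibody deposit many fluorescent tyramides,
amplifying the per-copy signal several-fold. `evquant` implements the
analysis that makes such data quantitative — and a full generative model
of the experiment, so every stage is testable against known ground truth:

- **`evquant.synthetic`** — ground-truth particle fields (EVs, cells,
  non-specific background) rendered through the DS/PSS/TSA staining
  chemistries, a Gaussian-PSF camera model, photobleaching time series,
  two-plex staining with residual-HRP cross-reactivity, and
  single-antibody calibration substrates.
- **`evquant.detection`** — spot segmentation with the control-calibrated
  threshold rule (*fewer than 10 detections on EV-free control
  substrates*), hole filling, watershed separation, a 10-px minimum size,
  ImageJ-style noise-tolerance maxima counting, and rule-based CTC/WBC
  cell classification from DAPI + membrane markers.
- **`evquant.quantify`** — background-subtracted integrated intensities,
  normalized mean intensity (integrated / area / acquisition time),
  dynamic ranges, fold changes, counts/FOV, photobleaching retention.
- **`evquant.multiplex`** — two-channel colocalization (assignment
  matching by centroid distance), single/double-positive composition,
  normalized EV counts for cross-reactivity, intensity correlation.
- **`evquant.lod`** — the single-antibody peak-ratio limit of detection:
  minimum detectable protein copies per EV.
- **`evquant.cohort`** — CTCs/mL, cohort detection rate, baseline-adjusted
  tumour-EV percentages.
- **`evquant.io` / `evquant` CLI** — TIFF in, CSV/JSON out, and an
  end-to-end `simulate -> calibrate -> detect -> quantify` pipeline.

## The core quantities

For a detected particle with mask M on image I with background b,

    IntI = sum_{p in M'} (I[p] - b)            (M' = M dilated 3 px)
    normalized mean intensity = IntI / area / t_acq
    dynamic range = max - min of the intensity distribution

Cross-reactivity of a two-plex TSA protocol is the normalized count of a
probe-only condition, 100 x N_probe-only / mean(N_complete); the limit of
detection is

    min copies / EV = max(1, round(first_peak(EV) / first_peak(single antibody)))

where `first_peak` is the lowest mode of a kernel-density estimate; and
cohort burden uses CTCs/mL = whole-slide count / blood volume and
%tumour-EV = max(0, 100 x double/total - healthy baseline).

## Worked example

```python
import dataclasses
from evquant import synthetic as syn
from evquant.detection import DetectionParams, calibrate_threshold, detect_particles
from evquant.quantify import IntensityDistribution, measure_particles

optics = syn.OpticsCameraConfig()           # 65 nm px, 100 ms, gain 2
cfg    = syn.FieldConfig()                  # ~150 EVs + ~8 NSB per 256x256 FOV
stain  = syn.tsa_default()                  # TSA chemistry, calibrated defaults

# EV-free control substrates -> calibrated threshold
controls = []
for k in range(3):
    ctl = syn.control_field(cfg, seed=100 + k)
    rates = syn.simulate_staining(ctl, stain, None, seed=200 + k, specific=False)
    controls.append(syn.render_image(ctl, rates, optics, seed=300 + k))
params = DetectionParams()
params = dataclasses.replace(params, threshold=calibrate_threshold(controls, params))

# one EV field: simulate, detect, quantify
field = syn.sample_field(cfg, seed=1)
rates = syn.simulate_staining(field, stain, "CD63", seed=2)
image = syn.render_image(field, rates, optics, seed=3)
particles = detect_particles(image, params)
table = measure_particles(particles, image, params)
dist = IntensityDistribution(table["integrated"].to_numpy())
print(f"threshold {params.threshold:.1f} ADU; "
      f"{len(field.of_kind('EV'))} EVs simulated, {len(particles)} detected")
print(f"mean IntI {dist.mean:.0f} ADU, median {dist.median:.0f}, "
      f"dynamic range {dist.dynamic_range:.0f}")
```

prints

```
threshold 109.0 ADU; 150 EVs simulated, 135 detected
mean IntI 4493 ADU, median 3162, dynamic range 26310
```

The calibrated threshold sits ~9 ADU above the camera offset — the
smallest value keeping every control FOV under 10 detections — and 135 of
150 simulated vesicles are recovered (the remainder are either dimmer than
the control-calibrated threshold or merged with a near neighbour). The
right-skewed intensity distribution (mean well above median) is the
TSA amplification cascade at work.

The same stages run from the shell:

```bash
evquant simulate --out sim --n-fovs 4 --seed 1
evquant simulate --out ctl --n-fovs 3 --control --seed 2
evquant calibrate ctl/fov_*.tiff --out cal.json
evquant detect sim/fov_00.tiff --calibration cal.json --out particles.csv
evquant quantify particles.csv
```

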