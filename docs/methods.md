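# Methods

`evquant` quantifies single extracellular vesicles (EVs) and circulating
tumour cells (CTCs) in multi-channel fluorescence images, with an emphasis
on tyramide signal amplification (TSA) staining, and ships a generative
model of the whole imaging experiment so that every analysis stage can be
exercised against known ground truth. This note records the models, the
parameter choices, and what the synthetic data can and cannot establish
about real images.

## The staining model

Each particle carries integer protein copy numbers per marker. A staining
chemistry converts copies into fluorophore counts:

- **DS** (direct staining): `bound ~ Binomial(copies, label_efficiency)`,
  then `fluors = bound * fluors_per_primary`. Deterministic beyond the
  binding step — a dye-conjugated primary carries a fixed dye load.
- **PSS** (primary + secondary): each bound primary recruits
  `Poisson(secondaries_per_primary)` dye-conjugated secondaries, each
  carrying `fluors_per_secondary` dyes.
- **TSA**: the secondaries carry HRP instead of dyes; each deposits
  `Poisson(tyramide_mean)` fluorescent tyramides. This double-Poisson
  cascade is what produces both the large amplification and the broad
  single-EV intensity distributions characteristic of TSA.

A mean-one log-normal brightness factor (`brightness_sigma_log = 0.3`)
multiplies every particle's output, modelling deposition and illumination
heterogeneity; it also keeps fixed-copy-number intensity distributions
smooth and unimodal, as observed distributions are.

**Default calibration.** No per-particle amplification distributions are
published for this assay; what is published are population means (DS 95,
PSS 143, TSA 607 a.u. for single-EV CD63, i.e. TSA/DS = 6.4 and
TSA/PSS = 4.2). The defaults reproduce those ratios exactly in expectation:
`label_efficiency = 0.8`, DS `fluors_per_primary = 3`, shared
`secondaries_per_primary = 1.25`, PSS `fluors_per_secondary = 3.61`, TSA
`tyramide_mean = 15.33` (per-copy mean fluor outputs 2.4 : 3.61 : 15.33 —
the 95 : 143 : 607 ratios). Two further constraints shaped the choice:
PSS and TSA share the same secondary-binding step (so they share
`secondaries_per_primary`), and `label_efficiency * secondaries_per_primary
= 1` so that one antigen copy drives on average one HRP secondary — the
premise under which the single-antibody peak-ratio LOD estimate reads out
copy numbers directly.

**Photobleaching** is single-exponential per chemistry,
`rate(t) = rate(0) * exp(-bleach_rate * t)` with t in minutes. Defaults:
DS 1.5/min (direct dyes on EVs bleach drastically within the first minute
of continuous excitation), PSS and TSA 0.01/min (both are reported stable
over a 5-minute series). Retention curves are measured on the time-0
detection masks — re-detecting per frame would silently drop bleached
particles and bias retention upward.

## Optics and camera

Spots are pixel-integrated 2D Gaussians (sigma 130 nm, slightly wider than
the 0.21 λ/NA Airy approximation, reflecting measured widths; vesicle
diameter adds in quadrature as d/4). Cells render as uniform nuclear disks
or membrane rings convolved with the PSF. The camera applies Poisson shot
noise on expected photons (background default 0.02 photons/px/ms), gain
2 ADU/photon, offset 100 ADU and Gaussian read noise (2 ADU). Expected
total above-offset intensity therefore equals gain x exposure x summed
photon rate — the photon-conservation property the tests assert.

EV copy numbers are log-normal rounded to integers (mean 60 copies,
sigma_log 0.8 for tetraspanin-class markers): vesicle populations are
strongly right-skewed and span orders of magnitude. When two markers are
simulated, their log-copies share a Gaussian copula with correlation 0.73,
matching the measured inter-marker correlation on double-positive EVs.

**Non-specific background (NSB).** EV-free control substrates still show
detections; the generator reproduces this with faint point sources at
1.2e-4 /px^2 (~8 per 256x256 FOV), each contaminating one randomly chosen
channel with a log-normal photon rate (mean 1.0 photons/ms, sigma_log 0.8,
i.e. dimmer than a typical stained EV but with a bright tail). The
control-calibration rule exists precisely to absorb this population.

## Detection

Binarisation is inclusive (`pixel >= threshold`), followed by hole filling,
marker-based watershed separation, 8-connected labelling (matching the
conventions of the ImageJ-family tools this emulates) and a minimum size of
10 px. Watershed runs only on components larger than 4x the median
component area — sub-diffraction spots must never be split — and never on
components covering more than a quarter of the image. Components covering
more than half the image are classed as background, not particles: a
threshold at or below the camera offset makes the whole frame foreground,
and treating that blob as "one particle" would let calibration accept
pathologically low thresholds.

**Threshold calibration** selects the smallest candidate threshold at which
every EV-free control image yields strictly fewer than 10 detections. The
candidate grid mixes pixel-intensity quantiles (3/4 of the levels — dense
where the pixel mass is) with uniformly spaced levels (1/4 — so the sparse
bright tail, where only a handful of spot pixels live, is still resolved;
pure mass quantiles can leave tens of ADU between adjacent candidates
there), at most 512 levels plus a sentinel just above the control maximum,
which guarantees a passing candidate exists. Because detection counts are
monotone in threshold only above the background level, the search locates
the passing region contiguous with the top of the grid (geometric probe
down, then bisection, then verification). A per-image strict criterion is
the default; a pooled mode exists. Consequence worth knowing: the rule
intentionally rides the count curve just below 10, so held-out control
counts are Poisson-distributed with mean well below, but not negligibly
below, the limit.

**Maxima counting** implements flood-based noise-tolerance semantics: a
local maximum survives unless flooding down by the tolerance reaches a
strictly higher region, and equal maxima connected within the tolerance
merge into one count. Implemented as a single descending sweep with
union-find (component persistence); a constant image has no maxima. The
test suite checks it against an exhaustive per-plateau prominence oracle.

**Cells.** Nuclei are DAPI components passing a Michelson local contrast
`(peak - background)/(peak + background) >= 0.5` and a mean intensity above
10 (both evaluated after subtracting the per-image median background — the
published rules assume background-free units, and a camera offset of
~100 ADU would otherwise make them vacuous). The membrane ring is a 3-px
dilation band; a cell is kept only when more than 30% of the ring is
marker-positive. Classification is rule-based: tumour-cocktail positive
and complete → CTC; CD45/CD11c positive → WBC; both → excluded and flagged.

## Quantification

Integrated intensity sums the original image over the detection mask
dilated by 3 px (the PSF tails carry a brightness-dependent fraction of
the photons; integrating the bare threshold mask would bias bright-to-dim
comparisons upward), minus the per-image median of non-particle pixels.
Normalized mean intensity divides by 2D area and acquisition time. Dynamic
range is max − min, optionally after quantile truncation (default none; a
(1%, 99%) option mirrors truncated violin plots — since the exact published
truncation is unknown, dynamic ranges are compared as ratios, not absolute
values). Fold changes are reported to one decimal, matching printed
precision.

## Two-plex and cross-reactivity

Colocalization matches detections across channels by centroid distance
within 2 PSF sigma. The matching is the maximum-cardinality,
minimum-total-distance assignment (Hungarian algorithm) with deterministic
tie-breaks; greedy mutual-nearest-neighbour matching was considered and
rejected because it can disagree with the exhaustive minimal-distance
assignment on ambiguous configurations, and the exhaustive assignment is
the behaviour the test oracles pin down. Mask-overlap criteria make no
sense for PSF-limited spots.

Residual-HRP cross-reactivity is generated mechanistically: after the
channel-A TSA cycle, each A-stained particle retains its HRP secondaries;
with probability `cross_react_fraction` (x (1 − quench_efficiency) when
the H2O2 quench is applied) those secondaries also deposit channel-B
tyramide — so spurious channel-B signal has exactly channel-B-typical
magnitude. Defaults: `cross_react_fraction = 0.20` and
`quench_efficiency = 0.85`, i.e. an effective 3% carryover after
quenching, the measured pair of values. The estimator follows the
normalized-count procedure: per-FOV counts divided by the mean count of
the complete protocol, x100.

## Limit of detection

`find_first_peak` fits a Gaussian KDE (Silverman bandwidth) and returns the
lowest-intensity local maximum whose density reaches 10% of the global
maximum; a Freedman-Diaconis histogram mode is available as a sensitivity
check. `min_detectable_copies` is `max(1, round(ev_first_peak /
antibody_peak))` — copies are integers and the estimator can never claim
zero. The API accepts configuration tokens for both substrates and refuses
mismatched acquisitions: the ratio is only meaningful when the calibration
and EV substrates share stain and optics. Whether published first peaks
were taken from integrated or per-pixel intensities is not stated;
integrated is the default here.

The in-silico LOD experiment (`evquant.experiments.lod_experiment`) uses a
4 s exposure (one secondary's tyramide burst must clear the shot-noise
floor; signal grows linearly and background noise as the square root of
exposure) and clean substrates (`nsb_rate_mean = 0.1` photons/ms): the
calibration substrates are purpose-made — buffer, diluted secondaries and
probes only — and single-antibody events are only observable at all in a
regime where background binding is fainter than one antibody's output.
Fields of view are large (1024 px) so the handful of permitted false
detections per FOV stays a negligible fraction of the intensity sample and
cannot form a spurious "first peak".

## Cohort statistics

CTCs/mL divides the whole-slide count by the blood volume. The detection
rate is the rounded percentage of patients above the positivity threshold,
which defaults to the maximum healthy-control rate (zero when imaging
conditions were set that way); with several healthy controls the EV
baseline combines as the max (default, conservative) or mean. The
tumour-EV percentage is `max(0, 100 * double/total − healthy_baseline)` —
clipped at zero, never negative. EV statistics carry a `fovs_sampled` flag:
four FOVs sample the plating area, so no extrapolation to absolute EV
numbers is attempted. Group comparisons are descriptive only; significance
testing is out of scope.

## Problem sizes and what the tests show

The experiment harness (`evquant.experiments`) runs at desk scale: 512 px
FOVs with ~700 EVs for the amplification comparison, 1024-2048 px FOVs
with 500-2000 EVs each for the two-plex recoveries (chosen so EV counts
dwarf the <10-per-FOV control background and spot merging stays below a
few percent — the regime the published per-FOV counts come from), and
1024 px substrates for the LOD chain. Recovery tolerances in the test
suite (±3 points on composition and no-quench cross-reactivity, ±2 on the
quenched value, ±0.05 on correlation, [5.4, 7.4] on the 6.4x fold) reflect
the residual biases these conditions leave: a percent-level count deficit
from merged spots in dense fields, sub-percent false-detection
contamination, and survivor bias against the dimmest particles.

What passing does show: the analysis stages recover the generative truth of
a field that obeys the stated models. What it cannot show: correctness
under real-microscope effects the generator omits — spatially varying
background and illumination, aggregation and clumping beyond isolated
merging, chromatic misregistration between channels, spectral crosstalk
(channels are modelled crosstalk-free, as the acquisition this emulates
reports), focus drift, and fixed-pattern camera noise. Conclusions about
real data rest on the published experiments, not on these simulations.

## Numerical conventions

Coordinates are 0-based, pixel-centred, (x, y) = (column, row). All
stochastic operations take explicit integer seeds; pipeline-level seeds
derive per-stage seeds by fixed offsets (`evquant.derive_seed`), and equal
config + seed reproduces every output byte (timestamps are confined to
logs). Degenerate inputs fail loudly: empty distributions, zero areas or
exposures, non-positive volumes, unmatched channel names and out-of-bounds
masks all raise with descriptive messages rather than propagating NaNs.
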