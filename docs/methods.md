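# Methods

`liposort` simulates an image-based screening-and-sorting workflow for
gene-expressing liposomes ("synthetic cells") end to end: a ground-truth
vesicle population is rendered into confocal-like images, analysed by a
real-time-style detector, selected vesicles are photo-tagged, the pooled
sample is sorted by simulated flow cytometry, and the genetic composition
of the sorted pool is quantified. This note documents the models, their
parameters, and the design choices made where the workflow leaves the
design open.

## Population model

Each field of view (FOV) is a 128 x 128 um plane holding 50-150 vesicles;
the sampler defaults to a uniform draw from 50-120 per FOV because the
placement rule below cannot reliably seat more than ~120 vesicles of the
default size distribution in one FOV. Diameters follow a log-normal with
median 8 um and log-SD 0.45, truncated by rejection to the observed 2-20 um
range. Genotypes are drawn per vesicle with probabilities equal to the
volume fractions of the clonal populations in the mix; the expression flag
is an independent Bernoulli draw with p = 0.6, the midpoint of the 40-80%
expressing fraction seen in clonal samples. A non-expressing vesicle shows
no reporter signal regardless of genotype.

Vesicle centers are placed by random sequential insertion, largest first,
with a pairwise spacing of r_i + r_j + 1 um and each center at least its
own radius from the FOV edge. This forbids overlapping renders (overlap
and multilamellar structure are out of scope); a FOV that cannot be packed
raises a placement error. The diameter draw is refreshed between placement
restarts, so delivered samples are implicitly conditioned on placeability.
Uniform placement is an assumption; real FOVs may be locally clustered.

Reporter localization is a per-vesicle membrane fraction m(t) plus an
angular weight profile:

| mode            | m(t)                   | angular profile                 |
|-----------------|------------------------|---------------------------------|
| static_lumen    | 0.05                   | uniform                         |
| static_membrane | 0.9                    | uniform                         |
| pulsing         | square wave 0.9 / 0.1  | uniform                         |
| pole_to_pole    | 0.9                    | Gaussian cap, flips pi per T/2  |
| circling        | 0.9                    | Gaussian cap rotating at 2pi/T  |
| halted          | 0.9                    | Gaussian cap, frozen            |

Oscillation periods are uniform in 15-45 s with a uniform random phase.
The functional forms (square wave; wrapped-Gaussian cap of angular sigma
0.5 rad) are artifact definitions -- the underlying biology only names the
modes -- and the mode mix of real samples is unknown, so the mode weights
are a free configuration parameter (default: equal weight on the three
time-varying modes with a 10% halted fraction).

Brownian drift uses independent per-axis Gaussian increments with SD
`diffusion_scale * sqrt(dt)` and reflection at the FOV boundary. The
default scale, 0.126 um s^-1/2 per axis, is derived in closed form so that
the mean planar (Rayleigh) displacement over 10 s equals the measured
0.5 um.

## Rendering

Geometry matches the imaging setup being emulated: 512 x 512 px at
0.25 um/px, 16-bit, 5 frames at 12-s spacing for videos. The membrane-dye
channel draws an annulus of width 0.3 um at the vesicle radius with total
signal proportional to circumference; the reporter channel splits a total
signal proportional to projected area between the annulus (weight m(t)
times the angular profile) and a uniform lumen disk (weight 1 - m(t)); the
photoactivatable-tag channel is a lumen disk at basal level, 20x once
activated. Per-vesicle kernels are normalized to unit sum before scaling,
so the total ideal signal is exactly independent of the membrane/lumen
split (photon conservation) and survives pixel-size changes.

The point-spread function is an isotropic Gaussian of sigma 0.3 um --
chosen below the smallest vesicle radius; the real instrument's PSF is not
reported. Noise is Poisson on the blurred photon image plus Gaussian read
noise (SD 20 counts) and a constant offset of 100 counts; no detector
model is reported for the real system, so these are conventional camera
constants. Absolute channel gains are instrument-specific and therefore
free parameters; the defaults put lumen signals near 300 counts over
background (SNR ~ 10). Confocal sectioning, photobleaching and vesicle
deformation are not modelled.

## Detection and classification

The geometric detector mirrors a real-time "general analysis" pipeline:
3x3 mean convolution, intensity threshold, 8-connected labeling, hole
filling, then size (equivalent diameter 3.5-20 um) and circularity
(4 pi A / P^2 in 0.3-1) gates; border-touching components are discarded.
The default threshold is background median + 5 MAD (the original
software's threshold value is unpublished; Otsu is available), with the
background statistics taken on a 4x subsampled grid. The perimeter is the
marching-squares contour length at the mask boundary, which reads ~10%
above the analytic circumference for pixelated disks -- circularity gates
should be interpreted with that bias in mind. Detection runs on the
membrane channel by default (rings fill to disks); a config switch
thresholds the reporter channel instead, which is the expression-intensity
screening mode.

At the default density and minimum spacing, neighbouring rings can merge
above threshold and fail the size/circularity gates; the >=95%
precision/recall contract therefore applies to sparse, well-separated
FOVs, mirroring how the real system's learned detector was validated on
curated images. Merging only lowers sensitivity, never inflates counts.

Localization classification is a deterministic ring-profile score standing
in for the learned two-class detector: R = mean background-subtracted
reporter intensity in the annulus [0.75 r, 1.05 r] over the same in the
central disk [0, 0.6 r], background = image median. Class 2 (membrane) is
called at R >= 1.5; the confidence is logistic(2 ln(R/1.5)). The radii and
threshold are artifact choices, configurable; the score is invariant to
global gain/offset changes up to the background-estimation error. Any
detector emitting (bbox, class, confidence) can replace this one;
downstream stages only consume `Detection` objects.

## Tracking and dynamic calling

Tracks are seeded from frame 0 and extended greedily: candidate pairs
within 5 um of the track's frame-0 anchor are matched in ascending
distance order, one-to-one (ties under 1 nm break toward the lower
detection index); unmatched detections never seed new tracks, and tracks
missing a frame are dropped by default (the handling of partial tracks is
unspecified in the original workflow). Greedy matching is used for speed;
on sparse instances it coincides with exhaustive minimum-total-distance
matching, which the tests assert. A config switch matches against the
previous frame instead of the anchor for comparison.

A track is *dynamic* when its class sequence contains both classes. The
source workflow compares classes "over the consecutive time frames"; for
full-length tracks the contains-both rule and the adjacent-change rule
coincide, so the ambiguity is noted but has no effect here. With 12-s
frames over 48 s, every pulsing period in 15-45 s is sampled in both
phase halves, so pulsing vesicles are always called dynamic (the
phase-integral probability is exactly 1 there; it drops below 1 only for
periods beyond twice the video span). Pole-to-pole and circling vesicles
keep membrane-bound reporter throughout and are never called dynamic --
reproducing the mechanism behind the real pipeline's sub-100% video
sensitivity.

## Photoactivation and sorting

Targets are stimulated with probability 1. Off-target activation is
planar: each non-target within 15 um of a stimulation point activates
independently with probability p_off(power); out-of-plane cone activation
is folded into p_off because most vesicles sediment into one z-plane. The
p_off defaults {34 uW: 0.0124, 84 uW: 0.0368, 167 uW: 0.0485} are produced
by `scripts/calibrate_laser.py`: with the Monte-Carlo mean neighbor count
nbar = 3.36 at 100 vesicles/FOV, precision = 1/(1 + nbar p_off) is solved
for the measured activation precisions 96/89/86%.

FACS recovery applies an event-per-vesicle Bernoulli with p = 0.15 (the
observed 10-20% recovery), size-independent -- whether recovery is
size-biased is unknown. Event intensities scale with relative volume
(d/8)^3 under log-normal noise (CV 0.25); the reporter channel reads an
autofluorescence floor (2% of the expressing level) for dark vesicles, and
the tag channel reads 20x basal when activated (the real data show clear
separation but no number). Gates: the workflow this emulates placed
quadrant gates such that the unstimulated control sample is entirely
negative. The simulation does the same parametrically: the tag gate sits
3.25 robust log-SDs (median/MAD) above the basal mode of a simulated
unstimulated control aliquot. A histogram-valley rule was rejected because
activated events are ~0.5% of the sample and do not form a detectable
mode at realistic event counts; the control-exclusion gate is what a
cytometrist actually does in that situation. 3.25 log-SDs is the operating
point at which, under the default size spread, basal leakage into the
sorted fraction stays negligible while ~20% of tag-activated events are
recovered. Sorted = tag-high events (both tag-high quadrants).

## Quantification

Presort template pools are multinomial draws (default 100,000 templates)
with probabilities proportional to volume fraction times per-population
template share. Fold enrichment is post-sort fraction over presort
fraction, computed per replicate before averaging (matching the mean +/-
SD presentation of replicate experiments); a genotype with zero presort
fraction but post-sort counts is flagged rather than given an infinite
fold. qPCR curves are least-squares fits of Cq on log10(concentration);
the implied efficiency is reported but not used to correct concentrations.

Sequencing reads are full-length amplicons (1398 bp backbone with a 6-nt
two-codon variant window) with substitution errors, Gaussian length jitter
trimmed from the ends, and a junk fraction outside the 1100-1400 bp
recovery window; qualities are fixed at Q20 (quality modelling is not part
of the emulated procedure). Variant counting replaces read mapping with
exact 12-nt flank anchoring searched on both strands: deterministic, no
external index, and a substitution inside a flank discards the read into
the QC tally. Beyond discarding ambiguous anchors and windows containing
N, no further quality control is applied (the original pipeline's QC step
is not specified in more detail). The backbone sequence is a synthetic
stand-in generated deterministically from a fixed key; it is not the real
gene sequence, which the analysis never needs.

## Experiment presets and problem sizes

The four presets encode the canonical experiment designs: expression
screening of a 1:39 two-gene mock library (84 uW, stimulation anywhere in
the FOV, matching the replicates where stimulation was not restricted to
the FOV center; 15% recovery; three replicates), localization screening of
1:9 / 1:39 / 1:39 mock mixtures, five-frame video screening for dynamic
events with center-of-FOV stimulation, and a pooled nine-variant
membrane-targeting-sequence library (two functional binders) with a
sequencing readout.

The mock-library preset screens 2000 FOVs of exactly 100 vesicles per
replicate -- the lower end of the 2000-5000 FOVs the real screens covered,
and the density at which the off-target model was calibrated. This scale
was chosen so the sorted fraction holds on the order of 10^2 events per
replicate and replicate means of the post-sort composition are stable;
smaller screens give sorted pools of only a handful of vesicles whose
fractions are dominated by counting noise. The video and library presets
default to smaller FOV counts since their readouts are structural rather
than statistical.

## What the synthetic data does and does not show

The generator reproduces the *mechanisms* of the workflow -- mixing ratios,
expression stochasticity, localization dynamics, off-target activation
geometry, FACS losses, sequencing recovery -- under clean conditions:
perfectly spherical unilamellar vesicles, a single z-plane, no debris, no
clustering, no detector miscalibration. Detection and classification are
therefore near-perfect here where the real learned detector reached
82/82% precision/recall, and simulated enrichment outcomes sit toward the
favourable end of the measured bands. Passing tests validate the pipeline
logic and its statistical behaviour, not performance on real microscopy
data. Encapsulation biochemistry, multilamellarity, 3D structure,
hardware control and network training are explicitly out of scope.

## Numerical notes

All randomness flows from explicitly passed NumPy generators or seeds;
replicate seeds are spawned from the experiment seed, and equal seeds give
byte-identical reports. Degenerate inputs fail loudly: saturated images
(>= 99% of pixels above threshold), empty class sequences, zero-total
count tables, non-positive perimeters and invalid standard curves raise
typed errors instead of propagating NaNs. Ring-score denominators at
background level are floored at a small multiple of the image MAD, and a
signal-free interior scores R = 1 (class 1). Quadrant assignment treats
gate values as inclusive lower bounds for "high".
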