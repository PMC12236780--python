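# Methods

This note documents the models, defaults and design choices behind
`embryohub`, in the spirit of a methods supplement: what each stage
assumes, which knobs matter, and what the synthetic benchmark does and
does not establish.

## Preprocessing

All analysis operates on maximal-intensity projections of the z-stack
(`max_project`), matching standard practice for syncytial-blastoderm
movies where nuclei form a monolayer. Background is removed per 2-D
plane by rolling-ball subtraction (`rolling_ball_subtract`), implemented
as grayscale opening with a non-flat ball structuring element of the
given radius (default 50 px); pixels outside the image are ignored
rather than padded, so borders are not darkened by the structuring
element overhanging the frame. The output is clipped at zero. Axis
order is canonicalized to (t, z, c, y, x) with 0-based indices and
half-open crop ranges; TIFF axis ambiguity is resolved by file metadata
when present, else a required axis string.

Whether background subtraction runs before or after projection is
configurable; the pipelines apply it after projection (the default), and
disable it entirely for simulated movies, whose background is flat by
construction.

## Segmentation

Two routes share a preparation chain — *clip bright foci, Gaussian blur,
Otsu threshold*:

* **Combined chromatin mask** (`combined_chromatin_mask`): the two hub
  channels are summed so that both interphase nuclei and mitotic
  chromosomes are captured in one binary mask per frame.
* **Labelled nuclei** (`segment_nuclei`): one channel is thresholded,
  the mask dilated (default 2-px disk) so peripheral reporter foci fall
  inside their nucleus, touching nuclei are split by watershed seeded
  from Euclidean-distance-transform maxima (minimum seed separation
  default 10 px, about one nuclear radius), and regions smaller than a
  cutoff or touching the X-Y border are discarded. Labels are
  renumbered consecutively per frame.

Clipping exists because bright sub-nuclear foci (histone-locus bodies)
otherwise dominate the Otsu histogram and shrink the foreground to the
foci alone. The clip threshold is in principle a per-movie manual
choice; the automated default is the 99.5th intensity percentile of the
frame with sub-threshold median as the replacement value. This surrogate
works when foci occupy well under 0.5% of the frame; for images whose
nuclei have nearly flat intensity profiles the percentile can land
inside the nuclear-body intensity range, and an explicit threshold
should be passed instead. The small-region cutoff defaults to 25% of
the frame's median region area. Blur sigma defaults to 2 px. The
original acquisition also excluded nuclei touching the top or bottom of
the z-stack; after projection that criterion is unrecoverable and is
approximated by the area filter.

Otsu thresholding note: runs of empty histogram bins produce exactly
tied maxima of the between-class variance; any tied cut is a valid
threshold, and tests assert maximality rather than a particular tied
bin.

## Hub dynamics

Per frame, the mean and the **population** variance (1/N; the convention
is fixed for reproducibility, not estimated-variance inference) of
intensities under the chromatin mask form `IntensitySeries`. Cluster
formation raises the variance while leaving the mean nearly unchanged,
so the variance series is the hub readout. Recruitment onset is, by
default, the first frame at which a series reaches 20% of its dynamic
range (`detect_recruitment_onset`); any manually chosen frame can be
supplied instead, and the pipelines use the known S-phase entry frames
when a simulated movie provides them. `peak_in_window` extracts the
maximum over a 2-minute window (window_seconds / frame_interval frames,
clipped to the series end) after onset. For treatment comparisons,
`per_nucleus_intensities` reports the brightest pixel per labelled
nucleus — a proxy for protein clustering — pooled across embryos.

## ON/OFF transcription kinetics

Nuclei are linked across frames by greedy nearest-centroid assignment
capped at a maximum displacement (default: one nuclear radius, derived
from the median region area); only nuclei present in **every** analyzed
frame are retained, fixing the denominator of all percentages. MCP foci
are detected per frame as local maxima of the scale-normalized
Laplacian-of-Gaussian response (−σ²∇²G) over a geometric ladder of six
scales in [1.5, 4] px; the response threshold (pipeline default 5.0, in
background-subtracted intensity units) was chosen on blank synthetic
frames to keep false positives below one per ten frames. A nucleus is
ON at a frame when at least one focus lands inside its dilated label.
`first_off_after_on` starts at the first run of ≥ debounce (default 1)
consecutive OFF frames after first-ON, so foci that appear and vanish
within minutes are counted as OFF events rather than smoothed away.
Cumulative curves report, per frame since S-phase entry, the percentage
of retained nuclei that have turned ON, and that have subsequently
turned OFF; replicate embryos are aggregated as pointwise mean ± SEM.
Mitotic frames are excluded by analyzing one S-phase block at a time. A
nucleus with several simultaneous foci counts the same as one with a
single focus.

## Dual 5'/3' reporter analysis

Spots are detected on the **sum** of the two channels (so a spot visible
in either is found) after a 1-px blur, as local maxima of the
difference-of-Gaussians response with sigmas (1.5, 3) px. Each
detection is quantified per channel as the mean of the 17×17-px square
centred on it, minus a local background. The background window is the
31×31 square **excluding** the inner 17×17 (annulus policy, the
default) so that spot signal does not contaminate its own background; a
full-square mode (31×31 including the centre) is available where the
literal larger-window mean is wanted. Corrected intensities may be
negative. Detections whose 31×31 window leaves the image are flagged
border-touching.

Tracks are built by greedy nearest-neighbour linking with gap closing: a
track may skip up to 5 consecutive undetected frames (a gap of exactly 5
links; 6 splits), and positions during gaps are not interpolated —
quantification happens only at detected frames, while montages reuse the
last known position. Tracks of a single frame or ever flagged
border-touching are discarded. Ordering is by first appearance
(ascending), then total — summed, not averaged — corrected 3' intensity
(descending, so strong elongators lead each emergence cohort), with
stable ties. Montages tile 17×17 crops, rows = tracks, columns = frames
from the embryo-wide earliest appearance; tiles before a track's first
appearance are blank. The per-track elongation readout `onset_lag` is
the first frame whose corrected 3' intensity exceeds a threshold
(default 5 a.u.) minus the same for the 5' channel; tracks that never
acquire 3' signal (elongation-defective) are excluded from the median.

## Statistics

`mann_whitney_u` is two-sided; `auto` mode uses exact enumeration of all
C(n_x+n_y, n_x) group assignments when n_x + n_y ≤ 16 and the pooled
sample is tie-free, else a normal approximation with midrank tie
correction and 0.5 continuity correction. The exact two-sided p is
P(|U − μ| ≥ |U_obs − μ|) under the permutation null, which is also
well-defined with ties. Bonferroni adjustment is min(1, m·p) with the
family size m stated per comparison family. Box summaries follow the
Tukey convention (linear-interpolation quartiles, whiskers at the most
extreme data within 1.5·IQR). SEM is sample SD / √n across replicate
curves.

## The simulator as benchmark

The generator emulates the features the analyses rely on: S/M
alternation with per-cycle durations (defaults 8.5 and 15.5 min S phases
with 3-min mitoses at 20-s frames), nucleus doubling with daughters
placed ~2.2 radii apart and relaxed to a minimum separation (real
blastoderm nuclei pack densely but do not interpenetrate), a shared slow
drift vector per movie (nuclei move coherently with the cytoplasm;
placement margins reserve the whole-movie drift budget so nuclei never
cross the border mid-track), soft-edged disk nuclei with condensed
brighter mitotic blobs, Gaussian foci with fixed sub-nuclear offsets,
bookmark foci that brighten per cycle (default gain 1.4) and persist
through mitosis before dispersing (default within 1 min of S onset),
kinase foci spanning late mitosis to ~1 min into S phase, polymerase
foci from ~2 min into S phase, and telegraph transcription: ON wait =
120 s + Exp(60 s) after S entry (mean onset 3 min), per-frame OFF
probability 0.01, and a deterministic 10-frame 5'→3' onset lag. Noise is
Poisson(signal × photon scale)/scale plus Gaussian read noise (defaults
200 and 2 a.u.). All draws consume one generator seeded from
`rng_seed` in a fixed order: geometry, kinetics, then noise.

The `cdc7i` preset encodes the inhibited phenotype as parameter changes:
kinase recruitment delayed (lead 40→10 s), weakened (amplitude ×0.5) and
prolonged (dispersal 60→180 s), bookmark dispersal 60→240 s, ON wait
shifted by +120 s with tripled mean, OFF probability 0.01→0.10, and 3'
amplitude ×0.5. Amplitude ratios between major and minor foci (minor =
half amplitude) are free parameters, not measurements.

What passing the benchmark shows: the pipelines recover segmentation
identity, focus positions, state-transition times and the configured
elongation delay from images with realistic shot noise, and reproduce
the qualitative control-vs-inhibitor contrasts. What it does not show:
robustness to photobleaching, uneven illumination, z-drift, 3-D
point-spread blur, chromatin texture, or segmentation of crowded NC14
nuclei — none of which the generator renders. Thresholds (LoG/DoG
response, clip percentile) will need per-dataset adjustment on real
movies.

## Problem sizes and numerical choices

Tests and the acceptance script use 256×256 movies of 60–90 frames with
16–32 nuclei in the analyzed cycle, which keeps a full run in tens of
seconds while leaving nuclei large enough (radius ~10 px) for watershed
separation. Degenerate inputs raise explicit errors: constant images
(Otsu, onset detection), empty masks, blank frames (reported with the
frame index), empty sample sets. Ties are broken deterministically
everywhere (first maximum in argmax scans; stable sorts). Montage tiles
whose crop would leave the image are skipped rather than zero-padded,
which can only affect tracks that the border filter failed to remove.

## Known limitations

* The nucleus linker is greedy; globally optimal assignment (Hungarian)
  would be more robust under fast flows, but the complete-track
  retention rule makes linker errors self-excluding in practice.
* Spot positions are integer-pixel local maxima; no sub-pixel Gaussian
  fitting (out of scope by design).
* The exact Mann–Whitney path enumerates combinations and is intended
  for n_x + n_y ≤ 16; larger samples use the asymptotic path
  automatically.
* Per-frame auto-clip percentiles assume foci are sparse relative to
  nuclei; pass explicit clip thresholds for images violating that.
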