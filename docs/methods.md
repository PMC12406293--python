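# Methods

This note records the models, conventions and numerical choices behind
`cinesync`, and what the phantom-based validation does and does not show.

## Pipeline model and assumptions

The method assumes (i) bright-blood short-axis contrast (blood >
myocardium), so the LV cross-sectional area is measurable per frame from a
blood-pool segmentation; (ii) quasi-periodic cardiac motion, so end
diastole recurs and two consecutive ED frames bound one cycle; and (iii)
that frames selected near end expiration are close enough in respiratory
state to be combined across slices. It deliberately avoids assumptions
about the *shape* of cardiac motion: timeframes are used in consecutively
acquired order, never re-binned across heartbeats, so exercise-induced
deviations from a canonical contraction pattern survive into the cine.

### Respiratory surrogate

The diaphragm-ROI frames are embedded with Laplacian eigenmaps: a symmetric
binary k-NN graph (Euclidean metric) over per-frame ROI vectors, normalized
graph Laplacian, eigenvector of the smallest nonzero eigenvalue, scaled to
unit SD. The solver is a dense symmetric eigendecomposition (frame counts
are a few hundred), deterministic up to a global sign; the sign is fixed by
an orientation heuristic — the supra-median-intensity row centroid inside
the ROI tracks the cranio-caudal diaphragm position, and end expiration is
its cranial extreme — with an explicit user override that always wins. A
correlation magnitude below 0.3 between signal and centroid aborts rather
than guessing. Defaults: k = max(10, 5% of frames); peak detection on a
3-frame moving average with a 1.5 s minimum peak separation (breathing
above 40/min not expected); tolerance band 0.15 of the full signal
amplitude below a peak; selections under 20 frames rejected as too short to
hold a cardiac cycle.

### Cardiac gating

Segmentation is a pluggable contract (frames → binary masks), because the
contribution is the gating rules, not any particular segmenter.
The bundled `ReferenceSegmenter` thresholds inside a circular search region
with a 3-class multi-Otsu split and keeps the largest connected top-class
component, holes filled. A single Otsu level is not used: with trimodal
bright-blood contrast (background < myocardium < blood) it can fall between
background and myocardium and return the epicardial disk instead of the
cavity. The epicardial mode keeps the above-lower-threshold component
containing the blood pool. This segmenter is warranted only for
phantom-like contrast and carries an area contract (within 5% of truth),
not a frame-exact timing contract.

The ED rule uses strict inequality over a ±3-frame window; plateaus of
equal quantized areas therefore yield *no* detection, with a warning — a
real failure mode (see Limitations) that is reported rather than silently
tie-broken. ES ties break to the earliest frame. Automated-vs-manual
agreement matches detections one-to-one by nearest distance within ±5
frames (well under half a cardiac period at exercise heart rates; the
matching rule is this package's choice).

### Synchronization

"Temporal down-sampling" is pure per-pixel linear interpolation along time;
spatial resolution is never altered. The sample grid is endpoint-inclusive
(j·(L−1)/(N−1)), so ED and ES frames pass through bit-exact and no
extrapolation occurs; sample times are strictly increasing, so frame order
is preserved. The ES frame is shared by both limbs and stored once, giving
cine length N_sys + N_dia − 1; the trailing ED duplicate is kept for
unambiguous interval bounds (drop it for cyclic playback). Re-synchronizing
an already synchronized cine is the identity. Full provenance (per-slice
source frame indices and sample times) is written alongside the cine.

The end-to-end pipeline tries end-expiratory peaks in decreasing run-length
order, then widens the tolerance band (×1.5, ×2) before declaring a slice
failed — the scriptable equivalent of the interactive choice among
suggested timeframe sets. Failed slices either abort the run (default) or
are skipped and counted, mirroring how per-subject failures are reported in
practice.

### Volumetry and phases

Volume is Simpson slice summation (area × thickness, no basal
partial-slice correction); mass is (epi − endo) volume × 1.05 g/mL
(standard myocardial density). Endocardium protruding beyond the
epicardium is clipped with a warning up to 5% of the epicardial area and
rejected beyond. Phase conventions on a synchronized volume curve: ED = 0
and ES = N_sys − 1 by construction; MS = the systolic midpoint (half-up
rounding); ERF = the frame starting the largest forward volume step at or
after ES (max filling rate). Both MS and ERF are deterministic stand-ins
for what is interactively picked in practice, and both are overridable. A
non-filling diastolic curve requires a manual ERF. Bland–Altman: bias =
mean difference, SD with ddof = 1, limits of agreement bias ± 1.96 SD,
percent variants relative to a stated reference mean.

## The phantom

The phantom emulates sequential multi-slice real-time acquisition: each
slice is an independent time series with random cardiac and respiratory
phase offsets. Defaults are one fixed set of study conditions: 14 slices ×
250 frames at 36 ms; 1.9 × 2.8 mm pixels, 6 mm slices, 96 × 72 grid; heart
rate 100 bpm with 4% uniform beat-to-beat period jitter and systole_frac
1/3 (cosine systolic and diastolic limbs — any smooth asymmetric waveform
with a unique per-cycle maximum would do); breathing 19 /min as a
sin⁴ waveform (expiratory dwell, as in real breathing — this produces
end-expiratory runs of ~30–40 frames at the default tolerance, the scale a
gating method actually encounters) with 6 px (~11 mm) peak-to-peak caudal
translation; endocardial radius 24 → 17 mm scaled by an apex→base profile
(0.6 → 1.0); myocardial ring area 1100 mm² held constant every frame
(incompressible myocardium), epicardial radius derived from it; Gaussian
intensity noise with SD 0.1 of the myocardial intensity; bSSFP-like levels
background 0.05 < myocardium 0.5 < diaphragm 0.8 < blood 1.0. A bright
half-plane below the heart translates with respiration so the
diaphragm-ROI workflow is exercised literally. Respiration is in-plane
translation only by default; a through-plane intensity-modulation flag
exists but is off (no quantitative model for it is available).

Truth masks use **area-exact rasterization**: a disk mask is the N pixels
nearest the centre in mm metric with N = round(πr²/pixel area). Plain
threshold rasterization at these pixel sizes carries Gauss-circle area
noise of several percent of the ring area, which would corrupt the
mass-conservation ground truth; area-exact masks keep the rasterized
annulus within one pixel of the analytic ring area in every frame. ED/ES
truth labels are the frames of maximal/minimal sampled radius per beat
(within ~0.7 frames of the true phase instants; the asymmetric waveform
skews the sampled extremum toward the slow limb), i.e. exactly what a
perfect area-based detector should report.

What the phantom does **not** model: MR physics (k-space, banding, flow),
exercise bulk motion, through-plane motion and the complex basal/apical
morphologies it creates, ECG, or segmentation-quality variation. Passing
phantom tests therefore validates the gating rules, the synchronization
arithmetic and the volumetric bookkeeping — not robustness to real
exercise image quality.

## Known limitations

- **Apical slices.** Small cavities mean small, heavily quantized areas;
  the strict ED rule then suffers exact ties at the flat area maximum, and
  the most apical phantom slices occasionally fail gating (reported, not
  hidden). The same weakness at basal/apical levels is a documented
  property of the area-peak assumption in vivo.
- **Quantization ties vs noise.** The two frames straddling the ED instant
  are near-identical images; their integer-pixel areas tie for a sizeable
  fraction of beats at zero noise, and a little image noise *raises*
  detection recall by dithering the ties apart. ED-detection recall is
  therefore not monotone in image noise at the low-noise end; it degrades
  only once noise dominates the quantization scale.
- Problem sizes in tests and the acceptance script (slice counts 2–14,
  250 frames) are the package's chosen study conditions; embedding and
  synchronization are exercised at full per-slice length.
- One diaphragm ROI is applied to all slices of a phantom stack (their
  geometry is identical); real data may need per-slice ROIs, which
  `RoiSpec` supports.
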