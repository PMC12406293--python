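# cinesync

Retrospectively synchronized, time-resolved ventricular cine images from 2D
real-time free-breathing cardiovascular MR.

## The problem

Imaging the heart during exercise rules out the two pillars of standard cine
CMR: breath-holding and ECG gating (the ECG is corrupted by the
magneto-hydrodynamic effect and motion). The practical alternative is
continuous 2D real-time imaging — hundreds of free-breathing timeframes per
short-axis slice position, acquired sequentially from apex to base — which
leaves the respiratory and cardiac phases unsynchronized across slices.
Volumetric measures (LV volume and mass by Simpson slice summation) require
every slice of a time point to sit at a similar respiratory and cardiac
state.

`cinesync` reconstructs a single-cycle, time-resolved short-axis cine from
such multi-heartbeat real-time stacks in three steps:

1. **Respiratory gating.** A user-placed rectangular ROI over the diaphragm
   is reduced to a 1D surrogate by manifold learning (Laplacian eigenmaps on
   a symmetric k-NN graph of the per-frame ROI vectors). After orienting the
   signal so maxima mean end-expiration, the peak with the greatest number
   of consecutive timeframes within a tolerance band of its extreme is
   selected.
2. **Cardiac gating.** Within the selected consecutive frames, the LV blood
   pool is segmented (pluggable; a reference intensity segmenter is bundled
   for phantom-like contrast) and the cross-sectional area A(t) computed.
   ED frames satisfy A(t) > A(t ± k) for k = 1..3 strictly; ES is
   argmin A(t) between two consecutive EDs. Two consecutive EDs bound one
   R-R interval; frames are never shared between heartbeats, preserving the
   true temporal coherence of the acquisition.
3. **Synchronization.** Per slice, the systolic limb (ED..ES) and diastolic
   limb (ES..ED) are down-sampled independently to the across-slice minimum
   counts N_sys and N_dia by per-pixel linear interpolation in time on an
   endpoint-inclusive grid, then rejoined on the shared ES frame. Every
   slice then has ED at index 0 and ES at index N_sys − 1; cine length is
   N_sys + N_dia − 1.

Validation statistics mirror how such a method is assessed: timeframe
differences ΔT = T_automatic − T_manual (mean ± SD per phase, after
nearest matching within ±5 frames), and Bland–Altman agreement
(bias ± 1.96 SD) of LV mass across cardiac phases — the anatomical mass is
constant over time, so its spread across ED, mid-systole (MS), end-systole
(ES) and early rapid filling (ERF) measures synchronization fidelity.

Because no in-vivo data are bundled, the package ships a fully
ground-truthed synthetic phantom: multi-slice free-breathing real-time
stacks (36 ms temporal resolution, 1.9 × 2.8 mm pixels, bright-blood
contrast, a translating diaphragm edge) with exactly known cardiac phase,
respiratory displacement, ED/ES labels, LV masks and myocardial mass.

## Worked example

`python examples/05_full_pipeline.py` runs the whole chain on a 14-slice
default phantom and prints:

```
gated 12 of 14 slices (failed: [0, 2])
synchronized cine: (12, 16, 96, 72) (N_sys=6, N_dia=11)
analysis phases (frame indices): {'ed': 0, 'ms': 3, 'es': 5, 'erf': 11}
LV volume curve: 91 mL at ED -> 47 mL at ES
LV mass per phase (g): ed=82.5, ms=82.9, es=82.9, erf=83.8
true mass of gated slices: 83.2 g
mass CV across phases: 0.55% (< 2%: anatomy is preserved through gating, resampling and synchronization)
```

Two apical slices fail cardiac gating here (the LV area rule is least
reliable at the apex, where areas are small and their quantized maxima can
tie); failures are reported, the remaining slices synchronize, and the
measured mass matches the analytic truth of the gated sub-stack to well
under a gram per phase. The other examples (`examples/01…04`) demonstrate
each stage in isolation.

A thin CLI mirrors the stages: `cinesync phantom | resp-gate |
cardiac-gate | sync | analyze | run` (see `cinesync --help`); the library
API is the primary surface.

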