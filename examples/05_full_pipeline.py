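"""End-to-end: phantom stack -> synchronized cine -> LV mass consistency.

Because the anatomical mass of the ventricle is constant over time, the
spread of pipeline-measured LV mass across the four analysis phases (ED,
MS, ES, ERF) quantifies how well the synchronized cine preserves anatomy.
"""

import numpy as np

import cinesync as cs
from cinesync.pipeline import PipelineConfig, run_pipeline

params = cs.PhantomParams(seed=1)  # 14 slices x 250 frames, defaults
stack, truth = cs.generate_phantom(params)

rr, cc = cs.default_diaphragm_roi(params)
config = PipelineConfig(roi_row_range=rr, roi_col_range=cc,
                        lv_center_px=cs.heart_center_px(params),
                        lv_search_radius_px=24,
                        on_slice_failure="skip")
result = run_pipeline(stack, config)

print(f"gated {len(result.used_slices)} of {params.n_slices} slices "
      f"(failed: {result.failed_slices or 'none'})")
print(f"synchronized cine: {result.cine.data.shape} "
      f"(N_sys={result.cine.n_sys}, N_dia={result.cine.n_dia})")
print(f"analysis phases (frame indices): {result.phases.as_dict()}")

v = result.volume_curve.volumes_ml
print(f"LV volume curve: {v.max():.0f} mL at ED -> {v.min():.0f} mL at ES")

masses = np.array([result.phase_masses_g[k] for k in ("ed", "ms", "es", "erf")])
true_used = (params.ring_area_mm2 * len(result.used_slices)
             * params.slice_thickness_mm * 1.05 / 1000.0)
print("LV mass per phase (g):",
      ", ".join(f"{k}={result.phase_masses_g[k]:.1f}" for k in ("ed", "ms", "es", "erf")))
print(f"true mass of gated slices: {true_used:.1f} g")
print(f"mass CV across phases: {100 * masses.std() / masses.mean():.2f}% "
      "(< 2%: anatomy is preserved through gating, resampling and synchronization)")
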