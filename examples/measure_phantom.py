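"""Measure a synthetic subject end to end and compare with ground truth.

Generates a healthy-phenotype respiratory phantom (15 frames from
end-expiration to end-inspiration), rasterises it to 1 mm binary masks the
way segmentations arrive from a scanner workstation, runs the full pipeline
(contour extraction, landmark detection, outcome ratios) and prints the
measured ratios next to the analytic ground truth.
"""

import diaquant as dq

params = dq.preset("healthy", seed=7)
result = dq.generate_phantom_series(params, rasterize=True,
                                    subject_id="demo")
measured = dq.measure_series(result.mask_series()).record
truth = result.ground_truth

print(f"{'outcome':<22}{'measured':>10}{'truth':>10}")
for name in ("cc_ratio", "ap_ratio", "cc_ap_ratio", "area_ratio",
             "da_ratio", "dh_ratio", "post_displacement_mm"):
    print(f"{name:<22}{getattr(measured, name):>10.3f}"
          f"{getattr(truth, name):>10.3f}")

print()
print("Ratios are end-inspiration / end-expiration.  A CC ratio of ~1.7 "
      "with a DH ratio < 1 is the healthy pattern: the diaphragm descends "
      "strongly and flattens during forced inspiration.  Residual "
      "differences from truth are 1 mm rasterisation error (a few "
      "percent on a single phantom; under 1.5% averaged over seeds).")
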