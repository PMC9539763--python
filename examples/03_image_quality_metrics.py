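"""Image-quality metrics on a controlled synthetic-CT error pattern.

Takes a phantom CT as reference, builds a fake "synthetic CT" with known
defects (a +100 HU bias in bone, 30 HU noise everywhere), and shows how the
per-segment report localizes them: the bone mean error recovers the bias,
soft tissue stays near zero.
"""

import numpy as np

import synthct as s

case = s.generate_paired_case(
    s.PhantomSpec(seed=3, shape=(48, 48, 48), spacing=(6.0, 6.0, 4.0)))

seg = s.segment_tissues(case.ct, case.body_mask)
rng = np.random.default_rng(0)
sct_vals = case.ct.values + np.where(seg.bone, 100.0, 0.0) + rng.normal(0, 30, case.ct.shape)
sct = case.ct.with_values(np.clip(sct_vals, -1000, 3095), "SCT")

report = s.evaluate(sct, case.ct, case.body_mask)
print("segment   n voxels      MAE (HU)     ME (HU)")
for name in ("whole", "air", "soft", "bone"):
    print(f"{name:8s} {getattr(report, 'n_' + name):9d}  "
          f"{getattr(report, 'mae_' + name):10.1f}  {getattr(report, 'me_' + name):10.1f}")
print(f"\nPSNR {report.psnr:.2f} dB, global SSIM {report.ssim:.4f}")
print("the +100 HU defect appears in bone ME only; symmetric noise leaves "
      "soft-tissue ME near zero while its MAE reflects the noise level.")
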