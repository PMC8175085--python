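"""Histogram-matching bleach correction on a synthetic time-lapse.

A static scene is bleached at 10% intensity loss per frame, then every
frame is quantile-matched to frame 0. The per-frame means collapse back
to the reference level; the QC report verifies that matching never
worsened a frame's ECDF distance to the reference.
"""

import numpy as np

import ktrquant as kq
from ktrquant.synth import AcquisitionParams

scene = kq.make_wound_scene(
    seed=2,
    frame_times_min=np.arange(-15.0, 0.0),
    activity_noise=False,
    acquisition=AcquisitionParams(
        bleach_rate_per_frame={0: 0.1, 1: 0.1},
        read_noise_sd=0.0,
        photon_scale=float("inf"),
    ),
)
bleached = kq.apply_noise_and_bleach(kq.render_scene(scene), scene.acquisition, seed=2)
corrected, report = kq.correct_stack(bleached, channel=0)

pre = bleached.data[:, 0].mean(axis=(1, 2, 3))
post = corrected.data[:, 0].mean(axis=(1, 2, 3))
print("frame  bleached-mean  corrected-mean")
for t in (0, 5, 10, 14):
    print(f"{t:5d}  {pre[t]:13.2f}  {post[t]:14.2f}")
print()
print(f"max corrected-mean deviation from frame 0: {100*np.max(np.abs(post/post[0]-1)):.3f}%")
df = report.to_frame()
print(f"ECDF-distance invariant (post <= pre) holds on all frames: "
      f"{bool(np.all(df.post_ecdf_distance <= df.pre_ecdf_distance + 1e-12))}")
print()
print("Correction is for display/QC only; quantification always uses raw data.")
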