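"""Render a small synthetic scene and recover the ground truth.

Builds a noise-free two-channel stack (reporter + nuclear marker) for a
handful of cells, runs segmentation + banded-cytoplasm measurement, and
compares the measured nuclear/cytoplasmic ratio of each cell and frame
with the generator's hidden partition ratio.
"""

import numpy as np

import ktrquant as kq

scene = kq.make_wound_scene(
    n_control=2, n_ablated=2, n_adjacent=2,
    frame_times_min=np.arange(-2.0, 6.0), activity_noise=False, seed=11,
)
stack = kq.render_scene(scene)
measured = kq.measure_stack(stack).drop(columns=["time_min"])
truth = kq.ground_truth_table(scene)

# match measured tracks to ground-truth cells by centroid
t0 = truth[truth.frame == 0]
mapping = {}
for cid, grp in measured.groupby("cell_id"):
    row = grp[grp.frame == grp.frame.min()].iloc[0]
    d = np.hypot(t0.centroid_y - row.centroid_y, t0.centroid_x - row.centroid_x)
    mapping[cid] = int(t0.iloc[int(np.argmin(d.to_numpy()))].cell_id)
measured = measured.assign(gt=measured.cell_id.map(mapping))
j = measured.merge(truth, left_on=["gt", "frame"], right_on=["cell_id", "frame"])

ratio = j.nuclear_mean_ekc / j.cyto_mean_ekc
err = np.abs(ratio / j.nc_ratio_true - 1.0)
print(f"{len(scene.cells)} cells x {scene.n_frames} frames")
print(f"measured nuc/cyt ratio vs ground-truth partition ratio:")
print(f"  max relative error  = {100 * err.max():.2f}%")
print(f"  mean relative error = {100 * err.mean():.2f}%")
print()
print("On a noise-free render the banded-cytoplasm measurement recovers")
print("the true reporter partition to within rasterization error (<5%).")
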