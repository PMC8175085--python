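"""Critical-D thresholds for position-vs-control KS comparisons.

The two-sample KS test rejects when the sup-norm ECDF distance D exceeds
D_crit = sqrt(ln(2/alpha)/2) * sqrt((n1+n2)/(n1*n2)). For per-position
comparisons the samples pool each cell's values over a 21-frame window,
so n = cells x 21: 24 control cells against 9/9/9/8/5 cells at ranks
one..five from the wound, at alpha = 0.001.
"""

from ktrquant import ks_critical_d, ks_two_sample

n_control = 24 * 21
for rank, n_cells in [("first", 9), ("second", 9), ("third", 9), ("fourth", 8), ("fifth", 5)]:
    d = ks_critical_d(n_control, n_cells * 21, alpha=0.001)
    print(f"control vs {rank:>6} cell from wound: critical D = {d:.5f} (prints as {int(d*1000)/1000})")

print()
r = ks_two_sample([1, 2, 3], [2, 3, 4])
print(f"worked example: D({{1,2,3}}, {{2,3,4}}) = {r.D:.4f} (= 1/3)")
print("a comparison is significant when its observed D exceeds the critical D")
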