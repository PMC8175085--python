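# Methods

## The measurement model

A kinase-translocation reporter is a fluorescent fusion whose nuclear
localization signal is inactivated by kinase phosphorylation, so the
reporter's nuclear/cytoplasmic concentration ratio is a monotone proxy for
kinase activity. The package measures that ratio on 2D maximum-intensity
z-projections: nuclei come from thresholding the nuclear-marker channel,
cytoplasm from a banded selection around each nucleus, and all means are
taken over "defined" pixels only (background pixels are masked out, the
software analogue of converting non-cell pixels of a 32-bit image to NaN).
A 3D variant takes plain voxel means over a nuclear mask for workflows that
quantify entire nuclei volumetrically.

Assumptions: nuclei are well separated at the working resolution (no
watershed splitting of touching nuclei); cells move less than the linking
radius between frames; the banded selection samples cytoplasm of its own
cell wherever the band is defined. Bands of neighbouring cells are *not*
arbitrated — shared pixels stay in both bands and a per-cell
`band_overlap_fraction` is reported instead, because any arbitration rule
would be an unverifiable convention; downstream users can filter on it.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| nuclear threshold | Otsu | — | bimodal marker histograms; `fixed`/`triangle` selectable |
| background mask | triangle | — | long-tailed reporter histograms with dominant background |
| band gap | 1 | px | keeps the band off the nuclear rim at the synthetic pixel scale |
| band width | 4 | px | enough pixels for a stable mean without reaching neighbours |
| min defined band fraction | 0.25 | — | below this the cytoplasmic mean (and the ratio) is undefined rather than noisy |
| linking radius | 10 | px | well above frame-to-frame drift of non-motile cells |
| KS α | 0.001 | — | the stringent level used for the critical-D decision rule |
| default α | 0.05 | — | all other decisions |
| permutations | 999 | — | add-one p resolution of 10⁻³ |

Measurement defaults (gap, width, thresholds) are configuration keys and are
recorded in output provenance. Quantification always uses raw intensities;
bleach-corrected stacks feed quantification only under an explicit
`quantify_corrected` flag.

Ellipticity is defined from second-order image moments as
`e = 1 − minor/major` axis of the moment-equivalent ellipse: rotation
invariant, 0 for a disk. It is a stated substitute for proprietary-software
"ellipticity" outputs whose formula is not public.

## The synthetic generator

The generator emulates two-channel endothelial KTR imaging: elliptical
nuclei (marker channel) inside larger elliptical cytoplasm envelopes,
arranged along vertical vessel-like segments with rejection-sampled,
non-overlapping placement (error after 200 failed attempts rather than
silent overlap). Each cell carries a conserved total reporter amount
redistributed between compartments so that the nuclear/cytoplasmic
concentration ratio equals a log-linear partition map
`ln r(E) = (1−E)·ln r_inactive + E·ln r_active`, defaults
`r_inactive = 2.0`, `r_active = 0.5` — symmetric in log space and matching
the sensor's qualitative bidirectional range. These defaults are test
instrumentation, not biology: published data for this sensor class are
qualitative, so the dynamic range here is a declared choice.

Hidden activity trajectories follow
`E(t) = baseline + amplitude·(1−exp(−t/τ_rise))·exp(−max(0, t−t_on)/τ_decay)`
with `E = baseline` before the wound at `t = 0`. The three classes are:
control (`amplitude 0`), wounded/"ablated" (`amplitude 0.6`, `τ_rise 3 min`,
`τ_decay = ∞`, a rapid sustained rise) and adjacent (`amplitude 0.45`,
`τ_decay 25 min`, a transient rise that relaxes to baseline well before
3 h). Baseline activity is 0.2; per-timepoint Gaussian activity noise has
sd 0.05, clipped to [0, 1]. Response grading by distance from the wound:
amplitude shrinks 12% per rank step and onset is delayed 1.5 min per step,
reproducing a graded, sequential activation pattern. The default imaging
schedule is 1 frame/min with a 20-frame pre-wound window (−20..−1 min), the
21-frame early window (2..22 min) and a 5-frame late epoch near 3 h.

Acquisition noise is the standard fluorescence-camera model: per-channel
exponential bleaching `(1 − rate)^t`, Poisson shot noise on the
photon-scaled signal, additive Gaussian read noise (sd 2 counts), clipped at
zero, over a constant background of 5 counts. All randomness flows from one
root seed through keyed stream splitting (operation-name CRC32 into a
`SeedSequence`), so results are reproducible and independent of call order.

What the generator does **not** emulate: optics (no PSF, so edges are
sharp), cell motility and division, vessel lumen rendering, x/y drift
(a registration hook exists in config but no algorithm is implemented), and
spatially structured background. Passing recovery tests therefore
demonstrates correctness of the measurement logic, not robustness to
blur-induced compartment cross-talk in real microscopes — on real data the
band gap should be widened as the PSF dictates.

## Bleach correction

Histogram matching maps each frame's intensity distribution onto a
reference frame (frame 0 by default) via quantile mapping on 256-bin
histograms. Each distribution is binned over its own range (resolution does
not degrade as frames dim) and each bin is represented by the mean of the
values that fell in it, so point masses such as a uniform background map
exactly rather than to bin centers. The mapping is monotone nondecreasing,
preserving pixel rank order. The QC report records per-frame pre/post means
and a binned sup-norm ECDF distance to the reference; a frame is replaced
only when matching strictly reduces that distance, which guarantees the
report invariant (post ≤ pre) including the degenerate case of a frame
already identical to the reference, where binning alone could otherwise
worsen it. Equivalence to any specific external implementation's binning
internals is not claimed — the contract is the quantile-mapping behaviour
above.

## Statistics

`ks_two_sample` evaluates `D = sup|F₁ − F₂|` at all pooled jump points
(which attains the sup for right-continuous step ECDFs) and reports the
asymptotic p from the Kolmogorov series (100 terms, tolerance 1e−10). The
decision rule rejects when `D > D_crit(α, n₁, n₂) =
sqrt(ln(2/α)/2)·sqrt((n₁+n₂)/(n₁n₂))`, the standard large-sample critical
value. For position-vs-control comparisons the samples pool each cell's
values across the 21-frame comparison window (n = cells × 21); this pooling
is the one sample formation that reproduces the published critical-D
triplet (0.166/0.173/0.209) from the stated cell counts, and it is exact
under the generator's noise model, where timepoint values of control cells
are iid. On real data with within-cell autocorrelation the pooled KS test
is anti-conservative; the permutation test is the safer default there.

The permutation test treats the whole cell curve as the exchangeable unit.
Default statistic `T = meanₜ|mean_A(t) − mean_B(t)|` (L1; L2 and sup
selectable). With ≤ 10 curves in total, all `C(n, k)` label assignments are
enumerated and `p = #{T ≥ T_obs}/#assignments` with the observed assignment
included; otherwise assignments are sampled and
`p = (1 + #{T_perm ≥ T_obs})/(n_perm + 1)` (add-one, so p > 0). Two p-value
conventions coexist deliberately: exact enumeration needs no add-one
correction because the observed assignment is in the enumeration.
Group-order invariance is guaranteed by canonicalising the pooled curve
matrix (lexicographic row sort, NaN high) before generating assignments and
always permuting the smaller group size; the statistic is symmetric, so
`(A,B)` and `(B,A)` give identical p at the same seed. Statistic
comparisons use a 1e−12 tolerance so exact ties count as ≥.

Calibration (Monte-Carlo, on the generator's control class): at pooled
n = 10 cells × 21 frames per group, the KS critical-D rule's null rejection
rate at α = 0.05 lies within the 95% binomial CI of 0.05 over 500
replicates, as does the permutation test's (499 permutations per
replicate); power of both tests is monotone over effect amplitudes
0/0.02/0.06 and saturates near 1 at amplitude 0.06. These replicate counts
are the package's standard desk-scale verification sizes.

Standard omnibus tests (Mann-Whitney, Kruskal-Wallis, ANOVA, normality
tests) are deliberately not re-implemented; `scipy.stats` provides them.
No multiple-testing correction is applied anywhere.

## Numerical and design choices

* Coordinates are 0-based `(y, x)` with pixel centers at integers; ellipse
  rasterization includes pixels whose center lies inside.
* Undefined values propagate as NaN; group means skip them and report the
  count used; a mean over an empty defined set is an error, never 0.
* Nuclei are 4-connected components; segmentation is deterministic
  (scan-order labels).
* Greedy nearest-centroid linking breaks ties by (distance, label, label);
  matches beyond the radius start new tracks.
* The dorsal-aorta normalization rectangle is user-supplied configuration
  (in synthetic scenes, part of the scene), never auto-detected, and the
  normalization uses the projected-2D mean of that region.
* Position indices (first..fifth cell from the wound) come from ground
  truth in synthetic data and would come from a user-supplied ordering on
  real data; there is no automatic wound detection.
* The 5D TIFF + `key=value` sidecar convention keeps all physical metadata
  in plain text; non-uniform imaging schedules ride along as explicit frame
  times in minutes.

## Known limitations

* Touching nuclei merge into one ROI (no watershed); heavily overlapping
  bands are reported, not resolved.
* The asymptotic critical-D rule is approximate at small n; at the pooled
  sizes used here it holds its size empirically, but for very small samples
  an exact KS test would be preferable.
* Histogram matching cannot distinguish bleaching from genuine global
  signal loss; that is why corrected data never feed quantification by
  default.
* The generator's sharp-edged, drift-free scenes make segmentation easier
  than real microscopy; recovery tolerances (5% noiseless, 15% at default
  noise) are statements about the pipeline, not about real-data accuracy.
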