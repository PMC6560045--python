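# Methods

`vlmalign` renders batches of centroided time-of-flight (ToF) mass spectra
comparable: it finds *virtual lock masses* (VLMs) — m/z points supported by
exactly one peak in every spectrum — recalibrates each spectrum's m/z axis
against them, and converts the corrected spectra into aligned feature
vectors for statistical or machine-learning analysis. This note records the
model, the algorithms, the defaults, and what the synthetic benchmarks do
and do not establish.

## The model of mass error

ToF mass measurement error grows linearly with m/z, so every tolerance in
the package is *relative*: a window of half-width `w` around a peak at `mz`
spans `[mz·(1−w), mz·(1+w)]`. Internally `w` is a dimensionless fraction;
user-facing surfaces use ppm (40 ppm ⇔ `w = 4e-5`). Two error components
are distinguished:

- a **per-spectrum multiplicative drift** `(1+ε_σ)` — miscalibration between
  acquisitions, instruments or days — which a piecewise-linear map through
  data-derived anchors can remove; and
- a **per-peak jitter** `(1+η)` — independent centroiding/measurement noise
  — which no recalibration can undo and which sets the accuracy floor.

## Virtual lock masses

Given m spectra and a window half-width `w`, a VLM is an m/z value `v` with
a peak set P such that (1) P holds exactly one peak per spectrum, (2) `v` is
the mean m/z of P, (3) every peak of P lies in `[v(1−w), v(1+w)]`, (4) no
other peak of the collection lies in that window, and (5) every peak of P
has intensity in `[t_a, t_b]`. Only *isolated* VLMs — whose windows
intersect no other VLM's window — are kept; an overlapping pair is removed
entirely (both members), since overlapping anchors would make the
correction ambiguous.

Detection sweeps the pooled, m/z-sorted peak sequence once. A binary
min-heap holds the next unprocessed peak of each spectrum (so pushes and
pops total at most `2n` for `n` pooled peaks) and an *active sequence*
holds the consecutive run of peaks currently considered as a candidate
group, with per-spectrum membership flags, the running mean, and the m/z of
the most recently discarded front peak. The run is greedily extended while
extension is feasible (candidate from an unrepresented spectrum; front and
candidate inside the window around the prospective mean); on failure the
last validated content is emitted as a candidate and the front advances.
Overlap removal on the sorted candidates then needs only adjacent
comparisons. Total work is O(n log m).

Two refinements beyond the narrowest reading of the sweep were needed so
that its output matches a literal implementation of the definition
(`brute_force_vlms`, the package's quadratic-time oracle):

- the content is re-validated after each front advance, not only after
  insertions — otherwise a maximal group created by shrinking (down to a
  singleton, possible in alignment mode) is skipped; and
- a pending valid group is *flushed* as a candidate, rather than
  overwritten, when the content later re-validates after growing by two or
  more peaks: the failed one-peak extension proves the pending group was
  maximal in its own right. (Both emitted groups share a peak, so their
  windows overlap and overlap-removal arbitrates — exactly as the literal
  definition demands.) Symmetrically, the terminal drain emits every valid
  suffix once the heap is exhausted.

**Known divergence.** When the window size is comparable to the typical
peak spacing, the definition admits groups spanning nearly the entire
window which the incremental test (front and candidate inside the window
around the *running* mean) cannot assemble. In such tie configurations the
sweep may miss a boundary-spanning group that the oracle finds; it never
emits a group violating the definition (every output is re-audited in the
tests, including maximality for alignment points). Under the intended
operating regime — within-group spread well below the window, compound
spacing well above it — fuzzing finds no disagreement.

Sub-threshold peaks (intensity outside `[t_a, t_b]`) are invisible to the
sweep: they are never pushed onto the heap, so they can neither join a
group nor veto one through property (4). `audit_vlms(strict_exclusivity=
True)` re-checks exclusivity against *all* peaks for users who prefer the
stricter reading; it is off by default because the thresholded reading is
what the sweep computes and the two differ only when background noise falls
inside an anchor window.

## Window-size selection

The isolated-VLM count is low for windows too narrow to span the jitter,
low again for windows so wide that candidates overlap, and peaks in
between. `scan_window_sizes` evaluates a user grid (default: geometric,
1–200 ppm, 20 points — a score of values suffices given the unimodal
behaviour) and returns the count maximizer, ties broken toward the
smallest window. On plateaus this tie-break returns the left edge, which
can sit close to the group spread; protocols that re-detect on subsets
(homologue comparison, stability) therefore use a mid-plateau window
(40 ppm by default) rather than the plateau edge.

## Correction

For each spectrum, every VLM window is searched for its unique anchor peak
(`match_vlm_peaks`). Matching applies the detection intensity bounds: a
lock-mass anchor is by definition a thresholded peak, and without the
bounds a sub-threshold background peak inside the window of an *unseen*
spectrum would make the match ambiguous even though detection guarantees
uniqueness among thresholded peaks. For spectra of the detection set the
match is exact and complete; for new spectra a window with zero or several
admissible peaks leaves that VLM unmatched and the interpolation bridges
over it. Fewer than two matches make a spectrum uncorrectable (reported,
and skipped or raised per caller's choice); with a single VLM there is no
interpolation interval and no fallback is defined.

Between consecutive matched anchors `(μ_i, v_i)` and `(μ_{i+1}, v_{i+1})`
peaks are mapped by `μ′ = aμ + b` with `a = (v_{i+1}−v_i)/(μ_{i+1}−μ_i)`
and `b = v_i − a·μ_i`. The explicit slope/intercept form (rather than a
generic interpolation routine) is deliberate: anchors map onto their lock
masses exactly, and when the anchors already sit on the lock masses the
segment is the identity bit-for-bit, which makes re-correcting an
already-corrected set a no-op. Likewise the candidate mean recorded during
detection snaps to the common value for zero-spread groups, so re-detection
on a corrected set reproduces the lock masses exactly. All slopes are
positive (isolated windows force strictly increasing anchors), so peak
order is preserved. Intensities are never modified.

Peaks outside the outermost matched anchors could only be corrected by
extrapolation, which is unreliable; they are removed by default
(`trim=True`) or passed through unmodified and counted when trimming is
off. Correction is O(peaks) per spectrum.

## Alignment window and feature representation

After correction, peaks of the same compound cluster far more tightly than
`w`. The alignment window `θ` is estimated by leave-one-out: withholding
each interior lock mass `v_i` (the outermost two lack a bridge) and
re-correcting its member peaks through the segment joining its neighbours
yields `θ_i = max_σ |μ′_σ − v_i|/v_i`, the smallest window that would still
gather that group. Only the two adjacent segments change, so each `θ_i`
costs O(m). `θ` is the nearest-rank upper 95th percentile of the `θ_i`
(the smallest value covering 95% of them; the maximum is a deliberate
overestimate, kept as `percentile_z=100`). In the inductive workflow the
percentile is the natural hyperparameter to cross-validate. The
leave-one-out must run on the *raw* spectra: on a corrected set the anchors
sit exactly on the lock masses and every deviation is zero.

Alignment points are then detected on the corrected spectra with the same
sweep, with the one-peak-per-*every*-spectrum rule relaxed to one peak per
*distinct* spectrum (1..m members; singletons are legal) and no intensity
ceiling. A lower `noise_floor` (default 0) can suppress background peaks.
By the 95% construction roughly 5% of marginal groups can exceed `θ`; an
outlying member then drops out of its group silently (it cannot form its
own point, because the group sits inside its window), which appears
downstream as an occasional zero in an otherwise present feature.

Each alignment point defines one feature column labelled by its mean m/z:
for a corrected spectrum the feature is the intensity of the in-window peak
closest to the point (ties to the lower m/z; an alignment set admits at
most one peak per spectrum, so a second in-window peak is off-model and
"closest" keeps the representation deterministic and order-independent), or
0 when the window is empty. `bin_spectrum` provides the conventional
fixed-bin baseline (half-open bins, sum or max aggregation, fixed-Th or
geometric/relative widths) for comparison.

Two workflows wire these stages together. *Transductive*: all spectra are
pooled through detection → correction → θ → alignment before the
train/test split. *Inductive*: every model is fitted on the training
spectra alone and frozen; test spectra are matched against the frozen
windows and represented on the training-time columns. The inductive path
never reads test spectra before the models are frozen — the contract that
makes downstream evaluation honest.

## Synthetic data

The generator emulates a single-batch acquisition of same-nature samples:
`k_common` backbone compounds present in every sample, `k_variable`
compounds present with probability `presence_prob`, and
`k_noise_per_spectrum` background peaks uniform over the mass range.
Observed m/z is `M·(1+ε_σ)·(1+η)`; drift `ε_σ` is uniform in ±`drift_scale`
and jitter `η` uniform in ±`jitter_scale` (uniform by default so worst-case
deviations are bounded and recovery bounds are assertable; Gaussian
available). Compound intensities are log-normal with median 5·10⁴ counts
(σ = 0.5 in log space), comfortably above the customary 1000-count lower
threshold; noise intensities are log-normal with median 150 counts
(σ = 0.35) — background of exactly the kind the lower intensity threshold
exists to exclude. Defaults: 50 spectra, 100 common + 50 variable
compounds (p = 0.5), 50 noise peaks per spectrum, masses in [50, 1000] Th
with ≥ 200 ppm relative separation, drift ±10 ppm, jitter ±5 ppm.
`sub_ta_fraction` can force a fraction of backbone compounds below the
threshold in one spectrum each, emulating intensity dropouts.

What the generator does *not* emulate: isotope envelopes, adducts, chimeric
peaks, intensity drift, heteroscedastic jitter, or drift that is nonlinear
in m/z. Because the planted drift is exactly multiplicative, piecewise
linear interpolation can remove it fully; passing benchmarks therefore
demonstrate correctness of the machinery and behaviour under the stated
error model, not performance on instruments whose residual calibration
error is nonlinear between anchors.

## Numerical and protocol choices

- Heap ties on equal m/z break by spectrum index; detection output is
  independent of spectrum input order (up to re-indexing).
- All window membership uses closed intervals; a peak exactly on an edge is
  inside, consistently everywhere.
- `mu_l` starts as a sentinel "none" (outside every window) rather than 0.
- Duplicate m/z within one spectrum are retained as distinct peaks; the
  detector's uniqueness checks simply never admit both into one group.
- Zero-intensity rows are kept on read; thresholding belongs to detection.
- Correction RMSE between two corrections of the same spectra is
  `sqrt(mean((1e6·(mz_a − mz_b)/mz_b)²))` over homologous peaks — peaks in
  1–1 correspondence by original index, restricted to the corrected span of
  both models when the models trim differently.
- Benchmark problem sizes: oracle-equivalence runs use 100 instances with
  m ≤ 5 and ≤ 500 pooled peaks; the learning-curve protocol uses 185
  spectra (25 held out, training subsets 10→160, 50 re-partitioned
  replicates — fewer leave the per-size medians too noisy to order, since
  adjacent doubling sizes differ by only √2 in expected RMSE); stability
  uses 3/5/10-fold splits of the default 50-spectrum batch. These sizes
  exercise every code path at a small fraction of the cost of a full-scale
  study.

## Known limitations

- Spectra must share enough common compounds (same-nature samples); with
  very few peaks per spectrum, full-coverage groups become improbable.
- Correction reaches only the span between the outermost anchors; nothing
  is corrected (or, by default, kept) outside it. Compounds below the first
  or above the last lock mass are invisible to the aligned representation.
- Lock masses carry the *mean* observed m/z, not the compound's exact mass:
  the correction removes inter-spectrum disagreement, not absolute
  calibration error. A conventional external lock mass can be applied on
  top.
- The relaxed-mode sweep inherits the boundary-tie divergence described
  above; it is irrelevant at `θ ≪` compound spacing but worth knowing when
  pushing `θ` toward the spacing scale.
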