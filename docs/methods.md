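# Methods

This note documents the models, estimators and numerical choices behind
`boldcausal`, in the order the pipeline runs them.

## Synthetic data generator

The generator emulates a block-design BOLD study.  A
`GroundTruthGraph` is a lag-annotated directed graph over named ROIs whose
links carry one of three functional forms:

* **linear** — the target receives `c · x_src(t − λ)`;
* **quadratic** — `c · x_src(t − λ)²`; with a symmetric zero-mean source,
  `corr(x, x²) = 0`, so this form is invisible to correlation-based tests
  while remaining a smooth (GP-learnable) dependence;
* **multiplicative_noise** — the target's innovation standard deviation is
  scaled by `1 + |c · x_src(t − λ)|`; there is no signal in the conditional
  mean at all, only in the conditional scale, the canonical case a
  model-free information-theoretic test should catch.

One canonical alternative per detection regime is deliberate: it makes the
nature-triangulation claim falsifiable link by link.

Per node, innovations are AR(1)-smoothed (`e_t = φ e_{t−1} + w_t`, variance
normalized to `noise_sd²`) as a stand-in for hemodynamic autocorrelation;
there is no explicit HRF convolution and no voxel space.  Note the reduced
form of this choice: a structural link at lag λ into a node with smoothed
innovations implies a genuine echo dependence at lag λ+1 (coefficient
`−φc`).  Benchmarks that score adjacencies therefore use graphs with
explicit lag-1 self-links and `φ = 0` so structural and reduced-form
adjacency sets coincide.

Each (subject, condition, block) is simulated independently with a 50-step
burn-in, from an RNG stream derived counter-style from
`(master seed, subject index, condition index, block index)` — adding
subjects never perturbs earlier subjects' data, and identical inputs give
bit-identical panels (no implicit entropy; a missing seed is an error).

Stationarity is enforced at construction: the companion matrix of the full
linear system (structural lag-0/lagged links plus the AR(1) noise, folded
into one VAR) must have spectral radius < 1.  Quadratic links on a feedback
cycle are rejected outright — a squared variable feeding back onto itself is
explosive at any coefficient.  This same linear-system view powers the
closed-form oracle `var_stationary_cov` (discrete Lyapunov equation on the
companion form), which the tests compare simulated moments against.

A shared low-frequency confound — three sinusoids with frequencies drawn
from U(0.002, 0.009) Hz with random phases and amplitudes U(0.7, 1.3), plus
a linear drift — is added to every ROI with per-ROI loadings U(0.5, 1.5)
and returned separately, playing the role of the white-matter/ventricle
nuisance series.  The generator does not emulate: HRF shape and its
between-subject variability, motion spikes, non-stationary noise, or
spatially correlated physiological artifacts.  Passing tests therefore
demonstrate correctness of the estimation machinery under the stated
assumptions, not robustness to everything real fMRI does.

Default study shape: 20 subjects × 2 conditions × 2 blocks × 100 volumes at
TR = 1.6 s, 9 ROIs — giving the 4000-sample concatenated series per
condition that the analysis design prescribes.

## Preprocessing

Fixed order: confound regression → high-pass → per-subject centering →
same-condition concatenation.  (Whether nuisance regression preceded the
high-pass in the original acquisition chain is not recoverable; the order
here is fixed by this package and recorded in run provenance.)

* **Confound regression**: per block and ROI, OLS residuals on
  [intercept, confound].
* **High-pass**: projection onto the complement of the discrete-cosine
  (DCT-II) components with frequency `k / (2·L·TR) < 0.009 Hz`, per block.
  A projection has no IIR edge transients and is bit-exact, which matters
  for 100-volume blocks whose span (160 s) barely exceeds the cutoff period
  (111 s).  At that ratio the filter is well-behaved but not surgical:
  a pure drift retains ≈ 6% of its RMS and a worst-phase pass-band sinusoid
  changes by ≈ 8%; both effects fall below 5% for blocks of ≳ 400 samples.
  This trade-off is intrinsic to any linear filter at this block-length /
  cutoff ratio.
* **Centering**: "normalized around the mean" is read as per-(subject,
  condition, ROI) mean-centering without variance scaling — the downstream
  tests are scale-equivariant (partial correlation), standardized
  internally (GPDC) or rank-based (CMIknn).  A `zscore` switch exposes the
  alternative reading.
* **Concatenation**: blocks of one condition joined in lexicographic
  (subject_id, block_index) order (recorded in the output metadata); the
  first and last 5 samples of each block are replaced by a centered
  Gaussian moving average (window 5, σ = 1 sample, weights ∝ exp(−k²/2),
  renormalized at series edges) computed within the concatenated series, so
  windows at a join deliberately mix adjacent blocks — that is the point of
  the smoothing.  At most 10 samples per block per ROI change.

## Conditional-independence tests

All tests evaluate `X^i_{t−λ} ⫫ X^j_t | Z` on lag-aligned columns (the
first `max(lags)` rows dropped).  Windows spanning block boundaries are kept
by default — boundary smoothing exists precisely to make joins benign — and
`mask_boundaries=True` excludes them for sensitivity analysis.

* **parcorr** — Pearson correlation of the OLS residuals of each target on
  [intercept, Z]; two-sided permutation p.  Rank-deficient Z is absorbed by
  least squares with a logged warning.
* **gpdc** — each target is standardized and regressed on standardized Z by
  a Gaussian process (constant × RBF + white kernel; hyperparameters by
  marginal-likelihood maximization with 2 restarts; length-scale bounds
  [1e−2, 1e2], white-level bounds [1e−5, 10]); the statistic is the
  V-statistic (double-centering) distance correlation of the residual pair.
  With empty Z the residuals are the standardized variables themselves (no
  GP fit).  `gp_optimize=False` selects a fixed median-heuristic
  length-scale (also the automatic fallback if optimization fails) — used
  by the heavier benchmark harnesses where hundreds of fits would dominate
  runtime.  One-sided p (dcor has no sign).
* **cmiknn** — columns are rank-transformed to uniform scores (making the
  statistic exactly invariant under monotone transforms), then the
  Frenzel–Pompe / KSG estimator with maximum-norm balls:
  `CMI = ψ(k) − ⟨ψ(n_xz+1) + ψ(n_yz+1) − ψ(n_z+1)⟩`, with `n_z = n − 1`
  for empty Z (the KSG mutual information).  Default `k = max(5, 0.1·n)` —
  large k reduces variance, which favors testing over unbiased estimation;
  the estimation-oriented oracle tests use smaller k.  One-sided p.

### Permutation significance

The null distribution always comes from permutations that respect
autocorrelation:

* **Block shuffle** (parcorr, gpdc, cmiknn with empty Z): contiguous blocks
  reordered uniformly.  Automatic block length = 2 × the smallest lag at
  which |acf| of the permuted vector drops below 2/√n, clamped to
  [1, n/10]; the doubling is needed because dependence reaching across
  block boundaries at the bare crossing lag measurably inflates size for
  AR(1) with φ ≈ 0.9.  At large n the block length is additionally floored
  at n/500 (shuffling at most ~500 blocks); coarser blocks preserve
  dependence at least as well, so validity is unaffected while index
  generation stays cheap.
* **Local permutation** (cmiknn with non-empty Z): each sample draws its
  x-value from one of its 5 nearest Z-neighbors, re-using donors only when
  unavoidable — the X–Z dependence survives under the null, which is what
  makes the conditional test calibrated.  With empty Z this scheme would
  degenerate to an i.i.d. shuffle and break autocorrelation, hence the
  block-shuffle fallback above.

p = (1 + #{|T_perm| ≥ |T_obs|}) / (1 + B) (absolute values dropped for the
one-sided statistics).  The expensive loops use sequential (Besag–Clifford)
stopping: once 6 permuted statistics have exceeded the observed one the
test cannot reach α = 0.01 and p = exceedances/draws is returned; the
rejection boundary is untouched, only clearly-null tests finish early
(`early_stop=False` restores the fixed-length loop, e.g. for studying the
full p distribution).  Permutation comparisons inside gpdc/cmiknn run in
float32 (observed and permuted statistics at the same precision, so the
exchangeable comparison is like-for-like); reported statistics and the
public `distance_correlation` / `cmi_knn` estimators are float64.

gpdc and cmiknn subsample to `max_samples` (default 1000) with seeded,
order-preserving subsampling before testing.

## PCMCI+

* **Condition selection** (per target, separately for the lagged pool
  {all nodes} × {1..τ_max} and the contemporaneous pool): iteratively test
  each surviving candidate given the q strongest other survivors (by
  |statistic|, ties by (node, lag)), remove those with p > pc_alpha
  (= α = 0.01 by default), increment q until it exceeds the surviving set.
  Separating sets are recorded at removal.
* **MCI tests**: every ordered pair (i at t−λ, j at t) is tested given
  parents(j) \ {(i, λ)} plus the λ-shifted lagged parents of i.  Lagged
  tests are evaluated twice — with and without the contemporaneous parents
  of the target in the conditioning set — and the larger p is kept:
  present-time conditions can be children of the effect and open collider
  paths, while omitting them leaves contemporaneous chains unblocked; a
  genuine link must survive both.  Contemporaneous pairs are tested once
  per unordered pair given the union of both parent sets.  Links with
  p ≤ α are kept; lagged links are oriented past → present.
* **Orientation**: for lagged unshielded triples
  (i, τ) → k ∘−∘ j with (i, τ) ⊥̂ j, the middle node's collider status is
  decided by re-testing the outer pair with (k, 0) added to its separating
  set — dependence appearing under that extra condition identifies k as a
  collider (the recorded lagged separating sets cannot contain lag-0
  conditions, so set membership alone is uninformative there).
  Contemporaneous triples i ∘−∘ k ∘−∘ j use the recorded separating set of
  (i, j) directly.  Meek-style rules (R1/R2) propagate orientations without
  creating new colliders; contradictory demands yield a conflict mark
  (`x-x`) that is never silently overwritten; the rest stay undirected —
  the analysis reports those as "undefined" relationships, a first-class
  outcome.

Determinism: every CI test's RNG seed derives from
(run seed, i, λ, j, hash of the conditioning set), so reruns — and
reorderings of the test schedule — are bit-reproducible; results are
memoized across phases on the same key.

## Relationship classification

Lag classes: 0 → contemporaneous, 1 → single-delayed (1.6 s),
2 → double-delayed (3.2 s).  Roles: undirected marks → undefined; directed
seed→partner → causative; partner→seed → response; a delayed dependence
running in both directions → interactive.  Nature by triangulation over the
methods detecting a record: PC ⇒ linear, else GPDC ⇒ non-linear, else
complex.

Collapse accounting (the unit in which totals are reported):

* one record per (seed, partner, task, lag class, role); undirected and
  directed evidence at the same lag class stay separate records;
* a group of directed links is a single *interactive* record only when one
  method evidences both directions (that method demonstrates the reciprocal
  interaction; opposite directions seen only by different methods remain a
  causative and a response record);
* an undefined relationship detected by all three methods in both tasks is
  task-invariant ("permanent") and is counted once with `task='both'`.

Statistic normalization is per method: |statistic| / max |statistic| over
that method's significant links (sign removed first; `minmax` and `rank`
schemes available), yielding values in [0, 1] comparable across methods.
The packaged transcription of the published per-method link lists carries
link structure only — the printed statistic values could not be reliably
aligned to (pair, lag) cells in the available text — so its collapsed
records have no normalized statistics; the counting is unaffected.

## Benchmark harness sizes

Chosen to make each claim testable on one desktop CPU; recorded here as the
package's own design:

* size calibration: 500 replicates of length-400 AR(1) pairs (φ = 0.8),
  199 permutations (parcorr/gpdc), 99-permutation granularity is avoided so
  the α = 0.01 boundary is resolvable;
* graph recovery: 20 panels of n = 4000 from the 9-node linear benchmark;
* nature triangulation: 20 panels of n = 4000 from a 6-node mixed-form
  graph (one linear, one quadratic, one multiplicative-noise link at lag 1
  plus lag-1 self-links); gpdc subsamples to 400 with the median-heuristic
  GP, cmiknn to 500 with k = 50; the multiplicative-noise coefficient (1.0)
  was sized by pilot power analysis to give the model-free test interior
  power at that subsample;
* sensitivity ordering: 200 replicates at n = 500 per (method, form), with
  link coefficients (0.17 linear, 0.35 quadratic) sized so powers are
  interior rather than saturated at 1.

## Known limitations

* The MCI double-evaluation removes the two dominant classes of spurious
  lagged links but is not a full replication of the reference PCMCI+
  condition-search heuristics; exotic mixed lagged/contemporaneous
  structures can still yield extra links at the α-level.
* The quadratic form is centered on detectability contrast, not biological
  realism; real non-linear BOLD coupling is presumably smoother and
  weaker.
* Multiplicative-noise detection power depends strongly on sample size;
  at the default `max_samples = 500` a coefficient ≲ 0.5 is essentially
  undetectable.
* Conflict marks (`x-x`) are preserved, never resolved by statistic size;
  downstream accounting treats them as undefined.
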