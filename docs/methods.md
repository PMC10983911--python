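# Methods

## The measurement model

The unit of analysis is an `n × k` matrix: one scalar measurement per
subject (n ≥ 2) per measurement occasion (k ≥ 2, runs within a session or
sessions).  A two-way crossed ANOVA with subjects random and occasions
fixed partitions the total sum of squares as

    SS_subjects = k·Σᵢ(m̄ᵢ − m̄)²        MSBS = SS_subjects / (n−1)
    SS_columns  = n·Σⱼ(m̄ⱼ − m̄)²        MSC  = SS_columns / (k−1)
    SS_error    = SS_total − SS_subjects − SS_columns
                                         MSE  = SS_error / ((n−1)(k−1))
    MSWS = (SS_total − SS_subjects) / (n(k−1))

MSWS is the one-way pooled within-subject mean square: it absorbs both
occasion shifts and residual noise, which is exactly why ICC(1) — built on
MSWS — is penalized by systematic occasion effects while ICC(3,1) — built
on MSE — is not.  Occasions are treated as fixed for the primary
consistency estimand because repeated scanning occasions are not
exchangeable in practice: task practice, scanner familiarity and
development all travel with occasion order.  ICC(2,1) (occasions random,
absolute agreement) and ICC(1) are exposed alongside for completeness.

## Confidence bounds

Intervals come from the F statistic rather than bootstrap, for speed and
determinism:

* ICC(3,1): F = MSBS/MSE on (n−1, (n−1)(k−1)) df; with
  F_L = F / F_{1−α/2}(df1, df2) and F_U = F · F_{1−α/2}(df2, df1), the
  bounds are (F_L − 1)/(F_L + k − 1) and (F_U − 1)/(F_U + k − 1).
* ICC(1): same construction with F = MSBS/MSWS on (n−1, n(k−1)) df.
* ICC(2,1): the Shrout–Fleiss agreement interval with a
  Satterthwaite-style effective df for the occasion term.  This choice is
  a documented convention, not a derived fact: several defensible
  agreement intervals exist, and this one matches the widely used
  implementations (it reproduces `pingouin.intraclass_corr` exactly,
  which the unit tests verify).

Degenerate units (zero error variance, e.g. a constant voxel) return NaN
for the estimate and both bounds.  NaN deliberately distinguishes "no
variance to assess" from "zero consistency"; spatial medians exclude NaN
voxels.  Negative ICC estimates are reported as computed, not floored at
zero — reliability distributions over many pipelines genuinely extend
below zero and flooring would bias their summaries.

## Voxelwise maps

`voxelwise_icc` flattens a masked stack into an `(n, k, V)` array and
evaluates the decomposition for all V voxels in one vectorized pass.  The
scalar path (`decompose`/`icc_scalar`) calls the same stacked kernel with
V = 1, so the two paths share every floating-point operation; the test
suite additionally checks the maps against an independent loop-based
ANOVA written with explicit sums.  Voxel order is row-major (C order)
over array indices — a pure function of the mask — and out-of-mask voxels
are NaN in memory, with an optional fill value (e.g. 0) applied only when
writing NIfTI for viewer compatibility.

Grids must match exactly (shape equal; affines equal within 1e-4 mm).
Nothing is ever resampled: a mismatched grid is an error, because silent
resampling hides registration bugs in exactly the analyses this package
is meant to audit.

ROI reliability defaults to mean-signal-then-ICC: the spatial mean within
each atlas region per subject/occasion feeds `icc_scalar`.  The
alternative reading — median of the voxelwise ICC map within the region —
is available as `strategy="voxel_median"`, since both conventions exist
in the field and they answer slightly different questions (reliability of
the regional summary signal vs typical voxel reliability).

## Similarity

Thresholding is strict (>): "exceeding z = 3.1" excludes voxels exactly
at the threshold, a measure-zero set for real statistics.  Jaccard and
Dice on two empty masks return NaN rather than 0 or 1 — a vacuous
comparison should be loud, not quietly perfect.  Spearman uses average
ranks for ties (ties are common in masked, discretized maps); with no
ties this is identical to the textbook 1 − 6Σd²/(n(n²−1)) form.  The
Cohen's d conversion d = t/√N commutes with thresholding: binarizing the
d map at c equals binarizing the t map at c·√N, which is property-tested.

## Multiverse bookkeeping

The decision grid spans four axes: smoothing FWHM (built as
multiplier × voxel-size × weight, multipliers 1.5–3.5, rounded to 0.1 mm;
the weight compensates acquisitions whose larger voxels are inherently
smoother), motion-correction option, model parameterization and
contrast.  Enumeration is a deterministic Cartesian product (FWHM
outermost, contrast innermost, ids 1..R).  The package does not execute
GLMs: it consumes per-permutation summary estimates or map sets keyed by
permutation id, which cleanly separates the in-scope statistics from
out-of-scope preprocessing.

Specification-curve tables rank permutations by the across-sample mean
estimate, ties broken by permutation id; the across-sample 95% interval
is mean ± 1.96·SE (the interval construction for such panels is not
standardized, so this normal-theory choice is documented rather than
derived).  Percentile selection is nearest-rank: rank ⌈q·R⌉.  Missing
permutations raise an error rather than being dropped — a specification
curve with silently absent cells misrepresents the multiverse.
Downstream hierarchical modeling of the estimates is out of scope; the
long-format TSV output is directly consumable by any mixed-model tool.

## Bootstrap stability

`bootstrap_stability` resamples subjects with replacement at each sample
size in a grid (default 25–525 in steps of 50, 100 draws per size),
re-runs the voxelwise decomposition per draw on precomputed subject maps,
and retains the in-mask median ICC, MSBS and MSWS.  Per-size summaries
use percentile (2.5/97.5) intervals across draws — at 100 draws,
normal-theory intervals would lean on symmetry the small-n draws do not
have.  One master `SeedSequence` spawns an independent substream per
(size, iteration) cell, so the grid is reproducible and could be
parallelized without changing results.  A without-replacement option
exists so that drawing the full sample once reproduces the full-data
analysis exactly (used as an identity test).

## Synthetic data

The generator draws from the model the estimators assume:

    y[i, j, v] = μ + shift·j + b_i[v] + e_ij[v],
    b ~ N(0, σ_b²),  e ~ N(0, σ_e²)

so the population ICC at voxel v is σ_b²/(σ_b² + σ_e²) — an analytic
ground truth.  Defaults, chosen once as a realistic small study: a
10×10×10 grid at 2.4 mm, n = 60 subjects, k = 2 occasions, background
σ_b² = σ_e² = 1 (ICC 0.5), and a mid-grid sphere (radius 0.3·min(shape))
with σ_b² = 3 (ICC 0.75) emulating elevated task-positive reliability.
The companion reference z-map exceeds 3.1 exactly on the sphere and the
two-label atlas marks sphere vs complement; both are synthetic
stand-ins, labelled as such, for the meta-analytic reference map and
anatomical atlas a real analysis would use.  The occasion shift enters
after the random draws, so identical seeds give identical subject/noise
effects with and without shift — which is what makes the exact
consistency-invariance test possible.

What the generator does *not* emulate: spatial autocorrelation (voxels
are independent, so thresholded-cluster behavior is unrealistic),
non-Gaussian BOLD artifacts, motion, task timing and HRF structure, and
any spatial covariance induced by smoothing real data.  Passing tests
therefore certify the estimators and their orchestration under the
assumed model, not the field behavior of any preprocessing pipeline.

## Problem sizes in the test suite

The suite favors the smallest sizes that still separate signal from
Monte-Carlo noise: parameter recovery uses 8×8×8 × 200 subjects × 20
seeds per ground-truth level; the stability check runs the full
25–525 × 100-draw grid on a 10×10×10 stack of 525 subjects; oracle
equivalence uses 100 random voxels at n = 15.  All are the package's own
choices for a compact, deterministic suite.

## Known limitations

* ICC variants beyond single-measure (average-measure ICC(·,k)), and
  multivariate reliability indices, are not implemented.
* No resampling/registration: inputs must share one grid.
* The ICC(2,1) interval is approximate; coverage at very small n and
  extreme variance ratios inherits the Shrout–Fleiss approximation
  error.
* Group t-maps in the generator use a shared subject effect across
  occasions, which induces realistic between-occasion correlation but is
  not a model of session-specific group variance.
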