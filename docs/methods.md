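# Methods

## Generative model of the synthetic data

The simulator emulates preprocessed multi-subject task BOLD on a common
voxel grid.  Each of K planted networks is a spatial weight field
m_k(v) ≥ 0 — a sum of Gaussian bumps of width σ voxels (default 2),
peak-normalised to 1 — with a matching binary template {v : m_k(v) > 0.5}.
Placement is rejection-sampled until pairwise mask overlap is at most 10%
of the smaller mask; infeasible geometry fails explicitly.

Network k's time course for subject s is

    y_ks(t) = b_ks(t) + Σ_c w_kc · x_c(t)

where x_c is condition c's boxcar convolved with the canonical HRF and
b_ks is a baseline fluctuation: white Gaussian noise low-pass filtered at
0.1 Hz (4th-order Butterworth, zero-phase), standardised to SD 1.  The
low-pass baseline makes planted components identifiable by ICA; real
resting fluctuations have 1/f-like spectra that this does not model.  The
voxel signal is the outer product Σ_k m_k(v) y_ks(t) plus i.i.d. Gaussian
noise (default SD 0.5 against in-mask signal SD ≈ 1, an SNR chosen for
testability — the simulator makes no claim of matching any empirical
SNR).  Noise is temporally white by default so closed-form regression
oracles are exact.

Optional per-subject amplitude jitter (`weight_jitter_sd`) adds independent
Gaussian variation to each (network, condition) weight.  It defaults to 0,
keeping the generative post-condition exact; the pipeline fixture sets it
to 0.15 because real populations vary in response amplitude, and with
literally zero between-subject variance any systematic residual (for
instance the 2–3% time-course leakage that survives even near-perfect ICA
separation) registers as a significant paired t.  Fixture geometry uses a
20³ grid: on much smaller grids the Gaussian tails of neighbouring blobs
overlap, the sources are no longer spatially independent, and time-course
mixing grows to tens of percent — a property of the geometry, not of the
estimator.

What passing tests therefore show: the pipeline recovers what it is
mathematically supposed to recover under its own assumptions (linear
mixing, spatially independent smooth sources, white noise).  They do not
show robustness to scanner artefacts, physiological noise, spatial
autocorrelation of noise, subject misregistration, or motion applied to the
images (motion exists only as a QC trace).

Motion traces are uniform baseline movement in (0.02, 0.3) mm with
injected spikes at 1.25× the requested magnitude, plus a Gaussian
intensity series; spikes therefore exceed the flagging threshold exactly at
the requested positions.

## Design matrices

The canonical HRF is the double-gamma difference
g(t; 6, 1) − g(t; 16, 1)/6 (response peak 6 s, undershoot 16 s, ratio
1/6), sampled at the repetition time over a 32 s window and scaled to unit
peak.  No temporal or dispersion derivatives are modelled: the analysis
extracts a single beta per condition.  Condition boxcars are built on a
grid oversampled 16× (so jittered, off-grid onsets land accurately),
convolved, and downsampled to volume onset times; zero-duration events are
unit impulses.  Runs concatenate with one intercept each; no high-pass or
drift columns are included because the pipeline assumes unfiltered data.
Rest is never a column — condition betas are relative to the implicit rest
baseline, which is why vs-rest contrasts are one-sample t-tests on betas.

## Motion QC

A volume is flagged iff relative movement > 1 mm or |z| > 2.5 of the
trace's own intensity distribution; a constant intensity series yields no
intensity flags (warned).  A participant is excluded iff strictly more
than a quarter of volumes are flagged — exactly one quarter keeps them.
Flagged volumes are dropped from both the data and the design-matrix rows
before decomposition, preserving row alignment; removal is volume-wise (no
notion of trial boundaries exists at this stage).

## Order selection

Per subject, eigenvalues λ₁ ≥ … ≥ λ_p of the time-demeaned data
covariance (p = volumes, N = voxels as samples) enter the classical MDL
criterion

    MDL(k) = −N(p−k)·log( gm(λ_{k+1..p}) / am(λ_{k+1..p}) )
             + ½·k(2p−k)·log N,

minimised over k after averaging across subjects.  A flat spectrum makes
the data term vanish, the penalty selects k = 0, and the pipeline floors
the order at 1 with a warning.  The raw sample count N is used; the
autocorrelation-subsampling correction some toolboxes apply is omitted —
on synthetic data the selected order is validated directly by planted-rank
recovery, which is the property that matters here.

## Group ICA and back-reconstruction

Two-stage reduction: each subject's (time × voxel) data are projected onto
their top d temporal principal directions (d = ⌈1.5·C⌉ by default), the
reduced data are stacked across subjects and reduced again to C, and the
C × voxel group matrix is unmixed by fixed-point ICA with the logcosh
nonlinearity (spatial sources, temporal mixing).  Five seeded restarts are
run; restarts that fail to converge are discarded and the best converged
run by a negentropy score is kept; if none converges the decomposition
fails, naming the seed.  Subject time courses and maps are recovered
through the stored projection operators: with group basis block B_s and
mixing A, the subject mixing is M_s = B_s A, time courses U_s M_s, maps
M_s⁺ X_s.

Two indeterminacies are resolved deterministically: each group map's sign
is flipped to nonnegative skewness ("activation" is positive), and
components are ordered by variance contribution.  Group maps are z-scaled;
subject maps are z-scored per component before group statistics, so
one-sample t-maps test standardised intensities.  Recovery is assessed by
Hungarian matching on |spatial correlation| — never by bit-equality with
any particular ICA implementation, since the algorithm (and its restarts)
is configuration, not a claim.

## Group maps and cluster correction

Voxel-wise one-sample t against zero across subjects (df = n−1);
zero-variance voxels get t = 0 (zero mean, flagged) or a capped ±t_max.
The cluster-forming threshold is one-sided positive by default (component
involvement is positive under the sign convention; two-sided is available)
at voxel p < .001.  Clusters form by 26-connectivity (configurable).
Family-wise error over cluster extents is controlled by subject-wise
sign-flipping: each permutation flips each subject's map with probability
½, re-thresholds, and records the maximum cluster size; a cluster survives
iff its permutation p-value (1 + #{null ≥ size})/(n_perm + 1) is ≤ α.
This exchangeability-based correction replaces the parametric random-field
FWE of standard neuroimaging software: it is assumption-light and exactly
testable at desk scale, and its calibration is verified by simulation in
the acceptance suite.  A consequence worth noting: with voxel p = 1 every
permutation saturates the grid, the observed grid-sized cluster has
permutation p = 1, and the corrected mask is empty — the degenerate
threshold carries no evidence, which is the behaviour a calibrated
procedure must have.

## Template matching

J = |A∩B| / |A∪B| on active voxels (both-empty defined as 0, warned).
Step 1: candidates are components with J ≥ .15.  Step 2 operationalises
"does combining components improve the fit" as greedy forward search:
start from the best single candidate, add whichever candidate's mask union
most increases J, stop when no addition strictly improves (ties within
1e-12 break toward the lower component index).  On split-network cases the
greedy optimum coincides with exhaustive subset search (verified across
generated instances); on arbitrary unstructured masks greedy can fall
short of the exhaustive optimum, and the full search log of evaluated
combinations is kept in the report for review.  With no candidate, strict
mode (default) selects nothing and reports the best single J; non-strict
mode selects the best single component.  Two templates may be supplied;
their selections are compared and disagreement is flagged, not resolved.
Weighted-map similarities (spatial correlation, continuous Dice) are
deliberately not selection criteria — the selection quantity is the
Jaccard on binarised maps.  Note that Jaccard values run low compared with
Dice or correlation; values around .2–.3 against a matching template are
normal, which is why the candidate threshold sits at .15.

## Functional profiling

Per subject, OLS of the back-reconstructed component time course on the
design matrix yields one beta per condition (rank-deficient designs fail,
naming the collinear columns).  The one-way ANOVA treats every subject ×
condition cell as an observation — df = (k−1, N·k−k) — matching the df
convention of the analyses this pipeline mirrors; a repeated-measures
layout would give different df and is intentionally not the default.
Planned contrasts are paired t-tests on beta differences (vs-rest: betas
against 0), df = n−1, Bonferroni-adjusted with min(1, p·m) over the
declared family.  Contrasts are computed even when the ANOVA gate fails;
`gate_passed` records the gate so downstream reporting can mark them as
not interpretable.  Betas are scale-equivariant in the time course while
t, F and p are scale-invariant, so ICA's scale indeterminacy does not
affect inference.

## Pipeline

Stages run from a single validated config (bad thresholds are rejected
before any computation); every stage logs to `run.log` with the config
hash, summary tables contain no timestamps, and identical config + seeds
reproduce byte-identical summaries.  A completed run directory is not
recomputed without `force`.  Artefact-component classification is manual
by design: the pipeline applies a user-authored exclusion list (intended
to be written before matching, so the classifier stays blind to template
correspondence) and emits a grey-matter overlap fraction per component as
a diagnostic only — nothing is auto-excluded.  The emulated a priori
template binarises the planted field at 0.2 of peak rather than the 0.5
half-peak core, because a real template is a thresholded statistical map
from a prior study and covers a network's detectable extent; the half-peak
core would undercount overlap for purely geometric reasons.

## Problem sizes

Defaults are desk-scale by choice: 20³ voxel grids, 100–200 volumes at
TR 2 s, 8–12 subjects, 200–500 permutations, order ≤ 8.  These sizes keep
every validation — including the 200-replicate FWE calibration and
500-replicate contrast calibration — runnable in minutes while leaving all
statistical behaviour (calibration, power, recovery) measurable.  All
sizes are configuration.

## Known limitations

- Volume-wise (not trial-wise) motion scrubbing; no motion applied to images.
- No ICASSO-style stability clustering; restart selection is by negentropy.
- No spatial or temporal noise autocorrelation by default; FWE calibration
  is demonstrated under exchangeability, which real data only approximate.
- The ANOVA's independent-cells layout ignores the subject factor.
- Template resampling is nearest-neighbour on matching grids only; no
  registration.
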