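# Methods

## The measure

Local functional connectivity density (lFCD) quantifies, for every brain
voxel, how large a *spatially contiguous* cluster of functionally connected
tissue surrounds it. Given a preprocessed BOLD series per voxel, a seed x0 is
scored by region growing: the spatial neighbours of x0 are examined first,
and any candidate voxel x_j whose Pearson correlation with the seed satisfies
r(x0, x_j) > R joins the cluster; the neighbours of accepted voxels are then
examined in turn, always correlating against the *seed's* series, until no
unexamined neighbour of the cluster remains. The cluster size k (seed
excluded) is lFCD(x0). The procedure is repeated with every in-mask voxel as
seed.

Properties that follow from the definition, and that the test suite asserts
exactly: lFCD is non-increasing in R, non-decreasing in neighbourhood order
(6 ≤ 18 ≤ 26), and non-increasing under mask shrinkage; and the grown set
equals the connected component containing x0 of the graph of suprathreshold
voxels (r with seed > R) under the chosen spatial adjacency — which is how
the brute-force test oracle computes it.

### Algorithmic choices

- **Neighbourhood**: "closest neighbours" defaults to 26-connectivity (the
  3×3×3 cube minus its centre), configurable to 6 or 18. 26 is the common
  choice in functional connectivity density mapping.
- **Strict threshold**: membership requires r > R, not ≥.
- **Seed-anchored growth**: correlations are always against the seed, not
  against the neighbour that contributed the candidate. A "chain" variant
  (correlate with the adding voxel) exists in other FCD tools; anyone
  comparing outputs across tools must check which variant the other tool
  uses.
- **Visited-set semantics**: each voxel's correlation with the seed is
  evaluated at most once per seed; a failed candidate is not revisited. This
  guarantees termination and matches the component characterization above.
- **Seed counting**: k excludes the seed by default; `count_includes_seed`
  shifts every value by exactly +1 (tested as such).
- **Zero-variance voxels** are removed from the analysis mask up front (with
  a logged count); they can neither seed nor join clusters.
- Correlations are computed on demeaned, unit-norm series; the moment
  normalization (1/T vs 1/(T−1)) cancels in r.

## Temporal preprocessing

The chain is fixed: discard the first `discard_volumes` frames (default 5,
scanner equilibration at TR = 2 s), then per-voxel linear detrend plus an
ideal DFT band-pass, then global-signal regression.

- **Band-pass (0.01–0.08 Hz default)**: real-FFT coefficients with frequency
  inside the closed band are retained, all others zeroed. The ideal spectral
  mask is parameter-free and exactly reproducible, and it is an orthogonal
  projection: re-applying it changes nothing (the only non-idempotent part of
  the chain is the detrend's small edge effect, < 5% relative at T ≈ 250). No
  padding is used; the detrend mitigates edge leakage. DC is outside any band
  with low > 0, so filtered series are mean-free.
- **Global-signal regression**: the mask-average series g(t) is removed from
  each in-mask voxel by OLS on [intercept, g]. "Mean signal removal" admits
  two readings (global regression vs per-voxel demeaning); the package
  implements global regression as the default and `none` as the alternative —
  per-voxel demeaning already falls out of the band-pass. If g is constant
  the regression degenerates to demeaning, with a warning.
- Out-of-mask voxels pass through all stages untouched and never enter any
  statistic (including g).

## Map post-processing

Each subject's count map is divided by its in-mask mean (mask-mean exactly 1
afterwards) and then smoothed — in that order. Smoothing is Gaussian with
σ_vox = FWHM / (2√(2 ln 2) · voxel size) per axis (default FWHM 8 mm ≈
σ 1.13 voxels at 3 mm), with **mask-renormalized weights**: numerator and
denominator are both convolved (`G(map·mask)/G(mask)`), so uniform fields are
fixed points and the brain boundary is not attenuated. This differs from
zero-padded convolution; comparison tools must match it.

## Cohort inference

- **Group contrast**: voxelwise two-sample Student t with pooled variance,
  oriented expert ("top") minus comparison ("lower"); two-sided p with
  n1+n2−2 df. Pooled rather than Welch, the convention of the era's
  neuroimaging software; Welch could be added behind the same surface.
  Zero-pooled-variance voxels get t = 0, p = 1 (counted and logged).
- **Covariate correlation**: voxelwise Pearson r between subjects' lFCD and
  the expertise score ("rank level"), typically within the expert subset;
  two-sided p via t = r√((n−2)/(1−r²)) with n−2 df.
- **Multiplicity**: Benjamini–Hochberg step-up over the in-mask voxelwise
  p-values at q = 0.05 (delegated to statsmodels; verified against a direct
  step-up enumeration), then a cluster-extent filter keeping components with
  **strictly more than** `min_cluster_voxels` voxels (default 20) under
  26-connectivity.
- **Signed clustering**: components are formed separately on
  positive-statistic and negative-statistic significant voxels. Increased and
  decreased connectivity are distinct findings; merging a touching
  positive/negative pair into one "cluster" would make its extent and peak
  meaningless.
- **Reporting**: per cluster — extent, peak statistic (max |value|, ties to
  the smallest linear index for determinism), peak world-mm coordinate via
  the image affine, and optional atlas labels ordered by overlap count. No
  atlas ships with the package; any integer-labelled NIfTI plus a two-column
  TSV of names works.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes: 4D
volumes whose local temporal coupling is elevated in planted spherical hubs,
differs between groups, and scales with a per-subject covariate. Per subject:

    x_v(t) = g·G(t) + c·L_h(t) + sqrt(1 − g² − c²)·ε_v(t)   (hub voxel)
    x_v(t) = g·G(t) + sqrt(1 − g²)·ε_v(t)                    (elsewhere)

with L_h a per-hub, per-subject band-limited (0.01–0.08 Hz) unit-variance
latent, G an equally band-limited brain-wide signal with amplitude g = 0.3,
and ε_v unit-variance AR(1) noise (lag-1 autocorrelation 0.3) with a small
spatial point-spread (Gaussian, FWHM 1.4 voxels, periodic and
variance-renormalized). All series are unit variance by construction; with
g = 0 two hub voxels with couplings c_i, c_j correlate at c_i·c_j in
expectation, which the tests check against Monte-Carlo.

Two realism terms deserve justification because the analysis *fails* without
them, for reasons that are instructive about real data:

- **Global signal (g = 0.3)**: global-signal regression removes the
  mask-average series. On a small simulated brain with purely voxel-specific
  noise, that average is dominated by the planted hub latent itself, and the
  regression cancels the coupling being planted. Real global signal is
  carried by the whole mask (respiration, vasomotion); simulating it restores
  the regression's intended behaviour (it removes G and barely touches L).
- **Spatial noise correlation (FWHM 1.4 voxels ≈ 4.2 mm at 3 mm voxels, the
  scale of EPI point-spread)**: with spatially independent noise, background
  lFCD is exactly zero for nearly every voxel of every subject; the 8 mm
  smoothing then manufactures shells of near-zero-variance voxels around any
  hub, which produce arbitrarily large t values. A weak point-spread gives
  the map the positive noise floor real data has.

**Coupling model**: c = clamp(base + group_effect·[group = top] +
slope·z, 0, √(1−g²)), where z is the subject's rank level standardized
*within its group's* sampling range (top: uniform 70–95; lower: uniform
35–60, on a fixed 0–100 scale). Within-group standardization makes the
covariate term mean-zero inside each group, so the group contrast is
governed by `group_effect` alone and the slope creates the within-group
lFCD–rank association that the correlation analysis is meant to detect. (A
slope applied to a cohort-wide z would confound the two effects and, at the
default effect sizes, push every expert subject's coupling into the clamp.)

**What the generator does not emulate**: head motion, physiological spikes
and drifts beyond AR(1)+global, anatomical geometry and tissue boundaries,
distance-dependent connectivity fall-off, multiple interacting networks, and
between-subject anatomical variability. Passing recovery tests therefore
shows the pipeline is correct and sensitive under its own assumptions — not
that those assumptions hold in any particular dataset.

## Problem sizes used in the recovery experiments

- **Effect recovery**: 16³ grid of 3 mm voxels, one central hub of radius 3
  (123 voxels), 26 + 34 subjects, 255 volumes at TR 2 s, base coupling 0.45,
  group effect 0.3 (covariate slope 0.3 for the correlation run). Scored as
  the best Dice overlap of any surviving positive cluster with the
  ground-truth hub dilated by one voxel; the acceptance bound is Dice > 0.3
  in ≥ 8/10 replicates (correlation: hub intersection in ≥ 7/10). Typical
  observed Dice ≈ 0.9.
- **Null calibration**: 12³ grid, 120 volumes, 8 + 8 subjects, hub present at
  base coupling 0.45 in both groups with zero effects; 200 replicates; the
  fraction with any surviving cluster must stay ≤ 10%. Observed ≈ 0.
  The cohort is scaled down from the study size to keep 200 full-pipeline
  replicates cheap; FDR validity does not depend on n.

## Numerical and degenerate-input conventions

- Affine grid equality uses absolute tolerance 1e-4 per entry (absorbs
  float32 header round-trips without hiding misregistration). Masks binarize
  at value > 0. Voxel indices are 0-based; world coordinates come from the
  affine (NIfTI convention).
- An all-zero count map cannot be normalized (error advising a threshold /
  connectivity review). fwhm = 0 smoothing is the identity.
- Cluster labels are assigned 1..C by descending size (ties by scan order);
  report rows are written by descending extent, ties by cluster id; floats
  print with 4 significant digits.
- All simulation randomness derives from `numpy.random.default_rng` seeded
  with (design seed, subject seed); identical seeds give bit-identical
  cohorts, and the whole pipeline is deterministic — NIfTI and TSV outputs
  are byte-identical across reruns.

## Known limitations

- The search evaluates each seed independently; runtime grows with cluster
  size and is vectorized per frontier, which is ample for the grid sizes
  here but would benefit from a compiled kernel at full-brain resolution
  with dense hubs.
- Per-map mean normalization couples hub strength to background scaling:
  when a large fraction of total lFCD mass sits in a strong hub, normalized
  background values shift in the opposite direction, producing genuine (but
  easily misread) negative group differences outside the hub. This is a
  property of the published normalization itself; the signed cluster reports
  keep the two effects separate.
- Global FCD (long-range connection counts) and other four-dimensional local
  consistency measures are out of scope.
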