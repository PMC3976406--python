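# Methods

## The design and what is being estimated

The package targets repeated-measures resting-state fMRI studies in which
each of S subjects is scanned five times — morning and evening of a free day
(`FD-T1`, `FD-T3`) and morning, midday and evening of a mentally fatiguing
working day (`WD-T1`, `WD-T2`, `WD-T3`). The scientific quantity is a
regional, condition-dependent change in the amplitude of a resting-state
network's spontaneous BOLD fluctuations, expressed in the spatial z-scores
of single-subject ICA component maps: a gain > 1 in the most exhausted
condition is an *enhancement*, a gain < 1 a *suppression*.

## Synthetic studies

Because such datasets are rarely deposited, the generator is a first-class
module. One scan is

    data(t, v) = Σ_k a_k · g_k(v) · w_k(v) · s_k(t) + drift + physio + ε

- `w_k`: nonnegative network weight maps — Gaussian-smoothed spherical blobs
  (default FWHM 6 mm) with pairwise-disjoint core masks; supports may
  overlap, as real RSNs do.
- `s_k`: network time courses — white Gaussian series FFT-brick-wall
  band-passed to 0.01–0.1 Hz (the canonical resting-state band at TR = 2 s)
  and then mutually orthogonalized (QR; linear combinations stay
  band-limited) and scaled to unit SD. Orthogonalization makes every voxel's
  noise-free temporal SD exactly `sqrt(Σ_k (a_k g_k w_k)²)`, so planted
  gains are analytically verifiable and null studies are exactly
  exchangeable across condition labels.
- `g_k(v)`: the planted gain field — 1 everywhere except inside an effect's
  target region (default: the network's core) for the conditions named in
  its schedule. The default pattern plants the full gain at WD-T3 and the
  geometric midpoint at WD-T2, emulating progressive exhaustion.
- drift: first/second Legendre polynomials with smooth random spatial
  weights (amplitude 0.2); physio: cardiac (~1 Hz) and respiratory
  (~0.3 Hz) sinusoids aliased at the TR, harmonics 1–2, with smooth spatial
  weights (amplitude 0.3) — exactly removable by the order-2 RETROICOR
  regressors built from the returned phase series; ε: white Gaussian noise,
  default SD 0.5 per unit network amplitude (moderate single-voxel SNR).
- Between-subject variability: each subject's maps are rigidly shifted by a
  seeded sub-voxel translation (≤ 1 voxel) and network amplitudes are
  perturbed log-normally (CV ≈ 0.1). Truth regions stay at the group
  location — jitter models residual misregistration after normalization.
- Behavior: pooled exhaustion = subject baseline (VAS ≈ 60 ± 10) +
  80 · mean|gain − 1| + N(0, 8), split into a tiredness rating and a
  reversed restedness rating. The coupling is linear in the planted
  modulation so the final ANCOVA has a recoverable signal.
- Motion traces are small random walks (never near the 4 mm gate); motion
  *image artifacts* are out of scope, as are hemodynamic modeling and
  scanner drift beyond low-order polynomials.

Everything is reproducible bit-exactly from one integer seed; per-scan
generators are spawned as `SeedSequence([seed, subject_index,
condition_index])`, so any single scan can be regenerated in isolation.

What passing tests on these surrogates do **not** show: robustness to real
motion artifacts, to hemodynamic variability, to non-Gaussian or spatially
structured noise, or to registration errors beyond one voxel.

## Preprocessing

High-pass filtering projects out a drift basis of the constant plus
cosine/sine pairs at 1..⌊c⌋ whole-course cycles (default c = 2). A Fourier
pair basis was chosen over a DCT because "remove up to c cycles per
time-course" is then exact: an integer-cycle sampled cosine of any phase
lies in the span, while out-of-band sinusoids are untouched. The operation
is an idempotent projection; order is fixed as high-pass → nuisance
regression (flag to flip). Nuisance regression residualizes each voxel on
[intercept | motion | RETROICOR order 2 | extras] and rejects rank-deficient
designs naming the offending columns. The motion gate excludes a scan when
peak absolute translation strictly exceeds 4 mm; rotations are logged, not
gating (the conventional summary when only a millimeter criterion is
stated).

## Decomposition

Spatial ICA runs per scan, never concatenated. FastICA (deflation scheme,
logcosh contrast, tol 1e-4) unmixes the voxels-as-samples orientation, so
sources are spatial maps and the mixing matrix holds time courses. The
deflation scheme is used because trailing components of a K-dimensional
reduction are near-Gaussian and the parallel update then cycles without
converging; deflation extracts sources one at a time and converges
reliably. Up to 5 seeded restarts precede failure. Conventions (the
decomposition is otherwise sign- and order-ambiguous): maps z-scored over
the brain mask, positive spatial skewness per map, ordering by descending
explained variance (‖course‖²·‖map‖²). K defaults to ⌈T/6⌉ — at least one
sixth of the time points, the standard rule of thumb (180 volumes → 30).
The PCA retained-variance diagnostic is logged; it reaches 99%+ only when
thermal noise is low, since white noise is full-rank by construction.

## Grouping

Group networks are formed by constrained clustering: exactly one component
per contributing set per cluster. The published self-organizing group-ICA
algorithm lives in external tooling whose objective, metric and tie-breaks
are not fully specified; the implementation here is a deterministic
stand-in honoring the stated constraints. Similarity is absolute spatial
Pearson correlation only — scans are separate sessions, so time courses are
not comparable, and the ICA sign is arbitrary. Clusters are seeded with the
first set's components (sets processed in sorted subject/day/timepoint
order); each subsequent set is matched one-to-one to the running centroids
by solving the linear assignment problem (maximum summed similarity, ties
to the lowest component index); centroids are the re-z-scored means of
member maps, updated after each set. On well-separated instances this
greedy scheme attains the exhaustive optimum (verified on 3×3 instances).
The hierarchy: level 1 matches each subject's FD-T1/WD-T1 baseline sets and
averages matched pairs (re-z-scored) into one representative set per
subject; level 2 clusters the representatives across subjects. Exhausted
scans are rejected at the door — templates cannot be biased by the
conditions later tested.

## Templates and component selection

Each cluster yields a one-sample t-map across its member maps (df = S − 1;
zero-variance voxels capped at ±1e6 and flagged). The template mask keeps
voxels with one-tailed positive t above the Bonferroni threshold at
P = 0.05 over brain voxels — one-tailed because network membership is
positive engagement; Bonferroni because the corrected voxel-level procedure
is otherwise unspecified and it is the conservative default. Goodness of
fit of a component map to a template is mean z inside the mask minus mean z
outside (outside = brain minus mask), the standard template-matching score;
the best-fitting component per subject per scan is the GOF argmax (ties to
the lowest index). Network labels come from spatial matching against
reference maps — generator truth for synthetic data, user-supplied masks
for real data; no anatomical naming is attempted.

## Inference

The day × time-point repeated-measures question is tested through a single
combined contrast, by default 3·WD-T3 − WD-T1 − FD-T1 − FD-T3 (WD-T2 never
enters the contrast; it only feeds the regional score table and plots). For
one within-subject contrast, the ANOVA F reduces to a one-sample t on the
per-subject contrast scores, which is how it is computed (df = S − 1,
two-tailed, since both signs are of interest). Subject-specific constant
maps cancel exactly; floating-point residue of the zero-sum weights is
floored so identical inputs give exactly t = 0.

Cluster-extent correction simulates null Gaussian fields inside the brain
mask at the observed map's estimated smoothness, thresholds two-tailed at
the voxel p, and returns the smallest cluster size k whose null exceedance
probability is below alpha (default 500 iterations; the familywise level is
alpha/N for N networks tested). The null-threshold simulation clusters the
full two-tailed exceedance set; cluster *extraction* on the real map labels
positive and negative exceedances separately (6-connectivity), since
enhancements and suppressions are reported as distinct regions. Smoothness
is estimated from the variance of first spatial differences:
σ = Δ·sqrt(var(map)/(2·var(diff))) per axis, FWHM = 2.3548σ averaged over
axes (≈ 1.18 voxels on white noise), with a manual override flag. Cluster
reports give the |t|-weighted center of mass in mm, extension in mm³
(voxels × 27 at 3 mm), average t and signed peak t.

Regional scores are the mean best-fit z over a surviving cluster's voxels
for WD-T2 and WD-T3; the ANCOVA fits score ~ intercept + scan + VAS +
scan:VAS by OLS and reports partial F tests — the interaction against the
additive model, and the covariate against the scan-only model (testing the
covariate *with* the interaction present would let the interaction absorb
its main effect). P-values are uncorrected, as the regional analyses are
exploratory.

## Behavior

Pooled exhaustion = (tired + (150 − rested))/2, computed on the raw scales
before any standardization (the scales are pooled first, then standardized,
matching the order in which the ratings are described; a flag could invert
this). Z-standardization is per participant with the sample SD (n − 1);
constant ratings raise an error flagging the participant for exclusion.
The 2×2 ANOVA (day × time-of-day, T1/T3 only) is the balanced fixed-effects
decomposition on the standardized scores — per-participant standardization
has already removed subject means, which is what gives the design its
power. Simple main effects use the pooled error term; each family of two
comparisons is Bonferroni-adjusted (p × 2, capped at 1). The effort-rating
(RSME) GLMs with a day-order covariate and the negative-binomial error-count
model are deliberately out of scope — routine off-the-shelf fits; the
columns pass through the behavior table untouched.

## Numerical conventions

- Zero-variance t statistics are capped at ±1e6 and flagged rather than
  raised, so degenerate synthetic inputs flow through inference.
- Sums of squares below 1e-12 × total SS count as exact zeros in partial-F
  tests (noiseless inputs otherwise produce 0/0 artifacts).
- All assignment/labeling tie-breaks resolve to the lowest index; cluster
  labels are canonical (seeded by the sorted-first component set), making
  grouping invariant to input order.
- Problem sizes in the validation suite: 24×24×16 grid (≈ 3000 brain
  voxels), 8 subjects, 120 volumes for full-pipeline runs and 180 where the
  component-count rule is exercised; Monte-Carlo iterations 500 (200 in the
  40-study null-calibration batch). These sizes keep the whole suite
  routinely re-runnable while leaving every statistic's sampling behavior
  intact.

## Known limitations

- The grouping objective is a documented stand-in for the published
  self-organizing group-ICA plug-in, not a reproduction of its internals.
- The Monte-Carlo null assumes a stationary Gaussian random field at a
  single scalar smoothness; heavy spatial nonstationarity would miscalibrate
  the cluster threshold.
- Phase series for RETROICOR must be supplied (the generator emits them);
  estimating phases from raw pulse/respiration waveforms is not implemented.
- Real-data use assumes spatially aligned inputs on a common grid; no
  motion estimation, slice-timing, smoothing or normalization is performed.
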