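# Methods

This note documents the models, parameter choices and numerical decisions
behind `phaselink`, and what the synthetic test bed does and does not
establish about real data.

## Synthetic experiment

The generator emulates a cued bimanual motor-state transition experiment.

**Paradigm schedule.** A trial is start cue → transition cue → pause.
Scheduling is probabilistic: the transition cue is a switch with
probability 5/6 (continuation:switching ≈ 1:5), every non-pause cue slot is
replaced by a thumb reaction-time probe with probability 0.05 (per-event
Bernoulli; the design states the rates, not the mechanism, so independent
Bernoulli draws are the simplest mechanism consistent with them), pauses
last 3000 ms, a probe is always followed by a pause 1000 ms later, and cue
onsets are jittered uniformly within a 5000–8000 ms inter-stimulus
interval. Trial counts per block vary in practice, so the session length is
a plain configuration parameter rather than a block scheduler.

**Tap streams.** Beats are paced at the subject's tapping frequency
(default 1.6 Hz, a typical individually adjusted rate); after a switch cue
the pattern changes after a gamma-distributed latency (shape 9,
scale 60 ms → mean 540 ms, matching the order of observed transition
latencies), with the first post-latency pair placed exactly at
cue + latency so noise-free streams round-trip the latency through the
scorer. Error injection operates at three levels: per-pair pattern flips,
whole-trial failures, and an always-wrong mode for plumbing tests.

**Sources.** Three labelled sources (left/right sensorimotor, occipital)
at 250 Hz, epoched ±2.5 s around the transition cue. The left source
carries a band-limited cosine at the band's geometric-mean frequency with a
random per-trial phase; the right source carries the same oscillation
shifted by a per-trial lag drawn from a von Mises distribution
(mean `mean_lag_rad`, concentration κ; κ = 0 degrades to uniform lags =
no coupling). The lag may step at the transition (optionally with a
different pre-transition concentration) to emulate peri-transition coupling
modulation. The occipital source is independent unless explicitly coupled.
All sources ride on 1/f-plus-white noise (80/20 power split) — the
standard EEG background surrogate; no forward model, volume conduction or
source leakage is simulated, so tests passing here do not speak to
leakage-induced spurious connectivity in real source-projected EEG.

**Cohorts.** Subject tables are drawn exactly from the moderated-mediation
process (outcome and mediator regressions below) with exGaussian residuals,
plus group-structured GABA+ (sensorimotor offset between age groups,
occipital shared) and Dirichlet-distributed voxel tissue fractions around a
sensorimotor mix (fGM/fWM/fCSF ≈ 0.38/0.47/0.15). All randomness is keyed
by (seed, subject, trial), so any slice of a dataset regenerates
bit-identically.

## Spectral decomposition

Complex Morlet wavelets are specified by the temporal FWHM of their
Gaussian taper, exp(−4 ln 2 · t²/FWHM²): 50 log-spaced center frequencies
from 2 to 40 Hz, FWHM interpolated linearly in log-frequency from 400 ms
at 2 Hz to 104 ms at 40 Hz (only the endpoints are prescribed; log-linear
interpolation matches the log-spaced frequency grid). Kernels are
odd-length (6×FWHM + 1 samples) and normalized to unit spectral peak gain,
which makes narrowband amplitudes comparable across frequencies; for
broadband signals expected power then scales with kernel bandwidth (the
white-noise test asserts the Parseval identity E|x∗k|² = σ²Σ|k|² rather
than raw flatness). Samples within half a kernel of an epoch border are
masked; the ±2.5 s epoch padding exists to keep the analysis windows clear
of this region at the frequencies used for inference. Decomposition runs at
250 Hz; connectivity uses every 5th sample (50 Hz grid).

## Connectivity

ISPC clusters the phase-angle differences over *trials* at each
time-frequency point. The printed formula sums over time points; a
time-resolved trial-clustered map is required for cluster inference over
time × frequency, so trials are the default clustering dimension and
`ispc_over_time` provides the literal over-time reading (full-epoch or
sliding window). Baseline correction subtracts the per-frequency mean over
−500…−200 ms. Response-locking re-windows each trial to ±260 ms around the
per-transition-mode median latency (median of an even count = midpoint of
the central pair, applied uniformly). Band pooling of single-trial lags
uses the circular mean — arithmetic averaging of wrapped angles is wrong at
the ±π boundary (bins at +170° and −170° must pool to 180°, not 0°). The
baseline control lag is taken at start cue − 300 ms, fixed rather than
re-randomized, for reproducibility.

## Cluster inference

Within-subject z: each trial contributes its time-of-interest phase-lag
series and one randomly drawn baseline time point; the observed
TOI − baseline ISPC difference is standardized against a null that
exchanges the two assignments per trial (the permutable unit is the trial —
the natural exchangeable unit when no trial structure is assumed). Cells
with zero permutation SD are masked, not silently zeroed.

Group level: two-tailed t maps thresholded at the cluster-forming alpha
(0.05 two-tailed by default; cluster-forming and cluster-level alphas are
separate configuration knobs), 4-connected clusters, cluster **mass** (sum
of t) as the default statistic with extent as an option — mass is generally
more sensitive to distributed effects, and the choice is recorded in the
serialized result. The null is the distribution of the maximum cluster
statistic over both signs under sign flips (one-sample) or group-label
permutation (between groups), with p = (b+1)/(m+1) so p is never exactly
zero. Under a 20-subject Gaussian null on a 35×60 grid the realized
family-wise error rate is statistically compatible with 0.05 (slight
conservatism from the max-over-signs null and the +1 correction is
expected).

## Circular statistics

Rayleigh (z = n·R̄², small-sample-corrected p) and Mardia's circular-linear
correlation are delegated to pingouin and verified in the test suite
against Monte-Carlo/permutation oracles. The circular mean's confidence arc
uses the large-sample dispersion estimate (half-arc = asin(z·σ̂),
σ̂² = (1−ρ̂₂)/(2nR̄²)) and is declared undefined when the resultant is too
weak for the formula. The two-way circular ANOVA follows the
Harrison–Kanji decomposition of resultant lengths with automatic branch
choice by the pooled concentration estimate: concentrated samples (κ̂ > 2)
use F-ratios with the high-concentration correction 1/(1−1/(5κ)−1/(10κ²));
dispersed samples use the chi-square approximation with doubled degrees of
freedom. The branch and κ̂ are reported with every table; degrees of
freedom follow this implementation's conventions. Both branches are
calibrated by simulation in the test suite. GABA+ dichotomization splits at
the within-age-group median with ties going to "low" (deterministic). The
FDR family is all subgroup × band × condition tests of one analysis run
(Benjamini–Hochberg).

## Moderated mediation

Outcome and mediator models (identity links on μ, σ and the exponential
tail β of the exGaussian) share no parameters, so sampling them separately
yields the exact joint posterior. Uniform priors default to ±50 on
coefficients and (0, 50] on scales — effectively flat for standardized
inputs, recorded in the model spec. All input variables must be centered;
the fit refuses non-centered data rather than silently centering, since the
conditional effects are interpreted relative to group means.

The sampler is an affine-invariant ensemble (emcee) with
differential-evolution moves, run as four independent ensembles
("chains"); defaults are 10,000 iterations with 1000 discarded as burn-in.
Walkers start near the least-squares solution with small jitter. R-hat is
computed across the four ensembles (step-major, so split-R-hat compares
early vs late steps) and effective sample size treats each walker as a
chain so autocorrelation along steps is honestly counted; fits failing
R-hat < 1.01 or ESS > 400 are flagged, never silently accepted. The
exGaussian log-density uses the scaled complementary error function and is
stable to the Gaussian limit β → 0 (verified against scipy's exponnorm).

Conditional effects are evaluated as posterior draws at the 20th/80th
percentiles of the observed moderator (and mediator) — the lowest/highest
sample quintile boundaries. pd = 100·max(P(>0), P(<0)); the HDI is the
shortest sorted-sample window containing the requested mass (cross-checked
against arviz). Two statistical facts the tests encode deliberately:
under a true null the pd is uniform-equivalent (mean ≈ 75, not ≈ 50), and
the "deterministic limit" of the mediation model pins down only the
outcome-model paths — when both residual scales shrink together the
mediator column becomes collinear with X and the mediator-path posterior
width does not vanish.

## GABA+ preparation

Tissue correction assumes GABA+ negligible in CSF and a WM:GM ratio of 0.5
(α-correction), weighting the water reference by per-compartment effective
visibility/relaxation coefficients shipped as an editable constants table
(defaults w_GM = 0.78, w_WM = 0.65, w_CSF = 0.97; the exact scanner
calibration constants are site-specific, so results reproduce the formula's
structure, not any particular institutional-unit scale). Group
normalization divides by the correction factor evaluated at the group-mean
tissue fractions, computed after removing subjects beyond ±3 SD within
group — a pure per-group rescale, so it is the identity for homogeneous
groups, leaves a subject at the group-mean composition on the raw scale,
and cannot introduce composition artifacts. Manual quality exclusions are
boolean flags in the cohort table, not automated rules.

## Pipeline scale and reproducibility

The packaged demo runs 12 + 12 subjects with 60 trials each, 100
within-subject and 500 group-level permutations, and 4 × 800 mediation
iterations — sizes chosen so a full end-to-end run finishes in well under a
minute while every stage still operates above its statistical
preconditions; analysis-scale values (1000 permutations, 4 × 10,000
iterations) are the configuration defaults of the individual modules.
Identical config + seed reproduce every result table byte-for-byte (fixed
float formatting, seeded permutations and MCMC); each table embeds the
config hash.

## Known limitations

- No scalp-level simulation, forward modelling, or leakage correction:
  zero-lag spurious coupling from volume conduction is out of scope.
- The synthetic oscillation is a constant-frequency cosine per trial; real
  beta bursts are non-stationary, so wavelet bandwidth interactions with
  burstiness are untested.
- The circular ANOVA's chi-square branch is an approximation whose
  calibration is verified only at the simulated sample sizes (n ≈ 80–100
  per analysis cell).
- The mediation model is associational; no causal identification machinery
  is included.
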