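# Methods

## Model

`phistress` analyses a multichannel recording as a single lagged Gaussian
system.  For a node set S (default Fz, Cz, Pz, ECG, EDA), each analysis
window supplies second-order statistics of the pair (X(t−τ), X(t)): the
past and present covariances and their lag-τ cross-covariance
(`LaggedGaussianModel`).  All information quantities are functionals of
these matrices; the analysis is therefore blind to waveform morphology and
sensitive only to (lagged) second-order dependence.  That is an assumption,
not a convenience: channels are treated as jointly Gaussian within a
window, and windows are treated as locally stationary.

### Mismatched decoding and Φ*

The decoder induced by a bipartition π = {A, B} factorizes the predictive
model across the parts: q(y|x) = N(y_A; A_A x_A, Γ_A) · N(y_B; A_B x_B, Γ_B),
with A_P and Γ_P the part-restricted regression and conditional covariance.
The information transmitted under this decoder at decoding exponent β is

    Ĩ(β) = β·E[ln q(y|x)] − E[ ln ∫ p(x′) q(y|x′)^β dx′ ]

which for Gaussians reduces to the closed form (x past, y present,
Sx/Sy covariances, A′/Γ the block regression/conditional matrices,
R = E[(y−A′x)(y−A′x)ᵀ], P = Sx⁻¹ + βA′ᵀΓ⁻¹A′,
Q = βΓ⁻¹ − β²Γ⁻¹A′P⁻¹A′ᵀΓ⁻¹):

    Ĩ(β) = −(β/2)·tr(Γ⁻¹R) + ½ln det Sx + ½ln det P + ½tr(Q·Sy)

At the matched decoder and β = 1 this equals the mutual information I; at
β = 0 it vanishes.  Φ*(π) = I − max_β Ĩ(β).  This closed form was derived
directly from the defining expectations above and is gated in the test
suite on an independent Monte-Carlo estimator that *samples* those
expectations (nested sampling of the normalizer included), rather than on
any reprinted formula: the analytic and sampled Φ* agree within
max(5%, 0.01 nats) across random 2- and 3-node systems.

β is maximized on [0, 10] by a vectorized grid search with four refinement
passes (final β resolution ≈ 3·10⁻⁶); a grid is preferred over a
derivative-based or golden-section search because Ĩ(β) is cheap to evaluate
after a spectral reduction (an eigendecomposition turns each evaluation
into an O(n) expression) and the grid is robust if the profile is not
unimodal.  The empirical maximizer sits near β ≈ 1 for weakly mismatched
decoders; nothing in the data ever pushed β* near the upper bound, and the
bound is configurable.

Units are nats throughout.  z-scoring of log Φ is invariant to the
information base (an affine change of log Φ), so this is presentation-only.

Numerical conventions:

- Φ* values in (−10⁻⁹·max(|I|, 1), 0) are clamped to 0 (round-off); more
  negative values raise an error rather than pass silently.
- Covariances are checked by Cholesky factorization *and* a conditioning
  gate (smallest/largest eigenvalue < 10⁻¹²) at estimation time — an
  exactly constant channel acquires a ~10⁻²⁸ variance in floating point and
  would otherwise slip through.  Degenerate windows are flagged and
  excluded, never silently dropped.
- An optional ridge (`ridge × mean diagonal`) can stabilize near-singular
  windows; it is off by default and logged wherever a caller enables it.
- MIP ties (exactly exchangeable systems) are broken canonically: the first
  partition in the documented enumeration order (anchor node with
  lexicographically ordered companions, increasing part size) wins, with a
  10⁻⁹ relative tie tolerance.

### MIP, complexes, main complexes

The MIP search is exhaustive over the 2^(|S|−1) − 1 bipartitions; for the
5-node study system that is 15 partitions and entirely tractable.  Φ_MIP is
*not* normalized by partition entropy — raw Φ* is minimized.  An
entropy-normalized variant exists in some integrated-information toolboxes;
it is deliberately not implemented here because no stage of this analysis
uses it and it would change which cut is called minimal.

A complex is a subsystem whose Φ_MIP strictly exceeds that of every strict
superset; a main complex additionally strictly exceeds every strict subset
of size ≥ 2.  Singletons are excluded (Φ of one node is undefined under
bipartition).  Strict inequalities are used in both definitions; ties are
measure-zero for continuous data.

Theory predicts two main complexes never overlap.  Under the strict local-
maximum definition this is *not* a theorem — the map φ(ab)=5, φ(ac)=4,
φ(abc)=1, φ(bc)=0.5 has two overlapping main complexes — and windowed
estimates do produce more than two main complexes, which five nodes cannot
accommodate disjointly.  `find_main_complexes` therefore takes
`on_overlap="keep"` (default, used by the pipeline) or `"raise"` to enforce
exclusivity where the caller wants the prediction checked.

### Windowed pipeline

Recordings are cut into windows of Td frames shifted by 500 frames (study
profile: Td ∈ {1000, 2000, 3000} at 500 frames/s).  Head windows are
left-padded with zeros so the series starts at the first shift; exactly
Td/shift − 1 head windows actually contain padding and are flagged (and
excluded from baseline statistics by default).  The lag τ is chosen by
maximizing mean Φ_MIP over a documented τ grid across recordings; a profile
whose spread is within ~2 standard errors of the window means is reported
as flat (no meaningful lag — e.g. white noise).  τ = 0 is degenerate by
construction (past and present coincide, the joint covariance is singular)
and is skipped with a flag if included in a grid.

Per window the pipeline records the full-system Φ_MIP and cut, Φ_MIP of all
26 subsystems, and the main complexes.  log Φ is z-scored per recording
against a pre-task baseline: all windows fully inside the pre-task phase,
minus padded windows, minus a guard of `guard_windows` windows at the phase
boundary (default 10 at study scale; reduced-profile runs use 2 because the
1:10 pre-task phase holds only ~11 windows).  An explicit 1-based window
range override is available.  Baseline mean/sd use ddof = 1 and the
baseline windows standardize exactly (mean 0 / sd 1 to 10⁻¹²).  Windows
with nonpositive Φ are missing for that quantity, never logged at −∞.

Σz(log Φ) and max z(log Φ) are per-window aggregates over that window's own
main complexes.  Frequency shifts compare the within-phase relative
frequency of a label (MIP cut, or argmax main complex) between pre-task and
task.  Periodic protocol disturbances are *not* filtered (an optional
artifact generator plants them; no masking is applied by default),
mirroring the analysis-on-raw-data stance of the study design.

### Rank-pattern test

Each participant contributes one pattern: the descending ordering of their
per-condition task-mean Σz(log Φ).  Pattern counts over participants are
tested against uniformity over the k! orderings with a Pearson χ² whose
null distribution is simulated by Monte-Carlo multinomial draws (default
10⁷ at study scale; 10⁵ in tests), p = (1 + #{χ²_sim ≥ χ²_obs})/(1 + n_mc).
Exact ties drop the participant (measure-zero for continuous data).  The
reported χ² behaves like a df = 5 Pearson statistic for three conditions.
Pooled per-window pattern frequencies are also reported as a diagnostic.
Under the uniform null the test's attainable size at α = 0.05 is ~0.04
(the multinomial(18) χ² is discrete), verified by calibration.

### Feeling scores and ratings

Ratings are VAS values in [0, 100] per participant × condition × phase ×
item.  r = Task − Pre per item; dr = r_X − r_Moderate (baseline condition
configurable).  The feeling score s_i^X sums, over task windows, the
difference between condition X's and the baseline condition's Σz(log Φ).
The inner sum runs over each condition's *own* main complexes at each
window: main-complex sets generally differ across conditions, so no
cross-condition matching of subsets is well defined, and this reading makes
s_i exactly the windowed difference of the Σz series.  Windows missing in
either series are skipped and counted; more than 50% skipped is a
reliability error.  A recording whose baseline has more than 10% degenerate
windows is excluded from cohort analyses (threshold configurable),
generalizing the study's by-hand participant exclusion.  Correlations are
Pearson r with t = r√((n−2)/(1−r²)) and two-sided p.

Conventional per-150-s binned means (z-scored against the pre-task period)
are provided for already-derived scalar series (heart rate etc.); R-peak
detection and group-test machinery are deliberately out of scope.

## Synthetic data

The generator emulates the study's design at the level the analysis
consumes: 5 channels, three phases (pre-task 0–600 s, task 600–2400 s,
post-task 2400–3300 s at 500 frames/s by default), per-phase stationary
VAR(1) dynamics with the off-diagonal coupling scaled per condition during
the task (defaults: Easy ×1.5, Difficult ×1.3, Moderate ×1.0 — the
condition ordering the pipeline is expected to resolve), innovation noise
mildly correlated within the EEG block (exercising Φ*'s sensitivity to
correlated noise), optional square artifact pulses every 500 s, and ≥10
autocorrelation times of burn-in at each phase switch.  Stationary
covariances solve the discrete Lyapunov equation Σ = AΣAᵀ + Q, so exact
Φ*/MIP/main-complex ground truth is available for every phase and condition
(`ground_truth`).

Cohorts add a per-participant latent u_i ~ N(0,1) with weight 0.2 on the
Easy-task coupling (individual differences large enough to dominate
estimation noise in s_i) plus 0.04 condition-level jitter, and plant a
rating coupling: the Boring item's Easy-task value loads on u_i with
population correlation 0.6 (scale 20 VAS points, other cells 50 ± 2).
Ratings are clipped to [0, 100] with a warning if clipping exceeds 20%.

The reduced test profile — 50 fps, 60/180/90 s phases (1:10), 10 s windows
with 5 s shift, baseline guard 2 — is the problem size used by the test
suite and the acceptance script; the full study profile is one constructor
call away and differs only in scale.  What passing tests show: the
estimators recover planted second-order structure, orderings and couplings
at these noise levels.  What they cannot show: robustness to non-Gaussian,
nonstationary or morphologically structured real signals, which the
generator deliberately does not model.

## Known limitations

- Gaussian, order-1 autoregressive surrogate dynamics only; higher-order or
  nonlinear dependence in real data is invisible to the lagged covariance
  and not exercised by the generator.
- Exhaustive MIP search scales as 2^(n−1); the implementation targets the
  5-node design and is not meant for large systems.
- The feeling score requires a baseline condition recorded in the same
  participant; nothing guarantees such a baseline exists outside a
  within-subject design.
- The rank-pattern χ² is discrete at small n; its attainable size at
  α = 0.05 is below the nominal level (~0.04 at n = 18).
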