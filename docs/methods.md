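# Methods

This note documents the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter.

## Motion model and MSD estimation

Motile particles are modelled as one-dimensional fractional Brownian motion
(fBm) along the tightrope with Hurst exponent H = α/2, so the ensemble MSD is
2D·t^α by construction and α = 1 reduces to ordinary Brownian motion. fBm was
chosen because it is the minimal stationary-increment Gaussian process with a
tunable MSD exponent; the observed α values (≈1.0–1.2) do not by themselves
identify a mechanism, and nothing downstream depends on the choice beyond the
MSD scaling. Sampling is exact: fractional Gaussian noise is drawn through a
Cholesky factor of its Toeplitz covariance (cached per trajectory length and
H, with a 1e-12 diagonal jitter for numerical positive-definiteness), and
H = 1/2 short-circuits to i.i.d. normals. Stationary particles are pure
localization noise about a fixed damage site.

The MSD uses every overlapping start index (the time-averaged estimator with
N − n displacement pairs at lag n). D comes from an OLS line over the first
25 % of lags; α from an OLS line in log–log coordinates over the same range.
The 25 % default balances the bias of including noisy large-lag points
against the variance of using too few; the ≥10 %-of-plot validity criterion
is evaluated against the full N − 1 available lags, and estimates with
R² < 0.8 are likewise flagged invalid rather than dropped silently.

Two known estimator properties worth stating:

* Per-trajectory log–log slopes carry a small negative (Jensen) bias,
  roughly −0.04 to −0.08 for 300-frame tracks, because log of a noisy MSD
  estimate is biased below the log of its mean. Cohort means therefore sit
  slightly below the generating α; this is a property of the standard
  estimator, not of the generator.
* The linear-model D on superdiffusive (α > 1) input is upward-biased;
  D-recovery statements in the tests use Brownian cohorts, and α-recovery
  uses fBm cohorts, so each estimator is evaluated on the data it models.

## Phase segmentation and motility calls

A frame is provisionally motile when the rolling standard deviation of
position over 10 frames exceeds 0.09 μm = 3× the default 0.03 μm
localization precision (typical for quantum-dot antibody labelling; this is
a configuration field, not a measured property of any instrument). Runs
shorter than a minimum phase length (default: the window) are absorbed into
their longer neighbour, and a particle is called motile iff it retains at
least one motile phase. With 10-frame windows the per-window false-positive
probability under pure 0.03 μm noise is ~1e-13, so stationary particles are
essentially never miscalled over a 3750-frame movie; sensitivity for motile
particles at D ≈ 1e-2 μm²/s relies on the length of the observation, and
short (tens of seconds) tracks can be missed. The defaults target the full
300 s window.

## Colocalization

A cross-channel pair is a candidate if its positions sit within 0.2 μm for
at least 10 concurrent frames; candidates are matched greedily, one-to-one,
by ascending mean close-frame distance, ties broken by lower particle id.
The reported fraction uses the union convention (a matched pair counts
once): n_coloc / (n_A + n_B − n_coloc). The generator's two-channel field
places co-bound pairs on a shared site with a ≤0.05 μm registration offset
and independent localization noise per channel, and is stationary by
default: the dual-colour experiment it emulates is a counting measurement,
and holding motion out of it isolates the counting statistic from
false-positive encounters between independently wandering particles. Callers
can set `motile_fraction` to study that regime explicitly.

## Dwell-time survival

Lifetimes are exponential with mean t½/ln 2, independent of motion (no
coupling is modelled). A particle whose lifetime reaches the window (300 s
default) is right-censored at the window. Survival curves are product-limit
(Kaplan–Meier) estimates via `lifelines`; with no censoring they equal the
empirical complementary CDF exactly.

Two half-life estimators are provided:

* **least_squares** (default, matching how survival-fraction decays are
  conventionally fit): unweighted nonlinear LS of exp(−t·ln2/t½) to the
  survival curve. The residual-scaled covariance of this fit drastically
  understates uncertainty when the curve has many correlated steps, so the
  reported `fit_error` is floored at the exponential Fisher-information
  bound t½/√n_events. A weighted fit is deliberately not the default since
  no weighting convention is standard for this kind of decay fit.
* **mle_censored** (recommended): t½ = ln2 · (Σ all durations)/(# observed),
  the closed-form censored-exponential MLE, with SE t½/√n_observed. Under
  ~98 % censoring (t½ = 8900 s against a 300 s window) this remains usable
  but inherits a small positive bias of order 1/E[# events] (Jensen bias of
  1/rate at few events) — about +9 % at ~11 events, shrinking as events
  accumulate.

The dissociation frequency is simply (# observed)/(# total) with a binomial
standard error. Note that at exponential lifetimes of 8900 s vs 590 s a
300 s window predicts frequencies of ~0.023 vs ~0.30 — a ratio far above 3 —
so frequency ratios are checked qualitatively (faster cohort dissociates
more often), not as a numeric recovery.

## AFM volumetrics

Volumes follow (⟨H⟩ − B)·A exactly; negative (sub-background) volumes are
flagged, never dropped. The DNA correction subtracts the mean of two
flanking unbound-DNA volumes. The standard curve is an OLS line of volume on
known molecular weight; calibration points are input data (the shipped
fixture values are synthetic placeholders, not literature masses). Species
deconvolution operates on calibrated molecular weights (the alternative —
fitting volumes directly and converting component means afterwards — is
equivalent up to the affine calibration and is not separately implemented).
The mixture fit is a hand-rolled 1-D EM because the per-iteration
log-likelihood trace is part of the module contract (monotonicity is
asserted in tests); initialization is k-means, 10 restarts, best
log-likelihood kept, component SDs floored at 1e-8 of the data range to
prevent collapse, components reported in ascending-mean order, and BIC
reported for information (k itself is caller-specified).

## Bulk biochemistry

Gel lanes: per-band percent = 100·(band − background)/(lane − background),
with corrected intensities clipped at zero; band-to-group mapping is
user-defined (default: everything except "free" is "bound"). Percentages are
invariant to uniform intensity rescaling.

Binding: the exact single-site ligand-depletion solution is used both to
generate and to fit isotherms — necessary because gel-shift titrations run
at DNA concentrations near K_d, where the hyperbolic approximation fails
(the implementation is verified in tests against an independent
root-finding oracle and against the hyperbolic limit at S = K_d/100). The
fit requires ≥4 points and a ≥0.2 span in fraction bound; flatter isotherms
raise an identifiability error instead of returning an arbitrary K_d.

Excision: the standard pre-steady-state burst form A₀(1 − e^{−k_b t}) +
A₀·k_ss·t, parameters bounded non-negative and A₀ ≤ total enzyme. The
generator clamps product at the substrate cap and flags bursts that exceed
it. Fold stimulation is reported two ways — end-point product ratio and
k_ss ratio — because they genuinely differ near substrate exhaustion; the
package does not force them to agree.

## Problem sizes and determinism

Default study conditions: 12.5 frames/s, 300 s windows, one damage site per
2 kb (0.68 μm at 0.34 μm/kb), 0.03 μm localization noise. Recovery suites
use cohorts of 50 trajectories of 300 frames for D/α, 200 particles for
motility and colocalization, 1000–2000 dwell draws for half-lives, 100-point
replicate sets for K_d, and 2000-particle fields for the 4-component mixture
— sizes at which the estimators' sampling errors sit comfortably inside the
tolerances being checked while every suite completes in seconds. All
randomness flows through `numpy` Generators seeded from explicit config
fields; identical seeds give byte-identical serialized output.

## Limitations

The generator emulates extracted observables, not raw data: no kymograph
images, quantum-dot blinking, photobleaching, drift of the tightrope,
2-D off-axis motion, or gel densitometry. Lifetimes are single-exponential
by construction (no mixtures or hazard covariates), motion and lifetime are
independent, and co-bound pairs share one trajectory rather than interacting
dynamically. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated generative model — it does not validate the
upstream image-processing steps that real data would require.
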