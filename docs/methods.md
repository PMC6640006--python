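# Methods

This note documents the models, algorithms, numerical choices and known
limitations of the `qcsf` package: a simulation and analysis pipeline for
Bayesian adaptive contrast-sensitivity measurement and binocular-combination
analysis in an amblyopia / strabismus / control setting.

## The contrast sensitivity function

Contrast sensitivity `S(f)` — the reciprocal of the Michelson contrast
threshold at spatial frequency `f` (cycles per degree, cpd) — is modelled
by the four-parameter truncated log-parabola:

    log10 S0(f) = log10(gmax) - 4 log10(2) * ((log10 f - log10 fmax) / beta)^2
    log10 S(f)  = max(log10 S0(f), log10(gmax) - delta)   for f < fmax
                  log10 S0(f)                             for f >= fmax

with peak gain `gmax` (linear sensitivity), peak frequency `fmax` (cpd),
bandwidth `beta` (full width at half maximum in log10-frequency units; the
`4 log10 2` constant makes `S(fmax * 10^(±beta/2)) = gmax/2` exact) and
low-frequency truncation `delta` (log10 units below peak).  Two scalar
summaries serve as clinical endpoints:

* **AULCSF** — trapezoidal area under `max(0, log10 S)` over log10-frequency,
  by default across the tested stimulus range 0.64–41 cpd (bounds and the
  clipping are configurable; the integration range is not standardized in
  the field, and the absolute AULCSF value depends on it).
* **CSF acuity** — the high-frequency cutoff where sensitivity falls to a
  criterion (default 1.0, i.e. 100% contrast), closed-form on the
  high-frequency branch; undefined (`nan`) when the peak never reaches the
  criterion.

## The psychometric function and its slope

Probability correct in the 10-alternative letter task is

    P(c, tau) = guess + (1 - guess - lapse) * Phi(k * (c - tau))

with `c`, `tau` log10 Michelson contrast, `guess = 0.1` (10-AFC) and
`lapse = 0.04`.  The lapse default is forced by the threshold criterion:
at `c = tau` the prediction is `guess + (1 - guess - lapse)/2 = 0.53`, the
probability at which thresholds are defined throughout the analysis.

The effective slope `k` (per log10-contrast unit) is assembled from a
slope constant (0.6) and a slope parameter (`beta_p = 0.25`) under a
configurable convention, because the printed form of this expression in
the source literature is typographically ambiguous and the readings differ
by a factor of ~60.  The package default is `k = 0.6 / beta_p^2 = 9.6`.
This is the only reading consistent with binocular psychophysics: with
`k = 9.6`, probability summation between two equally sensitive eyes
predicts a sensitivity gain of ×1.13, close to the canonical ~×1.2
reported for independent detectors, whereas the literal product
(`k = 0.15`) predicts a gain of ×2000 — under which a normal observer's
~40% binocular advantage would count as massive *inhibition* and no
control group could ever exceed probability summation.  The convention
(and a fully free `fixed` slope) is a `PsychometricSpec` field; every
quantity defined *at* threshold (the 0.53 criterion, AULCSF, CSF acuity)
is slope-independent.

## The adaptive engine

The quick-CSF procedure maintains a discrete posterior over
(gain, peak frequency, bandwidth, truncation) on log-spaced axes.  Default
grid: 30 gain nodes in [2, 2000], 25 peak-frequency nodes in [0.2, 20] cpd,
15 bandwidth nodes in [1, 9] octaves (converted internally to log10 units;
octaves are the unit in which CSF bandwidth ranges are conventionally
quoted), 15 truncation nodes in [0.02, 2] — about 170k nodes.  Stimuli live
on a 30 x 40 grid of frequencies in [0.64, 41] cpd and contrasts in
[0.001, 1].

Each trial selects the stimulus maximizing the expected information gain
— the mutual information between the Bernoulli response and the
parameters, `H(p̄) − Σ w(θ) H(p(θ))` in bits — with exact ties broken
toward the lowest contrast, then lowest frequency.  The Bayes update
multiplies the weights by `p(θ)` (correct) or `1 − p(θ)` (error) and
renormalizes; weights sum to 1 within 1e-12 after every update.

Summaries from the posterior: parameter estimates are posterior means on
the log10 axes; the AULCSF estimate is the posterior-weighted mean of
per-node AULCSF (node AULCSF uses a 128-point trapezoid, accurate to
~1e-4); the 68.3% credible-interval width — the test-retest proxy — is the
central-quantile spread (0.1585 to 0.8415, step-CDF convention) of the
weighted node-AULCSF distribution.  The credible interval is computed on
AULCSF rather than raw parameters; which functional the original analysis
used is not documented, so this choice is flagged here.

Sessions are reproducible: one integer seed drives the observer's
responses; stimulus selection is deterministic.  A recorded session can be
*rescored* under a different prior by replaying its trial log (selection
is not re-run).  For speed, a `LikelihoodCache` precomputes the
probability-correct table over (stimulus space x grid) once and reuses it
across sessions; selection then costs two matrix-vector products per
trial.  The cache can hold float32 tables (the pipeline default), halving
memory traffic; posterior updates are always carried out in float64.

## Synthetic observers

Each observer carries ground-truth CSFs for the non-dominant eye (NDE),
dominant eye (DE), and a binocular sensitivity profile derived from the
monocular pair under a combination regime:

* `supra(k)`: `S_bin(f) = k * max(S_nde, S_de)`; `k = 1.4` encodes the
  ~40% binocular advantage of normal vision.
* `probability`: at each frequency the binocular threshold is root-found
  (vectorized bisection, 60 iterations) as the contrast where the
  guessing-corrected combination of the two monocular probabilities
  reaches the 0.53 criterion — independent detectors, no neural summation.
* `sub(k < 1)`: `k * max(S_nde, S_de)`; default 0.85 for binocular
  inhibition (no published value exists for this factor; 0.85 places the
  deficit well outside measurement noise while remaining physiologically
  mild).

Binocular profiles are stored as dense log-log interpolated frequency
tables (probability summation of two parabolas is not a parabola); a
least-squares parabola refit exists for reporting only.

The default cohort reproduces the clinical group structure: 11 amblyopes
(5 able to fuse), 20 strabismics without amblyopia (7 fusers), 24 controls
(all fuse).  Controls get `supra(1.4)`; amblyopes and fusing strabismics
`probability`; non-fusing strabismics `sub(0.85)`.  Group parameter
distributions are independent log-normal marginals per eye.  Their
calibration, frozen from a deterministic procedure:

1. Amblyopic-DE bandwidth is solved so that an eye at the printed group
   means (log10 gain 1.89, peak 3.89 cpd, truncation 0.5) has a
   **Monte-Carlo mean** AULCSF of 1.68 under the group spreads; this gives
   the shared bandwidth mean 0.3282 log10 units (1.09 octaves).
2. Amblyopic-NDE truncation is solved likewise (gain 1.77, peak 1.94 cpd,
   shared bandwidth) for the 0.99 target, giving truncation 1.695.  The
   four printed monocular means are mutually inconsistent with fully
   shared bandwidth *and* truncation, so the amblyopic eye carries the
   difference in its truncation.
3. Control gain is solved for AULCSF 1.65 at control spreads (1.8654).
4. Gain SDs are solved so the simulated group AULCSF SDs match the printed
   0.467 (amblyopic NDE), 0.147 (controls) and a chosen 0.20 (amblyopic
   DE, not printed); the secondary spreads (peak frequency, bandwidth,
   truncation) are fixed small values.

Strabismic eyes use the control marginals (no monocular deficit).  The two
eyes are sampled independently — no interocular correlation is imposed, as
none is documented; this is configurable by construction (supply your own
`GroupSpec`).

A consequence of matching the printed AULCSF means at the printed gains:
the synthetic CSFs are narrow, with control acuity cutoffs near 10 cpd —
lower than real adult controls (~30 cpd).  Roughly 40% of the 0.64–41 cpd
band is then beyond any measurable threshold, which matters for the
summation analysis (below).

## Binocular summation analysis

Two layers, both computed per observer from the three estimated CSFs:

1. **Summation index** `AULCSF_bin / AULCSF_DE`; > 1 indicates binocular
   benefit; group inference is a one-sample t-test against 1.
2. **Probability-summation comparison.**  The binocular CSF is converted
   into threshold contrasts (probability 0.53) at 1,000 log-spaced
   frequencies in 0.64–41 cpd; each monocular psychometric function is
   evaluated at those contrasts; the per-condition probabilities are
   averaged across frequency; and the expected binocular probability under
   independent-detector combination is computed with guessing correction:

       q_i = (P_i - 0.1) / 0.9
       P_expected = 0.1 + 0.9 * (q_NDE + q_DE - q_NDE * q_DE)

   `P_expected` below the 0.53 criterion means the binocular system beats
   independent detectors (supra-summation); above means inhibition.

Numerical and design points worth knowing:

* **Aggregation order.**  Averaging probabilities across frequency first
  and then applying the combination (mean-first, the original order, the
  default) differs from combining per frequency and then averaging by the
  across-frequency covariance of the two eyes' corrected probabilities;
  for heterogeneous eyes this artifact reaches a few hundredths of
  probability.  The per-frequency order (`p_expected_freqwise`) is exactly
  self-consistent: a probability-summation observer lands on 0.53 to
  interpolation precision.  Both are computed.
* **Presentable-contrast mask.**  The pipeline evaluates the profile only
  at frequencies where the estimated binocular threshold contrast is
  <= 1 (`AnalysisConfig.max_threshold_contrast`).  Beyond the acuity
  cutoff the nominal threshold exceeds full contrast and — when the CSFs
  are adaptive estimates — the binocular and monocular estimates both
  regress toward shared prior behaviour, so `c - tau` collapses to 0 and
  every such frequency contributes an artifactual expected probability of
  ~0.75.  With the narrow synthetic CSFs this artifact dominated the
  band; masking removes it while leaving ground-truth values essentially
  unchanged.  The unmasked full-range average (the literal original
  computation) is available by setting the ceiling to `None`.
* **Group test statistic.**  Group-level classification runs a
  one-sample two-sided t-test of the per-observer expected probabilities
  against the 0.53 criterion (significantly below -> supra; above -> sub;
  otherwise consistent with probability summation) — the same test the
  analysis this package models applied to its groups.  Be aware that
  `P_expected` computed from *estimated* CSFs is a sigmoidal readout of
  the binocular-vs-monocular threshold estimation error: symmetric
  estimation noise skews the probability-scale mean (upward for
  probability-summation groups whose eyes sit mid-range), while the
  attenuation of each eye's probability toward chance biases strong
  supra/sub effects toward the criterion.  These two artifacts pull in
  opposite directions and roughly offset at the pipeline's default
  precision; the alternative statistics exposed through
  `AnalysisConfig.group_test_scale` behave differently: `"probit"` tests
  the probit of the mean, and `"latent"` uses `latent_summation_score`
  (per-frequency guessing-corrected probit, symmetrically clipped at the
  lapse-limited latent ceiling, averaged across frequency), which is
  near-linear in the threshold errors and exactly calibrated at
  `probit(0.53)` for a true probability-summation observer, at the cost
  of losing the inflation that happens to assist sub-summation detection
  on the probability scale.  All three are computed and reported in the
  study's test table.

## False-positive-risk simulation

For an observed p-value and assumed populations, the FPR answers: *if this
experiment were repeated under the null and under the alternative with
equal prior weight, what fraction of the outcomes that look like ours come
from the null?*  Each of 100,000 replicates per arm draws an n=11 test
sample (null N(1.65, 0.147) or alternative N(0.99, 0.467)) and an
independent n=24 reference from the null distribution, applies a two-sided
Welch t-test, and counts p-values within a multiplicative band
(factor 2) around the observed p = 0.0009:

    FPR = M_null / (M_null + M_alt)

Drawing a fresh reference per replicate uses only the published summary
statistics and makes the null arm a genuine null experiment.  Welch is the
appropriate test given the 3x SD ratio of the two populations, and it is
the test whose p-values reproduce the observed ~0.0009 at the stated group
statistics; its Satterthwaite approximation does inflate the extreme null
tail by roughly 20% at these sample sizes (the pooled-variance Student
variant, exact under the null, is available via `FPRConfig.test`, but its
pooled SE badly mismatches the heteroscedastic alternative arm).  The
band half-width is not standardized; the FPR ratio is a density-ratio
estimate and changes only weakly (well within one order of magnitude) as
the band factor moves over [1.5, 4], while the raw counts scale with the
band and are reported as band-dependent.

## The study pipeline

`run_study` chains cohort generation, three 25-trial sessions per subject
(condition order randomized per subject), population-prior rescoring,
summation analysis, and group statistics; everything derives from one
master seed through `numpy` `SeedSequence` spawning, so a run is exactly
reproducible.  Sessions are collected under a uniform prior and rescored
afterwards under an informative population prior (independent Gaussians on
the log10 axes, centred at control-typical values with spreads wide enough
to cover severe amblyopia), mirroring the original two-stage scoring
protocol.  Group statistics: paired Wilcoxon signed-rank for
NDE-vs-DE AULCSF within groups, one-sample t-tests of the summation index
against 1, the probit-scale probability-summation tests, a Welch t
comparison of amblyopic-NDE vs control AULCSF, and an FPR simulation
anchored at that comparison's own p-value.

**Problem sizes.**  The pipeline's default engine uses a reduced grid
(18 x 14 x 9 x 9 ~ 20k nodes) and stimulus space (20 x 24), which keeps a
full 165-session study near twenty seconds on one CPU while preserving
estimation quality; the full-resolution engine defaults remain available
through `EngineConfig`.  Test suites run studies at this scale, and some
smoke tests use still coarser grids.

## What the synthetic tests do and do not show

The generator emulates the *statistical structure* the analysis assumes:
printed group means and spreads of the CSF parameters and AULCSF, exact
group and fuser counts, and three binocular-combination regimes.  Passing
the end-to-end pattern check (controls supra, amblyopes and fusing
strabismics consistent with probability summation, non-fusing strabismics
sub, in >= 90% of seeded studies) shows the pipeline detects the regimes
it simulates through 25-trial adaptive estimation noise.  It does not
validate the log-parabola as a model of real vision, the independence of
the two eyes' parameters, the absence of letter-confusion structure in
10-AFC responses (responses are Bernoulli in correctness only), or any
clinical claim about real cohorts.  Real trial logs can be analyzed
through the same entry points (`read_trial_log`, `analyze_trial_log`), but
session timing, response times and UI effects are out of scope.

## Known limitations

* The sub-summation factor (0.85) and the amblyopic-DE AULCSF SD (0.20)
  are package choices; no published values exist for them.
* AULCSF calibration at the printed gains forces narrow bandwidths and
  ~10 cpd control acuity cutoffs; synthetic observers are more myopic in
  spatial frequency than the real cohort.
* The detection-probability analysis is sensitive to estimation noise by
  construction (a steep sigmoid of threshold differences); with 25-trial
  sessions the per-observer expected probability carries a scatter of
  ~0.15–0.25, and group-level conclusions rest on the probit-scale test.
* The Welch-based FPR null tail is calibrated only to ~20% in the extreme
  tail; the reported `null_tail_count` inherits that.
* CSF-acuity posterior means average only over grid nodes whose CSF
  reaches the criterion; for observers far below criterion the estimate is
  prior-dominated.
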