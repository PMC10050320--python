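# Methods

## Task design

The task crosses two domains (gain, loss) with six uncertainty levels —
three risk levels (P = 0.25, 0.50, 0.75; ambiguity A = 0) and three
ambiguity levels (A = 0.24, 0.50, 0.74; reference P = 0.50) — and twenty
unsigned magnitudes ($5, 6, 7, 8, 10, 12, 14, 16, 19, 23, 27, 31, 37, 44,
52, 61, 73, 86, 101, 120), giving 120 unique trials per domain (240 total).
The sure option is fixed at ±$5. The twelve trials whose lottery magnitude
equals $5 are catch trials: one option weakly dominates (in gains the sure
$5; in losses the $5 lottery), and a subject choosing the dominated option
on strictly more than half of responded catch trials fails quality control.

Trials are scheduled into 8 single-domain blocks of 30 (4 gain, 4 loss) over
two sessions, counterbalanced as Gain-Gain-Loss-Loss / Loss-Loss-Gain-Gain
(order 1) or its reverse (order 2). Within a domain, trials are dealt into
blocks round-robin by sorted magnitude separately for risky and ambiguous
trials, so every block holds 15 risky + 15 ambiguous trials spanning the
magnitude range; this keeps the subjective-value spread comparable across
blocks, which the per-block z-normalisation of GLM modulators implicitly
assumes. Presentation order within block is a seeded shuffle. Each trial
occupies 6 s display + 3.5 s response window + ITI drawn uniformly from
{4, 6, 8} s; unused response-window time folds into the ITI, so nominal
onsets are exact regardless of response time. One block = one scan run at
TR = 1 s, rounded up to a whole number of TRs.

## Choice model

Subjective value is `SV = [P − β·(A/2)] · V^α`, with the certain option at
P = 1, A = 0, V = 5. Losses are represented internally with a negative
sign, so one logistic choice rule `P(lottery) = expit(γ·(SV_L − SV_C))`
with γ ≥ 0 serves both domains and higher-valued options are always chosen
more often. (Written with losses entered as positive magnitudes, the same
rule appears with a positive exponent; the signed representation is the
convention used throughout this package and matches the sign of the GLM
modulators: positive for gains, negative for losses.)

Fitting is per subject × domain by maximum likelihood over bounded
parameters: α ∈ [0.0894, 4.34] (symmetric in log space around 1),
β ∈ [−4, 4], γ ∈ [0, 20]. The optimiser works in (log α, β, log γ) with an
analytic gradient — log-scaling keeps the likelihood well conditioned, and
without it multistarts launched at large γ sit on saturated plateaus — via
L-BFGS-B from 20 seeded Latin-hypercube starts (ties broken by the
lexicographically smallest transformed parameter vector). The numeric
lower bound for γ is 1e-4; fits landing there are flagged
low-identifiability (α, β are unconstrained by data when choices carry no
value signal). Missed responses are dropped from the likelihood;
probabilities are clamped away from 0/1 by machine epsilon. BIC is
`2·NLL + 3·ln(n)`. Both combined-session and per-day fits are supported;
the pipeline uses combined fits for attitudes and per-day fits for the
trial-wise SVs entering the GLMs (the estimate closest in time to the
scan).

## Synthetic cohort

One latent severity factor drives the clinical profile: the five CAPS
symptom factors (loading 0.85 each; means/SDs/ranges chosen to resemble
published combat-veteran cohorts), PCL-5, BDI, state/trait STAI, and DES.
Combat exposure (CES) and childhood trauma (CTQ) load weakly (0.30/0.25)
and carry their own latent factors, so a clinical PCA yields a dominant
severity component plus distinct exposure/trauma components. CAPS total is
exactly the sum of the five (integer-rounded, range-clipped) factor scores.
Group labels come from a CAPS-total cutoff (default 40, splitting roughly
40% of subjects into the ptsd group) or can be fixed to an exact group size
by severity rank.

Behavioural parameters: log α ~ Normal(log 0.75, 0.30) for gains and
Normal(log 0.95, 0.30) for losses; β ~ Normal(0.35, 0.5) gains /
Normal(0.25, 0.5) losses; log γ ~ Normal(log 1.0, 0.5). The γ prior is
calibrated to realism on catch trials: a median γ of 1 yields dominated-
option error rates of roughly 10–20%, matching the observed low exclusion
rates in real cohorts, whereas γ an order of magnitude lower would fail
half the cohort on the >50% rule. Severity couples to behaviour with
slopes −0.12 (on log α, gains; more severe → more risk averse) and −0.20
(on β, losses; more severe → more ambiguity averse in losses), sized to
produce rank correlations of roughly −0.3 to −0.4 between CAPS and the
corresponding attitudes at realistic cohort sizes. Choices are Bernoulli
draws from the model; response times are log-normal (median 1.2 s)
truncated at the 3.5-s window, with a 2% lapse rate.

ROI time series are generated on the percent-signal-change scale at
TR = 1 s as: condition box-car (0.2 PSC) + amplitude × valuation modulator
+ cosine drift + motion-coupled nuisance + white Gaussian noise (1 PSC per
TR). The valuation modulator is the z-scored signed SV (value mode) or its
absolute value (saliency mode), built with the same box-car/HRF machinery
as the estimating GLMs. Two normalisation scopes are available: `global`
(default) z-scores signed SV across the whole session — the brain keeps a
common value scale across blocks, which is what makes the 6-bin profile
monotone for value coders and U-shaped for saliency coders — while
`per_block` reuses the estimating GLM's per-block normalisation, making
the generative and estimating designs identical; the noiseless closed-loop
identity (amplitude recovery to < 1e-6 relative error) holds under
`per_block`. Encoding mode follows group (controls: value; ptsd: saliency)
with subject amplitudes log-normal around 0.1 PSC per z-SV unit
(log-SD 0.5). Nuisance series are six small random walks; no AR temporal
autocorrelation is modelled (a deliberate simplification — the estimator
is plain OLS, so simulated and estimated noise models agree).

What the generator does *not* emulate: voxelwise spatial structure,
physiological noise, motion spikes, scanner drift nonstationarity,
session-level attitude drift, and any learning effects. Passing tests
therefore demonstrate correctness of the analysis chain under the stated
generative model, not robustness to real-scanner artefacts.

## First-level GLMs

Five variants: (1) four condition box-cars (ambiguous/risky × gain/loss);
(2) those plus four signed-SV parametric modulators; (3) two condition
predictors (ambiguous, risky) across domains with signed-SV modulators —
the *value* model; (4) as (3) with |SV| modulators — the *saliency* model;
(5) twelve SV-bin box-cars (2 uncertainty × 2 domain × 3 equal-count bins,
losses 1–3 and gains 4–6 ascending, ties broken by trial id, remainders to
lower bins). Modulators are z-normalised with sample SD (ddof = 1) *per
condition within each scanning block* — the parametric-modulation
convention; normalising across the whole block would leave the masked
modulators with nonzero means and leaks several percent of a pure value
signal into the saliency estimate. The normalised value multiplies the
box-car before convolution. Zero-variance modulator blocks normalise to
zeros with a warning. The HRF is a peak-normalised double gamma (peak 6 s,
undershoot 16 s, 6:1 ratio), sampled on a 0.5-s microtime grid (all onsets
fall on it) and downsampled to TR; no slice-timing offsets. Every model
adds a 1-TR response regressor at the button press and six unconvolved
motion-like nuisance columns. Runs are concatenated with run-wise
intercepts and estimated by OLS; all-zero columns are dropped and
reported, rank deficiency raises with the offending columns named, and
modulators are not orthogonalised against their condition columns
(collinearity is reported via the condition number instead, since silent
orthogonalisation changes what a beta means). Runs can be excluded by
configuration, mirroring motion-based run exclusion.

## Group inference

Correlations use Spearman for analyses involving CAPS (heavily tied at
zero) and Pearson for PCL-5 and principal components. The covariate model
`outcome ~ symptom + age + C(income) + C(education) + KBIT + BIC` tests
the symptom term with a type-II F (full vs full-minus-symptom), complete
cases per analysis. Value/saliency group tests are four one-sample t tests
(value/saliency × control/ptsd) forming one Benjamini–Hochberg FDR family,
plus a Welch unequal-variance two-sample t on saliency betas (Welch is the
natural reading of fractional between-group degrees of freedom). A
subject's value (saliency) beta is the mean of the two modulator betas of
GLM 3 (GLM 4). Exhaustive subset selection enumerates all non-empty
predictor subsets (refusing p > 15), ranks by the Gaussian-likelihood OLS
BIC `n·ln(RSS/n) + (k+1)·ln(n)` (intercept counted; other BIC conventions
differ by constants that do not change the ranking), and reports the best
model per size. Clinical PCA eigendecomposes the correlation matrix of the
six standardised measures, with each component signed so its
largest-magnitude loading is positive.

## Validation studies and problem sizes

- Parameter recovery: 50 subjects × 2 domains on the 120-trial per-domain
  design; rank correlation true-vs-recovered α ≈ 0.9 and β ≈ 0.85–0.9,
  median γ ratio near 1, under the default priors.
- Closed-loop GLM: noiseless `per_block` simulations recover generative
  amplitudes to machine precision; off-mode leakage is ~1–4% of the
  on-mode beta across seeds (bounded below 5%).
- Encoding dissociation: 20 seeded 48-subject cohorts (19 saliency-coding
  ptsd, 29 value-coding controls); the per-subject chain uses per-day
  behavioural refits for the GLM SVs with 8 multistarts (a runtime-sized
  profile of the 20-start default; at 60 trials per day-domain fit the
  optimum is insensitive to the extra starts).
- Subset selection runs at n = 200: BIC's fixed ln(n) penalty admits a
  spurious collinear covariate with probability ≈ 6·P(χ²₁ > ln n) — about
  27% at n = 48 *independent of the noise scale*, falling below 15% by
  n = 200. Known limitation: at real-cohort sizes, single-factor BIC
  selection among collinear symptom factors is only ~75% reliable.
- Type-I calibration: 1000 null cohorts; raw rejection rate of the
  one-sample tests is checked against 0.05 within binomial tolerance.

## Numerical conventions and degenerate inputs

Sample SD (ddof = 1) everywhere a z-score appears; percent signal change is
`100·(x − mean)/mean` per run with zero-mean runs rejected; empty choice
lists, mixed-domain fits, mismatched SV/schedule lengths, out-of-range
probabilities and p-values raise immediately with named context. All
randomness flows from explicit seeds (one root seed split per stage in the
pipeline), and refits of identical inputs are bit-identical.
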