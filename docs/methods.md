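# Methods

This package re-implements, as a tested pipeline over synthetic sessions,
the analysis chain used to dissect auditory mismatch responses recorded
extracellularly in rat medial prefrontal cortex (mPFC) under oddball
stimulation with "no-repetition" controls.

## The paradigms

A session presents 400 pure tones (75 ms, 5 ms ramps) at 2/s (SOA 0.5 s)
drawn from 10 frequencies spaced 0.5 octaves apart:

* **Oddball** — one standard tone (STD, 90%) with rare deviants (DEV, 10%).
  The deviant count is enforced exactly (40 of 400) because the analysis
  consumes exactly 40 trials per condition; the first 10 events are
  standards and at least 3 standards precede every deviant. Deviant
  positions are drawn uniformly from the set of all placements satisfying
  those constraints via a stars-and-bars bijection (sample 40 distinct
  values from the gap-transformed index range and map back); this is
  exactly the distribution rejection sampling would target, without its
  vanishing acceptance rate.
* **Cascade** (ascending/descending) — deterministic cyclic frequency ramp;
  each tone appears at probability 0.10, and the tone preceding the tone of
  interest equals its oddball predecessor, making it the preferred control
  (CTR).
* **Many-standards** — random equiprobable tones, built from per-block
  permutations with no immediate repetition across block boundaries, so no
  stimulus-specific adaptation is induced.
* **DEV alone** — the oddball with every standard muted; with the 3-standard
  separation the minimum silent offset-to-onset gap between audible tones is
  `4*SOA - duration = 1.925 s`.

## Response quantification

Trials are epoched at [-0.1, 0.7] s around onset. The matched triplet for
one tone of interest is: DEV = the 40 oddball deviants, STD = the last
standard before each deviant, CTR = the 40 same-direction cascade
occurrences of that tone. Spike counts use the half-open window
[0.1, 0.6) s — delayed 100 ms and preserving the 500-ms interstimulus
span — because prefrontal responses begin only ~150 ms post-onset. No
baseline correction is applied; a 0–50 ms post-onset window estimates the
spontaneous rate (this interval is response-free under the late prefrontal
response geometry). A pre-stimulus option ([-0.1, 0] s) exists and is the
default for the fast auditory-cortex preset, whose count window is
[0, 0.2) s: the 100-ms-delayed window would miss a response that peaks
inside 75 ms entirely.

Spike-density functions smooth each trial with a unit-area 6-ms Gaussian on
a 1-ms grid; the SDF is the trial mean and the SEM is taken across trials
per time point.

**Monte Carlo inclusion test.** A multiunit is "sound-driven" when its mean
baseline-corrected deviant count exceeds what homogeneous Poisson spiking
at the baseline rate produces: `n_sim = 10,000` simulated trial sets, each
reduced to the same statistic, give `p = (g + 1) / (n_sim + 1)` with `g`
the number of null statistics at or above the observed one, tested at
alpha = 0.05. Because a sum of independent Poisson counts is Poisson, each
null trial-set total is drawn as a single Poisson variate — identical in
distribution to simulating full PSTHs, at a fraction of the cost.

## Index decomposition

The mean DEV/STD/CTR counts form a 3-vector normalized by its Euclidean
norm `N = sqrt(DEV^2 + STD^2 + CTR^2)`. With normalized coordinates:

    iMM = DEV_n - STD_n   (neuronal mismatch)
    iRS = CTR_n - STD_n   (repetition suppression)
    iPE = DEV_n - CTR_n   (prediction error)

so `iMM = iRS + iPE` holds identically and all indices lie in [-1, 1].
The time-resolved iPE averages per-window (20 ms, 35 contiguous windows
over [-0.05, 0.65] s) normalized count differences across tones; each
tone reuses its whole-response-window norm so windows remain comparable.
Each window's distribution across tones is tested against zero with a
two-sided Wilcoxon signed-rank test (zeros discarded, the standard
convention) and corrected across the 35 windows by Benjamini–Hochberg at
0.05; the Methods-level family level of 0.1 is exposed as configuration.

## Adaptation dynamics

The trial course orders normalized per-trial counts at their absolute
sequence position (all 360 standards, not only pre-deviant ones) and
averages across multiunits. The block comparison partitions positions
1–400 into 40 consecutive blocks of 10 — the only partition that yields 40
paired measurements for both conditions — averages each condition within
blocks, and applies a two-sided signed-rank test to the 40 paired
differences.

Six families are fitted by nonlinear least squares (the source analysis
names the families without equations; the forms here are declared):
linear `a*t + c`; exponential `a*exp(b*t) + c`; double exponential
`a*exp(b*t) + c*exp(d*t)`; inverse polynomial `a/t + c`; power2 `a*t^b`;
power3 `a*t^b + c`, with `t` the 1-based trial index. Curved families use
multi-start initialization (`b0` in {-0.5, -1, -2}; `a = y(1) - y(end)`,
`c = y(end)`) with best-SSE selection; 95% coefficient intervals come from
the local covariance with t-quantiles; comparison uses adjusted
`R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)`, ties broken toward fewer
parameters.

On noisy synthetic power-law courses (sigma = 0.05) the power3 family wins
outright in roughly 80–85% of replicates; the remainder are losses to the
equal-parameter exponential family by under 0.01 adjusted R² — noise-level
fluctuation, not a modeling failure — so the model-selection test asserts a
strict-win majority plus a never-beaten-by-a-meaningful-margin bound rather
than near-certain victory.

**Decay summary.** For `y(t) = a*t^b + c` the decayable remaining fraction
at trial t is `t^b` regardless of a and c, so the half-decay trial is the
smallest `t` with `t^b <= 0.5` and the steady-state trial the smallest with
`t^b <=` 0.25 (default; chosen so the published prefrontal exponent
b = -1.373 reaches steady state at trial 3, i.e., after 2 repetitions,
matching the reported dynamics). Repetitions-to-half = half-decay trial - 1.

## PE-LFP

Raw traces are band-passed 2.2–50 Hz with a second-order Butterworth filter
applied forward–backward (zero phase, preserving latencies), epoched at
[-0.05, 0.65] s with the same trial selection as the spike analysis, and
averaged per recording site. The prediction-error potential is
`PE-LFP = mean LFP_DEV - mean LFP_CTR` of the site-level means; pointwise
two-tailed paired t-tests run at 428 evenly spaced samples of the epoch
grid (the t-test is justified because each site-level trace is already an
average of 40 waves). Bonferroni correction across the 428 tests is the
default, with Benjamini–Hochberg as an option; maximal runs of corrected-
significant points give the significance intervals and onset. The 428-point
grid is a configuration parameter: the original count is reported without a
grid definition, and evenly spaced samples are this package's reading.

## The synthetic generator

Sessions are the *test bench*: inhomogeneous-Poisson spike trains whose
rate is a baseline plus, per tone, a unit-peak kernel — alpha-like rise
`(tau/peak)*exp(1 - tau/peak)` from the onset latency, then exponential
decay — scaled by `peak_rate` and a per-condition gain. Standards (and,
more mildly, controls) adapt over trials by the power law
`(a*t^b + c)`. Sampling uses Poisson superposition: baseline and per-event
evoked components are drawn independently, the evoked count from the
kernel integral and spike times by inverse-CDF on a 1-ms grid. LFP traces
are `1/f` Gaussian noise (a standard cortical background model; the source
reports none) plus a one-cycle biphasic deflection per tone scaled by
condition.

Preset effect sizes were fixed analytically from the published median
response ratios before any test was run. mPFC preset: baseline 4 Hz, onset
150 ms, peak +250 ms, decay 200 ms, peak rate 30 Hz; gains DEV 1.0,
CTR 0.40 (mild adaptation to 0.65), STD 0.60 with (0.7, -1.4, 0.3)
adaptation. Expected window counts are then ≈13.4/4.0/5.1 (DEV/STD/CTR),
i.e., normalized ≈(0.90, 0.27, 0.34) against published medians
(0.87, 0.28, 0.34). AC preset: baseline 5 Hz, onset 5 ms, peak +30 ms,
decay 25 ms, peak rate 80 Hz; gains chosen to land near the published
nonlemniscal normalized triplet (0.81, 0.21, 0.54) implied by iMM = 0.60,
iPE = 0.27. In the LFP model the standard's amplitude equals the control's
so a deviant's predecessor (a standard) evokes the same deflection as a
control trial's predecessor (the previous cascade tone), isolating the
difference wave to the deviant's own deflection.

### What the generator does *not* emulate

* **Evoked carryover mismatch.** With 0.5-s SOA and a 200-ms decay, a
  tone's firing tail reaches into the next epoch. The deviant's
  predecessor is an adapted standard while the control's predecessor is a
  less-adapted cascade tone, so a small negative iPE exists *before* tone
  onset by construction. Real recordings share this covariate but bury it
  in inter-tone variability; the generator's variability is lower, so the
  windowed-iPE analysis can flag pre-onset windows as (weakly) significant.
  Tests of onset latency therefore use configurations with matched or
  silenced predecessors.
* **Zero-phase smear.** Forward–backward filtering spreads deflection
  energy symmetrically, moving detected PE-LFP onsets tens of milliseconds
  earlier than the generating deflection's latency. The known-effect
  recovery test epochs the unfiltered synthetic trace (which contains no
  drift) for this reason.
* No spike sorting, no receptive-field structure across the 10 tones, no
  laminar or field differences (field labels are metadata only), and no
  long-term habituation across sequences.

Passing tests therefore demonstrate that the *procedures* are correct and
calibrated under their stated assumptions, not that the synthetic data
reproduce every property of cortical recordings.

## Problem sizes

Default runs use 10–12 simulated multiunits (one tested tone each), 40
trials per condition, 10,000 Monte Carlo null draws, 100 replicate courses
for recovery checks, and 200 simulations for null calibrations — sizes at
which every reported rate is stable to a few percent.

## Numerical conventions

Windows are half-open `[start, end)` in onset-relative seconds; tone and
event indices are 0-based, trial positions 1-based. All randomness flows
from a single integer seed through `numpy.random.default_rng`. An all-zero
count triplet has no direction and raises rather than returning NaNs;
signed-rank zeros are discarded; non-converging fit families are flagged
and excluded from selection rather than raised.
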