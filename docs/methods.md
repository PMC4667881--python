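# Methods

## Scope and data model

The unit of analysis is the `PhaseRecording`: one animal × calendar day
× circadian phase, 720 minute-samples of abdominal temperature and
activity counts for a complete 12-h phase. Phase windows are half-open
`[lights_on, lights_off)` / `[lights_off, next lights_on)`, so a sample
stamped exactly at a transition belongs to the window that starts there
and complete days partition exactly into 720 + 720 samples. A dark
phase is attributed to the calendar day on which it starts; a day is
*disturbed* when any handling / bed-change / injection event falls on
it, and both phases of that day inherit the label (an alternative
window-scoped policy is available via `disturb_whole_day=False`).
Partial first/last windows are flagged and excluded from pooling, as are
recordings with more than 5% missing samples in either signal
(configurable).

Missing samples are NaN throughout. Descriptors are computed over
non-missing samples; quantities defined on consecutive samples
(temperature changes, Poincaré pairs, activity runs) never span a
missing minute — a 1-min lag is part of their definition.

## Poincaré descriptors and the asymmetry partition

For the lag-1 return map with N valid pairs, Δ_n = BT_{n+1} − BT_n and
m the mean of all pair coordinates:

* SD1² = ΣΔ²/(2(N−1)) — the second moment of the signed perpendicular
  distance to the identity line. SD1 measures dispersion **about the
  line itself**, not about the cloud's centroid: the identity line is
  the physiological reference ("no change between consecutive
  minutes"), and this choice is what makes the decrease/increase
  partition exact.
* SD2² = ΣD²/(N−1), D_n = (BT_n+BT_{n+1}−2m)/√2 — dispersion along the
  line about the centroid. Because m is the pair-coordinate mean, SD2
  equals the sample standard deviation of the rotated along-line
  coordinate.
* SDNN² = (SD1²+SD2²)/2, which equals the series' overall variance
  about m computed over the pair multiset — with SD1 ≪ SD2 (the usual
  "slim cigar"), SDNN ≈ SD2.

Partition: SD1d²/SD1i² collect ΣΔ² over decreases/increases (on-line
points contribute nothing); SD2d²/SD2i² collect ΣD² over
decreases/increases with Δ=0 points split half-and-half. Under these
conventions SD1d²+SD1i²=SD1², SD2d²+SD2i²=SD2² and C1d+C1i=C2d+C2i=1
hold at machine precision, which the test suite asserts against
independent rotation and pairwise-accumulation oracles. Sample (N−1)
denominators are used everywhere. Contribution ratios are reported as
missing when the corresponding variance is zero; classification
(SD1d > SD1i short-term, SD2i > SD2d long-term) uses strict
inequalities, so exact ties are "not asymmetric". The lag defaults to
one sample (1 min) and is exposed as a parameter.

## Group-level tests

* Number of asymmetric recordings: exact two-sided binomial test
  against 0.5 using the minimum-likelihood two-sided rule
  (`scipy.stats.binomtest`), the natural two-sided convention when no
  direction is pre-specified.
* Relative contributions: Wilcoxon signed-rank test of the
  contributions against 0.5. Since c_d + c_i = 1 per recording, this is
  identical (same ranks, same signs) to the paired test of c_d vs c_i.
  The exact null distribution is used for ≤ 25 non-zero differences
  without ties, otherwise the normal approximation with continuity
  correction. All-zero differences return p = 1.
* Significance threshold α = 0.05. A summary cell is flagged
  significant when both tests fall below α.
* Routine mean comparisons between groups/phases (ANOVA-style analyses)
  are deliberately left to general statistics packages; the directional
  group contrasts in the test suite use one-sided Mann–Whitney tests.

## Event-response profiles

Baseline = mean over the 60 min before the event (missing if < 50% of
those minutes are valid). The post-event period is tiled with 10-min
epochs — 6 (1 h) for light transitions, 12 (2 h) for interventions,
matching the faster photic vs. slower stress-handling dynamics. Epoch
windows start at the event minute (the event minute belongs to epoch 1);
deltas are epoch mean − baseline. Profiles not fully covered by the
series are flagged incomplete and excluded from pooling. The three
intervention kinds are poolable under one label because they evoke the
same transient hyperactivity + hyperthermia pattern; pooling reports
epoch-wise mean ± SEM (sample SD/√n; undefined for a single profile).

## Synthetic cohort generator

The generator emulates the structure of a two-group telemetric study:
6 animals per group recorded for 13 days from lights-on, with
interventions on 5 designated days (2× handling, 2× bed change, 1×
morning injection at 08:45), giving 48 undisturbed and 30 disturbed
recordings per group per phase after pooling.

**Activity.** Per phase, a minute-resolution two-state Markov chain
with switch probabilities q_ai (active→inactive) and q_ia
(inactive→active); run lengths are geometric, so mean active/inactive
bout durations are 1/q_ai and 1/q_ia and the stationary active fraction
is q_ia/(q_ia+q_ai). Active minutes emit geometric counts on {1,2,…}
with mean `activity_mean` (right-skewed, integer). Each contiguous
phase block starts from its stationary distribution; the resulting
closed forms (MI, DI, DA, RMI) are recovered within 5% at 10⁵ minutes
in the acceptance suite.

**Temperature.** BT_t = baseline(phase) + g·MA₃₀(activity)_t + X_t.
The 30-min trailing moving average models metabolic heat lag (a
physiologically plausible value; the coupling gain g is °C per smoothed
count). X_t is AR(1) with φ = 0.98 and innovations drawn from a
zero-mean two-sided mixture: with probability p_up a half-normal draw
of scale σ_up, otherwise the negative of one with scale σ_down. The
mixture skew is the asymmetry knob. Temperatures are clipped to the
admissible 30–42 °C band (never reached under defaults).

An **iid-increment mode** draws the 1-min increments directly from the
mixture, making the asymptotic short-term decrease contribution exact:

    C1d → (1−p)σ_down² / (p σ_up² + (1−p) σ_down²),

and under the zero-drift constraint p σ_up = (1−p) σ_down this
simplifies to C1d → p_up (substituting σ_up = (1−p)/p·σ_down makes the
denominator σ_down²(1−p)/p). `InnovationMix.from_c1d` constructs the
constrained mixture, giving the generator analytically known asymmetry
ground truth for recovery tests.

**Interventions** add `amplitude·exp(−t/decay)` to temperature after a
latency, and Poisson counts with the analogous decaying rate to
activity (keeping counts integral); temperature coupling acts on the
total activity, so evoked movement also warms the animal.

**Reproducibility.** One master seed; per-animal generators are spawned
from `numpy.random.SeedSequence(seed)` in (sorted group, animal index)
order. The config hash excludes the seed, so differently seeded
replicates of one design share an identity.

### Default phenotype calibration

The defaults are a one-time calibration chosen from the closed forms
above to reproduce the qualitative physiology of a healthy nocturnal
rat and a dysregulated comparison substrain; they are documented as
calibration, not estimation.

| parameter | control light | control dark | substrain light | substrain dark |
|---|---|---|---|---|
| q_ai / q_ia | 0.35 / 0.08 | 0.15 / 0.25 | 0.45 / 0.055 | 0.30 / 0.30 |
| activity_mean (counts) | 5 | 12 | 4 | 8 |
| BT baseline (°C) | 36.6 | 37.3 | 36.6 | 37.65 |
| innovation σ_down (°C) | 0.045 | 0.060 | 0.055 | 0.075 |
| mixture C1d target | 0.60 | 0.60 | 0.53 | 0.53 |

Both groups: coupling gain 0.04 °C per smoothed count, φ = 0.98.
Control interventions: 0.6 °C / 30 counts·min⁻¹ amplitude, no latency,
30-min decay; substrain: 0.5 °C / 12 counts·min⁻¹, 15-min latency,
40-min decay (blunted, delayed responses). With φ = 0.98 the AR(1)
component alone gives SD2/SD1 ≈ √((1+φ)/(1−φ)) ≈ 10; the slow
activity-coupled component adds long-term variance, so control dark
recordings land at SD2/SD1 ≈ 9–12 (the "slim cigar"). In AR mode the
observed C1d sits slightly below the mixture target because the
(1−φ)X_{t−1} term and the coupling increments dilute the skew
symmetrically — control recordings average C1d ≈ 0.56–0.59, the
substrain ≈ 0.52–0.53.

### What the generator does and does not emulate

It reproduces: dark-phase maxima in both signals, bout-structured
activity with phase-dependent fragmentation, activity-coupled
autocorrelated temperature with tunable rise/fall asymmetry, transient
intervention responses, and the study's pooling bookkeeping. It does
not emulate: ultradian rhythms and feeding bouts, gradual entrainment
or drift across days, anticipatory pre-lights activity, sensor dropout
patterns (missingness must be injected explicitly), or inter-animal
heterogeneity beyond seed-driven sampling variation (all animals of a
group share one phenotype). Passing tests therefore demonstrate
correctness of the descriptors and inference on data with this
structure, not robustness to every artefact of real telemetry.

## Numerical and policy choices

* AL epochs: non-overlapping hourly windows aligned to the phase start;
  windows containing any missing minute are excluded (a sum over a gap
  would be biased); the epoched temperature mean instead tolerates
  gaps within an epoch since means are unbiased under missingness.
* Recordings shorter than one epoch fall back to the grand mean.
* `min_bout > 1` run smoothing uses a greedy forward merge (a short run
  is absorbed by its predecessor); it is a sensitivity knob, default
  off.
* Problem sizes in the test and acceptance suites (e.g. 10⁵-minute
  chains for closed-form recovery, 20–200 recordings for calibration
  and classification checks, 1000 random series for the identity suite)
  were chosen so sampling error is an order of magnitude below the
  asserted tolerances while the whole suite runs in well under a
  minute of simulation time.

## Known limitations

* The disturbed-day policy treats the whole calendar day as disturbed
  even for a morning injection whose dark phase precedes it — the
  alternative is exposed as a flag but not the default.
* The exact Wilcoxon path requires untied absolute differences;
  real-world contributions occasionally tie at machine precision, in
  which case the approximation is used even for small n.
* The two-state activity model cannot represent graded activity levels
  within a bout (RMI is bout-length independent by construction).
* Event responses are additive; interactions between closely spaced
  events are not modelled (the default schedule spaces them by days).
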