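# Methods

This note documents the statistical procedures, their assumptions, the
package's own design choices where the field leaves room, and what the
synthetic-data generator does and does not emulate.

## Time and epoch conventions

All times are seconds from session start, as real numbers. Every epoch is
half-open, `[start, end)`, so a spike exactly at an odor onset belongs to
the odor period and windows tile without double counting. Trials whose 4 s
baseline would precede the session start are dropped with a logged warning.

Spontaneous windows are the final `spont_tail` (default 10) seconds of each
gap between an odor offset and the next onset — by then delivered odor has
cleared. Gaps shorter than the tail contribute their full length rather
than being discarded: this maximizes the spontaneous sample and is rare
under the default 28 s interstimulus interval. Segments before the first
and after the last presentation are not interstimulus intervals and are
excluded. ISIs are pooled across all tail windows into one distribution
before computing the rate (reciprocal mean ISI) and the CV; intervals that
straddle a window boundary are excluded. The CV uses the sample (n−1) SD;
at typical counts the difference from the population SD is negligible, but
the choice is fixed and tested.

## Odor-response statistics

Per-trial rates are window counts divided by window length (4 s each by
default). The z-score divides the odor-minus-baseline mean rate difference
by the *trial-to-trial* sample SD of baseline rates. A pooled-bin SD would
be an alternative reading; trial-wise rates are the minimal structure
consistent with a per-pair statistic and are the documented default. When
the baseline SD is zero, z is defined as 0 if the means agree and as a
signed-infinity sentinel otherwise; sentinels are excluded from rank-based
interregional comparisons (they carry no usable magnitude) and from median
z summaries.

The paired rank-biserial correlation uses the simple-difference formula on
signed ranks: zero differences are discarded, ties receive average ranks,
and `r = (R⁺ − R⁻)/(R⁺ + R⁻)`. It is exactly +1 when every nonzero
difference is positive, which happens often at 8 trials with strong
excitation — the reason the z-score is carried alongside it.

Significance per pair is a two-sided Wilcoxon signed-rank test at
α = 0.01, with no correction across pairs: the classification rule is the
published per-pair criterion, and the cohort summaries report raw counts of
pairs passing it. The vehicle channel is tested like any odorant but is
excluded from responsiveness proportions and from the selectivity index.

### Exact small-sample tests

For n ≤ 25 nonzero differences the signed-rank p-value is exact:
conditional on the observed (average, possibly tied) ranks, the null
distribution of W⁺ is the convolution of independent two-point laws
{0, rᵢ}, computed by polynomial products over integer-scaled ranks.
Critically, ties do **not** force a fallback to the normal approximation.
With integer spike counts, tied |differences| occur in nearly every pair;
under a tie-free-only exact policy the approximation returns p ≈ 0.0116
even for perfect 8-of-8 separation and the p < 0.01 criterion becomes
unreachable at 8 trials. The tie-tolerant exact path (the same behavior as
the exact mode of common statistics packages) restores the intended
operating point: the smallest attainable two-sided p at n = 8 is
2/256 ≈ 0.0078. Above n = 25 the tie-corrected normal approximation is
used. The Mann-Whitney U test (two-sided, average ranks) is exact for
small tie-free samples and asymptotic with tie correction otherwise; both
tests delegate the numerics to scipy behind this policy layer, and both
are verified against brute-force enumeration oracles in the test suite.

A consequence worth knowing: at 8 trials a pair is significant at
α = 0.01 *only* when all eight differences are nonzero and share a sign,
so the realized per-pair false-positive rate on discrete counts is well
below 0.01 (≈ 0.004 in calibration runs). This conservatism is inherent to
the exact test on small discrete samples, not a bug.

## Respiratory phase analysis

Cycle segmentation is the package's own recipe: zero-phase Butterworth
band-pass smoothing (default 0.5–15 Hz, order 2) followed by rising
zero-crossing detection with sub-sample linear interpolation; cycles
outside physiologic duration bounds (default 0.1–2 s) are discarded. The
0.5 Hz high-pass corner was chosen because a corner at 1 Hz sits close
enough to the 2.5–4 Hz instantaneous respiratory band to displace crossing
positions by several milliseconds when consecutive cycle durations differ;
at 0.5 Hz, ≥ 99% of simulator ground-truth boundaries are recovered within
10 ms. The passband is configurable.

Spike phase is proportional position within the cycle,
`360° · (t − start)/duration`, which makes phase invariant to cycle-length
variation. There are two common origin conventions — inspiration onset vs
the inhalation-exhalation transition, half a cycle apart; the cycle table
carries an origin label and `rotate_origin` converts between them (a 180°
rotation). All recovery tests use matched conventions between simulator
and analysis, so the labeling cannot silently bias them.

Phase statistics use 6° bins (60 bins per cycle): one vector per bin at
the bin-center angle with the bin count as magnitude, and θ/ρ from the
normalized vector sum. Binning quantizes θ by at most half a bin (3°).
The Rayleigh statistic is Z = nρ² with the standard closed-form
small-sample correction of exp(−Z),
`p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n))` with R = nρ; it requires
n ≥ 4 and is cross-checked against an independent circular-statistics
implementation in the tests. Significantly modulated cells are confirmed
unimodal by comparing the resultant at the fundamental (R₁) with the
doubled-angle resultant (R₂): antipodal bimodality concentrates mass at
the second harmonic, so `unimodal = (R₁ ≥ R₂)`. This deterministic check
was chosen over mixture-fitting because it is assertable and has no tuning
parameters.

Phase statistics pool spikes across all trials within the 8 s window
starting at each odor onset (per-odor splits are available by filtering
the event table). Spikes in cycles truncated by the window edge are kept
whenever their cycle was detected. The population mean phase is the angle
of the sum of unit vectors at each qualifying cell's θ, equally weighted.

## Synthetic sessions

The generator emulates the assumed statistical structure of anesthetized
olfactory-peduncle recordings:

- **Stimulus protocol:** 2 s odor pulses, 28 s interstimulus interval,
  default 11 odorants plus a mineral-oil vehicle, 8 trials each, presented
  in pseudorandom blocks (every stimulus once per block), 30 s lead-in.
- **Spontaneous rates:** log-normal across cells, median 1.4 Hz with
  σ_log = 1, matching the ~1–2 Hz cohort medians such recordings show.
- **Respiration:** gamma-distributed cycle durations (mean rate 3 Hz, CV
  0.15 — a plausible anesthetized breathing rate, configurable), rendered
  as one sinusoid period per cycle at 100 Hz with additive noise
  (σ = 0.05); the ground-truth cycle table is returned alongside.
- **Respiratory coupling:** a fraction (default 0.6) of cells carry a von
  Mises phase gain `exp(κ cos(φ − μ))/I₀(κ)` — normalized so the
  cycle-averaged intensity equals the baseline rate — with κ log-normal
  (median 0.8) and preferred phases normal around 25° (SD 15°), the
  just-after-inhalation-exhalation region where such cells concentrate.
- **Odor responses:** excitatory only (gain ≥ 1). A region-specific
  fraction of cells (defaults 0.30 DTT, 0.11 AON, assigned exactly by
  rounded count for recovery testing) respond to 2–6 odorants with a
  multiplicative gain (log-normal, median 4), onset latency ~0.4 s
  (within the first respiratory cycle or two) and duration ~5 s
  (outlasting the 2 s pulse), applied as a boxcar on the intensity.
- **Sampling:** inhomogeneous Poisson by thinning against the intensity
  upper bound; one master seed derives deterministic per-subject and
  per-cell substreams, so a fixed seed reproduces a cohort byte-for-byte.

What it deliberately does not emulate: bursting and refractory structure
(spiking is Poisson given the rate), rate drift, inhibitory responses
(available as a gain < 1 only by editing ground truth; off by default),
cross-cell correlations, sniff-frequency dynamics, electrode artifacts,
and spike-sorting errors. Passing recovery tests therefore demonstrates
correctness of the analysis chain under the assumed generative structure,
not robustness to every property of real recordings.

## Cohort aggregation

Region summaries count significant pairs and responsive cells (≥ 1
significant non-vehicle odorant), strong pairs (z ≥ 3), medians of
spontaneous metrics and selectivity, phase-locking counts among cells with
respiration, and the population mean phase. Interregional comparisons are
Mann-Whitney tests on per-cell metrics and per-odorant z distributions for
a configurable region pair (default DTT vs AON; VTT-sized samples are
summarized descriptively). The sex comparison runs on the full sample
because sex is typically unbalanced across regions. Grand-average
peristimulus histograms (default 100 ms bins, −4 to +8 s; bin width
configurable since no canonical value exists) average the per-pair PSTHs
of strong responses with across-pair SEM.

## Problem sizes and numerical choices

Validation runs use desk-scale sizes chosen to make the statistics
decisive: 5,000 synthetic cells (100 spikes each) for Rayleigh
calibration; 200 cells of ~1,000 spikes for phase recovery (median θ
within ±5° of the programmed 30°); 5,000 null pairs for the classifier's
false-positive rate; 10,000 exponential ISIs for spontaneous-metric
recovery; and a 37 + 37 cell cohort — the study-scale regional sample —
for end-to-end recovery of programmed responsive fractions (checked
against exact binomial 95% intervals) and population phase (±5° of the
programmed 25°). Degenerate inputs are flagged rather than raised wherever
a metric can be legitimately undefined (too few ISIs or trials, zero
baseline SD, empty phase samples); validation errors are reserved for
violated data-model invariants.

## Known limitations

- The z-score denominator (trial-wise baseline SD) and the phase-origin
  convention are both points where reasonable alternatives exist; both are
  configurable and documented rather than silently fixed.
- The selectivity index is bounded by 1 for nonnegative rates by
  construction; published values above 1 for this index imply a different
  rate transformation (e.g. baseline-subtracted rates) and cannot be
  reproduced by the formula as printed.
- Exact Mann-Whitney p-values fall back to the asymptotic form in the
  presence of any tie; for continuous per-cell metrics this is immaterial,
  but per-odorant z comparisons with many identical values would use the
  approximation.
- Cycle detection assumes a roughly sinusoidal, band-limited respiration
  signal; strongly asymmetric or clipped piezo traces may need a custom
  passband or an external cycle table, which `RespCycleTable` accepts
  directly.
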