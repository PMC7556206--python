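# Methods

This note documents the models, parameters and design choices behind
`hfoasym`: what is computed, what the synthetic data emulate, and where
the genuinely open decisions were made.

## The analysis

### Event types and rates

Four interictal event classes are counted per SEEG contact over a fixed
interictal segment (default 60 min of slow-wave sleep, ≥2 h from any
seizure): epileptic spikes (IES), ripples (80–250 Hz), ripples
co-occurring with spikes (IES-ripples), and fast ripples (250–500 Hz).
Rates are events/min. "Ripple" rates include IES-ripples by default
(the IES-ripple subset is always reported alongside, so the isolated
count is recoverable); whether published ripple rates include
spike-coupled ripples is generally ambiguous, so both conventions are
exposed (`ripples_include_cooccurring`).

### Lesion asymmetry ratio

Per patient and event type, with h̄ and n̄ the mean rates over the
hippocampal- and neocortical-lesion contacts,

R = (h̄ − n̄)/(h̄ + n̄) ∈ [−1, 1].

"Mean rate" is the arithmetic mean across contacts of per-contact rates
(each contact weighted equally), because channel-level rate
distributions are the natural observable; a pooled-count alternative is
kept behind a flag for recordings with unequal per-contact durations.
R is computed from **all** contacts in either lesion — never from SOZ
labels — so it is independent of any seizure information. R is
undefined (NaN) only when both lesion means are zero, or when a patient
lacks contacts in one lesion; undefined patients are excluded from
correlations and ranked last with a warning.

The ratio normalises away the fact that hippocampal lesions generate
more interictal events of every type than neocortical lesions; the raw
rate comparison (pooled channels, Mann-Whitney U) and the
group-asymmetry correlation are therefore separate questions and
separate module operations.

### Rank-zone prediction and its null

Patients are sorted by descending R_fast-ripples (stable sort, patient-id
tiebreak). With true group counts (n₁, n₂, n₃) the top n₁ ranks are
predicted group 1 (hippocampal onset), the bottom n₃ group 3, the rest
group 2. The predicted label multiset therefore always equals the true
one; the rule reassigns labels rather than inventing them. A tie in R
straddling a zone boundary sets `tie_warning`, since those patients'
predictions depend on the arbitrary tiebreak; the packaged reference
cohort has three tied pairs, none straddling a boundary (verified by
perturbation in the test suite).

Significance of the observed match count m is assessed one-sidedly —
the question is whether the rule beats chance — by holding the zone
pattern fixed and permuting the true-label multiset uniformly over rank
positions: p = #{shuffles with matches ≥ m}/N with N = 100,000 by
default (seeded, vectorised); an add-one-smoothed p accompanies the
plain proportion. The exact null distribution is computed alongside by
summing over 3×3 contingency tables with fixed margins, each weighted
by its multinomial arrangement count (integer arithmetic; the pmf sums
to 1 exactly and its mean obeys E[m] = Σnᵢ²/N_patients, used as a
closed-form check). The exact tail bounds the Monte-Carlo error in
every report.

### Statistics

- Mann-Whitney U (two-sided): for pooled sizes ≤ 40 the p-value comes
  from exact enumeration — a subset-sum dynamic programme over doubled
  midranks, which remains exact under ties (where the textbook exact
  tables and scipy's exact method do not apply); larger samples use the
  tie-corrected normal approximation with continuity correction.
  Channels are pooled across patients and treated as independent, a
  simplification the contact-level design implies.
- Spearman rank correlation: average ranks for ties, ρ = Pearson
  correlation of rank vectors, p from the t approximation on n−2
  degrees of freedom; an exact permutation p (all n! orderings) is
  available for n ≤ 10.

## The synthetic-data generator

The generator's defaults define the study conditions the pipeline is
validated under: a 16-patient cohort with group counts 5/7/4, 60
hippocampal and 124 neocortical contacts cohort-wide (split over
patients uniformly at random, at least one contact per lesion each),
1-hour segments at 2 kHz through an 800 Hz low-pass.

Statistical structure:

- Per-channel true rates are Gamma(shape 4, mean/4) around lesion-level
  means — coefficient of variation 0.5 across contacts, a typical
  between-channel dispersion; observed counts are Poisson(rate ×
  duration). Event times are uniform; same-type events never overlap
  (unambiguous ground truth), different types may (IES-ripples are a
  ripple summed onto a spike).
- Baseline rates (events/min, hippocampal/neocortical): IES 4.0/1.5,
  ripples 2.0/0.8, IES-ripples 1.0/0.4, fast ripples 1.0/0.4.
  Hippocampal baselines exceed neocortical ones for every type,
  reproducing the overall hippocampal predominance that motivates using
  a ratio rather than raw rates.
- Fast-ripple lesion means are rescaled per group to hit configured
  expected asymmetries, preserving their sum: defaults (0.6, 0.1, −0.3)
  for groups 1/2/3 — strong hippocampal excess, near-zero, moderate
  neocortical excess. Group 2 sits near zero because dual-onset
  patients occupy the middle of the observed ranking. The calibration
  test verifies that the mean realized R per group over 100 cohorts
  stays within 0.05 of these targets.
- SOZ flags follow the group definition: group 1 → hippocampal contacts,
  group 3 → neocortical, group 2 → both.

Waveforms (signal tier):

- Background: 1/f^α Gaussian noise (α = 1), low-passed at 800 Hz,
  scaled to 25 µV SD.
- HFO bursts: Gaussian-windowed sinusoids (σ = duration/6), 6–10
  cycles, peak amplitude 6× background SD. Centre frequencies are drawn
  uniformly within an *inset* sub-band: the time-bandwidth limit means a
  6-cycle burst at a printed band edge necessarily leaks energy across
  it, so frequencies keep 2.9 power-spectrum widths clear of both
  edges, guaranteeing ≥ 99% in-band energy and spectrally unambiguous
  ground truth.
- Spikes: one raised-cosine-windowed cycle whose positive lobe spans
  50–80 ms (biphasic; fundamental plus harmonics reach into the 10–60 Hz
  detection band), half carrying a 200 ms after-going slow wave at 35%
  opposite amplitude; random polarity.

What the generator does **not** emulate: sleep staging, pulse/movement
artifacts, line noise, ictal activity, electrode geometry, within-
patient rate correlations beyond the lesion means, or non-stationarity
across the hour. Passing recovery tests therefore demonstrate the
pipeline's internal consistency under the assumed statistical
structure, not detector performance on clinical recordings — which is
why every detector threshold lives in `DetectionParams` for
recalibration.

## The detector

A deterministic band-energy stand-in for learned clinical detectors,
Staba-style: zero-phase FIR band-pass (forward-backward, so event
timing is phase-neutral; 401 taps), RMS envelope (10 ms window for
ripples, 5 ms for fast ripples), baseline = median and robust SD
(1.4826 × MAD) of the envelope — robust so the events themselves do not
inflate the baseline — and threshold median + 3 SD. Candidate intervals
merge across gaps < 10 ms. Two additional gates, both found necessary
for usable precision:

- Cycle criterion: the band-passed signal must alternate through ≥ 4
  supra-threshold extrema of each polarity inside the interval.
  Counting rectified peaks above *half*-threshold (a common
  formulation) let 10–20 ms noise excursions in the fast-ripple band
  qualify, at ~0.9 false events/min; requiring full-threshold extrema
  of both polarities reduces this to ≤ 0.1/min without costing
  sensitivity.
- Spectral dominance: the event snippet (±10 ms) must hold at least
  twice as much power inside the detection band as outside it,
  considering only frequencies above 60 Hz (zero-padded FFT, Hann
  window). This rejects cross-band leakage — ripples near 250 Hz
  triggering the fast-ripple band, and spike tails — which the
  per-band envelope thresholds cannot see because each band is
  thresholded against its own (very quiet) noise floor.

Spikes: band-pass 10–60 Hz, candidates are extrema above 3 robust SD
whose width lies in 20–200 ms. The width is measured at 35% of peak
amplitude rather than 50%: at half height, band noise perturbs the
flank crossings of near-threshold events enough to misclassify a
substantial fraction of true spikes, while the lower measurement height
separates spike widths from narrow noise lobes cleanly. Candidates
within 50 ms merge (the phases of one biphasic transient). A ripple is
an IES-ripple iff its interval overlaps a spike interval dilated by
±50 ms (half-open intervals; a ripple starting exactly at the dilated
edge is isolated). The ±50 ms window follows common spike–HFO coupling
windows and is configurable.

The test suite pins the operating point on synthetic cohorts (4
patients, 5-minute segments — sizes chosen to exercise every path at
useful statistical resolution): per-type sensitivity ≥ 0.85 and
precision ≥ 0.8 at the default 6× SNR, < 1 false event/min per band on
pure background, and monotone event counts in the threshold.

## Numerical and I/O choices

- Times are seconds from segment start; all intervals half-open
  [start, end). Rates are events/min; amplitudes µV.
- Determinism: every stochastic stage takes a seed; per-channel streams
  derive from (seed, stage, patient, channel) so cohorts are
  reproducible bit-for-bit and channels are independent. Reports embed
  seed and config hash.
- EDF is the signal container (clinical interchange standard); reading
  goes through MNE, writing through a minimal built-in 16-bit encoder
  (1-second records, per-channel symmetric physical range), round-trip
  tested against MNE's reader to sub-µV agreement.
- All tabular artifacts carry a schema tag (`# hfoasym-schema <name>
  v1`) on line one; readers reject unknown tags.
- Degenerate inputs: constant signals yield no events; empty contact
  subsets yield flagged (NaN) statistics rather than exceptions inside
  batch reports; 0/0 ratios are NaN with downstream warnings; a missing
  group aborts prediction (zones undefined).

## Limitations

The reference cohort is small (16 patients) and its published ratios
are rounded to two decimals, which bounds how precisely the correlation
can be reproduced (recomputed ρ = −0.51 vs published −0.52). The
prediction procedure is in-sample by construction — zone sizes come
from the cohort's own group counts — and carries no out-of-sample
claim. Channel pooling ignores within-patient correlation. The
detector is a transparent threshold method, not a replication of any
learned clinical detector; absolute rates from real SEEG will depend on
its calibration.
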