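# Methods

## Problem and scope

Activity counts from body-worn accelerometers are the de-facto currency of
free-living physical-activity research, but the mapping from counts to
walking speed is population-specific. `gaitcounts` implements the
calibration workflow for post-stroke gait: converting tri-axial acceleration
to per-epoch counts, labeling epochs by trial annotations, calibrating count
thresholds that separate non-ambulation from walking and the three
community-ambulation speed bands (0.41–0.8, 0.81–1.2, >1.2 m/s), and
classifying new epochs with calibrated or published cut-points. The original
cohort data are not publicly shareable, so a synthetic generator reproduces
the study conditions; all empirical statements below are computed by the
test suite or `scripts/acceptance.py`, not quoted.

## Count engine

The vendor count algorithm is proprietary; this engine is an *emulation*
with the same published structure and open, documented defaults. Its
contracts are zero-input → zero-count and amplitude monotonicity (scaling
the in-band signal up never decreases a count); bit-exact agreement with
vendor software is explicitly not a goal.

Chain per axis, at 30 Hz (other rates are rejected rather than resampled):

1. zero-phase 4th-order Butterworth band-pass, 0.25–2.5 Hz
   (`filter_mode="lfe"` lowers the low cut to 0.05 Hz for slow movement; the
   true low-frequency-extension passband is not public, so only the
   qualitative contract — a 0.1 Hz tone yields more counts under LFE than
   under the default filter — is asserted);
2. 12-bit ADC quantization over ±6 g, zero acceleration at mid-scale
   (level 2048 of 4096);
3. rectification, dead-band (default 0.05 g — samples below it contribute
   nothing), ceiling clip (2.13 g), quantization in steps of 1/128 g;
4. integer summation per 1 s base epoch.

Vector magnitude is computed **at the 1 s level** as the Euclidean norm of
the three axis counts, rounded to the nearest integer (an arithmetic-sum
switch is provided, since "summation of counts for all three axes" is the
other reading found in the literature; Euclidean is the field convention and
the default). Computing VM at the base-epoch level makes aggregation to
15 s / 60 s epochs a plain integer sum for *all four* series, which gives
the conservation law used in testing: each 60 s epoch equals the sum of its
four 15 s epochs exactly, VM included. Trailing partial epochs are dropped.

## Segmentation

Every trial loses its first and last 15 s (initiation/termination are not
steady state); a trial must therefore exceed 30 s. Walking speed is distance
walked over trial duration — one speed per trial, inherited by all its
retained epochs. Band edges follow the published cut-point table: SLOW upper
bound inclusive at 0.80 m/s, MED inclusive at 1.20 m/s, minimum walking
speed 0.41 m/s (the source material also prints "0.4" once; 0.41 is
adopted). Walking trials slower than 0.41 m/s are excluded with a warning
rather than silently binned — the bands do not cover them. The three
household tasks are pooled into one non-ambulation class, with the task
label kept for provenance.

## ROC calibration

Each boundary b ∈ {1, 2, 3} of the ordered categories is a binary problem.
The default dichotomization is cumulative (categories < b vs ≥ b), chosen
because the published intervals are contiguous and exhaustive; adjacent-pair
splitting (only the two classes flanking the boundary) is available as an
option. Candidate thresholds are the midpoints between consecutive distinct
scores plus ±∞ endpoints, so tied scores share an operating point and the
curve always contains both corners. AUC is trapezoidal, which equals the
Mann–Whitney concordance U/(n₁n₂) with ties counted ½ — the test suite
verifies this to 1e-9 against a brute-force pairwise oracle and against
scikit-learn's independent implementation.

The cut-point is the operating point minimizing the distance to the ideal
corner, √((1−Se)² + (1−Sp)²). Ties are broken toward higher sensitivity
(favoring detection of walking), then the lower threshold. For equal-variance
Gaussian classes this criterion's large-sample optimum is the midpoint of
the class means (by symmetry of the corner distance), which the suite uses
as a closed-form recovery check. The optimal real threshold t becomes the
integer boundary T = ⌊t⌋ with intervals ≤T / ≥T+1, so any cut-point table
partitions the non-negative integers into exactly four contiguous ranges.
If sampling noise makes a boundary not exceed its predecessor, that boundary
is recomputed with the search restricted to thresholds above the predecessor
and the event is logged.

AUC grades follow the conventional bands: <0.70 poor, 0.70–0.79 fair,
0.80–0.89 good, ≥0.90 excellent, exactly 1 perfect.

Per-category sensitivity/specificity are computed from interval
classification (category c's sensitivity = fraction of c's epochs landing in
c's interval; specificity = fraction of other epochs landing outside it),
not from the boundary's binary problem — the published report is ambiguous
on this point, and interval classification is what a user of the cut-points
experiences. Thresholds are optimized on pooled epochs with no
participant-level clustering adjustment, matching the source procedure as
described.

## Synthetic cohort generator

The generator defines the conditions every downstream result is computed
under. Defaults mirror the study: 42 participants, waist and ankle
placements, 15 s epochs, three non-ambulation trials (sitting 5 min,
setting the table 3 min, washing dishes 6 min) and two 6-min walking trials
per participant. A single global seed spawns per-participant sub-streams, so
regeneration is deterministic (byte-identical output for an identical
configuration).

**Count-level path** (default; used for calibration experiments). Walking
categories draw per-epoch counts from a lognormal with median equal to the
configured class median and log-scale SD `dispersion`; counts are
non-negative and right-skewed, which the lognormal captures with two
parameters. Default medians are the published per-category sample medians
(waist VM/15 s: 0 / 519 / 759 / 1147; ankle VM/15 s: 0 / 1394 / 2546 /
4045; vertical-axis and 1-min variants included). The non-ambulation class
is zero-inflated — P(zero) = 0.6, non-zero tail lognormal with median 6% of
the SLOW median — reproducing its published median of 0 with a positive
upper tail. The published intervals accompanying those medians are
internally inconsistent (medians of 0 outside their interval) and their
construction is undocumented, so only the medians are calibration targets.
`dispersion = 0.25` was chosen from the spread of the published
per-category intervals; it is deliberately "moderate" — classes overlap but
remain separable. Per-epoch vertical counts are drawn coupled to the VM draw
(v = VM × median ratio × small lognormal jitter, capped at VM), and the
AP/ML axes split the Euclidean residual equally, so every row satisfies
VM ≥ max(axis counts).

Walking speeds are drawn once per trial: self-selected ~ N(0.78, 0.26)
truncated to [0.42, 1.6] m/s, brisk = self-selected + U(0.30, 0.60) capped
at 2.4 m/s. These values put the expected walking-trial mix near the
published cohort's composition (≈29% slow / 40% medium / 31% fast) and keep
every category present in a 42-participant cohort with high probability.

**Signal-level path.** Gait is modeled as the first two harmonics of the
step cadence (cadence = 0.75 + 0.6·speed Hz, inside the count passband) with
amplitude proportional to speed (0.12 g per m/s at the waist, 0.35 at the
ankle — the distal placement sees the larger signal), slow amplitude
modulation, axis-specific scaling, 0.02 g sensor noise and a 1 g gravity
offset on the vertical axis. Non-ambulation tasks combine sub-dead-band
in-band motion, out-of-band postural drift, noise, and occasional 0.5 s
transients, so sitting epochs have median count 0 after conversion. The two
paths share one table schema; signal-level count magnitudes are *not*
calibrated to the published medians (the emulated chain's absolute scale
differs from the vendor's), so the count-level path is used wherever
median-calibrated conditions matter.

What the generator does **not** emulate: hemiparetic asymmetry, walking-aid
artifacts, within-trial speed drift, between-participant count-level random
effects (epochs are exchangeable within a trial), device idle-sleep
artifacts, or vendor-exact count scaling. Passing tests therefore
demonstrate correctness of the calibration machinery under controlled,
realistic-order conditions — not clinical validity on real post-stroke
recordings.

## Problem sizes and numerical choices

Calibration-recovery experiments use 20 cohorts of 42 participants
(≈7,900 epochs each); ROC oracle checks use 100 random instances of up to
200 points; exhaustive partition checks cover counts 0–10,000; the Gaussian
threshold-recovery check uses 10,000 draws per class. Bootstrap intervals in
summaries use 2,000 seeded resamples. Degenerate inputs are signalled, not
coerced: single-class ROC input, single-point curves, trials ≤30 s,
sub-minimum walking speeds, non-integer or negative counts, and mixed-stratum
tables all raise typed exceptions.

## Known limitations

- The count engine's absolute scale is an emulation; calibrated boundaries
  from signal-level data are internally consistent but not comparable to
  vendor-count thresholds.
- The corner criterion with cumulative dichotomization is sensitive to class
  imbalance: the large zero-count non-ambulation mass inflates specificity
  at boundary 2, pulling its population optimum toward the SLOW median
  (≈554 vs the 627 geometric midpoint under default conditions). This
  mirrors the behaviour of the criterion itself, not an implementation
  artifact.
- Published 1-min and vertical-axis cut-points are shipped as loadable
  fixtures, but the recommended configuration — and the only built-in
  default — is VM at 15 s epochs, since cut-points do not transfer across
  epoch lengths or axes.
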