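# Methods

## Playback paradigms

**Voluntary (silence replacement).** White noise and one target sound
(conspecific advertisement call, 1 kHz pure tone, or screech call; all
1280 ms slots with 7.5 ms rise/fall) alternate antiphonally at a fixed
1500 ms ISI.  After an even number of familiarization presentations
(default 20, flagged and excluded from analysis), the sequence runs 120
cycles; a cycle of length N contributes N white-noise/target pairs followed
by one white-noise/silence pair, i.e. the target at the last position of
every N+1 presentations is omitted.  The cycle-length multiset
{3,4,5,6} × 30 is shuffled without replacement by the session seed, which
fixes the totals at 660 + 540 + 120 = 1320.  Cycles are split evenly into 4
contiguous blocks separated by 5 min breaks.  Replaced-silence slots keep
the full 1280 ms duration so downstream epoch timing is unchanged.  Time is
real-valued ms from session start; slots are half-open `[onset, onset+duration)`.

**Reflexive (equiprobable random).** 100 white-noise and 100 target
presentations in uniformly random order; each presentation's ISI is drawn
uniformly from {1.1, 1.3, 1.5, 1.7, 1.9} s.  The analytic expected span is
200 × (1.28 + 1.5) s = 556 s ≈ 9 min.  `expected_duration` counts one ISI
per presentation (and breaks where present); a realized schedule's span
ends at the last offset, one ISI shorter in expectation.

One target pair per session is assumed; the three pair types are run as
separate sessions per subject.

## Generative model (synthetic cohorts)

Each of 6 channels (LT/RT, LD/RD, LM/RM over telencephalon, diencephalon,
mesencephalon) carries, in µV:

* **Background**: Gaussian noise spectrally shaped to power ∝ 1/f
  (amplitude flattened below 0.25 Hz, no DC), scaled to a time-domain sd of
  10 µV per channel.  The shaping exponent is the canonical EEG choice; the
  sd is a free scale (the source figures give no µV calibration) chosen so
  that rejection is driven by artifacts rather than by noise tails at the
  ±60 µV rule.
* **N1**: a negative raised-cosine (Hann) lobe, 60 ms wide with an odd
  sample count so its minimum equals exactly the programmed amplitude at
  the programmed latency (default 70 ms), added after every white-noise and
  target onset.  Amplitudes are region × stimulus parameters of the subject
  profile.  The lobe is band-limited well inside 0.25–25 Hz, so the
  analysis filter changes its amplitude by far less than 5 %.
* **SPN** (voluntary sessions only): a linear negative ramp ending at every
  expected target/silence onset.  The ramp spans `spn_ramp_span_ms`
  (default 1500 ms — anticipation builds through the silent gap after the
  preceding white noise; the span is configurable).  The ground truth
  records the closed-form mean of the ramp's last 500 ms,
  slope × (span − 250)/1000, which is what the SPN measurement reads at
  zero noise.  The ramp resets at the stimulus onset (anticipation
  resolved); consequently the 200 ms pre-target baseline of voluntary N1
  epochs sits on the ramp tail and the measured voluntary N1 carries a
  region-dependent positive "release" offset.  This mirrors the real
  superposition of anticipatory and evoked activity; it leaves the
  mesencephalic N1 dominance intact (forebrain N1 values are pushed toward
  or past zero) and is the reason per-subject latency extraction falls back
  to peak latency when a window contains no negative excursion (flagged in
  the measure table).
* **Artifacts**: 100 ms square pulses of ±120 µV on one random channel at
  Poisson times.  `artifact_rate` is parameterized as the probability that
  a 700 ms epoch is contaminated (λ = −ln(1−p)/0.7 s); default 0.05.

Cohorts are sex-balanced (default 16 subjects, 8 female + 8 male); subject
parameters are population means plus i.i.d. Gaussian jitter (sd 0.8 µV; SPN
slope jitter scaled so the measured window mean jitters by the same sd).

The **"paper" effect profile** programs the study's qualitative directions:
N1 most negative over the mesencephalon for every stimulus (−12 vs −5 µV);
in the telencephalon a larger N1 for the screech call than for the
conspecific call (−9 vs −4 µV); SPN slope most negative over the
telencephalon and smallest over the mesencephalon, with stimulus marginals
equalized so only the region main effect and the stimulus × region
interaction (forebrain dominance strongest for conspecific calls) are
non-null.  SPN slope magnitudes were fixed by a one-shot power design: the
zero-phase 0.25 Hz high-pass attenuates a ramp of this period by a measured
factor ≈ 0.47, so slopes were sized to give a filtered paired
telencephalon−mesencephalon contrast of Cohen's d ≥ 2.2 at n = 16 (power ≈ 1
at the Bonferroni-corrected α).  The **"null" profile** equalizes all
region × stimulus means.

What the generator does **not** emulate: volume conduction between
channels, dipole geometry, heartbeat/movement artifact morphology,
habituation or attention drift over a session, and the acquisition
hardware's 0.16–100 Hz analog band.  Passing tests therefore certify the
analysis chain and its statistics, not biological realism of any single
waveform.

## Preprocessing

4th-order Butterworth band-pass 0.25–25 Hz plus a biquad 50 Hz notch
(Q = 30), each applied forward–backward (zero phase, DC removed exactly);
filtering always precedes epoching.  Epoch geometries (half-open windows,
t = 0 at the anchor onset): target N1 −200…+500 ms; SPN −200…+2780 ms
anchored on the white noise preceding a silence replacement; combined
−200…+3280 ms anchored on the white noise preceding a genuine target;
reflexive N1 −200…+500 ms.  Baseline is the 200 ms before the anchor; the
combined epoch's N1 read-out is re-baselined on the 200 ms before the
target onset.  An epoch is rejected when |amplitude| exceeds 60 µV on any
channel at any sample of the baseline-corrected data (whole-epoch
rejection; the original visual inspection is approximated by this single
quantitative rule).  Epochs extending past either end of the recording are
dropped with a logged warning.  Accepted epochs are averaged per stimulus
condition; empty cells are flagged missing, never zero-filled.

## Component measurement

Grand averages are unweighted means of subject averages (≥ 2 subjects).
N1 peak latencies are read from grand averages per region × stimulus
(search range 10–200 ms, ties to the earliest sample); the N1 window is
median ± 50 ms regardless of region and stimulus (even counts use the mean
of the two central values; windows are clipped at 0 with a warning).
Amplitude is the arithmetic mean over the half-open window, computed on
subject averages; SPN amplitude is the mean over t ∈ [2280, 2780) ms of the
pre-silence epoch.  Half-area latency integrates the polarity-consistent
part (|min(value, 0)| for negative components) with the trapezoid rule and
returns the earliest time where the cumulative area reaches half the
total, interpolated linearly between samples; zero polarity-consistent
area raises a flagged error (the pipeline then falls back to peak latency).
Restricting to the polarity-consistent lobe is the standard reading for
sign-changing waveforms and the only choice keeping the area positive.

## Statistics

Channel measures are averaged left/right into regions.  Shapiro–Wilk (per
stimulus × region cell) and Levene (across sexes) are advisory and never
gate the ANOVA; degenerate cells are skipped with a note.

The mixed three-way RM-ANOVA uses the balanced split-plot decomposition
with subjects nested in sex: sex is tested against subjects-within-sex;
each within effect (stimulus, region, stimulus × region, and their
sex interactions) against its own subject-interaction stratum.  At
n = 16 this gives df (1,14), (2,28), (2,28), (4,56).  Greenhouse–Geisser ε
uses Box's formula on the pooled within-sex covariance of orthonormal
(Helmert) contrast scores, clamped to [1/df₁, 1]; ε is exactly 1 for
2-level factors.  Corrected and uncorrected p are both reported; the
headline p is GG-corrected when a Mauchly chi-square test rejects
sphericity at 0.05 (the original software's conditional correction).
Partial η² = SS_effect/(SS_effect+SS_error).  α = 0.05 throughout.

Post-hoc comparisons are paired t-tests on subject-level marginal means
with Bonferroni multiplication (adjusted p capped at 1).  Ordering strings
(e.g. "MN > TN, DN") sort levels by component magnitude (more negative =
greater), group levels not separated at the corrected α, and list
within-group members in canonical order.  Simple effects run a one-way
RM-ANOVA of one factor inside each level of the other with the error term
computed within that level (self-contained and reproducible; the original
software's route is not documented), followed by the same pairwise
machinery.

When several exemplars of a stimulus class are presented (the four
conspecific-call exemplars), `pool_stimulus_pairs` first runs the same
mixed design with the exemplar as the within factor and pools by
subject × region averaging only when the exemplar main effect is null
(p ≥ 0.05), mirroring the original pooling step.

Latencies are analyzed with the same machinery as amplitudes; all
programmed latency effects are null.

## Problem sizes and numerical choices

Full-scale defaults reproduce the study geometry (1000 Hz, 120
replacements, 100 presentations per stimulus).  Multi-cohort simulation
studies use `RunConfig.scaled()`: 500 Hz sampling, 12 replacements per
voluntary session, 30 presentations per stimulus in reflexive sessions,
4 familiarization slots and no breaks — sizes chosen so a 100-cohort study
runs on one CPU in minutes while keeping ≥ 12 accepted epochs per SPN cell.
The pattern-recovery study scores four orderings per cohort: SPN region
main effect with telencephalon > mesencephalon; mesencephalic N1 dominance
in both paradigms; and the telencephalic screech > conspecific simple
contrast in the reflexive experiment.  Seeds derive from a single run seed
through `numpy` seed sequences; equal configurations produce bit-identical
outputs and manifest hashes.

Known limitations: EDF is read (via MNE) but not written — recordings
persist as delimited text with a JSON sidecar; the voluntary-session
printed duration depends on whether breaks are counted (no duration target
is defined for it); SPN amplitudes are reported after the analysis
band-pass, which attenuates slow ramps — comparisons across regions are
unaffected (the filter is linear and identical across channels), but
absolute SPN µV values are smaller than the injected terminal values.
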