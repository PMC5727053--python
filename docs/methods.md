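# Methods notes

This note documents the modeling and numerical choices behind `dfhm`: what
each stage computes, which parameters matter, what the synthetic generator
does and does not emulate, and where the design was genuinely open.

## Signal chain

**Filtering.** The bandpass is a linear-phase Hamming-window FIR
(`scipy.signal.firwin`, `order + 1` taps, default 0.5–40 Hz, order 100 at
500 Hz), applied in a single forward pass with the group delay
(`order/2` samples) removed, so outputs are time-aligned and band power in
the passband is preserved.  Zero-phase (forward–backward) filtering would
square the magnitude response; we keep the single compensated pass so the
response matches the designed filter exactly.  Edge samples within the group
delay at the recording boundaries are retained from the zero-padded
convolution rather than trimmed — deterministic and length-preserving.

A consequence of the short published filter order worth knowing: 101 taps at
500 Hz give a ≈16 Hz transition band, so the 0.5 Hz high-pass edge is *soft*
— a DC offset is attenuated to only ≈0.89 of its input value, and the upper
edge reaches −6 dB at 40 Hz.  This is harmless for the method (band powers
are read at 4 Hz and above, far from both edges; the unit tests pin the
6 Hz and 10 Hz passband gain to within 5 % of unity), but users expecting
DC rejection should demean or use a longer filter.

**ICA artifact removal** uses MNE's Infomax with a fixed seed.  The
automatic component classifier of the original system is proprietary to its
lineage; `dfhm` ships a documented heuristic as the default policy — a
component is removed if its scalp topography peaks on a fronto-polar
electrode *and* ≥ 60 % of its source power lies below 4 Hz (ocular
signature), or if its sample excess kurtosis exceeds 15 (sporadic
transients) — plus a plug-in interface (`ArtifactPolicy`) for anything
smarter.  Policy `"none"` bypasses rejection; ICA failure raises rather
than silently passing raw data through.

**Segmentation** restarts at every task-block boundary, so no segment mixes
tasks (a requirement for per-task portions to be well defined).  The count
per block is `floor((T − w)/s) + 1` for window `w = 10 s` and step
`s = 5 s`.

**Band power** is a single Hamming-tapered periodogram over the full 10 s
segment (no Welch averaging), summed over bins in `[low, high)` and scaled
so that a unit-amplitude in-band sinusoid yields its variance, 0.5 µV².
The half-open convention puts the 8 Hz bin in alpha only.  Absolute power
(µV²) is used rather than density or log power; the downstream z-scoring
makes the scale choice immaterial, but it is fixed and documented.  The
taper mainlobe (±0.2 Hz at 10 s) leaks a little energy across a band edge
when a component sits exactly on it; tests account for this.

**Personalization.** Baselines use all segments lying fully inside the
first 60 s of each block — 11 per block at the default grid; windows
crossing the boundary are excluded (conservative, deterministic).  Rest
blocks are included by default (`include_tasks` restricts them) because
they widen the sampled range of the subject's oscillatory states; this is
configurable since protocols differ on whether rests count as "tasks".
Standard deviations use the n−1 (sample) convention: the baseline is a
small sample of the subject's state space.  A zero SD anywhere is an error
naming the electrode — z-scores would be undefined.

**Map labeling.** The original reference labels were assigned by visual
inspection of the maps.  `dfhm` codifies that judgment as a symmetric
threshold rule on the frontal and parietal region means: frontal mean
≥ +0.5 and parietal mean ≤ −0.5 z-units → high; the mirror image → low;
anything else → moderate.  The ±0.5 default is this package's own surrogate
for "pronounced" and is configurable (`LabelRule`) for sensitivity studies.
For training-set selection, the deterministic "one first-minute segment per
measurement" is the block's first complete window (offset 0); the demanding
span-type dual task is excluded by default, and selected maps are flagged so
evaluation summaries can drop them.

**Classifier pair.** The kernel convention is fixed to
`k(x, y) = exp(−‖x−y‖²/(2σ²))`, i.e. scikit-learn's `gamma = 1/(2σ²)`;
implementations using a different "width" convention must convert.
Monte Carlo cross-validation stratifies splits by the three-way label by
default (unstratified mode available), and is bit-reproducible for a fixed
seed.  Decisions are hard labels — the index logic consumes booleans.  The
conflict case (both detectors positive) is not defined by the logical
combination's truth table; it is mapped to moderate, the least-committal
class, with a config switch to raise instead when auditing.

**Statistics.** The portions table is analyzed with pingouin's
repeated-measures ANOVA; the reported `df1/df2` are Greenhouse–Geisser
corrected (`ε·(k−1)`, `ε·(k−1)(n−1)`), and post-hocs are paired t tests with
Bonferroni adjustment over the full family of level pairs at family
α = 0.05.  Listwise completeness is required — an incomplete subjects×levels
table is an error, never silently dropped.  The test family for post-hocs is
paired t (the least-surprising reading of "multiple paired comparisons").

## Synthetic cohorts: what is emulated, what is not

The generator works at the channel level — no dipole/forward model.  Per
block it superimposes, on every channel, unit-variance 1/f^1.0 noise scaled
to 10 µV RMS, and adds amplitude-modulated oscillation bursts: theta
(carrier drawn uniformly in 4–8 Hz) on frontal channels with base amplitude
6.5 µV × the block's `theta_gain_frontal`, and alpha (8–12 Hz) on parietal
channels with base 5 µV × `alpha_gain_parietal`.  With the moderate profile
(gains 1.0) the in-band signal-to-background power ratio is ≈ 2 — strong
enough to drive the index, weak enough that single-segment estimates are
noisy.  Burst envelopes interpolate lognormal-ish node draws every 2 s
(SD 0.1), so band power varies segment to segment and baseline SDs are
non-degenerate.

Two slower sources of variation matter for realism:

* **Latent workload-state drift** — an AR(1) process (5 s nodes,
  autocorrelation 0.6, SD 0.35 on the log-amplitude) shared by all channels
  within a block, pushing theta up and alpha down together.  Real task
  blocks are *mixtures* of states; this drift is what makes per-task class
  portions a graded statistic (e.g. a demanding block at ~60 % high-load
  segments) rather than 0 or 100 %.
* **Per-subject gain jitter** — one lognormal multiplier per subject and
  band (SD 0.1).  Because z-scoring is affine-invariant per electrode, this
  checks that personalization actually removes inter-individual amplitude
  scale, rather than injecting cross-subject signal.

Graded condition profiles default to theta/alpha gains (0.6, 1.5) for low,
(1.0, 1.0) for moderate, (1.7, 0.5) for high, and (1.35, 0.7) for the
held-out stop-signal-type validation task (ground truth: high, sitting
between moderate and high).  The standard session is two 3 min rests framing
nine tasks (5–20 min each, 81 min total); `scale_battery` shrinks durations
for desk-scale studies, flooring at 60 s so the baseline minute always
exists (a scaled 3 min rest becomes 60 s).

Not emulated: volume conduction and electrode covariance structure, non-EEG
physiology (ECG/EMG), electrode drift and impedance artifacts, fatigue
trends across the session, and any behavioral coupling.  Passing end-to-end
tests on this generator therefore demonstrates the *pipeline's* correctness
and the method's internal logic — not clinical validity on human EEG.

### The map-space generator and kernel geometry

The classifier-level generator draws maps directly in z-space around three
archetypes — region means (−m, +m), (0, 0), (+m, −m) for (frontal,
parietal) with margin m = 1 — adding region-coherent jitter (SD 0.05) and
per-electrode jitter (SD 0.05), then labels them with the threshold rule
(so labels are rule-consistent by construction).

The tight default jitter deserves explanation.  With the fixed kernel
convention, the high-load detector's published width σ = 0.3 makes
`k ≈ exp(−d²/0.18)`: the kernel is effectively zero beyond map distances of
~0.6 z-units in the 25-dimensional map space.  Such a machine only
discriminates when same-class maps cluster within that reach — which is
evidently the geometry of the corpus the width was originally selected on.
The generator's defaults reproduce that geometry; with them, the Monte
Carlo accuracies land above the published recognition rates but below 100 %
for the high-load machine (the accuracy-limiting detector, matching its
lower published rate).  Wider within-class spread collapses the σ = 0.3
machine to majority-class behavior — a property worth knowing before
transferring the published hyperparameters to new feature scalings.

For the same reason, the *end-to-end* cohort study selects its
hyperparameters empirically on its own training corpus (a small (C, σ) grid
scored by Monte Carlo CV — the same "empirically selected" procedure that
produced the published values on the original corpus) rather than assuming
the published widths transfer to pipeline-derived maps, whose within-class
spread (band-power estimation noise plus state drift, ≈ 0.2–0.5 z per
electrode) is far beyond the σ = 0.3 reach.  On synthetic training cohorts
the grid typically selects (C = 3, σ = 3) for both detectors.  Relatedly,
the study rule-labels *all* maps of the training cohort rather than only
the 1-per-measurement first-minute selection: the generator's low/moderate
first-minute maps essentially never wander into the high-load region the
way human data do, so the strict selection would yield a training set with
no high-load examples at desk scale.

## Numerical details and degenerate inputs

* All seeds are explicit; per-subject streams derive from
  `SeedSequence([seed, subject_index])`, so cohorts are reproducible and
  subjects independent of cohort size.
* BrainVision output is IEEE float32 multiplexed; float32 data round-trips
  bit-for-bit.  EDF output is 16-bit with per-channel physical scaling
  (round trip exact to the quantization step, ~range/2¹⁶).
* Empty batteries, single-channel ICA input, zero-variance baselines,
  single-class training sets, dimension mismatches and incomplete ANOVA
  tables all raise typed errors (`ValidationError` and subclasses) rather
  than degrading silently.
* Desk-scale study sizes used by the test suite: 540-map corpora for the
  classifier; 4 training + 8 evaluation subjects at battery scale 0.2 for
  the cohort study.  These sizes are the package's chosen defaults for fast,
  deterministic verification; the pipeline itself streams subjects and runs
  at full session length.

## Known limitations

* The default 25-electrode montage is a reconstructed 10–20 layout
  (Cz-referenced cap); real caps must supply their own label/region mapping.
  The frontal/parietal split of the central row is a convention (central row
  → parietal) and configurable.
* The artifact-component heuristic is deliberately simple; for publication-
  grade artifact handling plug in a trained classifier.
* The index's absolute class portions depend on the label-rule threshold
  (±0.5 z) and on baseline composition (with vs without rests); comparisons
  should hold these fixed.
* Published recognition rates are reproduced in the sense of *procedure*
  (same corpus size, split protocol, hyperparameters, margin) on synthetic
  maps; human-cohort statistics (ANOVA F values on real data) are not
  reproducible without the original recordings.
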