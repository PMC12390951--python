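# Methods

`neorhythm` re-implements, as a tested offline pipeline, the stimulus design,
signal processing and statistics of a block-design fNIRS experiment probing
auditory beat perception in premature neonates. Real neonatal recordings are
privileged data; a forward-model simulator generates synthetic sessions with
the same acquisition geometry, rates and protocol, so every stage of the
inverse chain is exercisable and checkable against known ground truth.

## Stimulus design

**Base rhythms.** Five beat-based sequences are built from four onset-to-onset
interval categories: the fastest interval is 1 time unit, the others 2, 3 and
4 units. A sequence has 42–45 intervals (43–46 tones) and a total length of
94–102 units, so every tempo rendering falls in the 13–24 s window once the
0.5 s tone tail is included. The concrete interval patterns are generated, not
transcribed: sequences are assembled from 2-unit beat cells — `2` and `1+1`
keep a tone on the beat; the two-beat cells `4`, `3+1` and `1+3` skip one grid
beat each — with the number of beat-skipping cells bounded so that at least
80 % of grid beats carry a tone. Cell shuffling provides the variety between
the five bases; all constraints hold by construction and are re-checked by
property tests.

**Arrhythmic controls.** For each base, within every interval category a
random third of the intervals is shortened by 20, 25 or 33 %, a third kept,
and a third lengthened by the same factor set; the full interval list is then
shuffled uniformly. Category sizes not divisible by 3 have the remainder
allocated randomly among the three labels. The shorten and lengthen groups of
a category draw from one shared factor multiset, so the category's total
duration change cancels up to the ±1-count remainder; this duration-matching
refinement is needed because the 30 renderings derive from only five
independent sequences, and a paired t-test across such pseudo-replicated
pairs detects even a fraction-of-a-percent systematic length bias.

**Rendering.** Each base and its control are rendered at three tempi
(1 unit = 140, 185, 230 ms) and two pitches (440/880 Hz): 30 stimuli per
condition. Tones are percussive bursts (5 ms linear attack, exponential decay
with τ ≈ 60 ms) at 44.1 kHz, with ~1 dB per-tone amplitude and ~10 %
decay-time variation emulating naturally produced strikes (draws are
deterministic per stimulus). Waveforms are normalized to a common RMS —
constant presentation loudness — rather than to peak; arrhythmic sequences
have more tone overlap and a higher crest factor, and peak normalization
would systematically depress their envelope power.

**Envelope equivalence.** The amplitude envelope is the magnitude of the
analytic signal, decimated to 100 Hz and zero-padded to one shared
4096-sample FFT (Δf ≈ 0.024 Hz), so all stimuli live on one frequency grid
and the 0–10 Hz average power is comparable across unequal durations. The
generator accepts an arrhythmic draw only if paired t-tests detect no
duration or 0–10 Hz power difference at α = 0.05 (redrawing with the next
derived seed otherwise) — the same validation gate the experimental design
imposes on its stimulus set. Beat-frequency power (at 1/(2 units)) is higher
for the rhythmic member of every matched pair on the default set.

**Protocol.** The 60 stimuli are ordered with no run of three or more
same-condition blocks and no consecutive blocks from the same base rhythm
under a different tempo or pitch, via greedy random construction restarted on
dead ends (capped at 10 000 restarts); silent gaps are drawn uniformly from
25–35 s.

## Synthetic sessions

**Montage.** Each hemisphere carries 10 emitters and 8 detectors on a 2-D
lateral scalp plane; channels are all emitter–detector pairs with 15–40 mm
separation, located at the pair midpoint. The frozen fixture yields 39 left /
40 right channels with mirrored region labels and at least three channels per
hemisphere in each analysis ROI (auditory, sensorimotor, premotor). There is
no photon-migration head model: ROI membership is declared per channel,
mirroring the functional-ROI logic of the analysis.

**Hemodynamics.** The HbO impulse response is a single gamma kernel with its
mode at 10 s (shape 9), unit peak, decayed to <2 % by 25 s; HbR is −1/3 × HbO
(only HbO is analyzed downstream). Each block contributes one unit-peak HRF
at its onset: the neonatal response to these long blocks is modeled as
non-sustained, peaking near 10 s regardless of block duration. A
duration-long boxcar drive was rejected because it keeps rising through the
whole epoch, contradicting the ~10 s peak the analysis is built around, and
because the impulse form makes noise-free trial averages equal the injected
kernel exactly — the pipeline's recovery oracle.

**Noise and artifacts** (defaults, per channel, in µM): cardiac 0.4 at
≈2.5 Hz, respiratory 0.4 at ≈1 Hz, Mayer waves 0.5 at ≈0.1 Hz (each with ±5 %
frequency jitter and random phase), white noise 0.3 per sample, and a
normalized random-walk drift scaled to 0.3. Motion artifacts: half-sine
spikes (0.5–2 s, amplitude 2–10× the detection threshold expressed in
concentration units, hitting a random group of 3–8 channels; 2 per session)
and baseline steps (1 per session). Responses default to 1.0 µM HbO peak with
a lognormal (σ = 0.3) per-participant scale; the default condition effect
raises the rhythmic amplitude by 60 % on right-sensorimotor and left-premotor
channels. These levels were chosen so that single-trial responses sit near
z ≈ 1 against the physiological background — typical for infant fNIRS — and
were frozen after a design-stage power check that the default cohort of 11
meets the pipeline's stated recovery properties.

**Forward model.** OD_λ = (ε_HbO,λ·ΔHbO + ε_HbR,λ·ΔHbR) · L · DPF_λ with
tabulated molar extinction coefficients (690 nm: 276 / 2051.96; 830 nm: 974 /
693.04 cm⁻¹ M⁻¹, pinned in `data/extinction_coefficients.json`), separation
in cm and neonatal DPF 5.4 / 4.7 at 690 / 830 nm; intensity I = 10^(−OD) with
unit baseline (arbitrary units cancel in OD). Sessions are written as SNIRF
(HDF5) plus an events TSV.

## Preprocessing

Intensity → OD relative to the channel's temporal mean; zero-phase 3rd-order
Butterworth band-pass 0.03–0.5 Hz (filter order and type are package choices;
the band is part of the design); MBLL inversion with the same extinction/DPF
tables (forward-then-inverse is the identity to machine precision). Motion
detection flags any sample whose |ΔHbO| × separation exceeds 0.01 Molar·mm,
masking 3 s around it on that channel, or on all channels when more than 10
channels flag the same sample. Channels are z-scored over unmasked samples of
the whole recording. Epochs span −5 to +25 s around block onsets (half-open,
0-based sample indexing, 304 samples at 10.1215 Hz), linearly detrended over
the whole epoch then baseline-corrected by the −5–0 s mean.

Four trial-rejection rules, evaluated in order (first hit recorded): (1) any
within-trial |z| > 3; (2) any |z(t+0.4 s) − z(t)| > 1.5; (3) area under the
post-onset curve below 10 z·s; (4) overlap with the motion mask. The AUC
statistic defaults to the integral of |z| ("abs" mode): the rule's role is to
drop flat, dead trials, and a signed integral cannot plausibly reach 10 z·s
for a detrended z-scored epoch — signed mode would reject essentially all
trials, contradicting the modest channel-discard counts the rule produces in
practice. Signed mode remains available (`auc_mode="signed"`), and both the
threshold and interpretation are configurable because the original units are
ambiguous.

A channel × condition is excluded when more than 80 % of its trials are
rejected (80 % exactly is retained); kept trials are averaged over tempi and
pitches per condition, downsampled to 1 Hz by non-overlapping 1-s bin means
(anti-aliasing already ensured by the 0.5 Hz low-pass; bins are labeled by
their left edge, −5 … 24 s). Group analyses retain channels with at least 4
contributing participants. The study's manual channel screen is replaced by
an automated criterion (raw-intensity coefficient of variation > 0.5 marks a
channel bad) — a documented deviation.

## Statistics

**Rising slope.** slope = (HbO_peak − HbO_onset)/(t_peak − t_onset), with the
onset value at t = 0 and the peak the maximum strictly after onset within
0–25 s (so the denominator is positive); normalized slope =
(slope_RC − slope_AC)/(slope_RC + slope_AC), NaN with a warning when the
denominator is zero.

**Cluster permutation tests.** Pointwise paired t-tests are thresholded at
the two-sided α = 0.05 critical value (per-point degrees of freedom where
participants are missing); supra-threshold points of equal sign are grouped
into contiguous temporal runs or spatially connected channel sets and scored
by summed t. The null distribution of the maximal cluster mass is built from
participant-level sign flips of the paired differences: exhaustive
enumeration when 2ⁿ fits the permutation budget (n ≤ 12), otherwise sampled
flips with duplicates allowed, and p = (1 + #{null ≥ observed})/(1 + n_perm).
Spatial neighbors are same-hemisphere channels whose midpoints lie within a
radius that defaults to the smallest value giving every channel at least two
neighbors on the fixture montage (20.5 mm); singleton clusters are permitted
(`min_cluster_size` can require more). Sign-flip nulls are exact under
exchangeability; the suite verifies the family-wise error empirically.

**ROI analysis.** Mean HbO over 8–12 s inclusive (5 bins at 1 Hz), averaged
over retained channels per ROI × hemisphere, feeds a fully within-subject
three-way ANOVA (condition × ROI × hemisphere) implemented by balanced
sums-of-squares decomposition with orthonormal contrasts; each effect's error
term is its subject interaction, partial η² = SS_eff/(SS_eff + SS_err), and
Greenhouse–Geisser-corrected p-values accompany every multi-df effect (with
Mauchly's test; uncorrected values always reported). Follow-ups mirror the
design: two ROI × hemisphere ANOVAs (per condition), three condition ×
hemisphere ANOVAs (per ROI), and Tukey–Kramer post-hocs on ROI using the
studentized range with the ROI × subject mean square. The implementation is
cross-checked in the tests against statsmodels `AnovaRM` (F, p) and pingouin
(Greenhouse–Geisser, Mauchly). Participants with an empty ROI cell are
dropped from the ANOVA (as participants with too few remaining trials are
dropped in practice).

## What the simulator does and does not show

The generator reproduces the design's structure (block protocol, montage,
sampling, dual-wavelength forward physics, ~10 s response, physiological
rhythms, spike/step artifacts, condition-specific sensorimotor/premotor
effects) but not real-data phenomena such as serial correlations of infant
state, habituation across the 52-minute session, optode-coupling drift,
heterogeneous channel SNR, or true neonatal HbR dynamics. Passing recovery
tests therefore demonstrates that the pipeline is correct and powerful under
its stated model — not that the biological effect sizes are as assumed.

## Problem sizes and numerics

Unit and property tests run on single sessions or crafted fixtures; the
permutation-validity checks use 500 null cohorts (n = 11, 30 time points, 200
permutations) and 10 exhaustive-vs-sampled comparisons at n = 8 with 8000
sampled flips (Monte-Carlo error ≪ the 0.02 agreement band); parameter
recovery uses 50 effect cohorts and 12 null cohorts of 11 participants with
the full 60-block protocol and 800-permutation spatial tests. Tolerances:
MBLL round-trip 1e-6 µM (observed ~1e-14); filter gains checked at 0.005/0.1/
2 Hz; ANOVA cross-checks at float precision. Ties in peak picking resolve to
the earliest sample; degenerate inputs (zero variance, empty categories,
all-rejected channels) follow the documented guards rather than erroring
where the design prescribes best-effort behavior.
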