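# Methods

## Scope

`mromgla` implements the computational chain linking orthographic
similarity to region-level brain responses: an interactive-activation
word-recognition network with multiple read-out lexical decision, the
global-lexical-activity (GLA) familiarity measure, orthographic lexicon
statistics, constrained construction of GLA-graded word/nonword stimulus
sets, and the balanced 2 × 3 repeated-measures trend analysis of
per-region signal-change tables. Voxelwise fMRI computation (GLM fitting,
HRF convolution, normalization, cluster inference) is out of scope: the
analysis starts from extracted per-subject, per-condition scalars.

## The lexical network

Units are position-specific letters (positions × alphabet) and one unit
per lexicon word. A word of length L receives excitation from its own
letter-at-position units (gain 0.07), inhibition from every other letter
unit at positions 1..L (0.04), lateral inhibition from all other word
units (0.10), and sends excitatory feedback to its own letters (0.30).
Letter evidence is clamped directly at the letter layer (+1 for the
stimulus letter at each position, −1 for its competitors); there is no
visual-feature layer because the stimuli modelled are clear static
letter strings. Updates are synchronous with positive-part ("active
senders only") contributions:

    da = net · (a_max − a) − θ (a − rest)   if net > 0
    da = net · (a − a_min) − θ (a − rest)   otherwise,

clipped to [a_min, a_max] = [−0.2, 1.0], decay θ = 0.07. A single unit
under constant positive net input n converges to
a* = (n·a_max + θ·rest)/(n + θ); this closed form anchors the numerical
tests. Word resting levels map log10(freq+1) linearly onto
rest_range = (−0.92, 0): the most frequent word rests at 0. Resting
levels below a_min are realized at the a_min floor (the stored rest value
still acts as the decay attractor), so every activation, including the
initial state, respects the bounds.

**Lateral word–word inhibition is 0.10, not the classic 0.21.** With
0.21 the target unit dominates word-layer activity: its neighbors are
laterally suppressed and, under Zipf-distributed frequencies, mostly
rest too deep to turn positive within the seven-cycle GLA window, so the
GLA of words decouples from neighborhood density (r ≈ 0.4 at best). The
construct being modelled is a familiarity signal that *rises* with
neighborhood density for words and nonwords alike (reported couplings in
this paradigm are ≈ 0.75–0.8); at 0.10 the package reproduces that
coupling (≈ 0.6 for words, 0.65–0.85 for nonwords) while identification
and rejection behavior are unchanged. All gains are configurable in
`ModelParams`.

## Global lexical activity

Raw GLA of a stimulus is the mean over post-stimulus cycles 1..7
(cycle 0 is rest and is excluded) of the summed positive word-unit
activation, then z-scored with the sample (n−1) standard deviation over
the joint word+nonword candidate pool. Per-lexicality z-scoring is
available as an option. The S read-out criterion compares *instantaneous*
summed activity; GLA-the-measure is the 7-cycle mean.

## Multiple read-out lexical decision

At each cycle, three criteria are checked in order:

* **M** — any single word unit ≥ m_criterion (0.55) → YES
  (identification);
* **S** — instantaneous summed positive word activity ≥ S′ → YES (global
  fast guess);
* **T** — cycle reaches the deadline T′ → NO.

At cycle τ = 3 the momentary global activity g is read out and
linearly shifts the adjustable criteria: T′ = round(20 + 10·g) and
S′ = max(0.4, 1.1 − 1.5·g). High early activity therefore both delays
the rejection deadline and lowers the fast-guess threshold — wordlike
stimuli are accepted faster and rejected slower, the two classic
neighborhood effects. The numeric read-out defaults were fixed once from
the separation in activation magnitude between words (single-unit
maximum ≈ 0.6–0.7, early global activity ≈ 0.3–0.4) and nonwords
(≤ 0.5 and ≈ 0–0.15) so that words are identified before the deadline
and nonwords mostly time out; they are deliberately round values inside
those gaps, not fits to human data (no RT fitting is attempted).

## Orthographic measures

Neighbors are same-length words at Hamming distance 1 (substitution
neighbors); N counts them, FN sums their frequencies, NHF/FHN count and
sum the neighbors more frequent than the target (nonwords carry implicit
frequency 0, so all their neighbors count as higher-frequency). Bigrams
are adjacent ordered letter pairs, position-independent by default
(position-specific matching is a switch): BiC counts token occurrences
of the target's bigrams in other words, BiN the words sharing at least
one bigram, BiF their summed frequency. Type counting (each shared
bigram type once per word) is available; token counting is the default
reading of "number of times the bigrams occur". LogF = log10(freq+1), the
offset keeping zero-frequency entries finite.

## Stimulus construction

From the four-letter words of the lexicon, a pool of 2000 nonwords is
generated by substituting 1–4 uniformly chosen positions with uniformly
chosen different letters, excluding strings that are themselves words.
GLA is simulated for the joint pool and z-scored jointly. Selection then
returns 300 words and 300 nonwords whose z-GLA samples are each
normally distributed (Shapiro–Wilk p > 0.10), differ in mean (Welch
p < 0.01) and have equal variances (median-centered Levene p > 0.10).

Because simulated GLA distributions are lumpy — nonwords with no
neighbors form an atom at zero, and neighbor counts quantize the rest —
blind rejection subsampling cannot satisfy a Shapiro test at n = 300.
Selection therefore proposes samples by matching candidates to the order
statistics of two normal distributions with a common sd and separated
means, searching a deterministic grid of per-class centers (percentiles)
and scales, followed by seeded random proposals with trimming of
extreme-tail candidates; the three statistical constraints are always
re-tested on the returned samples, and failure raises an error carrying
the best attempt's p-values. The whole procedure is a pure function of
its seed.

Tertile GLA levels (low/medium/high) are assigned within lexicality by
ranking on z-GLA, stable on input order for ties; level sizes differ by
at most one (remainders go to low, then high). Descriptor tables report
per lexicality × level means of GLA, LogF, Fmio, N, FN, BiC and BiF
(frequency columns blank for nonwords); GLA is reported on the raw
scale, with the z values carried in the full stimulus table.

## Region trend analysis

Input is a balanced subject × lexicality(2) × GLA-level(3) table of
scalar signal change. The two-factor within-subject ANOVA tests each
effect against its own subject-by-effect interaction; no sphericity
correction is applied by default because the convention modelled reports
uncorrected dfs (with n = 20: main effects (1, 19)/(2, 38), interaction
(2, 38)). Polynomial trend contrasts use weights (−1, 0, +1) and
(+1, −2, +1) on the ordered levels, each tested against its
subject-by-contrast error, df (1, n−1); the decomposition
SS_linear + SS_quadratic = SS_GLA is exact. Simple effects of GLA are
computed per lexicality slice with the slice-wise error term, df
(2, 2(n−1)); a pooled-error option exists. Sums of squares are computed
after grand-mean centering, which is algebraically neutral and keeps
degenerate (constant) tables at exactly F = 0.

`classify_region_profile` labels a region by its per-lexicality linear
contrasts: word-significant only → `word-specific-linear`,
nonword only → `nonword-specific-linear`, both → `shared-linear`;
with neither, a significant GLA main effect is `shared-linear` when its
pooled linear contrast is significant and `interaction-nonlinear`
otherwise; otherwise `null`. The per-lexicality contrasts decide first —
without an omnibus-interaction gate — because interactions of realistic
size in this design are routinely marginal while the slice-wise trend is
clear (by noncentral-F computation, the 2-df interaction has only ≈ 50%
power at the effect size the recovery simulations use, while the word
linear contrast has ≈ 85%). The sign of the relevant trend (high minus
low) is attached as the direction.

## Synthetic data generators

**Lexicon.** 1025 unique strings over consonant/vowel skeleton templates
(CVC; CVCC, CCVC; CCVCC, CVCCC) with 13 consonants and 5 vowels, lengths
3/4/5 in proportions 0.25/0.54/0.21 (a little over half four-letter, as
in the emulated material). This is a statistical emulation of a
monosyllabic lexicon — enough structure to induce non-degenerate
substitution-neighbor overlap (the generator re-draws if fewer than 10%
of four-letter words have a neighbor), not a phonotactic grammar, and no
claim to any real language's phonology. Frequencies are Zipf: rank r
gets freq_max·r^(−s) per million with s = 1.05 and freq_max = 2000,
ranks assigned by a seeded permutation so frequency is independent of
string structure. Realized neighborhood density (mean N ≈ 1 for
four-letter words) is sparser than a natural dense lexicon; the
correlations and benchmark effects computed on synthetic sets therefore
echo the direction and rough strength of their empirical counterparts,
not their exact values.

**Region signals.** value(s, ℓ, j) = grand_mean + b_s + slope_ℓ·j + ε
with b_s ~ N(0, subject_sd²), ε ~ N(0, residual_sd²), levels coded
j = 0, 1, 2. Defaults: 20 subjects, grand_mean 0.2, subject_sd 0.1,
residual_sd 0.1, slopes 0 (all in the arbitrary units of percent signal
change). Noise is Gaussian and homoscedastic — the assumption the ANOVA
makes anyway; real BOLD signal-change tables additionally carry
heteroscedasticity and cross-condition correlation that the generator
does not emulate, so passing recovery tests demonstrate correctness of
the statistics, not robustness to those violations.

## Problem sizes and numerical choices

* Simulation-based checks run at sizes chosen to keep the full suite in
  tens of seconds: RT benchmark directions over 50 seeded 500-word
  lexicons (15 extreme-N items per set, sign tests), selection self-audit
  at the full 300+300 scale on a 1025-word lexicon, ANOVA oracle on 100
  random tables, type-I calibration on 1000 null tables, power/profile
  recovery on 200 replicates with word slope 0.5·residual_sd.
* Dynamics equivalence uses max |Δ| < 1e−10 against a loop-coded naive
  oracle; the closed-form asymptote 1e−8 after 5000 iterations on a grid
  whose fixed points lie inside the activation bounds; GLA golden values
  1e−12.
* Degenerate inputs: empty lexicons, single-letter alphabets, constant
  z-inputs, unbalanced tables, windows longer than traces and targets
  shorter than a bigram all raise typed errors rather than propagating
  NaNs.

## Known limitations

* The network has no visual-feature layer, no letter-position noise, and
  no phonological read-out; RTs are in cycles and are not fitted to
  human latencies.
* The exact historical parameterization of the multiple read-out model
  is not recoverable from the sources emulated here; the S-criterion's
  instantaneous-vs-integrated choice and the criterion-adjustment gains
  are declared conventions (configurable), not estimates.
* Nonword higher-frequency-neighbor statistics depend on the implicit
  frequency-0 convention.
* The profile classifier uses fixed α = 0.05 per region with no
  multiple-testing correction across regions, mirroring per-region
  reporting practice.
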