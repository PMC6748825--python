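# Methods

`finchsong` quantifies how well a juvenile Bengalese finch copies the
spectral content of a tutor song, and simulates tutoring experiments in
which the instructive stimulus is matched or mismatched to a bird's
heritable tempo bias. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic generator does and
does not emulate.

## Segmentation and tempo

Songs are high-pass filtered (elliptic IIR, order 4, 0.05 dB passband
ripple, 40 dB stopband, passband edge at 0.04 × Nyquist = 640 Hz at
32 kHz — the "~500 Hz" regime; the small ripple keeps repeated filtering
nearly idempotent for passband content) and reduced to an amplitude
envelope by
full-wave rectification and convolution with an 8 ms unit-area square
kernel. Filtering is zero-phase (forward–backward) so that syllable onsets
are not delayed; onset timing feeds the tempo statistic directly.

Syllables are uninterrupted supra-threshold envelope regions. Candidate
regions separated by ≤ 5 ms are merged *before* the duration filter, then
regions are kept only if strictly longer than 10 ms. Runs of syllables with
no gap exceeding 250 ms (inclusive) form a song bout. The automatic
threshold is `floor + k·(peak − floor)` with floor = 10th percentile,
peak = 95th percentile, `k = 0.1`; this rule is scale-equivariant, so
segmentation is invariant to recording gain. All boundary conventions
(merge ≤ 5 ms; keep > 10 ms; bout gap ≤ 250 ms) are deliberate and tested.

Song tempo is the syllable count of a bout divided by its first-onset to
last-offset duration, averaged over bouts. Sixty bouts is the nominal
corpus size; smaller corpora are scored but flagged (`reliable=False`) —
the floor is a data-quality rule, not part of the statistic. Father-song
tempos are binned slow / medium / fast at 7.5 and 9.5 syl/s with both
edges in "medium".

## Song Divergence

Each bird's spectral repertoire is modelled from a corpus of song bouts:

1. one Welch PSD per segmented syllable (512-sample windows, 50% overlap,
   500 Hz–16 kHz band, unit-sum normalized) — a single PSD per syllable
   deliberately discards within-syllable temporal structure, so the score
   is orthogonal to tempo;
2. each PSD is mapped to its Pearson correlation (on log power) with a
   random basis of 50 reference syllables drawn from the pooled
   tutor+tutee set, then reduced to 10 whitened principal axes fitted on
   the pooled set — both birds share one coordinate system;
3. a Gaussian mixture (diagonal covariance) is fitted per bird, the
   component count chosen by BIC over 2–12 with 5 EM restarts;
4. the Song Divergence is the Monte-Carlo estimate of
   KL(tutor ∥ tutee) = E_tutor[log₂ p_tutor − log₂ p_tutee] bits, with
   10⁵ draws from the tutor model, clamped at zero.

The score is directional: it measures tutor content missing from the tutee
and ignores tutee improvisation (tested: adding tutee-only syllable types
shifts SD by far less than corrupting tutor content does).

### Numerical choices

*Covariance floor.* EM covariances are floored at `reg_covar = 0.05` per
whitened axis (i.e. 5% of per-axis variance). This is a density-smoothing
choice, not just a conditioning fix: KL between two *independently fitted*
mixtures of the same repertoire is positively biased by model-fit variance,
and with near-degenerate components that bias is large and seed-noisy. The
floor bounds how sharply either model can concentrate, which keeps the
self-comparison near zero while leaving an ample dynamic range (corrupted
songs score 5–100 bits). With 60-bout corpora the self-comparison floor is
about one bit; "perfect copy ≈ 0" should be read on that scale.

*Component range.* The BIC scan stops at 12 components. Wider scans let the
two birds' models split the same syllable cluster differently, which
inflates the self-comparison without improving sensitivity; 12 comfortably
covers the 9-type repertoire plus corruption-induced satellite clusters.

*Monte-Carlo error.* The KL estimator reports a standard error from the
per-sample log-ratios; it shrinks as 1/√n (tested at n = 10³…10⁵) and the
single-Gaussian limit reproduces the closed-form Gaussian KL within three
standard errors.

*Reference convention.* For one-exemplar computer tutors, tutees are scored
against a designated well-learned reference corpus (here: a simulated bird
with corruption 0), not against the stimulus itself; the same reference
serves every bird in an experiment.

## The synthetic song generator

The canonical stimulus is two short introductory syllables followed by
three repetitions of a seven-syllable motif — nine categorically distinct
types: 2 noisy intro notes, 3 harmonic stacks (fundamentals 700, 1100,
1600 Hz), 2 noise bands (2–4, 5–8 kHz), 2 linear FM sweeps (2→6, 7→3 kHz),
durations 25–100 ms. Inter-syllable gaps follow a fixed relative pattern
(shorter after intro notes, longer between motifs) scaled so the nominal
tempo is exactly 8.5 syl/s; per-gap SDs default to 15% of the mean,
truncated at 2 ms. Rendered bouts carry their ground-truth onsets and type
ids, and are padded with 300 ms of near-silence so bout grouping is
unambiguous.

*Retiming* scales every gap mean and SD by the single factor
`g = (N/target − Σdurations) / Σgaps`, leaving syllable waveforms
untouched — variants at 6.5 and 10.5 syl/s have identical spectral content
by construction, and infeasible targets (non-positive gaps) raise.

*Tutees.* A simulated learner sings the tutor song at
`tutor + pull·(bias − tutor)` with `pull = 0.75` (juveniles' tempos are
strongly drawn to their fathers'), and copies spectral content with
errors controlled by an effective corruption level

    c_eff = min(1, c₀ + w·κ·|tutor tempo − bias|)

where `c₀` is baseline infidelity, `κ` the mismatch coupling, and `w ≥ 1`
an optional extra weight when the tutor is *faster* than the bias (the
generator's asymmetry hypothesis). Copy errors are per-bird *systematic*:
for each syllable type the bird either consistently substitutes another
type (probability 0.3·c_eff) or consistently displaces its frequencies
(log-normal, SD 0.25·c_eff), plus a per-rendition dropout (0.2·c_eff) and
an always-on 2% rendition-to-rendition frequency jitter. The rendition
jitter exists because real adult song varies between renditions; without
it, fitted clusters are near-degenerate and the divergence is dominated by
estimation noise. Making mis-copying systematic (rather than i.i.d. per
rendition) matches how real tutees err — a badly copied syllable is sung
badly every time — and is what gives SD a smooth, monotone response to
corruption.

The coupling is a generator *hypothesis*: the study phenomenon (matched
tutoring yields better spectral copying) is imposed so that pipeline-level
analyses have recoverable structure. Nothing in the generator mimics real
finch acoustics beyond category structure, so passing tests demonstrate
that the measurement and analysis pipeline recovers known ground truth —
not that it would behave identically on recorded song (no reverberation,
cage noise, amplitude modulation, syntax variability, or developmental
drift is modelled).

## The 3×3 experiment and statistics

`run_grid_experiment` simulates cohorts from slow / medium / fast genetic
backgrounds (father tempos 7.18, 7.89, 10.31 syl/s — colony lower decile,
median, upper decile) tutored at 6.5 / 8.5 / 10.5 syl/s, with defaults
`c₀ = 0.05`, `κ = 0.08`, `w = 2`. Each bird's match category uses the
nearest-tutor rule (its tutor is "matched" if it is the grid tempo closest
to the father's tempo). The analysis reports per-cell mean SD (min–max
normalized across the nine cells for display), and partitions SD variance
by match category, background alone, and tutor tempo alone via one-way
ANOVA with omega-squared

    ω² = (SS_between − (k−1)·MS_within) / (SS_total + MS_within), clamped at 0,

Holm-corrected as one family. Under the coupled generator the match
category dominates both single factors, the matched category has the
lowest mean SD, and with `w > 1` unmatched-slow tutoring beats
unmatched-fast — the qualitative interaction pattern the pipeline is
designed to detect.

Other analyses: within-nest home vs cross-fostered medians compared by
Wilcoxon signed-rank (zeros dropped; exact null for n ≤ 25 without ties,
midrank normal approximation otherwise); Welch t tests, one-tailed at the
0.025 level when the hypothesis is directional; maximum-likelihood gamma
fits (location fixed at 0, since SD ≥ 0) with the 50th/80th percentiles of
the fit; and Pearson trade-off correlations of SD with tutee tempo and
with |tutee − tutor| tempo error. All corrections use Holm–Bonferroni
within an experiment family.

## Problem sizes

Full-scale scoring uses 60-bout corpora and 10⁵ Monte-Carlo samples
(`scripts/acceptance.py` measures stimulus tempos over 60 rendered bouts
per condition). Corpus-level test batteries (corruption monotonicity over
10 seeds, the 27-bird grid) run at a reduced configuration chosen as this
package's test-scale condition: 15–20 bouts per corpus, basis 40, 8
dimensions, BIC 2–10, 2×10⁴ Monte-Carlo samples. The qualitative
conclusions are insensitive to this reduction; absolute SD values shift
slightly with corpus size because of the finite-sample floor discussed
above.

## Known limitations

- The similarity-space construction (correlation kernel, basis size 50,
  10 axes) and GMM settings are package choices; no claim is made that
  they match any other implementation of a divergence-based song score.
- SD values depend on corpus size through the model-variance floor;
  compare scores only across birds scored with the same configuration and
  corpus size.
- The generator's gap model is Gaussian-truncated, not fitted to real gap
  distributions; its "naturalism" is limited to means/SD magnitudes and
  prosodic ordering.
- Segmentation assumes clean recordings (high SNR); there is no noise
  robustness beyond the high-pass filter and threshold rule.
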