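# finchsong

Tools for quantifying vocal learning in Bengalese finches — and for
simulating the tutoring experiments used to study how genetic
predisposition and instructive experience interact.

Juvenile songbirds learn song from an adult tutor, but individuals from
different genetic backgrounds carry heritable biases (for example, a bias
to sing at their father's tempo even if they never heard him). This
package implements the measurement pipeline for such studies:

- **Segmentation** — syllables as supra-threshold regions of a rectified,
  8 ms-smoothed amplitude envelope (merge gaps ≤ 5 ms, keep > 10 ms), and
  song bouts as syllable runs with no gap over 250 ms.
- **Tempo** — syllables per second of bout, averaged over ≥ 60 bouts; the
  heritable bias proxy, binned slow (< 7.5), medium (7.5–9.5) and fast
  (> 9.5 syl/s).
- **Song Divergence (SD)** — the learning-quality score. Each bird's
  syllable spectral content (one Welch PSD per syllable) is embedded in a
  similarity space and modelled with a Gaussian mixture; SD is the
  Monte-Carlo Kullback–Leibler divergence KL(tutor ∥ tutee) in bits.
  SD = 0 is a perfect copy; larger values mean more tutor content missing
  from the learned song. The score is directional (improvisation is not
  penalized) and, because it discards temporal structure, orthogonal to
  tempo.
- **Synthetic songs** — a tutor stimulus of 2 intro syllables plus three
  repetitions of a 7-syllable motif (9 distinct types), retimed to other
  tempos by scaling only the inter-syllable gaps, and simulated tutee
  corpora whose copy fidelity can be coupled to the tutor-tempo /
  genetic-bias mismatch.
- **Statistics** — Wilcoxon signed-rank (exact for small n), Welch t
  tests (one-tailed at the 0.025 level), one-way ANOVA with omega-squared
  effect sizes, gamma fits to SD distributions, and Holm–Bonferroni
  correction within each experiment family.

See `docs/methods.md` for the models, parameter defaults and their
rationale, and known limitations.

## Worked example

Simulate the 3×3 tutoring grid — cohorts from slow / medium / fast
genetic backgrounds (father tempos 7.18, 7.89, 10.31 syl/s) tutored with
the same song at 6.5 / 8.5 / 10.5 syl/s — and ask which factor explains
the learning outcomes:

```python
from finchsong.divergence import DivergenceConfig
from finchsong.experiments import run_grid_experiment
from finchsong.stats import grid_analysis

cfg = DivergenceConfig(basis_size=40, n_dims=8, k_range=(2, 10),
                       n_init=2, mc_samples=20_000)
records = run_grid_experiment(n_per_cell=3, n_bouts=20, seed=1, config=cfg)
res = grid_analysis(records)
print(res.cell_means.round(2))
print({k: round(v, 2) for k, v in res.category_means.items()})
print("omega2:", round(res.category_test.effect_size, 3),
      round(res.background_test.effect_size, 3),
      round(res.tutor_test.effect_size, 3))
```

Output (seed 1):

```
        6.5    8.5    10.5
7.18    3.39  20.48  24.75
7.89    7.69   6.40  30.48
10.31  13.31   7.40   2.04
{'matched': 3.94, 'tutor_faster': 25.23, 'tutor_slower': 9.46}
omega2: 0.587 0.035 0.089
```

Rows are genetic backgrounds, columns tutor tempos, values mean SD in
bits (lower = better learning). The diagonal — tutor tempo matched to the
bird's bias — is the best cell in every row; birds tutored *slower* than
their bias (9.5 bits) fare better than birds tutored faster (25.2 bits);
and the match category explains far more outcome variance (ω² = 0.59)
than genetic background (0.04) or tutor tempo (0.09) alone. That is the
gene-by-experience interaction the pipeline is designed to detect.

A single bird is scored like this:

```python
from finchsong.divergence import song_divergence
from finchsong.synth import (TuteeSpec, canonical_song_spec,
                             generate_reference_corpus, generate_tutee_corpus)

tutor = canonical_song_spec()                       # 8.5 syl/s stimulus
reference = generate_reference_corpus(tutor, 60)    # designated good learner
tutee = generate_tutee_corpus(
    TuteeSpec(tutor=tutor, corruption=0.3, seed=5), 60)
print(song_divergence(reference, tutee).bits)       # ~12 bits: a poor copy
```

There is also a thin CLI (`finchsong generate|segment|tempo|divergence`)
for working with WAV files on disk.

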