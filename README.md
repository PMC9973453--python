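# verserhythm

Rhythm analysis of oral reading of metered poetry, for speech-prosody and
psycholinguistics researchers working with Praat-annotated recordings of
conventional (iambic or trochaic) verse.

When people read metered, rhymed poetry aloud, they project the poem's
alternating weak–strong grid onto their articulation: metrically strong
syllables are spoken longer and louder.  A way to probe how much of that
rhythm is top-down (the projected meter) versus bottom-up (the phonetic
material itself) is to replace random syllables with the lexically
meaningless syllable *tack* and measure what happens to timing and
loudness.  This package implements the full analysis pipeline for such
studies, plus a synthetic oral-reading generator so every stage is testable
without recordings:

- **Stimulus model** — metrical grids (strong/weak syllable slots per
  line), with seeded random tack substitution from the third line on,
  0–5 tacks per line.
- **Annotation I/O** — Praat TextGrid reading/writing (long and short text
  dialects, UTF-8/UTF-16) and construction of the chronological syllable
  table joined to the stimulus grid.
- **Rhythm features** — the syllable onset interval
  SOI(k) = onset(k+1) − onset(k), which integrates within-line pauses
  (line-final pauses are excluded: the last syllable of a line gets its own
  duration), per-syllable mean intensity (dB, joined from a per-interval
  table), and the rule that rows with SOI > 2000 ms are excluded.
- **nPVI** — the normalized pairwise variability index of a line,

  nPVI = 100/(m−1) · Σₖ |dₖ − dₖ₊₁| / ((dₖ + dₖ₊₁)/2),

  a 0–200 measure of long–short (or loud–quiet) alternation, computed per
  verse line over SOIs and intensities.
- **Inference** — sum-coded (±1) Gaussian linear mixed models fitted by
  REML with Satterthwaite degrees of freedom: crossed random effects
  (participant and syllable type, or participant and poem), a correlated
  participant intercept + slope block, a two-pass procedure that refits
  after removing rows whose residual falls outside the Tukey fences
  (1.5 × IQR beyond the residual quartiles), Cohen's d = 2t/√df, the
  intraclass correlation, and marginal/conditional R².  Because factors
  are sum-coded, the predicted difference between a factor's two levels is
  2β.
- **Synthetic reader** — a generative mirror of the fitted models
  (13 readers, six poems, 991 syllable slots, 120 lines) used for
  parameter-recovery testing and as a stand-in for the unavailable
  recordings.

## Worked example

```python
>>> from verserhythm import npvi, cohens_d, icc_from_components
>>> npvi([250, 270, 280])        # a fairly even line: low contrast
5.66
>>> npvi([130, 190] * 4)         # strict long-short alternation
37.5
>>> cohens_d(3.09, 16.53)        # effect size from a model t and df
1.52
>>> icc_from_components([5982.17, 406.63], 2623.56)
0.71
```

The numbered drivers under `analysis/` run the whole study on synthetic
data and narrate what they find; `python analysis/01_simulate_reading.py`
followed by `02`–`05` prints, among other things:

```
simulated 12883 syllable tokens for 13 readers (1950 tacks, 54 rows beyond the 2000 ms SOI rule)
aggregated 1560 verse lines (1105 contain at least one tack; tacks per line range 0-5)
...
  regular syllables: strong syllables are spoken 40.9 ms longer than weak ones (2 x beta, p = 9.8e-07).
  tacks: the stress effect collapses (beta = -11.51 ms, p = 0.01); instead each later tack in a line adds 14.2 ms (tack index, p = 0.0081).
  each additional tack in a line lowers the SOI-based nPVI by 3.00 (2 x beta, p = 0.0048): lines with tacks are read with less long-short alternation.
```

That is the package's core result pattern: on regular syllables the
metrical grid is realised in articulation timing; on tacks the stress
contrast disappears while rhythmic contrast (nPVI) drops in proportion to
the number of tacks in the line.

The same pipeline is scriptable from the shell:

```sh
verserhythm simulate --seed 1 --out results/run1
verserhythm ingest --textgrid-dir grids/ --poem-spec poems.tsv \
    --participants participants.tsv --intensity intensity.tsv --out results/run2
```

`ingest` consumes real Praat TextGrids (one per reader × poem, with a
`syllables` interval tier) and is verified to reproduce the simulate path
exactly on generator-emitted annotation.

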