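# syllasync

A toolkit for modelling the syllable as a synchronization of
target-approximation movements:

- **`qta`** — closed-form dynamics of one interval: a channel variable
  asymptotically approaches a linear target `b + m*t` under a critically
  damped third-order system with rate constant `lam`, with full
  (position, velocity, acceleration) state matching at the interval onset.
- **`sequencing`** — strict sequential synthesis of several targets on one
  channel with analytic state transfer (C²-continuous surfaces), plus
  truncation of an interval (undershoot) and blending via an inserted
  averaged target.
- **`score`** — compiles syllable specifications (onset consonants, nucleus,
  coda, tone, phonation) into per-dimension target sequences under edge
  synchronization and dimension-specific sequential target approximation,
  synthesizes multi-channel trajectories, exports the synchronization-based
  segmentation as Praat TextGrids, and derives locus-equation regressions
  from synthesized CV families.
- **`divergence`** — minimal-triplet divergence-point analysis: aggregates
  repetitions (with optional per-interval linear time normalization),
  detects where two mean trajectories start to diverge with a
  threshold/run-length detector, and tests consonant–vowel onset synchrony
  with bootstrap confidence intervals.
- **`estimation`** — analysis-by-synthesis: recovers underlying targets from
  observed trajectories by bounded nonlinear least squares (multi-started
  over the strength parameter), with fixed or free boundary alignment, and
  runs the synchronized-vs-flexible alignment-learning experiment.
- **`syndata`** — seeded generators for every synthetic input the analysis
  modules need: noisy contours, minimal triplets with constructed divergence
  truth, and tone corpora.
- **`io` / `cli`** — CSV/TSV trajectory tables with unit-annotated headers,
  TextGrid read (long and short format) and write (long), condition
  manifests, YAML/JSON score configs, and a `syllasync` command.

## Command line

```sh
# synthesize the packaged two-syllable example
syllasync synth src/syllasync/examples/mali.yaml --out out/

# generate a minimal triplet and test C-V onset synchrony
syllasync --seed 1 generate triplet --n-reps 20 --out fixtures/
syllasync --seed 1 diverge fixtures/manifest.json --out results/

# fit targets to a trajectory table
syllasync fit out/trajectories.csv --channel f0 --boundaries 0,0.2,0.4 --out fit/

# run the alignment-learning experiment
syllasync learn --n-corpora 20 --out learn.tsv
```

Global flags `--seed`, `--rate`, `--format {csv,tsv}` and `--log-level` go
before the subcommand. Exit codes: 0 success, 1 processing error, 2 usage
error.

## File formats

- Trajectory tables: `time,<channel>[unit],...` with a uniform time step;
  empty cells are masked samples (honoured by the fitter).
- Score configs: see `src/syllasync/examples/mali.yaml` and the
  `syllasync.io.read_score_config` docstring for the schema.
- Manifests: `{"conditions": {"control": [files...], "c_contrast": [...],
  "v_contrast": [...]}}`, paths relative to the manifest.
- Pitch conversion helpers `hz_to_st`/`st_to_hz` are explicit; the library
  never converts units implicitly.
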