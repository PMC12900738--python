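# padpref

PAD (Pleasure–Arousal–Dominance) affective-preference scoring and a
desk-scale ERP analysis pipeline, with synthetic-data generators so every
stage is testable without external recordings.

## What it does

**`padpref.pad_core`** — all PAD arithmetic:

- `score_pad` scores a 12-item semantic-differential response (9-point
  bipolar scale, −4…+4) into a PAD vector:
  `P=(V1−V4+V7−V10)/4`, `A=(−V2+V5−V8+V11)/4`, `D=(V3−V6+V9−V12)/4`.
- `classify_octant` maps the sign triple of (P, A, D) to one of eight
  octant emotion names (exact zeros count as negative and raise a flag).
- `proximity` / `nearest_emotion` compute Euclidean distance to a table of
  normative emotion points (eight built-in defaults); the minimum distance
  defines the emotional preference. Ties break by table order.
- `smd` is the variance-free standardized mean difference
  `(M1 − M2)/(|M1| + |M2|)`, bounded in [−1, 1].
- `classify_pleasure_band` assigns a Pleasure mean to
  Unpleased / General / Pleased bands (painting scheme: nodes −1.25,
  −0.25, 0.25, 1.25; interior scheme: −1.5, −0.2, 0.5, 1.5; values on a
  shared node go to the band farther from zero).
- `aggregate_group` / `run_pad_pipeline` compute per-group × stimulus mean
  PADs and full preference results.

**`padpref.erp_pipeline`** — fixed-order EEG chain (μV, ms):
zero-phase 30 Hz low-pass → 50 Hz notch → segmentation (−200…800 ms,
half-open right edge) → baseline correction (−200…0 ms) → averaged-mastoid
re-reference → ±100 μV artifact rejection → per-condition averaging →
signed-extremum peak extraction in the 250–600 ms window →
frontal-asymmetry valence (`mean(Fp1,F3) − mean(Fp2,F4)` vs. a ±ε band,
ε = 0.5 μV default).

**`padpref.synthetic_data`** — deterministic (seeded) generators:
`generate_ratings` inverts the scoring map and adds clipped Gaussian item
noise; `generate_epochs` builds Gaussian-noise epochs with a lateralized
Gaussian late-positive bump (left × (1+λ) / right × (1−λ) for "like",
mirrored for "dislike").

**`padpref.io` / `padpref.cli`** — CSV readers/writers with strict
validation, a text epoch container (`.dat` matrix + `.json` sidecar), and
the `padpref` command.

## CLI

```sh
padpref simulate-ratings --target 0.8,0.2,-0.1 --n-raters 40 --noise-sd 0.5 \
    --seed 1 --out ratings.csv
padpref preference --ratings ratings.csv --scheme painting --out prefs.csv
padpref smd -- 0.8 -0.25
padpref simulate-eeg --n-trials 40 --noise-sd 2 --lateralization 0.5 \
    --seed 2 --out epochs
padpref erp-extract --epochs epochs --window 250 600 \
    --channels Fp1,Fpz,Fp2,F3,F4,Fz,Cz,Pz --threshold 100 --epsilon 0.5 \
    --out peaks.json
padpref report --ratings ratings.csv --epochs epochs --out-prefix final
```

The simulators also accept `--config file` with `key = value` lines
mirroring the config dataclass fields (command-line options win).

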