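# emmap — multilevel time-scale maps for eye-movement event detection

`emmap` analyses eye-movement velocity recordings with three nonlinear
time-series measures — approximate entropy (ApEn), fuzzy entropy (FuzEn) and
the largest Lyapunov exponent (LLE) — organised as **multilevel maps**: a
dyadic time-scale decomposition in which each measure is evaluated on every
segment of length 64·2^(l−1) ms at map level *l* of a 1024 ms recording
(16, 8, 4, 2, 1 segments on levels 1–5).  The normalized map cells then feed
a kNN classifier, under leave-one-session-out cross-validation, that
recognises which post-stimulus time window a sample came from — i.e. which
eye-movement event (saccadic latency, saccade, fixation) it contains.

It is aimed at eye-tracking and biosignal researchers who want
threshold-free event characterisation of 1000 Hz oculographic recordings,
and ships a seeded synthetic saccade generator so the whole pipeline runs
and is testable without any recorded data.

## The measures

For a series u(1),…,u(N) with pattern length m and tolerance r:

- **ApEn(m, r, N) = Φ^m(r) − Φ^{m+1}(r)**, where Φ^q(r) is the mean log
  fraction of length-q patterns within Chebyshev distance r of each pattern
  (self-matches included).  Defaults m = 2, r = 0.2 × SD of the whole
  1024-sample series.
- **FuzEn(m, n, r, N) = ln φ^m − ln φ^{m+1}**, where φ^q averages the fuzzy
  similarity exp(−d^n / r) between baseline-removed (de-meaned) patterns,
  self-matches excluded.  Defaults m = 2, n = 2, r = 0.075 × SD of the
  series.
- **LLE**: after delay embedding x_i = (u_i, u_{i+τ}, …, u_{i+(m−1)τ}) with τ
  from the first prominent minimum of lagged mutual information and m from
  the false-nearest-neighbours criterion, nearest-neighbour separations are
  modelled as d_j(i) ≈ d_j(0)·e^{λ·iΔt}; λ is estimated either by averaging
  ln(d_j(i)/d_j(0))/(iΔt) over reference points, or as the least-squares
  slope of ⟨ln d_j(i)⟩ versus iΔt (Rosenstein's robust variant).

Feature sets are named `set64_128_256_ApEn_FuzEn_LLE`-style: segment lengths
of the included levels, then the included measures.  The class count is
Ncl = NEMr / (Nss·2^(lX−1)) where lX is the finest included level (16, 8, 4,
2 classes for levels 1–4 at the default geometry).

## Worked example

```python
from emmap import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    seed=1,
    synth={"n_participants": 6, "n_sessions": 2, "n_points": 4},
    specs=("set64_ApEn", "set64_128_256_ApEn_FuzEn_LLE"),
    k_grid=(3, 7),
)
run_pipeline(cfg, "out")
print(open("out/accuracy_table.csv").read())
```

simulates 48 recordings (6 participants × 2 sessions × 4 points), builds the
three maps per recording, min-max normalizes each map level across the
dataset, and classifies the level-1 segments.  It prints:

```
segment,set64_ApEn_k3,set64_ApEn_k7,set64_128_256_ApEn_FuzEn_LLE_k3,set64_128_256_ApEn_FuzEn_LLE_k7
0-64,0.125000,0.104167,0.312500,0.354167
64-128,0.104167,0.125000,0.312500,0.416667
128-192,0.104167,0.125000,0.666667,0.625000
192-256,0.375000,0.583333,0.541667,0.625000
```

Rows are the first four 64 ms segments, columns the feature set × k.  With
16 classes, chance is 0.0625: the single-measure, single-level ApEn vector
stays near chance except in the late saccade window, while the nine-feature
set combining all three measures over levels 1–3 recognises the
saccade-bearing windows (128–192 and 192–256 ms, where the generator places
the saccade) an order of magnitude above chance — the central qualitative
effect of combining measures and time scales.  The output directory also contains the per-sample recordings,
the long-format map table (`maps.csv`), per-spec feature tables, full
confusion matrices, heat-map figures of the averaged maps, and a
`manifest.json` echoing every parameter in effect.

The same stages are available as composable shell commands:

```bash
emmap simulate --config cfg.yaml --out rec.csv
emmap map --in rec.csv --config cfg.yaml --out maps.csv
emmap features --maps maps.csv --spec set64_128_256_ApEn_FuzEn_LLE --out feats.csv
emmap classify --features feats.csv --spec set64_128_256_ApEn_FuzEn_LLE --k 7 --out report.csv
emmap report --reports report.csv --out table.csv
emmap run --config cfg.yaml --out outdir     # the whole chain
```

Recordings are plain CSV, one sample per row, with columns
`participant,session,point,sample_index,velocity` (or `position`, which is
converted to velocity by two-point differentiation).

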