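# hdcfusion

Memory-optimized hyperdimensional computing (HDC) with early sensor fusion
for multi-channel, multi-modal physiological feature streams — the kind of
pre-extracted feature tables produced for wearable emotion-recognition
tasks (e.g. GSR + ECG + EEG features with binary valence/arousal labels).

## The problem and the method

Affect classifiers on wearables must handle >200 feature channels across
3–5 sensor modalities under tight memory budgets. HDC encodes everything in
D-dimensional binary hypervectors (default D = 10,000), where random
vectors are nearly orthogonal (normalized Hamming distance ≈ 0.5), using
three operations: binding (componentwise XOR, `⊕`), bundling
(componentwise majority, `+`) and permutation (1-bit cyclic shift, `ρ`).

The datapath, per time sample *j*:

- **map into hyperspace** — channel *i* contributes
  `SE_{i,j} = iM_i ⊕ FP_{i,j}`, where `iM_i` is the channel's item-memory
  vector and `FP_{i,j}` is its positive or negative feature-projection
  vector, selected by the sign of the feature value (values are scaled to
  [−1, +1]; only the sign is encoded);
- **spatial encoding with early fusion** —
  `SE_{m,j} = (iM_1 ⊕ FP_{1,j}) + ⋯ + (iM_k ⊕ FP_{k,j})` per modality,
  then `SE_j = SE_{1,j} + ⋯ + SE_{m,j}` across modalities, so each
  modality is weighted equally rather than by channel count;
- **temporal encoding** — an n-gram over N consecutive samples (default
  N = 3): `TE_j = SE_j ⊕ ρ^{+1}(SE_{j−1}) ⊕ ⋯ ⊕ ρ^{+(N−1)}(SE_{j−N+1})`;
- **associative memory** — training bundles every window of a class into a
  prototype; inference returns the class whose prototype has minimum
  Hamming distance to the query. Windows mixing two labels
  ("transitionary" n-grams) can be excluded from training and testing.

Storing three fresh random vectors per channel costs 3·C vectors (642 for
a 214-channel layout). Five provisioning strategies cut this down, the last
two by generating vectors on the fly with the rule-90 elementary cellular
automaton (`HV_{n+1} = ρ^{+1}(HV_n) ⊕ ρ^{−1}(HV_n)`):

| strategy          | stored vectors (C channels, m modalities, K = largest modality) |
|-------------------|------------------------------------------------|
| `unoptimized`     | 3·C                                            |
| `im_per_modality` | K + 2·C                                        |
| `fp_per_channel`  | K + 2·m                                        |
| `combinatorial`   | smallest v with TFC(v) ≥ C                     |
| `rule90`          | 2·m + 1                                        |
| `hybrid`          | bank + 2·m + 1, request rate bank/TFC(bank)    |

The combinatorial scheme reuses a small bank of v vectors, pairing each
bank vector with every other at most once; its capacity is
`TFC(v) = Σ_{n=1}^{v−2} ⌊(v−n)/2⌋` channel triples.

## Worked example

Everything runs on bundled synthetic data (no dataset download). The
generator plants class signal in channel signs: each joint
valence×arousal class owns a random sign prototype, and every sample
matches it per channel with probability *p* (the separability).

```
$ hdcfusion generate --preset amigos_like --subjects 4 --trials 8 \
    --samples 30 --separability 0.62 --seed 7 \
    --out-table features.csv --out-layout layout.json
wrote 960 samples x 214 channels to features.csv

$ hdcfusion evaluate --table features.csv --layout layout.json \
    --protocol loso --strategy rule90 --seed 7 --out report.json
valence: mean accuracy 0.9319
arousal: mean accuracy 0.9018
```

At p = 0.62 each channel is only weakly informative, yet bundling 214
channels and a 3-gram of samples recovers the labels for >90% of held-out
windows under leave-one-subject-out evaluation — while the `rule90`
strategy stores just 7 vectors (2 projection vectors per modality plus one
seed). At p = 1.0 accuracy is 100%; at p = 0.5 it sits at chance.

```
$ hdcfusion provision-stats --preset amigos_like --bank-size 7
       strategy bank_size  stored_vectors  storage_reduction_pct  request_rate request_reduction_pct
    unoptimized      <NA>             642                   0.00      0.000000                  <NA>
im_per_modality      <NA>             533                  16.98      0.000000                  <NA>
 fp_per_channel      <NA>             111                  82.71      0.000000                  <NA>
  combinatorial      <NA>              31                  95.17      0.000000                  <NA>
         rule90      <NA>               7                  98.91      1.000000                   0.0
         hybrid         7              14                  97.82      0.777778                 22.22
```

Storage falls from 642 to 7 vectors (−98.91%); the hybrid scheme encodes
TFC(7) = 9 channels per 7-vector burst, cutting the vector-request rate by
22.22% relative to pure rule-90 generation.

Other subcommands: `train`, `infer`, `sweep-dim`; the same functionality is
available as a library (`hdcfusion.provision`, `encode_stream`,
`AssociativeMemory`, `run_loso`, `run_split`, `sweep_dimension`, ...).

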