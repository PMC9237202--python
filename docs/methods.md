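# Methods

## Model and assumptions

The classifier operates on pre-extracted feature tables: one row per time
sample, one column per feature channel, values scaled to [−1, +1], with
binary valence and arousal labels and subject/trial identifiers. Raw-signal
preprocessing and feature extraction are out of scope; the package ingests
any table in this shape.

Information is carried by dense binary hypervectors of dimension D
(default 10,000). Everything downstream relies on one statistical fact:
independent random binary vectors at large D concentrate at normalized
Hamming distance 0.5 (σ = 1/(2√D) ≈ 0.005 at D = 10,000), so unrelated
encodings are distinguishable from related ones. The encoding uses only the
*sign* of each feature value — the sign-multiplexer simplification that
replaces per-level value codebooks with one positive and one negative
projection vector per channel. A value of exactly 0 maps to the positive
projection (non-negative → PFP); the ternary formulation it replaces
leaves zero unassigned, and a fixed convention keeps encoding
deterministic. Magnitude quantization is deliberately not implemented.

Early fusion bundles per-modality spatial vectors into a single stream
before the temporal encoder, so one temporal encoder serves all modalities
and each modality is weighted equally regardless of channel count. The
late-fusion variant (per-modality temporal encoders, bundled afterwards)
is provided only as a comparison baseline, with N exposed as a parameter.

## Tie-breaking

Bundling is a strict per-position majority. For an even number of inputs a
position can tie; ties are resolved by *augmented majority*: a single
tie-breaker hypervector, drawn once per run from the run RNG, contributes
one extra vote to any even-sized bundle. This is unbiased across
positions, deterministic given the seed, and identical in training and
inference. The same rule binarizes associative-memory accumulators for
classes with an even number of training windows. Inference ties (equal
Hamming distance to two prototypes) go to the earliest class in declared
class order.

## Provisioning strategies

Each channel needs a triple {iM, PFP, NFP}. The five storage schemes and
their closed-form costs (C channels, m modalities, K_max the largest
modality):

- `unoptimized` — 3 fresh random vectors per channel; 3·C stored.
- `im_per_modality` — one iM bank of size K_max reused across modalities,
  fresh projection pair per channel; K_max + 2·C.
- `fp_per_channel` — the shared iM bank plus one projection pair per
  modality; K_max + 2·m.
- `combinatorial` — a bank of v random vectors, v minimal with
  TFC(v) = Σ_{n=1}^{v−2} ⌊(v−n)/2⌋ ≥ C. Channel triples are enumerated
  canonically: for bank index n ascending, iM = bank[n] is paired with
  sequential partner pairs (n+1, n+2), (n+3, n+4), … while both exist.
  Every unordered {iM, FP} pair occurs at most once, which keeps every
  bound pair iM ⊕ FP distinct (binding two vectors already used together
  would reproduce an existing spatial encoding). Any enumeration with
  these two properties is equivalent; this one is fixed so that runs are
  reproducible.
- `rule90` — one stored seed; the chain HV_{n+1} = ρ^{+1}(HV_n) ⊕
  ρ^{−1}(HV_n) supplies first the 2·m per-modality projection pairs, then
  one iM per channel in layout order; 2·m + 1 stored.
- `hybrid` — the chain burst-generates banks of b vectors, consumed
  combinatorially (TFC(b) channels per burst); when a bank is exhausted
  the chain continues into the next bank, so cross-bank pair collisions
  are impossible. Steady-state request rate b/TFC(b) versus 1 for pure
  rule-90 generation. Default b = 2·m + 1 (the rule-90 storage budget,
  making the two schemes directly comparable). Reported storage follows
  the b + 2·m + 1 closed form.

Because channel access order is fixed, on-the-fly generation is made
reproducible by restarting the chain from the stored seed on every
encoding pass; `ProvisionedMemory` caches the resulting sets and
`regenerate()` verifies the restart produces bit-identical vectors.
Training and inference therefore always see the same channel vectors.

**Rule-90 degeneracy.** Rule 90 is linear over GF(2). Constant seeds are
rejected (all-zero is a fixed point; all-one collapses to it in one step).
Less obviously, on rings whose size is a power of two the update matrix is
nilpotent — every orbit reaches all-zero within D/2 steps — so the chain
guards against collapse at runtime and raises `DegenerateSeedError` rather
than silently emitting constant vectors. Any dimension with an odd factor
(10,000 = 2⁴·5⁴·… included, and all odd dimensions) is safe for the chain
lengths used here (≈ 2·m + C steps). Empirically, successive chain states
from a random seed at D = 10,000 stay pairwise within [0.45, 0.55]
normalized distance over 250 steps, i.e. the generator is
indistinguishable from fresh randomness at the scales provisioned.

## Synthetic data

The generator emulates the statistical skeleton of post-extraction affect
feature tables: each of the four joint valence×arousal classes owns a
fixed random sign prototype over the channels; every sample matches its
class prototype per channel independently with probability p (the
separability), and magnitudes are uniform in (0, 1] carrying no
information — exactly mirroring what the sign-only encoder can use. Labels
are balanced over the four joint classes and assigned per trial; an
optional block scheme flips the class mid-trial to create genuine
transitionary windows. Defaults: 4 subjects, 8 trials each, 30 samples per
trial, p = 0.9.

What it does *not* emulate: inter-channel correlation structure,
subject-specific effects, non-stationarity, class imbalance, and
informative magnitudes. Passing tests therefore demonstrate that the
pipeline recovers plantable sign structure at known difficulty — p = 1.0
must give 100% accuracy, p = 0.5 must give chance — not that any
particular accuracy is attainable on real recordings.

## Protocols and numerical choices

- Leave-one-subject-out and per-subject 80/20 splits both split by whole
  trials, never samples, so no temporal window straddles a train/test
  boundary; windows also never cross trial boundaries.
- Transitionary-window exclusion is on by default; the window label under
  exclusion is the common label of its N samples.
- Spatial encoding is computed with two matrix products per modality
  against stacked projection matrices in float32 — exact, since
  per-position counts never approach the 2²⁴ float32 integer limit — and
  verified bit-identical to the per-sample definition in tests.
- Batch Hamming inference is chunked (2048 queries) to bound memory.
- The per-window accuracy is the primary metric; per-trial majority-vote
  accuracy is reported alongside it, since published results do not always
  state the aggregation level.
- Dimensions below 100 are rejected; below 1,000 a warning is issued
  (pseudo-orthogonality degrades).

## Operating-regime caveats

Two findings worth knowing when interpreting results on this generator:

1. **Encoded-distance geometry.** Two samples with *independent* random
   sign patterns agree on ~half their channels, so their bundles'
   per-position counts correlate at ~1/2 and the expected encoded distance
   is (1/π)·arccos(1/2)·2 ≈ 1/3, not 0.5. Class separation at inference
   rests on this gap between ~0 (same class, high p) and ~1/3
   (independent), not on full orthogonality.
2. **Strategy equivalence is regime-dependent.** At the default
   separability (p = 0.9) and above, all six provisioning strategies agree
   to within a fraction of a point, matching the storage-reduction claim
   of no meaningful accuracy cost. Near chance (p ≈ 0.55–0.65), strategies
   that share projection pairs across a modality (`fp_per_channel`,
   `rule90`) measurably *outperform* the rest on this generator (by 10–20
   points at p = 0.6): a sign flip then XORs the channel contribution with
   the same modality-wide difference vector PFP ⊕ NFP, correlating the
   noise instead of spreading it. This is a property of the synthetic sign
   model in the barely-separable regime, and no claim about real feature
   tables.

## Sizes used in the bundled checks

End-to-end checks run on the AMIGOS-like layout (GSR 32 / ECG 77 / EEG
105) at D = 10,000: label recovery at p = 1.0 (3 subjects × 8 trials × 20
samples), chance behaviour at p = 0.5 (4 × 28 × 40, ≥2,000 held-out
windows), strategy agreement at p = 0.9 (4 × 12 × 30, all six strategies),
and the dimension trend at p = 0.6 (1,000 vs 10,000, three seeds). These
sizes give binomial noise well inside the asserted bands while the whole
suite completes in well under a minute.

## Known limitations

- Binary targets only (high/low valence, high/low arousal); no multi-class
  emotion categories, no prototype refinement/retraining, no confidence
  calibration.
- Only sign information is encoded; feature tables whose signal lives in
  magnitudes will not classify well without upstream transformation.
- The hybrid scheme's stored-vector accounting follows the closed form
  above; its channel triples are drawn wholly from the burst bank.
- Rule-90 provisioning requires a dimension that is not a power of two.
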