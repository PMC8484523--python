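# Methods

## The model

`lexcompnet` implements a sequence-to-static-target mapping: a gated
recurrent unit receives, one timestep at a time, the rows of a word's
dynamic phonological representation and is trained to hold the word's
static aggregated semantic‖visual‖lexical binary vector at its output
throughout the trial. The architecture is deliberately minimal:

* the hidden state is the output (no readout layer), so the hidden
  dimension equals the aggregate target length;
* there is no feedback from the semantic-visual output to the
  phonological input, and no attention mechanism — in visual-world
  simulations the Jaccard activation of a candidate is used as a proxy
  for attention;
* the initial hidden state is zero at every trial; no state carries
  between trials.

### Phonological input

Phones are binary vectors of 20 articulatory/phonological features. A
label of p phones unfolds as 3(p+1)+2 rows: two ramp-up rows from
silence (the all-zero state), each phone's code, two interpolated
co-articulation rows between consecutive codes, the all-ones
segmentation character, and two ramp-down rows back to silence. The
interpolation is linear at fractions 0.05 and 0.95, so a feature
transitioning 1→0 passes through 0.95 then 0.05 and a feature constant
across two phones stays constant. Trials are padded with zero rows to
the vocabulary-wide length 3·n_slots+2, and the target is held active
over the padded tail as well. Ramping from and to the all-zero state is
our reading of "ramping up to the first phone"; silence is the natural
origin and keeps the interpolation rule uniform.

The static lexical vector concatenates the phone codes plus the
segmentation code into n_slots slots of 20 features (zero-padded), so a
10-slot vocabulary has 200 lexical dimensions. Including the
segmentation character in the lexical vector is toggleable but on by
default, since the slot capacity is defined to accommodate it.

### Semantic and visual preprocessing

Real-valued representation matrices (one row per item) pass through:

1. outlier replacement — per dimension, values with |z| > 2 (population
   SD across items) are replaced by that dimension's median; statistics
   are computed once on the raw matrix, so the operation is idempotent
   under the fitted statistics and zero-variance dimensions are left
   unchanged;
2. (visual only) PCA to 150 dimensions (default; configurable), keeping
   the cumulative explained variance as a diagnostic;
3. median binarization — values strictly greater than the dimension
   median become 1, ties and smaller values 0. The tie policy is
   configurable; strict-greater makes constant dimensions all-zero
   rather than all-one.

The aggregate target is the fixed concatenation semantic ‖ visual ‖
lexical; the order is arbitrary but recorded in checkpoints.

### Training

Full-batch gradient descent with Nesterov momentum at the reference
hyperparameters: learning rate 0.4, momentum 0.4. The loss is the mean
squared error between the hidden state and the constant binary target,
averaged over items, timesteps and dimensions; targets lie in {0,1}, so
the tanh-bounded output can approach them. The loss form is a design
choice (mean squared error is the conventional default for this kind of
mapping); cross-entropy over a sigmoid readout is available as a config
alternative. "Batch update" is read as full-batch; a mini-batch size is
exposed for exploration. Gradients are computed by closed-form
backpropagation through time and are verified in the test suite against
central finite differences at 1e-5 relative tolerance. Weights are
initialised uniformly in ±1/√hidden_dim from a seeded generator; the
seed is the only factor that differs between models in a multi-seed run.
Training uses single precision, which halves the wall time of the large
matrix products at no observable cost to the learning trajectory
(gradient correctness is verified in double precision).

Convergence criterion: recognition of both constituents for 100% of
items, sustained for two consecutive evaluations (evaluations every 250
epochs by default), with a hard epoch cap.

### Recognition and evaluation

The model's continuous output is binarized at 0.5 and compared with
every item's stored binary vectors by the Jaccard index, separately for
the semantic-visual segment and the lexical segment; the argmax item is
the model's output, with ties broken deterministically by item order and
flagged. A min/max fuzzy-Jaccard alternative (no thresholding) is
available behind config. "Word offset" is the last non-padded row, i.e.
the end of the ramp-down after the segmentation character.

### Target-absent visual-world simulation

Candidate sets are enumerated exhaustively over consonant-onset targets:
PREL shares the target's onset phone, does not share its rhyme, and is
semantically and visually unrelated; SREL is semantically related but
visually and phonologically unrelated; VREL visually related but
semantically and phonologically unrelated; UREL unrelated on all three.
Semantic/visual (un)relatedness means the pair's Jaccard index is at or
above the 85th / at or below the 15th percentile of all unordered pairs
across the vocabulary (self-pairs excluded; ties at the cutoff count as
satisfying the criterion). Two labels share a rhyme when the phone
sequences from each label's last vowel to its end are identical (a
final-n-phones alternative is configurable). At every timestep of the
target's unfolding, each candidate is scored by the Jaccard index
between the binarized semantic-visual output segment and the candidate's
static semantic-visual vector; relative activations subtract the UREL
value, which is therefore identically zero. The grand average pools
trials and model seeds and attaches bootstrap 95% percentile intervals,
and reports the crossover timestep at which mean SREL relative
activation first exceeds mean PREL after PREL has led. For assertions
about the early phonological preference, the "onset window" is every
timestep before the second phone row — ramp-up, the onset phone and the
co-articulation rows out of it; during the first two or three rows the
thresholded output is still empty for every candidate class, because the
hidden state needs a few steps to cross the binarization threshold.

## Synthetic data

The generator produces the statistical structure the model exploits,
not real corpora:

* **Phone inventory** — random distinct binary 20-feature codes (never
  all-ones, which is reserved for the segmentation character, and never
  all-zeros, which encodes silence), tagged consonant or vowel. An
  articulatory-style fixed inventory is used in the engineered
  visual-world fixture.
* **Labels** — lengths uniform over a configurable range; onset phones
  drawn from a profile that concentrates most probability mass on a few
  popular onsets, which yields the large-cohort structure typical of
  toddler vocabularies; a small fraction of vowel onsets (6%); labels
  alternate consonant-like and vowel-like positions and are all
  distinct.
* **Semantic vectors** — category prototypes with per-dimension flip
  noise. Prototypes are mutations of a shared base vector at rates drawn
  per category from U(0.15, 0.5), so between-category similarity is
  graded rather than uniform and the extreme percentile tails of the
  pairwise Jaccard distribution are stably populated — without this the
  15th/85th-percentile relatedness criteria select near-arbitrary pairs.
* **Visual vectors** — each item belongs to a visual cluster drawn
  independently of its category; a `sem_vis_coupling` fraction (default
  0.3) of visual dimensions is driven by the item's *category* prototype
  instead of its cluster prototype, which makes semantic and visual
  relatedness correlated but dissociable, as the SREL/VREL candidate
  criteria require. Both matrices are continuousized with Gaussian noise
  (sd 0.2) plus sparse large outliers (1% of entries at ±4) so the
  preprocessing pipeline is exercised end to end.
* **Visual-world fixture** — an 11-item vocabulary with hand-placed
  binary supports engineering exactly two valid
  (target, PREL, SREL, VREL, UREL) tuples at the percentile extremes;
  construction is verified by re-running the selection criteria and
  raises on failure. It is a synthetic stand-in for a real vocabulary,
  built for deterministic testing of the trial machinery and for
  multi-seed simulations of the activation crossover. The target's two
  onset competitors share most of their support: corpus-derived binary
  vectors are dense and overlapping, so the model's early cohort-blend
  output crosses the binarization threshold on dimensions shared within
  the cohort; a two-word cohort with disjoint sparse supports would sit
  exactly at threshold and could express no early phonological
  preference at all.

### What the generator does not emulate

Real word-frequency and age-of-acquisition structure, articulatory
feature correlations between phones, the long-tailed category-size
distribution of toddler vocabularies, and the specific similarity
statistics of corpus-derived embeddings. Passing tests therefore show
that the *mechanisms* (unfolding input, co-articulation, cohort
competition, percentile-based trial construction, activation crossover)
behave as designed — not that the quantitative time courses match any
particular empirical dataset.

## Scaled-down study conditions

The reference-scale experiment (200 items, 450-dimensional aggregates,
20 models × 100,000 epochs) is supported by the code but is not what the
test suite runs. The package's default synthetic conditions are chosen
so that a complete training run converges in minutes on one CPU:

| condition | default | used by |
|---|---|---|
| 50 items, 6 categories, labels 2–4 phones, 5 slots | `SynthConfig()` | acceptance script, convergence criterion |
| semantic 30 dims, visual 60→20 dims (PCA), aggregate 150 | `SynthConfig()` | same |
| 18 items, 4 categories, labels 2–3 phones, 4 slots, aggregate 118 | test preset | multi-seed learning-curve properties |
| 11-item engineered fixture, aggregate 184 | `gen_vwp_fixture` | multi-seed visual-world properties |

Multi-seed suites train five models with different weight-initialisation
seeds on one fixed vocabulary, mirroring the one-vocabulary/many-models
design of the reference experiment. The fixed vocabulary seed for each
suite is part of the study conditions.

## Numerical choices and degenerate inputs

* Jaccard of two all-zero vectors is defined as 1 (the vectors are
  identical); the recognition and simulation paths guard the zero-union
  case explicitly.
* Argmax ties (recognition, attended candidate) are broken by lowest
  item index and flagged in recognition results.
* Zero-variance dimensions never trigger outlier replacement, and median
  binarization maps constant dimensions to all-zeros.
* Unfolding-matrix entries built from binary codes lie exactly on the
  lattice {0, 0.05, 0.95, 1}; the interpolation is computed as
  0.95a + 0.05b (not a + 0.05(b−a)) so the values are floating-point
  exact.
* Checkpoints store all six weight matrices, the segment boundaries and
  the training config in HDF5; save → load → forward is bit-identical.

## Known limitations

* The trial-yield of the percentile-based candidate criteria is
  combinatorially fragile on small vocabularies: many seeds of the
  default 50-item generator yield no valid target-absent trials at the
  15th/85th-percentile cutoffs (the reference 200-item vocabulary
  yielded 695 trials from only 16 targets — the criteria are restrictive
  by design). Multi-seed visual-world properties are therefore asserted
  on the engineered fixture, where trial existence is guaranteed by
  construction.
* Convergence epoch counts vary by a factor of ~2 across weight seeds;
  the epoch caps are generous relative to the observed medians.
* No GPU path and no gating variants; the model is a single GRU cell by
  design.
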