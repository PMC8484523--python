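# lexcompnet

A neural-network model of spoken-word recognition with lexical-semantic
competition, plus a simulator for *target-absent* visual-world trials.

Spoken words unfold in time. When listeners hear a word in a display that
contains no picture of its referent, their gaze briefly favours a
*phonologically* related picture (shared onset) before shifting to
*semantically* and *visually* related ones. `lexcompnet` implements a
minimal bottom-up account of that crossover: a gated recurrent unit (GRU)
receives a dynamically unfolding phonological representation of a word
and learns to map it onto the word's static, aggregated semantic, visual
and lexical representations. No attention mechanism and no top-down
feedback are involved — the time course of candidate activations alone
produces the early-phonological / late-semantic-visual preference
pattern. The package is aimed at computational psycholinguists who want
to explore dynamic phonological input representations, lexical cohort
effects, and visual-world simulations without assembling corpora: a
synthetic-data generator emulates the statistical structure the model
needs.

## Model

Each phone is a binary vector of 20 articulatory/phonological features.
A word of *p* phones unfolds as a matrix of 3(p+1)+2 rows: two ramp-up
rows, the phone codes, two interpolated co-articulation rows between
consecutive phones (a feature moving 1→0 passes through 0.95 then 0.05),
an all-ones segmentation character marking word offset, and two ramp-down
rows — zero-padded to 3·n_slots+2 rows (32 at the default 10 slots).

The GRU maps each input row x_t to output h_t via update and reset gates:

    u_t  = σ(Wᵘ x_t + Hᵘ h_{t−1})
    r_t  = σ(Wʳ x_t + Hʳ h_{t−1})
    h′_t = tanh(W x_t + r_t ⊙ U h_{t−1})
    h_t  = u_t ⊙ h_{t−1} + (1 − u_t) ⊙ h′_t

The hidden state *is* the model output: its dimension equals the length
of the aggregated binary target — semantic ‖ visual ‖ lexical
(100 + 150 + 200 = 450 at full scale). Training is full-batch gradient
descent with Nesterov momentum (learning rate 0.4, momentum 0.4) on the
mean squared error between h_t and the constant target at every timestep
of every trial; gradients come from backpropagation through time,
implemented in closed form and verified against finite differences.

A vocabulary item counts as recognized when the Jaccard index between
the (thresholded) model output and the item's own target is the highest
across the vocabulary — evaluated separately for the semantic-visual and
the lexical segment, at word offset. In a target-absent visual-world
trial the model hears one word while four candidate referents are scored
at every timestep by the Jaccard index between the output's
semantic-visual segment and each candidate's stored representation:
a phonological competitor (PREL, shares the onset), a semantic
competitor (SREL), a visual competitor (VREL) and an unrelated item
(UREL). Relatedness is decided by the 85th/15th percentiles of the
vocabulary-wide pairwise Jaccard distributions.

## Worked example

```python
from lexcompnet import (SynthConfig, gen_phone_inventory, gen_vocabulary,
                        gen_semvis, build_dataset, GRUWordRecognizer)
from lexcompnet.evaluation import TrainingMonitor

cfg = SynthConfig(n_items=12, n_categories=3, n_slots=4, length_range=(2, 3),
                  sem_dims=10, vis_raw_dims=20, vis_dims=8, seed=5)
inv = gen_phone_inventory(cfg)
vocab = gen_vocabulary(cfg, inv)
sem, vis = gen_semvis(cfg, vocab)
ds, var = build_dataset(vocab, inv, sem, vis, vis_k=cfg.vis_dims,
                        n_slots=cfg.n_slots)
print(f"inputs: {ds.X.shape}, targets: {ds.Y.shape}, "
      f"visual PCA variance: {var:.2f}")

monitor = TrainingMonitor(X=ds.X, offsets=ds.offsets,
                          semvis_targets=ds.semvis_targets,
                          lexical_targets=ds.lexical_targets,
                          item_ids=ds.item_ids, spec=ds.spec)
model = GRUWordRecognizer(hidden_dim=ds.spec.total_dim, epochs=4000,
                          eval_every=500, random_state=7)
model.fit(ds.X, ds.Y, eval_fn=monitor)
for entry in model.log_:
    print(f"epoch {entry['epoch']:5d}  loss {entry['loss']:.4f}  "
          f"both {entry['pct_both']:5.1f}%")
```

Output:

```
inputs: (12, 14, 20), targets: (12, 98), visual PCA variance: 0.96
epoch   500  loss 0.1637  both  25.0%
epoch  1000  loss 0.1250  both  66.7%
epoch  1500  loss 0.1066  both  83.3%
epoch  2000  loss 0.0957  both  91.7%
epoch  2500  loss 0.0888  both 100.0%
epoch  3000  loss 0.0845  both 100.0%
```

Twelve three-phone words from three semantic categories are mapped to
98-dimensional aggregate targets (10 semantic + 8 visual + 80 lexical).
`both` is the percentage of items whose semantic-visual *and* lexical
representations are both correctly recognized at word offset; it reaches
100% and training stops early once recognition is sustained. The
remaining loss reflects the early timesteps at which the word is not yet
identifiable from its onset.

The same pipeline is available from the shell:

```sh
lexcompnet gen --seed 5 --out data/
lexcompnet train --vocab data/vocabulary.csv --features data/phone_features.csv \
    --semantic data/semantic.csv --visual data/visual.csv --out run/
lexcompnet simulate-vwp --checkpoint run/model_seed0.h5 --out run/vwp/
lexcompnet run --config experiment.yaml   # end-to-end, n seeds, resumable
```

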