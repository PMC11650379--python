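# copolyvae

Semi-supervised graph-to-string variational autoencoder for copolymer
**ensemble** inverse design. A copolymer is represented not as a single
molecule but as a stochastic ensemble: a set of repeat units, their
stoichiometric fractions, and the chain architecture (alternating, random or
block) encoded as edge probabilities between attachment points. The model
learns a continuous 32-dimensional latent space over such ensembles, predicts
electron affinity (EA) and ionization potential (IP) from the latent code,
and supports gradient-free optimization (genetic algorithm or Bayesian
optimization) in that space to propose new copolymers with target properties
— for example, photocatalysts for hydrogen evolution, where a less negative
EA and an IP near 1 eV are desirable.

## The science in brief

- **Representation.** A copolymer ensemble is a string
  `SMILES('.'SMILES)*|frac|…|<a-b:p_ab:p_ba<…`: period-separated monomer
  SMILES with numbered attachment points `[*:n]`, one stoichiometric fraction
  per monomer, and weighted connectivity entries giving the probability that
  attachment point `a` bonds to point `b`. Alternating, random and block
  architectures are particular probability patterns. The same ensemble also
  has an equivalent graph form: one disconnected fragment per monomer,
  fraction-weighted nodes, and probability-weighted "stochastic" edges
  between attachment points.
- **Encoder.** A weighted directed message-passing network (wD-MPNN) runs
  chemprop-style edge messages over the ensemble graph, scaling messages by
  the stochastic edge weights and pooling node states with the stoichiometric
  node weights, so stoichiometry and architecture both reach the latent code.
- **Decoder.** A 4-layer, 4-head causal transformer generates the string form
  token by token. The latent code conditions generation twice: concatenated
  to every input embedding and cross-attended as a small learned memory.
  Numbers are tokenized digit-by-digit with explicit decimal places, so
  fractions and probabilities round-trip exactly.
- **Semi-supervision.** A small MLP head predicts (EA, IP) from the latent
  mean. Its squared-error loss is masked so unlabelled records contribute
  exactly zero gradient; labelled and unlabelled data train in the same
  batches. Loss = reconstruction + β·KL + α·property (α = 0.2, β ramped
  cyclically to 4·10⁻⁴).
- **Inverse design.** Decoded candidates are validated and re-encoded
  (decode–re-encode "repair" keeps the search on the manifold of real
  polymers); the objective f(z) = w·|IP(z) − 1| + w·EA(z) (+ penalty for
  invalid decodes) is minimized by an NSGA-II-style GA or by GP-based
  Bayesian optimization with a UCB acquisition (κ = 2.576).

Everything runs on CPU with NumPy: the package ships its own small
reverse-mode autodiff engine (`copolyvae.autodiff`) instead of a deep
learning framework. See `docs/methods.md` for details and rationale.

## Worked example

```python
from copolyvae import (
    ModelConfig, TrainConfig, CopolymerVAE, Vocabulary,
    fixture_dataset, split_by_combination, train,
    sample_prior, validity_rate, reconstruction_accuracy,
    ObjectiveSpec, default_bounds, run_ga, report_top_k,
)

# 1. A small enumerated A-B design space with pseudo-labels (EA, IP) on 30%
#    of records; split by monomer combination so nothing leaks across folds.
records = fixture_dataset(n_a=6, n_b=12, labelled_fraction=0.3, seed=0)[:500]
train_set, val_set, test_set = split_by_combination(records, seed=0)

# 2. Train the semi-supervised VAE.
vocab = Vocabulary.build([r.polymer_string for r in train_set])
model = CopolymerVAE(ModelConfig(max_len=160), vocab, seed=0)
train(model, train_set, val_set,
      TrainConfig(epochs=45, batch_size=32, alpha=0.2, beta_max=4e-4))

# 3. Generative metrics.
print(reconstruction_accuracy(model, test_set))     # % exact round trips
print(validity_rate(sample_prior(model, n=200)))    # % valid prior samples

# 4. Inverse design: minimize |IP - 1| + EA over the latent space.
bounds = default_bounds(model, [r.polymer_string for r in train_set])
result = run_ga(model, ObjectiveSpec(), budget=300, population=50,
                bounds=bounds, seed=0)
for cand in report_top_k(result, k=5).candidates:
    print(cand.objective, cand.decoded)
```

The same pipeline is available from the CLI (`copolyvae --help`):
`validate`, `dataset build/augment/split`, `train`, `sample`, `reconstruct`,
`evaluate`, `latent grid/perturb/interpolate/project`, and `optimize`.

```bash
copolyvae dataset build --n-a 2 --n-b 6 --out data.csv
copolyvae dataset split data.csv --prefix part
copolyvae train part_train.csv --val part_val.csv --epochs 20 --ckpt model.npz
copolyvae sample model.npz -n 10
copolyvae optimize model.npz --train-path part_train.csv --algo ga --budget 300
```

## Layout

| Module | Contents |
| --- | --- |
| `copolyvae.polymer_repr` | grammar, parser/serializer, canonicalization, validation, graph building, tokenizer |
| `copolyvae.dataset` | fixture monomer library, design-space enumeration, augmentation, pseudo-property oracle, splits, CSV I/O |
| `copolyvae.autodiff` | minimal NumPy reverse-mode autodiff (fused attention and cross-entropy) |
| `copolyvae.model_core` | wD-MPNN encoder, transformer decoder, property head, checkpointing |
| `copolyvae.training` | losses, KL annealing schedule, Adam, training loop |
| `copolyvae.evaluation` | reconstruction / validity / novelty / uniqueness metrics, prior sampling |
| `copolyvae.latent_tools` | latent grids, perturbation, interpolation, 2-D projection |
| `copolyvae.inverse_design` | objective, decode–re-encode repair, GA (NSGA-II style), Bayesian optimization, reporting |
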