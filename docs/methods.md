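# Methods

This note records what the model is, why the parameters are what they are,
how the synthetic data is constructed and where it is unrealistic, and the
numerical choices that matter for reproducing results.

## 1. Representation

A copolymer ensemble is a tuple (monomers, fractions, connectivity):

- monomers: SMILES with numbered attachment points `[*:n]`, canonicalized
  with RDKit; monomer order is canonicalized by sorting canonical SMILES.
- fractions: one stoichiometric weight per monomer, summing to 1.
- connectivity: directed entries `<a-b:p_ab:p_ba` between attachment points;
  for every attachment point that has outgoing entries, the outgoing
  probabilities sum to 1.

Alternating (A–B bonds only), random (bond probabilities proportional to
stoichiometry) and block (self-bonds at probability 1 − ε) architectures are
generated by `make_spec`. Numbers serialize with at least one decimal digit
and trailing zeros trimmed beyond it, so `serialize ∘ parse` is the identity
on canonical strings — this exactness is load-bearing for the reconstruction
metric, which compares canonical forms, not raw text.

The graph form used by the encoder keeps one fragment per monomer,
node weights = that monomer's fraction (shared across its atoms), unit
weights on covalent bonds, and the connectivity probabilities as weights on
"stochastic" edges joining attachment-point neighbors across fragments.

Tokenization is reversible: SMILES are split into atom/bond/ring tokens, and
every number becomes digit-place tokens (`0.125` → `[0@0] [.num] [1@-1]
[2@-2] [5@-3]`), so the decoder can emit arbitrary fractions without a
fixed-precision vocabulary.

## 2. Model

- **Encoder** — weighted directed MPNN over edges (chemprop convention):
  initial edge state `h⁰_uv = relu(W_init·[x_u ‖ e_uv])`, then T − 1 = 2
  updates `h_uv ← relu(h⁰_uv + W_msg·Σ_{w→u, w≠v} w_edge·h_wu)`, node
  readout `relu(W_node·[x_v ‖ Σ incoming])`, and stoichiometry-weighted mean
  pooling. Edge-message scaling by the stochastic edge weights plus weighted
  pooling is what makes two ensembles with the same atoms but different
  stoichiometry or architecture encode differently. Two linear heads give μ
  and log σ² of a diagonal Gaussian posterior.
- **Latent** — 32 dimensions. Small enough that a GA/BO search with a few
  hundred evaluations is meaningful, large enough to separate monomer
  chemistry, stoichiometry and architecture in practice.
- **Decoder** — pre-LN causal transformer, 4 layers × 4 heads, d_model 64,
  FFN 128. The latent code enters twice: (a) projected and concatenated to
  every token embedding, (b) as 4 learned memory slots attended by
  cross-attention. The duplication is deliberate: the concat path gives every
  position direct access to z (useful early in training), the memory path
  lets attention select what it needs. Greedy and beam (default width 5)
  decoding; decoding always returns a string, and stray BOS/PAD emitted by
  an untrained decoder are stripped rather than raising, with validity
  judged downstream.
- **Property head** — MLP (32 → 48 → 2) on the latent mean, predicting
  standardized (EA, IP); standardization constants are stored in the
  checkpoint.

## 3. Losses and training

`total = recon + β·KL + α·prop` with

- recon: mean token cross entropy (nats) over non-PAD positions;
- KL: closed-form diagonal-Gaussian-to-standard-normal divergence
  (0 at the prior; 0.5 for a unit-mean unit-variance 1-D posterior — both
  asserted in tests);
- prop: masked squared error, mean over labelled rows and both properties;
  an all-unlabelled batch contributes an exact structural zero with exactly
  zero gradient — the semi-supervised contract.

α = 0.2 and β_max = 4·10⁻⁴ with a cyclical ramp (linear to β_max over half a
cycle of 200 optimizer steps, then flat). The small β reflects the loss
scale: per-token reconstruction is O(1) nat while the summed KL is O(10)
nats, and a larger β collapses the posterior before the decoder learns the
grammar.

**β at the overfit scale.** With only 10 records, β = 4·10⁻⁴ yields perfect
reconstruction but an aggregate posterior ~36 nats from the prior, so prior
samples decode to garbage. The 10-record smoke runs therefore use β = 0.003
(same schedule), which keeps the posterior near the prior (KL ≈ 5) while
still reconstructing ≥ 9/10. The weight on a sample-averaged KL is
effectively dataset-size dependent; this is documented here rather than
hidden in the fixtures.

Optimizer: Adam (lr 10⁻³, global-norm gradient clipping at 1.0). Batches are
length-bucketed — records sorted once by token length, fixed buckets, bucket
order shuffled per epoch — which cuts PAD computation substantially and
remains deterministic under the seed.

## 4. Numerical choices

- Training runs in float32 (memory and speed on CPU); encoding for metrics,
  latent tools and inverse design runs in float64 for stable re-encoding and
  PCA. The autodiff engine propagates input dtype everywhere — two earlier
  float64-promotion leaks (relu backward mask, where-mask constant) doubled
  step time and are guarded by a dtype test.
- Attention and token cross entropy are fused ops with analytic backwards,
  avoiding materializing large intermediate graphs.
- The wD-MPNN forward is vectorized with incidence/reverse-index matrices;
  its correctness is pinned by a brute-force loop oracle (≤ 10⁻⁵) and a node
  permutation-invariance test (≤ 10⁻⁵) in float64.
- PCA (`project_2d`) uses SVD on centered data and raises on rank-deficient
  inputs instead of returning meaningless axes.

## 5. Inverse design

Objective (minimized): `f(z) = w_ip·|IP̂(z) − ip_target| + w_ea·EÂ(z)`
(or `w_ea·|EÂ − ea_target|` in target mode), plus a fixed penalty of 10 when
the decoded string is invalid. Properties are predicted from the
decode–re-encode **corrected** latent: each z is decoded, validated, and
re-encoded; this projects off-manifold points back onto encodings of real
polymers, and (for the GA) valid individuals breed from the corrected,
bounds-clipped latent.

- **GA**: NSGA-II machinery (Latin-hypercube initialization via
  `scipy.stats.qmc`, simulated binary crossover η = 15 at rate 0.9,
  polynomial mutation η = 20 at rate 1/D, fast non-dominated sort, crowding
  distance, binary tournament, elitist environmental selection), run
  single-objective by default. Populations are evaluated in one
  `decode_batch` call per generation. Budget accounting is exact.
- **BO**: sklearn `GaussianProcessRegressor` (Constant × Matérn ν = 2.5 +
  White kernel, `normalize_y`) on the negated objective; UCB acquisition
  μ + κσ with κ = 2.576 (the two-sided 99% normal quantile), maximized over
  2000 uniform random candidates per iteration. Exactly `budget`
  evaluations including the LHS initial design.
- Search bounds default to the axis-aligned box of training-set encodings
  padded by one per-dimension standard deviation.

Recovery of a known optimum on a quadratic (GA within 0.1 at budget 2000, BO
within 0.2 at budget 60, non-increasing incumbent trace, exact call counts)
is asserted in the acceptance suite.

## 6. Synthetic data: realism and limits

No DFT labels ship with the package. `fixture_monomers` builds a
deterministic library of substituted aromatic diradicals (phenylene,
thiophene, furan, pyrrole, pyridine, naphthalene scaffolds × 20
substituents), large enough to materialize the full 9 × 682 × 7 = 42 966
labelled + 682 × 20 × 7 = 95 480 augmented = 138 446-record design space.

`pseudo_property_oracle` assigns (EA, IP) as linear functions of
stoichiometry-weighted heteroatom/halogen counts, ring count and a
blockiness term, clipped to EA ∈ [−5, 1] eV and IP ∈ [0, 3] eV, with
optional Gaussian noise. This captures the *structure* a real label source
would have — smooth dependence on composition, explicit dependence on
stoichiometry and architecture (so combination-level splits are honest),
ranges matching conjugated-polymer photocatalysis — but it is deliberately
simple: linear, local, conformer-free, and far easier to regress than DFT.
Held-out R² ≈ 0.9 here therefore demonstrates that the semi-supervised
pipeline transmits label information through the latent bottleneck, not that
the architecture would reach that accuracy on quantum-chemical labels.

Other limits worth naming: monomers are restricted to two attachment points;
the decoder's max length (160–256 tokens) caps monomer size; validity of
generated strings is grammatical + valence-level (RDKit), not synthetic
accessibility; and BO's random-candidate acquisition maximization is crude in
32 dimensions — it is the budget-limited baseline, the GA is the workhorse.

## 7. Limitations

- CPU-only NumPy training: minutes for hundreds of records, not suited to
  the 10⁵-record regime without a framework backend.
- Single diagonal-Gaussian prior; no explicit disentanglement of chemistry
  vs. architecture in the latent space.
- Property predictions come from the latent mean only; predictive
  uncertainty is available solely through the BO surrogate, not the model.
- Novelty/uniqueness metrics treat canonical-string identity as material
  identity; tautomers or resonance-equivalent monomers drawn differently
  would count as distinct.
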