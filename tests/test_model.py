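"""Model core: encoder oracle + invariance, decoder contracts, persistence."""

import numpy as np
import pytest

from copolyvae import dataset as ds
from copolyvae.model_core import (
    CopolymerVAE, EncoderOutput, LatentPoint, LengthError, ModelConfig,
    decoder_forward, encoder_forward, init_params, pack_graphs,
)
from copolyvae.polymer_repr import (
    NODE_FEATURE_DIM, EDGE_FEATURE_DIM, PolymerGraph, Vocabulary,
    build_graph, parse_polymer_string, tokenize,
)

STRINGS = [r.polymer_string for r in ds.fixture_dataset(2, 4, seed=0)[:8]]


@pytest.fixture(scope="module")
def model():
    vocab = Vocabulary.build(STRINGS)
    return CopolymerVAE(ModelConfig(max_len=160), vocab, seed=0)


def np_params(model):
    return {k: v.data.astype(np.float64) for k, v in model.params.items()}


# -- encoder ----------------------------------------------------------------

def test_encoder_output_shapes(model):
    out = model.encode(parse_polymer_string(STRINGS[0]))
    assert out.mu.shape == (32,)
    assert out.sigma2.shape == (32,)
    assert np.all(out.sigma2 > 0)


def test_encoder_batch_matches_single(model):
    graphs = [build_graph(parse_polymer_string(s)) for s in STRINGS[:3]]
    batch = model.encode_graphs(graphs)
    for i, g in enumerate(graphs):
        single = model.encode_graphs([g])
        assert np.allclose(batch.mu[i], single.mu[0], atol=1e-9)


def random_unit_graph(rng, n_nodes=5):
    """Synthetic all-unit-weight graph: path + one branch, both directions."""
    und = [(i, i + 1) for i in range(n_nodes - 1)] + [(0, n_nodes - 1)]
    src, dst = [], []
    for a, b in und:
        src += [a, b]
        dst += [b, a]
    E = len(src)
    return PolymerGraph(
        node_features=rng.uniform(size=(n_nodes, NODE_FEATURE_DIM)),
        node_weights=np.full(n_nodes, 1.0 / n_nodes) * n_nodes / n_nodes + (1.0 - 1.0),
        monomer_of_node=np.zeros(n_nodes, dtype=int),
        edge_src=np.array(src),
        edge_dst=np.array(dst),
        edge_features=rng.uniform(size=(E, EDGE_FEATURE_DIM)),
        edge_weights=np.ones(E),
    )


def brute_force_mpnn(p, g: PolymerGraph, iters: int):
    """Unweighted directed message passing computed with explicit loops."""
    relu = lambda x: np.maximum(x, 0.0)
    E = g.n_edges
    h0 = np.stack([
        relu(np.concatenate([g.node_features[g.edge_src[e]],
                             g.edge_features[e]]) @ p["enc.W_init"]
             + p["enc.b_init"]) for e in range(E)])
    h = h0.copy()
    for _ in range(iters - 1):
        new = np.empty_like(h)
        for e in range(E):
            u, v = g.edge_src[e], g.edge_dst[e]
            m = np.zeros(h.shape[1])
            for k in range(E):
                # incoming edges w->u except the reverse edge v->u
                if g.edge_dst[k] == u and g.edge_src[k] != v:
                    m += h[k]
            new[e] = relu(h0[e] + m @ p["enc.W_msg"])
        h = new
    hv = np.empty((g.n_nodes, h.shape[1]))
    for v in range(g.n_nodes):
        incoming = sum((h[e] for e in range(E) if g.edge_dst[e] == v),
                       np.zeros(h.shape[1]))
        hv[v] = relu(np.concatenate([g.node_features[v], incoming])
                     @ p["enc.W_node"] + p["enc.b_node"])
    return hv.mean(axis=0)  # uniform node weights


def test_encoder_matches_brute_force_oracle(model):
    rng = np.random.default_rng(0)
    cfg = model.cfg
    p = np_params(model)
    for trial in range(3):
        g = random_unit_graph(rng, n_nodes=4 + trial)
        g.node_weights = np.full(g.n_nodes, 1.0 / g.n_nodes)
        packed = pack_graphs([g], dtype=np.float64)
        _, _, emb = encoder_forward(p, packed, cfg)
        oracle = brute_force_mpnn(p, g, cfg.mpnn_iters)
        assert np.max(np.abs(np.asarray(emb)[0] - oracle)) < 1e-5


def permute_graph(g: PolymerGraph, perm: np.ndarray) -> PolymerGraph:
    inv = np.argsort(perm)
    return PolymerGraph(
        node_features=g.node_features[perm],
        node_weights=g.node_weights[perm],
        monomer_of_node=np.asarray(g.monomer_of_node)[perm],
        edge_src=inv[g.edge_src],
        edge_dst=inv[g.edge_dst],
        edge_features=g.edge_features,
        edge_weights=g.edge_weights,
    )


def test_encoder_permutation_invariance(model):
    rng = np.random.default_rng(1)
    for s in STRINGS[:4]:
        g = build_graph(parse_polymer_string(s))
        perm = rng.permutation(g.n_nodes)
        mu1 = model.encode_graphs([g]).mu[0]
        mu2 = model.encode_graphs([permute_graph(g, perm)]).mu[0]
        assert np.max(np.abs(mu1 - mu2)) < 1e-5


def test_weighted_pooling_duplication_limit(model):
    """Duplicating a disconnected component while halving its node weights
    leaves the pooled embedding unchanged (pooling is weight-linear)."""
    g = build_graph(parse_polymer_string(STRINGS[0]))
    n, e = g.n_nodes, g.n_edges
    dup = PolymerGraph(
        node_features=np.concatenate([g.node_features, g.node_features]),
        node_weights=np.concatenate([g.node_weights, g.node_weights]) / 2.0,
        monomer_of_node=np.concatenate([g.monomer_of_node, g.monomer_of_node]),
        edge_src=np.concatenate([g.edge_src, g.edge_src + n]),
        edge_dst=np.concatenate([g.edge_dst, g.edge_dst + n]),
        edge_features=np.concatenate([g.edge_features, g.edge_features]),
        edge_weights=np.concatenate([g.edge_weights, g.edge_weights]),
    )
    mu1 = model.encode_graphs([g]).mu[0]
    mu2 = model.encode_graphs([dup]).mu[0]
    assert np.max(np.abs(mu1 - mu2)) < 1e-5


# -- reparameterization -----------------------------------------------------

def test_reparameterize_zero_variance(model):
    out = EncoderOutput(mu=np.ones(32), sigma2=np.zeros(32))
    z = CopolymerVAE.reparameterize(out, seed=0)
    assert np.allclose(z.z, 1.0)


def test_reparameterize_seeded_deterministic():
    out = EncoderOutput(mu=np.zeros(8), sigma2=np.ones(8))
    z1 = CopolymerVAE.reparameterize(out, seed=3)
    z2 = CopolymerVAE.reparameterize(out, seed=3)
    assert np.array_equal(z1.z, z2.z)


def test_reparameterize_moments():
    out = EncoderOutput(mu=np.full(4, 0.7), sigma2=np.full(4, 0.25))
    rng = np.random.default_rng(0)
    draws = np.stack([CopolymerVAE.reparameterize(out, rng=rng).z
                      for _ in range(10000)])
    se = 0.5 / np.sqrt(10000)
    assert np.all(np.abs(draws.mean(axis=0) - 0.7) < 3 * se)


def test_latent_point_rejects_nonfinite():
    with pytest.raises(ValueError):
        LatentPoint(z=np.array([1.0, np.nan]))


# -- decoder ----------------------------------------------------------------

def test_teacher_forced_causality(model):
    s = STRINGS[0]
    seq = tokenize(s, model.vocab)
    z = LatentPoint(z=np.zeros(32))
    base = model.teacher_forced_logits(z, seq)
    ids = list(seq.ids)
    t = len(ids) // 2
    ids[t] = model.vocab.eos_id  # perturb token t
    pert = model.teacher_forced_logits(z, type(seq)(ids=ids, vocabulary=model.vocab))
    # positions < t (predicting tokens 1..t) see only tokens < t
    assert np.allclose(base[:t - 1], pert[:t - 1], atol=1e-8)
    assert not np.allclose(base[t:], pert[t:], atol=1e-6)


def test_teacher_forced_normalized(model):
    seq = tokenize(STRINGS[1], model.vocab)
    logits = model.teacher_forced_logits(LatentPoint(z=np.zeros(32)), seq)
    probs = np.exp(logits - logits.max(axis=-1, keepdims=True))
    probs /= probs.sum(axis=-1, keepdims=True)
    assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6)


def test_concat_latent_path_separable(model):
    seq = tokenize(STRINGS[0], model.vocab)
    z = LatentPoint(z=np.ones(32))
    with_cat = model.teacher_forced_logits(z, seq, concat_latent=True)
    without = model.teacher_forced_logits(z, seq, concat_latent=False)
    assert not np.allclose(with_cat, without, atol=1e-6)


def test_length_error(model):
    ids = [model.vocab.bos_id] + [model.vocab.eos_id] * (model.cfg.max_len + 5)
    from copolyvae.polymer_repr import TokenSequence
    with pytest.raises(LengthError):
        model.teacher_forced_logits(
            LatentPoint(z=np.zeros(32)),
            TokenSequence(ids=ids, vocabulary=model.vocab))


def test_beam_one_equals_greedy(model):
    rng = np.random.default_rng(2)
    for z in rng.standard_normal((3, 32)):
        g = model.decode(LatentPoint(z=z), mode="greedy", max_len=60)
        b = model.decode(LatentPoint(z=z), mode="beam", beam_size=1, max_len=60)
        assert g == b


def test_decode_terminates_within_max_len(model):
    z = LatentPoint(z=np.zeros(32))
    s = model.decode(z, max_len=30)
    assert isinstance(s, str)


def test_decode_deterministic(model):
    z = LatentPoint(z=np.full(32, 0.3))
    assert model.decode(z, max_len=40) == model.decode(z, max_len=40)


# -- property head ----------------------------------------------------------

def test_predict_properties_shape_and_determinism(model):
    z = LatentPoint(z=np.linspace(-1, 1, 32))
    out1 = model.predict_properties(z)
    out2 = model.predict_properties(z)
    assert len(out1) == 2
    assert out1 == out2
    assert all(np.isfinite(v) for v in out1)


# -- persistence ------------------------------------------------------------

def test_save_load_round_trip(model, tmp_path):
    path = str(tmp_path / "ckpt.npz")
    model.prop_mean = np.array([-1.0, 1.2])
    model.prop_std = np.array([0.5, 0.4])
    model.save(path)
    clone = CopolymerVAE.load(path)
    g = build_graph(parse_polymer_string(STRINGS[0]))
    assert np.allclose(model.encode_graphs([g]).mu, clone.encode_graphs([g]).mu)
    z = LatentPoint(z=np.zeros(32))
    assert model.decode(z, max_len=40) == clone.decode(z, max_len=40)
    assert model.predict_properties(z) == clone.predict_properties(z)
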