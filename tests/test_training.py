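"""Loss closed forms, schedule, optimizer, and the training loop."""

import numpy as np
import pytest

import copolyvae.autodiff as ad
from copolyvae.autodiff import Tensor
from copolyvae import dataset as ds
from copolyvae.model_core import CopolymerVAE, EncoderOutput, ModelConfig
from copolyvae.polymer_repr import Vocabulary
from copolyvae.training import (
    Adam, DegenerateInputError, DomainError, LossBreakdown, TrainConfig,
    batch_losses, beta_schedule, kl_from_mu_logvar, kl_loss,
    masked_property_loss, prepare_records, reconstruction_loss, train,
)


# -- reconstruction loss ----------------------------------------------------

def test_reconstruction_near_delta_logits():
    V, pad = 6, 0
    targets = np.array([[1, 2, 3]])
    logits = np.full((1, 3, V), -20.0)
    for t, tok in enumerate(targets[0]):
        logits[0, t, tok] = 20.0
    loss = reconstruction_loss(Tensor(logits), targets, pad)
    assert float(loss.data) < 1e-3


def test_reconstruction_uniform_logits_ln_v():
    V, pad = 11, 0
    targets = np.array([[3, 4, 5, 6]])
    logits = np.zeros((1, 4, V))
    loss = reconstruction_loss(Tensor(logits), targets, pad)
    assert float(loss.data) == pytest.approx(np.log(V), rel=1e-5)


def test_reconstruction_pad_exclusion():
    V, pad = 7, 0
    rng = np.random.default_rng(0)
    logits = rng.standard_normal((1, 3, V))
    targets = np.array([[2, 5, 1]])
    base = float(reconstruction_loss(Tensor(logits), targets, pad).data)
    padded_logits = np.concatenate([logits, rng.standard_normal((1, 2, V))], axis=1)
    padded_targets = np.array([[2, 5, 1, pad, pad]])
    padded = float(reconstruction_loss(Tensor(padded_logits), padded_targets, pad).data)
    assert padded == pytest.approx(base, rel=1e-6)


def test_reconstruction_all_pad_error():
    with pytest.raises(DegenerateInputError):
        reconstruction_loss(Tensor(np.zeros((1, 2, 4))), np.zeros((1, 2), int), 0)


# -- KL ---------------------------------------------------------------------

def test_kl_zero_at_prior():
    out = EncoderOutput(mu=np.zeros(32), sigma2=np.ones(32))
    assert kl_loss(out) == pytest.approx(0.0, abs=1e-12)


def test_kl_half_at_unit_mean_1d():
    out = EncoderOutput(mu=np.array([[1.0]]), sigma2=np.array([[1.0]]))
    assert kl_loss(out) == pytest.approx(0.5)


def test_kl_nonnegative_random():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        mu = rng.standard_normal(4)
        s2 = np.exp(rng.standard_normal(4))
        assert kl_loss(EncoderOutput(mu=mu, sigma2=s2)) >= 0.0


def test_kl_domain_error():
    with pytest.raises(DomainError):
        kl_loss(EncoderOutput(mu=np.zeros(2), sigma2=np.array([1.0, 0.0])))


def test_kl_tensor_path_matches_float_path():
    rng = np.random.default_rng(1)
    mu = rng.standard_normal((3, 5))
    logvar = rng.standard_normal((3, 5)) * 0.3
    t = kl_from_mu_logvar(Tensor(mu), Tensor(logvar))
    f = kl_loss(EncoderOutput(mu=mu, sigma2=np.exp(logvar)))
    assert float(t.data) == pytest.approx(f, rel=1e-5)


# -- masked property loss ---------------------------------------------------

def test_masked_property_all_zero_mask():
    pred = np.zeros((3, 2))
    assert float(masked_property_loss(pred, np.ones((3, 2)), np.zeros(3))) == 0.0


def test_masked_property_exact_match():
    labels = np.array([[1.0, -2.0]])
    assert float(masked_property_loss(labels.copy(), labels, np.ones(1))) == 0.0


def test_masked_property_hand_case():
    pred = np.array([[1.0, 2.0]])
    labels = np.array([[0.0, 0.0]])
    loss = masked_property_loss(pred, labels, np.ones(1))
    assert float(loss) == pytest.approx(2.5)


def test_property_gradients_zero_for_unlabelled():
    pred = Tensor(np.ones((4, 2)), requires_grad=True)
    loss = masked_property_loss(pred, np.full((4, 2), 9.0), np.zeros(4))
    loss.backward()
    assert np.all(pred.grad == 0.0)


def test_property_gradients_only_from_labelled_rows():
    pred = Tensor(np.ones((3, 2)), requires_grad=True)
    mask = np.array([1.0, 0.0, 1.0])
    loss = masked_property_loss(pred, np.zeros((3, 2)), mask)
    loss.backward()
    assert np.all(pred.grad[1] == 0.0)
    assert np.all(pred.grad[[0, 2]] != 0.0)


# -- loss composition -------------------------------------------------------

def test_total_identity_random():
    rng = np.random.default_rng(2)
    for _ in range(20):
        bd = LossBreakdown(recon=rng.uniform(0, 5), kl=rng.uniform(0, 50),
                           prop=rng.uniform(0, 3), beta=rng.uniform(0, 1e-3),
                           alpha=rng.uniform(0, 1))
        assert bd.total == pytest.approx(
            bd.recon + bd.beta * bd.kl + bd.alpha * bd.prop)


# -- beta schedule -----------------------------------------------------------

def test_beta_schedule_shape():
    cfg = TrainConfig(cycle=100, beta_max=0.0004)
    assert beta_schedule(0, cfg) == 0.0
    assert beta_schedule(50, cfg) == pytest.approx(cfg.beta_max)
    assert beta_schedule(75, cfg) == pytest.approx(cfg.beta_max)
    for t in range(0, 300):
        b = beta_schedule(t, cfg)
        assert 0.0 <= b <= cfg.beta_max
        assert b == pytest.approx(beta_schedule(t + cfg.cycle, cfg))
    with pytest.raises(ValueError):
        beta_schedule(-1, cfg)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(alpha=-0.1)
    with pytest.raises(ValueError):
        TrainConfig(beta_max=0.0)


# -- optimizer ---------------------------------------------------------------

def test_adam_descends_quadratic():
    x = Tensor(np.array([5.0]), requires_grad=True)
    opt = Adam({"x": x}, lr=0.1, clip_norm=0.0)
    for _ in range(200):
        loss = ad.tsum(x * x)
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert abs(float(x.data[0])) < 0.1


def test_adam_clipping_bounds_update_norm():
    x = Tensor(np.array([1000.0]), requires_grad=True)
    opt = Adam({"x": x}, lr=0.1, clip_norm=1.0)
    loss = ad.tsum(x * x)
    loss.backward()
    g_before = x.grad.copy()
    opt.step()
    assert abs(g_before[0]) > 1.0  # raw grad was large; clip engaged


# -- train loop ---------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_setup():
    records = ds.fixture_dataset(1, 3, seed=0)[:6]
    vocab = Vocabulary.build([r.polymer_string for r in records])
    return records, vocab


def test_train_loss_decreases(tiny_setup):
    records, vocab = tiny_setup
    model = CopolymerVAE(ModelConfig(max_len=160), vocab, seed=0)
    hist = train(model, records, None,
                 TrainConfig(epochs=8, batch_size=6, patience=50, seed=0))
    assert hist[-1]["total"] < hist[0]["total"]


def test_train_determinism(tiny_setup):
    records, vocab = tiny_setup
    h = []
    for _ in range(2):
        model = CopolymerVAE(ModelConfig(max_len=160), vocab, seed=0)
        h.append(train(model, records, None,
                       TrainConfig(epochs=1, batch_size=6, patience=5, seed=0)))
    assert h[0][0]["total"] == pytest.approx(h[1][0]["total"], rel=1e-6)


def test_train_alpha_zero_leaves_property_head_unchanged(tiny_setup):
    records, vocab = tiny_setup
    unlabelled = [type(r)(polymer_string=r.polymer_string, properties=None,
                          key=r.key) for r in records]
    model = CopolymerVAE(ModelConfig(max_len=160), vocab, seed=0)
    before = {k: v.data.copy() for k, v in model.params.items()
              if k.startswith("prop.")}
    train(model, unlabelled, None,
          TrainConfig(alpha=0.0, epochs=2, batch_size=6, patience=5, seed=0))
    for k, v in before.items():
        assert np.array_equal(v, model.params[k].data)


def test_train_empty_partition_error(tiny_setup):
    _, vocab = tiny_setup
    model = CopolymerVAE(ModelConfig(max_len=160), vocab, seed=0)
    with pytest.raises(ValueError):
        train(model, [], None, TrainConfig(epochs=1))


def test_batch_losses_identity(tiny_setup):
    records, vocab = tiny_setup
    model = CopolymerVAE(ModelConfig(max_len=160), vocab, seed=0)
    graphs, toks, labels, mask = prepare_records(records, model)
    total, bd = batch_losses(model, graphs, toks, np.nan_to_num(labels), mask,
                             beta=2e-4, alpha=0.2,
                             rng=np.random.default_rng(0))
    assert float(total.data) == pytest.approx(bd.total, rel=1e-5)
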