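"""Shared fixtures.

The two expensive session fixtures (the 10-record overfit model and the
500-record semi-supervised run) are trained once and reused by every test
that needs a converged model, keeping the whole suite inside its time
budget.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pytest

from copolyvae import dataset as ds
from copolyvae import inverse_design as idn
from copolyvae.model_core import CopolymerVAE, ModelConfig
from copolyvae.polymer_repr import (
    Vocabulary, build_graph, parse_polymer_string,
)
from copolyvae.training import TrainConfig, train


@dataclass
class OverfitBundle:
    model: CopolymerVAE
    strings: List[str]
    train_seconds: float


@dataclass
class E2EBundle:
    model: CopolymerVAE
    train_records: list
    val_records: list
    test_records: list
    r2: Dict[str, float]
    ga_top100_ea: float
    prior100_ea: float
    total_seconds: float


@pytest.fixture(scope="session")
def records10():
    return ds.fixture_dataset(2, 6, seed=0)[:10]


@pytest.fixture(scope="session")
def overfit_bundle(records10) -> OverfitBundle:
    """Train the 10-record smoke model (single batch per step, strong KL
    weight so the posterior stays near the prior at this tiny scale)."""
    strings = [r.polymer_string for r in records10]
    vocab = Vocabulary.build(strings)
    model = CopolymerVAE(ModelConfig(max_len=160), vocab, seed=0)
    cfg = TrainConfig(epochs=1800, batch_size=10, patience=1800, seed=0,
                      beta_max=0.003, cycle=400)
    t0 = time.perf_counter()
    train(model, records10, None, cfg)
    return OverfitBundle(model=model, strings=strings,
                         train_seconds=time.perf_counter() - t0)


@pytest.fixture(scope="session")
def e2e_bundle() -> E2EBundle:
    """The 500-record semi-supervised pipeline: split by combination, train
    with 30% labels, measure held-out R^2 and the GA-vs-prior EA shift."""
    t0 = time.perf_counter()
    records = ds.fixture_dataset(6, 12, labelled_fraction=0.3, seed=0)[:500]
    tr, va, te = ds.split_by_combination(records, seed=0)
    vocab = Vocabulary.build([r.polymer_string for r in tr])
    model = CopolymerVAE(ModelConfig(max_len=160), vocab, seed=0)
    cfg = TrainConfig(epochs=45, batch_size=32, patience=10, seed=0,
                      alpha=0.2, beta_max=0.0004, cycle=200)
    train(model, tr, va, cfg)

    graphs = [build_graph(parse_polymer_string(r.polymer_string)) for r in te]
    mu = model.encode_graphs(graphs).mu
    pred = model.predict_properties_batch(mu)
    true = np.array([ds.pseudo_property_oracle(
        parse_polymer_string(r.polymer_string)) for r in te])
    r2 = {}
    for j, name in enumerate(("ea", "ip")):
        ss_res = float(((true[:, j] - pred[:, j]) ** 2).sum())
        ss_tot = float(((true[:, j] - true[:, j].mean()) ** 2).sum())
        r2[name] = 1.0 - ss_res / ss_tot

    bounds = idn.default_bounds(model, [r.polymer_string for r in tr])
    res = idn.run_ga(model, idn.ObjectiveSpec(), budget=300, population=50,
                     bounds=bounds, seed=0)
    top = sorted(res.evaluations, key=lambda e: e.objective)[:100]
    ga_ea = float(np.mean([e.ea_hat for e in top]))
    zs = np.random.default_rng(123).standard_normal((100, model.cfg.latent_dim))
    prior_ea = float(model.predict_properties_batch(zs)[:, 0].mean())
    return E2EBundle(model=model, train_records=tr, val_records=va,
                     test_records=te, r2=r2, ga_top100_ea=ga_ea,
                     prior100_ea=prior_ea,
                     total_seconds=time.perf_counter() - t0)
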