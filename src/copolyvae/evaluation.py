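"""Generative-model evaluation metrics: reconstruction, validity, novelty
(with its monomer-level decomposition), uniqueness, and prior sampling.

All string comparisons use canonical-form equality: monomer SMILES are
canonicalized, monomers sorted, and numeric fields rendered at fixed
precision, so the metrics are invariant to cosmetic rewrites of the same
ensemble.  Novelty decomposes exactly as

    novel% = novel-monomer% + novel-combination%

where a sampled polymer is "novel-monomer" if it contains at least one
canonical monomer SMILES absent from the training set, and
"novel-combination" if it is novel overall but all its monomers are known
(new pairing, stoichiometry or architecture).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .dataset import DatasetRecord
from .model_core import CopolymerVAE
from .polymer_repr import (
    PolymerError, build_graph, canonical_string, parse_polymer_string, validate,
)


class EmptySetError(ValueError):
    pass


@dataclass
class MetricReport:
    """Percentages in [0, 100]; fields may be None when not computed."""
    reconstruction: Optional[float] = None
    validity: Optional[float] = None
    novelty: Optional[float] = None
    uniqueness: Optional[float] = None
    monomer_novelty: Optional[float] = None
    combination_novelty: Optional[float] = None
    n_samples: int = 0

    def __post_init__(self):
        for f in ("reconstruction", "validity", "novelty", "uniqueness",
                  "monomer_novelty", "combination_novelty"):
            v = getattr(self, f)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{f} must lie in [0, 100], got {v}")

    def to_dict(self) -> dict:
        return {
            "reconstruction": self.reconstruction,
            "validity": self.validity,
            "novelty": self.novelty,
            "uniqueness": self.uniqueness,
            "monomer_novelty": self.monomer_novelty,
            "combination_novelty": self.combination_novelty,
            "n_samples": self.n_samples,
        }


def _canonical_or_none(s: str) -> Optional[str]:
    try:
        return canonical_string(parse_polymer_string(s))
    except PolymerError:
        return None
    except Exception:
        return None


def reconstruction_accuracy(model: CopolymerVAE,
                            records: Sequence[DatasetRecord],
                            mode: str = "greedy",
                            batch_size: int = 32) -> float:
    """Percent of records whose decode(encode-mean) equals the input string
    in canonical form (monomers, stoichiometry and connectivity included)."""
    if not records:
        raise EmptySetError("reconstruction_accuracy needs a non-empty test set")
    strings = [r.polymer_string for r in records]
    targets = [_canonical_or_none(s) for s in strings]
    n_ok = 0
    for lo in range(0, len(strings), batch_size):
        chunk = strings[lo:lo + batch_size]
        graphs = [build_graph(parse_polymer_string(s)) for s in chunk]
        mu = model.encode_graphs(graphs).mu
        decoded = model.decode_batch(mu, mode=mode)
        for d, tgt in zip(decoded, targets[lo:lo + batch_size]):
            if tgt is not None and _canonical_or_none(d) == tgt:
                n_ok += 1
    return 100.0 * n_ok / len(strings)


def validity_rate(strings: Sequence[str]) -> float:
    """Percent of strings accepted by the full grammar + chemistry validator."""
    if not strings:
        raise EmptySetError("validity_rate needs a non-empty set")
    n_ok = sum(1 for s in strings if validate(s).valid)
    return 100.0 * n_ok / len(strings)


def _training_keys(training: Iterable[str]) -> Tuple[Set[str], Set[str]]:
    canon: Set[str] = set()
    monomers: Set[str] = set()
    for s in training:
        spec = parse_polymer_string(s)
        canon.add(canonical_string(spec))
        for m in spec.monomers:
            monomers.add(m.canonical_smiles())
    return canon, monomers


def novelty(sampled: Sequence[str],
            training: Sequence[str]) -> Tuple[float, float, float]:
    """(% novel, % novel-monomer, % novel-combination) over the *valid*
    interpretation of each sampled string; invalid samples count as not novel
    (they are not new materials).  The three percentages satisfy
    novel = novel_monomer + novel_combination exactly."""
    if not sampled:
        raise EmptySetError("novelty needs a non-empty sampled set")
    train_canon, train_monomers = _training_keys(training)
    n_novel = n_novel_mono = 0
    for s in sampled:
        try:
            spec = parse_polymer_string(s)
        except Exception:
            continue
        if canonical_string(spec) in train_canon:
            continue
        n_novel += 1
        if any(m.canonical_smiles() not in train_monomers for m in spec.monomers):
            n_novel_mono += 1
    n = len(sampled)
    pct = 100.0 / n
    return (n_novel * pct, n_novel_mono * pct, (n_novel - n_novel_mono) * pct)


def uniqueness(sampled: Sequence[str]) -> float:
    """Percent of distinct canonical strings among the sampled set; invalid
    strings are distinguished by their raw text."""
    if not sampled:
        raise EmptySetError("uniqueness needs a non-empty set")
    keys = set()
    for s in sampled:
        c = _canonical_or_none(s)
        keys.add(c if c is not None else ("__raw__", s))
    return 100.0 * len(keys) / len(sampled)


def sample_prior(model: CopolymerVAE, n: int = 16000, seed: int = 0,
                 mode: str = "greedy", batch_size: int = 64) -> List[str]:
    """Decode n latent points drawn from the standard-normal prior."""
    rng = np.random.default_rng(seed)
    out: List[str] = []
    for lo in range(0, n, batch_size):
        b = min(batch_size, n - lo)
        zs = rng.standard_normal((b, model.cfg.latent_dim))
        out.extend(model.decode_batch(zs, mode=mode))
    return out


def evaluate_model(model: CopolymerVAE,
                   test_records: Sequence[DatasetRecord],
                   train_records: Sequence[DatasetRecord],
                   n_samples: int = 500, seed: int = 0,
                   mode: str = "greedy") -> MetricReport:
    """One-stop metric computation used by the CLI."""
    samples = sample_prior(model, n=n_samples, seed=seed, mode=mode)
    nov, nov_m, nov_c = novelty(samples, [r.polymer_string for r in train_records])
    return MetricReport(
        reconstruction=reconstruction_accuracy(model, test_records, mode=mode),
        validity=validity_rate(samples),
        novelty=nov,
        uniqueness=uniqueness(samples),
        monomer_novelty=nov_m,
        combination_novelty=nov_c,
        n_samples=n_samples,
    )
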