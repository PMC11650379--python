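"""Combinatorial copolymer design space, augmentation, leakage-free splits
and synthetic fixtures with a deterministic pseudo-property oracle.

The design space pairs a small set of A-monomers with a large set of
B-monomers under seven stoichiometry/architecture combinations: 1:1, 1:3 and
3:1 each with block and random chains, plus alternating at 1:1 (alternating
is only well defined at equal stoichiometry).  An augmented, unlabelled B–B
set widens the chemistry seen by the encoder; only the enumerated A–B records
carry property labels, giving the partly-labelled structure a semi-supervised
model trains on.

The pseudo-property oracle replaces quantum-chemistry labels with a
deterministic, composition-based surrogate so that supervised behaviour is
testable offline: both outputs are clipped linear functions of
stoichiometry-weighted monomer descriptors (heteroatom counts, ring counts)
plus a chain-architecture blockiness term.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem

from .polymer_repr import (
    Monomer, PolymerEnsembleSpec, StructuralError, combination_key, make_spec,
    serialize,
)

# the seven stoichiometry/architecture combinations of the A-B design space
STOICHIOMETRIES = ((0.5, 0.5), (0.25, 0.75), (0.75, 0.25))
DEFAULT_COMBOS: Tuple[Tuple[Tuple[float, float], str], ...] = tuple(
    (s, arch)
    for s in STOICHIOMETRIES
    for arch in ("alternating", "block", "random")
    if not (arch == "alternating" and s != (0.5, 0.5))
)
assert len(DEFAULT_COMBOS) == 7


class SplitError(ValueError):
    pass


class SamplingError(ValueError):
    pass


@dataclass
class DatasetRecord:
    """One polymer string with optional (EA, IP) labels in eV."""

    polymer_string: str
    properties: Optional[Tuple[float, float]] = None
    key: str = ""

    @property
    def label_mask(self) -> int:
        return 1 if self.properties is not None else 0


@dataclass
class DesignSpace:
    a_monomers: List[Monomer]
    b_monomers: List[Monomer]
    combos: Tuple[Tuple[Tuple[float, float], str], ...] = DEFAULT_COMBOS

    def __post_init__(self):
        if not self.combos:
            raise ValueError("combos must be non-empty")


# --------------------------------------------------------------------------
# fixture monomer library

_SCAFFOLDS = (
    "[*:1]c1ccc([*:2])cc1",            # p-phenylene
    "[*:1]c1ccc([*:2])s1",             # thiophene-2,5-diyl
    "[*:1]c1ccc([*:2])o1",             # furan-2,5-diyl
    "[*:1]c1ccc([*:2])[nH]1",          # pyrrole-2,5-diyl
    "[*:1]c1ccc([*:2])nc1",            # pyridine-2,5-diyl
    "[*:1]c1cc(X)cc([*:2])c1",         # m-substituted phenylene
    "[*:1]c1cc(X)c([*:2])s1",          # substituted thiophene
    "[*:1]c1c(X)cc([*:2])cc1(X)",      # doubly substituted phenylene
    "[*:1]c1nc(X)c([*:2])c1(X)",       # substituted pyrrole-type diazole
    "[*:1]c1cc(X)c(X)cc1[*:2]",        # ortho-disubstituted phenylene
    "[*:1]c1nc([*:2])c(X)s1",          # thiazole-like
    "[*:1]c1cc2cc([*:2])cc(X)c2cc1",   # naphthalene-like
)
_SUBSTITUENTS = ("", "F", "Cl", "Br", "C", "CC", "CCC", "C(C)C", "N", "N(C)C",
                 "NC", "O", "OC", "OCC", "C#N", "C(F)(F)F", "C=O", "C(=O)C",
                 "C(=O)OC", "SC")


def fixture_monomers(n: int, seed: int = 0) -> List[Monomer]:
    """Deterministic library of `n` distinct valid two-point monomers drawn
    from a substituted aromatic template family."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    candidates: List[str] = []
    for scaffold in _SCAFFOLDS:
        slots = scaffold.count("(X)")
        if slots == 0:
            candidates.append(scaffold)
            continue
        for subs in itertools.product(_SUBSTITUENTS, repeat=slots):
            s = scaffold
            for sub in subs:
                s = s.replace("(X)", f"({sub})" if sub else "", 1)
            candidates.append(s)
    order = rng.permutation(len(candidates))
    out, seen = [], set()
    for i in order:
        smi = candidates[i]
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        m = Monomer(canon)
        if m.n_points != 2:
            continue
        seen.add(canon)
        out.append(m)
        if len(out) == n:
            return out
    raise SamplingError(f"template family exhausted at {len(out)} < {n} monomers")


# --------------------------------------------------------------------------
# pseudo-property oracle

# per-heteroatom EA increments (eV); documented so tests can assert deltas
EA_COEF = {"N": -0.35, "S": -0.20, "O": -0.15, "F": -0.25, "Cl": -0.18}
IP_COEF = {"N": 0.20, "S": 0.10, "O": 0.12, "F": 0.15, "Cl": 0.08}
EA_BASE, EA_RING, EA_ARCH = -1.0, -0.30, -0.40
IP_BASE, IP_RING, IP_ARCH = 1.2, 0.15, 0.25
EA_RANGE, IP_RANGE = (-5.0, 1.0), (0.0, 3.0)


from functools import lru_cache


@lru_cache(maxsize=100_000)
def _descriptor_by_smiles(smiles: str) -> Tuple[Tuple[str, float], ...]:
    return tuple(_monomer_descriptor_uncached(Monomer(smiles)).items())


def _monomer_descriptor(mono: Monomer) -> Dict[str, float]:
    return dict(_descriptor_by_smiles(mono.smiles))


def _monomer_descriptor_uncached(mono: Monomer) -> Dict[str, float]:
    mol = mono.mol()
    counts = {el: 0 for el in EA_COEF}
    heavy = 0
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            continue
        heavy += 1
        sym = atom.GetSymbol()
        if sym in counts:
            counts[sym] += 1
    counts["rings"] = float(mol.GetRingInfo().NumRings())
    counts["heavy"] = float(heavy)
    return counts


def _blockiness(spec: PolymerEnsembleSpec) -> float:
    """Mean probability that a chain continues within the same monomer."""
    tot, n = 0.0, 0
    for (a, b), p in spec.connectivity.items():
        tot += p if a[0] == b[0] else 0.0
        n += 1
    return tot / n if n else 0.0


def pseudo_property_oracle(spec: PolymerEnsembleSpec,
                           noise_sigma: float = 0.0,
                           rng: Optional[np.random.Generator] = None,
                           ) -> Tuple[float, float]:
    """Deterministic EA/IP-like labels (eV) from composition and architecture.

    EA = clip(EA_BASE + Σ_el EA_COEF[el]·⟨n_el⟩ + EA_RING·⟨rings⟩
              + EA_ARCH·blockiness, −5, 1), analogously for IP, where ⟨·⟩ is
    the stoichiometry-weighted mean over monomers.  Permutation-invariant
    because descriptors come from the canonical molecular graph.
    """
    descs = [_monomer_descriptor(m) for m in spec.monomers]
    mix = {k: sum(f * d[k] for f, d in zip(spec.fractions, descs))
           for k in descs[0]}
    blocky = _blockiness(spec)
    ea = EA_BASE + sum(EA_COEF[el] * mix[el] for el in EA_COEF) \
        + EA_RING * mix["rings"] + EA_ARCH * blocky
    ip = IP_BASE + sum(IP_COEF[el] * mix[el] for el in IP_COEF) \
        + IP_RING * mix["rings"] + IP_ARCH * blocky
    if noise_sigma > 0.0:
        if rng is None:
            rng = np.random.default_rng(0)
        ea += rng.normal(0.0, noise_sigma)
        ip += rng.normal(0.0, noise_sigma)
    return (float(np.clip(ea, *EA_RANGE)), float(np.clip(ip, *IP_RANGE)))


# --------------------------------------------------------------------------
# enumeration / augmentation / splits

def _record(mono_a: Monomer, mono_b: Monomer,
            combo: Tuple[Tuple[float, float], str],
            labelled: bool, noise_sigma: float = 0.0,
            rng: Optional[np.random.Generator] = None) -> DatasetRecord:
    fractions, arch = combo
    spec = make_spec([mono_a, mono_b], fractions, arch)
    props = pseudo_property_oracle(spec, noise_sigma, rng) if labelled else None
    return DatasetRecord(polymer_string=serialize(spec), properties=props,
                         key=combination_key(spec))


def enumerate_space(space: DesignSpace, labelled: bool = True,
                    noise_sigma: float = 0.0, seed: int = 0) -> List[DatasetRecord]:
    """One record per (A, B, combo) triple; count = |A|·|B|·|combos|."""
    for m in space.a_monomers + space.b_monomers:
        if m.n_points != 2:
            raise StructuralError(f"monomer {m.smiles!r} needs exactly 2 attachment points")
    rng = np.random.default_rng(seed)
    out = []
    for a in space.a_monomers:
        for b in space.b_monomers:
            for combo in space.combos:
                out.append(_record(a, b, combo, labelled, noise_sigma, rng))
    return out


def augment_bb(b_monomers: Sequence[Monomer], partners_per_b: int,
               combos: Tuple[Tuple[Tuple[float, float], str], ...] = DEFAULT_COMBOS,
               seed: int = 0) -> List[DatasetRecord]:
    """Unlabelled B–B copolymers: each B monomer paired with `partners_per_b`
    randomly chosen distinct other B monomers, across all combos."""
    if partners_per_b < 0 or partners_per_b > len(b_monomers) - 1:
        raise SamplingError(
            f"partners_per_b={partners_per_b} exceeds pool of {len(b_monomers) - 1}")
    rng = np.random.default_rng(seed)
    out = []
    for i, b in enumerate(b_monomers):
        pool = [j for j in range(len(b_monomers)) if j != i]
        partners = rng.choice(pool, size=partners_per_b, replace=False)
        for j in partners:
            for combo in combos:
                out.append(_record(b, b_monomers[j], combo, labelled=False))
    return out


def split_by_combination(records: Sequence[DatasetRecord],
                         fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
                         seed: int = 0,
                         ) -> Tuple[List[DatasetRecord], List[DatasetRecord], List[DatasetRecord]]:
    """Partition by monomer-combination key so no combination leaks across
    train/val/test.  Groups are assigned to partitions by largest-remainder
    rounding of the requested fractions."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise SplitError("fractions must sum to 1")
    keys = sorted({r.key for r in records})
    if len(keys) < 3:
        raise SplitError(f"need >= 3 combination groups, got {len(keys)}")
    rng = np.random.default_rng(seed)
    keys = [keys[i] for i in rng.permutation(len(keys))]
    n = len(keys)
    quotas = [f * n for f in fractions]
    counts = [int(q) for q in quotas]
    rem = n - sum(counts)
    order = np.argsort([-(q - int(q)) for q in quotas])
    for i in range(rem):
        counts[order[i]] += 1
    bounds = np.cumsum(counts)
    assign: Dict[str, int] = {}
    for i, k in enumerate(keys):
        assign[k] = int(np.searchsorted(bounds, i, side="right"))
    parts: Tuple[List[DatasetRecord], ...] = ([], [], [])
    for r in records:
        parts[assign[r.key]].append(r)
    return parts


# --------------------------------------------------------------------------
# CSV io (schema: polymer_string, ea, ip, labelled)

def records_to_frame(records: Sequence[DatasetRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "polymer_string": [r.polymer_string for r in records],
        "ea": [r.properties[0] if r.properties else np.nan for r in records],
        "ip": [r.properties[1] if r.properties else np.nan for r in records],
        "labelled": [r.label_mask for r in records],
    })


def frame_to_records(df: pd.DataFrame) -> List[DatasetRecord]:
    from .polymer_repr import parse_polymer_string
    out = []
    for _, row in df.iterrows():
        props = None
        if int(row.get("labelled", 0)) == 1:
            props = (float(row["ea"]), float(row["ip"]))
        spec = parse_polymer_string(row["polymer_string"])
        out.append(DatasetRecord(polymer_string=row["polymer_string"],
                                 properties=props, key=combination_key(spec)))
    return out


def write_csv(records: Sequence[DatasetRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_csv(path) -> List[DatasetRecord]:
    return frame_to_records(pd.read_csv(path))


# --------------------------------------------------------------------------
# convenience fixture dataset for tests and smoke training

def fixture_dataset(n_a: int = 2, n_b: int = 6, labelled_fraction: float = 1.0,
                    seed: int = 0,
                    combos: Tuple[Tuple[Tuple[float, float], str], ...] = DEFAULT_COMBOS,
                    ) -> List[DatasetRecord]:
    """Small enumerated A-B space with pseudo-labels on a random subset."""
    monos = fixture_monomers(n_a + n_b, seed=seed)
    space = DesignSpace(a_monomers=monos[:n_a], b_monomers=monos[n_a:], combos=combos)
    records = enumerate_space(space, labelled=True, seed=seed)
    if labelled_fraction < 1.0:
        rng = np.random.default_rng(seed + 1)
        drop = rng.random(len(records)) >= labelled_fraction
        for r, d in zip(records, drop):
            if d:
                r.properties = None
    return records
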