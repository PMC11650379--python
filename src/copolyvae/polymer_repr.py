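"""Copolymer-ensemble representations: weighted stochastic graph and
numeric-token string.

A copolymer ensemble is described by its monomer SMILES (attachment points as
``[*:k]`` wildcards), stoichiometric fractions and a table of inter-monomer
connection probabilities that encodes the chain architecture (alternating,
random, block).  Two machine-readable views are provided:

* a one-line **polymer string**::

      SMILES('.'SMILES)* '|' frac ('|' frac)* '|' ('<'a'-'b':'p_ab':'p_ba)+

  where ``a``, ``b`` are global attachment-point labels (numbered
  consecutively over the monomers in order) and each ``<`` entry gives the
  probability that point ``a`` bonds to point ``b`` and vice versa;

* a **polymer graph** whose nodes are atoms carrying the stoichiometric
  fraction of their monomer as node weight, with intra-monomer bond edges of
  weight 1.0 and stochastic inter-monomer edges weighted by connection
  probability.

The string is tokenized with a SMILES tokenizer for chemistry and a
digit-place tokenizer for numbers, so that e.g. ``0.125`` becomes five
numeric tokens (``0`` at place 0, the decimal point, ``1``/``2``/``5`` at
places −1/−2/−3) that never collide with SMILES ring-closure digits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

FRACTION_TOL = 1e-6
NUMERIC_DECIMALS = 4  # serialization precision for fractions/probabilities

ARCHITECTURES = ("alternating", "block", "random")


# --------------------------------------------------------------------------
# errors
class PolymerError(ValueError):
    """Base class for representation errors."""


class GrammarError(PolymerError):
    """Malformed polymer-string grammar; message names the offending field."""


class NormalizationError(PolymerError):
    """Fractions or connection probabilities do not normalize."""


class ChemistryError(PolymerError):
    """A monomer SMILES does not parse as a chemical structure."""


class StructuralError(PolymerError):
    """Connectivity references a missing attachment point."""


class TokenizationError(PolymerError):
    """Character or token outside the vocabulary."""


# --------------------------------------------------------------------------
# domain types

_WILDCARD_RE = re.compile(r"\[\*:(\d+)\]")

from functools import lru_cache  # noqa: E402


@lru_cache(maxsize=100_000)
def _canonical_smiles_cached(smiles: str) -> str:
    return Chem.MolToSmiles(Chem.MolFromSmiles(smiles))


@dataclass(frozen=True)
class Monomer:
    """A monomer SMILES with ``[*:k]`` attachment wildcards."""

    smiles: str
    attachment_points: Tuple[int, ...] = ()

    def __post_init__(self):
        pts = tuple(int(k) for k in _WILDCARD_RE.findall(self.smiles))
        if not pts:
            raise ChemistryError(f"monomer {self.smiles!r} has no attachment point")
        if len(set(pts)) != len(pts):
            raise ChemistryError(f"monomer {self.smiles!r} has duplicate attachment indices")
        object.__setattr__(self, "attachment_points", tuple(sorted(pts)))
        if self.mol() is None:
            raise ChemistryError(f"monomer SMILES {self.smiles!r} does not parse")

    def mol(self):
        return Chem.MolFromSmiles(self.smiles)

    def canonical_smiles(self) -> str:
        return _canonical_smiles_cached(self.smiles)

    @property
    def n_points(self) -> int:
        return len(self.attachment_points)


@dataclass(frozen=True)
class PolymerEnsembleSpec:
    """Monomers + stoichiometric fractions + connection-probability table.

    ``connectivity`` maps ordered pairs of (monomer index, local wildcard
    label) to a probability in [0, 1]; for every attachment point that has
    outgoing entries the probabilities sum to 1.
    """

    monomers: Tuple[Monomer, ...]
    fractions: Tuple[float, ...]
    connectivity: Dict[Tuple[Tuple[int, int], Tuple[int, int]], float] = field(default_factory=dict)
    architecture_label: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "monomers", tuple(self.monomers))
        object.__setattr__(self, "fractions", tuple(float(f) for f in self.fractions))
        if len(self.monomers) < 1:
            raise GrammarError("spec needs at least one monomer")
        if len(self.fractions) != len(self.monomers):
            raise GrammarError("fractions: one fraction per monomer required")
        if any(not (0.0 < f <= 1.0) for f in self.fractions):
            raise NormalizationError("fractions: each must lie in (0, 1]")
        if abs(sum(self.fractions) - 1.0) > FRACTION_TOL:
            raise NormalizationError(
                f"fractions: sum {sum(self.fractions):.6f} != 1 within {FRACTION_TOL}")
        if self.architecture_label is not None and self.architecture_label not in ARCHITECTURES:
            raise GrammarError(f"architecture: unknown label {self.architecture_label!r}")
        valid_pts = {(i, k) for i, m in enumerate(self.monomers) for k in m.attachment_points}
        outgoing: Dict[Tuple[int, int], float] = {}
        for (a, b), p in self.connectivity.items():
            for pt in (a, b):
                if pt not in valid_pts:
                    raise StructuralError(f"connectivity: attachment point {pt} does not exist")
            if not (0.0 <= p <= 1.0):
                raise NormalizationError(f"connectivity: probability {p} outside [0, 1]")
            if p > 0.0:
                outgoing[a] = outgoing.get(a, 0.0) + p
        for pt, s in outgoing.items():
            if abs(s - 1.0) > FRACTION_TOL:
                raise NormalizationError(
                    f"connectivity: outgoing probabilities of point {pt} sum to {s:.6f}")

    # -- helpers -----------------------------------------------------------
    def global_labels(self) -> Dict[Tuple[int, int], int]:
        """Consecutive global attachment labels in monomer order."""
        labels, nxt = {}, 1
        for i, m in enumerate(self.monomers):
            for k in m.attachment_points:
                labels[(i, k)] = nxt
                nxt += 1
        return labels

    def canonicalize(self) -> "PolymerEnsembleSpec":
        """Canonical monomer SMILES, monomers sorted lexicographically."""
        canon = [m.canonical_smiles() for m in self.monomers]
        order = sorted(range(len(canon)), key=lambda i: canon[i])
        perm = {old: new for new, old in enumerate(order)}
        conn = {((perm[a[0]], a[1]), (perm[b[0]], b[1])): p
                for (a, b), p in self.connectivity.items()}
        return PolymerEnsembleSpec(
            monomers=tuple(Monomer(canon[i]) for i in order),
            fractions=tuple(self.fractions[i] for i in order),
            connectivity=conn,
            architecture_label=self.architecture_label,
        )

    def __eq__(self, other):
        if not isinstance(other, PolymerEnsembleSpec):
            return NotImplemented
        if tuple(m.smiles for m in self.monomers) != tuple(m.smiles for m in other.monomers):
            return False
        if any(abs(a - b) > FRACTION_TOL for a, b in zip(self.fractions, other.fractions)):
            return False
        keys = set(self.connectivity) | set(other.connectivity)
        return all(abs(self.connectivity.get(k, 0.0) - other.connectivity.get(k, 0.0))
                   <= FRACTION_TOL for k in keys)

    def __hash__(self):
        return hash(serialize(self))


@dataclass
class PolymerGraph:
    """Atom graph with stochastic edge weights and stoichiometric node weights."""

    node_features: "np.ndarray"          # (N, F_v)
    node_weights: "np.ndarray"           # (N,)
    monomer_of_node: "np.ndarray"        # (N,) int
    edge_src: "np.ndarray"               # (E,) int, directed
    edge_dst: "np.ndarray"               # (E,) int
    edge_features: "np.ndarray"          # (E, F_e)
    edge_weights: "np.ndarray"           # (E,)

    @property
    def n_nodes(self) -> int:
        return len(self.node_weights)

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)


# --------------------------------------------------------------------------
# numeric rendering / parsing

def format_number(x: float, decimals: int = NUMERIC_DECIMALS) -> str:
    """Fixed-precision decimal with trailing zeros trimmed, min one decimal."""
    s = f"{x:.{decimals}f}"
    s = s.rstrip("0")
    if s.endswith("."):
        s += "0"
    return s


def _parse_number(text: str, what: str) -> float:
    if not re.fullmatch(r"\d+(\.\d+)?", text):
        raise GrammarError(f"{what}: malformed number {text!r}")
    return float(text)


# --------------------------------------------------------------------------
# parse / serialize

_CONN_ENTRY_RE = re.compile(r"<(\d+)-(\d+):([\d.]+):([\d.]+)")


def parse_polymer_string(text: str) -> PolymerEnsembleSpec:
    """Parse the one-line polymer string into a validated ensemble spec."""
    if not text or not text.strip():
        raise GrammarError("polymer string: empty input")
    fields = text.strip().split("|")
    if len(fields) < 3:
        raise GrammarError("polymer string: expected monomers|fractions...|connectivity")
    smiles_field, conn_field = fields[0], fields[-1]
    frac_fields = fields[1:-1]
    if not conn_field.startswith("<"):
        raise GrammarError("connectivity: field must start with '<'")

    monomers = tuple(Monomer(s) for s in smiles_field.split("."))
    fractions = tuple(_parse_number(f, "fraction") for f in frac_fields)
    if len(fractions) != len(monomers):
        raise GrammarError(
            f"fractions: {len(fractions)} fractions for {len(monomers)} monomers")

    # build the global-label -> (monomer, local) map in input order
    labels: Dict[int, Tuple[int, int]] = {}
    nxt = 1
    for i, m in enumerate(monomers):
        for k in m.attachment_points:
            labels[nxt] = (i, k)
            nxt += 1

    connectivity: Dict[Tuple[Tuple[int, int], Tuple[int, int]], float] = {}
    consumed = 0
    for mt in _CONN_ENTRY_RE.finditer(conn_field):
        if mt.start() != consumed:
            raise GrammarError(f"connectivity: unparseable text at {conn_field[consumed:mt.start()]!r}")
        consumed = mt.end()
        a, b = int(mt.group(1)), int(mt.group(2))
        p_ab = _parse_number(mt.group(3), "connectivity probability")
        p_ba = _parse_number(mt.group(4), "connectivity probability")
        for lbl in (a, b):
            if lbl not in labels:
                raise StructuralError(f"connectivity: attachment label {lbl} does not exist")
        if p_ab > 0.0:
            connectivity[(labels[a], labels[b])] = p_ab
        if p_ba > 0.0:
            connectivity[(labels[b], labels[a])] = p_ba
    if consumed != len(conn_field) or not connectivity and consumed == 0:
        raise GrammarError(f"connectivity: unparseable tail {conn_field[consumed:]!r}")
    return PolymerEnsembleSpec(monomers=monomers, fractions=fractions,
                               connectivity=connectivity)


def serialize(spec: PolymerEnsembleSpec, canonical: bool = False) -> str:
    """Deterministic writer; exact inverse of :func:`parse_polymer_string`.

    With ``canonical=True`` the monomer SMILES are RDKit-canonicalized and the
    monomers sorted lexicographically (the canonical ordering rule used for
    novelty and reconstruction-equality comparisons); by default monomer text
    and order are preserved so that parse/serialize round-trips bit-exactly.
    """
    if canonical:
        spec = spec.canonicalize()
    labels = spec.global_labels()
    smiles_field = ".".join(m.smiles for m in spec.monomers)
    frac_fields = [format_number(f) for f in spec.fractions]
    # group reciprocal directed entries into symmetric '<a-b:p_ab:p_ba' entries
    pairs: Dict[Tuple[int, int], List[float]] = {}
    for (a, b), p in spec.connectivity.items():
        la, lb = labels[a], labels[b]
        key = (min(la, lb), max(la, lb))
        ent = pairs.setdefault(key, [0.0, 0.0])
        ent[0 if la <= lb else 1] = p
    conn_field = "".join(
        f"<{a}-{b}:{format_number(pab)}:{format_number(pba)}"
        for (a, b), (pab, pba) in sorted(pairs.items()))
    return "|".join([smiles_field, *frac_fields, conn_field])


def canonical_string(text_or_spec) -> str:
    """Canonical form of a polymer string (or spec) for equality comparisons."""
    spec = (text_or_spec if isinstance(text_or_spec, PolymerEnsembleSpec)
            else parse_polymer_string(text_or_spec))
    return serialize(spec, canonical=True)


def combination_key(spec: PolymerEnsembleSpec) -> str:
    """Key identifying the unordered monomer combination (ignores
    stoichiometry and architecture); used for leakage-free data splits."""
    return "+".join(sorted(m.canonical_smiles() for m in spec.monomers))


# --------------------------------------------------------------------------
# graph construction

import numpy as np  # noqa: E402  (placed after rdkit to keep import order tidy)

DEFAULT_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "Si", "P", "B", "I")
_BOND_ORDERS = (Chem.BondType.SINGLE, Chem.BondType.DOUBLE,
                Chem.BondType.TRIPLE, Chem.BondType.AROMATIC)
MAX_DEGREE = 4

NODE_FEATURE_DIM = len(DEFAULT_ELEMENTS) + 1 + 1 + 1 + (MAX_DEGREE + 1)
EDGE_FEATURE_DIM = len(_BOND_ORDERS) + 1


def _atom_features(atom) -> np.ndarray:
    f = np.zeros(NODE_FEATURE_DIM)
    sym = atom.GetSymbol()
    if sym in DEFAULT_ELEMENTS:
        f[DEFAULT_ELEMENTS.index(sym)] = 1.0
    else:
        f[len(DEFAULT_ELEMENTS) - 1] = 1.0  # fold rare elements onto last slot
    off = len(DEFAULT_ELEMENTS)
    f[off] = 1.0 if atom.GetIsAromatic() else 0.0
    f[off + 1] = float(atom.GetFormalCharge())
    f[off + 2] = float(atom.GetTotalNumHs())
    deg = min(atom.GetDegree(), MAX_DEGREE)
    f[off + 3 + deg] = 1.0
    return f


def _bond_features(bond) -> np.ndarray:
    f = np.zeros(EDGE_FEATURE_DIM)
    bt = bond.GetBondType()
    if bt in _BOND_ORDERS:
        f[_BOND_ORDERS.index(bt)] = 1.0
    f[-1] = 1.0 if bond.IsInRing() else 0.0
    return f


_STOCHASTIC_BOND = np.zeros(EDGE_FEATURE_DIM)
_STOCHASTIC_BOND[0] = 1.0  # stochastic inter-monomer linkage treated as single bond


def build_graph(spec: PolymerEnsembleSpec) -> PolymerGraph:
    """Assemble the weighted stochastic polymer graph.

    Wildcard atoms are deleted; the atoms that carried them become the
    endpoints of directed stochastic edges weighted by connection probability.
    """
    node_feats: List[np.ndarray] = []
    node_w: List[float] = []
    node_mono: List[int] = []
    esrc: List[int] = []
    edst: List[int] = []
    efeat: List[np.ndarray] = []
    ew: List[float] = []

    # (monomer idx, local wildcard label) -> global atom index of the bearer
    bearer: Dict[Tuple[int, int], int] = {}

    offset = 0
    for mi, (mono, frac) in enumerate(zip(spec.monomers, spec.fractions)):
        mol = mono.mol()
        keep: Dict[int, int] = {}
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() == 0:
                continue
            keep[atom.GetIdx()] = offset + len(keep)
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() == 0:
                continue
            node_feats.append(_atom_features(atom))
            node_w.append(frac)
            node_mono.append(mi)
        for bond in mol.GetBonds():
            a, b = bond.GetBeginAtom(), bond.GetEndAtom()
            if a.GetAtomicNum() == 0 or b.GetAtomicNum() == 0:
                wc, real = (a, b) if a.GetAtomicNum() == 0 else (b, a)
                bearer[(mi, wc.GetAtomMapNum())] = keep[real.GetIdx()]
                continue
            ia, ib = keep[a.GetIdx()], keep[b.GetIdx()]
            bf = _bond_features(bond)
            for s, d in ((ia, ib), (ib, ia)):
                esrc.append(s)
                edst.append(d)
                efeat.append(bf)
                ew.append(1.0)
        offset += len(keep)

    for (a, b), p in spec.connectivity.items():
        if a not in bearer or b not in bearer:
            raise StructuralError(f"connectivity: attachment point {a if a not in bearer else b} "
                                  "has no bearer atom")
        esrc.append(bearer[a])
        edst.append(bearer[b])
        efeat.append(_STOCHASTIC_BOND)
        ew.append(p)

    return PolymerGraph(
        node_features=np.array(node_feats),
        node_weights=np.array(node_w),
        monomer_of_node=np.array(node_mono, dtype=int),
        edge_src=np.array(esrc, dtype=int),
        edge_dst=np.array(edst, dtype=int),
        edge_features=np.array(efeat),
        edge_weights=np.array(ew),
    )


# --------------------------------------------------------------------------
# architecture -> connectivity defaults

def connectivity_from_architecture(monomers: Sequence[Monomer],
                                   fractions: Sequence[float],
                                   architecture: str,
                                   block_epsilon: float = 0.05,
                                   ) -> Dict[Tuple[Tuple[int, int], Tuple[int, int]], float]:
    """Default connection-probability tables for the three chain architectures.

    Monomers must have exactly two attachment points (head = lower label,
    tail = higher label).  A tail bonds to the head of the next monomer:
    alternating forces cross-monomer continuation, random follows the
    stoichiometric fractions, block keeps self-continuation at 1 − ε.
    """
    if architecture not in ARCHITECTURES:
        raise GrammarError(f"architecture: unknown label {architecture!r}")
    for m in monomers:
        if m.n_points != 2:
            raise StructuralError(
                f"architecture table requires 2 attachment points, got {m.n_points}")
    n = len(monomers)
    heads = [(i, monomers[i].attachment_points[0]) for i in range(n)]
    tails = [(i, monomers[i].attachment_points[1]) for i in range(n)]

    if n == 1:
        return {(tails[0], heads[0]): 1.0, (heads[0], tails[0]): 1.0}

    def probs(i: int) -> Dict[int, float]:
        if architecture == "alternating":
            if n != 2:
                raise StructuralError("alternating architecture defined for 2 monomers")
            return {1 - i: 1.0}
        if architecture == "random":
            return {j: fractions[j] for j in range(n)}
        # block
        out = {j: block_epsilon / (n - 1) for j in range(n) if j != i}
        out[i] = 1.0 - block_epsilon
        return out

    conn: Dict[Tuple[Tuple[int, int], Tuple[int, int]], float] = {}
    for i in range(n):
        for j, p in probs(i).items():
            if p > 0.0:
                conn[(tails[i], heads[j])] = p
                conn[(heads[i], tails[j])] = p
    return conn


def make_spec(monomers: Sequence[Monomer], fractions: Sequence[float],
              architecture: str, block_epsilon: float = 0.05) -> PolymerEnsembleSpec:
    """Build a validated spec from monomers + stoichiometry + architecture."""
    conn = connectivity_from_architecture(monomers, fractions, architecture,
                                          block_epsilon=block_epsilon)
    return PolymerEnsembleSpec(monomers=tuple(monomers), fractions=tuple(fractions),
                               connectivity=conn, architecture_label=architecture)


# --------------------------------------------------------------------------
# validation

@dataclass(frozen=True)
class Verdict:
    valid: bool
    diagnostic: str = ""

    def __bool__(self):
        return self.valid


def validate(text: str) -> Verdict:
    """Grammar + chemistry + normalization check of a polymer string."""
    try:
        spec = parse_polymer_string(text)
    except ChemistryError as e:
        return Verdict(False, f"chemistry: {e}")
    except NormalizationError as e:
        return Verdict(False, f"normalization: {e}")
    except (GrammarError, StructuralError) as e:
        return Verdict(False, f"grammar: {e}")
    for m in spec.monomers:
        if Chem.MolFromSmiles(m.smiles) is None:
            return Verdict(False, f"chemistry: monomer {m.smiles!r} does not parse")
    return Verdict(True)


# --------------------------------------------------------------------------
# tokenization

_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|Se|se|@@|%\d{2}|[BCNOSPFIbcnosp]|[=#\-+\\/:~@\.\(\)]|\d)")

BOS, EOS, PAD = "[BOS]", "[EOS]", "[PAD]"
SEP_MONOMER, SEP_FIELD = ".", "|"
SPECIAL_TOKENS = (PAD, BOS, EOS)
DELIMS = (SEP_FIELD, "<", "-", ":")
NUM_PLACES = range(-NUMERIC_DECIMALS, 4)  # decimal places covered by numeric tokens
DECIMAL_POINT = "[.num]"


def _num_token(digit: str, place: int) -> str:
    return f"[{digit}@{place}]"


def tokenize_number(text: str) -> List[str]:
    """Digit-place tokens for a decimal number, one token per character."""
    if "." in text:
        ip, fp = text.split(".", 1)
    else:
        ip, fp = text, ""
    toks = [_num_token(d, len(ip) - 1 - i) for i, d in enumerate(ip)]
    if "." in text:
        toks.append(DECIMAL_POINT)
        toks += [_num_token(d, -(i + 1)) for i, d in enumerate(fp)]
    return toks


def tokenize_smiles(text: str) -> List[str]:
    toks, pos = [], 0
    for m in _SMILES_TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise TokenizationError(
                f"character {text[pos:m.start()]!r} outside SMILES vocabulary")
        toks.append(m.group(0))
        pos = m.end()
    if pos != len(text):
        raise TokenizationError(f"character {text[pos:]!r} outside SMILES vocabulary")
    return toks


def tokenize_string(text: str) -> List[str]:
    """Token strings (no ids) for a polymer string: SMILES fields through the
    SMILES tokenizer, numeric fields through the digit-place tokenizer."""
    fields = text.split("|")
    if len(fields) < 3:
        raise TokenizationError("polymer string must have >= 3 '|' fields")
    out: List[str] = tokenize_smiles(fields[0])
    for f in fields[1:-1]:
        out.append(SEP_FIELD)
        out += tokenize_number(f)
    out.append(SEP_FIELD)
    conn = fields[-1]
    for mt in _CONN_ENTRY_RE.finditer(conn):
        a, b, pab, pba = mt.groups()
        out.append("<")
        out += tokenize_number(a)
        out.append("-")
        out += tokenize_number(b)
        out.append(":")
        out += tokenize_number(pab)
        out.append(":")
        out += tokenize_number(pba)
    return out


def detokenize_tokens(tokens: Sequence[str]) -> str:
    """Inverse of :func:`tokenize_string` on token strings."""
    parts = []
    for t in tokens:
        if t in SPECIAL_TOKENS:
            raise TokenizationError(f"stray special token {t!r} mid-sequence")
        if t == DECIMAL_POINT:
            parts.append(".")
        elif t.startswith("[") and "@" in t:
            parts.append(t[1])
        else:
            parts.append(t)
    return "".join(parts)


class Vocabulary:
    """Bijection token-string <-> id, covering SMILES tokens, numeric
    digit-place tokens, delimiters and specials.  PAD is always id 0."""

    def __init__(self, tokens: Sequence[str]):
        base = list(SPECIAL_TOKENS)
        for t in tokens:
            if t not in base:
                base.append(t)
        self.id_to_token: List[str] = base
        self.token_to_id: Dict[str, int] = {t: i for i, t in enumerate(base)}

    def __len__(self):
        return len(self.id_to_token)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def bos_id(self) -> int:
        return self.token_to_id[BOS]

    @property
    def eos_id(self) -> int:
        return self.token_to_id[EOS]

    def numeric_ids(self) -> set:
        return {i for t, i in self.token_to_id.items()
                if t == DECIMAL_POINT or (t.startswith("[") and "@" in t)}

    def smiles_ids(self) -> set:
        special = set(SPECIAL_TOKENS) | set(DELIMS) | {"<"}
        return {i for t, i in self.token_to_id.items()
                if t not in special and i not in self.numeric_ids()}

    @classmethod
    def build(cls, strings: Sequence[str]) -> "Vocabulary":
        """Vocabulary from a corpus, plus every numeric digit-place token in
        the covered range and the delimiters (so decoding can emit any number)."""
        toks: List[str] = []
        for d in "0123456789":
            for p in NUM_PLACES:
                toks.append(_num_token(d, p))
        toks.append(DECIMAL_POINT)
        toks += list(DELIMS) + ["<"]
        seen = set(toks)
        for s in strings:
            for t in tokenize_string(s):
                if t not in seen:
                    seen.add(t)
                    toks.append(t)
        return cls(toks)

    def to_json(self) -> List[str]:
        return list(self.id_to_token)

    @classmethod
    def from_json(cls, tokens: Sequence[str]) -> "Vocabulary":
        v = cls.__new__(cls)
        v.id_to_token = list(tokens)
        v.token_to_id = {t: i for i, t in enumerate(tokens)}
        return v


@dataclass
class TokenSequence:
    """Token ids (BOS … EOS [PAD…]) plus the vocabulary they live in."""

    ids: List[int]
    vocabulary: Vocabulary

    def __len__(self):
        return len(self.ids)


def tokenize(text: str, vocab: Vocabulary) -> TokenSequence:
    toks = tokenize_string(text)
    ids = [vocab.bos_id]
    for t in toks:
        if t not in vocab.token_to_id:
            raise TokenizationError(f"token {t!r} outside vocabulary")
        ids.append(vocab.token_to_id[t])
    ids.append(vocab.eos_id)
    return TokenSequence(ids=ids, vocabulary=vocab)


def detokenize(seq: TokenSequence) -> str:
    """Strip BOS/EOS/PAD framing and reassemble the polymer string."""
    vocab = seq.vocabulary
    ids = list(seq.ids)
    if ids and ids[0] == vocab.bos_id:
        ids = ids[1:]
    body: List[int] = []
    for i in ids:
        if i == vocab.eos_id:
            break
        body.append(i)
    while body and body[-1] == vocab.pad_id:
        body.pop()
    return detokenize_tokens([vocab.id_to_token[i] for i in body])
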