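"""Graph-to-string VAE: weighted directed message-passing encoder, Gaussian
latent space, latent-conditioned autoregressive transformer decoder, and a
feed-forward property head.

The encoder is an edge-centric message passing network in which every
incoming message is scaled by the stochastic weight of its edge, and graph
pooling is a node-weight-weighted mean, so stoichiometry (node weights) and
chain architecture (edge weights) shape the embedding directly.  Two parallel
linear heads give the posterior mean and log-variance over a D-dimensional
latent space (D = 32 by default).

The decoder is a pre-norm transformer: the latent vector is injected both as
cross-attention memory and by concatenation to every token embedding after
positional encoding.  Decoding is autoregressive with greedy or beam search.

All tensors ride on the package's NumPy autodiff engine; the same forward
code serves training (with gradients) and inference (plain arrays).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .polymer_repr import (
    EDGE_FEATURE_DIM, NODE_FEATURE_DIM, PolymerEnsembleSpec, PolymerGraph,
    TokenSequence, Vocabulary, build_graph, detokenize,
)


class ConfigurationError(ValueError):
    pass


class LengthError(ValueError):
    pass


@dataclass
class ModelConfig:
    latent_dim: int = 32          # D
    mpnn_iters: int = 3           # message-passing iterations T
    encoder_hidden: int = 64
    d_model: int = 64
    n_layers: int = 4
    n_heads: int = 4
    ffn_hidden: int = 128
    n_memory: int = 4             # latent memory slots for cross-attention
    max_len: int = 256
    beam_size: int = 5
    prop_hidden: Tuple[int, ...] = (48,)
    n_props: int = 2              # M

    def __post_init__(self):
        for name in ("latent_dim", "mpnn_iters", "encoder_hidden", "d_model",
                     "n_layers", "n_heads", "ffn_hidden", "n_memory",
                     "max_len", "beam_size", "n_props"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.d_model % self.n_heads:
            raise ConfigurationError("d_model must be divisible by n_heads")


@dataclass
class EncoderOutput:
    mu: np.ndarray       # (D,) or (B, D)
    sigma2: np.ndarray   # same shape, positive


@dataclass
class LatentPoint:
    z: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("latent point has non-finite entries")


# --------------------------------------------------------------------------
# parameter initialization

def _glorot(rng, n_in, n_out):
    s = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-s, s, size=(n_in, n_out))


def init_params(cfg: ModelConfig, vocab_size: int, seed: int = 0) -> Dict[str, Tensor]:
    rng = np.random.default_rng(seed)
    p: Dict[str, np.ndarray] = {}
    H, D, d = cfg.encoder_hidden, cfg.latent_dim, cfg.d_model

    # encoder (wD-MPNN)
    p["enc.W_init"] = _glorot(rng, NODE_FEATURE_DIM + EDGE_FEATURE_DIM, H)
    p["enc.b_init"] = np.zeros(H)
    p["enc.W_msg"] = _glorot(rng, H, H)
    p["enc.W_node"] = _glorot(rng, NODE_FEATURE_DIM + H, H)
    p["enc.b_node"] = np.zeros(H)
    p["enc.W_mu"] = _glorot(rng, H, D)
    p["enc.b_mu"] = np.zeros(D)
    p["enc.W_lv"] = _glorot(rng, H, D)
    p["enc.b_lv"] = np.zeros(D) - 1.0   # start with small posterior variance

    # decoder
    p["dec.embed"] = rng.normal(0.0, 0.02, size=(vocab_size, d))
    p["dec.W_in"] = _glorot(rng, d + D, d)
    p["dec.W_mem"] = _glorot(rng, D, cfg.n_memory * d)
    for l in range(cfg.n_layers):
        for nm in ("q", "k", "v", "o"):
            p[f"dec.{l}.sa.{nm}"] = _glorot(rng, d, d)
        for nm in ("q", "k", "v", "o"):
            p[f"dec.{l}.ca.{nm}"] = _glorot(rng, d, d)
        p[f"dec.{l}.ffn.W1"] = _glorot(rng, d, cfg.ffn_hidden)
        p[f"dec.{l}.ffn.b1"] = np.zeros(cfg.ffn_hidden)
        p[f"dec.{l}.ffn.W2"] = _glorot(rng, cfg.ffn_hidden, d)
        p[f"dec.{l}.ffn.b2"] = np.zeros(d)
        for ln in ("ln1", "ln2", "ln3"):
            p[f"dec.{l}.{ln}.g"] = np.ones(d)
            p[f"dec.{l}.{ln}.b"] = np.zeros(d)
    p["dec.lnf.g"] = np.ones(d)
    p["dec.lnf.b"] = np.zeros(d)
    p["dec.W_out"] = _glorot(rng, d, vocab_size)
    p["dec.b_out"] = np.zeros(vocab_size)

    # property head
    sizes = (D,) + tuple(cfg.prop_hidden) + (cfg.n_props,)
    for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
        p[f"prop.W{i}"] = _glorot(rng, a, b)
        p[f"prop.b{i}"] = np.zeros(b)

    return {k: Tensor(v, requires_grad=True, name=k) for k, v in p.items()}


# --------------------------------------------------------------------------
# graph batching

@dataclass
class PackedGraphs:
    """Several polymer graphs packed as one disjoint graph plus the constant
    scatter matrices the encoder needs."""

    node_features: np.ndarray     # (N, Fv)
    edge_features: np.ndarray     # (E, Fe)
    src_of_edge: np.ndarray       # (E,) int
    inc: np.ndarray               # (N, E) weighted incidence: inc[v, e] = w_e if dst(e)=v
    rev_index: np.ndarray         # (E,) int, -1 if no reverse directed edge
    rev_weight: np.ndarray        # (E,)
    pool: np.ndarray              # (G, N) node-weight-normalized pooling matrix
    n_graphs: int


def pack_graphs(graphs: Sequence[PolymerGraph],
                dtype=np.float64) -> PackedGraphs:
    nf, ef, src, dst, ew = [], [], [], [], []
    gid = []
    nw = []
    off = 0
    for g_i, g in enumerate(graphs):
        nf.append(g.node_features)
        ef.append(g.edge_features)
        src.append(g.edge_src + off)
        dst.append(g.edge_dst + off)
        ew.append(g.edge_weights)
        gid += [g_i] * g.n_nodes
        nw.append(g.node_weights)
        off += g.n_nodes
    nf = np.concatenate(nf)
    ef = np.concatenate(ef)
    src = np.concatenate(src)
    dst = np.concatenate(dst)
    ew = np.concatenate(ew)
    nw = np.concatenate(nw)
    gid = np.asarray(gid)
    N, E, G = len(nf), len(src), len(graphs)

    inc = np.zeros((N, E))
    inc[dst, np.arange(E)] = ew

    pair_to_e = {}
    for e in range(E):
        pair_to_e.setdefault((src[e], dst[e]), e)
    rev = np.full(E, -1, dtype=int)
    rvw = np.zeros(E)
    for e in range(E):
        r = pair_to_e.get((dst[e], src[e]), -1)
        rev[e] = r
        if r >= 0:
            rvw[e] = ew[r]

    pool = np.zeros((G, N))
    pool[gid, np.arange(N)] = nw
    pool /= pool.sum(axis=1, keepdims=True)

    return PackedGraphs(node_features=nf.astype(dtype), edge_features=ef.astype(dtype),
                        src_of_edge=src, inc=inc.astype(dtype), rev_index=rev,
                        rev_weight=rvw.astype(dtype), pool=pool.astype(dtype),
                        n_graphs=G)


# --------------------------------------------------------------------------
# forward passes (autodiff-agnostic: params may be Tensors or ndarrays)

def _linear(x, W, b=None):
    y = ad.matmul(x, W)
    return y if b is None else y + b


def encoder_forward(p, packed: PackedGraphs, cfg: ModelConfig):
    """wD-MPNN forward; returns (mu, sigma2, graph_embedding)."""
    xe = np.concatenate([packed.node_features[packed.src_of_edge],
                         packed.edge_features], axis=1)
    h0 = ad.relu(_linear(xe, p["enc.W_init"], p["enc.b_init"]))   # (E, H)
    h = h0
    has_rev = packed.rev_index >= 0
    rev = np.where(has_rev, packed.rev_index, 0)
    rw = (packed.rev_weight * has_rev)[:, None]
    for _ in range(cfg.mpnn_iters - 1):
        node_in = ad.matmul(packed.inc, h)                        # (N, H) Σ w_e h_e into v
        msg = ad.take(node_in, packed.src_of_edge) - ad.take(h, rev) * rw
        h = ad.relu(h0 + ad.matmul(msg, p["enc.W_msg"]))
    node_in = ad.matmul(packed.inc, h)
    node_x = ad.concatenate([packed.node_features, node_in], axis=1)
    hv = ad.relu(_linear(node_x, p["enc.W_node"], p["enc.b_node"]))
    g = ad.matmul(packed.pool, hv)                                # (G, H)
    mu = _linear(g, p["enc.W_mu"], p["enc.b_mu"])
    logvar = _linear(g, p["enc.W_lv"], p["enc.b_lv"])
    return mu, logvar, g


def _layer_norm(x, g, b, eps: float = 1e-5):
    m = ad.tmean(x, axis=-1, keepdims=True)
    xc = x - m
    v = ad.tmean(xc * xc, axis=-1, keepdims=True)
    return xc / ad.sqrt(v + eps) * g + b


def _split_heads(x, n_heads):
    # (B, L, d) -> (B, H, L, dh)
    B, L, d = x.shape
    return ad.transpose(ad.reshape(x, (B, L, n_heads, d // n_heads)), (0, 2, 1, 3))


def _merge_heads(x):
    B, H, L, dh = x.shape
    return ad.reshape(ad.transpose(x, (0, 2, 1, 3)), (B, L, H * dh))


def _attention(q, k, v, bias=None):
    dh = q.shape[-1]
    return ad.attention(q, k, v, bias=bias, scale=1.0 / np.sqrt(dh))


def _positional_encoding(L: int, d: int) -> np.ndarray:
    pos = np.arange(L)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe.astype(ad.DTYPE)


def decoder_forward(p, z, tokens: np.ndarray, cfg: ModelConfig,
                    pad_id: int, concat_latent: bool = True):
    """Teacher-forced decoder logits.

    tokens: (B, L) int input ids (BOS-first prefix); returns (B, L, V) logits,
    position t conditioned on z and tokens[:, :t+1] only (causal mask).
    """
    B, L = tokens.shape
    if L > cfg.max_len:
        raise LengthError(f"sequence length {L} exceeds max_len {cfg.max_len}")
    d = cfg.d_model
    emb = ad.take(p["dec.embed"], tokens)                       # (B, L, d)
    emb = emb + _positional_encoding(L, d)[None]
    zt = z if isinstance(z, Tensor) else np.asarray(z, dtype=np.float64)
    z3 = ad.reshape(zt, (B, 1, cfg.latent_dim))
    z3 = ad.broadcast_to(z3, (B, L, cfg.latent_dim))
    if not concat_latent:
        z3 = z3 * 0.0
    u = _linear(ad.concatenate([emb, z3], axis=2), p["dec.W_in"])

    mem = ad.reshape(ad.matmul(zt, p["dec.W_mem"]), (B, cfg.n_memory, d))
    mem_h = _split_heads(mem, cfg.n_heads)

    causal = np.triu(np.full((L, L), -1e9, dtype=ad.DTYPE), k=1)[None, None]
    key_pad = np.where(tokens == pad_id, ad.DTYPE(-1e9), ad.DTYPE(0.0))[:, None, None, :]
    bias = causal + key_pad                                     # (B,1,L,L)

    h = u
    for l in range(cfg.n_layers):
        x = _layer_norm(h, p[f"dec.{l}.ln1.g"], p[f"dec.{l}.ln1.b"])
        q = _split_heads(_linear(x, p[f"dec.{l}.sa.q"]), cfg.n_heads)
        k = _split_heads(_linear(x, p[f"dec.{l}.sa.k"]), cfg.n_heads)
        v = _split_heads(_linear(x, p[f"dec.{l}.sa.v"]), cfg.n_heads)
        h = h + _linear(_merge_heads(_attention(q, k, v, bias)), p[f"dec.{l}.sa.o"])

        x = _layer_norm(h, p[f"dec.{l}.ln2.g"], p[f"dec.{l}.ln2.b"])
        q = _split_heads(_linear(x, p[f"dec.{l}.ca.q"]), cfg.n_heads)
        km = _split_heads(_linear(mem, p[f"dec.{l}.ca.k"]), cfg.n_heads)
        vm = _split_heads(_linear(mem, p[f"dec.{l}.ca.v"]), cfg.n_heads)
        h = h + _linear(_merge_heads(_attention(q, km, vm)), p[f"dec.{l}.ca.o"])

        x = _layer_norm(h, p[f"dec.{l}.ln3.g"], p[f"dec.{l}.ln3.b"])
        f = ad.relu(_linear(x, p[f"dec.{l}.ffn.W1"], p[f"dec.{l}.ffn.b1"]))
        h = h + _linear(f, p[f"dec.{l}.ffn.W2"], p[f"dec.{l}.ffn.b2"])

    h = _layer_norm(h, p["dec.lnf.g"], p["dec.lnf.b"])
    return _linear(h, p["dec.W_out"], p["dec.b_out"])


def property_forward(p, z, cfg: ModelConfig):
    h = z
    n_layers = len(cfg.prop_hidden) + 1
    for i in range(n_layers):
        h = _linear(h, p[f"prop.W{i}"], p[f"prop.b{i}"])
        if i < n_layers - 1:
            h = ad.relu(h)
    return h


# --------------------------------------------------------------------------
# the model object

class CopolymerVAE:
    """Bundles config, vocabulary, parameters and property scaling."""

    def __init__(self, cfg: ModelConfig, vocab: Vocabulary, seed: int = 0):
        self.cfg = cfg
        self.vocab = vocab
        self.params = init_params(cfg, len(vocab), seed=seed)
        self.prop_mean = np.zeros(cfg.n_props)
        self.prop_std = np.ones(cfg.n_props)
        self.seed = seed

    # -- numpy views of parameters ----------------------------------------
    def np_params(self) -> Dict[str, np.ndarray]:
        return {k: v.data for k, v in self.params.items()}

    # -- encoding ----------------------------------------------------------
    def encode_graphs(self, graphs: Sequence[PolymerGraph],
                      params=None) -> EncoderOutput:
        # inference encoding runs in float64 for tight isomorphism invariance
        packed = pack_graphs(graphs, dtype=np.float64)
        if params is None:
            params = {k: v.data.astype(np.float64)
                      for k, v in self.params.items() if k.startswith("enc.")}
        mu, logvar, _ = encoder_forward(params, packed, self.cfg)
        mu = mu.data if isinstance(mu, Tensor) else mu
        logvar = logvar.data if isinstance(logvar, Tensor) else logvar
        return EncoderOutput(mu=mu, sigma2=np.exp(logvar))

    def encode(self, item: Union[PolymerGraph, PolymerEnsembleSpec]) -> EncoderOutput:
        g = build_graph(item) if isinstance(item, PolymerEnsembleSpec) else item
        out = self.encode_graphs([g])
        return EncoderOutput(mu=out.mu[0], sigma2=out.sigma2[0])

    @staticmethod
    def reparameterize(out: EncoderOutput, seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None) -> LatentPoint:
        if rng is None:
            rng = np.random.default_rng(seed)
        eps = rng.standard_normal(np.shape(out.mu))
        return LatentPoint(z=np.asarray(out.mu) + np.sqrt(np.asarray(out.sigma2)) * eps)

    # -- decoding ----------------------------------------------------------
    def teacher_forced_logits(self, z: LatentPoint, target: TokenSequence,
                              concat_latent: bool = True) -> np.ndarray:
        """Per-position next-token logits for a single sequence: logits[t]
        is the distribution over target position t+1 given z, target[:t+1]."""
        ids = np.asarray(target.ids)[None, :-1]
        zb = np.asarray(z.z)[None]
        logits = decoder_forward(self.np_params(), zb, ids, self.cfg,
                                 self.vocab.pad_id, concat_latent=concat_latent)
        return logits[0]

    def _step_logits(self, p, zb: np.ndarray, prefix: np.ndarray) -> np.ndarray:
        logits = decoder_forward(p, zb, prefix, self.cfg, self.vocab.pad_id)
        return logits[:, -1, :]

    def decode_batch(self, zs: np.ndarray, mode: str = "greedy",
                     beam_size: Optional[int] = None,
                     max_len: Optional[int] = None) -> List[str]:
        if mode == "beam":
            bs = beam_size if beam_size is not None else self.cfg.beam_size
            return [self._beam_decode(z, bs, max_len) for z in zs]
        return self._greedy_decode(zs, max_len)

    def decode(self, z: LatentPoint, mode: str = "greedy",
               beam_size: Optional[int] = None,
               max_len: Optional[int] = None) -> str:
        return self.decode_batch(np.asarray(z.z)[None], mode=mode,
                                 beam_size=beam_size, max_len=max_len)[0]

    def _greedy_decode(self, zs: np.ndarray, max_len: Optional[int]) -> List[str]:
        p = self.np_params()
        L = max_len or self.cfg.max_len
        B = len(zs)
        prefix = np.full((B, 1), self.vocab.bos_id, dtype=int)
        done = np.zeros(B, dtype=bool)
        for _ in range(L - 1):
            logits = self._step_logits(p, zs, prefix)
            nxt = logits.argmax(axis=-1)
            nxt = np.where(done, self.vocab.pad_id, nxt)
            prefix = np.concatenate([prefix, nxt[:, None]], axis=1)
            done |= nxt == self.vocab.eos_id
            if done.all():
                break
        return [self._ids_to_string(row) for row in prefix]

    def _beam_decode(self, z: np.ndarray, beam_size: int,
                     max_len: Optional[int], length_norm: float = 1.0) -> str:
        """Beam search; final ranking by length-normalized log-probability."""
        p = self.np_params()
        L = max_len or self.cfg.max_len
        beams = [([self.vocab.bos_id], 0.0)]
        finished: List[Tuple[List[int], float]] = []
        for _ in range(L - 1):
            prefix = np.array([b[0] for b in beams])
            zb = np.repeat(z[None], len(beams), axis=0)
            raw = self._step_logits(p, zb, prefix)
            logp = raw - np.logaddexp.reduce(raw, axis=-1, keepdims=True)
            cand = []
            for (ids, score), row in zip(beams, logp):
                top = np.argsort(row)[::-1][:beam_size]
                for t in top:
                    cand.append((ids + [int(t)], score + row[t]))
            cand.sort(key=lambda c: c[1], reverse=True)
            beams = []
            for ids, score in cand:
                if ids[-1] == self.vocab.eos_id:
                    finished.append((ids, score))
                else:
                    beams.append((ids, score))
                if len(beams) == beam_size:
                    break
            if not beams or len(finished) >= beam_size:
                break
        pool = finished if finished else beams
        best = max(pool, key=lambda c: c[1] / max(len(c[0]) - 1, 1) ** length_norm)
        return self._ids_to_string(np.array(best[0]))

    def _ids_to_string(self, ids: np.ndarray) -> str:
        # an untrained decoder may emit BOS/PAD mid-sequence; drop stray
        # specials after the leading BOS so decode always yields a string
        # (garbage output is caught by downstream validation, not here)
        ids = [int(i) for i in ids]
        specials = {self.vocab.bos_id, self.vocab.pad_id}
        body = ids[:1] + [i for i in ids[1:] if i not in specials]
        seq = TokenSequence(ids=body, vocabulary=self.vocab)
        return detokenize(seq)

    # -- properties --------------------------------------------------------
    def predict_properties(self, z: LatentPoint) -> Tuple[float, float]:
        """(EA_hat, IP_hat) in eV (de-standardized)."""
        out = property_forward(self.np_params(), np.asarray(z.z)[None], self.cfg)[0]
        out = out * self.prop_std + self.prop_mean
        return tuple(float(v) for v in out)

    def predict_properties_batch(self, zs: np.ndarray) -> np.ndarray:
        out = property_forward(self.np_params(), zs, self.cfg)
        return out * self.prop_std + self.prop_mean

    # -- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        np.savez(path if str(path).endswith(".npz") else str(path) + ".npz",
                 **self.np_params(),
                 __prop_mean=self.prop_mean, __prop_std=self.prop_std)
        meta = {"config": asdict(self.cfg), "vocab": self.vocab.to_json(),
                "seed": self.seed}
        with open(str(path).removesuffix(".npz") + ".json", "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, path: str) -> "CopolymerVAE":
        base = str(path).removesuffix(".npz")
        with open(base + ".json") as fh:
            meta = json.load(fh)
        cfg_d = meta["config"]
        cfg_d["prop_hidden"] = tuple(cfg_d["prop_hidden"])
        cfg = ModelConfig(**cfg_d)
        model = cls(cfg, Vocabulary.from_json(meta["vocab"]), seed=meta.get("seed", 0))
        data = np.load(base + ".npz")
        for k in model.params:
            model.params[k] = Tensor(data[k], requires_grad=True, name=k)
        model.prop_mean = data["__prop_mean"]
        model.prop_std = data["__prop_std"]
        return model
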