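"""Latent-space diagnostics: 2-D neighborhood grids around a seed polymer,
noise perturbation sampling, linear interpolation between candidates, and
principal-component projection for property-gradient maps.

All tools consume only the model's public encode/decode interface, so they
work with any checkpoint.  Directions for the neighborhood grid are two
random orthogonal unit vectors in the latent space, scaled per-dimension by
the empirical standard deviation of a reference batch of encoded polymers,
so a unit step spans a comparable quantile in every dimension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .model_core import CopolymerVAE
from .polymer_repr import PolymerEnsembleSpec, build_graph, parse_polymer_string


class DegenerateInputError(ValueError):
    pass


def _seed_latent(model: CopolymerVAE,
                 seed_spec: Union[str, PolymerEnsembleSpec]) -> np.ndarray:
    spec = (parse_polymer_string(seed_spec)
            if isinstance(seed_spec, str) else seed_spec)
    return np.asarray(model.encode(spec).mu, dtype=np.float64)


def orthogonal_directions(dim: int, seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Two random orthonormal vectors in R^dim (Gram-Schmidt on Gaussians)."""
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(dim)
    u /= np.linalg.norm(u)
    v = rng.standard_normal(dim)
    v -= (v @ u) * u
    v /= np.linalg.norm(v)
    return u, v


def latent_std(model: CopolymerVAE,
               reference: Sequence[Union[str, PolymerEnsembleSpec]]) -> np.ndarray:
    """Per-dimension std of the encode-means of a reference batch."""
    specs = [parse_polymer_string(s) if isinstance(s, str) else s
             for s in reference]
    graphs = [build_graph(sp) for sp in specs]
    mu = model.encode_graphs(graphs).mu
    return np.maximum(np.asarray(mu).std(axis=0), 1e-8)


def neighborhood_grid(model: CopolymerVAE,
                      seed_spec: Union[str, PolymerEnsembleSpec],
                      half_steps: int,
                      scale: float = 1.0,
                      reference: Optional[Sequence[Union[str, PolymerEnsembleSpec]]] = None,
                      direction_seed: int = 0) -> List[List[str]]:
    """(2k+1) x (2k+1) grid of decodes around the seed's encode-mean.

    Cell (i, j), with i, j in [-k, k], decodes
        z = z_seed + i * scale * (sigma * u) + j * scale * (sigma * v)
    where u and v are random orthogonal unit vectors and sigma the
    per-dimension latent std of the reference batch (all-ones when no
    reference is given).  Cell (0, 0) is exactly decode(z_seed).
    """
    if half_steps < 1:
        raise ValueError("half_steps must be >= 1")
    z0 = _seed_latent(model, seed_spec)
    u, v = orthogonal_directions(model.cfg.latent_dim, seed=direction_seed)
    sigma = (latent_std(model, reference) if reference is not None
             else np.ones(model.cfg.latent_dim))
    du, dv = sigma * u, sigma * v
    k = half_steps
    zs = np.stack([z0 + i * scale * du + j * scale * dv
                   for i in range(-k, k + 1) for j in range(-k, k + 1)])
    flat = model.decode_batch(zs)
    n = 2 * k + 1
    return [flat[r * n:(r + 1) * n] for r in range(n)]


def perturb_sample(model: CopolymerVAE,
                   seed_spec: Union[str, PolymerEnsembleSpec],
                   noise_scale: float, n: int, seed: int = 0) -> List[str]:
    """Reference decode followed by n decodes of z_seed + noise_scale * eps,
    eps ~ N(0, I).  Element 0 is the unperturbed reference."""
    z0 = _seed_latent(model, seed_spec)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n, z0.shape[-1]))
    zs = np.concatenate([z0[None], z0[None] + noise_scale * eps])
    return model.decode_batch(zs)


def interpolate(model: CopolymerVAE,
                spec_a: Union[str, PolymerEnsembleSpec],
                spec_b: Union[str, PolymerEnsembleSpec],
                n_points: int,
                collapse_duplicates: bool = True) -> List[str]:
    """Decodes along the straight latent path z(t) = (1-t) za + t zb at
    n_points equally spaced t in [0, 1]; consecutive duplicate decodes are
    collapsed by default (unique path states)."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    za, zb = _seed_latent(model, spec_a), _seed_latent(model, spec_b)
    ts = np.linspace(0.0, 1.0, n_points)
    zs = (1.0 - ts)[:, None] * za[None] + ts[:, None] * zb[None]
    decoded = model.decode_batch(zs)
    if not collapse_duplicates:
        return decoded
    path = [decoded[0]]
    for s in decoded[1:]:
        if s != path[-1]:
            path.append(s)
    return path


@dataclass
class Projection2D:
    coords: np.ndarray              # (N, 2)
    explained_variance: np.ndarray  # (2,) fractions, non-increasing
    components: np.ndarray          # (2, D) principal axes
    mean: np.ndarray                # (D,) center used


def project_2d(latents: np.ndarray) -> Projection2D:
    """Project latent points onto their top-2 principal components."""
    X = np.asarray(latents, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 3:
        raise DegenerateInputError("project_2d needs >= 3 points of shape (N, D)")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD-based PCA: singular values give component variances directly
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    total = float(var.sum())
    if total <= 0 or len(var) < 2 or var[1] / var[0] < 1e-15:
        raise DegenerateInputError("rank-deficient input: fewer than 2 "
                                   "independent directions")
    comps = Vt[:2]
    return Projection2D(coords=Xc @ comps.T,
                        explained_variance=var[:2] / total,
                        components=comps,
                        mean=mean)
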