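"""Property-guided inverse design in the latent space.

Two optimizers minimize the design objective

    f(z) = w_ip * |IP_hat(z') - ip_target| + w_ea * EA_hat(z')   (minimize mode)
    f(z) = w_ip * |IP_hat(z') - ip_target|
           + w_ea * |EA_hat(z') - ea_target|                      (target mode)

plus a large additive penalty when decode(z) is not a valid polymer string.
z' is the decode--re-encode corrected point: optimizer proposals are decoded
to a structure and that structure is re-encoded, which projects arbitrary
latent points back onto the model's high-density manifold before property
prediction.

* run_bo: Gaussian-process surrogate (scikit-learn, Matern 5/2) with the
  upper-confidence-bound acquisition UCB(z; kappa) = mu(z) + kappa * sigma(z)
  maximized over random candidates inside the box bounds (we minimize f, so
  the surrogate models -f).
* run_ga: elitist NSGA-II with Latin Hypercube initialization, binary
  tournament selection, simulated binary crossover (SBX) and polynomial
  mutation (PM).  With one objective it degenerates to a standard elitist
  GA; a two-objective mode returns the non-dominated front.

Both optimizers spend exactly `budget` objective evaluations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .model_core import CopolymerVAE, LatentPoint
from .polymer_repr import build_graph, parse_polymer_string, validate


class BoundsError(ValueError):
    pass


class BudgetError(ValueError):
    pass


# --------------------------------------------------------------------------
# objective

@dataclass
class ObjectiveSpec:
    ip_target: float = 1.0
    ea_mode: str = "minimize"           # "minimize" or "target"
    ea_target: Optional[float] = None
    w_ip: float = 1.0
    w_ea: float = 1.0
    invalid_penalty: float = 10.0

    def __post_init__(self):
        if self.invalid_penalty <= 0:
            raise ValueError("invalid_penalty must be > 0")
        if self.w_ip < 0 or self.w_ea < 0:
            raise ValueError("weights must be >= 0")
        if self.ea_mode not in ("minimize", "target"):
            raise ValueError("ea_mode must be 'minimize' or 'target'")
        if self.ea_mode == "target" and self.ea_target is None:
            raise ValueError("ea_target required in target mode")

    def value(self, ea_hat: float, ip_hat: float, valid: bool) -> float:
        v = self.w_ip * abs(ip_hat - self.ip_target)
        if self.ea_mode == "minimize":
            v += self.w_ea * ea_hat
        else:
            v += self.w_ea * abs(ea_hat - self.ea_target)
        if not valid:
            v += self.invalid_penalty
        return float(v)

    def terms(self, ea_hat: float, ip_hat: float) -> Tuple[float, float]:
        """(|IP - target| term, EA term) for the two-objective mode."""
        t_ip = self.w_ip * abs(ip_hat - self.ip_target)
        t_ea = (self.w_ea * ea_hat if self.ea_mode == "minimize"
                else self.w_ea * abs(ea_hat - self.ea_target))
        return t_ip, t_ea


@dataclass
class Evaluation:
    z: np.ndarray
    z_corrected: np.ndarray
    decoded: Optional[str]
    valid: bool
    ea_hat: float
    ip_hat: float
    objective: float


@dataclass
class OptimizationResult:
    evaluations: List[Evaluation]
    budget: int
    best_trace: List[float] = field(default_factory=list)

    def __post_init__(self):
        if len(self.evaluations) > self.budget:
            raise BudgetError("more evaluations than budget")
        if not self.best_trace:
            best = np.inf
            for e in self.evaluations:
                best = min(best, e.objective)
                self.best_trace.append(best)

    @property
    def best(self) -> Evaluation:
        return min(self.evaluations, key=lambda e: e.objective)


def reencode_correct(z: LatentPoint, model: CopolymerVAE
                     ) -> Tuple[LatentPoint, bool, Optional[str]]:
    """Decode z and re-encode the decoded structure.

    Returns (z_corrected, valid, decoded_string); when the decode is not a
    valid polymer string, z is returned unchanged with valid=False.
    """
    zz = np.asarray(z.z, dtype=np.float64)
    s = model.decode(LatentPoint(z=zz))
    if not validate(s).valid:
        return LatentPoint(z=zz), False, s
    spec = parse_polymer_string(s)
    mu = model.encode(spec).mu
    return LatentPoint(z=np.asarray(mu, dtype=np.float64)), True, s


def objective(z: LatentPoint, model: CopolymerVAE,
              spec: ObjectiveSpec) -> float:
    """Eq-4-style objective with decode--re-encode correction."""
    return _evaluate(np.asarray(z.z, dtype=np.float64), model, spec).objective


def _evaluate(z: np.ndarray, model: CopolymerVAE,
              spec: ObjectiveSpec) -> Evaluation:
    zc, valid, s = reencode_correct(LatentPoint(z=z), model)
    ea_hat, ip_hat = model.predict_properties(zc)
    return Evaluation(z=z.copy(), z_corrected=np.asarray(zc.z), decoded=s,
                      valid=valid, ea_hat=ea_hat, ip_hat=ip_hat,
                      objective=spec.value(ea_hat, ip_hat, valid))


def _evaluate_batch(X: np.ndarray, model: CopolymerVAE,
                    spec: ObjectiveSpec) -> List[Evaluation]:
    """Batched decode -> validate -> re-encode -> predict for N latents;
    one decoder pass for the whole batch instead of N sequential decodes."""
    X = np.asarray(X, dtype=np.float64)
    decoded = model.decode_batch(X)
    out: List[Evaluation] = []
    valid_specs, valid_pos = [], []
    for i, s in enumerate(decoded):
        if validate(s).valid:
            valid_specs.append(parse_polymer_string(s))
            valid_pos.append(i)
    zc = X.copy()
    if valid_pos:
        graphs = [build_graph(sp) for sp in valid_specs]
        mu = np.asarray(model.encode_graphs(graphs).mu, dtype=np.float64)
        zc[valid_pos] = mu
    props = model.predict_properties_batch(zc)
    valid_set = set(valid_pos)
    for i, s in enumerate(decoded):
        ok = i in valid_set
        ea_hat, ip_hat = float(props[i, 0]), float(props[i, 1])
        out.append(Evaluation(z=X[i].copy(), z_corrected=zc[i], decoded=s,
                              valid=ok, ea_hat=ea_hat, ip_hat=ip_hat,
                              objective=spec.value(ea_hat, ip_hat, ok)))
    return out


def _make_evaluator(model, spec) -> Callable[[np.ndarray], Evaluation]:
    if callable(model) and not isinstance(model, CopolymerVAE):
        # test hook: a bare callable f(z) -> scalar stands in for the model
        def ev(z: np.ndarray) -> Evaluation:
            v = float(model(z))
            return Evaluation(z=z.copy(), z_corrected=z.copy(), decoded=None,
                              valid=True, ea_hat=np.nan, ip_hat=np.nan,
                              objective=v)
        return ev
    return lambda z: _evaluate(z, model, spec)


def _make_batch_evaluator(model, spec) -> Callable[[np.ndarray], List[Evaluation]]:
    if callable(model) and not isinstance(model, CopolymerVAE):
        single = _make_evaluator(model, spec)
        return lambda X: [single(np.asarray(x, dtype=np.float64)) for x in X]
    return lambda X: _evaluate_batch(X, model, spec)


def default_bounds(model: CopolymerVAE,
                   reference: Sequence[str]) -> np.ndarray:
    """Per-dimension [min, max] of encoded reference latents +/- 1 sd."""
    graphs = [build_graph(parse_polymer_string(s)) for s in reference]
    mu = np.asarray(model.encode_graphs(graphs).mu)
    sd = mu.std(axis=0)
    return np.stack([mu.min(axis=0) - sd, mu.max(axis=0) + sd], axis=1)


def _check_bounds(bounds: np.ndarray) -> np.ndarray:
    b = np.asarray(bounds, dtype=np.float64)
    if b.ndim != 2 or b.shape[1] != 2 or np.any(b[:, 1] <= b[:, 0]):
        raise BoundsError("bounds must be (D, 2) with max > min per dimension")
    return b


# --------------------------------------------------------------------------
# Bayesian optimization (GP + UCB)

def ucb(mu: np.ndarray, sigma: np.ndarray, kappa: float = 2.576) -> np.ndarray:
    """Upper confidence bound acquisition: mu + kappa * sigma."""
    return np.asarray(mu) + kappa * np.asarray(sigma)


def run_bo(model, spec: Optional[ObjectiveSpec] = None, budget: int = 60,
           bounds: Optional[np.ndarray] = None, kappa: float = 2.576,
           n_init: int = 10, n_candidates: int = 2000,
           seed: int = 0) -> OptimizationResult:
    """GP-based Bayesian optimization minimizing the objective.

    The surrogate regresses -f so that maximizing UCB(mu, sigma, kappa)
    trades off low objective (exploitation) against model uncertainty
    (exploration).  Acquisition is maximized over `n_candidates` uniform
    random points in the box (a dense random search is robust in 32-D and
    keeps every proposal inside bounds by construction).
    """
    spec = spec if spec is not None else ObjectiveSpec()
    if bounds is None:
        raise BoundsError("run_bo requires explicit box bounds")
    b = _check_bounds(bounds)
    if budget < n_init:
        raise BudgetError("budget must be >= n_init")
    rng = np.random.default_rng(seed)
    ev = _make_evaluator(model, spec)
    D = b.shape[0]
    lo, hi = b[:, 0], b[:, 1]

    sampler = qmc.LatinHypercube(d=D, seed=int(rng.integers(2 ** 31)))
    X = qmc.scale(sampler.random(n_init), lo, hi)
    evals = _make_batch_evaluator(model, spec)(X)
    y = np.array([e.objective for e in evals])

    kernel = (ConstantKernel(1.0, (1e-3, 1e3))
              * Matern(length_scale=np.ones(D), nu=2.5,
                       length_scale_bounds=(1e-2, 1e3))
              + WhiteKernel(1e-6, (1e-10, 1e-1)))
    for _ in range(budget - n_init):
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                      random_state=int(rng.integers(2 ** 31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(np.asarray(X), -y)
        cand = rng.uniform(lo, hi, size=(n_candidates, D))
        mu_c, sd_c = gp.predict(cand, return_std=True)
        x_next = cand[int(np.argmax(ucb(mu_c, sd_c, kappa)))]
        e = ev(x_next)
        evals.append(e)
        X = np.vstack([X, x_next])
        y = np.append(y, e.objective)
    return OptimizationResult(evaluations=evals, budget=budget)


# --------------------------------------------------------------------------
# NSGA-II genetic algorithm

def _sbx(rng, p1, p2, lo, hi, eta=15.0, prob=0.9):
    """Simulated binary crossover (per-variable, bounded)."""
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() > prob:
        return c1, c2
    for i in range(len(p1)):
        if rng.random() > 0.5 or abs(p1[i] - p2[i]) < 1e-14:
            continue
        x1, x2 = sorted((p1[i], p2[i]))
        u = rng.random()
        beta = (2 * u) ** (1 / (eta + 1)) if u <= 0.5 else \
            (1 / (2 * (1 - u))) ** (1 / (eta + 1))
        a = 0.5 * ((x1 + x2) - beta * (x2 - x1))
        bvals = 0.5 * ((x1 + x2) + beta * (x2 - x1))
        c1[i] = np.clip(a if rng.random() < 0.5 else bvals, lo[i], hi[i])
        c2[i] = np.clip(bvals if c1[i] == a else a, lo[i], hi[i])
    return c1, c2


def _pm(rng, x, lo, hi, eta=20.0, prob=None):
    """Polynomial mutation (bounded)."""
    y = x.copy()
    D = len(x)
    prob = prob if prob is not None else 1.0 / D
    for i in range(D):
        if rng.random() > prob:
            continue
        span = hi[i] - lo[i]
        d1 = (y[i] - lo[i]) / span
        d2 = (hi[i] - y[i]) / span
        u = rng.random()
        if u < 0.5:
            dq = (2 * u + (1 - 2 * u) * (1 - d1) ** (eta + 1)) ** (1 / (eta + 1)) - 1
        else:
            dq = 1 - (2 * (1 - u) + 2 * (u - 0.5) * (1 - d2) ** (eta + 1)) ** (1 / (eta + 1))
        y[i] = np.clip(y[i] + dq * span, lo[i], hi[i])
    return y


def _nondominated_sort(F: np.ndarray) -> List[np.ndarray]:
    """Fast non-dominated sorting; F is (N, M) objective values (minimized)."""
    N = len(F)
    dominates = [[] for _ in range(N)]
    dom_count = np.zeros(N, dtype=int)
    for i in range(N):
        for j in range(i + 1, N):
            if np.all(F[i] <= F[j]) and np.any(F[i] < F[j]):
                dominates[i].append(j)
                dom_count[j] += 1
            elif np.all(F[j] <= F[i]) and np.any(F[j] < F[i]):
                dominates[j].append(i)
                dom_count[i] += 1
    fronts, current = [], np.flatnonzero(dom_count == 0)
    while len(current):
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominates[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        current = np.array(nxt, dtype=int)
    return fronts


def _crowding(F: np.ndarray) -> np.ndarray:
    N, M = F.shape
    d = np.zeros(N)
    for m in range(M):
        order = np.argsort(F[:, m], kind="stable")
        d[order[0]] = d[order[-1]] = np.inf
        span = F[order[-1], m] - F[order[0], m]
        if span <= 0:
            continue
        d[order[1:-1]] += (F[order[2:], m] - F[order[:-2], m]) / span
    return d


def run_ga(model, spec: Optional[ObjectiveSpec] = None, budget: int = 2000,
           population: int = 50, bounds: Optional[np.ndarray] = None,
           seed: int = 0, n_objectives: int = 1,
           repair: bool = True) -> OptimizationResult:
    """NSGA-II over the box-bounded latent space, spending exactly `budget`
    objective evaluations (initial population included).

    n_objectives=1 minimizes the aggregated objective; n_objectives=2
    minimizes (|IP - target| term, EA term) jointly and the non-dominated
    front can be read off the returned evaluations.
    """
    spec = spec if spec is not None else ObjectiveSpec()
    if population < 2:
        raise ValueError("population must be >= 2")
    if budget < population:
        raise BudgetError("budget must be >= population")
    if bounds is None:
        raise BoundsError("run_ga requires explicit box bounds")
    b = _check_bounds(bounds)
    rng = np.random.default_rng(seed)
    ev_batch = _make_batch_evaluator(model, spec)
    lo, hi = b[:, 0], b[:, 1]
    D = b.shape[0]

    def obj_vec(e: Evaluation) -> np.ndarray:
        if n_objectives == 1:
            return np.array([e.objective])
        t_ip, t_ea = spec.terms(e.ea_hat, e.ip_hat)
        pen = 0.0 if e.valid else spec.invalid_penalty
        return np.array([t_ip + pen, t_ea + pen])

    def genome(e: Evaluation) -> np.ndarray:
        # decode--re-encode repair: valid individuals breed from their
        # corrected latent point (already computed during evaluation)
        if repair and e.valid:
            return np.clip(e.z_corrected, lo, hi)
        return e.z

    sampler = qmc.LatinHypercube(d=D, seed=int(rng.integers(2 ** 31)))
    X = qmc.scale(sampler.random(population), lo, hi)
    evals: List[Evaluation] = ev_batch(X)
    pop_idx = list(range(population))
    used = population

    def tournament(idx: Sequence[int], F: np.ndarray, crowd: np.ndarray,
                   rank: np.ndarray) -> int:
        a_pos, b_pos = rng.integers(len(idx)), rng.integers(len(idx))
        if rank[a_pos] != rank[b_pos]:
            return idx[a_pos] if rank[a_pos] < rank[b_pos] else idx[b_pos]
        return idx[a_pos] if crowd[a_pos] >= crowd[b_pos] else idx[b_pos]

    while used < budget:
        F = np.stack([obj_vec(evals[i]) for i in pop_idx])
        fronts = _nondominated_sort(F)
        rank = np.empty(len(pop_idx), dtype=int)
        for r, fr in enumerate(fronts):
            rank[fr] = r
        crowd = _crowding(F)

        n_off = min(population, budget - used)
        offspring: List[np.ndarray] = []
        while len(offspring) < n_off:
            i1 = tournament(pop_idx, F, crowd, rank)
            i2 = tournament(pop_idx, F, crowd, rank)
            c1, c2 = _sbx(rng, genome(evals[i1]), genome(evals[i2]), lo, hi)
            offspring.append(_pm(rng, c1, lo, hi))
            if len(offspring) < n_off:
                offspring.append(_pm(rng, c2, lo, hi))
        evals.extend(ev_batch(np.stack(offspring)))
        new_idx = list(range(used, used + len(offspring)))
        used += len(offspring)

        # elitist environmental selection over parents + offspring
        union = pop_idx + new_idx
        FU = np.stack([obj_vec(evals[i]) for i in union])
        fronts = _nondominated_sort(FU)
        chosen: List[int] = []
        for fr in fronts:
            if len(chosen) + len(fr) <= population:
                chosen.extend(fr)
            else:
                cd = _crowding(FU[fr])
                order = np.argsort(-cd, kind="stable")
                need = population - len(chosen)
                chosen.extend(fr[order[:need]])
                break
        pop_idx = [union[i] for i in chosen]

    return OptimizationResult(evaluations=evals, budget=budget)


# --------------------------------------------------------------------------
# reporting

@dataclass
class TopKReport:
    candidates: List[Evaluation]
    top10_mean_objective: float
    top3_objectives: List[float]
    truncated: bool = False


def report_top_k(result: OptimizationResult, k: int = 10) -> TopKReport:
    """k lowest-objective valid candidates, deduplicated by canonical string."""
    if not result.evaluations:
        raise ValueError("empty result")
    from .polymer_repr import canonical_string as _canon

    seen, distinct = set(), []
    for e in sorted(result.evaluations, key=lambda e: e.objective):
        if not e.valid:
            continue
        if e.decoded is None:
            key = tuple(np.round(e.z_corrected, 6))
        else:
            try:
                key = _canon(parse_polymer_string(e.decoded))
            except Exception:
                continue
        if key in seen:
            continue
        seen.add(key)
        distinct.append(e)
    truncated = k > len(distinct)
    if truncated:
        warnings.warn(f"only {len(distinct)} distinct valid candidates "
                      f"(requested {k})")
    top = distinct[:k]
    top10 = distinct[:10]
    return TopKReport(
        candidates=top,
        top10_mean_objective=float(np.mean([e.objective for e in top10]))
        if top10 else np.nan,
        top3_objectives=[e.objective for e in distinct[:3]],
        truncated=truncated,
    )
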