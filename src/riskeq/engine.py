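"""Addition-only symbolic regression over binary clinical conditions.

A candidate model is an expression tree whose only internal operator is
'+' and whose leaves are threshold conditions; flattened, it is simply a
multiset of conditions.  For each candidate the weights w_j and bias b
of the additive risk equation R = sum w_j x_j + b are refit by
ridge-penalized logistic maximum likelihood, and fitness is the mean
training log-loss plus a small parsimony penalty per term.  The
population evolves by tournament selection with crossover and three
mutation operators (hoist, point, subtree); the three mutation
probabilities can themselves be tuned by Gaussian-process Bayesian
optimization of the cross-validated log-loss over [0, 0.1]^3.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss

from .encoding import BinaryDesign
from .model import RiskEquation

__all__ = [
    "GPConfig",
    "Program",
    "TuneResult",
    "fit_term_weights",
    "fitness",
    "mutate",
    "crossover",
    "random_program",
    "evolve",
    "tune",
    "integer_score_table",
    "risk_score",
    "predict_prob",
]


@dataclass(frozen=True)
class GPConfig:
    """Evolutionary-search settings.

    Mutation probabilities live in [0, 0.1] when produced by the tuner;
    together with the crossover probability they must not exceed 1 (the
    remainder is plain reproduction).
    """

    population_size: int = 1000
    max_generations: int = 50
    tournament_size: int = 20
    p_crossover: float = 0.7
    p_hoist: float = 0.05
    p_point: float = 0.05
    p_subtree: float = 0.05
    parsimony_penalty: float = 1e-3
    early_stop_patience: int = 5
    early_stop_tol: float = 1e-4
    ridge: float = 1e-4
    init_size_max: int = 6
    local_search: bool = True
    local_search_passes: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in ("population_size", "max_generations", "tournament_size"):
            if getattr(self, name) < (0 if name == "max_generations" else 1):
                raise ValueError(f"{name} must be positive")
        probs = (self.p_crossover, self.p_hoist, self.p_point, self.p_subtree)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if sum(probs) > 1 + 1e-12:
            raise ValueError("p_crossover + p_hoist + p_point + p_subtree must be <= 1")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")


# ----------------------------------------------------------------------
# programs: '+'-only expression trees with condition-index leaves
# ----------------------------------------------------------------------

class Program:
    """Expression tree; a leaf is an int condition index, an internal
    node a 2-tuple of children (the '+' operator)."""

    __slots__ = ("node",)

    def __init__(self, node):
        self.node = node

    # structural helpers ----------------------------------------------
    def flatten(self) -> list:
        out = []
        stack = [self.node]
        while stack:
            n = stack.pop()
            if isinstance(n, tuple):
                stack.extend(n)
            else:
                out.append(n)
        out.reverse()
        return out

    def size(self) -> int:
        return len(self.flatten())

    def paths(self) -> list:
        """All subtree paths (tuples of 0/1 child indices), root included."""
        out = []
        stack = [((), self.node)]
        while stack:
            path, n = stack.pop()
            out.append(path)
            if isinstance(n, tuple):
                stack.append((path + (0,), n[0]))
                stack.append((path + (1,), n[1]))
        return out

    def get(self, path):
        n = self.node
        for i in path:
            n = n[i]
        return n

    def replaced(self, path, subnode) -> "Program":
        def rebuild(n, p):
            if not p:
                return subnode
            i, rest = p[0], p[1:]
            children = list(n)
            children[i] = rebuild(children[i], rest)
            return tuple(children)

        return Program(rebuild(self.node, tuple(path)))

    def term_key(self) -> tuple:
        return tuple(sorted(set(self.flatten())))

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"Program({self.node!r})"


def random_program(rng, n_pool: int, max_leaves: int = 6) -> Program:
    """Random '+'-only tree with 1..max_leaves leaves drawn from the pool."""
    n_leaves = int(rng.integers(1, max_leaves + 1))
    nodes = [int(i) for i in rng.integers(0, n_pool, n_leaves)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        merged = (nodes[i], nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return Program(nodes[0])


def mutate(program: Program, kind: str, rng, n_pool: int, max_leaves: int = 6) -> Program:
    """Apply one mutation; the result remains addition-only.

    hoist: a random subtree is replaced by one of its own subtrees (size
    never increases).  point: one random leaf is replaced by a random
    pool condition.  subtree: a random subtree is replaced by a freshly
    generated random tree.
    """
    if kind == "hoist":
        paths = program.paths()
        p = paths[int(rng.integers(len(paths)))]
        sub = Program(program.get(p))
        q = sub.paths()[int(rng.integers(len(sub.paths())))]
        return program.replaced(p, sub.get(q))
    if kind == "point":
        leaves = [p for p in program.paths() if not isinstance(program.get(p), tuple)]
        p = leaves[int(rng.integers(len(leaves)))]
        return program.replaced(p, int(rng.integers(n_pool)))
    if kind == "subtree":
        paths = program.paths()
        p = paths[int(rng.integers(len(paths)))]
        return program.replaced(p, random_program(rng, n_pool, max_leaves).node)
    raise ValueError(f"unknown mutation kind {kind!r}")


def crossover(a: Program, b: Program, rng) -> Program:
    """Replace a random subtree of ``a`` with a random subtree of ``b``."""
    pa = a.paths()
    pb = b.paths()
    p = pa[int(rng.integers(len(pa)))]
    q = pb[int(rng.integers(len(pb)))]
    return a.replaced(p, b.get(q))


# ----------------------------------------------------------------------
# weight refitting and fitness
# ----------------------------------------------------------------------

def _fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float):
    """Minimize mean log-loss + ridge * ||w||^2 (bias unpenalized).

    Returns (w, b, mean_logloss).  Raises on non-convergence.
    """
    n = len(y)
    if X.shape[1] == 0:
        prev = float(np.mean(y))
        prev = min(max(prev, 1e-12), 1 - 1e-12)
        b = float(np.log(prev / (1 - prev)))
        ll = -(prev * np.log(prev) + (1 - prev) * np.log(1 - prev))
        return np.empty(0), b, float(ll)
    C = 1.0 / (2.0 * n * ridge) if ridge > 0 else np.inf
    clf = LogisticRegression(C=C, solver="lbfgs", tol=1e-8, max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(X, y)
        except ConvergenceWarning as w:  # pragma: no cover - pathological
            raise RuntimeError(
                f"logistic refit failed to converge after {clf.max_iter} iterations "
                f"(n={n}, d={X.shape[1]}, ridge={ridge}): {w}"
            ) from None
    w = clf.coef_.ravel().astype(float)
    b = float(clf.intercept_[0])
    p = clf.predict_proba(X)[:, 1]
    ll = float(log_loss(y, p, labels=[0, 1]))
    return w, b, ll


def fit_term_weights(S: list, design: BinaryDesign, ridge: float = 1e-4):
    """Refit weights and bias for the condition set ``S`` on the training
    rows of ``design``; duplicated conditions are collapsed first.

    Returns (weights, bias) aligned with the de-duplicated order of S.
    """
    seen = []
    for c in S:
        if c not in seen:
            seen.append(c)
    names = [c.name for c in seen]
    missing = [nm for nm in names if nm not in design.X.columns]
    if missing:
        raise KeyError(f"design does not cover conditions: {missing}")
    mask = design.train_mask
    X = design.X.loc[:, names].to_numpy(dtype=float)[mask]
    w, b, _ = _fit_logistic(X, design.y[mask], ridge)
    return w, b


def fitness(program: Program, design: BinaryDesign, cfg: GPConfig, _ctx=None) -> float:
    """Mean training log-loss of the refit equation plus parsimony penalty
    per program term (duplicates count).  Lower is better."""
    if _ctx is None:
        mask = design.train_mask
        _ctx = (design.matrix(mask), design.y[mask], {})
    Xtr, ytr, cache = _ctx
    key = program.term_key()
    if key not in cache:
        cols = np.asarray(key, dtype=int)
        _, _, ll = _fit_logistic(Xtr[:, cols], ytr, cfg.ridge)
        cache[key] = ll
    return cache[key] + cfg.parsimony_penalty * program.size()


# ----------------------------------------------------------------------
# evolution
# ----------------------------------------------------------------------

def evolve(design: BinaryDesign, cfg: GPConfig) -> RiskEquation:
    """Evolve an additive risk equation on the training rows.

    Tournament selection with elitism; per-generation best fitness is
    non-increasing; stops early when the best fitness fails to improve
    by ``early_stop_tol`` for ``early_stop_patience`` generations.
    Fully reproducible given ``cfg.seed``.
    """
    n_pool = design.n_conditions
    if n_pool == 0:
        raise ValueError("empty candidate condition pool")
    rng = np.random.default_rng(cfg.seed)
    mask = design.train_mask
    Xtr = design.matrix(mask)
    ytr = design.y[mask]
    cache: dict = {}
    ctx = (Xtr, ytr, cache)

    def evaluate(prog):
        return fitness(prog, design, cfg, _ctx=ctx)

    pop = [random_program(rng, n_pool, cfg.init_size_max) for _ in range(cfg.population_size)]
    fits = np.array([evaluate(p) for p in pop])
    best_i = int(np.argmin(fits))
    best_prog, best_fit, best_gen = pop[best_i], float(fits[best_i]), 0
    history = [best_fit]

    def tournament():
        k = min(cfg.tournament_size, len(pop))
        idx = rng.choice(len(pop), size=k, replace=False)
        return pop[int(idx[np.argmin(fits[idx])])]

    stall = 0
    pc, ps, ph, pm = cfg.p_crossover, cfg.p_subtree, cfg.p_hoist, cfg.p_point
    for gen in range(1, cfg.max_generations + 1):
        newpop = [best_prog]  # elitism
        while len(newpop) < cfg.population_size:
            r = rng.random()
            if r < pc:
                child = crossover(tournament(), tournament(), rng)
            elif r < pc + ps:
                child = mutate(tournament(), "subtree", rng, n_pool, cfg.init_size_max)
            elif r < pc + ps + ph:
                child = mutate(tournament(), "hoist", rng, n_pool, cfg.init_size_max)
            elif r < pc + ps + ph + pm:
                child = mutate(tournament(), "point", rng, n_pool, cfg.init_size_max)
            else:
                child = Program(tournament().node)  # reproduction
            newpop.append(child)
        pop = newpop
        fits = np.array([evaluate(p) for p in pop])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit - cfg.early_stop_tol:
            stall = 0
        else:
            stall += 1
        if fits[gen_best] < best_fit:
            best_prog, best_fit, best_gen = pop[gen_best], float(fits[gen_best]), gen
        history.append(best_fit)
        if stall >= cfg.early_stop_patience:
            break

    # final refit of the winning term set
    order = []
    for i in best_prog.flatten():
        if i not in order:
            order.append(i)
    if cfg.local_search:
        order = _refine_terms(order, design, cfg, ctx)
    conds = [design.conditions[i] for i in order]
    w, b, ll = _fit_logistic(Xtr[:, order], ytr, cfg.ridge)
    return RiskEquation(
        terms=list(zip(conds, w.tolist())),
        bias=b,
        provenance={
            "generation_found": best_gen,
            "generations_run": len(history) - 1,
            "train_logloss": ll,
            "fitness": best_fit,
            "fitness_history": history,
            "seed": cfg.seed,
            "config": asdict(cfg),
            "n_train": int(mask.sum()),
        },
    )


def _refine_terms(order: list, design: BinaryDesign, cfg: GPConfig, ctx) -> list:
    """Memetic refinement of the evolved term set.

    Greedy first-improvement passes under the same penalized fitness:
    drop a term, swap a term for another condition on the same variable
    (threshold neighbours are highly correlated and easily confused by
    the evolutionary search), or add the single best condition from the
    pool.  Stops when a full pass yields no improvement.
    """
    Xtr, ytr, cache = ctx

    def set_fit(terms):
        key = tuple(sorted(set(terms)))
        if key not in cache:
            _, _, ll = _fit_logistic(Xtr[:, list(key)], ytr, cfg.ridge)
            cache[key] = ll
        return cache[key] + cfg.parsimony_penalty * len(key)

    by_var: dict = {}
    for i, c in enumerate(design.conditions):
        by_var.setdefault(c.variable, []).append(i)
    cur = list(dict.fromkeys(order))
    cur_fit = set_fit(cur)
    for _ in range(cfg.local_search_passes):
        improved = False
        # drop
        for i in range(len(cur) - 1, -1, -1):
            cand = cur[:i] + cur[i + 1:]
            f = set_fit(cand)
            if f < cur_fit - 1e-12:
                cur, cur_fit, improved = cand, f, True
        # swap within the same variable
        for i in range(len(cur)):
            var = design.conditions[cur[i]].variable
            for j in by_var[var]:
                if j in cur:
                    continue
                cand = cur[:i] + [j] + cur[i + 1:]
                f = set_fit(cand)
                if f < cur_fit - 1e-12:
                    cur, cur_fit, improved = cand, f, True
        # best single addition over the full pool
        best_j, best_f = None, cur_fit
        for j in range(design.n_conditions):
            if j in cur:
                continue
            f = set_fit(cur + [j])
            if f < best_f - 1e-12:
                best_j, best_f = j, f
        if best_j is not None:
            cur, cur_fit, improved = cur + [best_j], best_f, True
        if not improved:
            break
    return cur


# ----------------------------------------------------------------------
# Bayesian tuning of mutation probabilities
# ----------------------------------------------------------------------

@dataclass
class TuneResult:
    points: np.ndarray        # (n_calls, 3) evaluated (p_hoist, p_point, p_subtree)
    values: np.ndarray        # objective per point
    best_point: np.ndarray
    best_value: float
    kernel: str = ""

    def __post_init__(self):
        i = int(np.argmin(self.values))
        assert np.allclose(self.best_point, self.points[i])


def _fold_design(design: BinaryDesign, fold_id: int) -> BinaryDesign:
    """Training rows only: fold ``fold_id`` becomes the held-out part."""
    mask = design.train_mask
    fold = np.asarray(design.fold)[mask]
    split = np.where(fold == fold_id, "test", "train")
    return BinaryDesign(
        X=design.X.loc[mask].reset_index(drop=True),
        conditions=design.conditions,
        y=design.y[mask],
        split=split,
    )


def _cv_objective(design: BinaryDesign, base_cfg: GPConfig):
    if design.fold is None:
        raise ValueError("design needs CV fold ids for tuning")
    fold_ids = sorted(set(np.asarray(design.fold)[design.train_mask]))

    def objective(p):
        ph, pm, ps = [float(v) for v in p]
        losses = []
        for f in fold_ids:
            sub = _fold_design(design, f)
            cfg = replace(base_cfg, p_hoist=ph, p_point=pm, p_subtree=ps)
            eq = evolve(sub, cfg)
            prob = eq.predict_prob(sub.X.loc[sub.test_mask])
            losses.append(log_loss(sub.y[sub.test_mask], prob, labels=[0, 1]))
        return float(np.mean(losses))

    return objective


def _expected_improvement(mu, sigma, y_best, xi=0.01):
    sigma = np.maximum(sigma, 1e-12)
    z = (y_best - mu - xi) / sigma
    return (y_best - mu - xi) * sps.norm.cdf(z) + sigma * sps.norm.pdf(z)


def tune(
    design: BinaryDesign,
    base_cfg: GPConfig,
    n_calls: int = 20,
    seed: int = 0,
    n_initial: int = 5,
    objective=None,
    bounds: tuple = (0.0, 0.1),
) -> TuneResult:
    """Gaussian-process Bayesian optimization of the three mutation
    probabilities over [0, 0.1]^3, minimizing 5-fold CV mean log-loss.

    ``base_cfg`` should describe a reduced search (smaller population /
    fewer generations) than the final fit.  An alternative ``objective``
    callable mapping (p_hoist, p_point, p_subtree) -> float may be
    supplied.  A failed evaluation is recorded as the worst value seen
    and the run continues.  Expected-improvement acquisition on a
    Matérn-5/2 surrogate, maximized over a random candidate cloud.
    """
    if n_calls < n_initial:
        raise ValueError("n_calls must be >= the number of initial random points")
    if objective is None:
        objective = _cv_objective(design, base_cfg)
    lo, hi = bounds
    rng = np.random.default_rng(seed)
    pts: list = []
    vals: list = []

    def safe_eval(p):
        try:
            return float(objective(p))
        except Exception:
            finite = [v for v in vals if np.isfinite(v)]
            return float(max(finite)) if finite else 1e6

    for _ in range(n_initial):
        p = rng.uniform(lo, hi, 3)
        pts.append(p)
        vals.append(safe_eval(p))
    kernel = ConstantKernel(1.0) * Matern(length_scale=[0.03] * 3, nu=2.5) + WhiteKernel(
        noise_level=1e-6, noise_level_bounds=(1e-12, 1e-1)
    )
    gp_kernel_str = ""
    for _ in range(n_calls - n_initial):
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, alpha=1e-10,
            n_restarts_optimizer=2, random_state=int(rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.array(pts), np.array(vals))
        # candidate cloud: global uniform plus local jitter of the incumbent
        incumbent = pts[int(np.argmin(vals))]
        cand = np.vstack([
            rng.uniform(lo, hi, size=(2048, 3)),
            np.clip(incumbent + rng.normal(0, 0.004, size=(256, 3)), lo, hi),
        ])
        mu, sd = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sd, min(vals), xi=1e-4)
        p = cand[int(np.argmax(ei))]
        pts.append(p)
        vals.append(safe_eval(p))
        gp_kernel_str = str(gp.kernel_)
    pts_arr = np.array(pts)
    vals_arr = np.array(vals)
    i = int(np.argmin(vals_arr))
    return TuneResult(
        points=pts_arr, values=vals_arr,
        best_point=pts_arr[i], best_value=float(vals_arr[i]),
        kernel=gp_kernel_str,
    )


# ----------------------------------------------------------------------
# presentation
# ----------------------------------------------------------------------

def integer_score_table(eq: RiskEquation, scale: float = 100.0) -> pd.DataFrame:
    """Score-table rendering: (variable, range, score = round(w * scale)),
    sorted by score descending."""
    if not scale > 0:
        raise ValueError("scale must be > 0")
    rows = [
        {"variable": c.variable, "range": c.range_text(),
         "score": int(round(w * scale))}
        for c, w in eq.terms
    ]
    df = pd.DataFrame(rows, columns=["variable", "range", "score"])
    return df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)


# thin functional aliases for the equation operations
def risk_score(eq: RiskEquation, row):
    """R = sum_j w_j x_j + b for one row or a design matrix."""
    return eq.risk_score(row)


def predict_prob(eq: RiskEquation, row):
    """sigma(R); strictly increasing in the risk score."""
    return eq.predict_prob(row)
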