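"""Genetic-programming engine: weight refitting, mutations, evolution,
Bayesian tuning of mutation probabilities, and score-table rendering."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import riskeq as rq
from riskeq.engine import Program, _fit_logistic, crossover, mutate, random_program

from conftest import make_toy_design


# -- ridge-logistic refit ----------------------------------------------

def test_uninformative_feature_gets_zero_weight():
    rng = np.random.default_rng(0)
    n = 4000
    X = (rng.random((n, 1)) < 0.5).astype(float)
    y = rng.integers(0, 2, n)  # balanced, independent of X
    w, b, _ = _fit_logistic(X, y, ridge=1e-4)
    prev = y.mean()
    assert abs(w[0]) < 0.1
    assert b == pytest.approx(math.log(prev / (1 - prev)), abs=0.1)


def test_perfect_separator_stays_finite_under_ridge():
    X = np.array([[1.0]] * 50 + [[0.0]] * 50)
    y = np.array([1] * 50 + [0] * 50)
    w, b, _ = _fit_logistic(X, y, ridge=1e-3)
    assert np.isfinite(w[0]) and abs(w[0]) < 50


def test_planted_logistic_weights_recovered():
    """sigma(2x - 1) generator: w-hat in [1.8, 2.2], b-hat in [-1.2, -0.8]."""
    rng = np.random.default_rng(42)
    n = 5000
    x = (rng.random(n) < 0.5).astype(float)
    p = 1 / (1 + np.exp(-(2 * x - 1)))
    y = (rng.random(n) < p).astype(int)
    w, b, _ = _fit_logistic(x.reshape(-1, 1), y, ridge=1e-4)
    assert 1.8 <= w[0] <= 2.2
    assert -1.2 <= b <= -0.8


def test_refit_minimizes_stated_penalized_objective():
    """Cross-check against direct numerical minimization of
    mean log-loss + ridge * ||w||^2 (bias unpenalized)."""
    rng = np.random.default_rng(3)
    n, d, ridge = 300, 3, 1e-2
    X = (rng.random((n, d)) < 0.4).astype(float)
    r = X @ np.array([1.0, -0.8, 0.3]) - 0.2
    y = (rng.random(n) < 1 / (1 + np.exp(-r))).astype(int)

    def objective(theta):
        w, b = theta[:d], theta[d]
        z = X @ w + b
        ll = np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0) - y * z)
        return ll + ridge * np.sum(w**2)

    ref = optimize.minimize(objective, np.zeros(d + 1), method="BFGS").x
    w, b, _ = _fit_logistic(X, y, ridge)
    np.testing.assert_allclose(w, ref[:d], atol=2e-4)
    assert b == pytest.approx(ref[d], abs=2e-4)


def test_fit_term_weights_deduplicates_and_names_missing(toy_design):
    design, _ = toy_design
    S = [design.conditions[0], design.conditions[1], design.conditions[0]]
    w, b = rq.fit_term_weights(S, design)
    assert len(w) == 2
    with pytest.raises(KeyError, match="nope"):
        rq.fit_term_weights([rq.Condition("nope", "eq", (True,))], design)


# -- fitness -----------------------------------------------------------

def test_constant_predictor_fitness_is_ln2_plus_penalty():
    rng = np.random.default_rng(1)
    n = 200
    X = pd.DataFrame({"dead ==True": np.zeros(n, dtype=int)})
    design = rq.BinaryDesign(X=X, conditions=[rq.Condition("dead", "eq", (True,))],
                             y=np.array([0, 1] * (n // 2)))
    cfg = rq.GPConfig(population_size=2, max_generations=0, tournament_size=1)
    prog = Program(0)
    f = rq.fitness(prog, design, cfg)
    assert f == pytest.approx(math.log(2) + cfg.parsimony_penalty, abs=1e-6)
    f0 = rq.fitness(prog, design, replace(cfg, parsimony_penalty=0.0))
    assert f0 == pytest.approx(math.log(2), abs=1e-6)


def test_duplicate_terms_only_add_parsimony_cost(toy_design):
    design, _ = toy_design
    cfg = rq.GPConfig(population_size=2, max_generations=0, tournament_size=1,
                      parsimony_penalty=1e-3)
    single = Program(0)
    doubled = Program((0, 0))
    f1 = rq.fitness(single, design, cfg)
    f2 = rq.fitness(doubled, design, cfg)
    # identical refit optimum; the doubled program pays one extra penalty
    assert f2 - f1 == pytest.approx(cfg.parsimony_penalty, abs=1e-12)


# -- mutation operators ------------------------------------------------

def test_hoist_never_grows_and_point_preserves_shape():
    rng = np.random.default_rng(5)
    for _ in range(300):
        prog = random_program(rng, n_pool=20, max_leaves=8)
        hoisted = mutate(prog, "hoist", rng, 20)
        assert hoisted.size() <= prog.size()
        pointed = mutate(prog, "point", rng, 20)
        assert pointed.size() == prog.size()
    one = Program(7)
    assert mutate(one, "point", rng, 20).size() == 1


def test_mutation_closure_all_outputs_flatten_to_valid_multisets():
    """Every mutated/crossed program remains addition-only: it flattens
    to a multiset of pool indices."""
    rng = np.random.default_rng(6)
    pool = 15
    progs = [random_program(rng, pool, 6) for _ in range(30)]
    for _ in range(3000):
        kind = ("hoist", "point", "subtree")[int(rng.integers(3))]
        p = progs[int(rng.integers(len(progs)))]
        child = mutate(p, kind, rng, pool)
        leaves = child.flatten()
        assert len(leaves) >= 1
        assert all(isinstance(v, int) and 0 <= v < pool for v in leaves)
    for _ in range(500):
        a, b = rng.integers(0, len(progs), 2)
        child = crossover(progs[a], progs[b], rng)
        assert all(0 <= v < pool for v in child.flatten())


# -- evolution ---------------------------------------------------------

SMALL_GP = dict(population_size=60, max_generations=10, tournament_size=5,
                early_stop_patience=4, init_size_max=4)


def test_zero_generations_returns_best_of_initial_population(toy_design):
    design, _ = toy_design
    eq = rq.evolve(design, rq.GPConfig(**{**SMALL_GP, "max_generations": 0,
                                          "local_search": False}, seed=1))
    assert eq.provenance["generations_run"] == 0
    assert len(eq) >= 1


def test_best_fitness_trace_is_monotone_nonincreasing(toy_design):
    design, _ = toy_design
    eq = rq.evolve(design, rq.GPConfig(**SMALL_GP, seed=2))
    hist = eq.provenance["fitness_history"]
    assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))


def test_evolve_is_seed_deterministic(toy_design):
    design, _ = toy_design
    cfg = rq.GPConfig(**SMALL_GP, seed=7)
    eq1 = rq.evolve(design, cfg)
    eq2 = rq.evolve(design, cfg)
    assert [(c.name, w) for c, w in eq1.terms] == [(c.name, w) for c, w in eq2.terms]
    assert eq1.bias == eq2.bias


def test_evolve_recovers_two_planted_rules():
    """Planted 2-rule generator (w = 2 and -1.5, b = -0.5): both
    conditions appear in the selected set across seeded runs."""
    hits = 0
    for seed in range(10):
        design, truth = make_toy_design(n=2000, p=12, seed=seed)
        eq = rq.evolve(design, rq.GPConfig(**SMALL_GP, seed=seed))
        names = {c.name for c in eq.conditions}
        hits += all(c.name in names for c in truth.conditions)
    assert hits >= 9


def test_evolve_rejects_empty_pool():
    design = rq.BinaryDesign(
        X=pd.DataFrame(index=range(4)), conditions=[], y=np.array([0, 1, 0, 1]))
    with pytest.raises(ValueError, match="empty candidate"):
        rq.evolve(design, rq.GPConfig(**SMALL_GP))


# -- tuner -------------------------------------------------------------

def test_tuner_bookkeeping_with_mock_objective():
    calls = []

    def mock(p):
        calls.append(tuple(p))
        return float((p[0] - 0.05) ** 2 + (p[1] - 0.02) ** 2 + p[2] ** 2)

    res = rq.tune(None, None, n_calls=20, seed=0, objective=mock)
    assert res.points.shape == (20, 3)
    assert len(calls) == 20
    assert np.all((res.points >= 0.0) & (res.points <= 0.1))
    assert res.best_value == res.values.min()
    np.testing.assert_allclose(res.best_point, res.points[np.argmin(res.values)])


def test_tuner_beats_random_search_on_smooth_objective():
    """Median over seeds: GP-guided search's best is no worse than the
    best of the same number of uniform random draws."""
    def mock(p):
        return float((p[0] - 0.07) ** 2 + (p[1] - 0.03) ** 2 + (p[2] - 0.05) ** 2)

    deltas = []
    for seed in range(10):
        res = rq.tune(None, None, n_calls=20, seed=seed, objective=mock)
        rng = np.random.default_rng(1000 + seed)
        rand_best = min(mock(rng.uniform(0, 0.1, 3)) for _ in range(20))
        deltas.append(res.best_value - rand_best)
    assert np.median(deltas) <= 0.0


def test_tuner_records_failures_as_worst_value():
    def flaky(p):
        if p[0] > 0.05:
            raise RuntimeError("boom")
        return float(p[0])

    res = rq.tune(None, None, n_calls=12, seed=3, objective=flaky)
    assert len(res.values) == 12
    assert np.isfinite(res.values).all()


# -- score table -------------------------------------------------------

def test_integer_score_table_rounds_scales_and_sorts():
    terms = [
        (rq.Condition("LOC_preop", "ge", (2.0,), display=("stupor",)), 0.44),
        (rq.Condition("RBC transfusion", "ge", (12.0,)), 0.57),
        (rq.Condition("RBC transfusion", "interval", (4.0, 12.0)), 0.41),
    ]
    eq = rq.RiskEquation(terms=terms, bias=-1.0)
    tab = rq.integer_score_table(eq, scale=100)
    assert list(tab["score"]) == sorted(tab["score"], reverse=True)
    assert tab.iloc[0]["variable"] == "RBC transfusion"
    assert tab.iloc[0]["range"] == "≥12"
    assert tab.iloc[0]["score"] == 57
    assert set(tab["range"]) == {"≥12", "≥stupor", "≥4 and <12"}
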