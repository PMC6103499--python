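"""Ising pseudo-likelihood structure learning: conditionals, objective,
optimizer, samplers, and graph recovery."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from spixcrf import (
    IsingModel,
    LabelSamples,
    extract_graph,
    fit_structure,
    gibbs_sample,
    ising_conditional,
    npl_objective,
    pixel_draw_samples,
    slic_adaptive,
)
from spixcrf.structure import _npl_value_grad


def _random_model(p, rng, density=1.0, scale=0.8):
    pairs = np.array(list(itertools.combinations(range(p), 2)))
    keep = rng.random(len(pairs)) < density
    edges = pairs[keep] if keep.any() else pairs[:1]
    return IsingModel(
        theta_node=rng.normal(0, 0.5, p),
        theta_edge=rng.normal(0, scale, len(edges)),
        edges=edges,
    )


def _enumerate_joint(model):
    """Exact joint over all 2^p states via the explicit partition function."""
    p = model.n_nodes
    states = np.array(list(itertools.product([-1, 1], repeat=p)), dtype=float)
    w = model.coupling_matrix()
    energy = states @ model.theta_node + 0.5 * np.einsum("si,ij,sj->s", states, w, states)
    un = np.exp(energy)
    return states, un / un.sum()


class TestConditional:
    def test_all_zero_parameters_give_half(self):
        m = IsingModel(theta_node=np.zeros(3), theta_edge=np.zeros(3),
                       edges=np.array([[0, 1], [1, 2], [0, 2]]))
        assert ising_conditional(m, np.array([1, 1, 1]), 0) == 0.5

    def test_hand_evaluated_local_field(self):
        # a = 0.5 + 1*1 = 1.5 -> e^3 / (e^3 + 1)
        m = IsingModel(theta_node=np.array([0.5, 0.0]), theta_edge=np.array([1.0]),
                       edges=np.array([[0, 1]]))
        p = ising_conditional(m, np.array([0, 1]), 0)
        assert np.isclose(p, np.exp(3) / (np.exp(3) + 1))
        assert np.isclose(p, 0.95257, atol=5e-6)

    def test_conditionals_normalize(self, rng):
        for _ in range(50):
            m = _random_model(5, rng)
            y = rng.choice([-1.0, 1.0], size=5)
            i = int(rng.integers(5))
            p_plus = ising_conditional(m, y, i)
            y_m = y.copy()
            y_m[i] = -1
            y_p = y.copy()
            y_p[i] = 1
            # flipping y_i must not change the conditional; p(+1)+p(-1)=1
            assert np.isclose(ising_conditional(m, y_m, i), ising_conditional(m, y_p, i))
            a = m.theta_node[i] + sum(
                m.theta_edge[k] * y[v if u == i else u]
                for k, (u, v) in enumerate(m.edges) if i in (u, v))
            p_minus = 1.0 / (1.0 + np.exp(2 * a))
            assert np.isclose(p_plus + p_minus, 1.0, atol=1e-12)

    def test_matches_exact_enumeration_conditionals(self, rng):
        # pseudo-likelihood conditionals == conditionals of the enumerated
        # joint for small models
        for p in (2, 3, 4):
            m = _random_model(p, rng)
            states, probs = _enumerate_joint(m)
            for _ in range(10):
                y = rng.choice([-1.0, 1.0], size=p)
                i = int(rng.integers(p))
                match_rest = np.all(
                    np.delete(states, i, axis=1) == np.delete(y, i), axis=1)
                plus = probs[match_rest & (states[:, i] == 1)].sum()
                minus = probs[match_rest & (states[:, i] == -1)].sum()
                assert np.isclose(ising_conditional(m, y, i), plus / (plus + minus),
                                  atol=1e-10)


class TestObjective:
    def test_zero_parameters_give_log2_per_term(self, rng):
        p, n = 6, 11
        m = _random_model(p, rng)
        m.theta_node[:] = 0
        m.theta_edge[:] = 0
        samples = LabelSamples(rng.choice([-1, 1], size=(n, p)))
        value, _ = npl_objective(m, samples)
        assert np.isclose(value, n * p * np.log(2))

    def test_duplicating_samples_doubles_value(self, rng):
        m = _random_model(4, rng)
        y = rng.choice([-1, 1], size=(7, 4))
        v1, _ = npl_objective(m, LabelSamples(y))
        v2, _ = npl_objective(m, LabelSamples(np.vstack([y, y])))
        assert np.isclose(v2, 2 * v1)

    def test_gradient_matches_finite_differences(self, rng):
        p = 5
        edges = np.array(list(itertools.combinations(range(p), 2)))
        y = rng.choice([-1.0, 1.0], size=(20, p))
        x0 = rng.normal(0, 0.3, p + len(edges))

        def f(x):
            return _npl_value_grad(x[:p], x[p:], edges, y)[0]

        v, gn, ge = _npl_value_grad(x0[:p], x0[p:], edges, y)
        grad = np.concatenate([gn, ge])
        eps = 1e-6
        for k in range(len(x0)):
            e = np.zeros_like(x0)
            e[k] = eps
            fd = (f(x0 + e) - f(x0 - e)) / (2 * eps)
            assert abs(fd - grad[k]) <= 1e-5 * max(1.0, abs(grad[k]))

    def test_convexity_on_random_segments(self, rng):
        p = 4
        edges = np.array(list(itertools.combinations(range(p), 2)))
        y = rng.choice([-1.0, 1.0], size=(15, p))
        for _ in range(20):
            xa = rng.normal(0, 1, p + len(edges))
            xb = rng.normal(0, 1, p + len(edges))
            fa = _npl_value_grad(xa[:p], xa[p:], edges, y)[0]
            fb = _npl_value_grad(xb[:p], xb[p:], edges, y)[0]
            mid = (xa + xb) / 2
            fm = _npl_value_grad(mid[:p], mid[p:], edges, y)[0]
            assert fm <= (fa + fb) / 2 + 1e-9


class TestFit:
    def test_large_lambda_fully_shrinks_edges(self, rng):
        p = 5
        edges = np.array(list(itertools.combinations(range(p), 2)))
        y = rng.choice([-1, 1], size=(40, p))
        m = fit_structure(LabelSamples(y), edges, lambda_struct=1e4)
        assert np.allclose(m.theta_edge, 0.0)
        # node biases at the per-node logistic MLE: sigmoid(2 theta) = freq(+1)
        freq = (y == 1).mean(axis=0)
        expect = 0.5 * (np.log(freq) - np.log1p(-freq))
        assert np.allclose(m.theta_node, expect, atol=1e-3)

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_structure(LabelSamples(np.ones((3, 2), dtype=int)),
                          np.array([[0, 1]]), lambda_struct=-1.0)

    def test_unpenalized_fit_matches_quasi_newton_oracle(self, rng):
        p = 4
        edges = np.array(list(itertools.combinations(range(p), 2)))
        y = rng.choice([-1.0, 1.0], size=(30, p))
        m = fit_structure(LabelSamples(y), edges, lambda_struct=0.0,
                          max_iter=3000, tol=1e-12)

        def fun(x):
            v, gn, ge = _npl_value_grad(x[:p], x[p:], edges, y)
            return v, np.concatenate([gn, ge])

        ref = minimize(fun, np.zeros(p + len(edges)), jac=True, method="L-BFGS-B",
                       options={"ftol": 1e-15, "gtol": 1e-12})
        ours = np.concatenate([m.theta_node, m.theta_edge])
        assert fun(ours)[0] <= ref.fun + 1e-4
        assert np.allclose(ours, ref.x, atol=1e-3)

    def test_objective_trace_non_increasing(self, rng):
        p = 6
        edges = np.array(list(itertools.combinations(range(p), 2)))
        y = rng.choice([-1, 1], size=(25, p))
        m = fit_structure(LabelSamples(y), edges, lambda_struct=2.0)
        trace = np.array(m.trace)
        assert np.all(np.diff(trace) <= 1e-10)

    def test_cycle_graph_recovery_f1(self):
        # Gibbs samples from a known 20-node cycle; the learned support
        # should recover the cycle at the best lambda on a log grid
        p = 20
        cycle = np.array([[i, (i + 1) % p] for i in range(p)])
        cycle = np.sort(cycle, axis=1)
        truth = IsingModel(theta_node=np.zeros(p),
                           theta_edge=np.full(p, 0.8), edges=cycle)
        samples = gibbs_sample(truth, n_draws=2000, burn_in=300, thin=2, seed=9)
        candidates = np.array(list(itertools.combinations(range(p), 2)))
        true_set = {tuple(e) for e in cycle}
        best_f1 = 0.0
        for lam in 2.0 ** np.arange(2, 10):
            m = fit_structure(samples, candidates, lambda_struct=float(lam),
                              max_iter=400, tol=1e-8)
            got = {tuple(e) for e in extract_graph(m, 1e-6)}
            if not got:
                continue
            tp = len(got & true_set)
            prec = tp / len(got)
            rec = tp / len(true_set)
            if prec + rec:
                best_f1 = max(best_f1, 2 * prec * rec / (prec + rec))
        assert best_f1 >= 0.9

    def test_recovered_weights_correlate_with_truth(self):
        p = 20
        cycle = np.sort(np.array([[i, (i + 1) % p] for i in range(p)]), axis=1)
        rng = np.random.default_rng(4)
        signs = rng.choice([-1.0, 1.0], size=p)
        truth = IsingModel(theta_node=np.zeros(p), theta_edge=0.8 * signs, edges=cycle)
        samples = gibbs_sample(truth, n_draws=2000, burn_in=300, thin=2, seed=10)
        m = fit_structure(samples, cycle, lambda_struct=4.0, max_iter=400)
        r = np.corrcoef(m.theta_edge, truth.theta_edge)[0, 1]
        assert r >= 0.8


class TestExtract:
    def test_zero_model_gives_empty_graph(self):
        m = IsingModel(theta_node=np.zeros(4), theta_edge=np.zeros(2),
                       edges=np.array([[0, 1], [2, 3]]))
        assert len(extract_graph(m)) == 0

    def test_learned_graph_subset_of_candidates(self, rng):
        p = 6
        edges = np.array(list(itertools.combinations(range(p), 2)))
        y = rng.choice([-1, 1], size=(30, p))
        m = fit_structure(LabelSamples(y), edges, lambda_struct=1.0)
        learned = {tuple(e) for e in extract_graph(m)}
        assert learned <= {tuple(e) for e in edges}

    def test_edge_count_mostly_nonincreasing_in_lambda(self, noisy_phantom):
        from spixcrf import build_rag

        sp = slic_adaptive(noisy_phantom.image, 60)
        rag = build_rag(sp, 2)
        samples = pixel_draw_samples(noisy_phantom.image, sp, 150, seed=2)
        counts = []
        for lam in 2.0 ** np.arange(-2, 7):
            m = fit_structure(samples, rag.edges, float(lam), max_iter=250)
            counts.append(len(extract_graph(m)))
        increases = sum(b > a for a, b in zip(counts, counts[1:]))
        assert increases <= max(1, int(0.05 * len(counts)))
        assert counts[-1] <= counts[0]


class TestSamplers:
    def test_gibbs_zero_model_is_fair(self):
        m = IsingModel(theta_node=np.zeros(5), theta_edge=np.zeros(0),
                       edges=np.empty((0, 2), dtype=int))
        s = gibbs_sample(m, n_draws=2000, burn_in=50, thin=1, seed=1)
        assert np.all(np.abs(s.data.mean(axis=0)) <= 3.0 / np.sqrt(2000))

    def test_gibbs_two_node_matches_enumeration(self):
        m = IsingModel(theta_node=np.zeros(2), theta_edge=np.array([1.0]),
                       edges=np.array([[0, 1]]))
        states, probs = _enumerate_joint(m)
        p_agree = probs[states[:, 0] == states[:, 1]].sum()
        s = gibbs_sample(m, n_draws=4000, burn_in=200, thin=2, seed=3)
        emp = (s.data[:, 0] == s.data[:, 1]).mean()
        # 4 sigma Monte-Carlo band (thinned draws are weakly dependent)
        assert abs(emp - p_agree) <= 4 * np.sqrt(p_agree * (1 - p_agree) / 4000) + 0.02

    def test_strong_coupling_aligns_neighbors(self):
        p = 10
        path = np.array([[i, i + 1] for i in range(p - 1)])
        m = IsingModel(theta_node=np.zeros(p), theta_edge=np.full(p - 1, 2.0),
                       edges=path)
        s = gibbs_sample(m, n_draws=500, burn_in=200, thin=2, seed=5)
        agree = (s.data[:, :-1] == s.data[:, 1:]).mean()
        assert agree > 0.9

    def test_pixel_draw_constant_image(self):
        img = np.full((20, 20), 0.5)
        sp = slic_adaptive(img, 1)
        s = pixel_draw_samples(img, sp, 10, seed=0)
        assert len(np.unique(s.data)) == 1

    def test_pixel_draw_core_nodes_always_positive(self, noiseless_phantom):
        from spixcrf import node_labels_from_mask

        sp = slic_adaptive(noiseless_phantom.image, 100)
        core_nodes = node_labels_from_mask(sp, noiseless_phantom.mask_core) == 1
        s = pixel_draw_samples(noiseless_phantom.image, sp, 50, seed=1)
        assert np.all(s.data[:, core_nodes] == 1)

    def test_pixel_draw_matches_binomial_rates(self, noisy_phantom):
        from skimage.filters import threshold_otsu

        sp = slic_adaptive(noisy_phantom.image, 40)
        s = pixel_draw_samples(noisy_phantom.image, sp, 500, seed=8)
        thr = threshold_otsu(noisy_phantom.image)
        pos_frac = np.array([
            (noisy_phantom.image[sp.labels == rid] > thr).mean()
            for rid in range(sp.n_regions)
        ])
        emp = (s.data == 1).mean(axis=0)
        sd = np.sqrt(pos_frac * (1 - pos_frac) / 500)
        assert np.all(np.abs(emp - pos_frac) <= 3 * sd + 1e-9)
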