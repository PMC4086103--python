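import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragspec.chem import POSITIVE, parse_structure
from fragspec.features import FEATURE_NAMES, N_FEATURES, transition_features
from fragspec.fraggraph import build_graph, prune_graph
from fragspec.model import (
    SingleEnergyModel,
    TrainConfig,
    TransitionModel,
    marginals,
    prune_by_probability,
    train_em,
    transition_probs,
)
from fragspec.spectra import Peak, Spectrum
from fragspec.tolerance import MassTolerance


def two_node_chain(break_prob):
    """Root -> single child graph with the requested break probability,
    realized through the bias weight (all feature weights zero)."""
    graph = build_graph(parse_structure("CO"), POSITIVE, max_depth=1)
    child = graph.nodes[1].id
    chain = prune_graph(graph, {child})
    assert len(chain.nodes) == 2 and len(chain.transitions) == 1
    theta = np.zeros(N_FEATURES + 1)
    phi = transition_features(chain, chain.transitions[0])
    # softmax([score, bias]) with score = theta_f . phi = 0:
    # P(break) = 1 / (1 + exp(bias))
    theta[-1] = math.log((1 - break_prob) / break_prob)
    return chain, theta, child


def dense_kernel(model, graph):
    """Explicit transition matrix from the public per-node distribution."""
    ids = [n.id for n in graph.nodes]
    pos = {nid: k for k, nid in enumerate(ids)}
    K = np.zeros((len(ids), len(ids)))
    for nid in ids:
        for target, p in transition_probs(model, graph, nid).items():
            j = pos[nid] if target is None else pos[target]
            K[pos[nid], j] += p
    return K, pos


def test_zero_weights_give_uniform_moves(ethanol_graph, zero_model):
    probs = transition_probs(zero_model, ethanol_graph, 0)
    k = len(probs)
    assert all(p == pytest.approx(1.0 / k) for p in probs.values())


def test_leaf_is_absorbing(ethanol_graph, zero_model):
    leaves = [n.id for n in ethanol_graph.nodes
              if not any(t.parent_id == n.id for t in ethanol_graph.transitions)]
    assert leaves
    probs = transition_probs(zero_model, ethanol_graph, leaves[0])
    assert probs == {None: 1.0}


def test_water_loss_weight_dominates(ethanol_graph):
    """A large weight on the H2O-loss flag makes the water-loss child the
    most probable move among the root's children."""
    theta = np.zeros(N_FEATURES + 1)
    theta[FEATURE_NAMES.index("loss_H2O")] = 5.0
    model = TransitionModel(theta)
    probs = transition_probs(model, ethanol_graph, 0)
    h2o_children = {
        t.child_id for t in ethanol_graph.transitions
        if t.parent_id == 0 and t.neutral_loss_formula == {"H": 2, "O": 1}
    }
    assert h2o_children
    best = max((c for c in probs if c is not None), key=lambda c: probs[c])
    assert best in h2o_children


def test_two_step_chain_marginal_closed_form():
    """Root->A with P(break)=0.6 and A absorbing: after two steps
    P(A) = 1 - 0.4^2 = 0.84."""
    chain, theta, child = two_node_chain(0.6)
    model = TransitionModel(theta, depth=2)
    marg = marginals(model, chain)
    assert marg[child] == pytest.approx(0.84, abs=1e-12)
    assert marg[0] == pytest.approx(0.16, abs=1e-12)


def test_chain_depth_zero_is_invalid():
    with pytest.raises(ValueError):
        TransitionModel(np.zeros(N_FEATURES + 1), depth=0)


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_marginals_sum_to_one_for_any_theta(ethanol_graph, seed):
    rng = np.random.default_rng(seed)
    theta = rng.normal(0, 2, N_FEATURES + 1)
    model = TransitionModel(theta, depth=3)
    marg = marginals(model, ethanol_graph)
    assert sum(marg.values()) == pytest.approx(1.0, abs=1e-9)
    assert all(p >= 0 for p in marg.values())


@settings(max_examples=10, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_kernel_rows_sum_to_one(ethanol_graph, seed):
    rng = np.random.default_rng(seed)
    model = TransitionModel(rng.normal(0, 3, N_FEATURES + 1))
    for n in ethanol_graph.nodes:
        probs = transition_probs(model, ethanol_graph, n.id)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("smiles,depth", [("CCO", 2), ("CCN", 3), ("CC(C)O", 2)])
def test_marginals_match_matrix_power_oracle(smiles, depth):
    """Chain propagation equals an explicit kernel power on graphs small
    enough to materialize."""
    graph = build_graph(parse_structure(smiles), POSITIVE, max_depth=2)
    assert len(graph.nodes) <= 50
    rng = np.random.default_rng(3)
    model = TransitionModel(rng.normal(0, 1, N_FEATURES + 1), depth=depth)
    K, pos = dense_kernel(model, graph)
    assert np.allclose(K.sum(axis=1), 1.0)
    p0 = np.zeros(len(graph.nodes))
    p0[pos[0]] = 1.0
    expected = p0 @ np.linalg.matrix_power(K, depth)
    marg = marginals(model, graph)
    for nid, k in pos.items():
        assert marg[nid] == pytest.approx(expected[k], abs=1e-12)


def test_prune_by_probability_edges(ethanol_graph, zero_model):
    same = prune_by_probability(ethanol_graph, zero_model, 0.0)
    assert same is ethanol_graph
    only_root = prune_by_probability(ethanol_graph, zero_model, 1 - 1e-9)
    assert [n.id for n in only_root.nodes] == [0]
    with pytest.raises(ValueError):
        prune_by_probability(ethanol_graph, zero_model, 1.0)


def test_prune_by_probability_matches_exhaustive_filter(ethanol_graph):
    rng = np.random.default_rng(5)
    model = TransitionModel(rng.normal(0, 1, N_FEATURES + 1))
    threshold = 0.05
    pruned = prune_by_probability(ethanol_graph, model, threshold)
    # oracle: dense kernel power, filter, plus root paths
    K, pos = dense_kernel(model, ethanol_graph)
    p0 = np.zeros(len(K))
    p0[pos[0]] = 1.0
    pd = p0 @ np.linalg.matrix_power(K, model.depth)
    keep = {nid for nid, k in pos.items() if pd[k] >= threshold}
    expected = prune_graph(ethanol_graph, keep)
    assert {n.id for n in pruned.nodes} == {n.id for n in expected.nodes}


# ---------------------------------------------------------------------------
# EM


def _spectrum_for(graph, weights, energy="medium"):
    peaks = [Peak(graph.node(nid).ion_mass, w) for nid, w in weights.items()]
    return Spectrum(energy, peaks)


def test_zero_iterations_returns_init():
    chain, theta, child = two_node_chain(0.5)
    spec = _spectrum_for(chain, {0: 50.0, child: 50.0})
    init = np.full(N_FEATURES + 1, 0.25)
    fitted, trace = train_em([(chain, spec)], init_theta=init, iterations=0)
    assert np.array_equal(fitted.theta, init)
    assert len(trace) == 1


@pytest.mark.parametrize("q", [0.2, 0.5, 0.8])
def test_single_break_probability_recovery(q):
    """Root with one child at chain depth 1: placing fraction q of the
    intensity on the child mass must recover break probability q
    (closed-form Bernoulli MLE)."""
    chain, _, child = two_node_chain(0.5)
    spec = _spectrum_for(chain, {0: 100.0 * (1 - q), child: 100.0 * q})
    cfg = TrainConfig(chain_depth=1, l2_penalty=0.0, convergence_tol=1e-12,
                      inner_steps=100)
    fitted, trace = train_em([(chain, spec)], init_theta=np.zeros(N_FEATURES + 1),
                             iterations=60, config=cfg)
    probs = transition_probs(fitted, chain, 0)
    assert probs[child] == pytest.approx(q, abs=0.01)


def test_em_loglik_trace_monotone(tiny_library, ref_models):
    from fragspec.simulate import FixtureConfig, sample_spectra

    cfg = FixtureConfig(seed=11)
    rng = np.random.default_rng(11)
    dataset = [
        (mol, sample_spectra(mol, ref_models, cfg, rng=rng)["medium"])
        for mol in tiny_library[:4]
    ]
    _, trace = train_em(dataset, iterations=6, seed=1)
    assert len(trace) >= 2
    assert all(b - a >= -1e-6 for a, b in zip(trace, trace[1:]))


def test_model_file_roundtrip_byte_identical(ref_models):
    for model in ref_models.values():
        text = model.to_text()
        again = TransitionModel.from_text(text)
        assert again.to_text() == text
        assert again.depth == model.depth
        assert again.energy_level == model.energy_level


def test_model_file_rejects_weight_mismatch():
    text = TransitionModel.zeros().to_text().replace("loss_H2O", "loss_XYZ")
    with pytest.raises(ValueError, match="mismatch"):
        TransitionModel.from_text(text)


def test_results_object_carries_fit_diagnostics(tiny_library, ref_models):
    """statsmodels-style surface: fit() returns params, llf trace,
    standard errors and a readable summary."""
    from fragspec.simulate import FixtureConfig, sample_spectra

    cfg = FixtureConfig(seed=13)
    rng = np.random.default_rng(13)
    dataset = [
        (mol, sample_spectra(mol, ref_models, cfg, rng=rng)["medium"])
        for mol in tiny_library[:3]
    ]
    sem = SingleEnergyModel(dataset, energy_level="medium")
    res = sem.fit(maxiter=3, seed=0)
    assert res.params.shape == (N_FEATURES + 1,)
    assert res.llf == res.llf_trace[-1]
    assert res.bse.shape == res.params.shape
    text = res.summary()
    assert "loss_H2O" in text and "self_bias" in text
    spec = res.predict(tiny_library[0])
    assert spec.peaks


def test_mismatched_energy_dataset_rejected(tiny_library):
    spec = Spectrum("high", [Peak(50.0, 100.0)])
    with pytest.raises(ValueError, match="high"):
        SingleEnergyModel([(tiny_library[0], spec)], energy_level="low")


def test_unmatchable_spectrum_policy(tiny_library):
    bogus = Spectrum("medium", [Peak(9999.0, 100.0)])
    cfg_err = TrainConfig(on_unmatched="error")
    with pytest.raises(Exception):
        train_em([(tiny_library[0], bogus)], iterations=1, config=cfg_err)
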