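"""Single-energy probabilistic fragmentation model.

The fragmentation of a precursor ion is modelled as a d-step Markov chain
over the nodes of its fragmentation graph. At each step the ion either
stays intact or takes one of its outgoing cleavage transitions; the move
distribution is a softmax over linear scores ``theta_f . Phi(parent,
child)`` for each transition and a scalar bias for staying put. The
marginal occupancy after d steps gives the predicted peak intensities.

Parameters are learned per collision energy by expectation-maximization:
observed peak intensity is soft-assigned to tolerance-matched graph nodes
in proportion to the current marginals (the exact posterior for the
"terminal state lies in the matched set" observation model), expected
transition counts follow from a forward-backward pass over the chain, and
the M-step fits theta to those counts by L2-penalized gradient ascent.

Two surfaces are provided: plain functions (:func:`transition_probs`,
:func:`marginals`, :func:`prune_by_probability`, :func:`train_em`) and a
statsmodels-style :class:`SingleEnergyModel` whose ``fit`` returns a
:class:`SingleEnergyResults` with the estimates, their standard errors,
the log-likelihood trace and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import POSITIVE, MoleculeStructure
from .features import FEATURE_NAMES, N_FEATURES, feature_matrix
from .fraggraph import (
    DEFAULT_MAX_DEPTH,
    FragmentationGraph,
    build_graph,
    prune_graph,
)
from .spectra import ENERGY_LEVELS, Spectrum
from .tolerance import MassTolerance

DEFAULT_CHAIN_DEPTH = 2
DEFAULT_PRUNE_THRESHOLD = 0.001


class TrainingError(ValueError):
    """Raised when a training spectrum cannot be used."""


@dataclass
class TransitionModel:
    """Parameter vector of one single-energy model.

    ``theta`` has one weight per cleavage feature plus a trailing
    self-transition bias; ``depth`` is the number of chain steps.
    """

    theta: np.ndarray
    depth: int = DEFAULT_CHAIN_DEPTH
    energy_level: str = "medium"

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (N_FEATURES + 1,):
            raise ValueError(
                f"theta must have length {N_FEATURES + 1} "
                f"({N_FEATURES} features + bias), got {self.theta.shape}"
            )
        if self.depth < 1:
            raise ValueError("chain depth must be >= 1")
        if self.energy_level not in ENERGY_LEVELS:
            raise ValueError(f"unknown energy level {self.energy_level!r}")

    @property
    def bias(self) -> float:
        return float(self.theta[-1])

    @classmethod
    def zeros(cls, depth: int = DEFAULT_CHAIN_DEPTH,
              energy_level: str = "medium") -> "TransitionModel":
        return cls(np.zeros(N_FEATURES + 1), depth, energy_level)

    def to_text(self) -> str:
        lines = ["# fragspec transition model",
                 f"energy {self.energy_level}",
                 f"depth {self.depth}"]
        for name, w in zip(FEATURE_NAMES, self.theta[:-1]):
            lines.append(f"{name} {w:.12g}")
        lines.append(f"self_bias {self.theta[-1]:.12g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "TransitionModel":
        energy, depth = "medium", DEFAULT_CHAIN_DEPTH
        weights: dict[str, float] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, value = line.split(None, 1)
            if key == "energy":
                energy = value.strip()
            elif key == "depth":
                depth = int(value)
            else:
                weights[key] = float(value)
        expected = set(FEATURE_NAMES) | {"self_bias"}
        if set(weights) != expected:
            missing = expected - set(weights)
            extra = set(weights) - expected
            raise ValueError(f"model file weight mismatch: missing={sorted(missing)} "
                             f"unknown={sorted(extra)}")
        theta = np.array([weights[n] for n in FEATURE_NAMES] + [weights["self_bias"]])
        return cls(theta, depth, energy)


# ---------------------------------------------------------------------------
# kernel and marginals


class _GraphKernel:
    """Cached per-graph structures: transition features, adjacency, and the
    softmax move distributions for a given theta."""

    def __init__(self, graph: FragmentationGraph):
        self.graph = graph
        self.ids = [n.id for n in graph.nodes]
        self.pos = {nid: k for k, nid in enumerate(self.ids)}
        self.features = feature_matrix(graph)  # (T, D) in transition order
        self.out: list[list[int]] = [[] for _ in self.ids]  # transition indices
        for t_idx, tr in enumerate(graph.transitions):
            self.out[self.pos[tr.parent_id]].append(t_idx)
        self.child_pos = np.array(
            [self.pos[tr.child_id] for tr in graph.transitions], dtype=int
        ) if graph.transitions else np.zeros(0, dtype=int)

    def move_probs(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (stay_prob per node, prob per transition)."""
        scores = self.features @ theta[:-1] if len(self.features) else np.zeros(0)
        bias = theta[-1]
        stay = np.ones(len(self.ids))
        tprob = np.zeros(len(scores))
        for k, t_indices in enumerate(self.out):
            if not t_indices:
                continue
            s = scores[t_indices]
            m = max(bias, float(np.max(s)))
            es = np.exp(s - m)
            eb = math.exp(bias - m)
            z = eb + es.sum()
            stay[k] = eb / z
            tprob[t_indices] = es / z
        return stay, tprob

    def step(self, p: np.ndarray, stay: np.ndarray, tprob: np.ndarray) -> np.ndarray:
        out = p * stay
        if len(tprob):
            np.add.at(out, self.child_pos, p[self._parent_pos()] * tprob)
        return out

    def _parent_pos(self) -> np.ndarray:
        if not hasattr(self, "_ppos"):
            self._ppos = np.array(
                [self.pos[tr.parent_id] for tr in self.graph.transitions], dtype=int
            ) if self.graph.transitions else np.zeros(0, dtype=int)
        return self._ppos

    def forward(self, theta: np.ndarray, depth: int) -> list[np.ndarray]:
        """Occupancy vectors alpha_0..alpha_depth."""
        stay, tprob = self.move_probs(theta)
        p = np.zeros(len(self.ids))
        p[self.pos[0]] = 1.0
        alphas = [p]
        for _ in range(depth):
            p = self.step(p, stay, tprob)
            alphas.append(p)
        return alphas


def transition_probs(model: TransitionModel, graph: FragmentationGraph,
                     parent_id: int) -> dict[int | None, float]:
    """Move distribution out of one node: child id -> probability, with
    key ``None`` for the self-transition. A childless node stays with
    probability 1."""
    kernel = _GraphKernel(graph)
    if parent_id not in kernel.pos:
        raise KeyError(f"node {parent_id} not in graph")
    stay, tprob = kernel.move_probs(model.theta)
    k = kernel.pos[parent_id]
    probs: dict[int | None, float] = {None: float(stay[k])}
    for t_idx in kernel.out[k]:
        probs[graph.transitions[t_idx].child_id] = float(tprob[t_idx])
    return probs


def marginals(model: TransitionModel, graph: FragmentationGraph) -> dict[int, float]:
    """Node id -> probability of occupying that fragment after
    ``model.depth`` chain steps, starting from the precursor."""
    kernel = _GraphKernel(graph)
    alpha = kernel.forward(model.theta, model.depth)[-1]
    return {nid: float(alpha[k]) for k, nid in enumerate(kernel.ids)}


def prune_by_probability(graph: FragmentationGraph, model: TransitionModel,
                         threshold: float) -> FragmentationGraph:
    """Drop nodes whose terminal marginal falls below ``threshold``
    (keeping root paths to every survivor). Threshold 0 is a no-op."""
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    if threshold == 0:
        return graph
    marg = marginals(model, graph)
    keep = {nid for nid, p in marg.items() if p >= threshold}
    return prune_graph(graph, keep)


# ---------------------------------------------------------------------------
# EM training


@dataclass
class TrainConfig:
    """Knobs of the EM fit. Defaults are pinned for reproducibility."""

    mode: str = POSITIVE
    graph_depth: int = DEFAULT_MAX_DEPTH
    chain_depth: int = DEFAULT_CHAIN_DEPTH
    tolerance: MassTolerance = field(default_factory=MassTolerance)
    learning_rate: float = 0.1
    inner_steps: int = 50
    l2_penalty: float = 0.01
    convergence_tol: float = 1e-4
    on_unmatched: str = "skip"  # or "error"


class _TrainingInstance:
    """One (graph, matched spectrum) pair prepared for EM."""

    def __init__(self, graph: FragmentationGraph, spectrum: Spectrum,
                 cfg: TrainConfig, label: str = "?"):
        self.kernel = _GraphKernel(graph)
        masses = np.array([n.ion_mass for n in graph.nodes])
        total = float(spectrum.intensity.sum())
        self.peak_weights: list[float] = []
        self.peak_nodes: list[np.ndarray] = []  # node positions per peak
        dropped = 0.0
        for p in spectrum.peaks:
            hits = np.nonzero(np.abs(masses - p.mz)
                              <= cfg.tolerance.window(p.mz))[0]
            w = p.intensity / total
            if len(hits) == 0:
                if cfg.on_unmatched == "error":
                    raise TrainingError(
                        f"peak {p.mz:.5f} of {label} matches no fragment")
                dropped += w
                continue
            self.peak_weights.append(w)
            self.peak_nodes.append(hits)
        if not self.peak_weights:
            raise TrainingError(f"no matchable peaks in spectrum for {label}")
        # renormalize over the matched intensity
        s = sum(self.peak_weights)
        self.peak_weights = [w / s for w in self.peak_weights]

    def loglik(self, theta: np.ndarray, depth: int) -> float:
        alpha = self.kernel.forward(theta, depth)[-1]
        ll = 0.0
        for w, hits in zip(self.peak_weights, self.peak_nodes):
            m = float(alpha[hits].sum())
            ll += w * math.log(max(m, 1e-300))
        return ll

    def expected_counts(self, theta: np.ndarray, depth: int
                        ) -> tuple[np.ndarray, np.ndarray, float]:
        """E-step: (expected stay counts per node, expected counts per
        transition, observed log-likelihood)."""
        k = self.kernel
        stay, tprob = k.move_probs(theta)
        alphas = k.forward(theta, depth)
        alpha_d = alphas[-1]
        # soft-assign peak intensity to matched nodes by current marginals
        q = np.zeros(len(k.ids))
        ll = 0.0
        for w, hits in zip(self.peak_weights, self.peak_nodes):
            m = alpha_d[hits]
            tot = float(m.sum())
            ll += w * math.log(max(tot, 1e-300))
            if tot > 0:
                q[hits] += w * m / tot
            else:
                q[hits] += w / len(hits)
        # backward recursion for r_t(i) = E[q-weight | F_t = i] / alpha_d
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(alpha_d > 0, q / np.where(alpha_d > 0, alpha_d, 1.0), 0.0)
        stay_counts = np.zeros(len(k.ids))
        trans_counts = np.zeros(len(tprob))
        ppos = k._parent_pos()
        for t in range(depth - 1, -1, -1):
            a = alphas[t]
            stay_counts += a * stay * r
            r_next = stay * r
            if len(tprob):
                flow = tprob * r[k.child_pos]
                trans_counts += a[ppos] * flow
                np.add.at(r_next, ppos, flow)
            r = r_next
        return stay_counts, trans_counts, ll


def _m_step(instances: list[_TrainingInstance], counts, theta0: np.ndarray,
            cfg: TrainConfig) -> np.ndarray:
    """Penalized weighted softmax regression on expected counts, by
    gradient ascent with backtracking."""
    total = sum(float(sc.sum() + tc.sum()) for sc, tc in counts)
    if total <= 0:
        return theta0

    def objective_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        obj = 0.0
        grad = np.zeros_like(theta)
        for inst, (stay_c, trans_c) in zip(instances, counts):
            k = inst.kernel
            stay, tprob = k.move_probs(theta)
            scores = (k.features @ theta[:-1]) if len(k.features) else np.zeros(0)
            for node_k, t_indices in enumerate(k.out):
                n_total = stay_c[node_k] + (trans_c[t_indices].sum() if t_indices else 0.0)
                if n_total <= 0:
                    continue
                if not t_indices:
                    continue  # leaf: stay prob 1, no contribution
                s = scores[t_indices]
                m = max(theta[-1], float(np.max(s)))
                logz = m + math.log(math.exp(theta[-1] - m)
                                    + np.exp(s - m).sum())
                obj += stay_c[node_k] * theta[-1] + float(trans_c[t_indices] @ s)
                obj -= n_total * logz
                pi_stay = stay[node_k]
                pi_t = tprob[t_indices]
                grad[-1] += stay_c[node_k] - n_total * pi_stay
                diff = trans_c[t_indices] - n_total * pi_t
                grad[:-1] += k.features[t_indices].T @ diff
        obj = obj / total - cfg.l2_penalty * float(theta @ theta)
        grad = grad / total - 2.0 * cfg.l2_penalty * theta
        return obj, grad

    theta = theta0.copy()
    obj, grad = objective_grad(theta)
    lr = cfg.learning_rate
    for _ in range(cfg.inner_steps):
        cand = theta + lr * grad
        cand_obj, cand_grad = objective_grad(cand)
        if cand_obj < obj:
            lr *= 0.5
            if lr < 1e-8:
                break
            continue
        theta, obj, grad = cand, cand_obj, cand_grad
    return theta


def train_em(dataset: list[tuple[MoleculeStructure | FragmentationGraph, Spectrum]],
             init_theta: np.ndarray | None = None,
             iterations: int = 20,
             seed: int | None = None,
             energy_level: str = "medium",
             config: TrainConfig | None = None,
             ) -> tuple[TransitionModel, list[float]]:
    """EM fit of one single-energy model.

    ``dataset`` pairs each molecule (or a prebuilt fragmentation graph)
    with its observed spectrum at this energy. Returns the fitted model
    and the per-iteration penalized observed-data log-likelihood trace
    (non-decreasing up to numerical slack). ``seed`` jitters the
    initialization when ``init_theta`` is not given.
    """
    cfg = config or TrainConfig()
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if init_theta is None:
        rng = np.random.default_rng(seed)
        theta = 0.01 * rng.standard_normal(N_FEATURES + 1) if seed is not None \
            else np.zeros(N_FEATURES + 1)
    else:
        theta = np.asarray(init_theta, dtype=float).copy()

    instances: list[_TrainingInstance] = []
    for idx, (item, spectrum) in enumerate(dataset):
        graph = item if isinstance(item, FragmentationGraph) else build_graph(
            item, cfg.mode, max_depth=cfg.graph_depth)
        label = getattr(item, "canonical_key", f"pair#{idx}")
        try:
            instances.append(_TrainingInstance(graph, spectrum, cfg, label))
        except TrainingError:
            if cfg.on_unmatched == "error":
                raise
            # skip-with-warning path: molecule contributes nothing
            import warnings
            warnings.warn(f"skipping unmatchable training spectrum for {label}")
    if not instances:
        raise TrainingError("no usable training pairs")

    def penalized_ll(th: np.ndarray) -> float:
        ll = sum(inst.loglik(th, cfg.chain_depth) for inst in instances)
        return ll / len(instances) - cfg.l2_penalty * float(th @ th)

    trace = [penalized_ll(theta)]
    for _ in range(iterations):
        counts = []
        for inst in instances:
            stay_c, trans_c, _ = inst.expected_counts(theta, cfg.chain_depth)
            counts.append((stay_c, trans_c))
        theta = _m_step(instances, counts, theta, cfg)
        trace.append(penalized_ll(theta))
        if trace[-1] - trace[-2] < cfg.convergence_tol:
            break
    model = TransitionModel(theta, cfg.chain_depth, energy_level)
    return model, trace


# ---------------------------------------------------------------------------
# statsmodels-style surface


class SingleEnergyModel:
    """Fragmentation model for one collision energy, built from
    (molecule, spectrum) training pairs.

    Parameters
    ----------
    dataset : list of (MoleculeStructure, Spectrum)
        Training pairs; spectra must carry this model's energy level.
    energy_level : {"low", "medium", "high"}
    config : TrainConfig, optional
        Graph depth, chain depth, tolerance and optimizer knobs.
    """

    def __init__(self, dataset: list[tuple[MoleculeStructure, Spectrum]],
                 energy_level: str = "medium",
                 config: TrainConfig | None = None):
        self.energy_level = energy_level
        self.config = config or TrainConfig()
        bad = [s.energy_level for _, s in dataset if s.energy_level != energy_level]
        if bad:
            raise ValueError(f"dataset contains spectra at {set(bad)}, "
                             f"expected {energy_level!r}")
        self.dataset = dataset
        # graphs are reused across EM iterations and the predict step
        self.graphs = [
            build_graph(mol, self.config.mode, max_depth=self.config.graph_depth)
            for mol, _ in dataset
        ]

    @property
    def exog_names(self) -> list[str]:
        return FEATURE_NAMES + ["self_bias"]

    def fit(self, start_params: np.ndarray | None = None, maxiter: int = 20,
            seed: int | None = None) -> "SingleEnergyResults":
        pairs = list(zip(self.graphs, (s for _, s in self.dataset)))
        model, trace = train_em(pairs, init_theta=start_params,
                                iterations=maxiter, seed=seed,
                                energy_level=self.energy_level,
                                config=self.config)
        converged = len(trace) >= 2 and (trace[-1] - trace[-2]
                                         < self.config.convergence_tol)
        return SingleEnergyResults(self, model, trace, converged)

    def loglike(self, theta: np.ndarray) -> float:
        """Mean penalized observed-data log-likelihood at ``theta``."""
        cfg = self.config
        insts = [
            _TrainingInstance(g, s, cfg)
            for g, (_, s) in zip(self.graphs, self.dataset)
        ]
        ll = sum(i.loglik(np.asarray(theta, float), cfg.chain_depth) for i in insts)
        return ll / len(insts) - cfg.l2_penalty * float(np.dot(theta, theta))


class SingleEnergyResults:
    """Fit results: parameter estimates, numerical standard errors, the
    EM log-likelihood trace, and spectrum prediction under the fit."""

    def __init__(self, model: SingleEnergyModel, fitted: TransitionModel,
                 llf_trace: list[float], converged: bool):
        self.model = model
        self.fitted = fitted
        self.params = fitted.theta
        self.llf_trace = list(llf_trace)
        self.llf = llf_trace[-1]
        self.converged = converged
        self._bse: np.ndarray | None = None

    @property
    def bse(self) -> np.ndarray:
        """Standard errors from the numerically differenced Hessian of
        the penalized log-likelihood (NaN where not positive definite)."""
        if self._bse is None:
            h = _numerical_hessian(self.model.loglike, self.params)
            with np.errstate(invalid="ignore"):
                try:
                    cov = np.linalg.inv(-h)
                    diag = np.diag(cov)
                    self._bse = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
                except np.linalg.LinAlgError:
                    self._bse = np.full_like(self.params, np.nan)
        return self._bse

    def predict(self, mol: MoleculeStructure, adduct=None,
                prune_threshold: float = DEFAULT_PRUNE_THRESHOLD) -> Spectrum:
        from .predict import predict_single_energy

        return predict_single_energy(mol, self.model.config.mode, self.fitted,
                                     adduct=adduct,
                                     prune_threshold=prune_threshold)

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(self.fitted.to_text())

    def summary(self) -> str:
        lines = [
            "Single-Energy Fragmentation Model Results",
            "=" * 57,
            f"energy level:   {self.fitted.energy_level:>8}    "
            f"chain depth: {self.fitted.depth}",
            f"n molecules:    {len(self.model.dataset):>8}    "
            f"EM iterations: {len(self.llf_trace) - 1}",
            f"penalized llf:  {self.llf:>12.6f}    converged: {self.converged}",
            "-" * 57,
            f"{'parameter':<20}{'estimate':>12}{'std err':>12}",
            "-" * 57,
        ]
        for name, w, se in zip(self.model.exog_names, self.params, self.bse):
            se_s = f"{se:12.4f}" if np.isfinite(se) else f"{'--':>12}"
            lines.append(f"{name:<20}{w:12.4f}{se_s}")
        lines.append("=" * 57)
        return "\n".join(lines)


def _numerical_hessian(fun, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = np.zeros((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            if i == j:
                # xpp/xmm step the coordinate by 2*eps when i == j
                h[i, i] = (fun(xpp) - 2.0 * f0 + fun(xmm)) / (4.0 * eps * eps)
            else:
                h[i, j] = h[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) \
                    / (4.0 * eps * eps)
    return h
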