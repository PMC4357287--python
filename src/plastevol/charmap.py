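"""Two-state Markov inference and stochastic character mapping.

The binary character here is the presence of the mouth dimorphism.  Its
history on the tree is inferred by (i) computing the likelihood of tip
states under a continuous-time two-state Markov chain (Mk2) by Felsenstein
pruning, (ii) calibrating discretized gamma/beta priors on the overall
rate and gain/loss bias by MCMC, and (iii) drawing full transition
histories ("stochastic maps") conditional on the tips: joint node states
from the pruning conditionals, then endpoint-conditioned paths along each
branch by uniformization.  Gains (0->1) and losses (1->0) are counted per
sampled history.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import Phylogeny, TreeSet

Segments = list[tuple[float, int]]  # (length, state), rootward -> tipward


@dataclass
class Mk2Model:
    """Rates of a two-state chain, in both natural parameterizations.

    ``q01``/``q10`` are gain/loss rates per unit branch length.  The
    (overall rate, bias) pair follows the convention ``q01 = 2*lam*beta``,
    ``q10 = 2*lam*(1-beta)``, so that ``lam`` equals the expected number of
    transitions per unit length at stationarity when ``beta = 1/2``.
    """

    q01: float
    q10: float

    def __post_init__(self) -> None:
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("rates must be non-negative")

    @classmethod
    def from_rate_bias(cls, lam: float, beta: float) -> "Mk2Model":
        if not (0.0 < beta < 1.0):
            raise ValueError("bias must lie in (0, 1)")
        return cls(q01=2.0 * lam * beta, q10=2.0 * lam * (1.0 - beta))

    @property
    def overall_rate(self) -> float:
        return 0.5 * (self.q01 + self.q10)

    @property
    def bias(self) -> float:
        s = self.q01 + self.q10
        return 0.5 if s == 0 else self.q01 / s

    def stationary(self) -> np.ndarray:
        s = self.q01 + self.q10
        if s == 0:
            return np.array([0.5, 0.5])
        return np.array([self.q10 / s, self.q01 / s])

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = expm(Q t) in closed form for the 2-state chain."""
        s = self.q01 + self.q10
        if s == 0 or t == 0:
            return np.eye(2)
        pi = self.stationary()
        e = np.exp(-s * t)
        return np.array([
            [pi[0] + pi[1] * e, pi[1] * (1 - e)],
            [pi[0] * (1 - e), pi[1] + pi[0] * e],
        ])


@dataclass
class CharacterHistory:
    """A piecewise-constant state painting of every branch.

    ``segments[i]`` lists ``(length, state)`` pieces along the edge above
    node ``i``, ordered from the parent end toward node ``i``; adjacent
    pieces differ in state and lengths sum to the branch length.
    """

    tree: Phylogeny
    segments: list[Segments]
    node_states: np.ndarray

    def __post_init__(self) -> None:
        self.node_states = np.asarray(self.node_states, dtype=int)

    def transition_counts(self) -> tuple[int, int]:
        """(#gains 0->1, #losses 1->0) over the whole tree."""
        gains = losses = 0
        for node in range(self.tree.n_nodes):
            segs = self.segments[node]
            prev = None
            for _, state in segs:
                if prev is not None and state != prev:
                    if state == 1:
                        gains += 1
                    else:
                        losses += 1
                prev = state
            # boundary with the parent node's state
            parent = self.tree.parent[node]
            if parent >= 0 and segs:
                if segs[0][1] != self.node_states[parent]:
                    if segs[0][1] == 1:
                        gains += 1
                    else:
                        losses += 1
        return gains, losses

    def tip_states(self) -> pd.Series:
        return pd.Series(
            self.node_states[: self.tree.n_tips], index=self.tree.tip_labels,
            name="state",
        )

    def time_in_state(self, state: int) -> np.ndarray:
        """Per-edge total length spent in ``state`` (indexed by child node)."""
        out = np.zeros(self.tree.n_nodes)
        for node in range(self.tree.n_nodes):
            out[node] = sum(l for l, s in self.segments[node] if s == state)
        return out

    def validate(self) -> None:
        for node in range(self.tree.n_nodes):
            if self.tree.parent[node] < 0:
                continue
            segs = self.segments[node]
            total = sum(l for l, _ in segs)
            if not np.isclose(total, self.tree.edge_length[node], atol=1e-9):
                raise ValueError(f"segments on edge {node} do not sum to its length")
            if segs and segs[-1][1] != self.node_states[node]:
                raise ValueError(f"segment end state mismatch at node {node}")


def _resolve_root(root_distribution, model: Mk2Model) -> np.ndarray:
    if isinstance(root_distribution, str):
        if root_distribution == "stationary":
            return model.stationary()
        if root_distribution == "flat":
            return np.array([0.5, 0.5])
        raise ValueError(f"unknown root distribution {root_distribution!r}")
    arr = np.asarray(root_distribution, dtype=float)
    if arr.shape != (2,) or not np.isclose(arr.sum(), 1.0):
        raise ValueError("root distribution must be two probabilities summing to 1")
    return arr


def _tip_state_array(tree: Phylogeny, tip_states) -> np.ndarray:
    if isinstance(tip_states, pd.Series):
        tip_states = tip_states.to_dict()
    if isinstance(tip_states, dict):
        missing = [t for t in tree.tip_labels if t not in tip_states]
        if missing:
            raise ValueError(f"missing tip states for: {missing}")
        arr = np.array([tip_states[t] for t in tree.tip_labels], dtype=int)
    else:
        arr = np.asarray(tip_states, dtype=int)
        if arr.shape != (tree.n_tips,):
            raise ValueError("tip state array has wrong length")
    if not np.isin(arr, [0, 1]).all():
        raise ValueError("tip states must be 0 or 1")
    return arr


def _pruning_partials(tree: Phylogeny, states: np.ndarray, model: Mk2Model):
    """Down-pass conditional likelihoods with per-node log scaling."""
    partial = np.zeros((tree.n_nodes, 2))
    logscale = 0.0
    P = [None] * tree.n_nodes
    for node in tree.postorder:
        if not tree.children[node]:
            partial[node, states[node]] = 1.0
        else:
            vec = np.ones(2)
            for child in tree.children[node]:
                Pc = model.transition_matrix(tree.edge_length[child])
                P[child] = Pc
                vec *= Pc @ partial[child]
            mx = vec.max()
            if mx <= 0:
                return partial, -np.inf, P
            partial[node] = vec / mx
            logscale += np.log(mx)
    return partial, logscale, P


def mk2_loglik(tree: Phylogeny, tip_states, model: Mk2Model,
               root_distribution="stationary") -> float:
    """Log-likelihood of binary tip states under the Mk2 chain.

    Felsenstein pruning with closed-form 2x2 transition matrices; the root
    is integrated against ``root_distribution`` (stationary by default).
    """
    states = _tip_state_array(tree, tip_states)
    root_p = _resolve_root(root_distribution, model)
    partial, logscale, _ = _pruning_partials(tree, states, model)
    like = float(root_p @ partial[tree.root])
    if like <= 0 or not np.isfinite(logscale):
        return -np.inf
    return np.log(like) + logscale


def ancestral_marginals(tree: Phylogeny, tip_states, model: Mk2Model,
                        root_distribution="stationary") -> np.ndarray:
    """Marginal posterior state probabilities at every node (re-rooting pass)."""
    states = _tip_state_array(tree, tip_states)
    root_p = _resolve_root(root_distribution, model)
    partial, logscale, P = _pruning_partials(tree, states, model)
    up = np.zeros((tree.n_nodes, 2))  # outside-subtree message, unnormalized
    up[tree.root] = root_p
    marg = np.zeros((tree.n_nodes, 2))
    for node in tree.postorder[::-1]:
        m = up[node] * partial[node]
        marg[node] = m / m.sum()
        for child in tree.children[node]:
            sib = up[node].copy()
            for other in tree.children[node]:
                if other != child:
                    sib *= P[other] @ partial[other]
            msg = sib @ P[child]
            s = msg.sum()
            up[child] = msg / s if s > 0 else msg
    return marg


# --------------------------------------------------------------------------
# Prior calibration (MCMC over overall rate and bias, then discretization)
# --------------------------------------------------------------------------

@dataclass
class PriorGrid:
    """Discretized gamma (rate) and beta (bias) priors.

    Each prior is split into ``k`` equal-probability categories represented
    by their bin medians (the discrete-gamma convention); category masses
    are uniform.  Defaults k=90 for the rate and k=31 for the bias.
    """

    gamma_shape: float
    gamma_scale: float
    beta_a: float
    beta_b: float
    k_rate: int = 90
    k_bias: int = 31
    rate_values: np.ndarray = field(init=False)
    bias_values: np.ndarray = field(init=False)
    ess: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        from scipy import stats

        q = (np.arange(self.k_rate) + 0.5) / self.k_rate
        self.rate_values = stats.gamma.ppf(q, a=self.gamma_shape,
                                           scale=self.gamma_scale)
        q = (np.arange(self.k_bias) + 0.5) / self.k_bias
        self.bias_values = stats.beta.ppf(q, a=self.beta_a, b=self.beta_b)
        # keep bias strictly inside (0, 1)
        self.bias_values = np.clip(self.bias_values, 1e-9, 1 - 1e-9)

    def draw(self, rng: np.random.Generator) -> Mk2Model:
        lam = self.rate_values[rng.integers(self.k_rate)]
        beta = self.bias_values[rng.integers(self.k_bias)]
        return Mk2Model.from_rate_bias(lam, beta)


def _ess(x: np.ndarray) -> float:
    """Effective sample size from the initial positive autocorrelation sum."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, min(n - 1, 1000)):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1 + 2 * s))


def calibrate_priors(trees, tip_states, generations: int = 500_000,
                     sample_every: int = 100, burnin: float = 0.5,
                     k_rate: int = 90, k_bias: int = 31, seed: int = 0,
                     root_distribution="stationary") -> PriorGrid:
    """Fit discretized priors on (overall rate, bias) by MCMC.

    The chain targets the posterior of ``(lam, beta)`` under the Mk2
    likelihood on the (first) tree rescaled to total length 1, with vague
    hyperpriors (Exponential(mean 10) on ``lam``, flat on ``beta``).
    Gamma/beta hyperparameters are then moment-matched to the posterior
    draws and discretized into equal-mass categories.
    """
    from scipy import stats

    tree = trees[0] if isinstance(trees, TreeSet) else trees
    tree = tree.rescaled(1.0)
    states = _tip_state_array(tree, tip_states)
    rng = np.random.default_rng(seed)

    def logpost(lam, beta):
        if lam <= 0 or not (0 < beta < 1):
            return -np.inf
        ll = mk2_loglik(tree, states, Mk2Model.from_rate_bias(lam, beta),
                        root_distribution)
        return ll + stats.expon.logpdf(lam, scale=10.0)

    lam, beta = 1.0, 0.5
    lp = logpost(lam, beta)
    keep_lam, keep_beta = [], []
    n_samples = generations // sample_every
    for g in range(generations):
        if g % 2 == 0:
            prop_lam = lam * np.exp(0.4 * rng.normal())
            prop_beta = beta
            hastings = np.log(prop_lam / lam)  # multiplier proposal
        else:
            prop_lam = lam
            prop_beta = beta + 0.15 * rng.normal()
            prop_beta = prop_beta % 2.0
            if prop_beta > 1.0:
                prop_beta = 2.0 - prop_beta  # reflect off the (0,1) edges
            hastings = 0.0
        lp_new = logpost(prop_lam, prop_beta)
        if np.log(rng.uniform()) < lp_new - lp + hastings:
            lam, beta, lp = prop_lam, prop_beta, lp_new
        if (g + 1) % sample_every == 0:
            keep_lam.append(lam)
            keep_beta.append(beta)
    cut = int(burnin * len(keep_lam))
    lam_s = np.array(keep_lam[cut:])
    beta_s = np.array(keep_beta[cut:])

    m, v = lam_s.mean(), max(lam_s.var(), 1e-12)
    gamma_shape, gamma_scale = m * m / v, v / m
    mb, vb = beta_s.mean(), beta_s.var()
    vb = min(max(vb, 1e-12), mb * (1 - mb) * 0.999)
    common = mb * (1 - mb) / vb - 1.0
    beta_a, beta_b = mb * common, (1 - mb) * common

    grid = PriorGrid(gamma_shape=gamma_shape, gamma_scale=gamma_scale,
                     beta_a=beta_a, beta_b=beta_b, k_rate=k_rate, k_bias=k_bias)
    grid.ess = {"rate": _ess(lam_s), "bias": _ess(beta_s)}
    if min(grid.ess.values()) < 100:
        warnings.warn(
            f"low effective sample size in prior calibration: {grid.ess}",
            stacklevel=2,
        )
    return grid


# --------------------------------------------------------------------------
# Stochastic mapping
# --------------------------------------------------------------------------

def _sample_path(rng: np.random.Generator, model: Mk2Model, t: float,
                 a: int, b: int) -> Segments:
    """Endpoint-conditioned path on one branch, by uniformization (exact)."""
    if t == 0:
        if a != b:
            raise ValueError("state change required on zero-length branch")
        return []
    mu = max(model.q01, model.q10)
    if mu == 0:
        if a != b:
            raise ValueError("endpoint change impossible under zero rates")
        return [(t, a)]
    Q = np.array([[-model.q01, model.q01], [model.q10, -model.q10]])
    R = np.eye(2) + Q / mu
    Pab = model.transition_matrix(t)[a, b]
    if Pab <= 0:
        raise ValueError("impossible endpoint pair under the given rates")
    # sample the number of uniformized jumps n | endpoints
    Rpow = [np.eye(2)]
    log_pois = -mu * t
    target = np.log(rng.uniform()) + np.log(Pab)
    acc = -np.inf
    n = -1
    while True:
        n += 1
        if n > 0:
            Rpow.append(Rpow[-1] @ R)
            log_pois += np.log(mu * t) - np.log(n)
        term = log_pois + np.log(Rpow[n][a, b]) if Rpow[n][a, b] > 0 else -np.inf
        acc = np.logaddexp(acc, term)
        if acc >= target or n > 100_000:
            break
    # jump chain states, forward-filtered toward the endpoint
    states = [a]
    for k in range(1, n):
        prev = states[-1]
        w = R[prev] * Rpow[n - k][:, b]
        states.append(int(rng.choice(2, p=w / w.sum())))
    if n > 0:
        states.append(b)
    times = np.sort(rng.uniform(0, t, size=n))
    # collapse virtual jumps into segments
    segs: Segments = []
    cur_state, cur_start = a, 0.0
    for k in range(n):
        if states[k + 1] != cur_state:
            segs.append((times[k] - cur_start, cur_state))
            cur_state, cur_start = states[k + 1], times[k]
    segs.append((t - cur_start, cur_state))
    return segs


def sample_history(tree: Phylogeny, tip_states, model=None, prior_grid=None,
                   n_maps: int = 10, seed: int = 0,
                   root_distribution="stationary") -> list[CharacterHistory]:
    """Draw stochastic character maps conditional on the tip states.

    For each map, rates are either fixed (``model``) or drawn from a
    calibrated :class:`PriorGrid`; joint node states are sampled from the
    pruning conditionals root-to-tip, and each branch is filled in with an
    endpoint-conditioned path.
    """
    if (model is None) == (prior_grid is None):
        raise ValueError("provide exactly one of model= or prior_grid=")
    states = _tip_state_array(tree, tip_states)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_maps):
        m = prior_grid.draw(rng) if prior_grid is not None else model
        root_p = _resolve_root(root_distribution, m)
        partial, logscale, P = _pruning_partials(tree, states, m)
        node_states = np.zeros(tree.n_nodes, dtype=int)
        w = root_p * partial[tree.root]
        if w.sum() <= 0:
            raise ValueError("data impossible under the supplied model")
        node_states[tree.root] = rng.choice(2, p=w / w.sum())
        for node in tree.postorder[::-1]:
            for child in tree.children[node]:
                Pc = P[child] if P[child] is not None else m.transition_matrix(
                    tree.edge_length[child])
                w = Pc[node_states[node]] * partial[child]
                node_states[child] = rng.choice(2, p=w / w.sum())
        segments: list[Segments] = [[] for _ in range(tree.n_nodes)]
        for node in range(tree.n_nodes):
            par = tree.parent[node]
            if par < 0:
                continue
            segments[node] = _sample_path(
                rng, m, float(tree.edge_length[node]),
                int(node_states[par]), int(node_states[node]))
        out.append(CharacterHistory(tree=tree, segments=segments,
                                    node_states=node_states))
    return out


def rescale_history(history: CharacterHistory, tree: Phylogeny
                    ) -> CharacterHistory:
    """Transfer a history onto the same topology with other branch lengths.

    Segment lengths on each edge are scaled proportionally (used to map on
    a unit-length tree — where the rate priors live — and carry the result
    back to the original operational-time tree).
    """
    if tree.n_nodes != history.tree.n_nodes:
        raise ValueError("trees differ in size")
    segments: list[Segments] = []
    for node in range(tree.n_nodes):
        old = history.segments[node]
        total = sum(l for l, _ in old)
        if not old or total == 0:
            segments.append([(float(tree.edge_length[node]), s)
                             for _, s in old[:1]] if old else [])
            continue
        f = float(tree.edge_length[node]) / total
        segments.append([(l * f, s) for l, s in old])
    return CharacterHistory(tree=tree, segments=segments,
                            node_states=history.node_states.copy())


def summarize_histories(histories: list[CharacterHistory]):
    """Gain/loss count distribution and a per-branch state-1 density map.

    Returns ``(counts, density)`` where ``counts`` is a DataFrame with one
    row per history (columns ``gains``, ``losses``) and ``density`` the
    per-edge time-weighted posterior probability of state 1.
    """
    if not histories:
        raise ValueError("no histories supplied")
    tree = histories[0].tree
    rows = [h.transition_counts() for h in histories]
    counts = pd.DataFrame(rows, columns=["gains", "losses"])
    dens = np.zeros(tree.n_nodes)
    lengths = tree.edge_length.copy()
    lengths[lengths == 0] = np.nan
    for h in histories:
        dens += np.nan_to_num(h.time_in_state(1) / lengths)
    dens /= len(histories)
    return counts, dens
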