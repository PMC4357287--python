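"""Multi-rate Brownian-motion inference on painted trees.

Branches (or branch segments) are painted with regime labels — here the
three nematode groups: non-diplogastrid Rhabditina (Rh), dimorphic
Diplogastridae (Dm) and secondarily monomorphic Diplogastridae (Mn).  Two
complementary approaches estimate how the Brownian rate sigma^2 of a
continuous trait (a PC1 score) varies across regimes:

* a maximum-likelihood "non-censored" rate test over five regime-to-rate
  models ("1,1,1" ... "1,2,3"), compared by AICc and likelihood-ratio
  tests, optionally averaged across many mapped character histories and
  trees;
* a reversible-jump MCMC over branch-specific rates with a bounded number
  of local clocks, from which group-level posterior rate distributions,
  HPD intervals and randomization-test p-values are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .charmap import CharacterHistory
from .trees import Phylogeny

LOG2PI = np.log(2 * np.pi)

RegimeSegments = list[tuple[float, str]]


@dataclass
class RegimePainting:
    """Per-branch (piecewise) regime labels on a tree.

    ``segments[i]`` paints the edge above node ``i`` rootward-to-tipward;
    every unit of branch length carries exactly one regime.
    """

    tree: Phylogeny
    segments: list[RegimeSegments]

    def regimes(self) -> list[str]:
        out: set[str] = set()
        for segs in self.segments:
            out.update(s for _, s in segs)
        return sorted(out)

    def regime_edge_lengths(self) -> dict[str, np.ndarray]:
        """Per-regime array of painted length on each edge."""
        out = {g: np.zeros(self.tree.n_nodes) for g in self.regimes()}
        for node, segs in enumerate(self.segments):
            for length, g in segs:
                out[g][node] += length
        return out

    def regime_total_lengths(self) -> dict[str, float]:
        return {g: float(v.sum()) for g, v in self.regime_edge_lengths().items()}

    def validate(self) -> None:
        for node in range(self.tree.n_nodes):
            if self.tree.parent[node] < 0:
                continue
            total = sum(l for l, _ in self.segments[node])
            if not np.isclose(total, self.tree.edge_length[node], atol=1e-9):
                raise ValueError(f"painting on edge {node} does not cover it")

    def regime_cov_matrices(self) -> dict[str, np.ndarray]:
        """Per-regime shared path-length matrices C_g.

        ``C_g[i, j]`` is the length painted with regime g on the shared
        root-to-MRCA path of tips i and j, so a multirate BM covariance is
        ``V = sum_g sigma2_g * C_g``.
        """
        tree = self.tree
        per_regime = self.regime_edge_lengths()
        M = tree.mrca_matrix()
        out = {}
        for g, lens in per_regime.items():
            depth = np.zeros(tree.n_nodes)
            for node in tree.postorder[::-1]:
                if tree.parent[node] >= 0:
                    depth[node] = depth[tree.parent[node]] + lens[node]
            out[g] = depth[M]
        return out


def paint_by_clades(tree: Phylogeny, tip_groups, background: str
                    ) -> RegimePainting:
    """Paint whole branches by tip group: an edge takes group g when all of
    its descendant tips belong to g, otherwise the background regime."""
    tip_groups = pd.Series(tip_groups)
    missing = [t for t in tree.tip_labels if t not in tip_groups.index]
    if missing:
        raise ValueError(f"tips absent from group table: {missing}")
    node_group: dict[int, str | None] = {}
    for node in tree.postorder:
        if not tree.children[node]:
            node_group[node] = str(tip_groups[tree.tip_labels[node]])
        else:
            kids = {node_group[c] for c in tree.children[node]}
            node_group[node] = kids.pop() if len(kids) == 1 else None
    segments: list[RegimeSegments] = []
    for node in range(tree.n_nodes):
        if tree.parent[node] < 0:
            segments.append([])
        else:
            g = node_group[node] or background
            segments.append([(float(tree.edge_length[node]), g)])
    return RegimePainting(tree=tree, segments=segments)


def paint_from_history(tree: Phylogeny, history: CharacterHistory, group_table,
                       ingroup: str = "Dip", outgroup_regime: str = "Rh",
                       state1_regime: str = "Dm", state0_regime: str = "Mn"
                       ) -> RegimePainting:
    """Convert a mapped dimorphism history into the three-regime painting.

    Branches outside the ingroup clade (tips labelled ``ingroup`` in
    ``group_table``) are painted ``Rh``.  Within the clade, segments in
    state 1 (dimorphism present) become ``Dm`` and state-0 segments become
    ``Mn`` (secondarily monomorphic), following the mapped history.
    """
    group_table = pd.Series(group_table)
    missing = [t for t in tree.tip_labels if t not in group_table.index]
    if missing:
        raise ValueError(f"tips absent from group table: {missing}")
    is_in: dict[int, bool] = {}
    for node in tree.postorder:
        if not tree.children[node]:
            is_in[node] = group_table[tree.tip_labels[node]] == ingroup
        else:
            is_in[node] = all(is_in[c] for c in tree.children[node])
    segments: list[RegimeSegments] = []
    for node in range(tree.n_nodes):
        if tree.parent[node] < 0:
            segments.append([])
        elif not is_in[node]:
            segments.append([(float(tree.edge_length[node]), outgroup_regime)])
        else:
            segs: RegimeSegments = []
            for length, state in history.segments[node]:
                g = state1_regime if state == 1 else state0_regime
                if segs and segs[-1][1] == g:
                    segs[-1] = (segs[-1][0] + length, g)
                else:
                    segs.append((length, g))
            segments.append(segs)
    return RegimePainting(tree=tree, segments=segments)


def _trait_array(tree: Phylogeny, trait) -> np.ndarray:
    if isinstance(trait, pd.Series):
        trait = trait.to_dict()
    if isinstance(trait, dict):
        missing = [t for t in tree.tip_labels if t not in trait]
        if missing:
            raise ValueError(f"missing trait values for: {missing}")
        return np.array([float(trait[t]) for t in tree.tip_labels])
    arr = np.asarray(trait, dtype=float)
    if arr.shape != (tree.n_tips,):
        raise ValueError("trait array length must equal tip count")
    return arr


def bm_loglik(tree: Phylogeny, trait, painting: RegimePainting,
              rates: dict[str, float]) -> tuple[float, float]:
    """Multirate BM log-likelihood with the root value profiled by GLS.

    ``V = sum_g rates[g] * C_g``; returns ``(lnL, GLS root)``.
    """
    x = _trait_array(tree, trait)
    if any(r < 0 for r in rates.values()):
        raise ValueError("rates must be non-negative")
    Cg = painting.regime_cov_matrices()
    missing = [g for g in Cg if g not in rates]
    if missing:
        raise ValueError(f"no rate supplied for regimes: {missing}")
    V = sum(rates[g] * Cg[g] for g in Cg)
    return _mvn_profile_loglik(V, x)


def _mvn_profile_loglik(V: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    n = len(x)
    try:
        cho = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular BM covariance matrix") from exc
    logdet = 2 * np.log(np.diag(cho)).sum()
    one = np.ones(n)
    Vi_x = np.linalg.solve(V, x)
    Vi_1 = np.linalg.solve(V, one)
    root = float(one @ Vi_x / (one @ Vi_1))
    r = x - root
    quad = float(r @ np.linalg.solve(V, r))
    return -0.5 * (n * LOG2PI + logdet + quad), root


def _make_peeler(tree: Phylogeny):
    """Closure computing the profiled BM log-likelihood in O(n) scalar ops."""
    from math import log

    TWO_PI = 2.0 * np.pi
    order = [(int(n), tuple(int(c) for c in tree.children[n]))
             for n in tree.postorder if tree.children[n]]
    n_tips, n_nodes, root = tree.n_tips, tree.n_nodes, tree.root

    def peel(x: list[float], ev: list[float]) -> tuple[float, float]:
        mean = [0.0] * n_nodes
        var = [0.0] * n_nodes
        mean[:n_tips] = x
        lnK = 0.0
        for node, kids in order:
            sw = swm = acc = 0.0
            for c in kids:
                d = var[c] + ev[c]
                if d < 1e-300:
                    d = 1e-300
                w = 1.0 / d
                m = mean[c]
                sw += w
                swm += w * m
                acc += log(TWO_PI * d) + m * m * w
            v = 1.0 / sw
            mu = swm * v
            lnK += -0.5 * (acc - log(TWO_PI * v) - mu * mu * sw)
            mean[node] = mu
            var[node] = v
        return lnK - 0.5 * log(TWO_PI * var[root]), mean[root]

    return peel


def bm_loglik_peel(tree: Phylogeny, trait, edge_variance) -> tuple[float, float]:
    """Profiled BM log-likelihood by post-order peeling, O(n).

    ``edge_variance[i]`` is the trait variance accumulated along the edge
    above node ``i`` (rate x length, summed over painted segments).
    Matches :func:`bm_loglik` to numerical precision; used inside MCMC.
    """
    x = _trait_array(tree, trait)
    ev = np.asarray(edge_variance, dtype=float)
    if ev.shape != (tree.n_nodes,):
        raise ValueError("edge_variance must have one entry per node")
    lnL, root = _make_peeler(tree)(x.tolist(), ev.tolist())
    return float(lnL), float(root)


# --------------------------------------------------------------------------
# ML non-censored rate test
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BMModelSpec:
    """Maps regime labels to shared rate-parameter indices (1-based)."""

    name: str
    assignment: tuple[tuple[str, int], ...]

    @classmethod
    def from_mapping(cls, name: str, mapping: dict[str, int]) -> "BMModelSpec":
        idx = sorted(set(mapping.values()))
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("parameter indices must be contiguous from 1")
        return cls(name=name, assignment=tuple(sorted(mapping.items())))

    @property
    def mapping(self) -> dict[str, int]:
        return dict(self.assignment)

    @property
    def n_params(self) -> int:
        return len({i for _, i in self.assignment})

    def partition(self) -> frozenset[frozenset[str]]:
        groups: dict[int, set[str]] = {}
        for g, i in self.assignment:
            groups.setdefault(i, set()).add(g)
        return frozenset(frozenset(v) for v in groups.values())

    def nests_within(self, other: "BMModelSpec") -> bool:
        """True when this model's regime partition coarsens ``other``'s."""
        coarse, fine = self.partition(), other.partition()
        if len(coarse) >= len(fine):
            return False
        return all(any(f <= c for c in coarse) for f in fine)


def standard_models(regimes: tuple[str, str, str] = ("Rh", "Dm", "Mn")
                    ) -> list[BMModelSpec]:
    """The five regime-to-rate models of the three-group rate test."""
    a, b, c = regimes
    defs = {
        "1,1,1": {a: 1, b: 1, c: 1},
        "1,2,2": {a: 1, b: 2, c: 2},
        "1,2,1": {a: 1, b: 2, c: 1},
        "1,1,2": {a: 1, b: 1, c: 2},
        "1,2,3": {a: 1, b: 2, c: 3},
    }
    return [BMModelSpec.from_mapping(n, m) for n, m in defs.items()]


@dataclass
class BMFit:
    model: BMModelSpec
    rates: dict[int, float]            # parameter index -> sigma^2
    regime_rates: dict[str, float]     # regime label -> sigma^2
    root: float
    loglik: float
    K: int                             # free parameters incl. the root
    n: int
    aicc: float


def aicc(loglik: float, K: int, n: int) -> float:
    if n - K - 1 <= 0:
        raise ValueError("AICc undefined: n - K - 1 <= 0")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def fit_multirate(tree: Phylogeny, trait, painting: RegimePainting,
                  spec: BMModelSpec, n_starts: int = 3) -> BMFit:
    """ML fit of one regime-to-rate model (rates optimized in log space)."""
    x = _trait_array(tree, trait)
    Cg = painting.regime_cov_matrices()
    mapping = spec.mapping
    present = [g for g in Cg]
    missing = [g for g in present if g not in mapping]
    if missing:
        raise ValueError(f"model {spec.name} has no parameter for: {missing}")
    indices = sorted({mapping[g] for g in present})
    # collapse the per-regime matrices onto parameter indices
    Cp = {i: sum(Cg[g] for g in present if mapping[g] == i) for i in indices}

    def negloglik(logrates: np.ndarray) -> float:
        V = sum(np.exp(lr) * Cp[i] for lr, i in zip(logrates, indices))
        try:
            ll, _ = _mvn_profile_loglik(V, x)
        except ValueError:
            return 1e10
        return -ll

    # single-rate analytic estimate seeds the starts
    Ctot = sum(Cp.values())
    _, root0 = _mvn_profile_loglik(Ctot, x)
    sig0 = float((x - root0) @ np.linalg.solve(Ctot, x - root0)) / len(x)
    sig0 = max(sig0, 1e-12)
    rng = np.random.default_rng(len(x) + spec.n_params)
    best = None
    for s in range(n_starts):
        start = np.full(len(indices), np.log(sig0))
        if s > 0:
            start += rng.normal(scale=1.0, size=len(indices))
        res = optimize.minimize(
            negloglik, start, method="L-BFGS-B",
            bounds=[(np.log(1e-10), np.log(1e10))] * len(indices))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"optimization failed for model {spec.name}: {best}")
    rates = {i: float(np.exp(lr)) for i, lr in zip(indices, best.x)}
    V = sum(rates[i] * Cp[i] for i in indices)
    ll, root = _mvn_profile_loglik(V, x)
    K = len(indices) + 1
    return BMFit(model=spec, rates=rates,
                 regime_rates={g: rates[mapping[g]] for g in present},
                 root=root, loglik=ll, K=K, n=len(x),
                 aicc=aicc(ll, K, len(x)))


def compare_models(fits: list[BMFit], delta_threshold: float = 4.0
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Model table with delta-AICc plus LRTs for nested pairs.

    Returns ``(table, lrt)``: the first ranks models by AICc and flags
    those with delta-AICc above the threshold as much less supported; the
    second holds the chi-square likelihood-ratio tests for nested pairs.
    """
    if len({f.n for f in fits}) != 1:
        raise ValueError("fits were not computed on identical data")
    table = pd.DataFrame({
        "model": [f.model.name for f in fits],
        "loglik": [f.loglik for f in fits],
        "K": [f.K for f in fits],
        "AICc": [f.aicc for f in fits],
    })
    table["dAICc"] = table["AICc"] - table["AICc"].min()
    table["much_less_supported"] = table["dAICc"] > delta_threshold
    table = table.sort_values("AICc").reset_index(drop=True)

    rows = []
    for i, fa in enumerate(fits):
        for fb in fits:
            if fa.model.nests_within(fb.model):
                stat = 2.0 * (fb.loglik - fa.loglik)
                if stat < -1e-6:
                    raise RuntimeError(
                        f"nested model {fb.model.name} fits worse than "
                        f"{fa.model.name}: optimization pathology")
                df = fb.K - fa.K
                rows.append({
                    "null": fa.model.name, "alternative": fb.model.name,
                    "stat": max(stat, 0.0), "df": df,
                    "p": float(stats.chi2.sf(max(stat, 0.0), df)),
                })
    return table, pd.DataFrame(rows)


def model_average(fits_per_recon: list[list[BMFit]] | list[BMFit],
                  scheme: str = "akaike") -> pd.DataFrame:
    """Mean and SD of per-regime rates across reconstructions.

    Each reconstruction (one mapped history on one tree) contributes one
    per-regime rate: under ``scheme='akaike'`` the Akaike-weighted average
    over its candidate models, under ``'best'`` the minimum-AICc model's
    rate.  A plain list of fits is treated as one model per reconstruction.
    """
    if fits_per_recon and isinstance(fits_per_recon[0], BMFit):
        fits_per_recon = [[f] for f in fits_per_recon]
    if scheme not in ("akaike", "best"):
        raise ValueError("scheme must be 'akaike' or 'best'")
    per_group: dict[str, list[float]] = {}
    for fits in fits_per_recon:
        a = np.array([f.aicc for f in fits])
        if scheme == "best" or len(fits) == 1:
            w = np.zeros(len(fits))
            w[int(np.argmin(a))] = 1.0
        else:
            w = np.exp(-0.5 * (a - a.min()))
            w /= w.sum()
        regimes = fits[0].regime_rates.keys()
        for g in regimes:
            val = float(sum(wi * f.regime_rates[g] for wi, f in zip(w, fits)))
            per_group.setdefault(g, []).append(val)
    return pd.DataFrame({
        "mean_rate": {g: float(np.mean(v)) for g, v in per_group.items()},
        "sd_rate": {g: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
                    for g, v in per_group.items()},
        "n_reconstructions": {g: len(v) for g, v in per_group.items()},
    })


# --------------------------------------------------------------------------
# Reversible-jump MCMC over branch rates (local clocks)
# --------------------------------------------------------------------------

@dataclass
class BranchRateTrace:
    """Posterior samples of per-branch rates from the rjMCMC sampler.

    ``rates[s, i]`` is the rate on the edge above node ``i`` at sample s
    (root column included but unused).  ``n_clocks`` counts distinct local
    clocks per sample; acceptance statistics are per move type.
    """

    tree: Phylogeny
    rates: np.ndarray
    n_clocks: np.ndarray
    acceptance: dict[str, float]

    def mean_edge_rates(self) -> np.ndarray:
        return self.rates.mean(axis=0)


def _edge_clock_assignment(tree: Phylogeny, shifts: dict[int, float],
                           root_lograte: float) -> np.ndarray:
    """Per-edge log-rate under the nearest-ancestor-shift rule."""
    logr = np.zeros(tree.n_nodes)
    for node in tree.postorder[::-1]:
        par = tree.parent[node]
        if node in shifts:
            logr[node] = shifts[node]
        elif par < 0:
            logr[node] = root_lograte
        else:
            logr[node] = logr[par]
    return logr


def mcmc_branch_rates(tree: Phylogeny, trait, generations: int,
                      max_clocks: int = 3, proposal_width: float = 1.5,
                      sample_every: int = 5000, burnin: float = 0.25,
                      seed: int = 0, n_chains: int = 3,
                      rate_prior_sd: float = 2.0,
                      clock_prior: str = "poisson") -> BranchRateTrace:
    """Relaxed-BM sampling of branch rates with at most ``max_clocks`` clocks.

    The model places rate shifts on edges: every edge inherits the clock of
    its nearest ancestral shift (the root clock by default).  Moves are
    clock-rate scaling (uniform kernel of width ``proposal_width`` on the
    log rate), shift relocation, and birth/death of a shift (reversible
    jump, locally-centred birth).  The prior is truncated Poisson(ln 2) on
    the number of shifts (``clock_prior="uniform"`` for a flat alternative),
    uniform over shift placements, and log-normal(0, ``rate_prior_sd``) on
    each clock rate; the Poisson default penalizes unidentifiable extra
    clocks so single-rate data concentrates on one clock.  Chains run
    independently and are pooled after burn-in.
    """
    from math import log, sqrt, pi

    x = _trait_array(tree, trait)
    if np.var(x) == 0:
        raise ValueError("trait is constant: rate likelihood is degenerate")
    if generations < sample_every:
        raise ValueError("generations must be >= sample_every")
    lengths = tree.edge_length.tolist()
    non_root = [i for i in range(tree.n_nodes) if tree.parent[i] >= 0]
    preorder = [int(n) for n in tree.postorder[::-1]]
    parent = tree.parent.tolist()
    peel = _make_peeler(tree)
    xs = x.tolist()
    n_nodes = tree.n_nodes
    prior_const = -0.5 * log(2 * pi) - log(rate_prior_sd)
    inv2var = 0.5 / rate_prior_sd ** 2
    birth_sd = 1.0  # SD of the local-rate-centred birth proposal

    def assign(sh: dict[int, float], r0: float) -> list[float]:
        logr = [0.0] * n_nodes
        for node in preorder:
            if node in sh:
                logr[node] = sh[node]
            elif parent[node] < 0:
                logr[node] = r0
            else:
                logr[node] = logr[parent[node]]
        return logr

    def loglik(sh, r0):
        logr = assign(sh, r0)
        ev = [np.exp(v) * l for v, l in zip(logr, lengths)]
        return peel(xs, ev)[0], logr

    from math import lgamma

    def log_choose(n, k):
        return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)

    if clock_prior == "poisson":
        lam_shift = np.log(2.0)
        shift_logp = [s * np.log(lam_shift) - lgamma(s + 1)
                      for s in range(max_clocks)]
    elif clock_prior == "uniform":
        shift_logp = [0.0] * max_clocks
    else:
        raise ValueError("clock_prior must be 'poisson' or 'uniform'")

    def logprior(sh, r0):
        # prior on the shift count, uniform over placements given the
        # count, log-normal(0, sd) on each clock's rate
        out = prior_const - inv2var * r0 * r0
        for v in sh.values():
            out += prior_const - inv2var * v * v
        return (out + shift_logp[len(sh)]
                - log_choose(len(non_root), len(sh)))

    def norm_logpdf(v, mean, sd):
        return -0.5 * log(2 * pi) - log(sd) - 0.5 * ((v - mean) / sd) ** 2

    all_samples = []
    all_k = []
    attempts = {"rate": 0, "shift": 0, "jump": 0}
    accepts = {"rate": 0, "shift": 0, "jump": 0}
    for chain in range(n_chains):
        rng = np.random.default_rng((seed + 1) * 7919 + chain)
        shifts: dict[int, float] = {}
        root_lograte = float(np.log(max(np.var(x), 1e-8)))
        ll, cur_logr = loglik(shifts, root_lograte)
        lp = logprior(shifts, root_lograte)
        keep = []
        kk = []
        for g in range(generations):
            u = rng.uniform()
            if u < 0.6:
                move = "rate"
                which = rng.integers(len(shifts) + 1)
                new_shifts, new_r0 = dict(shifts), root_lograte
                delta = proposal_width * (rng.uniform() - 0.5)
                if which == len(shifts):
                    new_r0 += delta
                else:
                    key = list(shifts)[which]
                    new_shifts[key] += delta
                log_hastings = 0.0
            elif u < 0.8:
                # state-independent move probabilities keep the reversible
                # jump balanced; with no shifts this slot updates the root
                if shifts:
                    move = "shift"
                    key = list(shifts)[rng.integers(len(shifts))]
                    candidates = [e for e in non_root if e not in shifts]
                    new_edge = candidates[rng.integers(len(candidates))]
                    new_shifts = dict(shifts)
                    new_shifts[new_edge] = new_shifts.pop(key)
                    new_r0 = root_lograte
                else:
                    move = "rate"
                    new_shifts = dict(shifts)
                    new_r0 = root_lograte + proposal_width * (rng.uniform() - 0.5)
                log_hastings = 0.0
            else:
                move = "jump"
                k = len(shifts) + 1
                can_birth = k < max_clocks
                can_death = k > 1
                if can_birth and (not can_death or rng.uniform() < 0.5):
                    # birth: propose the new clock's rate around the rate
                    # currently painting the chosen edge
                    free = [e for e in non_root if e not in shifts]
                    new_edge = free[rng.integers(len(free))]
                    center = cur_logr[new_edge]
                    val = center + birth_sd * rng.normal()
                    new_shifts = dict(shifts)
                    new_shifts[new_edge] = val
                    new_r0 = root_lograte
                    p_b = 0.5 if can_death else 1.0
                    p_d_rev = 0.5 if (k + 1) < max_clocks else 1.0
                    log_hastings = (log(p_d_rev) - log(p_b)
                                    + log(len(free)) - log(len(new_shifts))
                                    - norm_logpdf(val, center, birth_sd))
                elif can_death:
                    key = list(shifts)[rng.integers(len(shifts))]
                    new_shifts = dict(shifts)
                    dropped = new_shifts.pop(key)
                    new_r0 = root_lograte
                    # reverse birth would re-propose around the rate the
                    # edge inherits once the shift is gone
                    center = assign(new_shifts, new_r0)[key]
                    p_d = 0.5 if can_birth else 1.0
                    p_b_rev = 0.5 if len(new_shifts) + 1 > 1 else 1.0
                    free_rev = len(non_root) - len(new_shifts)
                    log_hastings = (log(p_b_rev) - log(p_d)
                                    + log(len(shifts)) - log(free_rev)
                                    + norm_logpdf(dropped, center, birth_sd))
                else:
                    new_shifts, new_r0, log_hastings = dict(shifts), root_lograte, 0.0
            attempts[move] += 1
            new_ll, new_logr = loglik(new_shifts, new_r0)
            new_lp = logprior(new_shifts, new_r0)
            if log(rng.uniform()) < (new_ll + new_lp) - (ll + lp) + log_hastings:
                shifts, root_lograte, ll, lp = new_shifts, new_r0, new_ll, new_lp
                cur_logr = new_logr
                accepts[move] += 1
            if (g + 1) % sample_every == 0:
                keep.append(np.exp(cur_logr))
                kk.append(len(shifts) + 1)
        cut = int(burnin * len(keep))
        all_samples.extend(keep[cut:])
        all_k.extend(kk[cut:])
    acc = {m: (accepts[m] / attempts[m] if attempts[m] else np.nan)
           for m in attempts}
    return BranchRateTrace(tree=tree, rates=np.array(all_samples),
                           n_clocks=np.array(all_k), acceptance=acc)


def hpd_interval(samples: np.ndarray, prob: float = 0.95
                 ) -> tuple[float, float]:
    """Shortest interval containing ``prob`` posterior mass."""
    s = np.sort(np.asarray(samples, dtype=float))
    n = len(s)
    m = max(1, int(np.ceil(prob * n)))  # samples inside the interval
    if m >= n:
        return float(s[0]), float(s[-1])
    widths = s[m - 1:] - s[: n - m + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m - 1])


def group_rate_test(trace: BranchRateTrace, edge_groups, n_perm: int = 10_000,
                    seed: int = 0, prob: float = 0.95):
    """Group-level posterior rates and randomization-test comparisons.

    Edges are weighted by branch length.  Returns ``(summary, pairwise)``:
    posterior mean and HPD of the weighted mean rate per group, and
    two-tailed p-values from permuting edge-to-group labels.
    """
    tree = trace.tree
    edge_groups = np.asarray(edge_groups, dtype=object)
    if edge_groups.shape != (tree.n_nodes,):
        raise ValueError("edge_groups must label every node's parent edge")
    lengths = tree.edge_length
    valid = (lengths > 0) & np.array([g is not None for g in edge_groups])
    labels = sorted({str(g) for g in edge_groups[valid]})
    if not labels:
        raise ValueError("no branch carries a group label")
    idx = {g: np.flatnonzero(valid & (edge_groups.astype(str) == g))
           for g in labels}
    for g, ii in idx.items():
        if len(ii) == 0:
            raise ValueError(f"group {g} has no branches")
    summary = {}
    for g, ii in idx.items():
        w = lengths[ii] / lengths[ii].sum()
        per_sample = trace.rates[:, ii] @ w
        lo, hi = hpd_interval(per_sample, prob)
        summary[g] = {"mean": float(per_sample.mean()),
                      "hpd_low": lo, "hpd_high": hi,
                      "n_branches": int(len(ii))}
    mean_rates = trace.mean_edge_rates()
    rng = np.random.default_rng(seed)
    rows = []
    for a_i in range(len(labels)):
        for b_i in range(a_i + 1, len(labels)):
            ga, gb = labels[a_i], labels[b_i]
            ii = np.concatenate([idx[ga], idx[gb]])
            na = len(idx[ga])
            r, w = mean_rates[ii], lengths[ii]

            def wmean(rr, ww):
                return float((rr * ww).sum() / ww.sum())

            obs = wmean(r[:na], w[:na]) - wmean(r[na:], w[na:])
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(len(ii))
                d = (wmean(r[perm[:na]], w[perm[:na]])
                     - wmean(r[perm[na:]], w[perm[na:]]))
                if abs(d) >= abs(obs) - 1e-15:
                    count += 1
            rows.append({"group_a": ga, "group_b": gb,
                         "observed_diff": obs,
                         "p": (count + 1) / (n_perm + 1)})
    return pd.DataFrame(summary).T, pd.DataFrame(rows)
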