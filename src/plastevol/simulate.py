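"""Synthetic data with the statistical structure the analysis assumes.

Every input the pipeline consumes can be generated here: a birth-death
tree, a binary character evolving under a two-state Markov chain with its
full transition history, a continuous trait under group-specific Brownian
rates, landmark configurations with group-level deformation and specimen
noise, correlated binary/ordinal traits under the threshold model, and
replicate induction-count tables.  :func:`reference_dataset` assembles a
"study-shaped" dataset: 90 tips in three groups (outgroup Rhabditina,
dimorphic and secondarily monomorphic Diplogastridae), a dimorphism gained
once and lost ten times, faster trait evolution inside the radiation, and
inflated morphological scatter in the secondarily monomorphic group.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .charmap import CharacterHistory, Segments
from .morphometrics import LandmarkConfig
from .trees import Phylogeny
from .bmrates import RegimePainting, paint_from_history


def _rng_for(seed: int, stream: str) -> np.random.Generator:
    """Named sub-stream so one stage's draws do not disturb another's."""
    streams = {"tree": 0, "mk2": 1, "bm": 2, "landmarks": 3, "threshold": 4,
               "induction": 5, "structures": 6, "general": 7}
    return np.random.default_rng([int(seed), streams[stream]])


# --------------------------------------------------------------------------
# Trees
# --------------------------------------------------------------------------

def simulate_tree(n_tips: int, birth: float = 1.0, death: float = 0.0,
                  seed: int = 0, labels: list[str] | None = None,
                  rng: np.random.Generator | None = None) -> Phylogeny:
    """Forward birth-death simulation conditioned on ``n_tips`` extant tips.

    The process starts from a root split and runs until the standing
    diversity first reaches ``n_tips``, plus one exponential holding time;
    extinct lineages are pruned.  Restarted on total extinction.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth <= death or birth <= 0:
        raise ValueError("need birth > death >= 0 for a terminating simulation")
    if death < 0:
        raise ValueError("death rate must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(seed)
    while True:  # restart on extinction
        # node records: [parent, t_start, t_end, children]
        nodes = [[-1, 0.0, None, []]]
        for _ in range(2):
            nodes.append([0, 0.0, None, []])
            nodes[0][3].append(len(nodes) - 1)
        active = [1, 2]
        t = 0.0
        died = False
        while len(active) < n_tips:
            total = len(active) * (birth + death)
            t += rng.exponential(1.0 / total)
            k = active[rng.integers(len(active))]
            if rng.uniform() < birth / (birth + death):
                nodes[k][2] = t
                for _ in range(2):
                    nodes.append([k, t, None, []])
                    nodes[k][3].append(len(nodes) - 1)
                active.remove(k)
                active.extend([len(nodes) - 2, len(nodes) - 1])
            else:
                nodes[k][2] = t
                active.remove(k)
                if not active:
                    died = True
                    break
        if died:
            continue
        t += rng.exponential(1.0 / (len(active) * (birth + death)))
        for k in active:
            nodes[k][2] = t
        return _nodes_to_phylogeny(nodes, set(active), labels)


def _nodes_to_phylogeny(nodes, extant: set[int],
                        labels: list[str] | None) -> Phylogeny:
    """Prune extinct lineages / unifurcations and emit a Phylogeny."""
    keep = {}

    def prune(i):
        """Return (subtree-node or None, extra pendant length)."""
        node = nodes[i]
        if not node[3]:
            if i not in extant:
                return None, 0.0
            return ("tip", i, []), 0.0
        kids = []
        for c in node[3]:
            sub = prune(c)
            if sub[0] is not None:
                length = nodes[c][2] - nodes[c][1] + sub[1]
                kids.append((sub[0], length))
        if not kids:
            return None, 0.0
        if len(kids) == 1:
            return kids[0][0], kids[0][1]
        return ("internal", i, kids), 0.0

    rooted, extra = prune(0)
    if rooted is None or rooted[0] == "tip":
        raise RuntimeError("simulation produced no internal structure")
    # count tips, assign indices: tips first, internals after, root last
    tip_records, internal_records = [], []

    def collect(rec):
        if rec[0] == "tip":
            tip_records.append(rec)
        else:
            internal_records.append(rec)
            for child, _ in rec[2]:
                collect(child)

    collect(rooted)
    n_tips = len(tip_records)
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise ValueError("label count does not match tip count")
    index = {}
    for j, rec in enumerate(tip_records):
        index[id(rec)] = j
    order = list(reversed(internal_records))  # children before parents later
    for j, rec in enumerate(order):
        index[id(rec)] = n_tips + j
    n_nodes = n_tips + len(order)
    parent = np.full(n_nodes, -1, dtype=int)
    lengths = np.zeros(n_nodes)
    children: list[list[int]] = [[] for _ in range(n_nodes)]

    def wire(rec):
        i = index[id(rec)]
        for child, length in rec[2]:
            j = index[id(child)]
            parent[j] = i
            lengths[j] = length
            children[i].append(j)
            if child[0] == "internal":
                wire(child)

    wire(rooted)
    return Phylogeny(parent=parent, edge_length=lengths, children=children,
                     tip_labels=list(labels))


def join_trees(left: Phylogeny, right: Phylogeny, stem_left: float,
               stem_right: float) -> Phylogeny:
    """Join two trees under a new root with the given stem lengths."""
    nL, nR = left.n_tips, right.n_tips
    iL, iR = left.n_nodes - nL, right.n_nodes - nR
    n_nodes = left.n_nodes + right.n_nodes + 1
    root = n_nodes - 1

    def remap_left(i):
        return i if i < nL else nL + nR + (i - nL)

    def remap_right(i):
        return nL + i if i < nR else nL + nR + iL + (i - nR)

    parent = np.full(n_nodes, -1, dtype=int)
    lengths = np.zeros(n_nodes)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for src, remap, stem in ((left, remap_left, stem_left),
                             (right, remap_right, stem_right)):
        for i in range(src.n_nodes):
            j = remap(i)
            if src.parent[i] >= 0:
                parent[j] = remap(src.parent[i])
                lengths[j] = src.edge_length[i]
                children[parent[j]].append(j)
            else:
                parent[j] = root
                lengths[j] = stem
                children[root].append(j)
    return Phylogeny(parent=parent, edge_length=lengths, children=children,
                     tip_labels=list(left.tip_labels) + list(right.tip_labels))


# --------------------------------------------------------------------------
# Discrete character
# --------------------------------------------------------------------------

def _simulate_segments(rng, q01, q10, t, start):
    segs: Segments = []
    state, remaining = start, t
    while True:
        rate = q01 if state == 0 else q10
        wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        if wait >= remaining:
            segs.append((remaining, state))
            return segs, state
        segs.append((wait, state))
        state = 1 - state
        remaining -= wait


def simulate_mk2(tree: Phylogeny, q01: float, q10: float, root_state: int = 0,
                 seed: int = 0, rng: np.random.Generator | None = None
                 ) -> tuple[pd.Series, CharacterHistory]:
    """Simulate a two-state character with its full branch-wise history."""
    if q01 < 0 or q10 < 0:
        raise ValueError("rates must be non-negative")
    rng = rng if rng is not None else _rng_for(seed, "mk2")
    node_states = np.zeros(tree.n_nodes, dtype=int)
    node_states[tree.root] = root_state
    segments: list[Segments] = [[] for _ in range(tree.n_nodes)]
    for node in tree.postorder[::-1]:
        for child in tree.children[node]:
            segs, end = _simulate_segments(
                rng, q01, q10, float(tree.edge_length[child]),
                int(node_states[node]))
            segments[child] = segs
            node_states[child] = end
    history = CharacterHistory(tree=tree, segments=segments,
                               node_states=node_states)
    return history.tip_states(), history


# --------------------------------------------------------------------------
# Continuous trait under regime-specific BM
# --------------------------------------------------------------------------

def simulate_bm_regimes(tree: Phylogeny, painting, regime_rates: dict,
                        root_value: float = 0.0, seed: int = 0,
                        rng: np.random.Generator | None = None) -> pd.Series:
    """Brownian trait with per-regime rates along a painted tree.

    ``painting`` may be a :class:`RegimePainting` (string regimes) or a
    :class:`CharacterHistory` (integer states as regimes).  Each branch
    segment contributes a Normal(0, rate x length) increment.
    """
    rng = rng if rng is not None else _rng_for(seed, "bm")
    if isinstance(painting, CharacterHistory):
        segments = painting.segments
    elif isinstance(painting, RegimePainting):
        segments = painting.segments
    else:
        segments = painting
    values = np.zeros(tree.n_nodes)
    values[tree.root] = root_value
    for node in tree.postorder[::-1]:
        for child in tree.children[node]:
            var = 0.0
            for length, regime in segments[child]:
                if regime not in regime_rates:
                    raise ValueError(f"no rate for regime {regime!r} "
                                     f"(edge above node {child})")
                if regime_rates[regime] < 0:
                    raise ValueError("rates must be non-negative")
                var += regime_rates[regime] * length
            values[child] = values[node] + rng.normal(scale=np.sqrt(var)) \
                if var > 0 else values[node]
    return pd.Series(values[: tree.n_tips], index=tree.tip_labels,
                     name="trait")


# --------------------------------------------------------------------------
# Landmarks
# --------------------------------------------------------------------------

# An idealized lateral stoma outline: ventral wall up landmarks 1-5,
# dorsal wall down 6-11 (type-1 boundaries and type-2 apices).
DEFAULT_TEMPLATE = np.array([
    [0.00, 0.00], [0.08, 0.30], [0.12, 0.52], [0.15, 0.70], [0.35, 0.92],
    [0.60, 1.00], [0.72, 0.80], [0.85, 0.70], [0.88, 0.52], [0.92, 0.30],
    [1.00, 0.00],
])


def simulate_landmarks(units: pd.DataFrame,
                       template: np.ndarray = DEFAULT_TEMPLATE,
                       group_deformations: dict | None = None,
                       n_specimens: int = 5, noise_sd: float = 0.02,
                       species_scatter_sd=0.04,
                       size_lognormal=(0.0, 0.2),
                       seed: int = 0,
                       rng: np.random.Generator | None = None
                       ) -> list[LandmarkConfig]:
    """Landmark configurations for species/morph units.

    ``units`` needs columns ``species``, ``morph`` (St/Eu/monomorphic) and
    ``group``.  A unit's mean shape is the template plus its group's
    deformation plus a per-unit landmark scatter (SD per group via a dict,
    or one value); each specimen is that mean under a log-normal size, a
    random rotation/translation, and isotropic landmark noise.
    """
    template = np.asarray(template, dtype=float)
    if template.shape[0] < 3 or np.allclose(template, template[0]):
        raise ValueError("degenerate landmark template")
    rng = rng if rng is not None else _rng_for(seed, "landmarks")
    group_deformations = group_deformations or {}
    configs: list[LandmarkConfig] = []
    for _, row in pd.DataFrame(units).iterrows():
        group = row["group"]
        scatter = (species_scatter_sd.get(group, 0.04)
                   if isinstance(species_scatter_sd, dict)
                   else float(species_scatter_sd))
        mu, sg = (size_lognormal.get(group, (0.0, 0.2))
                  if isinstance(size_lognormal, dict) else size_lognormal)
        deform = group_deformations.get(group, np.zeros_like(template))
        mean_shape = template + deform + rng.normal(scale=scatter,
                                                    size=template.shape)
        for j in range(n_specimens):
            size = rng.lognormal(mean=mu, sigma=sg)
            angle = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(angle), -np.sin(angle)],
                            [np.sin(angle), np.cos(angle)]])
            coords = (mean_shape @ rot.T) * size
            coords = coords + rng.uniform(-1, 1, size=2)
            coords = coords + rng.normal(scale=noise_sd * size,
                                         size=template.shape)
            morph = row["morph"]
            spec_id = f"{row['species']}__{morph}__{j + 1}"
            configs.append(LandmarkConfig(
                specimen_id=spec_id, coords=coords, species=row["species"],
                morph=morph))
    return configs


# --------------------------------------------------------------------------
# Correlated binary / ordinal traits (threshold model)
# --------------------------------------------------------------------------

def simulate_threshold_pair(tree: Phylogeny, rho: float,
                            liability_rates=(1.0, 1.0),
                            binary_threshold: float = 0.0,
                            ordinal_cuts=None, seed: int = 0,
                            rng: np.random.Generator | None = None):
    """Binary + ordinal (0-9) traits from correlated BM liabilities.

    Two liabilities evolve under bivariate BM with instantaneous
    correlation ``rho``; the binary trait indicates liability 1 above the
    threshold and the ordinal trait bins liability 2 by ``ordinal_cuts``
    (nine cuts by default, spanning the expected liability spread, giving
    an index from 0 to 9).  Returns ``(binary, ordinal, liabilities)``.
    """
    if not (-1.0 <= rho <= 1.0):
        raise ValueError("|rho| must be <= 1")
    s1, s2 = liability_rates
    if s1 < 0 or s2 < 0:
        raise ValueError("liability rates must be non-negative")
    rng = rng if rng is not None else _rng_for(seed, "threshold")
    cov_unit = np.array([[s1, rho * np.sqrt(s1 * s2)],
                         [rho * np.sqrt(s1 * s2), s2]])
    values = np.zeros((tree.n_nodes, 2))
    chol = np.linalg.cholesky(cov_unit + 1e-12 * np.eye(2))
    for node in tree.postorder[::-1]:
        for child in tree.children[node]:
            t = float(tree.edge_length[child])
            inc = chol @ rng.normal(size=2) * np.sqrt(t)
            values[child] = values[node] + inc
    liab = values[: tree.n_tips]
    if ordinal_cuts is None:
        sd = np.sqrt(max(np.mean(tree.node_depths()[: tree.n_tips]) * s2,
                         1e-12))
        from scipy import stats as _st
        ordinal_cuts = sd * _st.norm.ppf(np.linspace(0.1, 0.9, 9))
    cuts = np.asarray(ordinal_cuts, dtype=float)
    if np.any(np.diff(cuts) <= 0):
        raise ValueError("ordinal cuts must be strictly increasing")
    binary = pd.Series((liab[:, 0] > binary_threshold).astype(int),
                       index=tree.tip_labels, name="binary")
    ordinal = pd.Series(np.searchsorted(cuts, liab[:, 1]),
                        index=tree.tip_labels, name="ordinal")
    liabilities = pd.DataFrame(liab, index=tree.tip_labels,
                               columns=["liability1", "liability2"])
    return binary, ordinal, liabilities


# --------------------------------------------------------------------------
# Induction experiments
# --------------------------------------------------------------------------

def simulate_induction(p_treat: float, p_ctrl: float, n_per_plate: int = 200,
                       n_plates: int = 3, seed: int = 0,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-plate Eu counts in a treatment/control induction assay.

    Up to 200 screened adults per plate, replicate plates per arm; Eu
    counts are binomial with the arm's induction probability.
    """
    for p in (p_treat, p_ctrl):
        if not (0.0 <= p <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
    if not (1 <= n_per_plate <= 200):
        raise ValueError("plate sample size must be between 1 and 200")
    rng = rng if rng is not None else _rng_for(seed, "induction")
    rows = []
    for arm, p in (("treatment", p_treat), ("control", p_ctrl)):
        for plate in range(1, n_plates + 1):
            rows.append({"arm": arm, "plate": plate,
                         "n_eu": int(rng.binomial(n_per_plate, p)),
                         "n_total": n_per_plate})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Study-shaped preset
# --------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Generator settings; defaults reproduce the study's design."""

    n_outgroup: int = 36          # non-diplogastrid Rhabditina + outgroups
    n_ingroup: int = 54           # Diplogastridae
    birth: float = 1.0
    death: float = 0.0
    q01: float = 0.01             # regain rate inside the radiation
    q10: float = 0.15             # loss rate of the dimorphism
    target_gains: int = 1
    target_losses: int = 10
    min_group_tips: int = 15      # smallest usable Dm group
    mn_tips_range: tuple = (22, 38)  # study: 31 of 54 diplogastrids
    max_attempts: int = 10_000
    regime_rates: dict = field(default_factory=lambda: {
        "Rh": 1.0, "Dm": 3.0, "Mn": 9.0})
    n_specimens: int = 5          # ~ the study's 4.8 images per species/morph
    noise_sd: float = 0.02
    species_scatter_sd: dict = field(default_factory=lambda: {
        "Rh": 0.025, "St": 0.035, "Eu": 0.035, "Mn": 0.09})
    size_lognormal: dict = field(default_factory=lambda: {
        "Rh": (0.0, 0.15), "St": (0.0, 0.15), "Eu": (0.45, 0.15),
        "Mn": (0.15, 0.25)})
    threshold_rho: float = 0.8
    p_treat: float = 0.34         # the starved-assay induction fractions
    p_ctrl: float = 0.06
    n_per_plate: int = 200
    n_plates: int = 3


@dataclass
class SyntheticDataset:
    """One fully generated dataset plus the provenance to regenerate it."""

    tree: Phylogeny
    history: CharacterHistory
    tip_states: pd.Series          # dimorphism presence, 0/1
    groups2: pd.Series             # Rh / Dip
    groups3: pd.Series             # Rh / Dm / Mn
    trait: pd.Series               # continuous trait (PC1 analog)
    painting: RegimePainting
    landmarks: list[LandmarkConfig]
    structure_matrix: pd.DataFrame
    induction_plates: pd.DataFrame
    config: SimConfig
    seed: int

    def write(self, directory) -> None:
        """Write the dataset in the formats the pipeline ingests
        (Newick, TPS, CSV)."""
        import os

        from .morphometrics import write_tps

        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "tree.nwk"), "w") as fh:
            fh.write(self.tree.to_newick() + "\n")
        write_tps(self.landmarks, os.path.join(directory, "landmarks.tps"))
        pd.DataFrame({
            "species": self.tip_states.index,
            "state": self.tip_states.values,
            "group2": self.groups2.reindex(self.tip_states.index).values,
            "group3": self.groups3.reindex(self.tip_states.index).values,
        }).to_csv(os.path.join(directory, "states.csv"), index=False)
        self.trait.rename("trait").to_csv(
            os.path.join(directory, "trait.csv"), index_label="species")
        self.structure_matrix.to_csv(
            os.path.join(directory, "structures.csv"), index_label="species")
        self.induction_plates.to_csv(
            os.path.join(directory, "induction.csv"), index=False)


def reference_dataset(seed: int = 0, config: SimConfig | None = None
                      ) -> SyntheticDataset:
    """Generate the study-shaped dataset.

    The dimorphism is gained exactly once (on the stem of the radiating
    clade) and lost ``target_losses`` times; histories are
    rejection-sampled until the gain/loss counts and minimum group sizes
    match.  The continuous trait evolves fastest in secondarily
    monomorphic lineages; landmark scatter is inflated in that group.
    """
    cfg = config or SimConfig()
    rng_tree = _rng_for(seed, "tree")
    out_labels = [f"rhab{i + 1:02d}" for i in range(cfg.n_outgroup)]
    in_labels = [f"diplo{i + 1:02d}" for i in range(cfg.n_ingroup)]
    left = simulate_tree(cfg.n_outgroup, cfg.birth, cfg.death,
                         labels=out_labels, rng=rng_tree)
    right = simulate_tree(cfg.n_ingroup, cfg.birth, cfg.death,
                          labels=in_labels, rng=rng_tree)
    depth_l = left.node_depths()[: left.n_tips].mean()
    depth_r = right.node_depths()[: right.n_tips].mean()
    # stems chosen so both subtrees reach comparable root-to-tip depths
    base = 0.2 * max(depth_l, depth_r)
    tree = join_trees(left, right, stem_left=base + max(0.0, depth_r - depth_l),
                      stem_right=base + max(0.0, depth_l - depth_r))

    groups2 = pd.Series({t: ("Dip" if t in in_labels else "Rh")
                         for t in tree.tip_labels})
    # locate the ingroup MRCA (child of root on the ingroup side)
    ingroup_mrca = None
    for child in tree.children[tree.root]:
        tips_below = _tips_below(tree, child)
        if set(tree.tip_labels[i] for i in tips_below) == set(in_labels):
            ingroup_mrca = child
    if ingroup_mrca is None:
        raise RuntimeError("ingroup clade not found after joining")

    rng_mk2 = _rng_for(seed, "mk2")
    history = None
    for _ in range(cfg.max_attempts):
        cand = _preset_history(tree, ingroup_mrca, cfg, rng_mk2)
        if cand is None:
            continue
        gains, losses = cand.transition_counts()
        states = cand.node_states[: tree.n_tips]
        n_dm = int(states[[tree.tip_index(t) for t in in_labels]].sum())
        n_mn = cfg.n_ingroup - n_dm
        # the tip pattern must itself evidence every loss: each loss event
        # founds its own maximal monomorphic clade, and no cheaper
        # (delayed-gain / merged-loss) reconstruction may exist
        evident = _maximal_zero_clades(tree, cand, ingroup_mrca)
        minimal = _min_transitions(tree, cand)
        if (gains == cfg.target_gains and losses == cfg.target_losses
                and evident == cfg.target_losses
                and minimal == cfg.target_gains + cfg.target_losses
                and cfg.mn_tips_range[0] <= n_mn <= cfg.mn_tips_range[1]
                and n_dm >= cfg.min_group_tips):
            history = cand
            break
    if history is None:
        raise RuntimeError(
            f"no identifiable history with {cfg.target_gains} gain(s) and "
            f"{cfg.target_losses} losses in {cfg.max_attempts} attempts")
    tip_states = history.tip_states()
    groups3 = pd.Series({
        t: ("Rh" if groups2[t] == "Rh"
            else ("Dm" if tip_states[t] == 1 else "Mn"))
        for t in tree.tip_labels})

    painting = paint_from_history(tree, history, groups2)
    trait = simulate_bm_regimes(tree, painting, cfg.regime_rates,
                                rng=_rng_for(seed, "bm"))

    unit_rows = []
    for t in tree.tip_labels:
        if groups3[t] == "Dm":
            unit_rows.append({"species": t, "morph": "St", "group": "St"})
            unit_rows.append({"species": t, "morph": "Eu", "group": "Eu"})
        else:
            unit_rows.append({"species": t, "morph": "monomorphic",
                              "group": groups3[t]})
    deform = _default_deformations()
    landmarks = simulate_landmarks(
        pd.DataFrame(unit_rows), group_deformations=deform,
        n_specimens=cfg.n_specimens, noise_sd=cfg.noise_sd,
        species_scatter_sd=cfg.species_scatter_sd,
        size_lognormal=cfg.size_lognormal, rng=_rng_for(seed, "landmarks"))

    rng_struct = _rng_for(seed, "structures")
    base_ci = {"Rh": 1.0, "Dm": 6.0, "Mn": 3.0}
    ci = {}
    for t in tree.tip_labels:
        val = base_ci[groups3[t]] + rng_struct.normal(scale=1.0)
        ci[t] = int(np.clip(round(val), 0, 9))
    structure = pd.DataFrame(
        0, index=tree.tip_labels,
        columns=[f"structure{i + 1:02d}" for i in range(25)], dtype=int)
    for t in tree.tip_labels:
        cols = rng_struct.choice(25, size=ci[t], replace=False)
        structure.iloc[structure.index.get_loc(t), cols] = 1
    structure["dimorphism"] = tip_states.reindex(structure.index)

    induction = simulate_induction(cfg.p_treat, cfg.p_ctrl, cfg.n_per_plate,
                                   cfg.n_plates, rng=_rng_for(seed, "induction"))
    return SyntheticDataset(
        tree=tree, history=history, tip_states=tip_states, groups2=groups2,
        groups3=groups3, trait=trait, painting=painting, landmarks=landmarks,
        structure_matrix=structure, induction_plates=induction,
        config=cfg, seed=seed)


def _tips_below(tree: Phylogeny, node: int) -> list[int]:
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if not tree.children[n]:
            out.append(n)
        else:
            stack.extend(tree.children[n])
    return out


def _preset_history(tree: Phylogeny, ingroup_mrca: int, cfg: SimConfig,
                    rng: np.random.Generator) -> CharacterHistory | None:
    """One candidate dimorphism history for the study-shaped preset.

    State 0 outside the radiation; a forced mid-stem gain; then
    ``target_losses`` loss events placed on distinct, non-nested ingroup
    edges with probability proportional to edge length (the placement law
    of a low-rate loss process conditioned on its event count), each at a
    uniform position along its edge.  Returns None when a draw nests one
    loss inside another.
    """
    inside = _descendants(tree, ingroup_mrca)
    candidates = np.array([n for n in inside])
    weights = tree.edge_length[candidates]
    if len(candidates) < cfg.target_losses:
        return None
    chosen = rng.choice(len(candidates), size=cfg.target_losses,
                        replace=False, p=weights / weights.sum())
    loss_edges = set(int(candidates[i]) for i in chosen)
    # reject nested placements: a loss below a loss needs a regain
    for e in loss_edges:
        node = tree.parent[e]
        while node >= 0 and node != ingroup_mrca:
            if node in loss_edges:
                return None
            node = tree.parent[node]

    node_states = np.zeros(tree.n_nodes, dtype=int)
    segments: list[Segments] = [[] for _ in range(tree.n_nodes)]
    for node in range(tree.n_nodes):
        if tree.parent[node] < 0 or node in set(inside) \
                or node == ingroup_mrca:
            continue
        segments[node] = [(float(tree.edge_length[node]), 0)]
    stem = float(tree.edge_length[ingroup_mrca])
    segments[ingroup_mrca] = [(stem / 2, 0), (stem / 2, 1)]
    node_states[ingroup_mrca] = 1
    for node in _preorder_within(tree, ingroup_mrca):
        for child in tree.children[node]:
            length = float(tree.edge_length[child])
            if node_states[node] == 0:
                segments[child] = [(length, 0)]
                node_states[child] = 0
            elif child in loss_edges:
                at = float(rng.uniform(0.05, 0.95)) * length
                segments[child] = [(at, 1), (length - at, 0)]
                node_states[child] = 0
            else:
                segments[child] = [(length, 1)]
                node_states[child] = 1
    return CharacterHistory(tree=tree, segments=segments,
                            node_states=node_states)


def _maximal_zero_clades(tree: Phylogeny, history: CharacterHistory,
                         ingroup_mrca: int) -> int:
    """Number of maximal all-state-0 clades inside the radiation.

    This is the parsimony-minimal loss count given a single gain, i.e. the
    number of losses the tip pattern alone can testify to.
    """
    states = history.node_states[: tree.n_tips]
    all_zero: dict[int, bool] = {}
    for node in tree.postorder:
        if not tree.children[node]:
            all_zero[node] = states[node] == 0
        else:
            all_zero[node] = all(all_zero[c] for c in tree.children[node])
    count = 0
    stack = [ingroup_mrca]
    while stack:
        node = stack.pop()
        if all_zero[node]:
            count += 1
        else:
            stack.extend(tree.children[node])
    return count


def _min_transitions(tree: Phylogeny, history: CharacterHistory) -> int:
    """Sankoff minimum number of state changes given the tips (root in
    state 0).  The preset requires this to equal the true event count, so
    no cheaper (e.g. delayed-gain) reconstruction explains the data."""
    states = history.node_states[: tree.n_tips]
    INF = 10 ** 9
    cost = np.zeros((tree.n_nodes, 2), dtype=np.int64)
    for node in tree.postorder:
        if not tree.children[node]:
            s = states[node]
            cost[node, s] = 0
            cost[node, 1 - s] = INF
        else:
            for s in (0, 1):
                total = 0
                for c in tree.children[node]:
                    total += min(cost[c, s], cost[c, 1 - s] + 1)
                cost[node, s] = total
    return int(cost[tree.root, 0])


def _descendants(tree: Phylogeny, node: int) -> list[int]:
    out, stack = [], list(tree.children[node])
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(tree.children[n])
    return out


def _preorder_within(tree: Phylogeny, node: int) -> list[int]:
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(tree.children[n])
    return out


def _default_deformations() -> dict[str, np.ndarray]:
    """Group-level mean-shape deformations: the Eu morph widens the mouth,
    Mn shapes drift away from the outgroup template."""
    widen = np.zeros_like(DEFAULT_TEMPLATE)
    widen[:, 0] = (DEFAULT_TEMPLATE[:, 0] - 0.5) * 0.5   # wider
    widen[:, 1] = -DEFAULT_TEMPLATE[:, 1] * 0.15         # shallower
    tilt = np.zeros_like(DEFAULT_TEMPLATE)
    tilt[:, 1] = (DEFAULT_TEMPLATE[:, 0] - 0.5) * 0.2
    return {
        "Rh": np.zeros_like(DEFAULT_TEMPLATE),
        "St": tilt * 0.5,
        "Eu": widen,
        "Mn": tilt,
    }
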