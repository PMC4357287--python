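"""Configuration-driven orchestration of the full analysis.

One call runs (or selectively re-runs) the chain: data ingestion or
simulation -> morphometrics -> disparity -> character mapping -> rate
models -> trait correlation -> induction statistics, and collects every
stage's headline numbers in a JSON-serializable report with a seed and
version manifest.  Study-scale settings (10 maps x 500 trees, 10,000 and
100,000 bootstraps, 50 x 500,000-generation threshold runs, ...) are the
config defaults; ``RunConfig.desk_scale()`` gives a configuration sized
for minutes rather than days.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bmrates import (fit_multirate, compare_models, group_rate_test,
                      mcmc_branch_rates, model_average, paint_from_history,
                      standard_models)
from .charmap import (Mk2Model, calibrate_priors, rescale_history,
                      sample_history, summarize_histories)
from .correlation import (phylo_regression_coefficient, randomwalk_corr_bf,
                          threshold_corr)
from .disparity import disparity_difference_test, rarefied_bootstrap, \
    retain_axes
from .morphometrics import form_space, gpa, pca, phylo_pca, read_tps, \
    species_average
from .simulate import SimConfig, SyntheticDataset, reference_dataset
from .traits_stats import complexity_index, fisher_exact, pool_replicates
from .trees import read_trees

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs.  Defaults are the study-scale settings."""

    seed: int = 0
    input_dir: str | None = None       # None -> simulate the reference preset
    out_dir: str | None = None
    stages: tuple[str, ...] = ("morphometrics", "disparity", "charmap",
                               "rates", "rates_mcmc", "correlation",
                               "induction")
    # morphometrics / disparity
    axis_threshold: float = 0.05
    n_boot: int = 10_000
    n_boot_test: int = 100_000
    # character mapping
    calibration_generations: int = 500_000
    calibration_sample_every: int = 100
    n_maps: int = 10
    n_trees: int = 500
    # ML rates
    n_fit_histories: int = 5000
    # rjMCMC rates
    mcmc_generations: int = 30_000_000
    mcmc_sample_every: int = 5000
    mcmc_chains: int = 3
    max_clocks: int = 3
    proposal_width: float = 1.5
    n_perm: int = 10_000
    # correlation
    threshold_generations: int = 500_000
    threshold_runs: int = 50
    randomwalk_generations: int = 10_000_000
    randomwalk_sample_every: int = 1000
    # trait source for the rate analyses: "auto" uses a supplied continuous
    # trait when present, otherwise PC1 of the phylogenetic form PCA
    rates_trait: str = "auto"

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "RunConfig":
        """A configuration sized to run in minutes on one CPU."""
        small = dict(
            n_boot=2000, n_boot_test=5000,
            calibration_generations=20_000, n_maps=10, n_trees=20,
            n_fit_histories=200,
            mcmc_generations=15_000, mcmc_sample_every=25, mcmc_chains=2,
            n_perm=2000,
            threshold_generations=40_000, threshold_runs=2,
            randomwalk_generations=200_000, randomwalk_sample_every=100,
        )
        small.update(overrides)
        return cls(seed=seed, **small)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if data.pop("desk_scale", False):
            return cls.desk_scale(**data)
        return cls(**data)


@dataclass
class RunReport:
    """Per-stage outputs plus a seed/version manifest."""

    sections: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps({"manifest": self.manifest,
                              "sections": self.sections},
                             indent=2, default=_jsonable)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _stage_key(name: str, config: RunConfig) -> str:
    digest = hashlib.sha256(
        json.dumps({"stage": name, "config": asdict(config)},
                   sort_keys=True, default=str).encode()).hexdigest()[:16]
    return f"{name}-{digest}"


class _Cache:
    """Content-hash keyed stage cache so partial reruns skip clean stages."""

    def __init__(self, out_dir: str | None):
        self.dir = os.path.join(out_dir, "cache") if out_dir else None
        if self.dir:
            os.makedirs(self.dir, exist_ok=True)

    def get_or_run(self, key: str, fn):
        if self.dir:
            path = os.path.join(self.dir, key + ".json")
            if os.path.exists(path):
                with open(path) as fh:
                    return json.load(fh), True
        result = fn()
        if self.dir:
            with open(os.path.join(self.dir, key + ".json"), "w") as fh:
                json.dump(result, fh, default=_jsonable)
            with open(os.path.join(self.dir, key + ".json")) as fh:
                result = json.load(fh)  # normalize types as a reload would
        return result, False


def load_inputs(input_dir) -> SyntheticDataset:
    """Read a dataset directory written by :meth:`SyntheticDataset.write`."""
    from .bmrates import paint_from_history  # noqa: F401  (re-painted below)
    from .simulate import SimConfig

    tree = read_trees(os.path.join(input_dir, "tree.nwk"))[0]
    states = pd.read_csv(os.path.join(input_dir, "states.csv"))
    tip_states = states.set_index("species")["state"]
    groups2 = states.set_index("species")["group2"]
    groups3 = states.set_index("species")["group3"]
    trait_path = os.path.join(input_dir, "trait.csv")
    trait = (pd.read_csv(trait_path).set_index("species")["trait"]
             if os.path.exists(trait_path) else None)
    landmarks = read_tps(os.path.join(input_dir, "landmarks.tps"))
    structure = pd.read_csv(os.path.join(input_dir, "structures.csv"),
                            index_col="species")
    induction = pd.read_csv(os.path.join(input_dir, "induction.csv"))
    return SyntheticDataset(
        tree=tree, history=None, tip_states=tip_states, groups2=groups2,
        groups3=groups3, trait=trait, painting=None, landmarks=landmarks,
        structure_matrix=structure, induction_plates=induction,
        config=SimConfig(), seed=-1)


def validate_inputs(dataset: SyntheticDataset) -> pd.DataFrame:
    """Cross-check tip labels across tree, traits, landmarks and matrix.

    Returns a findings table (empty when everything is consistent); never
    raises.
    """
    findings = []
    tips = set(dataset.tree.tip_labels)

    def check(name, labels):
        labels = set(labels)
        for orphan in sorted(labels - tips):
            hint = ""
            low = {t.lower(): t for t in tips}
            if orphan.lower() in low:
                hint = f" (case mismatch with {low[orphan.lower()]!r}?)"
            findings.append({"table": name, "label": orphan,
                             "problem": "not a tree tip" + hint})
        for missing in sorted(tips - labels):
            findings.append({"table": name, "label": missing,
                             "problem": "tip absent from table"})

    check("tip_states", dataset.tip_states.index)
    check("groups", dataset.groups3.index)
    check("structure_matrix", dataset.structure_matrix.index)
    if dataset.trait is not None:
        check("trait", dataset.trait.index)
    lm_species = {c.species for c in dataset.landmarks if c.species}
    check("landmarks", lm_species)
    return pd.DataFrame(findings, columns=["table", "label", "problem"])


def _morphometrics_stage(ds: SyntheticDataset, config: RunConfig):
    units = species_average(ds.landmarks)
    shape = gpa(units)
    sizes = pd.Series({u.specimen_id: u.centroid_size for u in units})
    form = form_space(shape, sizes)
    shape_only = form_space(shape)
    pc_form = pca(form)
    pc_shape = pca(shape_only)
    # phylogenetic PCA: dimorphic species represented by the St morph
    rows = {}
    for u in units:
        if u.morph == "Eu":
            continue
        rows[u.species or u.specimen_id] = u.specimen_id
    form_phylo = form.loc[list(rows.values())]
    form_phylo.index = list(rows.keys())
    ppc_form = phylo_pca(form_phylo, ds.tree)
    return {
        "units": [u.specimen_id for u in units],
        "form_pc_proportions": pc_form.proportions[:4],
        "shape_pc_proportions": pc_shape.proportions[:4],
        "logcs_loading_pc1": float(abs(pc_form.loadings.loc["logCS", "PC1"])),
        "phylo_form_pc_proportions": ppc_form.proportions[:4],
    }, pc_form, pc_shape, ppc_form


def _unit_groups(units: list[str], groups3: pd.Series) -> pd.Series:
    out = {}
    for u in units:
        if u.endswith("_St"):
            out[u] = "St"
        elif u.endswith("_Eu"):
            out[u] = "Eu"
        else:
            out[u] = str(groups3.get(u, "Rh"))
    return pd.Series(out)


def _disparity_stage(pc_form, groups3, config: RunConfig, seed: int):
    scores = retain_axes(pc_form, config.axis_threshold)
    unit_groups = _unit_groups(list(scores.index), groups3)
    ests = rarefied_bootstrap(scores, unit_groups, "sum_of_variances",
                              n_boot=config.n_boot, seed=seed)
    summary = {g: {"point": e.point, "mean": e.boot_mean, "sd": e.boot_sd,
                   "ci": [e.ci_low, e.ci_high]} for g, e in ests.items()}
    # Dip (St morph represents dimorphic species) vs outgroup Rhabditina
    dip_groups = unit_groups.replace({"St": "Dip", "Mn": "Dip"})
    dip_groups = dip_groups[dip_groups.isin(["Dip", "Rh"])]
    tests = {
        "Dip_vs_Rh": disparity_difference_test(
            retain_axes(pc_form, config.axis_threshold).loc[dip_groups.index],
            dip_groups, "Dip", "Rh", n_boot=config.n_boot_test, seed=seed),
        "Mn_vs_St": disparity_difference_test(
            scores, unit_groups, "Mn", "St",
            n_boot=config.n_boot_test, seed=seed + 1),
        "Mn_vs_Eu": disparity_difference_test(
            scores, unit_groups, "Mn", "Eu",
            n_boot=config.n_boot_test, seed=seed + 2),
    }
    return {"estimates": summary, "tests": tests,
            "n_axes": int(scores.shape[1])}


def _charmap_stage(ds: SyntheticDataset, config: RunConfig):
    # priors live on the unit-length tree; map there, then carry the
    # histories back onto operational time
    unit_tree = ds.tree.rescaled(1.0)
    grid = calibrate_priors(
        unit_tree, ds.tip_states,
        generations=config.calibration_generations,
        sample_every=config.calibration_sample_every,
        seed=config.seed)
    histories = sample_history(
        unit_tree, ds.tip_states, prior_grid=grid,
        n_maps=config.n_maps * config.n_trees, seed=config.seed + 1)
    histories = [rescale_history(h, ds.tree) for h in histories]
    counts, density = summarize_histories(histories)
    mode = counts.value_counts().idxmax()
    return {
        "gamma_shape": grid.gamma_shape, "gamma_scale": grid.gamma_scale,
        "beta_a": grid.beta_a, "beta_b": grid.beta_b,
        "gain_mode": int(mode[0]), "loss_mode": int(mode[1]),
        "gain_mean": float(counts["gains"].mean()),
        "loss_mean": float(counts["losses"].mean()),
    }, histories


def _rates_stage(ds: SyntheticDataset, trait, histories, config: RunConfig):
    specs = standard_models()
    n_hist = min(len(histories), config.n_fit_histories)
    fits_per = []
    for h in histories[:n_hist]:
        painting = paint_from_history(ds.tree, h, ds.groups2)
        regimes = set(painting.regimes())
        if regimes != {"Rh", "Dm", "Mn"}:
            continue  # a history missing a regime cannot feed 3-group models
        fits_per.append([fit_multirate(ds.tree, trait, painting, s)
                         for s in specs])
    if not fits_per:
        raise RuntimeError("no sampled history painted all three regimes")
    table, lrt = compare_models(fits_per[0])
    averaged = model_average(fits_per, scheme="akaike")
    return {
        "model_table": table, "lrt": lrt,
        "model_averaged_rates": averaged["mean_rate"].to_dict(),
        "model_averaged_sd": averaged["sd_rate"].to_dict(),
        "n_reconstructions": len(fits_per),
    }


def _rates_mcmc_stage(ds: SyntheticDataset, trait, config: RunConfig):
    trace = mcmc_branch_rates(
        ds.tree, trait, generations=config.mcmc_generations,
        max_clocks=config.max_clocks, proposal_width=config.proposal_width,
        sample_every=config.mcmc_sample_every, seed=config.seed,
        n_chains=config.mcmc_chains)
    painting = ds.painting
    if painting is None:
        from .bmrates import paint_by_clades
        painting = paint_by_clades(ds.tree, ds.groups3, background="Rh")
    edge_groups = np.array(
        [segs[-1][1] if segs else None for segs in painting.segments],
        dtype=object)
    summary, pairwise = group_rate_test(trace, edge_groups,
                                        n_perm=config.n_perm,
                                        seed=config.seed)
    return {"group_rates": summary.to_dict(orient="index"),
            "pairwise": pairwise,
            "acceptance": trace.acceptance}


def _correlation_stage(ds: SyntheticDataset, config: RunConfig):
    ci = complexity_index(
        ds.structure_matrix.drop(columns=["dimorphism"], errors="ignore"))
    fit = threshold_corr(ds.tree, ds.tip_states, ci.astype(float),
                         generations=config.threshold_generations,
                         n_runs=config.threshold_runs, seed=config.seed)
    bf = randomwalk_corr_bf(ds.tree, ds.tip_states, ci.astype(float),
                            generations=config.randomwalk_generations,
                            sample_every=config.randomwalk_sample_every,
                            seed=config.seed)
    # the harmonic-mean estimator is retained for comparability but is
    # unstable; the stepping-stone estimate is the reliable cross-check
    bf_ss = randomwalk_corr_bf(ds.tree, ds.tip_states, ci.astype(float),
                               generations=config.randomwalk_generations // 2,
                               sample_every=config.randomwalk_sample_every,
                               seed=config.seed + 1, method="stepping_stone")
    b = phylo_regression_coefficient(ds.tree, ds.tip_states, ci.astype(float))
    return {
        "threshold_r": fit.r_mean, "threshold_hpd": [fit.hpd_low, fit.hpd_high],
        "randomwalk_r": bf.r, "log_bayes_factor": bf.log_bf,
        "log_bayes_factor_stepping_stone": bf_ss.log_bf,
        "very_strong": bool(bf.very_strong),
        "regression_b": b,
        "ci_range": [int(ci.min()), int(ci.max())],
    }


def _induction_stage(ds: SyntheticDataset):
    pooled = pool_replicates(ds.induction_plates)
    p, orr = fisher_exact(pooled)
    return {"pooled": pooled, "fisher_p": p, "odds_ratio": orr}


def run(config: RunConfig) -> RunReport:
    """Execute the configured stages in dependency order.

    A stage failure marks the stage failed in the report and skips its
    dependents; completed stages cache their summaries under
    ``out_dir/cache`` keyed by a hash of the configuration.
    """
    t_start = time.time()
    cache = _Cache(config.out_dir)
    report = RunReport()
    report.manifest = {
        "plastevol_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
    }
    if config.input_dir:
        ds = load_inputs(config.input_dir)
    else:
        ds = reference_dataset(seed=config.seed)
    report.sections["validation"] = validate_inputs(ds).to_dict(
        orient="records")

    failed: set[str] = set()
    pc_form = histories = None
    trait = ds.trait

    def stage(name, deps, fn):
        nonlocal report
        if name not in config.stages:
            return None
        if any(d in failed for d in deps):
            report.sections[name] = {"status": "skipped (failed dependency)"}
            return None
        t0 = time.time()
        try:
            result = fn()
            logger.info("stage %s: %.1fs", name, time.time() - t0)
            return result
        except Exception as exc:  # pragma: no cover - defensive
            logger.exception("stage %s failed", name)
            report.sections[name] = {"status": f"failed: {exc}"}
            failed.add(name)
            return None

    def do_morpho():
        summary, pcf, pcs, ppcf = _morphometrics_stage(ds, config)
        report.sections["morphometrics"] = summary
        return pcf, ppcf

    out = stage("morphometrics", (), do_morpho)
    ppc_form = None
    if out is not None:
        pc_form, ppc_form = out
    if trait is None and ppc_form is not None:
        trait = ppc_form.scores["PC1"]

    if "disparity" in config.stages and pc_form is not None:
        def do_disp():
            result, _ = cache.get_or_run(
                _stage_key("disparity", config),
                lambda: _disparity_stage(pc_form, ds.groups3, config,
                                         config.seed))
            report.sections["disparity"] = result
        stage("disparity", ("morphometrics",), do_disp)
    elif "disparity" in config.stages:
        report.sections["disparity"] = {"status": "skipped (failed dependency)"}

    def do_charmap():
        summary, hists = _charmap_stage(ds, config)
        report.sections["charmap"] = summary
        return hists

    histories = stage("charmap", (), do_charmap)

    if "rates" in config.stages:
        def do_rates():
            report.sections["rates"] = _jsonround(
                _rates_stage(ds, trait, histories, config))
        if histories is None or trait is None:
            report.sections["rates"] = {"status": "skipped (failed dependency)"}
        else:
            stage("rates", ("charmap",), do_rates)

    if "rates_mcmc" in config.stages:
        def do_mcmc():
            report.sections["rates_mcmc"] = _jsonround(
                _rates_mcmc_stage(ds, trait, config))
        if trait is None:
            report.sections["rates_mcmc"] = {
                "status": "skipped (failed dependency)"}
        else:
            stage("rates_mcmc", (), do_mcmc)

    stage("correlation", (),
          lambda: report.sections.__setitem__(
              "correlation", _correlation_stage(ds, config)))
    stage("induction", (),
          lambda: report.sections.__setitem__(
              "induction", _jsonround(_induction_stage(ds))))

    report.manifest["wall_time_s"] = round(time.time() - t_start, 1)
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        report.to_json(os.path.join(config.out_dir, "report.json"))
    return report


def _jsonround(obj):
    """Make a stage result JSON-round-trippable (frames -> records)."""
    return json.loads(json.dumps(obj, default=_jsonable))
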