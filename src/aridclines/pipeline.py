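"""End-to-end orchestration: simulate or load a study, then run clines,
fitness, selection, and the Bayesian vector comparisons in one call.

A run is fully specified by a :class:`RunConfig`; a single global seed
fans out deterministically to per-stage seeds, so the manifest (config +
seeds) reproduces every number bit-for-bit, and stages can be re-run in
isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from . import bayes, clines, selection, study_data
from .geometry import TraitVector, subset_by_module
from .simulate import SyntheticConfig, generate_field_study, generate_glasshouse_study
from .traits import STRATEGY_MODULES, TRAIT_NAMES

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "stage_seed", "run_full_analysis"]

_STAGES = ("clines", "fitness", "selection", "compare")


def stage_seed(global_seed: int, stage: str, item: int = 0) -> int:
    """Deterministic per-stage seed fan-out (stays below 2**31)."""
    h = np.random.SeedSequence(
        [int(global_seed), abs(hash_stable(stage)), int(item)])
    return int(h.generate_state(1)[0] % (2**31))


def hash_stable(s: str) -> int:
    return int.from_bytes(hashlib.sha256(s.encode()).digest()[:4], "big")


@dataclass
class RunConfig:
    """Configuration of one reproducible analysis run."""

    plants_path: str | None = None        # CSV; None -> simulate
    aridity_path: str | None = None
    simulate: SyntheticConfig | None = None
    include_glasshouse: bool = True
    stages: tuple[str, ...] = _STAGES
    alpha: float = 0.05
    n_draws: int = 10_000
    burn_in: int = 2000
    seed: int = 0
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = {
            "plants_path": self.plants_path,
            "aridity_path": self.aridity_path,
            "simulate": self.simulate.to_jsonable() if self.simulate else None,
            "include_glasshouse": self.include_glasshouse,
            "stages": list(self.stages),
            "alpha": self.alpha,
            "n_draws": self.n_draws,
            "burn_in": self.burn_in,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    if config.plants_path is not None:
        plants, report = study_data.read_plant_table(config.plants_path)
        if config.aridity_path is None:
            raise ValueError("aridity_path is required when plants_path is given")
        aridity = study_data.read_aridity_table(config.aridity_path)
        truth = None
    else:
        sim = config.simulate if config.simulate is not None else SyntheticConfig()
        field_tbl, truth = generate_field_study(sim, stage_seed(config.seed, "simulate", 0))
        tables = [field_tbl]
        if config.include_glasshouse:
            gh_tbl, _ = generate_glasshouse_study(sim, stage_seed(config.seed, "simulate", 1))
            tables.append(gh_tbl)
        plants = pd.concat(tables, ignore_index=True)
        aridity = {p: a for p, a in truth.aridity.items()}
        report = study_data.ValidationReport(
            n_rows=len(plants), missing_per_column={})
    missing_pops = sorted(set(plants["population"]) - set(aridity))
    if missing_pops:
        raise ValueError(
            f"clines stage cannot run: no aridity record for population(s) "
            f"{missing_pops}"
        )
    return plants, aridity, truth, report


def run_full_analysis(config: RunConfig) -> dict:
    """Run the configured stages and return a result bundle.

    The bundle maps stage names to their outputs (tables, fits,
    VectorComparison objects) plus a ``manifest`` with the config hash,
    all derived seeds, and row counts. When ``config.out_dir`` is set the
    tables, comparison JSONs, a markdown report and the manifest are also
    written there.
    """
    t0 = time.time()
    plants, aridity, truth, report = _load_inputs(config)
    arid_values = {p: float(getattr(a, "aridity", a)) for p, a in aridity.items()}
    results: dict = {"truth": truth, "validation": report}
    timings: dict[str, float] = {}

    needs_derivation = "growth_rate" not in plants.columns
    if needs_derivation:
        plants = study_data.derive_traits(plants)
    field_mask = plants["experiment"] == "field2019"
    if field_mask.any() and "seed_count" in plants.columns:
        fld = study_data.relative_fitness(plants.loc[field_mask])
        plants = pd.concat([fld, plants.loc[~field_mask]], ignore_index=True)
    std = study_data.transform_and_standardize(
        plants, transform="none" if truth is not None else "registry")
    experiments = sorted(plants["experiment"].unique())
    results["plants"] = plants
    results["standardized"] = std

    try:
        if "clines" in config.stages:
            t = time.time()
            results["clines"] = {}
            for exp in experiments:
                model = "mixed" if exp == "glasshouse2018" else "fixed"
                table, fits = clines.cline_table(
                    std, aridity, experiment=exp, model=model, alpha=config.alpha)
                results["clines"][exp] = {"table": table, "fits": fits}
            timings["clines"] = time.time() - t

        if "fitness" in config.stages and "relative_fitness" in plants.columns:
            t = time.time()
            results["fitness_cline"] = clines.fitness_cline(
                plants.loc[plants["experiment"] == "field2019"], aridity,
                alpha=config.alpha)
            timings["fitness"] = time.time() - t

        if "selection" in config.stages and "relative_fitness" in plants.columns:
            t = time.time()
            results["selection"] = _selection_stage(plants, std, config)
            timings["selection"] = time.time() - t

        if "compare" in config.stages:
            t = time.time()
            results["comparisons"] = _compare_stage(
                plants, std, arid_values, experiments, config)
            timings["compare"] = time.time() - t
    except Exception as exc:
        # halt with the stage name; partial outputs stay in `results`
        stage = next((s for s in _STAGES if s not in timings and s in config.stages),
                     "unknown")
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        "n_rows": int(len(plants)),
        "experiments": experiments,
        "n_draws": config.n_draws,
        "alpha": config.alpha,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "elapsed_s": round(time.time() - t0, 3),
    }
    results["manifest"] = manifest
    if config.out_dir is not None:
        _write_bundle(Path(config.out_dir), results, manifest)
    return results


def _selection_stage(plants: pd.DataFrame, std, config: RunConfig) -> dict:
    out: dict = {}
    mask = (std.groups["experiment"] == "field2019").to_numpy()
    field = plants.loc[plants["experiment"] == "field2019"].reset_index(drop=True)
    z_field = std.values.loc[mask].reset_index(drop=True)
    trt = std.groups.loc[mask, "treatment"].reset_index(drop=True)
    for treatment in ("wet", "dry"):
        sel = trt == treatment
        z = z_field.loc[sel.to_numpy()]
        sub = field.loc[sel.to_numpy()]
        grads = selection.estimate_gradients_ols(
            z, sub["relative_fitness"].to_numpy(), treatment)
        counts = sub["seed_count"].to_numpy()
        n_zero = int((counts == 0).sum())
        # the hurdle needs enough failures to identify its logistic layer;
        # a stray count-model zero or two is left to the NB GLM
        if n_zero >= max(5, int(0.02 * len(counts))):
            fit = selection.fit_hurdle_model(counts > 0, counts, z)
            grads.z_values, grads.p_values = fit.z_values, fit.p_values
            grads.model_kind = "hurdle"
            out[f"{treatment}_hurdle"] = fit
        else:
            nb = selection.fit_negbin_glm(np.asarray(counts), z)
            grads.z_values, grads.p_values = nb.z_, nb.p_
            grads.model_kind = "negbin"
            out[f"{treatment}_negbin"] = nb
        grads.n_zero = n_zero
        out[treatment] = grads
    out["dbeta"] = selection.differential_selection(
        out["dry"].beta, out["wet"].beta)
    return out


def _dz_draws(std, experiments, arid_values, config: RunConfig,
              which: str) -> bayes.PosteriorDraws:
    """Posterior Delta-z draws for one experiment, or for the combined data
    (``which='combined'``)."""
    draws = {}
    for i, trait in enumerate(TRAIT_NAMES):
        seed = stage_seed(config.seed, f"lsmeans:{which}", i)
        if which == "combined":
            d = _combined_lsmean_draws(std, trait, config, seed)
        else:
            d = bayes.sample_population_lsmeans(
                std, trait, which, n_draws=config.n_draws, seed=seed,
                burn_in=config.burn_in)
        draws[trait] = d
    return bayes.propagate_cline_draws(draws, arid_values)


def _combined_lsmean_draws(std, trait, config: RunConfig, seed: int):
    y = std.values[trait].to_numpy()
    pops = pd.Categorical(std.design["population"].to_numpy())
    X = np.eye(len(pops.categories))[pops.codes]
    groupings: dict[str, np.ndarray] = {
        "treatment": std.groups["treatment"].to_numpy()}
    if std.groups["experiment"].nunique() >= 2:
        groupings["experiment"] = std.groups["experiment"].to_numpy()
    if "patch" in std.design.columns and std.design["patch"].nunique() >= 2:
        groupings["patch"] = std.design["patch"].to_numpy()
    return bayes.sample_posterior_mixed(
        y, X, groupings, n_draws=config.n_draws, seed=seed,
        burn_in=config.burn_in, labels=list(pops.categories))


def _beta_draws(plants: pd.DataFrame, std, config: RunConfig) -> dict[str, bayes.PosteriorDraws]:
    mask = (std.groups["experiment"] == "field2019").to_numpy()
    field = plants.loc[plants["experiment"] == "field2019"].reset_index(drop=True)
    z_field = std.values.loc[mask].reset_index(drop=True)
    trt = std.groups.loc[mask, "treatment"].reset_index(drop=True)
    out = {}
    for i, treatment in enumerate(("wet", "dry")):
        sel = (trt == treatment).to_numpy()
        Z = z_field.loc[sel].to_numpy()
        w = field.loc[sel, "relative_fitness"].to_numpy()
        X = np.column_stack([np.ones(len(w)), Z])
        d = bayes.sample_posterior_linear(
            w, X, n_draws=config.n_draws,
            seed=stage_seed(config.seed, "beta_draws", i),
            labels=["intercept"] + list(TRAIT_NAMES))
        out[treatment] = d.select(list(TRAIT_NAMES))
    return out


def _compare_stage(plants, std, arid_values, experiments, config: RunConfig) -> dict:
    comparisons: dict[str, object] = {}
    dz_by_exp = {}
    for exp in experiments:
        dz_by_exp[exp] = _dz_draws(std, experiments, arid_values, config, exp)
    if len(experiments) >= 2:
        comparisons["dz_glasshouse_vs_field"] = bayes.compare_vectors_posterior(
            dz_by_exp["glasshouse2018"], dz_by_exp["field2019"],
            "cline_slope", "cline_slope")
    has_fitness = "relative_fitness" in plants.columns
    if has_fitness:
        beta_draws = _beta_draws(plants, std, config)
        comparisons["beta_wet_vs_dry"] = bayes.compare_vectors_posterior(
            beta_draws["wet"], beta_draws["dry"],
            "selection_gradient", "selection_gradient")
        dbeta = bayes.PosteriorDraws(
            beta_draws["dry"].labels,
            beta_draws["dry"].draws - beta_draws["wet"].draws,
            seed=beta_draws["dry"].seed, model="differential selection draws")
        dz = (_dz_draws(std, experiments, arid_values, config, "combined")
              if len(experiments) >= 2 else dz_by_exp["field2019"])
        comparisons["dz_vs_dbeta"] = bayes.compare_vectors_posterior(
            dz, dbeta, "cline_slope", "differential_selection")
        for module in STRATEGY_MODULES:
            names = subset_by_module(
                TraitVector(TRAIT_NAMES, np.zeros(len(TRAIT_NAMES))), module).names
            comparisons[f"dz_vs_dbeta_{module}"] = bayes.compare_vectors_posterior(
                dz.select(list(names)), dbeta.select(list(names)),
                "cline_slope", "differential_selection")
    return comparisons


def _write_bundle(out_dir: Path, results: dict, manifest: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    for exp, block in results.get("clines", {}).items():
        tables[f"clines_{exp}"] = block["table"]
    sel = results.get("selection", {})
    for trt in ("wet", "dry"):
        if trt in sel:
            tables[f"selection_{trt}"] = sel[trt].to_frame()
    study_data.write_results(out_dir, tables, manifest)
    comps = results.get("comparisons", {})
    if comps:
        payload = {name: c.to_dict() for name, c in comps.items()}
        (out_dir / "comparisons.json").write_text(json.dumps(payload, indent=2))
    (out_dir / "report.md").write_text(_markdown_report(results, manifest))


def _markdown_report(results: dict, manifest: dict) -> str:
    lines = ["# Aridity-cline analysis report", ""]
    lines.append(f"- config hash: `{manifest['config_hash']}`")
    lines.append(f"- seed: {manifest['seed']}, draws: {manifest['n_draws']}")
    lines.append(f"- rows: {manifest['n_rows']}, experiments: {manifest['experiments']}")
    lines.append("")
    if "fitness_cline" in results:
        f = results["fitness_cline"]
        fi, pi, dfi = f.f_interaction, f.p_interaction, f.df_interaction
        lines += ["## Fitness along the aridity gradient", "",
                  f"Aridity x treatment interaction: F({dfi[0]}, {dfi[1]}) = "
                  f"{fi:.2f}, P = {pi:.4g}", ""]
        for _, row in f.per_treatment.iterrows():
            lines.append(
                f"- {row['treatment']}: slope {row['slope']:.3f} "
                f"(95% CI {row['lower95']:.3f}, {row['upper95']:.3f})")
        lines.append("")
    for exp, block in results.get("clines", {}).items():
        n_sig = int(block["table"]["holm_significant"].sum())
        lines += [f"## Clines ({exp})", "",
                  f"{n_sig} of {len(block['table'])} traits with a "
                  "Holm-significant aridity slope", ""]
    comps = results.get("comparisons", {})
    if comps:
        lines += ["## Vector comparisons", ""]
        for name, c in comps.items():
            s = c.angle_summary
            lines.append(
                f"- {name}: angle {s.mean:.1f} deg (95% CI {s.lower95:.1f}, "
                f"{s.upper95:.1f}) -> {c.alignment_verdict}; "
                f"norms {c.norm_u_summary.mean:.3f} / {c.norm_v_summary.mean:.3f}")
        lines.append("")
    return "\n".join(lines)
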