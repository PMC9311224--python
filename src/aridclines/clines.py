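"""Population-level adjusted means and per-trait clines along the aridity
gradient.

The two-stage analysis mirrors standard common-garden practice: first
compute population x treatment adjusted means (LSMEANS) for each
standardized trait — from a fixed linear model for the field design, or a
mixed model with patch-within-population and block random effects for the
glasshouse — then regress those means on source-location aridity with a
treatment term. Each trait's aridity x treatment interaction is tested
first; when it is not significant at ``alpha`` the additive model is
refitted and its Type II marginal F-tests are reported. Family-wise error
across the 13 traits is controlled by Holm's step-down procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .study_data import AridityRecord, StandardizedTraits

__all__ = [
    "ClineRegression",
    "ClineFit",
    "fit_lsmeans_fixed",
    "fit_lsmeans_mixed",
    "regress_cline",
    "marginal_slopes",
    "holm_bonferroni",
    "fitness_cline",
    "cline_table",
]


def _frame_for_trait(std: StandardizedTraits, trait: str, experiment: str | None) -> pd.DataFrame:
    if trait not in std.values.columns:
        raise ValueError(f"unknown trait {trait!r}")
    df = pd.DataFrame({
        "y": std.values[trait].to_numpy(),
        "experiment": std.groups["experiment"].to_numpy(),
        "treatment": std.groups["treatment"].to_numpy(),
    })
    for col in std.design.columns:
        df[col] = std.design[col].to_numpy()
    if experiment is not None:
        df = df[df["experiment"] == experiment].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"no rows for experiment {experiment!r}")
    return df


def fit_lsmeans_fixed(std: StandardizedTraits, trait: str,
                      experiment: str | None = None) -> pd.DataFrame:
    """Population x treatment LSMEANS of one trait from a saturated fixed
    linear model (cell-means parameterization).

    For the saturated model these equal the raw cell means; SEs use the
    pooled residual variance. Returns one row per population x treatment
    with columns (experiment, trait, population, treatment, lsmean, se,
    n, model_kind).
    """
    df = _frame_for_trait(std, trait, experiment)
    cells = df.groupby(["population", "treatment"], observed=True)["y"]
    counts = cells.count()
    if (counts < 1).any() or counts.index.size < df["population"].nunique() * df["treatment"].nunique():
        # find the empty combination for the error message
        full = pd.MultiIndex.from_product(
            [sorted(df["population"].unique()), sorted(df["treatment"].unique())])
        empty = [c for c in full if c not in counts.index]
        raise ValueError(f"empty population x treatment cell(s): {empty}")
    means = cells.mean()
    # pooled residual variance of the saturated model
    n, k = len(df), len(means)
    ss_res = float(((df["y"] - df.groupby(["population", "treatment"], observed=True)["y"]
                     .transform("mean")) ** 2).sum())
    dof = n - k
    s2 = ss_res / dof if dof > 0 else np.nan
    out = means.reset_index().rename(columns={"y": "lsmean"})
    out["se"] = np.sqrt(s2 / counts.reset_index(drop=True))
    out["n"] = counts.to_numpy()
    out.insert(0, "trait", trait)
    out.insert(0, "experiment", experiment if experiment is not None
               else df["experiment"].iloc[0])
    out["model_kind"] = "fixed"
    return out


def fit_lsmeans_mixed(std: StandardizedTraits, trait: str,
                      experiment: str | None = None) -> tuple[pd.DataFrame, dict[str, float]]:
    """Population x treatment LSMEANS of one trait from a REML linear mixed
    model with crossed patch and block random intercepts.

    Returns the LSMEANS table (as :func:`fit_lsmeans_fixed`, with
    ``model_kind='mixed'``) plus the estimated variance components
    ``{'patch': .., 'block': .., 'residual': ..}``. Variance components on
    the boundary are returned as 0 with a warning, as happens when patch is
    confounded with residual.
    """
    df = _frame_for_trait(std, trait, experiment)
    for col in ("patch", "block"):
        if col not in df.columns:
            raise ValueError(f"mixed model requires a {col!r} column")
    df = df.copy()
    df["cell"] = df["population"].astype(str) + ":" + df["treatment"].astype(str)
    df["_all"] = 1  # single super-group; crossed REs enter as variance components
    vc = {}
    if df["patch"].nunique() >= 2:
        vc["patch"] = "0 + C(patch)"
    if df["block"].nunique() >= 2:
        vc["block"] = "0 + C(block)"
    if not vc:
        raise ValueError("need >= 2 levels of patch or block for a mixed model")
    model = smf.mixedlm("y ~ 0 + C(cell)", data=df, groups=df["_all"],
                        vc_formula=vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True, method=["lbfgs", "powell"], maxiter=500)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"mixed model failed to converge for {trait!r}: {exc}")
    if not res.converged:
        raise RuntimeError(
            f"mixed model did not converge for trait {trait!r} after 500 iterations"
        )
    vcomp = {name: float(max(v, 0.0)) for name, v in zip(model.exog_vc.names, res.vcomp)}
    for name, v in vcomp.items():
        if v < 1e-10:
            warnings.warn(
                f"variance component {name!r} for trait {trait!r} is at the "
                "boundary (0); it may be confounded with the residual",
                stacklevel=2,
            )
    vcomp["residual"] = float(res.scale)
    fe = res.fe_params
    se = np.sqrt(np.diag(res.cov_params())[: len(fe)])
    labels = [lab.split("[")[1].rstrip("]") for lab in fe.index]
    rows = []
    counts = df.groupby("cell")["y"].count()
    for lab, est, s in zip(labels, fe.to_numpy(), se):
        pop, trt = lab.split(":")
        rows.append({
            "experiment": experiment if experiment is not None else df["experiment"].iloc[0],
            "trait": trait, "population": pop, "treatment": trt,
            "lsmean": float(est), "se": float(s), "n": int(counts[lab]),
            "model_kind": "mixed",
        })
    out = pd.DataFrame(rows).sort_values(["population", "treatment"]).reset_index(drop=True)
    return out, vcomp


@dataclass
class ClineFit:
    """Result of regressing one trait's LSMEANS on aridity x treatment."""

    trait: str
    slope_aridity: float
    slope_se: float
    treatment_effect: float
    interaction_present: bool
    f_aridity: float
    f_treatment: float
    f_interaction: float
    df_aridity: tuple[int, int]
    df_treatment: tuple[int, int]
    df_interaction: tuple[int, int]
    p_aridity: float
    p_treatment: float
    p_interaction: float
    per_treatment: pd.DataFrame      # treatment, slope, se, lower95, upper95, nonzero
    model_used: str                  # "additive" or "interaction"
    holm_significant: bool | None = None

    def to_row(self) -> dict:
        return {
            "trait": self.trait,
            "slope_aridity": self.slope_aridity,
            "slope_se": self.slope_se,
            "treatment_effect": self.treatment_effect,
            "interaction_present": self.interaction_present,
            "F_aridity": self.f_aridity, "p_aridity": self.p_aridity,
            "F_treatment": self.f_treatment, "p_treatment": self.p_treatment,
            "F_interaction": self.f_interaction, "p_interaction": self.p_interaction,
            "model_used": self.model_used,
            "holm_significant": self.holm_significant,
        }


class ClineRegression(BaseEstimator):
    """Per-trait cline model: LSMEAN ~ aridity x treatment.

    The interaction is tested with a partial F-test at ``alpha``; when it
    is not significant the additive model is refitted and Type II marginal
    F-tests for aridity and treatment are reported. ``force_interaction``
    keeps the interaction model regardless (used for the fitness cline,
    where the interaction is the quantity of interest). Population means
    enter unweighted unless ``weight_by_precision`` is set, in which case
    rows are weighted by 1/se**2.

    Fitted attributes: ``slope_``, ``slope_se_``, ``treatment_effect_``,
    ``interaction_present_``, ``fstats_``, ``marginal_slopes_``,
    ``model_used_``.
    """

    def __init__(self, alpha: float = 0.05, force_interaction: bool = False,
                 weight_by_precision: bool = False, trait: str = ""):
        self.alpha = alpha
        self.force_interaction = force_interaction
        self.weight_by_precision = weight_by_precision
        self.trait = trait

    def fit(self, X: pd.DataFrame, y=None):
        """Fit from a LSMEANS table with columns (population, treatment,
        lsmean, aridity) and optional se. ``y`` defaults to X['lsmean']."""
        df = X.copy()
        if y is not None:
            df["lsmean"] = np.asarray(y, float)
        for col in ("aridity", "treatment", "lsmean"):
            if col not in df.columns:
                raise ValueError(f"LSMEANS table lacks column {col!r}")
        if df["aridity"].nunique() < 3:
            raise ValueError(
                "need >= 3 distinct aridity values to identify a cline slope"
            )
        w = (1.0 / df["se"] ** 2 if (self.weight_by_precision and "se" in df.columns)
             else np.ones(len(df)))
        kwargs = dict(data=df, weights=np.asarray(w, float))
        full = smf.wls("lsmean ~ aridity * C(treatment)", **kwargs).fit()
        add = smf.wls("lsmean ~ aridity + C(treatment)", **kwargs).fit()

        # partial F-test of the interaction term
        df_num = int(add.df_resid - full.df_resid)
        df_den = int(full.df_resid)
        if df_den <= 0:
            raise ValueError("no residual degrees of freedom for the interaction test")
        # guard exactly- or near-perfect fits, where both SSRs vanish and the
        # F-ratio would be 0/0
        tiny = 1e-12 * (float(np.var(df["lsmean"])) * len(df) + 1e-300)
        diff = max(float(add.ssr - full.ssr), 0.0)
        if full.ssr <= tiny:
            f_int = np.inf if diff > tiny else 0.0
        else:
            f_int = float((diff / df_num) / (full.ssr / df_den))
        p_int = float(sps.f.sf(f_int, df_num, df_den))
        keep_interaction = self.force_interaction or p_int < self.alpha

        self.interaction_present_ = bool(p_int < self.alpha)
        self.model_used_ = "interaction" if keep_interaction else "additive"
        chosen = full if keep_interaction else add
        self.result_ = chosen

        # Type II marginal F-tests from the chosen model
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a2 = sm.stats.anova_lm(chosen, typ=2)
        def _term(name):
            row = a2.loc[name]
            return (float(row["F"]), float(row["PR(>F)"]),
                    (int(row["df"]), int(a2.loc["Residual", "df"])))
        f_a, p_a, dfs_a = _term("aridity")
        f_t, p_t, dfs_t = _term("C(treatment)")

        params = chosen.params
        cov = chosen.cov_params()
        self.slope_ = float(params["aridity"])
        self.slope_se_ = float(chosen.bse["aridity"])
        trt_terms = [t for t in params.index if t.startswith("C(treatment)")]
        self.treatment_effect_ = float(params[trt_terms[0]]) if trt_terms else 0.0

        # per-treatment marginal slopes (emtrends-style)
        treatments = sorted(df["treatment"].unique())
        ref = treatments[0]
        rows = []
        tcrit = sps.t.ppf(0.975, chosen.df_resid)
        for trt in treatments:
            if keep_interaction and trt != ref:
                iname = next(t for t in params.index
                             if t.startswith("aridity:") and f"[T.{trt}]" in t)
                slope = float(params["aridity"] + params[iname])
                var = float(cov.loc["aridity", "aridity"] + cov.loc[iname, iname]
                            + 2 * cov.loc["aridity", iname])
            else:
                slope = float(params["aridity"])
                var = float(cov.loc["aridity", "aridity"])
            se = float(np.sqrt(var))
            lo, hi = slope - tcrit * se, slope + tcrit * se
            rows.append({"treatment": trt, "slope": slope, "se": se,
                         "lower95": lo, "upper95": hi,
                         "nonzero": bool(lo > 0 or hi < 0)})
        self.marginal_slopes_ = pd.DataFrame(rows)
        self.fstats_ = {
            "aridity": (f_a, p_a, dfs_a),
            "treatment": (f_t, p_t, dfs_t),
            "interaction": (f_int, p_int, (df_num, df_den)),
        }
        return self

    def to_cline_fit(self) -> ClineFit:
        f = self.fstats_
        return ClineFit(
            trait=self.trait,
            slope_aridity=self.slope_, slope_se=self.slope_se_,
            treatment_effect=self.treatment_effect_,
            interaction_present=self.interaction_present_,
            f_aridity=f["aridity"][0], p_aridity=f["aridity"][1],
            df_aridity=f["aridity"][2],
            f_treatment=f["treatment"][0], p_treatment=f["treatment"][1],
            df_treatment=f["treatment"][2],
            f_interaction=f["interaction"][0], p_interaction=f["interaction"][1],
            df_interaction=f["interaction"][2],
            per_treatment=self.marginal_slopes_.copy(),
            model_used=self.model_used_,
        )


def _attach_aridity(means: pd.DataFrame, aridity: Mapping[str, AridityRecord] | Mapping[str, float]) -> pd.DataFrame:
    df = means.copy()
    vals = []
    for pop in df["population"]:
        if pop not in aridity:
            raise ValueError(f"no aridity record for population {pop!r}")
        rec = aridity[pop]
        vals.append(rec.aridity if isinstance(rec, AridityRecord) else float(rec))
    df["aridity"] = vals
    return df


def regress_cline(means: pd.DataFrame, aridity: Mapping, *, alpha: float = 0.05,
                  weight_by_precision: bool = False) -> ClineFit:
    """Regress one trait's LSMEANS on aridity x treatment (see
    :class:`ClineRegression`)."""
    df = _attach_aridity(means, aridity)
    trait = str(means["trait"].iloc[0]) if "trait" in means.columns else ""
    est = ClineRegression(alpha=alpha, weight_by_precision=weight_by_precision,
                          trait=trait).fit(df)
    return est.to_cline_fit()


def marginal_slopes(fit: ClineFit) -> pd.DataFrame:
    """Per-treatment aridity slopes with normal-approximation 95% CIs;
    ``nonzero`` flags a CI that excludes 0."""
    return fit.per_treatment.copy()


def holm_bonferroni(pvalues: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm's step-down multiple-testing procedure.

    Returns ``(reject, p_adjusted)`` at family-wise level ``alpha``;
    adjusted p-values are monotone in the usual step-down sense.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, p_adj


def fitness_cline(records: pd.DataFrame, aridity: Mapping, *, alpha: float = 0.05) -> ClineFit:
    """Test whether the fitness-aridity relationship differs between
    treatments.

    Computes population x treatment LSMEANS of relative fitness (fixed
    model), then fits LSMEAN ~ aridity x treatment. The interaction F-test
    has (1, 2 n_pop - 4) degrees of freedom, and per-treatment slopes come
    from the interaction model (post-hoc trends).
    """
    if "relative_fitness" not in records.columns:
        raise ValueError("records lack relative_fitness; call relative_fitness() first")
    cells = records.groupby(["population", "treatment"], observed=True)["relative_fitness"]
    means = cells.mean().reset_index().rename(columns={"relative_fitness": "lsmean"})
    means["trait"] = "relative_fitness"
    df = _attach_aridity(means, aridity)
    est = ClineRegression(alpha=alpha, force_interaction=True,
                          trait="relative_fitness").fit(df)
    return est.to_cline_fit()


def cline_table(std: StandardizedTraits, aridity: Mapping, *,
                experiment: str | None = None, model: str = "fixed",
                alpha: float = 0.05) -> tuple[pd.DataFrame, dict[str, ClineFit]]:
    """Fit every registry trait's cline and assemble the summary table with
    Holm-adjusted significance of the aridity term across the 13 traits."""
    if model not in ("fixed", "mixed"):
        raise ValueError(f"unknown model kind {model!r}")
    fits: dict[str, ClineFit] = {}
    for trait in std.values.columns:
        if model == "fixed":
            means = fit_lsmeans_fixed(std, trait, experiment)
        else:
            means, _ = fit_lsmeans_mixed(std, trait, experiment)
        fits[trait] = regress_cline(means, aridity, alpha=alpha)
    reject, p_adj = holm_bonferroni([f.p_aridity for f in fits.values()], alpha)
    for flag, f in zip(reject, fits.values()):
        f.holm_significant = bool(flag)
    table = pd.DataFrame([f.to_row() for f in fits.values()])
    table["p_aridity_holm"] = p_adj
    return table, fits
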