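"""Posterior sampling and propagation of uncertainty to derived vectors.

Point estimates of cline slopes and selection gradients are single
vectors; the quantities of scientific interest — the angle between two
such vectors and their norms — are nonlinear functions of them, so their
uncertainty is assessed by posterior simulation: draw coefficient vectors
from the Bayesian posterior of each underlying regression (10 000 draws by
default), push every draw through the slope/angle/norm computation, and
summarize the resulting distributions by their mean and equal-tailed 95%
credible interval.

Two samplers are provided:

* an exact conjugate normal-inverse-gamma sampler for linear models
  (independent draws, no burn-in), used for selection-gradient posteriors;
* a Gibbs sampler for Gaussian mixed models with crossed random
  intercepts, used for the population LSMEANS that feed the cline slopes
  (population fixed; treatment, and patch/block where present, random).

Priors are weakly informative: essentially flat normals on coefficients
(precision 1e-8) and inverse-gamma(0.001, 0.001) on variances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .geometry import TraitVector, VectorComparison, angle_between, vector_norm
from .study_data import StandardizedTraits

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "PosteriorDraws",
    "CredibleSummary",
    "BayesianLinearRegression",
    "MixedModelGibbs",
    "sample_posterior_linear",
    "sample_posterior_mixed",
    "sample_population_lsmeans",
    "propagate_cline_draws",
    "compare_vectors_posterior",
    "summarize_scalar_draws",
    "split_rhat",
]

DEFAULT_N_DRAWS = 10_000


@dataclass(frozen=True)
class PriorSpec:
    """Weakly-informative defaults approximating the common R samplers:
    coefficient precision ``coef_precision`` (flat in the limit -> 0) and
    inverse-gamma(``ig_shape``, ``ig_scale``) on every variance."""

    coef_precision: float = 1e-8
    ig_shape: float = 0.001
    ig_scale: float = 0.001

    def validate(self) -> None:
        if self.coef_precision < 0:
            raise ValueError("coef_precision must be >= 0")
        if self.ig_shape <= 0 or self.ig_scale <= 0:
            raise ValueError("inverse-gamma prior parameters must be positive")


@dataclass
class PosteriorDraws:
    """Labeled matrix of posterior draws: one column per parameter."""

    labels: tuple[str, ...]
    draws: np.ndarray          # n_draws x n_params
    seed: int
    model: str = ""
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.draws = np.asarray(self.draws, float)
        self.labels = tuple(self.labels)
        if self.draws.ndim != 2 or self.draws.shape[1] != len(self.labels):
            raise ValueError(
                f"draws shape {self.draws.shape} does not match "
                f"{len(self.labels)} labels"
            )
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("posterior draws contain non-finite values")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.draws[:, self.labels.index(label)]

    def select(self, labels: Sequence[str]) -> "PosteriorDraws":
        idx = [self.labels.index(l) for l in labels]
        return PosteriorDraws(tuple(labels), self.draws[:, idx], self.seed, self.model)


@dataclass(frozen=True)
class CredibleSummary:
    """Posterior mean and equal-tailed 95% credible interval."""

    mean: float
    lower95: float
    upper95: float
    n_draws: int

    def excludes(self, value: float) -> bool:
        return value < self.lower95 or value > self.upper95


def summarize_scalar_draws(draws: Sequence[float], *, min_draws: int = 1000) -> CredibleSummary:
    """Mean and central 2.5/97.5% quantile interval of scalar draws."""
    x = np.asarray(draws, float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D array of scalar draws")
    if len(x) < min_draws:
        raise ValueError(f"need >= {min_draws} draws, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("draws contain non-finite values")
    lo, hi = np.quantile(x, [0.025, 0.975])
    s = CredibleSummary(float(np.mean(x)), float(lo), float(hi), len(x))
    if not (s.lower95 <= s.mean <= s.upper95):
        logger.warning(
            "posterior mean %.4g lies outside the central interval (%.4g, %.4g); "
            "the distribution is strongly skewed", s.mean, s.lower95, s.upper95)
    return s


# ---------------------------------------------------------------------------
# exact conjugate sampler for the linear model
# ---------------------------------------------------------------------------

class BayesianLinearRegression(BaseEstimator):
    """Conjugate normal-inverse-gamma posterior for a Gaussian linear model.

    With prior b ~ N(0, tau^-1 I), sigma^2 ~ IG(a0, b0), the posterior is
    available in closed form and is sampled exactly (independent draws, no
    Markov chain, no burn-in).

    Fitted attributes: ``posterior_mean_``, ``posterior_cov_scale_`` (the
    matrix V with cov(b | sigma^2) = sigma^2 V), ``ig_shape_``,
    ``ig_scale_``.
    """

    def __init__(self, prior: PriorSpec = PriorSpec(), n_draws: int = DEFAULT_N_DRAWS,
                 seed: int = 0):
        self.prior = prior
        self.n_draws = n_draws
        self.seed = seed

    def fit(self, X, y):
        self.prior.validate()
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n, p = X.shape
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("design matrix is rank deficient")
        xtx = X.T @ X + self.prior.coef_precision * np.eye(p)
        v = np.linalg.inv(xtx)
        m = v @ (X.T @ y)
        self.posterior_mean_ = m
        self.posterior_cov_scale_ = v
        self.ig_shape_ = self.prior.ig_shape + n / 2.0
        self.ig_scale_ = self.prior.ig_scale + 0.5 * float(y @ y - m @ xtx @ m)
        self._chol_v = np.linalg.cholesky(v)
        return self

    def sample(self, n_draws: int | None = None, seed: int | None = None) -> np.ndarray:
        """Draw (coefficients, sigma2) jointly; returns n_draws x (p + 1)."""
        n_draws = self.n_draws if n_draws is None else n_draws
        seed = self.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        p = len(self.posterior_mean_)
        sigma2 = self.ig_scale_ / rng.gamma(self.ig_shape_, 1.0, size=n_draws)
        eps = rng.standard_normal((n_draws, p))
        coefs = self.posterior_mean_ + np.sqrt(sigma2)[:, None] * (eps @ self._chol_v.T)
        return np.column_stack([coefs, sigma2])

    def closed_form_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Analytic posterior mean and covariance of the coefficients
        (multivariate-t moments), for self-checks against the sampled
        draws."""
        a, b = self.ig_shape_, self.ig_scale_
        if a <= 1:
            raise ValueError("posterior variance undefined for shape <= 1")
        cov = (b / (a - 1.0)) * self.posterior_cov_scale_
        return self.posterior_mean_.copy(), cov


def sample_posterior_linear(
    y, X, n_draws: int = DEFAULT_N_DRAWS, prior: PriorSpec = PriorSpec(),
    seed: int = 0, labels: Sequence[str] | None = None,
) -> PosteriorDraws:
    """Exact draws from the conjugate posterior of a linear regression.

    Returns coefficient columns (named by ``labels``) plus ``sigma2``.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    X = np.asarray(X, float)
    est = BayesianLinearRegression(prior=prior, n_draws=n_draws, seed=seed).fit(X, y)
    draws = est.sample()
    if labels is None:
        labels = tuple(f"b{i}" for i in range(X.shape[1]))
    cols = tuple(labels) + ("sigma2",)
    out = PosteriorDraws(cols, draws, seed, model="conjugate linear")
    mean, cov = est.posterior_mean_, None
    out.diagnostics["posterior_mean_closed_form"] = mean.tolist()
    return out


# ---------------------------------------------------------------------------
# Gibbs sampler for the Gaussian mixed model
# ---------------------------------------------------------------------------

class MixedModelGibbs(BaseEstimator):
    """Gibbs sampler for y = X b + sum_k Z_k u_k + e with crossed random
    intercepts u_k ~ N(0, s2_k I) and e ~ N(0, s2_e I).

    The chain alternates draws of (b | rest), each (u_k | rest), and all
    variances (inverse-gamma full conditionals). Draws are returned after
    ``burn_in`` iterations, thinned by ``thin``; a split-half Rhat per
    fixed effect and a crude effective sample size are attached as
    diagnostics and checked against ``rhat_threshold``.
    """

    def __init__(self, prior: PriorSpec = PriorSpec(), n_draws: int = DEFAULT_N_DRAWS,
                 burn_in: int = 2000, thin: int = 1, seed: int = 0,
                 rhat_threshold: float = 1.05):
        self.prior = prior
        self.n_draws = n_draws
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.rhat_threshold = rhat_threshold

    def fit(self, X, y, groupings: Mapping[str, Sequence] | None = None,
            labels: Sequence[str] | None = None):
        self.prior.validate()
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n, p = X.shape
        groupings = groupings or {}
        group_idx: dict[str, np.ndarray] = {}
        group_sizes: dict[str, np.ndarray] = {}
        for name, codes in groupings.items():
            codes = pd.Categorical(np.asarray(codes))
            if len(codes.categories) < 2:
                raise ValueError(f"random grouping {name!r} needs >= 2 levels")
            idx = np.asarray(codes.codes)
            group_idx[name] = idx
            group_sizes[name] = np.bincount(idx)

        rng = np.random.default_rng(self.seed)
        a0, b0 = self.prior.ig_shape, self.prior.ig_scale
        tau0 = self.prior.coef_precision

        # Few-level groupings (e.g. a 2-level treatment factor) compete with
        # the fixed effects for the overall level and mix badly if updated
        # separately, so they are folded into one joint Gaussian block with
        # the fixed effects; many-level groupings get cheap per-level updates.
        small: list[str] = []
        budget = 64 - p
        for k in sorted(group_idx, key=lambda k: len(group_sizes[k])):
            q = len(group_sizes[k])
            if q <= budget:
                small.append(k)
                budget -= q
        large = [k for k in group_idx if k not in small]
        blocks = [np.eye(len(group_sizes[k]))[group_idx[k]] for k in small]
        W = np.column_stack([X] + blocks) if blocks else X
        q_small = [len(group_sizes[k]) for k in small]
        offs = np.cumsum([p] + q_small)
        wtw = W.T @ W
        d = W.shape[1]

        coef = np.zeros(d)
        coef[:p] = np.linalg.lstsq(X, y, rcond=None)[0]
        u = {k: np.zeros(len(group_sizes[k])) for k in large}
        s2 = {k: 1.0 for k in group_idx}
        s2e = max(float(np.var(y - X @ coef[:p])), 1e-6)

        n_keep = self.n_draws
        total = self.burn_in + n_keep * self.thin
        out = np.empty((n_keep, p + len(group_idx) + 1))
        kept = 0
        for it in range(total):
            # joint (fixed effects + small random effects) block
            resid_large = y.copy()
            for k in large:
                resid_large -= u[k][group_idx[k]]
            prior_prec = np.full(d, tau0)
            for j, k in enumerate(small):
                prior_prec[offs[j]:offs[j + 1]] = 1.0 / s2[k]
            prec = wtw / s2e + np.diag(prior_prec)
            chol = np.linalg.cholesky(prec)
            rhs = W.T @ resid_large / s2e
            mean = np.linalg.solve(prec, rhs)
            # draw ~ N(mean, prec^-1) via the Cholesky of the precision
            z = rng.standard_normal(d)
            coef = mean + np.linalg.solve(chol.T, z)
            base = y - W @ coef
            # large groupings: per-level scalar updates
            for k in large:
                r = base.copy()
                for k2 in large:
                    if k2 != k:
                        r -= u[k2][group_idx[k2]]
                sums = np.bincount(group_idx[k], weights=r)
                prec_u = group_sizes[k] / s2e + 1.0 / s2[k]
                mean_u = (sums / s2e) / prec_u
                u[k] = mean_u + rng.standard_normal(len(mean_u)) / np.sqrt(prec_u)
            # variance components
            for j, k in enumerate(small):
                uk = coef[offs[j]:offs[j + 1]]
                s2[k] = float((b0 + 0.5 * uk @ uk)
                              / rng.gamma(a0 + len(uk) / 2.0, 1.0))
            for k in large:
                s2[k] = float((b0 + 0.5 * u[k] @ u[k])
                              / rng.gamma(a0 + len(u[k]) / 2.0, 1.0))
            resid = base.copy()
            for k in large:
                resid -= u[k][group_idx[k]]
            s2e = float((b0 + 0.5 * resid @ resid) / rng.gamma(a0 + n / 2.0, 1.0))
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                out[kept, :p] = coef[:p]
                out[kept, p:p + len(group_idx)] = [s2[k] for k in group_idx]
                out[kept, -1] = s2e
                kept += 1

        if labels is None:
            labels = [f"b{i}" for i in range(p)]
        cols = tuple(labels) + tuple(f"s2_{k}" for k in group_idx) + ("s2_resid",)
        rhats = {cols[j]: split_rhat(out[:, j]) for j in range(p)}
        worst = max(rhats.values()) if rhats else 1.0
        self.draws_ = PosteriorDraws(
            cols, out, self.seed, model="gibbs mixed",
            diagnostics={"split_rhat": rhats,
                         "ess": {cols[j]: _ess(out[:, j]) for j in range(p)}},
        )
        if worst > self.rhat_threshold:
            raise RuntimeError(
                f"Gibbs chain not converged: worst split-Rhat {worst:.4f} > "
                f"{self.rhat_threshold}; diagnostics: {rhats}"
            )
        return self


def split_rhat(chain: np.ndarray) -> float:
    """Split-half potential scale reduction factor of a single chain."""
    x = np.asarray(chain, float)
    m = len(x) // 2
    halves = np.stack([x[:m], x[m:2 * m]])
    within = halves.var(axis=1, ddof=1).mean()
    between = m * halves.mean(axis=1).var(ddof=1)
    if within <= 0:
        return 1.0
    var_plus = (m - 1) / m * within + between / m
    return float(np.sqrt(var_plus / within))


def _ess(chain: np.ndarray, max_lag: int = 200) -> float:
    x = np.asarray(chain, float)
    n = len(x)
    x = x - x.mean()
    v = x @ x / n
    if v == 0:
        return float(n)
    s = 1.0
    for lag in range(1, min(max_lag, n - 1)):
        rho = (x[:-lag] @ x[lag:]) / (n * v)
        if rho < 0.05:
            break
        s += 2.0 * rho
    return float(n / s)


def sample_posterior_mixed(
    y, X, groupings: Mapping[str, Sequence], n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0, prior: PriorSpec = PriorSpec(), burn_in: int = 2000,
    thin: int = 1, labels: Sequence[str] | None = None,
    rhat_threshold: float = 1.05,
) -> PosteriorDraws:
    """Gibbs draws from the Gaussian mixed model posterior (see
    :class:`MixedModelGibbs`)."""
    est = MixedModelGibbs(prior=prior, n_draws=n_draws, burn_in=burn_in,
                          thin=thin, seed=seed, rhat_threshold=rhat_threshold)
    est.fit(X, y, groupings=groupings, labels=labels)
    return est.draws_


def sample_population_lsmeans(
    std: StandardizedTraits, trait: str, experiment: str,
    n_draws: int = DEFAULT_N_DRAWS, seed: int = 0, burn_in: int = 2000,
    prior: PriorSpec = PriorSpec(),
) -> PosteriorDraws:
    """Posterior draws of population-level means of one standardized trait.

    Population enters as a fixed factor (cell-means coding, so each
    coefficient is that population's adjusted mean); treatment — and patch
    and block where the design has them — enter as random intercepts, so
    the population means are marginal over treatment.
    """
    mask = (std.groups["experiment"] == experiment).to_numpy()
    if not mask.any():
        raise ValueError(f"no rows for experiment {experiment!r}")
    y = std.values.loc[mask, trait].to_numpy()
    pops = pd.Categorical(std.design.loc[mask, "population"].to_numpy())
    X = np.eye(len(pops.categories))[pops.codes]
    groupings: dict[str, np.ndarray] = {
        "treatment": std.groups.loc[mask, "treatment"].to_numpy()}
    if "patch" in std.design.columns:
        patch = std.design.loc[mask, "patch"].to_numpy()
        if pd.unique(patch).size >= 2:
            groupings["patch"] = patch
    if "block" in std.design.columns:
        block = std.design.loc[mask, "block"].to_numpy()
        if pd.unique(block).size >= 2 and experiment != "field2019":
            groupings["block"] = block
    return sample_posterior_mixed(
        y, X, groupings, n_draws=n_draws, seed=seed, prior=prior,
        burn_in=burn_in, labels=list(pops.categories))


def propagate_cline_draws(
    lsmean_draws: Mapping[str, PosteriorDraws], aridity: Mapping[str, float],
) -> PosteriorDraws:
    """Turn LSMEAN draws into cline-slope draws, one column per trait.

    For each posterior draw of the population means of a trait, the slope
    of the regression of those means on source aridity is computed; the
    result is an (n_draws x n_traits) matrix of Delta-z component draws.
    """
    traits = list(lsmean_draws)
    slope_cols = []
    n_ref = None
    for trait in traits:
        d = lsmean_draws[trait]
        pops = [l for l in d.labels if not l.startswith("s2")]
        missing = [p for p in pops if p not in aridity]
        if missing:
            raise ValueError(f"no aridity value for population(s) {missing}")
        a = np.array([float(getattr(aridity[p], "aridity", aridity[p])) for p in pops])
        A = np.column_stack([np.ones(len(a)), a])
        hat = np.linalg.solve(A.T @ A, A.T)[1]      # slope row of (A'A)^-1 A'
        block = d.select(pops).draws
        if n_ref is None:
            n_ref = block.shape[0]
        elif block.shape[0] != n_ref:
            raise ValueError("trait draw matrices have unequal n_draws")
        slope_cols.append(block @ hat)
    return PosteriorDraws(tuple(traits), np.column_stack(slope_cols),
                          seed=lsmean_draws[traits[0]].seed,
                          model="cline slopes propagated from LSMEAN draws")


def compare_vectors_posterior(
    draws_u: PosteriorDraws, draws_v: PosteriorDraws,
    kind_u: str = "generic", kind_v: str = "generic",
    max_dropped_fraction: float = 0.01,
) -> VectorComparison:
    """Angle and norms of two vector posteriors with credible intervals.

    Draws are paired row by row; any pair in which either vector has zero
    norm is dropped (logged; more than ``max_dropped_fraction`` dropped is
    an error). The point estimate is computed from the posterior-mean
    vectors; the verdict comes from whether the angle CI excludes 90 deg.
    """
    if draws_u.labels != draws_v.labels:
        raise ValueError(
            f"trait orderings differ: {draws_u.labels} vs {draws_v.labels}")
    if draws_u.n_draws != draws_v.n_draws:
        raise ValueError("draw matrices must have equal n_draws")
    U, V = draws_u.draws, draws_v.draws
    nu = np.linalg.norm(U, axis=1)
    nv = np.linalg.norm(V, axis=1)
    ok = (nu > 0) & (nv > 0)
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("compare_vectors_posterior: dropped %d zero-norm draw pair(s)",
                       dropped)
        if dropped > max_dropped_fraction * len(ok):
            raise ValueError(
                f"{dropped} of {len(ok)} draws have zero norm "
                f"(> {max_dropped_fraction:.0%})"
            )
    uh = U[ok] / nu[ok, None]
    vh = V[ok] / nv[ok, None]
    # Kahan's angle formulation, as in geometry.angle_between
    angles = np.degrees(2.0 * np.arctan2(
        np.linalg.norm(uh - vh, axis=1), np.linalg.norm(uh + vh, axis=1)))
    u_mean = TraitVector(draws_u.labels, U.mean(axis=0), kind_u)
    v_mean = TraitVector(draws_v.labels, V.mean(axis=0), kind_v)
    min_draws = min(1000, len(angles))
    return VectorComparison(
        vector_u=u_mean, vector_v=v_mean,
        angle_deg=angle_between(u_mean, v_mean),
        norm_u=vector_norm(u_mean), norm_v=vector_norm(v_mean),
        angle_summary=summarize_scalar_draws(angles, min_draws=min_draws),
        norm_u_summary=summarize_scalar_draws(nu[ok], min_draws=min_draws),
        norm_v_summary=summarize_scalar_draws(nv[ok], min_draws=min_draws),
        n_draws_dropped=dropped,
    )
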