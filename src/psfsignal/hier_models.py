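"""Hierarchical Bayesian models of phylogenetic signal in feedback responses.

Observed dissimilarity responses r_ij (replicate i of species pair j, with
known sampling variance sigma2_r_ij) are modelled with a two-level
measurement hierarchy,

    r_ij   ~ Normal(rstar_ij, sigma2_r_ij)
    rstar_ij ~ Normal(rstar_j, sigma2_w)

and seven competing pair-level models of how the latent pair mean rstar_j
changes with phylogenetic distance t_j (in units of 100 Myr):

    1  rstar_j ~ Normal(0, sigma2)                  no signal
    2  rstar_j ~ Normal(beta*t_j, sigma2)           directional trend
    3  rstar_j ~ Normal(0, sigma2 + k*t_j)          gradual (Brownian) divergence
    4  rstar_j ~ Normal(beta*t_j, sigma2 + k*t_j)   trend + gradual divergence
    5  rstar_j ~ t(0, s2, upsilon + k*t_j)          heavy-tailed divergence
    6  rstar_j ~ t(beta*t_j, s2, upsilon + k*t_j)   trend + heavy tails
    7  rstar_j ~ t(beta*t_j + alpha_f, s2, upsilon + k*t_j),
       alpha_f ~ t(0, s2_alpha, nu_alpha)           family-pair shifts

For the Student-t models smaller degrees of freedom mean heavier tails and
larger variance, so a negative k is a *divergent* signal (kurtosis and
variance grow with distance).

Fitting integrates the latent layers out of the likelihood: the replicate
level collapses analytically (r_ij | rstar_j ~ Normal(rstar_j,
sigma2_w + sigma2_r_ij)); the pair level is then marginalized exactly for
normal models (rank-one multivariate normal via Sherman-Morrison) and by
Gauss-Hermite quadrature against the pair's collapsed normal for Student-t
models. What remains is a low-dimensional marginal posterior sampled with a
seeded componentwise adaptive random-walk Metropolis sampler. Pointwise
per-pair log-likelihoods are recorded for every retained draw, which is what
leave-one-out model comparison consumes downstream.

Priors follow the uninformative choices used throughout: Normal(0, variance
10) on location-type parameters (beta, k), Uniform(0, 10) on every standard
deviation (sigma, sigma_w, s, s_alpha), Uniform(2, 100) on kurtosis
parameters (upsilon, nu_alpha) so the pair-level variance exists, with the
joint support truncated so that every pair's variance (normal models) or
degrees of freedom minus two (t models) stays positive at the observed
distances.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .dataset_io import SpeciesPair

__all__ = [
    "ModelSpec",
    "PairedData",
    "FeedbackSignalModel",
    "PosteriorResult",
    "MODEL_SUMMARIES",
    "build_model",
    "fit",
    "gelman_rubin",
    "posterior_summary",
]

_LOG2PI = np.log(2.0 * np.pi)

#: Human-readable one-line summaries, indexed by model id.
MODEL_SUMMARIES = {
    1: "Constant variance without directional trend",
    2: "Constant variance with directional trend",
    3: "Gradual divergence without directional trend",
    4: "Gradual divergence with directional trend",
    5: "Co-evolutionary shifts without directional trend",
    6: "Co-evolutionary shifts with directional trend",
    7: "Family-level shifts with directional trend",
}

_MODEL_FLAGS = {
    # model_id: (family, trend, variance_growth, family_effects)
    1: ("normal", False, False, False),
    2: ("normal", True, False, False),
    3: ("normal", False, True, False),
    4: ("normal", True, True, False),
    5: ("student_t", False, True, False),
    6: ("student_t", True, True, False),
    7: ("student_t", True, True, True),
}


class ModelConfigurationError(ValueError):
    """A model specification is inconsistent or unsatisfiable on the data."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one of the seven pair-level models.

    ``params`` optionally carries fixed (e.g. true generating) parameter
    values; it is ignored during fitting, where all parameters are free.
    """

    model_id: int
    params: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.model_id not in _MODEL_FLAGS:
            raise ModelConfigurationError(f"model_id must be 1..7, got {self.model_id}")

    @property
    def family(self) -> str:
        return _MODEL_FLAGS[self.model_id][0]

    @property
    def trend(self) -> bool:
        return _MODEL_FLAGS[self.model_id][1]

    @property
    def variance_growth(self) -> bool:
        return _MODEL_FLAGS[self.model_id][2]

    @property
    def family_effects(self) -> bool:
        return _MODEL_FLAGS[self.model_id][3]

    def parameter_names(self) -> list[str]:
        """Scalar parameter names, in sampling order (excludes alpha vector)."""
        names = ["sigma_w"]
        if self.trend:
            names.append("beta")
        if self.family == "normal":
            names.append("sigma")
            if self.variance_growth:
                names.append("k")
        else:
            names += ["s", "upsilon", "k"]
        if self.family_effects:
            names += ["s_alpha", "nu_alpha"]
        return names


@dataclass
class PairedData:
    """Flat array view of a list of species pairs, ready for likelihoods."""

    r: np.ndarray  # (n_obs,) observed responses
    var_r: np.ndarray  # (n_obs,) known sampling variances
    pair_index: np.ndarray  # (n_obs,) int index into pairs
    t100: np.ndarray  # (n_pairs,) distance in 100-Myr units
    n_reps: np.ndarray  # (n_pairs,) replicates per pair
    family_index: np.ndarray  # (n_pairs,) int index into family_pairs
    family_pairs: list[str]  # family-pair labels, sorted
    pair_ids: list[str]

    @property
    def n_pairs(self) -> int:
        return len(self.t100)

    @property
    def n_families(self) -> int:
        return len(self.family_pairs)

    @classmethod
    def from_pairs(cls, pairs: Sequence[SpeciesPair]) -> "PairedData":
        if len(pairs) < 2:
            raise ModelConfigurationError("need at least 2 species pairs")
        fam_labels = sorted({p.family_pair_id for p in pairs})
        fam_lookup = {f: i for i, f in enumerate(fam_labels)}
        r, var_r, idx = [], [], []
        t100, n_reps, fam_idx, pair_ids = [], [], [], []
        for j, pair in enumerate(pairs):
            if pair.n_replicates < 1:
                raise ModelConfigurationError(f"pair {pair.pair_id} has no observations")
            r.extend(o.r for o in pair.observations)
            var_r.extend(o.var_r for o in pair.observations)
            idx.extend([j] * pair.n_replicates)
            t100.append(pair.t_myr / 100.0)
            n_reps.append(pair.n_replicates)
            fam_idx.append(fam_lookup[pair.family_pair_id])
            pair_ids.append(pair.pair_id)
        return cls(
            r=np.asarray(r, float),
            var_r=np.asarray(var_r, float),
            pair_index=np.asarray(idx, int),
            t100=np.asarray(t100, float),
            n_reps=np.asarray(n_reps, int),
            family_index=np.asarray(fam_idx, int),
            family_pairs=fam_labels,
            pair_ids=pair_ids,
        )


def _t_logpdf(x: np.ndarray, scale: float, df: float) -> np.ndarray:
    """Log density of the three-parameter Student-t at location zero."""
    z2 = (np.asarray(x, float) / scale) ** 2
    return (
        gammaln((df + 1.0) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * np.log(df * np.pi)
        - np.log(scale)
        - (df + 1.0) / 2.0 * np.log1p(z2 / df)
    )


def _collapse_replicates(data: PairedData, sigma_w2: float):
    """Sufficient statistics of the replicate level given sigma2_w.

    With d_i = sigma2_w + sigma2_r_i, the product of replicate normals in
    rstar_j is proportional to a single normal with precision S1 = sum(1/d_i)
    and mean m = sum(r_i/d_i)/S1; the proportionality constant is returned in
    log form so pair-level integrals stay exact.
    """
    d = sigma_w2 + data.var_r
    w = 1.0 / d
    n = data.n_pairs
    S1 = np.bincount(data.pair_index, weights=w, minlength=n)
    Sr = np.bincount(data.pair_index, weights=w * data.r, minlength=n)
    Srr = np.bincount(data.pair_index, weights=w * data.r**2, minlength=n)
    Slogd = np.bincount(data.pair_index, weights=np.log(d), minlength=n)
    return S1, Sr, Srr, Slogd


class FeedbackSignalModel:
    """A fittable model: spec + data + marginal likelihood machinery."""

    def __init__(
        self,
        spec: ModelSpec,
        pairs: Sequence[SpeciesPair] | PairedData,
        quadrature_nodes: int = 64,
    ):
        self.spec = spec
        self.data = pairs if isinstance(pairs, PairedData) else PairedData.from_pairs(pairs)
        nodes, weights = np.polynomial.hermite.hermgauss(quadrature_nodes)
        self._gh_nodes = nodes
        self._gh_logw = np.log(weights) - 0.5 * np.log(np.pi)
        self._stat_cache: tuple | None = None  # (sigma_w2, collapsed stats)
        self._t_max = float(self.data.t100.max())
        if spec.params is not None:
            self._check_support(dict(spec.params))

    # -- support ---------------------------------------------------------

    def _check_support(self, params: Mapping[str, float]) -> None:
        if not self._in_support(params):
            raise ModelConfigurationError(
                f"model {self.spec.model_id} parameters {dict(params)} leave the "
                f"support (variance or df constraint violated at t_max={self._t_max:g})"
            )

    def _in_support(self, params: Mapping[str, float]) -> bool:
        spec = self.spec
        if not 0.0 < params.get("sigma_w", 1.0) < 10.0:
            return False
        if spec.family == "normal":
            sigma = params.get("sigma", 1.0)
            if not 0.0 < sigma < 10.0:
                return False
            if spec.variance_growth:
                k = params["k"]
                if sigma**2 + k * self._t_max <= 0.0 or sigma**2 + k * 0.0 <= 0.0:
                    return False
        else:
            if not 0.0 < params.get("s", 1.0) < 10.0:
                return False
            upsilon = params.get("upsilon", 30.0)
            if not 2.0 < upsilon < 100.0:
                return False
            k = params.get("k", 0.0)
            if upsilon + k * self._t_max <= 2.0 or upsilon + k * 0.0 <= 2.0:
                return False
        if spec.family_effects:
            if not 0.0 < params.get("s_alpha", 1.0) < 10.0:
                return False
            if not 2.0 < params.get("nu_alpha", 30.0) < 100.0:
                return False
        return True

    # -- likelihood ------------------------------------------------------

    def pointwise_loglik(
        self, params: Mapping[str, float | np.ndarray], subset: np.ndarray | None = None
    ) -> np.ndarray:
        """Per-pair log of the fully marginalized likelihood.

        Each entry is log p(r_j1..r_jn | params): the latent replicate and
        pair levels are integrated out, so these are directly the pointwise
        contributions used for LOO. ``subset`` restricts computation to the
        given pair indices (used for family-effect updates).
        """
        data = self.data
        spec = self.spec
        sigma_w2 = float(params["sigma_w"]) ** 2
        if self._stat_cache is None or self._stat_cache[0] != sigma_w2:
            self._stat_cache = (sigma_w2, _collapse_replicates(data, sigma_w2))
        S1, Sr, Srr, Slogd = self._stat_cache[1]
        if subset is not None:
            S1, Sr, Srr, Slogd = S1[subset], Sr[subset], Srr[subset], Slogd[subset]
            t = data.t100[subset]
            n_reps = data.n_reps[subset]
            fam = data.family_index[subset]
        else:
            t = data.t100
            n_reps = data.n_reps
            fam = data.family_index

        mu = np.zeros_like(t)
        if spec.trend:
            mu = float(params["beta"]) * t
        if spec.family_effects:
            alpha = np.asarray(params["alpha"], float)
            mu = mu + alpha[fam]

        if spec.family == "normal":
            sigma2 = float(params["sigma"]) ** 2
            V = sigma2 + (float(params["k"]) * t if spec.variance_growth else 0.0)
            denom = 1.0 + V * S1
            quad = Srr - 2 * mu * Sr + mu**2 * S1 - V * (Sr - mu * S1) ** 2 / denom
            return -0.5 * (n_reps * _LOG2PI + Slogd + np.log(denom) + quad)

        # Student-t pair level: collapse replicates to one normal, then
        # integrate t(x; mu, s, df) against Normal(x; m, v) by Gauss-Hermite.
        s = float(params["s"])
        df = float(params["upsilon"]) + float(params["k"]) * t
        m = Sr / S1
        v = 1.0 / S1
        logc = (
            0.5 * np.log(2.0 * np.pi * v)
            - 0.5 * (Srr - m**2 * S1)
            - 0.5 * (n_reps * _LOG2PI + Slogd)
        )
        x = m[:, None] + np.sqrt(2.0 * v)[:, None] * self._gh_nodes[None, :]
        z2 = ((x - mu[:, None]) / s) ** 2
        df_col = df[:, None]
        logt = (
            gammaln((df_col + 1.0) / 2.0)
            - gammaln(df_col / 2.0)
            - 0.5 * np.log(df_col * np.pi)
            - np.log(s)
            - (df_col + 1.0) / 2.0 * np.log1p(z2 / df_col)
        )
        return logc + logsumexp(logt + self._gh_logw[None, :], axis=1)

    def log_prior(self, params: Mapping[str, float | np.ndarray]) -> float:
        """Joint log prior density (unnormalized over truncation)."""
        if not self._in_support(params):
            return -np.inf
        lp = 0.0
        for name in ("beta", "k"):
            if name in params:
                lp += -0.5 * float(params[name]) ** 2 / 10.0 - 0.5 * np.log(
                    2.0 * np.pi * 10.0
                )
        # uniform priors contribute constants on their support
        if self.spec.family_effects:
            alpha = np.asarray(params["alpha"], float)
            lp += float(
                np.sum(_t_logpdf(alpha, float(params["s_alpha"]), float(params["nu_alpha"])))
            )
        return lp

    def log_posterior(self, params: Mapping[str, float | np.ndarray]) -> float:
        lp = self.log_prior(params)
        if not np.isfinite(lp):
            return -np.inf
        return lp + float(np.sum(self.pointwise_loglik(params)))

    # -- initialisation --------------------------------------------------

    def initial_params(self, rng: np.random.Generator) -> dict:
        """Data-informed start values with chain-specific jitter."""
        data = self.data
        pair_means = (
            np.bincount(data.pair_index, weights=data.r, minlength=data.n_pairs)
            / data.n_reps
        )
        spread = float(np.std(pair_means))
        spread = min(max(spread, 0.1), 5.0)
        jig = lambda x: float(np.clip(x * np.exp(0.1 * rng.standard_normal()), 1e-3, 9.9))
        params: dict = {"sigma_w": jig(max(0.3, 0.3 * spread))}
        if self.spec.trend:
            params["beta"] = 0.05 * rng.standard_normal()
        if self.spec.family == "normal":
            params["sigma"] = jig(spread)
            if self.spec.variance_growth:
                params["k"] = abs(0.02 * rng.standard_normal())
        else:
            params["s"] = jig(0.8 * spread)
            params["upsilon"] = float(np.clip(20.0 * np.exp(0.1 * rng.standard_normal()), 2.5, 99.0))
            params["k"] = 0.02 * rng.standard_normal()
            if params["upsilon"] + params["k"] * self._t_max <= 2.0:
                params["k"] = 0.0
        if self.spec.family_effects:
            params["s_alpha"] = jig(0.5 * spread)
            params["nu_alpha"] = float(np.clip(20.0 * np.exp(0.1 * rng.standard_normal()), 2.5, 99.0))
            params["alpha"] = 0.01 * rng.standard_normal(self.data.n_families)
        return params


@dataclass
class PosteriorResult:
    """Posterior draws and diagnostics from one fitted model.

    ``draws`` maps parameter names to arrays of shape (chains, kept draws)
    — (chains, kept, n_family_pairs) for ``alpha``. ``pointwise_loglik`` has
    shape (chains, kept, n_pairs) and holds the marginal per-pair
    log-likelihood at each retained draw.
    """

    spec: ModelSpec
    draws: dict[str, np.ndarray]
    pointwise_loglik: np.ndarray
    rhat: dict[str, float]
    seed: int
    pair_ids: list[str]
    family_pairs: list[str]
    warnings: list[str] = field(default_factory=list)
    runtime_s: float = 0.0
    n_chains: int = 0
    n_iterations: int = 0
    n_burn_in: int = 0

    def flat(self, name: str) -> np.ndarray:
        """All chains concatenated for one parameter."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def to_inference_data(self) -> az.InferenceData:
        posterior = {
            k: (v if v.ndim == 2 else v) for k, v in self.draws.items()
        }
        return az.from_dict(
            posterior=posterior,
            log_likelihood={"pair": self.pointwise_loglik},
        )


def build_model(
    spec: ModelSpec | int,
    pairs: Sequence[SpeciesPair] | PairedData,
    quadrature_nodes: int = 64,
) -> FeedbackSignalModel:
    """Construct a fittable model for one of the seven specifications."""
    if isinstance(spec, int):
        spec = ModelSpec(spec)
    return FeedbackSignalModel(spec, pairs, quadrature_nodes=quadrature_nodes)


_TARGET_ACCEPT = 0.44  # optimal-ish for one-dimensional random-walk updates


def fit(
    model: FeedbackSignalModel,
    chains: int = 3,
    iterations: int = 10_000,
    burn_in: int = 1_000,
    seed: int = 0,
    thin: int = 1,
    two_stage: bool = False,
) -> PosteriorResult:
    """Sample the marginal posterior by componentwise adaptive Metropolis.

    Proposal scales adapt toward a 44% acceptance rate during burn-in only
    (diminishing adaptation would also be valid; freezing is simpler and
    keeps the post-burn-in chain exactly Markovian). Identical ``seed``
    yields bit-identical draws. ``thin`` keeps every ``thin``-th post-burn-in
    iteration.

    ``two_stage`` switches to the plug-in sensitivity variant: each pair is
    first reduced to its empirical mean response with a fixed standard error,
    and the pair-level model is fitted to those estimates instead of the full
    hierarchy (within-pair variance is then not estimated from the data).
    """
    if chains < 2:
        raise ValueError("need at least 2 chains for convergence diagnostics")
    if two_stage:
        model = _two_stage_model(model)
    t0 = time.perf_counter()
    data = model.data
    scalar_names = model.spec.parameter_names()
    has_alpha = model.spec.family_effects
    n_keep = iterations // thin
    draws = {name: np.empty((chains, n_keep)) for name in scalar_names}
    if has_alpha:
        draws["alpha"] = np.empty((chains, n_keep, data.n_families))
    pointwise = np.empty((chains, n_keep, data.n_pairs))

    for chain in range(chains):
        rng = np.random.default_rng([int(seed) % (2**31), chain, model.spec.model_id])
        params = model.initial_params(rng)
        ll = model.pointwise_loglik(params)
        lprior = model.log_prior(params)
        scales = {name: 0.1 for name in scalar_names}
        scales["beta"] = scales.get("beta", 0.1) * 0.5
        if "upsilon" in scales:
            scales["upsilon"] = 0.4  # log-scale step
        if "nu_alpha" in scales:
            scales["nu_alpha"] = 0.4
        alpha_scales = np.full(data.n_families, 0.2) if has_alpha else None
        accept = {name: 0 for name in scalar_names}
        alpha_accept = np.zeros(data.n_families) if has_alpha else None
        rescale_scale, rescale_accept = 0.3, 0
        window = 0

        is_t = model.spec.family == "student_t"
        t_mid = float(np.median(data.t100)) if is_t else 1.0
        dir_scale = 2.0
        dir_accept = 0
        multiplicative = {"upsilon", "nu_alpha"}

        kept = 0
        for it in range(burn_in + iterations):
            adapting = it < burn_in
            for name in scalar_names:
                proposal = dict(params)
                hastings = 0.0
                if name in multiplicative:
                    # log-scale walk covers the 2..100 kurtosis range evenly
                    factor = np.exp(scales[name] * rng.standard_normal())
                    proposal[name] = params[name] * factor
                    hastings = np.log(factor)
                else:
                    proposal[name] = params[name] + scales[name] * rng.standard_normal()
                new_prior = model.log_prior(proposal)
                if np.isfinite(new_prior):
                    new_ll = model.pointwise_loglik(proposal)
                    log_ratio = new_prior - lprior + float(np.sum(new_ll - ll)) + hastings
                    if np.log(rng.uniform()) < log_ratio:
                        params, ll, lprior = proposal, new_ll, new_prior
                        accept[name] += 1
                else:
                    rng.uniform()  # keep the random stream aligned
            if is_t and model.spec.variance_growth:
                # joint move along the (upsilon, k) ridge: change upsilon while
                # holding the degrees of freedom at the median distance fixed
                step = dir_scale * rng.standard_normal()
                proposal = dict(params)
                proposal["upsilon"] = params["upsilon"] + step
                proposal["k"] = params["k"] - step / t_mid
                new_prior = model.log_prior(proposal)
                if np.isfinite(new_prior):
                    new_ll = model.pointwise_loglik(proposal)
                    log_ratio = new_prior - lprior + float(np.sum(new_ll - ll))
                    if np.log(rng.uniform()) < log_ratio:
                        params, ll, lprior = proposal, new_ll, new_prior
                        dir_accept += 1
                else:
                    rng.uniform()
            if has_alpha:
                # Non-centered rescale move against the hierarchical funnel:
                # scale s_alpha and every alpha_f by a common factor, leaving
                # the standardized effects alpha/s_alpha untouched. The
                # Jacobian of the alpha rescale contributes F*log(c).
                factor = np.exp(rescale_scale * rng.standard_normal())
                proposal = dict(
                    params,
                    s_alpha=params["s_alpha"] * factor,
                    alpha=params["alpha"] * factor,
                )
                new_prior = model.log_prior(proposal)
                if np.isfinite(new_prior):
                    new_ll = model.pointwise_loglik(proposal)
                    log_ratio = (
                        new_prior
                        - lprior
                        + float(np.sum(new_ll - ll))
                        + (data.n_families + 1) * np.log(factor)
                    )
                    if np.log(rng.uniform()) < log_ratio:
                        params, ll, lprior = proposal, new_ll, new_prior
                        rescale_accept += 1
                else:
                    rng.uniform()

                # The likelihood factorizes over pairs and each pair carries
                # exactly one alpha_f, so proposing every component at once
                # and accepting componentwise is a sequence of independent
                # one-dimensional Metropolis updates at the cost of a single
                # vectorized likelihood evaluation.
                alpha = params["alpha"]
                prop_alpha = alpha + alpha_scales * rng.standard_normal(data.n_families)
                ll_prop = model.pointwise_loglik(dict(params, alpha=prop_alpha))
                delta_lik = np.bincount(
                    data.family_index, weights=ll_prop - ll, minlength=data.n_families
                )
                s_a, nu_a = params["s_alpha"], params["nu_alpha"]
                delta_prior = _t_logpdf(prop_alpha, s_a, nu_a) - _t_logpdf(alpha, s_a, nu_a)
                accept_f = np.log(rng.uniform(size=data.n_families)) < (
                    delta_lik + delta_prior
                )
                if np.any(accept_f):
                    new_alpha = np.where(accept_f, prop_alpha, alpha)
                    params = dict(params, alpha=new_alpha)
                    ll = np.where(accept_f[data.family_index], ll_prop, ll)
                    lprior = model.log_prior(params)
                    alpha_accept += accept_f

            window += 1
            if adapting and window == 25:
                for name in scalar_names:
                    rate = accept[name] / 25.0
                    scales[name] *= np.exp(np.clip(rate - _TARGET_ACCEPT, -0.5, 0.5))
                    accept[name] = 0
                if is_t and model.spec.variance_growth:
                    dir_scale *= np.exp(np.clip(dir_accept / 25.0 - _TARGET_ACCEPT, -0.5, 0.5))
                    dir_accept = 0
                if has_alpha:
                    rates = alpha_accept / 25.0
                    alpha_scales *= np.exp(np.clip(rates - _TARGET_ACCEPT, -0.5, 0.5))
                    alpha_accept[:] = 0.0
                    rescale_scale *= np.exp(
                        np.clip(rescale_accept / 25.0 - _TARGET_ACCEPT, -0.5, 0.5)
                    )
                    rescale_accept = 0
                window = 0

            if it >= burn_in and (it - burn_in) % thin == 0:
                for name in scalar_names:
                    draws[name][chain, kept] = params[name]
                if has_alpha:
                    draws["alpha"][chain, kept] = params["alpha"]
                pointwise[chain, kept] = ll
                kept += 1

    rhat = _rhat_all(draws)
    warn: list[str] = []
    bad = {k: v for k, v in rhat.items() if v > 1.1}
    if bad:
        msg = f"R-hat > 1.1 for {sorted(bad)}: convergence not established"
        warn.append(msg)
        warnings.warn(msg, stacklevel=2)
    return PosteriorResult(
        spec=model.spec,
        draws=draws,
        pointwise_loglik=pointwise,
        rhat=rhat,
        seed=int(seed),
        pair_ids=list(data.pair_ids),
        family_pairs=list(data.family_pairs),
        warnings=warn,
        runtime_s=time.perf_counter() - t0,
        n_chains=chains,
        n_iterations=iterations,
        n_burn_in=burn_in,
    )


def _two_stage_model(model: FeedbackSignalModel) -> FeedbackSignalModel:
    """Plug-in variant: one pseudo-observation per pair, sigma_w effectively fixed."""
    data = model.data
    means = (
        np.bincount(data.pair_index, weights=data.r, minlength=data.n_pairs)
        / data.n_reps
    )
    mean_var = (
        np.bincount(data.pair_index, weights=data.var_r, minlength=data.n_pairs)
        / data.n_reps**2
    )
    reduced = PairedData(
        r=means,
        var_r=mean_var,
        pair_index=np.arange(data.n_pairs),
        t100=data.t100,
        n_reps=np.ones(data.n_pairs, int),
        family_index=data.family_index,
        family_pairs=data.family_pairs,
        pair_ids=data.pair_ids,
    )
    return FeedbackSignalModel(model.spec, reduced, quadrature_nodes=len(model._gh_nodes))


def _rhat_all(draws: dict[str, np.ndarray]) -> dict[str, float]:
    rhat: dict[str, float] = {}
    for name, values in draws.items():
        if values.ndim == 2:
            rhat[name] = gelman_rubin(values)
        else:
            for f in range(values.shape[2]):
                rhat[f"{name}[{f}]"] = gelman_rubin(values[:, :, f])
    return rhat


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor for one parameter.

    ``chains`` has shape (n_chains, n_draws). Uses the rank-normalized
    split-chain statistic; degenerate (constant) chains return 1.0 by
    convention.
    """
    chains = np.asarray(chains, float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need draws from at least 2 chains, shape (chains, draws)")
    if chains.shape[1] < 10:
        raise ValueError("need at least 10 draws per chain")
    if np.ptp(chains) == 0.0:
        return 1.0
    value = float(az.rhat(az.convert_to_dataset(chains))["x"].values)
    if not np.isfinite(value):
        return 1.0
    return value


def posterior_summary(result: PosteriorResult, transform_per_myr: float | None = None) -> pd.DataFrame:
    """Posterior mean and central 95% credible interval per parameter.

    Rates (beta, k) are reported per 100 Myr of phylogenetic distance.
    ``transform_per_myr`` optionally adds a column scaling beta to the total
    mean change over that many Myr (e.g. 600 reports the expected change in r
    across 600 Myr of divergence).
    """
    rows = []
    for name, values in result.draws.items():
        if values.ndim == 2:
            # rhat is keyed by name for scalars, name[index] for vectors
            entries = [(name, name, values.reshape(-1))]
        else:
            entries = [
                (f"{name}[{result.family_pairs[f]}]", f"{name}[{f}]", values[:, :, f].reshape(-1))
                for f in range(values.shape[2])
            ]
        for label, rhat_key, flat in entries:
            q025, q50, q975 = np.quantile(flat, [0.025, 0.5, 0.975])
            rows.append(
                {
                    "parameter": label,
                    "mean": float(np.mean(flat)),
                    "sd": float(np.std(flat)),
                    "q2.5": float(q025),
                    "median": float(q50),
                    "q97.5": float(q975),
                    "rhat": result.rhat.get(rhat_key, np.nan),
                }
            )
    frame = pd.DataFrame(rows).set_index("parameter")
    if transform_per_myr is not None and "beta" in result.draws:
        scale = transform_per_myr / 100.0
        flat = result.draws["beta"].reshape(-1) * scale
        frame.loc["beta", f"change_over_{int(transform_per_myr)}myr"] = float(
            np.mean(flat)
        )
    return frame
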