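"""Latent Gaussian joint mass imputation.

A joint model for mixed-type outcomes given covariates, in the spirit of
latent-process imputers such as GERBIL (this is an independent
implementation of the idea, not a port of the R package): every outcome is
linked to a latent standard-normal variable — continuous outcomes through an
empirical normal-score map, binary and ordinal outcomes through ordered-probit
thresholds fixed at the probit of the marginal cumulative frequencies — and
the joint latent distribution given covariates is factorized triangularly,

    z_(1) | x,  z_(2) | x, z_(1),  ...,  z_(q) | x, z_(<q),

with each factor a linear-Gaussian regression.  Latent values behind the
discrete outcomes are unobserved, so the factor regressions are estimated
with a Gibbs-style data-augmentation loop that alternates between refitting
the regressions and redrawing each discrete latent from its full conditional
(a truncated normal combining its own factor with every later factor in
which it appears as a predictor).

Imputation for the probability sample then draws the latent vector
sequentially down the factorization given the unit's covariates and
back-transforms to the observed scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

from .fcs import ImputerSpec, MassImputedSample, infer_outcomes, _linear_design
from .sampling import SurveySample
from .schema import Schema

_EPS = 1e-10


@dataclass(frozen=True)
class MarginalTransform:
    """Monotone link between one observed variable and its latent normal."""

    kind: str  # "affine" | "normal_score" | "ordinal" | "constant"
    # affine: standardization by the observed location/scale
    loc: float = 0.0
    scale: float = 1.0
    # normal_score: observed order statistics and their scores
    sorted_values: np.ndarray | None = None
    sorted_scores: np.ndarray | None = None
    # ordinal: levels and interior thresholds (len(levels) - 1 of them)
    levels: tuple = ()
    thresholds: np.ndarray | None = None
    constant_value: float | None = None

    def to_latent(self, v: np.ndarray) -> np.ndarray:
        if self.kind == "affine":
            return (np.asarray(v, dtype=float) - self.loc) / self.scale
        if self.kind == "normal_score":
            return np.interp(v, self.sorted_values, self.sorted_scores)
        raise ValueError("discrete latents are sampled, not deterministic")

    def latent_interval(self, v: np.ndarray) -> tuple:
        """Per-observation (lo, hi) latent interval for ordinal values."""
        edges = np.concatenate(([-np.inf], self.thresholds, [np.inf]))
        idx = np.searchsorted(np.asarray(self.levels), v)
        return edges[idx], edges[idx + 1]

    def from_latent(self, z: np.ndarray) -> np.ndarray:
        if self.kind == "constant":
            return np.full(len(z), self.constant_value)
        if self.kind == "affine":
            return z * self.scale + self.loc
        if self.kind == "normal_score":
            # linear interpolation between order statistics, clamped to range
            return np.interp(z, self.sorted_scores, self.sorted_values)
        cat = np.searchsorted(self.thresholds, z, side="left")
        return np.asarray(self.levels)[cat]


def _normal_score_transform(values: np.ndarray) -> MarginalTransform:
    n = len(values)
    ranks = rankdata(values, method="average")  # ties get average ranks
    scores = ndtri((ranks - 0.5) / n)
    order = np.argsort(values, kind="stable")
    return MarginalTransform(
        "normal_score",
        sorted_values=values[order].astype(float),
        sorted_scores=scores[order],
    )


def _ordinal_transform(values: np.ndarray, levels: tuple) -> MarginalTransform:
    observed = [lev for lev in levels if np.any(values == lev)]
    if len(observed) < 2:
        return MarginalTransform("constant", constant_value=float(observed[0]))
    freqs = np.array([(values == lev).mean() for lev in observed])
    cum = np.cumsum(freqs)[:-1]
    return MarginalTransform(
        "ordinal", levels=tuple(observed), thresholds=ndtri(np.clip(cum, _EPS, 1 - _EPS))
    )


def _truncnorm_draw(mean, sd, lo, hi, rng):
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = a + (b - a) * rng.random(len(mean))
    return mean + sd * ndtri(np.clip(u, _EPS, 1 - _EPS))


@dataclass
class LatentModel:
    """Fitted latent joint model: transforms + triangular factor regressions."""

    order: tuple                 # outcome names, factorization order
    covariates: tuple
    schema: Schema
    transforms: dict             # name -> MarginalTransform
    coefs: dict                  # name -> regression coefficients
    resid_scales: dict           # name -> residual sd (>0 unless degenerate)
    covariate_levels: dict = field(default_factory=dict)  # donor-observed levels
    fit_diagnostics: pd.DataFrame | None = None

    @property
    def active_order(self) -> tuple:
        return tuple(n for n in self.order if self.transforms[n].kind != "constant")


def _factor_design(x_design: np.ndarray, latents: dict, order, j: int) -> np.ndarray:
    prev = [latents[name][:, None] for name in order[:j]]
    return np.hstack([x_design] + prev) if prev else x_design


def fit_latent_joint(
    sB: SurveySample,
    order: tuple | None = None,
    covariates: tuple | None = None,
    n_iter: int = 50,
    burn: int = 25,
    continuous_link: str = "affine",
    rng: np.random.Generator | int | None = None,
) -> LatentModel:
    """Fit the latent joint model on the fully observed nonprobability sample.

    ``continuous_link`` selects how continuous outcomes map to their latent:
    ``"affine"`` (default) standardizes by the observed mean and standard
    deviation, so the conditional model is linear-Gaussian on the observed
    scale; ``"normal_score"`` uses the empirical normal-score (Gaussian
    copula) map instead.  The affine link is exactly invertible and transfers
    a correctly specified linear conditional mean to the recipients without
    distortion; the score link forces the donor marginal onto the
    imputations, which under informative selection biases recipient means
    (see docs/methods.md).
    """
    if continuous_link not in ("affine", "normal_score"):
        raise ValueError("continuous_link must be 'affine' or 'normal_score'")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    schema = sB.schema
    covariates = tuple(covariates) if covariates is not None else tuple(
        c for c in sB.observed_columns if c not in sB.observed_columns
    )
    if not covariates:
        raise ValueError("covariates must be specified for the latent model")
    all_out = tuple(order) if order is not None else tuple(
        c for c in sB.observed_columns if c not in covariates
    )

    cols = {c: sB.data[c].to_numpy() for c in sB.data.columns}
    x_design = _linear_design(cols, list(covariates), schema)

    transforms, latents, intervals = {}, {}, {}
    for name in all_out:
        v = cols[name]
        if schema[name].is_discrete:
            tr = _ordinal_transform(v, schema[name].level_tuple())
            transforms[name] = tr
            if tr.kind == "constant":
                continue
            lo, hi = tr.latent_interval(v)
            intervals[name] = (lo, hi)
            latents[name] = _truncnorm_draw(
                np.zeros(len(v)), np.ones(len(v)), lo, hi, rng
            )
        elif continuous_link == "affine":
            vf = v.astype(float)
            sd = float(vf.std())
            tr = MarginalTransform("affine", loc=float(vf.mean()), scale=sd if sd > 0 else 1.0)
            transforms[name] = tr
            latents[name] = tr.to_latent(vf)
        else:
            tr = _normal_score_transform(v.astype(float))
            transforms[name] = tr
            latents[name] = ndtri((rankdata(v, method="average") - 0.5) / len(v))

    active = tuple(n for n in all_out if transforms[n].kind != "constant")
    # average post-burn-in draws; if burn swallows the run, keep the last half
    n_keep = n_iter - burn if n_iter > burn else max(n_iter // 2, 1)
    coef_sums = {n: 0.0 for n in active}
    scale_sums = {n: 0.0 for n in active}
    diag_rows = []
    coefs, scales = {}, {}
    for it in range(n_iter):
        preds = {}
        for j, name in enumerate(active):
            d = _factor_design(x_design, latents, active, j)
            n_obs, k = d.shape
            gram = d.T @ d
            gram_inv = np.linalg.pinv(gram)  # pinv: tolerate unseen levels
            beta_hat = gram_inv @ (d.T @ latents[name])
            resid = latents[name] - d @ beta_hat
            rss = float(resid @ resid)
            # conjugate posterior draw under a flat prior (proper Gibbs step;
            # plugging in the OLS point estimates instead would leave the
            # sampler at a stochastic-EM fixed point with O(1) bias for the
            # augmented factors)
            dof = max(n_obs - k, 1)
            sigma = float(np.sqrt(max(rss, _EPS) / max(rng.chisquare(dof), _EPS)))
            eigval, eigvec = np.linalg.eigh(gram_inv)
            half = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
            beta = beta_hat + sigma * half @ rng.standard_normal(k)
            pred = d @ beta
            if name in intervals and len(transforms[name].thresholds) == 1:
                # a single threshold near zero leaves the joint scale of
                # (beta, sigma) on a flat likelihood ridge; the fixed marginal
                # threshold presupposes a standard-normal latent, so project
                # the draw onto E[z^2] = 1.  With two or more thresholds the
                # scale is likelihood-identified and must not be projected.
                c = float(np.sqrt(np.mean(pred**2) + sigma**2))
                beta, sigma, pred = beta / c, sigma / c, pred / c
            coefs[name], scales[name] = beta, sigma
            preds[name] = pred
        # redraw each discrete latent from its full conditional
        p = x_design.shape[1]
        for j, name in enumerate(active):
            if name not in intervals:
                continue
            z_j = latents[name]
            prec = 1.0 / scales[name] ** 2
            num = preds[name] * prec
            for k in range(j + 1, len(active)):
                later = active[k]
                col = p + j  # position of z_j in the later factor's design
                b = coefs[later][col]
                if b == 0.0:
                    continue
                partial = preds[later] - b * z_j
                w = 1.0 / scales[later] ** 2
                num += b * (latents[later] - partial) * w
                prec += b * b * w
            mean = num / prec
            sd = np.sqrt(1.0 / prec)
            lo, hi = intervals[name]
            new_z = _truncnorm_draw(mean, sd, lo, hi, rng)
            # keep the cached predictions of later factors consistent
            delta = new_z - z_j
            for k in range(j + 1, len(active)):
                b = coefs[active[k]][p + j]
                if b != 0.0:
                    preds[active[k]] = preds[active[k]] + b * delta
            latents[name] = new_z
        if it >= n_iter - n_keep:
            for name in active:
                coef_sums[name] = coef_sums[name] + coefs[name]
                scale_sums[name] += scales[name]
        diag_rows.extend(
            (it, name, float(np.mean(latents[name])), scales[name]) for name in active
        )

    final_coefs = {n: coef_sums[n] / n_keep for n in active}
    final_scales = {n: scale_sums[n] / n_keep for n in active}
    diagnostics = pd.DataFrame(
        diag_rows, columns=["iteration", "variable", "latent_mean", "resid_scale"]
    )
    covariate_levels = {
        c: set(np.unique(cols[c])) for c in covariates if schema[c].is_discrete
    }
    return LatentModel(
        order=all_out,
        covariates=covariates,
        schema=schema,
        transforms=transforms,
        coefs=final_coefs,
        resid_scales=final_scales,
        covariate_levels=covariate_levels,
        fit_diagnostics=diagnostics,
    )


def _check_unseen_levels(model: LatentModel, sA: SurveySample) -> None:
    for c, donor_levels in model.covariate_levels.items():
        unseen = set(np.unique(sA.data[c])) - donor_levels
        if unseen:
            warnings.warn(
                f"covariate {c!r} has levels {sorted(unseen)} never observed in the "
                "donor sample; imputing through the linear predictor anyway",
                stacklevel=3,
            )


def _draw_latents(
    model: LatentModel, x_design: np.ndarray, rng: np.random.Generator, noise: bool = True
) -> dict:
    latents = {}
    active = model.active_order
    for j, name in enumerate(active):
        d = _factor_design(x_design, latents, active, j)
        mean = d @ model.coefs[name]
        if noise:
            mean = mean + model.resid_scales[name] * rng.standard_normal(len(mean))
        latents[name] = mean
    return latents


def impute_latent_joint(
    model: LatentModel,
    sA: SurveySample,
    m: int = 10,
    rng: np.random.Generator | int | None = None,
    spec: ImputerSpec | None = None,
) -> MassImputedSample:
    """Draw m completed outcome tables for the probability sample."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    _check_unseen_levels(model, sA)
    cols = {c: sA.data[c].to_numpy() for c in model.covariates}
    x_design = _linear_design(cols, list(model.covariates), model.schema)

    completions = []
    for _ in range(m):
        latents = _draw_latents(model, x_design, rng, noise=True)
        out = {}
        for name in model.order:
            tr = model.transforms[name]
            if tr.kind == "constant":
                out[name] = np.full(sA.n, tr.constant_value)
            else:
                vals = tr.from_latent(latents[name])
                if model.schema[name].is_discrete:
                    vals = vals.astype(np.int64)
                out[name] = vals
        completions.append(pd.DataFrame(out))
    spec = spec or ImputerSpec(method="latent_joint", m=m)
    return MassImputedSample(base=sA, completions=completions, spec=spec)


def conditional_means(model: LatentModel, sA: SurveySample) -> pd.DataFrame:
    """Model-implied conditional means on the observed scale (zero noise).

    Propagates the latent conditional means down the factorization and
    back-transforms them; for continuous outcomes with an approximately
    affine normal-score map this equals the conditional mean of the
    imputation distribution.
    """
    cols = {c: sA.data[c].to_numpy() for c in model.covariates}
    x_design = _linear_design(cols, list(model.covariates), model.schema)
    latents = _draw_latents(model, x_design, np.random.default_rng(0), noise=False)
    out = {}
    for name in model.active_order:
        out[name] = model.transforms[name].from_latent(latents[name])
    return pd.DataFrame(out)


def mass_impute_latent(
    sA: SurveySample,
    sB: SurveySample,
    spec: ImputerSpec,
    rng: np.random.Generator | int | None = None,
    n_iter: int = 50,
    burn: int = 25,
    continuous_link: str = "affine",
) -> MassImputedSample:
    """Convenience wrapper: fit on the donors, impute the recipients."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(spec.seed if rng is None else rng)
    covariates = tuple(c for c in sA.observed_columns if c in sB.observed_columns)
    outcomes = tuple(spec.order) if spec.order else tuple(infer_outcomes(sA, sB))
    model = fit_latent_joint(
        sB, order=outcomes, covariates=covariates, n_iter=n_iter, burn=burn,
        continuous_link=continuous_link, rng=rng,
    )
    return impute_latent_joint(model, sA, m=spec.m, rng=rng, spec=spec)
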