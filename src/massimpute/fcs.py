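"""Fully conditional specification (FCS) mass imputation.

Conditional models for each outcome are fitted on the nonprobability sample
(the donors, who observe every outcome) and used to draw outcome values for
every unit of the probability sample (the recipients, who observe only
covariates).  The engine cycles through the outcomes in a fixed order for a
number of sweeps so that the imputed outcomes condition on each other, and
repeats the whole chain ``m`` times to produce ``m`` completed datasets.

Three conditional samplers are provided, mirroring common `mice` methods:

* ``pmm`` — predictive mean matching: a linear model on covariates and the
  other outcomes; each recipient receives the observed value of one of the
  ``k`` donors whose predicted means are nearest its own.  Matching is
  type 1: donors are predicted under the least-squares fit, recipients
  under a nonparametric bootstrap refit drawn fresh each sweep.
* ``cart`` — a single regression tree; recipients draw uniformly from the
  donor values in their leaf.
* ``rf`` — a bootstrap forest of such trees; each recipient picks one tree
  uniformly at random and then draws from that tree's leaf donors.

Because the donor records are fully observed, the conditional model for a
given outcome depends only on the donor data; the trees are therefore fitted
once per chain (rf: one forest; cart: one deterministic tree) while
recipient predictions are refreshed every sweep as the other imputed
outcomes change.

All three samplers only ever return values observed among the donors
(support preservation), so imputed categorical values automatically lie in
the donor levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .sampling import SurveySample
from .schema import Schema

FCS_METHODS = ("pmm", "cart", "rf")


@dataclass(frozen=True)
class ImputerSpec:
    """Configuration of one mass-imputation run."""

    method: str = "pmm"  # pmm | cart | rf | latent_joint
    m: int = 10
    iterations: int = 5
    order: tuple | None = None
    pmm_donors: int = 5
    tree_min_leaf: int = 5
    rf_trees: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.method not in FCS_METHODS + ("latent_joint",):
            raise ValueError(f"unknown imputation method {self.method!r}")
        if self.m < 1 or self.iterations < 1:
            raise ValueError("m and iterations must be >= 1")

    @property
    def label(self) -> str:
        return self.method


@dataclass
class MassImputedSample:
    """A probability sample augmented with ``m`` completed outcome tables."""

    base: SurveySample
    completions: list  # list of DataFrames with the outcome columns
    spec: ImputerSpec
    trace: pd.DataFrame | None = None  # per (imputation, sweep, variable) mean

    @property
    def m(self) -> int:
        return len(self.completions)

    def completed(self, t: int) -> pd.DataFrame:
        """The t-th fully completed recipient table (covariates + outcomes)."""
        return pd.concat(
            [self.base.data.reset_index(drop=True), self.completions[t]], axis=1
        )


# ---------------------------------------------------------------------------
# design-matrix helpers

def _linear_design(cols: dict, names: list, schema: Schema) -> np.ndarray:
    """Intercept + dummy-coded categoricals (drop first level) + numerics."""
    n = len(next(iter(cols.values())))
    parts = [np.ones((n, 1))]
    for name in names:
        v = np.asarray(cols[name])
        vs = schema[name]
        if vs.kind == "categorical":
            for lev in vs.levels[1:]:
                parts.append((v == lev).astype(float)[:, None])
        else:
            parts.append(v.astype(float)[:, None])
    return np.hstack(parts)


def _tree_features(cols: dict, names: list) -> np.ndarray:
    return np.column_stack([np.asarray(cols[name], dtype=np.float32) for name in names])


# ---------------------------------------------------------------------------
# conditional samplers

def pmm_draw(
    donor_pred: np.ndarray,
    donor_values: np.ndarray,
    recipient_pred: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Predictive mean matching: observed value of one of the k nearest donors.

    Nearness is measured on the predicted means.  Never interpolates: the
    returned values are a subset of ``donor_values``.
    """
    n_d = donor_pred.shape[0]
    if n_d < k:
        warnings.warn(
            f"only {n_d} donors available for pmm with k={k}; using all donors",
            stacklevel=2,
        )
        k = n_d
    order = np.argsort(donor_pred, kind="stable")
    sorted_pred = donor_pred[order]
    sorted_vals = donor_values[order]
    pos = np.searchsorted(sorted_pred, recipient_pred)
    # candidate window of 2k donors around the insertion point covers the k nearest
    start = np.clip(pos - k, 0, max(n_d - 2 * k, 0))
    idx = start[:, None] + np.arange(min(2 * k, n_d))
    dist = np.abs(sorted_pred[idx] - recipient_pred[:, None])
    nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
    pick = nearest[np.arange(len(recipient_pred)), rng.integers(0, k, len(recipient_pred))]
    return sorted_vals[idx[np.arange(len(recipient_pred)), pick]]


def _leaf_donor_draw(
    donor_leaves: np.ndarray,
    donor_values: np.ndarray,
    recipient_leaves: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    out = np.empty(len(recipient_leaves), dtype=donor_values.dtype)
    for leaf in np.unique(recipient_leaves):
        members = donor_values[donor_leaves == leaf]
        mask = recipient_leaves == leaf
        out[mask] = members[rng.integers(0, len(members), mask.sum())]
    return out


def tree_draw(
    tree: DecisionTreeRegressor,
    donor_features: np.ndarray,
    donor_values: np.ndarray,
    recipient_features: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Route recipients to their leaf and draw uniformly from its donors."""
    donor_leaves = tree.apply(donor_features, check_input=False)
    recipient_leaves = tree.apply(recipient_features, check_input=False)
    return _leaf_donor_draw(donor_leaves, donor_values, recipient_leaves, rng)


def forest_draw(
    trees: list,
    donor_features: np.ndarray,
    donor_values: np.ndarray,
    recipient_features: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One uniformly chosen tree per recipient, then a leaf-donor draw."""
    n_r = len(recipient_features)
    choice = rng.integers(0, len(trees), n_r)
    out = np.empty(n_r, dtype=donor_values.dtype)
    for t, tree in enumerate(trees):
        mask = choice == t
        if not mask.any():
            continue
        out[mask] = tree_draw(
            tree, donor_features, donor_values, recipient_features[mask], rng
        )
    return out


def _fit_tree(
    features: np.ndarray, y: np.ndarray, min_leaf: int,
    max_features=None, seed=None, classify: bool = False,
):
    # discrete outcomes get Gini classification trees (as mice does for
    # factors); continuous outcomes get variance-reduction regression trees
    cls = DecisionTreeClassifier if classify else DecisionTreeRegressor
    tree = cls(min_samples_leaf=min_leaf, max_features=max_features, random_state=seed)
    tree.fit(features, y.astype(np.float64), check_input=False)
    return tree


# ---------------------------------------------------------------------------
# the FCS engine

def infer_outcomes(sA: SurveySample, sB: SurveySample) -> list:
    return [c for c in sB.observed_columns if c not in sA.observed_columns]


def initialize_completions(
    sA: SurveySample,
    sB: SurveySample,
    order: list,
    rng: np.random.Generator,
) -> dict:
    """Hot-deck start: each outcome filled by uniform draws from its donors."""
    init = {}
    for name in order:
        donor = sB.data[name].to_numpy()
        if len(donor) == 0 or pd.isna(donor).all():
            raise ValueError(f"outcome {name!r} has no observed values in the donor sample")
        init[name] = donor[rng.integers(0, len(donor), sA.n)]
    return init


def mass_impute_fcs(
    sA: SurveySample,
    sB: SurveySample,
    spec: ImputerSpec,
    rng: np.random.Generator | int | None = None,
) -> MassImputedSample:
    """Run the full FCS mass imputation: m chains of `iterations` sweeps."""
    if spec.method not in FCS_METHODS:
        raise ValueError(f"mass_impute_fcs handles {FCS_METHODS}, not {spec.method!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(spec.seed if rng is None else rng)

    covariates = [c for c in sA.observed_columns if c in sB.observed_columns]
    outcomes = infer_outcomes(sA, sB)
    order = list(spec.order) if spec.order is not None else outcomes
    if sorted(order) != sorted(outcomes):
        raise ValueError("spec.order must be a permutation of the outcome variables")
    schema = sB.schema

    donor_cols = {c: sB.data[c].to_numpy() for c in covariates + outcomes}
    recip_cov = {c: sA.data[c].to_numpy() for c in covariates}

    completions: list = []
    trace_rows = []
    for t in range(spec.m):
        chain_rng = np.random.default_rng(rng.integers(0, 2**63))
        recip = dict(recip_cov)
        recip.update(initialize_completions(sA, sB, order, chain_rng))

        # per-variable conditional models, fitted once per chain on the donors
        samplers = {}
        for name in order:
            predictors = covariates + [o for o in outcomes if o != name]
            y_d = donor_cols[name]
            if spec.method == "pmm":
                # type-1 matching: donors predicted under the least-squares
                # fit, recipients under a bootstrap parameter draw (per sweep)
                x_d = _linear_design(donor_cols, predictors, schema)
                beta_hat = np.linalg.lstsq(x_d, y_d.astype(float), rcond=None)[0]
                samplers[name] = ("pmm", predictors, (x_d, beta_hat), x_d @ beta_hat, y_d)
            else:
                f_d = _tree_features(donor_cols, predictors)
                classify = schema[name].is_discrete
                if spec.method == "cart":
                    tree = _fit_tree(f_d, y_d, spec.tree_min_leaf, classify=classify,
                                     seed=int(chain_rng.integers(0, 2**31)))
                    samplers[name] = ("cart", predictors, tree, f_d, y_d)
                else:
                    # classification trees grown to leaf size 1, regression to
                    # tree_min_leaf, mirroring the usual random-forest defaults
                    min_leaf = 1 if classify else spec.tree_min_leaf
                    seeds = chain_rng.integers(0, 2**31, spec.rf_trees)
                    trees = []
                    for s in seeds:
                        boot = chain_rng.integers(0, len(y_d), len(y_d))
                        trees.append(
                            _fit_tree(f_d[boot], y_d[boot], min_leaf,
                                      max_features="sqrt", seed=int(s),
                                      classify=classify)
                        )
                    samplers[name] = ("rf", predictors, trees, f_d, y_d)

        for sweep in range(spec.iterations):
            for name in order:
                kind, predictors, model, donor_x, y_d = samplers[name]
                if kind == "pmm":
                    x_d, _ = model
                    boot = chain_rng.integers(0, len(y_d), len(y_d))
                    beta_star = np.linalg.lstsq(
                        x_d[boot], y_d[boot].astype(float), rcond=None
                    )[0]
                    x_r = _linear_design(recip, predictors, schema)
                    drawn = pmm_draw(donor_x, y_d, x_r @ beta_star,
                                     spec.pmm_donors, chain_rng)
                elif kind == "cart":
                    f_r = _tree_features(recip, predictors)
                    drawn = tree_draw(model, donor_x, y_d, f_r, chain_rng)
                else:
                    f_r = _tree_features(recip, predictors)
                    drawn = forest_draw(model, donor_x, y_d, f_r, chain_rng)
                recip[name] = drawn
                trace_rows.append(
                    (t, sweep, name, float(np.asarray(drawn, dtype=float).mean()))
                )

        completions.append(pd.DataFrame({name: recip[name] for name in outcomes}))

    trace = pd.DataFrame(trace_rows, columns=["imputation", "sweep", "variable", "mean"])
    return MassImputedSample(base=sA, completions=completions, spec=spec, trace=trace)
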