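"""Latent joint imputer: transforms, Gaussian oracle, parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri

import massimpute as mi
from massimpute.latent import (
    MarginalTransform,
    _normal_score_transform,
    _ordinal_transform,
    conditional_means,
    fit_latent_joint,
    impute_latent_joint,
)
from massimpute.schema import VariableSchema


def continuous_sample(n=2000, seed=0, rho=0.6):
    """Bivariate normal outcomes given one covariate, with known regressions."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y1 = 0.8 * x + 0.6 * rng.standard_normal(n)
    y2 = 0.5 * x + rho * y1 + 0.5 * rng.standard_normal(n)
    schema = {
        "X": VariableSchema("continuous"),
        "Y1": VariableSchema("continuous"),
        "Y2": VariableSchema("continuous"),
    }
    return mi.SurveySample(
        unit_ids=np.arange(n), weights=np.ones(n),
        observed_columns=("X", "Y1", "Y2"),
        data=pd.DataFrame({"X": x, "Y1": y1, "Y2": y2}), schema=schema,
    )


def binary_sample(n=1000, p=0.3, seed=1):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    b = (rng.random(n) < p).astype(np.int64)
    schema = {"X": VariableSchema("continuous"), "B": VariableSchema("binary")}
    return mi.SurveySample(
        unit_ids=np.arange(n), weights=np.ones(n), observed_columns=("X", "B"),
        data=pd.DataFrame({"X": x, "B": b}), schema=schema,
    )


class TestTransforms:
    def test_binary_threshold_is_probit_of_prevalence(self):
        s = binary_sample(n=4000, p=0.3, seed=2)
        model = fit_latent_joint(s, order=("B",), covariates=("X",), n_iter=5, rng=0)
        tr = model.transforms["B"]
        observed_p = s.data["B"].mean()
        # P(latent <= tau) = 1 - p  =>  tau = Phi^-1(1 - p)
        assert tr.thresholds[0] == pytest.approx(ndtri(1 - observed_p), abs=1e-9)

    def test_normal_score_round_trip_is_identity(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(200) * 2 + 1
        tr = _normal_score_transform(v)
        assert np.allclose(tr.from_latent(tr.to_latent(v)), v)

    def test_affine_round_trip_is_identity(self):
        tr = MarginalTransform("affine", loc=2.0, scale=3.0)
        v = np.array([-1.0, 0.0, 5.5])
        assert np.allclose(tr.from_latent(tr.to_latent(v)), v)

    def test_ordinal_levels_preserved(self):
        rng = np.random.default_rng(4)
        v = rng.choice([1, 2, 3], 500, p=[0.2, 0.5, 0.3])
        tr = _ordinal_transform(v, (1, 2, 3))
        lo, hi = tr.latent_interval(v)
        mid = np.clip((lo + hi) / 2, -8, 8)  # midpoint of each interval
        assert (tr.from_latent(mid) == v).all()

    def test_degenerate_marginal_flagged_constant(self):
        v = np.full(50, 2)
        tr = _ordinal_transform(v, (1, 2, 3))
        assert tr.kind == "constant"
        assert tr.constant_value == 2


class TestGaussianOracle:
    def test_conditional_means_match_closed_form_mvn(self):
        # well-specified all-continuous data: fitted conditional means must
        # match the closed-form triangular (= MVN conditional) regression
        sB = continuous_sample(n=5000, seed=5)
        model = fit_latent_joint(
            sB, order=("Y1", "Y2"), covariates=("X",), n_iter=30, burn=15, rng=0
        )
        rng = np.random.default_rng(6)
        xa = rng.standard_normal(400)
        sA = mi.SurveySample(
            unit_ids=np.arange(400), weights=np.ones(400), observed_columns=("X",),
            data=pd.DataFrame({"X": xa}), schema=sB.schema,
        )
        cm = conditional_means(model, sA)
        true_y1 = 0.8 * xa
        true_y2 = 0.5 * xa + 0.6 * true_y1
        assert np.max(np.abs(cm["Y1"].to_numpy() - true_y1)) < 0.05
        assert np.max(np.abs(cm["Y2"].to_numpy() - true_y2)) < 0.05

    def test_zero_residual_scale_is_deterministic(self):
        sB = continuous_sample(n=500, seed=7)
        model = fit_latent_joint(sB, order=("Y1", "Y2"), covariates=("X",), n_iter=5, rng=0)
        model.resid_scales = {k: 0.0 for k in model.resid_scales}
        sA = mi.SurveySample(
            unit_ids=np.arange(50), weights=np.ones(50), observed_columns=("X",),
            data=pd.DataFrame({"X": np.linspace(-2, 2, 50)}), schema=sB.schema,
        )
        mis = impute_latent_joint(model, sA, m=3, rng=1)
        assert mis.completions[0].equals(mis.completions[1])
        assert mis.completions[1].equals(mis.completions[2])


class TestParameterRecovery:
    def test_triangular_coefficients_recovered(self):
        # data generated from a known triangular latent model with one binary
        # outcome; fitted coefficients must land within 3 standard errors
        n = 5000
        rng = np.random.default_rng(8)
        x = rng.standard_normal(n)
        z1 = 0.8 * x + 0.6 * rng.standard_normal(n)  # observed continuous
        z2 = 0.5 * x + 0.4 * z1 + 0.6 * rng.standard_normal(n)  # latent of B
        b = (z2 > 0).astype(np.int64)
        schema = {
            "X": VariableSchema("continuous"),
            "Y1": VariableSchema("continuous"),
            "B": VariableSchema("binary"),
        }
        sB = mi.SurveySample(
            unit_ids=np.arange(n), weights=np.ones(n),
            observed_columns=("X", "Y1", "B"),
            data=pd.DataFrame({"X": x, "Y1": z1, "B": b}), schema=schema,
        )
        model = fit_latent_joint(sB, order=("Y1", "B"), covariates=("X",),
                                 n_iter=60, burn=30, rng=9)
        # continuous factor: coefficients on (intercept, X) with OLS SEs
        beta1 = model.coefs["Y1"]
        design = np.column_stack([np.ones(n), x])
        sigma1 = model.resid_scales["Y1"]
        se1 = sigma1 * np.sqrt(np.diag(np.linalg.inv(design.T @ design)))
        # the affine standardization rescales the outcome; undo it for comparison
        scale1 = model.transforms["Y1"].scale
        assert beta1[1] * scale1 == pytest.approx(0.8, abs=3 * se1[1] * scale1)

        # binary factor: latent regression on (intercept, X, z1-standardized);
        # true latent z2 has residual sd 0.6, marginal sd ~1: coefficients on the
        # standardized scale are (0.5/sd2, 0.4*sd1/sd2) with sd2 = sd(z2)
        beta2 = model.coefs["B"]
        sd1, sd2 = z1.std(), z2.std()
        target_x = 0.5 / sd2
        target_z1 = 0.4 * sd1 / sd2
        # Gibbs-augmented fit: allow 3 x (OLS SE at the latent scale)
        se2 = (0.6 / sd2) * np.sqrt(
            np.diag(np.linalg.inv(np.column_stack([np.ones(n), x, z1 / sd1]).T
                                  @ np.column_stack([np.ones(n), x, z1 / sd1])))
        )
        assert beta2[1] == pytest.approx(target_x, abs=3 * max(se2[1], 0.02))
        assert beta2[2] == pytest.approx(target_z1, abs=3 * max(se2[2], 0.02))


class TestWarnings:
    def test_unseen_covariate_level_warns(self):
        rng = np.random.default_rng(10)
        n = 300
        schema = {
            "G": VariableSchema("categorical", (1, 2, 3)),
            "Y": VariableSchema("continuous"),
        }
        g = rng.choice([1, 2], n)  # level 3 never observed in donors
        sB = mi.SurveySample(
            unit_ids=np.arange(n), weights=np.ones(n), observed_columns=("G", "Y"),
            data=pd.DataFrame({"G": g, "Y": g + rng.standard_normal(n)}), schema=schema,
        )
        model = fit_latent_joint(sB, order=("Y",), covariates=("G",), n_iter=5, rng=0)
        sA = mi.SurveySample(
            unit_ids=np.arange(10), weights=np.ones(10), observed_columns=("G",),
            data=pd.DataFrame({"G": np.full(10, 3)}), schema=schema,
        )
        with pytest.warns(UserWarning, match="never observed"):
            impute_latent_joint(model, sA, m=1, rng=0)
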