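"""FCS engine: initialization, conditional samplers, support preservation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import massimpute as mi
from massimpute.fcs import initialize_completions, pmm_draw, tree_draw, _fit_tree
from massimpute.schema import VariableSchema


def make_pair(n_a=60, n_b=80, seed=0, constant_outcome=None):
    """Small covariate-sharing sample pair with two outcomes (Y binary, Z real)."""
    rng = np.random.default_rng(seed)
    schema = {
        "X": VariableSchema("continuous"),
        "Y": VariableSchema("binary"),
        "Z": VariableSchema("continuous"),
    }
    xb = rng.standard_normal(n_b)
    y = (rng.random(n_b) < 0.4).astype(np.int64)
    if constant_outcome is not None:
        y[:] = constant_outcome
    z = 1.0 + xb + 0.5 * y + 0.3 * rng.standard_normal(n_b)
    sB = mi.SurveySample(
        unit_ids=np.arange(n_b), weights=np.ones(n_b),
        observed_columns=("X", "Y", "Z"),
        data=pd.DataFrame({"X": xb, "Y": y, "Z": z}), schema=schema,
    )
    xa = rng.standard_normal(n_a)
    sA = mi.SurveySample(
        unit_ids=np.arange(n_a), weights=np.full(n_a, 2.0),
        observed_columns=("X",), data=pd.DataFrame({"X": xa}), schema=schema,
    )
    return sA, sB


class TestInitialization:
    def test_constant_outcome_initializes_constant(self):
        sA, sB = make_pair(constant_outcome=1)
        init = initialize_completions(sA, sB, ["Y", "Z"], np.random.default_rng(0))
        assert (init["Y"] == 1).all()

    def test_binary_support_preserved(self):
        sA, sB = make_pair()
        init = initialize_completions(sA, sB, ["Y", "Z"], np.random.default_rng(0))
        assert set(init["Y"]) <= {0, 1}
        assert set(init["Z"]) <= set(sB.data["Z"])

    def test_marginal_matches_donor_marginal(self):
        sA, sB = make_pair(n_a=4000)
        init = initialize_completions(sA, sB, ["Y"], np.random.default_rng(1))
        p = sB.data["Y"].mean()
        assert init["Y"].mean() == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / 4000))


class TestPMMDraw:
    def test_exact_prediction_match_returns_that_donor(self):
        donor_pred = np.array([0.0, 1.0, 2.0, 5.0])
        donor_vals = np.array([10.0, 11.0, 12.0, 15.0])
        out = pmm_draw(donor_pred, donor_vals, np.array([5.0]), 1, np.random.default_rng(0))
        assert out[0] == 15.0

    def test_identical_donor_values_deterministic(self):
        donor_pred = np.linspace(0, 1, 30)
        donor_vals = np.full(30, 7.0)
        out = pmm_draw(donor_pred, donor_vals, np.random.default_rng(0).random(10), 5,
                       np.random.default_rng(1))
        assert (out == 7.0).all()

    def test_fewer_donors_than_k_warns_and_uses_all(self):
        with pytest.warns(UserWarning, match="donors"):
            out = pmm_draw(np.array([0.0, 1.0]), np.array([3.0, 4.0]),
                           np.array([0.2, 0.9]), 5, np.random.default_rng(0))
        assert set(out) <= {3.0, 4.0}

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 10))
    def test_support_property_never_interpolates(self, seed, k):
        rng = np.random.default_rng(seed)
        donor_pred = rng.standard_normal(40)
        donor_vals = rng.integers(0, 5, 40).astype(float)
        recip = rng.standard_normal(25) * 3
        out = pmm_draw(donor_pred, donor_vals, recip, k, rng)
        assert set(out) <= set(donor_vals)


class TestTreeDraws:
    def test_stump_is_marginal_hot_deck(self):
        rng = np.random.default_rng(0)
        feats = rng.standard_normal((50, 2)).astype(np.float32)
        vals = rng.integers(0, 3, 50).astype(float)
        stump = _fit_tree(feats, vals, min_leaf=50)  # cannot split
        out = tree_draw(stump, feats, vals, feats[:20], rng)
        assert set(out) <= set(vals)

    def test_pure_leaf_is_deterministic(self):
        feats = np.array([[0.0], [0.0], [1.0], [1.0]], dtype=np.float32)
        vals = np.array([2.0, 2.0, 9.0, 9.0])
        tree = _fit_tree(feats, vals, min_leaf=1)
        out = tree_draw(tree, feats, vals, np.array([[1.0]], dtype=np.float32),
                        np.random.default_rng(0))
        assert out[0] == 9.0


@pytest.mark.parametrize("method", ["pmm", "cart", "rf"])
class TestMassImputeFCS:
    def test_support_preservation_and_shape(self, method):
        sA, sB = make_pair()
        spec = mi.ImputerSpec(method=method, m=3, iterations=2, seed=5)
        mis = mi.mass_impute_fcs(sA, sB, spec)
        assert mis.m == 3
        for comp in mis.completions:
            assert len(comp) == sA.n
            assert not comp.isna().any().any()
            assert set(comp["Y"]) <= set(sB.data["Y"])
            assert set(comp["Z"]) <= set(sB.data["Z"])  # donor values only

    def test_seed_determinism(self, method):
        sA, sB = make_pair()
        spec = mi.ImputerSpec(method=method, m=2, iterations=2, seed=42)
        a = mi.mass_impute_fcs(sA, sB, spec)
        b = mi.mass_impute_fcs(sA, sB, spec)
        for ca, cb in zip(a.completions, b.completions):
            assert ca.equals(cb)

    def test_trace_records_every_sweep(self, method):
        sA, sB = make_pair()
        spec = mi.ImputerSpec(method=method, m=2, iterations=3, seed=0)
        mis = mi.mass_impute_fcs(sA, sB, spec)
        assert len(mis.trace) == 2 * 3 * 2  # m * sweeps * outcomes
        assert set(mis.trace["variable"]) == {"Y", "Z"}


class TestSpecValidation:
    def test_single_outcome_runs(self):
        sA, sB = make_pair()
        sB_single = mi.SurveySample(
            unit_ids=sB.unit_ids, weights=sB.weights,
            observed_columns=("X", "Y"), data=sB.data[["X", "Y"]], schema=sB.schema,
        )
        mis = mi.mass_impute_fcs(sA, sB_single, mi.ImputerSpec(method="pmm", m=2, seed=0))
        assert list(mis.completions[0].columns) == ["Y"]

    def test_bad_order_rejected(self):
        sA, sB = make_pair()
        spec = mi.ImputerSpec(method="pmm", order=("Y",), seed=0)
        with pytest.raises(ValueError, match="permutation"):
            mi.mass_impute_fcs(sA, sB, spec)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            mi.ImputerSpec(method="svm")
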