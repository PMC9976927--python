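"""Attribution additivity, factor aggregation, minimal set, Fisher test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pausescape.interpretation import (
    ContributionTable,
    _rf_path_attributions,
    aggregate_by_binding_mode,
    aggregate_by_factor,
    aggregate_by_group,
    compute_attributions,
    factor_mode_scores,
    fisher_enrichment,
    select_minimal_factor_set,
    splicing_intron_enrichment_table,
)
from pausescape.modeling import ModelSpec, train_model

from .test_modeling import random_X, tiny_spec


class TestAttributions:
    @pytest.mark.parametrize("learner", ["xgb", "gbdt", "rf", "ridge"])
    def test_additivity_per_row(self, rng, learner):
        X = random_X(rng, n=150)
        y = 2 * X["chip.F1.5prime"] - X["chip.F4.5prime"] + rng.normal(0, 0.2, 150)
        spec = tiny_spec(learner=learner, max_depths=(3,) if learner != "rf" else (0,))
        model = train_model(X, y, spec)
        ct = compute_attributions(model, X)
        recon = ct.base_value + ct.phi.sum(axis=1)
        assert np.allclose(recon, ct.predictions, rtol=1e-4, atol=1e-4)

    def test_constant_model_all_zero(self, rng):
        X = random_X(rng, n=60)
        y = np.full(60, 1.5)
        model = train_model(X, y, tiny_spec())
        ct = compute_attributions(model, X)
        assert np.allclose(ct.phi.to_numpy(), 0.0, atol=1e-6)
        assert ct.base_value == pytest.approx(1.5, abs=1e-3)

    def test_single_depth_one_tree_closed_form(self):
        """A one-split forest credits the split feature with the leaf-mean
        difference and nothing else."""
        from sklearn.tree import DecisionTreeRegressor
        from sklearn.ensemble import RandomForestRegressor

        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 10, dtype=float)
        y = X[:, 0] * 2.0
        rf = RandomForestRegressor(
            n_estimators=1, max_depth=1, bootstrap=False, random_state=0
        ).fit(X, y)
        phi, base = _rf_path_attributions(rf, X)
        # root mean 1.0; leaves 0 and 2 -> contributions -1 / +1 on feature 0
        assert base == pytest.approx(1.0)
        assert np.allclose(phi[:, 1], 0.0)
        assert np.allclose(phi[:, 0], np.where(X[:, 0] > 0.5, 1.0, -1.0))

    def test_ridge_route_closed_form(self, rng):
        X = random_X(rng, n=120)
        y = X.to_numpy() @ rng.normal(size=X.shape[1]) + rng.normal(0, 0.1, 120)
        model = train_model(X, y, tiny_spec(learner="ridge"))
        ct = compute_attributions(model, X)
        coef = model.model_.coef_
        expected = (X.to_numpy() - model.train_mean_) * coef
        assert np.allclose(ct.phi.to_numpy(), expected)


def _ct(phi: pd.DataFrame, base=0.0):
    preds = base + phi.sum(axis=1)
    return ContributionTable(phi=phi, base_value=base, predictions=preds)


def _meta(columns):
    rows = []
    for c in columns:
        if c.startswith(("chip.", "clip.")):
            parts = c.split(".")
            rank = int(parts[-1]) if "ncRNA" in c else None
            region = parts[2]
            rows.append(
                {
                    "name": c,
                    "kind": "binding",
                    "assay": parts[0],
                    "factor": parts[1],
                    "region": region,
                    "rank": rank,
                    "p_obs": 0.3,
                }
            )
        else:
            rows.append(
                {
                    "name": c,
                    "kind": "annotation",
                    "assay": None,
                    "factor": None,
                    "region": None,
                    "rank": None,
                    "p_obs": np.nan,
                }
            )
    return pd.DataFrame(rows)


class TestAggregation:
    def test_single_factor_share_is_one(self, rng):
        cols = ["chip.A.5prime", "chip.A.intron"]
        phi = pd.DataFrame(rng.normal(size=(20, 2)), columns=cols)
        df = aggregate_by_factor(_ct(phi), _meta(cols))
        assert df.loc["A", "share"] == pytest.approx(1.0)

    def test_mirrored_factors_score_equal(self, rng):
        cols = ["chip.A.5prime", "chip.B.5prime"]
        a = rng.normal(size=20)
        phi = pd.DataFrame({"chip.A.5prime": a, "chip.B.5prime": -a})
        df = aggregate_by_factor(_ct(phi), _meta(cols))
        assert df.loc["A", "S"] == pytest.approx(df.loc["B", "S"])

    def test_matches_double_loop_oracle(self, rng):
        cols = [
            "chip.A.5prime",
            "chip.A.intron",
            "clip.B.intron",
            "clip.B.intron.Proximal.ncRNA.1",
            "tx.len",
        ]
        phi = pd.DataFrame(rng.normal(size=(50, len(cols))), columns=cols)
        meta = _meta(cols)
        df = aggregate_by_factor(_ct(phi), meta, share_base="all")
        expected = {}
        for c in cols:
            f = c.split(".")[1] if c.startswith(("chip.", "clip.")) else "annotation"
            expected[f] = expected.get(f, 0.0) + np.abs(phi[c]).mean()
        for f, s in expected.items():
            assert df.loc[f, "S"] == pytest.approx(s)
        assert df["share"].sum() == pytest.approx(1.0)
        # conservation: sum of factor scores equals sum of column importances
        assert df["S"].sum() == pytest.approx(np.abs(phi).mean(axis=0).sum())

    def test_unmapped_column_rejected(self, rng):
        phi = pd.DataFrame(rng.normal(size=(5, 1)), columns=["chip.A.5prime"])
        with pytest.raises(ValueError, match="missing"):
            aggregate_by_factor(_ct(phi), _meta(["chip.B.5prime"]))

    def test_group_aggregation_overlap_and_empty(self):
        scores = pd.Series({"A": 1.0, "B": 2.0, "C": 4.0})
        groups = {"all": ["A", "B", "C"], "none": [], "ab": ["A", "B"], "bc": ["B", "C"]}
        out = aggregate_by_group(scores, groups)
        assert out["all"] == 7.0 and out["none"] == 0.0
        assert out["ab"] + out["bc"] == 9.0  # B counted in both

    def test_binding_modes(self, rng):
        cols = [
            "chip.A.5prime",
            "clip.B.intron",
            "clip.B.intron.Proximal.ncRNA.2",
            "tx.len",
        ]
        phi = pd.DataFrame(rng.normal(size=(30, len(cols))), columns=cols)
        modes = aggregate_by_binding_mode(_ct(phi), _meta(cols))
        assert modes["DNA_5prime"] == pytest.approx(np.abs(phi[cols[0]]).mean())
        assert modes["RNA_intron"] == pytest.approx(np.abs(phi[cols[1]]).mean())
        assert modes["RNA_ncRNA"] == pytest.approx(np.abs(phi[cols[2]]).mean())
        assert "tx.len" not in modes.index


class TestMinimalSet:
    def test_exhaustive_prefix_oracle(self):
        shares = pd.Series({"A": 0.4, "B": 0.2, "C": 0.2, "D": 0.2})
        assert select_minimal_factor_set(shares, 0.5) == ["A", "B"]

    def test_single_factor(self):
        shares = pd.Series({"A": 1.0})
        for t in (0.01, 0.5, 1.0):
            assert select_minimal_factor_set(shares, t) == ["A"]

    def test_tie_breaks_lexicographic(self):
        shares = pd.Series({"B": 0.5, "A": 0.5})
        assert select_minimal_factor_set(shares, 0.5) == ["A"]

    def test_invalid_target_rejected(self):
        shares = pd.Series({"A": 1.0})
        for t in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                select_minimal_factor_set(shares, t)

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=15),
        st.floats(min_value=0.01, max_value=1.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_minimality_property(self, weights, target):
        """The selected prefix reaches the target and is minimal."""
        v = np.array(weights)
        shares = pd.Series(v / v.sum(), index=[f"F{i}" for i in range(len(v))])
        picked = select_minimal_factor_set(shares, target)
        assert shares[picked].sum() >= target - 1e-9
        if len(picked) > 1:
            assert shares[picked[:-1]].sum() < target

    def test_minimality_property_random(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 12))
            v = rng.random(k)
            shares = pd.Series(v / v.sum(), index=[f"F{i}" for i in range(k)])
            target = float(rng.uniform(0.05, 1.0))
            picked = select_minimal_factor_set(shares, target)
            assert shares[picked].sum() >= target - 1e-9
            if len(picked) > 1:
                assert shares[picked[:-1]].sum() < target


class TestFisher:
    def test_balanced_table(self):
        orat, p = fisher_enrichment([[1, 1], [1, 1]])
        assert orat == pytest.approx(1.0)
        # enumeration oracle: P(X >= 1) under Hypergeom(N=4, K=2, n=2)
        expected = sum(
            stats.hypergeom.pmf(k, 4, 2, 2) for k in range(1, 3)
        )
        assert p == pytest.approx(expected)

    def test_diagonal_closed_form(self):
        orat, p = fisher_enrichment([[5, 0], [0, 5]])
        assert math.isinf(orat)
        assert p == pytest.approx(1.0 / math.comb(10, 5))

    def test_monotone_in_concordance(self):
        # growing the concordant diagonal with fixed margins shrinks p
        ps = [fisher_enrichment([[a, 10 - a], [10 - a, a]])[1] for a in range(5, 11)]
        assert all(x > y for x, y in zip(ps, ps[1:]))

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(1000):
            t = rng.integers(0, 30, size=(2, 2))
            orat, p = fisher_enrichment(t, alternative="greater")
            assert p == pytest.approx(
                stats.fisher_exact(t, alternative="greater")[1]
            )
            a, b, c, d = t.ravel()
            if b * c > 0:
                assert orat == pytest.approx((a * d) / (b * c))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment([[1, -1], [0, 2]])

    def test_enrichment_table_construction(self, rng):
        scores = pd.Series(rng.random(20), index=[f"F{i}" for i in range(20)])
        members = {f"F{i}" for i in range(0, 10)}
        t = splicing_intron_enrichment_table(scores, members)
        assert t.sum() == 20
        median = scores.median()
        assert t[0].sum() == (scores > median).sum()
        assert (t[0, 0] + t[1, 0]) == 10
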