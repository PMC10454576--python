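import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import csti_oracle, jacobi_eigh, correlation_matrix_loops
from saltpipe.csti import (DegenerateInput, classify, csti_scores,
                           evaluate_panel, membership, pca_weights)


class TestMembership:
    @pytest.mark.parametrize("x,lo,hi,direction,expected", [
        (0.0, 0.0, 2.0, "positive", 0.0),
        (2.0, 0.0, 2.0, "positive", 1.0),
        (1.0, 0.0, 2.0, "positive", 0.5),
        (1.0, 0.0, 2.0, "negative", 0.5),
        (0.0, 0.0, 2.0, "negative", 1.0),
        (5.0, 5.0, 5.0, "positive", 0.5),   # degenerate range
    ])
    def test_boundary_values(self, x, lo, hi, direction, expected):
        assert membership(x, lo, hi, direction) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            membership(3.0, 0.0, 2.0)

    @settings(max_examples=300, derandomize=True)
    @given(st.floats(0, 1, allow_nan=False))
    def test_duality(self, frac):
        lo, hi = -1.3, 2.7
        x = lo + frac * (hi - lo)
        assert membership(x, lo, hi, "positive") + \
            membership(x, lo, hi, "negative") == pytest.approx(1.0)


class TestPCAWeights:
    def test_rank_one_matrix_selects_single_component(self):
        g = np.linspace(0.4, 1.4, 5)
        sti = pd.DataFrame({"a": g, "b": 2 * g + 1},
                           index=[f"G{i}" for i in range(5)])
        model = pca_weights(sti)
        assert model.k_selected == 1
        assert model.contribution[0] == pytest.approx(1.0)

    def test_contribution_arithmetic(self):
        # eigenvalue shares (0.75, 0.25, 0, 0) with an 80% target keep 2
        # components weighted by their shares
        shares = np.array([0.75, 0.25, 0.0, 0.0])
        k = int(np.searchsorted(np.cumsum(shares), 0.80 - 1e-12) + 1)
        assert k == 2
        w = shares[:k] / shares[:k].sum()
        assert np.allclose(w, [0.75, 0.25])

    def test_eigenvalues_match_jacobi_oracle(self, sti_fixture):
        model = pca_weights(sti_fixture)
        corr = correlation_matrix_loops(sti_fixture.values)
        oracle_vals, _ = jacobi_eigh(corr)
        assert np.allclose(model.eigenvalues, np.clip(oracle_vals, 0, None),
                           atol=1e-9)
        assert model.contribution.sum() == pytest.approx(1.0)

    def test_constant_trait_dropped(self, sti_fixture):
        sti = sti_fixture.assign(flat=1.0)
        with pytest.warns(UserWarning, match="flat"):
            model = pca_weights(sti)
        assert "flat" not in model.loadings.index

    def test_too_small_inputs_rejected(self, sti_fixture):
        with pytest.raises(DegenerateInput):
            pca_weights(sti_fixture.iloc[:2])
        with pytest.raises(DegenerateInput):
            pca_weights(sti_fixture.assign(b=1.0, c=2.0)[["b", "c"]])


class TestCSTI:
    def test_matches_full_oracle(self, sti_fixture):
        directions = ["negative" if t.startswith("Na") else "positive"
                      for t in sti_fixture.columns]
        oracle = csti_oracle(sti_fixture.values, directions)
        result, model = csti_scores(sti_fixture)
        assert model.k_selected == oracle["k"]
        assert np.allclose(model.scores.values, oracle["scores"], atol=1e-8)
        assert np.allclose(result["csti"].values, oracle["csti"], atol=1e-8)
        weights = np.array(list(result.attrs["weights"].values()))
        assert weights.sum() == pytest.approx(1.0)
        assert ((result["csti"] >= 0) & (result["csti"] <= 1)).all()

    def test_single_component_hits_unit_interval_endpoints(self):
        g = np.array([0.2, 0.5, 0.8, 1.1, 1.4])
        sti = pd.DataFrame({"a": g, "b": 3 * g},
                           index=[f"G{i}" for i in range(5)])
        result, model = csti_scores(sti)
        assert model.k_selected == 1
        assert result["csti"].max() == pytest.approx(1.0)
        assert result["csti"].min() == pytest.approx(0.0)
        # best genotype is the one with the highest STI
        assert result["csti"].idxmax() == "G4"

    def test_order_equivariance(self, sti_fixture):
        base, _ = csti_scores(sti_fixture)
        perm = sti_fixture.iloc[[3, 0, 5, 1, 4, 2]]
        shuffled, _ = csti_scores(perm)
        pd.testing.assert_series_equal(base["csti"].sort_index(),
                                       shuffled["csti"].sort_index())

    def test_affine_trait_rescaling_invariance(self, sti_fixture):
        base, _ = csti_scores(sti_fixture)
        scaled = sti_fixture.copy()
        scaled["DW_shoot"] = 7.0 * scaled["DW_shoot"] + 3.0
        got, _ = csti_scores(scaled)
        assert np.allclose(base["csti"], got["csti"], atol=1e-12)

    def test_monotone_in_sti_for_effectively_one_trait(self):
        # duplicated trait -> one component; CSTI order must equal STI order
        rng = np.random.default_rng(5)
        g = rng.uniform(0.3, 1.5, 8)
        sti = pd.DataFrame({"a": g, "a2": g}, index=[f"G{i}" for i in range(8)])
        result, _ = csti_scores(sti)
        assert (result["csti"].rank() == pd.Series(g, result.index).rank()).all()

    def test_trait_level_reading_stays_convex(self, sti_fixture):
        result, _ = csti_scores(sti_fixture, membership_level="trait")
        weights = np.array(list(result.attrs["weights"].values()))
        assert weights.sum() == pytest.approx(1.0)
        assert ((result["csti"] >= 0) & (result["csti"] <= 1)).all()


class TestClassify:
    def test_well_separated_three_classes(self):
        csti = pd.Series([0.95, 0.9, 0.5, 0.45, 0.1],
                         index=["a", "b", "c", "d", "e"])
        classes = classify(csti)
        assert classes.tolist() == ["salt-resistant", "salt-resistant",
                                    "salt-tolerant", "salt-tolerant",
                                    "salt-sensitive"]

    def test_all_equal_is_degenerate(self):
        with pytest.raises(DegenerateInput, match="degenerate"):
            classify(pd.Series([0.5] * 5, index=list("abcde")))

    def test_too_few_genotypes_rejected(self):
        with pytest.raises(DegenerateInput):
            classify(pd.Series([0.1, 0.9], index=["a", "b"]))

    def test_evaluate_panel_assigns_ranks_and_classes(self, sti_fixture):
        result, _ = evaluate_panel(sti_fixture)
        assert sorted(result["rank"]) == list(range(1, 7))
        assert set(result["class"]) <= {"salt-resistant", "salt-tolerant",
                                        "salt-sensitive"}
        # rank 1 is the top CSTI
        assert result.loc[result["rank"] == 1, "csti"].iloc[0] == result["csti"].max()
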