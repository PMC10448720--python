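import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ketox import curves, ke_model
from oracles import fine_grid_trapezoid, roc_auc_pairwise


def constant_surface(assay_id, grid, rows):
    """Surface with per-chemical constant rows (values assumed pre-normalized)."""
    chem_ids = list(rows)
    values = np.stack([np.full(len(grid), rows[c]) for c in chem_ids])
    return curves.ResponseSurface(assay_id=assay_id, chem_ids=chem_ids, grid=grid, values=values)


class TestComposeKECurve:
    def test_single_assay_identity(self, grid):
        surf = constant_surface("A1", grid, {"C1": 0.8})
        curve = ke_model.compose_ke_curve("KE1", ["A1"], {"A1": surf}, "C1")
        np.testing.assert_allclose(curve.values, surf.row("C1"))

    def test_untested_chemical_gets_zero_curve(self, grid):
        surf = constant_surface("A1", grid, {"C1": 0.8})
        curve = ke_model.compose_ke_curve("KE1", ["A1"], {"A1": surf}, "MISSING")
        assert not curve.values.any()

    def test_mean_of_constant_rows(self, grid):
        surfaces = {
            "A1": constant_surface("A1", grid, {"C1": 0.2}),
            "A2": constant_surface("A2", grid, {"C1": 0.6}),
        }
        curve = ke_model.compose_ke_curve("KE1", ["A1", "A2"], surfaces, "C1")
        np.testing.assert_allclose(curve.values, 0.4)

    def test_empty_ke_rejected(self, grid):
        with pytest.raises(ValueError):
            ke_model.compose_ke_curve("KE1", [], {}, "C1")

    def test_permutation_invariant_in_assay_order(self, grid, rng):
        surfaces = {
            f"A{i}": constant_surface(f"A{i}", grid, {"C1": rng.uniform(0, 1), "C2": rng.uniform(0, 1)})
            for i in range(4)
        }
        order1 = ["A0", "A1", "A2", "A3"]
        order2 = ["A3", "A1", "A0", "A2"]
        f1 = ke_model.compose_ke_curves("KE1", order1, surfaces, ["C1", "C2"])
        f2 = ke_model.compose_ke_curves("KE1", order2, surfaces, ["C1", "C2"])
        pd.testing.assert_frame_equal(f1, f2)

    def test_values_stay_in_unit_interval(self, grid, rng):
        surfaces = {
            f"A{i}": constant_surface(f"A{i}", grid, {f"C{j}": rng.uniform(0, 1) for j in range(5)})
            for i in range(3)
        }
        frame = ke_model.compose_ke_curves("KE1", list(surfaces), surfaces, [f"C{j}" for j in range(5)])
        assert (frame.to_numpy() >= 0).all() and (frame.to_numpy() <= 1).all()

    def test_monotone_in_single_assay_response(self, grid):
        low = {
            "A1": constant_surface("A1", grid, {"C1": 0.3}),
            "A2": constant_surface("A2", grid, {"C1": 0.5}),
        }
        high = {
            "A1": constant_surface("A1", grid, {"C1": 0.9}),
            "A2": constant_surface("A2", grid, {"C1": 0.5}),
        }
        c_low = ke_model.compose_ke_curve("KE1", ["A1", "A2"], low, "C1")
        c_high = ke_model.compose_ke_curve("KE1", ["A1", "A2"], high, "C1")
        assert np.all(c_high.values >= c_low.values)
        assert ke_model.ke_score(c_high.values, grid) >= ke_model.ke_score(c_low.values, grid)

    def test_sum_rescaled_mode_peaks_at_one(self, grid):
        surfaces = {
            "A1": constant_surface("A1", grid, {"C1": 0.5, "C2": 0.1}),
            "A2": constant_surface("A2", grid, {"C1": 0.5, "C2": 0.3}),
        }
        frame = ke_model.compose_ke_curves("KE1", ["A1", "A2"], surfaces, ["C1", "C2"], mode="sum-rescaled")
        assert frame.to_numpy().max() == pytest.approx(1.0)
        np.testing.assert_allclose(frame.loc["C2"], 0.4)


class TestKEScore:
    def test_zero_curve_scores_zero(self, grid):
        assert ke_model.ke_score(np.zeros(len(grid)), grid) == 0.0

    def test_constant_one_scores_one(self, grid):
        assert ke_model.ke_score(np.ones(len(grid)), grid) == pytest.approx(1.0)

    def test_matches_fine_grid_quadrature(self, coarse_grid, rng):
        values = rng.uniform(0, 1, len(coarse_grid))
        expected = fine_grid_trapezoid(values, coarse_grid.log10_points, refine=1000)
        assert ke_model.ke_score(values, coarse_grid) == pytest.approx(expected, abs=1e-6)

    def test_hill_curve_score_matches_fine_quadrature(self, grid):
        values = np.asarray(curves.hill_response(1.0, 2.0, 0.5, grid.points))
        expected = fine_grid_trapezoid(values, grid.log10_points, refine=1000)
        assert ke_model.ke_score(values, grid) == pytest.approx(expected, abs=1e-6)

    def test_wrong_length_rejected(self, grid):
        with pytest.raises(ValueError):
            ke_model.ke_score(np.zeros(5), grid)


class TestScaleScores:
    def test_divide_by_max(self):
        raw = pd.Series({"C1": 0.2, "C2": 0.1, "C3": 0.0})
        scaled = ke_model.scale_scores(raw)
        assert scaled.to_dict() == {"C1": 1.0, "C2": 0.5, "C3": 0.0}

    def test_all_zero_stays_zero(self):
        raw = pd.Series({"C1": 0.0, "C2": 0.0})
        assert ke_model.scale_scores(raw).to_dict() == {"C1": 0.0, "C2": 0.0}

    def test_single_positive_chemical_scales_to_one(self):
        assert ke_model.scale_scores(pd.Series({"C1": 0.07})).to_dict() == {"C1": 1.0}

    def test_idempotent(self, rng):
        raw = pd.Series(rng.uniform(0, 0.9, 10), index=[f"C{i}" for i in range(10)])
        once = ke_model.scale_scores(raw)
        pd.testing.assert_series_equal(ke_model.scale_scores(once), once)


class TestRankChemicals:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ({"C1": 0.1, "C2": 0.9, "C3": 0.5}, ["C2", "C3", "C1"]),
            ({"B": 0.5, "A": 0.5, "C": 0.2}, ["A", "B", "C"]),
            ({"X": 0.0, "Y": 1.0, "Z": 0.0}, ["Y", "X", "Z"]),
        ],
    )
    def test_hand_ordered(self, scores, expected):
        assert ke_model.rank_chemicals(pd.Series(scores)) == expected


class TestROCAUC:
    def test_perfect_separation(self):
        scores = pd.Series({"C1": 0.9, "C2": 0.8, "C3": 0.1, "C4": 0.2})
        labels = pd.Series({"C1": 1, "C2": 1, "C3": 0, "C4": 0})
        assert ke_model.ke_roc_auc(scores, labels) == pytest.approx(1.0)

    def test_pure_ties_give_half(self):
        scores = pd.Series({"C1": 0.5, "C2": 0.5, "C3": 0.5, "C4": 0.5})
        labels = pd.Series({"C1": 1, "C2": 0, "C3": 1, "C4": 0})
        assert ke_model.ke_roc_auc(scores, labels) == pytest.approx(0.5)

    def test_six_chemical_oracle(self):
        vals = [0.9, 0.4, 0.4, 0.3, 0.8, 0.1]
        labs = [1, 0, 1, 0, 1, 0]
        ids = [f"C{i}" for i in range(6)]
        expected = roc_auc_pairwise(vals, labs)
        got = ke_model.ke_roc_auc(pd.Series(vals, index=ids), pd.Series(labs, index=ids))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        scores = pd.Series({"C1": 0.5, "C2": 0.6})
        labels = pd.Series({"C1": 1, "C2": 1})
        with pytest.raises(ValueError):
            ke_model.ke_roc_auc(scores, labels)

    @settings(max_examples=100, deadline=None)
    @given(
        n=st.integers(min_value=2, max_value=12),
        seed=st.integers(min_value=0, max_value=100_000),
    )
    def test_matches_pairwise_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        # coarse score levels force plenty of ties
        vals = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)
        labs = rng.integers(0, 2, size=n)
        if labs.min() == labs.max():
            labs[0] = 1 - labs[0]
        ids = [f"C{i}" for i in range(n)]
        expected = roc_auc_pairwise(vals.tolist(), labs.tolist())
        got = ke_model.ke_roc_auc(pd.Series(vals, index=ids), pd.Series(labs, index=ids))
        assert got == pytest.approx(expected, abs=1e-12)


class TestScoreTable:
    def test_end_to_end_bounds_and_scaling(self, grid, small_bundle):
        from ketox import io

        fits = io.best_fits(small_bundle.curve_fits)
        chem_ids = sorted({c for c, _ in fits})
        members = io.ke_groups(small_bundle.ke_assignments)
        assay_ids = sorted({a for assays in members.values() for a in assays})
        surfaces = curves.build_surfaces(fits, grid, chem_ids, assay_ids)
        table = ke_model.score_table(members, surfaces, chem_ids, grid)
        assert ((table["raw_auc"] >= 0) & (table["raw_auc"] <= 1)).all()
        assert ((table["scaled_score"] >= 0) & (table["scaled_score"] <= 1)).all()
        for _, group in table.groupby("ke_id"):
            if group["raw_auc"].max() > 0:
                assert group["scaled_score"].max() == pytest.approx(1.0)

    def test_plot_export_smoke(self, grid, tmp_path):
        frame = pd.DataFrame(
            np.linspace(0, 1, len(grid))[None, :].repeat(2, axis=0),
            index=pd.Index(["C1", "C2"], name="chem_id"),
            columns=[f"{lg:.3f}" for lg in grid.log10_points],
        )
        out = tmp_path / "ke.png"
        ke_model.plot_ke_curves(frame, grid, out, title="KE1")
        assert out.stat().st_size > 0
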