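"""Dynamic-CpG selection, Manhattan distances, axis derivation and the
per-CpG linear model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methylcoom.io import BetaMatrix, SampleSheet
from methylcoom.synthetic import SimulationConfig, simulate_scenario
from methylcoom.trajectory import (
    Trajectory,
    build_axis,
    fit_linear_model,
    identify_dynamic_cpgs,
    manhattan_distances,
    refit_with_linear_cpgs,
    subpopulation_profiles,
)


def _sheet(groups):
    """groups: list of (subpopulation, ordinal, n_samples)."""
    rows, idx = [], []
    for sub, o, n in groups:
        for k in range(n):
            idx.append(f"{sub}{k}")
            rows.append(("reference", sub, o))
    return SampleSheet(
        pd.DataFrame(
            rows,
            columns=["role", "subpopulation", "ordinal"],
            index=pd.Index(idx, name="sample_id"),
        )
    )


def _matrix(rows, samples):
    return BetaMatrix(
        pd.DataFrame(rows, index=[f"cg{i}" for i in range(len(rows))], columns=samples)
    )


class TestDynamicCpGs:
    def test_delta_and_p_match_hand_computed_t_test(self):
        sheet = _sheet([("S", 0, 3), ("E", 1, 3)])
        m = _matrix([[0.80, 0.78, 0.82, 0.40, 0.42, 0.38]], list(sheet.table.index))
        out = identify_dynamic_cpgs(m, sheet)
        assert out.loc["cg0", "delta"] == pytest.approx(-0.40)
        # independent oracle: pooled-variance Student t from first principles
        a = np.array([0.80, 0.78, 0.82])
        b = np.array([0.40, 0.42, 0.38])
        sp2 = ((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p = 2 * stats.t.sf(abs(t), 4)
        assert out.loc["cg0", "p_value"] == pytest.approx(p, rel=1e-9)
        assert bool(out.loc["cg0", "dynamic"]) is True

    def test_small_delta_never_dynamic(self):
        sheet = _sheet([("S", 0, 3), ("E", 1, 3)])
        m = _matrix([[0.50, 0.50, 0.50, 0.65, 0.66, 0.64]], list(sheet.table.index))
        out = identify_dynamic_cpgs(m, sheet)
        assert abs(out.loc["cg0", "delta"]) == pytest.approx(0.15)
        assert not out.loc["cg0", "dynamic"]

    def test_identical_groups_not_dynamic(self):
        sheet = _sheet([("S", 0, 2), ("E", 1, 2)])
        m = _matrix([[0.4, 0.4, 0.4, 0.4]], list(sheet.table.index))
        out = identify_dynamic_cpgs(m, sheet)
        assert out.loc["cg0", "delta"] == 0
        assert out.loc["cg0", "p_value"] == 1.0
        assert not out.loc["cg0", "dynamic"]

    def test_single_sample_group_rejected(self):
        sheet = _sheet([("S", 0, 1), ("E", 1, 3)])
        m = _matrix([[0.1, 0.2, 0.3, 0.4]], list(sheet.table.index))
        with pytest.raises(ValueError):
            identify_dynamic_cpgs(m, sheet)


class TestManhattan:
    def test_identical_columns_zero(self):
        m = _matrix([[0.2, 0.2], [0.7, 0.7]], ["a", "b"])
        assert manhattan_distances(m).loc["a", "b"] == 0.0

    def test_hand_summed_example(self):
        m = _matrix([[0.0, 1.0], [0.5, 0.5], [1.0, 0.0]], ["a", "b"])
        assert manhattan_distances(m).loc["a", "b"] == pytest.approx(2.0)

    def test_matches_elementwise_double_loop(self):
        rng = np.random.default_rng(3)
        vals = rng.random((50, 6))
        m = _matrix(vals, [f"s{i}" for i in range(6)])
        d = manhattan_distances(m)
        for i in range(6):
            for j in range(6):
                expected = sum(abs(vals[p, i] - vals[p, j]) for p in range(50))
                assert d.iloc[i, j] == pytest.approx(expected, abs=1e-9)

    def test_empty_subset_rejected(self):
        m = _matrix([[0.1, 0.2]], ["a", "b"])
        with pytest.raises(ValueError):
            manhattan_distances(m, probes=[])

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((20, 4))
        d = manhattan_distances(_matrix(vals, list("abcd"))).to_numpy()
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestAxis:
    def test_noiseless_continuum_recovers_planted_stages(self, clean_fitted):
        planted = clean_fitted.scenario.config.stages
        subs = clean_fitted.sheet.subpopulations()
        got = np.array([clean_fitted.axis.ds_map[s] for s in subs])
        assert np.abs(got - planted).max() < 1e-9

    def test_endpoints_are_zero_and_hundred(self, small_fitted):
        axis = small_fitted.axis
        assert axis.ds_map[axis.start] == 0.0
        assert axis.ds_map[axis.end] == pytest.approx(100.0)
        vals = [axis.ds_map[s] for s in axis.backbone]
        assert vals == sorted(vals)

    def test_two_subpopulations_fixed_endpoints(self):
        sheet = _sheet([("S", 0, 2), ("E", 1, 2)])
        rng = np.random.default_rng(0)
        m = _matrix(
            np.column_stack([rng.random(30)] * 2 + [rng.random(30)] * 2),
            list(sheet.table.index),
        )
        axis = build_axis(m, sheet, m.probe_ids)
        assert axis.ds_map == {"S": 0.0, "E": 100.0}

    def test_reversing_labels_flips_axis(self, clean_scenario, clean_fitted):
        sheet = clean_fitted.sheet
        flipped = SampleSheet(
            sheet.table.assign(ordinal=-sheet.table["ordinal"])
        )
        axis_rev = build_axis(
            clean_fitted.ref, flipped, clean_fitted.linear_dynamic
        )
        for sub, ds in clean_fitted.axis.ds_map.items():
            assert axis_rev.ds_map[sub] == pytest.approx(100.0 - ds, abs=1e-6)

    def test_axis_invariant_to_sample_order(self, clean_fitted):
        ref = clean_fitted.ref
        rng = np.random.default_rng(1)
        perm = list(rng.permutation(ref.sample_ids))
        shuffled = BetaMatrix(ref.data[perm])
        axis2 = build_axis(shuffled, clean_fitted.sheet, clean_fitted.linear_dynamic)
        for sub, ds in clean_fitted.axis.ds_map.items():
            assert axis2.ds_map[sub] == pytest.approx(ds, abs=1e-9)


def _trajectory(ds_map):
    subs = sorted(ds_map, key=ds_map.get)
    return Trajectory(
        tree=None, backbone=subs, ds_map=ds_map, branchedness=0.0,
        start=subs[0], end=subs[-1], probes=[],
    )


class TestLinearModel:
    def test_exact_line_recovered(self):
        ds_map = {"A": 0.0, "B": 50.0, "C": 100.0}
        sheet = _sheet([("A", 0, 2), ("B", 1, 2), ("C", 2, 2)])
        ds = np.array([0, 0, 50, 50, 100, 100], dtype=float)
        vals = 0.2 + 0.003 * ds
        m = _matrix([vals], list(sheet.table.index))
        out = fit_linear_model(m, sheet, _trajectory(ds_map))
        assert out.loc["cg0", "alpha"] == pytest.approx(0.2, abs=1e-10)
        assert out.loc["cg0", "beta"] == pytest.approx(0.003, abs=1e-10)
        assert bool(out.loc["cg0", "linear"])

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(5)
        sheet = _sheet([(f"P{o}", o, 3) for o in range(6)])
        ds_map = {f"P{o}": o * 20.0 for o in range(6)}
        n = 2000
        vals = np.clip(0.5 + rng.normal(0, 0.02, (n, 18)), 0, 1)
        m = BetaMatrix(
            pd.DataFrame(vals, index=[f"cg{i}" for i in range(n)],
                         columns=list(sheet.table.index))
        )
        out = fit_linear_model(m, sheet, _trajectory(ds_map))
        rate = out["linear"].mean()
        sd = np.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) <= 3 * sd

    def test_missing_reference_value_flags_probe(self):
        sheet = _sheet([("A", 0, 2), ("B", 1, 2), ("C", 2, 2)])
        ds_map = {"A": 0.0, "B": 50.0, "C": 100.0}
        vals = np.array([[0.1, 0.2, 0.3, 0.4, 0.5, np.nan]])
        m = _matrix(vals, list(sheet.table.index))
        out = fit_linear_model(m, sheet, _trajectory(ds_map))
        assert np.isnan(out.loc["cg0", "alpha"])
        assert not out.loc["cg0", "linear"]


class TestRefit:
    def test_all_linear_input_is_fixed_point(self, clean_fitted):
        """Without contaminants the refit reproduces the first pass."""
        dyn = identify_dynamic_cpgs(clean_fitted.ref, clean_fitted.sheet)
        first = build_axis(
            clean_fitted.ref, clean_fitted.sheet, list(dyn.index[dyn["dynamic"]])
        )
        assert set(clean_fitted.linear_dynamic) == set(dyn.index[dyn["dynamic"]])
        for sub, ds in first.ds_map.items():
            assert clean_fitted.axis.ds_map[sub] == pytest.approx(ds, abs=1e-9)

    def test_refit_removes_contaminants_and_improves_axis(self):
        """Non-monotone contaminant programs distort the first-pass axis;
        the lack-of-fit filter removes them and the refit axis lands closer
        (L2) to the planted stages."""
        cfg = SimulationConfig(
            n_probes=2500, fraction_nonlinear=0.2, nonlinear_shape="bump",
            planted_counts={"A": 0, "B": 0, "C": 0, "D": 0},
            n_correlated_genes=0, n_null_genes=5, n_mirnas=4,
            n_planted_mirnas=0, seed=23,
        )
        sc = simulate_scenario(cfg)
        from methylcoom.io import filter_probes

        ref = filter_probes(sc.ref, sc.annotation)
        axis, model, table = refit_with_linear_cpgs(
            ref, sc.sheet, lack_of_fit=True
        )
        dyn_probes = list(table.index[table["dynamic"]])
        first = build_axis(ref, sc.sheet, dyn_probes)
        planted = dict(zip(sc.sheet.subpopulations(), sc.config.stages))
        def l2(ds_map):
            return np.sqrt(sum((ds_map[s] - planted[s]) ** 2 for s in planted))
        # contaminants really were removed
        contaminated = set(sc.ref_truth.index[sc.ref_truth["program"] == "bump"])
        assert len(contaminated & set(axis.probes)) < 0.25 * len(contaminated)
        assert l2(axis.ds_map) <= l2(first.ds_map)

    def test_refit_deterministic(self, small_fitted):
        axis2, model2, table2 = refit_with_linear_cpgs(
            small_fitted.ref, small_fitted.sheet
        )
        assert axis2.ds_map == small_fitted.axis.ds_map
        pd.testing.assert_frame_equal(model2, small_fitted.model)
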