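"""Path analysis: standardization contract, recovery, bootstrap inference."""

import numpy as np
import pandas as pd
import pytest

from divstab.paths import (
    PathModelSpec,
    PathModel,
    default_path_spec,
    default_chains,
    prepare_path_data,
    fit_paths,
    indirect_effects,
    compare_groups,
    indirect_trends,
    minmax_log,
)

CHAIN_SPEC = PathModelSpec(
    nodes=("SR_log", "CE", "ANPP"),
    edges=(("SR_log", "CE"), ("CE", "ANPP")),
    residual_covariances=(),
)


def _chain_data(n=500, seed=0, noise=0.1, shift=0.0):
    """Standardize data from SR -> CE -> ANPP with unit raw coefficients."""
    rng = np.random.default_rng(seed)
    sr = rng.normal(size=n)
    ce = sr + rng.normal(0, noise, n)
    anpp = (1 + shift) * ce + rng.normal(0, noise, n)
    df = pd.DataFrame({"SR_log": sr, "CE": ce, "ANPP": anpp})
    return (df - df.mean()) / df.std(ddof=1)


class TestSpec:
    def test_default_spec_is_acyclic_with_declared_nodes(self):
        spec = default_path_spec()
        order = spec.topological_order()
        assert set(order) == set(spec.nodes)
        assert order.index("SR_log") < order.index("CommStab")

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            PathModelSpec(nodes=("A", "B"), edges=(("A", "B"), ("B", "A")),
                          residual_covariances=())

    def test_undeclared_node_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            PathModelSpec(nodes=("A",), edges=(("A", "Z"),), residual_covariances=())


class TestPrepare:
    @staticmethod
    def _raw(n=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "plot_id": [f"P{i}" for i in range(n)],
            "SR_raw": rng.choice([2, 4, 8, 16], n),
            "CE_raw": rng.normal(50, 30, n),
            "SE_raw": rng.normal(0, 20, n),
            "ANPP_raw": rng.lognormal(6, 0.4, n),
            "CVpop_inv_raw": rng.lognormal(0.5, 0.3, n),
            "Async_raw": rng.uniform(0.05, 0.6, n),
            "CommStab_raw": rng.lognormal(1, 0.3, n),
            "outlier_flag": False,
        })

    def test_standardization_contract(self):
        data = prepare_path_data(self._raw())
        for col in default_path_spec().nodes:
            assert abs(data[col].mean()) < 1e-12
            assert data[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_minmax_log_spec_example(self):
        """{−5, 0, 15} min-max scales to {ε, 0.25, 1}, order preserved."""
        scaled = np.exp(minmax_log(np.array([-5.0, 0.0, 15.0]), epsilon=1e-3))
        assert scaled[0] == pytest.approx(1e-3)
        assert scaled[1] == pytest.approx(0.25)
        assert scaled[2] == pytest.approx(1.0)
        assert np.all(np.diff(scaled) > 0)

    def test_constant_column_errors(self):
        raw = self._raw()
        raw["SE_raw"] = 3.0
        with pytest.raises(ValueError, match="zero variance"):
            prepare_path_data(raw)

    def test_too_few_rows_error(self):
        with pytest.raises(ValueError, match=">= 10"):
            prepare_path_data(self._raw(n=6))

    def test_undefined_rows_dropped_and_counted(self):
        raw = self._raw()
        raw.loc[0, "ANPP_raw"] = -1.0  # log undefined
        data = prepare_path_data(raw)
        assert data.attrs["n_dropped"] == 1
        assert len(data) == len(raw) - 1


class TestFit:
    def test_single_edge_equals_pearson_correlation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=200)
        b = 0.6 * a + rng.normal(0, 0.8, 200)
        df = pd.DataFrame({"A": a, "B": b})
        df = (df - df.mean()) / df.std(ddof=1)
        spec = PathModelSpec(nodes=("A", "B"), edges=(("A", "B"),), residual_covariances=())
        res = fit_paths(df, spec=spec, n_boot=50, seed=0)
        assert res.coef("A", "B") == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)

    def test_chain_recovery_within_bootstrap_ci(self):
        """Known chain SR→CE→ANPP with unit raw coefficients and noise SD
        0.1: the exact standardized coefficients (1/√1.01 for SR→CE,
        √(1.01/1.02) for CE→ANPP) fall inside the 95% bootstrap CI at the
        binomially expected rate over replicate datasets, and every point
        estimate is close to truth. (A single dataset would be fragile:
        the CI here is only ~0.002 wide.)"""
        truths = {("SR_log", "CE"): 1 / np.sqrt(1.01),
                  ("CE", "ANPP"): np.sqrt(1.01 / 1.02)}
        n_rep = 20
        covered = {e: 0 for e in CHAIN_SPEC.edges}
        for rep in range(n_rep):
            data = _chain_data(n=500, seed=100 + rep)
            res = fit_paths(data, spec=CHAIN_SPEC, n_boot=200, seed=rep)
            tbl = res.edges.set_index(["src", "dst"])
            for edge, truth in truths.items():
                row = tbl.loc[edge]
                covered[edge] += row["ci_lo"] <= truth <= row["ci_hi"]
                assert row["coef"] == pytest.approx(truth, abs=0.01)
        for edge, truth in truths.items():
            # binomial(20, 0.95) lower 0.1% bound is 14
            assert covered[edge] >= 14

    def test_bootstrap_reproducible(self):
        data = _chain_data(n=100, seed=3)
        a = fit_paths(data, spec=CHAIN_SPEC, n_boot=100, seed=42)
        b = fit_paths(data, spec=CHAIN_SPEC, n_boot=100, seed=42)
        assert np.array_equal(a.boot, b.boot)
        pd.testing.assert_frame_equal(a.edges, b.edges)

    def test_collinear_parents_rejected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        df = pd.DataFrame({"A": a, "B": a * 1.0, "C": rng.normal(size=50)})
        df = (df - df.mean()) / df.std(ddof=1)
        spec = PathModelSpec(nodes=("A", "B", "C"),
                             edges=(("A", "C"), ("B", "C")), residual_covariances=())
        with pytest.raises(ValueError, match="collinear"):
            fit_paths(df, spec=spec, n_boot=10, seed=0)

    def test_estimates_invariant_to_node_declaration_order(self):
        data = _chain_data(n=200, seed=5)
        spec_rev = PathModelSpec(
            nodes=("ANPP", "CE", "SR_log"),
            edges=(("CE", "ANPP"), ("SR_log", "CE")),
            residual_covariances=(),
        )
        a = fit_paths(data, spec=CHAIN_SPEC, n_boot=10, seed=0)
        b = fit_paths(data, spec=spec_rev, n_boot=10, seed=0)
        assert a.coef("SR_log", "CE") == pytest.approx(b.coef("SR_log", "CE"), abs=1e-12)
        assert a.coef("CE", "ANPP") == pytest.approx(b.coef("CE", "ANPP"), abs=1e-12)

    def test_null_coefficients_covered_by_ci(self):
        """Permuted response: 95% CIs cover 0 in >= 90% of replicates."""
        rng = np.random.default_rng(0)
        covered = 0
        n_rep = 60
        for rep in range(n_rep):
            sr = rng.normal(size=80)
            ce = rng.normal(size=80)  # independent of sr
            df = pd.DataFrame({"SR_log": sr, "CE": ce})
            df = (df - df.mean()) / df.std(ddof=1)
            spec = PathModelSpec(nodes=("SR_log", "CE"),
                                 edges=(("SR_log", "CE"),), residual_covariances=())
            res = fit_paths(df, spec=spec, n_boot=200, seed=rep)
            row = res.edges.iloc[0]
            covered += row["ci_lo"] <= 0 <= row["ci_hi"]
        assert covered / n_rep >= 0.9


class TestIndirectEffects:
    def test_chain_effect_is_product_of_edges(self):
        data = _chain_data(n=300, seed=7)
        res = fit_paths(data, spec=CHAIN_SPEC, n_boot=200, seed=0)
        chains = {"SR->CE->ANPP": (("SR_log", "CE"), ("CE", "ANPP"))}
        ie = indirect_effects(res, chains)
        expected = res.coef("SR_log", "CE") * res.coef("CE", "ANPP")
        assert ie.iloc[0]["effect"] == pytest.approx(expected, abs=1e-12)
        # generative chain product ≈ (1/sqrt(1.01))² within the CI
        truth = 1 / 1.01
        assert ie.iloc[0]["ci_lo"] <= truth <= ie.iloc[0]["ci_hi"]

    def test_missing_edge_in_chain_errors(self):
        data = _chain_data(n=100, seed=8)
        res = fit_paths(data, spec=CHAIN_SPEC, n_boot=10, seed=0)
        with pytest.raises(ValueError, match="absent"):
            indirect_effects(res, {"bad": (("ANPP", "SR_log"),)})

    def test_default_chains_enumerate_all_sr_to_commstab_paths(self):
        chains = default_chains()
        assert len(chains) == 9
        for trail in chains.values():
            assert trail[0][0] == "SR_log"
            assert trail[-1][1] == "CommStab"

    def test_total_effect_is_direct_plus_indirect(self):
        data = _chain_data(n=200, seed=9)
        spec = PathModelSpec(
            nodes=("SR_log", "CE", "ANPP"),
            edges=(("SR_log", "CE"), ("CE", "ANPP"), ("SR_log", "ANPP")),
            residual_covariances=(),
        )
        res = fit_paths(data, spec=spec, n_boot=10, seed=0)
        total = res.total_effect("SR_log", "ANPP")
        expected = res.coef("SR_log", "ANPP") + res.coef("SR_log", "CE") * res.coef("CE", "ANPP")
        assert total == pytest.approx(expected, abs=1e-12)


class TestGroupComparison:
    def test_identical_data_gives_zero_differences(self):
        data = _chain_data(n=200, seed=10)
        a = fit_paths(data, spec=CHAIN_SPEC, n_boot=150, seed=0, label="g1")
        b = fit_paths(data, spec=CHAIN_SPEC, n_boot=150, seed=1, label="g2")
        a.row_ids = tuple(f"a{i}" for i in range(200))
        b.row_ids = tuple(f"b{i}" for i in range(200))
        cmp = compare_groups([a, b])
        assert np.allclose(cmp["difference"], 0.0, atol=1e-12)
        assert (cmp["p"] > 0.05).all()
        assert (cmp["letters_a"] == cmp["letters_b"]).all()

    def test_shifted_coefficient_detected(self):
        a = fit_paths(_chain_data(n=400, seed=11), spec=CHAIN_SPEC,
                      n_boot=200, seed=0, label="early")
        b = fit_paths(_chain_data(n=400, seed=12, noise=1.5), spec=CHAIN_SPEC,
                      n_boot=200, seed=1, label="late")
        a.row_ids = tuple(f"a{i}" for i in range(400))
        b.row_ids = tuple(f"b{i}" for i in range(400))
        cmp = compare_groups([a, b])
        edge = cmp[(cmp["src"] == "SR_log") & (cmp["dst"] == "CE")].iloc[0]
        assert edge["p"] < 0.05
        assert edge["letters_a"] != edge["letters_b"]

    def test_overlapping_row_sets_rejected(self):
        data = _chain_data(n=100, seed=13)
        a = fit_paths(data, spec=CHAIN_SPEC, n_boot=10, seed=0, label="g1")
        b = fit_paths(data, spec=CHAIN_SPEC, n_boot=10, seed=1, label="g2")
        with pytest.raises(ValueError, match="share rows"):
            compare_groups([a, b])


class TestTrendsAndImpliedCorrelations:
    def test_indirect_trend_recovered(self):
        tbl = pd.DataFrame({
            "chain": "SR->CE->ANPP", "window_index": [1, 2, 3],
            "effect": [0.0, 0.1, 0.2],
        })
        tr = indirect_trends(tbl)
        assert tr.iloc[0]["trend"] == pytest.approx(0.1, abs=1e-12)

    def test_constant_effects_zero_trend(self):
        tbl = pd.DataFrame({"chain": "c", "window_index": [1, 2, 3, 4], "effect": 0.3})
        assert indirect_trends(tbl).iloc[0]["trend"] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_windows_error(self):
        tbl = pd.DataFrame({"chain": "c", "window_index": [1, 2], "effect": [0.1, 0.2]})
        with pytest.raises(ValueError, match=">= 3 windows"):
            indirect_trends(tbl)

    def test_implied_correlations_match_observed_on_model_data(self):
        """Wright-style tracing through the fitted recursive system
        reproduces the observed SR correlations on data generated from a
        matching structure (equation-wise OLS ≙ SEM point estimates)."""
        rng = np.random.default_rng(20)
        n = 2000
        sr = rng.normal(size=n)
        ce = 0.5 * sr + rng.normal(0, 0.8, n)
        se = 0.3 * sr + rng.normal(0, 0.9, n)
        anpp = 0.3 * sr + 0.4 * ce + 0.2 * se + rng.normal(0, 0.7, n)
        cvpop = -0.2 * sr + 0.3 * ce + 0.2 * se - 0.3 * anpp + rng.normal(0, 0.8, n)
        async_ = 0.4 * sr + 0.2 * ce - 0.1 * se + rng.normal(0, 0.8, n)
        comm = 0.6 * cvpop + 0.5 * async_ + rng.normal(0, 0.5, n)
        df = pd.DataFrame({
            "SR_log": sr, "CE": ce, "SE": se, "ANPP": anpp,
            "CVpop_inv": cvpop, "Async": async_, "CommStab": comm,
        })
        df = (df - df.mean()) / df.std(ddof=1)
        res = fit_paths(df, n_boot=10, seed=0)
        implied = res.implied_correlations()
        for node in ("CE", "SE", "ANPP", "CVpop_inv", "Async", "CommStab"):
            observed = np.corrcoef(df["SR_log"], df[node])[0, 1]
            assert implied[node] == pytest.approx(observed, abs=0.02)
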