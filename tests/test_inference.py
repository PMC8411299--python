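"""ANOVA, pairwise contrasts, and cluster-robust regression inference."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import egsnet as eg
from egsnet.inference import (
    DEFAULT_BLOCKS,
    RESOURCE_BLOCKS,
    CentralityAssociationModel,
    run_sensitivity_suite,
)


def anova_frame(groups: dict[str, list[float]], characteristic="icu_category"):
    rows = []
    for level, values in groups.items():
        for v in values:
            rows.append({characteristic: level, "log_centrality_ratio": v})
    return pd.DataFrame(rows)


def make_frame(n=120, seed=0, effect=0.0, n_states=6, with_quartiles=True):
    """Synthetic analysis frame: log ratio driven by the ICU tier + noise."""
    rng = np.random.default_rng(seed)
    icu = rng.choice(["0-10", "11-25", ">25"], n)
    tier = pd.Series(icu).map({"0-10": 0, "11-25": 1, ">25": 2}).to_numpy()
    frame = pd.DataFrame(
        {
            "hospital_id": [f"H{i}" for i in range(n)],
            "log_centrality_ratio": effect * tier + rng.normal(0, 1, n),
            "bed_category": rng.choice(["0-100", "101-250", ">250"], n),
            "icu_category": icu,
            "trauma_level": rng.choice(["none", "3", "2", "1"], n),
            "fellowship": rng.choice(["no", "yes"], n),
            "teaching_status": rng.choice(["nonteaching", "small", "large"], n),
            "state": rng.choice([f"S{k}" for k in range(n_states)], n),
            "network_label": "all",
        }
    )
    if with_quartiles:
        for col in ("volume_quartile", "mortality_quartile", "ftr_quartile"):
            frame[col] = rng.choice(["Q1", "Q2", "Q3", "Q4"], n)
    return frame


def brute_force_cluster_cov(X, y, groups):
    """Hand-coded cluster sandwich with the finite-sample scaling
    G/(G-1) x (n-1)/(n-k): bread (X'X)^-1, meat = sum_g (X_g'u_g)(X_g'u_g)'."""
    n, k = X.shape
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    u = y - X @ beta
    bread = np.linalg.inv(X.T @ X)
    meat = np.zeros((k, k))
    for g in np.unique(groups):
        idx = groups == g
        s = X[idx].T @ u[idx]
        meat += np.outer(s, s)
    G = len(np.unique(groups))
    c = G / (G - 1) * (n - 1) / (n - k)
    return beta, c * bread @ meat @ bread


class TestAnova:
    def test_identical_groups_give_zero_difference_p_one(self):
        frame = anova_frame({"a": [0.0, 1.0, 2.0], "b": [0.0, 1.0, 2.0]})
        res = eg.anova_with_pairwise(frame, "icu_category")
        assert res.f_statistic == 0.0 and res.p_value == 1.0
        assert res.difference("a", "b") == 0.0

    def test_two_group_f_equals_t_squared(self):
        frame = anova_frame({"a": [0.0, 1.0, 0.5], "b": [2.0, 3.0, 2.5]})
        res = eg.anova_with_pairwise(frame, "icu_category", posthoc="none")
        a = np.array([0.0, 1.0, 0.5])
        b = np.array([2.0, 3.0, 2.5])
        t, _ = scipy.stats.ttest_ind(a, b)
        assert res.f_statistic == pytest.approx(t**2, rel=1e-10)
        assert res.difference("b", "a") == pytest.approx(2.0)

    def test_degenerate_separated_groups(self):
        res = eg.anova_with_pairwise(
            anova_frame({"a": [0.0, 0.0], "b": [1.0, 1.0]}), "icu_category"
        )
        assert res.f_statistic == np.inf and res.p_value == 0.0
        assert res.difference("b", "a") == pytest.approx(1.0)

    def test_small_groups_dropped_with_warning(self):
        frame = anova_frame({"a": [0.0, 1.0], "b": [2.0, 3.0], "c": [9.0]})
        res = eg.anova_with_pairwise(frame, "icu_category")
        assert res.dropped_levels == ("c",)
        assert set(res.group_summary["level"]) == {"a", "b"}

    def test_pairwise_differences_antisymmetric(self):
        frame = make_frame(n=90, seed=3, effect=0.8)
        res = eg.anova_with_pairwise(frame, "icu_category")
        for _, row in res.pairwise.iterrows():
            assert res.difference(row["level_b"], row["level_a"]) == pytest.approx(
                row["difference"], rel=1e-9
            )
            assert res.difference(row["level_a"], row["level_b"]) == pytest.approx(
                -row["difference"], rel=1e-9
            )

    def test_tukey_flags_a_planted_effect(self):
        frame = make_frame(n=300, seed=5, effect=1.5)
        res = eg.anova_with_pairwise(frame, "icu_category")
        top = res.pairwise[
            (res.pairwise["level_a"] == "0-10") & (res.pairwise["level_b"] == ">25")
        ].iloc[0]
        assert top["difference"] > 0 and top["ci_low"] > 0 and top["p_adj"] < 0.05


class TestClusteredRegression:
    def test_noiseless_outcome_recovered_exactly(self):
        frame = make_frame(n=200, seed=1, effect=0.0)
        tier = frame["icu_category"].map({"0-10": 0.0, "11-25": 1.0, ">25": 2.0})
        frame["log_centrality_ratio"] = 0.5 + 0.7 * tier
        res = CentralityAssociationModel(frame, blocks=("icu_category",)).fit()
        coef = res.coefficient_table().set_index("level")
        assert coef.loc["11-25", "beta"] == pytest.approx(0.7, abs=1e-10)
        assert coef.loc[">25", "beta"] == pytest.approx(1.4, abs=1e-10)
        ci = coef.loc[">25", ["ci_low", "ci_high"]].astype(float)
        assert ci["ci_high"] - ci["ci_low"] == pytest.approx(0.0, abs=1e-7)

    def test_sandwich_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        frame = pd.DataFrame(
            {
                "log_centrality_ratio": rng.normal(size=12),
                "fellowship": list("nynynynynyny"),
                "state": list("aaaabbbbcccc"),
                "network_label": "all",
            }
        ).replace({"fellowship": {"n": "no", "y": "yes"}})
        frame["fellowship"] = pd.Categorical(frame["fellowship"], ["no", "yes"])
        model = CentralityAssociationModel(frame, blocks=("fellowship",))
        res = model.fit()
        X = np.column_stack(
            [np.ones(12), (frame["fellowship"] == "yes").to_numpy(float)]
        )
        y = frame["log_centrality_ratio"].to_numpy()
        beta, V = brute_force_cluster_cov(X, y, frame["state"].to_numpy())
        assert np.allclose(res.params.to_numpy(), beta, atol=1e-10)
        assert np.max(np.abs(res.cov_params().to_numpy() - V)) <= 1e-10

    def test_point_estimates_invariant_to_cluster_assignment(self):
        frame = make_frame(n=150, seed=9, effect=0.4)
        res1 = CentralityAssociationModel(frame, blocks=RESOURCE_BLOCKS).fit()
        shuffled = frame.copy()
        shuffled["state"] = np.random.default_rng(0).permutation(shuffled["state"].to_numpy())
        res2 = CentralityAssociationModel(shuffled, blocks=RESOURCE_BLOCKS).fit()
        assert np.allclose(res1.params.to_numpy(), res2.params.to_numpy())
        assert not np.allclose(res1.bse.to_numpy(), res2.bse.to_numpy())

    def test_single_cluster_rejected(self):
        frame = make_frame(n=40, seed=2, n_states=1)
        with pytest.raises(ValueError, match="at least 2 clusters"):
            CentralityAssociationModel(frame, blocks=("icu_category",))

    def test_rank_deficiency_names_blocks(self):
        frame = make_frame(n=60, seed=3)
        frame["bed_category"] = frame["icu_category"].map(
            {"0-10": "0-100", "11-25": "101-250", ">25": ">250"}
        )
        frame["bed_category"] = pd.Categorical(
            frame["bed_category"], ["0-100", "101-250", ">250"]
        )
        with pytest.raises(ValueError, match="rank deficient"):
            CentralityAssociationModel(
                frame, blocks=("bed_category", "icu_category")
            ).fit()

    def test_partial_f_of_single_level_block_is_t_squared(self):
        frame = make_frame(n=120, seed=4, effect=0.3)
        res = CentralityAssociationModel(frame, blocks=RESOURCE_BLOCKS).fit()
        term = "C(fellowship)[T.yes]"
        t = res.params[term] / res.bse[term]
        pf = res.partial_f_table().set_index("block")
        assert pf.loc["fellowship", "f_statistic"] == pytest.approx(t**2, rel=1e-8)

    def test_singleton_clusters_match_hc1(self):
        frame = make_frame(n=60, seed=6, effect=0.2)
        frame["state"] = [f"S{i}" for i in range(len(frame))]
        model = CentralityAssociationModel(frame, blocks=("icu_category",))
        clustered = model.fit(cov_type="cluster")
        hc1 = model.fit(cov_type="HC1")
        assert np.allclose(clustered.bse.to_numpy(), hc1.bse.to_numpy())

    def test_reference_rows_pinned_at_zero(self):
        frame = make_frame(n=200, seed=7)
        res = CentralityAssociationModel(frame, blocks=DEFAULT_BLOCKS).fit()
        table = res.coefficient_table()
        refs = table[table["reference"]]
        assert len(refs) == len(DEFAULT_BLOCKS)
        assert (refs["beta"] == 0).all()
        nonref = table[~table["reference"]]
        assert (nonref["ci_low"] <= nonref["ci_high"]).all()
        assert "0 [Reference]" in res.summary()


class TestSensitivitySuite:
    def test_identical_frames_give_identical_results(self):
        frame = make_frame(n=150, seed=11, effect=0.5)
        out = run_sensitivity_suite(
            {"ed_to_ip": frame, "ip_to_ip": frame}, blocks=RESOURCE_BLOCKS
        )
        t1 = out["ed_to_ip"].coefficient_table()
        t2 = out["ip_to_ip"].coefficient_table()
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_effect_detected_only_in_its_subnetwork(self):
        with_effect = make_frame(n=400, seed=12, effect=1.2)
        null = make_frame(n=400, seed=13, effect=0.0)
        out = run_sensitivity_suite(
            {"ip_to_ip": with_effect, "ed_to_ip": null}, blocks=RESOURCE_BLOCKS
        )
        top = lambda r: r.coefficient_table().query("block=='icu_category' and level=='>25'").iloc[0]  # noqa: E731
        hit = top(out["ip_to_ip"])
        miss = top(out["ed_to_ip"])
        assert hit["beta"] > 0 and hit["ci_low"] > 0
        assert miss["ci_low"] < 0 < miss["ci_high"]

    def test_empty_subnetwork_yields_structured_skip(self):
        out = run_sensitivity_suite({"ed_to_ip": pd.DataFrame()}, blocks=RESOURCE_BLOCKS)
        assert out["ed_to_ip"] == {"skipped": True, "reason": "empty analysis frame"}
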