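"""Correlation network, communities, layout and trend summary."""

import numpy as np
import pandas as pd
import pytest

import immunoclock as ic
from immunoclock.errors import DegenerateNetworkError, ValidationError


def _frame(cols: dict) -> pd.DataFrame:
    df = pd.DataFrame(cols)
    df.index = [f"s{i}" for i in range(len(df))]
    return df


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


class TestBuildNetwork:
    def test_identical_features_edge_r_one(self, rng):
        x = rng.standard_normal(20)
        net = ic.build_network(_frame({"a": x, "b": x.copy()}), threshold=0.8)
        assert net.has_edge("a", "b")
        assert net.edges["a", "b"]["r"] == pytest.approx(1.0)

    def test_negated_feature_edge_r_minus_one(self, rng):
        x = rng.standard_normal(20)
        net = ic.build_network(_frame({"a": x, "b": -x}), threshold=0.8)
        assert net.has_edge("a", "b")
        assert net.edges["a", "b"]["r"] == pytest.approx(-1.0)

    def test_threshold_is_strict(self, rng):
        """A pair exactly at the threshold gets no edge (strict >)."""
        x = rng.standard_normal(30)
        # |r| = 1 exactly; with threshold 1.0 the strict rule excludes it
        net = ic.build_network(_frame({"a": x, "b": 2 * x}), threshold=1.0)
        assert not net.has_edge("a", "b")
        # a pair constructed at r = 0.8 (to float precision): no edge either
        xc = x - x.mean()
        z = rng.standard_normal(30)
        zc = z - z.mean()
        zc -= (zc @ xc) / (xc @ xc) * xc  # orthogonal to xc, zero-mean
        r_target = 0.8 - 1e-12
        y = r_target * xc / np.linalg.norm(xc) + np.sqrt(
            1 - r_target**2
        ) * zc / np.linalg.norm(zc)
        assert abs(np.corrcoef(xc, y)[0, 1]) <= 0.8
        net2 = ic.build_network(_frame({"a": xc, "b": y}), threshold=0.8)
        assert not net2.has_edge("a", "b")

    def test_zero_variance_features_excluded(self, rng):
        net = ic.build_network(
            _frame({"a": rng.standard_normal(10), "c": np.ones(10),
                    "b": rng.standard_normal(10)})
        )
        assert "c" not in net

    def test_too_few_features_degenerate(self, rng):
        with pytest.raises(DegenerateNetworkError):
            ic.build_network(_frame({"a": rng.standard_normal(10),
                                     "c": np.ones(10)}))

    def test_feature_order_permutation_invariance(self, rng):
        x = rng.standard_normal((15, 4))
        cols = {f"f{j}": x[:, j] for j in range(4)}
        net1 = ic.build_network(_frame(cols), threshold=0.1)
        net2 = ic.build_network(_frame(dict(reversed(list(cols.items())))), threshold=0.1)
        assert {frozenset(e) for e in net1.edges} == {
            frozenset(e) for e in net2.edges
        }

    def test_raising_threshold_never_adds_edges(self, rng):
        x = rng.standard_normal((20, 6))
        x[:, 1] = x[:, 0] + 0.2 * rng.standard_normal(20)
        x[:, 3] = -x[:, 2] + 0.4 * rng.standard_normal(20)
        frame = _frame({f"f{j}": x[:, j] for j in range(6)})
        low = ic.build_network(frame, threshold=0.3)
        high = ic.build_network(frame, threshold=0.7)
        assert set(high.edges) <= set(low.edges)


def _planted_blocks(rng, n_blocks=2, size=5, n=30):
    cols = {}
    for b in range(n_blocks):
        f = rng.standard_normal(n)
        for j in range(size):
            cols[f"b{b}_{j}"] = f + 0.05 * rng.standard_normal(n)
    return _frame(cols)


class TestCommunities:
    def test_two_disjoint_cliques_two_communities(self, rng):
        frame = _planted_blocks(rng)
        net = ic.build_network(frame, threshold=0.8)
        labels = ic.detect_communities(net, seed=0)
        assert labels.nunique() == 2
        for b in range(2):
            block = labels[[f"b{b}_{j}" for j in range(5)]]
            assert block.nunique() == 1

    def test_single_clique_single_community(self, rng):
        frame = _planted_blocks(rng, n_blocks=1)
        net = ic.build_network(frame, threshold=0.8)
        assert ic.detect_communities(net, seed=3).nunique() == 1

    def test_disconnected_blocks_equal_components_any_seed(self, rng):
        frame = _planted_blocks(rng, n_blocks=3, size=4)
        net = ic.build_network(frame, threshold=0.8)
        ref = ic.detect_communities(net, seed=0)
        for seed in (1, 2, 3):
            labels = ic.detect_communities(net, seed=seed)
            # same partition regardless of seed (components are communities)
            assert labels.nunique() == ref.nunique() == 3
            grouping = labels.groupby(labels).groups
            ref_grouping = ref.groupby(ref).groups
            assert {frozenset(v) for v in grouping.values()} == {
                frozenset(v) for v in ref_grouping.values()
            }

    def test_isolated_nodes_become_singletons(self, rng):
        frame = _planted_blocks(rng, n_blocks=1)
        frame["lone"] = rng.standard_normal(len(frame))
        net = ic.build_network(frame, threshold=0.8)
        labels = ic.detect_communities(net, seed=0)
        assert (labels == labels["lone"]).sum() == 1

    def test_empty_subset_rejected(self, rng):
        net = ic.build_network(_planted_blocks(rng), threshold=0.8)
        with pytest.raises(ValidationError):
            ic.detect_communities(net, nodes=[])


class TestCoverage:
    def test_examples(self):
        one = pd.Series([0, 0, 0])
        assert ic.community_coverage(one, 1) == 1.0
        four_equal = pd.Series([0, 1, 2, 3] * 3)
        assert ic.community_coverage(four_equal, 2) == pytest.approx(0.5)
        assert ic.community_coverage(four_equal, 10) == 1.0

    def test_monotone_in_k(self):
        labels = pd.Series([0] * 5 + [1] * 3 + [2, 3])
        cov = [ic.community_coverage(labels, k) for k in range(1, 5)]
        assert cov == sorted(cov)
        with pytest.raises(ValidationError):
            ic.community_coverage(labels, 0)


class TestMdsLayout:
    def test_perfectly_correlated_nodes_coincide(self, rng):
        x = rng.standard_normal(20)
        net = ic.build_network(_frame({"a": x, "b": x.copy()}), threshold=0.5)
        coords = ic.mds_layout(net, seed=0)
        d = np.linalg.norm(coords.loc["a"] - coords.loc["b"])
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_three_uncorrelated_nodes_equidistant(self, rng):
        x = rng.standard_normal((60, 3))
        q, _ = np.linalg.qr(x - x.mean(0))  # exactly orthogonal columns
        frame = _frame({"a": q[:, 0], "b": q[:, 1], "c": q[:, 2]})
        net = ic.build_network(frame, threshold=0.9)
        coords = ic.mds_layout(net, seed=0)
        dists = [
            np.linalg.norm(coords.loc[u] - coords.loc[v])
            for u, v in (("a", "b"), ("a", "c"), ("b", "c"))
        ]
        assert max(dists) - min(dists) == pytest.approx(0.0, abs=1e-8)

    def test_deterministic(self, rng):
        frame = _planted_blocks(rng)
        net = ic.build_network(frame, threshold=0.8)
        a = ic.mds_layout(net, seed=5)
        b = ic.mds_layout(net, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestDirectionSummary:
    def _uni(self, rows):
        return pd.DataFrame(rows).set_index("feature_id")

    def test_all_positive_basal_gives_zero_decreasing_fraction(self):
        uni = self._uni(
            [dict(feature_id=f"basal_{i}", rho=0.5, p=0.001, q=0.01) for i in range(4)]
        )
        classes = pd.Series("basal", index=uni.index)
        out = ic.direction_summary(list(uni.index), uni, classes)
        assert out["basal_decreasing_frac"] == 0.0

    def test_mixed_directions_and_fdr_cut(self):
        uni = self._uni(
            [
                dict(feature_id="b1", rho=-0.6, p=1e-4, q=1e-3),
                dict(feature_id="b2", rho=0.6, p=1e-4, q=1e-3),
                dict(feature_id="b3", rho=-0.6, p=0.5, q=0.9),  # fails FDR cut
                dict(feature_id="r1", rho=0.7, p=1e-5, q=1e-4),
                dict(feature_id="r2", rho=-0.7, p=1e-5, q=1e-4),
            ]
        )
        classes = pd.Series(
            {"b1": "basal", "b2": "basal", "b3": "basal",
             "r1": "response", "r2": "response"}
        )
        out = ic.direction_summary(list(uni.index), uni, classes, fdr_cut=0.1)
        assert out["basal_decreasing_frac"] == pytest.approx(0.5)
        assert out["response_increasing_frac"] == pytest.approx(0.5)
        assert out["n_basal"] == 2 and out["n_response"] == 2

    def test_empty_class_reported_missing(self):
        uni = self._uni([dict(feature_id="b1", rho=-0.6, p=1e-4, q=1e-3)])
        classes = pd.Series({"b1": "basal"})
        out = ic.direction_summary(["b1"], uni, classes)
        assert np.isnan(out["response_increasing_frac"])
        assert 0.0 <= out["basal_decreasing_frac"] <= 1.0
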