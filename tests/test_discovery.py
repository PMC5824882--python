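"""ANOVA, FDR, scaling, PCA and clustering checks against independent oracles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import fibrosort as fs


def brute_force_bh(p):
    """Textbook BH step-up, written independently of the implementation."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running_min = min(running_min, p[idx] * m / rank)
        q[idx] = running_min
    return np.clip(q, 0, 1)


class TestBhFdr:
    def test_singleton_unchanged(self):
        np.testing.assert_allclose(fs.bh_fdr([0.01]), [0.01])

    def test_hand_executed_step_up(self):
        np.testing.assert_allclose(
            fs.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 500))
            p = rng.random(n) ** rng.uniform(0.5, 3)
            np.testing.assert_allclose(
                fs.bh_fdr(p), brute_force_bh(p), atol=1e-12
            )

    def test_order_preserving(self, rng):
        p = rng.random(200)
        q = fs.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            fs.bh_fdr([0.1, np.nan])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=80)
    )
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_property_matches_brute_force_and_bounds(self, p):
        q = fs.bh_fdr(p)
        np.testing.assert_allclose(q, brute_force_bh(p), atol=1e-12)
        assert ((q >= np.asarray(p) - 1e-15) & (q <= 1.0)).all()


class TestAnovaAcrossGates:
    def _resid(self, small_bulk):
        bulk, meta, _ = small_bulk
        return fs.residualize_donor(bulk, meta), meta

    def test_constant_gene_gets_p_one(self, small_bulk):
        resid, meta = self._resid(small_bulk)
        resid.values[0, :] = 0.0
        de = fs.anova_across_gates(resid, meta)
        assert de.iloc[0]["statistic"] == 0.0
        assert de.iloc[0]["p_value"] == 1.0

    def test_two_groups_f_equals_t_squared(self, rng):
        values = rng.normal(size=(30, 10))
        m = fs.ExpressionMatrix(
            [f"g{i}" for i in range(30)], [f"s{j}" for j in range(10)], values, "log2"
        )
        gates = [fs.DEFAULT_GATES[0]] * 5 + [fs.DEFAULT_GATES[1]] * 5
        meta = pd.DataFrame(
            {
                "sample_id": m.sample_ids,
                "donor_id": [f"d{j}" for j in range(10)],
                "disease": "RA",
                "modality": "bulk",
                "gate": gates,
            }
        )
        resid = fs.ResidualMatrix(
            m.gene_ids, m.sample_ids, values, meta.set_index("sample_id")["donor_id"]
        )
        de = fs.anova_across_gates(resid, meta)
        t = scipy.stats.ttest_ind(values[:, :5], values[:, 5:], axis=1).statistic
        np.testing.assert_allclose(de["statistic"], t**2, atol=1e-10)

    def test_matches_scipy_f_oneway_without_donor_adjustment(self, small_bulk):
        resid, meta = self._resid(small_bulk)
        de = fs.anova_across_gates(resid, meta, donor_df=0)
        groups = [
            resid.values[:, [resid.sample_ids.index(s) for s in block]]
            for _, block in meta.groupby("gate")["sample_id"]
        ]
        ref = scipy.stats.f_oneway(*groups, axis=1)
        np.testing.assert_allclose(de["statistic"], ref.statistic, atol=1e-8)
        np.testing.assert_allclose(de["p_value"], ref.pvalue, atol=1e-10)

    def test_donor_df_adjustment_scales_f_and_df(self, small_bulk):
        # 5 donors spend 4 df: F scales by (n-k-4)/(n-k) and p uses the
        # reduced denominator df
        resid, meta = self._resid(small_bulk)
        plain = fs.anova_across_gates(resid, meta, donor_df=0)
        adjusted = fs.anova_across_gates(resid, meta)
        n, k, d = 35, 7, 5
        factor = (n - k - (d - 1)) / (n - k)
        np.testing.assert_allclose(
            adjusted["statistic"], plain["statistic"] * factor, atol=1e-10
        )
        expected_p = scipy.stats.f.sf(adjusted["statistic"], k - 1, n - k - (d - 1))
        np.testing.assert_allclose(adjusted["p_value"], expected_p, atol=1e-12)

    def test_small_gate_excluded_with_warning(self, small_bulk, caplog):
        resid, meta = self._resid(small_bulk)
        meta = meta.copy()
        # orphan one gate down to a single sample
        lone_gate = fs.DEFAULT_GATES[0]
        keep = meta[meta["gate"] != lone_gate].index.tolist()
        keep.append(meta[meta["gate"] == lone_gate].index[0])
        meta2 = meta.loc[sorted(keep)]
        sub = fs.ExpressionMatrix(
            resid.gene_ids,
            meta2["sample_id"].tolist(),
            resid.to_frame()[meta2["sample_id"]].to_numpy(),
            "log2",
        )
        resid2 = fs.ResidualMatrix(
            sub.gene_ids, sub.sample_ids, sub.values,
            meta2.set_index("sample_id")["donor_id"],
        )
        with caplog.at_level("WARNING"):
            de = fs.anova_across_gates(resid2, meta2)
        assert "excluded" in caplog.text
        assert de["contrast"].iloc[0] == "6-gate ANOVA"

    def test_planted_signal_detected(self, small_bulk):
        bulk, meta, truth = small_bulk
        resid = fs.residualize_donor(bulk, meta)
        de = fs.anova_across_gates(resid, meta).set_index("gene_id")
        sig = sorted(set().union(*truth.signature_genes.values()))
        sensitivity = (de.loc[sig, "q_value"] < 0.01).mean()
        assert sensitivity >= 0.99


class TestIntersectPlatforms:
    def _de(self, genes, qs):
        return pd.DataFrame(
            {"gene_id": genes, "statistic": 1.0, "p_value": qs, "q_value": qs,
             "contrast": "x"}
        )

    def test_identical_collections(self):
        de = self._de(["a", "b", "c"], [0.001, 0.5, 0.002])
        assert fs.intersect_platforms(de, de, 0.01) == {"a", "c"}

    def test_disjoint_significance_empty(self):
        a = self._de(["a", "b"], [0.001, 0.9])
        b = self._de(["a", "b"], [0.9, 0.001])
        assert fs.intersect_platforms(a, b, 0.01) == set()

    def test_no_shared_genes_is_error(self):
        a = self._de(["a"], [0.1])
        b = self._de(["b"], [0.1])
        with pytest.raises(ValueError, match="share no measured genes"):
            fs.intersect_platforms(a, b, 0.01)

    def test_matches_brute_force_sets(self, rng):
        genes_a = [f"g{i}" for i in range(100)]
        genes_b = [f"g{i}" for i in range(50, 150)]
        qa, qb = rng.random(100), rng.random(100)
        a, b = self._de(genes_a, qa), self._de(genes_b, qb)
        expected = {
            g
            for g in set(genes_a) & set(genes_b)
            if qa[genes_a.index(g)] < 0.3 and qb[genes_b.index(g)] < 0.3
        }
        assert fs.intersect_platforms(a, b, 0.3) == expected


class TestSpecificityScale:
    def test_rows_standardized(self, rng):
        x = rng.normal(size=(20, 8))
        out = fs.specificity_scale(x)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        sds = out.std(axis=1, ddof=1)
        assert ((np.abs(sds - 1.0) < 1e-12) | (sds == 0)).all()

    def test_two_by_two_collapses_to_zero(self, caplog):
        # after sample scaling both gene rows are constant -> zeroed
        with caplog.at_level("WARNING"):
            out = fs.specificity_scale(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(out, 0.0)
        assert "constant after sample scaling" in caplog.text

    def test_invariant_to_per_sample_shift(self, rng):
        x = rng.normal(size=(15, 6))
        shift = rng.normal(size=6) * 10
        np.testing.assert_allclose(
            fs.specificity_scale(x), fs.specificity_scale(x + shift), atol=1e-10
        )

    def test_sample_permutation_equivariance(self, rng):
        x = rng.normal(size=(15, 6))
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            fs.specificity_scale(x)[:, perm],
            fs.specificity_scale(x[:, perm]),
            atol=1e-12,
        )

    def test_zero_variance_sample_named(self, rng):
        x = rng.normal(size=(10, 4))
        x[:, 2] = 7.0
        with pytest.raises(ValueError, match="sampleC"):
            fs.specificity_scale(x, ["sampleA", "sampleB", "sampleC", "sampleD"])


class TestPca:
    def test_rank_one_data(self, rng):
        direction = rng.normal(size=6)
        t = rng.normal(size=30)
        x = np.outer(t, direction) + rng.normal(size=6)  # line through offset
        scores, loadings, var = fs.pca(x, 3)
        assert var[0] == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(var[1:], 0.0, atol=1e-10)

    def test_full_reconstruction(self, rng):
        x = rng.normal(size=(10, 7))
        scores, loadings, _ = fs.pca(x, 7)
        z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        np.testing.assert_allclose(scores @ loadings.T, z, atol=1e-8)

    def test_sign_convention(self, rng):
        x = rng.normal(size=(12, 5))
        _, loadings, _ = fs.pca(x, 5)
        for j in range(5):
            assert loadings[np.argmax(np.abs(loadings[:, j])), j] > 0

    def test_variance_nonincreasing(self, rng):
        x = rng.normal(size=(20, 10))
        _, _, var = fs.pca(x, 10)
        assert (np.diff(var) <= 1e-12).all()

    def test_bad_component_counts_rejected(self, rng):
        x = rng.normal(size=(5, 4))
        with pytest.raises(ValueError):
            fs.pca(x, 0)
        with pytest.raises(ValueError):
            fs.pca(x, 5)


def naive_average_linkage(d):
    """O(n^3) agglomerative average linkage written as an independent oracle."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    dist = {
        frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    heights = []
    next_id = n
    while len(clusters) > 1:
        pair, h = min(dist.items(), key=lambda kv: kv[1])
        i, j = sorted(pair)
        heights.append(h)
        merged = clusters.pop(i) + clusters.pop(j)
        new_dist = {}
        for k, members in clusters.items():
            pairs = [d[a, b] for a in merged for b in members]
            new_dist[frozenset((next_id, k))] = float(np.mean(pairs))
        dist = {
            key: v
            for key, v in dist.items()
            if i not in key and j not in key
        }
        dist.update(new_dist)
        clusters[next_id] = merged
        next_id += 1
    return np.array(heights)


class TestCorrelationCluster:
    def test_identical_items_merge_at_zero(self, rng):
        profile = rng.normal(size=20)
        x = np.vstack([profile, profile, rng.normal(size=20)])
        result = fs.correlation_cluster(x, ["a", "b", "c"])
        assert result.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_three_planted_groups_recovered(self, rng):
        centers = rng.normal(size=(3, 30)) * 3
        x = np.vstack([centers[i % 3] + rng.normal(size=30) * 0.01 for i in range(12)])
        ids = [f"i{i}" for i in range(12)]
        result = fs.correlation_cluster(x, ids)
        labels = result.labels(3)
        truth = [i % 3 for i in range(12)]
        assert fs.adjusted_rand_index(labels.loc[ids].to_numpy(), truth) == 1.0

    def test_heights_match_naive_oracle(self, rng):
        x = rng.normal(size=(20, 15))
        ids = [f"i{i:02d}" for i in range(20)]
        result = fs.correlation_cluster(x, ids)
        d = 1.0 - np.corrcoef(x)
        np.fill_diagonal(d, 0.0)
        np.testing.assert_allclose(
            np.sort(result.linkage[:, 2]),
            np.sort(naive_average_linkage(np.clip(d, 0, None))),
            atol=1e-10,
        )

    def test_input_order_invariance(self, rng):
        x = rng.normal(size=(10, 12))
        ids = [f"i{i}" for i in range(10)]
        r1 = fs.correlation_cluster(x, ids)
        perm = rng.permutation(10)
        r2 = fs.correlation_cluster(x[perm], [ids[i] for i in perm])
        l1, l2 = r1.labels(3), r2.labels(3)
        assert fs.adjusted_rand_index(
            l1.loc[sorted(ids)].to_numpy(), l2.loc[sorted(ids)].to_numpy()
        ) == 1.0

    def test_zero_variance_item_named(self, rng):
        x = rng.normal(size=(4, 10))
        x[2] = 5.0
        with pytest.raises(ValueError, match="i2"):
            fs.correlation_cluster(x, ["i0", "i1", "i2", "i3"])


class TestCollapseGates:
    def test_marker_rule_partition_sizes(self, small_bulk):
        _, meta, _ = small_bulk
        mapping, report = fs.collapse_gates(meta, rule="marker")
        one_donor = meta[meta["donor_id"] == meta["donor_id"].iloc[0]]
        sizes = sorted(
            mapping.loc[one_donor["sample_id"]].value_counts().tolist()
        )
        assert sizes == [2, 2, 3]
        assert report["disagreement_rate"] == 0.0

    def test_data_driven_equals_marker_on_clean_data(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, noise_sd=0.05, donor_sd=0.0)
        bulk, meta, truth = fs.generate_bulk_cohort(cfg)
        resid = fs.residualize_donor(bulk, meta)
        cl = fs.correlation_cluster(resid.values.T, resid.sample_ids)
        dd_map, report = fs.collapse_gates(meta, cl, rule="data_driven")
        marker_map, _ = fs.collapse_gates(meta, rule="marker")
        assert report["disagreement_rate"] == 0.0
        assert (dd_map.loc[marker_map.index] == marker_map).all()

    def test_single_gate_maps_to_one_subset(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "donor_id": ["d1", "d1"],
                "disease": "RA",
                "modality": "bulk",
                "gate": [fs.DEFAULT_GATES[6]] * 2,
            }
        )
        mapping, _ = fs.collapse_gates(meta, rule="marker")
        assert set(mapping) == {"CD34pos"}
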