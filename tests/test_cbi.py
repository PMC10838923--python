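import itertools

import numpy as np
import pytest
from scipy import stats

from connid.cbi import (
    METRICS,
    SUBMODELS,
    DistanceMatrix,
    EmptyMaskError,
    FeatureSelection,
    build_feature_vectors,
    cbi_distance,
    cbi_identify,
    edgewise_spearman,
    permutation_test_features,
    permutation_test_labels,
)
from connid.fc_core import EdgeIndex, vectorize_upper
from connid.synthetic import Cohort, SyntheticConfig, generate_cohort


class TestEdgewiseSpearman:
    def test_matches_scipy_oracle_on_every_edge(self, tiny_cohort):
        sel = edgewise_spearman(tiny_cohort)
        idx = EdgeIndex(tiny_cohort.r)
        P = np.vstack([vectorize_upper(p, idx) for p in tiny_cohort.parents])
        C = np.vstack([vectorize_upper(c, idx) for c in tiny_cohort.children])
        for e in range(idx.n_edges):
            rho, p = stats.spearmanr(P[:, e], C[:, e])
            assert sel.rho[e] == pytest.approx(rho, abs=1e-10)
            assert sel.p[e] == pytest.approx(p, abs=1e-10)

    def test_five_dyad_hand_example(self):
        parents = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        children = np.array([0.3, 0.1, 0.4, 0.2, 0.5])
        co = _cohort_with_edge(parents, children)
        sel = edgewise_spearman(co)
        expected = stats.spearmanr(parents, children).statistic
        assert sel.rho[0] == pytest.approx(expected, abs=1e-12)

    def test_identical_and_reversed_edges(self):
        vals = np.linspace(-0.5, 0.5, 7)
        same = _cohort_with_edge(vals, vals)
        assert edgewise_spearman(same).rho[0] == pytest.approx(1.0)
        reversed_ = _cohort_with_edge(vals, -(vals**3))  # strictly decreasing map
        assert edgewise_spearman(reversed_).rho[0] == pytest.approx(-1.0)

    def test_masks_respect_threshold_rule(self, coupled_cohort):
        sel = edgewise_spearman(coupled_cohort, alpha=0.05)
        assert not (sel.pos_mask & sel.neg_mask).any()
        assert np.all(sel.p[sel.pos_mask] < 0.05)
        assert np.all(sel.rho[sel.pos_mask] > 0)
        assert np.all(sel.p[sel.neg_mask] < 0.05)
        assert np.all(sel.rho[sel.neg_mask] < 0)

    def test_constant_edge_excluded_and_counted(self):
        vals = np.linspace(-0.5, 0.5, 6)
        co = _cohort_with_edge(vals, np.full(6, 0.2), extra_edge=(vals, vals))
        sel = edgewise_spearman(co)
        assert sel.n_constant_edges >= 1
        const = np.isnan(sel.rho)
        assert not (sel.pos_mask[const]).any() and not (sel.neg_mask[const]).any()

    def test_too_few_dyads_rejected(self):
        cfg = SyntheticConfig(n_dyads=3, r=8, seed=0)
        with pytest.raises(ValueError, match="4 dyads"):
            edgewise_spearman(generate_cohort(cfg))


class TestFeatureVectors:
    def test_shapes_and_direct_lookup(self, coupled_cohort):
        sel = edgewise_spearman(coupled_cohort)
        fv = build_feature_vectors(coupled_cohort, sel)
        n = coupled_cohort.n_dyads
        assert fv.Pp.shape == (n, sel.pos_mask.sum())
        assert fv.Nc.shape == (n, sel.neg_mask.sum())
        idx = EdgeIndex(coupled_cohort.r)
        i, j = idx.rows[fv.pos_edges[0]], idx.cols[fv.pos_edges[0]]
        for d in range(n):
            assert fv.Pp[d, 0] == coupled_cohort.parents[d].matrix[i, j]
            assert fv.Pc[d, 0] == coupled_cohort.children[d].matrix[i, j]

    def test_random_mask_restriction_matches_oracle(self, tiny_cohort, rng):
        idx = EdgeIndex(tiny_cohort.r)
        m = idx.n_edges
        mask = np.zeros(m, bool)
        mask[rng.choice(m, size=5, replace=False)] = True
        sel = FeatureSelection(
            rho=np.where(mask, 0.9, 0.0), p=np.where(mask, 1e-4, 0.9)
        )
        fv = build_feature_vectors(tiny_cohort, sel)
        for d, parent in enumerate(tiny_cohort.parents):
            np.testing.assert_array_equal(
                fv.Pp[d], vectorize_upper(parent, idx)[mask]
            )

    def test_empty_mask_raises_named_error(self, tiny_cohort):
        sel = FeatureSelection(
            rho=np.zeros(EdgeIndex(tiny_cohort.r).n_edges),
            p=np.ones(EdgeIndex(tiny_cohort.r).n_edges),
        )
        fv = build_feature_vectors(tiny_cohort, sel)
        with pytest.raises(EmptyMaskError, match="positive"):
            cbi_distance(fv, "positive", "euclidean")


class TestDistanceAndIdentify:
    def test_identical_vectors(self):
        fv = _fv(parent=np.array([[1.0, 2.0, 3.0]]), child=np.array([[1.0, 2.0, 3.0]]))
        assert cbi_distance(fv, "positive", "euclidean").values[0, 0] == 0.0
        assert cbi_distance(fv, "positive", "spearman").values[0, 0] == pytest.approx(1.0)

    def test_unit_distance_arithmetic(self):
        fv = _fv(parent=np.array([[1.0, 2.0, 3.0]]), child=np.array([[1.0, 2.0, 4.0]]))
        assert cbi_distance(fv, "positive", "euclidean").values[0, 0] == pytest.approx(1.0)

    def test_matches_nested_loop_oracle(self, rng):
        parent = rng.standard_normal((4, 5))
        child = rng.standard_normal((4, 5))
        fv = _fv(parent=parent, child=child)
        De = cbi_distance(fv, "positive", "euclidean").values
        Ds = cbi_distance(fv, "positive", "spearman").values
        for i in range(4):
            for j in range(4):
                assert De[i, j] == pytest.approx(
                    np.linalg.norm(parent[i] - child[j]), abs=1e-12
                )
                assert Ds[i, j] == pytest.approx(
                    stats.spearmanr(parent[i], child[j]).statistic, abs=1e-12
                )

    def test_negative_euclidean_hand_enumeration(self):
        D = DistanceMatrix(
            np.array([[5, 1, 1], [1, 6, 1], [1, 1, 0.5]], float),
            metric="euclidean",
            submodel="negative",
        )
        res = cbi_identify(D)
        np.testing.assert_array_equal(res.hits, [True, True, False])
        assert res.rate == pytest.approx(2 / 3)

    @pytest.mark.parametrize(
        "submodel,metric", list(itertools.product(SUBMODELS, METRICS))
    )
    def test_all_rules_match_brute_force(self, submodel, metric, rng):
        values = rng.uniform(0.1, 1.0, size=(6, 6))
        res = cbi_identify(DistanceMatrix(values, metric=metric, submodel=submodel))
        want_min = (submodel == "positive") == (metric == "euclidean")
        for i in range(6):
            row = values[i]
            best = min(range(6), key=lambda j: row[j] if want_min else -row[j])
            assert res.matches[i] == best

    def test_equivariance_under_joint_permutation(self, rng):
        values = rng.uniform(size=(7, 7))
        perm = rng.permutation(7)
        a = cbi_identify(DistanceMatrix(values, "euclidean", "positive")).rate
        b = cbi_identify(
            DistanceMatrix(values[np.ix_(perm, perm)], "euclidean", "positive")
        ).rate
        assert a == b


class TestPermutationTests:
    def test_labels_mean_is_fixed_point_expectation(self, coupled_cohort):
        sel = edgewise_spearman(coupled_cohort)
        reports = permutation_test_labels(coupled_cohort, sel, n_perm=2000, seed=1)
        for report in reports.values():
            assert report.observed_rate == 1.0
            assert report.p_value == 0.0
            assert report.mean_rate == pytest.approx(1 / 13, abs=0.005)

    def test_labels_two_dyad_null_matches_exhaustive_enumeration(self):
        """n = 2 has exactly two pairings: identity (rate 1 for a diagonal-
        dominant matrix) and the swap (rate 0), each drawn with probability
        1/2, so the per-permutation rates must be Bernoulli(1/2) on {0, 1}."""
        cfg = SyntheticConfig(n_dyads=2, r=10, coupling=1.5, noise_sd=0.1, seed=3)
        co = generate_cohort(cfg)
        m = co.edge_index().n_edges
        mask = np.zeros(m, bool)
        mask[list(co.planted_pos_edges)] = True
        sel = FeatureSelection(
            rho=np.where(mask, 0.9, 0.0), p=np.where(mask, 1e-4, 0.9)
        )
        reports = permutation_test_labels(co, sel, n_perm=3000, seed=2)
        rep = reports[("positive", "euclidean")]
        assert set(np.unique(rep.per_perm_rates)) <= {0.0, 1.0}
        assert rep.mean_rate == pytest.approx(0.5, abs=0.04)

    def test_labels_mean_fixed_point_for_any_cohort_size(self):
        cfg = SyntheticConfig(n_dyads=4, r=10, coupling=1.5, noise_sd=0.1, seed=3)
        co = generate_cohort(cfg)
        sel = edgewise_spearman(co)
        rep = permutation_test_labels(co, sel, n_perm=3000, seed=2)
        # mean hits per iteration must approach 1 (rate 1/n) for any data
        assert rep[("positive", "euclidean")].mean_rate * 4 == pytest.approx(1.0, abs=0.1)

    def test_features_null_cohort_mean_near_chance(self, null_cohort):
        reports = permutation_test_features(null_cohort, n_perm=300, seed=4)
        for report in reports.values():
            # expected true identifications per iteration ~ 1 under chance
            assert report.mean_rate * 13 == pytest.approx(1.0, abs=0.6)

    def test_features_report_is_deterministic(self):
        cfg = SyntheticConfig(n_dyads=5, r=10, coupling=1.0, noise_sd=0.3, seed=6)
        co = generate_cohort(cfg)
        a = permutation_test_features(co, n_perm=50, seed=7)
        b = permutation_test_features(co, n_perm=50, seed=7)
        for key in a:
            np.testing.assert_array_equal(a[key].per_perm_rates, b[key].per_perm_rates)
            assert a[key].to_dict() == b[key].to_dict()

    def test_features_report_tracks_max_and_recurrence(self, null_cohort):
        reports = permutation_test_features(null_cohort, n_perm=200, seed=8)
        for report in reports.values():
            rates = report.per_perm_rates
            assert report.max_rate == rates.max()
            assert report.max_recurrence == np.sum(rates >= rates.max() - 1e-12)

    def test_conservative_p_adds_small_sample_correction(self, coupled_cohort):
        sel = edgewise_spearman(coupled_cohort)
        rep = permutation_test_labels(
            coupled_cohort, sel, n_perm=100, seed=9, conservative_p=True
        )[("positive", "euclidean")]
        assert rep.p_value == pytest.approx(1 / 101)


# ---------------------------------------------------------------------------
# helpers


def _cohort_with_edge(parent_vals, child_vals, extra_edge=None, r=4):
    """Cohort whose edge 0 takes the given per-dyad values; other edges vary."""
    from connid.fc_core import FCProfile, devectorize_upper

    n = len(parent_vals)
    idx = EdgeIndex(r)
    rng = np.random.default_rng(99)
    parents, children = [], []
    for d in range(n):
        pv = rng.uniform(-0.4, 0.4, idx.n_edges)
        cv = rng.uniform(-0.4, 0.4, idx.n_edges)
        pv[0], cv[0] = parent_vals[d], child_vals[d]
        if extra_edge is not None:
            pv[1], cv[1] = extra_edge[0][d], extra_edge[1][d]
        parents.append(FCProfile(f"P{d}", devectorize_upper(pv, idx)))
        children.append(FCProfile(f"C{d}", devectorize_upper(cv, idx)))
    return Cohort(
        dyad_ids=[f"D{d}" for d in range(n)], parents=parents, children=children
    )


def _fv(parent, child):
    from connid.cbi import FeatureVectors

    edges = np.arange(parent.shape[1])
    return FeatureVectors(
        Pp=parent, Pc=child, Np=parent, Nc=child, pos_edges=edges, neg_edges=edges
    )
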