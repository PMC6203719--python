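from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from omiclust.io import OmicsMatrix
from omiclust.stats import (
    SurvivalRecord,
    apply_censoring,
    cluster_fractions,
    discretize,
    drop_singleton_clusters,
    enrichment_table,
    fdr_adjust,
    hypergeom_enrich,
    km_estimate,
    logrank_test,
    representativeness_filter,
    survival_separation,
)


def rec(time, event, age=None, metric="OS", pid="P"):
    return SurvivalRecord(pid, float(time), bool(event), age, metric)


class TestCensoring:
    def test_early_os_death_becomes_censored(self):
        out = apply_censoring([rec(20, True)])
        assert out[0].event is False and out[0].time == 20

    def test_horizon_caps_time_and_event(self):
        out = apply_censoring([rec(4000, True)])
        assert out[0].time == 3650 and out[0].event is False

    def test_age_rule_applies_to_os_only(self):
        dfi = apply_censoring([rec(400, True, age=85, metric="DFI")])
        assert dfi[0].event is True and dfi[0].time == 400
        os_ = apply_censoring([rec(400, True, age=85, metric="OS")])
        assert os_[0].event is False

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            rec(-1, True)


class TestDropSingletons:
    def test_singleton_cluster_removed(self):
        labels = np.array([1] * 10 + [2] + [3] * 5)
        records = [rec(i + 1, True, pid=f"P{i}") for i in range(16)]
        out_labels, out_records = drop_singleton_clusters(labels, records)
        assert set(out_labels) == {1, 3} and len(out_records) == 15

    def test_no_singletons_is_identity(self):
        labels = np.array([1, 1, 2, 2])
        records = [rec(i + 1, True, pid=f"P{i}") for i in range(4)]
        out_labels, out_records = drop_singleton_clusters(labels, records)
        assert np.array_equal(out_labels, labels) and len(out_records) == 4

    def test_all_singletons_error(self):
        with pytest.raises(ValueError):
            drop_singleton_clusters(np.array([1, 2, 3]), [rec(1, True)] * 3)


class TestKaplanMeier:
    def test_no_events_constant_one(self):
        curve = km_estimate([rec(5, False), rec(8, False)])
        assert curve(10) == pytest.approx(1.0)

    def test_single_event_drop(self):
        curve = km_estimate([rec(3, True)] + [rec(9, False, pid=f"P{i}") for i in range(4)])
        assert curve(2.9) == pytest.approx(1.0)
        assert curve(3) == pytest.approx(4 / 5)

    def test_hand_computed_product_limit(self):
        # times 1..5, events (1,1,0,1,0): S(4) = (4/5)(3/4)(1/2) = 0.3
        records = [rec(t, e) for t, e in zip([1, 2, 3, 4, 5], [1, 1, 0, 1, 0])]
        curve = km_estimate(records)
        assert curve(4) == pytest.approx(0.3)

    def test_matches_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, size=25)
        records = [rec(t, True, pid=f"P{i}") for i, t in enumerate(times)]
        curve = km_estimate(records)
        for q in np.quantile(times, [0.2, 0.5, 0.8]):
            assert curve(q) == pytest.approx((times > q).mean(), abs=1e-10)

    def test_curve_monotone_in_unit_interval(self):
        rng = np.random.default_rng(1)
        records = [
            rec(t, e, pid=f"P{i}")
            for i, (t, e) in enumerate(zip(rng.exponential(5, 30), rng.random(30) < 0.7))
        ]
        curve = km_estimate(records)
        assert np.all(np.diff(curve.probs) <= 1e-12)
        assert curve.probs.min() >= 0 and curve.probs.max() <= 1


class TestLogrank:
    def identical_groups(self):
        times = [2, 4, 6, 2, 4, 6]
        events = [1, 0, 1, 1, 0, 1]
        records = [rec(t, e, pid=f"P{i}") for i, (t, e) in enumerate(zip(times, events))]
        return records, np.array([1, 1, 1, 2, 2, 2])

    def test_identical_groups_give_null_result(self):
        records, groups = self.identical_groups()
        chi2, df, p = logrank_test(records, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 1 and p == pytest.approx(1.0)

    def test_df_is_k_minus_one(self):
        records = [rec(t, 1, pid=f"P{i}") for i, t in enumerate([1, 2, 3, 4, 5, 6])]
        _, df, _ = logrank_test(records, np.array([1, 1, 2, 2, 3, 3]))
        assert df == 2

    def test_matches_exhaustive_permutation_reference(self):
        # 6 patients; the permutation p enumerates all C(6,3)=20 assignments
        times = [2.0, 4.0, 5.0, 7.0, 9.0, 12.0]
        events = [1, 1, 0, 1, 1, 0]
        records = [rec(t, e, pid=f"P{i}") for i, (t, e) in enumerate(zip(times, events))]
        observed = np.array([1, 1, 1, 2, 2, 2])
        chi2, _, p = logrank_test(records, observed)
        stats = []
        for idx in combinations(range(6), 3):
            g = np.ones(6, dtype=int)
            g[list(idx)] = 2
            c, _, _ = logrank_test(records, g)
            stats.append(c)
        p_perm = float(np.mean(np.array(stats) >= chi2 - 1e-12))
        assert p == pytest.approx(p_perm, abs=0.1)

    def test_group_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        records = [
            rec(t, e, pid=f"P{i}")
            for i, (t, e) in enumerate(zip(rng.exponential(5, 20), rng.random(20) < 0.7))
        ]
        groups = rng.integers(1, 4, 20)
        chi2a, _, pa = logrank_test(records, groups)
        relabeled = np.select([groups == 1, groups == 2, groups == 3], [3, 1, 2])
        chi2b, _, pb = logrank_test(records, relabeled)
        assert chi2a == pytest.approx(chi2b) and pa == pytest.approx(pb)

    def test_patient_censored_before_first_event_is_inert(self):
        records, groups = self.identical_groups()
        rng_rec = records + [rec(0.5, False, pid="PX")]
        groups2 = np.append(groups, 1)
        chi2a, _, _ = logrank_test(records, groups)
        chi2b, _, _ = logrank_test(rng_rec, groups2)
        assert chi2a == pytest.approx(chi2b, abs=1e-10)

    def test_no_events_vacuous(self):
        records = [rec(3, False), rec(5, False)]
        with pytest.warns(UserWarning, match="vacuous"):
            chi2, df, p = logrank_test(records, np.array([1, 2]))
        assert (chi2, p) == (0.0, 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([rec(1, True), rec(2, True)], np.array([1, 1]))

    def test_survival_separation_on_distinct_hazards(self):
        rng = np.random.default_rng(3)
        n = 60
        labels = np.repeat([1, 2], n // 2)
        hazards = np.where(labels == 1, 1 / 2000, 1 / 200)
        times = rng.exponential(1 / hazards)
        records = [rec(t, True, pid=f"P{i}") for i, t in enumerate(times)]
        out = survival_separation(labels, records)
        assert out["p_value"] < 0.01
        assert set(out["curves"]) == {1, 2}


def matrix(data_type, values):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return OmicsMatrix(
        tuple(f"P{i}" for i in range(values.shape[0])),
        tuple(f"G{j}" for j in range(values.shape[1])),
        values, data_type,
    )


class TestDiscretize:
    def test_cna_gain_loss_thresholds(self):
        out = discretize(matrix("cna", [[1.0], [0.9], [-1.0], [-0.5]]))
        np.testing.assert_array_equal(out["gain"][:, 0], [True, False, False, False])
        np.testing.assert_array_equal(out["loss"][:, 0], [False, False, True, False])

    def test_expression_z_score_thresholds(self):
        out = discretize(matrix("expression", [[1.0], [-1.0], [0.0]]))
        np.testing.assert_array_equal(out["over"][:, 0], [True, False, False])
        np.testing.assert_array_equal(out["under"][:, 0], [False, True, False])

    def test_methylation_beta_thresholds(self):
        out = discretize(matrix("methylation", [[0.75], [0.5], [0.25]]))
        np.testing.assert_array_equal(out["hyper"][:, 0], [True, False, False])
        np.testing.assert_array_equal(out["hypo"][:, 0], [False, False, True])

    def test_mutation_passthrough(self):
        out = discretize(matrix("mutation", [[1.0], [0.0]]))
        np.testing.assert_array_equal(out["mutated"][:, 0], [True, False])

    def test_beta_range_validated(self):
        with pytest.raises(ValueError, match="beta"):
            discretize(matrix("methylation", [[1.2]]))

    def test_normalized_matrix_rejected(self):
        m = matrix("cna", [[0.5], [0.7]])
        from dataclasses import replace

        with pytest.raises(ValueError, match="raw-scale"):
            discretize(replace(m, normalized=True))


class TestHypergeometric:
    def test_all_alterations_in_cluster(self):
        # N=10, K=3 altered, cluster of 3 holds all of them: p = 1/C(10,3)
        indicator = np.array([True] * 3 + [False] * 7)
        labels = np.array([1] * 3 + [2] * 7)
        assert hypergeom_enrich(indicator, labels, 1) == pytest.approx(1 / 120)

    @pytest.mark.parametrize("value", [True, False])
    def test_constant_indicator_gives_one(self, value):
        indicator = np.full(8, value)
        labels = np.array([1] * 4 + [2] * 4)
        assert hypergeom_enrich(indicator, labels, 1) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        # exact tail by enumerating all C(N, K) placements of altered patients
        n, k_total, cluster_size = 10, 4, 5
        labels = np.array([1] * cluster_size + [2] * (n - cluster_size))
        for x_obs in range(k_total + 1):
            indicator = np.zeros(n, dtype=bool)
            indicator[:x_obs] = True
            indicator[cluster_size:cluster_size + (k_total - x_obs)] = True
            hits = 0
            total = 0
            for placement in combinations(range(n), k_total):
                total += 1
                inside = sum(1 for i in placement if i < cluster_size)
                if inside >= x_obs:
                    hits += 1
            assert hypergeom_enrich(indicator, labels, 1) == pytest.approx(hits / total)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(np.array([True, False]), np.array([1, 1]), 2)


class TestFdr:
    def test_hand_computed_bh(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2]), [0.2])

    def test_ties_stay_equal(self):
        np.testing.assert_allclose(fdr_adjust([0.04, 0.04, 0.04]), [0.04, 0.04, 0.04])

    def test_q_dominates_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        assert np.all(fdr_adjust(p) >= p - 1e-12)

    @given(st.permutations(list(range(6))))
    @settings(max_examples=30, deadline=None)
    def test_order_equivariance(self, order):
        p = np.array([0.001, 0.04, 0.2, 0.5, 0.8, 0.013])
        q = fdr_adjust(p)
        q_perm = fdr_adjust(p[order])
        np.testing.assert_allclose(q_perm, q[order])


class TestRepresentativeness:
    def build(self, frac_in, frac_others):
        # cluster 1 of 30, other clusters of 30 each
        sizes = [30] * (1 + len(frac_others))
        labels = np.concatenate([[c + 1] * s for c, s in enumerate(sizes)])
        indicator = np.zeros(sum(sizes), dtype=bool)
        indicator[: int(round(frac_in * 30))] = True
        offset = 30
        for frac in frac_others:
            indicator[offset: offset + int(round(frac * 30))] = True
            offset += 30
        return indicator, labels

    def test_passes_with_one_depleted_cluster(self):
        indicator, labels = self.build(0.7, [0.2, 0.5])
        assert representativeness_filter(indicator, labels, 1) is True

    def test_fails_below_two_thirds(self):
        indicator, labels = self.build(0.6, [0.0])
        assert representativeness_filter(indicator, labels, 1) is False

    def test_fails_when_no_cluster_is_depleted(self):
        indicator, labels = self.build(1.0, [0.9, 0.9])
        assert representativeness_filter(indicator, labels, 1) is False

    def test_fraction_bookkeeping(self):
        indicator, labels = self.build(0.7, [0.2, 0.5])
        frac_in, min_out = cluster_fractions(indicator, labels, 1)
        assert frac_in == pytest.approx(0.7)
        assert min_out == pytest.approx(0.2)


class TestEnrichmentTable:
    def test_planted_driver_is_detected(self):
        rng = np.random.default_rng(1)
        n = 60
        labels = np.repeat([1, 2], n // 2)
        values = (rng.random((n, 5)) < 0.05).astype(float)
        values[labels == 1, 0] = (rng.random(n // 2) < 0.9).astype(float)
        m = matrix("mutation", values)
        table = enrichment_table([m], labels)
        hit = table[(table.cluster == 1) & (table.gene == "G0")]
        assert bool(hit.significant.iloc[0])
        background = table[(table.cluster == 1) & (table.gene != "G0")]
        assert not background.significant.any()

    def test_representativeness_applies_to_cna_only_family(self):
        rng = np.random.default_rng(2)
        n = 30
        labels = np.repeat([1, 2], n // 2)
        values = rng.normal(0, 0.1, (n, 3))
        values[labels == 1, 0] = 2.0  # universal gain in cluster 1
        table = enrichment_table([matrix("cna", values)], labels)
        row = table[(table.cluster == 1) & (table.gene == "G0") & (table.direction == "gain")]
        assert bool(row.passes_representativeness.iloc[0])
        assert bool(row.significant.iloc[0])
        assert row.q_fdr.iloc[0] >= row.p_raw.iloc[0] - 1e-12
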