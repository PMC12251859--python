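import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metaqtl.meta_analysis import (
    ChromosomeQTLSet, QTLObservation, best_partition, cluster_mle,
    information_criteria, meta_analyze, meta_analyze_chromosome, mixture_loglik,
    mqtl_summary, sd_from_ci, select_k,
)
from metaqtl.meta_analysis import MQTL
from conftest import make_qset


def brute_force_best_loglik(xs, sigmas, k):
    """Independent oracle: enumerate all C(n-1, k-1) contiguous partitions."""
    n = len(xs)
    best = -math.inf
    for splits in itertools.combinations(range(1, n), k - 1):
        bounds = zip((0, *splits), (*splits, n))
        total = sum(cluster_mle(xs[i:j], sigmas[i:j])[2] for i, j in bounds)
        best = max(best, total)
    return best


class TestSdFromCi:
    def test_unit_and_linear_cases(self):
        assert sd_from_ci(0.0, 3.92) == pytest.approx(1.0)
        assert sd_from_ci(10.0, 17.84) == pytest.approx(2.0)

    def test_published_width_case(self):
        # a 19.9 cM interval, as printed for one of the reference MQTLs
        assert sd_from_ci(383.5, 403.4) == pytest.approx(19.9 / 3.92, abs=1e-4)
        assert sd_from_ci(0.0, 19.9) == pytest.approx(5.0765, abs=1e-4)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            sd_from_ci(5.0, 5.0)


class TestClusterMle:
    def test_single_member(self):
        mu, se, _ = cluster_mle([10.0], [2.0])
        assert (mu, se) == (10.0, 2.0)

    def test_equal_sigma_symmetry(self):
        mu, se, _ = cluster_mle([0.0, 10.0], [2.0, 2.0])
        assert mu == pytest.approx(5.0)
        assert se == pytest.approx(2.0 / math.sqrt(2))

    def test_inverse_variance_weighting_and_grid_optimality(self):
        xs, sigmas = [0.0, 10.0], [1.0, 3.0]
        mu, se, loglik = cluster_mle(xs, sigmas)
        assert mu == pytest.approx(1.0)
        assert se == pytest.approx(math.sqrt(0.9), abs=1e-6)
        # mu maximizes the log-likelihood over a fine grid
        def ll(m):
            return sum(
                -0.5 * math.log(2 * math.pi) - math.log(s) - (x - m) ** 2 / (2 * s * s)
                for x, s in zip(xs, sigmas)
            )
        grid = np.arange(-2.0, 12.0, 0.001)
        assert loglik >= max(ll(m) for m in grid) - 1e-9

    @given(
        xs=st.lists(st.floats(0, 300), min_size=1, max_size=12),
        seed=st.integers(0, 2**16),
    )
    @settings(deadline=None, max_examples=50)
    def test_mu_within_data_range(self, xs, seed):
        rng = np.random.default_rng(seed)
        sigmas = rng.uniform(0.5, 10.0, len(xs)).tolist()
        mu, se, _ = cluster_mle(xs, sigmas)
        assert min(xs) - 1e-9 <= mu <= max(xs) + 1e-9
        assert se <= min(sigmas) + 1e-12


class TestBestPartition:
    def test_k_equals_n_closed_form(self):
        rng = np.random.default_rng(0)
        qset = make_qset(rng, [50.0], 5)
        model = best_partition(qset, k=5)
        expected = sum(
            -math.log(o.sigma * math.sqrt(2 * math.pi)) for o in qset.items
        )
        assert model.loglik == pytest.approx(expected, abs=1e-9)

    def test_k1_equals_single_cluster_mle(self):
        rng = np.random.default_rng(1)
        qset = make_qset(rng, [50.0, 150.0], 4)
        model = best_partition(qset, k=1)
        xs = [o.x for o in qset.items]
        ss = [o.sigma for o in qset.items]
        assert model.loglik == pytest.approx(cluster_mle(xs, ss)[2], abs=1e-9)

    def test_two_tight_groups_split_at_the_gap(self):
        xs = [19.0, 20.0, 21.0, 79.0, 80.0, 81.0]
        items = tuple(
            QTLObservation(f"q{i}", x, 2.0, "PH") for i, x in enumerate(xs)
        )
        model = best_partition(ChromosomeQTLSet(1, items), k=2)
        assert model.boundaries == ((0, 3), (3, 6))
        assert model.clusters[0].mu == pytest.approx(20.0)
        assert model.clusters[1].mu == pytest.approx(80.0)
        # oracle: enumerate all 5 contiguous splits
        ss = [2.0] * 6
        assert model.loglik == pytest.approx(
            brute_force_best_loglik(xs, ss, 2), abs=1e-9
        )

    @given(seed=st.integers(0, 2**16))
    @settings(deadline=None, max_examples=40)
    def test_dp_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        xs = np.sort(rng.uniform(0, 300, n)).tolist()
        ss = rng.uniform(0.5, 15.0, n).tolist()
        items = tuple(
            QTLObservation(f"q{i}", x, s, "PH") for i, (x, s) in enumerate(zip(xs, ss))
        )
        qset = ChromosomeQTLSet(1, items)
        for k in range(1, n + 1):
            model = best_partition(qset, k)
            assert model.loglik == pytest.approx(
                brute_force_best_loglik(xs, ss, k), abs=1e-9
            )

    def test_loglik_monotone_in_k(self):
        rng = np.random.default_rng(9)
        qset = make_qset(rng, [40.0, 160.0, 260.0], 5)
        logliks = [best_partition(qset, k).loglik for k in range(1, len(qset) + 1)]
        assert all(b >= a - 1e-9 for a, b in zip(logliks, logliks[1:]))

    def test_k_out_of_range_rejected(self):
        rng = np.random.default_rng(2)
        qset = make_qset(rng, [50.0], 3)
        with pytest.raises(ValueError):
            best_partition(qset, 4)


class TestInformationCriteria:
    def test_plugin_values_k1(self):
        crit = information_criteria(0.0, k=1, n=10)
        assert crit["AIC"] == pytest.approx(2.0)
        assert crit["AIC3"] == pytest.approx(3.0)
        assert crit["BIC"] == pytest.approx(math.log(10), abs=1e-4)

    def test_hand_arithmetic_with_p_equal_k(self):
        crit = information_criteria(-50.0, k=3, n=20, n_params=3)
        assert crit["AIC"] == pytest.approx(106.0)
        assert crit["AICc"] == pytest.approx(107.5)
        assert crit["AIC3"] == pytest.approx(109.0)
        assert crit["BIC"] == pytest.approx(108.99, abs=0.01)
        assert crit["AWE"] == pytest.approx(126.97, abs=0.01)

    def test_default_mixture_parameter_count(self):
        crit = information_criteria(-50.0, k=3, n=20)  # p = 2k - 1 = 5
        assert crit["AIC"] == pytest.approx(110.0)
        assert crit["BIC"] == pytest.approx(100 + 5 * math.log(20), abs=1e-6)

    def test_aicc_guard_is_infinite(self):
        crit = information_criteria(-5.0, k=2, n=3)  # n - p - 1 = -1
        assert math.isinf(crit["AICc"])


class TestSelectK:
    @staticmethod
    def _rows(per_criterion_choice, kmax=3):
        """Build a criteria table whose per-criterion minima sit at given ks."""
        rows = {k: {} for k in range(1, kmax + 1)}
        for crit, kstar in per_criterion_choice.items():
            for k in rows:
                rows[k][crit] = 0.0 if k == kstar else 10.0 + k
        return rows

    def test_unanimity(self):
        rows = self._rows({c: 2 for c in ("AIC", "AICc", "AIC3", "BIC", "AWE")})
        chosen, votes, _ = select_k(rows)
        assert chosen == 2 and votes == {2: 5}

    def test_three_vote_majority_wins(self):
        rows = self._rows({"AIC": 3, "AICc": 3, "AIC3": 2, "BIC": 2, "AWE": 2})
        chosen, votes, _ = select_k(rows)
        assert chosen == 2 and votes[2] == 3

    def test_no_consensus_falls_back_to_smallest_plurality(self):
        rows = self._rows({"AIC": 1, "AICc": 1, "AIC3": 2, "BIC": 2, "AWE": 3})
        chosen, _, _ = select_k(rows)
        assert chosen == 1

    def test_within_criterion_tie_goes_to_smaller_k(self):
        rows = {1: {c: 5.0 for c in ("AIC", "AICc", "AIC3", "BIC", "AWE")},
                2: {c: 5.0 for c in ("AIC", "AICc", "AIC3", "BIC", "AWE")}}
        chosen, votes, _ = select_k(rows)
        assert chosen == 1 and votes == {1: 5}


class TestMetaAnalyzeChromosome:
    def test_two_distant_clusters_recovered_with_covering_cis(self):
        rng = np.random.default_rng(42)
        qset = make_qset(rng, [60.0, 120.0], 8, sigma_range=(2.0, 2.0))
        mqtls, table = meta_analyze_chromosome(qset)
        assert table.chosen_k == 2
        assert [m.mqtl_id for m in mqtls] == ["MQTL1-1", "MQTL1-2"]
        for m, truth in zip(mqtls, (60.0, 120.0)):
            assert m.ci_lo <= truth <= m.ci_hi

    def test_single_qtl_passthrough(self):
        qset = ChromosomeQTLSet(4, (QTLObservation("solo", 30.0, 2.5, "EH"),))
        mqtls, table = meta_analyze_chromosome(qset)
        (m,) = mqtls
        assert table.chosen_k == 1
        assert m.position == 30.0
        assert m.ci_width == pytest.approx(2 * 1.96 * 2.5)
        assert m.trait_class == "EH"

    def test_mixed_traits_render_joint_class(self):
        items = (
            QTLObservation("a", 49.0, 3.0, "PH"),
            QTLObservation("b", 50.0, 3.0, "PH"),
            QTLObservation("c", 51.0, 3.0, "EH"),
        )
        mqtls, _ = meta_analyze_chromosome(ChromosomeQTLSet(1, items))
        assert [m.trait_class for m in mqtls] == ["PH, EH"]

    def test_ci_never_wider_than_sharpest_member(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            qset = make_qset(rng, [50.0, 150.0, 250.0], 8, sigma_range=(0.5, 20.0))
            mqtls, _ = meta_analyze_chromosome(qset)
            by_id = {o.qtl_id: o for o in qset.items}
            for m in mqtls:
                min_member_width = min(
                    2 * 1.96 * by_id[q].sigma for q in m.member_qtl_ids
                )
                assert m.ci_width <= min_member_width + 1e-9

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        qset = make_qset(rng, [50.0, 200.0], 6)
        shuffled_items = list(qset.items)
        rng.shuffle(shuffled_items)
        a, _ = meta_analyze_chromosome(qset)
        b, _ = meta_analyze_chromosome(ChromosomeQTLSet(1, tuple(shuffled_items)))
        assert a == b


class TestMetaAnalyze:
    def _records(self):
        from metaqtl.compendium import QTLRecord

        recs = []
        rng = np.random.default_rng(8)
        for chrom in (1, 2):
            for li, locus in enumerate((60.0, 180.0)):
                for i in range(6):
                    x = float(rng.normal(locus, 3.0))
                    recs.append(QTLRecord(
                        qtl_id=f"c{chrom}l{li}q{i}", study_ref="S", trait="PH" if i % 2 else "EH",
                        chromosome=chrom, source_map_id="ref", position=x,
                        population_type="F2", population_size=200,
                        ci_lo=x - 6.0, ci_hi=x + 6.0,
                    ))
        return recs

    def test_pooled_ids_indexed_left_to_right_per_chromosome(self):
        mqtls, tables = meta_analyze(self._records())
        assert {m.chromosome for m in mqtls} == {1, 2}
        for chrom in (1, 2):
            ids = [m.mqtl_id for m in mqtls if m.chromosome == chrom]
            assert ids == [f"MQTL{chrom}-{i}" for i in range(1, len(ids) + 1)]
            pos = [m.position for m in mqtls if m.chromosome == chrom]
            assert pos == sorted(pos)

    def test_per_trait_mode_prefixes_ids(self):
        mqtls, _ = meta_analyze(self._records(), mode="per-trait")
        assert all(m.mqtl_id.startswith(("PH_MQTL", "EH_MQTL")) for m in mqtls)
        assert all(m.trait_class in {"PH", "EH"} for m in mqtls)


class TestMqtlSummary:
    def test_single_mqtl_widths(self):
        m = MQTL("MQTL1-1", 1, 5.0, 0.0, 10.0, "PH", 1)
        s = mqtl_summary([m])
        assert s.ci_width_min == s.ci_width_mean == s.ci_width_max == 10.0
        assert s.member_total == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mqtl_summary([])


def test_mixture_loglik_single_component_matches_direct_sum():
    xs, ss = [1.0, 2.0, 5.0], [1.0, 2.0, 0.5]
    direct = sum(
        -0.5 * math.log(2 * math.pi) - math.log(s) - (x - 2.0) ** 2 / (2 * s * s)
        for x, s in zip(xs, ss)
    )
    assert mixture_loglik(xs, ss, [2.0], [1.0]) == pytest.approx(direct, abs=1e-12)
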