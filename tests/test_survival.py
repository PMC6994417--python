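"""Kaplan–Meier and log-rank against hand computations and lifelines."""

import numpy as np
import pytest

from somatic_screen.io_model import SurvivalRecord
from somatic_screen.survival import (
    km_estimate,
    km_median,
    logrank_test,
    stratify_by_gene,
    survival_at,
)


def _records(spec):
    """spec: list of (time, event_bool) tuples."""
    return [
        SurvivalRecord(f"P{i}", float(t), bool(e)) for i, (t, e) in enumerate(spec)
    ]


class TestKaplanMeier:
    def test_four_events_closed_form(self):
        curve = km_estimate(_records([(1, 1), (2, 1), (3, 1), (4, 1)]))
        assert list(curve.event_times) == [1, 2, 3, 4]
        assert curve.survival == pytest.approx([0.75, 0.5, 0.25, 0.0])

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate(_records([(5, 0), (8, 0), (10, 0)]))
        assert curve.event_times.size == 0
        assert survival_at(curve, 100.0) == 1.0
        assert km_median(curve) is None

    def test_six_patient_hand_oracle(self):
        # (1,E),(2,C),(3,E),(4,E),(5,C),(6,E):
        # S = 5/6, then ×3/4, ×2/3, ×0 at t=6
        curve = km_estimate(
            _records([(1, 1), (2, 0), (3, 1), (4, 1), (5, 0), (6, 1)])
        )
        assert list(curve.event_times) == [1, 3, 4, 6]
        assert curve.survival == pytest.approx(
            [5 / 6, 5 / 6 * 3 / 4, 5 / 6 * 3 / 4 * 2 / 3, 0.0]
        )
        assert list(curve.n_at_risk) == [6, 4, 3, 1]

    def test_ties_events_before_censorings(self):
        # censored at the event time remains at risk for that event
        curve = km_estimate(_records([(2, 1), (2, 0), (3, 1)]))
        assert curve.survival == pytest.approx([2 / 3, 0.0])
        assert list(curve.n_at_risk) == [3, 1]

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            km_estimate([])

    def test_median_smallest_time_reaching_half(self):
        curve = km_estimate(_records([(1, 1), (2, 1), (3, 1), (4, 1)]))
        assert km_median(curve) == 2.0

    def test_survival_at_before_first_event(self):
        curve = km_estimate(_records([(5, 1), (7, 1)]))
        assert survival_at(curve, 4.9) == 1.0
        assert survival_at(curve, 0.0) == 1.0

    def test_survival_beyond_last_event_all_events(self):
        curve = km_estimate(_records([(1, 1), (2, 1)]))
        assert survival_at(curve, 99.0) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_lifelines_on_random_cohorts(self, seed):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        times = rng.exponential(20, size=n).round(2) + 0.5
        events = rng.random(n) < 0.7
        records = _records(list(zip(times, events)))
        curve = km_estimate(records)
        kmf = KaplanMeierFitter().fit(times, events)
        for t in [0.0, 5.0, 10.0, 25.0, 60.0]:
            assert survival_at(curve, t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-12
            )


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        group = _records([(1, 1), (3, 1), (5, 0)])
        result = logrank_test(group, list(group))
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_four_patient_hand_hypergeometric(self):
        # A: events at 1 and 3; B: event at 2, censored at 4.
        # O_A=2, E_A=0.5+1/3+0.5=4/3, V=1/4+2/9+1/4=13/18,
        # chi2 = (2-4/3)^2/(13/18) = 8/13
        a = _records([(1, 1), (3, 1)])
        b = _records([(2, 1), (4, 0)])
        result = logrank_test(a, b)
        assert result.observed == (2.0, 1.0)
        assert result.expected[0] == pytest.approx(4 / 3)
        assert result.variance == pytest.approx(13 / 18)
        assert result.statistic == pytest.approx(8 / 13)

    def test_expected_counts_sum_to_total_events(self):
        a = _records([(1, 1), (4, 1), (6, 0)])
        b = _records([(2, 1), (3, 0), (9, 1)])
        result = logrank_test(a, b)
        assert sum(result.expected) == pytest.approx(sum(result.observed))

    def test_label_swap_invariance(self):
        a = _records([(1, 1), (4, 1), (6, 0)])
        b = _records([(2, 1), (3, 0), (9, 1)])
        assert logrank_test(a, b).statistic == pytest.approx(
            logrank_test(b, a).statistic
        )

    def test_no_events_is_error(self):
        with pytest.raises(ValueError):
            logrank_test(_records([(1, 0)]), _records([(2, 0)]))

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_lifelines_on_random_cohorts(self, seed):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(seed)
        a = _records(
            list(zip(rng.exponential(15, 20).round(1) + 0.5, rng.random(20) < 0.8))
        )
        b = _records(
            list(zip(rng.exponential(25, 15).round(1) + 0.5, rng.random(15) < 0.8))
        )
        ours = logrank_test(a, b)
        ll = ll_logrank(
            [r.os_months for r in a],
            [r.os_months for r in b],
            event_observed_A=[r.event for r in a],
            event_observed_B=[r.event for r in b],
        )
        assert ours.statistic == pytest.approx(ll.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(ll.p_value, rel=1e-9)

    def test_chi_square_p_close_to_permutation_null(self):
        # small-sample sanity: the asymptotic p lands near a label-
        # permutation estimate (Monte-Carlo error allowed)
        rng = np.random.default_rng(99)
        times = list(rng.exponential(10, 14).round(1) + 0.5)
        events = [True] * 14
        labels = [0] * 7 + [1] * 7
        records = _records(list(zip(times, events)))
        observed = logrank_test(
            [r for r, l in zip(records, labels) if l == 0],
            [r for r, l in zip(records, labels) if l == 1],
        )
        hits = 0
        n_perm = 500
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            stat = logrank_test(
                [r for r, l in zip(records, perm) if l == 0],
                [r for r, l in zip(records, perm) if l == 1],
            ).statistic
            hits += stat >= observed.statistic - 1e-12
        assert abs(hits / n_perm - observed.p_value) < 0.12


class TestStratification:
    def test_reference_partition_exhaustive_disjoint(self, bundle, targeted_result):
        from somatic_screen.pipeline import mutated_samples_by_gene

        by_gene = mutated_samples_by_gene(targeted_result)
        mutated, wildtype = stratify_by_gene(by_gene, bundle.clinical, "FAT1")
        assert len(mutated) + len(wildtype) == len(bundle.clinical)
        assert not {r.patient_id for r in mutated} & {r.patient_id for r in wildtype}

    def test_unknown_gene_is_error(self, bundle, targeted_result):
        from somatic_screen.pipeline import mutated_samples_by_gene

        by_gene = mutated_samples_by_gene(targeted_result)
        with pytest.raises(KeyError):
            stratify_by_gene(by_gene, bundle.clinical, "NOT_A_GENE")

    def test_gene_with_no_mutant_patients_all_wildtype(self, bundle):
        mutated, wildtype = stratify_by_gene(
            {"EMPTY": set()}, bundle.clinical, "EMPTY"
        )
        assert mutated == [] and len(wildtype) == len(bundle.clinical)

    def test_patients_without_clinical_records_excluded(self):
        clinical = _records([(5, 1), (8, 0)])
        mutated, wildtype = stratify_by_gene(
            {"G": {"P0", "GHOST"}}, clinical, "G"
        )
        assert [r.patient_id for r in mutated] == ["P0"]
        assert [r.patient_id for r in wildtype] == ["P1"]
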