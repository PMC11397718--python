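"""Family aggregation, PD progression, section aggregation and
hybridization frequency."""

import numpy as np
import pytest

from pollenstats import (
    BreedingRoute,
    Pedigree,
    Rank,
    TaxonRecord,
    aggregation_from_labels,
    frequency_concordance,
    hybridization_frequency,
    load_parentage_panel,
    panel_aggregation,
    panel_pd_progression,
    panel_pedigree,
    pd_progression,
    percent_share,
    section_aggregation,
)
from pollenstats.pedigree import NOT_EVALUABLE, EmptyInputError, _row_aggregation
from pollenstats.traits import UNKNOWN, UNTESTED


def ped(*routes):
    return Pedigree([BreedingRoute(*r) for r in routes])


class TestAggregationFromLabels:
    def test_single_known_parent_match(self):
        labels = {"c1": "A", "p1": "A", "c2": "B", "p2": "A"}
        rep = aggregation_from_labels(
            labels, ped(("c1", "p1", UNKNOWN), ("c2", "p2", UNKNOWN)))
        assert rep.indicators == {"c1": True, "c2": False}
        assert rep.percentage == 50.0 and rep.n_evaluable == 2

    def test_any_vs_all_rule(self):
        labels = {"c1": "A", "p1": "A", "p2": "B"}
        routes = ped(("c1", "p1", "p2"))
        assert aggregation_from_labels(labels, routes, rule="any").percentage == 100.0
        assert aggregation_from_labels(labels, routes, rule="all").percentage == 0.0

    def test_unclustered_parent_not_evaluable(self):
        labels = {"c1": "A"}
        rep_err = ped(("c1", "p_absent", UNKNOWN), ("c2", "p_absent", UNKNOWN))
        with pytest.raises(EmptyInputError):
            aggregation_from_labels(labels, rep_err)

    def test_not_evaluable_excluded_from_denominator(self):
        labels = {"c1": "A", "p1": "A", "c2": "B"}
        rep = aggregation_from_labels(
            labels, ped(("c1", "p1", UNKNOWN), ("c2", "nope", UNKNOWN)))
        assert rep.indicators["c2"] is NOT_EVALUABLE
        assert rep.percentage == 100.0 and rep.n_evaluable == 1


class TestPDProgression:
    PDM = {"c1": 5.0, "c2": 1.0, "p1": 2.0, "p2": 8.0}

    def test_exceeds_at_least_one_parent(self):
        routes = ped(("c1", "p1", "p2"), ("c2", "p1", "p2"))
        rep = pd_progression(self.PDM, routes, "exclude_unknown")
        # c1 (5) > p1 (2): yes; c2 (1) beats neither
        assert rep.indicators == {"c1": True, "c2": False}
        assert rep.percentage == 50.0

    def test_assume_lower_auto_succeeds_unknown(self):
        routes = ped(("c2", "p2", UNKNOWN))
        assert pd_progression(self.PDM, routes, "assume_lower").percentage == 100.0
        rep = pd_progression(self.PDM, routes, "exclude_unknown")
        assert rep.percentage == 0.0  # c2 (1) < p2 (8), unknown dropped

    def test_untested_parent_dropped_in_exclude_mode(self):
        routes = ped(("c2", "zzz_not_measured", UNKNOWN))
        with pytest.raises(EmptyInputError):
            pd_progression(self.PDM, routes, "exclude_unknown")
        assert pd_progression(self.PDM, routes, "assume_lower").percentage == 100.0

    def test_missing_progeny_pd_raises(self):
        routes = ped(("cX", "p1", "p2"))
        with pytest.raises(ValueError, match="cX"):
            pd_progression(self.PDM, routes)

    def test_mode_ordering_invariant_random_pedigrees(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_par, n_prog = 4, 8
            pdm = {f"p{i}": float(rng.uniform(0, 10)) for i in range(n_par)}
            routes = []
            for j in range(n_prog):
                pdm[f"c{j}"] = float(rng.uniform(0, 10))
                a = f"p{rng.integers(n_par)}"
                b = rng.choice([f"p{rng.integers(n_par)}", UNKNOWN, UNTESTED])
                routes.append(BreedingRoute(f"c{j}", a, str(b)))
            pedigree = Pedigree(routes)
            hi = pd_progression(pdm, pedigree, "assume_lower").percentage
            lo = pd_progression(pdm, pedigree, "exclude_unknown").percentage
            assert hi >= lo


class TestSectionAggregation:
    @staticmethod
    def _result(group_of, subgroup_of=None):
        from pollenstats.cluster import ClusterResult
        return ClusterResult(dendrogram=None, group_of=group_of,
                             subgroup_of=subgroup_of or {}, largest_group="D")

    def test_concentrated_sections_score_100(self):
        taxonomy = [TaxonRecord(f"s{i}", f"s{i}", Rank.SPECIES, (i % 2) + 1)
                    for i in range(6)]
        group_of = {f"s{i}": ("A" if i % 2 == 0 else "B") for i in range(6)}
        rep = section_aggregation(self._result(group_of), taxonomy)
        assert rep.group_percentage == 100.0

    def test_modal_membership_counting(self):
        # section 1: 3 of 4 species in A -> 3 hits; section 2: 2 of 2 in B
        taxonomy = [TaxonRecord(f"s{i}", f"s{i}", Rank.SPECIES,
                                1 if i < 4 else 2) for i in range(6)]
        group_of = {"s0": "A", "s1": "A", "s2": "A", "s3": "B",
                    "s4": "B", "s5": "B"}
        rep = section_aggregation(self._result(group_of), taxonomy)
        assert rep.group_percentage == pytest.approx(percent_share(5, 6))

    def test_singleton_sections_trivially_aggregate(self):
        taxonomy = [TaxonRecord(f"s{i}", f"s{i}", Rank.SPECIES, i + 1)
                    for i in range(3)]
        group_of = {"s0": "A", "s1": "B", "s2": "C"}
        rep = section_aggregation(self._result(group_of), taxonomy)
        assert rep.group_percentage == 100.0

    def test_modal_tie_accepts_both_and_logs(self):
        taxonomy = [TaxonRecord(f"s{i}", f"s{i}", Rank.SPECIES, 1)
                    for i in range(4)]
        group_of = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        rep = section_aggregation(self._result(group_of), taxonomy)
        assert rep.group_percentage == 100.0
        assert rep.ties


class TestHybridizationFrequency:
    def test_hand_count(self):
        routes = ped(("c1", "A", "B"), ("c2", "A", UNKNOWN), ("c3", "B", "C"))
        hf = hybridization_frequency(routes)
        assert hf.frequency == pytest.approx(
            {"A": 2 / 3, "B": 2 / 3, "C": 1 / 3})
        assert hf.total_crosses == 3

    def test_single_route_both_parents_full_frequency(self):
        hf = hybridization_frequency(ped(("c1", "A", "B")))
        assert hf.frequency == {"A": 1.0, "B": 1.0}
        assert hf.classification == {"A": "high", "B": "high"}

    def test_unused_species_gets_zero(self):
        hf = hybridization_frequency(ped(("c1", "A", "B")),
                                     species=["A", "B", "C"])
        assert hf.frequency["C"] == 0.0 and hf.classification["C"] == "low"

    def test_classification_thresholds(self):
        routes = ped(*[(f"c{i}", "A", "B" if i == 0 else UNKNOWN)
                       for i in range(10)])
        hf = hybridization_frequency(routes)
        assert hf.classification["A"] == "high"      # 10/10
        assert hf.classification["B"] == "medium"    # 1/10


class TestFrequencyConcordance:
    def test_identical_and_proportional_vectors(self):
        a = {"x": 0.1, "y": 0.2, "z": 0.3}
        assert frequency_concordance(a, a) == pytest.approx((1.0, 1.0))
        b = {k: 2 * v for k, v in a.items()}
        r, r2 = frequency_concordance(a, b)
        assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_null_r_squared_matches_expectation(self):
        # independent vectors of length n: E[R^2] = 1/(n-1)
        rng = np.random.default_rng(1)
        n = 12
        r2s = []
        for _ in range(1000):
            a = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(size=n))}
            b = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(size=n))}
            r2s.append(frequency_concordance(a, b)[1])
        assert np.mean(r2s) == pytest.approx(1 / (n - 1), abs=0.02)

    def test_degenerate_inputs_raise(self):
        a = {"x": 0.1, "y": 0.1, "z": 0.1}
        b = {"x": 0.1, "y": 0.2, "z": 0.3}
        with pytest.raises(ValueError):
            frequency_concordance(a, b)
        with pytest.raises(ValueError):
            frequency_concordance({"x": 0.1, "y": 0.2}, b)


class TestParentagePanel:
    def test_panel_shape_and_states(self):
        panel = load_parentage_panel()
        assert len(panel) == 28
        pedigree = panel_pedigree(panel)
        assert len(pedigree) == 14  # rows with printed routes
        assert any(e.parent2 == UNKNOWN for e in pedigree)

    def test_row_indicators_recompute_from_printed_labels(self):
        panel = load_parentage_panel()
        checked = 0
        for _, row in panel.iterrows():
            for level in ("four_group", "six_group"):
                recomputed = _row_aggregation(row, level)
                if recomputed is None:
                    continue
                col = ("aggregated_four_group" if level == "four_group"
                       else "aggregated_six_group")
                assert recomputed == bool(row[col]), (row["progeny"], level)
                checked += 1
        assert checked >= 28  # 14 label-complete rows x 2 levels

    def test_headline_percentages(self):
        panel = load_parentage_panel()
        assert panel_aggregation(panel, "four_group").percentage == pytest.approx(
            percent_share(26, 28))
        assert panel_aggregation(panel, "six_group").percentage == pytest.approx(
            percent_share(19, 28))
        assert panel_pd_progression(panel, "assume_lower").percentage == (
            pytest.approx(percent_share(27, 28)))
        assert panel_pd_progression(panel, "exclude_unknown").percentage == (
            pytest.approx(percent_share(15, 28)))
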