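import datetime as dt

import pytest

from mosvkit import (
    Mode,
    MOSVEvent,
    child_based,
    counterfactual_receipt,
    potential_coverage,
    stratified_run,
    time_to_correction,
    visit_based,
)

from conftest import make_child


def _cohort_abc():
    """A: one corrected DPT1 MOSV; B: one uncorrected OPV1 MOSV; C: clean."""
    a = make_child({"BCG": 0, "OPV1": 42, "DPT1": 80, "OPV2": 80}, child_id="A")
    b = make_child({"BCG": 0, "DPT1": 42}, child_id="B")
    c = make_child({"BCG": 0, "DPT1": 42, "OPV1": 42}, child_id="C")
    return [a, b, c]


class TestVisitBased:
    def test_vb1_direct_count(self, schedule):
        # A: two DPT1-eligible visits, one with a DPT1 MOSV; B: one eligible
        # visit, no MOSV -> VB1(DPT1) = 1/3
        a = make_child({"BCG": 0, "OPV1": 42, "DPT1": 80, "OPV2": 80}, child_id="A")
        b = make_child({"BCG": 0, "DPT1": 42, "OPV1": 42}, child_id="B")
        res = visit_based([a, b], schedule, Mode.CRUDE)
        r = res.vb1["DPT1"]
        assert (r.num_n, r.den_n) == (1, 3)
        assert r.unweighted == pytest.approx(1 / 3)
        assert r.weighted == pytest.approx(1 / 3)

    def test_no_events_all_zero(self, schedule):
        rec = make_child(
            {"BCG": 0, "OPV1": 42, "DPT1": 42, "OPV2": 70, "DPT2": 70,
             "OPV3": 98, "DPT3": 98, "MCV1": 270}
        )
        res = visit_based([rec], schedule, Mode.CRUDE)
        assert res.vb2.weighted == 0
        assert res.vb3.weighted == 0
        assert res.vb3_inverse_weighted is None

    def test_two_misses_per_visit(self, schedule):
        # single visit, DPT1 administered, BCG and OPV1 both missed
        rec = make_child({"DPT1": 42})
        res = visit_based([rec], schedule, Mode.CRUDE)
        assert res.vb2.weighted == 1.0
        assert res.vb3.weighted == 2.0
        assert res.vb3_inverse_weighted == 0.5

    def test_zero_denominator_reports_null(self, schedule):
        res = visit_based([], schedule, Mode.CRUDE)
        assert res.vb1["DPT1"].weighted is None
        assert res.vb1["DPT1"].den_n == 0

    def test_vb3_at_least_vb2(self, schedule):
        recs = [make_child({"DPT1": 42}, child_id="x"), _cohort_abc()[0]]
        res = visit_based(recs, schedule, Mode.CRUDE)
        assert res.vb3.weighted >= res.vb2.weighted

    def test_weighted_tracks_child_weights(self, schedule):
        a = make_child({"DPT1": 42}, child_id="A", weight=3.0)  # misses BCG+OPV1
        b = make_child({"BCG": 0, "DPT1": 42, "OPV1": 42}, child_id="B", weight=1.0)
        res = visit_based([a, b], schedule, Mode.CRUDE)
        # eligible visits: A's one (weight 3) + B's two (weight 1 each)
        assert res.vb2.weighted == pytest.approx(3 / 5)
        assert res.vb2.unweighted == pytest.approx(1 / 3)


class TestChildBased:
    def test_cb2_splits_direct_count(self, schedule):
        res = child_based(_cohort_abc(), schedule, Mode.CRUDE)
        assert res.cb2["any"].unweighted == pytest.approx(2 / 3)
        assert res.cb2["all_corrected"].unweighted == pytest.approx(1 / 3)
        assert res.cb2["some_corrected"].unweighted == 0.0
        assert res.cb2["none_corrected"].unweighted == pytest.approx(1 / 3)

    def test_mixed_child_counts_as_some_corrected(self, schedule):
        # one corrected DPT1 event (caught up at 80 d) and an uncorrected
        # MCV1 event at the 280-day visit
        rec = make_child({"BCG": 0, "OPV1": 42, "DPT1": 80, "OPV2": 80, "OPV3": 280})
        res = child_based([rec], schedule, Mode.CRUDE)
        assert res.cb2["some_corrected"].unweighted == 1.0

    def test_all_corrected_zero_none_share(self, schedule):
        a = _cohort_abc()[0]
        res = child_based([a], schedule, Mode.CRUDE)
        assert res.cb2["none_corrected"].unweighted == 0.0

    def test_cb1_denominator_needs_eligible_visit(self, schedule):
        # child with a single birth visit was never DPT1-eligible at a visit
        rec = make_child({"BCG": 0})
        res = child_based([rec], schedule, Mode.CRUDE)
        assert res.cb1["DPT1"]["any"].den_n == 0
        assert res.cb1["BCG"]["any"].den_n == 1

    def test_splits_sum_to_headline(self, schedule):
        res = child_based(_cohort_abc(), schedule, Mode.CRUDE)
        for dose, parts in res.cb1.items():
            if parts["any"].den_n == 0:
                continue
            assert parts["corrected"].num_w + parts["uncorrected"].num_w == pytest.approx(
                parts["any"].num_w
            )
        total = sum(
            res.cb2[k].num_w
            for k in ("all_corrected", "some_corrected", "none_corrected")
        )
        assert total == pytest.approx(res.cb2["any"].num_w)


class TestPotentialCoverage:
    def test_counterfactual_walk_hand_trace(self, schedule):
        """Visits at 42 d {BCG} and 100 d {OPV1, DPT1}: the counterfactual
        credits BCG+OPV1+DPT1 at 42 d, then OPV2+DPT2 at 100 d."""
        rec = make_child({"BCG": 42, "OPV1": 100, "DPT1": 100})
        cf = counterfactual_receipt(rec, schedule)
        d42 = rec.dob + dt.timedelta(days=42)
        d100 = rec.dob + dt.timedelta(days=100)
        assert {k: v for k, v in cf.items()} == {
            "BCG": d42, "OPV1": d42, "DPT1": d42, "OPV2": d100, "DPT2": d100,
        }
        comps = {c.dose_name: c for c in potential_coverage([rec], schedule, Mode.CRUDE)}
        assert comps["DPT2"].observed.weighted == 0.0
        assert comps["DPT2"].potential.weighted == 1.0
        assert comps["OPV1"].observed.weighted == 1.0

    def test_identity_when_fully_vaccinated(self, schedule):
        rec = make_child(
            {"BCG": 0, "OPV1": 42, "DPT1": 42, "OPV2": 70, "DPT2": 70,
             "OPV3": 98, "DPT3": 98, "MCV1": 270}
        )
        for comp in potential_coverage([rec], schedule, Mode.CRUDE):
            assert comp.observed.weighted == comp.potential.weighted

    def test_potential_never_below_observed_with_early_dose(self, schedule):
        # crude mode credits the early DPT1 even though no counterfactual
        # visit could have delivered it validly
        rec = make_child({"DPT1": 20})
        comps = {c.dose_name: c for c in potential_coverage([rec], schedule, Mode.CRUDE)}
        assert comps["DPT1"].observed.weighted == 1.0
        assert comps["DPT1"].potential.weighted == 1.0

    def test_valid_mode_excludes_invalid_and_tick_doses_from_observed(self, schedule):
        rec = make_child({"DPT1": 20, "MCV1": "tick", "OPV1": 50})
        comps = {c.dose_name: c for c in potential_coverage([rec], schedule, Mode.VALID)}
        assert comps["DPT1"].observed.weighted == 0.0
        assert comps["MCV1"].observed.weighted == 0.0
        # tick credit still seeds the counterfactual
        assert comps["MCV1"].potential.weighted == 1.0
        assert comps["OPV1"].observed.weighted == 1.0


class TestTimeToCorrection:
    def _event(self, delay, dose="DPT1", i=0):
        first = dt.date(2017, 6, 1)
        return MOSVEvent(
            child_id=f"c{i}",
            dose_name=dose,
            first_missed_date=first,
            n_missed_visits=1,
            corrected=True,
            correction_date=first + dt.timedelta(days=delay),
            delay_days=delay,
        )

    def test_single_delay(self):
        dist = time_to_correction([self._event(28)], "DPT1")
        assert dist.ecdf == [(28, 1.0)]
        assert dist.quantiles[50] == 28

    def test_inverse_ecdf_quantiles(self):
        events = [self._event(d, i=i) for i, d in enumerate((10, 20, 30, 40))]
        dist = time_to_correction(events, "DPT1")
        assert dist.quantiles == {25: 10, 50: 20, 75: 30, 90: 40}

    def test_small_n_flag_below_25(self):
        events = [self._event(d, i=i) for i, d in enumerate(range(1, 25))]
        dist = time_to_correction(events, "DPT1")
        assert dist.n_corrected == 24 and dist.small_n
        events.append(self._event(99, i=99))
        assert not time_to_correction(events, "DPT1").small_n

    def test_empty_distribution(self):
        dist = time_to_correction([], "DPT1")
        assert dist.ecdf == [] and dist.quantiles[50] is None

    def test_ecdf_monotone_ends_at_one(self):
        events = [self._event(d, i=i) for i, d in enumerate((5, 5, 9, 30, 30, 41))]
        dist = time_to_correction(events, "DPT1")
        fracs = [f for _, f in dist.ecdf]
        assert fracs == sorted(fracs)
        assert fracs[-1] == pytest.approx(1.0)

    def test_uncorrected_and_other_doses_ignored(self):
        first = dt.date(2017, 6, 1)
        events = [
            self._event(10),
            self._event(10, dose="MCV1", i=1),
            MOSVEvent("c9", "DPT1", first, 1, False),
        ]
        assert time_to_correction(events, "DPT1").n_corrected == 1


class TestStratifiedRun:
    def _strata_cohort(self, schedule):
        kids = []
        for i, stratum in enumerate(["n"] * 3 + ["s"] * 3 + ["central"] * 2):
            doses = {"BCG": 0, "DPT1": 42} if i % 2 else {"DPT1": 42}
            kids.append(
                make_child(doses, child_id=f"k{i}", stratum_id=stratum)
            )
        return kids

    def test_overall_numerators_sum_of_disjoint_strata(self, schedule):
        kids = [k for k in self._strata_cohort(schedule) if k.stratum_id != "central"]
        table = stratified_run(kids, schedule, Mode.CRUDE)
        overall = table.overall.visit_based.vb2
        parts = [table.strata[s].visit_based.vb2 for s in ("n", "s")]
        assert overall.num_n == sum(p.num_n for p in parts)
        assert overall.den_n == sum(p.den_n for p in parts)

    def test_super_stratum_covering_everything_equals_overall(self, schedule):
        kids = self._strata_cohort(schedule)
        table = stratified_run(
            kids, schedule, Mode.CRUDE, {"all": ["n", "s", "central"]}
        )
        assert (
            table.strata["all"].visit_based.vb2.weighted
            == table.overall.visit_based.vb2.weighted
        )

    def test_children_outside_super_strata_national_only(self, schedule):
        # a central region that belongs to neither north nor south contributes
        # to the overall results but to no reporting stratum
        kids = self._strata_cohort(schedule)
        table = stratified_run(
            kids, schedule, Mode.CRUDE, {"north": ["n"], "south": ["s"]}
        )
        n_in_strata = sum(r.n_children for r in table.strata.values())
        assert table.overall.n_children == 8
        assert n_in_strata == 6

    def test_unknown_stratum_in_spec_raises(self, schedule):
        kids = self._strata_cohort(schedule)
        with pytest.raises(KeyError, match="nowhere"):
            stratified_run(kids, schedule, Mode.CRUDE, {"x": ["nowhere"]})

    def test_equal_weights_match_unweighted(self, schedule):
        table = stratified_run(self._strata_cohort(schedule), schedule, Mode.CRUDE)
        vb = table.overall.visit_based
        for r in [vb.vb2, vb.vb3, *vb.vb1.values()]:
            if r.den_n:
                assert r.weighted == pytest.approx(r.unweighted)
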