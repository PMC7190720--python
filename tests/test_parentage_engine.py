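"""Calibration, candidate search, verdict tiers and maternal annotation."""

import pytest

from grapekin import (
    IBDResult,
    MendelResult,
    ThresholdSet,
    Verdict,
    calibrate,
    classify_duo,
    classify_trio,
    duo_mi_snp,
    maternal_consistency,
    search_duos,
    search_trios,
    trio_mi_snp,
)
from grapekin.errors import CalibrationError, DataError
from grapekin.ibd_moments import IBDMomentsEstimator
from grapekin.parentage_engine import ParentageClassifier, _pair_key
from grapekin.pedigree_sim import FS, PO


def ibd(pair, z0, z1, z2, n=10000):
    return IBDResult(pair, z0, z1, z2, z2 + 0.5 * z1, n)


def mendel(unit, mi, n_panel=10000, kind="duo"):
    return MendelResult(unit=unit, kind=kind, mi_total=mi,
                        n_compared=n_panel, n_panel=n_panel)


class TestCalibrate:
    def test_z1_min_is_lowest_reference(self):
        refs = [("P", "A"), ("Q", "B")]
        ibds = {_pair_key("P", "A"): ibd(("A", "P"), 0.03, 0.8279, 0.14),
                _pair_key("Q", "B"): ibd(("B", "Q"), 0.0, 0.9538, 0.046)}
        mis = {_pair_key("P", "A"): mendel(("A", "P"), 25),
               _pair_key("Q", "B"): mendel(("B", "Q"), 37)}
        t = calibrate(refs, ibds, mis)
        assert t.z1_min == 0.8279
        assert t.mi_rate_ref_max == 37 / 10000

    def test_single_reference_thresholds_equal_its_metrics(self):
        refs = [("P", "A")]
        ibds = {_pair_key("P", "A"): ibd(("A", "P"), 0.0, 0.95, 0.05)}
        mis = {_pair_key("P", "A"): mendel(("A", "P"), 10)}
        t = calibrate(refs, ibds, mis)
        assert t.z1_min == 0.95
        assert t.mi_rate_ref_max == 10 / 10000

    def test_empty_reference_set_demands_manual_thresholds(self):
        with pytest.raises(CalibrationError):
            calibrate([], {}, {})

    def test_clean_simulated_references_give_zero_mi_ceiling(self, clean_study):
        study, truth = clean_study
        est = IBDMomentsEstimator().fit(study.snp)
        ibds, mis = {}, {}
        for child, p1, p2 in truth.reference_trios:
            for parent in (p1, p2):
                k = _pair_key(child, parent)
                ibds[k] = est.estimate(*k)
                mis[k] = duo_mi_snp(study.snp, *k)
            mis[(child, p1, p2)] = trio_mi_snp(study.snp, child, p1, p2)
        t = calibrate([tuple(x) for x in truth.reference_trios], ibds, mis)
        assert t.mi_rate_ref_max == 0.0
        assert t.trio_rate_ref_max == 0.0
        assert t.z1_min > 0.95


@pytest.fixture
def thresholds():
    return ThresholdSet(z1_min=0.8279, mi_rate_ref_max=0.0037,
                        trio_rate_ref_max=0.008)


class TestDuoVerdicts:
    def test_conflicting_pair_with_ninefold_mi_rejected(self, thresholds):
        """A pair at Z1 ~ 0.50 with MI nine times the reference ceiling."""
        r = ibd(("M", "MB"), 0.4965, 0.5035, 0.0)
        m = mendel(("M", "MB"), 404, n_panel=11929)
        v = classify_duo(r, m, thresholds)
        assert v.status is Verdict.REJECTED
        assert len(v.reasons) == 2  # both the MI and the Z1 rule fired

    def test_supported_requires_all_three_conditions(self, thresholds):
        good = classify_duo(ibd(("a", "b"), 0.03, 0.96, 0.01),
                            mendel(("a", "b"), 30), thresholds)
        assert good.status is Verdict.SUPPORTED
        # PI-HAT outside the window blocks support
        odd = classify_duo(ibd(("a", "b"), 0.0, 0.85, 0.15),
                           mendel(("a", "b"), 30), thresholds)
        assert odd.ibd.PI_HAT > 0.56
        assert odd.status is not Verdict.SUPPORTED

    def test_middle_tier_is_possible(self, thresholds):
        # Z1 slightly below the floor, MI between accept and reject
        v = classify_duo(ibd(("a", "b"), 0.1, 0.78, 0.12),
                         mendel(("a", "b"), 50), thresholds)
        assert v.status is Verdict.POSSIBLE

    def test_fs_like_pair_not_supported_as_po(self, thresholds):
        # Z2 far from zero (full-sib signature) drags Z1 below the floor
        v = classify_duo(ibd(("GL", "G"), 0.1226, 0.5798, 0.2976),
                         mendel(("GL", "G"), 97, n_panel=11929), thresholds)
        assert v.status is Verdict.REJECTED


class TestTrioVerdicts:
    def _legs(self, thresholds):
        leg = classify_duo(ibd(("c", "p"), 0.03, 0.95, 0.02),
                           mendel(("c", "p"), 20), thresholds)
        return (leg, leg)

    def test_rate_below_reference_supported(self, thresholds):
        tm = mendel(("c", "p1", "p2"), 60, kind="trio")  # rate 0.006 < 0.008
        v = classify_trio(tm, self._legs(thresholds), None, thresholds)
        assert v.status is Verdict.SUPPORTED

    def test_rate_at_1_2x_reference_is_possible(self, thresholds):
        tm = mendel(("c", "p1", "p2"), 96, kind="trio")  # 0.0096 = 1.2x ref
        v = classify_trio(tm, self._legs(thresholds), None, thresholds)
        assert v.status is Verdict.POSSIBLE

    def test_rate_beyond_possible_factor_rejected(self, thresholds):
        tm = mendel(("c", "p1", "p2"), 200, kind="trio")
        v = classify_trio(tm, self._legs(thresholds), None, thresholds)
        assert v.status is Verdict.REJECTED

    def test_rejected_leg_blocks_support(self, thresholds):
        bad_leg = classify_duo(ibd(("c", "p"), 0.9, 0.1, 0.0),
                               mendel(("c", "p"), 500), thresholds)
        tm = mendel(("c", "p1", "p2"), 10, kind="trio")
        v = classify_trio(tm, (bad_leg, bad_leg), None, thresholds)
        assert v.status is Verdict.REJECTED


class TestSearch:
    def test_planted_po_duos_fully_recalled(self, clean_study):
        study, truth = clean_study
        for child, parents in truth.parents.items():
            if not parents:
                continue
            found = {c.candidate_id for c in search_duos(child, study.ssr)}
            assert set(parents) <= found

    def test_clone_flagged_not_proposed_as_duo(self, clean_study):
        study, truth = clean_study
        est = IBDMomentsEstimator().fit(study.snp)
        lookup = {_pair_key(*r.pair): r for r in est.pairwise()}
        clone, source = next(iter(truth.clones.items()))
        cands = search_duos(source, study.ssr, ibd_lookup=lookup)
        flags = {c.candidate_id: c.is_clone for c in cands}
        if clone in flags:
            assert flags[clone]

    def test_empty_database_gives_empty_list(self):
        from grapekin import SSRProfile

        db = {"T": SSRProfile("T", {"L": (1, 2)})}
        assert search_duos("T", db) == []

    def test_unknown_target_rejected(self):
        with pytest.raises(DataError):
            search_duos("nope", {})

    def test_planted_trios_recovered_with_zero_ssr_mismatches(self, clean_study):
        study, truth = clean_study
        est = IBDMomentsEstimator().fit(study.snp)
        lookup = {_pair_key(*r.pair): r for r in est.pairwise()}
        for child, p1, p2 in truth.reference_trios:
            cands = search_trios(child, study.ssr, study.snp, lookup)
            match = [c for c in cands
                     if {c.parent1, c.parent2} >= {p1, p2} or
                     {truth.genet(c.parent1), truth.genet(c.parent2)} == {p1, p2}]
            assert match
            assert any(c.ssr_mismatches == [] and c.trio_mendel.mi_total == 0
                       for c in match)

    def test_candidate_set_of_one_yields_no_pairs(self):
        from grapekin import SSRProfile

        db = {"T": SSRProfile("T", {"L": (1, 2)}),
              "P": SSRProfile("P", {"L": (2, 3)})}
        assert search_trios("T", db) == []


class TestMaternal:
    def test_single_matching_parent_is_maternal(self, clean_study):
        study, truth = clean_study
        for child, parents in truth.parents.items():
            if not parents:
                continue
            mother, father = parents
            got = maternal_consistency((child, mother, father), study.chlorotypes)
            if study.chlorotypes.label(mother) != study.chlorotypes.label(father):
                assert got == mother
            else:
                assert got == "undetermined"

    def test_conflict_flagged_when_neither_parent_matches(self):
        from grapekin import ChlorotypeTable

        table = ChlorotypeTable({
            "c": [1] * 8, "p1": [2] * 8, "p2": [3] * 8,
        })
        assert maternal_consistency(("c", "p1", "p2"), table) == "conflict"


class TestEndToEndPrecision:
    def test_supported_calls_on_clean_panel(self, clean_study):
        """Classifier front end: clean PO duos never REJECTED, non-first-degree
        pairs never SUPPORTED."""
        study, truth = clean_study
        est = IBDMomentsEstimator().fit(study.snp)
        lookup = {_pair_key(*r.pair): r for r in est.pairwise()}
        mendel_lookup = {}
        for child, p1, p2 in truth.reference_trios:
            for parent in (p1, p2):
                k = _pair_key(child, parent)
                mendel_lookup[k] = duo_mi_snp(study.snp, *k)
            mendel_lookup[(child, p1, p2)] = trio_mi_snp(study.snp, child, p1, p2)
        clf = ParentageClassifier().fit(
            [tuple(t) for t in truth.reference_trios], lookup, mendel_lookup
        )
        labels = truth.all_pair_labels()
        for pair, r in lookup.items():
            if r.PI_HAT > clf.clone_pi:
                continue
            v = clf.predict_duo(r, duo_mi_snp(study.snp, *pair))
            lab = labels[pair]
            if lab == PO:
                assert v.status is not Verdict.REJECTED
            elif lab not in (PO, FS):
                assert v.status is not Verdict.SUPPORTED
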