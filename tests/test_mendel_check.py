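"""Mendelian-inconsistency engines against exhaustive enumeration oracles,
SSR exclusion checks, and the per-class stratification arithmetic."""

import itertools

import numpy as np
import pytest

from grapekin import (
    MISSING,
    SNPClass,
    SSRProfile,
    duo_compatible_ssr,
    duo_mi_snp,
    stratify_mi,
    trio_compatible_ssr,
    trio_mi_snp,
)
from grapekin.errors import DataError
from grapekin.mendel_check import mi_reduction_pct
from tests.test_genotype_io import make_matrix


def duo_oracle(g1, g2):
    """A duo conflict iff no gamete of one can be a gamete of the other."""
    gametes = {0: {0}, 1: {0, 1}, 2: {1}}
    return not (gametes[g1] & gametes[g2])


def trio_oracle(child, p1, p2):
    """Enumerate all gamete combinations of the proposed parents."""
    gametes = {0: {0}, 1: {0, 1}, 2: {1}}
    possible = {a + b for a in gametes[p1] for b in gametes[p2]}
    return child not in possible


class TestDuoSNP:
    def test_exhaustive_3x3_table(self):
        conflicts = [
            (a, b) for a, b in itertools.product((0, 1, 2), repeat=2) if duo_oracle(a, b)
        ]
        assert len(conflicts) == 2  # only the two opposite-homozygote cells
        for a, b in itertools.product((0, 1, 2), repeat=2):
            m = make_matrix([[a], [b]])
            got = duo_mi_snp(m, "S1", "S2").mi_total
            assert got == int(duo_oracle(a, b))

    def test_symmetry(self, noisy_study):
        study, _ = noisy_study
        a = duo_mi_snp(study.snp, "C01", "F004")
        b = duo_mi_snp(study.snp, "F004", "C01")
        assert a.mi_total == b.mi_total
        assert sorted(a.mi_loci) == sorted(b.mi_loci)

    def test_true_po_duos_clean_when_error_free(self, clean_study):
        study, truth = clean_study
        for child, parents in truth.parents.items():
            if parents:
                for p in set(parents):
                    assert duo_mi_snp(study.snp, child, p).mi_total == 0

    def test_unrelated_duo_mi_matches_analytic_expectation(self):
        """E[MI] per locus for two panmictic genotypes is 2 p^2 q^2."""
        from grapekin import SimulationConfig, simulate_founders

        cfg = SimulationConfig(n_founders=2, snp_loci=20000,
                               error_rate=0, missing_rate=0, seed=55)
        study = simulate_founders(cfg)
        p = study.snp_freqs
        e = 2 * p**2 * (1 - p) ** 2
        expect = e.sum()
        sigma = np.sqrt((e * (1 - e)).sum())
        got = duo_mi_snp(study.snp, "F001", "F002").mi_total
        assert abs(got - expect) <= 3 * sigma

    def test_zero_comparable_loci_error(self):
        m = make_matrix([[MISSING, 0], [1, MISSING]])
        with pytest.raises(DataError):
            duo_mi_snp(m, "S1", "S2")

    def test_mi_rate_uses_panel_denominator(self):
        m = make_matrix([[0, 2, MISSING], [2, 0, 1]])
        r = duo_mi_snp(m, "S1", "S2")
        assert r.mi_total == 2
        assert r.mi_rate == 2 / 3       # retained panel loci
        assert r.error_rate == 2 / 2    # per compared locus


class TestTrioSNP:
    def test_exhaustive_27_cell_table(self):
        for c, p1, p2 in itertools.product((0, 1, 2), repeat=3):
            m = make_matrix([[c], [p1], [p2]])
            got = trio_mi_snp(m, "S1", "S2", "S3").mi_total
            assert got == int(trio_oracle(c, p1, p2)), (c, p1, p2)
        n_conflicts = sum(
            trio_oracle(*t) for t in itertools.product((0, 1, 2), repeat=3)
        )
        # duo-style conflicts plus het child of double homozygotes
        assert n_conflicts == 12

    def test_parent_swap_invariance(self, noisy_study):
        study, _ = noisy_study
        a = trio_mi_snp(study.snp, "C01", "F001", "F003")
        b = trio_mi_snp(study.snp, "C01", "F003", "F001")
        assert a.mi_total == b.mi_total

    def test_planted_trio_clean_when_error_free(self, clean_study):
        study, truth = clean_study
        for child, p1, p2 in truth.reference_trios:
            assert trio_mi_snp(study.snp, child, p1, p2).mi_total == 0

    def test_het_child_of_double_homozygotes_inconsistent(self):
        m = make_matrix([[1], [0], [0]])
        assert trio_mi_snp(m, "S1", "S2", "S3").mi_total == 1


class TestSSRChecks:
    def test_duo_shared_allele(self):
        a = SSRProfile("a", {"L": (145, 149)})
        b = SSRProfile("b", {"L": (149, 153)})
        ok, mm = duo_compatible_ssr(a, b, max_mismatch=0)
        assert ok and mm == []

    def test_duo_no_shared_allele_mismatch(self):
        a = SSRProfile("a", {"L": (145, 149)})
        b = SSRProfile("b", {"L": (151, 153)})
        ok, mm = duo_compatible_ssr(a, b, max_mismatch=0)
        assert not ok and mm == ["L"]

    def test_unrelated_pairs_excluded_at_analytic_rate(self):
        """Frequency of zero-mismatch unrelated pairs matches the product of
        per-locus allele-sharing probabilities computed from the simulated
        frequencies (the SSR exclusion-power calculation)."""
        from grapekin import SimulationConfig, simulate_founders

        cfg = SimulationConfig(n_founders=400, ssr_loci=12, snp_loci=10,
                               error_rate=0, missing_rate=0, seed=9)
        study = simulate_founders(cfg)

        # per-locus P(no shared allele) for two random genotypes
        p_mismatch = []
        for freqs in study.ssr_freqs:
            f = np.array(list(freqs.values()))
            p_no_share = 0.0
            for i, fi in enumerate(f):
                for j, fj in enumerate(f):
                    gi = fi * fj  # ordered genotype (i, j)
                    others = 1 - fi - (fj if j != i else 0)
                    p_no_share += gi * others**2
            p_mismatch.append(p_no_share)
        p_all_share = float(np.prod(1 - np.array(p_mismatch)))

        ids = study.sample_ids
        rng = np.random.default_rng(1)
        n_pairs, share = 2000, 0
        for _ in range(n_pairs):
            i, j = rng.choice(len(ids), size=2, replace=False)
            ok, _ = duo_compatible_ssr(study.ssr[ids[i]], study.ssr[ids[j]], 0)
            share += ok
        sigma = np.sqrt(p_all_share * (1 - p_all_share) / n_pairs)
        assert share / n_pairs == pytest.approx(p_all_share, abs=max(4 * sigma, 0.02))
        assert share / n_pairs < 0.2  # the vast majority excluded

    def test_trio_bipartite_assignment(self):
        child = SSRProfile("c", {"L": (145, 151)})
        p1 = SSRProfile("p1", {"L": (145, 149)})
        p2 = SSRProfile("p2", {"L": (151, 153)})
        ok, _ = trio_compatible_ssr(child, p1, p2, 0)
        assert ok

    def test_trio_homozygote_needs_allele_in_both_parents(self):
        child = SSRProfile("c", {"L": (145, 145)})
        p1 = SSRProfile("p1", {"L": (145, 149)})
        p2 = SSRProfile("p2", {"L": (151, 153)})
        ok, mm = trio_compatible_ssr(child, p1, p2, 0)
        assert not ok and mm == ["L"]

    def test_trio_exhaustive_single_locus_configurations(self):
        """Every child/parent genotype combination over a 4-allele locus
        agrees with brute-force enumeration of allele-origin assignments."""
        alleles = [100, 102, 104, 106]
        genos = [tuple(sorted(g)) for g in
                 itertools.combinations_with_replacement(alleles, 2)]

        def oracle(cg, g1, g2):
            return any(
                set((a, b)) == set(cg) or (a, b) == cg or (b, a) == cg
                for a in g1 for b in g2
            )

        for cg, g1, g2 in itertools.product(genos, repeat=3):
            child = SSRProfile("c", {"L": cg})
            p1 = SSRProfile("p1", {"L": g1})
            p2 = SSRProfile("p2", {"L": g2})
            ok, _ = trio_compatible_ssr(child, p1, p2, 0)
            assert ok == oracle(cg, g1, g2), (cg, g1, g2)


class TestStratify:
    def _result(self, mi_loci, n_panel=100):
        from grapekin.mendel_check import MendelResult

        return MendelResult(
            unit=("a", "b"), kind="duo", mi_total=len(mi_loci),
            n_compared=n_panel, n_panel=n_panel, mi_loci=list(mi_loci),
        )

    def test_partition_of_counts(self):
        class_map = {
            "l1": SNPClass.ROBUST, "l2": SNPClass.DISTORTED,
            "l3": SNPClass.ONE_HOM_RARE_HWE, "l4": SNPClass.DISCARDED,
            "l5": SNPClass.ROBUST,
        }
        r = stratify_mi(self._result(["l1", "l2", "l3", "l4"]), class_map)
        assert r.mi_pruned_total == 3            # l4 is DISCARDED
        assert sum(r.per_class.values()) == r.mi_pruned_total
        assert r.mi_merged == 2                  # ROBUST + one-hom-rare
        assert r.mi_merged <= r.mi_total

    @pytest.mark.parametrize("full,pruned,expect", [
        (32, 9, 71.9),   # strongest pruning improvement
        (31, 19, 38.7),
        (25, 17, 32.0),
        (0, 0, 0.0),
    ])
    def test_reduction_percentage_rounding(self, full, pruned, expect):
        assert mi_reduction_pct(full, pruned) == expect

    def test_full_coverage_class_map_partitions_everything(self, clean_study):
        study, truth = clean_study
        from grapekin import classify_panel

        cm = classify_panel(study.snp)
        r = duo_mi_snp(study.snp, "F009", "F010")
        s = stratify_mi(r, cm)
        n_discarded_hits = sum(1 for l in r.mi_loci if cm[l] is SNPClass.DISCARDED)
        assert s.mi_pruned_total + n_discarded_hits == r.mi_total
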