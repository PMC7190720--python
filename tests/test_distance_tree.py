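"""Pseudo-sequence encoding, K2P distances, UPGMA against independent
oracles, bootstrap supports and Newick round-trips."""

import io
import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from grapekin import (
    MISSING,
    Locus,
    MarkerPanel,
    SNPGenotypeMatrix,
    bootstrap_support,
    encode_sequences,
    k2p_distance,
    upgma,
)
from grapekin.distance_tree import (
    decode_sequences,
    distance_matrix,
    _char_matrix,
    _k2p_matrix,
)
from grapekin.errors import DataError
from tests.test_genotype_io import make_matrix


class TestEncoding:
    def test_het_characters_alphabetical(self):
        panel = MarkerPanel([Locus("s1", "SNP", "G", "A"), Locus("s2", "SNP", "C", "T")])
        m = SNPGenotypeMatrix(["x"], [[1, 1]], panel)
        seq = encode_sequences(m)[0]
        assert seq.characters == "AGCT"

    def test_missing_becomes_nn_and_lengths(self):
        m = make_matrix([[0, MISSING, 2]])
        seq = encode_sequences(m)[0]
        assert seq.characters == "AANNGG"
        assert len(seq.characters) == 2 * m.n_loci

    def test_round_trip_decode(self, rng):
        m = make_matrix(rng.integers(-1, 3, size=(6, 40)))
        seqs = encode_sequences(m)
        np.testing.assert_array_equal(decode_sequences(seqs, m), m.calls)


class TestK2P:
    def test_identical_sequences_zero(self):
        assert k2p_distance("ACGT" * 10, "ACGT" * 10) == 0.0

    def test_closed_form_at_known_proportions(self):
        # 100 sites: 10 transitions (A<->G), 5 transversions (A<->C), 85 equal
        s1 = "A" * 100
        s2 = "G" * 10 + "C" * 5 + "A" * 85
        expect = -0.5 * math.log((1 - 2 * 0.1 - 0.05) * math.sqrt(1 - 2 * 0.05))
        assert k2p_distance(s1, s2) == pytest.approx(expect, rel=1e-12)

    def test_pairwise_deletion_leaves_identity(self):
        assert k2p_distance("ANAN", "ANNA") == 0.0

    def test_saturation_flagged_as_inf(self):
        assert k2p_distance("AAAA", "GAAA") < math.inf
        # P = 0.5, Q = 0 makes the log argument zero -> saturation flag
        assert k2p_distance("AAAA", "GGAA") == math.inf
        assert k2p_distance("AA", "GG") == math.inf

    def test_zero_comparable_sites_error(self):
        with pytest.raises(DataError):
            k2p_distance("NN", "AA")

    def test_vectorised_matrix_equals_pairwise_function(self, rng):
        m = make_matrix(rng.integers(-1, 3, size=(8, 200)))
        seqs = encode_sequences(m)
        d = _k2p_matrix(_char_matrix(m))  # raw: saturation still inf here
        for i in range(8):
            for j in range(i + 1, 8):
                ref = k2p_distance(seqs[i], seqs[j])
                if math.isinf(ref):
                    assert math.isinf(d[i, j])
                else:
                    assert d[i, j] == pytest.approx(ref, abs=1e-9)
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)
        # the public matrix replaces saturated entries by 1.1 x max finite
        _, pub = distance_matrix(m)
        assert np.isfinite(pub).all()


class TestUPGMA:
    def test_hand_executed_three_taxa(self):
        d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float)
        tree = upgma(d, ["a", "b", "c"])
        root = tree.root
        assert root.height == 3.0
        cherry = [c for c in root.children if not c.is_leaf][0]
        assert cherry.height == 1.0
        assert sorted(cherry.leaves()) == ["a", "b"]

    def test_two_taxa_cherry_at_half_distance(self):
        tree = upgma(np.array([[0.0, 4.0], [4.0, 0.0]]), ["a", "b"])
        assert tree.root.height == 2.0
        assert tree.to_newick() == "(a:2,b:2);"

    def test_matches_scipy_average_linkage_on_random_matrices(self, rng):
        """Independent oracle: cophenetic distances of scipy 'average' linkage."""
        for _ in range(20):
            n = 6
            x = rng.random((n, 4))
            d = squareform(np.round(
                np.abs(x[:, None, :] - x[None, :, :]).sum(-1), 6))
            tree = upgma(squareform(d), [f"t{i}" for i in range(n)])
            labels, coph = tree.cophenetic()
            z = linkage(d, method="average")
            ref = squareform(cophenet(z))
            # same leaf order: our labels sort as t0..t5
            np.testing.assert_allclose(coph, ref, atol=1e-9)

    def test_ultrametric_within_tolerance(self, rng):
        d = rng.random((10, 10))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tree = upgma(d, [f"t{i}" for i in range(10)])
        assert tree.is_ultrametric(1e-9)

    def test_clone_pair_coalesces_first(self, clean_study):
        study, truth = clean_study
        labels, d = distance_matrix(study.snp)
        tree = upgma(d, labels)
        clone, source = next(iter(truth.clones.items()))
        # the cherry containing the clone contains exactly {clone, source}
        for node in tree.internal_nodes():
            lv = set(node.leaves())
            if clone in lv and len(lv) == 2:
                assert lv == {clone, source}
                break
        else:
            pytest.fail("clone has no cherry")


@pytest.fixture(scope="module")
def family_matrix():
    from grapekin import SimulationConfig, simulate_study

    cfg = SimulationConfig(n_founders=8, snp_loci=800,
                           error_rate=0, missing_rate=0, seed=42)
    study, truth = simulate_study(cfg)
    return study, truth


class TestBootstrap:

    def test_separated_families_get_high_support(self, family_matrix):
        study, truth = family_matrix
        tree = bootstrap_support(study.snp, n_reps=60, seed=1)
        # the (F001, F001cl) clone cherry is unbreakable by locus resampling
        clone, source = next(iter(truth.clones.items()))
        for node in tree.internal_nodes():
            if set(node.leaves()) == {clone, source}:
                assert node.support >= 95
                break
        else:
            pytest.fail("clone cherry not in tree")

    def test_single_replicate_supports_binary_and_reproducible(self, family_matrix):
        study, _ = family_matrix
        sub = study.snp.subset_samples(study.snp.sample_ids[:8])
        a = bootstrap_support(sub, n_reps=1, seed=7)
        b = bootstrap_support(sub, n_reps=1, seed=7)
        sup_a = sorted(n.support for n in a.internal_nodes())
        sup_b = sorted(n.support for n in b.internal_nodes())
        assert sup_a == sup_b
        assert set(sup_a) <= {0.0, 100.0}

    def test_nreps_must_be_positive(self, family_matrix):
        with pytest.raises(DataError):
            bootstrap_support(family_matrix[0].snp, n_reps=0)

    def test_sample_order_invariance_of_topology(self, family_matrix):
        study, _ = family_matrix
        sub = study.snp.subset_samples(study.snp.sample_ids[:10])
        rev = sub.subset_samples(list(reversed(sub.sample_ids)))
        ta = upgma(*reversed(distance_matrix(sub)))
        tb = upgma(*reversed(distance_matrix(rev)))
        assert ta.clades() == tb.clades()


class TestNewick:
    def test_cherry_serialisation(self):
        tree = upgma(np.array([[0.0, 2.0], [2.0, 0.0]]), ["a", "b"])
        assert tree.to_newick() == "(a:1,b:1);"

    def test_round_trip_with_independent_reader(self, rng):
        import skbio

        d = rng.random((7, 7))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        labels = [f"t{i}" for i in range(7)]
        tree = upgma(d, labels)
        parsed = skbio.TreeNode.read(io.StringIO(tree.to_newick()))
        assert {t.name for t in parsed.tips()} == set(labels)
        # root-to-tip distances reproduce the merge heights to 1e-9
        for tip in parsed.tips():
            depth = 0.0
            node = tip
            while node.parent is not None:
                depth += node.length or 0.0
                node = node.parent
            assert depth == pytest.approx(tree.root.height, abs=1e-9)

    def test_supports_serialised_as_integer_labels(self, clean_study):
        study, _ = clean_study
        sub = study.snp.subset_samples(study.snp.sample_ids[:6]).subset_loci(
            study.snp.locus_ids[:300]
        )
        tree = bootstrap_support(sub, n_reps=10, seed=3)
        nwk = tree.to_newick()
        import re

        labels = re.findall(r"\)(\d+)", nwk)
        assert labels  # internal nodes carry integer supports
        assert all(0 <= int(x) <= 100 for x in labels)
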