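"""Signature derivation: DE pairs, SMGs, eMSGs, intersections, score correlations."""

import numpy as np
import pandas as pd
import pytest

from coexnet.containers import ExpressionMatrix, GeneSignature, ValidationError
from coexnet.signatures import (
    MethylationMatrix,
    MutationMatrix,
    SignaturePair,
    derive_emsg,
    derive_methylation_intersection,
    derive_smg,
    differential_expression,
    score_correlated_signature,
)


def _em(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix([f"g{i:03d}" for i in range(values.shape[0])],
                            [f"s{j:03d}" for j in range(values.shape[1])],
                            values, "normalized")


class TestDifferentialExpression:
    def test_planted_shift_recovered_and_direction(self, rng):
        v = rng.normal(0, 0.5, (200, 60))
        v[:30, :30] += 1.0   # 2-fold up in group 1
        v[30:60, :30] -= 1.0  # 2-fold down in group 1
        pair = differential_expression(_em(v), np.r_[np.ones(30), np.zeros(30)])
        up_hit = np.mean([f"g{i:03d}" in pair.up.genes for i in range(30)])
        dn_hit = np.mean([f"g{i:03d}" in pair.down.genes for i in range(30, 60)])
        assert up_hit >= 0.9 and dn_hit >= 0.9
        assert not (pair.up.genes & pair.down.genes)

    def test_null_false_discoveries_controlled(self, rng):
        false = 0
        for _ in range(50):
            v = rng.normal(0, 1, (300, 40))
            pair = differential_expression(_em(v), np.r_[np.ones(20), np.zeros(20)])
            false += len(pair.up) + len(pair.down)
        assert false / 50 <= 0.05 * 300

    def test_exact_fold_change_boundary_excluded(self):
        # strict inequality: a gene at exactly fold change 1.2 is excluded
        table = pd.DataFrame({"gene_id": ["exact", "above", "below"],
                              "log2fc": [np.log2(1.2), np.log2(1.2) + 1e-9,
                                         np.log2(1.2) - 1e-9],
                              "q_value": [1e-6, 1e-6, 1e-6]})
        pair = SignaturePair.from_table("b", table, fdr=0.05, fc=1.2)
        assert pair.up.genes == {"above"}

    def test_membership_consistent_with_strict_thresholds(self, rng):
        v = rng.normal(0, 0.6, (150, 40))
        v[:40, :20] += rng.uniform(0.1, 1.2, (40, 1))
        pair = differential_expression(_em(v), np.r_[np.ones(20), np.zeros(20)],
                                       fdr=0.05, fc=1.2)
        t = pair.table
        expect_up = set(t.loc[(t.q_value < 0.05) & (2.0 ** t.log2fc > 1.2), "gene_id"])
        expect_dn = set(t.loc[(t.q_value < 0.05) & (2.0 ** t.log2fc < 1 / 1.2), "gene_id"])
        assert pair.up.genes == expect_up and pair.down.genes == expect_dn

    def test_group_size_contract(self, rng):
        v = rng.normal(0, 1, (10, 10))
        with pytest.raises(ValidationError, match="3 samples"):
            differential_expression(_em(v), np.r_[np.ones(2), np.zeros(8)])

    def test_sample_order_invariance(self, rng):
        v = rng.normal(0, 1, (50, 30))
        v[:5, :15] += 1.5
        group = np.r_[np.ones(15), np.zeros(15)]
        x = _em(v)
        perm = rng.permutation(30)
        x2 = ExpressionMatrix(x.gene_ids, [x.sample_ids[j] for j in perm],
                              v[:, perm], "normalized")
        p1 = differential_expression(x, group)
        p2 = differential_expression(x2, group[perm])
        assert p1.up.genes == p2.up.genes and p1.down.genes == p2.down.genes

    def test_external_table_hook(self):
        table = pd.DataFrame({"gene_id": ["a", "b", "c"],
                              "log2fc": [1.0, -1.0, 0.1],
                              "q_value": [0.001, 0.001, 0.001]})
        pair = SignaturePair.from_table("ext", table, fdr=0.05, fc=1.2)
        assert pair.up.genes == {"a"} and pair.down.genes == {"b"}


class TestDeriveSmg:
    def test_planted_mutation_targets_recovered_driver_excluded(self, rng):
        n = 60
        v = rng.normal(0, 0.5, (120, n))
        carriers = np.zeros(n, int)
        carriers[:20] = 1
        # targets g010..g049 shifted ~1.5-fold in carriers; driver g000 also shifted
        for i in list(range(10, 50)) + [0]:
            v[i, carriers == 1] += np.log2(1.5)
        x = _em(v)
        mut = MutationMatrix(["g000"], x.sample_ids, carriers[None, :])
        pair = derive_smg(x, mut, "g000", fdr=0.05, fc=1.2)
        hit = np.mean([f"g{i:03d}" in pair.up.genes for i in range(10, 50)])
        assert hit >= 0.8
        assert "g000" not in pair.up.genes and "g000" not in pair.down.genes

    def test_too_few_mutants_skipped(self, rng):
        x = _em(rng.normal(0, 1, (10, 20)))
        mut = MutationMatrix(["g000"], x.sample_ids,
                             np.r_[np.ones(2), np.zeros(18)].astype(int)[None, :])
        assert derive_smg(x, mut, "g000") is None

    def test_all_mutant_degenerate(self, rng):
        x = _em(rng.normal(0, 1, (10, 12)))
        mut = MutationMatrix(["g000"], x.sample_ids, np.ones((1, 12), int))
        assert derive_smg(x, mut, "g000") is None


class TestDeriveEmsg:
    def test_perfect_anticorrelation_lands_in_cis_negative(self, rng):
        n = 50
        expr = rng.standard_normal((5, n))
        beta = 1 / (1 + np.exp(expr[0]))  # strictly decreasing in g000
        x = _em(expr)
        meth = MethylationMatrix(["p0"], x.sample_ids, beta[None, :], {"p0": "g000"})
        sigs = derive_emsg(x, meth)
        assert "g000" in sigs["cis-"].genes and not sigs["cis+"].genes

    def test_perfect_positive_correlation(self, rng):
        n = 40
        expr = rng.standard_normal((4, n))
        beta = 1 / (1 + np.exp(-expr[1]))
        x = _em(expr)
        meth = MethylationMatrix(["p0"], x.sample_ids, beta[None, :], {"p0": "g001"})
        sigs = derive_emsg(x, meth)
        assert "g001" in sigs["cis+"].genes

    def test_zero_variance_probe_skipped(self, rng):
        n = 30
        x = _em(rng.standard_normal((3, n)))
        beta = np.vstack([np.full(n, 0.5), 1 / (1 + np.exp(-x.values[0]))])
        meth = MethylationMatrix(["p0", "p1"], x.sample_ids, beta,
                                 {"p0": "g000", "p1": "g000"})
        sigs = derive_emsg(x, meth)  # must not raise
        assert "g000" in sigs["cis+"].genes

    def test_trans_pairs_tested_separately(self, rng):
        n = 60
        expr = rng.standard_normal((4, n))
        beta = 1 / (1 + np.exp(-expr[2]))  # probe tracks g002, annotated to g000
        x = _em(expr)
        meth = MethylationMatrix(["p0"], x.sample_ids, beta[None, :], {"p0": "g000"})
        sigs = derive_emsg(x, meth, trans_pairs=[("p0", "g002")])
        assert "g002" in sigs["trans+"].genes

    def test_min_shared_samples(self, rng):
        x = _em(rng.standard_normal((3, 5)))
        meth = MethylationMatrix(["p0"], x.sample_ids,
                                 np.full((1, 5), 0.4), {"p0": "g000"})
        with pytest.raises(ValidationError, match="10 shared"):
            derive_emsg(x, meth)


class TestIntersectionSignatures:
    def test_set_algebra(self):
        deg = SignaturePair(GeneSignature("u", frozenset("XY"), "up"),
                            GeneSignature("d", frozenset("ABC"), "down"), 0.05, 1.2)
        hyper = GeneSignature("hyper", frozenset("BCD"))
        hypo = GeneSignature("hypo", frozenset("XZ"))
        hemg, homg = derive_methylation_intersection(deg, hyper, hypo)
        assert hemg.genes == {"B", "C"} and homg.genes == {"X"}

    def test_disjoint_inputs_give_empty_signatures(self):
        deg = SignaturePair(GeneSignature("u", frozenset("A"), "up"),
                            GeneSignature("d", frozenset("B"), "down"), 0.05, 1.2)
        hemg, homg = derive_methylation_intersection(
            deg, GeneSignature("hyper", frozenset("Q")), GeneSignature("hypo", frozenset("R")))
        assert not hemg.genes and not homg.genes


class TestScoreCorrelatedSignature:
    def test_score_equal_to_gene_expression(self, rng):
        v = rng.standard_normal((20, 40))
        x = _em(v)
        pos, neg = score_correlated_signature(x, v[3], q_cut=0.05, name="stromal")
        assert "g003" in pos.genes

    def test_negated_module_mean_recovers_module_in_negative(self, rng):
        v = rng.standard_normal((30, 50))
        shared = rng.standard_normal(50)
        v[:10] = 2 * shared + 0.3 * rng.standard_normal((10, 50))
        x = _em(v)
        pos, neg = score_correlated_signature(x, -v[:10].mean(0), q_cut=0.05)
        hit = np.mean([f"g{i:03d}" in neg.genes for i in range(10)])
        assert hit >= 0.9

    def test_constant_score_rejected(self, rng):
        x = _em(rng.standard_normal((5, 20)))
        with pytest.raises(ValidationError, match="constant"):
            score_correlated_signature(x, np.ones(20))

    def test_null_score_calibrated(self, rng):
        sizes = []
        for _ in range(30):
            x = _em(rng.standard_normal((200, 40)))
            pos, neg = score_correlated_signature(x, rng.standard_normal(40))
            sizes.append(len(pos) + len(neg))
        assert np.mean(sizes) <= 0.05 * 200


def test_mutation_matrix_validation():
    with pytest.raises(ValidationError, match="binary"):
        MutationMatrix(["g1"], ["s1", "s2"], np.array([[0, 2]]))


def test_methylation_matrix_validation():
    with pytest.raises(ValidationError, match="0, 1"):
        MethylationMatrix(["p1"], ["s1"], np.array([[1.5]]), {})
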