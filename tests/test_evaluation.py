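"""Benchmark metrics, eQTL recall, CS-gene selection and sharing tables."""

import math

import numpy as np
import pandas as pd
import pytest

from gabc.evaluation import (
    EQTLPair,
    compare_roc_paired,
    delong_variance,
    eqtl_recall_at_k,
    interaction_overlap_summary,
    pr_curve_auprc,
    roc_auc,
    score_effect_correlation,
    select_cs_genes,
)
from gabc.io import CandidateEnhancer, GeneModel, GenomicRegion

from _oracles import (
    oracle_auprc,
    oracle_jackknife_delta_auc_var,
    oracle_overlap_counts,
    oracle_recall_at_k,
    oracle_roc_auc,
)


def preds(labels, scores, effects=None):
    df = pd.DataFrame(
        {
            "region_id": [f"r{i}" for i in range(len(labels))],
            "gene_id": "g",
            "score": scores,
            "label": labels,
        }
    )
    if effects is not None:
        df["effect_size"] = effects
    return df


class TestPRCurve:
    def test_perfect_separation(self):
        _, auprc = pr_curve_auprc(preds([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]))
        assert auprc == pytest.approx(1.0)

    def test_all_scores_equal_gives_prevalence(self):
        curve, auprc = pr_curve_auprc(preds([1, 0, 0, 0], [0.5] * 4))
        assert auprc == pytest.approx(0.25)

    def test_no_positives_is_error(self):
        with pytest.raises(ValueError, match="positive"):
            pr_curve_auprc(preds([0, 0], [0.1, 0.2]))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_threshold_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 10)
        if labels.sum() in (0, 10):
            labels[0] = 1 - labels[0]
        scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=10)  # force ties
        _, auprc = pr_curve_auprc(preds(labels, scores))
        assert auprc == pytest.approx(
            oracle_auprc(list(labels), list(scores)), rel=1e-12
        )


class TestROC:
    def test_perfect_and_error_cases(self):
        assert roc_auc(preds([1, 0], [0.9, 0.1])) == 1.0
        with pytest.raises(ValueError):
            roc_auc(preds([1, 1], [0.9, 0.1]))

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 4000)
        scores = rng.normal(size=4000)
        assert roc_auc(preds(labels, scores)) == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 12)
        if labels.sum() in (0, 12):
            labels[0] = 1 - labels[0]
        scores = rng.choice([0.2, 0.4, 0.6], size=12)
        assert roc_auc(preds(labels, scores)) == pytest.approx(
            oracle_roc_auc(list(labels), list(scores)), rel=1e-12
        )


class TestPairedROCComparison:
    def test_identical_scores_delta_zero_p_one(self):
        a = preds([1, 0, 1, 0], [0.9, 0.2, 0.7, 0.4])
        delta, p = compare_roc_paired(a, a.copy())
        assert delta == 0.0 and p == 1.0

    def test_monotone_transform_has_zero_delta(self):
        a = preds([1, 0, 1, 0, 1], [0.9, 0.2, 0.7, 0.4, 0.5])
        b = a.copy()
        b["score"] = np.exp(3 * b["score"])
        delta, _ = compare_roc_paired(a, b)
        assert delta == pytest.approx(0.0, abs=1e-15)

    def test_mismatched_universe_is_error(self):
        a = preds([1, 0], [0.9, 0.1])
        b = preds([0, 1], [0.9, 0.1])
        with pytest.raises(ValueError, match="universes"):
            compare_roc_paired(a, b)

    def test_variance_matches_jackknife(self):
        rng = np.random.default_rng(42)
        n = 120
        y = rng.integers(0, 2, n)
        base = rng.normal(0, 1, n) + 0.8 * y
        sa = base + rng.normal(0, 0.5, n)
        sb = base + rng.normal(0, 0.7, n)
        v_delong = delong_variance(preds(y, sa), preds(y, sb))
        v_jack = oracle_jackknife_delta_auc_var(list(y), list(sa), list(sb))
        assert v_delong == pytest.approx(v_jack, rel=0.05)


class TestScoreEffectCorrelation:
    def test_perfect_and_inverted(self):
        df = preds([1] * 5, [0.1, 0.2, 0.3, 0.4, 0.5],
                   effects=[1, 2, 3, 4, 5])
        assert score_effect_correlation(df) == pytest.approx(1.0)
        df["effect_size"] = [-1, -2, -3, -4, -5]
        assert score_effect_correlation(df) == pytest.approx(-1.0)

    def test_constant_scores_undefined(self):
        df = preds([1] * 4, [0.5] * 4, effects=[1, 2, 3, 4])
        with pytest.warns(UserWarning):
            assert math.isnan(score_effect_correlation(df))

    def test_matches_rank_formula(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=30)
        e = rng.normal(size=30)
        df = preds([1] * 30, s, effects=e)
        # direct rank formula (no ties with continuous draws)
        rs = pd.Series(s).rank().to_numpy()
        re = pd.Series(e).rank().to_numpy()
        d2 = ((rs - re) ** 2).sum()
        rho = 1 - 6 * d2 / (30 * (30**2 - 1))
        assert score_effect_correlation(df) == pytest.approx(rho, rel=1e-12)


def _enh(chrom, start, end, rid):
    return CandidateEnhancer(GenomicRegion(chrom, start, end, rid), {"c": 1.0})


class TestEqtlRecall:
    def _universe(self):
        enhancers = [
            _enh("chr1", 1000, 2000, "E1"),
            _enh("chr1", 5000, 6000, "E2"),
            _enh("chr1", 9000, 9500, "E3"),
        ]
        genes = [
            GeneModel("G1", "chr1", "+", (3000,)),
            GeneModel("G2", "chr1", "+", (8000,)),
        ]
        eqtls = [
            EQTLPair("chr1", 1500, "G1"),  # in E1, G1 in window
            EQTLPair("chr1", 5500, "G2"),  # in E2, G2 in window
            EQTLPair("chr1", 9100, "G1"),  # in E3, G1 in window
        ]
        interactions = pd.DataFrame(
            {
                "region_id": ["E1", "E2", "E3", "E1"],
                "gene_id": ["G1", "G2", "G1", "G2"],
                "score": [0.9, 0.6, 0.3, 0.1],
            }
        )
        return enhancers, genes, eqtls, interactions

    def test_partial_recall(self):
        enhancers, genes, eqtls, inter = self._universe()
        rec = eqtl_recall_at_k(inter, eqtls, enhancers, genes,
                               window=100_000, k=2)
        assert rec == pytest.approx(2 / 3)

    def test_k_at_least_n_includes_all_scored(self):
        enhancers, genes, eqtls, inter = self._universe()
        rec = eqtl_recall_at_k(inter, eqtls, enhancers, genes,
                               window=100_000, k=100)
        assert rec == pytest.approx(1.0)

    def test_monotone_in_k_and_oracle_match(self):
        rng = np.random.default_rng(17)
        enhancers = [
            _enh("chr1", i * 3000, i * 3000 + 1000, f"E{i}")
            for i in range(10)
        ]
        genes = [
            GeneModel(f"G{j}", "chr1", "+", (int(rng.integers(0, 30_000)),))
            for j in range(4)
        ]
        eqtls = [
            EQTLPair("chr1",
                     int(rng.integers(0, 30_000)),
                     f"G{int(rng.integers(4))}")
            for _ in range(5)
        ]
        rows = [
            {"region_id": e.region.region_id, "gene_id": g.gene_id,
             "score": float(rng.random())}
            for e in enhancers for g in genes
        ]
        inter = pd.DataFrame(rows)
        window = 40_000
        half = window / 2
        supported = set()
        for e in enhancers:
            for q in eqtls:
                g = next(x for x in genes if x.gene_id == q.gene_id)
                if (e.region.start <= q.position < e.region.end
                        and abs(e.region.midpoint - g.tss[0]) <= half):
                    supported.add((e.region.region_id, g.gene_id))
        prev = 0.0
        for k in (1, 3, 5, 10, 40):
            got = eqtl_recall_at_k(inter, eqtls, enhancers, genes, window, k)
            if math.isnan(got):
                continue
            want = oracle_recall_at_k(
                supported,
                list(zip(inter.region_id, inter.gene_id, inter.score)), k,
            )
            assert got == pytest.approx(want)
            assert got >= prev
            prev = got

    def test_empty_denominator_missing(self):
        enhancers, genes, _, inter = self._universe()
        with pytest.warns(UserWarning, match="no eQTL-supported"):
            rec = eqtl_recall_at_k(inter, [EQTLPair("chr9", 1, "G1")],
                                   enhancers, genes, 100_000, 5)
        assert math.isnan(rec)


class TestSelectCSGenes:
    def _expr(self):
        return pd.DataFrame(
            {
                f"ct{i}": col
                for i, col in enumerate(
                    np.array(
                        [
                            [10.0] + [0.1] * 7,   # specific to ct0
                            [5.0] * 8,            # constant -> never CS
                            [0.4] + [0.0] * 7,    # big z but TPM < 0.5
                        ]
                    ).T
                )
            },
            index=["g_spec", "g_const", "g_low"],
        )

    def test_rules(self):
        cs = select_cs_genes(self._expr())
        assert cs["ct0"] == {"g_spec"}
        assert all(not s for c, s in cs.items() if c != "ct0")
        # z for g_spec in ct0: (10 - 1.3375) / popsd ~ 2.65 >= 2
        x = self._expr().loc["g_spec"].to_numpy()
        z = (x[0] - x.mean()) / x.std()
        assert z == pytest.approx(2.6457, abs=1e-3)

    def test_threshold_monotonicity(self):
        expr = self._expr()
        loose = select_cs_genes(expr, z_threshold=1.0)
        tight = select_cs_genes(expr, z_threshold=2.5)
        for cond in expr.columns:
            assert tight[cond] <= loose[cond]

    def test_too_few_conditions(self):
        with pytest.raises(ValueError, match="3 conditions"):
            select_cs_genes(self._expr().iloc[:, :2])


class TestInteractionOverlap:
    def test_identical_sets(self):
        s = {("E1", "G1"), ("E2", "G1")}
        counts, per_cond = interaction_overlap_summary({"A": s, "B": set(s)})
        assert counts == {frozenset({"A", "B"}): 2}
        assert (per_cond["fraction_unique"] == 0).all()
        assert (per_cond["fraction_shared_all"] == 1).all()

    def test_disjoint_sets(self):
        counts, per_cond = interaction_overlap_summary(
            {"A": {("E1", "G1")}, "B": {("E2", "G2")}}
        )
        assert counts == {frozenset({"A"}): 1, frozenset({"B"}): 1}
        assert (per_cond["fraction_unique"] == 1).all()

    def test_matches_membership_oracle_and_sums_to_union(self):
        rng = np.random.default_rng(8)
        pairs = [(f"E{i}", f"G{j}") for i in range(6) for j in range(3)]
        sets = {
            c: {p for p in pairs if rng.random() < 0.5}
            for c in ("A", "B", "C")
        }
        counts, _ = interaction_overlap_summary(sets)
        assert counts == oracle_overlap_counts(sets)
        union = set().union(*sets.values())
        assert sum(counts.values()) == len(union)
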