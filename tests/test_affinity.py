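"""TRAP energies, region affinities and gene-level summarization."""

import math

import numpy as np
import pandas as pd
import pytest

from gabc.affinity import (
    BackgroundComposition,
    assign_regions,
    background_composition,
    default_ln_r0,
    gene_features,
    pfm_to_energy,
    summarize_gene_tf,
    trap_region_affinity,
)
from gabc.io import MotifPFM
from gabc.scoring import ScoringConfig
from gabc.synth import make_motif_fixture

from _oracles import (
    oracle_energy_matrix,
    oracle_summarize,
    oracle_trap_affinity,
)

UNIFORM = BackgroundComposition.uniform()


def uniform_pfm(name, width, count=10.0):
    return MotifPFM(name, np.full((width, 4), count))


class TestBackgroundComposition:
    def test_two_base_sequence_with_floor(self):
        bg = background_composition(["AACC"])
        assert bg.frequencies[0] == pytest.approx(0.5, abs=1e-3)
        assert bg.frequencies[1] == pytest.approx(0.5, abs=1e-3)
        assert 0 < bg.frequencies[2] <= 1e-4  # floored, renormalized
        assert sum(bg.frequencies) == pytest.approx(1.0)

    def test_uniform_sequence(self):
        bg = background_composition(["ACGT", "TGCA"])
        assert bg.frequencies == pytest.approx((0.25,) * 4)

    def test_n_bases_skipped(self):
        bg = background_composition(["AANN"])
        assert bg.frequencies[0] == pytest.approx(1.0, abs=1e-3)

    def test_no_usable_bases_is_error(self):
        with pytest.raises(ValueError, match="usable"):
            background_composition(["NNNN"])


class TestPfmToEnergy:
    def test_uniform_column_uniform_background_all_zero(self):
        em = pfm_to_energy(uniform_pfm("U", 4), UNIFORM)
        assert np.allclose(em.energies, 0.0)

    def test_consensus_base_always_zero(self):
        rng = np.random.default_rng(3)
        pfm = MotifPFM("R", rng.integers(0, 40, size=(6, 4)).astype(float) + 1)
        em = pfm_to_energy(pfm, UNIFORM)
        for p in range(6):
            bmax = int(np.argmax(pfm.counts[p] + 1.0))
            assert em.energies[p, bmax] == 0.0
        assert (em.energies >= 0).all()

    def test_matches_hand_computed_formula(self):
        counts = [[8, 2, 0, 2], [1, 1, 9, 1], [3, 3, 3, 3]]
        bg = BackgroundComposition((0.3, 0.2, 0.2, 0.3))
        em = pfm_to_energy(MotifPFM("T", np.array(counts, float)), bg)
        expected = oracle_energy_matrix(counts, bg.frequencies)
        assert np.allclose(em.energies, expected, atol=1e-12)


class TestTrapRegionAffinity:
    def test_sequence_shorter_than_motif(self):
        em = pfm_to_energy(uniform_pfm("U", 10), UNIFORM)
        assert trap_region_affinity(em, "ACGTACG") == 0.0

    def test_zero_energy_closed_form(self):
        # all energies 0 -> every site contributes R0 / (1 + R0)
        w, length = 10, 60
        em = pfm_to_energy(uniform_pfm("U", w), UNIFORM)
        r0 = math.exp(default_ln_r0(w))
        n_sites = 2 * (length - w + 1)
        seq = "ACGT" * 15
        expected = n_sites * r0 / (1 + r0)
        assert trap_region_affinity(em, seq) == pytest.approx(
            expected, rel=1e-12
        )

    def test_planted_consensus_outscores_background(self):
        fx = make_motif_fixture(seed=11, width=8, n_planted_sites=3)
        em = pfm_to_energy(fx["pfm"], UNIFORM)
        assert trap_region_affinity(
            em, fx["planted_sequence"]
        ) > trap_region_affinity(em, fx["background_sequence"])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_site_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pfm = MotifPFM(
            "R", rng.integers(0, 30, size=(5, 4)).astype(float) + 0.5
        )
        bg = background_composition(
            ["".join(rng.choice(list("ACGT"), 200))]
        )
        em = pfm_to_energy(pfm, bg)
        seq = "".join(rng.choice(list("ACGTN"), size=80, p=[0.24] * 4 + [0.04]))
        expected = oracle_trap_affinity(
            [list(row) for row in em.energies], em.r0, seq
        )
        assert trap_region_affinity(em, seq) == pytest.approx(
            expected, rel=1e-12
        )

    def test_motif_length_normalization_closed_form(self):
        # uniform motifs differ only through R0(W) and site counts
        seq = "ACGT" * 30
        length = len(seq)
        for w in (6, 12):
            em = pfm_to_energy(uniform_pfm(f"U{w}", w), UNIFORM)
            r0 = math.exp(default_ln_r0(w))
            per_length = trap_region_affinity(em, seq) / w
            closed = 2 * (length - w + 1) * r0 / (1 + r0) / w
            assert per_length == pytest.approx(closed, rel=1e-12)


def _assigned_frame(rng, n=3):
    return pd.DataFrame(
        {
            "region_id": [f"E{i}" for i in range(n)],
            "activity": rng.gamma(2, 10, n).round(3),
            "adapted_activity": rng.gamma(2, 5, n).round(3),
            "contact": rng.gamma(2, 3, n).round(3),
            "distance": [1000.0, 5000.0, 40_000.0][:n],
        }
    )


class TestSummarizeGeneTF:
    @pytest.mark.parametrize("mode", ["window", "abc", "gabc"])
    def test_matches_brute_force(self, mode):
        rng = np.random.default_rng(21)
        assigned = _assigned_frame(rng)
        affinities = pd.DataFrame(
            rng.gamma(2, 1, size=(3, 2)).round(4),
            index=assigned["region_id"],
            columns=["TF1", "TF2"],
        )
        widths = {"TF1": 8, "TF2": 12}
        cfg = ScoringConfig()
        c_max = 7.5
        rec = summarize_gene_tf(
            "G1", "ct1", assigned, affinities, widths, mode, cfg, c_max=c_max
        )
        for tf in widths:
            expected = oracle_summarize(
                assigned.to_dict("records"),
                dict(zip(affinities.index, affinities[tf])),
                widths[tf], mode, cfg.decay_d0, cfg.tss_proximal_bp, c_max,
            )
            assert rec.affinities[tf] == pytest.approx(expected, rel=1e-12)

    def test_decay_factor_values(self):
        cfg = ScoringConfig()
        affinities = pd.DataFrame({"TF": [8.0]}, index=["E0"])
        for dist, factor in [(0.0, 1.0), (5000.0, math.exp(-1))]:
            assigned = pd.DataFrame(
                {"region_id": ["E0"], "activity": [2.0],
                 "adapted_activity": [1.0], "contact": [1.0],
                 "distance": [dist]}
            )
            rec = summarize_gene_tf("G", "c", assigned, affinities,
                                    {"TF": 8}, "window", cfg)
            assert rec.affinities["TF"] == pytest.approx(
                8.0 / 8 * 2.0 * factor, rel=1e-12
            )

    def test_abc_mode_contact_ratio(self):
        # distal region, C_rg=2, C_max=4 -> multiplier A_r * 0.5
        cfg = ScoringConfig()
        assigned = pd.DataFrame(
            {"region_id": ["E0"], "activity": [3.0],
             "adapted_activity": [9.9], "contact": [2.0],
             "distance": [50_000.0]}
        )
        affinities = pd.DataFrame({"TF": [4.0]}, index=["E0"])
        rec = summarize_gene_tf("G", "c", assigned, affinities, {"TF": 4},
                                "abc", cfg, c_max=4.0)
        assert rec.affinities["TF"] == pytest.approx(4.0 / 4 * 3.0 * 0.5)

    def test_modes_agree_on_proximal_regions(self):
        cfg = ScoringConfig()
        assigned = pd.DataFrame(
            {"region_id": ["E0", "E1"], "activity": [3.0, 1.5],
             "adapted_activity": [0.7, 0.2], "contact": [2.0, 1.0],
             "distance": [100.0, 2500.0]}
        )
        affinities = pd.DataFrame({"TF": [4.0, 2.0]},
                                  index=assigned["region_id"])
        recs = {
            m: summarize_gene_tf("G", "c", assigned, affinities, {"TF": 6},
                                 m, cfg, c_max=3.0)
            for m in ("abc", "gabc", "window")
        }
        assert recs["abc"].affinities["TF"] == pytest.approx(
            recs["gabc"].affinities["TF"], rel=1e-12
        )
        assert recs["abc"].affinities["TF"] == pytest.approx(
            recs["window"].affinities["TF"], rel=1e-12
        )

    def test_summarization_linearity(self):
        rng = np.random.default_rng(5)
        assigned = _assigned_frame(rng)
        affinities = pd.DataFrame(
            rng.gamma(2, 1, size=(3, 1)), index=assigned["region_id"],
            columns=["TF"],
        )
        cfg = ScoringConfig()
        base = summarize_gene_tf("G", "c", assigned, affinities, {"TF": 8},
                                 "gabc", cfg)
        scaled = summarize_gene_tf("G", "c", assigned, affinities * 4.0,
                                   {"TF": 8}, "gabc", cfg)
        assert scaled.affinities["TF"] == pytest.approx(
            4.0 * base.affinities["TF"], rel=1e-12
        )

    def test_abc_mode_requires_positive_cmax(self):
        cfg = ScoringConfig()
        assigned = pd.DataFrame(
            {"region_id": ["E0"], "activity": [1.0],
             "adapted_activity": [0.5], "contact": [1.0],
             "distance": [50_000.0]}
        )
        affinities = pd.DataFrame({"TF": [1.0]}, index=["E0"])
        with pytest.raises(ValueError, match="C_max"):
            summarize_gene_tf("G", "c", assigned, affinities, {"TF": 4},
                              "abc", cfg, c_max=0.0)


class TestAssignRegions:
    def test_called_union_proximal(self):
        cfg = ScoringConfig(cutoff=0.02)
        scored = pd.DataFrame(
            {"region_id": ["a", "b", "c"], "gene_id": "G", "condition": "c",
             "score": [0.5, 0.001, 0.001],
             "distance": [10_000.0, 1_000.0, 10_000.0]}
        )
        got = assign_regions(scored, "gabc", cfg)
        assert got["region_id"].tolist() == ["a", "b"]
        assert assign_regions(scored, "window", cfg)["region_id"].tolist() == [
            "a", "b", "c"
        ]


class TestGeneFeatures:
    def test_counts_and_means(self):
        assigned = pd.DataFrame(
            {"region_id": ["a", "b"], "distance": [1000.0, 3000.0]}
        )
        lengths = {"a": 500, "b": 1500}
        assert gene_features(assigned, lengths) == (2, 2000.0, 1000.0)

    def test_single_region(self):
        assigned = pd.DataFrame({"region_id": ["a"], "distance": [700.0]})
        assert gene_features(assigned, {"a": 350}) == (1, 700.0, 350.0)

    def test_zero_regions_missing_means(self):
        n, d, ln = gene_features(
            pd.DataFrame({"region_id": [], "distance": []}), {}
        )
        assert n == 0 and math.isnan(d) and math.isnan(ln)
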