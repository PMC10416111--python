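"""QC cascade: HWE exact test, variant/sample filters, relatedness,
harmonization, sumstats hygiene, genotype PCs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats

from admetagrs.qc import (
    genotype_pca,
    harmonize,
    hwe_exact,
    pi_hat,
    qc_cascade,
    relatedness_filter,
    sample_qc,
    sumstats_qc,
    variant_qc,
)
from conftest import make_geno, make_sumstats


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Brute-force exact HWE p: enumerate every heterozygote count of the
    right parity, with probabilities from the conditional distribution
    given allele counts computed via log-factorials."""
    from math import lgamma, exp

    n = n_AA + n_Aa + n_aa
    n_rare = 2 * min(n_AA, n_aa) + n_Aa

    def log_prob(h):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        # P(h | n, n_rare) ∝ n! / (hom_r! het! hom_c!) * 2^het
        return (
            lgamma(n + 1)
            - lgamma(rare_hom + 1)
            - lgamma(h + 1)
            - lgamma(common_hom + 1)
            + h * np.log(2)
        )

    hets = list(range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2))
    lps = np.array([log_prob(h) for h in hets])
    probs = np.exp(lps - lps.max())
    probs /= probs.sum()
    p_obs = probs[hets.index(n_Aa)]
    return probs[probs <= p_obs * (1 + 1e-12)].sum()


class TestHweExact:
    def test_single_het_is_mode(self):
        assert hwe_exact(0, 1, 0) == 1.0

    def test_monomorphic(self):
        assert hwe_exact(100, 0, 0) == 1.0

    def test_known_table_vs_enumeration(self):
        p = hwe_exact(57, 14, 50)
        assert abs(p - hwe_enumeration_oracle(57, 14, 50)) < 1e-12

    @pytest.mark.parametrize("seed", range(8))
    def test_random_tables_match_oracle(self, seed):
        """Exact test equals full enumeration on random tables with n <= 200."""
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 200))
        n_AA = int(r.integers(0, n + 1))
        n_Aa = int(r.integers(0, n - n_AA + 1))
        n_aa = n - n_AA - n_Aa
        assert abs(hwe_exact(n_AA, n_Aa, n_aa) - hwe_enumeration_oracle(n_AA, n_Aa, n_aa)) < 1e-12

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact(0, 0, 0)

    @given(
        n_AA=st.integers(0, 120),
        n_Aa=st.integers(0, 120),
        n_aa=st.integers(0, 120),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_property_matches_oracle_everywhere(self, n_AA, n_Aa, n_aa):
        """hwe_exact equals the enumeration oracle on every table."""
        assume(n_AA + n_Aa + n_aa > 0)
        p = hwe_exact(n_AA, n_Aa, n_aa)
        assert 0.0 < p <= 1.0
        assert abs(p - hwe_enumeration_oracle(n_AA, n_Aa, n_aa)) < 1e-12


class TestVariantQc:
    def test_maf_arithmetic_retention(self):
        """(AA,Aa,aa)=(50,50,0) in 100 samples: MAF 0.25 passes the filter."""
        col = np.array([0.0] * 50 + [1.0] * 50)
        g = make_geno(col[:, None])
        g2, rep = variant_qc(g)
        assert g2.n_variants == 1 and rep.removed["maf"] == 0

    def test_low_maf_removed_and_attributed(self):
        col = np.array([1.0] * 8 + [0.0] * 92)  # MAF 0.04
        g = make_geno(col[:, None])
        with pytest.raises(ValueError, match="empty panel"):
            variant_qc(g)
        # alongside a clean variant, the report attributes the removal to MAF
        clean = np.tile([0.0, 1.0, 2.0, 1.0], 25)
        g = make_geno(np.column_stack([col, clean]))
        g2, rep = variant_qc(g)
        assert g2.n_variants == 1 and rep.removed["maf"] == 1

    def test_fixture_counts_match_hand_enumeration(self, rng):
        """A panel built to trip each filter a known number of times."""
        n = 200
        cols, expect = [], {"missing": 0, "maf": 0, "hwe": 0}
        base = rng.integers(0, 3, size=(n, 4)).astype(float)  # balanced, clean
        for j in range(4):
            cols.append(np.tile([0.0, 1.0, 2.0, 1.0], 50))
        # 2 variants with >5% missing
        for _ in range(2):
            c = np.tile([0.0, 1.0, 2.0, 1.0], 50)
            c[: int(0.2 * n)] = np.nan
            cols.append(c)
            expect["missing"] += 1
        # 3 variants with MAF < 0.05
        for _ in range(3):
            c = np.zeros(n)
            c[:4] = 1.0
            cols.append(c)
            expect["maf"] += 1
        # 1 variant grossly out of HWE: all hets
        cols.append(np.ones(n))
        expect["hwe"] += 1
        g = make_geno(np.column_stack(cols))
        g2, rep = variant_qc(g)
        assert rep.removed == expect
        assert g2.n_variants == 4
        rep.check()


class TestSampleQc:
    def test_high_missingness_sample_removed(self):
        dos = np.tile([0.0, 1.0, 2.0, 1.0], (10, 25)).astype(float)
        dos[0, :3] = np.nan  # 3% missing
        g = make_geno(dos)
        g2, rep = sample_qc(g)
        assert rep.removed["call_rate"] == 1 and g2.n_samples == 9

    def test_degenerate_sd_means_no_outliers(self):
        dos = np.tile([0.0, 1.0, 2.0, 1.0], (10, 25)).astype(float)
        g = make_geno(dos)
        _, rep = sample_qc(g)
        assert rep.removed["heterozygosity"] == 0

    def test_planted_full_het_outlier_removed(self, rng):
        dos = rng.binomial(2, 0.3, size=(200, 120)).astype(float)
        dos[7] = 1.0  # forced 100% heterozygosity
        g = make_geno(dos)
        g2, rep = sample_qc(g)
        assert rep.removed["heterozygosity"] >= 1
        assert "S7" not in set(g2.samples["sample_id"])


class TestRelatedness:
    def test_duplicate_sample_flagged(self, rng):
        dos = rng.binomial(2, rng.uniform(0.2, 0.5, size=800), size=(60, 800)).astype(float)
        dos[1] = dos[0]
        g = make_geno(dos)
        rel = pi_hat(g)
        assert rel[0, 1] > 0.9
        g2, rep = relatedness_filter(g)
        assert rep.removed["related"] >= 1
        ids = set(g2.samples["sample_id"])
        assert not {"S0", "S1"} <= ids

    def test_unrelated_mostly_untouched(self, rng):
        dos = rng.binomial(2, rng.uniform(0.2, 0.5, size=1000), size=(100, 1000)).astype(float)
        _, rep = relatedness_filter(make_geno(dos))
        assert rep.removed["related"] <= 1

    def test_parent_offspring_pihat_and_flag(self, rng):
        """Mendelian transmission: offspring shares one allele with each
        parent, giving PI-HAT ~ 0.5."""
        m = 1500
        p = rng.uniform(0.2, 0.5, size=m)

        def hap(n):
            return (rng.uniform(size=(n, m)) < p).astype(float)

        mother_h, father_h = (hap(1), hap(1)), (hap(1), hap(1))
        pick_m = rng.integers(0, 2, size=(1, m))
        pick_f = rng.integers(0, 2, size=(1, m))
        child = np.where(pick_m, mother_h[1], mother_h[0]) + np.where(
            pick_f, father_h[1], father_h[0]
        )
        mother = mother_h[0] + mother_h[1]
        father = father_h[0] + father_h[1]
        # enough unrelated background for accurate allele frequencies;
        # the moment estimator is biased when freqs come from a handful
        # of samples
        unrelated = hap(200) + hap(200)
        g = make_geno(np.vstack([mother, father, child, unrelated]))
        rel = pi_hat(g)
        assert abs(rel[0, 2] - 0.5) < 0.05 and abs(rel[1, 2] - 0.5) < 0.05
        _, rep = relatedness_filter(g)
        assert rep.removed["related"] >= 1


class TestHarmonize:
    def _panel(self):
        return make_geno(np.zeros((3, 3)), a1=["G", "G", "G"], a2=["A", "A", "A"])

    def test_allele_swap_negates_beta(self):
        ss = make_sumstats([0.2], [0.01], snps=["rs0"], a1=["A"], a2=["G"])
        out, rep = harmonize(self._panel(), ss)
        assert out.table["BETA"].iloc[0] == pytest.approx(-0.2)
        assert rep.params["recoded"] == 1

    def test_strand_flip_keeps_beta(self):
        ss = make_sumstats([0.2], [0.01], snps=["rs1"], a1=["C"], a2=["T"])
        out, rep = harmonize(self._panel(), ss)
        assert out.table["BETA"].iloc[0] == pytest.approx(0.2)
        assert rep.params["strand_flipped"] == 1

    def test_flip_and_swap_negates(self):
        ss = make_sumstats([0.2], [0.01], snps=["rs1"], a1=["T"], a2=["C"])
        out, rep = harmonize(self._panel(), ss)
        assert out.table["BETA"].iloc[0] == pytest.approx(-0.2)
        assert rep.params["flipped_and_recoded"] == 1

    def test_mismatch_dropped_and_counted(self):
        ss = make_sumstats([0.2], [0.01], snps=["rs2"], a1=["G"], a2=["C"])
        out, rep = harmonize(self._panel(), ss)
        assert len(out) == 0 and rep.removed["allele_mismatch"] == 1

    def test_eaf_flipped_with_alleles(self):
        ss = make_sumstats([0.2], [0.01], snps=["rs0"], a1=["A"], a2=["G"], eaf=[0.3])
        out, _ = harmonize(self._panel(), ss)
        assert out.table["EAF"].iloc[0] == pytest.approx(0.7)


class TestSumstatsQc:
    def test_ambiguous_snp_removed(self):
        ss = make_sumstats([0.1], [0.5], a1=["A"], a2=["T"], eaf=[0.3])
        out, rep = sumstats_qc(ss)
        assert len(out) == 0 and rep.removed["ambiguous"] == 1

    def test_duplicates_both_removed(self):
        ss = make_sumstats([0.1, 0.2], [0.5, 0.6], snps=["rs1", "rs1"],
                           a1=["A", "A"], a2=["G", "G"], eaf=[0.3, 0.3])
        out, rep = sumstats_qc(ss)
        assert len(out) == 0 and rep.removed["duplicate_id"] == 2

    def test_fixture_counts_match_hand_enumeration(self):
        """10 rows: 1 indel, 2 duplicate copies, 1 A/T, 1 C/G, 1 low-MAF,
        4 clean."""
        ss = make_sumstats(
            [0.1] * 10,
            [0.5] * 10,
            snps=["rs0", "rs1", "rs1", "rs2", "rs3", "rs4", "rs5", "rs6", "rs7", "rs8"],
            a1=["AT", "A", "A", "A", "C", "A", "A", "A", "A", "A"],
            a2=["G", "G", "G", "T", "G", "G", "G", "G", "G", "G"],
            eaf=[0.3, 0.3, 0.3, 0.3, 0.3, 0.005, 0.3, 0.3, 0.3, 0.3],
        )
        out, rep = sumstats_qc(ss)
        assert rep.removed == {
            "indel_or_nonacgt": 1, "duplicate_id": 2, "ambiguous": 2, "low_maf": 1,
        }
        assert len(out) == 4

    def test_maf_rule_skipped_without_eaf(self):
        ss = make_sumstats([0.1], [0.5], a1=["A"], a2=["G"])
        out, rep = sumstats_qc(ss)
        assert len(out) == 1 and rep.params["maf_rule_skipped_no_eaf"]


class TestGenotypePca:
    def test_two_subpopulations_separate_on_pc1(self, rng):
        m = 400
        f1 = rng.uniform(0.1, 0.9, size=m)
        shift = np.clip(f1 + rng.choice([-0.3, 0.3], size=m), 0.05, 0.95)
        a = rng.binomial(2, f1, size=(100, m)).astype(float)
        b = rng.binomial(2, shift, size=(100, m)).astype(float)
        g = make_geno(np.vstack([a, b]))
        pcs = genotype_pca(g, n_pcs=2)
        labels = np.r_[np.zeros(100), np.ones(100)]
        r = np.corrcoef(pcs[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_permutation_equivariance(self, rng):
        dos = rng.binomial(2, 0.4, size=(30, 50)).astype(float)
        g = make_geno(dos)
        pcs = genotype_pca(g, n_pcs=3)
        perm = rng.permutation(30)
        pcs_p = genotype_pca(g.subset_samples(perm), n_pcs=3)
        np.testing.assert_allclose(pcs[perm], pcs_p, atol=1e-8)

    def test_rank_deficiency_rejected(self, rng):
        dos = rng.binomial(2, 0.4, size=(4, 50)).astype(float)
        with pytest.raises(ValueError, match="rank"):
            genotype_pca(make_geno(dos), n_pcs=10)


class TestCascade:
    def test_idempotent(self, rng):
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, size=300), size=(80, 300)).astype(float)
        dos[rng.uniform(size=dos.shape) < 0.01] = np.nan
        g = make_geno(dos)
        g1, reports1 = qc_cascade(g)
        g2, reports2 = qc_cascade(g1)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        assert [r.step for r in reports1] == [
            "variant_qc", "sample_qc", "variant_qc_repass", "relatedness_filter",
        ]
        for r in reports2:
            assert sum(r.removed.values()) == 0
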