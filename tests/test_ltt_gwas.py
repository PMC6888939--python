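"""LTT phenotype construction, SNP QC (incl. exact HWE), association scan
and effect-size decomposition."""

import math

import numpy as np
import pandas as pd
import pytest

from tractsel.genome_model import LTTRecord, ValidationError
from tractsel.ltt_gwas import (
    bonferroni_threshold,
    build_phenotype,
    effect_size,
    gwas_scan,
    hwe_exact_test,
    phenotype_vector,
    qc_filter,
)

from conftest import make_matrix


class TestBuildPhenotype:
    def test_max_rise_and_tolerant_class(self):
        rec = LTTRecord("S1", "FZR", baseline=5.0, g20=5.5, g40=6.9, g60=6.2)
        (p,) = build_phenotype([rec])
        assert p.max_rise == pytest.approx(1.9)
        assert p.ltt_class == "tolerant"
        assert p.score == 2

    @pytest.mark.parametrize(
        "rise,cls,score",
        [(1.05, "intolerant", 0), (1.3, "intermediate", 1), (1.9, "tolerant", 2),
         (1.1, "intermediate", 1), (1.7, "tolerant", 2)],
    )
    def test_threshold_classes(self, rise, cls, score):
        # baseline 1.0 keeps the float difference g40 - baseline >= rise
        rec = LTTRecord("S", "CS", baseline=1.0, g40=1.0 + rise)
        (p,) = build_phenotype([rec])
        assert (p.ltt_class, p.score) == (cls, score)

    def test_all_below_baseline_gives_negative_rise_intolerant(self):
        rec = LTTRecord("S", "CS", baseline=5.0, g20=4.5, g40=4.8, g60=4.2)
        (p,) = build_phenotype([rec])
        assert p.max_rise == pytest.approx(-0.2)
        assert p.ltt_class == "intolerant"

    def test_missing_post_measurements_ignored_in_max(self):
        rec = LTTRecord("S", "CS", baseline=5.0, g20=None, g40=6.0, g60=None)
        (p,) = build_phenotype([rec])
        assert p.max_rise == pytest.approx(1.0)


def hwe_enumeration_oracle(n_het, n_hom_minor, n_hom_major):
    """Exact-integer enumeration of the conditional het-count distribution."""
    from fractions import Fraction

    n = n_het + n_hom_minor + n_hom_major
    minor = 2 * n_hom_minor + n_het
    if minor > n:
        minor = 2 * n - minor

    def weight(h):
        hom_min = (minor - h) // 2
        hom_maj = n - h - hom_min
        if hom_min < 0 or hom_maj < 0:
            return Fraction(0)
        # P(h) proportional to n! / (hom_min! h! hom_maj!) * 2^h
        return Fraction(
            math.factorial(n) * 2**h,
            math.factorial(hom_min) * math.factorial(h) * math.factorial(hom_maj),
        )

    hets = [h for h in range(minor % 2, minor + 1, 2)]
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= obs) / total)


class TestHWEExactTest:
    @pytest.mark.parametrize(
        "het,hom1,hom2",
        [(10, 5, 85), (57, 14, 50), (0, 10, 90), (20, 0, 80), (1, 0, 0), (3, 2, 3)],
    )
    def test_matches_integer_enumeration_oracle(self, het, hom1, hom2):
        assert hwe_exact_test(het, hom1, hom2) == pytest.approx(
            hwe_enumeration_oracle(het, hom1, hom2), rel=1e-9
        )

    def test_equilibrium_counts_not_rejected(self):
        # 2pq*n het with p=0.5, n=100: the modal configuration
        assert hwe_exact_test(50, 25, 25) > 0.5

    def test_extreme_heterozygote_deficit_rejected(self):
        assert hwe_exact_test(0, 50, 50) < 1e-20


class TestQCFilter:
    def test_low_maf_snp_removed(self, rng):
        H = rng.integers(0, 2, size=(40, 3)).astype(np.uint8)
        H[:, 1] = 0
        H[:2, 1] = 1  # MAF 0.05 < 0.1
        m = make_matrix(H)
        kept, report = qc_filter(m, maf_min=0.1)
        assert report["n_removed_maf"] >= 1
        assert 2000 not in set(kept.snps["pos"])

    def test_monomorphic_snp_removed(self, rng):
        H = rng.integers(0, 2, size=(40, 2)).astype(np.uint8)
        H[:, 0] = 1
        m = make_matrix(H)
        kept, report = qc_filter(m)
        assert 1000 not in set(kept.snps["pos"])

    def test_hwe_violating_snp_removed(self):
        # 20 hom-ref + 20 hom-alt, no hets: gross HWE violation
        H = np.zeros((80, 2), dtype=np.uint8)
        H[:40, 0] = 1
        H[::2, 1] = 1  # second SNP: all hets -> also extreme, but MAF 0.5
        m = make_matrix(H)
        kept, report = qc_filter(m, hwe_p_min=1e-8)
        assert 1000 not in set(kept.snps["pos"])

    def test_clean_panel_unchanged_and_idempotent(self, rng):
        H = (rng.random((60, 10)) < rng.uniform(0.3, 0.7, size=10)).astype(np.uint8)
        m = make_matrix(H)
        kept, report = qc_filter(m)
        assert report["n_kept"] == report["n_input"]
        again, report2 = qc_filter(kept)
        assert report2["n_kept"] == report["n_kept"]
        assert again == kept


def _signal_setup(rng, n=80, L=40, causal=7):
    freqs = rng.uniform(0.25, 0.75, size=L)
    H = (rng.random((2 * n, L)) < freqs).astype(np.uint8)
    m = make_matrix(H)
    dosage = m.dosage().astype(float)
    return m, dosage


class TestGwasScan:
    def test_perfect_signal_snp_has_minimal_p_and_unit_beta(self, rng):
        m, dosage = _signal_setup(rng)
        y = pd.Series(dosage[:, 7], index=m.samples)
        scan = gwas_scan(y, m)
        best = scan.loc[scan["p"].idxmin()]
        assert best["index"] == 7
        assert best["beta"] == pytest.approx(1.0)

    def test_permuted_phenotype_p_values_uniform(self):
        rng = np.random.default_rng(17)
        n, L = 150, 2500
        freqs = rng.uniform(0.2, 0.8, size=L)
        H = (rng.random((2 * n, L)) < freqs).astype(np.uint8)
        m = make_matrix(H)
        y = pd.Series(rng.normal(size=n), index=m.samples)  # pure noise
        scan = gwas_scan(y, m)
        from scipy import stats

        ks = stats.kstest(scan["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_group_covariate_absorbs_group_effect(self, rng):
        m, dosage = _signal_setup(rng, n=100)
        groups = ["FZR" if i < 50 else "CS" for i in range(100)]
        y = pd.Series(
            dosage[:, 3] + np.where(np.array(groups) == "CS", 5.0, 0.0),
            index=m.samples,
        )
        covar = pd.DataFrame({"group": groups}, index=m.samples)
        scan = gwas_scan(y, m, covariates=covar)
        assert scan.loc[scan["p"].idxmin(), "index"] == 3

    def test_conditioning_on_causal_removes_its_signal(self, rng):
        m, dosage = _signal_setup(rng, n=120)
        y = pd.Series(dosage[:, 7] + 0.3 * rng.normal(size=120), index=m.samples)
        cond = gwas_scan(y, m, condition_on=[7])
        assert 7 not in set(cond["index"])  # excluded from output
        assert cond["p"].min() > 1e-4  # no residual signal elsewhere

    def test_singular_covariates_named(self, rng):
        m, _ = _signal_setup(rng, n=30)
        covar = pd.DataFrame(
            {"a": np.ones(30), "b": 2 * np.ones(30)}, index=m.samples
        )
        y = pd.Series(np.arange(30.0), index=m.samples)
        with pytest.raises(ValidationError, match="collinear"):
            gwas_scan(y, m, covariates=covar)


class TestEffectSize:
    def test_exact_linear_relation_gives_hundred_percent(self, rng):
        m, dosage = _signal_setup(rng)
        y = pd.Series(2.0 * dosage[:, 5] + 1.0, index=m.samples)
        res = effect_size(y, m, [5])
        assert res.adj_r2_pct == pytest.approx(100.0, abs=1e-6)

    def test_independent_snp_near_zero(self, rng):
        m, dosage = _signal_setup(rng, n=200)
        y = pd.Series(rng.normal(size=200), index=m.samples)
        res = effect_size(y, m, [5])
        assert abs(res.adj_r2_pct) < 5.0

    def test_two_independent_causal_snps_combine_additively(self):
        rng = np.random.default_rng(23)
        n = 400
        g1 = rng.binomial(2, 0.4, size=n)
        g2 = rng.binomial(2, 0.5, size=n)
        H = np.zeros((2 * n, 2), dtype=np.uint8)
        for i in range(n):  # phase dosages into haplotypes
            H[2 * i, 0] = min(g1[i], 1)
            H[2 * i + 1, 0] = max(g1[i] - 1, 0)
            H[2 * i, 1] = min(g2[i], 1)
            H[2 * i + 1, 1] = max(g2[i] - 1, 0)
        m = make_matrix(H)
        y = pd.Series(
            0.5 * g1 + 0.4 * g2 + rng.normal(scale=1.0, size=n), index=m.samples
        )
        a = effect_size(y, m, [0]).adj_r2_pct
        b = effect_size(y, m, [1]).adj_r2_pct
        ab = effect_size(y, m, [0, 1]).adj_r2_pct
        assert ab == pytest.approx(a + b, abs=4.0)


class TestBonferroni:
    @pytest.mark.parametrize(
        "n,alpha,expected",
        [(1_000_000, 0.05, 5e-8), (1, 0.05, 0.05), (20, 0.05, 2.5e-3)],
    )
    def test_threshold(self, n, alpha, expected):
        assert bonferroni_threshold(n, alpha) == pytest.approx(expected)

    def test_invalid_count(self):
        with pytest.raises(ValidationError):
            bonferroni_threshold(0)


class TestPhenotypeVector:
    def test_score_and_rise_kinds(self):
        recs = [
            LTTRecord("A", "FZR", baseline=5.0, g40=7.0),
            LTTRecord("B", "FZR", baseline=5.0, g40=5.5),
        ]
        phenos = build_phenotype(recs)
        rises = phenotype_vector(phenos, "max_rise")
        scores = phenotype_vector(phenos, "score")
        assert rises["A"] == pytest.approx(2.0)
        assert scores.tolist() == [2.0, 0.0]
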