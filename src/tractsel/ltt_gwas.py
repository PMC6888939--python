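"""Lactose-tolerance phenotype construction and GWAS stage.

Phenotype: the maximal blood-glucose rise over the 20/40/60-min
post-ingestion measurements relative to baseline (mmol/l), classified as
intolerant (< 1.1), intermediate (1.1-1.7) or tolerant (>= 1.7); the
boundary values are assigned upward. The quantitative ``max_rise`` is the
default GWAS phenotype; the 3-class score {0,1,2} is available as an
alternative coding.

GWAS: SNP QC (call rate >= 0.95, MAF >= 0.1, Hardy-Weinberg exact-test
p >= 1e-8), then a per-SNP 1-df test of additive allele dosage against the
phenotype residualized on covariates (study group, optionally sex and
conditioning SNP dosages). Effect sizes are adjusted R-squared percentages
from a linear model of the covariate-residualized phenotype on one or more
SNP dosages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genome_model import (
    ComputeError,
    LTTRecord,
    PhasedGenotypeMatrix,
    ValidationError,
)

__all__ = [
    "LTTPhenotype",
    "EffectSizeResult",
    "build_phenotype",
    "phenotype_vector",
    "hwe_exact_test",
    "qc_filter",
    "gwas_scan",
    "effect_size",
    "bonferroni_threshold",
    "INTOLERANT_MAX_RISE",
    "TOLERANT_MIN_RISE",
]

INTOLERANT_MAX_RISE = 1.1  # mmol/l; rises below this are lactose intolerant
TOLERANT_MIN_RISE = 1.7  # mmol/l; rises at or above this are lactose tolerant


@dataclass
class LTTPhenotype:
    """Derived lactose-tolerance phenotype for one individual."""

    sample_id: str
    group: str
    max_rise: float  # raw difference, may be negative
    ltt_class: str  # intolerant | intermediate | tolerant
    score: int  # 0 | 1 | 2
    sex: str | None = None


def _classify(max_rise: float) -> tuple[str, int]:
    if max_rise < INTOLERANT_MAX_RISE:
        return "intolerant", 0
    if max_rise < TOLERANT_MIN_RISE:
        return "intermediate", 1
    return "tolerant", 2


def build_phenotype(records: Iterable[LTTRecord]) -> list[LTTPhenotype]:
    """Maximal post-ingestion glycemia rise and 3-class coding per record.

    Missing post-ingestion measurements are ignored in the maximum; the rise
    is the raw difference (no flooring), so all-below-baseline measurements
    give a negative rise and class intolerant.
    """
    out = []
    for rec in records:
        rise = max(rec.post_values) - rec.baseline
        cls, score = _classify(rise)
        out.append(
            LTTPhenotype(
                sample_id=rec.sample_id,
                group=rec.group,
                max_rise=rise,
                ltt_class=cls,
                score=score,
                sex=rec.sex,
            )
        )
    return out


def phenotype_vector(
    phenotypes: Sequence[LTTPhenotype], kind: str = "max_rise"
) -> pd.Series:
    """Sample-indexed phenotype values (``max_rise`` or the 3-class ``score``)."""
    if kind == "max_rise":
        vals = {p.sample_id: p.max_rise for p in phenotypes}
    elif kind == "score":
        vals = {p.sample_id: float(p.score) for p in phenotypes}
    else:
        raise ValidationError(f"unknown phenotype kind {kind!r}")
    return pd.Series(vals, name=kind)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def hwe_exact_test(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg test p-value for biallelic genotype counts.

    Sums the probabilities of all heterozygote counts (with the same allele
    counts) whose conditional probability does not exceed that of the
    observed configuration.
    """
    if min(n_het, n_hom_minor, n_hom_major) < 0:
        raise ValidationError("negative genotype count")
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    minor = 2 * n_hom_minor + n_het
    if minor > n:  # ensure 'minor' really is the rarer allele
        return hwe_exact_test(n_het, n_hom_major, n_hom_minor)
    # probabilities over feasible het counts, by stable recurrence
    h_max = minor if (minor % 2 == n_het % 2) else minor - 1
    hets = np.arange(n_het % 2, h_max + 1, 2)
    probs = np.empty(hets.size)
    probs[0] = 1.0
    for i in range(1, hets.size):
        h = hets[i]
        hom_min = (minor - h) // 2
        hom_maj = n - h - hom_min
        # P(h) / P(h-2) = 4 * hom_min(h-2) * hom_maj(h-2) / (h * (h-1))
        probs[i] = probs[i - 1] * 4.0 * (hom_min + 1) * (hom_maj + 1) / (h * (h - 1))
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == n_het)[0]]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def qc_filter(
    matrix: PhasedGenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.1,
    hwe_p_min: float = 1e-8,
) -> tuple[PhasedGenotypeMatrix, dict]:
    """Remove SNPs failing call-rate, minor-allele-frequency or HWE filters.

    The phased matrix carries no missing genotypes, so the per-SNP call rate
    is 1.0 unless a missingness mask was attached upstream; the filter is
    kept for interface completeness. Returns the filtered matrix and a
    report counting removals per filter (a SNP failing several filters is
    counted once, under the first in call-rate, MAF, HWE order).
    """
    dosage = matrix.dosage().astype(np.int64)
    n = matrix.n_samples
    call_rate = np.ones(matrix.n_snps)
    af = dosage.sum(axis=0) / (2 * n)
    maf = np.minimum(af, 1 - af)
    n_het = (dosage == 1).sum(axis=0)
    n_hom_alt = (dosage == 2).sum(axis=0)
    n_hom_ref = (dosage == 0).sum(axis=0)
    hwe_p = np.array(
        [
            hwe_exact_test(int(n_het[j]), int(n_hom_alt[j]), int(n_hom_ref[j]))
            for j in range(matrix.n_snps)
        ]
    )
    fail_call = call_rate < call_rate_min
    fail_maf = ~fail_call & (maf < maf_min)
    fail_hwe = ~fail_call & ~fail_maf & (hwe_p < hwe_p_min)
    keep = ~(fail_call | fail_maf | fail_hwe)
    report = {
        "n_input": matrix.n_snps,
        "n_removed_call_rate": int(fail_call.sum()),
        "n_removed_maf": int(fail_maf.sum()),
        "n_removed_hwe": int(fail_hwe.sum()),
        "n_kept": int(keep.sum()),
    }
    return matrix.restrict(keep), report


# ---------------------------------------------------------------------------
# Association scan
# ---------------------------------------------------------------------------


def _design_matrix(covariates: pd.DataFrame | None, n: int) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["const"]
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, prefix=name, drop_first=True)
                for dname in dummies.columns:
                    cols.append(dummies[dname].to_numpy(dtype=float))
                    names.append(dname)
            else:
                cols.append(col.to_numpy(dtype=float))
                names.append(name)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        collinear = []
        for j in range(1, X.shape[1]):
            sub = X[:, : j + 1]
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                collinear.append(names[j])
        raise ValidationError(f"singular covariate design; collinear columns: {collinear}")
    return X, names


def _residualize(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta, X.shape[1]


def gwas_scan(
    phenotype: pd.Series,
    matrix: PhasedGenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    condition_on: Sequence[int] = (),
) -> pd.DataFrame:
    """Per-SNP association of additive ALT dosage with a phenotype.

    The phenotype is first residualized on the covariates (plus the dosages
    of any ``condition_on`` SNP indices); each remaining SNP then gets a
    Wald 1-df chi-square test of its centred dosage against the residualized
    phenotype. Conditioning SNPs are excluded from the output. ``phenotype``
    must be indexed by sample id and cover all samples of ``matrix``.
    """
    samples = matrix.samples
    missing = [s for s in samples if s not in phenotype.index]
    if missing:
        raise ValidationError(f"phenotype missing for samples {missing[:5]}")
    y = phenotype.loc[samples].to_numpy(dtype=float)
    n = len(samples)
    if covariates is not None:
        covariates = covariates.loc[samples] if not covariates.index.equals(
            pd.Index(range(n))
        ) else covariates
    X, _ = _design_matrix(covariates, n)
    dosage = matrix.dosage().astype(float)
    condition_on = list(condition_on)
    if condition_on:
        X = np.column_stack([X] + [dosage[:, j] for j in condition_on])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValidationError("conditioning SNP dosage collinear with covariates")
    y_res, p_x = _residualize(y, X)
    g = dosage - dosage.mean(axis=0)
    sgg = (g**2).sum(axis=0)
    sgy = g.T @ y_res
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sgg > 0, sgy / np.where(sgg > 0, sgg, 1.0), np.nan)
        dof = max(n - p_x - 1, 1)
        rss = (y_res**2).sum() - beta**2 * sgg
        sigma2 = np.maximum(rss, 0.0) / dof
        se = np.sqrt(np.where(sgg > 0, sigma2 / np.where(sgg > 0, sgg, 1.0), np.nan))
        chi2 = (beta / se) ** 2
    p = stats.chi2.sf(chi2, df=1)
    af = dosage.sum(axis=0) / (2 * n)
    out = pd.DataFrame(
        {
            "chrom": matrix.snps["chrom"],
            "pos": matrix.snps["pos"],
            "index": np.arange(matrix.n_snps),
            "n": n,
            "beta": beta,
            "se": se,
            "chi2": chi2,
            "p": p,
            "maf": np.minimum(af, 1 - af),
        }
    )
    drop = set(condition_on) | set(np.flatnonzero(sgg == 0))
    out = out[~out["index"].isin(drop)].reset_index(drop=True)
    out["neg_log10_p"] = -np.log10(out["p"].clip(lower=np.finfo(float).tiny))
    return out


@dataclass
class EffectSizeResult:
    adj_r2_pct: float  # adjusted R-squared of residual variance, percent
    p_value: float  # F-test of the SNP model
    n_snps: int


def effect_size(
    phenotype: pd.Series,
    matrix: PhasedGenotypeMatrix,
    snp_indices: Sequence[int],
    covariates: pd.DataFrame | None = None,
) -> EffectSizeResult:
    """Share of covariate-residual phenotype variance explained by SNP dosages.

    Residualizes the phenotype on the covariates, fits an OLS model of the
    residuals on the given SNP dosage column(s), and reports the adjusted
    R-squared as a percentage (reported as-is, so slightly negative values
    are possible for uninformative SNPs).
    """
    if not snp_indices:
        raise ValidationError("need at least one SNP index")
    samples = matrix.samples
    y = phenotype.loc[samples].to_numpy(dtype=float)
    X, _ = _design_matrix(covariates, len(samples))
    y_res, _ = _residualize(y, X)
    dosage = matrix.dosage().astype(float)[:, list(snp_indices)]
    model = sm.OLS(y_res, sm.add_constant(dosage)).fit()
    return EffectSizeResult(
        adj_r2_pct=float(model.rsquared_adj * 100.0),
        p_value=float(model.f_pvalue),
        n_snps=len(snp_indices),
    )


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    return alpha / n_tests
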