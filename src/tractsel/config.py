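"""Pipeline configuration and the end-to-end demo orchestration.

:class:`PipelineConfig` gathers every stage parameter (with the study's
defaults) and round-trips through YAML. :func:`run_pipeline` generates
synthetic data and runs each stage — mosaic simulation, co-segmentation
tests, ancestry-dosage scan, sweep simulation with iHS peak calling,
selection-coefficient estimation and the LTT GWAS — writing stage artifacts
and a deterministic JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ancestry_scan, cosegmentation, haplotype_selection, ltt_gwas, selcoef
from . import synthetic_data as synth
from .genome_model import ValidationError, write_scan_table, write_tracts

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters of the pipeline, with study defaults."""

    seed: int = 1
    # admixture / mosaic stage
    scenario: str = "nested"
    proportions: tuple[float, float, float] = synth.DEFAULT_PROPORTIONS
    t1: int = synth.DEFAULT_T1
    t2: int = synth.DEFAULT_T2
    n_individuals: int = 53
    n_chromosomes: int = 4
    chrom_length: int = 100_000_000
    # co-segmentation stage
    target: str = "EUR"
    flank: str = "NAF"
    mode: str = "any_side"
    bootstrap_replicates: int = 9999
    sim_replicates: int = 100
    null_fragments: int = 10_000
    # selection-scan stage
    max_gap_bp: int = 200_000
    peak_window_snps: int = 10
    sweep_s: float = 0.05
    sweep_n_diploid: int = 500
    sweep_n_snps: int = 1500
    sweep_generations: int = 100
    # selection-coefficient stage
    alpha_european: float = 0.214
    source_allele_freq: float = 0.74
    observed_allele_freq: float = 0.48
    admixture_years: int = 1828
    generation_time_years: int = 29
    # GWAS stage
    n_gwas_individuals: int = 120
    intolerant_max_rise: float = 1.1
    tolerant_min_rise: float = 1.7
    qc_call_rate: float = 0.95
    qc_maf: float = 0.1
    qc_hwe_p: float = 1e-8

    def validate(self) -> None:
        if self.bootstrap_replicates < 1 or self.sim_replicates < 1:
            raise ValidationError("replicate counts must be >= 1")
        if self.null_fragments < 2:
            raise ValidationError("null_fragments must be >= 2")
        if self.scenario not in ("nested", "independent"):
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        if self.mode not in ("any_side", "both_sides"):
            raise ValidationError(f"unknown flanking mode {self.mode!r}")
        if not (0 < self.qc_call_rate <= 1 and 0 <= self.qc_maf < 0.5):
            raise ValidationError("QC thresholds out of bounds")
        if self.intolerant_max_rise >= self.tolerant_min_rise:
            raise ValidationError("phenotype class thresholds out of order")
        if self.generation_time_years < 1 or self.admixture_years < 1:
            raise ValidationError("time parameters must be positive")
        p = np.asarray(self.proportions, float)
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise ValidationError("ancestry proportions must be >= 0 and sum to 1")

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["proportions"] = list(data["proportions"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "proportions" in data:
            data["proportions"] = tuple(data["proportions"])
        return cls(**data)

    @property
    def admixture_generations(self) -> int:
        return round(self.admixture_years / self.generation_time_years)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on self-generated synthetic data; returns the summary.

    Deterministic given ``config.seed``: stage seeds are derived from it
    with fixed offsets. Artifacts (tract tables, scan tables, the summary)
    are written under ``outdir``.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    summary: dict = {"parameters": {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(config).items()
    }}

    # --- stage 1: ancestry mosaics -----------------------------------------
    model = synth.AdmixtureModel(
        scenario=config.scenario,
        proportions=config.proportions,
        t1=config.t1,
        t2=config.t2,
        n_individuals=config.n_individuals,
        genome=synth.default_admixture_genome(config.n_chromosomes, config.chrom_length),
        seed=seed,
    )
    mosaics = synth.simulate_mosaics(model)
    write_tracts(mosaics, outdir / "mosaics.tsv")
    summary["mosaics"] = {
        "scenario": config.scenario,
        "n_haplotypes": mosaics.n_haplotypes,
        "eur_fraction": round(mosaics.ancestry_fraction(config.target), 6),
    }

    # --- stage 2: co-segmentation ------------------------------------------
    observed = cosegmentation.flanking_statistic(
        mosaics, config.target, config.flank, config.mode
    )
    boot = cosegmentation.bootstrap_flank_null(
        mosaics, config.target, config.flank, config.mode,
        n_replicates=config.bootstrap_replicates, seed=seed + 1,
    )
    indep = cosegmentation.independent_admixture_test(
        observed,
        proportions=config.proportions,
        target=config.target,
        flank=config.flank,
        mode=config.mode,
        n_individuals=config.n_individuals,
        n_fragments=config.null_fragments,
        reps=config.sim_replicates,
        seed=seed + 2,
    )
    summary["cosegmentation"] = {
        "observed": round(observed, 6),
        "bootstrap_p": boot.p_value,
        "bootstrap_null_mean": round(float(boot.replicates.mean()), 6),
        "independent_admixture_p": indep.p_value,
        "independent_null_mean": round(float(indep.replicates.mean()), 6),
    }

    # --- stage 3: ancestry-dosage scan -------------------------------------
    track = ancestry_scan.dosage_track(mosaics, config.target)
    track.to_bedgraph(outdir / "dosage.bedgraph")
    # score the 2-Mb region centred on the genome-wide dosage maximum
    best = None
    for chrom, (breaks, values) in track.steps.items():
        i = int(np.argmax(values))
        if best is None or values[i] > best[2]:
            best = (chrom, int((breaks[i] + breaks[i + 1]) // 2), float(values[i]))
    chrom, centre, _ = best
    half = 1_000_000
    lo = max(centre - half, 0)
    hi = min(centre + half, int(track.steps[chrom][0][-1]))
    z = ancestry_scan.region_departure(track, chrom, lo, hi)
    summary["ancestry_scan"] = {
        "genome_mean": round(track.mean, 6),
        "genome_sd": round(track.sd, 6),
        "top_region": f"{chrom}:{lo}-{hi}",
        "top_region_z": round(float(z), 4),
    }

    # --- stage 4: sweep + iHS peak calling ---------------------------------
    sweep = synth.simulate_sweep(
        synth.SweepModel(
            n_diploid=config.sweep_n_diploid,
            n_snps=config.sweep_n_snps,
            s=config.sweep_s,
            generations=config.sweep_generations,
            # introduced-haplotype frequency alpha_E * f_source, scaled to 2N
            initial_carriers=max(2, round(0.16 * 2 * config.sweep_n_diploid)),
            seed=seed + 3,
        )
    )
    scan = haplotype_selection.ihs_scan(sweep.matrix, max_gap=config.max_gap_bp)
    write_scan_table(scan, outdir / "ihs.tsv")
    windows = haplotype_selection.peak_windows(scan, window=config.peak_window_snps)
    top = windows.iloc[0]
    focal_in_top = bool(top["start_pos"] <= sweep.focal_pos <= top["end_pos"])
    fitted = None
    if 0 < sweep.p0 < sweep.trajectory[-1] < 1:
        fitted = selcoef.solve_s(
            sweep.p0, float(sweep.trajectory[-1]), config.sweep_generations, "dominant"
        ).s
    summary["sweep_scan"] = {
        "true_s": config.sweep_s,
        "focal_pos": sweep.focal_pos,
        "focal_p0": round(sweep.p0, 4),
        "focal_p_final": round(float(sweep.trajectory[-1]), 4),
        "n_snps_scored": int(len(scan)),
        "top_window": f"{top['chrom']}:{int(top['start_pos'])}-{int(top['end_pos'])}",
        "focal_in_top_window": focal_in_top,
        "refit_s_from_trajectory": None if fitted is None else round(fitted, 4),
    }

    # --- stage 5: selection coefficient for the LP allele -------------------
    p0 = selcoef.admixture_initial_frequency(
        config.alpha_european, config.source_allele_freq
    )
    fit = selcoef.solve_s(
        p0, config.observed_allele_freq, config.admixture_generations, "dominant"
    )
    summary["selection_coefficient"] = {
        "p0": round(p0, 6),
        "pt": config.observed_allele_freq,
        "generations": config.admixture_generations,
        "model": "dominant",
        "s": round(fit.s, 6),
    }

    # --- stage 6: LTT phenotypes + GWAS ------------------------------------
    panel = synth.simulate_neutral_panel(
        n_diploid=config.n_gwas_individuals, n_snps=1200, seed=seed + 4
    )
    panel2 = synth.simulate_neutral_panel(
        n_diploid=config.n_gwas_individuals, n_snps=1200, seed=seed + 5
    )
    import pandas as pd

    snps2 = panel2.snps.copy()
    snps2["chrom"] = "2"
    from .genome_model import PhasedGenotypeMatrix

    combined = PhasedGenotypeMatrix(
        panel.samples,
        pd.concat([panel.snps, snps2], ignore_index=True),
        np.concatenate([panel.haplotypes, panel2.haplotypes], axis=1),
    )
    qc_matrix, qc_report = ltt_gwas.qc_filter(
        combined, config.qc_call_rate, config.qc_maf, config.qc_hwe_p
    )
    dosage = qc_matrix.dosage()
    n1 = int((qc_matrix.snps["chrom"] == "1").sum())
    rng = np.random.default_rng(seed + 6)
    focal = _pick_snp(dosage, rng, range(0, n1), target_freq=0.35)
    locus2 = _pick_snp(dosage, rng, range(n1, qc_matrix.n_snps), target_freq=0.5)
    records = synth.simulate_phenotypes(
        qc_matrix, synth.PhenotypeModel(), focal, locus2, seed=seed + 7
    )
    phenos = ltt_gwas.build_phenotype(records)
    y = ltt_gwas.phenotype_vector(phenos)
    covar = pd.DataFrame({"group": [p.group for p in phenos]}, index=[p.sample_id for p in phenos])
    covar = covar.loc[qc_matrix.samples]
    scan = ltt_gwas.gwas_scan(y, qc_matrix, covariates=covar)
    write_scan_table(scan, outdir / "gwas.tsv")
    top_by_chrom = scan.loc[scan.groupby("chrom")["p"].idxmin()]
    es1 = ltt_gwas.effect_size(y, qc_matrix, [focal], covariates=covar)
    es2 = ltt_gwas.effect_size(y, qc_matrix, [locus2], covariates=covar)
    es12 = ltt_gwas.effect_size(y, qc_matrix, [focal, locus2], covariates=covar)
    cond1 = ltt_gwas.gwas_scan(y, qc_matrix, covariates=covar, condition_on=[focal])
    chrom_f = qc_matrix.snps["chrom"].iloc[focal]
    residual_top_p = float(cond1.loc[cond1["chrom"] == chrom_f, "p"].min())
    summary["gwas"] = {
        "qc": qc_report,
        "planted": {
            "focal_index": int(focal),
            "locus2_index": int(locus2),
        },
        "top_snp_per_chrom": {
            str(r["chrom"]): {"pos": int(r["pos"]), "p": float(r["p"]), "index": int(r["index"])}
            for _, r in top_by_chrom.iterrows()
        },
        "bonferroni_threshold": ltt_gwas.bonferroni_threshold(len(scan)),
        "effect_size_pct": {
            "focal": round(es1.adj_r2_pct, 2),
            "locus2": round(es2.adj_r2_pct, 2),
            "combined": round(es12.adj_r2_pct, 2),
        },
        "conditional_top_p_same_chrom": residual_top_p,
    }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _pick_snp(dosage: np.ndarray, rng: np.random.Generator, candidates, target_freq: float) -> int:
    """Choose a causal SNP with allele frequency near ``target_freq``."""
    idx = np.fromiter(candidates, dtype=int)
    af = dosage[:, idx].mean(axis=0) / 2.0
    near = np.abs(af - target_freq)
    best = idx[near < 0.05]
    if best.size == 0:
        best = idx[np.argsort(near)[:10]]
    return int(rng.choice(best))
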