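"""Synthetic-data generators for every pipeline stage.

The generators emulate the study conditions of an admixed Sahelian pastoralist
population carrying West African, North African and European ancestry:

* :func:`simulate_mosaics` — haplotype ancestry mosaics under a *nested*
  two-pulse history (European ancestry first admixed into a North African
  population, whose descendants then admixed into the focal population) or
  under two *independent* pulses, with tract breakpoints following the
  standard exponential (Markov) model at a rate of T breakpoints per Morgan
  for an admixture pulse T generations ago.
* :func:`simulate_independent_null` — the fragment-permutation null used by
  the co-segmentation test: each haploid genome is a run of equal-length
  fragments with i.i.d. ancestry labels.
* :func:`simulate_sweep` — a forward diploid Wright–Fisher simulation of a
  post-admixture selective sweep on standing variation, founded from a
  neutral coalescent panel (msprime).
* :func:`simulate_phenotypes` — lactose-tolerance-test glycemia records
  driven by a dominant focal allele plus an additive second locus.

All generators are fully reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_model import (
    GenomeMap,
    LTTRecord,
    MosaicSet,
    PhasedGenotypeMatrix,
    ValidationError,
)

__all__ = [
    "AdmixtureModel",
    "SweepModel",
    "SweepResult",
    "PhenotypeModel",
    "default_admixture_genome",
    "simulate_mosaics",
    "simulate_independent_null",
    "simulate_sweep",
    "simulate_neutral_panel",
    "simulate_phenotypes",
]

#: Default ancestry labels, in proportion order.
DEFAULT_LABELS = ("EUR", "NAF", "WAF")

#: Genome-wide ancestry fractions of the study population (EUR, NAF, WAF).
DEFAULT_PROPORTIONS = (0.13, 0.19, 0.68)

#: Generations since the main admixture pulse: 1828 years at 29 y/generation.
DEFAULT_T2 = 63

#: Generations since the older European->North African pulse. The
#: trans-Gibraltar contact that mixed these ancestries predates the focal
#: admixture by millennia; ~3000 years at 29 y/generation is used as a
#: realistic default.
DEFAULT_T1 = 103


def default_admixture_genome(n_chrom: int = 4, chrom_length: int = 100_000_000) -> GenomeMap:
    """A compact stand-in genome: ``n_chrom`` chromosomes at 1 cM/Mb."""
    return GenomeMap.uniform({str(i + 1): chrom_length for i in range(n_chrom)})


@dataclass
class AdmixtureModel:
    """Two-pulse admixture history generating haplotype ancestry mosaics.

    ``scenario='nested'`` draws a two-level mosaic: level 1 partitions each
    chromosome into (combined Eurasian *source*) vs WAF tracts with
    breakpoints at rate ``t2`` per Morgan; level 2 partitions each source
    tract into EUR vs NAF at rate ``t1`` per Morgan with EUR weight
    ``alpha_e / (alpha_e + alpha_n)``. ``scenario='independent'`` draws a
    single-level three-label mosaic at rate ``t2``.
    """

    scenario: str = "nested"
    proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS
    labels: tuple[str, str, str] = DEFAULT_LABELS
    t1: int = DEFAULT_T1
    t2: int = DEFAULT_T2
    n_individuals: int = 53
    genome: GenomeMap = field(default_factory=default_admixture_genome)
    seed: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.size != 3 or np.any(p < 0) or np.any(p > 1):
            raise ValidationError("proportions must be three values in [0,1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError(f"proportions sum to {p.sum()}, expected 1")
        if self.scenario not in ("nested", "independent"):
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "nested" and not (self.t1 >= self.t2 >= 1):
            raise ValidationError("nested scenario requires t1 >= t2 >= 1")
        if self.t2 < 1:
            raise ValidationError("t2 must be >= 1")
        if self.n_individuals < 1:
            raise ValidationError("need at least one individual")


def _morgans_to_bp(genome: GenomeMap, chrom: str, morgan_pos: np.ndarray) -> np.ndarray:
    """Invert the bp->cM map (piecewise linear, hence invertible)."""
    cm = morgan_pos * 100.0
    if chrom in genome.cm_maps:
        knots_bp, knots_cm = genome.cm_maps[chrom]
        return np.interp(cm, knots_cm, knots_bp)
    return cm / (genome.rate_cm_per_mb / 1e6)


def _markov_segments(rng: np.random.Generator, total_m: float, rate: float,
                     weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One realisation of the exponential tract process on [0, total_m] Morgans.

    Returns segment start positions (Morgans, first is 0) and i.i.d. label
    codes drawn from ``weights`` (one per segment). Labels are *not* merged.
    """
    n_break = rng.poisson(rate * total_m)
    starts = np.concatenate([[0.0], np.sort(rng.random(n_break) * total_m)])
    codes = rng.choice(weights.size, size=starts.size, p=weights)
    return starts, codes


def simulate_mosaics(model: AdmixtureModel, seed: int | None = None) -> MosaicSet:
    """Generate ancestry mosaics for ``2 * n_individuals`` haplotypes."""
    rng = np.random.default_rng(model.seed if seed is None else seed)
    alpha_e, alpha_n, alpha_w = model.proportions
    alpha_src = alpha_e + alpha_n
    labels = list(model.labels)
    haps: dict[tuple[str, int], dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for ind in range(model.n_individuals):
        sample = f"S{ind:04d}"
        for hap in (0, 1):
            chroms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for chrom, length in model.genome.lengths.items():
                total_m = model.genome.morgans(chrom)
                if total_m <= 0:
                    raise ValidationError(f"chromosome {chrom} has zero genetic length")
                if model.scenario == "independent":
                    starts, codes = _markov_segments(
                        rng, total_m, model.t2, np.array(model.proportions)
                    )
                else:
                    # level 1: source (code 0) vs WAF (code 1)
                    s1, c1 = _markov_segments(
                        rng, total_m, model.t2, np.array([alpha_src, alpha_w])
                    )
                    bounds = np.concatenate([s1, [total_m]])
                    w_eur = 0.5 if alpha_src == 0 else alpha_e / alpha_src
                    seg_starts: list[np.ndarray] = []
                    seg_codes: list[np.ndarray] = []
                    for i, code in enumerate(c1):
                        a, b = bounds[i], bounds[i + 1]
                        if code == 1:  # WAF tract
                            seg_starts.append(np.array([a]))
                            seg_codes.append(np.array([2]))
                        else:  # source tract: EUR/NAF sub-mosaic
                            s2, c2 = _markov_segments(
                                rng, b - a, model.t1, np.array([w_eur, 1 - w_eur])
                            )
                            seg_starts.append(s2 + a)
                            seg_codes.append(c2)  # 0=EUR, 1=NAF
                    starts = np.concatenate(seg_starts)
                    codes = np.concatenate(seg_codes)
                bp = np.rint(_morgans_to_bp(model.genome, chrom, starts)).astype(np.int64)
                bp[0] = 0
                breaks = np.concatenate([bp, [length]])
                # drop zero-length segments created by bp rounding
                keep = np.diff(breaks) > 0
                breaks = np.concatenate([breaks[:-1][keep], [length]])
                chroms[chrom] = (breaks, codes[keep])
            haps[(sample, hap)] = chroms
    return MosaicSet(labels, model.genome, haps)


def independent_label_matrix(
    rng: np.random.Generator,
    n_haplotypes: int,
    n_fragments: int,
    proportions: Sequence[float],
) -> np.ndarray:
    """Raw i.i.d. fragment label codes, shape (n_haplotypes, n_fragments).

    Fast path used by the simulation null of the co-segmentation test; the
    mosaic-level wrapper is :func:`simulate_independent_null`.
    """
    p = np.asarray(proportions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"proportions sum to {p.sum()}, expected 1")
    cut = np.cumsum(p)
    u = rng.random((n_haplotypes, n_fragments))
    return np.searchsorted(cut, u, side="right").astype(np.int64)


def simulate_independent_null(
    n_individuals: int = 53,
    n_fragments: int = 10_000,
    proportions: Sequence[float] = DEFAULT_PROPORTIONS,
    labels: Sequence[str] = DEFAULT_LABELS,
    fragment_length: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> MosaicSet:
    """Independent-admixture null: i.i.d. equal-length fragments per haplotype.

    Each of the ``2 * n_individuals`` haploid genomes is one chromosome of
    ``n_fragments`` fragments whose ancestries are drawn independently from
    ``proportions``; same-label neighbours merge on construction, so stored
    tracts are maximal runs.
    """
    if n_fragments < 2:
        raise ValidationError("need at least 2 fragments per haplotype")
    if rng is None:
        rng = np.random.default_rng(seed)
    codes2d = independent_label_matrix(rng, 2 * n_individuals, n_fragments, proportions)
    length = n_fragments * fragment_length
    genome = GenomeMap.uniform({"1": length})
    grid = np.arange(n_fragments + 1, dtype=np.int64) * fragment_length
    haps: dict[tuple[str, int], dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for h in range(codes2d.shape[0]):
        row = codes2d[h]
        change = np.flatnonzero(row[1:] != row[:-1]) + 1
        starts = np.concatenate([[0], change])
        breaks = np.concatenate([grid[starts], [length]])
        haps[(f"S{h // 2:04d}", h % 2)] = {"1": (breaks, row[starts])}
    return MosaicSet(list(labels), genome, haps)


# ---------------------------------------------------------------------------
# Forward Wright-Fisher sweep simulation
# ---------------------------------------------------------------------------


@dataclass
class SweepModel:
    """Forward diploid Wright-Fisher sweep on a neutral founder panel.

    The focal allele receives a genotype fitness advantage at a central SNP:
    dominant — w(AA)=w(Aa)=1+s, w(aa)=1; additive — w(Aa)=1+s, w(AA)=1+2s.
    Gametes recombine between adjacent SNPs with probability
    ``recomb_rate_per_bp`` times the inter-SNP spacing.

    ``carrier_init`` controls the starting state of the selected class:

    * ``"donor_haplotype"`` (default): the allele sits on ``initial_carriers``
      copies of a single donor haplotype — the post-admixture scenario in
      which a selected variant enters on one introgressed haplotype
      background, the regime EHH-family scans are designed for;
    * ``"standing"``: the allele is an existing standing variant of the
      founder panel with derived count closest to ``initial_carriers``
      (older, mixed backgrounds: a soft selective sweep).
    """

    n_diploid: int = 500
    n_snps: int = 2000
    s: float = 0.05
    dominance: str = "dominant"
    initial_carriers: int = 160
    carrier_init: str = "donor_haplotype"
    generations: int = 63
    recomb_rate_per_bp: float = 1e-7
    sequence_length: float = 2_000_000.0
    founder_ne: float = 10_000.0
    mutation_rate: float = 1.25e-8
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0):
            raise ValidationError("selection coefficient must be in [0,1]")
        if self.dominance not in ("dominant", "additive"):
            raise ValidationError(f"unknown dominance model {self.dominance!r}")
        if self.carrier_init not in ("donor_haplotype", "standing"):
            raise ValidationError(f"unknown carrier_init {self.carrier_init!r}")
        if self.n_diploid < 2 or self.generations < 0:
            raise ValidationError("invalid population size or generation count")
        if not (0 < self.initial_carriers < 2 * self.n_diploid):
            raise ValidationError("initial_carriers must be in (0, 2N)")


@dataclass
class SweepResult:
    matrix: PhasedGenotypeMatrix
    trajectory: np.ndarray  # focal derived-allele frequency, length generations+1
    focal_index: int
    focal_pos: int
    p0: float
    lost: bool
    fixed: bool


def _msprime_panel(
    n_diploid: int,
    n_snps: int,
    sequence_length: float,
    recomb_rate: float,
    mutation_rate: float,
    ne: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Neutral coalescent founder haplotypes: (2N, L) derived indicators and
    integer bp positions (strictly increasing), thinned to ~n_snps sites."""
    import msprime

    ts = msprime.sim_ancestry(
        samples=n_diploid,
        population_size=ne,
        sequence_length=sequence_length,
        recombination_rate=recomb_rate,
        random_seed=seed,
    )
    ts = msprime.sim_mutations(
        ts, rate=mutation_rate, random_seed=seed + 1,
        model=msprime.BinaryMutationModel(),
    )
    G = ts.genotype_matrix()  # sites x haplotypes
    pos = np.array([s.position for s in ts.sites()])
    # keep strictly biallelic segregating 0/1 sites at unique integer positions
    seg = (G.max(axis=1) == 1) & (G.min(axis=1) == 0)
    G, pos = G[seg], pos[seg]
    ipos = pos.astype(np.int64)
    uniq = np.concatenate([[True], np.diff(ipos) > 0])
    G, ipos = G[uniq], ipos[uniq]
    if G.shape[0] > n_snps:
        take = np.linspace(0, G.shape[0] - 1, n_snps).round().astype(int)
        take = np.unique(take)
        G, ipos = G[take], ipos[take]
    return np.ascontiguousarray(G.T.astype(np.uint8)), ipos


def _wf_generation(
    rng: np.random.Generator,
    haps: np.ndarray,
    focal: int,
    s: float,
    dominance: str,
    r_adj: np.ndarray,
) -> np.ndarray:
    """One Wright-Fisher generation with selection at ``focal``."""
    n2, L = haps.shape
    n = n2 // 2
    g = haps[0::2, focal].astype(np.int64) + haps[1::2, focal]
    if dominance == "dominant":
        w = np.where(g >= 1, 1.0 + s, 1.0)
    else:
        w = 1.0 + s * g
    probs = w / w.sum()
    parents = rng.choice(n, size=n2, p=probs)  # two gametes per child
    start = rng.integers(0, 2, size=n2)
    if L > 1 and np.any(r_adj > 0):
        xo = rng.random((n2, L - 1)) < r_adj
        which = np.empty((n2, L), dtype=np.int8)
        which[:, 0] = start
        which[:, 1:] = (start[:, None] + np.cumsum(xo, axis=1)) % 2
    else:
        which = np.repeat(start[:, None], L, axis=1).astype(np.int8)
    rows0 = haps[2 * parents]
    rows1 = haps[2 * parents + 1]
    return np.where(which == 0, rows0, rows1)


def simulate_sweep(
    model: SweepModel,
    seed: int | None = None,
    founder_haplotypes: np.ndarray | None = None,
    founder_positions: np.ndarray | None = None,
) -> SweepResult:
    """Forward-simulate a sweep; returns final haplotypes and the true
    per-generation focal-allele frequency trajectory.

    Allele loss or fixation is reported on the result, not raised. Founder
    haplotypes default to a neutral msprime coalescent panel but can be
    supplied directly (derived-allele indicators, shape (2N, L)).
    """
    seed = model.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if founder_haplotypes is None:
        ms_seed = int(rng.integers(1, 2**31 - 2))
        haps, pos = _msprime_panel(
            model.n_diploid, model.n_snps, model.sequence_length,
            model.recomb_rate_per_bp, model.mutation_rate, model.founder_ne, ms_seed,
        )
    else:
        haps = np.asarray(founder_haplotypes, dtype=np.uint8).copy()
        if founder_positions is None:
            founder_positions = np.arange(haps.shape[1], dtype=np.int64) * 1000 + 1
        pos = np.asarray(founder_positions, dtype=np.int64)
    n2, L = haps.shape
    counts = haps.sum(axis=0)
    centre = pos[0] + (pos[-1] - pos[0]) / 2
    central = np.flatnonzero(np.abs(pos - centre) <= (pos[-1] - pos[0]) * 0.15)
    if central.size == 0:
        central = np.arange(L)
    if model.carrier_init == "standing":
        # focal SNP: central standing variant with count closest to the target
        focal = int(central[np.argmin(np.abs(counts[central] - model.initial_carriers))])
    else:
        # introduce the allele on copies of one donor haplotype: the carriers
        # start identical along the whole chromosome, as after a single-source
        # admixture pulse, and recombination erodes the shared background
        focal = int(central[np.argmin(np.abs(pos[central] - centre))])
        donor = int(rng.integers(0, n2))
        carriers = rng.choice(n2, size=model.initial_carriers, replace=False)
        haps[carriers] = haps[donor]
        haps[:, focal] = 0
        haps[carriers, focal] = 1
    r_adj = np.minimum(np.diff(pos) * model.recomb_rate_per_bp, 0.5)
    traj = np.empty(model.generations + 1)
    traj[0] = haps[:, focal].sum() / n2
    for t in range(1, model.generations + 1):
        haps = _wf_generation(rng, haps, focal, model.s, model.dominance, r_adj)
        traj[t] = haps[:, focal].sum() / n2
    import pandas as pd

    snps = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos + 1,  # stored positions are 1-based
            "ref": "A",
            "alt": "T",
            "ancestral": "A",
        }
    )
    samples = [f"S{i:04d}" for i in range(n2 // 2)]
    matrix = PhasedGenotypeMatrix(samples, snps, haps)
    return SweepResult(
        matrix=matrix,
        trajectory=traj,
        focal_index=focal,
        focal_pos=int(pos[focal] + 1),
        p0=float(traj[0]),
        lost=bool(traj[-1] == 0.0),
        fixed=bool(traj[-1] == 1.0),
    )


def simulate_scan_genome(
    sweep_model: SweepModel,
    n_neutral_chrom: int = 4,
    neutral_n_snps: int = 1000,
    neutral_sequence_length: float = 1_000_000.0,
    seed: int | None = None,
) -> tuple[PhasedGenotypeMatrix, "SweepResult"]:
    """A multi-chromosome scan target: one swept chromosome plus neutral ones.

    Chromosome "1" carries the sweep of ``sweep_model``; the remaining
    chromosomes evolve neutrally (``s = 0``) under the *same* forward
    demography (population size and generation count), so genome-wide
    standardization of haplotype statistics compares like with like.
    """
    import dataclasses

    import pandas as pd

    rng = np.random.default_rng(sweep_model.seed if seed is None else seed)
    sweep = simulate_sweep(sweep_model, seed=int(rng.integers(1, 2**31 - 2)))
    snp_tables = [sweep.matrix.snps]
    hap_blocks = [sweep.matrix.haplotypes]
    for c in range(n_neutral_chrom):
        neutral_model = dataclasses.replace(
            sweep_model,
            s=0.0,
            n_snps=neutral_n_snps,
            sequence_length=neutral_sequence_length,
            seed=int(rng.integers(1, 2**31 - 2)),
        )
        neutral = simulate_sweep(neutral_model)
        snps = neutral.matrix.snps.copy()
        snps["chrom"] = str(c + 2)
        snp_tables.append(snps)
        hap_blocks.append(neutral.matrix.haplotypes)
    matrix = PhasedGenotypeMatrix(
        sweep.matrix.samples,
        pd.concat(snp_tables, ignore_index=True),
        np.concatenate(hap_blocks, axis=1),
    )
    return matrix, sweep


def simulate_neutral_panel(
    n_diploid: int = 100,
    n_snps: int = 1500,
    sequence_length: float = 2_000_000.0,
    recomb_rate_per_bp: float = 1e-8,
    mutation_rate: float = 1.25e-8,
    ne: float = 10_000.0,
    seed: int | None = None,
) -> PhasedGenotypeMatrix:
    """Neutral coalescent haplotype panel with known ancestral alleles."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    ms_seed = int(rng.integers(1, 2**31 - 2))
    haps, pos = _msprime_panel(
        n_diploid, n_snps, sequence_length, recomb_rate_per_bp, mutation_rate, ne, ms_seed
    )
    snps = pd.DataFrame(
        {"chrom": "1", "pos": pos + 1, "ref": "A", "alt": "T", "ancestral": "A"}
    )
    samples = [f"S{i:04d}" for i in range(haps.shape[0] // 2)]
    return PhasedGenotypeMatrix(samples, snps, haps)


# ---------------------------------------------------------------------------
# LTT phenotypes
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeModel:
    """Two-locus architecture for the lactose-tolerance-test glycemia rise.

    The maximal post-ingestion rise (mmol/l) is
    ``carrier_rise`` (if the individual carries >= 1 copy of the focal allele,
    dominant coding) or ``noncarrier_rise``, plus ``locus2_effect`` per ALT
    allele at an unlinked second locus, plus a group offset and Gaussian
    noise. Defaults place carriers above the 1.7 mmol/l tolerant threshold
    and non-carriers below the 1.1 mmol/l intolerant threshold.
    """

    carrier_rise: float = 2.1
    noncarrier_rise: float = 0.7
    locus2_effect: float = 0.45
    residual_sd: float = 0.35
    baseline_mean: float = 5.0
    baseline_sd: float = 0.4
    group_offsets: dict[str, float] = field(default_factory=lambda: {"FZR": 0.0, "CS": 0.2})
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.residual_sd < 0 or self.baseline_sd < 0:
            raise ValidationError("standard deviations must be >= 0")


def simulate_phenotypes(
    matrix: PhasedGenotypeMatrix,
    model: PhenotypeModel,
    focal_index: int,
    locus2_index: int,
    groups: Sequence[str] | None = None,
    seed: int | None = None,
) -> list[LTTRecord]:
    """Generate one LTT record per sample of ``matrix``.

    The maximal rise over the 20/40/60-min measurements equals the model's
    linear predictor exactly (the 40-min value carries the peak; the other
    two sit a fixed 0.3 and 0.5 mmol/l below it).
    """
    if not (0 <= focal_index < matrix.n_snps and 0 <= locus2_index < matrix.n_snps):
        raise ValidationError("focal/locus2 index outside SNP table")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    dosage = matrix.dosage()
    carrier = dosage[:, focal_index] >= 1
    d2 = dosage[:, locus2_index].astype(float)
    n = matrix.n_samples
    if groups is None:
        groups = ["FZR" if i < n // 2 else "CS" for i in range(n)]
    offsets = np.array([model.group_offsets.get(g, 0.0) for g in groups])
    rise = (
        np.where(carrier, model.carrier_rise, model.noncarrier_rise)
        + model.locus2_effect * d2
        + offsets
        + rng.normal(0.0, model.residual_sd, size=n)
    )
    baseline = rng.normal(model.baseline_mean, model.baseline_sd, size=n)
    baseline = np.maximum(baseline, 0.5)
    records = []
    for i, sample in enumerate(matrix.samples):
        peak = baseline[i] + rise[i]
        records.append(
            LTTRecord(
                sample_id=sample,
                group=groups[i],
                baseline=float(baseline[i]),
                g20=float(max(peak - 0.3, 0.0)),
                g40=float(max(peak, 0.0)),
                g60=float(max(peak - 0.5, 0.0)),
            )
        )
    return records
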