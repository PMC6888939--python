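"""Domain types and IO for ancestry tracts, phased genotypes and phenotypes.

Everything downstream (co-segmentation, ancestry-dosage scans, EHH-family
selection scans, GWAS) consumes only the containers defined here:

* :class:`GenomeMap` — chromosome lengths plus an optional bp→cM map
  (default: uniform 1 cM/Mb).
* :class:`MosaicSet` — per-haplotype ordered ancestry segments ("tracts"),
  normalized so that every tract is a *maximal* run of one ancestry label.
* :class:`PhasedGenotypeMatrix` — haplotype × SNP binary matrix with SNP
  metadata including the ancestral allele where known.
* :class:`LTTRecord` — per-individual lactose-tolerance-test glycemia
  measurements (baseline and 20/40/60 min post-ingestion, mmol/l).

Coordinate conventions: tracts are 0-based half-open (BED); SNP positions are
1-based (VCF). The label ``UNK`` marks windows of unknown/low-confidence
ancestry; it is stored like any other label but breaks tract adjacency in the
flanking analyses (a fragment bordering UNK has a missing neighbour on that
side).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TractselError",
    "ValidationError",
    "ComputeError",
    "UNKNOWN_LABEL",
    "GenomeMap",
    "AncestryTract",
    "MosaicSet",
    "PhasedGenotypeMatrix",
    "LTTRecord",
    "read_tracts",
    "write_tracts",
    "read_rfmix_msp",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_ancestral_table",
    "write_ancestral_table",
    "read_phenotypes",
    "write_phenotypes",
    "read_scan_table",
    "write_scan_table",
]

UNKNOWN_LABEL = "UNK"


class TractselError(Exception):
    """Base class for all package errors."""


class ValidationError(TractselError):
    """Invalid input data or configuration."""


class ComputeError(TractselError):
    """A computation could not produce a result (degenerate input etc.)."""


# ---------------------------------------------------------------------------
# Genome map
# ---------------------------------------------------------------------------


@dataclass
class GenomeMap:
    """Chromosome lengths and a (piecewise-linear) physical→genetic map.

    Parameters
    ----------
    lengths
        Mapping chromosome name → length in bp (positive).
    cm_maps
        Optional per-chromosome piecewise-linear map given as
        ``(bp_knots, cm_knots)`` arrays; cM values must be monotone
        non-decreasing in bp. Chromosomes without an entry fall back to the
        uniform rate.
    rate_cm_per_mb
        Uniform recombination rate used in the absence of a map, in cM/Mb.
    """

    lengths: dict[str, int]
    cm_maps: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    rate_cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValidationError(f"chromosome {chrom!r} has non-positive length {length}")
        if self.rate_cm_per_mb <= 0:
            raise ValidationError("rate_cm_per_mb must be positive")
        for chrom, (bp, cm) in self.cm_maps.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.shape != cm.shape or bp.ndim != 1 or bp.size < 2:
                raise ValidationError(f"cM map for {chrom!r} must be two equal 1-d arrays")
            if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) < 0):
                raise ValidationError(f"cM map for {chrom!r} must be monotone in bp")
            self.cm_maps[chrom] = (bp, cm)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    def bp_to_cm(self, chrom: str, bp) -> np.ndarray:
        """Interpolate genetic position (cM) at physical position(s) ``bp``."""
        bp = np.asarray(bp, dtype=float)
        if chrom in self.cm_maps:
            knots_bp, knots_cm = self.cm_maps[chrom]
            return np.interp(bp, knots_bp, knots_cm)
        return bp * (self.rate_cm_per_mb / 1e6)

    def morgans(self, chrom: str) -> float:
        """Genetic length of a chromosome in Morgans."""
        return float(self.bp_to_cm(chrom, self.lengths[chrom])) / 100.0

    @classmethod
    def uniform(cls, lengths: Mapping[str, int], rate_cm_per_mb: float = 1.0) -> "GenomeMap":
        return cls(lengths=dict(lengths), rate_cm_per_mb=rate_cm_per_mb)


# ---------------------------------------------------------------------------
# Ancestry tracts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AncestryTract:
    """One maximal run of a single ancestry on one haplotype.

    Coordinates are 0-based half-open (``start_bp <= x < end_bp``).
    """

    chrom: str
    start_bp: int
    end_bp: int
    sample_id: str
    hap_index: int
    ancestry: str

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValidationError(
                f"tract {self.chrom}:{self.start_bp}-{self.end_bp} has start >= end"
            )

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp


def _merge_runs(breaks: np.ndarray, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse adjacent equal-code segments; breaks has len(codes)+1."""
    if codes.size <= 1:
        return breaks, codes
    keep = np.empty(codes.size, dtype=bool)
    keep[0] = True
    keep[1:] = codes[1:] != codes[:-1]
    idx = np.flatnonzero(keep)
    new_breaks = np.concatenate([breaks[idx], breaks[-1:]])
    return new_breaks, codes[idx]


class MosaicSet:
    """A collection of haplotype ancestry mosaics sharing one label set.

    Each haplotype-chromosome is stored as a pair of arrays: breakpoints
    ``breaks`` (length k+1, ``breaks[0] == 0`` and ``breaks[-1] ==``
    chromosome length) and integer label ``codes`` (length k) indexing
    :attr:`labels`. Construction normalizes: adjacent tracts with the same
    label are merged, so stored tracts are maximal runs.
    """

    def __init__(
        self,
        labels: Sequence[str],
        genome: GenomeMap,
        haplotypes: Mapping[tuple[str, int], Mapping[str, tuple[np.ndarray, np.ndarray]]],
    ) -> None:
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate ancestry labels")
        self.labels = list(labels)
        self.genome = genome
        self._haps: dict[tuple[str, int], dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        for key, chroms in haplotypes.items():
            store: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for chrom, (breaks, codes) in chroms.items():
                breaks = np.asarray(breaks, dtype=np.int64)
                codes = np.asarray(codes, dtype=np.int64)
                self._validate_hap(key, chrom, breaks, codes)
                store[chrom] = _merge_runs(breaks, codes)
            self._haps[key] = store

    # -- construction helpers -------------------------------------------------

    def _validate_hap(
        self, key: tuple[str, int], chrom: str, breaks: np.ndarray, codes: np.ndarray
    ) -> None:
        sample, hap = key
        where = f"{sample}/hap{hap}/{chrom}"
        if chrom not in self.genome.lengths:
            raise ValidationError(f"{where}: chromosome not in genome map")
        if breaks.size != codes.size + 1 or codes.size == 0:
            raise ValidationError(f"{where}: malformed tract arrays")
        if breaks[0] != 0:
            raise ValidationError(f"{where}: coverage gap at bp 0 (first tract starts at {breaks[0]})")
        if breaks[-1] != self.genome.lengths[chrom]:
            raise ValidationError(
                f"{where}: tracts end at {breaks[-1]}, chromosome length is "
                f"{self.genome.lengths[chrom]}"
            )
        diffs = np.diff(breaks)
        if np.any(diffs <= 0):
            pos = breaks[np.flatnonzero(diffs <= 0)[0]]
            raise ValidationError(f"{where}: non-positive tract at bp {pos}")
        if np.any(codes < 0) or np.any(codes >= len(self.labels)):
            raise ValidationError(f"{where}: ancestry code out of range")

    # -- basic accessors ------------------------------------------------------

    @property
    def haplotype_keys(self) -> list[tuple[str, int]]:
        return list(self._haps)

    @property
    def n_haplotypes(self) -> int:
        return len(self._haps)

    def chromosome_arrays(self, sample_id: str, hap_index: int, chrom: str):
        """Return (breaks, codes) arrays for one haplotype-chromosome."""
        return self._haps[(sample_id, hap_index)][chrom]

    def iter_hap_chroms(self) -> Iterator[tuple[str, int, str, np.ndarray, np.ndarray]]:
        for (sample, hap), chroms in self._haps.items():
            for chrom, (breaks, codes) in chroms.items():
                yield sample, hap, chrom, breaks, codes

    def tracts(self) -> Iterator[AncestryTract]:
        for sample, hap, chrom, breaks, codes in self.iter_hap_chroms():
            for i, code in enumerate(codes):
                yield AncestryTract(
                    chrom=chrom,
                    start_bp=int(breaks[i]),
                    end_bp=int(breaks[i + 1]),
                    sample_id=sample,
                    hap_index=hap,
                    ancestry=self.labels[code],
                )

    def label_code(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"unknown ancestry label {label!r}") from None

    def normalize(self) -> "MosaicSet":
        """Return a merged copy (idempotent: construction already merges)."""
        return MosaicSet(self.labels, self.genome, self._haps)

    def ancestry_fraction(self, label: str) -> float:
        """Genome-wide, bp-weighted fraction of haplotypes carrying ``label``."""
        code = self.label_code(label)
        num = 0.0
        den = 0.0
        for _, _, _, breaks, codes in self.iter_hap_chroms():
            lengths = np.diff(breaks)
            num += float(lengths[codes == code].sum())
            den += float(lengths.sum())
        if den == 0:
            raise ComputeError("empty mosaic set")
        return num / den

    # -- fragment adjacency table --------------------------------------------

    def fragment_table(self) -> dict[str, np.ndarray]:
        """Flat arrays describing every fragment and its immediate neighbours.

        Returns arrays ``label``, ``left``, ``right`` (neighbour codes, -1 for
        a missing neighbour: chromosome end or an UNK neighbour) and
        ``length`` (bp). UNK fragments themselves are listed (they are never
        targets but count as fragments for resampling).
        """
        unk = self.labels.index(UNKNOWN_LABEL) if UNKNOWN_LABEL in self.labels else -2
        lab_parts, left_parts, right_parts, len_parts = [], [], [], []
        for _, _, _, breaks, codes in self.iter_hap_chroms():
            k = codes.size
            left = np.full(k, -1, dtype=np.int64)
            right = np.full(k, -1, dtype=np.int64)
            left[1:] = codes[:-1]
            right[:-1] = codes[1:]
            left[left == unk] = -1
            right[right == unk] = -1
            lab_parts.append(codes)
            left_parts.append(left)
            right_parts.append(right)
            len_parts.append(np.diff(breaks))
        if not lab_parts:
            raise ComputeError("empty mosaic set")
        return {
            "label": np.concatenate(lab_parts),
            "left": np.concatenate(left_parts),
            "right": np.concatenate(right_parts),
            "length": np.concatenate(len_parts),
        }

    # -- dataframe conversion -------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (t.chrom, t.start_bp, t.end_bp, t.sample_id, t.hap_index, t.ancestry)
            for t in self.tracts()
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "hap", "ancestry"])

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        genome: GenomeMap | None = None,
        labels: Sequence[str] | None = None,
    ) -> "MosaicSet":
        """Build a MosaicSet from a tract table, validating coverage.

        If ``genome`` is omitted, chromosome lengths are inferred as the
        maximum tract end per chromosome. If ``labels`` is omitted the label
        set is the sorted set of labels present.
        """
        required = ["chrom", "start", "end", "sample", "hap", "ancestry"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"tract table missing columns {missing}")
        if labels is None:
            labels = sorted(df["ancestry"].astype(str).unique())
        else:
            seen = set(df["ancestry"].astype(str).unique())
            unknown = seen - set(labels)
            if unknown:
                first = df.index[df["ancestry"].isin(unknown)][0]
                raise ValidationError(
                    f"unknown ancestry label(s) {sorted(unknown)} (first at table row {first})"
                )
        code_of = {lab: i for i, lab in enumerate(labels)}
        if genome is None:
            lengths = df.groupby("chrom")["end"].max().astype(int).to_dict()
            genome = GenomeMap.uniform(lengths)
        haps: dict[tuple[str, int], dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        for (sample, hap, chrom), grp in df.groupby(["sample", "hap", "chrom"], sort=False):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy(dtype=np.int64)
            ends = grp["end"].to_numpy(dtype=np.int64)
            where = f"{sample}/hap{int(hap)}/{chrom}"
            bad = np.flatnonzero(starts[1:] != ends[:-1])
            if bad.size:
                i = bad[0]
                if starts[i + 1] > ends[i]:
                    raise ValidationError(
                        f"{where}: coverage gap at bp {ends[i]} "
                        f"(table rows {grp.index[i]} and {grp.index[i + 1]})"
                    )
                raise ValidationError(
                    f"{where}: overlapping tracts at bp {starts[i + 1]} "
                    f"(table rows {grp.index[i]} and {grp.index[i + 1]})"
                )
            breaks = np.concatenate([starts, ends[-1:]])
            codes = np.array([code_of[a] for a in grp["ancestry"].astype(str)], dtype=np.int64)
            haps.setdefault((str(sample), int(hap)), {})[str(chrom)] = (breaks, codes)
        return cls(labels, genome, haps)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MosaicSet):
            return NotImplemented
        if self.labels != other.labels or set(self._haps) != set(other._haps):
            return False
        for key, chroms in self._haps.items():
            och = other._haps[key]
            if set(chroms) != set(och):
                return False
            for chrom, (b, c) in chroms.items():
                ob, oc = och[chrom]
                if not (np.array_equal(b, ob) and np.array_equal(c, oc)):
                    return False
        return True


# ---------------------------------------------------------------------------
# Tract TSV IO
# ---------------------------------------------------------------------------


def read_tracts(
    path, genome: GenomeMap | None = None, labels: Sequence[str] | None = None
) -> MosaicSet:
    """Read a tract TSV (chrom, start, end, sample, hap, ancestry; 0-based
    half-open) into a normalized :class:`MosaicSet`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str, "ancestry": str})
    if df.empty:
        raise ValidationError(f"{path}: empty tract table")
    return MosaicSet.from_dataframe(df, genome=genome, labels=labels)


def write_tracts(mosaics: MosaicSet, path) -> None:
    mosaics.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# RFMix msp.tsv dialect
# ---------------------------------------------------------------------------


def read_rfmix_msp(path, genome: GenomeMap | None = None) -> MosaicSet:
    """Read an RFMix-style per-window most-likely-ancestry table.

    Expected dialect: a first comment line declaring ancestry codes
    (``#Subpopulation order/codes: WAF=0 EUR=1 ...``), a header line starting
    with ``#chm`` whose trailing columns name haplotypes (``Sample.0``), and
    data rows ``chrom  spos  epos  [sgpos  egpos  nsnps]  code...``. Windows
    must be sorted and contiguous per chromosome; they are collapsed to
    maximal tracts.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValidationError(f"{path}: empty RFMix file")
    if not lines[0].startswith("#") or "=" not in lines[0]:
        raise ValidationError(f"{path}: missing subpopulation code header")
    codes_part = lines[0].split(":", 1)[-1]
    code_to_label: dict[int, str] = {}
    for tok in codes_part.replace(",", " ").split():
        if "=" in tok:
            lab, code = tok.split("=")
            code_to_label[int(code)] = lab.strip()
    if not code_to_label:
        raise ValidationError(f"{path}: no ancestry codes declared")
    if len(lines) < 3:
        raise ValidationError(f"{path}: no data rows")
    header = lines[1].lstrip("#").split("\t")
    n_meta = 6 if len(header) >= 6 and header[3].lower().startswith("sg") else 3
    hap_names = header[n_meta:]
    if not hap_names:
        raise ValidationError(f"{path}: header declares no haplotype columns")
    df = pd.read_csv(
        io.StringIO("\n".join(lines[2:])), sep="\t", header=None, dtype=str
    )
    if df.shape[1] != n_meta + len(hap_names) or df.isna().any().any():
        raise ValidationError(
            f"{path}: inconsistent haplotype count across rows "
            f"(header declares {len(hap_names)} haplotypes)"
        )
    labels = [code_to_label[c] for c in sorted(code_to_label)]
    remap = {c: labels.index(lab) for c, lab in code_to_label.items()}
    spos = df.iloc[:, 1].astype(np.int64).to_numpy()
    epos = df.iloc[:, 2].astype(np.int64).to_numpy()
    chroms = df.iloc[:, 0].astype(str).to_numpy()
    hap_codes = df.iloc[:, n_meta:].astype(np.int64).to_numpy()
    hap_codes = np.vectorize(remap.get)(hap_codes)
    haps: dict[tuple[str, int], dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    lengths: dict[str, int] = {}
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        s, e = spos[sel], epos[sel]
        if np.any(s[1:] != e[:-1]):
            raise ValidationError(f"{path}: windows not contiguous on {chrom}")
        breaks = np.concatenate([s, e[-1:]])
        # treat the first window as starting at 0 even if RFMix trimmed edges
        breaks[0] = min(breaks[0], 0)
        lengths[str(chrom)] = int(e[-1])
        for j, name in enumerate(hap_names):
            if "." in name:
                sample, hap_s = name.rsplit(".", 1)
                hap = int(hap_s)
            else:
                sample, hap = name, 0
            haps.setdefault((sample, hap), {})[str(chrom)] = (breaks, hap_codes[sel, j])
    if genome is None:
        genome = GenomeMap.uniform(lengths)
    return MosaicSet(labels, genome, haps)


# ---------------------------------------------------------------------------
# Phased genotypes
# ---------------------------------------------------------------------------


class PhasedGenotypeMatrix:
    """Haplotype × SNP binary matrix (1 = ALT allele) with SNP metadata.

    ``snps`` is a DataFrame with columns ``chrom``, ``pos`` (1-based),
    ``ref``, ``alt``, ``ancestral`` (base string, or ``None`` when unknown).
    Haplotype rows come in sample order: rows ``2i`` and ``2i+1`` are the two
    phased haplotypes of ``samples[i]``.
    """

    def __init__(self, samples: Sequence[str], snps: pd.DataFrame, haplotypes: np.ndarray):
        haplotypes = np.asarray(haplotypes, dtype=np.uint8)
        if haplotypes.ndim != 2 or haplotypes.shape[0] != 2 * len(samples):
            raise ValidationError("haplotype matrix must be (2*n_samples, n_snps)")
        if haplotypes.shape[1] != len(snps):
            raise ValidationError("SNP table and matrix disagree on SNP count")
        if haplotypes.size and haplotypes.max() > 1:
            raise ValidationError("haplotype matrix entries must be 0/1")
        for chrom, grp in snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(f"positions not strictly increasing on {chrom}")
        self.samples = list(samples)
        self.snps = snps.reset_index(drop=True)
        self.haplotypes = haplotypes

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def hap_ids(self) -> list[str]:
        return [f"{s}_{h}" for s in self.samples for h in (0, 1)]

    def dosage(self) -> np.ndarray:
        """Diploid ALT dosage matrix (n_samples × n_snps), values 0/1/2."""
        return (self.haplotypes[0::2].astype(np.int16) + self.haplotypes[1::2]).astype(np.int8)

    def ancestral_known(self) -> np.ndarray:
        anc = self.snps["ancestral"]
        return ((anc == self.snps["ref"]) | (anc == self.snps["alt"])).to_numpy()

    def derived_haplotypes(self) -> tuple[np.ndarray, np.ndarray]:
        """Derived-allele indicator matrix and per-SNP known-ancestral mask.

        Where the ancestral allele equals ALT, the derived indicator is the
        complement of the ALT indicator; where it equals REF they coincide;
        elsewhere the SNP is masked unknown (indicator left as ALT).
        """
        anc = self.snps["ancestral"]
        is_ref = (anc == self.snps["ref"]).to_numpy()
        is_alt = (anc == self.snps["alt"]).to_numpy()
        known = is_ref | is_alt
        der = self.haplotypes.copy()
        der[:, is_alt] = 1 - der[:, is_alt]
        return der, known

    def restrict(self, snp_mask: np.ndarray) -> "PhasedGenotypeMatrix":
        return PhasedGenotypeMatrix(
            self.samples, self.snps.loc[np.asarray(snp_mask)], self.haplotypes[:, snp_mask]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhasedGenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.haplotypes, other.haplotypes)
            and self.snps[["chrom", "pos", "ref", "alt"]].equals(
                other.snps[["chrom", "pos", "ref", "alt"]]
            )
        )


def read_ancestral_table(path) -> dict[tuple[str, int], str]:
    """Read a two-column ancestral-allele table: ``chrom:pos<TAB>base``."""
    out: dict[tuple[str, int], str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                locus, base = line.split("\t")
                chrom, pos = locus.rsplit(":", 1)
                out[(chrom, int(pos))] = base.strip().upper()
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: malformed ancestral-allele row") from None
    return out


def write_ancestral_table(table: Mapping[tuple[str, int], str], path) -> None:
    with open(path, "w") as fh:
        for (chrom, pos), base in table.items():
            fh.write(f"{chrom}:{pos}\t{base}\n")


def read_phased_vcf(
    path, ancestral: Mapping[tuple[str, int], str] | None = None
) -> PhasedGenotypeMatrix:
    """Read a phased VCF into a :class:`PhasedGenotypeMatrix`.

    All GT fields must be phased (``|`` separator); multiallelic records are
    skipped (count stored on the result as ``n_multiallelic_skipped``). SNPs
    absent from the ``ancestral`` table get ``ancestral=None`` (unknown).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[tuple] = []
    cols: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = np.array(var.genotype.array())  # columns: allele0, allele1, phased flag
        if np.any(gts[:, 2] == 0):
            raise ValidationError(
                f"{path}: unphased genotype at {var.CHROM}:{var.POS}"
            )
        if np.any(gts[:, :2] < 0):
            raise ValidationError(f"{path}: missing genotype at {var.CHROM}:{var.POS}")
        aa = ancestral.get((var.CHROM, var.POS)) if ancestral else None
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0], aa))
        cols.append(gts[:, :2].astype(np.uint8).reshape(-1))
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "ancestral"])
    if rows:
        haps = np.stack(cols, axis=1)
    else:
        haps = np.zeros((2 * len(samples), 0), dtype=np.uint8)
    out = PhasedGenotypeMatrix(samples, snps, haps)
    out.n_multiallelic_skipped = n_multi
    return out


def write_phased_vcf(matrix: PhasedGenotypeMatrix, path) -> None:
    """Write a minimal phased VCF 4.2 (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(matrix.snps["chrom"]):
            max_pos = int(matrix.snps.loc[matrix.snps["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.samples) + "\n")
        H = matrix.haplotypes
        for j, row in matrix.snps.iterrows():
            gts = "\t".join(
                f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(matrix.n_samples)
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


@dataclass
class LTTRecord:
    """Lactose-tolerance-test glycemia record for one individual (mmol/l)."""

    sample_id: str
    group: str
    baseline: float
    g20: float | None = None
    g40: float | None = None
    g60: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        vals = [self.baseline, self.g20, self.g40, self.g60]
        if any(v is not None and v < 0 for v in vals):
            raise ValidationError(f"{self.sample_id}: negative glycemia value")
        if all(v is None for v in (self.g20, self.g40, self.g60)):
            raise ValidationError(f"{self.sample_id}: no post-ingestion measurement")

    @property
    def post_values(self) -> list[float]:
        return [v for v in (self.g20, self.g40, self.g60) if v is not None]


def read_phenotypes(path) -> list[LTTRecord]:
    df = pd.read_csv(path, dtype={"sample": str, "group": str})
    records = []
    for _, row in df.iterrows():
        def _get(col):
            if col in row and pd.notna(row[col]):
                return float(row[col])
            return None

        records.append(
            LTTRecord(
                sample_id=str(row["sample"]),
                group=str(row["group"]),
                sex=str(row["sex"]) if "sex" in row and pd.notna(row.get("sex")) else None,
                baseline=float(row["baseline"]),
                g20=_get("g20"),
                g40=_get("g40"),
                g60=_get("g60"),
            )
        )
    return records


def write_phenotypes(records: Iterable[LTTRecord], path) -> None:
    df = pd.DataFrame(
        [
            (r.sample_id, r.group, r.sex, r.baseline, r.g20, r.g40, r.g60)
            for r in records
        ],
        columns=["sample", "group", "sex", "baseline", "g20", "g40", "g60"],
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Generic scan tables
# ---------------------------------------------------------------------------


def write_scan_table(df: pd.DataFrame, path) -> None:
    """Write a per-position scan table as TSV (round-trips via read_scan_table)."""
    df.to_csv(path, sep="\t", index=False)


def read_scan_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
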