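"""EHH-family selection scans: EHH curves, iHS, XP-EHH and peak windows.

EHH (extended haplotype homozygosity) at a distance from a core SNP is the
probability that two haplotypes drawn at random from a carrier set are
identical over the whole interval between the core and that distance:
``EHH = sum_g C(n_g, 2) / C(n, 2)`` over the haplotype groups ``g`` at that
extension. Curves are truncated when EHH drops below 0.05 or when the next
inter-SNP gap exceeds 200,000 bp (both configurable); iHH is the trapezoid
integral of EHH over physical distance, summed over both sides of the core.

* iHS: ``ln(iHH_ancestral / iHH_derived)``, standardized within
  derived-allele-frequency bins (2% wide, small bins merged), two-sided
  normal p-values.
* XP-EHH: ``ln(iHH_A / iHH_B)`` with site-EHH over *all* haplotypes of each
  population (the partition at the core is by core allele), standardized
  genome-wide. Positive scores mean longer haplotype homozygosity in A.
* Peak calling: mean -log10(p) in non-overlapping windows of 10 consecutive
  SNPs, ranked descending with ties broken by genomic order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import ComputeError, PhasedGenotypeMatrix, ValidationError

__all__ = [
    "EHHCurve",
    "ehh",
    "integrated_ehh",
    "ihs_scan",
    "xpehh_scan",
    "peak_windows",
    "DEFAULT_MAX_GAP_BP",
    "DEFAULT_EHH_LIMIT",
]

DEFAULT_MAX_GAP_BP = 200_000
DEFAULT_EHH_LIMIT = 0.05


@dataclass
class EHHCurve:
    """EHH values on one side of a core SNP.

    ``distance_bp[0] == 0`` is the core itself; for carrier-set EHH the value
    there is 1 by definition. EHH is non-increasing with distance.
    """

    core_index: int
    side: str  # "left" | "right"
    distance_bp: np.ndarray
    ehh: np.ndarray

    def ihh(self) -> float:
        """Trapezoid integral of the curve over physical distance (bp)."""
        return float(np.trapezoid(self.ehh, self.distance_bp))


try:  # compiled walk kernel; EHH walks are the scan's inner loop
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _walk_kernel(
    haps: np.ndarray,
    positions: np.ndarray,
    core: int,
    rows: np.ndarray,
    direction: int,
    max_gap: int,
    limit: float,
    partition_core: bool,
    out_dist: np.ndarray,
    out_ehh: np.ndarray,
) -> int:  # pragma: no cover - exercised via _ehh_side
    n = rows.size
    denom = n * (n - 1) / 2.0
    group = np.zeros(n, dtype=np.int64)
    counts = np.zeros(2 * n + 2, dtype=np.int64)
    remap = np.zeros(2 * n + 2, dtype=np.int64)
    n_groups = 1
    e0 = 1.0
    if partition_core:
        pairs = 0
        ones = 0
        for i in range(n):
            if haps[rows[i], core] == 1:
                ones += 1
        zeros = n - ones
        pairs = ones * (ones - 1) // 2 + zeros * (zeros - 1) // 2
        e0 = pairs / denom
        for i in range(n):
            group[i] = haps[rows[i], core]
        n_groups = 2 if 0 < ones < n else 1
    out_dist[0] = 0.0
    out_ehh[0] = e0
    k = 1
    j = core
    L = haps.shape[1]
    while out_ehh[k - 1] >= limit:
        jn = j + direction
        if jn < 0 or jn >= L:
            break
        gap = positions[jn] - positions[j]
        if gap < 0:
            gap = -gap
        if gap > max_gap:
            break  # truncate at the last pre-gap SNP
        max_key = 2 * n_groups
        for i in range(max_key):
            counts[i] = 0
        for i in range(n):
            key = 2 * group[i] + haps[rows[i], jn]
            group[i] = key
            counts[key] += 1
        pairs = 0
        n_groups = 0
        for key in range(max_key):
            c = counts[key]
            if c > 0:
                pairs += c * (c - 1) // 2
                remap[key] = n_groups
                n_groups += 1
        for i in range(n):
            group[i] = remap[group[i]]
        out_ehh[k] = pairs / denom
        d = positions[jn] - positions[core]
        out_dist[k] = d if d >= 0 else -d
        k += 1
        j = jn
        if n_groups == n:  # all singletons: EHH stays 0 from here on
            break
    return k


def _ehh_side(
    haps: np.ndarray,
    positions: np.ndarray,
    core: int,
    rows: np.ndarray,
    direction: int,
    max_gap: int,
    limit: float,
    partition_core: bool,
) -> tuple[np.ndarray, np.ndarray]:
    n = rows.size
    L = haps.shape[1]
    out_dist = np.empty(L + 1)
    out_ehh = np.empty(L + 1)
    k = _walk_kernel(
        np.ascontiguousarray(haps),
        np.ascontiguousarray(positions, dtype=np.int64),
        int(core),
        np.ascontiguousarray(rows, dtype=np.int64),
        int(direction),
        int(max_gap),
        float(limit),
        bool(partition_core),
        out_dist,
        out_ehh,
    )
    return out_dist[:k].copy(), out_ehh[:k].copy()


def ehh(
    matrix: PhasedGenotypeMatrix,
    core_index: int,
    carrier_rows: np.ndarray,
    max_gap: int = DEFAULT_MAX_GAP_BP,
    limit: float = DEFAULT_EHH_LIMIT,
    partition_core: bool = False,
) -> tuple[EHHCurve, EHHCurve]:
    """EHH curves (left, right) around a core SNP for a carrier set.

    ``carrier_rows`` indexes haplotype rows; fewer than two carriers is an
    error (EHH undefined). With ``partition_core=True`` the initial partition
    is by the core allele itself (site-EHH, as used by XP-EHH).
    """
    rows = np.asarray(carrier_rows)
    if rows.size < 2:
        raise ComputeError("EHH undefined for fewer than 2 carrier haplotypes")
    chrom = matrix.snps["chrom"].iloc[core_index]
    on_chrom = (matrix.snps["chrom"] == chrom).to_numpy()
    lo = int(np.argmax(on_chrom))
    # extension is confined to the core's chromosome
    haps = matrix.haplotypes[:, on_chrom]
    positions = matrix.snps["pos"].to_numpy()[on_chrom]
    local_core = core_index - lo
    curves = []
    for side, direction in (("left", -1), ("right", +1)):
        d, v = _ehh_side(
            haps, positions, local_core, rows, direction, max_gap, limit, partition_core
        )
        curves.append(EHHCurve(core_index=core_index, side=side, distance_bp=d, ehh=v))
    return curves[0], curves[1]


def integrated_ehh(left: EHHCurve, right: EHHCurve) -> float:
    """iHH: sum of the trapezoid integrals of both side curves."""
    return left.ihh() + right.ihh()


def _ihh_for_rows(
    haps: np.ndarray,
    positions: np.ndarray,
    core: int,
    rows: np.ndarray,
    max_gap: int,
    limit: float,
    partition_core: bool = False,
) -> float:
    total = 0.0
    for direction in (-1, +1):
        d, v = _ehh_side(haps, positions, core, rows, direction, max_gap, limit,
                         partition_core)
        total += float(np.trapezoid(v, d))
    return total


def _merged_freq_bins(freqs: np.ndarray, bin_width: float, min_per_bin: int) -> np.ndarray:
    """Assign each SNP a frequency-bin group id; bins with fewer than
    ``min_per_bin`` SNPs are merged with their right neighbour (the last
    group absorbs leftovers)."""
    raw_bin = np.minimum((freqs / bin_width).astype(int), int(1 / bin_width) - 1)
    order = np.unique(raw_bin)
    group_of: dict[int, int] = {}
    gid = 0
    count = 0
    for i, b in enumerate(order):
        group_of[b] = gid
        count += int(np.sum(raw_bin == b))
        if count >= min_per_bin and i < len(order) - 1:
            gid += 1
            count = 0
    if count and count < min_per_bin and gid > 0:
        # fold the trailing underfull group into the previous one
        for b, g in group_of.items():
            if g == gid:
                group_of[b] = gid - 1
    return np.array([group_of[b] for b in raw_bin])


def _standardize(raw: np.ndarray, groups: np.ndarray) -> np.ndarray:
    z = np.empty_like(raw)
    for g in np.unique(groups):
        sel = groups == g
        mu = raw[sel].mean()
        sd = raw[sel].std()
        z[sel] = 0.0 if sd == 0 else (raw[sel] - mu) / sd
    return z


def ihs_scan(
    matrix: PhasedGenotypeMatrix,
    maf_min: float = 0.05,
    max_gap: int = DEFAULT_MAX_GAP_BP,
    limit: float = DEFAULT_EHH_LIMIT,
    bin_width: float = 0.02,
    min_per_bin: int = 10,
) -> pd.DataFrame:
    """Genome-wide iHS scan.

    Scores every SNP with a known ancestral allele and derived-allele
    frequency in ``[maf_min, 1 - maf_min]``. Returns a position-sorted
    DataFrame with columns ``chrom, pos, daf, ihh_anc, ihh_der, raw, z, p,
    neg_log10_p``; SNPs whose ancestral- or derived-carrier iHH is zero (or
    with <2 carriers on either side) are dropped, with counts in
    ``df.attrs['n_dropped']``.
    """
    der, known = matrix.derived_haplotypes()
    positions = matrix.snps["pos"].to_numpy()
    chroms = matrix.snps["chrom"].to_numpy()
    n_hap = der.shape[0]
    daf = der.mean(axis=0)
    scorable = known & (daf >= maf_min) & (daf <= 1 - maf_min)
    rows_out = []
    n_dropped = 0
    for chrom in pd.unique(chroms):
        on = chroms == chrom
        idx = np.flatnonzero(on)
        sub = der[:, idx]
        sub_pos = positions[idx]
        for local_j, j in enumerate(idx):
            if not scorable[j]:
                continue
            der_rows = np.flatnonzero(sub[:, local_j] == 1)
            anc_rows = np.flatnonzero(sub[:, local_j] == 0)
            if der_rows.size < 2 or anc_rows.size < 2:
                n_dropped += 1
                continue
            ihh_d = _ihh_for_rows(sub, sub_pos, local_j, der_rows, max_gap, limit)
            ihh_a = _ihh_for_rows(sub, sub_pos, local_j, anc_rows, max_gap, limit)
            if ihh_d <= 0 or ihh_a <= 0:
                n_dropped += 1
                continue
            rows_out.append((chrom, positions[j], daf[j], ihh_a, ihh_d, np.log(ihh_a / ihh_d)))
    df = pd.DataFrame(
        rows_out, columns=["chrom", "pos", "daf", "ihh_anc", "ihh_der", "raw"]
    )
    df.attrs["n_dropped"] = n_dropped
    if df.empty:
        for col in ("z", "p", "neg_log10_p"):
            df[col] = pd.Series(dtype=float)
        return df
    groups = _merged_freq_bins(df["daf"].to_numpy(), bin_width, min_per_bin)
    df["z"] = _standardize(df["raw"].to_numpy(), groups)
    df["p"] = 2 * stats.norm.sf(np.abs(df["z"]))
    df["p"] = df["p"].clip(lower=np.finfo(float).tiny)
    df["neg_log10_p"] = -np.log10(df["p"])
    return df


def xpehh_scan(
    matrix_a: PhasedGenotypeMatrix,
    matrix_b: PhasedGenotypeMatrix,
    max_gap: int = DEFAULT_MAX_GAP_BP,
    limit: float = DEFAULT_EHH_LIMIT,
) -> pd.DataFrame:
    """Cross-population XP-EHH scan over the shared SNP set.

    Both matrices must carry identical SNP tables (same chromosomes and
    positions). Raw scores are ``ln(iHH_A / iHH_B)`` from site-EHH over all
    haplotypes per population, standardized genome-wide; positive scores mean
    longer haplotype homozygosity in population A.
    """
    if not matrix_a.snps[["chrom", "pos"]].equals(matrix_b.snps[["chrom", "pos"]]):
        raise ValidationError("XP-EHH requires an identical shared SNP set")
    positions = matrix_a.snps["pos"].to_numpy()
    chroms = matrix_a.snps["chrom"].to_numpy()
    rows_a = np.arange(matrix_a.haplotypes.shape[0])
    rows_b = np.arange(matrix_b.haplotypes.shape[0])
    out = []
    n_dropped = 0
    for chrom in pd.unique(chroms):
        on = chroms == chrom
        idx = np.flatnonzero(on)
        sub_a = matrix_a.haplotypes[:, idx]
        sub_b = matrix_b.haplotypes[:, idx]
        sub_pos = positions[idx]
        for local_j, j in enumerate(idx):
            ihh_a = _ihh_for_rows(sub_a, sub_pos, local_j, rows_a, max_gap, limit,
                                  partition_core=True)
            ihh_b = _ihh_for_rows(sub_b, sub_pos, local_j, rows_b, max_gap, limit,
                                  partition_core=True)
            if ihh_a <= 0 or ihh_b <= 0:
                n_dropped += 1
                continue
            out.append((chrom, positions[j], ihh_a, ihh_b, np.log(ihh_a / ihh_b)))
    df = pd.DataFrame(out, columns=["chrom", "pos", "ihh_a", "ihh_b", "raw"])
    df.attrs["n_dropped"] = n_dropped
    if df.empty:
        for col in ("z", "p", "neg_log10_p"):
            df[col] = pd.Series(dtype=float)
        return df
    raw = df["raw"].to_numpy()
    sd = raw.std()
    df["z"] = 0.0 if sd == 0 else (raw - raw.mean()) / sd
    df["p"] = 2 * stats.norm.sf(np.abs(df["z"]))
    df["p"] = df["p"].clip(lower=np.finfo(float).tiny)
    df["neg_log10_p"] = -np.log10(df["p"])
    return df


def peak_windows(records: pd.DataFrame, window: int = 10) -> pd.DataFrame:
    """Rank non-overlapping windows of ``window`` consecutive SNPs by mean
    -log10(p).

    Windows never span chromosomes; a trailing block shorter than ``window``
    forms a partial window flagged ``complete=False``. Ties in score are
    broken by genomic order (stable).
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    required = {"chrom", "pos", "neg_log10_p"}
    if not required.issubset(records.columns):
        raise ValidationError(f"records need columns {sorted(required)}")
    rows = []
    for chrom, grp in records.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        scores = grp["neg_log10_p"].to_numpy()
        for start in range(0, len(grp), window):
            block = slice(start, start + window)
            n = len(scores[block])
            rows.append(
                (
                    chrom,
                    int(pos[block][0]),
                    int(pos[block][-1]),
                    n,
                    float(scores[block].mean()),
                    n == window,
                )
            )
    df = pd.DataFrame(
        rows, columns=["chrom", "start_pos", "end_pos", "n_snps", "score", "complete"]
    )
    df = df.sort_values(
        ["score", "chrom", "start_pos"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
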