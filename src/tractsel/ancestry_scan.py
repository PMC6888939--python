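"""Per-position ancestry dosage along the genome and SD-departure scoring.

The ancestry *dosage* of a label at a base pair is the fraction of haplotypes
whose local-ancestry tract at that position carries the label. The track is
an exact step function built from the tract unions (no binning); genome-wide
moments are bp-weighted over the step function. A candidate region is scored
as ``z = (region mean - genome mean) / genome SD`` with whole-genome moments
(the region itself is not excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_model import ComputeError, MosaicSet, ValidationError

__all__ = ["DosageTrack", "dosage_track", "region_departure"]


@dataclass
class DosageTrack:
    """Breakpoint-sorted step function of ancestry dosage per chromosome.

    ``steps[chrom] = (breaks, values)`` with ``len(breaks) == len(values)+1``;
    ``values[i]`` is the dosage on ``[breaks[i], breaks[i+1])``.
    """

    label: str
    steps: dict[str, tuple[np.ndarray, np.ndarray]]
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        total = 0.0
        s1 = 0.0
        s2 = 0.0
        for chrom, (breaks, values) in self.steps.items():
            if np.any(values < -1e-12) or np.any(values > 1 + 1e-12):
                raise ValidationError(f"dosage outside [0,1] on {chrom}")
            w = np.diff(breaks).astype(float)
            total += w.sum()
            s1 += float(w @ values)
            s2 += float(w @ (values**2))
        if total == 0:
            raise ValidationError("empty dosage track")
        self.mean = s1 / total
        self.sd = float(np.sqrt(max(s2 / total - self.mean**2, 0.0)))

    def value_at(self, chrom: str, bp: int) -> float:
        breaks, values = self.steps[chrom]
        i = int(np.searchsorted(breaks, bp, side="right")) - 1
        i = min(max(i, 0), values.size - 1)
        return float(values[i])

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        """bp-weighted mean dosage over [start, end)."""
        if chrom not in self.steps:
            raise ValidationError(f"chromosome {chrom!r} not in track")
        breaks, values = self.steps[chrom]
        if not (0 <= start < end <= breaks[-1]):
            raise ValidationError(f"region {chrom}:{start}-{end} outside chromosome")
        lo = np.clip(breaks[:-1], start, end)
        hi = np.clip(breaks[1:], start, end)
        w = (hi - lo).astype(float)
        return float(w @ values) / (end - start)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, (breaks, values) in self.steps.items():
                for i, v in enumerate(values):
                    fh.write(f"{chrom}\t{breaks[i]}\t{breaks[i + 1]}\t{v:.6g}\n")


def dosage_track(mosaics: MosaicSet, label: str) -> DosageTrack:
    """Exact per-bp dosage of ``label`` across all haplotypes of a mosaic set.

    A label absent from the mosaics yields an all-zero (valid) track.
    """
    try:
        code = mosaics.label_code(label)
    except ValidationError:
        code = -1  # absent label: all-zero track
    # per chromosome: +1/-1 events at tract bounds of the focal label
    events: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    n_haps: dict[str, int] = {}
    for _, _, chrom, breaks, codes in mosaics.iter_hap_chroms():
        n_haps[chrom] = n_haps.get(chrom, 0) + 1
        sel = codes == code
        if sel.any():
            starts = breaks[:-1][sel]
            ends = breaks[1:][sel]
            events.setdefault(chrom, []).append((starts, ends))
    steps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, length in mosaics.genome.lengths.items():
        if chrom not in n_haps:
            continue
        n = n_haps[chrom]
        if chrom not in events:
            steps[chrom] = (np.array([0, length], dtype=np.int64), np.zeros(1))
            continue
        starts = np.concatenate([s for s, _ in events[chrom]])
        ends = np.concatenate([e for _, e in events[chrom]])
        pos = np.concatenate([[0], starts, ends, [length]])
        delta = np.concatenate(
            [[0], np.ones_like(starts), -np.ones_like(ends), [0]]
        ).astype(np.int64)
        order = np.argsort(pos, kind="stable")
        pos, delta = pos[order], delta[order]
        grid, inverse = np.unique(pos, return_inverse=True)
        counts = np.zeros(grid.size, dtype=np.int64)
        np.add.at(counts, inverse, delta)
        coverage = np.cumsum(counts)[:-1]  # on [grid[i], grid[i+1])
        steps[chrom] = (grid, coverage / n)
    return DosageTrack(label=label, steps=steps)


def region_departure(track: DosageTrack, chrom: str, start: int, end: int) -> float:
    """SD units by which a region's mean dosage departs from the genome mean.

    Raises :class:`ComputeError` for a constant (zero-SD) track.
    """
    if track.sd == 0.0:
        raise ComputeError("genome-wide dosage SD is zero; z-score undefined")
    return (track.region_mean(chrom, start, end) - track.mean) / track.sd
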