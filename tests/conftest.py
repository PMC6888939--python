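import numpy as np
import pandas as pd
import pytest

from tractsel.genome_model import GenomeMap, MosaicSet, PhasedGenotypeMatrix


def make_mosaic(rows, lengths=None, labels=None):
    """Build a MosaicSet from (chrom, start, end, sample, hap, ancestry) rows."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "hap", "ancestry"])
    genome = GenomeMap.uniform(lengths) if lengths else None
    return MosaicSet.from_dataframe(df, genome=genome, labels=labels)


def mosaic_from_labels(label_seqs, seg_len=10, labels=None):
    """One single-chromosome haplotype per sequence of ancestry labels."""
    rows = []
    length = None
    for h, seq in enumerate(label_seqs):
        if length is None:
            length = len(seq) * seg_len
        assert len(seq) * seg_len == length
        for i, lab in enumerate(seq):
            rows.append(("chr1", i * seg_len, (i + 1) * seg_len, f"S{h}", 0, lab))
    return make_mosaic(rows, lengths={"chr1": length}, labels=labels)


def make_matrix(haplotypes, positions=None, chrom="1", ancestral="ref"):
    """PhasedGenotypeMatrix from a (2n, L) 0/1 array."""
    H = np.asarray(haplotypes, dtype=np.uint8)
    n2, L = H.shape
    assert n2 % 2 == 0
    if positions is None:
        positions = np.arange(1, L + 1) * 1000
    snps = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions),
            "ref": "A",
            "alt": "T",
            "ancestral": "A" if ancestral == "ref" else ("T" if ancestral == "alt" else None),
        }
    )
    samples = [f"S{i}" for i in range(n2 // 2)]
    return PhasedGenotypeMatrix(samples, snps, H)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def toy_mosaic():
    # one haplotype: W E N E W on a 50 bp chromosome
    return mosaic_from_labels([list("WENEW")], labels=["E", "N", "W"])
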