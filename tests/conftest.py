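import numpy as np
import pytest

from lncsnp.core_io import GeneModel, GenomicInterval, LncRNAGene, Variant


def make_gene(gene_id="G1", chrom="chr1", start=1000, end=9000, strand="+",
              exons=None, biotype="protein_coding"):
    interval = GenomicInterval(chrom, start, end, strand)
    if exons is None:
        exons = (
            GenomicInterval(chrom, start, start + 500, strand),
            GenomicInterval(chrom, end - 500, end, strand),
        )
    return GeneModel(gene_id=gene_id, interval=interval, exons=tuple(exons),
                     biotype=biotype)


def make_lnc(lnc_id="L1", chrom="chr1", start=2000, end=2300, strand="+",
             exons=None, seq=None, seed=0):
    interval = GenomicInterval(chrom, start, end, strand)
    if exons is None:
        exons = (interval,)
    if seq is None:
        rng = np.random.default_rng(seed)
        length = sum(e.end - e.start for e in exons)
        seq = "".join(rng.choice(list("ACGU"), size=length))
    return LncRNAGene(lnc_id, interval, tuple(exons), transcript_seq=seq)


def make_variant(vid="rs1", chrom="chr1", pos=2100, ref="A", alt="G", p=None):
    return Variant(id=vid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                   assoc_p=p or {"IBD": 0.001})


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
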