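import pytest

from isoflat.annotation_io import Config, GenomicInterval, TranscriptModel
from isoflat.gene_model import flatten_gene


def tx(tid, pairs, strand="+", chrom="chr1", gene="G", source="reference"):
    return TranscriptModel(
        tid, gene, [GenomicInterval(chrom, s, e, strand) for s, e in pairs], source=source
    )


@pytest.fixture
def cfg():
    return Config()


@pytest.fixture
def gene_g():
    """Four-exon '+' gene: flat exons 1:(100,200) 2:(300,400) 3:(500,600) 4:(700,800).

    T1 uses all four exons; T2 skips exon 2. Known internal donors are
    200/400/600, acceptors 300/500/700, plus T2's skip junction (200,500).
    """
    t1 = tx("T1", [(100, 200), (300, 400), (500, 600), (700, 800)])
    t2 = tx("T2", [(100, 200), (500, 600), (700, 800)])
    refs = [t1, t2]
    return refs, flatten_gene(refs)
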