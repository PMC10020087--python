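import numpy as np
import pandas as pd
import pytest

from m6asplice.annotation import GeneAnnotation, Transcript


def make_tx(tid, exons, *, gene="G1", contig="chr1", strand="+", cds=None):
    return Transcript(tid, gene, contig, strand, tuple(exons),
                      tuple(cds) if cds else None)


def annotation_from(*transcripts) -> GeneAnnotation:
    ann = GeneAnnotation()
    for tx in transcripts:
        ann.add_transcript(tx)
    return ann


@pytest.fixture
def se_gene():
    """Cassette-exon gene: A-B-C vs A-C on the plus strand."""
    t1 = make_tx("t1", [(0, 100), (200, 300), (400, 500)])
    t2 = make_tx("t2", [(0, 100), (400, 500)])
    return annotation_from(t1, t2)


@pytest.fixture
def multi_event_gene():
    """Five-transcript gene engineered to carry one SE, RI, A5 and MX event.

    A seven-exon backbone (E0..E6 at 1 kb spacing) with one variant
    transcript per slot: skip E1 (SE), retain the E2-E3 intron (RI), extend
    the E4 donor by 60 nt (A5), and swap E5 for a disjoint alternative
    internal exon (MX).
    """
    backbone = [(k * 1000, k * 1000 + 100) for k in range(7)]
    t_ref = make_tx("t_ref", backbone)
    t_se = make_tx("t_se", [e for e in backbone if e != (1000, 1100)])
    t_ri = make_tx(
        "t_ri", [e for e in backbone if e not in ((2000, 2100), (3000, 3100))]
        + [(2000, 3100)]
    )
    t_a5 = make_tx(
        "t_a5", [e for e in backbone if e != (4000, 4100)] + [(4000, 4160)]
    )
    t_mx = make_tx(
        "t_mx", [e for e in backbone if e != (5000, 5100)] + [(5500, 5600)]
    )
    return annotation_from(t_ref, t_se, t_ri, t_a5, t_mx)


def quant_from_dict(tpm: dict, conditions: dict, counts: dict | None = None):
    """Build a QuantTable from {transcript: {sample: tpm}} nests."""
    from m6asplice.psi import QuantTable

    tpm_df = pd.DataFrame(tpm).T.astype(float)
    counts_df = (
        pd.DataFrame(counts).T.astype(int)
        if counts is not None
        else tpm_df.round().astype(int)
    )
    return QuantTable(tpm=tpm_df, counts=counts_df, conditions=conditions)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
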