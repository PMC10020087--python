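"""Gene models: genes, transcripts, exons and CDS intervals.

All coordinates are 0-based half-open on the genomic (plus) strand.
Conversion from the 1-based closed GTF convention happens exactly once,
in :mod:`m6asplice.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Raised for malformed gene models (overlapping exons, bad intervals)."""


@dataclass(frozen=True)
class Transcript:
    """One transcript: ordered, disjoint exons on a contig.

    Exons are stored sorted by genomic start regardless of strand; use
    :meth:`exons_5to3` for transcription order.  ``cds`` is the genomic
    extent of the coding region split by exon, or ``None`` when the
    transcript has no annotated CDS.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        exons = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", exons)
        for s, e in exons:
            if s >= e:
                raise AnnotationError(
                    f"{self.transcript_id}: empty/inverted exon [{s}, {e})"
                )
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons at {e1}/{s2}"
                )
        if self.cds is not None:
            object.__setattr__(self, "cds", tuple(sorted(self.cds)))

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exons_5to3(self) -> tuple[Interval, ...]:
        """Exons in transcription order (reversed on the minus strand)."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def introns(self) -> tuple[Interval, ...]:
        """Intron intervals in genomic order: (donor_end, acceptor_start) pairs."""
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def genomic_to_mrna(self, pos: int) -> int:
        """Map a genomic position inside an exon to mRNA (5'->3') coordinates."""
        offset = 0
        for s, e in self.exons_5to3():
            if s <= pos < e:
                return offset + (pos - s if self.strand == "+" else e - 1 - pos)
            offset += e - s
        raise ValueError(f"position {pos} not exonic in {self.transcript_id}")


@dataclass
class Gene:
    gene_id: str
    contig: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts.values())

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts.values())


@dataclass
class GeneAnnotation:
    """A set of genes with their transcript models, plus contig lengths."""

    genes: dict[str, Gene] = field(default_factory=dict)
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def add_transcript(self, tx: Transcript) -> None:
        gene = self.genes.get(tx.gene_id)
        if gene is None:
            gene = Gene(gene_id=tx.gene_id, contig=tx.contig, strand=tx.strand)
            self.genes[tx.gene_id] = gene
        elif gene.contig != tx.contig or gene.strand != tx.strand:
            raise AnnotationError(
                f"{tx.transcript_id}: contig/strand differs from gene {tx.gene_id}"
            )
        gene.transcripts[tx.transcript_id] = tx

    @property
    def transcripts(self) -> dict[str, Transcript]:
        return {
            tid: tx
            for g in self.genes.values()
            for tid, tx in g.transcripts.items()
        }

    def __len__(self) -> int:
        return len(self.genes)
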