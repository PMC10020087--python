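"""Alternative-splicing event calculus and PTC/NMD classification.

Seven local event classes are derived from a gene's transcript models by
pairwise structural comparison, SUPPA-style:

* ``SE`` — skipped (cassette) exon
* ``RI`` — retained intron
* ``MX`` — mutually exclusive exons
* ``A5``/``A3`` — alternative 5'/3' splice site (strand-mirrored)
* ``AF``/``AL`` — alternative first/last exon (strand-mirrored)

Each event carries the transcript sets compatible with its inclusion and
exclusion forms; "inclusion" means, by convention, the form with more exonic
sequence (SE: exon in; RI: intron retained; A5/A3: the longer exon; MX/AF/AL:
the genomically left alternative exon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation import GeneAnnotation, Gene, Interval, Transcript

EVENT_TYPES = ("SE", "RI", "MX", "A5", "A3", "AF", "AL")


@dataclass(frozen=True)
class ASEvent:
    """One alternative-splicing event within a gene."""

    event_id: str
    event_type: str
    gene_id: str
    contig: str
    strand: str
    inclusion_transcripts: frozenset[str]
    exclusion_transcripts: frozenset[str]
    coordinates: tuple[int, ...]
    #: flanking introns of the cassette exon (SE events only)
    flanking_introns: tuple[Interval, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not self.inclusion_transcripts or not self.exclusion_transcripts:
            raise ValueError(f"{self.event_id}: empty inclusion/exclusion set")
        if self.inclusion_transcripts & self.exclusion_transcripts:
            raise ValueError(f"{self.event_id}: overlapping transcript sets")


@dataclass(frozen=True)
class NMDFlag:
    """PTC classification of a coding transcript (50-nt rule)."""

    transcript_id: str
    is_ptc: bool
    stop_to_last_junction_distance: int


# --- structural predicates -------------------------------------------------

def _has_junction(tx: Transcript, donor: int, acceptor: int) -> bool:
    return (donor, acceptor) in tx.introns()


def _has_exon(tx: Transcript, start: int, end: int) -> bool:
    return (start, end) in tx.exons


def _covers(tx: Transcript, start: int, end: int) -> bool:
    """True if a single exon of ``tx`` covers [start, end) entirely."""
    return any(es <= start and end <= ee for es, ee in tx.exons)


# --- candidate generation --------------------------------------------------
# Each candidate is (event_type, coordinates, inclusion_pred, exclusion_pred,
# flanking_introns).  Generators emit canonical keys so that scanning both
# orders of a transcript pair cannot duplicate an event.

def _candidates_from_pair(t_a: Transcript, t_b: Transcript, strand: str):
    out = []
    for t1, t2 in ((t_a, t_b), (t_b, t_a)):
        introns1 = t1.introns()
        # SE: t1 shows C1-A-C2 with two junctions, t2 skips straight C1-C2
        for i in range(len(introns1) - 1):
            (d, x), (y, a) = introns1[i], introns1[i + 1]
            if _has_exon(t1, x, y) and _has_junction(t2, d, a):
                out.append((
                    "SE", (d, x, y, a),
                    lambda tx, d=d, x=x, y=y, a=a: _has_junction(tx, d, x)
                    and _has_junction(tx, y, a) and _has_exon(tx, x, y),
                    lambda tx, d=d, a=a: _has_junction(tx, d, a),
                    ((d, x), (y, a)),
                ))
        # RI: t2 splices (d, a), t1 retains it inside one exon spanning s..e
        for d, a in t2.introns():
            left = next((e for e in t2.exons if e[1] == d), None)
            right = next((e for e in t2.exons if e[0] == a), None)
            if left is None or right is None:
                continue
            s, e = left[0], right[1]
            if _has_exon(t1, s, e):
                out.append((
                    "RI", (s, d, a, e),
                    lambda tx, d=d, a=a: _covers(tx, d, a),
                    lambda tx, d=d, a=a: _has_junction(tx, d, a),
                    (),
                ))
    # A5/A3: introns sharing one boundary, variable region exonic in the
    # longer-exon form.  Donor-side difference = A5 on '+', A3 on '-'.
    for d1, a1 in t_a.introns():
        for d2, a2 in t_b.introns():
            if a1 == a2 and d1 != d2:
                dmin, dmax = sorted((d1, d2))
                long_tx = t_a if d1 == dmax else t_b
                if any(ee == dmax and es <= dmin for es, ee in long_tx.exons):
                    etype = "A5" if strand == "+" else "A3"
                    out.append((
                        etype, (dmin, dmax, a1),
                        lambda tx, dmin=dmin, dmax=dmax, a=a1:
                            _has_junction(tx, dmax, a) and _covers(tx, dmin, dmax),
                        lambda tx, dmin=dmin, a=a1: _has_junction(tx, dmin, a),
                        (),
                    ))
            if d1 == d2 and a1 != a2:
                amin, amax = sorted((a1, a2))
                long_tx = t_a if a1 == amin else t_b
                if any(es == amin and ee >= amax for es, ee in long_tx.exons):
                    etype = "A3" if strand == "+" else "A5"
                    out.append((
                        etype, (d1, amin, amax),
                        lambda tx, d=d1, amin=amin, amax=amax:
                            _has_junction(tx, d, amin) and _covers(tx, amin, amax),
                        lambda tx, d=d1, amax=amax: _has_junction(tx, d, amax),
                        (),
                    ))
    # MX: C1-A-C2 vs C1-B-C2 with disjoint internal exons sharing flanks
    for t1, t2 in ((t_a, t_b),):
        for i in range(len(t1.introns()) - 1):
            (c1e, As), (Ae, c2s) = t1.introns()[i], t1.introns()[i + 1]
            if not _has_exon(t1, As, Ae):
                continue
            for j in range(len(t2.introns()) - 1):
                (c1e2, Bs), (Be, c2s2) = t2.introns()[j], t2.introns()[j + 1]
                if c1e2 != c1e or c2s2 != c2s or not _has_exon(t2, Bs, Be):
                    continue
                if (As, Ae) == (Bs, Be):
                    continue
                # canonical order: left exon first; require disjoint exons
                (ls, le), (rs, re) = sorted(((As, Ae), (Bs, Be)))
                if le > rs:
                    continue
                out.append((
                    "MX", (c1e, ls, le, rs, re, c2s),
                    lambda tx, c1e=c1e, ls=ls, le=le, c2s=c2s:
                        _has_junction(tx, c1e, ls) and _has_junction(tx, le, c2s)
                        and _has_exon(tx, ls, le),
                    lambda tx, c1e=c1e, rs=rs, re=re, c2s=c2s:
                        _has_junction(tx, c1e, rs) and _has_junction(tx, re, c2s)
                        and _has_exon(tx, rs, re),
                    (),
                ))
    # AF/AL: distinct terminal exons joined to a shared internal splice site.
    # Genomic-left terminal = first exon on '+' (AF) / last exon on '-' (AL).
    for left_side in (True, False):
        e1 = t_a.exons[0] if left_side else t_a.exons[-1]
        e2 = t_b.exons[0] if left_side else t_b.exons[-1]
        if e1 == e2 or len(t_a.exons) < 2 or len(t_b.exons) < 2:
            continue
        if not (e1[1] <= e2[0] or e2[1] <= e1[0]):  # must be disjoint
            continue
        if left_side:
            a1 = t_a.introns()[0][1]
            a2 = t_b.introns()[0][1]
            if a1 != a2:
                continue
            etype = "AF" if strand == "+" else "AL"
            (ls, le), (rs, re) = sorted((e1, e2))
            out.append((
                etype, (ls, le, rs, re, a1),
                lambda tx, ls=ls, le=le, a=a1:
                    _has_exon(tx, ls, le) and _has_junction(tx, le, a)
                    and tx.exons[0] == (ls, le),
                lambda tx, rs=rs, re=re, a=a1:
                    _has_exon(tx, rs, re) and _has_junction(tx, re, a)
                    and tx.exons[0] == (rs, re),
                (),
            ))
        else:
            d1 = t_a.introns()[-1][0]
            d2 = t_b.introns()[-1][0]
            if d1 != d2:
                continue
            etype = "AL" if strand == "+" else "AF"
            (ls, le), (rs, re) = sorted((e1, e2))
            out.append((
                etype, (d1, ls, le, rs, re),
                lambda tx, d=d1, ls=ls, le=le:
                    _has_exon(tx, ls, le) and _has_junction(tx, d, ls)
                    and tx.exons[-1] == (ls, le),
                lambda tx, d=d1, rs=rs, re=re:
                    _has_exon(tx, rs, re) and _has_junction(tx, d, rs)
                    and tx.exons[-1] == (rs, re),
                (),
            ))
    return out


def _event_id(gene: Gene, etype: str, coords: tuple[int, ...]) -> str:
    coord_str = "-".join(str(c) for c in coords)
    return f"{gene.gene_id};{etype}:{gene.contig}:{coord_str}:{gene.strand}"


def build_events(annotation: GeneAnnotation) -> list[ASEvent]:
    """Enumerate AS events across all genes of an annotation.

    Every local structural difference between two transcripts of a gene is
    emitted as exactly one event of the matching class; inclusion/exclusion
    sets contain all of the gene's transcripts compatible with each form.
    Genes with a single transcript yield nothing.  Output is sorted by
    event_id and invariant to transcript input order.
    """
    events: list[ASEvent] = []
    for gene in annotation.genes.values():
        txs = sorted(gene.transcripts.values(), key=lambda t: t.transcript_id)
        if len(txs) < 2:
            continue
        seen: dict[tuple, tuple] = {}
        for i in range(len(txs)):
            for j in range(i + 1, len(txs)):
                for etype, coords, inc_p, exc_p, flanks in _candidates_from_pair(
                    txs[i], txs[j], gene.strand
                ):
                    seen.setdefault((etype, coords), (inc_p, exc_p, flanks))
        for (etype, coords), (inc_p, exc_p, flanks) in seen.items():
            inc = frozenset(t.transcript_id for t in txs if inc_p(t))
            exc = frozenset(t.transcript_id for t in txs if exc_p(t))
            # a transcript cannot satisfy both structural forms; guard anyway
            inc, exc = inc - exc, exc - inc
            if not inc or not exc:
                continue
            events.append(ASEvent(
                event_id=_event_id(gene, etype, coords),
                event_type=etype,
                gene_id=gene.gene_id,
                contig=gene.contig,
                strand=gene.strand,
                inclusion_transcripts=inc,
                exclusion_transcripts=exc,
                coordinates=coords,
                flanking_introns=flanks,
            ))
    events.sort(key=lambda e: e.event_id)
    return events


def flag_nmd(annotation: GeneAnnotation, min_distance: int = 50) -> list[NMDFlag]:
    """Classify coding transcripts as PTC+ by the 50-nt rule.

    The distance is measured in mRNA coordinates from the 3' end of the stop
    codon to the last exon–exon junction; a transcript is PTC+ (predicted
    NMD substrate) when the stop lies strictly more than ``min_distance``
    nucleotides upstream of that junction.  Transcripts without a CDS are
    omitted (flag absent, not false).
    """
    flags = []
    for tid, tx in sorted(annotation.transcripts.items()):
        if tx.cds is None or len(tx.cds) == 0:
            continue
        if len(tx.exons) == 1:
            flags.append(NMDFlag(tid, False, 0))
            continue
        # genomic position of the stop codon's final (3'-most) base
        stop_end = tx.cds[-1][1] - 1 if tx.strand == "+" else tx.cds[0][0]
        p = tx.genomic_to_mrna(stop_end)
        last_junction = tx.length() - (
            tx.exons_5to3()[-1][1] - tx.exons_5to3()[-1][0]
        )
        distance = last_junction - p - 1
        in_last_exon = p >= last_junction
        flags.append(NMDFlag(tid, (not in_last_exon) and distance > min_distance,
                             max(distance, 0) if not in_last_exon else 0))
    return flags
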